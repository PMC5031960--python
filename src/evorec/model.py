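"""Amino-acid substitution models for simulation, distances and likelihood.

A model is a reversible continuous-time Markov chain on the 20 amino acids,
defined by symmetric exchangeabilities and stationary frequencies, normalized
to one expected substitution per unit branch length.  The built-in default is
the uniform-exchangeability ("poisson") model; any empirical matrix (LG, WAG,
...) can be plugged in from a PAML-format ``.dat`` file via
:meth:`ProteinModel.from_paml`.  Rate heterogeneity uses the discrete
Gamma approximation with mean-of-bin category rates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20

# p-distances at or above this cap are treated as saturated and clamped;
# the 20-state correction itself diverges at p = 19/20.
P_DISTANCE_CAP = 0.93


class ModelConfigurationError(ValueError):
    pass


class ProteinModel:
    """Reversible amino-acid substitution model.

    Parameters
    ----------
    exchangeabilities:
        Symmetric (20, 20) array of relative rates (diagonal ignored).
    freqs:
        Stationary frequencies, length 20, summing to 1.
    name:
        Display name.
    """

    def __init__(self, exchangeabilities, freqs, name="custom"):
        R = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(freqs, dtype=float)
        if R.shape != (N_STATES, N_STATES) or pi.shape != (N_STATES,):
            raise ModelConfigurationError("expected 20x20 rates and 20 freqs")
        if not np.allclose(R, R.T):
            raise ModelConfigurationError("exchangeability matrix must be symmetric")
        if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ModelConfigurationError("frequencies must be positive and sum to 1")
        self.name = name
        self.freqs = pi / pi.sum()
        Q = R * self.freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalize to expected rate 1 substitution/site/unit length
        mu = -(self.freqs * np.diag(Q)).sum()
        self.Q = Q / mu
        # symmetrized eigendecomposition for fast, stable matrix exponentials
        sqrt_pi = np.sqrt(self.freqs)
        B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]
        self._right = evecs.T * sqrt_pi[None, :]

    @classmethod
    def poisson(cls) -> "ProteinModel":
        """Uniform exchangeabilities and frequencies (JC-type, 20 states)."""
        R = np.ones((N_STATES, N_STATES))
        return cls(R, np.full(N_STATES, 1.0 / N_STATES), name="poisson")

    @classmethod
    def named(cls, name: str) -> "ProteinModel":
        registry = {"poisson": cls.poisson}
        try:
            return registry[name.lower()]()
        except KeyError:
            raise ModelConfigurationError(
                f"unknown substitution model {name!r}; "
                f"supported: {sorted(registry)} or a PAML .dat file "
                "via ProteinModel.from_paml"
            ) from None

    @classmethod
    def from_paml(cls, path, name=None) -> "ProteinModel":
        """Load an empirical matrix in PAML ``.dat`` layout: 19 lower-triangle
        exchangeability rows followed by the 20 stationary frequencies."""
        values = []
        with open(path) as fh:
            for line in fh:
                values.extend(float(tok) for tok in line.split())
        need = 190 + 20
        if len(values) < need:
            raise ModelConfigurationError(
                f"PAML file {path}: expected at least {need} numbers"
            )
        R = np.zeros((N_STATES, N_STATES))
        k = 0
        for i in range(1, N_STATES):
            for j in range(i):
                R[i, j] = R[j, i] = values[k]
                k += 1
        freqs = np.array(values[k : k + N_STATES])
        return cls(R, freqs / freqs.sum(), name=name or str(path))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the ancestral state."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def expected_p_distance(self, t: float) -> float:
        """Probability that endpoint states of a branch of length t differ."""
        P = self.transition_matrix(t)
        return float(1.0 - (self.freqs * np.diag(P)).sum())


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of the k equal-probability bins of Gamma(alpha, mean 1)."""
    if k == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


def correct_p_distance(p: float) -> float:
    """20-state Jukes-Cantor-type correction d = -(19/20) ln(1 - 20p/19),
    with saturated p clamped at ``P_DISTANCE_CAP``."""
    p = min(p, P_DISTANCE_CAP)
    if p <= 0:
        return 0.0
    return float(-(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0))
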