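"""Goldman–Yang codon rate matrix and transition probabilities.

Instantaneous rates between sense codons i != j:

    q_ij = 0                      if i and j differ at more than one position
         = pi_j                   synonymous transversion
         = kappa * pi_j           synonymous transition
         = omega * pi_j           nonsynonymous transversion
         = omega * kappa * pi_j   nonsynonymous transition

The matrix is rescaled so the expected number of substitutions per codon per
unit time at stationarity is 1 (-sum_i pi_i q_ii = 1), so branch lengths are
in expected substitutions per codon. The chain is time-reversible by
construction (pi_i q_ij = pi_j q_ji), which licenses the symmetric
eigendecomposition used for exp(Qt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..genetics import (
    N_CODONS,
    PAIR_I,
    PAIR_IS_SYNONYMOUS,
    PAIR_IS_TRANSITION,
    PAIR_J,
)


def _symmetric_factors(pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sqrt_pi = np.sqrt(pi)
    return sqrt_pi, 1.0 / sqrt_pi


@dataclass
class CodonRateMatrix:
    kappa: float
    omega: float
    pi: np.ndarray
    Q: np.ndarray = field(init=False)
    #: share of the (unit) stationary rate flux that is synonymous
    rho_syn: float = field(init=False)
    rho_nonsyn: float = field(init=False)
    #: stationary mean rate of the unnormalized matrix (the factor divided
    #: out); site mixtures share one normalization across classes via this
    rate_scale: float = field(init=False)
    _eig: tuple | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (N_CODONS,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("pi must be a positive 61-vector summing to 1")
        self.pi = pi

        rates = pi[PAIR_J].copy()
        rates[PAIR_IS_TRANSITION] *= self.kappa
        rates[~PAIR_IS_SYNONYMOUS] *= self.omega

        Q = np.zeros((N_CODONS, N_CODONS))
        Q[PAIR_I, PAIR_J] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))

        scale = -(pi * np.diag(Q)).sum()
        if scale <= 0:  # omega=0 with kappa tiny cannot occur; guard anyway
            raise ValueError("degenerate rate matrix (zero total flux)")
        Q /= scale
        self.Q = Q
        self.rate_scale = float(scale)

        flux = pi[PAIR_I] * rates / scale
        self.rho_syn = float(flux[PAIR_IS_SYNONYMOUS].sum())
        self.rho_nonsyn = float(flux[~PAIR_IS_SYNONYMOUS].sum())

    # ------------------------------------------------------------- expm

    def _eigendecomposition(self):
        if self._eig is None:
            sqrt_pi, inv_sqrt_pi = _symmetric_factors(self.pi)
            S = (sqrt_pi[:, None] * self.Q) * inv_sqrt_pi[None, :]
            S = 0.5 * (S + S.T)  # symmetrize roundoff
            lam, U = np.linalg.eigh(S)
            # P(t) = D^-1/2 U exp(lam t) U^T D^1/2
            left = inv_sqrt_pi[:, None] * U
            right = U.T * sqrt_pi[None, :]
            self._eig = (lam, left, right)
        return self._eig

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clamped at 0."""
        if t < 0:
            raise ValueError("t must be >= 0")
        lam, left, right = self._eigendecomposition()
        P = (left * np.exp(lam * t)) @ right
        np.clip(P, 0.0, None, out=P)
        return P


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> CodonRateMatrix:
    return CodonRateMatrix(kappa, omega, pi)


def transition_probabilities(Q: CodonRateMatrix, t: float) -> np.ndarray:
    return Q.transition_probabilities(t)


def site_proportions(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Synonymous and nonsynonymous flux shares at omega = 1.

    These are the "site opportunity" proportions used to normalize dN and dS:
    under neutrality the mutation process alone decides how much of the flux
    is synonymous.
    """
    neutral = CodonRateMatrix(kappa, 1.0, pi)
    return neutral.rho_syn, neutral.rho_nonsyn
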