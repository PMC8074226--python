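"""Goldman–Yang-style codon rate matrices.

The instantaneous rate between sense codons i and j is

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

for pairs differing at exactly one nucleotide position, and 0 otherwise.
kappa is the transition/transversion rate ratio, omega the nonsynonymous/
synonymous (dN/dS) ratio, and pi the stationary codon frequencies. The
matrix is rescaled so the expected substitution rate at stationarity is one
per unit time, making branch lengths expected substitutions per codon site.

The model is time-reversible (pi_i q_ij = pi_j q_ji), so transition
probabilities P(t) = exp(Qt) are computed through a symmetric
eigendecomposition — numerically stable and cheap to reuse across branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    IS_NONSYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_NT,
)

_FREQ_TOL = 1e-8


def validate_codon_freqs(codon_freqs: np.ndarray) -> np.ndarray:
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError(f"codon_freqs must have length {N_CODONS}")
    if np.any(pi < 0):
        raise ValueError("codon frequencies must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"codon frequencies sum to {pi.sum():.8f}, not 1")
    # a hard zero breaks the reversible similarity transform; floor and renormalize
    pi = np.maximum(pi, _FREQ_TOL)
    return pi / pi.sum()


@dataclass
class CodonRateModel:
    """A scaled 61x61 codon generator with its spectral decomposition."""

    kappa: float
    omega: float
    codon_freqs: np.ndarray
    Q: np.ndarray = field(init=False)
    _evals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)   # D^{-1/2} V
    _right: np.ndarray = field(init=False, repr=False)  # V^T D^{1/2}

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        pi = validate_codon_freqs(self.codon_freqs)
        self.codon_freqs = pi

        rate = np.where(SINGLE_NT, pi[None, :], 0.0)
        rate = np.where(IS_TRANSITION, rate * self.kappa, rate)
        rate = np.where(IS_NONSYNONYMOUS, rate * self.omega, rate)
        np.fill_diagonal(rate, 0.0)
        np.fill_diagonal(rate, -rate.sum(axis=1))
        mean_rate = -float(np.dot(pi, np.diag(rate)))
        if mean_rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        Q = rate / mean_rate
        self.Q = Q

        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        evals, V = np.linalg.eigh(B)
        self._evals = evals
        self._left = V / sqrt_pi[:, None]
        self._right = V.T * sqrt_pi[None, :]

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt): row-stochastic transition matrix after time t."""
        if t < 0:
            raise ValueError("time must be non-negative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_probabilities_many(self, times: np.ndarray) -> np.ndarray:
        """(n_times, 61, 61) stack of P(t) sharing one eigendecomposition."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        expl = np.exp(times[:, None] * self._evals[None, :])  # (T, 61)
        A = self._left[None, :, :] * expl[:, None, :]  # (T, 61, 61)
        P = A @ self._right
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


def build_rate_matrix(
    kappa: float, omega: float, codon_freqs: np.ndarray
) -> CodonRateModel:
    """Construct the scaled codon rate model (see module docstring)."""
    return CodonRateModel(kappa=kappa, omega=omega, codon_freqs=np.asarray(codon_freqs))


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(aln) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4).

    Counts nucleotides at each codon position over all non-gap, unambiguous
    codons, forms the product distribution over the 61 sense codons and
    renormalizes. This is the default frequency convention of standard
    codon-model software.
    """
    from .genetic_code import CODON_INDEX, SENSE_CODONS

    counts = np.zeros((3, 4))  # positions x TCAG
    nt_index = {n: k for k, n in enumerate("TCAG")}
    for row in aln.codons:
        for codon in row:
            cu = codon.upper()
            if cu not in CODON_INDEX:
                continue
            for pos, nt in enumerate(cu):
                counts[pos, nt_index[nt]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous codons to estimate frequencies from")
    probs = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    pi = np.array(
        [
            probs[0, nt_index[c[0]]] * probs[1, nt_index[c[1]]] * probs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of a generator, by linear solve (test oracle helper)."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi
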