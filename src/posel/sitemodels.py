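"""Site-class (random-sites) models of dN/dS variation across codons.

Each model assigns every codon column to one of a small number of omega
classes with mixture weights:

* **M0** — a single class: one global omega for the whole gene.
* **M2** (M2a variant) — three classes: omega0 in (0,1) (conserved),
  omega1 = 1 (neutral), omega2 >= 1 (positive selection), weights free.
* **M8** — ten equal-weight bins of a Beta(p, q) distribution on (0,1),
  carrying total weight p0, plus an eleventh class at omega_s >= 1 with
  weight 1 - p0.
* **M8a** — M8 with the eleventh class pinned at omega_s = 1; the null
  model of the M8-vs-M8a likelihood ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc

MODEL_NAMES = ("M0", "M2", "M8a", "M8")

N_BETA_BINS = 10


def discretize_beta(p: float, q: float, k: int = N_BETA_BINS) -> tuple[np.ndarray, np.ndarray]:
    """K equal-probability classes of Beta(p, q); class omega = within-bin mean.

    Returns (omega values, weights); weights are all 1/K. The conditional
    mean of Beta(p,q) on (a, b] is  mean * (I_b(p+1,q) - I_a(p+1,q)) / (1/K)
    with I the regularized incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shape parameters must be positive")
    if k < 1:
        raise ValueError("need at least one bin")
    # equal-probability bin edges via the inverse CDF
    from scipy.stats import beta as beta_dist

    probs = np.linspace(0.0, 1.0, k + 1)
    edges = beta_dist.ppf(probs, p, q)
    edges[0], edges[-1] = 0.0, 1.0
    mean = p / (p + q)
    cdf_shift = betainc(p + 1, q, edges)  # CDF of Beta(p+1, q) at the edges
    bin_means = mean * np.diff(cdf_shift) * k
    # pathological shapes can put a bin mass below float resolution; clamp into (0,1)
    bin_means = np.clip(bin_means, 1e-12, 1.0 - 1e-12)
    return bin_means, np.full(k, 1.0 / k)


@dataclass(frozen=True)
class SiteClassModel:
    """A concrete mixture of omega classes (after any discretization)."""

    name: str
    omegas: np.ndarray  # class omega values
    weights: np.ndarray  # class weights, sum to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        om = np.asarray(self.omegas, dtype=float)
        if w.shape != om.shape or w.ndim != 1:
            raise ValueError("omegas and weights must be 1-D and aligned")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(om < 0):
            raise ValueError("omega values must be non-negative")
        object.__setattr__(self, "omegas", om)
        object.__setattr__(self, "weights", w)

    @property
    def n_classes(self) -> int:
        return len(self.omegas)

    def positive_class_index(self) -> int | None:
        """Index of the omega>1 selection class, or None (M0, M8a)."""
        if self.name == "M8":
            return self.n_classes - 1
        if self.name == "M2":
            return self.n_classes - 1
        return None


def m0_model(omega: float) -> SiteClassModel:
    return SiteClassModel("M0", np.array([omega]), np.array([1.0]))


def m2_model(p0: float, p2: float, omega0: float, omega2: float) -> SiteClassModel:
    p1 = 1.0 - p0 - p2
    if p1 < -1e-9:
        raise ValueError("M2 weights exceed 1")
    return SiteClassModel(
        "M2",
        np.array([omega0, 1.0, omega2]),
        np.array([p0, max(p1, 0.0), p2]),
    )


def m8_model(
    p0: float, p: float, q: float, omega_s: float, k: int = N_BETA_BINS
) -> SiteClassModel:
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if omega_s < 1.0:
        raise ValueError("the selection class omega must be >= 1")
    om, w = discretize_beta(p, q, k)
    return SiteClassModel(
        "M8",
        np.append(om, omega_s),
        np.append(w * p0, 1.0 - p0),
    )


def m8a_model(p0: float, p: float, q: float, k: int = N_BETA_BINS) -> SiteClassModel:
    om, w = discretize_beta(p, q, k)
    return SiteClassModel(
        "M8a",
        np.append(om, 1.0),
        np.append(w * p0, 1.0 - p0),
    )
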