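"""Per-gene hypothesis testing for recurrent positive selection.

The central test is the likelihood-ratio comparison of M8 against the
nested null M8a: 2*(lnL_M8 - lnL_M8a) referred to a chi-square distribution
with one degree of freedom, followed by Benjamini-Hochberg control of the
false discovery rate across genes. (The statistic's true null distribution
at the omega_s = 1 boundary is a 50:50 mix of a point mass at 0 and
chi-square(1), so the df=1 reference is conservative; the mixture reference
is available behind a flag.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .fit import FitResult, SitePosteriors

LRT_CLAMP_TOL = 1e-4


class InferenceError(RuntimeError):
    """Raised when fits violate nesting beyond optimizer tolerance."""


def lrt_m8_vs_m8a(
    lnl_m8: float,
    lnl_m8a: float,
    mixture_null: bool = False,
    clamp_tol: float = LRT_CLAMP_TOL,
) -> tuple[float, float]:
    """Likelihood-ratio test statistic and p-value for M8 vs M8a.

    Returns (2*delta lnL, p). Negative statistics within ``clamp_tol`` are
    optimizer noise and are clamped to 0; larger violations indicate an
    upstream optimization failure and raise. With ``mixture_null`` the
    p-value uses the boundary-corrected 50:50 chi2(0):chi2(1) reference
    instead of plain chi2(1).
    """
    if not (np.isfinite(lnl_m8) and np.isfinite(lnl_m8a)):
        raise InferenceError("non-finite log-likelihoods")
    two_delta = 2.0 * (lnl_m8 - lnl_m8a)
    if two_delta < 0:
        if two_delta < -clamp_tol:
            raise InferenceError(
                f"lnL(M8) < lnL(M8a) by {-two_delta / 2:.6g}: refit with more starts"
            )
        two_delta = 0.0
    if mixture_null:
        p = 0.5 * chi2.sf(two_delta, df=1) if two_delta > 0 else 1.0
    else:
        p = float(chi2.sf(two_delta, df=1))
    return two_delta, p


def benjamini_hochberg(p_values, fdr: float = 0.10) -> np.ndarray:
    """Step-up BH significance flags at the given FDR, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return flags


@dataclass
class GeneRecord:
    """Everything the cohort analysis needs about one gene."""

    gene_id: str
    category: str
    lnl_m8: float = np.nan
    lnl_m8a: float = np.nan
    two_delta_lnl: float = np.nan
    p_value: float = np.nan
    bh_significant: bool = False
    omega_m0: float = np.nan
    tree_length_m0: float = np.nan
    pct_sites_omega_gt1_m8: float = np.nan   # 100 * (1 - p0) from the M8 fit
    pct_sites_selected_neb: float = np.nan   # alternative: % sites NEB-assigned to omega_s
    pct_sites_conserved_m2: float = np.nan   # 100 * weight of the omega<1 class in M2
    n_taxa: int = 0
    n_sites_analyzed: int = 0
    complete: bool = False
    selected_sites: list[tuple[int, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.complete:
            assert 0.0 <= self.p_value <= 1.0
            assert self.two_delta_lnl >= 0.0
            assert self.tree_length_m0 >= 0.0


def summarize_gene(
    fits: dict[str, FitResult],
    gene_id: str,
    category: str,
    posteriors: SitePosteriors | None = None,
    mixture_null: bool = False,
) -> GeneRecord:
    """Assemble the per-gene record from the model fits.

    Requires at minimum M8 and M8a; M0 and M2 fill the global-rate and
    conserved-fraction summaries when present. A missing or unconverged fit
    leaves the record flagged incomplete (it is then excluded from cohort
    tests rather than raising).
    """
    rec = GeneRecord(gene_id=gene_id, category=category)
    needed = [m for m in ("M8", "M8a") if m not in fits or not fits[m].converged]
    if needed:
        return rec

    m8, m8a = fits["M8"], fits["M8a"]
    rec.lnl_m8, rec.lnl_m8a = m8.lnl, m8a.lnl
    try:
        rec.two_delta_lnl, rec.p_value = lrt_m8_vs_m8a(
            m8.lnl, m8a.lnl, mixture_null=mixture_null
        )
    except InferenceError:
        return rec
    rec.pct_sites_omega_gt1_m8 = 100.0 * (1.0 - m8.params["p0"])
    rec.n_taxa = m8.tree.n_leaves
    rec.n_sites_analyzed = m8.n_sites_analyzed

    m0 = fits.get("M0")
    if m0 is not None and m0.converged:
        rec.omega_m0 = m0.params["omega"]
        rec.tree_length_m0 = m0.tree_length
    m2 = fits.get("M2")
    if m2 is not None and m2.converged:
        rec.pct_sites_conserved_m2 = 100.0 * m2.site_model.weights[0]

    if posteriors is not None:
        rec.selected_sites = list(posteriors.selected_sites)
        if posteriors.positive_class is not None and len(posteriors.columns):
            rec.pct_sites_selected_neb = 100.0 * float(
                np.mean(posteriors.positive_posterior() > 0.5)
            )
    rec.complete = True
    rec.validate()
    return rec


def apply_bh(records: list[GeneRecord], fdr: float = 0.10) -> list[GeneRecord]:
    """Set bh_significant across all complete records (in place; returns them)."""
    complete = [r for r in records if r.complete]
    flags = benjamini_hochberg([r.p_value for r in complete], fdr=fdr)
    for r, f in zip(complete, flags):
        r.bh_significant = bool(f)
    return records
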