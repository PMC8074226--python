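"""Category-level comparison of selection signatures between gene cohorts.

Genes are grouped into categories (by design: interferon "induction" genes,
interferon-stimulated genes, and a random control set); this module counts
BH-significant genes per category, compares proportions between category
pairs by two-tailed Fisher's exact tests (BH-corrected within the family of
pairwise comparisons), compares continuous per-gene statistics (M0 omega,
site-class occupancies) by two-sample tests, and implements the
size-equalizing resampling in which one category is repeatedly subsampled
to match the others before re-testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact, ks_2samp, mannwhitneyu

from .inference import GeneRecord, benjamini_hochberg

CATEGORIES = ("induction", "isg", "random")


@dataclass
class CategoryCounts:
    n_genes: int
    n_selected: int

    @property
    def proportion(self) -> float:
        return self.n_selected / self.n_genes if self.n_genes else float("nan")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    bh_significant: bool = False

    def higher_category(self) -> str:
        (a_sel, a_not), (b_sel, b_not) = self.table
        pa = a_sel / max(a_sel + a_not, 1)
        pb = b_sel / max(b_sel + b_not, 1)
        return self.pair[0] if pa >= pb else self.pair[1]


@dataclass
class CohortTable:
    counts: dict[str, CategoryCounts]
    comparisons: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {
                c: {
                    "n_genes": v.n_genes,
                    "n_selected": v.n_selected,
                    "proportion": v.proportion,
                }
                for c, v in self.counts.items()
            },
            "comparisons": [
                {
                    "pair": list(c.pair),
                    "table": [list(r) for r in c.table],
                    "p_value": c.p_value,
                    "bh_significant": c.bh_significant,
                }
                for c in self.comparisons
            ],
        }


def count_selected_by_category(
    records: list[GeneRecord], warn: bool = True
) -> CohortTable:
    """Exact per-category counts of BH-flagged genes (complete records only)."""
    counts: dict[str, CategoryCounts] = {}
    for r in records:
        if not r.complete:
            continue
        c = counts.setdefault(r.category, CategoryCounts(0, 0))
        c.n_genes += 1
        c.n_selected += int(r.bh_significant)
    empty = [c for c, v in counts.items() if v.n_genes == 0]
    for c in empty:
        del counts[c]
    return CohortTable(counts=counts)


def fisher_pairwise(table: CohortTable, fdr: float = 0.10) -> CohortTable:
    """Two-tailed Fisher's exact test for every category pair, BH at ``fdr``.

    Each pair forms the 2x2 table [[selected_a, rest_a], [selected_b,
    rest_b]]; the two-tailed p sums hypergeometric tables at most as
    probable as the observed one.
    """
    comparisons = []
    for a, b in itertools.combinations(sorted(table.counts), 2):
        ca, cb = table.counts[a], table.counts[b]
        t = ((ca.n_selected, ca.n_genes - ca.n_selected),
             (cb.n_selected, cb.n_genes - cb.n_selected))
        if min(min(row) for row in t) < 0:
            raise ValueError("negative counts")
        _, p = fisher_exact(t, alternative="two-sided")
        comparisons.append(PairwiseComparison(pair=(a, b), table=t, p_value=float(p)))
    if comparisons:
        flags = benjamini_hochberg([c.p_value for c in comparisons], fdr=fdr)
        for c, f in zip(comparisons, flags):
            c.bh_significant = bool(f)
    table.comparisons = comparisons
    return table


def selected_counts_table(records: list[GeneRecord], fdr: float = 0.10) -> CohortTable:
    return fisher_pairwise(count_selected_by_category(records), fdr=fdr)


@dataclass
class DistributionComparison:
    pair: tuple[str, str]
    test: str
    statistic: float
    p_value: float
    bh_significant: bool = False


def compare_distributions(
    values_by_category: dict[str, np.ndarray],
    test: str = "ks",
    fdr: float = 0.10,
) -> list[DistributionComparison]:
    """Pairwise two-sample comparisons of a per-gene statistic.

    ``test`` is "ks" (two-sample Kolmogorov-Smirnov, exact for small
    samples) or "mann_whitney". BH correction is applied within the family
    of pairwise comparisons.
    """
    clean = {
        c: np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        for c, vals in values_by_category.items()
    }
    for c, v in clean.items():
        if v.size < 2:
            raise ValueError(f"category {c!r} has fewer than 2 observations")
    out = []
    for a, b in itertools.combinations(sorted(clean), 2):
        if test == "ks":
            res = ks_2samp(clean[a], clean[b])
        elif test == "mann_whitney":
            res = mannwhitneyu(clean[a], clean[b], alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        out.append(
            DistributionComparison(
                pair=(a, b),
                test=test,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
            )
        )
    flags = benjamini_hochberg([c.p_value for c in out], fdr=fdr)
    for c, f in zip(out, flags):
        c.bh_significant = bool(f)
    return out


# ---------------------------------------------------------------------------
# Size-equalizing resampling
# ---------------------------------------------------------------------------


@dataclass
class ResamplingResult:
    n_replicates: int
    subsampled_category: str
    subsample_size: int
    seed: int
    patterns: list[frozenset[tuple[str, str]]]  # significant pairs, per replicate
    pattern_counts: dict[str, int]


def classify_pattern(
    significant_pairs: frozenset[tuple[str, str]],
    comparisons: list[PairwiseComparison],
    focus: str = "isg",
) -> str:
    """Label a replicate outcome the way the headline result is phrased:
    the focus category beats only the random set, beats both other sets,
    neither, or something else entirely."""
    higher = {c.pair: c.higher_category() for c in comparisons}
    beats = set()
    for pair in significant_pairs:
        if focus in pair and higher.get(pair) == focus:
            beats.add(pair[0] if pair[1] == focus else pair[1])
    others = {p for pair in higher for p in pair if p != focus}
    if not significant_pairs:
        return "none_significant"
    if beats == others and len(others) > 1:
        return f"{focus}_beats_both"
    if beats == {"random"}:
        return f"{focus}_beats_random_only"
    return "other"


def resample_equalized(
    records: list[GeneRecord],
    subsample_category: str = "induction",
    subsample_size: int = 100,
    n_replicates: int = 100,
    fdr: float = 0.10,
    seed: int = 0,
    focus: str = "isg",
) -> ResamplingResult:
    """Repeatedly subsample one category to equalize sizes and re-test.

    Each replicate draws ``subsample_size`` genes without replacement from
    ``subsample_category``, rebuilds the cohort table with the other
    categories untouched, reruns the pairwise Fisher tests with BH at
    ``fdr``, and records which comparisons came out significant.
    """
    pool = [r for r in records if r.complete and r.category == subsample_category]
    rest = [
        r for r in records if r.complete and r.category != subsample_category
    ]
    if subsample_size > len(pool):
        raise ValueError(
            f"subsample_size {subsample_size} exceeds category size {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    patterns = []
    pattern_counts: dict[str, int] = {}
    for _ in range(n_replicates):
        idx = rng.choice(len(pool), size=subsample_size, replace=False)
        sub = [pool[i] for i in idx] + rest
        table = selected_counts_table(sub, fdr=fdr)
        sig = frozenset(c.pair for c in table.comparisons if c.bh_significant)
        patterns.append(sig)
        label = classify_pattern(sig, table.comparisons, focus=focus)
        pattern_counts[label] = pattern_counts.get(label, 0) + 1
    return ResamplingResult(
        n_replicates=n_replicates,
        subsampled_category=subsample_category,
        subsample_size=subsample_size,
        seed=seed,
        patterns=patterns,
        pattern_counts=pattern_counts,
    )


# ---------------------------------------------------------------------------
# Cohort quality summaries
# ---------------------------------------------------------------------------


@dataclass
class CohortQualitySummary:
    species_presence_pct: dict[str, float]        # % of alignments containing each species
    taxon_counts: dict[str, list[int]]            # per category
    tree_lengths: dict[str, list[float]]          # per category
    mean_tree_length: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "species_presence_pct": self.species_presence_pct,
            "taxon_counts": self.taxon_counts,
            "tree_lengths": self.tree_lengths,
            "mean_tree_length": self.mean_tree_length,
        }


def cohort_quality_summary(
    gene_taxa: dict[str, tuple[str, ...]],
    categories: dict[str, str],
    tree_lengths: dict[str, float],
) -> CohortQualitySummary:
    """Species representation, species-count and tree-length distributions.

    ``gene_taxa`` maps gene id to the taxa present in its alignment,
    ``categories`` to its category, ``tree_lengths`` to its fitted M0 tree
    length.
    """
    n_aln = len(gene_taxa)
    presence: dict[str, int] = {}
    for taxa in gene_taxa.values():
        for t in taxa:
            presence[t] = presence.get(t, 0) + 1
    presence_pct = {t: 100.0 * c / n_aln for t, c in sorted(presence.items())}

    taxon_counts: dict[str, list[int]] = {}
    lengths: dict[str, list[float]] = {}
    for gene, taxa in gene_taxa.items():
        cat = categories[gene]
        taxon_counts.setdefault(cat, []).append(len(taxa))
        if gene in tree_lengths and np.isfinite(tree_lengths[gene]):
            lengths.setdefault(cat, []).append(float(tree_lengths[gene]))
    mean_tl = {
        c: float(np.mean(v)) if v else float("nan") for c, v in lengths.items()
    }
    return CohortQualitySummary(
        species_presence_pct=presence_pct,
        taxon_counts=taxon_counts,
        tree_lengths=lengths,
        mean_tree_length=mean_tl,
    )
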