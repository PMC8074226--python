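"""Phylogenetic likelihood of codon alignments under site-class mixtures.

The likelihood of one codon column under a single omega class is computed by
Felsenstein pruning: partial likelihoods are accumulated leaf-to-root, with
per-node rescaling to avoid underflow. Columns are compressed to unique site
patterns first, and all classes and patterns are evaluated in one batched
pass, so an evaluation costs one 61x61 eigendecomposition per class plus a
handful of batched matrix products.

Columns containing a gap or a masked ambiguous codon in any analyzed taxon
are excluded from the likelihood entirely; ``n_sites_analyzed`` counts the
columns that remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import CodonAlignment
from .genetic_code import N_CODONS
from .rates import CodonRateModel
from .trees import PhyloTree

_TINY = 1e-300


@dataclass
class SitePatterns:
    """Gap-free codon columns compressed to unique patterns."""

    leaf_order: tuple[str, ...]         # taxa, aligned with pattern rows
    patterns: np.ndarray                # (n_leaves, n_patterns) codon indices
    counts: np.ndarray                  # (n_patterns,) column multiplicities
    site_to_pattern: np.ndarray         # (n_sites_analyzed,) pattern index per kept column
    kept_columns: np.ndarray            # (n_sites_analyzed,) original column indices

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_sites_analyzed(self) -> int:
        return len(self.kept_columns)


def compress_alignment(aln: CodonAlignment, taxa: tuple[str, ...]) -> SitePatterns:
    """Extract gap-free columns over the given taxa and collapse duplicates."""
    missing = set(taxa) - set(aln.taxa)
    if missing:
        raise ValueError(f"taxa absent from alignment: {sorted(missing)}")
    rows = [aln.taxa.index(t) for t in taxa]
    idx = aln.codon_indices()[rows]  # (n_leaves, n_cols); -1 = gap/ambiguous
    usable = np.all(idx >= 0, axis=0)
    kept = np.flatnonzero(usable)
    if kept.size == 0:
        raise ValueError("no gap-free codon columns to analyze")
    cols = idx[:, kept]
    uniq, inverse = np.unique(cols.T, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    return SitePatterns(
        leaf_order=tuple(taxa),
        patterns=uniq.T.copy(),
        counts=counts,
        site_to_pattern=inverse,
        kept_columns=kept,
    )


def class_pattern_loglik(
    tree: PhyloTree,
    patterns: SitePatterns,
    class_models: list[CodonRateModel],
) -> np.ndarray:
    """log L_k(pattern) for every class k and unique pattern.

    Returns an (n_classes, n_patterns) array. The root prior is each class's
    stationary distribution (identical across classes when frequencies are
    shared, as they are for all models here).
    """
    name_to_node = tree.leaf_index()
    if set(patterns.leaf_order) != set(tree.leaf_names):
        raise ValueError("tree leaves do not match pattern taxa")
    obs = {
        name_to_node[name]: patterns.patterns[i]
        for i, name in enumerate(patterns.leaf_order)
    }
    n_classes = len(class_models)
    n_pat = patterns.n_patterns

    if tree.n_nodes == 1:  # degenerate single-leaf "tree": L = pi_codon
        (only,) = obs
        return np.stack(
            [np.log(m.codon_freqs[obs[only]]) for m in class_models]
        )

    # PT[k, node] = transposed transition matrix along the edge above `node`
    # under class k: PT[x, y] = P(y -> x), the layout pruning consumes.
    PT = np.empty((n_classes, tree.n_nodes, N_CODONS, N_CODONS))
    for k, m in enumerate(class_models):
        PT[k] = m.transition_probabilities_many(tree.edge_length).transpose(0, 2, 1)

    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((n_classes, n_pat))
    leaf_set = set(int(i) for i in tree.leaf_ids)
    for node in range(tree.n_nodes):
        kids = tree.children[node]
        if not kids:
            continue
        acc: np.ndarray | None = None
        for c in kids:
            if c in leaf_set:
                # sum_y P(x,y) 1[y=obs] = P[:, x, obs] = PT[:, obs, x]
                contrib = PT[:, c][:, obs[c], :]
            else:
                contrib = partial.pop(c) @ PT[:, c]
            if acc is None:
                acc = contrib
            else:
                acc *= contrib
        assert acc is not None
        scale = acc.max(axis=2)
        safe = np.where(scale > 0, scale, 1.0)
        acc /= safe[:, :, None]
        logscale += np.log(safe)
        partial[node] = acc

    root_partial = partial[tree.root]
    pi = np.stack([m.codon_freqs for m in class_models])  # (k, 61)
    site_lik = np.einsum("kpc,kc->kp", root_partial, pi)
    return np.log(np.maximum(site_lik, _TINY)) + logscale


def mixture_loglik(
    logl_kp: np.ndarray, weights: np.ndarray, counts: np.ndarray
) -> float:
    """Total lnL: sum over patterns of count * log sum_k w_k L_k(pattern)."""
    w = np.asarray(weights, dtype=float)
    logw = np.where(w > 0, np.log(np.maximum(w, _TINY)), -np.inf)
    per_pattern = logsumexp(logl_kp + logw[:, None], axis=0)
    return float(np.dot(per_pattern, counts))


def site_log_likelihood(
    column: dict[str, int],
    tree: PhyloTree,
    class_models: list[CodonRateModel],
    class_weights: np.ndarray,
) -> float:
    """Log-likelihood of a single gap-free codon column under the mixture.

    ``column`` maps taxon name to sense-codon index (0..60).
    """
    if set(column) != set(tree.leaf_names):
        raise ValueError("column taxa do not match tree leaves")
    if any(v < 0 or v >= N_CODONS for v in column.values()):
        raise ValueError("column must be gap-free sense codons")
    order = tuple(tree.leaf_names)
    pats = SitePatterns(
        leaf_order=order,
        patterns=np.array([[column[t]] for t in order]),
        counts=np.ones(1),
        site_to_pattern=np.zeros(1, dtype=int),
        kept_columns=np.zeros(1, dtype=int),
    )
    logl = class_pattern_loglik(tree, pats, class_models)
    return mixture_loglik(logl, class_weights, pats.counts)


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    class_models: list[CodonRateModel],
    class_weights: np.ndarray,
) -> tuple[float, int]:
    """Alignment lnL under a site-class mixture; returns (lnL, n_sites_analyzed)."""
    pats = compress_alignment(aln, tuple(tree.leaf_names))
    logl = class_pattern_loglik(tree, pats, class_models)
    return mixture_loglik(logl, class_weights, pats.counts), pats.n_sites_analyzed
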