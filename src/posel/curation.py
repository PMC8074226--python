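"""Alignment pruning and quality control.

A six-rule curation pipeline for codon alignments of closely related
orthologs, where poor local alignment almost always indicates
mis-annotation rather than genuine divergence:

0. codons containing the ambiguity character 'n' are masked to gaps
   (downstream likelihoods skip gapped columns anyway);
1. orthologs with a single contiguous gap covering more than a threshold
   fraction (default 10%) of the reference's ungapped length are removed —
   multiple shorter gaps are tolerated;
2. orthologs that align poorly to the consensus of the remaining rows over
   a contiguous stretch longer than the same fraction are removed;
3. terminal regions are trimmed when too few rows share the reference's
   start or termination site, stopping at the first conserved column (or
   one whose variation is compatible with a single mutation on the supplied
   tree);
4. codon columns at gap edges where more than one residue disagrees with
   the column majority are deleted;
5. runs of more than four residues in one row matching no other row are
   masked in that row;
6. alignments left with fewer than a minimum number of rows (default 10,
   reference included) are rejected.

All thresholds use strict inequalities. Every change is recorded in a
machine-readable report whose replay reproduces the output exactly. The
full pipeline iterates the rule sequence to a fixed point so that curation
is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .genetic_code import GAP_CODON
from .trees import PhyloTree

# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCEntry:
    """One atomic change: drop a taxon, delete columns, or mask codons.

    Column coordinates are 0-based and refer to the alignment state at the
    time the entry was applied (entries replay sequentially).
    """

    step: str
    action: str  # drop_taxon | delete_columns | mask_codons
    taxon: str | None = None
    columns: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "action": self.action,
            "taxon": self.taxon,
            "columns": list(self.columns),
        }


@dataclass
class QCReport:
    entries: list[QCEntry] = field(default_factory=list)
    status: str = "retained"  # retained | rejected_too_few_orthologs
    n_taxa_final: int = 0

    def extend(self, entries: list[QCEntry]) -> None:
        self.entries.extend(entries)

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "n_taxa_final": self.n_taxa_final,
            "entries": [e.to_dict() for e in self.entries],
        }


def report_to_rows(report: QCReport) -> list[dict]:
    """Flatten a report for TSV output (one row per entry, 1-based columns)."""
    rows = []
    for e in report.entries:
        rows.append(
            {
                "step": e.step,
                "action": e.action,
                "taxon": e.taxon or "",
                "n_columns": len(e.columns),
                "columns_1based": ",".join(str(c + 1) for c in e.columns),
            }
        )
    return rows


def replay_report(aln: CodonAlignment, report: QCReport) -> CodonAlignment | None:
    """Re-apply a QC report to its input; returns the curated alignment
    (or None if the report ends in rejection)."""
    cur = aln
    for e in report.entries:
        if e.action == "drop_taxon":
            cur = cur.drop_taxa({e.taxon})
        elif e.action == "delete_columns":
            cur = cur.drop_columns(np.array(e.columns, dtype=int))
        elif e.action == "mask_codons":
            codons = cur.codons.copy()
            codons[cur.taxa.index(e.taxon), list(e.columns)] = GAP_CODON
            cur = cur.with_codons(codons)
        else:
            raise ValueError(f"unknown action {e.action!r}")
    if report.status != "retained":
        return None
    return cur


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open intervals."""
    out = []
    in_run, start = False, 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def _consensus_of_others(aa: np.ndarray, row: int) -> np.ndarray:
    """Per-column majority residue among all rows but `row` ('' if none)."""
    n_cols = aa.shape[1]
    out = np.empty(n_cols, dtype="<U1")
    others = np.delete(aa, row, axis=0)
    for j in range(n_cols):
        col = others[:, j]
        col = col[(col != "-") & (col != "X")]
        if col.size == 0:
            out[j] = ""
            continue
        vals, counts = np.unique(col, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        out[j] = winners[0] if len(winners) == 1 else ""
    return out


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------


def mask_ambiguous(aln: CodonAlignment) -> tuple[CodonAlignment, list[QCEntry]]:
    """Replace every codon containing 'n' with the gap codon."""
    amb = aln.is_ambiguous()
    if not amb.any():
        return aln, []
    codons = aln.codons.copy()
    codons[amb] = GAP_CODON
    entries = [
        QCEntry(
            step="mask_ambiguous",
            action="mask_codons",
            taxon=aln.taxa[r],
            columns=tuple(int(c) for c in np.flatnonzero(amb[r])),
        )
        for r in range(aln.n_taxa)
        if amb[r].any()
    ]
    return aln.with_codons(codons), entries


def drop_long_gap_orthologs(
    aln: CodonAlignment, threshold: float = 0.10
) -> tuple[CodonAlignment, list[QCEntry]]:
    """Remove rows with one contiguous gap > threshold of the reference length.

    A gap run is measured as the number of its columns at which the
    reference has sequence (missing sequence relative to the reference);
    the inequality is strict, so a run of exactly the threshold survives.
    """
    ref_len = aln.reference_ungapped_length()
    limit = threshold * ref_len
    ref_has_seq = aln.reference_row != GAP_CODON
    gaps = aln.is_gap()
    to_drop = []
    for r, taxon in enumerate(aln.taxa):
        if taxon == aln.reference_taxon:
            continue
        for s, e in _runs(gaps[r]):
            if int(ref_has_seq[s:e].sum()) > limit:
                to_drop.append(taxon)
                break
    entries = [
        QCEntry(step="drop_long_gap", action="drop_taxon", taxon=t) for t in to_drop
    ]
    return (aln.drop_taxa(set(to_drop)) if to_drop else aln), entries


def drop_misaligned_orthologs(
    aln: CodonAlignment,
    stretch_fraction: float = 0.10,
    identity_threshold: float = 0.5,
    window: int = 15,
) -> tuple[CodonAlignment, list[QCEntry]]:
    """Remove rows with a long contiguous stretch of poor alignment.

    Poor alignment is judged per residue as a sliding-window amino-acid
    identity to the column consensus of all other rows falling below
    ``identity_threshold``; a row is removed when a contiguous poor stretch
    exceeds ``stretch_fraction`` of the reference's ungapped length.
    Rows are judged against the original alignment in a single pass.
    """
    if aln.n_taxa < 3:
        return aln, []
    aa = aln.amino_acids()
    ref_len = aln.reference_ungapped_length()
    limit = stretch_fraction * ref_len
    to_drop = []
    for r, taxon in enumerate(aln.taxa):
        if taxon == aln.reference_taxon:
            continue
        consensus = _consensus_of_others(aa, r)
        defined = (aa[r] != "-") & (consensus != "")
        cols = np.flatnonzero(defined)
        if cols.size < window:
            continue
        match = (aa[r][cols] == consensus[cols]).astype(float)
        kernel = np.ones(window) / window
        ident = np.convolve(match, kernel, mode="same")
        poor_cols = cols[ident < identity_threshold]
        if poor_cols.size == 0:
            continue
        poor = np.zeros(aln.length_codons, dtype=bool)
        poor[poor_cols] = True
        longest = max((e - s) for s, e in _runs(poor))
        if longest > limit:
            to_drop.append(taxon)
    entries = [
        QCEntry(step="drop_misaligned", action="drop_taxon", taxon=t) for t in to_drop
    ]
    return (aln.drop_taxa(set(to_drop)) if to_drop else aln), entries


def _is_conserved_column(
    aa_col: np.ndarray, taxa: tuple[str, ...], tree: PhyloTree | None
) -> bool:
    """Fully conserved: no gaps and a single residue. With a tree, a column
    whose two-state partition is compatible with one mutation on one edge
    (the minority state forms a clade) also stops trimming."""
    if np.any(aa_col == "-") or np.any(aa_col == "X"):
        return False
    states = np.unique(aa_col)
    if len(states) == 1:
        return True
    if tree is None or len(states) != 2:
        return False
    clades = _clade_sets(tree)
    for st in states:
        members = frozenset(t for t, a in zip(taxa, aa_col) if a == st)
        if members in clades:
            return True
    return False


def _clade_sets(tree: PhyloTree) -> set[frozenset[str]]:
    names = {int(i): n for i, n in zip(tree.leaf_ids, tree.leaf_names)}
    below: dict[int, set[str]] = {}
    out: set[frozenset[str]] = set()
    for node in range(tree.n_nodes):
        if not tree.children[node]:
            below[node] = {names[node]}
        else:
            s: set[str] = set()
            for c in tree.children[node]:
                s |= below[c]
            below[node] = s
        out.add(frozenset(below[node]))
    return out


def trim_termini(
    aln: CodonAlignment,
    min_concordant: int = 10,
    tree: PhyloTree | None = None,
) -> tuple[CodonAlignment, list[QCEntry]]:
    """Trim terminal columns when too few rows share the reference's
    start/termination site, stopping at the first conserved column."""
    non_gap = ~aln.is_gap()
    if not non_gap[aln.taxa.index(aln.reference_taxon)].any():
        return aln, []
    aa = aln.amino_acids()
    first = np.argmax(non_gap, axis=1)
    last = aln.length_codons - 1 - np.argmax(non_gap[:, ::-1], axis=1)
    ref_r = aln.taxa.index(aln.reference_taxon)

    drop: set[int] = set()
    if int((first == first[ref_r]).sum()) < min_concordant:
        for j in range(aln.length_codons):
            if _is_conserved_column(aa[:, j], aln.taxa, tree):
                drop.update(range(0, j))
                break
    if int((last == last[ref_r]).sum()) < min_concordant:
        for j in range(aln.length_codons - 1, -1, -1):
            if _is_conserved_column(aa[:, j], aln.taxa, tree):
                drop.update(range(j + 1, aln.length_codons))
                break
    if not drop:
        return aln, []
    cols = tuple(sorted(drop))
    entry = QCEntry(step="trim_termini", action="delete_columns", columns=cols)
    return aln.drop_columns(np.array(cols, dtype=int)), [entry]


def scrub_gap_edges(aln: CodonAlignment) -> tuple[CodonAlignment, list[QCEntry]]:
    """Delete codon columns at gap edges where >1 residue misaligns.

    A gap-edge column is a non-gap column immediately adjacent to a gap run
    in any row. The column is deleted when more than one of its residues
    disagrees with the column's majority residue (a tied majority counts
    everything beyond the largest group as disagreement).
    """
    gaps = aln.is_gap()
    edge_cols: set[int] = set()
    for r in range(aln.n_taxa):
        for s, e in _runs(gaps[r]):
            if s - 1 >= 0:
                edge_cols.add(s - 1)
            if e < aln.length_codons:
                edge_cols.add(e)
    if not edge_cols:
        return aln, []
    aa = aln.amino_acids()
    to_delete = []
    for j in sorted(edge_cols):
        col = aa[:, j]
        col = col[(col != "-") & (col != "X")]
        if col.size == 0:
            continue
        vals, counts = np.unique(col, return_counts=True)
        best = int(counts.max())
        tie = int((counts == best).sum()) > 1
        if tie:
            delete = len(vals) >= 2  # no majority at all
        else:
            delete = (col.size - best) > 1  # "more than one" is strict
        if delete:
            to_delete.append(j)
    if not to_delete:
        return aln, []
    entry = QCEntry(
        step="scrub_gap_edges", action="delete_columns", columns=tuple(to_delete)
    )
    return aln.drop_columns(np.array(to_delete, dtype=int)), [entry]


def remove_orphan_runs(
    aln: CodonAlignment, run_threshold: int = 4
) -> tuple[CodonAlignment, list[QCEntry]]:
    """Mask runs of more than ``run_threshold`` consecutive residues in one
    row that match no other row at their columns (strict inequality).
    Residue adjacency follows the row's own sequence, skipping its gaps.
    The reference row is never masked."""
    aa = aln.amino_acids()
    codons = aln.codons.copy()
    entries = []
    ref_r = aln.taxa.index(aln.reference_taxon)
    for r, taxon in enumerate(aln.taxa):
        if r == ref_r:
            continue
        cols = np.flatnonzero(aa[r] != "-")
        if cols.size == 0:
            continue
        orphan = np.empty(cols.size, dtype=bool)
        for k, j in enumerate(cols):
            others = np.delete(aa[:, j], r)
            orphan[k] = not np.any(others == aa[r, j])
        masked_cols: list[int] = []
        for s, e in _runs(orphan):
            if e - s > run_threshold:
                masked_cols.extend(int(c) for c in cols[s:e])
        if masked_cols:
            codons[r, masked_cols] = GAP_CODON
            entries.append(
                QCEntry(
                    step="remove_orphan_runs",
                    action="mask_codons",
                    taxon=taxon,
                    columns=tuple(masked_cols),
                )
            )
    if not entries:
        return aln, []
    return aln.with_codons(codons), entries


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class QCConfig:
    long_gap_threshold: float = 0.10
    stretch_fraction: float = 0.10
    identity_threshold: float = 0.5
    window: int = 15
    min_concordant: int = 10
    orphan_run_threshold: int = 4
    min_orthologs: int = 10
    max_sweeps: int = 10


def apply_qc_pipeline(
    aln: CodonAlignment,
    config: QCConfig | None = None,
    tree: PhyloTree | None = None,
) -> tuple[CodonAlignment | None, QCReport]:
    """Run the full curation sequence; returns (alignment | None, report).

    The rule sequence (mask 'n' -> long gaps -> misaligned stretches ->
    terminal trim -> gap-edge scrub -> orphan runs) is iterated until no rule
    changes the alignment, then the minimum-ortholog rule decides retention.
    Rejection is a reported status, not an error.
    """
    cfg = config or QCConfig()
    report = QCReport()
    cur = aln
    for _ in range(cfg.max_sweeps):
        changed = False
        for step in (
            lambda a: mask_ambiguous(a),
            lambda a: drop_long_gap_orthologs(a, cfg.long_gap_threshold),
            lambda a: drop_misaligned_orthologs(
                a, cfg.stretch_fraction, cfg.identity_threshold, cfg.window
            ),
            lambda a: trim_termini(a, cfg.min_concordant, tree),
            lambda a: scrub_gap_edges(a),
            lambda a: remove_orphan_runs(a, cfg.orphan_run_threshold),
        ):
            cur, entries = step(cur)
            if entries:
                report.extend(entries)
                changed = True
        if not changed:
            break
    report.n_taxa_final = cur.n_taxa
    if cur.n_taxa < cfg.min_orthologs:
        report.status = "rejected_too_few_orthologs"
        return None, report
    report.status = "retained"
    return cur, report
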