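"""Synthetic codon alignments with known evolutionary ground truth.

This module generates the study material for the rest of the package:
codon alignments evolved on a primate-like species tree under the same
site-class substitution models the inference code fits (one shared rate-
matrix implementation, so simulation and inference cannot drift apart),
plus controlled alignment defects that exercise each curation rule, and
whole synthetic gene cohorts mirroring the induction / interferon-
stimulated / random category design.

Gaps are injected as defects, never evolved: there is no indel process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import CodonAlignment
from .fit import build_class_models
from .genetic_code import CODON_AA, GAP_CODON, N_CODONS, SENSE_CODONS
from .rates import validate_codon_freqs
from .sitemodels import SiteClassModel, m8_model, m8a_model
from .trees import PhyloTree

REFERENCE_TAXON = "Homo_sapiens"

# A 20-species simian primate tree: apes, Old World monkeys and New World
# monkeys with a plausible topology. Branch lengths are synthetic package
# fixtures in expected substitutions per codon site, chosen to give tree
# lengths of simian magnitude (~1.9 per codon site); they are not estimates
# from any published dataset.
_DEFAULT_PRIMATE_NEWICK = (
    "((((((Homo_sapiens:0.040,(Pan_troglodytes:0.016,Pan_paniscus:0.016):0.024):0.012,"
    "Gorilla_gorilla:0.050):0.024,Pongo_abelii:0.090):0.016,Nomascus_leucogenys:0.100):0.050,"
    "((((Macaca_mulatta:0.024,Macaca_fascicularis:0.024):0.030,((Papio_anubis:0.040,"
    "Mandrillus_leucophaeus:0.040):0.012,Cercocebus_atys:0.044):0.012):0.016,"
    "Chlorocebus_sabaeus:0.070):0.024,((Colobus_angolensis:0.060,"
    "Piliocolobus_tephrosceles:0.056):0.016,Rhinopithecus_bieti:0.064):0.024):0.060):0.080,"
    "((Callithrix_jacchus:0.120,Saimiri_boliviensis:0.110):0.020,(Cebus_capucinus:0.100,"
    "(Aotus_nancymaae:0.090,Ateles_geoffroyi:0.110):0.016):0.020):0.200);"
)


def default_primate_tree() -> PhyloTree:
    """The packaged 20-leaf primate-like master tree (deterministic)."""
    return PhyloTree.from_newick(_DEFAULT_PRIMATE_NEWICK)


def default_codon_freqs() -> np.ndarray:
    """Mildly non-uniform codon frequencies (product of GC-biased nucleotide
    frequencies over the 61 sense codons), the generator's default stationary
    distribution."""
    nt = {"T": 0.22, "C": 0.26, "A": 0.24, "G": 0.28}
    pi = np.array([nt[c[0]] * nt[c[1]] * nt[c[2]] for c in SENSE_CODONS])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    tree: PhyloTree
    n_codons: int
    site_model: SiteClassModel
    kappa: float = 3.0
    codon_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.codon_freqs is None:
            self.codon_freqs = default_codon_freqs()
        self.codon_freqs = validate_codon_freqs(self.codon_freqs)


def simulate_alignment(spec: SimulationSpec) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codons down the tree; returns (alignment, true class per site).

    Each site draws an omega class from the model weights and a root codon
    from the stationary frequencies, then evolves along every branch with the
    transition probabilities of the corresponding class rate matrix.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    model = spec.site_model
    n = spec.n_codons

    class_models = build_class_models(model, spec.kappa, spec.codon_freqs)
    site_class = rng.choice(model.n_classes, size=n, p=model.weights)
    states = np.empty((tree.n_nodes, n), dtype=np.int64)
    states[tree.root] = rng.choice(N_CODONS, size=n, p=spec.codon_freqs)

    for node in range(tree.n_nodes - 1, -1, -1):  # root-to-tips (reverse postorder)
        for child in tree.children[node]:
            t = float(tree.edge_length[child])
            if t == 0.0:
                states[child] = states[node]
                continue
            child_state = np.empty(n, dtype=np.int64)
            for k in range(model.n_classes):
                sel = site_class == k
                if not np.any(sel):
                    continue
                P = class_models[k].transition_probabilities(t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(int(sel.sum()))
                child_state[sel] = (cum[states[node][sel]] > u[:, None]).argmax(axis=1)
            states[child] = child_state

    codon_arr = np.array(SENSE_CODONS, dtype="<U3")
    rows = codon_arr[states[tree.leaf_ids]]
    ref = REFERENCE_TAXON if REFERENCE_TAXON in tree.leaf_names else tree.leaf_names[0]
    aln = CodonAlignment(taxa=tuple(tree.leaf_names), codons=rows, reference_taxon=ref)
    return aln, site_class


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LongGap:
    fraction: float
    start: int | None = None  # codon column; random if None

    kind = "long_gap"


@dataclass(frozen=True)
class ScrambledStretch:
    fraction: float
    start: int | None = None

    kind = "scrambled_stretch"


@dataclass(frozen=True)
class AmbiguityRun:
    length: int  # codons
    start: int | None = None

    kind = "ambiguity_run"


@dataclass(frozen=True)
class TerminalOverhang:
    codons: int
    end: str = "3"  # "5" or "3"

    kind = "terminal_overhang"


@dataclass(frozen=True)
class OrphanRun:
    aa_count: int
    start: int | None = None

    kind = "orphan_run"


Defect = LongGap | ScrambledStretch | AmbiguityRun | TerminalOverhang | OrphanRun


@dataclass
class CorruptionSpec:
    defects: list[tuple[str, Defect]]  # (taxon, defect)
    seed: int = 0


@dataclass(frozen=True)
class DefectRecord:
    taxon: str
    kind: str
    start: int  # 0-based codon column in the corrupted alignment
    length: int  # codons


def _span_length(defect: Defect, ref_len: int) -> int:
    if isinstance(defect, (LongGap, ScrambledStretch)):
        if not 0.0 < defect.fraction <= 1.0:
            raise ValueError("defect fractions must be in (0, 1]")
        return max(1, math.ceil(defect.fraction * ref_len))
    if isinstance(defect, AmbiguityRun):
        return int(defect.length)
    if isinstance(defect, OrphanRun):
        return int(defect.aa_count)
    raise TypeError(defect)


def corrupt_alignment(
    aln: CodonAlignment, spec: CorruptionSpec
) -> tuple[CodonAlignment, list[DefectRecord]]:
    """Inject the requested defects; untouched cells are bit-identical.

    Returns the corrupted alignment and a ledger recording every defect with
    its coordinates. Overlapping interior defects on one taxon are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    codons = aln.codons.copy()
    ref_len = aln.reference_ungapped_length()
    n_cols = aln.length_codons
    ledger: list[DefectRecord] = []
    claimed: dict[str, list[tuple[int, int]]] = {}

    interior = [
        (t, d) for t, d in spec.defects if not isinstance(d, TerminalOverhang)
    ]
    overhangs = [
        (t, d) for t, d in spec.defects if isinstance(d, TerminalOverhang)
    ]

    for taxon, defect in interior:
        row = aln.taxa.index(taxon)
        span = _span_length(defect, ref_len)
        if span > n_cols - 2:
            raise ValueError(f"defect on {taxon} does not fit inside the alignment")
        start = defect.start
        if start is None:
            start = int(rng.integers(1, n_cols - span))  # keep termini intact
        if start < 0 or start + span > n_cols:
            raise ValueError(f"defect on {taxon} out of bounds")
        for s, e in claimed.get(taxon, []):
            if start < e and s < start + span:
                raise ValueError(f"overlapping defects on taxon {taxon}")
        claimed.setdefault(taxon, []).append((start, start + span))

        cols = slice(start, start + span)
        if isinstance(defect, LongGap):
            codons[row, cols] = GAP_CODON
        elif isinstance(defect, AmbiguityRun):
            codons[row, cols] = "nnn"
        elif isinstance(defect, ScrambledStretch):
            codons[row, cols] = _random_codons(rng, span)
        elif isinstance(defect, OrphanRun):
            for j in range(start, start + span):
                other_aas = {
                    CODON_AA[_codon_idx(codons[r, j])]
                    for r in range(aln.n_taxa)
                    if r != row and _codon_idx(codons[r, j]) >= 0
                }
                candidates = [
                    i for i, a in enumerate(CODON_AA) if a not in other_aas
                ]
                if not candidates:
                    raise ValueError(
                        f"cannot construct orphan residue at column {j}"
                    )
                codons[row, j] = SENSE_CODONS[int(rng.choice(candidates))]
        ledger.append(DefectRecord(taxon, defect.kind, start, span))

    if overhangs:
        lead = max((d.codons for _, d in overhangs if d.end == "5"), default=0)
        trail = max((d.codons for _, d in overhangs if d.end == "3"), default=0)
        n_new = codons.shape[1] + lead + trail
        extended = np.full((aln.n_taxa, n_new), GAP_CODON, dtype="<U3")
        extended[:, lead : lead + codons.shape[1]] = codons
        for taxon, d in overhangs:
            row = aln.taxa.index(taxon)
            if d.end == "5":
                extended[row, lead - d.codons : lead] = _random_codons(rng, d.codons)
                ledger.append(DefectRecord(taxon, d.kind, lead - d.codons, d.codons))
            else:
                extended[row, n_new - trail : n_new - trail + d.codons] = (
                    _random_codons(rng, d.codons)
                )
                ledger.append(DefectRecord(taxon, d.kind, n_new - trail, d.codons))
        codons = extended

    return aln.with_codons(codons), ledger


def _codon_idx(codon: str) -> int:
    from .genetic_code import CODON_INDEX

    return CODON_INDEX.get(codon.upper(), -1)


def _random_codons(rng: np.random.Generator, n: int) -> np.ndarray:
    idx = rng.integers(0, N_CODONS, size=n)
    return np.array([SENSE_CODONS[i] for i in idx], dtype="<U3")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CategorySpec:
    n_genes: int
    selected_fraction: float
    n_codons_range: tuple[int, int] = (200, 600)
    n_taxa_range: tuple[int, int] = (10, 20)
    tree_scale: float = 1.0  # category-wide branch-length multiplier

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("each category needs at least one gene")
        if not 0.0 <= self.selected_fraction <= 1.0:
            raise ValueError("selected_fraction must be in [0, 1]")
        if self.n_taxa_range[0] < 2:
            raise ValueError("taxon subsamples need at least 2 taxa")


# Study-condition defaults: genes under selection carry an omega_s = 4 class
# over 20% of sites; null genes follow M8a with 90% of sites on Beta(0.5, 1.5).
DEFAULT_SELECTED_P1 = 0.2
DEFAULT_OMEGA_S = 4.0
DEFAULT_NULL_P0 = 0.9
DEFAULT_BETA_P = 0.5
DEFAULT_BETA_Q = 1.5


@dataclass
class CohortSpec:
    categories: dict[str, CategorySpec] = field(
        default_factory=lambda: {
            "induction": CategorySpec(131, 0.2),
            "isg": CategorySpec(100, 0.35),
            "random": CategorySpec(100, 0.18),
        }
    )
    tree: PhyloTree | None = None
    kappa: float = 3.0
    selected_p1: float = DEFAULT_SELECTED_P1
    omega_s: float = DEFAULT_OMEGA_S
    null_p0: float = DEFAULT_NULL_P0
    beta_p: float = DEFAULT_BETA_P
    beta_q: float = DEFAULT_BETA_Q
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree is None:
            self.tree = default_primate_tree()


@dataclass
class TruthRecord:
    gene_id: str
    category: str
    true_model: str  # "M8" (selection) or "M8a" (null)
    true_p1: float
    true_omega_s: float
    n_taxa: int
    n_codons: int
    taxa: tuple[str, ...]
    seed: int


@dataclass
class SimulatedGene:
    gene_id: str
    category: str
    alignment: CodonAlignment
    tree: PhyloTree
    truth: TruthRecord
    site_classes: np.ndarray


def simulate_cohort(spec: CohortSpec) -> list[SimulatedGene]:
    """Generate a full synthetic gene cohort with per-gene ground truth.

    Within each category exactly round(selected_fraction * n_genes) genes are
    simulated under M8 (with the omega_s > 1 class); the rest under M8a.
    Taxon subsets always include the reference and use the induced subtree of
    the master tree. Deterministic given the spec seed.
    """
    master = spec.tree
    assert master is not None
    rng = np.random.default_rng(spec.seed)
    genes: list[SimulatedGene] = []
    others = [n for n in master.leaf_names if n != REFERENCE_TAXON]

    for category, cat in spec.categories.items():
        n_selected = int(round(cat.selected_fraction * cat.n_genes))
        flags = np.zeros(cat.n_genes, dtype=bool)
        flags[:n_selected] = True
        rng.shuffle(flags)
        for g, selected in enumerate(flags):
            gene_id = f"{category}_{g + 1:04d}"
            lo, hi = cat.n_taxa_range
            n_taxa = int(rng.integers(lo, hi + 1))
            n_taxa = min(n_taxa, master.n_leaves)
            if n_taxa < 2:
                raise ValueError("taxon subsample must have >= 2 taxa")
            picked = [REFERENCE_TAXON] if REFERENCE_TAXON in master.leaf_names else []
            extra = rng.choice(others, size=n_taxa - len(picked), replace=False)
            taxa = picked + [str(t) for t in extra]
            gene_tree = master.subtree(taxa).scaled(cat.tree_scale)
            n_codons = int(rng.integers(cat.n_codons_range[0], cat.n_codons_range[1] + 1))
            if selected:
                model = m8_model(
                    1.0 - spec.selected_p1, spec.beta_p, spec.beta_q, spec.omega_s
                )
                true_model, p1, ws = "M8", spec.selected_p1, spec.omega_s
            else:
                model = m8a_model(spec.null_p0, spec.beta_p, spec.beta_q)
                true_model, p1, ws = "M8a", 1.0 - spec.null_p0, 1.0
            gene_seed = int(rng.integers(0, 2**31 - 1))
            aln, classes = simulate_alignment(
                SimulationSpec(
                    tree=gene_tree,
                    n_codons=n_codons,
                    site_model=model,
                    kappa=spec.kappa,
                    seed=gene_seed,
                )
            )
            genes.append(
                SimulatedGene(
                    gene_id=gene_id,
                    category=category,
                    alignment=aln,
                    tree=gene_tree,
                    truth=TruthRecord(
                        gene_id=gene_id,
                        category=category,
                        true_model=true_model,
                        true_p1=p1,
                        true_omega_s=ws,
                        n_taxa=len(taxa),
                        n_codons=n_codons,
                        taxa=tuple(sorted(taxa)),
                        seed=gene_seed,
                    ),
                    site_classes=classes,
                )
            )
    return genes
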