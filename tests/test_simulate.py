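"""Simulator ground truth: determinism, composition, defect injection, cohorts."""

import numpy as np
import pytest
from scipy.stats import chisquare

from posel.genetic_code import GAP_CODON, STOP_CODONS
from posel.simulate import (
    AmbiguityRun,
    CategorySpec,
    CohortSpec,
    CorruptionSpec,
    LongGap,
    OrphanRun,
    ScrambledStretch,
    SimulationSpec,
    TerminalOverhang,
    corrupt_alignment,
    default_codon_freqs,
    default_primate_tree,
    simulate_alignment,
    simulate_cohort,
)
from posel.sitemodels import m0_model, m8_model
from posel.trees import PhyloTree


def test_identical_seed_reproduces_alignment(primate_tree):
    spec = lambda: SimulationSpec(
        tree=primate_tree, n_codons=100, site_model=m0_model(0.5), seed=11
    )
    a1, c1 = simulate_alignment(spec())
    a2, c2 = simulate_alignment(spec())
    assert a1 == a2
    assert np.array_equal(c1, c2)


def test_zero_branch_lengths_give_identical_sequences(primate_tree):
    frozen = primate_tree.with_edge_lengths(np.zeros(primate_tree.n_nodes))
    aln, _ = simulate_alignment(
        SimulationSpec(tree=frozen, n_codons=50, site_model=m0_model(0.5), seed=1)
    )
    for row in aln.codons[1:]:
        assert np.array_equal(row, aln.codons[0])


def test_omega_zero_changes_are_synonymous():
    tree = PhyloTree.from_newick("(A:0.5,B:0.5);")
    aln, _ = simulate_alignment(
        SimulationSpec(tree=tree, n_codons=2000, site_model=m0_model(0.0), seed=2)
    )
    aa = aln.amino_acids()
    n_diff_codon = int(np.sum(aln.codons[0] != aln.codons[1]))
    assert n_diff_codon > 0  # plenty of synonymous change at this divergence
    assert np.all(aa[0] == aa[1])  # but never an amino-acid difference


def test_no_stop_codons_emitted(primate_tree):
    aln, _ = simulate_alignment(
        SimulationSpec(tree=primate_tree, n_codons=300, site_model=m0_model(1.0), seed=3)
    )
    assert not set(np.unique(aln.codons)) & set(STOP_CODONS)


def test_codon_usage_converges_to_frequencies():
    # chi-square goodness of fit of root draws + evolved leaves at 10,000 sites
    tree = PhyloTree.from_newick("(A:0.01,B:0.01);")
    pi = default_codon_freqs()
    aln, _ = simulate_alignment(
        SimulationSpec(tree=tree, n_codons=10000, site_model=m0_model(0.5),
                       codon_freqs=pi, seed=4)
    )
    idx = aln.codon_indices()[0]
    counts = np.bincount(idx, minlength=61)
    stat, p = chisquare(counts, f_exp=pi * counts.sum())
    assert p > 0.01


def test_site_classes_follow_weights(primate_tree):
    model = m8_model(0.8, 0.5, 1.5, 4.0)
    _, classes = simulate_alignment(
        SimulationSpec(tree=primate_tree, n_codons=5000, site_model=model, seed=5)
    )
    frac_selected = np.mean(classes == 10)
    assert abs(frac_selected - 0.2) < 0.02


def test_invalid_frequencies_rejected(primate_tree):
    bad = np.full(61, 1 / 61)
    bad[0] *= -1
    with pytest.raises(ValueError):
        SimulationSpec(
            tree=primate_tree, n_codons=10, site_model=m0_model(0.5),
            codon_freqs=bad, seed=0,
        )


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------


@pytest.fixture()
def base_alignment(clean_alignment):
    return clean_alignment


def test_empty_defect_list_is_identity(base_alignment):
    out, ledger = corrupt_alignment(base_alignment, CorruptionSpec(defects=[], seed=0))
    assert out == base_alignment
    assert ledger == []


def test_long_gap_injection(base_alignment):
    taxon = "Pan_troglodytes"
    out, ledger = corrupt_alignment(
        base_alignment, CorruptionSpec(defects=[(taxon, LongGap(0.12))], seed=1)
    )
    (rec,) = ledger
    assert rec.kind == "long_gap" and rec.taxon == taxon
    expected = int(np.ceil(0.12 * base_alignment.reference_ungapped_length()))
    assert rec.length == expected
    row = out.row(taxon)
    assert np.all(row[rec.start : rec.start + rec.length] == GAP_CODON)
    # untouched cells identical
    mask = np.ones(out.length_codons, dtype=bool)
    mask[rec.start : rec.start + rec.length] = False
    assert np.all(row[mask] == base_alignment.row(taxon)[mask])


def test_ambiguity_run_injection(base_alignment):
    out, ledger = corrupt_alignment(
        base_alignment,
        CorruptionSpec(defects=[("Gorilla_gorilla", AmbiguityRun(5, start=20))], seed=2),
    )
    (rec,) = ledger
    assert rec.start == 20 and rec.length == 5
    assert np.all(out.row("Gorilla_gorilla")[20:25] == "nnn")


def test_orphan_run_matches_no_other_row(base_alignment):
    out, ledger = corrupt_alignment(
        base_alignment,
        CorruptionSpec(defects=[("Pongo_abelii", OrphanRun(6, start=50))], seed=3),
    )
    (rec,) = ledger
    aa = out.amino_acids()
    r = out.taxa.index("Pongo_abelii")
    for j in range(rec.start, rec.start + rec.length):
        others = np.delete(aa[:, j], r)
        assert aa[r, j] not in others


def test_terminal_overhang_extends_alignment(base_alignment):
    out, ledger = corrupt_alignment(
        base_alignment,
        CorruptionSpec(
            defects=[("Macaca_mulatta", TerminalOverhang(4, end="3"))], seed=4
        ),
    )
    (rec,) = ledger
    assert out.length_codons == base_alignment.length_codons + 4
    row = out.row("Macaca_mulatta")
    assert np.all(row[-4:] != GAP_CODON)
    assert np.all(out.reference_row[-4:] == GAP_CODON)


def test_overlapping_defects_rejected(base_alignment):
    spec = CorruptionSpec(
        defects=[
            ("Pan_paniscus", LongGap(0.10, start=10)),
            ("Pan_paniscus", AmbiguityRun(5, start=12)),
        ],
        seed=5,
    )
    with pytest.raises(ValueError, match="overlap"):
        corrupt_alignment(base_alignment, spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _tiny_cohort_spec(seed=0, **kw):
    cats = {
        "induction": CategorySpec(4, 0.25, n_codons_range=(30, 40), n_taxa_range=(4, 6)),
        "isg": CategorySpec(10, 0.3, n_codons_range=(30, 40), n_taxa_range=(4, 6)),
        "random": CategorySpec(3, 0.0, n_codons_range=(30, 40), n_taxa_range=(4, 6)),
    }
    return CohortSpec(categories=cats, seed=seed, **kw)


def test_cohort_counts_and_selected_fraction_exact():
    genes = simulate_cohort(_tiny_cohort_spec())
    by_cat = {}
    for g in genes:
        by_cat.setdefault(g.category, []).append(g)
    assert len(by_cat["induction"]) == 4
    assert len(by_cat["isg"]) == 10
    assert len(by_cat["random"]) == 3
    assert sum(g.truth.true_model == "M8" for g in by_cat["isg"]) == 3
    assert sum(g.truth.true_model == "M8" for g in by_cat["induction"]) == 1
    assert sum(g.truth.true_model == "M8" for g in by_cat["random"]) == 0


def test_cohort_deterministic():
    g1 = simulate_cohort(_tiny_cohort_spec(seed=42))
    g2 = simulate_cohort(_tiny_cohort_spec(seed=42))
    for a, b in zip(g1, g2):
        assert a.gene_id == b.gene_id
        assert a.alignment == b.alignment
        assert a.truth == b.truth


def test_cohort_trees_are_induced_subtrees(primate_tree):
    genes = simulate_cohort(_tiny_cohort_spec(seed=1))
    for g in genes[:5]:
        assert set(g.tree.leaf_names) == set(g.truth.taxa)
        names = list(g.tree.leaf_names)
        full_sub = primate_tree.subtree(names)
        assert np.isclose(g.tree.tree_length(), full_sub.tree_length())


def test_reference_always_included():
    genes = simulate_cohort(_tiny_cohort_spec(seed=2))
    assert all("Homo_sapiens" in g.alignment.taxa for g in genes)
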