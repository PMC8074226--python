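"""Quality-control rules on constructed fixtures and injected defects."""

import numpy as np

from posel.curation import (
    QCConfig,
    apply_qc_pipeline,
    drop_long_gap_orthologs,
    drop_misaligned_orthologs,
    mask_ambiguous,
    remove_orphan_runs,
    replay_report,
    scrub_gap_edges,
    trim_termini,
)
from posel.genetic_code import GAP_CODON
from posel.simulate import (
    AmbiguityRun,
    CorruptionSpec,
    LongGap,
    OrphanRun,
    ScrambledStretch,
    corrupt_alignment,
)

from conftest import make_alignment


# ---------------------------------------------------------------------------
# masking of ambiguity codes
# ---------------------------------------------------------------------------


def test_mask_ambiguous_single_codon():
    aln = make_alignment(
        {"Homo_sapiens": "ATGAAA", "chimp": "ATGAnT", "gorilla": "ATGAAA"}
    )
    out, entries = mask_ambiguous(aln)
    assert out.row("chimp")[1] == GAP_CODON
    assert out.row("chimp")[0] == "ATG"
    assert len(entries) == 1 and entries[0].columns == (1,)


def test_mask_ambiguous_identity_without_ns(clean_alignment):
    out, entries = mask_ambiguous(clean_alignment)
    assert out == clean_alignment and entries == []


def test_mask_ambiguous_on_injected_run(clean_alignment):
    corrupted, _ = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(defects=[("Pan_paniscus", AmbiguityRun(5, start=30))], seed=0),
    )
    out, entries = mask_ambiguous(corrupted)
    (e,) = entries
    assert e.taxon == "Pan_paniscus"
    assert e.columns == tuple(range(30, 35))


# ---------------------------------------------------------------------------
# step 1: long gaps
# ---------------------------------------------------------------------------


def _gap_fixture(gap_codons: int, n_codons: int = 100, split: bool = False):
    """Reference plus two orthologs; 'bad' carries gap_codons of gap."""
    ref = "ATG" + "AAA" * (n_codons - 1)
    good = ref
    if split:
        third = gap_codons // 3
        rest = gap_codons - 2 * third
        pieces = [
            "ATG",
            "---" * third,
            "AAA" * 20,
            "---" * third,
            "AAA" * 20,
            "---" * rest,
            "AAA" * (n_codons - 1 - 40 - gap_codons),
        ]
        bad = "".join(pieces)
    else:
        bad = "ATG" + "---" * gap_codons + "AAA" * (n_codons - 1 - gap_codons)
    return make_alignment({"Homo_sapiens": ref, "good": good, "bad": bad})


def test_long_gap_over_threshold_removed():
    aln = _gap_fixture(12)  # 12% of 100 codons
    out, entries = drop_long_gap_orthologs(aln, threshold=0.10)
    assert [e.taxon for e in entries] == ["bad"]
    assert "bad" not in out.taxa


def test_gap_exactly_at_threshold_retained():
    aln = _gap_fixture(10)  # exactly 10%: strict inequality
    out, entries = drop_long_gap_orthologs(aln, threshold=0.10)
    assert entries == [] and "bad" in out.taxa


def test_multiple_short_gaps_retained():
    # three gaps of 8 codons each (24% total, each < 10%)
    aln = _gap_fixture(24, split=True)
    out, entries = drop_long_gap_orthologs(aln, threshold=0.10)
    assert entries == [] and "bad" in out.taxa


def test_long_gap_fixture_detected_with_exact_coordinates(clean_alignment):
    corrupted, ledger = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(defects=[("Nomascus_leucogenys", LongGap(0.12))], seed=1),
    )
    out, entries = drop_long_gap_orthologs(corrupted)
    assert [e.taxon for e in entries] == ["Nomascus_leucogenys"]


# ---------------------------------------------------------------------------
# step 2: misaligned stretches
# ---------------------------------------------------------------------------


def test_scrambled_stretch_removed(clean_alignment):
    corrupted, _ = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(defects=[("Ateles_geoffroyi", ScrambledStretch(0.15))], seed=2),
    )
    out, entries = drop_misaligned_orthologs(corrupted)
    assert [e.taxon for e in entries] == ["Ateles_geoffroyi"]


def test_short_scramble_retained(clean_alignment):
    corrupted, _ = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(defects=[("Ateles_geoffroyi", ScrambledStretch(0.05))], seed=3),
    )
    out, entries = drop_misaligned_orthologs(corrupted)
    assert entries == []


def test_pristine_alignment_untouched(clean_alignment):
    out, entries = drop_misaligned_orthologs(clean_alignment)
    assert entries == [] and out == clean_alignment


# ---------------------------------------------------------------------------
# step 3: terminal trimming
# ---------------------------------------------------------------------------


def _termini_fixture():
    """12 rows; 4 rows lack the first 3 codons; column 4 (index 3) is the
    first fully conserved column."""
    rows = {}
    core = "ATGGGGCCCTTT" + "AAA" * 6  # 10 codons total... built below
    # columns: 0..2 variable/gapped, 3 conserved 'AAA', rest conserved
    n_tail = 6
    for i in range(12):
        lead = []
        for j in range(3):
            if i < 4:
                lead.append("---")
            else:
                # variable: two different codons among rows -> not conserved
                lead.append("GGA" if (i + j) % 2 else "GGC")
        name = "Homo_sapiens" if i == 11 else f"t{i}"
        rows[name] = "".join(lead) + "AAA" + "ACCTGGTTC" * 2
    return make_alignment(rows)


def test_trim_leading_columns_to_first_conserved():
    aln = _termini_fixture()
    out, entries = trim_termini(aln, min_concordant=10)
    (e,) = entries
    assert e.columns == (0, 1, 2)
    assert out.length_codons == aln.length_codons - 3
    assert np.all(out.codons[:, 0] == "AAA")


def test_no_trim_when_concordant(clean_alignment):
    out, entries = trim_termini(clean_alignment, min_concordant=10)
    assert entries == [] and out == clean_alignment


def test_phylogeny_concordant_column_stops_trimming(small_tree):
    # column 0: half rows gapped (trigger); column 1 has two amino acids that
    # split exactly along the (A,B) vs (C,D) clades -> concordant, stops trim
    rows = {
        "A": "---GGG" + "AAA" * 4,
        "B": "ATGGGG" + "AAA" * 4,
        "C": "ATGCCC" + "AAA" * 4,
        "D": "---CCC" + "AAA" * 4,
    }
    aln = make_alignment(rows, reference="A")
    out, entries = trim_termini(aln, min_concordant=4, tree=small_tree)
    (e,) = entries
    assert e.columns == (0,)
    out2, entries2 = trim_termini(aln, min_concordant=4, tree=None)
    # without the tree, trimming runs to the first invariant column (2)
    assert entries2[0].columns == (0, 1)


# ---------------------------------------------------------------------------
# step 4: gap-edge scrubbing
# ---------------------------------------------------------------------------


def _gap_edge_fixture(edge_aas):
    """5 rows; row 't0' has a gap at columns 2-3; column 4 (gap edge) gets
    the supplied amino acids (as codons) across rows."""
    aa_to_codon = {"V": "GTG", "L": "CTG", "I": "ATT", "M": "ATG"}
    rows = {}
    for i, aa in enumerate(edge_aas):
        name = "Homo_sapiens" if i == 0 else f"t{i}"
        middle = "---" * 2 if i == 1 else "CCC" * 2
        rows[name] = "ATGAAA" + middle + aa_to_codon[aa] + "TTTGGG"
    return make_alignment(rows)


def test_gap_edge_two_mismatches_deleted():
    aln = _gap_edge_fixture(["V", "V", "V", "L", "I"])
    out, entries = scrub_gap_edges(aln)
    assert len(entries) == 1
    assert 4 in entries[0].columns
    assert out.length_codons < aln.length_codons


def test_gap_edge_single_mismatch_retained():
    aln = _gap_edge_fixture(["V", "V", "V", "V", "L"])
    out, entries = scrub_gap_edges(aln)
    cols = entries[0].columns if entries else ()
    assert 4 not in cols


def test_no_gaps_no_scrub(clean_alignment):
    out, entries = scrub_gap_edges(clean_alignment)
    assert entries == [] and out == clean_alignment


# ---------------------------------------------------------------------------
# step 5: orphan runs
# ---------------------------------------------------------------------------


def _orphan_fixture(run_len):
    n = 40
    base = "AAA" * n
    # 'odd' row: run_len consecutive codons encoding residues found in no other row
    odd = "AAA" * 10 + "TGG" * run_len + "AAA" * (n - 10 - run_len)
    return make_alignment(
        {"Homo_sapiens": base, "x": base, "y": base, "odd": odd}
    )


def test_orphan_run_of_five_masked():
    aln = _orphan_fixture(5)
    out, entries = remove_orphan_runs(aln, run_threshold=4)
    (e,) = entries
    assert e.taxon == "odd" and e.columns == tuple(range(10, 15))
    assert np.all(out.row("odd")[10:15] == GAP_CODON)


def test_orphan_run_of_four_retained():
    aln = _orphan_fixture(4)
    out, entries = remove_orphan_runs(aln, run_threshold=4)
    assert entries == []


def test_orphan_fixture_coordinates_match_truth(clean_alignment):
    corrupted, ledger = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(defects=[("Cebus_capucinus", OrphanRun(6, start=77))], seed=4),
    )
    out, entries = remove_orphan_runs(corrupted)
    (e,) = entries
    truth = ledger[0]
    assert e.taxon == "Cebus_capucinus"
    assert e.columns == tuple(range(truth.start, truth.start + truth.length))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_pristine_alignment_retained_with_empty_ledger(clean_alignment):
    out, report = apply_qc_pipeline(clean_alignment)
    assert report.status == "retained"
    assert report.entries == []
    assert out == clean_alignment


def test_rejection_below_minimum_orthologs(clean_alignment):
    # drop to 11 taxa, then let two long-gap removals push below 10
    keep = list(clean_alignment.taxa[:11])
    small = clean_alignment.take_taxa(keep)
    victims = [t for t in keep if t != small.reference_taxon][:2]
    corrupted, _ = corrupt_alignment(
        small,
        CorruptionSpec(defects=[(v, LongGap(0.2)) for v in victims], seed=5),
    )
    out, report = apply_qc_pipeline(corrupted)
    assert out is None
    assert report.status == "rejected_too_few_orthologs"
    assert report.n_taxa_final == 9


def test_exactly_ten_orthologs_retained(clean_alignment):
    small = clean_alignment.take_taxa(list(clean_alignment.taxa[:10]))
    out, report = apply_qc_pipeline(small)
    assert report.status == "retained"


def test_pipeline_idempotent(clean_alignment):
    corrupted, _ = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(
            defects=[
                ("Pan_troglodytes", LongGap(0.15)),
                ("Gorilla_gorilla", AmbiguityRun(6, start=40)),
                ("Pongo_abelii", OrphanRun(7, start=90)),
            ],
            seed=6,
        ),
    )
    once, r1 = apply_qc_pipeline(corrupted)
    twice, r2 = apply_qc_pipeline(once)
    assert r2.entries == []
    assert twice == once


def test_ledger_replay_reproduces_output(clean_alignment):
    corrupted, _ = corrupt_alignment(
        clean_alignment,
        CorruptionSpec(
            defects=[
                ("Pan_troglodytes", LongGap(0.15)),
                ("Saimiri_boliviensis", ScrambledStretch(0.2)),
                ("Gorilla_gorilla", AmbiguityRun(6, start=40)),
                ("Aotus_nancymaae", OrphanRun(7, start=90)),
            ],
            seed=7,
        ),
    )
    out, report = apply_qc_pipeline(corrupted)
    replayed = replay_report(corrupted, report)
    assert replayed == out


def test_columns_deleted_across_all_rows():
    aln = _gap_edge_fixture(["V", "V", "V", "L", "I"])
    out, _ = scrub_gap_edges(aln)
    lengths = {len(row) for row in out.codons}
    assert len(lengths) == 1  # rectangular
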