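"""Universal genetic code tables for the 61-sense-codon state space.

The three stop codons (TAA, TAG, TGA) are excluded from the state space:
codon substitution models condition on coding sequence remaining coding, so
stops are neither emitted by the simulator nor accepted by the likelihood.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "TCAG"
GAP_CODON = "---"

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))

#: the 61 sense codons, in fixed lexicographic (TCAG) order
SENSE_CODONS = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid encoded by each sense codon (one-letter), aligned with SENSE_CODONS
CODON_AA = tuple(standard_dna_table.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if nucleotides a, b differ by a transition (A<->G or C<->T)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """Boolean 61x61 tables: single-nt-difference transitions / nonsynonymous pairs.

    Entries for pairs differing at zero or more than one nucleotide position
    are False in both tables; those pairs have rate zero.
    """
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = CODON_AA[i] != CODON_AA[j]
    return single & transition, single & nonsyn


_TS, _NONSYN = _pair_tables()
SINGLE_NT = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i != _j and sum(a != b for a, b in zip(_ci, _cj)) == 1:
            SINGLE_NT[_i, _j] = True
IS_TRANSITION = _TS
IS_NONSYNONYMOUS = _NONSYN


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '-' for gaps, 'X' for ambiguous."""
    if codon == GAP_CODON:
        return "-"
    cu = codon.upper()
    if cu in CODON_INDEX:
        return CODON_AA[CODON_INDEX[cu]]
    return "X"
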