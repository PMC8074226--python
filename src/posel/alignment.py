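"""In-frame codon alignments.

A :class:`CodonAlignment` is a rectangular matrix of codons over named taxa,
with one row designated as the reference (the human sequence in the original
study design). Cells hold either one of the 61 sense codons, the gap codon
``---``, or a codon containing the ambiguity character ``n``. Internal stop
codons are rejected on construction: the downstream substitution models are
defined on sense codons only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import CODON_INDEX, GAP_CODON, STOP_CODONS, translate_codon


class AlignmentError(ValueError):
    """Malformed alignment input (frame violation, stops, ragged rows...)."""


@dataclass
class CodonAlignment:
    taxa: tuple[str, ...]
    codons: np.ndarray  # (n_taxa, n_codons) array of 3-char strings, dtype <U3
    reference_taxon: str

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype="<U3")
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        if self.reference_taxon not in self.taxa:
            raise AlignmentError(f"reference taxon {self.reference_taxon!r} absent")
        self._validate_codons()

    def _validate_codons(self) -> None:
        for t, row in zip(self.taxa, self.codons):
            for j, codon in enumerate(row):
                cu = codon.upper()
                if cu in STOP_CODONS:
                    raise AlignmentError(
                        f"stop codon {codon} in taxon {t!r} at codon {j + 1}"
                    )
                if cu in CODON_INDEX or codon == GAP_CODON:
                    continue
                if "N" in cu or "-" in codon:
                    continue
                raise AlignmentError(
                    f"unrecognized codon {codon!r} in taxon {t!r} at codon {j + 1}"
                )

    # -- shape -------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    @property
    def reference_row(self) -> np.ndarray:
        return self.row(self.reference_taxon)

    def reference_ungapped_length(self) -> int:
        """Codon length of the reference sequence, gaps excluded."""
        return int(np.sum(self.reference_row != GAP_CODON))

    # -- views -------------------------------------------------------------
    def is_gap(self) -> np.ndarray:
        """Boolean (n_taxa, n_codons): gap codons."""
        return self.codons == GAP_CODON

    def is_ambiguous(self) -> np.ndarray:
        """Boolean (n_taxa, n_codons): codons containing 'n'/'N'."""
        low = np.char.lower(self.codons)
        return np.char.find(low, "n") >= 0

    def amino_acids(self) -> np.ndarray:
        """(n_taxa, n_codons) one-letter amino acids; '-' gaps, 'X' ambiguous."""
        out = np.empty(self.codons.shape, dtype="<U1")
        flat = self.codons.ravel()
        out_flat = out.ravel()
        for i, codon in enumerate(flat):
            out_flat[i] = translate_codon(codon)
        return out

    def codon_indices(self) -> np.ndarray:
        """(n_taxa, n_codons) ints: sense-codon index, or -1 for gap/ambiguous."""
        out = np.full(self.codons.shape, -1, dtype=np.int64)
        flat = self.codons.ravel()
        out_flat = out.ravel()
        for i, codon in enumerate(flat):
            out_flat[i] = CODON_INDEX.get(codon.upper(), -1)
        return out

    # -- edits (all return new objects) ------------------------------------
    def drop_taxa(self, names: set[str]) -> "CodonAlignment":
        if self.reference_taxon in names:
            raise AlignmentError("cannot drop the reference taxon")
        keep = [i for i, t in enumerate(self.taxa) if t not in names]
        return CodonAlignment(
            taxa=tuple(self.taxa[i] for i in keep),
            codons=self.codons[keep],
            reference_taxon=self.reference_taxon,
        )

    def drop_columns(self, cols: np.ndarray) -> "CodonAlignment":
        mask = np.ones(self.length_codons, dtype=bool)
        mask[np.asarray(cols, dtype=int)] = False
        return CodonAlignment(
            taxa=self.taxa,
            codons=self.codons[:, mask],
            reference_taxon=self.reference_taxon,
        )

    def take_taxa(self, names: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(n) for n in names]
        ref = self.reference_taxon if self.reference_taxon in names else names[0]
        return CodonAlignment(
            taxa=tuple(names), codons=self.codons[idx], reference_taxon=ref
        )

    def with_codons(self, codons: np.ndarray) -> "CodonAlignment":
        return CodonAlignment(
            taxa=self.taxa, codons=codons, reference_taxon=self.reference_taxon
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CodonAlignment):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.reference_taxon == other.reference_taxon
            and self.codons.shape == other.codons.shape
            and bool(np.all(self.codons == other.codons))
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_sequences(
        cls, named_seqs: list[tuple[str, str]], reference_taxon: str
    ) -> "CodonAlignment":
        if not named_seqs:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in named_seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(
                f"alignment length {length} nt is not a multiple of 3"
            )
        rows = [
            [seq[k : k + 3] for k in range(0, length, 3)] for _, seq in named_seqs
        ]
        return cls(
            taxa=tuple(n for n, _ in named_seqs),
            codons=np.array(rows, dtype="<U3"),
            reference_taxon=reference_taxon,
        )


def read_alignment_fasta(path: str | Path, reference_taxon: str) -> CodonAlignment:
    """Read an aligned, in-frame FASTA into a CodonAlignment.

    Rejects ragged rows, lengths not divisible by 3 and internal stop codons,
    reporting the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    named = [(r.id, str(r.seq)) for r in records]
    try:
        return CodonAlignment.from_sequences(named, reference_taxon=reference_taxon)
    except AlignmentError as e:
        raise AlignmentError(f"{path}: {e}") from e


def write_alignment_fasta(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=t, description="")
        for t, row in zip(aln.taxa, aln.codons)
    ]
    SeqIO.write(records, str(path), "fasta")
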