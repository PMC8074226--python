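"""Readers and writers for the tabular interchange formats.

Alignments travel as in-frame FASTA (see :mod:`posel.alignment`), trees as
Newick (see :mod:`posel.trees`); this module covers the gene-category table,
per-gene result records and selected-site reports. Codon coordinates in all
reports are 1-based and inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .inference import GeneRecord

CATEGORY_COLUMNS = ("gene", "category")

RECORD_COLUMNS = (
    "gene_id",
    "category",
    "lnl_m8",
    "lnl_m8a",
    "two_delta_lnl",
    "p_value",
    "bh_significant",
    "omega_m0",
    "tree_length_m0",
    "pct_sites_omega_gt1_m8",
    "pct_sites_selected_neb",
    "pct_sites_conserved_m2",
    "n_taxa",
    "n_sites_analyzed",
    "complete",
)


def read_category_table(path: str | Path) -> dict[str, str]:
    """TSV with header columns gene, category -> {gene id: category}."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CATEGORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(df["gene"].astype(str), df["category"].astype(str)))


def write_category_table(categories: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": list(categories), "category": list(categories.values())}
    ).to_csv(path, sep="\t", index=False)


def records_to_frame(records: list[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    )


def write_records_tsv(records: list[GeneRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in RECORD_COLUMNS if c in df.columns}
        kwargs["bh_significant"] = bool(kwargs.get("bh_significant", False))
        kwargs["complete"] = bool(kwargs.get("complete", False))
        for k in ("n_taxa", "n_sites_analyzed"):
            kwargs[k] = int(kwargs.get(k, 0))
        out.append(GeneRecord(**kwargs))
    return out


def write_selected_sites_tsv(records: list[GeneRecord], path: str | Path) -> None:
    """BED-like TSV of positively selected codons: gene, 1-based codon, posterior."""
    rows = [
        {"gene": r.gene_id, "codon": site, "posterior": post}
        for r in records
        for site, post in r.selected_sites
    ]
    pd.DataFrame(rows, columns=["gene", "codon", "posterior"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce) + "\n")


def _coerce(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(list(x) for x in o)
    raise TypeError(f"not JSON serializable: {type(o)}")
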