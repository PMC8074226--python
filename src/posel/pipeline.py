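"""End-to-end orchestration: curation -> model fits -> LRT/BH -> cohorts.

One :class:`RunConfig` drives the whole analysis; a :class:`RunManifest`
records what happened to every input gene (qc_rejected, fit_failed or
complete) together with checksums of all written outputs, so a run is fully
reproducible from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import CodonAlignment, read_alignment_fasta
from .cohort import (
    cohort_quality_summary,
    compare_distributions,
    resample_equalized,
    selected_counts_table,
)
from .curation import QCConfig, apply_qc_pipeline
from .fit import FitOptions, fit_all_models, site_posteriors
from .inference import GeneRecord, apply_bh, summarize_gene
from .io import (
    read_category_table,
    write_json,
    write_records_tsv,
    write_selected_sites_tsv,
)
from .simulate import CohortSpec, simulate_cohort
from .trees import PhyloTree


@dataclass
class RunConfig:
    out_dir: str = "posel_run"
    # inputs: either a directory of per-gene FASTA + a category table ...
    alignments_dir: str | None = None
    tree_file: str | None = None
    category_table: str | None = None
    reference_taxon: str = "Homo_sapiens"
    # ... or a built-in synthetic cohort
    simulate: bool = False
    cohort_spec: CohortSpec | None = None
    # stages
    run_qc: bool = True
    qc: QCConfig = field(default_factory=QCConfig)
    models: tuple[str, ...] = ("M0", "M2", "M8a", "M8")
    fit: FitOptions = field(default_factory=FitOptions)
    fdr: float = 0.10
    mixture_null: bool = False
    site_posterior_cutoff: float = 0.5
    resample_subsample_size: int | None = None
    resample_replicates: int = 100
    distribution_test: str = "ks"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("cohort_spec", None)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc = QCConfig(**raw.pop("qc", {}))
        fit = FitOptions(**raw.pop("fit", {}))
        models = tuple(raw.pop("models", ("M0", "M2", "M8a", "M8")))
        return cls(qc=qc, fit=fit, models=models, **raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    config: dict
    version: str
    gene_status: dict[str, str]  # qc_rejected | fit_failed | complete
    checksums: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "gene_status": self.gene_status,
            "checksums": self.checksums,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(base: int, stage: str) -> int:
    """Stage seeds derive from the global seed by hashing; reproducible and
    independent across stages (kept below 2**31)."""
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _load_inputs(
    config: RunConfig,
) -> tuple[dict[str, CodonAlignment], dict[str, PhyloTree], dict[str, str]]:
    """Returns (alignments, per-gene trees, categories)."""
    if config.simulate:
        spec = config.cohort_spec or CohortSpec(seed=_derive_seed(config.seed, "cohort"))
        genes = simulate_cohort(spec)
        alns = {g.gene_id: g.alignment for g in genes}
        trees = {g.gene_id: g.tree for g in genes}
        cats = {g.gene_id: g.category for g in genes}
        return alns, trees, cats
    if not (config.alignments_dir and config.tree_file and config.category_table):
        raise ValueError(
            "need alignments_dir, tree_file and category_table (or simulate=True)"
        )
    master = PhyloTree.from_newick(Path(config.tree_file).read_text())
    cats = read_category_table(config.category_table)
    alns: dict[str, CodonAlignment] = {}
    trees: dict[str, PhyloTree] = {}
    for gene in sorted(cats):
        fasta = Path(config.alignments_dir) / f"{gene}.fasta"
        if not fasta.exists():
            fasta = Path(config.alignments_dir) / f"{gene}.fa"
        aln = read_alignment_fasta(fasta, reference_taxon=config.reference_taxon)
        shared = [t for t in master.leaf_names if t in set(aln.taxa)]
        dropped = set(aln.taxa) - set(shared)
        if dropped:
            aln = aln.take_taxa([t for t in aln.taxa if t in set(shared)])
        alns[gene] = aln
        trees[gene] = master.subtree(shared) if len(shared) < master.n_leaves else master
    return alns, trees, cats


def run_full_pipeline(config: RunConfig) -> RunManifest:
    """Execute qc -> fits -> per-gene records -> cohort comparisons.

    Per-gene failures are recorded in the manifest and skipped; only
    unreadable inputs abort the run. Deterministic given (inputs, config,
    seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alns, trees, cats = _load_inputs(config)

    gene_status: dict[str, str] = {}
    qc_reports: dict[str, dict] = {}
    records: list[GeneRecord] = []
    kept: dict[str, CodonAlignment] = {}

    for gene in sorted(alns):
        aln, tree = alns[gene], trees[gene]
        if config.run_qc:
            curated, report = apply_qc_pipeline(aln, config.qc, tree=tree)
            qc_reports[gene] = report.to_dict()
            if curated is None:
                gene_status[gene] = "qc_rejected"
                continue
            aln = curated
        kept[gene] = aln

    fit_seed = _derive_seed(config.seed, "fit")
    for gene, aln in kept.items():
        tree = trees[gene]
        try:
            opts = FitOptions(**{**asdict(config.fit), "seed": fit_seed})
            fits = fit_all_models(aln, tree, opts, models=config.models)
            post = None
            if "M8" in fits and fits["M8"].converged:
                post = site_posteriors(
                    fits["M8"], aln, cutoff=config.site_posterior_cutoff
                )
            rec = summarize_gene(
                fits, gene, cats[gene], posteriors=post,
                mixture_null=config.mixture_null,
            )
        except Exception:
            gene_status[gene] = "fit_failed"
            continue
        if not rec.complete:
            gene_status[gene] = "fit_failed"
            continue
        gene_status[gene] = "complete"
        records.append(rec)

    apply_bh(records, fdr=config.fdr)

    # ---- cohort level -----------------------------------------------------
    table = selected_counts_table(records, fdr=config.fdr)
    results: dict = {"cohort_table": table.to_dict()}
    by_cat: dict[str, list[float]] = {}
    for metric in ("omega_m0", "pct_sites_omega_gt1_m8", "pct_sites_conserved_m2"):
        vals = {}
        for r in records:
            v = getattr(r, metric)
            if np.isfinite(v):
                vals.setdefault(r.category, []).append(v)
        if len(vals) >= 2 and all(len(v) >= 2 for v in vals.values()):
            results[f"compare_{metric}"] = [
                asdict(c)
                for c in compare_distributions(
                    {k: np.array(v) for k, v in vals.items()},
                    test=config.distribution_test,
                    fdr=config.fdr,
                )
            ]
    if config.resample_subsample_size:
        res = resample_equalized(
            records,
            subsample_size=config.resample_subsample_size,
            n_replicates=config.resample_replicates,
            fdr=config.fdr,
            seed=_derive_seed(config.seed, "resample"),
        )
        results["resampling"] = {
            "n_replicates": res.n_replicates,
            "subsample_size": res.subsample_size,
            "pattern_counts": res.pattern_counts,
        }
    quality = cohort_quality_summary(
        gene_taxa={g: a.taxa for g, a in kept.items() if gene_status[g] == "complete"},
        categories=cats,
        tree_lengths={r.gene_id: r.tree_length_m0 for r in records},
    )
    results["quality"] = quality.to_dict()

    # ---- outputs ----------------------------------------------------------
    write_records_tsv(records, out / "records.tsv")
    write_selected_sites_tsv(records, out / "selected_sites.tsv")
    write_json(results, out / "cohort.json")
    write_json({"qc_reports": qc_reports}, out / "qc_reports.json")

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        gene_status=gene_status,
    )
    for f in ("records.tsv", "selected_sites.tsv", "cohort.json", "qc_reports.json"):
        manifest.checksums[f] = _sha256(out / f)
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
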