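"""End-to-end orchestration of the prioritization funnel.

One config drives the whole chain: fraction set algebra -> PPI expansion
-> differential expression -> DEG intersection and candidate ranking ->
gene-set enrichment (-> optional Elispot survival statistics), with every
stage's output serialized and a machine-readable report whose JSON is
bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import io as sio
from .degs import DifferentialExpression
from .enrichment import GeneSetCollection, PrerankedGSEA, summarize_gene_sets
from .integration import overlap_targets, rank_candidates
from .network import expand, filter_confidence, load_network
from .proteomics import filter_psms, run_funnel
from .survival import anova_conditions

logger = logging.getLogger(__name__)

_THRESHOLD_RANGES = {
    "psm_fdr": (0.0, 1.0),
    "min_peptide_length": (1, 10**6),
    "min_abundance_log2": (-100.0, 100.0),
    "deg_fdr": (0.0, 1.0),
    "gsea_fdr": (0.0, 1.0),
    "report_threshold": (0, 10**9),
    "min_confidence": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled."""

    counts_path: str = ""
    annotation_path: str = ""
    network_path: str = ""
    gene_sets_path: str = ""
    fractions: list[dict] = field(default_factory=list)
    psm_path: str | None = None
    elispot_path: str | None = None
    network_dialect: str = "edgelist"
    outdir: str = "pipeline_out"
    seed: int = 0
    n_perm: int = 1000
    psm_fdr: float = 0.01
    min_peptide_length: int = 7
    min_abundance_log2: float = 3.0
    deg_fdr: float = 0.05
    gsea_fdr: float = 0.05
    report_threshold: int = 45
    min_confidence: float = 0.0
    adjust_batch: bool = True
    include_seed_partners: bool = True
    log_scale_survival: bool = False
    group_a: str = "bloodASC"
    group_b: str = "bmLLPC"


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path or a dict.

    Every violation is collected and reported at once.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    for name in ("counts_path", "annotation_path", "network_path", "gene_sets_path"):
        if not getattr(cfg, name):
            errors.append(f"missing required field: {name}")
        elif not Path(getattr(cfg, name)).exists():
            errors.append(f"{name} does not exist: {getattr(cfg, name)}")
    if not cfg.fractions:
        errors.append("missing required field: fractions")
    for fr in cfg.fractions:
        for key in ("path", "id", "activity"):
            if key not in fr:
                errors.append(f"fraction entry missing {key!r}: {fr}")
        if "path" in fr and not Path(fr["path"]).exists():
            errors.append(f"fraction path does not exist: {fr['path']}")
    for name, (lo, hi) in _THRESHOLD_RANGES.items():
        val = getattr(cfg, name)
        if not (lo <= val <= hi):
            errors.append(f"{name}={val} outside [{lo}, {hi}]")
    if cfg.n_perm < 1:
        errors.append(f"n_perm={cfg.n_perm} must be positive")
    if cfg.network_dialect not in {"edgelist", "hippie"}:
        errors.append(f"network_dialect={cfg.network_dialect!r} not edgelist/hippie")
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return cfg


@dataclass
class PipelineReport:
    """Funnel counts and stage outputs of one pipeline run."""

    funnel_counts: dict
    candidates: list[dict]
    significant_sets: list[str]
    survival: dict | None
    seed: int
    config: dict
    version: str = ""

    def to_json(self) -> str:
        payload = {
            "version": self.version or __version__,
            "seed": self.seed,
            "funnel_counts": self.funnel_counts,
            "candidates": self.candidates,
            "significant_sets": self.significant_sets,
            "survival": self.survival,
            "config": self.config,
        }
        return json.dumps(_round_floats(payload), indent=2, sort_keys=True) + "\n"


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full funnel from serialized inputs.

    Stage order: fraction set algebra -> network expansion -> differential
    expression -> DEG intersection and ranking -> pre-ranked GSEA ->
    optional survival statistics. Every stage output is written under
    ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fractions = _stage("proteomics_sets")(
        lambda: [
            sio.read_fraction(fr["path"], fr["id"], fr["activity"])
            for fr in config.fractions
        ]
    )()
    if config.psm_path:
        psm_proteins = _stage("psm_filter")(
            lambda: filter_psms(
                sio.read_psm_table(config.psm_path),
                fdr_threshold=config.psm_fdr,
                min_length=config.min_peptide_length,
            )
        )()
        sio.write_json({"psm_proteins": sorted(psm_proteins)}, outdir / "psm_proteins.json")

    funnel = _stage("proteomics_sets")(lambda: run_funnel(fractions))()
    sio.write_json(funnel.to_dict(), outdir / "protein_sets.json")
    seeds = funnel.intersection
    if not seeds:
        raise RuntimeError(
            "pipeline stage 'proteomics_sets' produced an empty candidate set"
        )

    network = _stage("ppi_network")(
        lambda: load_network(config.network_path, config.network_dialect,
                             config.min_confidence)
    )()
    if config.min_confidence > 0:
        network = filter_confidence(network, config.min_confidence)
    expansion = _stage("ppi_network")(
        lambda: expand(network, seeds, config.include_seed_partners)
    )()
    sio.write_json(expansion.to_dict(), outdir / "expansion.json")

    study = _stage("deg_core")(
        lambda: sio.read_counts(config.counts_path, config.annotation_path)
    )()
    deg_results = _stage("deg_core")(
        lambda: DifferentialExpression(
            study,
            group_a=config.group_a,
            group_b=config.group_b,
            min_abundance_log2=config.min_abundance_log2,
            adjust_batch=config.adjust_batch,
        ).fit(fdr=config.deg_fdr)
    )()
    deg_results.table.to_csv(outdir / "deg_results.tsv", sep="\t", index_label="gene")
    degs = deg_results.deg_genes
    if not degs:
        logger.warning("no differentially expressed genes at q <= %g", config.deg_fdr)

    targets = _stage("integration")(lambda: overlap_targets(expansion, degs))()
    candidates = _stage("integration")(
        lambda: rank_candidates(expansion, degs, config.report_threshold)
    )()
    candidates.table.to_csv(outdir / "candidates.csv", index=False)

    sets = _stage("enrichment")(
        lambda: GeneSetCollection.from_gmt(config.gene_sets_path)
    )()
    gsea = _stage("enrichment")(
        lambda: PrerankedGSEA(deg_results.ranking, sets).fit(
            n_perm=config.n_perm, seed=config.seed
        )
    )()
    gsea.table.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
    significant = gsea.significant(config.gsea_fdr)
    if significant and len(significant) >= 2:
        summary = summarize_gene_sets(
            deg_results.expr, study.annotation["population"], sets, significant
        )
        sio.write_json(summary.to_dict(), outdir / "eigengene_summary.json")
        if summary.newick:
            (outdir / "gene_set_tree.nwk").write_text(summary.newick + "\n")

    survival_out = None
    if config.elispot_path:
        series = _stage("survival_stats")(lambda: sio.read_elispot(config.elispot_path))()
        if len(series) >= 2:
            f_stat, p = _stage("survival_stats")(
                lambda: anova_conditions(series, include_day=True)
            )()
            survival_out = {"anova_F": float(f_stat), "anova_p": float(p),
                            "conditions": [s.condition for s in series]}
            sio.write_json(survival_out, outdir / "survival_stats.json")

    report = PipelineReport(
        funnel_counts={
            "union_active": len(funnel.union_active),
            "differential": len(funnel.differential),
            "intersection": len(funnel.intersection),
            "union_partners": len(expansion.union_partners),
            "potential_ppi": expansion.n_interactions(),
            "genes_tested": len(deg_results.table),
            "deg": len(degs),
            "overlap_targets": len(targets),
            "significant_sets": len(significant),
        },
        candidates=candidates.table.to_dict(orient="records"),
        significant_sets=significant,
        survival=survival_out,
        seed=config.seed,
        config={k: v for k, v in asdict(config).items()},
        version=__version__,
    )
    (outdir / "report.json").write_text(report.to_json())
    return report


def simulate_inputs(outdir, seed: int = 0, **overrides) -> dict:
    """Generate a complete synthetic study on disk and return a config dict
    pointing at it (ready for :func:`validate_config` / :func:`run_pipeline`).

    Overrides are forwarded to the individual generators by prefix, e.g.
    ``n_genes``, ``n_nodes``, ``n_factors``, ``batch_effect_sd``.
    """
    from . import synthetic as syn

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net_kw = {k: overrides[k] for k in ("n_nodes", "n_edges", "attachment_bias")
              if k in overrides}
    network = syn.generate_ppi_network(seed=seed, **net_kw)
    fac_kw = {k: overrides[k] for k in ("n_factors", "min_degree") if k in overrides}
    factors = syn.plant_factors(network, seed=seed, **fac_kw)
    cnt_kw = {k: overrides[k] for k in (
        "n_genes", "samples_per_group", "neighbor_de_prob", "background_de_prob",
        "lfc_scale", "dispersion", "batch_effect_sd", "n_batches") if k in overrides}
    study, truth = syn.generate_counts(network, factors, seed=seed, **cnt_kw)
    fr_kw = {k: overrides[k] for k in ("dropout_rate", "contaminant_rate",
                                       "background_size") if k in overrides}
    fractions = syn.generate_fraction_proteomes(factors, seed=seed, **fr_kw)
    psms = syn.generate_psm_table(seed=seed)
    sets = syn.generate_gene_sets(sorted(study.genes), truth=truth, seed=seed)
    elispot = syn.generate_elispot_series(seed=seed)

    sio.write_network(network, outdir / "network.tsv")
    sio.write_counts(study, outdir / "counts.tsv", outdir / "annotation.tsv")
    fraction_entries = []
    for fr in fractions:
        path = outdir / f"fraction_{fr.fraction_id}.csv"
        sio.write_fraction(fr, path)
        fraction_entries.append(
            {"path": str(path), "id": fr.fraction_id, "activity": fr.activity}
        )
    sio.write_psm_table(psms, outdir / "psms.tsv")
    sets.to_gmt(outdir / "gene_sets.gmt")
    sio.write_elispot(elispot, outdir / "elispot.csv")
    sio.write_json(truth.to_dict(), outdir / "truth.json")

    config = {
        "counts_path": str(outdir / "counts.tsv"),
        "annotation_path": str(outdir / "annotation.tsv"),
        "network_path": str(outdir / "network.tsv"),
        "gene_sets_path": str(outdir / "gene_sets.gmt"),
        "fractions": fraction_entries,
        "psm_path": str(outdir / "psms.tsv"),
        "elispot_path": str(outdir / "elispot.csv"),
        "outdir": str(outdir / "results"),
        "seed": seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
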