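"""End-to-end orchestration of the pipeline stages.

Stage order: simulate (optional) -> normalize -> rank -> de -> scan ->
enrich. Every stage writes TSV outputs with a commented provenance header
under the configured run directory and appends a line to ``manifest.jsonl``
recording row counts and the parameters in force, so the gene/motif funnel
is auditable. Outputs carry no timestamps: identical config and seed give
byte-identical runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tc2tf import diffexp, enrichment, ranking
from tc2tf.io_formats import (read_design_tsv, read_expression_tsv,
                              read_fasta, read_probe_map_tsv, read_transfac,
                              write_expression_tsv, write_table_tsv)
from tc2tf.preprocess import (ExpressionDataset, fold_change_cube,
                              quantile_normalize)
from tc2tf.pwm import build_hit_table
from tc2tf.simulate import SimConfig, write_fixture_bundle

STAGES = ("simulate", "normalize", "rank", "de", "scan", "enrich")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and parameters of a pipeline run.

    Defaults follow the emulated study: top 1,000 ranked genes per replicate,
    6 k-means clusters, differential significance at adjusted p < 0.05, scan
    significance at permutation p < 0.1 with 1,000 shuffles, 3 sub-clusters.
    """

    output_dir: Path = Path("tc2tf_run")
    expression: Path | None = None
    design: Path | None = None
    probe_map: Path | None = None
    promoters: Path | None = None
    motifs: Path | None = None
    top_k: int = 1000
    kmeans_k: int = 6
    restarts: int = 10
    de_alpha: float = 0.05
    scan_alpha: float = 0.1
    n_perm: int = 1000
    subclusters: int = 3
    enrich_time_h: float = 24.0
    seed: int = 0
    simulate: dict | None = None

    def validate(self) -> None:
        if not 0 < self.de_alpha <= 1:
            raise PipelineError("config: de_alpha must lie in (0, 1]")
        if not 0 < self.scan_alpha <= 1:
            raise PipelineError("config: scan_alpha must lie in (0, 1]")
        if self.top_k < 1:
            raise PipelineError("config: top_k must be >= 1")
        if self.n_perm < 1:
            raise PipelineError("config: n_perm must be >= 1")
        if self.kmeans_k < 1 or self.subclusters < 1:
            raise PipelineError("config: cluster counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        cfg = {}
        inputs = raw.pop("inputs", {}) or {}
        for key in ("expression", "design", "probe_map", "promoters", "motifs"):
            if key in inputs:
                cfg[key] = Path(inputs[key])
        params = raw.pop("params", {}) or {}
        for k, v in {**raw, **params}.items():
            if k == "output_dir":
                cfg[k] = Path(v)
            elif k in known:
                cfg[k] = v
            else:
                raise PipelineError(f"config: unknown key {k!r}")
        out = cls(**cfg)
        out.validate()
        return out

    def params_dict(self) -> dict:
        return {"top_k": self.top_k, "kmeans_k": self.kmeans_k,
                "restarts": self.restarts, "de_alpha": self.de_alpha,
                "scan_alpha": self.scan_alpha, "n_perm": self.n_perm,
                "subclusters": self.subclusters,
                "enrich_time_h": self.enrich_time_h, "seed": self.seed}


def _manifest_append(cfg: PipelineConfig, stage: str, **info) -> None:
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    record = {"stage": stage, **info, "params": cfg.params_dict()}
    with open(cfg.output_dir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


_FIXTURE_FILES = {"expression": "expression.tsv", "design": "design.tsv",
                  "probe_map": "probe_map.tsv",
                  "promoters": "promoters.fasta", "motifs": "motifs.transfac"}


def _resolve_inputs(cfg: PipelineConfig) -> None:
    """Point unset input paths at a fixture written by a previous simulate."""
    fixture = cfg.output_dir / "fixture"
    for attr, fname in _FIXTURE_FILES.items():
        if getattr(cfg, attr) is None and (fixture / fname).exists():
            setattr(cfg, attr, fixture / fname)


def _require(path: Path | None, what: str, producer: str) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(
            f"missing {what} ({path}); run the '{producer}' stage first or "
            f"point the config at an existing file")
    return Path(path)


def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate the synthetic fixture bundle and wire it into the config."""
    if cfg.simulate is None:
        raise PipelineError("simulate: no 'simulate' section in config")
    sim_keys = set(SimConfig.__dataclass_fields__)
    extra_keys = {"n_motifs", "promoter_length", "planted_motif_prob",
                  "background_motif_prob"}
    unknown = set(cfg.simulate) - sim_keys - extra_keys
    if unknown:
        raise PipelineError(f"simulate: unknown keys {sorted(unknown)}")
    sim_cfg = SimConfig(**{k: v for k, v in cfg.simulate.items()
                           if k in sim_keys})
    if "seed" not in cfg.simulate:
        sim_cfg = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
    extra = {k: v for k, v in cfg.simulate.items() if k in extra_keys}
    fixture_dir = cfg.output_dir / "fixture"
    paths = write_fixture_bundle(fixture_dir, sim_cfg, **extra)
    cfg.expression = paths["expression"]
    cfg.design = paths["design"]
    cfg.probe_map = paths["probe_map"]
    cfg.promoters = paths["promoters"]
    cfg.motifs = paths["motifs"]
    _manifest_append(cfg, "simulate", n_genes=sim_cfg.n_genes,
                     seed=sim_cfg.seed)
    return paths


def load_dataset(cfg: PipelineConfig, normalized: bool = False
                 ) -> ExpressionDataset:
    _resolve_inputs(cfg)
    if normalized:
        expr = _require(cfg.output_dir / "normalized.tsv",
                        "normalized expression", "normalize")
    else:
        expr = _require(cfg.expression, "expression matrix", "simulate")
    design = read_design_tsv(_require(cfg.design, "design table", "simulate"))
    probe_map = read_probe_map_tsv(_require(cfg.probe_map, "probe map",
                                            "simulate"))
    values = read_expression_tsv(expr)
    return ExpressionDataset(values=values, design=design,
                             probe_map=probe_map)


def stage_normalize(cfg: PipelineConfig) -> ExpressionDataset:
    dataset = load_dataset(cfg, normalized=False)
    normalized = quantile_normalize(dataset.values)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(normalized, cfg.output_dir / "normalized.tsv",
                         params=cfg.params_dict())
    _manifest_append(cfg, "normalize", n_probes=len(normalized),
                     n_samples=normalized.shape[1])
    return dataset.with_values(normalized)


def stage_rank(cfg: PipelineConfig, dataset: ExpressionDataset | None = None
               ) -> dict:
    if dataset is None:
        dataset = load_dataset(cfg, normalized=True)
    cube = fold_change_cube(dataset)
    tables = ranking.rank_genes(cube, genotype="wt")
    for rep, tab in tables.items():
        write_table_tsv(tab, cfg.output_dir / f"rank_replicate{rep}.tsv",
                        params=cfg.params_dict())
    k = min(cfg.top_k, min(len(t) for t in tables.values()))
    common = ranking.intersect_top_k(tables, k)
    write_table_tsv(pd.DataFrame({"gene_id": common}),
                    cfg.output_dir / "responsive_genes.tsv",
                    params={**cfg.params_dict(), "k_used": k})
    kmeans_k = min(cfg.kmeans_k, len(common)) if common else 0
    if kmeans_k >= 1 and common:
        assignment = ranking.kmeans_profiles(common, cube, k=kmeans_k,
                                             n_restarts=cfg.restarts,
                                             seed=cfg.seed)
        labels = assignment.labels.rename_axis("gene_id").reset_index()
        write_table_tsv(labels, cfg.output_dir / "clusters.tsv",
                        params=cfg.params_dict())
        sup = ranking.superimpose(assignment, cube)
        write_table_tsv(sup, cfg.output_dir / "superimposition.tsv",
                        params=cfg.params_dict())
    else:
        assignment, sup = None, pd.DataFrame()
    _manifest_append(cfg, "rank", n_genes=len(cube.genes),
                     n_common=len(common), k_used=k)
    return {"cube": cube, "rank_tables": tables, "responsive": common,
            "assignment": assignment, "superimposition": sup}


def stage_de(cfg: PipelineConfig, dataset: ExpressionDataset | None = None
             ) -> pd.DataFrame:
    if dataset is None:
        dataset = load_dataset(cfg, normalized=True)
    fit = diffexp.fit_cell_means(dataset)
    stats = diffexp.select_significant(fit, alpha=cfg.de_alpha)
    pm = dataset.probe_map.set_index("probe_id")
    stats = stats.rename(columns={"gene_id": "probe_id"})
    stats["gene_id"] = [
        pm.loc[p, "gene_id"] if (p in pm.index and not pm.loc[p, "ambiguous"])
        else "" for p in stats["probe_id"]]
    write_table_tsv(stats, cfg.output_dir / "de_stats.tsv",
                    params=cfg.params_dict())
    sig = stats[stats["significant"]]
    write_table_tsv(sig, cfg.output_dir / "de_significant.tsv",
                    params=cfg.params_dict())
    counts = sig.groupby("time_h").size().to_dict()
    _manifest_append(cfg, "de", n_tests=len(stats),
                     n_significant_by_time={str(k): int(v)
                                            for k, v in counts.items()})
    return stats


def stage_scan(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    _resolve_inputs(cfg)
    promoters = read_fasta(_require(cfg.promoters, "promoter FASTA",
                                    "simulate"))
    motifs = read_transfac(_require(cfg.motifs, "motif library", "simulate"))
    hit_table, scan = build_hit_table(promoters, motifs,
                                      alpha=cfg.scan_alpha,
                                      n_perm=cfg.n_perm, seed=cfg.seed)
    write_table_tsv(hit_table.astype(int).reset_index(),
                    cfg.output_dir / "hit_table.tsv",
                    params=cfg.params_dict())
    write_table_tsv(scan, cfg.output_dir / "scan_results.tsv",
                    params=cfg.params_dict())
    _manifest_append(cfg, "scan", n_promoters=len(promoters),
                     n_motifs=len(motifs),
                     n_hits=int(hit_table.to_numpy().sum()))
    return hit_table, scan


def _load_hit_table(cfg: PipelineConfig) -> pd.DataFrame:
    path = _require(cfg.output_dir / "hit_table.tsv", "hit table", "scan")
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    return df.astype(bool)


def stage_enrich(cfg: PipelineConfig,
                 dataset: ExpressionDataset | None = None,
                 de_stats: pd.DataFrame | None = None,
                 hit_table: pd.DataFrame | None = None) -> pd.DataFrame:
    if dataset is None:
        dataset = load_dataset(cfg, normalized=True)
    if de_stats is None:
        path = _require(cfg.output_dir / "de_stats.tsv",
                        "differential statistics", "de")
        de_stats = pd.read_csv(path, sep="\t", comment="#",
                               dtype={"probe_id": str, "gene_id": str})
        de_stats["gene_id"] = de_stats["gene_id"].fillna("")
    if hit_table is None:
        hit_table = _load_hit_table(cfg)
    promoters_available = set(hit_table.index)
    sig = de_stats[(de_stats["significant"])
                   & (de_stats["time_h"] == cfg.enrich_time_h)]
    sig_genes = sorted({g for g in sig["gene_id"] if g})
    usable = [g for g in sig_genes if g in promoters_available]
    if len(usable) < max(2, cfg.subclusters):
        write_table_tsv(pd.DataFrame(
            columns=["motif_id", "gene_set", "a", "b", "c", "d",
                     "odds_ratio", "p", "q"]),
            cfg.output_dir / "enrichment.tsv", params=cfg.params_dict())
        _manifest_append(cfg, "enrich", n_de_genes=len(sig_genes),
                         n_promoter_mapped=len(usable), n_rows=0,
                         note="too few promoter-mapped significant genes")
        return pd.DataFrame()

    # sub-cluster the significant genes on their late-time sample columns
    design = dataset.design
    cols = design.loc[design["time_h"] == cfg.enrich_time_h,
                      "sample_id"].tolist()
    pm = dataset.probe_map
    primary = (pm[(~pm["ambiguous"]) & pm["gene_id"].isin(usable)]
               .sort_values(["gene_id", "probe_id"])
               .drop_duplicates("gene_id"))
    profiles = dataset.values.loc[primary["probe_id"], cols]
    profiles.index = primary["gene_id"].tolist()
    dist = enrichment.correlation_distance(profiles)
    sub = enrichment.hcluster_cut(dist, k=cfg.subclusters)
    write_table_tsv(sub.rename_axis("gene_id").reset_index(),
                    cfg.output_dir / "subclusters.tsv",
                    params=cfg.params_dict())
    background = sorted(promoters_available - set(usable))
    table = enrichment.enrich_all(hit_table, sub, background)
    write_table_tsv(table, cfg.output_dir / "enrichment.tsv",
                    params=cfg.params_dict())
    _manifest_append(cfg, "enrich", n_de_genes=len(sig_genes),
                     n_promoter_mapped=len(usable), n_rows=len(table))
    return table


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; any failure names the stage."""
    cfg.validate()
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    manifest = cfg.output_dir / "manifest.jsonl"
    if manifest.exists():
        manifest.unlink()
    results: dict = {}
    try:
        stage = "simulate"
        if cfg.simulate is not None:
            results["fixture"] = stage_simulate(cfg)
        stage = "normalize"
        dataset = stage_normalize(cfg)
        stage = "rank"
        results["rank"] = stage_rank(cfg, dataset)
        stage = "de"
        results["de"] = stage_de(cfg, dataset)
        stage = "scan"
        hit_table, scan = stage_scan(cfg)
        results["scan"] = scan
        stage = "enrich"
        results["enrichment"] = stage_enrich(cfg, dataset, results["de"],
                                             hit_table)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return results
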