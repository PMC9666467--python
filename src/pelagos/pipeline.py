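"""End-to-end orchestration of the analysis stages with provenance capture.

A :class:`PipelineConfig` (usually read from YAML) names either input files
(counts/metadata/tree/taxonomy) or a synthetic scenario, plus per-stage
parameter blocks.  :func:`run_stage` executes one of
``simulate | preprocess | mechanisms | indices | decay | stats | all`` and
writes TSV artifacts plus a JSON run manifest (config echo, derived seeds,
per-stage wall time) under the output directory.  A single global seed
deterministically derives per-stage substreams so stages rerun in isolation
reproduce the chained run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .table import (CountTable, FilterRule, abundance_filter, inverse_simpson,
                    rarefy, read_count_table, read_sample_metadata,
                    relative_abundance, write_count_table)
from .phylo import cophenetic_distances, read_tree
from .mechanisms import AssemblyModel, NullConfig
from .interactions import SparccConfig, sparcc_correlations, tina_dissimilarity, \
    pina_dissimilarity
from .biogeo import (anosim, bray_curtis_matrix, distance_decay_curve,
                     family_unifrac_decay_clusters, geographic_distance_matrix,
                     permanova_table)
from .synthetic import ScenarioConfig, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "mechanisms", "indices", "decay", "stats", "all")
_CHAIN = ("preprocess", "mechanisms", "indices", "decay", "stats")


class ConfigError(ValueError):
    """Raised for invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: str = "pelagos_out"
    seed: int = 0
    inputs: dict = field(default_factory=dict)       # counts/metadata/tree/taxonomy
    scenario: dict | None = None                     # alternative to inputs
    filter: dict = field(default_factory=lambda: {"enabled": True})
    rarefaction: dict = field(default_factory=lambda: {"depth": 8000, "enabled": False})
    nulls: dict = field(default_factory=lambda: {"n_null": 999, "pool_scope": "pairwise"})
    sparcc: dict = field(default_factory=dict)
    decay: dict = field(default_factory=lambda: {"span": 0.75, "grid_size": 100})
    stats: dict = field(default_factory=lambda: {"n_perm": 999})
    temperature_bin_width: float = 4.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Derive a reproducible per-stage seed from the global seed."""
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _load_dataset(cfg: PipelineConfig, outdir: Path):
    """Resolve counts/metadata/tree either from inputs or a prior simulate."""
    inputs = dict(cfg.inputs)
    simdir = outdir / "data"
    if not inputs and (simdir / "counts.tsv").exists():
        inputs = {"counts": simdir / "counts.tsv",
                  "metadata": simdir / "metadata.tsv",
                  "tree": simdir / "tree.nwk"}
    if "counts" not in inputs:
        raise ConfigError("missing input: counts (give inputs.counts or run simulate)")
    table = read_count_table(inputs["counts"])
    meta = read_sample_metadata(inputs["metadata"]) if inputs.get("metadata") else None
    tree = read_tree(inputs["tree"]) if inputs.get("tree") else None
    taxonomy = None
    if inputs.get("taxonomy"):
        taxonomy = pd.read_csv(inputs["taxonomy"], sep="\t", index_col=0).iloc[:, 0]
    return table, meta, tree, taxonomy


def _preprocessed(cfg: PipelineConfig, outdir: Path) -> CountTable:
    p = outdir / "preprocess" / "counts_filtered.tsv"
    if p.exists():
        return read_count_table(p)
    table, _, _, _ = _load_dataset(cfg, outdir)
    return table


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Execute a pipeline stage (or ``all``); returns the run manifest."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(_CHAIN) if stage == "all" else [stage]
    manifest = {"pelagos_version": __version__, "seed": cfg.seed, "stages": []}
    for st in stages:
        t0 = time.time()
        status = "ok"
        try:
            _STAGE_FUNCS[st](cfg, outdir)
        except Exception as exc:  # partial failure: keep completed artifacts
            status = f"failed: {exc}"
            logger.error("stage %s failed: %s", st, exc)
            manifest["stages"].append({"stage": st, "status": status,
                                       "seconds": round(time.time() - t0, 3)})
            _write_manifest(outdir, manifest)
            raise
        manifest["stages"].append({"stage": st, "status": status,
                                   "seed": cfg.stage_seed(st),
                                   "seconds": round(time.time() - t0, 3)})
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    if cfg.scenario is None:
        raise ConfigError("simulate requires a 'scenario' block")
    sc = dict(cfg.scenario)
    sc.setdefault("seed", cfg.stage_seed("simulate"))
    if "lat_range" in sc:
        sc["lat_range"] = tuple(sc["lat_range"])
    scenario = ScenarioConfig(**sc)
    generate_dataset(scenario, outdir=outdir / "data")


def _stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    table, _, _, _ = _load_dataset(cfg, outdir)
    stage_dir = outdir / "preprocess"
    stage_dir.mkdir(exist_ok=True)
    if cfg.filter.get("enabled", True):
        rule_kwargs = {k: v for k, v in cfg.filter.items() if k != "enabled"}
        table = abundance_filter(table, FilterRule(**rule_kwargs))
    if cfg.rarefaction.get("enabled", False):
        table = rarefy(table, cfg.rarefaction.get("depth", 8000),
                       seed=cfg.stage_seed("preprocess"))
    write_count_table(table, stage_dir / "counts_filtered.tsv",
                      provenance={"stage": "preprocess", "seed": cfg.stage_seed("preprocess")})


def _stage_mechanisms(cfg: PipelineConfig, outdir: Path) -> None:
    table, meta, tree, _ = _load_dataset(cfg, outdir)
    if tree is None:
        raise ConfigError("missing input: tree (required by mechanisms)")
    table = _preprocessed(cfg, outdir)
    stage_dir = outdir / "mechanisms"
    stage_dir.mkdir(exist_ok=True)
    null = NullConfig(n_null=int(cfg.nulls.get("n_null", 999)),
                      seed=cfg.stage_seed("mechanisms"),
                      pool_scope=cfg.nulls.get("pool_scope", "pairwise"))
    model = AssemblyModel(table, tree=tree, metadata=meta, config=null)
    if meta is not None and "temperature" in meta.data.columns:
        sig = model.check_phylogenetic_signal(
            n_perm=int(cfg.stats.get("n_perm", 999)),
            seed=cfg.stage_seed("mechanisms"))
        sig.to_csv(stage_dir / "phylo_signal_correlogram.tsv", sep="\t", index=False)
    res = model.fit()
    res.to_tsv(stage_dir / "mechanisms.tsv")
    res.fractions().to_csv(stage_dir / "fractions.tsv", sep="\t")
    if meta is not None and "temperature" in meta.data.columns:
        res.fractions_by_temperature_difference(cfg.temperature_bin_width) \
            .to_csv(stage_dir / "fractions_by_dT.tsv", sep="\t", index=False)
    (stage_dir / "summary.txt").write_text(res.summary() + "\n")


def _stage_indices(cfg: PipelineConfig, outdir: Path) -> None:
    table, _, tree, _ = _load_dataset(cfg, outdir)
    table = _preprocessed(cfg, outdir)
    stage_dir = outdir / "indices"
    stage_dir.mkdir(exist_ok=True)
    sp = SparccConfig(seed=cfg.stage_seed("indices"), **cfg.sparcc)
    assoc = sparcc_correlations(table, sp)
    assoc.to_csv(stage_dir / "sparcc.tsv", sep="\t")
    tina = tina_dissimilarity(table, assoc)
    pd.DataFrame(tina.data, index=tina.ids, columns=tina.ids) \
        .to_csv(stage_dir / "tina.tsv", sep="\t")
    if tree is not None:
        coph = cophenetic_distances(tree)
        pina = pina_dissimilarity(table, coph)
        pd.DataFrame(pina.data, index=pina.ids, columns=pina.ids) \
            .to_csv(stage_dir / "pina.tsv", sep="\t")


def _stage_decay(cfg: PipelineConfig, outdir: Path) -> None:
    table, meta, tree, taxonomy = _load_dataset(cfg, outdir)
    table = _preprocessed(cfg, outdir)
    if meta is None:
        raise ConfigError("missing input: metadata (required by decay)")
    stage_dir = outdir / "decay"
    stage_dir.mkdir(exist_ok=True)
    bc = bray_curtis_matrix(table, transform="total_sum_sqrt")
    geo = geographic_distance_matrix(meta, table.sample_ids)
    curve = distance_decay_curve(bc, geo, span=float(cfg.decay.get("span", 0.75)),
                                 grid_size=int(cfg.decay.get("grid_size", 100)))
    pd.DataFrame({"distance_km": curve.grid_km, "bray_curtis": curve.fitted}) \
        .to_csv(stage_dir / "bray_curtis_decay.tsv", sep="\t", index=False)
    if taxonomy is not None and tree is not None:
        assignments, curves = family_unifrac_decay_clusters(
            table, taxonomy, tree, meta,
            min_asvs=int(cfg.decay.get("min_asvs", 10)),
            min_span_km=float(cfg.decay.get("min_span_km", 10_000)),
            span=float(cfg.decay.get("span", 0.75)))
        assignments.to_csv(stage_dir / "family_clusters.tsv", sep="\t")
        curves.to_csv(stage_dir / "family_curves.tsv", sep="\t")


def _stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    table, meta, tree, _ = _load_dataset(cfg, outdir)
    table = _preprocessed(cfg, outdir)
    if meta is None:
        raise ConfigError("missing input: metadata (required by stats)")
    stage_dir = outdir / "stats"
    stage_dir.mkdir(exist_ok=True)
    alpha = pd.Series({s: inverse_simpson(table.sample(s).to_numpy())
                       for s in table.sample_ids}, name="inverse_simpson")
    alpha.to_csv(stage_dir / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    variables = cfg.stats.get("variables")
    if variables is None:
        variables = meta.aligned_to(table.sample_ids).env_variables()
    if variables:
        bc = bray_curtis_matrix(table, transform="total_sum_sqrt")
        permanova_table(bc, meta, variables,
                        n_perm=int(cfg.stats.get("n_perm", 999)),
                        seed=cfg.stage_seed("stats")) \
            .to_csv(stage_dir / "permanova_bray_curtis.tsv", sep="\t", index=False)
        grouping_col = cfg.stats.get("anosim_grouping", "province")
        groups = meta.aligned_to(table.sample_ids).data.get(grouping_col)
        if groups is not None and groups.nunique() >= 2 and \
                (groups.value_counts() >= 2).sum() >= 2:
            r, p = anosim(bc, groups, n_perm=int(cfg.stats.get("n_perm", 999)),
                          seed=cfg.stage_seed("stats"))
            pd.DataFrame([{"grouping": grouping_col, "anosim_r": r, "p_value": p}]) \
                .to_csv(stage_dir / "anosim.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "mechanisms": _stage_mechanisms,
    "indices": _stage_indices,
    "decay": _stage_decay,
    "stats": _stage_stats,
}
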