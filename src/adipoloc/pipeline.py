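"""Pipeline orchestration: simulation -> fine-mapping -> colocalization
-> enrichment -> cellularity, with validated configuration and a run
manifest.

A run is driven by one :class:`PipelineConfig` (YAML-loadable, schema-
validated, unknown keys rejected).  All randomness flows from the
single config seed through fixed per-stage substreams.  Every
intermediate is persisted in the documented text formats; a JSON
manifest records the config hash, per-file checksums, package versions
and wall-clock time per stage, and is written atomically at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import cellularity, coloc, enrich, io, locus_sim
from .finemap import credible_set, enumerate_posteriors

logger = logging.getLogger("adipoloc")


class FinemapParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    prior_variance_w: float = Field(0.01, gt=0)  # 0.1^2 on the standardized scale
    prior_per_variant: float | None = Field(None, gt=0, lt=1)  # default 1/m
    max_k: int = Field(1, ge=1)


class ColocParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = Field(0.8, gt=0, le=1)


class EnrichParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = Field(1000, ge=1)
    max_shift_bp: int = Field(500_000, gt=0)
    level: float = Field(0.99, gt=0, le=1)


class SimParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_individuals: int = Field(5000, ge=1)
    m_variants: int = Field(100, ge=1)
    locus_span_bp: int = Field(1_000_000, ge=2)
    ld_decay: float = Field(0.95, ge=0, lt=1)
    causal_index: int = Field(50, ge=0)
    h2_gwas: float = Field(0.05, ge=0, lt=1)
    h2_eqtl: float = Field(0.05, ge=0, lt=1)
    shared_causal: bool = True
    distinct_causal_index: int | None = None  # eQTL causal when not shared
    n_intervals: int = Field(10, ge=0)
    interval_length_bp: int = Field(2_000, ge=1)
    enrichment_mode: str = "causal-centered"


class CellularityParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = Field(2000, ge=1)
    group_a: dict = {"label": "WT_SAT", "mean_um": 40.4, "sd_um": 17.6, "depot_mass_g": 0.3}
    group_b: dict = {"label": "KO_SAT", "mean_um": 36.1, "sd_um": 12.1, "depot_mass_g": 0.3}
    density_g_per_ml: float = Field(0.915, gt=0)


class PipelineConfig(BaseModel):
    """Validated configuration for one single-locus run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "adipoloc_run"
    sim: SimParams = SimParams()
    finemap: FinemapParams = FinemapParams()
    coloc: ColocParams = ColocParams()
    enrich: EnrichParams = EnrichParams()
    cellularity: CellularityParams = CellularityParams()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _architecture(sim: SimParams) -> locus_sim.CausalArchitecture:
    eqtl_idx = sim.causal_index
    if not sim.shared_causal:
        if sim.distinct_causal_index is None:
            raise ValueError("distinct_causal_index required when shared_causal is false")
        eqtl_idx = sim.distinct_causal_index
    return locus_sim.CausalArchitecture(
        causal_indices_gwas=(sim.causal_index,),
        causal_indices_eqtl=(eqtl_idx,),
        h2_gwas=sim.h2_gwas,
        h2_eqtl=sim.h2_eqtl,
        shared=sim.shared_causal,
    )


def _sim_config(cfg: PipelineConfig) -> locus_sim.SimConfig:
    s = cfg.sim
    return locus_sim.SimConfig(
        n_individuals=s.n_individuals,
        m_variants=s.m_variants,
        locus_span_bp=s.locus_span_bp,
        ld_decay=s.ld_decay,
        seed=cfg.seed,
        architecture=_architecture(s),
        n_intervals=s.n_intervals,
        interval_length_bp=s.interval_length_bp,
        enrichment_mode=s.enrichment_mode,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, persist artifacts, return the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "versions": _versions(),
        "stages": {},
        "files": {},
    }
    report: dict = {}
    try:
        _stage_locus(config, out, manifest, report)
        _stage_cellularity(config, out, manifest, report)
    except Exception as exc:
        # keep partial outputs on disk for post-mortem
        failed_stage = next(
            (s for s, d in manifest["stages"].items() if "seconds" not in d), "unknown"
        )
        raise RuntimeError(f"pipeline failed in stage {failed_stage!r}: {exc}") from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1))
    _write_text_report(report, out / "report.txt")
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1))
    os.replace(tmp, out / "manifest.json")
    return manifest


def _stage_locus(config: PipelineConfig, out: Path, manifest: dict, report: dict) -> None:
    simcfg = _sim_config(config)
    arch = simcfg.architecture

    t0 = time.perf_counter()
    manifest["stages"]["simulate"] = {}
    logger.info("simulating locus: m=%d, n=%d", simcfg.m_variants, simcfg.n_individuals)
    haps = locus_sim.simulate_haplotypes(simcfg)
    ld = locus_sim.compute_ld(haps)
    y_gwas, y_eqtl = locus_sim.simulate_phenotypes(haps, arch, config.seed)
    gwas = locus_sim.marginal_summary_stats(haps, y_gwas)
    eqtl = locus_sim.marginal_summary_stats(haps, y_eqtl)
    track = locus_sim.simulate_annotation_track(simcfg, arch)
    io.write_summary_stats(gwas, out / "gwas.tsv")
    io.write_summary_stats(eqtl, out / "eqtl.tsv")
    io.write_ld(ld, out / "ld_r2.tsv")
    io.write_bed(track, out / "annotation.bed")
    manifest["stages"]["simulate"]["seconds"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    manifest["stages"]["finemap"] = {}
    fm = config.finemap
    post_g = enumerate_posteriors(gwas, ld, fm.max_k, fm.prior_per_variant, fm.prior_variance_w)
    post_e = enumerate_posteriors(eqtl, ld, fm.max_k, fm.prior_per_variant, fm.prior_variance_w)
    io.write_posteriors(post_g, out / "gwas_pip.tsv")
    io.write_posteriors(post_e, out / "eqtl_pip.tsv")
    cs = credible_set(post_e, config.enrich.level)
    report["credible_set"] = {
        "level": config.enrich.level,
        "n_members": len(cs.member_ids),
        "cumulative_mass": cs.cumulative_mass,
        "members": cs.member_ids,
    }
    manifest["stages"]["finemap"]["seconds"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    manifest["stages"]["coloc"] = {}
    res = coloc.colocalize_locus(
        gwas, eqtl, ld,
        max_k=fm.max_k,
        prior_per_variant=fm.prior_per_variant,
        prior_variance_w=fm.prior_variance_w,
        threshold=config.coloc.threshold,
    )
    report["colocalization"] = {
        "clpp": res.clpp,
        "mclpp": res.mclpp,
        "lead_pair": list(res.lead_pair),
        "colocalized": res.colocalized,
        "threshold": res.threshold,
    }
    manifest["stages"]["coloc"]["seconds"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    manifest["stages"]["enrich"] = {}
    en = config.enrich
    enr = enrich.credible_set_enrichment(
        post_e, track,
        level=en.level,
        n_perm=en.n_perm,
        max_shift_bp=en.max_shift_bp,
        window=(0, simcfg.locus_span_bp),
        seed=config.seed,
    )
    np.savetxt(
        out / "enrichment_null.tsv", enr.null_stats, fmt="%.10g",
        header="null overlap statistics (one per permutation)",
    )
    report["enrichment"] = {
        "observed_stat": enr.observed_stat,
        "empirical_p": enr.empirical_p,
        "n_perm": enr.n_perm,
        "max_shift_bp": enr.max_shift_bp,
    }
    manifest["stages"]["enrich"]["seconds"] = round(time.perf_counter() - t0, 3)


def _stage_cellularity(config: PipelineConfig, out: Path, manifest: dict, report: dict) -> None:
    t0 = time.perf_counter()
    manifest["stages"]["cellularity"] = {}
    cp = config.cellularity
    samples = {}
    for tag, grp in (("a", cp.group_a), ("b", cp.group_b)):
        sample = locus_sim.simulate_diameters(
            mean_um=float(grp["mean_um"]),
            sd_um=float(grp["sd_um"]),
            n_cells=cp.n_cells,
            seed=config.seed + (0 if tag == "a" else 1),
            depot=str(grp.get("label", tag)),
            animal_id=str(grp.get("label", tag)),
            depot_mass_g=float(grp["depot_mass_g"]),
        )
        samples[tag] = sample
        io.write_diameters(sample, out / f"diameters_{grp.get('label', tag)}.csv")
        res = cellularity.depot_cell_count(sample, cp.density_g_per_ml)
        report.setdefault("cellularity", {})[grp.get("label", tag)] = {
            "mean_diameter_um": res.mean_diameter_um,
            "mean_volume_um3": res.mean_volume_um3,
            "mean_cell_weight_g": res.mean_cell_weight_g,
            "cells_per_depot": res.cells_per_depot,
        }
    d_stat, p = cellularity.ks_two_sample(
        samples["a"].diameters_um, samples["b"].diameters_um
    )
    report["cellularity"]["ks_test"] = {"D": d_stat, "p": p}
    manifest["stages"]["cellularity"]["seconds"] = round(time.perf_counter() - t0, 3)


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["adipoloc run report", "===================", ""]
    cz = report.get("colocalization", {})
    if cz:
        lines += [
            f"colocalization: CLPP={cz['clpp']:.4f}  mCLPP={cz['mclpp']:.4f}  "
            f"colocalized={cz['colocalized']} (threshold {cz['threshold']})",
            f"lead pair: GWAS {cz['lead_pair'][0]}  eQTL {cz['lead_pair'][1]}",
        ]
    cs = report.get("credible_set", {})
    if cs:
        lines.append(
            f"{cs['level']:.0%} credible set: {cs['n_members']} variants "
            f"(mass {cs['cumulative_mass']:.4f})"
        )
    en = report.get("enrichment", {})
    if en:
        lines.append(
            f"annotation enrichment: stat={en['observed_stat']:.4f}  "
            f"empirical p={en['empirical_p']:.4g} ({en['n_perm']} permutations)"
        )
    cell = report.get("cellularity", {})
    for label, r in cell.items():
        if label == "ks_test":
            continue
        lines.append(
            f"cellularity [{label}]: mean diameter {r['mean_diameter_um']:.1f} um, "
            f"{r['cells_per_depot']:.3g} cells/depot"
        )
    if "ks_test" in cell:
        ks = cell["ks_test"]
        lines.append(f"KS test between groups: D={ks['D']:.4f}  p={ks['p']:.4g}")
    path.write_text("\n".join(lines) + "\n")


def _versions() -> dict:
    import pandas
    import scipy

    from . import __version__

    return {
        "adipoloc": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
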