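"""Configured, logged, seeded end-to-end pipeline over the library stages.

Each stage reads the previous stage's TSV artifacts from the output
directory, writes its own TSVs plus a JSON run summary (probe accounting,
thresholds, seeds), and logs to standard error.  Identical config + seeds
give byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffmeth, qpcr, quantify, regions, replicates, sim
from .errors import ConfigError, MissingArtifactError
from .preprocess import BetaMatrix, preprocess_dataset

log = logging.getLogger("oxbsarray")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(asctime)s] %(name)s %(levelname)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

STAGES = ("simulate", "preprocess", "detect", "quantify", "regions", "replicates", "validate")


@dataclass
class PipelineConfig:
    out_dir: str = "oxbs_out"
    data_dir: str | None = None  # fixture dir; default <out_dir>/sim
    alpha: float = 100.0
    det_threshold: float = 0.01
    max_failed_arrays: int = 1
    failed_if_ge: bool = True
    fdr: float = 0.01
    swan_seed: int = 0
    normalize: bool = True
    subsets: list = field(default_factory=lambda: [[1, 3], [2, 4]])
    sim: dict = field(default_factory=dict)
    qpcr_n_sites: int = 27
    qpcr_noise_sd: float = 0.02
    qpcr_seed: int = 0

    def validate(self) -> None:
        for name in ("det_threshold", "fdr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}: must lie in (0, 1), got {v}")
        if self.alpha < 0:
            raise ConfigError("alpha: must be >= 0")
        if self.max_failed_arrays < 0:
            raise ConfigError("max_failed_arrays: must be >= 0")
        sim.config_from_dict(self.sim).validate()

    @property
    def fixture_dir(self) -> Path:
        return Path(self.data_dir) if self.data_dir else Path(self.out_dir) / "sim"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_summary(out: Path, stage: str, payload: dict) -> None:
    (out / f"{stage}_summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _require(path: Path, producer: str):
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{producer}' stage first"
        )
    return path


def stage_simulate(cfg: PipelineConfig) -> Path:
    sim_cfg = sim.config_from_dict(cfg.sim)
    dataset = sim.simulate_dataset(sim_cfg)
    out = cfg.fixture_dir
    sim.write_fixture(dataset, out)
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    _write_summary(
        Path(cfg.out_dir),
        "simulate",
        {
            "n_probes": int(sim_cfg.n_probes),
            "n_arrays": int(2 * sim_cfg.n_reps_per_arm),
            "seed": int(sim_cfg.seed),
            "pi0": float(sim_cfg.pi0),
            "fixture_dir": os.path.relpath(out, cfg.out_dir),
        },
    )
    log.info("simulate: %d probes x %d arrays -> %s", sim_cfg.n_probes, 2 * sim_cfg.n_reps_per_arm, out)
    return out


def _load_dataset(cfg: PipelineConfig) -> sim.SimDataset:
    d = cfg.fixture_dir
    if not (d / "manifest.tsv").exists():
        raise MissingArtifactError(f"no dataset at {d}; run the 'simulate' stage first")
    return sim.read_fixture(d)


def stage_preprocess(cfg: PipelineConfig) -> BetaMatrix:
    dataset = _load_dataset(cfg)
    bm, mask = preprocess_dataset(
        dataset,
        alpha=cfg.alpha,
        det_threshold=cfg.det_threshold,
        max_failed_arrays=cfg.max_failed_arrays,
        swan_seed=cfg.swan_seed,
        normalize=cfg.normalize,
        failed_if_ge=cfg.failed_if_ge,
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bm.values.to_csv(out / "betas.tsv", sep="\t")
    bm.arrays.to_csv(out / "beta_arrays.tsv", sep="\t", index=False)
    mask.detp.to_csv(out / "detection_p.tsv", sep="\t")
    (out / "kept_probes.txt").write_text("\n".join(bm.values.index) + "\n")
    _write_summary(
        out,
        "preprocess",
        {
            "n_input": int(len(mask.detp)),
            "n_kept": int(mask.keep.sum()),
            "n_filtered": int((~mask.keep).sum()),
            "det_threshold": cfg.det_threshold,
            "max_failed_arrays": cfg.max_failed_arrays,
            "alpha": cfg.alpha,
            "swan_seed": cfg.swan_seed,
            "normalized": cfg.normalize,
        },
    )
    log.info("preprocess: kept %d / %d probes", int(mask.keep.sum()), len(mask.detp))
    return bm


def _load_betas(cfg: PipelineConfig) -> BetaMatrix:
    out = Path(cfg.out_dir)
    _require(out / "betas.tsv", "preprocess")
    _require(out / "beta_arrays.tsv", "preprocess")
    values = pd.read_csv(out / "betas.tsv", sep="\t", index_col="probe_id")
    arrays = pd.read_csv(out / "beta_arrays.tsv", sep="\t")
    return BetaMatrix(values=values, arrays=arrays)


def stage_detect(cfg: PipelineConfig) -> pd.DataFrame:
    bm = _load_betas(cfg)
    results, fit = diffmeth.test_probes(bm, fdr=cfg.fdr)
    out = Path(cfg.out_dir)
    cols = ["delta", "s_sq", "s_tilde_sq", "F", "p", "q", "significant", "sign"]
    results[cols].to_csv(out / "probe_tests.tsv", sep="\t")
    counts = diffmeth.significant_counts(results)
    _write_summary(
        out,
        "detect",
        {
            **counts,
            "n_tested": int(len(results)),
            "fdr_threshold": cfg.fdr,
            "d0": float(fit.d0) if np.isfinite(fit.d0) else "inf",
            "s0_sq": float(fit.s0_sq),
            "residual_df": float(fit.d),
        },
    )
    log.info(
        "detect: %d significant (%d positive, %d negative) of %d probes",
        counts["n_significant"], counts["n_positive"], counts["n_negative"], len(results),
    )
    return results


def _load_results(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    _require(out / "probe_tests.tsv", "detect")
    return pd.read_csv(out / "probe_tests.tsv", sep="\t", index_col="probe_id")


def stage_quantify(cfg: PipelineConfig) -> pd.DataFrame:
    bm = _load_betas(cfg)
    results = _load_results(cfg)
    estimates = quantify.estimate_levels(bm, results)
    out = Path(cfg.out_dir)
    estimates.to_csv(out / "modification_levels.tsv", sep="\t")
    summary = quantify.summarize_positive_calls(estimates)
    summary["median_effect_size_x100"] = quantify.effect_size_summary(results)
    _write_summary(out, "quantify", summary)
    log.info(
        "quantify: %d significant positive probes, median 5hmC %.3f",
        summary["n_significant_positive"], summary.get("median", float("nan")),
    )
    return estimates


def _load_estimates(cfg: PipelineConfig) -> pd.DataFrame:
    out = Path(cfg.out_dir)
    _require(out / "modification_levels.tsv", "quantify")
    return pd.read_csv(out / "modification_levels.tsv", sep="\t", index_col="probe_id")


def stage_regions(cfg: PipelineConfig) -> None:
    dataset = _load_dataset(cfg)
    estimates = _load_estimates(cfg)
    manifest = dataset.manifest.set_index("probe_id").loc[estimates.index].reset_index()
    gene_cat = regions.annotate_gene_regions(manifest, dataset.truth.gene_features)
    island_ctx = regions.annotate_island_context(manifest, dataset.truth.islands)
    est = estimates.reset_index(drop=True)
    out = Path(cfg.out_dir)
    regions.summarize_by_region(est, gene_cat, categories=regions.GENE_CATEGORIES).to_csv(
        out / "region_summary.tsv", sep="\t", index=False
    )
    regions.summarize_by_region(est, island_ctx, categories=regions.ISLAND_CONTEXTS).to_csv(
        out / "island_summary.tsv", sep="\t", index=False
    )
    regions.tss_profile(manifest, dataset.truth.gene_features, est).to_csv(
        out / "tss_profile.tsv", sep="\t", index=False
    )
    _write_summary(out, "regions", {"n_annotated": int(len(manifest))})
    log.info("regions: annotated %d probes", len(manifest))


def stage_replicates(cfg: PipelineConfig) -> replicates.SubsetComparison:
    bm = _load_betas(cfg)
    comp = replicates.subset_analysis(bm, tuple(tuple(s) for s in cfg.subsets), fdr=cfg.fdr)
    out = Path(cfg.out_dir)
    results = _load_results(cfg)
    estimates = quantify.estimate_levels(bm, results)
    truth_probes = None
    truth_path = cfg.fixture_dir / "truth.tsv"
    if truth_path.exists():
        truth_probes = pd.read_csv(truth_path, sep="\t")
    floor, curve = replicates.detection_floor(estimates, truth_probes)
    if curve is not None:
        curve.to_csv(out / "power_curve.tsv", sep="\t", index=False)
    payload = comp.as_dict()
    payload["detection_floor_full"] = floor
    _write_summary(out, "replicates", payload)
    pd.DataFrame([payload["min_positive_level"]]).to_csv(out / "subset_comparison.tsv", sep="\t", index=False)
    log.info(
        "replicates: full=%d, %s=%d, %s=%d significant",
        comp.n_sig_full, comp.subset_a, comp.n_sig_a, comp.subset_b, comp.n_sig_b,
    )
    return comp


def stage_validate(cfg: PipelineConfig) -> qpcr.ConcordanceResult:
    estimates = _load_estimates(cfg)
    dataset = _load_dataset(cfg)
    truth = dataset.truth.probes.set_index("probe_id")
    sites = qpcr.select_validation_sites(estimates, n_sites=cfg.qpcr_n_sites, seed=cfg.qpcr_seed)
    panel = qpcr.simulate_qpcr_panel(
        truth.loc[sites, "true_5hmc"], noise_sd=cfg.qpcr_noise_sd, seed=cfg.qpcr_seed
    )
    qpcr_levels = pd.Series(
        {t.site_id: qpcr.qpcr_5hmc_fraction(t) for t in panel}, name="qpcr_5hmc"
    )
    conc = qpcr.concordance(estimates.loc[sites, "level_5hmc"], qpcr_levels)
    out = Path(cfg.out_dir)
    conc.table.to_csv(out / "concordance.tsv", sep="\t")
    _write_summary(
        out,
        "validate",
        {
            "n_sites": int(len(sites)),
            "pearson_r": conc.r,
            "n_zero_qpcr_sites": len(conc.zero_qpcr_sites),
        },
    )
    log.info("validate: %d sites, r = %s", len(sites), f"{conc.r:.3f}" if conc.r is not None else "NA")
    return conc


_STAGE_FNS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "detect": stage_detect,
    "quantify": stage_quantify,
    "regions": stage_regions,
    "replicates": stage_replicates,
    "validate": stage_validate,
}


def run_pipeline(cfg: PipelineConfig, command: str = "all"):
    """Run one stage or the whole pipeline; returns the last stage's output."""
    cfg.validate()
    names = STAGES if command == "all" else (command,)
    result = None
    for name in names:
        if name not in _STAGE_FNS:
            raise ConfigError(f"unknown command {name!r}; choose from {STAGES + ('all',)}")
        t0 = time.perf_counter()
        result = _STAGE_FNS[name](cfg)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
    return result
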