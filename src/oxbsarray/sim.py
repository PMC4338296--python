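"""Synthetic Infinium-style paired BS/oxBS datasets with known ground truth.

The generator emulates a single biological sample split into four bisulfite
(BS) and four oxidative-bisulfite (oxBS) replicate arrays.  Per probe it
draws true fractions of unmodified C, 5mC and 5hmC that sum to one exactly;
the BS arm measures 5mC + 5hmC, the oxBS arm 5mC alone, so 5hmC is
recoverable by subtraction downstream.  Beta-scale replicate noise is
injected on the logit scale (keeping betas in (0,1)) and converted to
two-channel fluorescence intensities so the intensity -> beta path is
exercised end to end.  Truth is region-structured — CpG islands and
TSS-proximal probes carry low modification, gene bodies high — on a small
synthetic genome written out as BED tracks.

Everything is a pure function of the :class:`SimConfig` seed: identical
configs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import regions as _regions
from .errors import ConfigError, ValidationError

# ---------------------------------------------------------------------------
# distribution specs

_DIST_KINDS = {"uniform", "beta", "constant"}


def draw_dist(spec: dict, rng: np.random.Generator, size: int, *, fieldname: str) -> np.ndarray:
    """Draw from a distribution spec dict ({kind: uniform|beta|constant, ...})."""
    if not isinstance(spec, dict) or "kind" not in spec:
        raise ConfigError(f"{fieldname}: distribution spec must be a dict with a 'kind' key")
    kind = spec["kind"]
    try:
        if kind == "uniform":
            lo, hi = float(spec["low"]), float(spec["high"])
            if not lo <= hi:
                raise ConfigError(f"{fieldname}: uniform requires low <= high")
            return rng.uniform(lo, hi, size)
        if kind == "beta":
            return rng.beta(float(spec["a"]), float(spec["b"]), size)
        if kind == "constant":
            return np.full(size, float(spec["value"]))
    except KeyError as exc:
        raise ConfigError(f"{fieldname}: missing distribution parameter {exc}") from None
    raise ConfigError(f"{fieldname}: unknown distribution kind {kind!r} (use {sorted(_DIST_KINDS)})")


def _dist_support(spec: dict) -> tuple[float, float]:
    kind = spec.get("kind")
    if kind == "uniform":
        return float(spec["low"]), float(spec["high"])
    if kind == "beta":
        return 0.0, 1.0
    if kind == "constant":
        v = float(spec["value"])
        return v, v
    return -np.inf, np.inf


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study-design parameters for the simulated oxBS-array experiment.

    Defaults mirror the emulated experiment: 4 + 4 replicate arrays of one
    sample, 70% of probes with zero true 5hmC and the rest uniform on
    [0.005, 0.45], per-probe beta-scale noise SD uniform on [0.005, 0.05]
    (calibrated so between-replicate beta correlations land near the
    .97-.98 observed on real arrays), mean total probe intensity 5000
    fluorescence units against a background near 200.
    """

    n_probes: int = 10_000
    n_reps_per_arm: int = 4
    seed: int = 0
    pi0: float = 0.7
    hmc_truth_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 0.005, "high": 0.45})
    mc_truth_dist: dict | None = None  # None -> region-structured defaults
    noise_sd_dist: dict = field(default_factory=lambda: {"kind": "uniform", "low": 0.005, "high": 0.05})
    intensity_scale: float = 5000.0
    intensity_cv: float = 0.2
    background_mean: float = 200.0
    background_sd: float = 50.0
    frac_type2: float = 0.72
    n_negative_controls: int = 600
    fail_rate: float = 0.002

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ConfigError("n_probes: must be positive")
        if self.n_reps_per_arm < 1:
            raise ConfigError("n_reps_per_arm: must be >= 1")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ConfigError("pi0: must lie in [0, 1]")
        if not 0.0 <= self.frac_type2 <= 1.0:
            raise ConfigError("frac_type2: must lie in [0, 1]")
        if not 0.0 <= self.fail_rate < 1.0:
            raise ConfigError("fail_rate: must lie in [0, 1)")
        if self.intensity_scale <= 0 or self.intensity_cv <= 0:
            raise ConfigError("intensity_scale/intensity_cv: must be positive")
        if self.background_mean <= 0 or self.background_sd <= 0:
            raise ConfigError("background_mean/background_sd: must be positive")
        for name in ("hmc_truth_dist", "noise_sd_dist"):
            spec = getattr(self, name)
            lo, hi = _dist_support(spec)
            if name == "hmc_truth_dist" and not (0.0 <= lo and hi <= 1.0):
                raise ConfigError(f"{name}: support must lie within [0, 1]")
            if name == "noise_sd_dist" and lo < 0.0:
                raise ConfigError(f"{name}: noise SDs must be >= 0")
        if self.mc_truth_dist is not None:
            lo, hi = _dist_support(self.mc_truth_dist)
            if not (0.0 <= lo and hi <= 1.0):
                raise ConfigError("mc_truth_dist: support must lie within [0, 1]")


# ---------------------------------------------------------------------------
# truth


@dataclass
class TruthLandscape:
    """Simulator ground truth: per-probe modification fractions plus genome tracks.

    ``probes`` columns: probe_id, chrom, pos, design_type, n_cpgs,
    region_label, island_context, true_c, true_5mc, true_5hmc, noise_sd.
    ``gene_features`` / ``islands`` are BED-like frames for the synthetic
    genome the probes live on.
    """

    probes: pd.DataFrame
    gene_features: pd.DataFrame
    islands: pd.DataFrame


def _layout_genome(n_probes: int, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Tile one synthetic chromosome with genes (UTRs/exons/introns) and CpG islands."""
    span = max(int(n_probes) * 500, 100_000)
    feat_rows: list[tuple] = []
    island_rows: list[tuple] = []
    pos = int(rng.integers(2_000, 5_000))
    while pos + 4_000 < span:
        u5 = int(rng.integers(100, 600))
        u3 = int(rng.integers(100, 1_200))
        body_len = int(rng.integers(1_500, 18_000))
        glen = u5 + body_len + u3
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + glen
        feat_rows.append(("chr1", start, end, "gene", ".", strand))
        if strand == "+":
            feat_rows.append(("chr1", start, start + u5, "5utr", ".", strand))
            feat_rows.append(("chr1", end - u3, end, "3utr", ".", strand))
            body = (start + u5, end - u3)
        else:
            feat_rows.append(("chr1", end - u5, end, "5utr", ".", strand))
            feat_rows.append(("chr1", start, start + u3, "3utr", ".", strand))
            body = (start + u3, end - u5)
        # alternate exon/intron across the body, first and last segments exonic
        p = body[0]
        is_exon = True
        while p < body[1]:
            seg = int(rng.integers(150, 400)) if is_exon else int(rng.integers(500, 3_000))
            q = min(p + seg, body[1])
            feat_rows.append(("chr1", p, q, "exon" if is_exon else "intron", ".", strand))
            p = q
            is_exon = not is_exon
        tss = start if strand == "+" else end - 1
        if rng.random() < 0.6:
            ilen = int(rng.integers(400, 1_600))
            island_rows.append(("chr1", max(0, tss - ilen // 2), tss + ilen // 2))
        gap = int(rng.integers(2_000, 30_000))
        if rng.random() < 0.15:  # occasional intergenic island
            ilen = int(rng.integers(300, 1_000))
            istart = end + int(rng.integers(500, max(600, gap - ilen)))
            island_rows.append(("chr1", istart, istart + ilen))
        pos = end + gap
    gene_features = pd.DataFrame(feat_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end"])
    return gene_features, islands, span


_MC_BETA_PARAMS = {
    # (a, b) of a Beta draw for true 5mC, by context
    "island": (0.6, 6.0),
    "tss_proximal": (1.2, 6.0),
    "gene_body": (7.0, 3.0),
    "shore": (3.0, 4.0),
    "background": (4.0, 3.0),
}

_HMC_REGION_WEIGHT = {
    # relative probability that a probe carries any 5hmC
    "island": 0.3,
    "tss_proximal": 0.5,
    "gene_body": 1.3,
    "shore": 0.8,
    "background": 1.0,
}


def _nonzero_probability(weights: np.ndarray, target: float) -> np.ndarray:
    """Per-probe probability of carrying any 5hmC.

    Proportional to the region weights, clipped to [0, 1], with the scale
    chosen (by bisection; mean is monotone in the scale) so the average
    probability equals ``target`` exactly.
    """
    if target <= 0.0:
        return np.zeros(len(weights))
    if target >= 1.0:
        return np.ones(len(weights))
    lo, hi = 0.0, 1.0 / weights.min()
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.clip(mid * weights, 0.0, 1.0).mean() < target:
            lo = mid
        else:
            hi = mid
    return np.clip(0.5 * (lo + hi) * weights, 0.0, 1.0)


def _sample_positions(n: int, span: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct sorted probe coordinates, drawn without materialising range(span)."""
    pos = np.unique(rng.integers(0, span, int(n * 1.2) + 10))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(0, span, n)]))
    if len(pos) > n:
        pos = np.sort(rng.choice(pos, n, replace=False))
    return pos


def _context_class(region: np.ndarray, island_ctx: np.ndarray) -> np.ndarray:
    out = np.full(len(region), "background", dtype=object)
    body = np.isin(region, ("exon", "intron", "3utr", "downstream"))
    out[body] = "gene_body"
    tssp = np.isin(region, ("upstream", "5utr"))
    out[tssp] = "tss_proximal"
    out[island_ctx == "shore"] = "shore"
    out[island_ctx == "island"] = "island"
    return out


def simulate_truth(config: SimConfig) -> TruthLandscape:
    """Draw the ground-truth modification landscape for one simulated sample.

    Per probe, (true_c, true_5mc, true_5hmc) sum to one exactly.  A fraction
    ``pi0`` of probes carries zero 5hmC; the chance of a nonzero draw is
    modulated by genomic context (islands/TSS low, gene bodies high) while
    nonzero levels come from ``hmc_truth_dist`` everywhere, so region medians
    of the positive levels stay comparable but positive-probe proportions
    differ by region.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_probes

    gene_features, islands, span = _layout_genome(n, rng)
    pos = _sample_positions(n, span, rng)
    manifest = pd.DataFrame({"chrom": "chr1", "pos": pos})
    region = _regions.annotate_gene_regions(manifest, gene_features).to_numpy()
    island_ctx = _regions.annotate_island_context(manifest, islands).to_numpy()
    ctx = _context_class(region, island_ctx)

    # 5hmC mixture: zero with prob 1 - p_i, p_i region-weighted, mean = 1 - pi0
    w = np.array([_HMC_REGION_WEIGHT[c] for c in ctx])
    p_nonzero = _nonzero_probability(w, 1.0 - config.pi0)
    nonzero = rng.random(n) < p_nonzero
    hmc = np.zeros(n)
    hmc[nonzero] = draw_dist(config.hmc_truth_dist, rng, int(nonzero.sum()), fieldname="hmc_truth_dist")

    if config.mc_truth_dist is not None:
        mc = draw_dist(config.mc_truth_dist, rng, n, fieldname="mc_truth_dist")
    else:
        mc = np.empty(n)
        for cls, (a, b) in _MC_BETA_PARAMS.items():
            m = ctx == cls
            mc[m] = rng.beta(a, b, int(m.sum()))
    # keep betas off the exact boundary, then enforce the sum-to-one constraint
    mc = np.clip(mc, 0.01, 0.98)
    over = mc + hmc > 1.0
    mc[over] = 1.0 - hmc[over]
    c = 1.0 - mc - hmc

    noise_sd = draw_dist(config.noise_sd_dist, rng, n, fieldname="noise_sd_dist")
    if np.any(noise_sd < 0):
        raise ConfigError("noise_sd_dist: produced negative SDs")

    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n)],
            "chrom": "chr1",
            "pos": pos,
            "design_type": np.where(rng.random(n) < config.frac_type2, "II", "I"),
            "n_cpgs": rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2]),
            "region_label": region,
            "island_context": island_ctx,
            "true_c": c,
            "true_5mc": mc,
            "true_5hmc": hmc,
            "noise_sd": noise_sd,
        }
    )
    return TruthLandscape(probes=probes, gene_features=gene_features, islands=islands)


# ---------------------------------------------------------------------------
# intensities


@dataclass
class SimDataset:
    """A complete simulated experiment ready for preprocessing.

    ``intensities`` holds methylated/unmethylated channel columns
    ``M_<array>`` / ``U_<array>`` indexed by probe_id; ``arrays`` maps each
    array id to its arm (BS/oxBS) and replicate index.
    """

    manifest: pd.DataFrame
    intensities: pd.DataFrame
    negative_controls: pd.DataFrame
    arrays: pd.DataFrame
    truth: TruthLandscape


def array_ids(n_reps_per_arm: int) -> pd.DataFrame:
    rows = [("BS_%d" % (i + 1), "BS", i + 1) for i in range(n_reps_per_arm)]
    rows += [("oxBS_%d" % (i + 1), "oxBS", i + 1) for i in range(n_reps_per_arm)]
    return pd.DataFrame(rows, columns=["array_id", "arm", "replicate"])


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(25)
_GH_X = np.sqrt(2.0) * _GH_NODES
_GH_W = _GH_WEIGHTS / np.sqrt(np.pi)


def _centering_shift(z0: np.ndarray, s_logit: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Logit-scale shift making the logit-normal mean equal ``target``.

    Solves E[expit(z0 + shift + s*eps)] = target by Newton iteration with a
    Gauss-Hermite quadrature for the expectation; initialised at the
    second-order delta-method correction.
    """
    shift = 0.5 * (2.0 * target - 1.0) * s_logit**2
    for _ in range(6):
        g = expit(z0[:, None] + shift[:, None] + s_logit[:, None] * _GH_X[None, :])
        mean = g @ _GH_W
        deriv = (g * (1.0 - g)) @ _GH_W
        step = (target - mean) / np.maximum(deriv, 1e-12)
        shift = shift + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return shift


def _noisy_beta(beta: np.ndarray, noise_sd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Logit-normal perturbation with beta-scale SD ~= noise_sd and exact mean.

    The logit-scale SD is noise_sd / (b(1-b)) by the delta method, with b
    clamped to [0.02, 0.98] so the implied spread stays finite near the
    boundary (where the achievable beta-scale SD is necessarily smaller).
    The perturbation is mean-centred numerically so that
    E[beta_noisy] = beta (the logit-normal is otherwise skewed off-centre).
    """
    bc = np.clip(beta, 0.02, 0.98)
    s_logit = noise_sd / (bc * (1.0 - bc))
    target = np.clip(beta, 1e-4, 1.0 - 1e-4)
    z0 = logit(target)
    shift = _centering_shift(z0, s_logit, target)
    z = z0 + shift + rng.normal(0.0, 1.0, beta.shape) * s_logit
    out = expit(z)
    exact = noise_sd == 0.0
    if np.any(exact):
        out = np.where(exact, beta, out)
    return out


def _background_channels(n: int, config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    total = np.maximum(rng.normal(config.background_mean, config.background_sd, n), 1.0)
    split = rng.uniform(0.0, 1.0, n)
    return total * split, total * (1.0 - split)


def simulate_intensities(truth: TruthLandscape, config: SimConfig) -> SimDataset:
    """Render truth into per-array two-channel intensities.

    BS arrays target beta = true_5mc + true_5hmc, oxBS arrays beta =
    true_5mc.  Each probe x array cell draws a total intensity T (gamma, mean
    ``intensity_scale``), splits it as M = T*beta_noisy, U = T*(1-beta_noisy),
    and with probability ``fail_rate`` is replaced by a background-level draw.
    Negative-control probes are pure background on every array.
    """
    config.validate()
    probes = truth.probes
    if len(probes) != config.n_probes:
        raise ValidationError(
            f"truth has {len(probes)} probes but config.n_probes = {config.n_probes}"
        )
    rng = np.random.default_rng([config.seed, 1])
    n = len(probes)
    arrays = array_ids(config.n_reps_per_arm)
    beta_true = {
        "BS": (probes["true_5mc"] + probes["true_5hmc"]).to_numpy(),
        "oxBS": probes["true_5mc"].to_numpy(),
    }
    noise_sd = probes["noise_sd"].to_numpy()
    shape = 1.0 / config.intensity_cv**2

    cols: dict[str, np.ndarray] = {}
    for row in arrays.itertuples(index=False):
        b = _noisy_beta(beta_true[row.arm], noise_sd, rng)
        total = rng.gamma(shape, config.intensity_scale / shape, n)
        fail = rng.random(n) < config.fail_rate
        if fail.any():
            m_bg, u_bg = _background_channels(int(fail.sum()), config, rng)
            total[fail] = m_bg + u_bg
            b[fail] = m_bg / (m_bg + u_bg)
        cols[f"M_{row.array_id}"] = total * b
        cols[f"U_{row.array_id}"] = total * (1.0 - b)
    intensities = pd.DataFrame(cols, index=pd.Index(probes["probe_id"], name="probe_id"))

    neg_cols: dict[str, np.ndarray] = {}
    for row in arrays.itertuples(index=False):
        m_bg, u_bg = _background_channels(config.n_negative_controls, config, rng)
        neg_cols[f"M_{row.array_id}"] = m_bg
        neg_cols[f"U_{row.array_id}"] = u_bg
    negative_controls = pd.DataFrame(
        neg_cols,
        index=pd.Index([f"neg{i:05d}" for i in range(config.n_negative_controls)], name="control_id"),
    )

    manifest = probes[["probe_id", "chrom", "pos", "design_type", "n_cpgs"]].copy()
    manifest["is_control"] = False
    return SimDataset(
        manifest=manifest,
        intensities=intensities,
        negative_controls=negative_controls,
        arrays=arrays,
        truth=truth,
    )


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Convenience wrapper: truth + intensities in one call."""
    return simulate_intensities(simulate_truth(config), config)


# ---------------------------------------------------------------------------
# fixtures on disk

_FILES = {
    "manifest": "manifest.tsv",
    "intensities": "intensities.tsv",
    "negative_controls": "negative_controls.tsv",
    "arrays": "arrays.tsv",
    "truth": "truth.tsv",
    "gene_features": "gene_features.bed",
    "islands": "cpg_islands.bed",
}


def write_fixture(dataset: SimDataset, out_dir) -> dict[str, Path]:
    """Write the dataset as plain TSV/BED files; round-trips via read_fixture."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in _FILES.items()}
    dataset.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    dataset.intensities.to_csv(paths["intensities"], sep="\t")
    dataset.negative_controls.to_csv(paths["negative_controls"], sep="\t")
    dataset.arrays.to_csv(paths["arrays"], sep="\t", index=False)
    dataset.truth.probes.to_csv(paths["truth"], sep="\t", index=False)
    _regions.write_bed(dataset.truth.gene_features, paths["gene_features"], columns=6)
    _regions.write_bed(dataset.truth.islands.assign(name=".", score=".", strand="."), paths["islands"], columns=3)
    return paths


def read_fixture(in_dir) -> SimDataset:
    """Read a fixture written by :func:`write_fixture`."""
    p = Path(in_dir)
    for key, fname in _FILES.items():
        if not (p / fname).exists():
            raise ValidationError(f"fixture directory {p} is missing {fname}")
    manifest = pd.read_csv(p / _FILES["manifest"], sep="\t")
    intensities = pd.read_csv(p / _FILES["intensities"], sep="\t", index_col="probe_id")
    negative_controls = pd.read_csv(p / _FILES["negative_controls"], sep="\t", index_col="control_id")
    arrays = pd.read_csv(p / _FILES["arrays"], sep="\t")
    probes = pd.read_csv(p / _FILES["truth"], sep="\t")
    gene_features = _regions.read_bed(p / _FILES["gene_features"])
    islands = _regions.read_bed(p / _FILES["islands"])[["chrom", "start", "end"]]
    truth = TruthLandscape(probes=probes, gene_features=gene_features, islands=islands)
    return SimDataset(
        manifest=manifest,
        intensities=intensities,
        negative_controls=negative_controls,
        arrays=arrays,
        truth=truth,
    )


def config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(d) - known
    if bad:
        raise ConfigError(f"unknown simulation config fields: {sorted(bad)}")
    return SimConfig(**d)
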