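"""Intensity-level preprocessing: betas, detection p-values, failed-probe
filtering and subset-quantile within-array (SWAN-style) normalization.

The pipeline order is: normalize intensities, filter probes that fail
detection against the negative-control background, then compute beta values
(beta = M / (M + U + alpha), alpha = 100 by platform convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError

DEFAULT_ALPHA = 100.0
DEFAULT_DET_THRESHOLD = 0.01
DEFAULT_MAX_FAILED = 1


@dataclass
class BetaMatrix:
    """Probes x arrays beta values with per-array arm labels and replicate ids.

    ``values``: DataFrame indexed by probe_id, one column per array.
    ``arrays``: DataFrame with array_id / arm (BS|oxBS) / replicate columns,
    one row per column of ``values``.
    """

    values: pd.DataFrame
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if list(self.arrays["array_id"]) != cols:
            raise ValidationError("arrays table must list the beta columns in order")
        v = self.values.to_numpy()
        if np.any(v < 0) or np.any(v > 1) or np.any(~np.isfinite(v)):
            raise ValidationError("beta values must lie in [0, 1]")
        arms = set(self.arrays["arm"])
        if not arms <= {"BS", "oxBS"}:
            raise ValidationError(f"unknown arm labels: {sorted(arms - {'BS', 'oxBS'})}")
        pairs = list(zip(self.arrays["arm"], self.arrays["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicated (arm, replicate) pair")

    def arm_columns(self, arm: str) -> list[str]:
        return list(self.arrays.loc[self.arrays["arm"] == arm, "array_id"])

    def subset_replicates(self, replicates) -> "BetaMatrix":
        """Restrict both arms to the given replicate indices (1-based)."""
        keep = self.arrays["replicate"].isin(list(replicates))
        arrays = self.arrays[keep].reset_index(drop=True)
        return BetaMatrix(values=self.values[list(arrays["array_id"])], arrays=arrays)


@dataclass(frozen=True)
class BackgroundModel:
    """Per-array Gaussian background for total (M + U) intensity."""

    mu_bg: pd.Series
    sigma_bg: pd.Series


@dataclass
class DetectionMask:
    """Per-cell detection p-values plus the per-probe keep decision."""

    detp: pd.DataFrame
    keep: pd.Series
    threshold: float
    max_failed_arrays: int


def compute_beta(M, U, alpha: float = DEFAULT_ALPHA):
    """beta = M / (M + U + alpha); zero-signal cells return 0 by convention."""
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0) or alpha < 0:
        raise ValidationError("intensities and alpha must be non-negative")
    denom = M + U + alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, M / np.where(denom > 0, denom, 1.0), 0.0)
    return beta if beta.ndim else float(beta)


def fit_background(negative_controls: pd.DataFrame, arrays: pd.DataFrame) -> BackgroundModel:
    """Background model per array from negative-control probes.

    mu_bg = mean(M_neg) + mean(U_neg), sigma_bg = sd(M_neg) + sd(U_neg).
    """
    if negative_controls is None or len(negative_controls) == 0:
        raise ValidationError(
            "no negative-control probes supplied; a background model is required "
            "for detection p-values"
        )
    mu, sigma = {}, {}
    for a in arrays["array_id"]:
        m = negative_controls[f"M_{a}"]
        u = negative_controls[f"U_{a}"]
        mu[a] = float(m.mean() + u.mean())
        sigma[a] = float(m.std(ddof=1) + u.std(ddof=1))
        if sigma[a] <= 0:
            raise ValidationError(f"array {a}: degenerate background SD")
    return BackgroundModel(mu_bg=pd.Series(mu), sigma_bg=pd.Series(sigma))


def detection_pvalue(M, U, mu_bg: float, sigma_bg: float):
    """Upper-tail Gaussian probability that total signal M+U is background."""
    if sigma_bg <= 0:
        raise ValidationError("sigma_bg must be positive")
    return norm.sf(np.asarray(M, dtype=float) + np.asarray(U, dtype=float), loc=mu_bg, scale=sigma_bg)


def detection_pvalues(
    intensities: pd.DataFrame, arrays: pd.DataFrame, bg: BackgroundModel
) -> pd.DataFrame:
    out = {}
    for a in arrays["array_id"]:
        out[a] = detection_pvalue(
            intensities[f"M_{a}"], intensities[f"U_{a}"], bg.mu_bg[a], bg.sigma_bg[a]
        )
    return pd.DataFrame(out, index=intensities.index)


def filter_failed_probes(
    detp: pd.DataFrame,
    threshold: float = DEFAULT_DET_THRESHOLD,
    max_failed_arrays: int = DEFAULT_MAX_FAILED,
    failed_if_ge: bool = True,
) -> DetectionMask:
    """Keep probes failing detection in at most ``max_failed_arrays`` arrays.

    By default a cell FAILS when detp >= threshold (low detection p = good
    signal); ``failed_if_ge=False`` flips to the literal reading where
    detp < threshold marks the failure.
    """
    failed = (detp.to_numpy() >= threshold) if failed_if_ge else (detp.to_numpy() < threshold)
    n_failed = failed.sum(axis=1)
    keep = pd.Series(n_failed <= max_failed_arrays, index=detp.index, name="keep")
    return DetectionMask(detp=detp, keep=keep, threshold=threshold, max_failed_arrays=max_failed_arrays)


# ---------------------------------------------------------------------------
# SWAN-style normalization

_STRATA = (1, 2, 3)  # n_cpgs strata; 3 means "3 or more"


def _subset_indices(manifest: pd.DataFrame, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Equal-count random subsets of Type I / Type II probes per CpG stratum."""
    ncpg = np.minimum(manifest["n_cpgs"].to_numpy(), 3)
    dtype = manifest["design_type"].to_numpy()
    cells = {}
    for t in ("I", "II"):
        for s in _STRATA:
            idx = np.flatnonzero((dtype == t) & (ncpg == s))
            if len(idx) == 0:
                raise ValidationError(
                    f"SWAN: no Type {t} probes in CpG stratum {s}; cannot build matched subsets"
                )
            cells[(t, s)] = idx
    n_per = min(len(v) for v in cells.values())
    subs = {}
    for t in ("I", "II"):
        subs[t] = np.concatenate(
            [rng.choice(cells[(t, s)], n_per, replace=False) for s in _STRATA]
        )
    return subs["I"], subs["II"]


def _map_to_reference(x: np.ndarray, subset: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map one channel of one array onto the reference quantiles.

    Subset probes take the reference value at their rank; non-subset probes
    interpolate between flanking subset quantiles, with a constant offset
    beyond the extremes.  Output is clipped at zero.
    """
    out = x.astype(float).copy()
    xs = x[subset]
    order = np.argsort(xs, kind="stable")
    out[subset[order]] = reference
    xs_sorted = xs[order]
    mask = np.ones(len(x), dtype=bool)
    mask[subset] = False
    rest = np.flatnonzero(mask)
    if len(rest):
        xr = x[rest]
        interp = np.interp(xr, xs_sorted, reference)
        low = xr < xs_sorted[0]
        high = xr > xs_sorted[-1]
        interp[low] = xr[low] + (reference[0] - xs_sorted[0])
        interp[high] = xr[high] + (reference[-1] - xs_sorted[-1])
        out[rest] = interp
    return np.maximum(out, 0.0)


def swan_normalize(
    intensities: pd.DataFrame,
    manifest: pd.DataFrame,
    arrays: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Subset-quantile within-array normalization of both channels.

    Per array and channel: draw CpG-content-matched random subsets of Type I
    and Type II probes, average the two subsets' sorted intensities into a
    reference distribution, and map every probe onto it (subset probes by
    rank, the rest by interpolation).  Deterministic given ``seed``.
    """
    mf = manifest.set_index("probe_id").loc[intensities.index]
    rng = np.random.default_rng([seed, 17])
    out = intensities.copy()
    for a in arrays["array_id"]:
        for ch in ("M", "U"):
            sub1, sub2 = _subset_indices(mf, rng)
            x = intensities[f"{ch}_{a}"].to_numpy()
            s1 = np.sort(x[sub1], kind="stable")
            s2 = np.sort(x[sub2], kind="stable")
            reference = (s1 + s2) / 2.0
            y = x.astype(float).copy()
            y = _map_to_reference(y, sub1, reference)
            y2 = _map_to_reference(x.astype(float), sub2, reference)
            # each type owns its own mapping; non-subset probes of each type
            # follow their type's subset
            type1 = (mf["design_type"] == "I").to_numpy()
            res = np.where(type1, y, y2)
            out[f"{ch}_{a}"] = res
    return out


def betas_from_intensities(
    intensities: pd.DataFrame, arrays: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    cols = {}
    for a in arrays["array_id"]:
        cols[a] = compute_beta(intensities[f"M_{a}"], intensities[f"U_{a}"], alpha)
    return pd.DataFrame(cols, index=intensities.index)


def pairwise_correlation(betas: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between array beta columns, reported x100."""
    values = betas.values if isinstance(betas, BetaMatrix) else betas
    if values.shape[1] < 2:
        raise ValidationError("pairwise correlation needs at least 2 arrays")
    return values.corr(method="pearson") * 100.0


def mean_within_arm_correlation(bm: BetaMatrix, arm: str) -> float:
    """Mean off-diagonal correlation among one arm's replicates (x100 scale)."""
    cols = bm.arm_columns(arm)
    corr = pairwise_correlation(bm.values[cols]).to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def preprocess_dataset(
    dataset,
    alpha: float = DEFAULT_ALPHA,
    det_threshold: float = DEFAULT_DET_THRESHOLD,
    max_failed_arrays: int = DEFAULT_MAX_FAILED,
    swan_seed: int = 0,
    normalize: bool = True,
    failed_if_ge: bool = True,
) -> tuple[BetaMatrix, DetectionMask]:
    """Full preprocessing of a simulated dataset.

    Normalizes (SWAN), computes detection p-values against the raw
    negative-control background, filters failed probes, and returns the beta
    matrix restricted to kept probes together with the detection mask.
    """
    arrays = dataset.arrays
    bg = fit_background(dataset.negative_controls, arrays)
    detp = detection_pvalues(dataset.intensities, arrays, bg)
    mask = filter_failed_probes(detp, det_threshold, max_failed_arrays, failed_if_ge)
    intens = (
        swan_normalize(dataset.intensities, dataset.manifest, arrays, seed=swan_seed)
        if normalize
        else dataset.intensities
    )
    betas = betas_from_intensities(intens, arrays, alpha=alpha)
    bm = BetaMatrix(values=betas.loc[mask.keep.to_numpy()], arrays=arrays)
    return bm, mask
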