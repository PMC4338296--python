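"""Per-probe 5mC / 5hmC / unmodified-C estimates from arm-wise beta means.

The BS arm reads 5mC + 5hmC and the oxBS arm 5mC alone, so the subtraction
estimator is: 5mC = mean oxBS beta, 5hmC = mean BS beta - mean oxBS beta,
C = 1 - mean BS beta.  The three estimates sum to one by construction.
Negative 5hmC estimates are reported as-is — they are a diagnostic of assay
noise at sites with little or no 5hmC, not clamped away.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import BetaMatrix


def estimate_levels(bm: BetaMatrix, results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Subtraction estimates per probe; merges significance calls if given.

    Returns columns level_5mc, level_5hmc, level_c (+ significant, sign when
    ``results`` carries them).
    """
    arms = set(bm.arrays["arm"])
    if arms != {"BS", "oxBS"}:
        raise ValidationError(f"both BS and oxBS arms are required (got {sorted(arms)})")
    bs = bm.values[bm.arm_columns("BS")].mean(axis=1)
    ox = bm.values[bm.arm_columns("oxBS")].mean(axis=1)
    est = pd.DataFrame(
        {
            "level_5mc": ox,
            "level_5hmc": bs - ox,
            "level_c": 1.0 - bs,
        },
        index=bm.values.index,
    )
    if results is not None:
        est = est.join(results[["significant", "sign"]], how="left")
        est["significant"] = est["significant"].fillna(False).astype(bool)
        est["sign"] = est["sign"].fillna("zero")
    return est


def summarize_positive_calls(estimates: pd.DataFrame, hist_range=(-0.2, 0.6), hist_bins: int = 40) -> dict:
    """Distribution of 5hmC among significant positive probes.

    Returns counts of positive and negative significant calls plus order
    statistics (min, quartiles, max) of the positive levels and histogram
    bins suitable for a level-distribution plot.  Empty when nothing is
    significant (with a warning).
    """
    if "significant" not in estimates:
        raise ValidationError("estimates must carry significance calls")
    sig = estimates[estimates["significant"]]
    pos = sig[sig["sign"] == "positive"]["level_5hmc"]
    neg = sig[sig["sign"] == "negative"]["level_5hmc"]
    summary: dict = {
        "n_significant_positive": int(len(pos)),
        "n_significant_negative": int(len(neg)),
    }
    if len(pos) == 0:
        warnings.warn("no significant positive probes; summary is empty", stacklevel=2)
        return summary
    counts, edges = np.histogram(pos.to_numpy(), bins=hist_bins, range=hist_range)
    summary.update(
        {
            "min": float(pos.min()),
            "q1": float(pos.quantile(0.25)),
            "median": float(pos.median()),
            "q3": float(pos.quantile(0.75)),
            "max": float(pos.max()),
            "hist_counts": counts.tolist(),
            "hist_edges": edges.tolist(),
        }
    )
    return summary


def effect_size_summary(results: pd.DataFrame, probe_subset=None) -> float:
    """Median BS - oxBS difference among significant probes, x100.

    ``probe_subset`` optionally restricts to an index of probes (e.g. those
    shared between replicate-subset analyses).
    """
    res = results.loc[probe_subset] if probe_subset is not None else results
    sig = res[res["significant"]]
    if len(sig) == 0:
        return float("nan")
    return float(sig["delta"].median() * 100.0)


def attach_truth(estimates: pd.DataFrame, truth_probes: pd.DataFrame) -> pd.DataFrame:
    """Join simulator ground truth (by probe_id index) for recovery checks."""
    t = truth_probes.set_index("probe_id")[["true_c", "true_5mc", "true_5hmc", "noise_sd"]]
    return estimates.join(t, how="left")
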