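"""Replicate-count power analysis by subsampling replicate pairs.

Re-runs the differential test and quantification on replicate subsets
(default pairs {1,3} and {2,4} in both arms, analysed separately with the
shrinkage prior refit per subset), and compares detections against the full
analysis: counts, overlap, probes gained only in a subset, and the detection
floor — the smallest estimated 5hmC among validated positive calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from . import diffmeth, quantify
from .preprocess import BetaMatrix

DEFAULT_SUBSETS = ((1, 3), (2, 4))


@dataclass
class SubsetComparison:
    """Detection counts for two replicate subsets vs the full analysis.

    Counts come in two accountings: ``*_any`` includes both positive and
    negative significant calls; ``*_pos`` counts positives only.
    """

    subset_a: tuple
    subset_b: tuple
    n_sig_a: int
    n_sig_b: int
    n_sig_full: int
    n_sig_a_pos: int
    n_sig_b_pos: int
    n_sig_full_pos: int
    n_overlap: int
    n_new_a_vs_full: int
    n_new_b_vs_full: int
    min_positive_level: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_sig_a", "n_sig_b", "n_sig_full",
            "n_sig_a_pos", "n_sig_b_pos", "n_sig_full_pos",
            "n_overlap", "n_new_a_vs_full", "n_new_b_vs_full",
        )}
        d["subset_a"] = list(self.subset_a)
        d["subset_b"] = list(self.subset_b)
        d["min_positive_level"] = self.min_positive_level
        return d


def _analyse(bm: BetaMatrix, fdr: float):
    results, _ = diffmeth.test_probes(bm, fdr=fdr)
    estimates = quantify.estimate_levels(bm, results)
    return results, estimates


def _sig_sets(results: pd.DataFrame):
    sig = results[results["significant"]]
    return set(sig.index), set(sig[sig["sign"] == "positive"].index)


def _min_positive(estimates: pd.DataFrame) -> float:
    pos = estimates[estimates["significant"] & (estimates["sign"] == "positive")]["level_5hmc"]
    return float(pos.min()) if len(pos) else float("nan")


def subset_analysis(
    bm: BetaMatrix,
    subsets: tuple = DEFAULT_SUBSETS,
    fdr: float = diffmeth.DEFAULT_FDR,
) -> SubsetComparison:
    """Analyse two replicate subsets independently and compare with the full set.

    Each subset keeps the named replicate indices in BOTH arms and must
    retain >= 2 replicates per arm; the variance-shrinkage prior is refit
    within each subset.
    """
    if len(subsets) != 2:
        raise ValidationError("exactly two replicate subsets are compared")
    for s in subsets:
        if len(s) < 2:
            raise ValidationError(f"subset {tuple(s)} has fewer than 2 replicates per arm")
    sub_a = bm.subset_replicates(subsets[0])
    sub_b = bm.subset_replicates(subsets[1])
    res_full, est_full = _analyse(bm, fdr)
    res_a, est_a = _analyse(sub_a, fdr)
    res_b, est_b = _analyse(sub_b, fdr)

    any_full, pos_full = _sig_sets(res_full)
    any_a, pos_a = _sig_sets(res_a)
    any_b, pos_b = _sig_sets(res_b)

    return SubsetComparison(
        subset_a=tuple(subsets[0]),
        subset_b=tuple(subsets[1]),
        n_sig_a=len(any_a),
        n_sig_b=len(any_b),
        n_sig_full=len(any_full),
        n_sig_a_pos=len(pos_a),
        n_sig_b_pos=len(pos_b),
        n_sig_full_pos=len(pos_full),
        n_overlap=len(any_a & any_b),
        n_new_a_vs_full=len(any_a - any_full),
        n_new_b_vs_full=len(any_b - any_full),
        min_positive_level={
            "full": _min_positive(est_full),
            "a": _min_positive(est_a),
            "b": _min_positive(est_b),
        },
    )


def detection_floor(
    estimates: pd.DataFrame,
    truth_probes: pd.DataFrame | None = None,
    bin_width: float = 0.01,
    max_level: float = 0.5,
) -> tuple[float | None, pd.DataFrame | None]:
    """Minimum estimated 5hmC among significant positive calls, plus a power curve.

    With simulator truth supplied, the floor is restricted to probes whose
    true 5hmC is positive (validated calls) and a detection-rate curve over
    1%-wide bins of true level is returned; without truth, the raw minimum
    estimate is reported and the curve is None.  Returns (None, curve) when
    nothing is significant.
    """
    called_pos = estimates["significant"] & (estimates["sign"] == "positive")
    curve = None
    if truth_probes is not None:
        truth = truth_probes.set_index("probe_id").loc[estimates.index]
        true_h = truth["true_5hmc"].to_numpy()
        validated = called_pos.to_numpy() & (true_h > 0)
        floor = float(estimates["level_5hmc"].to_numpy()[validated].min()) if validated.any() else None
        edges = np.arange(0.0, max_level + bin_width, bin_width)
        which = np.digitize(true_h, edges) - 1
        rows = []
        for b in range(len(edges) - 1):
            m = which == b
            if b == 0:
                m = m | (true_h == 0.0)
            rows.append(
                {
                    "true_level_low": float(edges[b]),
                    "true_level_high": float(edges[b + 1]),
                    "n_probes": int(m.sum()),
                    "detection_rate": float(called_pos.to_numpy()[m].mean()) if m.any() else float("nan"),
                }
            )
        curve = pd.DataFrame(rows)
    else:
        floor = float(estimates["level_5hmc"][called_pos].min()) if called_pos.any() else None
    return floor, curve
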