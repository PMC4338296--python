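"""Glucosyl-MspI qPCR validation arithmetic and array concordance.

beta-glucosyltransferase adds glucose to 5hmC, protecting CCGG sites from
MspI digestion.  Comparing quantification cycles (Cq) of glucosylated +
digested, mock-glucosylated + digested, and undigested template gives the
protected fraction attributable to 5hmC:

    R_glu  = E^-(Cq_glu  - Cq_undig)      surviving fraction, glucosylated
    R_mock = E^-(Cq_mock - Cq_undig)      background protection
    5hmC   = R_glu - R_mock               (clamped to [-1, 1])

with E the amplification efficiency per cycle (2 = perfect doubling).  Only
Cq differences matter; technical-replicate Cqs are averaged on the Cq scale
before the exponential transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError


@dataclass
class QpcrTriplet:
    """Cq values for one CCGG site under the three reaction conditions."""

    site_id: str
    cq_glu: float
    cq_mock: float
    cq_undig: float
    efficiency: float = 2.0
    replicates: dict | None = None  # optional {condition: [cq, ...]}

    @classmethod
    def from_replicates(cls, site_id, glu, mock, undig, efficiency: float = 2.0) -> "QpcrTriplet":
        reps = {"glu": list(glu), "mock": list(mock), "undig": list(undig)}
        for cond, vals in reps.items():
            if len(vals) == 0:
                raise ValidationError(f"site {site_id}: no Cq replicates for condition {cond!r}")
        return cls(
            site_id=site_id,
            cq_glu=float(np.mean(reps["glu"])),
            cq_mock=float(np.mean(reps["mock"])),
            cq_undig=float(np.mean(reps["undig"])),
            efficiency=efficiency,
            replicates=reps,
        )


def qpcr_5hmc_fraction(t: QpcrTriplet) -> float:
    """5hmC fraction at one site from its Cq triplet (unit scale, signed)."""
    if not 1.0 < t.efficiency <= 2.0:
        raise ConfigError(f"efficiency: must lie in (1, 2], got {t.efficiency}")
    if min(t.cq_glu, t.cq_mock, t.cq_undig) <= 0:
        raise ValidationError(f"site {t.site_id}: Cq values must be positive")
    r_glu = t.efficiency ** -(t.cq_glu - t.cq_undig)
    r_mock = t.efficiency ** -(t.cq_mock - t.cq_undig)
    return float(np.clip(r_glu - r_mock, -1.0, 1.0))


def fraction_to_triplet(
    site_id: str,
    fraction: float,
    cq_undig: float = 20.0,
    background_protection: float = 0.05,
    efficiency: float = 2.0,
) -> QpcrTriplet:
    """Inverse of :func:`qpcr_5hmc_fraction`: synthesize Cqs for a known fraction.

    Used in simulation mode to build validation panels; the protected
    fractions are converted exactly, so the round-trip reproduces
    ``fraction`` up to the [-1, 1] clamp.
    """
    r_mock = background_protection
    r_glu = fraction + r_mock
    if not 0 < r_glu <= 1 or not 0 < r_mock <= 1:
        raise ValidationError(
            f"site {site_id}: fraction {fraction} with background {background_protection} "
            "leaves no amplifiable protected template"
        )
    return QpcrTriplet(
        site_id=site_id,
        cq_glu=cq_undig - np.log(r_glu) / np.log(efficiency),
        cq_mock=cq_undig - np.log(r_mock) / np.log(efficiency),
        cq_undig=cq_undig,
        efficiency=efficiency,
    )


def read_cq_table(path, efficiency: float = 2.0) -> list[QpcrTriplet]:
    """Read a long-format Cq TSV (site_id, condition in {glu,mock,undig}, cq)."""
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "condition", "cq"}
    if not required <= set(df.columns):
        raise ValidationError(f"Cq table must have columns {sorted(required)}")
    bad = set(df["condition"]) - {"glu", "mock", "undig"}
    if bad:
        raise ValidationError(f"unknown qPCR conditions: {sorted(bad)}")
    out = []
    for site, grp in df.groupby("site_id", sort=True):
        by_cond = {c: grp.loc[grp["condition"] == c, "cq"].tolist() for c in ("glu", "mock", "undig")}
        out.append(QpcrTriplet.from_replicates(site, by_cond["glu"], by_cond["mock"], by_cond["undig"], efficiency))
    return out


_SEQ_RE = re.compile(r"^[ACGTN]*$")


def find_ccgg_sites(sequence: str, probe_pos: int) -> list[int]:
    """Start positions of CCGG motifs sorted by distance to the probe's CpG.

    CCGG is its own reverse complement, so one strand scan covers both.
    Distance is 0 for motifs overlapping ``probe_pos``; ties in distance are
    broken by start position.
    """
    seq = sequence.upper()
    if not _SEQ_RE.match(seq):
        raise ValidationError("sequence may contain only A, C, G, T, N")
    if not 0 <= probe_pos < len(seq):
        raise ValidationError(f"probe_pos {probe_pos} outside sequence of length {len(seq)}")
    hits = []
    start = seq.find("CCGG")
    while start != -1:
        if start <= probe_pos <= start + 3:
            dist = 0
        elif probe_pos < start:
            dist = start - probe_pos
        else:
            dist = probe_pos - (start + 3)
        hits.append((dist, start))
        start = seq.find("CCGG", start + 1)
    hits.sort()
    return [s for _, s in hits]


@dataclass
class ConcordanceResult:
    """Array-vs-qPCR agreement: Pearson r (unit scale; None below 3 pairs) and
    per-site percent differences relative to qPCR (qPCR = 0 sites reported
    separately, excluded from the percent panel)."""

    r: float | None
    table: pd.DataFrame
    zero_qpcr_sites: list


def concordance(array_levels: pd.Series, qpcr_levels: pd.Series) -> ConcordanceResult:
    """Compare paired array and qPCR 5hmC estimates (aligned by site id)."""
    common = array_levels.index.intersection(qpcr_levels.index)
    a = array_levels.loc[common].astype(float)
    q = qpcr_levels.loc[common].astype(float)
    r = float(np.corrcoef(a, q)[0, 1]) if len(common) >= 3 else None
    nonzero = q != 0
    table = pd.DataFrame(
        {
            "array_5hmc": a[nonzero],
            "qpcr_5hmc": q[nonzero],
            "percent_difference": (a[nonzero] - q[nonzero]) / q[nonzero] * 100.0,
        }
    )
    return ConcordanceResult(r=r, table=table, zero_qpcr_sites=list(common[~nonzero]))


def select_validation_sites(
    estimates: pd.DataFrame,
    n_sites: int = 27,
    level_range: tuple[float, float] = (0.0, 0.40),
    n_negative: int = 4,
    seed: int = 0,
) -> pd.Index:
    """Pick a validation panel spanning the array's 5hmC range, negatives included.

    Mirrors a selection "first by 5hmC level": evenly spaced target levels
    across ``level_range`` plus ``n_negative`` sites with the most negative
    estimates; the nearest-by-level probe is taken for each target.
    """
    rng = np.random.default_rng(seed)
    lev = estimates["level_5hmc"]
    neg = lev.nsmallest(max(n_negative * 3, n_negative)).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    chosen = list(neg.index[:n_negative])
    targets = np.linspace(level_range[0], level_range[1], n_sites - n_negative)
    remaining = lev.drop(index=chosen)
    for t in targets:
        idx = (remaining - t).abs().idxmin()
        chosen.append(idx)
        remaining = remaining.drop(index=idx)
    return pd.Index(chosen)


def simulate_qpcr_panel(
    true_levels: pd.Series,
    noise_sd: float = 0.02,
    seed: int = 0,
    efficiency: float = 2.0,
    background_protection: float = 0.05,
) -> list[QpcrTriplet]:
    """Synthetic qPCR measurements of known 5hmC fractions.

    Each site's measured fraction is the true level plus Gaussian noise
    (SD ``noise_sd``), floored so the glucosylated reaction retains
    amplifiable template, then converted exactly to a Cq triplet.
    """
    rng = np.random.default_rng(seed)
    out = []
    for site, level in true_levels.items():
        measured = float(level) + rng.normal(0.0, noise_sd)
        measured = float(np.clip(measured, -background_protection + 1e-6, 1.0 - background_protection))
        out.append(
            fraction_to_triplet(
                str(site), measured,
                background_protection=background_protection,
                efficiency=efficiency,
            )
        )
    return out
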