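"""Genomic-context annotation of array probes and regional modification summaries.

Probes are assigned exactly one gene-feature category (5'UTR, 3'UTR, exon,
intron, upstream, downstream, other, intergenic) and one CpG-island context
(island, shore, shelf, open sea).  Upstream/downstream windows are 1 kb from
the strand-aware transcription start/termination site; shores are the 0-2 kb
flanks of CpG islands and shelves the 2-4 kb flanks.  Regional summaries
report per-category counts, the proportion of probes with a significant
positive 5hmC signal, and quartiles of the 5mC/5hmC levels; a TSS profile
bins the same levels by signed distance to the nearest transcription start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

#: Category precedence for probes overlapping several features: UTRs beat
#: exon/intron (common array-annotation practice), gene features beat flanks.
GENE_PRECEDENCE = ("5utr", "3utr", "exon", "intron", "upstream", "downstream")

GENE_CATEGORIES = GENE_PRECEDENCE + ("other", "intergenic")
ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")


@dataclass(frozen=True)
class RegionScheme:
    """Window sizes (bp) defining flanking regions.

    ``flank_bp``: upstream/downstream window around TSS/TTS.
    ``shore_bp``/``shelf_bp``: outer edges of the CpG-island shore and shelf.
    """

    flank_bp: int = 1000
    shore_bp: int = 2000
    shelf_bp: int = 4000

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValidationError("flank_bp must be positive")
        if not 0 < self.shore_bp < self.shelf_bp:
            raise ValidationError("require 0 < shore_bp < shelf_bp")


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a frame with chrom/start/end[/name/score/strand].

    Raises :class:`ValidationError` naming the first malformed line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-integer start/end"
                ) from None
            if not 0 <= start < end:
                raise ValidationError(
                    f"{path}: line {lineno}: require 0 <= start < end (got {start}, {end})"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(frame: pd.DataFrame, path, columns: int = 6) -> None:
    cols = ["chrom", "start", "end", "name", "score", "strand"][:columns]
    frame.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent half-open intervals; returns sorted arrays."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    starts, ends = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _flank_features(genes: pd.DataFrame, flank_bp: int) -> pd.DataFrame:
    """Derive strand-aware upstream/downstream windows from gene rows."""
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "-":
            up = (g.chrom, g.end, g.end + flank_bp, "upstream")
            down = (max(0, g.start - flank_bp), g.start)
            rows.append(up)
            rows.append((g.chrom, down[0], down[1], "downstream"))
        else:
            rows.append((g.chrom, max(0, g.start - flank_bp), g.start, "upstream"))
            rows.append((g.chrom, g.end, g.end + flank_bp, "downstream"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def annotate_gene_regions(
    manifest: pd.DataFrame,
    gene_features: pd.DataFrame,
    scheme: RegionScheme = RegionScheme(),
) -> pd.Series:
    """Assign each probe one gene-feature category.

    ``gene_features`` is a BED6-like frame whose ``name`` column holds the
    feature type: ``gene`` rows give the transcript span (with strand, used to
    derive 1 kb upstream/downstream flanks), while ``5utr``/``3utr``/``exon``/
    ``intron`` rows give sub-features.  A probe overlapping several features
    takes the highest-precedence category; a probe inside a gene span but in
    no sub-feature is ``other``; a probe overlapping no gene +- flank is
    ``intergenic``.
    """
    feats = gene_features.copy()
    feats["name"] = feats["name"].str.lower().str.replace("'", "", regex=False)
    genes = feats[feats["name"] == "gene"]
    flanks = _flank_features(genes, scheme.flank_bp)

    trees: dict[tuple[str, str], IntervalTree] = {}
    for frame in (feats[feats["name"] != "gene"], flanks):
        for row in frame.itertuples(index=False):
            trees.setdefault((row.chrom, row.name), IntervalTree()).addi(row.start, row.end)
    span_trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        span_trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)

    out = []
    for chrom, pos in zip(manifest["chrom"], manifest["pos"]):
        cat = None
        for name in GENE_PRECEDENCE:
            tree = trees.get((chrom, name))
            if tree is not None and tree.overlaps_point(pos):
                cat = name
                break
        if cat is None:
            span = span_trees.get(chrom)
            cat = "other" if span is not None and span.overlaps_point(pos) else "intergenic"
        out.append(cat)
    return pd.Series(out, index=manifest.index, name="region_label")


def annotate_island_context(
    manifest: pd.DataFrame,
    islands: pd.DataFrame,
    scheme: RegionScheme = RegionScheme(),
) -> pd.Series:
    """Assign island / shore / shelf / open_sea by distance to the nearest island edge.

    Islands are merged per chromosome on load.  Distance is measured in bp of
    gap to the half-open island interval (a probe one base past the end is at
    distance 1); shores are distances in (0, shore_bp], shelves in
    (shore_bp, shelf_bp].
    """
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in islands.groupby("chrom"):
        merged[chrom] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())

    out = np.full(len(manifest), "open_sea", dtype=object)
    for chrom, grp_idx in manifest.groupby("chrom").indices.items():
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        pos = manifest["pos"].to_numpy()[grp_idx]
        # nearest interval at or left of pos
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, None)])
        d_left = np.where(i >= 0, pos - ends[np.clip(i, 0, None)] + 1, np.iinfo(np.int64).max)
        j = np.clip(i + 1, 0, len(starts) - 1)
        d_right = np.where(i + 1 < len(starts), starts[j] - pos, np.iinfo(np.int64).max)
        dist = np.minimum(d_left, d_right)
        ctx = np.where(
            inside,
            "island",
            np.where(
                dist <= scheme.shore_bp,
                "shore",
                np.where(dist <= scheme.shelf_bp, "shelf", "open_sea"),
            ),
        )
        out[grp_idx] = ctx
    return pd.Series(out, index=manifest.index, name="island_context")


def summarize_by_region(
    estimates: pd.DataFrame,
    annotations: pd.Series,
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-category probe counts, positive-call proportions and level quartiles.

    ``estimates`` must carry ``level_5mc``, ``level_5hmc`` and boolean
    ``significant`` plus ``sign`` columns (as produced by
    :func:`oxbsarray.quantify.estimate_levels`).
    """
    df = estimates.copy()
    df["category"] = annotations.to_numpy()
    if categories is None:
        categories = tuple(pd.unique(df["category"]))
    rows = []
    for cat in categories:
        sub = df[df["category"] == cat]
        n = len(sub)
        pos = sub["significant"] & (sub["sign"] == "positive")
        rows.append(
            {
                "category": cat,
                "n_probes": n,
                "n_sig_positive": int(pos.sum()),
                "prop_sig_positive": float(pos.mean()) if n else float("nan"),
                "median_5mc": float(sub["level_5mc"].median()) if n else float("nan"),
                "q1_5mc": float(sub["level_5mc"].quantile(0.25)) if n else float("nan"),
                "q3_5mc": float(sub["level_5mc"].quantile(0.75)) if n else float("nan"),
                "median_5hmc": float(sub["level_5hmc"].median()) if n else float("nan"),
                "q1_5hmc": float(sub["level_5hmc"].quantile(0.25)) if n else float("nan"),
                "q3_5hmc": float(sub["level_5hmc"].quantile(0.75)) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def tss_profile(
    manifest: pd.DataFrame,
    gene_features: pd.DataFrame,
    estimates: pd.DataFrame,
    bin_bp: int = 200,
    max_bp: int = 4000,
) -> pd.DataFrame:
    """Median 5mC/5hmC in bins of signed distance to the nearest TSS.

    Distance is strand-aware: negative = upstream of the TSS, positive =
    into the gene body.  Probes farther than ``max_bp`` from every TSS are
    dropped.
    """
    feats = gene_features.copy()
    feats["name"] = feats["name"].str.lower()
    genes = feats[feats["name"] == "gene"]
    if genes.empty:
        raise ValidationError("gene model contains no 'gene' rows to take TSSs from")

    signed = np.full(len(manifest), np.nan)
    for chrom, grp in genes.groupby("chrom"):
        tss = np.where(grp["strand"].to_numpy() == "-", grp["end"].to_numpy() - 1, grp["start"].to_numpy())
        strand_neg = grp["strand"].to_numpy() == "-"
        order = np.argsort(tss, kind="stable")
        tss, strand_neg = tss[order], strand_neg[order]
        sel = manifest["chrom"].to_numpy() == chrom
        pos = manifest["pos"].to_numpy()[sel]
        j = np.searchsorted(tss, pos)
        j_left = np.clip(j - 1, 0, len(tss) - 1)
        j_right = np.clip(j, 0, len(tss) - 1)
        use_right = np.abs(tss[j_right] - pos) < np.abs(pos - tss[j_left])
        k = np.where(use_right, j_right, j_left)
        raw = pos - tss[k]
        signed[sel] = np.where(strand_neg[k], -raw, raw)

    keep = np.abs(signed) <= max_bp
    edges = np.arange(-max_bp, max_bp + bin_bp, bin_bp)
    which = np.digitize(signed[keep], edges) - 1
    lev = estimates.loc[manifest.index[keep]]
    rows = []
    for b in range(len(edges) - 1):
        m = which == b
        rows.append(
            {
                "bin_start": int(edges[b]),
                "bin_end": int(edges[b + 1]),
                "bin_center": float((edges[b] + edges[b + 1]) / 2),
                "n_probes": int(m.sum()),
                "median_5mc": float(np.median(lev["level_5mc"].to_numpy()[m])) if m.any() else float("nan"),
                "median_5hmc": float(np.median(lev["level_5hmc"].to_numpy()[m])) if m.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)
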