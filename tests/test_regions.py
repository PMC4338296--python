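"""Gene-feature and CpG-island annotation, regional summaries, TSS profile."""

import numpy as np
import pandas as pd
import pytest

import oxbsarray as ox
from oxbsarray import regions as rg


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": list(positions),
        }
    )


@pytest.fixture()
def gene_model():
    """One + strand gene [10000, 20000) and one - strand gene [50000, 60000)."""
    rows = [
        ("chr1", 10_000, 20_000, "gene", ".", "+"),
        ("chr1", 10_000, 10_500, "5utr", ".", "+"),
        ("chr1", 10_500, 11_000, "exon", ".", "+"),
        ("chr1", 11_000, 18_000, "intron", ".", "+"),
        ("chr1", 18_000, 19_500, "exon", ".", "+"),
        ("chr1", 19_500, 20_000, "3utr", ".", "+"),
        ("chr1", 50_000, 60_000, "gene", ".", "-"),
        ("chr1", 59_000, 60_000, "5utr", ".", "-"),
        ("chr1", 50_000, 51_000, "3utr", ".", "-"),
        ("chr1", 51_000, 59_000, "intron", ".", "-"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


@pytest.mark.parametrize(
    "pos,expected",
    [
        (9_500, "upstream"),  # 500 bp 5' of the + strand TSS
        (10_200, "5utr"),
        (15_000, "intron"),
        (19_700, "3utr"),
        (20_500, "downstream"),
        (30_000, "intergenic"),  # 10 kb from any gene
        (60_400, "upstream"),  # 5' flank of the - strand gene
        (49_500, "downstream"),  # 3' flank of the - strand gene
    ],
)
def test_gene_region_assignment(gene_model, pos, expected):
    cat = rg.annotate_gene_regions(_manifest([pos]), gene_model)
    assert cat.iloc[0] == expected


def test_gene_region_other_inside_uncovered_span():
    genes = pd.DataFrame(
        [("chr1", 1000, 3000, "gene", ".", "+"), ("chr1", 1000, 1200, "exon", ".", "+")],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    cats = rg.annotate_gene_regions(_manifest([1100, 2500]), genes)
    assert list(cats) == ["exon", "other"]


def test_gene_region_precedence_utr_over_exon(gene_model):
    """A probe under both a 5'UTR and an exon interval takes the UTR."""
    gm = pd.concat(
        [gene_model, pd.DataFrame([("chr1", 10_000, 11_000, "exon", ".", "+")], columns=gene_model.columns)],
        ignore_index=True,
    )
    assert rg.annotate_gene_regions(_manifest([10_200]), gm).iloc[0] == "5utr"


@pytest.mark.parametrize(
    "offset,expected",
    [
        (0, "island"),  # inside (at the last base)
        (1, "shore"),
        (1_500, "shore"),
        (2_000, "shore"),
        (2_001, "shelf"),
        (3_999, "shelf"),
        (4_000, "shelf"),
        (4_001, "open_sea"),
    ],
)
def test_island_context_boundaries(offset, expected):
    islands = pd.DataFrame([("chr1", 10_000, 12_000)], columns=["chrom", "start", "end"])
    pos = 11_999 + offset  # distance to the island's right edge = offset
    ctx = rg.annotate_island_context(_manifest([pos]), islands)
    assert ctx.iloc[0] == expected
    # mirror on the left edge
    ctx_l = rg.annotate_island_context(_manifest([10_000 - offset]), islands)
    assert ctx_l.iloc[0] == expected


def test_island_merge_on_load():
    islands = pd.DataFrame(
        [("chr1", 100, 300), ("chr1", 250, 500)], columns=["chrom", "start", "end"]
    )
    ctx = rg.annotate_island_context(_manifest([400]), islands)
    assert ctx.iloc[0] == "island"


def _brute_force_island(pos, islands, shore=2000, shelf=4000):
    best = None
    for s, e in islands:
        if s <= pos < e:
            return "island"
        d = s - pos if pos < s else pos - e + 1
        best = d if best is None else min(best, d)
    if best is None:
        return "open_sea"
    if best <= shore:
        return "shore"
    if best <= shelf:
        return "shelf"
    return "open_sea"


def test_island_context_matches_brute_force(rng):
    starts = np.sort(rng.choice(200_000, 300, replace=False))
    islands = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + rng.integers(50, 3000, 300)}
    )
    pos = rng.integers(0, 210_000, 500)
    ctx = rg.annotate_island_context(_manifest(pos), islands)
    merged = list(zip(*rg.merge_intervals(islands["start"].to_numpy(), islands["end"].to_numpy())))
    for p, c in zip(pos, ctx):
        assert c == _brute_force_island(p, merged)


def _brute_force_gene(pos, feats, flank=1000):
    hits = set()
    for chrom, s, e, name, _, strand in feats.itertuples(index=False):
        if name == "gene":
            if strand == "-":
                up, down = (e, e + flank), (max(0, s - flank), s)
            else:
                up, down = (max(0, s - flank), s), (e, e + flank)
            if up[0] <= pos < up[1]:
                hits.add("upstream")
            if down[0] <= pos < down[1]:
                hits.add("downstream")
        elif s <= pos < e:
            hits.add(name)
    for name in rg.GENE_PRECEDENCE:
        if name in hits:
            return name
    for chrom, s, e, name, _, strand in feats.itertuples(index=False):
        if name == "gene" and s <= pos < e:
            return "other"
    return "intergenic"


def test_gene_annotation_matches_brute_force():
    truth = ox.sim.simulate_truth(ox.sim.SimConfig(n_probes=400, seed=13))
    mf = truth.probes[["probe_id", "chrom", "pos"]]
    cats = rg.annotate_gene_regions(mf, truth.gene_features)
    for (_, row), cat in zip(mf.iterrows(), cats):
        assert cat == _brute_force_gene(row["pos"], truth.gene_features)


def test_annotation_is_a_partition_and_order_invariant():
    truth = ox.sim.simulate_truth(ox.sim.SimConfig(n_probes=600, seed=14))
    mf = truth.probes[["probe_id", "chrom", "pos"]]
    cats = rg.annotate_gene_regions(mf, truth.gene_features)
    ctx = rg.annotate_island_context(mf, truth.islands)
    assert cats.isin(rg.GENE_CATEGORIES).all()
    assert ctx.isin(rg.ISLAND_CONTEXTS).all()
    shuffled = mf.sample(frac=1.0, random_state=7)
    cats_s = rg.annotate_gene_regions(shuffled, truth.gene_features)
    ctx_s = rg.annotate_island_context(shuffled, truth.islands)
    assert (cats.loc[cats_s.index].to_numpy() == cats_s.to_numpy()).all()
    assert (ctx.loc[ctx_s.index].to_numpy() == ctx_s.to_numpy()).all()


def test_read_bed_errors_name_line(tmp_path):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t10\t20\nchr1\t30\tx\n")
    with pytest.raises(ox.ValidationError, match="line 2"):
        rg.read_bed(bad)
    bad.write_text("chr1\t50\t40\n")
    with pytest.raises(ox.ValidationError, match="line 1"):
        rg.read_bed(bad)


def test_region_scheme_validation():
    with pytest.raises(ox.ValidationError):
        rg.RegionScheme(shore_bp=4000, shelf_bp=2000)


def test_summarize_by_region_accounting():
    est = pd.DataFrame(
        {
            "level_5mc": np.linspace(0, 1, 10),
            "level_5hmc": np.linspace(-0.1, 0.4, 10),
            "significant": [True] * 5 + [False] * 5,
            "sign": ["positive", "negative"] * 5,
        }
    )
    ann = pd.Series(["exon"] * 6 + ["intron"] * 4)
    summ = rg.summarize_by_region(est, ann, categories=("exon", "intron", "5utr"))
    assert summ["n_probes"].sum() == 10
    assert summ.loc[summ["category"] == "5utr", "n_probes"].iloc[0] == 0
    total_pos = int((est["significant"] & (est["sign"] == "positive")).sum())
    assert summ["n_sig_positive"].sum() == total_pos
    assert ((summ["prop_sig_positive"].dropna() >= 0) & (summ["prop_sig_positive"].dropna() <= 1)).all()
    # all probes in one category -> that category holds the total
    one = rg.summarize_by_region(est, pd.Series(["exon"] * 10), categories=("exon", "intron"))
    assert one.loc[one["category"] == "exon", "n_probes"].iloc[0] == 10
    assert one.loc[one["category"] == "intron", "n_probes"].iloc[0] == 0


def test_island_low_truth_shows_in_regional_medians(small_run, small_dataset):
    """Simulated islands carry less 5mC than open sea, as summarized."""
    est = small_run["estimates"]
    mf = small_dataset.manifest.set_index("probe_id").loc[est.index].reset_index()
    ctx = rg.annotate_island_context(mf, small_dataset.truth.islands)
    summ = rg.summarize_by_region(est.reset_index(drop=True), ctx, categories=rg.ISLAND_CONTEXTS).set_index("category")
    assert summ.loc["island", "median_5mc"] < summ.loc["open_sea", "median_5mc"]


def test_tss_profile_bins(small_run, small_dataset):
    est = small_run["estimates"]
    mf = small_dataset.manifest.set_index("probe_id").loc[est.index].reset_index()
    prof = rg.tss_profile(mf, small_dataset.truth.gene_features, est.reset_index(drop=True), bin_bp=400)
    assert len(prof) == 20  # +-4 kb in 400 bp bins
    assert (prof["bin_end"] - prof["bin_start"] == 400).all()
    assert prof["n_probes"].sum() > 0
    # TSS-proximal 5mC is depressed relative to the far bins
    near = prof[(prof["bin_center"].abs() <= 400)]["median_5mc"].mean()
    far = prof[(prof["bin_center"].abs() >= 3000)]["median_5mc"].mean()
    assert near < far
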