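"""Moderated F-test: group stats, variance shrinkage, FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import oxbsarray as ox
from oxbsarray import diffmeth as dm
from oxbsarray.preprocess import BetaMatrix


def _beta_matrix(bs_rows, ox_rows):
    """Build a BetaMatrix from per-probe replicate lists."""
    bs = np.atleast_2d(np.asarray(bs_rows, dtype=float))
    oxv = np.atleast_2d(np.asarray(ox_rows, dtype=float))
    arrays = pd.DataFrame(
        [(f"BS_{i+1}", "BS", i + 1) for i in range(bs.shape[1])]
        + [(f"oxBS_{i+1}", "oxBS", i + 1) for i in range(oxv.shape[1])],
        columns=["array_id", "arm", "replicate"],
    )
    values = pd.DataFrame(
        np.hstack([bs, oxv]),
        columns=list(arrays["array_id"]),
        index=pd.Index([f"p{i}" for i in range(bs.shape[0])], name="probe_id"),
    )
    return BetaMatrix(values=values, arrays=arrays)


# ---------------------------------------------------------------------------
# groupwise stats


def test_groupwise_zero_variance():
    stats = dm.groupwise_stats(_beta_matrix([[0.5, 0.5]], [[0.4, 0.4]]))
    assert stats["delta"].iloc[0] == pytest.approx(0.1)
    assert stats["s_sq"].iloc[0] == 0.0
    assert stats["d"].iloc[0] == 2


def test_groupwise_pooled_variance_hand_computed():
    # BS {0.6, 0.4}: SS = 0.02; oxBS {0.5, 0.5}: SS = 0 -> pooled = 0.02/2 = 0.01
    stats = dm.groupwise_stats(_beta_matrix([[0.6, 0.4]], [[0.5, 0.5]]))
    assert stats["delta"].iloc[0] == pytest.approx(0.0)
    assert stats["s_sq"].iloc[0] == pytest.approx(0.01)


def test_groupwise_replicate_exchangeability(rng):
    bs = rng.uniform(0, 1, (30, 4))
    oxv = rng.uniform(0, 1, (30, 4))
    a = dm.groupwise_stats(_beta_matrix(bs, oxv))
    b = dm.groupwise_stats(_beta_matrix(bs[:, ::-1], oxv[:, [2, 0, 3, 1]]))
    pd.testing.assert_frame_equal(a, b)


def test_groupwise_needs_two_replicates():
    with pytest.raises(ox.ValidationError, match="2 replicates"):
        dm.groupwise_stats(_beta_matrix([[0.5]], [[0.4, 0.4]]))


# ---------------------------------------------------------------------------
# shrinkage


def test_trigamma_inverse_roundtrip():
    for v in np.geomspace(1e-4, 10, 40):
        x = dm.trigamma_inverse(v)
        assert abs(dm.trigamma(x) - v) / v < 1e-8


def test_fit_shrinkage_recovers_scaled_chi2_prior(rng):
    """s^2 ~ s0^2 chi^2_d / d with a point-mass prior: s0^2 within 5%, d0 large."""
    s0_sq, d = 4e-4, 6
    s_sq = s0_sq * rng.chisquare(d, 50_000) / d
    fit = dm.fit_shrinkage(s_sq, d)
    assert abs(fit.s0_sq - s0_sq) / s0_sq < 0.05
    assert fit.d0 > 50


def test_fit_shrinkage_equal_variances_gives_infinite_d0():
    """Zero dispersion in log variances -> complete pooling (d0 infinite).

    The point prior under the hierarchical model is exp(mean(e)); for
    constant s^2 that is s^2 * (d/2) / exp(digamma(d/2)) — the chi-square
    log-bias correction — and the squeezed variance equals it everywhere.
    """
    from scipy.special import digamma

    d = 6
    fit = dm.fit_shrinkage(np.full(200, 3e-4), d)
    assert np.isinf(fit.d0)
    expected_s0 = 3e-4 * (d / 2) / np.exp(digamma(d / 2))
    assert fit.s0_sq == pytest.approx(expected_s0, rel=1e-9)
    squeezed = dm.squeeze_variance(np.full(200, 3e-4), fit)
    np.testing.assert_allclose(squeezed, expected_s0)


def test_fit_shrinkage_hierarchical_recovery(rng):
    """Full hierarchical draw (finite d0) is re-estimated consistently."""
    d0_true, s0_sq, d = 8.0, 5e-4, 6
    sigma_sq = d0_true * s0_sq / rng.chisquare(d0_true, 40_000)
    s_sq = sigma_sq * rng.chisquare(d, 40_000) / d
    fit = dm.fit_shrinkage(s_sq, d)
    assert abs(fit.s0_sq - s0_sq) / s0_sq < 0.1
    assert 0.7 * d0_true < fit.d0 < 1.4 * d0_true


def test_fit_shrinkage_all_zero_errors():
    with pytest.raises(ox.ValidationError, match="floor"):
        dm.fit_shrinkage(np.zeros(100), 6)


@pytest.mark.parametrize(
    "d0,s0,s,expected",
    [
        (0.0, 2e-4, 6e-4, 6e-4),  # no shrinkage
        (np.inf, 2e-4, 6e-4, 2e-4),  # complete pooling
        (6.0, 2e-4, 6e-4, 4e-4),  # arithmetic midpoint at d0 = d
    ],
)
def test_squeeze_variance_limits(d0, s0, s, expected):
    fit = dm.ShrinkageFit(d0=d0, s0_sq=s0, d=6.0)
    assert dm.squeeze_variance(np.array([s]), fit)[0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# moderated F


def test_moderated_f_null_identity():
    fit = dm.ShrinkageFit(d0=4.0, s0_sq=1e-4, d=6.0)
    F, p = dm.moderated_f(np.array([0.0]), np.array([1e-4]), 4, 4, fit)
    assert F[0] == 0.0
    assert p[0] == 1.0


def test_moderated_f_quadruples_with_doubled_delta():
    fit = dm.ShrinkageFit(d0=4.0, s0_sq=1e-4, d=6.0)
    F1, _ = dm.moderated_f(np.array([0.05]), np.array([1e-4]), 4, 4, fit)
    F2, _ = dm.moderated_f(np.array([0.10]), np.array([1e-4]), 4, 4, fit)
    assert F2[0] == pytest.approx(4 * F1[0])


def test_moderated_f_d0_zero_equals_classical_t_squared():
    """With no shrinkage the moderated F is the pooled-variance t-test squared."""
    bs = np.array([0.62, 0.55, 0.58])
    oxv = np.array([0.49, 0.52, 0.47])
    bm = _beta_matrix([bs], [oxv])
    stats = dm.groupwise_stats(bm)
    fit = dm.ShrinkageFit(d0=0.0, s0_sq=1.0, d=4.0)
    s_tilde = dm.squeeze_variance(stats["s_sq"].to_numpy(), fit)
    F, p = dm.moderated_f(stats["delta"].to_numpy(), s_tilde, 3, 3, fit)
    t = sps.ttest_ind(bs, oxv, equal_var=True)
    assert F[0] == pytest.approx(t.statistic**2, rel=1e-12)
    assert p[0] == pytest.approx(t.pvalue, abs=1e-12)


def test_moderated_f_infinite_d0_is_chi2():
    fit = dm.ShrinkageFit(d0=np.inf, s0_sq=1e-4, d=6.0)
    F, p = dm.moderated_f(np.array([0.03]), np.array([1e-4]), 4, 4, fit)
    assert p[0] == pytest.approx(sps.chi2.sf(F[0], 1))


# ---------------------------------------------------------------------------
# BH FDR


def _bh_brute_force(p):
    """Step-up by explicit double loop over sorted p-values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(ps[j] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_bh_hand_example():
    q = dm.bh_fdr([0.01, 0.02, 0.03, 0.5])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])


def test_bh_degenerate_cases():
    assert dm.bh_fdr([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(dm.bh_fdr([1.0, 1.0, 1.0]), 1.0)


def test_bh_matches_brute_force_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(300):
        m = int(rng.integers(1, 200))
        p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
        q = dm.bh_fdr(p)
        np.testing.assert_allclose(q, _bh_brute_force(p), atol=1e-12)
        np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
def test_bh_order_preserving_and_bounded(p):
    p = np.asarray(p)
    q = dm.bh_fdr(p)
    assert ((q >= 0) & (q <= 1)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_invalid_p():
    with pytest.raises(ox.ValidationError):
        dm.bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# calling


@pytest.mark.parametrize(
    "q,delta,sig,sign",
    [
        (0.009, 0.05, True, "positive"),
        (0.009, -0.03, True, "negative"),
        (0.011, 0.5, False, "positive"),
    ],
)
def test_call_probes_threshold_logic(q, delta, sig, sign):
    res = pd.DataFrame({"q": [q], "delta": [delta]})
    out = dm.call_probes(res)
    assert bool(out["significant"].iloc[0]) is sig
    assert out["sign"].iloc[0] == sign


def test_pure_null_calibration():
    """With zero 5hmC everywhere the fraction of q<0.01 calls stays below 1%."""
    fracs = []
    for seed in range(5):
        cfg = ox.sim.SimConfig(n_probes=30_000, seed=400 + seed, pi0=1.0)
        ds = ox.sim.simulate_dataset(cfg)
        bm, _ = ox.preprocess.preprocess_dataset(ds, swan_seed=seed)
        res, _ = dm.test_probes(bm)
        fracs.append(res["significant"].mean())
    assert np.mean(fracs) <= 0.01
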