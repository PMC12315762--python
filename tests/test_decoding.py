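import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import roidecode as rd
from roidecode._utils import RoidecodeError, ValidationError
from roidecode.decoding import FISHER_CLIP

from oracles import naive_decode_cell


# ---------------------------------------------------------------------------
# split_trials
# ---------------------------------------------------------------------------

def test_split_covers_all_trials_when_sizes_sum():
    spec = rd.SplitSpec(n_train=350, n_test=350, rng_seed=1)
    tr, te = rd.split_trials(700, spec, 0)
    assert len(tr) == len(te) == 350
    assert set(tr) & set(te) == set()
    assert set(tr) | set(te) == set(range(700))


def test_split_leaves_trials_unused():
    spec = rd.SplitSpec(n_train=301, n_test=101, rng_seed=1)
    tr, te = rd.split_trials(804, spec, 0)
    assert set(tr) & set(te) == set()
    assert 804 - len(tr) - len(te) == 402


def test_split_deterministic_per_repeat():
    spec = rd.SplitSpec(n_train=5, n_test=5, rng_seed=3)
    a = rd.split_trials(10, spec, 4)
    b = rd.split_trials(10, spec, 4)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])
    c = rd.split_trials(10, spec, 5)
    assert not np.array_equal(a[0], c[0])


def test_split_oversized_errors():
    with pytest.raises(ValidationError):
        rd.split_trials(10, rd.SplitSpec(n_train=6, n_test=5), 0)


# ---------------------------------------------------------------------------
# fit_linear_decoder
# ---------------------------------------------------------------------------

def test_fit_exact_line():
    intercept, slope = rd.fit_linear_decoder([0, 1, 2], [1, 3, 5])
    assert intercept == pytest.approx(1.0, abs=1e-14)
    assert slope == pytest.approx(2.0, abs=1e-14)


def test_fit_constant_y():
    intercept, slope = rd.fit_linear_decoder([0.0, 1.0, 2.0], [4.0, 4.0, 4.0])
    assert slope == 0.0
    assert intercept == 4.0


def test_fit_matches_normal_equations():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(20)
    y = 0.7 * x + rng.standard_normal(20)
    intercept, slope = rd.fit_linear_decoder(x, y)
    A = np.column_stack([np.ones(20), x])
    ref = np.linalg.solve(A.T @ A, A.T @ y)
    assert intercept == pytest.approx(ref[0], abs=1e-10)
    assert slope == pytest.approx(ref[1], abs=1e-10)


def test_fit_zero_variance_raises():
    with pytest.raises(ValidationError):
        rd.fit_linear_decoder([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# fisher_aggregate
# ---------------------------------------------------------------------------

def test_fisher_constant_and_single():
    assert rd.fisher_aggregate([0.5, 0.5])[0] == pytest.approx(0.5, abs=1e-14)
    assert rd.fisher_aggregate([0.0])[0] == 0.0


def test_fisher_two_values_formula():
    r, z = rd.fisher_aggregate([0.3, 0.6])
    expected_z = (math.atanh(0.3) + math.atanh(0.6)) / 2
    assert z == pytest.approx(expected_z, abs=1e-14)
    assert r == pytest.approx(math.tanh(expected_z), abs=1e-14)


def test_fisher_ignores_missing_and_all_missing():
    r, _ = rd.fisher_aggregate([0.4, np.nan])
    assert r == pytest.approx(0.4, abs=1e-14)
    r, z = rd.fisher_aggregate([np.nan, np.nan])
    assert math.isnan(r) and math.isnan(z)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=-1.0, max_value=1.0), min_size=1,
                max_size=30))
def test_fisher_aggregate_property(rs):
    """Aggregate lies in [-1,1], equals the direct clipped formula, and is
    invariant to ordering."""
    r, z = rd.fisher_aggregate(rs)
    clipped = np.clip(rs, -FISHER_CLIP, FISHER_CLIP)
    assert r == pytest.approx(math.tanh(np.arctanh(clipped).mean()), abs=1e-12)
    assert -1.0 <= r <= 1.0
    assert rd.fisher_aggregate(rs[::-1])[0] == pytest.approx(r, abs=1e-12)


# ---------------------------------------------------------------------------
# decode_cell
# ---------------------------------------------------------------------------

def _line_subject(n=40, slope=1.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 2.0 + slope * x + noise * rng.standard_normal(n)
    y = y - y.min() + 0.1  # keep rt positive
    return rd.SubjectData("s", x[:, None], y,
                          np.full(n, np.nan), np.ones(n, dtype=int))


def test_decode_noiseless_planted_slope():
    sub = _line_subject(slope=1.0)
    spec = rd.SplitSpec(n_train=15, n_test=15, n_repeats=5)
    rep = rd.decode_cell(sub, 1, "rt", spec)
    np.testing.assert_allclose(rep.r_per_repeat, 1.0, atol=1e-12)
    assert rep.r_aggregated == pytest.approx(1.0, abs=1e-9)
    assert rep.mean_slope == pytest.approx(1.0, abs=1e-12)


def test_identity_r_pred_equals_r_x_times_sign():
    """For an affine decoder, r(y, yhat) = r(y, x) * sign(slope)."""
    rng = np.random.default_rng(3)
    for slope in (0.8, -0.8):
        sub = _line_subject(60, slope=slope, seed=4, noise=1.0)
        spec = rd.SplitSpec(n_train=25, n_test=25, n_repeats=6, rng_seed=9)
        rep = rd.decode_cell(sub, 1, "rt", spec)
        for i in range(6):
            tr, te = rd.split_trials(60, spec, i)
            x, y = sub.betas[:, 0], sub.rt
            r_xy = np.corrcoef(y[te], x[te])[0, 1]
            expect = r_xy * np.sign(rep.slope_per_repeat[i])
            assert rep.r_per_repeat[i] == pytest.approx(expect, abs=1e-12)


def test_decode_cell_matches_naive_loop():
    cfg = rd.SyntheticConfig(n_subjects=1, n_trials=50, n_rois=3,
                             coupling_sparsity=1.0, coupling_magnitude=0.4,
                             seed=8)
    cohort, _ = rd.simulate_cohort(cfg)
    spec = rd.SplitSpec(n_train=20, n_test=20, n_repeats=10, rng_seed=2)
    for roi in (1, 2, 3):
        mine = rd.decode_cell(cohort[0], roi, "rt", spec).r_aggregated
        ref = naive_decode_cell(cohort[0], roi, "rt", spec)
        assert mine == pytest.approx(ref, abs=1e-10)


def test_decode_drops_missing_target_trials():
    sub = _line_subject(50, slope=1.0)
    conf = np.full(50, np.nan)
    conf[:30] = np.round(sub.betas[:30, 0]) + 5  # decodable rated block
    sub = rd.SubjectData("s", sub.betas, sub.rt, conf, sub.run_id)
    spec = rd.SplitSpec(n_train=12, n_test=12, n_repeats=3)
    rep = rd.decode_cell(sub, 1, "confidence", spec)  # 30 usable trials
    assert np.isfinite(rep.slope_per_repeat).all()
    assert np.isfinite(rep.r_aggregated)
    with pytest.raises(ValidationError):
        rd.decode_cell(sub, 1, "confidence",
                       rd.SplitSpec(n_train=20, n_test=20))


# ---------------------------------------------------------------------------
# permutation_null
# ---------------------------------------------------------------------------

def test_permutation_p_floor_when_obs_exceeds_null():
    sub = _line_subject(60, slope=1.0, noise=0.05)
    spec = rd.SplitSpec(n_train=25, n_test=25, n_repeats=5)
    p, used = rd.permutation_null(sub, 1, "rt", spec, n_perm=100)
    assert used == 100
    assert p == pytest.approx(1.0 / 101.0)


def test_permutation_p_large_for_weak_observation():
    """An observed aggregate far below the null median must give p > 0.5."""
    rng = np.random.default_rng(12)
    n = 80
    sub = rd.SubjectData("s", rng.standard_normal((n, 1)),
                         rng.uniform(0.5, 1.5, n), np.full(n, np.nan),
                         np.ones(n, dtype=int))
    spec = rd.SplitSpec(n_train=30, n_test=30, n_repeats=5, rng_seed=100)
    weak = rd.decode_cell(sub, 1, "rt", spec)
    weak = rd.RepeatSet(weak.r_per_repeat, weak.slope_per_repeat,
                        r_aggregated=-0.5, z_aggregated=math.atanh(-0.5))
    p, _ = rd.permutation_null(sub, 1, "rt", spec, n_perm=100, observed=weak)
    assert p > 0.5


def test_permutation_null_on_shuffled_target_is_small_r():
    """Decoding a randomly permuted target yields |aggregate r| < 0.1."""
    cfg = rd.SyntheticConfig(n_subjects=1, n_trials=700, n_rois=1,
                             coupling_sparsity=1.0, coupling_magnitude=0.5,
                             seed=20)
    cohort, _ = rd.simulate_cohort(cfg)
    sub = cohort[0]
    rng = np.random.default_rng(0)
    shuffled = rd.SubjectData("s", sub.betas, rng.permutation(sub.rt),
                              sub.confidence, sub.run_id)
    spec = rd.SplitSpec(n_train=350, n_test=350, n_repeats=25)
    rep = rd.decode_cell(shuffled, 1, "rt", spec)
    assert abs(rep.r_aggregated) < 0.1


# ---------------------------------------------------------------------------
# regressors / decode_all
# ---------------------------------------------------------------------------

def test_svr_close_to_ols_on_linear_data():
    sub = _line_subject(200, slope=1.0, noise=0.3, seed=6)
    spec = rd.SplitSpec(n_train=80, n_test=80, n_repeats=5)
    r_ols = rd.decode_cell(sub, 1, "rt", spec, rd.OLSRegressor()).r_aggregated
    r_svr = rd.decode_cell(sub, 1, "rt", spec, rd.SVRRegressor()).r_aggregated
    assert abs(r_ols - r_svr) < 0.05


def test_regressor_contract_violation():
    class Broken:
        def fit(self, x, y):
            return self

        def predict(self, x):
            return np.zeros(len(x) + 1)

    sub = _line_subject(30)
    spec = rd.SplitSpec(n_train=10, n_test=10, n_repeats=2)
    with pytest.raises(RoidecodeError, match="contract"):
        rd.decode_cell(sub, 1, "rt", spec, Broken())


def test_decode_all_counts_and_determinism(small_cohort, atlas3):
    cohort, _ = small_cohort
    spec = rd.SplitSpec(n_train=20, n_test=20, n_repeats=5)
    res1 = rd.decode_all(cohort, atlas3, spec, n_perm=30, master_seed=3)
    assert len(res1) == 2 * 3 * 2  # subjects x rois x targets
    res2 = rd.decode_all(cohort, atlas3, spec, n_perm=30, master_seed=3)
    np.testing.assert_array_equal(res1.performance_matrix("rt"),
                                  res2.performance_matrix("rt"))
    np.testing.assert_array_equal(res1.p_matrix("confidence"),
                                  res2.p_matrix("confidence"))


def test_parametric_pvalue_matches_t_distribution():
    from scipy import stats
    r, n = 0.3, 100
    t = r * math.sqrt((n - 2) / (1 - r * r))
    assert rd.parametric_pvalue(r, n) == pytest.approx(
        stats.t.sf(t, df=n - 2), abs=1e-12)
    assert rd.parametric_pvalue(0.999999, 50) < 5e-6  # passes strict alpha
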