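"""RT series, zero-phase smoothing, instantaneous cross-correlation, index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import jointcoord.coordination as co
from _oracles import (
    local_corr_from_matrix,
    smooth_matrix,
    two_sided_exponential_kernel,
    weighted_pearson_local,
)
from jointcoord.simulate import Session, SimConfig, generate_pair_session


def _session_from_rts(rts, accuracy=None, agent="p0_a"):
    n = len(rts)
    accuracy = accuracy or ["correct"] * n
    frame = pd.DataFrame(
        {
            "pair_id": "p0",
            "agent_id": agent,
            "condition": "joint",
            "design": "cooperative",
            "block": 1,
            "trial_index": np.arange(1, n + 1),
            "stimulus_side": "left",
            "stimulus_color": "green",
            "required_responder": agent,
            "response_side": [
                "none" if a == "miss" else "left" for a in accuracy
            ],
            "rt_ms": [np.nan if a == "miss" else r for r, a in zip(rts, accuracy)],
            "accuracy": accuracy,
        }
    )
    return Session("p0", agent, "joint", frame)


def test_series_imputation_and_centering():
    sess = _session_from_rts([300.0, None, 320.0], ["correct", "miss", "correct"])
    series = co.build_rt_series(sess)
    assert series.values.tolist() == [-10.0, 0.0, 10.0]
    assert series.imputed_mask.tolist() == [False, True, False]


def test_series_mean_zero_without_misses(joint_pair):
    sess_a, _, _ = joint_pair
    series = co.build_rt_series(sess_a)
    assert len(series) == 192
    assert abs(series.values.mean()) < 1e-9
    assert not series.imputed_mask[~series.imputed_mask].any()


def test_series_requires_a_correct_response():
    sess = _session_from_rts([None, None], ["miss", "miss"])
    with pytest.raises(ValueError, match="no correct responses"):
        co.build_rt_series(sess)


def test_smoothing_identity_and_dc():
    x = np.random.default_rng(0).normal(size=50)
    np.testing.assert_allclose(co.smooth_noncausal(x, 1.0), x)
    np.testing.assert_allclose(co.smooth_noncausal(np.full(30, 3.7), 0.1), 3.7)
    with pytest.raises(ValueError):
        co.smooth_noncausal([], 0.5)


def test_smoothing_matches_exact_kernel_matrix():
    rng = np.random.default_rng(1)
    for n, eta in [(12, 0.5), (40, 0.1), (64, 0.3)]:
        x = rng.normal(size=n)
        W = smooth_matrix(n, eta)
        np.testing.assert_allclose(co.smooth_noncausal(x, eta), W @ x, atol=1e-10)


def test_smoothing_converges_to_two_sided_exponential_kernel():
    # interior response equals the normalized (1-eta)^|d| kernel
    rng = np.random.default_rng(2)
    eta = 0.2
    n = 400
    x = rng.normal(size=n)
    smoothed = co.smooth_noncausal(x, eta)
    w = two_sided_exponential_kernel(eta, half_width=120)
    conv = np.convolve(np.pad(x, 120, mode="edge"), w, mode="valid")
    interior = slice(150, n - 150)
    np.testing.assert_allclose(smoothed[interior], conv[interior], atol=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    st.integers(min_value=2, max_value=40),
    st.floats(min_value=0.05, max_value=1.0),
    st.integers(min_value=0, max_value=2**31 - 1),
)
def test_smoothing_is_linear(n, eta, seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(2, n))
    a, b = rng.normal(size=2)
    lhs = co.smooth_noncausal(a * x + b * y, eta)
    rhs = a * co.smooth_noncausal(x, eta) + b * co.smooth_noncausal(y, eta)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_selfcorrelation_is_one_and_sign_flips():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    cfg = co.CorrConfig(lag_min=-3, lag_max=3)
    m = co.instantaneous_crosscorr(x, x, cfg)
    zero = np.flatnonzero(m.lags == 0)[0]
    assert np.allclose(m.r[m.valid[:, zero], zero], 1.0)
    m2 = co.instantaneous_crosscorr(x, -x, cfg)
    assert np.allclose(m2.r[m2.valid[:, zero], zero], -1.0)


def test_crosscorr_symmetric_under_swap_and_lag_flip():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=(2, 80))
    cfg = co.CorrConfig(lag_min=-5, lag_max=5)
    mxy = co.instantaneous_crosscorr(x, y, cfg)
    myx = co.instantaneous_crosscorr(y, x, cfg)
    for j, d in enumerate(mxy.lags):
        jf = np.flatnonzero(myx.lags == -d)[0]
        for t in range(80):
            if not mxy.valid[t, j]:
                continue
            # row index refers to the first series; swapping moves it by d
            assert myx.valid[t + d, jf]
            assert mxy.r[t, j] == pytest.approx(myx.r[t + d, jf], abs=1e-10)


def test_crosscorr_matches_weighted_pearson_oracle():
    # recursive moments vs direct weighted-Pearson with the explicit kernel
    rng = np.random.default_rng(5)
    n, eta = 64, 0.5
    x, y = rng.normal(size=(2, n))
    m = co.instantaneous_crosscorr(x, y, co.CorrConfig(eta=eta, lag_min=0, lag_max=0))
    w = two_sided_exponential_kernel(eta, half_width=27)
    for t in range(28, n - 28):
        expect = weighted_pearson_local(x, y, w, t)
        assert m.r[t, 0] == pytest.approx(expect, abs=1e-6)


def test_crosscorr_exact_kernel_matrix_oracle():
    rng = np.random.default_rng(6)
    n = 48
    x, y = rng.normal(size=(2, n))
    for eta in (0.1, 0.4):
        m = co.instantaneous_crosscorr(
            x, y, co.CorrConfig(eta=eta, lag_min=-2, lag_max=2)
        )
        for j, d in enumerate(m.lags):
            if d >= 0:
                a, b, t0 = x[: n - d], y[d:], 0
            else:
                a, b, t0 = x[-d:], y[: n + d], -d
            expect = local_corr_from_matrix(a, b, eta)
            got = m.r[t0 : t0 + len(a), j]
            np.testing.assert_allclose(got, expect, atol=1e-9)


def test_crosscorr_edge_cells_invalid_not_zero_filled():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=(2, 30))
    m = co.instantaneous_crosscorr(x, y, co.CorrConfig(lag_min=-4, lag_max=4))
    jmax = np.flatnonzero(m.lags == 4)[0]
    assert not m.valid[-4:, jmax].any()
    assert np.isnan(m.r[-4:, jmax]).all()
    jmin = np.flatnonzero(m.lags == -4)[0]
    assert not m.valid[:4, jmin].any()


def test_crosscorr_rejects_too_short_series():
    with pytest.raises(ValueError, match="too short"):
        co.instantaneous_crosscorr(
            np.arange(10.0), np.arange(10.0), co.CorrConfig(lag_min=-9, lag_max=9)
        )


def test_crosscorr_truncates_with_warning():
    rng = np.random.default_rng(8)
    x = rng.normal(size=60)
    y = rng.normal(size=50)
    with pytest.warns(UserWarning, match="truncating"):
        m = co.instantaneous_crosscorr(x, y, co.CorrConfig(lag_min=-2, lag_max=2))
    assert m.r.shape[0] == 50


def test_coordination_index_bounds_and_scale_invariance():
    rng = np.random.default_rng(9)
    x, y = rng.normal(size=(2, 100))
    cfg = co.CorrConfig()
    m = co.instantaneous_crosscorr(x, y, cfg)
    idx = co.coordination_index(m)
    assert 0.0 <= idx <= 1.0
    m_scaled = co.instantaneous_crosscorr(5.0 * x, 5.0 * y, cfg)
    assert co.coordination_index(m_scaled) == pytest.approx(idx, abs=1e-12)
    # saturated matrices hit the bounds
    m.r[m.valid] = 1.0
    assert co.coordination_index(m) == 1.0
    m.r[m.valid] = 0.0
    assert co.coordination_index(m) == 0.0


def test_shared_component_raises_local_correlation():
    # white noise pairs gain |r| when a common slow AR(1) is mixed in
    rng = np.random.default_rng(10)
    gains = []
    for _ in range(25):
        x, y = rng.normal(size=(2, 192))
        shared = np.cumsum(rng.normal(size=192)) * 0.3
        cfg = co.CorrConfig()
        m0 = co.instantaneous_crosscorr(x, y, cfg)
        m1 = co.instantaneous_crosscorr(x + shared, y + shared, cfg)
        gains.append(
            np.nanmean(np.abs(m1.r[m1.valid])) - np.nanmean(np.abs(m0.r[m0.valid]))
        )
    assert np.mean(gains) > 0


def test_pseudo_pairs_partition(small_experiment):
    individual = [s for s in small_experiment.sessions if s.condition == "individual"]
    pairs = co.make_pseudo_pairs(individual)
    assert len(pairs) == 6
    members = [s.agent_id for ra, rb in pairs for s in (ra, rb)]
    assert len(set(members)) == 12
    with pytest.raises(ValueError, match="exactly two"):
        co.make_pseudo_pairs(individual[:-1])


def test_pseudo_pair_length_mismatch_warns():
    a = _session_from_rts(list(np.random.default_rng(11).normal(300, 10, 60)))
    a.trials["condition"] = "individual"
    b = _session_from_rts(list(np.random.default_rng(12).normal(300, 10, 40)), agent="p0_b")
    b.trials["condition"] = "individual"
    a.condition = b.condition = "individual"
    with pytest.warns(UserWarning, match="differ by more than 10%"):
        co.make_pseudo_pairs([a, b])
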