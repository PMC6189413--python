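"""Paired t, repeated-measures ANOVA, mixed-model comparison."""

import numpy as np
import pandas as pd
import pytest

import jointcoord.inference as inf
from _oracles import rm_anova_projection


def _cells(rng, n_parts=12, factors=(("condition", ("individual", "joint")),
                                      ("correspondence", ("C", "NC")))):
    rows = []
    for p in range(n_parts):
        base = rng.normal(330, 12)
        for combo in _combos(factors):
            rows.append(
                {"participant": f"s{p:02d}", "rt": base + rng.normal(0, 6), **combo}
            )
    return pd.DataFrame(rows)


def _combos(factors):
    if not factors:
        yield {}
        return
    (name, levels), *rest = factors
    for lv in levels:
        for tail in _combos(rest):
            yield {name: lv, **tail}


def test_paired_t_identity_and_cap():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = inf.paired_t(a, a)
    assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0
    res = inf.paired_t(a + 0.5, a, n_comparisons=2)
    assert res.p_corrected == min(1.0, res.p * 2)
    big = inf.paired_t(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))
    assert np.isinf(big.statistic) and big.p == 0.0


def test_paired_t_closed_form():
    # differences [1, 2, 3, 4]: t = mean / (SD / sqrt(n)), d = mean / SD
    b = np.zeros(4)
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = inf.paired_t(a, b)
    sd = np.std(a, ddof=1)
    assert res.statistic == pytest.approx(2.5 / (sd / 2.0), abs=1e-12)
    assert res.effect_size == pytest.approx(2.5 / sd, abs=1e-12)
    assert res.df == 3


def test_rm_anova_two_level_factor_equals_squared_paired_t():
    rng = np.random.default_rng(0)
    df = _cells(rng)
    res = inf.rm_anova(df, dv="rt", within=["condition", "correspondence"],
                       subject="participant")
    marg = df.groupby(["participant", "condition"])["rt"].mean().unstack()
    t = inf.paired_t(marg["joint"], marg["individual"])
    F = res.loc[res["effect"] == "condition", "F"].iloc[0]
    assert F == pytest.approx(t.statistic**2, abs=1e-9)


def test_rm_anova_matches_projection_oracle():
    rng = np.random.default_rng(1)
    df = _cells(rng, n_parts=20)
    res = inf.rm_anova(df, dv="rt", within=["condition", "correspondence"],
                       subject="participant")
    pivot = df.pivot_table(index="participant", columns=["condition", "correspondence"],
                           values="rt")
    oracle = rm_anova_projection(pivot.to_numpy(), [2, 2])
    by_name = {
        "condition": "1",
        "correspondence": "2",
        "condition x correspondence": "1x2",
    }
    for _, row in res.iterrows():
        F, df1, df2 = oracle[by_name[row["effect"]]]
        assert row["F"] == pytest.approx(F, abs=1e-8)
        assert (row["df1"], row["df2"]) == (df1, df2)


def test_rm_anova_three_within_and_between():
    rng = np.random.default_rng(2)
    factors = (
        ("condition", ("individual", "joint")),
        ("transition", ("Go/go", "Nogo/go")),
        ("correspondence", ("C", "NC")),
    )
    frames = []
    for g, exp in enumerate(("exp1", "exp2")):
        df = _cells(rng, n_parts=8, factors=factors)
        df["participant"] = df["participant"] + f"_{exp}"
        df["experiment"] = exp
        frames.append(df)
    data = pd.concat(frames)
    res = inf.rm_anova(
        data, dv="rt",
        within=["condition", "transition", "correspondence"],
        subject="participant", between="experiment",
    )
    effects = set(res["effect"])
    assert "experiment" in effects
    assert "condition x transition x correspondence" in effects
    assert "condition x experiment" in effects
    assert len(res) == 1 + 7 * 2  # between + 7 within effects each with x-group term
    assert ((res["p"] >= 0) & (res["p"] <= 1)).all()
    assert ((res["pes"] >= 0) & (res["pes"] <= 1)).all()


def test_rm_anova_matches_statsmodels_anovarm():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(3)
    df = _cells(rng, n_parts=10)
    ours = inf.rm_anova(df, dv="rt", within=["condition", "correspondence"],
                        subject="participant").set_index("effect")
    theirs = AnovaRM(df, depvar="rt", subject="participant",
                     within=["condition", "correspondence"]).fit().anova_table
    for name, sm_name in [
        ("condition", "condition"),
        ("correspondence", "correspondence"),
        ("condition x correspondence", "condition:correspondence"),
    ]:
        assert ours.loc[name, "F"] == pytest.approx(
            theirs.loc[sm_name, "F Value"], rel=1e-9
        )


def test_rm_anova_degenerate_data_raises():
    df = _cells(np.random.default_rng(4), n_parts=5)
    df["rt"] = 300.0
    with pytest.raises(ValueError, match="[Ff] undefined|error variance"):
        inf.rm_anova(df, dv="rt", within=["condition", "correspondence"],
                     subject="participant")


def test_rm_anova_missing_cell_raises():
    df = _cells(np.random.default_rng(5))
    df = df[~((df["participant"] == "s00") & (df["correspondence"] == "C"))]
    with pytest.raises(ValueError, match="missing"):
        inf.rm_anova(df, dv="rt", within=["condition", "correspondence"],
                     subject="participant")


def _lrt_dataset(rng, n_pairs=10, coord_slope_sd=0.0, coord_value=None):
    rows, coord = [], {}
    for p in range(n_pairs):
        pid = f"p{p:02d}"
        c = coord_value if coord_value is not None else rng.uniform(0.05, 0.30)
        coord[pid] = c
        b_pair = rng.normal(0.0, coord_slope_sd) * c
        for a in "ab":
            part = f"{pid}_{a}"
            u = rng.normal(0.0, 8.0)
            for cond in ("individual", "joint"):
                for corr in ("C", "NC"):
                    mu = 330.0 + (5.0 if corr == "NC" else 0.0)
                    rows.append(
                        dict(participant=part, pair=pid, condition=cond,
                             correspondence=corr,
                             rt=mu + u + b_pair + rng.normal(0.0, 3.0))
                    )
    return pd.DataFrame(rows), coord


def test_lrt_degrees_of_freedom_and_nonnegative():
    df, coord = _lrt_dataset(np.random.default_rng(6), coord_slope_sd=40.0)
    mc = inf.compare_models_lrt(df, coord)
    assert mc.df_2 == mc.df_1 + 1
    assert mc.chi2 >= -1e-6
    assert mc.converged


def test_lrt_constant_covariate_uninformative():
    # without pair-level variance a constant covariate buys nothing
    df, coord = _lrt_dataset(np.random.default_rng(7), coord_slope_sd=0.0,
                             coord_value=0.2)
    mc = inf.compare_models_lrt(df, coord)
    assert mc.chi2 == pytest.approx(0.0, abs=0.2)
    assert mc.boundary or mc.random_effect_var < 1.0


def test_lrt_detects_coordination_driven_variance():
    df, coord = _lrt_dataset(np.random.default_rng(8), coord_slope_sd=60.0)
    mc = inf.compare_models_lrt(df, coord)
    assert mc.chi2 > 3.84
    assert mc.p < 0.05


def test_lrt_missing_coordination_raises():
    df, coord = _lrt_dataset(np.random.default_rng(9))
    coord.pop("p00")
    with pytest.raises(ValueError, match="p00"):
        inf.compare_models_lrt(df, coord)
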