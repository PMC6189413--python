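"""Hypothesis tests: paired t, within-subject factorial ANOVA, mixed-model LRT.

The ANOVA is a standard repeated-measures sums-of-squares decomposition for
fully crossed within-subject designs (2-4 within factors, one observation per
participant per cell), with an optional between-participant factor handled by
split-plot error terms.  Effect sizes are Cohen's d (paired t, mean difference
over SD of differences) and partial eta squared (ANOVA).

The mixed-model comparison mirrors the lme4 protocol of testing a pair-level
random effect of response coordination: Model 1 has fixed effects Condition,
Correspondence and their interaction with a random intercept per participant;
Model 2 adds a pair-level random effect scaled by each pair's coordination
index.  Both are fitted by maximum likelihood (not REML — the models differ
in random structure) and compared with a 1-df chi-square on 2*dlogLik.  The
1-df reference is conservative for a variance component on the boundary; the
plain chi-square is reported as primary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf


@dataclass
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    p_corrected: float
    effect_size: float
    kind: str = "t"


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of the two coordination mixed models."""

    loglik_1: float
    loglik_2: float
    df_1: int
    df_2: int
    chi2: float
    p: float
    random_effect_var: float
    converged: bool
    boundary: bool
    fixed_effects_model2: pd.DataFrame  # term, estimate, z, p


def paired_t(a, b, n_comparisons: int = 1) -> TestResult:
    """Paired-samples t test with Bonferroni correction.

    Cohen's d is the mean difference divided by the SD of the differences.
    A zero-variance, nonzero-mean difference yields an infinite t with p = 0;
    all-equal pairs yield t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d samples with n >= 2")
    d = a - b
    n = len(d)
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if md == 0.0:
            t, p, eff = 0.0, 1.0, 0.0
        else:
            t = np.inf if md > 0 else -np.inf
            p, eff = 0.0, np.sign(md) * np.inf
    else:
        t = md / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
        eff = md / sd
    return TestResult(
        statistic=float(t),
        df=n - 1,
        p=float(p),
        p_corrected=float(min(1.0, p * n_comparisons)),
        effect_size=float(eff),
        kind="t",
    )


def _component(Y: np.ndarray, subset: tuple[int, ...], within_axes: range) -> np.ndarray:
    """Tensor effect component: center over axes in subset, average the rest."""
    u = Y
    for ax in within_axes:
        if ax in subset:
            u = u - u.mean(axis=ax, keepdims=True)
        else:
            u = u.mean(axis=ax, keepdims=True)
    return u


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    between: str | None = None,
) -> pd.DataFrame:
    """Repeated-measures factorial ANOVA.

    ``data`` is long format with one row per participant per design cell
    (aggregate to cell means first).  Returns one row per effect with F, dfs,
    p and partial eta squared.  Within effects (and their interactions with
    the between factor) are tested against the corresponding effect-by-subject
    error strata; the between factor against subjects-within-groups.
    """
    if not 1 <= len(within) <= 4:
        raise ValueError("supports 1-4 within-subject factors")
    levels = [np.sort(data[f].unique()) for f in within]
    subjects = np.sort(data[subject].unique())
    S = len(subjects)
    if S < 2:
        raise ValueError("need >= 2 participants")
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 else None
    if full is not None:
        pivot = pivot.reindex(columns=full)
    if pivot.isna().any().any():
        raise ValueError("missing design cells; the crossed design must be complete")
    shape = [S] + [len(l) for l in levels]
    Y = pivot.to_numpy().reshape(shape)

    if between is not None:
        gmap = data.groupby(subject)[between].agg(lambda s: s.unique())
        if gmap.map(len).max() > 1:
            raise ValueError("between-factor must be constant within participant")
        group = gmap.map(lambda u: u[0]).loc[pivot.index].to_numpy()
        glevels = np.sort(np.unique(group))
        G = len(glevels)
        gidx = [np.flatnonzero(group == g) for g in glevels]
    else:
        G = 1
        gidx = [np.arange(S)]

    within_axes = range(1, len(within) + 1)
    n_cells = int(np.prod(shape[1:]))
    results = []

    # between-participants stratum
    subj_means = Y.reshape(S, -1).mean(axis=1)
    grand = subj_means.mean()
    gmeans = np.array([subj_means[ix].mean() for ix in gidx])
    ss_subj_within = n_cells * sum(
        float(((subj_means[ix] - gm) ** 2).sum()) for ix, gm in zip(gidx, gmeans)
    )
    df_sw = S - G
    if between is not None:
        ss_g = n_cells * float(
            sum(len(ix) * (gm - grand) ** 2 for ix, gm in zip(gidx, gmeans))
        )
        df_g = G - 1
        if ss_subj_within <= 0 or df_sw <= 0:
            raise ValueError("no between-participant error variance; F undefined")
        F = (ss_g / df_g) / (ss_subj_within / df_sw)
        results.append(
            {
                "effect": between,
                "F": F,
                "df1": df_g,
                "df2": df_sw,
                "p": float(stats.f.sf(F, df_g, df_sw)),
                "pes": ss_g / (ss_g + ss_subj_within),
            }
        )

    # within strata: every nonempty subset of within factors
    for k in range(1, len(within) + 1):
        for subset in combinations(within_axes, k):
            u = _component(Y, subset, within_axes)  # shape (S, subset levels, 1s)
            u2 = u.reshape(S, -1)  # collapse kept axes
            m = n_cells // u2.shape[1]  # multiplicity of averaged-out axes
            col_mean = u2.mean(axis=0)
            ss_t = m * S * float((col_mean**2).sum())
            gcol = np.stack([u2[ix].mean(axis=0) for ix in gidx])  # (G, cells)
            resid = u2.copy()
            for g, ix in enumerate(gidx):
                resid[ix] -= gcol[g]
            ss_err = m * float((resid**2).sum())
            df_t = int(np.prod([len(levels[ax - 1]) - 1 for ax in subset]))
            df_err = df_t * (S - G)
            name = " x ".join(within[ax - 1] for ax in subset)
            if ss_err <= 0 or df_err <= 0:
                raise ValueError(
                    f"zero error variance for effect {name!r}; F undefined "
                    "(degenerate data)"
                )
            F = (ss_t / df_t) / (ss_err / df_err)
            results.append(
                {
                    "effect": name,
                    "F": F,
                    "df1": df_t,
                    "df2": df_err,
                    "p": float(stats.f.sf(F, df_t, df_err)),
                    "pes": ss_t / (ss_t + ss_err),
                }
            )
            if between is not None:
                ng = np.array([len(ix) for ix in gidx])
                wgrand = (ng[:, None] * gcol).sum(axis=0) / S
                ss_tg = m * float((ng[:, None] * (gcol - wgrand) ** 2).sum())
                df_tg = df_t * (G - 1)
                F = (ss_tg / df_tg) / (ss_err / df_err)
                results.append(
                    {
                        "effect": f"{name} x {between}",
                        "F": F,
                        "df1": df_tg,
                        "df2": df_err,
                        "p": float(stats.f.sf(F, df_tg, df_err)),
                        "pes": ss_tg / (ss_tg + ss_err),
                    }
                )
    return pd.DataFrame(results)


def compare_models_lrt(
    cell_means: pd.DataFrame, coordination: pd.Series | dict
) -> ModelComparison:
    """Does a pair-level coordination random effect improve the RT model?

    ``cell_means`` is long format with columns participant, pair, condition,
    correspondence and rt (per-participant cell means); ``coordination`` maps
    pair -> coordination index.  Model 1: rt ~ condition * correspondence with
    a random intercept per participant.  Model 2 adds a pair-level random
    effect whose loading is the pair's coordination index (a random slope on
    the covariate, one extra variance parameter).  Fits use ML; the LRT
    statistic is referred to chi-square with 1 df.
    """
    df = cell_means.copy()
    coord = pd.Series(coordination)
    df["coordination"] = df["pair"].map(coord)
    if df["coordination"].isna().any():
        missing = sorted(df.loc[df["coordination"].isna(), "pair"].unique())
        raise ValueError(f"no coordination index for pair(s) {missing}")

    fixed = "rt ~ C(condition) * C(correspondence)"
    vc = {"participant": "0 + C(participant)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = smf.mixedlm(
            fixed, df, groups=df["pair"], re_formula="0", vc_formula=vc
        ).fit(reml=False, method="lbfgs", maxiter=200)
        m2 = smf.mixedlm(
            fixed,
            df,
            groups=df["pair"],
            re_formula="0 + coordination",
            vc_formula=vc,
        ).fit(reml=False, method="lbfgs", maxiter=200)

    ll1, ll2 = float(m1.llf), float(m2.llf)
    chi2 = max(0.0, 2.0 * (ll2 - ll1))
    p = float(stats.chi2.sf(chi2, 1))
    re_var = float(np.asarray(m2.cov_re)[0, 0]) if m2.cov_re.size else 0.0
    scale = float(m2.scale)
    boundary = re_var < 1e-8 * max(scale, 1.0)

    fe = pd.DataFrame(
        {
            "term": m2.fe_params.index,
            "estimate": m2.fe_params.to_numpy(),
            "z": (m2.fe_params / m2.bse_fe).to_numpy(),
            "p": m2.pvalues.loc[m2.fe_params.index].to_numpy(),
        }
    )
    df1 = int(m1.params.shape[0])
    return ModelComparison(
        loglik_1=ll1,
        loglik_2=ll2,
        df_1=df1,
        df_2=df1 + 1,
        chi2=chi2,
        p=p,
        random_effect_var=re_var,
        converged=bool(m1.converged and m2.converged),
        boundary=boundary,
        fixed_effects_model2=fe,
    )
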