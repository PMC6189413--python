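"""End-to-end analysis workflow.

Runs the full dyadic Simon pipeline in the order the analyses build on each
other: trial coding and filtering, participant exclusion, mean /
distributional / sequential effect tables, coordination indices for joint
pairs and pseudo-pairs, paired tests and ANOVAs, and the coordination
mixed-model comparison.  Results are written as CSV tables plus a versioned
JSON summary; all randomness flows from the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coordination as coord
from . import effects, inference, trials
from .io import RunConfig, read_trial_log, write_trial_log
from .simulate import INDIVIDUAL, JOINT, Session, generate_experiment

SUMMARY_SCHEMA = 1

log = logging.getLogger("jointcoord")


def _sessions_by_pair(sessions: list[Session]) -> dict[tuple[str, str], list[Session]]:
    grouped: dict[tuple[str, str], list[Session]] = {}
    for s in sessions:
        grouped.setdefault((s.pair_id, s.condition), []).append(s)
    for members in grouped.values():
        members.sort(key=lambda s: s.agent_id)
    return grouped


def coded_trials(sessions: list[Session]) -> pd.DataFrame:
    """Code every session from its agent's perspective (partner-aware)."""
    grouped = _sessions_by_pair(sessions)
    frames = []
    for (pair_id, condition), members in grouped.items():
        for s in members:
            partner = None
            if condition == JOINT and len(members) == 2:
                partner = members[0] if members[1] is s else members[1]
            frames.append(trials.code_transitions(s, partner=partner))
    return pd.concat(frames, ignore_index=True)


def error_count_table(sessions: list[Session]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": s.pair_id,
            "agent_id": s.agent_id,
            "condition": s.condition,
            "n_errors": trials.count_errors(s),
        }
        for s in sessions
    ]
    return pd.DataFrame(rows)


def coordination_table(
    sessions: list[Session], config: RunConfig
) -> pd.DataFrame:
    """Coordination index per pair: joint pairs and individual pseudo-pairs."""
    grouped = _sessions_by_pair(sessions)
    rows = []
    individual = [s for s in sessions if s.condition == INDIVIDUAL]
    for ra, rb in coord.make_pseudo_pairs(individual):
        m = coord.instantaneous_crosscorr(ra, rb, config.corr)
        rows.append(
            {
                "pair_id": ra.agent_id.rsplit("_", 1)[0],
                "condition": INDIVIDUAL,
                "index": coord.coordination_index(m),
            }
        )
    for (pair_id, condition), members in sorted(grouped.items()):
        if condition != JOINT or len(members) != 2:
            continue
        rows.append(
            {
                "pair_id": pair_id,
                "condition": JOINT,
                "index": coord.pair_coordination(members[0], members[1], config.corr),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig, input: str | Path = "simulate", out_dir: str | Path | None = None
) -> dict:
    """Execute the full workflow; returns (and optionally writes) the summary.

    ``input`` is a trial-log CSV path, or the literal string ``"simulate"`` to
    generate data from ``config.sim`` / ``config.n_pairs`` / ``config.design``.
    """
    stage = "load"
    notes: list[str] = []
    try:
        if str(input) == "simulate":
            exp = generate_experiment(config.sim, config.n_pairs, config.design)
            sessions = exp.sessions
            notes.append(
                f"simulated {config.n_pairs} pairs, design={config.design}, "
                f"seed={config.sim.seed}"
            )
        else:
            sessions = read_trial_log(input)
            notes.append(f"read {len(sessions)} sessions from {input}")

        stage = "exclusions"
        errs = error_count_table(sessions)
        excluded = trials.excluded_pairs(errs, k=config.tukey_k)
        if excluded:
            notes.append(f"excluded pairs (Tukey fences on error counts): {excluded}")
            sessions = [s for s in sessions if s.pair_id not in excluded]

        stage = "coding"
        coded = coded_trials(sessions)
        rt_trials = trials.filter_for_rt_analysis(coded)
        seq_trials = trials.filter_for_sequential_analysis(coded)

        stage = "effect tables"
        table1 = effects.condition_means(rt_trials)
        jse = {
            cond: effects.simon_effect(table1, cond)
            for cond in table1.means.index
        }
        quartiles = effects.quartile_bin_means(rt_trials, n_bins=config.n_bins)
        seq_table = effects.sequential_effect_table(seq_trials)

        stage = "coordination"
        coord_table = coordination_table(sessions, config)

        stage = "inference"
        anova = inference.rm_anova(
            table1.per_participant,
            dv="rt_ms",
            within=["condition", "correspondence"],
            subject="agent_id",
        )
        per = table1.per_participant.pivot_table(
            index="agent_id", columns=["condition", "correspondence"], values="rt_ms"
        )
        ttests = {}
        for cond in table1.means.index:
            res = inference.paired_t(
                per[(cond, trials.NC)], per[(cond, trials.C)], n_comparisons=2
            )
            ttests[cond] = res
        cw = coord_table.pivot_table(index="pair_id", columns="condition", values="index")
        coord_t = None
        if {INDIVIDUAL, JOINT} <= set(cw.columns) and len(cw.dropna()) >= 2:
            cwc = cw.dropna()
            coord_t = inference.paired_t(cwc[JOINT], cwc[INDIVIDUAL])

        lrt = None
        if JOINT in cw.columns:
            cells = table1.per_participant.rename(columns={"rt_ms": "rt"}).copy()
            cells["participant"] = cells["agent_id"]
            cells["pair"] = cells["agent_id"].str.rsplit("_", n=1).str[0]
            lrt = inference.compare_models_lrt(
                cells, cw[JOINT].dropna()
            )
            if not lrt.converged:
                notes.append("mixed-model fit did not fully converge")

        stage = "report"
        summary = _summarize(
            config, notes, excluded, table1, jse, quartiles, seq_table,
            coord_table, anova, ttests, coord_t, lrt,
        )
        if out_dir is not None:
            _write_outputs(
                Path(out_dir), config, sessions, summary, table1, quartiles,
                seq_table, coord_table, anova,
            )
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _jsonify(x):
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return round(v, 10) if np.isfinite(v) else str(v)
    if isinstance(x, (np.integer, int)):
        return int(x)
    return x


def _test_dict(res: inference.TestResult | None):
    if res is None:
        return None
    return {
        "statistic": res.statistic,
        "df": res.df,
        "p": res.p,
        "p_corrected": res.p_corrected,
        "effect_size": res.effect_size,
    }


def _summarize(
    config, notes, excluded, table1, jse, quartiles, seq_table, coord_table,
    anova, ttests, coord_t, lrt,
):
    cfg_repr = json.dumps(_jsonify(asdict(config)), sort_keys=True)
    summary = {
        "schema_version": SUMMARY_SCHEMA,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        "seed": config.seed,
        "notes": notes,
        "excluded_pairs": excluded,
        "condition_means_ms": {
            cond: {corr: table1.means.loc[cond, corr] for corr in table1.means.columns}
            for cond in table1.means.index
        },
        "simon_effect_ms": jse,
        "quartile_means_ms": {
            " / ".join(map(str, idx if isinstance(idx, tuple) else (idx,))): row.tolist()
            for idx, row in quartiles.means.iterrows()
        },
        "sequential_table_ms": {
            f"{tr} after {prev}": {
                "C": seq_table.table.loc[(tr, prev), trials.C],
                "NC": seq_table.table.loc[(tr, prev), trials.NC],
                "SE": seq_table.table.loc[(tr, prev), "SE"],
            }
            for tr, prev in seq_table.table.index
        },
        "coordination_pct": {
            cond: grp["index"].mean() * 100.0
            for cond, grp in coord_table.groupby("condition")
        }
        if not coord_table.empty
        else {},
        "anova": anova.to_dict(orient="records"),
        "paired_t_simon": {c: _test_dict(t) for c, t in ttests.items()},
        "paired_t_coordination": _test_dict(coord_t),
        "model_comparison": None
        if lrt is None
        else {
            "loglik_model1": lrt.loglik_1,
            "loglik_model2": lrt.loglik_2,
            "df_model1": lrt.df_1,
            "df_model2": lrt.df_2,
            "chi2": lrt.chi2,
            "p": lrt.p,
            "random_effect_var": lrt.random_effect_var,
            "converged": lrt.converged,
            "boundary": lrt.boundary,
        },
    }
    return _jsonify(summary)


def _write_outputs(
    out_dir, config, sessions, summary, table1, quartiles, seq_table,
    coord_table, anova,
):
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trial_log(sessions, out_dir / "trials.csv")
    table1.means.to_csv(out_dir / "condition_means.csv")
    table1.sds.to_csv(out_dir / "condition_sds.csv")
    quartiles.means.to_csv(out_dir / "quartile_means.csv")
    seq_table.table.to_csv(out_dir / "sequential_table.csv")
    coord_table.to_csv(out_dir / "coordination.csv", index=False)
    anova.to_csv(out_dir / "anova.csv", index=False)
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote results to %s", out_dir)
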