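"""Descriptive decompositions of the (joint) Simon effect.

All tables use two-stage averaging: cell means are computed per participant
first, then averaged with equal weights across participants; reported SDs are
across participant cell means.  Input frames are filtered coded trials (see
:mod:`jointcoord.trials`) pooled over participants, with columns ``agent_id``
(the participant key), ``condition``, ``correspondence``, ``rt_ms`` and — for
the sequential table — ``transition`` and ``prev_correspondence``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import C, NC, GO_GO, NOGO_GO


def round_half_away(x: float | np.ndarray) -> np.ndarray:
    """Round half away from zero (table formatting convention)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _check_cells(per_part: pd.DataFrame, index_cols: list[str]) -> None:
    counts = per_part.groupby("agent_id").size()
    expected = counts.max()
    short = counts[counts < expected]
    if not short.empty:
        missing = short.index.tolist()
        raise ValueError(
            f"empty design cells for participant(s) {missing}: every "
            f"participant needs observations in each {' x '.join(index_cols)} cell"
        )


@dataclass
class EffectTable:
    """Condition x correspondence cell means and SDs (ms)."""

    means: pd.DataFrame  # index: condition, columns: correspondence
    sds: pd.DataFrame
    per_participant: pd.DataFrame  # agent_id, condition, correspondence, rt_ms


@dataclass
class QuartileTable:
    """Mean RT per quantile bin x condition x correspondence."""

    means: pd.DataFrame  # index: (condition, correspondence), columns: bin
    per_participant: pd.DataFrame


@dataclass
class TransitionTable:
    """Mean RT per transition x previous x current correspondence.

    ``table`` has one row per (transition, prev_correspondence) with columns
    C, NC and SE = NC - C (the rowwise Simon effect).
    """

    table: pd.DataFrame
    per_participant: pd.DataFrame


def condition_means(trials: pd.DataFrame) -> EffectTable:
    """Mean correct RT (and SD) by condition and correspondence."""
    per = (
        trials.groupby(["agent_id", "condition", "correspondence"], as_index=False)[
            "rt_ms"
        ].mean()
    )
    _check_cells(per, ["condition", "correspondence"])
    means = per.pivot_table(
        index="condition", columns="correspondence", values="rt_ms", aggfunc="mean"
    )
    sds = per.pivot_table(
        index="condition", columns="correspondence", values="rt_ms", aggfunc="std"
    )
    return EffectTable(means=means, sds=sds, per_participant=per)


def simon_effect(table: EffectTable, condition: str) -> float:
    """Non-corresponding minus corresponding mean RT for one condition."""
    try:
        row = table.means.loc[condition]
        return float(row[NC] - row[C])
    except KeyError as exc:
        raise ValueError(f"missing cell for condition {condition!r}: {exc}") from exc


def _bin_edges(n: int, n_bins: int) -> np.ndarray:
    """Cumulative bin sizes; remainder observations go to the earliest bins."""
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    return np.cumsum(np.concatenate([[0], sizes]))


def quartile_bin_means(
    trials: pd.DataFrame, n_bins: int = 4, pool_correspondence: bool = False
) -> QuartileTable:
    """Rank-ordered equal-count bin means of correct RTs.

    Within each participant x condition x correspondence cell (or per
    condition pooling correspondence, with ``pool_correspondence=True``), RTs
    are sorted ascending and split into ``n_bins`` equal-count bins (any
    remainder goes to the earliest bins); bin means are then averaged across
    participants.
    """
    keys = ["agent_id", "condition"]
    if not pool_correspondence:
        keys.append("correspondence")
    rows = []
    for key, grp in trials.groupby(keys):
        rts = np.sort(grp["rt_ms"].to_numpy())
        if len(rts) < n_bins:
            raise ValueError(
                f"cell {dict(zip(keys, key))} has {len(rts)} RTs; need >= {n_bins}"
            )
        edges = _bin_edges(len(rts), n_bins)
        for b in range(n_bins):
            rows.append(
                dict(zip(keys, key))
                | {"bin": b + 1, "rt_ms": float(rts[edges[b] : edges[b + 1]].mean())}
            )
    per = pd.DataFrame(rows)
    index = [k for k in keys if k != "agent_id"]
    means = per.pivot_table(index=index, columns="bin", values="rt_ms", aggfunc="mean")
    return QuartileTable(means=means, per_participant=per)


def sequential_effect_table(trials: pd.DataFrame) -> TransitionTable:
    """2 x 2 x 2 transition table with rowwise Simon effects.

    Cells are transition (Nogo/go, Go/go) x previous-trial correspondence x
    current-trial correspondence, two-stage averaged; SE = NC - C per row.
    """
    per = (
        trials.groupby(
            ["agent_id", "transition", "prev_correspondence", "correspondence"],
            as_index=False,
        )["rt_ms"].mean()
    )
    _check_cells(per, ["transition", "prev_correspondence", "correspondence"])
    cells = per.pivot_table(
        index=["transition", "prev_correspondence"],
        columns="correspondence",
        values="rt_ms",
        aggfunc="mean",
    )
    cells = cells.reindex(
        pd.MultiIndex.from_product(
            [[NOGO_GO, GO_GO], [C, NC]], names=["transition", "prev_correspondence"]
        )
    )
    cells["SE"] = cells[NC] - cells[C]
    return TransitionTable(table=cells, per_participant=per)


def plot_quartiles(qtable: QuartileTable, path: str | None = None):
    """Quartile-curve plot (mean RT per bin, one line per correspondence)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = qtable.means
    conditions = means.index.get_level_values(0).unique()
    fig, axes = plt.subplots(
        1, len(conditions), figsize=(4 * len(conditions), 3.2), squeeze=False
    )
    for ax, cond in zip(axes[0], conditions):
        sub = means.loc[cond]
        for corr, row in sub.iterrows():
            ax.plot(row.index, row.values, marker="o", label=str(corr))
        ax.set_title(str(cond))
        ax.set_xlabel("bin")
        ax.set_ylabel("mean RT (ms)")
        ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
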