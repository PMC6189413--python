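"""Trial coding and filtering rules for go/no-go Simon sessions.

Adds correspondence (C / NC), trial-transition (Go/go vs Nogo/go) and
previous-trial codes to a session, and implements the analysis filters:
correct-go-trial retention for mean/distributional RT analyses, the stricter
sequential-analysis filter (first trial of each block, errors, and trials
preceded by an error are discarded), and Tukey-fence participant exclusion on
error counts.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import LEFT, RIGHT, Session

C = "C"
NC = "NC"
GO_GO = "Go/go"
NOGO_GO = "Nogo/go"
UNDEFINED = "undefined"

_SIDES = (LEFT, RIGHT)


def code_correspondence(stimulus_side: str, response_side: str) -> str:
    """C if stimulus side equals the responder's key side, else NC."""
    if stimulus_side not in _SIDES or response_side not in _SIDES:
        raise ValueError(
            f"both sides must be in {_SIDES}; got "
            f"({stimulus_side!r}, {response_side!r}) — only response-defined "
            "trials can be coded from the responder's mapping"
        )
    return C if stimulus_side == response_side else NC


def agent_key_side(trials: pd.DataFrame, agent_id: str) -> str:
    """Infer an agent's response-key side from their recorded responses.

    The two members of a pair sit at opposite keys, so the co-agent's side is
    the opposite one; the modal recorded side is robust to stray entries.
    """
    own = trials.loc[
        (trials["agent_id"] == agent_id) & (trials["response_side"] != "none"),
        "response_side",
    ]
    if own.empty:
        raise ValueError(f"agent {agent_id!r} has no recorded responses")
    return own.mode().iloc[0]


def code_transitions(
    session: Session | pd.DataFrame,
    agent_id: str | None = None,
    partner: Session | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Code a session from one agent's perspective.

    Returns the session's trials with added columns:

    ``correspondence``
        C/NC of every trial, coded from the *required* responder's key-side
        mapping (for no-go trials this is the co-agent's geometry), so the
        previous-trial factor is defined on every transition.
    ``transition``
        Go/go if trial n-1 required this agent's response, Nogo/go otherwise;
        undefined on the first trial of each block.
    ``prev_correspondence``
        Correspondence of trial n-1 (undefined on first-of-block trials).
    ``prev_error``
        Whether trial n-1 ended in an error or miss by either member of the
        pair (the partner session supplies the co-agent's accuracy in joint
        sessions).
    ``is_go``
        Whether this trial required the perspective agent's response.
    """
    trials = session.trials if isinstance(session, Session) else session
    if agent_id is None:
        if not isinstance(session, Session):
            raise ValueError("agent_id is required when passing a bare frame")
        agent_id = session.agent_id

    idx = trials["trial_index"].to_numpy()
    if not np.all(np.diff(idx) > 0):
        raise ValueError("trials must be ordered by strictly increasing trial_index")

    own_side = agent_key_side(trials, agent_id)
    other_side = RIGHT if own_side == LEFT else LEFT
    required = trials["required_responder"].to_numpy()
    resp_side = np.where(required == agent_id, own_side, other_side)
    corr = np.where(trials["stimulus_side"].to_numpy() == resp_side, C, NC)

    is_go = required == agent_id
    first_of_block = trials["block"].ne(trials["block"].shift()).to_numpy()
    prev_required = np.roll(required, 1)
    transition = np.where(prev_required == agent_id, GO_GO, NOGO_GO)
    transition = np.where(first_of_block, UNDEFINED, transition).astype(object)
    prev_corr = np.where(first_of_block, UNDEFINED, np.roll(corr, 1)).astype(object)

    err_own = trials["accuracy"].isin(["error", "miss"]).to_numpy()
    err_any = err_own.copy()
    if partner is not None:
        ptrials = partner.trials if isinstance(partner, Session) else partner
        perr = (
            ptrials.set_index("trial_index")["accuracy"]
            .isin(["error", "miss"])
            .reindex(trials["trial_index"])
            .fillna(False)
            .to_numpy()
        )
        err_any |= perr
    prev_error = np.roll(err_any, 1)
    prev_error[0] = False
    prev_error = np.where(first_of_block, False, prev_error)

    coded = trials.copy()
    coded["correspondence"] = corr
    coded["transition"] = transition
    coded["prev_correspondence"] = prev_corr
    coded["prev_error"] = prev_error
    coded["is_go"] = is_go
    return coded


def filter_for_rt_analysis(coded: pd.DataFrame) -> pd.DataFrame:
    """Correct go-trial responses of the perspective agent only."""
    out = coded[coded["is_go"] & (coded["accuracy"] == "correct")]
    if out.empty:
        warnings.warn("no correct go responses retained", stacklevel=2)
    return out


def filter_for_sequential_analysis(coded: pd.DataFrame) -> pd.DataFrame:
    """Sequential-analysis filter.

    Drops, from the correct go trials: the first trial of each block, and
    trials whose immediately preceding trial (by either pair member) was an
    error or a miss.
    """
    keep = (
        coded["is_go"]
        & (coded["accuracy"] == "correct")
        & (coded["transition"] != UNDEFINED)
        & ~coded["prev_error"]
    )
    return coded[keep]


def tukey_error_outliers(
    error_counts: Sequence[float] | pd.Series, k: float = 1.5
) -> pd.Series:
    """Flag participants whose error counts fall outside the Tukey fences.

    Fences are Q1 - k*IQR and Q3 + k*IQR, quartiles by linear interpolation
    between order statistics.  Requires at least 4 participants.
    """
    counts = pd.Series(error_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("error counts must be >= 0")
    if len(counts) < 4:
        raise ValueError("need >= 4 participants for stable quartiles")
    q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
    iqr = q3 - q1
    return (counts > q3 + k * iqr) | (counts < q1 - k * iqr)


def excluded_pairs(
    error_counts: pd.DataFrame, k: float = 1.5, per_condition: bool = True
) -> list[str]:
    """Pair-level exclusion from per-participant error counts.

    ``error_counts`` has columns pair_id, agent_id, condition, n_errors.  A
    pair is excluded when either member is flagged in either condition
    (``per_condition=True``, the default) or on counts pooled over conditions.
    """
    flagged: set[str] = set()
    if per_condition:
        for _, grp in error_counts.groupby("condition"):
            flags = tukey_error_outliers(grp["n_errors"], k=k)
            flagged.update(grp.loc[flags.to_numpy(), "pair_id"])
    else:
        pooled = error_counts.groupby(["pair_id", "agent_id"], as_index=False)[
            "n_errors"
        ].sum()
        flags = tukey_error_outliers(pooled["n_errors"], k=k)
        flagged.update(pooled.loc[flags.to_numpy(), "pair_id"])
    return sorted(flagged)


def count_errors(session: Session) -> int:
    """Number of the agent's erroneous go trials (wrong responses + misses)."""
    t = session.trials
    go = t["required_responder"] == session.agent_id
    return int((go & t["accuracy"].isin(["error", "miss"])).sum())
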