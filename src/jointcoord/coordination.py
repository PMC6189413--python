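"""Inter-agent response coordination via instantaneous cross-correlation.

The coordination analysis asks whether two agents' trial-by-trial response
times co-fluctuate.  Each agent's RT series (go trials in collection order,
error/missing RTs imputed with the participant-condition mean, then centered
on that mean) is compared with the partner's at trial offsets ``lag_min`` to
``lag_max``.  At each time point and lag a *local* Pearson coefficient is
computed from first and second moments smoothed with a zero-phase (non-causal)
first-order exponential filter with smoothing factor ``eta``; the filter is a
forward recursion ``y[t] = eta*x[t] + (1-eta)*y[t-1]`` followed by the same
recursion run backward, whose combined impulse response is a two-sided
exponential of effective width ~ 2/eta - 1 trials.  The coordination index is
the proportion of valid (time, lag) cells whose local correlation exceeds a
threshold (r > 0.25 by default).  Pseudo-pairs — the two members of a pair
aligned over their parallel individual sessions — provide the no-interaction
baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .simulate import Session

#: local variance below this is treated as undefined (flat window)
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class CorrConfig:
    """Instantaneous cross-correlation settings.

    eta: smoothing factor in (0, 1]; small values average over many trials
    (conservative), eta = 1 disables smoothing entirely.
    lag_min, lag_max: trial offsets of the partner series, lag_min <= 0 <= lag_max.
    r_threshold: cutoff defining "correlated activity" for the index.
    absolute: count |r| > threshold instead of signed r > threshold.
    """

    eta: float = 0.1
    lag_min: int = -9
    lag_max: int = 9
    r_threshold: float = 0.25
    absolute: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must be in (0, 1]")
        if not self.lag_min <= 0 <= self.lag_max:
            raise ValueError("lag range must satisfy lag_min <= 0 <= lag_max")
        if not 0.0 <= self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in [0, 1)")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.lag_min, self.lag_max + 1)


@dataclass
class RTSeries:
    """Centered per-agent RT series over the agent's go trials."""

    agent_id: str
    condition: str
    values: np.ndarray
    imputed_mask: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class InstCorrMatrix:
    """Local correlation r(time, lag) with validity mask and its settings."""

    r: np.ndarray  # shape (n_time, n_lags); NaN where invalid
    valid: np.ndarray  # bool, same shape
    lags: np.ndarray
    config: CorrConfig

    def to_frame(self) -> pd.DataFrame:
        t, l = np.meshgrid(np.arange(self.r.shape[0]), self.lags, indexing="ij")
        return pd.DataFrame(
            {
                "time": t.ravel(),
                "lag": l.ravel(),
                "r": self.r.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def build_rt_series(session: Session, agent_id: str | None = None) -> RTSeries:
    """RT series of one agent: ordered go trials, imputed and mean-centered.

    Missing and incorrect RTs are substituted by the mean of the agent's
    correct RTs in this session (their condition), and that same mean is then
    subtracted from every point, so imputed points sit exactly at zero and the
    series mean is zero.
    """
    agent_id = agent_id or session.agent_id
    t = session.trials
    go = t[t["required_responder"] == agent_id].sort_values("trial_index")
    correct = go["accuracy"] == "correct"
    if not correct.any():
        raise ValueError(
            f"agent {agent_id!r} has no correct responses; nothing to impute from"
        )
    mean_rt = go.loc[correct, "rt_ms"].mean()
    values = go["rt_ms"].where(correct, mean_rt).to_numpy(dtype=float) - mean_rt
    return RTSeries(
        agent_id=agent_id,
        condition=str(go["condition"].iloc[0]),
        values=values,
        imputed_mask=(~correct).to_numpy(),
    )


def smooth_noncausal(series: Sequence[float] | np.ndarray, eta: float) -> np.ndarray:
    """Zero-phase first-order exponential smoothing.

    Forward pass ``y[t] = eta*x[t] + (1-eta)*y[t-1]`` (initialized at
    ``y[0] = x[0]``, which preserves constants exactly), then the same
    recursion run backward over the forward output.  ``eta = 1`` returns the
    input unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if not 0.0 < eta <= 1.0:
        raise ValueError("eta must be in (0, 1]")
    if eta == 1.0:
        return x.copy()
    fwd = _ewma(x, eta)
    return _ewma(fwd[::-1], eta)[::-1]


def _ewma(x: np.ndarray, eta: float) -> np.ndarray:
    a = 1.0 - eta
    zi = np.array([a * x[0]])  # makes y[0] = eta*x[0] + a*x[0] = x[0]
    y, _ = lfilter([eta], [1.0, -a], x, zi=zi)
    return y


def instantaneous_crosscorr(
    x: RTSeries | np.ndarray,
    y: RTSeries | np.ndarray,
    config: CorrConfig | None = None,
) -> InstCorrMatrix:
    """Time- and lag-resolved local Pearson correlation of two series.

    For each lag d the lagged pair (x[t], y[t+d]) is formed over the index
    range where both exist; local means of x, y, x^2, y^2 and x*y over that
    segment are obtained with :func:`smooth_noncausal` and combined into

        r(t, d) = (<xy> - <x><y>) / sqrt((<x^2> - <x>^2) (<y^2> - <y>^2))

    Cells with near-zero local variance or an out-of-range partner index are
    marked invalid; r is clipped to [-1, 1] against floating-point overshoot.
    Row index is the time point in ``x``.
    """
    config = config or CorrConfig()
    xv = x.values if isinstance(x, RTSeries) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, RTSeries) else np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        warnings.warn(
            f"series lengths differ ({len(xv)} vs {len(yv)}); truncating to the shorter",
            stacklevel=2,
        )
        n = min(len(xv), len(yv))
        xv, yv = xv[:n], yv[:n]
    n = len(xv)
    lags = config.lags
    if n < (config.lag_max - config.lag_min + 2):
        raise ValueError(
            f"series of length {n} too short for lag range "
            f"[{config.lag_min}, {config.lag_max}]"
        )
    r = np.full((n, len(lags)), np.nan)
    valid = np.zeros((n, len(lags)), dtype=bool)
    for j, d in enumerate(lags):
        if d >= 0:
            a, b = xv[: n - d], yv[d:]
            t0 = 0
        else:
            a, b = xv[-d:], yv[: n + d]
            t0 = -d
        if a.size < 2:
            continue
        ma = smooth_noncausal(a, config.eta)
        mb = smooth_noncausal(b, config.eta)
        maa = smooth_noncausal(a * a, config.eta)
        mbb = smooth_noncausal(b * b, config.eta)
        mab = smooth_noncausal(a * b, config.eta)
        va = maa - ma * ma
        vb = mbb - mb * mb
        ok = (va > _VAR_EPS) & (vb > _VAR_EPS)
        rj = np.full(a.size, np.nan)
        rj[ok] = np.clip(
            (mab[ok] - ma[ok] * mb[ok]) / np.sqrt(va[ok] * vb[ok]), -1.0, 1.0
        )
        r[t0 : t0 + a.size, j] = rj
        valid[t0 : t0 + a.size, j] = ok
    return InstCorrMatrix(r=r, valid=valid, lags=lags, config=config)


def coordination_index(m: InstCorrMatrix) -> float:
    """Proportion of valid (time, lag) cells with r above the threshold.

    Signed comparison (r > threshold) by default; set ``absolute=True`` in the
    matrix's :class:`CorrConfig` to count |r| > threshold.  Returned in
    [0, 1]; multiply by 100 for the percentage reported in outputs.
    """
    if not m.valid.any():
        raise ValueError("no valid cells in correlation matrix")
    vals = m.r[m.valid]
    if m.config.absolute:
        vals = np.abs(vals)
    return float(np.mean(vals > m.config.r_threshold))


def pair_coordination(
    sess_a: Session, sess_b: Session, config: CorrConfig | None = None
) -> float:
    """Coordination index of two agents' sessions (series built on the fly)."""
    m = instantaneous_crosscorr(
        build_rt_series(sess_a), build_rt_series(sess_b), config
    )
    return coordination_index(m)


def make_pseudo_pairs(
    individual_sessions: Iterable[Session],
) -> list[tuple[RTSeries, RTSeries]]:
    """Pair the members who performed individual sessions in parallel.

    Sessions are grouped by ``pair_id`` (the pairing that later did the joint
    session); each group must contain exactly two individual sessions.  Series
    are aligned by ordinal go-trial index; lengths differing by more than 10%
    draw a warning before truncation to the shorter.
    """
    groups: dict[str, list[Session]] = {}
    for s in individual_sessions:
        if s.condition != "individual":
            raise ValueError(f"session {s.agent_id!r} is not an individual session")
        groups.setdefault(s.pair_id, []).append(s)
    odd = [pid for pid, members in groups.items() if len(members) != 2]
    if odd:
        raise ValueError(
            f"pair(s) {odd} do not have exactly two individual sessions; "
            "pairing metadata incomplete"
        )
    out = []
    for pid in sorted(groups):
        sa, sb = sorted(groups[pid], key=lambda s: s.agent_id)
        ra, rb = build_rt_series(sa), build_rt_series(sb)
        if min(len(ra), len(rb)) < 0.9 * max(len(ra), len(rb)):
            warnings.warn(
                f"pseudo-pair {pid}: series lengths differ by more than 10% "
                f"({len(ra)} vs {len(rb)}); truncating to the shorter",
                stacklevel=2,
            )
        out.append((ra, rb))
    return out
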