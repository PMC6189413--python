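"""Synthetic dyadic go/no-go Simon sessions.

Generates trial-level logs for pairs of agents performing a go/no-go Simon
task, either alone (individual sessions, run in parallel rooms) or
side-by-side (joint sessions over a single shared stimulus schedule).  Every
downstream stage of the analysis pipeline — correspondence/transition coding,
effect tables, instantaneous cross-correlation — can be validated against the
ground truth this module records.

Reaction-time model for a go trial ``t`` of agent ``a``::

    RT = mu + (beta/2) * s(t) + seq(t) + z_a(t) + eps,   eps ~ N(0, sigma_rt)

where ``s(t)`` is +1 on non-corresponding and -1 on corresponding trials (so
the non-corresponding minus corresponding contrast recovers ``beta`` and the
grand mean stays at ``mu``), ``seq(t)`` is a conflict-adaptation term driven
by the correspondence of trial ``t-1``, and ``z_a(t)`` is a slow AR(1)
fluctuation.  Inter-agent coupling is carried by sharing a fraction of the
latent process: ``z_a = sqrt(c) * u + sqrt(1-c) * v_a`` with ``u`` common to
the pair and ``v_a`` private, all stationary AR(1) with SD ``sigma_latent``.
The latent processes are indexed over the full pair schedule so that coupling
survives the go-trial subsetting performed by the coordination analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

LEFT = "left"
RIGHT = "right"
INDIVIDUAL = "individual"
JOINT = "joint"
CONDITIONS = (INDIVIDUAL, JOINT)
DESIGNS = ("cooperative", "competitive")

#: seat / response-key side of agent slot 0 and 1 within a pair
AGENT_SIDES = (LEFT, RIGHT)
#: stimulus color assigned to agent slot 0 and 1
AGENT_COLORS = ("green", "red")


class ConfigError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the dyad simulator.

    All time quantities are in milliseconds.

    Parameters
    ----------
    n_blocks, trials_per_block
        Session structure; defaults give 384 trials in 4 blocks of 96.
    p_corresponding
        Fraction of corresponding trials; balanced exactly per block and per
        responder, not Bernoulli.
    mu_rt
        Baseline mean RT, a scalar applied to both agents or a pair.
    sigma_rt
        SD of the independent trial-level noise.
    beta_simon
        Correspondence effect: mean(non-corresponding) - mean(corresponding).
    lambda_seq, lambda_seq_rev
        Sequential-modulation amplitudes: the correspondence effect becomes
        ``beta + lambda_seq`` after a corresponding trial and
        ``beta - lambda_seq_rev`` after a non-corresponding trial.
        ``lambda_seq_rev=None`` means symmetric (equal to ``lambda_seq``).
    seq_transition_gate
        When true (default), sequential modulation applies only when the
        previous trial required the other agent's response (Nogo/go
        transitions), the pattern seen in go/no-go Simon data.
    phi, sigma_latent
        AR(1) coefficient and stationary SD of the latent fluctuation.
    coupling
        Share of latent variance common to both agents, in [0, 1].
    p_error
        Pooled probability that a go trial becomes a wrong response or a
        miss (split evenly between the two, recorded separately in the
        ground truth).
    rt_floor
        Lower clip for generated RTs.
    seed
        Root seed; batch runs derive per-pair child seeds from it.
    """

    n_blocks: int = 4
    trials_per_block: int = 96
    p_corresponding: float = 0.5
    mu_rt: float | tuple[float, float] = 325.0
    sigma_rt: float = 32.0
    beta_simon: float = 10.0
    lambda_seq: float = 14.0
    lambda_seq_rev: float | None = 19.0
    seq_transition_gate: bool = True
    phi: float = 0.9
    sigma_latent: float = 18.0
    coupling: float = 0.0
    p_error: float = 0.005
    rt_floor: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_corresponding <= 1.0:
            raise ConfigError("p_corresponding must be in [0, 1]")
        if not 0.0 <= self.p_error <= 1.0:
            raise ConfigError("p_error must be in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must be in [0, 1]")
        if not 0.0 <= self.phi < 1.0:
            raise ConfigError("phi must be in [0, 1)")
        if self.sigma_rt < 0 or self.sigma_latent < 0:
            raise ConfigError("sigma values must be >= 0")
        if self.rt_floor <= 0:
            raise ConfigError("rt_floor must be > 0")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigError("n_blocks and trials_per_block must be >= 1")
        if (self.n_blocks * self.trials_per_block) % 2:
            raise ConfigError("total trial count must be even")
        n_go = self.trials_per_block / 2.0
        if abs(self.p_corresponding * n_go - round(self.p_corresponding * n_go)) > 1e-9:
            raise ConfigError(
                "p_corresponding must yield an integer number of corresponding "
                "go trials per agent per block"
            )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def mu_for(self, slot: int) -> float:
        if isinstance(self.mu_rt, (tuple, list)):
            return float(self.mu_rt[slot])
        return float(self.mu_rt)

    @property
    def lambda_rev(self) -> float:
        return self.lambda_seq if self.lambda_seq_rev is None else self.lambda_seq_rev


@dataclass
class Session:
    """Ordered trials of one session from one agent's perspective.

    ``trials`` has one row per trial of the full schedule (go and no-go alike)
    in the trial-log dialect: pair_id, agent_id, condition, design, block,
    trial_index, stimulus_side, stimulus_color, required_responder,
    response_side, rt_ms, accuracy.
    """

    pair_id: str
    agent_id: str
    condition: str
    trials: pd.DataFrame
    design: str = "cooperative"

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class GroundTruth:
    """Per-trial latent state and injected parameters, aligned with trials."""

    latent: pd.DataFrame  # trial_index, shared, z_a, z_b
    beta_simon: float
    coupling: float
    lambda_seq: float
    lambda_seq_rev: float
    error_flags: dict[str, np.ndarray]  # agent_id -> bool over own go trials
    miss_flags: dict[str, np.ndarray]


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) path: x[t] = phi x[t-1] + e[t], SD(x) = sigma."""
    if sigma == 0.0:
        return np.zeros(n)
    e = rng.normal(0.0, sigma * math.sqrt(1.0 - phi * phi), size=n)
    e[0] = rng.normal(0.0, sigma)  # stationary start
    return lfilter([1.0], [1.0, -phi], e)


def _schedule(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    """Balanced stimulus schedule: responder slot and correspondence per trial.

    Each block contains trials_per_block/2 go trials per agent, of which an
    exact p_corresponding fraction is corresponding (fixed multiset, shuffled).
    """
    n_go = cfg.trials_per_block // 2
    n_c = round(cfg.p_corresponding * n_go)
    block_resp = np.repeat([0, 1], n_go)
    block_corr = np.tile(
        np.concatenate([np.ones(n_c, bool), np.zeros(n_go - n_c, bool)]), 2
    )
    responder = np.empty(cfg.n_trials, dtype=int)
    corresponding = np.empty(cfg.n_trials, dtype=bool)
    for b in range(cfg.n_blocks):
        order = rng.permutation(cfg.trials_per_block)
        sl = slice(b * cfg.trials_per_block, (b + 1) * cfg.trials_per_block)
        responder[sl] = block_resp[order]
        corresponding[sl] = block_corr[order]
    side = np.where(
        corresponding,
        np.asarray(AGENT_SIDES)[responder],
        np.asarray(AGENT_SIDES)[1 - responder],
    )
    return pd.DataFrame(
        {
            "block": np.repeat(np.arange(1, cfg.n_blocks + 1), cfg.trials_per_block),
            "trial_index": np.arange(1, cfg.n_trials + 1),
            "responder_slot": responder,
            "corresponding": corresponding,
            "stimulus_side": side,
            "stimulus_color": np.asarray(AGENT_COLORS)[responder],
        }
    )


def _agent_frame(
    cfg: SimConfig,
    rng: np.random.Generator,
    sched: pd.DataFrame,
    z: np.ndarray,
    slot: int,
    pair_id: str,
    agent_id: str,
    co_agent_id: str,
    condition: str,
    design: str,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Emit one agent's 384-row log over a schedule, plus error/miss flags."""
    n = len(sched)
    responder = sched["responder_slot"].to_numpy()
    corr = sched["corresponding"].to_numpy()
    go = responder == slot
    s = np.where(corr, -1.0, 1.0)  # +1 NC, -1 C

    seq = np.zeros(n)
    prev_corr = np.roll(corr, 1)
    prev_resp = np.roll(responder, 1)
    has_prev = np.arange(n) > 0
    gate = has_prev if not cfg.seq_transition_gate else has_prev & (prev_resp != slot)
    seq = np.where(
        gate & prev_corr, (cfg.lambda_seq / 2.0) * s, seq
    )
    seq = np.where(
        gate & ~prev_corr & has_prev, -(cfg.lambda_rev / 2.0) * s, seq
    )

    mu = cfg.mu_for(slot)
    eps = rng.normal(0.0, cfg.sigma_rt, size=n)
    rt = mu + (cfg.beta_simon / 2.0) * s + seq + z + eps
    rt = np.maximum(rt, cfg.rt_floor)

    n_go = int(go.sum())
    err = rng.random(n_go) < cfg.p_error
    is_miss = err & (rng.random(n_go) < 0.5)
    is_wrong = err & ~is_miss

    accuracy = np.full(n, "correct", dtype=object)
    response_side = np.full(n, "none", dtype=object)
    rt_ms = np.full(n, np.nan)
    go_idx = np.flatnonzero(go)
    own_side = AGENT_SIDES[slot]
    response_side[go_idx] = own_side
    rt_ms[go_idx] = rt[go_idx]
    accuracy[go_idx[is_wrong]] = "error"
    accuracy[go_idx[is_miss]] = "miss"
    response_side[go_idx[is_miss]] = "none"
    rt_ms[go_idx[is_miss]] = np.nan

    agent_names = {slot: agent_id, 1 - slot: co_agent_id}
    frame = pd.DataFrame(
        {
            "pair_id": pair_id,
            "agent_id": agent_id,
            "condition": condition,
            "design": design,
            "block": sched["block"].to_numpy(),
            "trial_index": sched["trial_index"].to_numpy(),
            "stimulus_side": sched["stimulus_side"].to_numpy(),
            "stimulus_color": sched["stimulus_color"].to_numpy(),
            "required_responder": [agent_names[r] for r in responder],
            "response_side": response_side,
            "rt_ms": np.round(rt_ms, 6),
            "accuracy": accuracy,
        }
    )
    return frame, err, is_miss


def generate_pair_session(
    config: SimConfig,
    condition: str,
    *,
    pair_id: str = "p00",
    design: str = "cooperative",
    rng: np.random.Generator | None = None,
) -> tuple[Session, Session, GroundTruth]:
    """Generate one session (both agents) of one pair.

    In the joint condition the two agents share a single stimulus schedule and
    a ``coupling`` fraction of latent variance; in the individual condition
    each agent gets an independent schedule and coupling is forced to zero
    (the two members only performed in parallel rooms).
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    agent_a, agent_b = f"{pair_id}_a", f"{pair_id}_b"

    coupling = config.coupling if condition == JOINT else 0.0
    shared = _ar1(rng, config.n_trials, config.phi, config.sigma_latent)
    z = []
    for _ in range(2):
        private = _ar1(rng, config.n_trials, config.phi, config.sigma_latent)
        z.append(
            math.sqrt(coupling) * shared + math.sqrt(1.0 - coupling) * private
        )

    if condition == JOINT:
        sched_a = sched_b = _schedule(rng, config)
    else:
        sched_a = _schedule(rng, config)
        sched_b = _schedule(rng, config)

    frame_a, err_a, miss_a = _agent_frame(
        config, rng, sched_a, z[0], 0, pair_id, agent_a, agent_b, condition, design
    )
    frame_b, err_b, miss_b = _agent_frame(
        config, rng, sched_b, z[1], 1, pair_id, agent_b, agent_a, condition, design
    )
    truth = GroundTruth(
        latent=pd.DataFrame(
            {
                "trial_index": np.arange(1, config.n_trials + 1),
                "shared": shared,
                "z_a": z[0],
                "z_b": z[1],
            }
        ),
        beta_simon=config.beta_simon,
        coupling=coupling,
        lambda_seq=config.lambda_seq,
        lambda_seq_rev=config.lambda_rev,
        error_flags={agent_a: err_a, agent_b: err_b},
        miss_flags={agent_a: miss_a, agent_b: miss_b},
    )
    sess_a = Session(pair_id, agent_a, condition, frame_a, design)
    sess_b = Session(pair_id, agent_b, condition, frame_b, design)
    return sess_a, sess_b, truth


#: per-condition parameter presets mimicking the two social contexts:
#: cooperation yields a joint-only Simon effect and coupled responding;
#: competition yields a small context-independent effect, no coupling, and
#: an overall speed-up in the joint session.
DESIGN_PRESETS = {
    "cooperative": {
        INDIVIDUAL: {"beta_simon": 2.0, "coupling": 0.0},
        JOINT: {"beta_simon": 10.0, "coupling": 0.8},
    },
    "competitive": {
        INDIVIDUAL: {"beta_simon": 5.0, "coupling": 0.0},
        JOINT: {"beta_simon": 4.0, "coupling": 0.0, "mu_shift": -34.0},
    },
}


@dataclass
class Experiment:
    """A batch of pairs, each with an individual and a joint session."""

    design: str
    config: SimConfig
    sessions: list[Session]
    truths: dict[tuple[str, str], GroundTruth] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Concatenate all sessions into one trial-log table."""
        return pd.concat([s.trials for s in self.sessions], ignore_index=True)

    def pair_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.pair_id, None)
        return list(seen)


def _preset_config(config: SimConfig, design: str, condition: str) -> SimConfig:
    preset = dict(DESIGN_PRESETS[design][condition])
    shift = preset.pop("mu_shift", 0.0)
    if shift:
        mu = config.mu_rt
        if isinstance(mu, (tuple, list)):
            mu = tuple(m + shift for m in mu)
        else:
            mu = mu + shift
        preset["mu_rt"] = mu
    return replace(config, **preset)


def generate_experiment(
    config: SimConfig, n_pairs: int, design: str = "cooperative"
) -> Experiment:
    """Generate ``n_pairs`` pairs, each with individual and joint sessions.

    ``design`` switches the per-condition Simon-effect and coupling presets
    (see :data:`DESIGN_PRESETS`); all other parameters come from ``config``.
    Child RNG streams are spawned deterministically from ``config.seed`` via
    ``numpy.random.SeedSequence(seed).spawn`` — one child per pair, split
    again per condition — so batch output is reproducible and pairs are
    independent.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    if design not in DESIGN_PRESETS:
        raise ConfigError(f"design must be one of {tuple(DESIGN_PRESETS)}")
    root = np.random.SeedSequence(config.seed)
    sessions: list[Session] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    width = max(2, len(str(n_pairs - 1)))
    for i, pair_ss in enumerate(root.spawn(n_pairs)):
        pair_id = f"p{i:0{width}d}"
        cond_ss = pair_ss.spawn(2)
        for condition, ss in zip((INDIVIDUAL, JOINT), cond_ss):
            cfg = _preset_config(config, design, condition)
            rng = np.random.default_rng(ss)
            a, b, truth = generate_pair_session(
                cfg, condition, pair_id=pair_id, design=design, rng=rng
            )
            sessions.extend([a, b])
            truths[(pair_id, condition)] = truth
    return Experiment(design=design, config=config, sessions=sessions, truths=truths)
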