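"""Synthetic trial streams with planted mode-locking structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage is testable without human data and parameter
recovery can be asserted end to end.  It plants exactly the two
relationships the statistics test:

* response times follow the Devil's staircase: for each trial the drive
  value of the depth-5 stimulus window ending at that trial is mapped
  through the staircase, rt = rt_intercept + rt_slope * rho(omega) +
  Gaussian(0, rt_sd), clipped to rt_bounds (clipping, not resampling, so
  downstream censorship is exercised);
* error probability grows with the Farey denominator on the log-odds
  scale: p_err = logistic(logit(error_base) + error_denom_slope * (q - 2)),
  the offset of 2 centring the model at the root ratio 1/2.

Stimulus schedules are balanced (independent fair R/L draws) or biased:
``repetition_biased`` repeats the previous stimulus with probability
``bias`` (default 2/3), ``alternation_biased`` alternates with that
probability; the first trial is always a fair draw.

Windows are classified by stimulus identity, matching the scanner; windows
starting with L use the wrapped L-leading drive value; the first depth-1
trials, which have no full window, use the root drive 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dynamics import Staircase, devils_staircase
from .farey import FareyTree, build_tree, history_omega
from .scan import analyze_streams
from .stats import denominator_regression, spearman_farey_test, staircase_test

__all__ = ["GeneratorConfig", "generate_schedule", "generate_responses",
           "generate_streams", "recovery_suite"]

HISTORY_DEPTH = 5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults give 8 participants of 4,000 trials with RTs spanning roughly
    450-650 ms (intercept 450 ms, 200 ms per unit rotation number, 30 ms
    trial noise) inside 200-980 ms bounds, a 4% baseline error rate rising
    with ratio denominator, and a 2/3 bias for the biased schedules.
    """

    n_participants: int = 8
    n_trials: int = 4000
    schedule: str = "balanced"  # balanced | repetition_biased | alternation_biased
    bias: float = 2.0 / 3.0
    rt_intercept: float = 450.0
    rt_slope: float = 200.0
    rt_sd: float = 30.0
    error_base: float = 0.04
    error_denom_slope: float = 0.12
    rt_bounds: tuple[float, float] = (200.0, 980.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule not in ("balanced", "repetition_biased", "alternation_biased"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if not 0.0 <= self.bias <= 1.0:
            raise ValueError("bias must lie in [0, 1]")
        if not 0.0 <= self.error_base < 1.0:
            raise ValueError("error_base must lie in [0, 1)")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be >= 0")
        if self.n_trials < HISTORY_DEPTH:
            raise ValueError(f"n_trials must be >= {HISTORY_DEPTH}")
        if not self.rt_bounds[0] < self.rt_bounds[1]:
            raise ValueError("rt_bounds must satisfy low < high")


def generate_schedule(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """One participant's stimulus sequence as an array of 'R'/'L'."""
    n = config.n_trials
    u = rng.random(n)
    stim = np.empty(n, dtype="<U1")
    stim[0] = "R" if u[0] < 0.5 else "L"
    if config.schedule == "balanced":
        stim[1:] = np.where(u[1:] < 0.5, "R", "L")
    else:
        repeat = u[1:] < config.bias
        if config.schedule == "alternation_biased":
            repeat = ~repeat
        flip = {"R": "L", "L": "R"}
        for t in range(1, n):
            prev = stim[t - 1]
            stim[t] = prev if repeat[t - 1] else flip[prev]
    return stim


def _window_tables(
    staircase: Staircase, tree: FareyTree
) -> tuple[dict[str, float], dict[str, int]]:
    """Per depth-5 window: planted rho and Farey denominator.

    R-leading windows are level-5 tree nodes; L-leading windows use the
    wrapped L-leading drive and the denominator of the letter-swapped
    R-leading complement's reciprocal (i.e. that complement's numerator).
    """
    from .farey import l_leading_ratio, swap_letters

    rho_of: dict[str, float] = {}
    denom_of: dict[str, int] = {}
    for node in tree.nodes:
        if node.level != HISTORY_DEPTH:
            continue
        rho_of[node.history] = float(staircase.lookup(node.omega))
        denom_of[node.history] = node.ratio.denominator
        lh = swap_letters(node.history)
        rho_of[lh] = float(staircase.lookup(history_omega(lh)))
        denom_of[lh] = l_leading_ratio(lh).denominator
    return rho_of, denom_of


def generate_responses(
    schedule: np.ndarray,
    config: GeneratorConfig,
    staircase: Staircase,
    tree: FareyTree,
    rng: np.random.Generator,
    participant: str = "p01",
) -> pd.DataFrame:
    """One participant's trial stream from a stimulus schedule."""
    n = schedule.size
    rho_of, denom_of = _window_tables(staircase, tree)
    root_rho = float(staircase.lookup(0.5))

    rho = np.full(n, root_rho)
    denom = np.full(n, 2, dtype=int)
    joined = "".join(schedule)
    for t in range(HISTORY_DEPTH - 1, n):
        window = joined[t - HISTORY_DEPTH + 1 : t + 1]
        rho[t] = rho_of[window]
        denom[t] = denom_of[window]

    rt = config.rt_intercept + config.rt_slope * rho
    if config.rt_sd > 0:
        rt = rt + rng.normal(0.0, config.rt_sd, size=n)
    rt = np.clip(rt, *config.rt_bounds)

    if config.error_base == 0.0:
        p_err = np.zeros(n)
    else:
        logit = np.log(config.error_base / (1.0 - config.error_base))
        logit = logit + config.error_denom_slope * (denom - 2)
        p_err = 1.0 / (1.0 + np.exp(-logit))
    errors = rng.random(n) < p_err
    flip = {"R": "L", "L": "R"}
    response = np.array(
        [flip[s] if e else s for s, e in zip(schedule, errors)], dtype="<U1"
    )
    return pd.DataFrame(
        {
            "participant": participant,
            "trial": np.arange(n),
            "stimulus": schedule,
            "response": response,
            "correct": (~errors).astype(int),
            "rt_ms": rt,
        }
    )


def generate_streams(
    config: GeneratorConfig,
    staircase: Staircase | None = None,
    tree: FareyTree | None = None,
) -> pd.DataFrame:
    """Full multi-participant stream; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tree = build_tree(HISTORY_DEPTH) if tree is None else tree
    if staircase is None:
        staircase = devils_staircase(rng=rng)
    frames = []
    for i in range(config.n_participants):
        schedule = generate_schedule(config, rng)
        frames.append(
            generate_responses(
                schedule, config, staircase, tree, rng, participant=f"p{i + 1:02d}"
            )
        )
    return pd.concat(frames, ignore_index=True)


def recovery_suite(
    config: GeneratorConfig | None = None,
    staircase: Staircase | None = None,
    tree: FareyTree | None = None,
) -> dict:
    """Generate -> scan -> stats; report whether the planted structure is
    recovered (staircase r^2, Farey-rank Spearman rho, denominator slope)."""
    config = GeneratorConfig() if config is None else config
    tree = build_tree(HISTORY_DEPTH) if tree is None else tree
    if staircase is None:
        staircase = devils_staircase(rng=np.random.default_rng(config.seed))
    streams = generate_streams(config, staircase=staircase, tree=tree)
    _, grand = analyze_streams(streams, depth=HISTORY_DEPTH)
    norm_means = grand.set_index("history")["norm_mean"]
    error_rates = grand.set_index("history")["error_rate"]
    st = staircase_test(norm_means, staircase, tree)
    sp = spearman_farey_test(error_rates, tree)
    slope, dr = denominator_regression(error_rates, tree)
    return {
        "config": asdict(config),
        "staircase_r2": st.r2,
        "staircase_report": st,
        "spearman_rho": sp.r,
        "spearman_report": sp,
        "denominator_slope": slope,
        "denominator_report": dr,
        "recovered": bool(st.r2 >= 0.6 and slope > 0),
    }
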