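"""Overlapping trial-history scanning and per-history statistics.

A trial stream is one row per trial (participant, trial index, stimulus
R/L, response R/L, correctness, response time in ms).  Every trial serves
as a potential origin of every history it begins, so occurrences of a
length-k history are *overlapping* windows: six correct R trials contain
six "R", five "RR", four "RRR", three "RRRR" and two "RRRRR" occurrences.

Windows are classified by STIMULUS identity (the response the stimulus
demands), never by the registered response — otherwise erroneous trials
could not belong to a named sequence type.  Correctness and response-time
censorship act as separate validity filters:

* a window contributes to the mean RT only if every member trial is
  correct and every member RT lies inside the censorship bounds
  (default 200-980 ms);
* the unique-error rate divides the number of *distinct* erroneous member
  trials by the member observations counted with multiplicity
  (|history| x n_occurrences), e.g. 56 unique errors over 185 length-5
  windows gives 56 / 925 = 0.0605.

Per-participant history means are unit-normalized, (mean - min)/(max - min)
over the participant's histories, before averaging across participants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .farey import FareyTree, build_tree, history_omega, l_leading_ratio, swap_letters

__all__ = [
    "SequenceOccurrence",
    "DegenerateRangeError",
    "DEFAULT_BOUNDS",
    "find_occurrences",
    "history_mean_rt",
    "unique_error_rate",
    "unit_normalize",
    "analyze_streams",
]

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = (200.0, 980.0)

STREAM_COLUMNS = ["participant", "trial", "stimulus", "response", "correct", "rt_ms"]


class DegenerateRangeError(ValueError):
    """Unit normalization of an all-equal set of means (zero range)."""


@dataclass(frozen=True)
class SequenceOccurrence:
    history: str
    start_index: int
    member_indices: tuple[int, ...]
    all_correct: bool
    all_in_bounds: bool


def _participant_arrays(stream: pd.DataFrame):
    """Validate one participant's stream and unpack to numpy arrays."""
    idx = stream["trial"].to_numpy()
    if idx.size and np.any(np.diff(idx) != 1):
        raise ValueError("trial indices must be consecutive within participant")
    stim = stream["stimulus"].to_numpy()
    correct = stream["correct"].to_numpy().astype(bool)
    rt = stream["rt_ms"].to_numpy(dtype=float)
    return idx, stim, correct, rt


def _window_starts(stim: np.ndarray, history: str) -> np.ndarray:
    """Start offsets (0-based positions) of all windows matching ``history``."""
    k = len(history)
    if stim.size < k:
        return np.empty(0, dtype=int)
    pattern = np.frombuffer(history.encode(), dtype=np.uint8)
    codes = stim.astype("S1").view(np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return np.nonzero((windows == pattern).all(axis=1))[0]


def _window_all(flags: np.ndarray, k: int) -> np.ndarray:
    """For each window start, whether all k member flags are True."""
    if flags.size < k:
        return np.empty(0, dtype=bool)
    return np.lib.stride_tricks.sliding_window_view(flags, k).all(axis=1)


def find_occurrences(
    stream: pd.DataFrame,
    history: str,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> list[SequenceOccurrence]:
    """All overlapping windows of one participant's stream whose stimulus
    sequence equals ``history``; correctness/censorship flags attached but
    not filtered here."""
    if not history or set(history) - {"R", "L"}:
        raise ValueError(f"invalid history {history!r}")
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    idx, stim, correct, rt = _participant_arrays(stream)
    k = len(history)
    starts = _window_starts(stim, history)
    in_bounds = (rt >= low) & (rt <= high)
    w_correct = _window_all(correct, k)
    w_bounds = _window_all(in_bounds, k)
    base = int(idx[0]) if idx.size else 0
    return [
        SequenceOccurrence(
            history=history,
            start_index=base + int(s),
            member_indices=tuple(range(base + int(s), base + int(s) + k)),
            all_correct=bool(w_correct[s]),
            all_in_bounds=bool(w_bounds[s]),
        )
        for s in starts
    ]


def _history_row(
    stim: np.ndarray,
    correct: np.ndarray,
    rt: np.ndarray,
    history: str,
    bounds: tuple[float, float],
    mode: str,
) -> dict:
    """Scan one participant's arrays for one history (vectorised core)."""
    k = len(history)
    low, high = bounds
    starts = _window_starts(stim, history)
    n_occ = starts.size
    row = {
        "history": history,
        "n_occurrences": int(n_occ),
        "n_valid": 0,
        "mean_rt": np.nan,
        "member_obs": int(k * n_occ),
        "unique_errors": 0,
        "error_rate": np.nan,
    }
    if n_occ == 0:
        return row
    valid = (
        _window_all(correct, k)[starts]
        & _window_all((rt >= low) & (rt <= high), k)[starts]
    )
    n_valid = int(valid.sum())
    row["n_valid"] = n_valid
    if n_valid:
        vstarts = starts[valid]
        if mode == "terminal":
            row["mean_rt"] = float(rt[vstarts + k - 1].mean())
        else:  # every member RT, with multiplicity
            members = (vstarts[:, None] + np.arange(k)).ravel()
            row["mean_rt"] = float(rt[members].mean())
    member_idx = np.unique((starts[:, None] + np.arange(k)).ravel())
    unique_errors = int((~correct[member_idx]).sum())
    row["unique_errors"] = unique_errors
    row["error_rate"] = unique_errors / row["member_obs"]
    return row


def history_mean_rt(
    stream: pd.DataFrame,
    history: str,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    mode: str = "terminal",
) -> tuple[float, int]:
    """Mean RT over valid occurrences (every member correct and censored-in).

    ``mode="terminal"`` averages the final member's RT of each valid window
    (conditioning trial-n latency on its history); ``mode="all"`` averages
    every member RT with multiplicity.  Returns (mean, n_valid); the mean is
    NaN — never zero — when no window survives the filters.
    """
    if mode not in ("terminal", "all"):
        raise ValueError(f"mode must be 'terminal' or 'all', got {mode!r}")
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    _, stim, correct, rt = _participant_arrays(stream)
    row = _history_row(stim, correct, rt, history, bounds, mode)
    return row["mean_rt"], row["n_valid"]


def unique_error_rate(stream: pd.DataFrame, history: str) -> dict:
    """Unique-error accounting for one history in one participant's stream.

    member_obs counts members with multiplicity (|history| x n_occurrences);
    unique_errors counts distinct erroneous trials belonging to at least one
    occurrence; error_rate is their quotient (NaN when no occurrence).
    """
    _, stim, correct, rt = _participant_arrays(stream)
    row = _history_row(stim, correct, rt, history, DEFAULT_BOUNDS, "terminal")
    return {
        "n_occurrences": row["n_occurrences"],
        "member_obs": row["member_obs"],
        "unique_errors": row["unique_errors"],
        "error_rate": row["error_rate"],
    }


def unit_normalize(means) -> np.ndarray | pd.Series:
    """(x - min) / (max - min) over the non-missing entries.

    Missing entries stay missing; fewer than two non-missing values or an
    all-equal set raises ``DegenerateRangeError``.
    """
    is_series = isinstance(means, pd.Series)
    values = means.to_numpy(dtype=float) if is_series else np.asarray(means, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise DegenerateRangeError("need at least two non-missing means")
    lo = values[finite].min()
    hi = values[finite].max()
    if hi == lo:
        raise DegenerateRangeError("all means equal: zero range")
    out = (values - lo) / (hi - lo)
    if is_series:
        return pd.Series(out, index=means.index)
    return out


def _target_histories(tree: FareyTree, l_leading: bool) -> list[tuple[str, object]]:
    """(history, ratio) pairs to scan: the R-leading tree and, optionally,
    the letter-swapped L-leading complements."""
    targets = [(n.history, n.ratio) for n in tree.nodes]
    if l_leading:
        targets += [
            (swap_letters(n.history), l_leading_ratio(swap_letters(n.history)))
            for n in tree.nodes
        ]
    return targets


def analyze_streams(
    streams: pd.DataFrame,
    depth: int = 5,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    mode: str = "terminal",
    l_leading: bool = False,
    tree: FareyTree | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan a multi-participant stream for every tree history.

    Returns ``(per_participant, grand)`` tables.  Per participant, all
    2^depth - 1 R-leading histories (and their L-leading complements when
    requested) are scanned, means censored and unit-normalized within the
    participant (R- and L-leading families normalized separately).  The
    grand table is the unweighted across-participant mean of normalized
    means and error rates; participants missing a history are dropped from
    that history's grand mean with a logged warning.
    """
    if streams.empty:
        raise ValueError("empty trial stream")
    missing = [c for c in STREAM_COLUMNS if c not in streams.columns]
    if missing:
        raise ValueError(f"trial stream missing columns: {missing}")
    tree = build_tree(depth) if tree is None else tree
    targets = _target_histories(tree, l_leading)

    rows = []
    for pid, part in streams.groupby("participant", sort=True):
        part = part.sort_values("trial")
        if len(part) < depth:
            raise ValueError(f"participant {pid!r} has fewer than {depth} trials")
        _, stim, correct, rt = _participant_arrays(part)
        for history, ratio in targets:
            row = _history_row(stim, correct, rt, history, bounds, mode)
            row.update(
                participant=pid,
                level=len(history),
                numerator=ratio.numerator,
                denominator=ratio.denominator,
                omega=history_omega(history),
                leading=history[0],
            )
            rows.append(row)
    per_part = pd.DataFrame(rows)

    logged = per_part.loc[per_part["n_valid"] == 0]
    for _, r in logged.iterrows():
        logger.warning(
            "participant %r has no valid occurrence of %s; history treated as missing",
            r["participant"], r["history"],
        )

    # unit-normalize within participant, separately per leading letter
    per_part["norm_mean"] = np.nan
    for (pid, lead), grp in per_part.groupby(["participant", "leading"]):
        per_part.loc[grp.index, "norm_mean"] = unit_normalize(grp["mean_rt"])

    cols = [
        "participant", "history", "level", "numerator", "denominator", "omega",
        "n_occurrences", "n_valid", "mean_rt", "norm_mean",
        "member_obs", "unique_errors", "error_rate",
    ]
    per_part = per_part[cols].sort_values(["participant", "level", "history"])
    per_part = per_part.reset_index(drop=True)

    grand = (
        per_part.groupby(["history", "level", "numerator", "denominator", "omega"])
        .agg(
            n_participants=("participant", "size"),
            n_occurrences=("n_occurrences", "sum"),
            n_valid=("n_valid", "sum"),
            mean_rt=("mean_rt", "mean"),
            norm_mean=("norm_mean", "mean"),
            member_obs=("member_obs", "sum"),
            unique_errors=("unique_errors", "sum"),
            error_rate=("error_rate", "mean"),
        )
        .reset_index()
        .sort_values(["level", "history"])
        .reset_index(drop=True)
    )
    return per_part, grand
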