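"""Farey tree machinery: trial histories as mediant fractions.

Every R-leading trial history (a string over {R, L} beginning with R, up to
five trials long, oldest trial first) names a node of the Farey tree grown
from the seed ratios 0/1 and 1/1.  The root R is their mediant 1/2; from a
node spanning the interval (lo, hi), appending R descends into (lo, node)
and appending L into (node, hi), the child ratio being the mediant of its
interval's endpoints in either case.  A depth-5 tree therefore holds all
2^5 - 1 = 31 histories studied in sequential-effects analyses.

Ranking the nodes ascending by level and descending by ratio magnitude
within each level assigns each node a *binary rank* whose base-2 digits
spell its history under 1 -> R, 0 -> L (e.g. RRRL = 2/7 has rank 14 =
0b1110; the golden-ratio node RLRLR = 8/13 has rank 21 = 0b10101).

L-leading histories live on the right half of the Stern-Brocot tree: each
is the reciprocal of its letter-swapped R-leading complement (LL -> RR =
1/3 -> 3/1).  Their drive values exceed 1 and the map dynamics repeat for
each integer increase, so a wrapped (mod 1, with exact 0 reported as 1)
drive value is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "Ratio",
    "FareyNode",
    "FareyTree",
    "mediant",
    "build_tree",
    "history_to_ratio",
    "binary_rank",
    "rank_to_history",
    "l_leading_ratio",
    "history_omega",
    "golden_path",
    "swap_letters",
]

#: Ratios are exact reduced integer pairs; ``fractions.Fraction`` already
#: guarantees coprimality and value comparison.
Ratio = Fraction

DEFAULT_DEPTH = 5

_SEED_LO = Fraction(0, 1)
_SEED_HI = Fraction(1, 1)


@dataclass(frozen=True)
class FareyNode:
    """A mediant fraction with its level, symbolic history and binary rank."""

    ratio: Fraction
    level: int
    history: str
    binary_rank: int
    parents: tuple[Fraction, Fraction]  # (lo, hi): the adjacent ratios

    @property
    def omega(self) -> float:
        return float(self.ratio)


def _validate_history(history: str, require_first: str | None = "R") -> None:
    if not history:
        raise ValueError("history must be non-empty")
    bad = set(history) - {"R", "L"}
    if bad:
        raise ValueError(f"history may contain only R and L, got {sorted(bad)}")
    if require_first == "R" and history[0] != "R":
        raise ValueError(
            f"R-leading history required, got {history!r}; "
            "use l_leading_ratio for L-leading histories"
        )
    if require_first == "L" and history[0] != "L":
        raise ValueError(f"L-leading history required, got {history!r}")


def mediant(a: Fraction, b: Fraction) -> Fraction:
    """(a.num + b.num) / (a.den + b.den); requires a < b, lies strictly between."""
    if a >= b:
        raise ValueError(f"mediant requires a < b, got {a} >= {b}")
    return Fraction(a.numerator + b.numerator, a.denominator + b.denominator)


def swap_letters(history: str) -> str:
    """Exchange R and L (the L-leading <-> R-leading complement map)."""
    return history.translate(str.maketrans("RL", "LR"))


def _resolve(history: str) -> tuple[Fraction, tuple[Fraction, Fraction]]:
    """Walk the tree along ``history``; returns (ratio, (lo, hi) parents)."""
    lo, hi = _SEED_LO, _SEED_HI
    ratio = mediant(lo, hi)
    for letter in history[1:]:
        if letter == "R":
            lo, hi = lo, ratio
        else:
            lo, hi = ratio, hi
        ratio = mediant(lo, hi)
    return ratio, (lo, hi)


class FareyTree:
    """The R-leading Farey tree to a fixed depth, with rank lookups."""

    def __init__(self, depth: int = DEFAULT_DEPTH):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        self.depth = depth
        nodes: list[FareyNode] = []
        for level in range(1, depth + 1):
            level_nodes = []
            for rank in range(2 ** (level - 1), 2**level):
                history = rank_to_history(rank)
                ratio, parents = _resolve(history)
                level_nodes.append(
                    FareyNode(ratio, level, history, rank, parents)
                )
            # sanity: binary rank order coincides with magnitude-descending
            # order within the level (this equivalence is what makes the
            # binary digits spell the history)
            assert [n.ratio for n in level_nodes] == sorted(
                (n.ratio for n in level_nodes), reverse=True
            )
            nodes.extend(level_nodes)
        self.nodes = nodes
        self._by_history = {n.history: n for n in nodes}
        self._by_ratio = {n.ratio: n for n in nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def node(self, key: str | Fraction) -> FareyNode:
        """Look a node up by history string or exact ratio."""
        table = self._by_history if isinstance(key, str) else self._by_ratio
        try:
            return table[key]
        except KeyError:
            raise KeyError(f"{key!r} is not a member of the depth-{self.depth} tree")

    def histories(self, level: int | None = None) -> list[str]:
        if level is None:
            return [n.history for n in self.nodes]
        return [n.history for n in self.nodes if n.level == level]


def build_tree(depth: int = DEFAULT_DEPTH) -> FareyTree:
    """Build the R-leading tree: 2^depth - 1 nodes, 2^(k-1) per level k."""
    return FareyTree(depth)


def history_to_ratio(history: str) -> Fraction:
    """The mediant fraction whose tree path spells ``history`` (R-leading)."""
    _validate_history(history, require_first="R")
    return _resolve(history)[0]


def binary_rank(key: str | Fraction, tree: FareyTree | None = None) -> int:
    """Rank under level-ascending, magnitude-descending ordering (1-based).

    The rank's binary digits spell the history (1 -> R, 0 -> L), so for a
    history string it equals ``int(history, base=2)`` after substitution; a
    ratio is first resolved through the tree.
    """
    if isinstance(key, str):
        _validate_history(key, require_first="R")
        return int(key.replace("R", "1").replace("L", "0"), 2)
    tree = build_tree() if tree is None else tree
    return tree.node(key).binary_rank


def rank_to_history(rank: int) -> str:
    """Inverse of ``binary_rank``: binary digits back to R/L letters."""
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    return format(rank, "b").replace("1", "R").replace("0", "L")


def l_leading_ratio(history: str) -> Fraction:
    """Stern-Brocot ratio (> 1) of an L-leading history.

    Swap R and L, resolve the R-leading complement, take the reciprocal
    (e.g. LL -> RR = 1/3 -> 3/1).
    """
    _validate_history(history, require_first="L")
    return 1 / history_to_ratio(swap_letters(history))


def history_omega(history: str, wrap_l_leading: bool = True) -> float:
    """Decimal drive value of a history's ratio.

    R-leading histories give their ratio directly (in (0, 1)).  L-leading
    ratios exceed 1; with ``wrap_l_leading`` the value is reduced mod 1,
    an exact 0 being reported as 1 by convention (the map's dynamics repeat
    for each integer increase in the drive).
    """
    _validate_history(history, require_first=None)
    if history[0] == "R":
        return float(history_to_ratio(history))
    ratio = l_leading_ratio(history)
    if not wrap_l_leading:
        return float(ratio)
    wrapped = ratio - int(ratio)
    return 1.0 if wrapped == 0 else float(wrapped)


def golden_path(depth: int = DEFAULT_DEPTH) -> list[tuple[str, Fraction]]:
    """The strict-alternation branch R, RL, RLR, ... with Fibonacci-quotient
    ratios 1/2, 2/3, 3/5, 5/8, 8/13 converging to the golden ratio."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    out = []
    history = ""
    for k in range(depth):
        history += "R" if k % 2 == 0 else "L"
        out.append((history, history_to_ratio(history)))
    return out
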