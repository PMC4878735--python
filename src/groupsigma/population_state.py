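"""Population configurations and the game-count statistics entering sigma.

A state assigns each of the ``N`` individuals a strategy bit (1 = A, 0 = B)
and a group label in ``1..M``.  Games are played only within groups, so all
statistics reduce to per-group strategy counts.  The module also provides the
small counting identities that explain, state by state, how occupying new
groups and uneven strategy distributions push the structural coefficient up
or down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InvalidParameterError

__all__ = [
    "PopulationState",
    "GameCounts",
    "game_counts",
    "occupancy",
    "single_group_paired",
    "two_group_quartet",
]


@dataclass(frozen=True)
class PopulationState:
    """Strategies and group labels of all ``N`` individuals.

    ``strategies[i]`` is the strategy bit of individual ``i`` (1 = A, 0 = B);
    ``groups[i]`` is its group label in ``1..M``.
    """

    strategies: tuple[int, ...]
    groups: tuple[int, ...]
    M: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "strategies", tuple(int(s) for s in self.strategies))
        object.__setattr__(self, "groups", tuple(int(g) for g in self.groups))
        if len(self.strategies) != len(self.groups):
            raise InvalidParameterError("strategies and groups must have equal length N")
        if any(s not in (0, 1) for s in self.strategies):
            raise InvalidParameterError("strategy bits must be 0 or 1")
        if any(not 1 <= g <= self.M for g in self.groups):
            raise InvalidParameterError(f"group labels must lie in 1..{self.M}")

    @property
    def N(self) -> int:
        return len(self.strategies)


@dataclass(frozen=True)
class GameCounts:
    """Game counts of one state: I_AA (A-A games, pairs counted twice), I_AB, abundances."""

    I_AA: int
    I_AB: int
    N_A: int
    N_B: int


def _group_tallies(st: PopulationState) -> dict[int, list[int]]:
    """Per-group [A-count, B-count] tallies."""
    tallies: dict[int, list[int]] = {}
    for s, g in zip(st.strategies, st.groups):
        t = tallies.setdefault(g, [0, 0])
        t[0 if s == 1 else 1] += 1
    return tallies


def game_counts(st: PopulationState, include_self: bool = False) -> GameCounts:
    """Count within-group games: ``I_AA = sum_g a_g (a_g - 1)`` and ``I_AB = sum_g a_g b_g``.

    Each unordered A-A pair plays two games (ordered counting), so ``I_AA`` is
    even when self-interaction is excluded; with self-interaction every
    A-player additionally plays itself once, adding ``N_A``.
    """
    iaa = 0
    iab = 0
    n_a = 0
    for a_g, b_g in _group_tallies(st).values():
        iaa += a_g * (a_g - 1)
        iab += a_g * b_g
        n_a += a_g
    if include_self:
        iaa += n_a
    return GameCounts(I_AA=iaa, I_AB=iab, N_A=n_a, N_B=st.N - n_a)


def occupancy(st: PopulationState) -> list[tuple[int, int, int]]:
    """Per-group occupancy table ``(group, count_A, count_B)`` for all groups 1..M."""
    tallies = _group_tallies(st)
    return [(g, *tallies.get(g, [0, 0])) for g in range(1, st.M + 1)]


def _single_group_state(x: int, y: int) -> PopulationState:
    return PopulationState(strategies=(1,) * x + (0,) * y, groups=(1,) * (x + y), M=1)


def single_group_paired(x: int, y: int) -> tuple[int, int]:
    """Counting identity for the mirror-symmetric pair of single-group states.

    With migration off, the population collapses into one group and the
    neutral steady states come in equal-weight mirror pairs ``(x, y)`` and
    ``(y, x)`` (x A-players, y B-players, and vice versa).  Summed over the
    pair (self-interaction excluded):

        ``sum (I_AA N_B - I_AB N_B) = -2 x y``,
        ``sum (I_AB N_B) = (x + y) x y``.

    The first sum is negative whenever both strategies are present, which is
    why sigma stays below 1 for vanishing migration.  Both values are also
    recomputed by direct game counting; a mismatch raises.
    """
    if x < 0 or y < 0:
        raise InvalidParameterError("strategy counts must be non-negative")
    diff_sum = -2 * x * y
    iab_sum = (x + y) * x * y
    brute_diff = 0
    brute_iab = 0
    for xa, yb in ((x, y), (y, x)):
        gc = game_counts(_single_group_state(xa, yb), include_self=False)
        brute_diff += (gc.I_AA - gc.I_AB) * gc.N_B
        brute_iab += gc.I_AB * gc.N_B
    if (brute_diff, brute_iab) != (diff_sum, iab_sum):
        raise AssertionError("closed form disagrees with direct game counting")
    return diff_sum, iab_sum


def _two_group_state(a1: int, b1: int, a2: int, b2: int) -> PopulationState:
    strategies = (1,) * a1 + (0,) * b1 + (1,) * a2 + (0,) * b2
    groups = (1,) * (a1 + b1) + (2,) * (a2 + b2)
    return PopulationState(strategies=strategies, groups=groups, M=2)


def two_group_quartet(x: int, y: int, k: int, m: int, N: int) -> tuple[int, int]:
    """Counting identity for a symmetry quartet of two-group states.

    For ``x`` A-players and ``y`` B-players split over two groups with ``k``
    A-players and ``m`` B-players in group 2, the four states related by
    strategy exchange and group exchange carry equal neutral weight.  Summed
    over the quartet (self-interaction excluded):

        ``sum (I_AA N_B - I_AB N_B) = (k+m)(x-y)^2 + 2 N (k-m)^2 - 4 x y``,
        ``sum (I_AB N_B) = N (2 x y - (k+m) N + 4 k m)``.

    ``k = m = 0`` recovers exactly twice the single-group pair values.  The
    identity shows the three routes by which migration raises sigma: occupying
    a second group (``k + m > 0``), spreading the strategies unevenly
    (``|k - m|`` large), and strategy-abundance disparity (``|x - y|`` large).
    Both values are also recomputed by direct game counting; a mismatch raises.
    """
    if x + y != N:
        raise InvalidParameterError(f"x + y must equal N, got {x} + {y} != {N}")
    if min(x - k, y - m, y - k, x - m, k, m) < 0:
        raise InvalidParameterError(
            "need 0 <= k <= min(x, y) and 0 <= m <= min(x, y) for all four states to exist"
        )
    diff_sum = (k + m) * (x - y) ** 2 + 2 * N * (k - m) ** 2 - 4 * x * y
    iab_sum = N * (2 * x * y - (k + m) * N + 4 * k * m)
    quartet = (
        (x - k, y - m, k, m),
        (y - m, x - k, m, k),
        (y - k, x - m, k, m),
        (x - m, y - k, m, k),
    )
    brute_diff = 0
    brute_iab = 0
    for a1, b1, a2, b2 in quartet:
        gc = game_counts(_two_group_state(a1, b1, a2, b2), include_self=False)
        brute_diff += (gc.I_AA - gc.I_AB) * gc.N_B
        brute_iab += gc.I_AB * gc.N_B
    if (brute_diff, brute_iab) != (diff_sum, iab_sum):
        raise AssertionError("closed form disagrees with direct game counting")
    return diff_sum, iab_sum
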