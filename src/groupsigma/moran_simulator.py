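"""Frequency-dependent Moran process with mutation and migration on the group circle.

One elementary event (one "generation") consists of: a reproducer drawn with
probability proportional to fitness ``1 + w * payoff`` (uniformly when
``w = 0``), a dying individual drawn uniformly from all ``N`` (the reproducer
included), and the dying slot refilled by the offspring.  The offspring keeps
the parent's strategy with probability ``1 - u`` and otherwise re-draws
uniformly from {A, B} (net switch probability ``u/2``); it stays in the
parent's group with probability ``1 - v`` and otherwise migrates uniformly
over the distinct groups reachable within circular displacement ``±1..±r``
(or over all other ``M - 1`` groups for global migration).

Under neutrality (``w = 0``) the time average of ``I_AA * N_B`` over
``I_AB * N_B`` estimates the structural coefficient; :func:`run_neutral_sigma`
implements that estimator with an O(1)-per-event incremental update of the
game counts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from math import sqrt
from typing import Optional, Sequence

from .errors import ConfigurationError, DegenerateParameterError, InvalidParameterError
from .kernels import ModelParams
from .population_state import PopulationState
from .sigma import PayoffMatrix

__all__ = [
    "SimulationConfig",
    "SigmaEstimate",
    "migration_destinations",
    "step",
    "payoff_vector",
    "run_neutral_sigma",
    "run_occupancy",
]

_NEUTRAL_PAYOFF = PayoffMatrix(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation run.

    ``migration_range`` selects the dispersal kernel (``None`` with
    ``global_migration=True`` for uniform dispersal over the other groups).
    ``burn_in`` defaults to 5% of ``generations`` when left as ``None``.
    """

    params: ModelParams
    generations: int
    seed: int
    migration_range: Optional[int] = None
    global_migration: bool = False
    payoff: PayoffMatrix = _NEUTRAL_PAYOFF
    w: float = 0.0
    include_self: bool = False
    burn_in: Optional[int] = None
    snapshot_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.w < 0.0:
            raise InvalidParameterError(f"selection intensity w must be >= 0, got {self.w}")
        if self.generations <= self.effective_burn_in:
            raise InvalidParameterError("generations must exceed the burn-in")
        M = self.params.M
        if M == 1:
            if self.global_migration:
                raise InvalidParameterError("global migration needs at least two groups")
        elif self.global_migration == (self.migration_range is not None):
            raise InvalidParameterError(
                "specify exactly one of migration_range or global_migration"
            )
        if self.migration_range is not None and M > 1:
            if not 1 <= self.migration_range <= M // 2:
                raise InvalidParameterError(
                    f"migration range must lie in [1, {M // 2}] for M={M}"
                )

    @property
    def effective_burn_in(self) -> int:
        return self.burn_in if self.burn_in is not None else self.generations // 20


@dataclass(frozen=True)
class SigmaEstimate:
    """Monte-Carlo estimate of sigma with a batch-means standard error."""

    sigma_hat: float
    se: float
    n_generations: int
    mean_iaa_nb: float
    mean_iab_nb: float
    seed: int


def migration_destinations(M: int, r: Optional[int], global_migration: bool) -> list[list[int]]:
    """Destination groups (0-based) reachable by one migration step from each group.

    For range ``r < M/2`` there are ``2 r`` distinct destinations; for even
    ``M`` with ``r = M/2`` the antipodal group is reachable one way only,
    giving ``M - 1``; global migration reaches all other ``M - 1`` groups.
    All destinations are used equiprobably, which is what makes the cosine
    structure functions of :mod:`groupsigma.kernels` the exact transform of
    this kernel.
    """
    if M == 1:
        return [[0]]  # a migrating offspring has nowhere else to go
    dests: list[list[int]] = []
    for g in range(M):
        if global_migration:
            ds = [h for h in range(M) if h != g]
        else:
            ds = sorted({(g + k) % M for k in range(-r, r + 1) if k != 0} - {g})
        dests.append(ds)
    return dests


def payoff_vector(
    st: PopulationState, m: PayoffMatrix, include_self: bool = False
) -> list[float]:
    """Total payoff of each individual from games with its group mates.

    ``p_i = sum over same-group j != i of payoff(s_i, s_j)``, plus the
    self-game ``payoff(s_i, s_i)`` when ``include_self`` is set.
    """
    a_g = [0] * (st.M + 1)
    b_g = [0] * (st.M + 1)
    for s, g in zip(st.strategies, st.groups):
        if s:
            a_g[g] += 1
        else:
            b_g[g] += 1
    out = []
    for s, g in zip(st.strategies, st.groups):
        if s:
            p = m.a * (a_g[g] - 1) + m.b * b_g[g]
            if include_self:
                p += m.a
        else:
            p = m.c * a_g[g] + m.d * (b_g[g] - 1)
            if include_self:
                p += m.d
        out.append(p)
    return out


def _offspring(
    parent_s: int,
    parent_g0: int,
    u: float,
    v: float,
    dests: list[list[int]],
    rng: random.Random,
) -> tuple[int, int]:
    """Strategy and 0-based group of one offspring of the given parent."""
    s = parent_s
    if rng.random() < u:
        s = 1 if rng.random() < 0.5 else 0
    g = parent_g0
    if rng.random() < v:
        ds = dests[parent_g0]
        g = ds[int(rng.random() * len(ds))]
    return s, g


def step(st: PopulationState, cfg: SimulationConfig, rng: random.Random) -> PopulationState:
    """Advance the population by one birth-death event and return the new state."""
    N = st.N
    if cfg.w == 0.0:
        repro = int(rng.random() * N)
    else:
        payoffs = payoff_vector(st, cfg.payoff, cfg.include_self)
        weights = [1.0 + cfg.w * p for p in payoffs]
        if min(weights) <= 0.0:
            raise ConfigurationError(
                "fitness 1 + w * payoff is non-positive for some individual; "
                "reduce the selection intensity w"
            )
        repro = rng.choices(range(N), weights=weights)[0]
    dier = int(rng.random() * N)
    dests = migration_destinations(st.M, cfg.migration_range, cfg.global_migration)
    s, g0 = _offspring(
        st.strategies[repro], st.groups[repro] - 1, cfg.params.u, cfg.params.v, dests, rng
    )
    strategies = list(st.strategies)
    groups = list(st.groups)
    strategies[dier] = s
    groups[dier] = g0 + 1
    return PopulationState(strategies=tuple(strategies), groups=tuple(groups), M=st.M)


def _random_state(N: int, M: int, rng: random.Random) -> tuple[list[int], list[int]]:
    """Uniform random initial strategies and 0-based groups."""
    strategies = [1 if rng.random() < 0.5 else 0 for _ in range(N)]
    groups = [int(rng.random() * M) for _ in range(N)]
    return strategies, groups


class _FastNeutralLoop:
    """Neutral chain with O(1) incremental updates of I_AA, I_AB, N_A, N_B."""

    def __init__(self, cfg: SimulationConfig, rng: random.Random):
        p = cfg.params
        self.N, self.M, self.u, self.v = p.N, p.M, p.u, p.v
        self.rng = rng
        self.dests = migration_destinations(p.M, cfg.migration_range, cfg.global_migration)
        self.strategies, self.groups = _random_state(p.N, p.M, rng)
        self.a = [0] * p.M
        self.b = [0] * p.M
        for s, g in zip(self.strategies, self.groups):
            (self.a if s else self.b)[g] += 1
        self.iaa = sum(x * (x - 1) for x in self.a)
        self.iab = sum(x * y for x, y in zip(self.a, self.b))
        self.na = sum(self.a)
        self.nb = p.N - self.na

    def advance(self) -> None:
        rng = self.rng
        N = self.N
        repro = int(rng.random() * N)
        dier = int(rng.random() * N)
        s, g = _offspring(
            self.strategies[repro], self.groups[repro], self.u, self.v, self.dests, rng
        )
        # remove the dier from the tallies, then add the offspring
        sd, gd = self.strategies[dier], self.groups[dier]
        if sd:
            self.a[gd] -= 1
            self.iaa -= 2 * self.a[gd]
            self.iab -= self.b[gd]
            self.na -= 1
        else:
            self.b[gd] -= 1
            self.iab -= self.a[gd]
            self.nb -= 1
        if s:
            self.iaa += 2 * self.a[g]
            self.iab += self.b[g]
            self.a[g] += 1
            self.na += 1
        else:
            self.iab += self.a[g]
            self.b[g] += 1
            self.nb += 1
        self.strategies[dier] = s
        self.groups[dier] = g

    def state(self) -> PopulationState:
        return PopulationState(
            strategies=tuple(self.strategies),
            groups=tuple(g + 1 for g in self.groups),
            M=self.M,
        )


def run_neutral_sigma(cfg: SimulationConfig, n_batches: int = 100) -> SigmaEstimate:
    """Estimate sigma from a neutral run as a ratio of time averages.

    After the burn-in, ``I_AA * N_B`` (per the ``include_self`` flag) and
    ``I_AB * N_B`` are accumulated every generation and sigma is their ratio.
    The standard error comes from ``n_batches`` batch-means ratios of equal
    contiguous blocks.  Two runs with the same config and seed are
    bit-identical.
    """
    if cfg.w != 0.0:
        raise InvalidParameterError(
            "the sigma estimator is defined under neutrality; set w = 0"
        )
    if cfg.params.u == 0.0:
        raise DegenerateParameterError("the sigma estimator requires u > 0")
    rng = random.Random(cfg.seed)
    loop = _FastNeutralLoop(cfg, rng)
    burn = cfg.effective_burn_in
    for _ in range(burn):
        loop.advance()
    kept = cfg.generations - burn
    n_batches = max(1, min(n_batches, kept))
    total_num = 0.0
    total_den = 0.0
    batch_ratios: list[float] = []
    base, extra = divmod(kept, n_batches)
    for bi in range(n_batches):
        bn = base + (1 if bi < extra else 0)
        bnum = 0
        bden = 0
        for _ in range(bn):
            loop.advance()
            iaa = loop.iaa + loop.na if cfg.include_self else loop.iaa
            bnum += iaa * loop.nb
            bden += loop.iab * loop.nb
        total_num += bnum
        total_den += bden
        if bden > 0:
            batch_ratios.append(bnum / bden)
    if total_den == 0.0:
        raise DegenerateParameterError(
            "denominator average <I_AB N_B> is zero over this run; run longer or raise u"
        )
    sigma_hat = total_num / total_den
    if len(batch_ratios) > 1:
        mean_r = sum(batch_ratios) / len(batch_ratios)
        var = sum((r - mean_r) ** 2 for r in batch_ratios) / (len(batch_ratios) - 1)
        se = sqrt(var / len(batch_ratios))
    else:
        se = float("nan")
    return SigmaEstimate(
        sigma_hat=sigma_hat,
        se=se,
        n_generations=kept,
        mean_iaa_nb=total_num / kept,
        mean_iab_nb=total_den / kept,
        seed=cfg.seed,
    )


def run_occupancy(cfg: SimulationConfig) -> list[tuple[int, int, int, int]]:
    """Neutral run reporting per-group occupancy at the requested generations.

    Returns ``(generation, group, count_A, count_B)`` records, groups 1-based,
    for every generation index in ``cfg.snapshot_times``.
    """
    if not cfg.snapshot_times:
        raise InvalidParameterError("snapshot_times must be nonempty for an occupancy run")
    rng = random.Random(cfg.seed)
    loop = _FastNeutralLoop(cfg, rng)
    wanted = sorted(set(cfg.snapshot_times))
    if wanted[0] < 0 or wanted[-1] > cfg.generations:
        raise InvalidParameterError("snapshot times must lie within [0, generations]")
    records: list[tuple[int, int, int, int]] = []
    t = 0
    for target in wanted:
        while t < target:
            loop.advance()
            t += 1
        for g in range(cfg.params.M):
            records.append((t, g + 1, loop.a[g], loop.b[g]))
    return records
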