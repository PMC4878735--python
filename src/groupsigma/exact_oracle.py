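"""Brute-force ground truth: the full neutral Markov chain for tiny populations.

For small ``(N, M)`` the neutral birth-death chain over per-individual
(strategy, group) assignments can be enumerated exactly and its stationary
distribution solved as a linear system.  The structural coefficient and the
triplet probabilities then follow directly from their definitions as
stationary averages, with no closed-form input — which is what makes this
module an independent check of :mod:`groupsigma.sigma`.

Two encodings are supported: the raw chain over the ``(2M)^N`` labelled
states, and an exact lumping by exchangeability over multisets of
(strategy, group) pairs (the dynamics depends only on category counts).  Both
must produce identical expectations; the lumped chain is the default because
it is exponentially smaller.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import (
    DegenerateParameterError,
    InvalidParameterError,
    ReducibleChainError,
)
from .kernels import ModelParams
from .moran_simulator import migration_destinations
from .sigma import SigmaResult

__all__ = [
    "ChainSpec",
    "StationaryResult",
    "neutral_transition_matrix",
    "stationary_distribution",
    "stationary_expectations",
    "sigma_by_definition",
    "triplet_probability_by_definition",
]

_RAW_STATE_GUARD = 100_000

Migration = Union[int, str]  # a range r, or "global"


@dataclass(frozen=True)
class ChainSpec:
    """Which chain to enumerate: population size, group count, and encoding."""

    N: int
    M: int
    lumping: bool = True

    def __post_init__(self) -> None:
        if self.N < 2 or self.M < 1:
            raise InvalidParameterError("need N >= 2 and M >= 1")
        if not self.lumping and (2 * self.M) ** self.N > _RAW_STATE_GUARD:
            raise InvalidParameterError(
                f"raw chain has (2M)^N = {(2 * self.M) ** self.N} states, "
                f"exceeding the guard of {_RAW_STATE_GUARD}; use lumping"
            )


@dataclass(frozen=True)
class StationaryResult:
    """Stationary weights of an enumerated chain plus named stationary averages."""

    probabilities: np.ndarray
    expectations: dict


def _categories(M: int) -> int:
    # category index c = s * M + g with s the strategy bit, g the 0-based group
    return 2 * M


def _category_kernel(p: ModelParams, migration: Migration) -> np.ndarray:
    """K[parent category, offspring category]: mutation x migration product kernel."""
    M = p.M
    if migration == "global":
        dests = migration_destinations(M, None, True)
    else:
        dests = migration_destinations(M, int(migration), False)
    strat = np.array(
        [[1.0 - p.u / 2.0, p.u / 2.0], [p.u / 2.0, 1.0 - p.u / 2.0]]
    )
    group = np.zeros((M, M))
    for g in range(M):
        group[g, g] += 1.0 - p.v
        for d in dests[g]:
            group[g, d] += p.v / len(dests[g])
    C = _categories(M)
    K = np.zeros((C, C))
    for s in (0, 1):
        for sp in (0, 1):
            K[s * M:(s + 1) * M, sp * M:(sp + 1) * M] = strat[s, sp] * group
    return K


def _lumped_states(N: int, C: int) -> list[tuple[int, ...]]:
    """All count vectors over C categories summing to N (multisets of size N)."""
    states = []
    for bars in itertools.combinations(range(N + C - 1), C - 1):
        prev = -1
        counts = []
        for b in bars:
            counts.append(b - prev - 1)
            prev = b
        counts.append(N + C - 2 - prev)
        states.append(tuple(counts))
    return states


def _check_chain_params(p: ModelParams) -> None:
    if p.u == 0.0:
        raise ReducibleChainError(
            "u = 0 makes the monomorphic strategy classes absorbing; "
            "the neutral chain is reducible"
        )
    if p.v == 0.0 and p.M > 1:
        raise ReducibleChainError(
            "v = 0 makes group occupancy absorbing (groups can be lost, never "
            "regained); handle the v = 0 limit analytically instead"
        )


def neutral_transition_matrix(
    spec: ChainSpec, p: ModelParams, migration: Migration
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Row-stochastic one-event matrix of the neutral chain, with its state list.

    One event: reproducer uniform (1/N), dier uniform (1/N), offspring
    category drawn from the mutation-migration product kernel of the
    reproducer's category.  Lumped states are count vectors over the ``2M``
    (strategy, group) categories; raw states are per-individual category
    tuples.
    """
    if spec.N != p.N or spec.M != p.M:
        raise InvalidParameterError("ChainSpec and ModelParams disagree on (N, M)")
    _check_chain_params(p)
    N, M = p.N, p.M
    C = _categories(M)
    K = _category_kernel(p, migration)
    if spec.lumping:
        states = _lumped_states(N, C)
        index = {s: i for i, s in enumerate(states)}
        P = np.zeros((len(states), len(states)))
        for i, n in enumerate(states):
            narr = np.asarray(n, dtype=float)
            # offspring category distribution, marginal over the uniform reproducer
            q = (narr / N) @ K
            for d in range(C):
                if n[d] == 0:
                    continue
                pd = n[d] / N
                for o in range(C):
                    if q[o] == 0.0:
                        continue
                    if o == d:
                        P[i, i] += pd * q[o]
                    else:
                        child = list(n)
                        child[d] -= 1
                        child[o] += 1
                        P[i, index[tuple(child)]] += pd * q[o]
        return P, states
    states = list(itertools.product(range(C), repeat=N))
    index = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for i, st in enumerate(states):
        for repro in range(N):
            for dier in range(N):
                for o in range(C):
                    ko = K[st[repro], o]
                    if ko == 0.0:
                        continue
                    child = list(st)
                    child[dier] = o
                    P[i, index[tuple(child)]] += ko / (N * N)
    return P, states


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Solve ``pi P = pi``, ``sum pi = 1`` by a dense linear solve.

    The transposed system ``(P^T - I) pi = 0`` has its last row replaced by the
    normalisation constraint.  Residuals beyond 1e-12 (typically caused by a
    reducible chain, i.e. u = 0 or v = 0) raise.
    """
    n = P.shape[0]
    A = P.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ReducibleChainError(
            "singular stationary system; the chain is likely reducible (u = 0 or v = 0)"
        ) from exc
    if np.min(pi) < -1e-10 or np.max(np.abs(pi @ P - pi)) > 1e-12:
        raise ReducibleChainError(
            "stationary solve failed its residual check; the chain is likely reducible"
        )
    return np.clip(pi, 0.0, None) / np.sum(np.clip(pi, 0.0, None))


def _counts_of(state: Sequence[int], spec: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-group (A-counts, B-counts) of a state in either encoding."""
    M = spec.M
    if spec.lumping:
        arr = np.asarray(state)
        return arr[M:], arr[:M]
    a = np.zeros(M, dtype=int)
    b = np.zeros(M, dtype=int)
    for c in state:
        s, g = divmod(c, M)
        if s:
            a[g] += 1
        else:
            b[g] += 1
    return a, b


def stationary_expectations(
    spec: ChainSpec, p: ModelParams, migration: Migration
) -> StationaryResult:
    """Stationary averages of every observable the closed forms predict.

    The expectations dict contains ``iaa_nb`` / ``iaa_self_nb`` / ``iab_nb``
    (the sigma building blocks without and with self-games), ``pair_prob``
    (``Pr(s1=1, s2=0)`` for an ordered sampled pair), ``coloc_prob`` (ordered
    pair sharing a group), and ``triplet[(d1, d2, d3)]`` — the probability
    that an ordered sampled triple has those strategies with individuals 2 and
    3 co-located.
    """
    P, states = neutral_transition_matrix(spec, p, migration)
    pi = stationary_distribution(P)
    N = spec.N
    exp = {
        "iaa_nb": 0.0,
        "iaa_self_nb": 0.0,
        "iab_nb": 0.0,
        "pair_prob": 0.0,
        "coloc_prob": 0.0,
        "triplet": {t: 0.0 for t in itertools.product((0, 1), repeat=3)},
    }
    pairs = N * (N - 1)
    triples = N * (N - 1) * (N - 2)
    for w, state in zip(pi, states):
        if w == 0.0:
            continue
        a, b = _counts_of(state, spec)
        na = int(a.sum())
        nb = N - na
        iaa = int((a * (a - 1)).sum())
        iab = int((a * b).sum())
        exp["iaa_nb"] += w * iaa * nb
        exp["iaa_self_nb"] += w * (iaa + na) * nb
        exp["iab_nb"] += w * iab * nb
        exp["pair_prob"] += w * na * nb / pairs
        occ = a + b
        exp["coloc_prob"] += w * int((occ * (occ - 1)).sum()) / pairs
        if N >= 3:
            cnt = {1: a, 0: b}
            tot = {1: na, 0: nb}
            for d2, d3 in itertools.product((0, 1), repeat=2):
                same = int(d2 == d3)
                pair_count = int((cnt[d2] * (cnt[d3] - same)).sum())
                if pair_count == 0:
                    continue
                for d1 in (0, 1):
                    n1 = tot[d1] - (d1 == d2) - (d1 == d3)
                    exp["triplet"][(d1, d2, d3)] += w * pair_count * n1 / triples
    return StationaryResult(probabilities=pi, expectations=exp)


def sigma_by_definition(
    spec: ChainSpec, p: ModelParams, migration: Migration, include_self: bool = False
) -> SigmaResult:
    """Sigma straight from its definition: the ratio of two stationary averages."""
    res = stationary_expectations(spec, p, migration)
    num = res.expectations["iaa_self_nb" if include_self else "iaa_nb"]
    den = res.expectations["iab_nb"]
    if den == 0.0:
        raise DegenerateParameterError("<I_AB N_B>_0 = 0; sigma is undefined (u = 0?)")
    return SigmaResult(
        sigma=num / den, numerator=num, denominator=den, include_self=include_self
    )


def triplet_probability_by_definition(
    spec: ChainSpec, p: ModelParams, migration: Migration, d1: int, d2: int, d3: int
) -> float:
    """Definitional triplet probability over the stationary law and a uniform ordered triple."""
    if spec.N < 3:
        raise InvalidParameterError("triplet probabilities need N >= 3")
    if any(d not in (0, 1) for d in (d1, d2, d3)):
        raise InvalidParameterError("strategy indicators must be 0 or 1")
    res = stationary_expectations(spec, p, migration)
    return res.expectations["triplet"][(d1, d2, d3)]
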