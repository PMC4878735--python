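"""Migration structure functions and the scalar coalescent kernels built from them.

The population consists of ``N`` haploid individuals distributed over ``M``
groups arranged on a circle.  Reproduction follows a frequency-dependent Moran
process: at each birth-death event the offspring keeps the parent's strategy
with probability ``1 - u`` (otherwise it re-draws a strategy uniformly) and
stays in the parent's group with probability ``1 - v`` (otherwise it migrates
according to a prescribed dispersal kernel on the circle).

Because both mutation and migration act as random walks along a lineage, every
isotropic dispersal kernel is summarised by its *structure function*
``f(x)``, ``x = 1..M`` — the discrete cosine transform of the single-step
displacement distribution.  Isotropy forces ``f(M) = 1`` and
``f(x) = f(M - x)``; displacement ``x = M`` plays the role of displacement 0
(periodic boundary).  All closed-form results in :mod:`groupsigma.sigma` are
finite sums of a handful of scalar kernels (``Psi``, ``Phi``, ``alpha``)
evaluated at the ``M`` values of the structure function.  Those kernels are
the neutral-coalescent identity probabilities of two- and three-lineage
samples and are defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import InvalidParameterError

__all__ = [
    "ModelParams",
    "MigrationPattern",
    "GlobalCoefficients",
    "global_pattern",
    "range_pattern",
    "well_mixed_pattern",
    "mutation_structure",
    "pair_kernels",
    "triple_kernels",
    "mutation_alpha",
    "global_coefficients",
]

_SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Demographic and stochastic parameters of the group-structured Moran model.

    Parameters
    ----------
    N : int
        Population size.  ``N >= 3`` because the three-lineage kernels carry
        ``N - 2`` factors and the structural coefficient is only reported for
        populations that admit three distinct sampled individuals.
    M : int
        Number of groups on the circle (``M >= 1``).
    u : float
        Strategy mutation probability per birth, in ``[0, 1]``.
    v : float
        Migration probability per birth, in ``[0, 1]``.
    """

    N: int
    M: int
    u: float
    v: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 3:
            raise InvalidParameterError(f"population size N must be an integer >= 3, got {self.N}")
        if int(self.M) != self.M or self.M < 1:
            raise InvalidParameterError(f"group number M must be an integer >= 1, got {self.M}")
        if not 0.0 <= self.u <= 1.0:
            raise InvalidParameterError(f"mutation probability u must lie in [0, 1], got {self.u}")
        if not 0.0 <= self.v <= 1.0:
            raise InvalidParameterError(f"migration probability v must lie in [0, 1], got {self.v}")

    @property
    def mu(self) -> float:
        """Scaled mutation rate ``mu = N * u`` used by the large-N approximation."""
        return self.N * self.u

    @property
    def nu(self) -> float:
        """Scaled migration rate ``nu = N * v`` used by the large-N approximation."""
        return self.N * self.v


@dataclass(frozen=True)
class MigrationPattern:
    """Structure function of an isotropic migration kernel on the circular lattice.

    ``f[x - 1]`` holds ``f(x)`` for displacements ``x = 1..M``.  Validity
    requires ``f(M) = 1``, the mirror symmetry ``f(x) = f(M - x)`` (isotropy),
    and ``|f(x)| <= 1`` (it is a mixture of cosines).
    """

    M: int
    f: tuple[float, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if int(self.M) != self.M or self.M < 1:
            raise InvalidParameterError(f"group number M must be an integer >= 1, got {self.M}")
        object.__setattr__(self, "f", tuple(float(x) for x in self.f))
        if len(self.f) != self.M:
            raise InvalidParameterError(
                f"structure function needs {self.M} values f(1)..f(M), got {len(self.f)}"
            )
        if abs(self.f[self.M - 1] - 1.0) > _SYMMETRY_TOL:
            raise InvalidParameterError(f"f(M) must equal 1, got {self.f[self.M - 1]!r}")
        for x in range(1, self.M):
            if abs(self.f[x - 1] - self.f[self.M - x - 1]) > _SYMMETRY_TOL:
                raise InvalidParameterError(
                    f"isotropy violated: f({x}) != f({self.M - x})"
                )
        if any(abs(x) > 1.0 + _SYMMETRY_TOL for x in self.f):
            raise InvalidParameterError("structure-function values must lie in [-1, 1]")

    def value(self, x: int) -> float:
        """Return ``f(x)`` for a 1-based displacement ``x`` in ``1..M``."""
        if not 1 <= x <= self.M:
            raise InvalidParameterError(f"displacement must lie in 1..{self.M}, got {x}")
        return self.f[x - 1]


def well_mixed_pattern() -> MigrationPattern:
    """Structure function of the single-group (well-mixed) population, ``M = 1``."""
    return MigrationPattern(M=1, f=(1.0,), name="well-mixed")


def global_pattern(M: int) -> MigrationPattern:
    """Structure function of global migration: dispersal uniform over the other groups.

    Computed as the cosine sum
    ``f(x) = (1/(M-1)) * sum_{k=1..M-1} cos(2 pi k x / M)``, which collapses to
    ``f(M) = 1`` and ``f(x) = -1/(M-1)`` for ``x != M``.  Both routes are
    evaluated and must agree to 1e-12.
    """
    if M < 2:
        raise InvalidParameterError("global migration requires at least two groups (M >= 2)")
    f = tuple(
        math.fsum(math.cos(2.0 * math.pi * k * x / M) for k in range(1, M)) / (M - 1)
        for x in range(1, M + 1)
    )
    closed = tuple(-1.0 / (M - 1) if x < M else 1.0 for x in range(1, M + 1))
    if any(abs(a - b) > 1e-12 for a, b in zip(f, closed)):
        raise AssertionError("cosine sum disagrees with the global closed form")
    return MigrationPattern(M=M, f=f, name="global")


def range_pattern(M: int, r: int) -> MigrationPattern:
    """Structure function for migration uniform over displacements ``{±1, .., ±r}``.

    For ``r < M/2`` the single step reaches ``2 r`` distinct groups and

        ``f(x; r) = (1/r) * sum_{k=1..r} cos(2 pi k x / M)``.

    For even ``M`` with ``r = M/2`` the antipodal displacement is reachable one
    way only, the step is uniform over all other ``M - 1`` groups, and the
    global form applies.  The cosine (not sine) form reflects left/right
    mirror symmetry of dispersal.
    """
    if M < 2:
        raise InvalidParameterError("range migration requires at least two groups (M >= 2)")
    if int(r) != r or not 1 <= r <= M // 2:
        raise InvalidParameterError(
            f"migration range must be an integer in [1, {M // 2}] for M={M}, got {r}"
        )
    if M % 2 == 0 and r == M // 2:
        f = tuple(
            math.fsum(math.cos(2.0 * math.pi * k * x / M) for k in range(1, M)) / (M - 1)
            for x in range(1, M + 1)
        )
    else:
        f = tuple(
            math.fsum(math.cos(2.0 * math.pi * k * x / M) for k in range(1, r + 1)) / r
            for x in range(1, M + 1)
        )
    return MigrationPattern(M=M, f=f, name=f"r={r}")


def mutation_structure(x: int) -> float:
    """Structure function ``g(x) = 1/2 + cos(pi x)/2`` of symmetric two-strategy mutation.

    On the two-point strategy cycle the mutation random walk jumps uniformly
    over both strategies; its cosine transform alternates between
    ``g(even) = 1`` and ``g(odd) = 0``.
    """
    return 0.5 + 0.5 * math.cos(math.pi * x)


def mutation_alpha(p: ModelParams) -> float:
    """Two-lineage strategy-identity kernel ``alpha_1 = (1-u) / (1 + (N-1) u)``.

    This is the stationary probability-generating quantity for two sampled
    lineages carrying the same strategy under neutrality; it decreases from 1
    at ``u = 0`` to 0 at ``u = 1``.
    """
    return (1.0 - p.u) / (1.0 + (p.N - 1) * p.u)


def pair_kernels(f: float, p: ModelParams) -> tuple[float, float]:
    """Two-lineage kernels ``(Psi_1, Psi_2)`` at a structure-function value ``f``.

    ``Psi_1(f) = (1 - v + v f) / (1 + (N-1) v (1-f))`` tracks co-location of a
    sampled pair; ``Psi_2`` additionally requires strategy identity and gains
    the mutation terms:
    ``Psi_2(f) = (1-u)(1 - v + v f) / (1 + (N-1) u + (N-1)(1-u) v (1-f))``.
    ``Psi_2 <= Psi_1`` with equality iff ``u = 0``.
    """
    if not -1.0 - _SYMMETRY_TOL <= f <= 1.0 + _SYMMETRY_TOL:
        raise InvalidParameterError(f"structure-function value must lie in [-1, 1], got {f}")
    N, u, v = p.N, p.u, p.v
    base = 1.0 - v + v * f
    psi1 = base / (1.0 + (N - 1) * v * (1.0 - f))
    psi2 = (1.0 - u) * base / (1.0 + (N - 1) * u + (N - 1) * (1.0 - u) * v * (1.0 - f))
    return psi1, psi2


def triple_kernels(f: float, p: ModelParams) -> tuple[float, float, float]:
    """Three-lineage kernels ``(Phi_1, Phi_2, Phi_3)`` at a structure-function value ``f``.

    All three share the denominator
    ``D = 2 + 2(N-2) u / 3 + (N-2)(2-u) v (1-f) / 3`` and differ in which of
    the three lineage pairs is constrained:

    * ``Phi_1 = (2 - u - v + v f) / D``
    * ``Phi_2 = (1-u)(2 - v + v f) / D``
    * ``Phi_3 = (2-u)(1 - v + v f) / D``
    """
    if not -1.0 - _SYMMETRY_TOL <= f <= 1.0 + _SYMMETRY_TOL:
        raise InvalidParameterError(f"structure-function value must lie in [-1, 1], got {f}")
    N, u, v = p.N, p.u, p.v
    D = 2.0 + 2.0 * (N - 2) * u / 3.0 + (N - 2) * (2.0 - u) * v * (1.0 - f) / 3.0
    phi1 = (2.0 - u - v + v * f) / D
    phi2 = (1.0 - u) * (2.0 - v + v * f) / D
    phi3 = (2.0 - u) * (1.0 - v + v * f) / D
    return phi1, phi2, phi3


class GlobalCoefficients(NamedTuple):
    """Scalar coefficients of the global-migration closed form for sigma."""

    alpha1: float
    alpha2: float
    alpha3: float
    tau1: float
    tau2: float
    tau3: float


def global_coefficients(p: ModelParams) -> GlobalCoefficients:
    """Coefficients ``(alpha_1..alpha_3, tau_1..tau_3)`` of the global closed form.

    These are the pair and triple kernels specialised to the global structure
    function, whose only off-diagonal value is ``-1/(M-1)``; the recurring
    combination is ``Mv/(M-1) = v (1 - f)``.  As printed, the correspondence
    with the generic kernels at ``f = -1/(M-1)`` is ``alpha2 = Psi_1``,
    ``alpha3 = Psi_2``, ``tau1 = Phi_3``, ``tau2 = Phi_2``, ``tau3 = Phi_1``.
    """
    if p.M < 2:
        raise InvalidParameterError("global coefficients require at least two groups (M >= 2)")
    N, M, u, v = p.N, p.M, p.u, p.v
    mv = M * v / (M - 1)
    alpha1 = mutation_alpha(p)
    alpha2 = (1.0 - mv) / (1.0 + (N - 1) * mv)
    alpha3 = (1.0 - u) * (1.0 - mv) / (1.0 + (N - 1) * u + (N - 1) * (1.0 - u) * mv)
    D = 2.0 + 2.0 * (N - 2) * u / 3.0 + (N - 2) * (2.0 - u) * mv / 3.0
    tau1 = (2.0 - u) * (1.0 - mv) / D
    tau2 = (1.0 - u) * (2.0 - mv) / D
    tau3 = (2.0 - u - mv) / D
    return GlobalCoefficients(alpha1, alpha2, alpha3, tau1, tau2, tau3)
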