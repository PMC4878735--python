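"""Closed-form structural coefficients for two-strategy competition under weak selection.

For any population structure with a symmetric update rule, weak selection
tilts the two-strategy abundance comparison into the linear condition

    ``sigma * a + b > c + sigma * d``

for the payoff matrix ``[[a, b], [c, d]]`` (row strategy A against column
strategy B).  The single *structural coefficient* ``sigma`` summarises the
entire effect of population structure and update rule and equals the ratio of
two neutral stationary averages,

    ``sigma = <I_AA * N_B>_0 / <I_AB * N_B>_0``,

where ``I_AA`` (``I_AB``) counts games A-players play with A-players
(B-players), each A-A game counted twice, and ``N_B`` is the number of
B-players.  This module evaluates those averages exactly for circular
group-structured populations as finite sums of the coalescent kernels in
:mod:`groupsigma.kernels`, for any isotropic migration pattern, any mutation
and migration probability, and any finite ``N >= 3``.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import kernels
from .errors import DegenerateParameterError, InvalidParameterError
from .kernels import MigrationPattern, ModelParams

__all__ = [
    "SigmaResult",
    "PayoffMatrix",
    "triplet_probability",
    "sigma_exact",
    "sigma_global_closed",
    "sigma_approx",
    "sigma_tilt",
    "relative_difference",
    "critical_ratios",
    "favors_A",
]


@dataclass(frozen=True)
class SigmaResult:
    """A structural coefficient with the two stationary averages that define it.

    ``numerator`` and ``denominator`` are ``<I_AA * N_B>_0`` and
    ``<I_AB * N_B>_0`` up to one common positive factor, so only their ratio
    ``sigma`` is physically meaningful.  ``include_self`` records whether
    self-games contributed to ``I_AA``.
    """

    sigma: float
    numerator: float
    denominator: float
    include_self: bool

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "include_self": self.include_self,
        }


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 payoff matrix ``[[a, b], [c, d]]`` in strategy order (A, B)."""

    a: float
    b: float
    c: float
    d: float

    @staticmethod
    def prisoners_dilemma(benefit: float, cost: float) -> "PayoffMatrix":
        """Donation-game parametrisation ``[b - c, -c; b, 0]``."""
        return PayoffMatrix(benefit - cost, -cost, benefit, 0.0)

    @staticmethod
    def snowdrift(benefit: float, cost: float) -> "PayoffMatrix":
        """Snowdrift parametrisation ``[b - c/2, b - c; b, 0]``."""
        return PayoffMatrix(benefit - cost / 2.0, benefit - cost, benefit, 0.0)


def _check_pattern(p: ModelParams, pat: MigrationPattern) -> None:
    if pat.M != p.M:
        raise InvalidParameterError(
            f"pattern is defined on M={pat.M} groups but parameters have M={p.M}"
        )


def _theta(f: float, p: ModelParams) -> float:
    """Mixed three-lineage term ``Phi_1 Psi_2 + Phi_2 Psi_1 + Phi_3 alpha_1`` at ``f``."""
    psi1, psi2 = kernels.pair_kernels(f, p)
    phi1, phi2, phi3 = kernels.triple_kernels(f, p)
    return phi1 * psi2 + phi2 * psi1 + phi3 * kernels.mutation_alpha(p)


def triplet_probability(
    d1: int, d2: int, d3: int, p: ModelParams, pat: MigrationPattern
) -> float:
    """Neutral stationary probability of a strategy-and-co-location triplet event.

    For three individuals sampled uniformly at random without replacement and
    labelled 1, 2, 3, returns ``Pr(s1=d1, s2=d2, s3=d3, individuals 2 and 3
    share a group)`` under neutral stationarity.  The value is a structure-
    function sum with one of three integrands depending on the agreement
    pattern of the strategy bits:

    * all three equal:          ``3 Psi_1 + 3 Psi_2 + 2 Theta``
    * bit 1 pairs with 2 or 3:  ``3 Psi_1 - 3 Psi_2``
    * bits 2, 3 pair against 1: ``3 Psi_1 + 3 Psi_2 - 2 Theta``

    each divided by ``24 M``, where
    ``Theta = Phi_1 Psi_2 + Phi_2 Psi_1 + Phi_3 alpha_1``.
    """
    if any(d not in (0, 1) for d in (d1, d2, d3)):
        raise InvalidParameterError("strategy indicators must be 0 or 1")
    _check_pattern(p, pat)
    total = 0.0
    for f in pat.f:
        psi1, psi2 = kernels.pair_kernels(f, p)
        if d1 == d2 == d3:
            total += 3.0 * psi1 + 3.0 * psi2 + 2.0 * _theta(f, p)
        elif d2 == d3:  # d1 differs from the co-located pair
            total += 3.0 * psi1 + 3.0 * psi2 - 2.0 * _theta(f, p)
        else:  # d1 agrees with exactly one of d2, d3
            total += 3.0 * psi1 - 3.0 * psi2
    return total / (24.0 * p.M)


def _sigma_sums(p: ModelParams, pat: MigrationPattern) -> tuple[float, float]:
    """Structure-function sums ``sum_x (3Psi1 + 3Psi2 - 2Theta)`` and ``sum_x (3Psi1 - 3Psi2)``."""
    num = 0.0
    den = 0.0
    for f in pat.f:
        psi1, psi2 = kernels.pair_kernels(f, p)
        num += 3.0 * psi1 + 3.0 * psi2 - 2.0 * _theta(f, p)
        den += 3.0 * psi1 - 3.0 * psi2
    return num, den


def sigma_exact(
    p: ModelParams, pat: MigrationPattern, include_self: bool = False
) -> SigmaResult:
    """Exact structural coefficient for any isotropic migration pattern.

    Without self-interaction,

        ``sigma = (N-2) sum_x (3Psi1 + 3Psi2 - 2Theta) / (N sum_x (3Psi1 - 3Psi2))``,

    all kernels evaluated at ``f(x)``.  With self-interaction the numerator
    gains ``+ 6 M (1 - alpha_1)``: each A-player also plays itself, which adds
    the pair event ``Pr(s1=1, s2=0) = (1 - alpha_1)/4`` on the same ``24 M``
    normalisation.  Requires ``u > 0``: without mutation both stationary
    averages vanish (the population fixes on one strategy) and sigma is a
    0/0 form.
    """
    if p.u == 0.0:
        raise DegenerateParameterError(
            "sigma is a 0/0 form at u = 0: without mutation the stationary state "
            "is monomorphic and both <I_AA N_B>_0 and <I_AB N_B>_0 vanish"
        )
    _check_pattern(p, pat)
    num_sum, den_sum = _sigma_sums(p, pat)
    numerator = (p.N - 2) * num_sum
    if include_self:
        numerator += 6.0 * p.M * (1.0 - kernels.mutation_alpha(p))
    denominator = p.N * den_sum
    return SigmaResult(
        sigma=numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        include_self=include_self,
    )


def sigma_global_closed(p: ModelParams) -> SigmaResult:
    """Closed-form sigma for global migration, self-interaction included.

    With dispersal uniform over the other ``M - 1`` groups the structure sum
    collapses to scalar coefficients (:func:`groupsigma.kernels.global_coefficients`):

        ``sigma_ac = [(N-2)(3(1-a1) + (M-1)(3 a2 + 3 a3 - 2 t1 a1 - 2 t2 a2 - 2 t3 a3))
        + 6 M (1-a1)] / [3 N (1 - a1 + (M-1)(a2 - a3))]``.

    Algebraically identical to
    ``sigma_exact(p, global_pattern(M), include_self=True)``.
    """
    if p.u == 0.0:
        raise DegenerateParameterError("sigma is a 0/0 form at u = 0")
    a1, a2, a3, t1, t2, t3 = kernels.global_coefficients(p)
    numerator = (p.N - 2) * (
        3.0 * (1.0 - a1)
        + (p.M - 1) * (3.0 * a2 + 3.0 * a3 - 2.0 * t1 * a1 - 2.0 * t2 * a2 - 2.0 * t3 * a3)
    ) + 6.0 * p.M * (1.0 - a1)
    denominator = 3.0 * p.N * (1.0 - a1 + (p.M - 1) * (a2 - a3))
    return SigmaResult(
        sigma=numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        include_self=True,
    )


def sigma_approx(p: ModelParams) -> float:
    """Large-population approximation ``sigma_ap`` for global migration.

    Expressed in the scaled rates ``mu = N u`` and ``nu = N v``; derived under
    exponentially distributed coalescence times and Poisson event counts along
    lineages, so it is accurate for large ``N`` and small ``u, v``.
    Self-interaction is included, matching :func:`sigma_global_closed`.  For
    ``M = 1`` both correction terms vanish identically and the value is 1.
    """
    M = p.M
    if M == 1:
        # Both bracketed numerators are identically zero at M = 1; the 0/0
        # limit is 1, consistent with the large-N well-mixed value (N-2)/N -> 1.
        return 1.0
    mu, nu = p.mu, p.nu
    n1 = 2.0 * (3 - 6 * M + 3 * M**2 + mu - 2 * M * mu + M**2 * mu)
    d1 = (3 + M + mu + M * mu) * (-3 + 3 * M - mu + M * mu + M * nu)
    n2 = 2.0 * (
        1 - 3 * M + 3 * M**2 - M**3
        + mu - 3 * M * mu + 3 * M**2 * mu - M**3 * mu
        + M * nu - 2 * M**2 * nu + M**3 * nu
        + M * mu * nu - 2 * M**2 * mu * nu + M**3 * mu * nu
    )
    d2 = (3 + M + mu + M * mu) * (
        1 - 2 * M + M**2
        + mu - 2 * M * mu + M**2 * mu
        - 2 * nu + 2 * M * nu
        - mu * nu + M * mu * nu + M * nu**2
    )
    if d1 == 0.0 or d2 == 0.0:
        raise DegenerateParameterError(
            "the approximate sigma has a vanishing denominator at these (M, mu, nu)"
        )
    return 1.0 + n1 / d1 + n2 / d2


def sigma_tilt(p: ModelParams, pat: MigrationPattern) -> float:
    """The tilt ``(sigma - 1)/(sigma + 1)`` for the no-self-interaction sigma.

    Computed directly as

        ``1 - N sum_x (3Psi1 - 3Psi2) /
        sum_x ((3N-3) Psi1 - 3 Psi2 - (N-2) Theta)``,

    which is the prisoner's-dilemma critical cost-to-benefit ratio and is
    monotone decreasing in the mutation probability ``u``.
    """
    if p.u == 0.0:
        raise DegenerateParameterError("the tilt is undefined at u = 0 (sigma is a 0/0 form)")
    _check_pattern(p, pat)
    den = 0.0
    half_sum = 0.0
    for f in pat.f:
        psi1, psi2 = kernels.pair_kernels(f, p)
        den += 3.0 * psi1 - 3.0 * psi2
        half_sum += (3.0 * p.N - 3.0) * psi1 - 3.0 * psi2 - (p.N - 2) * _theta(f, p)
    return 1.0 - p.N * den / half_sum


def relative_difference(p: ModelParams) -> float:
    """Relative error ``|sigma_ac - sigma_ap| / sigma_ac`` of the approximation.

    Shrinks as ``N`` grows, as ``M`` shrinks, and as ``u`` or ``v`` decreases.
    """
    ac = sigma_global_closed(p).sigma
    ap = sigma_approx(p)
    return abs(ac - ap) / ac


def critical_ratios(sigma: float) -> tuple[float, float]:
    """Critical cost-to-benefit ratios ``(c/b)*`` implied by a structural coefficient.

    Cooperation is favored over defection when ``c/b`` falls below
    ``(sigma - 1)/(sigma + 1)`` in the prisoner's dilemma
    (payoffs ``[b-c, -c; b, 0]``) and below ``2 sigma/(sigma + 2)`` in the
    snowdrift game (``[b-c/2, b-c; b, 0]``).  Both thresholds increase with
    sigma, so a larger structural coefficient widens the window for
    cooperation.
    """
    if sigma <= 0.0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    return (sigma - 1.0) / (sigma + 1.0), 2.0 * sigma / (sigma + 2.0)


def favors_A(sigma: float, m: PayoffMatrix) -> bool:
    """Whether strategy A is more abundant than B on average under weak selection.

    True iff ``sigma * a + b > c + sigma * d`` (strict).
    """
    if sigma <= 0.0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    return sigma * m.a + m.b > m.c + sigma * m.d
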