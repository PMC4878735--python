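# Methods

## Model

A haploid population of fixed size `N ≥ 3` lives on `M` groups arranged on a
circle. Each individual carries a strategy bit (A or B) and a group label.
Individuals play a 2×2 game with every other member of their own group
(optionally also with themselves) and accumulate the total payoff `p_i`;
fitness is `1 + w·p_i` with selection intensity `w`.

One generation is one birth-death event of the frequency-dependent Moran
process:

1. a reproducer is drawn with probability proportional to fitness (uniformly
   under neutrality, `w = 0`);
2. a dying individual is drawn uniformly from all `N`, the reproducer
   included;
3. the dying slot is filled by the offspring, which keeps the parent's
   strategy with probability `1 − u` and otherwise re-draws uniformly from
   {A, B} (net switch probability `u/2`), and stays in the parent's group with
   probability `1 − v`, otherwise migrating uniformly over the distinct groups
   within circular displacement `±1..±r` (global migration: uniformly over
   all other `M − 1` groups).

The "re-draw uniformly" mutation convention (rather than "always switch") is
forced by the two-strategy structure function `g(x) = 1/2 + cos(πx)/2`, whose
non-trivial eigenvalue is 0 — i.e. one mutation event completely randomises
the strategy. The exact-chain oracle confirms this convention: the closed
forms match the enumerated stationary distribution only under it.

## Structure functions

Every isotropic migration kernel on the circle is represented by its
structure function `f(x)`, `x = 1..M` — the cosine transform of the one-step
displacement distribution, with `f(M) = 1` (displacement M ≡ 0) and the
mirror symmetry `f(x) = f(M−x)`. Range-`r` migration gives
`f(x) = (1/r) Σ_{k≤r} cos(2πkx/M)`; for even `M` with `r = M/2` the antipodal
group is reachable one way only and the kernel coincides with global
migration, `f(x) = −1/(M−1)` off-diagonal. The structure functions are
evaluated as explicit finite cosine sums (with `math.fsum`), and the global
closed form is kept as an internal cross-check; for `M` up to a few hundred
the two agree to better than 1e−12, comfortably inside the validation
tolerance of the `MigrationPattern` type.

## The structural coefficient

σ is the ratio `⟨I_AA·N_B⟩₀ / ⟨I_AB·N_B⟩₀` of neutral stationary averages.
Both averages are linear in the probabilities that three sampled individuals
carry given strategies with two of them co-located, and those probabilities
are finite sums over `f(x)` of scalar two- and three-lineage kernels
(`Ψ₁, Ψ₂`, `Φ₁, Φ₂, Φ₃`, `α₁`). The package exposes:

- `sigma_exact` — the general finite-`N` formula for any pattern, with or
  without self-interaction. The self-interaction correction `+6M(1−α₁)` in
  the numerator is the ordered-pair probability `Pr(s₁=1, s₂=0) = (1−α₁)/4`
  expressed on the same `24M` normalisation as the triplet sums; the
  enumeration oracle verifies this normalisation directly.
- `sigma_global_closed` — the scalar closed form for global migration
  (self-interaction included); algebraically identical to `sigma_exact` on
  the global pattern (asserted to 1e−12 on random draws).
- `sigma_approx` — the classical large-`N` approximation in the scaled rates
  `μ = Nu`, `ν = Nv`, for comparison. At `M = 1` both of its correction
  numerators vanish identically while the printed denominators can also
  vanish, so the implementation returns the limit value 1 there instead of
  raising; zero denominators at `M ≥ 2` raise a degenerate-parameter error.
- `sigma_tilt` — `(σ−1)/(σ+1)` in a directly-evaluated form whose
  monotone decrease in `u` is transparent; equals the ratio built from
  `sigma_exact` to 1e−10.

Useful exact limits, all covered by tests: `M = 1` or `v = 0` give
`σ = (N−2)/N` without self-interaction and exactly 1 with it; at `v = 0` the
population inevitably collapses into a single group, which is why σ < 1
there — the mirror-pair counting identity `Σ(I_AA−I_AB)N_B = −2xy` over the
states `(x, y)` and `(y, x)` is negative whenever both strategies coexist.

## Degenerate inputs

σ is defined only under mutation: at `u = 0` the stationary state is
monomorphic and both averages vanish, so `sigma_exact` raises a typed
degenerate-parameter error rather than returning NaN. The enumeration oracle
likewise refuses `u = 0` and `v = 0` (reducible chains); the `v = 0` limit is
handled analytically as above.

## Simulator and estimator

`run_neutral_sigma` estimates σ as the ratio of time averages of `I_AA·N_B`
and `I_AB·N_B`, updated in O(1) per event from per-group strategy tallies.
Choices the underlying theory does not dictate, fixed here as conventions:

- initial state uniform random (strategies fair coin, groups uniform);
- burn-in defaults to 5% of the run length;
- the standard error comes from 100 batch-means ratios of contiguous blocks;
- one seeded `random.Random` generator per run; identical seed and
  configuration give bit-identical trajectories.

The simulator supports `w > 0` through fitness-proportional reproduction (and
raises a configuration error if `1 + w·p_i` can turn non-positive), but the σ
estimator itself is defined under neutrality and rejects `w ≠ 0`.

## Exact enumeration oracle

For tiny `(N, M)` the neutral chain is enumerated exactly and its stationary
law solved as a dense linear system (residual ≤ 1e−12). Because the dynamics
depends only on the counts of (strategy, group) categories, the chain lumps
exactly onto multisets of size `N` over `2M` categories; the lumped chain is
the default and is validated against the raw `(2M)^N`-state chain at
`(N, M) = (3, 2)` to 1e−10. A guard refuses raw chains beyond 1e5 states.
The oracle computes σ and the triplet probabilities *from their definitions*
(stationary averages of directly-counted observables), making it an
independent check of every closed form; agreement at 1e−8 over
`(N, M) ∈ {(3,2), (4,2), (3,3)}` and `(u, v) ∈ {0.1, 0.5, 0.9}²` is the
package's headline acceptance test.

## What a green test establishes — and what it does not

The Monte-Carlo agreement test runs 2×10⁶ generations at `N = 20, M = 5`
(seconds of runtime), not the 10⁹-generation, `N = 100` scale one would use
for publication figures; it establishes that the simulator and the closed
forms agree within 3 standard errors at small scale, not that every
large-scale figure is reproduced. The qualitative claims — σ decreasing in
`u`, an interior migration-probability maximum, the longest range winning at
low `v` and the shortest at high `v`, the approximation error shrinking with
`N` and with fewer groups — are asserted on deterministic closed-form grids
and hold exactly, not statistically.

## Known limitations

- Only two strategies; the multi-strategy generalisation of the kernels is
  out of scope.
- Only isotropic kernels on the circular group lattice; no weighted or
  anisotropic migration, and none of the graph-, set- or phenotype-structured
  variants of σ.
- Abundance under finite selection intensity is not predicted; the package
  evaluates the weak-selection condition `σa + b > c + σd` only.
- The enumeration oracle is intentionally capped at tiny populations; it is a
  correctness instrument, not a production path.
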