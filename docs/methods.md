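# Methods

## Model

The state of the network is a vector of activation levels x ∈ [0,1]^n, one
coordinate per protein.  Dynamics follow the fuzzy-logic interpolation of
Boolean regulatory rules (Mendoza & Xenarios, *Theor. Biol. Med. Model.*
2006): each node relaxes at rate γ toward a production term A(ω), where ω
is the fuzzy aggregate of its regulators and A a normalised sigmoid,

    dx_n/dt = A(ω_n) − γ x_n .

**Input aggregation ω.**  With activator sum s_a = Σ_k α x_k over the
activators of n (total weight W_a = Σ α) and inhibitor sum s_i = Σ_l β x_l
(weight W_i), ω is the activator factor ((1+W_a)/W_a)·s_a/(1+s_a) when the
node has only activators, one minus the analogous inhibitor factor when it
has only inhibitors, and the product of the two factors when it has both.
The factors are saturating Michaelis–Menten-type terms rescaled so that a
fully active regulator set drives the factor to exactly 1; the product form
makes full inhibition veto full activation (ω = 0 when all inhibitors sit
at 1), which is the fuzzy counterpart of "NOT wins" in the Boolean rule.
ω is clipped to [0,1] against rounding.

**Activation function.**  A(ω) = (e^{−h(ω−0.5)} − e^{0.5h}) /
((1−e^{0.5h})(1+e^{−h(ω−0.5)})) with gain h > 0.  The *product* of the two
denominator factors is essential: it is the only normalisation for which
A(0)=0, A(0.5)=0.5 and A(1)=1 hold exactly for every h (a summed
denominator, which sometimes appears in print, satisfies none of them).
The implementation evaluates the algebraically equivalent rescaled form
(e^{−hω}−1)/((e^{−0.5h}−1)(1+e^{−h(ω−0.5)})) so large gains do not
overflow, and switches to the exact Boolean step for 0.5·h beyond the
double-precision exponent range.

**Special nodes.**  Clamped nodes have their initial value overwritten by
the clamp value and their derivative fixed at zero — the constraint is
exact, with no solver chatter.  Nodes without regulators ("input" nodes)
have no defined ω; they hold their initial value (an implicit clamp) and a
warning is logged, because decay-to-zero would silence every root stimulus
and make clamping experiments meaningless.

## Parameters

| parameter | default | meaning |
|---|---|---|
| h | 10 | sigmoid gain; 10 gives smooth semi-quantitative behaviour, ≥50 approaches the Boolean limit |
| γ | 1 | first-order decay rate (per model time unit) |
| α, β | 1 | activator/inhibitor edge weights (homogeneous) |
| t_end | 30 | integration horizon; the system typically equilibrates well within it at γ=1 |
| t_max | 300 | cap when extending unconverged runs in t_end-sized chunks |
| ss_tol | 1e−6 | steady-state threshold on max \|dx/dt\| |
| rel_tol / abs_tol | 1e−6 / 1e−8 | adaptive-integrator tolerances |
| cluster_tol | 0.01 | attractor-identity tolerance (Chebyshev distance) |
| phenotype margin | 0.1 | dead band of the anabolic-vs-catabolic call |

Model time is artificial — no mapping to physical seconds is attempted or
claimed.

## Numerics

Default integrator: adaptive Runge–Kutta 4(5) (`scipy.integrate.solve_ivp`,
RK45 — the ode45 analogue).  A hand-written fixed-step RK4 (dt = 0.01) is
provided as an independent cross-check mode; the two agree to 1e−4 per
coordinate on the motif suite (verified in tests).  Convergence is judged
from the exact right-hand side at the chunk end, not from solver step
sizes; a run is converged when max |dx/dt| ≤ ss_tol.  Unconverged runs
(e.g. sustained oscillations) are returned flagged, never discarded
silently.  Trajectories are mathematically confined to [0,1]^n (0 ≤ A ≤ 1,
linear decay); sub-tolerance numerical excursions are clipped.  Fixed-point
search (used to build the motif inventories) runs Newton iterations from a
coordinate grid and classifies stability from the numerical Jacobian.

With the default tolerances the numerical trajectory contracts onto the
attractor far below ss_tol on all tested networks, so converged steady
states satisfy the residual identity ‖A(ω*) − γx*‖∞ ≤ 1e−6 directly.

## Protocols

**Baseline ensemble.**  100 runs by default; run k draws its initial state
uniformly from [0,1]^n using a Mersenne-Twister stream seeded seed_base+k
(seed_base defaults to 0, so runs use seeds 0…99).  Steady states are
grouped by single-linkage agglomeration under the Chebyshev metric at
cluster_tol; the dominant fraction is the largest cluster's share of
converged runs.  Per-node summaries report median, quartiles, 1.5×IQR
whiskers, outlier counts and the skewness sign (the distributions are
typically narrow and skewed, so medians are the robust location summary).

**Perturbation and rescue.**  Perturbations continue each baseline run's
steady state under the new clamp set, so perturbed run k is a deterministic
function of baseline run k (paired design).  Rescue experiments first
equilibrate the degenerate clamp set, then apply the rescue clamps on top
of the degenerate steady states; applying both clamp sets simultaneously
from the original baseline is available as an alternative mode, since
either reading of "stimulating a degenerate baseline" is defensible.
Node-wise shifts use the two-sided Mann–Whitney U with U = min(U1, U2):
exact null when min(n1,n2) ≤ 20 and the pooled sample is tie-free,
otherwise the normal approximation with tie correction; two identical
constant samples short-circuit to U = n1·n2/2, p = 1.  α = 0.05, no
multiple-testing correction — the screen is intentionally per-node.
The phenotype call averages ACAN, COL2A and the growth factors (anabolic
index) against the degrading enzymes and pro-inflammatory cytokines
(catabolic index), with a ±0.1 dead band for "balanced".

**Sensitivity.**  A full factorial over p factor nodes at levels {0,1}
(2^p rows, last factor fastest).  Factor levels are *initial values only*,
never clamps — the screen asks which initial stimulations tip the system,
not which sustained inputs hold it.  Non-factor nodes start from a
declared background state, by default the baseline ensemble's per-node
median (deterministic); a from-random alternative can be passed
explicitly.  Effects (mains and all second-order interactions) are 1-df
±1-coded contrasts; for contrast column c, the coefficient is b = cᵀy/N
and the effect sum of squares N·b², which on a balanced orthogonal design
equals the classical between-group sum of squares (the tests verify this
against a brute-force cell-means oracle).  MSW is the residual mean square
after removing all modelled effects.  The reported statistic is
(MSB/MSW)×100; p-values come from the *unscaled* ratio on (1, N−1−k) df,
because the ×100 is presentational and would invalidate the F reference
distribution.  Per-response records are aggregated to the two response
groups — structural proteins {ACAN, COL1A, COL2A} and degrading enzymes
{ADAMTS4/5, MMP1, MMP2, MMP3, MMP9, MMP13} — by max-F with
any-member-significant logic; analysing per node and then aggregating was
chosen over pooling responses before the ANOVA, because pooling would mix
scales across proteins.  The Pareto table keeps p ≤ 0.05 effects, sorts by
F (infinite-F, i.e. perfectly modelled responses, first; ties broken by
effect then response name) and attaches log10(F) for plotting; the
cytokine view conventionally restricts to main effects for legibility,
the growth-factor view keeps interactions.

## Synthetic data

The generator emulates the statistical shape of a curated disc-cell
corpus: hub-dominated connectivity (preferential attachment with exponent
hub_bias, default 1), roughly a third inhibitory edges (default 0.35 —
configurable, as the real fraction is not printed anywhere), and exact
degree-of-connectivity pins for named nodes.  Constraint satisfaction runs
first (greedy largest-deficit pairing, preferring unused partner pairs, so
a single 6-DoC pin on a 6-edge budget yields a star); remaining edges
attach preferentially among unconstrained nodes; direction flips (which
preserve DoC) guarantee a minimum in-degree where requested.  Everything
is deterministic per seed, and infeasible specifications fail before
sampling.

The 33-protein / 153-interaction fixture carries the published node names,
functional categories and the eight published hub DoC values (IL-4 19,
IL-10 18, TGF-β 15, TIMP1/2 9, IGF1 8, GDF5 6, CCN2 3, TIMP3 3).  Signs
follow category-level plausibility rules (pro-inflammatory cytokines
inhibit structural proteins and induce proteases, growth factors do the
opposite, TIMPs inhibit proteases, …) with the remaining signs drawn to
approach the target inhibitory fraction.  Its *edge placement is
synthetic*: the fixture reproduces the corpus's size, category structure
and hub statistics, not its true wiring, so quantitative conclusions about
disc biology require the real corpus file (accepted as input by every
entry point).  Every fixture node is guaranteed at least one regulator;
free input nodes would hold their random initial values and make a global
attractor impossible by construction.  Passing tests on the fixture
demonstrate the correctness and robustness of the machinery, not
biological predictions.

Toy motifs (activating/inhibiting cascades, the mutual-inhibition toggle,
an incoherent feed-forward loop, a negative-feedback ring) ship with
stable-fixed-point inventories recomputed at generation time by grid-seeded
Newton search at h=10, γ=1.  The negative-feedback ring deliberately has
no stable fixed point at h=10 — it oscillates within bounds and exercises
the unconverged-run path.

## Problem sizes

The test suite and the acceptance script run the 100-run baseline, the
paired TNF perturbation and the 2^5 growth-factor screen on the 33-node
fixture (a few hundred integrations, seconds on one CPU).  The 2^15
cytokine design is generated and validated in full; running all 32,768
integrations is a production-scale job and is left to the user (the
machinery is identical — `run_design` accepts any design).

## Known limitations

- Point attractors only: the ensemble machinery clusters steady states;
  limit cycles are reported as unconverged runs, not characterised.
- Homogeneous α, β: per-edge weights are out of scope.
- No intracellular pathways, delays, or stochastic dynamics; clamp values
  other than {0,1} are supported mechanically but carry no concentration
  calibration.
- The sign rules of the synthetic fixture constrain direct edges only;
  net (path-mediated) effects in a synthetic topology can oppose the
  direct-edge sign.
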