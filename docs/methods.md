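# Methods

## Model

Each gene in a signed regulatory circuit is one dynamical variable — total
expression, with no mRNA/protein split, no delays and no compartments. Node
`i` has a maximal production rate `g_i` (10⁶ molecules·hr⁻¹) and a
first-order degradation rate `k_i` (hr⁻¹); every edge carries a shifted
Hill factor `H_s(B) = H⁻(B) + λ·H⁺(B)` with threshold `B0` (10⁶ molecules),
integer cooperativity `n` and fold change `λ` (λ > 1 activation, λ < 1
inhibition). Multiple regulators of one target combine multiplicatively on
a single basal rate:

    dX_i/dt = g_i · Π_e H_s(X_src(e)) − k_i · X_i

so an unregulated node settles at `g/k` and every fixed point lies inside
`[g/k·Π min(1,λ), g/k·Π max(1,λ)]` per node — a fact used both for
sampling initial conditions and for seeding root searches.

The bundled wild-type circuit has four nodes (HNF4A, HNF1A, PPARG, SREBF1),
four self-activations, four cross-activations within the hepatic and
adipocytic pairs, and two inhibitions between the pairs. The bundled
literature parameterization (config `data/literature_params.yaml`) fixes
the rates from reported protein abundances and half-lives
(`k = ln 2 / t_half`); its PPARG degradation rate of 0.08 hr⁻¹ lies inside
the bistable hepatocyte/hybrid window.

## Random-circuit ensembles

Parameters are sampled per model: production uniform on (1, 100),
degradation uniform on (0.1, 1), activator fold change uniform on (1, 100)
and inhibitor fold change its reciprocal, cooperativity integer-uniform on
{1..6}. Thresholds follow the half-functional rule: for an edge from gene
A, `B0 ~ U(0.02·M_A, 1.98·M_A)` where `M_A` is the median level of A under
randomization. `M_A` is estimated once per topology by a self-consistent
Monte Carlo (level distributions rebuilt from the previous round's
regulator levels and medians, five rounds, 2·10⁵ samples, fixed internal
seed); in the realized wild-type ensemble every regulator then sits above
its threshold in 49–51% of steady states, which is the property the rule is
named for. A one-step estimate that ignores regulation of the source gene
misses this badly (36–40%), and centering thresholds on the *unregulated*
median makes strongly inhibited regulators essentially never functional,
suppressing almost all multistability — that variant is clearly not the
intended convention.

Each model derives its own PCG64 substream from the master seed by
counter, so results are reproducible and a shorter ensemble is a prefix of
a longer one. Variant topologies reuse the same substreams and draw order,
so comparisons across topologies differ only by edge signs.

Initial conditions are log2-uniform over the per-node attainable range
(see above), `n_init = 100` per model by default. Integration is explicit
Euler with `dt = 0.2` hr; a trajectory is converged when every node's
relative change over a 5-hour probe window falls below 10⁻⁵, within a
500-hour horizon. Non-converged runs (≈0.3%, mostly oscillatory or
critically slowed parameter sets) are discarded; a model with no converged
run is flagged. Converged endpoints merge into distinct states when all
nodes agree within 1% relative in log2 (absolute floor 0.01); the stored
state is the basin-weighted centroid. Models with more than
`max_states = 4` distinct states are flagged and excluded from downstream
tallies (their fraction is itself a reported statistic). These numerical
choices were fixed by cross-integrator agreement: state counts are
identical between Euler at dt = 0.2/10⁻⁵, Euler at dt = 0.1/10⁻⁶, and
adaptive Cash–Karp RK45 (rtol 10⁻⁸) on 300-model samples. A coarser preset
(`IntegrationSettings.fast()`, dt = 0.5) changes counts on ~0.3% of models
and is used only for the 45-network variant screen, identically across all
networks compared.

One caveat discovered during validation: on ~0.1–0.3% of sampled models a
thin-basin state (reached by ~1 of 50 initial conditions) sits behind a
near-saddle passage, where basin assignment is accuracy-limited for any
integrator — Newton root-finding confirms the state is real, but Euler and
RK45 can assign the single critical trajectory differently. Exact
integrator invariance of per-model state counts therefore holds for ≥99%
of models rather than all of them; aggregate statistics are unaffected.

## State classification

Pooled log2 steady-state levels are z-normalized per gene with the
population standard deviation (divide by n; fixed for testability).
Bimodality is Sarle's coefficient for finite samples,
`b = (g² + 1)/(k + 3(n−1)²/((n−2)(n−3)))` with population (biased) skewness
`g` and excess kurtosis `k`, whose n-correction presumes exactly those
moment conventions; `b > 5/9` (the uniform-distribution value) flags a
multimodal gene. A bimodal gene is thresholded at the interior minimum of a
Scott's-rule Gaussian KDE between its two highest modes (ties broken toward
the mode midpoint); a gene that fails the bimodality check, or has no
interior minimum, falls back to a z = 0 threshold with a warning. Calls
above threshold are H, below are L.

A steady state maps to a 4-letter H/L label (16 bins; the state-frequency
distribution over all retained states is normalized to 1) and to a 2-letter
label over the HNF4A/PPARG pair: HL hepatocyte, LH adipocyte, HH hybrid, LL
uncommitted. A model's *phase* is its set of co-existing pair labels. In
phase tallies restricted to n-stable models, only models whose states carry
distinct labels count (two states differing only in HNF1A/SREBF1 would
otherwise collapse); such label-degenerate models are rare and are excluded
from phase-specific analyses, including relative stability, where basin
attribution per label would be ambiguous. Ward-linkage agglomerative
clustering (k = 4, z-space Euclidean distance) provides the complementary
quadrant view used on scatter data.

## Relative stability, bifurcation, switching

Relative stability of a phase: models with exactly that phase are
re-simulated from fresh log2-uniform initial conditions (default 1000),
endpoints are matched to the model's known states by nearest log2
distance, and per-state convergence fractions are collected (they sum to 1
per model over converged runs).

Bifurcation scans locate all equilibria at each grid value of the swept
degradation rate by multi-start Newton (log-uniform starts plus the
attainable-range corners, analytic Jacobian), accept roots by a
rate-scaled residual test (|f_i| / (g_i + k_i|x_i|) < 10⁻⁹ — an absolute
test fails across the 10⁴-fold spread of sampled rate scales), classify
stability by Jacobian eigenvalues, stitch branches by nearest-neighbor
continuation, and refine fold points by bisection on the equilibrium
count. Quasi-static hysteresis sweeps relax the system at each grid value
from the previous endpoint, up then down; the sweep must span both folds to
display the loop.

Stochastic switching uses Euler–Maruyama,
`X ← X + f(X)·dt + a·ξ·√dt` (ξ standard normal, per-gene amplitude `a`,
levels clipped at 0), with dt = 0.01 hr. Default amplitudes are 0.1 for
HNF4A, HNF1A and SREBF1 (intrinsic noise) and 15 for PPARG (intrinsic plus
the extrinsic fatty-acid burden). The original analysis integrated the
noisy system with an adaptive deterministic solver, which is not a
convergent SDE scheme; with the fixed-step scheme here the amplitudes
reproduce the qualitative switching regime — repeated transitions between
hepatocyte and hybrid states with mean residence on the order of months —
rather than any particular trace. Attractor occupancy is the nearest
deterministic attractor in log2 space with a 5-sample dwell debounce
against noise flickers; switch events and residence times derive from it.

## Topology scoring

Sign shuffles enumerate all C(10,2) = 45 assignments of the two
inhibitions over the fixed wiring and drop the wild type (44 variants);
self-loop mutants enumerate all 2⁴ = 16 subsets of the self-activations
(codename tokens 4a/1a/g/f1, "null" = none). The Jensen–Shannon divergence
between 16-bin state-frequency distributions uses base-2 logarithms so
JSD ∈ [0, 1], with 0·log(0) = 0; `jsd(P, P) = 0` exactly and disjoint
supports give 1. The square root — the Jensen–Shannon *distance*, the
metric form — is reported alongside, and is the form in which the
44-variant screen's minimum separation (~0.24 at 2000 models per network)
is quoted: the divergence and the distance coincide at the endpoints 0 and
1 but differ in between, and the distance is what comparisons of
"distributional distance" conventionally mean. Plasticity is
N(multistable)/N(all) over retained models.

## Synthetic cohorts

The cohort generator draws per-group multivariate normal log2 expression
(a Gaussian copula with normal margins) with configurable per-gene means,
sds and a shared correlation matrix (validated symmetric PSD, unit
diagonal). The default design uses 50 healthy and 50 NASH samples — the
scale of the public liver cohorts this stage emulates — with NASH shifts of
−1 log2 on HNF4A/HNF1A and +1 log2 on PPARG/SREBF1 and correlations
matching the circuit's predicted sign structure (HNF4A–PPARG −0.5,
HNF4A–HNF1A +0.5, PPARG–SREBF1 +0.5, remaining cross terms −0.3…−0.4).
What it emulates: log2-normalized array data with realistic group sizes,
effect sizes and correlation signs. What it does not: probe-level
artifacts, batch effects, outliers, non-Gaussian tails, or the actual
effect sizes of any real cohort — so passing tests demonstrate that the
statistics detect the designed structure at clinical sample sizes, not
that any particular public dataset shows it. Statistics are Spearman rank
correlation (two-sided) and the equal-variance two-tailed Student's t-test
(the plain form, no Welch correction). `ensemble_cohort` treats ensemble
steady states as pseudo-samples to link circuit predictions to the same
statistics end to end.

## Problem sizes and reproducibility

Default analysis sizes: 10⁴ models × 100 initial conditions for wild-type
ensembles (three replicate seeds for headline statistics), 2×10³ models
per network for the 45-network screen, 1000 initial conditions for
relative stability, 2×10⁴ simulated hours for switching runs. The test
suite uses the same protocols with a 1500-model shared ensemble for
classification properties. All randomness flows from explicit integer
seeds; the threshold-median Monte Carlo uses its own fixed seed so a
topology always maps to one sampling distribution.

## Known limitations

* The ensemble statistics depend on the sampling conventions; with the
  conventions above the >4-state fraction comes out near 8% (7.9–8.4%
  across ten-thousand-model replicates, mean ≈ 8.1%) and plasticity at
  0.84–0.86 — the published protocol reports 7.58% and 0.89. These are
  convention-level residuals: the original tool's exact threshold and
  state-merging internals are not recoverable from its description, and no
  parameter here was adjusted against the published values.
* Fixed-step Euler trades per-trajectory accuracy for ensemble throughput;
  the cross-integrator checks above bound the cost of that trade.
* The noise model is additive and gene-diagonal; amplitudes are not
  inferred from data.
* Total-expression variables mean no mRNA/protein timescale separation;
  switching timescales are therefore qualitative (order months).
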