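# Model and methods

`retmap` simulates the development of the retinocollicular projection as the
joint outcome of four interacting mechanisms: molecular chemoaffinity
(ephrinA/EphA gradients represented by their net effect), spontaneous retinal
waves, trophic stabilisation of synapses by correlated firing (the
synaptotrophic hypothesis), and probabilistic growth and retraction of axon
segments and synapses.  Development is emergent: no rule refers to "the map";
retinotopy, eye-specific segregation and ON/OFF segregation arise from local
stochastic events under these influences.

## Geometry

The retina is a unit disk (NT and DV axes) populated by a jittered sunflower
packing; a physical radius (default 2.25 mm, mouse-like) scales positions for
wave propagation.  The colliculus is a tapered ellipse (AP:ML = 1.6, posterior
end 25% narrower) populated at 167 cells/mm (6 µm spacing, ≈27,900 cells/mm²);
its area is `n_cells / 27,900 mm²`, so density is scale-invariant.  Every
collicular neuron has a 25 µm-radius dendritic disk; a 10×10 µm grid indexes
dendrites for synapse targeting and stores extracellular factor
concentrations.  Temporal retina maps to anterior colliculus (high-EphA axons
are repelled from the posterior, ephrinA-rich pole), DV to ML, with the ML
coordinate scaled by the local outline half-width.  The outline equation is
a modelling choice — only the qualitative shape (longer AP axis, taper) is
constrained.

## Retinal waves (the synthetic-activity source)

Waves initiate as a spatial Poisson process at global rate
`A_retina / (mean_area × interval)`, which makes the spatially averaged
coverage rate of any retinal point exactly `1/interval`.  Origins are redrawn
(up to 10 times) away from tissue covered within the 30 s refractory window —
this biases placement without changing counts.  Each wave expands as a radial
front at a per-wave speed drawn from N(130, 10) µm/s and stops when the area
it covers inside the retina reaches an exponential target (mean 0.95 mm²,
capped at the full retina).  Covered cells burst at the front's arrival:
50 spikes at 20 Hz over 2.5 s, with per-wave participation probability 0.9.

The participation probability resolves a stated inconsistency: 90 s coverage
intervals × 50 spikes per burst give 0.556 Hz, not the quoted 0.5 Hz overall
rate; participation of 0.9 reconciles the triplet exactly
(50 × 0.9 / 90 = 0.5 Hz) while leaving interval and burst structure intact.

ON/OFF mode: each wave drives three burst cycles (4 s period).  OFF cells
join every covering wave (20 Hz, 2.5 s); ON cells join 67% of waves at 24 Hz
for 2.0 s and lead the OFF burst by 1 s.  The ON burst duration is a default
(the source value was not recoverable); it preserves "ON bursts more intense,
OFF bursts longer" qualitatively.  Binocular mode runs two congruent retinas;
synchronised mode replays the identical wave sequence and participation draws
in both eyes.

Trains are pre-computed per phase at 1 ms resolution and replayed, so runs
are reproducible and activity can be regenerated from seeds at resume.

Interval statistics are reported pooled (total observation time over total
interval count across sampled locations), which estimates the reciprocal mean
coverage rate without the Jensen bias of averaging per-location means.

## Chemoaffinity

All sigmoid-like decays use the family `f(x; k) = exp(-(x/k)^4)`: flat near
zero, strictly decreasing, asymptotically zero.  Chemoaffinity of a segment
at displacement (Δx AP, Δy ML) from its RGC's correct termination zone
(RC-TZ) is a product of per-axis terms

    A = f(γ_AP · s · |Δx| / L_c; k) · f(γ_LM · s · |Δy| / L_c; k)

with γ_LM = 2 γ_AP (the stronger ML response is needed for phenomenological
growth patterns along that axis), chemospecificity s (WT 1), and width
k = 0.7.  The product form (rather than a sum inside one sigmoid) was chosen
so that a blocked axis (γ = 0) contributes a neutral factor exactly.  The
broad width leaves the molecular phase with a deliberately coarse arborisation
— guidance alone cannot sharpen below it, which is what leaves room for the
activity-dependent phase to refine, mirroring the two-stage developmental
account the model embodies.

Mutants transform per-RGC profiles: ephrinA2 KO ramps s linearly from WT at
the anterior-most TZ to s/3 at the posterior-most; ephrinA5 KO sets s/3
everywhere; EphA knock-in compresses a seeded random half of RGC TZs into the
anterior third and triples their s; axis blocks zero the axis weight.  The
knockout floor s/3 mirrors the 3× knock-in gain (assumption, flagged).

## Collicular neurons

Integrate-and-fire with excitation E (summed synaptic input, not voltage):
per 1 ms step, `I ← I·exp(-1/τ_AMPA) + h·n_spikes` (τ_AMPA = 5 ms) and
`E ← E·exp(-1/τ_m) + (1-exp(-1/τ_m))·g(S)·I` (τ_m = 20 ms), threshold 2.05,
reset to zero, 2 ms absolute refractory.  Size S ∈ [0.05, 1] attenuates
inputs through `g(S) = 1/(0.2 + 0.8·S)`; the threshold is calibrated so ~3
near-coincident unit inputs fire an immature neuron and ~12 a mature one.
S relaxes toward `clip(rate/ρ, 0, 1)` with a 10 h time constant — neurons
mature when active at the 0.5 Hz target ρ and shrink back when silent.

Homeostasis: the firing-rate estimate is a 20-minute moving window updated
each second.  The synaptic scale h ∈ [0.05, 8] adapts multiplicatively,
`h ← h·exp((ρ - r)/ρ · dt/τ_h)`, with τ_h = 1800 s.  The adaptation constant
must be slower than the estimation window: faster gains produce a
limit-cycle in which h collapses while the stale rate estimate still reads
high, silencing the network (observed, and the reason for the value).
Over-active cells also down-regulate the trophic feedback they release:
multiplier `max(f((r-ρ)/ρ; 2), 0.05)`, creating presynaptic competition for
postsynaptic resources.

## Extracellular factors

Each neuron constitutively releases growth factor B (BDNF-like) at a rate
increasing with immaturity and rate deficit, and repulsive factor P
(proBDNF-like) increasing with maturity and rate excess, uniformly over the
grid squares its dendritic disk overlaps (no inter-square diffusion — release
is confined to the arbor).  Concentrations decay with τ = 5 min and are
updated once per second with the exact piecewise-constant-source solution, so
total mass with zero release decays exactly exponentially.  Rates are
normalised so a fully immature silent neuron's footprint saturates at
B = 1.0.  Release scales linearly with the rate deficit/excess (default; the
source form was not recoverable).

## Axon arbors

Axons enter anteriorly and traverse the full AP extent as a permanent trunk
of 11 µm chord segments following `y(x) = rel · half_width(x)` — holding
their relative ML position across the taper — where `rel` is set by the TZ's
ML position plus a Gaussian entry offset (SD 0.2 × ML width).  Extension
happens only at tips (heading ± 15° jitter), branching only at segments that
have extended but not branched (orthogonal, random side), retraction only at
non-trunk tips, so the tree stays connected by construction.

Growth exposure G = A·(B + 0.5·T̄) and repulsion R = (1-A)·(0.5 + P), where
T̄ is the hop-discounted sum (λ = 0.5 per hop) of synapse trophic values over
the arbor.  Event probabilities per 1-minute check:

    P(extend | tip)      = 0.5 · clip01(G - R) · f(N_seg / ω)
    P(branch | eligible) = 0.25 · clip01(G - R) · f(N_seg / ω)
    P(retract | tip)     = 0.5 · clip01(R)

with ω = segments spanning 25% of L_c (the arbor-size parameter) and N_seg
excluding the trunk.  A hard budget limits every RGC to 5 new segments per
sliding 10-minute window.  Tips carrying live synapses may retract (their
synapses are destroyed): retraction depends only on repulsion, and synapse
loss is already penalised upstream through T̄.

## Synapses

Formation is attempted per segment every 500 ms with probability
`0.4 · clip01(G) · f(N_syn/ν)` (ν = 8ω), capped at 4 synapses per segment
(the equation-adjacent statement; the figure text says 3 — both are
supported in config).  The target dendrite is drawn uniformly from those
overlapping the segment.  The postsynaptic cell accepts with probability
`f((r-ρ)/ρ; 1)` — over-active cells refuse — and never if the presynaptic
RGC already supplies ≥ 30% of its innervation.

Each synapse carries T ∈ [0, 1] (initialised 0.5 — neutral, so newcomers are
not instantly pruned by the comparative rule) and cleft bookkeeping.  On a
presynaptic spike, resident cleft pro-factor binds by the Δt-dependent
fraction `1 - exp(-Δt/τ_c)` (τ_c = 12 ms), destabilising:
`T ← T - 0.03·A·bound`; one fresh unit is added minus the bound amount.  On
a postsynaptic spike the unbound remainder converts to growth factor and
stabilises: `T ← T + 0.08·A·μ_post·(cleft - bound)` where μ_post is the
postsynaptic trophic-release modifier; the bound part destabilises as on any
event, and the cleft empties.  Conversion efficacy therefore decays with the
pre→post lag on the coincidence timescale.  τ_c = 12 ms (within the stated
"tens of milliseconds") and the stabilise:destabilise ratio were set so
that a postsynaptic cell bursting through a wave with its co-active afferents
net-stabilises them, while chance coincidences from temporally overlapping
but spatially distinct waves net-destabilise; with slower kernels the chance
coincidences win and the trophic signal carries no spatial information.

Survival is comparative.  Trophic support `T_s = 0.75·T + 0.25·T̄_local`
(T̄_local: λ-weighted mean over the other synapses of the same arbor
neighbourhood; ω = 1 and ω = 0 give the fully independent and fully
cooperative variants).  Every 500 ms two sequential checks retract a synapse
with probability `0.05 · max(0, 1 - T_s/mean) · reg(N)` where the mean is
taken over the axon's synapses (first check) and the dendrite's synapses
(second), and `reg(N) = 0.25 + 0.75·(1 - f(N/ν))` suppresses retraction in
sparse arbors.  Only below-average synapses can retract; the worst performers
go first.  The two checks are applied as independent draws per cycle (the
source's combination rule was not recoverable).

## Scheduler and phases

Cadences: 1 ms neural integration (numba kernel, active-set based; windows
with no events and no in-flight state are skipped — all traces are flushed
to exact zero once below 1e-12, making the skip bit-identical to stepping),
500 ms synapse checks, 1 s fields/rates/homeostasis, 60 s growth events and
maturation.  Phase 1 runs molecular guidance only (no spiking; trophic state
stays at initialisation; homeostatic h frozen since there is no activity to
regulate).  Phase 2 adds wave-driven spiking, trophic feedback and
homeostasis.  The combined variant enables activity from t = 0.  Every
stochastic component has a named seed stream; checkpoints serialise the full
dynamic state plus RNG states into the sqlite store and resume
bit-identically (pre-computed activity is regenerated from its seeds).

## Scale profiles and what reduced scale can show

Profiles: `tiny` (300 RGCs → 800 collicular cells, 6 h + 8 h), `reduced`
(2,515 → 6,772, 48 h + 60 h, the smallest published scale), `paper`
(10,000 → 25,000).  The property tests run a `micro` configuration
(~100 → ~400, 1 h + 2–8 h) chosen so a full developmental run takes tens of
seconds; the scenario contrasts (refinement vs none, ordering of mutant
disruption, segregation vs reversal) are qualitative and survive this
reduction, but quantitative outcomes are explicitly scale-dependent — the
relative size of an arbor to the colliculus grows as the colliculus shrinks,
and the wave-correlation footprint (≈ wave diameter / retina diameter ×
collicular length ≈ 0.24 L_c) sets a floor on how tightly activity can focus
an arbor.  Consequences at micro scale: refined termination-zone errors
plateau near that correlation floor, and disruptions in mutants are milder
than at full scale.  This mirrors the scale-dependence the model itself
demonstrates when colliculus size is varied with density held constant.

## What the synthetic activity does not emulate

Waves are phenomenological: radial fronts with deterministic arrival times,
no refractory suppression of burst amplitude, no cholinergic/glutamatergic
stage distinction, no direction bias, and no retinal circuitry.  Passing
statistics tests therefore shows the stated summary statistics are met, not
that the spatiotemporal fine structure of biological waves is reproduced.
Neurons are point integrators without inhibition, conductances or dendritic
compartments; "excitation" is summed input, not voltage.

## Numerical choices

1 ms integer timebase throughout; spike times are unique per (cell, ms).
Exponential-Euler updates for E and I; exact exponential updates for fields.
Growth uses per-minute Bernoulli draws of per-minute base probabilities.
Comparative retraction uses strict shortfall (a singleton synapse equals its
group mean and never self-retracts).  Ties in dendrite selection are broken
by the seeded synapse RNG stream.  Degenerate inputs (empty wave lists,
disconnected RGCs, monocular ocular-dominance requests) raise or return
defined sentinels rather than propagating NaNs.

## Segregation measurement

Per-cell dominance ratios (left-eye or ON share of a cell's synapses) are
built from small counts, so their distribution is discrete and a dip test
against a continuous null is misleadingly significant.  Segregation is
therefore quantified against the unsegregated *binomial* null (each
synapse's class i.i.d. with the pooled class fraction): the overdispersion
ratio (observed OD variance over the binomial expectation, ≈1 when
unsegregated) with a bootstrap p-value, and a dip test whose null resamples
binomial counts per cell.  Moran's I over the k-nearest-neighbour lattice
scores the spatial arrangement of thresholded dominance.

## Known limitations

Micro/tiny-scale runs leave some collicular cells weakly innervated, so
population rate convergence is broader than at full scale.  The ephrinA2
knockout's *anterior restriction* is not reliably resolvable at micro
scale: the wild-type-vs-knockout specificity contrast is small relative to
the noise floor once chemoaffinity is broad enough to leave refinement to
activity, and the activity phase pulls all arbors to the same
wave-correlation floor — the corresponding test documents this as an
expected failure of the reduced scale, while the severity ordering across
genotypes does hold.  The EphA knock-in posterior shift of the unaltered
map is a competition effect that weakens with network size.  Spatially *banded* ocular dominance cannot
be resolved at micro scale: the banding wavelength tracks arbor size, which
at a ~300 µm colliculus is commensurate with the whole domain, so
segregation appears cell-wise (strongly eye-selective neurons) rather than
as bands.  In this realisation the fully cooperative survival variant
(ω = 0) suppresses eye-selectivity rather than spatially organising it —
support decoupled from a synapse's own coincidence record removes the
dendritic competition that evicts minority-eye synapses; this is a point
where mathematically distinct implementations of the same hypothesis
genuinely diverge.  Arrays are append-only (dead segments and synapses keep
slots), which favours vectorisation over memory frugality; at the published
scale a compaction pass would be worth adding.
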