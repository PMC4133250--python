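# retmap

A developmental simulator of the retinocollicular (retinotectal) projection.
`retmap` models how individual retinal ganglion cell (RGC) axons, entering
the superior colliculus as unbranched overshooting trunks, develop into
compact retinotopically ordered arbors — and how the same machinery produces
eye-specific and ON/OFF afferent segregation and the phenotypes of
ephrinA/EphA guidance-molecule mutants.

The model is for developmental neuroscientists and modellers who want an
executable, mechanistic account of map formation in which nothing refers to
"the map" itself: every rule is local, and retinotopy is emergent.

## The model in brief

Four interacting mechanisms, each with its standard notation:

* **Chemoaffinity** (net ephrinA/EphA effect).  Each RGC has a
  retinotopically correct termination zone (RC-TZ); the affinity of an axon
  segment at axis-wise displacement (Δx, Δy) from it is
  `A = f(γ_AP·s·|Δx|/L_c) · f(γ_LM·s·|Δy|/L_c)` with the sigmoid-like decay
  `f(x) = exp(-(x/k)^4)`, chemospecificity `s`, and `γ_LM = 2γ_AP`.
  Mutants rescale `s` or remap the TZ (ephrinA2/A5 knockouts, EphA knock-in,
  axis blocks).
* **Retinal waves.**  Spontaneous waves (130 µm/s fronts, 90 s mean
  inter-wave interval per location, 0.95 mm² mean footprint) drive 20 Hz ×
  2.5 s bursts for a 0.5 Hz long-run RGC rate; ON/OFF and binocular variants
  alter burst timing and inter-eye correlation.
* **Trophic synapse dynamics** (synaptotrophic hypothesis).  Each synapse
  holds a trophic state `T ∈ [0,1]`.  Vesicle release deposits a
  destabilising pro-factor; a postsynaptic spike within tens of milliseconds
  converts the unbound remainder into a stabilising factor.  Survival is
  comparative: synapses below their axon's or dendrite's average support are
  retracted, worst first.
* **Probabilistic arbor growth.**  11 µm axon segments extend at tips,
  branch orthogonally from extended segments, and retract at tips, with
  probabilities shaped by growth-factor exposure `G`, repulsion `R`, and
  arbor size; every RGC is capped at 5 new segments per sliding 10-minute
  window.  Integrate-and-fire collicular neurons mature, scale their
  synaptic input homeostatically toward a 0.5 Hz target, and release
  growth/repulsive factors (BDNF/proBDNF-like fields on a 10 µm grid).

Development runs in two phases — molecular guidance only, then
activity-dependent refinement — or combined from the start.  See
`docs/methods.md` for the complete specification of every equation and
default.

## Worked example

Run a wild-type micro-scale development (100 RGCs onto ~400 collicular
cells, 1 h molecular + 4 h activity phase) and look at the map:

```python
from retmap import Simulation, SimulationConfig
from retmap.metrics import summary_metrics

cfg = SimulationConfig(scenario="wt", n_rgc=100, n_sc=400,
                       phase1_h=1.0, phase2_h=4.0, seed=1)
sim = Simulation(cfg)
sim.run(until_ms=int(1.0 * 3600 * 1000))     # end of the molecular phase
print(summary_metrics(sim))
sim.run()                                     # activity-dependent phase
print(summary_metrics(sim))
```

Output (seed 1):

```
{'n_synapses': 5889, 'n_segments': 2313, 'frac_connected': 1.0,
 'median_tz_error': 38.77, 'mean_spread': 50.55,
 'linearity_ap': 0.746, 'linearity_ml': 0.692, 'mean_sc_rate': 0.0}
{'n_synapses': 4315, 'n_segments': 2289, 'frac_connected': 1.0,
 'median_tz_error': 24.61, 'mean_spread': 45.16,
 'linearity_ap': 0.879, 'linearity_ml': 0.775, 'mean_sc_rate': 0.633}
```

Reading it: after the molecular phase every axon has a coarse arborisation
(median termination-zone error 38.8 µm on a ~290 µm colliculus, rank
correlation between retinal and collicular position 0.75 on the AP axis).
The activity phase refines the map — termination-zone error drops ~35%,
arbors tighten, and retinotopic order rises on both axes — while homeostasis
holds the mean collicular firing rate near the 0.5 Hz target.  Blocking
activity (`scenario="activity_block"`) leaves the error at its coarse value;
blocking guidance (`scenario="guidance_block"`) collapses AP order entirely.

The same interface runs ephrinA2/A5 knockouts, EphA knock-ins, binocular
(correlated or independent waves) and ON/OFF scenarios; a thin CLI wraps it:

```bash
retmap simulate --scenario wt --profile tiny --seed 1 --out run.sqlite
retmap waves --stats --duration 3600 --seed 1
retmap analyze run.sqlite
retmap export run.sqlite --outdir tables/
```

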