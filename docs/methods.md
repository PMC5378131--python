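# Methods

## Model overview

`afca` implements a discrete-time, multi-state (Moe-type) cellular
automaton of left-atrial electrical activity on a spherical surface,
together with the experiment protocols, episode classifiers and
coarse-grained stochastic-rate inference built on top of it. The package
trades biophysical detail (no ionic currents, no conduction-velocity
restitution, no anisotropy) for speed: one 15 s trial of the 10 242-node
substrate runs in a fraction of a second, so episode statistics can be
estimated from hundreds to thousands of sample paths on a single CPU.

## Geometry

* **Node placement.** Icosahedral dissection: the icosahedron is midpoint-
  subdivided L times with re-projection to the unit sphere (delegated to
  `trimesh.creation.icosphere`), giving 10·4^L + 2 nodes; L = 5 (10 242
  nodes) is the production substrate. The sphere's physical scale comes
  from a 40 ml atrial volume: r = (3V/4π)^(1/3) = 21.2 mm, so 1 scaled
  unit (= 1 radian of arc) is 21.2 mm.
* **Distance convention.** All membership tests (holes, neighbour map,
  functional regions, fibrosis weights) use great-circle distance. At the
  radii involved chord and arc differ by < 0.1%, but one convention must be
  fixed; arc length is the natural metric on the surface.
* **Anatomical holes.** Four PV discs of 5 mm (0.236 rad) centred at
  (2π/5 ± π/10, ±π/3) and a mitral-valve disc centred on the south pole.
  Only the MV's rim circumference (85 mm) is specified anatomically; the
  implemented disc is the unique spherical cap with that rim circumference,
  i.e. angular radius arcsin(C/2πR) ≈ 0.694 rad from the south pole. Hole
  nodes are retained in the arrays (empty neighbour rows, permanently
  inert) so node indices always refer to the raw icosphere; this is
  bookkeeping only and is dynamically identical to removing them.
* **Fibrosis.** Exactly FC nodes are relabelled inert by inverse-transform
  sampling without replacement on a discrete distribution whose per-node
  weight is the isotropic normal density, evaluated at the great-circle
  distance from (0.65π, 0) with σ = 0.4 sphere radii (8.48 mm), normalized
  over active nodes. Arc length is used in the density argument; the
  alternative chord reading differs negligibly at this σ. Fibrotic nodes
  occupy space but never activate, and are excluded from the denominator
  of the activity signal.
* **Functional regions.** Sinus-node disc: nodes within 1.696 mm of
  (5π/12, π/2) (near the right PVs, the earliest left-atrial breakthrough
  site). PV annuli: the 2 mm band outside each PV rim. Burst group of an
  annulus node: all nodes within 2.12 mm of it, itself included.

## Automaton dynamics

* **States.** Integer countdown per node: 0 = rest, k > 0 = activated with
  k steps of refractoriness left. One step is 2.5 ms.
* **Excitation rule.** A resting node fires when at least 8 neighbours
  within the 2.544 mm interaction radius were activated in the past 4
  steps ("recently excited": 1 ≤ t − t_act ≤ 4, the inclusive convention
  that makes the window exactly 10 ms). The 8-node threshold with the
  2.544 mm radius (≈36-node neighbourhood, safely above the 0.76 mm mean
  node spacing) calibrates the conduction velocity to 0.5 m s⁻¹; the
  measured pole-to-pole transit on the defect-free sphere is 125 ms
  against the ≈133 ms continuum expectation, within the discretization
  tolerance.
* **Update semantics.** Fully synchronous: all threshold tests read the
  previous step's timestamps, removing any dependence on node ordering.
  Stimuli are applied in the order sinus → PV burst → bulk rule within a
  step; a node excited by several mechanisms in one step is excited once.
* **Restitution.** RP = clamp(⌊121·(1 − B·e^(−DI/K))⌋, 64, 120) with
  DI = t − t_rest, the node's quiescent interval in steps. The scale
  factor 121 with the floor yields the 120-step (300 ms) maximum; the
  64-step clamp is the 160 ms physiological minimum. The same DI
  definition is used for every excitation path (sinus, burst, bulk); for a
  1:1 paced node it reduces to the cycle-length-minus-RP form. A node
  re-excited by a burst while refractory keeps its stale t_rest, so its DI
  spans the current activation — restitution is monotone, so this assigns
  near-maximal RPs around frequently bursting veins (see Limitations).
* **Restitution memory (optional).** RP = clamp(⌊α·RP_prev + (1−α)·121·
  (1 − B·e^(−DI/K))⌋): α = 0 is the instantaneous rule above, α = 1
  freezes RP. Default α = 0; the parameter exists for sensitivity studies.
* **Sinus pacing.** Every 400 steps (1 Hz) the resting part of the SN disc
  is excited; refractory SN nodes are never overridden, which is what lets
  established re-entry suppress sinus capture.
* **PV bursts.** Per step, with probability p = BR/400, one annulus node
  is drawn uniformly and its burst group fires to its restitution-updated
  maximal state; by default the burst overrides refractoriness
  (`burst_overrides_refractory`, with a flag to restrict bursts to resting
  nodes).
* **Initial condition.** All nodes at rest with effectively infinite
  preceding quiescence (timestamps at −10⁶ steps), so the first excitation
  of any node assigns RP = 120. An optional heterogeneous start draws
  initial RPs uniformly from [64, 120].
* **Engines.** A numba kernel executes production runs; a transparent
  numpy reference step implements identical semantics. Both consume the
  same pre-generated per-step uniforms (burst coin, then location), and a
  unit test asserts bit-identical trajectories. Per-trial RNG discipline:
  one generator, consumed in fixed order (fibrosis sampling, then step
  draws), so a recorded seed replays a sample path exactly — seeds, not
  states, are the storage format for sample paths.

## Classifiers

* **Classifier A (retrospective).** A trial is in re-entry if the fraction
  of activated non-fibrotic nodes is strictly positive at *every* step of
  the 10 s post-burst observation window. Sinus rhythm fails this test
  because the tissue is fully at rest between beats.
* **Classifier B (online).** AF onset τ is the first time the active
  fraction has exceeded 0.5 for more than 2 s (strictly: 801 consecutive
  2.5 ms samples above threshold; τ is reported at the end of the
  qualifying run, with the run start kept for diagnostics). It observes
  without perturbing the automaton.

## Experiment protocols

All protocols resample fibrosis per trial (a flag allows a fixed shared
substrate) and are fully determined by (parameters, master seed).

* **Initiation:** sinus throughout; bursts for duration T; 10 s quiet
  observation; probability = fraction of paths passing classifier A.
* **Onset survival:** bursts on for the whole horizon; empirical
  s(t) = Prob[τ > t] with right-censoring at the horizon.
* **Agreement:** run until classifier B fires, switch bursts off at τ,
  observe 10 s, count the fraction confirmed by classifier A.
* **Termination probe:** paths that sustained AF after a T1-second burst
  are pooled (seed + state hash recorded at burst-off); each path is
  replayed from its seed to the branch point (hash-verified), then
  branched per (T2, repeat): wait T2 without bursts, apply a 1 s burst,
  observe 10 s; terminated iff classifier A fails. The observation starts
  at second-burst *offset* (matching the initiation protocol's post-burst
  window); within one process the branch state is cached in memory so the
  T1 segment is replayed once per path, not once per probe.

## Coarse-grained kinetics

The two-state chain SR ⇌ AF (initiation r₁, inhibition r₂) has
P_AF(t) = r₁/(r₁+r₂)(1 − e^(−(r₁+r₂)t)) from P_AF(0) = 0 — the standard
telegraph-process solution; its small-t slope is r₁, connecting the linear
short-burst regime to the saturating long-burst regime. Fits weight the
probabilities by binomial standard errors √(p(1−p)/n) with a floor at the
smallest nonzero error so p ∈ {0, 1} points are not infinitely weighted;
the linear fit is through the origin. The burst-gated two-stage chain
(OFF→ON at k₁, ON→OFF at k₂, SR/AF frozen while OFF) is simulated exactly
event-by-event; its AF→SR rate reuses r₂ by default, with a config
override since the identification of the two is a modelling choice. The
stable/unstable AF extension is represented only as a labelled parameter
scaffold: quantifying its rates requires a sub-state classifier that the
temporal signal alone does not provide.

## Spectral analysis

Power spectra use a rectangular window on the exact observation interval
of the mean-subtracted active fraction; the dominant frequency is the
argmax excluding the zero-frequency bin, and peaks are local maxima above
5× the median power (ties resolved toward lower frequency). An optional
band floor (`min_hz`) restricts the search: on this geometry the slowest
possible re-entrant circuit — a great circle traversed at 0.5 m s⁻¹ — has
period ≈266 ms (≈3.8 Hz), so sub-2 Hz power is window-scale drift rather
than a rotation mode. The acceptance script uses the 2 Hz floor and
reports the median dominant mode over three re-entrant paths, which
suppresses the occasional fragmented-wavefront path whose spectrum has no
clear rotation line. Typical sustained re-entry at baseline shows a
5.5–6 Hz fundamental with a ≈2.8 Hz subharmonic where tissue undergoes
2:1 conduction block.

The Mollweide projection (for static visualization) solves the auxiliary
angle by Newton iteration to |Δ| < 10⁻¹⁰, is centred on the posterior wall
(φ = π) and is exactly equal-area.

## Problem sizes and Monte-Carlo error

The package targets reduced-replicate versions of the full-scale study
designs (which used 10⁴–10⁶ paths): the test suite runs tens of paths per
condition and asserts stochastic quantities only within ±3 binomial
standard errors of their reference values; the acceptance script uses
three re-entrant paths for the spectral mode. At these sizes the baseline
initiation-rate estimate carries a ~30–50% relative Monte-Carlo error —
the error bars, not the point estimates, are the claim.

## What the simulations do and do not show

The substrate is a stylized sphere: no left-atrial appendage, no regional
RP heterogeneity, fixed SN breakthrough site, time-independent fibrosis,
and no conduction-velocity restitution (a structural limitation of the CA
rule — the front speed is fixed by the threshold/radius calibration).
Passing tests therefore demonstrate internal consistency of the stochastic
machinery and agreement with the published model's emergent statistics at
reduced scale, not fidelity to real atrial electrophysiology.

Known quantitative deviations of this re-implementation, at desk scale:
the baseline initiation rate emerges a factor ≈2 above its reference value
(same order; covered by the 3-SE bars at the replicate counts used), and
the dynamic classifier's false-positive collapse at BR = 80 Hz is much
weaker here (≈0.8 of detections confirmed versus ≈0.16): burst-driven
activity hovers near 0.79 of nodes but dips below the 0.5 threshold often
enough to break the 2 s hold. Both are sensitive to the reconstructed
restitution bookkeeping (notably the DI convention for burst-re-excited
refractory nodes, which keeps RPs near bursting veins long); the
corresponding test is left failing rather than loosened, as an honest
record of the discrepancy.
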