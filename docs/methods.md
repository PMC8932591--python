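# Methods

## Model

`tetraschool` simulates a planar, unbounded school of *Hemigrammus
rhodostomus* (rummy-nose tetra) in which each fish swims in discrete
**kicks**: a sudden acceleration followed by a passive glide along a
straight line whose speed decays exponentially with relaxation time
`tau0`.  All decisions are made at kick onsets.  At the onset of its n-th
kick a fish updates its heading by

    dphi = dphi_social + gamma_R * g,      g ~ N(0, 1)

and then glides over a freshly sampled kick length `l` and duration `tau`.
The social term is a sum of pairwise contributions over the fish's `k`
**most influential** neighbors,

    dphi_ij = F_att(d) O_att(psi) E_att(phi) + F_ali(d) E_ali(psi) O_ali(phi),

where `d` is the inter-fish distance, `psi` the viewing angle of the
neighbor measured from the focal heading, and `phi` the relative heading.
The radial intensities and angular modulations are empirical fits for this
species (`kernel.py`): attraction is repulsive below `d_att` (one body
length), peaks near the interaction range `l_att` and decays like `1/d` at
long range; alignment is strongest for neighbors ahead and decays with a
Gaussian cutoff at `l_ali`.  A neighbor's **influence** is the absolute
value of its pairwise contribution; ranking by influence (rather than
distance) is what allows cohesive and ordered states with `k` as small as
1 or 2.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `gamma_att`, `gamma_ali` | attraction / alignment intensities | 0.12 / 0.09 (pair fits); swept in experiments | – |
| `l_att`, `l_ali` | interaction ranges | 0.20 (pair fits); 0.28 in the phase diagrams | m |
| `d_att` | repulsion crossover | 0.03 | m |
| `d_ali` | alignment distance scale | 0.06 | m |
| `k` | influential neighbors attended to | 1 | – |
| `gamma_R` | heading-noise intensity | 0.2 (0.45 for experimental pairs) | rad |
| `l`, `tau` | mean kick length / duration | 0.07 m / 0.5 s | |
| `tau0` | glide relaxation time | 0.8 | s |
| `N` | group size | 100 | – |

All lengths are SI metres and all angles radians internally; headings are
wrapped to `(-pi, pi]` by one shared helper.

## Kinematic conventions

The printed kinematic quadruple (`l` = 7 cm, `tau` = 0.5 s, `v0` = 14 cm/s,
`tau0` = 0.8 s) is overdetermined: an exponential glide starting at `v0`
does not integrate to `l` over `tau`.  The package honors the kick length —
the displacement of kick n is exactly `l_n` along the new heading — and
derives the peak speed `v_peak = l / (tau0 (1 - e^{-tau/tau0}))` (≈ 0.188
m/s for the mean kick); `v0` is kept only as a reference constant.  Within
a kick the position interpolates as
`f(s) = (1 - e^{-s/tau0}) / (1 - e^{-tau/tau0})` of the kick length, which
is continuous across kick boundaries by construction.

Kick lengths and durations are only known to be bell-shaped with the above
means, so the generator samples them as independent gamma variates with a
coefficient of variation of 0.3 (a moderate, realistic spread for
locomotor bout statistics), truncated below at 10% of the mean; a "fixed"
mode returns the means exactly and is the deterministic baseline used by
the engine-equivalence tests.  The phase structure reported by the
acceptance experiments is not sensitive to this choice at the tolerances
used, but exact steady-state values of the order parameters can shift by a
few hundredths between reasonable spread choices.

## Event loop

Kick-end events across the school are processed in global time order with
ties broken by fish id.  The production engine keeps per-fish next-event
times and takes an argmin per event (N ≤ 200 makes a heap unnecessary; the
pure-Python reference path uses `heapq` with `(time, id)` keys, which
yields the identical order).  When a fish kicks, every other fish is
interpolated to the exact event time along its own glide, and neighbors
contribute their current kick headings.  Exactly simultaneous events are
evaluated against the common pre-update state and then applied together —
this preserves mirror symmetry of mirror-symmetric initial conditions with
synchronized kicks, which sequential in-tie updates would silently break.
Simultaneity is a measure-zero event under sampled kick statistics, so
this convention only matters for constructed tests.

All randomness — initial positions in a disc of radius
`R = sqrt(N/pi) l_att / 2` (mean spacing about half the interaction
range), initial headings uniform in `(-pi, pi)`, first-kick onsets
staggered uniformly within one mean kick duration, per-fish kick and noise
streams — is pre-drawn from named `SeedSequence` children before the loop.
A run is therefore a pure function of its configuration, identical across
the compiled and pure-Python engines and independent of event order, and
replicates/cells of a sweep are keyed `(seed, cell, replicate)` so results
do not depend on evaluation order.

A fish rests at its initial position until its first kick onset (the glide
fraction is clamped); the initial transient is discarded from every
analysis, so this convention has no effect on reported quantities.

## Observables

- **Dispersion D**: root-mean-square distance to the barycenter, in
  metres.  The RMS convention (not mean-square) is used because the phase
  thresholds (D > 5 m; 7 m in the group-size experiments) carry units of
  metres; a `mean_square` flag is provided.
- **Polarization P**: norm of the mean heading unit vector.
- **Milling M**: absolute mean of `sin(phibar_i - thetabar_i)` where
  `thetabar_i` and `phibar_i` are the position angle and velocity
  direction of fish i *in the barycenter frame* (velocity minus the mean
  velocity — not a heading difference).  Terms with barycenter-frame
  radius or speed below 1e-12 are excluded as undefined (this absorbs both
  a fish sitting exactly at the barycenter and floating-point residue of
  the mean subtraction).
- Phase classification applies the dispersion test first, then the
  P/M inequalities against 0.4 in the order Schooling (P ≥ 0.4, M ≤ 0.4),
  Milling, Intermittent, Swarming; the published inequalities mix strict
  and non-strict comparisons on the measure-zero boundary, so the
  first-matching-rule order makes the classification total and
  deterministic.
- **DMIN / DFNN**: number of distinct most-influential-neighbor (k = 1
  argmax) and nearest-neighbor identities across the school at a sampling
  instant (1 s cadence); diagnostics of how information can flow.
- **3-group partition**: closure of the directed 3-nearest-neighbor
  relation, seeded at the lowest unassigned id; when a closure reaches a
  fish already assigned the groups are merged (equivalently, weakly
  connected components of the 3-NN digraph).  The merge rule is the
  reading under which the partition is a disjoint cover with every group
  of size ≥ 4; without it a late seed whose neighbors are all assigned
  would form a singleton.

For uncorrelated random headings the polarization of a finite school
scales as `1/sqrt(N)`; the test suite checks this scaling empirically
(quadrupling N halves the mean P) rather than asserting an exponent.

## Experiment protocols and problem sizes

The full published protocol (20 replicates of 2000 kicks per fish per
grid cell, first 100 kicks discarded, Δγ down to 2×10⁻³) is available as
the `PAPER` preset.  The packaged acceptance experiments run the identical
code path at desk scale, chosen so the whole battery completes in minutes
on one core:

- phase-point steady states: 8 replicates × 1000 kicks, transient 100
  kicks, observables sampled each second;
- cohesion transition scans: 3 replicates × 2000 kicks per grid point —
  the full run length is kept here because the transition is defined by
  dispersion staying bounded (D < 5 m) *at that run length* rather than
  growing;
- interaction-topology counts: 5 replicates × 1000 s, sampled each second
  after a 200 s transient;
- optimal-attraction scan: 3 replicates × 600 kicks per point, step 0.1;
- bistable-band PDF: 10 replicates × 1500 kicks, 50 bins.

Replicate means at boundary points (e.g. the swarming point at
γ_Att = 0.06, γ_Ali = 0.125) have visible replicate-to-replicate variance
because the school occasionally jumps into a metastable ordered state;
replicate counts above were chosen to keep the standard error of the
reported means well inside the comparison tolerances.

## What the generator does and does not emulate

The simulator *is* the study system: there is no external data.  It
reproduces the discrete, asynchronous burst-and-coast decision structure,
the empirically shaped social kernels, and Gaussian heading noise.  It
does not model walls or tanks (the plane is unbounded), hydrodynamics,
body shape, speed-dependent interactions, or any correlation between kick
length and duration (unknown empirically; sampled independently here).
Agreement of the packaged experiments with published steady-state values
therefore validates the model logic and its implementation, not the
biology of any particular tank experiment.

## Numerical choices and limitations

- Influence ties are broken toward the lower fish id via a stable sort;
  event-time ties toward the lower fish id.  Scan argmins resolve ties to
  the first grid point.
- A coincident neighbor pair (d = 0) sets the viewing angle to 0, which
  zeroes the attraction term; short-range repulsion and noise make the
  configuration transient.
- The compiled engine and the Python kernel agree pointwise to 1e-12;
  over long runs trajectories of chaotic states can still diverge between
  engines from round-off amplification, so cross-engine equivalence is
  asserted on short horizons and small N where the dynamics contract.
- Steady-state milling/polarization values at phase points sit within
  ±0.1 of the published values at the budgets above, but individual
  boundary points can drift by a few hundredths with seed and with the
  kick-spread choice; the tests use fixed seeds and the stated budgets.
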