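# Methods

This note records the model as implemented, the parameters that matter,
the choices made where the design was genuinely open, and what the tests
do and do not establish. All lengths are micrometres, rates Hz,
conductances nS.

## Morphologies and the disease-stage transforms

A morphology is a rooted tree of typed 3-D points with SWC semantics
(type codes 1 = soma, 2 = axon, 3 = dendrite; code 4 is read as dendrite).
Transforms never mix compartments: truncation touches only dendrites,
growth only axons.

**Stepwise truncation.** Arbors are resampled at 3 µm (section endpoints
and their ids preserved; interior nodes re-placed at equal arc spacing, so
chord-shortening across corners is below one resolution unit per
unbranched section). Each truncation step removes exactly 3 µm of path at
every dendritic terminal, within the terminal's own section:

* a terminal section shorter than the step is removed entirely; the
  remainder is *not* borrowed past the branch point in the same step.
  This keeps the per-step loss ≤ 3 µm per terminal, which is what makes
  the terminal count calibration below exact at PD1;
* a branch point whose arms are all consumed becomes a terminal and is
  truncated from the next step on; one with a single surviving arm
  becomes a pass-through;
* a fully consumed primary dendrite is deleted, so the primary count can
  decline across stages, as observed in the atrophy data.

Stages: PD1 = 10 steps, PD2 = 20, PD3 = 30; PD0 is the identity.

**Axonal growth.** Every axonal terminal is extended by exactly 61 µm: 20
full 3 µm steps plus one 1 µm step of a persistent random walk
(heading h ← normalize(τ·h + √(1−τ²)·ξ), τ = 0.8 by default, initial
heading = the terminal's last segment). With a radius cap set (we use the
healthy arbor's maximal axonal radius), a step that would leave the cap
has its radial component reflected inward, so total cable grows by
61 × terminals exactly while the field radius stays put — the arbor
densifies instead of expanding, matching the observation that the axonal
field radius does not change while intermediate Sholl crossings increase.

## Synthetic morphologies

The study's reconstructions are not public, so arbors are generated:

1. a random binary section tree with an *exact* terminal count T is drawn
   by uniform tip splitting from P primaries;
2. internal sections get gamma(shape 3) lengths with mean 25 µm (capped at
   half the budget), terminal sections share the remaining budget with
   gamma(shape 3) weights and a 3 µm floor, so the total length is exact;
3. the tree is embedded by a persistent outward walk in ≤3 µm steps
   (persistence 0.9, branch-direction jitter 0.5, reflective cap at the
   spatial extent), which makes every generated arbor directly compatible
   with the 3 µm truncation schedule.

Per-draw totals get a lognormal-free multiplicative jitter (normal,
CV 0.10, floored at 0.2) to emulate inter-neuron variability; the
population mean stays on target. A per-µm branching-hazard mode exists for
uncalibrated arbors (hazard 0 gives a star of unbranched neurites).

Terminal counts are calibrated from the printed stage table: each step
removes 3 µm per terminal, so the PD0→PD1 loss over 10 steps implies
T = round((L₀ − L₁)/30) — 37 (dSPN), 25 (iSPN), and 257 for the FS axon
(where the printed growth, +61.3%, equals 61 µm × 257 / 25,572 exactly).
Short-internal/long-terminal section statistics mirror real SPN arbors,
whose branch points cluster proximally; this is what makes PD2/PD3
remnants a genuine prediction rather than a construction: PD1 is matched
by calibration, while the measured PD2 remnants (≈51% dSPN, ≈55% iSPN
against printed 50% / 57%) emerge from how the trees collapse. Defaults
for arbors the sources do not quantify (SPN axons, FS dendrites,
ChIN/LTS) are generic and only play connectivity roles.

## Network construction

Placement is uniform i.i.d. in a cube at 80,500 neurons/mm³ with uniform
random rotations; composition 47.5% dSPN, 47.5% iSPN and 3.2% modeled
interneurons split FS 1.3%, ChIN 1.1%, LTS 0.8% (the split within the
3.2% is an assumption; the remaining 1.8% are placed but unconnected).

Touch detection reports one putative synapse per (axonal segment,
dendritic/somatic segment) pair whose minimum distance is ≤ 3 µm (somata
are zero-length segments), located at the midpoint of closest approach,
with the postsynaptic arc distance to soma interpolated along the
segment. A uniform voxel hash (default 10 µm) only accelerates the
candidate search; the neighbor radius is derived from the maximum segment
length so the result is provably identical to the all-pairs scan, which
is kept as the test oracle. The 3 µm reach deliberately overestimates
connectivity; pruning brings it down.

Pruning rules apply per ordered type pair, in order: (1) random keep
fraction; (2) distance-dependent keep — exp(−d/s) for proximally
targeting afferents (FS) and 1 − exp(−d/s) for distal ones (LTS), with d
the postsynaptic arc distance; (3) per-pair soft cap by random
subsampling; (4) all-or-none removal of pairs with fewer than k synapses,
with probability growing linearly as the count drops; (5) all-or-none
removal of connected pairs at a fixed probability. A bisection helper
calibrates the random keep fraction to a target connection probability.
`expected_connection_stats` returns the noise-free expectations (kept
synapses; connected pairs) implied by the per-synapse rules — used for
directional comparisons where a single Monte Carlo draw would be noise.

Stage networks: *degeneration* keeps the PD0 synapses whose postsynaptic
segment (tracked by its child-node id, so the error is bounded by the
3 µm resampling) survives truncation; *de novo* re-runs touch detection
and pruning on the transformed morphologies; *hybrid* keeps the
degeneration synapses in place and tops up each ordered type pair with
randomly drawn de-novo synapses to the de-novo count (trimming randomly
in the rare opposite case), reporting the emergent remapping fraction.

## Directed-clique topology

Counting follows the directed-flag-complex convention: a directed
n-clique is an ordered tuple (v₀…vₙ) of distinct vertices with an edge
vᵢ→vⱼ for all i < j. The enumerator is an exact depth-first expansion
over common out-neighborhoods with adjacency kept as integer bitsets;
dimension 0 and 1 counts are the vertex and edge counts by construction,
asserted on every run. The kernel filter counts a clique iff its vertex
set meets the kernel, with subtree pruning when no kernel vertex can be
reached. A set-based variant (each admissible vertex set once — the
strict unique-source/sink reading, differing only when cliques contain
reciprocal pairs) is available for sensitivity analysis on small graphs.
A permutation-checking brute-force enumerator (guarded to ≤15 vertices)
serves as the independent oracle. Default max dimension 13.

Kernel = the k nearest neurons to the cube center per requested
composition (default 4 dSPN + 4 iSPN, ties by lower id); core = kernel
plus all pre- and postsynaptic partners. Composition classes
(all-dSPN / all-iSPN / contains-interneuron / mixed) are exhaustive and
exclusive, with interneuron membership taking precedence. Per-clique
synapse totals sum edge weights in both directions where reciprocal
edges exist.

## Input drive and compensation

**Correlated trains.** The mother train is Poisson at f = λ; each mother
spike is transferred, with probability p = c, to *every* child (one
Bernoulli decision per spike); children add a private Poisson train at
(1 − p)·λ. Each child is then Poisson at λ and the pairwise spike-count
correlation equals c exactly. Had each child copied mother spikes
independently, the correlation would be c², contradicting the stated
p = c identity — the shared-transfer reading is the one consistent with
the protocol's correlation grid (0–0.5), and its two limits (c = 0
independent, c = 1 identical copies) are tested. Correlation is estimated
as the mean Pearson correlation of 25 ms-binned counts over distinct
pairs (the bin size is a declared choice; nothing in the protocol pins
it).

**Placement, loss, compensation.** Synapse sites are uniform per unit
dendritic arc length. A site survives a stage if its host segment's child
node survives truncation; on calibrated dSPN populations the PD2 survival
is ≈0.50 (printed estimate 47.5%), iSPN ≈0.57 (printed 53.25%).
Strengthening adds (cond_PD0 − cond_PD2)·x/100/n_syn_PD2 to every
surviving conductance (exact total-conductance restoration at x = 100);
rewiring adds round(x/100·(n₀ − n₂)) base-conductance sites uniformly on
the surviving dendrite (exact count restoration at x = 100). Rewired
positions are uniform by arc length, a declared choice.

**Surrogate neuron.** An adaptive leaky integrate-and-fire point neuron
with conductance synapses (E_rev = 0 mV) under Tsodyks–Markram depression
(utilization 0.3, recovery 800 ms, synaptic time constant 2 ms —
formalism defaults, not fitted). Parameters: g_L = 1 nS, τ_m = 20 ms,
E_L = −80 mV, threshold −50 mV, reset −65 mV, refractory 2 ms, adaptation
10 pA per spike with τ_w = 100 ms; Euler integration at 0.1 ms with
event-driven depression. The leak scale is chosen so that 0.5 nS
depressing synapses reach the 10 Hz @ 5 Hz calibration with several
hundred inputs (bisection on the synapse count per morphology). This is
explicitly *not* a reproduction of the multicompartment SPN models: it
carries only the direction of the disease-stage excitability changes
(dSPN up, iSPN down), implemented as ±5% scalings of the
threshold-to-rest distance and the leak. Five percent, not more: a point
neuron's rate-current relation is steep enough that larger shifts swamp
the synaptic-compensation effects the experiment is about; the shift is
an exposed parameter.

**Protocol.** The full grid is 12 scenarios (PD0, PD2, five strengthening
and five rewiring levels) × 10 rates (0.5–5 Hz in 0.5 steps) × 6
correlations (0–0.5 in 0.1 steps) = 720 simulation sets, with 10 s
stimulation, 2 s recovery and re-drawn synapse placements per repeat. The
rate grid follows the 10 × 6 = 60 combination count; the conflicting
0.1-step reading of the protocol string is treated as a typo. A reduced
desk grid (3 × 3 × 3, 2 repeats) is the default entry point.

## Desk scale: what the tests show

Everything stochastic runs at desk scale: a 120 µm cube (≈140 neurons) at
the real density, with morphologies scaled to 0.25 of the calibrated
targets (terminal counts scaled alike but floored at n_primary + 2 so
scaled trees keep branch points; otherwise whole short primaries are
consumed, an artifact full-size arbors do not show). At this scale every
neuron lies within every other's dendritic field, so the desk pruning
defaults are aggressive (random keep 0.15, few-synapse threshold 3 at
0.9, pair removal 0.6, FS proximal scale 15 µm ≈ the proximal third of
the scaled arbor, LTS distal scale 40 µm).

Consequences to keep in mind:

* Full-network headline numbers (2,712-neuron core, top clique dimensions
  12–13, clique-synapse thresholds) are functions of the 100,000-neuron
  build and the original reconstructions; desk runs reach top dimensions
  around 4–6. The suite therefore checks exact identities, oracle
  equivalences, conservation laws and *directions* (stage decay of clique
  counts, ablation vs erosion, connectivity shifts), not those magnitudes.
* The FS→iSPN connectivity increase is a ≈10% effect at desk scale and
  emerges only through the interaction of capped growth, distal-first
  atrophy and FS's perisomatic targeting; it is asserted on expected
  (noise-free) kept-synapse counts aggregated over eight fixed probe
  replicates. The iSPN→dSPN decrease is large and robust everywhere.
* Synthetic arbors have no spines, no diameter taper, generic interneuron
  geometry and walk-based tortuosity; passing tests show the transforms
  and statistics behave correctly and reproduce printed population-level
  morphometrics, not that the generator matches unpublished
  per-reconstruction statistics.

Numerical conventions: float64 throughout; ≤1e-9 slack in length
comparisons; truncation uses an epsilon of 1e-9 µm when deciding whether
a segment is consumed; clique counting is exact integer arithmetic; every
random draw flows from an explicit integer seed through
`numpy.random.default_rng`, and identical (config, seed) pairs reproduce
pipeline artifacts byte-for-byte (timestamps excepted).
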