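"""Corticostriatal drive, synaptic compensation and a surrogate SPN.

Excitatory drive is modeled as n correlated Poisson spike trains built by
the mother–child construction: a mother Poisson train of rate f = λ, and
children that superpose a private Poisson train of rate (1 − p)·f with the
mother spikes transferred at probability p. The transfer decision is made
once per mother spike and applied to every child, which makes each child a
Poisson train of rate λ and the pairwise spike-count correlation equal to
p = c exactly (independent per-child copying would square the correlation).

Dendritic atrophy removes synapses: a synapse placement drawn uniformly
per unit arc length on the healthy (PD0) dendrites loses the sites whose
branches are truncated away by stage PD2 (printed estimates: 47.5% of dSPN
and 53.25% of iSPN sites survive). Two compensation strategies restore SPN
output at levels x ∈ {20, 40, 60, 80, 100}%:

* strengthening — each surviving synapse's conductance is raised by
  (cond_PD0 − cond_PD2)·(x/100)/n_syn_PD2, so at x = 100 the total
  conductance equals the healthy total exactly;
* rewiring — round((x/100)·(n_syn_PD0 − n_syn_PD2)) new synapses at the
  0.5 nS base conductance are added uniformly on the surviving dendrite,
  so at x = 100 the site count equals the healthy count exactly.

Output is read from a surrogate point neuron: an adaptive leaky
integrate-and-fire cell with conductance synapses under Tsodyks–Markram
short-term depression. This is a declared stand-in for multicompartment
SPN models, calibrated so the healthy cell fires ≈10 Hz under 5 Hz
uncorrelated drive; disease-stage excitability shifts (dSPN up, iSPN down)
are implemented as ±5% threshold-distance/leak scalings (the
point neuron's steep rate-current relation makes larger shifts
disproportionate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphology import Morphology, Structure

__all__ = [
    "SpikeGenSpec",
    "SynapsePlacement",
    "CompensationSpec",
    "SurrogateNeuron",
    "ProtocolGrid",
    "generate_correlated_trains",
    "pairwise_count_correlation",
    "place_synapses",
    "surviving_fraction",
    "filter_surviving",
    "strengthen",
    "rewire",
    "simulate_surrogate",
    "calibrate_input_count",
    "run_protocol",
    "protocol_marginals",
]

BASE_CONDUCTANCE_NS = 0.5
RATE_GRID_HZ = tuple(0.5 * k for k in range(1, 11))          # 0.5 … 5.0
CORRELATION_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
COMPENSATION_LEVELS = (20, 40, 60, 80, 100)


# ---------------------------------------------------------------------------
# Correlated Poisson trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeGenSpec:
    n_trains: int
    rate: float                   # λ, Hz; also the mother rate f
    correlation: float = 0.0      # c = transfer probability p
    duration: float = 10.0        # s
    recovery: float = 2.0         # s, gap between protocol pairs
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [0, 1]")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")


def generate_correlated_trains(spec: SpikeGenSpec) -> list[np.ndarray]:
    """Mother–child correlated Poisson trains (sorted spike times, s).

    Each child superposes a private Poisson train of rate (1 − p)·λ with
    the subset of mother spikes selected once at probability p and shared
    by all children; every child has rate λ and every pair has spike-count
    correlation p = c. p = 0 gives independent trains; p = 1 makes all
    children copies of the mother.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.correlation
    n_mother = rng.poisson(spec.rate * spec.duration)
    mother = np.sort(rng.uniform(0.0, spec.duration, size=n_mother))
    shared = mother[rng.random(n_mother) < p]
    trains = []
    priv_rate = (1.0 - p) * spec.rate
    for _ in range(spec.n_trains):
        n_priv = rng.poisson(priv_rate * spec.duration)
        priv = rng.uniform(0.0, spec.duration, size=n_priv)
        trains.append(np.sort(np.concatenate([priv, shared])))
    return trains


def pairwise_count_correlation(trains: Sequence[np.ndarray],
                               duration: float,
                               bin_size: float = 0.025) -> float:
    """Mean Pearson correlation of binned spike counts over distinct pairs."""
    n_bins = int(math.floor(duration / bin_size))
    counts = np.stack([
        np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_size))[0]
        for t in trains]).astype(float)
    cm = np.corrcoef(counts)
    iu = np.triu_indices(len(trains), k=1)
    return float(np.nanmean(cm[iu]))


# ---------------------------------------------------------------------------
# Synapse placement on dendrites
# ---------------------------------------------------------------------------

@dataclass
class SynapsePlacement:
    """Excitatory synapse sites on a dendritic arbor.

    sites: one row per synapse (node_id = child node of the host segment,
    seg_frac = position along the segment, arc_dist = arc length to soma);
    cond: per-site conductance, nS. Tsodyks–Markram depression parameters
    are glutamatergic defaults (utilization 0.3, recovery 800 ms, synaptic
    time constant 2 ms).
    """

    sites: pd.DataFrame
    cond: np.ndarray
    tm_utilization: float = 0.3
    tm_tau_rec: float = 0.8       # s
    tau_syn: float = 0.002        # s
    e_rev: float = 0.0            # mV

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def total_conductance(self) -> float:
        return float(self.cond.sum())


def place_synapses(morph: Morphology, n: int, seed: int = 0
                   ) -> SynapsePlacement:
    """n sites uniform per unit dendritic arc length; deterministic per seed."""
    pi, ci = morph.segments()
    mask = morph.structure[ci] == Structure.DENDRITE
    pi, ci = pi[mask], ci[mask]
    if len(ci) == 0:
        if n > 0:
            raise ValueError("cannot place synapses: no dendrite")
        sites = pd.DataFrame(columns=["node_id", "seg_frac", "arc_dist",
                                      "x", "y", "z"])
        return SynapsePlacement(sites, np.empty(0))
    lengths = np.linalg.norm(morph.xyz[ci] - morph.xyz[pi], axis=1)
    arc = morph.arc_distance_to_soma()
    rng = np.random.default_rng(seed)
    probs = lengths / lengths.sum()
    seg = rng.choice(len(ci), size=n, p=probs)
    frac = rng.random(n)
    xyz = morph.xyz[pi[seg]] + frac[:, None] * (
        morph.xyz[ci[seg]] - morph.xyz[pi[seg]])
    arc_d = arc[pi[seg]] + frac * lengths[seg]
    sites = pd.DataFrame({
        "node_id": morph.ids[ci[seg]], "seg_frac": frac, "arc_dist": arc_d,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})
    return SynapsePlacement(sites, np.full(n, BASE_CONDUCTANCE_NS))


def surviving_fraction(placement: SynapsePlacement,
                       morph_degenerated: Morphology) -> float:
    """Fraction of sites whose host segment survives dendritic atrophy.

    A site survives when the child node of its segment is still present in
    the degenerated morphology (error bounded by the 3 µm resample
    resolution). Returns 1.0 for an empty placement.
    """
    if placement.n_sites == 0:
        return 1.0
    alive = set(morph_degenerated.ids.tolist())
    surv = placement.sites.node_id.map(lambda i: int(i) in alive)
    return float(surv.mean())


def filter_surviving(placement: SynapsePlacement,
                     morph_degenerated: Morphology) -> SynapsePlacement:
    """Placement restricted to the sites surviving degeneration."""
    alive = set(morph_degenerated.ids.tolist())
    keep = placement.sites.node_id.map(
        lambda i: int(i) in alive).to_numpy(bool)
    return replace(placement,
                   sites=placement.sites[keep].reset_index(drop=True),
                   cond=placement.cond[keep].copy())


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------

@dataclass
class CompensationSpec:
    """Strengthening or rewiring at level x% of the PD0→PD2 synapse loss."""

    strategy: str                 # "strengthen" | "rewire"
    level: float                  # x, percent
    n_syn_PD0: int
    n_syn_PD2: int
    base_conductance: float = BASE_CONDUCTANCE_NS

    def __post_init__(self):
        if self.strategy not in ("strengthen", "rewire"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.n_syn_PD2 > self.n_syn_PD0:
            raise ValueError("n_syn_PD2 must be <= n_syn_PD0")

    @property
    def cond_PD0(self) -> float:
        return self.n_syn_PD0 * self.base_conductance

    @property
    def cond_PD2(self) -> float:
        return self.n_syn_PD2 * self.base_conductance


def strengthen(placement: SynapsePlacement,
               spec: CompensationSpec) -> SynapsePlacement:
    """Raise every surviving conductance by (cond_PD0−cond_PD2)·x/100/n_syn_PD2.

    Site count is unchanged; at x = 100 the total conductance equals the
    healthy total exactly.
    """
    if spec.strategy != "strengthen":
        raise ValueError("spec.strategy must be 'strengthen'")
    if spec.n_syn_PD2 == 0:
        raise ValueError("no surviving synapses to strengthen")
    inc = (spec.cond_PD0 - spec.cond_PD2) * (spec.level / 100.0) / spec.n_syn_PD2
    return replace(placement, sites=placement.sites.copy(),
                   cond=placement.cond + inc)


def rewire(placement: SynapsePlacement, morph_degenerated: Morphology,
           spec: CompensationSpec, seed: int = 0) -> SynapsePlacement:
    """Add round((x/100)·(n_syn_PD0−n_syn_PD2)) base-conductance sites,
    uniform per arc length on the surviving dendrite; at x = 100 the site
    count is restored to n_syn_PD0 exactly."""
    if spec.strategy != "rewire":
        raise ValueError("spec.strategy must be 'rewire'")
    n_add = int(round((spec.level / 100.0)
                      * (spec.n_syn_PD0 - spec.n_syn_PD2)))
    if n_add == 0:
        return replace(placement, sites=placement.sites.copy(),
                       cond=placement.cond.copy())
    extra = place_synapses(morph_degenerated, n_add, seed=seed)
    sites = pd.concat([placement.sites, extra.sites], ignore_index=True)
    cond = np.concatenate([placement.cond,
                           np.full(n_add, spec.base_conductance)])
    return replace(placement, sites=sites, cond=cond)


# ---------------------------------------------------------------------------
# Surrogate neuron
# ---------------------------------------------------------------------------

@dataclass
class SurrogateNeuron:
    """Adaptive leaky integrate-and-fire point neuron with conductance
    synapses — a stand-in for the multicompartment SPN models, carrying
    only the disease-stage excitability direction (dSPN up, iSPN down,
    ±5% threshold-distance/leak scaling by default)."""

    g_leak: float = 1.0           # nS (surrogate point-neuron scale)
    tau_m: float = 20.0           # ms
    e_leak: float = -80.0         # mV
    threshold: float = -50.0      # mV
    reset: float = -65.0          # mV
    refractory: float = 2.0       # ms
    adapt_increment: float = 10.0 # pA per spike
    tau_adapt: float = 100.0      # ms

    def __post_init__(self):
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")

    @classmethod
    def preset(cls, name: str, shift: float = 0.05) -> "SurrogateNeuron":
        base = cls()
        span = base.threshold - base.e_leak
        if name in ("dSPN_PD0", "iSPN_PD0"):
            return base
        if name == "dSPN_PD2":       # more excitable, higher input resistance
            return replace(base,
                           threshold=base.e_leak + (1 - shift) * span,
                           g_leak=base.g_leak * (1 - shift))
        if name == "iSPN_PD2":       # less excitable, higher leak
            return replace(base,
                           threshold=base.e_leak + (1 + shift) * span,
                           g_leak=base.g_leak * (1 + shift))
        raise ValueError(f"unknown preset {name!r}")


def _conductance_trace(placement: SynapsePlacement,
                       trains: Sequence[np.ndarray],
                       duration: float, dt: float) -> np.ndarray:
    """Summed synaptic conductance per time step (nS), with per-site
    Tsodyks–Markram depression applied event-wise."""
    n_steps = int(round(duration / dt))
    impulses = np.zeros(n_steps + 1)
    n_tr = len(trains)
    u = placement.tm_utilization
    tau_rec = placement.tm_tau_rec
    events = []
    for k in range(placement.n_sites):
        tt = trains[k % n_tr]
        for t in tt[tt < duration]:
            events.append((t, k))
    events.sort()
    x = np.ones(placement.n_sites)
    last = np.zeros(placement.n_sites)
    for t, k in events:
        x[k] = 1.0 - (1.0 - x[k]) * math.exp(-(t - last[k]) / tau_rec)
        release = u * x[k] * placement.cond[k]
        x[k] *= (1.0 - u)
        last[k] = t
        impulses[min(n_steps, int(t / dt))] += release
    decay = math.exp(-dt / placement.tau_syn)
    g = np.empty(n_steps)
    acc = 0.0
    for i in range(n_steps):
        acc = acc * decay + impulses[i]
        g[i] = acc
    return g


def simulate_surrogate(neuron: SurrogateNeuron,
                       placement: SynapsePlacement,
                       trains: Sequence[np.ndarray],
                       duration: float,
                       dt: float = 1e-4) -> tuple[np.ndarray, float]:
    """Integrate the surrogate neuron; returns (spike times s, mean rate Hz).

    Fixed-step (dt ≤ 0.1 ms) conductance-based integration; deterministic
    given the placement and input trains. Zero input yields zero spikes.
    """
    if dt > 1e-4 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms")
    g_syn = _conductance_trace(placement, trains, duration, dt)
    dt_ms = dt * 1e3
    cap = neuron.g_leak * neuron.tau_m       # pF
    v = neuron.e_leak
    w = 0.0
    refr = 0.0
    spikes = []
    decay_w = math.exp(-dt_ms / neuron.tau_adapt)
    for i in range(len(g_syn)):
        w *= decay_w
        if refr > 0:
            refr -= dt_ms
            continue
        i_total = (-neuron.g_leak * (v - neuron.e_leak)
                   - g_syn[i] * (v - placement.e_rev) - w)
        v = v + dt_ms * i_total / cap
        if not np.isfinite(v):
            raise FloatingPointError("unstable surrogate integration")
        if v >= neuron.threshold:
            spikes.append(i * dt)
            v = neuron.reset
            w += neuron.adapt_increment
            refr = neuron.refractory
    spikes = np.asarray(spikes)
    return spikes, len(spikes) / duration


def calibrate_input_count(neuron: SurrogateNeuron, morph: Morphology,
                          target_rate: float = 10.0, drive_rate: float = 5.0,
                          tol: float = 1.0, n_lo: int = 10, n_hi: int = 4000,
                          duration: float = 5.0, seed: int = 0) -> int:
    """Bisect the synapse count so uncorrelated drive at drive_rate Hz
    yields target_rate Hz output on this morphology (healthy calibration)."""
    def rate_at(n):
        pl = place_synapses(morph, n, seed=seed)
        tr = generate_correlated_trains(SpikeGenSpec(
            n_trains=n, rate=drive_rate, correlation=0.0,
            duration=duration, seed=seed + 1))
        return simulate_surrogate(neuron, pl, tr, duration)[1]

    lo, hi = n_lo, n_hi
    if rate_at(hi) < target_rate:
        return hi
    for _ in range(14):
        mid = (lo + hi) // 2
        if mid in (lo, hi):
            break
        r = rate_at(mid)
        if abs(r - target_rate) <= tol:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) // 2


# ---------------------------------------------------------------------------
# Protocol grid
# ---------------------------------------------------------------------------

def _default_scenarios() -> list[str]:
    return (["PD0", "PD2"]
            + [f"strengthen_{x}" for x in COMPENSATION_LEVELS]
            + [f"rewire_{x}" for x in COMPENSATION_LEVELS])


@dataclass
class ProtocolGrid:
    """The drive experiment definition; the full grid enumerates
    12 scenarios × 10 rates × 6 correlations = 720 simulation sets."""

    scenarios: list[str] = field(default_factory=_default_scenarios)
    rates: tuple[float, ...] = RATE_GRID_HZ
    correlations: tuple[float, ...] = CORRELATION_GRID
    placement_repeats: int = 10

    @property
    def n_sets(self) -> int:
        return len(self.scenarios) * len(self.rates) * len(self.correlations)

    @classmethod
    def desk(cls) -> "ProtocolGrid":
        """Reduced grid for desk-scale runs."""
        return cls(scenarios=["PD0", "PD2", "strengthen_100"],
                   rates=(1.0, 3.0, 5.0), correlations=(0.0, 0.2, 0.5),
                   placement_repeats=2)


def _scenario_setup(scenario: str, cell_type: str, morph_pd0: Morphology,
                    morph_pd2: Morphology, placement_pd0: SynapsePlacement,
                    seed: int):
    neuron0 = SurrogateNeuron.preset(f"{cell_type}_PD0")
    if scenario == "PD0":
        return neuron0, placement_pd0
    neuron2 = SurrogateNeuron.preset(f"{cell_type}_PD2")
    pl2 = filter_surviving(placement_pd0, morph_pd2)
    if scenario == "PD2":
        return neuron2, pl2
    kind, level = scenario.rsplit("_", 1)
    spec = CompensationSpec(strategy=kind, level=float(level),
                            n_syn_PD0=placement_pd0.n_sites,
                            n_syn_PD2=pl2.n_sites)
    if kind == "strengthen":
        return neuron2, strengthen(pl2, spec)
    return neuron2, rewire(pl2, morph_pd2, spec, seed=seed + 7)


def run_protocol(grid: ProtocolGrid, cell_type: str,
                 morph_pd0: Morphology, morph_pd2: Morphology,
                 n_syn_pd0: int, seed: int = 0,
                 duration: float = 10.0) -> pd.DataFrame:
    """Mean output rate per (scenario, rate, correlation, repeat).

    Placements are redrawn per repeat (the paper's synapse-distribution
    variability); each stimulation lasts `duration` seconds.
    """
    rows = []
    for rep in range(grid.placement_repeats):
        pl0 = place_synapses(morph_pd0, n_syn_pd0, seed=seed + 1000 * rep)
        for scenario in grid.scenarios:
            neuron, pl = _scenario_setup(scenario, cell_type, morph_pd0,
                                         morph_pd2, pl0,
                                         seed + 1000 * rep)
            for rate in grid.rates:
                for corr in grid.correlations:
                    tr = generate_correlated_trains(SpikeGenSpec(
                        n_trains=max(1, pl.n_sites), rate=rate,
                        correlation=corr, duration=duration,
                        seed=seed + 1000 * rep
                        + int(1e4 * rate) + int(1e6 * corr)))
                    _, out = simulate_surrogate(neuron, pl, tr, duration)
                    rows.append((scenario, rate, corr, rep, out))
    return pd.DataFrame(rows, columns=["scenario", "rate", "correlation",
                                       "repeat", "output_rate"])


def protocol_marginals(results: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(rate vs λ averaged over c, rate vs c averaged over λ) per scenario."""
    by_rate = (results.groupby(["scenario", "rate"])
               .output_rate.mean().reset_index())
    by_corr = (results.groupby(["scenario", "correlation"])
               .output_rate.mean().reset_index())
    return by_rate, by_corr
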