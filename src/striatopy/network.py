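"""Neuron placement, touch detection, pruning and the PD network builds.

The striatal volume is modeled as a cube seeded with neurons at the
striatal density (80,500 neurons/mm³), ~95% of them projection neurons
(dSPN/iSPN in equal shares) and 3.2% modeled interneurons (FS, ChIN, LTS).
Putative synapses are located geometrically wherever a presynaptic axon
passes within a threshold distance of a postsynaptic dendrite or soma
(touch detection, deliberately an overestimate), then reduced by an ordered
set of stochastic pruning rules: a global random fraction, a
distance-to-soma-dependent keep probability, a per-pair soft cap, an
all-or-none removal of weakly coupled pairs, and an all-or-none removal of
coupled pairs at a fixed probability.

Disease-stage (PD) networks are derived three ways: the *degeneration*
method drops healthy-network synapses whose postsynaptic attachment point
was lost to dendritic atrophy; the *de novo* method re-runs touch detection
and pruning on the degenerated morphologies (capturing synapses gained by
FS axonal growth); and the *hybrid* method keeps the degeneration-method
synapses in place and tops up (or trims) each ordered type pair to the
de-novo count, the fraction added being the remapping fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .morphology import Morphology, Structure

__all__ = [
    "PlacementConfig",
    "NeuronInstance",
    "PruningRules",
    "PairRule",
    "PDBuildMethod",
    "SynapseTable",
    "ConfigurationError",
    "place_neurons",
    "touch_detect",
    "prune",
    "connection_probability",
    "build_pd_network",
    "ablate_types",
    "erode_synapses",
    "expected_connection_stats",
    "calibrate_f_keep",
]

MODELED_TYPES = ("dSPN", "iSPN", "FS", "ChIN", "LTS")
BASE_CONDUCTANCE_NS = 0.5

_SYNAPSE_COLUMNS = ["pre_id", "post_id", "pre_type", "post_type",
                    "x", "y", "z", "post_dist", "post_node", "cond"]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

@dataclass
class PlacementConfig:
    """Cube placement at striatal density and composition.

    The composition covers dSPN/iSPN (47.5% each) and the three modeled
    interneuron classes; the interneuron split within the 3.2% is a
    configuration assumption (FS 1.3%, ChIN 1.1%, LTS 0.8%). The remaining
    1.8% are placed as unmodeled cells that take part in no connectivity.
    """

    cube_side: float = 1000.0          # µm
    density: float = 80500.0           # neurons / mm³
    composition: Mapping[str, float] = field(default_factory=lambda: {
        "dSPN": 0.475, "iSPN": 0.475, "FS": 0.013, "ChIN": 0.011,
        "LTS": 0.008})
    seed: int = 0

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        if sum(self.composition.values()) > 1.0 + 1e-9:
            raise ValueError("composition fractions must sum to <= 1")


@dataclass
class NeuronInstance:
    id: int
    cell_type: str
    morphology_ref: str | None
    position: np.ndarray          # (3,) µm
    rotation: np.ndarray          # (3, 3)


def place_neurons(config: PlacementConfig,
                  morphology_refs: Mapping[str, Sequence[str]] | None = None,
                  ) -> list[NeuronInstance]:
    """Uniform i.i.d. positions and rotations in the cube, typed by fractions.

    Count = round(density × volume). Type counts follow the largest-remainder
    allocation of the composition fractions (the leftover fraction becomes
    unmodeled 'other' cells with no morphology). Deterministic per seed.
    """
    from scipy.spatial.transform import Rotation

    volume_mm3 = (config.cube_side * 1e-3) ** 3
    n = int(round(config.density * volume_mm3))
    if n == 0:
        return []
    rng = np.random.default_rng(config.seed)
    fracs = dict(config.composition)
    other = 1.0 - sum(fracs.values())
    if other > 1e-9:
        fracs["other"] = other
    raw = {t: f * n for t, f in fracs.items()}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    short = n - sum(counts.values())
    for t in sorted(raw, key=lambda t: raw[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    types = np.array([t for t, c in counts.items() for _ in range(c)])
    rng.shuffle(types)
    positions = rng.uniform(0.0, config.cube_side, size=(n, 3))
    rotations = Rotation.random(n, rng=rng).as_matrix()
    out = []
    for i in range(n):
        t = str(types[i])
        ref = None
        if t != "other":
            pool = (morphology_refs or {}).get(t)
            ref = (pool[rng.integers(len(pool))] if pool else t)
        out.append(NeuronInstance(i, t, ref, positions[i], rotations[i]))
    return out


# ---------------------------------------------------------------------------
# Touch detection
# ---------------------------------------------------------------------------

def _morph_segments(morph: Morphology):
    """Per-morphology segment cache: endpoints, child structure/arc/id."""
    pi, ci = morph.segments()
    arc = morph.arc_distance_to_soma()
    a = morph.xyz[pi]
    b = morph.xyz[ci]
    # soma represented as a zero-length segment at the soma position
    soma = morph.soma_position[None, :]
    a = np.vstack([a, soma])
    b = np.vstack([b, soma])
    struct = np.concatenate([morph.structure[ci],
                             [int(Structure.SOMA)]]).astype(np.int8)
    arcs = np.concatenate([arc[ci], [0.0]])
    child = np.concatenate([morph.ids[ci], [morph.ids[0]]])
    arc_par = np.concatenate([arc[pi], [0.0]])
    return a, b, struct, arcs, arc_par, child


def _segment_closest(a0, a1, b0, b1):
    """Closest-approach parameters and distance for segment pairs (vectorized).

    Segments a0→a1 and b0→b1; returns (dist, s, t) with closest points
    a0+s·(a1−a0) and b0+t·(b1−b0). Clamped closest-point algorithm,
    handling degenerate (point) segments on either side.
    """
    eps = 1e-12
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    a_safe = np.where(a > eps, a, 1.0)
    e_safe = np.where(e > eps, e, 1.0)
    denom = a * e - b * b
    s = np.where(denom > eps,
                 np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0),
                         0.0, 1.0), 0.0)
    t = np.where(e > eps, (b * s + f) / e_safe, 0.0)
    tlow = t < 0.0
    thigh = t > 1.0
    t = np.clip(t, 0.0, 1.0)
    s = np.where(tlow, np.clip(-c / a_safe, 0.0, 1.0),
                 np.where(thigh, np.clip((b - c) / a_safe, 0.0, 1.0), s))
    s = np.where(e <= eps, np.clip(-c / a_safe, 0.0, 1.0), s)
    s = np.where(a > eps, s, 0.0)
    c1 = a0 + s[:, None] * d1
    c2 = b0 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1), s, t


def _world_segment_tables(instances, morphologies):
    """World-coordinate axonal (pre) and dendritic/somatic (post) segments."""
    cache = {}
    pre, post = [], []
    for inst in instances:
        if inst.morphology_ref is None:
            continue
        if inst.morphology_ref not in cache:
            cache[inst.morphology_ref] = _morph_segments(
                morphologies[inst.morphology_ref])
        a, b, struct, arcs, arc_par, child = cache[inst.morphology_ref]
        aw = a @ inst.rotation.T + inst.position
        bw = b @ inst.rotation.T + inst.position
        mask = struct == Structure.AXON
        if mask.any():
            pre.append((inst.id, aw[mask], bw[mask]))
        mask = struct != Structure.AXON
        if mask.any():
            post.append((inst.id, aw[mask], bw[mask], arcs[mask],
                         arc_par[mask], child[mask]))
    return pre, post


def _concat_pre(pre):
    owner = np.concatenate([np.full(len(a), i) for i, a, b in pre])
    A = np.vstack([a for _, a, _ in pre])
    B = np.vstack([b for _, _, b in pre])
    return owner, A, B


def _concat_post(post):
    owner = np.concatenate([np.full(len(a), i) for i, a, *_ in post])
    A = np.vstack([p[1] for p in post])
    B = np.vstack([p[2] for p in post])
    arcs = np.concatenate([p[3] for p in post])
    arc_par = np.concatenate([p[4] for p in post])
    child = np.concatenate([p[5] for p in post])
    return owner, A, B, arcs, arc_par, child


def _ranges_concat(starts, counts):
    """Concatenate [s, s+c) ranges: vectorized grouped arange."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    rep = np.repeat(np.arange(len(starts)), counts)
    offs = np.arange(total) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    return rep, starts[rep] + offs


def _pairs_to_frame(instances, pre_owner, post_owner, dist_ok, xyz,
                    post_dist, post_node):
    type_of = {inst.id: inst.cell_type for inst in instances}
    df = pd.DataFrame({
        "pre_id": pre_owner, "post_id": post_owner,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        "post_dist": post_dist, "post_node": post_node})
    df["pre_type"] = df.pre_id.map(type_of)
    df["post_type"] = df.post_id.map(type_of)
    return df[["pre_id", "post_id", "pre_type", "post_type",
               "x", "y", "z", "post_dist", "post_node"]].reset_index(drop=True)


def touch_detect(instances: Sequence[NeuronInstance],
                 morphologies: Mapping[str, Morphology],
                 max_distance: float = 3.0,
                 voxel_size: float = 10.0,
                 method: str = "voxel") -> pd.DataFrame:
    """Putative synapses: axon segments within max_distance of dendrite/soma.

    One putative synapse per close (axonal segment, dendritic/somatic
    segment) pair, located at the midpoint of closest approach; the output
    is independent of voxel_size, which only accelerates the candidate
    search (method='brute' runs the all-pairs scan used as the oracle).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pre, post = _world_segment_tables(instances, morphologies)
    if not pre or not post:
        return _pairs_to_frame(instances, np.empty(0, int), np.empty(0, int),
                               None, np.empty((0, 3)), np.empty(0),
                               np.empty(0, int))
    pre_owner, PA, PB = _concat_pre(pre)
    post_owner, QA, QB, q_arc, q_arc_par, q_child = _concat_post(post)
    if method == "brute":
        i, j = np.meshgrid(np.arange(len(PA)), np.arange(len(QA)),
                           indexing="ij")
        cand_pre, cand_post = i.ravel(), j.ravel()
    elif method == "voxel":
        mid_pre = 0.5 * (PA + PB)
        mid_post = 0.5 * (QA + QB)
        len_pre = np.linalg.norm(PB - PA, axis=1)
        len_post = np.linalg.norm(QB - QA, axis=1)
        reach = max_distance + 0.5 * (len_pre.max() + len_post.max())
        r = max(1, int(math.ceil(reach / voxel_size)))
        origin = np.minimum(mid_pre.min(0), mid_post.min(0)) - voxel_size
        cp = np.floor((mid_pre - origin) / voxel_size).astype(np.int64)
        cq = np.floor((mid_post - origin) / voxel_size).astype(np.int64)
        dims = np.maximum(cp.max(0), cq.max(0)) + 2 * r + 2
        key_q = np.ravel_multi_index((cq + r).T, dims)
        order = np.argsort(key_q, kind="stable")
        key_q_sorted = key_q[order]
        cand_pre_parts, cand_post_parts = [], []
        offsets = [(dx, dy, dz) for dx in range(-r, r + 1)
                   for dy in range(-r, r + 1) for dz in range(-r, r + 1)]
        for off in offsets:
            kp = np.ravel_multi_index((cp + r + np.asarray(off)).T, dims)
            lo = np.searchsorted(key_q_sorted, kp, side="left")
            hi = np.searchsorted(key_q_sorted, kp, side="right")
            rep, idx = _ranges_concat(lo, hi - lo)
            if len(rep):
                cand_pre_parts.append(rep)
                cand_post_parts.append(order[idx])
        if cand_pre_parts:
            cand_pre = np.concatenate(cand_pre_parts)
            cand_post = np.concatenate(cand_post_parts)
        else:
            cand_pre = np.empty(0, dtype=np.int64)
            cand_post = np.empty(0, dtype=np.int64)
    else:
        raise ValueError(f"unknown method {method!r}")
    keep_rows = []
    chunk = 2_000_000
    for s0 in range(0, len(cand_pre), chunk):
        ip = cand_pre[s0:s0 + chunk]
        iq = cand_post[s0:s0 + chunk]
        same = pre_owner[ip] == post_owner[iq]
        ip, iq = ip[~same], iq[~same]
        if len(ip) == 0:
            continue
        d, s, t = _segment_closest(PA[ip], PB[ip], QA[iq], QB[iq])
        hit = d <= max_distance
        ip, iq, s, t = ip[hit], iq[hit], s[hit], t[hit]
        if len(ip) == 0:
            continue
        c1 = PA[ip] + s[:, None] * (PB[ip] - PA[ip])
        c2 = QA[iq] + t[:, None] * (QB[iq] - QA[iq])
        xyz = 0.5 * (c1 + c2)
        pdist = q_arc_par[iq] + t * (q_arc[iq] - q_arc_par[iq])
        keep_rows.append((pre_owner[ip], post_owner[iq], xyz, pdist,
                          q_child[iq]))
    if not keep_rows:
        return _pairs_to_frame(instances, np.empty(0, int), np.empty(0, int),
                               None, np.empty((0, 3)), np.empty(0),
                               np.empty(0, int))
    pre_o = np.concatenate([k[0] for k in keep_rows])
    post_o = np.concatenate([k[1] for k in keep_rows])
    xyz = np.vstack([k[2] for k in keep_rows])
    pdist = np.concatenate([k[3] for k in keep_rows])
    child = np.concatenate([k[4] for k in keep_rows])
    df = _pairs_to_frame(instances, pre_o, post_o, None, xyz, pdist, child)
    return df.sort_values(["pre_id", "post_id", "post_node", "post_dist"],
                          kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

@dataclass
class PairRule:
    """Pruning parameters for one ordered (pre type, post type) pair.

    dist_keep is a keep-probability profile in the postsynaptic
    distance-to-soma d: {'kind': 'exp_decay'|'exp_rise'|'none',
    'scale': µm} giving exp(−d/scale) or 1−exp(−d/scale) — proximal (FS)
    vs distal (LTS) targeting. The few-synapse rule removes all synapses of
    a pair with fewer than few_threshold synapses with probability
    few_removal_max·(few_threshold − k)/(few_threshold − 1).
    """

    f_keep_random: float = 1.0
    dist_keep: dict | None = None
    soft_max: int | None = None
    few_threshold: int | None = None
    few_removal_max: float = 0.0
    pair_removal_probability: float = 0.0

    def __post_init__(self):
        for p in (self.f_keep_random, self.few_removal_max,
                  self.pair_removal_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def dist_keep_probability(self, d: np.ndarray) -> np.ndarray:
        if self.dist_keep is None or self.dist_keep.get("kind", "none") == "none":
            return np.ones_like(d)
        scale = float(self.dist_keep["scale"])
        if self.dist_keep["kind"] == "exp_decay":
            return np.exp(-d / scale)
        if self.dist_keep["kind"] == "exp_rise":
            return 1.0 - np.exp(-d / scale)
        raise ConfigurationError(
            f"unknown dist_keep kind {self.dist_keep['kind']!r}")


@dataclass
class PruningRules:
    """Per-ordered-type-pair rules; every occurring pair must be covered."""

    pairs: Mapping[tuple[str, str], PairRule] = field(default_factory=dict)
    default: PairRule | None = None

    def for_pair(self, pre_type: str, post_type: str) -> PairRule:
        key = (pre_type, post_type)
        if key in self.pairs:
            return self.pairs[key]
        if self.default is not None:
            return self.default
        raise ConfigurationError(
            f"no pruning rule for type pair {key}")

    @classmethod
    def permissive(cls) -> "PruningRules":
        return cls(default=PairRule())


def prune(putative: pd.DataFrame, rules: PruningRules,
          seed: int = 0) -> "SynapseTable":
    """Apply the ordered pruning rules to a putative synapse table.

    Order: random fraction → distance-dependent keep → per-pair soft cap →
    all-or-none removal of weakly coupled pairs → all-or-none removal of
    coupled pairs. Never creates a synapse; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    df = putative.reset_index(drop=True)
    if len(df) == 0:
        return SynapseTable(df.assign(cond=pd.Series(dtype=float)))
    for pre_t, post_t in (df[["pre_type", "post_type"]]
                          .drop_duplicates().itertuples(index=False)):
        rules.for_pair(pre_t, post_t)   # fail fast on uncovered pairs

    pair_key = df.pre_type + "→" + df.post_type
    keep = np.ones(len(df), dtype=bool)
    # 1) random fraction, 2) distance-dependent keep
    for key in pair_key.unique():
        rule = rules.for_pair(*key.split("→"))
        sel = (pair_key == key).to_numpy()
        u = rng.random(int(sel.sum()))
        p = rule.f_keep_random * rule.dist_keep_probability(
            df.post_dist.to_numpy()[sel])
        keep[sel] &= u < p
    df = df[keep].reset_index(drop=True)
    # 3) soft cap per connected pair
    keep = np.ones(len(df), dtype=bool)
    grp = df.groupby(["pre_id", "post_id"], sort=True).indices
    for (pre, post), idx in grp.items():
        rule = rules.for_pair(df.pre_type.iat[idx[0]], df.post_type.iat[idx[0]])
        if rule.soft_max is not None and len(idx) > rule.soft_max:
            drop = rng.choice(idx, size=len(idx) - rule.soft_max,
                              replace=False)
            keep[drop] = False
    df = df[keep].reset_index(drop=True)
    # 4) too-few-synapses all-or-none, 5) coupled-pair removal
    keep = np.ones(len(df), dtype=bool)
    grp = df.groupby(["pre_id", "post_id"], sort=True).indices
    for (pre, post), idx in grp.items():
        rule = rules.for_pair(df.pre_type.iat[idx[0]], df.post_type.iat[idx[0]])
        k = len(idx)
        if (rule.few_threshold is not None and k < rule.few_threshold
                and rule.few_threshold > 1):
            p_rm = rule.few_removal_max * (rule.few_threshold - k) / (
                rule.few_threshold - 1)
            if rng.random() < min(1.0, p_rm):
                keep[idx] = False
                continue
        if rule.pair_removal_probability > 0 and \
                rng.random() < rule.pair_removal_probability:
            keep[idx] = False
    df = df[keep].reset_index(drop=True)
    df["cond"] = BASE_CONDUCTANCE_NS
    return SynapseTable(df)


def expected_connection_stats(putative: pd.DataFrame,
                              rules: PruningRules) -> tuple[float, float]:
    """Noise-free expectations under the per-synapse pruning rules.

    Returns (expected kept synapse count, expected connected-pair count),
    where each putative synapse is kept independently with probability
    f_keep_random × dist_keep(post_dist) and a pair connects when at least
    one synapse is kept. Pair-level rules (soft cap, few-synapse and
    coupled-pair removal) are not included. Deterministic; useful for
    directional comparisons without Monte Carlo noise.
    """
    df = putative
    if len(df) == 0:
        return 0.0, 0.0
    p = np.empty(len(df))
    pair_key = df.pre_type + "→" + df.post_type
    for key in pair_key.unique():
        rule = rules.for_pair(*key.split("→"))
        sel = (pair_key == key).to_numpy()
        p[sel] = rule.f_keep_random * rule.dist_keep_probability(
            df.post_dist.to_numpy()[sel])
    exp_syn = float(p.sum())
    log_miss = pd.Series(np.log1p(-np.clip(p, 0.0, 1.0 - 1e-12)))
    grp = log_miss.groupby([df.pre_id, df.post_id]).sum()
    exp_pairs = float((1.0 - np.exp(grp.to_numpy())).sum())
    return exp_syn, exp_pairs


def calibrate_f_keep(putative: pd.DataFrame, instances, pre_type: str,
                     post_type: str, target_p: float, within: float = 100.0,
                     seed: int = 0, tol: float = 0.01,
                     max_iter: int = 20) -> float:
    """Bisect the random keep fraction so the connection probability of the
    given ordered type pair (somata within `within` µm) matches target_p."""
    def p_at(f):
        rules = PruningRules(default=PairRule(f_keep_random=f))
        table = prune(putative, rules, seed=seed)
        bins = np.array([0.0, within])
        res = connection_probability(table, instances, pre_type, post_type,
                                     bins)
        return float(res.p_hat.iloc[0]) if len(res) else 0.0

    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = p_at(mid)
        if abs(p - target_p) < tol:
            return mid
        if p < target_p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Synapse table
# ---------------------------------------------------------------------------

class SynapseTable:
    """The network's ground truth: one row per synapse.

    Columns: pre_id, post_id, pre_type, post_type, x, y, z, post_dist (arc
    length to the postsynaptic soma, µm), post_node (postsynaptic segment's
    child node id), cond (nS).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        if "cond" not in df.columns:
            df = df.assign(cond=BASE_CONDUCTANCE_NS)
        if len(df):
            if (df.pre_id == df.post_id).any():
                raise ValueError("self-synapses are not allowed")
            if (df.cond <= 0).any():
                raise ValueError("conductances must be positive")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "SynapseTable":
        return SynapseTable(self.df.copy())

    def pair_counts(self) -> pd.Series:
        return self.df.groupby(["pre_type", "post_type"]).size()

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("pre", data=self.df.pre_id.to_numpy(np.int64))
            f.create_dataset("post", data=self.df.post_id.to_numpy(np.int64))
            f.create_dataset("xyz", data=self.df[["x", "y", "z"]].to_numpy())
            f.create_dataset("dist", data=self.df.post_dist.to_numpy())
            f.create_dataset("cond", data=self.df.cond.to_numpy())
            f.create_dataset("post_node",
                             data=self.df.post_node.to_numpy(np.int64))
            dt = h5py.string_dtype()
            f.create_dataset("pre_type",
                             data=self.df.pre_type.to_numpy(dtype=object),
                             dtype=dt)
            f.create_dataset("post_type",
                             data=self.df.post_type.to_numpy(dtype=object),
                             dtype=dt)

    @classmethod
    def from_hdf5(cls, path) -> "SynapseTable":
        import h5py

        with h5py.File(path, "r") as f:
            df = pd.DataFrame({
                "pre_id": f["pre"][:], "post_id": f["post"][:],
                "pre_type": [s.decode() for s in f["pre_type"][:]],
                "post_type": [s.decode() for s in f["post_type"][:]],
                "x": f["xyz"][:, 0], "y": f["xyz"][:, 1],
                "z": f["xyz"][:, 2],
                "post_dist": f["dist"][:], "post_node": f["post_node"][:],
                "cond": f["cond"][:]})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SynapseTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Pairwise connection probability
# ---------------------------------------------------------------------------

def connection_probability(table: SynapseTable, instances, pre_type: str,
                           post_type: str,
                           distance_bins: Sequence[float]) -> pd.DataFrame:
    """p̂ and Wilson 95% score interval per soma-distance bin.

    A pair counts as connected when it has at least one synapse; the
    denominator is every ordered (pre, post) pair of the requested types
    whose soma distance falls in the bin. Empty bins are flagged with NaN.
    """
    from statsmodels.stats.proportion import proportion_confint

    bins = np.asarray(distance_bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("distance_bins must be strictly increasing")
    pre = [i for i in instances if i.cell_type == pre_type]
    post = [i for i in instances if i.cell_type == post_type]
    if not pre or not post:
        raise ValueError("no instances of the requested types")
    ppos = np.array([i.position for i in pre])
    qpos = np.array([i.position for i in post])
    dmat = np.linalg.norm(ppos[:, None, :] - qpos[None, :, :], axis=2)
    pids = np.array([i.id for i in pre])
    qids = np.array([i.id for i in post])
    same = pids[:, None] == qids[None, :]
    sub = table.df[(table.df.pre_type == pre_type)
                   & (table.df.post_type == post_type)]
    big = int(max(pids.max(), qids.max(),
                  sub.post_id.max() if len(sub) else 0)) + 1
    pair_keys = pids[:, None].astype(np.int64) * big + qids[None, :]
    conn_keys = sub.pre_id.to_numpy(np.int64) * big + \
        sub.post_id.to_numpy(np.int64)
    conn = np.isin(pair_keys, conn_keys)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        sel = (dmat >= lo) & (dmat < hi) & ~same
        n = int(sel.sum())
        k = int(conn[sel].sum())
        if n == 0:
            rows.append((lo, hi, 0, 0, np.nan, np.nan, np.nan))
            continue
        low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((lo, hi, n, k, k / n, low, high))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_pairs",
                                       "n_connected", "p_hat",
                                       "wilson_low", "wilson_high"])


# ---------------------------------------------------------------------------
# PD network builds
# ---------------------------------------------------------------------------

@dataclass
class PDBuildMethod:
    method: str = "hybrid"            # degeneration | de_novo | hybrid

    def __post_init__(self):
        if self.method not in ("degeneration", "de_novo", "hybrid"):
            raise ValueError(f"unknown PD build method {self.method!r}")


def _degeneration_table(pd0: SynapseTable, instances,
                        stage_morphs: Mapping[str, Morphology]) -> pd.DataFrame:
    ref_of = {i.id: i.morphology_ref for i in instances}
    node_sets = {ref: set(m.ids.tolist())
                 for ref, m in stage_morphs.items()}
    df = pd0.df
    keep = np.fromiter(
        (int(node) in node_sets[ref_of[int(pid)]]
         for pid, node in zip(df.post_id, df.post_node)),
        dtype=bool, count=len(df))
    return df[keep].reset_index(drop=True)


def build_pd_network(pd0_table: SynapseTable,
                     instances: Sequence[NeuronInstance],
                     morphologies_by_stage: Mapping[str, Mapping[str, Morphology]],
                     stage: str,
                     method: PDBuildMethod,
                     rules: PruningRules,
                     seed: int = 0,
                     max_distance: float = 3.0,
                     voxel_size: float = 10.0,
                     ) -> tuple[SynapseTable, dict]:
    """Derive a disease-stage synapse table from the healthy network.

    Returns (table, info); info records per-type-pair counts and, for the
    hybrid method, the emergent remapping fraction (added de-novo synapses /
    de-novo count) per ordered type pair.
    """
    if stage not in morphologies_by_stage:
        raise ValueError(f"no morphologies for stage {stage!r}")
    if stage == "PD0":
        return pd0_table.copy(), {"stage": "PD0"}
    stage_morphs = morphologies_by_stage[stage]
    info: dict = {"stage": stage, "method": method.method}
    if method.method == "degeneration":
        df = _degeneration_table(pd0_table, instances, stage_morphs)
        df["cond"] = BASE_CONDUCTANCE_NS
        return SynapseTable(df), info
    putative = touch_detect(instances, stage_morphs,
                            max_distance=max_distance, voxel_size=voxel_size)
    de_novo = prune(putative, rules, seed=seed)
    if method.method == "de_novo":
        return de_novo, info
    # hybrid: degeneration synapses kept in place, counts matched per pair
    rng = np.random.default_rng(seed + 1)
    degen = _degeneration_table(pd0_table, instances, stage_morphs)
    parts = []
    remap = {}
    keys = set(map(tuple, degen[["pre_type", "post_type"]].itertuples(
        index=False))) | set(map(tuple, de_novo.df[
            ["pre_type", "post_type"]].itertuples(index=False)))
    for key in sorted(keys):
        d_rows = degen[(degen.pre_type == key[0])
                       & (degen.post_type == key[1])]
        n_rows = de_novo.df[(de_novo.df.pre_type == key[0])
                            & (de_novo.df.post_type == key[1])]
        target = len(n_rows)
        if len(d_rows) > target:
            idx = rng.choice(len(d_rows), size=target, replace=False)
            parts.append(d_rows.iloc[np.sort(idx)])
            remap[key] = 0.0
        else:
            parts.append(d_rows)
            n_add = target - len(d_rows)
            if n_add > 0:
                idx = rng.choice(len(n_rows), size=n_add, replace=False)
                parts.append(n_rows.iloc[np.sort(idx)])
            remap[key] = n_add / target if target else 0.0
    df = pd.concat(parts, ignore_index=True) if parts else degen.iloc[:0]
    df["cond"] = BASE_CONDUCTANCE_NS
    info["remapping_fraction"] = remap
    return SynapseTable(df.reset_index(drop=True)), info


# ---------------------------------------------------------------------------
# Ablation and erosion
# ---------------------------------------------------------------------------

def ablate_types(table: SynapseTable, types: set[str]) -> SynapseTable:
    """Remove every synapse touching any of the listed cell types."""
    df = table.df
    keep = ~(df.pre_type.isin(types) | df.post_type.isin(types))
    return SynapseTable(df[keep].reset_index(drop=True))


def erode_synapses(table: SynapseTable, fraction: float,
                   scope: str = "all", seed: int = 0) -> SynapseTable:
    """Remove a uniformly random fraction of synapses in scope.

    scope='SPN_only' restricts removal to synapses with both endpoints SPN;
    other synapses are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    df = table.df
    if scope == "all":
        in_scope = np.ones(len(df), dtype=bool)
    elif scope == "SPN_only":
        spn = {"dSPN", "iSPN"}
        in_scope = (df.pre_type.isin(spn) & df.post_type.isin(spn)).to_numpy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    rng = np.random.default_rng(seed)
    drop = in_scope & (rng.random(len(df)) < fraction)
    if fraction >= 1.0:
        drop = in_scope
    return SynapseTable(df[~drop].reset_index(drop=True))
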