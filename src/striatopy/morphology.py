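"""Neuronal morphologies and the Parkinsonian stage transforms.

A morphology is a rooted tree of typed 3-D points with SWC semantics: a
single soma root, axonal and dendritic nodes, each node connected to a
parent defined earlier in the file. On top of reading/writing and basic
morphometry (total length per structure, branch points, primary dendrites,
Sholl profiles) this module implements the two disease-stage transforms:

* stepwise dendritic truncation — at every truncation step each dendritic
  terminal loses a fixed 3 µm of path length, emulating the distal-first
  dendritic atrophy of striatal projection neurons (SPNs) across disease
  stages PD0 (healthy) through PD3;
* axonal terminal extension — every axonal terminal of a fast-spiking (FS)
  interneuron arbor is extended by a fixed 61 µm along a persistent random
  walk, emulating compensatory FS axonal sprouting while keeping the radius
  of the arbor approximately unchanged (optionally enforced by a reflective
  cap).

All lengths are in micrometres.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Structure",
    "Morphology",
    "MorphometryReport",
    "DegenerationSchedule",
    "GrowthSpec",
    "SWCParseError",
    "read_swc",
    "write_swc",
    "resample",
    "morphometry",
    "sholl_profile",
    "degenerate_step",
    "degenerate",
    "grow_axon_terminals",
]

_EPS = 1e-9


class Structure(enum.IntEnum):
    """SWC structure codes (4 = apical dendrite is folded into DENDRITE)."""

    SOMA = 1
    AXON = 2
    DENDRITE = 3


_SWC_CODE = {1: Structure.SOMA, 2: Structure.AXON, 3: Structure.DENDRITE,
             4: Structure.DENDRITE}


class SWCParseError(ValueError):
    pass


class Morphology:
    """Immutable rooted tree of typed 3-D points.

    Parameters
    ----------
    ids : (n,) int array — node identifiers, unique.
    structure : (n,) int array of :class:`Structure` codes.
    xyz : (n, 3) float array, µm.
    radius : (n,) float array, µm.
    parent : (n,) int array — parent *id* (not index); -1 marks the root.

    Nodes must be topologically ordered: every parent id refers to a node
    defined earlier in the arrays. There is exactly one root and it is the
    soma.
    """

    def __init__(self, ids, structure, xyz, radius, parent):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.structure = np.asarray(structure, dtype=np.int8)
        self.xyz = np.asarray(xyz, dtype=np.float64).reshape(-1, 3)
        self.radius = np.asarray(radius, dtype=np.float64)
        self.parent = np.asarray(parent, dtype=np.int64)
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        # parent index array (-1 for root)
        pidx = np.full(self.n_nodes, -1, dtype=np.int64)
        for k, p in enumerate(self.parent):
            if p != -1:
                pidx[k] = self._index[int(p)]
        self.parent_index = pidx
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(counts, pidx[pidx >= 0], 1)
        self.n_children = counts

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        n = len(self.ids)
        if not (len(self.structure) == len(self.xyz) == len(self.radius)
                == len(self.parent) == n):
            raise ValueError("inconsistent array lengths")
        if n == 0:
            raise ValueError("empty morphology")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("duplicate node ids")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if roots[0] != 0:
            raise ValueError("root must be the first node")
        if self.structure[0] != Structure.SOMA:
            raise ValueError("root must be a soma node")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        seen: set[int] = set()
        for k in range(n):
            if self.parent[k] != -1 and int(self.parent[k]) not in seen:
                raise ValueError(
                    f"node {int(self.ids[k])} references parent "
                    f"{int(self.parent[k])} not defined earlier")
            seen.add(int(self.ids[k]))

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def soma_position(self) -> np.ndarray:
        return self.xyz[0]

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def copy(self) -> "Morphology":
        return Morphology(self.ids.copy(), self.structure.copy(),
                          self.xyz.copy(), self.radius.copy(),
                          self.parent.copy())

    # -- derived geometry -----------------------------------------------------

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(parent_index, child_index) arrays, one entry per non-root node."""
        child = np.flatnonzero(self.parent_index >= 0)
        return self.parent_index[child], child

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of each parent→child segment (per non-root node)."""
        pi, ci = self.segments()
        return np.linalg.norm(self.xyz[ci] - self.xyz[pi], axis=1)

    def arc_distance_to_soma(self) -> np.ndarray:
        """Path length from the soma to every node, along the tree (µm)."""
        dist = np.zeros(self.n_nodes)
        for k in range(1, self.n_nodes):
            p = self.parent_index[k]
            dist[k] = dist[p] + np.linalg.norm(self.xyz[k] - self.xyz[p])
        return dist

    def total_length(self, structure: Structure) -> float:
        """Summed segment length; a segment carries its child's structure."""
        pi, ci = self.segments()
        mask = self.structure[ci] == structure
        return float(np.linalg.norm(
            self.xyz[ci[mask]] - self.xyz[pi[mask]], axis=1).sum())

    def terminals(self, structure: Structure | None = None) -> np.ndarray:
        """Indices of leaf nodes, optionally restricted to one structure."""
        leaf = self.n_children == 0
        leaf[0] = False
        if structure is not None:
            leaf &= self.structure == structure
        return np.flatnonzero(leaf)

    def children_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for k in range(1, self.n_nodes):
            out[self.parent_index[k]].append(k)
        return out


def _from_records(records) -> Morphology:
    """Build a Morphology from (id, structure, x, y, z, r, parent) tuples."""
    ids = [r[0] for r in records]
    struct = [r[1] for r in records]
    xyz = [(r[2], r[3], r[4]) for r in records]
    rad = [r[5] for r in records]
    par = [r[6] for r in records]
    return Morphology(ids, struct, xyz, rad, par)


# ---------------------------------------------------------------------------
# SWC input / output
# ---------------------------------------------------------------------------

def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file.

    Raises :class:`SWCParseError` naming the offending line for malformed
    records, unknown structure codes, forward parent references or multiple
    roots.
    """
    records = []
    seen: set[int] = set()
    n_roots = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path}: line {lineno}: expected 7 columns, "
                    f"got {len(fields)}")
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                par = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(
                    f"{path}: line {lineno}: {exc}") from None
            if code not in _SWC_CODE:
                raise SWCParseError(
                    f"{path}: line {lineno}: unsupported structure "
                    f"code {code}")
            if par == -1:
                n_roots += 1
                if n_roots > 1:
                    raise SWCParseError(
                        f"{path}: line {lineno}: multiple roots")
            elif par not in seen:
                raise SWCParseError(
                    f"{path}: line {lineno}: parent {par} not defined "
                    f"before node {nid}")
            seen.add(nid)
            records.append((nid, _SWC_CODE[code], x, y, z, r, par))
    if not records:
        raise SWCParseError(f"{path}: no records")
    try:
        return _from_records(records)
    except ValueError as exc:
        raise SWCParseError(f"{path}: {exc}") from None


def write_swc(morph: Morphology, path) -> None:
    """Write a 7-column SWC file, renumbering ids 1..n in topological order."""
    remap = {int(old): k + 1 for k, old in enumerate(morph.ids)}
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(morph.n_nodes):
            par = morph.parent[k]
            new_par = -1 if par == -1 else remap[int(par)]
            x, y, z = morph.xyz[k]
            fh.write(f"{k + 1} {int(morph.structure[k])} "
                     f"{x:.9g} {y:.9g} {z:.9g} "
                     f"{morph.radius[k]:.6g} {new_par}\n")


# ---------------------------------------------------------------------------
# Sections and resampling
# ---------------------------------------------------------------------------

def _sections(morph: Morphology) -> list[list[int]]:
    """Unbranched sections as node-index paths [anchor, ..., end].

    A section starts at a child of the root, of a branch point (≥2 children)
    or of a structure change, and runs until a leaf, a branch point or the
    next structure change. The anchor (first element) is the parent node and
    is shared with the upstream section.
    """
    kids = morph.children_lists()
    out = []
    for k in range(1, morph.n_nodes):
        p = morph.parent_index[k]
        starts = (p == 0 or morph.n_children[p] >= 2
                  or morph.structure[p] != morph.structure[k])
        if not starts:
            continue
        path = [int(p), k]
        cur = k
        while (morph.n_children[cur] == 1
               and morph.structure[kids[cur][0]] == morph.structure[cur]):
            cur = kids[cur][0]
            path.append(cur)
        out.append(path)
    return out


def resample(morph: Morphology, resolution: float) -> Morphology:
    """Re-place nodes along every unbranched section at spacing ≤ resolution.

    Section endpoints (anchors, branch points, terminals) are preserved,
    with their ids; interior nodes are replaced by equally spaced points
    along the original polyline. Path length per section is preserved up to
    the chord-shortening across corners (< resolution per section).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    keep_pos: dict[int, np.ndarray] = {}
    new_children: dict[int, list[tuple]] = {}
    next_id = int(morph.ids.max()) + 1
    for path in _sections(morph):
        pts = morph.xyz[path]
        rad = morph.radius[path]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total <= _EPS:
            n_seg = 1
        else:
            n_seg = max(1, int(math.ceil(total / resolution - 1e-9)))
        targets = np.linspace(0.0, total, n_seg + 1)[1:]
        new_pts = np.column_stack([
            np.interp(targets, arc, pts[:, d]) for d in range(3)])
        new_rad = np.interp(targets, arc, rad)
        anchor_id = int(morph.ids[path[0]])
        end_idx = path[-1]
        chain = []
        for j in range(n_seg):
            if j == n_seg - 1:
                nid = int(morph.ids[end_idx])
                pos, r = morph.xyz[end_idx], morph.radius[end_idx]
            else:
                nid = next_id
                next_id += 1
                pos, r = new_pts[j], new_rad[j]
            chain.append((nid, int(morph.structure[end_idx]), pos, r))
        new_children.setdefault(anchor_id, []).append(chain)
        keep_pos[int(morph.ids[end_idx])] = morph.xyz[end_idx]
    # rebuild depth-first from the root
    records = [(int(morph.ids[0]), int(morph.structure[0]),
                *morph.xyz[0], morph.radius[0], -1)]
    stack = [int(morph.ids[0])]
    emitted = {int(morph.ids[0])}
    while stack:
        nid = stack.pop()
        for chain in new_children.get(nid, []):
            par = nid
            for cid, struct, pos, r in chain:
                records.append((cid, struct, pos[0], pos[1], pos[2], r, par))
                par = cid
            last = chain[-1][0]
            if last not in emitted:
                emitted.add(last)
                stack.append(last)
    return _from_records(records)


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

@dataclass
class MorphometryReport:
    total_dendritic_length: float
    total_axonal_length: float
    n_branch_points: int
    n_primary_dendrites: int
    max_euclidean_distance_from_soma: float
    max_euclidean_distance_dendrite: float
    max_euclidean_distance_axon: float
    sholl: dict[float, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sholl"}
        return d


def sholl_profile(morph: Morphology, radii: Sequence[float],
                  structure: Structure = Structure.DENDRITE) -> dict[float, int]:
    """Crossing counts of concentric spheres centred on the soma.

    A segment crosses the sphere of radius r when its endpoint Euclidean
    distances from the soma straddle r.
    """
    pi, ci = morph.segments()
    mask = morph.structure[ci] == structure
    pi, ci = pi[mask], ci[mask]
    soma = morph.soma_position
    d0 = np.linalg.norm(morph.xyz[pi] - soma, axis=1)
    d1 = np.linalg.norm(morph.xyz[ci] - soma, axis=1)
    lo, hi = np.minimum(d0, d1), np.maximum(d0, d1)
    return {float(r): int(np.sum((lo < r) & (r <= hi))) for r in radii}


def morphometry(morph: Morphology, sholl_step: float = 10.0) -> MorphometryReport:
    """Summary morphometrics (Sholl computed for dendrites)."""
    dend_len = morph.total_length(Structure.DENDRITE)
    axon_len = morph.total_length(Structure.AXON)
    kids = morph.children_lists()
    n_branch = 0
    for k in range(morph.n_nodes):
        if morph.structure[k] != Structure.DENDRITE:
            continue
        same = sum(1 for c in kids[k]
                   if morph.structure[c] == Structure.DENDRITE)
        if same >= 2:
            n_branch += 1
    n_primary = sum(1 for c in kids[0]
                    if morph.structure[c] == Structure.DENDRITE)
    soma = morph.soma_position
    dist = np.linalg.norm(morph.xyz - soma, axis=1)
    dmask = morph.structure == Structure.DENDRITE
    amask = morph.structure == Structure.AXON
    max_d = float(dist[dmask].max()) if dmask.any() else 0.0
    max_a = float(dist[amask].max()) if amask.any() else 0.0
    max_all = float(dist.max())
    if max_d > 0:
        radii = np.arange(sholl_step, max_d + sholl_step, sholl_step)
        sholl = sholl_profile(morph, radii)
    else:
        sholl = {}
    return MorphometryReport(
        total_dendritic_length=dend_len,
        total_axonal_length=axon_len,
        n_branch_points=n_branch,
        n_primary_dendrites=n_primary,
        max_euclidean_distance_from_soma=max_all,
        max_euclidean_distance_dendrite=max_d,
        max_euclidean_distance_axon=max_a,
        sholl=sholl,
    )


# ---------------------------------------------------------------------------
# Dendritic degeneration
# ---------------------------------------------------------------------------

@dataclass
class DegenerationSchedule:
    """Truncation schedule: PD1 = 10 steps, PD2 = 20 steps, PD3 = 30 steps."""

    step_length: float = 3.0
    resample_resolution: float = 3.0
    stage_steps: Mapping[str, int] = field(default_factory=lambda: {
        "PD0": 0, "PD1": 10, "PD2": 20, "PD3": 30})

    def __post_init__(self):
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        vals = list(self.stage_steps.values())
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("stage_steps must be non-decreasing")


def degenerate_step(morph: Morphology, step_length: float = 3.0) -> Morphology:
    """One truncation step: every dendritic terminal loses `step_length` µm.

    The loss is taken within the terminal's own unbranched section; a
    terminal section shorter than the step is removed entirely without
    borrowing length past its branch point (the branch point then becomes a
    pass-through, or a fresh terminal once all its arms are gone, and is
    truncated from the next step onward). A primary dendrite fully consumed
    is deleted. Axon and soma are untouched. The morphology is expected to
    be resampled at a resolution ≤ step_length.
    """
    m = morph
    keep = np.ones(m.n_nodes, dtype=bool)
    xyz = m.xyz.copy()
    n_children0 = m.n_children.copy()
    struct = m.structure
    for t in m.terminals(Structure.DENDRITE):
        cur = int(t)
        rem = step_length
        while rem > _EPS:
            p = int(m.parent_index[cur])
            seg = float(np.linalg.norm(xyz[cur] - xyz[p]))
            boundary = (struct[p] != Structure.DENDRITE
                        or n_children0[p] >= 2)
            if seg > rem + _EPS:
                xyz[cur] = xyz[cur] + (xyz[p] - xyz[cur]) * (rem / seg)
                rem = 0.0
            else:
                keep[cur] = False
                rem -= seg
                if boundary:
                    break  # no borrowing past a branch point / the soma
                cur = p
    records = []
    for k in range(m.n_nodes):
        if not keep[k]:
            continue
        par = int(m.parent[k])
        records.append((int(m.ids[k]), int(struct[k]),
                        xyz[k, 0], xyz[k, 1], xyz[k, 2],
                        m.radius[k], par))
    return _from_records(records)


def degenerate(morph: Morphology, stage: str,
               schedule: DegenerationSchedule | None = None) -> Morphology:
    """Apply the truncation schedule for a named disease stage.

    PD0 is the identity (after no resampling); other stages resample the
    dendrites at the schedule resolution and apply the per-terminal
    truncation the scheduled number of times.
    """
    schedule = schedule or DegenerationSchedule()
    if stage not in schedule.stage_steps:
        raise ValueError(f"unknown stage {stage!r}")
    steps = schedule.stage_steps[stage]
    if steps == 0:
        return morph.copy()
    if np.all(morph.segment_lengths() <= schedule.resample_resolution + 1e-6):
        out = morph.copy()   # already sampled finely enough; keep node ids
    else:
        out = resample(morph, schedule.resample_resolution)
    for _ in range(steps):
        out = degenerate_step(out, schedule.step_length)
    return out


# ---------------------------------------------------------------------------
# Axonal growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthSpec:
    """Per-terminal axonal extension along a persistent random walk.

    tortuosity is the heading persistence in [0, 1]: 1 grows dead straight,
    0 is an isotropic random walk. radius_cap (µm, Euclidean from soma)
    reflects the walk inward, keeping the arbor radius bounded.
    """

    extension_per_terminal: float = 61.0
    tortuosity: float = 0.8
    radius_cap: float | None = None
    step_length: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.extension_per_terminal <= 0:
            raise ValueError("extension_per_terminal must be positive")
        if not 0.0 <= self.tortuosity <= 1.0:
            raise ValueError("tortuosity must be in [0, 1]")


def grow_axon_terminals(morph: Morphology,
                        spec: GrowthSpec | None = None) -> Morphology:
    """Extend every axonal terminal by exactly spec.extension_per_terminal µm.

    The new path is a persistent random walk launched along the terminal's
    last segment direction; with a radius_cap the walk reflects inward at
    the cap so the maximal arbor radius stays essentially unchanged while
    intermediate Sholl crossings increase. Dendrites and soma are untouched;
    total axonal length increases by extension × (number of terminals),
    exactly.
    """
    spec = spec or GrowthSpec()
    terms = morph.terminals(Structure.AXON)
    if len(terms) == 0:
        warnings.warn("no axonal terminals to extend; returning a copy")
        return morph.copy()
    rng = np.random.default_rng(spec.seed)
    records = [(int(morph.ids[k]), int(morph.structure[k]),
                morph.xyz[k, 0], morph.xyz[k, 1], morph.xyz[k, 2],
                morph.radius[k], int(morph.parent[k]))
               for k in range(morph.n_nodes)]
    next_id = int(morph.ids.max()) + 1
    soma = morph.soma_position
    n_full, last = divmod(spec.extension_per_terminal, spec.step_length)
    steps = [spec.step_length] * int(n_full)
    if last > _EPS:
        steps.append(last)
    sigma = math.sqrt(max(1e-12, 1.0 - spec.tortuosity ** 2))
    for t in terms:
        p = morph.parent_index[t]
        d = morph.xyz[t] - morph.xyz[p]
        norm = np.linalg.norm(d)
        if norm < _EPS:
            d = rng.standard_normal(3)
            norm = np.linalg.norm(d)
        d = d / norm
        pos = morph.xyz[t].copy()
        par = int(morph.ids[t])
        r = morph.radius[t]
        for h in steps:
            d = spec.tortuosity * d + sigma * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            if spec.radius_cap is not None:
                trial = pos + h * d
                if np.linalg.norm(trial - soma) > spec.radius_cap:
                    radial = pos - soma
                    rn = np.linalg.norm(radial)
                    if rn > _EPS:
                        rhat = radial / rn
                        d = d - 2.0 * np.dot(d, rhat) * rhat
            pos = pos + h * d
            records.append((next_id, int(Structure.AXON),
                            pos[0], pos[1], pos[2], r, par))
            par = next_id
            next_id += 1
    return _from_records(records)
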