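"""Seeded synthetic morphologies calibrated to printed morphometrics.

The reconstructions behind the striatal microcircuit are not deposited, so
this module generates stand-in arbors whose population morphometrics match
the printed healthy (PD0) values: total dendritic length 3,997.9 µm for
dSPNs (8 primary dendrites) and 3,116.7 µm for iSPNs (6 primaries), and a
25,572 µm FS axonal arbor. Terminal counts are calibrated from the printed
PD0→PD1 length loss under the 3 µm-per-terminal-per-step truncation rule
(:func:`calibrate_terminal_count`), so the first ten truncation steps
reproduce the printed loss by construction and later stages probe the
collapse dynamics of the tree.

Generator design: a random binary tree with an exact terminal count is
drawn first (uniform tip splitting), then section lengths — short internal
sections (gamma-distributed, mean 25 µm) and longer terminal sections that
share the remaining length budget — and finally a 3-D embedding by a
persistent outward random walk in 3 µm steps (resample-compatible with the
truncation schedule). Interneuron arbors other than the FS axon only play
connectivity roles downstream and use generic parameters.
"""

from __future__ import annotations

import csv
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .morphology import Morphology, Structure, _from_records, morphometry, write_swc

__all__ = [
    "MorphGenSpec",
    "default_spec",
    "generate_morphology",
    "generate_population",
    "write_population",
    "calibrate_terminal_count",
    "TABLE_STAGE_LENGTHS",
]

# printed mean total lengths per stage (µm); FS entries are axonal
TABLE_STAGE_LENGTHS = {
    "dSPN": {"PD0": 3997.9, "PD1": 2890.8, "PD2": 1984.6, "PD3": 1288.6},
    "iSPN": {"PD0": 3116.7, "PD1": 2362.5, "PD2": 1774.5, "PD3": 1302.0},
    "FS_axon": {"PD0": 25572.0, "PD1": 41249.0},
}


def calibrate_terminal_count(L0: float, L1: float, steps: int,
                             step_length: float) -> int:
    """Mean effective terminal count implied by a stage-to-stage length loss.

    Each truncation step removes step_length µm at every terminal, so a
    population losing L0−L1 over `steps` steps behaves as if it had
    (L0−L1)/(steps·step_length) terminals on average.
    """
    if steps <= 0 or step_length <= 0:
        raise ValueError("steps and step_length must be positive")
    if L1 >= L0:
        raise ValueError("loss must be positive (L0 > L1)")
    return int(round((L0 - L1) / (steps * step_length)))


@dataclass
class MorphGenSpec:
    """One arbor of a synthetic cell (plus an optional companion arbor).

    target_terminal_count fixes the tip count exactly; when None the tree
    is grown with a per-µm branching hazard instead
    (branch_probability_per_um = 0 gives a star of n_primary unbranched
    neurites). length_jitter is the coefficient of variation of a per-draw
    multiplier on target_total_length.
    """

    cell_type: str
    structure: Structure = Structure.DENDRITE
    n_primary: int = 8
    target_total_length: float = 3997.9
    target_terminal_count: int | None = None
    branch_probability_per_um: float = 0.0
    segment_step: float = 3.0
    spatial_extent: float = 250.0
    internal_section_mean: float = 25.0
    length_jitter: float = 0.0
    persistence: float = 0.9
    neurite_radius: float = 0.7
    soma_radius: float = 7.0
    seed: int = 0
    secondary: "MorphGenSpec | None" = None

    def __post_init__(self):
        if self.target_total_length <= 0:
            raise ValueError("target_total_length must be positive")
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if (self.target_terminal_count is not None
                and self.target_terminal_count < self.n_primary):
            raise ValueError(
                "target_terminal_count must be >= n_primary")


_DSPN_TERMINALS = calibrate_terminal_count(3997.9, 2890.8, 10, 3.0)   # 37
_ISPN_TERMINALS = calibrate_terminal_count(3116.7, 2362.5, 10, 3.0)   # 25
_FS_AXON_TERMINALS = int(round((41249.0 - 25572.0) / 61.0))           # 257


def default_spec(cell_type: str, seed: int = 0,
                 length_jitter: float = 0.1) -> MorphGenSpec:
    """Calibrated defaults per cell type (main arbor + companion arbor)."""
    if cell_type == "dSPN" or cell_type == "iSPN":
        dend = MorphGenSpec(
            cell_type=cell_type, structure=Structure.DENDRITE,
            n_primary=8 if cell_type == "dSPN" else 6,
            target_total_length=TABLE_STAGE_LENGTHS[cell_type]["PD0"],
            target_terminal_count=(_DSPN_TERMINALS if cell_type == "dSPN"
                                   else _ISPN_TERMINALS),
            spatial_extent=250.0, length_jitter=length_jitter, seed=seed,
            secondary=MorphGenSpec(
                cell_type=cell_type, structure=Structure.AXON,
                n_primary=1, target_total_length=6000.0,
                target_terminal_count=40, spatial_extent=300.0,
                internal_section_mean=40.0, neurite_radius=0.3,
                length_jitter=length_jitter, seed=seed + 1))
        return dend
    if cell_type == "FS":
        return MorphGenSpec(
            cell_type="FS", structure=Structure.AXON, n_primary=1,
            target_total_length=25572.0,
            target_terminal_count=_FS_AXON_TERMINALS,
            spatial_extent=350.0, internal_section_mean=30.0,
            neurite_radius=0.3, soma_radius=9.0,
            length_jitter=length_jitter, seed=seed,
            secondary=MorphGenSpec(
                cell_type="FS", structure=Structure.DENDRITE, n_primary=5,
                target_total_length=3000.0, target_terminal_count=20,
                spatial_extent=200.0, length_jitter=length_jitter,
                seed=seed + 1))
    if cell_type == "ChIN":
        return MorphGenSpec(
            cell_type="ChIN", structure=Structure.DENDRITE, n_primary=4,
            target_total_length=4000.0, target_terminal_count=20,
            spatial_extent=300.0, soma_radius=12.0,
            length_jitter=length_jitter, seed=seed,
            secondary=MorphGenSpec(
                cell_type="ChIN", structure=Structure.AXON, n_primary=1,
                target_total_length=10000.0, target_terminal_count=80,
                spatial_extent=350.0, internal_section_mean=35.0,
                neurite_radius=0.3, length_jitter=length_jitter,
                seed=seed + 1))
    if cell_type == "LTS":
        return MorphGenSpec(
            cell_type="LTS", structure=Structure.DENDRITE, n_primary=4,
            target_total_length=2500.0, target_terminal_count=14,
            spatial_extent=250.0, length_jitter=length_jitter, seed=seed,
            secondary=MorphGenSpec(
                cell_type="LTS", structure=Structure.AXON, n_primary=1,
                target_total_length=8000.0, target_terminal_count=60,
                spatial_extent=350.0, internal_section_mean=35.0,
                neurite_radius=0.3, length_jitter=length_jitter,
                seed=seed + 1))
    raise ValueError(f"unknown cell type {cell_type!r}")


def _partition(rng, total: float, n: int, shape: float,
               floor: float) -> np.ndarray:
    """n positive lengths with gamma-shaped spread summing exactly to total."""
    if total <= n * floor:
        return np.full(n, total / n)
    w = rng.gamma(shape, size=n)
    w = w / w.sum()
    return floor + w * (total - n * floor)


def _tree_topology(rng, n_primary: int, n_terminals: int):
    """Random binary section tree: uniform tip splitting until the target.

    Returns (parent_section, is_terminal) arrays; primaries have parent -1.
    """
    parents = [-1] * n_primary
    tips = list(range(n_primary))
    for _ in range(n_terminals - n_primary):
        j = tips.pop(rng.integers(len(tips)))
        for _ in range(2):
            parents.append(j)
            tips.append(len(parents) - 1)
    is_term = np.ones(len(parents), dtype=bool)
    for p in parents:
        if p >= 0:
            is_term[p] = False
    return np.asarray(parents), is_term


def _fibonacci_directions(n: int, rng) -> np.ndarray:
    """n roughly evenly spread unit vectors, randomly rotated."""
    from scipy.spatial.transform import Rotation

    i = np.arange(n) + 0.5
    phi = math.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.clip(1 - z * z, 0, 1))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    rot = Rotation.random(rng=rng).as_matrix()
    return dirs @ rot.T


def _walk_section(rng, start, direction, length, step, persistence,
                  extent, records, next_id, parent_id, structure, radius):
    """Grow one section as a persistent walk; returns (end pos, dir, id)."""
    n_seg = max(1, int(math.ceil(length / step - 1e-9)))
    h = length / n_seg
    sigma = math.sqrt(max(1e-12, 1.0 - persistence ** 2))
    pos = np.array(start, dtype=float)
    d = np.array(direction, dtype=float)
    for _ in range(n_seg):
        d = persistence * d + sigma * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        if np.linalg.norm(pos + h * d) > extent:
            rn = np.linalg.norm(pos)
            if rn > 1e-9:
                rhat = pos / rn
                d = d - 2.0 * np.dot(d, rhat) * rhat
        pos = pos + h * d
        records.append((next_id, int(structure),
                        pos[0], pos[1], pos[2], radius, parent_id))
        parent_id = next_id
        next_id += 1
    return pos, d, parent_id, next_id


def _perturb(rng, d, sigma):
    v = d + sigma * rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _grow_arbor(rng, spec: MorphGenSpec, records, next_id: int,
                soma_id: int) -> int:
    total = spec.target_total_length
    if spec.length_jitter > 0:
        total *= max(0.2, 1.0 + spec.length_jitter * rng.standard_normal())
    if spec.target_terminal_count is not None:
        parents, is_term = _tree_topology(rng, spec.n_primary,
                                          spec.target_terminal_count)
        n_sec = len(parents)
        lengths = np.empty(n_sec)
        internal = ~is_term
        n_int = int(internal.sum())
        if n_int:
            int_len = rng.gamma(3.0, spec.internal_section_mean / 3.0,
                                size=n_int)
            cap = 0.5 * total
            if int_len.sum() > cap:
                int_len *= cap / int_len.sum()
            lengths[internal] = int_len
        term_budget = total - (lengths[internal].sum() if n_int else 0.0)
        lengths[is_term] = _partition(rng, term_budget, int(is_term.sum()),
                                      3.0, spec.segment_step)
        # embed, sections in index order (parents precede children)
        prim_dirs = _fibonacci_directions(spec.n_primary, rng)
        end_pos: dict[int, np.ndarray] = {}
        end_dir: dict[int, np.ndarray] = {}
        end_id: dict[int, int] = {}
        child_rank: dict[int, int] = {}
        for s in range(n_sec):
            p = parents[s]
            if p < 0:
                start, d0, pid = np.zeros(3), prim_dirs[s], soma_id
            else:
                rank = child_rank.get(p, 0)
                child_rank[p] = rank + 1
                start, pid = end_pos[p], end_id[p]
                d0 = _perturb(rng, end_dir[p], 0.5)
            pos, d, last_id, next_id = _walk_section(
                rng, start, d0, lengths[s], spec.segment_step,
                spec.persistence, spec.spatial_extent, records, next_id,
                pid, spec.structure, spec.neurite_radius)
            end_pos[s], end_dir[s], end_id[s] = pos, d, last_id
        return next_id
    # hazard mode: round-robin growth with a per-µm branching hazard
    prim_dirs = _fibonacci_directions(spec.n_primary, rng)
    tips = [(np.zeros(3), prim_dirs[k], soma_id) for k in range(spec.n_primary)]
    budget = total
    step = spec.segment_step
    sigma = math.sqrt(max(1e-12, 1.0 - spec.persistence ** 2))
    while budget > 1e-9:
        new_tips = []
        for pos, d, pid in tips:
            if budget <= 1e-9:
                new_tips.append((pos, d, pid))
                continue
            h = min(step, budget)
            budget -= h
            d = spec.persistence * d + sigma * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            if np.linalg.norm(pos + h * d) > spec.spatial_extent:
                rn = np.linalg.norm(pos)
                if rn > 1e-9:
                    rhat = pos / rn
                    d = d - 2.0 * np.dot(d, rhat) * rhat
            pos = pos + h * d
            records.append((next_id, int(spec.structure),
                            pos[0], pos[1], pos[2], spec.neurite_radius,
                            pid))
            pid = next_id
            next_id += 1
            if rng.random() < spec.branch_probability_per_um * h:
                new_tips.append((pos, _perturb(rng, d, 0.5), pid))
                new_tips.append((pos, _perturb(rng, d, 0.5), pid))
            else:
                new_tips.append((pos, d, pid))
        tips = new_tips
    return next_id


def generate_morphology(spec: MorphGenSpec) -> Morphology:
    """Draw one synthetic cell: soma at the origin plus the specified arbors.

    Deterministic per spec.seed; the same seed yields identical node tables.
    """
    rng = np.random.default_rng(spec.seed)
    records = [(1, int(Structure.SOMA), 0.0, 0.0, 0.0, spec.soma_radius, -1)]
    next_id = _grow_arbor(rng, spec, records, 2, 1)
    if spec.secondary is not None:
        rng2 = np.random.default_rng(spec.secondary.seed)
        _grow_arbor(rng2, spec.secondary, records, next_id, 1)
    return _from_records(records)


def generate_population(cell_type: str, n: int, base_seed: int = 0,
                        length_jitter: float = 0.1) -> list[Morphology]:
    """n independent draws; draw k uses seed base_seed + 1000*k."""
    return [generate_morphology(
        default_spec(cell_type, seed=base_seed + 1000 * k,
                     length_jitter=length_jitter))
        for k in range(n)]


def write_population(outdir, cell_types: dict[str, int],
                     base_seed: int = 0) -> "Path":
    """Emit SWC files plus a manifest CSV (file, cell_type, seed, metrics)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "cell_type", "seed", "total_dendritic_length",
                    "total_axonal_length", "n_branch_points",
                    "n_primary_dendrites"])
        for ct, n in cell_types.items():
            for k in range(n):
                seed = base_seed + 1000 * k + zlib.crc32(ct.encode()) % 997
                m = generate_morphology(default_spec(ct, seed=seed))
                fname = f"{ct}_{k}.swc"
                write_swc(m, outdir / fname)
                rep = morphometry(m)
                w.writerow([fname, ct, seed,
                            f"{rep.total_dendritic_length:.1f}",
                            f"{rep.total_axonal_length:.1f}",
                            rep.n_branch_points, rep.n_primary_dendrites])
    return manifest
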