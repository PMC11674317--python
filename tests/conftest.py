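"""Shared fixtures: hand-built morphologies and a desk-scale network.

The desk-scale network places the full cell-type composition at striatal
density in a 120 µm cube with 0.25-scaled synthetic morphologies — small
enough to build in seconds, large enough to carry the connectivity
mechanisms (touch detection, pruning, stage transforms).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from striatopy import morphology as M
from striatopy import synthmorph as S
from striatopy import network as N
from striatopy.morphology import Structure, _from_records
from striatopy.pipeline import _scaled_spec

DESK_SCALE = 0.25
DESK_SEED = 7


def straight_dendrite(length: float = 30.0, step: float = 3.0) -> M.Morphology:
    """Soma at origin plus one straight dendrite along +x, sampled at step."""
    n = int(round(length / step))
    rec = [(1, int(Structure.SOMA), 0.0, 0.0, 0.0, 7.0, -1)]
    for i in range(n):
        rec.append((i + 2, int(Structure.DENDRITE), step * (i + 1), 0.0, 0.0,
                    0.7, i + 1))
    return _from_records(rec)


def y_tree(stem: float = 30.0, child: float = 15.0, step: float = 3.0,
           angle_deg: float = 30.0) -> M.Morphology:
    """Stem along +x with two symmetric children at ±angle in the xy plane."""
    rec = [(1, int(Structure.SOMA), 0.0, 0.0, 0.0, 7.0, -1)]
    nid = 2
    n_stem = int(round(stem / step))
    for i in range(n_stem):
        rec.append((nid, int(Structure.DENDRITE), step * (i + 1), 0.0, 0.0,
                    0.7, nid - 1))
        nid += 1
    branch_id = nid - 1
    base = np.array([stem, 0.0, 0.0])
    for sign in (+1, -1):
        a = np.deg2rad(angle_deg) * sign
        d = np.array([np.cos(a), np.sin(a), 0.0])
        parent = branch_id
        n_child = int(round(child / step))
        for i in range(n_child):
            p = base + step * (i + 1) * d
            rec.append((nid, int(Structure.DENDRITE), p[0], p[1], p[2],
                        0.7, parent))
            parent = nid
            nid += 1
    return _from_records(rec)


def star(n_arms: int = 8, length: float = 500.0,
         structure: Structure = Structure.DENDRITE) -> M.Morphology:
    """n straight arms radiating from the soma in the xy plane."""
    rec = [(1, int(Structure.SOMA), 0.0, 0.0, 0.0, 7.0, -1)]
    nid = 2
    for k in range(n_arms):
        a = 2 * np.pi * k / n_arms
        d = np.array([np.cos(a), np.sin(a), 0.0])
        parent = 1
        for i in range(int(round(length / 5.0))):
            p = 5.0 * (i + 1) * d
            rec.append((nid, int(structure), p[0], p[1], p[2], 0.7, parent))
            parent = nid
            nid += 1
    return _from_records(rec)


def desk_morphologies(seed: int = DESK_SEED):
    """Scaled PD0/PD2 morphology pairs for every modeled cell type."""
    m0, m2 = {}, {}
    for ct in ("dSPN", "iSPN", "FS", "ChIN", "LTS"):
        spec = _scaled_spec(S.default_spec(ct, seed=seed + 17), DESK_SCALE)
        m = S.generate_morphology(spec)
        m0[ct] = m
        mm = M.degenerate(m, "PD2") if ct in ("dSPN", "iSPN") else m
        if ct == "FS":
            cap = M.morphometry(m).max_euclidean_distance_axon
            mm = M.grow_axon_terminals(
                mm, M.GrowthSpec(seed=seed + 5, radius_cap=cap))
        m2[ct] = mm
    return m0, m2


def desk_rules() -> N.PruningRules:
    base = dict(f_keep_random=0.15, few_threshold=3, few_removal_max=0.9,
                pair_removal_probability=0.6)
    pairs = {}
    for t in ("dSPN", "iSPN"):
        pairs[("FS", t)] = N.PairRule(
            **base, dist_keep={"kind": "exp_decay", "scale": 15.0})
        pairs[("LTS", t)] = N.PairRule(
            **base, dist_keep={"kind": "exp_rise", "scale": 40.0})
    return N.PruningRules(pairs=pairs, default=N.PairRule(**base))


@dataclasses.dataclass
class DeskNetwork:
    instances: list
    morphs_pd0: dict
    morphs_pd2: dict
    rules: N.PruningRules
    putative_pd0: "object"
    pd0: N.SynapseTable
    pd2_hybrid: N.SynapseTable
    pd2_degeneration: N.SynapseTable
    hybrid_info: dict


@pytest.fixture(scope="session")
def desk_network() -> DeskNetwork:
    seed = DESK_SEED
    m0, m2 = desk_morphologies(seed)
    refs = {ct: [ct] for ct in m0}
    inst = N.place_neurons(
        N.PlacementConfig(cube_side=120.0, seed=seed), morphology_refs=refs)
    rules = desk_rules()
    putative = N.touch_detect(inst, m0)
    pd0 = N.prune(putative, rules, seed=seed + 1)
    stages = {"PD0": m0, "PD2": m2}
    pd2_h, info = N.build_pd_network(pd0, inst, stages, "PD2",
                                     N.PDBuildMethod("hybrid"), rules,
                                     seed=seed + 2)
    pd2_d, _ = N.build_pd_network(pd0, inst, stages, "PD2",
                                  N.PDBuildMethod("degeneration"), rules,
                                  seed=seed + 2)
    return DeskNetwork(inst, m0, m2, rules, putative, pd0, pd2_h, pd2_d,
                       info)
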