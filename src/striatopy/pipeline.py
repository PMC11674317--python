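"""Config-driven end-to-end runs with a reproducibility manifest.

A run executes the stages in order — synthetic morphologies → placement →
touch detection and pruning (PD0) → disease-stage transforms and network
builds → directed-clique topology → erosion → drive experiments — writing
every artifact under the output directory and recording file hashes, seeds
and the config hash in ``manifest.json``. The same config and seed
reproduce every artifact byte-for-byte (timestamps excepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphology as M
from . import synthmorph as S
from . import network as N
from . import topology as T
from . import drive as D

__all__ = ["RunConfig", "run_pipeline", "report"]

log = logging.getLogger("striatopy")


@dataclasses.dataclass
class RunConfig:
    """Desk-scale defaults: a small cube with reduced-scale morphologies.

    morphology_scale shrinks every arbor target length (and the spatial
    extent) so that networks of a few hundred neurons stay tractable while
    keeping the connectivity mechanisms intact; the disease-stage
    truncation/growth transforms always run at full per-step magnitudes.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    cube_side: float = 150.0
    density: float = 80500.0
    composition: dict = dataclasses.field(default_factory=lambda: {
        "dSPN": 0.475, "iSPN": 0.475, "FS": 0.013, "ChIN": 0.011,
        "LTS": 0.008})
    morphology_scale: float = 0.25
    n_morphs_per_type: int = 2
    stages: tuple = ("PD0", "PD2")
    pd_method: str = "hybrid"
    touch_max_distance: float = 3.0
    touch_voxel_size: float = 10.0
    # desk-scale pruning: everything sits within one dendritic field, so
    # pruning must be aggressive to reach realistic pairwise connectivity
    f_keep_random: float = 0.15
    few_threshold: int = 3
    few_removal_max: float = 0.9
    pair_removal_probability: float = 0.6
    # FS targets perisomatic sites, LTS distal ones; scales are in µm of
    # postsynaptic arc length on the (scaled) desk morphologies
    fs_proximal_scale: float = 15.0
    lts_distal_scale: float = 40.0
    max_dim: int = 13
    kernel_size: int = 8
    erosion_fractions: tuple = (0.0, 0.3, 0.6, 1.0)
    erosion_reps: int = 2
    run_drive: bool = False
    drive_duration: float = 3.0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def to_json(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        data["erosion_fractions"] = list(self.erosion_fractions)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _scaled_spec(spec: S.MorphGenSpec, scale: float) -> S.MorphGenSpec:
    sec = (_scaled_spec(spec.secondary, scale)
           if spec.secondary is not None else None)
    # keep at least a couple of branch points so distal-first truncation
    # spares proximal trunks, as it does on full-size arbors
    tgt = (None if spec.target_terminal_count is None else
           max(spec.n_primary + 2,
               int(round(spec.target_terminal_count * scale))))
    return dataclasses.replace(
        spec, target_total_length=spec.target_total_length * scale,
        target_terminal_count=tgt,
        spatial_extent=spec.spatial_extent * max(scale, 0.4) ** (1 / 3),
        secondary=sec)


def pd_connectivity_probe(pre_type: str, post_type: str, seed: int,
                          scale: float = 0.25, n_post: int = 40,
                          rmax: float = 100.0,
                          rules: "N.PruningRules | None" = None) -> dict:
    """Pairwise connectivity of one presynaptic cell against a shell of
    postsynaptic cells, healthy (PD0) versus stage PD2.

    One pre cell sits at the center with n_post target somata uniform in a
    ball of radius rmax (the paper's within-100 µm comparison); touch
    detection runs on the healthy and the transformed morphologies (SPN
    dendrites truncated 20 steps; FS axons extended 61 µm per terminal
    under the healthy radius cap). Returns the noise-free expected kept
    synapse and connected-pair counts under the pruning rules
    (:func:`striatopy.network.expected_connection_stats`) for both stages.
    """
    from scipy.spatial.transform import Rotation

    if rules is None:
        dist = ({"kind": "exp_decay", "scale": 15.0}
                if pre_type == "FS" else None)
        rules = N.PruningRules(default=N.PairRule(f_keep_random=0.3,
                                                  dist_keep=dist))
    rng = np.random.default_rng(seed)
    pre0 = S.generate_morphology(
        _scaled_spec(S.default_spec(pre_type, seed=seed + 17), scale))
    post0 = S.generate_morphology(
        _scaled_spec(S.default_spec(post_type, seed=seed + 31), scale))
    pre2 = (M.degenerate(pre0, "PD2") if pre_type in ("dSPN", "iSPN")
            else pre0)
    if pre_type == "FS":
        cap = M.morphometry(pre0).max_euclidean_distance_axon
        pre2 = M.grow_axon_terminals(
            pre2, M.GrowthSpec(seed=seed + 5, radius_cap=cap))
    post2 = (M.degenerate(post0, "PD2") if post_type in ("dSPN", "iSPN")
             else post0)
    center = np.full(3, 150.0)
    inst = [N.NeuronInstance(0, pre_type, "pre", center,
                             Rotation.random(rng=rng).as_matrix())]
    for k in range(n_post):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        r = rmax * rng.random() ** (1 / 3)
        inst.append(N.NeuronInstance(k + 1, post_type, "post",
                                     center + r * v,
                                     Rotation.random(rng=rng).as_matrix()))
    out = {}
    for stage, (mp, mq) in (("PD0", (pre0, post0)), ("PD2", (pre2, post2))):
        put = N.touch_detect(inst, {"pre": mp, "post": mq})
        put = put[put.pre_id == 0].reset_index(drop=True)
        syn, pairs = N.expected_connection_stats(put, rules)
        out[stage] = {"putative": len(put), "expected_synapses": syn,
                      "expected_connected_pairs": pairs}
    return out


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "seed": config.seed, "files": {}, "stages": []}
    t_start = time.time()

    def record(path: Path):
        manifest["files"][str(path.relative_to(out))] = _file_hash(path)

    def stage_done(name):
        log.info("stage=%s done t=%.1fs", name, time.time() - t_start)
        manifest["stages"].append(name)

    # 1 — morphology library, per stage
    refs: dict[str, list[str]] = {}
    morphs_by_stage: dict[str, dict[str, M.Morphology]] = {
        st: {} for st in config.stages}
    morph_dir = out / "morphologies"
    morph_dir.mkdir(exist_ok=True)
    growth_done: dict[str, M.Morphology] = {}
    for ct in config.composition:
        refs[ct] = []
        for k in range(config.n_morphs_per_type):
            ref = f"{ct}_{k}"
            refs[ct].append(ref)
            spec = _scaled_spec(
                S.default_spec(ct, seed=config.seed + 100 * k),
                config.morphology_scale)
            m0 = S.generate_morphology(spec)
            M.write_swc(m0, morph_dir / f"{ref}_PD0.swc")
            record(morph_dir / f"{ref}_PD0.swc")
            for st in config.stages:
                if st == "PD0":
                    morphs_by_stage[st][ref] = m0
                    continue
                mm = M.degenerate(m0, st) if ct in ("dSPN", "iSPN") else m0
                if ct == "FS":
                    cap = M.morphometry(m0).max_euclidean_distance_axon
                    mm = M.grow_axon_terminals(
                        mm, M.GrowthSpec(seed=config.seed + 13 * k,
                                         radius_cap=cap))
                morphs_by_stage[st][ref] = mm
                M.write_swc(mm, morph_dir / f"{ref}_{st}.swc")
                record(morph_dir / f"{ref}_{st}.swc")
    stage_done("morphologies")

    # 2 — placement
    placement = N.PlacementConfig(cube_side=config.cube_side,
                                  density=config.density,
                                  composition=config.composition,
                                  seed=config.seed)
    instances = N.place_neurons(placement, morphology_refs=refs)
    inst_df = pd.DataFrame(
        [(i.id, i.cell_type, i.morphology_ref, *i.position)
         for i in instances],
        columns=["id", "cell_type", "morphology_ref", "x", "y", "z"])
    inst_df.to_csv(out / "placement.csv", index=False)
    record(out / "placement.csv")
    stage_done("placement")

    # 3 — PD0 network
    base = dict(f_keep_random=config.f_keep_random,
                few_threshold=config.few_threshold,
                few_removal_max=config.few_removal_max,
                pair_removal_probability=config.pair_removal_probability)
    pair_rules = {}
    for t in ("dSPN", "iSPN"):
        pair_rules[("FS", t)] = N.PairRule(
            **base, dist_keep={"kind": "exp_decay",
                               "scale": config.fs_proximal_scale})
        pair_rules[("LTS", t)] = N.PairRule(
            **base, dist_keep={"kind": "exp_rise",
                               "scale": config.lts_distal_scale})
    rules = N.PruningRules(pairs=pair_rules, default=N.PairRule(**base))
    putative = N.touch_detect(instances, morphs_by_stage["PD0"],
                              max_distance=config.touch_max_distance,
                              voxel_size=config.touch_voxel_size)
    pd0 = N.prune(putative, rules, seed=config.seed + 1)
    tables: dict[str, N.SynapseTable] = {"PD0": pd0}
    stage_done("network_pd0")

    # 4 — PD transforms
    for st in config.stages:
        if st == "PD0":
            continue
        tbl, info = N.build_pd_network(
            pd0, instances, morphs_by_stage, st,
            N.PDBuildMethod(config.pd_method), rules,
            seed=config.seed + 2,
            max_distance=config.touch_max_distance,
            voxel_size=config.touch_voxel_size)
        tables[st] = tbl
        if "remapping_fraction" in info:
            log.info("stage=%s remapping=%s", st, {
                f"{a}->{b}": round(v, 3)
                for (a, b), v in info["remapping_fraction"].items()})
    for st, tbl in tables.items():
        tbl.to_tsv(out / f"synapses_{st}.tsv")
        record(out / f"synapses_{st}.tsv")
    stage_done("pd_networks")

    # 5 — topology
    clique_rows = []
    for st, tbl in tables.items():
        g = T.digraph_from_synapses(tbl, instances)
        try:
            sel = T.select_kernel_core(instances, g, k=config.kernel_size)
            sub = g.subgraph(sel.core)
            cc = T.count_directed_cliques(sub, kernel=sel.kernel,
                                          max_dim=config.max_dim)
            scope = "kernel_core"
        except ValueError:
            cc = T.count_directed_cliques(g, max_dim=config.max_dim)
            scope = "full"
        for d, c in enumerate(cc.counts):
            clique_rows.append((st, scope, d, int(c)))
    cliques_df = pd.DataFrame(clique_rows, columns=["stage", "scope",
                                                    "dimension", "count"])
    cliques_df.to_csv(out / "clique_counts.csv", index=False)
    record(out / "clique_counts.csv")
    stage_done("topology")

    # 6 — erosion
    ero = T.erosion_curves(tables[config.stages[-1]], instances,
                           config.erosion_fractions,
                           reps=config.erosion_reps,
                           seed=config.seed + 3, max_dim=config.max_dim)
    ero.to_csv(out / "erosion_curves.csv", index=False)
    record(out / "erosion_curves.csv")
    stage_done("erosion")

    # 7 — drive (optional; desk grid)
    if config.run_drive:
        ct = "dSPN"
        m0 = morphs_by_stage["PD0"][refs[ct][0]]
        m2 = morphs_by_stage[config.stages[-1]][refs[ct][0]]
        neuron = D.SurrogateNeuron.preset(f"{ct}_PD0")
        n_syn = D.calibrate_input_count(neuron, m0, seed=config.seed + 4,
                                        duration=2.0)
        res = D.run_protocol(D.ProtocolGrid.desk(), ct, m0, m2, n_syn,
                             seed=config.seed + 5,
                             duration=config.drive_duration)
        res.to_csv(out / "drive_rates.csv", index=False)
        record(out / "drive_rates.csv")
        stage_done("drive")

    config.to_json(out / "config.json")
    record(out / "config.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(run_dir) -> list[Path]:
    """Render figures (with CSV twins already on disk) from a finished run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}")
    made = []
    cl = run_dir / "clique_counts.csv"
    if cl.exists():
        df = pd.read_csv(cl)
        if len(df):
            fig, ax = plt.subplots(figsize=(5, 4))
            for st, sub in df.groupby("stage"):
                ax.semilogy(sub.dimension, sub["count"].clip(lower=0.5),
                            marker="o", label=st)
            ax.set_xlabel("clique dimension")
            ax.set_ylabel("count (log scale)")
            ax.legend()
            fig.tight_layout()
            fig.savefig(run_dir / "clique_counts.png", dpi=120)
            plt.close(fig)
            made.append(run_dir / "clique_counts.png")
        else:
            log.warning("clique_counts.csv is empty; skipping figure")
    ero = run_dir / "erosion_curves.csv"
    if ero.exists():
        df = pd.read_csv(ero)
        if len(df):
            tot = df.groupby("fraction").mean_count.sum().reset_index()
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.plot(tot.fraction, tot.mean_count, marker="s")
            ax.set_xlabel("eroded synapse fraction")
            ax.set_ylabel("total clique count")
            fig.tight_layout()
            fig.savefig(run_dir / "erosion_curves.png", dpi=120)
            plt.close(fig)
            made.append(run_dir / "erosion_curves.png")
    dr = run_dir / "drive_rates.csv"
    if dr.exists():
        df = pd.read_csv(dr)
        by_rate, _ = D.protocol_marginals(df)
        fig, ax = plt.subplots(figsize=(5, 4))
        for st, sub in by_rate.groupby("scenario"):
            ax.plot(sub.rate, sub.output_rate, marker="o", label=st)
        ax.set_xlabel("input rate (Hz)")
        ax.set_ylabel("output rate (Hz)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "drive_marginals.png", dpi=120)
        plt.close(fig)
        made.append(run_dir / "drive_marginals.png")
    return made
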