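"""Placement, touch detection, pruning and the PD network builds."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from striatopy import network as N
from striatopy.morphology import Structure, _from_records
from striatopy.synthmorph import MorphGenSpec, generate_morphology

from conftest import straight_dendrite


def _line_neuron(structure, start, direction, length=60.0, step=3.0):
    """Soma at start plus one straight neurite of the given structure."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    rec = [(1, int(Structure.SOMA), *np.asarray(start, float), 5.0, -1)]
    for i in range(int(length / step)):
        p = np.asarray(start) + step * (i + 1) * d
        rec.append((i + 2, int(structure), p[0], p[1], p[2], 0.5, i + 1))
    return _from_records(rec)


def _inst(i, ct, ref, pos):
    return N.NeuronInstance(i, ct, ref, np.asarray(pos, float), np.eye(3))


class TestPlacement:
    def test_count_matches_density_times_volume(self):
        cfg = N.PlacementConfig(cube_side=1000.0, density=80500.0, seed=0)
        inst = N.place_neurons(cfg)
        assert len(inst) == 80500

    def test_spn_fraction_about_95_percent(self):
        cfg = N.PlacementConfig(cube_side=500.0, seed=1)
        inst = N.place_neurons(cfg)
        spn = sum(1 for i in inst if i.cell_type in ("dSPN", "iSPN"))
        assert spn / len(inst) == pytest.approx(0.95, abs=0.005)
        others = sum(1 for i in inst if i.cell_type == "other")
        assert others / len(inst) == pytest.approx(0.018, abs=0.005)

    def test_same_seed_identical_placement(self):
        cfg = N.PlacementConfig(cube_side=200.0, seed=5)
        a = N.place_neurons(cfg)
        b = N.place_neurons(cfg)
        assert [i.cell_type for i in a] == [i.cell_type for i in b]
        np.testing.assert_allclose(
            np.array([i.position for i in a]),
            np.array([i.position for i in b]))

    def test_zero_volume_is_empty(self):
        assert N.place_neurons(N.PlacementConfig(cube_side=0.0)) == []


class TestTouchDetection:
    def test_orthogonal_crossing_yields_one_touch(self):
        # crossing above both segment midpoints at 2.9 µm: only the
        # crossing segment pair is within the 3 µm reach (neighboring
        # segments sit at sqrt(1.5² + 2.9²) = 3.26 µm)
        pre = _line_neuron(Structure.AXON, (0, 0, 0), (1, 0, 0))
        post = _line_neuron(Structure.DENDRITE, (31.5, -31.5, 2.9), (0, 1, 0))
        inst = [_inst(0, "dSPN", "pre", (0, 0, 0)),
                _inst(1, "iSPN", "post", (0, 0, 0))]
        # morphologies are expressed in world coordinates already
        morphs = {"pre": pre, "post": post}
        put = N.touch_detect(inst, morphs, max_distance=3.0)
        out = put[(put.pre_id == 0) & (put.post_id == 1)]
        assert len(out) == 1

    def test_parallel_neurites_beyond_reach_yield_none(self):
        pre = _line_neuron(Structure.AXON, (0, 0, 0), (1, 0, 0))
        post = _line_neuron(Structure.DENDRITE, (0, 6.5, 0), (1, 0, 0))
        inst = [_inst(0, "dSPN", "pre", (0, 0, 0)),
                _inst(1, "iSPN", "post", (0, 0, 0))]
        put = N.touch_detect(inst, {"pre": pre, "post": post},
                             max_distance=3.0)
        assert len(put[(put.pre_id == 0) & (put.post_id == 1)]) == 0

    def test_touch_is_directional_axon_onto_dendrite(self):
        pre = _line_neuron(Structure.AXON, (0, 0, 0), (1, 0, 0))
        post = _line_neuron(Structure.DENDRITE, (30, -30, 1), (0, 1, 0))
        inst = [_inst(0, "dSPN", "a", (0, 0, 0)),
                _inst(1, "iSPN", "b", (0, 0, 0))]
        put = N.touch_detect(inst, {"a": pre, "b": post})
        assert set(zip(put.pre_id, put.post_id)) == {(0, 1)}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_voxel_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        morphs, inst = {}, []
        for i in range(10):
            spec = MorphGenSpec(
                cell_type="dSPN", structure=Structure.DENDRITE, n_primary=3,
                target_total_length=300.0, target_terminal_count=5,
                spatial_extent=80.0, seed=seed * 100 + i,
                secondary=MorphGenSpec(
                    cell_type="dSPN", structure=Structure.AXON, n_primary=1,
                    target_total_length=500.0, target_terminal_count=6,
                    spatial_extent=120.0, neurite_radius=0.3,
                    seed=seed * 100 + i + 50))
            morphs[f"m{i}"] = generate_morphology(spec)
            inst.append(N.NeuronInstance(
                i, "dSPN", f"m{i}", rng.uniform(0, 80, 3),
                Rotation.random(rng=rng).as_matrix()))
        kw = dict(max_distance=3.0)
        a = N.touch_detect(inst, morphs, voxel_size=10.0, **kw)
        b = N.touch_detect(inst, morphs, method="brute", **kw)
        cols = ["pre_id", "post_id", "post_node"]
        pd.testing.assert_frame_equal(
            a[cols].sort_values(cols).reset_index(drop=True),
            b[cols].sort_values(cols).reset_index(drop=True))
        assert len(a) > 0


class TestPruning:
    def _putative(self, n, seed=0, pre_t="dSPN", post_t="iSPN",
                  n_pre=100, n_post=100):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "pre_id": rng.integers(0, n_pre, n),
            "post_id": rng.integers(n_pre, n_pre + n_post, n),
            "pre_type": pre_t, "post_type": post_t,
            "x": 0.0, "y": 0.0, "z": 0.0,
            "post_dist": rng.uniform(0, 200, n),
            "post_node": rng.integers(2, 400, n)})

    def test_all_permissive_rules_are_identity(self):
        put = self._putative(500)
        out = N.prune(put, N.PruningRules.permissive(), seed=0)
        assert len(out) == 500

    def test_random_fraction_within_binomial_bounds(self):
        put = self._putative(10_000)
        rules = N.PruningRules(default=N.PairRule(f_keep_random=0.5))
        kept = len(N.prune(put, rules, seed=1))
        sd = np.sqrt(10_000 * 0.25)
        assert abs(kept - 5000) < 2.58 * sd    # 99% bound

    def test_soft_max_caps_each_pair(self):
        put = self._putative(400, n_pre=3, n_post=3)
        rules = N.PruningRules(default=N.PairRule(soft_max=3))
        out = N.prune(put, rules, seed=2)
        assert out.df.groupby(["pre_id", "post_id"]).size().max() <= 3

    def test_missing_pair_rule_is_configuration_error(self):
        put = self._putative(10)
        rules = N.PruningRules(pairs={("FS", "iSPN"): N.PairRule()})
        with pytest.raises(N.ConfigurationError, match="dSPN"):
            N.prune(put, rules, seed=0)

    def test_prune_is_deterministic_per_seed(self):
        put = self._putative(2000)
        rules = N.PruningRules(default=N.PairRule(
            f_keep_random=0.4, few_threshold=3, few_removal_max=0.8,
            pair_removal_probability=0.2))
        a = N.prune(put, rules, seed=9).df
        b = N.prune(put, rules, seed=9).df
        pd.testing.assert_frame_equal(a, b)

    def test_distance_rule_prefers_proximal(self):
        put = self._putative(4000, seed=3)
        rules = N.PruningRules(default=N.PairRule(
            dist_keep={"kind": "exp_decay", "scale": 30.0}))
        out = N.prune(put, rules, seed=4).df
        assert out.post_dist.mean() < put.post_dist.mean() * 0.6

    def test_expected_stats_match_rule_arithmetic(self):
        put = pd.DataFrame({
            "pre_id": [0, 0, 1], "post_id": [2, 2, 3],
            "pre_type": "dSPN", "post_type": "dSPN",
            "x": 0.0, "y": 0.0, "z": 0.0,
            "post_dist": [0.0, 0.0, 0.0], "post_node": [5, 6, 7]})
        rules = N.PruningRules(default=N.PairRule(f_keep_random=0.5))
        syn, pairs = N.expected_connection_stats(put, rules)
        assert syn == pytest.approx(1.5)
        assert pairs == pytest.approx(0.75 + 0.5)


class TestConnectionProbability:
    def test_wilson_interval_closed_form(self):
        inst = ([_inst(i, "dSPN", None, (0, 0, 0)) for i in range(1)]
                + [_inst(10 + j, "iSPN", None, (10, 0, 0))
                   for j in range(10)])
        rows = pd.DataFrame({
            "pre_id": [0, 0, 0], "post_id": [10, 11, 12],
            "pre_type": "dSPN", "post_type": "iSPN",
            "x": 0.0, "y": 0.0, "z": 0.0, "post_dist": 10.0,
            "post_node": 2, "cond": 0.5})
        table = N.SynapseTable(rows)
        res = N.connection_probability(table, inst, "dSPN", "iSPN",
                                       [0.0, 50.0])
        assert res.p_hat.iloc[0] == pytest.approx(0.3)
        assert res.wilson_low.iloc[0] == pytest.approx(0.1078, abs=2e-3)
        assert res.wilson_high.iloc[0] == pytest.approx(0.6032, abs=2e-3)

    def test_zero_successes_lower_bound_zero(self):
        inst = [_inst(0, "dSPN", None, (0, 0, 0)),
                _inst(1, "iSPN", None, (10, 0, 0))]
        table = N.SynapseTable(pd.DataFrame(columns=[
            "pre_id", "post_id", "pre_type", "post_type", "x", "y", "z",
            "post_dist", "post_node", "cond"]))
        res = N.connection_probability(table, inst, "dSPN", "iSPN",
                                       [0.0, 50.0])
        assert res.p_hat.iloc[0] == 0.0
        assert res.wilson_low.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_bin_flagged_nan(self):
        inst = [_inst(0, "dSPN", None, (0, 0, 0)),
                _inst(1, "iSPN", None, (10, 0, 0))]
        table = N.SynapseTable(pd.DataFrame(columns=[
            "pre_id", "post_id", "pre_type", "post_type", "x", "y", "z",
            "post_dist", "post_node", "cond"]))
        res = N.connection_probability(table, inst, "dSPN", "iSPN",
                                       [100.0, 200.0])
        assert np.isnan(res.p_hat.iloc[0])


class TestAblationErosion:
    def _table(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        types = np.array(["dSPN", "iSPN", "FS", "ChIN", "LTS"])
        pre_t = types[rng.integers(0, 5, n)]
        post_t = types[rng.integers(0, 2, n)]
        return N.SynapseTable(pd.DataFrame({
            "pre_id": rng.integers(0, 50, n),
            "post_id": rng.integers(50, 100, n),
            "pre_type": pre_t, "post_type": post_t,
            "x": 0.0, "y": 0.0, "z": 0.0, "post_dist": 0.0,
            "post_node": 2, "cond": 0.5}))

    def test_ablating_interneurons_leaves_only_spn_rows(self):
        out = N.ablate_types(self._table(), {"FS", "ChIN", "LTS"})
        assert set(out.df.pre_type) <= {"dSPN", "iSPN"}
        assert set(out.df.post_type) <= {"dSPN", "iSPN"}

    def test_erosion_endpoints(self):
        t = self._table()
        assert len(N.erode_synapses(t, 0.0)) == len(t)
        assert len(N.erode_synapses(t, 1.0)) == 0
        spn_only = N.erode_synapses(t, 1.0, scope="SPN_only")
        spn = {"dSPN", "iSPN"}
        left = spn_only.df
        assert not ((left.pre_type.isin(spn))
                    & (left.post_type.isin(spn))).any()

    def test_erosion_fraction_within_binomial_bounds(self):
        t = self._table(10_000)
        out = N.erode_synapses(t, 0.3, seed=1)
        removed = 10_000 - len(out)
        sd = np.sqrt(10_000 * 0.3 * 0.7)
        assert abs(removed - 3000) < 2.58 * sd


class TestPDBuilds:
    def test_pd0_any_method_is_identity(self, desk_network):
        d = desk_network
        out, _ = N.build_pd_network(
            d.pd0, d.instances, {"PD0": d.morphs_pd0}, "PD0",
            N.PDBuildMethod("hybrid"), d.rules, seed=0)
        pd.testing.assert_frame_equal(out.df, d.pd0.df)

    def test_degeneration_table_is_subset_of_pd0(self, desk_network):
        d = desk_network
        key = ["pre_id", "post_id", "post_node", "x"]
        pd0_keys = set(map(tuple, d.pd0.df[key].itertuples(index=False)))
        deg_keys = set(map(tuple,
                           d.pd2_degeneration.df[key].itertuples(index=False)))
        assert deg_keys <= pd0_keys
        assert len(deg_keys) < len(pd0_keys)

    def test_degeneration_adds_no_fs_synapses(self, desk_network):
        d = desk_network
        fs0 = (d.pd0.df.pre_type == "FS").sum()
        fs_deg = (d.pd2_degeneration.df.pre_type == "FS").sum()
        assert fs_deg <= fs0

    def test_hybrid_matches_de_novo_pair_counts_exactly(self, desk_network):
        d = desk_network
        putative2 = N.touch_detect(d.instances, d.morphs_pd2)
        de_novo = N.prune(putative2, d.rules, seed=7 + 2)
        a = d.pd2_hybrid.pair_counts().sort_index()
        b = de_novo.pair_counts().sort_index()
        pd.testing.assert_series_equal(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            N.PDBuildMethod("mystery")

    def test_no_invented_synapses(self, desk_network):
        # hybrid rows all come from PD0 ∪ de-novo locations
        d = desk_network
        putative2 = N.touch_detect(d.instances, d.morphs_pd2)
        allowed = set(map(tuple, pd.concat([
            d.pd0.df[["pre_id", "post_id", "post_node"]],
            putative2[["pre_id", "post_id", "post_node"]],
        ]).itertuples(index=False)))
        got = set(map(tuple, d.pd2_hybrid.df[
            ["pre_id", "post_id", "post_node"]].itertuples(index=False)))
        assert got <= allowed


class TestSynapseTableIO:
    def test_hdf5_and_tsv_round_trip(self, desk_network, tmp_path):
        t = desk_network.pd0
        t.to_hdf5(tmp_path / "syn.h5")
        back = N.SynapseTable.from_hdf5(tmp_path / "syn.h5")
        assert len(back) == len(t)
        np.testing.assert_allclose(back.df.post_dist, t.df.post_dist)
        t.to_tsv(tmp_path / "syn.tsv")
        back2 = N.SynapseTable.from_tsv(tmp_path / "syn.tsv")
        assert len(back2) == len(t)

    def test_self_synapses_rejected(self):
        with pytest.raises(ValueError, match="self-synapses"):
            N.SynapseTable(pd.DataFrame({
                "pre_id": [1], "post_id": [1], "pre_type": "dSPN",
                "post_type": "dSPN", "x": 0.0, "y": 0.0, "z": 0.0,
                "post_dist": 0.0, "post_node": 2, "cond": 0.5}))
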