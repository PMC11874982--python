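"""Generator contracts: determinism, replay fidelity, stationarity,
linkage dial and the defense-effect modulation."""

import numpy as np
import pandas as pd
import pytest

from defenseflux.io import read_annotation, read_presence_matrix, read_trait_table
from defenseflux.simulate import (
    SimulationConfig,
    defense_segments,
    event_count_table,
    generate_dataset,
    read_event_history,
    simulate_defense_history,
    simulate_gene_families,
    simulate_mge_history,
    simulate_tree,
)
from defenseflux.tree import read_newick


def _cfg(**kw):
    base = dict(
        n_genomes=40, n_mge_families=10,
        n_families={"prophage": 5, "plasmid": 5, "transposon": 5, "neutral": 15},
        seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateTree:
    def test_exact_leaf_count_and_positive_paths(self):
        tree = simulate_tree(_cfg(n_genomes=5), seed=3)
        assert tree.n_leaves == 5
        depths = tree.node_depths()
        assert (depths[tree.leaf_indices] > 0).all()

    def test_pure_birth_binary_internal_count(self):
        cfg = _cfg(n_genomes=4, death_rate=0.0, clonal_fraction=0.0)
        tree = simulate_tree(cfg, seed=1)
        internal = [v for v in range(tree.n_nodes) if tree.children[v]]
        assert tree.n_leaves == 4 and len(internal) == 3

    def test_mean_tip_depth_matches_height_target(self):
        # the rescaling contract: exact per tree by construction
        for seed in range(5):
            cfg = _cfg(tree_height_target=0.02)
            tree = simulate_tree(cfg, seed=seed)
            mean_depth = tree.node_depths()[tree.leaf_indices].mean()
            assert mean_depth == pytest.approx(0.02, rel=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genomes=2)
        with pytest.raises(ValueError):
            SimulationConfig(birth_rate=0.5, death_rate=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(defense_effect=0.0)


class TestMgeHistory:
    def test_no_loss_mechanism_means_no_loss_events(self):
        cfg = _cfg(mge_loss_rate=0.0, mge_gain_rate=50.0)
        tree = simulate_tree(cfg)
        history, _ = simulate_mge_history(tree, cfg, seed=1)
        assert (history.events["event"] == "loss").sum() == 0
        # stationary root with l=0 puts every family at state 1: no gains either
        assert all(v == 1 for v in history.root_states.values())

    def test_stationary_occupancy(self):
        # long branches relative to 1/(g+l): leaf occupancy ~ g/(g+l)
        cfg = _cfg(mge_gain_rate=300.0, mge_loss_rate=300.0, n_mge_families=120,
                   tree_height_target=0.1)
        tree = simulate_tree(cfg, seed=5)
        _, states = simulate_mge_history(tree, cfg, seed=9)
        assert states.to_numpy().mean() == pytest.approx(0.5, abs=0.05)

    def test_per_branch_gain_flux_matches_stationary_expectation(self):
        # aggregate gains over the tree ~ n_fam * pi0 * g * total_length
        cfg = _cfg(mge_gain_rate=100.0, mge_loss_rate=200.0, n_mge_families=200,
                   n_genomes=80)
        tree = simulate_tree(cfg, seed=2)
        history, _ = simulate_mge_history(tree, cfg, seed=3)
        total_len = tree.lengths[1:].sum()
        expected = 200 * (200 / 300) * 100 * total_len
        observed = (history.events["event"] == "gain").sum()
        assert observed == pytest.approx(expected, rel=0.15)


class TestDefenseHistory:
    def test_full_linkage_forces_cogain(self):
        cfg = _cfg(defense_linkage=1.0, defense_independent_gain_rate=0.0,
                   defense_loss_linkage=1.0)
        tree = simulate_tree(cfg)
        mge, _ = simulate_mge_history(tree, cfg, seed=1)
        dh, _ = simulate_defense_history(tree, mge, cfg, seed=2)
        mge_gain_branches = set(
            mge.events.loc[mge.events["event"] == "gain", "branch"])
        def_gain_branches = set(
            dh.events.loc[dh.events["event"] == "gain", "branch"])
        assert def_gain_branches <= mge_gain_branches

    def test_no_gain_mechanism_gives_all_zero_traits(self):
        cfg = _cfg(defense_linkage=0.0, defense_independent_gain_rate=0.0)
        tree = simulate_tree(cfg)
        mge, _ = simulate_mge_history(tree, cfg, seed=1)
        dh, traits = simulate_defense_history(tree, mge, cfg, seed=2)
        assert len(dh.events) == 0
        assert traits.df.to_numpy().sum() == 0

    def test_cogain_fraction_monotone_in_linkage(self):
        # the linkage dial: co-gain fraction non-decreasing in p_link
        fracs = []
        for p_link in (0.0, 0.3, 0.6, 0.9, 1.0):
            co = tot = 0
            for seed in range(4):
                cfg = _cfg(defense_linkage=p_link,
                           defense_independent_gain_rate=30.0,
                           mge_gain_rate=60.0, seed=seed)
                tree = simulate_tree(cfg, seed=seed)
                mge, _ = simulate_mge_history(tree, cfg, seed=50 + seed)
                dh, _ = simulate_defense_history(tree, mge, cfg, seed=80 + seed)
                gains = dh.events[dh.events["event"] == "gain"]
                mge_gain_branches = set(
                    mge.events.loc[mge.events["event"] == "gain", "branch"])
                tot += len(gains)
                co += gains["branch"].isin(mge_gain_branches).sum()
            fracs.append(co / max(tot, 1))
        assert all(b >= a - 0.05 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]


class TestGeneFamilies:
    @staticmethod
    def _defense_residence(tree, dh):
        segments = defense_segments(tree, dh)
        on = sum((b - a) * tree.lengths[v]
                 for v, segs in segments.items() for a, b, s in segs if s)
        total = tree.lengths[1:].sum()
        return on, total - on

    def test_zero_effect_blocks_gains_under_defense(self):
        # phi -> 0 is an absorbing filter on defense-present segments
        cfg = _cfg(defense_effect=1e-12, defense_linkage=0.9,
                   mge_gain_rate=100.0)
        tree = simulate_tree(cfg)
        mge, _ = simulate_mge_history(tree, cfg, seed=1)
        dh, _ = simulate_defense_history(tree, mge, cfg, seed=2)
        matrix, annot, fh = simulate_gene_families(tree, dh, cfg, seed=3)
        segments = defense_segments(tree, dh)
        label_to_node = {tree.labels[v]: v for v in range(tree.n_nodes)}
        gains = fh.events[(fh.events["event"] == "gain")
                          & ~fh.events["family"].str.startswith(("SING", "DEF"))]
        for row in gains.itertuples(index=False):
            v = label_to_node[row.branch]
            state = [s for a, b, s in segments[v] if a <= row.position < b]
            assert state and not state[0]

    def test_gain_rate_modulation_recovered_from_history(self):
        # phi=0.5: realized gain rate per unit length on DEF+ segments is
        # about half the DEF- rate (ground-truth event counting)
        cfg = _cfg(defense_effect=0.5, n_genomes=120, mge_gain_rate=150.0,
                   defense_linkage=0.9, defense_loss_linkage=0.3,
                   n_families={"prophage": 0, "plasmid": 0, "transposon": 0,
                               "neutral": 400},
                   family_rate_gamma_shape=0.0,
                   tree_height_target=0.03)
        tree = simulate_tree(cfg, seed=11)
        mge, _ = simulate_mge_history(tree, cfg, seed=12)
        dh, _ = simulate_defense_history(tree, mge, cfg, seed=13)
        matrix, annot, fh = simulate_gene_families(tree, dh, cfg, seed=14)
        on_len, off_len = self._defense_residence(tree, dh)
        assert on_len > 0.05 * off_len
        segments = defense_segments(tree, dh)
        label_to_node = {tree.labels[v]: v for v in range(tree.n_nodes)}
        gains = fh.events[(fh.events["event"] == "gain")
                          & fh.events["family"].str.startswith("FAMNE")]
        n_on = 0
        for row in gains.itertuples(index=False):
            v = label_to_node[row.branch]
            if any(s for a, b, s in segments[v] if a <= row.position < b):
                n_on += 1
        rate_on = n_on / on_len
        rate_off = (len(gains) - n_on) / off_len
        assert rate_on / rate_off == pytest.approx(0.5, rel=0.25)

    def test_neutral_effect_is_null(self):
        cfg = _cfg(defense_effect=1.0)
        tree = simulate_tree(cfg)
        mge, _ = simulate_mge_history(tree, cfg, seed=1)
        dh, _ = simulate_defense_history(tree, mge, cfg, seed=2)
        matrix, annot, _ = simulate_gene_families(tree, dh, cfg, seed=3)
        assert (annot.df["mge_class"] != "none").sum() >= 15


class TestGenerateDataset:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = _cfg()
        generate_dataset(cfg, out_dir=tmp_path / "a")
        generate_dataset(cfg, out_dir=tmp_path / "b")
        for name in ("tree.nwk", "presence.Rtab", "traits.tsv",
                     "annotation.tsv", "events.tsv", "root_states.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_written_files_round_trip_to_memory_objects(self, tmp_path):
        cfg = _cfg()
        ds = generate_dataset(cfg, out_dir=tmp_path)
        tree = read_newick(tmp_path / "tree.nwk")
        assert tree.leaf_labels == ds.tree.leaf_labels
        matrix, _ = read_presence_matrix(tmp_path / "presence.Rtab")
        assert matrix == ds.matrix
        assert read_trait_table(tmp_path / "traits.tsv") == ds.traits
        assert read_annotation(tmp_path / "annotation.tsv") == ds.annotation
        history = read_event_history(tmp_path / "events.tsv",
                                     tmp_path / "root_states.tsv")
        assert len(history.events) == len(ds.full_history.events)

    def test_replaying_history_reproduces_leaf_states(self, small_dataset):
        ds = small_dataset
        replayed = ds.full_history.replay(ds.tree)
        mat = ds.matrix.df
        assert (replayed[mat.columns].loc[mat.index] == mat).all().all()

    def test_empty_class_absent_from_annotation(self):
        cfg = _cfg(n_families={"prophage": 0, "plasmid": 5, "transposon": 5,
                               "neutral": 10},
                   n_mge_families=0)
        ds = generate_dataset(cfg)
        assert not (ds.annotation.df["mge_class"] == "prophage").any()

    def test_event_count_table_additive(self, small_dataset):
        ds = small_dataset
        fams = ds.matrix.family_ids
        half1, half2 = fams[: len(fams) // 2], fams[len(fams) // 2:]
        t_all = event_count_table(ds.tree, ds.full_history, fams)
        t1 = event_count_table(ds.tree, ds.full_history, half1)
        t2 = event_count_table(ds.tree, ds.full_history, half2)
        assert np.allclose(t_all["expected_gains"],
                           t1["expected_gains"] + t2["expected_gains"])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = _cfg(defense_effect=0.5)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
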