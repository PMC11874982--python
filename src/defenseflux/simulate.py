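"""Synthetic species datasets with known gain/loss ground truth.

The generator emulates the statistical structure of a within-species strain
data set: a birth--death strain tree with heterogeneous branch lengths, a set
of MGE "driver" families gained and lost under a two-state Markov process,
a defense system whose gains and losses are linked to same-branch MGE events
with tunable strength, and accessory gene families whose gain rate is
multiplicatively modulated (factor ``defense_effect``) while the defense
system is present in the lineage.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy.random.SeedSequence``, so a config determines its dataset exactly.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .io import (
    MGE_CLASSES,
    FamilyAnnotation,
    PresenceMatrix,
    TraitTable,
    write_annotation,
    write_table,
    write_trait_table,
)
from .tree import StrainTree

log = logging.getLogger("defenseflux")

__all__ = [
    "SimulationConfig",
    "EventHistory",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_mge_history",
    "simulate_defense_history",
    "simulate_linked_histories",
    "simulate_gene_families",
    "generate_dataset",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic species.

    Rates are events per substitution/site of core-gene divergence, so a
    tree of height ~0.01 with MGE gain rate ~100 sees roughly one MGE
    turnover per family per root-to-tip path -- fast element turnover
    relative to core divergence, as in real strain data.
    """

    n_genomes: int = 200
    birth_rate: float = 1.0
    death_rate: float = 0.5
    tree_height_target: float = 0.01
    #: spread (sigma of a mean-1 lognormal) of per-branch rate multipliers;
    #: emulates the mix of near-clonal and diverged strains in species trees
    rate_lognormal_sigma: float = 1.0
    #: fraction of base tips expanded into near-clonal clusters (small
    #: coalescent subtrees), emulating densely sampled clonal lineages
    clonal_fraction: float = 0.25
    #: mean number of genomes per clonal cluster (>= 2)
    clonal_mean_size: float = 4.0
    #: height (substitutions/site) of the clonal clusters
    clonal_height: float = 5e-6

    n_mge_families: int = 30
    mge_gain_rate: float = 100.0
    mge_loss_rate: float = 200.0
    #: per-split standard deviation of a log-scale random walk on the MGE
    #: gain intensity (heritable lineage "mobility"); 0 = homogeneous rates
    mobility_sigma: float = 0.75

    defense_system: str = "CRISPR"
    defense_linkage: float = 0.9          # p_link
    defense_loss_linkage: float = 0.5     # q_link
    defense_independent_gain_rate: float = 5.0
    defense_root_present: bool = False
    #: feed the defense effect back onto MGE driver gains (defense blocks
    #: element acquisition); uses the defense state at the branch start
    defense_blocks_mge: bool = True

    n_families: dict = field(
        default_factory=lambda: {
            "prophage": 30, "plasmid": 30, "transposon": 30, "neutral": 150}
    )
    base_gain_rate: dict = field(
        default_factory=lambda: {
            "prophage": 30.0, "plasmid": 30.0, "transposon": 30.0, "neutral": 20.0}
    )
    base_loss_rate: dict = field(
        default_factory=lambda: {
            "prophage": 60.0, "plasmid": 60.0, "transposon": 60.0, "neutral": 40.0}
    )
    defense_effect: float = 1.0           # phi: gain-rate multiplier under defense
    #: mean number of same-class cargo families co-gained (co-lost) with
    #: each MGE driver gain (loss) on a branch -- elements carry gene cargo
    cargo_gain_burst: float = 5.0
    cargo_loss_burst: float = 5.0
    #: shape of the mean-1 gamma distribution of per-family rate multipliers
    #: applied jointly to gain and loss rates of accessory families
    #: (0 = homogeneous rates)
    family_rate_gamma_shape: float = 0.7
    singleton_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 3:
            raise ValueError("n_genomes must be >= 3")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        for p in (self.defense_linkage, self.defense_loss_linkage,
                  self.singleton_fraction, self.clonal_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not self.defense_effect > 0:
            raise ValueError("defense_effect must be > 0")
        for d in (self.n_families, self.base_gain_rate, self.base_loss_rate):
            if set(d) != {"prophage", "plasmid", "transposon", "neutral"}:
                raise ValueError("per-class dicts need the four family classes")
        rates = [self.mge_gain_rate, self.mge_loss_rate,
                 self.defense_independent_gain_rate,
                 *self.base_gain_rate.values(), *self.base_loss_rate.values()]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class EventHistory:
    """Ground-truth gain/loss events: one row per event, plus root states.

    ``events`` columns: branch (child-node label), family, event
    ('gain'/'loss'), position (fraction along the branch in [0, 1]).
    """

    events: pd.DataFrame
    root_states: dict  # family -> 0/1

    def branch_events(self, branch_label: str, family: str) -> list:
        sub = self.events[
            (self.events["branch"] == branch_label)
            & (self.events["family"] == family)
        ]
        return list(sub.sort_values("position")[["event", "position"]].itertuples(
            index=False, name=None))

    def replay(self, tree: StrainTree) -> pd.DataFrame:
        """Leaf states implied by applying every event from the root states."""
        families = sorted(self.root_states)
        fam_idx = {f: j for j, f in enumerate(families)}
        states = np.zeros((tree.n_nodes, len(families)), dtype=np.int8)
        states[0] = [self.root_states[f] for f in families]
        by_branch: dict = {}
        for row in self.events.sort_values("position").itertuples(index=False):
            by_branch.setdefault(row.branch, []).append((row.family, row.event))
        for v in tree.preorder():
            if v == 0:
                continue
            states[v] = states[tree.parent[v]]
            for fam, ev in by_branch.get(tree.labels[v], ()):
                states[v, fam_idx[fam]] = 1 if ev == "gain" else 0
        leaves = tree.leaf_indices
        return pd.DataFrame(
            states[leaves], index=[tree.labels[i] for i in leaves], columns=families
        )

    def concat(self, other: "EventHistory") -> "EventHistory":
        return EventHistory(
            events=pd.concat([self.events, other.events], ignore_index=True),
            root_states={**self.root_states, **other.root_states},
        )


_EVENT_COLS = ["branch", "family", "event", "position"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=_EVENT_COLS)


def _spawn(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


# ------------------------------------------------------------------ tree

def _expand_clonal_cluster(dtree, leaf, k, height, rng):
    """Replace ``leaf`` with a ``k``-tip coalescent-style subtree whose tips
    sit at exactly the leaf's original depth (cluster height <= ``height``)."""
    L = leaf.edge.length
    h = min(height, 0.5 * L) if L > 0 else 0.0
    merge_times = np.sort(rng.uniform(0, h, k - 1)) if h > 0 else np.zeros(k - 1)
    lineages = []
    for _ in range(k):
        tip = dendropy.Node()
        tip.taxon = dtree.taxon_namespace.new_taxon(
            f"tmp{id(tip)}")
        lineages.append((tip, 0.0))
    for t in merge_times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        joint = dendropy.Node()
        joint.add_child(a)
        joint.add_child(b)
        a.edge.length = t - ha
        b.edge.length = t - hb
        lineages = [x for r, x in enumerate(lineages) if r not in (i, j)]
        lineages.append((joint, t))
    root, hr = lineages[0]
    parent = leaf.parent_node
    parent.remove_child(leaf)
    parent.add_child(root)
    root.edge.length = L - hr


def simulate_tree(config: SimulationConfig, seed=None) -> StrainTree:
    """Birth--death tree on ``n_genomes`` extant tips, branch lengths
    rescaled so the mean root-to-tip path equals ``tree_height_target``.

    Two features emulate real strain trees: per-branch lognormal rate
    multipliers (mean 1, sigma ``rate_lognormal_sigma``, applied before
    rescaling) spread branch lengths over orders of magnitude, and a
    fraction of tips is expanded into near-clonal clusters -- small
    coalescent subtrees of height ``clonal_height`` whose tips keep the
    original tip's root-to-tip depth, standing in for densely sampled
    clonal lineages.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    pyrng = random.Random(int(ss.generate_state(1)[0] % (2**31)))
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_genomes
    cf = config.clonal_fraction
    kmean = max(config.clonal_mean_size, 2.0)
    m = n if cf == 0 else int(np.clip(round(n / (1 + cf * (kmean - 1))), 3, n))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=m,
        rng=pyrng,
    )
    dtree.seed_node.edge.length = None  # drop the root stem
    if config.rate_lognormal_sigma > 0:
        sig = config.rate_lognormal_sigma
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rng.lognormal(mean=-0.5 * sig**2, sigma=sig)
    depths = dtree.calc_node_root_distances(
        return_leaf_distances_only=True)
    mean_tip = float(np.mean(depths))
    if mean_tip <= 0:
        raise ValueError("degenerate simulated tree (zero height)")
    factor = config.tree_height_target / mean_tip
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor

    if m < n:
        base_leaves = list(dtree.leaf_node_iter())
        n_seeds = max(1, int(round(cf * m)))
        seed_idx = rng.choice(len(base_leaves), size=n_seeds, replace=False)
        sizes = np.ones(n_seeds, dtype=int)
        for _ in range(n - m):
            sizes[int(rng.integers(n_seeds))] += 1
        for idx, k in zip(seed_idx, sizes):
            if k >= 2:
                _expand_clonal_cluster(dtree, base_leaves[int(idx)], int(k),
                                       config.clonal_height, rng)

    for i, leaf in enumerate(dtree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = dtree.taxon_namespace.new_taxon("x")
        leaf.taxon.label = f"G{i + 1:04d}"
    tree = StrainTree.from_dendropy(dtree)
    # exact final rescale (cluster expansion reweights the tip-depth mean)
    mean_tip = float(np.mean(tree.node_depths()[tree.leaf_indices]))
    tree.lengths = tree.lengths * (config.tree_height_target / mean_tip)
    tree._postorder = None
    log.info("simulate_tree seed=%s n_leaves=%d height=%g",
             seed, tree.n_leaves, config.tree_height_target)
    return tree


# ----------------------------------------------------- two-state machinery

def _gillespie_branch(state: int, segments, rng, forced=()) -> tuple:
    """Evolve a 0/1 state along a branch split into constant-rate segments.

    ``segments``: iterable of (t0, t1, gain_rate, loss_rate) in absolute
    branch-time units.  ``forced``: optional (time, kind, prob) point events
    (burst co-transfer triggers) applied with probability ``prob`` when the
    state allows.  Returns (events, end_state) with events as (event, time)
    tuples.
    """
    events = []
    queue = sorted(forced)
    fi = 0

    def run(state, t, t_end, g, l):
        while True:
            rate = g if state == 0 else l
            if rate <= 0:
                return state
            t = t + rng.exponential(1.0 / rate)
            if t >= t_end:
                return state
            events.append(("gain" if state == 0 else "loss", t))
            state = 1 - state

    for t0, t1, g, l in segments:
        t = t0
        while fi < len(queue) and queue[fi][0] < t1:
            ft, kind, prob = queue[fi]
            fi += 1
            if ft < t:
                continue
            state = run(state, t, ft, g, l)
            t = ft
            if kind == "gain" and state == 0 and rng.random() < prob:
                events.append(("gain", ft))
                state = 1
            elif kind == "loss" and state == 1 and rng.random() < prob:
                events.append(("loss", ft))
                state = 0
        state = run(state, t, t1, g, l)
    return events, state


def _simulate_ctmc_family(tree, fam, g, l, rng, records, leaf_states,
                          segments_by_branch=None, phi=1.0,
                          forced_by_branch=None):
    """One family's history over the whole tree; appends to ``records`` and
    fills ``leaf_states[fam]``.  Defense modulation via per-branch segments
    of (a, b, defense_state) fractions; ``forced_by_branch`` carries burst
    co-transfer triggers as (time, kind, prob) per branch."""
    pi1 = g / (g + l) if (g + l) > 0 else 0.0
    state = int(rng.random() < pi1)
    root_state = state
    node_state = {0: state}
    for v in tree.preorder():
        if v == 0:
            continue
        t = tree.lengths[v]
        s = node_state[tree.parent[v]]
        if segments_by_branch is None or phi == 1.0:
            segs = [(0.0, t, g, l)]
        else:
            segs = [
                (a * t, b * t, g * (phi if d else 1.0), l)
                for a, b, d in segments_by_branch[v]
            ]
        forced = () if forced_by_branch is None else forced_by_branch.get(v, ())
        events, s_end = _gillespie_branch(s, segs, rng, forced)
        node_state[v] = s_end
        label = tree.labels[v]
        for ev, tt in events:
            records.append((label, fam, ev, tt / t if t > 0 else 0.0))
        if tree.is_leaf(v):
            leaf_states[fam][label] = s_end
    return root_state


# ----------------------------------------------------------------- MGEs

def simulate_mge_history(tree: StrainTree, config: SimulationConfig,
                         seed=None) -> tuple:
    """Evolve the MGE driver families as independent two-state chains.

    Returns ``(EventHistory, leaf_states)`` with leaf_states a genomes x
    families 0/1 DataFrame.  Root states are drawn from the stationary
    frequency g/(g+l).
    """
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list = []
    leaf_states: dict = {}
    root_states: dict = {}
    g, l = config.mge_gain_rate, config.mge_loss_rate
    for i in range(config.n_mge_families):
        cls = MGE_CLASSES[i % len(MGE_CLASSES)]
        fam = f"MGE{i + 1:04d}_{cls}"
        leaf_states[fam] = {}
        root_states[fam] = _simulate_ctmc_family(
            tree, fam, g, l, rng, records, leaf_states)
    events = pd.DataFrame(records, columns=_EVENT_COLS) if records else _empty_events()
    history = EventHistory(events=events, root_states=root_states)
    leaves = tree.leaf_labels
    df = pd.DataFrame(leaf_states, dtype=np.int8).reindex(leaves).fillna(0).astype(np.int8)
    log.info("simulate_mge_history seed=%s families=%d events=%d",
             seed, config.n_mge_families, len(events))
    return history, df


# --------------------------------------------------------------- defense

def simulate_defense_history(tree: StrainTree, mge_history: EventHistory,
                             config: SimulationConfig, seed=None) -> tuple:
    """Defense gains ride same-branch MGE gains with probability ``p_link``;
    background gains occur as a Poisson process; a present defense is lost
    with probability ``q_link`` on branches with at least one MGE loss.

    Returns ``(EventHistory, TraitTable)``.
    """
    if seed is None:
        seed = config.seed + 2
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_link = config.defense_linkage
    q_link = config.defense_loss_linkage
    bg = config.defense_independent_gain_rate
    name = config.defense_system
    fam = f"DEFSYS_{name}"

    mge_ev = mge_history.events
    gain_pos: dict = {}
    loss_pos: dict = {}
    if len(mge_ev):
        for br, grp in mge_ev.groupby("branch"):
            gp = grp.loc[grp["event"] == "gain", "position"]
            lp = grp.loc[grp["event"] == "loss", "position"]
            if len(gp):
                gain_pos[br] = float(gp.min())
            if len(lp):
                loss_pos[br] = float(lp.min())

    records: list = []
    leaf_states: dict = {}
    root_state = int(config.defense_root_present)
    node_state = {0: root_state}
    for v in tree.preorder():
        if v == 0:
            continue
        label = tree.labels[v]
        t = tree.lengths[v]
        state = node_state[tree.parent[v]]
        candidates = []  # (position_fraction, kind)
        if label in gain_pos and rng.random() < p_link:
            candidates.append((gain_pos[label], "linked_gain"))
        if label in loss_pos and rng.random() < q_link:
            candidates.append((loss_pos[label], "linked_loss"))
        if bg > 0 and t > 0:
            n_bg = rng.poisson(bg * t)
            for u in sorted(rng.random(n_bg)):
                candidates.append((u, "bg_gain"))
        for pos, kind in sorted(candidates):
            if kind in ("linked_gain", "bg_gain") and state == 0:
                records.append((label, fam, "gain", pos))
                state = 1
            elif kind == "linked_loss" and state == 1:
                records.append((label, fam, "loss", pos))
                state = 0
        node_state[v] = state
        if tree.is_leaf(v):
            leaf_states[label] = state

    events = pd.DataFrame(records, columns=_EVENT_COLS) if records else _empty_events()
    history = EventHistory(events=events, root_states={fam: root_state})
    traits = TraitTable(pd.DataFrame(
        {name: pd.Series(leaf_states, dtype=np.int8).reindex(tree.leaf_labels)}))
    log.info("simulate_defense_history seed=%s gains=%d losses=%d prevalence=%.3f",
             seed, (events["event"] == "gain").sum(),
             (events["event"] == "loss").sum(), traits.df[name].mean())
    return history, traits


def simulate_linked_histories(tree: StrainTree, config: SimulationConfig,
                              seed=None) -> tuple:
    """Joint MGE-driver / defense simulation with feedback: driver gain
    rates are multiplied by ``defense_effect`` on branches whose start state
    carries the defense system, while defense gains/losses ride same-branch
    driver events exactly as in :func:`simulate_defense_history`.

    Returns ``(mge_history, mge_leaf_states, defense_history, TraitTable)``.
    """
    if seed is None:
        seed = config.seed + 5
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g, l = config.mge_gain_rate, config.mge_loss_rate
    phi = config.defense_effect if config.defense_blocks_mge else 1.0
    p_link = config.defense_linkage
    q_link = config.defense_loss_linkage
    bg = config.defense_independent_gain_rate
    name = config.defense_system
    def_fam = f"DEFSYS_{name}"

    fams = [f"MGE{i + 1:04d}_{MGE_CLASSES[i % len(MGE_CLASSES)]}"
            for i in range(config.n_mge_families)]
    pi1 = g / (g + l) if (g + l) > 0 else 0.0
    root_states = {f: int(rng.random() < pi1) for f in fams}
    node_mge = {0: np.array([root_states[f] for f in fams], dtype=np.int8)}
    def_root = int(config.defense_root_present)
    node_def = {0: def_root}
    node_mob = {0: 0.0}  # log mobility random walk (one step per branch)

    mge_records: list = []
    def_records: list = []
    mge_leaf: dict = {}
    def_leaf: dict = {}
    for v in tree.preorder():
        v = int(v)
        if v == 0:
            continue
        label = tree.labels[v]
        t = tree.lengths[v]
        s_def = node_def[tree.parent[v]]
        mob = node_mob[tree.parent[v]]
        if config.mobility_sigma > 0:
            mob += rng.normal(0.0, config.mobility_sigma)
        node_mob[v] = mob
        gd = g * np.exp(mob) * (phi if s_def else 1.0)
        states = node_mge[tree.parent[v]].copy()
        gain_positions, loss_positions = [], []
        for j, f in enumerate(fams):
            events, s_end = _gillespie_branch(
                int(states[j]), [(0.0, t, gd, l)], rng)
            states[j] = s_end
            for ev, tt in events:
                pos = tt / t if t > 0 else 0.0
                mge_records.append((label, f, ev, pos))
                (gain_positions if ev == "gain" else loss_positions).append(pos)
        node_mge[v] = states

        candidates = []
        if gain_positions and rng.random() < p_link:
            candidates.append((min(gain_positions), "linked_gain"))
        if loss_positions and rng.random() < q_link:
            candidates.append((min(loss_positions), "linked_loss"))
        if bg > 0 and t > 0:
            for u in sorted(rng.random(rng.poisson(bg * t))):
                candidates.append((u, "bg_gain"))
        state = s_def
        for pos, kind in sorted(candidates):
            if kind in ("linked_gain", "bg_gain") and state == 0:
                def_records.append((label, def_fam, "gain", pos))
                state = 1
            elif kind == "linked_loss" and state == 1:
                def_records.append((label, def_fam, "loss", pos))
                state = 0
        node_def[v] = state
        if tree.is_leaf(v):
            mge_leaf[label] = states
            def_leaf[label] = state

    mge_events = (pd.DataFrame(mge_records, columns=_EVENT_COLS)
                  if mge_records else _empty_events())
    def_events = (pd.DataFrame(def_records, columns=_EVENT_COLS)
                  if def_records else _empty_events())
    mge_history = EventHistory(events=mge_events, root_states=root_states)
    defense_history = EventHistory(events=def_events,
                                   root_states={def_fam: def_root})
    leaves = tree.leaf_labels
    mge_states = pd.DataFrame(
        np.array([mge_leaf[lab] for lab in leaves], dtype=np.int8),
        index=leaves, columns=fams)
    traits = TraitTable(pd.DataFrame(
        {name: pd.Series(def_leaf, dtype=np.int8).reindex(leaves)}))
    log.info("simulate_linked_histories seed=%s mge_events=%d def_gains=%d "
             "prevalence=%.3f", seed, len(mge_events),
             (def_events["event"] == "gain").sum(), traits.df[name].mean())
    return mge_history, mge_states, defense_history, traits


def defense_segments(tree: StrainTree, defense_history: EventHistory) -> dict:
    """Per branch, the defense on/off segments as (a, b, state) fractions."""
    name = next(iter(defense_history.root_states))
    node_state = {0: defense_history.root_states[name]}
    by_branch: dict = {}
    ev = defense_history.events.sort_values("position")
    ev_by_branch = {br: list(zip(grp["event"], grp["position"]))
                    for br, grp in ev.groupby("branch")}
    for v in tree.preorder():
        if v == 0:
            continue
        state = node_state[tree.parent[v]]
        segs = []
        a = 0.0
        for kind, pos in ev_by_branch.get(tree.labels[v], ()):
            segs.append((a, pos, state))
            state = 1 if kind == "gain" else 0
            a = pos
        segs.append((a, 1.0, state))
        by_branch[v] = [(x, y, bool(s)) for x, y, s in segs if y > x]
        node_state[v] = state
    return by_branch


# ----------------------------------------------------------- gene families

def simulate_gene_families(tree: StrainTree, defense_history: EventHistory,
                           config: SimulationConfig, seed=None,
                           mge_history: EventHistory | None = None) -> tuple:
    """Accessory families of the four classes, gain rate multiplied by
    ``defense_effect`` on tree segments where the defense system is present.

    When ``mge_history`` is given, cargo families of the three MGE classes
    are additionally co-gained/co-lost in bursts with the same-class driver
    events (each driver gain recruits on average ``cargo_gain_burst``
    absent cargo families at the same branch position) -- elements carry
    cargo genes, which is what makes recent acquisitions bursty.

    Returns ``(PresenceMatrix, FamilyAnnotation, EventHistory)`` covering the
    accessory families, injected singletons and the defense family itself.
    """
    if seed is None:
        seed = config.seed + 3
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    segments = defense_segments(tree, defense_history)
    phi = config.defense_effect

    # burst triggers per MGE class x branch from the driver events
    label_to_node = {tree.labels[v]: v for v in range(tree.n_nodes)}
    triggers: dict = {}
    if mge_history is not None and len(mge_history.events):
        for row in mge_history.events.itertuples(index=False):
            cls = row.family.rsplit("_", 1)[-1]
            v = label_to_node[row.branch]
            triggers.setdefault(cls, {}).setdefault(v, []).append(
                (row.position * tree.lengths[v], row.event))

    records: list = []
    leaf_states: dict = {}
    root_states: dict = {}
    classes: dict = {}
    a = config.family_rate_gamma_shape
    for cls in ("prophage", "plasmid", "transposon", "neutral"):
        g = config.base_gain_rate[cls]
        l = config.base_loss_rate[cls]
        n_c = config.n_families[cls]
        forced = None
        if cls in triggers and n_c > 0:
            pg = min(1.0, config.cargo_gain_burst / n_c)
            pl = min(1.0, config.cargo_loss_burst / n_c)
            forced = {
                v: [(t, kind, pg if kind == "gain" else pl)
                    for t, kind in evs]
                for v, evs in triggers[cls].items()
            }
        for i in range(n_c):
            fam = f"FAM{cls[:2].upper()}{i + 1:05d}"
            classes[fam] = cls
            leaf_states[fam] = {}
            r = rng.gamma(a, 1.0 / a) if a > 0 else 1.0
            root_states[fam] = _simulate_ctmc_family(
                tree, fam, g * r, l * r, rng, records, leaf_states,
                segments_by_branch=segments, phi=phi,
                forced_by_branch=forced)

    # injected singleton families (noise: one random genome each)
    n_core = sum(config.n_families.values())
    n_single = int(round(config.singleton_fraction * n_core))
    leaves = tree.leaf_indices
    leaf_labels = tree.leaf_labels
    for i in range(n_single):
        fam = f"SING{i + 1:05d}"
        classes[fam] = "singleton"
        host = int(rng.integers(len(leaves)))
        leaf_states[fam] = {lab: 0 for lab in leaf_labels}
        leaf_states[fam][leaf_labels[host]] = 1
        root_states[fam] = 0
        records.append((tree.labels[leaves[host]], fam, "gain",
                        float(rng.random())))

    events = pd.DataFrame(records, columns=_EVENT_COLS) if records else _empty_events()
    history = EventHistory(events=events, root_states=root_states)

    # assemble matrix: accessory + singletons + the defense family itself
    fam_df = pd.DataFrame(leaf_states, dtype=np.int8).reindex(leaf_labels).fillna(0)
    def_fam = next(iter(defense_history.root_states))
    def_name = def_fam.removeprefix("DEFSYS_")
    def_states = defense_history.replay(tree)[def_fam]
    fam_df[def_fam] = def_states.reindex(leaf_labels).astype(np.int8)
    matrix = PresenceMatrix(fam_df.astype(np.int8))

    annot = pd.DataFrame(index=list(fam_df.columns))
    annot.index.name = "family"
    annot["mge_class"] = [
        classes.get(f, "none") if classes.get(f, "none") in MGE_CLASSES else "none"
        for f in annot.index
    ]
    annot["cog_category"] = [
        {"prophage": "X", "plasmid": "L", "transposon": "X"}.get(
            classes.get(f, "none"), "none")
        for f in annot.index
    ]
    annot["defense_system"] = ["none"] * len(annot)
    annot.loc[def_fam, "defense_system"] = def_name
    annot["mge_resident"] = [classes.get(f, "none") in MGE_CLASSES
                             for f in annot.index]
    annot["singleton"] = matrix.singleton_flags().reindex(annot.index).to_numpy()
    annotation = FamilyAnnotation(annot)
    log.info("simulate_gene_families seed=%s families=%d events=%d",
             seed, len(annot), len(events))
    return matrix, annotation, history


# ----------------------------------------------------------------- bundle

@dataclass
class SimulatedDataset:
    tree: StrainTree
    matrix: PresenceMatrix
    traits: TraitTable
    annotation: FamilyAnnotation
    mge_history: EventHistory
    defense_history: EventHistory
    family_history: EventHistory
    config: SimulationConfig

    @property
    def full_history(self) -> EventHistory:
        return self.mge_history.concat(self.defense_history).concat(
            self.family_history)


def generate_dataset(config: SimulationConfig, out_dir=None) -> SimulatedDataset:
    """End-to-end dataset generation; optionally writes the bundle to disk.

    Files written: ``tree.nwk``, ``presence.Rtab``, ``traits.tsv``,
    ``annotation.tsv``, ``events.tsv``, ``root_states.tsv``, ``config.yaml``.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in _spawn(config.seed, 4)]
    tree = simulate_tree(config, seed=seeds[0])
    if config.defense_blocks_mge:
        mge_history, mge_states, defense_history, traits = \
            simulate_linked_histories(tree, config, seed=seeds[1])
    else:
        mge_history, mge_states = simulate_mge_history(
            tree, config, seed=seeds[1])
        defense_history, traits = simulate_defense_history(
            tree, mge_history, config, seed=seeds[2])
    matrix, annotation, fam_history = simulate_gene_families(
        tree, defense_history, config, seed=seeds[3],
        mge_history=mge_history)

    # merge MGE driver families into the matrix/annotation
    merged = pd.concat([matrix.df, mge_states], axis=1)
    matrix = PresenceMatrix(merged)
    extra = pd.DataFrame(index=list(mge_states.columns))
    extra.index.name = "family"
    extra["mge_class"] = [f.rsplit("_", 1)[1] for f in extra.index]
    extra["cog_category"] = ["X"] * len(extra)
    extra["defense_system"] = ["none"] * len(extra)
    extra["mge_resident"] = True
    extra["singleton"] = False
    annot_df = pd.concat([annotation.df, extra])
    annot_df["singleton"] = matrix.singleton_flags().reindex(annot_df.index).to_numpy()
    annotation = FamilyAnnotation(annot_df)
    annotation.check_consistent(matrix)

    ds = SimulatedDataset(tree, matrix, traits, annotation,
                          mge_history, defense_history, fam_history, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tree.write_newick(out / "tree.nwk")
        rtab = matrix.df.T.copy()
        rtab.index.name = "Gene"
        rtab.to_csv(out / "presence.Rtab", sep="\t")
        write_trait_table(traits, out / "traits.tsv")
        write_annotation(annotation, out / "annotation.tsv")
        ev = ds.full_history.events.sort_values(
            ["branch", "family", "position"]).reset_index(drop=True)
        write_table(ev, out / "events.tsv")
        rs = pd.DataFrame(
            sorted(ds.full_history.root_states.items()),
            columns=["family", "root_state"])
        write_table(rs, out / "root_states.tsv")
        config.to_yaml(out / "config.yaml")
    log.info("generate_dataset seed=%d genomes=%d families=%d",
             config.seed, len(matrix.genome_ids), len(matrix.family_ids))
    return ds


def event_count_table(tree: StrainTree, history: EventHistory,
                      families=None) -> pd.DataFrame:
    """Ground-truth per-branch event counts for a family set, in the same
    layout as the inferred expected-event tables (branch, branch_length,
    is_terminal, expected_gains, expected_losses)."""
    ev = history.events
    if families is not None:
        ev = ev[ev["family"].isin(set(families))]
    gains = ev[ev["event"] == "gain"].groupby("branch").size()
    losses = ev[ev["event"] == "loss"].groupby("branch").size()
    rows = []
    for v in range(1, tree.n_nodes):
        lab = tree.labels[v]
        rows.append({
            "branch": lab,
            "branch_length": tree.lengths[v],
            "is_terminal": tree.is_leaf(v),
            "expected_gains": float(gains.get(lab, 0)),
            "expected_losses": float(losses.get(lab, 0)),
        })
    return pd.DataFrame(rows)


def read_event_history(events_path, root_states_path) -> EventHistory:
    events = pd.read_csv(events_path, sep="\t")
    rs = pd.read_csv(root_states_path, sep="\t")
    return EventHistory(
        events=events, root_states=dict(zip(rs["family"], rs["root_state"])))
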