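"""DEF+/DEF- sister-clade detection and gain/loss-rate comparison.

DEF+ clades are the maximal disjoint clades in which at least ``purity``
(default 80%) of the leaves carry the defense system; DEF- clades are
defined analogously on leaves lacking it.  Sister pairs (children of the
same node) are compared through per-clade flux rates: expected events
summed over the clade's branches (stem included by default, singleton
families excluded) divided by the summed branch length.  Comparisons use
log-transformed DEF+/DEF- ratios (Wilcoxon signed-rank against 0), and the
timescale analysis stratifies pairs by the depth of their last common
ancestor with a d'Agostino skewness test per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tree import StrainTree

__all__ = [
    "CladePair",
    "find_def_clades",
    "pair_sisters",
    "clade_rates",
    "clade_depth",
    "stratify",
    "test_logratios",
    "skewness_test",
    "sister_pair_table",
]

RECENT_CUTOFF = 1e-5
OLD_CUTOFF = 1e-3


@dataclass
class CladePair:
    """A DEF+ clade and its DEF- sister (children of ``parent``)."""

    plus_node: int
    minus_node: int
    parent: int
    n_leaves_plus: int
    n_leaves_minus: int


def _leaf_counts(tree: StrainTree, trait: np.ndarray):
    """Per-node total and trait-positive leaf counts (postorder sums)."""
    pos_leaf = {int(v): i for i, v in enumerate(tree.leaf_indices)}
    n_leaves = np.zeros(tree.n_nodes, dtype=int)
    n_pos = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder():
        v = int(v)
        if not tree.children[v]:
            n_leaves[v] = 1
            n_pos[v] = trait[pos_leaf[v]]
        else:
            for c in tree.children[v]:
                n_leaves[v] += n_leaves[c]
                n_pos[v] += n_pos[c]
    return n_leaves, n_pos


def _coerce_trait(tree: StrainTree, trait) -> np.ndarray:
    if isinstance(trait, pd.Series):
        return trait.loc[tree.leaf_labels].to_numpy()
    if isinstance(trait, dict):
        return np.array([trait[lab] for lab in tree.leaf_labels])
    trait = np.asarray(trait)
    if len(trait) != tree.n_leaves:
        raise ValueError("trait must cover all leaves")
    return trait


def find_def_clades(tree: StrainTree, trait, purity: float = 0.8,
                    state: int = 1) -> list:
    """Maximal disjoint clades in which >= ``purity`` of leaves have
    ``trait == state``; found by a preorder sweep that stops at the first
    qualifying node on each root-to-leaf path (so no selected clade is
    nested in another)."""
    x = _coerce_trait(tree, trait)
    n_leaves, n_pos = _leaf_counts(tree, (x == state).astype(int))
    found, stack = [], [0]
    while stack:
        v = stack.pop()
        if n_pos[v] >= purity * n_leaves[v]:
            found.append(v)
        else:
            stack.extend(tree.children[v])
    return sorted(found)


def pair_sisters(def_plus: list, def_minus: list, tree: StrainTree) -> list:
    """Sister pairs: one DEF+ and one DEF- clade sharing a parent node.
    Pairs in which both clades are single genomes are excluded."""
    by_parent: dict = {}
    for v in def_plus:
        if v != 0:
            by_parent.setdefault(int(tree.parent[v]), [[], []])[0].append(v)
    for v in def_minus:
        if v != 0:
            by_parent.setdefault(int(tree.parent[v]), [[], []])[1].append(v)
    pairs = []
    for parent, (plus, minus) in sorted(by_parent.items()):
        for p in plus:
            for m in minus:
                np_, nm = len(tree.leaf_set(p)), len(tree.leaf_set(m))
                if np_ == 1 and nm == 1:
                    continue
                pairs.append(CladePair(p, m, parent, np_, nm))
    return pairs


def clade_rates(branch_table: pd.DataFrame, tree: StrainTree,
                clade_node: int, include_stem: bool = True) -> tuple:
    """(gain_rate, loss_rate, total_length) for one clade.

    ``branch_table`` carries per-branch expected event sums for the family
    set of interest (columns: branch, branch_length, expected_gains,
    expected_losses).  By default the clade's stem branch counts towards
    the clade (a single-genome clade then has a defined rate over its
    terminal branch); with ``include_stem=False`` only branches strictly
    inside the clade are used and single-genome clades yield NaN rates.
    """
    desc = tree.descendants(clade_node)
    labels = {tree.labels[v] for v in desc}
    if include_stem and clade_node != 0:
        labels.add(tree.labels[clade_node])
    sub = branch_table[branch_table["branch"].isin(labels)]
    total_len = float(sub["branch_length"].sum())
    if total_len <= 0:
        return float("nan"), float("nan"), 0.0
    return (
        float(sub["expected_gains"].sum()) / total_len,
        float(sub["expected_losses"].sum()) / total_len,
        total_len,
    )


def clade_depth(tree: StrainTree, parent_node: int,
                method: str = "mean") -> float:
    """Depth of a sister pair: mean (or max) path length from the pair's
    parent node to its descendant leaves."""
    depths = tree.node_depths()
    leaves = tree.leaf_set(parent_node)
    dist = depths[leaves] - depths[parent_node]
    if method == "mean":
        return float(np.mean(dist))
    if method == "max":
        return float(np.max(dist))
    raise ValueError("method must be 'mean' or 'max'")


def stratify(depths, recent: float = RECENT_CUTOFF,
             old: float = OLD_CUTOFF) -> pd.Series:
    """Assign 'recent' (< recent), 'old' (> old) or 'middle' per depth;
    boundary values fall in the middle band (open intervals)."""
    depths = pd.Series(depths, dtype=float)
    out = pd.Series("middle", index=depths.index)
    out[depths < recent] = "recent"
    out[depths > old] = "old"
    return out


def test_logratios(log_ratios) -> tuple:
    """Median ratio and two-sided Wilcoxon signed-rank p against 0.

    Undefined (non-finite) log ratios must be removed by the caller.
    """
    lr = np.asarray(log_ratios, dtype=float)
    lr = lr[np.isfinite(lr)]
    if len(lr) == 0:
        raise ValueError("no finite log ratios")
    median_ratio = float(np.exp(np.median(lr)))
    if np.all(lr == 0):
        return median_ratio, 1.0
    p = float(stats.wilcoxon(lr, alternative="two-sided").pvalue)
    return median_ratio, p


def skewness_test(values) -> tuple:
    """Sample skewness g1 with the d'Agostino normalising transformation
    (two-sided)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 8:
        raise ValueError("insufficient n for skewtest (need >= 8)")
    g1 = float(stats.skew(v))
    z, p = stats.skewtest(v)
    return g1, float(z), float(p)


def sister_pair_table(tree: StrainTree, trait, branch_tables: dict,
                      purity: float = 0.8, depth_method: str = "mean",
                      include_stem: bool = True) -> pd.DataFrame:
    """One row per sister pair x family class, with rates, log ratios,
    depth and stratum.

    ``branch_tables``: mapping class name -> per-branch expected-event table
    (already restricted to that family class, singletons excluded).
    """
    plus = find_def_clades(tree, trait, purity=purity, state=1)
    minus = find_def_clades(tree, trait, purity=purity, state=0)
    pairs = pair_sisters(plus, minus, tree)
    rows = []
    for pair in pairs:
        depth = clade_depth(tree, pair.parent, method=depth_method)
        for cls, table in branch_tables.items():
            gp, lp, len_p = clade_rates(table, tree, pair.plus_node,
                                        include_stem=include_stem)
            gm, lm, len_m = clade_rates(table, tree, pair.minus_node,
                                        include_stem=include_stem)
            with np.errstate(divide="ignore", invalid="ignore"):
                lgr = np.log(gp / gm) if gp > 0 and gm > 0 else float("nan")
                llr = np.log(lp / lm) if lp > 0 and lm > 0 else float("nan")
            rows.append({
                "plus_node": tree.labels[pair.plus_node],
                "minus_node": tree.labels[pair.minus_node],
                "n_leaves_plus": pair.n_leaves_plus,
                "n_leaves_minus": pair.n_leaves_minus,
                "family_class": cls,
                "depth": depth,
                "gain_rate_plus": gp,
                "gain_rate_minus": gm,
                "loss_rate_plus": lp,
                "loss_rate_minus": lm,
                "log_gain_ratio": lgr,
                "log_loss_ratio": llr,
            })
    columns = ["plus_node", "minus_node", "n_leaves_plus", "n_leaves_minus",
               "family_class", "depth", "gain_rate_plus", "gain_rate_minus",
               "loss_rate_plus", "loss_rate_minus", "log_gain_ratio",
               "log_loss_ratio"]
    df = pd.DataFrame(rows, columns=columns)
    df["stratum"] = (stratify(df["depth"]).to_numpy() if len(df)
                     else np.array([], dtype=object))
    return df


def stratum_summary(pair_table: pd.DataFrame, ratio: str = "log_gain_ratio",
                    min_n_skew: int = 8) -> pd.DataFrame:
    """Per-stratum median, Wilcoxon p and skewness of the chosen log ratio."""
    rows = []
    for (cls, stratum), grp in pair_table.groupby(["family_class", "stratum"]):
        lr = grp[ratio].to_numpy()
        finite = lr[np.isfinite(lr)]
        row = {"family_class": cls, "stratum": stratum,
               "n_pairs": len(grp), "n_finite": len(finite),
               "n_undefined": int(len(grp) - len(finite))}
        if len(finite):
            med, wp = test_logratios(finite)
            row["median_ratio"] = med
            row["wilcoxon_p"] = wp
        if len(finite) >= min_n_skew:
            g1, z, p = skewness_test(finite)
            row.update({"skewness": g1, "skew_z": z, "skew_p": p})
        rows.append(row)
    return pd.DataFrame(rows)
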