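"""Stage functions shared by the command-line interface.

Each stage reads/writes the dataset directory layout produced by
``generate_dataset`` (tree.nwk, presence.Rtab, traits.tsv, annotation.tsv,
events.tsv, root_states.tsv) and adds its own result TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cladeflux, linkage
from .association import classify_battery, summarize
from .gainloss import TwoStateGainLoss
from .io import (
    FamilyAnnotation,
    PresenceMatrix,
    read_annotation,
    read_presence_matrix,
    read_trait_table,
    write_table,
)
from .pglmm import brownian_covariance, fit_species_battery
from .simulate import read_event_history
from .tree import read_newick

log = logging.getLogger("defenseflux")

#: aggregation groups written to branch_events.tsv
EVENT_GROUPS = ("prophage", "plasmid", "transposon", "none", "mge_any",
                "defense", "total")


def load_dataset_dir(path):
    path = Path(path)
    tree = read_newick(path / "tree.nwk")
    matrix, _ = read_presence_matrix(path / "presence.Rtab", dialect="rtab")
    traits = read_trait_table(path / "traits.tsv")
    annotation = read_annotation(path / "annotation.tsv")
    annotation.check_consistent(matrix)
    return tree, matrix.aligned_to(tree), traits.aligned_to(tree), annotation


def family_masks(annotation: FamilyAnnotation, family_ids) -> dict:
    """Boolean masks per aggregation group over ``family_ids``.

    Singletons are excluded everywhere; defense families are excluded from
    every group except ``defense``; ``total`` covers all non-defense,
    non-singleton families; ``mge_any`` unions the three MGE classes.
    """
    df = annotation.df.reindex(family_ids)
    singleton = df["singleton"].to_numpy()
    is_def = (df["defense_system"] != "none").to_numpy()
    cls = df["mge_class"].to_numpy()
    masks = {}
    for c in ("prophage", "plasmid", "transposon", "none"):
        masks[c] = (cls == c) & ~singleton & ~is_def
    masks["mge_any"] = np.isin(cls, ("prophage", "plasmid", "transposon")) \
        & ~singleton & ~is_def
    masks["defense"] = is_def
    masks["total"] = ~singleton & ~is_def
    return masks


def stage_gainloss(in_dir, out_dir, n_categories: int = 4) -> pd.DataFrame:
    """Fit the gain/loss model and write per-branch expected events,
    aggregated per family group."""
    tree, matrix, _, annotation = load_dataset_dir(in_dir)
    est = TwoStateGainLoss(n_categories=n_categories).fit(matrix, tree=tree)
    events = est.expected_events(matrix, tree=tree)
    masks = family_masks(annotation, events.family_ids)
    parts = []
    for group in EVENT_GROUPS:
        t = events.aggregate(masks[group])
        t.insert(3, "family_class", group)
        parts.append(t)
    table = pd.concat(parts, ignore_index=True)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(table, out / "branch_events.tsv")
    write_table(pd.DataFrame([{
        "gain_rate": est.gain_rate_, "loss_rate": est.loss_rate_,
        "gamma_shape": est.gamma_shape_, "n_categories": n_categories,
        "loglik": est.loglik_}]), out / "gainloss_model.tsv")
    log.info("stage_gainloss g=%.3g l=%.3g alpha=%.3g",
             est.gain_rate_, est.loss_rate_, est.gamma_shape_)
    return table


def responses_from_matrix(matrix: PresenceMatrix,
                          annotation: FamilyAnnotation) -> dict:
    """Per-genome count responses: total genes and MGE marker genes per
    class, always excluding defense-system families."""
    df = annotation.df.reindex(matrix.family_ids)
    non_def = (df["defense_system"] == "none").to_numpy()
    responses = {"total": matrix.df.loc[:, non_def].sum(axis=1)}
    for cls in ("prophage", "plasmid", "transposon"):
        m = non_def & (df["mge_class"] == cls).to_numpy()
        responses[cls] = matrix.df.loc[:, m].sum(axis=1)
    return responses


def stage_pglmm(in_dir, out_dir, mode: str = "single",
                species: str = "species") -> pd.DataFrame:
    tree, matrix, traits, annotation = load_dataset_dir(in_dir)
    cov = brownian_covariance(tree, rescale=True)
    responses = responses_from_matrix(matrix, annotation)
    table = fit_species_battery(responses, traits, cov, mode=mode,
                                species=species)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(table, out / "pglmm.tsv")
    return table


def stage_associate(pglmm_tables, out_dir) -> pd.DataFrame:
    """Classify a battery of per-species fits by both criteria."""
    merged = pd.concat([pd.read_csv(p, sep="\t") if not isinstance(
        p, pd.DataFrame) else p for p in pglmm_tables], ignore_index=True)
    classified = classify_battery(merged)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(classified, out / "associations.tsv")
    write_table(summarize(classified), out / "association_summary.tsv")
    return classified


def branch_tables_by_class(branch_events: pd.DataFrame) -> dict:
    return {cls: grp.reset_index(drop=True)
            for cls, grp in branch_events.groupby("family_class")}


def stage_clades(in_dir, out_dir, purity: float = 0.8,
                 depth_method: str = "mean") -> pd.DataFrame:
    tree, _, traits, _ = load_dataset_dir(in_dir)
    branch_events = pd.read_csv(Path(out_dir) / "branch_events.tsv", sep="\t")
    tables = branch_tables_by_class(branch_events)
    tables = {k: v for k, v in tables.items() if k != "defense"}
    parts = []
    for system in traits.systems:
        t = cladeflux.sister_pair_table(
            tree, traits.df[system], tables, purity=purity,
            depth_method=depth_method)
        if len(t):
            t.insert(0, "system", system)
            parts.append(t)
    if parts:
        table = pd.concat(parts, ignore_index=True)
    else:
        table = cladeflux.sister_pair_table(tree, traits.df.iloc[:, 0], {})
        table.insert(0, "system", pd.Series([], dtype=object))
    write_table(table, Path(out_dir) / "clade_pairs.tsv")
    return table


def stage_timescale(out_dir) -> pd.DataFrame:
    pairs = pd.read_csv(Path(out_dir) / "clade_pairs.tsv", sep="\t")
    summary = cladeflux.stratum_summary(pairs) if len(pairs) else pd.DataFrame()
    write_table(summary, Path(out_dir) / "timescale.tsv")
    return summary


def stage_linkage(in_dir, out_dir, source: str = "inferred",
                  threshold: float = 0.5) -> pd.DataFrame:
    """Branch-level co-occurrence statistics between defense and MGE events.

    ``source``: 'inferred' uses the gain/loss posterior calls from
    branch_events.tsv; 'truth' uses the simulator's events.tsv.
    """
    if source == "truth":
        in_path = Path(in_dir)
        tree = read_newick(in_path / "tree.nwk")
        annotation = read_annotation(in_path / "annotation.tsv")
        history = read_event_history(in_path / "events.tsv",
                                     in_path / "root_states.tsv")
        def_fams = annotation.df.index[
            annotation.df["defense_system"] != "none"]
        mge_fams = annotation.df.index[
            annotation.df["mge_class"].isin(
                ("prophage", "plasmid", "transposon"))]
        ev = history.events
        def_hist = type(history)(
            ev[ev["family"].isin(set(def_fams))], history.root_states)
        mge_hist = type(history)(
            ev[ev["family"].isin(set(mge_fams))], history.root_states)
        table = linkage.branch_table_from_history(tree, def_hist, mge_hist)
    elif source == "inferred":
        branch_events = pd.read_csv(
            Path(out_dir) / "branch_events.tsv", sep="\t")
        tables = branch_tables_by_class(branch_events)
        dt, mt = tables["defense"], tables["mge_any"]
        table = pd.DataFrame({
            "branch": dt["branch"],
            "branch_length": dt["branch_length"],
            "is_terminal": dt["is_terminal"],
            "def_gain": dt["p_ge1_gain"] > threshold,
            "def_loss": dt["p_ge1_loss"] > threshold,
            "mge_gain": mt["p_ge1_gain"].to_numpy() > threshold,
            "mge_loss": mt["p_ge1_loss"].to_numpy() > threshold,
        })
    else:
        raise ValueError("source must be 'inferred' or 'truth'")
    report = linkage.linkage_report(table)
    report.insert(0, "branch_subset", "all")
    for subset, rep in linkage.split_by_branch_type(table).items():
        if rep is not None:
            rep.insert(0, "branch_subset", subset)
            report = pd.concat([report, rep], ignore_index=True)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(table, out / "branch_calls.tsv")
    write_table(report, out / "linkage.tsv")
    return report
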