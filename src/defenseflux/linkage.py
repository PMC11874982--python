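"""Branch-level co-occurrence of defense and MGE gain/loss events.

Events are binary per branch (>= 1 event of the type).  The module computes
co-event fractions with exact binomial confidence intervals, the random
expectation under length-proportional placement of defense events,
conditional probabilities, risk ratios with log-normal CIs, exact binomial
and Fisher tests, and terminal/internal branch splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gainloss import BranchEvents
from .simulate import EventHistory
from .tree import StrainTree

__all__ = [
    "Contingency2x2",
    "branch_event_table",
    "branch_table_from_history",
    "cogain_fraction",
    "independence_expectation",
    "binomial_deviation_test",
    "conditional_probabilities",
    "risk_ratio",
    "fisher_exact",
    "split_by_branch_type",
    "linkage_report",
]


@dataclass
class Contingency2x2:
    """Branch counts; exposure = MGE event, outcome = defense event.

    a: both events, b: MGE only, c: defense only, d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


# ---------------------------------------------------------------- builders

def branch_event_table(def_events: BranchEvents, mge_events: BranchEvents,
                       def_mask=None, mge_mask=None,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Binary per-branch event calls from posterior expectations.

    A branch is called as carrying an event when the posterior probability
    of >= 1 event (aggregated over the family set) exceeds ``threshold``.
    """
    dt = def_events.aggregate(def_mask)
    mt = mge_events.aggregate(mge_mask)
    if list(dt["branch"]) != list(mt["branch"]):
        mt = mt.set_index("branch").loc[dt["branch"]].reset_index()
    return pd.DataFrame({
        "branch": dt["branch"],
        "branch_length": dt["branch_length"],
        "is_terminal": dt["is_terminal"],
        "def_gain": dt["p_ge1_gain"] > threshold,
        "def_loss": dt["p_ge1_loss"] > threshold,
        "mge_gain": mt["p_ge1_gain"] > threshold,
        "mge_loss": mt["p_ge1_loss"] > threshold,
    })


def branch_table_from_history(tree: StrainTree, def_history: EventHistory,
                              mge_history: EventHistory,
                              mge_families=None) -> pd.DataFrame:
    """Ground-truth binary event table from simulated histories."""
    def calls(history, families):
        ev = history.events
        if families is not None:
            ev = ev[ev["family"].isin(set(families))]
        gains = set(ev.loc[ev["event"] == "gain", "branch"])
        losses = set(ev.loc[ev["event"] == "loss", "branch"])
        return gains, losses

    dg, dl = calls(def_history, None)
    mg, ml = calls(mge_history, mge_families)
    rows = []
    for v in range(1, tree.n_nodes):
        lab = tree.labels[v]
        rows.append({
            "branch": lab,
            "branch_length": tree.lengths[v],
            "is_terminal": tree.is_leaf(v),
            "def_gain": lab in dg,
            "def_loss": lab in dl,
            "mge_gain": lab in mg,
            "mge_loss": lab in ml,
        })
    return pd.DataFrame(rows)


def contingency(table: pd.DataFrame, event: str = "gain") -> Contingency2x2:
    d = table[f"def_{event}"].to_numpy(dtype=bool)
    m = table[f"mge_{event}"].to_numpy(dtype=bool)
    return Contingency2x2(
        a=int((d & m).sum()), b=int((~d & m).sum()),
        c=int((d & ~m).sum()), d=int((~d & ~m).sum()))


# -------------------------------------------------------------- statistics

def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple:
    """Clopper--Pearson exact interval."""
    ci = stats.binomtest(k, n).proportion_ci(
        confidence_level=conf, method="exact")
    return float(ci.low), float(ci.high)


def cogain_fraction(table: pd.DataFrame, event: str = "gain") -> dict:
    """Percentage of defense-event branches that also carry the matching MGE
    event, with a 95% Clopper--Pearson CI (all on the percent scale)."""
    d = table[f"def_{event}"].to_numpy(dtype=bool)
    m = table[f"mge_{event}"].to_numpy(dtype=bool)
    n = int(d.sum())
    if n == 0:
        raise ValueError(f"no defense {event} events; fraction undefined")
    k = int((d & m).sum())
    lo, hi = _binom_ci(k, n)
    return {"percent": 100.0 * k / n, "ci_low": 100.0 * lo,
            "ci_high": 100.0 * hi, "k": k, "n": n}


def independence_expectation(table: pd.DataFrame, event: str = "gain",
                             weighting: str = "length") -> float:
    """Expected co-event percentage if defense events were placed
    independently of MGE events -- proportionally to branch length
    (default) or uniformly over branches."""
    m = table[f"mge_{event}"].to_numpy(dtype=bool)
    if weighting == "length":
        w = table["branch_length"].to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            raise ValueError("zero total branch length")
        return 100.0 * float(w[m].sum() / total)
    if weighting == "count":
        return 100.0 * float(m.mean())
    raise ValueError("weighting must be 'length' or 'count'")


def binomial_deviation_test(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value for observing k of n at null p0."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(stats.binomtest(k, n, p0, alternative="two-sided").pvalue)


def conditional_probabilities(table: pd.DataFrame, event: str = "gain") -> dict:
    """P(defense event | MGE event) and P(defense event | no MGE event)
    per branch, each with a 95% exact binomial CI."""
    t = contingency(table, event)
    out = {}
    for key, k, n in (("given_mge", t.a, t.a + t.b),
                      ("given_no_mge", t.c, t.c + t.d)):
        if n == 0:
            out[key] = {"p": float("nan"), "ci_low": float("nan"),
                        "ci_high": float("nan"), "n": 0}
            continue
        lo, hi = _binom_ci(k, n)
        out[key] = {"p": k / n, "ci_low": lo, "ci_high": hi, "n": n}
    return out


def risk_ratio(table_or_counts, event: str = "gain") -> dict:
    """Risk ratio of a defense event on MGE-event vs other branches.

    ``RR = [a/(a+b)] / [c/(c+d)]``; 95% CI by the log method with the
    standard error ``sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))``.  A zero
    unexposed risk (c = 0) yields an infinite RR flagged without a CI.
    """
    t = (table_or_counts if isinstance(table_or_counts, Contingency2x2)
         else contingency(table_or_counts, event))
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("empty exposure margin")
    p1 = t.a / (t.a + t.b)
    if t.c == 0:
        return {"rr": float("inf"), "ci_low": float("nan"),
                "ci_high": float("nan"), "finite": False}
    p0 = t.c / (t.c + t.d)
    rr = p1 / p0
    if t.a == 0:
        return {"rr": 0.0, "ci_low": float("nan"), "ci_high": float("nan"),
                "finite": False}
    se = np.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return {
        "rr": rr,
        "ci_low": float(np.exp(np.log(rr) - 1.96 * se)),
        "ci_high": float(np.exp(np.log(rr) + 1.96 * se)),
        "finite": True,
    }


def fisher_exact(table_or_counts, event: str = "gain") -> float:
    """Two-sided Fisher exact p for the branch-level 2x2 table."""
    t = (table_or_counts if isinstance(table_or_counts, Contingency2x2)
         else contingency(table_or_counts, event))
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def split_by_branch_type(table: pd.DataFrame) -> dict:
    """The same statistics recomputed on terminal-only and internal-only
    branch subsets; subsets without defense events are skipped."""
    out = {}
    for name, sub in (("terminal", table[table["is_terminal"]]),
                      ("internal", table[~table["is_terminal"]])):
        out[name] = linkage_report(sub) if len(sub) else None
    return out


def linkage_report(table: pd.DataFrame) -> pd.DataFrame:
    """Fig-4-style summary per event type: co-event %, expectation,
    conditionals, RR and test p-values."""
    rows = []
    for event in ("gain", "loss"):
        t = contingency(table, event)
        row = {"event": event, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
        n_def = t.a + t.c
        if n_def > 0:
            frac = cogain_fraction(table, event)
            row.update({"co_percent": frac["percent"],
                        "co_ci_low": frac["ci_low"],
                        "co_ci_high": frac["ci_high"]})
            exp = independence_expectation(table, event)
            row["expected_percent"] = exp
            if 0 < exp < 100:
                row["binomial_p"] = binomial_deviation_test(
                    frac["k"], frac["n"], exp / 100.0)
            cond = conditional_probabilities(table, event)
            row["p_def_given_mge"] = cond["given_mge"]["p"]
            row["p_def_given_no_mge"] = cond["given_no_mge"]["p"]
            if t.a + t.b > 0 and t.c + t.d > 0:
                rr = risk_ratio(t)
                row.update({"rr": rr["rr"], "rr_ci_low": rr["ci_low"],
                            "rr_ci_high": rr["ci_high"]})
            row["fisher_p"] = fisher_exact(t)
        rows.append(row)
    return pd.DataFrame(rows)
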