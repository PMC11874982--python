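"""Effect sizes and the two-criterion association classification.

Fitted coefficients are converted to effect sizes on the multiplicative
scale, ``ES = exp(beta) - 1`` (relative difference in expected counts under
the log link).  Associations are classified twice: by raw significance
(P < 0.05) and by the smallest significant effect size (SSES) criterion --
the minimal |ES| reaching P < 0.05 within each (response, system) group,
applied as a strict threshold ``|ES| > SSES``.  No multiple-testing
correction is applied in either criterion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["effect_size", "compute_sses", "classify", "summarize"]

P_THRESHOLD = 0.05


def effect_size(beta: float) -> float:
    """Relative difference in expected counts: ``exp(beta) - 1``."""
    return float(np.exp(beta) - 1.0)


def raw_effect_size(y, x) -> float:
    """Optional alternative: difference of group means over the baseline."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    base = y[x == 0].mean()
    return (y[x == 1].mean() - base) / base


def compute_sses(results: pd.DataFrame) -> float:
    """Smallest |effect size| reaching P < 0.05 in a (response, system) group.

    Returns NaN when no result in the group is significant (the group is
    then unclassifiable under the SSES criterion).
    """
    if "effect_size" not in results:
        results = results.assign(effect_size=np.exp(results["beta"]) - 1)
    sig = results.loc[results["p"] < P_THRESHOLD, "effect_size"]
    if sig.empty:
        return float("nan")
    return float(sig.abs().min())


def _sign_class(es: float) -> str:
    return "positive" if es > 0 else ("negative" if es < 0 else "null")


def classify(results: pd.DataFrame, sses: float | None = None) -> pd.DataFrame:
    """Attach both classifications to a group of per-species results.

    ``class_p`` is the sign of the effect when P < 0.05, else null;
    ``class_sses`` is the sign when |ES| strictly exceeds the group SSES
    (ties and undefined SSES classify as null).
    """
    out = results.copy()
    if "effect_size" not in out:
        out["effect_size"] = np.exp(out["beta"]) - 1
    if sses is None:
        sses = compute_sses(out)
    out["sses"] = sses
    out["class_p"] = [
        _sign_class(es) if p < P_THRESHOLD else "null"
        for es, p in zip(out["effect_size"], out["p"])
    ]
    if np.isnan(sses):
        out["class_sses"] = "null"
    else:
        out["class_sses"] = [
            _sign_class(es) if abs(es) > sses else "null"
            for es in out["effect_size"]
        ]
    return out


def classify_battery(results: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`classify` separately per (response, system) group."""
    parts = [classify(grp) for _, grp in
             results.groupby(["response", "system"], sort=False)]
    return pd.concat(parts, ignore_index=True)


def summarize(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts of positive/negative species per criterion and their ratio."""
    rows = []
    for (resp, syst), grp in classified.groupby(["response", "system"]):
        row = {"response": resp, "system": syst}
        for crit in ("class_p", "class_sses"):
            pos = int((grp[crit] == "positive").sum())
            neg = int((grp[crit] == "negative").sum())
            tag = crit.replace("class_", "")
            row[f"n_positive_{tag}"] = pos
            row[f"n_negative_{tag}"] = neg
            row[f"ratio_{tag}"] = pos / neg if neg else float("inf")
        rows.append(row)
    return pd.DataFrame(rows)
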