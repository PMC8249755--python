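"""Clinical and behavioral statistics.

Montgomery-Asberg Depression Rating Scale (MADRS) drug effect as a
difference-in-differences of pre/post means across the ketamine and
placebo sessions; dot-probe reaction-time bias (congruent minus
incongruent); and exploratory Pearson correlations between
ketamine-induced parameter changes and MADRS improvement, reported at an
uncorrected p < 0.05 with a Benjamini-Hochberg column for transparency.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["madrs_drug_effect", "rt_bias", "param_madrs_correlation",
           "correlation_table"]


def madrs_drug_effect(table: pd.DataFrame) -> float:
    """Difference-in-differences drug effect in MADRS points.

    (mean pre - mean post | ketamine) - (mean pre - mean post | placebo);
    positive values mean a greater symptom reduction under ketamine.
    ``table`` needs columns subject_id, session in {ketamine, placebo},
    timepoint_min in {-60, 230}, madrs; every included subject must have
    all four cells.
    """
    req = {"subject_id", "session", "timepoint_min", "madrs"}
    missing_cols = req - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    cells = table.pivot_table(index="subject_id", columns=["session",
                                                           "timepoint_min"],
                              values="madrs", aggfunc="mean")
    want = [("ketamine", -60), ("ketamine", 230),
            ("placebo", -60), ("placebo", 230)]
    for cell in want:
        if cell not in cells.columns:
            raise ValueError(f"no rows for session/timepoint {cell}")
    bad = cells[want].isna().any(axis=1)
    if bad.any():
        raise ValueError("incomplete MADRS cells for subjects: "
                         f"{sorted(cells.index[bad])}")
    ket = cells[("ketamine", -60)].mean() - cells[("ketamine", 230)].mean()
    plc = cells[("placebo", -60)].mean() - cells[("placebo", 230)].mean()
    return float(ket - plc)


def rt_bias(behavior: pd.DataFrame, correct_only: bool = True) -> pd.DataFrame:
    """Reaction-time bias per subject x session x emotion (ms).

    mean RT(congruent) - mean RT(incongruent); negative values indicate
    that attention drawn to the emotional face speeds congruent responses.
    Computed on correct trials by default. Cells with no trials on one
    side yield NaN with a warning.
    """
    req = {"subject_id", "session", "emotion", "congruency", "rt_ms"}
    missing = req - set(behavior.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = behavior
    if correct_only and "correct" in df.columns:
        df = df[df["correct"]]
    means = df.pivot_table(index=["subject_id", "session", "emotion"],
                           columns="congruency", values="rt_ms",
                           aggfunc="mean")
    for side in ("congruent", "incongruent"):
        if side not in means.columns:
            means[side] = np.nan
    out = (means["congruent"] - means["incongruent"]).rename("rt_bias_ms")
    if out.isna().any():
        warnings.warn("empty congruency cells produced missing RT bias values",
                      UserWarning, stacklevel=2)
    return out.reset_index()


def param_madrs_correlation(param_change, madrs_change) -> dict:
    """Pearson correlation between paired per-subject changes.

    Both inputs follow the baseline-minus-ketamine (parameters) and
    baseline-minus-post (MADRS) sign convention, so a positive r links a
    post-ketamine parameter decrease with symptom improvement. Returns
    r, the two-sided t-based p, n, and an uncorrected p < 0.05 flag.
    """
    x = np.asarray(param_change, dtype=float)
    y = np.asarray(madrs_change, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must be paired by subject")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size),
            "significant_unc": bool(p < 0.05)}


def correlation_table(changes: pd.DataFrame, madrs_change: pd.Series
                      ) -> pd.DataFrame:
    """Correlate each parameter-change column with the MADRS change.

    Emits r, uncorrected p, the p < 0.05 flag, and Benjamini-Hochberg
    adjusted q-values across the tested parameters.
    """
    rows = []
    common = changes.index.intersection(madrs_change.index)
    for col in changes.columns:
        res = param_madrs_correlation(changes.loc[common, col],
                                      madrs_change.loc[common])
        rows.append({"parameter": col, **res})
    df = pd.DataFrame(rows)
    m = len(df)
    order = np.argsort(df["p"].to_numpy())
    q = np.empty(m)
    prev = 1.0
    for rank_from_last, i in enumerate(order[::-1]):
        k = m - rank_from_last
        prev = min(prev, df["p"].iloc[i] * m / k)
        q[i] = prev
    df["q_bh"] = q
    return df
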