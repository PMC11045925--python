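"""Import/export calling from Xenopus oocyte pool measurements.

Each measurement is one LC-MS response for a pooled extract of several
oocytes expressing a candidate transporter (or GFP alone as control).
Responses are first normalized per oocyte so pools of different sizes are
comparable, replicate outliers are removed by the interquartile rule, and
each transporter x compound condition is compared to the GFP control with
a two-sided Student's t-test on the per-oocyte values. A significant
positive log2 fold change is import; a significant negative shift is
export, but only interpretable when the control shows endogenous
background uptake — without background there is nothing for an exporter
to deplete, so the call is indeterminate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import flag_outliers_iqr, one_sample_t, p_to_stars, two_sample_t

__all__ = [
    "OocyteMeasurement",
    "UptakeCall",
    "normalize_per_oocyte",
    "remove_outliers_iqr",
    "compare_to_control",
    "call_direction",
    "detect_control_background",
    "call_uptake",
]

GFP_CONTROL = "GFP_control"


@dataclass(frozen=True)
class OocyteMeasurement:
    """One pooled-extract response for one transporter x compound condition."""

    transporter: str
    compound: str
    pool_id: str
    n_oocytes: int
    response: float

    def validate(self) -> None:
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if not np.isfinite(self.response) or self.response < 0:
            raise ValueError("response must be finite and non-negative")


@dataclass
class UptakeCall:
    transporter: str
    compound: str
    n_used: int
    n_outliers_removed: int
    log2fc_vs_control: float
    p_value: float
    direction: str  # import | export | none | indeterminate
    significance_stars: str


def normalize_per_oocyte(measurement: OocyteMeasurement | pd.DataFrame):
    """Response divided by pool size — the common per-oocyte scale.

    Accepts a single measurement (returns a float) or a measurement frame
    (returns the frame with a ``per_oocyte`` column). Pools of different
    sizes within a condition thereby contribute on an equal footing: the
    condition mean is the mean of per-oocyte values, not of raw responses.
    """
    if isinstance(measurement, pd.DataFrame):
        n = measurement["n_oocytes"].to_numpy(dtype=float)
        if (n < 1).any():
            raise ValueError("n_oocytes must be >= 1")
        out = measurement.copy()
        out["per_oocyte"] = measurement["response"].to_numpy(dtype=float) / n
        return out
    measurement.validate()
    return measurement.response / measurement.n_oocytes


def remove_outliers_iqr(values, k: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Split values into (kept, flagged) by the Tukey fence rule.

    Fewer than four values are never flagged — quartiles below that are
    meaningless. Statistics downstream are recomputed on the kept values.
    """
    x = np.asarray(values, dtype=float)
    mask = flag_outliers_iqr(x, k=k)
    return x[~mask], x[mask]


def _pseudocount(*groups) -> float:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    positive = pooled[pooled > 0]
    return float(positive.min() / 2.0) if positive.size else 1.0


def compare_to_control(
    transporter_vals, control_vals, alpha: float = 0.05, equal_var: bool = True
) -> tuple[float, float]:
    """log2 fold change of group means and two-sided t-test p-value.

    A zero group mean triggers the screen's pseudo-count rule (half the
    smallest positive value across both groups added to both means) so the
    fold change stays finite.
    """
    t_vals = np.asarray(transporter_vals, dtype=float)
    c_vals = np.asarray(control_vals, dtype=float)
    if t_vals.size < 2 or c_vals.size < 2:
        raise ValueError("need >=2 values per group after outlier removal")
    mt, mc = t_vals.mean(), c_vals.mean()
    if mt == 0.0 and mc == 0.0:
        log2fc = 0.0
    elif mt == 0.0 or mc == 0.0:
        eps = _pseudocount(t_vals, c_vals)
        log2fc = float(np.log2((mt + eps) / (mc + eps)))
    else:
        log2fc = float(np.log2(mt / mc))
    _, p = two_sample_t(t_vals, c_vals, equal_var=equal_var, alternative="two-sided")
    return log2fc, p


def call_direction(
    log2fc: float, p_value: float, alpha: float = 0.05, control_background: bool = True
) -> str:
    """Map (log2FC, p) to an activity call.

    Non-significant -> none. Significant positive -> import. Significant
    negative -> export when the control carries endogenous background,
    otherwise indeterminate: with empty control oocytes only no-activity or
    import is detectable.
    """
    if not (np.isfinite(log2fc) and np.isfinite(p_value)):
        return "indeterminate"
    if p_value > alpha:
        return "none"
    if log2fc > 0:
        return "import"
    if log2fc < 0:
        return "export" if control_background else "indeterminate"
    return "none"


def detect_control_background(
    control_vals, blank_level: float = 0.0, alpha: float = 0.05
) -> bool:
    """True when control oocytes show consistent signal above the blank.

    One-sided one-sample t-test of the per-oocyte control values against
    ``blank_level``; an all-equal set strictly above the blank counts as
    background. A single control value cannot establish background and is
    treated as no-background with a warning.
    """
    x = np.asarray(control_vals, dtype=float)
    if x.size == 0:
        return False
    if x.size == 1:
        warnings.warn("single control value: background indeterminate, treated as absent")
        return False
    _, p = one_sample_t(x, blank_level, alternative="greater")
    return bool(p <= alpha and x.mean() > blank_level)


def call_uptake(
    measurements: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
    iqr_k: float = 1.5,
    bh: bool = False,
    blank_level: float = 0.0,
    control_label: str = GFP_CONTROL,
) -> pd.DataFrame:
    """Call import/export/none for every transporter x compound condition.

    ``measurements`` is the long frame with columns ``transporter, compound,
    pool_id, n_oocytes, response``. Per compound the GFP control pools give
    the reference distribution and the endogenous-background flag; each
    transporter's pools are normalized per oocyte, outlier-trimmed and
    tested against the control. ``bh=True`` applies Benjamini-Hochberg
    across the whole grid before calling directions (off by default: the
    assay reports per-comparison tests).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    norm = normalize_per_oocyte(measurements)
    records = []
    for compound, sub in norm.groupby("compound", sort=False):
        ctrl_raw = sub.loc[sub["transporter"] == control_label, "per_oocyte"].to_numpy()
        ctrl_kept, ctrl_flagged = (
            remove_outliers_iqr(ctrl_raw, k=iqr_k) if ctrl_raw.size else (ctrl_raw, ctrl_raw)
        )
        background = detect_control_background(ctrl_kept, blank_level, alpha)
        for transporter, cond in sub.groupby("transporter", sort=False):
            if transporter == control_label:
                continue
            vals = cond["per_oocyte"].to_numpy()
            kept, flagged = remove_outliers_iqr(vals, k=iqr_k)
            rec = dict(
                transporter=transporter, compound=compound,
                n_used=int(kept.size), n_outliers_removed=int(flagged.size),
                control_background=bool(background),
            )
            if kept.size < 2 or ctrl_kept.size < 2:
                rec.update(log2fc_vs_control=np.nan, p_value=np.nan,
                           direction="indeterminate", significance_stars="ns")
            else:
                log2fc, p = compare_to_control(kept, ctrl_kept, alpha, equal_var)
                rec.update(log2fc_vs_control=log2fc, p_value=p)
            records.append(rec)
    calls = pd.DataFrame.from_records(records)
    if calls.empty:
        return calls

    p_for_calls = calls.get("p_value", pd.Series(dtype=float)).copy()
    if bh:
        from statsmodels.stats.multitest import multipletests

        ok = p_for_calls.notna()
        if ok.any():
            _, adj, _, _ = multipletests(p_for_calls[ok], method="fdr_bh")
            p_for_calls.loc[ok] = adj
        calls["p_adjusted"] = p_for_calls

    directions, stars = [], []
    for i, row in calls.iterrows():
        if "direction" in row and isinstance(row.get("direction"), str) and pd.isna(row["p_value"]):
            directions.append("indeterminate")
            stars.append("ns")
            continue
        p_eff = float(p_for_calls.loc[i])
        directions.append(call_direction(row["log2fc_vs_control"], p_eff, alpha,
                                         row["control_background"]))
        stars.append(p_to_stars(p_eff))
    calls["direction"] = directions
    calls["significance_stars"] = stars
    return calls
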