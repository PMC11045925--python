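"""Exometabolome differential screen.

Compares compound levels in spent medium (cells incubated in serum, then
removed) against the untreated serum control. Per compound the screen
computes a log2 fold change of treated over control group means and the
per-group coefficient of variation, then applies a dual threshold —
|log2FC| above a fold-change cutoff and both group CVs below a
reproducibility cutoff — to call each compound consumed (level drops),
secreted (level rises) or unchanged.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import coefficient_of_variation

__all__ = [
    "ResponseTable",
    "compute_log2fc_cv",
    "classify_direction",
    "summarize_screen",
]

VALID_GROUPS = ("control", "treated")
VALID_CLASSES = ("metabolite", "drug", "unknown")


@dataclass
class ResponseTable:
    """Compound x sample measurement matrix with group/replicate metadata.

    Attributes
    ----------
    compounds : DataFrame with columns ``compound_id``, ``name``, ``class``.
    samples : DataFrame with columns ``sample_id``, ``group``, ``replicate``.
    values : DataFrame of non-negative responses, indexed by ``compound_id``
        with one column per ``sample_id``.
    """

    compounds: pd.DataFrame
    samples: pd.DataFrame
    values: pd.DataFrame

    def validate(self) -> None:
        if not set(self.samples["group"]).issubset(VALID_GROUPS):
            raise ValueError(f"sample groups must be in {VALID_GROUPS}")
        counts = self.samples.groupby("group").size()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need >=2 replicates in each of control and treated")
        if self.values.columns.duplicated().any() or self.values.index.duplicated().any():
            raise ValueError("duplicate compound or sample identifiers")
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("responses must be finite and non-negative")
        missing = set(self.samples["sample_id"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples without value columns: {sorted(missing)}")

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.loc[self.samples["group"] == group, "sample_id"])

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame: compound_id, class, sample_id, group, replicate, response."""
        long = (
            self.values.reset_index(names="compound_id")
            .melt(id_vars="compound_id", var_name="sample_id", value_name="response")
        )
        long = long.merge(self.samples, on="sample_id").merge(
            self.compounds[["compound_id", "class"]], on="compound_id"
        )
        return long[["compound_id", "class", "sample_id", "group", "replicate", "response"]]

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, mapping: dict[str, str] | None = None) -> "ResponseTable":
        """Build a table from a long-format frame.

        ``mapping`` renames user columns onto the canonical schema, e.g.
        ``{"peak_area": "response"}``.
        """
        if mapping:
            df = df.rename(columns=mapping)
        required = {"compound_id", "sample_id", "group", "response"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        if "class" not in df.columns:
            df = df.assign(**{"class": "unknown"})
        if "replicate" not in df.columns:
            df = df.assign(replicate=df.groupby(["compound_id", "group"]).cumcount() + 1)
        if df.duplicated(subset=["compound_id", "sample_id"]).any():
            raise ValueError("duplicate (compound, sample) cells")
        values = df.pivot(index="compound_id", columns="sample_id", values="response")
        samples = df[["sample_id", "group", "replicate"]].drop_duplicates("sample_id")
        compounds = (
            df[["compound_id", "class"]]
            .drop_duplicates("compound_id")
            .assign(name=lambda d: d["compound_id"])
        )[["compound_id", "name", "class"]]
        table = cls(compounds=compounds.reset_index(drop=True),
                    samples=samples.reset_index(drop=True),
                    values=values)
        table.validate()
        return table


def _auto_pseudocount(values: pd.DataFrame) -> float:
    v = values.to_numpy(dtype=float)
    positive = v[v > 0]
    if positive.size == 0:
        return 1.0
    return float(positive.min() / 2.0)


def compute_log2fc_cv(table: ResponseTable, pseudo: float | str = "auto") -> pd.DataFrame:
    """Per-compound log2 fold change (treated/control) and per-group CV.

    The pseudo-count is added to *both* group means only when one of them is
    zero, so finite fold changes exist without perturbing compounds that were
    measured cleanly. ``pseudo="auto"`` uses half the smallest positive
    response in the whole table. Compounds with all-zero responses in both
    groups are flagged not evaluable (``evaluable=False``) and carry NaN
    statistics.
    """
    table.validate()
    if pseudo == "auto":
        pseudo_val = _auto_pseudocount(table.values)
    else:
        pseudo_val = float(pseudo)
        if pseudo_val <= 0:
            raise ValueError("pseudo-count must be positive")

    ctrl_cols = table.group_columns("control")
    trt_cols = table.group_columns("treated")
    records = []
    for cid, row in table.values.iterrows():
        c = row[ctrl_cols].to_numpy(dtype=float)
        t = row[trt_cols].to_numpy(dtype=float)
        mc, mt = c.mean(), t.mean()
        if mc == 0.0 and mt == 0.0 and c.max() == 0.0 and t.max() == 0.0:
            records.append(
                dict(compound_id=cid, mean_control=0.0, mean_treated=0.0,
                     log2fc=np.nan, cv_control=np.nan, cv_treated=np.nan,
                     evaluable=False)
            )
            continue
        if mc == 0.0 or mt == 0.0:
            log2fc = float(np.log2((mt + pseudo_val) / (mc + pseudo_val)))
        else:
            log2fc = float(np.log2(mt / mc))
        records.append(
            dict(compound_id=cid, mean_control=mc, mean_treated=mt,
                 log2fc=log2fc,
                 cv_control=coefficient_of_variation(c),
                 cv_treated=coefficient_of_variation(t),
                 evaluable=True)
        )
    return pd.DataFrame.from_records(records)


def classify_direction(
    stats: pd.DataFrame, fc_threshold: float = 0.5, cv_threshold: float = 30.0
) -> pd.DataFrame:
    """Apply the dual-threshold filter and assign a direction per compound.

    A compound passes when |log2FC| exceeds ``fc_threshold`` and the larger
    of the two group CVs is below ``cv_threshold`` (percent). Passing
    compounds with negative log2FC are consumed, positive are secreted;
    everything else (including not-evaluable compounds) is unchanged.
    """
    if fc_threshold <= 0 or cv_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = stats.copy()
    cv_max = out[["cv_control", "cv_treated"]].max(axis=1)
    passes = (
        out["evaluable"]
        & (out["log2fc"].abs() > fc_threshold)
        & (cv_max < cv_threshold)
    )
    direction = np.where(
        passes & (out["log2fc"] < 0), "consumed",
        np.where(passes & (out["log2fc"] > 0), "secreted", "unchanged"),
    )
    out["passes_filter"] = passes.to_numpy()
    out["direction"] = direction
    return out


def summarize_screen(
    results: pd.DataFrame, compound_classes: pd.DataFrame | None = None
) -> dict:
    """Partition counts overall and per compound class.

    ``compound_classes`` maps ``compound_id`` to ``class``; unknown labels
    are bucketed under ``unknown`` with a warning. The three direction
    counts always sum to the number of compounds.
    """
    counts = results["direction"].value_counts().to_dict()
    summary = {
        "n_compounds": int(len(results)),
        "consumed": int(counts.get("consumed", 0)),
        "secreted": int(counts.get("secreted", 0)),
        "unchanged": int(counts.get("unchanged", 0)),
    }
    if compound_classes is not None:
        merged = results.merge(
            compound_classes[["compound_id", "class"]], on="compound_id", how="left"
        )
        bad = ~merged["class"].isin(VALID_CLASSES) | merged["class"].isna()
        if bad.any():
            warnings.warn("unknown compound class labels bucketed as 'unknown'")
            merged.loc[bad, "class"] = "unknown"
        by_class: dict[str, dict[str, int]] = {}
        for cls_name, sub in merged.groupby("class"):
            sub_counts = sub["direction"].value_counts().to_dict()
            by_class[str(cls_name)] = {
                d: int(sub_counts.get(d, 0)) for d in ("consumed", "secreted", "unchanged")
            }
        summary["by_class"] = by_class
    return summary
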