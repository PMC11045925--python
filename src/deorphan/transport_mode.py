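"""Concentrative vs equilibrative classification of significant importers.

An importer is concentrative when the intracellular concentration it
reaches exceeds the (assumed constant) medium concentration — evidence of
energy coupling — and equilibrative otherwise. The test is a one-sided
one-sample Student's t-test of the replicate intracellular concentrations
against the medium. When control oocytes themselves accumulate the
compound above the medium (endogenous uptake), the raw call is biased;
a background-corrected call based on replicate-wise differences from the
GFP control is reported alongside the raw one.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import one_sample_t, p_to_stars
from .oocyte_uptake import GFP_CONTROL, normalize_per_oocyte, remove_outliers_iqr

__all__ = [
    "AssayConstants",
    "ModeCall",
    "amount_to_concentration",
    "compare_to_medium",
    "classify_mode",
    "background_correct",
    "call_modes",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AssayConstants:
    """Conversion constants from per-oocyte amount to concentration.

    With unity calibration (``response_per_mM = 1``) only ratios of
    concentrations are meaningful, which is all the mode call needs.
    """

    c_medium_mM: float = 2.0
    oocyte_volume_uL: float = 1.0
    response_per_mM: float = 1.0

    def validate(self) -> None:
        if min(self.c_medium_mM, self.oocyte_volume_uL, self.response_per_mM) <= 0:
            raise ValueError("assay constants must be strictly positive")


@dataclass
class ModeCall:
    transporter: str
    compound: str
    c_in_mM: float
    log2fc_vs_medium: float
    p_one_sided: float
    mode: str  # concentrative | equilibrative | NA
    background_biased: bool
    mode_after_correction: str


def amount_to_concentration(per_oocyte_amount, constants: AssayConstants):
    """Per-oocyte amount -> intracellular concentration (mM)."""
    constants.validate()
    amount = np.asarray(per_oocyte_amount, dtype=float)
    if (amount < 0).any():
        raise ValueError("amounts must be non-negative")
    c = amount / (constants.response_per_mM * constants.oocyte_volume_uL)
    return float(c) if c.ndim == 0 else c


def compare_to_medium(c_in_values, c_medium: float = 2.0) -> tuple[float, float]:
    """log2(mean c_in / c_medium) and one-sided p for c_in > c_medium.

    The medium concentration is treated as a constant: the compound is in
    excess and the medium volume dwarfs the oocytes. All-zero intracellular
    values give a -inf log2FC sentinel with p = 1.
    """
    x = np.asarray(c_in_values, dtype=float)
    if x.size < 2:
        raise ValueError("need >=2 replicate concentrations")
    if c_medium <= 0:
        raise ValueError("c_medium must be positive")
    m = x.mean()
    if m == 0.0:
        return NEG_INF, 1.0
    log2fc = float(np.log2(m / c_medium))
    _, p = one_sample_t(x, c_medium, alternative="greater")
    return log2fc, p


def classify_mode(log2fc: float, p_one_sided: float, alpha: float = 0.05) -> str:
    """Concentrative iff the excess over the medium is positive and significant."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if log2fc > 0 and p_one_sided <= alpha:
        return "concentrative"
    return "equilibrative"


def background_correct(
    c_in_transporter, c_in_gfp, c_medium: float = 2.0, alpha: float = 0.05
) -> tuple[float, str, bool]:
    """Subtract the endogenous control uptake and re-classify.

    Returns ``(corrected_log2fc, mode_after_correction, background_biased)``.
    ``background_biased`` records whether the GFP control on its own tests
    significantly above the medium. The corrected concentration is
    ``max(mean_T - mean_GFP, 0)``; the significance of the corrected excess
    uses replicate-wise differences (pairing pools by order) so the control
    spread propagates into the test.
    """
    t = np.asarray(c_in_transporter, dtype=float)
    g = np.asarray(c_in_gfp, dtype=float)
    if g.size == 0:
        warnings.warn("no GFP control concentrations: correction skipped")
        log2fc, p = compare_to_medium(t, c_medium)
        return log2fc, classify_mode(log2fc, p, alpha), False

    if g.size >= 2 and g.mean() > 0:
        g_fc, g_p = compare_to_medium(g, c_medium)
        biased = g_fc > 0 and g_p <= alpha
    else:
        biased = False

    corrected_mean = max(t.mean() - g.mean(), 0.0)
    if corrected_mean == 0.0:
        return NEG_INF, "equilibrative", biased

    n = min(t.size, g.size)
    diffs = np.sort(t)[:n] - np.sort(g)[:n] if n >= 2 else t - g.mean()
    if diffs.size < 2:
        diffs = t - g.mean()
    _, p = one_sample_t(diffs, c_medium, alternative="greater")
    log2fc = float(np.log2(corrected_mean / c_medium))
    return log2fc, classify_mode(log2fc, p, alpha), biased


def call_modes(
    measurements: pd.DataFrame,
    uptake_calls: pd.DataFrame,
    constants: AssayConstants | None = None,
    alpha: float = 0.05,
    iqr_k: float = 1.5,
    control_label: str = GFP_CONTROL,
) -> pd.DataFrame:
    """Mode calls for every condition called ``import`` by the uptake stage.

    Conditions with other directions are carried through with mode NA so the
    report stays complete. Raw and background-corrected calls are always
    reported side by side.
    """
    constants = constants or AssayConstants()
    constants.validate()
    norm = normalize_per_oocyte(measurements)
    norm["c_in_mM"] = amount_to_concentration(norm["per_oocyte"].to_numpy(), constants)

    gfp_by_compound: dict[str, np.ndarray] = {}
    for compound, sub in norm[norm["transporter"] == control_label].groupby("compound"):
        kept, _ = remove_outliers_iqr(sub["c_in_mM"].to_numpy(), k=iqr_k)
        gfp_by_compound[compound] = kept

    records = []
    for _, call in uptake_calls.iterrows():
        transporter, compound = call["transporter"], call["compound"]
        cond = norm[(norm["transporter"] == transporter) & (norm["compound"] == compound)]
        kept, _ = remove_outliers_iqr(cond["c_in_mM"].to_numpy(), k=iqr_k) \
            if len(cond) else (np.array([]), np.array([]))
        rec = dict(transporter=transporter, compound=compound,
                   direction=call["direction"])
        if call["direction"] != "import" or kept.size < 2:
            rec.update(c_in_mM=float(kept.mean()) if kept.size else np.nan,
                       log2fc_vs_medium=np.nan, p_one_sided=np.nan, mode="NA",
                       background_biased=False, mode_after_correction="NA",
                       significance_stars="ns")
            records.append(rec)
            continue
        log2fc, p = compare_to_medium(kept, constants.c_medium_mM)
        mode = classify_mode(log2fc, p, alpha)
        gfp = gfp_by_compound.get(compound, np.array([]))
        corr_fc, corr_mode, biased = background_correct(
            kept, gfp, constants.c_medium_mM, alpha)
        rec.update(c_in_mM=float(kept.mean()), log2fc_vs_medium=log2fc,
                   p_one_sided=p, mode=mode, background_biased=biased,
                   mode_after_correction=corr_mode,
                   corrected_log2fc_vs_medium=corr_fc,
                   significance_stars=p_to_stars(p))
        records.append(rec)
    return pd.DataFrame.from_records(records)
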