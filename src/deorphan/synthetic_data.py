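"""Synthetic data generators with known ground truth.

Three generators emulate the statistical structure of the study's assays:

* a serum exometabolome screen — a mixture of consumed, secreted and
  unchanged compounds measured as lognormal-noisy LC-MS responses in a
  control and a treated group;
* a Xenopus oocyte uptake assay — pools of oocytes incubated with a
  substrate, with saturable importer uptake, endogenous background leak,
  exporter suppression of that background, and multiplicative lognormal
  measurement noise;
* dose-inhibited logistic growth curves with additive Gaussian OD noise.

Every generator returns its data together with a :class:`SimulationTruth`
carrying the per-item ground-truth labels and parameters, so downstream
callers can be tested for recovery.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exo_screen import ResponseTable

__all__ = [
    "SerumSimParams",
    "TransporterTruth",
    "OocyteSimParams",
    "GrowthSimParams",
    "SimulationTruth",
    "simulate_serum_screen",
    "simulate_oocyte_assay",
    "simulate_growth_curves",
    "expected_intracellular_mM",
]

GFP_CONTROL = "GFP_control"


@dataclass
class SimulationTruth:
    """Ground truth emitted by a generator; consumed only by tests/harnesses."""

    kind: str
    table: pd.DataFrame
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "params": self.params,
            "records": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Serum screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SerumSimParams:
    """Mixture design for a synthetic serum screen.

    True effect sizes are drawn uniformly from ``effect_log2fc_range`` (in
    absolute log2 units) and applied with a negative sign for consumed
    compounds and a positive sign for secreted ones. Replicate noise is
    multiplicative lognormal with the given CV; baselines are log-uniform
    over ``baseline_response_range``.
    """

    n_compounds: int = 1000
    frac_consumed: float = 0.2
    frac_secreted: float = 0.15
    effect_log2fc_range: tuple[float, float] = (0.8, 2.0)
    replicate_cv: float = 0.15
    n_replicates_per_group: int = 3
    baseline_response_range: tuple[float, float] = (1e4, 1e7)
    frac_drug: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_consumed", "frac_secreted", "frac_drug"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_consumed + self.frac_secreted > 1.0:
            raise ValueError("frac_consumed + frac_secreted must not exceed 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        lo, hi = self.effect_log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("effect_log2fc_range must be strictly positive and ordered")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")
        blo, bhi = self.baseline_response_range
        if blo <= 0 or bhi < blo:
            raise ValueError("baseline_response_range must be positive and ordered")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")


def simulate_serum_screen(params: SerumSimParams) -> tuple[ResponseTable, SimulationTruth]:
    """Simulate a compound x sample response table with known direction labels.

    The number of consumed/secreted compounds is exactly
    ``round(frac * n_compounds)``; remaining compounds are unchanged
    (true log2FC = 0).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_compounds
    n_cons = int(round(params.frac_consumed * n))
    n_secr = int(round(params.frac_secreted * n))

    classes = np.array(["consumed"] * n_cons + ["secreted"] * n_secr
                       + ["unchanged"] * (n - n_cons - n_secr))
    lo, hi = params.effect_log2fc_range
    effect = np.zeros(n)
    effect[:n_cons] = -rng.uniform(lo, hi, n_cons)
    effect[n_cons:n_cons + n_secr] = rng.uniform(lo, hi, n_secr)

    blo, bhi = params.baseline_response_range
    baseline = np.exp(rng.uniform(np.log(blo), np.log(bhi), n))
    compound_class = np.where(rng.random(n) < params.frac_drug, "drug", "metabolite")

    nrep = params.n_replicates_per_group
    ctrl = baseline[:, None] * _lognormal_factor(rng, params.replicate_cv, (n, nrep))
    trt = (baseline * np.exp2(effect))[:, None] * _lognormal_factor(
        rng, params.replicate_cv, (n, nrep))

    compound_ids = [f"C{i:05d}" for i in range(n)]
    ctrl_ids = [f"control_r{j + 1}" for j in range(nrep)]
    trt_ids = [f"treated_r{j + 1}" for j in range(nrep)]
    values = pd.DataFrame(
        np.hstack([ctrl, trt]), index=pd.Index(compound_ids, name="compound_id"),
        columns=ctrl_ids + trt_ids,
    )
    samples = pd.DataFrame({
        "sample_id": ctrl_ids + trt_ids,
        "group": ["control"] * nrep + ["treated"] * nrep,
        "replicate": list(range(1, nrep + 1)) * 2,
    })
    compounds = pd.DataFrame({
        "compound_id": compound_ids,
        "name": compound_ids,
        "class": compound_class,
    })
    table = ResponseTable(compounds=compounds, samples=samples, values=values)
    truth = SimulationTruth(
        kind="serum_screen",
        table=pd.DataFrame({
            "compound_id": compound_ids,
            "true_class": classes,
            "true_log2fc": effect,
            "baseline": baseline,
        }),
        params=asdict(params),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Oocyte uptake assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransporterTruth:
    """True activity of one transporter toward one compound.

    ``accumulation_ratio_A`` is the asymptotic intracellular-to-medium
    concentration ratio of an importer (A = 1 equilibrative, A > 1
    concentrative); ``rate_k`` its first-order approach rate per hour.
    ``exporter_factor_beta`` in [0, 1] multiplies the endogenous background
    for exporters (export is only measurable against a nonzero background).
    """

    transporter_id: str
    compound_id: str
    activity: str  # importer | exporter | none
    accumulation_ratio_A: float = 1.0
    rate_k: float = 1.0
    exporter_factor_beta: float = 1.0

    def validate(self) -> None:
        if self.activity not in ("importer", "exporter", "none"):
            raise ValueError(f"unknown activity {self.activity!r}")
        if self.activity == "importer":
            if self.accumulation_ratio_A < 1.0:
                raise ValueError("importer requires accumulation ratio A >= 1")
            if self.rate_k <= 0:
                raise ValueError("importer requires rate_k > 0")
        if self.activity == "exporter" and not 0.0 <= self.exporter_factor_beta < 1.0:
            raise ValueError("exporter requires beta in [0, 1)")


@dataclass(frozen=True)
class OocyteSimParams:
    """Assay design constants and noise for the oocyte generator.

    Defaults mirror the wet assay: 2 mM substrate in the medium, 3 h
    incubation, pools of 10 oocytes in triplicate. ``background_ratio`` is
    the endogenous leak expressed as the fraction of the medium
    concentration reached inside control oocytes by assay end.
    """

    c_medium: float = 2.0
    incubation_h: float = 3.0
    oocyte_volume_uL: float = 1.0
    pool_size: int = 10
    n_pools: int = 3
    background_ratio: float = 0.0
    noise_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.c_medium <= 0:
            raise ValueError("c_medium must be positive")
        if self.incubation_h <= 0 or self.oocyte_volume_uL <= 0:
            raise ValueError("incubation time and oocyte volume must be positive")
        if self.pool_size < 1 or self.n_pools < 1:
            raise ValueError("pool_size and n_pools must be >= 1")
        if self.noise_cv < 0 or self.background_ratio < 0:
            raise ValueError("noise_cv and background_ratio must be non-negative")


def expected_intracellular_mM(truth: TransporterTruth, params: OocyteSimParams) -> float:
    """Closed-form expected intracellular concentration for one condition.

    background = background_ratio * c_medium; importers add a saturable
    first-order uptake term A * c_medium * (1 - exp(-k t)); exporters
    deplete the background multiplicatively (beta * background); inactive
    transporters sit at the background.
    """
    background = params.background_ratio * params.c_medium
    if truth.activity == "importer":
        uptake = (truth.accumulation_ratio_A * params.c_medium
                  * -np.expm1(-truth.rate_k * params.incubation_h))
        return float(background + uptake)
    if truth.activity == "exporter":
        return float(truth.exporter_factor_beta * background)
    return float(background)


def importer_for_fold_change(
    transporter_id: str,
    compound_id: str,
    fold: float,
    params: OocyteSimParams,
    rate_k: float = 2.0,
) -> TransporterTruth:
    """Importer whose expected intracellular level is ``fold`` x the background.

    Solves the accumulation ratio A from
    ``fold = (background + A c_med (1 - e^(-k t))) / background``; requires a
    nonzero ``background_ratio``. Convenient for building recovery harnesses
    where truth is expressed as a fold change over the GFP control.
    """
    background = params.background_ratio * params.c_medium
    if background <= 0:
        raise ValueError("fold-change parametrization needs background_ratio > 0")
    if fold <= 1.0:
        raise ValueError("an importer needs fold > 1 over the background")
    sat = -np.expm1(-rate_k * params.incubation_h)
    A = (fold - 1.0) * background / (params.c_medium * sat)
    return TransporterTruth(transporter_id, compound_id, "importer",
                            accumulation_ratio_A=max(A, 1.0), rate_k=rate_k)


def simulate_oocyte_assay(
    truths: list[TransporterTruth], params: OocyteSimParams
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate pooled oocyte LC-MS responses for a set of conditions.

    Returns a long-format measurement frame with columns
    ``transporter, compound, pool_id, n_oocytes, response`` containing
    ``n_pools`` pools per condition. A GFP-only control condition (named
    ``GFP_control``) is always emitted once per distinct compound; its
    expected concentration is the endogenous background. The measured
    response of a pool is ``pool_size * oocyte_volume_uL * C_in`` times a
    mean-one lognormal noise factor.
    """
    params.validate()
    seen = set()
    for t in truths:
        t.validate()
        key = (t.transporter_id, t.compound_id)
        if key in seen:
            raise ValueError(f"duplicate condition {key}")
        if t.transporter_id == GFP_CONTROL:
            raise ValueError("GFP_control is reserved for the emitted control condition")
        seen.add(key)
    rng = np.random.default_rng(params.seed)

    compounds = list(dict.fromkeys(t.compound_id for t in truths))
    conditions: list[tuple[str, str, float]] = []
    background = params.background_ratio * params.c_medium
    for compound in compounds:
        conditions.append((GFP_CONTROL, compound, background))
    for t in truths:
        conditions.append((t.transporter_id, t.compound_id,
                           expected_intracellular_mM(t, params)))

    rows = []
    truth_rows = []
    for transporter, compound, c_in in conditions:
        noise = _lognormal_factor(rng, params.noise_cv, params.n_pools)
        amounts = params.pool_size * params.oocyte_volume_uL * c_in * noise
        for j in range(params.n_pools):
            rows.append(dict(
                transporter=transporter, compound=compound,
                pool_id=f"{transporter}:{compound}:p{j + 1}",
                n_oocytes=params.pool_size, response=float(amounts[j]),
            ))
        truth_rows.append(dict(transporter=transporter, compound=compound,
                               expected_c_in_mM=c_in))
    truth_tbl = pd.DataFrame(truth_rows).merge(
        pd.DataFrame([asdict(t) for t in truths]).rename(
            columns={"transporter_id": "transporter", "compound_id": "compound"}),
        on=["transporter", "compound"], how="left",
    )
    truth_tbl["activity"] = truth_tbl["activity"].fillna("control")
    truth = SimulationTruth(kind="oocyte_assay", table=truth_tbl, params=asdict(params))
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def _default_t_grid() -> tuple[float, ...]:
    # 72 h sampled every 20 min
    return tuple(np.round(np.arange(0.0, 72.0 + 1e-9, 1.0 / 3.0), 6))


@dataclass(frozen=True)
class GrowthSimParams:
    """Logistic growth with Hill-type dose inhibition.

    Both the specific growth rate and the carrying capacity are scaled by
    ``1 / (1 + (c / lc50_true)^hill_h)``, so at ``c = lc50_true`` the
    untreated maximum OD is halved — the LC50 anchors the dose axis.
    """

    mu0: float = 0.4
    K0: float = 1.2
    od0: float = 0.01
    hill_h: float = 2.0
    lc50_true: float = 2.45
    concentrations: tuple[float, ...] = (0.0, 0.6125, 1.225, 2.45, 4.9, 7.35, 9.8)
    t_grid: tuple[float, ...] = field(default_factory=_default_t_grid)
    od_noise_sd: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if not 0 < self.od0 < self.K0:
            raise ValueError("require 0 < od0 < K0")
        if self.lc50_true <= 0:
            raise ValueError("lc50_true must be positive")
        t = np.asarray(self.t_grid)
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("t_grid must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.od_noise_sd < 0:
            raise ValueError("od_noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def logistic_od(t: np.ndarray, mu: float, K: float, od0: float) -> np.ndarray:
    """Closed-form logistic curve K / (1 + ((K - od0)/od0) e^(-mu t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - od0) / od0) * np.exp(-mu * t))


def dose_scaled(value: float, c: float, lc50: float, h: float) -> float:
    """Hill inhibition: value / (1 + (c/lc50)^h)."""
    return float(value / (1.0 + (c / lc50) ** h))


def simulate_growth_curves(params: GrowthSimParams):
    """Simulate replicated growth curves across a concentration series.

    Returns ``(curves, truth)`` where ``curves`` is a list of
    :class:`~deorphan.growth_phenotype.GrowthCurve` and the truth table
    records the dose-scaled mu(c) and K(c) per concentration. Additive
    Gaussian OD noise is truncated at zero.
    """
    from .growth_phenotype import GrowthCurve  # local import avoids a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.t_grid, dtype=float)
    curves: list[GrowthCurve] = []
    truth_rows = []
    for c in params.concentrations:
        mu_c = dose_scaled(params.mu0, c, params.lc50_true, params.hill_h)
        K_c = dose_scaled(params.K0, c, params.lc50_true, params.hill_h)
        clean = logistic_od(t, mu_c, max(K_c, params.od0 * 1.0000001), params.od0)
        for rep in range(1, params.n_replicates + 1):
            od = clean + rng.normal(0.0, params.od_noise_sd, t.size)
            od = np.clip(od, 0.0, None)
            curves.append(GrowthCurve(
                strain="wildtype", condition="dose_series", conc_mM=float(c),
                replicate=f"r{rep}", times_h=t.copy(), od=od,
            ))
        truth_rows.append(dict(conc_mM=float(c), mu=mu_c, K=K_c,
                               lc50_true=params.lc50_true))
    truth = SimulationTruth(kind="growth_curves", table=pd.DataFrame(truth_rows),
                            params={**asdict(params),
                                    "t_grid": list(params.t_grid),
                                    "concentrations": list(params.concentrations)})
    return curves, truth


# ---------------------------------------------------------------------------
# Tidy CSV writers
# ---------------------------------------------------------------------------

def write_serum_csv(table: ResponseTable, path: str | Path) -> None:
    table.to_tidy().to_csv(path, index=False)


def write_oocyte_csv(measurements: pd.DataFrame, path: str | Path) -> None:
    cols = ["transporter", "compound", "pool_id", "n_oocytes", "response"]
    measurements[cols].to_csv(path, index=False)


def write_growth_csv(curves, path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times_h, c.od):
            rows.append(dict(strain=c.strain, condition=c.condition,
                             conc_mM=c.conc_mM, replicate=c.replicate,
                             time_h=float(t), od=float(od)))
    pd.DataFrame(rows).to_csv(path, index=False)
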