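"""Metabolic endpoints and qPCR relative expression.

* OGTT AUC: trapezoidal integral of the glucose–time curve over the measured
  span (mmol/L·min); the incremental AUC above the fasting baseline is also
  emitted since conventions differ.
* HOMA-IR: ``fasting insulin × fasting glucose / 22.5`` (unitless index;
  units of the inputs are taken as given).
* Relative expression: the 2^−ΔΔCt method with ΔCt = Ct_target − Ct_reference
  and ΔΔCt relative to the mean ΔCt of a calibrator group (amplification
  efficiency assumed 100%).
* Group comparison: Student's t-test for two groups, one-way ANOVA with
  Tukey's HSD post hoc test for three or more; summaries as mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import PhenotypeTable


@dataclass
class OgttResult:
    auc: float  # mmol/L·min, total area
    auc_incremental: float  # area above the t=0 baseline (clipped at 0)
    times: np.ndarray
    glucose: np.ndarray
    animal_id: str | None = None


@dataclass
class GroupCompareResult:
    test: str  # "t-test" or "anova+tukey"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    tukey: pd.DataFrame | None = None


def ogtt_auc(times, glucose, animal_id: str | None = None) -> OgttResult:
    """Trapezoidal AUC of a glucose tolerance curve."""
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if t.shape != g.shape or t.ndim != 1:
        raise ValueError("times and glucose must be 1-D and the same length")
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    auc = float(np.trapezoid(g, t))
    incremental = float(np.trapezoid(np.clip(g - g[0], 0.0, None), t))
    return OgttResult(auc, incremental, t, g, animal_id)


def homa_ir(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA insulin-resistance index: insulin × glucose / 22.5."""
    if fasting_insulin < 0 or fasting_glucose < 0:
        raise ValueError("fasting insulin and glucose must be >= 0")
    return float(fasting_insulin * fasting_glucose / 22.5)


def relative_expression(ct_target, ct_reference, groups,
                        calibrator_group: str) -> np.ndarray:
    """Per-sample fold change by 2^−ΔΔCt against a calibrator group."""
    ct_t = np.asarray(ct_target, dtype=float)
    ct_r = np.asarray(ct_reference, dtype=float)
    groups = np.asarray(groups)
    if not (len(ct_t) == len(ct_r) == len(groups)):
        raise ValueError("ct_target, ct_reference and groups length mismatch")
    if not (np.isfinite(ct_t).all() and np.isfinite(ct_r).all()):
        raise ValueError("Ct values must be finite")
    calibrator = groups == calibrator_group
    if not calibrator.any():
        raise ValueError(f"empty calibrator group {calibrator_group!r}")
    delta_ct = ct_t - ct_r
    ddct = delta_ct - delta_ct[calibrator].mean()
    return np.power(2.0, -ddct)


def group_compare(values_by_group: dict[str, np.ndarray]) -> GroupCompareResult:
    """Two groups → Student's t-test; three or more → ANOVA + Tukey HSD."""
    groups = sorted(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g, v in zip(groups, samples):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    means = {g: float(np.mean(v)) for g, v in zip(groups, samples)}
    sems = {g: float(stats.sem(v)) for g, v in zip(groups, samples)}
    if len(groups) == 2:
        t_stat, p = stats.ttest_ind(samples[0], samples[1])
        if not np.isfinite(t_stat):  # identical constant groups
            t_stat, p = 0.0, 1.0
        return GroupCompareResult("t-test", float(t_stat), float(p),
                                  means, sems)
    f_stat, p = stats.f_oneway(*samples)
    if not np.isfinite(f_stat):
        f_stat, p = 0.0, 1.0
    values = np.concatenate(samples)
    labels = np.concatenate([[g] * len(v) for g, v in zip(groups, samples)])
    res = pairwise_tukeyhsd(values, labels)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return GroupCompareResult("anova+tukey", float(f_stat), float(p),
                              means, sems, tukey)


def phenotype_report(table: PhenotypeTable) -> dict:
    """Endpoint computations and group statistics for a phenotype table.

    Returns per-animal AUC and HOMA-IR plus group comparisons for body
    weight, fasting glucose, OGTT AUC, HOMA-IR and relative expression of
    every Ct gene (reference gene Gapdh if present, else the first).
    """
    frame = table.frame
    times, glucose = table.glucose_series()
    auc = np.array([ogtt_auc(times, g).auc for g in glucose])
    homa = np.array([
        homa_ir(i, g0) for i, g0 in
        zip(frame["fasting_insulin"], frame[f"glucose_{int(times[0])}"])
    ])
    per_animal = frame[["animal_id", "group"]].copy()
    per_animal["ogtt_auc"] = auc
    per_animal["homa_ir"] = homa

    groups = frame["group"].to_numpy()

    def by_group(values: np.ndarray) -> dict[str, np.ndarray]:
        return {g: values[groups == g] for g in sorted(set(groups))}

    comparisons = {
        "body_weight": group_compare(
            by_group(frame["body_weight"].to_numpy(float))),
        "fasting_glucose": group_compare(
            by_group(frame[f"glucose_{int(times[0])}"].to_numpy(float))),
        "ogtt_auc": group_compare(by_group(auc)),
        "homa_ir": group_compare(by_group(homa)),
    }

    ct_genes = table.ct_genes()
    expression: dict[str, np.ndarray] = {}
    if ct_genes:
        reference = "Gapdh" if "Gapdh" in ct_genes else ct_genes[0]
        calibrator = sorted(set(groups))[0]
        if "CON" in groups:
            calibrator = "CON"
        for gene in ct_genes:
            if gene == reference:
                continue
            fold = relative_expression(frame[f"ct_{gene}"],
                                       frame[f"ct_{reference}"],
                                       groups, calibrator)
            expression[gene] = fold
            comparisons[f"expression_{gene}"] = group_compare(by_group(fold))
            per_animal[f"fold_{gene}"] = fold
    return {"per_animal": per_animal, "comparisons": comparisons,
            "expression": expression}
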