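"""Bisulfite-clone methylation summaries and between-group comparison.

A clone matrix holds binary methylation calls (clone × CpG site) for one
animal and amplicon.  The methylation ratio is methylated calls over
non-missing calls; the unit of between-group analysis is the animal (its
overall ratio), not the clone, to avoid pseudoreplication.  Groups are
compared per amplicon with one-way ANOVA followed by Tukey's HSD post hoc
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import BisulfiteCloneMatrix


@dataclass
class MethylationSummary:
    animal_id: str
    group: str
    amplicon_id: str
    per_site: np.ndarray  # fraction methylated per CpG position
    overall: float  # methylated / non-missing calls
    n_calls: int

    def __post_init__(self) -> None:
        finite = self.per_site[np.isfinite(self.per_site)]
        if len(finite) and ((finite < 0) | (finite > 1)).any():
            raise ValueError("per-site ratios outside [0, 1]")


@dataclass
class GroupComparison:
    amplicon_id: str
    anova_f: float
    anova_p: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject


def methylation_ratio(matrix: BisulfiteCloneMatrix) -> MethylationSummary:
    """Per-site and overall methylation ratios, missing calls excluded."""
    calls = matrix.calls
    finite = np.isfinite(calls)
    n_calls = int(finite.sum())
    if n_calls == 0:
        raise ValueError(
            f"{matrix.animal_id}/{matrix.amplicon_id}: all calls missing"
        )
    with np.errstate(invalid="ignore"):
        per_site = np.where(finite.sum(axis=0) > 0,
                            np.nansum(calls, axis=0)
                            / np.maximum(finite.sum(axis=0), 1),
                            np.nan)
    overall = float(np.nansum(calls) / n_calls)
    return MethylationSummary(matrix.animal_id, matrix.group,
                              matrix.amplicon_id, per_site, overall, n_calls)


def summaries_frame(summaries: Sequence[MethylationSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "animal_id": s.animal_id, "group": s.group,
        "amplicon_id": s.amplicon_id, "overall_ratio": s.overall,
        "n_calls": s.n_calls,
    } for s in summaries])


def compare_groups_methylation(
    summaries: Sequence[MethylationSummary],
) -> dict[str, GroupComparison]:
    """Per-amplicon one-way ANOVA + Tukey HSD on per-animal overall ratios."""
    frame = summaries_frame(summaries)
    out: dict[str, GroupComparison] = {}
    for amplicon, sub in frame.groupby("amplicon_id", sort=True):
        groups = sorted(sub["group"].unique())
        samples = [sub.loc[sub["group"] == g, "overall_ratio"].to_numpy()
                   for g in groups]
        for g, vals in zip(groups, samples):
            if len(vals) < 2:
                raise ValueError(
                    f"{amplicon}: group {g!r} has fewer than 2 animals"
                )
        if len(groups) < 2:
            raise ValueError(f"{amplicon}: need >= 2 groups")
        f_stat, p = stats.f_oneway(*samples)
        if not np.isfinite(f_stat):  # zero within- and between-group variance
            f_stat, p = 0.0, 1.0
        tukey_res = pairwise_tukeyhsd(
            sub["overall_ratio"].to_numpy(), sub["group"].to_numpy()
        )
        tukey = pd.DataFrame(
            tukey_res.summary().data[1:],
            columns=[str(c) for c in tukey_res.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
        out[str(amplicon)] = GroupComparison(
            amplicon_id=str(amplicon),
            anova_f=float(f_stat), anova_p=float(p),
            group_means={g: float(np.mean(v))
                         for g, v in zip(groups, samples)},
            group_sems={g: float(stats.sem(v))
                        for g, v in zip(groups, samples)},
            tukey=tukey,
        )
    return out
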