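"""The M′ differential statistic, differential peaks and the DEP filter.

M′ is the per-probe difference of group mean log2(MeDIP/Input):
``M′ = mean(treatment replicates) − mean(control replicates)``, so it is
antisymmetric under swapping the group labels.  Differential enrichment
peaks (DEPs) are called by running the windowed scorer and peak finder on M′
(hypermethylated direction) and on −M′ (hypomethylated direction), then
filtered by two reproducibility criteria:

1. at least one group has a median (over member probes) within-group mean
   log2 ratio >= 0.3, and the median M′ over member probes is > 0 in the
   peak's own direction (sign-flipped for hypo peaks, without which no
   hypomethylated region could ever survive);
2. in both groups at least half of the member probes have a coefficient of
   variation <= 0.8, where the CV is taken across replicates on the
   linear-scale ratio ``2**log2ratio`` (the CV of a signed log value is
   ill-defined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import DifferentialPeak, GroupDesign, Peak, ProbeTable
from .peaks import PeakCallParams, _windowed_mwu_scores, find_peaks

HYPER = "hyper"
HYPO = "hypo"


@dataclass
class DepFilterParams:
    median_ratio_min: float = 0.3
    cv_max: float = 0.8
    cv_pass_fraction_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_pass_fraction_min <= 1.0:
            raise ValueError("cv_pass_fraction_min must be in [0, 1]")
        for v in (self.median_ratio_min, self.cv_max):
            if not np.isfinite(v):
                raise ValueError("thresholds must be finite")


def compute_m_prime(table: ProbeTable, design: GroupDesign,
                    treatment: str, control: str) -> pd.DataFrame:
    """Per-probe M′ track aligned 1:1 with the probe table.

    Returns a frame with ``probe_id``, ``chrom``, ``start``, ``end``,
    ``position``, ``m_prime`` and the cached per-group probe means
    ``mean_<group>``.
    """
    for g in (treatment, control):
        if len(design.samples(g)) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    mean_t = np.nanmean(table.values_matrix(design.samples(treatment)), axis=1)
    mean_c = np.nanmean(table.values_matrix(design.samples(control)), axis=1)
    return pd.DataFrame({
        "probe_id": table.frame["probe_id"],
        "chrom": table.frame["chrom"],
        "start": table.frame["start"],
        "end": table.frame["end"],
        "position": table.midpoints,
        "m_prime": mean_t - mean_c,
        f"mean_{treatment}": mean_t,
        f"mean_{control}": mean_c,
    })


def find_differential_peaks(mprime: pd.DataFrame,
                            params: PeakCallParams | None = None,
                            direction: str = HYPER) -> list[Peak]:
    """Call peaks on M′ (hyper) or −M′ (hypo); peaks are tagged by direction."""
    if direction not in (HYPER, HYPO):
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    params = params or PeakCallParams()
    values = mprime["m_prime"].to_numpy(dtype=float)
    if direction == HYPO:
        values = -values
    codes = pd.factorize(mprime["chrom"].to_numpy())[0]
    scores = _windowed_mwu_scores(
        mprime["position"].to_numpy(dtype=float), codes, values,
        params.scoring_window, params.min_window_probes)
    track = mprime[["probe_id", "chrom", "start", "end", "position"]].copy()
    track["score"] = scores
    peaks = find_peaks(track, params)
    for p in peaks:
        p.direction = direction
        p.name = f"{p.name}_{direction}"
    return peaks


def _probe_cv(linear: np.ndarray) -> np.ndarray:
    """Per-probe CV (sample SD over mean) across replicate columns."""
    mean = np.nanmean(linear, axis=1)
    sd = np.nanstd(linear, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return sd / mean


def filter_deps(peaks: Iterable[Peak], table: ProbeTable,
                mprime: pd.DataFrame, design: GroupDesign,
                params: DepFilterParams | None = None,
                keep_rejected: bool = False) -> list[DifferentialPeak]:
    """Apply the two DEP filter criteria; returns surviving peaks by default.

    Probes with fewer than two non-missing replicate values in either group
    are dropped from peak membership before the summaries are computed; a
    peak losing all its probes that way is an error naming the peak.
    With ``keep_rejected=True`` every input peak is returned with its
    per-criterion verdicts for inspection.
    """
    params = params or DepFilterParams()
    groups = design.groups
    index = pd.Index(table.frame["probe_id"])
    m_by_probe = mprime.set_index("probe_id")["m_prime"]
    values_by_group = {g: table.values_matrix(design.samples(g))
                       for g in groups}
    out: list[DifferentialPeak] = []
    for peak in peaks:
        if peak.direction not in (HYPER, HYPO):
            raise ValueError(f"peak {peak.name!r} has no direction tag")
        idx = index.get_indexer(peak.probe_ids)
        if (idx < 0).any():
            missing = [p for p, i in zip(peak.probe_ids, idx) if i < 0]
            raise ValueError(f"peak {peak.name!r}: unknown probes {missing}")
        resolvable = np.ones(len(idx), dtype=bool)
        for g in groups:
            vals = values_by_group[g][idx]
            resolvable &= np.isfinite(vals).sum(axis=1) >= 2
        if not resolvable.any():
            raise ValueError(f"peak {peak.name!r} has zero resolvable probes")
        idx = idx[resolvable]
        probe_ids = [p for p, keep in zip(peak.probe_ids, resolvable) if keep]

        median_ratio = {}
        cv_pass = {}
        for g in groups:
            vals = values_by_group[g][idx]
            probe_means = np.nanmean(vals, axis=1)
            median_ratio[g] = float(np.median(probe_means))
            cv = _probe_cv(np.power(2.0, vals))
            cv_pass[g] = float(np.mean(cv <= params.cv_max))
        m_members = m_by_probe.loc[probe_ids].to_numpy(dtype=float)
        median_m = float(np.median(m_members))
        signed_median = median_m if peak.direction == HYPER else -median_m

        crit1 = (max(median_ratio.values()) >= params.median_ratio_min
                 and signed_median > 0.0)
        crit2 = all(cv_pass[g] >= params.cv_pass_fraction_min for g in groups)
        dep = DifferentialPeak(
            chrom=peak.chrom, start=peak.start, end=peak.end,
            probe_ids=probe_ids, score=peak.score, direction=peak.direction,
            median_m=median_m, median_ratio_by_group=median_ratio,
            cv_pass_fraction_by_group=cv_pass,
            criterion1_pass=bool(crit1), criterion2_pass=bool(crit2),
            name=peak.name,
        )
        if keep_rejected or dep.passed:
            out.append(dep)
    return out


def call_deps(table: ProbeTable, design: GroupDesign, treatment: str,
              control: str, peak_params: PeakCallParams | None = None,
              filter_params: DepFilterParams | None = None
              ) -> list[DifferentialPeak]:
    """Convenience wrapper: M′ → hyper+hypo peaks → DEP filter."""
    mprime = compute_m_prime(table, design, treatment, control)
    deps: list[DifferentialPeak] = []
    for direction in (HYPER, HYPO):
        peaks = find_differential_peaks(mprime, peak_params, direction)
        deps.extend(filter_deps(peaks, table, mprime, design, filter_params))
    deps.sort(key=lambda d: (d.chrom, d.start, d.direction))
    for i, d in enumerate(deps):
        d.name = f"dep_{i + 1}_{d.direction}"
    return deps


def recovery_metrics(deps: Iterable[DifferentialPeak],
                     truth: Iterable) -> dict:
    """Sensitivity and precision of DEP calls against planted regions.

    A truth region counts as recovered when any called DEP overlaps it by
    >= 1 bp (half-open intervals); a called DEP counts as a true positive
    when it overlaps any truth region.
    """
    deps = list(deps)
    truth = list(truth)

    def overlaps(a, b):
        return a.chrom == b.chrom and a.start < b.end and b.start < a.end

    recovered = sum(1 for t in truth if any(overlaps(d, t) for d in deps))
    true_pos = sum(1 for d in deps if any(overlaps(d, t) for t in truth))
    return {
        "n_truth": len(truth),
        "n_called": len(deps),
        "sensitivity": recovered / len(truth) if truth else float("nan"),
        "precision": true_pos / len(deps) if deps else float("nan"),
    }


def summarize_directions(
    deps: Iterable[DifferentialPeak] | Mapping[str, int],
) -> dict:
    """Counts and percentages (2 decimals) of hyper vs hypo calls.

    Accepts either DEP records or a precomputed ``{direction: count}``
    mapping (useful for summarizing externally reported call sets).
    """
    if isinstance(deps, Mapping):
        counts = {HYPER: int(deps.get(HYPER, 0)), HYPO: int(deps.get(HYPO, 0))}
    else:
        counts = {HYPER: 0, HYPO: 0}
        for d in deps:
            counts[d.direction] += 1
    total = counts[HYPER] + counts[HYPO]
    if total == 0:
        raise ValueError("no differential peaks to summarize")
    pct = {k: round(100.0 * v / total, 2) for k, v in counts.items()}
    return {"counts": counts, "percentages": pct, "total": total}
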