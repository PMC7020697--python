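"""CpG-density promoter classification (HCP / ICP / LCP).

Promoter sequences are scanned with 500-bp sliding windows (step 5 bp); each
window gets a GC fraction and a CpG observed/expected ratio
``(#CpG × L) / (#C × #G)`` (0 when the denominator is 0).  A promoter is a
high-CpG promoter (HCP) if any window has ratio > 0.75 and GC > 0.55, a
low-CpG promoter (LCP) if no window has ratio > 0.48, and an intermediate
promoter (ICP) otherwise — the standard three-way scheme for separating
strong from weak CpG islands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import PromoterRecord

HCP, ICP, LCP = "HCP", "ICP", "LCP"
CLASSES = (HCP, ICP, LCP)


@dataclass
class CpgClassThresholds:
    hcp_ratio: float = 0.75
    hcp_gc: float = 0.55
    lcp_ratio: float = 0.48
    window_len: int = 500
    step: int = 5


def window_stats(sequence: str, window_len: int = 500,
                 step: int = 5) -> pd.DataFrame:
    """Sliding-window GC fraction and CpG obs/exp ratio.

    Windows start every ``step`` bp; the final start is the largest one with
    a full window.  CpG dinucleotides are counted at every position ``i``
    with ``s[i:i+2] == "CG"`` whose pair lies fully inside the window.  A
    sequence shorter than the window is scored as a single whole-sequence
    window (with a warning).
    """
    seq = sequence.upper()
    n = len(seq)
    if n < window_len:
        warnings.warn(
            f"sequence length {n} < window {window_len}; scoring whole sequence",
            stacklevel=2,
        )
        window_len = n
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(0, n - window_len + 1, step)
    ends = starts + window_len
    n_c = cum_c[ends] - cum_c[starts]
    n_g = cum_g[ends] - cum_g[starts]
    n_cg = cum_cg[ends - 1] - cum_cg[starts]  # pair must fit inside window
    gc = (n_c + n_g) / window_len
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, n_cg * window_len / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame({"start": starts, "gc_fraction": gc,
                         "cpg_obs_exp": ratio,
                         "n_cpg": n_cg, "n_c": n_c, "n_g": n_g})


def classify_sequence(sequence: str,
                      thresholds: CpgClassThresholds | None = None) -> str:
    th = thresholds or CpgClassThresholds()
    stats = window_stats(sequence, th.window_len, th.step)
    ratio = stats["cpg_obs_exp"].to_numpy()
    gc = stats["gc_fraction"].to_numpy()
    if np.any((ratio > th.hcp_ratio) & (gc > th.hcp_gc)):
        return HCP
    if not np.any(ratio > th.lcp_ratio):
        return LCP
    return ICP


def classify_promoter(record: PromoterRecord,
                      thresholds: CpgClassThresholds | None = None
                      ) -> str | None:
    """Classify a promoter record in place; None when no sequence is present."""
    if record.sequence is None:
        record.cpg_class = None
        return None
    record.cpg_class = classify_sequence(record.sequence, thresholds)
    return record.cpg_class


def classify_promoters(records: Iterable[PromoterRecord],
                       thresholds: CpgClassThresholds | None = None
                       ) -> dict[str, str]:
    """Classify many records; returns gene_id → class for sequenced records."""
    out = {}
    for rec in records:
        label = classify_promoter(rec, thresholds)
        if label is not None:
            out[rec.gene_id] = label
    return out


def class_shares(assignments: Iterable[str] | dict[str, int]) -> dict:
    """Counts and percentages (2 decimals) per CpG class.

    Accepts class labels (e.g. classifier output values) or a precomputed
    ``{class: count}`` mapping; unassigned (None) labels are excluded.
    """
    if isinstance(assignments, dict):
        counts = {c: int(assignments.get(c, 0)) for c in CLASSES}
    else:
        counts = {c: 0 for c in CLASSES}
        for label in assignments:
            if label is None:
                continue
            if label not in counts:
                raise ValueError(f"unknown class label {label!r}")
            counts[label] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no class assignments to summarize")
    pct = {c: round(100.0 * counts[c] / total, 2) for c in CLASSES}
    return {"counts": counts, "percentages": pct, "total": total}
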