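import numpy as np
import pandas as pd
import pytest

from medipdiff import (
    GroupDesign,
    ProbeTable,
    SimulationConfig,
    simulate_probe_array,
)
from medipdiff.peaks import PeakCallParams


@pytest.fixture(scope="session")
def sim_bundle():
    """A small simulated array shared across tests (read-only)."""
    config = SimulationConfig(seed=11, n_promoters=120)
    table, design, truth = simulate_probe_array(config)
    return config, table, design, truth


@pytest.fixture()
def tiny_table():
    """Six probes on one chromosome, two groups of three constant samples."""
    frame = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(6)],
        "chrom": ["chr1"] * 6,
        "start": [100 * i for i in range(6)],
        "end": [100 * i + 60 for i in range(6)],
    })
    for s in ("t1", "t2", "t3"):
        frame[s] = 1.0
    for s in ("c1", "c2", "c3"):
        frame[s] = 0.5
    table = ProbeTable(frame, ["t1", "t2", "t3", "c1", "c2", "c3"])
    design = GroupDesign({s: "T" for s in ("t1", "t2", "t3")}
                         | {s: "C" for s in ("c1", "c2", "c3")})
    return table, design


def brute_force_peaks(track: pd.DataFrame, params: PeakCallParams):
    """Independent peak oracle: connected components of the adjacency graph.

    Above-cutoff probes on a chromosome are nodes; consecutive above-cutoff
    probes within max_gap (midpoint distance) are edges; peaks are the
    components with at least min_probes nodes, as ordered probe-id tuples.
    """
    peaks = []
    for chrom in pd.unique(track["chrom"]):
        seg = track[(track["chrom"] == chrom)
                    & (track["score"] >= params.score_cutoff)]
        seg = seg.sort_values("position", kind="mergesort")
        ids = seg["probe_id"].tolist()
        pos = seg["position"].to_numpy(dtype=float)
        n = len(ids)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n - 1):
            if pos[i + 1] - pos[i] <= params.max_gap:
                parent[find(i + 1)] = find(i)
        components: dict[int, list[str]] = {}
        for i in range(n):
            components.setdefault(find(i), []).append(ids[i])
        for comp in components.values():
            if len(comp) >= params.min_probes:
                peaks.append((str(chrom), tuple(comp)))
    return sorted(peaks)


def straight_line_filter_verdicts(table, design, mprime, peak, params):
    """Plain re-statement of the two DEP filter criteria (no numpy).

    Independent of the production implementation: per group, per member
    probe, the replicate mean and the linear-scale CV are computed with the
    statistics module; criterion (1) is max group median >= threshold and
    direction-signed median M' > 0; criterion (2) is the CV pass fraction
    >= 1/2 in both groups.
    """
    import statistics

    frame = table.frame.set_index("probe_id")
    m = mprime.set_index("probe_id")["m_prime"]
    medians = {}
    cv_fracs = {}
    for group in design.groups:
        samples = design.samples(group)
        probe_means = []
        n_cv_ok = 0
        for pid in peak.probe_ids:
            reps = [float(frame.loc[pid, s]) for s in samples]
            probe_means.append(statistics.fmean(reps))
            linear = [2.0 ** r for r in reps]
            cv = statistics.stdev(linear) / statistics.fmean(linear)
            n_cv_ok += cv <= params.cv_max
        medians[group] = statistics.median(probe_means)
        cv_fracs[group] = n_cv_ok / len(peak.probe_ids)
    med_m = statistics.median(float(m.loc[pid]) for pid in peak.probe_ids)
    if peak.direction == "hypo":
        med_m = -med_m
    crit1 = (max(medians.values()) >= params.median_ratio_min and med_m > 0)
    crit2 = all(f >= params.cv_pass_fraction_min for f in cv_fracs.values())
    return crit1, crit2


def random_member_peaks(table, rng, n_peaks=200):
    """Random single-chromosome probe runs tagged with random directions."""
    from medipdiff import Peak

    peaks = []
    while len(peaks) < n_peaks:
        start = int(rng.integers(0, table.n_probes - 10))
        length = int(rng.integers(2, 11))
        sub = table.frame.iloc[start : start + length]
        if sub["chrom"].nunique() > 1:
            continue
        peaks.append(Peak(sub["chrom"].iloc[0], int(sub["start"].iloc[0]),
                          int(sub["end"].iloc[-1]),
                          sub["probe_id"].tolist(), 3.0,
                          name=f"rp{len(peaks)}",
                          direction=("hyper", "hypo")[int(rng.integers(2))]))
    return peaks


def random_score_track(rng: np.random.Generator, max_probes: int = 200
                       ) -> pd.DataFrame:
    """A random sorted score track on 1-2 chromosomes for oracle testing."""
    n = int(rng.integers(2, max_probes + 1))
    chroms = np.sort(rng.choice(["chr1", "chr2"], size=n))
    rows = []
    pos = 0.0
    last_chrom = None
    for i in range(n):
        if chroms[i] != last_chrom:
            pos = 0.0
            last_chrom = chroms[i]
        pos += float(rng.integers(50, 700))
        rows.append({"probe_id": f"{chroms[i]}_p{i}", "chrom": chroms[i],
                     "start": int(pos - 30), "end": int(pos + 30),
                     "position": pos,
                     "score": float(rng.uniform(0.0, 4.0))})
    return pd.DataFrame(rows)
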