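"""Core domain types and on-disk formats for the MeDIP-chip pipeline.

Conventions used throughout the package:

* all genomic intervals are 0-based, half-open ``[start, end)``; BED files on
  disk follow the same convention, so coordinates round-trip unchanged;
* probe tables are kept sorted by ``(chrom, start)``;
* probe-level signal is the per-sample ``log2(MeDIP/Input)`` ratio (unitless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

PROBE_META_COLUMNS = ("probe_id", "chrom", "start", "end")
VALID_SEQUENCE_CHARS = frozenset("ACGTN")
DEFAULT_PHENOTYPE_GROUPS = ("CON", "HF", "HF-inulin")


# ---------------------------------------------------------------------------
# Probe-level array data
# ---------------------------------------------------------------------------

@dataclass
class ProbeTable:
    """Genomic tiling probes with per-sample log2(MeDIP/Input) values.

    ``frame`` holds the metadata columns :data:`PROBE_META_COLUMNS` followed by
    one numeric column per entry of ``sample_ids``.  Construction validates
    the invariants (unique probe ids, ``start < end``, sorted order) and sorts
    rows by ``(chrom, start)`` with values kept aligned.
    """

    frame: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        frame = self.frame
        missing = [c for c in PROBE_META_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        absent = [s for s in self.sample_ids if s not in frame.columns]
        if absent:
            raise ValueError(f"probe table missing sample columns: {absent}")
        dup = frame["probe_id"][frame["probe_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate probe_id values: {sorted(set(dup))}")
        if (frame["start"] >= frame["end"]).any():
            bad = frame.loc[frame["start"] >= frame["end"], "probe_id"].tolist()
            raise ValueError(f"probes with start >= end: {bad}")
        cols = list(PROBE_META_COLUMNS) + list(self.sample_ids)
        frame = frame[cols].sort_values(["chrom", "start"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        object.__setattr__(self, "frame", frame)

    @property
    def n_probes(self) -> int:
        return len(self.frame)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.frame["start"].to_numpy() + self.frame["end"].to_numpy()) / 2.0

    def values_matrix(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Probe × sample matrix of log2 ratios as float64."""
        samples = list(self.sample_ids if samples is None else samples)
        unknown = [s for s in samples if s not in self.sample_ids]
        if unknown:
            raise ValueError(f"unknown sample ids: {unknown}")
        return self.frame[samples].to_numpy(dtype=np.float64)

    def copy(self) -> "ProbeTable":
        return ProbeTable(self.frame.copy(), list(self.sample_ids))


@dataclass
class GroupDesign:
    """Assignment of array samples to exactly two analysis groups."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        groups = sorted(set(self.assignment.values()))
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly two analysis groups, got {groups}"
            )

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def samples(self, group: str) -> list[str]:
        out = [s for s, g in self.assignment.items() if g == group]
        if not out:
            raise ValueError(f"unknown group {group!r}")
        return out

    def validate_against(self, table: ProbeTable, min_replicates: int = 2) -> None:
        unassigned = [s for s in table.sample_ids if s not in self.assignment]
        if unassigned:
            raise ValueError(f"samples not assigned to a group: {unassigned}")
        for g in self.groups:
            if len(self.samples(g)) < min_replicates:
                raise ValueError(
                    f"group {g!r} has fewer than {min_replicates} samples"
                )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    """A maximal run of qualifying probes.

    ``score`` is the median −log10 p of member probes.  ``direction`` is set
    for peaks called on a differential (M′) track.
    """

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    score: float
    name: str | None = None
    direction: str | None = None

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class DifferentialPeak:
    """A peak on the M′ track with the DEP-filter summary quantities."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    score: float
    direction: str  # "hyper" or "hypo"
    median_m: float  # median per-probe M′ (raw sign)
    median_ratio_by_group: dict[str, float]
    cv_pass_fraction_by_group: dict[str, float]
    criterion1_pass: bool
    criterion2_pass: bool
    name: str | None = None
    gene_ids: list[str] = field(default_factory=list)
    cpg_class: str | None = None

    @property
    def passed(self) -> bool:
        return self.criterion1_pass and self.criterion2_pass

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass
class PromoterRecord:
    """A promoter interval around a TSS with (optionally) its sequence."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    sequence: str | None = None
    cpg_class: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start >= end")
        if self.sequence is not None:
            seq = self.sequence.upper()
            bad = set(seq) - VALID_SEQUENCE_CHARS
            if bad:
                raise ValueError(
                    f"{self.gene_id}: non-ACGTN characters {sorted(bad)}"
                )
            if len(seq) != self.end - self.start:
                raise ValueError(
                    f"{self.gene_id}: sequence length {len(seq)} != window "
                    f"length {self.end - self.start}"
                )
            self.sequence = seq


# ---------------------------------------------------------------------------
# Bisulfite clones, phenotypes, gene sets
# ---------------------------------------------------------------------------

@dataclass
class BisulfiteCloneMatrix:
    """Clone × CpG-site binary methylation calls for one animal/amplicon.

    ``calls`` is a float matrix with entries 0.0, 1.0 or NaN (missing).
    """

    animal_id: str
    group: str
    amplicon_id: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.float64)
        if calls.ndim != 2 or calls.shape[0] < 1:
            raise ValueError(
                f"{self.animal_id}/{self.amplicon_id}: need >=1 clone row"
            )
        finite = calls[np.isfinite(calls)]
        if not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError(
                f"{self.animal_id}/{self.amplicon_id}: calls must be 0/1/NA"
            )
        self.calls = calls

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]


@dataclass
class PhenotypeTable:
    """Per-animal metabolic phenotypes and qPCR Ct values.

    Wraps a data frame with columns ``animal_id``, ``group``, ``body_weight``,
    ``glucose_<minute>`` (OGTT series), ``fasting_insulin`` and ``ct_<gene>``
    columns (the reference gene is one of them, e.g. ``ct_Gapdh``).
    """

    frame: pd.DataFrame
    allowed_groups: tuple[str, ...] = DEFAULT_PHENOTYPE_GROUPS

    def __post_init__(self) -> None:
        frame = self.frame
        for col in ("animal_id", "group"):
            if col not in frame.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        unknown = sorted(set(frame["group"]) - set(self.allowed_groups))
        if unknown:
            raise ValueError(f"unknown group labels: {unknown}")
        times = self.glucose_times
        if times and (times[0] != 0 or np.any(np.diff(times) <= 0)):
            raise ValueError(
                f"glucose time points must start at 0 and increase: {times}"
            )
        numeric = [c for c in frame.columns
                   if c.startswith("glucose_") or c in
                   ("body_weight", "fasting_insulin")]
        for col in numeric:
            if (frame[col].to_numpy(dtype=float) < 0).any():
                raise ValueError(f"negative measurement in column {col!r}")
        self.frame = frame.reset_index(drop=True)

    @property
    def glucose_times(self) -> list[int]:
        times = [int(c.split("_", 1)[1]) for c in self.frame.columns
                 if c.startswith("glucose_")]
        return sorted(times)

    def glucose_series(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, animal × time glucose matrix), times ascending."""
        times = self.glucose_times
        cols = [f"glucose_{t}" for t in times]
        return np.asarray(times, float), self.frame[cols].to_numpy(dtype=float)

    def ct_genes(self) -> list[str]:
        return [c.split("_", 1)[1] for c in self.frame.columns
                if c.startswith("ct_")]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect members with ``universe`` and drop emptied sets."""
        universe = frozenset(universe)
        restricted = {}
        for sid, (desc, members) in self.sets.items():
            kept = members & universe
            if kept:
                restricted[sid] = (desc, kept)
        return GeneSetCollection(restricted, universe)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_probe_table(path, format: str = "log2",
                     sample_ids: Sequence[str] | None = None) -> ProbeTable:
    """Read a tab-delimited probe table.

    ``format="log2"`` expects one numeric column per sample holding
    precomputed log2(MeDIP/Input) values.  ``format="two_channel"`` expects
    column pairs ``<sample>_MeDIP`` / ``<sample>_Input`` of raw intensities,
    converted here via ``log2(MeDIP/Input)``; nonpositive intensities are
    rejected with the offending probe named.
    """
    frame = pd.read_csv(path, sep="\t")
    meta = list(PROBE_META_COLUMNS)
    if format == "log2":
        if sample_ids is None:
            sample_ids = [c for c in frame.columns if c not in meta]
        return ProbeTable(frame, list(sample_ids))
    if format != "two_channel":
        raise ValueError(f"unknown format {format!r}")
    medip_cols = [c for c in frame.columns if c.endswith("_MeDIP")]
    samples = [c[: -len("_MeDIP")] for c in medip_cols]
    out = frame[meta].copy()
    for sid in samples:
        m = frame[f"{sid}_MeDIP"].to_numpy(dtype=float)
        i = frame[f"{sid}_Input"].to_numpy(dtype=float)
        bad = np.nonzero((m <= 0) | (i <= 0))[0]
        if len(bad):
            probes = frame["probe_id"].iloc[bad].tolist()
            raise ValueError(
                f"nonpositive intensity for sample {sid!r} at probes {probes}"
            )
        out[sid] = np.log2(m / i)
    return ProbeTable(out, samples)


def write_probe_table(table: ProbeTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_design(design: GroupDesign, path) -> None:
    frame = pd.DataFrame(
        {"sample_id": list(design.assignment),
         "group": [design.assignment[s] for s in design.assignment]}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_design(path) -> GroupDesign:
    frame = pd.read_csv(path, sep="\t")
    return GroupDesign(dict(zip(frame["sample_id"], frame["group"])))


def _bed_name(record, index: int) -> str:
    name = getattr(record, "name", None)
    if name:
        return name
    direction = getattr(record, "direction", None)
    base = f"peak_{index + 1}"
    return f"{base}_{direction}" if direction else base


def write_bed(records: Sequence, path) -> None:
    """Write peaks/DEPs (anything with chrom/start/end) as BED6.

    Score is the record score clamped to [0, 1000]; strand is ``"."``.  An
    empty record list produces an empty file (no header).
    """
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            score = float(np.clip(getattr(rec, "score", 0.0), 0.0, 1000.0))
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{_bed_name(rec, i)}"
                f"\t{score:g}\t.\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into a frame (chrom, start, end, name, score, strand)."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        frame = pd.read_csv(path, sep="\t", header=None, names=cols,
                            dtype={"chrom": str, "name": str, "strand": str})
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=cols)
    frame["start"] = frame["start"].astype(np.int64, errors="ignore")
    frame["end"] = frame["end"].astype(np.int64, errors="ignore")
    return frame


def write_promoter_annotation(promoters: Sequence[PromoterRecord], path,
                              include_class: bool = False) -> None:
    rows = []
    for p in promoters:
        row = {"gene_id": p.gene_id, "chrom": p.chrom, "tss": p.tss,
               "strand": p.strand, "start": p.start, "end": p.end}
        if include_class:
            row["cpg_class"] = p.cpg_class
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta_promoters(promoters: Sequence[PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            if p.sequence is None:
                continue
            fh.write(f">{p.gene_id}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def read_fasta_promoters(fasta_path, annotation_path) -> list[PromoterRecord]:
    """Join promoter sequences (FASTA) to a TSS annotation table.

    Sequences are upper-cased; every annotation row must have a FASTA entry
    (missing ids are reported together) and sequences must be ACGTN only.
    """
    sequences = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(fasta_path), "fasta")}
    annot = pd.read_csv(annotation_path, sep="\t")
    missing = [g for g in annot["gene_id"] if g not in sequences]
    if missing:
        raise ValueError(f"annotation rows lacking FASTA entries: {missing}")
    records = []
    for row in annot.itertuples(index=False):
        records.append(
            PromoterRecord(
                gene_id=row.gene_id, chrom=row.chrom, tss=int(row.tss),
                strand=row.strand, start=int(row.start), end=int(row.end),
                sequence=sequences[row.gene_id],
                cpg_class=getattr(row, "cpg_class", None),
            )
        )
    return records


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set_id, description, member genes...).

    The universe is the union of all members; callers normally restrict it to
    the array's gene list with :meth:`GeneSetCollection.restrict`.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with <3 fields: {line!r}")
            sid, desc, members = fields[0], fields[1], fields[2:]
            members = frozenset(m for m in members if m)
            if not members:
                raise ValueError(f"GMT set {sid!r} has no members")
            sets[sid] = (desc, members)
            universe |= members
    return GeneSetCollection(sets, frozenset(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def read_clone_tsv(path) -> list[BisulfiteCloneMatrix]:
    """Read clone matrices from a wide TSV.

    Expected columns: ``animal_id``, ``group``, ``amplicon_id``, ``clone_id``,
    then one ``cpg_<k>`` column per CpG site with entries 0/1/NA.  One
    :class:`BisulfiteCloneMatrix` is returned per (animal, amplicon); site
    columns absent for an amplicon (all-NA trailing columns) are trimmed.
    """
    frame = pd.read_csv(path, sep="\t")
    site_cols = [c for c in frame.columns if c.startswith("cpg_")]
    if not site_cols:
        raise ValueError("clone table has no cpg_<k> columns")
    values = frame[site_cols].to_numpy(dtype=np.float64)
    finite = values[np.isfinite(values)]
    if not np.isin(finite, (0.0, 1.0)).all():
        raise ValueError("clone matrix entries must be 0, 1 or NA")
    matrices = []
    for (animal, group, amplicon), sub in frame.groupby(
        ["animal_id", "group", "amplicon_id"], sort=True
    ):
        calls = sub[site_cols].to_numpy(dtype=np.float64)
        used = ~np.all(np.isnan(calls), axis=0)
        # trailing all-NA columns pad amplicons with fewer CpG sites
        matrices.append(
            BisulfiteCloneMatrix(str(animal), str(group), str(amplicon),
                                 calls[:, used])
        )
    return matrices


def write_clone_tsv(matrices: Sequence[BisulfiteCloneMatrix], path) -> None:
    n_sites = max(m.n_sites for m in matrices)
    rows = []
    for m in matrices:
        for c in range(m.n_clones):
            row: dict[str, object] = {
                "animal_id": m.animal_id, "group": m.group,
                "amplicon_id": m.amplicon_id, "clone_id": f"clone_{c + 1}",
            }
            for k in range(n_sites):
                v = m.calls[c, k] if k < m.n_sites else np.nan
                row[f"cpg_{k + 1}"] = "" if np.isnan(v) else int(v)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path,
                    allowed_groups: tuple[str, ...] = DEFAULT_PHENOTYPE_GROUPS
                    ) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t")
    return PhenotypeTable(frame, allowed_groups)


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
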