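"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration and seed, and each
planted signal is returned in a truth object so downstream calls can be scored
against ground truth.  The array generator emulates a promoter tiling design
(two-colour MeDIP vs Input, log2 ratios, a few replicates per group) at desk
scale; see ``docs/methods.md`` for what is and is not emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    BisulfiteCloneMatrix,
    GeneSetCollection,
    GroupDesign,
    PhenotypeTable,
    ProbeTable,
    PromoterRecord,
)

LN2 = math.log(2.0)

# amplicon CpG counts used by the bisulfite-clone generator
DEFAULT_AMPLICON_CPGS = {"Wnt5a": 6, "Pik3c2a": 22, "Pik3c2b": 9, "Pik3r2": 31}

# per-amplicon mean methylation probability per group: the validated loci show
# opposite patterns (one locus loses methylation on the high-fat diet and is
# restored by the intervention; the three kinase loci gain it)
DEFAULT_BSP_PROBS = {
    "Wnt5a": {"CON": 0.60, "HF": 0.30, "HF-inulin": 0.50},
    "Pik3c2a": {"CON": 0.20, "HF": 0.50, "HF-inulin": 0.30},
    "Pik3c2b": {"CON": 0.20, "HF": 0.55, "HF-inulin": 0.35},
    "Pik3r2": {"CON": 0.25, "HF": 0.60, "HF-inulin": 0.40},
}

# 15-mer with exactly one CpG, five Cs and five Gs: tiled over a promoter it
# yields a windowed CpG obs/exp ratio of ~0.6 (between the LCP bound 0.48 and
# the HCP bound 0.75) in every 500-bp window, i.e. an intermediate promoter
ICP_UNIT = "CGGGGGCCCCAATAT"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic promoter tiling array.

    Defaults mirror the emulated study where it states them (3 replicates per
    group, two-group contrast) and a scaled-down but realistic array geometry
    elsewhere: 500 promoters, probes of 60 bp every 100 bp across a
    [-1300, +500) window around the TSS.
    """

    seed: int
    n_promoters: int = 500
    promoter_window: tuple[int, int] = (-1300, 500)
    probe_spacing: int = 100
    probe_length: int = 60
    n_replicates_per_group: int = 3
    treatment: str = "HF-inulin"
    control: str = "HF"
    baseline_log2ratio_mean: dict[str, float] = field(
        default_factory=lambda: {"unmethylated": 0.0, "methylated": 1.0}
    )
    fraction_methylated: float = 0.2
    effect_size: float = 1.0
    probe_noise_sd: float = 0.3
    cv_range: tuple[float, float] | None = None
    fraction_hyper: float = 0.04
    fraction_hypo: float = 0.04
    dmr_n_probes: int = 8
    cpg_class_mix: dict[str, float] = field(
        default_factory=lambda: {"HCP": 0.50, "ICP": 0.25, "LCP": 0.25}
    )

    def __post_init__(self) -> None:
        for name in ("fraction_methylated", "fraction_hyper", "fraction_hypo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_hyper + self.fraction_hypo > 1.0:
            raise ValueError("fraction_hyper + fraction_hypo must be <= 1")
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if abs(sum(self.cpg_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cpg_class_mix must sum to 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        w0, w1 = self.promoter_window
        if w1 - w0 < self.probe_length:
            raise ValueError("promoter window holds zero probes")

    def probe_offsets(self) -> list[int]:
        """Probe start offsets relative to the TSS."""
        w0, w1 = self.promoter_window
        offsets = list(range(w0, w1 - self.probe_length + 1,
                             self.probe_spacing))
        if not offsets:
            raise ValueError("configuration yields zero probes per promoter")
        return offsets


@dataclass
class TruthDmr:
    """A planted differentially methylated region."""

    chrom: str
    start: int
    end: int
    gene_id: str
    direction: str  # "hyper" or "hypo"
    score: float = 0.0

    @property
    def name(self) -> str:
        return f"{self.gene_id}_{self.direction}"


def read_truth_dmrs(path) -> list[TruthDmr]:
    """Parse a truth BED written by :func:`simulate_probe_array` outputs."""
    from .datamodel import read_bed

    out = []
    for row in read_bed(path).itertuples(index=False):
        gene, direction = row.name.rsplit("_", 1)
        out.append(TruthDmr(row.chrom, int(row.start), int(row.end),
                            gene, direction))
    return out


def _promoter_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic promoter placement: 19 chromosomes, TSS 100 kb apart."""
    idx = np.arange(config.n_promoters)
    chroms = [f"chr{(i % 19) + 1}" for i in idx]
    tss = 1_000_000 + (idx // 19) * 100_000
    genes = [f"gene{i:04d}" for i in idx]
    return pd.DataFrame({"gene_id": genes, "chrom": chroms, "tss": tss})


def promoter_records(config: SimulationConfig) -> list[PromoterRecord]:
    """Promoter intervals (no sequence) matching the simulated array."""
    w0, w1 = config.promoter_window
    out = []
    for row in _promoter_layout(config).itertuples(index=False):
        out.append(PromoterRecord(row.gene_id, row.chrom, int(row.tss), "+",
                                  int(row.tss) + w0, int(row.tss) + w1))
    return out


def simulate_probe_array(
    config: SimulationConfig,
) -> tuple[ProbeTable, GroupDesign, list[TruthDmr]]:
    """Simulate per-probe log2(MeDIP/Input) ratios for two groups.

    Each promoter carries a baseline drawn from its methylation state; in the
    treatment group a contiguous block of probes in planted promoters is
    shifted by ±``effect_size``; i.i.d. Gaussian noise (``probe_noise_sd``)
    is added per probe per sample.  Hypomethylated regions are planted on
    promoters with a methylated baseline (a loss needs something to lose) and
    hypermethylated regions on unmethylated ones.
    """
    rng = np.random.default_rng(config.seed)
    layout = _promoter_layout(config)
    offsets = np.asarray(config.probe_offsets())
    n_prom, n_off = len(layout), len(offsets)

    n_meth = round(config.fraction_methylated * n_prom)
    meth_idx = rng.choice(n_prom, size=n_meth, replace=False)
    is_meth = np.zeros(n_prom, dtype=bool)
    is_meth[meth_idx] = True

    n_hyper = round(config.fraction_hyper * n_prom)
    n_hypo = round(config.fraction_hypo * n_prom)
    unmeth_pool = np.nonzero(~is_meth)[0]
    meth_pool = np.nonzero(is_meth)[0]
    if n_hyper > len(unmeth_pool) or n_hypo > len(meth_pool):
        raise ValueError("not enough promoters to host the planted DMRs")
    hyper_idx = rng.choice(unmeth_pool, size=n_hyper, replace=False)
    hypo_idx = rng.choice(meth_pool, size=n_hypo, replace=False)

    groups = {config.treatment: [f"{config.treatment}_{r + 1}"
                                 for r in range(config.n_replicates_per_group)],
              config.control: [f"{config.control}_{r + 1}"
                               for r in range(config.n_replicates_per_group)]}
    sample_ids = groups[config.treatment] + groups[config.control]

    # probe metadata
    tss = layout["tss"].to_numpy()
    starts = (tss[:, None] + offsets[None, :]).ravel()
    ends = starts + config.probe_length
    chroms = np.repeat(layout["chrom"].to_numpy(), n_off)
    prom_of_probe = np.repeat(np.arange(n_prom), n_off)
    probe_ids = [f"{layout['gene_id'][p]}_p{k + 1:02d}"
                 for p in range(n_prom) for k in range(n_off)]

    baselines = np.where(
        is_meth,
        config.baseline_log2ratio_mean["methylated"],
        config.baseline_log2ratio_mean["unmethylated"],
    )
    mu = baselines[prom_of_probe].astype(float)

    # planted blocks: a centered run of dmr_n_probes probes per chosen promoter
    block = min(config.dmr_n_probes, n_off)
    b0 = (n_off - block) // 2
    effect = np.zeros(n_prom * n_off)
    truth: list[TruthDmr] = []
    for sign, chosen in ((+1.0, hyper_idx), (-1.0, hypo_idx)):
        for p in sorted(chosen):
            lo = p * n_off + b0
            hi = lo + block
            effect[lo:hi] = sign * config.effect_size
            truth.append(
                TruthDmr(chrom=str(chroms[lo]), start=int(starts[lo]),
                         end=int(ends[hi - 1]),
                         gene_id=str(layout["gene_id"][p]),
                         direction="hyper" if sign > 0 else "hypo")
            )
    truth.sort(key=lambda t: (t.chrom, t.start))

    if config.cv_range is not None:
        lo, hi = config.cv_range
        probe_sd = rng.uniform(lo, hi, size=len(mu)) / LN2
    else:
        probe_sd = np.full(len(mu), config.probe_noise_sd)

    frame = pd.DataFrame({"probe_id": probe_ids, "chrom": chroms,
                          "start": starts, "end": ends})
    for sid in sample_ids:
        treated = sid in groups[config.treatment]
        mean = mu + (effect if treated else 0.0)
        frame[sid] = mean + rng.normal(0.0, 1.0, size=len(mu)) * probe_sd

    table = ProbeTable(frame, sample_ids)
    design = GroupDesign({s: g for g, ss in groups.items() for s in ss})
    return table, design, truth


# ---------------------------------------------------------------------------
# Promoter sequences for the CpG-density classifier
# ---------------------------------------------------------------------------

def _random_at(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("AT")), size=n)


def simulate_promoter_sequences(
    config: SimulationConfig,
) -> tuple[list[PromoterRecord], dict[str, str]]:
    """Construct promoter sequences with known CpG-density classes.

    Truth labels come from the construction rules, never from running the
    classifier: a high-CpG promoter embeds a 500-bp alternating-CG block
    (obs/exp ratio 2.0, GC 1.0); a low-CpG promoter is CpG-free A/T sequence;
    an intermediate promoter tiles a unit whose windowed obs/exp ratio is
    ~0.6 everywhere.  Class counts follow ``cpg_class_mix`` exactly
    (largest-remainder rounding).
    """
    rng = np.random.default_rng(config.seed + 1)
    w0, w1 = config.promoter_window
    length = w1 - w0
    if length < 500:
        raise ValueError("promoter window must be >= 500 bp for classification")

    classes = list(config.cpg_class_mix)
    raw = {c: config.cpg_class_mix[c] * config.n_promoters for c in classes}
    counts = {c: int(math.floor(raw[c])) for c in classes}
    leftover = config.n_promoters - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - counts[c], reverse=True):
        if leftover <= 0:
            break
        counts[c] += 1
        leftover -= 1

    labels = np.array([c for c in classes for _ in range(counts[c])])
    labels = labels[rng.permutation(len(labels))]

    icp_tile = (ICP_UNIT * (length // len(ICP_UNIT) + 1))[:length]
    records, truth = [], {}
    for rec, label in zip(promoter_records(config), labels):
        if label == "LCP":
            seq = "".join(_random_at(rng, length))
        elif label == "ICP":
            seq = icp_tile
        elif label == "HCP":
            chars = _random_at(rng, length)
            start = 5 * int(rng.integers(0, (length - 500) // 5 + 1))
            chars[start : start + 500] = list("CG" * 250)
            seq = "".join(chars)
        else:
            raise ValueError(f"unknown class label {label!r}")
        rec.sequence = seq
        records.append(rec)
        truth[rec.gene_id] = str(label)
    return records, truth


# ---------------------------------------------------------------------------
# Bisulfite clone matrices
# ---------------------------------------------------------------------------

def simulate_clone_matrices(
    group_probs: dict[str, dict[str, float]] | None = None,
    amplicon_cpgs: dict[str, int] | None = None,
    n_animals: int = 10,
    n_clones: int = 10,
    seed: int = 0,
    overdispersion: float = 0.0,
) -> tuple[list[BisulfiteCloneMatrix], dict[str, dict[str, float]]]:
    """Bernoulli clone × CpG-site calls per animal per amplicon.

    ``overdispersion`` > 0 draws each animal's methylation probability from a
    Beta distribution centred on the group mean (concentration
    ``1/overdispersion``); 0 keeps every animal at the group mean.
    Returns the matrices plus the truth (the group probabilities used).
    """
    group_probs = DEFAULT_BSP_PROBS if group_probs is None else group_probs
    amplicon_cpgs = (DEFAULT_AMPLICON_CPGS if amplicon_cpgs is None
                     else amplicon_cpgs)
    rng = np.random.default_rng(seed)
    matrices = []
    for amplicon, probs in group_probs.items():
        n_sites = amplicon_cpgs[amplicon]
        for group, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {amplicon}/{group}")
            for a in range(n_animals):
                if overdispersion > 0 and 0.0 < p < 1.0:
                    c = 1.0 / overdispersion
                    p_animal = rng.beta(p * c, (1.0 - p) * c)
                else:
                    p_animal = p
                calls = rng.binomial(1, p_animal,
                                     size=(n_clones, n_sites)).astype(float)
                matrices.append(
                    BisulfiteCloneMatrix(f"{group}_{a + 1}", group, amplicon,
                                         calls)
                )
    return matrices, group_probs


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeEffects:
    """Group effects for the phenotype generator.

    Defaults echo the emulated study's printed contrasts: a 22.5% body-weight
    gap and a 49.7% OGTT-AUC gap between the high-fat and control groups at
    weaning, with the inulin group intermediate.  Units: body weight g,
    glucose mmol/L, insulin in units consistent with glucose for HOMA-IR.
    """

    body_weight_base: float = 8.0
    body_weight_multipliers: dict[str, float] = field(
        default_factory=lambda: {"CON": 1.0, "HF": 1.225, "HF-inulin": 1.10}
    )
    ogtt_base: dict[int, float] = field(
        default_factory=lambda: {0: 5.0, 15: 11.0, 30: 13.0, 60: 10.0,
                                 120: 7.0}
    )
    ogtt_multipliers: dict[str, float] = field(
        default_factory=lambda: {"CON": 1.0, "HF": 1.497, "HF-inulin": 1.20}
    )
    insulin_base: float = 8.0
    insulin_multipliers: dict[str, float] = field(
        default_factory=lambda: {"CON": 1.0, "HF": 2.5, "HF-inulin": 1.5}
    )
    reference_gene: str = "Gapdh"
    reference_ct: float = 18.0
    target_delta_ct: dict[str, float] = field(
        default_factory=lambda: {"Wnt5a": 6.0, "Pik3c2a": 7.0,
                                 "Pik3c2b": 7.5, "Pik3r2": 6.5}
    )
    expression_fold: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "Wnt5a": {"CON": 1.0, "HF": 2.0, "HF-inulin": 1.2},
            "Pik3c2a": {"CON": 1.0, "HF": 0.5, "HF-inulin": 0.8},
            "Pik3c2b": {"CON": 1.0, "HF": 0.5, "HF-inulin": 0.8},
            "Pik3r2": {"CON": 1.0, "HF": 0.5, "HF-inulin": 0.8},
        }
    )


def simulate_phenotypes(
    effects: PhenotypeEffects | None = None,
    n_per_group: int = 10,
    noise_fraction: float = 0.1,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    groups: tuple[str, ...] = ("CON", "HF", "HF-inulin"),
) -> PhenotypeTable:
    """Per-animal body weight, OGTT glucose series, insulin and Ct values.

    Positive-valued measurements get multiplicative Gaussian noise with
    coefficient of variation ``noise_fraction``; Ct values get additive
    Gaussian noise of ``ct_noise_sd`` cycles.  ``noise_fraction=0`` and
    ``ct_noise_sd=0`` reproduce the configured group effects exactly.
    """
    eff = PhenotypeEffects() if effects is None else effects
    for m in (eff.body_weight_multipliers, eff.ogtt_multipliers,
              eff.insulin_multipliers):
        if not all(np.isfinite(list(m.values()))):
            raise ValueError("group effects must be finite")
    rng = np.random.default_rng(seed)
    times = sorted(eff.ogtt_base)
    rows = []
    for group in groups:
        for a in range(n_per_group):
            def noisy(x: float) -> float:
                return float(x * (1.0 + rng.normal(0.0, 1.0) * noise_fraction))

            row: dict[str, object] = {
                "animal_id": f"{group}_{a + 1}",
                "group": group,
                "body_weight": noisy(eff.body_weight_base
                                     * eff.body_weight_multipliers[group]),
            }
            for t in times:
                row[f"glucose_{t}"] = noisy(eff.ogtt_base[t]
                                            * eff.ogtt_multipliers[group])
            row["fasting_insulin"] = noisy(eff.insulin_base
                                           * eff.insulin_multipliers[group])
            ref_ct = eff.reference_ct + rng.normal(0.0, 1.0) * ct_noise_sd
            row[f"ct_{eff.reference_gene}"] = float(ref_ct)
            for gene, dct in eff.target_delta_ct.items():
                fold = eff.expression_fold[gene][group]
                ct = (ref_ct + dct - math.log2(fold)
                      + rng.normal(0.0, 1.0) * ct_noise_sd)
                row[f"ct_{gene}"] = float(ct)
            rows.append(row)
    return PhenotypeTable(pd.DataFrame(rows), tuple(groups))


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    universe: list[str],
    enriched_in: list[str] | None = None,
    n_sets: int = 20,
    set_size: int = 25,
    n_enriched: int = 2,
    enriched_overlap: float = 0.6,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over ``universe``, optionally with planted enrichment.

    The first ``n_enriched`` sets draw ``enriched_overlap`` of their members
    from ``enriched_in`` (e.g. the genes hosting planted DMRs) so the
    over-representation stage has signal to find.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    enriched_in = list(enriched_in or [])
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        if i < n_enriched and enriched_in:
            n_hit = min(int(round(enriched_overlap * set_size)),
                        len(enriched_in))
            hits = list(rng.choice(enriched_in, size=n_hit, replace=False))
            rest_pool = [g for g in universe if g not in hits]
            rest = list(rng.choice(rest_pool, size=set_size - n_hit,
                                   replace=False))
            members = frozenset(hits + rest)
            desc = "planted enriched set"
        else:
            members = frozenset(rng.choice(universe, size=set_size,
                                           replace=False))
            desc = "random set"
        sets[f"SET{i + 1:03d}"] = (desc, members)
    return GeneSetCollection(sets, frozenset(universe))
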