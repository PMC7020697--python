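"""DEP → gene annotation, genomic summaries and gene-set over-representation.

Annotation maps each differential peak to promoters by >= 1 bp interval
overlap (half-open coordinates); the study gene list is the deduplicated set
of mapped genes.  Over-representation is the upper-tail hypergeometric test
of a study list against user-supplied gene sets (GMT), with
Benjamini–Hochberg adjustment across all tested sets; the universe defaults
to the genes on the array, the standard background for array designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DifferentialPeak, GeneSetCollection, PromoterRecord


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    overlap: int  # k
    set_size: int  # K (within universe)
    study_size: int  # n
    universe_size: int  # N
    p_value: float
    p_adjusted: float = float("nan")

    @property
    def significant_go(self) -> bool:
        """GO-style call (adjusted P < 0.01)."""
        return self.p_adjusted < 0.01

    @property
    def significant_kegg(self) -> bool:
        """KEGG-style call (adjusted P < 0.05)."""
        return self.p_adjusted < 0.05


def map_deps_to_genes(
    deps: Sequence[DifferentialPeak],
    promoters: Sequence[PromoterRecord],
) -> tuple[list[DifferentialPeak], list[str], dict]:
    """Assign genes (and promoter CpG classes) to DEPs by interval overlap.

    A DEP overlapping two promoters gets both genes.  Unmapped DEPs are
    retained with an empty gene list.  Returns (annotated deps, unique gene
    list, summary counts).
    """
    by_chrom: dict[str, list[PromoterRecord]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    for recs in by_chrom.values():
        recs.sort(key=lambda r: r.start)

    genes: list[str] = []
    seen: set[str] = set()
    for dep in deps:
        dep.gene_ids = []
        dep.cpg_class = None
        for rec in by_chrom.get(dep.chrom, []):
            if rec.start < dep.end and dep.start < rec.end:
                dep.gene_ids.append(rec.gene_id)
                if dep.cpg_class is None:
                    dep.cpg_class = rec.cpg_class
                if rec.gene_id not in seen:
                    seen.add(rec.gene_id)
                    genes.append(rec.gene_id)
    summary = {
        "n_deps": len(deps),
        "n_mapped_deps": sum(1 for d in deps if d.gene_ids),
        "n_annotated_genes": len(genes),
        "n_chromosomes": len({d.chrom for d in deps}),
    }
    return list(deps), genes, summary


def chromosome_distribution(deps: Sequence[DifferentialPeak]) -> pd.DataFrame:
    """Per-chromosome hyper/hypo counts (rows sum to the DEP count)."""
    if not deps:
        return pd.DataFrame(columns=["hyper", "hypo"]).astype(int)
    frame = pd.DataFrame({"chrom": [d.chrom for d in deps],
                          "direction": [d.direction for d in deps]})
    table = (frame.value_counts(["chrom", "direction"]).unstack(fill_value=0)
             .reindex(columns=["hyper", "hypo"], fill_value=0))
    table.columns.name = None
    return table.sort_index()


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    ``q_i = min_{j >= i} (p_(j) * m / j)`` over the ascending order, capped
    at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def hypergeom_ora(
    study_genes: Iterable[str],
    collection: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation against every set.

    The study list is restricted to the collection universe (with a warning
    when genes are dropped); results are BH-adjusted across all tested sets
    and sorted by adjusted then raw p.
    """
    study = set(study_genes)
    if not study:
        raise ValueError("empty study gene list")
    universe = set(collection.universe)
    outside = study - universe
    if outside:
        warnings.warn(
            f"{len(outside)} study genes outside the universe were dropped",
            stacklevel=2,
        )
        study &= universe
        if not study:
            raise ValueError("no study genes left inside the universe")
    n_universe = len(universe)
    n_study = len(study)
    results = []
    for sid, (desc, members) in collection.sets.items():
        members = members & universe
        k = len(study & members)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_study))
        results.append(EnrichmentResult(sid, desc, k, big_k, n_study,
                                        n_universe, min(p, 1.0)))
    adjusted = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_id))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_id": r.set_id, "description": r.description,
        "overlap": r.overlap, "set_size": r.set_size,
        "study_size": r.study_size, "universe_size": r.universe_size,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "significant_go": r.significant_go,
        "significant_kegg": r.significant_kegg,
    } for r in results])
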