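"""Candidate-gene nomination and pathway enrichment.

Genes are nominated when they (a) pass the differential-expression
filter — FDR < 0.01 and a fold change of at least 2 in either direction
on the bulk-F / bulk-S ratio scale — and (b) overlap a called associated
region by at least 1 bp. Pathway enrichment of the DE gene set uses the
upper-tail hypergeometric test with Benjamini-Hochberg adjustment, and
the enrichment fold is the DE-set annotation proportion over the
background annotation proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneRecord, logger
from .scan import GenomicRegion

DEFAULT_MIN_FOLD = 2.0
DEFAULT_MAX_FDR = 0.01


@dataclass(frozen=True)
class CandidateGene:
    """A differentially expressed gene inside an associated region."""

    gene_id: str
    region_id: int
    chrom: str
    start: int
    end: int
    fold_change: float
    fdr: float
    direction: str


def filter_de(
    de: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> pd.DataFrame:
    """Keep genes with FDR < max_fdr and >= min_fold change either way.

    ``fold_change`` is on the F/S ratio scale; down-regulation in bulk F
    appears as fold_change <= 1/min_fold. Adds a ``direction`` column
    (up/down).
    """
    bad = de[de["fold_change"] <= 0]
    if not bad.empty:
        raise ValueError(f"non-positive fold change for gene {bad.iloc[0]['gene_id']!r}")
    fc = de["fold_change"].to_numpy(dtype=float)
    keep = (de["fdr"].to_numpy(dtype=float) < max_fdr) & ((fc >= min_fold) | (fc <= 1.0 / min_fold))
    out = de.loc[keep].copy()
    out["direction"] = np.where(out["fold_change"] >= min_fold, "up", "down")
    return out.reset_index(drop=True)


def intersect_genes(
    regions: list[GenomicRegion],
    genes: list[GeneRecord],
) -> dict[str, int]:
    """Assign genes to regions by >= 1 bp interval overlap.

    A gene overlapping several regions goes to the one with the larger
    overlap (ties broken toward the lower region id). Returns
    {gene_id: region_id}.
    """
    assignment: dict[str, int] = {}
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in sorted(regions, key=lambda r: r.region_id):
        by_chrom.setdefault(r.chrom, []).append(r)
    for g in genes:
        best_overlap = 0
        best_region = None
        for r in by_chrom.get(g.chrom, ()):
            overlap = min(g.end, r.end) - max(g.start, r.start) + 1
            if overlap >= 1 and overlap > best_overlap:
                best_overlap = overlap
                best_region = r.region_id
        if best_region is not None:
            assignment[g.gene_id] = best_region
    return assignment


def nominate(
    regions: list[GenomicRegion],
    genes: list[GeneRecord],
    de: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_fdr: float = DEFAULT_MAX_FDR,
) -> pd.DataFrame:
    """Candidate genes: the DE filter intersected with region membership.

    Returns one row per candidate (gene_id, region_id, chrom, start,
    end, fold_change, fdr, direction), sorted by region then position.
    """
    kept = filter_de(de, min_fold, max_fdr)
    gene_map = {g.gene_id: g for g in genes}
    missing = [gid for gid in kept["gene_id"] if gid not in gene_map]
    if missing:
        logger.warning("%d DE genes lack annotation coordinates and are excluded (e.g. %s)",
                       len(missing), missing[0])
    assignment = intersect_genes(regions, genes)
    rows = []
    for rec in kept.itertuples(index=False):
        g = gene_map.get(rec.gene_id)
        if g is None or g.gene_id not in assignment:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "region_id": assignment[g.gene_id],
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "fold_change": rec.fold_change,
                "fdr": rec.fdr,
                "direction": rec.direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "region_id", "chrom", "start", "end", "fold_change", "fdr", "direction"],
    )
    return out.sort_values(["region_id", "start"], kind="mergesort").reset_index(drop=True)


def region_candidate_counts(regions: list[GenomicRegion], candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-region counts of nominated DE genes (0 for empty regions)."""
    counts = candidates.groupby("region_id").size() if len(candidates) else pd.Series(dtype=int)
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "n_candidates": [int(counts.get(r.region_id, 0)) for r in regions],
        }
    )


def enrich(
    de_gene_ids,
    term2gene: pd.DataFrame,
    background,
) -> pd.DataFrame:
    """Per-term over-representation of the DE set in the background.

    ``background`` is either the background gene-id collection or its
    size N (in which case every term/DE gene is assumed drawn from it).
    For each term with n_term_genome background genes, of which
    n_term_de are in the n_de-gene DE set:

        fold = (n_term_de / n_de) / (n_term_genome / N)
        p    = P[X >= n_term_de],  X ~ Hypergeom(N, n_term_genome, n_de)
        q    = Benjamini-Hochberg adjusted p across terms

    Results are sorted by q ascending.
    """
    if isinstance(background, (int, np.integer)):
        n_bg = int(background)
        bg_set = None
    else:
        bg_set = set(background)
        n_bg = len(bg_set)
    de_set = set(de_gene_ids)
    if bg_set is not None and not de_set <= bg_set:
        extra = sorted(de_set - bg_set)
        raise ValueError(f"{len(extra)} DE genes not in background (e.g. {extra[0]!r})")
    n_de = len(de_set)
    if n_de == 0 or n_bg == 0:
        raise ValueError("empty DE set or background")

    rows = []
    for (term_id, term_name), grp in term2gene.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(grp["gene_id"])
        if bg_set is not None:
            term_genes &= bg_set
        n_term = len(term_genes)
        if n_term == 0:
            logger.warning("term %s has no background genes; skipped", term_id)
            continue
        n_hit = len(term_genes & de_set)
        fold = (n_hit / n_de) / (n_term / n_bg)
        p = float(hypergeom.sf(n_hit - 1, n_bg, n_term, n_de))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "n_term_genome": n_term,
                "n_de": n_de,
                "n_term_de": n_hit,
                "fold": fold,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "n_term_genome", "n_de", "n_term_de", "fold", "p"],
    )
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)


def keyword_filter(candidates: pd.DataFrame, annotations: dict[str, str], keywords) -> pd.DataFrame:
    """Optional screen of candidates whose annotation matches any keyword.

    Final shortlisting of candidates by functional annotation is a
    manual, judgement-based step; this helper only automates the obvious
    substring screen.
    """
    kws = [k.lower() for k in keywords]
    mask = [
        any(k in annotations.get(gid, "").lower() for k in kws) for gid in candidates["gene_id"]
    ]
    return candidates.loc[mask].reset_index(drop=True)
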