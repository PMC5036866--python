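"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally (VCF/GFF3
convention); only the BED export converts to 0-based half-open. Site
read counts travel as a pandas DataFrame with one row per SNP site and
columns ``chrom, pos, fA, fC, fG, fT, sA, sC, sG, sT`` (``f*`` = bulk F,
``s*`` = bulk S), sorted by (chrom, pos) with natural chromosome order
and no duplicate sites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bsrscan")

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: column layout of the normalized site-count frame
COUNT_COLUMNS = ["chrom", "pos", "fA", "fC", "fG", "fT", "sA", "sC", "sG", "sT"]
F_COLS = ["fA", "fC", "fG", "fT"]
S_COLS = ["sA", "sC", "sG", "sT"]

DEFAULT_MIN_DEPTH = 3


@dataclass(frozen=True)
class BulkBaseCounts:
    """A/C/G/T read counts for one SNP site in the two bulks."""

    chrom: str
    pos: int
    counts_f: tuple[int, int, int, int]
    counts_s: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if min(self.counts_f) < 0 or min(self.counts_s) < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


def natural_chrom_key(name: str) -> tuple:
    """Sort key giving natural order: chr1 < chr2 < chr10 < chrX."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def normalize_counts(df: pd.DataFrame, chrom_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Sort by (chrom, pos) and drop duplicate sites (last record wins).

    Chromosomes are ordered naturally unless an explicit ``chrom_order``
    list is given.
    """
    n_dup = int(df.duplicated(subset=["chrom", "pos"]).sum())
    if n_dup:
        logger.warning("dropping %d duplicate (chrom, pos) records (last wins)", n_dup)
        df = df.drop_duplicates(subset=["chrom", "pos"], keep="last")
    if chrom_order is not None:
        rank = {c: i for i, c in enumerate(chrom_order)}
        missing = set(df["chrom"]) - set(rank)
        if missing:
            raise ValueError(f"chromosomes not in supplied order list: {sorted(missing)}")
        key = df["chrom"].map(rank)
    else:
        uniq = sorted(df["chrom"].unique(), key=natural_chrom_key)
        key = df["chrom"].map({c: i for i, c in enumerate(uniq)})
    df = df.assign(_ck=key).sort_values(["_ck", "pos"], kind="mergesort")
    return df.drop(columns="_ck").reset_index(drop=True)


def apply_depth_filter(df: pd.DataFrame, min_depth: int) -> pd.DataFrame:
    """Drop sites where either bulk's total depth is below ``min_depth``.

    Applied to each bulk separately: a site must have >= min_depth reads
    in bulk F AND in bulk S. Kept counts are never altered.
    """
    depth_f = df[F_COLS].sum(axis=1)
    depth_s = df[S_COLS].sum(axis=1)
    keep = (depth_f >= min_depth) & (depth_s >= min_depth)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("depth filter (min_depth=%d): dropped %d of %d sites", min_depth, n_drop, len(df))
    return df.loc[keep].reset_index(drop=True)


def read_vcf_counts(
    vcf_path: str | Path,
    bulk_f_sample: str,
    bulk_s_sample: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    chrom_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read per-bulk allelic depths from a VCF into the site-count frame.

    The VCF must carry the two named samples with a per-sample ``AD``
    field. Allelic depths are mapped onto the A/C/G/T slots by the
    REF/ALT base letters; indel and symbolic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for name in (bulk_f_sample, bulk_s_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF; available samples: {samples}")
    i_f = samples.index(bulk_f_sample)
    i_s = samples.index(bulk_s_sample)

    rows = []
    n_skipped = n_no_ad = 0
    for v in vcf:
        alleles = [v.REF] + list(v.ALT)
        if len(alleles) > 4 or any(len(a) != 1 or a not in BASE_INDEX for a in alleles):
            n_skipped += 1
            continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            n_no_ad += 1
            continue
        cf = np.zeros(4, dtype=np.int64)
        cs = np.zeros(4, dtype=np.int64)
        for j, a in enumerate(alleles):
            cf[BASE_INDEX[a]] += max(int(ad[i_f][j]), 0)
            cs[BASE_INDEX[a]] += max(int(ad[i_s][j]), 0)
        rows.append((v.CHROM, v.POS, *cf, *cs))
    if n_skipped:
        logger.info("skipped %d non-SNP records", n_skipped)
    if n_no_ad:
        logger.warning("skipped %d sites lacking the AD field", n_no_ad)
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    if df.empty:
        logger.warning("no SNP sites read from %s", vcf_path)
        df = df.astype({c: np.int64 for c in COUNT_COLUMNS[1:]} | {"chrom": str})
    return apply_depth_filter(normalize_counts(df, chrom_order), min_depth)


def read_counts_table(
    tsv_path: str | Path,
    min_depth: int = DEFAULT_MIN_DEPTH,
    chrom_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read the native tab-separated base-count table.

    Expected header: ``chrom pos fA fC fG fT sA sC sG sT``. Lines
    starting with ``#`` are ignored.
    """
    try:
        df = pd.read_csv(
            tsv_path,
            sep="\t",
            comment="#",
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed count table {tsv_path}: {exc}") from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {tsv_path} lacks columns {missing}")
    df = df[COUNT_COLUMNS]
    for col in COUNT_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any():
            line = int(np.flatnonzero(vals.isna() | (vals % 1 != 0))[0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"malformed count table {tsv_path}: non-integer {col!r} at line {line}")
        df[col] = vals.astype(np.int64)
    if (df[F_COLS + S_COLS].to_numpy() < 0).any():
        raise ValueError(f"negative counts in {tsv_path}")
    if df.empty:
        logger.warning("count table %s is empty", tsv_path)
    return apply_depth_filter(normalize_counts(df, chrom_order), min_depth)


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the site-count frame as TSV (round-trips with read_counts_table)."""
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gff_genes(gff3_path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Extract gene features from a GFF3 file.

    Gene IDs come from the ``ID`` attribute; duplicate IDs are fatal,
    features without an ID are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_no_id = 0
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            n_no_id += 1
            continue
        if gid in seen:
            raise ValueError(f"duplicate gene ID {gid!r} in {gff3_path}")
        seen.add(gid)
        genes.append(GeneRecord(gid, feat.seqid, feat.start, feat.end, feat.strand or "."))
    if n_no_id:
        logger.warning("skipped %d %s features without an ID attribute", n_no_id, feature_type)
    if not genes:
        logger.warning("no %s features found in %s", feature_type, gff3_path)
    genes.sort(key=lambda g: (natural_chrom_key(g.chrom), g.start))
    return genes


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table.

    Accepts either a signed ratio (``fold_change`` alone, F/S ratio scale,
    down-regulation < 1) or a (magnitude, direction) pair as printed in
    typical DE reports (``fold_change`` >= 1 plus a ``regulated`` column
    of up/down), which is converted to the ratio scale.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    need = {"gene_id", "fold_change", "fdr"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} lacks columns {sorted(missing)}")
    df["fold_change"] = df["fold_change"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    bad = df[(df["fold_change"] <= 0)]
    if not bad.empty:
        raise ValueError(f"non-positive fold change for gene {bad.iloc[0]['gene_id']!r}")
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise ValueError(f"FDR outside [0, 1] in {path}")
    if "regulated" in df.columns:
        down = df["regulated"].astype(str).str.lower() == "down"
        df.loc[down, "fold_change"] = 1.0 / df.loc[down, "fold_change"]
        df = df.drop(columns="regulated")
    return df.reset_index(drop=True)


def read_term2gene(path: str | Path) -> pd.DataFrame:
    """Read a term-to-gene mapping TSV (term_id, gene_id [, term_name])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = {"term_id", "gene_id"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"term2gene table {path} lacks columns {sorted(missing)}")
    if "term_name" not in df.columns:
        df["term_name"] = ""
    return df.drop_duplicates(subset=["term_id", "gene_id"]).reset_index(drop=True)


def write_regions_bed(regions: Iterable, path: str | Path, track_name: str = "bsrscan_regions") -> None:
    """Write called regions as BED4+ (0-based half-open; score = scaled peak).

    The score column is the region's peak smoothed statistic scaled by
    1000 and clamped to [0, 1000] as the BED spec requires.
    """
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for r in regions:
            score = int(np.clip(round(r.peak_value * 1000), 0, 1000))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t{score}\n")
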