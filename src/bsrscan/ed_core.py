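"""The per-SNP Euclidean-distance (ED) statistic between two bulks.

At each SNP site the A/C/G/T read counts of each bulk are turned into an
allele-frequency vector, and the ED between the bulks is

    ED = sqrt((A_F - A_S)^2 + (C_F - C_S)^2 + (G_F - G_S)^2 + (T_F - T_S)^2)

where e.g. A_F is the frequency of base A in bulk F. ED lies in
[0, sqrt(2)]; it is 0 when the bulks have identical frequencies and
sqrt(2) when they are fixed for disjoint bases. Raising ED to a power k
(default 5) suppresses small sampling fluctuations while preserving the
ranking of sites.

Frequencies are simple maximum-likelihood proportions (count / total);
no pseudocounts are applied — low-coverage sites are handled upstream by
the per-bulk depth filter instead.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import F_COLS, S_COLS

DEFAULT_POWER = 5

#: column layout of the per-SNP ED profile frame
PROFILE_COLUMNS = ["chrom", "pos", "depth_f", "depth_s", "ed", "ed_k", "smoothed"]


def allele_frequencies(counts) -> np.ndarray:
    """Base frequencies (A, C, G, T) of one bulk at one site.

    ``counts`` is a length-4 sequence of non-negative integers; the site
    must have at least one read (zero-depth sites are filtered upstream).
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,):
        raise ValueError(f"expected 4 base counts, got shape {c.shape}")
    if (c < 0).any():
        raise ValueError("negative base count")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero counts: site should have been depth-filtered")
    return c / total


def euclidean_distance(freq_f, freq_s) -> float:
    """ED between the two bulks' four-base frequency vectors."""
    f = np.asarray(freq_f, dtype=float)
    s = np.asarray(freq_s, dtype=float)
    if f.shape != (4,) or s.shape != (4,):
        raise ValueError("frequency vectors must have length 4")
    for v in (f, s):
        if not math.isclose(v.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"frequencies must sum to 1, got {v.sum()!r}")
    return float(np.sqrt(((f - s) ** 2).sum()))


def ed_power(ed: float, k: int = DEFAULT_POWER) -> float:
    """ED^k, the noise-suppressing power transform (monotone for k >= 1)."""
    if k < 1:
        raise ValueError(f"power k must be >= 1, got {k}")
    if np.any(np.asarray(ed) < 0):
        raise ValueError("ED must be non-negative")
    return ed**k


def build_profile(counts: pd.DataFrame, k: int = DEFAULT_POWER) -> pd.DataFrame:
    """Compute the genome-ordered ED profile from a site-count frame.

    Returns one row per site, in input order, with columns
    ``chrom, pos, depth_f, depth_s, ed, ed_k, smoothed`` — ``smoothed``
    is NaN until filled by :func:`bsrscan.smoothing.sliding_median`.
    Input must already be sorted by (chrom, pos).
    """
    _check_sorted(counts)
    cf = counts[F_COLS].to_numpy(dtype=float)
    cs = counts[S_COLS].to_numpy(dtype=float)
    depth_f = cf.sum(axis=1)
    depth_s = cs.sum(axis=1)
    if len(counts) and (min(depth_f.min(), depth_s.min()) == 0):
        raise ValueError("zero-depth site in input: apply the depth filter first")
    with np.errstate(invalid="ignore"):
        ff = cf / depth_f[:, None]
        fs = cs / depth_s[:, None]
    ed = np.sqrt(((ff - fs) ** 2).sum(axis=1))
    return pd.DataFrame(
        {
            "chrom": counts["chrom"].to_numpy(),
            "pos": counts["pos"].to_numpy(),
            "depth_f": depth_f.astype(np.int64),
            "depth_s": depth_s.astype(np.int64),
            "ed": ed,
            "ed_k": ed_power(ed, k),
            "smoothed": np.full(len(counts), np.nan),
        }
    )


def _check_sorted(df: pd.DataFrame) -> None:
    """Sites must be grouped by chromosome with strictly increasing pos.

    Chromosome blocks may appear in any order (an explicit order list can
    be applied upstream); a chromosome split into two blocks, or a
    non-increasing position within a block, is a sorting error.
    """
    if df.empty:
        return
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    block_starts = np.concatenate(([0], boundaries))
    block_chroms = chroms[block_starts]
    if len(set(block_chroms)) != len(block_chroms):
        raise ValueError("input sites are not sorted by (chrom, pos)")
    for start, stop in zip(block_starts, np.append(boundaries, len(df))):
        if stop - start > 1 and not (np.diff(pos[start:stop]) > 0).all():
            raise ValueError("input sites are not sorted by (chrom, pos)")


def write_profile_table(profile: pd.DataFrame, path, significant=None, header_lines=()) -> None:
    """Write the ED profile as TSV, optionally with a significance column."""
    out = profile.copy()
    if significant is not None:
        out["significant"] = np.asarray(significant, dtype=int)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
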