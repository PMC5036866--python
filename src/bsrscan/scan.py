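"""Significance threshold and associated-region calling.

The genome-wide empirical q-quantile (default q = 0.99) of the smoothed
ED^k values is taken as the significance cutoff; sites at or above the
cutoff are flagged, and maximal runs of flagged sites (per chromosome,
optionally bridging short gaps) become associated genomic regions whose
boundaries are the first and last member-SNP positions. Region size is
end - start in bp.

The threshold can alternatively be computed on the raw (unsmoothed)
ED^k track via ``threshold_source="raw"`` — a per-dot cutoff rather
than a fitted-curve cutoff; both conventions appear in the BSA
literature and tiny single-SNP regions are typically raw-mode artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ed_core import DEFAULT_POWER
from .io_formats import DEFAULT_MIN_DEPTH
from .smoothing import DEFAULT_HALF_WINDOW

_SOURCE_COL = {"smoothed": "smoothed", "raw": "ed_k"}


@dataclass(frozen=True)
class GenomicRegion:
    """A called associated interval: a run of significant member SNPs."""

    region_id: int
    chrom: str
    start: int  # bp of first member SNP, 1-based
    end: int  # bp of last member SNP
    n_snps: int
    peak_value: float  # max track value among members
    peak_pos: int  # bp of that max

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak_pos outside region")
        if self.n_snps < 1:
            raise ValueError("region must contain at least one SNP")

    @property
    def size(self) -> int:
        return region_size(self)


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the ED scan, defaulting to the standard analysis."""

    quantile: float = 0.99
    power: int = DEFAULT_POWER
    half_window: int = DEFAULT_HALF_WINDOW
    threshold_source: str = "smoothed"
    max_gap_snps: int = 0
    min_region_snps: int = 1
    min_depth: int = DEFAULT_MIN_DEPTH

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.threshold_source not in _SOURCE_COL:
            raise ValueError(f"threshold_source must be one of {sorted(_SOURCE_COL)}")

    def to_dict(self) -> dict:
        return asdict(self)


def significance_threshold(profile: pd.DataFrame, q: float = 0.99, source: str = "smoothed") -> float:
    """Empirical q-quantile of the chosen genome-wide track.

    Linear interpolation between adjacent order statistics at rank
    1 + q(n-1), so at most a fraction (1-q) of values strictly exceed
    the cutoff.
    """
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    vals = profile[_SOURCE_COL[source]].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("cannot take a quantile of an empty profile")
    if np.isnan(vals).any():
        raise ValueError(f"{source} track contains NaN (run smoothing first?)")
    return float(np.quantile(vals, q, method="linear"))


def flag_significant(profile: pd.DataFrame, cutoff: float, source: str = "smoothed") -> np.ndarray:
    """Boolean per-site flags: track value >= cutoff (boundary inclusive)."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return profile[_SOURCE_COL[source]].to_numpy(dtype=float) >= cutoff


def call_regions(
    profile: pd.DataFrame,
    flags: np.ndarray,
    max_gap_snps: int = 0,
    min_region_snps: int = 1,
    source: str = "smoothed",
) -> list[GenomicRegion]:
    """Merge runs of significant SNPs into associated genomic regions.

    Runs are maximal within each chromosome's SNP order and may bridge
    up to ``max_gap_snps`` consecutive non-significant sites; runs
    shorter than ``min_region_snps`` members are dropped. Regions are
    returned sorted by (chromosome appearance order, start) and numbered
    1..n.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(profile):
        raise ValueError("flags not aligned to profile")
    track = profile[_SOURCE_COL[source]].to_numpy(dtype=float)
    pos = profile["pos"].to_numpy()
    regions: list[GenomicRegion] = []
    for chrom, idx in profile.groupby("chrom", sort=False).indices.items():
        sig = np.flatnonzero(flags[idx])
        if sig.size == 0:
            continue
        # split where the gap between consecutive significant SNPs
        # exceeds max_gap_snps intervening sites
        breaks = np.flatnonzero(np.diff(sig) > max_gap_snps + 1) + 1
        for run in np.split(sig, breaks):
            if run.size < min_region_snps:
                continue
            members = idx[run]
            peak_local = members[int(np.argmax(track[members]))]
            regions.append(
                GenomicRegion(
                    region_id=0,
                    chrom=str(chrom),
                    start=int(pos[members[0]]),
                    end=int(pos[members[-1]]),
                    n_snps=int(run.size),
                    peak_value=float(track[peak_local]),
                    peak_pos=int(pos[peak_local]),
                )
            )
    return [
        GenomicRegion(i + 1, r.chrom, r.start, r.end, r.n_snps, r.peak_value, r.peak_pos)
        for i, r in enumerate(regions)
    ]


def region_size(region) -> int:
    """Region size in bp under the end - start convention."""
    return int(region.end) - int(region.start)


def regions_to_frame(regions: list[GenomicRegion]) -> pd.DataFrame:
    """Tabulate called regions (region_id, chrom, start, end, ...)."""
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "peak_pos": r.peak_pos,
                "peak_value": r.peak_value,
                "size": r.size,
            }
            for r in regions
        ],
        columns=["region_id", "chrom", "start", "end", "n_snps", "peak_pos", "peak_value", "size"],
    )


def write_regions_table(regions: list[GenomicRegion], path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        regions_to_frame(regions).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_regions_table(path) -> list[GenomicRegion]:
    """Read back a regions TSV written by :func:`write_regions_table`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return [
        GenomicRegion(
            region_id=int(r.region_id),
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            n_snps=int(r.n_snps),
            peak_value=float(r.peak_value),
            peak_pos=int(r.peak_pos),
        )
        for r in df.itertuples(index=False)
    ]


def plot_scan(
    profile: pd.DataFrame,
    cutoff: float,
    regions: list[GenomicRegion] | None = None,
    path=None,
    chrom: str | None = None,
):
    """Genome-wide dot track of ED^k with the fitted curve and threshold.

    With ``chrom`` set, renders a close-up of one chromosome against
    physical position instead of the concatenated genome view.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = profile if chrom is None else profile[profile["chrom"] == chrom]
    fig, ax = plt.subplots(figsize=(10, 3.2))
    if chrom is None:
        x = np.arange(len(data))
        offsets = {}
        for c, idx in data.groupby("chrom", sort=False).indices.items():
            offsets[c] = (idx.min() + idx.max()) / 2
            ax.axvline(idx.max() + 0.5, color="0.8", ls=":", lw=0.6)
        for c, idx in data.groupby("chrom", sort=False).indices.items():
            ax.scatter(x[idx], data["ed_k"].to_numpy()[idx], s=2, alpha=0.5)
        ax.set_xticks(list(offsets.values()), list(offsets.keys()))
        ax.set_xlabel("chromosome (SNP index)")
    else:
        x = data["pos"].to_numpy() / 1e6
        ax.scatter(x, data["ed_k"], s=2, alpha=0.5, color="0.5")
        ax.set_xlabel(f"{chrom} position (Mb)")
    if data["smoothed"].notna().all():
        ax.plot(x, data["smoothed"], color="C3", lw=1.2, label="median fit")
    ax.axhline(cutoff, color="magenta", ls="--", lw=1, label=f"cutoff {cutoff:.4g}")
    if regions:
        for r in regions:
            if chrom is not None and r.chrom != chrom:
                continue
            if chrom is not None:
                ax.axvspan(r.start / 1e6, r.end / 1e6, color="C1", alpha=0.15)
    ax.set_ylabel("ED$^k$")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
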