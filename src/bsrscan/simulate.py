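"""Synthetic bulked-segregant data generator with ground truth.

Emulates an advanced-backcross (BC) near-isogenic mapping design: a
parent heterozygous for a donor haplotype is backcrossed to a recurrent
inbred, so each progeny inherits one recombinant gamete from the
heterozygous parent on the segregating chromosome(s) and is otherwise
fixed for the recurrent genome. Individuals carrying the donor allele
at every causal locus express the rescued phenotype (subject to a
penetrance parameter) and are pooled into bulk F; non-carriers form
bulk S. At a marker, carrier individuals are heterozygous (donor dosage
0.5) and non-carriers homozygous recurrent (dosage 0), so with full
penetrance the expected donor-allele frequencies are 0.5 in bulk F and
0 in bulk S at a fully linked marker — an ED of 1/sqrt(2) ~ 0.7071 and
an ED^5 of 0.17678.

Recombination follows the Haldane model: crossover counts are Poisson
with mean equal to the map length in Morgans (length_Mb x cM_per_Mb /
100), positions uniform, no interference. Pooled sequencing draws a
Poisson read depth per marker per bulk and assigns each read a base from
the bulk's allele frequency with a uniform miscall probability.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import BASES, COUNT_COLUMNS, GeneRecord, logger

# Guard against impossible bulk compositions (e.g. penetrance ~ 0 with a
# causal locus): give up after this many simulated individuals.
_MAX_INDIVIDUALS_FACTOR = 2000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic BC bulked-segregant design.

    Defaults emulate the study conditions: two bulks of 30 individuals,
    pooled sequencing at mean depth 50x per marker per bulk, 0.1%
    base-calling error, full penetrance and clean bulk assignment.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 150_000_000), ("chr2", 150_000_000))
    cm_per_mb: float = 1.0
    n_markers: int = 5000  # per chromosome
    marker_placement: str = "random"  # random | grid
    causal_loci: tuple[tuple[str, int], ...] = ()
    bulk_size: int = 30
    depth: float = 50.0
    depth_mode: str = "poisson"  # poisson | fixed
    base_error: float = 0.001
    penetrance: float = 1.0
    misclassification: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("penetrance", self.penetrance),
                        ("misclassification", self.misclassification),
                        ("base_error", self.base_error)):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.marker_placement not in ("random", "grid"):
            raise ValueError("marker_placement must be 'random' or 'grid'")
        if self.depth_mode not in ("poisson", "fixed"):
            raise ValueError("depth_mode must be 'poisson' or 'fixed'")
        chrom_names = [c for c, _ in self.chromosomes]
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("duplicate chromosome names")
        for chrom, pos in self.causal_loci:
            length = dict(self.chromosomes).get(chrom)
            if length is None:
                raise ValueError(f"causal locus on unknown chromosome {chrom!r}")
            if not 1 <= pos <= length:
                raise ValueError(f"causal position {pos} outside {chrom} (1..{length})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        d["causal_loci"] = [list(c) for c in self.causal_loci]
        return d


@dataclass
class Gamete:
    """One recombinant gamete: alternating donor/recurrent segments.

    ``starts[i]`` is the 1-based start of segment i; segment i extends
    to starts[i+1]-1 (or the chromosome end) and is donor-derived where
    ``donor[i]`` is True. Segments tile [1, length].
    """

    starts: np.ndarray
    donor: np.ndarray
    length: int

    def dosage_at(self, pos) -> np.ndarray:
        """Donor-allele dosage (0 or 0.5) of a BC individual at pos."""
        idx = np.searchsorted(self.starts, np.atleast_1d(pos), side="right") - 1
        return np.where(self.donor[idx], 0.5, 0.0)

    def donor_intervals(self) -> list[tuple[int, int]]:
        ends = np.append(self.starts[1:] - 1, self.length)
        return [(int(s), int(e)) for s, e, d in zip(self.starts, ends, self.donor) if d]


@dataclass
class Individual:
    """One BC progeny: a gamete per segregating chromosome."""

    gametes: dict[str, Gamete]
    carrier: bool = False
    phenotype_positive: bool = False

    def dosage_at(self, chrom: str, pos) -> np.ndarray:
        g = self.gametes.get(chrom)
        if g is None:
            return np.zeros(np.atleast_1d(pos).shape)
        return g.dosage_at(pos)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset, for recovery testing."""

    causal_loci: tuple[tuple[str, int], ...]
    bulk_f: list[Individual] = field(default_factory=list)
    bulk_s: list[Individual] = field(default_factory=list)
    planted_de_genes: list[str] = field(default_factory=list)


def simulate_meiosis(length_bp: int, cm_per_mb: float, rng: np.random.Generator) -> Gamete:
    """One gamete from a chromosome-wide heterozygous parent (Haldane).

    Crossover count ~ Poisson(length_Mb x cM_per_Mb / 100 Morgans),
    positions uniform, starting phase a fair coin.
    """
    if length_bp <= 0:
        raise ValueError("chromosome length must be > 0")
    morgans = (length_bp / 1e6) * cm_per_mb / 100.0
    n_x = rng.poisson(morgans)
    xpos = rng.integers(2, length_bp + 1, size=n_x) if n_x else np.empty(0, dtype=np.int64)
    # coincident crossovers cancel pairwise: keep odd-multiplicity breakpoints
    uniq, mult = np.unique(xpos, return_counts=True)
    xpos = uniq[mult % 2 == 1]
    starts = np.concatenate(([1], xpos)).astype(np.int64)
    phase0 = bool(rng.random() < 0.5)
    donor = np.zeros(len(starts), dtype=bool)
    donor[0] = phase0
    donor[1:] = phase0 ^ (np.arange(1, len(starts)) % 2).astype(bool)
    return Gamete(starts=starts, donor=donor, length=int(length_bp))


def _segregating_chromosomes(config: SimConfig) -> list[tuple[str, int]]:
    if not config.causal_loci:
        # null design: every chromosome segregates, bulks are random splits
        return list(config.chromosomes)
    causal_chroms = {c for c, _ in config.causal_loci}
    return [(c, l) for c, l in config.chromosomes if c in causal_chroms]


def _new_individual(config: SimConfig, rng: np.random.Generator) -> Individual:
    gametes = {
        chrom: simulate_meiosis(length, config.cm_per_mb, rng)
        for chrom, length in _segregating_chromosomes(config)
    }
    ind = Individual(gametes=gametes)
    if config.causal_loci:
        ind.carrier = all(
            float(ind.dosage_at(chrom, pos)[0]) > 0 for chrom, pos in config.causal_loci
        )
        ind.phenotype_positive = ind.carrier and (rng.random() < config.penetrance)
    return ind


def simulate_population(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    """Fill the two bulks from an adaptively sized BC population.

    Bulk F takes phenotype-positive individuals (donor carriers at every
    causal locus expressing the phenotype), bulk S phenotype-negative
    ones; misclassification then swaps each pair of slots independently
    with the configured probability. With no causal locus the bulks are
    a random partition of 2 x bulk_size individuals.
    """
    truth = SimTruth(causal_loci=config.causal_loci)
    if not config.causal_loci:
        inds = [_new_individual(config, rng) for _ in range(2 * config.bulk_size)]
        order = rng.permutation(len(inds))
        truth.bulk_f = [inds[i] for i in order[: config.bulk_size]]
        truth.bulk_s = [inds[i] for i in order[config.bulk_size:]]
        return truth
    cap = _MAX_INDIVIDUALS_FACTOR * config.bulk_size
    n_tried = 0
    while (len(truth.bulk_f) < config.bulk_size or len(truth.bulk_s) < config.bulk_size):
        if n_tried >= cap:
            raise RuntimeError(
                f"could not fill bulks after {cap} individuals "
                f"(penetrance={config.penetrance}); the design is infeasible"
            )
        ind = _new_individual(config, rng)
        n_tried += 1
        if ind.phenotype_positive and len(truth.bulk_f) < config.bulk_size:
            truth.bulk_f.append(ind)
        elif not ind.phenotype_positive and len(truth.bulk_s) < config.bulk_size:
            truth.bulk_s.append(ind)
    if config.misclassification > 0:
        for i in range(config.bulk_size):
            if rng.random() < config.misclassification:
                truth.bulk_f[i], truth.bulk_s[i] = truth.bulk_s[i], truth.bulk_f[i]
    return truth


def place_markers(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Marker map: positions plus recurrent/donor bases per marker.

    ``n_markers`` per chromosome, uniformly random (default) or on an
    even grid; every marker distinguishes the parents (distinct
    recurrent and donor bases drawn at random).
    """
    frames = []
    for chrom, length in config.chromosomes:
        if config.marker_placement == "grid":
            pos = np.linspace(1, length, config.n_markers, dtype=np.int64)
            pos = np.unique(pos)
        else:
            # rejection-free enough: collisions among n << length are rare
            pos = np.unique(rng.integers(1, length + 1, size=config.n_markers))
            while len(pos) < config.n_markers:
                extra = rng.integers(1, length + 1, size=config.n_markers - len(pos))
                pos = np.unique(np.concatenate([pos, extra]))
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref_base": np.array(BASES)[ref_idx],
                    "alt_base": np.array(BASES)[alt_idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _bulk_frequencies(bulk: list[Individual], markers: pd.DataFrame) -> np.ndarray:
    """Per-marker donor-allele frequency in one pooled bulk."""
    freq = np.zeros(len(markers))
    for chrom, idx in markers.groupby("chrom", sort=False).indices.items():
        pos = markers["pos"].to_numpy()[idx]
        dos = np.zeros(len(pos))
        for ind in bulk:
            dos += ind.dosage_at(str(chrom), pos)
        freq[idx] = dos / len(bulk)
    return freq


def pool_and_sequence(
    truth: SimTruth,
    markers: pd.DataFrame,
    depth: float,
    base_error: float,
    rng: np.random.Generator,
    depth_mode: str = "poisson",
) -> pd.DataFrame:
    """Sequence both pooled bulks: the site-count frame of the pipeline.

    Per marker per bulk, the read count is Poisson(depth) (or exactly
    ``depth`` in fixed mode); each read carries the donor base with
    probability equal to the bulk's pooled donor-allele frequency and is
    then miscalled with probability ``base_error``, uniformly over the
    other three bases.
    """
    n = len(markers)
    ref_idx = np.array([BASES.index(b) for b in markers["ref_base"]])
    alt_idx = np.array([BASES.index(b) for b in markers["alt_base"]])
    out = {"chrom": markers["chrom"].to_numpy(), "pos": markers["pos"].to_numpy(dtype=np.int64)}
    for label, bulk in (("f", truth.bulk_f), ("s", truth.bulk_s)):
        freq = _bulk_frequencies(bulk, markers)
        if depth_mode == "fixed":
            n_reads = np.full(n, int(round(depth)))
        else:
            n_reads = rng.poisson(depth, size=n)
        # observed-base probabilities: true base -> uniform miscall model
        pvals = np.full((n, 4), base_error / 3.0)
        rows = np.arange(n)
        pvals[rows, alt_idx] = freq * (1 - base_error) + (1 - freq) * base_error / 3.0
        pvals[rows, ref_idx] = (1 - freq) * (1 - base_error) + freq * base_error / 3.0
        counts = rng.multinomial(n_reads, pvals)
        for j, base in enumerate(BASES):
            out[f"{label}{base}"] = counts[:, j].astype(np.int64)
    return pd.DataFrame(out)[COUNT_COLUMNS]


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """End-to-end generation: (site counts, marker map, truth)."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_population(config, rng)
    markers = place_markers(config, rng)
    counts = pool_and_sequence(truth, markers, config.depth, config.base_error, rng,
                               config.depth_mode)
    return counts, markers, truth


def simulate_de_table(
    truth_regions: list[tuple[str, int, int]],
    chromosomes: tuple[tuple[str, int], ...],
    rng: np.random.Generator,
    n_genes: int = 500,
    n_planted: int = 12,
    n_decoys: int = 0,
    gene_length: int = 3000,
    planted_fold_range: tuple[float, float] = (2.0, 20.0),
    planted_max_fdr: float = 1e-3,
) -> tuple[list[GeneRecord], pd.DataFrame, list[str]]:
    """Companion gene-annotation + DE-table fixture with planted truth.

    Places ``n_genes`` background genes uniformly on the genome with
    null expression statistics (fold change near 1, FDR >= 0.05),
    ``n_planted`` differentially expressed genes (fold >= 2, FDR below
    ``planted_max_fdr``) inside the given truth regions, and optionally
    ``n_decoys`` strongly DE genes guaranteed OUTSIDE every truth
    region. Returns (genes, de_table, planted_gene_ids).
    """
    if n_planted and not truth_regions:
        raise ValueError("cannot plant DE genes without truth regions")
    genes: list[GeneRecord] = []
    rows = []
    planted_ids: list[str] = []

    def in_truth(chrom, start, end) -> bool:
        return any(c == chrom and start <= re and rs <= end for c, rs, re in truth_regions)

    chrom_arr = [c for c, _ in chromosomes]
    len_by_chrom = dict(chromosomes)
    k = 0
    made_bg = 0
    while made_bg < n_genes:
        chrom = chrom_arr[rng.integers(len(chrom_arr))]
        start = int(rng.integers(1, max(2, len_by_chrom[chrom] - gene_length)))
        end = start + gene_length - 1
        if in_truth(chrom, start, end):
            continue  # background genes stay outside truth regions
        k += 1
        gid = f"GENE{k:05d}"
        genes.append(GeneRecord(gid, chrom, start, end, "+" if rng.random() < 0.5 else "-"))
        fc = float(np.exp(rng.normal(0.0, 0.2)))
        rows.append({"gene_id": gid, "fold_change": fc, "fdr": float(rng.uniform(0.05, 1.0))})
        made_bg += 1
    for i in range(n_planted):
        chrom, rs, re_ = truth_regions[i % len(truth_regions)]
        start = int(rng.integers(rs, max(rs + 1, re_ - gene_length)))
        end = min(start + gene_length - 1, re_)
        k += 1
        gid = f"GENE{k:05d}"
        genes.append(GeneRecord(gid, chrom, start, end, "+"))
        fc = float(rng.uniform(*planted_fold_range))
        rows.append({"gene_id": gid, "fold_change": fc,
                     "fdr": float(10 ** rng.uniform(-12, np.log10(planted_max_fdr)))})
        planted_ids.append(gid)
    made = 0
    while made < n_decoys:
        chrom = chrom_arr[rng.integers(len(chrom_arr))]
        start = int(rng.integers(1, max(2, len_by_chrom[chrom] - gene_length)))
        end = start + gene_length - 1
        if in_truth(chrom, start, end):
            continue
        k += 1
        gid = f"GENE{k:05d}"
        genes.append(GeneRecord(gid, chrom, start, end, "-"))
        rows.append({"gene_id": gid, "fold_change": float(rng.uniform(5, 30)),
                     "fdr": float(10 ** rng.uniform(-12, -4))})
        made += 1
    genes.sort(key=lambda g: (g.chrom, g.start))
    de = pd.DataFrame(rows, columns=["gene_id", "fold_change", "fdr"])
    return genes, de, planted_ids


# ---------------------------------------------------------------------------
# fixture writers


def write_vcf(counts: pd.DataFrame, markers: pd.DataFrame, path: str | Path,
              chromosomes=None, seed: int | None = None) -> None:
    """Write the simulated site counts as a minimal VCF 4.2.

    Two samples F and S with per-sample DP and AD over [REF, ALT];
    ref/alt bases come from the marker map. Counts on the two
    non-allelic bases (miscalls) are not representable in a biallelic
    record and are omitted from AD, matching what a variant caller
    would emit.
    """
    m = markers.set_index(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsrscan-simulate\n")
        if seed is not None:
            fh.write(f"##bsrscan_seed={seed}\n")
        if chromosomes:
            for chrom, length in chromosomes:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tS\n")
        for rec in counts.itertuples(index=False):
            ref, alt = m.loc[(rec.chrom, rec.pos), ["ref_base", "alt_base"]]
            i_ref, i_alt = BASES.index(ref), BASES.index(alt)
            cf = [rec.fA, rec.fC, rec.fG, rec.fT]
            cs = [rec.sA, rec.sC, rec.sG, rec.sT]
            ad_f = f"{cf[i_ref]},{cf[i_alt]}"
            ad_s = f"{cs[i_ref]},{cs[i_alt]}"
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{ref}\t{alt}\t.\tPASS\tNS=2\tDP:AD\t"
                f"{sum(cf)}:{ad_f}\t{sum(cs)}:{ad_s}\n"
            )


def write_truth_table(truth: SimTruth, path: str | Path) -> None:
    """Tabulate the ground truth: causal loci and per-individual state."""
    with open(path, "w") as fh:
        loci = ";".join(f"{c}:{p}" for c, p in truth.causal_loci) or "none"
        fh.write(f"# causal_loci={loci}\n")
        if truth.planted_de_genes:
            fh.write(f"# planted_de_genes={','.join(truth.planted_de_genes)}\n")
        fh.write("individual\tbulk\tcarrier\tdonor_segments\n")
        for bulk_name, bulk in (("F", truth.bulk_f), ("S", truth.bulk_s)):
            for i, ind in enumerate(bulk):
                segs = ";".join(
                    f"{chrom}:{s}-{e}"
                    for chrom, g in sorted(ind.gametes.items())
                    for s, e in g.donor_intervals()
                )
                fh.write(f"{bulk_name}{i + 1:03d}\t{bulk_name}\t{int(ind.carrier)}\t{segs or '.'}\n")


def write_gff3(genes: list[GeneRecord], path: str | Path) -> None:
    """Write gene records as a minimal GFF3 annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbsrscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)
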