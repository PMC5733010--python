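"""Synthetic two-bulk pooled-sequencing data with known truth.

The generative model mirrors the study design the scan is built for: a
parent heterozygous at every marker and at a single causal locus is selfed
to give an F2-like population; plants are phenotyped (one dominant locus,
~3:1 split); two bulks of phenotype-selected plants are pooled and
sequenced, giving per-site base counts whose between-bulk divergence decays
with map distance from the causal locus.

Gametes recombine between adjacent loci under Haldane's map function,
r = 0.5 * (1 - exp(-2d)), with map distance d taken as physical distance
times a uniform cM/Mb rate.  Read depth is Poisson per site and bulk; each
read draws its source haplotype uniformly from the 2 x (bulk size)
chromosomes in the pool and is miscalled to a uniformly chosen other base
with the configured error probability.  Reads are independent across sites,
which is adequate for a per-site statistic.

A fraction of markers is emitted as indels, and a configurable rate of
markers is expanded into dense artifact clusters (3 SNPs within 5 bp, or
indel pairs < 10 bp apart) purely to exercise the proximity filters.

Everything is driven by one integer seed: the same config always produces
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .variant_io import BASES, BulkVariantSite, write_bulk_vcf

# rng stream ids, one per stage, so stages stay independently reproducible
_STREAM_MARKERS = 11
_STREAM_POPULATION = 12
_STREAM_BULKS = 13
_STREAM_READS = 14
_STREAM_ANNOT = 15

DOMINANT = "dominant"
ADDITIVE_THRESHOLD = "additive-threshold"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Full generative description of the synthetic cross and sequencing.

    Defaults encode the study design the scan targets: two 25-plant bulks
    from a selfed population segregating ~3:1 for a dominant trait,
    sequenced at mean depths 23x and 28x.  ``causal_chrom=None`` gives a
    null trait (phenotype independent of genotype, P(dominant) = 0.75).
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {f"A{i:02d}": 30_000_000 for i in range(1, 11)}
    )
    marker_spacing: int = 3_000
    causal_chrom: str | None = "A06"
    causal_pos: int = 15_000_000
    dominance_model: str = DOMINANT
    phenotype_threshold: int = 1  # min copies of the dominant allele
    n_plants: int = 200
    plants_per_bulk: int = 25
    mean_depth_r01: float = 23.0
    mean_depth_r02: float = 28.0
    error_rate: float = 0.001
    indel_fraction: float = 0.02
    cluster_rate: float = 0.01
    cm_per_mb: float = 4.0
    misphenotype_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths: at least one chromosome required")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ConfigError(f"chrom_lengths[{chrom}]: length must be >= 1")
        if self.marker_spacing < 1:
            raise ConfigError("marker_spacing: must be >= 1")
        if self.causal_chrom is not None:
            if self.causal_chrom not in self.chrom_lengths:
                raise ConfigError(
                    f"causal_chrom: {self.causal_chrom!r} is not a declared "
                    f"chromosome {sorted(self.chrom_lengths)}"
                )
            if not 1 <= self.causal_pos <= self.chrom_lengths[self.causal_chrom]:
                raise ConfigError(
                    f"causal_pos: {self.causal_pos} outside "
                    f"[1, {self.chrom_lengths[self.causal_chrom]}]"
                )
        if self.dominance_model not in (DOMINANT, ADDITIVE_THRESHOLD):
            raise ConfigError(
                f"dominance_model: {self.dominance_model!r} not in "
                f"({DOMINANT!r}, {ADDITIVE_THRESHOLD!r})"
            )
        if not 1 <= self.phenotype_threshold <= 2:
            raise ConfigError("phenotype_threshold: must be 1 or 2")
        if self.n_plants < 1:
            raise ConfigError("n_plants: must be >= 1")
        if self.plants_per_bulk < 1:
            raise ConfigError("plants_per_bulk: must be >= 1")
        if self.mean_depth_r01 < 0 or self.mean_depth_r02 < 0:
            raise ConfigError("mean_depth: must be >= 0")
        if not 0 <= self.error_rate < 0.25:
            raise ConfigError("error_rate: must be in [0, 0.25)")
        if not 0 <= self.indel_fraction <= 1:
            raise ConfigError("indel_fraction: must be in [0, 1]")
        if not 0 <= self.cluster_rate <= 1:
            raise ConfigError("cluster_rate: must be in [0, 1]")
        if self.cm_per_mb < 0:
            raise ConfigError("cm_per_mb: must be >= 0")
        if not 0 <= self.misphenotype_rate <= 1:
            raise ConfigError("misphenotype_rate: must be in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "chrom_lengths": dict(self.chrom_lengths),
            "marker_spacing": self.marker_spacing,
            "causal_chrom": self.causal_chrom,
            "causal_pos": self.causal_pos,
            "dominance_model": self.dominance_model,
            "phenotype_threshold": self.phenotype_threshold,
            "n_plants": self.n_plants,
            "plants_per_bulk": self.plants_per_bulk,
            "mean_depth_r01": self.mean_depth_r01,
            "mean_depth_r02": self.mean_depth_r02,
            "error_rate": self.error_rate,
            "indel_fraction": self.indel_fraction,
            "cluster_rate": self.cluster_rate,
            "cm_per_mb": self.cm_per_mb,
            "misphenotype_rate": self.misphenotype_rate,
            "seed": self.seed,
        }
        return d


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Deterministic marker layout: positions and allele identities.

    Allele 0 (parental haplotype 0) carries the REF base; allele 1 carries
    the ALT.  At the causal locus allele 0 is the dominant 'A' allele and
    allele 1 the recessive 'a'.
    """

    chrom: str
    positions: np.ndarray          # 1-based, sorted
    ref_idx: np.ndarray            # index into BASES
    alt_idx: np.ndarray
    is_indel: np.ndarray           # bool
    is_cluster: np.ndarray         # bool
    causal_index: int | None = None


def build_marker_map(config: SimConfig) -> dict[str, MarkerMap]:
    rng = _rng(config, _STREAM_MARKERS)
    maps: dict[str, MarkerMap] = {}
    for chrom in config.chrom_lengths:
        length = config.chrom_lengths[chrom]
        positions = np.arange(
            config.marker_spacing, length + 1, config.marker_spacing, dtype=np.int64
        )
        if len(positions) == 0:
            positions = np.array([max(1, length // 2)], dtype=np.int64)
        causal_index = None
        if config.causal_chrom == chrom:
            if config.causal_pos not in positions:
                positions = np.sort(
                    np.append(positions, np.int64(config.causal_pos))
                )
            causal_index = int(np.searchsorted(positions, config.causal_pos))
        m = len(positions)
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
        is_indel = rng.random(m) < config.indel_fraction
        is_cluster = rng.random(m) < config.cluster_rate
        if causal_index is not None:
            is_indel[causal_index] = False
            is_cluster[causal_index] = False
        maps[chrom] = MarkerMap(
            chrom, positions, ref_idx, alt_idx, is_indel, is_cluster, causal_index
        )
    return maps


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

@dataclass
class PlantGenotype:
    """Diploid genotype: per chromosome, a (2, n_markers) array of allele
    indicators (0 = parental haplotype 0 / REF, 1 = haplotype 1 / ALT)."""

    haplotypes: dict[str, np.ndarray]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlantGenotype):
            return NotImplemented
        return self.haplotypes.keys() == other.haplotypes.keys() and all(
            np.array_equal(self.haplotypes[c], other.haplotypes[c])
            for c in self.haplotypes
        )

    def genotype_at(self, chrom: str, marker_index: int) -> int:
        """Copies of allele 1 (the recessive/ALT allele) at one marker."""
        return int(self.haplotypes[chrom][:, marker_index].sum())


def recombination_fractions(
    positions: np.ndarray, cm_per_mb: float
) -> np.ndarray:
    """Haldane map: r = 0.5 (1 - exp(-2d)), d in Morgans from bp distance."""
    d_morgans = np.diff(positions) * cm_per_mb / 1e6 / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def simulate_population(
    config: SimConfig,
    n: int | None = None,
    markers: dict[str, MarkerMap] | None = None,
) -> list[PlantGenotype]:
    """Self a parent heterozygous at every marker: each plant is two
    independent gametes, each gamete a recombinant mosaic of the two
    parental haplotypes.  Single-locus genotypes are 1:2:1 in expectation.
    """
    if n is None:
        n = config.n_plants
    if n < 1:
        raise ConfigError("n: population size must be >= 1")
    markers = markers or build_marker_map(config)
    rng = _rng(config, _STREAM_POPULATION)

    per_chrom: dict[str, np.ndarray] = {}
    n_gametes = 2 * n
    for chrom, mm in markers.items():
        m = len(mm.positions)
        r = recombination_fractions(mm.positions, config.cm_per_mb)
        start = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
        if m > 1:
            switches = (rng.random((n_gametes, m - 1)) < r).astype(np.int8)
            hap = (start + np.cumsum(switches, axis=1, dtype=np.int32)) % 2
            hap = np.concatenate([start, hap.astype(np.int8)], axis=1)
        else:
            hap = start
        per_chrom[chrom] = hap.astype(np.int8)

    return [
        PlantGenotype(
            {chrom: per_chrom[chrom][2 * i : 2 * i + 2] for chrom in per_chrom}
        )
        for i in range(n)
    ]


def _dominant_phenotype(
    plant: PlantGenotype, config: SimConfig, markers: dict[str, MarkerMap]
) -> bool:
    """True when the plant shows the dominant phenotype."""
    mm = markers[config.causal_chrom]  # type: ignore[index]
    n_alt = plant.genotype_at(config.causal_chrom, mm.causal_index)  # type: ignore[arg-type]
    n_dom = 2 - n_alt  # copies of the dominant 'A' allele
    if config.dominance_model == DOMINANT:
        return n_dom >= 1
    return n_dom >= config.phenotype_threshold


def select_bulks(
    population: Sequence[PlantGenotype],
    config: SimConfig,
    markers: dict[str, MarkerMap] | None = None,
) -> tuple[list[PlantGenotype], list[PlantGenotype]]:
    """Phenotype the population and draw the two bulks without replacement.

    Returns (bulk_high, bulk_low): dominant-phenotype plants and
    homozygous-recessive plants respectively.  With a null trait
    (``causal_chrom=None``) phenotypes are random at the 3:1 rate.
    """
    markers = markers or build_marker_map(config)
    rng = _rng(config, _STREAM_BULKS)
    n = len(population)

    if config.causal_chrom is None:
        pheno = rng.random(n) < 0.75
    else:
        pheno = np.array(
            [_dominant_phenotype(p, config, markers) for p in population]
        )
    if config.misphenotype_rate > 0:
        flip = rng.random(n) < config.misphenotype_rate
        pheno = pheno ^ flip

    high_idx = np.flatnonzero(pheno)
    low_idx = np.flatnonzero(~pheno)
    k = config.plants_per_bulk
    for name, idx in (("dominant", high_idx), ("recessive", low_idx)):
        if len(idx) < k:
            raise SimulationError(
                f"only {len(idx)} {name}-phenotype plants for a {k}-plant "
                f"bulk; simulate a larger population"
            )
    bulk_high = [population[i] for i in rng.choice(high_idx, size=k, replace=False)]
    bulk_low = [population[i] for i in rng.choice(low_idx, size=k, replace=False)]
    return bulk_high, bulk_low


# ---------------------------------------------------------------------------
# Pooled reads
# ---------------------------------------------------------------------------

_OTHER_BASES = np.array(
    [[b for b in range(4) if b != r] for r in range(4)], dtype=np.int64
)


def _bulk_counts(
    bulk: Sequence[PlantGenotype],
    chrom: str,
    mm: MarkerMap,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (counts[m,4], ad_ref[m], ad_alt[m]) for one bulk."""
    hap = np.concatenate([p.haplotypes[chrom] for p in bulk], axis=0)
    f_alt = hap.mean(axis=0)
    m = len(mm.positions)
    depth = rng.poisson(mean_depth, size=m)
    alt_true = rng.binomial(depth, f_alt)
    ref_true = depth - alt_true
    # sequencing error: each read miscalled with prob error_rate, landing
    # uniformly on one of the three other bases (for indels: on the other
    # allele)
    ref_err = rng.binomial(ref_true, error_rate)
    alt_err = rng.binomial(alt_true, error_rate)
    counts = np.zeros((m, 4), dtype=np.int64)
    rows = np.arange(m)
    counts[rows, mm.ref_idx] = ref_true - ref_err
    counts[rows, mm.alt_idx] += alt_true - alt_err
    third = np.full(3, 1.0 / 3.0)
    ref_spill = rng.multinomial(ref_err, third)
    alt_spill = rng.multinomial(alt_err, third)
    np.add.at(counts, (rows[:, None], _OTHER_BASES[mm.ref_idx]), ref_spill)
    np.add.at(counts, (rows[:, None], _OTHER_BASES[mm.alt_idx]), alt_spill)
    # indel AD: errors flip the read to the other allele
    ad_ref = ref_true - ref_err + alt_err
    ad_alt = alt_true - alt_err + ref_err
    return counts, ad_ref, ad_alt


def _marker_alleles(mm: MarkerMap, i: int) -> tuple[str, str]:
    ref_base = BASES[mm.ref_idx[i]]
    alt_base = BASES[mm.alt_idx[i]]
    if mm.is_indel[i]:
        # emit as a 1-bp deletion anchored on the ref base
        return ref_base + alt_base, ref_base
    return ref_base, alt_base


def simulate_bulk_reads(
    bulks: tuple[Sequence[PlantGenotype], Sequence[PlantGenotype]],
    config: SimConfig,
    markers: dict[str, MarkerMap] | None = None,
) -> list[BulkVariantSite]:
    """Pooled sequencing of (bulk_high, bulk_low) -> per-site read counts.

    Cluster-flagged SNP markers are expanded into three SNPs within a 5-bp
    window and cluster-flagged indels into a pair < 10 bp apart, so the
    proximity filters always have work to do.
    """
    bulk_high, bulk_low = bulks
    if not bulk_high or not bulk_low:
        raise SimulationError("both bulks must be non-empty")
    markers = markers or build_marker_map(config)
    rng = _rng(config, _STREAM_READS)

    sites: list[BulkVariantSite] = []
    for chrom in config.chrom_lengths:
        mm = markers[chrom]
        c_hi, adr_hi, ada_hi = _bulk_counts(
            bulk_high, chrom, mm, config.mean_depth_r01, config.error_rate, rng
        )
        c_lo, adr_lo, ada_lo = _bulk_counts(
            bulk_low, chrom, mm, config.mean_depth_r02, config.error_rate, rng
        )
        length = config.chrom_lengths[chrom]
        m = len(mm.positions)
        for i in range(m):
            ref, alt = _marker_alleles(mm, i)
            indel = mm.is_indel[i]
            if indel:
                counts_hi = (0, 0, 0, 0)
                counts_lo = (0, 0, 0, 0)
            else:
                counts_hi = tuple(int(x) for x in c_hi[i])
                counts_lo = tuple(int(x) for x in c_lo[i])
            ad_hi = (int(adr_hi[i]), int(ada_hi[i]))
            ad_lo = (int(adr_lo[i]), int(ada_lo[i]))
            pos = int(mm.positions[i])
            next_pos = int(mm.positions[i + 1]) if i + 1 < m else length + 100
            offsets = [0]
            if mm.is_cluster[i]:
                offsets = [0, 8] if indel else [0, 2, 4]
            for off in offsets:
                p = pos + off
                if p > length or (off > 0 and p >= next_pos):
                    continue
                sites.append(
                    BulkVariantSite(
                        chrom=chrom,
                        pos=p,
                        ref=ref,
                        alts=(alt,),
                        counts_r01=counts_hi,
                        counts_r02=counts_lo,
                        ad_r01=ad_hi,
                        ad_r02=ad_lo,
                    )
                )
    return sites


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[BulkVariantSite], dict[str, MarkerMap]]:
    """Population -> bulks -> pooled reads in one call."""
    markers = build_marker_map(config)
    population = simulate_population(config, markers=markers)
    bulks = select_bulks(population, config, markers=markers)
    sites = simulate_bulk_reads(bulks, config, markers=markers)
    return sites, markers


def write_sim_vcf(sites, config: SimConfig, path: str | Path) -> Path:
    return write_bulk_vcf(sites, config.chrom_lengths, path)


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixture:
    """Gene models plus pathway and DEG tables with planted structure."""

    genes: list  # list[GeneRecord]
    pathways: pd.DataFrame      # columns: gene_id, pathway_id
    degs: pd.DataFrame          # columns: gene_id, contrast, log2fc, adjusted_p
    enriched_pathway: str
    enriched_interval: tuple[str, int, int]
    deg_region_genes: list[str]
    untested_genes: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .region_annot import write_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff": outdir / "genes.gff3",
            "pathways": outdir / "pathways.tsv",
            "degs": outdir / "degs.tsv",
        }
        chrom_lengths = {}
        for g in self.genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
        write_gff3(self.genes, paths["gff"])
        self.pathways.to_csv(paths["pathways"], sep="\t", index=False)
        self.degs.to_csv(paths["degs"], sep="\t", index=False)
        return paths


def generate_annotation_fixture(
    config: SimConfig,
    n_genes: int | None = None,
    pathway_size: int = 10,
    n_enriched_in_interval: int = 4,
    enriched_pathway: str = "pw_hormone",
    n_background_pathways: int = 5,
    enriched_interval: tuple[str, int, int] | None = None,
    n_deg_in_interval: int = 2,
    n_deg_outside: int = 5,
    n_untested: int = 5,
) -> AnnotationFixture:
    """Non-overlapping genes tiled along the genome, one pathway planted as
    enriched inside a chosen interval, and a DEG table flagging a known
    subset, all deterministic in ``config.seed``.

    By default the enriched interval is a 1-Mb window centred on the causal
    locus, so the planted pathway signal co-locates with the association
    peak the simulator produces.
    """
    from .region_annot import GeneRecord

    rng = _rng(config, _STREAM_ANNOT)
    chroms = list(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    if n_genes is None:
        # one gene per 100 kb, so candidate regions hold tens of genes
        n_genes = max(total_len // 100_000, 10)

    if enriched_interval is None:
        if config.causal_chrom is not None:
            c = config.causal_chrom
            half = 500_000
            lo = max(1, config.causal_pos - half)
            hi = min(config.chrom_lengths[c], config.causal_pos + half)
            enriched_interval = (c, lo, hi)
        else:
            c = chroms[0]
            enriched_interval = (c, 1, min(1_000_000, config.chrom_lengths[c]))
    c, lo, hi = enriched_interval
    if c not in config.chrom_lengths or not (
        1 <= lo <= hi <= config.chrom_lengths[c]
    ):
        raise ConfigError(
            f"enriched_interval {enriched_interval} outside the genome"
        )

    # tile genes: slots proportional to chromosome length, gene fills the
    # middle half of its slot so neighbours never touch
    genes: list = []
    remaining = n_genes
    for k, chrom in enumerate(chroms):
        if k == len(chroms) - 1:
            k_genes = remaining
        else:
            k_genes = round(n_genes * config.chrom_lengths[chrom] / total_len)
            k_genes = min(k_genes, remaining)
        remaining -= k_genes
        if k_genes == 0:
            continue
        slot = config.chrom_lengths[chrom] // k_genes
        for i in range(k_genes):
            start = i * slot + slot // 4 + 1
            end = min(start + slot // 2, config.chrom_lengths[chrom])
            gid = f"gene{len(genes) + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gid, chrom, start, end, strand))

    in_interval = [
        g.gene_id
        for g in genes
        if g.chrom == c and g.start <= hi and g.end >= lo
    ]
    out_interval = [g.gene_id for g in genes if g.gene_id not in set(in_interval)]

    rows: list[tuple[str, str]] = []
    if n_genes > 0:
        if n_enriched_in_interval > len(in_interval):
            raise ConfigError(
                f"interval holds {len(in_interval)} genes, cannot plant "
                f"{n_enriched_in_interval} pathway members in it"
            )
        members = list(
            rng.choice(in_interval, size=n_enriched_in_interval, replace=False)
        )
        n_out = pathway_size - n_enriched_in_interval
        if n_out > 0:
            members += list(rng.choice(out_interval, size=n_out, replace=False))
        rows += [(g, enriched_pathway) for g in sorted(members)]
        all_ids = [g.gene_id for g in genes]
        for b in range(n_background_pathways):
            pw = f"pw_bg{b + 1:02d}"
            size = min(pathway_size, len(all_ids))
            for g in sorted(rng.choice(all_ids, size=size, replace=False)):
                rows.append((g, pw))
    pathways = pd.DataFrame(rows, columns=["gene_id", "pathway_id"])

    # DEG table: planted significant genes in and out of the interval; the
    # rest get null p-values except a few left untested (absent)
    deg_rows: list[tuple[str, str, float, float]] = []
    deg_region: list[str] = []
    untested: list[str] = []
    if n_genes > 0:
        deg_region = list(
            rng.choice(
                in_interval, size=min(n_deg_in_interval, len(in_interval)),
                replace=False,
            )
        )
        deg_out = list(
            rng.choice(
                out_interval, size=min(n_deg_outside, len(out_interval)),
                replace=False,
            )
        )
        flagged = set(deg_region) | set(deg_out)
        candidates_untested = [g for g in out_interval if g not in flagged]
        untested = list(
            rng.choice(
                candidates_untested,
                size=min(n_untested, len(candidates_untested)),
                replace=False,
            )
        )
        for g in (x.gene_id for x in genes):
            if g in untested:
                continue
            if g in flagged:
                lfc = float(rng.choice([-1, 1]) * rng.uniform(1.5, 3.0))
                p = float(rng.uniform(1e-6, 0.01))
            else:
                lfc = float(rng.normal(0, 0.2))
                p = float(rng.uniform(0.1, 1.0))
            deg_rows.append((g, "S", round(lfc, 4), round(p, 6)))
    degs = pd.DataFrame(
        deg_rows, columns=["gene_id", "contrast", "log2fc", "adjusted_p"]
    )
    return AnnotationFixture(
        genes=genes,
        pathways=pathways,
        degs=degs,
        enriched_pathway=enriched_pathway,
        enriched_interval=enriched_interval,
        deg_region_genes=sorted(deg_region),
        untested_genes=sorted(untested),
    )
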