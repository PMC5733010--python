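"""Reading and writing two-bulk variant data.

The scan works on per-site read counts for the four nucleotides in each of
two phenotype bulks (samples ``R01`` and ``R02`` by convention: the
reference-phenotype pool and the contrasting pool).  This module defines the
in-memory site container and converts between it and the standard on-disk
formats: VCF v4.2 on the way in, BED / TSV on the way out.

Coordinate conventions are fixed package-wide: internal coordinates and VCF
are 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, OutputError

__version__ = "0.1.0"

logger = logging.getLogger(__name__)

#: Nucleotide order used by every 4-vector of counts / frequencies.
BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SNP = "snp"
INDEL = "indel"


# ---------------------------------------------------------------------------
# Site containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BulkVariantSite:
    """One variant locus with per-bulk read counts.

    ``counts_r01`` / ``counts_r02`` hold read counts for the bases
    (A, C, G, T) in the two bulks.  For indel-class sites base counts are
    not meaningful; their ref/alt depths live in ``ad_r01`` / ``ad_r02``
    (the VCF AD field) and the base-count vectors are all zero.  Indels are
    carried through proximity filtering but are never scored.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    counts_r01: tuple[int, int, int, int]
    counts_r02: tuple[int, int, int, int]
    ad_r01: tuple[int, ...] | None = None  # (ref_depth, alt_depth, ...)
    ad_r02: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for c in (*self.counts_r01, *self.counts_r02):
            if c < 0:
                raise ValueError("read counts must be non-negative")

    @property
    def is_indel(self) -> bool:
        return any(len(a) != 1 for a in (self.ref, *self.alts))

    @property
    def variant_class(self) -> str:
        return INDEL if self.is_indel else SNP

    @property
    def depth_r01(self) -> int:
        t = sum(self.counts_r01)
        if t == 0 and self.ad_r01 is not None:
            return int(sum(self.ad_r01))
        return t

    @property
    def depth_r02(self) -> int:
        t = sum(self.counts_r02)
        if t == 0 and self.ad_r02 is not None:
            return int(sum(self.ad_r02))
        return t


@dataclass(frozen=True)
class FrequencyVector:
    """Per-bulk base frequencies at one site (each 4-tuple sums to 1)."""

    freqs_r01: tuple[float, float, float, float]
    freqs_r02: tuple[float, float, float, float]


def sort_sites(sites: Iterable[BulkVariantSite]) -> list[BulkVariantSite]:
    """Sort sites by (chromosome, position); the package-wide ordering."""
    return sorted(sites, key=lambda s: (s.chrom, s.pos))


def sites_are_sorted(sites: Sequence[BulkVariantSite]) -> bool:
    return all(
        (a.chrom, a.pos) <= (b.chrom, b.pos) for a, b in zip(sites, sites[1:])
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_bulk_vcf(
    path: str | Path,
    sample_high: str = "R01",
    sample_low: str = "R02",
) -> list[BulkVariantSite]:
    """Read a two-bulk VCF into :class:`BulkVariantSite` records.

    Per-base counts are taken from the auxiliary ``BC`` FORMAT field
    (counts for A,C,G,T) when present; otherwise they are reconstructed
    from ``AD`` by mapping the ref/alt depths onto their bases, leaving
    unobserved bases at zero (AD-only mode).  Multiallelic rows are read
    intact — rejecting them is the job of the downstream locus filters.

    Records are returned sorted by (chromosome, position); unsorted input
    is sorted silently with a logged warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (sample_high, sample_low):
        if name not in samples:
            raise InputError(
                f"sample {name!r} not in VCF; available samples: {samples}"
            )
    i_hi = samples.index(sample_high)
    i_lo = samples.index(sample_low)

    sites: list[BulkVariantSite] = []
    for rec in vcf:
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise InputError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks the required "
                "AD FORMAT field (per-sample allelic depths)"
            )
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negatives
        try:
            bc = rec.format("BC")
        except KeyError:
            bc = None
        alts = tuple(rec.ALT)
        alleles = (rec.REF, *alts)
        if bc is not None:
            counts_hi = tuple(int(x) for x in bc[i_hi][:4])
            counts_lo = tuple(int(x) for x in bc[i_lo][:4])
        else:
            counts_hi = _counts_from_ad(alleles, ad[i_hi])
            counts_lo = _counts_from_ad(alleles, ad[i_lo])
        sites.append(
            BulkVariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alts=alts,
                counts_r01=counts_hi,
                counts_r02=counts_lo,
                ad_r01=tuple(int(x) for x in ad[i_hi][: len(alleles)]),
                ad_r02=tuple(int(x) for x in ad[i_lo][: len(alleles)]),
            )
        )
    vcf.close()
    if not sites_are_sorted(sites):
        logger.warning("%s: records not sorted by (chrom, pos); sorting", path)
        sites = sort_sites(sites)
    return sites


def _counts_from_ad(
    alleles: Sequence[str], ad_row: np.ndarray
) -> tuple[int, int, int, int]:
    """Map ref/alt depths onto base counts; non-SNV alleles contribute 0."""
    counts = [0, 0, 0, 0]
    for allele, depth in zip(alleles, ad_row):
        if len(allele) == 1 and allele in BASE_INDEX:
            counts[BASE_INDEX[allele]] += int(depth)
    return tuple(counts)  # type: ignore[return-value]


def write_bulk_vcf(
    sites: Sequence[BulkVariantSite],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
    sample_high: str = "R01",
    sample_low: str = "R02",
) -> Path:
    """Write sites as a plain-text VCF v4.2.

    FORMAT carries ``DP`` (total depth), ``AD`` (ref,alt depths) and the
    auxiliary ``BC`` extension (read counts for A,C,G,T, documented in the
    header).  Output is deterministic: identical sites produce identical
    bytes, which the simulator relies on for its reproducibility contract.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=bsascan {__version__}",
    ]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Read depths for the ref and alt alleles">',
        '##FORMAT=<ID=BC,Number=4,Type=Integer,Description='
        '"Read counts for bases A,C,G,T (pooled bulk extension)">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        f"\t{sample_high}\t{sample_low}",
    ]
    for s in sites:
        ad_hi = s.ad_r01 if s.ad_r01 is not None else _default_ad(s, s.counts_r01)
        ad_lo = s.ad_r02 if s.ad_r02 is not None else _default_ad(s, s.counts_r02)
        fmt_hi = _format_sample(s.counts_r01, ad_hi, s.depth_r01)
        fmt_lo = _format_sample(s.counts_r02, ad_lo, s.depth_r02)
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{','.join(s.alts)}\t.\t.\t.\t"
            f"DP:AD:BC\t{fmt_hi}\t{fmt_lo}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _default_ad(site: BulkVariantSite, counts: tuple[int, ...]) -> tuple[int, ...]:
    ad = [0] * (1 + len(site.alts))
    if len(site.ref) == 1 and site.ref in BASE_INDEX:
        ad[0] = counts[BASE_INDEX[site.ref]]
    for i, alt in enumerate(site.alts, start=1):
        if len(alt) == 1 and alt in BASE_INDEX:
            ad[i] = counts[BASE_INDEX[alt]]
    return tuple(ad)


def _format_sample(counts: tuple[int, ...], ad: tuple[int, ...], dp: int) -> str:
    return f"{dp}:{','.join(map(str, ad))}:{','.join(map(str, counts))}"


# ---------------------------------------------------------------------------
# Tabular outputs (provenance-stamped TSV / BED)
# ---------------------------------------------------------------------------

def provenance_line(config_hash: str = "-") -> str:
    return f"#bsascan {__version__} config={config_hash}"


def write_ed_table(scores, path: str | Path, config_hash: str = "-") -> Path:
    """Write per-SNP scores as TSV (chrom, pos, ED, powered ED, depths).

    Floats are printed with six decimal places, lossless to the precision
    the scan reports.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(config_hash) + "\n")
        fh.write("chrom\tpos\ted\tpowered_ed\tdepth_r01\tdepth_r02\n")
        for s in scores:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ed:.6f}\t{s.powered_ed:.6f}"
                f"\t{s.depth_r01}\t{s.depth_r02}\n"
            )
    return path


def read_ed_table(path: str | Path):
    """Re-parse an ED TSV into :class:`~bsascan.ed_scan.SiteScore` records."""
    from .ed_scan import SiteScore

    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    return [
        SiteScore(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ed=float(r.ed),
            powered_ed=float(r.powered_ed),
            depth_r01=int(r.depth_r01),
            depth_r02=int(r.depth_r02),
        )
        for r in df.itertuples(index=False)
    ]


def write_regions_bed(regions, path: str | Path, config_hash: str = "-") -> Path:
    """Write candidate regions as BED3+ (0-based half-open), with columns
    for the peak fitted value and the supporting SNP count.

    Regions must be sorted and non-overlapping per chromosome.
    """
    regions = list(regions)
    for a, b in zip(regions, regions[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise OutputError("regions must be sorted by (chrom, start)")
        if a.chrom == b.chrom and b.start <= a.end:
            raise OutputError(
                f"overlapping regions: {a.chrom}:{a.start}-{a.end} and "
                f"{b.chrom}:{b.start}-{b.end}"
            )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(config_hash) + "\n")
        fh.write("#chrom\tstart\tend\tpeak_fitted\tn_snps\n")
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.peak_value:.6g}"
                f"\t{r.n_snps}\n"
            )
    return path


def read_regions_bed(path: str | Path):
    """Re-parse a regions BED into :class:`~bsascan.ed_scan.CandidateRegion`."""
    from .ed_scan import CandidateRegion

    regions = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, peak, n_snps = line.split("\t")
        regions.append(
            CandidateRegion(
                chrom=chrom,
                start=int(start) + 1,
                end=int(end),
                peak_value=float(peak),
                n_snps=int(n_snps),
            )
        )
    return regions


def write_track_tsv(track, path: str | Path, config_hash: str = "-") -> Path:
    """Write a fitted track as TSV (chrom, center, fitted value, SNP count);
    undefined windows print NA."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(config_hash) + "\n")
        fh.write("chrom\tcenter\tfitted\tn_snps\n")
        for chrom, ct in track.chroms.items():
            for c, v, n in zip(ct.centers, ct.values, ct.counts):
                v_str = "NA" if np.isnan(v) else f"{v:.6g}"
                fh.write(f"{chrom}\t{int(c)}\t{v_str}\t{int(n)}\n")
    return path
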