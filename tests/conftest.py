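"""Shared fixtures: site factories, small simulation configs, and
independent brute-force reference implementations used as oracles."""

from __future__ import annotations

import numpy as np
import pytest

from bsascan.simdata import SimConfig
from bsascan.variant_io import BASE_INDEX, BulkVariantSite


# ---------------------------------------------------------------------------
# Site factories
# ---------------------------------------------------------------------------

def make_snp(
    chrom: str = "A01",
    pos: int = 100,
    ref: str = "A",
    alt: str = "T",
    c1=(10, 0, 0, 0),
    c2=(0, 0, 0, 10),
) -> BulkVariantSite:
    return BulkVariantSite(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,),
        counts_r01=tuple(c1), counts_r02=tuple(c2),
    )


def make_indel(
    chrom: str = "A01",
    pos: int = 100,
    ad1=(20, 10),
    ad2=(15, 15),
) -> BulkVariantSite:
    return BulkVariantSite(
        chrom=chrom, pos=pos, ref="TA", alts=("T",),
        counts_r01=(0, 0, 0, 0), counts_r02=(0, 0, 0, 0),
        ad_r01=tuple(ad1), ad_r02=tuple(ad2),
    )


def make_biallelic(chrom, pos, f1, f2, depth=40, ref="A", alt="G"):
    """SNP with exact allele frequencies f1/f2 for the alt in each bulk."""
    c1 = [0, 0, 0, 0]
    c2 = [0, 0, 0, 0]
    a1 = round(depth * f1)
    a2 = round(depth * f2)
    c1[BASE_INDEX[alt]] = a1
    c1[BASE_INDEX[ref]] = depth - a1
    c2[BASE_INDEX[alt]] = a2
    c2[BASE_INDEX[ref]] = depth - a2
    return make_snp(chrom, pos, ref, alt, c1, c2)


@pytest.fixture
def snp_factory():
    return make_snp


@pytest.fixture
def indel_factory():
    return make_indel


def random_sites(rng: np.random.Generator, n: int = 200) -> list[BulkVariantSite]:
    """A messy random call set: clustered SNPs, close indel pairs,
    SNP-near-indel cases, zero-depth, homozygous-consistent and
    multiallelic sites, on two chromosomes."""
    sites = []
    taken: set[tuple[str, int]] = set()

    def fresh_pos(chrom, lo=1, hi=100_000):
        while True:
            p = int(rng.integers(lo, hi))
            if (chrom, p) not in taken:
                taken.add((chrom, p))
                return p

    for _ in range(n):
        chrom = "A01" if rng.random() < 0.6 else "A02"
        kind = rng.random()
        if kind < 0.12:  # indel, sometimes in a close pair
            p = fresh_pos(chrom)
            sites.append(make_indel(chrom, p))
            if rng.random() < 0.5:
                q = p + int(rng.integers(1, 15))
                if (chrom, q) not in taken:
                    taken.add((chrom, q))
                    sites.append(make_indel(chrom, q))
        elif kind < 0.24:  # SNP cluster
            p = fresh_pos(chrom, hi=99_000)
            span = rng.permutation([1, 2, 3, 4, 6, 8])[:2]
            for off in (0, *span):
                if (chrom, p + off) not in taken:
                    taken.add((chrom, p + off))
                    sites.append(make_snp(chrom, p + int(off)))
        elif kind < 0.32:  # SNP near an indel
            p = fresh_pos(chrom, hi=99_000)
            sites.append(make_indel(chrom, p))
            q = p + int(rng.integers(1, 9))
            if (chrom, q) not in taken:
                taken.add((chrom, q))
                sites.append(make_snp(chrom, q))
        elif kind < 0.42:  # zero depth in one bulk
            p = fresh_pos(chrom)
            sites.append(make_snp(chrom, p, c1=(25, 0, 0, 0), c2=(0, 0, 0, 0)))
        elif kind < 0.52:  # homozygous and consistent
            p = fresh_pos(chrom)
            sites.append(make_snp(chrom, p, c1=(25, 0, 0, 0), c2=(30, 0, 0, 0)))
        elif kind < 0.60:  # multiallelic counts
            p = fresh_pos(chrom)
            sites.append(make_snp(chrom, p, c1=(10, 9, 8, 0), c2=(12, 6, 5, 0)))
        else:  # ordinary segregating SNP
            p = fresh_pos(chrom)
            a = int(rng.integers(0, 30))
            b = int(rng.integers(0, 30))
            sites.append(
                make_snp(chrom, p, c1=(30 - a, 0, a, 0), c2=(30 - b, 0, b, 0))
            )
    return sorted(sites, key=lambda s: (s.chrom, s.pos))


# ---------------------------------------------------------------------------
# Independent O(n^2) references for the filter rules
# ---------------------------------------------------------------------------

def brute_force_proximity_survivors(sites) -> list[BulkVariantSite]:
    removed = set()
    for i, s in enumerate(sites):
        for j, t in enumerate(sites):
            if i == j or s.chrom != t.chrom:
                continue
            if (
                s.variant_class == "indel"
                and t.variant_class == "indel"
                and abs(s.pos - t.pos) < 10
            ):
                removed.add(i)
            if (
                s.variant_class == "snp"
                and t.variant_class == "indel"
                and abs(s.pos - t.pos) <= 5
            ):
                removed.add(i)
    for i, s in enumerate(sites):
        if s.variant_class != "snp":
            continue
        for w in range(s.pos - 4, s.pos + 1):  # every 5-bp window holding s
            n_in = sum(
                1
                for t in sites
                if t.chrom == s.chrom
                and t.variant_class == "snp"
                and w <= t.pos <= w + 4
            )
            if n_in > 2:
                removed.add(i)
                break
    return [s for i, s in enumerate(sites) if i not in removed]


def brute_force_ed_input_survivors(
    sites, min_alt_reads=2, hom_threshold=0.05
) -> list[BulkVariantSite]:
    out = []
    for s in sites:
        if s.variant_class != "snp":
            continue
        c1, c2 = s.counts_r01, s.counts_r02
        n_obs = sum(
            1 for b in range(4) if c1[b] >= min_alt_reads or c2[b] >= min_alt_reads
        )
        if len(s.alts) > 1 or n_obs > 2:
            continue
        d1, d2 = sum(c1), sum(c2)
        if d1 == 0 or d2 == 0:
            continue
        f1 = [x / d1 for x in c1]
        f2 = [x / d2 for x in c2]
        hom1 = 1 - max(f1) < hom_threshold
        hom2 = 1 - max(f2) < hom_threshold
        same = f1.index(max(f1)) == f2.index(max(f2))
        if hom1 and hom2 and same:
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Small simulation configs
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_sim_config() -> SimConfig:
    """One small chromosome, clean SNP markers; fast to simulate."""
    return SimConfig(
        chrom_lengths={"A06": 3_000_000},
        marker_spacing=3_000,
        causal_chrom="A06",
        causal_pos=1_500_000,
        n_plants=125,
        plants_per_bulk=25,
        indel_fraction=0.0,
        cluster_rate=0.0,
        seed=7,
    )
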