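"""Candidate-region annotation: gene overlap, pathway enrichment, and
cross-referencing with differential expression.

Genes are assigned to a region on >= 1 bp overlap (1-based inclusive
coordinates on both sides).  Pathway enrichment is a one-sided Fisher's
exact test of the 2x2 table [region & pathway, region & not, background &
pathway, background & not] with the entire gene set as background,
significant at raw P < alpha (a Benjamini-Hochberg option exists but is
off by default).  A region gene counts as a candidate when its adjusted P
is below the cut in at least one supplied expression contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

from .ed_scan import CandidateRegion


@dataclass(frozen=True)
class GeneRecord:
    """One gene model (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start must be <= end")


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact enrichment of one pathway among region genes."""

    pathway_id: str
    n_region_in: int
    n_region: int
    n_background_in: int   # pathway genes outside the region
    n_background: int      # genes outside the region
    odds_ratio: float
    p_value: float
    significant: bool

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.n_region_in, self.n_region - self.n_region_in),
            (self.n_background_in, self.n_background - self.n_background_in),
        )


@dataclass(frozen=True)
class CandidateGene:
    """A region gene flagged differentially expressed in >= 1 contrast."""

    gene_id: str
    contrasts: tuple[str, ...]
    min_adjusted_p: float


# ---------------------------------------------------------------------------
# GFF3 / TSV I/O
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """Read gene features from a GFF3 file (other feature types ignored)."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise InputError(f"GFF3 not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = [
        GeneRecord(
            gene_id=f.id,
            chrom=f.seqid,
            start=f.start,
            end=f.end,
            strand=f.strand if f.strand in ("+", "-") else "+",
        )
        for f in db.features_of_type("gene")
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end))


def write_gff3(genes: Iterable[GeneRecord], path: str | Path) -> Path:
    path = Path(path)
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbsascan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id}\n"
            )
    return path


def read_pathway_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"gene_id", "pathway_id"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: pathway table lacks columns {sorted(missing)}")
    return df


def read_deg_tsv(path: str | Path) -> pd.DataFrame:
    """Read a DEG table (gene_id, adjusted_p, optional log2fc/contrast),
    validating numeric columns row by row."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "adjusted_p"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: DEG table lacks columns {sorted(missing)}")
    p = pd.to_numeric(df["adjusted_p"], errors="coerce")
    bad = df.index[p.isna() | (p < 0) | (p > 1)]
    if len(bad):
        # +2: 1-based line numbers plus the header line
        raise InputError(
            f"{path}: malformed adjusted_p at line {int(bad[0]) + 2}"
        )
    df["adjusted_p"] = p
    if "contrast" not in df.columns:
        df["contrast"] = "default"
    return df


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def genes_in_regions(
    regions: Sequence[CandidateRegion],
    genes: Sequence[GeneRecord],
) -> dict[CandidateRegion, list[GeneRecord]]:
    """Genes overlapping each region by >= 1 bp, ordered by position."""
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))
    out: dict[CandidateRegion, list[GeneRecord]] = {}
    for region in regions:
        hits = [
            g
            for g in genes
            if g.chrom == region.chrom
            and g.start <= region.end
            and g.end >= region.start
        ]
        out[region] = hits
    return out


def pathway_enrichment(
    region_genes: Iterable[str],
    all_genes: Iterable[str],
    pathway_table: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """One-sided Fisher's exact enrichment for every pathway with at least
    one region gene, against the whole gene set as background.

    ``pathway_table`` is either a DataFrame with gene_id/pathway_id columns
    or a mapping pathway -> gene ids (many-to-many allowed).  Results are
    sorted by P-value.  With ``bh_correct`` the significance flag applies
    to Benjamini-Hochberg adjusted values instead of raw P.
    """
    region = set(region_genes)
    universe = set(all_genes)
    stray = region - universe
    if stray:
        raise InputError(
            f"region genes absent from the background set: {sorted(stray)[:5]}"
        )

    if isinstance(pathway_table, pd.DataFrame):
        members: dict[str, set[str]] = {}
        for gid, pw in zip(pathway_table["gene_id"], pathway_table["pathway_id"]):
            members.setdefault(str(pw), set()).add(str(gid))
    else:
        members = {pw: set(gs) for pw, gs in pathway_table.items()}

    n_region = len(region)
    n_background = len(universe) - n_region
    results: list[EnrichmentResult] = []
    for pw in sorted(members):
        in_pw = members[pw] & universe
        a = len(region & in_pw)
        if a == 0:
            continue
        b = n_region - a
        c = len(in_pw) - a
        d = n_background - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        results.append(
            EnrichmentResult(
                pathway_id=pw,
                n_region_in=a,
                n_region=n_region,
                n_background_in=c,
                n_background=n_background,
                odds_ratio=float(odds),
                p_value=float(p),
                significant=False,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if results:
        if bh_correct:
            adj = stats.false_discovery_control(
                [r.p_value for r in results], method="bh"
            )
            flags = [float(q) < alpha for q in adj]
        else:
            flags = [r.p_value < alpha for r in results]
        results = [
            EnrichmentResult(
                r.pathway_id, r.n_region_in, r.n_region, r.n_background_in,
                r.n_background, r.odds_ratio, r.p_value, bool(f),
            )
            for r, f in zip(results, flags)
        ]
    return results


def cross_reference_degs(
    region_genes: Iterable[str],
    deg_table: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[CandidateGene], int]:
    """Region genes differentially expressed (adjusted P < alpha) in at
    least one contrast, tagged with the significant contrasts.

    Returns (candidates sorted by min adjusted P, number of region genes
    absent from the table — the "untested" tally).
    """
    region = list(dict.fromkeys(region_genes))
    tested = set(deg_table["gene_id"].astype(str))
    n_untested = sum(1 for g in region if g not in tested)

    candidates: list[CandidateGene] = []
    for g in region:
        rows = deg_table[deg_table["gene_id"].astype(str) == g]
        if rows.empty:
            continue
        sig = rows[rows["adjusted_p"] < alpha]
        if sig.empty:
            continue
        candidates.append(
            CandidateGene(
                gene_id=g,
                contrasts=tuple(sorted(set(sig["contrast"].astype(str)))),
                min_adjusted_p=float(sig["adjusted_p"].min()),
            )
        )
    candidates.sort(key=lambda c: (c.min_adjusted_p, c.gene_id))
    return candidates, n_untested


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "pathway_id\tn_region_in\tn_region\tn_background_in"
            "\tn_background\todds_ratio\tp_value\tsignificant\n"
        )
        for r in results:
            odds = "inf" if np.isinf(r.odds_ratio) else f"{r.odds_ratio:.6g}"
            fh.write(
                f"{r.pathway_id}\t{r.n_region_in}\t{r.n_region}"
                f"\t{r.n_background_in}\t{r.n_background}\t{odds}"
                f"\t{r.p_value:.6g}\t{r.significant}\n"
            )
    return path


def write_candidates_tsv(
    candidates: Sequence[CandidateGene], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\tcontrasts\tmin_adjusted_p\n")
        for c in candidates:
            fh.write(
                f"{c.gene_id}\t{','.join(c.contrasts)}\t{c.min_adjusted_p:.6g}\n"
            )
    return path
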