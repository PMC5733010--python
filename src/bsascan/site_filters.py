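"""The two locus-filtering layers applied before the ED scan.

Layer 1 (variant-quality proximity rules, applied to the raw call set):
  * both indels of a same-chromosome pair closer than 10 bp are removed;
  * every SNP inside any 5-bp window that contains more than two SNPs is
    removed;
  * every SNP within 5 bp of an indel is removed (the indel is kept).

Layer 2 (ED-input locus rules, applied to the proximity-filtered set):
  * indel-class sites (never scored);
  * multiallelic loci ("multiple mutations"): more than two bases supported
    by at least ``min_alt_reads`` reads in either bulk, or an explicitly
    multiallelic VCF row;
  * loci undetected (zero depth) in either bulk;
  * loci homozygous for the same allele in both bulks.

Both layers evaluate every rule against the *input* set — removals do not
cascade — which makes filtering idempotent and order-independent.  A site
matching several rules is reported once, under the first matching rule in
the order listed above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .errors import ContractError
from .variant_io import SNP, BulkVariantSite, sites_are_sorted

PROXIMITY_RULES = ("indel_pair", "snp_cluster", "snp_near_indel")
ED_INPUT_RULES = ("not_snp", "multiallelic", "zero_depth", "hom_consistent")


@dataclass
class FilterReport:
    """Outcome of one filter layer.

    ``removed_counts`` counts each removed site exactly once, under its
    first matching rule in the layer's documented order, so
    ``len(survivors) + sum(removed_counts.values())`` equals the input size.
    """

    survivors: list[BulkVariantSite]
    removed_counts: dict[str, int]
    reasons: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.survivors) + sum(self.removed_counts.values())

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_survivors": len(self.survivors),
            "removed": dict(self.removed_counts),
        }

    def write_summary_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2) + "\n")
        return path

    def write_reasons_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("chrom\tpos\trule\n")
            for chrom, pos, rule in self.reasons:
                fh.write(f"{chrom}\t{pos}\t{rule}\n")
        return path


def _build_report(
    sites: Sequence[BulkVariantSite],
    removed_by_rule: dict[str, set[int]],
    rule_order: Sequence[str],
) -> FilterReport:
    assigned: dict[int, str] = {}
    for rule in rule_order:
        for idx in removed_by_rule.get(rule, ()):
            assigned.setdefault(idx, rule)
    counts = {rule: 0 for rule in rule_order}
    reasons = []
    for idx in sorted(assigned):
        rule = assigned[idx]
        counts[rule] += 1
        reasons.append((sites[idx].chrom, sites[idx].pos, rule))
    survivors = [s for i, s in enumerate(sites) if i not in assigned]
    return FilterReport(survivors=survivors, removed_counts=counts, reasons=reasons)


def filter_variant_proximity(
    sites: Sequence[BulkVariantSite],
    indel_pair_bp: int = 10,
    snp_window_bp: int = 5,
    max_snps_per_window: int = 2,
    snp_indel_bp: int = 5,
) -> FilterReport:
    """Apply the proximity rules to a (chrom, pos)-sorted call set.

    Defaults encode the published rules: indel pairs < 10 bp apart, more
    than 2 SNPs in a 5-bp window, SNPs within 5 bp of an indel.
    """
    sites = list(sites)
    if not sites_are_sorted(sites):
        raise ContractError("filter_variant_proximity requires sorted sites")

    removed: dict[str, set[int]] = {rule: set() for rule in PROXIMITY_RULES}
    # per-chromosome index groups
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)

    k = max_snps_per_window  # a window is offending when it holds > k SNPs
    for idx in by_chrom.values():
        snp_idx = [i for i in idx if sites[i].variant_class == SNP]
        indel_idx = [i for i in idx if sites[i].variant_class != SNP]
        snp_pos = np.array([sites[i].pos for i in snp_idx], dtype=np.int64)
        indel_pos = np.array([sites[i].pos for i in indel_idx], dtype=np.int64)

        # (a) indel pairs closer than indel_pair_bp: both removed
        for j in range(len(indel_idx) - 1):
            if indel_pos[j + 1] - indel_pos[j] < indel_pair_bp:
                removed["indel_pair"].add(indel_idx[j])
                removed["indel_pair"].add(indel_idx[j + 1])

        # (b) > k SNPs inside any window of snp_window_bp consecutive bases:
        # equivalently, any k+1 consecutive SNPs spanning <= window-1 bases.
        for j in range(len(snp_idx) - k):
            if snp_pos[j + k] - snp_pos[j] <= snp_window_bp - 1:
                for m in range(j, j + k + 1):
                    removed["snp_cluster"].add(snp_idx[m])

        # (c) SNP with an indel within +/- snp_indel_bp (SNP removed only)
        if len(indel_pos):
            lo = np.searchsorted(indel_pos, snp_pos - snp_indel_bp, side="left")
            hi = np.searchsorted(indel_pos, snp_pos + snp_indel_bp, side="right")
            for j, (a, b) in enumerate(zip(lo, hi)):
                if b > a:
                    removed["snp_near_indel"].add(snp_idx[j])

    return _build_report(sites, removed, PROXIMITY_RULES)


def filter_ed_input(
    sites: Sequence[BulkVariantSite],
    min_alt_reads: int = 2,
    hom_threshold: float = 0.05,
) -> FilterReport:
    """Apply the ED-input locus rules; survivors are SNP-class biallelic
    sites detected in both bulks and not jointly fixed for one allele.

    ``min_alt_reads`` is the read support needed for a base to count as an
    observed allele in the "multiple mutations" rule; ``hom_threshold`` is
    the minor-base frequency below which a bulk is called homozygous.
    """
    sites = list(sites)
    removed: dict[str, set[int]] = {rule: set() for rule in ED_INPUT_RULES}

    for i, s in enumerate(sites):
        if s.variant_class != SNP:
            removed["not_snp"].add(i)
            continue
        c1 = np.asarray(s.counts_r01, dtype=np.int64)
        c2 = np.asarray(s.counts_r02, dtype=np.int64)
        n_alleles = int(np.sum((c1 >= min_alt_reads) | (c2 >= min_alt_reads)))
        if len(s.alts) > 1 or n_alleles > 2:
            removed["multiallelic"].add(i)
        d1, d2 = int(c1.sum()), int(c2.sum())
        if d1 == 0 or d2 == 0:
            removed["zero_depth"].add(i)
            continue
        f1 = c1 / d1
        f2 = c2 / d2
        if (
            1.0 - f1.max() < hom_threshold
            and 1.0 - f2.max() < hom_threshold
            and int(f1.argmax()) == int(f2.argmax())
        ):
            removed["hom_consistent"].add(i)

    return _build_report(sites, removed, ED_INPUT_RULES)
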