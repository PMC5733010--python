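"""The Euclidean-distance (ED) association scan.

At every filtered SNP the statistic is

    ED = sqrt( (A1-A2)^2 + (C1-C2)^2 + (G1-G2)^2 + (T1-T2)^2 )

where A1..T1 and A2..T2 are the base frequencies in the two bulks.  ED is 0
when the pools look identical and sqrt(2) when they are fixed for different
bases.  ED is raised to a power (default 5) to shrink sampling noise
relative to true association peaks, the powered values are smoothed with a
sliding-window mean (default 1 Mb), and windows whose fitted value exceeds
the genome-wide median by more than three standard deviations are merged
into candidate regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, ConfigError, ContractError
from .variant_io import BulkVariantSite, FrequencyVector

logger = logging.getLogger(__name__)

ED_MAX = float(np.sqrt(2.0))


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteScore:
    """The ED statistic and its powered value at one SNP."""

    chrom: str
    pos: int
    ed: float
    powered_ed: float
    depth_r01: int = 0
    depth_r02: int = 0


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    power
        exponent applied to ED before smoothing (default 5).
    window
        sliding-window width in bp (default 1,000,000).
    step
        window step in bp; defaults to window/100 (10 kb at 1 Mb).
    min_snps
        windows holding fewer SNPs are emitted as undefined rather than
        zero, so sparse stretches do not fake troughs.
    mask
        optional repetitive-region mask, chrom -> [(start, end)] 1-based
        inclusive; SNPs inside masked intervals are excluded from the fit.
        Off by default.
    """

    power: float = 5.0
    window: int = 1_000_000
    step: int | None = None
    min_snps: int = 10
    mask: Mapping[str, Sequence[tuple[int, int]]] | None = None
    gap_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ConfigError(f"power must be >= 1, got {self.power}")
        if self.window <= 0:
            raise ConfigError(f"window must be > 0, got {self.window}")
        step = self.effective_step
        if step <= 0 or step > self.window:
            raise ConfigError(f"step must be in (0, window], got {step}")
        if self.gap_tolerance < 0:
            raise ConfigError("gap_tolerance must be >= 0")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else max(self.window // 100, 1)


@dataclass
class ChromTrack:
    """Fitted values along one chromosome; NaN marks undefined windows."""

    chrom: str
    centers: np.ndarray  # window centers, bp
    values: np.ndarray   # mean powered ED per window (NaN when undefined)
    counts: np.ndarray   # contributing SNPs per window


@dataclass
class FittedTrack:
    window: int
    step: int
    chroms: dict[str, ChromTrack] = field(default_factory=dict)

    def defined_values(self) -> np.ndarray:
        vals = [ct.values[~np.isnan(ct.values)] for ct in self.chroms.values()]
        return np.concatenate(vals) if vals else np.array([])


@dataclass(frozen=True)
class ThresholdResult:
    """Genome-wide peak-calling threshold: median + 3 * sample SD."""

    median: float
    sd: float
    n_sd: float = 3.0

    @property
    def tau(self) -> float:
        return self.median + self.n_sd * self.sd


@dataclass(frozen=True)
class CandidateRegion:
    """A contiguous interval whose fitted track exceeds the threshold.

    Coordinates are 1-based inclusive and clipped to the first/last
    contributing SNP.
    """

    chrom: str
    start: int
    end: int
    peak_value: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# Per-site statistic
# ---------------------------------------------------------------------------

def base_frequencies(site: BulkVariantSite) -> FrequencyVector:
    """Per-bulk base frequencies (count / total) at one SNP.

    Sites with zero depth in either bulk must be removed upstream; meeting
    one here is a contract violation, not a data error.
    """
    c1 = np.asarray(site.counts_r01, dtype=float)
    c2 = np.asarray(site.counts_r02, dtype=float)
    d1, d2 = c1.sum(), c2.sum()
    if d1 == 0 or d2 == 0:
        raise ContractError(
            f"zero-depth site {site.chrom}:{site.pos} reached base_frequencies; "
            "run filter_ed_input first"
        )
    return FrequencyVector(tuple(c1 / d1), tuple(c2 / d2))


def euclidean_distance(site: BulkVariantSite, power: float = 5.0) -> SiteScore:
    """ED between the two bulks' base-frequency vectors, and ED**power."""
    fv = base_frequencies(site)
    diff = np.asarray(fv.freqs_r01) - np.asarray(fv.freqs_r02)
    ed = float(np.sqrt(np.sum(diff * diff)))
    return SiteScore(
        chrom=site.chrom,
        pos=site.pos,
        ed=ed,
        powered_ed=ed**power,
        depth_r01=int(sum(site.counts_r01)),
        depth_r02=int(sum(site.counts_r02)),
    )


def score_sites(
    sites: Sequence[BulkVariantSite], power: float = 5.0
) -> list[SiteScore]:
    """Vectorised ED over many sites (same result as per-site scoring)."""
    if not sites:
        return []
    c1 = np.array([s.counts_r01 for s in sites], dtype=float)
    c2 = np.array([s.counts_r02 for s in sites], dtype=float)
    d1 = c1.sum(axis=1)
    d2 = c2.sum(axis=1)
    if np.any(d1 == 0) or np.any(d2 == 0):
        raise ContractError("zero-depth site in score_sites; filter first")
    diff = c1 / d1[:, None] - c2 / d2[:, None]
    ed = np.sqrt(np.sum(diff * diff, axis=1))
    powered = ed**power
    return [
        SiteScore(s.chrom, s.pos, float(e), float(pe), int(a), int(b))
        for s, e, pe, a, b in zip(sites, ed, powered, d1, d2)
    ]


# ---------------------------------------------------------------------------
# Sliding-window fit
# ---------------------------------------------------------------------------

def _apply_mask(
    scores: Sequence[SiteScore],
    mask: Mapping[str, Sequence[tuple[int, int]]] | None,
) -> list[SiteScore]:
    if not mask:
        return list(scores)
    out = []
    for s in scores:
        intervals = mask.get(s.chrom, ())
        if any(a <= s.pos <= b for a, b in intervals):
            continue
        out.append(s)
    return out


def sliding_window_fit(
    scores: Sequence[SiteScore],
    config: ScanConfig,
    chrom_lengths: Mapping[str, int] | None = None,
) -> FittedTrack:
    """Mean powered ED in windows of ``config.window`` bp stepped by
    ``config.step`` along each chromosome.

    Window centers run from W/2 to (chromosome end - W/2); each window
    covers [center - W/2, center + W/2).  Windows holding fewer than
    ``config.min_snps`` SNPs are undefined (NaN).  Chromosome ends default
    to the last SNP position when no lengths are supplied.
    """
    scores = _apply_mask(scores, config.mask)
    W = config.window
    step = config.effective_step
    track = FittedTrack(window=W, step=step)

    by_chrom: dict[str, list[SiteScore]] = {}
    for s in scores:
        by_chrom.setdefault(s.chrom, []).append(s)
    chroms = sorted(set(by_chrom) | set(chrom_lengths or {}))

    for chrom in chroms:
        chrom_scores = by_chrom.get(chrom, [])
        pos = np.array([s.pos for s in chrom_scores], dtype=np.int64)
        if not np.all(pos[1:] >= pos[:-1]):
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            chrom_scores = [chrom_scores[i] for i in order]
        length = (chrom_lengths or {}).get(chrom, int(pos[-1]) if len(pos) else 0)
        if length < W:
            logger.info("chromosome %s shorter than one window; empty track", chrom)
            track.chroms[chrom] = ChromTrack(
                chrom, np.array([]), np.array([]), np.array([])
            )
            continue
        centers = np.arange(W / 2, length - W / 2 + 0.5, step, dtype=float)
        vals = np.array([s.powered_ed for s in chrom_scores], dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        lo = np.searchsorted(pos, centers - W / 2, side="left")
        hi = np.searchsorted(pos, centers + W / 2, side="left")
        counts = hi - lo
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), np.nan)
        means = np.where(counts >= config.min_snps, means, np.nan)
        track.chroms[chrom] = ChromTrack(chrom, centers, means, counts.astype(int))
    return track


def compute_threshold(track: FittedTrack, n_sd: float = 3.0) -> ThresholdResult:
    """Genome-wide median and sample SD (n-1) of defined fitted values;
    the peak-calling threshold is median + n_sd * SD."""
    vals = track.defined_values()
    if len(vals) < 2:
        raise AnalysisError(
            f"need >= 2 defined windows genome-wide to set a threshold, "
            f"got {len(vals)}"
        )
    return ThresholdResult(
        median=float(np.median(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_sd=n_sd,
    )


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def call_candidate_regions(
    track: FittedTrack,
    tau: float,
    scores: Sequence[SiteScore],
    gap_tolerance: int = 0,
) -> list[CandidateRegion]:
    """Merge maximal runs of windows strictly above ``tau`` into regions.

    Within a run, up to ``gap_tolerance`` consecutive undefined windows may
    be bridged; a defined window at or below the threshold always ends the
    run.  Region boundaries are clipped to the first and last SNP inside
    the run's window span, matching the base-pair-resolved reporting of
    the statistic.  Runs whose clipped extents touch are merged.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in scores:
        pos_by_chrom.setdefault(s.chrom, [])  # type: ignore[arg-type]
    for chrom in pos_by_chrom:
        pos_by_chrom[chrom] = np.array(
            sorted(s.pos for s in scores if s.chrom == chrom), dtype=np.int64
        )

    regions: list[CandidateRegion] = []
    half = track.window / 2
    for chrom in sorted(track.chroms):
        ct = track.chroms[chrom]
        snp_pos = pos_by_chrom.get(chrom, np.array([], dtype=np.int64))
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(ct.centers)
        while i < n:
            v = ct.values[i]
            if np.isnan(v) or v <= tau:
                i += 1
                continue
            j = i
            last_above = i
            gap = 0
            while j + 1 < n:
                nxt = ct.values[j + 1]
                if not np.isnan(nxt) and nxt > tau:
                    j += 1
                    last_above = j
                    gap = 0
                elif np.isnan(nxt) and gap < gap_tolerance:
                    j += 1
                    gap += 1
                else:
                    break
            runs.append((i, last_above))
            i = last_above + 1

        chrom_regions: list[CandidateRegion] = []
        for a, b in runs:
            left = ct.centers[a] - half
            right = ct.centers[b] + half  # exclusive edge
            inside = snp_pos[(snp_pos >= left) & (snp_pos < right)]
            if len(inside) == 0:
                continue  # cannot happen when min_snps >= 1, kept defensive
            start, end = int(inside[0]), int(inside[-1])
            run_vals = ct.values[a : b + 1]
            peak = float(np.nanmax(run_vals))
            chrom_regions.append(
                CandidateRegion(chrom, start, end, peak, int(len(inside)))
            )

        # overlapping window extents from distinct runs can collide once
        # clipped to SNPs; merge any such neighbours
        merged: list[CandidateRegion] = []
        for r in chrom_regions:
            if merged and r.start <= merged[-1].end:
                prev = merged[-1]
                start, end = prev.start, max(prev.end, r.end)
                inside = snp_pos[(snp_pos >= start) & (snp_pos <= end)]
                merged[-1] = CandidateRegion(
                    chrom, start, end,
                    max(prev.peak_value, r.peak_value), int(len(inside)),
                )
            else:
                merged.append(r)
        regions.extend(merged)
    return regions


# ---------------------------------------------------------------------------
# One-call scan and plotting
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    scores: list[SiteScore]
    track: FittedTrack
    threshold: ThresholdResult
    regions: list[CandidateRegion]


def run_scan(
    sites: Sequence[BulkVariantSite],
    config: ScanConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> ScanResult:
    """Score filtered SNPs, fit the track, derive the threshold and call
    candidate regions in one pass."""
    config = config or ScanConfig()
    scores = score_sites(sites, power=config.power)
    track = sliding_window_fit(scores, config, chrom_lengths)
    threshold = compute_threshold(track)
    regions = call_candidate_regions(
        track, threshold.tau, scores, gap_tolerance=config.gap_tolerance
    )
    return ScanResult(scores, track, threshold, regions)


def plot_scan(track: FittedTrack, threshold: ThresholdResult, path) -> None:
    """Per-chromosome panels of the fitted track with the threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = [c for c in sorted(track.chroms) if len(track.chroms[c].centers)]
    if not chroms:
        return
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        ct = track.chroms[chrom]
        ax.plot(ct.centers / 1e6, ct.values, lw=0.8, color="tab:blue")
        ax.axhline(threshold.tau, color="tab:red", ls="--", lw=0.8,
                   label=f"median + {threshold.n_sd:g} SD")
        ax.set_ylabel("fitted ED$^p$")
        ax.set_title(chrom, fontsize=9)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
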