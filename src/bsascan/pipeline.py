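"""End-to-end orchestration: simulate -> read -> filter -> scan -> annotate.

Each mode writes its stage outputs plus a JSON manifest recording the
config echo, per-file checksums, per-filter removal counts, the number of
scored SNPs, the threshold and the regions called, so any run can be
audited and reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from . import variant_io
from .ed_scan import ScanConfig, plot_scan, run_scan
from .region_annot import (
    cross_reference_degs,
    genes_in_regions,
    pathway_enrichment,
    read_deg_tsv,
    read_gff3_genes,
    read_pathway_tsv,
    write_candidates_tsv,
    write_enrichment_tsv,
)
from .simdata import SimConfig, generate_annotation_fixture, simulate_dataset
from .site_filters import filter_ed_input, filter_variant_proximity

logger = logging.getLogger(__name__)

MODES = ("simulate", "scan", "annotate", "full")


@dataclass
class RunConfig:
    """One reproducible run: mode, inputs, outputs and stage parameters."""

    mode: str = "full"
    out_dir: Path = Path("bsascan_out")
    vcf: Path | None = None
    gff: Path | None = None
    pathways: Path | None = None
    degs: Path | None = None
    regions_bed: Path | None = None
    sample_high: str = "R01"
    sample_low: str = "R02"
    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    min_alt_reads: int = 2
    hom_threshold: float = 0.05
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("vcf", "gff", "pathways", "degs", "regions_bed"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        required: dict[str, Path | None] = {}
        if self.mode == "scan":
            required["vcf"] = self.vcf
        if self.mode == "annotate":
            required["regions_bed"] = self.regions_bed
            required["gff"] = self.gff
            required["pathways"] = self.pathways
        for name, p in required.items():
            if p is None:
                raise ConfigError(f"mode={self.mode} requires --{name}")
            if not Path(p).exists():
                raise ConfigError(f"{name} input does not exist: {p}")
        for name in ("degs",):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} input does not exist: {p}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "out_dir": str(self.out_dir),
            "vcf": str(self.vcf) if self.vcf else None,
            "gff": str(self.gff) if self.gff else None,
            "pathways": str(self.pathways) if self.pathways else None,
            "degs": str(self.degs) if self.degs else None,
            "regions_bed": str(self.regions_bed) if self.regions_bed else None,
            "sample_high": self.sample_high,
            "sample_low": self.sample_low,
            "sim": self.sim.to_dict(),
            "scan": {
                "power": self.scan.power,
                "window": self.scan.window,
                "step": self.scan.effective_step,
                "min_snps": self.scan.min_snps,
                "gap_tolerance": self.scan.gap_tolerance,
            },
            "min_alt_reads": self.min_alt_reads,
            "hom_threshold": self.hom_threshold,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_run_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    sim = SimConfig(**raw.pop("sim", {}))
    scan = ScanConfig(**raw.pop("scan", {}))
    return RunConfig(sim=sim, scan=scan, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured mode and return (and write) the manifest."""
    config.validate()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict[str, Any] = {
        "tool": f"bsascan {variant_io.__version__}",
        "config": config.to_dict(),
        "config_hash": chash,
        "stages": {},
        "complete": False,
    }

    try:
        if config.mode in ("simulate", "full"):
            _stage_simulate(config, out, manifest)
        if config.mode in ("scan", "full"):
            _stage_scan(config, out, manifest, chash)
        if config.mode in ("annotate", "full"):
            _stage_annotate(config, out, manifest)
    except Exception as exc:  # annotate the failing stage, then re-raise
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise
    manifest["complete"] = True
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict[str, Any], out: Path) -> Path:
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _record(manifest: dict, stage: str, outputs: dict[str, Path], stats: dict) -> None:
    manifest["stages"][stage] = {
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()},
        "stats": stats,
    }


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> None:
    sim = config.sim
    sites, _ = simulate_dataset(sim)
    vcf_path = out / "sim.vcf"
    variant_io.write_bulk_vcf(
        sites, sim.chrom_lengths, vcf_path,
        sample_high=config.sample_high, sample_low=config.sample_low,
    )
    fixture = generate_annotation_fixture(sim)
    fx_paths = fixture.write(out)
    cfg_path = out / "sim_config.yaml"
    cfg_path.write_text(yaml.safe_dump(sim.to_dict(), sort_keys=True))
    outputs = {"vcf": vcf_path, "sim_config": cfg_path, **fx_paths}
    logger.info("simulate: %d sites, %d genes", len(sites), len(fixture.genes))
    _record(manifest, "simulate", outputs, {
        "n_sites": len(sites),
        "n_genes": len(fixture.genes),
        "enriched_pathway": fixture.enriched_pathway,
    })
    # chain into the scan stage when running end-to-end
    if config.mode == "full":
        config.vcf = vcf_path
        config.gff = fx_paths["gff"]
        config.pathways = fx_paths["pathways"]
        config.degs = fx_paths["degs"]


def _stage_scan(config: RunConfig, out: Path, manifest: dict, chash: str) -> None:
    sites = variant_io.read_bulk_vcf(
        config.vcf, sample_high=config.sample_high, sample_low=config.sample_low
    )
    prox = filter_variant_proximity(sites)
    ed_in = filter_ed_input(
        prox.survivors,
        min_alt_reads=config.min_alt_reads,
        hom_threshold=config.hom_threshold,
    )
    chrom_lengths = None
    if config.mode == "full":
        chrom_lengths = dict(config.sim.chrom_lengths)
    result = run_scan(ed_in.survivors, config.scan, chrom_lengths)

    ed_path = variant_io.write_ed_table(result.scores, out / "ed.tsv", chash)
    track_path = variant_io.write_track_tsv(result.track, out / "track.tsv", chash)
    bed_path = variant_io.write_regions_bed(result.regions, out / "regions.bed", chash)
    filt_path = out / "filters.json"
    filt_path.write_text(json.dumps(
        {"proximity": prox.summary(), "ed_input": ed_in.summary()}, indent=2
    ) + "\n")
    plot_path = out / "scan.png"
    plot_scan(result.track, result.threshold, plot_path)

    logger.info(
        "scan: %d sites in, %d scored, tau=%.6g, %d region(s)",
        len(sites), len(result.scores), result.threshold.tau, len(result.regions),
    )
    _record(manifest, "scan", {
        "ed_table": ed_path, "track": track_path, "regions": bed_path,
        "filters": filt_path,
    }, {
        "n_input_sites": len(sites),
        "proximity_removed": prox.removed_counts,
        "ed_input_removed": ed_in.removed_counts,
        "n_scored_snps": len(result.scores),
        "threshold_median": result.threshold.median,
        "threshold_sd": result.threshold.sd,
        "tau": result.threshold.tau,
        "n_regions": len(result.regions),
        "regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "peak": r.peak_value, "n_snps": r.n_snps}
            for r in result.regions
        ],
    })
    if config.mode == "full":
        config.regions_bed = bed_path


def _stage_annotate(config: RunConfig, out: Path, manifest: dict) -> None:
    regions = variant_io.read_regions_bed(config.regions_bed)
    genes = read_gff3_genes(config.gff)
    pathway_table = read_pathway_tsv(config.pathways)
    by_region = genes_in_regions(regions, genes)
    region_gene_ids = sorted(
        {g.gene_id for hits in by_region.values() for g in hits}
    )
    all_ids = [g.gene_id for g in genes]
    enrichment = pathway_enrichment(
        region_gene_ids, all_ids, pathway_table, alpha=config.alpha
    )
    enr_path = write_enrichment_tsv(enrichment, out / "enrichment.tsv")
    outputs = {"enrichment": enr_path}
    stats: dict[str, Any] = {
        "n_regions": len(regions),
        "n_region_genes": len(region_gene_ids),
        "n_pathways_tested": len(enrichment),
        "n_significant_pathways": sum(r.significant for r in enrichment),
    }
    if config.degs is not None:
        degs = read_deg_tsv(config.degs)
        candidates, n_untested = cross_reference_degs(
            region_gene_ids, degs, alpha=config.alpha
        )
        cand_path = write_candidates_tsv(candidates, out / "candidates.tsv")
        outputs["candidates"] = cand_path
        stats["n_candidate_genes"] = len(candidates)
        stats["n_untested_genes"] = n_untested
    logger.info(
        "annotate: %d region gene(s), %d pathway(s) tested",
        len(region_gene_ids), len(enrichment),
    )
    _record(manifest, "annotate", outputs, stats)
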