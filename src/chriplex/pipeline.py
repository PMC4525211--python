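"""End-to-end orchestration: simulate -> enrich -> convert -> peaks -> triplex.

Stages run in dependency order; each writes its outputs under the run
directory and contributes digests to a manifest, so two runs of the same
configuration and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

import chriplex
from chriplex import io
from chriplex.conversions import (
    call_conversions,
    contact_site_transcripts,
    map_events_to_transcripts,
    sample_specific_events,
    substitution_spectrum,
)
from chriplex.enrichment import (
    call_dual_enriched,
    hypergeometric_overlap,
    quantify_rpkm,
    records_to_frame,
)
from chriplex.peaks import associate_peaks, build_regulatory_domains, intersect_with_marks
from chriplex.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_chrip_counts,
    simulate_conversion_pileup,
    simulate_gene_sets,
    simulate_peaks,
)
from chriplex.triplex import TriplexParams, summit_flank_density

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    min_alt_depth: int = 2
    triplex: TriplexParams = dataclasses.field(default_factory=TriplexParams)
    density_window: int = 200
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: Mapping[str, Any] = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.get("simulation", {}))
        tri = TriplexParams(**{
            k: tuple(v) if k == "motifs" else v
            for k, v in raw.get("triplex", {}).items()
        })
        keys = {
            "fold_threshold", "pseudocount", "min_alt_depth",
            "density_window", "basal_up", "basal_down", "max_extension", "log_level",
        }
        extra = {k: v for k, v in raw.items() if k in keys}
        return cls(outdir=Path(outdir), simulation=sim, triplex=tri, **extra)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage on a fresh simulation; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": chriplex.__version__,
        "seed": config.simulation.seed,
        "parameters": {
            "simulation": dataclasses.asdict(config.simulation),
            "triplex": dataclasses.asdict(config.triplex),
            "fold_threshold": config.fold_threshold,
            "pseudocount": config.pseudocount,
            "min_alt_depth": config.min_alt_depth,
            "density_window": config.density_window,
            "basal_up": config.basal_up,
            "basal_down": config.basal_down,
            "max_extension": config.max_extension,
        },
        "stages": [],
        "digests": {},
    }

    def _stage(name: str, fn):
        logger.info("stage %s", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)

    state: dict[str, Any] = {}

    def _simulate():
        genome, annotation = generate_genome(config.simulation)
        counts, truth_counts = simulate_chrip_counts(config.simulation, annotation)
        pileups, truth_sites = simulate_conversion_pileup(
            config.simulation, annotation, genome
        )
        peaks, marks, truth_peaks, genome = simulate_peaks(config.simulation, genome)
        universe, truth_genes = simulate_gene_sets(config.simulation)
        truth = (
            truth_counts.merge(truth_sites).merge(truth_peaks).merge(truth_genes)
        )
        io.write_fasta(genome, outdir / "genome.fa")
        io.write_gtf(annotation, outdir / "transcripts.gtf")
        io.write_tsv(counts, outdir / "chrip_counts.tsv")
        for sample, frame in pileups.items():
            io.write_tsv(frame, outdir / f"pileup_{sample}.tsv", index=False)
        io.write_bed(peaks, outdir / "chop_peaks.bed")
        io.write_bed(marks, outdir / "h3k4me1_peaks.bed")
        (outdir / "ground_truth.json").write_text(truth.to_json())
        state.update(
            genome=genome, annotation=annotation, counts=counts,
            pileups=pileups, peaks=peaks, marks=marks, universe=universe,
            truth=truth,
        )

    def _enrich():
        rpkm = quantify_rpkm(state["counts"], state["annotation"])
        enriched, records = call_dual_enriched(
            rpkm, config.fold_threshold, config.pseudocount
        )
        io.write_tsv(records_to_frame(records), outdir / "enrichment.tsv")
        io.write_gene_list(enriched, outdir / "enriched_transcripts.txt")
        state["enriched"] = enriched

    def _convert():
        events = {
            sample: call_conversions(frame, sample, config.min_alt_depth)
            for sample, frame in state["pileups"].items()
        }
        specific = sample_specific_events(
            events["ezh2"], events["input"], events["h3k27me3"]
        )
        spectrum = substitution_spectrum(specific, "ezh2_specific")
        mapping, _ = map_events_to_transcripts(specific, state["annotation"])
        contact = contact_site_transcripts(mapping)
        overlap = hypergeometric_overlap(
            state["enriched"] & set(state["annotation"].ids()),
            contact,
            state["annotation"].ids(),
        )
        (outdir / "conversion_spectrum.json").write_text(
            json.dumps(spectrum.counts, indent=2, sort_keys=True)
        )
        (outdir / "contact_overlap.json").write_text(
            json.dumps(overlap.__dict__, indent=2, sort_keys=True)
        )
        io.write_gene_list(contact, outdir / "contact_transcripts.txt")

    def _peaks():
        chrom_sizes = {c: len(s) for c, s in state["genome"].items()}
        domains = build_regulatory_domains(
            state["annotation"],
            config.basal_up,
            config.basal_down,
            config.max_extension,
            chrom_sizes,
        )
        assoc = associate_peaks(state["peaks"], domains)
        _, counts = intersect_with_marks(state["peaks"], state["marks"])
        summary = {
            "n_peaks": len(state["peaks"]),
            "n_associated": len(assoc.peak_genes),
            "n_promoter": len(assoc.promoter_peaks),
            "n_distal": len(assoc.distal_peaks),
            "n_unassociated": len(assoc.unassociated_peaks),
            "n_associated_genes": len(assoc.associated_genes),
            "h3k4me1_overlap": counts,
        }
        (outdir / "peak_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )

    def _triplex():
        result = summit_flank_density(
            state["peaks"], state["genome"], config.triplex, config.density_window
        )
        io.write_tsv(result.per_peak, outdir / "trts_density.tsv", index=False)
        (outdir / "trts_density.json").write_text(
            json.dumps(
                {
                    "n_summit_greater": result.n_summit_greater,
                    "n_flank_greater": result.n_flank_greater,
                    "n_ties": result.n_ties,
                    "direction": result.direction,
                    "p_value": result.p_value,
                },
                indent=2,
                sort_keys=True,
            )
        )

    _stage("simulate", _simulate)
    _stage("enrich", _enrich)
    _stage("convert", _convert)
    _stage("peaks", _peaks)
    _stage("triplex", _triplex)

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["digests"][path.name] = _digest(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
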