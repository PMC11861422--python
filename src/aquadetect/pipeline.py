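"""End-to-end demo pipeline: simulate -> map -> calibrate -> detect -> demarcate -> tree.

A single validated configuration (:class:`RunConfig`) drives a fully
synthetic, fully seeded run that exercises every stage and writes all
artifacts (FASTA/BED inputs, SAM alignments, coverage and detection TSVs,
threshold-model JSON, demarcation TSV, Newick tree, machine-readable run
log).  Outputs are bit-reproducible given the same config.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .coregenes import core_gene_selection  # noqa: F401  (re-exported for run extensions)
from .detection import (
    ThresholdModel,
    detection_report,
    fit_saturation,
    select_min_asymptote,
    subsample_series,
)
from .errors import FitError, ParameterError
from .io import (
    write_bed,
    write_genome_fasta,
    write_newick,
    write_reads,
    write_sam,
    write_tsv,
)
from .mapping import build_reference, compute_coverage, map_reads
from .phylo import MultipleAlignment, bootstrap_support, midpoint_root
from .synthetic import (
    CommunityDesign,
    derive_relative,
    generate_genome,
    plant_shared_repeat,
    simulate_metagenome,
)
from .taxonomy import fragment_ani, gbdp_d4, species_demarcation


class CommunityConfig(BaseModel):
    n_genomes: int = Field(3, ge=2, description="distinct species genomes")
    genome_length: int = Field(60_000, ge=11_000)
    gc: float = Field(0.42, gt=0.0, lt=1.0)
    relative_rate: float = Field(
        0.10, ge=0.0, lt=0.35,
        description="divergence of the decoy relative of the first genome",
    )
    repeat_length: int = Field(2_000, ge=100)
    repeat_copies: int = Field(1, ge=0)
    read_length: int = Field(150, ge=50)
    error_rate: float = Field(0.002, ge=0.0, lt=1.0)
    n_reads: int = Field(4_000, ge=100)
    abundances: list[float] = Field(
        default_factory=lambda: [0.7, 0.3],
        description="abundances of the first k genomes; the rest are absent",
    )

    @field_validator("abundances")
    @classmethod
    def _sum_to_one(cls, v: list[float]) -> list[float]:
        if not v or abs(sum(v) - 1.0) > 1e-6:
            raise ValueError("abundances must be non-empty and sum to 1")
        return v


class MappingConfig(BaseModel):
    min_identity_pct: float = Field(95.0, gt=0.0, le=100.0)
    k: int = Field(31, ge=11)


class DetectionConfig(BaseModel):
    model: str = Field("published", pattern="^(published|fitted)$")
    fractions: list[float] = Field(
        default_factory=lambda: [0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0]
    )
    breadth_cutoff_pct: float = 50.0
    floor_pct: float = 10.0


class PhylogenyConfig(BaseModel):
    enabled: bool = True
    marker_length: int = Field(1_200, ge=600)
    marker_rate_step: float = Field(0.02, gt=0.0, lt=0.1)
    bootstrap_replicates: int = Field(100, ge=10)


class TaxonomyConfig(BaseModel):
    enabled: bool = True


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    seed: int = 0
    community: CommunityConfig = Field(default_factory=CommunityConfig)
    mapping: MappingConfig = Field(default_factory=MappingConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    taxonomy: TaxonomyConfig = Field(default_factory=TaxonomyConfig)
    phylogeny: PhylogenyConfig = Field(default_factory=PhylogenyConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, str]:
    """Execute the full synthetic pipeline; returns artifact name -> path."""
    cc = config.community
    if len(cc.abundances) > cc.n_genomes:
        raise ParameterError("more abundances than genomes")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- simulate -----------------------------------------------------------
    genomes = [
        generate_genome(cc.genome_length, cc.gc, seed=config.seed * 1000 + i,
                        genome_id=f"sp{i:02d}")
        for i in range(cc.n_genomes)
    ]
    decoy = derive_relative(genomes[0], cc.relative_rate,
                            seed=config.seed * 1000 + 500, genome_id="sp00_rel")
    all_genomes = genomes + [decoy]
    if cc.repeat_copies > 0:
        all_genomes = plant_shared_repeat(
            all_genomes, cc.repeat_length, cc.repeat_copies,
            seed=config.seed * 1000 + 600,
        )
    for g in all_genomes:
        p = out / f"{g.genome_id}.fasta"
        write_genome_fasta(g, p)
        artifacts[f"genome:{g.genome_id}"] = str(p)
        if g.masked_intervals:
            bp = out / f"{g.genome_id}.mask.bed"
            write_bed(g, bp)
            artifacts[f"mask:{g.genome_id}"] = str(bp)

    members = [(all_genomes[i].genome_id, a) for i, a in enumerate(cc.abundances)]
    design = CommunityDesign(
        members=members, n_reads=cc.n_reads, read_length=cc.read_length,
        substitution_error_rate=cc.error_rate, seed=config.seed * 1000 + 700,
    )
    reads = simulate_metagenome(design, all_genomes)
    reads_path = out / "reads.fasta"
    write_reads(reads, reads_path, fmt="fasta")
    artifacts["reads"] = str(reads_path)

    # --- map + coverage -----------------------------------------------------
    ref = build_reference(all_genomes)
    alignments = map_reads(
        reads, ref,
        min_identity_pct=config.mapping.min_identity_pct, k=config.mapping.k,
    )
    sam_path = out / "alignments.sam"
    write_sam(alignments, ref, sam_path)
    artifacts["alignments"] = str(sam_path)

    profiles = compute_coverage(alignments, ref, total_reads=len(reads))
    cov_df = pd.DataFrame(
        [
            {
                "genome_id": p.genome_id,
                "unmasked_length": int(ref.unmasked_length[ref.genome_index(p.genome_id)]),
                "mapped_reads": p.mapped_reads,
                "mapped_read_pct": p.mapped_read_pct,
                "mean_depth": p.mean_depth,
                "breadth_pct": p.breadth_pct,
            }
            for p in profiles
        ]
    )
    cov_path = out / "coverage.tsv"
    write_tsv(cov_df, cov_path)
    artifacts["coverage"] = str(cov_path)

    # --- calibrate + detect -------------------------------------------------
    if config.detection.model == "fitted":
        series = subsample_series(
            alignments, ref, total_reads=len(reads),
            fractions=tuple(config.detection.fractions),
            seed=config.seed * 1000 + 800,
        )
        models = {}
        for gid, s in series.items():
            try:
                models[gid] = fit_saturation(s)
            except (FitError, ParameterError):
                continue
        if not models:
            raise FitError("no genome yielded a usable saturation fit")
        model = select_min_asymptote(models)
    else:
        model = ThresholdModel.published()
    model_path = out / "model.json"
    model_path.write_text(model.to_json() + "\n")
    artifacts["model"] = str(model_path)

    det = detection_report(
        profiles, model, metagenome_id="synthetic",
        breadth_cutoff_pct=config.detection.breadth_cutoff_pct,
        floor_pct=config.detection.floor_pct,
    )
    det_path = out / "detection.tsv"
    write_tsv(det, det_path)
    artifacts["detection"] = str(det_path)

    # --- demarcation --------------------------------------------------------
    if config.taxonomy.enabled:
        pairs = [(all_genomes[0], decoy)]
        if cc.n_genomes >= 2:
            pairs.append((genomes[0], genomes[1]))
        rows = []
        for a, b in pairs:
            ani = fragment_ani(a, b)
            ddh = gbdp_d4(a, b)
            dec = species_demarcation(ani, ddh)
            rows.append(
                {
                    "genome_a": a.genome_id, "genome_b": b.genome_id,
                    "ani_pct": ani.ani_pct, "aligned_fraction": ani.aligned_fraction,
                    "d4": ddh.d4_distance, "ddh_pct": ddh.ddh_pct,
                    "same_species": dec.same_species,
                }
            )
        dem_path = out / "demarcation.tsv"
        write_tsv(pd.DataFrame(rows), dem_path)
        artifacts["demarcation"] = str(dem_path)

    # --- marker tree --------------------------------------------------------
    if config.phylogeny.enabled:
        pc = config.phylogeny
        ancestor = generate_genome(
            max(pc.marker_length, 1000), 0.5, seed=config.seed * 1000 + 900,
            genome_id="marker",
        ).contigs[0][: pc.marker_length]
        taxa, rows = [], []
        for i, g in enumerate(all_genomes):
            rel = derive_relative(
                # wrap the marker in a GenomeRecord to reuse the mutation model
                type(g)(genome_id="m", contigs=[ancestor]),
                min(pc.marker_rate_step * (i + 1), 0.30),
                seed=config.seed * 1000 + 910 + i,
            )
            taxa.append(g.genome_id)
            rows.append(rel.contigs[0])
        aln = MultipleAlignment(taxa, rows)
        tree = bootstrap_support(
            aln, n_replicates=pc.bootstrap_replicates, seed=config.seed * 1000 + 920
        )
        rooted = midpoint_root(tree)
        tree_path = out / "marker_tree.nwk"
        write_newick(rooted, tree_path)
        artifacts["tree"] = str(tree_path)

    # --- run log ------------------------------------------------------------
    log = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "n_reads": len(reads),
        "n_aligned": len(alignments),
        "artifacts": artifacts,
    }
    log_path = out / "runlog.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    artifacts["runlog"] = str(log_path)
    return artifacts
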