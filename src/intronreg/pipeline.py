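"""End-to-end orchestration of the first-intron analysis stages.

The pipeline runs classify -> fragments -> orthology/conservation ->
motif scan -> ChIP assignment -> PDI network -> in-degree modeling,
reading real input files or a self-generated synthetic bundle, and writes
per-stage TSV/JSON outputs plus a summary JSON that echoes every
threshold and the seed (auditability: the summary states exactly the
configuration that produced the outputs).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np

from intronreg import chip as chipmod
from intronreg import degree as degreemod
from intronreg import genome as genomemod
from intronreg import motifscan
from intronreg import orthology
from intronreg import pdi as pdimod
from intronreg import simulate as simmod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "intronreg_out"
    seed: int = 0
    simulate: bool = False
    n_genes: int = 120
    # input paths (ignored when simulate=True)
    fasta_a: str | None = None
    gff_a: str | None = None
    fasta_b: str | None = None
    gff_b: str | None = None
    orthologs: str | None = None
    pwms: str | None = None
    peaks: str | None = None
    pdi_edges: str | None = None
    coexpression: str | None = None
    # thresholds
    promoter_span: int = 2000
    conservation_cutoff: int = 500
    long_first_intron_cutoff: int = 250
    occupancy_threshold: float = 0.09
    j_cut: float = 0.3
    coexp_cuts: tuple[float, float] = (0.2, 0.5)
    projection_bins: tuple[int, ...] = (65, 129, 257, 513)
    # stage toggles
    run_classify: bool = True
    run_conserve: bool = True
    run_scan: bool = True
    run_chip: bool = True
    run_pdi: bool = True
    run_degree: bool = True

    def __post_init__(self) -> None:
        if self.promoter_span <= 0 or self.conservation_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if list(self.projection_bins) != sorted(set(self.projection_bins)):
            raise ValueError("projection bins must be strictly increasing")


def _require(path: str | None, what: str) -> str:
    if path is None or not os.path.exists(path or ""):
        raise FileNotFoundError(f"{what} input missing: {path}")
    return path


def _write_json(outdir: str, name: str, payload) -> None:
    with open(os.path.join(outdir, name), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns (and writes) the summary dict."""
    os.makedirs(config.outdir, exist_ok=True)
    summary: dict = {"config": asdict(config), "stages": {}}
    stage = "setup"
    try:
        if config.simulate:
            simcfg = simmod.SimConfig.conservation_preset(
                seed=config.seed, n_genes=config.n_genes
            )
            pair = simmod.simulate_genome_pair(simcfg)
            simdir = os.path.join(config.outdir, "sim")
            paths = simmod.write_simulation(pair, simdir)
            peaks, _ = simmod.simulate_chip_peaks(pair)
            simmod.write_peaks_bed(peaks, os.path.join(simdir, "peaks.bed"))
            network, coexpression = simmod.simulate_pdi_network(simcfg)
            with open(os.path.join(simdir, "pdi.tsv"), "w") as fh:
                fh.write(network.to_tsv())
            simmod.write_coexpression_tsv(
                coexpression, os.path.join(simdir, "coexpression.tsv")
            )
            config = dataclass_replace(
                config,
                fasta_a=paths["fasta_a"], gff_a=paths["gff_a"],
                fasta_b=paths["fasta_b"], gff_b=paths["gff_b"],
                orthologs=paths["orthologs"], pwms=paths["pwms"],
                peaks=os.path.join(simdir, "peaks.bed"),
                pdi_edges=os.path.join(simdir, "pdi.tsv"),
                coexpression=os.path.join(simdir, "coexpression.tsv"),
            )
            summary["config"]["resolved_inputs"] = paths

        stage = "load"
        genome_a, genes_a = genomemod.load_annotation(
            _require(config.gff_a, "annotation A"),
            _require(config.fasta_a, "genome A"), "A",
        )
        genes_by_id_a = {g.gene_id: g for g in genes_a}

        statuses = [genomemod.classify_conventional(g) for g in genes_a]
        conventional_ids = {s.gene_id for s in statuses if s.is_conventional}

        if config.run_classify:
            stage = "classify"
            with open(os.path.join(config.outdir, "conventional.tsv"), "w") as fh:
                fh.write("gene\tutr5_intron\talt_start\toperon_downstream\t"
                         "conventional\n")
                for s in statuses:
                    fh.write(
                        f"{s.gene_id}\t{int(s.has_utr5_intron)}\t"
                        f"{int(s.has_alt_start)}\t{int(s.is_operon_downstream)}\t"
                        f"{int(s.is_conventional)}\n"
                    )
            summary["stages"]["classify"] = {
                "n_genes": len(statuses),
                "n_conventional": len(conventional_ids),
                "conventional_fraction": len(conventional_ids) / len(statuses),
            }

        stage = "fragments"
        fragments_a: dict[str, list] = {}
        promoters_a: dict[str, object] = {}
        for g in genes_a:
            frags = genomemod.extract_fragments(g, genome_a)
            prom = genomemod.define_promoter(
                g, genes_a, genome_a, span=config.promoter_span
            )
            fragments_a[g.gene_id] = frags
            promoters_a[g.gene_id] = prom
        all_frags_a = [
            f for gid in conventional_ids
            for f in fragments_a[gid] + [promoters_a[gid]]
        ]
        with open(os.path.join(config.outdir, "fragments.bed"), "w") as fh:
            fh.write(genomemod.fragments_to_bed(all_frags_a))
        n_zero_prom = sum(
            1 for gid in conventional_ids if promoters_a[gid].length == 0
        )
        summary["stages"]["fragments"] = {
            "n_fragments": len(all_frags_a),
            "n_zero_length_promoters_excluded": n_zero_prom,
        }

        identical: list[tuple[str, str]] = []
        genes_by_id_b: dict = {}
        fragments_b: dict[str, list] = {}
        if config.run_conserve or config.run_scan:
            stage = "orthology"
            genome_b, genes_b = genomemod.load_annotation(
                _require(config.gff_b, "annotation B"),
                _require(config.fasta_b, "genome B"), "B",
            )
            genes_by_id_b = {g.gene_id: g for g in genes_b}
            ortho_pairs = []
            with open(_require(config.orthologs, "ortholog table")) as fh:
                for line in fh:
                    if line.strip():
                        ga, gb = line.split()[:2]
                        ortho_pairs.append((ga, gb))
            for ga, gb in ortho_pairs:
                if ga not in genes_by_id_a or gb not in genes_by_id_b:
                    continue
                if ga not in conventional_ids:
                    continue
                ex_a = [f.sequence for f in fragments_a[ga] if f.kind == "exon"]
                frags_b = genomemod.extract_fragments(genes_by_id_b[gb], genome_b)
                fragments_b[gb] = frags_b
                ex_b = [f.sequence for f in frags_b if f.kind == "exon"]
                corr = orthology.align_exons_translated(ex_a, ex_b)
                if corr.is_identical_structure:
                    identical.append((ga, gb))
            summary["stages"]["orthology"] = {
                "n_ortholog_pairs": len(ortho_pairs),
                "n_identical_structure": len(identical),
            }

        if config.run_conserve:
            stage = "conserve"
            records = []
            for ga, gb in identical:
                ia = [f.length for f in sorted(
                    (f for f in fragments_a[ga] if f.kind == "intron"),
                    key=lambda f: f.index)]
                ib = [f.length for f in sorted(
                    (f for f in fragments_b[gb] if f.kind == "intron"),
                    key=lambda f: f.index)]
                records.extend(orthology.length_ratio_records(ga, gb, ia, ib))
            report = orthology.conservation_comparison(
                records, cutoff=config.conservation_cutoff
            )
            with open(os.path.join(config.outdir, "length_ratios.tsv"), "w") as fh:
                fh.write("gene_a\tgene_b\tintron\tlen_a\tlen_b\tratio\tpasses\n")
                for r in records:
                    fh.write(
                        f"{r.gene_a}\t{r.gene_b}\t{r.intron_index}\t{r.length_a}\t"
                        f"{r.length_b}\t{r.ratio:.4f}\t"
                        f"{int(r.passes_filter(config.conservation_cutoff))}\n"
                    )
            _write_json(config.outdir, "conservation.json", report.to_dict())
            summary["stages"]["conserve"] = report.to_dict()

        if config.run_scan:
            stage = "scan"
            pwms = motifscan.read_pwms_tsv(_require(config.pwms, "PWM table"))
            ems = [
                motifscan.pwm_to_energy(p, threshold=config.occupancy_threshold)
                for p in pwms
            ]
            entries = []
            for ga, gb in identical:
                pa = {("promoter", 1): promoters_a[ga].sequence}
                pa.update({
                    (f.kind, f.index): f.sequence for f in fragments_a[ga]
                    if f.kind == "intron"
                })
                pb = {
                    (f.kind, f.index): f.sequence for f in fragments_b[gb]
                    if f.kind == "intron"
                }
                gb_model = genes_by_id_b[gb]
                pb[("promoter", 1)] = genomemod.define_promoter(
                    gb_model, list(genes_by_id_b.values()), genome_b,
                    span=config.promoter_span,
                ).sequence
                for key in pa:
                    if key not in pb or not pa[key] or not pb[key]:
                        continue
                    conserved = motifscan.conserved_predicted_tfs(
                        pa[key], pb[key], ems
                    )
                    kind, index = key
                    cls = ("promoter" if kind == "promoter"
                           else "first_intron" if index == 1 else "other_intron")
                    entries.append((cls, conserved))
            scan_summary = motifscan.mean_conserved_by_region(entries)
            _write_json(config.outdir, "conserved_predicted.json",
                        scan_summary.to_dict())
            summary["stages"]["scan"] = scan_summary.to_dict()

        if config.run_chip:
            stage = "chip"
            peaks = chipmod.read_peaks_bed(_require(config.peaks, "ChIP peaks"))
            assignments = chipmod.assign_peaks(peaks, all_frags_a)
            with open(os.path.join(config.outdir, "chip_assignments.tsv"), "w") as fh:
                fh.write(chipmod.assignments_to_tsv(assignments))
            binding = chipmod.region_binding_summary(assignments, all_frags_a)
            firsts = [
                f for f in all_frags_a if f.kind == "intron" and f.index == 1
            ]
            corr = None
            if len(firsts) >= 3:
                counts = [
                    len(assignments[(f.gene_id, f.kind, f.index)]) for f in firsts
                ]
                lengths = [f.length for f in firsts]
                corr = chipmod.length_binding_correlation(lengths, counts)
            oi = []
            for gid in conventional_ids:
                p_set = assignments.get((gid, "promoter", 1), set())
                i_set = assignments.get((gid, "intron", 1), set())
                frac = chipmod.promoter_intron_overlap(p_set, i_set)
                if frac is not None:
                    oi.append(frac)
            chip_summary = {
                "binding": binding.to_dict(),
                "length_correlation": corr,
                "mean_overlap_intron_fraction": (
                    float(np.mean(oi)) if oi else None
                ),
                "n_oi_genes": len(oi),
            }
            _write_json(config.outdir, "chip_summary.json", chip_summary)
            summary["stages"]["chip"] = chip_summary

        if config.run_pdi or config.run_degree:
            stage = "pdi"
            network = pdimod.PDINetwork.from_tsv(
                _require(config.pdi_edges, "PDI edge list")
            )
            pdi_genes = sorted(network.genes())

        if config.run_pdi:
            coexpression = pdimod.read_coexpression_tsv(
                _require(config.coexpression, "co-expression table")
            )
            table = pdimod.similarity_table(network, pdi_genes, coexpression)
            table.to_csv(
                os.path.join(config.outdir, "similarity.tsv"), sep="\t", index=False
            )
            enrich = {
                mode: pdimod.coexpression_enrichment(
                    table, mode=mode, j_cut=config.j_cut,
                    coexp_cuts=config.coexp_cuts,
                ).to_dict()
                for mode in ("promoter", "first_intron", "combined")
            }
            _write_json(config.outdir, "coexpression_enrichment.json", enrich)
            summary["stages"]["pdi"] = {
                "n_pairs": int(len(table)),
                "enrichment": enrich,
            }

        if config.run_degree:
            stage = "degree"
            prom_deg = np.array([
                network.in_degree(g, "promoter") for g in pdi_genes
            ], dtype=float)
            intr_deg = np.array([
                network.in_degree(g, "first_intron") for g in pdi_genes
            ], dtype=float)
            comparison = degreemod.compare_degree_models(prom_deg, intr_deg)
            _write_json(config.outdir, "degree_models.json", comparison.to_dict())
            summary["stages"]["degree"] = comparison.to_dict()

    except Exception:
        logger.exception("pipeline failed during stage %s", stage)
        summary["failed_stage"] = stage
        _write_json(config.outdir, "summary.json", summary)
        raise
    _write_json(config.outdir, "summary.json", summary)
    return summary


def dataclass_replace(config: PipelineConfig, **kw) -> PipelineConfig:
    from dataclasses import replace

    return replace(config, **kw)
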