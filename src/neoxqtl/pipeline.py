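"""End-to-end pipeline runner: simulate -> qc -> map -> scan -> marey -> xo -> coverage.

Each stage writes its artifacts under the output directory and contributes
to a machine-readable ``summary.json``. A single top-level seed fans out to
per-stage streams via fixed offsets so stages are reproducible in
isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from neoxqtl import crossovers, linkmap, marey, qc, qtl, vcfio
from neoxqtl import coverage as sexcov
from neoxqtl.config import RunConfig
from neoxqtl.genome import default_genome
from neoxqtl.simulate import (
    ObservationModel,
    QTLModel,
    SimulationConfig,
    ViabilityModel,
    simulate_annotation,
    simulate_cross,
    simulate_depth,
    write_gff3,
)

log = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"simulate": 11, "scan": 23, "coverage": 37}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run all stages; returns (and writes) the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # --- inputs / simulation ---------------------------------------
        stage = "simulate"
        annotation_path = config.annotation
        depth_paths = (config.depth_male, config.depth_female)
        if config.simulate.enabled:
            s = config.simulate
            genome = default_genome(with_inversions=s.with_inversions)
            sim_cfg = SimulationConfig(
                genome=genome,
                n_markers=s.n_markers,
                n_f2=s.n_f2,
                n_families=s.n_families,
                qtl=QTLModel(
                    pos_bp=s.qtl_pos_bp,
                    mean_az_hemi=s.qtl_mean_az_hemi,
                    mean_ut_hemi=s.qtl_mean_ut_hemi,
                    mean_het_female=s.qtl_mean_het_female,
                    mean_ut_female=s.qtl_mean_ut_female,
                    resid_sd=s.qtl_resid_sd,
                ),
                observation=ObservationModel(
                    genotype_error_rate=s.genotype_error_rate,
                    missing_rate=s.missing_rate,
                    neoy_contamination_rate=s.neoy_contamination_rate,
                ),
                viability=ViabilityModel(
                    region=s.viability_region,
                    male_recombinant_survival=s.viability_survival,
                ),
            )
            sim_seed = _stage_seed(config.seed, "simulate")
            dataset = simulate_cross(sim_cfg, seed=sim_seed)
            gm = dataset.genotypes
            phenotypes = dataset.phenotypes
            vcfio.write_vcf(gm, out / "genotypes.vcf")
            vcfio.write_sample_sheet(gm, out / "samples.tsv")
            vcfio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
            (out / "truth.json").write_text(dataset.truth.to_json())
            rng = np.random.default_rng(sim_seed + 1)
            ann = simulate_annotation(genome, rng)
            write_gff3(ann, out / "annotation.gff3")
            annotation_path = str(out / "annotation.gff3")
            cov_rng = np.random.default_rng(_stage_seed(config.seed, "coverage"))
            for sex, fname in (("M", "depth_male.tsv"), ("F", "depth_female.tsv")):
                vcfio.write_depth_tsv(simulate_depth(genome, sex, cov_rng), out / fname)
            depth_paths = (str(out / "depth_male.tsv"), str(out / "depth_female.tsv"))
            summary["simulate"] = {
                "n_f2": s.n_f2,
                "n_markers": gm.n_markers,
                "true_map_lengths_cm": dataset.truth.map_lengths_cm,
            }
        else:
            if not (config.vcf and config.sample_sheet and config.phenotype_table):
                raise ValueError("need vcf, sample_sheet and phenotype_table when not simulating")
            sheet = vcfio.read_sample_sheet(config.sample_sheet)
            gm, vcf_report = vcfio.read_genotype_vcf(config.vcf, sheet, config.x_chrom)
            phenotypes = vcfio.read_phenotypes(config.phenotype_table)
            summary["input"] = vcf_report

        # --- qc ----------------------------------------------------------
        stage = "qc"
        filtered, report = qc.run_qc(
            gm,
            p0_az_id=config.p0_az_id,
            p0_ut_id=config.p0_ut_id,
            gq_min=config.qc.gq_min,
            dp_min=config.qc.dp_min,
            marker_missing_max=config.qc.marker_missing_max,
            individual_missing_max=config.qc.individual_missing_max,
            min_gap_bp=config.qc.min_gap_bp,
            distortion_alpha=config.qc.distortion_alpha,
        )
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        vcfio.write_vcf(filtered, out / "genotypes.filtered.vcf")
        summary["qc"] = {
            "markers_in": gm.n_markers,
            "markers_out": filtered.n_markers,
            "individuals_out": filtered.n_individuals,
        }

        # --- linkage map --------------------------------------------------
        stage = "linkmap"
        orders = None
        if config.linkmap.validate_order:
            orders, removed = linkmap.order_and_validate(
                filtered, config.linkmap.map_function
            )
            if removed:
                keep = ~filtered.markers["name"].isin(removed).to_numpy()
                filtered = filtered.take_markers(keep)
            summary.setdefault("linkmap", {})["cross_linked_removed"] = removed
        gmap = linkmap.estimate_map(
            filtered,
            orders,
            error_prob=config.linkmap.error_prob,
            map_function=config.linkmap.map_function,
            error_lod_cutoff=config.linkmap.error_lod_cutoff,
        )
        vcfio.write_map_tsv(gmap, out / "map.tsv")
        summary.setdefault("linkmap", {}).update(
            {
                "total_cm": gmap.total_cm,
                "group_lengths_cm": {g.chrom: g.length_cm for g in gmap.groups},
            }
        )
        if config.linkmap.sex_specific:
            male_map, female_map = linkmap.sex_specific_maps(
                filtered,
                orders,
                error_prob=config.linkmap.error_prob,
                map_function=config.linkmap.map_function,
            )
            vcfio.write_map_tsv(male_map, out / "map.male.tsv")
            vcfio.write_map_tsv(female_map, out / "map.female.tsv")
            summary["linkmap"]["male_total_cm"] = male_map.total_cm
            summary["linkmap"]["female_total_cm"] = female_map.total_cm
            summary["linkmap"]["male_x_cm"] = male_map.group(config.x_chrom).length_cm
            summary["linkmap"]["female_x_cm"] = female_map.group(config.x_chrom).length_cm

        # --- QTL scans ----------------------------------------------------
        stage = "qtlscan"
        pheno_indexed = phenotypes.set_index("individual")
        summary["scan"] = {}
        scan_seed = _stage_seed(config.seed, "scan")
        for trait in config.scan.phenotypes:
            y = pheno_indexed[trait]
            scan = qtl.scan_em(
                gmap,
                filtered,
                y,
                step_cm=config.scan.step_cm,
                error_prob=config.scan.error_prob,
                sex_adjust_autosomes=config.scan.sex_adjust_autosomes,
            )
            thr_a, thr_x = qtl.permutation_thresholds(
                gmap,
                filtered,
                y,
                n_perm=config.scan.n_perm,
                alpha=config.scan.alpha,
                x_specific=config.scan.x_specific,
                seed=scan_seed,
                step_cm=config.scan.step_cm,
                error_prob=config.scan.error_prob,
                sex_adjust_autosomes=config.scan.sex_adjust_autosomes,
            )
            scan.threshold_auto, scan.threshold_x = thr_a, thr_x
            chrom, peak_cm, peak_lod = scan.peak
            lo, hi = qtl.bayes_interval(scan, chrom, config.scan.bayes_prob)
            scan.bayes_interval = (chrom, lo, hi)
            eff = qtl.effect_table(filtered, gmap, y, chrom, peak_cm)
            scan.positions.to_csv(out / f"scan.{trait}.tsv", sep="\t", index=False)
            eff.to_csv(out / f"effects.{trait}.tsv", sep="\t", index=False)
            thr = thr_x if chrom == config.x_chrom else thr_a
            summary["scan"][trait] = {
                "peak_chrom": chrom,
                "peak_cm": peak_cm,
                "peak_lod": peak_lod,
                "threshold_auto": thr_a,
                "threshold_x": thr_x,
                "significant": bool(peak_lod > thr),
                "bayes_interval_cm": [lo, hi],
            }

        # --- marey --------------------------------------------------------
        stage = "marey"
        table = marey.marey_table(gmap)
        calls = marey.detect_inversions(table, config.marey.min_run)
        corrected = marey.reverse_within_inversions(table, calls)
        rates = marey.local_recomb_rate(
            corrected, span=config.marey.span, degree=config.marey.degree
        )
        rates.to_csv(out / "recomb_rates.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (c.chrom, c.start_bp, c.end_bp, c.n_markers)
                for c in calls
            ],
            columns=["chrom", "start_bp", "end_bp", "n_markers"],
        ).to_csv(out / "inversions.tsv", sep="\t", index=False)
        summary["marey"] = {
            "inversions": [
                {"chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
                 "n_markers": c.n_markers}
                for c in calls
            ]
        }
        if annotation_path:
            dens = marey.gene_density(annotation_path, config.marey.density_window_bp)
            reg = marey.rate_density_regression(
                rates, dens, config.marey.density_window_bp
            )
            summary["marey"]["rate_density"] = {
                "slope": reg.slope,
                "r_squared": reg.r_squared,
                "p_value": reg.p_value,
                "n_markers_used": reg.n_markers_used,
                "n_excluded": len(reg.excluded),
            }

        # --- crossovers ---------------------------------------------------
        stage = "xo"
        # obligate counts are sensitive to single bad calls: mask calls the
        # error HMM flags before counting
        cleaned = linkmap.clean_genotypes(
            filtered,
            orders,
            error_prob=config.linkmap.error_prob,
            error_lod_cutoff=config.linkmap.error_lod_cutoff or 4.0,
        )
        all_counts = pd.concat(
            [crossovers.crossover_counts(cleaned, c) for c in cleaned.chromosomes()],
            ignore_index=True,
        )
        all_counts.to_csv(out / "crossover_counts.tsv", sep="\t", index=False)
        comparison = crossovers.compare_sexes(
            all_counts, cleaned.chromosomes(), n_tests=config.xo.n_tests
        )
        comparison.to_csv(out / "sex_comparison.tsv", sep="\t", index=False)
        xrow = comparison[comparison["chrom"] == config.x_chrom]
        summary["xo"] = {
            "comparison_x": xrow.iloc[0].to_dict() if len(xrow) else None,
        }
        x_in_map = any(g.chrom == config.x_chrom for g in gmap.groups)
        if x_in_map:
            region = tuple(config.xo.focal_region)
            focal_counts, focal_cmp = crossovers.region_restricted_counts(
                cleaned, config.x_chrom, region
            )
            male_rec = int(
                (focal_counts[(focal_counts["sex"] == "M")]["count"] > 0).sum()
            )
            female_rec = int(
                (focal_counts[(focal_counts["sex"] == "F")]["count"] > 0).sum()
            )
            hap = crossovers.haplotype_frequency(cleaned, config.x_chrom, region)
            hapraster = crossovers.infer_haplotypes(cleaned, config.x_chrom)
            hapraster.to_csv(out / "x_haplotypes.tsv", sep="\t")
            summary["xo"]["focal_region"] = {
                "region_bp": list(region),
                "males_with_crossover": male_rec,
                "n_males": int((focal_counts["sex"] == "M").sum()),
                "females_with_crossover": female_rec,
                "n_females": int((focal_counts["sex"] == "F").sum()),
                "haplotype_frequency": hap,
            }

        # --- coverage -----------------------------------------------------
        stage = "coverage"
        if depth_paths[0] and depth_paths[1]:
            dm = vcfio.read_depth_tsv(depth_paths[0])
            df_ = vcfio.read_depth_tsv(depth_paths[1])
            wm = sexcov.window_coverage(dm, config.coverage.window_bp, config.x_chrom)
            wf = sexcov.window_coverage(df_, config.coverage.window_bp, config.x_chrom)
            wm.to_csv(out / "coverage_male.tsv", sep="\t", index=False)
            wf.to_csv(out / "coverage_female.tsv", sep="\t", index=False)
            strata = sexcov.classify_strata(
                wm,
                wf,
                chrom=config.x_chrom,
                hemizygous_max=config.coverage.hemizygous_max,
                similar_min=config.coverage.similar_min,
                min_run=config.coverage.min_run,
            )
            vcfio.write_strata_bed(strata, out / "x_strata.bed")
            summary["coverage"] = {
                "strata": strata.to_dict(orient="records"),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_default))
    return summary
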