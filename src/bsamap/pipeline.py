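"""End-to-end simulate-and-map runs and the parameter-recovery experiment.

``run_pipeline`` chains the stages of a bulked-segregant study on
synthetic data: simulate an F2 population segregating for a recessive
locus, sequence two phenotype bulks in silico, scan the genome with the
delta-SNP-index statistic against simulated null bounds, narrow the locus
with codominant markers, and classify the candidate gene's frameshift
deletion.  All stage outputs are written to a directory with the seed and
a configuration digest embedded; two runs with the same configuration are
byte-identical.

``recovery_experiment`` repeats the scan across seeds and measures how
often the called candidate region contains the planted locus — the
package's substitute for re-analysing real sequencing bulks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bsaseq, finemap, io, segregation, seqeffect, simdata
from .config import PipelineConfig
from .exceptions import StageError

__all__ = ["PipelineResult", "RecoveryResult", "run_pipeline", "recovery_experiment"]

_SEED_MASK = 0x7FFFFFFF


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds derived from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & _SEED_MASK for s in state]


@dataclass
class PipelineResult:
    """In-memory artifacts of one full run."""

    config: PipelineConfig
    population: simdata.F2Population
    segregation_scan: segregation.RatioScan
    depth_records: pd.DataFrame
    filter_report: bsaseq.FilterReport
    windows: pd.DataFrame
    regions: pd.DataFrame
    interval: finemap.IntervalResult
    cosegregation: finemap.CosegregationSummary
    effect: seqeffect.CodingEffect
    summary: dict


@dataclass
class RecoveryResult:
    """Across-seed summary of planted-locus recovery.

    ``causal_snp_deltas`` holds the per-seed delta index at the causal SNP
    itself, whose Mendelian expectation is exactly 1/3 - 1 = -2/3;
    ``causal_window_deltas`` holds the surrounding window's mean delta,
    which is slightly attenuated towards zero by recombination with SNPs
    up to half a window away.
    """

    n_seeds: int
    n_recovered: int
    causal_window_deltas: list[float]
    causal_snp_deltas: list[float]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_seeds

    @property
    def mean_causal_delta(self) -> float:
        return float(np.mean(self.causal_snp_deltas))

    @property
    def se_causal_delta(self) -> float:
        return float(np.std(self.causal_snp_deltas, ddof=1) / np.sqrt(self.n_seeds))


def _build_design(config: PipelineConfig):
    genetic_map = simdata.default_map(
        n_chromosomes=config.n_chromosomes,
        chromosome_length=config.chromosome_length,
        genetic_length_morgans=config.genetic_length_morgans,
        snps_per_chromosome=config.snps_per_chromosome,
    )
    snps = genetic_map.snp_positions[config.causal_chromosome]
    position = config.causal_position
    if position is None:
        position = int(snps[snps.size // 2])
    causal = simdata.CausalLocusSpec(chromosome=config.causal_chromosome, position=position)
    return genetic_map, causal


def _marker_grid(genetic_map, causal, offsets) -> dict[str, np.ndarray]:
    snps = genetic_map.snp_positions[causal.chromosome]
    causal_idx = int(np.searchsorted(snps, causal.position))
    idx = np.clip(np.asarray(offsets) + causal_idx, 0, snps.size - 1)
    return {causal.chromosome: np.unique(snps[idx])}


def _map_stage(population, config: PipelineConfig, seeds: list[int]):
    """Bulk sequencing, filtering, window scan and region calling."""
    bulk = simdata.BulkSpec(
        bulk_size=config.bulk_size,
        mean_depth=config.mean_depth,
        depth_model=config.depth_model,
    )
    depth_records = simdata.simulate_bulk_depths(population, bulk, seed=seeds[0])
    filtered, report = bsaseq.filter_snps(
        depth_records, config.min_total_depth, config.min_index
    )
    lengths = {c.name: c.length_bp for c in population.map_spec.chromosomes}
    windows = bsaseq.sliding_windows(filtered, config.window_size, config.step, lengths)
    eff = windows["eff_depth"].dropna()
    depths = np.unique(np.round(eff).astype(int)) if len(eff) else np.array([1])
    ci = bsaseq.simulate_null_ci(
        depths,
        bulk_size=config.bulk_size,
        reps=config.ci_reps,
        confidence=(config.confidence,),
        seed=seeds[1],
    )
    windows, regions = bsaseq.attach_ci_and_call_regions(
        windows, ci, config.min_consecutive, config.confidence
    )
    return depth_records, report, windows, regions


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.outdir``."""
    config.validate()
    seeds = _stage_seeds(config.seed, 4)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.hash}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    genetic_map, causal = _build_design(config)
    population = stage(
        "simulate", simdata.simulate_f2_population, genetic_map, causal, config.n_f2, seeds[0]
    )

    counts = [
        sum(p == "long" for p in population.phenotypes),
        sum(p == "short" for p in population.phenotypes),
    ]
    seg_scan = stage("segregation", segregation.test_standard_ratios, counts)

    depth_records, filter_report, windows, regions = stage(
        "bsa", _map_stage, population, config, seeds[1:3]
    )

    markers = _marker_grid(genetic_map, causal, config.marker_offsets)
    table = stage("finemap", simdata.extract_marker_genotypes, population, markers)
    interval = stage("finemap", finemap.narrow_interval, table)
    causal_marker = f"M_{causal.chromosome}_{causal.position}"
    coseg = stage("finemap", finemap.cosegregation_summary, table, causal_marker)

    ref_cds, mut_cds, domains = stage(
        "effect",
        simdata.make_cds_fixture,
        config.cds_length,
        config.deletion_start,
        config.deletion_length,
        config.target_truncated_aa,
        seeds[3],
    )
    effect = stage(
        "effect",
        seqeffect.classify_effect,
        ref_cds,
        mut_cds,
        config.deletion_start,
        config.deletion_start + config.deletion_length - 1,
        domains,
    )

    causal_hit = bool(
        (
            (regions["chrom"] == causal.chromosome)
            & (regions["start"] <= causal.position)
            & (regions["end"] >= causal.position)
        ).any()
    ) if len(regions) else False

    summary = {
        "seed": config.seed,
        "config_hash": config.hash,
        "planted_locus": {"chromosome": causal.chromosome, "position": causal.position},
        "phenotype_counts": {"long": counts[0], "short": counts[1]},
        "segregation_best_ratio": seg_scan.best,
        "segregation_chi2": round(seg_scan.best_result.chi2, 4),
        "segregation_p": round(seg_scan.best_result.p, 4),
        "n_snps_input": filter_report.n_input,
        "n_snps_after_filter": filter_report.n_retained,
        "n_candidate_regions": int(len(regions)),
        "candidate_region_contains_planted_locus": causal_hit,
        "regions": regions.to_dict(orient="records"),
        "interval": {
            "chromosome": interval.chromosome,
            "left_marker": interval.left_marker,
            "right_marker": interval.right_marker,
            "start": interval.start,
            "end": interval.end,
            "length_bp": interval.length,
            "n_recombinants": interval.n_recombinants_used,
        },
        "cosegregation": {
            "marker": coseg.marker,
            "counts": coseg.counts,
            "concordance": coseg.concordance,
            "chi2_1_2_1": round(coseg.segregation.chi2, 4),
            "p_1_2_1": round(coseg.segregation.p, 4),
        },
        "coding_effect": {
            "deleted_length": effect.deleted_length,
            "frameshift": effect.frameshift,
            "protein_length_ref": effect.protein_length_ref,
            "protein_length_mut": effect.protein_length_mut,
            "lost_domains": [
                {"name": d.name, "partial": d.partial} for d in effect.lost_domains
            ],
        },
    }

    stage("report", _write_outputs, outdir, provenance, depth_records, windows, regions,
          table, ref_cds, mut_cds, summary)

    return PipelineResult(
        config=config,
        population=population,
        segregation_scan=seg_scan,
        depth_records=depth_records,
        filter_report=filter_report,
        windows=windows,
        regions=regions,
        interval=interval,
        cosegregation=coseg,
        effect=effect,
        summary=summary,
    )


def _write_outputs(outdir, provenance, depth_records, windows, regions, table,
                   ref_cds, mut_cds, summary):
    io.write_depth_table(depth_records, outdir / "depths.tsv", provenance)
    with open(outdir / "windows.tsv", "w") as fh:
        fh.write("".join(f"# {k}={v}\n" for k, v in provenance.items()))
        windows.to_csv(fh, sep="\t", index=False)
    io.write_regions_bed(regions, outdir / "regions.bed", provenance)
    io.write_marker_table(table, outdir / "markers.tsv", provenance)
    io.write_fasta({"reference_cds": ref_cds, "mutant_cds": mut_cds}, outdir / "cds.fa")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def recovery_experiment(
    n_seeds: int = 40,
    base_seed: int = 1,
    config: PipelineConfig | None = None,
) -> RecoveryResult:
    """Measure how often the scan recovers a planted recessive locus.

    For each seed: simulate the F2 design in ``config`` (default: n=400,
    30/30 bulks, ~30x Poisson depth, 10,000-rep null CIs), call candidate
    regions, and score a success when some called region contains the
    planted position.  Also records the delta of the window whose centre
    is nearest the planted locus (Mendelian expectation -2/3).
    """
    if config is None:
        config = PipelineConfig(n_f2=400)
    config.validate()
    genetic_map, causal = _build_design(config)

    n_recovered = 0
    causal_deltas: list[float] = []
    snp_deltas: list[float] = []
    for i in range(n_seeds):
        seed = (base_seed + 7_919 * i) & _SEED_MASK
        seeds = _stage_seeds(seed, 4)
        population = simdata.simulate_f2_population(genetic_map, causal, config.n_f2, seeds[0])
        depth_records, _, windows, regions = _map_stage(population, config, seeds[1:3])

        at_causal = bsaseq.add_indices(
            depth_records[
                (depth_records["chrom"] == causal.chromosome)
                & (depth_records["pos"] == causal.position)
            ]
        )
        snp_deltas.append(float((at_causal["index_L"] - at_causal["index_S"]).iloc[0]))

        hit = (
            (regions["chrom"] == causal.chromosome)
            & (regions["start"] <= causal.position)
            & (regions["end"] >= causal.position)
        ).any() if len(regions) else False
        n_recovered += bool(hit)

        on_chrom = windows[
            (windows["chrom"] == causal.chromosome) & (windows["n_snps"] > 0)
        ]
        centre = on_chrom["start"] + (on_chrom["end"] - on_chrom["start"]) / 2.0
        nearest = (centre - causal.position).abs().idxmin()
        causal_deltas.append(float(on_chrom.loc[nearest, "delta"]))

    return RecoveryResult(
        n_seeds=n_seeds,
        n_recovered=n_recovered,
        causal_window_deltas=causal_deltas,
        causal_snp_deltas=snp_deltas,
    )
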