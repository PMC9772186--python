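"""End-to-end orchestration: simulate -> cores -> thermal -> popgen -> stats.

``run_pipeline`` executes the configured stages in dependency order, writes
every stage's outputs under the configured output directory, and records a
manifest.  Any stage failure aborts with an error naming the stage; outputs
of completed stages are preserved.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, densitometry, io, popgen, simulate, stats, thermal
from .config import ConfigError, PipelineConfig, RunManifest

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "StageError", "analyze_cores", "analyze_loggers"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def analyze_cores(
    profiles: list[densitometry.DensityProfile],
    window: tuple[int, int],
    criteria: densitometry.StressBandCriteria,
    event_years: tuple[int, ...] = (1998, 2010),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-core band segmentation, growth means and stress-band flags.

    Returns (bands, summaries, calls, failed_core_ids).  Cores failing
    segmentation are excluded with a logged reason, mirroring manual
    exclusion of unreadable cores.
    """
    band_rows, summary_rows, call_rows, failed = [], [], [], []
    for profile in profiles:
        try:
            series = densitometry.segment_annual_bands(profile)
            growth = densitometry.mean_growth(series, window)
        except (densitometry.SegmentationError, ValueError) as err:
            logger.warning("core %s excluded: %s", profile.core_id, err)
            failed.append(profile.core_id)
            continue
        calls = densitometry.detect_stress_bands(profile, criteria)
        flags = densitometry.attribute_stress_years(calls, series, event_years)
        rec = series.records.assign(core_id=profile.core_id)
        band_rows.append(rec)
        row = {"id": profile.core_id, **growth}
        for year in event_years:
            row[f"stress_{year}"] = flags[year]
        summary_rows.append(row)
        for call in calls:
            call_rows.append(
                {
                    "core_id": call.core_id,
                    "start_mm": call.start_mm,
                    "end_mm": call.end_mm,
                    "thickness_mm": call.thickness_mm,
                    "peak_density_z": call.peak_density_z,
                    "peak_gradient_z": call.peak_gradient_z,
                }
            )
    bands = pd.concat(band_rows, ignore_index=True) if band_rows else pd.DataFrame()
    summaries = pd.DataFrame(summary_rows).set_index("id") if summary_rows else pd.DataFrame()
    calls_df = pd.DataFrame(call_rows)
    return bands, summaries, calls_df, failed


def analyze_loggers(
    series_list: list[thermal.TemperatureSeries],
    spec: thermal.FilterSpec,
) -> pd.DataFrame:
    """Regime summary table, one row per site."""
    rows = [thermal.regime_summary(s, spec).as_dict() for s in series_list]
    return pd.DataFrame(rows).set_index("site_id")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages end to end and write a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=config.digest(), seed=config.seed
    )
    collected: list[str] = []

    if not config.simulate:
        needed = [config.profiles_dir, config.metadata_path]
        if any(p is None for p in needed) or (
            config.vcf_path is None and config.microsat_path is None
        ):
            raise ConfigError(
                "stats without simulation needs profiles_dir, metadata_path and "
                "a genotype input (vcf_path or microsat_path)"
            )
        for p in [config.profiles_dir, config.metadata_path, config.vcf_path,
                  config.microsat_path, config.loggers_dir]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- stage: simulate / load inputs -------------------------------
        try:
            if config.simulate:
                names = simulate.LINEAGES[: config.k_lineages]
                stress = dict(
                    zip(
                        simulate.LINEAGES,
                        [
                            config.stress_prob_db,
                            config.stress_prob_lb,
                            config.stress_prob_pi,
                            config.stress_prob_rd,
                        ],
                    )
                )
                pop = simulate.PopSimSpec(
                    K=config.k_lineages,
                    divergence_F=config.divergence_f,
                    n_per_pop=config.n_per_pop,
                    n_loci=config.n_loci,
                    missing_rate=config.missing_rate,
                )
                genotypes, profiles, truth = simulate.simulate_cohort(
                    pop,
                    stress_prob={k: stress[k] for k in names},
                    seed=config.seed,
                    lineage_names=names,
                )
                truth.to_csv(out / "cohort_truth.csv", index=False)
                loggers = [
                    simulate.simulate_logger(
                        simulate.LoggerSimSpec(
                            site_id="rock_island", habitat="Rock Island",
                            site_mean=30.29, diurnal_amplitude=0.30,
                            seed=config.seed,
                        )
                    ),
                    simulate.simulate_logger(
                        simulate.LoggerSimSpec(
                            site_id="outer_reef", habitat="outer reef",
                            site_mean=29.11, diurnal_amplitude=0.16,
                            seed=config.seed,
                        )
                    ),
                ]
            else:
                meta = pd.read_csv(config.metadata_path).set_index("id")
                manifest.input_checksums[str(config.metadata_path)] = RunManifest.checksum(
                    config.metadata_path
                )
                profiles = []
                for f in sorted(Path(config.profiles_dir).glob("*.csv")):
                    date = (
                        meta.loc[f.stem, "collection_date"]
                        if f.stem in meta.index and "collection_date" in meta.columns
                        else None
                    )
                    profiles.append(io.read_profile_csv(f, collection_date=date))
                    manifest.input_checksums[str(f)] = RunManifest.checksum(f)
                loggers = []
                if config.loggers_dir:
                    for f in sorted(Path(config.loggers_dir).glob("*.csv")):
                        loggers.append(io.read_logger_csv(f))
                        manifest.input_checksums[str(f)] = RunManifest.checksum(f)
                if config.vcf_path:
                    genotypes, skipped = io.read_vcf(config.vcf_path, metadata=meta)
                    manifest.stage_counts["vcf_multiallelic_skipped"] = skipped
                    manifest.input_checksums[str(config.vcf_path)] = RunManifest.checksum(
                        config.vcf_path
                    )
                else:
                    raw = io.read_microsat_csv(config.microsat_path)
                    genotypes = popgen.curate_microsatellites(raw, metadata=meta)
                    manifest.input_checksums[str(config.microsat_path)] = (
                        RunManifest.checksum(config.microsat_path)
                    )
                truth = None
        except ConfigError:
            raise
        except Exception as err:  # noqa: BLE001 - stage-named rethrow
            raise StageError(f"stage 'inputs' failed: {err}") from err
        manifest.stage_counts["profiles"] = len(profiles)
        manifest.stage_counts["genotype_samples"] = genotypes.n_samples
        manifest.stage_counts["genotype_loci"] = genotypes.n_loci

        # --- stage: cores -------------------------------------------------
        try:
            criteria = densitometry.StressBandCriteria(
                min_thickness=config.min_thickness_mm, z_threshold=config.z_threshold
            )
            bands, summaries, calls, failed = analyze_cores(
                profiles, (config.window_start, config.window_end), criteria
            )
            bands.to_csv(out / "annual_bands.csv", index=False)
            summaries.to_csv(out / "core_summaries.csv")
            calls.to_csv(out / "stress_calls.csv", index=False)
        except Exception as err:  # noqa: BLE001
            raise StageError(f"stage 'cores' failed: {err}") from err
        manifest.stage_counts["cores_analyzed"] = len(summaries)
        manifest.stage_counts["cores_excluded"] = len(failed)
        manifest.stage_counts["stress_calls"] = len(calls)

        # --- stage: thermal ----------------------------------------------
        if loggers:
            try:
                spec = thermal.FilterSpec(
                    short_cutoff=config.short_cutoff_h,
                    long_cutoff=config.long_cutoff_h,
                    order=config.filter_order,
                )
                regimes = analyze_loggers(loggers, spec)
                regimes.to_csv(out / "regime_summary.csv")
                weekly = pd.DataFrame(
                    {s.site_id: thermal.weekly_average(s) for s in loggers}
                )
                weekly.to_csv(out / "weekly_temperature.csv")
            except Exception as err:  # noqa: BLE001
                raise StageError(f"stage 'thermal' failed: {err}") from err
            manifest.stage_counts["logger_sites"] = len(loggers)

        # --- stage: popgen -------------------------------------------------
        try:
            filtered, report = popgen.filter_loci_samples(
                genotypes, min_loci_per_sample=min(10, genotypes.n_loci)
            )
            (out / "filter_report.txt").write_text(str(report) + "\n")
            fit = popgen.estimate_admixture(
                filtered,
                K=config.k_fit,
                n_restarts=config.n_restarts,
                max_iter=config.max_iter,
                seed=config.seed,
            )
            names = simulate.LINEAGES[: config.k_fit] if config.simulate else None
            if config.simulate and truth is not None:
                # align cluster indices to true lineage labels
                ref = pd.get_dummies(
                    truth.set_index("id").loc[fit.samples, "lineage"]
                ).reindex(columns=list(names), fill_value=0)
                perm = popgen.match_labels(fit.Q, ref.to_numpy(dtype=float))
                # cluster c carries the truth name whose reference column it matched
                order = np.argsort(perm)
                assignments = popgen.assign_lineage(
                    fit, names=[names[order[c]] for c in range(fit.K)]
                )
            else:
                assignments = popgen.assign_lineage(fit)
            assignments.rename("lineage").to_csv(
                out / "lineage_assignments.csv", index_label="id"
            )
            io.write_structure_q(fit, out / "ancestry_q.txt")
            fst = popgen.nei_fst(
                filtered,
                assignments[assignments != popgen.ADMIXED],
                n_boot=config.n_boot,
                seed=config.seed,
            )
            frame = fst.as_frame()
            frame.to_csv(out / "fst_matrix.csv")
            pca = popgen.genotype_pca(filtered)
            pd.DataFrame(
                pca.coords[:, :10],
                index=pca.samples,
                columns=[f"PC{i + 1}" for i in range(min(10, pca.coords.shape[1]))],
            ).to_csv(out / "pca_coords.csv")
        except Exception as err:  # noqa: BLE001
            raise StageError(f"stage 'popgen' failed: {err}") from err
        manifest.stage_counts["samples_retained"] = report.n_samples_out
        manifest.stage_counts["loci_retained"] = report.n_loci_out
        manifest.stage_counts["admixed"] = int((assignments == popgen.ADMIXED).sum())

        # --- stage: stats ---------------------------------------------------
        try:
            if config.simulate:
                habitat = truth.set_index("id")["habitat"]
            elif genotypes.metadata is not None and "habitat" in genotypes.metadata:
                habitat = genotypes.metadata["habitat"]
            else:
                habitat = None
            core_cols = summaries.copy()
            if habitat is not None:
                core_cols = core_cols.join(habitat, how="left")
            flags = core_cols[[c for c in core_cols.columns if c.startswith("stress_")]]
            cohort = stats.build_cohort(
                assignments, core_cols.drop(columns=flags.columns), flags
            )
            cohort.to_csv(out / "cohort.csv")
            report_dict = stats.reproduce_report(cohort)
            stats.report_to_frame(report_dict).to_csv(out / "test_results.csv", index=False)
            (out / "report.txt").write_text(stats.report_to_text(report_dict))
        except Exception as err:  # noqa: BLE001
            raise StageError(f"stage 'stats' failed: {err}") from err
        manifest.stage_counts["cohort_rows"] = len(cohort)
        manifest.stage_counts["tests"] = len(
            [k for k, v in report_dict.items() if isinstance(v, stats.TestResult)]
        )

        manifest.warnings = sorted({str(w.message) for w in caught})
    manifest.write(out / "manifest.json")
    return manifest
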