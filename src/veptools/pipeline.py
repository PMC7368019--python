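"""End-to-end analyses binding the stages together.

``run_full`` mirrors the study's analysis order on a simulated cohort:
simulate -> per-bin harmonic table -> per-week bootstrap-SVM results for
both electrode configurations (with shuffled-label controls) -> VEP peak
latency table -> circular phase tests.  Each command writes delimited
tables stamped with the config hash and seed; re-running with the same
config reproduces them byte for byte.

No multiple-testing correction is applied across weeks or peaks here: the
tables are emitted for external statistics tooling, and the run log says
so explicitly.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import SyntheticRatBootstrapSVM
from .circular import harrison_kanji_test, pool_phases_per_rat
from .errors import DataError
from .io import RunConfig, write_recording
from .simulate import generate_cohort
from .spectral import extract_cohort_samples
from .vep import detect_peaks, grand_average, latency_table

logger = logging.getLogger("veptools")

__all__ = [
    "simulate_cohort_files",
    "compute_spectra",
    "classify_weeks",
    "vep_peaks",
    "phase_tests",
    "run_full",
]


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash()
    df["seed"] = config.seed
    return df


def _write(df: pd.DataFrame, out_dir: Path, name: str, config: RunConfig):
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    _stamp(df, config).to_csv(path, index=False, float_format="%.10g")
    logger.info("wrote %s (%d rows)", path, len(df))
    return path


def _cohort(config: RunConfig, paradigms=("SSVEP", "VEP")):
    cohort = config.cohort
    sim = config.simulation
    cohort.seed = config.seed
    return generate_cohort(cohort, sim, paradigms=paradigms)


def simulate_cohort_files(
    config: RunConfig, out_dir: Path, fmt: str = "edf"
) -> list[Path]:
    """Simulate the cohort and write one file per recording."""
    out_dir = Path(out_dir)
    paths = []
    for rec in _cohort(config):
        m = rec.meta
        rat_dir = out_dir / str(m["rat_id"])
        rat_dir.mkdir(parents=True, exist_ok=True)
        ext = "edf" if fmt == "edf" else "csv"
        name = f"{m['paradigm']}_w{m['week']}_{m['wavelength']}.{ext}"
        path = rat_dir / name
        write_recording(rec, path, format=fmt)
        paths.append(path)
    logger.info("simulated %d recordings under %s", len(paths), out_dir)
    return paths


def compute_spectra(config: RunConfig, recordings=None) -> pd.DataFrame:
    """Harmonic amplitude/phase/SNR table for every SSVEP recording."""
    if recordings is None:
        recordings = _cohort(config, paradigms=("SSVEP",))
    return extract_cohort_samples(recordings)


def classify_weeks(
    config: RunConfig,
    samples: pd.DataFrame,
    electrode_configs=("all_electrodes", "sc_left_vs_right"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-week bootstrap classification for each electrode configuration.

    Falls back to with-replacement resampling (logged) for a week whose
    SNR exclusions leave some pool short of the without-replacement demand.
    Returns (summary table, per-iteration accuracy table).
    """
    cc = config.classifier
    need = cc.n_synthetic_per_class * cc.bins_per_rat
    summaries, iterations = [], []
    for week, week_samples in samples.groupby("week"):
        for selector in electrode_configs:
            sampling = cc.sampling
            if sampling == "without_replacement":
                retained = week_samples[week_samples["retained"]]
                pool_sizes = retained.groupby(
                    ["group", "electrode", "wavelength", "harmonic"]
                ).size()
                if pool_sizes.min() < need:
                    logger.warning(
                        "week %s/%s: smallest pool has %d retained bins "
                        "(< %d); switching to with-replacement resampling",
                        week,
                        selector,
                        int(pool_sizes.min()),
                        need,
                    )
                    sampling = "with_replacement"
            est = SyntheticRatBootstrapSVM(
                electrode_configuration=selector,
                n_synthetic_per_class=cc.n_synthetic_per_class,
                bins_per_rat=cc.bins_per_rat,
                n_iterations=cc.n_iterations,
                k_folds=cc.k_folds,
                svm_c=cc.svm_c,
                svm_gamma=cc.svm_gamma,
                chance_level=cc.chance_level,
                sampling=sampling,
                zscore_axis=cc.zscore_axis,
                run_shuffled_control=True,
                random_state=cc.seed + int(week),
            )
            est.fit(week_samples)
            summaries.append(
                {
                    "week": week,
                    "electrode_config": selector,
                    "n_features": len(est.feature_names_),
                    "mean_accuracy": est.mean_accuracy_,
                    "p_below_chance": est.p_below_chance_,
                    "p_label": est.result_.p_label,
                    "significant": est.result_.significant,
                    "shuffled_mean_accuracy": est.shuffled_mean_accuracy_,
                    "sampling": sampling,
                }
            )
            for which, accs in (
                ("observed", est.per_iteration_accuracy_),
                ("shuffled", est.shuffled_result_.per_iteration_accuracy),
            ):
                iterations.append(
                    pd.DataFrame(
                        {
                            "week": week,
                            "electrode_config": selector,
                            "condition": which,
                            "iteration": np.arange(len(accs)),
                            "accuracy": accs,
                        }
                    )
                )
    return (
        pd.DataFrame(summaries),
        pd.concat(iterations, ignore_index=True),
    )


def accuracy_histograms(iteration_table: pd.DataFrame, out_dir: Path):
    """One accuracy histogram per (week, electrode configuration)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (week, selector), sub in iteration_table.groupby(
        ["week", "electrode_config"]
    ):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        bins = np.linspace(0, 1, 41)
        for cond, style in (("observed", "C0"), ("shuffled", "C1")):
            accs = sub.loc[sub["condition"] == cond, "accuracy"]
            ax.hist(
                accs, bins=bins, alpha=0.6, color=style, label=cond
            )
        ax.axvline(0.5, ls=":", color="k", label="chance")
        ax.set_xlabel("classification accuracy")
        ax.set_ylabel("bootstrap iterations")
        ax.set_title(f"week {week}, {selector}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = out_dir / f"accuracy_w{week}_{selector}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def vep_peaks(config: RunConfig, recordings=None) -> pd.DataFrame:
    """Grand-average every VEP recording and extract named peaks."""
    if recordings is None:
        recordings = _cohort(config, paradigms=("VEP",))
    peaksets = []
    for rec in recordings:
        if rec.meta.get("paradigm") != "VEP":
            continue
        for el in rec.electrodes:
            wf = grand_average(rec, electrode=el)
            peaksets.append(
                detect_peaks(
                    wf,
                    windows=config.peak_windows,
                    baseline_window=config.baseline_window,
                )
            )
    if not peaksets:
        raise DataError("no VEP recordings to analyse")
    return latency_table(peaksets)


def phase_tests(config: RunConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Harrison–Kanji group x side test per (week, harmonic).

    Phases are pooled across wavelengths; by default one circular-mean
    angle per (rat, side) enters the test.
    """
    rows = []
    for week, week_samples in samples.groupby("week"):
        for harmonic in sorted(week_samples["harmonic"].unique()):
            if config.phase_pooling == "per_rat":
                angles, groups, sides = pool_phases_per_rat(
                    week_samples, harmonic=int(harmonic)
                )
            else:
                sub = week_samples[
                    week_samples["retained"]
                    & (week_samples["harmonic"] == harmonic)
                    & week_samples["electrode"].isin(("SC_L", "SC_R"))
                ]
                angles = sub["phase_rad"].to_numpy()
                groups = sub["group"].to_numpy()
                sides = sub["electrode"].to_numpy()
            res = harrison_kanji_test(
                angles, groups, sides, kappa_threshold=config.kappa_threshold
            )
            rows.append(
                {
                    "week": week,
                    "harmonic": int(harmonic),
                    "n": len(angles),
                    "kappa": res.kappa,
                    "regime": res.regime,
                    "p_group": res.p_values["A"],
                    "p_side": res.p_values["B"],
                    "p_interaction": res.p_values["interaction"],
                    "stat_group": res.statistics["A"],
                    "stat_side": res.statistics["B"],
                }
            )
    return pd.DataFrame(rows)


def run_full(config: RunConfig, out_dir, histograms: bool = True) -> dict:
    """The whole analysis on a simulated cohort; returns artifact paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info(
            "veptools %s | python %s | seed %d | config %s",
            __version__,
            platform.python_version(),
            config.seed,
            config.config_hash(),
        )
        logger.info(
            "no multiple-testing correction is applied across weeks/peaks; "
            "tables are intended for external statistics tooling"
        )
        samples = compute_spectra(config)
        artifacts = {}
        artifacts["harmonics"] = _write(
            samples, out_dir, "harmonic_samples.csv", config
        )
        summary, iterations = classify_weeks(config, samples)
        artifacts["classification"] = _write(
            summary, out_dir, "classification_results.csv", config
        )
        artifacts["iterations"] = _write(
            iterations, out_dir, "classification_iterations.csv", config
        )
        peaks = vep_peaks(config)
        artifacts["vep_peaks"] = _write(
            peaks, out_dir, "vep_latency_table.csv", config
        )
        phases = phase_tests(config, samples)
        artifacts["phase_tests"] = _write(
            phases, out_dir, "circular_tests.csv", config
        )
        if histograms:
            artifacts["histograms"] = accuracy_histograms(
                iterations, out_dir / "figures"
            )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(
                {
                    "config_hash": config.config_hash(),
                    "seed": config.seed,
                    "version": __version__,
                    "artifacts": {
                        k: [str(p) for p in v]
                        if isinstance(v, list)
                        else str(v)
                        for k, v in artifacts.items()
                    },
                },
                fh,
                indent=1,
            )
        return artifacts
    finally:
        logger.removeHandler(handler)
        handler.close()
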