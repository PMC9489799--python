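"""End-to-end orchestration: simulate -> correct -> filter -> cluster -> measure.

These functions chain the per-stage modules into the runs a study would
perform: generating a field of view, analysing its localization table into
per-aggregate morphometry, accumulating measured populations across fields,
and the two toxicity quantifications (dye influx, calibrated spot
counting).  The command-line interface is a thin wrapper around
:func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assays import (
    average_frames,
    calibrate_threshold,
    compute_influx,
    count_spots,
    detect_spots,
    match_spots,
    specificity_ratio,
)
from .clustering import ClusterLabeling, dbscan
from .io_core import AnalysisConfig, dump_json, make_localizations, write_localizations
from .localization import correct_drift, filter_localizations
from .morphometry import MorphometryRecord, records_to_frame, summarize_sample
from .stats_compare import compare_groups
from .synthetic import (
    FIDUCIAL_ID,
    SimulationParams,
    apply_drift_and_fiducials,
    render_frame_stack,
    sample_aggregates,
    scenario_params,
    simulate_influx_experiment,
    simulate_localizations,
)

__all__ = [
    "RunManifest",
    "analyze_influx_stacks",
    "analyze_table",
    "measure_population",
    "run_pipeline",
    "simulate_fov",
    "simulate_simpull_experiment",
]


def simulate_fov(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, list, np.ndarray]:
    """One simulated field of view: ground truth -> localization table.

    Returns (table with drift and fiducials applied, ground-truth
    aggregates, fiducial reference positions).
    """
    aggregates = sample_aggregates(params, rng)
    table = simulate_localizations(aggregates, params, rng)
    table, _, refs = apply_drift_and_fiducials(table, params, rng)
    return table, aggregates, refs


def analyze_table(
    table: pd.DataFrame,
    config: AnalysisConfig,
    fiducial_refs: np.ndarray | None = None,
    length_metric: str = "feret",
) -> tuple[pd.DataFrame, ClusterLabeling, list[MorphometryRecord], object]:
    """The analysis chain for one localization table.

    Drift-corrects against ``fiducial_refs`` when given (fiducial rows are
    removed in the process), filters by signal and precision, clusters the
    surviving localizations, and measures every cluster.  Returns
    (filtered table, labeling, morphometry records, sample summary).
    """
    if fiducial_refs is not None and len(fiducial_refs):
        table, _ = correct_drift(table, fiducial_refs)
    elif "source_id" in table.columns:
        table = table.loc[table["source_id"] != FIDUCIAL_ID].reset_index(drop=True)
    filtered = filter_localizations(table, config.min_signal, config.max_precision)
    labeling = dbscan(
        filtered[["x", "y"]].to_numpy(), eps=config.eps, min_pts=config.min_pts
    )
    records, summary = summarize_sample(filtered, labeling,
                                        length_metric=length_metric)
    return filtered, labeling, records, summary


def measure_population(
    params: SimulationParams,
    config: AnalysisConfig,
    n_target: int,
    rng: np.random.Generator,
    max_fovs: int = 200,
) -> pd.DataFrame:
    """Accumulate measured aggregates over fields of view until ``n_target``.

    Mirrors how a study pools aggregates across many fields: each field is
    simulated, drift-corrected (when the scenario includes drift), filtered,
    clustered and measured; records are concatenated until at least
    ``n_target`` aggregates have been measured.
    """
    frames: list[pd.DataFrame] = []
    measured = 0
    fovs = 0
    while measured < n_target and fovs < max_fovs:
        table, _, refs = simulate_fov(params, rng)
        use_refs = refs if params.drift_mag > 0 else None
        _, _, records, _ = analyze_table(table, config, fiducial_refs=use_refs)
        df = records_to_frame(records)
        df["fov"] = fovs
        frames.append(df)
        measured += len(df)
        fovs += 1
    if not frames:
        return records_to_frame([])
    out = pd.concat(frames, ignore_index=True)
    return out.iloc[:n_target].copy() if len(out) > n_target else out


# ---------------------------------------------------------------------------
# toxicity read-outs


def analyze_influx_stacks(
    stack_background: np.ndarray,
    stack_sample: np.ndarray,
    stack_ionomycin: np.ndarray,
    pixel_size: float = 237.0,
    radius: float = 474.0,
) -> tuple[list, float, int]:
    """Quantify per-liposome influx from the three condition stacks.

    Frames are averaged per condition, spots detected on each average,
    matched into (background, sample, ionophore) triplets by mutual nearest
    neighbours, and scored with the influx ratio.  Returns (per-spot
    measurements, field-of-view mean influx %, unmatched spot count).
    """
    spots = [
        detect_spots(average_frames(s), pixel_size=pixel_size)
        for s in (stack_background, stack_sample, stack_ionomycin)
    ]
    triplets, unmatched = match_spots(*spots, radius=radius)
    measurements, fov_mean = compute_influx(triplets)
    return measurements, fov_mean, unmatched


def simulate_simpull_experiment(
    params: SimulationParams,
    rng: np.random.Generator,
    n_fovs: int = 15,
    target_mean_spots: float = 60.0,
    control_mean_spots: float = 3.0,
    spot_photons: float = 400.0,
    psf_sigma: float = 250.0,
    n_frames: int = 10,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulate target and isotype-control pulldown fields of view.

    Target fields carry Poisson(``target_mean_spots``) bright spots per
    field; isotype-control fields carry Poisson(``control_mean_spots``)
    (non-specific binding).  Spot brightness is exponential with mean
    ``spot_photons`` per frame.  Returns (target stacks, control stacks).
    """

    def _fields(mean_spots: float) -> list[np.ndarray]:
        stacks = []
        margin = 4 * params.fov_size / 84  # keep spots clear of the border
        for _ in range(n_fovs):
            k = rng.poisson(mean_spots)
            pos = rng.uniform(margin, params.fov_size - margin, size=(k, 2))
            photons = rng.exponential(spot_photons, size=k)
            spots = [((float(x), float(y)), float(p))
                     for (x, y), p in zip(pos, photons)]
            stacks.append(
                render_frame_stack(spots, psf_sigma, params, rng,
                                   pixel_size=237.0, n_frames=n_frames)
            )
        return stacks

    return _fields(target_mean_spots), _fields(control_mean_spots)


def analyze_simpull(
    target_stacks: Sequence[np.ndarray],
    control_stacks: Sequence[np.ndarray],
    pixel_size: float = 237.0,
    budget: float = 2.0,
) -> dict:
    """Calibrated spot counting and specificity for a pulldown experiment.

    The intensity threshold is the smallest value at which the mean
    isotype-control count per field drops to ``budget``; target and
    control fields are then counted at that threshold and the
    target/control ratio reported.
    """
    control_imgs = [average_frames(s) for s in control_stacks]
    target_imgs = [average_frames(s) for s in target_stacks]
    all_intensities = [
        i for img in control_imgs for _, i in detect_spots(img, pixel_size)
    ]
    candidates = sorted(set([0.0] + all_intensities))
    counts_by_threshold = {
        t: float(np.mean([count_spots(img, t, pixel_size).count
                          for img in control_imgs]))
        for t in candidates
    }
    threshold = calibrate_threshold(counts_by_threshold, budget=budget)
    target_counts = [count_spots(img, threshold, pixel_size, fov_id=i,
                                 condition="target").count
                     for i, img in enumerate(target_imgs)]
    control_counts = [count_spots(img, threshold, pixel_size, fov_id=i,
                                  condition="isotype").count
                      for i, img in enumerate(control_imgs)]
    ratio, ratio_sd = specificity_ratio(
        [float(c) for c in target_counts], [float(c) for c in control_counts]
    )
    return {
        "threshold": threshold,
        "target_counts": target_counts,
        "control_counts": control_counts,
        "specificity_ratio": ratio,
        "specificity_ratio_sd": ratio_sd,
    }


# ---------------------------------------------------------------------------
# full runs


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, outputs, and per-stage counts."""

    subcommand: str
    seed: int
    version: str
    config: dict
    scenario: str
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        return dump_json(dataclasses.asdict(self), path)


SUBCOMMANDS = ("simulate", "analyze", "compare", "influx", "simpull", "all")


def run_pipeline(
    config: AnalysisConfig,
    subcommand: str,
    out_dir: str | Path,
    scenario: str = "fraction20",
    scenario_b: str = "fraction30",
    seed: int | None = None,
    n_aggregates: int | None = None,
) -> RunManifest:
    """Execute one named pipeline run and write its artifacts to ``out_dir``.

    ``simulate`` writes a localization table for the scenario; ``analyze``
    simulates then runs the full chain to a morphometry CSV; ``compare``
    measures two scenarios and writes a comparison report; ``influx`` and
    ``simpull`` run the corresponding simulated assays; ``all`` chains
    analyze + compare + influx + simpull.  A manifest recording the seed,
    configuration, outputs, and per-stage counts is saved alongside.
    """
    if subcommand not in SUBCOMMANDS:
        raise ValueError(
            f"unknown subcommand '{subcommand}'; expected one of {SUBCOMMANDS}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    manifest = RunManifest(
        subcommand=subcommand,
        seed=seed,
        version=__version__,
        config=dataclasses.asdict(config),
        scenario=scenario,
    )

    def _params(name: str) -> SimulationParams:
        overrides = {"fov_size": config.fov_size, "n_frames": config.n_frames}
        if n_aggregates is not None:
            overrides["n_aggregates"] = n_aggregates
        return scenario_params(name, **overrides)

    def _write(obj, name: str) -> Path:
        path = out_dir / name
        if isinstance(obj, pd.DataFrame) and name.endswith(".csv"):
            if set(obj.columns) == set(
                ("frame", "x", "y", "intensity", "precision", "source_id")
            ):
                write_localizations(obj, path)
            else:
                obj.to_csv(path, index=False, float_format="%.6g",
                           lineterminator="\n")
        else:
            dump_json(obj, path)
        manifest.outputs.append(str(path))
        return path

    if subcommand in ("simulate", "analyze", "all"):
        params = _params(scenario)
        table, aggregates, refs = simulate_fov(params, rng)
        manifest.counts["simulated_localizations"] = int(len(table))
        manifest.counts["ground_truth_aggregates"] = len(aggregates)
        _write(table, f"{scenario}_localizations.csv")
        if subcommand != "simulate":
            use_refs = refs if params.drift_mag > 0 else None
            filtered, labeling, records, summary = analyze_table(
                table, config, fiducial_refs=use_refs
            )
            manifest.counts["filtered_localizations"] = int(len(filtered))
            manifest.counts["clusters"] = labeling.n_clusters
            manifest.counts["clustered_localizations"] = int(
                (labeling.labels >= 0).sum()
            )
            _write(records_to_frame(records), f"{scenario}_morphometry.csv")
            _write(dataclasses.asdict(summary), f"{scenario}_summary.json")

    if subcommand in ("compare", "all"):
        cfg = config
        a = measure_population(_params(scenario), cfg, n_target=1000, rng=rng)
        b = measure_population(_params(scenario_b), cfg, n_target=1000, rng=rng)
        comparison = compare_groups(
            a["length_nm"].to_numpy(), b["length_nm"].to_numpy(),
            bin_width=config.hist_bin_width,
        )
        manifest.counts["measured_a"] = int(len(a))
        manifest.counts["measured_b"] = int(len(b))
        _write(a, "morphometry_a.csv")
        _write(b, "morphometry_b.csv")
        report = {
            "median_a": comparison.median_a,
            "median_b": comparison.median_b,
            "ks_D": comparison.ks_D,
            "ks_p": comparison.ks_p,
            "mwu_U": comparison.mwu_U,
            "mwu_p": comparison.mwu_p,
            "max_cum_difference_location_nm": comparison.max_cum_difference[0],
            "max_cum_difference_value": comparison.max_cum_difference[1],
            "bin_edges": comparison.bin_edges,
            "hist_difference": comparison.hist_difference,
        }
        _write(report, "comparison.json")

    if subcommand in ("influx", "all"):
        params = _params(scenario)
        truth_mean = 0.3
        influx_truth = rng.beta(1.5, 3.5, size=100)  # mean 0.3
        stacks = simulate_influx_experiment(100, influx_truth, params, rng)
        measurements, fov_mean, unmatched = analyze_influx_stacks(*stacks[:3])
        manifest.counts["influx_spots"] = len(measurements)
        manifest.counts["influx_unmatched"] = unmatched
        _write(
            {
                "fov_mean_influx_pct": fov_mean,
                "ground_truth_mean_pct": 100.0 * float(stacks[3]["influx"].mean()),
                "nominal_mean_pct": 100.0 * truth_mean,
                "n_valid": sum(m.valid for m in measurements),
            },
            "influx.json",
        )

    if subcommand in ("simpull", "all"):
        params = _params(scenario)
        target, control = simulate_simpull_experiment(params, rng, n_fovs=5)
        result = analyze_simpull(target, control)
        manifest.counts["simpull_target_total"] = int(sum(result["target_counts"]))
        manifest.counts["simpull_control_total"] = int(sum(result["control_counts"]))
        _write(result, "simpull.json")

    manifest.save(out_dir / "manifest.json")
    return manifest
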