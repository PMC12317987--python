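"""End-to-end orchestration: synthesize or load data, prep, fit the nMVAR
network per band and condition, test edges against time-shifted surrogates,
extract source clusters, and run the behavioral statistics — all from one
config under one master seed.

Seed discipline: the master seed feeds a ``numpy.random.SeedSequence``;
child seeds are spawned in a fixed order (simulate, volumes, behavior, then
one child per band x condition for the connectivity stage), so any stage
can be re-run in isolation with identical results.  Every stage writes its
outputs and a status line into ``manifest.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .clusters import compute_nai, extract_clusters
from .connectivity import significance_mask
from .containers import TimeSeriesMatrix, ValidationError
from .model import NMVARConfig
from .prep import bandpass, concatenate_trials, select_epochs
from .stats import bh_fdr, cell_mean_array, paired_compare, rm_anova_2x2, summarize_behavior
from .synthetic import (
    BehaviorGenSpec,
    GroundTruthSpec,
    NonlinearTerm,
    band_resonant_coeffs,
    generate_behavior,
    generate_source_volume,
    simulate_nmvar,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated front door to :func:`run_pipeline`.

    ``synthetic`` mode generates every input from the scenario parameters;
    ``files`` mode reads prepped inputs from the referenced paths (checked
    up front, so a missing file fails before any stage runs).
    """

    mode: str = "synthetic"
    bands: list[str] = field(default_factory=lambda: ["alpha"])
    conditions: list[str] = field(default_factory=lambda: ["post_s1"])
    master_seed: int = 0
    fs: float = 256.0
    # synthetic scenario
    n_regions: int = 2
    pole_radius: float | list[float] = 0.9
    noise_sd: float | list[float] = 1.0
    n_trials: int = 30
    linear_edges: list[tuple[int, int, float]] = field(default_factory=lambda: [(0, 1, 0.8)])
    nonlinear_edges: list[tuple[int, int, int, str, float]] = field(default_factory=list)
    # network + surrogates
    nmvar: NMVARConfig = field(default_factory=NMVARConfig)
    n_surrogates: int = 100
    percentile: float = 95.0
    # volumes / clustering
    volume_dims: tuple[int, int, int] = (12, 12, 12)
    volume_spacing: float = 5.0
    volume_noise_sd: float = 0.05
    blob_centers: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {"alpha": [(3.0, 3.0, 3.0), (8.0, 8.0, 8.0)]}
    )
    blob_radius: float = 1.2
    blob_amplitude: float = 5.0
    top_percent: float = 1.0
    min_pts: int = 5
    # behavior
    behavior: BehaviorGenSpec | None = None
    # files mode inputs
    timeseries_paths: dict[str, str] = field(default_factory=dict)  # condition -> path
    power_volume_paths: dict[str, str] = field(default_factory=dict)  # band -> path
    noise_volume_paths: dict[str, str] = field(default_factory=dict)
    behavior_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not self.bands or not self.conditions:
            raise ValidationError("at least one band and one condition are required")
        if self.mode == "files":
            paths = list(self.timeseries_paths.values())
            paths += list(self.power_volume_paths.values())
            paths += list(self.noise_volume_paths.values())
            if self.behavior_path:
                paths.append(self.behavior_path)
            missing = [p for p in paths if not Path(p).exists()]
            if missing:
                raise ValidationError(f"files mode: missing input files {missing}")


def two_region_alpha_config(master_seed: int = 0) -> PipelineConfig:
    """Bundled synthetic scenario: two alpha-resonant regions with one true
    directed edge region0 -> region1, sized for a fast full run."""
    return PipelineConfig(
        mode="synthetic",
        bands=["alpha"],
        conditions=["post_s1"],
        master_seed=master_seed,
        n_regions=2,
        pole_radius=[0.9, 0.3],
        noise_sd=[1.0, 0.5],
        n_trials=30,
        linear_edges=[(0, 1, 0.8)],
        nmvar=NMVARConfig(order=5, hidden_units=10, n_folds=3, max_epochs=60,
                          patience=10, learning_rate=0.01, seed=0),
        n_surrogates=30,
        behavior=BehaviorGenSpec(
            n_subjects=12,
            trials_per_condition=12,
            accuracy_means={
                ("repetition", "full overlap"): 0.94,
                ("repetition", "no overlap"): 0.79,
                ("alternation", "no overlap"): 0.96,
                ("alternation", "full overlap"): 0.78,
            },
            rt_means_ms={
                ("repetition", "full overlap"): 480.0,
                ("repetition", "no overlap"): 540.0,
                ("alternation", "no overlap"): 470.0,
                ("alternation", "full overlap"): 555.0,
            },
            rt_sd_ms=80.0,
            subject_sd=0.04,
            rt_subject_sd_ms=40.0,
        ),
    )


def _ground_truth_spec(config: PipelineConfig, band: str, seed: int) -> GroundTruthSpec:
    m = config.n_regions
    radii = np.broadcast_to(np.asarray(config.pole_radius, dtype=float), (m,))
    lag1 = np.zeros((m, m))
    lag2 = np.zeros((m, m))
    for i, r in enumerate(radii):
        a1, a2 = band_resonant_coeffs(band, config.fs, float(r))
        lag1[i, i] = a1
        lag2[i, i] = a2
    for src, tgt, coeff in config.linear_edges:
        lag1[tgt, src] += coeff
    nl = [NonlinearTerm(target=t, source=s, lag=lag, form=form, coefficient=c)
          for (s, t, lag, form, c) in config.nonlinear_edges]
    trial_len = int(round(config.fs))
    return GroundTruthSpec(
        n_channels=m,
        linear_coeffs=[lag1, lag2],
        nonlinear_terms=nl,
        noise_sd=config.noise_sd,
        length=config.n_trials * trial_len,
        burn_in=500,
        seed=seed,
    )


def _child_seed(ss_child: np.random.SeedSequence) -> int:
    return int(ss_child.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage, returning the run directory.

    Stage order: simulate (synthetic mode) -> prep -> cluster extraction ->
    per band/condition connectivity with surrogate testing (skipped with a
    logged reason for any band with fewer than two clusters) -> behavioral
    statistics.  A machine-readable ``manifest.json`` records config,
    seeds, per-stage status and output files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.master_seed)
    seed_sim, seed_vol, seed_beh, seed_conn = ss.spawn(4)
    manifest: dict = {
        "master_seed": config.master_seed,
        "bands": config.bands,
        "conditions": config.conditions,
        "mode": config.mode,
        "nmvar_config": asdict(config.nmvar),
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, status: str, **extra) -> None:
        manifest["stages"].setdefault(stage, {})
        manifest["stages"][stage].update({"status": status, **extra})

    def save(path: Path) -> str:
        rel = str(path.relative_to(out))
        manifest["outputs"].append(rel)
        return rel

    try:
        # ---- simulate / load ---------------------------------------------
        raw: dict[tuple[str, str], TimeSeriesMatrix] = {}
        trial_len = int(round(config.fs))
        if config.mode == "synthetic":
            sim_children = seed_sim.spawn(len(config.bands) * len(config.conditions))
            k = 0
            for band in config.bands:
                for cond in config.conditions:
                    spec = _ground_truth_spec(config, band, _child_seed(sim_children[k]))
                    k += 1
                    series = simulate_nmvar(spec)
                    raw[(band, cond)] = series
                    p = out / f"raw_{band}_{cond}.tsv"
                    nio.write_timeseries(series, p)
                    save(p)
            record("simulate", "ok", n_series=len(raw))
        else:
            for cond in config.conditions:
                series = nio.read_timeseries(config.timeseries_paths[cond])
                for band in config.bands:
                    raw[(band, cond)] = series
            record("simulate", "skipped: files mode")

        # ---- volumes + behavior inputs -----------------------------------
        volumes: dict[str, tuple] = {}
        if config.mode == "synthetic":
            vol_children = seed_vol.spawn(len(config.bands))
            for b_idx, band in enumerate(config.bands):
                centers = config.blob_centers.get(band, [])
                blobs = [(c, config.blob_radius, config.blob_amplitude) for c in centers]
                power = generate_source_volume(
                    config.volume_dims, config.volume_spacing, blobs,
                    noise_sd=config.volume_noise_sd, seed=_child_seed(vol_children[b_idx]),
                    baseline=1.0,
                )
                noise_vol = generate_source_volume(
                    config.volume_dims, config.volume_spacing, [], noise_sd=0.0, baseline=1.0,
                )
                volumes[band] = (power, noise_vol)
                p = out / f"power_{band}.csv"
                nio.write_volume(power, p)
                save(p)
            behavior = generate_behavior(
                BehaviorGenSpec(**{**asdict(config.behavior), "seed": _child_seed(seed_beh)})
                if config.behavior is not None
                else BehaviorGenSpec(
                    n_subjects=12, trials_per_condition=12,
                    accuracy_means={c: 0.85 for c in
                                    [(r, o) for r in ("repetition", "alternation")
                                     for o in ("no overlap", "full overlap")]},
                    rt_means_ms={c: 500.0 for c in
                                 [(r, o) for r in ("repetition", "alternation")
                                  for o in ("no overlap", "full overlap")]},
                    seed=_child_seed(seed_beh),
                )
            )
            p = out / "behavior.csv"
            nio.write_behavior(behavior, p)
            save(p)
        else:
            for band in config.bands:
                power = nio.read_volume(config.power_volume_paths[band])
                noise_vol = nio.read_volume(config.noise_volume_paths[band])
                volumes[band] = (power, noise_vol)
            behavior = nio.read_behavior(config.behavior_path) if config.behavior_path else None

        # ---- cluster extraction ------------------------------------------
        n_clusters: dict[str, int] = {}
        for band in config.bands:
            power, noise_vol = volumes[band]
            nai = compute_nai(power, noise_vol)
            cset = extract_clusters(nai, percent=config.top_percent, min_pts=config.min_pts)
            n_clusters[band] = cset.n_clusters
            rows = []
            for cid, cl in enumerate(cset.clusters):
                for ijk in cl:
                    xyz = ijk * nai.spacing
                    rows.append({"cluster_id": cid, "i": int(ijk[0]), "j": int(ijk[1]),
                                 "k": int(ijk[2]), "x_mm": xyz[0], "y_mm": xyz[1],
                                 "z_mm": xyz[2],
                                 "value": float(nai.values[tuple(ijk)])})
            p = out / f"clusters_{band}.csv"
            pd.DataFrame(rows).to_csv(p, index=False, float_format="%.12g")
            save(p)
            summary = {
                "band": band, "n_clusters": cset.n_clusters, "sizes": cset.sizes(),
                "threshold": cset.threshold, "eps": cset.eps, "min_pts": cset.min_pts,
            }
            p = out / f"clusters_{band}.json"
            with open(p, "w") as fh:
                json.dump(summary, fh, sort_keys=True)
                fh.write("\n")
            save(p)
        record("clusters", "ok", n_clusters=n_clusters)

        # ---- prep + connectivity -----------------------------------------
        conn_children = seed_conn.spawn(len(config.bands) * len(config.conditions))
        k = 0
        conn_status = {}
        for band in config.bands:
            for cond in config.conditions:
                key = f"{band}/{cond}"
                child = conn_children[k]
                k += 1
                if n_clusters[band] < 2:
                    conn_status[key] = "skipped: <2 clusters"
                    logger.info("connectivity %s skipped: fewer than 2 clusters", key)
                    continue
                series = raw[(band, cond)]
                filt = bandpass(series, band)
                onsets = np.arange(0, series.n_samples - trial_len + 1, trial_len)
                epochs = select_epochs(filt, onsets, (0.0, 1000.0))
                prepped = concatenate_trials(epochs)
                p = out / f"prepped_{band}_{cond}.tsv"
                nio.write_timeseries(prepped, p)
                save(p)
                observed, null, masked = significance_mask(
                    prepped, config.nmvar,
                    n_surrogates=config.n_surrogates,
                    percentile=config.percentile,
                    seed=_child_seed(child),
                    band=band, condition=cond,
                )
                p = out / f"connectivity_{band}_{cond}.csv"
                nio.write_connectivity(masked, p, null)
                save(p)
                p = out / f"connectivity_{band}_{cond}_observed.csv"
                nio.write_connectivity(observed, p, null)
                save(p)
                conn_status[key] = f"ok: {int(null.n_surrogates)} surrogates, {null.n_dropped} dropped"
        record("connectivity", "ok", per_condition=conn_status)

        # ---- behavioral statistics ---------------------------------------
        if behavior is not None:
            summary = summarize_behavior(behavior)
            p = out / "behavior_summary.csv"
            summary.to_csv(p, index=False, float_format="%.12g")
            save(p)
            report = {}
            for measure in ("hit_rate_pct", "mean_rt_ms"):
                arr = cell_mean_array(summary, measure)
                if not np.all(np.isfinite(arr)):
                    report[measure] = {"status": "skipped: missing cells"}
                    continue
                anova = rm_anova_2x2(arr)
                report[measure] = {
                    name: {"F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                           "partial_eta_sq": e.partial_eta_sq}
                    for name, e in anova.items()
                }
                if anova["interaction"].p < 0.05:
                    # post-hoc: overlap effect within each response relation
                    posthoc = {}
                    pvals = []
                    for a_idx, resp in enumerate(("repetition", "alternation")):
                        res = paired_compare(arr[:, a_idx, 0], arr[:, a_idx, 1])
                        posthoc[resp] = {"test": res.test, "statistic": res.statistic,
                                         "p": res.p, "n": res.n}
                        pvals.append(res.p)
                    rejected, critical = bh_fdr(np.array(pvals), q=0.05)
                    report[measure]["posthoc"] = posthoc
                    report[measure]["fdr"] = {"rejected": rejected.tolist(),
                                              "critical_value": critical}
            p = out / "behavior_stats.json"
            with open(p, "w") as fh:
                json.dump(report, fh, sort_keys=True, indent=1)
                fh.write("\n")
            save(p)
            record("stats", "ok")
        else:
            record("stats", "skipped: no behavior table")
    except Exception as exc:
        record("failed_stage", "error", message=str(exc))
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from YAML/JSON (field names mirror the dataclass)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "nmvar" in data and isinstance(data["nmvar"], dict):
        nm = data["nmvar"]
        if "init_range" in nm:
            nm["init_range"] = tuple(nm["init_range"])
        data["nmvar"] = NMVARConfig(**nm)
    if "behavior" in data and isinstance(data["behavior"], dict):
        beh = dict(data["behavior"])
        for key in ("accuracy_means", "rt_means_ms"):
            if key in beh:
                beh[key] = {tuple(k.split("|")): v for k, v in beh[key].items()}
        data["behavior"] = BehaviorGenSpec(**beh)
    for key in ("linear_edges", "nonlinear_edges"):
        if key in data:
            data[key] = [tuple(e) for e in data[key]]
    if "volume_dims" in data:
        data["volume_dims"] = tuple(data["volume_dims"])
    if "blob_centers" in data:
        data["blob_centers"] = {b: [tuple(c) for c in cs] for b, cs in data["blob_centers"].items()}
    return PipelineConfig(**data)
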