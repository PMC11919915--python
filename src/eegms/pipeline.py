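"""End-to-end pipeline: simulate/load -> clean -> fit -> aggregate ->
backfit -> parameters -> statistics.

One global seed fans out to per-stage streams through ``SeedSequence``
(stream 0: simulation, 1: session fits, 2: aggregation), so each stage is
independently reproducible.  Every run writes its tables plus a manifest
(config echo, output checksums, timings) sufficient to reproduce outputs
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .microstates import (LabelSequence, MicrostateSet, aggregate_maps,
                          assign_letters, backfit, canonical_templates,
                          find_gfp_peaks, gev, gfp, modified_kmeans,
                          spatial_correlation)
from .parameters import PARAMETER_NAMES, parameter_table, summarize
from .recording import Recording
from .stats import paired_t_bonferroni, rm_anova_2way, spearman_matrix
from .synthetic import (GroundTruthConfig, PlantedEffect, SimulatedCohort,
                        simulate_cohort)

STAGE_ORDER = ("Training", "PracticeA", "PracticeB")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML."""

    out_dir: str = "results/run"
    k: int = 7
    n_init: int = 100
    n_init_session: int | None = None  # lighter restarts for session fits
    min_peak_distance: int = 10
    aggregate_n_iter: int = 100
    correlation_unit: str = "subject_stage"
    seed: int = 0
    simulate: GroundTruthConfig | None = None
    preprocess: bool = False  # synthetic data is generated clean

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("K must be >= 2")
        for name in ("n_init", "min_peak_distance", "aggregate_n_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            effects = [PlantedEffect(**e) for e in sim.pop("planted_effects", [])]
            cfg.simulate = GroundTruthConfig(planted_effects=effects, **sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"]["dwell_mean_ms"] = list(
                np.asarray(self.simulate.dwell_mean_ms))
            if self.simulate.occurrence_target is not None:
                d["simulate"]["occurrence_target"] = list(
                    np.asarray(self.simulate.occurrence_target))
        return d


# ---------------------------------------------------------------------------
# fitting stages (library surface used by drivers and tests)


def peak_maps(recording: Recording, min_peak_distance: int = 10) -> np.ndarray:
    """Topographies at GFP peaks (peaks x channels)."""
    peaks = find_gfp_peaks(gfp(recording), min_peak_distance)
    return recording.data[:, peaks].T


def fit_sessions(recordings: dict[tuple, Recording], k: int, n_init: int = 100,
                 min_peak_distance: int = 10,
                 seed: int | np.random.SeedSequence | None = None
                 ) -> dict[tuple, MicrostateSet]:
    """Modified k-means per session, on that session's GFP-peak maps."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    streams = ss.spawn(len(recordings))
    out = {}
    for stream, (key, rec) in zip(streams, sorted(recordings.items())):
        out[key] = modified_kmeans(peak_maps(rec, min_peak_distance), k,
                                   n_init=n_init,
                                   seed=np.random.default_rng(stream),
                                   level="session")
    return out


def aggregate_hierarchy(session_sets: dict[tuple, MicrostateSet], k: int,
                        n_iter: int = 100,
                        seed: int | np.random.SeedSequence | None = None
                        ) -> tuple[MicrostateSet, dict]:
    """Session -> subject(x stage) -> condition -> global aggregation.

    Keys of ``session_sets`` are (subject, stage, session).  Returns the
    global set plus every intermediate level for inspection.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    subject_sets: dict[tuple, MicrostateSet] = {}
    for (subject, stage) in sorted({(s, st) for (s, st, _) in session_sets}):
        lower = [v for (s, st, _), v in sorted(session_sets.items())
                 if (s, st) == (subject, stage)]
        subject_sets[(subject, stage)] = aggregate_maps(
            lower, k, n_iter, rng, level="subject")

    condition_sets: dict[str, MicrostateSet] = {}
    for stage in sorted({st for (_, st) in subject_sets}):
        lower = [v for (s, st), v in sorted(subject_sets.items()) if st == stage]
        condition_sets[stage] = aggregate_maps(lower, k, n_iter, rng,
                                               level="condition")

    global_set = aggregate_maps(list(condition_sets.values()), k, n_iter, rng,
                                level="global")
    return global_set, {"subject": subject_sets, "condition": condition_sets}


def backfit_all(recordings: dict[tuple, Recording],
                global_set: MicrostateSet) -> dict[tuple, LabelSequence]:
    return {key: backfit(rec, global_set) for key, rec in sorted(recordings.items())}


def match_to_truth(global_set: MicrostateSet, true_maps: np.ndarray) -> pd.DataFrame:
    """Optimal matching of fitted classes to planted ground-truth maps."""
    from scipy.optimize import linear_sum_assignment

    score = np.abs(spatial_correlation(global_set.maps, true_maps))
    rows, cols = linear_sum_assignment(-score)
    return pd.DataFrame({
        "fitted_class": rows, "true_class": cols,
        "abs_corr": score[rows, cols],
        "letter": [global_set.letters[r] if global_set.letters else None
                   for r in rows],
    })


# ---------------------------------------------------------------------------
# the driver


def effective_sim_config(config: PipelineConfig) -> GroundTruthConfig:
    """The simulation config a run actually uses.

    The global pipeline seed fans out to per-stage streams; stream 0 drives
    the simulation, overriding the nested config's own seed.  Analysis
    scripts use this to regenerate a run's cohort deterministically.
    """
    if config.simulate is None:
        raise ValueError("config has no simulation section")
    sim_ss = np.random.SeedSequence(config.seed).spawn(3)[0]
    return dataclasses.replace(
        config.simulate, seed=int(sim_ss.generate_state(1)[0] % (2**31)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_contrasts(stages) -> list[tuple]:
    stages = sorted(stages, key=lambda s: STAGE_ORDER.index(s)
                    if s in STAGE_ORDER else 99)
    return [(a, b) for i, a in enumerate(stages) for b in stages[i + 1:]]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).  Rerunning
    with the same config reproduces every output bit-exactly.
    """
    if config.simulate is None:
        raise ValueError("this driver runs on simulated cohorts; "
                         "load recordings via eegms.io for file-based runs")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        timings[stage] = round(time.perf_counter() - t0, 3)

    ss = np.random.SeedSequence(config.seed)
    _, fit_ss, agg_ss = ss.spawn(3)

    cohort = simulate_cohort(effective_sim_config(config))
    tick("simulate")

    recordings = cohort.recordings
    if config.preprocess:
        from .preprocess import clean

        recordings = {k: clean(r, use_neighbors=False)[0]
                      for k, r in recordings.items()}
        tick("preprocess")

    n_init_session = config.n_init_session or config.n_init
    session_sets = fit_sessions(recordings, config.k, n_init_session,
                                config.min_peak_distance, fit_ss)
    tick("fit_sessions")

    global_set, levels = aggregate_hierarchy(session_sets, config.k,
                                             config.aggregate_n_iter, agg_ss)
    canon = canonical_templates(cohort.montage)
    if global_set.n_classes <= canon.n_classes:
        global_set = assign_letters(global_set, canon)
    tick("aggregate")

    labels = backfit_all(recordings, global_set)
    gevs = pd.DataFrame([
        {"subject": s, "stage": st, "session": se,
         "gev": gev(recordings[(s, st, se)], lab, global_set)}
        for (s, st, se), lab in labels.items()])
    tick("backfit")

    params = parameter_table(labels, config.simulate.fs, config.k)
    summary = summarize(params)
    tick("parameters")

    anovas = {p: rm_anova_2way(summary, dv=p) for p in PARAMETER_NAMES}
    eval_anova = rm_anova_2way(cohort.evaluations, dv="score",
                               factor_a="dimension", factor_b="stage")
    stage_posthoc = {
        p: paired_t_bonferroni(summary, dv=p, condition="stage",
                               contrasts=_stage_contrasts(summary["stage"].unique()))
        for p in PARAMETER_NAMES}
    correlations = spearman_matrix(summary, cohort.evaluations,
                                   unit=config.correlation_unit)
    truth_match = match_to_truth(global_set, cohort.true_maps)
    tick("stats")

    # ------------------------------------------------------------------ write
    from .io import write_microstate_set

    outputs = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs[name] = _sha256(path)

    write_microstate_set(global_set, out / "global_maps.json")
    outputs["global_maps.json"] = _sha256(out / "global_maps.json")
    save("parameters.csv", params)
    save("summary.csv", summary)
    save("gev.csv", gevs)
    save("evaluations.csv", cohort.evaluations)
    for p, a in anovas.items():
        save(f"anova_{p}.csv", a)
    save("anova_evaluations.csv", eval_anova)
    for p, t in stage_posthoc.items():
        save(f"posthoc_stage_{p}.csv", t)
    save("correlations.csv", correlations)
    save("truth_match.csv", truth_match)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "timings_s": timings,
        "outputs_sha256": outputs,
        "global_cv": global_set.cv,
        "global_gev_peaks": global_set.gev,
        "mean_gev": float(gevs["gev"].mean()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
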