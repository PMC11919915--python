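"""Ground-truth cohort generator.

The study design this emulates: a cohort of subjects, each recorded over a
curriculum of short sessions grouped into three stages (Training,
PracticeA, PracticeB), with 64-channel scalp EEG and per-stage behavioral
evaluation scores on five dimensions (D1-D5).  No real data ships with the
package, so every downstream stage is exercised against cohorts with
*planted* truth:

* K template topographies (average-referenced, unit norm, bounded mutual
  correlation),
* a semi-Markov label process — gamma-distributed dwell times per class,
  uniform transitions to a *different* class — so dwell histograms are
  non-exponential, as real microstate dwell times are,
* EEG rendered as sign-randomized, amplitude-modulated templates plus
  spatially white sensor noise (sign randomization forces all downstream
  code to be polarity-invariant),
* evaluation scores with planted monotone (Spearman) associations to
  chosen class x parameter combinations.

Everything is deterministic given the config seed: one seed fans out to
independent per-purpose streams via ``numpy``'s ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .microstates import LabelSequence, normalize_maps
from .montage import Montage, synthetic_montage
from .parameters import parameter_table, summarize
from .recording import Recording
from .stats import DIMENSIONS

STAGES = ("Training", "PracticeA", "PracticeB")


def default_session_plan(duration_s: float = 30.0) -> list[tuple[str, str, float]]:
    """22 Trial sessions split 7 / 8 / 7 across the three stages.

    Session durations default to 30 s — a desk-scale stand-in for the
    recorded task lengths that keeps full-cohort simulations tractable.
    """
    plan = []
    for stage, n in zip(STAGES, (7, 8, 7)):
        plan += [(stage, "Trial", duration_s)] * n
    return plan


@dataclass
class PlantedEffect:
    """A monotone association planted between a parameter and a dimension."""

    class_index: int
    parameter: str  # coverage | duration | occurrence
    dimension: str  # D1..D5
    rho: float  # target Spearman correlation

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1:
            raise ValueError("target |rho| must be < 1 (1 is unattainable with noise)")
        if self.parameter not in ("coverage", "duration", "occurrence"):
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")


@dataclass
class GroundTruthConfig:
    """Cohort-level simulation settings.

    Defaults mirror the emulated study layout: 24 subjects, 64 channels at
    250 Hz (the post-preprocessing rate), 7 microstate classes, 22 sessions
    split 7/8/7 over Training/PracticeA/PracticeB.  Per-class dwell means
    span 60-110 ms — a plausible literature range that also plants a CLASS
    main effect for the ANOVA layer.  ``snr`` is the ratio of mean signal
    GFP to noise GFP; 4 gives clean but non-trivial recovery.
    """

    n_subjects: int = 24
    n_channels: int = 64
    fs: float = 250.0
    n_classes: int = 7
    session_plan: list[tuple[str, str, float]] = field(
        default_factory=default_session_plan)
    dwell_mean_ms: np.ndarray | float = None  # per class; default 60..110 ms
    dwell_shape: float = 2.0
    occurrence_target: np.ndarray | None = None  # relative visit rates
    snr: float = 4.0
    noise_sd: float | None = None  # uV; overrides snr when given
    max_abs_corr: float = 0.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    score_noise_sd: float = 1.0
    score_range: tuple[float, float] = (1.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_mean_ms is None:
            self.dwell_mean_ms = np.linspace(60.0, 110.0, self.n_classes)
        self.dwell_mean_ms = np.broadcast_to(
            np.asarray(self.dwell_mean_ms, dtype=float), (self.n_classes,)).copy()
        if np.any(self.dwell_mean_ms <= 0):
            raise ValueError("dwell means must be positive")
        if self.n_classes > self.n_channels - 1:
            raise ValueError("need n_classes <= n_channels - 1")


@dataclass
class SimulatedCohort:
    """A cohort with full ground truth attached.

    ``true_parameters`` are computed *from the simulated label sequences*
    (never from the config targets), so the generator and the parameter
    estimators close exactly on noiseless data.
    """

    config: GroundTruthConfig
    montage: Montage
    true_maps: np.ndarray
    true_labels: dict[tuple, LabelSequence]
    recordings: dict[tuple, Recording]
    true_parameters: pd.DataFrame
    evaluations: pd.DataFrame


# ---------------------------------------------------------------------------
# topographies


def make_topographies(n_channels: int, n_classes: int, max_abs_corr: float = 0.5,
                      seed: int | np.random.Generator | None = None,
                      max_tries: int = 200) -> np.ndarray:
    """Random average-referenced unit-norm template maps.

    Pairwise absolute spatial correlation is bounded by ``max_abs_corr``
    via rejection sampling; ``max_abs_corr=0`` switches to exact
    orthogonalization within the zero-mean subspace.  Fails explicitly if
    the constraint is infeasible within ``max_tries`` attempts per map.
    """
    if n_classes > n_channels - 1:
        raise ValueError("at most n_channels - 1 mutually decorrelated maps exist")
    if not 0 <= max_abs_corr < 1:
        raise ValueError("max_abs_corr must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if max_abs_corr == 0:
        raw = rng.standard_normal((n_channels, n_classes))
        raw -= raw.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(raw)
        q -= q.mean(axis=0, keepdims=True)  # QR preserves the zero-mean space
        return normalize_maps(q.T)
    maps: list[np.ndarray] = []
    for _ in range(n_classes):
        for _attempt in range(max_tries):
            cand = normalize_maps(rng.standard_normal(n_channels))[0]
            if all(abs(cand @ m) <= max_abs_corr for m in maps):
                maps.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw {n_classes} maps with |corr| <= {max_abs_corr} "
                f"in {max_tries} tries per map")
    return np.vstack(maps)


def make_smooth_topographies(montage: Montage, n_classes: int,
                             dipole_weight: float = 0.85,
                             seed: int | np.random.Generator | None = None
                             ) -> np.ndarray:
    """Spatially smooth template maps built from low-order harmonics.

    Real microstate topographies are large-scale dipolar/quadrupolar
    patterns; this draws each class as a random orthonormal mixture of the
    l=1 (3 dipole) and l=2 (5 quadrupole) real harmonics evaluated at the
    sensors, with mixing coefficients weighted toward the dipoles.  At most
    8 mutually decorrelated smooth classes exist.  Smooth maps give the
    high neighbor-channel correlations that the bad-channel rules assume;
    the random maps of :func:`make_topographies` do not.
    """
    if not 0 < dipole_weight <= 1:
        raise ValueError("dipole_weight must be in (0, 1]")
    n_basis = 3 if dipole_weight == 1 else 8
    if n_classes > n_basis:
        raise ValueError(f"at most {n_basis} smooth classes for this basis")
    x, y, z = montage.positions.T
    basis = np.stack([x, y, z, x * y, y * z, x * z,
                      x * x - y * y, 3 * z * z - 1])[:n_basis]
    basis = normalize_maps(basis)
    rng = np.random.default_rng(seed)
    w = np.array([dipole_weight] * 3 + [1 - dipole_weight] * 5)[:n_basis]
    coef = rng.standard_normal((n_basis, n_classes)) * w[:, None]
    q, _ = np.linalg.qr(coef)
    return normalize_maps(q.T @ basis)


# ---------------------------------------------------------------------------
# label dynamics


def simulate_labels(duration_s: float, fs: float, dwell_mean_ms: np.ndarray | float,
                    n_classes: int, seed: int | np.random.Generator | None = None,
                    dwell_shape: float = 2.0,
                    visit_weights: np.ndarray | None = None) -> LabelSequence:
    """Semi-Markov microstate label process.

    Dwell times are gamma (default shape 2) with the given per-class mean;
    successive runs never repeat a class; the next class is drawn with
    probability proportional to ``visit_weights`` over the *other* classes
    (uniform by default).  Run lengths are rounded to whole samples.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if n_classes < 2:
        raise ValueError("need at least 2 classes: a single state cannot transition")
    dwell = np.broadcast_to(np.asarray(dwell_mean_ms, dtype=float), (n_classes,))
    if np.any(dwell <= 0):
        raise ValueError("dwell means must be positive")
    if fs * dwell.min() / 1000.0 < 2:
        raise ValueError("shortest dwell mean spans < 2 samples: states unresolvable")
    w = (np.ones(n_classes) if visit_weights is None
         else np.asarray(visit_weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("visit weights must be positive")
    rng = np.random.default_rng(seed)

    n_total = round(duration_s * fs)
    labels = np.empty(n_total, dtype=np.int64)
    state = int(rng.choice(n_classes, p=w / w.sum()))
    pos = 0
    while pos < n_total:
        mean_samples = dwell[state] / 1000.0 * fs
        length = max(1, round(rng.gamma(dwell_shape, mean_samples / dwell_shape)))
        end = min(pos + length, n_total)
        labels[pos:end] = state
        pos = end
        p = w.copy()
        p[state] = 0.0
        state = int(rng.choice(n_classes, p=p / p.sum()))
    return LabelSequence(labels=labels, abs_corr=np.ones(n_total), fs=fs)


def implied_coverage(dwell_mean_ms: np.ndarray,
                     visit_weights: np.ndarray | None = None) -> np.ndarray:
    """Stationary per-class coverage implied by the label process.

    The embedded transition chain has P(i -> j) proportional to w_j for
    j != i; coverage is the stationary visit distribution weighted by the
    dwell means, computed exactly from the chain's stationary vector.
    """
    dwell = np.asarray(dwell_mean_ms, dtype=float)
    n = len(dwell)
    w = np.ones(n) if visit_weights is None else np.asarray(visit_weights, float)
    P = np.tile(w, (n, 1))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    cov = pi * dwell
    return cov / cov.sum()


# ---------------------------------------------------------------------------
# EEG rendering


def default_envelope(n_samples: int, fs: float, freq_hz: float = 10.0,
                     amplitude: float = 10.0, floor: float = 0.1) -> np.ndarray:
    """Rectified alpha-band sinusoid with a positive floor (uV scale).

    The rectified oscillation produces the local GFP maxima that peak
    picking relies on; the floor keeps the topography defined everywhere.
    """
    t = np.arange(n_samples) / fs
    return amplitude * (np.abs(np.sin(2 * np.pi * freq_hz * t)) + floor)


def noise_sd_for_snr(envelope: np.ndarray, n_channels: int, snr: float) -> float:
    """Sensor-noise SD giving the requested mean signal-GFP / noise-GFP."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(envelope.mean() / np.sqrt(n_channels) / snr)


def render_eeg(labels: LabelSequence, maps: np.ndarray, fs: float | None = None,
               envelope: np.ndarray | None = None, noise_sd: float = 0.0,
               seed: int | np.random.Generator | None = None,
               montage: Montage | None = None) -> Recording:
    """Render a label sequence into a multichannel recording.

    signal_t = s_r * envelope_t * map[label_t] + centered white noise,
    with s_r a random sign per run — so rendered data only match their
    generating templates up to polarity, as the microstate model assumes.
    The noise is re-centered across channels at every sample, keeping the
    recording exactly average-referenced.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    maps = normalize_maps(maps)
    lab = labels.labels
    if lab.max() >= maps.shape[0]:
        raise ValueError("label sequence references classes beyond the map set")
    fs = fs if fs is not None else labels.fs
    n_channels = maps.shape[1]
    if envelope is None:
        envelope = default_envelope(len(lab), fs)
    if len(envelope) != len(lab) or np.any(envelope <= 0):
        raise ValueError("envelope must be strictly positive, one value per sample")
    rng = np.random.default_rng(seed)

    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], change])
    signs = rng.choice([-1.0, 1.0], size=len(starts))
    sign_t = np.repeat(signs, np.diff(np.concatenate([starts, [len(lab)]])))

    data = (sign_t * envelope) * maps[lab].T  # channels x samples
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=data.shape)
        noise -= noise.mean(axis=0, keepdims=True)
        data = data + noise
    montage = montage if montage is not None else synthetic_montage(n_channels)
    return Recording(data=data, fs=fs, montage=montage, reference="average")


# ---------------------------------------------------------------------------
# evaluation scores


def simulate_evaluations(true_parameters: pd.DataFrame,
                         planted_effects: list[PlantedEffect],
                         noise_sd: float = 1.0,
                         score_range: tuple[float, float] = (1.0, 5.0),
                         seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Per subject x stage x dimension scores with planted associations.

    A planted (class, parameter, dimension, rho) effect couples the score
    to the subject x stage mean of that parameter through a latent
    bivariate-normal construction: the parameter's normal scores z are
    mixed as  rho_p * z + sqrt(1 - rho_p^2) * noise_sd * eps  with
    rho_p = 2 sin(pi * rho / 6) (the Pearson correlation whose bivariate
    normal has Spearman correlation rho).  With ``noise_sd = 1`` the
    population Spearman correlation approximates the target; ``noise_sd =
    0`` makes the score a strictly monotone transform of the parameter.
    Dimensions with no planted effect are pure noise.  The latent values
    are mapped linearly into ``score_range``.
    """
    rng = np.random.default_rng(seed)
    summary = summarize(true_parameters) if "session" in true_parameters.columns \
        else true_parameters
    by_dim = {e.dimension: e for e in planted_effects}
    if len(by_dim) < len(planted_effects):
        raise ValueError("at most one planted effect per dimension")
    cells = summary[["subject", "stage"]].drop_duplicates().reset_index(drop=True)
    n = len(cells)
    lo, hi = score_range

    rows = []
    for dim in DIMENSIONS:
        eff = by_dim.get(dim)
        eps = rng.standard_normal(n)
        if eff is None:
            latent = eps
        else:
            sub = summary[summary["class"] == eff.class_index]
            if sub.empty:
                raise ValueError(f"planted effect names missing class {eff.class_index}")
            base = cells.merge(sub, on=["subject", "stage"],
                               how="left")[eff.parameter].to_numpy(float)
            if np.any(np.isnan(base)):
                raise ValueError("planted parameter is missing for some cells")
            ranks = sst.rankdata(base)
            z = sst.norm.ppf((ranks - 0.5) / n)
            rho_p = 2.0 * np.sin(np.pi * eff.rho / 6.0)
            latent = rho_p * z + np.sqrt(1.0 - rho_p**2) * noise_sd * eps
        span = latent.max() - latent.min()
        score = (np.full(n, 0.5 * (lo + hi)) if span == 0
                 else lo + (latent - latent.min()) / span * (hi - lo))
        for (subject, stage), s in zip(cells.itertuples(index=False), score):
            rows.append({"subject": subject, "stage": stage,
                         "dimension": dim, "score": float(s)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the full cohort


def simulate_cohort(config: GroundTruthConfig, render: bool = True,
                    montage: Montage | None = None) -> SimulatedCohort:
    """Simulate an entire cohort with ground truth attached.

    Seeds fan out deterministically: stream 0 draws the topographies,
    stream 1 the evaluations, and one stream per subject x session drives
    its labels and noise — so any single recording can be regenerated
    without simulating the rest.
    """
    ss = np.random.SeedSequence(config.seed)
    n_sessions = len(config.session_plan)
    streams = ss.spawn(2 + config.n_subjects * n_sessions)
    maps = make_topographies(config.n_channels, config.n_classes,
                             config.max_abs_corr, np.random.default_rng(streams[0]))
    montage = montage if montage is not None else synthetic_montage(config.n_channels)

    true_labels: dict[tuple, LabelSequence] = {}
    recordings: dict[tuple, Recording] = {}
    i = 2
    for subject in range(config.n_subjects):
        for session, (stage, _task, duration_s) in enumerate(config.session_plan):
            rng = np.random.default_rng(streams[i]); i += 1
            lab = simulate_labels(duration_s, config.fs, config.dwell_mean_ms,
                                  config.n_classes, rng, config.dwell_shape,
                                  config.occurrence_target)
            key = (subject, stage, session)
            true_labels[key] = lab
            if render:
                env = default_envelope(len(lab), config.fs)
                sd = (config.noise_sd if config.noise_sd is not None else
                      noise_sd_for_snr(env, config.n_channels, config.snr))
                recordings[key] = render_eeg(lab, maps, config.fs, env, sd, rng,
                                             montage)

    params = parameter_table(true_labels, config.fs, config.n_classes)
    evaluations = simulate_evaluations(params, config.planted_effects,
                                       config.score_noise_sd, config.score_range,
                                       np.random.default_rng(streams[1]))
    return SimulatedCohort(config=config, montage=montage, true_maps=maps,
                           true_labels=true_labels, recordings=recordings,
                           true_parameters=params, evaluations=evaluations)
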