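"""Polarity-invariant microstate segmentation.

The microstate model treats the scalp potential at each moment as one of K
template topographies, active with arbitrary sign and amplitude.  This
module implements the full chain on that model:

* global field power (GFP) and GFP-peak picking,
* the modified k-means algorithm: assignment by squared spatial correlation
  (so a map and its negation are the same state), template update as the
  dominant eigenvector of the assigned maps' outer-product sum, restart
  selection by the cross-validation (CV) criterion,
* multi-level aggregation of template sets (session -> subject ->
  condition -> global),
* canonical letter assignment (A..G) by optimal matching,
* backfitting a recording sample-by-sample with no temporal smoothing, and
  the global explained variance (GEV) of the resulting labeling.

Conventions used throughout: template maps are stored as rows (K x
channels), average-referenced and unit L2 norm; spatial correlation is the
Pearson correlation across channels; all comparisons are polarity-free
(absolute or squared correlation); ties break to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .montage import Montage
from .recording import AVG_REF_ATOL, Recording


@dataclass
class GfpSeries:
    """Per-sample global field power (spatial SD across channels), in uV."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP is a standard deviation and cannot be negative")


@dataclass
class MicrostateSet:
    """K unit-norm, average-referenced template topographies.

    ``level`` records provenance in the aggregation hierarchy
    (session / subject / condition / global); ``letters`` are canonical
    class names attached by :func:`assign_letters` and never affect any
    numeric result.
    """

    maps: np.ndarray  # K x channels
    cv: float
    gev: float
    level: str = "session"
    letters: tuple[str, ...] | None = None
    letter_corrs: np.ndarray | None = None
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] < 1:
            raise ValueError("maps must be a K x channels matrix with K >= 1")
        if self.cv < 0:
            raise ValueError("CV is a scaled variance and cannot be negative")
        if not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValueError("GEV must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]


@dataclass
class LabelSequence:
    """Per-sample microstate assignment from backfitting."""

    labels: np.ndarray  # int class index per sample
    abs_corr: np.ndarray  # |spatial correlation| with the assigned template
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.abs_corr = np.asarray(self.abs_corr, dtype=float)
        if self.labels.shape != self.abs_corr.shape:
            raise ValueError("labels and abs_corr must align")

    def __len__(self) -> int:
        return len(self.labels)


# ---------------------------------------------------------------------------
# spatial correlation helpers


def center_maps(maps: np.ndarray) -> np.ndarray:
    """Remove the across-channel mean from each map (row)."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    return maps - maps.mean(axis=1, keepdims=True)


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Center each map and scale it to unit L2 norm (zero maps stay zero)."""
    maps = center_maps(maps)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def spatial_correlation(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between two stacks of maps.

    Returns an (n_a, n_b) matrix; rows of zero spatial variance correlate 0
    with everything.
    """
    return normalize_maps(maps_a) @ normalize_maps(maps_b).T


def _require_average_referenced(data: np.ndarray, what: str) -> None:
    if np.any(np.abs(np.asarray(data).mean(axis=-2 if data.ndim > 1 else 0))
              > max(AVG_REF_ATOL, 1e-8 * np.abs(data).max(initial=1.0))):
        raise ValueError(f"{what} must be average-referenced")


# ---------------------------------------------------------------------------
# GFP


def gfp(recording: Recording) -> GfpSeries:
    """Global field power: the spatial SD (population divisor) per sample."""
    _require_average_referenced(recording.data, "recording")
    return GfpSeries(values=recording.data.std(axis=0), fs=recording.fs)


def find_gfp_peaks(series: GfpSeries | np.ndarray, min_distance: int = 10) -> np.ndarray:
    """Strict local maxima of the GFP series, thinned to a minimum spacing.

    When two maxima fall within ``min_distance`` samples the higher one is
    kept (greedy by descending height).  The spacing keeps the retained
    peaks quasi-independent snapshots of the topography.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    values = series.values if isinstance(series, GfpSeries) else np.asarray(series, float)
    if len(values) < 3:
        return np.array([], dtype=np.int64)
    peaks, _ = sps.find_peaks(values, distance=min_distance)
    # find_peaks admits plateau midpoints; keep strict local maxima only
    strict = (values[peaks] > values[peaks - 1]) & (values[peaks] > values[peaks + 1])
    return peaks[strict].astype(np.int64)


# ---------------------------------------------------------------------------
# modified k-means


def _dominant_eigvec(S: np.ndarray, v0: np.ndarray | None = None,
                     tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Dominant eigenvector of a PSD matrix by warm-started power iteration."""
    C = S.shape[0]
    v = v0 if v0 is not None else np.full(C, 1.0 / np.sqrt(C))
    lam = 0.0
    for _ in range(max_iter):
        w = S @ v
        nw = np.linalg.norm(w)
        if nw == 0:  # degenerate cluster (all-zero maps)
            return v
        w /= nw
        if abs(nw - lam) <= tol * max(nw, 1.0):
            return w
        v, lam = w, nw
    return v


def cv_criterion(sigma2: float, n_channels: int, k: int) -> float:
    """Cross-validation criterion: residual variance penalized for K.

    CV = sigma^2 * ((C-1)/(C-1-K))^2 with C the channel count.  Undefined
    for K >= C-1 (one spatial degree of freedom is lost to the average
    reference).
    """
    if k >= n_channels - 1:
        raise ValueError(f"CV undefined for K={k} with {n_channels} channels")
    return sigma2 * ((n_channels - 1) / (n_channels - 1 - k)) ** 2


def _fit_quality(Xc: np.ndarray, templates: np.ndarray,
                 labels: np.ndarray) -> float:
    """Mean orthogonal residual variance of the polarity-free model."""
    n, C = Xc.shape
    proj = np.einsum("ij,ij->i", Xc, templates[labels])
    return float(max(0.0, (np.sum(Xc**2) - np.sum(proj**2)) / (n * (C - 1))))


def _assign(Xc: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Polarity-free assignment: argmax_k of the squared projection.

    With unit templates and fixed map norms this equals argmax of squared
    spatial correlation; ties go to the lowest class index (argmax rule).
    """
    return np.argmax((Xc @ templates.T) ** 2, axis=1)


def _kmeans_refine(Xc: np.ndarray, templates: np.ndarray, max_iter: int,
                   tol: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternate assignment / dominant-eigenvector update to convergence."""
    n, C = Xc.shape
    K = templates.shape[0]
    templates = normalize_maps(templates)
    sigma2_prev = np.inf
    labels = _assign(Xc, templates)
    for _ in range(max_iter):
        for k in range(K):
            members = labels == k
            if not members.any():
                # re-seed an empty cluster from the worst-fit map
                proj = np.einsum("ij,ij->i", Xc, templates[labels])
                resid = np.sum(Xc**2, axis=1) - proj**2
                worst = int(np.argmax(resid))
                templates[k] = normalize_maps(Xc[worst])[0]
                labels[worst] = k
                members = labels == k
            Xk = Xc[members]
            S = Xk.T @ Xk
            templates[k] = _dominant_eigvec(S, templates[k])
        labels = _assign(Xc, templates)
        sigma2 = _fit_quality(Xc, templates, labels)
        if sigma2_prev - sigma2 <= tol * max(sigma2_prev, 1e-300):
            break
        sigma2_prev = sigma2
    return templates, labels, _fit_quality(Xc, templates, labels)


def _peak_gev(Xc: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> float:
    """GEV over the peak maps: GFP- and correlation-weighted fit fraction."""
    gfp_vals = Xc.std(axis=1)
    corr = np.einsum("ij,ij->i", normalize_maps(Xc), templates[labels])
    denom = float(np.sum(gfp_vals**2))
    if denom == 0:
        return 0.0
    return float(np.sum((gfp_vals * corr) ** 2) / denom)


def _partition_init(Xc: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Initial templates from a random surjective partition of the maps."""
    n, C = Xc.shape
    labels = rng.integers(0, k, size=n)
    labels[rng.choice(n, size=k, replace=False)] = np.arange(k)
    templates = np.empty((k, C))
    for j in range(k):
        Xj = Xc[labels == j]
        templates[j] = _dominant_eigvec(Xj.T @ Xj)
    return templates


def modified_kmeans(peak_maps: np.ndarray, k: int, n_init: int = 100,
                    max_iter: int = 300, tol: float = 1e-6,
                    seed: int | np.random.Generator | None = None,
                    level: str = "session") -> MicrostateSet:
    """Cluster GFP-peak topographies into K polarity-free templates.

    Runs ``n_init`` random restarts and returns the solution with the
    lowest CV criterion; deterministic given ``seed``.  Restarts alternate
    two initializations: templates drawn from the data maps (explores well
    on large peak sets) and templates from random partitions (escapes the
    local optima that trap data-point starts on small instances).

    Parameters
    ----------
    peak_maps : ndarray, shape (n_peaks, n_channels)
        Average-referenced topographies at GFP peaks.
    k : int
        Number of microstate classes; must satisfy ``k < n_channels - 1``
        (CV undefined otherwise) and ``k < n_peaks``.
    """
    X = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    n, C = X.shape
    if n <= k:
        raise ValueError(f"need more than K={k} peak maps, got {n}")
    if k >= C - 1:
        raise ValueError(f"K={k} >= channels-1={C - 1}: CV criterion undefined")
    _require_average_referenced(X.T, "peak maps")
    Xc = center_maps(X)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for restart in range(n_init):
        if restart % 2 == 0:
            init = Xc[rng.choice(n, size=k, replace=False)]
        else:
            init = _partition_init(Xc, k, rng)
        templates, labels, sigma2 = _kmeans_refine(Xc, init, max_iter, tol)
        cv = cv_criterion(sigma2, C, k)
        if best is None or cv < best[0]:
            best = (cv, templates, labels)
    cv, templates, labels = best
    return MicrostateSet(maps=normalize_maps(templates), cv=cv,
                         gev=_peak_gev(Xc, normalize_maps(templates), labels),
                         level=level)


def aggregate_maps(lower_sets: list[MicrostateSet], k: int, n_iter: int = 100,
                   seed: int | np.random.Generator | None = None,
                   refine: bool = True, level: str = "subject",
                   max_iter: int = 300, tol: float = 1e-6) -> MicrostateSet:
    """Combine lower-level template sets into one representative set.

    Pools every template of every lower set as an observation.  Each of
    ``n_iter`` iterations draws K pooled maps as candidate templates; with
    ``refine=True`` (default) the modified k-means refinement is run from
    that start, otherwise the candidates are scored as-is (the literal
    "evaluate drawn sets only" variant).  The candidate set with the lowest
    CV wins.  Applied hierarchically: session -> subject -> condition ->
    global.
    """
    pooled = np.vstack([s.maps for s in lower_sets])
    n, C = pooled.shape
    if n < k:
        raise ValueError(f"only {n} pooled maps for K={k}")
    Xc = center_maps(pooled)
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_iter):
        idx = rng.choice(n, size=k, replace=False)
        if refine:
            templates, labels, sigma2 = _kmeans_refine(Xc, Xc[idx], max_iter, tol)
        else:
            templates = normalize_maps(Xc[idx])
            labels = _assign(Xc, templates)
            sigma2 = _fit_quality(Xc, templates, labels)
        cv = cv_criterion(sigma2, C, k)
        if best is None or cv < best[0]:
            best = (cv, templates, labels)
    cv, templates, labels = best
    return MicrostateSet(maps=normalize_maps(templates), cv=cv,
                         gev=_peak_gev(Xc, normalize_maps(templates), labels),
                         level=level)


# ---------------------------------------------------------------------------
# canonical letters


def canonical_templates(montage: Montage) -> MicrostateSet:
    """Synthetic approximations of the canonical A-G microstate classes.

    Built from low-order polynomials of the sensor positions: A and B are
    the two diagonal (occipital-to-frontal) gradients, C the front-back
    axis, D the central maximum, and E-G higher-order patterns.  These are
    a constructed stand-in for a published template library; letters are
    cosmetic metadata and never enter any numeric result.
    """
    x, y, z = montage.positions.T
    raw = np.stack([
        -(x + y),        # A: left-occipital to right-frontal diagonal
        x - y,           # B: right-occipital to left-frontal diagonal
        y,               # C: anterior-posterior axis
        z,               # D: central / vertex maximum
        y * z,           # E: fronto-central vs occipital band
        x * y,           # F: quadrupolar left-right diagonal pair
        x * x - y * y,   # G: midline parieto-central pattern
    ])
    return MicrostateSet(maps=normalize_maps(raw), cv=0.0, gev=0.0,
                         level="canonical",
                         letters=tuple("ABCDEFG"), montage=montage)


def assign_letters(mset: MicrostateSet, canonical: MicrostateSet) -> MicrostateSet:
    """Attach canonical letters by optimal one-to-one matching.

    Solves the assignment problem maximizing the total absolute spatial
    correlation between fitted and canonical templates (greedy matching can
    be suboptimal).  Requires the canonical library to cover at least K
    classes on the same montage.
    """
    if canonical.n_classes < mset.n_classes:
        raise ValueError("canonical library has fewer classes than the fitted set")
    if mset.maps.shape[1] != canonical.maps.shape[1]:
        raise ValueError("montage mismatch between fitted and canonical templates")
    if (mset.montage is not None and canonical.montage is not None
            and mset.montage.names != canonical.montage.names):
        raise ValueError("montage mismatch between fitted and canonical templates")
    score = np.abs(spatial_correlation(mset.maps, canonical.maps))
    rows, cols = linear_sum_assignment(-score)
    letters = [None] * mset.n_classes
    corrs = np.zeros(mset.n_classes)
    names = canonical.letters or tuple(str(i) for i in range(canonical.n_classes))
    for r, c in zip(rows, cols):
        letters[r] = names[c]
        corrs[r] = score[r, c]
    out = MicrostateSet(maps=mset.maps.copy(), cv=mset.cv, gev=mset.gev,
                        level=mset.level, letters=tuple(letters),
                        letter_corrs=corrs, montage=mset.montage)
    return out


# ---------------------------------------------------------------------------
# backfitting and explained variance


def backfit(recording: Recording, mset: MicrostateSet) -> LabelSequence:
    """Label every sample with its best-matching template, polarity-free.

    label_t = argmax_k |corr(map_t, template_k)| with ties to the lowest
    class index; no temporal smoothing of any kind is applied, so the raw
    switching dynamics are preserved.  Flat (zero-variance) samples get the
    tie-rule label with correlation recorded as 0.
    """
    _require_average_referenced(recording.data, "recording")
    if recording.n_channels != mset.maps.shape[1]:
        raise ValueError("recording and templates have different channel counts")
    Xn = normalize_maps(recording.data.T)  # samples x channels, unit rows
    corr = np.abs(Xn @ normalize_maps(mset.maps).T)
    labels = np.argmax(corr, axis=1)
    return LabelSequence(labels=labels,
                         abs_corr=np.clip(corr[np.arange(len(labels)), labels], 0, 1),
                         fs=recording.fs)


def gev(recording: Recording, labels: LabelSequence, mset: MicrostateSet) -> float:
    """Global explained variance of a labeling.

    GEV = sum_t (GFP_t * corr_t)^2 / sum_t GFP_t^2, with corr_t the spatial
    correlation between sample t and its assigned template.  Equals 1 when
    every sample is an exact (signed, scaled) copy of its template.
    """
    if len(labels) != recording.n_samples:
        raise ValueError("label sequence length does not match the recording")
    gfp_vals = gfp(recording).values
    denom = float(np.sum(gfp_vals**2))
    if denom == 0:
        raise ValueError("all-zero recording: GEV undefined")
    Xn = normalize_maps(recording.data.T)
    corr = np.einsum("ij,ij->i", Xn, normalize_maps(mset.maps)[labels.labels])
    return float(np.sum((gfp_vals * corr) ** 2) / denom)
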