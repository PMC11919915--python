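"""Rule-based EEG cleaning chain.

Deterministic operators mirroring a conventional lab preprocessing recipe:

1. zero-phase Hamming windowed-sinc band-pass (1-40 Hz),
2. whole-recording bad-channel detection (flatline, low neighbor
   correlation, outlying amplitude),
3. optional pluggable artifact-removal hook (stands where an ICA-based
   artifact classifier would run in a lab pipeline; default no-op),
4. 2-second epoching with per-epoch local-channel repair (variance /
   median gradient / amplitude range / deviation statistics, z > 3 across
   channels, spherical-spline interpolation),
5. epoch rejection (absolute amplitude and probability criteria),
6. global bad-channel interpolation, average reference, downsampling.

Bad channels are always *repaired* (interpolated), never dropped, so the
channel count is preserved end to end.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal as sps
from scipy import stats as sst
from numpy.polynomial import legendre as npleg

from .montage import Montage
from .recording import (EpochedRecording, Recording, average_reference, epoch,
                        merge_epochs, resample)

__all__ = [
    "bandpass_fir", "detect_bad_channels", "faster_local_channels",
    "reject_segments", "spherical_spline_interpolate", "interpolation_matrix",
    "clean",
]


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(fs: float, low_hz: float = 1.0, high_hz: float = 40.0,
                    transition_hz: float = 1.0) -> np.ndarray:
    """Hamming windowed-sinc band-pass kernel (odd length, linear phase)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError("need 0 < low < high < Nyquist")
    # Hamming main-lobe rule: transition width ~ 3.3 / N (normalized)
    numtaps = int(np.ceil(3.3 * fs / transition_hz)) | 1
    return sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                      window="hamming", fs=fs)


def bandpass_fir(recording: Recording, low_hz: float = 1.0, high_hz: float = 40.0,
                 transition_hz: float = 1.0) -> Recording:
    """Zero-phase band-pass: one forward pass of a centered symmetric kernel.

    The kernel is symmetric (linear phase) and applied centered, so the
    group delay is compensated exactly and an impulse maps to a symmetric
    response.
    """
    kernel = design_bandpass(recording.fs, low_hz, high_hz, transition_hz)
    if recording.n_samples < len(kernel):
        raise ValueError(
            f"recording ({recording.n_samples} samples) shorter than the "
            f"{len(kernel)}-tap filter kernel")
    data = sps.fftconvolve(recording.data, kernel[None, :], mode="same", axes=1)
    return recording.copy_with(data=data)


# ---------------------------------------------------------------------------
# whole-recording bad channels


def _max_run(mask: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    if not mask.any():
        return 0
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int(np.max(edges[1::2] - edges[0::2]))


def detect_bad_channels(recording: Recording, flat_s: float = 5.0,
                        neighbor_corr: float = 0.8, amp_sd: float = 3.0,
                        k_neighbors: int = 4, flat_floor: float = 1e-8,
                        use_neighbors: bool = True) -> set[str]:
    """Union of three whole-recording criteria.

    1. flatline: any contiguous run longer than ``flat_s`` seconds with
       per-sample absolute first difference below ``flat_floor`` uV;
    2. neighbor correlation: mean absolute Pearson correlation with the
       ``k_neighbors`` nearest montage channels below ``neighbor_corr``;
    3. amplitude: robust z-score (median/MAD) of the channel RMS across
       channels above ``amp_sd``.

    The neighbor rule needs the montage; disabling it (``use_neighbors=
    False``) is explicit, never silent.
    """
    data = recording.data
    names = recording.montage.names
    bad: set[str] = set()

    flat_run = int(flat_s * recording.fs)
    deriv = np.abs(np.diff(data, axis=1)) < flat_floor
    for c in range(data.shape[0]):
        if _max_run(deriv[c]) > flat_run:
            bad.add(names[c])

    rms = np.sqrt(np.mean(data**2, axis=1))
    mad = sst.median_abs_deviation(rms, scale="normal")
    if mad > 0:
        z = (rms - np.median(rms)) / mad
        bad |= {names[c] for c in np.flatnonzero(z > amp_sd)}

    if use_neighbors:
        # draw neighbors from channels not already flagged, so one dead
        # channel cannot drag its healthy neighbors below the threshold
        good = np.array([c for c, n in enumerate(names) if n not in bad])
        if len(good) > k_neighbors:
            pos = recording.montage.positions
            corr = np.nan_to_num(np.corrcoef(data), nan=0.0)
            cosines = np.clip(pos @ pos[good].T, -1.0, 1.0)
            for c in range(data.shape[0]):
                dist = np.arccos(cosines[c])
                dist[good == c] = np.inf
                nb = good[np.argsort(dist)[:k_neighbors]]
                if np.mean(np.abs(corr[c, nb])) < neighbor_corr:
                    bad.add(names[c])
    return bad


# ---------------------------------------------------------------------------
# spherical-spline interpolation


def _g_matrix(cosang: np.ndarray, order: int, n_legendre: int) -> np.ndarray:
    """Legendre-series g-function of the spherical spline."""
    n = np.arange(1, n_legendre + 1)
    coeffs = np.zeros(n_legendre + 1)
    coeffs[1:] = (2 * n + 1) / (n**order * (n + 1) ** order)
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolation_matrix(montage: Montage, bad: set[str] | list[str],
                         order: int = 4, n_legendre: int = 50,
                         lam: float = 1e-5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear operator mapping good-channel values to bad-channel estimates.

    Solves the regularized spherical-spline system on the good channels and
    evaluates the spline at the bad positions; returns ``(W, good_idx,
    bad_idx)`` with ``v_bad = W @ v_good``.
    """
    names = montage.names
    bad = set(bad)
    unknown = bad - set(names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    bad_idx = np.array([i for i, n in enumerate(names) if n in bad], dtype=int)
    good_idx = np.array([i for i, n in enumerate(names) if n not in bad], dtype=int)
    if len(good_idx) < 4:
        raise ValueError("spherical-spline interpolation needs >= 4 good channels")
    pos = montage.positions
    G = _g_matrix(pos[good_idx] @ pos[good_idx].T, order, n_legendre)
    Gb = _g_matrix(pos[bad_idx] @ pos[good_idx].T, order, n_legendre)
    ng = len(good_idx)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + lam * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular spherical-spline system (condition number {cond:.3g})")
    # v_bad = [Gb, 1] @ A^{-1}[:, :ng] @ v_good
    W = np.hstack([Gb, np.ones((len(bad_idx), 1))]) @ np.linalg.solve(
        A, np.eye(ng + 1)[:, :ng])
    return W, good_idx, bad_idx


def spherical_spline_interpolate(topography: np.ndarray, montage: Montage,
                                 bad: set[str] | list[str], order: int = 4,
                                 n_legendre: int = 50,
                                 lam: float = 1e-5) -> np.ndarray:
    """Replace bad-channel values of one topography by the spline estimate.

    Good channels are returned unchanged; an empty bad set is the identity.
    Works on a single topography (shape C) or a stack (shape C x T).
    """
    topo = np.array(topography, dtype=float)
    if not bad:
        return topo
    W, good_idx, bad_idx = interpolation_matrix(montage, bad, order, n_legendre, lam)
    topo[bad_idx] = W @ topo[good_idx]
    return topo


# ---------------------------------------------------------------------------
# epoch-level repair and rejection


def _faster_stats(ep: np.ndarray) -> np.ndarray:
    """Per-channel statistics of one epoch: variance, median gradient,
    amplitude range, deviation from the across-channel mean amplitude."""
    var = ep.var(axis=1)
    med_grad = np.median(np.abs(np.diff(ep, axis=1)), axis=1)
    amp_range = ep.max(axis=1) - ep.min(axis=1)
    chan_mean = ep.mean(axis=1)
    deviation = np.abs(chan_mean - chan_mean.mean())
    return np.stack([var, med_grad, amp_range, deviation])


def _zscore_channels(stat: np.ndarray) -> np.ndarray:
    sd = stat.std(axis=-1, keepdims=True, ddof=0)
    sd[sd == 0] = np.inf  # identical channels: all z = 0
    return (stat - stat.mean(axis=-1, keepdims=True)) / sd


def faster_local_channels(epoched: EpochedRecording, z: float = 3.0,
                          max_fraction: float = 0.25, order: int = 4,
                          n_legendre: int = 50, lam: float = 1e-5
                          ) -> EpochedRecording:
    """Per-epoch local-channel repair.

    Within each epoch the four channel statistics are z-scored across
    channels; any channel with any |z| > ``z`` is replaced in that epoch by
    spherical-spline interpolation from the remaining channels.  If more
    than ``max_fraction`` of channels are flagged, the epoch is marked
    rejected instead of over-interpolated.  Modifies epoch data in place
    on a copy and records the per-epoch interpolated channel sets.
    """
    data = epoched.data.copy()
    names = epoched.montage.names
    rejected = epoched.rejected.copy()
    interpolated: list[set[str]] = []
    for e in range(epoched.n_epochs):
        zs = np.abs(_zscore_channels(_faster_stats(data[e])))
        flagged = np.flatnonzero((zs > z).any(axis=0))
        flagged_names = {names[c] for c in flagged}
        if len(flagged) > max_fraction * data.shape[1]:
            rejected[e] = True
            interpolated.append(set())
            continue
        if flagged.size:
            W, good_idx, bad_idx = interpolation_matrix(
                epoched.montage, flagged_names, order, n_legendre, lam)
            data[e, bad_idx] = W @ data[e, good_idx]
        interpolated.append(flagged_names)
    return EpochedRecording(data=data, fs=epoched.fs, montage=epoched.montage,
                            epoch_len_s=epoched.epoch_len_s, rejected=rejected,
                            interpolated=interpolated)


def _nll_kde(values: np.ndarray) -> np.ndarray:
    """Negative log kernel-density of each value under the sample's KDE."""
    if np.ptp(values) == 0:
        return np.zeros_like(values)
    kde = sst.gaussian_kde(values)
    dens = np.maximum(kde(values), 1e-300)
    return -np.log(dens)


def reject_segments(epoched: EpochedRecording, amp_uv: float = 100.0,
                    prob_sd: float = 3.0) -> np.ndarray:
    """Epoch rejection flags from amplitude and probability criteria.

    An epoch is rejected when (a) any channel sample exceeds +-``amp_uv``,
    (b) any channel's kernel-density negative log-likelihood of its
    per-epoch mean amplitude is more than ``prob_sd`` SD above the
    across-epoch mean (single-electrode probability), or (c) the same
    statistic on the across-channel epoch means (electrode-group
    probability).  Raises if every epoch would be rejected.
    """
    data = epoched.data
    flags = np.abs(data).max(axis=(1, 2)) > amp_uv

    epoch_chan_means = data.mean(axis=2)  # epochs x channels
    for c in range(data.shape[1]):
        nll = _nll_kde(epoch_chan_means[:, c])
        zs = _zscore_channels(nll[None, :])[0]
        flags |= zs > prob_sd
    group = epoch_chan_means.mean(axis=1)
    zs = _zscore_channels(_nll_kde(group)[None, :])[0]
    flags |= zs > prob_sd

    if flags.all():
        raise ValueError(
            f"all {len(flags)} epochs rejected (amp_uv={amp_uv}, "
            f"prob_sd={prob_sd}); inspect the recording")
    return flags


# ---------------------------------------------------------------------------
# the full chain


def clean(recording: Recording, epoch_len_s: float = 2.0, low_hz: float = 1.0,
          high_hz: float = 40.0, target_hz: float = 250.0,
          flat_s: float = 5.0, neighbor_corr: float = 0.8, amp_sd: float = 3.0,
          faster_z: float = 3.0, amp_uv: float = 100.0, prob_sd: float = 3.0,
          artifact_hook: Callable[[Recording], Recording] | None = None,
          use_neighbors: bool = True) -> tuple[Recording, dict]:
    """Run the full cleaning chain and return (clean recording, report).

    Order: band-pass -> whole-recording bad channels -> artifact hook ->
    epoch -> local-channel repair -> segment rejection -> merge -> global
    bad-channel interpolation -> average reference -> downsample.  The
    amplitude rejection therefore acts *after* local-channel interpolation.
    Deterministic: identical inputs give identical outputs.
    """
    rec = bandpass_fir(recording, low_hz, high_hz)
    bads = detect_bad_channels(rec, flat_s, neighbor_corr, amp_sd,
                               use_neighbors=use_neighbors)
    if len(bads) > 0.25 * rec.n_channels:
        raise ValueError(
            f"{len(bads)}/{rec.n_channels} channels flagged bad "
            f"({sorted(bads)[:8]}...); refusing to interpolate more than 25%")
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    epoched = epoch(rec, epoch_len_s)
    epoched = faster_local_channels(epoched, faster_z)
    epoched.rejected |= reject_segments(epoched, amp_uv, prob_sd)
    merged = merge_epochs(epoched)
    if bads:
        merged = merged.copy_with(
            data=spherical_spline_interpolate(merged.data, merged.montage, bads))
    merged.bad_channels = set(bads)
    merged = average_reference(merged)
    merged = resample(merged, target_hz)
    report = {
        "bad_channels": sorted(bads),
        "n_epochs": int(epoched.n_epochs),
        "n_epochs_rejected": int(epoched.rejected.sum()),
        "interpolated_per_epoch": [sorted(s) for s in epoched.interpolated],
        "thresholds": {
            "low_hz": low_hz, "high_hz": high_hz, "epoch_len_s": epoch_len_s,
            "flat_s": flat_s, "neighbor_corr": neighbor_corr, "amp_sd": amp_sd,
            "faster_z": faster_z, "amp_uv": amp_uv, "prob_sd": prob_sd,
            "target_hz": target_hz,
        },
    }
    return merged, report
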