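"""Temporal microstate parameters: coverage, mean duration, occurrence.

All three are derived from the run-length structure of a backfitted label
sequence.  Boundary (possibly truncated) runs are counted in full, which
makes the identity

    coverage_k == occurrence_k * mean_duration_k / 1000

hold exactly for every class present in the sequence.  Dropping boundary
runs is available via ``include_boundary_runs=False`` but breaks that
identity and is off by default.  A class that never occurs has coverage 0,
occurrence 0 and a *missing* duration (NaN), never a zero duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .microstates import LabelSequence

PARAMETER_NAMES = ("coverage", "duration", "occurrence")


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence -> (run labels, run lengths)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def _coerce(labels: LabelSequence | np.ndarray) -> np.ndarray:
    return labels.labels if isinstance(labels, LabelSequence) else np.asarray(labels)


def coverage(labels: LabelSequence | np.ndarray, n_classes: int) -> np.ndarray:
    """Fraction of samples spent in each class; sums to 1 exactly."""
    lab = _coerce(labels)
    if lab.size == 0:
        raise ValueError("empty label sequence")
    return np.bincount(lab, minlength=n_classes) / lab.size


def mean_duration(labels: LabelSequence | np.ndarray, fs: float, n_classes: int,
                  include_boundary_runs: bool = True) -> np.ndarray:
    """Mean contiguous dwell per visit, in ms; NaN for absent classes."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    lab = _coerce(labels)
    rlab, rlen = run_lengths(lab)
    if not include_boundary_runs and len(rlab) > 2:
        rlab, rlen = rlab[1:-1], rlen[1:-1]
    out = np.full(n_classes, np.nan)
    counts = np.bincount(rlab, minlength=n_classes)
    sums = np.bincount(rlab, weights=rlen, minlength=n_classes)
    present = counts > 0
    out[present] = sums[present] / counts[present] / fs * 1000.0
    return out


def occurrence(labels: LabelSequence | np.ndarray, fs: float, n_classes: int,
               include_boundary_runs: bool = True) -> np.ndarray:
    """Visits per second for each class (0 for absent classes)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    lab = _coerce(labels)
    rlab, rlen = run_lengths(lab)
    if not include_boundary_runs and len(rlab) > 2:
        rlab = rlab[1:-1]
    duration_s = lab.size / fs
    return np.bincount(rlab, minlength=n_classes) / duration_s


def sequence_parameters(labels: LabelSequence | np.ndarray, fs: float,
                        n_classes: int) -> pd.DataFrame:
    """All three parameters of one sequence as a class-indexed frame."""
    return pd.DataFrame({
        "coverage": coverage(labels, n_classes),
        "duration": mean_duration(labels, fs, n_classes),
        "occurrence": occurrence(labels, fs, n_classes),
    }).rename_axis("class")


def parameter_table(sequences: dict[tuple, LabelSequence | np.ndarray], fs: float,
                    n_classes: int) -> pd.DataFrame:
    """Tidy parameter table over many sequences.

    ``sequences`` maps (subject, stage, session) keys to label sequences.
    Returns one row per (subject, stage, session, class) with the three
    parameter columns — the bridge from EEG to the statistics layer.
    """
    rows = []
    for (subject, stage, session), lab in sequences.items():
        f = getattr(lab, "fs", fs)
        p = sequence_parameters(lab, f, n_classes).reset_index()
        p.insert(0, "subject", subject)
        p.insert(1, "stage", stage)
        p.insert(2, "session", session)
        rows.append(p)
    return pd.concat(rows, ignore_index=True)


def summarize(table: pd.DataFrame, level: str = "stage") -> pd.DataFrame:
    """Average sessions within subject x stage x class.

    Unweighted mean across sessions; missing durations (absent classes) are
    excluded pairwise, with ``n_sessions`` reporting how many sessions
    contributed to each cell.  A subject x stage cell with no sessions at
    all is an error — the downstream ANOVA admits no missing cells.
    """
    if level != "stage":
        raise ValueError("only stage-level summaries are defined")
    required = {"subject", "stage", "session", "class", *PARAMETER_NAMES}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns {sorted(missing)}")
    grouped = table.groupby(["subject", "stage", "class"], sort=True)
    out = grouped[list(PARAMETER_NAMES)].mean()
    out["n_sessions"] = grouped["session"].nunique()
    if (out["n_sessions"] == 0).any():
        raise ValueError("subject x stage cell with zero sessions")
    return out.reset_index()
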