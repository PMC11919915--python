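"""Sensor montages: channel names and unit-sphere positions.

A montage is the geometric side of a recording: every channel has a name and
a 3D position normalized onto the unit sphere.  Positions drive the
neighbor-correlation bad-channel rule and spherical-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Montage:
    """Channel names plus unit-sphere 3D positions.

    Parameters
    ----------
    names : tuple of str
        Unique channel names, in data row order.
    positions : ndarray, shape (n_channels, 3)
        Cartesian positions; normalized to unit norm on construction.
    """

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(names)} channels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0):
            raise ValueError("montage positions must be nonzero")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "positions", pos / norms[:, None])

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def nearest_neighbors(self, k: int = 4) -> dict[int, np.ndarray]:
        """Indices of the ``k`` nearest channels by great-circle distance."""
        cosines = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        dist = np.arccos(cosines)
        np.fill_diagonal(dist, np.inf)
        order = np.argsort(dist, axis=1)
        return {i: order[i, :k] for i in range(len(self))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.positions, columns=["x", "y", "z"], index=list(self.names)
        ).rename_axis("name")


def biosemi64_montage() -> Montage:
    """The standard 64-channel BioSemi cap (10-20 extended layout)."""
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    pos = std.get_positions()["ch_pos"]
    names = tuple(std.ch_names)
    return Montage(names, np.array([pos[n] for n in names]))


def synthetic_montage(n_channels: int, cap_fraction: float = 2.0 / 3.0) -> Montage:
    """Evenly spread synthetic cap for desk-scale tests.

    Places ``n_channels`` points on the upper ``cap_fraction`` of the unit
    sphere with a Fibonacci lattice — a scalp-like coverage for montages of
    any size, used when a test does not need a named standard layout.
    ``cap_fraction=1`` covers the full sphere (a geometry with homogeneous
    channel density, useful for isolating rule logic from edge effects).
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if not 0 < cap_fraction <= 1:
        raise ValueError("cap_fraction must be in (0, 1]")
    i = np.arange(n_channels)
    z = 1.0 - 2.0 * cap_fraction * (i + 0.5) / n_channels
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    pos = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    names = tuple(f"S{j:03d}" for j in range(n_channels))
    return Montage(names, pos)


def read_montage_csv(path) -> Montage:
    """Read a plain-text montage table with columns name, x, y, z."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"montage file {path} must have columns {sorted(required)}")
    return Montage(tuple(df["name"].astype(str)), df[["x", "y", "z"]].to_numpy(float))


def write_montage_csv(montage: Montage, path) -> None:
    montage.to_frame().reset_index().to_csv(path, index=False)
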