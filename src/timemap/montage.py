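"""Electrode montages on the unit sphere.

The original recordings used a 192-channel BioSemi cap whose geometry is not
tabulated anywhere public, so the default montage is a synthetic equidistant
spherical layout (spiral / Fibonacci construction) restricted to the upper
part of the head.  Positions are unit vectors; physical head models scale
them to the scalp radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "spherical_montage", "read_montage", "write_montage"]


@dataclass(frozen=True)
class Montage:
    """Labelled electrode positions on the unit sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels and positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0):
            raise ValueError("zero-length electrode position")
        object.__setattr__(self, "positions", pos / norms[:, None])

    @property
    def n_channels(self) -> int:
        return len(self.labels)


def spherical_montage(n_channels: int = 192, coverage: float = 0.75) -> Montage:
    """Equidistant spherical cap layout.

    Electrodes are placed on a Fibonacci spiral over the upper ``coverage``
    fraction of the sphere (z from 1 down to 1 - 2*coverage), mimicking a
    high-density EEG cap that leaves the lower face/neck uncovered.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    i = np.arange(n_channels)
    # golden-angle spiral, z descending from vertex
    z = 1.0 - (2.0 * coverage) * (i + 0.5) / n_channels
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = tuple(f"E{k + 1:03d}" for k in i)
    return Montage(labels, pos)


def write_montage(montage: Montage, path) -> None:
    """Write ``label x y z`` per line (plain-text electrode file)."""
    with open(path, "w") as fh:
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{p[0]:.8f}\t{p[1]:.8f}\t{p[2]:.8f}\n")


def read_montage(path) -> Montage:
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed montage line: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return Montage(tuple(labels), np.asarray(rows))
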