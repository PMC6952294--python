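"""Boundary-aware S6 lattice distance (CS6Dist) and distance matrices.

The distance between two lattices is computed in the Selling (S6)
representation.  Both cells are Selling-reduced; the distance is the
minimum Euclidean distance between one reduced vector and the images of
the other under a fixed stack of unimodular S6 matrices (the 24
coordinate permutations composed with reflection-glued boundary
exchange operators), minimized symmetrically over both argument orders.

Calibration of the reported scale
---------------------------------
Raw S6 Euclidean distances carry A^2 units.  The reference CS6Dist
convention reports distances on an angstrom-like scale; calibrating
against the reference implementation's published distances for cells in
the 57 A size range pins the conversion to

    reported = 0.1 * sqrt(raw S6 Euclidean distance in A^2)

together with the candidate image stack in ``_s6ops.CANDIDATES``
({I} u {R_i o M_jv, i != j} composed with the 24 permutations; plain
one-exchange images excluded -- they are not isometries and undershoot
the reference values).  The raw A^2 value is always available via
``cs6dist_raw``.  See docs/methods.md for the full calibration record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import math

import numpy as np

from ._s6ops import CANDIDATES
from .cells import UnitCell, reduced_s6

__all__ = [
    "DistanceMatrix",
    "cs6dist",
    "cs6dist_raw",
    "distance_matrix",
    "METRICS",
]


def _images(s: np.ndarray) -> np.ndarray:
    """All candidate images of a reduced S6 vector (stack of shape (m, 6))."""
    return CANDIDATES @ s


def _raw_from_reduced(sx: np.ndarray, sy: np.ndarray) -> float:
    dx = np.linalg.norm(_images(sy) - sx, axis=1).min()
    dy = np.linalg.norm(_images(sx) - sy, axis=1).min()
    return float(min(dx, dy))


def cs6dist_raw(x: UnitCell, y: UnitCell) -> float:
    """CS6Dist between two (primitive) cells on the raw A^2 scale."""
    return _raw_from_reduced(reduced_s6(x), reduced_s6(y))


def cs6dist(x: UnitCell, y: UnitCell) -> float:
    """CS6Dist between two (primitive) cells on the calibrated reporting
    scale (0.1 * sqrt of the raw A^2 distance)."""
    return 0.1 * math.sqrt(cs6dist_raw(x, y))


def _calibrate(raw: float) -> float:
    return 0.1 * math.sqrt(max(raw, 0.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with item labels."""

    d: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not self.labels:
            self.labels = [str(i) for i in range(self.d.shape[0])]
        if len(self.labels) != self.d.shape[0]:
            raise ValueError("label count must match matrix size")
        self.validate()

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.d, self.d.T, atol=atol):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=atol):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.d < -atol).any():
            raise ValueError("distances must be non-negative")

    def submatrix(self, indices: Sequence[int]) -> "DistanceMatrix":
        idx = list(indices)
        return DistanceMatrix(self.d[np.ix_(idx, idx)], [self.labels[i] for i in idx])

    def condensed(self) -> np.ndarray:
        """Condensed upper-triangle form (scipy convention)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def write_square_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id"] + self.labels)
            for label, row in zip(self.labels, self.d):
                writer.writerow([label] + [f"{x:.6f}" for x in row])

    def write_flat_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id_i", "id_j", "distance"])
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    writer.writerow([self.labels[i], self.labels[j], f"{self.d[i, j]:.6f}"])

    @classmethod
    def read_square_csv(cls, path: str | Path) -> "DistanceMatrix":
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        labels = rows[0][1:]
        d = np.array([[float(x) for x in row[1:]] for row in rows[1:]])
        return cls(d, labels)


def _cs6_matrix(cells: Sequence[UnitCell], calibrated: bool) -> np.ndarray:
    reduced = [reduced_s6(c) for c in cells]
    images = [_images(s) for s in reduced]
    n = len(cells)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = min(
                float(np.linalg.norm(images[j] - reduced[i], axis=1).min()),
                float(np.linalg.norm(images[i] - reduced[j], axis=1).min()),
            )
            d[i, j] = d[j, i] = _calibrate(raw) if calibrated else raw
    return d


METRICS: dict[str, Callable] = {
    "cs6dist": lambda cells: _cs6_matrix(cells, calibrated=True),
    "cs6dist_raw": lambda cells: _cs6_matrix(cells, calibrated=False),
}


def distance_matrix(
    cells: Sequence[UnitCell],
    metric: str = "cs6dist",
    labels: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix over a list of primitive cells.

    ``metric`` is one of ``cs6dist`` (calibrated scale, default) or
    ``cs6dist_raw`` (A^2 scale).
    """
    if len(cells) < 2:
        raise ValueError("distance_matrix needs at least 2 cells")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    label_list = list(labels) if labels is not None else [str(i) for i in range(len(cells))]
    if len(label_list) != len(cells):
        raise ValueError("label count must match cell count")
    try:
        d = METRICS[metric](cells)
    except Exception as exc:  # identify the offending pair for diagnostics
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                try:
                    cs6dist_raw(cells[i], cells[j])
                except Exception:
                    raise RuntimeError(
                        f"distance computation failed for pair "
                        f"({label_list[i]}, {label_list[j]})"
                    ) from exc
        raise
    return DistanceMatrix(d, label_list)
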