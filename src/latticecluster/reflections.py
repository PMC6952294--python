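"""Reflection-set handling for second-stage (intensity-CC) clustering.

Covers per-image reflection lists (h, k, l, I, sigma), spot-count
filtering, inverse-variance merging, triclinic Friedel-unique
completeness, Pearson correlation between intensity sets, and the
CC-derived distance matrix.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cells import UnitCell, cell_basis
from .metrics import DistanceMatrix, cs6dist

__all__ = [
    "ReflectionSet",
    "ImageRecord",
    "spot_filter",
    "merge",
    "completeness",
    "pearson_cc",
    "cc_distance_matrix",
    "unique_reflections",
    "read_reflections",
    "write_reflections",
    "read_manifest",
    "write_manifest",
]

#: default minimum number of common reflections for a defined CC
MIN_COMMON_DEFAULT = 20

#: default compatibility threshold (calibrated cs6dist) for merging
MERGE_COMPATIBILITY_DEFAULT = 2.0


@dataclass
class ReflectionSet:
    """Unique-reflection records (h, k, l, intensity, sigma) with their cell."""

    hkl: np.ndarray          # (n, 3) integer Miller indices
    intensity: np.ndarray    # (n,)
    sigma: np.ndarray        # (n,) > 0
    cell: UnitCell
    d_min: float

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1)
        n = len(self.hkl)
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ValueError("hkl, intensity, sigma must have equal lengths")
        if n and (self.sigma <= 0).any():
            raise ValueError("all sigmas must be > 0")
        if n:
            keys = {tuple(row) for row in self.hkl}
            if len(keys) != n:
                raise ValueError("duplicate (h,k,l) records; merge first")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        if n:
            d = resolutions(self.cell, self.hkl)
            if (d < self.d_min - 1e-6).any():
                raise ValueError("records beyond the d_min resolution limit")

    def __len__(self) -> int:
        return len(self.hkl)

    def as_dict(self) -> dict[tuple[int, int, int], tuple[float, float]]:
        return {
            tuple(h): (float(i), float(s))
            for h, i, s in zip(self.hkl, self.intensity, self.sigma)
        }


@dataclass
class ImageRecord:
    """One serial-crystallography image (or small wedge)."""

    id: str
    spot_count: int
    cell: UnitCell | None = None
    reflections: ReflectionSet | None = None

    def __post_init__(self):
        if self.spot_count < 0:
            raise ValueError("spot_count must be non-negative")


# ---------------------------------------------------------------------------
# resolution machinery


def reciprocal_metric(cell: UnitCell) -> np.ndarray:
    basis = cell_basis(cell)
    g = basis @ basis.T
    return np.linalg.inv(g)


def resolutions(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """d-spacings (angstrom) of Miller indices for a cell."""
    gstar = reciprocal_metric(cell)
    hkl = np.asarray(hkl, dtype=float)
    q2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl)
    return 1.0 / np.sqrt(np.maximum(q2, 1e-300))


def unique_reflections(cell: UnitCell, d_min: float) -> np.ndarray:
    """All triclinic Friedel-unique Miller indices with d >= d_min.

    One representative per Friedel pair (h > 0, or h = 0 and k > 0, or
    h = k = 0 and l > 0); consistent with clustering in P1.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    hmax = [int(math.ceil(edge / d_min)) + 1 for edge in (cell.a, cell.b, cell.c)]
    rng_h = np.arange(-hmax[0], hmax[0] + 1)
    rng_k = np.arange(-hmax[1], hmax[1] + 1)
    rng_l = np.arange(-hmax[2], hmax[2] + 1)
    grid = np.array(np.meshgrid(rng_h, rng_k, rng_l, indexing="ij")).reshape(3, -1).T
    h, k, l = grid[:, 0], grid[:, 1], grid[:, 2]
    friedel = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    grid = grid[friedel]
    d = resolutions(cell, grid)
    return grid[d >= d_min - 1e-9]


def completeness(rs: ReflectionSet, d_min: float) -> float:
    """Observed fraction of theoretical triclinic Friedel-unique
    reflections with d >= d_min."""
    theoretical = unique_reflections(rs.cell, d_min)
    if len(theoretical) == 0:
        raise ValueError(f"no theoretical reflections to d_min={d_min}; undefined")
    if len(rs) == 0:
        return 0.0
    d = resolutions(rs.cell, rs.hkl)
    observed = {tuple(_friedel_canonical(h)) for h, di in zip(rs.hkl, d) if di >= d_min - 1e-9}
    theo = {tuple(h) for h in theoretical}
    return len(observed & theo) / len(theo)


def _friedel_canonical(h) -> tuple[int, int, int]:
    h = tuple(int(x) for x in h)
    if h > (0, 0, 0) and (h[0] > 0 or (h[0] == 0 and h[1] > 0) or (h[0] == 0 and h[1] == 0 and h[2] > 0)):
        return h
    return (-h[0], -h[1], -h[2])


# ---------------------------------------------------------------------------
# operations


def spot_filter(
    images: Sequence[ImageRecord], min_spots: int
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Partition images into (kept, discarded).

    Discarded = spot_count below threshold OR no indexing solution (no
    cell); this is the paper's "discard cluster" of bad images.
    """
    if min_spots < 0:
        raise ValueError("min_spots must be >= 0")
    kept, discarded = [], []
    for img in images:
        if img.cell is None or img.spot_count < min_spots:
            discarded.append(img)
        else:
            kept.append(img)
    return kept, discarded


def merge(
    sets: Sequence[ReflectionSet],
    compatibility: float | None = MERGE_COMPATIBILITY_DEFAULT,
) -> ReflectionSet:
    """Inverse-variance weighted merge of reflection sets.

    Per unique (h,k,l): I = sum(I_i / s_i^2) / sum(1 / s_i^2) and
    sigma = (sum 1/s_i^2)^(-1/2).  The merged set carries the min-sum
    medoid cell of the inputs.  ``compatibility`` is the maximum allowed
    pairwise cs6dist between input cells (pass None to skip the check
    when the caller has already clustered by lattice).
    """
    if not sets:
        raise ValueError("merge needs at least one reflection set")
    if compatibility is not None and len(sets) > 1:
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                d = cs6dist(sets[i].cell, sets[j].cell)
                if d > compatibility:
                    raise ValueError(
                        f"incompatible cells for merge: sets {i} and {j} "
                        f"are {d:.3f} apart (limit {compatibility})"
                    )
    acc: dict[tuple[int, int, int], tuple[float, float]] = {}
    for rs in sets:
        for h, inten, sig in zip(rs.hkl, rs.intensity, rs.sigma):
            key = tuple(int(x) for x in h)
            w = 1.0 / (sig * sig)
            wi, ww = acc.get(key, (0.0, 0.0))
            acc[key] = (wi + w * inten, ww + w)
    if len(sets) == 1:
        cell = sets[0].cell
    else:
        cells = [rs.cell for rs in sets]
        sums = [
            sum(cs6dist(ci, cj) for j, cj in enumerate(cells) if j != i)
            for i, ci in enumerate(cells)
        ]
        cell = cells[int(np.argmin(sums))]
    keys = sorted(acc)
    hkl = np.array(keys, dtype=int).reshape(-1, 3)
    intensity = np.array([acc[k][0] / acc[k][1] for k in keys])
    sigma = np.array([1.0 / math.sqrt(acc[k][1]) for k in keys])
    d_min = min(rs.d_min for rs in sets)
    return ReflectionSet(hkl, intensity, sigma, cell, d_min)


def pearson_cc(
    a: ReflectionSet, b: ReflectionSet, min_common: int = MIN_COMMON_DEFAULT
) -> tuple[float | None, int]:
    """Pearson correlation of intensities over the common (h,k,l) set.

    Returns (cc, n_common); cc is None (undefined) when fewer than
    ``min_common`` reflections are shared or either side has zero
    variance.
    """
    da, db = a.as_dict(), b.as_dict()
    common = sorted(set(da) & set(db))
    n_common = len(common)
    if n_common < max(min_common, 2):
        return None, n_common
    x = np.array([da[h][0] for h in common])
    y = np.array([db[h][0] for h in common])
    sx, sy = x.std(), y.std()
    if sx <= 0 or sy <= 0:
        return None, n_common
    cc = float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1.0, 1.0))
    return cc, n_common


def cc_distance_matrix(
    sets: Sequence[ReflectionSet],
    min_common: int = MIN_COMMON_DEFAULT,
    labels: Sequence[str] | None = None,
) -> tuple[DistanceMatrix, list[tuple[int, int]]]:
    """CC-derived distance matrix: d = sqrt(1 - cc).

    Pairs with undefined CC are set to the maximum defined distance (or
    sqrt(2) if none is defined) and returned in the flagged list.
    sqrt(1 - cc) is zero for identical sets and sqrt(2) for perfectly
    anti-correlated ones; it is not guaranteed to satisfy the triangle
    inequality.
    """
    n = len(sets)
    if n < 2:
        raise ValueError("cc_distance_matrix needs at least 2 sets")
    d = np.zeros((n, n))
    undefined: list[tuple[int, int]] = []
    max_defined = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            cc, _ = pearson_cc(sets[i], sets[j], min_common)
            if cc is None:
                undefined.append((i, j))
                d[i, j] = d[j, i] = math.nan
            else:
                val = math.sqrt(max(0.0, 1.0 - cc))
                d[i, j] = d[j, i] = val
                max_defined = max(max_defined, val)
    fill = max_defined if max_defined > 0 else math.sqrt(2.0)
    for i, j in undefined:
        d[i, j] = d[j, i] = fill
    label_list = list(labels) if labels is not None else [str(i) for i in range(n)]
    return DistanceMatrix(d, label_list), undefined


# ---------------------------------------------------------------------------
# file I/O


def read_reflections(path: str | Path, cell: UnitCell, d_min: float) -> ReflectionSet:
    """Read a whitespace/CSV reflection file: ``h k l I sigI`` per line,
    '#' comments ignored."""
    path = Path(path)
    hkl, inten, sig = [], [], []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 5:
                raise ValueError(f"{path}: expected 'h k l I sigI', got {line!r}")
            hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
            inten.append(float(parts[3]))
            sig.append(float(parts[4]))
    return ReflectionSet(np.array(hkl or np.empty((0, 3))), np.array(inten),
                         np.array(sig), cell, d_min)


def write_reflections(path: str | Path, rs: ReflectionSet) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# h k l I sigI\n")
        order = np.lexsort((rs.hkl[:, 2], rs.hkl[:, 1], rs.hkl[:, 0]))
        for idx in order:
            h, k, l = rs.hkl[idx]
            fh.write(f"{h} {k} {l} {rs.intensity[idx]:.6f} {rs.sigma[idx]:.6f}\n")


MANIFEST_COLUMNS = [
    "id", "a", "b", "c", "alpha", "beta", "gamma",
    "centering", "reflection_file", "spot_count",
]


def write_manifest(path: str | Path, images: Sequence[ImageRecord],
                   d_min: float) -> Path:
    """Write a manifest CSV plus per-image reflection files next to it."""
    path = Path(path)
    directory = path.parent
    directory.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS + ["d_min"])
        for img in images:
            if img.cell is not None:
                cell_fields = [f"{x:.6f}" for x in img.cell.parameters()]
            else:
                cell_fields = [""] * 6
            refl_file = ""
            if img.reflections is not None:
                refl_file = f"{img.id}.hkl"
                write_reflections(directory / refl_file, img.reflections)
            writer.writerow([img.id] + cell_fields + ["P", refl_file,
                                                      img.spot_count, f"{d_min:.6f}"])
    return path


def read_manifest(path: str | Path) -> list[ImageRecord]:
    """Read a manifest CSV (see :func:`write_manifest`) and its
    referenced reflection files."""
    path = Path(path)
    directory = path.parent
    images: list[ImageRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.lstrip().startswith("#"))
        for rec in reader:
            cell = None
            if rec["a"]:
                cell = UnitCell(*(float(rec[k]) for k in
                                  ("a", "b", "c", "alpha", "beta", "gamma")))
            reflections = None
            if rec.get("reflection_file") and cell is not None:
                d_min = float(rec.get("d_min") or 0.5)
                reflections = read_reflections(directory / rec["reflection_file"],
                                               cell, d_min)
            images.append(ImageRecord(rec["id"], int(rec["spot_count"]),
                                      cell, reflections))
    return images
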