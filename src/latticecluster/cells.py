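"""Unit-cell data model, centering transforms, and cell reductions.

Provides the core crystallographic plumbing:

* :class:`UnitCell`, :class:`CenteredCell`, :class:`G6Vector`,
  :class:`S6Vector`, :class:`ReducedCell` data types;
* ``primitive_from_centered`` -- conventional centered cell to primitive
  cell (P/A/B/C/I/F/R/H);
* ``niggli_reduce`` -- Krivy-Gruber Niggli reduction with accumulated
  determinant +1 integer transform;
* ``selling_reduce`` -- Selling/Delaunay reduction in S6 space;
* ``cell_to_s6`` / ``s6_to_cell`` -- the Selling embedding and inverse;
* ``read_cells`` -- CSV reader for cell lists.

Angles are degrees at every public interface and radians internally.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._s6ops import EXCHANGES

__all__ = [
    "UnitCell",
    "CenteredCell",
    "G6Vector",
    "S6Vector",
    "ReducedCell",
    "primitive_from_centered",
    "niggli_reduce",
    "selling_reduce",
    "cell_to_s6",
    "s6_to_cell",
    "cell_basis",
    "read_cells",
    "CellError",
    "ReductionError",
]

ITERATION_CAP = 1000

CENTERING_SYMBOLS = frozenset("PABCIFRH")


class CellError(ValueError):
    """Invalid cell parameters or centering symbol."""


class ReductionError(RuntimeError):
    """A reduction algorithm failed to converge within its iteration cap."""


@dataclass(frozen=True)
class UnitCell:
    """Six cell parameters: edges a, b, c in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise CellError(f"edge {name} must be > 0, got {getattr(self, name)}")
        ang = (self.alpha, self.beta, self.gamma)
        for name, v in zip(("alpha", "beta", "gamma"), ang):
            if not 0 < v < 180:
                raise CellError(f"angle {name} must be in (0, 180), got {v}")
        al, be, ga = ang
        if al + be + ga >= 360 - 1e-12:
            raise CellError("alpha + beta + gamma must be < 360")
        for name, v in zip(("alpha", "beta", "gamma"), ang):
            if v >= (al + be + ga) - v - 1e-12:
                raise CellError(f"angle {name} must be smaller than the sum of the other two")
        if not self.volume() > 0:
            raise CellError("cell volume must be strictly positive")

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    def g6(self) -> "G6Vector":
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return G6Vector(
            self.a ** 2, self.b ** 2, self.c ** 2,
            2.0 * self.b * self.c * ca,
            2.0 * self.a * self.c * cb,
            2.0 * self.a * self.b * cg,
        )

    def close_to(self, other: "UnitCell", tol_length: float = 1e-6,
                 tol_angle: float = 1e-4) -> bool:
        return (
            abs(self.a - other.a) <= tol_length
            and abs(self.b - other.b) <= tol_length
            and abs(self.c - other.c) <= tol_length
            and abs(self.alpha - other.alpha) <= tol_angle
            and abs(self.beta - other.beta) <= tol_angle
            and abs(self.gamma - other.gamma) <= tol_angle
        )


@dataclass(frozen=True)
class CenteredCell:
    """A conventional cell together with its lattice-centering symbol."""

    cell: UnitCell
    centering: str = "P"

    def __post_init__(self):
        sym = self.centering.upper()
        if sym not in CENTERING_SYMBOLS:
            raise CellError(
                f"unrecognized centering symbol {self.centering!r}; "
                f"expected one of {sorted(CENTERING_SYMBOLS)}"
            )
        object.__setattr__(self, "centering", sym)


@dataclass(frozen=True)
class G6Vector:
    """G6 embedding (a^2, b^2, c^2, 2bc cos(alpha), 2ac cos(beta), 2ab cos(gamma))."""

    g1: float
    g2: float
    g3: float
    g4: float
    g5: float
    g6: float

    def __post_init__(self):
        if min(self.g1, self.g2, self.g3) <= 0:
            raise CellError("g1, g2, g3 must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([self.g1, self.g2, self.g3, self.g4, self.g5, self.g6])


@dataclass(frozen=True)
class S6Vector:
    """Selling scalars (b.c, a.c, a.b, a.d, b.d, c.d), d = -(a+b+c), in A^2."""

    s1: float
    s2: float
    s3: float
    s4: float
    s5: float
    s6: float

    def __post_init__(self):
        a2, b2, c2 = self.implied_squared_edges()
        if min(a2, b2, c2) <= 0:
            raise CellError("S6 scalars imply a non-positive squared edge length")

    def implied_squared_edges(self) -> tuple[float, float, float]:
        return (
            -(self.s2 + self.s3 + self.s4),
            -(self.s1 + self.s3 + self.s5),
            -(self.s1 + self.s2 + self.s6),
        )

    def to_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4, self.s5, self.s6])

    @classmethod
    def from_array(cls, arr) -> "S6Vector":
        return cls(*(float(x) for x in arr))

    def is_reduced(self, eps: float = 1e-9) -> bool:
        return max(self.to_array()) <= eps


@dataclass(frozen=True)
class ReducedCell:
    """A Niggli-reduced cell plus the integer transform that produced it.

    ``transform`` is a 3x3 integer matrix of determinant +1; applying it
    to the rows of the input basis matrix yields a basis of the reduced
    cell.
    """

    cell: UnitCell
    transform: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.transform)
        if t.shape != (3, 3) or not np.allclose(t, np.round(t)):
            raise CellError("transform must be a 3x3 integer matrix")
        if not math.isclose(float(np.linalg.det(t)), 1.0, abs_tol=1e-9):
            raise CellError("transform determinant must be +1")
        object.__setattr__(self, "transform", np.round(t).astype(int))


# ---------------------------------------------------------------------------
# basis construction and conversions


def cell_basis(cell: UnitCell) -> np.ndarray:
    """Return a 3x3 matrix whose rows are the cell vectors in orthogonal
    coordinates (a along x, b in the xy plane)."""
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * math.cos(ga), b * math.sin(ga), 0.0])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz2 = c * c - cx * cx - cy * cy
    if cz2 <= 0:
        raise CellError("cell parameters do not define a 3D lattice")
    vc = np.array([cx, cy, math.sqrt(cz2)])
    return np.vstack([va, vb, vc])


def basis_to_cell(basis: np.ndarray) -> UnitCell:
    """Cell parameters of a row-vector basis matrix."""
    va, vb, vc = np.asarray(basis, dtype=float)
    a, b, c = (float(np.linalg.norm(v)) for v in (va, vb, vc))
    al = math.degrees(math.acos(float(vb @ vc) / (b * c)))
    be = math.degrees(math.acos(float(va @ vc) / (a * c)))
    ga = math.degrees(math.acos(float(va @ vb) / (a * b)))
    return UnitCell(a, b, c, al, be, ga)


def cell_to_s6(cell: UnitCell) -> S6Vector:
    """Selling embedding of a cell, computed from an explicit basis."""
    basis = cell_basis(cell)
    va, vb, vc = basis
    vd = -(va + vb + vc)
    return S6Vector(
        float(vb @ vc), float(va @ vc), float(va @ vb),
        float(va @ vd), float(vb @ vd), float(vc @ vd),
    )


def s6_to_cell(s: S6Vector | np.ndarray) -> UnitCell:
    """Inverse Selling embedding (raises CellError if not realizable)."""
    if not isinstance(s, S6Vector):
        s = S6Vector.from_array(np.asarray(s, dtype=float))
    a2, b2, c2 = s.implied_squared_edges()
    a, b, c = math.sqrt(a2), math.sqrt(b2), math.sqrt(c2)
    for value, denom, name in (
        (s.s1, b * c, "alpha"), (s.s2, a * c, "beta"), (s.s3, a * b, "gamma")
    ):
        if abs(value) >= denom:
            raise CellError(f"S6 scalars imply |cos({name})| >= 1")
    al = math.degrees(math.acos(s.s1 / (b * c)))
    be = math.degrees(math.acos(s.s2 / (a * c)))
    ga = math.degrees(math.acos(s.s3 / (a * b)))
    return UnitCell(a, b, c, al, be, ga)


# ---------------------------------------------------------------------------
# centered -> primitive

# Row transforms: primitive basis rows = M @ conventional basis rows.
# All have positive determinant equal to 1/(lattice points per cell).
_CENTERING_TRANSFORMS = {
    "P": np.eye(3),
    "A": np.array([[1.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.0, -0.5, 0.5]]),
    "B": np.array([[0.5, 0.0, 0.5], [0.0, 1.0, 0.0], [-0.5, 0.0, 0.5]]),
    "C": np.array([[0.5, 0.5, 0.0], [-0.5, 0.5, 0.0], [0.0, 0.0, 1.0]]),
    "I": np.array([[-0.5, 0.5, 0.5], [0.5, -0.5, 0.5], [0.5, 0.5, -0.5]]),
    "F": np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]),
    "R": np.eye(3),
    # obverse hexagonal setting of a rhombohedral lattice
    "H": np.array([
        [2.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [-1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [-1.0 / 3.0, -2.0 / 3.0, 1.0 / 3.0],
    ]),
}

#: lattice points per conventional cell (volume divisor)
CENTERING_DIVISOR = {"P": 1, "A": 2, "B": 2, "C": 2, "I": 2, "F": 4, "R": 1, "H": 3}


def _looks_hexagonal(cell: UnitCell) -> bool:
    return (
        abs(cell.gamma - 120.0) < 0.5
        and abs(cell.alpha - 90.0) < 0.5
        and abs(cell.beta - 90.0) < 0.5
    )


def primitive_from_centered(cc: CenteredCell) -> UnitCell:
    """Primitive cell of the lattice described by a centered conventional cell.

    The result is not reduced; chain with :func:`niggli_reduce`.
    ``R`` and ``H`` are disambiguated by the angle signature: a cell with
    alpha = beta = 90 and gamma = 120 is treated as the hexagonal setting
    of a rhombohedral lattice regardless of which of the two symbols was
    supplied (crystallographic usage mixes them).
    """
    sym = cc.centering
    if sym in ("R", "H"):
        sym = "H" if _looks_hexagonal(cc.cell) else "R"
    transform = _CENTERING_TRANSFORMS[sym]
    return basis_to_cell(transform @ cell_basis(cc.cell))


def parse_centering(token: str) -> str:
    """Centering symbol from a symbol or space-group string (leading letter)."""
    token = token.strip()
    if not token:
        return "P"
    sym = token[0].upper()
    if sym not in CENTERING_SYMBOLS:
        raise CellError(f"unrecognized centering symbol {token!r}")
    return sym


# ---------------------------------------------------------------------------
# Niggli reduction (Krivy & Gruber 1976)

_SWAP_AB = np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]])
_SWAP_BC = np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]])


def _g6_of_basis(basis: np.ndarray) -> tuple[float, float, float, float, float, float]:
    va, vb, vc = basis
    return (
        float(va @ va), float(vb @ vb), float(vc @ vc),
        2.0 * float(vb @ vc), 2.0 * float(va @ vc), 2.0 * float(va @ vb),
    )


def niggli_reduce(cell: UnitCell, eps: float | None = None) -> ReducedCell:
    """Niggli reduction by the Krivy-Gruber algorithm.

    ``eps`` is an absolute tolerance on the G6 components; the default is
    the relative tolerance 1e-5 * max(g1, g2, g3).  The returned
    :class:`ReducedCell` carries the accumulated determinant +1 integer
    transform from the input basis (rows) to the reduced basis.
    """
    basis = cell_basis(cell)
    total = np.eye(3, dtype=int)
    A, B, C, xi, eta, zeta = _g6_of_basis(basis)
    if eps is None:
        eps = 1e-5 * max(A, B, C)

    def apply(m: np.ndarray):
        nonlocal basis, total, A, B, C, xi, eta, zeta
        basis = m @ basis
        total = m @ total
        A, B, C, xi, eta, zeta = _g6_of_basis(basis)

    def gt(x, y):
        return x > y + eps

    def eq(x, y):
        return abs(x - y) <= eps

    for _ in range(ITERATION_CAP):
        # step 1: order A <= B
        if gt(A, B) or (eq(A, B) and gt(abs(xi), abs(eta))):
            apply(_SWAP_AB)
        # step 2: order B <= C (restart)
        if gt(B, C) or (eq(B, C) and gt(abs(eta), abs(zeta))):
            apply(_SWAP_BC)
            continue
        # sign classification
        l = 1 if xi > eps else (-1 if xi < -eps else 0)
        m_ = 1 if eta > eps else (-1 if eta < -eps else 0)
        n = 1 if zeta > eps else (-1 if zeta < -eps else 0)
        if l * m_ * n == 1:
            # step 3: make all three angle terms positive
            f = [1 if l >= 0 else -1, 1 if m_ >= 0 else -1, 1 if n >= 0 else -1]
            if f != [1, 1, 1]:
                apply(np.diag(f))
        else:
            # step 4: make all three angle terms non-positive
            f = [1, 1, 1]
            deferred = -1
            for idx, sgn in enumerate((l, m_, n)):
                if sgn > 0:
                    f[idx] = -1
                elif sgn == 0:
                    deferred = idx
            if f[0] * f[1] * f[2] < 0:
                if deferred < 0:
                    raise ReductionError("Niggli step 4 sign bookkeeping failed")
                f[deferred] = -1
            if f != [1, 1, 1]:
                apply(np.diag(f))
        # step 5
        if gt(abs(xi), B) or (eq(xi, B) and 2 * eta < zeta - eps) or \
                (eq(xi, -B) and zeta < -eps):
            s = 1 if xi > 0 else -1
            apply(np.array([[1, 0, 0], [0, 1, 0], [0, -s, 1]]))
            continue
        # step 6
        if gt(abs(eta), A) or (eq(eta, A) and 2 * xi < zeta - eps) or \
                (eq(eta, -A) and zeta < -eps):
            s = 1 if eta > 0 else -1
            apply(np.array([[1, 0, 0], [0, 1, 0], [-s, 0, 1]]))
            continue
        # step 7
        if gt(abs(zeta), A) or (eq(zeta, A) and 2 * xi < eta - eps) or \
                (eq(zeta, -A) and eta < -eps):
            s = 1 if zeta > 0 else -1
            apply(np.array([[1, 0, 0], [-s, 1, 0], [0, 0, 1]]))
            continue
        # step 8
        total_term = xi + eta + zeta + A + B
        if total_term < -eps or (eq(total_term, 0) and 2 * (A + eta) + zeta > eps):
            apply(np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]]))
            continue
        return ReducedCell(basis_to_cell(basis), total)
    raise ReductionError(
        f"Niggli reduction did not converge within {ITERATION_CAP} steps"
    )


# ---------------------------------------------------------------------------
# Selling reduction


def selling_reduce(s: S6Vector | np.ndarray, eps: float | None = None) -> S6Vector:
    """Selling (Delaunay) reduction: iterate boundary exchanges until all
    six scalars are <= eps.

    ``eps`` defaults to the relative tolerance 1e-9 * max(1, |s|_inf).
    """
    vec = s.to_array() if isinstance(s, S6Vector) else np.asarray(s, dtype=float).copy()
    if vec.shape != (6,):
        raise CellError("S6 vector must have six components")
    if eps is None:
        eps = 1e-9 * max(1.0, float(np.abs(vec).max()))
    for _ in range(ITERATION_CAP):
        i = int(np.argmax(vec))
        if vec[i] <= eps:
            return S6Vector.from_array(vec)
        vec = EXCHANGES[2 * i] @ vec
    raise ReductionError(
        f"Selling reduction did not converge within {ITERATION_CAP} steps"
    )


def reduced_s6(cell: UnitCell, eps: float | None = None) -> np.ndarray:
    """Selling-reduced S6 vector of a cell, as a plain array."""
    return selling_reduce(cell_to_s6(cell), eps).to_array()


# ---------------------------------------------------------------------------
# file input


def read_cells(path: str | Path) -> list[tuple[str, CenteredCell]]:
    """Read a cell list CSV: header ``id,a,b,c,alpha,beta,gamma,centering``.

    The centering column is optional (default P) and accepts either a
    one-letter centering symbol or a space-group string whose leading
    letter is used.  Lines starting with '#' are ignored.
    """
    path = Path(path)
    rows: list[tuple[str, CenteredCell]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.lstrip().startswith("#") and ln.strip()]
    reader = csv.DictReader(lines)
    required = {"id", "a", "b", "c", "alpha", "beta", "gamma"}
    if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
        raise CellError(
            f"cell list {path} must have columns {sorted(required)} (+ optional centering)"
        )
    for rec in reader:
        cell = UnitCell(*(float(rec[k]) for k in ("a", "b", "c", "alpha", "beta", "gamma")))
        centering = parse_centering(rec.get("centering") or "P")
        rows.append((rec["id"], CenteredCell(cell, centering)))
    return rows


def write_cells(path: str | Path, rows: Iterable[tuple[str, CenteredCell]]) -> None:
    """Write a cell list CSV in the format accepted by :func:`read_cells`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "a", "b", "c", "alpha", "beta", "gamma", "centering"])
        for ident, cc in rows:
            p = cc.cell.parameters()
            writer.writerow([ident] + [f"{x:.6f}" for x in p] + [cc.centering])
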