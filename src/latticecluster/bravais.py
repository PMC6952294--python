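"""Closest Bravais-lattice fitting in the Selling (S6) representation.

Each of the 14 Bravais characters is encoded as one or more exact linear
subspaces of S6 ("Delone sorts"): the Selling-reduced tetrad of a
lattice of a given character has dot products that are linear in a small
set of free parameters.  The sort forms used here were derived
symbolically from the conventional cells of each character (see
docs/methods.md for the explicit forms).

Fitting a character to a cell:

1. Selling-reduce the cell's S6 vector and enumerate its images under
   the 24 coordinate permutations and the boundary-exchange operators.
2. Orthogonally project each image onto each sort subspace; extract the
   character's conventional parameters from the projected vector.
3. Rebuild the fitted lattice from the extracted parameters and measure
   its distance to the input with the same CS6Dist metric used for
   clustering (rebuild-and-measure keeps reported distances honest even
   when a projection is slightly outside the character's validity
   region).
4. Polish the best candidate's free parameters with a small
   derivative-free minimization of the CS6Dist objective.

Because every higher-symmetry character is a special case of one or
more lower-symmetry characters, the fitted lattice of a specialization
is also a valid fit for the more general character; ``closest_bravais``
therefore takes the minimum over the character's own sorts and all its
specializations, which makes the symmetry hierarchy monotone by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._s6ops import CANDIDATES, EXCHANGES, P24_MATRICES
from .cells import (
    CellError,
    CenteredCell,
    UnitCell,
    primitive_from_centered,
    reduced_s6,
)

__all__ = ["BravaisFit", "closest_bravais", "best_bravais", "CHARACTERS"]

CHARACTERS = (
    "aP", "mP", "mC", "oP", "oC", "oF", "oI",
    "tP", "tI", "hP", "hR", "cP", "cI", "cF",
)

#: point-group order of the lattice symmetry (sorting key for best_bravais)
SYMMETRY_ORDER = {
    "cP": 48, "cI": 48, "cF": 48,
    "hP": 24,
    "tP": 16, "tI": 16,
    "hR": 12,
    "oP": 8, "oC": 8, "oI": 8, "oF": 8,
    "mP": 4, "mC": 4,
    "aP": 2,
}

#: characters that are exact special cases of the key character
#: (transitively closed)
SPECIALIZATIONS = {
    "aP": [c for c in CHARACTERS if c != "aP"],
    "mP": ["oP", "tP", "cP"],
    "mC": ["oC", "oF", "oI", "tI", "tP", "hP", "hR", "cP", "cI", "cF"],
    "oP": ["tP", "cP"],
    "oC": ["tP", "hP", "cP"],
    "oI": ["tI", "cI", "cF"],
    "oF": ["tI", "cI", "cF"],
    "tP": ["cP"],
    "tI": ["cI", "cF"],
    "hR": ["cP", "cI", "cF"],
    "hP": [],
    "cP": [],
    "cI": [],
    "cF": [],
}


@dataclass(frozen=True)
class BravaisFit:
    """Result of fitting one Bravais character to a lattice."""

    character: str
    fitted_cell: UnitCell      # conventional setting of the character
    distance: float            # calibrated CS6Dist from input to fitted lattice
    primitive_cell: UnitCell   # primitive cell of the fitted lattice
    consistent: bool = False


# ---------------------------------------------------------------------------
# sort subspace definitions

def _sqrt_pos(x: float) -> float | None:
    return math.sqrt(x) if x > 1e-12 else None


def _cubic(a2, centering):
    a = _sqrt_pos(a2)
    if a is None:
        return None
    conv = UnitCell(a, a, a, 90.0, 90.0, 90.0)
    return conv, centering


def _tetragonal(a2, c2, centering):
    a, c = _sqrt_pos(a2), _sqrt_pos(c2)
    if a is None or c is None:
        return None
    conv = UnitCell(a, a, c, 90.0, 90.0, 90.0)
    return conv, centering


def _ortho(a2, b2, c2, centering):
    edges = sorted(x for x in (a2, b2, c2))
    vals = [_sqrt_pos(x) for x in edges]
    if any(v is None for v in vals):
        return None
    conv = UnitCell(vals[0], vals[1], vals[2], 90.0, 90.0, 90.0)
    return conv, centering


def _rhombohedral(a2, ca):
    a = _sqrt_pos(a2)
    if a is None or abs(ca) >= 0.999999 or 1.0 + 2.0 * ca <= 1e-9:
        return None
    a_hex = math.sqrt(2.0 * a2 * (1.0 - ca))
    c_hex = math.sqrt(3.0 * a2 * (1.0 + 2.0 * ca))
    conv = UnitCell(a_hex, a_hex, c_hex, 90.0, 90.0, 120.0)
    return conv, "H"


def _monoclinic(a2, b2, c2, x, centering):
    a, b, c = _sqrt_pos(a2), _sqrt_pos(b2), _sqrt_pos(c2)
    if a is None or b is None or c is None:
        return None
    cb = x / (a * c)
    if abs(cb) >= 0.999999:
        return None
    if cb > 0:  # conventional obtuse beta (flip the a axis)
        cb = -cb
    beta = math.degrees(math.acos(cb))
    conv = UnitCell(a, b, c, 90.0, beta, 90.0)
    return conv, centering


def _mean(s, idx):
    return float(np.mean([s[i] for i in idx]))


# Each sort: (basis columns spanning the S6 subspace, extractor).
# The extractor maps a projected S6 vector to (conventional cell,
# centering symbol) or None if the projection is not realizable.

def _extract_cP(s):
    return _cubic(-_mean(s, [3, 4, 5]), "P")


def _extract_cI(s):
    return _cubic(-4.0 * _mean(s, range(6)), "I")


def _extract_cF(s):
    return _cubic(-4.0 * _mean(s, [1, 2, 4, 5]), "F")


def _extract_tP(s):
    return _tetragonal(-_mean(s, [3, 4]), -s[5], "P")


def _extract_tI1(s):
    p = -_mean(s, [0, 1, 3, 4])      # c^2 / 4
    q = _mean(s, [2, 5])             # c^2/4 - a^2/2
    return _tetragonal(2.0 * (p - q), 4.0 * p, "I")


def _extract_tI2(s):
    u = -_mean(s, [0, 1, 3, 4])      # a^2 / 2
    return _tetragonal(2.0 * u, 4.0 * (u - s[5]), "I")


def _extract_hP(s):
    a2 = -2.0 * _mean(s, [2, 3, 4])
    a, c = _sqrt_pos(a2), _sqrt_pos(-s[5])
    if a is None or c is None:
        return None
    return UnitCell(a, a, c, 90.0, 90.0, 120.0), "P"


def _extract_hR1(s):
    p = _mean(s, [0, 1, 2])          # a^2 cos(alpha)
    q = _mean(s, [3, 4, 5])          # -a^2 (1 + 2 cos(alpha))
    a2 = -q - 2.0 * p
    if a2 <= 1e-12:
        return None
    return _rhombohedral(a2, p / a2)


def _extract_hR2(s):
    u = -s[2]                        # a^2 cos(alpha)
    a2 = u - _mean(s, [1, 4, 5])     # a^2
    if a2 <= 1e-12:
        return None
    return _rhombohedral(a2, u / a2)


def _extract_oP(s):
    return _ortho(-s[3], -s[4], -s[5], "P")


def _extract_oC1(s):
    a2 = -2.0 * _mean(s, [1, 2])
    b2 = a2 - 4.0 * s[0]
    return _ortho_c(a2, b2, -s[5])


def _extract_oC2(s):
    b2 = -2.0 * _mean(s, [3, 4])
    a2 = b2 - 4.0 * s[2]
    return _ortho_c(a2, b2, -s[5])


def _ortho_c(a2, b2, c2):
    # C-centered orthorhombic: keep the centered (a, b) plane, sort a < b
    lo, hi = sorted((a2, b2))
    a, b, c = _sqrt_pos(lo), _sqrt_pos(hi), _sqrt_pos(c2)
    if a is None or b is None or c is None:
        return None
    return UnitCell(a, b, c, 90.0, 90.0, 90.0), "C"


def _extract_oF(s):
    a2 = -4.0 * _mean(s, [0, 2, 3, 5])
    return _ortho(a2, a2 - 4.0 * s[1], a2 - 4.0 * s[4], "F")


def _extract_oI1(s):
    p1, p2, p3 = _mean(s, [0, 3]), _mean(s, [1, 4]), _mean(s, [2, 5])
    return _ortho(-2.0 * (p2 + p3), -2.0 * (p1 + p3), -2.0 * (p1 + p2), "I")


def _extract_oI2(s):
    a2 = -2.0 * _mean(s, [0, 4])
    b2 = -2.0 * _mean(s, [1, 3])
    return _ortho(a2, b2, a2 + b2 - 4.0 * s[5], "I")


def _extract_mP(s):
    x = s[1]
    return _monoclinic(-s[3] - x, -s[4], -s[5] - x, x, "P")


def _extract_mC1(s):
    x = 2.0 * _mean(s, [3, 4])
    a2 = -2.0 * _mean(s, [0, 1]) - x
    return _monoclinic(a2, a2 - 4.0 * s[2], -s[5] - x, x, "C")


def _extract_mC2(s):
    x = 2.0 * s[0]
    b2 = -2.0 * _mean(s, [2, 3])
    a2 = -4.0 * s[4] - 2.0 * x + b2
    return _monoclinic(a2, b2, -s[5] - x / 2.0, x, "C")


def _extract_mC3(s):
    p1, p2 = _mean(s, [0, 3]), _mean(s, [1, 4])
    b2 = -2.0 * (p1 + p2)
    a2 = b2 - 4.0 * s[2]
    x = p2 - p1 - a2 / 2.0
    c2 = -s[5] - a2 / 4.0 + b2 / 4.0 - x
    return _monoclinic(a2, b2, c2, x, "C")


def _cols(*vecs):
    return np.array(vecs, dtype=float).T


_SORTS: dict[str, list[tuple[np.ndarray, object]]] = {
    "cP": [(_cols((0, 0, 0, 1, 1, 1)), _extract_cP)],
    "cI": [(_cols((1, 1, 1, 1, 1, 1)), _extract_cI)],
    "cF": [(_cols((0, 1, 1, 0, 1, 1)), _extract_cF)],
    "tP": [(_cols((0, 0, 0, 1, 1, 0), (0, 0, 0, 0, 0, 1)), _extract_tP)],
    "tI": [
        (_cols((1, 1, -1, 1, 1, -1), (0, 0, 1, 0, 0, 1)), _extract_tI1),
        (_cols((1, 1, 0, 1, 1, -1), (0, 0, 0, 0, 0, 1)), _extract_tI2),
    ],
    "hP": [(_cols((0, 0, 1, 1, 1, 0), (0, 0, 0, 0, 0, 1)), _extract_hP)],
    "hR": [
        (_cols((1, 1, 1, 0, 0, 0), (0, 0, 0, 1, 1, 1)), _extract_hR1),
        (_cols((0, 1, -1, 0, 1, 1), (0, 1, 0, 0, 1, 1)), _extract_hR2),
    ],
    "oP": [(_cols((0, 0, 0, 1, 0, 0), (0, 0, 0, 0, 1, 0), (0, 0, 0, 0, 0, 1)), _extract_oP)],
    "oC": [
        (_cols((1, 0, 0, 0, 0, 0), (0, 1, 1, 0, 0, 0), (0, 0, 0, 0, 0, 1)), _extract_oC1),
        (_cols((0, 0, 1, 0, 0, 0), (0, 0, 0, 1, 1, 0), (0, 0, 0, 0, 0, 1)), _extract_oC2),
    ],
    "oF": [(_cols((-1, 1, -1, -1, 1, -1), (0, 1, 0, 0, 0, 0), (0, 0, 0, 0, 1, 0)), _extract_oF)],
    "oI": [
        (_cols((1, 0, 0, 1, 0, 0), (0, 1, 0, 0, 1, 0), (0, 0, 1, 0, 0, 1)), _extract_oI1),
        (_cols((-2, 0, 0, 0, -2, 1), (0, -2, 0, -2, 0, 1), (0, 0, 0, 0, 0, 1)), _extract_oI2),
    ],
    "mP": [(_cols(
        (0, 1, 0, -1, 0, -1),
        (0, 0, 0, -1, 0, 0), (0, 0, 0, 0, -1, 0), (0, 0, 0, 0, 0, -1),
    ), _extract_mP)],
    "mC": [
        (_cols(
            (-0.5, -0.5, 0.25, 0, 0, 0), (0, 0, -0.25, 0, 0, 0),
            (0, 0, 0, 0, 0, -1), (-0.5, -0.5, 0, 0.5, 0.5, -1),
        ), _extract_mC1),
        (_cols(
            (0, 0, 0, 0, -0.25, 0), (0, 0, -0.5, -0.5, 0.25, 0),
            (0, 0, 0, 0, 0, -1), (0.5, 0, 0, 0, -0.5, -0.5),
        ), _extract_mC2),
        (_cols(
            (-0.25, 0.25, -0.25, -0.25, 0.25, -0.25),
            (-0.25, -0.25, 0.25, -0.25, -0.25, 0.25),
            (-0.5, 0.5, 0, -0.5, 0.5, -1), (0, 0, 0, 0, 0, -1),
        ), _extract_mC3),
    ],
}


def _fit_ops() -> np.ndarray:
    """Image operators for fitting: permutations composed with one
    optional boundary exchange (the reduced vector of a lattice that
    genuinely has a character lies on one of the sort subspaces in one
    of these images)."""
    seen = {}
    tset = [np.eye(6)] + list(EXCHANGES)
    for t in tset:
        for g in P24_MATRICES:
            m = t @ g
            seen[np.round(m).astype(np.int8).tobytes()] = m
    return np.array(list(seen.values()))


_FIT_OPS = _fit_ops()


# ---------------------------------------------------------------------------
# fitting machinery


def _prim_of(conv: UnitCell, centering: str) -> UnitCell:
    if centering == "P":
        return conv
    return primitive_from_centered(CenteredCell(conv, centering))


def _raw_distance(x: np.ndarray, x_images: np.ndarray, prim: UnitCell) -> float:
    sy = reduced_s6(prim)
    d1 = float(np.linalg.norm(CANDIDATES @ sy - x, axis=1).min())
    d2 = float(np.linalg.norm(x_images - sy, axis=1).min())
    return min(d1, d2)


def _try_extract(extract, sproj):
    try:
        result = extract(sproj)
    except (CellError, ValueError):
        return None
    if result is None:
        return None
    conv, centering = result
    try:
        prim = _prim_of(conv, centering)
    except (CellError, ValueError):
        return None
    return conv, centering, prim


def _fit_character(cell: UnitCell, character: str, polish: bool = True):
    """Fit the character's own sorts; returns (distance_raw, conv, prim)."""
    if character == "aP":
        return 0.0, cell, cell
    x = reduced_s6(cell)
    x_images = CANDIDATES @ x
    ys = _FIT_OPS @ x
    best = None  # (raw, conv, prim, V, sproj)
    for V, extract in _SORTS[character]:
        proj = V @ np.linalg.pinv(V)
        projected = ys @ proj.T
        resid = np.linalg.norm(ys - projected, axis=1)
        order = np.argsort(resid, kind="stable")
        seen = set()
        tried = 0
        for idx in order:
            key = tuple(np.round(projected[idx], 6))
            if key in seen:
                continue
            seen.add(key)
            cand = _try_extract(extract, projected[idx])
            if cand is None:
                continue
            conv, centering, prim = cand
            raw = _raw_distance(x, x_images, prim)
            if best is None or raw < best[0]:
                best = (raw, conv, prim, V, extract, projected[idx])
            tried += 1
            if tried >= 6:
                break
    if best is None:
        return None
    raw, conv, prim, V, extract, sproj = best
    if polish and raw > 1e-10:
        coeffs0, *_ = np.linalg.lstsq(V, sproj, rcond=None)
        scale = max(1.0, float(np.abs(coeffs0).max()))

        def objective(coeffs):
            cand = _try_extract(extract, V @ coeffs)
            if cand is None:
                return raw * 10.0 + scale
            return _raw_distance(x, x_images, cand[2])

        res = minimize(
            objective, coeffs0, method="Nelder-Mead",
            options={"maxiter": 120 * len(coeffs0), "xatol": 1e-8 * scale,
                     "fatol": 1e-10 * max(raw, 1.0)},
        )
        if res.fun < raw:
            cand = _try_extract(extract, V @ res.x)
            if cand is not None:
                raw = float(res.fun)
                conv, _, prim = cand
    return raw, conv, prim


def _refit_conventional(prim: UnitCell, character: str) -> UnitCell | None:
    """Express a lattice known to have (at least) the given character in
    that character's conventional setting (minimum-residual projection,
    no polish)."""
    fit = _fit_character(prim, character, polish=False)
    if fit is None:
        return None
    return fit[1]


def closest_bravais(cell: UnitCell, character: str, tolerance: float = 0.2,
                    polish: bool = True) -> BravaisFit:
    """Closest lattice of the requested Bravais character to a primitive cell.

    The distance is the calibrated CS6Dist between the input lattice and
    the fitted lattice.  Fits from exact specializations of the
    character are included (a cubic lattice is a valid tetragonal fit,
    and so on), so the symmetry hierarchy is monotone.
    """
    if character not in CHARACTERS:
        raise ValueError(
            f"unknown Bravais character {character!r}; expected one of {CHARACTERS}"
        )
    best = _fit_character(cell, character, polish=polish)
    best_char = character
    for spec in SPECIALIZATIONS[character]:
        fit = _fit_character(cell, spec, polish=polish)
        if fit is not None and (best is None or fit[0] < best[0] - 1e-12):
            best = fit
            best_char = spec
    if best is None:
        raise RuntimeError(f"no valid {character} fit found (degenerate input?)")
    raw, conv, prim = best
    if best_char != character and character != "aP":
        refit = _refit_conventional(prim, character)
        if refit is not None:
            conv = refit
    distance = 0.1 * math.sqrt(max(raw, 0.0))
    return BravaisFit(character, conv, distance, prim, distance <= tolerance)


def best_bravais(cell: UnitCell, tolerance: float = 0.2,
                 polish: bool = True) -> list[BravaisFit]:
    """Fit all 14 characters; sorted by descending symmetry order then
    ascending distance.  Fits within ``tolerance`` are flagged consistent."""
    own: dict[str, tuple] = {}
    for char in CHARACTERS:
        fit = _fit_character(cell, char, polish=polish)
        if fit is not None:
            own[char] = fit
    results = []
    for char in CHARACTERS:
        candidates = [(own[c], c) for c in [char] + SPECIALIZATIONS[char] if c in own]
        if not candidates:
            continue
        (raw, conv, prim), winner = min(candidates, key=lambda t: t[0][0])
        if winner != char and char != "aP":
            refit = _refit_conventional(prim, char)
            if refit is not None:
                conv = refit
        distance = 0.1 * math.sqrt(max(raw, 0.0))
        results.append(BravaisFit(char, conv, distance, prim, distance <= tolerance))
    results.sort(key=lambda f: (-SYMMETRY_ORDER[f.character], f.distance, f.character))
    return results
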