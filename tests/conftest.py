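"""Shared fixtures: the six published lysozyme-family cells used as the
worked example (PDB ids 1DPY, 1FE5, 1G0Z, 1U4J, 1G2X, 2OSN)."""

from __future__ import annotations

import pytest

from latticecluster import (
    CenteredCell,
    UnitCell,
    niggli_reduce,
    primitive_from_centered,
)

# conventional cells as published, with their centering symbols
CONVENTIONAL = {
    "1DPY": ((57.98, 57.98, 57.98, 92.02, 92.02, 92.02), "R"),
    "1FE5": ((57.98, 57.98, 57.98, 92.02, 92.02, 92.02), "R"),
    "1G0Z": ((80.36, 80.36, 99.44, 90.0, 90.0, 120.0), "H"),
    "1U4J": ((80.36, 80.36, 99.44, 90.0, 90.0, 120.0), "H"),
    "1G2X": ((80.95, 80.57, 57.1, 90.0, 90.35, 90.0), "C"),
    "2OSN": ((57.1, 57.1, 57.1, 89.75, 89.75, 89.75), "R"),
}

# published primitive reduced cells
PRIMITIVE_PUBLISHED = {
    "1DPY": (57.98, 57.98, 57.98, 92.02, 92.02, 92.02),
    "1FE5": (57.98, 57.98, 57.98, 92.02, 92.02, 92.02),
    "1G0Z": (57.02, 57.02, 57.02, 89.605, 89.605, 89.605),
    "1U4J": (57.02, 57.02, 57.02, 89.605, 89.605, 89.605),
    "1G2X": (57.098, 57.1065, 57.1065, 89.7325, 89.7519, 89.7519),
    "2OSN": (57.104, 57.104, 57.104, 89.75, 89.75, 89.75),
}

# published pairwise S6 (CS6Dist) distances
DISTANCES_PUBLISHED = {
    ("1DPY", "1FE5"): 0.0,
    ("1DPY", "1G0Z"): 1.720,
    ("1DPY", "1G2X"): 1.753,
    ("1DPY", "1U4J"): 1.720,
    ("1DPY", "2OSN"): 1.757,
    ("1FE5", "1G0Z"): 1.720,
    ("1FE5", "1G2X"): 1.753,
    ("1FE5", "1U4J"): 1.720,
    ("1FE5", "2OSN"): 1.757,
    ("1G0Z", "1G2X"): 0.555,
    ("1G0Z", "1U4J"): 0.0,
    ("1G0Z", "2OSN"): 0.564,
    ("1G2X", "1U4J"): 0.555,
    ("1G2X", "2OSN"): 0.127,
    ("1U4J", "2OSN"): 0.564,
}

# published closest-hR fits: hexagonal-setting cell and distance
CLOSEST_HR_PUBLISHED = {
    "1DPY": ((83.429, 83.429, 96.820), 0.0),
    "1FE5": ((83.429, 83.429, 96.820), 0.0),
    "1G0Z": ((80.360, 80.360, 99.440), 0.0),
    "1U4J": ((80.360, 80.360, 99.440), 0.0),
    "1G2X": ((80.577, 80.577, 99.345), 0.405),
    "2OSN": ((80.581, 80.581, 99.338), 0.0),
}

NAMES = sorted(CONVENTIONAL)


@pytest.fixture(scope="session")
def conventional_cells() -> dict[str, CenteredCell]:
    return {
        name: CenteredCell(UnitCell(*params), centering)
        for name, (params, centering) in CONVENTIONAL.items()
    }


@pytest.fixture(scope="session")
def primitive_cells(conventional_cells) -> dict[str, UnitCell]:
    return {
        name: niggli_reduce(primitive_from_centered(cc)).cell
        for name, cc in conventional_cells.items()
    }
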