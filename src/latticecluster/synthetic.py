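"""Seeded generator of polymorph-ensemble fixtures.

Produces mixtures of "species" (polymorphs): each species has a base
cell, Gaussian per-image cell jitter, and a per-reflection log-normal
intensity profile; images get multiplicative intensity noise, a random
subsample of the reflection sphere (to a target completeness), and
spot counts.  Junk images have low spot counts and carry no cell with
probability 0.5 (exercising the "not indexed" discard path).

Everything is deterministic given the spec's rng_seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cells import CellError, UnitCell
from .reflections import (
    ImageRecord,
    ReflectionSet,
    resolutions,
    unique_reflections,
    write_manifest,
)

__all__ = ["SpeciesSpec", "EnsembleSpec", "generate", "write_fixture", "read_labels"]


@dataclass
class SpeciesSpec:
    """One polymorph species in the mixture."""

    name: str
    base_cell: UnitCell
    cell_jitter: tuple[float, float, float, float, float, float] = (0, 0, 0, 0, 0, 0)
    intensity_loc: float = 2.0      # log-normal location of true intensities
    intensity_scale: float = 1.0    # log-normal scale of true intensities
    fraction: float = 1.0

    def __post_init__(self):
        if any(j < 0 for j in self.cell_jitter):
            raise ValueError("cell jitter standard deviations must be >= 0")
        if self.fraction < 0:
            raise ValueError("species fraction must be >= 0")


@dataclass
class EnsembleSpec:
    """A full synthetic ensemble."""

    species: list[SpeciesSpec]
    n_images: int = 100
    junk_fraction: float = 0.0
    spot_count_real: float = 120.0   # Poisson mean for good images
    spot_count_junk: float = 3.0     # Poisson mean for junk images
    d_min: float = 10.0
    completeness: float = 0.9        # per-image observed fraction
    noise: float = 0.1               # multiplicative intensity noise (log sd)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.junk_fraction < 1:
            raise ValueError("junk_fraction must be in [0, 1)")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if not self.species:
            raise ValueError("at least one species is required")
        total = sum(sp.fraction for sp in self.species)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("species fractions must sum to 1")
        if not 0 < self.completeness <= 1:
            raise ValueError("completeness must be in (0, 1]")


def _jittered_cell(rng: np.random.Generator, sp: SpeciesSpec) -> UnitCell:
    base = sp.base_cell.parameters()
    for _ in range(100):
        draw = rng.normal(size=6)
        params = [b + s * d for b, s, d in zip(base, sp.cell_jitter, draw)]
        try:
            return UnitCell(*params)
        except CellError:
            continue
    raise RuntimeError(
        f"species {sp.name}: no valid jittered cell after 100 redraws "
        "(jitter too large for the base cell)"
    )


def generate(spec: EnsembleSpec) -> tuple[list[ImageRecord], dict[str, str]]:
    """Generate an ensemble; returns (images, truth labels by image id)."""
    rng = np.random.default_rng(spec.rng_seed)
    # per-species true intensity profiles over the species' base index set
    profiles = []
    index_sets = []
    for si, sp in enumerate(spec.species):
        hkl = unique_reflections(sp.base_cell, spec.d_min)
        order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
        hkl = hkl[order]
        sp_rng = np.random.default_rng([spec.rng_seed, si])
        true_i = sp_rng.lognormal(sp.intensity_loc, sp.intensity_scale, size=len(hkl))
        index_sets.append(hkl)
        profiles.append(true_i)

    fractions = np.array([sp.fraction for sp in spec.species])
    images: list[ImageRecord] = []
    truth: dict[str, str] = {}
    width = len(str(spec.n_images - 1))
    for i in range(spec.n_images):
        ident = f"img{i:0{width}d}"
        is_junk = rng.random() < spec.junk_fraction
        if is_junk:
            spot_count = int(rng.poisson(spec.spot_count_junk))
            has_cell = rng.random() < 0.5
            cell = None
            if has_cell:
                si = int(rng.choice(len(spec.species), p=fractions))
                cell = _jittered_cell(rng, spec.species[si])
            images.append(ImageRecord(ident, spot_count, cell, None))
            truth[ident] = "junk"
            continue
        si = int(rng.choice(len(spec.species), p=fractions))
        sp = spec.species[si]
        cell = _jittered_cell(rng, sp)
        hkl = index_sets[si]
        n_obs = max(1, int(round(spec.completeness * len(hkl))))
        picked = np.sort(rng.choice(len(hkl), size=n_obs, replace=False))
        # a jittered cell can push indices of the base set just past the
        # resolution cutoff; such reflections are unobservable and dropped
        d = resolutions(cell, hkl[picked])
        observable = d >= spec.d_min - 1e-9
        noise = np.exp(rng.normal(0.0, spec.noise, size=n_obs))[observable]
        picked = picked[observable]
        intensity = profiles[si][picked] * noise
        sigma = np.maximum(spec.noise * intensity, 1e-6)
        rs = ReflectionSet(hkl[picked], intensity, sigma, cell, spec.d_min)
        spot_count = int(rng.poisson(spec.spot_count_real))
        images.append(ImageRecord(ident, spot_count, cell, rs))
        truth[ident] = sp.name
    return images, truth


def write_fixture(
    images: Sequence[ImageRecord],
    labels: dict[str, str],
    directory: str | Path,
    d_min: float,
) -> Path:
    """Write manifest + per-image reflection files + truth labels;
    returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = write_manifest(directory / "manifest.csv", images, d_min)
    lines = ["id,species"]
    for ident in sorted(labels):
        lines.append(f"{ident},{labels[ident]}")
    (directory / "labels.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a truth-label CSV written by :func:`write_fixture`."""
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    out = {}
    for line in lines[1:]:
        ident, species = line.split(",", 1)
        out[ident] = species
    return out
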