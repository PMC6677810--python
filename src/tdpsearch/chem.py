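"""Residue masses, terminal chemistry and ion-series offsets.

All fragment arithmetic in this package is done on *neutral monoisotopic*
masses, the convention of deconvolved top-down spectra: a whole proteoform
weighs the sum of its residue masses plus one water (N-terminal H, C-terminal
OH), and an ion series is the bare residue sum of the fragment plus a fixed
series offset.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

WATER_MONO = 18.010565
WATER_AVG = 18.01528
PROTON = 1.007276
HYDROGEN = 1.007825  # neutral H atom
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default neutral-loss specifications (name, delta in Da)
DEFAULT_LOSSES: tuple[tuple[str, float], ...] = (
    ("H2O", -18.010565),
    ("NH3", -17.026549),
)


class ResidueError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Per-residue masses plus the terminal water and proton constants."""

    masses: Mapping[str, float]
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON
    mass_mode: str = "monoisotopic"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.masses)
        if missing:
            raise ValueError(f"residue mass table incomplete, missing {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.masses[residue]
        except KeyError:
            raise ResidueError(f"unknown residue {residue!r}") from None


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("tdpsearch.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


@functools.lru_cache(maxsize=None)
def residue_table(mass_mode: str = "monoisotopic") -> ResidueMassTable:
    """Load the bundled residue-mass table (``monoisotopic`` or ``average``)."""
    if mass_mode not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass mode {mass_mode!r}")
    col = 1 if mass_mode == "monoisotopic" else 2
    masses = {row[0]: float(row[col]) for row in _read_table("residue_masses.tsv")}
    water = WATER_MONO if mass_mode == "monoisotopic" else WATER_AVG
    return ResidueMassTable(masses=masses, water_mass=water, mass_mode=mass_mode)


@functools.lru_cache(maxsize=None)
def series_offsets() -> dict[str, tuple[str, float]]:
    """Map ion series letter -> (terminus, neutral mass offset)."""
    return {row[0]: (row[1], float(row[2])) for row in _read_table("ion_series.tsv")}
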