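"""Theoretical fragment generation for proteoforms.

A proteoform is a base sequence plus optional modifications, a single-sided
truncation, and an optional unexplained mass shift localized to one residue.
Fragmentation emits L−1 neutral fragments per enabled ion series: N-terminal
series carry the prefix residue sum plus a series offset, C-terminal series
the complement (proteoform residue total minus the prefix) plus theirs.
Enabled neutral losses add one shifted copy per fragment.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .chem import HYDROGEN, ResidueMassTable, residue_table, series_offsets
from .errors import ConfigurationError, ProteoformError
from .protein_db import ProteinEntry

if TYPE_CHECKING:  # pragma: no cover
    from .ptm_search import ModificationSite

#: fragmentation mode -> enabled ion series
MODE_SERIES: dict[str, tuple[str, ...]] = {
    "CID": ("b", "y"),
    "HCD": ("b", "y"),
    "IRMPD": ("b", "y"),
    "SID": ("b", "y"),
    "BIRD": ("b", "y"),
    "ECD": ("c", "z"),
    "ETD": ("c", "z"),
    "EDD": ("a", "x"),
    "UVPD": ("a", "b", "c", "x", "y", "z"),
}

# literal reading of the nonstandard terminal-chemistry convention:
# hydroxyl added to every N-terminal ion, proton to every C-terminal ion
_PAPER_OFFSET_N = 17.002740
_PAPER_OFFSET_C = 1.007276


@dataclass(frozen=True)
class IonSeriesSpec:
    series: str
    terminus: str  # "N" or "C"
    mass_offset: float
    enabled_losses: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class TheoreticalFragment:
    mass: float
    series: str
    index: int          # 1-based cleavage count from the fragment's terminus
    loss: str | None = None

    @property
    def series_key(self) -> tuple[str, str, int]:
        """Grouping/order key used for consecutive-match bookkeeping."""
        return (self.series, self.loss or "", self.index)


@dataclass(frozen=True)
class Proteoform:
    """Base sequence + modifications + single-sided truncation + mass shift."""

    base: ProteinEntry
    modifications: tuple["ModificationSite", ...] = ()
    truncation: tuple[str, int] | None = None  # ("N", k) or ("C", k)
    unexplained_shift: float = 0.0
    shift_position: int = 1  # 1-based residue carrying the unexplained shift

    def __post_init__(self) -> None:
        if self.truncation is not None:
            side, k = self.truncation
            if side not in ("N", "C") or k < 0 or k >= len(self.base.sequence):
                raise ProteoformError(f"invalid truncation {self.truncation}")
        L = len(self.sequence)
        if L == 0:
            raise ProteoformError("empty sequence after truncation")
        seen = set()
        for site in self.modifications:
            if not 1 <= site.position <= L:
                raise ProteoformError(f"modification position {site.position} outside 1..{L}")
            if site.position in seen and site.ptm.kind == "variable":
                raise ProteoformError(f"two variable modifications at position {site.position}")
            seen.add(site.position)
        if self.unexplained_shift and not 1 <= self.shift_position <= L:
            raise ProteoformError(f"shift position {self.shift_position} outside 1..{L}")

    @property
    def sequence(self) -> str:
        seq = self.base.sequence
        if self.truncation is None:
            return seq
        side, k = self.truncation
        return seq[k:] if side == "N" else seq[: len(seq) - k]

    def mod_deltas(self) -> np.ndarray:
        """Per-position modification deltas over the post-truncation sequence."""
        deltas = np.zeros(len(self.sequence))
        for site in self.modifications:
            deltas[site.position - 1] += site.ptm.delta_mass
        return deltas

    def mass(self, table: ResidueMassTable | None = None) -> float:
        if table is None:
            table = residue_table()
        seq = self.sequence
        total = table.water_mass + sum(table.masses[r] for r in seq)
        total += float(self.mod_deltas().sum())
        return total + self.unexplained_shift

    def describe(self) -> str:
        mods = ";".join(f"{s.ptm.name}@{s.position}" for s in self.modifications) or "-"
        trunc = f"{self.truncation[0]}:{self.truncation[1]}" if self.truncation else "-"
        return f"{self.base.accession} mods={mods} trunc={trunc} shift={self.unexplained_shift:+.5f}"


def mode_to_series(
    mode: str,
    losses: Sequence[tuple[str, float]] = (),
    overrides: dict[str, Sequence[str]] | None = None,
    paper_offsets: bool = False,
) -> list[IonSeriesSpec]:
    """Ion series enabled by a fragmentation mode, with optional per-mode
    overrides (e.g. ``{"CID": ["a", "b", "y"]}``)."""
    table = series_offsets()
    if overrides and mode in overrides:
        names = tuple(overrides[mode])
    else:
        try:
            names = MODE_SERIES[mode]
        except KeyError:
            raise ConfigurationError(f"unknown fragmentation mode {mode!r}") from None
    specs = []
    for name in names:
        if name not in table:
            raise ConfigurationError(f"unknown ion series {name!r}")
        terminus, offset = table[name]
        if paper_offsets:
            offset = _PAPER_OFFSET_N if terminus == "N" else _PAPER_OFFSET_C
        specs.append(IonSeriesSpec(name, terminus, offset, tuple(losses)))
    return specs


def fragment(
    proteoform: Proteoform,
    mode: str = "CID",
    losses: Sequence[tuple[str, float]] = (),
    table: ResidueMassTable | None = None,
    overrides: dict[str, Sequence[str]] | None = None,
    paper_offsets: bool = False,
) -> list[TheoreticalFragment]:
    """All theoretical fragments of a proteoform, sorted by mass.

    For sequence length L each enabled series contributes L−1 fragments plus
    one extra copy per enabled neutral loss.  The unexplained shift, if any,
    moves every fragment containing ``shift_position``.
    """
    if table is None:
        table = residue_table()
    seq = proteoform.sequence
    L = len(seq)
    res = np.array([table.masses[r] for r in seq]) + proteoform.mod_deltas()
    prefix = np.cumsum(res)  # prefix[i-1] = residue sum of first i residues
    total = prefix[-1]
    shift, p = proteoform.unexplained_shift, proteoform.shift_position
    specs = mode_to_series(mode, losses, overrides, paper_offsets)
    frags: list[TheoreticalFragment] = []
    for spec in specs:
        for i in range(1, L):  # cleavage after residue i
            if spec.terminus == "N":
                mass = prefix[i - 1] + spec.mass_offset
                if shift and p <= i:
                    mass += shift
                index = i
            else:
                mass = total - prefix[i - 1] + spec.mass_offset
                if shift and p > i:
                    mass += shift
                index = L - i
            frags.append(TheoreticalFragment(float(mass), spec.series, index))
            for name, delta in spec.enabled_losses:
                frags.append(TheoreticalFragment(float(mass + delta), spec.series, index, name))
    frags.sort(key=lambda f: f.mass)
    return frags


def enumerate_truncations(
    entry: ProteinEntry,
    experimental_mass: float,
    thr: float,
    table: ResidueMassTable | None = None,
    include_intact: bool = True,
) -> list[Proteoform]:
    """All single-sided truncations of ``entry`` whose intact mass lies within
    ±thr of the experimental mass, computed incrementally from prefix sums."""
    if table is None:
        table = residue_table()
    seq = entry.sequence
    L = len(seq)
    res = np.array([table.masses[r] for r in seq])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    total = prefix[-1]
    out: list[Proteoform] = []
    # k = 0 (intact) emitted once, not once per side
    if include_intact and abs(total + table.water_mass - experimental_mass) <= thr:
        out.append(Proteoform(base=entry))
    for k in range(1, L):
        n_mass = (total - prefix[k]) + table.water_mass      # remove k from N-terminus
        if abs(n_mass - experimental_mass) <= thr:
            out.append(Proteoform(base=entry, truncation=("N", k)))
        c_mass = prefix[L - k] + table.water_mass            # remove k from C-terminus
        if abs(c_mass - experimental_mass) <= thr:
            out.append(Proteoform(base=entry, truncation=("C", k)))
    return out
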