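"""Post-translational modification search: fixed, variable and blind.

Fixed modifications decorate every occurrence of their target residue;
variable modifications are *predicted* per site from residue occurrence
propensities (product over the binding-site window, thresholded), and all
small combinations of predicted sites are enumerated.  The blind search
localizes a single unexplained precursor-mass shift by sliding it across the
sequence and re-matching, then names it from the bundled PTM table when the
delta and site residue agree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .chem import ResidueMassTable, residue_table
from .errors import ConfigurationError
from .fragmenter import Proteoform, fragment
from .matcher import MatchResult, match
from .peak_io import SpectrumRecord

log = logging.getLogger(__name__)

CHARACTERIZATION_TOL = 0.01  # Da window for naming a blind shift
PTM_KINDS = ("fixed", "variable", "terminal", "chemical")


@dataclass(frozen=True)
class PTMDefinition:
    name: str
    delta_mass: float
    target_residues: frozenset[str]
    terminus_constraint: str = "none"  # none | N | C | protein-N | protein-C
    kind: str = "variable"
    site_propensities: tuple[tuple[str, float], ...] = ()  # residue -> propensity

    def __post_init__(self) -> None:
        if self.kind not in PTM_KINDS:
            raise ValueError(f"unknown PTM kind {self.kind!r}")
        for _, p in self.site_propensities:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: propensity {p} outside [0, 1]")

    def propensity(self, residue: str) -> float:
        for res, p in self.site_propensities:
            if res == residue:
                return p
        return 1.0 if residue in self.target_residues else 0.0


@dataclass(frozen=True)
class ModificationSite:
    position: int  # 1-based, post-truncation coordinates
    ptm: PTMDefinition
    site_score: float = 1.0


def load_ptm_table(path: str | Path | None = None) -> list[PTMDefinition]:
    """Load a PTM definition table (tab-separated: name, delta_mass, residues,
    terminus, kind, propensities).  With no path, the bundled table ships."""
    if path is None:
        text = resources.files("tdpsearch.data").joinpath("ptms.tsv").read_text()
    else:
        text = Path(path).read_text()
    ptms: list[PTMDefinition] = []
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) < 5:
            raise ConfigurationError(f"malformed PTM row: {line!r}")
        name, delta, residues, terminus, kind = parts[:5]
        props: tuple[tuple[str, float], ...] = ()
        if len(parts) > 5 and parts[5].strip():
            props = tuple(
                (tok.split(":")[0], float(tok.split(":")[1]))
                for tok in parts[5].split(",")
            )
        ptms.append(
            PTMDefinition(
                name=name,
                delta_mass=float(delta),
                target_residues=frozenset(residues),
                terminus_constraint=terminus,
                kind=kind,
                site_propensities=props,
            )
        )
    return ptms


def _terminal_position(seq_len: int, constraint: str) -> int:
    return 1 if constraint in ("N", "protein-N") else seq_len


def apply_fixed(proteoform: Proteoform, ptms: list[PTMDefinition]) -> Proteoform:
    """Decorate every occurrence of each fixed modification's target residues;
    terminal/chemical modifications are applied once at their terminus."""
    seq = proteoform.sequence
    sites = list(proteoform.modifications)
    occupied = {s.position for s in sites if s.ptm.kind == "fixed"}
    for ptm in ptms:
        if ptm.kind == "fixed":
            positions = [i + 1 for i, r in enumerate(seq) if r in ptm.target_residues]
        elif ptm.kind in ("terminal", "chemical"):
            pos = _terminal_position(len(seq), ptm.terminus_constraint)
            positions = [pos] if seq[pos - 1] in ptm.target_residues else []
        else:
            raise ConfigurationError(f"{ptm.name}: apply_fixed expects fixed/terminal/chemical PTMs")
        for pos in positions:
            if pos in occupied:
                raise ConfigurationError(f"conflicting fixed modifications at position {pos}")
            occupied.add(pos)
            sites.append(ModificationSite(pos, ptm, 1.0))
    sites.sort(key=lambda s: s.position)
    return replace(proteoform, modifications=tuple(sites))


def predict_variable_sites(
    sequence: str,
    ptm: PTMDefinition,
    ptm_thr: float,
    context_width: int = 1,
) -> list[ModificationSite]:
    """Score each occurrence of a target residue by the product of residue
    propensities over a window of ``context_width`` centered on the site;
    emit sites scoring strictly above ``ptm_thr``."""
    if ptm.kind != "variable":
        raise ConfigurationError(f"{ptm.name}: site prediction applies to variable PTMs")
    half = context_width // 2
    sites = []
    for i, res in enumerate(sequence):
        if res not in ptm.target_residues:
            continue
        window = sequence[max(0, i - half): i + half + 1]
        score = 1.0
        for r in window:
            score *= ptm.propensity(r)
        if score > ptm_thr:
            sites.append(ModificationSite(i + 1, ptm, score))
    return sites


def enumerate_modified_proteoforms(
    base: Proteoform,
    sites: list[ModificationSite],
    max_sites: int = 3,
    hard_cap: int = 10_000,
) -> list[Proteoform]:
    """All subsets of predicted sites of size ≤ max_sites (at most one per
    position), each as one proteoform; deterministic order by subset size and
    positions.  If the enumeration would exceed ``hard_cap`` proteoforms, the
    lowest-scoring sites are dropped first."""
    if max_sites < 0:
        raise ValueError("max_sites must be >= 0")
    sites = sorted(sites, key=lambda s: (-s.site_score, s.position, s.ptm.name))

    def count(n: int) -> int:
        import math
        return sum(math.comb(n, k) for k in range(0, min(max_sites, n) + 1))

    while len(sites) > 0 and count(len(sites)) > hard_cap:
        sites.pop()
        log.warning("site enumeration capped at %d proteoforms; dropping lowest-scoring site", hard_cap)

    sites.sort(key=lambda s: (s.position, s.ptm.name))
    out: list[Proteoform] = []
    for k in range(0, min(max_sites, len(sites)) + 1):
        for combo in itertools.combinations(sites, k):
            positions = [s.position for s in combo]
            if len(set(positions)) != len(positions):
                continue  # at most one variable modification per residue
            out.append(
                replace(base, modifications=tuple(list(base.modifications) + list(combo)))
            )
    return out


@dataclass(frozen=True)
class BlindPtmResult:
    position: int | None
    shift: float
    characterization: str  # PTM name, "unexplained", or "none" when below tolerance
    match: MatchResult


def characterize_shift(
    shift: float,
    residue: str,
    ptm_table: list[PTMDefinition],
    tol: float = CHARACTERIZATION_TOL,
) -> str:
    """Name a localized mass shift from the PTM table: delta within ±tol and
    the site residue among the PTM's targets."""
    best = None
    for ptm in ptm_table:
        if abs(ptm.delta_mass - shift) <= tol and residue in ptm.target_residues:
            err = abs(ptm.delta_mass - shift)
            if best is None or err < best[0]:
                best = (err, ptm.name)
    return best[1] if best else "unexplained"


def blind_ptm_search(
    spectrum: SpectrumRecord,
    proteoform: Proteoform,
    tolerance_ppm: float = 15.0,
    ptm_table: list[PTMDefinition] | None = None,
    mode: str | None = None,
    losses=(),
    table: ResidueMassTable | None = None,
    **match_kwargs,
) -> BlindPtmResult:
    """Localize and name a single unknown mass shift.

    The residual shift is the (tuned) precursor mass minus the proteoform's
    theoretical mass.  Each candidate position carries the full shift in turn
    (moving every fragment that contains it); the position maximizing the
    in-silico score wins, smallest position on ties.
    """
    if table is None:
        table = residue_table()
    if ptm_table is None:
        ptm_table = load_ptm_table()
    if mode is None:
        mode = spectrum.fragmentation_mode
    shift = spectrum.precursor_mass - proteoform.mass(table)
    tol_da = proteoform.mass(table) * tolerance_ppm * 1e-6
    base_match = match(spectrum, fragment(proteoform, mode, losses, table), tolerance_ppm, **match_kwargs)
    if abs(shift) <= tol_da:
        return BlindPtmResult(None, shift, "none", base_match)
    seq = proteoform.sequence
    best_pos, best_match = None, None
    for p in range(1, len(seq) + 1):
        shifted = replace(proteoform, unexplained_shift=shift, shift_position=p)
        result = match(spectrum, fragment(shifted, mode, losses, table), tolerance_ppm, **match_kwargs)
        if best_match is None or result.score_insilico > best_match.score_insilico:
            best_pos, best_match = p, result
    name = characterize_shift(shift, seq[best_pos - 1], ptm_table)
    return BlindPtmResult(best_pos, shift, name, best_match)
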