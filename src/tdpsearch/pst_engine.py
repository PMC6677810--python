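"""De novo peptide sequence tag (PST) extraction and scoring.

A *hop* is a pair of peaks whose mass difference matches an amino-acid residue
mass within a tolerance; chaining hops end-to-start yields PST ladders, short
stretches of sequence read directly off the spectrum.  Tags are scored on
their cumulative mass error, the intensities of their supporting peaks, and
(quadratically) their length; a protein is then scored by how often its
sequence contains each tag, in either reading direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chem import ResidueMassTable, residue_table
from .peak_io import SpectrumRecord
from .protein_db import ProteinEntry


@dataclass(frozen=True)
class Hop:
    start_peak: int
    end_peak: int
    mass_diff: float
    residue: str
    residue_mass: float
    error: float  # signed, experimental − residue mass (Da)


@dataclass(frozen=True)
class PST:
    """A chained sequence tag with its component scores (populated by score_pst)."""

    hops: tuple[Hop, ...]
    residues: str
    rmse: float = 0.0
    error_score: float = 0.0
    intensity: float = 0.0   # cumulative normalized intensity of the tag
    len_score: float = 0.0   # N^2
    freq_score: float = 0.0  # intensity * len_score

    def __len__(self) -> int:
        return len(self.hops)


def extract_hops(
    spectrum: SpectrumRecord,
    hop_tolerance: float,
    collapse_leu_ile: bool = True,
    table: ResidueMassTable | None = None,
) -> list[Hop]:
    """All peak pairs (any gap, not only adjacent peaks) whose mass difference
    matches a residue mass within ``hop_tolerance``; one hop per matching
    residue.  Leucine/isoleucine share a mass and are collapsed to 'L' unless
    ``collapse_leu_ile`` is false.
    """
    if table is None:
        table = residue_table()
    residues = {r: m for r, m in table.masses.items() if not (collapse_leu_ile and r == "I")}
    masses = spectrum.masses
    n = len(masses)
    hops: list[Hop] = []
    ii, jj = np.triu_indices(n, k=1)
    diffs = masses[jj] - masses[ii]
    for res, rmass in residues.items():
        hits = np.abs(diffs - rmass) <= hop_tolerance
        for k in np.nonzero(hits)[0]:
            hops.append(
                Hop(
                    start_peak=int(ii[k]),
                    end_peak=int(jj[k]),
                    mass_diff=float(diffs[k]),
                    residue=res,
                    residue_mass=rmass,
                    error=float(diffs[k] - rmass),
                )
            )
    hops.sort(key=lambda h: (h.start_peak, h.end_peak, h.residue))
    return hops


def build_ladders(
    hops: list[Hop],
    min_len: int = 1,
    max_len: int = 50,
    max_ladders: int = 100_000,
) -> list[PST]:
    """Chain hops (end peak of one = start peak of the next) into maximal
    ladders by depth-first extension, then keep those whose length lies in
    [min_len, max_len].  Sub-chains of a maximal chain are not emitted.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("need 1 <= min_len <= max_len")
    out_edges: dict[int, list[Hop]] = {}
    has_incoming: set[int] = set()
    for h in hops:
        out_edges.setdefault(h.start_peak, []).append(h)
        has_incoming.add(h.end_peak)
    ladders: list[PST] = []

    def extend(chain: list[Hop]) -> None:
        if len(ladders) >= max_ladders:
            return
        nxt = out_edges.get(chain[-1].end_peak)
        if not nxt:
            if min_len <= len(chain) <= max_len:
                ladders.append(
                    PST(hops=tuple(chain), residues="".join(h.residue for h in chain))
                )
            return
        for h in nxt:
            chain.append(h)
            extend(chain)
            chain.pop()

    for start in sorted(out_edges):
        if start in has_incoming:
            continue  # extendable to the left -> not maximal
        for h in out_edges[start]:
            extend([h])
    return ladders


def score_pst(tag: PST, spectrum: SpectrumRecord) -> PST:
    """Populate a tag's component scores.

    rmse      = sqrt(sum of squared hop errors) / N  (N outside the radical —
                deliberately not the textbook RMSE)
    error     = exp(−2·rmse), in (0, 1]
    intensity = mean over hops of the average of the two supporting peaks'
                max-normalized intensities
    length    = N², frequency = intensity × length.
    """
    n = len(tag)
    errors = np.array([h.error for h in tag.hops])
    rmse = float(np.sqrt(np.sum(errors**2)) / n)
    error_score = math.exp(-2.0 * rmse)
    intens = spectrum.intensities
    top = intens.max() if len(intens) and intens.max() > 0 else 1.0
    norm = intens / top
    per_hop = [(norm[h.start_peak] + norm[h.end_peak]) / 2.0 for h in tag.hops]
    intensity = float(np.sum(per_hop) / n)
    len_score = float(n**2)
    return replace(
        tag,
        rmse=rmse,
        error_score=error_score,
        intensity=intensity,
        len_score=len_score,
        freq_score=intensity * len_score,
    )


def extract_tags(
    spectrum: SpectrumRecord,
    hop_tolerance: float = 0.01,
    min_len: int = 3,
    max_len: int = 6,
    rmse_tolerance: float | None = None,
    max_tags: int | None = None,
    table: ResidueMassTable | None = None,
) -> list[PST]:
    """Full tag workflow: hops -> ladders -> rmse filter -> scores.

    ``rmse_tolerance`` drops tags whose cumulative error exceeds the bound
    before scoring; ``max_tags`` keeps only the highest-frequency tags (for
    pipeline throughput on noisy spectra).
    """
    hops = extract_hops(spectrum, hop_tolerance, table=table)
    tags = build_ladders(hops, min_len, max_len)
    scored = [score_pst(t, spectrum) for t in tags]
    if rmse_tolerance is not None:
        scored = [t for t in scored if t.rmse <= rmse_tolerance]
    scored.sort(key=lambda t: (-t.freq_score, -t.error_score, t.residues))
    if max_tags is not None:
        scored = scored[:max_tags]
    return scored


def count_overlapping(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def score_protein_psts(protein: ProteinEntry, tags: list[PST]) -> float:
    """Tag-evidence score of one protein: sum over tags of
    Occurrence × (error score + frequency score).

    Occurrence counts overlapping substring matches of the tag in the
    sequence, in both reading directions (N-terminal ion series read a tag
    forward, C-terminal series read it reversed); palindromic tags are counted
    once.  I is collapsed to L on the protein side to mirror tag extraction.
    """
    seq = protein.sequence.replace("I", "L")
    total = 0.0
    for tag in tags:
        occ = count_overlapping(seq, tag.residues)
        rev = tag.residues[::-1]
        if rev != tag.residues:
            occ += count_overlapping(seq, rev)
        if occ:
            total += occ * (tag.error_score + tag.freq_score)
    return total
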