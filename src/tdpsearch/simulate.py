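"""Synthetic ground-truth proteoforms and deconvolved MS2 spectra.

The simulator is the inverse of the fragmenter: it draws random protein
sequences, optionally plants PTMs and single-sided truncations, fragments the
resulting proteoform, and degrades the theoretical ladder with peak dropout,
Gaussian mass jitter, log-normal intensities and uniform noise peaks.  Noise
peaks are rejection-sampled away from true fragment masses so that recovery
rates under noise remain interpretable.

What it does *not* emulate: isotope envelopes, charge states, deconvolution
artifacts (harmonics, off-by-one-Da errors) and correlated intensity
structure along ion series.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import AMINO_ACIDS, ResidueMassTable, residue_table
from .fragmenter import Proteoform, fragment
from .peak_io import SpectrumRecord, make_record
from .protein_db import ProteinEntry
from .ptm_search import ModificationSite, PTMDefinition, load_ptm_table


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic data generator."""

    n_proteins: int = 100
    length_range: tuple[int, int] = (50, 200)
    planted_ptms: tuple[str, ...] = ()     # names from the bundled PTM table
    ptm_probability: float = 0.0           # chance a simulated spectrum carries one PTM
    truncation_probability: float = 0.0
    dropout: float = 0.0                   # per-fragment omission probability
    n_noise_peaks: int = 0
    mass_jitter_sd: float = 0.0            # Da, per-peak
    precursor_jitter_sd: float = 0.0       # Da, on the reported precursor
    intensity_lognorm: tuple[float, float] = (0.0, 1.0)  # (mu, sigma) of log intensity
    residue_freqs: dict | None = None      # residue -> weight; default uniform
    noise_guard: float = 0.05              # Da; noise peaks stay this far from true fragments
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.ptm_probability, self.truncation_probability, self.dropout):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def simulate_database(spec: SimulationSpec, rng: np.random.Generator | None = None) -> list[ProteinEntry]:
    """Random protein sequences with uniform (or user-weighted) residue usage."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    if spec.residue_freqs:
        weights = np.array([spec.residue_freqs.get(r, 0.0) for r in AMINO_ACIDS], dtype=float)
        weights /= weights.sum()
    else:
        weights = None
    entries = []
    lo, hi = spec.length_range
    for i in range(spec.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=weights))
        entries.append(ProteinEntry(f"SIM{i:04d}", f"synthetic protein {i}", seq))
    return entries


def simulate_proteoform(
    entry: ProteinEntry,
    spec: SimulationSpec,
    rng: np.random.Generator,
    ptm_table: list[PTMDefinition] | None = None,
) -> Proteoform:
    """Optionally plant one PTM (at a random eligible site) and/or one
    single-sided truncation on a database entry."""
    truncation = None
    if spec.truncation_probability and rng.random() < spec.truncation_probability:
        side = "N" if rng.random() < 0.5 else "C"
        k = int(rng.integers(1, max(2, len(entry.sequence) // 4)))
        truncation = (side, k)
    prof = Proteoform(base=entry, truncation=truncation)
    if spec.planted_ptms and spec.ptm_probability and rng.random() < spec.ptm_probability:
        if ptm_table is None:
            ptm_table = load_ptm_table()
        by_name = {p.name: p for p in ptm_table}
        ptm = by_name[spec.planted_ptms[int(rng.integers(len(spec.planted_ptms)))]]
        seq = prof.sequence
        eligible = [i + 1 for i, r in enumerate(seq) if r in ptm.target_residues]
        if eligible:
            pos = int(eligible[int(rng.integers(len(eligible)))])
            prof = Proteoform(
                base=entry,
                truncation=truncation,
                modifications=(ModificationSite(pos, ptm, 1.0),),
            )
    return prof


def simulate_spectrum(
    proteoform: Proteoform,
    mode: str,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
    table: ResidueMassTable | None = None,
) -> SpectrumRecord:
    """Deconvolved MS2 spectrum of one proteoform under the study conditions."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if table is None:
        table = residue_table()
    frags = fragment(proteoform, mode, (), table)
    true_masses = np.array([f.mass for f in frags])
    keep = rng.random(len(true_masses)) >= spec.dropout
    masses = true_masses[keep]
    if spec.mass_jitter_sd:
        masses = masses + rng.normal(0.0, spec.mass_jitter_sd, size=len(masses))
    mu, sigma = spec.intensity_lognorm
    intensities = rng.lognormal(mu, sigma, size=len(masses))

    if spec.n_noise_peaks and len(true_masses):
        lo, hi = float(true_masses.min()), float(true_masses.max())
        noise = []
        while len(noise) < spec.n_noise_peaks:
            m = rng.uniform(lo, hi)
            if spec.noise_guard and np.min(np.abs(true_masses - m)) < spec.noise_guard:
                continue
            noise.append(m)
        masses = np.concatenate([masses, noise])
        intensities = np.concatenate(
            [intensities, rng.lognormal(mu, sigma, size=len(noise))]
        )

    precursor = proteoform.mass(table)
    if spec.precursor_jitter_sd:
        precursor += rng.normal(0.0, spec.precursor_jitter_sd)
    if len(masses) == 0:  # total dropout with no noise: keep the record valid
        masses, intensities = np.array([precursor / 2]), np.array([0.0])
    return make_record(
        spectrum_id or f"sim:{proteoform.base.accession}",
        precursor,
        masses,
        intensities,
        fragmentation_mode=mode,
    )


def clean_complementary_ladder(
    rng: np.random.Generator,
    length: int = 20,
    tolerance: float = 2.2,
    precursor_error: float = 1.0,
    table: ResidueMassTable | None = None,
):
    """Complete b/y ladder of a random peptide whose *only* in-tolerance
    fragment-pair sums are the complementary pairs (sum = neutral mass).

    Random sequences occasionally produce a coincidental cross-pair sum within
    the selection window; such draws are rejected — the same guard the noise
    model applies — so mass-tuner recovery on this fixture is unambiguous.
    Returns (spectrum record, true neutral mass); the reported precursor is
    jittered uniformly by up to ``precursor_error`` Da.
    """
    if table is None:
        table = residue_table()
    letters = np.array(list(AMINO_ACIDS))
    while True:
        seq = "".join(rng.choice(letters, size=length))
        prefix = np.cumsum([table.masses[r] for r in seq])
        true_mass = prefix[-1] + table.water_mass
        b = prefix[:-1]
        y = prefix[-1] - prefix[:-1] + table.water_mass
        masses = np.concatenate([b, y])
        sums = masses[:, None] + masses[None, :]
        iu = np.triu_indices(len(masses), k=1)
        near = np.abs(sums[iu] - true_mass) <= tolerance + precursor_error
        if np.all(np.abs(sums[iu][near] - true_mass) < 1e-6):
            reported = true_mass + rng.uniform(-precursor_error, precursor_error)
            rec = make_record("ladder", reported, masses, np.ones(len(masses)))
            return rec, true_mass


def write_fasta(entries: list[ProteinEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.accession} {e.description}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def simulate_dataset(
    spec: SimulationSpec,
    outdir: str | os.PathLike,
    mode: str = "CID",
    n_spectra: int | None = None,
) -> tuple[Path, Path, Path]:
    """Emit FASTA + MGF + truth TSV for a full synthetic study; returns paths."""
    from pyteomics import mgf as _mgf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    db = simulate_database(spec, rng)
    fasta_path = outdir / "database.fasta"
    write_fasta(db, fasta_path)
    ptm_table = load_ptm_table()
    n_spectra = n_spectra if n_spectra is not None else len(db)
    chosen = rng.choice(len(db), size=n_spectra, replace=n_spectra > len(db))
    mgf_path = outdir / "spectra.mgf"
    truth_path = outdir / "truth.tsv"
    mgf_entries = []
    with open(truth_path, "w") as truth:
        truth.write("spectrum_id\taccession\tmodifications\ttruncation\tprecursor_mass\n")
        for n, idx in enumerate(chosen):
            prof = simulate_proteoform(db[int(idx)], spec, rng, ptm_table)
            rec = simulate_spectrum(prof, mode, spec, rng, spectrum_id=f"sim{n:04d}")
            mgf_entries.append(
                {
                    "m/z array": rec.masses,
                    "intensity array": rec.intensities,
                    "params": {"title": rec.spectrum_id, "pepmass": rec.precursor_mass},
                }
            )
            mods = ";".join(f"{s.ptm.name}@{s.position}" for s in prof.modifications) or "-"
            trunc = f"{prof.truncation[0]}:{prof.truncation[1]}" if prof.truncation else "-"
            truth.write(
                f"{rec.spectrum_id}\t{prof.base.accession}\t{mods}\t{trunc}\t{rec.precursor_mass:.6f}\n"
            )
    _mgf.write(mgf_entries, str(mgf_path), file_mode="w")
    return fasta_path, mgf_path, truth_path
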