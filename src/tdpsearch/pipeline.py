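"""End-to-end search orchestration.

Per spectrum: tune the precursor mass, shortlist database proteoforms by
intact mass (including single-sided truncations and predicted variable-PTM
combinations), score tag evidence, fragment and match survivors, optionally
run the blind PTM search on the best preliminary candidates, combine the
component scores, and finally assign target-decoy q-values and E-values
across the whole run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chem import DEFAULT_LOSSES, residue_table
from .errors import ConfigurationError
from .fragmenter import Proteoform, enumerate_truncations, fragment
from .mass_filter import score_mass
from .mass_tuner import TunerConfig, tune_mass
from .matcher import count_matched_peaks, match
from .peak_io import SpectrumRecord, read_batch, read_spectra, write_results
from .protein_db import load_fasta, make_decoys, theoretical_mass
from .pst_engine import extract_tags, score_protein_psts
from .ptm_search import (
    apply_fixed,
    blind_ptm_search,
    enumerate_modified_proteoforms,
    load_ptm_table,
    predict_variable_sites,
)
from .stats_scoring import (
    PrSM,
    assign_q_values,
    e_value,
    final_score,
    sequence_log_probabilities,
)

log = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Every knob of the search pipeline; serializable to/from YAML."""

    database: str = ""
    spectra: str = ""
    spectrum_format: str = "auto"
    batch: bool = False
    output: str = ""
    precursor_mass: float | None = None      # for flat-text input
    fragmentation_mode: str | None = None    # override the per-record mode

    tune_mass: bool = True
    tuner_tolerance: float = 2.2
    tuner_step: float = 0.1

    mass_tolerance: float = 2.2              # Da, intact-mass shortlist
    mass_score_form: str = "bounded"

    pst_enabled: bool = True
    pst_tolerance: float = 0.01              # Da, hop matching
    pst_rmse_tolerance: float = 0.01
    pst_min_len: int = 3
    pst_max_len: int = 6
    pst_max_tags: int = 200

    match_tolerance_ppm: float = 15.0
    consecutive_bonus: str = "from_third"
    intensity_map: str = "step"
    losses: list = field(default_factory=list)  # [[name, delta], ...]
    truncation: bool = True

    ptm_table: str | None = None
    fixed_mods: list = field(default_factory=list)
    variable_mods: list = field(default_factory=list)
    ptm_threshold: float = 0.0
    max_variable_sites: int = 3
    blind_ptm: bool = False
    blind_top_k: int = 10

    w_mass: float = 1.0
    w_pst: float = 1.0
    w_insilico: float = 1.0

    mass_mode: str = "monoisotopic"
    n_decoys_per_target: int = 3
    n_mutations: int = 3
    decoy_seed: int = 1
    top_n_per_spectrum: int = 10
    fdr_threshold: float | None = None
    evalue_threshold: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SearchConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _candidate_proteoforms(entry, exp_mass, cfg, table, var_ptms):
    """Mass-shortlisted proteoforms of one database entry."""
    if cfg.truncation:
        profs = enumerate_truncations(entry, exp_mass, cfg.mass_tolerance, table)
    else:
        profs = []
        if abs(theoretical_mass(entry.sequence, table) - exp_mass) <= cfg.mass_tolerance:
            profs.append(Proteoform(base=entry))
    if not var_ptms:
        return profs
    out = []
    for prof in profs:
        sites = []
        for ptm in var_ptms:
            sites.extend(predict_variable_sites(prof.sequence, ptm, cfg.ptm_threshold))
        for cand in enumerate_modified_proteoforms(prof, sites, cfg.max_variable_sites):
            if abs(cand.mass(table) - exp_mass) <= cfg.mass_tolerance:
                out.append(cand)
    return out


def run_search(config: SearchConfig, spectra: list[SpectrumRecord] | None = None):
    """Run the full search.  Returns the ranked PrSM list (and writes the
    results table when ``config.output`` is set)."""
    table = residue_table(config.mass_mode)
    targets = load_fasta(config.database)
    decoys = make_decoys(
        targets, config.n_decoys_per_target, config.n_mutations, config.decoy_seed
    )
    db = targets + decoys
    ptm_table = load_ptm_table(config.ptm_table)
    by_name = {p.name: p for p in ptm_table}
    try:
        fixed_ptms = [by_name[n] for n in config.fixed_mods]
        var_ptms = [by_name[n] for n in config.variable_mods]
    except KeyError as exc:
        raise ConfigurationError(f"unknown PTM name {exc}") from None
    losses = [tuple(l) for l in config.losses]

    if spectra is None:
        if config.batch:
            spectra = read_batch(config.spectra, config.spectrum_format, config.precursor_mass)
        else:
            spectra = read_spectra(config.spectra, config.spectrum_format, config.precursor_mass)

    log_probs = sequence_log_probabilities(db)
    frag_cache: dict[tuple[str, str], np.ndarray] = {}
    all_prsms: list[PrSM] = []
    n_failed = 0
    for spectrum in spectra:
        try:
            all_prsms.extend(
                _search_spectrum(
                    spectrum, db, config, table, fixed_ptms, var_ptms,
                    losses, ptm_table, log_probs, frag_cache,
                )
            )
        except Exception:
            n_failed += 1
            log.exception("search failed for %s; skipping", spectrum.spectrum_id)
    ranked = assign_q_values(all_prsms)
    if config.fdr_threshold is not None:
        ranked = [p for p in ranked if p.q_value is not None and p.q_value <= config.fdr_threshold]
    if config.evalue_threshold is not None:
        ranked = [p for p in ranked if p.e_value is not None and p.e_value <= config.evalue_threshold]
    if config.output:
        write_results(ranked, config.output)
    if n_failed:
        log.warning("%d spectra failed and were skipped", n_failed)
    return ranked


def _search_spectrum(
    spectrum, db, cfg, table, fixed_ptms, var_ptms, losses, ptm_table, log_probs, frag_cache
):
    mode = cfg.fragmentation_mode or spectrum.fragmentation_mode
    exp_mass = spectrum.precursor_mass
    if cfg.tune_mass:
        tuned = tune_mass(
            spectrum, TunerConfig(tolerance=cfg.tuner_tolerance, step=cfg.tuner_step)
        )
        exp_mass = tuned.mass
        log.info(
            "%s: precursor %.4f -> %.4f (%d pairs)",
            spectrum.spectrum_id, spectrum.precursor_mass, exp_mass, tuned.n_pairs,
        )

    pst_on = cfg.pst_enabled and cfg.w_pst != 0
    tags = (
        extract_tags(
            spectrum,
            hop_tolerance=cfg.pst_tolerance,
            min_len=cfg.pst_min_len,
            max_len=cfg.pst_max_len,
            rmse_tolerance=cfg.pst_rmse_tolerance,
            max_tags=cfg.pst_max_tags,
            table=table,
        )
        if pst_on
        else []
    )

    candidates = []  # (proteoform, mass_score, pst_score, match_result)
    pst_cache: dict[str, float] = {}
    for entry in db:
        for prof in _candidate_proteoforms(entry, exp_mass, cfg, table, var_ptms):
            if fixed_ptms:
                prof = apply_fixed(prof, fixed_ptms)
                if abs(prof.mass(table) - exp_mass) > cfg.mass_tolerance:
                    continue
            ms = score_mass(exp_mass, prof.mass(table), cfg.mass_tolerance, cfg.mass_score_form)
            if prof.base.accession not in pst_cache:
                pst_cache[prof.base.accession] = (
                    score_protein_psts(prof.base, tags) if pst_on else 0.0
                )
            mres = match(
                spectrum,
                fragment(prof, mode, losses, table),
                cfg.match_tolerance_ppm,
                cfg.consecutive_bonus,
                cfg.intensity_map,
            )
            candidates.append((prof, ms, pst_cache[prof.base.accession], mres))

    def prelim(c):
        return final_score(c[1].score, c[2], c[3].score_insilico, cfg.w_mass, cfg.w_pst, cfg.w_insilico)

    candidates.sort(key=lambda c: (-prelim(c), c[0].base.accession))

    if cfg.blind_ptm:
        refined = []
        for rank, (prof, ms, sp, mres) in enumerate(candidates):
            residual = exp_mass - prof.mass(table)
            tol_da = prof.mass(table) * cfg.match_tolerance_ppm * 1e-6
            if rank < cfg.blind_top_k and abs(residual) > tol_da:
                blind = blind_ptm_search(
                    spectrum, prof, cfg.match_tolerance_ppm, ptm_table, mode, losses, table,
                    consecutive_bonus=cfg.consecutive_bonus, intensity_map=cfg.intensity_map,
                )
                if blind.position is not None and blind.match.score_insilico > mres.score_insilico:
                    prof = dataclasses.replace(
                        prof, unexplained_shift=blind.shift, shift_position=blind.position
                    )
                    mres = blind.match
                    log.info(
                        "%s: blind shift %+.4f at %d (%s)",
                        spectrum.spectrum_id, blind.shift, blind.position, blind.characterization,
                    )
            refined.append((prof, ms, sp, mres))
        candidates = sorted(refined, key=lambda c: (-prelim(c), c[0].base.accession))

    # database-wide match counts (unmodified entries) for spectral probabilities
    counts = {}
    for entry in db:
        key = (entry.accession, mode)
        if key not in frag_cache:
            frag_cache[key] = np.array(
                [f.mass for f in fragment(Proteoform(base=entry), mode, (), table)]
            )
        counts[entry.accession] = count_matched_peaks(
            spectrum.masses, frag_cache[key], cfg.match_tolerance_ppm
        )
    count_arr = np.array([counts[e.accession] for e in db])

    prsms = []
    best_decoy_kept = False
    for i, (prof, ms, sp, mres) in enumerate(candidates):
        if i >= cfg.top_n_per_spectrum and (best_decoy_kept or not prof.base.is_decoy):
            continue
        qualify = count_arr >= mres.n_matched
        spectral_prob = float(np.exp(_logsumexp_masked(log_probs, qualify))) if qualify.any() else 0.0
        prsms.append(
            PrSM(
                spectrum_id=spectrum.spectrum_id,
                proteoform=prof,
                score_mass=ms.score,
                score_pst=sp,
                score_insilico=mres.score_insilico,
                score_final=prelim((prof, ms, sp, mres)),
                n_matched=mres.n_matched,
                e_value=e_value(min(1.0, spectral_prob)),
            )
        )
        if prof.base.is_decoy:
            best_decoy_kept = True
    return prsms


def _logsumexp_masked(log_probs: np.ndarray, mask: np.ndarray) -> float:
    from scipy.special import logsumexp

    return float(logsumexp(log_probs[mask]))
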