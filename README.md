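# tdpsearch

Proteoform identification from top-down proteomics data: a library and CLI
that searches deconvolved intact-protein MS2 spectra against a protein
database and ranks proteoform–spectrum matches (PrSMs).

In top-down proteomics whole proteoforms — a base sequence plus its
post-translational modifications (PTMs) and truncations — are fragmented
intact. After upstream deconvolution, each MS2 scan is a list of neutral
monoisotopic fragment masses with relative intensities, plus a precursor
intact mass. `tdpsearch` is aimed at people who have such peak lists (MGF,
mzML, mzXML, or two-column flat text) and a FASTA database, and want ranked,
statistically validated identifications including modified and truncated
proteoforms and *unknown* mass shifts.

## The search pipeline

1. **Intact-mass tuning.** Complementary N-/C-terminal fragments sum to the
   precursor mass plus a fixed ion-chemistry offset (for neutral b/y
   fragments, b_i + y_(L−i) = M exactly). All peak-pair sums near the
   reported precursor are collected, a proton-mass-wide window slides over
   them in user-defined steps, and the most populated window's
   intensity-weighted mean becomes the tuned mass — correcting deconvolution
   precursor errors from the MS2 evidence itself.
2. **Intact-mass filter.** Candidates (including all single-sided
   truncations, computed incrementally from prefix sums) are kept when
   |Mass_exp − Mass_theo| ≤ Thr and scored with a function of the printed
   form 2^(1/Mass_diff), bounded into [0, 1] by default
   (Score_mass = clamp(2^(1/diff) − 1, 0, 1), = 1 at diff = 0, = 0 past Thr).
3. **Peptide sequence tags (PSTs).** Peak pairs whose mass difference matches
   a residue mass within tolerance become *hops*; chained hops form de novo
   sequence tags. A tag scores Error_score = e^(−2·RMSE) (RMSE =
   √Σε²⁄N), Intensity_PST (mean supporting-peak intensity), Len_score = N²
   and Freq_score = Intensity_PST·Len_score; a protein earns
   Score_PST = Σ Occurrence·(Error_score + Freq_score) over tags found in its
   sequence (both reading directions).
4. **Spectral comparison.** Theoretical b/y (CID/HCD), c/z (ETD/ECD), a/x
   (EDD) or all-six (UVPD) fragment ladders — with neutral losses, fixed and
   propensity-predicted variable PTMs — are matched one-to-one against the
   spectrum at a ppm tolerance. Matched peaks contribute their step-mapped
   intensity (0.001 below 9.2×10⁻⁵ of the base peak, else 1), upgraded to
   1.5 from the third consecutive match in a series;
   Score_insilico = Σ MatchScore ⁄ #experimental peaks.
5. **Blind PTM search.** When the tuned precursor disagrees with the
   candidate's mass, the residual shift is slid across every residue position
   and re-matched; the best-scoring position localizes the shift, which is
   then named from a bundled Unimod-style PTM table (or reported
   "unexplained").
6. **Scoring and statistics.** Score_final = (W₁·Score_mass + W₂·Score_PST +
   W₃·Score_insilico)/3. A shuffled-and-3×-mutated decoy database (three
   decoys per target) yields FDR = (2·DB + DO)/(TO + TB + DB) and q-values;
   E-values come from a database residue-frequency spectral probability,
   EValue = 0.693·P(matches ≥ t).

## Worked example

Simulate a ground-truth study (20 proteins, 5 spectra at 15% fragment
dropout with 10 noise peaks each), then search it:

```bash
cat > sim.yaml <<EOF
n_proteins: 20
length_range: [50, 150]
dropout: 0.15
n_noise_peaks: 10
seed: 11
EOF
tdpsearch simulate --spec sim.yaml --out demo --n-spectra 5
tdpsearch search --database demo/database.fasta --spectra demo/spectra.mgf \
    --output demo/results.tsv --decoy-seed 11
```

which prints `24 proteoform-spectrum matches` and writes a ranked TSV whose
top rows are:

```
spectrum_id          accession  is_decoy  score_mass  score_pst  score_insilico  score_final  n_matched  e_value      q_value
spectra.mgf:sim0001  SIM0019    0         1           44.0735    1.27329         15.4489      151        2.82714e-52  0
spectra.mgf:sim0004  SIM0017    0         1           25.1737    1.19118         9.12163      92         3.39556e-10  0
spectra.mgf:sim0002  SIM0012    0         1           21.8606    1.29375         8.05146      230        2.08804e-113 0
```

Reading the first row: spectrum `sim0001` matched target protein `SIM0019`
with a perfect intact-mass score (1), strong tag evidence (44.1), an
in-silico score above 1 (151 matched fragments with long consecutive runs),
a vanishing E-value and q-value 0 — a confident identification, and indeed
the protein that generated the spectrum (`demo/truth.tsv`). The same search
runs from Python via `tdpsearch.SearchConfig` + `tdpsearch.run_search`, and
every stage (tuner, tag extractor, fragmenter, matcher, blind PTM search) is
importable on its own.

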