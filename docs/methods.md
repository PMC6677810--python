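# Methods

This note records the model choices, defaults, numerical conventions and
known limitations behind `tdpsearch`. The package implements a top-down
proteoform search: each MS2 spectrum (deconvolved to neutral monoisotopic
fragment masses) is scored against candidate proteoforms from a FASTA
database, and matches are validated with target-decoy q-values and
spectral-probability E-values.

## Mass conventions

All arithmetic is on neutral monoisotopic masses. An intact chain weighs the
sum of its residue masses plus one water (18.010565 Da: N-terminal H,
C-terminal OH). The residue table ships as package data at 5-decimal
precision and is cross-checked against pyteomics in the test suite; an
average-mass table of the same shape backs `mass_mode="average"`.

Ion series are expressed as the bare residue sum of the fragment plus a
fixed offset: a = −CO (−27.994915), b = 0, c = +NH₃ (+17.026549),
x = +CO+H₂O−H₂ (+43.989830), y = +H₂O (+18.010565), z (z-dot radical)
= +1.991841. Fragmentation modes map to series as CID/HCD/IRMPD/SID/BIRD →
b/y, ECD/ETD → c/z, EDD → a/x, UVPD → all six; the mapping is overridable
per mode. A `paper_offsets` switch instead adds a hydroxyl to every
N-terminal ion and a proton to every C-terminal ion — a nonstandard
convention kept available for fidelity with older tooling, but not the
default because matching real deconvolved data requires standard chemistry.
Default neutral losses are H₂O (−18.010565) and NH₃ (−17.026549); users may
add arbitrary positive or negative deltas.

## Precursor mass tuner

Complementary fragment pairs sum to the precursor mass plus a
chemistry-dependent constant c: 0 for b/y (neutral masses), +1.007825 for
c/z•, −2.015650 for a/x. Pair sums within ±`tuner_tolerance` (default
2.2 Da, the conventional allowance for ±1 Da isotope errors plus margin) of
the reported precursor + c are collected; windows one proton wide
(1.007276 Da) slide from the smallest sum in steps of `tuner_step` (default
0.1 Da — resolving well inside the proton window); the window with the most
sums wins, ties broken by larger total pair intensity, then lower window
start; the tuned mass is the intensity-weighted mean of the winning window's
sums minus c. With no in-tolerance pairs the reported precursor is returned
flagged `not_tuned`. The sliding scan is checked against a brute-force
evaluation of every window placement in the tests.

## Sequence tags

Hops are taken over *all* peak pairs, not only adjacent peaks
(adjacency-only breaks on interleaved N-/C-terminal series); Leu/Ile are
collapsed to L (identical mass), Lys/Gln (0.036 Da apart) are disambiguated
by the hop tolerance (default 0.01 Da) and both are emitted when both fit.
Ladders are the maximal chains of the hop graph (cycles are impossible since
masses strictly increase); sub-chains are not emitted separately, and chains
outside [`pst_min_len`, `pst_max_len`] (defaults 3–6) are dropped — the
range filters out anomalously short or long ladders. A consequence worth
knowing: on a perfectly clean, complete ladder the single maximal chain is
long and is filtered out, so Score_PST can be 0 on noiseless synthetic
spectra while remaining informative on realistic (dropout-broken) ones.

Tag scores follow the printed forms exactly: RMSE = √(Σε²)/N with N outside
the radical — deliberately not the textbook RMSE; Error_score = e^(−2·RMSE);
per-hop intensity is the mean of the two supporting peaks' max-normalized
intensities; Len_score = N²; Freq_score = Intensity·Len_score. A protein's
Score_PST sums Occurrence × (Error_score + Freq_score), where Occurrence
counts overlapping substring matches of the tag and of its reverse (a tag
read off C-terminal ions appears reversed); palindromic tags are counted
once. Tags with RMSE above the user bound are dropped before scoring, and
the pipeline keeps at most `pst_max_tags` (200) highest-frequency tags per
spectrum for throughput.

## Intact-mass score

The printed score form 2^(1/Mass_diff) grows without bound as the
difference vanishes, which cannot be averaged with the other components.
Default `bounded` form: 1 at diff = 0, clamp(2^(1/diff) − 1, 0, 1) on
(0, Thr], 0 beyond — it preserves the printed functional form, is strictly
decreasing, and meets both endpoint conditions. The raw form stays available
as `mass_score_form="paper_raw"`.

## Spectral comparison

Intensities are max-normalized and step-mapped: 0.001 below 9.2×10⁻⁵, else
1 (a logistic alternative with midpoint 9.2×10⁻⁵ is available as
`intensity_map="sigmoid"`). Matching is one-to-one — candidate
peak–fragment pairs within the ppm tolerance (default 15 ppm; 25 is the
other commonly used setting) are assigned greedily by ascending |ppm error|,
ties to the lower series index — preventing double counting. Consecutive
matched fragments along a series earn the 1.5 bonus from the third
consecutive match onward (non-retroactive; `consecutive_bonus="retroactive"`
upgrades whole runs). Score_insilico divides by the number of experimental
peaks, so it is bounded by 1.5 and exceeds 1 only for near-complete
consecutive coverage.

## PTMs

Fixed modifications decorate every target-residue occurrence;
terminal/chemical ones apply once at their terminus. Variable sites are
predicted by the product of residue occurrence propensities over a window
centered on the site (width 1 by default — the site residue alone), emitted
above `ptm_threshold`; all subsets of predicted sites up to
`max_variable_sites` (3) are enumerated, hard-capped at 10⁴ proteoforms per
protein with lowest-scoring sites dropped first. The bundled 26-entry PTM
table uses Unimod-style deltas and order-of-magnitude propensities; it is a
schema-compatible stand-in for a full modification database and is fully
user-replaceable (same TSV schema).

The blind search localizes a single unexplained shift (positive or
negative): the residual between tuned precursor and candidate mass is
hypothesized at each residue position in turn — moving every fragment that
contains the position — and the position maximizing Score_insilico wins
(smallest position on ties). The shift is named when a table entry's delta
lies within ±0.01 Da and its targets include the residue at the chosen
position. One shift per spectrum; multi-shift search is out of scope.

## Decoys, FDR, E-values

Decoys are uniform permutations of each target followed by 3 substitutions
at distinct positions (never to the same residue), three decoys per target;
generation is reproducible from `decoy_seed`. FDR uses the paired
convention: per spectrum the best target and best decoy are kept, and at a
score threshold TO/DO count spectra where only the target/decoy search
passes, TB/DB where both pass with target/decoy better;
FDR = (2·DB + DO)/(TO + TB + DB), q-values are the running minimum from the
bottom of the ranked list, clamped to [0, 1] (raw values above 1 are
logged). The symbols' pairing semantics are this package's reconstruction —
the accounting that makes the printed ratio coherent.

Spectral probabilities use a database residue-frequency model: each
sequence's probability is the product of its residues' database frequencies,
computed in log space and renormalized over the database (raw products
underflow at protein length); the spectral probability at threshold t is the
normalized mass of sequences achieving ≥ t matches, and
EValue = 0.693 × SpectralProbability. Match counts for this step use a fast
nearest-fragment peak count over every (unmodified) database entry rather
than the strict one-to-one assignment — an O(db) approximation per spectrum
that only enters the E-value, never the ranking. This frequency model is an
approximation to generating-function spectral probabilities, not a
replacement for them.

## Synthetic data

The generator draws uniform-residue sequences (or a user frequency vector),
optionally plants one PTM and/or one single-sided truncation, fragments the
proteoform, and degrades the ladder with per-fragment dropout, Gaussian mass
jitter, log-normal intensities, and uniform noise peaks. Noise peaks are
rejection-sampled at least `noise_guard` (0.05 Da) away from true fragment
masses so recovery rates under noise are interpretable; the same principle
defines the tuner's clean-ladder fixture, which rejects random sequences
whose non-complementary cross-pair sums coincidentally land inside the
pair-selection window (about 1% of random 20-mers; a single such weight-1/20
straggler can pull the window mean right past the step/2 recovery bound).
The simulator does **not** emulate isotope envelopes, charge states,
deconvolution artifacts (harmonics, ±1 Da errors beyond precursor jitter) or
intensity correlation along series — so passing recovery tests demonstrate
algorithmic correctness, not robustness to real instrument artifacts.

Study sizes used by the tests and the acceptance script: 100 proteins of
50–200 residues plus 3× decoys searched with 50 spectra at 10% dropout and
5 noise peaks for identification; 100 trials each for tuner, tag and
blind-PTM recovery (proteins of 25–40 residues for localization); 1000
random proteoforms for fragment-mass conservation; 1000 paired
target/decoy score draws (correct targets N(10,1), null targets and decoys
N(7,1), 20% null) for FDR calibration.

## Degenerate inputs and tie-breaks

Duplicate peak masses within 10⁻⁶ Da are merged (intensities summed);
zero-intensity peaks are retained. All-zero intensity spectra map every peak
to 0.001 with a warning. Spectra with <2 peaks yield no pair sums and fall
back to the reported precursor. Empty mass-filter shortlists are allowed; a
spectrum whose search raises is logged and skipped without aborting the run.
Candidate ordering and every tie-break (window choice, match assignment,
blind position, output sorting) are deterministic, so identical
configuration + seeds give byte-identical results files.

## Limitations

No internal fragments, double-sided truncations or amino-acid
substitutions; one blind shift per spectrum; Da-level (not ppm) intact-mass
tolerance; the E-value model is the frequency approximation described above;
no protein quantitation. Batch directories accept all four formats (a
superset of flat-text-only batch processing).
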