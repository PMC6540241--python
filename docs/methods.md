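# Methods

## Antisense pairing tables and enumeration

The pairing tables are *derived*, never hard-coded: for every amino acid,
each of its codons in the standard genetic code (translation table 1,
obtained from Biopython) is base-wise complemented and translated. Two
reading conventions are supported. In the 3′→5′ reading the complementary
codon keeps the positional order of the sense codon (no reversal); in the
5′→3′ reading it is the reverse complement. Complementary codons that land
on a STOP are dropped from the pair set; on the standard table no residue
loses all of its partners in either direction, and the builder raises if a
non-standard table ever produced an empty set rather than emit one silently.
Because base complementation is an involution at codon level, the pairing
relation is symmetric (b ∈ pairs[a] ⇔ a ∈ pairs[b]); the test suite checks
all 400 ordered pairs in both directions.

Antisense candidates are aligned N→C with the sense peptide position by
position in both direction modes; the candidate ensemble is the Cartesian
product of per-position pair sets, emitted in lexicographic order
(deterministic, duplicates impossible). For RHSLFHP the 3′→5′ ensemble has
12 members and the 5′→3′ ensemble 1152 — the quantitative content of the
rule of thumb that 3′→5′ reading is the practical design direction. Both
numbers are verified in the tests against a brute-force oracle that
enumerates every codon spelling, complements, translates and collects
distinct peptides. `direction_comparison` computes counts as products of
pair-set sizes so the (potentially astronomical) 5′→3′ ensemble is never
materialised. DNA input (T) is normalised to RNA (U) on ingestion.

## Epitope profiling

Ten heterogeneous web servers are commonly consulted for linear B-cell
epitope prediction; this package instead ships five self-contained,
published methods so the consensus is reproducible offline: Kyte–Doolittle
hydropathy (oriented low-is-epitope), Parker hydrophilicity, Emini surface
probability (a windowed *product* of fractional surface probabilities
scaled by 0.37^window, per the original formulation), Chou–Fasman β-turn
propensity, and a windowed EIIP profile. ML-based predictors are not
reimplemented — they have no implementable closed description. The EIIP
windowed profile is oriented high-is-epitope; this is a pragmatic choice
(the EIIP scale itself carries no published epitope orientation) and only
affects the consensus vote, not any spectral quantity.

Window defaults to 9 residues everywhere — the one window size with
literature precedent in this workflow. Edge positions are clamped to the
nearest full-window value instead of averaging truncated windows, which
would otherwise manufacture spurious votes at the termini. Consensus
calling z-scores each profile (constant profiles are skipped with a
warning — they cannot be z-scored and carry no information), orients it,
and lets a residue vote when its normalised score is positive. Maximal runs
with vote fraction ≥ 0.5 and length ≥ 5 (defaults; no literature value
exists for either) become calls, ranked by mean vote then mean normalised
score. Calls are disjoint by construction.

The informational spectrum method maps residues to EIIP values, removes the
mean, and takes the discrete Fourier amplitude spectrum on frequencies
(0, 0.5] cycles/residue. Amplitudes carry a Parseval normalisation (the sum
of squared amplitudes equals the signal energy), which fixes an otherwise
arbitrary DFT scaling and makes the energy check a testable invariant.
Cross-spectra zero-pad the shorter signal onto the longer one's frequency
grid and multiply amplitudes element-wise; the peak marks a common
frequency component.

## Paratope consensus

Candidates are decomposed into overlapping k-mers (k = 4 by default,
matching the quadripeptide motif convention) and scored ungapped against
every width-k window of a user-supplied antibody reference FASTA with
BLOSUM62 (from Biopython's substitution matrix collection). A full
exhaustive scan replaces a heuristic BLAST search deliberately: the search
space — a handful of 4-mers against a reference FASTA — needs no seeding
heuristics, and exhaustive scanning makes the selection deterministic and
reproducible. The hit threshold defaults to 11 half-bits (BLOSUM62 4-mer
identity scores run roughly 16–44, so 11 admits conservative substitutions
while rejecting noise); both matrix and threshold are configurable.
Ranking is by motifs covered, then total best-hit score, then
lexicographically — a fully specified tie-break. The packaged demonstration
antibody segments are synthetic framework-like sequences carrying the four
reference motifs; recovering the published consensus paratope from a real
antibody database is *not* claimed (no database/version is specified
anywhere to reproduce), only that the ranking machinery selects the correct
candidate when its motifs are present.

## Binding analysis

**Isotherm.** `complex_concentration` evaluates the 1:1 mass-action root in
the form `2AB/(S + √(S² − 4AB))`, which is algebraically identical to the
textbook `(S − √(…))/2` root but avoids catastrophic cancellation when the
complex approaches the limiting total. It agrees with a bisection oracle to
1e-10 relative over a six-decade grid (tested), and is clamped to
[0, min(A, B)] against rounding at the stoichiometric limit.

**Identifiability and the fitter.** With the labeled total *L* constant,
the general signal model `baseline + s_free·(L − AB) + s_complex·AB`
collapses to `intercept + slope·AB`: the three linear coefficients are not
separately identifiable from one titration, so the fitter estimates the
full identifiable set (log₁₀ Kd, intercept, slope). Fitting on log₁₀ Kd
enforces positivity and conditions the problem. For robustness without a
multi-start: the two linear parameters are profiled out by linear least
squares on a 29-point log-spaced Kd grid (10⁻³–10⁴ µM), and the best grid
point seeds one trust-region refinement with tight (1e-15) tolerances.
The profiled objective is smooth and unimodal in log Kd for 1:1 data, so
the grid-plus-polish reliably finds the global optimum at a fraction of a
multi-start's cost. The Kd standard error is the asymptotic
curvature-based error of log₁₀ Kd mapped through the delta method; flat or
otherwise unidentifiable data yields `converged=False` (singular curvature
or non-finite SE), never a silent estimate. Noiseless synthetic titrations
are recovered to 1e-6 relative with r² = 1 within 1e-9 (tested).

**Signal modes.** Fluorescence titrations are modeled with an emitting
complex plus a small free-species term; MST as normalised fraction bound
(`signal = AB/L`, the form binding-affinity software reports), which maps
onto the affine model with s_free = 0; MPEIA with the same solution-phase
isotherm (bead-surface depletion is ignored — a documented simplification,
consistent with fitting all three experiments with one model). Dye
photophysics and thermophoresis physics are not modeled. The noise model is
multiplicative Gaussian with a coefficient of variation (default 2% in the
validation harness), seeded through `numpy.random.default_rng`;
heteroscedastic weighting is off by default.

**Study-condition designs.** The MST/fluorescence titrant design is a
16-point two-fold serial dilution from 2.8 mM (reaching 0.0854 µM); the
MPEIA design is a 7-point two-fold ladder from 70 µM (reaching 1.09375 µM).
The fluorescence experiment's own concentration design is not published, so
the validation harness reuses the wide MST design for it — a documented
substitution. The constant labeled-species total is set to 1 µM, a
realistic spectroscopic working concentration below all three dissociation
constants. Generating Kd values for the validation harness are 2.6 µM
(fluorescence), 24.3 µM (MST) and 24.6 µM (MPEIA). Monte-Carlo validation
uses 200 replicates per mode, which completes in seconds and pins the mean
estimate to well under the 10% acceptance band.

**SVD species counting.** Singular values of the wavelength × titration
intensity matrix are compared to
`max(noise_level·√(matrix size), 0.01·s₁)`: the first term is the expected
scale of the largest singular value of an i.i.d. noise matrix, the second
discards numerically negligible components. The synthetic two-species
spectra mix Gaussian emission profiles for free species (340 nm, σ 22 nm)
and complex (365 nm, σ 28 nm) weighted by the isotherm's free and complex
concentrations — rank 2 by construction; the one-species control emits
from the complex only.

## Peptide masses

Average (isotope-abundance-weighted) masses are the default because vendor
peptide specifications quote average molecular weights; monoisotopic mode
sits behind a flag. Residue and water masses come from Biopython's
`molecular_weight`. N-terminal biotinylation adds biotin (244.31 Da
average) minus one water, i.e. 226.2954 Da, reflecting amide conjugation to
the α-amine; this convention reproduces all four vendor-quoted reference
masses (893.02, 930.07, 970.15, 1000.14 Da) within ±0.02 Da. A C-terminal
single-residue tag (e.g. the tryptophan added to make a ligand fluoresce)
is appended before summation.

## What the synthetic data does and does not show

The synthetic harness emulates the *designs* of the three binding
experiments — their concentration ranges, a constant labeled species, 1:1
mass action, multiplicative noise. It does not emulate instrument drift,
inner-filter effects, bead-surface depletion, pipetting error correlated
across a dilution series, or aggregation at high peptide concentration.
Passing the recovery tests therefore shows that the estimator is unbiased
and precise *under the stated model*, not that any particular laboratory
titration meets that model. Likewise the epitope-consensus vote is a
documented substitute for a multi-server consensus, and the paratope
ranking demonstrates recoverability of a known answer from references
containing its motifs — neither claims to reproduce unversioned external
services.

## Numerical choices at a glance

| Quantity | Default | Why |
|---|---|---|
| profile window | 9 residues | the one size with precedent in this workflow |
| vote threshold / min length | 0.5 / 5 | no published value; majority vote, septapeptide-scale regions |
| k-mer size | 4 | quadripeptide paratope motif convention |
| motif hit threshold | 11 half-bits | admits conservative substitutions, rejects noise |
| Kd grid | 10⁻³–10⁴ µM, 29 points | brackets any plausible peptide affinity |
| optimizer tolerances | 1e-15 | noiseless round-trips to 1e-6 relative |
| SVD rel_tol | 0.01·s₁ | discards numerical rank only |
| labeled total | 1 µM | realistic working concentration below all Kd values |
| noise CV | 2% | typical well-run titration reproducibility |
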