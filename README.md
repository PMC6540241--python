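# antisense

A toolkit for designing short peptide ligands against protein epitopes by
**antisense (complementary) peptide translation**, and for quantifying how
well the designed ligand binds its target.

Monoclonal antibodies are the default reagent for recognising a protein
biomarker, but short synthetic peptides are cheaper to make, more stable,
and penetrate tissue better. The antisense-peptide idea offers a purely
sequence-based route to such ligands: translate the nucleotide strand
complementary to the one encoding the target (sense) peptide, and the
resulting "antisense" peptide tends to bind the sense peptide. This package
implements that design route end to end as a three-step workflow:

1. **Epitope selection** — score a protein with classic linear B-cell
   epitope propensity methods (Kyte–Doolittle hydropathy, Parker
   hydrophilicity, Emini surface probability, Chou–Fasman β-turn propensity,
   an EIIP profile, plus the informational spectrum method) and call
   consensus regions by a vote across z-normalised profiles.
2. **Antisense design** — derive amino-acid complementary pairing tables
   from the genetic code, enumerate every antisense candidate for the chosen
   epitope (the 3′→5′ reading yields far fewer degenerate candidates than
   5′→3′), decompose candidates into overlapping k-mer "paratope motifs",
   and rank candidates by ungapped BLOSUM62 motif homology against an
   antibody reference set. The top candidate is the consensus paratope.
3. **Binding evaluation** — fit the dissociation constant *K*d of the
   epitope–paratope complex from titration data (fluorescence, microscale
   thermophoresis, or magnetic-particle immunoassay formats), count
   spectrally active species by SVD, and simulate titrations for validation.

## The binding model

A 1:1 complex at equilibrium,

    A + B ⇌ AB,    Kd = [A][B] / [AB],

with one species held at constant total concentration *L* and the partner
titrated at totals *T*, has complex concentration

    AB = 2·L·T / (S + √(S² − 4·L·T)),    S = L + T + Kd,

the numerically stable root of the mass balance. The observed signal is
affine in AB (`intercept + slope·AB`), which covers fluorescence
(complex-emission), MST (fraction-bound) and plate-absorbance titrations
alike. `fit_kd` profiles the linear coefficients over a log-spaced Kd grid,
then polishes (log₁₀ Kd, intercept, slope) by trust-region least squares and
reports the curvature-based standard error and r².

## Worked example

The package's reference design is the human prostate specific antigen (hPSA)
epitope **RHSLFHP** (residues 53–59). Enumerating its 3′→5′ antisense
ensemble, ranking against an antibody reference FASTA containing the four
quadripeptide motifs, and checking the biotinylated ligand's mass:

```
$ antisense fixtures --out-dir demo            # demonstration inputs
$ antisense paratope --sense RHSLFHP --refs demo/demo_antibodies.fasta
[
 {
  "candidate": "AVRDKVG",
  "covered_motifs": 4,
  "total_score": 80.0
 },
 ...
]
```

The sense peptide RHSLFHP has 12 antisense candidates in the 3′→5′ reading
(1152 in 5′→3′); **AVRDKVG** ranks first with all four of its motifs (AVRD,
VRDK, RDKV, DKVG) found in the references at a summed BLOSUM62 score of 80
half-bits.

```
$ antisense mass --peptide AVRDKVG --nterm biotin
{
 "sequence": "AVRDKVG",
 "n_term_mod": "biotin",
 "average_mass": 970.15,
 ...
}
$ antisense fit --csv demo/titration_mst.csv
{
 "kd_uM": 23.188956035129742,
 "kd_se_uM": 1.140199955314373,
 "r2": 0.9986671816671616,
 "converged": true,
 "mode": "mst"
}
```

The biotinylated ligand weighs 970.15 Da, and refitting the simulated MST
titration (generated with *K*d = 24.3 µM and 2% noise) recovers
23.2 ± 1.1 µM with r² ≈ 0.999 — one noisy replicate scatters around the
generating value, which is why validation averages many replicates.

Other commands: `antisense enumerate`, `antisense epitope`,
`antisense species`, `antisense simulate`, `antisense design` (the full
pipeline with a run manifest). `antisense <cmd> --help` shows options.

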