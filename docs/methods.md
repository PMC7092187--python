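# Methods

## Scope and model

`neoedit` maps protein substitution variants to population-scale HLA class I
presentation and quantifies immunoediting in a tumor cohort as the depletion
of presentation-capable genotypes among patients whose tumors harbor the
corresponding variants. The core modelling assumptions are:

* **9-mer epitopes only.** A substitution at residue *p* of a protein of
  length *L* appears in the 9-mers starting at `max(1, p−8) .. min(p, L−8)`:
  nine windows for interior residues, fewer near the termini. Terminal
  variants are kept with their reduced window count rather than discarded —
  discarding them would silently bias silence calls toward the interior.
  Coordinates are 1-based, inclusive, on protein residues.
* **Strong binding = %rank ≤ 0.5 (inclusive).** The threshold is
  configurable; per (variant, allele) the best (minimum) %rank over the
  variant's mutant windows decides the call, ties broken by lower affinity,
  then lexicographically smaller peptide.
* **Population carrier model.** Within each locus genotypes follow
  Hardy–Weinberg equilibrium (two independent draws); the three loci are
  independent and linkage is disregarded. The carrier probability of an
  allele set with per-locus summed frequencies `f_L` is
  `1 − Π_L (1 − f_L)²`. Ignoring linkage slightly underestimates expected
  carrier frequencies, biasing editing estimates toward the conservative
  side. A single-draw "allelic" union `1 − Π_a (1 − f_a)` is available via
  `mode="allelic"` for sensitivity analysis; diploid is the default
  everywhere.
* **Regional combination is a union probability.** The regional score at a
  residue is the population fraction presenting *at least one* covering
  9-mer — the carrier probability of the union of the covering windows'
  strong-binding allele sets. This is the only combination that keeps the
  score a population fraction in [0, 1]; a mean-of-windows alternative is
  available behind `combine="mean"` for sensitivity analysis. Signal-peptide
  or other masked ranges can be supplied per protein (`mask=(lo, hi)`); no
  masking is automatic.

## Statistical tests

The estimand at every level is an observed:expected ratio (0 = complete
editing, 1 = none); the choice of tail tests follows the minimal assumptions
consistent with that structure, and each is a single seam that can be
swapped:

* **Allele level** — eligible patients are the unique patients harboring
  ≥ 1 variant strongly bound by the allele ("unique set" semantics: a patient
  counts once however many qualifying variants they carry; patients are
  treated as exchangeable). Observed is the carrier count among them;
  expected is the HWE carrier frequency `1 − (1 − f)²`; the p-value is the
  one-sided exact binomial lower tail. An allelic-frequency mode (copies out
  of 2n, expectation f) is behind a flag. Tests default to alleles above 5%
  population frequency — the comparison is powered only for common alleles.
* **Variant level** — with per-occurrence carrier probability `p_v` and `n`
  occurrences, the binder-carrying occurrence count is Binomial(n, p_v)
  under the null; observing zero has probability `(1 − p_v)^n` exactly.
  Silent variants are flagged and skipped, not scored 0/0.
* **Patient / histology level** — each non-silent harbored variant *i*
  contributes its carrier probability `p_i`; the observed presentable count
  follows a Poisson-binomial distribution under the null. Its exact lower
  tail is computed by dynamic-programming convolution (O(n²), exact for the
  cohort sizes used here; validated against exhaustive enumeration and the
  equal-p binomial special case). Histologies pool `p_i` and observed counts
  over their patients, so a single-patient histology reduces to the patient
  test.
* **Multiplicity** — Benjamini–Hochberg step-up across alleles.
* **Affinity comparison between allele groups** — Welch's t on
  log-affinities (predicted IC50s are approximately log-normal), with group
  means reported on the nM scale.
* **Silence enrichment** — observed fraction of (patient, variant)
  occurrences that are silent versus the unweighted silent fraction of the
  characterised variant universe, one-sided binomial.
* **Ligandome concordance** — the statistic is the mean regional score at
  the detected (deduplicated) positions; the null draws equal-sized position
  sets uniformly without replacement from all positions with a defined
  score; p = (r + 1)/(n + 1).

Exact one-sided binomial p-values are discrete and conservative: strict
uniformity under the null is unattainable at small sample sizes, and the
calibration tests therefore use cohorts large enough (≈10³ eligible
patients) that the discreteness deficit is negligible against the KS band.
No mid-p or randomised p-values are used.

Composite per-allele scores: `underrepresentation = max(0, 1 − ratio)`
(over-represented alleles score zero — the score is meaningful only for
depletion), `editing score = breadth × underrepresentation`, and
`population contribution = editing score × allele frequency`.

## Synthetic predictor

The built-in `MotifPredictor` scores a 9-mer for an allele as a sum of
per-position amino-acid log-weights in which the anchor rows (peptide
positions 2 and 9) carry the dominant dynamic range — reproducing the
anchor-residue biology of class I binding without trained weights. Scores
are converted to %rank by quantile lookup against a fixed background of
100,000 pseudo-random 9-mers drawn once from a seeded generator, so ranks
are calibrated (a random peptide's rank is uniform on [0, 100] within
Monte-Carlo error) and fully deterministic given the allele
parameterisation. Affinity in nM is a fixed monotone map of rank spanning
~20 nM (rank 0) to 50,000 nM (rank 100); rank order and affinity order
agree, so tie-breaking by affinity only matters for records from external
predictors, where the two scales are independent. Only 9-mers are scored;
other lengths are rejected.

## Synthetic cohort generator

The generator emulates the structure of a population-scale tumor cohort:

* **Panel** — per-locus frequencies from a symmetric Dirichlet scaled to a
  locus coverage (default 0.9 of each locus's mass, mirroring a
  common-allele panel that covers most but not all of the population); a
  residual `OTHER` allele per locus absorbs the remaining mass and binds
  nothing, so genotype sampling never assumes the panel is exhaustive.
  Default 10 alleles per locus ≈ the ~30 common alleles a well-powered
  allele-level analysis tests.
* **Genotypes** — two independent draws per locus (HWE), homozygotes
  possible.
* **Variants** — distinct substitutions sampled uniformly over proteome
  sites and alternate residues; defaults (a few hundred variants on a
  handful of proteins, ~5 somatic driver variants per patient) keep the
  full pipeline runnable in seconds while leaving per-variant window counts,
  silence fractions and per-allele breadths in realistic ranges.
* **Editing** — a candidate variant presented by the patient's genotype
  survives with probability `Π (1 − e_a)` over the edited alleles shared
  between its binding set and the genotype; unpresented candidates always
  survive. Patients with zero surviving variants are re-drawn, because a
  tumor cohort contains only diagnosed tumors — this survivor conditioning
  is what makes underrepresentation estimable. For a variant bound by a
  single allele with carrier frequency *c*, the carrier frequency among
  patients harboring it is `c(1 − e)/(1 − ce)`; the estimator is validated
  against this closed form.
* **Silent multiplicity** — silent variants' per-patient inclusion rate can
  be multiplied to exercise the silence-enrichment test.
* **Ligandome** — detected positions are drawn without replacement with
  probability ∝ `exp(bias × regional score)`; bias 0 is the uniform null
  the concordance test must not reject.

What the generator does **not** emulate: mutational signatures and hotspot
clustering, linkage disequilibrium between HLA loci, clonal evolution beyond
single-step elimination, expression/processing effects on presentation, and
the trained specificities of real predictors. Passing tests therefore
demonstrate correctness of the arithmetic and calibration of the estimators
under the stated model — not predictive accuracy on real tumors.

## Numerical and design choices

* Determinism: every stochastic component takes a seed or Generator; the
  predictor background seed is fixed independently of the panel, and
  identical configs reproduce byte-identical pipeline outputs.
* %rank ties: background comparison uses "strictly greater", so a peptide
  better than the whole background gets rank exactly 0 (a strong binder).
* Degenerate inputs: proteins shorter than 9 residues, reference
  mismatches, out-of-bounds positions, non-substitution rows and
  non-canonical residues are rejected with typed reasons rather than
  crashing the run; empty allele sets give carrier probability exactly 0.
* Region tiling ranks by carrier probability, ties by more alleles then
  lower start, making output deterministic.
* `run_pipeline` executes windows → predict → aggregate → map → profiles →
  editing, writes each stage as TSV plus a JSON manifest (input checksums,
  config, seed, row counts, written atomically). Re-running a single stage
  from cached upstream output is done through the per-stage CLI commands;
  the in-process `run` command recomputes all stages.
* Test problem sizes: the calibration experiments use 1,000 replicate
  cohorts of 1,000 patients (null uniformity) and 3 × 200 replicates of
  3,000 patients (efficiency recovery in a rare-allele regime, f = 0.02);
  the Monte-Carlo oracle for carrier probabilities uses 200,000 genotypes.

## Known limitations

* The Poisson-binomial DP is quadratic; for cohorts pooling ≫10⁴ non-silent
  variant occurrences a normal or saddlepoint approximation would be needed.
* Carrier probabilities ignore HLA linkage disequilibrium (conservative for
  editing, but anti-conservative if used as a coverage guarantee for vaccine
  design).
* The variant-level and allele-level tests treat occurrences/patients as
  independent; shared clonal origin or population stratification would
  violate this.
* External predictor input is adapter-based and limited to 9-mers with
  (peptide, allele, affinity_nM, percent_rank) columns.
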