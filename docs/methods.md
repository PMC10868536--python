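# Methods

This note documents the models implemented in `featuregp`, the design of
the synthetic-data generator, the numerical choices that matter, and the
problem sizes used by the test suite. Nothing here states an empirical
result that the tests or `scripts/acceptance.py` do not themselves compute.

## Phenotype adjustment and pre-correction (`pheno`)

Growth and carcass records taken near (not at) the 100 kg endpoint are
standardised with the industry formulas:

* **AGE** (days to 100 kg): `age − (weight − 100)/CF`,
  `CF = (weight/age) × m`, with `m = 1.826` for sire-line and `1.715` for
  dam-line animals. At exactly 100 kg the adjustment is the identity.
* **ADG**: `100 / AGE_adj` (kg/day).
* **BF, LMD** (mm): `value × A / (A + B·(weight − 100))` with sex-specific
  `(A, B)`: BF sire 13.47/0.1115, dam 15.65/0.1566; LMD sire 50.52/0.228,
  dam 52.01/0.228. The denominator is positive throughout the plausible
  weight range (30–150 kg); a nonpositive denominator is rejected loudly.
* **LMP** (%): `61.21920 − 0.77665·BF + 0.15239·LMD`, evaluated on the
  *adjusted* BF and LMD. The formula is labelled "adjusted to 100 kg", so
  its inputs are taken to be the 100 kg-adjusted depths; this is a
  documented assumption, and the function accepts any finite inputs if a
  caller prefers raw depths.

"Sire"/"dam" constants are mapped to animal sex (male/female). Fixed-effect
pre-correction is ordinary least-squares residualisation on dummy-coded
covariates with the grand mean re-added, so `mean(y_c) = mean(y)` to
machine precision; the minimum-norm solve makes redundant factor levels
harmless. This stands in for dedicated BLUP software whose adjusted
phenotype output is, for a purely fixed model, exactly the OLS residual.

## Genotype QC (`qc`)

Defaults: individual call rate > 0.90, variant call rate > 0.90,
MAF > 0.05, HWE exact p > 1e-6, autosomes only. All inequalities are
strict (a variant at MAF exactly 0.05 fails) — the literal reading of the
stated thresholds. The HWE test is the exact conditional test computed by
the standard heterozygote-count recurrence, without mid-p correction; the
test suite checks it against a log-gamma enumeration oracle to 1e-12 for
all tables with n ≤ 50. HWE is tested within each population by default
(a variant failing in any population is removed), with a pooled option;
filter order is individuals → variants (call rate, MAF, HWE), and the
variant filter is idempotent.

## Variant classification and panels (`annotate`)

Gene models are strand-aware single-transcript structures (exons, CDS with
frame, UTRs) read from GFF3. Classification is positional: upstream /
downstream are the 5 kb flanks *in transcription orientation* (mirroring a
gene to the − strand swaps which physical flank is which); within a gene,
UTR labels take precedence over the exon test, positions in no exon are
introns; coding SNVs are translated (reference vs alternate codon, minus
strand handled by complementing the alternate allele) into synonymous or
missense; coding INDELs and SNVs whose stated reference allele disagrees
with the FASTA are classified by position only. A variant overlapping
several genes keeps every label it earns, so class panels may share
variants and class proportions can sum past 100%. Anything farther than
5 kb from every gene is intergenic.

Class panels are equal-size uniform subsamples (without replacement,
seeded) — fixing panel size removes marker count as a confounder when
classes are compared as prediction features. The default class set for
panel building is {intergenic, intron, upstream, downstream}: UTR and
synonymous classes hold so few variants on desk-scale genomes that the
"min" size rule would collapse every panel to a handful of markers; they
can be requested explicitly. Panels are intersected with the prediction
dataset's variants (identity = chrom:pos:ref:alt) before use, and for the
chip+panel GFBLUP scenario the panel is deduplicated against the chip so
no marker enters both genetic components.

## Relationship matrices (`kinship`)

VanRaden method 1: `G = ZZ'/(2Σp_j(1−p_j))` with `Z` the dosage matrix
centered by `2p_j`, `p_j` the observed alternate-allele frequency of the
analysis sample, missing dosages imputed at `2p_j` (zero contribution).
`G_f` and `G_r` are each scaled by their own `2Σp(1−p)` so both have
near-unit mean diagonals — the λ-weighted combination assumes comparable
scales. IBS similarity is allele-sharing `(2 − |g_i − g_k|)/2` averaged
over shared non-missing sites. LD summaries use squared Pearson
correlation of dosages (composite LD), the standard surrogate for unphased
data; genotype-dosage r² equals haplotype r² under HWE.

## Variance components (`varcomp`)

*Single GRM:* exact REML via one eigendecomposition of `G`. The restricted
likelihood is profiled to the single ratio `δ = σe²/σg²`; a 121-point
log-grid bracket followed by bounded Brent search on `log δ` locates the
optimum, and both components are recovered in closed form. The test suite
verifies the optimum against an independent dense-matrix grid search to
Δloglik < 1e-6.

*Two GRMs:* average-information REML with EM-REML for the first three
iterations and as a fallback. Two safeguards matter in practice:

* **Active-set AI.** A component pinned at the variance floor with a
  downhill gradient is held fixed rather than included in the AI solve;
  otherwise the clamped step distorts the update of the free components
  and the algorithm degenerates into geometric EM creep.
* **Step halving.** When feature and remainder markers are in LD the two
  GRMs are correlated and the likelihood has a ridge; a full AI step can
  overshoot. Fractions 1, 1/2, 1/4, 1/8 of the step are tried and the
  first that does not decrease the restricted likelihood is taken.

Convergence: |Δloglik| < 1e-8 and relative component change < 1e-6
(floored components excluded from the latter), cap 100 iterations.
Components are floored at `1e-8·var(y)` rather than allowed negative; a
component finishing on the floor is flagged `boundary`. If `G_f = G_r`
numerically, only `σf²+σr²` is identifiable; the fit is flagged
non-identifiable and GFBLUP refuses to interpret λ.

Fixed effects default to an intercept only, since phenotypes are
pre-corrected upstream.

## Association and preselection (`assoc`)

EMMAX approximation: null components from single-GRM REML, then every
variant tested by GLS with `V = Gσ̂g² + Iσ̂e²` held fixed. One
eigendecomposition whitens phenotype, intercept and all genotype columns,
reducing each test to weighted simple regression (Wald 1-df chi-square).
Monomorphic variants are flagged untested, never silently dropped. The
candidate variant stays in the GRM (no leave-one-chromosome-out); proximal
contamination is accepted and documented. With `G = I` the scan reduces
exactly to per-variant OLS. Under permutation nulls at n=1000, m=5000 the
genomic inflation factor is within [0.9, 1.1] and p-values are
KS-uniform (verified in the acceptance tests).

The FDR threshold is the proportional rule `p_thr = FDR·N/M` (N = count of
p < 0.05, M = tested count) with FDR = 0.05; when every variant is below
0.05 the threshold equals the FDR. Benjamini–Hochberg is available behind
an explicit call for comparison, never as the default. Traits whose
discovery GWAS yields an empty panel simply have no GWAS scenario — the
pipeline skips them with a log entry.

## Prediction (`predict`)

GEBV for unphenotyped animals are conditional expectations:
`ĝ = σg²·G[:, ref]·V_rr⁻¹(y_ref − μ̂)` with
`V_rr = G_rr σg² + I σe²` and `μ̂` by GLS — algebraically identical to
solving Henderson's mixed-model equations with missing records (verified
against a hand-built MME solve to 1e-10, and against marker-effect ridge
regression to 1e-6). A ridge of 1e-6 is added to the diagonal only if the
Cholesky factorisation fails, and never stored. GFBLUP builds
`G_total = λG_f + (1−λ)G_r` and runs the same computation with genetic
variance `σf²+σr²`; with λ at 0 or 1 it reduces exactly to GBLUP on the
corresponding matrix.

Cross-validation: random folds of near-equal size (differing by ≤ 1),
variance components re-estimated on the training animals of every fold —
λ is never informed by validation animals. Accuracy is the raw Pearson
correlation between GEBV and corrected phenotype (not divided by h).
Default is fivefold with one repetition; repeats are configurable (5×5
gives 25 rounds). Fold assignment is seeded and recorded so any run is
exactly repeatable, and scenarios run with the same seed have paired folds,
which `compare_scenarios` exploits for paired differences.

## Synthetic data (`simdata`)

The generator emulates a commercial pig breeding setting in which real
genotypes are proprietary: a large validation population (default 2000)
plus a small discovery population (default 250), chip- and sequence-density
marker sets on a shared genome, LD over tens of kb, six growth traits
(AGE, ADG, BF, LMA, LMD, LMP) with realistic baselines and phenotypic SDs,
and a truth table (QTL, effects, true breeding values, realised h²).

* **Genome.** Random nucleotide sequence; non-overlapping genes on both
  strands, each with 5′UTR, a CDS of 100–300 codons split over 2–4 exons
  (start codon, no internal stops, terminal stop; length divisible by 3),
  introns of 1–6 kb, 3′UTR. Placement keeps the genic fraction at or
  below 60% of each chromosome and fails loudly when the requested density
  cannot fit. The resulting class geometry puts most variants in
  intergenic + intron, about 6% in each 5 kb flank, and makes UTR /
  coding classes rare — the qualitative shape of real annotation tables.
* **Genotypes.** Ancestral frequencies ~ Uniform(0.05, 0.95); population
  divergence by Balding–Nichols (Beta-distributed per-population
  frequencies with parameter Fst, default 0.10) — the simplest generative
  model that reproduces within- vs cross-population IBS separation.
  Haplotypes copy one of K = 4 founder haplotypes per 50 kb block, so r²
  is high within a block and decays to zero at the block length. These
  two defaults were calibrated to the LD profile reported for pig
  populations: measured on the generator, mean r² ≈ 0.31 at 0–10 kb,
  halving by ~30 kb, near zero beyond 50 kb. With `ld_block_bp = 0` sites
  are independent (no LD). Genotypes are sums of two independent
  haplotypes, so HWE holds within a population. The chip is an evenly
  spaced subsample of dense positions (always a subset). Missing calls are
  injected at 1% by default to exercise QC.
* **Phenotypes.** Per trait, `n_qtl` loci (default 50) with Gaussian
  effects; a configurable fraction can be forced into one genomic class to
  create feature-enriched architectures. The residual is orthogonalised
  against the genetic values in sample and scaled so the realised h²
  equals the target exactly; genetic and residual parts are then jointly
  rescaled to a realistic phenotypic SD per trait. Gaussian effects match
  GBLUP's own assumption, making parameter recovery a fair test. Raw
  "measured" fields (weight, age, BF, LMD, sex) are emitted so the
  endpoint-adjustment formulas can run on simulated records.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: pedigree/family structure (individuals are
unrelated draws, so prediction accuracy comes from marker–QTL LD rather
than relationship capture), recombination maps and realistic allele
frequency spectra, imputation error (the dense panel is observed, not
imputed), INDELs, selection, and genotype–environment effects.

## Problem sizes used by the test suite

Chosen as desk-scale versions of the study conditions:

* GRM diagonal and GWAS calibration: n = 1000, m = 5000 (20 permutation
  replicates for the null scan).
* Heritability recovery: 20 independent replicates at n = 2000,
  m = 10000, h² = 0.3; the single-replicate sampling SD of ĥ² there is
  ≈ 0.05 (it scales like √(2m)/n), so the mean of 20 carries an SE near
  0.011 and is checked against the target within ±0.03. A null phenotype
  at n = 200 has SD ≈ 0.12, which is why the null check asserts the bulk
  of the distribution, not individual estimates.
* Feature-weight recovery: n = 1000, m = 3000 with LD; 20 replicates each
  for the all-QTL-in-panel case (λ̂ > 0.8 expected) and the 50/50 split
  (mean λ̂ in [0.35, 0.65]).
* Prediction patterns: n = 800, m = 3000 dense / 300 chip; 20 paired seeds
  for the GFBLUP-advantage sign test, 5 seeds for chip-vs-dense parity.

## Known limitations

* Dense linear algebra throughout: O(n³) solves cap practical cohort sizes
  at a few thousand individuals — appropriate for validation-scale
  analyses, not national evaluations.
* One transcript per gene; splice/start/stop consequence classes are out
  of scope (they are rare enough to be excluded from the feature classes).
* The EMMAX approximation ignores per-variant refitting of variance
  components; for the preselection use case this is the standard
  trade-off.
* λ estimated per training fold can sit on a boundary for tiny feature
  panels; such fits are flagged rather than hidden, and GFBLUP then
  reduces toward plain GBLUP on the remainder.
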