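# featuregp

Feature-partitioned genomic prediction for livestock growth traits:
GBLUP and GFBLUP breeding-value estimation with variant panels preselected
by genomic-class annotation or GWAS, plus every stage around them —
phenotype endpoint adjustment, genotype QC, variant classification, genomic
relationship matrices, REML variance components, mixed-model association,
and cross-validated accuracy. A built-in synthetic-data generator emulates
the two-population pig chip/sequence setting the pipeline is designed for,
so the whole stack runs end to end with no external data.

## The problem

Genomic selection predicts an animal's additive genetic merit (GEBV) from
genome-wide markers. Sequence-density data should in principle beat a 50K
chip because it contains the causal variants, yet in practice plain GBLUP
gains little from density alone. One remedy is to *partition* markers using
prior biological information — positional annotation classes (intron,
intergenic, UTR, 5 kb flanks, synonymous) or trait-associated SNPs from a
GWAS in an independent discovery population — and give the prioritised
panel its own variance component.

**GBLUP** fits `y_c = 1μ + g + e` with `g ~ N(0, G σg²)`, where `G` is the
VanRaden genomic relationship matrix `G = ZZ' / 2Σp_j(1−p_j)` and `y_c` is
the fixed-effect-corrected phenotype.

**GFBLUP** splits the genome into a feature set `f` and remainder `r`:
`y_c = 1μ + f + r + e`, `f ~ N(0, G_f σf²)`, `r ~ N(0, G_r σr²)`. After
REML estimation of `(σf², σr², σe²)` the two matrices are collapsed into

    G_total = λ G_f + (1−λ) G_r,   λ = σf² / (σf² + σr²),

and prediction proceeds exactly as GBLUP with total genetic variance
`σf² + σr²`. λ is therefore the estimated share of genetic variance carried
by the feature panel: λ ≈ 1 means the panel captures the architecture,
λ ≈ panel-size share means it is no better than random markers.

GWAS preselection uses a mixed linear model (EMMAX-style: null variance
components fixed, per-variant generalised least squares) with the
proportional FDR threshold rule `p_thr = FDR × N / M`, where `N` is the
number of variants with p < 0.05 and `M` the number tested (deliberately
not Benjamini–Hochberg).

## Worked example

Simulate a cohort whose QTL all fall in introns, then compare whole-genome
GBLUP against GFBLUP with the intron panel as the genomic feature:

```python
from featuregp.simdata import SimConfig, simulate_to_dir
from featuregp.pipeline import ScenarioConfig, run_scenario, compare_scenarios

cfg = SimConfig(
    seed=7, n_chromosomes=2, chrom_length_bp=400_000, n_genes=10,
    n_variants_dense=3000, n_variants_chip=300,
    n_individuals={"validation": 600, "discovery": 150},
    h2_target=0.3, qtl_class="intron", qtl_class_fraction=1.0,
)
simulate_to_dir(cfg, "demo")

a, _ = run_scenario(ScenarioConfig(data_dir="demo", scenario="GBLUP_WGS",
                                   traits=("ADG", "BF", "LMP"), seed=1))
b, _ = run_scenario(ScenarioConfig(data_dir="demo",
                                   scenario="GFBLUP_WGS_PLUS_PANEL",
                                   traits=("ADG", "BF", "LMP"),
                                   panel_source="intron", seed=1))
print(compare_scenarios(a, b).to_string(index=False))
```

Output (fivefold cross-validation, accuracy = Pearson correlation between
GEBV and corrected phenotype in the held-out fold):

```
trait scenario_a            scenario_b  mean_accuracy_a  mean_accuracy_b  mean_difference  percent_improvement
  ADG  GBLUP_WGS GFBLUP_WGS_PLUS_PANEL         0.223434         0.232382         0.008948             4.004984
   BF  GBLUP_WGS GFBLUP_WGS_PLUS_PANEL         0.477635         0.499142         0.021508             4.502950
  LMP  GBLUP_WGS GFBLUP_WGS_PLUS_PANEL         0.417641         0.444973         0.027332             6.544390
```

Because the simulated QTL are intron-enriched, weighting the intron panel
by its estimated variance share lifts accuracy by 0.01–0.03. Re-running
with `qtl_class="uniform"` makes the improvement vanish (differences within
±0.002): a feature panel only helps when the architecture is actually
enriched in it. The same pattern holds for chip vs sequence density —
under uniform QTL placement, `GBLUP_50K` and `GBLUP_WGS` accuracies differ
by less than 0.01.

Five scenario families are available: `GBLUP_50K`, `GBLUP_WGS`,
`GBLUP_CLASS` (one equal-size annotation-class panel), and
`GFBLUP_50K_PLUS_PANEL` / `GFBLUP_WGS_PLUS_PANEL` (feature panel from a
class or from discovery-population GWAS, deduplicated against the base
marker set). A `featuregp` command-line interface wraps each stage
(`simulate`, `adjust`, `precorrect`, `qc`, `annotate`, `panel`, `grm`,
`ld`, `gwas`, `preselect`, `run`).

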