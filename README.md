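# funcneo

Functional (assay-first) neoantigen identification, as a tested Python
library and CLI.

Tumor-specific mutant peptides (neoantigens, NeoAg) are the targets of
personalized cancer vaccines. The dominant discovery strategy filters
somatic mutations by *predicted* MHC I binding (e.g. IC50 ≤ 500 nM), which
confines candidates to CD8+ T cell epitopes and misses much of what T cells
actually see. `funcneo` implements the alternative: select mutations purely
on tumor **expression** evidence, synthesize them as long peptides, and let
pooled IFN-γ ELISPOT with endogenous CD4+ and CD8+ T cells decide what is
immunogenic. The package covers every computational stage of that workflow:

* **Variant cascade** — total → coding → RNA-expressed (≥ 1 variant read) →
  strict (RNA VAF ≥ 20% and ≥ 10 reads) filtering of annotated somatic
  variants.
* **Peptide design** — mutant/wild-type 20-mer pairs with the mutated
  residue anchored at position 6 or 15 (minimally shifted at protein
  termini), 10/15-mer minimal-epitope tiling, and helper–effector constructs
  tethered by a triple-alanine (`-AAA-`) linker.
* **Pooled screening statistics** — the four-criterion ELISPOT positivity
  rule on replicate spot counts: mean SFC ≥ 50, pooled-variance Student
  *t* p < 0.05, stimulation index SI = mean(test)/mean(control) > 2, and a
  Poisson background-exceedance tail P(X ≥ round(mean test) | λ =
  mean(control)) < 0.05.
* **Deconvolution and subset attribution** — positive pools → singleton
  retest list → mutation-level hit table, with CD4/CD8-arm screens labelling
  each hit `CD4_only`, `CD8_only` or `dual`.
* **Prediction audit** — how efficiently an IC50 cutoff would have captured
  the functionally validated epitopes.
* **Synthetic data** — generators for variant tables, toy proteomes and
  ELISPOT plates with planted truth, so the full pipeline is testable
  end-to-end with no external data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from funcneo import (
    SimulationConfig, end_to_end_fixture, screen_fixture,
    cascade_summary, PredictionRecord, screening_efficiency,
)

# a synthetic screen: 200 variants, 39 strictly expressed mutations,
# 4 planted immunogenic (3 CD4-only, 1 dual), 16 pools, 3 wells/condition
cfg = SimulationConfig(
    seed=101, tier_counts=(200, 120, 80, 39), n_proteins=40,
    n_immunogenic=4, immunogenic_labels=("CD4_only",) * 3 + ("dual",),
    lambda_background=10.0, effect_multiplier=15.0, n_pools=16,
)
fx = end_to_end_fixture(cfg)
print(cascade_summary(fx.variants).as_tuple())
result = screen_fixture(fx)
print(result.positive_pool_ids)
print(result.hits[["mutation_id", "gene", "subset_label", "positive_peptides"]])
```

prints

```
(200, 120, 80, 39)
['Pool_02', 'Pool_05', 'Pool_07', 'Pool_08', 'Pool_09', 'Pool_10', 'Pool_14']
  mutation_id     gene subset_label     positive_peptides
0          05  GENE005     CD4_only  Mut_05_a6,Mut_05_a15
1          27  GENE027     CD4_only  Mut_27_a6,Mut_27_a15
2          30  GENE030     CD4_only  Mut_30_a6,Mut_30_a15
3          33  GENE033         dual  Mut_33_a6,Mut_33_a15
```

— the cascade recovers the planted tier counts exactly, 7 of 16 pools screen
positive, and the hit table equals the planted truth: all four immunogenic
mutations recovered, each with both anchor-variant peptides positive and the
correct responding T cell subset.

Auditing a prediction cutoff against functionally validated epitopes:

```python
records = [PredictionRecord("Mut_48.10", "X" * 10, "H-2Kk", 4988.7),
           PredictionRecord("Mut_72", "X" * 10, "H-2Kk", 250.9),
           PredictionRecord("Mut_73", "X" * 10, "H-2Kk", 250.9)]
eff = screening_efficiency(["Mut_48.10", "Mut_72", "Mut_73"], records, cutoff_nm=500)
print(eff.percent, eff.fraction)   # -> 66 2/3
```

A 500 nM pre-filter would have kept 2 of the 3 validated CD8+ epitopes
(66%), discarding the weakly-predicted one — exactly the kind of epitope the
functional approach exists to find.

The same stages are available as a CLI (`funcneo filter`, `design`, `pool`,
`elispot-call`, `deconvolute`, `hits`, `audit`, `simulate`); every stage
reads and writes plain tab-delimited tables or FASTA.

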