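# Methods

`funcneo` implements a *functional* (assay-first) neoantigen identification
workflow: instead of ranking mutations by predicted MHC binding, candidate
mutations are selected purely on tumor expression evidence, synthesized as
long peptides, and screened for actual CD4+/CD8+ T cell IFN-γ responses by
pooled ELISPOT. This note documents the models, rules, parameters and design
choices of each stage, and what the synthetic data do and do not emulate.

## Variant expression cascade

Input is a table of annotated somatic variants with tumor-DNA and tumor-RNA
allele read counts. Three sequential filters:

1. **Coding** — keep every class except `noncoding` (synonymous and
   splice-region variants count as "in coding sequence" at this tier; only
   protein-altering variants are used for peptide design downstream).
2. **Expressed** — `rna_alt_reads >= 1`: at least one tumor-RNA read carries
   the variant base.
3. **Strict** — RNA VAF `rna_alt_reads / rna_depth >= 0.20` **and** at least
   10 RNA reads. Both thresholds are inclusive ("at least"). The read-count
   floor applies to variant-supporting reads by default
   (`strict_reads_mode="alt"`); a `"depth"` mode applies it to total site
   depth instead, since either reading of "at least 10 reads" is defensible.
   VAF is computed from RNA counts: the thresholds describe tumor-RNA
   expression, not DNA clonality. Variants with zero RNA depth have no
   defined VAF and are silently removed at this tier rather than raising.

Filters preserve input order, are idempotent, and each output is a subset of
its input, so tier counts are non-increasing. `filter_strict` and
`filter_rna_expressed` commute whenever the strict read floor is at least the
expressed floor.

## Long-peptide design

For a missense mutation at protein residue *m*, a 20-mer mutant peptide is
emitted per anchor *a* (defaults 6 and 15), spanning residues
`[m − a + 1, m − a + 20]` of the mutant protein, with the wild-type
counterpart over the same window of the reference protein — so each pair
differs at exactly the anchor position. Two anchors sample two flanking
contexts, improving the odds that at least one peptide is processed and
presented on MHC I or II.

Boundary handling: when a window would overrun a protein terminus it is
**shifted minimally** to fit and the realized anchor recorded (a mutation at
residue 3 yields a window starting at residue 1 with realized anchor 3);
windows that coincide after shifting are emitted once. Only when the protein
itself is shorter than the peptide length is the peptide truncated (flagged
`truncated`). Shifting rather than shortening keeps peptide chemistry
(length, synthesis) uniform; the spirit of the rule is that the mutated
residue must always stay inside the peptide, which is asserted by tests.

Alternative splice products are handled by supplying each isoform as its own
protein record; the designer does not model splicing. Frameshift/indel
mutant proteins must be supplied precomputed, with the anchor at the first
altered residue.

**Minimal-epitope tiling** enumerates *every* contiguous window of each
requested length (defaults 10 and 15) that still contains the anchor
residue: offsets `max(1, k − L + 1) .. min(len − L + 1, k)` for anchor *k*.
For a 20-mer with anchor 15 this yields six 10-mers and six 15-mers. All
windows are enumerated because no principled subset rule exists; a user can
select among them downstream.

**Linked constructs** concatenate helper + linker + effector, with a
triple-alanine (`AAA`) linker by default — a minimal, conformationally
neutral tether that physically links a CD4+ helper epitope to a CD8+
effector epitope so both are taken up and presented by the same
antigen-presenting cell.

## Pooling and deconvolution

Peptides are assigned to `n_pools` pools by a seeded shuffle followed by
round-robin dealing: deterministic given (input order, n_pools, seed), pool
sizes differing by at most one (81 peptides into 16 pools gives one pool of
6 and fifteen of 5). Pool composition is otherwise unconstrained — sibling
peptides of one mutation may land in different pools, which is harmless
because deconvolution retests singles.

The screen is two-stage and one-dimensional: pools are called against
control; every member of a positive pool enters the singleton retest list
(union, deduplicated, in pool order). Matrix pooling is out of scope.

Mutation-level rollup: a mutation is a **hit** when at least one of its
peptides is positive at the singleton stage (bulk arm). Sorted-arm screens
attribute the subset: `dual` if both the CD4 and CD8 arms have a positive
peptide for the mutation, `CD4_only`/`CD8_only` if exactly one does, `none`
otherwise. Classification depends only on the arm-level any-positive
indicator, never on which particular sibling peptide fired.

## ELISPOT positivity rule

A stimulus condition (replicate spot-forming-cell counts on a fixed
cells-per-well basis) is positive against its control iff **all four** hold:

| criterion | statistic | threshold | comparison |
|---|---|---|---|
| count | mean test SFC | 50 | inclusive (≥) |
| p | two-tailed pooled-variance Student t, df = n₁+n₂−2 | 0.05 | strict (<) |
| SI | mean(test) / mean(control) | 2 | strict (>) |
| Poisson | P(X ≥ round(mean test)), X ~ Poisson(mean control) | 0.05 | strict (<) |

Numerical conventions: zero pooled variance gives p = 1 for equal means and
p = 0 for unequal means (the limit of the t statistic); a zero-background
control gives an infinite SI with a flag, and the SI criterion then passes
iff the test mean is positive; the Poisson tail uses half-up rounding of the
test mean, with P = 1 when the rounded mean is 0 and P = 0 when the rate is
0 but the signal is not. The count criterion uses the raw test mean;
`background_subtract=True` subtracts the control mean first.

The Poisson criterion deserves emphasis: "Poisson < 5%" is not a standard
named test, and the formulation here — the upper-tail probability that
background alone produces at least the observed mean count — is this
package's documented interpretation, chosen because ELISPOT well counts are
classically modelled as Poisson events. It is deliberately isolated in one
function (`poisson_tail`) so an alternative definition is a one-function
change.

The classic (pooled-variance) Student t is used rather than Welch, matching
the stated test; with equal replicate counts per condition the two differ
little. The choice of control condition (no-peptide wells) is an explicit
argument, never inferred.

Under a null simulation (test and control i.i.d. Poisson(60), 3 wells each)
the conjunction of the four criteria fires essentially never (measured rate
0 in 10,000 trials) — the rule is conservative by construction, dominated by
the joint count + SI requirement.

## Prediction audit

Given external peptide–MHC IC50 predictions (consumed from tables; no
predictor is bundled), `apply_affinity_cutoff` partitions records at a
cutoff (default 500 nM, the conventional pre-screening threshold), with
equality passing. `screening_efficiency` reports what percentage of
*functionally validated* epitopes the cutoff retains, truncated to a whole
percent (2/3 → 66%) with the exact fraction preserved. Truncation is
deliberate: it never overstates how well a prediction-first protocol would
have done. One record per validated id is expected; multi-allele
aggregation (e.g. taking the best affinity) is upstream of the audit.

## Synthetic data

The generator plants a known truth at every stage so recovery is checkable
exactly:

* **Variant table** — tier membership is planted by construction: strict-tier
  variants get VAF ∈ [0.24, 0.8] with ≥ 10 variant reads at ≥ 50× depth;
  expressed-but-not-strict get 1–9 variant reads at depth keeping VAF < 0.20
  (so they fail the strict tier under either read-count mode);
  coding-but-unexpressed get zero variant RNA reads; noncoding variants fill
  the remainder. Default tier counts are (4771, 1481, 270, 39), the scale of
  a real low-TMB squamous-cell screen. Strict variants are missense against
  a uniform-random toy proteome.
* **ELISPOT plates** — well counts are Poisson: background rate λ = 10 SFC
  (a typical clean no-peptide background), immunogenic wells at 15× λ
  (a strong recall response), 3 replicate wells per condition. A
  negative-binomial option (`overdispersion`) exists for robustness testing,
  off by default. The immunogenic effect enters as a rate multiplier, so the
  planted stimulation index is directly config-readable.
* **Planted immunogenicity** — 4 of the strict mutations are immunogenic, 3
  recognized by CD4+ T cells only and 1 by both subsets; all mutant peptides
  of an immunogenic mutation respond (sibling peptides act as internal
  controls), wild-type peptides never do. Pool wells are hot iff the pool
  contains an immunogenic member; sorted-arm singleton wells are hot iff the
  mutation's subset label includes that arm.

All generators are pure functions of (config, seed); each draws from its own
named substream of the global seed, so regenerating one artifact never
perturbs another.

What the synthetic data do **not** emulate: real somatic-variant calling
noise (mapping artifacts, multi-allelic sites, indel realignment), codon
structure or homology in proteins, MHC-binding-driven immunodominance,
plate-position or counting-saturation effects in ELISPOT, or inter-animal
variability. Passing recovery tests therefore demonstrates that the pipeline
machinery is correct and that the decision rule has the intended operating
characteristics under its own count model — not that the thresholds are
optimal for any particular real assay.

## Problem sizes and determinism

The test suite and the acceptance script run the cascade-recovery grid at 21
small configs, the peptide-design oracle at 1,000 random proteins, the null
ELISPOT calibration at 10,000 trials, and end-to-end recovery at 50 seeds of
a 200-variant / 39-strict-mutation screen — sizes chosen so the whole suite
runs in seconds on one CPU while keeping Monte-Carlo error negligible
relative to the asserted margins. All randomness is seeded; hypothesis-based
property tests are derandomized.

## Known limitations

* The VAF/read-count thresholds are calibrated screening choices, not
  statistically derived; the package treats them as parameters.
* One-dimensional pooling cannot separate co-pooled positives without the
  singleton stage; no pool-design optimization is attempted.
* The Poisson criterion interpretation is an assumption (above).
* `screening_efficiency` treats each validated id as one record; tie/allele
  aggregation policy is the caller's.
* Indel/frameshift peptide design requires a precomputed mutant protein.
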