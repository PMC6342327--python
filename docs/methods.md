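# Methods

## Model and procedure

The pipeline infers drug–ageing associations purely from overlap
statistics. Its unit of comparison is the *term*: a gene, a PPI
neighbour, or an annotation category (GO:BP, GO:CC, GO:MF, KEGG,
Reactome). At each of the seven levels:

1. **Drug-related terms.** Each drug's filtered target set is expanded:
   identity at the gene level; first neighbours at combined score ≥ 0.9
   at the PPI level; at annotation levels, every term containing at least
   one target.
2. **Ageing-related terms.** The ageing gene set maps to itself (gene
   level), to its ≥ 0.9 neighbours (PPI), or to the terms found by
   over-representation analysis — hypergeometric upper tail against the
   level's annotated universe, Benjamini–Yekutieli (BY) adjusted, kept at
   adjusted p ≤ 0.05, and for GO:BP truncated to the 500 smallest
   adjusted p-values (the pre-cap count is logged).
3. **Universe.** All terms associated with at least one drug. This makes
   the test conditional on what the interaction data can see: a term no
   drug touches carries no information about relative enrichment.
4. **Exact test.** For each drug the 2×2 table (k, l, m, n) over the
   universe is scored with the one-sided (upper-tail) Fisher exact test.
   One-sided is the appropriate convention here — the question is whether
   a drug hits *more* ageing terms than chance, and the reference
   per-drug results this implementation reproduces follow the same
   convention. The two-sided minimum-likelihood rule is available via
   `sidedness="two_sided_min_likelihood"`.
5. **Effect size.** The conditional maximum-likelihood odds ratio: the ψ
   maximising the Fisher noncentral hypergeometric likelihood of k given
   the margins. It is preferred to the sample cross-product ratio because
   it is defined on boundary tables, and it is the convention the
   reference per-drug odds ratios follow (both are reported in output
   tables). Because E_ψ[X] is strictly increasing in ψ, the MLE is found
   by Brent root-finding on the score equation in log ψ (xtol 1e-12),
   returning 0 / +∞ when k sits on the support boundary and 1 (with a
   warning) for degenerate margins.
6. **Multiplicity.** BY step-up across all tested drugs of a level;
   significance at adjusted p < 0.05. `adjust_by` accepts an explicit
   family size m larger than the supplied list, so the smallest-m head of
   a family (e.g. a published significant-drugs table) can be adjusted
   exactly as the full family would have been.
7. **Ranking and integration.** Drugs sort by ascending p, ties broken by
   descending odds ratio then drug id (determinism). The combined list is
   the arithmetic mean of per-level ranks; the default `intersect` policy
   averages only drugs present in every list, and `penalize_max` charges
   a missing level its list length + 1.

All hypergeometric quantities are evaluated in log space via log-gamma,
so universes of thousands of terms do not overflow.

### Bias permutation and evaluation

The permutation null redraws the ageing-related term set uniformly
without replacement from the level universe at matched size and reruns
the entire ranking (1,000 replicates by default; a master seed spawns one
substream per replicate, so the ensemble is reproducible and
parallelisable). A drug's *bias fraction* is the share of replicates that
rank it as well or better than observed: drugs that rank high against
arbitrary term sets — because they simply have many recorded targets —
are flagged by large fractions. Null term sets are drawn from the
universe rather than from all terms of the annotation, keeping the null
comparable to the observed analysis.

Rankings are evaluated by the cumulative label-recovery curve (rank i
scaled to x = i/N, with a prepended origin) and its trapezoid AUC; the
permutation p-value is the fraction of null replicates with AUC at least
the observed. Between-level agreement uses Kendall tau-b (tie-corrected,
since p-value ties occur) pairwise and the tie-corrected Kendall W across
lists, computed on the drugs common to all lists. The enrichment of
significant drugs for labelled drugs uses the hypergeometric mean and
upper tail with an explicit universe size, because the result is
sensitive to which drug universe the labels are counted in.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `interaction_min_score` | 700 | STITCH-style combined confidence (0–1000); 700 = "high confidence" 0.7 |
| allowed actions | activation, inhibition | restricts to cases where the chemical acts on the protein |
| `ppi_min_score` | 900 | STRING-style cutoff for PPI neighbourhoods, both ageing- and drug-side |
| `min_categories` | 2 | evidence classes (curated, expression, methylation, disease) a gene needs to count as ageing-related |
| `ora_alpha` | 0.05 | BY-adjusted threshold for ageing-side ORA |
| `bp_cap` | 500 | GO:BP keeps only the 500 smallest adjusted p-values |
| `sidedness` | greater | exact-test tail (see above) |
| `alpha` | 0.05 | per-level significance on BY-adjusted p |

Duplicate (drug, protein) rows collapse to the maximum score — the
conservative keep-if-ever-high rule. Identifier resolution is a local
two-column map file, never a network call; when two source ids map to one
drug their target profiles are unioned. A pair recorded with both
activation and inhibition survives as its single maximum-score record;
the ambiguity is tolerated because the statistic uses only target
identity, not direction.

## Synthetic data: what it emulates, what it does not

`SyntheticConfig` defaults describe a study of 1,000 drugs over 3,000
genes with a 450-gene ageing set (15%, matching the share of ageing terms
in a realistic gene-level universe), log-normal targets-per-drug with
mean ≈ 7.4 (the mean of the filtered interaction dataset the generator
emulates), log-normal term sizes (mean ≈ 20), an Erdős–Rényi PPI with
mean degree 4, and scores uniform in [700, 1000] so that confidence
filtering is exercised separately (`score_noise` adds sub-threshold
edges when wanted).

Planting: 10% of drugs draw their ageing-target count from the Fisher
noncentral hypergeometric with odds θ = 5 (the mid-range of realistic
per-drug enrichment effects). The biased urn is chosen deliberately so
that the generative θ is exactly the estimand of the conditional-MLE odds
ratio, enabling estimator-recovery checks; θ = 1 is an exact null.
Labels derive from the planted truth with a 10% noise rate plus 30
anti-longevity labels, so evaluation metrics are non-degenerate.

A fraction (20%) of annotation terms draw their genes with 8-fold weight
on the ageing set. Without this, uniformly assigned terms are never
ORA-enriched and the annotation levels would be empty; the bias emulates
the clustering of ageing genes in real pathway annotations.

Not emulated: the score structure of text-mining evidence channels, GO
DAG topology and ancestor closure (gene sets are taken as given, as in
the analysis itself), correlated drug families with shared targets, and
research-bias artefacts (target counts are independent of planting).
Passing tests on this generator therefore demonstrate correctness of the
statistics and calibration of the procedure — not that real STITCH/GO
inputs would yield any particular discovery rate.

## Numerical choices and degenerate inputs

- Two-sided minimum-likelihood tail uses a 1e-7 relative slack when
  comparing point probabilities, absorbing float ties in symmetric
  tables; a modal observed table returns exactly 1.
- Degenerate margins (empty row/column) return p = 1 and OR = 1 with
  warnings rather than erroring: they arise naturally in permutation
  replicates that draw no term hit by a given drug.
- ORA drops query genes outside the universe with a warning; an empty
  query or universe is an error.
- Permutation replicates skip the odds-ratio root-finding
  (`compute_or=False`): only the order matters there, and ties in p then
  break by the sample odds ratio, which orders identically on shared
  margins.
- Seeds: every stochastic component takes an explicit seed; substreams
  are derived with `SeedSequence.spawn` (per replicate) or a CRC-keyed
  sequence per generator artefact, so artefacts are independent yet
  reproducible.

## Problem sizes used in the checks

The test-suite and acceptance checks run the generator at its default
scale (1,000 drugs) for calibration properties — type-I control averaged
over 20 seeds at θ = 1, planted-drug recovery averaged over 3 seeds at
θ = 5 — and at a reduced 150-drug, 800-gene scale with all five
annotation levels for end-to-end plumbing. Exact-test and odds-ratio
oracle equivalence uses 1,000 random tables with margins up to 30, where
full enumeration of the support is feasible. The chance-level AUC
baseline uses 500 random-label permutations of a 1,000-drug ranking,
reported with tolerance ±0.01.

## Known limitations

- The method infers association, not direction: a top-ranked drug may
  promote or accelerate ageing phenotypes (genotoxic compounds rank high
  for exactly this reason).
- The exact test treats terms as exchangeable; term-term correlation
  (overlapping pathways) is only addressed globally by the conservative
  BY correction, not modelled.
- `intersect` integration silently restricts to well-covered drugs;
  `penalize_max` is provided but changes the interpretation of the
  average.
- The bias permutation redraws the ageing term set directly at each
  level; it does not re-derive ORA terms per draw, so it measures bias
  conditional on the level expansion, not bias of the expansion itself.
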