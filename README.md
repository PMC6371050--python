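# mateperm

Permutation-based analysis of **mate-choice consistency**: do people
repeatedly choose long-term partners with similar characteristics, and how
large is that effect? The package implements the full statistical pipeline
for long-format partner questionnaires — one row per (respondent, partner)
with a father flag and up to 21 numeric traits (3 demographic, 13 physical
on ordinal image scales, 5 TIPI personality domains) — together with a
synthetic-cohort generator so every stage is testable without any real
questionnaire data.

## The statistics

**Consistency index.** For respondent *i* with partner trait values
*t*<sub>*i*1</sub> … *t*<sub>*ip<sub>i</sub>*</sub>, her consistency on a
trait is the mean absolute difference over all unordered partner pairs,

&nbsp;&nbsp;&nbsp;&nbsp;*d<sub>i</sub>* = Σ<sub>*j*&lt;*k*</sub> |*t<sub>ij</sub>* − *t<sub>ik</sub>*| / [*p<sub>i</sub>*(*p<sub>i</sub>* − 1)/2],

and the population index Δ̄ = (1/*n*) Σ<sub>*i*</sub> *d<sub>i</sub>*
weights every respondent equally. Lower Δ̄ = more consistent choice. The
null model reassigns partners to respondents uniformly at random while
preserving each respondent's partner count; the one-tailed p-value is the
fraction of null Δ̄ draws strictly below the observed value.

**Relocation effect size.** The effect of consistency on a trait is the
percentage of partners that must switch respondents before Δ̄ first reaches
its null expectation. Swaps between random partners of different
respondents are proposed uniformly and kept only when they raise Δ̄; each
kept swap relocates two partners. The measure runs 0–50%: the Δ̄-maximal
configuration lies about half of all partners away from any fully
consistent one.

**Shared and cumulative effects.** Because effect sizes are partner
proportions they behave like set measures: E<sub>A</sub> + E<sub>B</sub> =
union + shared, where the union is estimated from directed residual runs
(randomize A to its expectation, then continue on B) and shared overlap is
clamped at zero. Higher-order intersections are apportioned proportionally
to the pairwise segments, and traits accumulate one at a time by maximal
unique contribution into the **maximal cumulative effect size** — the
proportion of partners to relocate to remove consistency on *all* traits
at once.

**Equivalent measures and father contrasts.** Per trait the package also
computes the respondent-attributable variance share (random-intercept REML
mixed model; 10/20/30% = meaningful/medium/large) and a double-entry
within-pair Pearson r, plus their cross-trait equivalence (correlations and
the OLS line of ICC% on relocation%). Father/non-father contrasts comprise
a father-exclusion permutation test (two-tailed) and mixed-model mean and
Levene-style variance contrasts, Benjamini–Hochberg adjusted per family.

## Worked example

```python
from mateperm import (CohortTable, TraitRegistry, TraitSpec,
                      population_delta, respondent_mean_pairwise_diff,
                      shared_effect)
import pandas as pd

# one respondent lists partners scoring 11 and 13; another 5, 10, 7, 14
reg = TraitRegistry([TraitSpec("extraversion", "personality", 2, 14)])
df = pd.DataFrame({
    "respondent_id": ["A", "A", "B", "B", "B", "B"],
    "partner_ordinal": [1, 2, 1, 2, 3, 4],
    "is_father": [0, 1, 0, 0, 0, 1],
    "extraversion": [11, 13, 5, 10, 7, 14],
})
cohort = CohortTable(df, reg)

print(respondent_mean_pairwise_diff([5, 10, 7, 14]))  # 5.0
print(population_delta(cohort, "extraversion"))       # 3.5
print(shared_effect(16, 11, 6, 11))                   # (5.0, 22.0)
```

The first number is respondent B's mean pairwise difference
((5+2+9+3+4+7)/6); the second averages the two respondents' values
((2+5)/2); the third decomposes two effect sizes of 16% and 11% with
directed residuals 6% and 11% into a 5% shared effect and a 22% union.

## The analysis

Numbered drivers under `analysis/` rebuild the full study on a synthetic
537-respondent cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort with reference-shaped ICCs
python analysis/02_consistency_tests.py    # Δ̄ + permutation tests (Table-1 style)
python analysis/03_effect_sizes.py         # relocation effect sizes
python analysis/04_association_measures.py # ICC, pairwise r, equivalence
python analysis/05_shared_cumulative.py    # shared + cumulative effects
python analysis/06_father_contrasts.py     # father exclusion + mixed models
```

On the bundled 21-trait reference table of simple and pairwise shared
effect sizes, stage 05 reports a maximal cumulative effect size of 49.31%
(bracketed by the largest simple effect, 19.4%, and the sum of simple
effects, 138.1%), led by residence, weight, relative height and age
difference. The same stages are scriptable through the `mateperm` CLI
(`simulate`, `consistency`, `effect`, `shared`, `cumulative`, `fathers`,
`run`).

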