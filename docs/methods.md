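# Methods

## Model

A tumour's profile over the 13-gene marker panel is a vector of binary
methylation calls; each call may instead be *uninformative* when the assay
failed or gave an irreproducible melt. The model is strictly on binary calls —
no continuous-methylation likelihood is attempted — because the upstream assay
(MS-HRM) is scored against a 10 % cut-off and low-level endogenous methylation
below that level is also seen in normal breast tissue.

Under **non-recurrence** the two tumours are independent, so gene *i*'s joint
call follows the product of two Bernoulli(*pᵢ*) draws. Under **recurrence**
the second tumour inherits the primary's call and then loses methylation with
probability γ or gains it with probability *g*·γ (*g* the gain multiplier).
Both 2×2 tables are normalised for any valid (p, γ, g), which the tests verify
on a grid and, for multi-gene panels, by brute-force enumeration of all 4^k
joint patterns.

The pair statistic is LR = Σᵢ ln Pr(xᵢ|R)/Pr(xᵢ|R̄) over the informative
genes. Natural logarithms are used throughout. Genes uninformative in either
tumour are excluded from the sum rather than imputed: the likelihood is then
exactly that of the observed (non-missing) data, neutral under both
hypotheses. A pair with *no* informative gene is degenerate: its LR is
reported as 0, both classifiers leave its labels unset, and a warning is
logged.

Note the statistic is orientation-dependent: swapping which tumour is "primary"
changes each discordant gene's contribution by ln(2(1−p)/p) (gain is twice as
likely as loss, and the marginal enters asymmetrically). This is why the
empirical null keeps both orientations of each cross-patient pairing.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| γ (loss rate) | 0.05 | probability | estimated from paired copy-number data in the originating study; exposed, not re-estimated |
| gain multiplier *g* | 2 | — | methylation gain on progression is likelier than loss; exposed for sensitivity analysis rather than hard-coding 2γ |
| prior Pr(R), ipsilateral | 0.75 | probability | literature consensus from molecular (aCGH/LOH/TP53) studies, range 0.69–0.76 |
| prior Pr(R), contralateral | 0.145 | probability | literature consensus, average of 14 % and 15 % |
| call threshold | 10 | % methylation | "above 10 %" read strictly: exactly 10 % is unmethylated; configurable |
| α | 0.05 | — | significance level of the empirical test (strict: p < α) |
| ε (clamping) | 0.01 | probability | cohort-observed frequencies include 0 (CDH1, MGMT), which would zero a likelihood denominator; pᵢ is clamped to [ε, 1−ε] with a logged warning |

Two frequency sets ship: `cohort` (the defaults, observed in a 29-pair breast
cohort: RASSF1A 0.64, TWIST1 0.61, CDH13 0.51, APC 0.50, MAL 0.35, GSTP1 0.30,
WIF1 0.26, RARβ 0.19, BRCA1/CDKN2A/TP73 0.02, CDH1/MGMT 0.00) and
`literature-partial` (published values for the six genes with a consensus —
RASSF1A 0.71, CDH13 0.49, RARβ 0.21, TWIST1 0.26, WIF1 0.65, CDH1 0.28 —
falling back to cohort values elsewhere, since no complete literature table is
available). Default is `cohort`. Any other set can be supplied as a panel TSV.

## Decision rules and numerical choices

* Bayesian: PLR = ln(prior odds) + LR; PLR > 0 ⇒ recurrent. A PLR of exactly
  0 is classified de novo — the conservative clinical call, since only strict
  inequalities are defined — with a logged tie warning.
* The equivalent LR thresholds are −ln(prior odds): −1.099 ipsilateral, 1.774
  contralateral at the default priors.
* Empirical: the null pools all ordered cross-patient pairings (2n·2(n−1);
  pairings involving the tested patient's own tumours are included — only
  same-patient pairings are excluded). A leave-one-individual-out null is
  available via `exclude_patient` / `--exclude-self-from-null` for stricter
  independence. The p-value is the raw count of null LRs *strictly greater*
  than the observed LR divided by the null size, so ties are not counted and
  p = 0 is reachable; an optional +1 smoothing exists but defaults off. No
  normal approximation is used even though the null is close to normal.
* Degenerate cross-pairings are dropped from the null with a logged count.
* Concordance: reference RECURRENT is the positive condition; a predictive
  value with a zero denominator is reported as undefined (None), never 0,
  to avoid misleading summaries at small n.

## Synthetic-data generator

`simulate_cohort` draws, per patient: a clonality indicator (true recurrence
rates default to 0.75 ipsilateral / 0.145 contralateral, matching the priors),
the primary's calls as independent Bernoulli(pᵢ), the second tumour's calls
from the recurrence table (if clonal) or independently (if not), and finally
independent masking of each call to uninformative at rate 0.05 — a package
choice loosely reflecting the failed-amplification rate of FFPE material, as
no dropout model is published. The default cohort shape is 16 ipsilateral +
13 contralateral pairs. One seeded stream is consumed in that documented
order, so a fixed seed reproduces a cohort byte-for-byte.

The generator emulates exactly the structure the likelihood assumes —
independent genes, homogeneous γ, missingness completely at random. Real
tumours violate all three (co-methylated pathways, field effects,
quality-driven dropout), so passing tests demonstrate internal consistency of
model, classifier and null, not clinical accuracy on real cohorts.

## Validation performed by the test suite

* Normalisation of both probability tables over a (p, γ) grid and of the
  induced joint measure over all 4^k patterns (k ≤ 5, brute force).
* Monte-Carlo agreement between generator and model cells at 10⁵ draws
  (within 3 standard errors), and positive/negative mean per-gene log ratios
  on clonal/independent draws for every interior-frequency gene.
* Type-I error of the empirical test on non-recurrent cohorts (20 seeds × 50
  pairs) inside a 99 % binomial band around α = 0.05. The tested pairs share
  the null they are scored against, a mild dependence accepted by the band.
* Recurrence-fraction ordering (ipsilateral > contralateral) under both rules
  in every one of 20 seeded 200-pair cohorts, and Bayesian accuracy above
  chance at 500 pairs per laterality across 20 repetitions.
* The cross-pairing count identity 2n·2(n−1) for n = 2…10, and exact
  agreement between the vectorized null builder and the scalar per-pair LR.

Problem sizes (10⁵-draw Monte-Carlo, 20-seed calibration at 50 pairs,
200-pair direction cohorts) were chosen so the full suite runs in seconds on
one CPU while leaving every check several standard errors of headroom.

## Limitations

* pᵢ, γ and the priors are inputs, not estimands; no empirical-Bayes or
  copy-number-based estimation is provided.
* The per-gene independence assumption is untested against real data here.
* The empirical p-value is granular at 1/|null| and anti-conservative in the
  presence of heavy ties (strict counting); with 13 genes ties are rare.
* Concordance is computed against whichever reference labelling is supplied;
  the package never derives clonality from copy-number data itself.
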