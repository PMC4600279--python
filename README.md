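# methclonal

When a breast-cancer patient develops a second tumour — in the same breast
(ipsilateral) or the opposite one (contralateral) — the clinical question is
whether it is a **recurrence** of the first tumour or a **new primary**,
because staging and therapy differ. `methclonal` answers this from a binary
promoter-methylation profile over a 13-gene marker panel (*RASSF1A, TWIST1,
CDH13, APC, MAL, GSTP1, WIF1, RARβ, BRCA1, CDKN2A, TP73, CDH1, MGMT*),
implementing a per-gene log-odds model, a Bayesian posterior-odds classifier,
and an empirical cross-patient null test. It is aimed at molecular-pathology
and epigenomics analysts working with paired tumour methylation calls (e.g.
from MS-HRM assays).

## The model

Each gene *i* has a background probability *pᵢ* of being methylated in a
breast tumour. For a pair of calls (primary, second) the joint probability is

| | second U | second M |
|---|---|---|
| **non-recurrence (R̄)**, primary U | (1−pᵢ)² | pᵢ(1−pᵢ) |
| primary M | pᵢ(1−pᵢ) | pᵢ² |
| **recurrence (R)**, primary U | (1−2γ)(1−pᵢ) | 2γ(1−pᵢ) |
| primary M | γpᵢ | (1−γ)pᵢ |

with γ = 0.05 the probability of losing methylation on progression and 2γ the
probability of gaining it (gain is the likelier direction as methylation tends
to increase during tumour progression). The pair statistic sums the
informative genes:

&nbsp;&nbsp;&nbsp;&nbsp;LR = Σᵢ ln Pr(xᵢ | R) / Pr(xᵢ | R̄)

Two decision rules are applied:

* **Bayesian** — PLR = ln(Pr(R)/(1−Pr(R))) + LR, with laterality priors
  Pr(R) = 0.75 (ipsilateral) and 0.145 (contralateral); PLR > 0 calls
  recurrence. Equivalently LR > −1.099 (ipsilateral) or LR > 1.774
  (contralateral).
* **Empirical** — tumours from different patients are non-recurrent by
  construction, so all ordered cross-patient pairings (2n·2(n−1) of them; 3248
  for 29 patients) form a null distribution of LRs. The p-value of a pair is
  the fraction of null LRs strictly greater than its LR; p < 0.05 calls
  recurrence.

A concordance module scores either labelling against an external reference
(e.g. clonality calls from copy-number profiling) via a 2×2 table with
sensitivity, specificity, PPV and NPV. A synthetic-data module generates
cohorts with exactly the generative structure above and known ground truth, so
the whole pipeline can be exercised and validated without patient data.

## Worked example

Simulate a study-sized cohort (16 ipsilateral + 13 contralateral pairs, true
recurrence rates 0.75 / 0.145) and analyse it, scoring the labels against the
generator's ground truth:

```sh
methclonal simulate --seed 11 --cohort-out cohort.tsv --truth-out truth.tsv
methclonal analyze cohort.tsv --out results.tsv --manifest manifest.json \
    --reference truth.tsv
```

prints

```
pairs analysed: 29
empirical null: 3248 LRs from 3248 cross-patient pairings (0 degenerate dropped)
recurrent fraction (bayesian): ipsilateral 88%, contralateral 15%
recurrent fraction (empirical): ipsilateral 75%, contralateral 23%
concordance vs reference (n=29): tp=14 fn=0 fp=2 tn=13
Sn=1.00 Sp=0.87 PPV=0.88 NPV=1.00
```

The null was built from all 2×29×2×28 = 3248 ordered cross-patient pairings.
Ipsilateral pairs are called recurrent far more often than contralateral ones
under both rules, as the differing priors and true recurrence rates dictate.
Against the known truth of this simulated cohort, the Bayesian labels recover
all 14 truly recurrent pairs (Sn = 1.00) and mislabel 2 of 15 new primaries
(Sp = 0.87). `results.tsv` holds one row per pair — LR, PLR, both labels, the
empirical p-value and the per-gene log-odds contributions:

```
patient_id  laterality   n_informative_genes  LR      PLR     bayesian_label  empirical_p  empirical_label
ipsi1       ipsilateral  11                   0.0443  1.1429  recurrent       0.1145       de_novo
ipsi2       ipsilateral  11                   5.7194  6.8180  recurrent       0.0037       recurrent
```

Pair `ipsi1` shows how the two rules can disagree: its LR ≈ 0 is pushed over
the Bayesian threshold by the 0.75 ipsilateral prior, while 11.45 % of null
pairings exceed its LR, short of the 0.05 significance cut-off.

The same steps are available as library calls (`simulate_cohort`,
`analyze_cohort`, `build_confusion`, …); see the module docstrings.

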