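# stagescore

Automated scoring of sentence-completion tests (SCT) on the 12-level STAGES
ego-development scale, with the statistical machinery to validate the
protocol against expert ratings.

## Who this is for

Researchers and practitioners in developmental psychology who want to score
SCT responses *at scale* — for groups, organizational units or corpora —
rather than hand-score every stem with a certified rater. The package is a
measurement and validation toolkit; it is explicitly **not** an instrument
for automated assessment of an individual's development.

## The model

The STAGES framework places a sentence at a level on the half-step grid
1.0, 1.5, …, 6.5 (12 levels) from three categorical judgements:

* **Q1 — tier of object awareness**: Concrete (1), Subtle (2), MetAware (3);
* **Q2 — person perspective**: Individual (1) or Collective (2);
* **Q3 — agency**: Passive (1) or Active (2).

The decision tree over the triple is the closed form

```
level = 2·(q1 − 1) + q2 + 0.5·(q3 − 1)
```

a bijection of the 12 triples onto the grid. Each question is answered by a
classifier backend — a remote large language model at temperature 0 with a
request cache, or a deterministic keyword-rule mock for offline work. Since
remote models are not perfectly deterministic, a sentence is classified
*n* times (default 10) and scored by the **lower median** of the per-run
levels; respondents are positioned by the mean of their sentence scores,
snapped back to the grid (minimum 5 sentences, 10 recommended).

Validation uses **Cohen's weighted kappa with quadratic weights** on the
12-category cross-tabulation of expert vs. protocol scores,

```
κ = 1 − Σ w·p_obs / Σ w·p_exp ,   w_ij = (i − j)² / (k − 1)² ,
```

with the Fleiss–Cohen–Everitt asymptotic (non-null) standard error and a
95% CI of κ ± 1.96·se. Calibration utilities answer "how many runs?"
(OLS slope of the median outcome vs. run count over shrinking windows) and
"how many stems?" (mean absolute deviation of subsample means from the
full-set mean over random combinations).

## Worked example

The bundled `table3` fixture holds 58 validation sentences with expert MAP
scores and the protocol's STAGES scores (both on the same grid):

```python
>>> import stagescore as sg
>>> ds = sg.load_fixture("table3")
>>> pairs = ds.pairs()                      # (MAP, STAGES) per sentence
>>> tab = sg.build_crosstab(pairs)          # 12x12 ordinal table
>>> int(tab.counts[sg.GRID.index(4.0), sg.GRID.index(4.0)])
14
>>> sg.weighted_kappa(tab)
AgreementResult(kappa=0.7798714056081443, se=0.054908180221325986,
                ci_low=0.6722513723743453, ci_high=0.8874914388419433, n=58)
```

κ ≈ 0.78 is substantial agreement between experts and the automated
protocol on single sentences; the CI excludes zero, so the agreement is
not attributable to chance. Group-level agreement is probed by resampling:

```python
>>> sg.aggregate_agreement(pairs, combo_size=10, n_combos=5000, seed=1).kappa
0.5520795234206295
```

Each of the 5,000 draws averages 10 sentences per rater and snaps both
means to the grid before the kappa is computed. The aggregate kappa is
*lower* than the per-sentence kappa here because weighted kappa on averaged
scores reduces to Lin's concordance, which penalizes the systematic offset
between the two raters' means (MAP 3.71 vs. STAGES 3.41) — averaging
shrinks random disagreement but leaves the offset intact. See
`docs/methods.md` for the full discussion.

Scoring your own sentences from the shell:

```sh
stagescore simulate --kind sentences --n 20 --out sentences.csv
stagescore score sentences.csv --backend mock --runs 10 --out scores.csv
stagescore agree pairs.csv --out agreement.json
```

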