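# ngtube-dta

Paired diagnostic-accuracy analysis of bedside pH strips for verifying
nasogastric (NG) feeding-tube placement, with a decision-analytic model
of the chest X-rays (CXRs) and cost the more sensitive strip avoids.

NG tubes are checked before every feed by testing the pH of a tube
aspirate: a reading ≤ 5.5 indicates gastric acidity and is taken as safe
to feed, while a higher reading sends the patient to a confirmatory
chest X-ray. Standard strips miss many true gastric placements in
patients on acid suppression or recent feeding, whose gastric pH is
elevated. An ester-impregnated strip adds a second, stomach-specific
signal: human gastric lipase (HGL) hydrolyses the impregnated ester
(tributyrin), releasing butyric acid that lowers the strip reading on
gastric aspirates only. This package implements the full analysis of
such a paired, two-gate comparison, for biostatisticians and
health-economics analysts who want the published pipeline as tested,
reusable code.

## What it computes

For a dataset of per-patient readings (two readers × two strips, with
a reference-standard tube location):

* **Sensitivity** per strip at cut-offs *c* ∈ {4, 5, 5.5, 6}: the
  proportion of gastric samples whose averaged reading ≤ *c*, with Wald
  95% CIs, and **lung specificity** (proportion of lung aspirates
  reading > *c*).
* **Paired comparison**: the 2×2 concordance table (a, b, c, d) of
  per-patient calls; sensitivity difference (c−b)/n with the paired
  Wald CI diff ± z√((b+c) − (b−c)²/n)/n, and McNemar's
  continuity-corrected test (|b−c|−1)²/(b+c) ~ χ²₁ on the discordant
  cells; paired t test on mean readings; Cohen's kappa between readers.
* **Institutional variation**: per-site sensitivities and a funnel plot
  with control limits p̄ ± z√(p̄(1−p̄)/n).
* **CXR savings**: a decision tree in which, of 1000 eligible checks,
  90% are gastric placements, 70% of those yield an aspirate, and each
  tested patient avoids a £28.53 CXR with probability equal to the
  strip's sensitivity; a *recheck* variant retests once before imaging
  (CXR count ∝ (1−s)²). Savings are optionally inflation-adjusted at
  3.5%/year.

Because no patient-level data are deposited, the package ships a
deterministic fixture reconstructing the published marginal counts
(376 gastric + 38 lung records) and a calibrated synthetic-cohort
generator (gastric pH elevated by acid suppression and feeding, a
lipase shift on gastric samples under the novel strip only, two
correlated readers on a 0.5-unit strip scale, 10-site clustering). See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
from ngtube_dta import (trial_fixture, sensitivity_table, lung_specificity,
                        DecisionModelParams, run_standard_scenario)

fx = trial_fixture()                      # 376 gastric + 38 lung records
table = sensitivity_table(fx)
for row in table.rows:
    print(f"cutoff {row.cutoff}: standard {row.standard.display()}, "
          f"novel {row.novel.display()}, "
          f"diff {row.comparison.difference*100:.1f}%")

print("lung specificity at 5.5:", lung_specificity(fx, 5.5).display())

row = sensitivity_table(fx, (5.5,)).rows[0]
res = run_standard_scenario(DecisionModelParams(
    sens_standard=row.standard.point, sens_novel=row.novel.point))
print(f"CXRs: standard {res.cxr_standard}, novel {res.cxr_novel}, "
      f"avoided {res.cxr_saved}")
print(f"saving: £{res.cost_saved_nominal:.0f} nominal, "
      f"£{res.cost_saved_inflated:.0f} inflation-adjusted")
```

prints

```
cutoff 4.0: standard 33.2% (125/376) (28.5%, 38.0%), novel 35.6% (134/376) (30.8%, 40.5%), diff 2.4%
cutoff 5.0: standard 43.4% (163/376) (38.3%, 48.4%), novel 56.1% (211/376) (51.1%, 61.1%), diff 12.8%
cutoff 5.5: standard 49.2% (185/376) (44.1%, 54.3%), novel 70.2% (264/376) (65.6%, 74.8%), diff 21.0%
cutoff 6.0: standard 64.6% (243/376) (59.8%, 69.5%), novel 83.0% (312/376) (79.2%, 86.8%), diff 18.4%
lung specificity at 5.5: 89.5% (34/38) (79.6%, 99.4%)
CXRs: standard 320, novel 188, avoided 132
saving: £3766 nominal, £4034 inflation-adjusted
```

At the recommended cut-off of 5.5 the ester strip identifies 70.2% of
gastric placements against 49.2% for the standard strip — a 21-point
margin — and per 1000 eligible checks that margin avoids 132
unnecessary chest X-rays, worth £4034 at today's prices.

The same pipeline is available from the shell:

```sh
ngtube-dta fixture --out fixture.csv
ngtube-dta accuracy --input fixture.csv --out table.csv
ngtube-dta simulate --seed 7 --out cohort.csv      # synthetic cohort
ngtube-dta funnel --input cohort.csv --out-prefix funnel
ngtube-dta decision-model --sens-standard 0.492 --sens-novel 0.702
ngtube-dta report --fixture --outdir report_out    # everything at once
```

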