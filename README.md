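# reconpref

Health-state utility elicitation for breast-reconstruction decisions:
card ranking, visual-analog-scale (VAS) rating, and the chained standard
gamble, with a synthetic respondent cohort and the complete nonparametric
analysis pipeline.

## The scientific problem

After total mastectomy a woman chooses between implant-based
reconstruction, tissue-based (autologous) reconstruction, and no
reconstruction, each with outcomes a surgeon would grade excellent, good,
fair, or poor.  A *health utility* summarises her strength of preference
for each of these nine health states on a cardinal scale from 0 (death)
to 1 (perfect health); such utilities feed cost–utility analyses and
decision aids.  Interview studies elicit them with three instruments:

- **Card ranking** — order the nine outcome cards from most (1) to least
  (9) preferred.
- **VAS / feeling thermometer** — place each card on a 0–100 scale, with
  and without a death card added.
- **Standard gamble (SG)** — choose between the certainty of an
  intermediate outcome and a lottery giving the best outcome with
  probability *P* and the worst with 1 − *P*; *P* is lowered from 100% in
  fixed decrements until the certainty is chosen, and the indifference
  probability measures the state's utility.

Because respondents facing cancer rarely accept gambles against death for
every card, the SG is *chained*: each intermediate state *i* is first
gambled against the respondent's own best/worst states (indifference
probability *P1ᵢ*), then the worst state is gambled against the best
outcome and death (*P2*).  On the death-anchored scale with
u(best) = 1 and u(death) = 0,

```
u(stateᵢ) = P1ᵢ + (1 − P1ᵢ) · P2
```

Raw interview data for such studies are not public, so `reconpref` pairs
the elicitation machinery with a **synthetic cohort generator** whose
defaults emulate a published 40-woman study population (covariate
distributions, median utilities, covariate effects, and behavioural
quirks such as "unexpected" rankings and equipoise).  Every stage of the
analysis is therefore testable end to end, and the statistical pipeline —
median/IQR summary tables, Spearman correlations between instruments,
paired Wilcoxon contrasts, Kruskal–Wallis comparisons across BMI
categories, and univariate screening (p < 0.2) followed by backward-AIC
linear model selection — can be validated against known generating truth.

## Worked example

```python
from reconpref import PreferenceStudy, GeneratorConfig

study = PreferenceStudy.from_simulation(GeneratorConfig(), seed=7)
results = study.fit()
print(results.summary())
```

```
Preference elicitation study results
====================================================================
participants: 40
complete responses per instrument: rank=40, vas=40, vas_death=40, utility=40
unexpected rankings (fair/poor in top 3 or excellent in bottom 3): 92%

Medians (IQR) by option group and quality
--------------------------------------------------------------------
                          rank            VAS      VAS+death      utility
group   quality
any     pooled     4.62 (0.50)  52.66 (20.55)   90.31 (5.31)  0.97 (0.06)
        excellent  4.50 (1.50)  63.12 (24.06)   91.25 (6.88)  0.98 (0.06)
...
implant pooled     4.88 (1.50)  55.31 (26.72)   90.94 (8.12)  0.98 (0.06)
tissue  pooled     5.00 (1.56)  54.38 (35.47)   90.94 (5.00)  0.98 (0.05)
none    pooled     8.00 (4.00)  28.75 (63.12)  82.50 (10.62)  0.93 (0.09)
...
Backward-AIC regression models (retained terms)
--------------------------------------------------------------------
vas:any  (AIC 310.3, n=40)
    breastq_breast           B=   0.485  CI [0.038, 0.931]  p=0.03409
    asir_self_evaluation     B=  -5.736  CI [-10.205, -1.267]  p=0.01334
    asir_control             B=  -6.869  CI [-13.526, -0.212]  p=0.04349
```

Reading the output: reconstruction states carry high chained-gamble
utilities (medians ≥ 0.93) while no reconstruction sits lowest; adding
the death card compresses VAS ratings toward 100; and at n = 40 the
backward-AIC models recover effects of the magnitude the generator
planted (e.g. VAS points falling with appearance self-evaluation), with
the instability expected of a small cohort.

The same run from a shell, with CSV tables and median/IQR figures:

```bash
reconpref all --n 40 --seed 7 --out out/
```

Subcommands `simulate`, `elicit` and `analyze` expose the stages
separately; `--config config.yaml` overrides any generator setting
(`GeneratorConfig().to_yaml(path)` writes a template).  Identical seeds
give byte-identical CSV output.

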