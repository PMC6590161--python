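# rxthreshold

Treatment-threshold decision analysis for clinical benefit–harm
trade-offs, with explicit patient preference weights.

## The problem

The threshold model of medical decision-making asks: at what probability
of disease does the expected utility of treating exceed that of not
treating?  Solving the classic treat/no-treat decision tree with net
benefit *B* = *U*₁ − *U*₃ and net harm *H* = *U*₄ − *U*₂ gives the
disease-probability threshold

```
Pt = 1 / (1 + B/H) = H / (B + H)
```

— treat when the estimated probability of disease exceeds *Pt*.

That formula assumes probabilities and utilities are **independent**.  In
a very common class of problems they are not: the disease is *defined by*
the outcome treatment is meant to prevent (recurrent venous
thromboembolism, myocardial infarction, cancer relapse).  Using the same
morbid event in both the probability branch and the utility branch double
counts it.  The remedy is to take the diagnosis — the predisposition to
the event — as certain (*P* = 1) and compute a threshold on the
**baseline outcome risk** *M* instead.  With treatment efficacy expressed
as a relative risk reduction (RRR), treatment-harm probability *H*ᵣₓ, and
a preference weight *RV*ₕ (how bad the harm outcome is relative to the
disease outcome; 1 = equally bad), the two closed forms are

```
Pt = RV_H · H_rx / (RRR · M)        (independent regime)
Mt = RV_H · H_rx / RRR              (dependent regime, P = 1)
```

with *Mt* = *Pt* · *M* ≤ *Pt* always.  The package implements both, the
NNT/NNH reformulation *Pt* = NNT/NNH, the regime guard that refuses a
*Pt* request when it would double count, a Monte-Carlo and bisection
oracle that verifies the closed forms directly on the decision tree, and
one-way sensitivity sweeps over bleeding risk and preference weights.

## Worked example

Extended anticoagulation after venous thromboembolism (VTE), using the
EINSTEIN extension trial arms: recurrence risk 42/594 = 7.1% on placebo
vs 8/602 = 1.3% on rivaroxaban (RRR = 81.2%), major bleeding risk
*H*ᵣₓ = 4.8%.

```python
import rxthreshold as rx

# recurrent VTE is diagnosed only when the outcome event occurs:
# dependent regime, so the outcome-risk threshold applies
mt = rx.outcome_threshold(rv=1.0, h_rx=0.048, rrr=0.812)
print(mt.display())          # 5.9%
print(rx.outcome_threshold(0.75, 0.048, 0.812).display())   # 4.4%
print(rx.outcome_threshold(0.045, 0.048, 0.812).display())  # 0.3%

# the classic disease-probability threshold, had the diagnosis been
# independent of the outcome, is implausibly high:
pt = rx.ebm_probability_threshold(rv=1.0, h_rx=0.048, rrr=0.812, m=0.071)
print(pt.display())          # 83%

# decision rule: a patient at 15% recurrence risk is above Mt
print(rx.decide(0.15, mt).value)   # treat
```

Treat a patient only if their untreated recurrence risk exceeds *Mt*:
5.9% when bleeding and recurrence are weighted equally, falling to 0.3%
for a patient who would accept 22 bleeds to avoid one clot
(*RV*ₕ = 1/22 ≈ 0.045).  The 83% disease-probability threshold shows why
the classic formula misleads in this regime.

The same analysis runs from the command line on a config file:

```
rxthreshold threshold examples/einstein.yaml
rxthreshold decide examples/einstein.yaml --estimate 15
rxthreshold sweep examples/einstein.yaml --out sweep.csv
rxthreshold simulate examples/einstein.yaml --arm treat --p 1.0 --seed 1
```

Exit codes: 0 success, 2 validation error, 3 domain/regime error (e.g.
requesting a disease-probability threshold for an outcome-defined
disease).

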