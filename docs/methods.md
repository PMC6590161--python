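# Methods

## Model

The package evaluates the two-action (treat / no treat), two-state
(disease / no disease) expected-utility decision tree.  Expected
utilities are

```
EU_Rx(p)   = p·U1 + (1−p)·U2
EU_NoRx(p) = p·U3 + (1−p)·U4
```

and the threshold is the indifference point EU_Rx = EU_NoRx.  With net
benefit B = U1 − U3 and net harm H = U4 − U2 this is
Pt = H/(B+H) = 1/(1+B/H), defined for H > 0 and B ≥ 0; B < 0 means
treatment is dominated everywhere and is reported as a never-treat
result rather than a number.

### Utility parameterization

Utilities live on a 0–1 scale (1 = perfect health) and are built from
trial-style effect parameters by **additive unit disutilities**: the
disease outcome costs its probability M in expected utility, the
treatment harm costs RV_H·H_rx, and treatment rescales the outcome risk
by (1 − RRR):

```
U1 = 1 − (1−RRR)·M − RV_H·H_rx      U2 = 1 − RV_H·H_rx
U3 = 1 − M                          U4 = 1
```

This is the unique additive form under which the generic threshold
H/(B+H) collapses exactly to the evidence-based closed form
Pt = RV_H·H_rx/(RRR·M); that algebraic identity is asserted to 1e-12 on
1,000 randomly generated scenarios.  Parameter combinations that would
push a terminal utility below 0 (very large combined disutility) are
**rejected, not clamped** — clamping would silently break the identity.

Assumptions inherited from this form: treatment effects are relative
and constant over baseline risk (the usual portability assumption for
RRR; odds-ratio inputs are first converted to risk ratios at the given
baseline); disutilities of the outcome and the harm combine linearly;
utilities are point estimates without uncertainty.

### Two regimes, two thresholds

The classic threshold requires the probability of disease and the
utilities to be independent.  When the outcome event is itself part of
the disease definition (recurrent thromboembolism, relapse detected by
imaging, infarction defined by a composite of tests), that independence
fails: the same event would be counted in both branches.  The package
makes the regime an explicit scenario field:

- **independent** — `scenario_probability_threshold` returns
  Pt = RV_H·H_rx/(RRR·M);
- **dependent** — the disease (the predisposition to the event) is taken
  as certain, P = 1, and the decision quantity becomes the baseline
  outcome risk with threshold Mt = RV_H·H_rx/RRR.  Requesting the
  probability threshold in this regime raises `DoubleCountingError`;
  this guard is deliberately an error, not a warning, because the
  resulting number would be normatively meaningless.

Since Mt = Pt·M, the outcome-risk threshold never exceeds the
probability threshold.

### Preference weight

RV_H > 0 is the decision-maker's disutility of the treatment-harm
outcome relative to the disease outcome.  It multiplies the harm terms
throughout, so both thresholds scale linearly in it.  A "k times worse"
trade statement converts as RV_H = 1/k (`rv_from_trade_ratio`); values
above 1 (harm worse than the outcome) are permitted.

## Parameters and defaults

| parameter | meaning | units | default |
|---|---|---|---|
| `baseline_risk` (M) | outcome risk without treatment | proportion | required |
| `treated_risk` (M_rx) or `rrr` | treated risk / relative risk reduction | proportion / fraction | one required |
| `harm_rx` (H_rx) | treatment-harm probability | proportion | required |
| `rv_harm` (RV_H) | harm valuation relative to outcome | ratio > 0 | 1 (equal weighting) |
| `disease_prob` (P) | disease probability | proportion | optional; forced to 1 in the dependent regime |

Config files carry a mandatory `units` key (`percent` or `proportion`);
percent inputs are divided by 100 at load.  RRR is always a
dimensionless fraction.  If risks and RRR are all supplied they must
agree to 1e-6.

## Numerical choices

- **Bisection oracle.**  `numeric_threshold` solves EU_Rx(x) = EU_NoRx(x)
  for one parameter by bisection: interval tolerance 1e-14, residual
  requirement |EU_Rx − EU_NoRx| < 1e-12, at most 200 iterations,
  deterministic.  The EU difference is linear in each single parameter
  under the additive form, but bisection stays correct if the
  parameterization is ever replaced by a nonlinear one, which is why a
  derivative-based method was not used.  Absence of a sign change over
  the bracket raises `NoRootError` (the decision is uniform there).
- **Monte-Carlo oracle.**  `mc_expected_utility` simulates patients with
  independent Bernoulli draws for disease, outcome-given-disease, and
  harm, with unit disutilities per event, so its expectation equals the
  closed-form EU exactly.  It takes an explicit integer seed
  (numpy `default_rng`); there is no global random state.  Agreement is
  tested at 4 standard errors with n = 2·10⁵ draws, and 4-SE coverage is
  checked across 100 seeds at n = 2·10⁴ — sizes chosen so the whole
  suite completes in seconds while leaving the SE (~5·10⁻⁴) far below
  the effects being checked.
- **Rounding.**  Stored values are never rounded.  Display formatting
  follows the conventional precision: whole percent for
  disease-probability thresholds, one decimal for outcome-risk
  thresholds.  The `paper` arithmetic mode for the absolute risk
  reduction subtracts risks after rounding each to one decimal on the
  percent scale, reproducing how clinical summaries quote ARR from
  already-rounded risks (7.1% − 1.3% = 5.8%, though the unrounded
  difference is 5.74%); the `exact` mode (default) keeps full precision.
- **Thresholds above 1** are returned as computed with
  `never_treat=True`: an unattainable threshold is a substantive
  finding about the scenario, not an input error.  Exact equality of an
  estimate with a threshold yields `indifferent`; callers choose their
  own tie policy.
- **Degenerate inputs.**  H_rx = 0 gives a zero threshold (harmless
  treatment: treat at any risk); RRR = 0 or M = 0 gives never-treat with
  a diagnostic message; H ≤ 0 in the generic form is a domain error
  because no threshold exists.

## Synthetic scenario generator

`generate_scenarios` draws scenarios with baseline risk U(0.001, 0.5),
RRR U(0.05, 0.99), harm risk U(0, 0.2), preference weight U(0.02, 1.5),
uniform disease probability, and a fair coin for the regime —
spanning rare-to-common outcomes, weak-to-near-complete treatment
effects, and strong outcome-aversion through harm-aversion.  Draws whose
combined disutility would produce a negative terminal utility are
rejection-sampled away, so every generated scenario is valid by
construction.  The generator emulates *parameter* diversity only: the
scenarios are exact closed-form worlds with no sampling error in their
inputs, no correlation between parameters, and no uncertainty intervals,
so passing property tests demonstrates algebraic and structural
correctness of the model — not robustness to noisy trial estimates.

## Design choices where the design was open

- The NNT/NNH threshold accepts an optional preference weight
  (default 1, the classical ratio); the weighting is the extension
  consistent with the RV_H-weighted closed form, since
  NNT = 1/(M·RRR) and NNH = 1/H_rx make RV_H·NNT/NNH identical to
  RV_H·H_rx/(RRR·M).
- The probability-threshold sweep evaluates both summary definitions
  (net benefit/harm ratio and NNT/NNH) over a single shared ratio grid,
  because the comparison is between two readings of the same axis.
- The shipped sweep grid covers treatment-harm risk 0–10% in 0.5% steps,
  bracketing the 4.8% bleeding risk of the worked example.
- Sweeps are tables first (long format: parameter value, series label,
  threshold, never-treat flag); plots are an optional rendering and
  never the source of truth.

## Limitations

- Two actions, two states, single period: no multi-arm trees, Markov /
  time-dependent utilities, QALY discounting, or cost units.
- No testing / test-treatment thresholds: when the diagnosis is the
  predisposition to the outcome, test sensitivity and specificity have
  no role, and the independent-regime testing model is out of scope.
- Point estimates only: no confidence intervals or probabilistic
  sensitivity analysis over trial parameters.
- The preference weight is a single scalar; it cannot represent
  outcome-severity gradations (fatal vs non-fatal bleeding, say) within
  one scenario.
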