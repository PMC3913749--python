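# recallmix

Mixture modelling and cohort statistics for **dual-feature continuous-report
visual-working-memory data**.

In a continuous-report (delayed estimation) task, a participant memorises an
array of items and then reproduces a probed item's features — here a bar's
orientation and its colour — on continuous circular scales. Each trial yields
an angular recall error rather than a binary outcome, and the *distribution*
of those errors is what carries the science: how precisely features are
stored, how often a feature of the wrong (nontarget) item is reported
(misbinding/swap errors), and how often the response is a pure guess.

`recallmix` is for researchers who analyse such data — particularly aging
cohorts — and for methodologists who want a tested, reproducible reference
implementation with a built-in synthetic-cohort generator for power analysis
and parameter-recovery studies.

## The model

The response distribution in one feature dimension is a three-component von
Mises mixture. With target feature value θ, nontarget values φ₁…φₘ and
response θ̂:

    p(θ̂) = α·φ_κ(θ̂ − θ) + (β/m)·Σᵢ φ_κ(θ̂ − φᵢ) + γ/2π

where φ_κ is the von Mises density with mean zero and concentration κ, α is
the probability of reporting the target, β the probability of misreporting a
nontarget, and γ = 1 − α − β the probability of responding at random.
Parameters are estimated by maximum likelihood with a multi-start
expectation-maximization algorithm; κ is also reported as the circular
standard deviation σ = √(−2 ln(I₁(κ)/I₀(κ))).

Model-free statistics complement the fit: recall **precision** is the
reciprocal of the circular SD of error minus the value expected from a
random responder (so 0 = chance), and misreporting is validated
nonparametrically through the RMS deviation of responses from nontarget
features, whose chance level is π/√3 ≈ 1.814 rad.

The cohort pipeline applies a 3-SD outlier rule, regresses every parameter
on age, runs repeated-measures ANCOVAs (load × feature with age as a
continuous covariate, every term on F(1, n−2)), compares the age–precision
correlation between memory loads (Hotelling–Williams, df = n−3), summarises
age quartiles, contrasts exposure-duration groups, and correlates precision
with span-test scores including age/education partial correlations.

## Worked example

Simulate a 24-subject aging cohort, fit every subject × dimension × load
cell, and run the cohort statistics:

```bash
recallmix simulate -o demo --subjects 24 --seed 7
recallmix fit demo/trials.csv -o demo/estimates.csv --n-starts 6 --seed 1
recallmix analyze demo/estimates.csv demo/subjects.csv \
    --trials demo/trials.csv -o demo/report
```

which prints (abridged):

```
[recallmix 0.1.0 | ...] simulating cohort: n=24, seed=7
[recallmix 0.1.0 | ...] wrote 9600 trial rows for 24 subjects to demo
[recallmix 0.1.0 | ...] fitting 96 cells (n_starts=6, seed=1)
[recallmix 0.1.0 | ...] age-precision r: low=-0.580, high=-0.739 (difference t(21)=-1.20, p=0.242)
[recallmix 0.1.0 | ...] report written to demo/report
```

Recall precision declines with age in both load conditions and more steeply
when three items must be held in memory (r = −0.74 vs −0.58 here; with only
24 subjects the load difference is not yet significant). The report
directory then holds the full tables; for instance
`demo/report/nontarget.csv` shows

```
mean_rms       1.7639
t_vs_chance   -7.6904
p_vs_chance    8.39e-08
```

— the mean RMS deviation of responses from nontarget features (1.76 rad)
sits significantly below the π/√3 ≈ 1.814 chance level, the nonparametric
signature of misbinding errors in the simulated cohort. `recallmix report
demo/estimates.csv -o demo/figs` renders the standard scatter and contrast
figures.

The same workflow is available as library calls:

```python
from recallmix import CohortSpec, generate_cohort, fit_cohort, analyze_cohort

trials, subjects, truth = generate_cohort(CohortSpec(n_subjects=24, seed=7))
estimates = fit_cohort(trials, n_starts=6, seed=1)
report = analyze_cohort(estimates, subjects, trials=trials)
print(report.precision_age)
```

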