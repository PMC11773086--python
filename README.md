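# fearcond

Trial-level analysis toolkit for differential fear-conditioning studies that
measure skin conductance across development (children, adolescents, adults).
It is aimed at psychophysiologists who want the full chain — task schedule,
electrodermal recording, trough-to-peak trial scoring, head-motion QC and
mixed-model statistics — as reproducible, tested code, with a synthetic-data
generator that plants known effects so every stage can be validated end to
end.

## What it implements

**Paradigm.** The four-phase "screaming lady" protocol: habituation
(4 CS+ / 4 CS−, 7 s), acquisition (10 CS+ / 10 CS−; CS+ 6 s, 8 of 10
followed by a 1 s aversive US — 80 % reinforcement; CS− 7 s), extinction and
a delayed retention test (10 + 10 at 7 s). Presentation order is
pseudorandom with at most two identical CS types in a row; inter-trial
intervals are drawn from a Gaussian (mean 12 s, SD 1 s, truncated at ±3 SD).

**SCR scoring.** For each trial the pipeline applies, in order: a 10 ms
median filter, a first-order Butterworth band-pass (0.03–5 Hz, zero-phase),
downsampling to 100 Hz, and baseline-corrected peak extraction

```
SCR = max{ x(t) : t ∈ [onset+1 s, onset+5 s) } − mean{ x(t) : t ∈ [onset, onset+1 s) }
```

followed by the amplitude rules (SCR < 0.01 µS → 0; SCR > 5 µS → missing)
and a square-root transform.

**Statistics.** Phase-wise Gaussian linear mixed models of √SCR,

```
y_ij = β₀ + β₁·CS+ + β₂·trial + β₃·CS+×trial (+ group terms) + b_i + e_ij,
b_i ~ N(0, τ²),  e_ij ~ N(0, σ²),
```

estimated by REML with Satterthwaite degrees of freedom (the variance ratio
is profiled analytically, so fits are fast and deterministic); the
extinction-retention score (mean √SCR of the first two CS+ trials minus the
first two CS− trials) regressed on age group; a US-habituation model; and
cumulative-link (proportional-odds) mixed models for the 1–5 ordinal fear
ratings, with a Gaussian subject intercept integrated out by adaptive
Gauss–Hermite quadrature. Framewise displacement is computed from six
realignment parameters (rotations scaled by a 50 mm head radius) and volumes
with FD > 0.9 mm are censored. Contingency awareness is the report
"CS+ screamed, CS− did not".

## Worked example

```python
from fearcond import RunConfig, run_all

report = run_all(RunConfig(master_seed=11, group_sizes={"child": 36, "adolescent": 40, "adult": 44}))
print(report.fits["phase_acquisition"].table.round(4).to_string(index=False))
```

```
        term  estimate     se    stat        df      p
   Intercept    0.4735 0.0137 34.6379  636.1888 0.0000
      cs:CS+   -0.0547 0.0157 -3.4851 2277.0005 0.0005
       trial   -0.0086 0.0018 -4.8330 2277.0005 0.0000
cs:CS+:trial    0.0295 0.0025 11.6553 2277.0005 0.0000
```

The positive `cs:CS+:trial` interaction is the signature of differential
fear learning: the CS+/CS− separation grows across acquisition trials
(here ≈ 0.03 √µS per trial, matching the generator's planted effect), while
the negative `trial` main effect reflects within-session habituation. The
same run produces extinction and retention tables, the per-subject retention
differential with its group regression, the ratings model, per-group
censoring summaries and a four-phase CS+/CS− trial-mean figure
(`scr_by_phase.png`).

The same pipeline runs from the shell:

```
fearcond simulate --seed 11 --out cohort/
fearcond preprocess --physio cohort/sub-001/acquisition_physio.tsv.gz \
                    --events cohort/sub-001/acquisition_events.tsv --out trials.csv
fearcond fd --rp cohort/sub-001/rp_retention.txt --out censor
fearcond run-all --seed 11 --out report/
```

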