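# ptsdsim

Agent-based microsimulation of community post-traumatic stress disorder
(PTSD) prevalence following a mass traumatic event, driven by exposure to
television and social-media coverage.

The package is for epidemiologists and computational social scientists who
want to reproduce, probe, or extend a media-exposure microsimulation of the
2018 Parkland / Coral Springs school-shooting setting: a synthetic community
of 118,000 agents drawn from American Community Survey (ACS) marginals, an
internal social network partitioning the population into primary (present at
the site: 900 students + 30 adults), secondary (4,725 family / close-friend
contacts) and tertiary (everyone else — the media-exposed community) trauma
tiers, and a categorical dose–response model of PTSD risk from hours of TV
coverage watched.

## Model

Each tertiary agent prefers TV news with probability *f*; TV watchers draw a
daily hours category from the four-bin distribution *w* = (w₁…w₄) over
(<4, 4–7, 8–11, 12+ h) — baseline (0.112, 0.131, 0.108, 0.649) — and develop
PTSD with probability

> P(PTSD | category *i*, engagement *m*) = min(cap, pᵢ · m),

where p = (p₁…p₄) is the monotone dose–response and *m* ∈ {1, m_casual,
m_video} is a multiplicative social-media engagement factor applied on top
of TV exposure (casual = viewing posts, video = sharing/watching videos).
Community prevalence therefore has the closed form *f* · Σᵢ wᵢ min(cap, pᵢ m),
which serves as the analytic oracle for the Monte Carlo engine.

The endpoints p₁ = 0.008 and p₄ = 0.101 are published post-9/11 conditional
prevalences; p₂, p₃, *f* and both multipliers are not published and are
recovered by `calibrate_params`, which solves the expected-prevalence
equations for the baseline and the two distribution-shift counterfactuals —
a system linear in (f, f·p₂, f·p₃) — and takes the multipliers as prevalence
ratios. The all-to-<4 h counterfactual (scenario 1) is deliberately left out
of the solve as an out-of-sample check.

Counterfactual scenarios remap each agent's hours category: scenario 1 sends
everyone to <4 h; scenario 2 clamps upper-half categories into the lower
half (8–11, 12+ → 4–7); scenario 3 clamps lower-half categories into the
upper half (<4, 4–7 → 8–11). Each condition is run 50 times and summarized
by the mean prevalence with nearest-rank 2.5th/97.5th percentiles.

## Worked example

`examples/` holds one short script per capability. The full experiment
(`python examples/05_full_experiment.py`, ~20 s) prints:

```
condition                 mean %   2.5th %  97.5th %
baseline                     3.1      2.99      3.22
s1_under4                    0.3      0.29      0.35
s2_lower_half                1.3      1.24      1.41
s3_upper_half                3.5      3.37      3.61
baseline+casual              3.4      3.30      3.50
baseline+video               5.3      5.15      5.39
```

Each row is the mean PTSD prevalence in the tertiary tier over 50 replicates
of 118,000 agents, with the replicate percentile band: cutting TV exposure
(scenarios 1–2) lowers community prevalence up to ten-fold, shifting it
upward (scenario 3) raises it modestly, and adding video-sharing engagement
on social media raises it by ~70%. `examples/03_calibration.py` shows the
calibrated parameters themselves (f = 0.3969, p = 0.008/0.0359/0.0645/0.101,
m_casual = 1.0968, m_video = 1.7097).

The same run is available from the shell:

```bash
ptsdsim simulate --scenario baseline --replicates 50 --seed 1 --out results/
ptsdsim calibrate            # print the calibrated config fragment
ptsdsim report --in results/ # bar chart of mean prevalence with bands
```

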