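# Methods

## Model overview

The package simulates the community burden of probable PTSD after a mass
shooting as a pipeline of five stochastic stages, all driven by a single
replicate seed:

1. **Synthetic population.** 118,000 agents are sampled from ACS marginal
   tables for sex, age band (under 20 / 20–44 / 45–64 / 65+),
   race/ethnicity and education. Attributes are sampled independently:
   only marginals are published for the study community, no joint microdata,
   and nothing downstream depends on cross-attribute structure. Education is
   assigned to all agents regardless of age; it is cosmetic (it never enters
   risk). Age is stored as the four bands only — no operation needs finer
   resolution.
2. **Exposure tiers.** 900 under-20 agents ("students") and 30 agents aged
   20+ are drawn uniformly as the primary tier. Secondary contacts are drawn
   uniformly without replacement from all non-primary agents until the tier
   holds exactly 4,725 agents, each linked round-robin to a primary agent in
   an explicit edge list. The tier targets the published count directly
   rather than sampling a per-primary family-size distribution, because only
   the count is verifiable; the implied mean of ≈5.08 contacts per primary
   agent is exposed as `ExposureConfig.contacts_per_primary`. Everyone else
   is tertiary. The published tertiary count (112,189 "adults") is
   inconsistent with the other published counts (118,000 − 930 − 4,725 =
   112,345) and with any adult fraction compatible with the age marginals;
   we define tertiary as the exact remainder, 112,345.
3. **Media profiles.** Each tertiary agent prefers TV news with probability
   *f* (scalar default, optional per-age-band overrides); TV watchers draw
   an hours category from the baseline four-bin distribution
   (0.112, 0.131, 0.108, 0.649) and carry a scenario-wide social-media
   engagement level (none / casual / video). Primary and secondary agents
   receive no media profile: no risk parameters exist for direct exposure
   in scope, so only the media-mediated tertiary pathway carries risk, and
   prevalence is reported over the tertiary denominator.
4. **Scenario transform.** Counterfactuals remap per-agent hours categories:
   all-to-<4 h (s1), clamp-to-lower-half (s2: 8–11 → 4–7, 12+ → 4–7), and
   clamp-to-upper-half (s3: <4 → 8–11, 4–7 → 8–11). The clamp reading of
   "shifted to the lower/upper half" was chosen over proportional
   redistribution within the half because only the clamp mapping admits a
   monotone dose–response consistent with all published prevalences
   (proportional redistribution forces p₂ > p₃ when solved against them).
   Because the transform acts on agent-level assignments, scenarios run from
   the same seed are paired comparisons sharing randomness.
5. **Risk and draw.** P(PTSD) = min(cap, p_category · m_engagement) for TV
   watchers, 0 otherwise; independent Bernoulli draws give agent status.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| population size | 118,000 | agents | published study community |
| primary tier | 900 + 30 | agents | published |
| secondary tier | 4,725 | agents | published |
| hours weights w | (0.112, 0.131, 0.108, 0.649) | probability | published baseline |
| p₁, p₄ | 0.008, 0.101 | probability | published dose–response endpoints |
| p₂, p₃ | 0.035879, 0.064507 | probability | calibrated |
| f | 0.396867 | probability | calibrated |
| m_casual, m_video | 1.096774, 1.709677 | ratio | calibrated (prevalence ratios) |
| cap | 1.0 | probability | upper bound on any per-agent risk |
| replicates | 50 | runs | published protocol |

Calibrated values live in `src/ptsdsim/data/default_config.yaml` with
provenance comments, not hard-coded in logic; every one is overridable.

## Calibration

With p₁, p₄ fixed, expected prevalence f·Σwᵢpᵢ equated to the published
baseline, lower-half and upper-half prevalences (0.031, 0.013, 0.035) gives
three equations that are linear in (f, x, y) with x = f p₂, y = f p₃; a 3×3
`numpy.linalg.solve` recovers them exactly. Engagement multipliers are the
prevalence ratios 0.034/0.031 and 0.053/0.031. Solutions with f ∉ (0, 1] or
a non-monotone p are rejected. The all-to-<4 h scenario is excluded from
the solve; its analytic prediction f·p₁ = 0.00317 rounds to the published
0.3%, an out-of-sample consistency check. The test suite freezes the exact
rational solution (obtained independently with sympy) and verifies the
round-trip to six decimals.

Whether engagement multiplies risk for all TV watchers or only a
social-media-using subset is observationally equivalent at population level
under a rescaled multiplier; the scenario-wide switch is the simplest
parameterization consistent with the three reported population conditions.

## Randomness and reproducibility

A master seed spawns one child seed per (scenario, engagement, replicate)
via `numpy.random.SeedSequence([master, scenario_index, engagement_index,
replicate])`, reduced mod 2³¹; within a replicate the five pipeline stages
draw from seeds spawned from the replicate seed. All child seeds are
recorded in the run manifest so any replicate is re-runnable in isolation.
Identical config + master seed yields byte-identical CSV output (floats are
written as `%.17g` and read back with round-trip parsing).

Percentiles use the nearest-rank method (no interpolation rule is published);
with 50 replicates the 2.5th/97.5th percentiles are the 2nd and 49th order
statistics. Prevalences are compared with published one-decimal percentages
after half-up rounding (`percent_round`).

## What the synthetic data does and does not capture

The generator reproduces the published study conditions: marginal
demographics, tier counts, the baseline hours distribution and the
calibrated dose–response. It does not model joint demographic structure,
realistic social-network topology (clustering, degree heterogeneity),
within-band ages, non-TV news sources, a social-media-only exposure pathway,
or symptom dynamics over time. Passing tests therefore demonstrate the
internal consistency of the simulation and its agreement with the published
aggregate results — not the external validity of the underlying
epidemiological parameters.

## Numerical choices and problem sizes

Unit and property tests run at 10,000–100,000 agents, where binomial error
bands (3–4 SE) are tight enough to detect category-level mistakes while
each pipeline run stays under ~0.1 s. End-to-end checks and the acceptance
script run the full 118,000 agents × 50 replicates per condition; the Monte
Carlo standard error of a 50-replicate mean at baseline prevalence is
≈0.007 percentage points, far inside one-decimal rounding. Hours-weight
validation uses a 1e-9 sum tolerance; marginal-table loading renormalizes
attribute sums within 0.5% of 1 (printed census tables carry rounding
residue, e.g. the race/ethnicity column sums to 99.996%) and rejects larger
deviations.

## Known limitations

- Calibrated parameters (p₂, p₃, f, multipliers) reproduce the published
  aggregates by construction; only scenario 1, the conditional dose–response
  endpoints, tier construction, and the property suite are non-circular
  checks.
- The discrepancy in the published tertiary count (112,189 vs the implied
  112,345) is resolved in favor of internal consistency; prevalences are
  insensitive to the 156-agent difference.
- Primary- and secondary-tier agents carry no PTSD risk in scope, so
  reported prevalence is media-mediated community prevalence, not total
  post-event prevalence.
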