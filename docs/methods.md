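# Methods

## World and time

The field is a continuous `[0, 100] × [0, 100]` plane.  The default
world scatters 1000 sites i.i.d. uniformly over it; the agent starts
every trial at (50.00, 50.00) and runs for 10 000 discrete time steps
(200 in the short-horizon comparison).  One time step is consumed by
exactly one action — moving onto a selected site (regardless of its
distance) or taking one random cardinal step of length 1 — so time is
counted in decisions, not distance.  Sites are never depleted: a visit
changes nothing about the world.

Although coordinates are continuous, the agent's reachable set is
effectively discrete: after its first site visit it sits exactly on
site coordinates, and random-walk positions are lattice offsets from
wherever the walk began.  The simulator exploits this by memoizing the
local-site query per exact position, which is what makes 100-trial,
10 000-step experiments run in seconds.

## Perception and site selection

The agent sees the *local sites* within a closed ball of radius 4.00
around its position.  The site it currently occupies (distance exactly
zero) is never a candidate — otherwise the nearest-site rule would
re-select it forever.  Two selection rules act on the candidates:

- **Exploitation**: minimum distance from the agent; exact ties broken
  uniformly at random.
- **Exploration**: the candidate "furthest from the local sites",
  implemented as the maximum mean distance to the *other* candidates —
  i.e. the most isolated site of the perceived scene.  This reading
  (rather than "farthest from the agent") sends exploration bursts to
  cluster edges, from which the next scene contains fresh sites; it is
  also what makes the fixed-exploration control measurably more mobile
  than the fixed-exploitation one, as observed in the reference
  experiments.  With a single candidate both rules coincide.

When no site is visible the agent steps 1.0 north/east/south/west with
probability 1/4 each.  Boundary handling for that walk is reflecting by
default (configurable to clamping); site selection never leaves the
field, so the choice only affects empty-field excursions.

## Scene memory and rule switching

The agent's only memory in the main model is one integer,
`memory_sum`, plus the step at which it was stored:

1. On the first perceiving step (and on the first perceiving step
   after every expiry) the current local-site count is **stored**; no
   comparison happens on a storing step, since a freshly stored count
   trivially equals itself.
2. The memory is **held for θ steps counting the storage step**: it
   expires once `step − stored_at ≥ θ`, so matches are possible at lags
   1 … θ−1.  θ = 1 therefore never compares and degenerates to fixed
   exploitation.
3. While held, a perceiving step whose count **equals** `memory_sum`
   flips the selection rule with probability 0.5.  The memory survives
   the match (only expiry clears it), and the agent moves under the
   *new* rule on the same step.

The expiry convention deserves a note, because the pooled results are
surprisingly sensitive to it.  Pinned revisitation cycles have period
two, so the parity of the re-storage lag determines whether the memory
is always stored at the same phase of a cycle (matches fire every
revisit) or at alternating phases (matches are rarer and rule phases
last longer).  Counting the storage step inside the θ-step window —
expiry at lag θ — is both the natural reading of "the memory is stored
for θ time steps" and the only convention under which the θ-sweep
behaves smoothly: visits are maximal near θ = 5 (mean ≈ 13–16 distinct
sites at the default configuration) and drop to a plateau of ≈ 7–8 from
θ = 10 onward.  Under the alternative (expiry at lag θ+1) the sweep
becomes a parity-driven zigzag.

Default rule is exploitation; `switch_prob = 0` makes the model
trajectory-identical to the fixed-exploitation control on a shared
seed (the switch coin is only drawn when it can matter, so the RNG
streams stay aligned).

## Control models

Three memory-free controls pin the selection for a whole trial:
nearest site, most isolated site, or a uniform-random candidate.

The spatial-memory control stores up to `n_locations` visited site
locations, each carrying two clocks from its last visit:

- **working memory** (θ_work = 5): while active the site is *avoided* —
  it is excluded from the exploitation candidates;
- **reference memory** (θ_reference = 10): while alive (and once the
  working memory has lapsed) the site is a candidate for a deliberate
  return, attempted with probability `prob` per step and executed as a
  direct one-step relocation (spatial memory implies the agent knows
  the way); a site not revisited within θ_reference is forgotten.

A full memory accepts no new sites; a slot frees only when a reference
memory lapses.  These two choices — avoidance-by-exclusion and
keep-until-forgotten — are what give the model its characteristic
behaviour: avoidance forces novelty (more remembered sites ⇒ more
distinct visits; 200-step means ≈ 3.6 at one slot vs ≈ 10 at five),
while higher `prob` drags the agent back to known sites and lowers the
count (≈ 4.4 / 4.1 / 3.6 at prob 0.2 / 0.5 / 0.8).  Under the simpler
reading in which working memory merely gates returns, the model
collapses onto fixed exploitation for every parameter setting, which
contradicts the reference behaviour this package reproduces.  A
consequence worth flagging: `prob = 0` alone does *not* reduce the
model to fixed exploitation (avoidance still operates); the exact
degenerate limit is `prob = 0` together with `theta_work = 0`, and that
equivalence is exercised trajectory-for-trajectory in the tests.

## Statistics

**Distinct visits.** The headline statistic is the number of unique
sites visited per trial, pooled as a mean over 100 trials.  Its
distribution is strongly right-skewed (mode 6–8, occasional trials
above 50 at defaults), so pooled means carry a 95% CI of roughly ±1.5
even at 100 trials; comparisons between models use the Mann–Whitney
rank-sum test (scipy) rather than the means alone.

**Revisit tails.** Per-site visit counts from a single trial are fitted
by maximum likelihood to two one-parameter discrete families on
support x ≥ 1: the zeta-normalised power law `p(x) = x^−μ / ζ(μ)`
(μ searched on (1, 50] by bounded scalar minimisation) and the discrete
exponential/geometric `p(x) = (1 − e^−λ) e^−λ(x−1)` (closed-form MLE).
AIC = 2 − 2 log L per family and Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)` arbitrate between them.  `x_min = 1`
because revisit counts start at one; an all-equal count vector is a
degenerate fit and is reported with a warning.  Parameter recovery of
both estimators is verified against numpy's independent zipf and
geometric samplers.

**Mean-squared displacement.** R²(t) is the squared Euclidean distance
from the trial's fixed start position, averaged across trials per step
and then over bins of 10 steps, reported at the bin midpoint t (and
t²).  "Saturation" is operationalised as: the last bin's ⟨R²⟩ is less
than twice ⟨R²⟩ near t = 200.  The rule-change model saturates (ratio
≈ 1.3 at defaults); the random-choice control does not (ratio ≈ 3.4 and
growing with trial length).

**Density maps.** Occupancy histograms of all logged positions with
half-open square bins of width 4.00; positions exactly on the upper
field boundary are counted in the last bin so mass is conserved.

## Reproducibility

Trial i of an experiment uses seed `base_seed + i`; a trial draws its
site field and then all behavioural randomness (direction draws, switch
coins, tie breaks, return lotteries) from one `numpy` Generator in a
fixed order, so a trial is a pure function of (config, seed).  Batch
runs write a manifest (config, seed range, version) sufficient to
reproduce every artifact byte-for-byte.

## Known limitations

- Two pooled means sit just outside a ±20% band around their reference
  values under every defensible reading of the model that we tested:
  the default-configuration rule-change mean (≈ 12.5–13.5 here vs
  16.66) and the 1500-site mean (≈ 19–19.5 vs 15.50).  Both statistics
  have heavy-tailed trial distributions, and every variant that closed
  one gap opened a larger one elsewhere; the values reported by
  `scripts/acceptance.py` are the model's honest output.
- The synthetic worlds are uniform Poisson-like site fields; real
  resource landscapes are patchy and dynamic, so passing tests say
  nothing about depletion, renewal or heterogeneous patch structure.
- One agent only; no interaction, no learning of `switch_prob`, no
  heterogeneous θ.
- The tail comparison is a two-family AIC arbitration, not a
  goodness-of-fit claim: no bootstrap KS p-values are computed, and a
  power-law Akaike win does not certify power-law data.
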