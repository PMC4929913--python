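# homerange

An agent-based simulator of foraging movement in which a **weak home
range** — bounded, revisitation-heavy movement punctuated by occasional
shifts to new regions — emerges *without any spatial memory*.

The model is aimed at movement ecologists and behavioural modellers who
study how simple cognition can produce home-range-like space use.  A
single agent moves among point sites ("food sources") scattered
uniformly over a bounded planar field.  At each time step it perceives
the *local sites* within its visual radius and moves onto one of them
under its current selection rule:

- **exploitation** — the site nearest the current position;
- **exploration** — the site furthest from the local scene (the
  candidate with the greatest mean distance to the other local sites).

When nothing is visible it takes a unit step in a random cardinal
direction (reflecting at the field boundary).

The only memory the agent carries is a **scene memory**: the count of
local sites, `memory_sum`, stored when first perceived and held for θ
time steps.  While the memory is held, a step whose local-site count
equals `memory_sum` makes the agent suspect it has looped back to
familiar ground, and it swaps its selection rule with probability 0.5.
Exploitation pins the agent into revisitation cycles among a few sites;
scene matches then trigger exploration bursts that relocate the range.
The result is a heavy-tailed (power-law) distribution of per-site
revisit counts and a mean-squared displacement ⟨R²(t)⟩ that saturates
after ~100 steps — the two signatures of a weak home range.

For calibration the package also implements four control models
(fixed exploitation, fixed exploration, uniform-random choice, and a
two-clock working/reference spatial-memory forager) and the movement
statistics used to compare them: distinct-visit counts, revisit
distributions with discrete power-law vs exponential maximum-likelihood
fits arbitrated by Akaike weights, binned MSD curves, and trajectory
density maps.

## Worked example

```python
from homerange import (SimulationConfig, run_trial, distinct_visited,
                       revisit_distribution, fit_tail)

cfg = SimulationConfig()          # 1000 sites, radius 4.00, theta=5, 10000 steps
log = run_trial(cfg, seed=0)
print("distinct sites visited:", distinct_visited(log))
print("rule switches:", log.n_rule_switches)

rd = revisit_distribution(log)
power, expo = fit_tail(rd.values())
print(f"sites ever visited (n_data): {rd.n_data}")
print(f"power-law: mu={power.exponent:.2f}, Akaike weight={power.akaike_weight:.2f}")
print(f"exponential: lambda={expo.exponent:.3f}, Akaike weight={expo.akaike_weight:.2f}")
```

prints

```
distinct sites visited: 49
rule switches: 2192
sites ever visited (n_data): 49
power-law: mu=1.27, Akaike weight=1.00
exponential: lambda=0.005, Akaike weight=0.00
```

This seed happens to be a wide-ranging trial: the agent touched 49
distinct sites in 10 000 steps, yet its revisit counts are strongly
heavy-tailed — a handful of sites soak up thousands of visits while
most are touched a few times — so the power law wins the Akaike
comparison outright (weight 1.00) with a shallow exponent μ ≈ 1.27.
Trial-to-trial variation is large by design; the distribution of
distinct-visit counts has a mode near 6–8 sites and a long right tail.

The same experiment from the shell:

```bash
homerange run --model rule_change --n-trials 10 --seed 0 --out out/demo
# rule_change: mean distinct visited = 20.20 over 10 trials
homerange sweep --param theta --values 5,10,20 --n-trials 100 --out out/theta
homerange compare out/a/summary.csv out/b/summary.csv   # Mann-Whitney U
```

Every run writes a per-trial `summary.csv`, pooled statistics and a
`manifest.json` (config + seed range + version) from which it can be
reproduced exactly; `--analyze` adds revisit, tail-fit, MSD and density
artifacts as CSV/JSON.

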