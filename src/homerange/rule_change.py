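"""Scene-memory-triggered switching between exploitation and exploration.

The agent defaults to the exploitation rule (move to the nearest visible
site).  On every step where it perceives local sites it also maintains a
single *scene memory*: the count of local sites seen when the memory was
last stored.  If the current count matches the remembered one, the agent
suspects it has looped back to familiar ground and flips its selection
rule with probability ``switch_prob``.  The memory is held for ``theta``
steps (counting the storage step) and re-stored on the first perceiving
step after it lapses; the comparison never fires on a storing step.

The exploration rule moves to the site furthest from the local scene:
among the perceived candidates, the one with the greatest mean distance
to the other local sites, i.e. the most isolated site in view.  This
pushes the agent toward the edge of the cluster it is in rather than
merely to the far side of its visual field.

Order within a step: perceive -> memory update / compare (possible rule
flip) -> select a site under the (possibly new) rule -> move.  When no
site is visible the agent takes one unit step in a random cardinal
direction instead.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .core import (
    AgentState,
    Rule,
    SceneMemory,
    SimulationConfig,
    SiteField,
    VisitLog,
    generate_site_field,
    local_sites,
    random_cardinal_step,
)

__all__ = [
    "select_site",
    "exploration_scores",
    "update_scene_memory",
    "step",
    "run_trial",
]


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------

def _pick_extremum(values: np.ndarray, maximize: bool, rng: np.random.Generator) -> int:
    target = values.max() if maximize else values.min()
    ties = np.flatnonzero(values == target)
    return int(ties[0]) if len(ties) == 1 else int(ties[rng.integers(len(ties))])


def exploration_scores(candidates: np.ndarray) -> np.ndarray:
    """Isolation score of each candidate: mean distance to the others.

    A single candidate scores 1 (it is trivially the choice).  The
    exploration rule selects the maximum-score candidate.
    """
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)
    n = len(candidates)
    if n <= 1:
        return np.ones(n)
    diff = candidates[:, None, :] - candidates[None, :, :]
    dm = np.sqrt((diff**2).sum(-1))
    return dm.sum(axis=1) / (n - 1)


def select_site(
    rule: Rule,
    candidates: np.ndarray,
    position,
    rng: np.random.Generator,
) -> int:
    """Index of the candidate chosen under ``rule``.

    EXPLOITATION takes the candidate nearest the agent; EXPLORATION the
    candidate furthest from the local scene (max mean distance to the
    other candidates).  Exact score ties are broken uniformly at random.
    Raises on an empty candidate list — the caller must branch to a
    random cardinal step instead.
    """
    candidates = np.asarray(candidates, dtype=float).reshape(-1, 2)
    if len(candidates) == 0:
        raise ValueError("select_site requires a non-empty candidate list")
    if rule is Rule.EXPLOITATION:
        d = np.hypot(*(candidates - np.asarray(position, float)).T)
        return _pick_extremum(d, maximize=False, rng=rng)
    return _pick_extremum(exploration_scores(candidates), maximize=True, rng=rng)


# ---------------------------------------------------------------------------
# Scene memory
# ---------------------------------------------------------------------------

def update_scene_memory(
    memory: SceneMemory,
    rule: Rule,
    n_local: int,
    step_index: int,
    theta: int,
    switch_prob: float,
    rng: np.random.Generator,
) -> tuple[Rule, bool]:
    """Store / compare the scene memory; possibly flip the rule.

    Called only on steps where ``n_local >= 1`` sites are perceived.  If
    the memory is empty or lapsed (``theta`` or more steps since
    storage) the current count is stored and no comparison happens this
    step.  Otherwise a count equal to ``memory_sum`` flips the rule with
    probability ``switch_prob``; the memory survives a match and is only
    cleared by expiry.
    """
    if n_local < 1:
        raise ValueError("scene memory is only updated when local sites are perceived")
    if memory.expired(step_index, theta):
        memory.store(n_local, step_index)
        return rule, False
    if n_local == memory.memory_sum:
        # short-circuit keeps the RNG stream identical to the fixed-rule
        # controls when switch_prob == 0
        if switch_prob > 0.0 and rng.random() < switch_prob:
            return rule.other(), True
    return rule, False


# ---------------------------------------------------------------------------
# Stepping engine (shared with the memory-free controls)
# ---------------------------------------------------------------------------

class _LocalSiteCache:
    """Memoized closed-ball site lookup for a static field.

    Agents revisit the same positions constantly (that is the point of
    the model), so caching by exact position avoids repeated KD-tree
    queries and isolation-score computations.  Distance-zero candidates
    (the occupied site) are excluded.
    """

    def __init__(self, field: SiteField, radius: float):
        self.field = field
        self.radius = radius
        self._cache: dict[tuple[float, float], tuple] = {}

    def get(self, position: np.ndarray):
        key = (float(position[0]), float(position[1]))
        hit = self._cache.get(key)
        if hit is None:
            idx = self.field.query_radius(position, self.radius)
            if len(idx):
                d = np.hypot(*(self.field.coords[idx] - position).T)
                keep = d > 0.0
                idx, d = idx[keep], d[keep]
            else:
                d = np.empty(0)
            iso = exploration_scores(self.field.coords[idx])
            hit = (self.field.site_ids[idx], d, self.field.coords[idx], iso)
            self._cache[key] = hit
        return hit


def _choose(rule: Rule, dists: np.ndarray, iso: np.ndarray, rng: np.random.Generator) -> int:
    if rule is Rule.EXPLOITATION:
        return _pick_extremum(dists, maximize=False, rng=rng)
    return _pick_extremum(iso, maximize=True, rng=rng)


def _simulate(
    config: SimulationConfig,
    field: SiteField,
    rng: np.random.Generator,
    selector: Callable[[Rule, np.ndarray, np.ndarray, np.random.Generator], int],
    use_scene_memory: bool,
    label: Optional[str] = None,
) -> VisitLog:
    """Run one trial with a pluggable per-step site selector.

    ``selector(rule, distances, isolation_scores, rng)`` returns the
    chosen candidate index.  With ``use_scene_memory`` the rule-change
    memory logic runs before selection; without it the rule is fixed for
    the whole trial.
    """
    cache = _LocalSiteCache(field, config.visual_radius)
    pos = np.asarray(config.start_position, dtype=float)
    rule = Rule.EXPLOITATION
    memory = SceneMemory()
    n_switch = 0

    positions = np.empty((config.n_steps + 1, 2))
    positions[0] = pos
    rules: list[str] = [label or rule.value]
    events: list[tuple[int, int]] = []

    for t in range(1, config.n_steps + 1):
        ids, dists, coords, iso = cache.get(pos)
        if len(ids) == 0:
            pos = random_cardinal_step(
                pos,
                config.step_size,
                rng,
                config.field_width,
                config.field_height,
                config.boundary,
            )
        else:
            if use_scene_memory:
                rule, switched = update_scene_memory(
                    memory, rule, len(ids), t, config.theta, config.switch_prob, rng
                )
                n_switch += switched
            k = selector(rule, dists, iso, rng)
            pos = coords[k].copy()
            events.append((t, int(ids[k])))
        positions[t] = pos
        rules.append(label or rule.value)

    return VisitLog(
        positions=positions,
        rules=rules,
        events=events,
        start_position=config.start_position,
        n_rule_switches=n_switch,
    )


def step(
    state: AgentState,
    field: SiteField,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> Optional[int]:
    """Advance ``state`` by one time step; return the visited site id or None.

    Perceive local sites; with none visible take one random cardinal
    step, otherwise run the scene-memory logic (possible rule flip) and
    move onto the site selected under the current rule.
    """
    state.step += 1
    ids, dists = local_sites(field, state.position, config.visual_radius)
    if len(ids) == 0:
        state.position = random_cardinal_step(
            state.position,
            config.step_size,
            rng,
            config.field_width,
            config.field_height,
            config.boundary,
        )
        return None
    state.rule, _ = update_scene_memory(
        state.memory, state.rule, len(ids), state.step, config.theta, config.switch_prob, rng
    )
    coords = np.array([field.position_of(int(s)) for s in ids])
    k = select_site(state.rule, coords, state.position, rng)
    state.position = coords[k].copy()
    return int(ids[k])


def run_trial(
    config: SimulationConfig, seed: int, field: Optional[SiteField] = None
) -> VisitLog:
    """One complete rule-change trial; deterministic given ``seed``.

    A fresh uniform site field is drawn from the trial stream unless an
    explicit ``field`` is supplied (e.g. loaded from CSV).
    """
    rng = np.random.default_rng(seed)
    if field is None:
        field = generate_site_field(config, rng)
    return _simulate(config, field, rng, _choose, True)
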