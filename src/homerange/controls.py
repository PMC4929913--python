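"""Control models: three memory-free fixed policies and a spatial-memory agent.

The memory-free controls share the rule-change stepping skeleton but
never consult scene memory: site selection is pinned to nearest (fixed
exploitation), most scene-isolated (fixed exploration) or uniform-random
(random choice) for the whole trial.

The spatial-memory control stores the *locations* of up to
``n_locations`` visited sites.  Each remembered site carries two clocks
measured from its last visit: a short working memory that makes the
agent avoid the site (it is excluded from the exploitation candidates
while active), and a longer reference memory that lets the agent
deliberately return to it (with probability ``prob`` per step) once the
working memory has lapsed.  A site not revisited within the reference
span is forgotten and frees its memory slot; while all slots are
occupied, newly visited sites are not committed to memory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    Rule,
    SimulationConfig,
    SiteField,
    VisitLog,
    generate_site_field,
    random_cardinal_step,
)
from .rule_change import _LocalSiteCache, _pick_extremum, _simulate

__all__ = [
    "ControlPolicy",
    "SpatialMemoryConfig",
    "run_control_trial",
    "run_spatial_memory_trial",
]


class ControlPolicy(enum.Enum):
    FIXED_EXPLOITATION = "fixed_exploitation"
    FIXED_EXPLORATION = "fixed_exploration"
    RANDOM_CHOICE = "random_choice"


def _selector_for(policy: ControlPolicy):
    from .rule_change import _choose

    if policy is ControlPolicy.FIXED_EXPLOITATION:
        return lambda rule, d, iso, rng: _choose(Rule.EXPLOITATION, d, iso, rng)
    if policy is ControlPolicy.FIXED_EXPLORATION:
        return lambda rule, d, iso, rng: _choose(Rule.EXPLORATION, d, iso, rng)
    return lambda rule, d, iso, rng: int(rng.integers(len(d)))


def run_control_trial(
    config: SimulationConfig,
    policy: ControlPolicy,
    seed: int,
    field: Optional[SiteField] = None,
) -> VisitLog:
    """One trial with a fixed site-selection policy; no scene memory."""
    rng = np.random.default_rng(seed)
    if field is None:
        field = generate_site_field(config, rng)
    return _simulate(
        config, field, rng, _selector_for(policy), use_scene_memory=False,
        label=policy.value,
    )


# ---------------------------------------------------------------------------
# Spatial-memory control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialMemoryConfig:
    """Two-clock spatial memory: working (avoidance) and reference (return).

    Both clocks run from a site's last visit.  While the working memory
    is active (``last visit < theta_work`` steps ago) the site is
    avoided; once it lapses but the reference memory is still alive
    (up to ``theta_reference`` steps) the site is a candidate for a
    deliberate return, attempted with probability ``prob`` per step.
    ``n_locations`` caps how many sites are remembered at once; a full
    memory accepts no new site until a reference memory lapses.
    """

    theta_reference: int = 10
    theta_work: int = 5
    prob: float = 0.5
    n_locations: int = 1

    def __post_init__(self) -> None:
        if not self.theta_work < self.theta_reference:
            raise ValueError("theta_work must be < theta_reference")
        if self.theta_work < 0:
            raise ValueError("theta_work must be >= 0")
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("prob must lie in [0, 1]")
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")


def run_spatial_memory_trial(
    config: SimulationConfig,
    mem_config: SpatialMemoryConfig,
    seed: int,
    field: Optional[SiteField] = None,
) -> VisitLog:
    """One trial of the spatial-memory agent; deterministic given ``seed``.

    Per step: (1) remembered sites not revisited within
    ``theta_reference`` are forgotten; (2) with probability ``prob`` the
    agent relocates directly to one remembered site whose working memory
    has lapsed (uniform among several); (3) otherwise it applies the
    exploitation rule to local sites whose working memory is not active,
    or takes a random cardinal step when none qualify; (4) a visited
    site refreshes its memory entry, or claims a free slot if one
    exists.

    With ``prob = 0`` and ``theta_work = 0`` the model degenerates to
    the fixed-exploitation control, trajectory for trajectory on a
    shared seed.
    """
    rng = np.random.default_rng(seed)
    if field is None:
        field = generate_site_field(config, rng)
    cache = _LocalSiteCache(field, config.visual_radius)

    pos = np.asarray(config.start_position, dtype=float)
    positions = np.empty((config.n_steps + 1, 2))
    positions[0] = pos
    label = "spatial_memory"
    rules = [label]
    events: list[tuple[int, int]] = []
    memory: dict[int, list] = {}  # site_id -> [last_visit_step, coords]

    for t in range(1, config.n_steps + 1):
        for sid in [s for s, (lv, _) in memory.items() if t - lv > mem_config.theta_reference]:
            del memory[sid]
        visit: Optional[int] = None
        # the prob coin is drawn once per step; skipping the draw at
        # prob == 0 keeps the stream identical to fixed exploitation
        if mem_config.prob > 0.0 and rng.random() < mem_config.prob:
            eligible = [s for s, (lv, _) in memory.items() if t - lv > mem_config.theta_work]
            if eligible:
                sid = (
                    eligible[0]
                    if len(eligible) == 1
                    else eligible[int(rng.integers(len(eligible)))]
                )
                pos = memory[sid][1].copy()
                visit = sid
        if visit is None:
            ids, dists, coords, _ = cache.get(pos)
            if len(ids):
                blocked = {s for s, (lv, _) in memory.items() if t - lv <= mem_config.theta_work}
                keep = np.array([s not in blocked for s in ids]) if blocked else None
                if keep is not None:
                    ids, dists, coords = ids[keep], dists[keep], coords[keep]
            if len(ids):
                k = _pick_extremum(dists, maximize=False, rng=rng)
                pos = coords[k].copy()
                visit = int(ids[k])
            else:
                pos = random_cardinal_step(
                    pos,
                    config.step_size,
                    rng,
                    config.field_width,
                    config.field_height,
                    config.boundary,
                )
        if visit is not None:
            events.append((t, visit))
            if visit in memory:
                memory[visit][0] = t
            elif len(memory) < mem_config.n_locations:
                memory[visit] = [t, pos.copy()]
        positions[t] = pos
        rules.append(label)

    return VisitLog(
        positions=positions,
        rules=rules,
        events=events,
        start_position=config.start_position,
    )
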