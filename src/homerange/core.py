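"""Domain types, geometry and random-number contracts shared by all models.

The world is a bounded planar field scattered with point sites (food
sources).  A single agent moves site-to-site inside it: each site
selection, or each unit random-walk step when no site is visible,
consumes exactly one time step.  Everything stochastic flows through a
per-trial :class:`numpy.random.Generator` so that a trial is a pure
function of ``(config, seed)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SimulationConfig",
    "SiteField",
    "Rule",
    "SceneMemory",
    "AgentState",
    "VisitLog",
    "generate_site_field",
    "local_sites",
    "random_cardinal_step",
    "trial_rng",
]

# Cardinal unit vectors in a fixed documented order; the direction draw is
# ``rng.integers(4)`` indexing this table.
_CARDINALS = np.array([(0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0)])  # N E S W


class Rule(enum.Enum):
    """Site-selection rule: nearest local site vs. farthest local site."""

    EXPLOITATION = "exploitation"
    EXPLORATION = "exploration"

    def other(self) -> "Rule":
        return Rule.EXPLORATION if self is Rule.EXPLOITATION else Rule.EXPLOITATION


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated trial.

    Defaults are the study conditions: a 100.00 x 100.00 field with 1000
    uniformly scattered sites, visual radius 4.00, scene-memory lifetime
    ``theta`` = 5 steps, switch probability 0.5, 10 000 steps starting
    from the field centre.
    """

    field_width: float = 100.0
    field_height: float = 100.0
    n_sites: int = 1000
    visual_radius: float = 4.0
    step_size: float = 1.0
    n_steps: int = 10_000
    theta: int = 5
    switch_prob: float = 0.5
    start_position: tuple[float, float] = (50.0, 50.0)
    base_seed: int = 0
    boundary: str = "reflect"  # reflect | clamp

    def __post_init__(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.visual_radius <= 0 or self.step_size <= 0:
            raise ValueError("visual_radius and step_size must be positive")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in [0, 1]")
        x, y = self.start_position
        if not (0.0 <= x <= self.field_width and 0.0 <= y <= self.field_height):
            raise ValueError("start_position must lie inside the field")
        if self.boundary not in ("reflect", "clamp"):
            raise ValueError("boundary must be 'reflect' or 'clamp'")

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (keys validated)."""
        for key in kwargs:
            if key not in self.__dataclass_fields__:
                raise KeyError(f"unknown config field: {key!r}")
        return replace(self, **kwargs)


class SiteField:
    """Immutable set of point sites with stable integer identifiers.

    Wraps an ``(n, 2)`` coordinate array plus a KD-tree for radius
    queries; site ids are the row indices ``0..n-1`` unless explicit ids
    are supplied (e.g. from a CSV).
    """

    def __init__(self, coords: np.ndarray, site_ids: Optional[np.ndarray] = None):
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        self.coords = coords
        self.coords.setflags(write=False)
        if site_ids is None:
            site_ids = np.arange(len(coords))
        else:
            site_ids = np.asarray(site_ids, dtype=int)
            if len(site_ids) != len(coords):
                raise ValueError("site_ids and coords length mismatch")
            if len(np.unique(site_ids)) != len(site_ids):
                raise ValueError("site_ids must be unique")
        self.site_ids = site_ids
        self.site_ids.setflags(write=False)
        self._tree = cKDTree(coords) if len(coords) else None

    def __len__(self) -> int:
        return len(self.coords)

    def position_of(self, site_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.site_ids == site_id)[0])
        return self.coords[idx]

    def query_radius(self, position: Sequence[float], radius: float):
        """Indices (not ids) of sites within the closed ball of ``radius``."""
        if self._tree is None:
            return np.empty(0, dtype=int)
        idx = self._tree.query_ball_point(np.asarray(position, float), radius)
        return np.asarray(sorted(idx), dtype=int)

    # -- CSV round-trip (header: site_id,x,y) --------------------------------
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"site_id": self.site_ids, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SiteField":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df[["x", "y"]].to_numpy(float), df["site_id"].to_numpy(int))


@dataclass
class SceneMemory:
    """One remembered local-site count and the step at which it was stored.

    ``memory_sum`` is the number of sites the agent saw at storage time.
    The memory is held for ``theta`` steps counting the storage step
    itself, i.e. it is forgotten once ``step - stored_at >= theta``, so
    comparisons are possible at lags ``1 .. theta-1``.
    """

    memory_sum: Optional[int] = None
    stored_at: Optional[int] = None

    @property
    def empty(self) -> bool:
        return self.memory_sum is None

    def expired(self, step: int, theta: int) -> bool:
        return self.empty or (step - self.stored_at) >= theta

    def store(self, n_local: int, step: int) -> None:
        if n_local < 1:
            raise ValueError("scene memory stores only perceived (>=1) counts")
        self.memory_sum = n_local
        self.stored_at = step


@dataclass
class AgentState:
    position: np.ndarray
    rule: Rule = Rule.EXPLOITATION
    memory: SceneMemory = field(default_factory=SceneMemory)
    step: int = 0


@dataclass
class VisitLog:
    """Per-step positions and rule labels plus ordered site-visit events.

    ``positions`` has ``n_steps + 1`` rows (step 0 included); ``rules``
    labels the rule active when each position was reached.  ``events`` is
    the ordered list of ``(step, site_id)`` visit events.
    """

    positions: np.ndarray
    rules: list[str]
    events: list[tuple[int, int]]
    start_position: tuple[float, float]
    n_rule_switches: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    def visited_site_ids(self) -> np.ndarray:
        return np.unique([sid for _, sid in self.events])

    def to_frame(self) -> pd.DataFrame:
        """Trajectory table ``step,x,y,rule,site_id`` (site_id empty on non-visits)."""
        site_col = np.full(len(self.positions), np.nan)
        for step, sid in self.events:
            site_col[step] = sid
        return pd.DataFrame(
            {
                "step": np.arange(len(self.positions)),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "rule": list(self.rules),
                "site_id": site_col,
            }
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def trial_rng(base_seed: int, trial: int = 0) -> np.random.Generator:
    """Per-trial RNG stream: seed = base_seed + trial index.

    All randomness of a trial (site field, direction draws, switch coin,
    tie breaks) is drawn from this single stream in a fixed order.
    """
    return np.random.default_rng(base_seed + trial)


def generate_site_field(config: SimulationConfig, seed_or_rng) -> SiteField:
    """Scatter ``config.n_sites`` i.i.d. uniform points over the field."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    xs = rng.uniform(0.0, config.field_width, config.n_sites)
    ys = rng.uniform(0.0, config.field_height, config.n_sites)
    return SiteField(np.column_stack([xs, ys]))


def local_sites(
    field: SiteField, position: Sequence[float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sites within the closed ball of ``radius`` around ``position``.

    Returns ``(site_ids, distances)`` ordered by site id.  The site the
    agent currently occupies (distance exactly 0) is excluded, so the
    exploitation rule always moves to a *different* site.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    idx = field.query_radius(position, radius)
    if len(idx) == 0:
        return np.empty(0, dtype=int), np.empty(0)
    d = np.hypot(*(field.coords[idx] - np.asarray(position, float)).T)
    keep = d > 0.0
    return field.site_ids[idx][keep], d[keep]


def _apply_boundary(pos: np.ndarray, width: float, height: float, mode: str) -> np.ndarray:
    if mode == "reflect":
        x, y = pos
        if x < 0.0:
            x = -x
        elif x > width:
            x = 2.0 * width - x
        if y < 0.0:
            y = -y
        elif y > height:
            y = 2.0 * height - y
        return np.array([x, y])
    return np.clip(pos, [0.0, 0.0], [width, height])


def random_cardinal_step(
    position: Sequence[float],
    step_size: float,
    rng: np.random.Generator,
    width: float = 100.0,
    height: float = 100.0,
    boundary: str = "reflect",
) -> np.ndarray:
    """Move one ``step_size`` north, east, south or west (p = 1/4 each).

    A step that would leave the field is reflected at the boundary (or
    clamped, if configured) so the position stays in bounds.
    """
    direction = _CARDINALS[rng.integers(4)]
    new = np.asarray(position, float) + step_size * direction
    return _apply_boundary(new, width, height, boundary)
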