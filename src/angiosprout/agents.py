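"""Endothelial-cell agents: filopodia, VEGF sensing, tip selection, movement.

Agents occupy one lattice site each.  Filopodia length sets the radius in
which a cell senses and binds extracellular VEGF-A; a cell adopts the tip
phenotype when VEGFR2 mRNA exceeds VEGFR1 mRNA, filopodia exceed A*, and
dll4 mRNA exceeds D* (all strictly).  Tips chemotax up the VEGF-A gradient
with a chance of deviating 45 degrees clockwise or counter-clockwise; the
vacated site is filled by a copy of a random non-tip neighbor (stalk
proliferation), which keeps sprouts connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ECAgent",
    "BehaviorParams",
    "MoveOutcome",
    "DIRECTIONS",
    "update_filopodia",
    "filopodia_step",
    "sensing_radius",
    "sensing_window",
    "sense_and_bind",
    "secrete_svegfr1",
    "is_tip",
    "tip_state",
    "gradient_direction",
    "move_tip",
    "neighbor_dll4",
    "moore_neighbors",
]

#: the 8 lattice directions in clockwise order starting north
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)
_DIR_INDEX = {d: i for i, d in enumerate(DIRECTIONS)}


@dataclass
class BehaviorParams:
    """Cell-behavior thresholds and rates.

    ``a_star``/``d_star`` are the filopodia and dll4-mRNA tip thresholds;
    filopodia extend at ``filopodia_ext_rate`` (sites/h) while VEGFR2a
    exceeds ``vegfr2a_setpoint`` and retract at ``filopodia_ret_rate``
    otherwise; ``move_rate`` (1/h) sets a tip's movement-attempt propensity;
    ``p_dev`` is the probability of each 45-degree deviation.
    """

    a_star: float = 2.0
    d_star: float = 40.0
    filopodia_ext_rate: float = 0.4
    filopodia_ret_rate: float = 0.2
    filopodia_max: float = 4.0
    vegfr2a_setpoint: float = 130.0
    p_dev: float = 0.3
    move_rate: float = 0.45
    deposit_radius: int = 0

    def __post_init__(self) -> None:
        if self.a_star <= 0 or self.d_star <= 0:
            raise ValueError("tip thresholds A*, D* must be > 0")
        if not 0.0 <= self.p_dev <= 0.5:
            raise ValueError("p_dev must be in [0, 0.5]")
        if min(self.filopodia_ext_rate, self.filopodia_ret_rate,
               self.filopodia_max, self.move_rate) < 0 or self.deposit_radius < 0:
            raise ValueError("rates and lengths must be >= 0")


@dataclass
class ECAgent:
    """One endothelial cell on the lattice."""

    id: int
    row: int
    col: int
    state: np.ndarray
    params: np.ndarray | None = None
    filopodia: float = 0.0
    phenotype: str = "non-tip"

    @property
    def pos(self) -> tuple[int, int]:
        return (self.row, self.col)

    @property
    def is_tip(self) -> bool:
        return self.phenotype == "tip"


# ---------------------------------------------------------------------------
# filopodia
# ---------------------------------------------------------------------------

def filopodia_step(length: float, vegfr2_active: float, b: BehaviorParams, dt: float) -> float:
    """Two-branch rule: extend while VEGFR2a exceeds its setpoint, else retract."""
    if vegfr2_active > b.vegfr2a_setpoint:
        length += b.filopodia_ext_rate * dt
    else:
        length -= b.filopodia_ret_rate * dt
    return min(max(float(length), 0.0), b.filopodia_max)


def update_filopodia(agent: ECAgent, b: BehaviorParams, dt: float,
                     vegfr2_active: float | None = None) -> ECAgent:
    if vegfr2_active is None:
        raise ValueError("pass the agent's current VEGFR2a amount")
    agent.filopodia = filopodia_step(agent.filopodia, vegfr2_active, b, dt)
    return agent


def sensing_radius(filopodia: float) -> int:
    """Sensing/binding radius in sites: one body site plus the filopodia."""
    return 1 + int(filopodia)


def sensing_window(row: int, col: int, radius: int, shape: tuple[int, int]):
    """Clipped square window slices around (row, col)."""
    r0, r1 = max(0, row - radius), min(shape[0], row + radius + 1)
    c0, c1 = max(0, col - radius), min(shape[1], col + radius + 1)
    return slice(r0, r1), slice(c0, c1)


def apply_vegf_exchange(grid: np.ndarray, row: int, col: int, radius: int,
                        delta: float) -> None:
    """Apply a net VEGF exchange: uptake proportionally over the sensing
    window (never below zero per site), release onto the cell's own site."""
    if delta >= 0:
        grid[row, col] += delta
        return
    win = sensing_window(row, col, radius, grid.shape)
    total = grid[win].sum()
    if total <= 0:
        return
    take = min(-delta, total)
    grid[win] -= grid[win] * (take / total)
    np.maximum(grid[win], 0.0, out=grid[win])


def sense_and_bind(agent: ECAgent, vegf, model, b: BehaviorParams, dt: float,
                   params: np.ndarray | None = None):
    """Bind VEGF within the sensing radius to the agent's free receptors.

    Association/dissociation follow the signaling model's VEGF reactions;
    the field is depleted proportionally to site contents and never below a
    site's own content.  Returns ``(agent, vegf)``.
    """
    radius = sensing_radius(agent.filopodia)
    win = sensing_window(agent.row, agent.col, radius, vegf.grid.shape)
    available = float(vegf.grid[win].sum())
    new_state, fx = model.euler_step(
        agent.state, dt, dll4_nb=0.0, vegf_local=available, params=params
    )
    agent.state = new_state if isinstance(new_state, np.ndarray) else new_state.amounts
    apply_vegf_exchange(vegf.grid, agent.row, agent.col, radius, fx.vegf_net)
    return agent, vegf


# ---------------------------------------------------------------------------
# secretion
# ---------------------------------------------------------------------------

def deposit(grid: np.ndarray, row: int, col: int, radius: int, amount: float) -> None:
    """Spread ``amount`` uniformly over the (clipped) deposit window."""
    if amount <= 0:
        return
    if radius == 0:
        grid[row, col] += amount
        return
    win = sensing_window(row, col, radius, grid.shape)
    n = (win[0].stop - win[0].start) * (win[1].stop - win[1].start)
    grid[win] += amount / n

def secrete_svegfr1(agent: ECAgent, sv, model, b: BehaviorParams, dt: float,
                    params: np.ndarray | None = None):
    """Export sVEGFR1 from the internal pool onto the field at the cell."""
    p = model._params(params)
    k = p[model.param_index["k_export"]]
    i = model.species_index("svegfr1_internal")
    q = min(agent.state[i], k * agent.state[i] * dt)
    agent.state[i] -= q
    deposit(sv.grid, agent.row, agent.col, b.deposit_radius, q)
    return agent, sv


# ---------------------------------------------------------------------------
# tip selection
# ---------------------------------------------------------------------------

def tip_state(vegfr2_mrna: float, vegfr1_mrna: float, dll4_mrna: float,
              filopodia: float, b: BehaviorParams) -> bool:
    """Strict tip criteria; boundary equality is non-tip."""
    return (
        vegfr2_mrna > vegfr1_mrna
        and filopodia > b.a_star
        and dll4_mrna > b.d_star
    )


def is_tip(agent: ECAgent, b: BehaviorParams, model=None) -> bool:
    s = agent.state
    if model is not None:
        get = lambda n: s[model.species_index(n)]
    else:  # SignalingState-like
        get = lambda n: s[n]
    return tip_state(get("vegfr2_mRNA"), get("vegfr1_mRNA"), get("dll4_mRNA"),
                     agent.filopodia, b)


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def gradient_direction(row: int, col: int, radius: int, grid: np.ndarray,
                       rng: np.random.Generator):
    """Direction of steepest VEGF increase among the 8 lattice directions.

    The slope along each direction is averaged over the sensing radius
    (differences to the center, normalized by Euclidean distance); exact
    ties are broken uniformly at random; a flat neighborhood gives None.
    """
    h, w = grid.shape
    center = grid[row, col]
    scores = np.full(8, -np.inf)
    for d, (dr, dc) in enumerate(DIRECTIONS):
        step = np.hypot(dr, dc)
        acc, cnt = 0.0, 0
        for k in range(1, radius + 1):
            r, c = row + k * dr, col + k * dc
            if not (0 <= r < h and 0 <= c < w):
                break
            acc += (grid[r, c] - center) / (k * step)
            cnt += 1
        if cnt:
            scores[d] = acc / cnt
    finite = np.isfinite(scores)
    if not finite.any():
        return None
    best = scores[finite].max()
    if np.isclose(best, 0.0, atol=1e-12) and np.allclose(
        scores[finite], 0.0, atol=1e-12
    ):
        return None  # flat within the sensing radius
    ties = np.flatnonzero(np.isclose(scores, best, rtol=1e-9, atol=1e-12) & finite)
    return DIRECTIONS[int(rng.choice(ties))]


@dataclass
class MoveOutcome:
    moved: bool
    target: tuple[int, int] | None = None
    vacated: tuple[int, int] | None = None
    stalk: ECAgent | None = None


def moore_neighbors(row: int, col: int, shape: tuple[int, int]):
    for dr, dc in DIRECTIONS:
        r, c = row + dr, col + dc
        if 0 <= r < shape[0] and 0 <= c < shape[1]:
            yield r, c


def choose_move_direction(direction, p_dev: float, rng: np.random.Generator):
    """Main direction with prob 1-2*p_dev, its 45-degree neighbors with p_dev each."""
    if direction is None:
        return DIRECTIONS[int(rng.integers(8))]
    i = _DIR_INDEX[direction]
    u = rng.random()
    if u < p_dev:
        return DIRECTIONS[(i - 1) % 8]
    if u < 2 * p_dev:
        return DIRECTIONS[(i + 1) % 8]
    return direction


def move_tip(
    agent: ECAgent,
    direction: tuple[int, int] | None,
    occupancy: dict[tuple[int, int], ECAgent],
    rng: np.random.Generator,
    *,
    grid_shape: tuple[int, int],
    p_dev: float = 0.2,
    spawn: Callable[[ECAgent, tuple[int, int]], ECAgent] | None = None,
) -> MoveOutcome:
    """Attempt one tip move with stalk proliferation into the vacated site.

    ``spawn(parent, pos)`` builds the new stalk agent (the engine supplies
    id assignment and per-cell parameter sampling); by default the neighbor
    is copied verbatim with the same id scheme left to the caller.
    """
    dr, dc = choose_move_direction(direction, p_dev, rng)
    target = (agent.row + dr, agent.col + dc)
    if not (0 <= target[0] < grid_shape[0] and 0 <= target[1] < grid_shape[1]):
        return MoveOutcome(False)
    if target in occupancy:
        return MoveOutcome(False)
    candidates = [
        occupancy[p]
        for p in moore_neighbors(agent.row, agent.col, grid_shape)
        if p in occupancy and not occupancy[p].is_tip
    ]
    if not candidates:
        return MoveOutcome(False)
    parent = candidates[int(rng.integers(len(candidates)))]
    vacated = agent.pos
    del occupancy[vacated]
    agent.row, agent.col = target
    occupancy[target] = agent
    if spawn is None:
        stalk = ECAgent(
            id=-1, row=vacated[0], col=vacated[1],
            state=np.array(parent.state, dtype=float, copy=True),
            params=None if parent.params is None else parent.params.copy(),
        )
    else:
        stalk = spawn(parent, vacated)
    occupancy[vacated] = stalk
    return MoveOutcome(True, target=target, vacated=vacated, stalk=stalk)


# ---------------------------------------------------------------------------
# Dll4 exchange
# ---------------------------------------------------------------------------

def neighbor_dll4(agent: ECAgent, occupancy: dict[tuple[int, int], ECAgent],
                  model, grid_shape: tuple[int, int]) -> float:
    """Trans-ligand available to ``agent``.

    Sum of Dll4 over occupied Moore-neighbor sites, each neighbor's ligand
    divided by that neighbor's own occupied-neighbor count (a cell's surface
    ligand is split among its contacts).
    """
    i_dll4 = model.species_index("dll4")
    total = 0.0
    for p in moore_neighbors(agent.row, agent.col, grid_shape):
        nb = occupancy.get(p)
        if nb is None:
            continue
        contacts = sum(
            1 for q in moore_neighbors(nb.row, nb.col, grid_shape) if q in occupancy
        )
        total += nb.state[i_dll4] / max(contacts, 1)
    return total
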