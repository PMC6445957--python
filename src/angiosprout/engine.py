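"""Simulation scheduler: the main loop, parameter sampling, and scenarios.

One outer step updates the extracellular fields, then visits every agent in
a fresh uniformly random permutation; each agent integrates its signaling,
exchanges VEGF and sVEGFR1 with the fields, trades Dll4 with its neighbors,
updates filopodia and phenotype, and (if a tip) attempts a chemotactic move
with stalk proliferation into the vacated site.  A single seeded RNG stream
drives every stochastic choice, so a run is bit-reproducible from
``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import agents as ag
from .fields import Field, MediumConfig, field_step
from .modelio import ModelDescription, packaged_model
from .signaling import NumericalError, SignalingModel

__all__ = [
    "SamplingConfig",
    "SimConfig",
    "SimRecord",
    "World",
    "sample_agent_params",
    "step",
    "run",
]

#: parameter-group membership used for per-cell sampling
GROUP_PREFIXES = {"tc": "vmax_tc_", "tl": "k_tl_"}
NICD_DEG_PARAM = "k_nicd_degradation"


def param_group(name: str) -> str | None:
    """Sampling group of a parameter: 'tc', 'tl', 'nicd_deg', or None."""
    for group, prefix in GROUP_PREFIXES.items():
        if name.startswith(prefix):
            return group
    if name == NICD_DEG_PARAM:
        return "nicd_deg"
    return None


@dataclass
class SamplingConfig:
    """Log-normal per-cell parameter sampling.

    ``sd_over_mean`` maps group name to the SD/mean ratio of the log-normal
    law each member parameter is drawn from (moment-matched so the
    distribution's mean is the configured mean and its SD is ratio*mean).
    ``select`` restricts which groups are sampled: one group name, 'all', or
    'none'.
    """

    sd_over_mean: dict[str, float] = field(
        default_factory=lambda: {"tc": 0.55, "tl": 0.55, "nicd_deg": 0.55}
    )
    select: str = "all"

    def __post_init__(self) -> None:
        for g, v in self.sd_over_mean.items():
            if v < 0:
                raise ValueError(f"SD/mean for group {g!r} must be >= 0")
        if self.select not in ("all", "none", *self.sd_over_mean, "tc", "tl", "nicd_deg"):
            raise ValueError(f"unknown sampling selector {self.select!r}")

    def ratio_for(self, group: str | None) -> float:
        if group is None or self.select == "none":
            return 0.0
        if self.select != "all" and group != self.select:
            return 0.0
        return float(self.sd_over_mean.get(group, 0.0))


def sample_agent_params(
    model: SignalingModel,
    sampling: SamplingConfig,
    rng: np.random.Generator,
    means: np.ndarray | None = None,
    fixed: tuple[str, ...] = (),
) -> np.ndarray:
    """Draw one cell's parameter vector.

    Sampled parameters follow log-normal laws parameterized by mean mu and
    SD = ratio*mu (sigma^2 = ln(1 + (SD/mu)^2), m = ln mu - sigma^2/2);
    non-sampled parameters stay at their means.
    """
    means = model.default_params if means is None else means
    out = np.array(means, dtype=float, copy=True)
    for i, name in enumerate(model.param_names):
        if name in fixed:
            continue
        ratio = sampling.ratio_for(param_group(name))
        mu = means[i]
        if ratio > 0.0 and mu > 0.0:
            sigma2 = math.log1p(ratio * ratio)
            out[i] = rng.lognormal(math.log(mu) - 0.5 * sigma2, math.sqrt(sigma2))
    return out


@dataclass
class SimConfig:
    """Run configuration; defaults are the packaged calibration."""

    grid_shape: tuple[int, int] = (100, 100)
    dx_um: float = 10.0
    dt: float = 0.5
    total_time: float = 199.0
    output_times: tuple[float, ...] = (60.0, 90.0, 120.0, 192.0, 199.0)
    seed: int = 0
    scenario: str = "wild_type"
    aggregates: tuple[tuple[float, float, float], ...] = (
        (0.5, 0.25, 4.0), (0.5, 0.75, 4.0),
    )
    medium: MediumConfig = field(default_factory=MediumConfig)
    behavior: ag.BehaviorParams = field(default_factory=ag.BehaviorParams)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelDescription | str | Path | None = None
    # extracellular transport (sites^2/h and 1/h)
    vegf_diffusion: float = 50.0
    sv_diffusion: float = 25.0
    svb_diffusion: float = 25.0
    vegf_deg: float = 0.02
    sv_deg: float = 0.1
    svb_deg: float = 0.2
    # parameter modifications, applied to the signaling means before sampling
    param_scales: dict[str, float] = field(default_factory=dict)
    param_values: dict[str, float] = field(default_factory=dict)
    # parameters pinned to their (modified) mean for every cell, exempt from
    # per-cell sampling — sensitivity sweeps impose one value on all cells
    fixed_params: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.total_time < 0:
            raise ValueError("total_time must be >= 0")
        if self.output_times and self.total_time < max(self.output_times):
            raise ValueError("total_time must cover the largest output time")
        if self.scenario not in ("wild_type", "vegfr1_ko", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def resolve_model(self) -> ModelDescription:
        if self.model is None:
            return packaged_model()
        if isinstance(self.model, ModelDescription):
            return self.model
        from .modelio import load_model

        return load_model(self.model)


@dataclass
class SimRecord:
    """Time-stamped snapshots and step-resolved tip/agent counts."""

    grid_shape: tuple[int, int]
    dx_um: float
    seed: int
    scenario: str
    snapshot_times: list[float] = field(default_factory=list)
    occupancy: list[np.ndarray] = field(default_factory=list)
    tip_counts: list[int] = field(default_factory=list)
    step_times: list[float] = field(default_factory=list)
    step_tip_counts: list[int] = field(default_factory=list)
    step_agent_counts: list[int] = field(default_factory=list)
    agent_table: pd.DataFrame | None = None

    def occupancy_at(self, time: float) -> np.ndarray:
        for t, occ in zip(self.snapshot_times, self.occupancy):
            if math.isclose(t, time, abs_tol=1e-9):
                return occ
        raise KeyError(f"no snapshot at t={time}")

    def arel_at(self, time: float) -> float:
        occ = self.occupancy_at(time)
        return 100.0 * occ.sum() / occ.size

    @property
    def final_arel(self) -> float:
        return 100.0 * self.occupancy[-1].sum() / self.occupancy[-1].size


class World:
    """Mutable simulation state backed by flat per-agent arrays."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.model = SignalingModel(config.resolve_model())
        self.rng = np.random.default_rng(config.seed)
        self.time = 0.0
        h, w = config.grid_shape

        means = np.array(self.model.default_params, copy=True)
        for name, scale in config.param_scales.items():
            means[self.model.param_index[name]] *= scale
        for name, value in config.param_values.items():
            means[self.model.param_index[name]] = value
        if config.scenario == "vegfr1_ko":
            means[self.model.param_index["vmax_tc_vegfr1"]] = 0.0
        self.param_means = means

        kon = means[self.model.param_index["kon_svegfr1"]]
        koff = means[self.model.param_index["koff_svegfr1"]]
        self._sv_kinetics = (float(kon), float(koff))

        ref = config.medium.vegf_reference
        self.vegf = Field.uniform("vegf", (h, w), ref,
                                  diffusion=config.vegf_diffusion,
                                  k_deg=config.vegf_deg, boundary_value=ref)
        self.sv = Field.uniform("svegfr1", (h, w), 0.0,
                                diffusion=config.sv_diffusion, k_deg=config.sv_deg)
        self.svb = Field.uniform("svegfr1b", (h, w), 0.0,
                                 diffusion=config.svb_diffusion, k_deg=config.svb_deg)

        cap = 1024
        nsp, npar = self.model.n_species, len(self.model.param_names)
        self.states = np.zeros((cap, nsp))
        self.params = np.zeros((cap, npar))
        self.pos = np.zeros((cap, 2), dtype=np.int32)
        self.filopodia = np.zeros(cap)
        self.tip = np.zeros(cap, dtype=bool)
        self.n_agents = 0
        # padded lattices: index with (row+1, col+1)
        self.occ = np.full((h + 2, w + 2), -1, dtype=np.int32)
        self.nbr_cnt = np.zeros((h + 2, w + 2), dtype=np.int32)

        # scratch buffer for the in-place Euler kernel (hot loop)
        self._vec = np.empty(self.model.n_vec)
        self._i_dll4 = self.model.species_index("dll4")
        self._i_v2a = self.model.species_index("vegfr2_active")
        self._i_v1m = self.model.species_index("vegfr1_mRNA")
        self._i_v2m = self.model.species_index("vegfr2_mRNA")
        self._i_d4m = self.model.species_index("dll4_mRNA")

        for fr, fc, radius in config.aggregates:
            self._seed_disc(int(round(fr * (h - 1))), int(round(fc * (w - 1))), radius)

    # -- agent management ------------------------------------------------
    def _grow(self) -> None:
        for name in ("states", "params", "pos", "filopodia", "tip"):
            arr = getattr(self, name)
            setattr(self, name, np.concatenate([arr, np.zeros_like(arr)], axis=0))

    def add_agent(self, row: int, col: int, state: np.ndarray | None = None,
                  params: np.ndarray | None = None) -> int:
        if self.occ[row + 1, col + 1] >= 0:
            raise ValueError(f"site ({row}, {col}) already occupied")
        if self.n_agents == len(self.filopodia):
            self._grow()
        i = self.n_agents
        self.n_agents += 1
        self.states[i] = self.model.initial_amounts if state is None else state
        self.params[i] = (
            sample_agent_params(self.model, self.config.sampling, self.rng,
                                self.param_means, self.config.fixed_params)
            if params is None else params
        )
        self.pos[i] = (row, col)
        self.filopodia[i] = 0.0
        self.tip[i] = False
        self.occ[row + 1, col + 1] = i
        self.nbr_cnt[row:row + 3, col:col + 3] += 1
        self.nbr_cnt[row + 1, col + 1] -= 1
        return i

    def _seed_disc(self, r0: int, c0: int, radius: float) -> None:
        h, w = self.config.grid_shape
        rr = int(math.ceil(radius))
        for r in range(max(0, r0 - rr), min(h, r0 + rr + 1)):
            for c in range(max(0, c0 - rr), min(w, c0 + rr + 1)):
                if (r - r0) ** 2 + (c - c0) ** 2 <= radius ** 2:
                    if self.occ[r + 1, c + 1] < 0:
                        self.add_agent(r, c)

    def agent(self, i: int) -> ag.ECAgent:
        """Materialize one agent as an :class:`~angiosprout.agents.ECAgent` view."""
        r, c = self.pos[i]
        return ag.ECAgent(
            id=i, row=int(r), col=int(c), state=self.states[i],
            params=self.params[i], filopodia=float(self.filopodia[i]),
            phenotype="tip" if self.tip[i] else "non-tip",
        )

    def occupancy_mask(self) -> np.ndarray:
        return self.occ[1:-1, 1:-1] >= 0

    def tip_count(self) -> int:
        return int(self.tip[: self.n_agents].sum())

    def agents_frame(self) -> pd.DataFrame:
        n = self.n_agents
        df = pd.DataFrame({
            "id": np.arange(n),
            "row": self.pos[:n, 0],
            "col": self.pos[:n, 1],
            "phenotype": np.where(self.tip[:n], "tip", "non-tip"),
            "filopodia": self.filopodia[:n],
        })
        for name in ("vegfr1_mRNA", "vegfr2_mRNA", "dll4_mRNA", "dll4", "nicd",
                     "vegfr2_active"):
            df[name] = self.states[:n, self.model.species_index(name)]
        return df

    # -- per-agent inner update -------------------------------------------
    def _neighbor_dll4(self, r: int, c: int):
        """Trans-ligand total and the contributing (index, share) pairs."""
        occ, cnt, dll4 = self.occ, self.nbr_cnt, self.states[:, self._i_dll4]
        total = 0.0
        contrib = []
        for dr, dc in ag.DIRECTIONS:
            j = occ[r + 1 + dr, c + 1 + dc]
            if j >= 0:
                share = dll4[j] / max(cnt[r + 1 + dr, c + 1 + dc], 1)
                if share > 0.0:
                    total += share
                    contrib.append((j, share))
        return total, contrib

    def _update_agent(self, i: int, dt: float, p_move: float) -> None:
        r, c = int(self.pos[i, 0]), int(self.pos[i, 1])
        radius = ag.sensing_radius(self.filopodia[i])
        win = ag.sensing_window(r, c, radius, self.config.grid_shape)
        available = float(self.vegf.grid[win].sum())
        dll4_nb, contrib = self._neighbor_dll4(r, c)

        model = self.model
        vec = self._vec
        n_sp = model.n_species
        vec[:n_sp] = self.states[i]
        vec[model._i_vegf] = available
        vec[model._i_dll4] = dll4_nb
        vec[model._i_svout] = 0.0
        try:
            model._advance(vec, self.params[i], dt)
        except NumericalError as exc:
            raise NumericalError(
                f"agent {i} at ({r}, {c}), t={self.time:.2f} h: {exc}"
            ) from exc
        self.states[i] = vec[:n_sp]
        vegf_net = vec[model._i_vegf] - available
        dll4_consumed = dll4_nb - vec[model._i_dll4]
        sv_exported = vec[model._i_svout]

        ag.apply_vegf_exchange(self.vegf.grid, r, c, radius, vegf_net)
        if dll4_consumed > 0.0 and dll4_nb > 0.0:
            dll4 = self.states[:, self._i_dll4]
            frac = dll4_consumed / dll4_nb
            for j, share in contrib:
                dll4[j] = max(dll4[j] - frac * share, 0.0)
        if sv_exported > 0.0:
            ag.deposit(self.sv.grid, r, c, self.config.behavior.deposit_radius,
                       sv_exported)

        b = self.config.behavior
        self.filopodia[i] = ag.filopodia_step(
            self.filopodia[i], self.states[i, self._i_v2a], b, dt
        )
        s = self.states[i]
        self.tip[i] = ag.tip_state(
            s[self._i_v2m], s[self._i_v1m], s[self._i_d4m], self.filopodia[i], b
        )
        if self.tip[i] and (p_move >= 1.0 or self.rng.random() < p_move):
            self._attempt_move(i, r, c)

    def _attempt_move(self, i: int, r: int, c: int) -> None:
        b = self.config.behavior
        shape = self.config.grid_shape
        radius = ag.sensing_radius(self.filopodia[i])
        direction = ag.gradient_direction(r, c, radius, self.vegf.grid, self.rng)
        dr, dc = ag.choose_move_direction(direction, b.p_dev, self.rng)
        tr, tc = r + dr, c + dc
        if not (0 <= tr < shape[0] and 0 <= tc < shape[1]):
            return
        if self.occ[tr + 1, tc + 1] >= 0:
            return
        candidates = [
            j for drr, dcc in ag.DIRECTIONS
            if (j := self.occ[r + 1 + drr, c + 1 + dcc]) >= 0 and not self.tip[j]
        ]
        if not candidates:
            return
        parent = candidates[int(self.rng.integers(len(candidates)))]
        # move the tip; the vacated site is refilled below, so only the
        # target site's neighbors gain a contact
        self.occ[tr + 1, tc + 1] = i
        self.pos[i] = (tr, tc)
        self.nbr_cnt[tr:tr + 3, tc:tc + 3] += 1
        self.nbr_cnt[tr + 1, tc + 1] -= 1
        # stalk proliferation: copy of a non-tip neighbor, fresh params
        if self.n_agents == len(self.filopodia):
            self._grow()
        k = self.n_agents
        self.n_agents += 1
        self.states[k] = self.states[parent]
        self.params[k] = sample_agent_params(
            self.model, self.config.sampling, self.rng, self.param_means,
            self.config.fixed_params,
        )
        self.pos[k] = (r, c)
        self.filopodia[k] = 0.0
        self.tip[k] = False
        self.occ[r + 1, c + 1] = k


def step(world: World, dt: float | None = None) -> World:
    """Advance the world one outer step: fields first, then agents in a
    fresh random permutation (each reading the already-updated world)."""
    dt = world.config.dt if dt is None else dt
    field_step(world.vegf, world.sv, world.svb, world.config.medium,
               *world._sv_kinetics, dt)
    n = world.n_agents
    if n:
        p_move = 1.0 - math.exp(-world.config.behavior.move_rate * dt)
        for i in world.rng.permutation(n):
            world._update_agent(int(i), dt, p_move)
    world.time += dt
    return world


def run(config: SimConfig, keep_agent_table: bool = False) -> SimRecord:
    """Run a full scenario and collect snapshots and metrics inputs."""
    world = World(config)
    record = SimRecord(
        grid_shape=config.grid_shape, dx_um=config.dx_um, seed=config.seed,
        scenario=config.scenario,
    )
    n_steps = int(round(config.total_time / config.dt))
    out_steps = {}
    for t in config.output_times:
        out_steps.setdefault(int(round(t / config.dt)), t)
    if n_steps not in out_steps:
        out_steps[n_steps] = config.total_time

    def snapshot(t: float) -> None:
        record.snapshot_times.append(t)
        record.occupancy.append(world.occupancy_mask().copy())
        record.tip_counts.append(world.tip_count())

    snapshot(0.0)
    record.step_times.append(0.0)
    record.step_tip_counts.append(world.tip_count())
    record.step_agent_counts.append(world.n_agents)
    for k in range(1, n_steps + 1):
        step(world)
        record.step_times.append(world.time)
        record.step_tip_counts.append(world.tip_count())
        record.step_agent_counts.append(world.n_agents)
        if k in out_steps:
            snapshot(out_steps[k])
    if keep_agent_table:
        record.agent_table = world.agents_frame()
    return record
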