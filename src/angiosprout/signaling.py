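"""Intracellular signaling of one endothelial cell.

Dll4-Notch1 lateral inhibition (with cis-inhibition and notch1
auto-activation), NICD-controlled transcription, VEGFR1/VEGFR2 synthesis and
VEGF binding.  Transcription follows Hill laws; every other reaction is mass
action.  The network is compiled from a :class:`~angiosprout.modelio.ModelDescription`
into index arrays so one forward-Euler step is a handful of vector
operations; the integrator sub-steps automatically when a step would change
a variable by more than 25% and clips reaction extents so no amount is
driven below zero.

Amounts are particle numbers per cell (dimensionless counts); time is hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modelio import ModelDescription, ModelFormatError

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "TranscriptionParams",
    "SignalingState",
    "SignalingModel",
    "ExchangeFluxes",
    "RingSystem",
    "hill_transcription",
    "hill_repression",
    "NumericalError",
]

#: variables below this amount are exempt from the 25% sub-step criterion
SUBSTEP_FLOOR = 1.0
#: relative change per sub-step above which the step is halved
SUBSTEP_REL = 0.25
#: maximum number of halvings of the outer step
MAX_HALVINGS = 14


class NumericalError(RuntimeError):
    pass


@dataclass(frozen=True)
class TranscriptionParams:
    """Hill-law parameters for one transcriptional regulation.

    ``v_max``: maximal transcription rate (particles/h); ``a``: fold change
    upon full (de)activation; ``m0``: modifier amount at half effect;
    ``h``: Hill exponent; ``mode``: 'activating' or 'repressing'.
    """

    v_max: float
    a: float
    m0: float
    h: float = 2.0
    mode: str = "activating"

    def __post_init__(self) -> None:
        if self.v_max < 0:
            raise ValueError("v_max must be >= 0")
        if self.a < 1:
            raise ValueError("fold change a must be >= 1")
        if self.m0 <= 0:
            raise ValueError("half-activation amount m0 must be > 0")
        if self.h <= 0:
            raise ValueError("Hill exponent h must be > 0")
        if self.mode not in ("activating", "repressing"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _hill_factor(mod: float, a: float, m0: float, h: float, activating: bool) -> float:
    """Fractional Hill activity in [1/a, 1]."""
    xh = mod ** h
    m0h = m0 ** h
    occ = xh / (xh + m0h)
    if not activating:
        occ = 1.0 - occ
    return 1.0 / a + (1.0 - 1.0 / a) * occ


def hill_transcription(mod: float, p: TranscriptionParams) -> float:
    """Transcription rate under an activating modifier.

    Bounded in [v_max/a, v_max]: basal rate v_max/a without modifier, full
    rate v_max at saturation, half effect at mod = m0.
    """
    if mod < 0:
        raise ValueError("modifier amount must be >= 0")
    return p.v_max * _hill_factor(mod, p.a, p.m0, p.h, activating=True)


def hill_repression(mod: float, p: TranscriptionParams) -> float:
    """Transcription rate under a repressing modifier.

    Mirror of :func:`hill_transcription`: v_max without repressor, floor
    v_max/a at saturation, half effect at mod = m0.
    """
    if mod < 0:
        raise ValueError("modifier amount must be >= 0")
    return p.v_max * _hill_factor(mod, p.a, p.m0, p.h, activating=False)


@dataclass(frozen=True)
class ExchangeFluxes:
    """Net exchange between one cell and its environment over one step.

    ``vegf_net``: change of the extracellular VEGF pool the cell saw
    (negative = net uptake by receptors); ``dll4_consumed``: neighbor Dll4
    removed by trans binding; ``svegfr1_exported``: sVEGFR1 deposited
    extracellularly.
    """

    vegf_net: float
    dll4_consumed: float
    svegfr1_exported: float


class SignalingState:
    """Named view over one cell's amount vector."""

    __slots__ = ("amounts", "_index")

    def __init__(self, amounts: np.ndarray, names: list[str]):
        object.__setattr__(self, "amounts", np.asarray(amounts, dtype=float))
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def names(self) -> list[str]:
        return list(self._index)

    def __len__(self) -> int:
        return len(self._index)

    def __getitem__(self, name: str) -> float:
        return float(self.amounts[self._index[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.amounts[self._index[name]] = value

    def __getattr__(self, name: str):
        try:
            return float(self.amounts[self._index[name]])
        except KeyError:
            raise AttributeError(name) from None

    def __repr__(self) -> str:
        body = ", ".join(f"{n}={self.amounts[i]:.3g}" for n, i in self._index.items())
        return f"SignalingState({body})"


@dataclass(frozen=True)
class _CompiledHill:
    rxn: int
    vmax_p: int
    h_p: int
    terms: tuple[tuple[np.ndarray, int, int], ...]  # (modifier indices, a, m0)
    activating: bool


@njit(cache=True)
def _rates_kernel(vec, params, k_idx, f1, f2,
                  hr_rxn, hr_vmax, hr_h, ht_ptr, ht_mod1, ht_mod2,
                  ht_a, ht_m0, ht_act, r):
    n_vec = vec.shape[0]
    for j in range(k_idx.shape[0]):
        x1 = vec[f1[j]] if f1[j] < n_vec else 1.0
        x2 = vec[f2[j]] if f2[j] < n_vec else 1.0
        r[j] = params[k_idx[j]] * x1 * x2
    for hi in range(hr_rxn.shape[0]):
        v = params[hr_vmax[hi]]
        h = params[hr_h[hi]]
        for ti in range(ht_ptr[hi], ht_ptr[hi + 1]):
            mod = vec[ht_mod1[ti]]
            if ht_mod2[ti] >= 0:
                mod += vec[ht_mod2[ti]]
            a = params[ht_a[ti]]
            m0 = params[ht_m0[ti]]
            xh = mod ** h
            den = xh + m0 ** h
            occ = xh / den if den > 0.0 else 0.0
            if not ht_act[ti]:
                occ = 1.0 - occ
            v *= 1.0 / a + (1.0 - 1.0 / a) * occ
        r[hr_rxn[hi]] = v
    return r


@njit(cache=True)
def _advance_kernel(vec, params, dt, k_idx, f1, f2,
                    hr_rxn, hr_vmax, hr_h, ht_ptr, ht_mod1, ht_mod2,
                    ht_a, ht_m0, ht_act,
                    st_i, st_j, st_v, cn_i, cn_j, cn_v,
                    floor, rel, max_halvings):
    """In-place sub-stepped forward Euler; returns 0 or 1 + index of the
    first non-finite variable."""
    n_vec = vec.shape[0]
    n_rxn = k_idx.shape[0]
    r = np.empty(n_rxn)
    dv = np.empty(n_vec)
    out = np.empty(n_vec)
    ratio = np.empty(n_vec)
    scale = np.empty(n_rxn)
    t = 0.0
    dt_try = dt
    dt_min = dt / 2.0 ** max_halvings
    while t < dt * (1.0 - 1e-12):
        if dt_try > dt - t:
            dt_try = dt - t
        _rates_kernel(vec, params, k_idx, f1, f2, hr_rxn, hr_vmax, hr_h,
                      ht_ptr, ht_mod1, ht_mod2, ht_a, ht_m0, ht_act, r)
        for i in range(n_vec):
            dv[i] = 0.0
        for m in range(st_i.shape[0]):
            dv[st_i[m]] += st_v[m] * r[st_j[m]] * dt_try
        if dt_try > dt_min:
            violated = False
            for i in range(n_vec):
                if vec[i] > floor and abs(dv[i]) > rel * vec[i]:
                    violated = True
                    break
            if violated:
                dt_try *= 0.5
                continue
        negative = False
        for i in range(n_vec):
            if vec[i] + dv[i] < 0.0:
                negative = True
                break
        if negative:
            # scale reaction extents so consumption never exceeds availability
            for i in range(n_vec):
                out[i] = 0.0
            for m in range(cn_i.shape[0]):
                out[cn_i[m]] += cn_v[m] * r[cn_j[m]] * dt_try
            for i in range(n_vec):
                ratio[i] = vec[i] / out[i] if out[i] > 0.0 else 1e300
            for j in range(n_rxn):
                scale[j] = 1.0
            for m in range(cn_i.shape[0]):
                if ratio[cn_i[m]] < scale[cn_j[m]]:
                    scale[cn_j[m]] = ratio[cn_i[m]]
            for j in range(n_rxn):
                r[j] *= scale[j]
            for i in range(n_vec):
                dv[i] = 0.0
            for m in range(st_i.shape[0]):
                dv[st_i[m]] += st_v[m] * r[st_j[m]] * dt_try
        for i in range(n_vec):
            x = vec[i] + dv[i]
            if x < 0.0:
                x = 0.0
            if not np.isfinite(x):
                return 1 + i
            vec[i] = x
        t += dt_try
        dt_try *= 2.0
    return 0


class SignalingModel:
    """A model description compiled for per-cell integration.

    The integrated vector holds the dynamic species followed by three
    environment pools: the extracellular VEGF available to the cell, the
    neighbor Dll4 pool, and an accumulator for exported sVEGFR1.  Reactions
    whose participants are all extracellular (the sVEGFR1·VEGF field
    kinetics) are excluded here and handled by the field layer.
    """

    VEGF_SLOT = "vegf_ext"
    DLL4_SLOT = "dll4_nb"
    SV_OUT_SLOT = "svegfr1_ext"

    def __init__(self, description: ModelDescription):
        self.description = description
        dyn = description.dynamic_species
        self.species_names = [s.id for s in dyn]
        self.n_species = len(dyn)
        self.initial_amounts = np.array([s.initial for s in dyn], dtype=float)
        self.param_names = list(description.parameters)
        self.param_index = {n: i for i, n in enumerate(self.param_names)}
        self.default_params = np.array(
            [description.parameters[n] for n in self.param_names], dtype=float
        )

        n = self.n_species
        self._i_vegf, self._i_dll4, self._i_svout = n, n + 1, n + 2
        self.n_vec = n + 3
        slot = {s.id: i for i, s in enumerate(dyn)}
        slot[self.VEGF_SLOT] = self._i_vegf
        slot[self.DLL4_SLOT] = self._i_dll4
        slot[self.SV_OUT_SLOT] = self._i_svout
        const = self.n_vec  # index of the constant-1 entry in the rate vector

        reactions = []
        for r in description.reactions:
            if r.kind == "mass_action":
                touched = set(r.rate_species) | set(r.consume) | set(r.produce)
            else:
                touched = {r.product}
            if not any(s in slot and slot[s] < n for s in touched):
                continue  # purely extracellular reaction
            reactions.append(r)
        self.reactions = reactions
        self.reaction_ids = [r.id for r in reactions]
        n_rxn = len(reactions)

        k_idx = np.zeros(n_rxn, dtype=np.intp)
        f1 = np.full(n_rxn, const, dtype=np.intp)
        f2 = np.full(n_rxn, const, dtype=np.intp)
        S = np.zeros((self.n_vec, n_rxn))
        hills: list[_CompiledHill] = []
        for j, r in enumerate(reactions):
            if r.kind == "mass_action":
                k_idx[j] = self.param_index[r.k]
                facts = [slot[s] for s in r.rate_species if s in slot]
                if len(facts) > 2:
                    raise ModelFormatError(f"reaction {r.id!r}: more than two rate species")
                if facts:
                    f1[j] = facts[0]
                if len(facts) > 1:
                    f2[j] = facts[1]
                for s in r.consume:
                    if s in slot:
                        S[slot[s], j] -= 1.0
                for s in r.produce:
                    if s in slot:
                        S[slot[s], j] += 1.0
            else:
                terms = tuple(
                    (
                        np.array([slot[m] for m in t.modifier], dtype=np.intp),
                        self.param_index[t.a],
                        self.param_index[t.m0],
                    )
                    for t in r.terms
                )
                hills.append(_CompiledHill(
                    rxn=j,
                    vmax_p=self.param_index[r.vmax],
                    h_p=self.param_index[r.h],
                    terms=terms,
                    activating=r.kind == "hill_activation",
                ))
                S[slot[r.product], j] += 1.0
        self._k_idx, self._f1, self._f2 = k_idx, f1, f2
        self.stoichiometry = S
        self._hills = hills
        self._Sneg = np.maximum(-S, 0.0)

        # flat arrays for the compiled kernels
        self._hr_rxn = np.array([hc.rxn for hc in hills], dtype=np.intp)
        self._hr_vmax = np.array([hc.vmax_p for hc in hills], dtype=np.intp)
        self._hr_h = np.array([hc.h_p for hc in hills], dtype=np.intp)
        ptr, m1, m2, ta, tm0, tact = [0], [], [], [], [], []
        for hc in hills:
            for mod_idx, a_p, m0_p in hc.terms:
                if len(mod_idx) > 2:
                    raise ModelFormatError("at most two summed modifiers per Hill term")
                m1.append(mod_idx[0])
                m2.append(mod_idx[1] if len(mod_idx) > 1 else -1)
                ta.append(a_p)
                tm0.append(m0_p)
                tact.append(hc.activating)
            ptr.append(len(m1))
        self._ht_ptr = np.array(ptr, dtype=np.intp)
        self._ht_mod1 = np.array(m1, dtype=np.intp)
        self._ht_mod2 = np.array(m2, dtype=np.intp)
        self._ht_a = np.array(ta, dtype=np.intp)
        self._ht_m0 = np.array(tm0, dtype=np.intp)
        self._ht_act = np.array(tact, dtype=np.bool_)
        st = np.nonzero(S)
        self._st_i = st[0].astype(np.intp)
        self._st_j = st[1].astype(np.intp)
        self._st_v = S[st]
        cn = np.nonzero(self._Sneg)
        self._cn_i = cn[0].astype(np.intp)
        self._cn_j = cn[1].astype(np.intp)
        self._cn_v = self._Sneg[cn]

    # -- public helpers --------------------------------------------------
    def state(self, amounts: np.ndarray | None = None) -> SignalingState:
        vec = self.initial_amounts.copy() if amounts is None else np.asarray(amounts, float)
        if vec.shape != (self.n_species,):
            raise ValueError(
                f"state vector length {vec.shape} does not match the model's "
                f"{self.n_species} variables"
            )
        return SignalingState(vec, self.species_names)

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    # -- rate evaluation -------------------------------------------------
    def reaction_rates(
        self,
        s: np.ndarray | SignalingState,
        dll4_nb: float = 0.0,
        vegf_local: float = 0.0,
        params: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-reaction rates (particles/h), ordered as ``reaction_ids``."""
        vec = self._vec(s, dll4_nb, vegf_local)
        return self._rates(vec, self._params(params))

    def rhs(
        self,
        s: np.ndarray,
        dll4_nb: float = 0.0,
        vegf_local: float = 0.0,
        params: np.ndarray | None = None,
    ) -> np.ndarray:
        """Time derivative of the cell's own variables (clamp-free).

        The environment pools are held constant, which is the single-cell
        ODE limit of a large well-mixed surrounding.
        """
        vec = self._vec(s, dll4_nb, vegf_local)
        ds = self.stoichiometry @ self._rates(vec, self._params(params))
        return ds[: self.n_species]

    def _params(self, params) -> np.ndarray:
        if params is None:
            return self.default_params
        params = np.asarray(params, dtype=float)
        if params.shape != self.default_params.shape:
            raise ValueError("parameter vector length mismatch")
        return params

    def _vec(self, s, dll4_nb: float, vegf_local: float) -> np.ndarray:
        if isinstance(s, SignalingState):
            s = s.amounts
        s = np.asarray(s, dtype=float)
        if s.shape != (self.n_species,):
            raise ValueError(
                f"state vector length {s.shape[0] if s.ndim else s.shape} does not "
                f"match the model's {self.n_species} variables"
            )
        if dll4_nb < 0 or vegf_local < 0 or np.any(s < 0):
            raise ValueError("amounts must be >= 0")
        vec = np.empty(self.n_vec)
        vec[: self.n_species] = s
        vec[self._i_vegf] = vegf_local
        vec[self._i_dll4] = dll4_nb
        vec[self._i_svout] = 0.0
        return vec

    def _rates(self, vec: np.ndarray, params: np.ndarray) -> np.ndarray:
        r = np.empty(len(self.reactions))
        _rates_kernel(vec, params, self._k_idx, self._f1, self._f2,
                      self._hr_rxn, self._hr_vmax, self._hr_h, self._ht_ptr,
                      self._ht_mod1, self._ht_mod2, self._ht_a, self._ht_m0,
                      self._ht_act, r)
        return r

    # -- integration -----------------------------------------------------
    def euler_step(
        self,
        s: np.ndarray | SignalingState,
        dt: float,
        dll4_nb: float = 0.0,
        vegf_local: float = 0.0,
        params: np.ndarray | None = None,
    ):
        """Advance one cell by ``dt`` hours of forward Euler.

        Returns ``(new_amounts, ExchangeFluxes)``.  Sub-steps are inserted
        whenever a candidate step would move a variable above the floor by
        more than 25%, and reaction extents are scaled down so consumption
        never exceeds availability within a sub-step.
        """
        if dt < 0:
            raise ValueError("dt must be >= 0")
        return_state = isinstance(s, SignalingState)
        vec = self._vec(s, dll4_nb, vegf_local)
        params = self._params(params)
        if dt > 0:
            self._advance(vec, params, dt)
        out = vec[: self.n_species].copy()
        fluxes = ExchangeFluxes(
            vegf_net=float(vec[self._i_vegf] - vegf_local),
            dll4_consumed=float(dll4_nb - vec[self._i_dll4]),
            svegfr1_exported=float(vec[self._i_svout]),
        )
        if return_state:
            return SignalingState(out, self.species_names), fluxes
        return out, fluxes

    def _advance(self, vec: np.ndarray, params: np.ndarray, dt: float) -> None:
        status = _advance_kernel(
            vec, params, dt, self._k_idx, self._f1, self._f2,
            self._hr_rxn, self._hr_vmax, self._hr_h, self._ht_ptr,
            self._ht_mod1, self._ht_mod2, self._ht_a, self._ht_m0, self._ht_act,
            self._st_i, self._st_j, self._st_v,
            self._cn_i, self._cn_j, self._cn_v,
            SUBSTEP_FLOOR, SUBSTEP_REL, MAX_HALVINGS,
        )
        if status:
            names = self.species_names + ["vegf_ext", "dll4_nb", "svegfr1_ext"]
            raise NumericalError(
                f"non-finite amount for {names[status - 1]!r} during Euler step"
            )


class RingSystem:
    """A static 1-D ring of coupled signaling cells (no movement, no fields).

    Cells exchange Dll4 with their ring neighbors (each neighbor's ligand is
    split evenly among its own contacts) under a clamped extracellular VEGF
    level — the minimal system exhibiting lateral inhibition.  ``n=2``
    degenerates to the classic two-cell mutual-inhibition motif.
    """

    def __init__(
        self,
        model: SignalingModel,
        n: int = 4,
        seed: int = 0,
        vegf: float | None = None,
        perturb: float = 0.0,
        params: np.ndarray | None = None,
    ):
        if n < 2:
            raise ValueError("a ring needs at least 2 cells")
        self.model = model
        self.n = n
        self.rng = np.random.default_rng(seed)
        self.vegf = (
            float(vegf)
            if vegf is not None
            else model.description.species_def("vegf_ext").initial
        )
        self.params = model._params(params)
        self.states = np.tile(model.initial_amounts, (n, 1))
        if perturb > 0:
            self.states *= self.rng.lognormal(0.0, perturb, size=self.states.shape)
        self._i_dll4 = model.species_index("dll4")
        if n == 2:
            self.neighbors = [(1,), (0,)]
        else:
            self.neighbors = [((i - 1) % n, (i + 1) % n) for i in range(n)]

    def dll4_inputs(self) -> np.ndarray:
        """Trans-ligand seen by each cell: neighbor Dll4 split among contacts."""
        dll4 = self.states[:, self._i_dll4]
        shares = dll4 / np.array([len(self.neighbors[j]) for j in range(self.n)])
        return np.array([sum(shares[j] for j in self.neighbors[i]) for i in range(self.n)])

    def step(self, dt: float) -> None:
        inputs = self.dll4_inputs()
        consumed = np.zeros(self.n)
        new = np.empty_like(self.states)
        for i in range(self.n):
            new[i], fx = self.model.euler_step(
                self.states[i], dt, dll4_nb=inputs[i], vegf_local=self.vegf,
                params=self.params,
            )
            if fx.dll4_consumed > 0 and inputs[i] > 0:
                # charge the consumption back to the presenting neighbors
                for j in self.neighbors[i]:
                    share = (self.states[j, self._i_dll4] / len(self.neighbors[j])) / inputs[i]
                    consumed[j] += fx.dll4_consumed * share
        self.states = new
        self.states[:, self._i_dll4] = np.maximum(
            self.states[:, self._i_dll4] - consumed, 0.0
        )

    def run(self, total_time: float, dt: float = 0.1) -> np.ndarray:
        steps = int(round(total_time / dt))
        for _ in range(steps):
            self.step(dt)
        return self.states

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.model.species_index(name)].copy()
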