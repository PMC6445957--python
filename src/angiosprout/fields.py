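"""Extracellular lattice variables: VEGF-A, sVEGFR1, and their complex.

Each field is a 2-D matrix of particle counts per lattice site evolved by an
explicit 5-point diffusion stencil under Dirichlet boundary conditions,
first-order degradation, sitewise mass-action binding, and (for VEGF-A) a
relaxation influx toward the culture-medium reference value.  Diffusion
sub-steps automatically so the stencil weight D*dt/dx^2 stays at or below
the stable 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "Field",
    "MediumConfig",
    "FieldStabilityError",
    "diffuse",
    "degrade",
    "replenish_vegf",
    "svegfr1_vegf_kinetics",
    "field_step",
]

#: largest stable explicit stencil weight
MAX_LAMBDA = 0.25
#: hard cap on diffusion sub-steps per call
MAX_SUBSTEPS = 100_000


class FieldStabilityError(RuntimeError):
    pass


@dataclass
class MediumConfig:
    """Culture-medium coupling: reference VEGF level and relaxation rate."""

    vegf_reference: float = 44.0
    k_influx: float = 0.03  # 1/h

    def __post_init__(self) -> None:
        if self.vegf_reference < 0 or self.k_influx < 0:
            raise ValueError("medium parameters must be >= 0")


@dataclass
class Field:
    """One extracellular molecular species on the simulation lattice.

    ``grid`` holds particle counts per site; ``diffusion`` is in units of
    sites^2/h, ``k_deg`` in 1/h.  ``boundary_value`` is the Dirichlet value
    imposed along the outer rim during diffusion.
    """

    name: str
    grid: np.ndarray
    diffusion: float = 0.0
    k_deg: float = 0.0
    boundary_value: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("field grid must be 2-D")
        if self.diffusion < 0 or self.k_deg < 0 or self.boundary_value < 0:
            raise ValueError("field parameters must be >= 0")
        if not np.isfinite(self.grid).all() or (self.grid < 0).any():
            raise ValueError(f"field {self.name!r}: entries must be finite and >= 0")

    @classmethod
    def uniform(cls, name: str, shape: tuple[int, int], value: float = 0.0, **kw) -> "Field":
        return cls(name, np.full(shape, float(value)), **kw)

    def total(self) -> float:
        return float(self.grid.sum())


def _apply_boundary(grid: np.ndarray, value: float) -> None:
    grid[0, :] = value
    grid[-1, :] = value
    grid[:, 0] = value
    grid[:, -1] = value


if _HAVE_NUMBA:

    @njit(cache=True)
    def _diffuse_kernel(g, lam, n_sub, bv):  # pragma: no cover - numpy twin below
        h, w = g.shape
        buf = np.empty((h - 2, w - 2))
        for _ in range(n_sub):
            for j in range(w):
                g[0, j] = bv
                g[h - 1, j] = bv
            for i in range(h):
                g[i, 0] = bv
                g[i, w - 1] = bv
            for i in range(1, h - 1):
                for j in range(1, w - 1):
                    buf[i - 1, j - 1] = (
                        g[i - 1, j] + g[i + 1, j] + g[i, j - 1] + g[i, j + 1]
                        - 4.0 * g[i, j]
                    )
            for i in range(1, h - 1):
                for j in range(1, w - 1):
                    g[i, j] += lam * buf[i - 1, j - 1]
        for j in range(w):
            g[0, j] = bv
            g[h - 1, j] = bv
        for i in range(h):
            g[i, 0] = bv
            g[i, w - 1] = bv


def diffuse(f: Field, dt: float) -> Field:
    """Explicit 5-point-stencil diffusion with Dirichlet boundaries (in place)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if f.diffusion == 0.0 or dt == 0.0:
        return f
    lam_total = f.diffusion * dt  # dx is the lattice unit
    n_sub = max(1, int(np.ceil(lam_total / MAX_LAMBDA)))
    if n_sub > MAX_SUBSTEPS:
        raise FieldStabilityError(
            f"field {f.name!r}: D*dt = {lam_total:.3g} needs {n_sub} sub-steps "
            f"(> {MAX_SUBSTEPS}); stencil weight cannot be brought below {MAX_LAMBDA}"
        )
    lam = lam_total / n_sub
    g = f.grid
    if _HAVE_NUMBA:
        _diffuse_kernel(g, lam, n_sub, f.boundary_value)
        return f
    for _ in range(n_sub):
        _apply_boundary(g, f.boundary_value)
        interior = g[1:-1, 1:-1]
        lap = (
            g[:-2, 1:-1] + g[2:, 1:-1] + g[1:-1, :-2] + g[1:-1, 2:]
            - 4.0 * interior
        )
        interior += lam * lap
    _apply_boundary(g, f.boundary_value)
    return f


def degrade(f: Field, dt: float) -> Field:
    """Sitewise first-order decay x -> x*(1 - k*dt), floored at zero (in place)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if f.k_deg == 0.0 or dt == 0.0:
        return f
    np.multiply(f.grid, max(0.0, 1.0 - f.k_deg * dt), out=f.grid)
    return f


def replenish_vegf(f: Field, m: MediumConfig, dt: float) -> Field:
    """Relax the field toward the medium reference (in place).

    The influx is signed: sites above the reference lose molecules back to
    the bulk medium.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    rate = min(m.k_influx * dt, 1.0)  # never overshoot the fixed point
    f.grid += rate * (m.vegf_reference - f.grid)
    np.maximum(f.grid, 0.0, out=f.grid)
    return f


def svegfr1_vegf_kinetics(
    vegf: Field, sv: Field, svb: Field, k_on: float, k_off: float, dt: float
) -> tuple[Field, Field, Field]:
    """Sitewise mass-action binding VEGF + sVEGFR1 <-> sVEGFR1b (in place).

    Conserves (vegf + svb) and (sv + svb) per site; association is capped so
    neither reactant is driven negative within the step.
    """
    if k_on < 0 or k_off < 0 or dt < 0:
        raise ValueError("rates and dt must be >= 0")
    assoc = k_on * vegf.grid * sv.grid * dt
    cap = np.minimum(vegf.grid, sv.grid)
    np.minimum(assoc, cap, out=assoc)
    dissoc = np.minimum(k_off * dt, 1.0) * svb.grid
    delta = assoc - dissoc
    vegf.grid -= delta
    sv.grid -= delta
    svb.grid += delta
    for f in (vegf, sv, svb):
        np.maximum(f.grid, 0.0, out=f.grid)
    return vegf, sv, svb


def field_step(
    vegf: Field,
    sv: Field,
    svb: Field,
    medium: MediumConfig,
    k_on: float,
    k_off: float,
    dt: float,
) -> None:
    """One composite field update: diffuse -> react -> degrade -> replenish."""
    for f in (vegf, sv, svb):
        diffuse(f, dt)
    svegfr1_vegf_kinetics(vegf, sv, svb, k_on, k_off, dt)
    for f in (vegf, sv, svb):
        degrade(f, dt)
    replenish_vegf(vegf, medium, dt)
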