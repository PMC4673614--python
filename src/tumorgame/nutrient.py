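"""Explicit finite-difference integration of the nutrient field.

The nutrient concentration ``phi`` obeys a reaction-diffusion equation

    d(phi)/dt = D * laplacian(phi) - k * N_T * phi

on the unit-spacing lattice, where ``N_T`` is the per-grid count of living
tumor cells.  The domain boundary is held at ``phi = 1`` (Dirichlet): the
vasculature surrounding the tissue is a stable nutrient source.  The field is
advanced with the standard 5-point explicit stencil, ``n_sub`` substeps of
length ``dt = 1/n_sub`` per cell cycle, which is stable for ``D*dt <= 1/4``.
Values are clamped to ``[0, 1]`` after every substep.

An alternative sink ``-k * N_T`` (consumption independent of the local
concentration) is selectable via ``consumption_form="constant"``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .world import DimensionError, StabilityError, WorldState

__all__ = ["NutrientParams", "diffusion_substep", "update_nutrient_field"]


@dataclasses.dataclass(frozen=True)
class NutrientParams:
    """Numerics of one diffusion substep.

    ``D`` in grid^2/tau, ``k`` in 1/tau, ``dt`` in tau (usually ``1/n_sub``).
    """

    D: float
    k: float
    dt: float
    consumption_form: str = "proportional"

    def __post_init__(self) -> None:
        if self.D < 0 or self.k < 0:
            raise ValueError("D and k must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.consumption_form not in ("proportional", "constant"):
            raise ValueError("consumption_form must be 'proportional' or 'constant'")
        if self.D * self.dt > 0.25 + 1e-12:
            raise StabilityError(
                f"explicit scheme unstable: D*dt = {self.D * self.dt:g} > 1/4"
            )


def diffusion_substep(
    phi: np.ndarray, living_total: np.ndarray, params: NutrientParams
) -> np.ndarray:
    """Advance ``phi`` one substep; boundary reset to 1; result in [0, 1].

    Interior update: ``phi += dt * (D * lap(phi) - sink)`` with the 5-point
    Laplacian at unit grid spacing and the sink given by
    ``params.consumption_form``.
    """
    if phi.shape != living_total.shape:
        raise DimensionError(
            f"phi shape {phi.shape} != living_total shape {living_total.shape}"
        )
    out = phi.copy()
    core = phi[1:-1, 1:-1]
    lap = (
        phi[:-2, 1:-1] + phi[2:, 1:-1] + phi[1:-1, :-2] + phi[1:-1, 2:] - 4.0 * core
    )
    if params.consumption_form == "proportional":
        sink = params.k * living_total[1:-1, 1:-1] * core
    else:
        sink = params.k * living_total[1:-1, 1:-1]
    out[1:-1, 1:-1] = core + params.dt * (params.D * lap - sink)
    out[0, :] = out[-1, :] = out[:, 0] = out[:, -1] = 1.0
    np.clip(out, 0.0, 1.0, out=out)
    return out


def update_nutrient_field(
    state: WorldState, params: NutrientParams, n_sub: int
) -> np.ndarray:
    """Renew ``phi`` for one cell cycle: ``n_sub`` substeps with N_T frozen.

    The living-cell counts are held at their current values for all substeps
    (the cell update happens afterwards, once per cycle).  Returns the new
    field; the input state is not modified.
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    return _relax(state.phi, state.living_total(), params, n_sub)


def _relax(
    phi: np.ndarray, living_total: np.ndarray, params: NutrientParams, n_sub: int
) -> np.ndarray:
    for _ in range(n_sub):
        phi = diffusion_substep(phi, living_total, params)
    return phi
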