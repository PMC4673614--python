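"""ECM degradation by living tumor cells and the placement-eligibility rule.

Tumor cells chew through the host extracellular matrix at a fixed rate
``gamma`` per living cell per cell cycle, and a grid only becomes available
for cell placement once its ECM density reaches exactly zero.  By default a
living cell degrades its own grid *and* its 8 Moore neighbors at the same
rate, so that a colony seeded in continuous-random ECM can actually open
neighboring grids for its offspring; the strictly-local footprint (own grid
only) is retained as a switch, in which case a tumor started from a single
founder can never expand into grids whose ECM was not already zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .world import DimensionError, moore_sum

__all__ = ["EcmParams", "degrade_ecm", "placement_eligible"]


@dataclasses.dataclass(frozen=True)
class EcmParams:
    """``gamma``: ECM density removed per acting living cell per tau."""

    gamma: float
    degrade_neighbors: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def degrade_ecm(
    rho: np.ndarray, living_total: np.ndarray, params: EcmParams
) -> np.ndarray:
    """Apply one cell cycle of degradation; result clamped at exactly 0.

    Each grid loses ``gamma`` times the number of living cells acting on it:
    with ``degrade_neighbors`` the actors are all living cells in the grid's
    3x3 Moore block, otherwise only the grid's own occupants.
    """
    if rho.shape != living_total.shape:
        raise DimensionError(
            f"rho shape {rho.shape} != living_total shape {living_total.shape}"
        )
    actors = moore_sum(living_total) if params.degrade_neighbors else living_total
    out = rho - params.gamma * actors
    np.clip(out, 0.0, None, out=out)
    return out


def placement_eligible(rho: np.ndarray) -> np.ndarray:
    """Boolean map: True exactly where the ECM density is exactly zero.

    Degradation clamps to exact 0.0, so the strict-zero comparison is
    well-defined in floating point; any residual density, however small,
    blocks placement.
    """
    return rho == 0.0
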