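"""Per-cell-cycle synchronous update of the tumor lattice.

Each cell cycle applies, in order:

1. ECM degradation by living cells;
2. nutrient relaxation (``n_sub`` explicit diffusion substeps);
3. necrosis — every living cell in a grid whose renewed nutrient falls
   strictly below ``phi_c`` becomes necrotic, permanently;
4. fate computation — for every surviving cell, a proliferation probability
   and an invasion probability are computed from the local nutrient per cell
   and from the payoff of game interactions with living neighbors (same grid,
   focal cell excluded, plus the 8 Moore-neighbor grids; phenotypes frozen at
   the previous round), normalized to sum to 1, and sampled;
5. synchronous application — proliferation-fated cells divide (parent stays,
   the daughter is placed on the current grid or an ECM-free Moore neighbor),
   invasion-fated cells move to an ECM-free Moore neighbor or stay if none is
   free.  Placement prefers the grid with the fewest cells (necrotic ones
   included), then the highest nutrient, with uniform-random tie-breaking.
   All placement decisions compare the counts and nutrient values frozen at
   the start of the placement phase, so the update order carries no bias.

Base fate probabilities as functions of the nutrient share ``phi / N_T``:

    P_p = 1 - exp(-(phi / (N_T * theta_p))^2)      (division needs nutrient)
    P_i =     exp(-(phi / (N_T * theta_i))^2)      (starvation drives motility)

These saturating forms rise (fall) sigmoidally with the per-cell nutrient
concentration and are exposed as plain functions so alternative response
curves can be swapped without touching the scheduler.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .ecm import EcmParams, degrade_ecm
from .metrics import summarize_state
from .nutrient import NutrientParams, update_nutrient_field
from .world import (
    PayoffMatrix,
    SimulationConfig,
    WorldState,
    initialize_world,
    moore_sum,
)

__all__ = [
    "SelectionError",
    "FateProbabilities",
    "GameIncrements",
    "SimulationResult",
    "apply_necrosis",
    "game_increments",
    "proliferation_probability",
    "invasion_probability",
    "draw_fates",
    "choose_site",
    "place_offspring",
    "move_invader",
    "step_world",
    "run_simulation",
    "tumor_reached_edge",
]

_MOORE_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


class SelectionError(ValueError):
    """choose_site was given an empty candidate list."""


@dataclasses.dataclass(frozen=True)
class FateProbabilities:
    """Normalized per-cell fate probabilities for one cycle.

    If both raw probabilities are zero the normalization is undefined and the
    cell *holds*: no division and no movement this cycle (``normalized`` stays
    False and both fields are 0).
    """

    p_prolif: float
    p_invade: float
    normalized: bool

    @classmethod
    def from_raw(cls, raw_prolif: float, raw_invade: float) -> "FateProbabilities":
        if raw_prolif < 0 or raw_invade < 0:
            raise ValueError("raw fate probabilities must be non-negative")
        s = raw_prolif + raw_invade
        if s == 0.0:
            return cls(0.0, 0.0, normalized=False)
        return cls(raw_prolif / s, raw_invade / s, normalized=True)


@dataclasses.dataclass(frozen=True)
class GameIncrements:
    """Aggregate payoff increments from one cell's living neighborhood."""

    delta_p: float
    delta_i: float


def game_increments(
    n_prolif_nbhd: int,
    n_invasive_nbhd: int,
    payoff: PayoffMatrix,
    aggregation: str = "mean",
) -> GameIncrements:
    """Payoff increments from ``n_P`` proliferative and ``n_I`` invasive neighbors.

    The neighborhood comprises the living cells in the focal grid (excluding
    the focal cell itself) plus the 8 Moore-neighbor grids, with phenotypes
    frozen at the previous round.  ``delta_p = agg(a_pp*n_P + a_pi*n_I)`` and
    ``delta_i = agg(b_ip*n_P + b_ii*n_I)``; ``agg`` divides by the number of
    living partners for ``"mean"`` (0 for an empty neighborhood) and is the
    identity for ``"sum"``.
    """
    if n_prolif_nbhd < 0 or n_invasive_nbhd < 0:
        raise ValueError("neighborhood counts must be non-negative")
    if aggregation not in ("mean", "sum"):
        raise ValueError("aggregation must be 'mean' or 'sum'")
    total = n_prolif_nbhd + n_invasive_nbhd
    if total == 0:
        return GameIncrements(0.0, 0.0)
    dp = payoff.a_pp * n_prolif_nbhd + payoff.a_pi * n_invasive_nbhd
    di = payoff.b_ip * n_prolif_nbhd + payoff.b_ii * n_invasive_nbhd
    if aggregation == "mean":
        dp /= total
        di /= total
    return GameIncrements(dp, di)


def proliferation_probability(
    phi: float, n_t: int, theta_p: float, delta_p: float = 0.0
) -> float:
    """Probability that a living cell is fated to divide this cycle.

    ``clamp(P_base + delta_p, 0, 1)`` with
    ``P_base = 1 - exp(-(phi/(N_T*theta_p))^2)``: monotone non-decreasing in
    the local nutrient ``phi``, non-increasing in the onsite living count
    ``N_T`` (crowding dilutes the nutrient share).
    """
    if theta_p <= 0:
        raise ValueError("theta_p must be positive")
    if n_t < 1:
        raise ValueError("n_t must be >= 1 (the focal cell counts itself)")
    base = 1.0 - np.exp(-((phi / (n_t * theta_p)) ** 2))
    return float(np.clip(base + delta_p, 0.0, 1.0))


def invasion_probability(
    phi: float, n_t: int, theta_i: float, delta_i: float = 0.0
) -> float:
    """Probability that a living cell is fated to migrate this cycle.

    ``clamp(P_base + delta_i, 0, 1)`` with
    ``P_base = exp(-(phi/(N_T*theta_i))^2)``: monotone non-increasing in the
    local nutrient.
    """
    if theta_i <= 0:
        raise ValueError("theta_i must be positive")
    if n_t < 1:
        raise ValueError("n_t must be >= 1 (the focal cell counts itself)")
    base = np.exp(-((phi / (n_t * theta_i)) ** 2))
    return float(np.clip(base + delta_i, 0.0, 1.0))


def apply_necrosis(state: WorldState, phi_c: float) -> WorldState:
    """Move all living cells of every grid with ``phi < phi_c`` (strict) to necrotic.

    Returns a new state; necrotic counts never decrease and grids at exactly
    ``phi_c`` are unaffected.
    """
    dead = state.phi < phi_c
    living = state.living_total()
    out = state.copy()
    out.n_necrotic = state.n_necrotic + np.where(dead, living, 0)
    out.n_prolif = np.where(dead, 0, state.n_prolif)
    out.n_invasive = np.where(dead, 0, state.n_invasive)
    return out


def draw_fates(
    p: FateProbabilities, n_cells: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Assign each of ``n_cells`` independently: proliferate vs invade.

    Returns ``(n_prolif_fated, n_invade_fated)`` summing to ``n_cells``; if
    the probabilities were un-normalizable (both raw 0) every cell holds and
    ``(0, 0)`` is returned.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if not p.normalized:
        return (0, 0)
    k = int(rng.binomial(n_cells, p.p_prolif)) if n_cells else 0
    return (k, n_cells - k)


def choose_site(
    candidates: Sequence[tuple[tuple[int, int], int, float]],
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Lexicographic site selection among ``(site, total_count, phi)`` triples.

    Minimum total cell count (necrotic cells included) first, then maximum
    nutrient, then uniform random among remaining ties.  Counts and nutrient
    values must be the synchronous start-of-phase values.
    """
    if not candidates:
        raise SelectionError("no candidate sites")
    best_key = None
    best: list[tuple[int, int]] = []
    for site, count, phi in candidates:
        key = (count, -phi)
        if best_key is None or key < best_key:
            best_key = key
            best = [site]
        elif key == best_key:
            best.append(site)
    if len(best) == 1:
        return best[0]
    return best[int(rng.integers(len(best)))]


def _eligible_moore(
    rho: np.ndarray, site: tuple[int, int]
) -> list[tuple[int, int]]:
    L0, L1 = rho.shape
    r, c = site
    out = []
    for dr, dc in _MOORE_OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < L0 and 0 <= cc < L1 and rho[rr, cc] == 0.0:
            out.append((rr, cc))
    return out


def place_offspring(
    state: WorldState, site: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    """Place one daughter cell of a division at ``site``; return the target.

    Candidates are the current grid plus ECM-free Moore neighbors (the
    current grid is always valid, so a division never fails); the parent
    stays put and one proliferative cell is added at the chosen target.
    """
    total = state.total_cells()
    cands = [site] + _eligible_moore(state.rho_ecm, site)
    target = choose_site(
        [(s, int(total[s]), float(state.phi[s])) for s in cands], rng
    )
    state.n_prolif[target] += 1
    return target


def move_invader(
    state: WorldState, site: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    """Move one invasive cell out of ``site``; return the target (or ``site``).

    Candidates are the ECM-free Moore neighbors only; with none free the cell
    has to stay in the current grid.  Cell count is conserved.
    """
    if state.n_invasive[site] < 1:
        raise ValueError("site hosts no invasive cell to move")
    cands = _eligible_moore(state.rho_ecm, site)
    if not cands:
        return site
    total = state.total_cells()
    target = choose_site(
        [(s, int(total[s]), float(state.phi[s])) for s in cands], rng
    )
    state.n_invasive[site] -= 1
    state.n_invasive[target] += 1
    return target


def _class_fate_draws(
    n_class: np.ndarray,
    own_is_prolif: bool,
    sum_p: np.ndarray,
    sum_i: np.ndarray,
    base_p: np.ndarray,
    base_i: np.ndarray,
    payoff: PayoffMatrix,
    aggregation: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fate draws for one last-round phenotype class.

    ``sum_p`` / ``sum_i`` are the 3x3 living counts at the occupied grids;
    the focal cell is excluded from its own class.  Returns per-grid counts
    ``(fated_prolif, fated_invade, held)``.  Batched binomial sampling is
    distribution-identical to independent per-cell draws.
    """
    nb_p = sum_p - (1 if own_is_prolif else 0)
    nb_i = sum_i - (0 if own_is_prolif else 1)
    partners = nb_p + nb_i
    dp = payoff.a_pp * nb_p + payoff.a_pi * nb_i
    di = payoff.b_ip * nb_p + payoff.b_ii * nb_i
    if aggregation == "mean":
        safe = np.maximum(partners, 1)
        dp = np.where(partners > 0, dp / safe, 0.0)
        di = np.where(partners > 0, di / safe, 0.0)
    raw_p = np.clip(base_p + dp, 0.0, 1.0)
    raw_i = np.clip(base_i + di, 0.0, 1.0)
    s = raw_p + raw_i
    active = (n_class > 0) & (s > 0)
    p_div = np.where(active, raw_p / np.where(s > 0, s, 1.0), 0.0)
    fated_p = np.zeros_like(n_class)
    fated_p[active] = rng.binomial(n_class[active], p_div[active])
    fated_i = np.where(active, n_class - fated_p, 0)
    held = np.where((n_class > 0) & (s == 0), n_class, 0)
    return fated_p, fated_i, held


def step_world(
    state: WorldState, config: SimulationConfig, rng: np.random.Generator
) -> WorldState:
    """Advance the world one cell cycle (synchronous update); returns new state.

    Randomness is consumed in a fixed order: proliferative-class fate draws
    over occupied grids in row-major order, then invasive-class draws, then
    placement tie-breaks grid by grid in row-major order — so a run is fully
    reproducible from the seed.
    """
    living0 = state.living_total()
    rho = degrade_ecm(
        state.rho_ecm, living0, EcmParams(config.gamma, config.degrade_neighbors)
    )
    nparams = NutrientParams(
        config.D, config.k, 1.0 / config.n_sub, config.consumption_form
    )
    phi = update_nutrient_field(state, nparams, config.n_sub)

    # necrosis on the renewed nutrient field
    dead = phi < config.phi_c
    n_p = np.where(dead, 0, state.n_prolif)
    n_i = np.where(dead, 0, state.n_invasive)
    n_n = state.n_necrotic + np.where(dead, living0, 0)

    next_state = WorldState(
        t=state.t + 1,
        n_prolif=np.zeros_like(n_p),
        n_invasive=np.zeros_like(n_i),
        n_necrotic=n_n,
        phi=phi,
        rho_ecm=rho,
    )

    rows, cols = np.nonzero(n_p + n_i)  # row-major occupied order
    if rows.size == 0:
        return next_state

    occ = (rows, cols)
    n_t = (n_p + n_i)[occ].astype(np.float64)
    ph = phi[occ]
    base_p = 1.0 - np.exp(-((ph / (n_t * config.theta_p)) ** 2))
    base_i = np.exp(-((ph / (n_t * config.theta_i)) ** 2))
    sum_p = moore_sum(n_p)[occ]
    sum_i = moore_sum(n_i)[occ]

    fpP, fiP, holdP = _class_fate_draws(
        n_p[occ], True, sum_p, sum_i, base_p, base_i,
        config.payoff, config.payoff_aggregation, rng,
    )
    fpI, fiI, holdI = _class_fate_draws(
        n_i[occ], False, sum_p, sum_i, base_p, base_i,
        config.payoff, config.payoff_aggregation, rng,
    )

    # parents of divisions take the proliferative label and stay put;
    # holding cells keep their previous label
    next_state.n_prolif[occ] += fpP + fpI + holdP
    next_state.n_invasive[occ] += holdI

    # synchronous placement: all decisions compare the frozen start-of-phase
    # totals (necrotic included) and the renewed nutrient field
    total_frozen = n_p + n_i + n_n
    daughters = fpP + fpI
    invaders = fiP + fiI
    new_p = next_state.n_prolif
    new_i = next_state.n_invasive
    L = rho.shape[0]
    for idx in np.nonzero((daughters > 0) | (invaders > 0))[0]:
        r = int(rows[idx])
        c = int(cols[idx])
        elig = []
        for dr, dc in _MOORE_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < L and 0 <= cc < L and rho[rr, cc] == 0.0:
                elig.append((rr, cc))
        d = int(daughters[idx])
        if d:
            _scatter(new_p, [(r, c)] + elig, d, total_frozen, phi, rng)
        m = int(invaders[idx])
        if m:
            if elig:
                _scatter(new_i, elig, m, total_frozen, phi, rng)
            else:
                new_i[r, c] += m  # blocked by ECM on all sides: stay
    return next_state


def _scatter(
    target_map: np.ndarray,
    candidates: list[tuple[int, int]],
    n: int,
    total: np.ndarray,
    phi: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Distribute ``n`` same-class arrivals from one grid over the best sites.

    Equivalent to ``n`` independent choose_site calls: the lexicographically
    best candidates are found once and a multinomial splits the arrivals
    uniformly among ties (one RNG draw per grid instead of per cell).
    """
    best_key = None
    best: list[tuple[int, int]] = []
    for s in candidates:
        key = (total[s], -phi[s])
        if best_key is None or key < best_key:
            best_key = key
            best = [s]
        elif key == best_key:
            best.append(s)
    if len(best) == 1:
        target_map[best[0]] += n
    else:
        alloc = rng.multinomial(n, np.full(len(best), 1.0 / len(best)))
        for s, a in zip(best, alloc):
            target_map[s] += int(a)


def tumor_reached_edge(state: WorldState) -> bool:
    """True if any tumor cell (living or necrotic) sits on the boundary ring."""
    tot = state.total_cells()
    return bool(
        tot[0, :].any() or tot[-1, :].any() or tot[:, 0].any() or tot[:, -1].any()
    )


@dataclasses.dataclass
class SimulationResult:
    """Everything a single run produces."""

    config: SimulationConfig
    final_state: WorldState
    records: list  # of metrics.TimeSeriesRecord, one per recorded step
    snapshots: dict[int, WorldState]
    halted_early: bool
    halt_reason: str  # "edge_contact" or "t_max"


def run_simulation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Run a full simulation from a fresh world.

    Iterates step_world until the tumor touches the lattice edge or ``t_max``
    cycles have elapsed, recording a metrics row every cycle (including t=0)
    and storing full-state snapshots at ``config.snapshot_times``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize_world(config, rng)
    records = [summarize_state(state, config.n_angular_bins)]
    snap_times = set(config.snapshot_times)
    snapshots: dict[int, WorldState] = {}
    if 0 in snap_times:
        snapshots[0] = state.copy()
    halted_early = False
    halt_reason = "t_max"
    for _ in range(config.t_max):
        state = step_world(state, config, rng)
        records.append(summarize_state(state, config.n_angular_bins))
        if state.t in snap_times:
            snapshots[state.t] = state.copy()
        if tumor_reached_edge(state):
            halted_early = True
            halt_reason = "edge_contact"
            break
    return SimulationResult(
        config=config,
        final_state=state,
        records=records,
        snapshots=snapshots,
        halted_early=halted_early,
        halt_reason=halt_reason,
    )
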