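"""Domain types, configuration validation, and world initialization.

The simulated system is a two-dimensional square lattice of ``L x L`` grids
hosting three coupled fields:

* per-grid tumor-cell counts split by phenotype (proliferative, invasive,
  necrotic) — a grid can hold many cells;
* a continuous nutrient concentration ``phi`` in ``[0, 1]``, supplied by the
  vasculature surrounding the domain (fixed at 1 on the boundary ring) and
  consumed by living cells;
* a host-tissue extracellular-matrix (ECM) density ``rho_ecm`` in ``[0, 1]``
  that must be degraded to exactly zero before a tumor cell can occupy a grid.

A single proliferative founder cell is placed at the central grid of an
otherwise uniform-random ECM / nutrient landscape.  Units are lattice units:
the grid spacing is 1 and the cell cycle ``tau`` is 1; all rate constants are
expressed per grid and per cell cycle.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "DimensionError",
    "StabilityError",
    "Phenotype",
    "PayoffMatrix",
    "SimulationConfig",
    "WorldState",
    "moore_sum",
    "validate_config",
    "initialize_world",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "save_snapshot",
    "load_snapshot",
]


class ConfigurationError(ValueError):
    """A SimulationConfig violates one of the model invariants."""


class DimensionError(ValueError):
    """Grid-map arguments have inconsistent shapes."""


class StabilityError(ValueError):
    """The explicit diffusion scheme would be unstable (D*dt > 1/4)."""


class Phenotype(enum.Enum):
    """Behavioral state of a tumor cell.

    ``NECROTIC`` is absorbing: a necrotic cell never changes state, never
    moves, and does not take part in payoff interactions.  Only living cells
    (proliferative and invasive) interact.
    """

    PROLIFERATIVE = "proliferative"
    INVASIVE = "invasive"
    NECROTIC = "necrotic"


@dataclasses.dataclass(frozen=True)
class PayoffMatrix:
    """Signed per-encounter increments to phenotype probabilities.

    ``a_pp`` and ``a_pi`` modify the proliferation probability of a cell that
    meets a proliferative or invasive neighbor; ``b_ip`` and ``b_ii`` modify
    the invasion probability likewise.  Entries are stored signed.  The
    conventional construction used throughout the literature on this model
    treats proliferative-proliferative contact as *inhibition* (magnitude
    ``alpha_pp`` stored as ``a_pp = -alpha_pp``) and invasive-invasive
    contact as *enhancement* (``b_ii = +beta_ii``); cross terms default to 0.
    """

    a_pp: float = 0.0
    a_pi: float = 0.0
    b_ip: float = 0.0
    b_ii: float = 0.0

    @classmethod
    def from_magnitudes(
        cls,
        alpha_pp: float = 0.0,
        beta_ii: float = 0.0,
        alpha_pi: float = 0.0,
        beta_ip: float = 0.0,
    ) -> "PayoffMatrix":
        """Build a payoff matrix in the inhibition/enhancement convention.

        ``alpha_pp >= 0`` is the inhibition magnitude between proliferative
        cells (stored negative); ``beta_ii >= 0`` the enhancement between
        invasive cells (stored positive).  ``alpha_pi`` and ``beta_ip`` are
        taken as signed raw increments.
        """
        if alpha_pp < 0:
            raise ConfigurationError("alpha_pp is an inhibition magnitude and must be >= 0")
        if beta_ii < 0:
            raise ConfigurationError("beta_ii is an enhancement magnitude and must be >= 0")
        return cls(a_pp=-alpha_pp, a_pi=alpha_pi, b_ip=beta_ip, b_ii=beta_ii)

    @property
    def alpha_pp(self) -> float:
        """Inhibition magnitude between proliferative cells (``-a_pp``)."""
        return -self.a_pp

    @property
    def beta_ii(self) -> float:
        """Enhancement magnitude between invasive cells (``+b_ii``)."""
        return self.b_ii


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Every model constant, lattice geometry, RNG seed and numerics setting.

    Parameters
    ----------
    L
        Lattice side length in grids; must be odd so a unique central grid
        exists.
    t_max
        Run length in cell cycles ``tau``.
    D
        Nutrient diffusion coefficient, grid^2 per tau.
    k
        Nutrient consumption rate per living cell, 1/tau.
    phi_c
        Necrosis threshold on the local nutrient concentration, in (0, 1).
    theta_p, theta_i
        Shape parameters of the nutrient-per-cell response of the
        proliferation and invasion base probabilities.
    gamma
        ECM degradation per living cell per tau.
    payoff
        Phenotype-phenotype interaction increments.
    n_sub
        Diffusion substeps per cell cycle (explicit scheme: ``D/n_sub`` must
        not exceed 1/4).
    degrade_neighbors
        Whether a living cell degrades the ECM of its Moore neighborhood in
        addition to its own grid (default) or its own grid only.
    payoff_aggregation
        ``"mean"`` (average increment over living interaction partners) or
        ``"sum"``.
    consumption_form
        ``"proportional"`` (sink ``-k*N_T*phi``) or ``"constant"``
        (sink ``-k*N_T`` with clamping).
    n_angular_bins
        Angular bins used for the tumor-front profile.
    rdf_bin_width
        Radial bin width (grids) of the sector radial distribution functions.
    burn_in
        Cell cycles discarded before velocity fits.
    seed
        RNG seed for the single per-simulation random stream.
    snapshot_times
        Times (tau) at which run_simulation stores full lattice snapshots.
    """

    L: int = 401
    t_max: int = 200
    D: float = 1.0
    k: float = 0.2
    phi_c: float = 0.06
    theta_p: float = 0.018
    theta_i: float = 0.018
    gamma: float = 0.4
    payoff: PayoffMatrix = dataclasses.field(
        default_factory=lambda: PayoffMatrix.from_magnitudes(alpha_pp=0.1, beta_ii=0.1)
    )
    n_sub: int = 8
    degrade_neighbors: bool = True
    payoff_aggregation: str = "mean"
    consumption_form: str = "proportional"
    n_angular_bins: int = 360
    rdf_bin_width: float = 2.0
    burn_in: float = 30.0
    seed: int = 0
    snapshot_times: tuple[int, ...] = (50, 100, 150, 200)

    @property
    def center(self) -> tuple[int, int]:
        """0-based (row, col) of the central grid; (201, 201) 1-based for L=401."""
        return ((self.L - 1) // 2, (self.L - 1) // 2)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def validate(self) -> None:
        """Raise ConfigurationError listing all invariant violations, if any."""
        problems = validate_config(self)
        if problems:
            raise ConfigurationError("; ".join(problems))


def validate_config(config: SimulationConfig) -> list[str]:
    """Check every SimulationConfig invariant; return one message per violation.

    An empty list means the configuration is valid.  This is a reporting
    operation and never raises.
    """
    v: list[str] = []
    if not isinstance(config.L, (int, np.integer)) or config.L < 3:
        v.append("L must be an integer >= 3")
    elif config.L % 2 == 0:
        v.append("L must be odd")
    if not isinstance(config.t_max, (int, np.integer)) or config.t_max < 0:
        v.append("t_max must be an integer >= 0")
    for name in ("D", "k", "gamma"):
        val = getattr(config, name)
        if not np.isfinite(val) or val < 0:
            v.append(f"{name} must be a finite non-negative real")
    if not (0.0 < config.phi_c < 1.0):
        v.append("phi_c must lie strictly in (0, 1)")
    for name in ("theta_p", "theta_i"):
        val = getattr(config, name)
        if not np.isfinite(val) or val <= 0:
            v.append(f"{name} must be a finite positive real")
    if not isinstance(config.n_sub, (int, np.integer)) or config.n_sub < 1:
        v.append("n_sub must be an integer >= 1")
    elif np.isfinite(config.D) and config.D / config.n_sub > 0.25 + 1e-12:
        v.append(f"stability D*dt <= 1/4 violated: D/n_sub = {config.D / config.n_sub:g}")
    for entry in dataclasses.astuple(config.payoff):
        if not np.isfinite(entry):
            v.append("payoff entries must be finite reals")
            break
    if config.payoff_aggregation not in ("mean", "sum"):
        v.append("payoff_aggregation must be 'mean' or 'sum'")
    if config.consumption_form not in ("proportional", "constant"):
        v.append("consumption_form must be 'proportional' or 'constant'")
    if not isinstance(config.n_angular_bins, (int, np.integer)) or config.n_angular_bins < 4:
        v.append("n_angular_bins must be an integer >= 4")
    if not np.isfinite(config.rdf_bin_width) or config.rdf_bin_width <= 0:
        v.append("rdf_bin_width must be a finite positive real")
    if not np.isfinite(config.burn_in) or config.burn_in < 0:
        v.append("burn_in must be a finite non-negative real")
    if not isinstance(config.seed, (int, np.integer)) or config.seed < 0:
        v.append("seed must be a non-negative integer")
    if any((not isinstance(t, (int, np.integer))) or t < 0 for t in config.snapshot_times):
        v.append("snapshot_times must be non-negative integers")
    return v


@dataclasses.dataclass
class WorldState:
    """Full lattice state at one time point.

    ``n_prolif``, ``n_invasive`` and ``n_necrotic`` are integer count maps;
    ``phi`` and ``rho_ecm`` are the nutrient and ECM fields.  Any grid with
    at least one cell (living or necrotic) has ``rho_ecm == 0``.
    """

    t: int
    n_prolif: np.ndarray
    n_invasive: np.ndarray
    n_necrotic: np.ndarray
    phi: np.ndarray
    rho_ecm: np.ndarray

    def living_total(self) -> np.ndarray:
        """Per-grid count of living (proliferative + invasive) cells, N_T."""
        return self.n_prolif + self.n_invasive

    def total_cells(self) -> np.ndarray:
        """Per-grid count of all cells including necrotic ones."""
        return self.n_prolif + self.n_invasive + self.n_necrotic

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi.shape

    def copy(self) -> "WorldState":
        return WorldState(
            t=self.t,
            n_prolif=self.n_prolif.copy(),
            n_invasive=self.n_invasive.copy(),
            n_necrotic=self.n_necrotic.copy(),
            phi=self.phi.copy(),
            rho_ecm=self.rho_ecm.copy(),
        )


def moore_sum(a: np.ndarray) -> np.ndarray:
    """Sum of each grid's 3x3 Moore block (center included), zero-padded edges."""
    p = np.pad(a, 1)
    return (
        p[:-2, :-2] + p[:-2, 1:-1] + p[:-2, 2:]
        + p[1:-1, :-2] + p[1:-1, 1:-1] + p[1:-1, 2:]
        + p[2:, :-2] + p[2:, 1:-1] + p[2:, 2:]
    )


def initialize_world(config: SimulationConfig, rng: np.random.Generator | None = None) -> WorldState:
    """Create the t=0 lattice: random fields and a single central founder cell.

    ECM density and nutrient concentration are drawn i.i.d. uniform on [0, 1]
    per grid (ECM first, then nutrient, so a given seed is reproducible
    bit-for-bit).  The boundary ring of ``phi`` is set to 1 (vascular supply)
    and the central grid's ECM is cleared to 0 so the founder placement obeys
    the occupancy invariant.  One proliferative cell is placed at the center.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.L
    rho = rng.random((L, L))
    phi = rng.random((L, L))
    phi[0, :] = phi[-1, :] = phi[:, 0] = phi[:, -1] = 1.0
    n_p = np.zeros((L, L), dtype=np.int64)
    n_i = np.zeros((L, L), dtype=np.int64)
    n_n = np.zeros((L, L), dtype=np.int64)
    cr, cc = config.center
    rho[cr, cc] = 0.0
    n_p[cr, cc] = 1
    return WorldState(t=0, n_prolif=n_p, n_invasive=n_i, n_necrotic=n_n, phi=phi, rho_ecm=rho)


# ---------------------------------------------------------------------------
# Configuration file I/O (canonical dialect: YAML)
# ---------------------------------------------------------------------------

_PAYOFF_KEYS = ("alpha_pp", "alpha_pi", "beta_ip", "beta_ii")


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialize a config to plain YAML-ready types.

    The payoff block uses the inhibition/enhancement magnitude convention
    (``alpha_pp``, ``beta_ii`` non-negative magnitudes; ``alpha_pi``,
    ``beta_ip`` signed raw increments).
    """
    d = dataclasses.asdict(config)
    d["payoff"] = {
        "alpha_pp": -config.payoff.a_pp,
        "alpha_pi": config.payoff.a_pi,
        "beta_ip": config.payoff.b_ip,
        "beta_ii": config.payoff.b_ii,
    }
    d["snapshot_times"] = list(config.snapshot_times)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a mapping; unknown keys are rejected."""
    if not isinstance(d, dict):
        raise ConfigurationError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs = dict(d)
    if "payoff" in kwargs:
        p = kwargs["payoff"]
        if not isinstance(p, dict):
            raise ConfigurationError("payoff must be a mapping")
        bad = set(p) - set(_PAYOFF_KEYS)
        if bad:
            raise ConfigurationError(f"unknown payoff keys: {sorted(bad)}")
        kwargs["payoff"] = PayoffMatrix.from_magnitudes(
            alpha_pp=float(p.get("alpha_pp", 0.0)),
            beta_ii=float(p.get("beta_ii", 0.0)),
            alpha_pi=float(p.get("alpha_pi", 0.0)),
            beta_ip=float(p.get("beta_ip", 0.0)),
        )
    if "snapshot_times" in kwargs:
        kwargs["snapshot_times"] = tuple(int(t) for t in kwargs["snapshot_times"])
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    config = config_from_dict(data or {})
    config.validate()
    return config


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Lattice snapshot I/O (compressed array container; lossless round trip)
# ---------------------------------------------------------------------------

def save_snapshot(state: WorldState, path: str | Path) -> None:
    """Write the five grid maps plus t to a compressed ``.npz`` archive."""
    np.savez_compressed(
        path,
        t=np.int64(state.t),
        n_prolif=state.n_prolif,
        n_invasive=state.n_invasive,
        n_necrotic=state.n_necrotic,
        phi=state.phi,
        rho_ecm=state.rho_ecm,
    )


def load_snapshot(path: str | Path) -> WorldState:
    with np.load(path) as archive:
        return WorldState(
            t=int(archive["t"]),
            n_prolif=archive["n_prolif"].copy(),
            n_invasive=archive["n_invasive"].copy(),
            n_necrotic=archive["n_necrotic"].copy(),
            phi=archive["phi"].copy(),
            rho_ecm=archive["rho_ecm"].copy(),
        )
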