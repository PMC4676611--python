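"""Lattice state: cell agents, scalar fields, and the model parameter set.

The simulated tissue is a regular 3D lattice (default 100x100x100, 5 um
spacing, roughly one myeloma-cell radius per site).  Each site holds at most
one cell agent -- a multiple myeloma cell (MM), an osteoblast (OB) or an
osteoclast (OC) -- and seven scalar fields live on the same lattice: four
cytokines (DKK1, RANKL, OPG, TNFa) and three drugs (BHQ880, glucocorticoid,
Lidamycin), all in relative concentration units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from enum import IntEnum
from typing import Iterator, Optional

import numpy as np

Position = tuple[int, int, int]

#: fixed face-neighbour offsets, order (+i, -i, +j, -j, +k, -k)
FACE_OFFSETS: tuple[Position, ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)

CYTOKINES = ("dkk1", "rankl", "opg", "tnfa")
DRUGS = ("bhq880", "gc", "lidamycin")
#: canonical drug names as used in dosing schedules / result tables
DRUG_NAMES = {"BHQ880": "bhq880", "GC": "gc", "Lidamycin": "lidamycin"}


class ParameterError(ValueError):
    """A model parameter violates its domain constraint."""


class CellType(IntEnum):
    MM = 1  # multiple myeloma cell
    OB = 2  # osteoblast
    OC = 3  # osteoclast


class Phenotype(IntEnum):
    QUIESCENT = 0
    MIGRATING = 1
    PROLIFERATING = 2
    APOPTOTIC = 3


class CyclePhase(IntEnum):
    NONE = 0
    G0G1 = 1
    S = 2
    G2 = 3
    M = 4


#: number of simulation steps an agent spends in apoptosis before removal
APOPTOSIS_DURATION = 10


class CellAgent:
    """One MM/OB/OC agent on the lattice.

    ``age`` is in hours.  ``cycle_phase`` is NONE unless the cell is in the
    proliferative cycle; ``phase_steps`` counts steps spent in the current
    phase.  ``apoptosis_countdown`` is set to 10 on apoptosis entry and the
    agent is removed when it reaches 0.
    """

    __slots__ = ("cell_type", "position", "age", "phenotype", "cycle_phase",
                 "phase_steps", "apoptosis_countdown", "removed")

    def __init__(self, cell_type: CellType, position: Position, age: float = 0.0,
                 phenotype: Phenotype = Phenotype.QUIESCENT,
                 cycle_phase: CyclePhase = CyclePhase.NONE):
        self.cell_type = CellType(cell_type)
        self.position = position
        self.age = float(age)
        self.phenotype = phenotype
        self.cycle_phase = cycle_phase
        self.phase_steps = 0
        self.apoptosis_countdown: Optional[int] = None
        self.removed = False

    @property
    def in_cycle(self) -> bool:
        return self.cycle_phase != CyclePhase.NONE

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"CellAgent({self.cell_type.name}, {self.position}, "
                f"age={self.age:.1f}h, {self.phenotype.name})")


class Grid:
    """Occupancy map of the lattice: at most one agent per site.

    Maintains both a dict ``position -> CellAgent`` (for iteration over
    agents) and an int8 type array (for fast source-mask construction).
    """

    def __init__(self, shape: tuple[int, int, int] = (100, 100, 100),
                 spacing_um: float = 5.0):
        if any(int(s) < 1 for s in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")
        if spacing_um <= 0:
            raise ValueError("lattice spacing must be > 0")
        self.shape = tuple(int(s) for s in shape)
        self.spacing_um = float(spacing_um)
        self.types = np.zeros(self.shape, dtype=np.int8)
        self.agents: dict[Position, CellAgent] = {}

    # -- queries ---------------------------------------------------------
    def in_bounds(self, pos: Position) -> bool:
        return (0 <= pos[0] < self.shape[0] and 0 <= pos[1] < self.shape[1]
                and 0 <= pos[2] < self.shape[2])

    def is_empty(self, pos: Position) -> bool:
        return self.types[pos] == 0

    def agent_at(self, pos: Position) -> Optional[CellAgent]:
        return self.agents.get(pos)

    def counts(self) -> dict[CellType, int]:
        out = {t: 0 for t in CellType}
        for agent in self.agents.values():
            out[agent.cell_type] += 1
        return out

    def type_mask(self, cell_type: CellType) -> np.ndarray:
        return self.types == int(cell_type)

    def __len__(self) -> int:
        return len(self.agents)

    def __iter__(self) -> Iterator[CellAgent]:
        return iter(self.agents.values())

    # -- mutation --------------------------------------------------------
    def place(self, agent: CellAgent, pos: Position) -> None:
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} out of bounds for grid {self.shape}")
        if self.types[pos] != 0:
            raise ValueError(f"site {pos} already occupied")
        agent.position = pos
        self.types[pos] = int(agent.cell_type)
        self.agents[pos] = agent

    def remove(self, pos: Position) -> CellAgent:
        agent = self.agents.pop(pos)
        self.types[pos] = 0
        agent.removed = True
        return agent

    def move(self, old: Position, new: Position) -> None:
        if self.types[new] != 0:
            raise ValueError(f"cannot move onto occupied site {new}")
        agent = self.agents.pop(old)
        self.types[old] = 0
        self.types[new] = int(agent.cell_type)
        agent.position = new
        self.agents[new] = agent

    def bounding_box(self) -> Optional[tuple[Position, Position]]:
        """(min corner, max corner) of occupied sites, or None if empty."""
        if not self.agents:
            return None
        arr = np.array(list(self.agents.keys()), dtype=np.int64)
        return tuple(arr.min(axis=0)), tuple(arr.max(axis=0))


@dataclass
class FieldSet:
    """The seven scalar lattice fields (relative concentration units, >= 0)."""

    dkk1: np.ndarray
    rankl: np.ndarray
    opg: np.ndarray
    tnfa: np.ndarray
    bhq880: np.ndarray
    gc: np.ndarray
    lidamycin: np.ndarray

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], dtype=np.float64) -> "FieldSet":
        return cls(**{name: np.zeros(shape, dtype=dtype)
                      for name in CYTOKINES + DRUGS})

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        setattr(self, name, value)

    @property
    def names(self) -> tuple[str, ...]:
        return CYTOKINES + DRUGS


@dataclass
class ModelParameters:
    """Every model constant, named by its conventional symbol.

    The first block holds the published system constants (Wnt/DKK1 response,
    basal proliferation and apoptosis rates, Hill thresholds for each drug
    and cytokine).  The second block holds transport and motility constants
    that the response functions do not fix; their defaults are the shipped
    calibration (see docs/methods.md).
    """

    # Wnt / DKK1 response (osteoblast axis)
    E0: float = 0.0            # basal Wnt signal
    beta_W: float = 0.5        # maximum Wnt signal amplitude
    K_D: float = 1.0           # DKK1 threshold inhibiting Wnt
    P0_ob: float = 0.1         # basal OB proliferation probability
    beta_ob: float = 1.0       # maximum Wnt-driven OB proliferation boost
    K_W: float = 0.8           # Wnt threshold activating OBs
    # osteoclast axis
    P0_oc: float = 0.1         # basal OC proliferation probability
    K_O_RL: float = 1.0        # OPG:RANKL ratio threshold inhibiting OCs
    P_pathway_oc: float = 0.25  # maximum RANKL-pathway OC proliferation boost
    # myeloma axis
    P0_mm: float = 0.15        # basal MM proliferation probability
    beta_mm_L: float = 0.5     # amplitude bound to symbol beta_mm^L (apoptosis Hill)
    K_T_mm: float = 1.0        # TNFa threshold promoting MM proliferation
    lambda0_mm: float = 0.0    # basal MM apoptosis rate (per hour)
    beta_mm_T: float = 0.05    # amplitude bound to symbol beta_mm^T (proliferation Hill)
    K_L_mm: float = 1.0e-7     # Lidamycin threshold activating MM apoptosis
    # glucocorticoid response
    lambda0_1: float = 3.5e-2  # basal OB apoptosis rate (per hour)
    beta1_GC: float = 0.15     # GC-driven OB apoptosis amplitude (per hour)
    K_GC_1: float = 0.15       # GC threshold for OB apoptosis
    lambda0_2: float = 0.0     # basal OC apoptosis rate (per hour)
    K_GC_2: float = 1.5e-6     # GC threshold for OC apoptosis
    beta2_GC: float = 0.0      # GC-driven OC apoptosis amplitude (per hour)

    # -- transport / motility constants (shipped calibration) ------------
    lambda_C: float = 0.5      # cytokine diffusivity (fraction exchanged per step)
    Se_G: float = 0.1          # cytokine secretion rate per source site per step
    DEG: float = 0.01          # cytokine degradation fraction per step
    lambda_d: float = 0.5      # drug diffusivity
    Pe_d: float = 0.5          # vessel permeability (drug influx scale)
    U_d: float = 0.02           # drug uptake fraction per step
    D_mot: float = 0.04        # motility constant, lattice units^2 per hour
    dt_hours: float = 2.0      # simulation step length

    # -- discrete-behaviour settings -------------------------------------
    cycle_steps_G0G1: int = 51
    cycle_steps_S: int = 4
    cycle_steps_G2: int = 2
    cycle_steps_M: int = 1
    division_search_distance: int = 1
    epsilon_ratio: float = 1e-9   # guard for the OPG:RANKL ratio denominator
    beta_binding: str = "labels"  # "symbols" | "labels" (MM amplitude binding)
    drug_source: str = "uniform"   # "uniform" | "as_printed" (OC-site influx)
    boundary: str = "no_flux"      # "no_flux" | "absorbing"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nonneg = ("E0", "beta_W", "P0_ob", "beta_ob", "P0_oc", "P_pathway_oc",
                  "P0_mm", "beta_mm_L", "lambda0_mm", "beta_mm_T", "lambda0_1",
                  "beta1_GC", "lambda0_2", "beta2_GC", "Se_G", "Pe_d")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("K_D", "K_W", "K_O_RL", "K_T_mm", "K_L_mm", "K_GC_1", "K_GC_2"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"Hill threshold {name} must be > 0, "
                                     f"got {getattr(self, name)}")
        for name in ("lambda_C", "lambda_d", "DEG", "U_d"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.D_mot <= 0:
            raise ParameterError(f"D_mot must be > 0, got {self.D_mot}")
        if self.dt_hours <= 0:
            raise ParameterError(f"dt_hours must be > 0, got {self.dt_hours}")
        for name in ("cycle_steps_G0G1", "cycle_steps_S", "cycle_steps_G2",
                     "cycle_steps_M"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.beta_binding not in ("symbols", "labels"):
            raise ParameterError("beta_binding must be 'symbols' or 'labels'")
        if self.drug_source not in ("uniform", "as_printed"):
            raise ParameterError("drug_source must be 'uniform' or 'as_printed'")
        if self.boundary not in ("no_flux", "absorbing"):
            raise ParameterError("boundary must be 'no_flux' or 'absorbing'")

    def cycle_lengths(self) -> dict[CyclePhase, int]:
        return {CyclePhase.G0G1: self.cycle_steps_G0G1,
                CyclePhase.S: self.cycle_steps_S,
                CyclePhase.G2: self.cycle_steps_G2,
                CyclePhase.M: self.cycle_steps_M}

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


#: reference ("1X") dose of each drug, in the same relative units as its
#: response threshold; part of the shipped calibration.
REFERENCE_DOSES = {"BHQ880": 1.0, "GC": 0.035, "Lidamycin": 1.0e-7}


@dataclass
class DoseWindow:
    """One drug's schedule: relative dose, active on steps [start, stop)."""

    dose: float
    start: int = 20
    stop: int = 60

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if self.start > self.stop:
            raise ValueError(f"dosing start {self.start} > stop {self.stop}")

    def active(self, t: int) -> bool:
        return self.start <= t < self.stop


@dataclass
class DoseSchedule:
    """Which drugs are given, at what relative dose, over which steps."""

    windows: dict[str, DoseWindow] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.windows:
            if name not in DRUG_NAMES:
                raise ValueError(f"unknown drug {name!r}; expected one of "
                                 f"{sorted(DRUG_NAMES)}")

    @classmethod
    def single(cls, drug: str, dose: Optional[float] = None,
               start: int = 20, stop: int = 60) -> "DoseSchedule":
        return cls.combination([drug], doses={drug: dose} if dose is not None
                               else None, start=start, stop=stop)

    @classmethod
    def combination(cls, drugs: list[str], doses: Optional[dict[str, float]] = None,
                    start: int = 20, stop: int = 60) -> "DoseSchedule":
        """Equal-ratio combination: each drug at 1X of its reference dose
        unless an explicit dose is given."""
        windows = {}
        for d in drugs:
            dose = (doses or {}).get(d, REFERENCE_DOSES[d])
            windows[d] = DoseWindow(dose=dose, start=start, stop=stop)
        return cls(windows)

    def active(self, drug: str, t: int) -> bool:
        w = self.windows.get(drug)
        return w is not None and w.active(t)

    def dose(self, drug: str) -> float:
        w = self.windows.get(drug)
        return 0.0 if w is None else w.dose

    def drugs(self) -> list[str]:
        return sorted(self.windows)


# ---------------------------------------------------------------------------
# neighbourhood queries
# ---------------------------------------------------------------------------

def face_neighbors(pos: Position, grid: Grid) -> list[Position]:
    """In-bounds sites at Manhattan distance 1, in fixed axis order.

    Order is (+i, -i, +j, -j, +k, -k); out-of-bounds neighbours are dropped
    (boundary truncation), so corners of a grid have three neighbours and a
    1x1x1 grid has none.
    """
    if not grid.in_bounds(pos):
        raise ValueError(f"position {pos} out of bounds for grid {grid.shape}")
    i, j, k = pos
    out = []
    for di, dj, dk in FACE_OFFSETS:
        q = (i + di, j + dj, k + dk)
        if grid.in_bounds(q):
            out.append(q)
    return out


def count_occupied_neighbors(pos: Position, grid: Grid) -> int:
    """Number of face neighbours holding a (non-removed) agent, in [0, 6]."""
    if not grid.in_bounds(pos):
        raise ValueError(f"position {pos} out of bounds for grid {grid.shape}")
    i, j, k = pos
    t = grid.types
    ni, nj, nk = grid.shape
    n = 0
    if i + 1 < ni and t[i + 1, j, k]:
        n += 1
    if i - 1 >= 0 and t[i - 1, j, k]:
        n += 1
    if j + 1 < nj and t[i, j + 1, k]:
        n += 1
    if j - 1 >= 0 and t[i, j - 1, k]:
        n += 1
    if k + 1 < nk and t[i, j, k + 1]:
        n += 1
    if k - 1 >= 0 and t[i, j, k - 1]:
        n += 1
    return n


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def central_ball_sites(shape: tuple[int, int, int], n_sites: int) -> list[Position]:
    """Sites of the smallest lattice ball centred in the grid that holds at
    least ``n_sites`` sites, sorted by squared distance from the centre
    (ties broken lexicographically for determinism)."""
    cx, cy, cz = (s // 2 for s in shape)
    radius = 0
    while True:
        r2 = radius * radius
        sites = []
        for i in range(max(0, cx - radius), min(shape[0], cx + radius + 1)):
            for j in range(max(0, cy - radius), min(shape[1], cy + radius + 1)):
                for k in range(max(0, cz - radius), min(shape[2], cz + radius + 1)):
                    d2 = (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2
                    if d2 <= r2:
                        sites.append((d2, (i, j, k)))
        if len(sites) >= n_sites:
            sites.sort()
            return [p for _, p in sites]
        if radius > max(shape):
            raise ValueError(
                f"initial counts ({n_sites} agents) exceed the capacity of a "
                f"central sphere in grid {shape}")
        radius += 1


def initialize_state(grid_shape: tuple[int, int, int],
                     initial_counts: dict[CellType, int],
                     rng: np.random.Generator,
                     spacing_um: float = 5.0,
                     field_dtype=np.float64) -> tuple[Grid, FieldSet]:
    """Seed the lattice: the requested number of each cell type mixed
    uniformly at random inside the smallest central sphere that holds them,
    ages uniform on [0, 24] hours, all fields zero."""
    counts = {CellType(t): int(n) for t, n in initial_counts.items()}
    for t, n in counts.items():
        if n < 0:
            raise ValueError(f"initial count for {t.name} must be >= 0")
    total = sum(counts.values())
    grid = Grid(grid_shape, spacing_um=spacing_um)
    fields = FieldSet.zeros(grid.shape, dtype=field_dtype)
    if total == 0:
        return grid, fields
    ball = central_ball_sites(grid.shape, total)
    chosen_idx = rng.choice(len(ball), size=total, replace=False)
    types: list[CellType] = []
    for t in (CellType.MM, CellType.OB, CellType.OC):
        types.extend([t] * counts.get(t, 0))
    rng.shuffle(types)  # type: ignore[arg-type]
    ages = rng.uniform(0.0, 24.0, size=total)
    for idx, cell_type, age in zip(chosen_idx, types, ages):
        grid.place(CellAgent(cell_type, ball[int(idx)], age=float(age)),
                   ball[int(idx)])
    return grid, fields
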