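"""Deterministic miniature fixtures: tiny grids, field presets and analytic
dose-response curves.

These generators let every module be exercised in milliseconds without
running a full simulation: exhaustive oracles (site enumeration, roulette
frequency counts, closed-form curve inversion) stay tractable on grids of
side 5-11.  Fixtures are pure functions of their spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .evaluation import DoseResponseCurve, geometric_dose_grid
from .state import CellAgent, CellType, FieldSet, Grid, Position

__all__ = ["FixtureSpec", "make_grid_fixture", "make_curve_fixture"]


@dataclass
class FixtureSpec:
    """Explicit description of a tiny lattice state.

    ``agents`` lists (cell type, position) pairs; ``field_presets`` maps a
    field name to a preset: ("uniform", value), ("point", position, value)
    or ("ramp", axis, slope) for a linear gradient along one axis.
    """

    grid_shape: tuple[int, int, int] = (5, 5, 5)
    agents: list[tuple[CellType, Position]] = field(default_factory=list)
    field_presets: dict[str, tuple] = field(default_factory=dict)


def _preset_array(shape: tuple[int, int, int], preset: tuple,
                  dtype=np.float64) -> np.ndarray:
    kind = preset[0]
    arr = np.zeros(shape, dtype=dtype)
    if kind == "uniform":
        arr[...] = preset[1]
    elif kind == "point":
        _, pos, value = preset
        arr[tuple(pos)] = value
    elif kind == "ramp":
        _, axis, slope = preset
        ramp = slope * np.arange(shape[axis], dtype=dtype)
        sl = [None, None, None]
        sl[axis] = slice(None)
        arr += ramp[tuple(sl)]
    else:
        raise ValueError(f"unknown field preset kind {kind!r}")
    if np.any(arr < 0):
        raise ValueError("field presets must be non-negative")
    return arr


def make_grid_fixture(spec: FixtureSpec) -> tuple[Grid, FieldSet]:
    """Materialise exactly the agents and fields of ``spec``.

    Raises on duplicate or out-of-bounds agent positions.
    """
    grid = Grid(spec.grid_shape)
    for cell_type, pos in spec.agents:
        pos = tuple(int(c) for c in pos)
        if not grid.in_bounds(pos):
            raise ValueError(f"fixture agent position {pos} out of bounds "
                             f"for grid {spec.grid_shape}")
        if not grid.is_empty(pos):
            raise ValueError(f"duplicate fixture agent position {pos}")
        grid.place(CellAgent(CellType(cell_type), pos), pos)
    fields = FieldSet.zeros(grid.shape)
    for name, preset in spec.field_presets.items():
        if name not in fields.names:
            raise ValueError(f"unknown field {name!r}")
        fields[name] = _preset_array(grid.shape, preset)
    return grid, fields


def make_curve_fixture(kind: str, *, reference_dose: float = 1.0,
                       n_levels: int = 20,
                       a: float = 0.0, b: float = 1.0,
                       top: float = 1000.0, K: Optional[float] = None,
                       doses: Optional[Sequence[float]] = None
                       ) -> DoseResponseCurve:
    """Analytic dose-response curve sampled on a geometric dose grid.

    kinds:
      * ``linear``       effect = a + b * ln(dose)  (closed-form invertible)
      * ``hill``         effect = top * dose^2 / (K^2 + dose^2), K defaults
                         to the reference dose (half-max at dose K)
      * ``nonmonotone``  V-shaped in log-dose: falls to a minimum at the
                         reference dose then rebounds, mimicking the relapse
                         seen at extreme doses
    """
    if doses is None:
        d = geometric_dose_grid(reference_dose, n_levels=n_levels)
    else:
        d = np.asarray(sorted(float(x) for x in doses))
    if kind == "linear":
        e = a + b * np.log(d)
    elif kind == "hill":
        Kv = reference_dose if K is None else K
        e = top * d ** 2 / (Kv ** 2 + d ** 2)
    elif kind == "nonmonotone":
        e = a + b * np.abs(np.log(d) - np.log(reference_dose))
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return DoseResponseCurve(drug=f"synthetic-{kind}", doses=d, effects=e,
                             reference_dose=reference_dose)
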