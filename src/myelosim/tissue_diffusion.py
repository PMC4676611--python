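"""Tissue scale: explicit lattice diffusion of cytokines and drugs.

Both species classes follow the same discrete update: a fraction ``lam`` of
each site's content is exchanged equally with its six face neighbours, a
source term is added at sites flagged by a characteristic mask, and the
result is scaled by one minus a loss fraction (degradation for cytokines,
cellular uptake for drugs).  For an interior site P:

    C'(P) = [ C(P)(1 - lam) + (lam/6) * sum_{6 neighbours} C + chi(P)*S ] * (1 - loss)

Under the default no-flux boundary a boundary site keeps the exchange share
of its missing neighbours, which conserves total mass exactly; the
``absorbing`` boundary instead loses that share across the wall.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .state import CellType, DoseSchedule, Grid, ModelParameters

__all__ = ["DiffusionParams", "diffuse", "cytokine_step", "drug_step",
           "build_source_masks", "cytokine_params", "drug_params"]


@dataclass
class DiffusionParams:
    """One species' transport constants for a single step.

    ``lam`` is the exchanged fraction per step, ``secretion`` the amount
    added per source site per step (cytokines: Se_G; drugs: Pe_d scaled by
    the relative dose), and ``loss`` the post-update removal fraction
    (cytokines: DEG; drugs: U_d).
    """

    lam: float
    secretion: float
    loss: float
    boundary: str = "no_flux"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"diffusivity must lie in [0, 1], got {self.lam}")
        if not (0.0 <= self.loss <= 1.0):
            raise ValueError(f"loss fraction must lie in [0, 1], got {self.loss}")
        if self.secretion < 0:
            raise ValueError(f"secretion must be >= 0, got {self.secretion}")
        if self.boundary not in ("no_flux", "absorbing"):
            raise ValueError("boundary must be 'no_flux' or 'absorbing'")


def cytokine_params(params: ModelParameters) -> DiffusionParams:
    return DiffusionParams(params.lambda_C, params.Se_G, params.DEG,
                           params.boundary)


def drug_params(params: ModelParameters, dose: float) -> DiffusionParams:
    return DiffusionParams(params.lambda_d, params.Pe_d * dose, params.U_d,
                           params.boundary)


def _neighbor_count(shape: tuple[int, ...], dtype) -> np.ndarray:
    """Number of in-bounds face neighbours per site (6 interior, fewer at
    faces/edges/corners)."""
    k = np.full(shape, 6, dtype=dtype)
    for ax in range(3):
        if shape[ax] == 1:
            k -= 2
            continue
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = 0
        sl_hi[ax] = shape[ax] - 1
        k[tuple(sl_lo)] -= 1
        k[tuple(sl_hi)] -= 1
    return k


def _neighbor_sum(field: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Sum of in-bounds face-neighbour values (missing neighbours contribute
    nothing), accumulated into ``out``."""
    out.fill(0.0)
    out[1:, :, :] += field[:-1, :, :]
    out[:-1, :, :] += field[1:, :, :]
    out[:, 1:, :] += field[:, :-1, :]
    out[:, :-1, :] += field[:, 1:, :]
    out[:, :, 1:] += field[:, :, :-1]
    out[:, :, :-1] += field[:, :, 1:]
    return out


def diffuse(field: np.ndarray, lam: float, boundary: str = "no_flux") -> np.ndarray:
    """One synchronous exchange step without sources or loss."""
    if field.ndim != 3:
        raise ValueError("field must be a 3D lattice")
    acc = _neighbor_sum(field, np.empty_like(field))
    w = lam / 6.0
    if boundary == "no_flux":
        k = _neighbor_count(field.shape, field.dtype)
        # each site trades only with existing neighbours; the missing share
        # stays put, so total mass is conserved exactly
        acc -= k * field
        acc *= w
        acc += field
        return acc
    # absorbing: the full lam fraction leaves every site, the share headed
    # out of bounds is lost
    acc *= w
    acc += field * (1.0 - lam)
    return acc


def _species_step(field: np.ndarray, source_mask, p: DiffusionParams) -> np.ndarray:
    new = diffuse(field, p.lam, p.boundary)
    if p.secretion != 0.0 and source_mask is not None:
        new += np.asarray(source_mask, dtype=field.dtype) * field.dtype.type(p.secretion)
    if p.loss != 0.0:
        new *= (1.0 - p.loss)
    # floating-point rounding of the exchange term can leave values a few
    # ulp below zero; concentrations are non-negative by definition
    np.maximum(new, 0.0, out=new)
    return new


def cytokine_step(field: np.ndarray, source_mask, params: DiffusionParams) -> np.ndarray:
    """One secretion-diffusion-degradation update of a cytokine field."""
    return _species_step(field, source_mask, params)


def drug_step(field: np.ndarray, source_mask, params: DiffusionParams) -> np.ndarray:
    """One influx-diffusion-uptake update of a drug field.

    The source mask marks sites receiving vascular influx this step; the
    secretion value already includes the dose-scaled permeability.
    """
    return _species_step(field, source_mask, params)


def build_source_masks(grid: Grid, dosing_active: dict[str, bool],
                       drug_source: str = "uniform") -> dict[str, np.ndarray | None]:
    """Characteristic source masks for every species this step.

    Cytokines are secreted by their producing cell type: DKK1 and RANKL at
    MM sites, OPG at OB sites, TNFa at OC sites.  Drug influx masks depend
    on the delivery mode: ``uniform`` floods every lattice site while the
    drug's schedule is active (systemic vascular delivery), ``as_printed``
    restricts influx to OC-occupied sites.  Inactive drugs get an empty
    (None) mask.
    """
    mm = grid.type_mask(CellType.MM)
    masks: dict[str, np.ndarray | None] = {
        "dkk1": mm,
        "rankl": mm,
        "opg": grid.type_mask(CellType.OB),
        "tnfa": grid.type_mask(CellType.OC),
    }
    oc_mask = None
    for drug in ("bhq880", "gc", "lidamycin"):
        if not dosing_active.get(drug, False):
            masks[drug] = None
        elif drug_source == "uniform":
            masks[drug] = np.ones(grid.shape, dtype=bool)
        else:
            if oc_mask is None:
                oc_mask = grid.type_mask(CellType.OC)
            masks[drug] = oc_mask
    return masks


def schedule_active_map(schedule: DoseSchedule, t: int) -> dict[str, bool]:
    """Field-name keyed activity flags for the three drugs at step ``t``."""
    from .state import DRUG_NAMES
    return {field: schedule.active(name, t) for name, field in DRUG_NAMES.items()}
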