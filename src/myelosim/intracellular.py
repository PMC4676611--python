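"""Intracellular scale: per-step phenotype decision for each agent.

Every simulation step each living cell either (1) enters apoptosis, drawn
against an exponential-survival hazard modulated by the drug it responds to
(Lidamycin for MMs, glucocorticoids for OBs/OCs), (2) proliferates --
gated by a Bernoulli draw against a cytokine-dependent Hill response, then
walked through a discrete G0/G1 -> S -> G2 -> M cycle with division in M,
(3) migrates to a ranked neighbouring site, or (4) quiesces when no site is
available.  All saturating responses are Hill functions of order 2:
Hill(x) = x^2 / (1 + x^2) evaluated at x = concentration / threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Optional

import numpy as np

from .state import (APOPTOSIS_DURATION, CellAgent, CellType, CyclePhase,
                    ModelParameters, Phenotype, Position)

__all__ = [
    "LocalEnvironment", "Outcome", "PhenotypeDecision",
    "apoptosis_probability", "mm_apoptosis_rate", "gc_apoptosis_rate",
    "apoptosis_rate", "proliferation_probability", "cell_cycle_gate",
    "advance_cell",
]


def _hill2(x: float) -> float:
    """Order-2 Hill response x^2/(1+x^2), saturating at 1."""
    x2 = x * x
    return x2 / (1.0 + x2)


@dataclass
class LocalEnvironment:
    """Concentrations seen by one agent at its lattice site.

    ``ewnt`` is the effective Wnt signal (already BHQ880-corrected by the
    intercellular module) and ``o_rl`` the OPG:RANKL ratio.
    """

    lidamycin: float = 0.0
    gc: float = 0.0
    tnfa: float = 0.0
    ewnt: float = 0.0
    o_rl: float = 0.0


class Outcome(Enum):
    APOPTOSE = "apoptose"
    PROLIFERATE = "proliferate"
    MIGRATE = "migrate"
    QUIESCE = "quiesce"


@dataclass
class PhenotypeDecision:
    outcome: Outcome
    site: Optional[Position] = None   # target site for migrate / divide
    remove: bool = False              # apoptosis completed this step


# ---------------------------------------------------------------------------
# hazard and probability primitives
# ---------------------------------------------------------------------------

def apoptosis_probability(rate: float, dt: float) -> float:
    """Per-step apoptosis probability 1 - exp(-rate * dt).

    ``rate`` is an hourly hazard; the exponential-survival form maps it to a
    probability in [0, 1) over one step of ``dt`` hours.
    """
    if rate < 0:
        raise ValueError(f"apoptosis rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


def _mm_amplitudes(params: ModelParameters) -> tuple[float, float]:
    """(apoptosis amplitude, proliferation amplitude) for MMs.

    Under the default ``symbols`` binding the Lidamycin-apoptosis Hill uses
    the value bound to beta_mm^L and the TNFa-proliferation Hill the value
    bound to beta_mm^T; the ``labels`` binding swaps them.
    """
    if params.beta_binding == "symbols":
        return params.beta_mm_L, params.beta_mm_T
    return params.beta_mm_T, params.beta_mm_L


def mm_apoptosis_rate(L: float, params: ModelParameters) -> float:
    """Hourly MM apoptosis hazard under a Lidamycin concentration ``L``."""
    if L < 0:
        raise ValueError("Lidamycin concentration must be >= 0")
    beta_apop, _ = _mm_amplitudes(params)
    return params.lambda0_mm + beta_apop * _hill2(L / params.K_L_mm)


def gc_apoptosis_rate(G: float, target: CellType, params: ModelParameters) -> float:
    """Hourly OB/OC apoptosis hazard under a glucocorticoid concentration.

    Uses (lambda0_1, beta1_GC, K_GC_1) for osteoblasts and
    (lambda0_2, beta2_GC, K_GC_2) for osteoclasts.
    """
    if G < 0:
        raise ValueError("GC concentration must be >= 0")
    if target == CellType.OB:
        lam0, beta, K = params.lambda0_1, params.beta1_GC, params.K_GC_1
    elif target == CellType.OC:
        lam0, beta, K = params.lambda0_2, params.beta2_GC, params.K_GC_2
    else:
        raise ValueError(f"GC apoptosis applies to OB or OC, not {target!r}")
    return lam0 + beta * _hill2(G / K)


def apoptosis_rate(cell_type: CellType, env: LocalEnvironment,
                   params: ModelParameters) -> float:
    """Drug-modulated apoptosis hazard for any cell type."""
    if cell_type == CellType.MM:
        return mm_apoptosis_rate(env.lidamycin, params)
    return gc_apoptosis_rate(env.gc, cell_type, params)


def proliferation_probability(cell_type: CellType, env: LocalEnvironment,
                              params: ModelParameters) -> float:
    """Probability of entering the cell cycle this step, clamped to [0, 1].

    MMs are stimulated by TNFa, OBs by effective Wnt, and OCs are inhibited
    by the OPG:RANKL ratio.
    """
    if cell_type == CellType.MM:
        _, beta_prol = _mm_amplitudes(params)
        p = params.P0_mm + beta_prol * _hill2(env.tnfa / params.K_T_mm)
    elif cell_type == CellType.OB:
        p = params.P0_ob + params.beta_ob * _hill2(env.ewnt / params.K_W)
    elif cell_type == CellType.OC:
        x = env.o_rl / params.K_O_RL
        p = params.P0_oc + params.P_pathway_oc / (1.0 + x * x)
    else:
        raise ValueError(f"unknown cell type {cell_type!r}")
    return min(1.0, max(0.0, p))


def cell_cycle_gate(p_prol: float, u: float) -> bool:
    """Bernoulli gate into the cell cycle: True iff u < p_prol."""
    if not (0.0 <= p_prol <= 1.0):
        raise ValueError(f"proliferation probability must be in [0, 1], got {p_prol}")
    if not (0.0 <= u < 1.0):
        raise ValueError(f"uniform draw must lie in [0, 1), got {u}")
    return u < p_prol


# ---------------------------------------------------------------------------
# the per-step decision
# ---------------------------------------------------------------------------

_NEXT_PHASE = {CyclePhase.G0G1: CyclePhase.S,
               CyclePhase.S: CyclePhase.G2,
               CyclePhase.G2: CyclePhase.M}

SiteChooser = Callable[[Position], Optional[Position]]


def advance_cell(cell: CellAgent, env: LocalEnvironment,
                 params: ModelParameters, rng: np.random.Generator,
                 choose_site: SiteChooser) -> PhenotypeDecision:
    """One phenotype-switch decision for a living agent.

    Order of checks: an already-apoptotic cell only runs down its countdown
    and is removed when it expires.  Otherwise the cell first draws against
    its drug-modulated apoptosis probability; on survival it draws the
    cell-cycle gate.  Cycling cells migrate through G0/G1, S and G2 and
    divide in M (into a site picked by ``choose_site``); non-cycling cells
    migrate.  A cell with no available site becomes reversibly quiescent --
    an M-phase cell retains its phase and retries next step.

    ``choose_site`` maps an origin position to an empty target site or None;
    the engine wires it to the intercellular ranked selection.  The cell's
    phenotype, cycle phase and countdown are mutated in place; the caller
    applies the returned movement/division/removal to the grid.
    """
    if cell.phenotype == Phenotype.APOPTOTIC:
        cell.apoptosis_countdown = (cell.apoptosis_countdown or 0) - 1
        return PhenotypeDecision(Outcome.APOPTOSE,
                                 remove=cell.apoptosis_countdown <= 0)

    p_apop = apoptosis_probability(apoptosis_rate(cell.cell_type, env, params),
                                   params.dt_hours)
    if rng.random() < p_apop:
        cell.phenotype = Phenotype.APOPTOTIC
        cell.cycle_phase = CyclePhase.NONE
        cell.phase_steps = 0
        cell.apoptosis_countdown = APOPTOSIS_DURATION
        return PhenotypeDecision(Outcome.APOPTOSE)

    if not cell.in_cycle:
        p_prol = proliferation_probability(cell.cell_type, env, params)
        if cell_cycle_gate(p_prol, rng.random()):
            cell.cycle_phase = CyclePhase.G0G1
            cell.phase_steps = 0

    if cell.in_cycle:
        cell.phenotype = Phenotype.PROLIFERATING
        if cell.cycle_phase == CyclePhase.M:
            site = choose_site(cell.position)
            if site is None:
                return PhenotypeDecision(Outcome.QUIESCE)  # phase retained
            cell.cycle_phase = CyclePhase.G0G1  # parent re-enters the cycle
            cell.phase_steps = 0
            return PhenotypeDecision(Outcome.PROLIFERATE, site=site)
        # interphase: advance the phase clock, then migrate
        cell.phase_steps += 1
        if cell.phase_steps >= params.cycle_lengths()[cell.cycle_phase]:
            cell.cycle_phase = _NEXT_PHASE[cell.cycle_phase]
            cell.phase_steps = 0
        site = choose_site(cell.position)
        if site is None:
            return PhenotypeDecision(Outcome.QUIESCE)
        return PhenotypeDecision(Outcome.MIGRATE, site=site)

    site = choose_site(cell.position)
    if site is None:
        cell.phenotype = Phenotype.QUIESCENT
        return PhenotypeDecision(Outcome.QUIESCE)
    cell.phenotype = Phenotype.MIGRATING
    return PhenotypeDecision(Outcome.MIGRATE, site=site)
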