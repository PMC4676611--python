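"""Intercellular scale: signal integration and ranked site selection.

Two jobs live here.  First, turning the local DKK1 concentration (optionally
neutralised by the anti-DKK1 antibody BHQ880) into an effective Wnt signal
for osteoblasts, and the local OPG/RANKL concentrations into the inhibitory
ratio seen by osteoclasts.  Second, the stochastic choice of a migration or
division site: candidate sites are scored by a motility kernel and a
crowding preference, the scores are normalised into a partition of [0, 1),
and a uniform draw picks the site (roulette-wheel selection).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .state import Grid, ModelParameters, Position, count_occupied_neighbors

__all__ = [
    "effective_dkk1", "wnt_effect", "opg_rankl_ratio", "migration_kernel",
    "neighborhood_preference", "SiteRanking", "rank_sites", "rank_and_select",
]

#: crowding preference V(n): mild aversion to isolation and to dense
#: neighbourhoods, strongest pull toward 1-2 neighbours.
_NEIGHBOR_PREFERENCE = {0: 1.0 / 16, 1: 1.0, 2: 1.0,
                        3: 0.25, 4: 0.25, 5: 0.125, 6: 0.125}


def effective_dkk1(D: float, B: float) -> float:
    """Effective DKK1 after neutralisation by a BHQ880 concentration ``B``.

    D_e = D^2 / (D + B); reduces to D when B = 0 and decreases toward 0 as
    the antibody dose grows.  Returns 0 at D = 0.
    """
    if D < 0 or B < 0:
        raise ValueError("concentrations must be >= 0")
    if D == 0.0:
        return 0.0
    return D * D / (D + B)


def wnt_effect(D_effective: float, params: ModelParameters) -> float:
    """Site-level Wnt activity under DKK1 inhibition.

    EWnt = E0 + beta_W / (1 + (D_e/K_D)^2): full signal E0 + beta_W with no
    DKK1, decaying to the basal E0 as DKK1 saturates.
    """
    if D_effective < 0:
        raise ValueError("effective DKK1 must be >= 0")
    x = D_effective / params.K_D
    return params.E0 + params.beta_W / (1.0 + x * x)


def opg_rankl_ratio(opg: float, rankl: float, epsilon: float = 1e-9) -> float:
    """OPG:RANKL concentration ratio with a guarded denominator.

    Returns opg / max(rankl, epsilon): finite and >= 0 even where RANKL has
    not yet diffused in.
    """
    if opg < 0 or rankl < 0:
        raise ValueError("concentrations must be >= 0")
    return opg / max(rankl, epsilon)


def migration_kernel(r: float, D_mot: float, dt: float) -> float:
    """Relative weight of a move of length ``r`` (lattice units).

    p(r) = exp(-r^2 / (4*pi*D_mot*dt)) / (4*pi*D_mot*dt), a Gaussian-shaped
    kernel strictly decreasing in r.  The prefactor is a constant shared by
    all candidates of one decision and cancels under normalisation.
    """
    if r < 0:
        raise ValueError("distance must be >= 0")
    if D_mot <= 0 or dt <= 0:
        raise ValueError("D_mot and dt must be > 0")
    s = 4.0 * math.pi * D_mot * dt
    return math.exp(-(r * r) / s) / s


def neighborhood_preference(occupied_count: int) -> float:
    """Crowding weight V for a candidate with ``occupied_count`` occupied
    face neighbours (0..6)."""
    try:
        return _NEIGHBOR_PREFERENCE[occupied_count]
    except KeyError:
        raise ValueError(
            f"occupied neighbour count must be in [0, 6], got {occupied_count}"
        ) from None


@dataclass
class SiteRanking:
    """Scored candidate sites and their roulette partition of [0, 1)."""

    candidates: list[Position]
    raw: np.ndarray         # R_l = (1/4) p(r_l) V_l
    normalized: np.ndarray  # R~_l, sums to 1
    cumulative: np.ndarray  # right edges of the half-open intervals S_l

    def select(self, u: float) -> Position:
        if not (0.0 <= u < 1.0):
            raise ValueError(f"uniform draw must lie in [0, 1), got {u}")
        idx = int(np.searchsorted(self.cumulative, u, side="right"))
        idx = min(idx, len(self.candidates) - 1)  # guard u ~ 1 - eps rounding
        return self.candidates[idx]


def rank_sites(origin: Position, candidates: Sequence[Position], grid: Grid,
               params: ModelParameters) -> Optional[SiteRanking]:
    """Score empty candidate sites around ``origin``.

    R_l = (1/4) * p(r_l) * V_l with r_l the Euclidean distance to the
    candidate and V_l the crowding preference of the candidate's own
    neighbourhood.  Returns None when there are no candidates or all raw
    scores vanish (the latter cannot occur with the positive preference
    table; kept as a guard).
    """
    if not candidates:
        return None
    raw = np.empty(len(candidates))
    for l, site in enumerate(candidates):
        dx = site[0] - origin[0]
        dy = site[1] - origin[1]
        dz = site[2] - origin[2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        v = neighborhood_preference(count_occupied_neighbors(site, grid))
        raw[l] = 0.25 * migration_kernel(r, params.D_mot, params.dt_hours) * v
    total = raw.sum()
    if total <= 0.0:
        return None
    normalized = raw / total
    return SiteRanking(list(candidates), raw, normalized, np.cumsum(normalized))


def rank_and_select(origin: Position, candidates: Sequence[Position],
                    grid: Grid, params: ModelParameters,
                    u: float) -> Optional[Position]:
    """Roulette-wheel selection among empty candidate sites.

    Returns the candidate whose half-open interval of the normalised-score
    partition contains ``u``, or None when the candidate list is empty (the
    caller then marks the cell reversibly quiescent).
    """
    ranking = rank_sites(origin, candidates, grid, params)
    if ranking is None:
        return None
    return ranking.select(u)
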