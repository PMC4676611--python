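"""Treatment scoring, dose-response curves, Loewe synergy and sensitivity.

The composite endpoint R_drug = N_MM(120) * |N_OC(120) - N_OC(0)| *
|N_OB(120) - N_OB(0)| rewards regimens that both kill the tumour and return
the osteoclast/osteoblast populations to their pre-treatment balance; lower
is better and 0 means either tumour eradication or an exactly rebalanced
lineage.  Synergy of a combination is judged by the Loewe combination index
CI = sum_i d_i / GCx(i), the combination doses over the single-agent doses
that reach the same R_drug effect: CI < 1 is synergy, 1 additivity, > 1
antagonism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationConfig, SimulationResult, run
from .state import CellType, DoseSchedule, REFERENCE_DOSES

__all__ = [
    "EndpointCounts", "endpoint_counts", "r_drug", "r_drug_of_result",
    "DoseResponseCurve", "geometric_dose_grid", "dose_response_curve",
    "equi_effective_dose", "OutOfRangeError", "SynergyResult", "loewe_ci",
    "regimen_table", "SensitivityReport", "sensitivity_spearman",
    "R_DRUG_EFFECT_THRESHOLD",
]

#: R_drug level used as the equi-effect target in the synergy analysis.
R_DRUG_EFFECT_THRESHOLD = 960.0


class OutOfRangeError(ValueError):
    """A requested effect lies outside the achieved range of a curve."""


@dataclass(frozen=True)
class EndpointCounts:
    """Cell counts entering the treatment score."""

    n_mm_end: int
    n_oc_end: int
    n_ob_end: int
    n_oc_start: int
    n_ob_start: int

    def __post_init__(self) -> None:
        for name in ("n_mm_end", "n_oc_end", "n_ob_end", "n_oc_start",
                     "n_ob_start"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a non-negative count")


def endpoint_counts(result: SimulationResult) -> EndpointCounts:
    first, last = result.initial_counts(), result.final_counts()
    return EndpointCounts(n_mm_end=last[CellType.MM],
                          n_oc_end=last[CellType.OC],
                          n_ob_end=last[CellType.OB],
                          n_oc_start=first[CellType.OC],
                          n_ob_start=first[CellType.OB])


def r_drug(counts: EndpointCounts) -> float:
    """Composite treatment-efficacy score; 0 iff the tumour is gone or one
    lineage ends exactly at its initial count."""
    return float(counts.n_mm_end
                 * abs(counts.n_oc_end - counts.n_oc_start)
                 * abs(counts.n_ob_end - counts.n_ob_start))


def r_drug_of_result(result: SimulationResult) -> float:
    return r_drug(endpoint_counts(result))


def mm_oc_crossing_step(result: SimulationResult,
                        margin: int = 5) -> Optional[int]:
    """First step at which the MM count reaches the OC count again after an
    initial separation (OC leading by at least ``margin`` cells).

    Returns None when the trajectories never separate; a run still
    uncrossed at its final step reports one past that step (censored).
    """
    mm = result.series(CellType.MM)
    oc = result.series(CellType.OC)
    separated = False
    for t in range(len(mm)):
        if not separated and oc[t] - mm[t] >= margin:
            separated = True
        elif separated and mm[t] >= oc[t]:
            return t
    return len(mm) if separated else None


# ---------------------------------------------------------------------------
# dose grids and dose-response curves
# ---------------------------------------------------------------------------

def geometric_dose_grid(reference_dose: float, n_levels: int = 20,
                        lo: float = 0.1, hi: float = 10.0) -> np.ndarray:
    """Geometric ladder of doses from lo*reference to hi*reference.

    With the defaults: 20 levels from 0.1X to 10X, consecutive ratio
    100^(1/19).
    """
    if reference_dose <= 0:
        raise ValueError("reference dose must be > 0")
    if n_levels < 2:
        raise ValueError("a dose grid needs at least 2 levels")
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    k = np.arange(n_levels)
    return reference_dose * lo * (hi / lo) ** (k / (n_levels - 1))


@dataclass
class DoseResponseCurve:
    """Mean treatment score at each dose of a single agent."""

    drug: str
    doses: np.ndarray
    effects: np.ndarray
    reference_dose: Optional[float] = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.doses.ndim != 1 or self.doses.shape != self.effects.shape:
            raise ValueError("doses and effects must be matching 1D arrays")
        if len(self.doses) < 2:
            raise ValueError("a curve needs at least 2 dose levels")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def monotone(self) -> bool:
        d = np.diff(self.effects)
        return bool(np.all(d >= 0) or np.all(d <= 0))

    def as_mapping(self) -> dict[float, float]:
        return dict(zip(self.doses.tolist(), self.effects.tolist()))


def dose_response_curve(drug: str, dose_levels: Sequence[float],
                        base_config: SimulationConfig, replicates: int,
                        seeds: Sequence[int],
                        start: int = 20, stop: int = 60,
                        runner: Optional[Callable[[SimulationConfig], SimulationResult]] = None
                        ) -> DoseResponseCurve:
    """Tabulate mean R_drug of single-agent regimens across dose levels."""
    if len(dose_levels) < 2:
        raise ValueError("need at least 2 dose levels")
    if replicates > len(seeds):
        raise ValueError("need one seed per replicate")
    runner = runner or run
    doses = np.asarray(sorted(float(d) for d in dose_levels))
    effects = np.empty_like(doses)
    for i, dose in enumerate(doses):
        schedule = DoseSchedule.single(drug, dose=dose, start=start, stop=stop)
        scores = []
        for rep in range(replicates):
            cfg = base_config.with_schedule(schedule, seed=int(seeds[rep]))
            scores.append(r_drug_of_result(runner(cfg)))
        effects[i] = float(np.mean(scores))
    return DoseResponseCurve(drug=drug, doses=doses, effects=effects,
                             reference_dose=REFERENCE_DOSES.get(drug))


def _monotone_branch(curve: DoseResponseCurve) -> tuple[np.ndarray, np.ndarray]:
    """Dose/effect arrays of the monotone branch used for inversion.

    A fully monotone curve is used whole.  Otherwise the maximal monotone
    run containing the reference dose (nearest grid point) is selected; the
    simulated curves can genuinely rebound at high dose, and inverting
    across a fold would be meaningless.
    """
    d, e = curve.doses, curve.effects
    if curve.monotone:
        return d, e
    if curve.reference_dose is None:
        raise OutOfRangeError(
            f"curve for {curve.drug} is non-monotone and has no reference "
            "dose to anchor a branch")
    anchor = int(np.argmin(np.abs(np.log(d) - math.log(curve.reference_dose))))
    s = np.sign(np.diff(e))
    # grow the run outward from the anchor point while segment directions
    # stay consistent (flat segments are compatible with either direction);
    # the low-dose side is claimed first so an anchor sitting exactly on a
    # fold resolves to the limb below the reference dose
    left, right, direction = anchor, anchor, 0
    j = anchor - 1
    while j >= 0:
        if s[j] != 0 and direction != 0 and s[j] != direction:
            break
        if s[j] != 0:
            direction = int(s[j])
        left = j
        j -= 1
    j = anchor
    while j < len(s):
        if s[j] != 0 and direction != 0 and s[j] != direction:
            break
        if s[j] != 0:
            direction = int(s[j])
        right = j + 1
        j += 1
    return d[left:right + 1], e[left:right + 1]


def equi_effective_dose(curve: DoseResponseCurve, target_effect: float) -> float:
    """Dose at which the single agent reaches ``target_effect``.

    Inverts the (monotone branch of the) curve by piecewise-linear
    interpolation in log-dose.  Raises OutOfRangeError rather than
    extrapolating beyond the achieved effects.
    """
    d, e = _monotone_branch(curve)
    lo, hi = float(np.min(e)), float(np.max(e))
    if not (lo <= target_effect <= hi):
        raise OutOfRangeError(
            f"target effect {target_effect} outside achieved range "
            f"[{lo}, {hi}] for {curve.drug}")
    # orient ascending in effect for interpolation
    if e[0] > e[-1]:
        e, d = e[::-1], d[::-1]
    # exact grid hit first (ties resolve to the tabulated dose)
    hits = np.nonzero(e == target_effect)[0]
    if hits.size:
        return float(d[hits[0]])
    logd = np.interp(target_effect, e, np.log(d))
    return float(np.exp(logd))


# ---------------------------------------------------------------------------
# Loewe synergy
# ---------------------------------------------------------------------------

@dataclass
class SynergyResult:
    """Loewe combination index for one combination dose triple."""

    ci: float
    combo_doses: dict[str, float]
    equi_effective: dict[str, float]
    target_effect: float

    @property
    def verdict(self) -> str:
        if self.ci < 1.0:
            return "synergy"
        if self.ci == 1.0:
            return "additivity"
        return "antagonism"


def loewe_ci(combo_doses: dict[str, float],
             single_curves: dict[str, DoseResponseCurve],
             target_effect: float = R_DRUG_EFFECT_THRESHOLD) -> SynergyResult:
    """Combination index CI = sum_i d_i / GCx(i) at a common effect level.

    ``combo_doses`` are the doses of each drug in the combination sitting on
    the target-effect isobologram; ``single_curves`` must cover the target
    so each single-agent equi-effective dose GCx(i) exists.
    """
    if not combo_doses:
        raise ValueError("combination must contain at least one drug")
    gcx: dict[str, float] = {}
    ci = 0.0
    for drug, dose in combo_doses.items():
        if dose < 0:
            raise ValueError(f"combination dose for {drug} must be >= 0")
        if drug not in single_curves:
            raise ValueError(f"no single-agent curve supplied for {drug}")
        g = equi_effective_dose(single_curves[drug], target_effect)
        if g <= 0:
            raise OutOfRangeError(f"equi-effective dose for {drug} is not positive")
        gcx[drug] = g
        ci += dose / g
    return SynergyResult(ci=ci, combo_doses=dict(combo_doses),
                         equi_effective=gcx, target_effect=target_effect)


# ---------------------------------------------------------------------------
# regimen scoring table
# ---------------------------------------------------------------------------

def regimen_table(results: dict[tuple[str, int], SimulationResult]) -> pd.DataFrame:
    """Long-format table of endpoint counts and R_drug per (regimen, rep)."""
    rows = []
    for (name, rep), res in sorted(results.items()):
        ep = endpoint_counts(res)
        rows.append({"regimen": name, "replicate": rep, "seed": res.seed,
                     "N_MM_end": ep.n_mm_end, "N_OB_end": ep.n_ob_end,
                     "N_OC_end": ep.n_oc_end, "R_drug": r_drug(ep)})
    return pd.DataFrame(rows)


def regimen_medians(table: pd.DataFrame) -> pd.Series:
    return table.groupby("regimen")["R_drug"].median()


# ---------------------------------------------------------------------------
# parameter sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    """Spearman rho and p-value per parameter and output cell type."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rho(self, parameter: str, cell_type: str) -> float:
        row = self.table[(self.table.parameter == parameter)
                         & (self.table.cell_type == cell_type)]
        return float(row.iloc[0]["rho"]) if len(row) else float("nan")


OutcomeFn = Callable[[SimulationConfig], tuple[float, float, float]]


def _default_outcome(config: SimulationConfig) -> tuple[float, float, float]:
    res = run(config)
    final = res.final_counts()
    return (final[CellType.MM], final[CellType.OB], final[CellType.OC])


def sensitivity_spearman(parameter_ranges: dict[str, Sequence[float]],
                         base_config: SimulationConfig,
                         n_sims_per_setting: int = 10,
                         seed: int = 0,
                         outcome_fn: Optional[OutcomeFn] = None
                         ) -> SensitivityReport:
    """One-at-a-time Spearman sensitivity sweep.

    Each listed parameter is varied over its range while all others stay at
    their base value; every setting is simulated ``n_sims_per_setting``
    times with fresh seeds, and the rank correlation of parameter value
    against the final count of each cell type is computed over the pooled
    (value, outcome) pairs.  A constant outcome leaves the correlation
    undefined and is reported as NaN, not as 0.

    ``outcome_fn`` may replace the simulator (e.g. in tests); it maps a
    configured run to final (MM, OB, OC) counts.
    """
    outcome_fn = outcome_fn or _default_outcome
    root = np.random.SeedSequence(seed)
    rows = []
    for param, values in parameter_ranges.items():
        values = list(values)
        if len(set(values)) < 3:
            raise ValueError(f"range for {param} needs >= 3 distinct values")
        xs: list[float] = []
        ys: dict[str, list[float]] = {"MM": [], "OB": [], "OC": []}
        child_seeds = root.spawn(1)[0].generate_state(
            len(values) * n_sims_per_setting)
        i = 0
        for value in values:
            for _ in range(n_sims_per_setting):
                params = replace(base_config.params, **{param: value})
                cfg = replace(base_config, params=params,
                              seed=int(child_seeds[i] % (2 ** 31)))
                i += 1
                mm, ob, oc = outcome_fn(cfg)
                xs.append(float(value))
                ys["MM"].append(mm)
                ys["OB"].append(ob)
                ys["OC"].append(oc)
        for cell_type, outcome in ys.items():
            arr = np.asarray(outcome)
            if np.all(arr == arr[0]) or np.all(np.asarray(xs) == xs[0]):
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(xs, arr)
            rows.append({"parameter": param, "cell_type": cell_type,
                         "rho": rho, "p_value": p})
    return SensitivityReport(table=pd.DataFrame(rows))
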