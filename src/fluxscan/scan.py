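"""Growth-coupled scanning: enforce target flux stepwise, profile, classify.

The scan asks which reactions' fluxes co-vary with production of a
target metabolite when the network is forced to make more of it while
still growing as fast as it can. Procedure:

1. *Initialisation* (:func:`initialize_scan`): record the non-growth ATP
   maintenance floor, the minimal and maximal biomass flux, and the
   theoretical maximum of the target sink flux.
2. *Schedule* (:func:`build_step_schedule`): divide the capped maximum
   (default 90% of it) into equal steps — five by default.
3. *Scan* (:func:`run_scan`): at each step, raise the target reaction's
   lower bound to the enforced value, re-maximise biomass with the
   deterministic (parsimonious) solve, and record every reaction's flux.
4. *Validity filter* (:func:`filter_valid_profiles`): keep only
   reactions with all steps feasible and a steadily (monotonically)
   changing |flux| profile.
5. *Classification* (:func:`classify_reactions`): flux-increasing
   (upregulation candidates), flux-decreasing (downregulation/deletion
   candidates) or unaffected, combined with the flux direction into the
   four proportionality classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import cobra
import pandas as pd

from .model_core import COMPARISON_TOL, find_atp_maintenance, optimize

__all__ = [
    "ClassificationRecord",
    "ScanError",
    "ScanInit",
    "ScanInitializationError",
    "ScanProfile",
    "ScanTable",
    "StepSchedule",
    "build_step_schedule",
    "classify_reactions",
    "filter_valid_profiles",
    "initialize_scan",
    "run_scan",
]

#: Default relative tolerance for the "steadily changing" monotonicity filter.
DEFAULT_MONOTONICITY_TOL = 1e-4
#: Default relative flux change (step 1 → step n) below which a reaction
#: counts as unaffected.
DEFAULT_CHANGE_TOL = 0.01
#: Absolute floor under both tolerances, above LP round-off.
DEFAULT_ABS_FLOOR = 1e-9

ReactionType = Literal["flux_increasing", "flux_decreasing", "unaffected"]
Proportionality = Literal[
    "positive_directly", "positive_contra", "negative_directly", "negative_contra", "none"
]


class ScanError(RuntimeError):
    """A scan invariant was violated or a precondition failed."""


class ScanInitializationError(ScanError):
    """Initialisation FBA failed; ``stage`` names the failing computation."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"scan initialisation failed at stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class ScanInit:
    """Fluxes anchoring the scan (mmol gDW^-1 h^-1; biomass in h^-1)."""

    atp_maintenance_floor: float
    biomass_min: float
    biomass_max: float
    target_max: float


@dataclass(frozen=True)
class StepSchedule:
    """Enforced target-flux levels, equally spaced up to the capped maximum."""

    enforced_values: tuple[float, ...]
    cap_fraction: float = 0.9
    n_steps: int = 5

    def __post_init__(self) -> None:
        if len(self.enforced_values) != self.n_steps:
            raise ValueError("enforced_values length must equal n_steps")
        if any(b <= a for a, b in zip(self.enforced_values, self.enforced_values[1:])):
            raise ValueError("enforced_values must be strictly increasing")


@dataclass
class ScanProfile:
    """One reaction's flux trajectory across the enforced-target steps."""

    reaction_id: str
    reaction_name: str
    subsystem: str
    stoichiometry_text: str
    flux_values: list[float]
    all_feasible: bool
    steadily_changing: bool = False
    direction_left_to_right: bool = True


@dataclass
class ScanTable:
    """Full scan result: per-reaction profiles plus the biomass trajectory."""

    profiles: list[ScanProfile]
    init: ScanInit
    schedule: StepSchedule
    biomass_per_step: list[float]

    def profile(self, reaction_id: str) -> ScanProfile:
        for entry in self.profiles:
            if entry.reaction_id == reaction_id:
                return entry
        raise KeyError(reaction_id)

    def to_frame(self) -> pd.DataFrame:
        """Supplementary-style table: Reactions_ID, Reactions_name,
        FBA_results_1..n, Subsystem, Var10 (stoichiometry text)."""
        n = self.schedule.n_steps
        rows = []
        for p in self.profiles:
            row = {"Reactions_ID": p.reaction_id, "Reactions_name": p.reaction_name}
            for k in range(n):
                row[f"FBA_results_{k + 1}"] = p.flux_values[k]
            row["Subsystem"] = p.subsystem
            row["Var10"] = p.stoichiometry_text
            rows.append(row)
        columns = (["Reactions_ID", "Reactions_name"]
                   + [f"FBA_results_{k + 1}" for k in range(n)]
                   + ["Subsystem", "Var10"])
        return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class ClassificationRecord:
    """Scan verdict for one retained reaction."""

    reaction_id: str
    reaction_type: ReactionType
    proportionality: Proportionality


def initialize_scan(
    model: cobra.Model,
    biomass_id: str,
    target_id: str,
    atp_maintenance_override: float | None = None,
) -> ScanInit:
    """Compute the anchor fluxes needed before scanning.

    The ATP maintenance floor is the maintenance pseudo-reaction's lower
    bound (or the explicit override); the model must already carry it as
    a bound — without a maintained ATP drain the network has no
    steady-state cost of staying alive and coupling is overestimated.
    """
    for rid in (biomass_id, target_id):
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model")

    if atp_maintenance_override is not None:
        atp_floor = float(atp_maintenance_override)
    else:
        maintenance = find_atp_maintenance(model)
        atp_floor = float(maintenance.lower_bound) if maintenance is not None else 0.0

    sol_max = optimize(model, biomass_id, "max")
    if not sol_max.ok:
        raise ScanInitializationError("biomass_max", f"status={sol_max.status}")
    sol_min = optimize(model, biomass_id, "min")
    if not sol_min.ok:
        raise ScanInitializationError("biomass_min", f"status={sol_min.status}")
    sol_target = optimize(model, target_id, "max")
    if not sol_target.ok:
        raise ScanInitializationError("target_max", f"status={sol_target.status}")

    return ScanInit(
        atp_maintenance_floor=atp_floor,
        biomass_min=max(0.0, sol_min.objective_value),
        biomass_max=sol_max.objective_value,
        target_max=sol_target.objective_value,
    )


def build_step_schedule(
    target_max: float, n_steps: int = 5, cap_fraction: float = 0.9
) -> StepSchedule:
    """Equally spaced enforced values ending at ``cap_fraction * target_max``.

    The cap keeps the last step strictly inside the feasible production
    range: at the raw theoretical maximum all flux is diverted to the
    product, biomass collapses to zero, and growth-coupled responses are
    no longer defined.
    """
    if target_max <= 0:
        raise ScanError("target cannot carry flux (target_max <= 0)")
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    if not 0 < cap_fraction <= 1:
        raise ValueError("cap_fraction must be in (0, 1]")
    cap = cap_fraction * target_max
    values = tuple(cap * k / n_steps for k in range(1, n_steps + 1))
    return StepSchedule(enforced_values=values, cap_fraction=cap_fraction, n_steps=n_steps)


def run_scan(
    model: cobra.Model,
    biomass_id: str,
    target_id: str,
    schedule: StepSchedule,
    deterministic: bool = True,
) -> ScanTable:
    """Execute the enforced-target scan and collect every flux profile.

    At each step the target reaction's lower bound is raised to the
    enforced value (its upper bound is kept, so the optimum may overshoot
    if that helps growth) and biomass is re-maximised. An infeasible
    step is flagged on every profile rather than raised. Bounds are
    restored afterwards.

    Raises
    ------
    ScanError
        If the biomass trajectory increases with enforced target flux —
        impossible for a shrinking feasible region, hence a solver or
        model defect.
    """
    init = initialize_scan(model, biomass_id, target_id)
    target = model.reactions.get_by_id(target_id)

    n = schedule.n_steps
    flux_rows: dict[str, list[float]] = {r.id: [] for r in model.reactions}
    biomass_per_step: list[float] = []
    step_feasible: list[bool] = []
    for enforced in schedule.enforced_values:
        if enforced > target.upper_bound:
            # outside the target's feasible range: the step cannot even
            # be posed as an LP, record it as infeasible
            biomass_per_step.append(math.nan)
            step_feasible.append(False)
            for rid in flux_rows:
                flux_rows[rid].append(math.nan)
            continue
        with model:
            target.lower_bound = enforced
            solution = optimize(model, biomass_id, "max", deterministic=deterministic)
        if solution.ok:
            biomass_per_step.append(solution.objective_value)
            step_feasible.append(True)
            for rid in flux_rows:
                flux_rows[rid].append(solution.fluxes[rid])
        else:
            biomass_per_step.append(math.nan)
            step_feasible.append(False)
            for rid in flux_rows:
                flux_rows[rid].append(math.nan)

    feasible_biomass = [b for b in biomass_per_step if not math.isnan(b)]
    for earlier, later in zip(feasible_biomass, feasible_biomass[1:]):
        if later > earlier + COMPARISON_TOL * max(1.0, abs(earlier)):
            raise ScanError(
                "biomass increased with enforced target flux "
                f"({earlier} -> {later}); scan invariant violated"
            )

    all_feasible = all(step_feasible)
    profiles = []
    for reaction in model.reactions:
        values = flux_rows[reaction.id]
        finite = [v for v in values if not math.isnan(v)]
        forward = True
        if finite:
            forward = finite[max(range(len(finite)), key=lambda i: abs(finite[i]))] >= 0
        profiles.append(
            ScanProfile(
                reaction_id=reaction.id,
                reaction_name=reaction.name or reaction.id,
                subsystem=reaction.subsystem or "",
                stoichiometry_text=reaction.build_reaction_string(),
                flux_values=values,
                all_feasible=all_feasible,
                direction_left_to_right=forward,
            )
        )
    return ScanTable(profiles=profiles, init=init, schedule=schedule,
                     biomass_per_step=biomass_per_step)


def _is_monotone(values: Sequence[float], rel_tol: float, abs_floor: float) -> bool:
    pairs = list(zip(values, values[1:]))
    slack = [max(rel_tol * max(abs(a), abs(b)), abs_floor) for a, b in pairs]
    non_decreasing = all(b >= a - s for (a, b), s in zip(pairs, slack))
    non_increasing = all(b <= a + s for (a, b), s in zip(pairs, slack))
    return non_decreasing or non_increasing


def filter_valid_profiles(
    table: ScanTable,
    monotonicity_tol: float = DEFAULT_MONOTONICITY_TOL,
    abs_floor: float = DEFAULT_ABS_FLOOR,
) -> ScanTable:
    """Keep reactions with all steps feasible and steadily changing |flux|.

    Non-monotone profiles indicate the LP jumped between alternative
    pathway usages rather than responding smoothly to the enforced
    production, so they are excluded from candidate calling.
    """
    survivors = []
    for profile in table.profiles:
        if not profile.all_feasible or any(math.isnan(v) for v in profile.flux_values):
            continue
        magnitudes = [abs(v) for v in profile.flux_values]
        if _is_monotone(magnitudes, monotonicity_tol, abs_floor):
            survivors.append(replace(profile, steadily_changing=True))
    return ScanTable(profiles=survivors, init=table.init, schedule=table.schedule,
                     biomass_per_step=table.biomass_per_step)


def classify_reactions(
    table: ScanTable,
    change_tol: float = DEFAULT_CHANGE_TOL,
    abs_floor: float = DEFAULT_ABS_FLOOR,
) -> list[ClassificationRecord]:
    """Three-way classification of every retained profile.

    A reaction is *flux-increasing* (upregulation candidate) when its
    |flux| grows from the first to the last step by more than
    ``change_tol`` (relative, with floor ``abs_floor``), *flux-decreasing*
    (downregulation/deletion candidate) when it shrinks by more, and
    *unaffected* otherwise. The proportionality class additionally
    records whether the flux runs with the reaction as written
    (left-to-right, "positive") or reversed ("negative").
    """
    records = []
    for profile in table.profiles:
        values = profile.flux_values
        magnitudes = [abs(v) for v in values]
        # direction from the data itself, not the stored flag: the peak
        # flux decides whether the reaction runs as written
        forward = values[max(range(len(values)), key=lambda i: magnitudes[i])] >= 0
        delta = magnitudes[-1] - magnitudes[0]
        threshold = max(change_tol * max(magnitudes[0], magnitudes[-1]), abs_floor)
        if delta > threshold:
            kind: ReactionType = "flux_increasing"
            proportionality: Proportionality = (
                "positive_directly" if forward else "negative_directly"
            )
        elif delta < -threshold:
            kind = "flux_decreasing"
            proportionality = (
                "positive_contra" if forward else "negative_contra"
            )
        else:
            kind, proportionality = "unaffected", "none"
        records.append(ClassificationRecord(profile.reaction_id, kind, proportionality))
    return records
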