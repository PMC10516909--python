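"""Small fixture models with known scan outcomes, plus a brute-force oracle.

The fixtures stand in for a full genome-scale reconstruction: they are
branched toy networks whose coupled / anti-coupled / unaffected
reactions are known by construction, so every stage of the scanning
pipeline can be checked against ground truth.

The oracle (:func:`oracle_scan`, :func:`oracle_optimum`,
:func:`oracle_essential_set`) is a deliberately independent code path:
it builds the dense stoichiometric matrix itself and solves every LP
with :func:`scipy.optimize.linprog` (HiGHS), classifying each reaction
by the trend of its flux-range midpoint across the enforced-target
steps. Midpoints are robust to alternate optima, so oracle/main-path
disagreement on a fixture indicates a real defect, not a tolerance
issue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction
from scipy.optimize import linprog

__all__ = [
    "TOY1_TRUTH",
    "ToySpec",
    "build_random_toy",
    "build_toy1",
    "oracle_essential_set",
    "oracle_optimum",
    "oracle_scan",
]

_BIG = 1000.0


def _add_reaction(model: Model, rid: str, stoich: dict, lb: float, ub: float,
                  name: str = "", subsystem: str = "") -> Reaction:
    reaction = Reaction(rid, name=name or rid, lower_bound=lb, upper_bound=ub)
    reaction.add_metabolites(stoich)
    reaction.subsystem = subsystem
    model.add_reactions([reaction])
    return reaction


def build_toy1() -> Model:
    """Deterministic 6-reaction, 4-metabolite fixture.

    Topology (uptake bound 10)::

        EX_A <-> A -R1-> B -R2-> (biomass drain, objective)
                     |      \\-R3-> P -EX_P-> (target sink)
                     \\-R5-> W (dead end, never carries flux)

    Known truth: R3 and EX_P are flux-increasing, R2 flux-decreasing,
    EX_A/R1/R5 unaffected; R1, R2 and EX_A are essential, R5 and the
    target branch are not.
    """
    model = Model("TOY1")
    A = Metabolite("A", name="substrate", compartment="c")
    B = Metabolite("B", name="precursor", compartment="c")
    P = Metabolite("P", name="product", compartment="c")
    W = Metabolite("W", name="waste", compartment="c")
    _add_reaction(model, "EX_A", {A: -1}, -10.0, 0.0, name="substrate exchange")
    _add_reaction(model, "R1", {A: -1, B: 1}, 0.0, _BIG, name="substrate to precursor")
    _add_reaction(model, "R2", {B: -1}, 0.0, _BIG, name="biomass drain")
    _add_reaction(model, "R3", {B: -1, P: 1}, 0.0, _BIG, name="precursor to product")
    _add_reaction(model, "EX_P", {P: -1}, 0.0, _BIG, name="product sink")
    _add_reaction(model, "R5", {A: -1, W: 1}, 0.0, _BIG, name="dead-end branch")
    model.objective = "R2"
    model.solver = "glpk"
    return model


#: Ground-truth classification of TOY1 under the default 5-step scan
#: (reaction_type, proportionality).
TOY1_TRUTH: dict[str, tuple[str, str]] = {
    "EX_A": ("unaffected", "none"),
    "R1": ("unaffected", "none"),
    "R2": ("flux_decreasing", "positive_contra"),
    "R3": ("flux_increasing", "positive_directly"),
    "EX_P": ("flux_increasing", "positive_directly"),
    "R5": ("unaffected", "none"),
}


@dataclass
class ToySpec:
    """Parameters for a seeded random fixture (≤ 15 reactions)."""

    n_branch_reactions: int = 2
    uptake_bound: float = 10.0
    include_maintenance: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.uptake_bound <= 0:
            raise ValueError(f"uptake_bound must be positive, got {self.uptake_bound}")
        if self.n_branch_reactions < 0:
            raise ValueError("n_branch_reactions must be non-negative")


def build_random_toy(spec: ToySpec) -> Model:
    """Seeded random branched network, feasible with positive biomass.

    The network is a tree rooted at the uptake metabolite: a linear
    backbone to the biomass drain, a target branch tapped at a random
    backbone node (randomly written in either stoichiometric direction,
    so negative-flux profiles occur), and side branches that are either
    dead ends or unprofitable secretions. Tree topology guarantees the
    optimal flux vector is unique at every scan step, so the fixture's
    truth is unambiguous.
    """
    rng = np.random.default_rng(spec.seed)
    model = Model(f"RANDTOY_{spec.seed}")
    length = int(rng.integers(2, 5))
    nodes = [Metabolite(f"M{i}", compartment="c") for i in range(length + 1)]
    _add_reaction(model, "EX_S", {nodes[0]: -1}, -spec.uptake_bound, 0.0,
                  name="substrate exchange")
    for i in range(1, length + 1):
        _add_reaction(model, f"R{i}", {nodes[i - 1]: -1, nodes[i]: 1}, 0.0, _BIG,
                      subsystem=f"backbone_{i % 2}")
    _add_reaction(model, "BIOMASS", {nodes[length]: -1}, 0.0, _BIG, name="biomass drain")

    tap = int(rng.integers(0, length + 1))
    target_met = Metabolite("T", compartment="c")
    if rng.random() < 0.5:
        _add_reaction(model, "TR", {nodes[tap]: -1, target_met: 1}, 0.0, _BIG,
                      subsystem="target_branch")
    else:
        # same conversion written right-to-left; carries negative flux
        _add_reaction(model, "TR", {target_met: -1, nodes[tap]: 1}, -_BIG, 0.0,
                      subsystem="target_branch")
    _add_reaction(model, "DM_T", {target_met: -1}, 0.0, _BIG, name="target sink")

    budget = 15 - len(model.reactions)
    for k in range(spec.n_branch_reactions):
        if budget <= 0:
            break
        origin = nodes[int(rng.integers(0, length + 1))]
        side = Metabolite(f"X{k}", compartment="c")
        _add_reaction(model, f"SB{k}", {origin: -1, side: 1}, 0.0, _BIG,
                      subsystem="side_branch")
        budget -= 1
        if budget > 0 and rng.random() < 0.5:
            _add_reaction(model, f"EX_X{k}", {side: -1}, 0.0, _BIG)
            budget -= 1

    if spec.include_maintenance:
        maintenance = 0.05 * spec.uptake_bound
        _add_reaction(model, "ATPM", {nodes[0]: -1}, maintenance, _BIG,
                      name="non-growth maintenance")

    model.objective = "BIOMASS"
    model.solver = "glpk"
    return model


# ---------------------------------------------------------------------------
# dense-LP oracle (independent of cobra's solver stack)
# ---------------------------------------------------------------------------

def _dense_arrays(model: Model) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    met_index = {met.id: i for i, met in enumerate(model.metabolites)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(rids)))
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    for j, reaction in enumerate(model.reactions):
        lb[j] = reaction.lower_bound
        ub[j] = reaction.upper_bound
        for metabolite, coefficient in reaction.metabolites.items():
            S[met_index[metabolite.id], j] = coefficient
    return S, lb, ub, rids


def _solve(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, j: int,
           sense: str) -> tuple[float | None, np.ndarray | None]:
    c = np.zeros(S.shape[1])
    c[j] = -1.0 if sense == "max" else 1.0
    result = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=list(zip(lb, ub)), method="highs")
    if not result.success:
        return None, None
    value = result.x[j]
    return float(value), result.x


def oracle_optimum(model: Model, objective_id: str, sense: str = "max") -> float | None:
    """Optimal flux of one reaction by dense LP; None when infeasible."""
    S, lb, ub, rids = _dense_arrays(model)
    value, _ = _solve(S, lb, ub, rids.index(objective_id), sense)
    return value


def oracle_essential_set(model: Model, biomass_id: str,
                         essentiality_fraction: float = 1e-3) -> set[str]:
    """Reactions whose removal drops max biomass below the threshold."""
    S, lb, ub, rids = _dense_arrays(model)
    j_bio = rids.index(biomass_id)
    wild_type, _ = _solve(S, lb, ub, j_bio, "max")
    if wild_type is None or wild_type <= 0:
        raise ValueError("wild-type growth must be positive")
    essential: set[str] = set()
    for j, rid in enumerate(rids):
        lb_j, ub_j = lb[j], ub[j]
        lb[j] = ub[j] = 0.0
        growth, _ = _solve(S, lb, ub, j_bio, "max")
        lb[j], ub[j] = lb_j, ub_j
        if growth is None or growth < essentiality_fraction * wild_type:
            essential.add(rid)
    return essential


def _monotone(values: Sequence[float], rel_tol: float, abs_floor: float) -> bool:
    slack = [max(rel_tol * max(abs(a), abs(b)), abs_floor)
             for a, b in zip(values, values[1:])]
    non_dec = all(b >= a - s for (a, b), s in zip(zip(values, values[1:]), slack))
    non_inc = all(b <= a + s for (a, b), s in zip(zip(values, values[1:]), slack))
    return non_dec or non_inc


def oracle_scan(
    model: Model,
    biomass_id: str,
    target_id: str,
    enforced_values: Sequence[float],
    change_tol: float = 0.01,
    monotonicity_tol: float = 1e-4,
    abs_floor: float = 1e-9,
    zero_tol: float = 1e-6,
) -> dict[str, tuple[str, str]]:
    """Ground-truth classification of every reaction by exhaustive LP.

    At each enforced target level the target's lower bound is raised,
    biomass is maximised, then (with biomass pinned at that optimum)
    each reaction's feasible flux range is computed by min/max LP; the
    reaction is summarised by the range midpoint. Midpoint profiles are
    filtered and classified with the same thresholds as the main scan.

    Returns ``{reaction_id: (reaction_type, proportionality)}`` for
    retained reactions only; reactions with an infeasible step or a
    non-monotone profile are dropped, mirroring the validity filter.

    Midpoints below ``zero_tol`` in magnitude are snapped to zero: the
    biomass-pinning slack (a few 1e-9) otherwise leaks microscopic
    capacity into secretion branches and fabricates trends at the
    tolerance floor.
    """
    S, lb0, ub0, rids = _dense_arrays(model)
    if len(rids) > 20:
        raise ValueError("oracle_scan is restricted to models with <= 20 reactions")
    j_bio = rids.index(biomass_id)
    j_tgt = rids.index(target_id)

    midpoints = np.full((len(rids), len(enforced_values)), np.nan)
    feasible_step = [True] * len(enforced_values)
    for k, enforced in enumerate(enforced_values):
        lb = lb0.copy()
        ub = ub0.copy()
        lb[j_tgt] = max(lb[j_tgt], enforced)
        biomass, _ = _solve(S, lb, ub, j_bio, "max")
        if biomass is None:
            feasible_step[k] = False
            continue
        eps = 1e-9 + 1e-9 * abs(biomass)
        lb_fix, ub_fix = lb.copy(), ub.copy()
        lb_fix[j_bio] = biomass - eps
        ub_fix[j_bio] = biomass + eps
        for j in range(len(rids)):
            lo, _ = _solve(S, lb_fix, ub_fix, j, "min")
            hi, _ = _solve(S, lb_fix, ub_fix, j, "max")
            if lo is None or hi is None:
                continue
            mid = 0.5 * (lo + hi)
            midpoints[j, k] = 0.0 if abs(mid) < zero_tol else mid

    out: dict[str, tuple[str, str]] = {}
    for j, rid in enumerate(rids):
        profile = midpoints[j]
        if not all(feasible_step) or np.isnan(profile).any():
            continue
        magnitudes = [abs(v) for v in profile]
        if not _monotone(magnitudes, monotonicity_tol, abs_floor):
            continue
        delta = magnitudes[-1] - magnitudes[0]
        threshold = max(change_tol * max(magnitudes[-1], magnitudes[0]), abs_floor)
        peak = profile[int(np.argmax(magnitudes))]
        forward = peak >= 0
        if delta > threshold:
            kind = "flux_increasing"
            proportionality = "positive_directly" if forward else "negative_directly"
        elif delta < -threshold:
            kind = "flux_decreasing"
            proportionality = "positive_contra" if forward else "negative_contra"
        else:
            kind, proportionality = "unaffected", "none"
        out[rid] = (kind, proportionality)
    return out
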