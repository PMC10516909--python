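"""Model loading, experimental constraints, and deterministic FBA.

This module wraps constraint-based genome-scale metabolic models
(:class:`cobra.Model`) with the small contract the scanning pipeline
relies on:

* :func:`load_model` / :func:`save_model` — SBML Level 3 (FBC) and
  COBRA-style JSON io with validation, round-trip safe;
* :class:`ConstraintSet` — exchange-flux bounds taken from
  exometabolomics measurements (substrate/O2 uptake, CO2 evolution,
  measured growth rate), applied by :func:`apply_constraints`;
* :func:`optimize` — steady-state flux optimization that, by default,
  resolves alternate optima with a minimal-total-absolute-flux secondary
  objective (parsimonious FBA) so repeated solves return the same flux
  vector.

Units follow the COBRA convention throughout: fluxes in mmol gDW^-1 h^-1
(growth in h^-1), uptake encoded as negative exchange flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import cobra
import yaml
from cobra.flux_analysis import pfba
from cobra.io import (
    load_json_model,
    read_sbml_model,
    save_json_model,
    write_sbml_model,
)
from optlang.interface import OPTIMAL

__all__ = [
    "FEASIBILITY_TOL",
    "COMPARISON_TOL",
    "ConstraintSet",
    "FluxSolution",
    "ModelValidationError",
    "apply_constraints",
    "dcw_from_wcw",
    "load_model",
    "optimize",
    "save_model",
    "validate_model",
]

#: Solver feasibility / optimality tolerance.
FEASIBILITY_TOL: float = 1e-9
#: Tolerance used when comparing reported flux values.
COMPARISON_TOL: float = 1e-6

ModelFormat = Literal["sbml", "json"]


class ModelValidationError(ValueError):
    """A loaded model violates a structural invariant."""


def _infer_format(path: Path, format: str | None) -> ModelFormat:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("sbml", "json"):
            raise ValueError(f"unsupported model format: {format!r}")
        return fmt  # type: ignore[return-value]
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(
        f"cannot infer model format from {path.name!r}; pass format='sbml' or 'json'"
    )


def validate_model(model: cobra.Model) -> None:
    """Check the structural invariants the scan relies on.

    Raises
    ------
    ModelValidationError
        If a reaction references an undeclared metabolite, or any
        reaction has lower_bound > upper_bound.
    """
    declared = set(model.metabolites)
    for reaction in model.reactions:
        for metabolite in reaction.metabolites:
            if metabolite not in declared:
                raise ModelValidationError(
                    f"reaction {reaction.id!r} references undeclared "
                    f"metabolite {metabolite.id!r}"
                )
        if reaction.lower_bound > reaction.upper_bound:
            raise ModelValidationError(
                f"reaction {reaction.id!r} has lower_bound "
                f"{reaction.lower_bound} > upper_bound {reaction.upper_bound}"
            )


def load_model(path: str | Path, format: str | None = None) -> cobra.Model:
    """Load a genome-scale model from SBML (Level 3 + FBC) or COBRA JSON.

    Parameters
    ----------
    path
        Model file. The format is inferred from the suffix
        (``.xml``/``.sbml`` vs ``.json``) unless ``format`` is given.
    format
        ``"sbml"`` or ``"json"``.

    Returns
    -------
    cobra.Model
        Validated model; subsystem and name annotations are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "sbml":
            model = read_sbml_model(str(path))
        else:
            model = load_json_model(str(path))
    except Exception as exc:  # libsbml/json errors carry the offending element
        raise ModelValidationError(f"could not parse {path.name} as {fmt}: {exc}") from exc
    validate_model(model)
    model.solver = "glpk"
    model.tolerance = FEASIBILITY_TOL
    return model


def save_model(model: cobra.Model, path: str | Path, format: str | None = None) -> Path:
    """Write a model to SBML or JSON; round-trips losslessly via load_model."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        write_sbml_model(model, str(path))
    else:
        save_json_model(model, str(path))
    return path


@dataclass
class ConstraintSet:
    """Experimentally measured bounds applied to exchange reactions.

    Attributes
    ----------
    bounds
        Raw signed bounds ``reaction_id -> (lower, upper)`` in
        mmol gDW^-1 h^-1, used verbatim.
    uptake
        Uptake rates given as positive magnitudes (the way rates are
        usually reported from gas/exometabolome analysis):
        ``reaction_id -> (low, high)`` becomes exchange bounds
        ``(-high, -low)`` under the uptake-is-negative convention.
    measured_mu
        Measured specific growth rate in h^-1 (recorded; applied only
        when the caller constrains the biomass reaction with it).
    substrate
        ``"glycerol"`` or ``"methanol"``; selects which of a model's two
        biomass compositions is active when both are present.
    atp_maintenance_override
        Non-growth ATP maintenance flux to impose instead of the value
        found in the model.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    uptake: dict[str, tuple[float, float]] = field(default_factory=dict)
    measured_mu: float | None = None
    substrate: Literal["glycerol", "methanol"] | None = None
    atp_maintenance_override: float | None = None

    def __post_init__(self) -> None:
        for name, table in (("bounds", self.bounds), ("uptake", self.uptake)):
            for rid, (lo, hi) in table.items():
                if lo > hi:
                    raise ValueError(
                        f"{name}[{rid!r}]: lower {lo} exceeds upper {hi}"
                    )

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        """Signed bounds with uptake magnitudes negated (uptake < 0)."""
        resolved = dict(self.bounds)
        for rid, (lo, hi) in self.uptake.items():
            resolved[rid] = (-hi, -lo)
        return resolved

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConstraintSet":
        """Read a constraint configuration from YAML.

        Recognised keys: ``substrate``, ``bounds`` (mapping
        reaction_id -> [lower, upper]), ``uptake`` (positive magnitudes),
        ``measured_mu``, ``atp_maintenance``.
        """
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        as_pairs = lambda m: {k: (float(v[0]), float(v[1])) for k, v in (m or {}).items()}
        return cls(
            bounds=as_pairs(raw.get("bounds")),
            uptake=as_pairs(raw.get("uptake")),
            measured_mu=raw.get("measured_mu"),
            substrate=raw.get("substrate"),
            atp_maintenance_override=raw.get("atp_maintenance"),
        )


def apply_constraints(model: cobra.Model, constraints: ConstraintSet) -> cobra.Model:
    """Return a copy of ``model`` with the constraint bounds installed.

    The original model is left untouched. Unknown reaction ids raise
    ``KeyError``. Bounds that render the model infeasible are accepted
    here and surface as ``status="infeasible"`` at solve time.
    """
    resolved = constraints.resolved_bounds()
    missing = [rid for rid in resolved if rid not in model.reactions]
    if missing:
        raise KeyError(
            f"constraint reaction id(s) not in model: {', '.join(sorted(missing))}"
        )
    constrained = model.copy()
    for rid, (lo, hi) in resolved.items():
        constrained.reactions.get_by_id(rid).bounds = (lo, hi)
    return constrained


@dataclass
class FluxSolution:
    """Outcome of one steady-state optimization.

    ``fluxes`` maps every reaction id to its signed flux when
    ``status == "optimal"`` and is empty otherwise.
    """

    status: Literal["optimal", "infeasible", "unbounded"]
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _map_status(status: str) -> str:
    if status == OPTIMAL:
        return "optimal"
    if "unbounded" in status:
        return "unbounded"
    return "infeasible"


def optimize(
    model: cobra.Model,
    objective_reaction: str,
    sense: Literal["max", "min"] = "max",
    deterministic: bool = True,
) -> FluxSolution:
    """Maximise (or minimise) one reaction's flux by FBA.

    With ``deterministic=True`` (default) the optimum is re-solved with
    a minimal-total-absolute-flux secondary objective (pFBA), so the
    returned flux vector is reproducible across calls even when the LP
    optimum is degenerate. ``deterministic=False`` returns the raw
    solver vertex.
    """
    if objective_reaction not in model.reactions:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    direction = {"max": "max", "min": "min"}[sense]
    with model:
        model.objective = objective_reaction
        model.objective_direction = direction
        value = model.slim_optimize(error_value=math.nan)
        status = _map_status(model.solver.status)
        if status != "optimal" or not math.isfinite(value):
            if math.isinf(value):
                status = "unbounded"
            elif status == "optimal":
                status = "infeasible"
            return FluxSolution(status=status, objective_value=math.nan)
        if deterministic:
            solution = pfba(model)
        else:
            solution = model.optimize()
        fluxes = {rid: float(v) for rid, v in solution.fluxes.items()}
    return FluxSolution(status="optimal", objective_value=float(value), fluxes=fluxes)


def check_mass_balance(
    model: cobra.Model, fluxes: Mapping[str, float], tol: float = COMPARISON_TOL
) -> float:
    """Max absolute metabolite imbalance |S.v| of a flux vector."""
    worst = 0.0
    accum: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for reaction in model.reactions:
        v = fluxes.get(reaction.id, 0.0)
        for metabolite, coefficient in reaction.metabolites.items():
            accum[metabolite.id] += coefficient * v
    for imbalance in accum.values():
        worst = max(worst, abs(imbalance))
    return worst


def dcw_from_wcw(wcw: float) -> float:
    """Dry cell weight from wet cell weight (g L^-1): DCW = 0.3 * WCW."""
    if wcw < 0:
        raise ValueError(f"wet cell weight must be non-negative, got {wcw}")
    return 0.3 * wcw


def find_atp_maintenance(model: cobra.Model) -> cobra.Reaction | None:
    """Locate the non-growth ATP maintenance pseudo-reaction, if any.

    Matches common identifiers (ATPM, NGAM) or a name containing
    "maintenance"; returns None when the model carries no such reaction.
    """
    for candidate in ("ATPM", "NGAM", "ATPM_c", "R_ATPM"):
        if candidate in model.reactions:
            return model.reactions.get_by_id(candidate)
    for reaction in model.reactions:
        name = (reaction.name or "").lower()
        if "maintenance" in name or reaction.id.lower().startswith("atpm"):
            return reaction
    return None
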