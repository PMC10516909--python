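"""Single-reaction-deletion essentiality screening.

Deleting a reaction proposed for downregulation can be lethal; only
non-essential reactions are usable as deletion targets. A reaction is
*essential* when zeroing its bounds drops the maximal biomass flux
below a small fraction of the wild-type optimum (default 0.1%, just
above solver noise — the point is to distinguish "still grows" from
"numerically zero growth", not to impose a fitness cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import cobra

from .model_core import optimize

__all__ = [
    "DEFAULT_ESSENTIALITY_FRACTION",
    "EssentialityRecord",
    "delete_and_grow",
    "filter_nonessential",
    "screen_essentiality",
]

DEFAULT_ESSENTIALITY_FRACTION = 1e-3


@dataclass(frozen=True)
class EssentialityRecord:
    """Growth outcome of deleting one reaction."""

    reaction_id: str
    growth_after_deletion: float
    wild_type_growth: float
    essential: bool


def delete_and_grow(model: cobra.Model, reaction_id: str, biomass_id: str) -> float:
    """Max biomass flux with ``reaction_id`` knocked out (bounds 0, 0).

    Returns 0.0 when the deletion makes the model infeasible; the model
    is restored afterwards.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"reaction {reaction_id!r} not in model")
    with model:
        model.reactions.get_by_id(reaction_id).bounds = (0.0, 0.0)
        # objective value only; no need for the deterministic flux vector
        solution = optimize(model, biomass_id, "max", deterministic=False)
    return solution.objective_value if solution.ok else 0.0


def screen_essentiality(
    model: cobra.Model,
    candidate_ids: Sequence[str] | None,
    biomass_id: str,
    essentiality_fraction: float = DEFAULT_ESSENTIALITY_FRACTION,
) -> list[EssentialityRecord]:
    """Deletion-screen the candidates (or every reaction when None).

    Records are returned in the input order. Raises when wild-type
    growth is not positive — essentiality is undefined for a
    non-growing model.
    """
    wild_type = optimize(model, biomass_id, "max", deterministic=False)
    if not wild_type.ok or wild_type.objective_value <= 0:
        raise RuntimeError(
            "essentiality screen requires positive wild-type growth "
            f"(status={wild_type.status})"
        )
    reference = wild_type.objective_value
    if candidate_ids is None:
        candidate_ids = [r.id for r in model.reactions]
    records = []
    for rid in candidate_ids:
        growth = delete_and_grow(model, rid, biomass_id)
        records.append(
            EssentialityRecord(
                reaction_id=rid,
                growth_after_deletion=growth,
                wild_type_growth=reference,
                essential=growth < essentiality_fraction * reference,
            )
        )
    return records


def filter_nonessential(
    records: Iterable[EssentialityRecord], downregulation_list: Sequence[str]
) -> list[str]:
    """Drop essential ids from a ranked downregulation list, keeping order."""
    by_id = {r.reaction_id: r for r in records}
    missing = [rid for rid in downregulation_list if rid not in by_id]
    if missing:
        raise KeyError(f"no essentiality record for: {', '.join(missing)}")
    return [rid for rid in downregulation_list if not by_id[rid].essential]
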