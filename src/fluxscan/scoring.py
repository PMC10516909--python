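"""Step-weighted-factor scoring and candidate ranking.

The step-weighted factor (SWF) summarises how strongly a reaction's
flux profile moves across the enforced-target steps, relative to its
own mean — the stronger the relative movement, the more the reaction is
coupled to production and the better a regulation candidate it is.

Two variants are exposed:

* ``deviation`` (default): SWF = Σ_k |v_k − mean| / |mean| · 100%, the
  summed absolute percent deviation from the profile mean. Zero for a
  constant profile, invariant under profile scaling, and grows with
  coupling strength.
* ``literal``: SWF = Σ_k v_k / mean · 100%, which is algebraically
  identical to 100·n whenever the mean is the profile's arithmetic mean
  and therefore cannot discriminate candidates; it is retained for
  comparison only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .scan import ClassificationRecord

__all__ = ["SWFRecord", "UndefinedScoreError", "rank_candidates", "step_weighted_factor"]

logger = logging.getLogger(__name__)

SWFVariant = Literal["deviation", "literal"]

#: A profile mean closer to zero than this has no meaningful relative scale.
_MEAN_TOL = 1e-12


class UndefinedScoreError(ValueError):
    """The profile mean is zero, so a relative score is undefined."""


@dataclass(frozen=True)
class SWFRecord:
    """Step-weighted-factor score for one reaction."""

    reaction_id: str
    swf_percent: float
    variant: SWFVariant
    profile_mean: float


def step_weighted_factor(
    profile: Sequence[float],
    variant: SWFVariant = "deviation",
    reaction_id: str = "",
) -> SWFRecord:
    """Score one flux profile.

    Parameters
    ----------
    profile
        The reaction's flux values across the scan steps (typically 5).
    variant
        ``"deviation"`` (default) or ``"literal"`` — see module docstring.

    Raises
    ------
    UndefinedScoreError
        When the profile mean is zero; such reactions are excluded from
        ranking and logged by the caller.
    """
    values = [float(v) for v in profile]
    if not values or any(v != v or abs(v) == float("inf") for v in values):
        raise ValueError("profile must contain finite values")
    mean = sum(values) / len(values)
    if abs(mean) < _MEAN_TOL:
        raise UndefinedScoreError(
            f"profile mean is zero for reaction {reaction_id or '<unnamed>'}"
        )
    if variant == "deviation":
        score = sum(abs(v - mean) for v in values) / abs(mean) * 100.0
    elif variant == "literal":
        score = sum(v / mean for v in values) * 100.0
    else:
        raise ValueError(f"unknown SWF variant: {variant!r}")
    return SWFRecord(reaction_id=reaction_id, swf_percent=score,
                     variant=variant, profile_mean=mean)


def score_profiles(
    profiles: Mapping[str, Sequence[float]], variant: SWFVariant = "deviation"
) -> dict[str, SWFRecord]:
    """Score many profiles, logging and skipping zero-mean ones."""
    records: dict[str, SWFRecord] = {}
    for rid, profile in profiles.items():
        try:
            records[rid] = step_weighted_factor(profile, variant=variant, reaction_id=rid)
        except UndefinedScoreError:
            logger.info("excluding %s from ranking: zero-mean profile", rid)
    return records


def rank_candidates(
    classifications: Iterable[ClassificationRecord],
    swf_records: Mapping[str, SWFRecord],
    direction: Literal["upregulation", "downregulation"],
) -> list[str]:
    """Rank candidates of one direction by SWF, largest first.

    Upregulation candidates are the flux-increasing reactions,
    downregulation/deletion candidates the flux-decreasing ones
    (essentiality filtering is applied downstream). Ties are broken
    lexicographically by reaction id; reactions without a score
    (zero-mean profiles) are excluded.
    """
    wanted = {"upregulation": "flux_increasing", "downregulation": "flux_decreasing"}[direction]
    pool = [c.reaction_id for c in classifications if c.reaction_type == wanted]
    scored = [rid for rid in pool if rid in swf_records]
    return sorted(scored, key=lambda rid: (-swf_records[rid].swf_percent, rid))
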