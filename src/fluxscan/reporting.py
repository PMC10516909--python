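"""Report assembly: supplementary-style tables, partitions, summaries.

Canonical output is CSV (UTF-8, "." decimal, header row) for
diff-ability; an XLSX workbook mirroring the supplementary sheet layout
can be written alongside. Run metadata (model id, constraint digest,
schedule, tolerances, variant flags, timestamp) goes to a YAML sidecar
so the CSVs themselves are byte-identical across re-runs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .essentiality import EssentialityRecord
from .scan import ClassificationRecord, ScanProfile, ScanTable
from .scoring import SWFRecord

__all__ = [
    "PARTITION_NAMES",
    "ReportBundle",
    "build_report",
    "fraction_of_total",
    "partition_proportionality",
    "summarize_subsystems",
    "write_essentiality_csv",
    "write_report",
]

#: Canonical names of the four proportionality tables.
PARTITION_NAMES = (
    "Positive_directly_proportional",
    "Positive_contra_proportional",
    "Negative_directly_proportional",
    "Negative_contra_proportional",
)

_PROPORTIONALITY_TO_NAME = {
    "positive_directly": "Positive_directly_proportional",
    "positive_contra": "Positive_contra_proportional",
    "negative_directly": "Negative_directly_proportional",
    "negative_contra": "Negative_contra_proportional",
}


def fraction_of_total(count: int, total: int) -> float:
    """Percentage of ``count`` in ``total``, rounded to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def partition_proportionality(
    classifications: Iterable[ClassificationRecord],
) -> dict[str, list[str]]:
    """Split classified reactions into the four proportionality tables.

    "Positive"/"Negative" records whether the flux runs left-to-right or
    right-to-left as the reaction is written; "directly"/"contra" whether
    |flux| rises or falls with the enforced production. Unaffected
    reactions appear in no partition.
    """
    out: dict[str, list[str]] = {name: [] for name in PARTITION_NAMES}
    for record in classifications:
        name = _PROPORTIONALITY_TO_NAME.get(record.proportionality)
        if name is not None:
            out[name].append(record.reaction_id)
    return out


def summarize_subsystems(
    records: Iterable[ScanProfile], scope: str = "downregulation"
) -> pd.DataFrame:
    """Count candidate reactions per subsystem with percentage of scope total.

    Records lacking a subsystem annotation are bucketed as
    "unannotated". Fractions sum to 100% within rounding.
    """
    subsystems = [(r.subsystem or "unannotated") for r in records]
    if not subsystems:
        return pd.DataFrame(columns=["Subsystem", "Count", "Fraction_percent"])
    counts = pd.Series(subsystems).value_counts().sort_values(ascending=False)
    total = int(counts.sum())
    frame = pd.DataFrame(
        {
            "Subsystem": counts.index,
            "Count": counts.values,
            "Fraction_percent": [fraction_of_total(int(c), total) for c in counts.values],
        }
    )
    frame.attrs["scope"] = scope
    return frame.sort_values(["Count", "Subsystem"], ascending=[False, True],
                             kind="stable").reset_index(drop=True)


@dataclass
class ReportBundle:
    """Everything one scan run produces, ready for serialization."""

    scan_frame: pd.DataFrame
    partitions: dict[str, pd.DataFrame]
    upregulation: pd.DataFrame
    downregulation: pd.DataFrame
    subsystem_summaries: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    @property
    def upregulation_ids(self) -> list[str]:
        return list(self.upregulation["Reactions_ID"])

    @property
    def surviving_downregulation_ids(self) -> list[str]:
        frame = self.downregulation
        return list(frame.loc[~frame["Essential"], "Reactions_ID"])


def build_report(
    table: ScanTable,
    classifications: Sequence[ClassificationRecord],
    swf_records: Mapping[str, SWFRecord],
    upregulation_ranked: Sequence[str],
    downregulation_ranked: Sequence[str],
    essentiality_records: Sequence[EssentialityRecord],
    metadata: Mapping | None = None,
) -> ReportBundle:
    """Assemble the report tables from the pipeline's intermediate results."""
    scan_frame = table.to_frame()
    by_id = scan_frame.set_index("Reactions_ID", drop=False)

    partition_ids = partition_proportionality(classifications)
    partitions = {
        name: by_id.loc[by_id.index.intersection(ids)].reset_index(drop=True)
        if ids else scan_frame.iloc[0:0].copy()
        for name, ids in partition_ids.items()
    }

    def _swf_columns(ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Reactions_ID": list(ids),
                "SWF_percent": [swf_records[r].swf_percent for r in ids],
                "SWF_variant": [swf_records[r].variant for r in ids],
            }
        )

    upregulation = _swf_columns(upregulation_ranked)

    essential_by_id = {r.reaction_id: r for r in essentiality_records}
    downregulation = _swf_columns(downregulation_ranked)
    downregulation["Essential"] = [
        essential_by_id[r].essential for r in downregulation_ranked
    ]
    downregulation["Growth_after_deletion"] = [
        essential_by_id[r].growth_after_deletion for r in downregulation_ranked
    ]

    profile_by_id = {p.reaction_id: p for p in table.profiles}
    summaries = {
        scope: summarize_subsystems(
            [profile_by_id[r] for r in ids if r in profile_by_id], scope=scope
        )
        for scope, ids in (
            ("upregulation", upregulation_ranked),
            ("downregulation", downregulation_ranked),
        )
    }

    meta = dict(metadata or {})
    meta.setdefault("schedule", {
        "enforced_values": list(table.schedule.enforced_values),
        "n_steps": table.schedule.n_steps,
        "cap_fraction": table.schedule.cap_fraction,
    })
    meta.setdefault("init", {
        "atp_maintenance_floor": table.init.atp_maintenance_floor,
        "biomass_min": table.init.biomass_min,
        "biomass_max": table.init.biomass_max,
        "target_max": table.init.target_max,
    })
    meta.setdefault("biomass_per_step", list(table.biomass_per_step))
    return ReportBundle(
        scan_frame=scan_frame,
        partitions=partitions,
        upregulation=upregulation,
        downregulation=downregulation,
        subsystem_summaries=summaries,
        metadata=meta,
    )


def constraints_digest(bounds: Mapping[str, tuple[float, float]]) -> str:
    """Stable short digest of a resolved bound set, for run metadata."""
    canonical = ";".join(f"{rid}:{lo!r}:{hi!r}" for rid, (lo, hi) in sorted(bounds.items()))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_report(
    bundle: ReportBundle, out_dir: str | Path, formats: Sequence[str] = ("csv",)
) -> list[Path]:
    """Write the report to ``out_dir``; returns the paths written.

    CSV output is seven tables: the scan table, the four proportionality
    partitions, and the ranked upregulation / downregulation candidate
    tables. With ``"xlsx"`` in ``formats`` a single workbook mirrors the
    supplementary layout (one sheet per table, plus the subsystem
    summaries). Metadata goes to ``metadata.yaml`` — the only file
    carrying a timestamp, so the data files are reproducible
    byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables: dict[str, pd.DataFrame] = {"scan_table": bundle.scan_frame}
    for name in PARTITION_NAMES:
        tables[name] = bundle.partitions[name]
    tables["upregulation"] = bundle.upregulation
    tables["downregulation"] = bundle.downregulation

    if "csv" in formats:
        for name, frame in tables.items():
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
    if "xlsx" in formats:
        path = out_dir / "growth_coupled_report.xlsx"
        with pd.ExcelWriter(path, engine="openpyxl") as workbook:
            for name, frame in tables.items():
                frame.to_excel(workbook, sheet_name=name[:31], index=False)
            for scope, frame in bundle.subsystem_summaries.items():
                if not frame.empty:
                    frame.to_excel(workbook, sheet_name=f"subsystems_{scope}"[:31],
                                   index=False)
        written.append(path)

    meta = dict(bundle.metadata)
    meta["written_at"] = datetime.now(timezone.utc).isoformat()
    sidecar = out_dir / "metadata.yaml"
    with open(sidecar, "w") as handle:
        yaml.safe_dump(meta, handle, sort_keys=True)
    written.append(sidecar)
    return written


def write_essentiality_csv(
    records: Sequence[EssentialityRecord], path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "reaction_id": [r.reaction_id for r in records],
            "growth_after_deletion": [r.growth_after_deletion for r in records],
            "wild_type_growth": [r.wild_type_growth for r in records],
            "essential": [r.essential for r in records],
        }
    ).to_csv(path, index=False)
    return path
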