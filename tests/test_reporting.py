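"""Report tables: partitions, subsystem summaries, serialization."""

import pandas as pd
import pytest

import fluxscan as fs
from fluxscan.reporting import (
    PARTITION_NAMES,
    build_report,
    fraction_of_total,
    partition_proportionality,
    summarize_subsystems,
    write_essentiality_csv,
)
from fluxscan.scan import ScanProfile

from conftest import FIXTURE_SEEDS


def _profile(rid, subsystem=""):
    return ScanProfile(reaction_id=rid, reaction_name=rid, subsystem=subsystem,
                       stoichiometry_text="", flux_values=[1, 2, 3, 4, 5],
                       all_feasible=True)


class TestPartitionProportionality:
    def test_toy1_partition_assignment(self, toy1_pipeline):
        partitions = partition_proportionality(toy1_pipeline["classifications"])
        assert partitions["Positive_contra_proportional"] == ["R2"]
        assert sorted(partitions["Positive_directly_proportional"]) == ["EX_P", "R3"]
        # unaffected reactions appear in no partition
        assert "EX_A" not in sum(partitions.values(), [])

    def test_partitions_disjoint_and_cover_affected(self, fixture_scans):
        for seed in FIXTURE_SEEDS:
            classified = fixture_scans[seed]["classified"]
            records = [
                fs.ClassificationRecord(rid, kind, prop)
                for rid, (kind, prop) in classified.items()
            ]
            partitions = partition_proportionality(records)
            pooled = sum(partitions.values(), [])
            assert len(pooled) == len(set(pooled))
            affected = {rid for rid, (kind, _) in classified.items()
                        if kind != "unaffected"}
            assert set(pooled) == affected


class TestSummarizeSubsystems:
    def test_amino_acid_share_of_downregulation_candidates(self):
        # 26 amino-acid reactions among 66 candidates -> about 39.4%
        records = [_profile(f"AA{i}", "Amino acid metabolism") for i in range(26)]
        records += [_profile(f"O{i}", "Other") for i in range(40)]
        table = summarize_subsystems(records, scope="downregulation")
        amino = table.loc[table["Subsystem"] == "Amino acid metabolism"].iloc[0]
        assert amino["Count"] == 26
        assert amino["Fraction_percent"] == pytest.approx(39.39, abs=0.01)
        assert table["Fraction_percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_single_record_is_100_percent(self):
        table = summarize_subsystems([_profile("X", "Glycolysis")])
        assert list(table["Fraction_percent"]) == [100.0]

    def test_empty_scope_gives_empty_table(self):
        assert summarize_subsystems([]).empty

    def test_missing_subsystem_bucketed_as_unannotated(self):
        table = summarize_subsystems([_profile("X")])
        assert list(table["Subsystem"]) == ["unannotated"]


def test_fraction_of_total_candidate_share():
    # 33 upregulation candidates among 2243 model reactions
    assert fraction_of_total(33, 2243) == 1.47
    assert fraction_of_total(26, 66) == pytest.approx(39.39)
    with pytest.raises(ValueError):
        fraction_of_total(1, 0)


@pytest.fixture(scope="module")
def toy1_bundle(toy1_pipeline):
    return build_report(
        toy1_pipeline["filtered"],
        toy1_pipeline["classifications"],
        toy1_pipeline["swf"],
        toy1_pipeline["upregulation"],
        toy1_pipeline["downregulation"],
        toy1_pipeline["essentiality"],
        metadata={"model_id": "TOY1"},
    )


class TestWriteReport:
    EXPECTED_CSVS = ["scan_table"] + list(PARTITION_NAMES) + [
        "upregulation", "downregulation"]

    def test_csv_report_writes_seven_tables(self, toy1_bundle, tmp_path):
        paths = fs.write_report(toy1_bundle, tmp_path)
        csvs = [p for p in paths if p.suffix == ".csv"]
        assert sorted(p.stem for p in csvs) == sorted(self.EXPECTED_CSVS)
        assert (tmp_path / "metadata.yaml").exists()

    def test_scan_table_header_matches_supplementary_layout(self, toy1_bundle, tmp_path):
        fs.write_report(toy1_bundle, tmp_path)
        header = (tmp_path / "scan_table.csv").read_text().splitlines()[0]
        assert header == ("Reactions_ID,Reactions_name,FBA_results_1,FBA_results_2,"
                          "FBA_results_3,FBA_results_4,FBA_results_5,Subsystem,Var10")

    def test_csv_read_back_reproduces_values(self, toy1_bundle, tmp_path):
        fs.write_report(toy1_bundle, tmp_path)
        back = pd.read_csv(tmp_path / "scan_table.csv", keep_default_na=False)
        expected = toy1_bundle.scan_frame
        assert list(back.columns) == list(expected.columns)
        flux_cols = [c for c in back.columns if c.startswith("FBA_results_")]
        assert back[flux_cols].to_numpy() == pytest.approx(
            expected[flux_cols].to_numpy()
        )
        assert list(back["Reactions_ID"]) == list(expected["Reactions_ID"])

    def test_repeated_writes_are_byte_identical(self, toy1_bundle, tmp_path):
        first = tmp_path / "a"
        second = tmp_path / "b"
        fs.write_report(toy1_bundle, first)
        fs.write_report(toy1_bundle, second)
        for name in self.EXPECTED_CSVS:
            assert (first / f"{name}.csv").read_bytes() == (
                second / f"{name}.csv").read_bytes()

    def test_xlsx_workbook_has_expected_sheets(self, toy1_bundle, tmp_path):
        from openpyxl import load_workbook

        fs.write_report(toy1_bundle, tmp_path, formats=("xlsx",))
        workbook = load_workbook(tmp_path / "growth_coupled_report.xlsx")
        assert len(workbook.sheetnames) >= 6
        assert "scan_table" in workbook.sheetnames

    def test_bundle_candidate_views(self, toy1_bundle):
        assert toy1_bundle.upregulation_ids == ["EX_P", "R3"]
        # R2 is essential, so no downregulation candidate survives
        assert toy1_bundle.surviving_downregulation_ids == []


def test_essentiality_csv_layout(toy1_pipeline, tmp_path):
    path = write_essentiality_csv(toy1_pipeline["essentiality"],
                                  tmp_path / "essentiality.csv")
    frame = pd.read_csv(path)
    assert list(frame.columns) == [
        "reaction_id", "growth_after_deletion", "wild_type_growth", "essential"]
    assert len(frame) == 6
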