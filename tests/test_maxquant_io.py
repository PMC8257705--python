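"""MaxQuant dialect parsing, flag filtering and auxiliary input readers."""

from __future__ import annotations

import csv
import math
import random

import pytest

from slicesilac import (
    MaxQuantFormatError,
    ProteinGroupRecord,
    SliceQuant,
    read_cleavage_sites,
    read_contaminant_list,
    read_fasta,
    read_peptides,
    read_protein_groups,
    remove_flagged,
    write_protein_groups,
)
from .conftest import write_protein_groups_text


class TestReadProteinGroups:
    def test_minimal_two_row_table(self, tmp_path):
        path = write_protein_groups_text(
            tmp_path / "pg.txt",
            [
                {"ids": "P1;P2", "gene": "GENE1", "mass": "120.5",
                 "ratio": {1: "2.0", 3: "0.5"}, "count": {1: "3", 3: "2"}},
                {"ids": "Q9", "mass": "55", "ratio": {2: "1.5"}, "count": {2: "4"}},
            ],
        )
        records = read_protein_groups(path)
        assert len(records) == 2
        first, second = records
        assert first.group_id == "P1"
        assert first.all_ids == ["P1", "P2"]
        assert first.gene_name == "GENE1"
        assert first.theoretical_mass == 120.5
        assert sorted(first.per_slice) == [1, 3]
        assert first.per_slice[1].ratio_hl == 2.0
        assert first.per_slice[1].ratio_count == 3
        assert second.quantified_slices == [2]
        assert len(second.per_slice) <= 3

    def test_contaminant_flag_parsed(self, tmp_path):
        path = write_protein_groups_text(
            tmp_path / "pg.txt",
            [{"ids": "KRT1", "contaminant": "+", "ratio": {1: "1.0"},
              "count": {1: "2"}}],
        )
        (rec,) = read_protein_groups(path)
        assert rec.is_contaminant and not rec.is_reverse

    def test_empty_ratio_with_zero_count_is_absent_not_zero(self, tmp_path):
        path = write_protein_groups_text(
            tmp_path / "pg.txt",
            [{"ids": "P1", "ratio": {2: "3.0"}, "count": {1: "0", 2: "2"}}],
        )
        (rec,) = read_protein_groups(path)
        assert 1 not in rec.per_slice  # absence of quantification, never ratio 0
        assert rec.per_slice[2].ratio_hl == 3.0

    def test_agrees_with_manual_cell_by_cell_parse(self, tmp_path):
        rows = [
            {"ids": "P1", "ratio": {1: "1.25", 2: "0.8125"},
             "count": {1: "2", 2: "5"}, "ih": {1: "1000.5"}, "il": {1: "800.25"}},
            {"ids": "P2", "ratio": {3: "4.5"}, "count": {3: "1"}},
        ]
        path = write_protein_groups_text(tmp_path / "pg.txt", rows)
        records = read_protein_groups(path)

        with open(path) as fh:
            table = list(csv.DictReader(fh, delimiter="\t"))
        for rec, raw in zip(records, table):
            for s in (1, 2, 3):
                cell = raw[f"Ratio H/L {s}"]
                if cell == "":
                    assert (
                        s not in rec.per_slice
                        or rec.per_slice[s].ratio_hl is None
                    )
                else:
                    assert rec.per_slice[s].ratio_hl == float(cell)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "pg.txt"
        path.write_text("Majority protein IDs\tRatio H/L 1\nP1\t2.0\n")
        with pytest.raises(MaxQuantFormatError, match="Mol. weight"):
            read_protein_groups(path)

    def test_unparseable_slice_labels_are_reported(self, tmp_path):
        path = tmp_path / "pg.txt"
        path.write_text(
            "Majority protein IDs\tMol. weight [kDa]\tRatio H/L A\nP1\t100\t2.0\n"
        )
        with pytest.raises(MaxQuantFormatError, match="Ratio H/L A"):
            read_protein_groups(path)

    def test_non_positive_ratio_is_hard_error_with_row_id(self, tmp_path):
        path = write_protein_groups_text(
            tmp_path / "pg.txt",
            [{"ids": "BAD1", "ratio": {1: "-2.0"}, "count": {1: "2"}}],
        )
        with pytest.raises(MaxQuantFormatError, match="BAD1"):
            read_protein_groups(path)

    def test_round_trip_is_lossless_for_ratios(self, tmp_path):
        rng = random.Random(0)
        records = [
            ProteinGroupRecord(
                group_id=f"P{i}",
                all_ids=[f"P{i}"],
                gene_name=f"G{i}",
                theoretical_mass=rng.uniform(10, 300),
                per_slice={
                    s: SliceQuant(
                        ratio_hl=math.exp(rng.uniform(-3, 3)),
                        ratio_count=rng.randint(1, 9),
                        intensity_h=rng.uniform(1e4, 1e8),
                        intensity_l=rng.uniform(1e4, 1e8),
                    )
                    for s in rng.sample(range(1, 47), 4)
                },
            )
            for i in range(20)
        ]
        path = tmp_path / "pg.txt"
        write_protein_groups(records, path, n_slices=46)
        back = read_protein_groups(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.theoretical_mass == b.theoretical_mass
            assert set(a.per_slice) == set(b.per_slice)
            for s in a.per_slice:
                assert a.per_slice[s].ratio_hl == b.per_slice[s].ratio_hl  # bit-exact
                assert a.per_slice[s].ratio_count == b.per_slice[s].ratio_count


class TestRemoveFlagged:
    def _records(self):
        def rec(gid, contaminant=False, reverse=False, ids=None):
            return ProteinGroupRecord(
                group_id=gid, all_ids=ids or [gid], gene_name="",
                theoretical_mass=50.0,
                per_slice={1: SliceQuant(ratio_hl=1.0, ratio_count=2)},
                is_contaminant=contaminant, is_reverse=reverse,
            )
        return [rec("A"), rec("B", contaminant=True), rec("C", ids=["C", "C2"])]

    def test_drops_flagged(self):
        out = remove_flagged(self._records())
        assert [r.group_id for r in out] == ["A", "C"]

    def test_extra_list_matches_any_majority_id(self):
        out = remove_flagged(self._records(), extra_contaminants=["C2"])
        assert [r.group_id for r in out] == ["A"]

    def test_identity_without_flags_or_list(self):
        records = [r for r in self._records() if not r.is_contaminant]
        assert remove_flagged(records) == records

    def test_idempotent_and_order_equivariant(self):
        records = self._records()
        once = remove_flagged(records, ["C2"])
        assert remove_flagged(once, ["C2"]) == once
        shuffled = [records[2], records[0], records[1]]
        out = remove_flagged(shuffled, ["C2"])
        assert {r.group_id for r in out} == {r.group_id for r in once}
        # relative order of survivors is preserved
        assert [r.group_id for r in out] == ["A"]


class TestAuxiliaryReaders:
    def test_cleavage_site_line(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("P09874\t214\tDEVD\tcaspase\n")
        (rec,) = read_cleavage_sites(path)
        assert rec.accession == "P09874"
        assert rec.p1_position == 214
        assert rec.motif == "DEVD"

    def test_duplicate_sites_collapse(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("P09874\t214\tDEVD\tcaspase\nP09874\t214\tDEVD\tother\n")
        records = read_cleavage_sites(path)
        assert len(records) == 1

    def test_zero_position_is_error_with_line_number(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("P1\t214\tDEVD\tx\nP2\t0\tDEVD\tx\n")
        with pytest.raises(MaxQuantFormatError, match="line 2"):
            read_cleavage_sites(path)

    def test_contaminant_list_with_comments(self, tmp_path):
        path = tmp_path / "contaminants.txt"
        path.write_text("# keratins\nP04264\nP35908  # another\n\n")
        assert read_contaminant_list(path) == ["P04264", "P35908"]

    def test_fasta_uniprot_style_keys(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        path.write_text(">sp|P12345|TEST_HUMAN test\nMKWVTFISLLG\n>plain\nGGG\n")
        seqs = read_fasta(path)
        assert seqs["P12345"] == "MKWVTFISLLG"
        assert seqs["plain"] == "GGG"

    def test_peptides_reader_extracts_slice_ratios(self, tmp_path):
        path = tmp_path / "peptides.txt"
        path.write_text(
            "Sequence\tProteins\tStart position\tEnd position\t"
            "Ratio H/L 1\tRatio H/L 2\n"
            "PEPTIDEK\tP1\t10\t17\t2.0\t\n"
        )
        df = read_peptides(path)
        assert list(df["sequence"]) == ["PEPTIDEK"]
        assert df.loc[0, "start_position"] == 10
        assert df.loc[0, "ratio_1"] == 2.0
        assert math.isnan(df.loc[0, "ratio_2"])
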