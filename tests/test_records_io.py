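"""Record schemas, CSV ingestion, taxonomy pooling and table writing."""

import csv

import pytest

from owlpellets import (
    ElementRecord,
    TaxonomyMap,
    ValidationError,
    apply_taxonomy,
)
from owlpellets.io import (
    RowError,
    SchemaError,
    read_abundance_table,
    read_element_records,
    write_element_records,
    write_table,
)
from owlpellets.taxonomy import HISTORIC_PROFILE


def _write_csv(path, rows, header="collection_id,pellet_id,taxon,age_class,element,count"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")


class TestElementRecords:
    def test_single_row_round_trip(self, tmp_path):
        f = tmp_path / "e.csv"
        _write_csv(f, ["c1,p1,Sminthopsis douglasi,adult,left_mandible,2"])
        records, meta, errors = read_element_records(f)
        assert errors == []
        assert records == [
            ElementRecord("c1", "p1", "Sminthopsis douglasi", "adult", "left_mandible", 2)
        ]
        assert meta["c1"].n_pellets_total == 1

    def test_negative_count_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "e.csv"
        _write_csv(
            f,
            [
                "c1,p1,Sminthopsis douglasi,adult,left_mandible,2",
                "c1,p2,Planigale spp.,unknown,left_mandible,-1",
            ],
        )
        records, _, errors = read_element_records(f)
        assert len(records) == 1
        assert errors == [RowError(3, errors[0].message)]
        assert "non-negative" in errors[0].message or "-1" in errors[0].message

    def test_non_integer_count_and_bad_vocab_rejected(self, tmp_path):
        f = tmp_path / "e.csv"
        _write_csv(
            f,
            [
                "c1,p1,Planigale spp.,unknown,left_mandible,1.5",
                "c1,p2,Planigale spp.,adolescent,left_mandible,1",
                "c1,p3,Planigale spp.,adult,femur,1",
            ],
        )
        records, _, errors = read_element_records(f)
        assert records == []
        assert [e.line for e in errors] == [2, 3, 4]

    def test_duplicate_key_rejected(self, tmp_path):
        f = tmp_path / "e.csv"
        row = "c1,p1,Planigale spp.,unknown,left_mandible,1"
        _write_csv(f, [row, row])
        records, _, errors = read_element_records(f)
        assert len(records) == 1 and len(errors) == 1
        with pytest.raises(ValidationError):
            read_element_records(f, strict=True)

    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "e.csv"
        f.write_text("collection_id,pellet_id,taxon,age_class,element\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="count"):
            read_element_records(f)

    def test_schema_remaps_third_party_column_names(self, tmp_path):
        f = tmp_path / "e.csv"
        _write_csv(
            f,
            ["c1,p1,Planigale spp.,unknown,left_mandible,3"],
            header="site,pellet,species,age,part,n",
        )
        records, _, _ = read_element_records(
            f,
            schema={
                "collection_id": "site", "pellet_id": "pellet", "taxon": "species",
                "age_class": "age", "element": "part", "count": "n",
            },
        )
        assert records[0].count == 3

    def test_write_read_round_trip(self, tmp_path):
        records = [
            ElementRecord("c1", "p1", "Rattus villosissimus", "adult", "left_mandible", 2),
            ElementRecord("c1", "p1", "Rattus villosissimus", "adult", "skull", 1),
            ElementRecord("c1", "p2", "unidentifiable", "unknown", "unidentifiable_postcranial", 1),
        ]
        f = tmp_path / "rt.csv"
        write_element_records(records, f)
        back, _, errors = read_element_records(f)
        assert back == records and errors == []


class TestTaxonomy:
    def test_historic_profile_pools_birds_into_aves(self):
        records = [
            ElementRecord("c1", "p1", "Taeniopygia sp.", "unknown", "left_mandible", 3),
            ElementRecord("c1", "p1", "Mirafra javanica", "unknown", "left_mandible", 1),
        ]
        pooled = apply_taxonomy(records, HISTORIC_PROFILE)
        assert pooled == [
            ElementRecord("c1", "p1", "Aves spp.", "unknown", "left_mandible", 4)
        ]

    def test_identity_map_is_noop(self):
        records = [
            ElementRecord("c1", "p1", "Sminthopsis douglasi", "adult", "skull", 1)
        ]
        assert apply_taxonomy(records, TaxonomyMap("identity")) == records

    def test_applying_twice_equals_once(self):
        records = [
            ElementRecord("c1", "p1", "Taeniopygia sp.", "unknown", "left_mandible", 2),
            ElementRecord("c1", "p2", "Gekkonidae", "unknown", "skull", 1),
            ElementRecord("c1", "p2", "Sminthopsis douglasi", "adult", "left_mandible", 1),
        ]
        once = apply_taxonomy(records, HISTORIC_PROFILE)
        assert apply_taxonomy(once, HISTORIC_PROFILE) == once

    def test_total_element_count_conserved_per_element_class(self):
        records = [
            ElementRecord("c1", "p1", "Taeniopygia sp.", "unknown", "left_mandible", 3),
            ElementRecord("c1", "p1", "Artamus sp.", "unknown", "left_mandible", 2),
            ElementRecord("c1", "p1", "Artamus sp.", "unknown", "skull", 1),
        ]
        pooled = apply_taxonomy(records, HISTORIC_PROFILE)
        for elem in ("left_mandible", "skull"):
            before = sum(r.count for r in records if r.element == elem)
            after = sum(r.count for r in pooled if r.element == elem)
            assert before == after

    def test_non_idempotent_map_rejected(self):
        with pytest.raises(ValidationError, match="idempotent"):
            TaxonomyMap("bad", {"A": "B", "B": "C"})

    def test_default_group_absorbs_unmapped(self):
        tm = TaxonomyMap("grouped", {"X": "G"}, default_group="Other")
        assert tm.resolve("X") == "G"
        assert tm.resolve("never seen") == "Other"


class TestAbundanceTableIO:
    def test_unknown_counts_read_as_none(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text(
            "collection_id,taxon,age_class,individuals,pellets_containing\n"
            "H,Sminthopsis douglasi,unknown,13,\n"
            "H,Planigale spp.,unknown,,\n",
            encoding="utf-8",
        )
        vec = read_abundance_table(f, n_total={"H": 400})["H"]
        assert vec.count("Sminthopsis douglasi") == 13
        assert vec.count("Planigale spp.") is None
        assert vec.n == 400

    def test_split_species_union_left_unknown(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text(
            "collection_id,taxon,age_class,individuals,pellets_containing\n"
            "c1,Sminthopsis douglasi,juvenile,36,30\n"
            "c1,Sminthopsis douglasi,adult,99,82\n"
            "c1,Planigale spp.,unknown,46,32\n",
            encoding="utf-8",
        )
        vec = read_abundance_table(f)["c1"]
        # per-pellet overlap of the two age classes is unknown; 30 and 82
        # cannot be combined into a species-level occurrence count
        assert vec.pellets_containing["Sminthopsis douglasi"] is None
        assert vec.pellets_containing["Planigale spp."] == 32


class TestWriteTable:
    def test_small_p_gets_display_column_with_full_numeric(self, tmp_path):
        f = tmp_path / "t.csv"
        write_table([{"taxon": "x", "p_adj": 0.0032}, {"taxon": "y", "p_adj": 0.23}], f)
        rows = list(csv.DictReader(f.open()))
        assert rows[0]["p_adj_display"] == "< 0.01"
        assert float(rows[0]["p_adj"]) == 0.0032
        assert rows[1]["p_adj_display"] == "0.23"

    def test_percentages_rendered_to_two_decimals(self, tmp_path):
        f = tmp_path / "t.csv"
        write_table([{"pct": 100 * 82 / 280}], f)
        assert list(csv.DictReader(f.open()))[0]["pct"] == "29.29"

    def test_empty_rows_give_header_only_file(self, tmp_path):
        import pandas as pd

        f = tmp_path / "t.csv"
        write_table(pd.DataFrame(columns=["a", "b"]), f)
        assert f.read_text().strip() == "a,b"

    def test_csv_and_json_carry_identical_content(self, tmp_path):
        import json

        rows = [{"group": "g", "value": 1.23456, "p_adj": 0.004}]
        c = write_table(rows, tmp_path / "t.csv")
        j = write_table(rows, tmp_path / "t.json")
        csv_row = list(csv.DictReader(c.open()))[0]
        json_row = json.loads(j.read_text())[0]
        assert float(csv_row["value"]) == json_row["value"] == 1.23
        assert float(csv_row["p_adj"]) == json_row["p_adj"] == 0.004
        assert csv_row["p_adj_display"] == json_row["p_adj_display"] == "< 0.01"
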