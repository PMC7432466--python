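"""Curation pipeline: loading, standardization, filtering, pKi, merging."""

import numpy as np
import pandas as pd
import pytest

from cb2screen import curation
from cb2screen.curation import (
    ActivityRecord,
    ConversionError,
    CurationReport,
    SchemaError,
    StandardizationError,
    drop_feature_duplicates,
    filter_records,
    load_activity_table,
    merge_duplicates,
    standardize_structure,
    to_pki,
)


def _record(**kw):
    base = dict(
        smiles="c1ccccc1O",
        standard_type="Ki",
        standard_value=50.0,
        standard_units="nM",
        standard_relation="=",
        document_id="DOC1",
        confidence_score=9,
        target="CB1",
    )
    base.update(kw)
    return ActivityRecord(**base)


class TestLoadActivityTable:
    def test_row_count_preserved(self, tmp_path):
        df = pd.DataFrame(
            {
                "canonical_smiles": ["CCO", "c1ccccc1", "CC(=O)O"],
                "standard_type": ["Ki"] * 3,
                "standard_value": ["12.5", "3", "7"],
                "standard_units": ["nM"] * 3,
                "standard_relation": ["="] * 3,
                "document_chembl_id": ["D1"] * 3,
                "confidence_score": ["9"] * 3,
            }
        )
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        records = load_activity_table(path, "CB1")
        assert len(records) == 3
        assert records[0].standard_value == 12.5
        assert records[0].standard_units == "nM"

    def test_empty_smiles_preserved_as_absent(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "canonical_smiles,standard_type,standard_value,standard_units,"
            "standard_relation,document_chembl_id,confidence_score\n"
            ",Ki,5,nM,=,D1,9\n"
        )
        (rec,) = load_activity_table(path, "CB2")
        assert rec.smiles is None

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("canonical_smiles,standard_type\nCCO,Ki\n")
        with pytest.raises(SchemaError, match="standard_value"):
            load_activity_table(path, "CB1")

    def test_unparseable_numeric_collected_not_raised(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "canonical_smiles,standard_type,standard_value,standard_units,"
            "standard_relation,document_chembl_id,confidence_score\n"
            "CCO,Ki,not_a_number,nM,=,D1,9\n"
            "CCC,Ki,5,nM,=,D1,9\n"
        )
        report = CurationReport()
        records = load_activity_table(path, "CB1", report=report)
        assert len(records) == 1
        assert len(report.row_errors) == 1


class TestStandardizeStructure:
    def test_canonical_key_independent_of_atom_order(self):
        _, k1 = standardize_structure("CCO")
        _, k2 = standardize_structure("OCC")
        assert k1 == k2

    def test_benzene_inchikey_pinned(self):
        _, key = standardize_structure("c1ccccc1")
        assert key == "UHOVQNZJYSORNB-UHFFFAOYSA-N"

    def test_salt_stripped_to_parent(self):
        _, k_salt = standardize_structure("CC(=O)O.[Na+]")
        _, k_parent = standardize_structure("CC(=O)O")
        assert k_salt == k_parent

    @pytest.mark.parametrize(
        "smiles,reason",
        [
            ("", "no_structure"),
            (None, "no_structure"),
            ("C1CC(", "unparseable"),
            ("*CC*", "polymer"),
            ("[Pt](Cl)(Cl)(N)N", "metal_complex"),
            ("O=[Si]=O", "not_organic"),
        ],
    )
    def test_failure_reason_codes(self, smiles, reason):
        with pytest.raises(StandardizationError) as err:
            standardize_structure(smiles)
        assert err.value.reason == reason


class TestToPki:
    @pytest.mark.parametrize(
        "value,unit,stype,expected",
        [
            (1.0, "nM", "Ki", 9.0),
            (7.2, None, "pKi", 7.2),
            (50.0, "nM", "Ki", 9 - np.log10(50)),
            (1.0, "uM", "Ki", 6.0),
            (1.0, "M", "Ki", 0.0),
            (-8.0, None, "logKi", 8.0),
        ],
    )
    def test_conversions(self, value, unit, stype, expected):
        assert to_pki(value, unit, stype) == pytest.approx(expected, abs=1e-12)

    def test_tenfold_ki_shifts_pki_by_one(self):
        for v in (0.3, 7.0, 120.0):
            assert to_pki(10 * v, "nM", "Ki") == pytest.approx(
                to_pki(v, "nM", "Ki") - 1
            )

    @pytest.mark.parametrize(
        "value,unit,stype",
        [(-5.0, "nM", "Ki"), (0.0, "nM", "Ki"), (5.0, "parsec", "Ki"),
         (5.0, None, "Ki"), (5.0, "nM", "IC50")],
    )
    def test_conversion_errors(self, value, unit, stype):
        with pytest.raises(ConversionError):
            to_pki(value, unit, stype)


class TestFilterRecords:
    def test_assay_size_filter_groups_by_document(self):
        records = [_record(document_id="BIG") for _ in range(12)] + [
            _record(document_id="SMALL") for _ in range(9)
        ]
        report = CurationReport()
        kept = filter_records(records, report=report)
        assert len(kept) == 12
        assert all(r.document_id == "BIG" for r in kept)

    def test_low_confidence_removed_at_step_3(self):
        records = [_record(document_id="D", confidence_score=9) for _ in range(10)]
        records.append(_record(document_id="D", confidence_score=7))
        report = CurationReport()
        kept = filter_records(records, report=report)
        assert len(kept) == 10
        assert report.count_at("confidence") == 10

    def test_no_filter_fires_on_clean_input(self):
        records = [_record(document_id="D") for _ in range(10)]
        assert len(filter_records(records)) == 10

    def test_non_exact_relation_dropped_with_ki_step(self):
        records = [_record(document_id="D") for _ in range(10)]
        records.append(_record(document_id="D", standard_relation=">"))
        report = CurationReport()
        kept = filter_records(records, report=report)
        assert len(kept) == 10
        # the censored record still counted toward its assay's size
        assert report.count_at("assay_size") == 11

    def test_step_counts_non_increasing(self, activity_table):
        path, _ = activity_table
        records = load_activity_table(path, "CB1")
        report = CurationReport()
        filter_records(records, report=report)
        counts = [c for _, c in report.steps]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMergeDuplicates:
    def _frame(self, pairs):
        return pd.DataFrame(
            [(k, f"smi_{k}", v) for k, v in pairs],
            columns=["inchikey", "smiles", "pki"],
        )

    def test_consistent_group_merges_to_mean(self):
        df = self._frame([("A", 7.0), ("A", 7.1), ("LO", 4.0), ("HI", 10.0)])
        out = merge_duplicates(df)
        row = out[out.inchikey == "A"].iloc[0]
        assert row.pki == pytest.approx(7.05)
        assert row.n_merged == 2

    def test_inconsistent_group_dropped_entirely(self):
        df = self._frame([("A", 5.0), ("A", 9.0), ("LO", 4.0), ("HI", 10.0)])
        report = CurationReport()
        out = merge_duplicates(df, report=report)
        assert "A" not in set(out.inchikey)
        assert report.dropped_inconsistent_groups == ["A"]

    def test_singleton_passes_through(self):
        df = self._frame([("A", 6.2), ("B", 5.0)])
        out = merge_duplicates(df)
        assert out[out.inchikey == "A"].iloc[0].n_merged == 1
        assert out[out.inchikey == "A"].iloc[0].pki == 6.2

    def test_output_keys_unique_and_means_match_brute_force(self):
        rng = np.random.default_rng(4)
        keys = rng.choice(list("ABCDEFGH"), size=40)
        pki = rng.uniform(4, 10, size=40)
        df = self._frame(list(zip(keys, pki)))
        out = merge_duplicates(df, sd_fraction=0.5)
        assert out.inchikey.is_unique
        for _, row in out.iterrows():
            members = pki[keys == row.inchikey]
            assert row.pki == pytest.approx(members.mean())


class TestDropFeatureDuplicates:
    def test_all_members_of_identical_group_removed(self):
        df = pd.DataFrame(
            {"inchikey": ["A", "B", "C"], "smiles": ["x", "y", "z"],
             "pki": [6.0, 8.0, 7.0]}
        )
        feats = {
            "A": np.array([1.0, 2.0]),
            "B": np.array([1.0, 2.0]),
            "C": np.array([3.0, 4.0]),
        }
        out = drop_feature_duplicates(df, feats)
        assert list(out.inchikey) == ["C"]

    def test_distinct_vectors_untouched(self):
        df = pd.DataFrame(
            {"inchikey": ["A", "B"], "smiles": ["x", "y"], "pki": [6, 7]}
        )
        feats = {"A": np.array([1.0]), "B": np.array([2.0])}
        assert len(drop_feature_duplicates(df, feats)) == 2

    def test_missing_vector_raises_naming_compound(self):
        df = pd.DataFrame({"inchikey": ["A"], "smiles": ["x"], "pki": [6.0]})
        with pytest.raises(KeyError, match="A"):
            drop_feature_duplicates(df, {})


class TestPipeline:
    def test_idempotent_on_own_output(self, activity_table):
        """Re-curating curated data must change nothing."""
        path, _ = activity_table
        records = load_activity_table(path, "CB1")
        df, _ = curation.curate(records, "CB1")
        # re-express the curated set as activity records and curate again
        records2 = [
            ActivityRecord(
                smiles=row.smiles,
                standard_type="pKi",
                standard_value=row.pki,
                standard_units=None,
                standard_relation="=",
                document_id="ALL",
                confidence_score=9,
                target="CB1",
            )
            for row in df.itertuples()
        ]
        df2, _ = curation.curate(records2, "CB1", min_assay_size=1)
        assert set(df2.inchikey) == set(df.inchikey)
        assert np.allclose(
            df2.set_index("inchikey").loc[df.inchikey, "pki"], df.pki
        )

    def test_report_totals_and_monotonicity(self, activity_table):
        path, manifest = activity_table
        records = load_activity_table(path, "CB1")
        _, report = curation.curate(records, "CB1")
        counts = [c for _, c in report.steps]
        assert counts[0] == manifest.n_total
        assert all(a >= b for a, b in zip(counts, counts[1:]))
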