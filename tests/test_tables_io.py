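from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methanocycle.tables_io import (
    TableFormatError,
    TableValidationError,
    completion_fraction,
    load_vocabulary,
    parse_gtdb_lineage,
    read_annotations,
    read_coverage,
    write_table,
)

LINEAGE = (
    "d__Archaea;p__Halobacterota;c__X;o__Methanosarcinales;"
    "f__Methanosarcinaceae;g__Methanosarcina;s__"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAnnotations:
    def test_well_formed_rows_are_all_retained(self, tmp_path):
        path = _write(
            tmp_path,
            "a.tsv",
            "mag_id\tgene_symbol\tscaffold_id\tscaffold_length\n"
            "m1\tmcrA\ts1\t4000\nm1\tmcrB\ts1\t4000\nm2\tpmoA\ts2\t3500\n",
        )
        table = read_annotations(path)
        assert len(table.frame) == 3
        assert not table.unrecognized

    def test_unknown_token_retained_and_reported(self, tmp_path):
        path = _write(
            tmp_path,
            "a.tsv",
            "mag_id\tgene_symbol\tscaffold_id\tscaffold_length\nm1\txyz\ts1\t1000\n",
        )
        table = read_annotations(path)
        assert table.unrecognized == {"xyz": 1}
        assert list(table.frame["gene_symbol"]) == ["xyz"]

    def test_dialect_label_normalized_to_canonical_symbol(self, tmp_path):
        path = _write(
            tmp_path,
            "a.tsv",
            "mag_id\tgene_symbol\tscaffold_id\tscaffold_length\n"
            "m1\tSCFA and alcohol conversions: acetate pt. 1\ts1\t1000\n",
        )
        assert list(read_annotations(path).frame["gene_symbol"]) == ["pta"]

    def test_missing_column_is_a_format_error(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "mag_id\tgene_symbol\tscaffold_id\nm1\tmcrA\ts1\n")
        with pytest.raises(TableFormatError, match="scaffold_length"):
            read_annotations(path)

    def test_negative_length_is_a_validation_error(self, tmp_path):
        path = _write(
            tmp_path,
            "a.tsv",
            "mag_id\tgene_symbol\tscaffold_id\tscaffold_length\nm1\tmcrA\ts1\t-5\n",
        )
        with pytest.raises(TableValidationError):
            read_annotations(path)


class TestGtdbLineage:
    def test_full_lineage_splits_into_ranks(self):
        t = parse_gtdb_lineage(LINEAGE)
        assert t.family == "Methanosarcinaceae"
        assert t.genus == "Methanosarcina"
        assert t.species == ""

    def test_domain_only_leaves_lower_ranks_empty(self):
        t = parse_gtdb_lineage("d__Bacteria")
        assert t.domain == "Bacteria"
        assert t.phylum == t.species == ""

    def test_wrong_rank_order_rejected(self):
        with pytest.raises(TableFormatError):
            parse_gtdb_lineage("p__X;d__Bacteria")

    @pytest.mark.parametrize("bad", ["", "x__Y", "d__A;d__B", "d__A;" * 8])
    def test_non_grammar_strings_rejected(self, bad):
        with pytest.raises((TableFormatError, TableValidationError)):
            parse_gtdb_lineage(bad)

    def test_classified_rank_below_unclassified_rejected(self):
        with pytest.raises(TableValidationError):
            parse_gtdb_lineage("d__Archaea;p__;c__Something")

    @given(depth=st.integers(1, 7))
    def test_total_on_prefixes_of_the_grammar(self, depth):
        parts = [f"{p}Name{i}" for i, p in enumerate(("d__", "p__", "c__", "o__", "f__", "g__", "s__"))]
        t = parse_gtdb_lineage(";".join(parts[:depth]))
        assert t.domain == "Name0"


class TestCompletionFraction:
    @pytest.mark.parametrize(
        "present,total,expected",
        [(6, 8, Fraction(3, 4)), (0, 8, 0), (2, 2, 1)],
    )
    def test_exact_values(self, present, total, expected):
        assert completion_fraction(present, total) == expected

    def test_overfull_pathway_rejected(self):
        with pytest.raises(TableValidationError):
            completion_fraction(3, 2)

    @given(total=st.integers(1, 12), present=st.integers(0, 12))
    def test_monotone_in_steps_present(self, total, present):
        present = min(present, total)
        if present < total:
            assert completion_fraction(present, total) <= completion_fraction(present + 1, total)


class TestRoundTrip:
    @given(
        rows=st.lists(
            st.tuples(
                st.sampled_from(["m1", "m2", "m3"]),
                st.sampled_from(["mcrA", "pmoA", "acs", "pta"]),
                st.integers(0, 5),
                st.integers(0, 50000),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_write_then_read_reproduces_records(self, tmp_path_factory, rows):
        df = pd.DataFrame(
            [(m, g, f"{m}_s{s}", ln) for m, g, s, ln in rows],
            columns=["mag_id", "gene_symbol", "scaffold_id", "scaffold_length"],
        )
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_table(df, path)
        back = read_annotations(path).frame
        key = ["mag_id", "gene_symbol", "scaffold_id", "scaffold_length"]
        pd.testing.assert_frame_equal(
            df.sort_values(key).reset_index(drop=True),
            back.sort_values(key).reset_index(drop=True),
        )


def test_duplicate_scaffold_in_coverage_rejected(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text(
        "site_id\tmag_id\tscaffold_id\tcoverage\nA\tm1\ts1\t5.0\nA\tm1\ts1\t6.0\n"
    )
    with pytest.raises(TableValidationError, match="duplicate"):
        read_coverage(p)


def test_vocabulary_aliases_point_at_canonical_tokens():
    vocab = load_vocabulary()
    assert vocab.normalize("Acetate pt 1") == "acs"
    assert vocab.normalize("mcrA") == "mcrA"
    assert vocab.normalize("nope") is None
    assert set(vocab.alias_to_canonical.values()) <= set(vocab.canonical)
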