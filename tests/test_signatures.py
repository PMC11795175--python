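import math

import pytest
from hypothesis import given, settings, strategies as st

from sigoverlap.signatures import (
    GeneEntry,
    OrthologMap,
    Signature,
    SignatureFormatError,
    build_universe,
    harmonize,
    read_deg_table,
    read_gmt,
    write_deg_table,
)

from conftest import make_signature


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
    return path


class TestGeneEntry:
    def test_direction_follows_sign(self):
        assert GeneEntry("A", 0.5).direction == 1
        assert GeneEntry("A", -0.5).direction == -1

    @pytest.mark.parametrize(
        "score", [0.0, float("nan"), float("inf")], ids=["zero", "nan", "inf"]
    )
    def test_degenerate_scores_rejected(self, score):
        with pytest.raises(ValueError):
            GeneEntry("A", score)

    def test_blank_symbol_rejected(self):
        with pytest.raises(ValueError):
            GeneEntry("  ", 1.0)


class TestReadDegTable:
    def test_ranked_by_absolute_score(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            ["gene", "log2fc"],
            [("gene1", 1.0), ("gene2", -0.5), ("gene3", 0.3)],
        )
        sig = read_deg_table(p)
        assert sig.ranked_symbols == ["GENE1", "GENE2", "GENE3"]

    def test_duplicate_symbol_keeps_max_abs_score(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            ["gene", "log2fc"],
            [("Gfap", 0.4), ("Gfap", -1.1)],
        )
        sig = read_deg_table(p)
        assert sig.n == 1
        assert sig.entries[0].score == -1.1

    def test_linear_fold_change_converted_to_log2(self, tmp_path):
        p = write_tsv(tmp_path / "t.tsv", ["gene", "score"], [("A", 1.2)])
        sig = read_deg_table(p, score_column_is_log2=False)
        assert sig.entries[0].score == pytest.approx(math.log2(1.2), abs=1e-12)

    def test_zero_and_nonfinite_rows_rejected(self, tmp_path):
        p = write_tsv(
            tmp_path / "t.tsv",
            ["gene", "log2fc"],
            [("A", 0.0), ("B", "nan"), ("C", 0.7)],
        )
        sig = read_deg_table(p)
        assert sig.ranked_symbols == ["C"]

    def test_missing_columns_and_empty_file_error(self, tmp_path):
        bad = write_tsv(tmp_path / "bad.tsv", ["gene", "stat"], [("A", 1)])
        with pytest.raises(SignatureFormatError):
            read_deg_table(bad)
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(SignatureFormatError):
            read_deg_table(empty)

    def test_round_trip_preserves_scores_and_ranking(self, tmp_path):
        sig = make_signature(
            "s", {"A": 0.1234567890123456, "B": -2.5e-17, "C": 1.0 / 3.0}
        )
        write_deg_table(sig, tmp_path / "s.tsv")
        back = read_deg_table(tmp_path / "s.tsv")
        assert back.ranked_symbols == sig.ranked_symbols
        assert [e.score for e in back.entries] == [e.score for e in sig.entries]

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["a1", "b2", "c3", "d4"]),
                st.floats(
                    min_value=1e-3, max_value=10, allow_nan=False
                ).map(lambda v: round(v, 3)),
                st.sampled_from([-1, 1]),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_dedup_stable_under_row_duplication(self, tmp_path_factory, rows):
        """Duplicating input rows never changes the parsed signature."""
        d = tmp_path_factory.mktemp("dup")
        scored = [(g, m * s) for g, m, s in rows]
        p1 = write_tsv(d / "once.tsv", ["gene", "log2fc"], scored)
        p2 = write_tsv(d / "twice.tsv", ["gene", "log2fc"], scored + scored)
        s1 = read_deg_table(p1)
        s2 = read_deg_table(p2)
        assert s1.ranked_symbols == s2.ranked_symbols
        assert [e.score for e in s1.entries] == [e.score for e in s2.entries]


class TestGmt:
    def test_line_parsed_and_symbols_normalized(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\ta\tB\tc\n")
        coll = read_gmt(p)
        assert coll.sets["S1"] == {"A", "B", "C"}

    def test_duplicate_set_name_errors(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(SignatureFormatError):
            read_gmt(p)

    def test_short_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\td\tA\nS2\tonlydesc\n")
        with pytest.raises(SignatureFormatError, match=":2"):
            read_gmt(p)

    def test_fixture_with_15_sets(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text(
            "".join(f"S{i}\td\tA{i}\tB{i}\n" for i in range(15))
        )
        assert len(read_gmt(p)) == 15


class TestHarmonize:
    def test_default_upper_cases_symbols(self):
        sig = make_signature("s", {"Bdnf": 1.0})
        assert harmonize(sig).ranked_symbols == ["BDNF"]

    def test_identity_map_equals_no_map(self):
        sig = make_signature("s", {"Fos": 1.0, "Bdnf": -0.4})
        identity = OrthologMap({s: s for s in ("FOS", "BDNF")})
        assert harmonize(sig, identity) == harmonize(sig)

    def test_unmapped_entries_dropped(self):
        sig = make_signature("s", {"Fos": 1.0, "Xyz1": 0.2})
        out = harmonize(sig, OrthologMap({"Fos": "FOS"}))
        assert out.ranked_symbols == ["FOS"]

    def test_collision_keeps_max_abs_score(self):
        sig = make_signature("s", {"A1": 0.8, "A2": -1.5})
        out = harmonize(sig, OrthologMap({"A1": "T", "A2": "T"}))
        assert out.n == 1
        assert out.entries[0].score == -1.5


class TestBuildUniverse:
    def test_intersection_and_union(self):
        lists = [{"A", "B", "C"}, {"B", "C", "D"}]
        assert build_universe(lists).n == 2
        assert build_universe(lists, mode="union").n == 4

    def test_single_list(self):
        assert build_universe([[f"g{i}" for i in range(1000)]]).n == 1000

    def test_empty_intersection_advises_union(self):
        with pytest.raises(ValueError, match="union"):
            build_universe([{"A"}, {"B"}])
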