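"""Temporal matrix I/O, replicate collapsing and the fold-change filter."""

import numpy as np
import pandas as pd
import pytest

from temposig import (
    TemporalMatrix,
    collapse_replicates,
    fold_change_filter,
    read_temporal_matrix,
    write_temporal_matrix,
)
from temposig.errors import (
    AllMissingRowError,
    DuplicateIdError,
    ParameterError,
    TimeAxisError,
)

TIMES = [1, 3, 5, 7, 10, 14]


def _write(tmp_path, text, name="m.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadWrite:
    def test_plain_3x6_matrix(self, tmp_path):
        header = "variable_id\t" + "\t".join(map(str, TIMES))
        rows = [f"V{i}\t" + "\t".join(str(i + j / 10) for j in range(6))
                for i in range(3)]
        m = read_temporal_matrix(_write(tmp_path, "\n".join([header] + rows)))
        assert m.values.shape == (3, 6)
        np.testing.assert_array_equal(m.time_points, TIMES)
        assert m.variable_ids == ["V0", "V1", "V2"]
        assert not m.missing_mask.any()

    def test_round_trip_exact(self, tmp_path, small_matrix):
        path = tmp_path / "round.tsv"
        write_temporal_matrix(small_matrix, path)
        back = read_temporal_matrix(path)
        np.testing.assert_array_equal(back.missing_mask,
                                      small_matrix.missing_mask)
        np.testing.assert_array_equal(
            back.values[~back.missing_mask],
            small_matrix.values[~small_matrix.missing_mask])
        np.testing.assert_array_equal(back.time_points,
                                      small_matrix.time_points)
        assert back.variable_ids == small_matrix.variable_ids

    def test_mixed_missing_tokens_match_oracle_parse(self, tmp_path):
        # token-by-token oracle: every listed missing token maps to a hole
        cells = [["1.0", "NA", "2.0", "", "NaN", "null"],
                 ["0.5", "na", "3.0", "1.0", "", "2.5"]]
        header = "variable_id\t" + "\t".join(map(str, TIMES))
        body = "\n".join(f"V{i}\t" + "\t".join(row)
                         for i, row in enumerate(cells))
        m = read_temporal_matrix(_write(tmp_path, header + "\n" + body))
        tokens = {"", "na", "nan", "null"}
        oracle = np.array([[c.lower() in tokens for c in row]
                           for row in cells])
        np.testing.assert_array_equal(m.missing_mask, oracle)

    def test_all_missing_row_rejected_with_id(self, tmp_path):
        header = "variable_id\t" + "\t".join(map(str, TIMES))
        body = "GOOD\t1\t2\t3\t4\t5\t6\nBAD\tNA\tNA\tNA\tNA\tNA\tNA"
        with pytest.raises(AllMissingRowError, match="BAD"):
            read_temporal_matrix(_write(tmp_path, header + "\n" + body))

    def test_non_monotone_time_header(self, tmp_path):
        header = "variable_id\t1\t3\t2\t7\t10\t14"
        body = "V1\t1\t2\t3\t4\t5\t6"
        with pytest.raises(TimeAxisError):
            read_temporal_matrix(_write(tmp_path, header + "\n" + body))

    def test_duplicate_ids(self, tmp_path):
        header = "variable_id\t" + "\t".join(map(str, TIMES))
        body = "V1\t1\t2\t3\t4\t5\t6\nV1\t6\t5\t4\t3\t2\t1"
        with pytest.raises(DuplicateIdError):
            read_temporal_matrix(_write(tmp_path, header + "\n" + body))


def _rep_table(records):
    return pd.DataFrame(records, columns=["variable_id", "time", "condition",
                                          "replicate", "occupancy"])


class TestCollapseReplicates:
    def test_unit_ratios_give_zero(self):
        recs = [("V1", 1, c, r, 0.5) for c in ("treated", "control")
                for r in range(1, 5)]
        m = collapse_replicates(_rep_table(recs + [
            ("V1", 3, c, r, 0.2) for c in ("treated", "control")
            for r in range(1, 5)]))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("log_base,expected", [(2.0, 1.0), (10.0, np.log10(2))])
    def test_doubling_gives_log_of_two(self, log_base, expected):
        recs = ([("V1", 1, "control", r, 0.3) for r in range(1, 5)]
                + [("V1", 1, "treated", r, 0.6) for r in range(1, 5)]
                + [("V1", 3, "control", 1, 0.3), ("V1", 3, "treated", 1, 0.6)])
        m = collapse_replicates(_rep_table(recs), log_base=log_base)
        np.testing.assert_allclose(m.values[0], expected, atol=1e-12)

    def test_mean_of_mixed_ratios(self):
        # ratios {1, 2, 4, 8}: cell = log2 of their mean = log2(3.75)
        recs = ([("V1", 1, "control", r, 1.0) for r in range(1, 5)]
                + [("V1", 1, "treated", r, v)
                   for r, v in zip(range(1, 5), [1.0, 2.0, 4.0, 8.0])]
                + [("V1", 3, "control", 1, 1.0), ("V1", 3, "treated", 1, 1.0)])
        m = collapse_replicates(_rep_table(recs))
        assert m.values[0, 0] == pytest.approx(np.log2(3.75), abs=1e-12)

    def test_invariant_to_replicate_ordering(self, rng):
        recs = []
        for t in (1, 3, 5):
            for r in range(1, 5):
                recs.append(("V1", t, "control", r, rng.uniform(0.1, 1)))
                recs.append(("V1", t, "treated", r, rng.uniform(0.1, 1)))
        table = _rep_table(recs)
        shuffled = table.sample(frac=1.0, random_state=1)
        np.testing.assert_allclose(collapse_replicates(table).values,
                                   collapse_replicates(shuffled).values)

    def test_zero_control_pair_discarded(self):
        recs = ([("V1", 1, "control", 1, 0.0), ("V1", 1, "treated", 1, 9.0),
                 ("V1", 1, "control", 2, 0.5), ("V1", 1, "treated", 2, 1.0),
                 ("V1", 3, "control", 1, 1.0), ("V1", 3, "treated", 1, 1.0)])
        m = collapse_replicates(_rep_table(recs))
        # only replicate 2 contributes: ratio 2
        assert m.values[0, 0] == pytest.approx(1.0)

    def test_unmatched_replicates_skipped_and_empty_pairs_missing(self):
        recs = ([("V1", 1, "treated", 1, 2.0), ("V1", 1, "control", 1, 1.0),
                 ("V1", 1, "treated", 2, 99.0),          # no control mate
                 ("V1", 3, "treated", 1, 5.0)])          # no control at all
        m = collapse_replicates(_rep_table(recs))
        assert m.values[0, 0] == pytest.approx(1.0)
        assert np.isnan(m.values[0, 1])


class TestFoldChangeFilter:
    def _matrix(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        n = values.shape[1]
        return TemporalMatrix(values, np.arange(1, n + 1),
                              [f"V{i}" for i in range(values.shape[0])],
                              {"log_base": "2"})

    def test_borderline_kept_and_flat_dropped(self):
        m = self._matrix([[np.log2(1.3), 0, 0, 0, 0, 0],
                          [0, 0, 0, 0, 0, 0]])
        kept, report = fold_change_filter(m, threshold=1.2)
        assert kept.variable_ids == ["V0"]
        assert report.dropped_ids == ["V1"]
        assert report.n_kept + report.n_dropped == report.n_input == 2

    def test_matches_exhaustive_cell_scan(self, rng):
        values = rng.normal(scale=0.4, size=(50, 6))
        values[rng.random((50, 6)) < 0.2] = np.nan
        values[:, 0] = rng.normal(scale=0.4, size=50)  # keep rows valid
        m = self._matrix(values)
        kept, report = fold_change_filter(m, threshold=1.2)
        cutoff = np.log2(1.2)
        oracle = []
        for i, row in enumerate(values):
            if any(abs(x) >= cutoff for x in row if not np.isnan(x)):
                oracle.append(f"V{i}")
        assert kept.variable_ids == oracle

    def test_idempotent(self, rng):
        values = rng.normal(scale=0.5, size=(40, 6))
        m = self._matrix(values)
        once, _ = fold_change_filter(m, 1.2)
        twice, report = fold_change_filter(once, 1.2)
        np.testing.assert_array_equal(once.values, twice.values)
        assert report.n_dropped == 0

    def test_threshold_must_exceed_one(self, small_matrix):
        with pytest.raises(ParameterError):
            fold_change_filter(small_matrix, threshold=1.0)
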