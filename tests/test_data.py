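"""MET data model: validation, I/O round-trips, concurrence, plot ordering."""

import numpy as np
import pytest

from metfa import (
    METDataset,
    METValidationError,
    PlotRecord,
    TrialDesign,
    concurrence_matrix,
    read_met_csv,
    sort_rows_within_columns,
    write_met_csv,
)
from metfa.structures import ar1_matrix


def _dataset(entry_sets, n_cols=2, n_rows=5):
    trials = [
        TrialDesign(f"T{i}", n_cols, n_rows, tuple(es), 2)
        for i, es in enumerate(entry_sets)
    ]
    return METDataset(trials=trials)


class TestValidation:
    def test_duplicate_plot_rejected(self):
        t = TrialDesign("A", 2, 2, ("g1", "g2"), 2)
        recs = [
            PlotRecord("A", "g1", "R1", 1, 1, 1.0),
            PlotRecord("A", "g2", "R1", 1, 1, 2.0),
        ]
        with pytest.raises(METValidationError, match=r"duplicate plot \('A', 1, 1\)"):
            METDataset(trials=[t], records=recs)

    def test_unknown_genotype_and_out_of_grid(self):
        t = TrialDesign("A", 2, 2, ("g1",), 2)
        with pytest.raises(METValidationError, match="not an entry"):
            METDataset(trials=[t], records=[PlotRecord("A", "gX", "R1", 1, 1, 1.0)])
        with pytest.raises(METValidationError, match="outside"):
            METDataset(trials=[t], records=[PlotRecord("A", "g1", "R1", 3, 1, 1.0)])

    def test_min_two_reps_enforced(self):
        with pytest.raises(METValidationError, match="two replicates"):
            TrialDesign("A", 4, 4, ("g1",), 1)


class TestCSV:
    def _lcb_like_csv(self, tmp_path):
        # 9 trials of 16 entries on 4 x 12 grids, 3 reps (48 = 16 x 3)
        lines = ["trial,genotype,replicate,column,row,yield"]
        rng = np.random.default_rng(0)
        for t in range(9):
            plot = 0
            for rep in range(3):
                for g in rng.permutation(16):
                    c, r = divmod(plot, 12)
                    lines.append(
                        f"E{t+1},G{g+1},R{rep+1},{c+1},{r+1},{rng.normal(4, 0.5):.4f}"
                    )
                    plot += 1
        p = tmp_path / "lcb.csv"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_lcb_like_file_shape(self, tmp_path):
        d = read_met_csv(self._lcb_like_csv(tmp_path))
        assert len(d.trials) == 9
        assert all(len(d.records_for(t.trial)) == 48 for t in d.trials)
        assert all(t.n_reps == 3 and len(t.entries) == 16 for t in d.trials)
        assert all((t.n_cols, t.n_rows) == (4, 12) for t in d.trials)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("trial,genotype,replicate,column,row,yield\n")
        with pytest.raises(METValidationError, match="no records"):
            read_met_csv(p)

    def test_duplicate_lines_named(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "trial,genotype,replicate,column,row,yield\n"
            "A,g1,R1,1,1,1.0\n"
            "A,g2,R2,1,1,2.0\n"
        )
        with pytest.raises(METValidationError, match="lines 2 and 3"):
            read_met_csv(p)

    def test_bad_yield_token(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "trial,genotype,replicate,column,row,yield\nA,g1,R1,1,1,oops\n"
        )
        with pytest.raises(METValidationError, match="neither numeric"):
            read_met_csv(p)

    def test_roundtrip_exact(self, tmp_path, small_trial):
        d, _ = small_trial
        # punch a missing yield in to exercise the NA path
        recs = list(d.records)
        recs[3] = PlotRecord(
            recs[3].trial, recs[3].genotype, recs[3].replicate,
            recs[3].column, recs[3].row, None,
        )
        d = METDataset(trials=d.trials, records=recs)
        p = tmp_path / "out.csv"
        write_met_csv(d, p)
        d2 = read_met_csv(p)
        assert len(d2.records) == len(d.records)
        for a, b in zip(d.records, d2.records):
            assert (a.trial, a.genotype, a.replicate, a.column, a.row) == (
                b.trial, b.genotype, b.replicate, b.column, b.row,
            )
            assert a.yield_value == b.yield_value  # full precision via repr


class TestConcurrence:
    def test_hand_enumerated_intersections(self):
        sets = [range(1, 11), range(6, 16), range(1, 6)]
        d = _dataset([[f"G{i}" for i in s] for s in sets], n_cols=4, n_rows=5)
        C = concurrence_matrix(d)
        assert C.tolist() == [[10, 5, 5], [5, 10, 0], [5, 0, 5]]

    def test_identical_and_disjoint(self):
        d = _dataset([[f"G{i}" for i in range(16)]] * 2, n_cols=4, n_rows=8)
        assert (concurrence_matrix(d) == 16).all()
        d2 = _dataset([["A1", "A2"], ["B1", "B2"]])
        C = concurrence_matrix(d2)
        assert C[0, 1] == 0 and C[0, 0] == 2


class TestPlotOrdering:
    def _grid_dataset(self, n_cols, n_rows):
        entries = tuple(f"G{i}" for i in range(n_cols * n_rows // 2))
        t = TrialDesign("A", n_cols, n_rows, entries, 2)
        recs = []
        i = 0
        for c in range(n_cols):  # insert row-major to make ordering nontrivial
            for r in range(n_rows):
                recs.append(PlotRecord("A", entries[i % len(entries)], "R1", c + 1, r + 1, float(i)))
                i += 1
        rng = np.random.default_rng(1)
        order = rng.permutation(len(recs))
        return METDataset(trials=[t], records=[recs[j] for j in order])

    def test_2x3_definition(self):
        d = self._grid_dataset(2, 3)
        idx = sort_rows_within_columns(d, "A")
        plots = [(d.records[i].column, d.records[i].row) for i in idx]
        assert plots == [(1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3)]

    def test_1xn_identity_order(self):
        d = self._grid_dataset(1, 6)
        idx = sort_rows_within_columns(d, "A")
        rows = [d.records[i].row for i in idx]
        assert rows == [1, 2, 3, 4, 5, 6]

    def test_kronecker_consistency_4x12(self):
        """Ordered as rows-within-columns, the separable covariance is
        elementwise sigma^2 * rho_c^|dcol| * rho_r^|drow|."""
        d = self._grid_dataset(4, 12)
        idx = sort_rows_within_columns(d, "A")
        assert len(idx) == 48 and (idx >= 0).all()
        s2, rc, rr = 1.7, 0.56, 0.3
        R = s2 * np.kron(ar1_matrix(4, rc), ar1_matrix(12, rr))
        cols = np.array([d.records[i].column for i in idx])
        rows = np.array([d.records[i].row for i in idx])
        expected = s2 * rc ** np.abs(cols[:, None] - cols[None, :]) * rr ** np.abs(
            rows[:, None] - rows[None, :]
        )
        np.testing.assert_allclose(R, expected, rtol=0, atol=1e-12)

    def test_missing_plots_get_placeholders(self):
        t = TrialDesign("A", 2, 2, ("g1", "g2"), 2)
        recs = [PlotRecord("A", "g1", "R1", 1, 1, 1.0), PlotRecord("A", "g2", "R1", 2, 2, 2.0)]
        d = METDataset(trials=[t], records=recs)
        idx = sort_rows_within_columns(d, "A")
        assert len(idx) == 4 and (idx == -1).sum() == 2
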