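"""Table types, prior-to-hyperparameter mapping, I/O, and MC summaries."""

import json

import numpy as np
import pytest

from veribayes import (
    BinaryVerificationTable,
    DrawMatrix,
    OrdinalVerificationTable,
    PriorSpec,
    TableValidationError,
    ZeroCellError,
    hyperparameters,
    load_table,
    summarize,
    write_table,
)


class TestValidation:
    def test_binary_totals(self, table2):
        assert table2.n_subjects == 116
        assert np.array_equal(table2.m, table2.s + table2.r + table2.u)

    def test_ordinal_totals(self, table6):
        assert table6.n_subjects == 1768
        assert table6.m[3] == 124  # consistent cell total, not the misprinted 224

    def test_negative_count_rejected(self):
        with pytest.raises(TableValidationError):
            BinaryVerificationTable(s=[[1, -2], [3, 4]], r=[[1, 1], [1, 1]], u=[[0, 0], [0, 0]])

    def test_inconsistent_m_rejected(self, tmp_path):
        doc = {"design": "binary", "s": [[0, 0], [0, 1]], "r": [[1, 1], [1, 1]],
               "u": [[0, 0], [0, 0]], "m": [[1, 1], [1, 3]]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(TableValidationError, match="m != s"):
            load_table(p)

    def test_all_unverified_table_unusable_under_improper_prior(self):
        t = OrdinalVerificationTable(K=2, s=[0] * 4, r=[0] * 4, u=[5] * 4)
        with pytest.raises(ZeroCellError):
            hyperparameters(t, PriorSpec())

    def test_wrong_cell_count_rejected(self):
        with pytest.raises(TableValidationError):
            OrdinalVerificationTable(K=3, s=[1] * 8, r=[1] * 8, u=[0] * 8)


class TestIO:
    def test_json_round_trip(self, table6, tmp_path):
        p = tmp_path / "t.json"
        write_table(table6, p)
        back = load_table(p, design="ordinal")
        assert np.array_equal(back.s, table6.s)
        assert np.array_equal(back.r, table6.r)
        assert np.array_equal(back.u, table6.u)

    def test_binary_round_trip(self, table2, tmp_path):
        p = tmp_path / "t.json"
        write_table(table2, p)
        back = load_table(p, design="binary")
        assert np.array_equal(back.s, table2.s)
        assert back.n_subjects == 116

    def test_csv_binary(self, table2, tmp_path):
        p = tmp_path / "t.csv"
        lines = ["cell,y1,y2,s,r,u"]
        for i in range(2):
            for j in range(2):
                lines.append(
                    f"{2 * i + j},{i},{j},{table2.s[i, j]},{table2.r[i, j]},{table2.u[i, j]}"
                )
        p.write_text("\n".join(lines) + "\n")
        back = load_table(p)
        assert np.array_equal(back.s, table2.s)

    def test_design_mismatch(self, table2, tmp_path):
        p = tmp_path / "t.json"
        write_table(table2, p)
        with pytest.raises(TableValidationError):
            load_table(p, design="ordinal")


class TestHyperparameters:
    def test_improper_matches_counts(self, table2):
        hp = hyperparameters(table2, PriorSpec())
        assert hp.a[1, 1] == 14 and hp.b[1, 1] == 4
        assert np.array_equal(hp.d, [31, 31, 29, 25])
        assert hp.notes == ()

    def test_uniform_adds_one(self, table2):
        hp = hyperparameters(table2, PriorSpec(kind="uniform"))
        assert hp.a[1, 1] == 15 and hp.b[1, 1] == 5
        assert np.array_equal(hp.d, [32, 32, 30, 26])

    def test_zero_cell_default_errors(self, table4):
        with pytest.raises(ZeroCellError):
            hyperparameters(table4, PriorSpec())

    def test_zero_cell_add_one(self, table4):
        hp = hyperparameters(table4, PriorSpec(zero_fix="add_one"))
        assert hp.a[0, 0] == 1 and hp.b[0, 0] == 1
        assert np.array_equal(hp.d, [21, 22, 21, 18])
        assert len(hp.notes) == 2  # both s00 and r00 substituted

    def test_uniform_equals_improper_on_incremented_table(self, table2):
        bumped = BinaryVerificationTable(
            s=table2.s + 1, r=table2.r + 1, u=table2.u - 1
        )  # m increments by 1 cell-wise
        hp_u = hyperparameters(table2, PriorSpec(kind="uniform"))
        hp_i = hyperparameters(bumped, PriorSpec())
        assert np.array_equal(hp_u.a, hp_i.a)
        assert np.array_equal(hp_u.b, hp_i.b)
        assert np.array_equal(hp_u.d, hp_i.d)

    def test_bad_prior_spec(self):
        with pytest.raises(ValueError):
            PriorSpec(kind="jeffreys")
        with pytest.raises(ValueError):
            PriorSpec(zero_fix="drop")


class TestSummarize:
    def test_constant_column(self):
        dm = DrawMatrix(names=("c",), draws=np.full((500, 1), 0.5), seed=0)
        s = summarize(dm)["c"]
        assert s.mean == 0.5 and s.sd == 0.0 and s.mc_error == 0.0
        assert s.q025 == s.median == s.q975 == 0.5

    def test_uniform_column_moments(self):
        rng = np.random.default_rng(7)
        dm = DrawMatrix(names=("u",), draws=rng.random((100_000, 1)), seed=7)
        s = summarize(dm)["u"]
        assert abs(s.mean - 0.5) < 0.01
        assert abs(s.q025 - 0.025) < 0.02

    def test_beta_posterior_mean(self):
        # phi11 for the lung study under the improper prior is beta(14, 4)
        rng = np.random.default_rng(3)
        dm = DrawMatrix(names=("phi11",), draws=rng.beta(14, 4, (50_000, 1)), seed=3)
        assert abs(summarize(dm)["phi11"].mean - 14 / 18) < 0.01

    def test_too_few_draws(self):
        dm = DrawMatrix(names=("x",), draws=np.zeros((40, 1)), seed=0)
        with pytest.raises(ValueError):
            summarize(dm)

    def test_mean_recovery_within_mc_error(self):
        # |mean - mu| < 4 * mc_error should hold in at least 95 of 100 repeats
        mu, sigma = 0.3, 1.7
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(mu, sigma, 5_000)
            dm = DrawMatrix(names=("x",), draws=x[:, None], seed=seed)
            s = summarize(dm)["x"]
            hits += abs(s.mean - mu) < 4 * s.mc_error
        assert hits >= 95

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            DrawMatrix(names=("a", "a"), draws=np.zeros((200, 2)), seed=0)
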