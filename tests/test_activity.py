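"""Enrichment statistic, permutation null, and differential-activity rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfdyngrn.activity import (
    DaTfSet,
    TooFewTargets,
    activity_matrix,
    differential_activity,
    enrichment_table,
    nes,
    permutation_p,
    select_da_tfs,
)
from tfdyngrn.datamodel import DataError, ExpressionMatrix, Regulon


def _signature(values: dict) -> pd.Series:
    return pd.Series(values, dtype=float)


def _regulon(rows) -> Regulon:
    return Regulon(pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"]))


SMALL_REG = _regulon(
    [("T", f"g{i}", 1, 1.0) for i in range(5)]
)


class TestNes:
    def test_zero_signature_gives_zero(self):
        sig = _signature({f"g{i}": 0.0 for i in range(10)})
        assert nes(sig, SMALL_REG, "T").nes == 0.0

    def test_single_target_identity(self):
        reg = _regulon([("T", "g0", 1, 1.0)])
        sig = _signature({"g0": 3.0})
        assert nes(sig, reg, "T", min_targets=1).nes == pytest.approx(3.0)

    def test_two_target_worked_value(self):
        # z = (2, −2), modes (+1, −1), weights 1 → (2·1 + (−2)·(−1))/√2 = 4/√2
        reg = _regulon([("T", "a", 1, 1.0), ("T", "b", -1, 1.0)])
        sig = _signature({"a": 2.0, "b": -2.0})
        assert nes(sig, reg, "T", min_targets=2).nes == pytest.approx(4 / np.sqrt(2))

    def test_linearity_in_signature(self):
        rng = np.random.default_rng(0)
        sig = _signature({f"g{i}": rng.normal() for i in range(10)})
        base = nes(sig, SMALL_REG, "T").nes
        assert nes(2.5 * sig, SMALL_REG, "T").nes == pytest.approx(2.5 * base)

    def test_mode_flip_negates(self):
        rng = np.random.default_rng(1)
        sig = _signature({f"g{i}": rng.normal() for i in range(10)})
        flipped = _regulon([("T", f"g{i}", -1, 1.0) for i in range(5)])
        assert nes(sig, flipped, "T").nes == pytest.approx(-nes(sig, SMALL_REG, "T").nes)

    def test_too_few_measured_targets_raises(self):
        sig = _signature({"g0": 1.0, "g1": 2.0})
        with pytest.raises(TooFewTargets):
            nes(sig, SMALL_REG, "T", min_targets=5)


class TestPermutationP:
    def test_extreme_observed_gets_add_one_minimum(self):
        # five huge target z-values in an otherwise null signature
        values = {f"g{i}": 0.001 * i for i in range(200)}
        for i in range(5):
            values[f"g{i}"] = 50.0 + i
        reg = _regulon([("T", f"g{i}", 1, 1.0) for i in range(5)])
        res = permutation_p(_signature(values), reg, "T", n_perm=1000, seed=3)
        assert res.p == pytest.approx(1 / 1001)

    def test_zero_observed_gives_p_one(self):
        values = {f"g{i}": (1.0 if i >= 100 else 0.0) for i in range(200)}
        reg = _regulon([("T", f"g{i}", 1, 1.0) for i in range(5)])
        res = permutation_p(_signature(values), reg, "T", n_perm=200, seed=4)
        assert res.nes == 0.0
        assert res.p == 1.0

    def test_p_uniform_under_null(self):
        # regulon drawn at random from a standard-normal signature → p ~ U(0,1)
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(300)]
        pvals = []
        for rep in range(200):
            sig = pd.Series(rng.normal(size=300), index=genes)
            targets = rng.choice(genes, size=10, replace=False)
            reg = _regulon([("T", t, 1, 1.0) for t in targets])
            pvals.append(permutation_p(sig, reg, "T", n_perm=1000, seed=rep).p)
        d, _ = stats.kstest(pvals, "uniform")
        critical_5pct = 1.358 / np.sqrt(len(pvals))
        assert d < critical_5pct


class TestActivityMatrix:
    def test_constructed_top_tf(self):
        # TF whose targets are the most up-standardised genes of sample s0
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        data = pd.DataFrame(rng.normal(size=(40, 6)), index=genes,
                            columns=[f"s{i}" for i in range(6)])
        data.iloc[:5, 0] += 10
        std = ExpressionMatrix(
            data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0),
            layer="standardised",
        )
        reg = _regulon(
            [("HOT", g, 1, 1.0) for g in genes[:5]]
            + [("COLD", g, 1, 1.0) for g in genes[5:10]]
        )
        amat = activity_matrix(std, reg)
        assert amat.loc["HOT", "s0"] == amat["s0"].max()

    def test_zero_sample_gives_zero_activity(self):
        data = pd.DataFrame(np.zeros((10, 3)), index=[f"g{i}" for i in range(10)],
                            columns=["s0", "s1", "s2"])
        std = ExpressionMatrix(data, layer="standardised")
        reg = _regulon([("T", f"g{i}", 1, 1.0) for i in range(5)])
        amat = activity_matrix(std, reg)
        assert (amat == 0).all().all()

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(20, 4)), index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(4)])
        std = ExpressionMatrix(data, layer="standardised")
        reg = _regulon([("T", f"g{i}", 1, 1.0) for i in range(8)])
        a1 = activity_matrix(std, reg)
        a2 = activity_matrix(std, reg)
        pd.testing.assert_frame_equal(a1, a2)

    def test_requires_standardised_layer(self):
        data = pd.DataFrame(np.ones((5, 2)), columns=["s0", "s1"])
        with pytest.raises(DataError, match="standardised"):
            activity_matrix(ExpressionMatrix(data, layer="normalised"), SMALL_REG)


def _two_day_design_and_expr(jump_targets, n_genes=60, seed=0):
    """One patient/condition, 2 replicates, 3 days; jump_targets shift at day 8."""
    from tfdyngrn.datamodel import SampleDesign

    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for day in (1, 4, 8):
        for rep in (1, 2):
            sid = f"p1_auto_d{day}_r{rep}"
            rows.append((sid, "p1", "autologous", day, rep))
            cols.append(sid)
    design = SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "patient", "condition", "day", "replicate"]))
    genes = [f"g{i}" for i in range(n_genes)]
    data = pd.DataFrame(rng.normal(50, 1, size=(n_genes, 6)), index=genes, columns=cols)
    for g in jump_targets:
        data.loc[g, ["p1_auto_d8_r1", "p1_auto_d8_r2"]] += 40
    return design, ExpressionMatrix(data, layer="normalised")


class TestDifferentialActivity:
    def test_jump_interval_is_the_significant_one(self):
        targets = [f"g{i}" for i in range(8)]
        design, expr = _two_day_design_and_expr(targets)
        reg = _regulon([("T", g, 1, 1.0) for g in targets])
        table = differential_activity(expr, design, reg, n_perm=500, seed=9)
        by_int = table.set_index(["day_a", "day_b"])
        assert by_int.loc[(4, 8), "score"] != 0
        assert by_int.loc[(1, 4), "score"] == 0

    def test_zeroing_rule_holds_for_every_row(self):
        design, expr = _two_day_design_and_expr([f"g{i}" for i in range(8)])
        reg = _regulon([("T", f"g{i}", 1, 1.0) for i in range(8)]
                       + [("U", f"g{i}", 1, 1.0) for i in range(10, 16)])
        table = differential_activity(expr, design, reg, alpha=0.05, n_perm=200, seed=2)
        zeroed = table["p"] > 0.05
        assert (table.loc[zeroed, "score"] == 0).all()
        assert (table.loc[~zeroed, "score"] == table.loc[~zeroed, "score_raw"]).all()

    def test_missing_interval_skipped_with_warning(self):
        targets = [f"g{i}" for i in range(8)]
        design, expr = _two_day_design_and_expr(targets)
        # drop one replicate of day 4 → interval needs ≥2 per group
        keep = [s for s in design.sample_ids if s != "p1_auto_d4_r2"]
        from tfdyngrn.datamodel import SampleDesign

        design2 = SampleDesign(design.table[design.table["sample_id"].isin(keep)])
        expr2 = ExpressionMatrix(expr.data[keep], layer="normalised")
        reg = _regulon([("T", g, 1, 1.0) for g in targets])
        with pytest.warns(UserWarning, match="skipped"):
            table = differential_activity(expr2, design2, reg, n_perm=100, seed=1)
        assert set(zip(table["day_a"], table["day_b"])) == set()


class TestOraTfTargets:
    def test_query_is_da_tfs_plus_their_targets(self):
        from tfdyngrn.activity import ora_tf_targets

        reg = _regulon([("T1", f"g{i}", 1, 1.0) for i in range(3)]
                       + [("T2", f"h{i}", 1, 1.0) for i in range(3)])
        tags = pd.DataFrame(
            [("T1", "p1", "autologous", 1, 4, 2.0, 2.0, 0.01)],
            columns=["tf", "patient", "condition", "day_a", "day_b",
                     "score_raw", "score", "p"],
        )
        da = DaTfSet(tfs=["T1"], tags=tags)
        universe = {"T1", "T2"} | {f"g{i}" for i in range(3)} | {f"h{i}" for i in range(3)}
        sets = {"T1_like": {"T1", "g0", "g1", "g2"}, "other": {"h0", "h1"}}
        table = ora_tf_targets(da, reg, sets, universe)
        rec = table.set_index("set")
        # query = {T1, g0, g1, g2}: full overlap with its own set, none with the other
        assert rec.loc["T1_like", "k"] == 4 and rec.loc["T1_like", "n"] == 4
        assert rec.loc["other", "k"] == 0
        assert rec.loc["T1_like", "p"] < rec.loc["other", "p"]


class TestSelectDaTfs:
    def _table(self):
        return pd.DataFrame(
            [
                ("T1", "p1", "autologous", 1, 4, 2.0, 2.0, 0.002),
                ("T1", "p1", "autologous", 4, 8, 1.0, 0.0, 0.40),
                ("T2", "p2", "monoculture", 4, 8, -1.5, 0.0, 0.30),
            ],
            columns=["tf", "patient", "condition", "day_a", "day_b",
                     "score_raw", "score", "p"],
        )

    def test_single_hit_included_and_tagged(self):
        da = select_da_tfs(self._table(), alpha=0.05)
        assert da.tfs == ["T1"]
        assert da.conditions_of("T1") == {"autologous"}
        assert da.patients_of("T1") == {"p1"}
        assert da.intervals_of("T1") == {(1, 4)}

    def test_empty_selection_raises(self):
        with pytest.raises(DataError, match="no TF"):
            select_da_tfs(self._table(), alpha=1e-9)
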