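"""Random-effects synthesis: harmonization, REML, BH, export formats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from txmeta import metamodel
from txmeta.metamodel import (
    CI_Z,
    EffectMatrix,
    bh_adjust,
    forest_data,
    harmonize,
    presence_filter,
    rem_fit,
    results_table,
    run_meta,
)
from txmeta.published import top_genes


def _de(genes, log2fc, se):
    return pd.DataFrame(
        {"log2fc": log2fc, "se": se},
        index=pd.Index([str(g) for g in genes], name="gene_id"),
    )


def _ortholog(keys, mouse=None, rat=None):
    return pd.DataFrame(
        {
            "harmonized_key": keys,
            "mouse_entrez": mouse if mouse is not None else keys,
            "rat_entrez": rat if rat is not None else [f"r{k}" for k in keys],
        }
    )


def _effects(y, v, studies=None):
    y = pd.DataFrame(y)
    v = pd.DataFrame(v)
    if studies:
        y.columns = v.columns = studies
    y.index = v.index = [f"g{i}" for i in range(len(y))]
    return EffectMatrix(y, v)


class TestHarmonize:
    def test_identity_map_passthrough(self):
        de = {"A": _de(["10", "11"], [0.5, -0.2], [0.1, 0.2])}
        eff, drop = harmonize(de, _ortholog(["10", "11"]), {"A": "mouse"})
        assert list(eff.y.index) == ["10", "11"]
        assert eff.y.loc["10", "A"] == 0.5
        assert eff.v.loc["11", "A"] == pytest.approx(0.04)
        assert len(drop) == 0

    def test_unmapped_gene_dropped_and_logged(self):
        ortho = _ortholog(["10"], mouse=["10"], rat=[pd.NA])
        de = {"R": _de(["999"], [0.3], [0.1])}
        eff, drop = harmonize(de, ortho, {"R": "rat"})
        assert len(eff.y) == 0
        assert drop.iloc[0]["gene_id"] == "999"
        assert drop.iloc[0]["reason"] == "no ortholog"

    def test_dual_species_ids_share_one_row(self):
        # rat 24827 and mouse 21802 both land on the harmonized Tgfa key
        ortho = _ortholog(["21802"], mouse=["21802"], rat=["24827"])
        de = {
            "M": _de(["21802"], [-0.4], [0.1]),
            "R": _de(["24827"], [-0.3], [0.12]),
        }
        eff, _ = harmonize(de, ortho, {"M": "mouse", "R": "rat"})
        assert list(eff.y.index) == ["21802"]
        assert eff.k.loc["21802"] == 2

    def test_colliding_native_ids_raise(self):
        ortho = pd.DataFrame(
            {
                "harmonized_key": ["k", "k"],
                "mouse_entrez": ["10", "11"],
                "rat_entrez": ["20", "21"],
            }
        )
        de = {"M": _de(["10", "11"], [0.1, 0.2], [0.1, 0.1])}
        with pytest.raises(ValueError, match="multiple native IDs"):
            harmonize(de, ortho, {"M": "mouse"})


class TestPresenceFilter:
    def test_four_of_five_retained_three_dropped(self):
        y = np.full((2, 5), 0.3)
        v = np.full((2, 5), 0.01)
        y[0, 4] = np.nan
        v[0, 4] = np.nan
        y[1, 3:] = np.nan
        v[1, 3:] = np.nan
        eff = presence_filter(_effects(y, v), min_k=4)
        assert list(eff.y.index) == ["g0"]

    def test_min_k_two_keeps_everything(self):
        y = np.full((3, 2), 0.1)
        v = np.full((3, 2), 0.02)
        eff = presence_filter(_effects(y, v), min_k=2)
        assert len(eff.y) == 3

    def test_min_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            presence_filter(_effects(np.ones((1, 3)), np.full((1, 3), 0.1)), min_k=1)


class TestRemFit:
    def test_homogeneous_closed_form(self):
        res = rem_fit([0.5] * 4, [0.1] * 4)
        assert res.estimate == pytest.approx(0.5)
        assert res.tau2 == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.1 / 4))
        assert res.converged and res.method == "reml"

    def test_matches_grid_search_oracle(self):
        # brute-force REML profile over a fine tau^2 grid
        rng = np.random.default_rng(31)
        grid = np.arange(0.0, 1.0 + 1e-5, 1e-5)
        for _ in range(10):
            v = rng.uniform(0.002, 0.05, 5)
            y = 0.3 + rng.normal(0, 0.12, 5) + rng.normal(0, np.sqrt(v))
            res = rem_fit(y, v)
            vv = v[None, :] + grid[:, None]
            w = 1.0 / vv
            mu = (w * y).sum(axis=1) / w.sum(axis=1)
            ll = -0.5 * (
                np.log(vv).sum(axis=1)
                + np.log(w.sum(axis=1))
                + (w * (y - mu[:, None]) ** 2).sum(axis=1)
            )
            best = int(np.argmax(ll))
            assert res.tau2 == pytest.approx(grid[best], abs=1e-4)
            assert res.estimate == pytest.approx(mu[best], abs=1e-4)

    def test_fixed_zero_tau2_equals_inverse_variance_pooling(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0.2, 0.3, 6)
        v = rng.uniform(0.01, 0.2, 6)
        res = rem_fit(y, v, fixed_tau2=0.0)
        w = 1.0 / v
        assert res.estimate == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-10)
        assert res.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-10)

    def test_ci_arithmetic_reproduces_published_rounding(self):
        # the Cldn11 row: -0.30 +/- 1.96 * 0.06 -> (-0.42, -0.18) at 2 dp
        row = top_genes().set_index("symbol").loc["Cldn11"]
        lb = row["estimate"] - CI_Z * row["se"]
        ub = row["estimate"] + CI_Z * row["se"]
        assert round(lb, 2) == row["ci_lb"]
        assert round(ub, 2) == row["ci_ub"]

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            rem_fit([0.1, 0.2], [0.05, 0.0])
        with pytest.raises(ValueError):
            rem_fit([0.1], [0.05])

    def test_estimates_invariant_to_study_order(self):
        rng = np.random.default_rng(55)
        y = rng.normal(0, 0.4, 5)
        v = rng.uniform(0.005, 0.05, 5)
        a = rem_fit(y, v)
        perm = [3, 0, 4, 2, 1]
        b = rem_fit(y[perm], v[perm])
        assert a.estimate == pytest.approx(b.estimate, abs=1e-10)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-8)


class TestBHAdjust:
    def test_published_top_p_value_reproduced(self):
        # smallest printed p among m = 11,885 tests adjusts to 0.00114
        p = top_genes()["p"].to_numpy()
        q = bh_adjust(p, m=11_885)
        assert float(f"{q.min():.3g}") == 0.00114

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_against_statsmodels(self, rng):
        p = rng.uniform(size=500)
        assert bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        for rank_pos, idx in enumerate(order):
            # O(m^2) step-up: min over all suffix ranks
            expected = min(
                min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_pos, m)
            )
            assert q[idx] == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=60))
    def test_monotone_and_dominates_p(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)


class TestRunMeta:
    def test_all_genes_stable(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.3, (20, 5))
        v = rng.uniform(0.005, 0.05, (20, 5))
        table, unstable = run_meta(_effects(y, v))
        assert len(table) == 20 and unstable == []
        assert "fdr" in table.columns

    def test_unstable_gene_excluded_from_fdr_family(self, monkeypatch):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.3, (5, 5))
        v = rng.uniform(0.005, 0.05, (5, 5))
        eff = _effects(y, v)
        real = metamodel.rem_fit

        def flaky(y, v, **kwargs):
            res = real(y, v, **kwargs)
            if abs(y[0] - eff.y.iloc[2, 0]) < 1e-12:
                raise ValueError("pathological sampling variances")
            return res

        monkeypatch.setattr(metamodel, "rem_fit", flaky)
        table, unstable = run_meta(eff)
        assert unstable == ["g2"]
        assert len(table) == 4

    def test_study_order_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 0.3, (10, 5))
        v = rng.uniform(0.005, 0.05, (10, 5))
        studies = ["A", "B", "C", "D", "E"]
        t1, _ = run_meta(_effects(y, v, studies))
        perm = ["D", "A", "E", "C", "B"]
        e2 = _effects(y, v, studies)
        t2, _ = run_meta(EffectMatrix(e2.y[perm], e2.v[perm]))
        pd.testing.assert_series_equal(t1["estimate"], t2["estimate"], atol=1e-10)


class TestResultsTable:
    def test_empty_input_writes_header_only(self, tmp_path):
        empty, _ = run_meta(
            _effects(np.empty((0, 5)), np.empty((0, 5)))
        )
        path = tmp_path / "meta.tsv"
        results_table(empty, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("harmonized_key\t")

    def test_sorted_by_estimate_with_tier_counts(self):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 0.4, (30, 5))
        v = rng.uniform(0.001, 0.01, (30, 5))
        table, _ = run_meta(_effects(y, v))
        out = results_table(table)
        est = out["estimate"].to_numpy()
        assert np.all(np.diff(est) >= 0)
        fdr = out["fdr"].to_numpy()
        assert (out["significance"] == "FDR<0.05").sum() == (fdr < 0.05).sum()
        assert (out["significance"] == "FDR<0.1").sum() == (
            ((fdr >= 0.05) & (fdr < 0.10)).sum()
        )


class TestForestData:
    def test_single_study_ci_half_width(self):
        y = np.array([[0.2, 0.1, 0.3, -0.1, 0.0]])
        v = np.full((1, 5), 0.01)
        eff = _effects(y, v)
        table, _ = run_meta(eff)
        rec = forest_data(eff, table.iloc[0])
        study_rows = rec[rec["label"] != "RE Model"]
        half = (study_rows["ci_ub"] - study_rows["log2fc"]).to_numpy()
        assert half == pytest.approx(0.196, abs=5e-4)

    def test_summary_row_equals_meta_row(self):
        rng = np.random.default_rng(9)
        eff = _effects(rng.normal(0, 0.3, (3, 5)), rng.uniform(0.005, 0.05, (3, 5)))
        table, _ = run_meta(eff)
        row = table.iloc[1]
        rec = forest_data(eff, row)
        summary = rec[rec["label"] == "RE Model"].iloc[0]
        assert summary["log2fc"] == row["estimate"]
        assert summary["ci_lb"] == row["ci_lb"]
        assert summary["ci_ub"] == row["ci_ub"]

    def test_five_study_record_matches_hand_build(self):
        y = np.array([[0.1, 0.2, np.nan, 0.4, 0.5]])
        v = np.array([[0.01, 0.02, np.nan, 0.04, 0.05]])
        eff = _effects(y, v, ["A", "B", "C", "D", "E"])
        table, _ = run_meta(eff, )
        rec = forest_data(eff, table.iloc[0])
        assert rec["label"].tolist() == ["A", "B", "D", "E", "RE Model"]
        assert rec.iloc[1]["ci_lb"] == pytest.approx(0.2 - CI_Z * np.sqrt(0.02))

    def test_unknown_gene_rejected(self):
        eff = _effects(np.ones((2, 5)) * 0.1, np.full((2, 5), 0.01))
        table, _ = run_meta(eff)
        ghost = table.iloc[0].copy()
        ghost.name = "nope"
        with pytest.raises(KeyError):
            forest_data(eff, ghost)
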