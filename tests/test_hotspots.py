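"""Residual z-scores, BH FDR, gene annotation, Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmut.grid import build_windows
from regmut.hotspots import (
    annotate_genes,
    cancer_gene_enrichment,
    fisher_enrichment,
    score_residuals,
)


def _bh_oracle(p):
    """Step-up BH by explicit sort, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestScoreResiduals:
    def test_mean_residual_maps_to_half(self):
        obs = np.array([5.0] * 9 + [10.0])
        exp = np.array([3.0] * 9 + [8.0])  # residuals all equal 2
        with pytest.raises(ValueError, match="zero residual variance"):
            score_residuals(obs, exp)

    def test_hand_computed_z(self):
        obs = np.concatenate([np.zeros(3), [10.0], np.zeros(6) + 1])
        exp = np.concatenate([np.zeros(3), [0.0], np.zeros(6) + 1])
        # residuals: (0,0,0,10,0,...,0); check against direct formula
        t = score_residuals(obs, exp)
        resid = obs - exp
        z_direct = (10 - resid.mean()) / resid.std(ddof=1)
        top = t.iloc[0]
        assert top["residual"] == 10
        assert top["z"] == pytest.approx(z_direct)
        assert top["p"] == pytest.approx(stats.norm.sf(z_direct))

    def test_four_residual_example(self):
        # residuals (0,0,0,10): sample sd 5, mean 2.5 -> z=1.5, p~0.0668
        resid = np.array([0.0, 0, 0, 10])
        z = (resid - resid.mean()) / resid.std(ddof=1)
        assert z[-1] == pytest.approx(1.5)
        assert stats.norm.sf(z[-1]) == pytest.approx(0.0668, abs=2e-4)

    def test_bh_step_up_hand_example(self):
        q = _bh_oracle([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 1000))
            obs = rng.normal(size=n)
            exp = rng.normal(size=n)
            t = score_residuals(obs, exp).sort_values("window")
            resid = obs - exp
            z = (resid - resid.mean()) / resid.std(ddof=1)
            p = stats.norm.sf(z)
            np.testing.assert_allclose(t["z"].to_numpy(), z, atol=1e-12)
            np.testing.assert_allclose(t["p"].to_numpy(), p, atol=1e-12)
            np.testing.assert_allclose(t["q"].to_numpy(), _bh_oracle(p), atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        obs = rng.normal(size=200)
        t = score_residuals(obs, np.zeros(200)).sort_values("p")
        assert (np.diff(t["q"].to_numpy()) >= -1e-15).all()
        assert (t["q"] >= t["p"] - 1e-15).all()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            score_residuals(np.arange(5.0), np.zeros(5))


class TestAnnotateGenes:
    def test_gene_window_overlap_and_min_p_rule(self):
        g = build_windows({"chr1": 12_000_000}, 1_000_000)
        obs = np.full(12, 5.0)
        obs[0] = 60.0
        table = score_residuals(obs, np.full(12, 5.0), grid=g)
        genes = pd.DataFrame(
            [
                {"gene_id": "inside", "chrom": "chr1", "start": 100, "end": 5000},
                {"gene_id": "spanning", "chrom": "chr1", "start": 900_000, "end": 1_200_000},
                {"gene_id": "elsewhere", "chrom": "chr2", "start": 0, "end": 100},
            ]
        )
        annotated, gene_table = annotate_genes(table, genes, g)
        gt = gene_table.set_index("gene_id")
        p0 = table.set_index("window").loc[0, "p"]
        assert gt.loc["inside", "p"] == pytest.approx(p0)
        # spanning gene takes the smaller of windows 0 and 1
        assert gt.loc["spanning", "p"] == pytest.approx(p0)
        assert "elsewhere" not in gt.index
        row0 = annotated.set_index("window").loc[0]
        assert "inside" in row0["genes"] and "spanning" in row0["genes"]


class TestFisherEnrichment:
    def test_worked_example_top_predictor_classes(self):
        expected, odds, p = fisher_enrichment(111, 166, 421, 869)
        assert round(expected) == 80
        assert p == pytest.approx(8.7e-8, rel=0.05)

    def test_all_items_labelled_p_one(self):
        _, _, p = fisher_enrichment(3, 3, 10, 10)
        assert p == pytest.approx(1.0)

    def test_small_enumeration(self):
        # N=4, K=2, n=2: P(X>=1) = 1 - C(2,2)/C(4,2) = 5/6
        _, _, p = fisher_enrichment(1, 2, 2, 4)
        assert p == pytest.approx(5 / 6)

    def test_expected_formula(self):
        expected, _, _ = fisher_enrichment(2, 10, 30, 100)
        assert expected == pytest.approx(3.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_enrichment(5, 4, 10, 20)
        with pytest.raises(ValueError, match="inconsistent"):
            fisher_enrichment(1, 15, 3, 10)

    def test_two_sided_option(self):
        _, _, p1 = fisher_enrichment(8, 10, 20, 100)
        _, _, p2 = fisher_enrichment(8, 10, 20, 100, alternative="two-sided")
        assert 0 < p1 <= p2 + 1e-12 and p2 <= 1


def test_cancer_gene_enrichment_pipeline(rng):
    g = build_windows({"chr1": 20_000_000}, 1_000_000)
    obs = np.full(20, 10.0)
    obs[[3, 7]] = 100.0  # two clear hotspot windows
    table = score_residuals(obs, np.full(20, 10.0), grid=g)
    genes = pd.DataFrame(
        [
            {"gene_id": f"G{i}", "chrom": "chr1", "start": i * 1_000_000 + 1000,
             "end": i * 1_000_000 + 50_000}
            for i in range(20)
        ]
    )
    _, gene_table = annotate_genes(table, genes, g)
    res = cancer_gene_enrichment(gene_table, genes, cancer_genes={"G3", "G7"})
    assert res["n_cancer_gene_hits"] == 2
    assert res["p"] < 0.02


def test_cancer_gene_enrichment_recovered_on_planted_data():
    """Hotspots are planted preferentially on flagged cancer genes, so
    the one-sided enrichment must reach p < 0.01 in >= 90% of
    replicates."""
    from regmut.burden import PAN_CANCER, count_burden
    from regmut.models import ModelSpec, fit_forest
    from regmut.synthdata import default_scenario

    hits = 0
    n_rep = 10
    for rep in range(n_rep):
        scen = default_scenario(seed=7000 + rep)
        y = count_burden(scen["snvs"], scen["grid"], PAN_CANCER).counts
        fit = fit_forest(scen["X"], y, ModelSpec(n_trees=100, seed=rep))
        table = score_residuals(y, fit.oob_prediction, grid=scen["grid"])
        genes = scen["genes"][["gene_id", "chrom", "start", "end"]]
        _, gene_table = annotate_genes(table, genes, scen["grid"])
        res = cancer_gene_enrichment(
            gene_table, genes, set(scen["truth"].cancer_genes)
        )
        hits += int(res["p"] < 0.01)
    assert hits >= 0.9 * n_rep, f"enrichment significant in {hits}/{n_rep}"
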