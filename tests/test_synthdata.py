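"""Planted-truth generator: determinism, conservation, recovery hooks."""

import numpy as np
import pandas as pd
import pytest

from regmut.burden import count_burden, PAN_CANCER
from regmut.grid import WindowGrid
from regmut.signatures import signature_burden, conservation_check
from regmut.synthdata import (
    SyntheticTruth,
    default_scenario,
    generate_genes,
    generate_grid,
    generate_mutations,
    generate_tracks,
    write_dataset,
)

SMALL = dict(n_chroms=3, chrom_length=30_000_000)  # 90 windows


@pytest.fixture(scope="module")
def scenario():
    return default_scenario(seed=77, **SMALL)


class TestDeterminism:
    def test_tracks_reproducible(self):
        g = generate_grid(**SMALL, seed=1)
        t1, _ = generate_tracks(g, seed=5)
        t2, _ = generate_tracks(g, seed=5)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_scenario_reproducible(self, scenario):
        other = default_scenario(seed=77, **SMALL)
        pd.testing.assert_frame_equal(scenario["snvs"], other["snvs"])
        pd.testing.assert_frame_equal(scenario["X"], other["X"])
        pd.testing.assert_frame_equal(scenario["genes"], other["genes"])

    def test_different_seeds_differ(self):
        a = default_scenario(seed=1, **SMALL)
        b = default_scenario(seed=2, **SMALL)
        assert not a["X"].equals(b["X"])


class TestTracks:
    def test_zero_noise_track_equals_latent(self):
        g = generate_grid(**SMALL, seed=1)
        tracks, truth = generate_tracks(
            g, n_cancer=1, n_normal=0, n_rt=0, a_cancer=1.0, noise_sd=0.0, seed=3
        )
        np.testing.assert_allclose(tracks[0].values, truth.latent_ca)

    def test_noise_degrades_latent_correlation(self):
        g = generate_grid(n_chroms=5, chrom_length=100_000_000, seed=1)
        cors = []
        for sd in (0.1, 1.0, 3.0):
            tracks, truth = generate_tracks(
                g, n_cancer=1, n_normal=0, n_rt=0, noise_sd=sd, seed=3
            )
            cors.append(abs(np.corrcoef(tracks[0].values, truth.latent_ca)[0, 1]))
        assert cors[0] > cors[1] > cors[2]

    def test_track_effect_signs(self, scenario):
        eff = scenario["truth"].track_effects
        assert all(eff[t] < 0 for t in scenario["arms"]["cancer_CA"])
        late = [t for t in eff if t.startswith(("RT_S3", "RT_S4", "RT_G2"))]
        early = [t for t in eff if t.startswith(("RT_G1b", "RT_S1", "RT_S2"))]
        assert late and all(eff[t] > 0 for t in late)
        assert early and all(eff[t] < 0 for t in early)


class TestMutations:
    def test_posteriors_sum_to_one(self, scenario):
        sig_cols = [c for c in scenario["probs"].columns if c.startswith("SBS")]
        total = scenario["probs"][sig_cols].to_numpy().sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_positions_inside_their_windows(self, scenario):
        grid: WindowGrid = scenario["grid"]
        idx = grid.window_index(
            scenario["snvs"]["chrom"].to_numpy(dtype=object),
            scenario["snvs"]["pos"].to_numpy() - 1,
        )
        assert (idx >= 0).all()

    def test_signature_burden_conserves_counts(self, scenario):
        b = signature_burden(
            scenario["snvs"], scenario["probs"], scenario["grid"], PAN_CANCER
        )
        allv = count_burden(scenario["snvs"], scenario["grid"], PAN_CANCER)
        assert conservation_check(b, allv.counts)

    def test_expected_burden_tracks_observed(self, scenario):
        y = count_burden(scenario["snvs"], scenario["grid"], PAN_CANCER).counts
        rho = np.corrcoef(y, scenario["truth"].expected_burden)[0, 1]
        assert rho > 0.8

    def test_hotspots_have_excess_counts(self, scenario):
        y = count_burden(scenario["snvs"], scenario["grid"], PAN_CANCER).counts
        truth = scenario["truth"]
        hot = truth.hotspot_windows
        base = truth.expected_burden[hot] / truth.hotspot_factor
        assert (y[hot] > base * 1.5).mean() >= 0.8

    def test_null_scenario_uncorrelated(self):
        scen = default_scenario(seed=5, beta_ca=0.0, beta_rt=0.0, hotspot_factor=1.0)
        y = count_burden(scen["snvs"], scen["grid"], PAN_CANCER).counts
        rho = np.corrcoef(y, scen["truth"].latent_ca)[0, 1]
        assert abs(rho) < 0.15  # ~3 sd of a null correlation at n=500

    def test_expected_value_burden_unbiased_for_true_labels(self):
        """Summed posteriors per window estimate the true per-signature
        counts without systematic bias (averaged over replicates)."""
        errs = []
        for seed in range(5):
            scen = default_scenario(seed=900 + seed, **SMALL)
            b = signature_burden(
                scen["snvs"], scen["probs"], scen["grid"], PAN_CANCER
            )
            truth_counts = (
                scen["snvs"].groupby("true_signature").size().reindex(b.keys()).fillna(0)
            )
            for s, vec in b.items():
                errs.append(vec.total - truth_counts[s])
        mean_count = np.mean(
            [default_scenario(seed=900, **SMALL)["snvs"].shape[0] / 3]
        )
        assert abs(np.mean(errs)) < 0.02 * mean_count


class TestGenes:
    def test_every_hotspot_window_has_a_gene(self, scenario):
        genes = scenario["genes"]
        assert set(scenario["truth"].hotspot_windows) <= set(genes["window"])

    def test_cancer_gene_count(self, scenario):
        genes = scenario["genes"]
        assert genes["is_cancer_gene"].sum() == scenario["truth"].params["n_cancer_genes"]

    def test_zero_bias_gives_unenriched_flags(self):
        g = generate_grid(**SMALL, seed=1)
        _, truth = generate_tracks(g, seed=2)
        generate_mutations(g, truth, seed=3)
        hits = 0
        total = 0
        for s in range(30):
            genes = generate_genes(g, truth, n_genes=50, n_cancer_genes=10,
                                   hotspot_bias=0.0, seed=s)
            on_hot = genes["window"].isin(set(truth.hotspot_windows))
            hits += int((genes["is_cancer_gene"] & on_hot).sum())
            total += int(on_hot.sum())
        # flags independent of hotspots: ~20% of hotspot genes flagged
        assert hits / total == pytest.approx(0.2, abs=0.08)

    def test_gene_bounds_inside_grid(self, scenario):
        grid = scenario["grid"]
        genes = scenario["genes"]
        for _, g in genes.iterrows():
            w = int(g["window"])
            assert grid.starts[w] <= g["start"] < g["end"] <= grid.ends[w]


class TestRoundTrip:
    def test_written_dataset_parses_back(self, scenario, tmp_path):
        from regmut import io as rio

        paths = write_dataset(scenario, tmp_path)
        grid = rio.read_grid(paths["grid"])
        assert len(grid) == len(scenario["grid"])
        tracks = rio.read_track_matrix(tmp_path / "tracks")
        assert len(tracks) == len(scenario["tracks"])
        assert tracks[0].feature_class == scenario["tracks"][0].feature_class
        snvs = rio.read_mutations(paths["mutations"])
        assert len(snvs) == len(scenario["snvs"])
        probs = rio.read_signature_probabilities(paths["probs"])
        assert len(probs) == len(scenario["probs"])
        genes = rio.read_genes_bed(paths["genes"])
        assert set(genes["gene_id"]) == set(scenario["genes"]["gene_id"])
        cg = rio.read_gene_list(paths["cancer_genes"])
        assert cg == set(scenario["truth"].cancer_genes)
        truth = SyntheticTruth.from_json(paths["truth"])
        np.testing.assert_array_equal(
            truth.hotspot_windows, scenario["truth"].hotspot_windows
        )
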