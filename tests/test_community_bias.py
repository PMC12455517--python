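"""Filtering, abundance comparison, rarefaction, Hellinger-PCoA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from amplihijack.community_bias import (
    FeatureTable,
    FilterParams,
    compare_with_without,
    filter_features,
    hellinger_distances,
    hellinger_pcoa,
    mean_distance_to_centroid,
    rarefaction_curve,
    relative_abundance,
)


def _table(counts: dict, taxonomy: dict | None = None) -> FeatureTable:
    tax = None
    if taxonomy is not None:
        tax = pd.DataFrame.from_dict(taxonomy, orient="index")
    return FeatureTable(counts=pd.DataFrame(counts).T, taxonomy=tax)


class TestFilterFeatures:
    def test_low_abundance_genus_removed(self):
        # GenusB peaks at 0.005% relative abundance, below the 0.01% cut
        t = _table(
            {"f1": {"S1": 999_950, "S2": 999_950},
             "f2": {"S1": 50, "S2": 30}},
            {"f1": {"phylum": "P", "genus": "GenusA", "organelle": False},
             "f2": {"phylum": "P", "genus": "GenusB", "organelle": False}},
        )
        res = filter_features(t)
        assert "f2" not in res.table.feature_ids
        row = res.log[res.log["id"] == "GenusB"].iloc[0]
        assert row["reason"] == "max_abundance"

    def test_rare_prevalence_genus_removed(self):
        counts = {"f1": {f"S{i}": 100 for i in range(200)}}
        counts["f2"] = {f"S{i}": 0 for i in range(200)}
        counts["f2"]["S0"] = 90  # present in 0.5% of 200 samples
        t = _table(counts,
                   {"f1": {"phylum": "P", "genus": "GenusA", "organelle": False},
                    "f2": {"phylum": "P", "genus": "GenusB", "organelle": False}})
        res = filter_features(t)
        assert "f2" not in res.table.feature_ids
        assert (res.log["reason"] == "prevalence").any()

    def test_organelle_and_unassigned_dropped(self):
        t = _table(
            {"f1": {"S1": 100}, "mito": {"S1": 50}, "mystery": {"S1": 40}},
            {"f1": {"phylum": "P", "genus": "GenusA", "organelle": False},
             "mito": {"phylum": "P", "genus": "Mitochondria", "organelle": True},
             "mystery": {"phylum": "", "genus": "GenusX", "organelle": False}},
        )
        res = filter_features(t)
        assert res.table.feature_ids == ["f1"]
        reasons = set(res.log["reason"])
        assert {"organelle", "unassigned_phylum"} <= reasons

    def test_idempotent(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.integers(0, 2000, size=(30, 8)),
                              index=[f"f{i}" for i in range(30)],
                              columns=[f"S{i}" for i in range(8)])
        tax = pd.DataFrame({
            "phylum": ["P"] * 30,
            "genus": [f"G{i % 10}" for i in range(30)],
            "organelle": [False] * 30,
        }, index=counts.index)
        t = FeatureTable(counts=counts, taxonomy=tax)
        once = filter_features(t)
        twice = filter_features(once.table)
        assert once.table.feature_ids == twice.table.feature_ids
        assert twice.log[twice.log["level"] == "genus"].empty

    def test_empty_result_is_error(self):
        t = _table({"f1": {"S1": 100}},
                   {"f1": {"phylum": "P", "genus": "Mito", "organelle": True}})
        with pytest.raises(ValueError, match="survive"):
            filter_features(t)

    def test_taxonomy_required_for_taxonomy_drops(self):
        t = FeatureTable(counts=pd.DataFrame({"S1": [1]}, index=["f1"]))
        with pytest.raises(ValueError, match="taxonomy"):
            filter_features(t)
        res = filter_features(t, FilterParams(drop_unassigned_phylum=False,
                                              drop_organelles=False))
        assert res.table.feature_ids == ["f1"]


class TestCompareWithWithout:
    def test_denominator_arithmetic(self):
        t = _table(
            {"m1": {"S1": 50}, "m2": {"S1": 30}, "host": {"S1": 20}},
            {"m1": {"phylum": "P", "genus": "GenusA", "organelle": False},
             "m2": {"phylum": "P", "genus": "GenusB", "organelle": False}},
        )
        out = compare_with_without(t, {"host"})
        assert out.loc["GenusA", "mean_retained"] == pytest.approx(0.50)
        assert out.loc["GenusA", "mean_removed"] == pytest.approx(0.625)

    def test_empty_host_set_is_identity(self):
        t = _table({"m1": {"S1": 70}, "m2": {"S1": 30}})
        out = compare_with_without(t, set())
        assert np.allclose(out["delta"].abs(), 0.0)

    def test_all_host_rejected(self):
        t = _table({"h1": {"S1": 10}})
        with pytest.raises(ValueError, match="microbial"):
            compare_with_without(t, {"h1"})

    def test_abundances_sum_to_one_per_sample_in_both_modes(self):
        rng = np.random.default_rng(14)
        counts = pd.DataFrame(rng.integers(1, 500, size=(12, 5)),
                              index=[f"f{i}" for i in range(12)],
                              columns=[f"S{i}" for i in range(5)])
        t = FeatureTable(counts=counts)
        host = {"f0", "f1"}
        host_tab, microb_tab = t.partition(host)
        retained = pd.concat([microb_tab.genus_table(),
                              host_tab.counts.sum(axis=0).rename("host").to_frame().T])
        assert np.allclose(relative_abundance(retained).sum(axis=0), 1.0)
        assert np.allclose(
            relative_abundance(microb_tab.genus_table()).sum(axis=0), 1.0)

    def test_removed_mode_never_below_retained(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            counts = pd.DataFrame(
                rng.integers(0, 300, size=(15, 6)) + 1,
                index=[f"f{i}" for i in range(15)],
                columns=[f"S{i}" for i in range(6)])
            t = FeatureTable(counts=counts)
            host = {f"f{i}" for i in rng.choice(15, size=4, replace=False)}
            out = compare_with_without(t, host)
            microbial = out.drop(index="host_offtarget", errors="ignore")
            nonzero = microbial[microbial["mean_retained"] > 0]
            assert (nonzero["delta"] > 0).all()  # host reads present everywhere


class TestRarefaction:
    def test_single_genus_flat_curve(self):
        r = rarefaction_curve({"g1": 1000}, step=100)
        assert all(v == pytest.approx(1.0) for _, v in r.curve)
        assert r.final_slope == pytest.approx(0.0)
        assert r.saturated

    def test_all_singletons_identity_curve(self):
        r = rarefaction_curve({f"g{i}": 1 for i in range(1000)}, step=100)
        for depth, value in r.curve:
            assert value == pytest.approx(depth)
        assert r.final_slope == pytest.approx(1.0)
        assert not r.saturated

    def test_below_two_steps_unevaluable(self):
        r = rarefaction_curve({"g1": 150}, step=100, sample_id="tiny")
        assert not r.evaluable
        assert r.saturated is None

    def test_curve_nondecreasing(self):
        rng = np.random.default_rng(16)
        counts = {f"g{i}": int(c) for i, c in
                  enumerate(rng.integers(1, 500, size=25))}
        r = rarefaction_curve(counts, step=50)
        values = [v for _, v in r.curve]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_analytic_curve_within_monte_carlo_ci(self):
        """Analytic expected richness sits inside the 99% CI of 10,000
        hypergeometric subsampling replicates."""
        rng = np.random.default_rng(17)
        counts = rng.integers(1, 200, size=20)
        N = int(counts.sum())
        r = rarefaction_curve({f"g{i}": int(c) for i, c in enumerate(counts)},
                              step=max(100, N // 10))
        reps = 10_000
        for depth, expected in r.curve[:-1]:
            draws = rng.multivariate_hypergeometric(counts, depth, size=reps)
            richness = (draws > 0).sum(axis=1)
            se = richness.std(ddof=1) / np.sqrt(reps)
            assert abs(richness.mean() - expected) <= max(2.58 * se, 1e-9)


class TestHellingerPcoa:
    def test_identical_samples_distance_zero(self):
        counts = pd.DataFrame({"S1": [10, 20, 30], "S2": [10, 20, 30]},
                              index=["a", "b", "c"])
        dm = hellinger_distances(counts)
        assert dm.loc["S1", "S2"] == pytest.approx(0.0)
        res = hellinger_pcoa(counts, k=2)
        assert np.allclose(res.coordinates.loc["S1"], res.coordinates.loc["S2"])

    def test_disjoint_samples_reach_sqrt_two(self):
        counts = pd.DataFrame({"S1": [100, 0], "S2": [0, 50]}, index=["a", "b"])
        dm = hellinger_distances(counts)
        assert dm.loc["S1", "S2"] == pytest.approx(np.sqrt(2.0))

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"S1": [10], "empty": [0]}, index=["a"])
        with pytest.raises(ValueError, match="empty"):
            hellinger_distances(counts)

    def test_distances_reconstructed_from_coordinates(self):
        """Gower double-centering identity: full-rank coordinates
        reproduce the input distances to 1e-10 relative error."""
        rng = np.random.default_rng(18)
        counts = pd.DataFrame(rng.integers(1, 400, size=(12, 7)),
                              index=[f"t{i}" for i in range(12)],
                              columns=[f"S{i}" for i in range(7)])
        res = hellinger_pcoa(counts, k=7)
        coords = res.coordinates.to_numpy()
        rec = squareform(pdist(coords))
        want = res.distance_matrix.to_numpy()
        scale = want.max()
        assert np.allclose(rec, want, atol=1e-10 * max(scale, 1.0))

    def test_metric_axioms_on_random_tables(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            counts = pd.DataFrame(rng.integers(0, 100, size=(10, 6)) + 1,
                                  columns=[f"S{i}" for i in range(6)])
            d = hellinger_distances(counts).to_numpy()
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= -1e-12).all()
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_eigenvalues_descending_and_proportions_positive(self):
        rng = np.random.default_rng(20)
        counts = pd.DataFrame(rng.integers(1, 100, size=(8, 5)),
                              columns=[f"S{i}" for i in range(5)])
        res = hellinger_pcoa(counts, k=3)
        eig = res.eigenvalues
        assert all(a >= b - 1e-12 for a, b in zip(eig, eig[1:]))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_offtarget_contamination_inflates_dispersion(self, study_system):
        """On the seeded contaminated cohort, sample dispersion with host
        off-targets retained exceeds dispersion after their removal."""
        import numpy as np

        from amplihijack.synthetic_data import (
            make_feature_tables,
            simulate_pcr_reads,
        )

        cfg = study_system["config"]
        rng = np.random.default_rng(99)
        samples = {}
        for i in range(6):
            factor = float(np.exp(rng.normal(0.0, 1.5)))
            samples[f"S{i}"] = simulate_pcr_reads(
                study_system["truths"], study_system["community"],
                study_system["abundances"], cfg, rng,
                kitome=study_system["kitome"], host_copy_factor=factor)
        table, host_ids = make_feature_tables(samples, study_system["templates"])
        with_host = hellinger_pcoa(table)
        _, microb = table.partition(host_ids)
        without = hellinger_pcoa(microb)
        assert (mean_distance_to_centroid(with_host.distance_matrix)
                >= mean_distance_to_centroid(without.distance_matrix))
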