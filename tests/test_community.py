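import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lakeprod.community import (
    EcoplatePlate,
    WaterSample,
    awcd,
    class_utilization,
    composition_pca,
    ecoplate_class_map,
    ward_cluster,
)
from lakeprod.synthetic import gen_ecoplate, gen_ion_table


def _sample(label, **over):
    base = dict(na=22000.0, k=1300.0, mg=100.0, ca=2.0, so4=250.0,
                cl=27500.0, tal=14000.0)
    base.update(over)
    return WaterSample(label=label, **base)


class TestWardClustering:
    def test_identical_samples_merge_at_zero(self):
        clust = ward_cluster([_sample("a"), _sample("b")])
        assert clust.merge_heights[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_sample_degenerate_tree(self):
        clust = ward_cluster([_sample("only")])
        assert len(clust.merge_heights) == 0
        assert clust.to_newick() == "only;"
        assert list(clust.cut(1)) == [1]

    def test_planted_three_clusters_recovered_exactly(self):
        df = gen_ion_table(n_per_cluster=5, seed=0)
        truth = df["planted"]
        clust = ward_cluster(df.drop(columns="planted"))
        labels = clust.cut(3)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_merge_heights_monotone(self):
        df = gen_ion_table(n_per_cluster=7, seed=4)
        clust = ward_cluster(df.drop(columns="planted"))
        assert np.all(np.diff(clust.merge_heights) >= -1e-9)

    def test_missing_value_rejected(self):
        df = gen_ion_table(seed=0).drop(columns="planted")
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            ward_cluster(df)

    def test_newick_contains_all_labels(self):
        df = gen_ion_table(n_per_cluster=2, seed=1)
        clust = ward_cluster(df.drop(columns="planted"))
        nwk = clust.to_newick()
        assert all(lbl in nwk for lbl in clust.labels)
        assert nwk.endswith(";")


class TestCompositionPca:
    def test_variance_concentrated_where_planted(self):
        rng = np.random.default_rng(0)
        n = 20
        df = pd.DataFrame({
            "na": 1000.0 + rng.normal(0, 1e-6, n),
            "k": 100.0 + rng.normal(0, 1e-6, n),
            "mg": 50.0 + rng.normal(0, 1e-6, n),
            "ca": 10.0 + rng.normal(0, 1e-6, n),
            "so4": 200.0 + rng.normal(0, 1e-6, n),
            "cl": 1500.0 + rng.normal(0, 2000.0, n),
            "tal": 9000.0 + rng.normal(0, 5000.0, n),
        })
        out = composition_pca(df, standardize=False)
        top2 = out["loadings"].iloc[:2].abs()
        # the dominant loadings of the first two axes are tal and cl
        assert set(top2.idxmax(axis=1)) == {"tal", "cl"}

    def test_explained_variance_sums_to_one(self):
        df = gen_ion_table(seed=2).drop(columns="planted")
        out = composition_pca(df)
        assert out["explained_variance_ratio"].sum() == \
            pytest.approx(1.0, abs=1e-9)

    def test_duplicating_samples_preserves_geometry(self):
        df = gen_ion_table(seed=3).drop(columns="planted")
        base = composition_pca(df)["scores"]
        doubled = composition_pca(pd.concat([df, df]))["scores"]
        half = doubled.iloc[: len(df)].to_numpy()
        # same geometry up to per-axis sign flips
        for j in range(half.shape[1]):
            col, ref = half[:, j], base.to_numpy()[:, j]
            assert np.allclose(col, ref, atol=1e-8) or \
                np.allclose(col, -ref, atol=1e-8)

    def test_constant_variable_dropped_with_warning(self):
        df = gen_ion_table(seed=1).drop(columns="planted")
        df["ca"] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            out = composition_pca(df)
        assert "ca" not in out["variables"]


class TestEcoplate:
    def test_class_map_has_31_substrates_in_6_classes(self):
        cmap = ecoplate_class_map()
        assert len(cmap) == 31
        counts = cmap.value_counts()
        assert counts["amino acids"] == 6
        assert counts["amines"] == 2
        assert counts["phenolic compounds"] == 2
        assert counts["polymers"] == 4

    def test_all_wells_at_blank_gives_zero_awcd(self):
        df = gen_ecoplate(awcd_value=0.0, blank_od=0.08)
        plate = EcoplatePlate(readings=df)
        assert np.allclose(awcd(plate, 96.0), 0.0)

    def test_uniform_corrected_od_awcd(self):
        """31 wells at corrected OD 0.5 average to AWCD 0.5."""
        df = gen_ecoplate(class_percent={
            "amines": 100 * 2 / 31, "amino acids": 100 * 6 / 31,
            "carbohydrates": 100 * 9 / 31, "carboxylic acids": 100 * 8 / 31,
            "phenolic compounds": 100 * 2 / 31, "polymers": 100 * 4 / 31},
            awcd_value=0.5)
        vals = awcd(EcoplatePlate(readings=df), 96.0)
        assert np.allclose(vals, 0.5)

    def test_below_blank_wells_clamp_to_zero(self):
        df = gen_ecoplate(blank_od=0.30)
        df.loc[df["substrate"] == "D-xylose", "od590"] = 0.10  # 0.2 below blank
        plate = EcoplatePlate(readings=df)
        wells = plate.corrected_od(96.0)
        assert (wells.loc[wells["substrate"] == "D-xylose",
                          "corrected"] == 0.0).all()

    def test_awcd_translation_invariant(self):
        df = gen_ecoplate()
        shifted = df.copy()
        shifted["od590"] += 0.25
        a0 = awcd(EcoplatePlate(readings=df), 96.0)
        a1 = awcd(EcoplatePlate(readings=shifted), 96.0)
        assert np.allclose(a0, a1)

    def test_single_class_signal_takes_100pct(self):
        df = gen_ecoplate(class_percent={"carbohydrates": 100.0})
        pct = class_utilization(EcoplatePlate(readings=df), 96.0)
        assert pct["carbohydrates"] == pytest.approx(100.0)
        assert pct.drop("carbohydrates").sum() == pytest.approx(0.0)

    def test_oxic_2011_style_fixture_inverts_exactly(self):
        """A plate built to a published-style class profile recovers it."""
        target = {"amines": 1.1, "amino acids": 26.5, "carbohydrates": 47.6,
                  "carboxylic acids": 15.2, "phenolic compounds": 0.4,
                  "polymers": 9.2}
        plate = EcoplatePlate(readings=gen_ecoplate(class_percent=target,
                                                    awcd_value=0.482))
        pct = class_utilization(plate, 96.0)
        for cls, val in target.items():
            assert round(pct[cls], 1) == val
        assert awcd(plate, 96.0).mean() == pytest.approx(0.482, rel=1e-9)

    def test_percentages_sum_to_100_and_are_order_invariant(self):
        df = gen_ecoplate()
        pct = class_utilization(EcoplatePlate(readings=df), 96.0)
        assert pct.sum() == pytest.approx(100.0, abs=0.1)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pct2 = class_utilization(EcoplatePlate(readings=shuffled), 96.0)
        assert np.allclose(pct, pct2)

    def test_all_zero_plate_rejected(self):
        df = gen_ecoplate(awcd_value=0.0)
        with pytest.raises(ValueError, match="no colour"):
            class_utilization(EcoplatePlate(readings=df), 96.0)

    def test_missing_blank_rejected(self):
        df = gen_ecoplate()
        df = df[df["substrate"] != "water"]
        with pytest.raises(ValueError, match="blank"):
            EcoplatePlate(readings=df).corrected_od(96.0)
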