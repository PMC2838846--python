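import numpy as np
import pytest

from kinomeprofiler.domain_annotator import DomainInventory
from kinomeprofiler.domain_pca import (
    DomainFrequencyMatrix,
    build_frequency_matrix,
    cluster_separation,
    pca,
    project3,
)
from kinomeprofiler.proteome_io import SpeciesRecord


def _inv(counts):
    return DomainInventory(hits=[], n_kinases=1, per_type_counts=counts)


class TestFrequencyMatrix:
    def test_at_least_half_boundary_is_inclusive(self):
        invs = {
            "s1": _inv({"FHA": 1}), "s2": _inv({"FHA": 2}),
            "s3": _inv({"WD40": 1}), "s4": _inv({"WD40": 1, "PX": 1}),
        }
        m = build_frequency_matrix(invs, prevalence_threshold=0.5)
        assert "FHA" in m.domain_names     # 2 of 4 species = exactly half
        assert "WD40" in m.domain_names
        assert "PX" not in m.domain_names  # 1 of 4 dropped

    def test_row_percentages_use_per_species_domain_totals(self):
        invs = {
            "s1": _inv({"FHA": 3, "WD40": 1}),
            "s2": _inv({"FHA": 1, "WD40": 1}),
        }
        m = build_frequency_matrix(invs)
        df = m.to_frame()
        assert df.loc["s1", "FHA"] == pytest.approx(75.0)
        assert df.loc["s1", "WD40"] == pytest.approx(25.0)
        assert df.loc["s2", "FHA"] == pytest.approx(50.0)

    def test_exactly_21_of_40_types_survive_designed_cohort(self):
        # cohort built so 21 domain types sit at/above the half-prevalence
        # boundary and 19 below it
        n_species, n_common, n_rare = 30, 21, 19
        invs = {}
        for i in range(n_species):
            counts = {f"D{j:02d}": 1 for j in range(n_common)
                      if (i + j) % 2 == 0 or i < 15}
            for j in range(n_rare):
                if i == j % 10:  # each rare type in exactly one species
                    counts[f"R{j:02d}"] = 1
            invs[f"s{i}"] = _inv(counts)
        m = build_frequency_matrix(invs, prevalence_threshold=0.5)
        assert len(m.domain_names) == 21

    def test_raising_threshold_never_adds_columns(self):
        rng = np.random.default_rng(0)
        invs = {
            f"s{i}": _inv({f"D{j}": int(rng.integers(0, 3)) for j in range(12)})
            for i in range(8)
        }
        widths = [
            len(build_frequency_matrix(invs, prevalence_threshold=t).domain_names)
            for t in (0.1, 0.3, 0.5, 0.8, 1.0)
        ]
        assert widths == sorted(widths, reverse=True)

    def test_zero_domain_species_flagged(self):
        invs = {"s1": _inv({"FHA": 1}), "s2": _inv({"FHA": 1}), "s3": _inv({})}
        m = build_frequency_matrix(invs)
        assert m.zero_species == ["s3"]
        assert np.all(m.values[2] == 0)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_matrix({"s1": _inv({"FHA": 1})})


class TestPCA:
    def test_collinear_points_put_all_variance_on_pc1(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0]])
        res = pca(X)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_agrees_with_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        res = pca(X)
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        var_svd = S**2 / (X.shape[0] - 1)
        np.testing.assert_allclose(
            res.explained_variance_fraction[:4] * np.trace(Xc.T @ Xc / 5),
            var_svd, atol=1e-8,
        )
        for k in range(4):
            dot = abs(np.dot(res.component_loadings[:, k], Vt[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)
            score_dot = np.abs(res.scores[:, k]) - np.abs(U[:, k] * S[k])
            np.testing.assert_allclose(score_dot, 0.0, atol=1e-8)

    def test_loadings_orthonormal_and_variance_descending(self):
        rng = np.random.default_rng(2)
        res = pca(rng.normal(size=(10, 5)))
        G = res.component_loadings.T @ res.component_loadings
        np.testing.assert_allclose(G, np.eye(5), atol=1e-8)
        ev = res.explained_variance_fraction
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-9

    def test_full_reconstruction_of_centered_matrix(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 4))
        res = pca(X)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            res.scores @ res.component_loadings.T, Xc, atol=1e-8
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca(np.ones((4, 3)))


def _species(ids, clades):
    return [SpeciesRecord(i, i, "P", c, c) for i, c in zip(ids, clades)]


class TestProject3:
    def _matrix(self, ids, values):
        return DomainFrequencyMatrix(
            species_ids=list(ids), domain_names=[f"D{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_two_component_result_pads_pc3_with_zeros(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 2))
        m = self._matrix([f"s{i}" for i in range(5)], vals)
        res = pca(m)
        df = project3(res, m, _species(m.species_ids, ["A"] * 5))
        assert (df["PC3"] == 0).all()
        assert df.attrs["padded"]
        assert len(df) == 5

    def test_species_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        m = self._matrix(["s0", "s1", "s2"], rng.normal(size=(3, 4)))
        res = pca(m)
        with pytest.raises(ValueError, match="missing"):
            project3(res, m, _species(["s0", "s1"], ["A", "A"]))

    def test_coordinates_invariant_to_species_order(self):
        rng = np.random.default_rng(6)
        invs = {
            f"s{i}": _inv({f"D{j}": int(rng.integers(1, 5)) for j in range(6)})
            for i in range(6)
        }
        m1 = build_frequency_matrix(invs)
        m2 = build_frequency_matrix(dict(reversed(list(invs.items()))))
        sp = _species([f"s{i}" for i in range(6)], ["A"] * 6)
        d1 = project3(pca(m1), m1, sp).set_index("species").sort_index()
        d2 = project3(pca(m2), m2, sp).set_index("species").sort_index()
        np.testing.assert_allclose(
            d1[["PC1", "PC2", "PC3"]].to_numpy(),
            d2[["PC1", "PC2", "PC3"]].to_numpy(), atol=1e-8,
        )


class TestClusterSeparation:
    def test_well_separated_clouds_score_high(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 0.1, size=(10, 3))
        b = rng.normal(5.0, 0.1, size=(10, 3))
        score = cluster_separation(np.vstack([a, b]), ["A"] * 10 + ["B"] * 10)
        assert score > 0.8

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(20, 3))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        scores = []
        for _ in range(20):
            rng.shuffle(labels)
            scores.append(cluster_separation(coords, labels))
        assert max(abs(s) for s in scores) < 0.2

    def test_singleton_clade_contributes_zero(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [9.0, 0, 0]])
        score = cluster_separation(coords, ["A", "A", "B"])
        # singleton B contributes 0; the two A points are far from B
        assert 0 < score < 1

    def test_single_clade_rejected(self):
        with pytest.raises(ValueError):
            cluster_separation(np.zeros((3, 2)), ["A", "A", "A"])
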