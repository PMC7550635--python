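import numpy as np
import pytest

from connectomeclf.cohort import (
    CohortSpec,
    between_module_pairs,
    build_population_covariance,
    generate_cohort,
    load_cohort,
    simulate_subject,
)


def _spec(**kw):
    base = dict(n_group_pos=5, n_group_neg=5, n_roi=10, n_timepoints=50,
                module_sizes=(5, 5), seed=0)
    base.update(kw)
    return CohortSpec(**base)


class TestPopulationCovariance:
    def test_zero_effect_gives_identical_groups(self):
        spec = _spec(effect_edges=((0, 7),), effect_delta=0.0)
        np.testing.assert_array_equal(
            build_population_covariance(spec, "pos"),
            build_population_covariance(spec, "neg"),
        )

    @pytest.mark.parametrize("delta", [0.0, 0.2, -0.05, 0.4])
    def test_spd_contract(self, delta):
        spec = _spec(effect_edges=((0, 7), (1, 8)), effect_delta=delta,
                     within_module_weight=0.4, between_module_weight=0.05)
        for group in ("pos", "neg"):
            cov = build_population_covariance(spec, group)
            assert np.linalg.eigvalsh(cov)[0] > 0
            np.linalg.cholesky(cov)  # must not raise

    def test_block_values_read_back(self):
        # construct-and-read-back: off-diagonals take exactly the two planted values
        spec = _spec(within_module_weight=0.4, between_module_weight=0.05)
        cov = build_population_covariance(spec, "neg")
        labels = spec.module_assignment
        for i in range(10):
            for j in range(10):
                if i == j:
                    assert cov[i, j] == 1.0
                elif labels[i] == labels[j]:
                    assert cov[i, j] == pytest.approx(0.4)
                else:
                    assert cov[i, j] == pytest.approx(0.05)

    def test_unrepairable_delta_is_parameter_error(self):
        spec = _spec(effect_edges=((0, 7),), effect_delta=0.99)
        with pytest.raises(ValueError, match="outside"):
            build_population_covariance(spec, "pos")

    def test_invalid_module_sizes_rejected(self):
        with pytest.raises(ValueError, match="module_sizes"):
            _spec(module_sizes=(4, 4))

    def test_self_loop_effect_edge_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            _spec(effect_edges=((3, 3),))


class TestSimulateSubject:
    def test_deterministic_given_seed(self):
        cov = build_population_covariance(_spec(), "neg")
        a = simulate_subject(cov, 40, 0.5, seed=7)
        b = simulate_subject(cov, 40, 0.5, seed=7)
        np.testing.assert_array_equal(a, b)
        c = simulate_subject(cov, 40, 0.5, seed=8)
        assert not np.array_equal(a, c)

    def test_large_sample_correlation_converges(self):
        # law of large numbers: noiseless sample correlation ~ population
        cov = build_population_covariance(_spec(), "neg")
        x = simulate_subject(cov, 100_000, 0.0, seed=1)
        r = np.corrcoef(x, rowvar=False)
        assert np.abs(r - cov).max() < 0.02

    def test_strong_noise_washes_out_correlation(self):
        cov = build_population_covariance(_spec(within_module_weight=0.5), "neg")
        x = simulate_subject(cov, 20_000, 100.0, seed=2)
        r = np.corrcoef(x, rowvar=False)
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_non_spd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            simulate_subject(bad, 10, 0.1, seed=0)

    def test_ar_smoothing_preserves_marginal_correlation(self):
        cov = build_population_covariance(_spec(), "neg")
        x = simulate_subject(cov, 100_000, 0.0, seed=3, ar_coef=0.4)
        r = np.corrcoef(x, rowvar=False)
        assert np.abs(r - cov).max() < 0.03


class TestGenerateCohort:
    def test_paper_scale_manifest_has_42_rows(self):
        spec = CohortSpec(n_group_pos=22, n_group_neg=20, n_roi=12, n_timepoints=30)
        data = generate_cohort(spec)
        assert len(data.manifest) == 42
        assert (data.labels == 1).sum() == 22
        assert (data.labels == -1).sum() == 20

    def test_different_seeds_differ(self):
        a = generate_cohort(_spec(seed=1))
        b = generate_cohort(_spec(seed=2))
        assert not np.array_equal(a.timeseries["sub-000"], b.timeseries["sub-000"])

    def test_regeneration_is_deterministic(self):
        a = generate_cohort(_spec(seed=5))
        b = generate_cohort(_spec(seed=5))
        for sid in a.timeseries:
            np.testing.assert_array_equal(a.timeseries[sid], b.timeseries[sid])

    def test_differential_edges_match_planting(self):
        spec = _spec(effect_edges=((0, 7), (2, 9)), effect_delta=0.2)
        data = generate_cohort(spec)
        assert set(data.ground_truth.differential_edges) == {(0, 7), (2, 9)}

    def test_roundtrip_through_disk(self, tmp_path):
        data = generate_cohort(_spec(seed=9))
        manifest_path = data.write(tmp_path)
        manifest, series, roi_names = load_cohort(manifest_path)
        assert len(manifest) == 10
        assert roi_names == data.roi_names
        np.testing.assert_allclose(
            series["sub-003"], data.timeseries["sub-003"], atol=1e-9
        )

    def test_unreadable_file_names_subject(self, tmp_path):
        data = generate_cohort(_spec(seed=9))
        manifest_path = data.write(tmp_path)
        (tmp_path / "timeseries" / "sub-004.tsv").unlink()
        with pytest.raises(OSError, match="sub-004"):
            load_cohort(manifest_path)


class TestStatisticalContracts:
    def test_null_edge_selection_calibrated(self):
        # with no planted effect the edge screen should fire at its nominal rate
        from connectomeclf.network import edge_vector, compute_connectivity
        from connectomeclf.selection import edge_ttest_select

        rates = []
        for seed in range(5):
            spec = CohortSpec(
                n_group_pos=30, n_group_neg=30, n_roi=20, n_timepoints=100,
                within_module_weight=0.25, between_module_weight=0.1, seed=seed,
            )
            data = generate_cohort(spec)
            edges = np.array(
                [edge_vector(compute_connectivity(ts)) for ts in data.timeseries.values()]
            )
            sel = edge_ttest_select(edges, data.labels, alpha=0.05)
            rates.append(sel.selected.size / edges.shape[1])
        m_edges = 5 * 190
        se = np.sqrt(0.05 * 0.95 / m_edges)
        assert abs(np.mean(rates) - 0.05) < 3 * se

    def test_planted_edges_recovered(self):
        # Jaccard >= 0.6 between t-test selections and the planted set
        from connectomeclf.network import edge_vector, compute_connectivity, edge_index_pairs
        from connectomeclf.selection import edge_ttest_select

        jaccards = []
        for seed in range(3):
            base = CohortSpec(n_group_pos=100, n_group_neg=100, n_roi=12, n_timepoints=230)
            planted = between_module_pairs(base)[:20]
            spec = CohortSpec(
                n_group_pos=100, n_group_neg=100, n_roi=12, n_timepoints=230,
                effect_edges=tuple(planted), effect_delta=0.3, seed=seed,
            )
            data = generate_cohort(spec)
            edges = np.array(
                [edge_vector(compute_connectivity(ts)) for ts in data.timeseries.values()]
            )
            sel = edge_ttest_select(edges, data.labels, alpha=0.05)
            pairs = [tuple(p) for p in edge_index_pairs(12)[sel.selected]]
            inter = len(set(pairs) & set(planted))
            union = len(set(pairs) | set(planted))
            jaccards.append(inter / union)
        assert np.mean(jaccards) >= 0.6
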