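import numpy as np
import pandas as pd
import pytest

from panelprs.genotypes import DosageMatrix
from panelprs.ld import HaplotypeCounts, ld_stats
from panelprs.model import ArrayStatus, ProxyAction
from panelprs.scoring import prs_series, resolve_matrix
from panelprs.simulate import (
    SimulationConfig,
    feasible_r_range,
    haplotype_frequencies,
    ngs_site_profile,
    simulate_array_observation,
    simulate_ngs_observation,
    simulate_study,
    simulate_truth_cohort,
    simulate_two_locus_haplotypes,
    synthetic_lifetime_risk,
    write_fixture_set,
)
from panelprs.validate import (
    allele_frequency,
    coefficient_of_determination,
    concordance,
    confusion_counts,
    confusion_metrics,
    depth_qc,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_samples=0)
    with pytest.raises(ValueError):
        SimulationConfig(n_genotyped=500)
    with pytest.raises(ValueError):
        SimulationConfig(array_error_imputed=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_low_depth=1, n_dead=2)


def test_infeasible_r_names_feasible_range():
    with pytest.raises(ValueError, match="feasible range"):
        haplotype_frequencies(0.1, 0.9, 1.0)
    lo, hi = feasible_r_range(0.1, 0.9)
    haplotype_frequencies(0.1, 0.9, hi)  # boundary itself is feasible


def test_independent_loci_have_near_zero_r2():
    rng = np.random.default_rng(0)
    haps = simulate_two_locus_haplotypes(0.4, 0.6, 0.0, 10_000, rng)
    stats = ld_stats(
        HaplotypeCounts.from_haplotypes(haps[:, :, 0].ravel(), haps[:, :, 1].ravel())
    )
    assert stats.r2 < 3 / 20_000 * 4  # r2-hat ~ chi2(1)/n under independence


def test_complete_coupling_emits_only_ab_and_AB():
    rng = np.random.default_rng(0)
    haps = simulate_two_locus_haplotypes(0.3, 0.3, 1.0, 2_000, rng)
    assert (haps[:, :, 0] == haps[:, :, 1]).all()


def test_truth_cohort_geometry_and_determinism():
    config = SimulationConfig(seed=5)
    cohort_a = simulate_truth_cohort(config)
    cohort_b = simulate_truth_cohort(config)
    pd.testing.assert_frame_equal(cohort_a.truth.data, cohort_b.truth.data)
    assert len(cohort_a.model) == 313
    assert len(cohort_a.model.subset(ArrayStatus.GENOTYPED)) == 105
    assert len(cohort_a.model.subset(ArrayStatus.IMPUTED)) == 208
    substitutions = [
        e for e in cohort_a.proxy_map.values() if e.action is ProxyAction.SUBSTITUTE
    ]
    assert len(substitutions) == 27
    assert len(cohort_a.dead_ids) == 2
    assert len(cohort_a.low_depth_ids) == 15
    assert sum(1 for e in substitutions if e.orientation.value == "negative") == 2


def test_truth_frequencies_match_targets(small_study):
    cohort = small_study.cohort
    big = simulate_truth_cohort(
        SimulationConfig(n_samples=10_000, n_variants=20, n_genotyped=8,
                         n_indels=3, n_proxies=3, n_negative=1, n_dead=1,
                         n_low_depth=1, seed=21)
    )
    observed = allele_frequency(big.truth)
    for vid, target in big.freqs.items():
        se = np.sqrt(target * (1 - target) / (2 * 10_000))
        assert abs(observed[vid] - target) < 3 * se


def test_realized_proxy_ld_matches_design(small_study):
    cohort = small_study.cohort
    big = simulate_truth_cohort(
        SimulationConfig(n_samples=10_000, n_variants=30, n_genotyped=10,
                         n_indels=0, n_proxies=5, n_negative=2, n_dead=0,
                         n_low_depth=0, seed=33)
    )
    for entry in big.proxy_map.values():
        # dosage correlation approximates haplotype correlation for random mating
        r2_obs = coefficient_of_determination(
            big.truth.data[entry.original_id], big.truth.data[entry.proxy_id]
        )
        se = np.sqrt(4 * entry.r2 * max(1 - entry.r2, 1e-3) ** 2 / 10_000) + 0.01
        assert abs(r2_obs - entry.r2) < 3 * se


def test_array_observation_zero_error_is_identity(small_study):
    config = SimulationConfig(
        n_samples=50, n_variants=20, n_genotyped=8, n_indels=0, n_proxies=2,
        n_negative=0, n_dead=0, n_low_depth=0, seed=9,
        array_error_genotyped=0.0, array_error_imputed=0.0,
    )
    cohort = simulate_truth_cohort(config)
    rng = np.random.default_rng(1)
    observed = simulate_array_observation(cohort.truth, cohort.model, config, rng)
    pd.testing.assert_frame_equal(
        observed.data, cohort.truth.data[cohort.model.variant_ids]
    )


def test_array_error_rate_recovers_in_concordance():
    epsilon = 0.1
    config = SimulationConfig(
        n_samples=5_000, n_variants=12, n_genotyped=4, n_indels=0, n_proxies=2,
        n_negative=0, n_dead=0, n_low_depth=0, seed=17,
        array_error_genotyped=0.0, array_error_imputed=epsilon,
    )
    cohort = simulate_truth_cohort(config)
    rng = np.random.default_rng(2)
    observed = simulate_array_observation(cohort.truth, cohort.model, config, rng)
    truth = cohort.truth_model_only()
    report = concordance(truth, observed)
    se = np.sqrt(epsilon * (1 - epsilon) / 5_000)
    for v in cohort.model.variants:
        expected = 1.0 if v.array_status is ArrayStatus.GENOTYPED else 1 - epsilon
        assert abs(report.per_snp[v.variant_id] - expected) <= 3 * se


def test_dead_site_is_all_missing_and_flagged_low(small_study):
    cohort = small_study.cohort
    dead = cohort.dead_ids[0]
    assert small_study.ngs_obs.data[dead].isna().all()
    qc = depth_qc(small_study.ngs_depths)
    assert qc.at[dead, "mean_depth"] == 0
    assert qc.at[dead, "flag"] == "low"


def test_deep_clean_sites_concord_with_truth(small_study):
    cohort = small_study.cohort
    clean = [
        v.variant_id
        for v in cohort.model.variants
        if not v.low_complexity and v.variant_id not in cohort.low_depth_ids
    ]
    report = concordance(
        cohort.truth.select(clean), small_study.ngs_obs.select(clean)
    )
    # at 559x mean depth and 0.1% read error, miscalls are negligible
    assert report.per_snp.min() > 0.999


def test_ngs_observation_deterministic(small_study):
    config = small_study.cohort.config
    rng_a = np.random.default_rng(99)
    rng_b = np.random.default_rng(99)
    profile = ngs_site_profile(small_study.cohort)
    obs_a, depths_a = simulate_ngs_observation(
        small_study.cohort.truth, profile, config, rng_a
    )
    obs_b, depths_b = simulate_ngs_observation(
        small_study.cohort.truth, profile, config, rng_b
    )
    pd.testing.assert_frame_equal(obs_a.data, obs_b.data)
    pd.testing.assert_frame_equal(depths_a.data, depths_b.data)


def test_zero_error_end_to_end_recovery(zero_error_study):
    cohort = zero_error_study.cohort
    ref = DosageMatrix(
        resolve_matrix(zero_error_study.array_obs, cohort.model)[0].astype(float)
    )
    test = DosageMatrix(
        resolve_matrix(zero_error_study.ngs_obs, cohort.model, cohort.proxy_map)[0]
        .astype(float)
    )
    metrics = confusion_metrics(confusion_counts(ref, test))
    assert metrics.rounded() == {
        "sensitivity": 100.0, "specificity": 100.0, "ppv": 100.0, "npv": 100.0
    }
    prs_ref = prs_series(ref, cohort.model)
    prs_test = prs_series(zero_error_study.ngs_obs, cohort.model, cohort.proxy_map)
    pd.testing.assert_series_equal(prs_ref, prs_test)
    assert coefficient_of_determination(prs_ref, prs_test) == pytest.approx(1.0)


def test_synthetic_risk_mapping_is_monotone():
    scores = np.linspace(-3, 3, 50)
    risks = [synthetic_lifetime_risk(s) for s in scores]
    assert all(a < b for a, b in zip(risks, risks[1:]))
    assert synthetic_lifetime_risk(0.0) == pytest.approx(11.5)


def test_fixture_set_round_trip(tmp_path, small_study):
    from panelprs.genotypes import read_depths, read_dosages
    from panelprs.model import load_model, load_proxy_map

    paths = write_fixture_set(small_study, tmp_path / "fx")
    model = load_model(paths["model"])
    proxy_map = load_proxy_map(paths["proxy_map"], model)
    assert model.variants == small_study.cohort.model.variants
    assert proxy_map == small_study.cohort.proxy_map
    panel = list(model.variants) + list(load_model(paths["panel_extra"]).variants)
    ngs = read_dosages(paths["ngs_vcf"], panel)
    pd.testing.assert_frame_equal(
        ngs.data[small_study.ngs_obs.variant_ids], small_study.ngs_obs.data
    )
    depths = read_depths(paths["depths"], panel, sample_ids=ngs.sample_ids)
    pd.testing.assert_frame_equal(
        depths.data[small_study.ngs_depths.variant_ids], small_study.ngs_depths.data
    )
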