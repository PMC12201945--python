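"""Tests for the synthetic-data generators and their ground truth."""

import numpy as np
import pytest
from scipy import stats as sps

from phycoflow.containers import ValidationError
from phycoflow.interactions import compute_eci, compute_mro, si_matrix
from phycoflow.simulate import (
    MetabolomeDesign,
    NanoSimsDesign,
    SequentialDesign,
    generate_metabolome,
    generate_nanosims,
    generate_sequential,
    generate_uptake_sets,
    simulate_consumer_resource,
)
from phycoflow.isotope import atom_fraction, carbon_ratio


# --------------------------------------------------------------- metabolome


def test_metabolome_deterministic_under_seed():
    d = MetabolomeDesign(n_features=20, n_isolates=3, seed=77)
    t1, _ = generate_metabolome(d)
    t2, _ = generate_metabolome(MetabolomeDesign(n_features=20, n_isolates=3,
                                                 seed=77))
    assert t1.intensities.equals(t2.intensities)


def test_metabolome_no_consumption_matches_control():
    """With p = 0 everywhere, isolate samples are statistically
    indistinguishable from controls."""
    props = np.zeros((2, 30))
    table, _ = generate_metabolome(MetabolomeDesign(
        n_features=30, n_isolates=2, true_proportions=props, seed=3))
    control = table.group_matrix("control")
    for iso in table.isolate_names:
        mat = table.group_matrix(f"isolate:{iso}")
        _, p = sps.ttest_ind(mat, control, axis=1)
        # No feature should be significant after Bonferroni.
        assert (p * p.size > 0.05).all()


def test_metabolome_complete_consumption_noise_free():
    """p = 1 and zero noise: the feature drops to the blank background."""
    props = np.zeros((1, 5))
    props[0, 2] = 1.0
    design = MetabolomeDesign(n_features=5, n_isolates=1,
                              true_proportions=props, noise_cv=0.0, seed=1)
    table, _ = generate_metabolome(design)
    iso = table.group_matrix("isolate:Iso01")
    assert np.allclose(iso[2], design.blank_level)


def test_metabolome_validation_names_field():
    with pytest.raises(ValidationError, match="n_reps_control"):
        generate_metabolome(MetabolomeDesign(n_reps_control=1))
    with pytest.raises(ValidationError, match="true_proportions"):
        generate_metabolome(MetabolomeDesign(
            n_features=2, n_isolates=1, true_proportions=np.array([[2.0, 0]])))
    bad = MetabolomeDesign(
        n_features=1, n_isolates=1,
        true_proportions=np.array([[0.5]]),
        production_rates=np.array([[1.0]]))
    with pytest.raises(ValidationError, match="overlap"):
        generate_metabolome(bad)


def test_metabolome_ground_truth_is_consistent():
    table, truth = generate_metabolome(MetabolomeDesign(
        n_features=10, n_isolates=2, seed=6))
    for prof in truth:
        consumed = prof.data["call"] == "consumed"
        assert (prof.data.loc[consumed, "proportion"] > 0).all()
        assert (prof.data.loc[~consumed, "proportion"] == 0).all()


# --------------------------------------------------------------- sequential


def test_sequential_noise_free_counts_match_expectations():
    si = np.zeros((3, 3))
    si[1, 2] = -1.0
    g = generate_sequential(SequentialDesign(
        n_strains=3, true_si=si, baseline_counts=5000.0, noise_cv=0.0,
        seed=0))
    # SI = 0: counts equal baseline.
    assert np.allclose(g.counts("S01", "S01"), 5000.0)
    # SI = -1 (primary S02 on secondary S03): zero growth.
    assert np.allclose(g.counts("S03", "S02"), 0.0)
    mat = si_matrix(g)
    np.testing.assert_allclose(mat.values.to_numpy(), si, atol=1e-12)


def test_sequential_recovery_matches_monte_carlo_oracle():
    """Coverage of the +-0.1 recovery band agrees with a brute-force
    Monte-Carlo of the same sampling model.

    The oracle draws the ratio of two 3-replicate lognormal means directly
    (no growth-table machinery) at matched true SI values.
    """
    n_seeds = 60
    cv = 0.1
    within = []
    truths = []
    for seed in range(n_seeds):
        g = generate_sequential(SequentialDesign(
            n_strains=5, noise_cv=cv, n_reps=3, seed=seed))
        est = si_matrix(g).values.to_numpy()
        tru = g.true_si.to_numpy()
        within.append((np.abs(est - tru) <= 0.1).ravel())
        truths.append(tru.ravel())
    observed = float(np.concatenate(within).mean())

    # Brute-force oracle at the same true SI values.
    rng = np.random.default_rng(12345)
    sigma = np.sqrt(np.log1p(cv ** 2))
    tru = np.concatenate(truths)
    reps = 40
    mu = -sigma ** 2 / 2
    num = rng.lognormal(mu, sigma, size=(reps, tru.size, 3)).mean(axis=2)
    den = rng.lognormal(mu, sigma, size=(reps, tru.size, 3)).mean(axis=2)
    si_hat = (1 + tru)[None, :] * num / den - 1
    predicted = float((np.abs(si_hat - tru[None, :]) <= 0.1).mean())
    assert observed == pytest.approx(predicted, abs=0.03)


def test_sequential_validation():
    with pytest.raises(ValidationError, match="baseline_counts"):
        generate_sequential(SequentialDesign(baseline_counts=0.0))
    with pytest.raises(ValidationError, match="true_si"):
        generate_sequential(SequentialDesign(
            n_strains=2, true_si=np.full((2, 2), -2.0)))


# ----------------------------------------------------------------- nanosims


def test_nanosims_unlabelled_cells_recover_natural_ratio():
    d = NanoSimsDesign(n_cells_per_treatment=200, true_cnet_median=0.0,
                       mean_total_counts=1e6, seed=4)
    rois = generate_nanosims(d)
    r = carbon_ratio(rois["c12c13"], rois["c12c12"])
    assert np.mean(r) == pytest.approx(d.natural_ratio_13C, rel=1e-3)


def test_nanosims_fully_labelled_cells_recover_algal_fraction():
    d = NanoSimsDesign(n_cells_per_treatment=200, true_cnet_median=100.0,
                       true_cnet_spread=0.0, mean_total_counts=1e6, seed=5)
    rois = generate_nanosims(d)
    f = atom_fraction(carbon_ratio(rois["c12c13"], rois["c12c12"]))
    assert np.mean(f) == pytest.approx(d.algal_atom_fraction, rel=1e-3)


def test_nanosims_poisson_ratio_expectation():
    """The recovered median C_net matches the analytic expectation of the
    Poisson-ratio measurement model at high counts."""
    d = NanoSimsDesign(n_cells_per_treatment=300, true_cnet_median=2.71,
                       mean_total_counts=1e6, n_algal_rois=0, seed=6)
    rois = generate_nanosims(d)
    f = atom_fraction(carbon_ratio(rois["c12c13"], rois["c12c12"]))
    f_nat = d.natural_ratio_13C / (1 + d.natural_ratio_13C)
    cnet = 100 * (f - f_nat) / (d.algal_atom_fraction - f_nat)
    true_cnet = rois.attrs["true_cnet"]
    # Per-cell measurement error at 1e6 counts is ~0.2 pp.
    assert np.median(cnet) == pytest.approx(np.median(true_cnet), abs=0.05)
    assert np.median(cnet) == pytest.approx(2.71, abs=0.3)


def test_nanosims_validation():
    with pytest.raises(ValidationError, match="algal_atom_fraction"):
        generate_nanosims(NanoSimsDesign(algal_atom_fraction=0.001))


# -------------------------------------------------------------- uptake sets


@pytest.mark.parametrize("overlap, expected", [(1.0, 1.0), (0.0, 0.0)])
def test_uptake_sets_extremes(overlap, expected):
    sets = generate_uptake_sets(4, 200, overlap, seed=0, set_size=10)
    strains = list(sets)
    for a in strains:
        for b in strains:
            if a != b:
                assert compute_mro(sets[a], sets[b]) == expected
    if overlap == 1.0:
        assert len(set(sets.values())) == 1


def test_uptake_sets_intermediate_overlap_exhaustive_count():
    """Directed MRO of every ordered pair equals the requested overlap,
    verified by exhaustive set counting."""
    sets = generate_uptake_sets(4, 200, 0.5, seed=1, set_size=40)
    strains = list(sets)
    mros = []
    for a in strains:
        for b in strains:
            if a == b:
                continue
            shared = sum(1 for n in sets[a] if n in sets[b])
            assert compute_mro(sets[a], sets[b]) == shared / len(sets[a])
            mros.append(shared / len(sets[a]))
    assert np.mean(mros) == pytest.approx(0.5, abs=0.05)


def test_uptake_sets_universe_too_small():
    with pytest.raises(ValidationError, match="universe too small"):
        generate_uptake_sets(10, 100, 0.0, set_size=20)


# ---------------------------------------------------- consumer-resource


def test_consumer_resource_trivial_cases():
    p_sec = np.array([1.0, 1.0, 0.0])
    pool = np.ones(3)
    y = np.ones(3)
    g_with, g_without = simulate_consumer_resource(
        np.zeros(3), p_sec, pool, y)
    assert g_with == g_without                     # no primary depletion
    g_with, g_without = simulate_consumer_resource(
        np.array([1.0, 1.0, 0.0]), p_sec, pool, y)
    assert g_with == 0.0                           # SI = -1


def test_consumer_resource_si_equals_eci_for_binary_profiles():
    """With binary secondary profiles, equal pools and yields, the
    simulated SI equals ECI exactly — checked by brute-force enumeration
    over random binary/continuous profile pairs."""
    rng = np.random.default_rng(99)
    for _ in range(200):
        m = rng.integers(2, 12)
        p_sec = rng.integers(0, 2, size=m).astype(float)
        if not p_sec.any():
            continue
        p_prim = rng.uniform(0, 1, size=m)
        pool = np.ones(m)
        y = np.ones(m)
        g_with, g_without = simulate_consumer_resource(p_prim, p_sec, pool, y)
        si = g_with / g_without - 1.0
        # Brute-force ECI via explicit loops.
        num = sum(p_sec[i] * p_prim[i] for i in range(m))
        den = sum(p_sec[i] ** 2 for i in range(m))
        assert si == pytest.approx(-num / den, abs=1e-15)
        assert si == pytest.approx(compute_eci(p_sec, p_prim), abs=1e-15)


def test_consumer_resource_length_mismatch():
    with pytest.raises(ValidationError):
        simulate_consumer_resource([0.5], [0.5, 0.5], [1, 1], [1, 1])
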