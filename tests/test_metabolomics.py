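"""Tests for background filtering, change calls and consumption proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phycoflow.containers import (
    CONSUMED,
    PRODUCED,
    UNCHANGED,
    ConsumptionProfile,
    FeatureTable,
    ValidationError,
)
from phycoflow.metabolomics import (
    build_profiles,
    classify_changes,
    estimate_proportions,
    filter_above_background,
    shared_depletion_summary,
)
from phycoflow.simulate import MetabolomeDesign, generate_metabolome

from conftest import make_profile


def _table(feature_means, n_by_group, cv=0.02, seed=0):
    """Feature table from {feature: {group: mean}} with mild noise."""
    rng = np.random.default_rng(seed)
    features = list(feature_means)
    samples, groups = {}, {}
    for group, n in n_by_group.items():
        for i in range(n):
            sid = f"{group.replace(':', '_')}_{i}"
            samples[sid] = [
                max(feature_means[f][group] * (1 + cv * rng.standard_normal()),
                    0.0)
                for f in features]
            groups[sid] = group
    return FeatureTable(
        pd.DataFrame(samples, index=pd.Index(features, name="feature_id")),
        pd.Series(groups))


# ------------------------------------------------------------- filtering


def test_filter_drops_background_level_features(toy_feature_table):
    filtered = filter_above_background(toy_feature_table)
    assert "F2" not in filtered.feature_ids      # background-level everywhere
    assert {"F1", "F3"} <= set(filtered.feature_ids)
    assert filtered.meta["n_retained"] == len(filtered.feature_ids)


def test_filter_matches_hand_computed_t_statistic():
    """Strong feature (blank ~100, one group ~10000) must survive; the
    underlying pooled-variance t statistic is recomputed by hand."""
    rng = np.random.default_rng(1)
    blank = 100 + 10 * rng.standard_normal(12)
    group = 10_000 + 500 * rng.standard_normal(5)
    # Hand-computed two-sample pooled t statistic.
    n1, n2 = len(group), len(blank)
    sp2 = (((n1 - 1) * group.var(ddof=1) + (n2 - 1) * blank.var(ddof=1))
           / (n1 + n2 - 2))
    t_hand = (group.mean() - blank.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t_scipy = sps.ttest_ind(group, blank).statistic
    assert t_scipy == pytest.approx(t_hand, rel=1e-12)

    samples = {f"blank_{i}": [b] for i, b in enumerate(blank)}
    samples.update({f"iso_{i}": [g] for i, g in enumerate(group)})
    groups = pd.Series({**{f"blank_{i}": "blank" for i in range(12)},
                        **{f"iso_{i}": "isolate:X" for i in range(5)}})
    table = FeatureTable(pd.DataFrame(samples, index=["F"]), groups)
    filtered = filter_above_background(table)
    assert filtered.feature_ids == ["F"]


def test_filter_requires_blank_and_replicates(toy_feature_table):
    no_blank = FeatureTable(
        toy_feature_table.intensities.drop(
            columns=toy_feature_table.samples_in("blank")),
        toy_feature_table.groups[toy_feature_table.groups != "blank"])
    with pytest.raises(ValidationError, match="blank"):
        filter_above_background(no_blank)

    singleton = toy_feature_table.intensities.drop(
        columns=toy_feature_table.samples_in("isolate:IsoB")[1:])
    groups = toy_feature_table.groups[singleton.columns]
    with pytest.raises(ValidationError, match="IsoB"):
        filter_above_background(FeatureTable(singleton, groups))


def test_filter_monotone_in_alpha():
    """The retained set at a stricter alpha is a subset of the laxer one."""
    table, _ = generate_metabolome(MetabolomeDesign(
        n_features=60, n_isolates=4, seed=5))
    strict = set(filter_above_background(table, alpha=0.001).feature_ids)
    lax = set(filter_above_background(table, alpha=0.05).feature_ids)
    assert strict <= lax


def test_filter_retains_real_features_among_background():
    """~162 real features plus pure-background features: the filter keeps
    the real ones and drops (almost all of) the background."""
    design = MetabolomeDesign(n_features=162, n_isolates=5, seed=9)
    table, _ = generate_metabolome(design)
    # Append 38 pure-background features at the blank level.
    rng = np.random.default_rng(10)
    bg = pd.DataFrame(
        design.blank_level
        * rng.lognormal(0, 0.1, size=(38, len(table.sample_ids))),
        index=[f"bg-{i}" for i in range(38)], columns=table.sample_ids)
    big = FeatureTable(pd.concat([table.intensities, bg]), table.groups)
    filtered = filter_above_background(big)
    kept = set(filtered.feature_ids)
    n_real_kept = sum(1 for f in table.feature_ids if f in kept)
    n_bg_kept = sum(1 for f in bg.index if f in kept)
    assert n_real_kept >= 155           # nearly all real features retained
    assert n_bg_kept <= 2               # background essentially eliminated


# ----------------------------------------------------------- change calls


def test_classify_unchanged_when_equal():
    table = _table({"F": {"control": 1000, "isolate:X": 1000}},
                   {"control": 12, "isolate:X": 5}, cv=0.0)
    prof, = classify_changes(table)
    row = prof.data.loc["F"]
    assert row["call"] == UNCHANGED
    assert row["log2fc"] == 0.0


def test_classify_consumed_log2fc_hand_value():
    table = _table({"F": {"control": 1000, "isolate:X": 250}},
                   {"control": 12, "isolate:X": 5}, cv=0.01, seed=3)
    prof, = classify_changes(table)
    row = prof.data.loc["F"]
    assert row["call"] == CONSUMED
    assert row["log2fc"] == pytest.approx(-2.0, abs=0.1)


def test_classify_produced_and_zero_control_sentinel():
    table = _table({"F": {"control": 0.0, "isolate:X": 500},
                    "G": {"control": 0.0, "isolate:X": 0.0}},
                   {"control": 12, "isolate:X": 5}, cv=0.01, seed=4)
    prof, = classify_changes(table)
    assert np.isposinf(prof.data.loc["F", "log2fc"])
    assert prof.data.loc["F", "call"] == PRODUCED
    assert "F" in prof.flags["zero_control_features"]
    assert prof.data.loc["G", "call"] == UNCHANGED


def test_classify_recovers_engineered_consumption_count():
    """One isolate consuming 54 of 162 features strongly yields 54
    significant consumed calls."""
    rng = np.random.default_rng(7)
    props = np.zeros((1, 162))
    consumed_idx = rng.choice(162, size=54, replace=False)
    props[0, consumed_idx] = rng.uniform(0.6, 0.95, size=54)
    table, _ = generate_metabolome(MetabolomeDesign(
        n_features=162, n_isolates=1, true_proportions=props, seed=8))
    prof, = classify_changes(table)
    assert prof.n_called(CONSUMED) == 54


# ------------------------------------------------------------ proportions


@pytest.mark.parametrize("i0, i_s, expected", [
    (1000.0, 1000.0, 0.0),
    (1000.0, 0.0, 1.0),
    (1000.0, 250.0, 0.75),
])
def test_proportion_values(i0, i_s, expected):
    data = pd.DataFrame({
        "mean_control": [i0], "mean_isolate": [i_s],
        "log2fc": [np.log2(i_s / i0) if i_s else -np.inf],
        "p_adj": [0.001], "call": [CONSUMED], "proportion": [0.0]},
        index=["F"])
    prof = estimate_proportions(ConsumptionProfile("X", data))
    assert prof.data.loc["F", "proportion"] == pytest.approx(expected)


def test_proportion_conventions_and_consumed_only():
    data = pd.DataFrame({
        "mean_control": [1000.0, 1000.0], "mean_isolate": [250.0, 4000.0],
        "log2fc": [-2.0, 2.0], "p_adj": [0.001, 0.001],
        "call": [CONSUMED, PRODUCED], "proportion": [0.0, 0.0]},
        index=["F", "G"])
    from phycoflow.containers import ConsumptionProfile
    default = estimate_proportions(ConsumptionProfile("X", data))
    assert default.data["proportion"].tolist() == [0.75, 0.0]
    literal = estimate_proportions(ConsumptionProfile("X", data.copy()),
                                   convention="ratio")
    assert literal.data.loc["F", "proportion"] == pytest.approx(0.25)


def test_proportion_zero_control_flagged():
    from phycoflow.containers import ConsumptionProfile
    data = pd.DataFrame({
        "mean_control": [0.0], "mean_isolate": [10.0],
        "log2fc": [np.inf], "p_adj": [0.001], "call": [CONSUMED],
        "proportion": [0.0]}, index=["F"])
    prof = estimate_proportions(ConsumptionProfile("X", data))
    assert prof.data.loc["F", "proportion"] == 0.0
    assert prof.flags["undefined_proportion_features"] == ["F"]


def test_proportions_invariant_under_global_rescaling(toy_feature_table):
    profs = build_profiles(toy_feature_table)
    scaled = FeatureTable(toy_feature_table.intensities * 37.5,
                          toy_feature_table.groups)
    profs_scaled = build_profiles(scaled)
    for a, b in zip(profs, profs_scaled):
        np.testing.assert_allclose(a.proportions, b.proportions, atol=1e-12)


def test_bonferroni_family_size_logged(toy_feature_table):
    profs = classify_changes(toy_feature_table)
    # 3 features x 2 isolates contrasts in one run.
    assert all(p.flags["n_tests"] == 6 for p in profs)


# ------------------------------------------------------- shared depletion


def test_shared_depletion_threshold_logic():
    features = ["m1", "m2"]
    a = make_profile("A", features, [0.75, 0.3], log2fc=[-2.0, -0.5],
                     calls=[CONSUMED, CONSUMED])
    b = make_profile("B", features, [0.75, 0.75], log2fc=[-2.0, -2.0],
                     calls=[CONSUMED, CONSUMED])
    # m2 fails in A (log2fc -0.5 > -1): excluded; m1 passes in both.
    assert shared_depletion_summary([a, b]) == ["m1"]


def test_shared_depletion_engineered_four_features():
    """10 isolates engineered so exactly 4 features are depleted by at
    least half by everyone."""
    rng = np.random.default_rng(12)
    n_iso, n_feat = 10, 40
    props = rng.uniform(0.0, 0.4, size=(n_iso, n_feat))  # weak depletion
    props[:, :4] = rng.uniform(0.6, 0.9, size=(n_iso, 4))  # shared >= half
    # Ensure no other feature is >= 0.5 for all isolates.
    table, _ = generate_metabolome(MetabolomeDesign(
        n_features=n_feat, n_isolates=n_iso, true_proportions=props,
        noise_cv=0.05, seed=13))
    profs = build_profiles(table)
    shared = shared_depletion_summary(profs)
    assert shared == [f"Positive-{i + 1:04d}" for i in range(4)]


def test_recovery_of_true_proportions_small():
    """Estimated proportions track the design truth; doubling replicates
    tightens the recovery (consistency)."""
    props = np.tile(np.linspace(0.3, 0.9, 20), (3, 1))
    errs = {}
    for n_reps in (5, 50):
        table, truth = generate_metabolome(MetabolomeDesign(
            n_features=20, n_isolates=3, true_proportions=props,
            n_reps_isolate=n_reps, seed=21))
        profs = build_profiles(table)
        est = np.vstack([p.proportions.to_numpy() for p in profs])
        errs[n_reps] = np.median(np.abs(est - props))
    assert errs[5] <= 0.05
    assert errs[50] <= errs[5]
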