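import numpy as np
import pandas as pd
import pytest

from phycoflow.containers import (
    BASELINE_PRIMARY,
    CONSUMED,
    ConsumptionProfile,
    FeatureTable,
    GrowthTable,
)


def make_profile(isolate, features, proportions, log2fc=None, calls=None,
                 control_mean=1000.0):
    """Small hand-built consumption profile for interaction tests."""
    proportions = np.asarray(proportions, dtype=float)
    if calls is None:
        calls = np.where(proportions > 0, CONSUMED, "unchanged")
    if log2fc is None:
        with np.errstate(divide="ignore"):
            log2fc = np.log2(1.0 - proportions)
    data = pd.DataFrame(
        {
            "mean_control": control_mean,
            "mean_isolate": control_mean * (1.0 - proportions),
            "log2fc": log2fc,
            "p_adj": np.where(np.asarray(calls) == "unchanged", 1.0, 0.001),
            "call": calls,
            "proportion": proportions,
        },
        index=pd.Index(features, name="feature_id"),
    )
    return ConsumptionProfile(isolate, data)


def make_growth_table(counts_by_pair, baselines, n_reps=3):
    """GrowthTable from {(secondary, primary): count or list} plus
    {secondary: baseline count or list}."""
    rows = []
    for sec, base in baselines.items():
        vals = np.atleast_1d(base)
        if vals.size == 1:
            vals = np.repeat(vals, n_reps)
        for r, v in enumerate(vals):
            rows.append((sec, BASELINE_PRIMARY, r + 1, float(v)))
    for (sec, prim), counts in counts_by_pair.items():
        vals = np.atleast_1d(counts)
        if vals.size == 1:
            vals = np.repeat(vals, n_reps)
        for r, v in enumerate(vals):
            rows.append((sec, prim, r + 1, float(v)))
    return GrowthTable(pd.DataFrame(
        rows, columns=["secondary", "primary", "replicate", "count"]))


@pytest.fixture
def toy_feature_table():
    """Tiny deterministic feature table: 3 features, blank/control/2 isolates.

    Feature F1 is consumed by IsoA (75%), F2 is background-only, F3 is
    produced by IsoB.
    """
    rng = np.random.default_rng(42)

    def reps(mean, n, cv=0.02):
        return mean * (1 + cv * rng.standard_normal(n))

    samples = {}
    groups = {}
    spec = {
        "blank": {"F1": 10, "F2": 10, "F3": 10},
        "control": {"F1": 1000, "F2": 10, "F3": 500},
        "isolate:IsoA": {"F1": 250, "F2": 10, "F3": 500},
        "isolate:IsoB": {"F1": 1000, "F2": 10, "F3": 2000},
    }
    n_by_group = {"blank": 4, "control": 12, "isolate:IsoA": 5,
                  "isolate:IsoB": 5}
    for group, means in spec.items():
        n = n_by_group[group]
        mat = np.vstack([reps(means[f], n) for f in ("F1", "F2", "F3")])
        for i in range(n):
            sid = f"{group.replace(':', '_')}_{i}"
            samples[sid] = mat[:, i]
            groups[sid] = group
    table = FeatureTable(
        pd.DataFrame(samples, index=pd.Index(["F1", "F2", "F3"],
                                             name="feature_id")),
        pd.Series(groups))
    return table
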