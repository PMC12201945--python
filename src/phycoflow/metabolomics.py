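"""From LC-MS/MS feature-intensity tables to per-isolate consumption profiles.

The workflow mirrors an untargeted exometabolomics comparison: (1) keep
only features significantly above the extraction-blank background in at
least one sample group; (2) per isolate, call each feature consumed /
produced / unchanged against the uninoculated spent-medium control using a
Student's t-test with Bonferroni correction and a log2 fold change;
(3) convert consumed calls to proportions p_m,s = 1 - I_s/I_0 (clamped to
[0, 1]), the quantities entering the expected competitive interaction.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BLANK,
    CONSUMED,
    CONTROL,
    ISOLATE_PREFIX,
    PRODUCED,
    UNCHANGED,
    ConsumptionProfile,
    FeatureTable,
    ValidationError,
    align_profiles,
)
from .stats import adjust_pvalues, two_sample_t

log = logging.getLogger(__name__)

__all__ = [
    "filter_above_background",
    "classify_changes",
    "estimate_proportions",
    "shared_depletion_summary",
    "build_profiles",
]


def _check_replicates(table: FeatureTable, groups: Sequence[str]) -> None:
    for g in groups:
        n = len(table.samples_in(g))
        if n < 2:
            raise ValidationError(f"group {g!r} has {n} replicate(s); "
                                  "need >= 2 for a t-test")


def filter_above_background(table: FeatureTable, alpha: float = 0.05,
                            correction: str = "bonferroni",
                            equal_var: bool = True) -> FeatureTable:
    """Retain features significantly above the extraction-blank background.

    A feature is kept when, for at least one non-blank sample group, its
    mean intensity exceeds the blank mean *and* the two-sample t-test
    p-value, adjusted over the full feature x group family, is below
    ``alpha``. The returned table records the number retained and the
    family size in ``meta``.
    """
    groups = table.group_names
    if BLANK not in groups:
        raise ValidationError("feature table has no 'blank' group")
    non_blank = [g for g in groups if g != BLANK]
    if not non_blank:
        raise ValidationError("feature table has no non-blank group")
    _check_replicates(table, groups)

    blank = table.group_matrix(BLANK)
    blank_mean = blank.mean(axis=1)
    n_features = len(table.feature_ids)

    pvals = np.empty((n_features, len(non_blank)))
    above = np.empty((n_features, len(non_blank)), dtype=bool)
    for j, g in enumerate(non_blank):
        mat = table.group_matrix(g)
        _, p = two_sample_t(mat, blank, axis=1, equal_var=equal_var)
        pvals[:, j] = p
        above[:, j] = mat.mean(axis=1) > blank_mean

    n_tests = pvals.size
    p_adj = adjust_pvalues(pvals.ravel(), correction).reshape(pvals.shape)
    keep = np.any(above & (p_adj < alpha), axis=1)
    retained = [f for f, k in zip(table.feature_ids, keep) if k]
    log.info("background filter: %d/%d features retained "
             "(family of %d tests, %s at alpha=%g)",
             len(retained), n_features, n_tests, correction, alpha)
    return table.subset(retained, n_retained=len(retained), n_tests=n_tests,
                        filter_alpha=alpha, filter_correction=correction)


def classify_changes(table: FeatureTable, control_group: str = CONTROL,
                     alpha: float = 0.05, correction: str = "bonferroni",
                     equal_var: bool = True) -> list[ConsumptionProfile]:
    """Call consumption / production per (isolate, feature) vs. the control.

    For each isolate group, log2fc = log2(I_s / I_0) of the replicate mean
    intensities; a feature is ``consumed`` when the adjusted p <= alpha and
    I_s < I_0, ``produced`` when adjusted p <= alpha and I_s > I_0, else
    ``unchanged``. Bonferroni (or other) adjustment spans all
    feature x isolate contrasts of the run. Zero-control features with
    nonzero isolate intensity get a +inf log2fc sentinel and are flagged;
    proportions are left at 0 until :func:`estimate_proportions`.
    """
    groups = table.group_names
    if control_group not in groups:
        raise ValidationError(f"control group {control_group!r} not present")
    isolate_groups = [g for g in groups if g.startswith(ISOLATE_PREFIX)]
    if not isolate_groups:
        raise ValidationError("no isolate groups (prefix 'isolate:') present")
    _check_replicates(table, [control_group] + isolate_groups)

    control = table.group_matrix(control_group)
    control_mean = control.mean(axis=1)
    features = table.feature_ids

    means = {}
    pvals = np.empty((len(features), len(isolate_groups)))
    for j, g in enumerate(isolate_groups):
        mat = table.group_matrix(g)
        means[g] = mat.mean(axis=1)
        _, p = two_sample_t(mat, control, axis=1, equal_var=equal_var)
        pvals[:, j] = p
    n_tests = pvals.size
    p_adj = adjust_pvalues(pvals.ravel(), correction).reshape(pvals.shape)
    log.info("change calls: family of %d tests (%s)", n_tests, correction)

    profiles = []
    for j, g in enumerate(isolate_groups):
        isolate = g[len(ISOLATE_PREFIX):]
        i_s = means[g]
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(i_s / control_mean)
        both_zero = (i_s == 0) & (control_mean == 0)
        log2fc[both_zero] = 0.0
        zero_control = (control_mean == 0) & (i_s > 0)
        log2fc[zero_control] = np.inf
        if zero_control.any():
            log.warning("isolate %s: %d features with zero control mean; "
                        "log2fc set to +inf", isolate, int(zero_control.sum()))

        sig = p_adj[:, j] <= alpha
        call = np.where(sig & (i_s < control_mean), CONSUMED,
                        np.where(sig & (i_s > control_mean), PRODUCED,
                                 UNCHANGED))
        call[both_zero] = UNCHANGED
        data = pd.DataFrame(
            {
                "mean_control": control_mean,
                "mean_isolate": i_s,
                "log2fc": log2fc,
                "p_adj": p_adj[:, j],
                "call": call,
                "proportion": 0.0,
            },
            index=pd.Index(features, name="feature_id"),
        )
        flags = {"n_tests": n_tests, "alpha": alpha, "correction": correction,
                 "zero_control_features":
                     [f for f, z in zip(features, zero_control) if z]}
        profiles.append(ConsumptionProfile(isolate, data, flags))
    return profiles


def estimate_proportions(profile: ConsumptionProfile,
                         convention: str = "one-minus-ratio",
                         consumed_only: bool = True) -> ConsumptionProfile:
    """Fill consumption proportions p_m,s from the profile's mean intensities.

    Default convention: p = clamp(1 - I_s/I_0, 0, 1), so complete depletion
    gives 1 and no change gives 0. The literal intensity-ratio reading
    (p = clamp(I_s/I_0, 0, 1)) is available as ``convention="ratio"`` for
    sensitivity checks. With ``consumed_only`` (default), proportions are
    assigned only to features called consumed; others stay 0, preventing
    production or noise from inflating downstream overlap. Features with a
    zero control mean get p = 0 and are flagged.
    """
    data = profile.data.copy()
    i0 = data["mean_control"].to_numpy(dtype=float)
    i_s = data["mean_isolate"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i0 > 0, i_s / i0, np.nan)
    if convention == "one-minus-ratio":
        p = 1.0 - ratio
    elif convention == "ratio":
        p = ratio
    else:
        raise ValidationError(f"unknown proportion convention {convention!r}")
    p = np.clip(p, 0.0, 1.0)
    undefined = ~np.isfinite(p)
    p[undefined] = 0.0
    if consumed_only:
        p = np.where(data["call"].to_numpy() == CONSUMED, p, 0.0)
    data["proportion"] = p
    flags = dict(profile.flags)
    flags["proportion_convention"] = convention
    flags["undefined_proportion_features"] = [
        f for f, u in zip(data.index, undefined) if u]
    if flags["undefined_proportion_features"]:
        log.warning("isolate %s: %d features with I_0 = 0; proportion set "
                    "to 0", profile.isolate,
                    len(flags["undefined_proportion_features"]))
    return ConsumptionProfile(profile.isolate, data, flags)


def build_profiles(table: FeatureTable, control_group: str = CONTROL,
                   alpha: float = 0.05, correction: str = "bonferroni",
                   convention: str = "one-minus-ratio",
                   equal_var: bool = True) -> list[ConsumptionProfile]:
    """Classify changes and fill proportions in one call."""
    return [estimate_proportions(p, convention)
            for p in classify_changes(table, control_group, alpha,
                                      correction, equal_var)]


def shared_depletion_summary(profiles: Sequence[ConsumptionProfile],
                             threshold_log2fc: float = -1.0) -> list[str]:
    """Features consumed by *every* isolate with log2fc <= threshold.

    With the default threshold of -1 this lists the metabolites depleted by
    at least half by all isolates.
    """
    profiles = align_profiles(profiles)
    features = profiles[0].feature_ids
    keep = np.ones(len(features), dtype=bool)
    for prof in profiles:
        d = prof.data
        keep &= ((d["call"].to_numpy() == CONSUMED)
                 & (d["log2fc"].to_numpy(dtype=float) <= threshold_log2fc))
    return [f for f, k in zip(features, keep) if k]
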