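"""Directed pairwise interaction coefficients between bacterial strains.

Three complementary statistics describe how a *primary* strain (the one
with first access to the algal exometabolite pool) affects a *secondary*
strain that receives the altered pool:

ECI (expected competitive interaction), from exometabolomics consumption
proportions p_m (fraction of metabolite m removed when grown alone)::

    ECI(s, p) = - sum_m p[m, s] * p[m, p] / sum_m p[m, s] ** 2

ECI is always in [-1, 0]: -1 when primary and secondary have identical
affinities for every metabolite (complete competition, e.g. a strain with
itself), 0 when the sets of consumed metabolites are disjoint.

MRO (metabolic resource overlap), from minimal nutrient-requirement sets
M derived from genome-scale models::

    MRO(s, p) = |M_s intersect M_p| / |M_s|

MRO is directed and lies in [0, 1]: 1 when the primary can take up every
resource the secondary requires, 0 when it can take up none.

SI (sequential interaction), from cell counts of the secondary strain
grown on the primary strain's spent medium (G_s,p) versus on plain algal
spent medium (G_s,PtSM)::

    SI(s, p) = -(G_s,PtSM - G_s,p) / G_s,PtSM = G_s,p / G_s,PtSM - 1

SI is >= -1 for non-negative counts: -1 means no growth (complete
competition), 0 the same growth, +1 twice the growth. Unlike ECI it can be
positive, capturing facilitation (cross-feeding, inhibitor removal).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import (
    BASELINE_PRIMARY,
    ConsumptionProfile,
    GrowthTable,
    InteractionMatrix,
    ValidationError,
    align_profiles,
)

log = logging.getLogger(__name__)

__all__ = [
    "compute_eci",
    "compute_mro",
    "compute_si",
    "eci_matrix",
    "mro_matrix",
    "si_matrix",
    "classify_interaction",
    "interaction_tally",
    "compare_matrices",
    "growth_call",
]


def compute_eci(p_secondary: Sequence[float], p_primary: Sequence[float]) -> float:
    """Expected competitive interaction of a primary on a secondary strain.

    Parameters are the two strains' consumption-proportion vectors over the
    same metabolite ordering, entries in [0, 1]. Returns a value in
    [-1, 0]. A secondary strain that consumes nothing has no competition to
    suffer; the coefficient is reported as 0.0 (callers that need to
    distinguish this case should test ``p_secondary`` directly, or use
    :func:`eci_matrix` which carries a validity flag).
    """
    s = np.asarray(p_secondary, dtype=float)
    p = np.asarray(p_primary, dtype=float)
    if s.shape != p.shape or s.ndim != 1:
        raise ValidationError("proportion vectors must be 1-D and equal length")
    for name, v in (("secondary", s), ("primary", p)):
        if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
            raise ValidationError(f"{name} proportions must lie in [0, 1]")
    denom = float(np.dot(s, s))
    if denom == 0.0:
        warnings.warn("secondary strain consumes nothing; ECI reported as 0",
                      stacklevel=2)
        return 0.0
    return -float(np.dot(s, p)) / denom + 0.0  # +0.0 normalises -0.0


def compute_mro(m_secondary: Iterable, m_primary: Iterable) -> float:
    """Directed metabolic resource overlap |M_s ∩ M_p| / |M_s|."""
    ms = frozenset(m_secondary)
    mp = frozenset(m_primary)
    if not ms:
        raise ValidationError("secondary strain's nutrient set is empty; "
                              "MRO is undefined")
    return len(ms & mp) / len(ms)


def compute_si(growth: GrowthTable, secondary: str, primary: str,
               aggregate: str = "ratio-of-means") -> float:
    """Sequential interaction coefficient from replicate cell counts.

    Replicates are aggregated as a ratio of means by default (robust when
    individual counts are small); ``aggregate="mean-of-ratios"`` averages
    per-replicate ratios instead (requires matching replicate counts).
    """
    g_p = growth.counts(secondary, primary)
    g_base = growth.baseline_counts(secondary)
    if g_base.size == 0:
        raise ValidationError(f"no baseline ({BASELINE_PRIMARY}) counts for "
                              f"secondary {secondary!r}")
    if g_p.size == 0:
        raise ValidationError(f"no counts for pair ({secondary!r}, {primary!r})")
    base_mean = float(np.mean(g_base))
    if base_mean == 0.0:
        raise ValidationError(f"baseline mean is 0 for secondary "
                              f"{secondary!r}; SI undefined")
    if aggregate == "ratio-of-means":
        return float(np.mean(g_p)) / base_mean - 1.0
    if aggregate == "mean-of-ratios":
        if g_p.size != g_base.size:
            raise ValidationError("mean-of-ratios needs equal replicate counts")
        if np.any(g_base == 0):
            raise ValidationError("zero baseline replicate; ratio undefined")
        return float(np.mean(g_p / g_base)) - 1.0
    raise ValidationError(f"unknown aggregation {aggregate!r}")


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------


def eci_matrix(profiles: Sequence[ConsumptionProfile]) -> InteractionMatrix:
    """Build the directed ECI matrix from per-isolate consumption profiles.

    Entry [primary, secondary] applies the primary's proportions against the
    secondary's. Cells whose secondary consumes nothing are 0 and flagged
    invalid.
    """
    profiles = align_profiles(profiles)
    strains = [p.isolate for p in profiles]
    vectors = {p.isolate: p.proportions.to_numpy(dtype=float) for p in profiles}
    values = pd.DataFrame(0.0, index=strains, columns=strains)
    valid = pd.DataFrame(True, index=strains, columns=strains)
    for s in strains:
        if not np.any(vectors[s] > 0):
            valid.loc[:, s] = False
            log.info("secondary %s consumes nothing; ECI column flagged", s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in strains:
            for s in strains:
                values.loc[p, s] = compute_eci(vectors[s], vectors[p])
    return InteractionMatrix("ECI", values, valid)


def mro_matrix(uptake_sets: Mapping[str, Iterable]) -> InteractionMatrix:
    """Directed MRO matrix from strain -> nutrient-set mapping."""
    strains = list(uptake_sets)
    sets = {s: frozenset(uptake_sets[s]) for s in strains}
    values = pd.DataFrame(0.0, index=strains, columns=strains)
    valid = pd.DataFrame(True, index=strains, columns=strains)
    for p in strains:
        for s in strains:
            if not sets[s]:
                valid.loc[p, s] = False
                continue
            values.loc[p, s] = compute_mro(sets[s], sets[p])
    return InteractionMatrix("MRO", values, valid)


def si_matrix(growth: GrowthTable,
              aggregate: str = "ratio-of-means") -> InteractionMatrix:
    """Directed SI matrix from a sequential growth-count table."""
    strains = growth.secondaries
    prim = growth.primaries
    if set(prim) - set(strains):
        raise ValidationError("growth table primaries are not a subset of "
                              "secondaries; cannot build a square matrix")
    values = pd.DataFrame(np.nan, index=strains, columns=strains)
    valid = pd.DataFrame(False, index=strains, columns=strains)
    for p in prim:
        for s in strains:
            try:
                values.loc[p, s] = compute_si(growth, s, p, aggregate)
                valid.loc[p, s] = True
            except ValidationError:
                values.loc[p, s] = 0.0
    values = values.fillna(0.0)
    return InteractionMatrix("SI", values, valid)


# ---------------------------------------------------------------------------
# Classification and metric comparison
# ---------------------------------------------------------------------------


def classify_interaction(si: float, neutral_band: float = 0.0) -> str:
    """Classify a sequential interaction by sign.

    ``neutral_band`` widens the neutral class to |SI| <= band; the default
    0 reproduces a strict sign-based call.
    """
    if not np.isfinite(si):
        raise ValidationError("SI must be finite")
    if si < -neutral_band:
        return "competitive"
    if si > neutral_band:
        return "facilitative"
    return "neutral"


def interaction_tally(matrix: InteractionMatrix, neutral_band: float = 0.0,
                      include_diagonal: bool = True) -> dict:
    """Count competitive / neutral / facilitative cells of an SI matrix."""
    pairs = matrix.pairs(include_diagonal=include_diagonal)
    pairs = pairs[pairs["valid"]]
    calls = [classify_interaction(v, neutral_band) for v in pairs["value"]]
    return {
        "n_pairs": len(calls),
        "competitive": calls.count("competitive"),
        "neutral": calls.count("neutral"),
        "facilitative": calls.count("facilitative"),
    }


def compare_matrices(a: InteractionMatrix, b: InteractionMatrix,
                     method: str = "spearman",
                     include_diagonal: bool = True) -> dict:
    """Correlate two interaction matrices over their ordered strain pairs.

    Only cells valid in both matrices enter; excluded cells are logged.
    Returns ``{statistic, p_value, n_pairs, fraction_a_greater, method}``
    where ``fraction_a_greater`` is the share of pairs with A > B (used to
    report, e.g., how many SIs are less negative than the matching ECIs).
    """
    if a.strains != b.strains:
        raise ValidationError("matrices must share the same strain ordering")
    pa = a.pairs(include_diagonal=include_diagonal)
    pb = b.pairs(include_diagonal=include_diagonal)
    ok = pa["valid"].to_numpy() & pb["valid"].to_numpy()
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("compare_matrices: excluded %d invalid pairs", n_excluded)
    x = pa.loc[ok, "value"].to_numpy(dtype=float)
    y = pb.loc[ok, "value"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 valid pairs for a correlation")
    if method == "pearson":
        stat, p = sps.pearsonr(x, y)
    elif method == "spearman":
        stat, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "n_pairs": int(x.size),
        "n_excluded": n_excluded,
        "fraction_a_greater": float(np.mean(x > y)),
        "method": method,
    }


# ---------------------------------------------------------------------------
# Sole-carbon-source growth calls (phenotype microarray)
# ---------------------------------------------------------------------------


def growth_call(times: Sequence[float], absorbance: Sequence[float],
                blank_absorbance: Sequence[float],
                abs_threshold: float = 0.05, blank_factor: float = 2.0,
                window: int = 3) -> bool:
    """Classify growth on a sole carbon source from an OD600 time series.

    The series is smoothed with a centred moving average (``window``
    points); growth is called when the smoothed rise above the initial
    reading exceeds both ``abs_threshold`` (absolute OD units) and
    ``blank_factor`` times the blank's rise.
    """
    t = np.asarray(times, dtype=float)
    od = np.asarray(absorbance, dtype=float)
    blank = np.asarray(blank_absorbance, dtype=float)
    if t.size < 3:
        raise ValidationError("need >= 3 timepoints")
    if od.shape != t.shape or blank.shape != t.shape:
        raise ValidationError("series must share the time grid")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("time vector must be strictly increasing")

    def _smooth(x: np.ndarray) -> np.ndarray:
        if window <= 1 or x.size < window:
            return x
        kernel = np.ones(window) / window
        sm = np.convolve(x, kernel, mode="valid")
        pad_left = (x.size - sm.size) // 2
        pad_right = x.size - sm.size - pad_left
        return np.concatenate([x[:pad_left], sm, x[x.size - pad_right:]])

    od_s = _smooth(od)
    blank_s = _smooth(blank)
    delta = float(np.max(od_s) - od_s[0])
    blank_delta = float(np.max(blank_s) - blank_s[0])
    return delta > abs_threshold and delta > blank_factor * blank_delta
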