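"""Synthetic data generators with known ground truth.

Each generator emulates one of the pipeline's measurement designs so the
whole analysis can be exercised and scored against truth:

* :func:`generate_metabolome` — LC-MS/MS feature intensities for blanks,
  uninoculated spent-medium controls and isolate-inoculated replicates,
  with strain-specific consumption proportions and production rates;
* :func:`generate_sequential` — secondary-strain cell counts on each
  primary strain's spent medium, from a true SI matrix;
* :func:`generate_nanosims` — per-cell NanoSIMS ion counts at a chosen net
  carbon incorporation (C_net) distribution, Poisson counting statistics;
* :func:`generate_uptake_sets` — minimal-nutrient sets with a prescribed
  directed resource overlap;
* :func:`simulate_consumer_resource` — a linear-yield consumer-resource
  model linking depletion by a primary strain to secondary growth.

Intensity and count noise is multiplicative lognormal (parameterised so
the mean equals the design expectation); ion counts are Poisson. All
generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    BASELINE_PRIMARY,
    BLANK,
    CONSUMED,
    CONTROL,
    ISOLATE_PREFIX,
    PRODUCED,
    UNCHANGED,
    ConsumptionProfile,
    FeatureTable,
    GrowthTable,
    ValidationError,
)

__all__ = [
    "MetabolomeDesign",
    "SequentialDesign",
    "NanoSimsDesign",
    "generate_metabolome",
    "generate_sequential",
    "generate_nanosims",
    "generate_uptake_sets",
    "simulate_consumer_resource",
    "random_proportions",
    "random_si_matrix",
]


def _lognormal_noise(rng: np.random.Generator, cv: float,
                     size) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def random_proportions(n_isolates: int, n_features: int,
                       density: float = 0.3,
                       prop_range: tuple[float, float] = (0.3, 0.9),
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Sparse isolate x feature consumption-proportion matrix.

    Each isolate consumes a random ``density`` fraction of the features
    with proportions drawn uniformly from ``prop_range``; the remaining
    entries are 0. Defaults reflect that roughly a third of detected
    features changed for at least one isolate, with clearly measurable
    depletion where they did.
    """
    rng = rng or np.random.default_rng()
    consumed = rng.random((n_isolates, n_features)) < density
    props = rng.uniform(*prop_range, size=(n_isolates, n_features))
    return np.where(consumed, props, 0.0)


def random_si_matrix(n_strains: int, negative_fraction: float = 0.7,
                     negative_range: tuple[float, float] = (-1.0, 0.0),
                     positive_range: tuple[float, float] = (0.0, 0.5),
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """True SI matrix mixing competition and facilitation.

    Each ordered pair is competitive (SI uniform in ``negative_range``)
    with probability ``negative_fraction`` and facilitative (uniform in
    ``positive_range``) otherwise; the default 70/30 split mirrors the
    prevalence of competition-dominated pairs among marine
    phycosphere isolates.
    """
    rng = rng or np.random.default_rng()
    neg = rng.random((n_strains, n_strains)) < negative_fraction
    si = np.where(neg, rng.uniform(*negative_range, (n_strains, n_strains)),
                  rng.uniform(*positive_range, (n_strains, n_strains)))
    return si


# ---------------------------------------------------------------------------
# Metabolome
# ---------------------------------------------------------------------------


@dataclass
class MetabolomeDesign:
    """Design of a synthetic exometabolomics experiment.

    The replicate structure defaults to the common bench layout: 5
    inoculated replicates per isolate, 12 uninoculated spent-medium
    controls, plus extraction blanks. Per-feature baseline intensities are
    lognormal (``baseline_log_mean``/``baseline_log_sd`` on the natural-log
    scale); replicate intensities scatter multiplicatively with coefficient
    of variation ``noise_cv``. ``true_proportions[i, m]`` is the fraction
    of feature m's baseline that isolate i removes; ``production_rates``
    adds absolute intensity instead. Consumption and production are
    mutually exclusive per (isolate, feature) so that sign-based calls
    are identifiable. ``blank_level`` is the low instrument background
    around which extraction blanks scatter.
    """

    n_features: int = 162
    n_isolates: int = 10
    n_reps_isolate: int = 5
    n_reps_control: int = 12
    n_reps_blank: int = 4
    baseline_log_mean: float = float(np.log(1e6))
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.10
    blank_level: float = 1e3
    true_proportions: np.ndarray | None = None
    production_rates: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_features", "n_isolates"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("n_reps_isolate", "n_reps_control", "n_reps_blank"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.blank_level < 0:
            raise ValidationError("blank_level must be >= 0")
        shape = (self.n_isolates, self.n_features)
        if self.true_proportions is not None:
            tp = np.asarray(self.true_proportions, dtype=float)
            if tp.shape != shape:
                raise ValidationError("true_proportions must be "
                                      f"isolates x features {shape}")
            if np.any((tp < 0) | (tp > 1)):
                raise ValidationError("true_proportions must lie in [0, 1]")
        if self.production_rates is not None:
            pr = np.asarray(self.production_rates, dtype=float)
            if pr.shape != shape:
                raise ValidationError("production_rates must be "
                                      f"isolates x features {shape}")
            if np.any(pr < 0):
                raise ValidationError("production_rates must be >= 0")
        if (self.true_proportions is not None
                and self.production_rates is not None):
            both = (np.asarray(self.true_proportions) > 0) \
                   & (np.asarray(self.production_rates) > 0)
            if both.any():
                raise ValidationError(
                    "true_proportions and production_rates overlap for "
                    f"{int(both.sum())} (isolate, feature) cells")


def generate_metabolome(design: MetabolomeDesign
                        ) -> tuple[FeatureTable, list[ConsumptionProfile]]:
    """Simulate a feature table and return it with its ground truth.

    Expected intensities: blanks around ``blank_level``; controls around
    ``blank_level + baseline``; isolate samples around
    ``blank_level + baseline * (1 - p) + production``. The returned
    ground-truth profiles carry the design proportions and the expected
    log2 fold changes so recovery can be scored.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_i, n_f = design.n_isolates, design.n_features

    if design.true_proportions is None:
        props = random_proportions(n_i, n_f, rng=rng)
    else:
        props = np.asarray(design.true_proportions, dtype=float)
    if design.production_rates is None:
        prod = np.zeros((n_i, n_f))
    else:
        prod = np.asarray(design.production_rates, dtype=float)

    baseline = rng.lognormal(design.baseline_log_mean,
                             design.baseline_log_sd, size=n_f)
    features = [f"Positive-{i + 1:04d}" for i in range(n_f)]
    isolates = [f"Iso{i + 1:02d}" for i in range(n_i)]

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}

    def _draw(expected: np.ndarray, n_reps: int, prefix: str, group: str):
        noise = _lognormal_noise(rng, design.noise_cv, (n_f, n_reps))
        mat = expected[:, None] * noise
        for r in range(n_reps):
            sid = f"{prefix}_{r + 1:02d}"
            columns[sid] = mat[:, r]
            groups[sid] = group

    _draw(np.full(n_f, design.blank_level), design.n_reps_blank,
          "blank", BLANK)
    _draw(design.blank_level + baseline, design.n_reps_control,
          "control", CONTROL)
    truth: list[ConsumptionProfile] = []
    control_expected = design.blank_level + baseline
    for i, iso in enumerate(isolates):
        expected = (design.blank_level + baseline * (1.0 - props[i])
                    + prod[i])
        _draw(expected, design.n_reps_isolate, iso, ISOLATE_PREFIX + iso)
        with np.errstate(divide="ignore"):
            log2fc = np.log2(expected / control_expected)
        call = np.where(props[i] > 0, CONSUMED,
                        np.where(prod[i] > 0, PRODUCED, UNCHANGED))
        data = pd.DataFrame(
            {
                "mean_control": control_expected,
                "mean_isolate": expected,
                "log2fc": log2fc,
                "p_adj": np.where(call == UNCHANGED, 1.0, 0.0),
                "call": call,
                "proportion": props[i],
            },
            index=pd.Index(features, name="feature_id"),
        )
        truth.append(ConsumptionProfile(iso, data, {"ground_truth": True}))

    intensities = pd.DataFrame(columns,
                               index=pd.Index(features, name="feature_id"))
    table = FeatureTable(intensities, pd.Series(groups),
                         meta={"design_seed": design.seed})
    return table, truth


# ---------------------------------------------------------------------------
# Sequential spent-media exchange
# ---------------------------------------------------------------------------


@dataclass
class SequentialDesign:
    """Design of a synthetic sequential spent-media exchange.

    ``true_si[p, s]`` is the true sequential-interaction coefficient of
    primary strain p on secondary strain s (>= -1). ``baseline_counts``
    gives each secondary strain's expected cell count on plain algal spent
    medium (scalar or per-strain vector). Replicate counts scatter
    multiplicatively with CV ``noise_cv``; the 3-replicate default matches
    a 48-well assay plate with triplicate wells per primary strain.
    """

    n_strains: int = 10
    true_si: np.ndarray | None = None
    baseline_counts: float | np.ndarray = 1e5
    n_reps: int = 3
    noise_cv: float = 0.10
    strains: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValidationError("n_strains must be >= 1")
        if self.strains is not None and len(self.strains) != self.n_strains:
            raise ValidationError("strains must have n_strains entries")
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.true_si is not None:
            si = np.asarray(self.true_si, dtype=float)
            if si.shape != (self.n_strains, self.n_strains):
                raise ValidationError("true_si must be n_strains x n_strains")
            if np.any(si < -1):
                raise ValidationError("true_si must be >= -1 elementwise")
        base = np.asarray(self.baseline_counts, dtype=float)
        if np.any(base <= 0):
            raise ValidationError("baseline_counts must be > 0")


def generate_sequential(design: SequentialDesign) -> GrowthTable:
    """Simulate secondary-strain cell counts for every ordered strain pair.

    Expected count of secondary s on primary p's medium is
    ``baseline_s * (1 + true_si[p, s])``; baseline rows (primary label
    ``PtSM``) are included. Counts are truncated at zero.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_strains
    si = (np.asarray(design.true_si, dtype=float)
          if design.true_si is not None
          else random_si_matrix(n, rng=rng))
    base = np.broadcast_to(np.asarray(design.baseline_counts, dtype=float),
                           (n,)).copy()
    strains = (list(design.strains) if design.strains is not None
               else [f"S{i + 1:02d}" for i in range(n)])

    rows = []
    for s_idx, s in enumerate(strains):
        for rep in range(design.n_reps):
            count = base[s_idx] * _lognormal_noise(rng, design.noise_cv, None)
            rows.append((s, BASELINE_PRIMARY, rep + 1, max(float(count), 0.0)))
        for p_idx, p in enumerate(strains):
            expected = base[s_idx] * (1.0 + si[p_idx, s_idx])
            for rep in range(design.n_reps):
                count = expected * _lognormal_noise(rng, design.noise_cv, None)
                rows.append((s, p, rep + 1, max(float(count), 0.0)))
    data = pd.DataFrame(rows, columns=["secondary", "primary",
                                       "replicate", "count"])
    table = GrowthTable(data)
    table.true_si = pd.DataFrame(si, index=strains, columns=strains)
    return table


# ---------------------------------------------------------------------------
# NanoSIMS
# ---------------------------------------------------------------------------


@dataclass
class NanoSimsDesign:
    """Design of a synthetic NanoSIMS measurement of one treatment.

    Per cell, a true C_net (percent of carbon derived from the labelled
    alga) is drawn from a lognormal distribution with median
    ``true_cnet_median`` and percentage-point spread ``true_cnet_spread``
    (approximately the standard deviation; the lognormal shape parameter is
    ``spread / median``). The cell's expected 13C atom fraction is
    F = F_nat + (C_net/100) (F_alga - F_nat); ion counts follow Poisson
    statistics with ``mean_total_counts`` expected counts in the major
    (12C12C) channel and the dimer convention for 12C13C, so that
    ([12C13C/12C12C] / 2) estimates the 13C/12C ratio. The 15N channel is
    analogous (monomer; ``n15_enrichment`` scales the natural 15N/14N
    ratio). ``n_algal_rois`` optionally adds algal cells (treatment label
    ``alga``) at the full labelling level, from which the algal endmember
    can be estimated downstream.
    """

    n_cells_per_treatment: int = 300
    true_cnet_median: float = 2.71
    true_cnet_spread: float = 1.0
    algal_atom_fraction: float = 0.05
    natural_ratio_13C: float = 0.011237
    natural_ratio_15N: float = 0.003676
    mean_total_counts: float = 1e6
    n15_enrichment: float = 1.0
    treatment: str = "treatment"
    well: str = "distal"
    n_algal_rois: int = 0
    mean_biovolume: float = 0.3
    biovolume_cv: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_treatment < 1:
            raise ValidationError("n_cells_per_treatment must be >= 1")
        if not 0 <= self.true_cnet_median <= 100:
            raise ValidationError("true_cnet_median must lie in [0, 100]")
        if self.true_cnet_spread < 0:
            raise ValidationError("true_cnet_spread must be >= 0")
        f_nat = self.natural_ratio_13C / (1 + self.natural_ratio_13C)
        if not (0 < self.algal_atom_fraction < 1):
            raise ValidationError("algal_atom_fraction must lie in (0, 1)")
        if self.algal_atom_fraction <= f_nat:
            raise ValidationError("algal_atom_fraction must exceed the "
                                  "natural 13C atom fraction")
        if self.natural_ratio_13C <= 0 or self.natural_ratio_15N <= 0:
            raise ValidationError("natural ratios must be > 0")
        if self.mean_total_counts <= 0:
            raise ValidationError("mean_total_counts must be > 0")


def generate_nanosims(design: NanoSimsDesign) -> pd.DataFrame:
    """Simulate a per-cell ROI ion-count table for one treatment."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_cells_per_treatment

    if design.true_cnet_median == 0:
        cnet = np.zeros(n)
    elif design.true_cnet_spread == 0:
        cnet = np.full(n, design.true_cnet_median)
    else:
        sigma = design.true_cnet_spread / design.true_cnet_median
        cnet = design.true_cnet_median * rng.lognormal(0.0, sigma, size=n)
    cnet = np.minimum(cnet, 100.0)

    f_nat = design.natural_ratio_13C / (1 + design.natural_ratio_13C)
    f_cell = f_nat + cnet / 100.0 * (design.algal_atom_fraction - f_nat)
    rows = _draw_rois(rng, design, f_cell, design.treatment, "cell")
    if design.n_algal_rois:
        f_alga = np.full(design.n_algal_rois, design.algal_atom_fraction)
        rows += _draw_rois(rng, design, f_alga, "alga", "alga")
    rois = pd.DataFrame(rows, columns=["roi_id", "treatment", "well",
                                       "c12c12", "c12c13", "c12c14n",
                                       "c12c15n", "biovolume"])
    # Tuple, not ndarray: DataFrame.attrs must stay comparable under concat.
    rois.attrs["true_cnet"] = tuple(float(c) for c in cnet)
    return rois


def _draw_rois(rng: np.random.Generator, design: NanoSimsDesign,
               f13c: np.ndarray, treatment: str, prefix: str) -> list[tuple]:
    """Draw Poisson ion counts for cells at the given 13C atom fractions."""
    n = len(f13c)
    r13 = f13c / (1.0 - f13c)
    mt = design.mean_total_counts
    c12c12 = rng.poisson(mt, size=n)
    # Dimer: expected 12C13C / 12C12C = 2 * (13C/12C).
    c12c13 = rng.poisson(mt * 2.0 * r13, size=n)
    r15 = design.natural_ratio_15N * design.n15_enrichment
    c12c14n = rng.poisson(mt, size=n)
    c12c15n = rng.poisson(mt * r15, size=n)
    biovol = design.mean_biovolume * _lognormal_noise(
        rng, design.biovolume_cv, n)
    return [(f"{prefix}_{treatment}_{i + 1:04d}", treatment, design.well,
             int(c12c12[i]), int(c12c13[i]), int(c12c14n[i]),
             int(c12c15n[i]), float(biovol[i])) for i in range(n)]


# ---------------------------------------------------------------------------
# Uptake sets and consumer-resource model
# ---------------------------------------------------------------------------


def generate_uptake_sets(n_strains: int, universe_size: int, overlap: float,
                         seed: int | None = None, set_size: int = 20,
                         strains: Sequence[str] | None = None
                         ) -> dict[str, frozenset]:
    """Minimal-nutrient sets with a prescribed directed resource overlap.

    Every strain's set shares a common core of ``round(overlap *
    set_size)`` nutrients; the remainder of each set is private and
    disjoint between strains, so the directed MRO of every ordered pair
    equals ``overlap`` exactly (up to core-size rounding). Raises when the
    universe is too small to hold the core plus disjoint private pools.
    """
    if not 0 <= overlap <= 1:
        raise ValidationError("overlap must lie in [0, 1]")
    if n_strains < 1 or set_size < 1:
        raise ValidationError("n_strains and set_size must be >= 1")
    core_size = int(round(overlap * set_size))
    private = set_size - core_size
    needed = core_size + n_strains * private
    if needed > universe_size:
        raise ValidationError(
            f"universe too small: need {needed} nutrients for {n_strains} "
            f"sets of {set_size} at overlap {overlap}, have {universe_size}")
    if strains is not None and len(strains) != n_strains:
        raise ValidationError("strains must have n_strains entries")
    names = (list(strains) if strains is not None
             else [f"S{s + 1:02d}" for s in range(n_strains)])
    rng = np.random.default_rng(seed)
    universe = [f"N{i + 1:04d}" for i in range(universe_size)]
    order = rng.permutation(universe_size)
    core = [universe[i] for i in order[:core_size]]
    out: dict[str, frozenset] = {}
    pos = core_size
    for name in names:
        priv = [universe[i] for i in order[pos:pos + private]]
        pos += private
        out[name] = frozenset(core + priv)
    return out


def simulate_consumer_resource(p_primary: Sequence[float],
                               p_secondary: Sequence[float],
                               pool: Sequence[float],
                               yields: Sequence[float]
                               ) -> tuple[float, float]:
    """Linear-yield consumer-resource model of a sequential exchange.

    The secondary strain converts the fraction ``p_secondary[m]`` of what
    remains of metabolite m into biomass at ``yields[m]`` per unit; the
    primary strain has already removed the fraction ``p_primary[m]`` of
    the pool. Returns ``(growth_with_primary, growth_without_primary)``::

        G_without = sum_m yields[m] * p_sec[m] * pool[m]
        G_with    = sum_m yields[m] * p_sec[m] * pool[m] * (1 - p_prim[m])

    from which SI = G_with / G_without - 1. For binary secondary profiles
    with equal pools and yields this SI equals ECI(p_secondary, p_primary)
    exactly.
    """
    pp = np.asarray(p_primary, dtype=float)
    ps = np.asarray(p_secondary, dtype=float)
    pool = np.asarray(pool, dtype=float)
    y = np.asarray(yields, dtype=float)
    if not (pp.shape == ps.shape == pool.shape == y.shape):
        raise ValidationError("all vectors must have the same length")
    if np.any(pool < 0) or np.any(y < 0):
        raise ValidationError("pool amounts and yields must be >= 0")
    for name, v in (("p_primary", pp), ("p_secondary", ps)):
        if np.any((v < 0) | (v > 1)):
            raise ValidationError(f"{name} must lie in [0, 1]")
    g_without = float(np.sum(y * ps * pool))
    g_with = float(np.sum(y * ps * pool * (1.0 - pp)))
    return g_with, g_without
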