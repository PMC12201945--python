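"""Core in-memory containers shared across the pipeline.

All containers are thin, validated wrappers around pandas objects so that
every module exchanges the same few shapes: a feature-by-sample intensity
matrix with group labels, per-isolate consumption profiles, directed
primary-by-secondary interaction matrices, long-format growth-count tables,
and NanoSIMS region-of-interest (ROI) tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sample-group label for extraction blanks.
BLANK = "blank"
#: Sample-group label for uninoculated spent-medium controls.
CONTROL = "control"
#: Prefix marking isolate-inoculated sample groups, e.g. ``isolate:Devosia``.
ISOLATE_PREFIX = "isolate:"
#: Primary-strain label marking plain algal spent medium (the SI baseline).
BASELINE_PRIMARY = "PtSM"

#: Consumption-call values used throughout.
CONSUMED = "consumed"
PRODUCED = "produced"
UNCHANGED = "unchanged"


class ValidationError(ValueError):
    """Raised when a container or design violates its invariants."""


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with per-sample group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by feature id with one column per sample.
        Values must be finite and non-negative.
    groups
        Series mapping sample id to group label: ``blank``, ``control``
        or ``isolate:<name>``.
    meta
        Free-form provenance (e.g. number of tests in a filtering run).
    """

    intensities: pd.DataFrame
    groups: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.intensities, pd.DataFrame):
            self.intensities = pd.DataFrame(self.intensities)
        self.groups = pd.Series(self.groups)
        missing = set(self.intensities.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group labels: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.intensities.columns)]
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensities must be finite")
        if (vals < 0).any():
            raise ValidationError("intensities must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def isolate_names(self) -> list[str]:
        return [g[len(ISOLATE_PREFIX):] for g in self.group_names
                if g.startswith(ISOLATE_PREFIX)]

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_matrix(self, group: str) -> np.ndarray:
        """Intensity sub-matrix (features x replicates) for one group."""
        cols = self.samples_in(group)
        if not cols:
            raise ValidationError(f"no samples in group {group!r}")
        return self.intensities[cols].to_numpy(dtype=float)

    def subset(self, feature_ids: Sequence[str], **meta) -> "FeatureTable":
        sub = self.intensities.loc[list(feature_ids)]
        return FeatureTable(sub, self.groups.copy(), {**self.meta, **meta})

    def to_long(self) -> pd.DataFrame:
        long = (self.intensities
                .reset_index(names="feature_id")
                .melt(id_vars="feature_id", var_name="sample_id",
                      value_name="intensity"))
        long["group"] = long["sample_id"].map(self.groups)
        return long[["feature_id", "sample_id", "group", "intensity"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "FeatureTable":
        wide = long.pivot(index="feature_id", columns="sample_id",
                          values="intensity")
        groups = long.drop_duplicates("sample_id").set_index("sample_id")["group"]
        return cls(wide, groups)


#: Columns of a ConsumptionProfile data frame.
PROFILE_COLUMNS = ["mean_control", "mean_isolate", "log2fc", "p_adj",
                   "call", "proportion"]


@dataclass
class ConsumptionProfile:
    """Per-isolate consumption/production profile over metabolite features.

    ``data`` is indexed by feature id with columns ``mean_control``
    (mean intensity in uninoculated spent medium, I_0), ``mean_isolate``
    (I_s), ``log2fc`` = log2(I_s / I_0), ``p_adj`` (multiplicity-adjusted
    p-value), ``call`` in {consumed, produced, unchanged} and
    ``proportion`` p_m,s in [0, 1] (the fraction of the metabolite the
    isolate removed; 0 unless called consumed under the default
    convention).
    """

    isolate: str
    data: pd.DataFrame
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"profile missing columns: {missing}")
        p = self.data["proportion"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("proportions must lie in [0, 1]")
        bad = self.data.index[(self.data["call"] != CONSUMED) & (p > 0)]
        if len(bad):
            raise ValidationError(
                f"nonzero proportion on non-consumed features: {list(bad)[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def proportions(self) -> pd.Series:
        return self.data["proportion"]

    def n_called(self, call: str) -> int:
        return int((self.data["call"] == call).sum())


def align_profiles(profiles: Sequence[ConsumptionProfile]) -> list[ConsumptionProfile]:
    """Check all profiles cover the same feature set; return them ordered
    on the first profile's feature ordering."""
    if not profiles:
        raise ValidationError("no profiles given")
    ref = profiles[0].feature_ids
    out = []
    for prof in profiles:
        if set(prof.feature_ids) != set(ref):
            raise ValidationError(
                f"profile {prof.isolate!r} covers a different feature set")
        out.append(ConsumptionProfile(prof.isolate, prof.data.loc[ref],
                                      prof.flags))
    return out


@dataclass
class InteractionMatrix:
    """Directed strain x strain coefficient matrix.

    ``values`` is indexed [primary, secondary]: ``values.loc[p, s]`` is the
    effect of primary strain ``p`` on secondary strain ``s``. Rendered
    outputs put primaries in columns and secondaries in rows (transpose),
    matching the conventional heatmap layout.
    """

    metric: str
    values: pd.DataFrame
    valid: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.metric not in {"ECI", "MRO", "SI"}:
            raise ValidationError(f"unknown metric {self.metric!r}")
        v = self.values
        if list(v.index) != list(v.columns):
            raise ValidationError("matrix must be square with identical "
                                  "primary/secondary strain ordering")
        if self.valid is None:
            self.valid = pd.DataFrame(True, index=v.index, columns=v.columns)
        arr = v.to_numpy(dtype=float)
        ok = self.valid.to_numpy(dtype=bool)
        checked = arr[ok]
        if self.metric == "ECI" and np.any(checked > 1e-12):
            raise ValidationError("ECI entries must be <= 0")
        if self.metric == "MRO" and np.any((checked < -1e-12) | (checked > 1 + 1e-12)):
            raise ValidationError("MRO entries must lie in [0, 1]")
        if self.metric == "SI" and np.any(checked < -1 - 1e-9):
            raise ValidationError("SI entries must be >= -1")

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    def get(self, primary: str, secondary: str) -> float:
        return float(self.values.loc[primary, secondary])

    def pairs(self, include_diagonal: bool = True) -> pd.DataFrame:
        """Long form: one row per ordered (primary, secondary) pair."""
        rows = []
        for p in self.strains:
            for s in self.strains:
                if not include_diagonal and p == s:
                    continue
                rows.append((p, s, self.get(p, s),
                             bool(self.valid.loc[p, s])))
        return pd.DataFrame(rows, columns=["primary", "secondary",
                                           "value", "valid"])

    def rendered(self) -> pd.DataFrame:
        """Figure orientation: primaries as columns, secondaries as rows."""
        return self.values.T


@dataclass
class GrowthTable:
    """Long-format secondary-strain cell counts from the sequential
    spent-media exchange.

    Columns: ``secondary``, ``primary``, ``replicate``, ``count``. The
    primary label ``PtSM`` marks growth on plain algal spent medium, the
    baseline G_s,PtSM of the sequential-interaction coefficient.
    """

    data: pd.DataFrame

    REQUIRED = ("secondary", "primary", "replicate", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"growth table missing columns: {missing}")
        counts = self.data["count"].to_numpy(dtype=float)
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValidationError("counts must be finite and non-negative")

    @property
    def secondaries(self) -> list[str]:
        return sorted(self.data["secondary"].unique())

    @property
    def primaries(self) -> list[str]:
        prim = [p for p in self.data["primary"].unique() if p != BASELINE_PRIMARY]
        return sorted(prim)

    def counts(self, secondary: str, primary: str) -> np.ndarray:
        sel = self.data[(self.data["secondary"] == secondary)
                        & (self.data["primary"] == primary)]
        return sel["count"].to_numpy(dtype=float)

    def baseline_counts(self, secondary: str) -> np.ndarray:
        return self.counts(secondary, BASELINE_PRIMARY)


#: Required columns of a NanoSIMS ROI table.
ROI_COLUMNS = ("roi_id", "treatment", "well", "c12c12", "c12c13",
               "c12c14n", "c12c15n")
#: Required columns of a well census table.
CENSUS_COLUMNS = ("well", "strain", "treatment", "cell_count",
                  "mean_biovolume")
#: Allowed well positions in the porous microplate.
WELL_POSITIONS = ("proximal", "distal", "center")


def validate_roi_table(rois: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-cell ion-count table (one row per ROI)."""
    missing = [c for c in ROI_COLUMNS if c not in rois.columns]
    if missing:
        raise ValidationError(f"ROI table missing columns: {missing}")
    for col in ("c12c12", "c12c13", "c12c14n", "c12c15n"):
        v = rois[col].to_numpy(dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError(f"ion counts in {col!r} must be finite "
                                  "and non-negative")
    bad = set(rois["well"].unique()) - set(WELL_POSITIONS)
    if bad:
        raise ValidationError(f"unknown well positions: {sorted(bad)}")
    return rois


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-well census (flow-cytometry counts + mean biovolume)."""
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise ValidationError(f"census missing columns: {missing}")
    if (census["cell_count"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("cell_count must be non-negative")
    if (census["mean_biovolume"].to_numpy(dtype=float) <= 0).any():
        raise ValidationError("mean_biovolume must be positive")
    return census


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal.

    The triangle inequality is not assumed (profile distances may violate
    it after thresholding); symmetry is enforced to 1e-12.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distances must be finite")
        if np.any(self.values < -1e-12):
            raise ValidationError("distances must be non-negative")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValidationError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(self.values))) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])


def uptake_sets_from_mapping(mapping: Mapping[str, Iterable[str]]) -> dict[str, frozenset]:
    """Normalise a strain -> nutrient-identifier mapping, checking uniqueness."""
    out: dict[str, frozenset] = {}
    for strain, nutrients in mapping.items():
        nutrients = list(nutrients)
        if len(nutrients) != len(set(nutrients)):
            raise ValidationError(f"duplicate nutrients for strain {strain!r}")
        out[str(strain)] = frozenset(str(n) for n in nutrients)
    return out
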