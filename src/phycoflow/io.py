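"""Readers and writers for the pipeline's plain-text table formats.

Everything is TSV (or JSON for set-valued and report data): feature
intensity matrices with a sample sheet, long-form profiles, labelled
square interaction/distance matrices (metric recorded in a ``#`` comment
line), growth-count tables, uptake sets, ROI and census tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .containers import (
    CENSUS_COLUMNS,
    PROFILE_COLUMNS,
    ROI_COLUMNS,
    ConsumptionProfile,
    DistanceMatrix,
    FeatureTable,
    GrowthTable,
    InteractionMatrix,
    ValidationError,
    uptake_sets_from_mapping,
    validate_census,
    validate_roi_table,
)

__all__ = [
    "read_feature_table", "write_feature_table",
    "read_profiles", "write_profiles",
    "read_matrix", "write_matrix",
    "read_distance_matrix", "write_distance_matrix",
    "read_growth_table", "write_growth_table",
    "read_uptake_sets", "write_uptake_sets",
    "read_roi_table", "write_roi_table",
    "read_census", "write_census",
]


def read_feature_table(path, sample_sheet=None) -> FeatureTable:
    """Read a feature table from long TSV (``feature_id, sample_id, group,
    intensity``) or from a wide matrix TSV plus a sample sheet
    (``sample_id, group``)."""
    df = pd.read_csv(path, sep="\t")
    long_cols = {"feature_id", "sample_id", "group", "intensity"}
    if long_cols.issubset(df.columns):
        return FeatureTable.from_long(df)
    if sample_sheet is None:
        raise ValidationError("wide feature table needs a sample sheet")
    wide = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(sample_sheet, sep="\t")
    groups = sheet.set_index("sample_id")["group"]
    return FeatureTable(wide, groups)


def write_feature_table(table: FeatureTable, path, sample_sheet) -> None:
    table.intensities.to_csv(path, sep="\t", index_label="feature_id")
    (table.groups.rename("group").rename_axis("sample_id").reset_index()
     .to_csv(sample_sheet, sep="\t", index=False))


def write_profiles(profiles: Sequence[ConsumptionProfile], path) -> None:
    frames = []
    for prof in profiles:
        d = prof.data.reset_index(names="feature_id")
        d.insert(0, "isolate", prof.isolate)
        frames.append(d)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_profiles(path) -> list[ConsumptionProfile]:
    df = pd.read_csv(path, sep="\t")
    needed = {"isolate", "feature_id", *PROFILE_COLUMNS}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"profiles file missing columns: {sorted(missing)}")
    out = []
    for iso, grp in df.groupby("isolate", sort=False):
        data = grp.set_index("feature_id")[list(PROFILE_COLUMNS)]
        out.append(ConsumptionProfile(str(iso), data))
    return out


def write_matrix(matrix: InteractionMatrix, path) -> None:
    """Labelled square TSV, metric recorded in a leading comment line.

    Stored in internal orientation: rows = primary, columns = secondary.
    """
    with open(path, "w") as fh:
        fh.write(f"# metric: {matrix.metric}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="primary")
    flagged = matrix.valid.to_numpy().size - int(matrix.valid.to_numpy().sum())
    if flagged:
        valid_path = Path(path).with_suffix(".valid.tsv")
        matrix.valid.to_csv(valid_path, sep="\t", index_label="primary")


def read_matrix(path) -> InteractionMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# metric:"):
            raise ValidationError("matrix file must start with '# metric:'")
        metric = header.split(":", 1)[1].strip()
        values = pd.read_csv(fh, sep="\t", index_col=0)
        values.index.name = None
    valid = None
    valid_path = Path(path).with_suffix(".valid.tsv")
    if valid_path.exists():
        valid = pd.read_csv(valid_path, sep="\t", index_col=0).astype(bool)
    return InteractionMatrix(metric, values, valid)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    dist.to_frame().to_csv(path, sep="\t", index_label="label")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix labels must match on both axes")
    return DistanceMatrix(list(df.index), df.to_numpy(dtype=float))


def write_growth_table(growth: GrowthTable, path) -> None:
    growth.data.to_csv(path, sep="\t", index=False)


def read_growth_table(path) -> GrowthTable:
    return GrowthTable(pd.read_csv(path, sep="\t"))


def write_uptake_sets(sets: Mapping[str, frozenset], path) -> None:
    """JSON (``{strain: [nutrients]}``) or TSV (``strain, nutrient``),
    chosen by file extension."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {s: sorted(m) for s, m in sets.items()}
        path.write_text(json.dumps(payload, indent=1))
    else:
        rows = [(s, n) for s, m in sets.items() for n in sorted(m)]
        pd.DataFrame(rows, columns=["strain", "nutrient"]).to_csv(
            path, sep="\t", index=False)


def read_uptake_sets(path) -> dict[str, frozenset]:
    path = Path(path)
    if path.suffix == ".json":
        return uptake_sets_from_mapping(json.loads(path.read_text()))
    df = pd.read_csv(path, sep="\t")
    mapping = {s: list(g["nutrient"]) for s, g in df.groupby("strain")}
    return uptake_sets_from_mapping(mapping)


def write_roi_table(rois: pd.DataFrame, path) -> None:
    validate_roi_table(rois).to_csv(path, sep="\t", index=False)


def read_roi_table(path) -> pd.DataFrame:
    return validate_roi_table(pd.read_csv(path, sep="\t"))


def write_census(census: pd.DataFrame, path) -> None:
    validate_census(census).to_csv(path, sep="\t", index=False)


def read_census(path) -> pd.DataFrame:
    return validate_census(pd.read_csv(path, sep="\t"))
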