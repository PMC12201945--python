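"""NanoSIMS ion counts to single-cell C_net and population C_total.

Per-cell carbon isotope ratios come from the C2- dimer channels:
(12C13C / 12C12C) / 2 estimates 13C/12C, since a dimer with one heavy atom
is twice as likely as the square of the atom fraction suggests. The atom
fraction F = R / (1 + R) of each cell is compared with the natural
abundance baseline and the labelled algal endmember to give the percent of
cellular carbon derived from the alga::

    C_net = 100 * (F_cell - F_nat) / (F_alga - F_nat)

Because the isotope composition of the exuded metabolites may differ from
the measured enrichment of the algal cells, C_net is a comparative
estimate between treatments, not an absolute tracer budget.

Population totals combine per-well flow-cytometry abundances, mean cell
biovolume converted to carbon mass, and the treatment's median C_net::

    C_total = sum_wells N_cells * m_C(biovolume) * C_net / 100
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ValidationError, validate_census, validate_roi_table
from .stats import kruskal_wallis, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = [
    "IsotopeConstants",
    "carbon_ratio",
    "nitrogen_ratio",
    "atom_fraction",
    "c_net",
    "cnet_table",
    "summarize_treatments",
    "percent_reduction",
    "fold_change",
    "cell_carbon_mass",
    "c_total",
    "c_total_ratio",
]

#: Default carbon mass density of bacterial biovolume, fg C per um^3.
CARBON_PER_UM3 = 148.0


@dataclass(frozen=True)
class IsotopeConstants:
    """Natural-abundance isotope ratios and the C_net clamping policy.

    Defaults are the standard terrestrial values 13C/12C = 0.011237 (VPDB)
    and 15N/14N = 0.003676 (air). With ``clamp`` (default), C_net is
    restricted to [0, 100]; small negative excesses are counting noise.
    """

    natural_ratio_13c: float = 0.011237
    natural_ratio_15n: float = 0.003676
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.natural_ratio_13c <= 0 or self.natural_ratio_15n <= 0:
            raise ValidationError("natural isotope ratios must be > 0")

    @property
    def natural_fraction_13c(self) -> float:
        return atom_fraction(self.natural_ratio_13c)

    @property
    def natural_fraction_15n(self) -> float:
        return atom_fraction(self.natural_ratio_15n)


def carbon_ratio(c12c13, c12c12):
    """13C/12C ratio from the dimer ion counts: (12C13C / 12C12C) / 2."""
    num = np.asarray(c12c13, dtype=float)
    den = np.asarray(c12c12, dtype=float)
    if np.any(den <= 0):
        raise ValidationError("12C12C count must be > 0 for a carbon ratio")
    return (num / den) / 2.0


def nitrogen_ratio(c12c15n, c12c14n):
    """15N/14N ratio from the CN- monomer channels (no dimer factor)."""
    num = np.asarray(c12c15n, dtype=float)
    den = np.asarray(c12c14n, dtype=float)
    if np.any(den <= 0):
        raise ValidationError("12C14N count must be > 0 for a nitrogen ratio")
    return num / den


def atom_fraction(ratio):
    """Isotope ratio R to atom fraction F = R / (1 + R), in [0, 1)."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValidationError("isotope ratio must be >= 0")
    out = r / (1.0 + r)
    return float(out) if np.isscalar(ratio) else out


def c_net(f_cell, f_alga: float,
          constants: IsotopeConstants = IsotopeConstants()):
    """Percent of cellular carbon derived from the labelled algal source.

    ``f_cell`` is the cell's 13C atom fraction (scalar or array);
    ``f_alga`` the algal endmember's. Raises when the source is not
    enriched above natural abundance.
    """
    f_nat = constants.natural_fraction_13c
    if f_alga <= f_nat:
        raise ValidationError("unlabeled source: F_alga must exceed the "
                              "natural 13C atom fraction")
    f = np.asarray(f_cell, dtype=float)
    out = 100.0 * (f - f_nat) / (f_alga - f_nat)
    if constants.clamp:
        out = np.clip(out, 0.0, 100.0)
    return float(out) if np.isscalar(f_cell) else out


def cnet_table(rois: pd.DataFrame,
               constants: IsotopeConstants = IsotopeConstants(),
               f_alga: float | None = None) -> pd.DataFrame:
    """Per-cell isotope ratios, atom fractions and C_net from an ROI table.

    When ``f_alga`` is not given, the algal endmember is the median 13C
    atom fraction over ROIs labelled ``treatment == "alga"`` in the same
    table. ROIs with a zero major-isotope count are flagged
    (``flag_zero_denominator``) and get NaN values rather than aborting
    the run; algal ROIs are excluded from the returned per-cell rows.
    """
    rois = validate_roi_table(rois)
    out = rois.copy()
    ok_c = out["c12c12"].to_numpy(dtype=float) > 0
    ok_n = out["c12c14n"].to_numpy(dtype=float) > 0
    flagged = ~(ok_c & ok_n)
    if flagged.any():
        log.warning("%d ROIs flagged for zero denominator counts",
                    int(flagged.sum()))
    r13 = np.full(len(out), np.nan)
    r13[ok_c] = carbon_ratio(out.loc[ok_c, "c12c13"], out.loc[ok_c, "c12c12"])
    r15 = np.full(len(out), np.nan)
    r15[ok_n] = nitrogen_ratio(out.loc[ok_n, "c12c15n"],
                               out.loc[ok_n, "c12c14n"])
    out["ratio_13c"] = r13
    out["ratio_15n"] = r15
    out["frac_13c"] = r13 / (1.0 + r13)
    out["frac_15n"] = r15 / (1.0 + r15)
    out["flag_zero_denominator"] = flagged

    is_alga = out["treatment"] == "alga"
    if f_alga is None:
        if not is_alga.any():
            raise ValidationError("no algal ROIs present; pass f_alga "
                                  "explicitly")
        f_alga = float(np.nanmedian(out.loc[is_alga, "frac_13c"]))
    cells = out[~is_alga].copy()
    valid = ~cells["flag_zero_denominator"]
    cnet = np.full(len(cells), np.nan)
    cnet[valid.to_numpy()] = c_net(
        cells.loc[valid, "frac_13c"].to_numpy(), f_alga, constants)
    cells["cnet"] = cnet
    cells.attrs["f_alga"] = f_alga
    return cells


def summarize_treatments(cnet_by_treatment: Mapping[str, Sequence[float]] | pd.DataFrame
                         ) -> dict:
    """Median / IQR / n per treatment plus rank-based comparisons.

    Accepts either a mapping of treatment -> C_net values or the output of
    :func:`cnet_table` (grouped on its ``treatment`` column). Requires
    >= 2 treatments with >= 3 cells each. Pairwise Wilcoxon rank-sum and a
    global Kruskal-Wallis test are computed exactly for small samples
    (see :mod:`phycoflow.stats`); the method used is recorded.
    """
    if isinstance(cnet_by_treatment, pd.DataFrame):
        df = cnet_by_treatment.dropna(subset=["cnet"])
        groups = {t: g["cnet"].to_numpy(dtype=float)
                  for t, g in df.groupby("treatment")}
    else:
        groups = {t: np.asarray(v, dtype=float)
                  for t, v in cnet_by_treatment.items()}
    if len(groups) < 2:
        raise ValidationError("need >= 2 treatments")
    for t, v in groups.items():
        if len(v) < 3:
            raise ValidationError(f"treatment {t!r} has {len(v)} cells; "
                                  "need >= 3")
    summary = {
        t: {
            "median": float(np.median(v)),
            "iqr": [float(np.percentile(v, 25)), float(np.percentile(v, 75))],
            "n": int(len(v)),
        }
        for t, v in groups.items()
    }
    pairwise = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        res = wilcoxon_rank_sum(groups[a], groups[b])
        pairwise[f"{a} vs {b}"] = res
    kw = kruskal_wallis([groups[t] for t in sorted(groups)])
    return {"treatments": summary, "pairwise_wilcoxon": pairwise,
            "kruskal_wallis": kw}


def percent_reduction(treatment_value: float, control_value: float) -> float:
    """Percent reduction of a treatment median relative to a control median:
    100 * (1 - treatment / control)."""
    if control_value <= 0:
        raise ValidationError("control value must be > 0")
    return 100.0 * (1.0 - treatment_value / control_value)


def fold_change(a: float, b: float) -> float:
    """Simple ratio a / b (e.g. 'x-fold higher than')."""
    if b <= 0:
        raise ValidationError("denominator must be > 0")
    return a / b


def cell_carbon_mass(biovolume: float, conversion: float = CARBON_PER_UM3,
                     allometric: tuple[float, float] | None = None) -> float:
    """Carbon mass (fg C) of a cell of the given biovolume (um^3).

    Linear by default, m = conversion * V; an allometric law m = a * V**b
    (common for marine bacterioplankton) is available via
    ``allometric=(a, b)``.
    """
    if biovolume <= 0:
        raise ValidationError("biovolume must be > 0")
    if allometric is not None:
        a, b = allometric
        if a <= 0:
            raise ValidationError("allometric prefactor must be > 0")
        return a * biovolume ** b
    if conversion <= 0:
        raise ValidationError("conversion factor must be > 0")
    return conversion * biovolume


def c_total(census: pd.DataFrame, cnet_by_well: Mapping[str, float],
            conversion: float = CARBON_PER_UM3,
            allometric: tuple[float, float] | None = None) -> pd.DataFrame:
    """Total algal carbon mass (fg) incorporated per treatment.

    ``census`` holds one row per well (columns ``well``, ``strain``,
    ``treatment``, ``cell_count``, ``mean_biovolume``; an optional
    ``microplate`` column identifies replicate plates). ``cnet_by_well``
    maps well position to its median C_net (percent). Each well
    contributes N_cells * m_C(mean biovolume) * C_net/100; wells are summed
    within treatment (and microplate when present). Raises when any well
    lacks a C_net value, listing the wells.
    """
    census = validate_census(census)
    missing = sorted(set(census["well"]) - set(cnet_by_well))
    if missing:
        raise ValidationError(f"missing C_net for wells: {missing}")
    df = census.copy()
    df["cell_mass_fg"] = [
        cell_carbon_mass(v, conversion, allometric)
        for v in df["mean_biovolume"]]
    df["cnet"] = df["well"].map(cnet_by_well)
    df["c_total_fg"] = (df["cell_count"] * df["cell_mass_fg"]
                        * df["cnet"] / 100.0)
    keys = ["treatment"]
    if "microplate" in df.columns:
        keys.append("microplate")
    totals = (df.groupby(keys, as_index=False)["c_total_fg"].sum())
    return totals


def c_total_ratio(totals: pd.DataFrame, treatment_a: str,
                  treatment_b: str) -> dict:
    """Ratio of total carbon incorporation between two treatments.

    When replicate microplates are present the ratio is of the means over
    plates and the spread is propagated from the per-plate standard
    deviations (independent relative errors in quadrature).
    """
    def _vals(t: str) -> np.ndarray:
        v = totals.loc[totals["treatment"] == t, "c_total_fg"]
        if v.empty:
            raise ValidationError(f"treatment {t!r} absent from totals")
        return v.to_numpy(dtype=float)

    a = _vals(treatment_a)
    b = _vals(treatment_b)
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_b == 0:
        raise ValidationError("denominator treatment has zero total")
    ratio = mean_a / mean_b
    sd = None
    if len(a) > 1 and len(b) > 1:
        rel = np.sqrt((np.std(a, ddof=1) / mean_a) ** 2
                      + (np.std(b, ddof=1) / mean_b) ** 2)
        sd = abs(ratio) * float(rel)
    return {"ratio": ratio, "sd": sd, "mean_a": mean_a, "mean_b": mean_b,
            "n_a": len(a), "n_b": len(b)}
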