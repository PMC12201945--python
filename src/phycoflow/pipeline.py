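"""End-to-end orchestration: simulate or load inputs, run every analysis
stage whose inputs are present, and emit a machine-readable results bundle.

A run is described by a :class:`RunConfig` (built in code or from YAML).
Stages: exometabolomics filtering/classification -> ECI; uptake sets ->
MRO; sequential growth -> SI and interaction tallies; metric comparisons
(SI~ECI Spearman, MRO~ECI Pearson, fraction of SIs above ECIs); profile
clustering and optional Mantel test against a phylogeny; NanoSIMS ->
per-treatment C_net summaries and C_total ratios. All randomness flows
from the single config seed; a rerun with the same seed and inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .containers import InteractionMatrix, ValidationError
from .interactions import (
    compare_matrices,
    eci_matrix,
    interaction_tally,
    mro_matrix,
    si_matrix,
)
from .isotope import (
    IsotopeConstants,
    c_total,
    c_total_ratio,
    cnet_table,
    summarize_treatments,
)
from .metabolomics import (
    build_profiles,
    filter_above_background,
    shared_depletion_summary,
)
from .profiles import hierarchical_cluster, mantel_test, profile_distance
from .simulate import (
    MetabolomeDesign,
    NanoSimsDesign,
    SequentialDesign,
    generate_metabolome,
    generate_nanosims,
    generate_sequential,
    generate_uptake_sets,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "render_report"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Each stage runs when either a simulation design (``simulate``) or an
    input path (``inputs``) provides its data; stages with neither are
    skipped. ``simulate`` accepts sub-dicts ``metabolome``, ``sequential``,
    ``nanosims`` (design-field overrides) and ``uptake_sets``
    (n_strains/universe_size/overlap/set_size); ``inputs`` accepts paths
    ``feature_table``/``sample_sheet``, ``growth_table``, ``uptake_sets``,
    ``roi_table``, ``census``, ``phylogeny`` (distance-matrix TSV).
    """

    seed: int = 0
    out_dir: str | Path | None = None
    alpha: float = 0.05
    correction: str = "bonferroni"
    proportion_convention: str = "one-minus-ratio"
    equal_var: bool = True
    correlation_include_diagonal: bool = True
    neutral_band: float = 0.0
    mantel_permutations: int = 999
    natural_ratio_13c: float = 0.011237
    natural_ratio_15n: float = 0.003676
    clamp_cnet: bool = True
    f_alga: float | None = None
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate(self) -> None:
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise ValidationError(f"input path for {key!r} does not "
                                      f"exist: {p}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (out_dir excluded so
        reruns into different directories are recognisably identical)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @property
    def isotope_constants(self) -> IsotopeConstants:
        return IsotopeConstants(self.natural_ratio_13c,
                                self.natural_ratio_15n, self.clamp_cnet)


@dataclass
class ResultsBundle:
    """Machine-readable summary of one pipeline run."""

    provenance: dict
    metabolomics: dict | None = None
    interactions: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    profile_stats: dict | None = None
    isotope: dict | None = None
    matrices: dict = field(default_factory=dict)  # metric -> InteractionMatrix

    def to_dict(self) -> dict:
        out = {
            "provenance": self.provenance,
            "metabolomics": self.metabolomics,
            "interactions": self.interactions,
            "comparisons": self.comparisons,
            "profile_stats": self.profile_stats,
            "isotope": self.isotope,
            "matrices": {m: mat.rendered().round(6).to_dict()
                         for m, mat in self.matrices.items()},
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True,
                          default=_jsonable, **kwargs)


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _seed_stream(seed: int):
    """Independent per-stage seeds derived from the root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(8)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute every stage whose inputs are available; see module docs."""
    config.validate()
    seeds = _seed_stream(config.seed)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    bundle = ResultsBundle(provenance={
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package": "phycoflow",
    })
    ground_truth: dict[str, Any] = {}

    # ---- stage: exometabolomics -> ECI -----------------------------------
    table = None
    if "metabolome" in config.simulate:
        design = MetabolomeDesign(**{**config.simulate["metabolome"],
                                     "seed": seeds[0]})
        table, truth = generate_metabolome(design)
        ground_truth["metabolome"] = truth
    elif "feature_table" in config.inputs:
        table = pio.read_feature_table(config.inputs["feature_table"],
                                       config.inputs.get("sample_sheet"))
    profiles = None
    if table is not None:
        try:
            filtered = filter_above_background(
                table, config.alpha, config.correction, config.equal_var)
        except ValidationError as err:
            log.info("background filter skipped: %s", err)
            filtered = table
        profiles = build_profiles(filtered, alpha=config.alpha,
                                  correction=config.correction,
                                  convention=config.proportion_convention,
                                  equal_var=config.equal_var)
        eci = eci_matrix(profiles)
        bundle.matrices["ECI"] = eci
        bundle.metabolomics = {
            "n_features_input": len(table.feature_ids),
            "n_features_retained": len(filtered.feature_ids),
            "n_tests_background": filtered.meta.get("n_tests"),
            "per_isolate_calls": {
                p.isolate: {"consumed": p.n_called("consumed"),
                            "produced": p.n_called("produced")}
                for p in profiles},
            "shared_depleted_features":
                shared_depletion_summary(profiles),
        }
        if out_dir:
            pio.write_profiles(profiles, out_dir / "profiles.tsv")
            pio.write_matrix(eci, out_dir / "eci_matrix.tsv")

    # Reuse the simulated metabolome's isolate names in the other simulated
    # stages so matrices share a strain ordering and can be compared.
    sim_strains = None
    if profiles is not None and "metabolome" in config.simulate:
        sim_strains = [p.isolate for p in profiles]

    # ---- stage: uptake sets -> MRO ---------------------------------------
    uptake = None
    if "uptake_sets" in config.simulate:
        spec = dict(config.simulate["uptake_sets"])
        spec.setdefault("seed", seeds[1])
        if sim_strains is not None and spec.get("n_strains") == len(sim_strains):
            spec.setdefault("strains", sim_strains)
        uptake = generate_uptake_sets(**spec)
    elif "uptake_sets" in config.inputs:
        uptake = pio.read_uptake_sets(config.inputs["uptake_sets"])
    if uptake is not None:
        mro = mro_matrix(uptake)
        bundle.matrices["MRO"] = mro
        bundle.interactions["mro_strains"] = list(uptake)
        if out_dir:
            pio.write_matrix(mro, out_dir / "mro_matrix.tsv")

    # ---- stage: sequential growth -> SI ----------------------------------
    growth = None
    if "sequential" in config.simulate:
        spec = dict(config.simulate["sequential"])
        if sim_strains is not None \
                and spec.get("n_strains") == len(sim_strains):
            spec.setdefault("strains", sim_strains)
        design = SequentialDesign(**{**spec, "seed": seeds[2]})
        growth = generate_sequential(design)
        ground_truth["sequential"] = getattr(growth, "true_si", None)
    elif "growth_table" in config.inputs:
        growth = pio.read_growth_table(config.inputs["growth_table"])
    if growth is not None:
        si = si_matrix(growth)
        bundle.matrices["SI"] = si
        tally = interaction_tally(si, config.neutral_band,
                                  config.correlation_include_diagonal)
        bundle.interactions["si_tally"] = tally
        if out_dir:
            pio.write_growth_table(growth, out_dir / "growth_table.tsv")
            pio.write_matrix(si, out_dir / "si_matrix.tsv")

    # ---- stage: metric comparisons ---------------------------------------
    diag = config.correlation_include_diagonal
    comparisons = {}
    pairs = [("SI", "ECI", "spearman"), ("MRO", "ECI", "pearson")]
    for a, b, method in pairs:
        if a in bundle.matrices and b in bundle.matrices:
            ma, mb = bundle.matrices[a], bundle.matrices[b]
            if ma.strains == mb.strains:
                comparisons[f"{a}~{b}"] = compare_matrices(
                    ma, mb, method, include_diagonal=diag)
            else:
                log.info("skipping %s~%s: strain sets differ", a, b)
    bundle.comparisons = comparisons

    # ---- stage: profile clustering + Mantel ------------------------------
    if profiles is not None and len(profiles) >= 2:
        dist = profile_distance(profiles)
        dendro = hierarchical_cluster(dist)
        stats: dict[str, Any] = {"newick": dendro.to_newick()}
        if "phylogeny" in config.inputs:
            phylo = pio.read_distance_matrix(config.inputs["phylogeny"])
            phylo = phylo.reorder(dist.labels)
            stats["mantel"] = mantel_test(
                dist, phylo, n_perm=config.mantel_permutations,
                seed=seeds[3])
        bundle.profile_stats = stats
        if out_dir:
            pio.write_distance_matrix(dist, out_dir / "profile_distances.tsv")
            (out_dir / "profile_dendrogram.nwk").write_text(
                dendro.to_newick() + "\n")

    # ---- stage: NanoSIMS -> C_net / C_total ------------------------------
    rois = None
    if "nanosims" in config.simulate:
        spec = config.simulate["nanosims"]
        if isinstance(spec, dict) and any(isinstance(v, dict)
                                          for v in spec.values()):
            frames = []
            for i, (name, sub) in enumerate(sorted(spec.items())):
                d = NanoSimsDesign(**{**sub, "treatment": name,
                                      "seed": seeds[4] + i})
                frames.append(generate_nanosims(d))
            rois = pd.concat(frames, ignore_index=True)
        else:
            design = NanoSimsDesign(**{**spec, "seed": seeds[4]})
            rois = generate_nanosims(design)
    elif "roi_table" in config.inputs:
        rois = pio.read_roi_table(config.inputs["roi_table"])
    if rois is not None:
        f_alga = config.f_alga
        cells = cnet_table(rois, config.isotope_constants, f_alga)
        iso: dict[str, Any] = {"f_alga": cells.attrs.get("f_alga", f_alga)}
        if cells["treatment"].nunique() >= 2:
            iso["summary"] = summarize_treatments(cells)
        else:
            t = str(cells["treatment"].iloc[0])
            v = cells["cnet"].dropna()
            iso["summary"] = {"treatments": {t: {
                "median": float(v.median()),
                "iqr": [float(v.quantile(0.25)), float(v.quantile(0.75))],
                "n": int(v.size)}}}
        if "census" in config.inputs:
            census = pio.read_census(config.inputs["census"])
            medians = (cells.dropna(subset=["cnet"])
                       .groupby("well")["cnet"].median().to_dict())
            totals = c_total(census, medians)
            iso["c_total"] = totals.to_dict(orient="records")
            treatments = list(totals["treatment"].unique())
            if len(treatments) >= 2:
                iso["c_total_ratio"] = {
                    f"{treatments[0]} / {treatments[1]}":
                        c_total_ratio(totals, treatments[0], treatments[1])}
        bundle.isotope = iso
        if out_dir:
            cells.to_csv(out_dir / "cnet_cells.tsv", sep="\t", index=False)

    # ---- recovery report against ground truth ----------------------------
    if ground_truth:
        recovery = {}
        if "metabolome" in ground_truth and "ECI" in bundle.matrices:
            true_eci = eci_matrix(ground_truth["metabolome"])
            est = bundle.matrices["ECI"].values.to_numpy()
            tru = true_eci.values.to_numpy()
            recovery["eci_median_abs_error"] = float(
                np.median(np.abs(est - tru)))
        if ground_truth.get("sequential") is not None \
                and "SI" in bundle.matrices:
            tru = ground_truth["sequential"].to_numpy()
            est = bundle.matrices["SI"].values.to_numpy()
            err = np.abs(est - tru)
            recovery["si_median_abs_error"] = float(np.median(err))
            recovery["si_fraction_within_0.1"] = float(np.mean(err <= 0.1))
        bundle.provenance["recovery"] = recovery

    if out_dir:
        (out_dir / "results.json").write_text(bundle.to_json())
        (out_dir / "report.md").write_text(render_report(bundle))
    return bundle


def render_report(bundle: ResultsBundle) -> str:
    """Human-readable markdown summary of a results bundle.

    Matrices are rendered with primary strains as columns and secondary
    strains as rows.
    """
    lines = ["# phycoflow run report", ""]
    prov = bundle.provenance
    lines.append(f"Seed {prov.get('seed')}, config {prov.get('config_hash')}.")
    lines.append("")
    if bundle.metabolomics:
        m = bundle.metabolomics
        lines += [
            "## Exometabolomics",
            f"- features retained above background: "
            f"{m['n_features_retained']} / {m['n_features_input']}",
            f"- features depleted by >= half by all isolates: "
            f"{len(m['shared_depleted_features'])}",
            "",
        ]
    if not bundle.matrices:
        lines.append("No interaction matrices computed: no pairs.")
    for metric, mat in bundle.matrices.items():
        lines.append(f"## {metric} (columns: primary, rows: secondary)")
        lines.append("")
        lines.append("```")
        lines.append(mat.rendered().round(3).to_string())
        lines.append("```")
        lines.append("")
    if "si_tally" in bundle.interactions:
        t = bundle.interactions["si_tally"]
        lines.append(f"Of {t['n_pairs']} ordered pairs, {t['competitive']} "
                     f"had negative SI (competition-dominated), "
                     f"{t['facilitative']} positive (facilitation), "
                     f"{t['neutral']} neutral.")
        lines.append("")
    for name, comp in bundle.comparisons.items():
        lines.append(
            f"- {name}: {comp['method']} statistic = "
            f"{comp['statistic']:.3f} (p = {comp['p_value']:.3g}, "
            f"n = {comp['n_pairs']}); fraction first > second = "
            f"{comp['fraction_a_greater']:.2f}")
    if bundle.comparisons:
        lines.append("")
    if bundle.profile_stats:
        lines.append("## Profile clustering")
        lines.append(f"Dendrogram: `{bundle.profile_stats['newick']}`")
        if "mantel" in bundle.profile_stats:
            mt = bundle.profile_stats["mantel"]
            lines.append(f"Mantel test vs phylogeny: r = {mt['r']:.3f}, "
                         f"p = {mt['p']:.3g} ({mt['n_perm']} permutations"
                         f"{', exact' if mt['exact'] else ''}).")
        lines.append("")
    if bundle.isotope:
        lines.append("## Algal carbon incorporation")
        for t, s in bundle.isotope["summary"]["treatments"].items():
            lines.append(f"- {t}: median C_net = {s['median']:.2f}% "
                         f"(IQR {s['iqr'][0]:.2f}-{s['iqr'][1]:.2f}, "
                         f"n = {s['n']})")
        if "c_total_ratio" in bundle.isotope:
            for k, v in bundle.isotope["c_total_ratio"].items():
                lines.append(f"- C_total ratio {k}: {v['ratio']:.2f}")
        lines.append("")
    return "\n".join(lines)
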