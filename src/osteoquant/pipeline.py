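"""End-to-end study orchestration: simulate -> analyse -> compare.

A study run generates (or loads) per-animal raw signals for the two
groups, pushes each modality through its analysis module, aggregates to
per-animal values plus pooled per-observation samples, and runs the
two-group statistical decision tree.  One corrupt unit (site, curve,
spectrum, fibril) never aborts the run; failures are collected and listed
in the report with their animal/site identifier.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import afm, fibril, hplc, raman, rpi, stats, synthetic
from .exceptions import OsteoquantError, ParameterError


@dataclass
class StudyConfig:
    """Structured configuration for one reproducible study run."""

    seed: int = 0
    n_per_group: int = 6
    group_effects: dict | None = None  # None -> study's observed shifts
    noise: dict | None = None
    alpha: float = 0.05
    holm: bool = False
    expected_cycles: int = 10
    n_rpi_sites: int = synthetic.N_RPI_SITES
    n_afm_grids: int = synthetic.N_AFM_GRIDS
    n_afm_curves_per_grid: int = synthetic.N_AFM_CURVES_PER_GRID
    n_raman_sites: int = synthetic.N_RAMAN_SITES
    n_fibril_fields: int = synthetic.N_FIBRIL_FIELDS
    n_fibrils_per_field: int = synthetic.N_FIBRILS_PER_FIELD
    output_dir: str | None = None

    def validate(self):
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class StudyResult:
    """Everything a study run produced."""

    config: StudyConfig
    per_animal: pd.DataFrame  # one row per animal, one column per metric
    comparisons: pd.DataFrame
    heterogeneity: stats.HeterogeneityPanel | None
    failures: list[str]
    report: str


# metrics whose pooled per-observation values feed distribution tests
_POOLED_METRICS = ("afm_modulus_mpa", "fibril_d_nm")


def _analyze_animal(
    animal: synthetic.AnimalData,
    standards: dict,
    config: StudyConfig,
    failures: list[str],
) -> tuple[dict, dict]:
    """Per-animal metric row plus pooled per-observation samples."""
    row: dict = {"animal_id": animal.animal_id, "group": animal.group_label}
    pooled: dict[str, np.ndarray] = {}

    # -- RPI ---------------------------------------------------------------
    summaries = []
    for i, (trace, _truth) in enumerate(animal.rpi):
        try:
            summaries.append(
                rpi.analyze_trace(trace, expected_cycles=config.expected_cycles)
            )
        except OsteoquantError as exc:
            failures.append(f"{animal.animal_id}/rpi_site{i + 1}: {exc}")
    if summaries:
        agg = rpi.aggregate_animal(summaries)
        row.update({
            "rpi_first_depth": agg.first_cycle_indentation_distance,
            "rpi_energy": agg.first_cycle_energy_dissipation,
            "rpi_slope": agg.first_cycle_unloading_slope,
            "rpi_creep": agg.first_cycle_creep_distance,
            "rpi_idi": agg.indentation_distance_increase,
            "rpi_total_depth": agg.total_indentation_distance,
            "rpi_total_energy": agg.total_energy_dissipation,
        })

    # -- AFM ---------------------------------------------------------------
    fits = []
    for i, (curve, _truth) in enumerate(animal.afm):
        try:
            fits.append(afm.fit_hertz(curve))
        except OsteoquantError as exc:
            failures.append(f"{animal.animal_id}/afm_curve{i + 1}: {exc}")
    moduli = afm.aggregate_moduli(fits, scheme="pooled")
    if moduli.size:
        row["afm_modulus_mpa"] = float(np.mean(moduli)) / 1e6
        pooled["afm_modulus_mpa"] = moduli / 1e6

    # -- Raman -------------------------------------------------------------
    comps = []
    for i, (spec, _truth) in enumerate(animal.raman):
        try:
            comps.append(raman.analyze_spectrum(spec))
        except OsteoquantError as exc:
            failures.append(f"{animal.animal_id}/raman_site{i + 1}: {exc}")
    if comps:
        agg = raman.aggregate_composition(comps)
        row.update({
            "raman_mineral_to_matrix": agg.mineral_to_matrix,
            "raman_carbonate_sub": agg.carbonate_substitution,
            "raman_crystallinity": agg.crystallinity,
        })

    # -- Fibril D-spacing ---------------------------------------------------
    measures = []
    for fi, (image, rois) in enumerate(animal.fibril_fields):
        for ri, (roi, _d_true) in enumerate(rois):
            try:
                measures.append(fibril.measure_fibril(image, roi, 0.0))
            except OsteoquantError as exc:
                failures.append(
                    f"{animal.animal_id}/field{fi + 1}/fibril{ri + 1}: {exc}"
                )
    if measures:
        ds = np.array([m.d_spacing for m in measures])
        row["fibril_d_nm"] = float(np.mean(ds))
        pooled["fibril_d_nm"] = ds

    # -- HPLC ---------------------------------------------------------------
    try:
        fluor_std = standards["fluorescence"]
        uv_std = standards["uv"]
        fluor, _ = animal.hplc_fluor
        uv, _ = animal.hplc_uv
        amounts = {}
        for name in ("pyd", "dpd", "pe"):
            cal = hplc.build_calibration(
                fluor_std["standards"][name],
                fluor_std["windows"][name],
                fluor_std["windows"][fluor_std["internal_standard"]],
                analyte=name,
            )
            amounts[name] = hplc.quantify_analyte(
                fluor, cal,
                fluor_std["windows"][name],
                fluor_std["windows"][fluor_std["internal_standard"]],
            )
        hyp_cal = hplc.build_calibration(
            uv_std["standards"]["hyp"],
            uv_std["windows"]["hyp"],
            uv_std["windows"][uv_std["internal_standard"]],
            analyte="hyp",
        )
        hyp_mass = hplc.quantify_analyte(
            uv, hyp_cal,
            uv_std["windows"]["hyp"],
            uv_std["windows"][uv_std["internal_standard"]],
        )
        collagen = hplc.collagen_from_hydroxyproline(hyp_mass)
        res = hplc.crosslink_ratios(amounts, collagen, hyp_mass)
        row.update({
            "hplc_pyd": res.pyd_per_collagen,
            "hplc_dpd": res.dpd_per_collagen,
            "hplc_pe": res.pe_per_collagen,
        })
    except OsteoquantError as exc:
        failures.append(f"{animal.animal_id}/hplc: {exc}")

    return row, pooled


def run_study(config: StudyConfig) -> StudyResult:
    """Execute a full synthetic study under one seed and compare groups."""
    config.validate()
    bundle = synthetic.generate_group_study(
        n_per_group=config.n_per_group,
        group_effects=config.group_effects,
        seed=config.seed,
        noise=config.noise,
        n_rpi_sites=config.n_rpi_sites,
        n_afm_grids=config.n_afm_grids,
        n_afm_curves_per_grid=config.n_afm_curves_per_grid,
        n_raman_sites=config.n_raman_sites,
        n_fibril_fields=config.n_fibril_fields,
        n_fibrils_per_field=config.n_fibrils_per_field,
    )
    return analyze_study(bundle, config)


def analyze_study(
    bundle: synthetic.StudyBundle, config: StudyConfig
) -> StudyResult:
    """Analyse an existing bundle (synthetic or loaded) and compare groups."""
    failures: list[str] = []
    rows = []
    pooled_by_group: dict[str, dict[str, list[np.ndarray]]] = {
        "normal": {}, "cyplus": {},
    }
    for animal in bundle.animals:
        row, pooled = _analyze_animal(
            animal, bundle.hplc_standards, config, failures
        )
        rows.append(row)
        for metric, vals in pooled.items():
            pooled_by_group[animal.group_label].setdefault(metric, []).append(vals)

    per_animal = pd.DataFrame(rows)

    measures = []
    metric_cols = [
        c for c in per_animal.columns if c not in ("animal_id", "group")
    ]
    for metric in metric_cols:
        a = per_animal.loc[per_animal["group"] == "normal", metric].dropna()
        b = per_animal.loc[per_animal["group"] == "cyplus", metric].dropna()
        if a.size < 2 or b.size < 2:
            failures.append(f"stats/{metric}: insufficient group sizes")
            continue
        kw = {}
        if metric in _POOLED_METRICS:
            kw = {
                "pooled_normal": np.concatenate(
                    pooled_by_group["normal"].get(metric, [np.array([])])
                ),
                "pooled_cyplus": np.concatenate(
                    pooled_by_group["cyplus"].get(metric, [np.array([])])
                ),
            }
        measures.append(stats.GroupedMeasure(metric, a.to_numpy(), b.to_numpy(), **kw))

    results = stats.compare_all(measures, alpha=config.alpha, holm=config.holm)
    comparisons = pd.DataFrame([
        {
            "metric": r.metric,
            "test": r.test_used,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "percent_difference": r.percent_difference,
            "significant": r.significant,
        }
        for r in results
    ])

    het = None
    for m in measures:
        if m.name == "afm_modulus_mpa" and m.pooled_normal is not None \
                and m.pooled_normal.size >= 5 and m.pooled_cyplus.size >= 5:
            het = stats.heterogeneity_panel(m.pooled_normal, m.pooled_cyplus)

    report = _render_report(config, per_animal, comparisons, het, failures)
    result = StudyResult(
        config=config,
        per_animal=per_animal,
        comparisons=comparisons,
        heterogeneity=het,
        failures=failures,
        report=report,
    )
    if config.output_dir:
        _write_outputs(result)
    return result


def _render_report(config, per_animal, comparisons, het, failures) -> str:
    lines = [
        "# osteoquant study report",
        f"# version: {__version__}",
        f"# seed: {config.seed}",
        f"# config: {config.digest()}",
        "",
        "## Per-animal means",
        per_animal.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "## Group comparisons (normal vs cyplus)",
        comparisons.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
    ]
    if het is not None:
        lines += [
            "",
            "## Modulus heterogeneity (pooled indents)",
            f"SD normal: {het.sd_a:.4g} MPa, SD cyplus: {het.sd_b:.4g} MPa",
            f"joint deciles: {het.joint_q10:.4g} / {het.joint_q90:.4g} MPa",
            "tail proportions below/above joint deciles: "
            f"normal {het.low_tail_a:.3f}/{het.high_tail_a:.3f}, "
            f"cyplus {het.low_tail_b:.3f}/{het.high_tail_b:.3f}",
            f"KS D = {het.ks_statistic:.4f}, p = {het.ks_p_value:.3g}",
        ]
    if failures:
        lines += ["", "## Failures"] + [f"- {f}" for f in failures]
    else:
        lines += ["", "## Failures", "none"]
    return "\n".join(lines)


def _write_outputs(result: StudyResult):
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"# version: {__version__}\n"
        f"# seed: {result.config.seed}\n"
        f"# config: {result.config.digest()}\n"
    )
    for name, df in (
        ("per_animal.csv", result.per_animal),
        ("comparisons.csv", result.comparisons),
    ):
        with (out / name).open("w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    (out / "report.md").write_text(result.report)
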