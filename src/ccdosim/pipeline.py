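"""Config-driven campaign orchestration.

A campaign enumerates (current path, frequency, touch voltage) scenarios on
one phantom, selects the body-model variant per scenario, runs the solves,
and emits dose and heart-current-factor tables.  Heart-current-factor
campaigns force the Intern-BM for every solve -- the skin layer scales source
and reference fields identically and cancels from the factor -- while
impedance campaigns follow the frequency/voltage regime classification;
case-by-case scenarios are never decided silently: they are skipped with a
logged warning unless a mode is forced.

Campaign outputs are a pure function of the configuration: completed solves
are cached by a content hash and reruns are idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .contact import BodyModelMode, select_body_model
from .dosimetry import DoseReport, HCFTable, evaluate_solution, hcf
from .paths import DEFAULT_PATHS, REFERENCE_PATH, CurrentPath, expand_paths
from .phantom import PhantomConfig, PhantomError, build_phantom
from .solver import ContactScenario, solve_scenario
from .tissues import MaterialSet

__all__ = ["Campaign", "CampaignResult", "run_campaign", "sensitivity_sweep",
           "DEFAULT_FREQUENCIES"]

logger = logging.getLogger("ccdosim")

#: DC plus the four spot frequencies of the standard factor tables.
DEFAULT_FREQUENCIES: tuple[float, ...] = (0.0, 50.0, 1e3, 1e4, 1e5)


@dataclass(frozen=True)
class Campaign:
    """One scenario grid.  Defaults reproduce the standard factor-table grid:
    16 paths x 5 frequencies, Intern-BM, one touch voltage."""

    phantom_config: PhantomConfig = field(default_factory=PhantomConfig)
    paths: tuple[str, ...] = DEFAULT_PATHS
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    touch_voltages: tuple[float, ...] = (220.0,)
    mode_policy: str = "auto"          # "auto" | "TOTAL" | "INTERN"
    hcf: bool = True                   # force Intern-BM and emit factor tables
    out_dir: str | None = None
    solver_tolerance: float = 1e-8
    solver_method: str = "auto"
    n_planes: int = 4
    sigma_scales: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom_config"] = self.phantom_config.to_dict()
        d["sigma_scales"] = dict(self.sigma_scales)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Campaign":
        d = dict(d)
        d["phantom_config"] = PhantomConfig.from_dict(d.get("phantom_config", {}))
        for key in ("paths", "frequencies", "touch_voltages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = self.to_dict()
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CampaignResult:
    doses: list[DoseReport]
    f99: HCFTable | None
    fsam: HCFTable | None
    failures: list[dict]
    skipped: list[dict]
    config_hash: str

    @property
    def ok(self) -> bool:
        return not self.failures


def _scenario_mode(campaign: Campaign, frequency: float, voltage: float):
    """Resolve the body-model mode for one scenario, or None to skip."""
    if campaign.hcf:
        return BodyModelMode.INTERN
    if campaign.mode_policy == "auto":
        mode = select_body_model(frequency, voltage)
        if mode is BodyModelMode.CASE_BY_CASE:
            return None
        return mode
    return BodyModelMode(campaign.mode_policy)


def _solve_one(phantom, materials, path: CurrentPath, frequency: float,
               voltage: float, mode: BodyModelMode, campaign: Campaign) -> DoseReport:
    scenario = ContactScenario(path=path, frequency=frequency,
                               touch_voltage=voltage, mode=mode)
    solution = solve_scenario(phantom, materials, scenario,
                              tolerance=campaign.solver_tolerance,
                              method=campaign.solver_method)
    report = evaluate_solution(solution, n_planes=campaign.n_planes)
    logger.info("solved %s f=%g Hz U=%g V mode=%s: |I|=%.4g A |Z|=%.4g Ohm "
                "iters=%d residual=%.2e spread=%.2e",
                path.label, frequency, voltage, mode.value,
                abs(report.i_body), abs(report.z_total),
                solution.iterations, report.residual, report.plane_spread)
    return report


def run_campaign(campaign: Campaign,
                 materials: MaterialSet | None = None) -> CampaignResult:
    """Run every scenario of the campaign; cache, post-process, write tables.

    Failed solves are recorded and the campaign continues; the result's
    ``ok`` flag (and the CLI exit status) reflects them.
    """
    materials = materials or MaterialSet.default()
    for tissue, factor in campaign.sigma_scales.items():
        materials = materials.with_sigma_scale(tissue, factor)
    phantom = build_phantom(campaign.phantom_config)
    paths = expand_paths(campaign.paths)
    if campaign.hcf and REFERENCE_PATH not in {p.label for p in paths}:
        raise ValueError(
            f"factor tables need the reference path {REFERENCE_PATH} in the campaign")

    chash = campaign.config_hash()
    cache_dir = None
    if campaign.out_dir is not None:
        cache_dir = Path(campaign.out_dir) / "solves"
        cache_dir.mkdir(parents=True, exist_ok=True)

    doses: list[DoseReport] = []
    failures: list[dict] = []
    skipped: list[dict] = []
    for path in paths:
        for frequency in campaign.frequencies:
            for voltage in campaign.touch_voltages:
                mode = _scenario_mode(campaign, frequency, voltage)
                if mode is None:
                    msg = (f"{path.label} at {frequency} Hz / {voltage} V falls in "
                           "the case-by-case regime; skipped (force a mode to run it)")
                    logger.warning(msg)
                    skipped.append({"path": path.label, "frequency": frequency,
                                    "touch_voltage": voltage, "reason": msg})
                    continue
                key = hashlib.sha256(
                    f"{chash}|{path.label}|{frequency}|{voltage}|{mode.value}"
                    .encode()).hexdigest()[:24]
                cache_file = cache_dir / f"{key}.json" if cache_dir else None
                if cache_file is not None and cache_file.exists():
                    doses.append(_report_from_json(json.loads(cache_file.read_text())))
                    continue
                try:
                    report = _solve_one(phantom, materials, path, frequency,
                                        voltage, mode, campaign)
                except Exception as exc:  # recorded; campaign continues
                    logger.error("solve failed for %s f=%g U=%g: %s",
                                 path.label, frequency, voltage, exc)
                    failures.append({"path": path.label, "frequency": frequency,
                                     "touch_voltage": voltage, "error": str(exc)})
                    continue
                doses.append(report)
                if cache_file is not None:
                    cache_file.write_text(json.dumps(_report_to_json(report),
                                                     sort_keys=True))

    f99 = fsam = None
    if campaign.hcf and doses:
        f99 = hcf(doses, "F99")
        fsam = hcf(doses, "FSAM")
        lut99 = {(p, f): v for p, row in f99.frame.iterrows()
                 for f, v in row.items()}
        lutsam = {(p, f): v for p, row in fsam.frame.iterrows()
                  for f, v in row.items()}
        doses = [dataclasses.replace(
            d, f99_num=lut99.get((d.path_label, d.frequency)),
            f_sam_num=lutsam.get((d.path_label, d.frequency))) for d in doses]

    if campaign.out_dir is not None:
        out = Path(campaign.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_dose_reports(doses, out / "doses.csv")
        if f99 is not None:
            f99.to_csv(out / "hcf_f99.csv")
            fsam.to_csv(out / "hcf_fsam.csv")
        (out / "campaign.json").write_text(json.dumps({
            "config": campaign.to_dict(),
            "config_hash": chash,
            "n_solves": len(doses),
            "failures": failures,
            "skipped": skipped,
        }, sort_keys=True, indent=2, default=str))
    return CampaignResult(doses=doses, f99=f99, fsam=fsam, failures=failures,
                          skipped=skipped, config_hash=chash)


def _report_to_json(d: DoseReport) -> dict:
    return {
        "path_label": d.path_label, "frequency": d.frequency,
        "touch_voltage": d.touch_voltage, "mode": d.mode,
        "i_body": [d.i_body.real, d.i_body.imag],
        "z_total": [d.z_total.real, d.z_total.imag],
        "e99_heart": d.e99_heart, "e_sam": d.e_sam,
        "plane_spread": d.plane_spread, "residual": d.residual,
    }


def _report_from_json(j: dict) -> DoseReport:
    return DoseReport(
        path_label=j["path_label"], frequency=j["frequency"],
        touch_voltage=j["touch_voltage"], mode=j["mode"],
        i_body=complex(*j["i_body"]), z_total=complex(*j["z_total"]),
        e99_heart=j["e99_heart"], e_sam=j["e_sam"],
        plane_spread=j["plane_spread"], residual=j["residual"])


def sensitivity_sweep(campaign: Campaign, sweep: Mapping,
                      materials: MaterialSet | None = None) -> pd.DataFrame:
    """Rerun the campaign over a sweep grid, reporting factor ratios to baseline.

    ``sweep`` is one of

    * ``{"electrode_offset": {"site": s, "offsets_mm": [(d1, d2), ...]}}`` --
      shift the site's patch window by (d1, d2) mm in its transverse axes;
    * ``{"tissue_sigma_scale": {"tissue": name, "factors": [...]}}`` --
      scale the tissue's conductivity.

    For every sweep point and (path, frequency) the reported ``f99_ratio`` is
    (E99/|I|) of the perturbed solve divided by (E99/|I|) of the *baseline
    reference path* at that frequency, so a point identical to the baseline
    reproduces the baseline factor exactly and perturbations of the reference
    path itself remain visible.  Sweep points whose phantom cannot be built
    (e.g. an electrode pushed off the body) are flagged and the sweep
    continues.
    """
    materials = materials or MaterialSet.default()
    base = run_campaign(campaign, materials)
    if base.f99 is None:
        raise ValueError("sensitivity sweeps need an HCF campaign (hcf=True)")
    base_ref = {}
    for d in base.doses:
        if d.path_label == REFERENCE_PATH:
            base_ref[d.frequency] = d.e99_heart / abs(d.i_body)

    rows = []
    if "electrode_offset" in sweep:
        spec = sweep["electrode_offset"]
        site = spec["site"]
        points = [("electrode_offset", site, tuple(off)) for off in spec["offsets_mm"]]
    elif "tissue_sigma_scale" in sweep:
        spec = sweep["tissue_sigma_scale"]
        points = [("tissue_sigma_scale", spec["tissue"], float(f))
                  for f in spec["factors"]]
    else:
        raise ValueError("sweep must contain electrode_offset or tissue_sigma_scale")

    for kind, target, value in points:
        if kind == "electrode_offset":
            pcfg = campaign.phantom_config.with_electrode_offset(
                target, value[0], value[1])
            sub = dataclasses.replace(campaign, phantom_config=pcfg, out_dir=None)
            mats = materials
        else:
            sub = dataclasses.replace(campaign, out_dir=None)
            mats = materials.with_sigma_scale(target, value)
        try:
            res = run_campaign(sub, mats)
        except (PhantomError, ValueError) as exc:
            rows.append({"kind": kind, "target": target, "value": str(value),
                         "path": None, "frequency_hz": None,
                         "f99_ratio": np.nan, "delta_vs_baseline": np.nan,
                         "flag": str(exc)})
            continue
        base_f99 = {(d.path_label, d.frequency): d.f99_num for d in base.doses}
        for d in res.doses:
            ratio = (d.e99_heart / abs(d.i_body)) / base_ref[d.frequency]
            baseline = base_f99.get((d.path_label, d.frequency), np.nan)
            rows.append({"kind": kind, "target": target, "value": str(value),
                         "path": d.path_label, "frequency_hz": d.frequency,
                         "f99_ratio": ratio,
                         "delta_vs_baseline": ratio - baseline,
                         "flag": ""})
    df = pd.DataFrame(rows)
    if campaign.out_dir is not None:
        Path(campaign.out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(campaign.out_dir) / "sweep.csv", index=False)
    return df
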