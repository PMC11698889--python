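"""Pipeline orchestration: simulate -> calibrate -> process -> stats.

Each stage is a pure function of its recorded inputs and a single
:class:`RunConfig`; every intermediate (curves, thresholds, concentration
maps, masks, summaries) is written to disk, and a JSON manifest records the
parameters and per-sample thresholds so any stage can be re-run
reproducibly.  A failure in one sample aborts that sample with a logged
reason, not the whole run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import denoise, imaging, stats, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis parameters in one auditable document."""

    seed: int = 0
    shape: tuple[int, int] = (120, 160)
    cohort: dict[str, int] = field(default_factory=lambda: {"H": 4, "NM": 7, "M": 11})
    denoise_size: int = 5
    denoise_k: float = 3.0
    segment_k: int = 3
    segment_t: int = 1
    segment_t_overrides: dict[str, int] = field(default_factory=dict)
    calibrate_elements: list[str] = field(
        default_factory=lambda: ["56Fe", "63Cu", "66Zn", "88Sr"])
    normalize_element: Optional[str] = "138Ba"
    reference_element: str = "88Sr"
    reference_conc: float = synthetic.SR_REFERENCE_CONC
    alpha: float = 0.05
    sr_ba_rank_correlation: float = 0.90

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.shape = tuple(cfg.shape)  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def denoise_params(self) -> denoise.DenoiseParams:
        return denoise.DenoiseParams(size=self.denoise_size, k=self.denoise_k)

    def segment_params(self, element: str) -> denoise.SegmentParams:
        t = self.segment_t_overrides.get(element, self.segment_t)
        return denoise.SegmentParams(k=self.segment_k, t=t, seed=self.seed)

    def phantom_config(self) -> synthetic.PhantomConfig:
        return synthetic.PhantomConfig(
            shape=self.shape, seed=self.seed,
            sr_ba_rank_correlation=self.sr_ba_rank_correlation)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def standards_to_csv(standards: dict[str, list[cal.StandardMeasurement]],
                     path: str | Path) -> None:
    rows = []
    for element, sset in standards.items():
        for si, s in enumerate(sset):
            sid = f"{element}_std{si}"
            for li, line in enumerate(s.lines):
                for pi, v in enumerate(line):
                    rows.append((element, sid, s.nominal_conc, s.measured_conc,
                                 li, pi, v))
    pd.DataFrame(rows, columns=["element", "standard_id", "nominal_conc",
                                "measured_conc", "line_id", "pixel_index",
                                "intensity"]).to_csv(path, index=False)


def standards_from_csv(path: str | Path) -> dict[str, list[cal.StandardMeasurement]]:
    df = pd.read_csv(path)
    out: dict[str, list[cal.StandardMeasurement]] = {}
    for (element, sid), sub in df.groupby(["element", "standard_id"], sort=False):
        lines = [g["intensity"].to_numpy()
                 for _, g in sub.groupby("line_id", sort=True)]
        out.setdefault(element, []).append(cal.StandardMeasurement(
            element=element, nominal_conc=float(sub["nominal_conc"].iloc[0]),
            measured_conc=float(sub["measured_conc"].iloc[0]), lines=lines))
    return out


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic cohort: sample stacks, annotations, truth
    maps, the standards table (including the Sr reference block) and the
    sample records."""
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    pconfig = config.phantom_config()
    rng = np.random.default_rng(config.seed)

    standards = {el: synthetic.generate_standard_set(
        el, pconfig, seed=int(rng.integers(2**31)))
        for el in config.calibrate_elements}
    if config.normalize_element:
        ref = synthetic.generate_sr_reference(pconfig,
                                              seed=int(rng.integers(2**31)))
        standards.setdefault(ref.element, []).append(ref)
    standards_to_csv(standards, out / "standards.csv")

    cohort = synthetic.generate_cohort(
        pconfig, n_h=config.cohort.get("H", 0), n_nm=config.cohort.get("NM", 0),
        n_m=config.cohort.get("M", 0), seed=int(rng.integers(2**31)))
    records = []
    for phantom, record in cohort:
        sdir = out / "samples" / record.sample_id
        imaging.write_stack(phantom.stack, sdir)
        imaging.write_annotation(phantom.annotation, sdir / "annotation.csv")
        for el, truth in phantom.truth_conc.items():
            np.savetxt(sdir / f"truth_{el}.csv", truth, fmt="%.17g",
                       delimiter=",")
        records.append(record)
    imaging.write_sample_records(records, out / "records.csv")
    manifest = {"stage": "simulate", "seed": config.seed,
                "n_samples": len(records),
                "config": dataclasses.asdict(config) | {"shape": list(config.shape)}}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# calibrate
# ---------------------------------------------------------------------------

def run_calibrate(standards_path: str | Path, config: RunConfig,
                  out_dir: str | Path) -> dict[str, cal.CalibrationCurve]:
    """Fit per-element calibration curves and write curves.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    standards = standards_from_csv(standards_path)
    curves: dict[str, cal.CalibrationCurve] = {}
    for el in config.calibrate_elements:
        if el not in standards:
            raise ValueError(f"no standards found for element {el}")
        # the spiked reference block is not part of the regression series
        series = [s for s in standards[el]
                  if not (el == config.reference_element
                          and s.nominal_conc == config.reference_conc)]
        curves[el] = cal.fit_calibration(series)
    pd.DataFrame([{
        "element": c.element, "slope": c.slope, "intercept": c.intercept,
        "r_squared": c.r_squared, "blank_sd": c.blank_sd, "loq": c.loq,
        "range_min": c.range[0], "range_max": c.range[1]}
        for c in curves.values()]).to_csv(out / "curves.csv", index=False)
    return curves


def _reference_intensity(standards: dict[str, list[cal.StandardMeasurement]],
                         config: RunConfig) -> float:
    """Mean intensity of the spiked reference standard (for Ba/Sr)."""
    ref_el = config.reference_element
    for s in standards.get(ref_el, []):
        if s.nominal_conc == config.reference_conc:
            return s.mean_intensity
    raise ValueError(
        f"Ba normalization requested but no {ref_el} standard at "
        f"{config.reference_conc} ug/g is present in the standards file")


# ---------------------------------------------------------------------------
# process
# ---------------------------------------------------------------------------

def process_sample(stack: imaging.ImageStack, annotation: imaging.RegionAnnotation,
                   curves: dict[str, cal.CalibrationCurve],
                   config: RunConfig,
                   norm_params: Optional[cal.NormalizationParams] = None
                   ) -> tuple[list[stats.RegionSummary],
                              dict[str, cal.ConcentrationMap],
                              dict[str, denoise.SegmentationResult]]:
    """Denoise -> calibrate/normalize -> k-means mask -> summarize one sample.

    Returns (summaries, concentration maps, segmentations).  Summaries
    include the k-means-retained pseudo-region ("retained", the unit for
    group comparisons) and each annotated region without the k-means mask
    (the unit for paired region comparisons).
    """
    dparams = config.denoise_params()
    summaries: list[stats.RegionSummary] = []
    conc_maps: dict[str, cal.ConcentrationMap] = {}
    segs: dict[str, denoise.SegmentationResult] = {}
    for el in stack.isotopes:
        filtered = denoise.rolling_median_filter(stack[el], dparams)
        if el in curves:
            conc = cal.apply_calibration(filtered, curves[el])
        elif config.normalize_element == el and norm_params is not None:
            conc = cal.normalize_by_standard(filtered, norm_params)
        else:
            continue
        seg = denoise.segment_image(filtered, config.segment_params(el))
        conc_maps[el] = conc
        segs[el] = seg
        summaries.append(stats.masked_summary(conc, seg.mask,
                                              sample_id=stack.sample_id,
                                              element=el))
        for region in annotation.regions_present():
            if region == "background":
                continue
            summaries.append(stats.region_summary(
                conc, annotation, region, sample_id=stack.sample_id,
                element=el))
    return summaries, conc_maps, segs


def run_process(cohort_dir: str | Path, config: RunConfig,
                out_dir: str | Path,
                standards_path: str | Path | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Process every sample of a cohort directory.

    Returns (summaries dataframe, failed sample ids).  Pre-flight checks
    (standards for every calibrated element, the spiked reference standard
    when normalization is requested) run before any sample is read.
    """
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    if standards_path is None:
        standards_path = cohort_dir / "standards.csv"

    standards = standards_from_csv(standards_path)
    missing = [el for el in config.calibrate_elements if el not in standards]
    if missing:
        raise ValueError(f"standards file lacks elements: {missing}")
    norm_params = None
    if config.normalize_element:
        norm_params = cal.NormalizationParams(
            reference_element=config.reference_element,
            reference_conc=config.reference_conc,
            reference_intensity=_reference_intensity(standards, config))

    curves = run_calibrate(standards_path, config, out)
    records = imaging.read_sample_records(cohort_dir / "records.csv")

    all_summaries: list[stats.RegionSummary] = []
    failures: list[str] = []
    manifest_samples: dict[str, dict] = {}
    for record in records:
        sdir = cohort_dir / "samples" / record.sample_id
        try:
            stack = imaging.read_stack(sdir)
            annotation = imaging.read_annotation(sdir / "annotation.csv")
            summaries, conc_maps, segs = process_sample(
                stack, annotation, curves, config, norm_params)
        except Exception as err:  # noqa: BLE001 - sample-level isolation
            logger.error("sample %s failed: %s", record.sample_id, err)
            failures.append(record.sample_id)
            continue
        odir = out / "samples" / record.sample_id
        odir.mkdir(parents=True, exist_ok=True)
        for el, conc in conc_maps.items():
            np.savetxt(odir / f"conc_{el}.csv", conc.data, fmt="%.17g",
                       delimiter=",")
            imaging.write_mask(segs[el].mask, odir / f"mask_{el}.csv")
        manifest_samples[record.sample_id] = {
            el: {"threshold": segs[el].threshold,
                 "centroids": list(map(float, segs[el].centroids)),
                 "n_negative": conc_maps[el].n_negative}
            for el in conc_maps}
        all_summaries.extend(summaries)

    df = pd.DataFrame([dataclasses.asdict(s) for s in all_summaries])
    df.to_csv(out / "summaries.csv", index=False)
    manifest = {
        "stage": "process", "seed": config.seed,
        "config": dataclasses.asdict(config) | {"shape": list(config.shape)},
        "curves": {el: dataclasses.asdict(c) for el, c in curves.items()},
        "samples": manifest_samples, "failures": failures,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return df, failures


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

def run_stats(cohort_dir: str | Path, process_dir: str | Path,
              config: RunConfig, out_dir: str | Path | None = None
              ) -> tuple[stats.ReportTables, pd.DataFrame]:
    """Group/paired statistics plus the per-sample Sr-Ba correlation table."""
    cohort_dir, process_dir = Path(cohort_dir), Path(process_dir)
    out = Path(out_dir) if out_dir is not None else process_dir
    out.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(process_dir / "summaries.csv")
    records = imaging.read_sample_records(cohort_dir / "records.csv")
    summaries = [stats.RegionSummary(
        sample_id=str(r.sample_id), element=str(r.element), region=str(r.region),
        median=float(r.median), q1=float(r.q1), q3=float(r.q3),
        n_pixels=int(r.n_pixels),
        pct_below_loq=None if pd.isna(r.pct_below_loq) else float(r.pct_below_loq))
        for r in df.itertuples(index=False)]
    plan = stats.StatsPlan(alpha=config.alpha)
    report = stats.group_comparison_report(summaries, records, plan)

    corr_rows = []
    ref_el, ba_el = config.reference_element, config.normalize_element
    if ba_el:
        for record in records:
            odir = process_dir / "samples" / record.sample_id
            sr_f, ba_f = odir / f"conc_{ref_el}.csv", odir / f"conc_{ba_el}.csv"
            if not (sr_f.exists() and ba_f.exists()):
                continue
            annotation = imaging.read_annotation(
                cohort_dir / "samples" / record.sample_id / "annotation.csv")
            sr = np.loadtxt(sr_f, delimiter=",")
            ba = np.loadtxt(ba_f, delimiter=",")
            res = stats.spearman_colocalization(
                sr, ba, annotation.region_mask("epithelial"),
                sample_id=record.sample_id, elements=(ref_el, ba_el))
            corr_rows.append({
                "sample_id": res.sample_id, "group": record.group,
                "element_a": ref_el, "element_b": ba_el, "rho": res.rho,
                "n_pixels": res.n_pixels, "strength": res.strength,
                "p_value": res.p_value})
    correlations = pd.DataFrame(corr_rows)

    report.group_summary.to_csv(out / "group_summary.csv", index=False)
    report.tests.to_csv(out / "tests.csv", index=False)
    correlations.to_csv(out / "correlations.csv", index=False)
    return report, correlations


def run_all(config: RunConfig, out_dir: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """simulate -> process (incl. calibrate) -> stats under one seed."""
    out = Path(out_dir)
    cohort_dir = out / "cohort"
    process_dir = out / "processed"
    run_simulate(config, cohort_dir)
    df, failures = run_process(cohort_dir, config, process_dir)
    run_stats(cohort_dir, process_dir, config)
    return df, failures
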