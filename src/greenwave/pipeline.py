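"""End-to-end orchestration: simulate/load -> metrics -> fit -> report.

A run is described by a :class:`RunConfig` (usually parsed from YAML),
executes deterministically given the config and seed, and emits CSV tables
(metrics, LS-means, contrasts, variance components per response) plus a
provenance record sufficient to re-derive every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DEFAULT_RICHNESS_COUNTS, TREATMENTS, Design, build_design
from .inference import (ModelSpec, day_contrast, fit_lmm, lsmeans,
                        percent_contrast)
from .observations import (ObservationRecord, assemble_series, coverage_filter,
                           observations_frame, read_observations)
from .phenology import PARTITION_MODES, compute_ndvi, metrics_table
from .simulate import (CurveParams, EffectConfig, SamplingSchedule,
                       VarianceConfig, reference_effects, simulate_experiment)

log = logging.getLogger("greenwave")

DEFAULT_RESPONSES = [
    "indvi_total", "indvi_early", "indvi_late",
    "greenup_slope", "senescence_slope", "peak_doy",
]

#: responses whose effect sizes are reported as day differences, not percent
DAY_SCALE_RESPONSES = {"peak_doy"}


@dataclass
class SyntheticSource:
    richness_counts: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS_COUNTS))
    treatments: list[str] = field(default_factory=lambda: list(TREATMENTS))
    years: list[int] = field(default_factory=lambda: list(range(2010, 2015)))
    curve: CurveParams = field(default_factory=CurveParams)
    effects: EffectConfig = field(default_factory=reference_effects)
    variance: VarianceConfig = field(default_factory=VarianceConfig)
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)

    def design(self) -> Design:
        return build_design(self.richness_counts, self.treatments, self.years)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    synthetic: SyntheticSource | None = None
    input_file: str | None = None
    dialect: dict[str, str] = field(default_factory=dict)
    partition_mode: str = "median_doy"
    min_per_half: int = 2
    boundary_doy: int | None = None
    responses: list[str] = field(default_factory=lambda: list(DEFAULT_RESPONSES))
    seed: int = 0
    out_dir: str = "greenwave-run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_file is None):
            raise ValueError("exactly one input source (synthetic or file) required")
        if self.partition_mode not in PARTITION_MODES:
            raise ValueError(f"unknown partition mode {self.partition_mode!r}")


_CURVE_KEYS = {"B", "A", "t_g", "g", "t_s", "s"}
_VAR_KEYS = {"sd_year", "sd_plot", "sd_subplot", "sd_resid", "seed"}
_SCHED_KEYS = {"start_doy", "end_doy", "interval_days", "jitter_days", "miss_prob"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _parse_effects(raw) -> EffectConfig:
    if raw in (None, "reference"):
        return reference_effects()
    _check_keys(raw, {"amplitude_mult", "phenology_shift", "senescence_mult",
                      "amplitude_treat_mult"}, "effects")
    atm = {tuple(k.split(":")) if isinstance(k, str) else tuple(k): v
           for k, v in (raw.get("amplitude_treat_mult") or {}).items()}
    atm = {(int(r), t): v for (r, t), v in atm.items()}
    return EffectConfig(
        amplitude_mult={int(k): float(v)
                        for k, v in (raw.get("amplitude_mult") or {}).items()},
        phenology_shift={int(k): float(v)
                         for k, v in (raw.get("phenology_shift") or {}).items()},
        senescence_mult={str(k): float(v)
                         for k, v in (raw.get("senescence_mult") or {}).items()},
        amplitude_treat_mult=atm,
    )


def parse_config(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a YAML-derived mapping; unknown keys
    are rejected with the offending name."""
    _check_keys(raw, {"input", "partition_mode", "coverage", "responses",
                      "seed", "out_dir", "log_level"}, "config")
    inp = raw.get("input") or {}
    _check_keys(inp, {"synthetic", "file", "dialect"}, "input")
    if ("synthetic" in inp) and ("file" in inp):
        raise ValueError("config lists both synthetic and file input sources")

    synthetic = None
    if "synthetic" in inp:
        s = inp["synthetic"] or {}
        _check_keys(s, {"richness_counts", "treatments", "years", "curve",
                        "effects", "variance", "schedule"}, "synthetic")
        curve_raw = s.get("curve") or {}
        _check_keys(curve_raw, _CURVE_KEYS, "curve")
        var_raw = s.get("variance") or {}
        _check_keys(var_raw, _VAR_KEYS, "variance")
        sched_raw = s.get("schedule") or {}
        _check_keys(sched_raw, _SCHED_KEYS, "schedule")
        synthetic = SyntheticSource(
            richness_counts={int(k): int(v) for k, v in
                             (s.get("richness_counts")
                              or DEFAULT_RICHNESS_COUNTS).items()},
            treatments=list(s.get("treatments") or TREATMENTS),
            years=[int(y) for y in (s.get("years")
                                    or range(2010, 2015))],
            curve=CurveParams(**curve_raw),
            effects=_parse_effects(s.get("effects")),
            variance=VarianceConfig(**var_raw),
            schedule=SamplingSchedule(**sched_raw),
        )
    cov = raw.get("coverage") or {}
    _check_keys(cov, {"min_per_half", "boundary_doy"}, "coverage")
    return RunConfig(
        synthetic=synthetic,
        input_file=inp.get("file"),
        dialect=dict(inp.get("dialect") or {}),
        partition_mode=raw.get("partition_mode", "median_doy"),
        min_per_half=int(cov.get("min_per_half", 2)),
        boundary_doy=cov.get("boundary_doy"),
        responses=list(raw.get("responses", DEFAULT_RESPONSES)),
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "greenwave-run")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh) or {})


def _records_from_config(cfg: RunConfig) -> tuple[list[ObservationRecord], str]:
    """(records, input checksum) from either source."""
    if cfg.synthetic is not None:
        src = cfg.synthetic
        var = VarianceConfig(**{**asdict(src.variance), "seed": cfg.seed})
        records = simulate_experiment(src.design(), src.curve, src.effects,
                                      var, src.schedule)
        digest = hashlib.sha256(
            observations_frame(records).to_csv(index=False).encode()
        ).hexdigest()
        return records, digest
    data = Path(cfg.input_file).read_bytes()
    records, report = read_observations(cfg.input_file, cfg.dialect)
    if report.rejected:
        log.warning("%d rows rejected during ingest", len(report.rejected))
    return records, hashlib.sha256(data).hexdigest()


def _ensure_ndvi(records: list[ObservationRecord]) -> None:
    for r in records:
        if r.ndvi is None:
            r.ndvi = float(compute_ndvi(r.red, r.nir))


@dataclass
class RunReport:
    out_dir: Path
    artifacts: dict[str, Path]
    n_series: int
    n_excluded: int
    failed_stage: str | None = None
    warnings: int = 0

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def analyze_metrics(metrics: pd.DataFrame, responses: list[str]):
    """Fit each response's weighted mixed model and derive LS-means and
    margin contrasts (levels vs the reference richness / control treatment)."""
    results = {}
    for resp in responses:
        spec = ModelSpec(response=resp)
        fit = fit_lmm(metrics, spec)
        table = lsmeans(fit)
        contrasts = []
        rich_levels = sorted({c[0] for c in table.cells})
        treat_levels = [t for t in TREATMENTS
                        if t in {c[1] for c in table.cells}] or \
            sorted({c[1] for c in table.cells})
        ref_r, ref_t = rich_levels[0], treat_levels[0]
        for r in rich_levels[1:]:
            contrasts.append(("richness", r, ref_r,
                              _contrast(table, ("richness", r),
                                        ("richness", ref_r), resp)))
        for t in treat_levels[1:]:
            contrasts.append(("treatment", t, ref_t,
                              _contrast(table, ("treatment", t),
                                        ("treatment", ref_t), resp)))
        results[resp] = {"fit": fit, "lsmeans": table, "contrasts": contrasts}
    return results


def _contrast(table, a, b, resp):
    if resp in DAY_SCALE_RESPONSES:
        return day_contrast(table, a, b)
    return percent_contrast(table, a, b)


def contrasts_frame(results: dict) -> pd.DataFrame:
    rows = []
    for resp, res in results.items():
        for factor, level, ref, c in res["contrasts"]:
            rows.append({
                "response": resp, "factor": factor,
                "level": level, "reference": ref,
                "difference": c.difference, "difference_se": c.difference_se,
                "percent": c.percent, "percent_se": c.percent_se,
            })
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the whole pipeline; deterministic given config + seed.

    On a stage failure, outputs already written are kept and the report names
    the failed stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    artifacts: dict[str, Path] = {}
    stage = "ingest"
    try:
        t0 = time.time()
        records, checksum = _records_from_config(cfg)
        _ensure_ndvi(records)
        data_path = out / "observations.csv"
        observations_frame(records).to_csv(data_path, index=False)
        artifacts["observations"] = data_path
        log.info("ingest: %d records (%.1fs)", len(records), time.time() - t0)

        stage = "metrics"
        series = assemble_series(records)
        retained, excluded = coverage_filter(series, cfg.min_per_half,
                                             cfg.boundary_doy)
        metrics = metrics_table(retained, cfg.partition_mode)
        metrics_path = out / "metrics.csv"
        metrics.to_csv(metrics_path, index=False)
        artifacts["metrics"] = metrics_path
        if excluded:
            excl = pd.DataFrame(
                [{"subplot_id": s.subplot_id, "year": s.year, "reason": r}
                 for s, r in excluded])
            excl_path = out / "excluded_series.csv"
            excl.to_csv(excl_path, index=False)
            artifacts["excluded"] = excl_path

        stage = "fit"
        results = analyze_metrics(metrics, cfg.responses)
        for resp, res in results.items():
            lsm_path = out / f"lsmeans_{resp}.csv"
            _write_table(res["lsmeans"].to_frame(), lsm_path, cfg, resp)
            artifacts[f"lsmeans_{resp}"] = lsm_path
            vc = pd.DataFrame([res["fit"].variance_components])
            vc_path = out / f"variance_components_{resp}.csv"
            _write_table(vc, vc_path, cfg, resp)
            artifacts[f"variance_components_{resp}"] = vc_path
        con_path = out / "contrasts.csv"
        contrasts_frame(results).to_csv(con_path, index=False)
        artifacts["contrasts"] = con_path

        stage = "report"
        for name, tab in report_tables(results).items():
            p = out / f"figure_{name}.csv"
            tab.to_csv(p, index=False)
            artifacts[f"figure_{name}"] = p

        stage = "provenance"
        prov = {
            "version": __version__,
            "seed": cfg.seed,
            "partition_mode": cfg.partition_mode,
            "responses": cfg.responses,
            "input_checksum_sha256": checksum,
            "config": asdict(cfg),
            "n_series_retained": len(retained),
            "n_series_excluded": len(excluded),
        }
        prov_path = out / "provenance.json"
        prov_path.write_text(json.dumps(prov, indent=2, default=str))
        artifacts["provenance"] = prov_path
        return RunReport(out_dir=out, artifacts=artifacts,
                         n_series=len(retained), n_excluded=len(excluded))
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        return RunReport(out_dir=out, artifacts=artifacts, n_series=0,
                         n_excluded=0, failed_stage=stage)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, resp: str) -> None:
    # header comment fingerprints the model spec that produced the table
    with open(path, "w") as fh:
        fh.write(f"# response={resp} weights=auto "
                 f"partition={cfg.partition_mode} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


FIGURE_TABLES = {
    "indvi_whole_season": ["indvi_total"],
    "indvi_early_late": ["indvi_early", "indvi_late"],
    "slopes": ["greenup_slope", "senescence_slope"],
    "peak_day": ["peak_doy"],
}


def report_tables(results: dict) -> dict[str, pd.DataFrame]:
    """Per-figure analogue tables: LS-mean and 95% CI per treatment cell.

    Missing responses are skipped with a warning rather than failing the
    report stage.
    """
    out = {}
    for name, resps in FIGURE_TABLES.items():
        frames = []
        for resp in resps:
            if resp not in results:
                log.warning("report: response %s missing, skipping", resp)
                continue
            df = results[resp]["lsmeans"].to_frame()
            df.insert(0, "response", resp)
            frames.append(df)
        if frames:
            out[name] = pd.concat(frames, ignore_index=True)
    return out


def seasonal_smoother(observations: pd.DataFrame, frac: float = 0.75,
                      by: tuple[str, ...] = ("richness", "treatment")):
    """Local polynomial (lowess) display smoother of NDVI on day of year.

    Mirrors a loess trajectory figure with span ``frac`` (default 0.75);
    purely cosmetic — never used in metric computation.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    frames = []
    for keys, grp in observations.groupby(list(by)):
        sm = lowess(grp["ndvi"], grp["doy"], frac=frac, return_sorted=True)
        df = pd.DataFrame(sm, columns=["doy", "ndvi_smooth"])
        for k, v in zip(by, keys if isinstance(keys, tuple) else (keys,)):
            df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
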