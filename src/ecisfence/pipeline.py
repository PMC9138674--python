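"""End-to-end orchestration: simulate -> analyse -> summarise.

``run_pipeline`` drives the whole fence workflow on synthetic data: it emits
the CSV bundle for the configured run, reads it back through the public
dialects, extracts per-well kinetics (Sc, Sr, T50), micromotion (Var32) and
morphology (Rb, h, Cm from scan fits), and reports per-substrate
mean +/- SEM.  Any per-well failure is logged and the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .kinetics import (
    DEFAULT_CAP_THRESHOLDS,
    extract_capacitance_slope,
    extract_resistance_slope,
    extract_t50,
)
from .micromotion import var32
from .model import fit_cell_params
from .synth import GeneratorConfig, default_profiles, simulate

__all__ = ["PipelineReport", "run_pipeline", "sem"]

log = logging.getLogger("ecisfence")

METRICS = ("Sc", "Sr", "T50", "Var32", "Rb", "h", "Cm")
_UNITS = {
    "Sc": "nF/h", "Sr": "Ohm/h", "T50": "h", "Var32": "-",
    "Rb": "Ohm*cm^2", "h": "nm", "Cm": "uF/cm^2",
}


def sem(values) -> float:
    """Standard error of the mean, sd/sqrt(n) with sample sd (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


@dataclass
class PipelineReport:
    per_well: pd.DataFrame  # columns: well, substrate, metric, value
    summary: pd.DataFrame  # columns: substrate, metric, unit, mean, sem, n
    failures: list = field(default_factory=list)  # (well, stage, message)
    out_dir: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def _substrate_of(well_id: str) -> str:
    return well_id.rsplit("-", 1)[0]


def run_pipeline(config: eio.RunConfig) -> PipelineReport:
    """Run the configured simulated experiment end to end."""
    out = Path(config.out_dir)
    gen = GeneratorConfig(
        array_type=config.array_type,
        profiles={s: default_profiles(config.array_type)[s] for s in config.substrates},
        noise_sd=config.noise_sd,
        migration_mode=config.migration_mode,
        seed=config.seed,
    )
    simulate(gen, out, wells_per_substrate=config.wells_per_substrate)

    upper_c, lower_c = config.cap_thresholds or DEFAULT_CAP_THRESHOLDS[config.array_type]
    rows = []
    failures = []

    def record(well, metric, value):
        rows.append({"well": well, "substrate": _substrate_of(well),
                     "metric": metric, "value": float(value)})

    if "attachment" in config.include:
        for tr in eio.read_timeseries(out / "attachment.csv"):
            try:
                res = extract_capacitance_slope(tr, upper_c, lower_c)
                record(tr.well_id, "Sc", res.slope)
            except Exception as exc:  # noqa: BLE001 - per-well isolation
                failures.append((tr.well_id, "attachment", str(exc)))
                log.warning("attachment analysis failed for %s: %s", tr.well_id, exc)

    if "migration" in config.include:
        for tr in eio.read_timeseries(out / "migration.csv"):
            try:
                res = extract_resistance_slope(tr, config.baseline_frac, config.plateau_frac)
                record(tr.well_id, "Sr", res.slope)
                record(tr.well_id, "T50", extract_t50(tr))
            except Exception as exc:  # noqa: BLE001
                failures.append((tr.well_id, "migration", str(exc)))
                log.warning("migration analysis failed for %s: %s", tr.well_id, exc)

    if "micromotion" in config.include:
        for series in eio.read_rtc(out / "rtc.csv"):
            try:
                record(series.well_id, "Var32", var32(series).var32)
            except Exception as exc:  # noqa: BLE001
                failures.append((series.well_id, "micromotion", str(exc)))
                log.warning("micromotion analysis failed for %s: %s", series.well_id, exc)

    if "scan" in config.include:
        scans = eio.read_scans(out / "scans.csv")
        by_key = {(s.well_id, s.coverage_state): s for s in scans}
        wells = sorted({s.well_id for s in scans})
        for well in wells:
            free = by_key.get((well, "cell_free"))
            covered = by_key.get((well, "cell_covered"))
            if free is None or covered is None:
                failures.append((well, "scan", "missing cell_free/cell_covered pair"))
                continue
            try:
                profile = gen.profiles[_substrate_of(well)]
                fit = fit_cell_params(
                    covered, free, gen.electrode,
                    n_starts=config.fit_n_starts, seed=config.seed,
                    rc_um=profile.rc_um,
                )
                record(well, "Rb", fit.params.rb)
                record(well, "h", fit.params.h_nm)
                record(well, "Cm", fit.params.cm)
            except Exception as exc:  # noqa: BLE001
                failures.append((well, "scan", str(exc)))
                log.warning("scan fit failed for %s: %s", well, exc)

    per_well = pd.DataFrame(rows, columns=["well", "substrate", "metric", "value"])
    summary_rows = []
    if not per_well.empty:
        for (substrate, metric), grp in per_well.groupby(["substrate", "metric"], sort=True):
            vals = grp["value"].to_numpy()
            summary_rows.append(
                {
                    "substrate": substrate,
                    "metric": metric,
                    "unit": _UNITS.get(metric, ""),
                    "mean": float(vals.mean()),
                    "sem": sem(vals),
                    "n": int(vals.size),
                }
            )
    summary = pd.DataFrame(
        summary_rows, columns=["substrate", "metric", "unit", "mean", "sem", "n"]
    )

    per_well.to_csv(out / "per_well.csv", index=False, float_format="%.6g")
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
    (out / "report.txt").write_text(_format_report(summary, failures))
    return PipelineReport(per_well=per_well, summary=summary, failures=failures, out_dir=out)


def _format_report(summary: pd.DataFrame, failures) -> str:
    lines = ["ECIS electric-fence run summary (mean +/- SEM per substrate)", ""]
    for metric in METRICS:
        sub = summary[summary["metric"] == metric]
        if sub.empty:
            continue
        lines.append(f"{metric} [{_UNITS.get(metric, '')}]")
        for _, row in sub.iterrows():
            lines.append(
                f"  {row['substrate']:>10}: {row['mean']:.6g} +/- {row['sem']:.6g}"
                f"  (n={row['n']})"
            )
        lines.append("")
    if failures:
        lines.append("failures:")
        lines.extend(f"  {w} [{stage}]: {msg}" for w, stage, msg in failures)
        lines.append("")
    return "\n".join(lines)
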