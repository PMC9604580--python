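"""File formats, run configuration and the end-to-end pipeline.

Everything on disk is delimited text. A waveform file holds one beat:

    # subject=S0001 adjusted=0
    time_s,area_mm2,velocity_m_per_s
    0.000,612.4,0.012
    ...

(comma or tab delimited; the optional comment line carries the subject id
and the rectified-velocity flag). Areas are mm² on disk and m² in memory.

A cohort table is one row per subject with columns
``subject_id,age,sex,BSA,HR,PR_pct,lv_edvi,lv_esvi,rv_edvi,rv_esvi,adjusted``.

:func:`run_pipeline` analyses every waveform in a directory, joins the
cohort table if present, runs the severity-group statistics and returns a
reproducible report bundle (per-subject results, group comparisons,
regressions, run log).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .cohort import (
    GroupComparison,
    chi_square,
    group_compare,
    regress,
)
from .errors import InsufficientDataError, ParseError, PipelineError, WiaError
from .signal import AorticSignal
from .wia import WaveIntensityModel, WiaConfig

WAVEFORM_COLUMNS = ("time_s", "area_mm2", "velocity_m_per_s")

#: Table-1-style continuous variables compared across severity groups
TABLE1_VARIABLES = (
    "age", "BSA", "HR", "PR_pct", "lv_edvi", "lv_esvi", "lv_sv", "lv_ef",
    "lv_ci", "rv_edvi", "rv_esvi",
)
#: Table-2-style wave variables (table-scale columns of the results file)
TABLE2_VARIABLES = (
    "c_m_per_s", "D_e-3_per_mmHg", "fcw_peak_e-5_m_per_s", "fcw_area_e-3_m",
    "few_peak_e-5_m_per_s", "few_area_e-3_m",
)


@dataclass(frozen=True)
class RunConfig:
    """Analysis-run configuration; every field has a documented default
    and a serialised copy is written into every output directory."""

    dt: float = 0.030             # analysis sampling interval, s
    smooth_window: int = 5        # Savitzky–Golay window (odd; 1 = off)
    smooth_order: int = 3
    onset_frac: float = 0.05      # lnA–U loop window start (fraction of peak U)
    end_frac: float = 0.50        # loop window end
    rho: float = 1060.0           # blood density, kg/m³
    alpha: float = 0.05           # significance threshold
    multiplicity: str = "bonferroni"  # Dunn post hoc adjustment
    seed: int = 0

    def wia(self) -> WiaConfig:
        return WiaConfig(
            dt=self.dt,
            smooth_window=self.smooth_window,
            smooth_order=self.smooth_order,
            onset_frac=self.onset_frac,
            end_frac=self.end_frac,
            rho=self.rho,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Waveform files


def read_waveform(path: str | Path) -> AorticSignal:
    """Read one beat from a delimited text file, converting mm² → m².

    Malformed rows are reported with their line numbers and the invariant
    they violate.
    """
    path = Path(path)
    subject_id = path.stem
    adjusted = False
    header_lines = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        header_lines = 1
        for tok in first[1:].split():
            if tok.startswith("subject="):
                subject_id = tok.split("=", 1)[1]
            elif tok.startswith("adjusted="):
                adjusted = tok.split("=", 1)[1] not in ("0", "false", "False")
    try:
        df = pd.read_csv(path, skiprows=header_lines, sep=None,
                         engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse delimited text: {exc}") from exc
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    offset = header_lines + 2  # 1-based line of the first data row
    for col in WAVEFORM_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col} at line {bad[0] + offset}"
            )
        df[col] = vals
    t = df["time_s"].to_numpy(float)
    nonmono = np.nonzero(np.diff(t) <= 0)[0]
    if len(nonmono):
        raise ParseError(
            f"{path}: time not strictly increasing at line "
            f"{nonmono[0] + 1 + offset} (rule: t strictly increasing)"
        )
    a = df["area_mm2"].to_numpy(float)
    nonpos = np.nonzero(a <= 0)[0]
    if len(nonpos):
        raise ParseError(
            f"{path}: non-positive area at line {nonpos[0] + offset} "
            "(rule: area must be strictly positive, lnA undefined)"
        )
    dt_native = None
    d = np.diff(t)
    if len(d) and np.max(d) - np.min(d) <= 1e-6 * np.mean(d):
        dt_native = float(np.mean(d))
    return AorticSignal(
        subject_id=subject_id,
        t=t,
        A=a * 1e-6,
        U=df["velocity_m_per_s"].to_numpy(float),
        dt_native=dt_native,
        adjusted=adjusted,
    )


def write_waveform(signal: AorticSignal, path: str | Path) -> None:
    """Write one beat to delimited text (areas back in mm²)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject={signal.subject_id} "
                 f"adjusted={int(signal.adjusted)}\n")
        fh.write(",".join(WAVEFORM_COLUMNS) + "\n")
        for t, a, u in zip(signal.t, signal.A, signal.U):
            fh.write(f"{t:.17g},{a * 1e6:.17g},{u:.17g}\n")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in df.columns:
        raise ParseError(f"{path}: cohort table needs a subject_id column")
    if "adjusted" in df.columns:
        df["adjusted"] = df["adjusted"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineReport:
    """Everything one run produces, in memory."""

    results: pd.DataFrame                 # one row per analysed subject
    comparisons: dict = field(default_factory=dict)   # variable -> GroupComparison
    chi2: dict = field(default_factory=dict)          # variable -> (stat, p)
    regressions: dict = field(default_factory=dict)   # name -> RegressionReport
    log: dict = field(default_factory=dict)
    exit_code: int = 0                    # 0 ok / 1 partial / 2 fatal


def analyse_directory(
    directory: str | Path, config: RunConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the beat-level model on every waveform file in a directory."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix in (".csv", ".tsv", ".txt")
        and p.name not in ("cohort.csv", "truth.csv")
    )
    rows, failures = [], []
    for f in files:
        try:
            sig = read_waveform(f)
            res = WaveIntensityModel(sig, config.wia()).fit()
            rows.append(res.to_row())
        except (WiaError, PipelineError) as exc:
            failures.append({"file": f.name, "error": str(exc)})
    return pd.DataFrame(rows), failures


def cohort_statistics(
    merged: pd.DataFrame, config: RunConfig
) -> tuple[dict, dict, dict]:
    """Severity-group comparisons, categorical tests and the FCW
    regressions on a merged cohort+results table."""
    comparisons: dict[str, GroupComparison] = {}
    chi2: dict[str, tuple[float, float]] = {}
    regressions = {}
    for var in (*TABLE1_VARIABLES, *TABLE2_VARIABLES):
        if var not in merged.columns:
            continue
        try:
            comparisons[var] = group_compare(merged, var)
        except InsufficientDataError:
            continue
    if "sex" in merged.columns:
        try:
            stat, p, _ = chi_square(merged, "sex")
            chi2["sex"] = (stat, p)
        except (InsufficientDataError, WiaError):
            pass
    outcome = "fcw_peak_e-5_m_per_s"
    preds = ["PR_pct", "age", "sex", "D_e-3_per_mmHg"]
    if outcome in merged.columns:
        avail = [p for p in preds if p in merged.columns]
        for p_ in avail:
            try:
                regressions[f"univariate_{p_}"] = regress(merged, outcome, [p_])
            except WiaError:
                pass
        if len(avail) > 1:
            try:
                regressions["multivariable"] = regress(merged, outcome, avail)
            except WiaError:
                pass
    return comparisons, chi2, regressions


def run_pipeline(
    config: RunConfig,
    cohort_dir: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Analyse a cohort directory end to end.

    Deterministic given (inputs, config, seed): rerunning writes identical
    bytes. Partial subject failures are logged and excluded (exit code 1);
    no valid subject at all is fatal (exit code 2, raises).
    """
    cohort_dir = Path(cohort_dir)
    results, failures = analyse_directory(cohort_dir, config)
    if results.empty:
        raise PipelineError("pipeline", f"no valid subjects in {cohort_dir}")
    cohort_path = cohort_dir / "cohort.csv"
    merged = results
    if cohort_path.exists():
        cohort = read_cohort_table(cohort_path)
        merged = cohort.merge(results, on="subject_id", how="inner")
    comparisons, chi2, regressions = ({}, {}, {})
    if "severity" in merged.columns:
        comparisons, chi2, regressions = cohort_statistics(merged, config)

    excluded_ws = [
        r["subject_id"]
        for _, r in results.iterrows()
        if "wave_speed_excluded_adjusted" in str(r.get("flags", ""))
    ]
    log = {
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "config": json.loads(config.to_json()),
        "n_analysed": int(len(results)),
        "n_failed": len(failures),
        "failures": failures,
        "wave_speed_excluded": excluded_ws,
    }
    report = PipelineReport(
        results=results,
        comparisons=comparisons,
        chi2=chi2,
        regressions=regressions,
        log=log,
        exit_code=1 if failures else 0,
    )
    if out_dir is not None:
        write_report(report, config, out_dir)
    return report


def _comparison_frame(comparisons: dict, chi2: dict) -> pd.DataFrame:
    rows = []
    for var, c in comparisons.items():
        row = {"variable": var, "test": "kruskal-wallis",
               "statistic": c.statistic, "p": c.p_value}
        for g, n, m, s in zip(c.group_names, c.n, c.means, c.sds):
            row[f"{g}_n"] = n
            row[f"{g}_mean"] = m
            row[f"{g}_sd"] = s
        rows.append(row)
    for var, (stat, p) in chi2.items():
        rows.append({"variable": var, "test": "chi-squared",
                     "statistic": stat, "p": p})
    return pd.DataFrame(rows)


def write_report(
    report: PipelineReport, config: RunConfig, out_dir: str | Path
) -> None:
    """Serialise a report bundle as delimited text + JSON run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.results.to_csv(out / "wia_results.csv", index=False,
                          float_format="%.10g")
    frame = _comparison_frame(report.comparisons, report.chi2)
    if not frame.empty:
        frame.to_csv(out / "group_comparisons.csv", index=False,
                     float_format="%.10g")
    if report.regressions:
        rows = []
        for name, rep in report.regressions.items():
            for term in rep.coefficients.index:
                rows.append({
                    "model": name, "outcome": rep.outcome, "term": term,
                    "beta": rep.coefficients[term],
                    "p": rep.p_values[term],
                    "r_squared": rep.r_squared, "n": rep.n,
                })
        pd.DataFrame(rows).to_csv(out / "regressions.csv", index=False,
                                  float_format="%.10g")
    (out / "config.json").write_text(config.to_json() + "\n")
    (out / "run_log.json").write_text(
        json.dumps(report.log, indent=2, sort_keys=True) + "\n"
    )
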