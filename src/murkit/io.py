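"""Delimited-text readers/writers and provenance shared by all stages.

Formats are deliberately plain: peak lists, rate tables and traces are
TSV/CSV with headers; reports are TSV with ``#``-prefixed provenance lines
(package version and a configuration hash — no timestamp, so identical
invocations produce byte-identical output).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .ions import IdentificationReport, Peak
from .kinetics import AssayConfig, AssayTrace, PHProfile, RateSeries

__all__ = [
    "read_peaklist",
    "read_rate_table",
    "read_trace",
    "read_ph_profile",
    "provenance_lines",
    "report_frame",
    "write_report",
    "read_report",
]


class PeaklistFormatError(ValueError):
    """Malformed peak-list row; message carries the 1-based line number."""


def _read_delimited(path) -> pd.DataFrame:
    # choose the separator from the header line; csv sniffing misfires on
    # single-column numeric files
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line
                break
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_peaklist(path) -> list[Peak]:
    """Parse a delimited peak list (columns: mz[, intensity, treatment, fraction])."""
    df = _read_delimited(path)
    if "mz" not in df.columns:
        raise PeaklistFormatError(f"{path}: missing required column 'mz'")
    if df.empty:
        warnings.warn(f"{path}: peak list is empty", stacklevel=2)
        return []
    peaks: list[Peak] = []
    for row in df.itertuples():
        # +2: header line plus 1-based indexing
        line_no = int(row.Index) + 2
        try:
            mz = float(row.mz)
        except (TypeError, ValueError):
            raise PeaklistFormatError(
                f"{path}: line {line_no}: malformed m/z value {row.mz!r}"
            ) from None
        peaks.append(
            Peak(
                mz=mz,
                intensity=float(row.intensity) if "intensity" in df.columns else None,
                treatment=str(row.treatment) if "treatment" in df.columns else None,
                fraction=str(row.fraction) if "fraction" in df.columns else None,
            )
        )
    return peaks


def read_rate_table(path) -> RateSeries:
    """Rate table with columns S_uM, v0[, replicate]."""
    df = _read_delimited(path)
    for col in ("S_uM", "v0"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return RateSeries(s_um=df["S_uM"].to_numpy(float), v0=df["v0"].to_numpy(float), replicate=rep)


def read_trace(path, config: AssayConfig) -> AssayTrace:
    """Absorbance trace with columns t, A340."""
    df = _read_delimited(path)
    for col in ("t", "A340"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return AssayTrace(time_s=df["t"].to_numpy(float), a340=df["A340"].to_numpy(float), config=config)


def read_ph_profile(path) -> PHProfile:
    df = _read_delimited(path)
    for col in ("pH", "v0"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return PHProfile(ph=df["pH"].to_numpy(float), v0=df["v0"].to_numpy(float))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def provenance_lines(config: dict) -> list[str]:
    return [
        f"# murkit {__version__}",
        f"# config {config_hash(config)} {json.dumps(config, sort_keys=True, default=str)}",
    ]


_REPORT_COLUMNS = [
    "peak_mz",
    "treatment",
    "fraction",
    "precursor",
    "ion_label",
    "theoretical_mz",
    "ppm_error",
    "assigned",
]


def report_frame(report: IdentificationReport) -> pd.DataFrame:
    """Flatten a report: one row per peak, stable column order, m/z to 4 dp."""
    rows = []
    for m in report.matches:
        rows.append(
            {
                "peak_mz": round(m.peak.mz, 4),
                "treatment": m.peak.treatment or "",
                "fraction": m.peak.fraction or "",
                "precursor": m.ion.parent.identifier,
                "ion_label": m.ion.label,
                "theoretical_mz": round(m.ion.mz, 4),
                "ppm_error": round(m.ppm_error, 2),
                "assigned": True,
            }
        )
    for p in report.unassigned:
        rows.append(
            {
                "peak_mz": round(p.mz, 4),
                "treatment": p.treatment or "",
                "fraction": p.fraction or "",
                "precursor": "",
                "ion_label": "",
                "theoretical_mz": float("nan"),
                "ppm_error": float("nan"),
                "assigned": False,
            }
        )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_report(report: IdentificationReport, path, fmt: str = "tsv") -> None:
    """Write a report as TSV or JSON-lines, preceded by provenance lines."""
    path = Path(path)
    cfg = {
        "tolerance_ppm": report.config.tolerance_ppm,
        "z_range": list(report.config.z_range),
        "k_range": list(report.config.k_range),
        "min_ions": report.config.min_ions,
        "require_base_ion": report.config.require_base_ion,
        "convention": report.config.convention,
    }
    df = report_frame(report)
    with path.open("w") as fh:
        for line in provenance_lines(cfg):
            fh.write(line + "\n")
        if fmt == "tsv":
            df.to_csv(fh, sep="\t", index=False)
        elif fmt == "json-lines":
            fh.write(df.to_json(orient="records", lines=True) + "\n")
        else:
            raise ValueError(f"fmt must be 'tsv' or 'json-lines', got {fmt!r}")


def read_report(path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("# murkit"):
        return pd.read_csv(path, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t")
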