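"""CSV/JSON readers and writers.

All files are plain text.  Times in file headers and columns are minutes;
concentrations are molar with the unit embedded in the column name
(``conc_M``).  Every writer has a matching reader that round-trips the
in-memory objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, kinetics, spectra
from .errors import ConfigurationError
from .units import seconds_to_minutes

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_series",
    "read_series",
    "write_trajectory",
    "read_trajectory",
    "write_timecourses",
    "read_timecourses",
    "write_peak_table",
    "read_peak_table",
    "reports_to_frame",
    "write_report",
    "read_report",
]

TIMECOURSE_COLUMNS = ["time_min", "intensity", "label", "state", "isomer", "direction"]


# -- spectra ----------------------------------------------------------------

def write_spectrum(path: str | Path, spectrum: spectra.Spectrum) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# time_min={spectrum.time:.6g}\n")
        fh.write("ppm,intensity\n")
        for p, i in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{p:.10g},{i:.10g}\n")


def read_spectrum(path: str | Path) -> spectra.Spectrum:
    path = Path(path)
    time = 0.0
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# time_min="):
            time = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if list(df.columns) != ["ppm", "intensity"]:
        raise ConfigurationError(f"{path}: expected columns ppm,intensity, got {list(df.columns)}")
    return spectra.Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), time=time)


def write_series(out_dir: str | Path, series: list[spectra.Spectrum]) -> Path:
    """Write a spectra series plus its manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, spec in enumerate(series):
        name = f"spectrum_{j:04d}.csv"
        write_spectrum(out_dir / name, spec)
        rows.append({"file": name, "time_min": spec.time})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_series(manifest_path: str | Path) -> list[spectra.Spectrum]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    for col in ("file", "time_min"):
        if col not in df.columns:
            raise ConfigurationError(f"{manifest_path}: manifest is missing column {col!r}")
    series = []
    for _, row in df.iterrows():
        spec = read_spectrum(manifest_path.parent / row["file"])
        spec.time = float(row["time_min"])
        series.append(spec)
    return series


# -- trajectories -----------------------------------------------------------

def write_trajectory(path: str | Path, trajectory: list[kinetics.SystemState]) -> None:
    """Long-format CSV: time_min,state,isomer,species,conc_M."""
    rows = []
    for st in trajectory:
        t_min = seconds_to_minutes(st.time)
        for (tag, label), sc in st.species.items():
            for species_name in ("hexa", "penta", "bound"):
                rows.append(
                    {
                        "time_min": t_min,
                        "state": tag,
                        "isomer": label,
                        "species": species_name,
                        "conc_M": getattr(sc, species_name),
                    }
                )
        rows.append(
            {"time_min": t_min, "state": "", "isomer": "", "species": "ligand_free",
             "conc_M": st.ligand_free}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    expected = ["time_min", "state", "isomer", "species", "conc_M"]
    if list(df.columns) != expected:
        raise ConfigurationError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


# -- time courses -----------------------------------------------------------

def write_timecourses(path: str | Path, tcs: list[fitting.TimeCourse]) -> None:
    rows = []
    for tc in tcs:
        for t, i in zip(tc.times, tc.intensities):
            rows.append(
                {"time_min": t, "intensity": i, "label": tc.label,
                 "state": tc.state, "isomer": tc.isomer, "direction": tc.direction}
            )
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False)


def read_timecourses(path: str | Path) -> list[fitting.TimeCourse]:
    df = pd.read_csv(path)
    for col in TIMECOURSE_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    out = []
    for (label, state, isomer, direction), grp in df.groupby(
        ["label", "state", "isomer", "direction"], sort=False
    ):
        grp = grp.sort_values("time_min")
        out.append(
            fitting.TimeCourse(
                times=grp["time_min"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                direction=str(direction),
                label=str(label),
                state=str(state),
                isomer=str(isomer),
            )
        )
    return out


# -- peak tables ------------------------------------------------------------

def write_peak_table(path: str | Path, peaks: list[spectra.PeakDef]) -> None:
    pd.DataFrame(
        [
            {"label": p.label, "shift_ppm": p.shift, "fwhm_ppm": p.fwhm,
             "species_tag": p.species_tag, "response": p.response}
            for p in peaks
        ]
    ).to_csv(path, index=False)


def read_peak_table(path: str | Path) -> list[spectra.PeakDef]:
    df = pd.read_csv(path)
    expected = ["label", "shift_ppm", "fwhm_ppm", "species_tag", "response"]
    for col in expected:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: peak table is missing column {col!r}")
    return [
        spectra.PeakDef(
            label=str(r["label"]), shift=float(r["shift_ppm"]), fwhm=float(r["fwhm_ppm"]),
            species_tag=str(r["species_tag"]), response=float(r["response"]),
        )
        for _, r in df.iterrows()
    ]


# -- reports ----------------------------------------------------------------

def reports_to_frame(reports: list[fitting.BindingReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state": r.state,
                "isomer": r.isomer,
                "T_min": r.T,
                "k_obs_per_M_s": r.k_obs,
                "K_d_M": r.K_d if r.K_d is not None else np.nan,
                "k_off_per_s": r.k_off if r.k_off is not None else np.nan,
                "free_fraction_eq": (
                    r.free_fraction_eq if r.free_fraction_eq is not None else np.nan
                ),
                "mode": r.mode,
                "label": r.label,
                "notes": "; ".join(r.notes),
            }
            for r in reports
        ]
    )


def write_report(
    base: str | Path,
    reports: list[fitting.BindingReport],
    ratios: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Write ``<base>.csv`` and ``<base>.json`` (field-for-field identical)."""
    base = Path(base)
    frame = reports_to_frame(reports)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    frame.to_csv(csv_path, index=False)
    payload = {"reports": json.loads(frame.to_json(orient="records", double_precision=15))}
    if ratios is not None:
        ratios.to_csv(base.parent / f"{base.name}_ratios.csv", index=False)
        payload["ratios"] = json.loads(ratios.to_json(orient="records", double_precision=15))
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return csv_path, json_path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
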