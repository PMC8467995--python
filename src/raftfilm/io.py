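"""CSV dialects for isotherm, stability, ACV and impedance data.

All files are one-header-row, comma-separated, UTF-8.  Metadata travel in
``# key: value`` comment lines before the header:

* isotherm: ``area_A2,pressure_mN_m`` (+ ``# temperature_C: 21``)
* stability: ``time_s,pressure_mN_m``
* ACV: ``potential_V,i_in_A_cm2,i_out_A_cm2`` with ``# frequency_Hz`` and
  ``# amplitude_V_rms``, or ``potential_V,capacitance_uF_cm2``;
  optional ``# anchor_potential_V`` / ``# anchor_sigma_uC_cm2``
* EIS: ``frequency_Hz,z_real_ohm_cm2,z_imag_ohm_cm2`` (capacitive Z'' < 0)
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ACVCurve, ImpedanceSpectrum, Isotherm, StabilityTrace
from .errors import InvalidInputError

__all__ = [
    "read_isotherm",
    "write_isotherm",
    "read_stability",
    "write_stability",
    "read_acv",
    "write_acv",
    "read_spectrum",
    "write_spectrum",
]


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, float | str] = {}
    text_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    value = value.strip()
                    try:
                        meta[key.strip()] = float(value)
                    except ValueError:
                        meta[key.strip()] = value
            else:
                text_lines.append(line)
    try:
        df = pd.read_csv(_io.StringIO("".join(text_lines)))
    except Exception as exc:  # malformed CSV
        raise InvalidInputError(f"{path}: cannot parse CSV ({exc})") from exc
    return df, meta


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_isotherm(path) -> Isotherm:
    df, meta = _read_csv_with_meta(path)
    _require_columns(df, ["area_A2", "pressure_mN_m"], path)
    return Isotherm(
        area=df["area_A2"].to_numpy(float),
        pressure=df["pressure_mN_m"].to_numpy(float),
        temperature=float(meta.get("temperature_C", 21.0)),
        label=str(meta.get("label", Path(path).stem)),
    )


def write_isotherm(iso: Isotherm, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# temperature_C: {iso.temperature:g}\n")
        if iso.label:
            fh.write(f"# label: {iso.label}\n")
        pd.DataFrame({"area_A2": iso.area, "pressure_mN_m": iso.pressure}).to_csv(
            fh, index=False
        )


def read_stability(path) -> StabilityTrace:
    df, _ = _read_csv_with_meta(path)
    _require_columns(df, ["time_s", "pressure_mN_m"], path)
    return StabilityTrace(
        time=df["time_s"].to_numpy(float), pressure=df["pressure_mN_m"].to_numpy(float)
    )


def write_stability(trace: StabilityTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "pressure_mN_m": trace.pressure}).to_csv(
        path, index=False
    )


def read_acv(path) -> ACVCurve:
    df, meta = _read_csv_with_meta(path)
    if "capacitance_uF_cm2" in df.columns:
        _require_columns(df, ["potential_V", "capacitance_uF_cm2"], path)
        curve = ACVCurve(
            potential=df["potential_V"].to_numpy(float),
            capacitance=df["capacitance_uF_cm2"].to_numpy(float),
            frequency=meta.get("frequency_Hz"),
            amplitude=meta.get("amplitude_V_rms"),
        )
    else:
        _require_columns(df, ["potential_V", "i_in_A_cm2", "i_out_A_cm2"], path)
        if "frequency_Hz" not in meta or "amplitude_V_rms" not in meta:
            raise InvalidInputError(
                f"{path}: current-mode ACV needs '# frequency_Hz' and '# amplitude_V_rms'"
            )
        curve = ACVCurve(
            potential=df["potential_V"].to_numpy(float),
            i_in=df["i_in_A_cm2"].to_numpy(float),
            i_out=df["i_out_A_cm2"].to_numpy(float),
            frequency=float(meta["frequency_Hz"]),
            amplitude=float(meta["amplitude_V_rms"]),
        )
    if "anchor_potential_V" in meta:
        curve.anchor_potential = float(meta["anchor_potential_V"])
        curve.anchor_sigma = float(meta.get("anchor_sigma_uC_cm2", 0.0))
    return curve


def write_acv(curve: ACVCurve, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if curve.frequency is not None:
            fh.write(f"# frequency_Hz: {curve.frequency:g}\n")
        if curve.amplitude is not None:
            fh.write(f"# amplitude_V_rms: {curve.amplitude:g}\n")
        if curve.anchor_potential is not None:
            fh.write(f"# anchor_potential_V: {curve.anchor_potential:.12g}\n")
            fh.write(f"# anchor_sigma_uC_cm2: {curve.anchor_sigma:.12g}\n")
        if curve.capacitance is not None:
            df = pd.DataFrame(
                {"potential_V": curve.potential, "capacitance_uF_cm2": curve.capacitance}
            )
        else:
            df = pd.DataFrame(
                {
                    "potential_V": curve.potential,
                    "i_in_A_cm2": curve.i_in,
                    "i_out_A_cm2": curve.i_out,
                }
            )
        df.to_csv(fh, index=False)


def read_spectrum(path) -> ImpedanceSpectrum:
    df, meta = _read_csv_with_meta(path)
    _require_columns(df, ["frequency_Hz", "z_real_ohm_cm2", "z_imag_ohm_cm2"], path)
    return ImpedanceSpectrum(
        frequency=df["frequency_Hz"].to_numpy(float),
        z_real=df["z_real_ohm_cm2"].to_numpy(float),
        z_imag=df["z_imag_ohm_cm2"].to_numpy(float),
        label=str(meta.get("label", Path(path).stem)),
    )


def write_spectrum(spec: ImpedanceSpectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if spec.label:
            fh.write(f"# label: {spec.label}\n")
        pd.DataFrame(
            {
                "frequency_Hz": spec.frequency,
                "z_real_ohm_cm2": spec.z_real,
                "z_imag_ohm_cm2": spec.z_imag,
            }
        ).to_csv(fh, index=False)


def validate_file(path, kind: str) -> list[str]:
    """Schema diagnostics for one file; empty list means the file is valid.

    ``kind``: isotherm | stability | acv | eis.  Diagnostics carry line
    numbers for non-numeric cells.
    """
    readers = {
        "isotherm": (read_isotherm, ["area_A2", "pressure_mN_m"]),
        "stability": (read_stability, ["time_s", "pressure_mN_m"]),
        "acv": (read_acv, None),
        "eis": (read_spectrum, ["frequency_Hz", "z_real_ohm_cm2", "z_imag_ohm_cm2"]),
    }
    if kind not in readers:
        return [f"unknown data kind '{kind}'"]
    problems: list[str] = []
    if not Path(path).exists():
        return [f"{path}: file not found"]
    try:
        df, _ = _read_csv_with_meta(path)
    except InvalidInputError as exc:
        return [str(exc)]
    reader, columns = readers[kind]
    if columns is not None:
        for c in columns:
            if c not in df.columns:
                problems.append(f"{path}: missing column '{c}'")
    if not problems:
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        for col in df.columns:
            for row in np.flatnonzero(bad[col].to_numpy()):
                # +2: one for the header row, one for 1-based numbering
                problems.append(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                    f"'{col}' at data line {row + 2}"
                )
    if not problems:
        try:
            reader(path)
        except Exception as exc:
            problems.append(f"{path}: {exc}")
    return problems
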