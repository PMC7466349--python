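"""Minimal JCAMP-DX 1D reader/writer.

Two dialects are emitted, both recorded in the file header:

* FIDs — ``##DATA CLASS= NTUPLES`` with two pages (real and imaginary
  components) in AFFN ``(X++(Y..Y))`` tables, the convention of JCAMP-DX
  for NMR time-domain data;
* spectra — ``##DATA CLASS= XYDATA`` holding the real (absorption) trace on
  a ppm axis.

Acquisition settings travel in ``##$`` private labels so a round trip
restores a working :class:`~arsqnmr.spin_sim.FID` or
:class:`~arsqnmr.nmr_processing.Spectrum`; the processing log is serialised
into ``##$PROCESSING`` comment lines and, optionally, a sidecar CSV.
Amplitudes are written in AFFN (plain decimal) form at 10 significant
digits, so round-trip error is far below format-quantization concerns.

Only 1D data are supported: files declaring more dimensions raise
:class:`~arsqnmr.errors.UnsupportedDimensionError`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import JcampParseError, UnsupportedDimensionError
from .nmr_processing import Spectrum
from .spin_sim import FID, AcquisitionParams, SampleSpec

__all__ = ["write_jcamp", "read_jcamp", "write_manifest", "read_manifest",
           "write_processing_log"]

_PARAM_LABELS = {
    "spectrometer_freq": "$SPECTROMETERFREQ",
    "sweep_width": "$SWEEPWIDTH",
    "td_points": "$TDPOINTS",
    "acquisition_time": "$ACQUISITIONTIME",
    "relaxation_delay": "$RELAXATIONDELAY",
    "n_scans": "$NSCANS",
    "line_broadening_default": "$LINEBROADENING",
    "temperature": "$TEMPERATURE",
    "pulse_angle": "$PULSEANGLE",
    "center_ppm": "$CENTERPPM",
}

_VALUES_PER_LINE = 6


def _params_header(params: AcquisitionParams) -> list[str]:
    lines = []
    for attr, label in _PARAM_LABELS.items():
        lines.append(f"##{label}= {getattr(params, attr)!r}")
    return lines


def _params_from_header(head: dict[str, str]) -> AcquisitionParams:
    kwargs = {}
    for attr, label in _PARAM_LABELS.items():
        if label in head:
            raw = head[label]
            kwargs[attr] = int(raw) if attr in ("td_points", "n_scans") \
                else float(raw)
    kwargs["check_timing"] = False
    return AcquisitionParams(**kwargs)


def _format_table(x: np.ndarray, y: np.ndarray) -> list[str]:
    lines = []
    for i in range(0, y.size, _VALUES_PER_LINE):
        chunk = y[i:i + _VALUES_PER_LINE]
        vals = " ".join(f"{v:.10g}" for v in chunk)
        lines.append(f"{x[i]:.10g} {vals}")
    return lines


def _log_header(log) -> list[str]:
    return [f"##$PROCESSING= {json.dumps(entry)}" for entry in log or ()]


def write_jcamp(path: str | Path, obj: FID | Spectrum,
                title: str = "arsqnmr synthetic data") -> Path:
    """Write a FID or Spectrum to a JCAMP-DX 1D file."""
    path = Path(path)
    lines = [f"##TITLE= {title}",
             "##JCAMP-DX= 5.01",
             "##ORIGIN= arsqnmr",
             "##OWNER= arsqnmr",
             "##NUM DIM= 1"]
    if isinstance(obj, FID):
        lines += ["##DATA TYPE= NMR FID",
                  "##DATA CLASS= NTUPLES",
                  f"##.OBSERVE FREQUENCY= {obj.params.spectrometer_freq}"]
        lines += _params_header(obj.params)
        lines += _log_header(obj.processing_log)
        lines += [f"##$PROVENANCE= {obj.provenance}"]
        t = obj.time_axis()
        n = obj.data.size
        lines += ["##NTUPLES= NMR FID",
                  "##VAR_NAME= TIME, FID/REAL, FID/IMAG",
                  "##UNITS= SECONDS, ARBITRARY UNITS, ARBITRARY UNITS",
                  f"##VAR_DIM= {n}, {n}, {n}"]
        for page, comp in (("1", obj.data.real), ("2", obj.data.imag)):
            lines += [f"##PAGE= N={page}",
                      f"##NPOINTS= {n}",
                      "##DATA TABLE= (X++(Y..Y)), XYDATA"]
            lines += _format_table(t, comp)
        lines += ["##END NTUPLES= NMR FID"]
    elif isinstance(obj, Spectrum):
        lines += ["##DATA TYPE= NMR SPECTRUM",
                  "##DATA CLASS= XYDATA",
                  f"##.OBSERVE FREQUENCY= {obj.params.spectrometer_freq}",
                  "##XUNITS= PPM",
                  "##YUNITS= ARBITRARY UNITS"]
        lines += _params_header(obj.params)
        lines += _log_header(obj.processing_log)
        lines += [f"##FIRSTX= {obj.ppm[0]:.10g}",
                  f"##LASTX= {obj.ppm[-1]:.10g}",
                  f"##NPOINTS= {obj.ppm.size}",
                  "##XFACTOR= 1",
                  "##YFACTOR= 1",
                  "##XYDATA= (X++(Y..Y))"]
        lines += _format_table(obj.ppm, obj.real)
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    lines += ["##END="]
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_header_line(line: str, lineno: int) -> tuple[str, str]:
    body = line[2:]
    if "=" not in body:
        raise JcampParseError(f"line {lineno}: malformed label {line!r}")
    key, _, value = body.partition("=")
    return key.strip(), value.strip()


def read_jcamp(path: str | Path) -> FID | Spectrum:
    """Read a 1D JCAMP-DX file written by :func:`write_jcamp`.

    Also accepts plain ``XYDATA`` spectra from other sources as long as the
    observe frequency is present.  Raises
    :class:`~arsqnmr.errors.UnsupportedDimensionError` for multi-dimensional
    files and :class:`~arsqnmr.errors.JcampParseError` (with line context)
    for malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head: dict[str, str] = {}
    log: list[dict] = []
    tables: list[list[float]] = []
    current: list[float] | None = None
    in_data = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, value = _parse_header_line(line, lineno)
            in_data = False
            if key == "$PROCESSING":
                try:
                    log.append(json.loads(value))
                except json.JSONDecodeError as e:
                    raise JcampParseError(
                        f"line {lineno}: bad processing-log entry") from e
            elif key in ("XYDATA", "DATA TABLE"):
                current = []
                tables.append(current)
                in_data = True
            else:
                head[key] = value
            continue
        if in_data and current is not None:
            try:
                values = [float(tok) for tok in line.replace(",", " ").split()]
            except ValueError as e:
                raise JcampParseError(
                    f"line {lineno}: non-numeric data {line!r}") from e
            current.extend(values[1:])   # first token is the abscissa
        elif line:
            raise JcampParseError(f"line {lineno}: unexpected content {line!r}")

    ndim = head.get("NUM DIM") or head.get("NUMDIM") or "1"
    try:
        ndim_i = int(ndim)
    except ValueError:
        raise JcampParseError(f"unreadable NUM DIM value {ndim!r}") from None
    if ndim_i != 1:
        raise UnsupportedDimensionError(
            f"{ndim_i}-dimensional data not supported (only 1D)")

    data_type = head.get("DATA TYPE", "").upper()
    params = _params_from_header(head)

    if "FID" in data_type:
        if len(tables) != 2:
            raise JcampParseError(
                f"FID file must hold 2 data tables (real, imag), "
                f"found {len(tables)}")
        real, imag = (np.asarray(t) for t in tables)
        if real.size != imag.size:
            raise JcampParseError("real/imaginary tables differ in length")
        return FID(real + 1j * imag, params,
                   provenance=head.get("$PROVENANCE", ""),
                   processing_log=tuple(log))

    if not tables:
        raise JcampParseError("no data table found")
    y = np.asarray(tables[0])
    try:
        first = float(head["FIRSTX"])
        last = float(head["LASTX"])
        npoints = int(head["NPOINTS"])
    except KeyError as e:
        raise JcampParseError(f"missing required label ##{e.args[0]}=") from e
    if y.size != npoints:
        raise JcampParseError(
            f"NPOINTS={npoints} but data table holds {y.size} values")
    ppm = np.linspace(first, last, npoints)
    return Spectrum(y, np.zeros_like(y), ppm, params, tuple(log))


# ---------------------------------------------------------------------------
# manifests and sidecars
# ---------------------------------------------------------------------------

def write_manifest(path: str | Path, samples: list[SampleSpec]) -> Path:
    """SampleSpec manifest as CSV (one row per sample)."""
    path = Path(path)
    rows = [{
        "matrix_name": s.matrix_name,
        "ars_mg_per_kg": s.ars_mg_per_kg,
        "sample_mass_mg": s.sample_mass,
        "is_mass_mg": s.is_mass,
        "is_solution_volume_ml": s.is_solution_volume,
        "extraction_efficiency": s.extraction_efficiency,
        "extraction_cycles": s.extraction_cycles,
        "seed": s.seed,
    } for s in samples]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> list[SampleSpec]:
    df = pd.read_csv(path)
    return [SampleSpec(matrix_name=r.matrix_name,
                       ars_mg_per_kg=float(r.ars_mg_per_kg),
                       seed=int(r.seed),
                       sample_mass=float(r.sample_mass_mg),
                       is_mass=float(r.is_mass_mg),
                       is_solution_volume=float(r.is_solution_volume_ml),
                       extraction_efficiency=float(r.extraction_efficiency),
                       extraction_cycles=int(r.extraction_cycles))
            for r in df.itertuples()]


def write_processing_log(path: str | Path, obj: FID | Spectrum) -> Path:
    """Sidecar CSV of the processing log (step name + JSON parameters)."""
    path = Path(path)
    rows = [{"order": i, "step": e.get("step", "?"),
             "parameters": json.dumps({k: v for k, v in e.items()
                                       if k != "step"})}
            for i, e in enumerate(obj.processing_log, start=1)]
    pd.DataFrame(rows, columns=["order", "step", "parameters"]).to_csv(
        path, index=False)
    return path
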