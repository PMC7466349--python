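"""Flat key=value run configuration.

Every constant defaults to the published method value; any override found in
a config file or on the command line is echoed into the provenance block so
no run can silently deviate from the standard protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from . import constants as c
from .errors import ValidationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # acquisition
    spectrometer_freq: float = c.SPECTROMETER_FREQ_MHZ
    sweep_width: float = c.SWEEP_WIDTH_HZ
    td_points: int = c.TD_POINTS
    relaxation_delay: float = c.RELAXATION_DELAY_S
    n_scans: int = c.N_SCANS
    # processing
    line_broadening: float = c.LINE_BROADENING_HZ
    zero_fill_factor: int = 2
    baseline_degree: int = 3
    # quantification constants
    is_mmol: float = c.IS_MMOL_PRINTED
    mw_avg: float = c.MW_AVG
    sample_mass: float = c.SAMPLE_MASS_MG
    ars_window_center: float = c.ARS_SHIFT_PPM
    is_window_center: float = c.IS_SHIFT_PPM
    window_half_width: float = c.WINDOW_HALF_WIDTH_PPM
    # thresholds
    lod_snr: float = c.LOD_SNR
    loq_snr: float = c.LOQ_SNR
    # simulation
    noise_sigma: float = c.DEFAULT_NOISE_SIGMA
    seed: int = 0
    overrides: dict = field(default_factory=dict, repr=False)

    _INT_FIELDS = {"td_points", "n_scans", "zero_fill_factor",
                   "baseline_degree", "seed"}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse ``key = value`` lines; ``#`` starts a comment."""
        cfg = cls()
        known = {f.name for f in fields(cls)} - {"overrides"}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
            cfg.set(key, value.strip())
        return cfg

    def set(self, key: str, value) -> None:
        """Set one field from a string or number, recording the override."""
        cast = int if key in self._INT_FIELDS else float
        value = cast(value)
        if value != getattr(self, key):
            self.overrides[key] = value
        setattr(self, key, value)

    def provenance_block(self) -> list[str]:
        lines = ["# run configuration (method defaults unless noted)"]
        for f in fields(self):
            if f.name == "overrides":
                continue
            mark = "  # OVERRIDDEN" if f.name in self.overrides else ""
            lines.append(f"{f.name} = {getattr(self, f.name)}{mark}")
        return lines
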