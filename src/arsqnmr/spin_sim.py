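"""Synthetic sample generator: extraction model and FID synthesis.

Emulates the wet-lab side of the assay — ultrasonic DMSO-d6 extraction of a
flour sample spiked with a syringaldehyde internal standard, followed by a
single-pulse 1H acquisition — so that the processing and quantification
stages can be exercised without an instrument.

The spin model is deliberately simple: each resonance is an exponentially
decaying complex sinusoid (a Lorentzian line after Fourier transform) whose
amplitude is proportional to ``n_protons * amount * saturation``, with the
steady-state saturation factor ``1 - exp(-(d1 + aq)/T1)`` of a 90-degree
pulse train.  Scans accumulate coherently while per-scan white Gaussian
noise accumulates as sqrt(n_scans), reproducing the usual signal-averaging
gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from . import constants as c
from .errors import EfficiencyError, SweepWindowError, ValidationError

__all__ = [
    "AcquisitionParams",
    "Resonance",
    "SampleSpec",
    "FID",
    "ExtractionResult",
    "extract",
    "amount_from_concentration",
    "saturation_factor",
    "synthesize_fid",
    "ars_resonance",
    "is_resonance",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Single-pulse acquisition settings.

    ``td_points`` counts real+imaginary points (instrument convention), so
    the stored complex FID has ``td_points / 2`` entries and
    ``acquisition_time = td_points / (2 * sweep_width)``.
    """

    spectrometer_freq: float = c.SPECTROMETER_FREQ_MHZ   # MHz
    sweep_width: float = c.SWEEP_WIDTH_HZ                # Hz
    td_points: int = c.TD_POINTS                         # real + imaginary
    acquisition_time: float = c.ACQUISITION_TIME_S       # s
    relaxation_delay: float = c.RELAXATION_DELAY_S       # s
    n_scans: int = c.N_SCANS
    line_broadening_default: float = c.LINE_BROADENING_HZ  # Hz
    temperature: float = c.TEMPERATURE_K                 # K
    pulse_angle: float = c.PULSE_ANGLE_DEG               # degrees
    center_ppm: float = c.CENTER_PPM                     # mid-sweep reference
    check_timing: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sweep_width <= 0:
            raise ValidationError("sweep_width must be positive")
        if self.n_scans < 1:
            raise ValidationError("n_scans must be >= 1")
        if self.td_points < 2 or self.td_points % 2:
            raise ValidationError("td_points must be an even count >= 2")
        if self.check_timing:
            implied = self.td_points / (2.0 * self.sweep_width)
            if abs(implied - self.acquisition_time) > 0.01 * implied:
                raise ValidationError(
                    f"acquisition_time {self.acquisition_time:.4f} s is not "
                    f"td/(2*sweep) = {implied:.4f} s within 1%"
                )

    @property
    def n_complex(self) -> int:
        return self.td_points // 2

    @property
    def dwell_time(self) -> float:
        """Complex dwell time in seconds."""
        return 1.0 / self.sweep_width

    @property
    def fid_resolution(self) -> float:
        """Digital resolution of the raw FID in Hz (1 / acquisition time)."""
        return 1.0 / self.acquisition_time

    @property
    def sweep_ppm(self) -> float:
        return self.sweep_width / self.spectrometer_freq

    def ppm_bounds(self) -> tuple[float, float]:
        """(high, low) ppm extent of the acquired window."""
        half = self.sweep_ppm / 2.0
        return (self.center_ppm + half, self.center_ppm - half)


@dataclass(frozen=True)
class Resonance:
    """One simulated line: a singlet at ``shift`` ppm from ``amount`` mmol of
    a species contributing ``n_protons`` equivalent protons."""

    shift: float                 # ppm
    n_protons: int
    amount: float                # mmol in the detected volume
    t2: float = c.T2_DEFAULT_S   # s
    t1: float = c.T1_ARS_S       # s
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ValidationError("n_protons must be >= 1")
        if self.amount < 0:
            raise ValidationError("amount must be >= 0")
        if not (self.t1 >= self.t2 > 0):
            raise ValidationError("relaxation times must satisfy t1 >= t2 > 0")


def ars_resonance(amount_mmol: float, *, t1: float = c.T1_ARS_S,
                  t2: float = c.T2_DEFAULT_S) -> Resonance:
    """Aromatic H-2,4,6 singlet of total 5-alkylresorcinols at 6.00 ppm."""
    return Resonance(c.ARS_SHIFT_PPM, c.ARS_N_PROTONS, amount_mmol,
                     t2=t2, t1=t1, label="ARS")


def is_resonance(amount_mmol: float = c.IS_MMOL_PRINTED, *,
                 t1: float = c.T1_IS_S,
                 t2: float = c.T2_DEFAULT_S) -> Resonance:
    """Syringaldehyde aldehyde proton at 9.79 ppm (internal standard)."""
    return Resonance(c.IS_SHIFT_PPM, c.IS_N_PROTONS, amount_mmol,
                     t2=t2, t1=t1, label="IS")


@dataclass(frozen=True)
class SampleSpec:
    """A synthetic flour/grain/product sample.

    ``ars_mg_per_kg`` is the concentration the method reports, i.e. what one
    standard extraction delivers to the NMR tube; the per-cycle extraction
    model is used by the recovery study, where the nominal amount plays the
    role of the exhaustively extractable pool.
    """

    matrix_name: str
    ars_mg_per_kg: float
    seed: int
    sample_mass: float = c.SAMPLE_MASS_MG           # mg
    is_mass: float = c.IS_MASS_MG                   # mg
    is_solution_volume: float = c.IS_SOLUTION_VOLUME_ML  # mL
    extraction_efficiency: float = c.DEFAULT_EXTRACTION_EFFICIENCY
    extraction_cycles: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.extraction_efficiency <= 1.0):
            raise EfficiencyError(
                f"extraction_efficiency must be in (0, 1], got "
                f"{self.extraction_efficiency}"
            )
        if self.sample_mass <= 0:
            raise ValidationError("sample_mass must be positive")
        if self.ars_mg_per_kg < 0:
            raise ValidationError("ars_mg_per_kg must be >= 0")
        if self.extraction_cycles < 1:
            raise ValidationError("extraction_cycles must be >= 1")

    @property
    def is_mmol(self) -> float:
        """Moles of internal standard actually weighed in (exact MW)."""
        return self.is_mass * self.is_solution_volume / c.SYRINGALDEHYDE_MW


@dataclass(frozen=True)
class FID:
    """Complex free induction decay plus the settings that produced it."""

    data: np.ndarray
    params: AcquisitionParams
    provenance: str = ""
    processing_log: tuple = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.complex128)
        object.__setattr__(self, "data", data)
        if data.ndim != 1:
            raise ValidationError("FID data must be one-dimensional")
        if data.size != self.params.n_complex:
            raise ValidationError(
                f"FID length {data.size} != td_points/2 = "
                f"{self.params.n_complex}"
            )
        if not np.all(np.isfinite(data)):
            raise ValidationError("FID contains non-finite values")

    def with_data(self, data: np.ndarray, *, params: AcquisitionParams | None = None,
                  log_entry: dict | None = None) -> "FID":
        log = self.processing_log + ((log_entry,) if log_entry else ())
        return FID(data, params or self.params, self.provenance, log)

    def time_axis(self) -> np.ndarray:
        return np.arange(self.data.size) * self.params.dwell_time


class ExtractionResult(NamedTuple):
    recovered_mmol: float
    remaining_mmol: float
    fraction: float


def amount_from_concentration(sample: SampleSpec,
                              mw_avg: float = c.MW_AVG) -> float:
    """Moles (mmol) of alkylresorcinols in the analysed portion.

    mmol = (mg/Kg * sample_mass_mg * 1e-6) / MW, with MW the C19/C21
    average molecular weight (390 g/mol by default).
    """
    if mw_avg <= 0:
        raise ValidationError("mw_avg must be positive")
    return sample.ars_mg_per_kg * sample.sample_mass * 1e-6 / mw_avg


def extract(sample: SampleSpec, cycle: int,
            mw_avg: float = c.MW_AVG) -> ExtractionResult:
    """Amount recovered in extraction cycle ``cycle`` under a single-pool model.

    Cycle k removes a fraction ``eff * (1 - eff)**(k-1)`` of the total pool,
    so cumulative recovery converges geometrically to 1.
    """
    if cycle < 1:
        raise ValidationError("cycle must be >= 1")
    eff = sample.extraction_efficiency
    total = amount_from_concentration(sample, mw_avg)
    fraction = eff * (1.0 - eff) ** (cycle - 1)
    remaining = total * (1.0 - eff) ** cycle
    return ExtractionResult(total * fraction, remaining, fraction)


def saturation_factor(t1: float, relaxation_delay: float,
                      acquisition_time: float) -> float:
    """Steady-state fractional magnetization recovered between 90-degree
    pulses separated by ``relaxation_delay + acquisition_time``."""
    return 1.0 - np.exp(-(relaxation_delay + acquisition_time) / t1)


def synthesize_fid(resonances: Sequence[Resonance],
                   params: AcquisitionParams | None = None,
                   noise_sigma: float = 0.0,
                   seed: int = 0,
                   provenance: str = "") -> FID:
    """Simulate a scan-accumulated FID for a set of singlet resonances.

    Each resonance contributes, per scan,
    ``n_protons * amount * (1 - exp(-(d1+aq)/t1))`` units of transverse
    magnetization precessing at the offset implied by its chemical shift and
    decaying with its T2.  Independent complex Gaussian noise of standard
    deviation ``noise_sigma`` (per real/imaginary component, per point) is
    added for every scan before summation, so the spectral signal-to-noise
    ratio grows as sqrt(n_scans).  Deterministic for a fixed seed.
    """
    params = params or AcquisitionParams()
    n = params.n_complex
    t = np.arange(n) * params.dwell_time
    high, low = params.ppm_bounds()

    signal = np.zeros(n, dtype=np.complex128)
    for r in resonances:
        if not (low <= r.shift <= high):
            raise SweepWindowError(
                f"resonance {r.label or r.shift} at {r.shift} ppm lies "
                f"outside the sweep window [{low:.2f}, {high:.2f}] ppm"
            )
        offset_hz = (r.shift - params.center_ppm) * params.spectrometer_freq
        amp = r.n_protons * r.amount * saturation_factor(
            r.t1, params.relaxation_delay, params.acquisition_time)
        signal += amp * np.exp((2j * np.pi * offset_hz - 1.0 / r.t2) * t)

    data = params.n_scans * signal
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        for _ in range(params.n_scans):
            data = data + rng.normal(0.0, noise_sigma, n) \
                        + 1j * rng.normal(0.0, noise_sigma, n)
    return FID(data, params, provenance=provenance or f"seed={seed}")


def resonances_to_params_window(params: AcquisitionParams) -> tuple[float, float]:
    """Convenience: the (high, low) ppm window a resonance must fall in."""
    return params.ppm_bounds()


def replace_params(params: AcquisitionParams, **kwargs) -> AcquisitionParams:
    """dataclasses.replace that tolerates timing-breaking edits (used by
    zero-filling, which changes td_points without changing acquisition time)."""
    kwargs.setdefault("check_timing", False)
    return replace(params, **kwargs)
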