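"""Sample presets: flours, grains and processed products.

Each preset carries the reported total-alkylresorcinol content (mg/Kg dry
material) and, where published, the matching mmol/Kg value.  Two rows are
flagged ``conversion_consistent=False``: their printed mg/Kg and mmol/Kg
columns do not agree with the 390 g/mol average molecular weight (one
implies an MW near 367, the other sits on a rounding-direction edge); they
are kept as-is and excluded from exact unit-conversion checks.

An ``adversarial`` preset adds a matrix peak at 6.3 ppm, just outside the
alkylresorcinol integration window, to exercise window discipline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownPresetError
from .spin_sim import SampleSpec

__all__ = ["MatrixPreset", "PRESETS", "get_preset", "make_sample",
           "preset_names"]


@dataclass(frozen=True)
class MatrixPreset:
    name: str
    description: str
    mg_per_kg: float                   # 0.0 encodes "not detected"
    printed_mmol_per_kg: float | None  # None for ND rows
    category: str                      # flour | grain | product | synthetic
    conversion_consistent: bool = True
    adversarial: bool = False          # extra matrix peak at 6.3 ppm

    @property
    def detected(self) -> bool:
        return self.mg_per_kg > 0.0


_ROWS = [
    # flours
    MatrixPreset("t_monococcum_wholegrain", "T. monococcum, whole-grain flour",
                 638.0, 1.64, "flour"),
    MatrixPreset("secale_cereale_wholegrain", "Secale cereale, whole-grain flour",
                 574.0, 1.47, "flour"),
    MatrixPreset("t_dicoccum_wholegrain", "T. dicoccum, whole-grain flour",
                 510.0, 1.31, "flour"),
    MatrixPreset("t_durum_wholegrain", "T. durum, whole-grain flour",
                 191.0, 0.49, "flour"),
    MatrixPreset("t_aestivum_wholegrain", "T. aestivum, whole-grain flour",
                 121.0, 0.33, "flour", conversion_consistent=False),
    MatrixPreset("t_turgidum_wholegrain", "T. turgidum, whole-grain flour",
                 63.0, 0.16, "flour"),
    MatrixPreset("t_aestivum_white", "T. aestivum, white flour",
                 0.0, None, "flour"),
    # wheat grains
    MatrixPreset("t_dicoccum_grain", "T. dicoccum grain",
                 1148.0, 2.95, "grain", conversion_consistent=False),
    MatrixPreset("t_monococcum_grain", "T. monococcum grain",
                 925.0, 2.37, "grain"),
    MatrixPreset("t_aestivum_grain", "T. aestivum grain",
                 255.0, 0.65, "grain"),
    MatrixPreset("t_durum_deveta_grain", "T. durum grain (cv. deveta)",
                 255.0, 0.65, "grain"),
    MatrixPreset("t_durum_dourouki_grain", "T. durum grain (cv. dourouki)",
                 191.0, 0.49, "grain"),
    # processed products
    MatrixPreset("t_dicoccum_bread", "T. dicoccum bread from whole-grain flour",
                 455.0, 1.17, "product"),
    MatrixPreset("t_dicoccum_flakes", "T. dicoccum flakes",
                 1090.0, 2.79, "product"),
    MatrixPreset("t_dicoccum_wafers", "T. dicoccum wafers",
                 351.0, 0.90, "product"),
    MatrixPreset("t_dicoccum_pasta", "T. dicoccum pasta",
                 330.0, 0.85, "product"),
    MatrixPreset("t_monococcum_flakes", "T. monococcum flakes",
                 1084.0, 2.78, "product"),
    MatrixPreset("t_aestivum_white_bread", "T. aestivum bread from white flour",
                 0.0, None, "product"),
    # synthetic stress test
    MatrixPreset("adversarial", "whole-grain-like matrix with an extra peak "
                 "at 6.3 ppm bordering the ARS window",
                 638.0, None, "synthetic", conversion_consistent=False,
                 adversarial=True),
]

PRESETS: dict[str, MatrixPreset] = {p.name: p for p in _ROWS}


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str) -> MatrixPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(PRESETS)) from None


def make_sample(name: str, seed: int, **overrides) -> SampleSpec:
    """Build a :class:`SampleSpec` from a preset name."""
    p = get_preset(name)
    kwargs = dict(matrix_name=p.name, ars_mg_per_kg=p.mg_per_kg, seed=seed)
    kwargs.update(overrides)
    return SampleSpec(**kwargs)
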