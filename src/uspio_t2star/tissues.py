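"""Normal-value tables and acquisition defaults.

R2* normal values (s^-1, mean +/- SD) for healthy volunteers before and
24 h after ferumoxytol (4 mg Fe/kg), at 1.5 T and 3 T.  The per-tissue
entries drive the synthetic cohort generator: pre-contrast R2* and the
pre->post change are the generative quantities; post-contrast values are
always pre + change per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default multi-gradient-echo scheme: 8 echoes evenly spaced 2.1-17.1 ms
DEFAULT_ECHO_TIMES_MS: tuple[float, ...] = tuple(np.linspace(2.1, 17.1, 8).round(10))

#: r-squared gate below which a pixel decay fit is discarded
DEFAULT_R2_GATE: float = 0.85

#: minimum echoes for a fit to be considered valid
DEFAULT_MIN_ECHOES: int = 4

#: ferumoxytol dose, mg Fe per kg body weight (metadata only)
DEFAULT_DOSE_MG_PER_KG: float = 4.0

TISSUES: tuple[str, ...] = (
    "panmyocardium",
    "skeletal_muscle",
    "kidney",
    "liver",
    "spleen",
    "blood",
    "bone",
)


@dataclass(frozen=True)
class TissueParams:
    """Generative R2* parameters for one tissue at one field strength.

    Attributes
    ----------
    tissue_name:
        One of :data:`TISSUES`.
    r2star_pre_mean, r2star_pre_sd:
        Baseline R2* distribution, s^-1.
    dr2star_mean, dr2star_sd:
        Pre->post change distribution, s^-1.
    s0:
        Proton-density signal scale, arbitrary units.
    """

    tissue_name: str
    r2star_pre_mean: float
    r2star_pre_sd: float
    dr2star_mean: float
    dr2star_sd: float
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if self.tissue_name not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue_name!r}; expected one of {TISSUES}")
        if self.r2star_pre_mean <= 0:
            raise ValueError("r2star_pre_mean must be > 0")
        if self.r2star_pre_sd < 0 or self.dr2star_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")

    @property
    def r2star_post_mean(self) -> float:
        return self.r2star_pre_mean + self.dr2star_mean


def _params(field_strength: float, rows: dict[str, tuple[float, float, float, float]]
            ) -> dict[str, TissueParams]:
    return {
        name: TissueParams(name, pre_m, pre_sd, d_m, d_sd)
        for name, (pre_m, pre_sd, d_m, d_sd) in rows.items()
    }


# (pre mean, pre SD, change mean, change SD) in s^-1
NORMAL_VALUES: dict[float, dict[str, TissueParams]] = {
    1.5: _params(1.5, {
        "panmyocardium":   (33.5, 5.4, 26.5, 7.3),
        "skeletal_muscle": (34.7, 4.2, 10.2, 5.8),
        "kidney":          (16.6, 2.0, 64.6, 16.1),
        "liver":           (36.0, 7.2, 216.3, 32.6),
        "spleen":          (22.0, 7.7, 336.3, 60.3),
        "blood":           (11.3, 4.1, 84.7, 27.2),
        "bone":            (84.4, 29.2, 69.9, 79.9),
    }),
    3.0: _params(3.0, {
        "panmyocardium":   (46.9, 4.1, 37.2, 9.6),
        "skeletal_muscle": (55.5, 17.1, 4.3, 16.3),
        "kidney":          (43.5, 39.1, 71.8, 48.8),
        "liver":           (65.3, 21.2, 275.6, 69.9),
        "spleen":          (51.2, 21.1, 463.9, 136.7),
        "blood":           (18.8, 5.3, 72.6, 18.3),
        "bone":            (330.0, 168.7, 417.9, 370.3),
    }),
}

#: cohort BMI (kg/m^2) defaults, near the study groups' medians
DEFAULT_BMI_MEAN: float = 24.5
DEFAULT_BMI_SD: float = 3.5
#: observed correlation between BMI and panmyocardial delta-R2*
DEFAULT_BMI_DR2STAR_CORR: float = 0.72


def normal_values(field_strength: float) -> dict[str, TissueParams]:
    """Per-tissue generative parameters for a field strength (1.5 or 3)."""
    key = float(field_strength)
    if key == 3:
        key = 3.0
    if key not in NORMAL_VALUES:
        raise ValueError(f"field_strength must be 1.5 or 3, got {field_strength}")
    return NORMAL_VALUES[key]
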