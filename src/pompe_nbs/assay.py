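"""GAA enzyme-activity computation from MRM ion abundances, and the fixed
screening cutoff.

Activity (µmol/L/h) from a dried-blood-spot (DBS) punch assayed by
flow-injection tandem mass spectrometry in multiple-reaction-monitoring
mode is

    activity = (P / IS) * [IS] * V_IS / RF / V_blood / t

where P and IS are the integrated ion abundances of reaction product and
internal standard, [IS] the internal-standard concentration (µmol/L), V_IS
its volume, RF the product/internal-standard response-factor ratio, V_blood
the blood volume assigned to the punch (3.1 µL for a 1/8-inch punch) and t
the incubation time in hours (nominally 18 ± 2).  P is assumed already
blank-corrected (blank filter-paper background subtracted upstream).

The program screens against a fixed activity cutoff of 2.10 µmol/L/h,
set at ~18% of the apparently-normal newborn mean activity; results
strictly below the cutoff are abnormal on either tier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

#: Blood volume (µL) assigned to a 1/8-inch DBS punch.
DBS_PUNCH_VOLUME_UL = 3.1

#: Fixed GAA activity cutoff, µmol/L/h.
DEFAULT_CUTOFF = 2.10

#: The cutoff as a fraction of the apparently-normal newborn mean activity.
DEFAULT_NORMAL_MEAN_FRACTION = 0.18


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class MRMReading:
    """One multiple-reaction-monitoring readout for the GAA reaction.

    Units: abundances are ion counts, ``internal_standard_concentration``
    µmol/L, volumes µL (``internal_standard_volume`` and ``blood_volume``
    must share units), ``incubation_time`` hours.
    """

    product_abundance: float
    internal_standard_abundance: float
    internal_standard_concentration: float
    internal_standard_volume: float
    response_factor: float
    incubation_time: float = 18.0
    blood_volume: float = DBS_PUNCH_VOLUME_UL

    def __post_init__(self) -> None:
        if not math.isfinite(self.product_abundance) or self.product_abundance < 0:
            raise DomainError(
                f"product_abundance must be finite and >= 0, got {self.product_abundance!r}"
            )
        _require_positive(
            internal_standard_abundance=self.internal_standard_abundance,
            internal_standard_concentration=self.internal_standard_concentration,
            internal_standard_volume=self.internal_standard_volume,
            response_factor=self.response_factor,
            incubation_time=self.incubation_time,
            blood_volume=self.blood_volume,
        )


@dataclass(frozen=True)
class CutoffConfig:
    """Screening cutoff configuration (both tiers use the same cutoff)."""

    gaa_cutoff: float = DEFAULT_CUTOFF
    normal_mean_fraction: float = DEFAULT_NORMAL_MEAN_FRACTION

    def __post_init__(self) -> None:
        if not math.isfinite(self.gaa_cutoff) or self.gaa_cutoff <= 0:
            raise DomainError(f"gaa_cutoff must be > 0, got {self.gaa_cutoff!r}")
        if not 0 < self.normal_mean_fraction < 1:
            raise DomainError(
                f"normal_mean_fraction must lie in (0, 1), got {self.normal_mean_fraction!r}"
            )

    @property
    def implied_normal_mean(self) -> float:
        """Apparently-normal newborn mean activity implied by the cutoff."""
        return self.gaa_cutoff / self.normal_mean_fraction


def compute_activity(r: MRMReading) -> float:
    """Enzyme activity in µmol/L/h from one MRM reading.

    Linear in product abundance; homogeneous of degree −1 in each of the
    response factor, incubation time and blood volume.
    """
    ratio = r.product_abundance / r.internal_standard_abundance
    return (
        ratio
        * r.internal_standard_concentration
        * r.internal_standard_volume
        / r.response_factor
        / r.blood_volume
        / r.incubation_time
    )


def derive_cutoff(normal_mean: float, fraction: float = DEFAULT_NORMAL_MEAN_FRACTION) -> float:
    """Cutoff implied by a normal-population mean activity and a fraction."""
    if not math.isfinite(normal_mean) or normal_mean <= 0:
        raise DomainError(f"normal_mean must be > 0, got {normal_mean!r}")
    if not 0 < fraction < 1:
        raise DomainError(f"fraction must lie in (0, 1), got {fraction!r}")
    return normal_mean * fraction


def below_cutoff(activity: float, cfg: CutoffConfig | None = None) -> bool:
    """True iff the activity is strictly below the screening cutoff.

    An activity exactly at the cutoff is screen-negative on both tiers.
    """
    cfg = cfg or CutoffConfig()
    if not math.isfinite(activity) or activity < 0:
        raise DomainError(f"activity must be finite and >= 0, got {activity!r}")
    return activity < cfg.gaa_cutoff
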