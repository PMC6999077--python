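"""Closed-form acquisition-geometry and optics quantities.

The scan protocol of the imaging system is fully determined by a handful of
constants (A-scan rate, samples per B-scan, flyback time, field of view,
wavelength, beam telescope).  The functions here derive the quantities a
reader would check against a system description: the B-scan repetition
period that sets the angiography time delay, the beam diameter delivered to
the pupil by the de-magnifying telescope, the diffraction-limited lateral
spot size in the eye, and the en-face pixel pitches.

All functions are pure; units are stated in each name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TelescopeSpec",
    "ScanProtocol",
    "MOUSE_RETINA_PROTOCOL",
    "REFOCUS_TELESCOPE",
    "bscan_period_ms",
    "reduced_beam_diameter_mm",
    "theoretical_lateral_resolution_um",
    "pixel_pitch_um",
    "protocol_report",
]


@dataclass(frozen=True)
class TelescopeSpec:
    """Two-lens beam-reduction telescope in front of the eye."""

    input_beam_diameter_mm: float
    focal_length_1_mm: float
    focal_length_2_mm: float

    def __post_init__(self) -> None:
        for name in ("input_beam_diameter_mm", "focal_length_1_mm", "focal_length_2_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class ScanProtocol:
    """Raster-scan timing and geometry constants.

    ``flyback_time_s`` is the slow-axis scanner return time added to each
    B-scan period.  ``eye_focal_length_mm`` is the focal length of the eye
    being imaged (≈2.6 mm for the mouse).
    """

    ascan_rate_hz: float
    n_ascans_per_bscan: int
    n_bscan_locations: int
    n_repeats: int
    flyback_time_s: float
    fov_x_mm: float
    fov_y_mm: float
    center_wavelength_nm: float
    eye_focal_length_mm: float

    def __post_init__(self) -> None:
        positive = (
            "ascan_rate_hz",
            "n_ascans_per_bscan",
            "n_bscan_locations",
            "n_repeats",
            "fov_x_mm",
            "fov_y_mm",
            "center_wavelength_nm",
            "eye_focal_length_mm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.flyback_time_s < 0:
            raise ValueError("flyback_time_s must be non-negative")


#: 840-nm mouse-retina raster protocol: 512 A-scans per B-scan at 83 kHz,
#: 5 repeats at each of 400 slow-axis locations over a 1 mm x 1 mm field.
MOUSE_RETINA_PROTOCOL = ScanProtocol(
    ascan_rate_hz=83_000.0,
    n_ascans_per_bscan=512,
    n_bscan_locations=400,
    n_repeats=5,
    flyback_time_s=1.5e-3,
    fov_x_mm=1.0,
    fov_y_mm=1.0,
    center_wavelength_nm=840.0,
    eye_focal_length_mm=2.6,
)

#: 80 mm / 50 mm achromat pair reducing a 0.8 mm collimated beam.
REFOCUS_TELESCOPE = TelescopeSpec(
    input_beam_diameter_mm=0.8,
    focal_length_1_mm=80.0,
    focal_length_2_mm=50.0,
)


def bscan_period_ms(protocol: ScanProtocol) -> float:
    """Time from the start of one B-scan to the start of the next, in ms.

    Acquisition time (A-scans / rate) plus scanner flyback.  This interval is
    the inter-scan time delay that produces angiographic motion contrast.
    """
    if protocol.ascan_rate_hz <= 0:
        raise ValueError("ascan_rate_hz must be positive")
    return 1e3 * (protocol.n_ascans_per_bscan / protocol.ascan_rate_hz + protocol.flyback_time_s)


def reduced_beam_diameter_mm(telescope: TelescopeSpec) -> float:
    """Beam diameter after the reduction telescope: d_in * f2 / f1 (mm)."""
    if telescope.input_beam_diameter_mm <= 0:
        raise ValueError("input beam diameter must be positive")
    return telescope.input_beam_diameter_mm * (
        telescope.focal_length_2_mm / telescope.focal_length_1_mm
    )


def theoretical_lateral_resolution_um(
    protocol: ScanProtocol, beam_diameter_mm: float
) -> float:
    """Gaussian 1/e^2 focal-spot diameter 4*lambda*f/(pi*d), in um.

    ``beam_diameter_mm`` is the (reduced) beam diameter incident on the
    pupil; aberrations are neglected.
    """
    if beam_diameter_mm <= 0:
        raise ValueError("beam diameter must be positive")
    lam_mm = protocol.center_wavelength_nm * 1e-6
    spot_mm = 4.0 * lam_mm * protocol.eye_focal_length_mm / (math.pi * beam_diameter_mm)
    return spot_mm * 1e3


def pixel_pitch_um(protocol: ScanProtocol) -> tuple[float, float]:
    """En-face sampling pitch (x_pitch, y_pitch) in um: fov / sample count."""
    if protocol.n_ascans_per_bscan <= 0 or protocol.n_bscan_locations <= 0:
        raise ValueError("sample counts must be positive")
    return (
        1e3 * protocol.fov_x_mm / protocol.n_ascans_per_bscan,
        1e3 * protocol.fov_y_mm / protocol.n_bscan_locations,
    )


def protocol_report(
    protocol: ScanProtocol = MOUSE_RETINA_PROTOCOL,
    telescope: TelescopeSpec = REFOCUS_TELESCOPE,
) -> dict[str, float]:
    """All derived protocol quantities as a flat name -> value mapping."""
    d = reduced_beam_diameter_mm(telescope)
    px, py = pixel_pitch_um(protocol)
    return {
        "bscan_period_ms": bscan_period_ms(protocol),
        "reduced_beam_diameter_mm": d,
        "theoretical_lateral_resolution_um": theoretical_lateral_resolution_um(protocol, d),
        "x_pixel_pitch_um": px,
        "y_pixel_pitch_um": py,
    }
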