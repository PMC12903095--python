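"""Acquisition parameters shared by the simulator and the inference stages.

Fast SMT with stroboscopic HILO illumination is modelled as instantaneous
point sampling of each molecule every ``dt`` seconds, with an isotropic
Gaussian localization error of ``sigma_loc`` per axis and detection restricted
to an axial slab of depth ``dz`` (molecules outside the slab are not seen).
Track length is photobleaching-limited with ``mean_track_len`` localizations
on average before axial losses.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging parameters of a fast-SMT acquisition.

    Parameters
    ----------
    dt:
        Frame interval in seconds.
    sigma_loc:
        Localization error (1D, per axis) in micrometers.
    dz:
        Axial detection depth (HILO slab thickness) in micrometers.
    pixel_size:
        Camera pixel size in micrometers per pixel.
    mean_track_len:
        Expected number of localizations per trajectory before axial losses
        (photobleaching-limited).
    """

    dt: float = 0.01
    sigma_loc: float = 0.035
    dz: float = 0.7
    pixel_size: float = 0.11
    mean_track_len: float = 4.0

    def __post_init__(self) -> None:
        for name in ("dt", "sigma_loc", "dz", "pixel_size", "mean_track_len"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"AcquisitionParams.{name} must be strictly positive, got {value!r}")
        if self.mean_track_len < 2:
            raise ValueError(
                f"AcquisitionParams.mean_track_len must be >= 2, got {self.mean_track_len!r}"
            )

    @property
    def bleach_survival(self) -> float:
        """Per-frame survival probability of the geometric track-length model."""
        return 1.0 - 1.0 / self.mean_track_len
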