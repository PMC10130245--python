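"""Imaging-system configurations.

A :class:`SystemConfig` bundles the reconstruction geometry (field of view,
matrix, slice thickness), the dose level (CTDI_vol), and the two free
image-quality parameters of the desk-scale degradation model: an in-plane
Gaussian point-spread-function FWHM and a quantum-noise standard deviation
in HU at the 9-mGy reference dose.

Four presets describe a silicon photon-counting prototype (``si_pcct``) and
a conventional energy-integrating scanner (``eidct``), each reconstructed at
150-mm and 50-mm FOV.  The PSF width is treated as a detector-system
property (it does not change with reconstruction FOV): the photon-counting
system is modelled at twice its native 150-mm-FOV pixel size (0.292 mm
FWHM) and the energy-integrating system at twice its own (0.586 mm FWHM).
Neither scanner's MTF is published, so both values are overridable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidParameterError, PresetLookupError

#: Dose at which ``noise_sd_hu`` is specified; noise scales as 1/sqrt(dose).
REFERENCE_CTDI_MGY = 9.0


def pixel_size(fov_mm: float, matrix_n: int) -> float:
    """In-plane pixel size (mm) of a reconstruction: FOV divided by matrix.

    Parameters
    ----------
    fov_mm
        Reconstruction field of view along one axis, in mm.  Must be > 0.
    matrix_n
        Number of pixels along that axis.  Must be a positive integer.
    """
    if not math.isfinite(fov_mm) or fov_mm <= 0:
        raise InvalidParameterError(f"fov_mm must be positive, got {fov_mm!r}")
    if int(matrix_n) != matrix_n or matrix_n < 1:
        raise InvalidParameterError(f"matrix_n must be a positive integer, got {matrix_n!r}")
    return fov_mm / int(matrix_n)


@dataclass(frozen=True)
class SystemConfig:
    """One imaging system's geometry, dose and image-quality parameters.

    Lengths are in mm, dose in mGy, noise in HU.  ``pixel_mm`` is derived
    from ``fov_mm / matrix_n``; passing it explicitly is allowed (round-trip
    serialization) but it must agree with the derived value.
    """

    label: str
    fov_mm: float
    matrix_n: int
    slice_thickness_mm: float
    psf_fwhm_mm: float
    noise_sd_hu: float
    ctdi_vol_mgy: float
    focal_spot_mm: float = 0.0  # metadata only; folded into psf_fwhm_mm
    tube_kvp: float = 120.0  # metadata only
    metadata: dict = field(default_factory=dict, compare=False)
    pixel_mm: float = 0.0  # derived in __post_init__ if left at 0

    def __post_init__(self) -> None:
        derived = pixel_size(self.fov_mm, self.matrix_n)
        if self.pixel_mm:
            if not math.isclose(self.pixel_mm, derived, rel_tol=1e-9, abs_tol=1e-9):
                raise InvalidParameterError(
                    f"pixel_mm={self.pixel_mm} inconsistent with fov_mm/matrix_n={derived}"
                )
        else:
            object.__setattr__(self, "pixel_mm", derived)
        if self.matrix_n < 2:
            raise InvalidParameterError("matrix_n must be >= 2")
        for name in ("fov_mm", "slice_thickness_mm", "ctdi_vol_mgy"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {v!r}")
        for name in ("psf_fwhm_mm", "noise_sd_hu"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                # zero is allowed: it selects the noiseless / unblurred
                # idealization used for resolution sweeps
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")

    def effective_noise_sd(self) -> float:
        """Noise SD in HU at this configuration's dose.

        ``noise_sd_hu`` is defined at the 9-mGy reference; quantum noise
        scales with the inverse square root of dose.
        """
        return self.noise_sd_hu * math.sqrt(REFERENCE_CTDI_MGY / self.ctdi_vol_mgy)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "fov_mm": self.fov_mm,
            "matrix_n": self.matrix_n,
            "pixel_mm": self.pixel_mm,
            "slice_thickness_mm": self.slice_thickness_mm,
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "noise_sd_hu": self.noise_sd_hu,
            "ctdi_vol_mgy": self.ctdi_vol_mgy,
            "focal_spot_mm": self.focal_spot_mm,
            "tube_kvp": self.tube_kvp,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SystemConfig":
        d = dict(d)
        d.setdefault("metadata", {})
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write as YAML (``.yaml``/``.yml``) or JSON (anything else)."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SystemConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def with_overrides(self, **kwargs: Any) -> "SystemConfig":
        """Copy with selected fields replaced (e.g. psf_fwhm_mm, noise_sd_hu)."""
        if "pixel_mm" not in kwargs and ("fov_mm" in kwargs or "matrix_n" in kwargs):
            kwargs["pixel_mm"] = 0.0
        return replace(self, **kwargs)


def _preset_table() -> dict[str, SystemConfig]:
    common_si = dict(
        matrix_n=1024,
        slice_thickness_mm=0.42,
        psf_fwhm_mm=0.292,
        noise_sd_hu=25.0,
        ctdi_vol_mgy=8.9,
        focal_spot_mm=0.6,
        tube_kvp=120.0,
        metadata={
            "detector": "silicon photon-counting",
            "scan_mode": "helical",
            "pitch": 0.99,
            "bowtie_filter": "medium",
            "tube_current_ma": 255,
            "tube_rotation_s": 0.5,
            "z_coverage_mm": 40,
            "kernel": "bone + ASIR0",
        },
    )
    common_eid = dict(
        matrix_n=512,
        slice_thickness_mm=0.63,
        psf_fwhm_mm=0.586,
        noise_sd_hu=25.0,
        ctdi_vol_mgy=9.0,
        focal_spot_mm=1.2,
        tube_kvp=120.0,
        metadata={
            "detector": "gemstone scintillator (energy-integrating)",
            "scan_mode": "helical",
            "pitch": 0.98,
            "bowtie_filter": "head (medium body)",
            "tube_current_ma": 245,
            "tube_rotation_s": 0.5,
            "z_coverage_mm": 40,
            "kernel": "bone + ASIR0",
        },
    )
    return {
        "si_pcct_150": SystemConfig(label="si_pcct_150", fov_mm=150.0, **common_si),
        "si_pcct_50": SystemConfig(label="si_pcct_50", fov_mm=50.0, **common_si),
        "eidct_150": SystemConfig(label="eidct_150", fov_mm=150.0, **common_eid),
        "eidct_50": SystemConfig(label="eidct_50", fov_mm=50.0, **common_eid),
    }


PRESET_NAMES: tuple[str, ...] = ("si_pcct_150", "si_pcct_50", "eidct_150", "eidct_50")


def preset_config(name: str) -> SystemConfig:
    """Return one of the four study configurations by name.

    Valid names: ``si_pcct_150``, ``si_pcct_50``, ``eidct_150``, ``eidct_50``.
    """
    table = _preset_table()
    if name not in table:
        raise PresetLookupError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    return table[name]
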