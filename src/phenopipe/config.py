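"""Configuration for the phenotyping pipeline.

All tunable constants live here rather than being hard-coded in the stage
modules.  The camera calibration constants default to the values measured
for the imaging cabinet the pipeline was developed on; the temperature
response parameters ship wheat-like defaults that are clearly labelled as
implementer choices and should be set explicitly for production runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Reference temperature for thermal-time compensation, in Kelvin (20 degC).
T_REF_K = 293.15


@dataclass(frozen=True)
class CameraCalibration:
    """Pixel-to-mm conversion constants for the side and top cameras.

    ``side_coeff`` is the side-view pixel size (mm px^-1).  The top-view
    pixel size depends on plant height through the side-view centre of
    mass: ``top_coeff = top_slope * cm_pix + top_offset``.
    """

    side_coeff: float = 0.5156      # mm px^-1
    top_slope: float = 0.0001097    # mm px^-2
    top_offset: float = 0.2899      # mm px^-1

    def __post_init__(self) -> None:
        if not (self.side_coeff > 0 and self.top_slope > 0 and self.top_offset > 0):
            raise ValueError("camera calibration constants must be strictly positive")


@dataclass(frozen=True)
class TemperatureResponseParams:
    """Parameters of the temperature response F(T) used for thermal time.

    ``dHa`` (J mol^-1) is the enthalpy of activation and sets the curvature
    at low temperature; ``alpha`` (dimensionless, 3.5 for developmental
    processes) sets how sharply the rate declines above the optimum;
    ``T0`` (K) is the temperature of maximum rate; ``A`` is a trait scaling
    coefficient that cancels in every compensation ratio.  ``dHd`` is an
    optional distinct enthalpy for the high-temperature decline term; by
    default the same enthalpy is used in both exponents.
    """

    A: float = 1.0
    dHa: float = 73_000.0   # J mol^-1, implementer default for wheat-like tests
    alpha: float = 3.5      # fixed for developmental processes
    T0: float = 305.0       # K, implementer default
    dHd: float | None = None
    explicit: bool = False  # set True when values were supplied by the user

    def __post_init__(self) -> None:
        if self.dHa <= 0 or self.alpha <= 0 or self.A <= 0:
            raise ValueError("dHa, alpha and A must be strictly positive")
        if self.T0 <= 273.15:
            raise ValueError("T0 must be above 273.15 K")
        if not self.explicit:
            warnings.warn(
                "TemperatureResponseParams is using implementer defaults "
                "(dHa=73 kJ/mol, T0=305 K); set explicit values for production runs",
                stacklevel=2,
            )

    @property
    def dHd_effective(self) -> float:
        return self.dHa if self.dHd is None else self.dHd


@dataclass(frozen=True)
class SoilConfig:
    """Pot and soil constants used in the water balance.

    The platform pots hold ~3 kg of potting mix in 2.5 l pots; the dry-soil
    mass and pot tare are what the balance arithmetic needs.
    """

    tare_g: float = 200.0
    dry_soil_g: float = 2400.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Thermal-time window over which average traits are computed (d20)."""

    start: float = 35.0
    end: float = 50.0

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class PipelineConfig:
    """Top-level configuration driving a full pipeline run."""

    camera: CameraCalibration = field(default_factory=CameraCalibration)
    thermal: TemperatureResponseParams = field(
        default_factory=lambda: TemperatureResponseParams(explicit=True)
    )
    soil: SoilConfig = field(default_factory=SoilConfig)
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    # growth-fitting options
    growth_candidates: tuple[str, ...] = ("linear", "exponential", "logistic3")
    rgr_mode: str = "window_mean"        # or "midpoint"
    per_treatment_calibration: bool = False
    # pot-weight correction for plant growth: the treatment-population
    # mean modelled fresh weight (default), or each plant's own model
    plant_weight_correction: str = "population_mean"  # or "per_plant"
    # genetics options
    n_permutations: int = 1000
    alpha: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str) -> PipelineConfig:
    """Load a nested key-value YAML config, falling back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "camera" in raw:
        cfg.camera = CameraCalibration(**raw["camera"])
    if "thermal" in raw:
        cfg.thermal = TemperatureResponseParams(**{"explicit": True, **raw["thermal"]})
    if "soil" in raw:
        cfg.soil = SoilConfig(**raw["soil"])
    if "window" in raw:
        cfg.window = AnalysisWindow(**raw["window"])
    for key in (
        "growth_candidates",
        "rgr_mode",
        "per_treatment_calibration",
        "plant_weight_correction",
        "n_permutations",
        "alpha",
    ):
        if key in raw:
            setattr(cfg, key, raw[key])
    if isinstance(cfg.growth_candidates, list):
        cfg.growth_candidates = tuple(cfg.growth_candidates)
    return cfg


def dump_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
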