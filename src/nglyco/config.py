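"""Pipeline configuration: every stage threshold in one structured,
serializable place, with the conventional defaults of the processing
scheme (discovery S/N > 3, relative intensity > 0.1%, curation S/N > 9,
|ppm| < 20, QC score < 25%, presence > 50%, screening alpha = 0.05)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .extract import CurationThresholds, ExtractionParams
from .mccv import MccvConfig
from .sim import CohortDesign, InstrumentModel

__all__ = ["PipelineThresholds", "CalibrationSettings", "PipelineConfig"]


@dataclass(frozen=True)
class PipelineThresholds:
    snr_discovery: float = 3.0
    rel_int: float = 0.001
    ppm_match: float = 20.0
    snr_curation: float = 9.0
    ppm: float = 20.0
    qc: float = 0.25
    presence: float = 0.50
    presence_mode: str = "any"
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.presence <= 1:
            raise ValueError(f"presence threshold {self.presence} outside [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if not 0 <= self.rel_int < 1:
            raise ValueError(f"relative-intensity threshold {self.rel_int} outside [0, 1)")
        if min(self.snr_discovery, self.snr_curation, self.ppm, self.qc) < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.presence_mode not in ("any", "all"):
            raise ValueError("presence_mode must be 'any' or 'all'")


@dataclass(frozen=True)
class CalibrationSettings:
    degree: int = 2
    min_calibrants: int = 4
    ppm_window: float = 200.0
    snr_min: float = 3.0
    n_calibrants: int = 8
    max_failure_fraction: float = 0.20

    def validate(self) -> None:
        if self.min_calibrants < self.degree + 1:
            raise ValueError("min_calibrants must exceed the polynomial degree")


def _build(cls, data):
    if data is None:
        return cls()
    if isinstance(data, cls):
        return data
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("effects", "drift_ppm", "drift_jitter_ppm", "model_sizes"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run."""

    seed: int = 0
    cohorts: dict = field(default_factory=lambda: {
        "discovery": CohortDesign(label="discovery"),
        "validation": CohortDesign(n_untreated=18, n_treated=30, n_hc=40,
                                   label="validation"),
    })
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    extraction: ExtractionParams = field(default_factory=ExtractionParams)
    mccv: MccvConfig = field(default_factory=MccvConfig)
    target_source: str = "discovered"        # or "registry"
    registry_path: str | None = None
    trait_registry_path: str | None = None

    def validate(self) -> None:
        self.thresholds.validate()
        self.calibration.validate()
        if self.target_source not in ("discovered", "registry"):
            raise ValueError("target_source must be 'discovered' or 'registry'")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")

    @property
    def curation_thresholds(self) -> CurationThresholds:
        t = self.thresholds
        return CurationThresholds(snr=t.snr_curation, ppm=t.ppm, qc=t.qc,
                                  presence=t.presence)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        cohorts = {}
        for name, cd in (data.pop("cohorts", None) or {}).items():
            if isinstance(cd, dict):
                cd = dict(cd)
                cd.setdefault("label", name)
                cd.pop("covariates", None)  # nested covariate models: defaults only
                if "effects" in cd and cd["effects"] is not None:
                    from .sim import PlantedEffect
                    cd["effects"] = tuple(
                        e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                        for e in cd["effects"])
            cohorts[name] = _build(CohortDesign, cd)
        cfg = cls(
            seed=int(data.pop("seed", 0)),
            cohorts=cohorts or None,
            instrument=_build(InstrumentModel, data.pop("instrument", None)),
            thresholds=_build(PipelineThresholds, data.pop("thresholds", None)),
            calibration=_build(CalibrationSettings, data.pop("calibration", None)),
            extraction=_build(ExtractionParams, data.pop("extraction", None)),
            mccv=_build(MccvConfig, data.pop("mccv", None)),
            target_source=data.pop("target_source", "discovered"),
            registry_path=data.pop("registry_path", None),
            trait_registry_path=data.pop("trait_registry_path", None),
        )
        if data:
            raise ValueError(f"unknown config option(s): {sorted(data)}")
        if cfg.cohorts is None:
            cfg.cohorts = PipelineConfig().cohorts
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
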