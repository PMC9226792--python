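"""Study configuration: one structured object covering design, simulation,
ERP and statistics parameters, serializable to/from YAML.

A config round-trips load -> save -> load to an identical structure, and
every value is validated against the owning module's preconditions when the
object is built.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .simulate import (ComponentTemplate, ErpTemplateParams, RaceModelParams)
from .task_design import DesignParams

__all__ = ["ErpAnalysisParams", "StatsParams", "StudyConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class ErpAnalysisParams:
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    filter_low_hz: float = 0.1
    filter_high_hz: float = 45.0
    reject_threshold_uv: float = 100.0
    eog_corr_threshold: float = 0.8
    clean_blinks: bool = True

    def validate(self) -> None:
        if self.epoch_window_ms[0] >= self.epoch_window_ms[1]:
            raise ValueError("epoch window empty")
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ValueError("filter band must satisfy 0 < low < high")
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        if not 0 < self.eog_corr_threshold <= 1:
            raise ValueError("EOG correlation threshold outside (0, 1]")


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    equal_var_ttest: bool = True
    trial_factor: str = "condition"     # name of the within "trial type" factor

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")


@dataclass
class StudyConfig:
    design: DesignParams = field(default_factory=DesignParams)
    race_control: RaceModelParams = field(default_factory=RaceModelParams)
    race_vga: RaceModelParams | None = None
    erp_control: ErpTemplateParams = field(default_factory=ErpTemplateParams)
    erp_vga: ErpTemplateParams | None = None
    n_per_group: int = 30
    seed: int = 0
    with_eeg: bool = True
    erp_analysis: ErpAnalysisParams = field(default_factory=ErpAnalysisParams)
    stats: StatsParams = field(default_factory=StatsParams)

    def __post_init__(self) -> None:
        if self.race_vga is None:
            self.race_vga = self.race_control
        if self.erp_vga is None:
            self.erp_vga = self.erp_control
        self.validate()

    def validate(self) -> None:
        self.design.cell_counts()
        self.race_control.validate()
        self.race_vga.validate()
        self.erp_control.validate()
        self.erp_vga.validate()
        self.erp_analysis.validate()
        self.stats.validate()
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")

    def group_effects(self):
        return {"control": (self.race_control, self.erp_control),
                "vga": (self.race_vga, self.erp_vga)}


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _tpl(d: dict) -> ComponentTemplate:
    d = dict(d)
    d["scalp_weights"] = dict(d.get("scalp_weights", {}))
    return ComponentTemplate(**d)


def _erp_params(d: dict) -> ErpTemplateParams:
    d = dict(d)
    for k in ("p3cue", "p3go", "n2stop", "p3stop"):
        d[k] = _tpl(d[k])
    return ErpTemplateParams(**d)


def _design(d: dict) -> DesignParams:
    d = dict(d)
    d["ssd_grid_ms"] = tuple(d["ssd_grid_ms"])
    return DesignParams(**d)


def _pairs(d: dict | list) -> tuple[float, float]:
    return tuple(float(v) for v in d)  # type: ignore[return-value]


def config_to_dict(cfg: StudyConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(d: dict) -> StudyConfig:
    d = dict(d)
    erp_an = dict(d.get("erp_analysis", {}))
    for k in ("epoch_window_ms", "baseline_ms"):
        if k in erp_an:
            erp_an[k] = _pairs(erp_an[k])
    return StudyConfig(
        design=_design(d["design"]) if "design" in d else DesignParams(),
        race_control=RaceModelParams(**d.get("race_control", {})),
        race_vga=(RaceModelParams(**d["race_vga"])
                  if d.get("race_vga") else None),
        erp_control=(_erp_params(d["erp_control"])
                     if "erp_control" in d else ErpTemplateParams()),
        erp_vga=(_erp_params(d["erp_vga"]) if d.get("erp_vga") else None),
        n_per_group=int(d.get("n_per_group", 30)),
        seed=int(d.get("seed", 0)),
        with_eeg=bool(d.get("with_eeg", True)),
        erp_analysis=ErpAnalysisParams(**erp_an),
        stats=StatsParams(**d.get("stats", {})),
    )


def save_config(cfg: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=False))


def load_config(path) -> StudyConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
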