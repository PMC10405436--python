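"""Configuration objects for the synthetic scenario and the analysis pipeline.

Every threshold that drives a filtering or modelling rule lives here with its
default value, so a run is fully described by one :class:`PipelineConfig` (plus
a :class:`SimulationConfig` when the inputs are simulated).  Both objects
round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError


@dataclass
class MovementProposal:
    """Gamma step-length / von Mises turning-angle movement kernel.

    Defaults give a mean step of ~2.9 m per 20 s (~0.15 m/s over ground),
    with mild forward persistence.
    """

    gamma_shape: float = 3.0
    gamma_scale: float = 1.8  # m
    vm_mu: float = 0.0  # rad
    vm_kappa: float = 0.4

    def validate(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0 or self.vm_kappa <= 0:
            raise ConfigurationError("movement proposal parameters must be positive")


@dataclass
class DetectionModel:
    """Observation model degrading a true path into acoustic detections."""

    mean_interval_s: float = 1.2  # high-residency ping interval
    dropout_prob: float = 0.10
    noise_sd_m: float = 0.30  # isotropic positioning noise; site value unknown

    def validate(self) -> None:
        if self.mean_interval_s <= 0:
            raise ConfigurationError("mean_interval_s must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")
        if self.noise_sd_m < 0:
            raise ConfigurationError("noise_sd_m must be non-negative")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic river scenario.

    The hydraulic targets (mean depth 2.50 m, mean velocity 0.35 m/s at the
    reference discharge, 0.5 m cells, discharges 10..80 m3/s) emulate the
    summary statistics of the study reach; the functional forms of the depth
    and velocity fields are this package's own invention.
    """

    channel_length: float = 500.0  # m, flow along +x
    channel_width: float = 50.0  # m
    cell_size: float = 0.5  # m
    discharges: tuple = tuple(range(10, 90, 10))  # m3/s
    ref_discharge: float = 50.0
    target_mean_depth: float = 2.50  # m, over wetted cells at ref discharge
    target_mean_velocity: float = 0.35  # m/s, over wetted cells at ref discharge
    depth_discharge_exponent: float = 0.3
    velocity_discharge_exponent: float = 0.7
    cross_section_flatness: float = 0.3  # parabola exponent; <1 flattens the bed
    pool_rel_depth: float = 0.5  # scour pool amplitude relative to local depth
    pool_radius: float = 12.0  # m
    thalweg_amplitude: float = 9.0  # m, lateral meander of the velocity core
    thalweg_wavelength: float = 70.0  # m
    thalweg_width: float = 7.0  # m
    dune_wavelength: float = 9.0  # m, longitudinal depth undulation
    dune_rel_amplitude: float = 0.55
    ripple_wavelength: float = 8.0  # m, cross-channel velocity undulation
    ripple_rel_amplitude: float = 0.45
    flow_dir_amplitude: float = 12.0  # deg of lateral variation around downstream
    dry_depth: float = 0.20  # m, cells shallower than this are out of river

    pass_xy: tuple = (14.0, 25.0)  # m, fish-pass entrance
    release_xy: tuple = (470.0, 25.0)  # m

    proposal: MovementProposal = field(default_factory=MovementProposal)
    detection: DetectionModel = field(default_factory=DetectionModel)
    n_candidates: int = 50  # M, softmax candidates per simulated step
    max_retries: int = 20

    true_beta: dict = field(
        default_factory=lambda: {
            "WV (end)": 0.6,
            "D (end)": 0.4,
            "DiffVang (end)": 0.25,
            "log(SL)": 1.0,
            "log(SL):WV (start)": -0.5,
        }
    )
    approach_bias: float = 1.5  # migration drive toward the pass (not a model term)

    n_fish: int = 6
    species_cycle: tuple = ("barbel", "grayling")
    n_steps: int = 240  # 20 s steps per simulated approach track
    dt: float = 20.0  # s
    track_starts: dict = field(
        default_factory=lambda: {
            "barbel": "2018-05-10T09:00:00+00:00",
            "grayling": "2018-04-03T09:00:00+00:00",
        }
    )
    track_spacing_days: int = 1  # successive fish start on successive days

    site_lat: float = 47.80
    site_lon: float = 10.13
    timezone: str = "UTC"
    study_start: str = "2018-05-01"
    study_end: str = "2018-06-16"
    temp_base_c: float = 11.0
    temp_seasonal_amp_c: float = 3.0
    temp_diel_amp_c: float = 0.8

    seed: int = 20180501

    def validate(self) -> None:
        if self.channel_length <= 0 or self.channel_width <= 0:
            raise ConfigurationError("channel dimensions must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.n_candidates < 2:
            raise ConfigurationError("n_candidates (M) must be at least 2")
        self.proposal.validate()
        self.detection.validate()

    @property
    def n_rows(self) -> int:
        return int(round(self.channel_width / self.cell_size))

    @property
    def n_cols(self) -> int:
        return int(round(self.channel_length / self.cell_size))


@dataclass
class PipelineConfig:
    """All analysis-stage thresholds.

    The documented study rules appear here with their stated defaults:
    10 m trigger radius, 2 h refractory, 60 min window, >90% within 15 m
    loiter rejection, 30 min minimum span, 10 detections minimum, 20 s step,
    60 s gap split, 100 raw / 10 kept random steps, 2 steps/min, delta-AIC 2,
    95% CI and p < 0.05.
    """

    # approach extraction
    trigger_radius_m: float = 10.0
    refractory_h: float = 2.0
    window_min: float = 60.0
    loiter_frac: float = 0.90  # reject when MORE than this fraction is near-pass
    loiter_radius_m: float = 15.0
    min_span_min: float = 30.0
    min_detections: int = 10

    # regularization
    dt_s: float = 20.0
    gap_s: float = 60.0
    segment_min_detections: int = 10
    regularization_method: str = "ctcrw"  # or "linear"
    measurement_floor_m: float = 0.1

    # post filters (directedness defaults are declared, not taken from the study)
    near_pass_start_radius_m: float = 50.0
    directedness_min: float = 0.25
    min_start_distance_m: float = 50.0
    min_steps_per_min: float = 2.0
    season_cutoffs: dict = field(
        default_factory=lambda: {"barbel": "06-16", "grayling": "04-16"}
    )

    # random steps
    n_raw_steps: int = 100
    n_kept_steps: int = 10
    sl_floor_m: float = 1e-3
    kappa_max: float = 50.0
    distribution_scope: str = "fish"  # or "pooled"

    # modelling
    delta_aic: float = 2.0
    reference_tod: str = "day"
    separation_threshold: float = 15.0
    enforce_hierarchy: bool = False

    # population inference
    outlier_rule: str = "iqr"  # or "none"
    iqr_fences: float = 1.5
    ci_level: float = 0.95
    alpha: float = 0.05

    # context
    discharge: float = 50.0  # raster scenario used for covariates
    site_lat: float = 47.80
    site_lon: float = 10.13
    pass_xy: tuple = (14.0, 25.0)
    release_xy: tuple = (470.0, 25.0)
    seed: int = 1

    def validate(self) -> None:
        for name in ("trigger_radius_m", "window_min", "dt_s", "gap_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.pass_xy is None or len(tuple(self.pass_xy)) != 2:
            raise ConfigurationError("pass_xy (fish-pass entrance) is required")
        if not 0 < self.loiter_frac < 1:
            raise ConfigurationError("loiter_frac must lie in (0, 1)")
        if self.n_kept_steps > self.n_raw_steps:
            raise ConfigurationError("n_kept_steps cannot exceed n_raw_steps")
        if self.regularization_method not in ("ctcrw", "linear"):
            raise ConfigurationError("regularization_method must be ctcrw|linear")
        if self.outlier_rule not in ("iqr", "none"):
            raise ConfigurationError("outlier_rule must be iqr|none")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_yaml(config) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def _from_mapping(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(f"unknown {cls.__name__} field: {key}")
        if key == "proposal":
            value = MovementProposal(**value)
        elif key == "detection":
            value = DetectionModel(**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def simulation_config_from_yaml(text: str) -> SimulationConfig:
    cfg = _from_mapping(SimulationConfig, yaml.safe_load(text) or {})
    cfg.validate()
    return cfg


def pipeline_config_from_yaml(text: str) -> PipelineConfig:
    cfg = _from_mapping(PipelineConfig, yaml.safe_load(text) or {})
    cfg.validate()
    return cfg
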