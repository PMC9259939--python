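"""Validated configuration models for simulation and pipeline runs.

All knobs of the pipeline live here as pydantic models so that a YAML run
configuration is checked before any computation starts and every default is
explicit (they are all dumped into the run manifest).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

from .errors import ConfigError

#: Role names for channels in an image stack.
NUCLEUS_STAIN = "nucleus_stain"
TRANSCRIPT_PROBE = "transcript_probe"


class CountModel(BaseModel):
    """Per-cell transcript count distribution for one (cell type, channel).

    ``negative_binomial`` uses the (mean, dispersion) parameterisation with
    variance ``mean + mean**2 / dispersion``; Poisson is the
    dispersion -> infinity limit and takes only ``mean``.
    """

    model_config = ConfigDict(frozen=True)

    distribution: Literal["poisson", "negative_binomial"] = "negative_binomial"
    mean: float = Field(ge=0)
    dispersion: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CountModel":
        if self.distribution == "negative_binomial" and self.dispersion is None:
            raise ValueError("negative_binomial requires a dispersion")
        return self

    def frozen(self):
        """Return the scipy frozen distribution (degenerate at 0 if mean==0)."""
        if self.mean == 0:
            return sps.poisson(0.0)
        if self.distribution == "poisson":
            return sps.poisson(self.mean)
        k = self.dispersion
        p = k / (k + self.mean)
        return sps.nbinom(k, p)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.mean == 0:
            return np.zeros(size, dtype=np.int64)
        if self.distribution == "poisson":
            return rng.poisson(self.mean, size=size).astype(np.int64)
        k = self.dispersion
        p = k / (k + self.mean)
        return rng.negative_binomial(k, p, size=size).astype(np.int64)

    def prob_at_least(self, k: int) -> float:
        """P(count >= k) in closed form."""
        return float(self.frozen().sf(k - 1))


class Bleedthrough(BaseModel):
    """Linear leakage of a fraction of one channel's signal into another."""

    model_config = ConfigDict(frozen=True)

    src: str
    dst: str
    fraction: float = Field(ge=0.0, le=1.0)


def _default_count_model() -> dict:
    # Two cortical populations; the target transcript is enriched in the
    # inhibitory population, each population expresses its own marker highly
    # and the other marker at trace level.
    return {
        "glutamatergic": {
            "Gprc5b": CountModel(distribution="negative_binomial", mean=3.0, dispersion=2.0),
            "Slc17a7": CountModel(distribution="negative_binomial", mean=20.0, dispersion=5.0),
            "Gad1": CountModel(distribution="poisson", mean=0.1),
        },
        "GABAergic": {
            "Gprc5b": CountModel(distribution="negative_binomial", mean=8.0, dispersion=2.0),
            "Slc17a7": CountModel(distribution="poisson", mean=0.1),
            "Gad1": CountModel(distribution="negative_binomial", mean=20.0, dispersion=5.0),
        },
    }


class SimConfig(BaseModel):
    """Parameters of one simulated multiplex ISH field.

    Defaults emulate a confocal field of cortical tissue at 0.5 um/px with
    two neuronal populations (glutamatergic / GABAergic), marker probes and a
    target probe whose per-cell counts are negative-binomially distributed.
    """

    model_config = ConfigDict(frozen=True)

    field_size_px: tuple[int, int] = (288, 288)
    pixel_size_um: float = Field(default=0.5, gt=0)
    n_cells: int = Field(default=50, ge=0)
    type_proportions: dict[str, float] = Field(
        default_factory=lambda: {"glutamatergic": 0.5, "GABAergic": 0.5}
    )
    count_model: dict[str, dict[str, CountModel]] = Field(default_factory=_default_count_model)
    nucleus_radius_um: tuple[float, float] = (3.0, 0.3)  # (mean, sd)
    nucleus_amplitude: float = Field(default=120.0, ge=0)
    psf_sigma_px: float = Field(default=1.1, gt=0)
    dot_amplitude: float = Field(default=150.0, ge=0)
    background_level: float = Field(default=20.0, ge=0)
    noise_sd: float = Field(default=15.0, ge=0)
    bleedthrough: tuple[Bleedthrough, ...] = ()
    min_nucleus_separation_px: float = Field(default=16.0, ge=0)
    stray_dot_rate_per_mm2: float = Field(default=0.0, ge=0)
    mask_expansion_factor: float = Field(default=2.0, ge=1.0)
    nucleus_channel: str = "DAPI"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {total!r}, expected 1")
        if any(f < 0 for f in self.type_proportions.values()):
            raise ValueError("type_proportions must be non-negative")
        types = set(self.count_model)
        if types != set(self.type_proportions):
            raise ValueError(
                f"count_model types {sorted(types)} != proportions {sorted(self.type_proportions)}"
            )
        channel_sets = {frozenset(m) for m in self.count_model.values()}
        if len(channel_sets) > 1:
            raise ValueError("all cell types must define the same transcript channels")
        names = set(self.transcript_channels) | {self.nucleus_channel}
        for b in self.bleedthrough:
            if b.src not in names or b.dst not in names:
                raise ValueError(f"bleedthrough references unknown channel {b.src}->{b.dst}")
        if self.nucleus_radius_um[0] <= 0 or self.nucleus_radius_um[1] < 0:
            raise ValueError("nucleus_radius_um must be (mean>0, sd>=0)")
        return self

    @property
    def transcript_channels(self) -> list[str]:
        first = next(iter(self.count_model.values()), {})
        return sorted(first)

    @property
    def type_labels(self) -> list[str]:
        return sorted(self.type_proportions)

    @property
    def nucleus_radius_px(self) -> tuple[float, float]:
        m, s = self.nucleus_radius_um
        return (m / self.pixel_size_um, s / self.pixel_size_um)


class SegmentationParams(BaseModel):
    """Knobs of the DAPI nucleus segmentation recipe."""

    model_config = ConfigDict(frozen=True)

    smoothing_sigma_px: float = Field(default=1.5, ge=0)
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    threshold_value: Optional[float] = None
    min_nucleus_area_px: int = Field(default=40, ge=0)
    split_touching: bool = True
    min_seed_distance_px: float = Field(default=8.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SegmentationParams":
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold_method requires threshold_value")
        return self


class SpotDetectionParams(BaseModel):
    """Multiscale Laplacian-of-Gaussian blob detection parameters.

    ``threshold`` is an absolute cutoff on the scale-normalised LoG response
    (for a Gaussian dot of amplitude A detected at the matched scale the
    response peaks near A/2). When ``threshold`` is None the cutoff is set to
    ``threshold_sigma`` robust standard deviations (1.4826 * MAD) of the
    response, which adapts to the noise floor.
    """

    model_config = ConfigDict(frozen=True)

    sigma_min_px: float = Field(default=0.9, gt=0)
    sigma_max_px: float = Field(default=1.8, gt=0)
    n_scales: int = Field(default=3, ge=1)
    threshold: Optional[float] = Field(default=None, gt=0)
    threshold_sigma: float = Field(default=5.0, gt=0)
    min_separation_px: float = Field(default=1.0, ge=1.0)
    background_subtraction: Literal["none", "rolling_ball"] = "none"
    rolling_ball_radius_px: float = Field(default=10.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "SpotDetectionParams":
        if self.sigma_min_px > self.sigma_max_px:
            raise ValueError("sigma_min_px must be <= sigma_max_px")
        return self


class TypingRule(BaseModel):
    """One marker-channel -> cell-type rule (count or density threshold)."""

    model_config = ConfigDict(frozen=True)

    marker_channel: str
    type_label: str
    min_dots: int = Field(default=3, ge=1)
    min_density: Optional[float] = Field(default=None, gt=0)


DEFAULT_TYPING_RULES: tuple[TypingRule, ...] = (
    TypingRule(marker_channel="Slc17a7", type_label="glutamatergic"),
    TypingRule(marker_channel="Gad1", type_label="GABAergic"),
    TypingRule(marker_channel="Chat", type_label="cholinergic"),
)


class StudyConfig(BaseModel):
    """Sampling design of a simulated study: animals x sections x images.

    The default mirrors a typical design of four sections per animal with
    2-4 images per section.
    """

    model_config = ConfigDict(frozen=True)

    n_animals: int = Field(default=1, ge=1)
    sections_per_animal: int = Field(default=4, ge=1)
    images_per_section: int = Field(default=3, ge=1)
    sim: SimConfig = Field(default_factory=SimConfig)

    @property
    def n_images(self) -> int:
        return self.n_animals * self.sections_per_animal * self.images_per_section


class StatsOptions(BaseModel):
    model_config = ConfigDict(frozen=True)

    bin_width: float = Field(default=1.0, gt=0)
    exact_limit: int = Field(default=16, ge=2)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    score_mode: Literal["density", "count"] = "density"


class PositivityOptions(BaseModel):
    model_config = ConfigDict(frozen=True)

    target_channel: str = "Gprc5b"
    min_dots: int = Field(default=1, ge=1)


class ImageInput(BaseModel):
    """One on-disk image with its grouping identifiers."""

    model_config = ConfigDict(frozen=True)

    path: str
    animal_id: str = "A1"
    section_id: str = "S1"
    image_id: str = "I1"


class RunConfig(BaseModel):
    """Full pipeline run configuration (simulated or on-disk inputs)."""

    model_config = ConfigDict(frozen=True)

    study: Optional[StudyConfig] = None
    inputs: tuple[ImageInput, ...] = ()
    channel_names: tuple[str, ...] = ()  # order of pages for plain TIFF inputs
    nucleus_channel: str = "DAPI"
    pixel_size_um: Optional[float] = None
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    detection: SpotDetectionParams = Field(default_factory=SpotDetectionParams)
    detection_per_channel: dict[str, SpotDetectionParams] = Field(default_factory=dict)
    typing_rules: tuple[TypingRule, ...] = DEFAULT_TYPING_RULES
    positivity: PositivityOptions = Field(default_factory=PositivityOptions)
    stats: StatsOptions = Field(default_factory=StatsOptions)
    region_label: str = "region"
    population_a: str = "glutamatergic"
    population_b: str = "GABAergic"
    drop_edge_cells: bool = False
    make_plots: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.study is None and not self.inputs:
            raise ValueError("RunConfig needs either a simulation study or input images")
        if self.study is not None and self.inputs:
            raise ValueError("RunConfig cannot mix simulated and on-disk inputs")
        if self.study is not None:
            known = set(self.study.sim.transcript_channels)
            pos = self.positivity.target_channel
            if pos not in known:
                raise ValueError(f"positivity target channel {pos!r} not simulated ({sorted(known)})")
            usable = [r for r in self.typing_rules if r.marker_channel in known]
            labels = {r.type_label for r in usable}
            for pop in (self.population_a, self.population_b):
                if pop not in labels:
                    raise ValueError(f"population {pop!r} has no typing rule on a simulated channel")
        return self


def validate_config(obj: BaseModel) -> None:
    """Re-run a model's validators, raising :class:`ConfigError` on failure."""
    try:
        type(obj).model_validate(obj.model_dump())
    except Exception as exc:  # pydantic wraps everything in ValidationError
        raise ConfigError(str(exc)) from exc
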