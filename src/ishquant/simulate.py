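"""Synthetic multiplex fluorescent ISH fields with per-cell ground truth.

The generator produces what a single-molecule ISH experiment images: a DAPI
channel of stained nuclei plus one transcript channel per probe in which each
transcript appears as one diffraction-limited punctum. Per-cell transcript
counts are drawn from configurable negative-binomial (or Poisson) models per
cell type, dots are placed uniformly within the cytoplasmic disk that the
downstream mask expansion will reconstruct, and the field records full ground
truth (cell positions, types, true counts, dot positions) so every pipeline
stage can be scored against it.

Randomness is organised as per-stage substreams spawned from one integer
seed (placement, radii, types, counts, dots, stray dots, noise), so adding a
stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NUCLEUS_STAIN, TRANSCRIPT_PROBE, SimConfig, StudyConfig, validate_config
from .errors import ConfigError, PlacementError

_MAX_TRIES_PER_CELL = 2000


@dataclass(frozen=True)
class GroundTruthCell:
    """True position, size, type and per-channel transcript counts of one cell."""

    cell_id: int
    centroid_px: tuple[float, float]  # (row, col)
    nucleus_radius_px: float
    type_label: str
    true_counts: dict[str, int]


@dataclass
class GroundTruthField:
    """Simulated cells plus every dot's position and owning cell."""

    cells: list[GroundTruthCell]
    config: SimConfig
    #: per channel, list of (row, col, owner_cell_id or None for stray dots)
    dot_positions: dict[str, list[tuple[float, float, int | None]]] = field(default_factory=dict)

    def cells_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "cell_id": c.cell_id,
                "centroid_row": c.centroid_px[0],
                "centroid_col": c.centroid_px[1],
                "nucleus_radius_px": c.nucleus_radius_px,
                "type_label": c.type_label,
            }
            for ch, n in c.true_counts.items():
                row[f"true_count_{ch}"] = n
            rows.append(row)
        return pd.DataFrame(rows)

    def dots_dataframe(self) -> pd.DataFrame:
        rows = [
            {"channel": ch, "row": r, "col": c, "owner_cell_id": owner}
            for ch, dots in self.dot_positions.items()
            for (r, c, owner) in dots
        ]
        return pd.DataFrame(rows, columns=["channel", "row", "col", "owner_cell_id"])


@dataclass
class ImageStack:
    """Named-channel 2D intensity field with a physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    channel_roles: dict[str, str]
    probe_names: dict[str, str]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ConfigError(f"channel shapes differ: {shapes}")
        if NUCLEUS_STAIN not in self.channel_roles.values():
            raise ConfigError("an ImageStack needs at least one nucleus_stain channel")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def nucleus_channel(self) -> str:
        for name, role in self.channel_roles.items():
            if role == NUCLEUS_STAIN:
                return name
        raise ConfigError("no nucleus_stain channel")  # unreachable after __post_init__

    @property
    def transcript_channel_names(self) -> list[str]:
        return [n for n, r in self.channel_roles.items() if r == TRANSCRIPT_PROBE]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["placement", "radii", "types", "counts", "dots", "stray", "noise"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.Generator(np.random.PCG64(c)) for n, c in zip(names, children)}


def sample_ground_truth(config: SimConfig, seed: int | None = None) -> GroundTruthField:
    """Draw cell positions, radii, types, counts and dot positions.

    Nuclei are placed by rejection sampling at pairwise centre distance
    >= ``min_nucleus_separation_px``, with a per-cell margin from the field
    border large enough that the whole cytoplasmic placement disk
    (radius ``sqrt(mask_expansion_factor) * nucleus_radius``) stays inside
    the field. Dots of a cell are uniform within that disk.

    Raises
    ------
    PlacementError
        If a position cannot be found after a bounded number of retries,
        i.e. the requested density is infeasible.
    """
    validate_config(config)
    if seed is None:
        seed = config.seed
    rngs = _substreams(seed)
    n = config.n_cells
    rows, cols = config.field_size_px

    r_mean, r_sd = config.nucleus_radius_px
    radii = np.clip(rngs["radii"].normal(r_mean, r_sd, size=n), 0.3 * r_mean, 2.0 * r_mean)
    placement_radii = np.sqrt(config.mask_expansion_factor) * radii

    centroids = np.empty((n, 2), dtype=float)
    min_sep2 = config.min_nucleus_separation_px ** 2
    rng_p = rngs["placement"]
    for i in range(n):
        margin = placement_radii[i] + 1.5
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError(
                f"field {rows}x{cols} px too small for nucleus of placement radius "
                f"{placement_radii[i]:.1f} px"
            )
        for _ in range(_MAX_TRIES_PER_CELL):
            cand = margin + rng_p.random(2) * [rows - 2 * margin, cols - 2 * margin]
            if i == 0:
                centroids[i] = cand
                break
            d2 = np.sum((centroids[:i] - cand) ** 2, axis=1)
            if d2.min() >= min_sep2:
                centroids[i] = cand
                break
        else:
            density = n / (rows * cols * config.pixel_size_um ** 2 * 1e-6)
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} at separation "
                f"{config.min_nucleus_separation_px} px after {_MAX_TRIES_PER_CELL} tries "
                f"(requested density ~{density:.0f} cells/mm^2 is too high)"
            )

    labels = config.type_labels
    probs = np.array([config.type_proportions[t] for t in labels])
    types = rngs["types"].choice(labels, size=n, p=probs / probs.sum())

    channels = config.transcript_channels
    rng_c = rngs["counts"]
    counts = {ch: np.zeros(n, dtype=np.int64) for ch in channels}
    for t in labels:
        idx = np.flatnonzero(types == t)
        for ch in channels:
            counts[ch][idx] = config.count_model[t][ch].sample(rng_c, idx.size)

    cells = [
        GroundTruthCell(
            cell_id=i + 1,
            centroid_px=(float(centroids[i, 0]), float(centroids[i, 1])),
            nucleus_radius_px=float(radii[i]),
            type_label=str(types[i]),
            true_counts={ch: int(counts[ch][i]) for ch in channels},
        )
        for i in range(n)
    ]

    rng_d = rngs["dots"]
    dot_positions: dict[str, list[tuple[float, float, int | None]]] = {ch: [] for ch in channels}
    for i, cell in enumerate(cells):
        big_r = placement_radii[i]
        for ch in channels:
            k = cell.true_counts[ch]
            if k == 0:
                continue
            rr = big_r * np.sqrt(rng_d.random(k))
            theta = rng_d.random(k) * 2 * np.pi
            drow = centroids[i, 0] + rr * np.sin(theta)
            dcol = centroids[i, 1] + rr * np.cos(theta)
            dot_positions[ch].extend(
                (float(a), float(b), cell.cell_id) for a, b in zip(drow, dcol)
            )

    if config.stray_dot_rate_per_mm2 > 0:
        area_mm2 = rows * cols * (config.pixel_size_um * 1e-3) ** 2
        rng_s = rngs["stray"]
        for ch in channels:
            k = rng_s.poisson(config.stray_dot_rate_per_mm2 * area_mm2)
            pos = rng_s.random((k, 2)) * [rows, cols]
            dot_positions[ch].extend((float(a), float(b), None) for a, b in pos)

    return GroundTruthField(cells=cells, config=config, dot_positions=dot_positions)


def _render_nucleus(img: np.ndarray, centroid: tuple[float, float], radius: float,
                    amplitude: float, edge_sigma: float = 0.8) -> None:
    """Add one soft-edged nuclear blob (logistic radial falloff) in place."""
    rows, cols = img.shape
    ext = int(math.ceil(radius + 5 * edge_sigma))
    r0 = max(0, int(math.floor(centroid[0])) - ext)
    r1 = min(rows, int(math.ceil(centroid[0])) + ext + 1)
    c0 = max(0, int(math.floor(centroid[1])) - ext)
    c1 = min(cols, int(math.ceil(centroid[1])) + ext + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d = np.hypot(rr - centroid[0], cc - centroid[1])
    img[r0:r1, c0:c1] += amplitude / (1.0 + np.exp((d - radius) / edge_sigma))


def _render_dot(img: np.ndarray, pos: tuple[float, float], sigma: float, amplitude: float) -> None:
    """Add one isotropic Gaussian punctum in place."""
    rows, cols = img.shape
    ext = int(math.ceil(4 * sigma))
    r0 = max(0, int(math.floor(pos[0])) - ext)
    r1 = min(rows, int(math.ceil(pos[0])) + ext + 1)
    c0 = max(0, int(math.floor(pos[1])) - ext)
    c1 = min(cols, int(math.ceil(pos[1])) + ext + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = (rr - pos[0]) ** 2 + (cc - pos[1]) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2 * sigma ** 2))


def render_field(gt: GroundTruthField, seed: int | None = None) -> ImageStack:
    """Render a ground-truth field into a multi-channel image stack.

    Rendering order: clean nuclear blobs and Gaussian puncta, then linear
    bleed-through mixing of the clean channels, then additive background and
    Gaussian read noise, then clipping at zero.
    """
    config = gt.config
    if seed is None:
        seed = config.seed
    rng_noise = _substreams(seed)["noise"]
    shape = tuple(config.field_size_px)
    names = [config.nucleus_channel] + config.transcript_channels

    clean = {name: np.zeros(shape, dtype=np.float64) for name in names}
    for cell in gt.cells:
        _render_nucleus(clean[config.nucleus_channel], cell.centroid_px,
                        cell.nucleus_radius_px, config.nucleus_amplitude)
    for ch in config.transcript_channels:
        for (r, c, _owner) in gt.dot_positions.get(ch, []):
            _render_dot(clean[ch], (r, c), config.psf_sigma_px, config.dot_amplitude)

    mixed = {name: clean[name].copy() for name in names}
    for b in config.bleedthrough:
        mixed[b.dst] += b.fraction * clean[b.src]

    out: dict[str, np.ndarray] = {}
    for name in names:  # fixed order so the noise stream is reproducible
        img = mixed[name] + config.background_level
        if config.noise_sd > 0:
            img = img + rng_noise.normal(0.0, config.noise_sd, size=shape)
        out[name] = np.clip(img, 0.0, None).astype(np.float32)

    roles = {config.nucleus_channel: NUCLEUS_STAIN}
    roles.update({ch: TRANSCRIPT_PROBE for ch in config.transcript_channels})
    probes = {name: name for name in names}
    return ImageStack(channels=out, pixel_size_um=config.pixel_size_um,
                      channel_roles=roles, probe_names=probes)


def simulate_field(config: SimConfig, seed: int | None = None) -> tuple[ImageStack, GroundTruthField]:
    """Sample ground truth and render it; bit-identical for identical (config, seed)."""
    gt = sample_ground_truth(config, seed=seed)
    stack = render_field(gt, seed=seed)
    return stack, gt


def simulate_study(study: StudyConfig, seed: int | None = None):
    """Yield (ids, stack, ground truth) per image of an animal/section/image design.

    ``ids`` is a dict with keys ``animal_id``, ``section_id``, ``image_id``.
    Each image gets its own deterministic child seed, so the study is
    reproducible as a whole and per image.
    """
    if seed is None:
        seed = study.sim.seed
    ss = np.random.SeedSequence(seed)
    image_seeds = ss.generate_state(study.n_images) % (2 ** 31)
    k = 0
    for a in range(1, study.n_animals + 1):
        for s in range(1, study.sections_per_animal + 1):
            for i in range(1, study.images_per_section + 1):
                ids = {
                    "animal_id": f"A{a}",
                    "section_id": f"A{a}-S{s}",
                    "image_id": f"A{a}-S{s}-I{i}",
                }
                stack, gt = simulate_field(study.sim, seed=int(image_seeds[k]))
                k += 1
                yield ids, stack, gt


def paper_like_study(**sim_overrides) -> StudyConfig:
    """The default two-population study: 4 sections x 3 images, 50 cells each."""
    sim = SimConfig(**sim_overrides) if sim_overrides else SimConfig()
    return StudyConfig(n_animals=1, sections_per_animal=4, images_per_section=3, sim=sim)
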