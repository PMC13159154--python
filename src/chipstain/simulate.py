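"""Synthetic paired bright-field / fluorescence chip-image generator.

Real chip micrographs for this assay are not publicly deposited, so the
package ships a forward model with known ground truth: cells and aggregates
are placed in the gel-channel ROI, grow over days, and die under drug
following a 4PL viability curve; each population is rendered into a
bright-field image plus DAPI (all nuclei) and TRITC (dead cells) stains with
uneven-staining and detector-noise artifacts.

The bright-field render is a deterministic function of the cell layout
(dark membrane rims, interior shading that differs between live and dead
cells, mild deterministic texture), so the BF→fluorescence mapping exists
and is learnable; the fluorescence renders then serve as ground truth for
in-silico staining and for every downstream viability metric.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import ConfigurationError, SimConfig
from .imagecore import Channel, ChipImage

# split pattern cycled over chips: 7:2:1 train/val/test per block of 10
_SPLIT_PATTERN = (
    "train", "train", "train", "val", "train",
    "train", "test", "train", "val", "train",
)

_MAX_AGGREGATE_FRACTION = 0.8


def _derive_rng(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible stream keyed by seed + string/int context."""
    entropy = [int(seed)]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _hash01(i: np.ndarray, salt: float) -> np.ndarray:
    """Deterministic per-cell pseudo-random value in [0,1) (no RNG state)."""
    x = np.sin(np.asarray(i, dtype=np.float64) * 12.9898 + salt * 78.233) * 43758.5453
    return x - np.floor(x)


def four_pl_viability(dose: float | np.ndarray, config: SimConfig) -> float | np.ndarray:
    """Expected live fraction at a drug dose (µM) under the 4PL model.

    ``v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)``; at dose 0 the
    curve sits at ``top`` and decays to ``bottom`` at saturating dose.
    """
    dose = np.asarray(dose, dtype=np.float64)
    if np.any(dose < 0):
        raise ConfigurationError("dose must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / config.drug_ic50) ** config.drug_hill, 0.0)
    v = config.drug_bottom + (config.drug_top - config.drug_bottom) / (1.0 + ratio)
    return float(v) if v.ndim == 0 else v


@dataclass
class CellPopulation:
    """Ground-truth cells/aggregates of one chip at one timepoint.

    ``cells`` columns: x, y (px, 0-based pixel-centred, origin top-left),
    radius (px), live (bool), aggregate_id (int, -1 for singletons).
    """

    cells: pd.DataFrame
    chip_id: str = "chip"
    day: int = 0

    def __post_init__(self) -> None:
        required = {"x", "y", "radius", "live", "aggregate_id"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        if len(self.cells) and (self.cells["radius"] <= 0).any():
            raise ValueError("all radii must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def live_fraction(self) -> float:
        if not len(self.cells):
            return float("nan")
        return float(self.cells["live"].mean())

    def mean_radius(self) -> float:
        return float(self.cells["radius"].mean())


def generate_population(config: SimConfig, day: int, chip_id: str = "chip") -> CellPopulation:
    """Place cells for one chip at a culture day, with growth and clustering.

    The spatial layout and per-cell identities are drawn once per chip (from
    the config seed and chip id), so calls for successive days describe the
    same cells: radii scale by ``growth_rate**day``, an increasing fraction
    of cells is pulled into aggregates, and the baseline-dead subset is
    fixed. Deaths only accumulate (live→dead), never reverse.
    """
    if day < 0:
        raise ConfigurationError("day must be non-negative")
    n = config.seeding_density
    rng = _derive_rng(config.seed, chip_id, "layout")

    w, h = config.channel_width_px, config.channel_height_px
    margin = min(2.0 * config.base_radius_px, w / 4, h / 4)
    x = rng.uniform(margin, w - margin, size=n)
    y = rng.uniform(margin, h - margin, size=n)
    sigma = np.sqrt(np.log1p(config.radius_cv**2))
    radii = config.base_radius_px * np.exp(rng.normal(0.0, sigma, size=n) - sigma**2 / 2)
    baseline_u = rng.uniform(size=n)
    perm = rng.permutation(n)  # fixed recruitment order into aggregates
    cluster_sizes = 2 + rng.poisson(2.0, size=n)  # sizes of successive clusters

    radii = radii * config.growth_rate**day

    aggregate_id = np.full(n, -1, dtype=np.int64)
    frac = min(_MAX_AGGREGATE_FRACTION, config.aggregate_fraction_per_day * day)
    k = int(round(frac * n))
    if k >= 2:
        members = perm[:k]
        pos = 0
        agg = 0
        while pos < k:
            size = int(min(cluster_sizes[agg], k - pos))
            group = members[pos : pos + size]
            cx, cy = x[group[0]], y[group[0]]
            # sunflower packing around the cluster anchor
            j = np.arange(size, dtype=np.float64)
            spacing = 1.15 * float(np.mean(radii[group]))
            ang = j * 2.399963
            rad = spacing * np.sqrt(j)
            x[group] = np.clip(cx + rad * np.cos(ang), margin / 2, w - margin / 2)
            y[group] = np.clip(cy + rad * np.sin(ang), margin / 2, h - margin / 2)
            aggregate_id[group] = agg
            pos += size
            agg += 1

    live = baseline_u >= config.baseline_death_fraction
    cells = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "radius": radii,
            "live": live,
            "aggregate_id": aggregate_id,
        }
    )
    return CellPopulation(cells=cells, chip_id=chip_id, day=day)


def apply_drug(
    pop: CellPopulation, dose: float, config: SimConfig, seed: int
) -> CellPopulation:
    """Kill live cells independently with probability ``1 - v(dose)``.

    ``v`` is the 4PL viability curve, so the expected live fraction among
    previously live cells equals ``v(dose)``. Dead cells stay dead.
    """
    if dose < 0:
        raise ConfigurationError("dose must be non-negative")
    v = four_pl_viability(dose, config)
    rng = _derive_rng(seed, pop.chip_id, "drug")
    cells = pop.cells.copy()
    survive = rng.uniform(size=len(cells)) < v
    cells["live"] = cells["live"].to_numpy() & survive
    return CellPopulation(cells=cells, chip_id=pop.chip_id, day=pop.day)


# ---------------------------------------------------------------------------
# rendering


def _soft_disk(dist: np.ndarray, radius: float, edge: float = 0.8) -> np.ndarray:
    return 1.0 / (1.0 + np.exp((dist - radius) / edge))


def _cell_windows(pop: CellPopulation, config: SimConfig, pad: float = 4.0):
    """Yield (rows, cols, dist, idx) windows around each cell."""
    w, h = config.channel_width_px, config.channel_height_px
    xs = pop.cells["x"].to_numpy()
    ys = pop.cells["y"].to_numpy()
    rs = pop.cells["radius"].to_numpy()
    if len(xs) and (
        (xs < 0).any() or (xs >= w).any() or (ys < 0).any() or (ys >= h).any()
    ):
        raise ValueError("population lies outside the image bounds")
    for i in range(len(xs)):
        r = rs[i] + pad
        x0, x1 = int(max(0, np.floor(xs[i] - r))), int(min(w, np.ceil(xs[i] + r) + 1))
        y0, y1 = int(max(0, np.floor(ys[i] - r))), int(min(h, np.ceil(ys[i] + r) + 1))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - xs[i], yy - ys[i])
        yield slice(y0, y1), slice(x0, x1), dist, i


def _render_bf(pop: CellPopulation, config: SimConfig) -> np.ndarray:
    """Bright-field forward model: deterministic function of the layout."""
    bg = 0.80
    canvas = np.full((config.channel_height_px, config.channel_width_px), bg)
    live = pop.cells["live"].to_numpy() if len(pop.cells) else np.array([], bool)
    xs = pop.cells["x"].to_numpy()
    ys = pop.cells["y"].to_numpy()
    rs = pop.cells["radius"].to_numpy()
    for rows, cols, dist, i in _cell_windows(pop, config):
        r = rs[i]
        # per-cell optical density: denser cells are darker in BF and carry
        # proportionally brighter stains (see _render_fluor) — this keeps the
        # BF→fluorescence mapping learnable at the single-cell level
        density = _hash01(np.array([i]), 1.3)[0] - 0.5
        interior = (0.62 if live[i] else 0.38) - 0.12 * density
        core = _soft_disk(dist, r - 1.0, 0.6)
        rim = np.exp(-(((dist - r) / 1.1) ** 2))
        # mild deterministic internal texture, stronger mottle in dead cells
        phase = 2 * np.pi * _hash01(np.array([i]), 3.7)[0]
        yy, xx = np.mgrid[rows, cols]
        tex_amp = 0.03 if live[i] else 0.06
        tex = tex_amp * np.sin(0.9 * (xx - xs[i]) + phase) * np.cos(0.8 * (yy - ys[i]) - phase)
        appearance = bg - (bg - interior) * core - 0.35 * rim + tex * core
        canvas[rows, cols] = np.minimum(canvas[rows, cols], appearance)
    return np.clip(canvas, 0.02, 1.0)


def _render_fluor(pop: CellPopulation, config: SimConfig, channel: Channel) -> np.ndarray:
    """Fluorescence forward model (unit scale, before unevenness/noise)."""
    bg = 0.02
    canvas = np.full((config.channel_height_px, config.channel_width_px), bg)
    if not len(pop.cells):
        return canvas
    live = pop.cells["live"].to_numpy()
    for rows, cols, dist, i in _cell_windows(pop, config):
        if channel is Channel.TRITC and live[i]:
            continue  # live cells carry no dead-cell stain
        amp_jitter = 0.12 * (_hash01(np.array([i]), 1.3)[0] - 0.5)
        amp = (0.75 if channel is Channel.DAPI else 0.70) * (1.0 + amp_jitter)
        r = pop.cells["radius"].iloc[i]
        # steep edge (≈0.35 px) keeps the thresholded mask close to the true disk
        blob = amp * _soft_disk(dist, r, edge=0.35)
        if channel is Channel.TRITC:
            # faint diffuse halo of leaked dead-cell stain: populates the
            # middle intensity class that 3-class thresholding separates out
            blob = np.maximum(blob, 0.15 * _soft_disk(dist, 1.6 * r, edge=2.0))
        canvas[rows, cols] = np.maximum(canvas[rows, cols], bg + blob)
    return np.clip(canvas, 0.0, 1.0)


def _unevenness_field(config: SimConfig, pop: CellPopulation) -> np.ndarray:
    """Smooth multiplicative staining field: 1 + amplitude * sum-of-cosines."""
    amp = config.stain_unevenness_amplitude
    h, w = config.channel_height_px, config.channel_width_px
    if amp == 0:
        return np.ones((h, w))
    rng = _derive_rng(config.seed, pop.chip_id, pop.day, "stain-field")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    f = np.zeros((h, w))
    n_waves = 3
    for _ in range(n_waves):
        fx = rng.uniform(0.5, 2.0) / w
        fy = rng.uniform(0.5, 2.0) / h
        phase = rng.uniform(0, 2 * np.pi)
        f += np.cos(2 * np.pi * (fx * xx + fy * yy) + phase)
    f /= np.max(np.abs(f))
    return 1.0 + amp * f


def _digitize(field: np.ndarray, config: SimConfig, noise_rng: np.random.Generator) -> np.ndarray:
    out = field * config.max_value
    if config.noise_sd > 0:
        out = out + noise_rng.normal(0.0, config.noise_sd, size=out.shape)
    out = np.clip(np.rint(out), 0, config.max_value)
    return out.astype(np.uint8 if config.bit_depth == 8 else np.uint16)


def render_channels(
    pop: CellPopulation, config: SimConfig
) -> tuple[ChipImage, ChipImage, ChipImage]:
    """Render one population into (BF, DAPI, TRITC) images.

    DAPI marks every cell, TRITC only dead cells; the uneven-staining field
    multiplies the fluorescence channels but never bright-field; Gaussian
    detector noise is added last, independently per channel.
    """
    meta = dict(
        chip_id=pop.chip_id,
        day=pop.day,
        pixel_size_um=config.pixel_size_um,
        bit_depth=config.bit_depth,
    )
    bf_field = _render_bf(pop, config)
    dapi_field = _render_fluor(pop, config, Channel.DAPI)
    tritc_field = _render_fluor(pop, config, Channel.TRITC)
    stain = _unevenness_field(config, pop)
    dapi_field = np.clip(dapi_field * stain, 0.0, 1.0)
    tritc_field = np.clip(tritc_field * stain, 0.0, 1.0)

    images = []
    for channel, f in ((Channel.BF, bf_field), (Channel.DAPI, dapi_field), (Channel.TRITC, tritc_field)):
        noise_rng = _derive_rng(config.seed, pop.chip_id, pop.day, channel.value, "noise")
        images.append(ChipImage(pixels=_digitize(f, config, noise_rng), channel=channel, **meta))
    return tuple(images)


def render_zstack(
    pop: CellPopulation,
    config: SimConfig,
    channel: Channel,
    n_slices: int = 19,
    step_um: float = 14.0,
    defocus_blur_px: float = 0.8,
) -> "ZStack":
    """Simulate a through-focus stack of one channel as defocus-blurred slices.

    The in-focus plane sits mid-stack; slices blur progressively with focal
    distance (σ = ``defocus_blur_px`` per slice step). The maximum-intensity
    projection of such a stack recovers the in-focus render up to the slight
    blob thickening defocused light produces — mirroring how acquisition
    compresses a tall gel channel into one analysis image.
    """
    from scipy.ndimage import gaussian_filter

    from .imagecore import ZStack

    full = {c.channel: c for c in render_channels(pop, config)}[channel]
    pixels = full.pixels.astype(np.float64)
    focus = n_slices // 2
    slices = []
    for i in range(n_slices):
        sigma = defocus_blur_px * abs(i - focus)
        slices.append(gaussian_filter(pixels, sigma) if sigma else pixels.copy())
    return ZStack(
        slices=slices,
        step_um=step_um,
        channel=channel,
        chip_id=pop.chip_id,
        day=pop.day,
        pixel_size_um=config.pixel_size_um,
        bit_depth=config.bit_depth,
    )


def render_tiles(
    pop: CellPopulation,
    config: SimConfig,
    channel: Channel,
    n_tiles: int = 2,
    overlap_fraction: float = 0.10,
) -> list[ChipImage]:
    """Cut a rendered channel into ``n_tiles`` horizontally overlapping fields."""
    if not 0 <= overlap_fraction < 0.5:
        raise ConfigurationError("overlap_fraction must be in [0, 0.5)")
    full = {c.channel: c for c in render_channels(pop, config)}[channel]
    width = config.channel_width_px
    # tile width such that n tiles with the given overlap span the chip
    tile_w = int(np.ceil(width / (n_tiles - (n_tiles - 1) * overlap_fraction)))
    overlap = int(round(tile_w * overlap_fraction))
    step = tile_w - overlap
    tiles = []
    for i in range(n_tiles):
        x0 = min(i * step, width - tile_w)
        tiles.append(full.with_pixels(full.pixels[:, x0 : x0 + tile_w].copy()))
    return tiles


# ---------------------------------------------------------------------------
# ground truth


def rasterize_masks(pop: CellPopulation, config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Hard-disk boolean masks (all cells, dead cells) for ground truth."""
    h, w = config.channel_height_px, config.channel_width_px
    all_mask = np.zeros((h, w), dtype=bool)
    dead_mask = np.zeros((h, w), dtype=bool)
    if not len(pop.cells):
        return all_mask, dead_mask
    live = pop.cells["live"].to_numpy()
    rs = pop.cells["radius"].to_numpy()
    for rows, cols, dist, i in _cell_windows(pop, config):
        inside = dist <= rs[i]
        all_mask[rows, cols] |= inside
        if not live[i]:
            dead_mask[rows, cols] |= inside
    return all_mask, dead_mask


def simulated_atp(live_area_px: float, seed: int, chip_id: str = "chip",
                  cv: float = 0.10, scale: float = 1.0) -> float:
    """ATP-luminescence readout emulated as a noisy proxy of live area.

    The biochemical viability assay enters the analysis only as a numeric
    readout; here it is proportional to the true live area with lognormal
    measurement noise of coefficient of variation ``cv``.
    """
    rng = _derive_rng(seed, chip_id, "atp")
    sigma = np.sqrt(np.log1p(cv**2))
    return float(scale * live_area_px * rng.lognormal(-sigma**2 / 2, sigma))


def true_viable_area(pop: CellPopulation, config: SimConfig) -> dict:
    """Ground-truth chip areas: total, dead and viable (total − dead) px."""
    all_mask, dead_mask = rasterize_masks(pop, config)
    total = int(all_mask.sum())
    dead = int(dead_mask.sum())
    return {
        "true_total_area_px": total,
        "true_dead_area_px": dead,
        "true_viable_area_px": total - dead,
    }


# ---------------------------------------------------------------------------
# dataset generation


def assign_splits(n_chips: int) -> list[str]:
    """7:2:1 train/val/test assignment by chip, cycling a 10-chip pattern."""
    if n_chips < 10:
        raise ConfigurationError(
            "n_chips must be >= 10 for a 7:2:1 split (smaller runs would leave an empty set)"
        )
    return [_SPLIT_PATTERN[i % 10] for i in range(n_chips)]


def generate_dataset(
    config: SimConfig,
    n_chips: int,
    days: list[int],
    doses: list[float],
    out_dir: str | Path,
    split: bool = True,
    treatment_start_day: int = 6,
) -> pd.DataFrame:
    """Render a full dataset to disk and return its manifest.

    Each chip receives one dose (cycled over ``doses``; dose 0 is the
    vehicle). Drug deaths are applied only at days after
    ``treatment_start_day`` — the treatment window of the emulated
    experiment (dose after a baseline culture period, endpoint 48 h later).
    Writes per-chip/day/channel TIFFs, a ``manifest.csv``, a ground-truth
    ``truth.csv`` and the config as ``config.yaml``.
    """
    if n_chips <= 0:
        raise ConfigurationError("n_chips must be positive")
    if not days:
        raise ConfigurationError("at least one day required")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    splits = assign_splits(n_chips) if split else ["all"] * n_chips
    manifest_rows = []
    truth_rows = []
    for i in range(n_chips):
        chip_id = f"chip{i:03d}"
        dose = float(doses[i % len(doses)])
        for day in days:
            pop = generate_population(config, day, chip_id)
            if dose > 0 and day > treatment_start_day:
                pop = apply_drug(pop, dose, config, seed=config.seed)
            bf, dapi, tritc = render_channels(pop, config)
            paths = {}
            for img in (bf, dapi, tritc):
                rel = f"images/{chip_id}_day{day}_{img.channel.value}.tif"
                tifffile.imwrite(out_dir / rel, img.pixels)
                paths[img.channel.value] = rel
            manifest_rows.append(
                {
                    "chip_id": chip_id,
                    "day": day,
                    "dose": dose,
                    "replicate": i // max(len(doses), 1),
                    "split": splits[i],
                    "bf_path": paths["BF"],
                    "dapi_path": paths["DAPI"],
                    "tritc_path": paths["TRITC"],
                }
            )
            truth = true_viable_area(pop, config)
            truth_rows.append(
                {
                    "chip_id": chip_id,
                    "day": day,
                    "dose": dose,
                    "split": splits[i],
                    "n_cells": pop.n_cells,
                    "live_fraction": pop.live_fraction,
                    **truth,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    config.save(out_dir / "config.yaml")
    return manifest


def load_image(root: str | Path, rel_path: str, channel: Channel, **meta) -> ChipImage:
    """Read one dataset TIFF back as a :class:`ChipImage`."""
    pixels = tifffile.imread(Path(root) / rel_path)
    bit_depth = 8 if pixels.dtype == np.uint8 else 16
    return ChipImage(pixels=pixels, channel=channel, bit_depth=bit_depth, **meta)
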