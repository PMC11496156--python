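"""Seeded synthetic chest-texture data.

The generator emulates the statistical structure the staging method relies
on: small rounded opacities dispersed uniformly over a lung subregion, whose
*count* grows with the profusion level (the signal), superimposed on a
smooth noisy background with bright rib-like bands whose distribution is
identical across levels (salient distractors — any classifier signal from
them is spurious, which is exactly what the suppression strategy targets).

Each sample owns a pseudo-random stream derived from ``(seed, index)``, so
datasets are order-independent and partially regenerable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .config import ConfigError, SyntheticParams

__all__ = [
    "SyntheticSample",
    "ChestPhantom",
    "generate_subregion_image",
    "generate_arrays",
    "generate_dataset",
    "generate_chest_phantom",
]

_LEVELS = (0, 1, 2, 3)


@dataclass
class SyntheticSample:
    image: np.ndarray           # (tile, tile) float32 in [0, 1]
    level: int
    opacity_count: int
    opacity_centers: list
    zone: str | None = None


def _sample_rng(seed: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


def _add_bands(img: np.ndarray, params: SyntheticParams, rng: np.random.Generator) -> None:
    """Bright horizontal/oblique bands mimicking ribs and clavicles."""
    t = img.shape[0]
    rr, cc = np.mgrid[0:t, 0:t].astype(np.float64)
    for _ in range(params.rib_band_count):
        angle = np.deg2rad(rng.uniform(-20.0, 20.0))
        r0 = rng.uniform(0.1 * t, 0.9 * t)
        inten = rng.uniform(*params.rib_band_intensity_range)
        # signed distance to the line through (r0, t/2) at the drawn angle
        dist = (rr - r0 - np.tan(angle) * (cc - t / 2)) * np.cos(angle)
        img += inten * np.exp(-((dist / (params.rib_band_width / 2.0)) ** 2))


def _add_blob(img: np.ndarray, r: float, c: float, radius: float, inten: float) -> None:
    t = img.shape[0]
    sigma = radius / 2.0
    half = int(np.ceil(3 * sigma)) + 1
    r0, r1 = max(0, int(r) - half), min(t, int(r) + half + 1)
    c0, c1 = max(0, int(c) - half), min(t, int(c) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    img[r0:r1, c0:c1] += inten * np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)))


def generate_subregion_image(level: int, params: SyntheticParams | None = None,
                             seed: int = 0) -> SyntheticSample:
    """One synthetic lung-subregion tile of the requested profusion level.

    Deterministic given (params, seed): smoothed-noise background, additive
    rib-like bands (level-independent), and n Gaussian blob opacities with n
    drawn from the level's configured count range.
    """
    if level not in _LEVELS:
        raise ConfigError(f"profusion level must be in [0, 3], got {level}")
    params = (params or SyntheticParams()).validate()
    rng = _sample_rng(seed)
    t = params.tile_size

    noise = rng.normal(0.0, 1.0, size=(t, t))
    smooth = gaussian_filter(noise, params.background_smoothing)
    std = smooth.std()
    img = 0.35 + params.background_noise * (smooth / std if std > 0 else smooth)

    _add_bands(img, params, rng)

    lo, hi = params.opacity_count_ranges[level]
    n = int(rng.integers(lo, hi + 1))
    centers = []
    for _ in range(n):
        r = rng.uniform(0, t - 1)
        c = rng.uniform(0, t - 1)
        radius = rng.uniform(*params.opacity_radius_range)
        inten = rng.uniform(*params.opacity_intensity_range)
        _add_blob(img, r, c, radius, inten)
        centers.append((float(r), float(c)))

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(image=img, level=level, opacity_count=n, opacity_centers=centers)


def _plan_counts(n_per_level: int, imbalance) -> list[int]:
    if imbalance is None:
        return [n_per_level] * 4
    props = np.asarray(imbalance, dtype=np.float64)
    if props.ndim != 1 or props.size != 4 or (props < 0).any() or props.sum() <= 0:
        raise ConfigError("imbalance must be four non-negative proportions")
    props = props / props.sum()
    total = n_per_level  # with imbalance, n_per_level is the total sample count
    raw = props * total
    counts = np.floor(raw).astype(int)
    # largest-remainder apportionment to hit the total exactly
    for i in np.argsort(-(raw - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_arrays(n_per_level: int, params: SyntheticParams | None = None,
                    seed: int = 0, imbalance=None):
    """In-memory dataset: (images (n, t, t) float32, levels, opacity counts).

    Samples are stratified level-major then shuffled with the seed.  With
    ``imbalance`` given, ``n_per_level`` is the *total* count apportioned to
    the four levels by the proportions (largest remainder).
    """
    if n_per_level < 1:
        raise ConfigError("n_per_level must be >= 1")
    params = (params or SyntheticParams()).validate()
    counts = _plan_counts(n_per_level, imbalance)
    samples = []
    index = 0
    for level, cnt in zip(_LEVELS, counts):
        for _ in range(cnt):
            s = generate_subregion_image(level, params, seed=_child_seed(seed, index))
            samples.append(s)
            index += 1
    order = np.random.default_rng(seed).permutation(len(samples))
    samples = [samples[i] for i in order]
    images = np.stack([s.image for s in samples])
    levels = np.array([s.level for s in samples], dtype=np.intp)
    ocounts = np.array([s.opacity_count for s in samples], dtype=np.intp)
    return images, levels, ocounts


def _child_seed(seed: int, index: int) -> int:
    # stable per-sample entropy below 2**31
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))
               .generate_state(1)[0] % (2**31))


def generate_dataset(n_per_level: int, params: SyntheticParams | None = None,
                     seed: int = 0, out_dir=None, imbalance=None) -> pd.DataFrame:
    """Write PNG tiles and a ``path,level,opacity_count`` manifest CSV.

    Returns the manifest frame; files land in ``out_dir`` with the manifest
    at ``out_dir/manifest.csv``.  Regeneration with the same arguments is
    bit-identical.
    """
    if out_dir is None:
        raise ConfigError("out_dir is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    params = (params or SyntheticParams()).validate()
    images, levels, ocounts = generate_arrays(n_per_level, params, seed, imbalance)
    rows = []
    counters = {lv: 0 for lv in _LEVELS}
    for img, lv, oc in zip(images, levels, ocounts):
        name = f"level{lv}_{counters[lv]:04d}.png"
        counters[lv] += 1
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(out_dir / name)
        rows.append({"path": name, "level": int(lv), "opacity_count": int(oc)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# -- chest phantom -----------------------------------------------------

_ZONES = ("RU", "RM", "RL", "LU", "LM", "LL")


@dataclass
class ChestPhantom:
    """End-to-end fixture: a two-lung canvas with known per-zone content."""

    image: np.ndarray
    mask: np.ndarray
    zone_boxes: dict          # zone -> (row_start, row_end, col_start, col_end), half-open
    levels: dict              # zone -> profusion level
    aggregation: bool
    zone_counts: dict         # zone -> ground-truth opacity count


def generate_chest_phantom(per_zone_levels, params: SyntheticParams | None = None,
                           seed: int = 0, aggregation: bool = False) -> ChestPhantom:
    """Compose a synthetic chest image from six per-zone profusion levels.

    The two lungs are rectangular mask regions on a larger canvas; each lung
    is split into three equal-height zones filled with a synthetic subregion
    of the requested level.  With ``aggregation`` the highest-level zone
    additionally carries one large merged blob.  Ground-truth zone boxes are
    recorded for round-trip tests against the subregion splitter.
    """
    params = (params or SyntheticParams()).validate()
    levels = dict(zip(_ZONES, per_zone_levels)) if not isinstance(per_zone_levels, dict) \
        else dict(per_zone_levels)
    if set(levels) != set(_ZONES):
        raise ConfigError(f"need levels for zones {_ZONES}, got {sorted(levels)}")
    for z, lv in levels.items():
        if lv not in _LEVELS:
            raise ConfigError(f"zone {z}: level {lv} outside [0, 3]")

    zone = max(32, params.tile_size // 2)       # square zone tiles on the canvas
    margin, gap = 16, 24
    lung_h, lung_w = 3 * zone, zone
    h = lung_h + 2 * margin
    w = 2 * lung_w + gap + 2 * margin
    if h < lung_h or w < 2 * lung_w + gap:
        raise ConfigError("canvas too small for the tile layout")

    image = np.full((h, w), 0.1, dtype=np.float32)
    mask = np.zeros((h, w), dtype=np.uint8)
    # patient's right lung appears on the image left
    col0 = {"R": margin, "L": margin + lung_w + gap}
    zone_params = params.scaled(zone) if zone != params.tile_size else params

    boxes, counts = {}, {}
    agg_zone = None
    if aggregation:
        agg_zone = max(_ZONES, key=lambda z: (levels[z], -_ZONES.index(z)))
    for zi, zname in enumerate(_ZONES):
        side, band = zname[0], "UML".index(zname[1])
        r0 = margin + (lung_h * band) // 3
        r1 = margin + (lung_h * (band + 1)) // 3
        c0 = col0[side]
        c1 = c0 + lung_w
        tile = generate_subregion_image(levels[zname], zone_params,
                                        seed=_child_seed(seed, zi))
        sub = tile.image[: r1 - r0, :lung_w].copy()
        if aggregation and zname == agg_zone:
            big = np.zeros_like(sub, dtype=np.float64)
            _add_blob(big, sub.shape[0] / 2, sub.shape[1] / 2, zone / 5.0, 0.5)
            sub = np.clip(sub + big, 0.0, 1.0).astype(np.float32)
        image[r0:r1, c0:c1] = sub
        mask[r0:r1, c0:c1] = 1
        boxes[zname] = (r0, r1, c0, c1)
        counts[zname] = tile.opacity_count
    return ChestPhantom(image=image, mask=mask, zone_boxes=boxes, levels=levels,
                        aggregation=aggregation, zone_counts=counts)
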