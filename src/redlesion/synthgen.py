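"""Seeded generator of fundus-like test images with known lesion ground truth.

The generator emulates only the statistical structure the detector's
conditions probe: a bright circular field of view on a black surround, a
smooth illumination gradient, dark roughly-circular lesions (mild ellipses,
axis ratio at most ~1.3, with a one-pixel cosine-tapered rim outside the
ground-truth disc so edges are not artificially hard), dark curvilinear
vessel distractors drawn as smoothed random walks, and additive Gaussian
noise.  It makes no attempt at photorealism — no optic disc, fovea or
texture.

Vessels never enter the ground-truth mask: they are distractors, and any
detection touching one is a false positive by construction.  The ground
truth is the exact union of the rendered lesion discs and never depends on
the noise level.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["SynthParams", "SynthSample", "GenerationError",
           "generate", "generate_suite", "write_sample", "write_suite"]


class GenerationError(RuntimeError):
    """Raised when lesion/vessel placement is infeasible after bounded retries."""


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one synthetic image.

    Intensities are on the unit scale, sizes in pixels.  The defaults mirror
    the conditions the detector is specified against: five lesions of radius
    8–13 px with boundary contrast 0.25–0.45 against a background near 0.6,
    three vessel distractors of width 2–4 px, a bright circular field of
    view, a mild illumination gradient and weak sensor noise.  Lesions keep a
    boundary gap of at least ``min_separation`` = 2·(a0+d) = 26 px from each
    other and from vessel centrelines.
    """

    size: tuple[int, int] = (384, 384)
    n_lesions: int = 5
    lesion_radius_range: tuple[float, float] = (8.0, 13.0)
    lesion_contrast_range: tuple[float, float] = (0.25, 0.45)
    n_vessels: int = 3
    vessel_width_range: tuple[int, int] = (2, 4)
    vessel_contrast: float = 0.25
    background_level: float = 0.60
    gradient_amplitude: float = 0.08
    noise_sd: float = 0.01
    fov: bool = True
    min_separation: float = 26.0
    seed: int = 0
    max_retries: int = 500


@dataclass
class SynthSample:
    """A generated image, its exact lesion ground truth, and the lesion list
    as (center, radius, contrast) records."""

    image: np.ndarray
    gt_mask: np.ndarray
    lesion_list: list[tuple[tuple[int, int], float, float]]
    params: SynthParams


def _background(p: SynthParams, rng: np.random.Generator) -> np.ndarray:
    m, n = p.size
    rr = (np.arange(m)[:, None] / max(m - 1, 1)) - 0.5
    cc = (np.arange(n)[None, :] / max(n - 1, 1)) - 0.5
    phi = rng.uniform(0.0, 2.0 * math.pi)
    plane = rr * math.sin(phi) + cc * math.cos(phi)
    return p.background_level + p.gradient_amplitude * plane


def _fov_geometry(p: SynthParams) -> tuple[float, float, float]:
    m, n = p.size
    return (m - 1) / 2.0, (n - 1) / 2.0, 0.47 * min(m, n)


def _place_lesions(p: SynthParams, rng: np.random.Generator,
                   fov_radius: float, cr: float, cc: float
                   ) -> list[tuple[float, float, float, float, float, float]]:
    """Sample (row, col, radius, contrast, axis_ratio, orientation) tuples
    honouring the pairwise boundary gap."""
    lesions: list[tuple[float, float, float, float, float, float]] = []
    m, n = p.size
    for _ in range(p.n_lesions):
        for _attempt in range(p.max_retries):
            radius = rng.uniform(*p.lesion_radius_range)
            contrast = rng.uniform(*p.lesion_contrast_range)
            ratio = rng.uniform(1.0, 1.3)
            orient = rng.uniform(0.0, math.pi)
            if p.fov:
                # keep the lesion and a verification margin inside the FOV
                rho = rng.uniform(0.0, max(fov_radius - radius - p.min_separation, 1.0))
                ang = rng.uniform(0.0, 2.0 * math.pi)
                r = cr + rho * math.sin(ang)
                c = cc + rho * math.cos(ang)
            else:
                margin = radius + p.min_separation
                r = rng.uniform(margin, m - 1 - margin)
                c = rng.uniform(margin, n - 1 - margin)
            ok = True
            for (r2, c2, rad2, *_rest) in lesions:
                gap = math.hypot(r - r2, c - c2) - radius - rad2
                if gap < p.min_separation:
                    ok = False
                    break
            if ok:
                lesions.append((r, c, radius, contrast, ratio, orient))
                break
        else:
            raise GenerationError(
                f"could not place lesion {len(lesions) + 1} of {p.n_lesions} "
                f"after {p.max_retries} attempts")
    return lesions


def _render_lesions(p: SynthParams, lesions, shape) -> tuple[np.ndarray, np.ndarray]:
    """Depth map (intensity drop) and exact ground-truth mask."""
    depth = np.zeros(shape, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    m, n = shape
    for (r, c, radius, contrast, ratio, orient) in lesions:
        a = radius * math.sqrt(ratio)     # semi-major
        b = radius / math.sqrt(ratio)     # semi-minor (area preserved)
        half = int(math.ceil(a + 2))
        r0, r1 = max(int(r) - half, 0), min(int(r) + half + 1, m)
        c0, c1 = max(int(c) - half, 0), min(int(c) + half + 1, n)
        yy = np.arange(r0, r1)[:, None] - r
        xx = np.arange(c0, c1)[None, :] - c
        u = yy * math.cos(orient) + xx * math.sin(orient)
        v = -yy * math.sin(orient) + xx * math.cos(orient)
        s = np.sqrt((u / a) ** 2 + (v / b) ** 2)   # 1.0 on the ellipse edge
        edge_px = (s - 1.0) * radius               # ~distance past the edge, px
        taper = 0.5 * (1.0 + np.cos(np.pi * np.clip(edge_px, 0.0, 1.0)))
        patch = contrast * np.where(s <= 1.0, 1.0, taper)
        depth[r0:r1, c0:c1] = np.maximum(depth[r0:r1, c0:c1], patch)
        mask[r0:r1, c0:c1] |= s <= 1.0
    return depth, mask


def _draw_vessel(p: SynthParams, rng: np.random.Generator, lesions,
                 fov_radius: float, cr: float, cc: float,
                 width: int) -> np.ndarray:
    """Boolean mask of one smooth random-walk vessel steered around lesions."""
    m, n = p.size
    vessel = np.zeros((m, n), dtype=bool)
    start_ang = rng.uniform(0.0, 2.0 * math.pi)
    pos_r = cr + 0.92 * fov_radius * math.sin(start_ang)
    pos_c = cc + 0.92 * fov_radius * math.cos(start_ang)
    heading = start_ang + math.pi + rng.uniform(-0.4, 0.4)
    half_w = max(width / 2.0, 0.5)
    stamp = int(math.ceil(half_w))
    yy, xx = np.mgrid[-stamp:stamp + 1, -stamp:stamp + 1]
    disk = (yy ** 2 + xx ** 2) <= half_w ** 2
    max_steps = int(4 * fov_radius)
    for step in range(max_steps):
        ir, ic = int(round(pos_r)), int(round(pos_c))
        r0, r1 = max(ir - stamp, 0), min(ir + stamp + 1, m)
        c0, c1 = max(ic - stamp, 0), min(ic + stamp + 1, n)
        if r0 < r1 and c0 < c1:
            vessel[r0:r1, c0:c1] |= disk[r0 - (ir - stamp):r1 - (ir - stamp),
                                         c0 - (ic - stamp):c1 - (ic - stamp)]
        heading += rng.normal(0.0, 0.12)
        # steer away from any lesion closer than its exclusion zone
        for (lr, lc, radius, *_rest) in lesions:
            dr, dc = pos_r - lr, pos_c - lc
            dist = math.hypot(dr, dc)
            guard = radius + p.min_separation + 12.0
            if dist < guard:
                away = math.atan2(dr, dc)
                delta = (away - heading + math.pi) % (2.0 * math.pi) - math.pi
                heading += 0.35 * delta
        pos_r += 2.0 * math.sin(heading)
        pos_c += 2.0 * math.cos(heading)
        if step > 20 and math.hypot(pos_r - cr, pos_c - cc) > 0.97 * fov_radius:
            break
        if not (0 <= pos_r < m and 0 <= pos_c < n):
            break
    return vessel


def _vessel_clear_of_lesions(vessel: np.ndarray, lesions,
                             min_separation: float) -> bool:
    if not vessel.any() or not lesions:
        return True
    rows, cols = np.nonzero(vessel)
    for (lr, lc, radius, *_rest) in lesions:
        d2 = (rows - lr) ** 2 + (cols - lc) ** 2
        if d2.min() < (radius + min_separation) ** 2:
            return False
    return True


def generate(p: SynthParams) -> SynthSample:
    """Render one seeded synthetic sample (deterministic for a fixed seed)."""
    m, n = p.size
    rng = np.random.default_rng(p.seed)
    image = _background(p, rng)
    cr, cc, fov_radius = _fov_geometry(p)

    lesions = _place_lesions(p, rng, fov_radius, cr, cc)
    depth, gt_mask = _render_lesions(p, lesions, (m, n))

    vessel_depth = np.zeros((m, n), dtype=np.float64)
    for _ in range(p.n_vessels):
        for _attempt in range(50):
            width = int(rng.integers(p.vessel_width_range[0],
                                     p.vessel_width_range[1] + 1))
            vessel = _draw_vessel(p, rng, lesions, fov_radius, cr, cc, width)
            if _vessel_clear_of_lesions(vessel, lesions, p.min_separation):
                vessel_depth[vessel] = p.vessel_contrast
                break
        else:
            raise GenerationError("could not route a vessel clear of lesions")

    image = image - depth - vessel_depth
    if p.fov:
        rr = np.arange(m)[:, None] - cr
        xx = np.arange(n)[None, :] - cc
        outside = (rr ** 2 + xx ** 2) > fov_radius ** 2
        image[outside] = 0.02
    if p.noise_sd > 0:
        image = image + rng.normal(0.0, p.noise_sd, size=(m, n))
    image = np.clip(image, 0.0, 1.0)

    lesion_list = [((int(round(r)), int(round(c))), radius, contrast)
                   for (r, c, radius, contrast, *_rest) in lesions]
    return SynthSample(image=image, gt_mask=gt_mask,
                       lesion_list=lesion_list, params=p)


def generate_suite(base: SynthParams, n_images: int, seed: int) -> list[SynthSample]:
    """``n_images`` samples with per-image seeds ``seed + index``, so every
    image is reproducible on its own and the suite as a whole."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    return [generate(replace(base, seed=seed + i)) for i in range(n_images)]


def write_sample(sample: SynthSample, out_dir, stem: str) -> dict[str, Path]:
    """Write the image and mask as 8-bit PNGs and the lesion list as CSV."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "mask": out_dir / f"{stem}_mask.png",
        "lesions": out_dir / f"{stem}_lesions.csv",
    }
    iio.imwrite(paths["image"],
                np.round(sample.image * 255).astype(np.uint8))
    iio.imwrite(paths["mask"],
                (sample.gt_mask.astype(np.uint8) * 255))
    with open(paths["lesions"], "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "radius", "contrast"])
        for (r, c), radius, contrast in sample.lesion_list:
            writer.writerow([r, c, f"{radius:.4f}", f"{contrast:.4f}"])
    return paths


def write_suite(base: SynthParams, n_images: int, seed: int, out_dir) -> list[dict]:
    """Write a whole suite plus a key-value manifest recording the conditions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_suite(base, n_images, seed)
    written = []
    for idx, sample in enumerate(samples):
        written.append(write_sample(sample, out_dir, f"synth_{idx:03d}"))
    with open(out_dir / "manifest.txt", "w") as fh:
        fh.write(f"n_images = {n_images}\n")
        fh.write(f"suite_seed = {seed}\n")
        for key, value in vars(base).items():
            fh.write(f"{key} = {value}\n")
    return written
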