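"""Synthetic fundus-image generator with known hemorrhage ground truth.

Emulates the salient structure of 50-degree field-of-view fundus photographs:
a bright, unevenly illuminated circular retina on a near-black frame, dark
curvilinear vessels radiating inward from the rim, and dark roughly
elliptical hemorrhages.  Two lesion classes the detection pipeline must
handle are planted on demand: lesions adjoined to a vessel, and lesions
touching the field-of-view rim (where they blend into the dark background).

Every sample carries pixel-accurate masks and per-lesion records, so the
seed-extraction, segmentation and classification stages can be scored
against exact ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .types import PlacementError

__all__ = ["SynthConfig", "HemorrhageRecord", "SynthSample", "generate_sample", "save_sample"]

# Base retina / structure colors (R, G, B) before illumination shading.
_RETINA_RGB = np.array([196.0, 138.0, 62.0])
# Thin vessels average with surrounding tissue over the point-spread function
# (partial-volume effect), so they darken far less than pooled hemorrhage blood.
_VESSEL_FACTOR = np.array([0.87, 0.80, 0.83])  # multiplicative darkening
_LESION_FACTOR = np.array([0.48, 0.30, 0.40])


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults define the standard study conditions."""

    image_height: int = 512
    image_width: int = 512
    fov_radius_fraction: float = 0.92
    illumination_gradient_strength: float = 0.3
    n_vessels: int = 8
    vessel_width_range: tuple[int, int] = (2, 5)
    n_hemorrhages: int = 6
    hemorrhage_radius_range: tuple[int, int] = (10, 22)
    fraction_vessel_attached: float = 0.3
    fraction_border_touching: float = 0.2
    noise_sigma: float = 2.0
    texture_sigma: float = 12.0
    texture_scale: float = 24.0
    n_dark_shades: int = 3
    shade_depth: float = 0.25
    shade_radius_range: tuple[int, int] = (25, 50)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("frame must be at least 64x64")
        if not 0.0 < self.fov_radius_fraction <= 1.0:
            raise ValueError("fov_radius_fraction must be in (0, 1]")
        for name in ("illumination_gradient_strength", "fraction_vessel_attached",
                     "fraction_border_touching"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_vessel_attached + self.fraction_border_touching > 1.0 + 1e-9:
            raise ValueError("attached + border fractions must not exceed 1")
        rmax = self.hemorrhage_radius_range[1]
        if rmax >= min(self.image_height, self.image_width) / 2:
            raise ValueError("hemorrhage radii must fit inside the frame")
        if self.hemorrhage_radius_range[0] > rmax:
            raise ValueError("hemorrhage_radius_range must be (min, max)")
        if self.vessel_width_range[0] > self.vessel_width_range[1]:
            raise ValueError("vessel_width_range must be (min, max)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.texture_sigma < 0 or self.texture_scale <= 0:
            raise ValueError("texture parameters must be non-negative")
        if self.n_dark_shades < 0 or not 0.0 <= self.shade_depth < 1.0:
            raise ValueError("invalid dark-shade parameters")


@dataclass(frozen=True)
class HemorrhageRecord:
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (major, minor) semi-axes, px
    attached_to_vessel: bool
    touches_border: bool


@dataclass
class SynthSample:
    image: np.ndarray  # HxWx3 uint8
    hemorrhage_mask: np.ndarray  # bool
    vessel_mask: np.ndarray  # bool
    fov_mask: np.ndarray  # bool
    hemorrhage_records: list[HemorrhageRecord] = field(default_factory=list)


def _fov_geometry(cfg: SynthConfig) -> tuple[np.ndarray, float, tuple[float, float]]:
    h, w = cfg.image_height, cfg.image_width
    # fraction of the largest inscribed circle's radius
    radius = cfg.fov_radius_fraction * min(h, w) / 2.0
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - center[0], cc - center[1])
    return dist <= radius, radius, center


def _illumination(cfg: SynthConfig, rng: np.random.Generator,
                  radius: float, center: tuple[float, float]) -> np.ndarray:
    """Radial vignette plus a random linear gradient, scaled by strength."""
    h, w = cfg.image_height, cfg.image_width
    rr, cc = np.mgrid[0:h, 0:w]
    radial = np.hypot(rr - center[0], cc - center[1]) / max(radius, 1.0)
    theta = rng.uniform(0, 2 * np.pi)
    lin = ((rr - center[0]) * np.sin(theta) + (cc - center[1]) * np.cos(theta))
    lin = (lin / max(radius, 1.0) + 1.0) / 2.0  # 0..1 across the disc
    g = cfg.illumination_gradient_strength
    shade = 1.0 - g * (0.55 * np.clip(radial, 0, 1) ** 2 + 0.45 * np.clip(lin, 0, 1))
    if cfg.texture_sigma > 0:
        # smooth multiplicative mottle emulating choroidal background texture
        field = rng.normal(0.0, 1.0, size=(h, w))
        field = ndi.gaussian_filter(field, cfg.texture_scale)
        sd = field.std()
        if sd > 0:
            rel = cfg.texture_sigma / _RETINA_RGB[1]
            shade = shade * (1.0 + rel * field / sd)
    return shade


def _dark_shades(cfg: SynthConfig, rng: np.random.Generator,
                 radius: float, center: tuple[float, float]
                 ) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Soft dark elliptical shades from uneven lighting (non-lesion decoys).

    Returns the multiplicative field and the (row, col, radius) of each
    shade so lesion placement can keep clear of them.
    """
    h, w = cfg.image_height, cfg.image_width
    field = np.ones((h, w))
    centers: list[tuple[float, float, float]] = []
    if cfg.n_dark_shades == 0 or cfg.shade_depth == 0:
        return field, centers
    rr, cc = np.mgrid[0:h, 0:w]
    lo, hi = cfg.shade_radius_range
    for _ in range(cfg.n_dark_shades):
        ang = rng.uniform(0, 2 * np.pi)
        d0 = rng.uniform(0.2, 0.85) * radius
        cy = center[0] + d0 * np.sin(ang)
        cx = center[1] + d0 * np.cos(ang)
        sa = rng.uniform(lo, hi)
        sb = sa * rng.uniform(0.7, 1.0)
        th = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        depth = cfg.shade_depth * rng.uniform(0.7, 1.0)
        field *= 1.0 - depth * np.exp(-0.5 * ((u / sa) ** 2 + (v / sb) ** 2))
        centers.append((float(cy), float(cx), float(sa)))
    return field, centers


def _draw_vessels(cfg: SynthConfig, rng: np.random.Generator, fov: np.ndarray,
                  radius: float, center: tuple[float, float]) -> np.ndarray:
    """Smoothed random-walk polylines from the rim toward the disc center."""
    h, w = cfg.image_height, cfg.image_width
    mask = np.zeros((h, w), dtype=bool)
    wmin, wmax = cfg.vessel_width_range
    for _ in range(cfg.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        pos = np.array([center[0] + 0.98 * radius * np.sin(ang),
                        center[1] + 0.98 * radius * np.cos(ang)])
        # heading: inward with jitter
        heading = ang + np.pi + rng.uniform(-0.3, 0.3)
        width = int(rng.integers(wmin, wmax + 1))
        stamp_r = max(width / 2.0, 1.0)
        n_steps = int(radius * rng.uniform(0.8, 1.4))
        turn = 0.0
        for _ in range(n_steps):
            turn = 0.85 * turn + rng.normal(0.0, 0.06)
            heading += turn
            pos = pos + np.array([np.sin(heading), np.cos(heading)]) * 2.0
            d = np.hypot(pos[0] - center[0], pos[1] - center[1])
            if d > 0.99 * radius or d < 0.08 * radius:
                break
            rr, cc = skdraw.disk((pos[0], pos[1]), stamp_r + 0.5, shape=(h, w))
            mask[rr, cc] = True
    mask &= fov
    return mask


def _lesion_polygon(rng: np.random.Generator, center: tuple[float, float],
                    a: float, b: float, angle: float,
                    shape: tuple[int, int]) -> np.ndarray:
    """Rotated ellipse with low-frequency radial boundary perturbation."""
    thetas = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    k1, k2 = rng.integers(2, 5), rng.integers(5, 9)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    wobble = 1.0 + 0.06 * np.sin(k1 * thetas + p1) + 0.03 * np.sin(k2 * thetas + p2)
    x = a * np.cos(thetas) * wobble
    y = b * np.sin(thetas) * wobble
    ca, sa = np.cos(angle), np.sin(angle)
    rows = center[0] + x * sa + y * ca
    cols = center[1] + x * ca - y * sa
    mask = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


def _plan_flags(n: int, frac_attached: float, frac_border: float) -> list[tuple[bool, bool]]:
    n_border = int(round(frac_border * n))
    n_attached = int(round(frac_attached * n))
    if n_border + n_attached > n:
        n_attached = n - n_border
    flags = [(False, True)] * n_border + [(True, False)] * n_attached
    flags += [(False, False)] * (n - len(flags))
    return flags


def generate_sample(config: SynthConfig) -> SynthSample:
    """Generate one synthetic fundus image with ground-truth masks.

    Deterministic for a fixed ``config.rng_seed``.  Raises
    :class:`PlacementError` when the requested lesions cannot be placed
    without overlap under the configured geometry.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    h, w = cfg.image_height, cfg.image_width
    fov, radius, center = _fov_geometry(cfg)
    shade = _illumination(cfg, rng, radius, center)
    shade_field, shade_centers = _dark_shades(cfg, rng, radius, center)
    shade = shade * shade_field
    vessels = _draw_vessels(cfg, rng, fov, radius, center)

    # distance from any vessel pixel, for keeping plain lesions off vessels
    if vessels.any():
        vessel_dist = ndi.distance_transform_edt(~vessels)
    else:
        vessel_dist = np.full((h, w), np.inf)

    lesion_mask = np.zeros((h, w), dtype=bool)
    records: list[HemorrhageRecord] = []
    placed_centers: list[tuple[float, float, float]] = []  # (row, col, a)
    rmin, rmax = cfg.hemorrhage_radius_range

    # vessel pixels comfortably interior to the FOV, usable as attachment sites
    vessel_pixels = np.empty((0, 2), dtype=int)
    if vessels.any():
        rr, cc = np.nonzero(vessels)
        d = np.hypot(rr - center[0], cc - center[1])
        interior = d < radius - rmax - 6
        vessel_pixels = np.stack([rr[interior], cc[interior]], axis=1)

    def too_close(row: float, col: float, a: float) -> bool:
        if any(np.hypot(row - r0, col - c0) < a + a0 + 4
               for r0, c0, a0 in placed_centers):
            return True
        # lesions stay clear of the dark-shade decoys
        return any(np.hypot(row - r0, col - c0) < a + s0 + 8
                   for r0, c0, s0 in shade_centers)

    for attached, border in _plan_flags(cfg.n_hemorrhages,
                                        cfg.fraction_vessel_attached,
                                        cfg.fraction_border_touching):
        a = rng.uniform(rmin, rmax)
        b = a * rng.uniform(0.65, 0.95)
        placed = False
        for _ in range(200):
            if border:
                ang = rng.uniform(0, 2 * np.pi)
                # major axis oriented radially; center set so the outer lip
                # crosses the FOV boundary while most of the lesion stays inside
                d0 = radius - 0.90 * a
                row = center[0] + d0 * np.sin(ang)
                col = center[1] + d0 * np.cos(ang)
                angle = ang
            elif attached:
                if len(vessel_pixels) == 0:
                    raise PlacementError(
                        "vessel-attached lesion requested but no interior vessel "
                        "pixels exist (n_vessels too small or FOV too tight)")
                idx = rng.integers(0, len(vessel_pixels))
                vr, vc = vessel_pixels[idx]
                off_ang = rng.uniform(0, 2 * np.pi)
                off = a * 0.8
                row, col = vr + off * np.sin(off_ang), vc + off * np.cos(off_ang)
                angle = rng.uniform(0, np.pi)
            else:
                ang = rng.uniform(0, 2 * np.pi)
                d0 = rng.uniform(0.15, 0.80) * (radius - a - 8)
                row = center[0] + d0 * np.sin(ang)
                col = center[1] + d0 * np.cos(ang)
                angle = rng.uniform(0, np.pi)
            if too_close(row, col, a):
                continue
            if not border:
                d_center = np.hypot(row - center[0], col - center[1])
                if d_center > radius - a - 6:
                    continue
                if not attached:
                    ir, ic = int(round(row)), int(round(col))
                    if not (0 <= ir < h and 0 <= ic < w):
                        continue
                    if vessel_dist[ir, ic] < a + 5:
                        continue  # plain lesion must stay clear of vessels
            cand = _lesion_polygon(rng, (row, col), a, b, angle, (h, w))
            if not cand.any() or (cand & lesion_mask).any():
                continue
            if attached and not (ndi.binary_dilation(cand) & vessels).any():
                continue
            if border:
                ring = fov & ~ndi.binary_erosion(fov)
                if not (cand & ring).any():
                    continue
            lesion_mask |= cand
            placed_centers.append((row, col, a))
            records.append(HemorrhageRecord(center=(row, col), axes=(a, b),
                                            attached_to_vessel=attached,
                                            touches_border=border))
            placed = True
            break
        if not placed:
            kind = "border-touching" if border else (
                "vessel-attached" if attached else "interior")
            raise PlacementError(
                f"could not place a {kind} hemorrhage without overlap; "
                f"reduce n_hemorrhages or hemorrhage_radius_range")

    # ---- render ----
    img = np.zeros((h, w, 3), dtype=float)
    base = _RETINA_RGB[None, None, :] * shade[..., None]
    img[fov] = base[fov]
    vis_vessels = vessels & ~lesion_mask  # lesions drawn over vessels
    img[vis_vessels] *= _VESSEL_FACTOR
    vis_lesions = lesion_mask & fov  # outside-FOV lip stays black (blended)
    img[vis_lesions] = base[vis_lesions] * _LESION_FACTOR
    img[~fov] = 2.0  # near-black frame
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SynthSample(image=img, hemorrhage_mask=lesion_mask,
                       vessel_mask=vessels, fov_mask=fov,
                       hemorrhage_records=records)


def save_sample(sample: SynthSample, out_dir: str | Path, stem: str = "sample") -> None:
    """Write image and masks as PNGs and the lesion records as JSON."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(out / f"{stem}.png")
    for name, mask in (("hemorrhage_mask", sample.hemorrhage_mask),
                       ("vessel_mask", sample.vessel_mask),
                       ("fov_mask", sample.fov_mask)):
        Image.fromarray((mask.astype(np.uint8) * 255)).save(out / f"{stem}_{name}.png")
    recs = [
        {"center": list(r.center), "axes": list(r.axes),
         "attached_to_vessel": r.attached_to_vessel,
         "touches_border": r.touches_border}
        for r in sample.hemorrhage_records
    ]
    (out / f"{stem}_records.json").write_text(json.dumps(recs, indent=2))
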