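"""Synthetic panoramic-radiograph scenes with exact per-tooth ground truth.

Real panoramic radiographs with pixel-level per-tooth annotation are scarce
and usually private, so this module renders parametric stand-ins: two dental
arches of 16 teeth each laid out on parabolic curves, every tooth drawn as a
crown (rounded quadrilateral) plus 1-3 tapered root prongs, with controllable
lateral neighbor overlap, missing teeth, a bone-like background gradient,
Gaussian intensity noise and bright elliptical restoration-like artifacts.

Ground truth is exact by construction: each tooth is rasterized into its own
binary plane of a 32-channel :class:`ToothMaskStack` (FDI channel order), and
overlapping neighbors genuinely share pixels, which is the property the
multi-label segmentation head is designed to handle.

The generator is a pure function of its :class:`SyntheticSceneSpec`: the same
spec (including seed) reproduces the scene bit for bit.  What it does *not*
emulate: true radiographic physics, anatomy of jaws/sinuses, caries or
fractures, and the blur/ghosting of rotational tomography.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .fdi import FDILabelMap, build_fdi_label_map

__all__ = [
    "SyntheticSceneSpec",
    "ToothMaskStack",
    "generate_scene",
    "render_clean",
    "sample_dataset",
    "write_sample",
    "read_sample",
]

# Root prongs per FDI position (1 = central incisor .. 8 = third molar).
# Simplified anatomy: single roots for incisors/canines, 1-2 for premolars,
# 2-3 for molars; affects realism only, never the mask contracts.
_ROOTS_BY_POSITION = {1: 1, 2: 1, 3: 1, 4: 2, 5: 1, 6: 2, 7: 3, 8: 3}

_TOOTH_BRIGHTNESS = 0.35
_ARTIFACT_BRIGHTNESS = 0.95


@dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic panoramic scene.

    ``overlap_fraction`` is the lateral overlap between adjacent crowns as a
    fraction of crown width (0 = just touching, 0.5 = half overlapped);
    ``arch_curvature`` is the dimensionless sag of the parabolic arches;
    ``noise_sigma`` is the standard deviation of additive Gaussian intensity
    noise on the [0, 1] scale.
    """

    image_height: int = 256
    image_width: int = 512
    arch_curvature: float = 0.6
    tooth_presence: tuple[bool, ...] = field(default=(True,) * 32)
    overlap_fraction: float = 0.25
    noise_sigma: float = 0.02
    artifact_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.overlap_fraction <= 0.5:
            raise ValueError("overlap_fraction must lie in [0, 0.5]")
        if len(self.tooth_presence) != 32:
            raise ValueError("tooth_presence must have 32 entries")
        if not any(self.tooth_presence):
            raise ValueError("at least one tooth must be present")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.artifact_count < 0:
            raise ValueError("artifact_count must be non-negative")

    def without_teeth(self, fdi_codes: "list[int]") -> "SyntheticSceneSpec":
        lm = build_fdi_label_map()
        presence = list(self.tooth_presence)
        for code in fdi_codes:
            presence[lm.channel_of(code)] = False
        return replace(self, tooth_presence=tuple(presence))


@dataclass
class ToothMaskStack:
    """H x W x 32 binary mask planes in fixed FDI channel order."""

    planes: np.ndarray
    label_map: FDILabelMap

    def __post_init__(self) -> None:
        p = np.asarray(self.planes)
        if p.ndim != 3 or p.shape[2] != 32:
            raise ValueError(f"expected H x W x 32 planes, got {p.shape}")
        if not np.isin(p, (0, 1)).all():
            raise ValueError("mask planes must be binary")
        self.planes = p.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.planes.shape

    def pixel_counts(self) -> np.ndarray:
        """Foreground pixel count per channel (length 32)."""
        return self.planes.reshape(-1, 32).sum(axis=0)

    def multilabel_pixel_count(self) -> int:
        """Number of pixels claimed by two or more teeth."""
        return int((self.planes.sum(axis=2) >= 2).sum())


def _superellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    """Rounded-quadrilateral crown footprint (superellipse of exponent 4)."""
    y = (np.arange(h)[:, None] - cy) / max(ry, 1e-9)
    x = (np.arange(w)[None, :] - cx) / max(rx, 1e-9)
    return y**4 + x**4 <= 1.0


def _root_prongs(
    h: int, w: int, cy_base: float, cx: float, half_width: float,
    length: float, n_roots: int, direction: int, tip_jitter: float,
) -> np.ndarray:
    """Tapered triangular root prongs leaving the crown base.

    ``direction`` is -1 for upper teeth (roots point toward the image top)
    and +1 for lower teeth.
    """
    mask = np.zeros((h, w), dtype=bool)
    yy = np.arange(h)[:, None]
    xx = np.arange(w)[None, :]
    offsets = np.linspace(-0.55, 0.55, n_roots) * half_width if n_roots > 1 else [0.0]
    for k, off in enumerate(offsets):
        tip_y = cy_base + direction * length
        tip_x = cx + off + tip_jitter * (1 if k % 2 else -1)
        base_half = half_width / (n_roots + 0.5)
        # linear taper from base_half at the crown base to ~1 px at the tip
        t = np.clip((yy - cy_base) / (tip_y - cy_base + 1e-9), 0.0, 1.0)
        in_span = (yy - cy_base) * direction >= 0
        in_span &= (yy - tip_y) * direction <= 0
        hw = base_half * (1.0 - t) + 1.0 * t
        mask |= in_span & (np.abs(xx - (cx + off + (tip_x - cx - off) * t)) <= hw)
    return mask


def render_clean(spec: SyntheticSceneSpec):
    """Render the noiseless scene.

    Returns ``(clean, planes, background)``: the artifact-and-teeth composite
    before noise, the H x W x 32 mask planes, and the pure background grid.
    Every mask foreground pixel is strictly brighter in ``clean`` than the
    background mean, which is what makes the scene segmentable at all.
    """
    H, W = spec.image_height, spec.image_width
    label_map = build_fdi_label_map()

    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_art, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    # Fixed-size jitter block so presence flags never shift the stream.
    jitter = rng_geom.uniform(-1.0, 1.0, size=(32, 3))

    background = 0.18 + 0.10 * (np.arange(H)[:, None] / max(H - 1, 1)) * np.ones((1, W))
    background = background + 0.02 * np.cos(np.linspace(0, 2 * np.pi, W))[None, :]

    planes = np.zeros((H, W, 32), dtype=np.uint8)

    margin = 0.06 * W
    usable = W - 2 * margin
    spacing = usable / 16.0
    crown_w = spacing / (1.0 - spec.overlap_fraction)  # overlap = f * crown_w
    crown_h_base = 0.13 * H
    root_len_base = 0.13 * H
    mid = 0.5 * H
    gap = 0.035 * H  # occlusal separation between the arches

    for ch in range(32):
        code = label_map.code_of(ch)
        quadrant, position = divmod(code, 10)
        upper = quadrant in (1, 2)
        # slot index 0..15 left-to-right across the film
        if upper:
            slot = (8 - position) if quadrant == 1 else (7 + position)
        else:
            slot = (8 - position) if quadrant == 4 else (7 + position)
        cx = margin + (slot + 0.5) * spacing
        u = (cx - W / 2) / (usable / 2)  # -1 .. 1 across the arch
        sag = spec.arch_curvature * 0.08 * H * u * u
        jh, jx, jt = jitter[ch]
        crown_h = crown_h_base * (0.9 + 0.15 * (position >= 6)) * (1 + 0.05 * jh)
        root_len = root_len_base * (1.0 - 0.15 * (position >= 6)) * (1 + 0.05 * jh)
        cx_j = cx + 0.6 * jx

        if upper:
            crown_cy = mid - gap - crown_h / 2 - sag
            base_y = crown_cy - crown_h / 2
            direction = -1
        else:
            crown_cy = mid + gap + crown_h / 2 + sag
            base_y = crown_cy + crown_h / 2
            direction = +1

        if not spec.tooth_presence[ch]:
            continue
        crown = _superellipse(H, W, crown_cy, cx_j, crown_h / 2, crown_w / 2)
        roots = _root_prongs(
            H, W, base_y, cx_j, crown_w / 2 * 0.8, root_len,
            _ROOTS_BY_POSITION[position], direction, 0.8 * jt,
        )
        planes[:, :, ch] = (crown | roots).astype(np.uint8)

    clean = background + _TOOTH_BRIGHTNESS * planes.sum(axis=2, dtype=np.float64)

    for _ in range(spec.artifact_count):
        acy = rng_art.uniform(0.2 * H, 0.8 * H)
        acx = rng_art.uniform(0.1 * W, 0.9 * W)
        ry = rng_art.uniform(0.008 * H, 0.03 * H) + 1.0
        rx = rng_art.uniform(0.008 * W, 0.025 * W) + 1.0
        yy = (np.arange(H)[:, None] - acy) / ry
        xx = (np.arange(W)[None, :] - acx) / rx
        ellipse = yy**2 + xx**2 <= 1.0
        clean = np.where(ellipse, np.maximum(clean, _ARTIFACT_BRIGHTNESS), clean)

    return clean, planes, background


def generate_scene(spec: SyntheticSceneSpec):
    """Generate one scene: a noisy [0, 1] image and its exact mask stack.

    Deterministic: identical specs (same seed) give bit-identical output.
    """
    clean, planes, _ = render_clean(spec)
    ss = np.random.SeedSequence(spec.seed)
    rng_noise = np.random.default_rng(ss.spawn(3)[2])
    noisy = clean + rng_noise.normal(0.0, spec.noise_sigma, size=clean.shape)
    image = np.clip(noisy, 0.0, 1.0)
    return image, ToothMaskStack(planes, build_fdi_label_map())


def sample_dataset(
    n: int,
    seed: int = 0,
    image_height: int = 256,
    image_width: int = 512,
    overlap_fraction: float = 0.25,
    missing_tooth_prob: float = 0.05,
    noise_sigma: float = 0.02,
    artifact_count: int = 3,
    arch_curvature: float = 0.6,
):
    """Draw ``n`` varied scenes: per-sample seeds and random missing teeth.

    Each tooth is independently absent with ``missing_tooth_prob`` (subject
    to at least one present).  Returns a list of ``(image, masks)`` pairs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    out = []
    for i in range(n):
        presence = master.random(32) >= missing_tooth_prob
        if not presence.any():
            presence[0] = True
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = SyntheticSceneSpec(
            image_height=image_height,
            image_width=image_width,
            arch_curvature=arch_curvature,
            tooth_presence=tuple(bool(b) for b in presence),
            overlap_fraction=overlap_fraction,
            noise_sigma=noise_sigma,
            artifact_count=artifact_count,
            seed=sub_seed,
        )
        out.append(generate_scene(spec))
    return out


# ---------------------------------------------------------------------------
# Persistence: 8-bit PNG image, multi-frame TIFF masks, JSON label-map sidecar
# ---------------------------------------------------------------------------

def write_sample(directory: str | Path, name: str, image: np.ndarray,
                 masks: ToothMaskStack) -> None:
    """Persist a sample as ``<name>.png`` + ``<name>_masks.tif`` + sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.asarray(image) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(directory / f"{name}.png")
    # planes stored frame-major: frame k = channel k, 0/255 uint8
    frames = (masks.planes.transpose(2, 0, 1) * 255).astype(np.uint8)
    tifffile.imwrite(directory / f"{name}_masks.tif", frames)
    masks.label_map.to_json(directory / f"{name}_labelmap.json")


def read_sample(directory: str | Path, name: str):
    """Inverse of :func:`write_sample` (exact for masks, 8-bit for image)."""
    directory = Path(directory)
    img_path = directory / f"{name}.png"
    tif_path = directory / f"{name}_masks.tif"
    sidecar = directory / f"{name}_labelmap.json"
    if not img_path.exists():
        raise FileNotFoundError(f"image not found: {img_path}")
    if not tif_path.exists():
        raise FileNotFoundError(f"mask stack not found: {tif_path}")
    label_map = FDILabelMap.from_json(sidecar)  # raises naming the sidecar
    image = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
    frames = tifffile.imread(tif_path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != 32:
        raise ValueError(
            f"mask stack {tif_path} has {frames.shape[0]} planes, expected 32"
        )
    planes = (frames > 127).astype(np.uint8).transpose(1, 2, 0)
    return image, ToothMaskStack(planes, label_map)
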