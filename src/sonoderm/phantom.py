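"""Synthetic skin phantoms: layered B-mode images, elasticity maps, cohorts.

Every stochastic generator is a pure function of (spec, seed), so all
downstream modules are testable without any acquired data. The B-mode
phantom is a three-layer axial model (coupling gel / dermis / subcutis)
with optional within-layer texture; the noise model is additive zero-mean
white Gaussian noise on an 8-bit intensity scale (a multiplicative
speckle mode is available but off by default). The elasticity phantom is
a disk lesion on a uniform background, optionally surrounded by a stiffer
margin band — the "hard ring" seen at the periphery of sclerotic skin
lesions. Cohorts are two-group Gaussian samples parameterized by an
effect size in units of the common standard deviation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .elasto import ElasticityMap, LesionMask
from .image import Image2D

__all__ = [
    "NoiseSpec",
    "SkinPhantomSpec",
    "ElasticityPhantomSpec",
    "CohortSpec",
    "make_skin_phantom",
    "add_noise",
    "make_elasticity_phantom",
    "make_cohort",
    "save_image_tiff",
    "load_image_tiff",
    "save_mask_png",
    "load_mask_png",
    "spec_to_json",
    "spec_from_json",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: additive zero-mean Gaussian (default) or multiplicative speckle.

    ``sigma`` is in intensity units for the additive model and is a unitless
    coefficient of variation for the speckle model. ``clip_range`` optionally
    clips the noisy output to [lo, hi].
    """

    kind: str = "additive_gaussian"
    sigma: float = 20.0
    clip_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "speckle_multiplicative"):
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.clip_range is not None:
            lo, hi = self.clip_range
            if not lo < hi:
                raise ValueError(f"clip_range must satisfy lo < hi, got {self.clip_range}")
            object.__setattr__(self, "clip_range", (float(lo), float(hi)))


@dataclass(frozen=True)
class SkinPhantomSpec:
    """Three-layer axial skin model on an 8-bit intensity scale.

    Rows above ``entry_depth_px`` are coupling gel, rows in
    [entry_depth_px, dermis_base_depth_px) are dermis, rows below are
    subcutis. Ground-truth dermal thickness is
    (dermis_base_depth_px − entry_depth_px) × pixel_spacing.
    """

    height: int = 128
    width: int = 128
    pixel_spacing: float = 0.05  # mm/px, typical of 20 MHz high-frequency skin US
    entry_depth_px: int = 40
    dermis_base_depth_px: int = 100
    layer_intensities: tuple[float, float, float] = (40.0, 170.0, 90.0)
    texture_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if not (0 < self.entry_depth_px < self.dermis_base_depth_px < self.height):
            raise ValueError(
                "depths must satisfy 0 < entry_depth_px < dermis_base_depth_px < height; "
                f"got entry_depth_px={self.entry_depth_px}, "
                f"dermis_base_depth_px={self.dermis_base_depth_px}, height={self.height}"
            )
        if len(self.layer_intensities) != 3:
            raise ValueError("layer_intensities must have 3 entries (gel, dermis, subcutis)")
        for v in self.layer_intensities:
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"layer_intensities must lie in [0, 255], got {v}")
        if self.texture_sigma < 0:
            raise ValueError(f"texture_sigma must be >= 0, got {self.texture_sigma}")

    @property
    def thickness_mm(self) -> float:
        return (self.dermis_base_depth_px - self.entry_depth_px) * self.pixel_spacing


@dataclass(frozen=True)
class ElasticityPhantomSpec:
    """Disk lesion on a uniform background, with an optional stiffer margin band."""

    height: int = 64
    width: int = 64
    pixel_spacing: float = 0.1  # mm/px
    background_kpa: float = 20.0
    lesion_center: tuple[int, int] = (32, 32)
    lesion_radius_px: int = 12
    lesion_kpa: float = 60.0
    ring_width_mm: float | None = 1.0
    ring_kpa: float | None = 90.0
    jitter_sigma_kpa: float = 2.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        for name in ("background_kpa", "lesion_kpa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if (self.ring_width_mm is None) != (self.ring_kpa is None):
            raise ValueError("ring_width_mm and ring_kpa must be set together")
        if self.ring_width_mm is not None and self.ring_width_mm <= 0:
            raise ValueError(f"ring_width_mm must be positive, got {self.ring_width_mm}")
        if self.ring_kpa is not None and self.ring_kpa <= 0:
            raise ValueError(f"ring_kpa must be positive, got {self.ring_kpa}")
        if self.jitter_sigma_kpa < 0:
            raise ValueError(f"jitter_sigma_kpa must be >= 0, got {self.jitter_sigma_kpa}")
        cy, cx = self.lesion_center
        r = self.lesion_radius_px
        if r < 1:
            raise ValueError(f"lesion_radius_px must be >= 1, got {r}")
        if not (cy - r >= 0 and cy + r < self.height and cx - r >= 0 and cx + r < self.width):
            raise ValueError("lesion disk must lie fully inside the image")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group Gaussian cohort for a per-subject scalar measurement.

    ``effect_size`` is the case-minus-control mean difference in units of
    the common standard deviation ``base_sd``. Defaults emulate a
    50-patient / 50-control dermal-thickness comparison in which the
    sclerotic-stage lesional skin is roughly 50% thicker than control
    skin (base 1.3 mm, sd 0.3 mm, effect 2.2 sd ≈ +0.66 mm ≈ +51%).
    """

    n_cases: int = 50
    n_controls: int = 50
    effect_size: float = 2.2
    base_mean: float = 1.3
    base_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        if self.base_sd <= 0:
            raise ValueError(f"base_sd must be positive, got {self.base_sd}")


def make_skin_phantom(
    spec: SkinPhantomSpec, seed: int
) -> tuple[Image2D, dict[str, float]]:
    """Generate a layered B-mode skin phantom and its ground truth.

    Returns the image plus a dict with ``entry_depth_px``,
    ``dermis_base_depth_px`` and ``thickness_mm``. Bit-identical for
    identical (spec, seed).
    """
    gel, dermis, subcutis = spec.layer_intensities
    img = np.empty((spec.height, spec.width), dtype=np.float64)
    img[: spec.entry_depth_px, :] = gel
    img[spec.entry_depth_px : spec.dermis_base_depth_px, :] = dermis
    img[spec.dermis_base_depth_px :, :] = subcutis
    if spec.texture_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, spec.texture_sigma, size=img.shape)
    truth = {
        "entry_depth_px": float(spec.entry_depth_px),
        "dermis_base_depth_px": float(spec.dermis_base_depth_px),
        "thickness_mm": spec.thickness_mm,
    }
    return Image2D(img, pixel_spacing=spec.pixel_spacing), truth


def add_noise(image: Image2D, noise: NoiseSpec, seed: int) -> Image2D:
    """Apply the noise model; same (image, noise, seed) → identical realization."""
    rng = np.random.default_rng(seed)
    if noise.sigma == 0:
        out = image.pixels.copy()
    elif noise.kind == "additive_gaussian":
        out = image.pixels + rng.normal(0.0, noise.sigma, size=image.shape)
    else:  # speckle_multiplicative
        out = image.pixels * (1.0 + noise.sigma * rng.normal(0.0, 1.0, size=image.shape))
    if noise.clip_range is not None:
        lo, hi = noise.clip_range
        out = np.clip(out, lo, hi)
    return image.with_pixels(out)


def make_elasticity_phantom(
    spec: ElasticityPhantomSpec, seed: int
) -> tuple[ElasticityMap, LesionMask]:
    """Generate an elasticity map (kPa) and the lesion-disk mask.

    The mask marks the lesion disk only; the ring band, if configured,
    is part of the map but not of the mask (it is what ``shell_ring``
    recovers downstream).
    """
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = spec.lesion_center
    dist = np.hypot(yy - cy, xx - cx)
    values = np.full((spec.height, spec.width), spec.background_kpa, dtype=np.float64)
    lesion = dist <= spec.lesion_radius_px
    values[lesion] = spec.lesion_kpa
    if spec.ring_width_mm is not None:
        ring_px = spec.ring_width_mm / spec.pixel_spacing
        band = (~lesion) & (dist <= spec.lesion_radius_px + ring_px)
        values[band] = spec.ring_kpa
    if spec.jitter_sigma_kpa > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.jitter_sigma_kpa, size=values.shape)
        values = np.maximum(values, 0.1)  # moduli stay physically positive
    return ElasticityMap(values, pixel_spacing=spec.pixel_spacing), LesionMask(lesion)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a two-group cohort table (subject_id, group, measurement)."""
    rng = np.random.default_rng(spec.seed)
    controls = rng.normal(spec.base_mean, spec.base_sd, size=spec.n_controls)
    cases = rng.normal(
        spec.base_mean + spec.effect_size * spec.base_sd, spec.base_sd, size=spec.n_cases
    )
    rows = [
        {"subject_id": f"C{i + 1:03d}", "group": "control", "measurement": v}
        for i, v in enumerate(controls)
    ] + [
        {"subject_id": f"P{i + 1:03d}", "group": "case", "measurement": v}
        for i, v in enumerate(cases)
    ]
    return pd.DataFrame(rows, columns=["subject_id", "group", "measurement"])


# ---------------------------------------------------------------------------
# File interchange: TIFF images, PNG masks, JSON specs.

def save_image_tiff(path, image: Image2D, dtype: str = "float32") -> None:
    import tifffile

    arr = image.pixels
    if dtype == "float32":
        arr = arr.astype(np.float32)
    elif dtype == "uint8":
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    elif dtype == "uint16":
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    meta = {}
    if image.pixel_spacing is not None:
        meta = {"pixel_spacing_mm": image.pixel_spacing}
    tifffile.imwrite(str(path), arr, metadata=meta)


def load_image_tiff(path, pixel_spacing: float | None = None) -> Image2D:
    import tifffile

    arr = tifffile.imread(str(path))
    if pixel_spacing is None:
        try:
            with tifffile.TiffFile(str(path)) as tf:
                meta = tf.shaped_metadata or tf.imagej_metadata
                if meta:
                    entry = meta[0] if isinstance(meta, (list, tuple)) else meta
                    pixel_spacing = entry.get("pixel_spacing_mm")
        except Exception:
            pixel_spacing = None
    return Image2D(np.asarray(arr, dtype=np.float64), pixel_spacing=pixel_spacing)


def save_mask_png(path, mask: LesionMask) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def load_mask_png(path) -> LesionMask:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return LesionMask(arr > 127)


_SPEC_TYPES = {
    "NoiseSpec": NoiseSpec,
    "SkinPhantomSpec": SkinPhantomSpec,
    "ElasticityPhantomSpec": ElasticityPhantomSpec,
    "CohortSpec": CohortSpec,
}


def spec_to_json(spec: Any) -> str:
    """Serialize any phantom spec to a JSON string (round-trips with spec_from_json)."""
    name = type(spec).__name__
    if name not in _SPEC_TYPES:
        raise TypeError(f"not a phantom spec: {name}")
    return json.dumps({"type": name, **dataclasses.asdict(spec)})


def spec_from_json(text: str) -> Any:
    payload = json.loads(text)
    name = payload.pop("type", None)
    cls = _SPEC_TYPES.get(name)
    if cls is None:
        raise ValueError(f"unknown spec type: {name!r}")
    for key in ("clip_range", "layer_intensities", "lesion_center"):
        if key in payload and isinstance(payload[key], list):
            payload[key] = tuple(payload[key])
    return cls(**payload)
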