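"""Synthetic two-domain image benchmark with a shared class space.

Real camera-trap collections from different networks share species but
differ in backgrounds, lighting and shooting scale.  This module emulates
exactly that structure with parametric glyphs (one glyph family per class)
rendered onto procedural backgrounds, so the whole adaptation pipeline can
be exercised deterministically without photographic data.

What shifts between domains (nuisance parameters only — label k always
means the same glyph):

* background texture family (smooth blobby noise vs. oriented stripes),
* overall brightness (day vs. dusk),
* object scale range (near vs. far subjects),
* object hue (film/terrain color cast).

Everything is a pure function of (spec, seed): per-image RNG streams are
spawned from a seed sequence keyed by (domain, class, index), so output is
byte-identical across runs and independent of generation order.
"""

from __future__ import annotations

import colorsys
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "DomainParams",
    "DomainShiftSpec",
    "generate_arrays",
    "generate_dataset",
    "render_image",
    "shift_severity",
]

DOMAINS = ("source", "target")


@dataclass(frozen=True)
class DomainParams:
    """Nuisance parameters of one domain."""

    texture: str = "blobs"  # "blobs" | "stripes" | "plain"
    brightness: float = 0.62  # mean background luminance in [0, 1]
    scale_range: tuple[float, float] = (0.45, 0.70)  # object diameter / image size
    hue: float = 0.08  # object hue on the [0, 1) color circle

    def __post_init__(self):
        if self.texture not in ("blobs", "stripes", "plain"):
            raise ValueError(f"unknown texture family {self.texture!r}")
        lo, hi = self.scale_range
        if not (0 < lo <= hi < 1):
            raise ValueError("scale_range must satisfy 0 < lo <= hi < 1")


_HIGH_SHIFT_TARGET = DomainParams(
    texture="stripes", brightness=0.52, scale_range=(0.36, 0.58), hue=0.30
)


@dataclass(frozen=True)
class DomainShiftSpec:
    """Benchmark specification: class space plus per-domain nuisances.

    The class space is identical across domains by construction; only the
    nuisance parameters differ.  Defaults give the high-severity benchmark
    (all four nuisance factors shifted) at desk scale: 11 classes, 64x64.
    ``class_weights`` optionally skews the per-class counts (both domains
    equally); by default classes are balanced.
    """

    n_classes: int = 11
    img_size: int = 64
    n_per_class_per_domain: int = 40
    seed: int = 0
    source: DomainParams = field(default_factory=DomainParams)
    target: DomainParams = field(default_factory=lambda: _HIGH_SHIFT_TARGET)
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_classes > len(_GLYPHS):
            raise ValueError(f"at most {len(_GLYPHS)} glyph classes are available")
        if self.class_weights is not None and len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights must have one entry per class")

    def params(self, domain: str) -> DomainParams:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return self.source if domain == "source" else self.target

    def counts(self) -> np.ndarray:
        """Images per class (per domain)."""
        if self.class_weights is None:
            return np.full(self.n_classes, self.n_per_class_per_domain, dtype=int)
        w = np.asarray(self.class_weights, dtype=float)
        n = np.maximum(1, np.round(w / w.max() * self.n_per_class_per_domain)).astype(int)
        return n

    def with_severity(self, severity: float) -> "DomainShiftSpec":
        """Interpolate the target nuisances from none (0) to the full shift (1)."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        s, hi = self.source, _HIGH_SHIFT_TARGET
        lo_s, hi_s = s.scale_range
        lo_h, hi_h = hi.scale_range
        target = DomainParams(
            texture=s.texture if severity < 0.5 else hi.texture,
            brightness=s.brightness + severity * (hi.brightness - s.brightness),
            scale_range=(
                lo_s + severity * (lo_h - lo_s),
                hi_s + severity * (hi_h - hi_s),
            ),
            hue=s.hue + severity * (hi.hue - s.hue),
        )
        return dataclasses.replace(self, target=target)


def _circular_gap(a: float, b: float) -> float:
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)


def shift_severity(spec: DomainShiftSpec) -> float:
    """Normalized L2 of the nuisance-parameter gaps; 0 iff domains identical."""
    s, t = spec.source, spec.target
    mid = lambda r: (r[0] + r[1]) / 2.0
    components = np.array(
        [
            0.0 if s.texture == t.texture else 1.0,
            abs(s.brightness - t.brightness) / 0.5,
            abs(mid(s.scale_range) - mid(t.scale_range)) / 0.3,
            _circular_gap(s.hue, t.hue) / 0.5,
        ]
    )
    return float(np.linalg.norm(components) / np.sqrt(len(components)))


# -- glyph geometry ------------------------------------------------------------
# every glyph is a list of (points_fn, additive) parts in a unit circle frame


def _regular_polygon(n: int, phase: float = -np.pi / 2, aspect: float = 1.0) -> np.ndarray:
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.stack([np.cos(ang), aspect * np.sin(ang)], axis=1)


def _star(n: int, inner: float = 0.45) -> np.ndarray:
    ang = -np.pi / 2 + np.pi * np.arange(2 * n) / n
    r = np.where(np.arange(2 * n) % 2 == 0, 1.0, inner)
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


def _circle(r: float = 1.0, cx: float = 0.0, cy: float = 0.0, n: int = 48) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack([cx + r * np.cos(ang), cy + r * np.sin(ang)], axis=1)


def _rect(w: float, h: float, cx: float = 0.0, cy: float = 0.0) -> np.ndarray:
    return np.array(
        [[cx - w, cy - h], [cx + w, cy - h], [cx + w, cy + h], [cx - w, cy + h]]
    )


_GLYPHS: list[list[tuple[np.ndarray, bool]]] = [
    [(_circle(), True)],
    [(_regular_polygon(48, aspect=0.42), True)],  # elongated ellipse
    [(_regular_polygon(3), True)],
    [(_regular_polygon(4, phase=np.pi / 4), True)],  # axis-aligned square
    [(_regular_polygon(5), True)],
    [(_star(5), True)],
    [(_rect(1.0, 0.3), True), (_rect(0.3, 1.0), True)],  # cross
    [(_circle(), True), (_circle(0.55), False)],  # ring
    [(_rect(1.0, 0.22), True)],  # thin bar
    [(_circle(), True), (_circle(0.85, cx=0.5), False)],  # crescent
    [(_circle(0.38, cx=-0.6), True), (_circle(0.38, cx=0.6), True), (_circle(0.38, cy=0.62), True)],  # triple dot
]


def _background(rng: np.random.Generator, size: int, params: DomainParams) -> np.ndarray:
    base = params.brightness + rng.uniform(-0.05, 0.05)
    img = np.full((size, size, 3), base, dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size] / size
    if params.texture == "blobs":
        coarse = rng.normal(0.0, 1.0, size=(size, size))
        smooth = gaussian_filter(coarse, sigma=size / 9.0, mode="reflect")
        smooth = smooth / (np.abs(smooth).max() + 1e-9)
        img += 0.16 * smooth[..., None]
    elif params.texture == "stripes":
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(3.0, 6.0)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
        img += 0.14 * wave[..., None]
    # mild color cast so backgrounds are not pure gray
    cast = rng.uniform(-0.04, 0.04, size=3)
    img += cast
    return img


def _object_color(rng: np.random.Generator, params: DomainParams) -> np.ndarray:
    hue = (params.hue + rng.uniform(-0.04, 0.04)) % 1.0
    sat = rng.uniform(0.30, 0.50)
    # subjects are darker than their background in every domain (consistent
    # contrast polarity); how much darker tracks the scene brightness
    val = float(np.clip(params.brightness - rng.uniform(0.25, 0.40), 0.05, 0.95))
    return np.array(colorsys.hsv_to_rgb(hue, sat, val))


def _glyph_mask(rng: np.random.Generator, size: int, class_id: int, params: DomainParams) -> np.ndarray:
    """Rasterize the class glyph with per-image scale/position/rotation jitter."""
    ss = 2  # supersampling factor for soft edges
    big = size * ss
    scale = rng.uniform(*params.scale_range)
    radius = scale * size / 2.0
    margin = radius + 2
    cx = rng.uniform(margin, size - margin) if size - margin > margin else size / 2.0
    cy = rng.uniform(margin, size - margin) if size - margin > margin else size / 2.0
    theta = rng.uniform(-0.35, 0.35)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mask = Image.new("L", (big, big), 0)
    from PIL import ImageDraw

    draw = ImageDraw.Draw(mask)
    for points, additive in _GLYPHS[class_id]:
        pts = (points @ rot.T) * radius + np.array([cx, cy])
        pts = [tuple(p * ss) for p in pts]
        draw.polygon(pts, fill=255 if additive else 0)
    arr = np.asarray(mask, dtype=np.float64) / 255.0
    return arr.reshape(size, ss, size, ss).mean(axis=(1, 3))


def _image_rng(spec: DomainShiftSpec, domain: str, class_id: int, index: int) -> np.random.Generator:
    key = (DOMAINS.index(domain), class_id, index)
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=key))


def render_image(spec: DomainShiftSpec, domain: str, class_id: int, index: int) -> np.ndarray:
    """Render one image as a (size, size, 3) uint8 array."""
    if not 0 <= class_id < spec.n_classes:
        raise ValueError("class_id out of range")
    params = spec.params(domain)
    rng = _image_rng(spec, domain, class_id, index)
    bg = _background(rng, spec.img_size, params)
    color = _object_color(rng, params)
    mask = _glyph_mask(rng, spec.img_size, class_id, params)[..., None]
    img = bg * (1.0 - mask) + color * mask
    img += rng.normal(0.0, 0.015, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def generate_arrays(spec: DomainShiftSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Render the full benchmark in memory: domain -> (images, labels)."""
    out = {}
    counts = spec.counts()
    for domain in DOMAINS:
        images, labels = [], []
        for k in range(spec.n_classes):
            for i in range(counts[k]):
                images.append(render_image(spec, domain, k, i))
                labels.append(k)
        out[domain] = (np.stack(images), np.asarray(labels, dtype=np.int64))
    return out


def generate_dataset(spec: DomainShiftSpec, out_dir) -> pd.DataFrame:
    """Write PNGs as ``<domain>/class_<k>/img_<i>.png`` plus a manifest CSV.

    Returns the manifest (columns path, label, domain; paths relative to
    ``out_dir``).  Also serializes the spec alongside for provenance.
    Output is byte-identical for identical (spec, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counts = spec.counts()
    for domain in DOMAINS:
        for k in range(spec.n_classes):
            cls_dir = out_dir / domain / f"class_{k:02d}"
            cls_dir.mkdir(parents=True, exist_ok=True)
            for i in range(counts[k]):
                rel = f"{domain}/class_{k:02d}/img_{i:04d}.png"
                Image.fromarray(render_image(spec, domain, k, i)).save(out_dir / rel)
                rows.append({"path": rel, "label": k, "domain": domain})
    manifest = pd.DataFrame(rows, columns=["path", "label", "domain"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    for domain in DOMAINS:
        manifest[manifest.domain == domain].to_csv(out_dir / f"{domain}.csv", index=False)
    spec_dict = dataclasses.asdict(spec)
    (out_dir / "spec.json").write_text(json.dumps(spec_dict, indent=2, default=list))
    return manifest
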