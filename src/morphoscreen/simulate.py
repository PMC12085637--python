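"""Procedural generator of synthetic brightfield frames for five morphotypes.

Each class renders a distinct texture on a noisy, unevenly illuminated
background, mimicking how the corresponding cell states look under
transmitted light:

* ``apo`` (apoptosis)   — clusters of small, high-contrast round bodies
  (apoptotic-body accumulation);
* ``fer`` (ferroptosis) — large, smooth, bright discs ("ballooning");
* ``nec`` (necroptosis) — rounded cells with ragged, blebbed outlines and
  no satellite bodies;
* ``aut`` (autophagy)   — elongated spindles containing small dark vacuoles;
* ``hea`` (healthy)     — elongated, adherent, low-contrast cells.

Intensities live in a floating [0, 1] range internally; writers quantize to
16-bit TIFF.  Rendering is fully deterministic: an identical
:class:`SceneSpec` (seed included) produces bit-identical frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .labels import CLASSES, check_label
from .patches import BrightfieldImage

BACKGROUND = 0.55
_EDGE = 1.5  # soft-edge width in px for anti-aliased masks


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic frame.

    Phenotype knobs (``apo_body_count``, ``aut_vacuole_density``,
    ``nec_bleb_amplitude``) default to values that keep the five classes
    visually and statistically well separated.
    """

    class_label: str
    frame_height: int = 1040
    frame_width: int = 1408
    cell_count: int = 60
    size_mean: float = 36.0
    size_sd: float = 8.0
    noise_sd: float = 0.02
    illumination_gradient: float = 0.08
    seed: int = 0
    apo_body_count: int = 9
    aut_vacuole_density: float = 0.12  # vacuoles per px of spindle length
    nec_bleb_amplitude: float = 0.22   # fractional radial modulation

    def __post_init__(self) -> None:
        check_label(self.class_label)
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")
        if self.frame_height < 224 or self.frame_width < 224:
            raise ValueError(
                f"frame must be at least 224x224, got "
                f"{self.frame_height}x{self.frame_width}"
            )
        if self.size_mean <= 0:
            raise ValueError("size_mean must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruthRecord:
    """Per-frame ground truth: label, cell geometry and generator parameters."""

    image_id: str
    class_label: str
    centers: list[tuple[float, float]]  # (x, y) px
    radii: list[float]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# drawing primitives (all operate in-place on a float frame)


def _soft_mask_disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    d = np.hypot(yy - cy, xx - cx)
    return np.clip((r + _EDGE - d) / (2 * _EDGE), 0.0, 1.0)


def _blend(frame: np.ndarray, sl: tuple[slice, slice], mask: np.ndarray, value: float, opacity: float = 1.0) -> None:
    a = opacity * mask
    frame[sl] = frame[sl] * (1 - a) + value * a


def _bbox(frame: np.ndarray, cy: float, cx: float, r: float):
    h, w = frame.shape
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    if y0 >= y1 or x0 >= x1:
        return None
    sl = (slice(y0, y1), slice(x0, x1))
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    return sl, yy, xx


def _draw_disc(frame, cy, cx, r, value, opacity=1.0):
    box = _bbox(frame, cy, cx, r + 2 * _EDGE)
    if box is None:
        return
    sl, yy, xx = box
    _blend(frame, sl, _soft_mask_disc(yy, xx, cy, cx, r), value, opacity)


def _draw_ring(frame, cy, cx, r, width, value, opacity=1.0):
    box = _bbox(frame, cy, cx, r + width + 2 * _EDGE)
    if box is None:
        return
    sl, yy, xx = box
    d = np.hypot(yy - cy, xx - cx)
    mask = np.clip((width / 2 + _EDGE - np.abs(d - r)) / (2 * _EDGE), 0.0, 1.0)
    _blend(frame, sl, mask, value, opacity)


def _draw_ellipse(frame, cy, cx, a, b, theta, value, opacity=1.0):
    """Soft-edged filled ellipse with semi-axes a (major) and b (minor)."""
    reach = a + 2 * _EDGE
    box = _bbox(frame, cy, cx, reach)
    if box is None:
        return
    sl, yy, xx = box
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    # signed distance approximated via normalized quadratic form
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    mask = np.clip((1 + _EDGE / b - q) * (b / _EDGE) / 2, 0.0, 1.0)
    _blend(frame, sl, mask, value, opacity)


# ---------------------------------------------------------------------------
# per-class renderers; each returns the effective footprint radius


def _render_hea(frame, rng, cy, cx, s):
    theta = rng.uniform(0, np.pi)
    a, b = s, max(3.0, s / 3.0)
    _draw_ellipse(frame, cy, cx, a, b, theta, BACKGROUND - 0.09, opacity=0.8)
    _draw_ellipse(frame, cy, cx, a * 0.45, b * 0.55, theta, BACKGROUND - 0.16, opacity=0.6)
    return a


def _render_apo(frame, rng, cy, cx, s, body_count):
    n = max(3, int(rng.poisson(body_count)))
    spread = s * 0.9
    for _ in range(n):
        ang = rng.uniform(0, 2 * np.pi)
        rad = spread * np.sqrt(rng.uniform(0, 1.0))
        by, bx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        rb = max(2.5, s / 5.5 + rng.normal(0, s / 22))
        _draw_disc(frame, by, bx, rb * 1.35, 0.18, opacity=0.9)  # dark halo
        _draw_disc(frame, by, bx, rb, 0.92, opacity=0.95)        # bright body
    return spread


def _render_fer(frame, rng, cy, cx, s):
    r = 1.5 * s
    _draw_ring(frame, cy, cx, r, 3.0, 0.22, opacity=0.9)
    _draw_disc(frame, cy, cx, r - 2.0, 0.86, opacity=0.95)
    # faint internal shading keeps the disc smooth but not flat
    _draw_disc(frame, cy, cx, r * 0.35, 0.78, opacity=0.35)
    return r


def _render_nec(frame, rng, cy, cx, s, bleb_amplitude):
    box = _bbox(frame, cy, cx, s * (1 + bleb_amplitude) + 3 * _EDGE)
    if box is None:
        return s
    sl, yy, xx = box
    phi = np.arctan2(yy - cy, xx - cx)
    # ragged outline: random low-order harmonics of the angular coordinate
    r_phi = np.full_like(phi, float(s))
    for k in range(4, 9):
        amp = bleb_amplitude * s * rng.uniform(0.2, 0.5)
        r_phi += amp * np.sin(k * phi + rng.uniform(0, 2 * np.pi))
    d = np.hypot(yy - cy, xx - cx)
    mask = np.clip((r_phi + _EDGE - d) / (2 * _EDGE), 0.0, 1.0)
    _blend(frame, sl, mask, 0.38, opacity=0.9)
    inner = np.clip((r_phi * 0.55 + _EDGE - d) / (2 * _EDGE), 0.0, 1.0)
    _blend(frame, sl, inner, 0.30, opacity=0.5)
    return s * (1 + bleb_amplitude)


def _render_aut(frame, rng, cy, cx, s, vacuole_density):
    theta = rng.uniform(0, np.pi)
    a, b = 1.6 * s, max(3.0, s / 4.5)
    _draw_ellipse(frame, cy, cx, a, b, theta, 0.42, opacity=0.85)
    n_vac = max(2, int(round(vacuole_density * 2 * a)))
    ct, st = np.cos(theta), np.sin(theta)
    for _ in range(n_vac):
        t = rng.uniform(-0.85, 0.85) * a
        off = rng.uniform(-0.5, 0.5) * b
        vy = cy + t * st + off * ct
        vx = cx + t * ct - off * st
        _draw_disc(frame, vy, vx, max(1.8, s / 11), 0.15, opacity=0.9)
    return a


# ---------------------------------------------------------------------------


def _place_centers(rng, spec: SceneSpec, footprint: float) -> list[tuple[float, float]]:
    """Rejection-sampled centers keeping cells mostly non-overlapping."""
    h, w = spec.frame_height, spec.frame_width
    margin = min(footprint, min(h, w) / 2 - 1)
    centers: list[tuple[float, float]] = []
    min_sep = 1.9 * footprint
    for _ in range(spec.cell_count):
        for _attempt in range(200):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep**2 for py, px in centers):
                break
        centers.append((cy, cx))
    return centers


_FOOTPRINT_SCALE = {"apo": 0.9, "aut": 1.6, "fer": 1.5, "hea": 1.0, "nec": 1.25}


def simulate_scene(spec: SceneSpec) -> tuple[BrightfieldImage, GroundTruthRecord]:
    """Render one labeled synthetic frame.

    Returns the frame (intensities clipped to [0, 1]) together with its
    ground-truth record (cell centers, footprint radii, parameters).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_height, spec.frame_width
    frame = np.full((h, w), BACKGROUND, dtype=np.float32)

    if spec.illumination_gradient > 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy = np.linspace(-0.5, 0.5, h, dtype=np.float32)[:, None]
        xx = np.linspace(-0.5, 0.5, w, dtype=np.float32)[None, :]
        ramp = np.sin(angle) * yy + np.cos(angle) * xx
        frame += spec.illumination_gradient * ramp.astype(np.float32)

    footprint = _FOOTPRINT_SCALE[spec.class_label] * spec.size_mean
    centers = _place_centers(rng, spec, footprint)
    radii: list[float] = []
    for cy, cx in centers:
        s = float(np.clip(rng.normal(spec.size_mean, spec.size_sd), 6.0, 3 * spec.size_mean))
        if spec.class_label == "hea":
            r = _render_hea(frame, rng, cy, cx, s)
        elif spec.class_label == "apo":
            r = _render_apo(frame, rng, cy, cx, s, spec.apo_body_count)
        elif spec.class_label == "fer":
            r = _render_fer(frame, rng, cy, cx, s)
        elif spec.class_label == "nec":
            r = _render_nec(frame, rng, cy, cx, s, spec.nec_bleb_amplitude)
        else:
            r = _render_aut(frame, rng, cy, cx, s, spec.aut_vacuole_density)
        radii.append(float(r))

    if spec.noise_sd > 0:
        frame += rng.normal(0.0, spec.noise_sd, size=frame.shape).astype(np.float32)
    np.clip(frame, 0.0, 1.0, out=frame)

    image_id = f"{spec.class_label}_s{spec.seed}"
    image = BrightfieldImage(
        image_id=image_id, pixels=frame, hour=None, condition=spec.class_label
    )
    record = GroundTruthRecord(
        image_id=image_id,
        class_label=spec.class_label,
        centers=[(float(cx), float(cy)) for cy, cx in centers],
        radii=radii,
        params=asdict(spec),
    )
    return image, record


def mix_seed(base_seed: int, index: int) -> int:
    """Splitmix-style integer mixing for reproducible per-frame seeds."""
    mask = (1 << 64) - 1
    z = (base_seed + 0x9E3779B97F4A7C15 * (index + 1)) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z ^= z >> 31
    return int(z % (1 << 31))


def iter_simulated(
    per_class_counts: Mapping[str, int],
    base_seed: int = 0,
    hour: int | None = 8,
    **spec_overrides,
):
    """Lazily generate a labeled frame collection, one seed per frame.

    Frame seeds are derived from ``base_seed`` by splitmix-style mixing, so
    two runs with the same base seed produce identical collections.  By
    default frames carry the 8-hour acquisition label, the time point used
    for training.  Yields ``(BrightfieldImage, GroundTruthRecord)`` pairs;
    streaming keeps memory flat for large collections.
    """
    index = 0
    for label in CLASSES:
        n = int(per_class_counts.get(label, 0))
        if n < 0:
            raise ValueError("per-class counts must be >= 0")
        for k in range(n):
            spec = SceneSpec(
                class_label=label, seed=mix_seed(base_seed, index), **spec_overrides
            )
            image, record = simulate_scene(spec)
            image.image_id = f"{label}_{k:04d}"
            image.hour = hour
            record.image_id = image.image_id
            yield image, record
            index += 1


def dataset_image_ids(per_class_counts: Mapping[str, int]) -> dict[str, list[str]]:
    """The image ids :func:`iter_simulated` will assign, per class."""
    return {
        label: [f"{label}_{k:04d}" for k in range(int(per_class_counts.get(label, 0)))]
        for label in CLASSES
    }


def simulate_dataset(
    per_class_counts: Mapping[str, int],
    base_seed: int = 0,
    hour: int | None = 8,
    **spec_overrides,
) -> list[tuple[BrightfieldImage, GroundTruthRecord]]:
    """Eager counterpart of :func:`iter_simulated`."""
    return list(iter_simulated(per_class_counts, base_seed, hour, **spec_overrides))


# ---------------------------------------------------------------------------
# dataset writers


def write_dataset(
    pairs: list[tuple[BrightfieldImage, GroundTruthRecord]],
    outdir: str | Path,
    image_format: str = "tiff",
) -> Path:
    """Write frames (16-bit TIFF or PNG), ground-truth CSV and a manifest.

    Returns the manifest CSV path.
    """
    outdir = Path(outdir)
    frames_dir = outdir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    gt_rows = []
    for image, record in pairs:
        quantized = np.round(image.pixels * 65535).astype(np.uint16)
        if image_format == "tiff":
            import tifffile

            path = frames_dir / f"{image.image_id}.tiff"
            tifffile.imwrite(path, quantized)
        elif image_format == "png":
            import imageio.v3 as iio

            path = frames_dir / f"{image.image_id}.png"
            iio.imwrite(path, quantized)
        else:
            raise ValueError(f"unsupported image format {image_format!r}")
        manifest_rows.append(
            {
                "image_id": image.image_id,
                "path": str(path.relative_to(outdir)),
                "well": image.well_id,
                "hour": image.hour,
                "condition": image.condition,
            }
        )
        for (cx, cy), r in zip(record.centers, record.radii):
            gt_rows.append(
                {
                    "image_id": image.image_id,
                    "class": record.class_label,
                    "center_x": round(cx, 2),
                    "center_y": round(cy, 2),
                    "radius": round(r, 2),
                }
            )
    manifest_csv = outdir / "manifest.csv"
    pd.DataFrame(
        manifest_rows, columns=["image_id", "path", "well", "hour", "condition"]
    ).to_csv(manifest_csv, index=False)
    pd.DataFrame(
        gt_rows, columns=["image_id", "class", "center_x", "center_y", "radius"]
    ).to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps({"n_frames": len(pairs), "frames": manifest_rows}, indent=1)
    )
    return manifest_csv
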