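"""Synthetic phase-contrast slide generator with pixel-exact ground truth.

Emulates the appearance of mycelial particles of filamentous microorganisms
(e.g. *Streptomyces*) in ×10 phase-contrast whole-slide images: a pellet shows
relatively dark protruding hyphae around its rim, then a brighter ring where
the dense region starts, followed by a darker interior.  Contaminant artifacts
(air bubbles, fibers, debris) are rendered with the geometry that the
downstream size and rule-set filters are designed to reject.

No optical physics is simulated — no point-spread function and no true
phase-contrast transfer function.  The generator produces intensity patterns
with the qualitative structure above plus additive Gaussian noise, which is
sufficient to exercise thresholding, watershed separation and the radial band
profiler, together with an exact per-object pixel mask as ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.78
"""Default calibration: 780 nm per pixel (×10 objective)."""

BACKGROUND_INTERVAL = (50, 90)
"""Grey-value interval treated as background by the default segmentation."""

FRAGMENT_CUTOFF_UM = 150.0
"""Operational split between mycelial fragments and pellets (max length)."""


# ---------------------------------------------------------------------------
# Object specifications


@dataclass(frozen=True)
class PelletSpec:
    """One synthetic pellet (or, if small, mycelial fragment).

    The rendered particle is a disk of ``core_radius_um`` with a bright ring
    placed ``ring_depth_fraction`` of the radius inside the disk edge, a
    dark fringe zone between ring and edge, a darker core inside the ring,
    and ``n_hyphae`` jagged dark filaments protruding radially outward.
    """

    center: tuple[float, float]  # (row, col) in px
    core_radius_um: float
    ring_depth_fraction: float = 0.2
    core_intensity: float = 65.0
    ring_intensity: float = 120.0
    fringe_intensity: float = 40.0
    n_hyphae: int = 8
    hypha_length_um: float = 15.0
    hypha_thickness_px: float = 2.0
    ring_width_px: float = 12.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ring_depth_fraction <= 1.0):
            raise ValueError("ring_depth_fraction must lie in [0, 1]")
        if self.ring_intensity <= self.core_intensity:
            raise ValueError("ring intensity must exceed core intensity")
        if self.core_radius_um <= 0:
            raise ValueError("core radius must be positive")

    def extent_um(self) -> float:
        """Maximum tip-to-tip length of the rendered particle."""
        return 2.0 * (self.core_radius_um + self.hypha_length_um)

    @property
    def kind(self) -> str:
        """'fragment' below the 150 µm length cutoff, 'pellet' above."""
        return "fragment" if self.extent_um() < FRAGMENT_CUTOFF_UM else "pellet"


@dataclass(frozen=True)
class ArtifactSpec:
    """A contaminant object: air bubble, fiber (e.g. cotton) or cell debris.

    Invariants mirror what the pipeline's filters assume: bubbles are larger
    than 900 µm across, debris is smaller than 200 px, fibers are at least
    10× longer than wide.
    """

    kind: str  # "bubble" | "fiber" | "debris"
    center: tuple[float, float]
    bubble_diameter_um: float = 1000.0
    bubble_ring_width_px: float = 6.0
    fiber_length_px: float = 300.0
    fiber_width_px: float = 10.0
    fiber_angle_deg: float = 0.0
    debris_area_px: float = 120.0
    intensity: float = 35.0

    def __post_init__(self) -> None:
        if self.kind not in ("bubble", "fiber", "debris"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.kind == "bubble" and self.bubble_diameter_um <= 900.0:
            raise ValueError("bubble diameter must exceed 900 µm")
        if self.kind == "debris" and self.debris_area_px >= 200.0:
            raise ValueError("debris area must be below 200 px")
        if self.kind == "fiber" and self.fiber_length_px < 10.0 * self.fiber_width_px:
            raise ValueError("fiber elongation (length/width) must be >= 10")


@dataclass(frozen=True)
class SynthSpec:
    """Complete description of one synthetic slide image.

    The seed fully determines both the image and the ground truth; an
    identical spec always renders bit-identically.
    """

    shape: tuple[int, int]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    background: float = 70.0
    noise_sd: float = 2.0
    pellets: tuple[PelletSpec, ...] = ()
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0
    dtype: str = "uint8"

    def __post_init__(self) -> None:
        lo, hi = BACKGROUND_INTERVAL
        if not (lo <= self.background <= hi):
            raise ValueError(
                f"background grey level must lie in the background interval "
                f"[{lo}, {hi}], got {self.background}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        vmax = np.iinfo(np.dtype(self.dtype)).max
        for p in self.pellets:
            for v in (p.core_intensity, p.ring_intensity, p.fringe_intensity):
                if not (0 <= v <= vmax):
                    raise ValueError("pellet intensity outside image bit depth")
            if p.fringe_intensity >= self.background:
                raise ValueError(
                    "fringe intensity must be darker than the background "
                    "(hyphae image dark in phase contrast)"
                )
        for a in self.artifacts:
            if not (0 <= a.intensity <= vmax):
                raise ValueError("artifact intensity outside image bit depth")

    def objects(self) -> tuple:
        """All objects in rendering/label order: pellets first, then artifacts."""
        return tuple(self.pellets) + tuple(self.artifacts)


@dataclass
class GroundTruth:
    """Exact per-object masks and generating parameters for one slide."""

    label_map: np.ndarray  # uint16, 0 = background
    records: pd.DataFrame  # one row per object: label, kind, center, detail
    pixel_size_um: float

    def mask(self, label: int) -> np.ndarray:
        return self.label_map == label

    @property
    def foreground(self) -> np.ndarray:
        """Union of all object masks (every non-background pixel pre-noise)."""
        return self.label_map > 0

    def labels_of_kind(self, *kinds: str) -> list[int]:
        sel = self.records[self.records["kind"].isin(kinds)]
        return [int(v) for v in sel["label"]]


# ---------------------------------------------------------------------------
# Rendering helpers


def _window(shape, center, ext):
    """Integer bounding window [r0, r1) x [c0, c1) around center; None if it
    does not fit inside the canvas."""
    r0 = int(math.floor(center[0] - ext))
    r1 = int(math.ceil(center[0] + ext)) + 1
    c0 = int(math.floor(center[1] - ext))
    c1 = int(math.ceil(center[1] + ext)) + 1
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        return None
    return r0, r1, c0, c1


def _dist_grid(win, center):
    r0, r1, c0, c1 = win
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return np.hypot(rr - center[0], cc - center[1])


def _stamp_path(mask, win, points, radius):
    """Mark all pixels of the window-local mask within `radius` of any
    sample point of a polyline path."""
    r0, r1, c0, c1 = win
    rad = max(radius, 0.5)
    ir = int(math.ceil(rad))
    h, w = mask.shape
    for pr, pc in points:
        lr, lc = pr - r0, pc - c0
        a0, a1 = int(math.floor(lr)) - ir, int(math.ceil(lr)) + ir + 1
        b0, b1 = int(math.floor(lc)) - ir, int(math.ceil(lc)) + ir + 1
        a0, a1 = max(a0, 0), min(a1, h)
        b0, b1 = max(b0, 0), min(b1, w)
        if a0 >= a1 or b0 >= b1:
            continue
        rr, cc = np.mgrid[a0:a1, b0:b1]
        mask[a0:a1, b0:b1] |= np.hypot(rr - lr, cc - lc) <= rad


def _render_pellet(img, labels, spec: SynthSpec, obj: PelletSpec, label: int,
                   rng: np.random.Generator, index: int) -> None:
    px = spec.pixel_size_um
    radius = obj.core_radius_um / px
    hypha_len = obj.hypha_length_um / px
    ext = radius + hypha_len + obj.hypha_thickness_px + 2
    win = _window(img.shape, obj.center, ext)
    if win is None:
        raise ValueError(
            f"object {index} ({obj.kind}) extends outside the canvas"
        )
    r0, r1, c0, c1 = win
    d = _dist_grid(win, obj.center)

    disk = d <= radius
    ring_r = radius * (1.0 - obj.ring_depth_fraction)
    half_w = obj.ring_width_px / 2.0
    ring = np.abs(d - ring_r) <= half_w
    fringe_zone = disk & (d > ring_r + half_w)

    # hyphae: jagged radial random walks starting at the disk edge
    hyphae = np.zeros_like(disk)
    step = 2.0
    n_steps = max(1, int(round(hypha_len / step)))
    for _ in range(obj.n_hyphae):
        ang = rng.uniform(0.0, 2.0 * math.pi)
        pos = np.array([obj.center[0] + radius * math.sin(ang),
                        obj.center[1] + radius * math.cos(ang)])
        pts = [tuple(pos)]
        for _ in range(n_steps):
            ang += rng.normal(0.0, 0.2)
            pos = pos + step * np.array([math.sin(ang), math.cos(ang)])
            pts.append(tuple(pos))
        _stamp_path(hyphae, win, pts, obj.hypha_thickness_px / 2.0)
    hyphae &= ~disk

    view = img[r0:r1, c0:c1]
    view[disk] = obj.core_intensity
    view[fringe_zone] = obj.fringe_intensity
    view[ring & disk] = obj.ring_intensity
    view[hyphae] = obj.fringe_intensity
    labels[r0:r1, c0:c1][disk | hyphae] = label


def _render_artifact(img, labels, spec: SynthSpec, obj: ArtifactSpec,
                     label: int, rng: np.random.Generator, index: int) -> None:
    px = spec.pixel_size_um
    if obj.kind == "bubble":
        radius = obj.bubble_diameter_um / (2.0 * px)
        ext = radius + obj.bubble_ring_width_px + 1
        win = _window(img.shape, obj.center, ext)
        if win is None:
            raise ValueError(f"object {index} (bubble) extends outside the canvas")
        d = _dist_grid(win, obj.center)
        mask = np.abs(d - radius) <= obj.bubble_ring_width_px / 2.0
    elif obj.kind == "fiber":
        half = obj.fiber_length_px / 2.0
        theta = math.radians(obj.fiber_angle_deg)
        u = np.array([math.sin(theta), math.cos(theta)])
        ext = half + obj.fiber_width_px + 1
        win = _window(img.shape, obj.center, ext)
        if win is None:
            raise ValueError(f"object {index} (fiber) extends outside the canvas")
        r0, r1, c0, c1 = win
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rel = np.stack([rr - obj.center[0], cc - obj.center[1]], axis=-1)
        t = np.clip(rel @ u, -half, half)
        closest = t[..., None] * u
        dist = np.hypot(rel[..., 0] - closest[..., 0], rel[..., 1] - closest[..., 1])
        mask = dist <= obj.fiber_width_px / 2.0
    else:  # debris
        radius = math.sqrt(obj.debris_area_px / math.pi)
        ext = radius + 1
        win = _window(img.shape, obj.center, ext)
        if win is None:
            raise ValueError(f"object {index} (debris) extends outside the canvas")
        d = _dist_grid(win, obj.center)
        mask = d <= radius
    r0, r1, c0, c1 = win
    img[r0:r1, c0:c1][mask] = obj.intensity
    labels[r0:r1, c0:c1][mask] = label


# ---------------------------------------------------------------------------
# Public operations


def generate_image(spec: SynthSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one slide image plus its exact ground truth.

    Objects are rendered in spec order (pellets first, then artifacts); later
    objects overwrite earlier pixels.  The spec seed drives the single RNG
    used for both hyphal random walks and the additive noise, so identical
    specs produce bit-identical output.

    Raises ``ValueError`` naming the object index if any object would extend
    outside the canvas.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full(spec.shape, float(spec.background), dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.uint16)

    rows = []
    for index, obj in enumerate(spec.objects()):
        label = index + 1
        if isinstance(obj, PelletSpec):
            _render_pellet(img, labels, spec, obj, label, rng, index)
            detail = {
                "core_radius_um": obj.core_radius_um,
                "ring_depth_fraction": obj.ring_depth_fraction,
                "n_hyphae": obj.n_hyphae,
                "hypha_length_um": obj.hypha_length_um,
            }
            kind = obj.kind
        else:
            _render_artifact(img, labels, spec, obj, label, rng, index)
            detail = {
                "bubble_diameter_um": obj.bubble_diameter_um,
                "fiber_length_px": obj.fiber_length_px,
                "fiber_width_px": obj.fiber_width_px,
                "debris_area_px": obj.debris_area_px,
            }
            kind = obj.kind
        rows.append({
            "label": label,
            "kind": kind,
            "center_row_px": obj.center[0],
            "center_col_px": obj.center[1],
            "detail": json.dumps(detail, sort_keys=True),
        })

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vmax = np.iinfo(np.dtype(spec.dtype)).max
    out = np.clip(np.rint(img), 0, vmax).astype(spec.dtype)

    records = pd.DataFrame(
        rows, columns=["label", "kind", "center_row_px", "center_col_px", "detail"]
    )
    return out, GroundTruth(labels, records, spec.pixel_size_um)


def grid_footprint(tile_px: int, n: int, overlap_fraction: float) -> int:
    """Closed-form mosaic extent: tile + (n-1) * round(tile * (1 - overlap))."""
    step = int(round(tile_px * (1.0 - overlap_fraction)))
    return tile_px + (n - 1) * step


def meander_order(rows: int, cols: int):
    """Grid positions in meander (boustrophedon) acquisition order:
    row 0 left→right, row 1 right→left, and so on."""
    for r in range(rows):
        cs = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        for c in cs:
            yield (r, c)


def _derive_tile_size(extent: int, n: int, overlap_fraction: float) -> int:
    t = int(extent / (1.0 + (n - 1) * (1.0 - overlap_fraction))) + 2
    while t > 0 and grid_footprint(t, n, overlap_fraction) > extent:
        t -= 1
    if t <= 0:
        raise ValueError("cannot derive a positive tile size for this grid")
    return t


def generate_tile_grid(spec: SynthSpec, rows: int, cols: int,
                       overlap_fraction: float, out_dir,
                       tile_shape: tuple[int, int] | None = None) -> list[dict]:
    """Render a master slide and cut it into an overlapping tile grid.

    Tiles are crops of the single master image (so re-stitching at the same
    overlap reproduces it exactly), written as single-channel TIFFs in
    meander order together with a JSON manifest recording grid position and
    pixel offsets.  The master image, the ground-truth label map and a CSV of
    per-label parameters are written alongside.

    Returns the manifest (list of dicts, meander order).
    """
    from pathlib import Path

    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")

    master, truth = generate_image(spec)
    H, W = master.shape
    if tile_shape is None:
        th = _derive_tile_size(H, rows, overlap_fraction)
        tw = _derive_tile_size(W, cols, overlap_fraction)
    else:
        th, tw = tile_shape
    foot_h = grid_footprint(th, rows, overlap_fraction)
    foot_w = grid_footprint(tw, cols, overlap_fraction)
    if foot_h > H or foot_w > W:
        raise ValueError(
            f"master image {H}x{W} is smaller than the required grid "
            f"footprint {foot_h}x{foot_w}"
        )
    step_r = int(round(th * (1.0 - overlap_fraction)))
    step_c = int(round(tw * (1.0 - overlap_fraction)))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for r, c in meander_order(rows, cols):
        y, x = r * step_r, c * step_c
        tile = master[y:y + th, x:x + tw]
        fname = f"r{r}_c{c}.tif"
        tifffile.imwrite(out / fname, tile)
        manifest.append({
            "filename": fname, "row": r, "col": c,
            "x_offset_px": x, "y_offset_px": y,
        })
    with open(out / "manifest.json", "w") as fh:
        json.dump({
            "rows": rows, "cols": cols,
            "overlap_fraction": overlap_fraction,
            "pixel_size_um": spec.pixel_size_um,
            "tiles": manifest,
        }, fh, indent=2)
    tifffile.imwrite(out / "master.tif", master)
    tifffile.imwrite(out / "ground_truth_labels.tif", truth.label_map)
    truth.records.to_csv(out / "ground_truth.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Standard study-condition slide


def random_slide(seed: int, shape: tuple[int, int] = (2048, 2048),
                 n_pellets: int = 10, n_debris: int = 3,
                 include_bubble: bool = True,
                 include_fiber: bool = True) -> SynthSpec:
    """Standard synthetic slide: mycelial particles plus contaminants.

    Places one oversized air bubble at the slide centre and distributes the
    particles, one fiber and several debris specks on a ring of anchor
    positions around it, with seeded jitter — guaranteeing a valid,
    non-overlapping layout for every seed.  Particle radii span 25–115 px
    (≈ 40–180 µm diameter at the default calibration) so the population
    contains both fragments and pellets under the 150 µm length split.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cy, cx = h / 2.0, w / 2.0

    n_anchor = 16
    anchor_r = min(h, w) / 2.0 - 170.0
    anchors = []
    for k in range(n_anchor):
        a = 2.0 * math.pi * (k + 0.5) / n_anchor
        anchors.append((cy + anchor_r * math.sin(a), cx + anchor_r * math.cos(a)))
    order = rng.permutation(n_anchor)

    needed = n_pellets + (1 if include_fiber else 0) + n_debris
    if needed > n_anchor:
        raise ValueError(f"slide layout supports at most {n_anchor} objects")

    def jitter(pos, amp):
        return (pos[0] + rng.uniform(-amp, amp), pos[1] + rng.uniform(-amp, amp))

    pellets = []
    idx = 0
    for _ in range(n_pellets):
        pos = jitter(anchors[order[idx]], 25.0)
        idx += 1
        radius_px = rng.uniform(25.0, 115.0)
        pellets.append(PelletSpec(
            center=pos,
            core_radius_um=radius_px * DEFAULT_PIXEL_SIZE_UM,
            ring_depth_fraction=rng.uniform(0.15, 0.3),
            n_hyphae=int(rng.integers(6, 11)),
            hypha_length_um=rng.uniform(12.0, 20.0),
        ))

    artifacts = []
    if include_bubble:
        artifacts.append(ArtifactSpec(
            kind="bubble",
            center=jitter((cy, cx), 20.0),
            bubble_diameter_um=rng.uniform(905.0, 960.0),
        ))
    if include_fiber:
        artifacts.append(ArtifactSpec(
            kind="fiber",
            center=jitter(anchors[order[idx]], 15.0),
            fiber_length_px=280.0,
            fiber_width_px=10.0,
            fiber_angle_deg=float(rng.uniform(0.0, 180.0)),
            intensity=30.0,
        ))
        idx += 1
    for _ in range(n_debris):
        artifacts.append(ArtifactSpec(
            kind="debris",
            center=jitter(anchors[order[idx]], 25.0),
            debris_area_px=float(rng.uniform(40.0, 150.0)),
            intensity=30.0,
        ))
        idx += 1

    return SynthSpec(shape=shape, pellets=tuple(pellets),
                     artifacts=tuple(artifacts), seed=int(seed))


# ---------------------------------------------------------------------------
# YAML config support (CLI)


def spec_from_dict(d: dict) -> SynthSpec:
    pellets = tuple(
        PelletSpec(center=tuple(p.pop("center")), **p)
        for p in (dict(x) for x in d.get("pellets", []))
    )
    artifacts = tuple(
        ArtifactSpec(kind=a.pop("kind"), center=tuple(a.pop("center")), **a)
        for a in (dict(x) for x in d.get("artifacts", []))
    )
    return SynthSpec(
        shape=tuple(d["shape"]),
        pixel_size_um=d.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM),
        background=d.get("background", 70.0),
        noise_sd=d.get("noise_sd", 2.0),
        pellets=pellets,
        artifacts=artifacts,
        seed=d.get("seed", 0),
        dtype=d.get("dtype", "uint8"),
    )
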