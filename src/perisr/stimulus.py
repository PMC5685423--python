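"""Masked Landolt-C stimulus generation.

Renders the six target/mask dynamic conditions of the peripheral-acuity
paradigm: a Landolt ring (gap = 20% of diameter) presented 10 deg from
fixation on the horizontal meridian, behind a 7 deg x 7 deg occluder
mask of 5.25-arcmin square elements.  Opaque mask elements take the
background luminance, so they occlude the target without being visible
against the background.

Targets are either static, move along an isoeccentric arc at 2 deg/s, or
follow a frame-shuffled version of that arc; the mask can itself be
static, move along the arc with a rigid element pattern, or have its
element pattern regenerated on every video frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .display import MERIDIAN_POINT, DisplayModel
from .errors import (
    ClippingError,
    CoverageError,
    DegenerateStimulusError,
    ParameterError,
    UsageError,
)

#: The four oblique gap positions, mapped to polar angle (deg, x-axis = 0, CCW).
ORIENTATIONS: dict[str, float] = {
    "upper-right": 45.0,
    "upper-left": 135.0,
    "lower-left": 225.0,
    "lower-right": 315.0,
}

GAP_RATIO = 0.2  # critical detail (gap) and stroke width, fraction of diameter

MASK_EXTENT = 420.0  # arcmin (7 deg)
MASK_ELEMENT = 5.25  # arcmin
MASK_SIDE = int(round(MASK_EXTENT / MASK_ELEMENT))  # 80 elements
MASK_N = MASK_SIDE * MASK_SIDE  # 6400 elements

FIXATION_SIZE = 30.0  # arcmin (0.5 deg) cross arm-to-arm extent


@dataclass(frozen=True)
class LandoltTarget:
    """Geometric Landolt ring: outer diameter d, stroke d/5, gap d/5."""

    diameter: float
    gap_size: float
    stroke_width: float
    gap_orientation: str

    def __post_init__(self) -> None:
        if self.gap_orientation not in ORIENTATIONS:
            raise ParameterError(
                f"gap_orientation must be one of {sorted(ORIENTATIONS)}"
            )
        if self.diameter <= 0:
            raise DegenerateStimulusError("diameter must be positive (empty glyph)")
        if not np.isclose(self.gap_size, GAP_RATIO * self.diameter):
            raise ParameterError("gap_size must equal 20% of the diameter")
        if not np.isclose(self.stroke_width, GAP_RATIO * self.diameter):
            raise ParameterError("stroke_width must equal 20% of the diameter")

    @classmethod
    def from_gap(cls, gap_size: float, gap_orientation: str) -> "LandoltTarget":
        """Build the ring whose critical detail is ``gap_size`` arcmin."""
        d = gap_size / GAP_RATIO
        return cls(
            diameter=d,
            gap_size=gap_size,
            stroke_width=GAP_RATIO * d,
            gap_orientation=gap_orientation,
        )


@dataclass(frozen=True)
class MaskSpec:
    """Square-grid occluder mask with an exact count of opaque elements."""

    density: float
    opaque_set: np.ndarray  # flat indices into the 80x80 grid, row-major
    extent: float = MASK_EXTENT
    element_size: float = MASK_ELEMENT
    regenerate_per_frame: bool = False

    @property
    def n_side(self) -> int:
        return int(round(self.extent / self.element_size))

    def opaque_grid(self) -> np.ndarray:
        """Boolean (n_side, n_side) grid of opaque elements."""
        g = np.zeros(self.n_side * self.n_side, dtype=bool)
        g[self.opaque_set] = True
        return g.reshape(self.n_side, self.n_side)


@dataclass(frozen=True)
class MotionPath:
    """Per-frame target (or mask) center positions, arcmin from fixation."""

    kind: str  # static | smooth_arc | shuffled_arc
    positions: np.ndarray  # (n_frames, 2)
    eccentricity: float = 10.0  # deg
    speed: float = 2.0  # deg/s
    direction: str = "ccw"


@dataclass(frozen=True)
class ConditionSpec:
    """One of the six target/mask dynamic conditions."""

    label: str
    target_path_kind: str
    mask_path_kind: str
    mask_regenerate_per_frame: bool
    density: float

    _VALID = {
        ("static", "static", False),
        ("smooth_arc", "static", False),
        ("static", "static", True),
        ("smooth_arc", "static", True),
        ("static", "smooth_arc", False),
        ("shuffled_arc", "static", False),
    }

    def __post_init__(self) -> None:
        combo = (self.target_path_kind, self.mask_path_kind, self.mask_regenerate_per_frame)
        if combo not in self._VALID:
            raise ParameterError(f"invalid target/mask dynamics combination {combo}")
        if not 0.0 <= self.density <= 1.0:
            raise ParameterError("density must lie in [0, 1]")


#: The six conditions, in the order of the experimental design.
CONDITION_DYNAMICS: dict[str, tuple[str, str, bool]] = {
    "static-target/static-mask": ("static", "static", False),
    "smooth-target/static-mask": ("smooth_arc", "static", False),
    "static-target/updating-mask": ("static", "static", True),
    "smooth-target/updating-mask": ("smooth_arc", "static", True),
    "static-target/moving-mask": ("static", "smooth_arc", False),
    "shuffled-target/static-mask": ("shuffled_arc", "static", False),
}


def condition(label: str, density: float) -> ConditionSpec:
    """Look up one of the six named conditions at a given mask density."""
    try:
        tgt, msk, regen = CONDITION_DYNAMICS[label]
    except KeyError:
        raise ParameterError(
            f"unknown condition {label!r}; valid: {sorted(CONDITION_DYNAMICS)}"
        ) from None
    return ConditionSpec(label, tgt, msk, regen, density)


@dataclass
class StimulusSequence:
    """A rendered trial: 25-frame luminance movie plus full provenance."""

    frames: np.ndarray  # (n_frames, H, W) float32, cd/m^2
    target_positions: np.ndarray  # (n_frames, 2) arcmin
    mask_centers: np.ndarray  # (n_frames, 2) arcmin
    masks: list[MaskSpec]  # one per frame (shared object if fixed)
    gap_orientation: str
    gap_size: float
    condition: ConditionSpec
    seed: int
    display: DisplayModel
    frames_shared: bool = False

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def render_landolt(
    target: LandoltTarget,
    position: tuple[float, float],
    display: DisplayModel,
    canvas: np.ndarray | None = None,
    supersample: int = 4,
) -> np.ndarray:
    """Rasterize a Landolt ring at an arcmin position onto the canvas.

    The ring is drawn analytically (annulus minus a square-profile radial
    slot of width 0.2*d on the gap side) on a ``supersample`` x finer
    grid, then area-averaged, giving anti-aliased edges.  Pixels covered
    by the glyph are raised toward the target luminance in proportion to
    their coverage; the rest of the canvas is left untouched.
    """
    app = display.arcmin_per_pixel
    if target.diameter <= 0 or target.diameter < app:
        raise DegenerateStimulusError(
            f"diameter {target.diameter:.3g} arcmin is below one pixel ({app} arcmin)"
        )
    x0, y0 = position
    r_out = target.diameter / 2.0
    if not display.contains(x0, y0, margin=0.0) or not (
        display.contains(x0 - r_out, y0 - r_out)
        and display.contains(x0 + r_out, y0 + r_out)
    ):
        raise ClippingError(
            f"Landolt ring at ({x0:.1f}, {y0:.1f}) arcmin would be clipped"
        )
    if canvas is None:
        canvas = display.blank_canvas()

    r_in = r_out - target.stroke_width
    half_gap = target.gap_size / 2.0
    theta = np.deg2rad(ORIENTATIONS[target.gap_orientation])
    ux, uy = np.cos(theta), np.sin(theta)

    # patch bounding box (pixel indices), one pixel of margin
    row_c, col_c = display.to_pixel(x0, y0)
    half_px = r_out / app + 1.0
    r0 = max(0, int(np.floor(row_c - half_px)))
    r1 = min(canvas.shape[0], int(np.ceil(row_c + half_px)) + 1)
    c0 = max(0, int(np.floor(col_c - half_px)))
    c1 = min(canvas.shape[1], int(np.ceil(col_c + half_px)) + 1)

    s = int(supersample)
    sub = app / s
    xs = display.x_left + (np.arange(c0 * s, c1 * s) + 0.5) * sub - x0
    ys = display.y_top - (np.arange(r0 * s, r1 * s) + 0.5) * sub - y0
    r2 = xs[None, :] ** 2 + ys[:, None] ** 2
    in_ring = (r2 >= r_in * r_in) & (r2 <= r_out * r_out)
    proj = xs[None, :] * ux + ys[:, None] * uy
    cross = xs[None, :] * uy - ys[:, None] * ux
    in_gap = (proj > 0) & (np.abs(cross) <= half_gap)
    cov_sub = (in_ring & ~in_gap).astype(np.float32)
    cov = cov_sub.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))

    lum = display.background_luminance + cov * (
        display.target_luminance - display.background_luminance
    )
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, lum, out=patch)
    return canvas


def landolt_coverage_area(target: LandoltTarget, display: DisplayModel,
                          supersample: int = 4) -> float:
    """Glyph area in arcmin^2 as rendered (sum of pixel coverage)."""
    bg, tl = display.background_luminance, display.target_luminance
    tmp = render_landolt(target, display.canvas_center, display,
                         canvas=display.blank_canvas(), supersample=supersample)
    cov = (tmp - bg) / (tl - bg)
    return float(cov.sum()) * display.arcmin_per_pixel ** 2


def generate_mask(
    density: float,
    seed,
    extent: float = MASK_EXTENT,
    element_size: float = MASK_ELEMENT,
    regenerate_per_frame: bool = False,
) -> MaskSpec:
    """Draw the opaque element set: round(density * N) elements, uniform
    without replacement, reproducible from the seed."""
    if not 0.0 <= density <= 1.0:
        raise ParameterError("density must lie in [0, 1]")
    n_side = int(round(extent / element_size))
    n = n_side * n_side
    k = int(round(density * n))
    rng = np.random.default_rng(seed)
    opaque = np.sort(rng.choice(n, size=k, replace=False))
    return MaskSpec(density=density, opaque_set=opaque, extent=extent,
                    element_size=element_size,
                    regenerate_per_frame=regenerate_per_frame)


def paint_mask(
    canvas: np.ndarray,
    mask: MaskSpec,
    center: tuple[float, float],
    display: DisplayModel,
) -> np.ndarray:
    """Overdraw opaque mask elements at background luminance (occlusion)."""
    if mask.opaque_set.size == 0:
        return canvas
    half = mask.extent / 2.0
    left, top = center[0] - half, center[1] + half
    xc = display.col_centers()
    yc = display.row_centers()
    cols = np.nonzero((xc >= left) & (xc < left + mask.extent))[0]
    rows = np.nonzero((yc <= top) & (yc > top - mask.extent))[0]
    if cols.size == 0 or rows.size == 0:
        return canvas
    ex = np.floor((xc[cols] - left) / mask.element_size).astype(np.intp)
    ey = np.floor((top - yc[rows]) / mask.element_size).astype(np.intp)
    np.clip(ex, 0, mask.n_side - 1, out=ex)
    np.clip(ey, 0, mask.n_side - 1, out=ey)
    grid = mask.opaque_grid()
    sub = canvas[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    sub[grid[ey[:, None], ex[None, :]]] = display.background_luminance
    return canvas


def draw_fixation(canvas: np.ndarray, display: DisplayModel,
                  size: float = FIXATION_SIZE) -> np.ndarray:
    """White 0.5 x 0.5 deg fixation cross at the fixation point, if on-canvas."""
    app = display.arcmin_per_pixel
    half = size / 2.0
    if not display.contains(0.0, 0.0, margin=half):
        return canvas
    row_c, col_c = display.to_pixel(0.0, 0.0)
    half_px = int(round(half / app))
    rc, cc = int(round(row_c)), int(round(col_c))
    canvas[rc, cc - half_px: cc + half_px + 1] = display.target_luminance
    canvas[rc - half_px: rc + half_px + 1, cc] = display.target_luminance
    return canvas


# ---------------------------------------------------------------------------
# motion paths
# ---------------------------------------------------------------------------


def static_path(n_frames: int, center: tuple[float, float] = MERIDIAN_POINT,
                eccentricity: float = 10.0) -> MotionPath:
    """All-frames-identical path at a fixed position."""
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    pos = np.tile(np.asarray(center, dtype=float), (n_frames, 1))
    return MotionPath(kind="static", positions=pos, eccentricity=eccentricity,
                      speed=0.0)


def smooth_arc_path(
    n_frames: int,
    speed: float = 2.0,
    eccentricity: float = 10.0,
    direction: str = "ccw",
    frame_rate: float = 75.0,
) -> MotionPath:
    """Isoeccentric arc at constant angular speed, centered on the meridian.

    Consecutive frames are separated by an arc of speed/frame_rate along
    the circle of radius ``eccentricity`` about fixation; the path span
    is symmetric about the horizontal meridian (the mid-trajectory point
    sits exactly on it for an odd frame count).
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if eccentricity <= 0:
        raise ParameterError("eccentricity must be positive")
    if direction not in ("ccw", "cw"):
        raise ParameterError("direction must be 'ccw' or 'cw'")
    ecc = eccentricity * 60.0  # arcmin
    arc_per_frame = speed * 60.0 / frame_rate  # arcmin along the circle
    dphi = arc_per_frame / ecc  # radians of polar angle per frame
    sign = 1.0 if direction == "ccw" else -1.0
    phi = sign * dphi * (np.arange(n_frames) - (n_frames - 1) / 2.0)
    pos = np.column_stack([ecc * np.cos(phi), ecc * np.sin(phi)])
    return MotionPath(kind="smooth_arc", positions=pos,
                      eccentricity=eccentricity, speed=speed,
                      direction=direction)


def shuffle_path(path: MotionPath, seed) -> MotionPath:
    """Frame-shuffled arc: same multiset of positions, random order."""
    if path.kind != "smooth_arc":
        raise UsageError("shuffle_path requires a smooth_arc path")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(path.positions.shape[0])
    return replace(path, kind="shuffled_arc", positions=path.positions[perm])


# ---------------------------------------------------------------------------
# sequence composition
# ---------------------------------------------------------------------------


def compose_sequence(
    cond: ConditionSpec,
    gap_size: float,
    orientation: str,
    seed: int,
    display: DisplayModel | None = None,
    duration: float = 1.0 / 3.0,
    direction: str | None = None,
) -> StimulusSequence:
    """Render the full luminance movie for one trial.

    Per frame: the Landolt ring is drawn at its path position, then the
    opaque mask elements are overdrawn at background luminance (the mask
    occludes the target), with the mask centered at its own path
    position; the fixation cross is drawn whenever it lies on-canvas.
    Motion direction is drawn at random per trial unless given.
    """
    if display is None:
        display = DisplayModel()
    if gap_size <= 0:
        raise ParameterError("gap_size must be positive")
    target = LandoltTarget.from_gap(gap_size, orientation)

    n_frames = int(round(duration * display.frame_rate))
    rng = np.random.default_rng(seed)
    if direction is None:
        direction = "ccw" if rng.random() < 0.5 else "cw"

    def arc() -> MotionPath:
        return smooth_arc_path(n_frames, speed=2.0, eccentricity=10.0,
                               direction=direction,
                               frame_rate=display.frame_rate)

    if cond.target_path_kind == "static":
        tpath = static_path(n_frames)
    elif cond.target_path_kind == "smooth_arc":
        tpath = arc()
    else:  # shuffled_arc
        tpath = shuffle_path(arc(), rng.integers(2**31))

    if cond.mask_path_kind == "static":
        mpath = static_path(n_frames)
    else:
        mpath = arc()

    # coverage: target must stay inside the mask extent at every frame
    half = MASK_EXTENT / 2.0 - target.diameter / 2.0
    rel = tpath.positions - mpath.positions
    if np.any(np.abs(rel) > half):
        raise CoverageError("target path exits the occluder-mask extent")

    if cond.mask_regenerate_per_frame:
        masks = [
            generate_mask(cond.density, s, regenerate_per_frame=True)
            for s in rng.integers(2**31, size=n_frames)
        ]
    else:
        masks = [generate_mask(cond.density, rng.integers(2**31))] * n_frames

    static_scene = (
        cond.target_path_kind == "static"
        and cond.mask_path_kind == "static"
        and not cond.mask_regenerate_per_frame
    )

    def render_frame(i: int) -> np.ndarray:
        canvas = display.blank_canvas()
        draw_fixation(canvas, display)
        render_landolt(target, tuple(tpath.positions[i]), display, canvas=canvas)
        paint_mask(canvas, masks[i], tuple(mpath.positions[i]), display)
        return canvas

    if static_scene:
        frame = render_frame(0)
        frames = np.broadcast_to(frame, (n_frames,) + frame.shape)
    else:
        frames = np.stack([render_frame(i) for i in range(n_frames)])

    return StimulusSequence(
        frames=frames,
        target_positions=tpath.positions,
        mask_centers=mpath.positions,
        masks=masks,
        gap_orientation=orientation,
        gap_size=gap_size,
        condition=cond,
        seed=int(seed),
        display=display,
        frames_shared=static_scene,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_sequence(seq: StimulusSequence, tiff_path, sidecar_path=None) -> None:
    """Write a multi-page 16-bit TIFF (cd/m^2 x 100) plus a JSON sidecar."""
    import tifffile

    pages = np.clip(np.asarray(seq.frames) * 100.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, pages, photometric="minisblack")
    if sidecar_path is not None:
        meta = {
            "condition": seq.condition.label,
            "density": seq.condition.density,
            "gap_arcmin": seq.gap_size,
            "orientation": seq.gap_orientation,
            "seed": seq.seed,
            "n_frames": seq.n_frames,
            "luminance_scale": "cd/m^2 x 100",
            "target_positions_arcmin": np.asarray(seq.target_positions).tolist(),
            "mask_centers_arcmin": np.asarray(seq.mask_centers).tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
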