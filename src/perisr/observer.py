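"""Model observers: synthetic subjects for the masked-acuity paradigm.

Each observer converts a rendered :class:`~perisr.stimulus.StimulusSequence`
into a four-alternative forced-choice response about the Landolt-gap
position.  Three strategies are implemented:

``single_frame``
    Decide from the middle frame only (no temporal integration).
``prob_summation``
    Independent looks: decide evidence per frame, pool with a max rule.
    This is the null mechanism that benefits from *more* samples but
    performs no cross-frame image synthesis.
``super_resolution``
    Shift-and-add: motion-register all frames to the mid-trajectory
    reference (using oracle, estimated, or no motion knowledge), average
    them into a composite, and decide on the composite.  This embodies
    the idea that multiple undersampled looks at a moving target can be
    synthesized into a more complete image.

The front end applies isotropic Gaussian blur (peripheral spatial
filtering), retina-fixed spatially correlated fixed-pattern noise (one
field per trial, constant across frames), and per-pixel temporal noise,
fresh on every frame.  Decisions are template matches: normalized
cross-correlation of the analysis window against the four noiseless
gap-orientation templates, argmax with a seeded uniform tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
import scipy.ndimage as ndi

from .display import DisplayModel
from .errors import (
    ConfigurationError,
    ParameterError,
    UndefinedCorrelationError,
    UsageError,
)
from .stimulus import ORIENTATIONS, LandoltTarget, StimulusSequence, render_landolt

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class ObserverParams:
    """Configuration of a model observer.

    Parameters
    ----------
    blur_sigma:
        Scale of the front-end Gaussian blur, arcmin.  Stands in for
        peripheral spatial filtering.
    noise_sd:
        SD of per-pixel additive temporal internal noise, cd/m^2, drawn
        fresh on every frame.
    fixed_pattern_sd:
        SD of additive fixed-pattern noise, cd/m^2: a spatial noise
        field tied to retinal (display) coordinates, drawn once per
        trial and identical on every frame.  It models static
        inhomogeneity of the sampling array (receptor/ganglion gain
        variability).  Temporal noise averages out over frames for any
        integrating observer; fixed-pattern noise only averages out
        when the image *moves* across the array and the frames are
        motion-registered -- the signature benefit of shift-and-add.
    fixed_pattern_scale:
        Correlation length of the fixed-pattern field, arcmin (Gaussian
        kernel scale), reflecting the coarse grain of peripheral
        pooling units.  Smooth inhomogeneity disturbs coarse spatial
        judgments (the large-gap regime that masking forces observers
        into) much more than fine ones, so its impact grows with mask
        density.
    strategy:
        ``single_frame``, ``prob_summation`` or ``super_resolution``.
    motion_knowledge:
        ``oracle`` (true path metadata), ``estimated`` (trajectory
        search: the registration velocity that maximizes registered
        template evidence), or ``none`` (zero shifts).  Only meaningful
        for the super-resolution strategy.
    window_factor:
        Analysis-window extent as a multiple of the target diameter,
        centered on the assumed (mid-trajectory) target position.
    """

    blur_sigma: float = 2.5
    noise_sd: float = 6.0
    fixed_pattern_sd: float = 4.0
    fixed_pattern_scale: float = 12.0
    strategy: str = "super_resolution"
    motion_knowledge: str = "oracle"
    window_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0 or self.noise_sd < 0 or self.fixed_pattern_sd < 0:
            raise ParameterError("noise and blur parameters must be >= 0")
        if self.strategy not in ("single_frame", "prob_summation", "super_resolution"):
            raise ParameterError(f"unknown strategy {self.strategy!r}")
        if self.motion_knowledge not in ("oracle", "estimated", "none"):
            raise ParameterError(f"unknown motion_knowledge {self.motion_knowledge!r}")


@dataclass(frozen=True)
class MotionEstimate:
    """Estimated inter-frame shift (arcmin) with an NCC-peak confidence."""

    shift: tuple[float, float]  # (dx, dy), arcmin, y positive up
    confidence: float


@dataclass(frozen=True)
class TrialResponse:
    """Outcome of one simulated 4AFC trial."""

    chosen_orientation: str
    correct: bool
    decision_variables: np.ndarray  # one per orientation, template order
    strategy: str


# ---------------------------------------------------------------------------
# front end
# ---------------------------------------------------------------------------


def front_end(image: np.ndarray, params: ObserverParams, rng,
              arcmin_per_pixel: float = 1.05) -> np.ndarray:
    """Gaussian blur (scale ``blur_sigma`` arcmin) then independent
    zero-mean additive Gaussian pixel noise of SD ``noise_sd``."""
    rng = np.random.default_rng(rng)
    return _front_end_px(image, params, rng, arcmin_per_pixel)


def _front_end_px(image: np.ndarray, params: ObserverParams, rng,
                  arcmin_per_pixel: float) -> np.ndarray:
    out = np.asarray(image, dtype=np.float64)
    if params.blur_sigma > 0:
        out = ndi.gaussian_filter(out, params.blur_sigma / arcmin_per_pixel,
                                  mode="nearest")
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def estimate_shift(frame_a: np.ndarray, frame_b: np.ndarray,
                   arcmin_per_pixel: float = 1.0) -> MotionEstimate:
    """Translation of ``frame_b`` relative to ``frame_a`` by NCC peak.

    Computes the circular normalized cross-correlation of the two
    zero-mean frames, takes the peak, and refines it to sub-pixel
    precision with a 1-D quadratic fit along each axis.  The peak value
    (in [-1, 1]) is returned as the confidence.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise UsageError("frames must have the same shape")
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("zero-variance frame")
    # c[s] = sum_y a0[y - s] * b0[y] (circular): if b is a translated by
    # s*, the peak sits at index s*.
    c = sfft.irfft2(np.conj(sfft.rfft2(a0)) * sfft.rfft2(b0), s=a.shape)
    c /= na * nb
    peak = np.unravel_index(np.argmax(c), c.shape)
    conf = float(c[peak])

    def subpix(axis: int) -> float:
        idx = list(peak)
        n = c.shape[axis]
        idx_m = idx.copy(); idx_m[axis] = (peak[axis] - 1) % n
        idx_p = idx.copy(); idx_p[axis] = (peak[axis] + 1) % n
        cm, c0_, cp = c[tuple(idx_m)], c[tuple(peak)], c[tuple(idx_p)]
        denom = cm - 2.0 * c0_ + cp
        if abs(denom) < 1e-12:
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    drow = peak[0] + subpix(0)
    dcol = peak[1] + subpix(1)
    # wrap to signed shifts
    if drow > a.shape[0] / 2:
        drow -= a.shape[0]
    if dcol > a.shape[1] / 2:
        dcol -= a.shape[1]
    dx = dcol * arcmin_per_pixel
    dy = -drow * arcmin_per_pixel  # row increases downward
    return MotionEstimate(shift=(dx, dy), confidence=conf)


def accumulate_sr(
    frames,
    shifts,
    arcmin_per_pixel: float = 1.0,
    fill_value: float = 0.0,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift-and-add: register each frame and average (target-centered).

    ``shifts[i]`` is the (dx, dy) displacement, arcmin, of frame i's
    target relative to the reference; each frame is translated by the
    negative of its shift (spline interpolation of the given order) and
    the registered stack is averaged with per-pixel sample counts.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in frames]
    shifts = np.asarray(shifts, dtype=np.float64)
    if shifts.ndim != 2 or shifts.shape[0] != len(frames):
        raise UsageError("need exactly one (dx, dy) shift per frame")
    acc = np.zeros_like(frames[0])
    wsum = np.zeros_like(frames[0])
    for f, (dx, dy) in zip(frames, shifts):
        drow = dy / arcmin_per_pixel  # undo: move content opposite to its shift
        dcol = -dx / arcmin_per_pixel
        if dx == 0 and dy == 0:
            reg, w = f, np.ones_like(f)
        else:
            reg = ndi.shift(f, (drow, dcol), order=order, mode="constant", cval=0.0)
            w = ndi.shift(np.ones_like(f), (drow, dcol), order=1,
                          mode="constant", cval=0.0)
        acc += reg
        wsum += w
    counts = wsum
    composite = np.where(wsum > 1e-9, acc / np.maximum(wsum, 1e-9), fill_value)
    return composite, counts


# ---------------------------------------------------------------------------
# decision
# ---------------------------------------------------------------------------


def _template_bank(gap_size: float, window_px: int, center_rc: tuple[float, float],
                   display: DisplayModel) -> dict[str, np.ndarray]:
    """Noiseless zero-mean Landolt templates, one per gap orientation,
    rendered at the same sub-pixel position as the analysis window center."""
    app = display.arcmin_per_pixel
    tdisp = DisplayModel(
        frame_rate=display.frame_rate,
        arcmin_per_pixel=app,
        background_luminance=display.background_luminance,
        target_luminance=display.target_luminance,
        canvas_center=(0.0, 0.0),
        canvas_extent=(window_px * app, window_px * app),
    )
    # sub-pixel offset of the true center from the window's center pixel
    frac_r = center_rc[0] - np.round(center_rc[0])
    frac_c = center_rc[1] - np.round(center_rc[1])
    pos = (frac_c * app, -frac_r * app)
    bank = {}
    for name in ORIENTATIONS:
        tgt = LandoltTarget.from_gap(gap_size, name)
        img = render_landolt(tgt, pos, tdisp, canvas=tdisp.blank_canvas())
        t0 = img - img.mean()
        bank[name] = t0
    return bank


def _ncc_scalar(window: np.ndarray, template0: np.ndarray) -> float:
    w0 = window - window.mean()
    nw = np.linalg.norm(w0)
    nt = np.linalg.norm(template0)
    if nw < 1e-12 or nt < 1e-12:
        return 0.0
    return float(np.sum(w0 * template0) / (nw * nt))


def _choose(dv: np.ndarray, names: list[str], rng) -> str:
    top = np.max(dv)
    ties = np.nonzero(dv >= top - _TIE_EPS)[0]
    idx = ties[0] if ties.size == 1 else rng.choice(ties)
    return names[int(idx)]


def decide_4afc(
    composite: np.ndarray,
    gap_size: float,
    center_rc: tuple[float, float],
    params: ObserverParams,
    rng,
    display: DisplayModel,
) -> TrialResponse:
    """Template-match the composite against the four gap orientations.

    ``center_rc`` is the assumed target center in (row, col) pixel
    coordinates of ``composite``.  The decision variables are scalar
    normalized cross-correlations within the analysis window; the chosen
    orientation is the argmax, with a seeded uniform tie-break.
    """
    if gap_size <= 0:
        raise ParameterError("gap_size must be positive")
    rng = np.random.default_rng(rng)
    app = display.arcmin_per_pixel
    diameter = gap_size / 0.2
    half_px = max(2, int(round(params.window_factor * diameter / 2.0 / app)))
    r0 = int(np.round(center_rc[0])) - half_px
    c0 = int(np.round(center_rc[1])) - half_px
    r1, c1 = r0 + 2 * half_px + 1, c0 + 2 * half_px + 1
    if r0 < 0 or c0 < 0 or r1 > composite.shape[0] or c1 > composite.shape[1]:
        raise UsageError("analysis window exceeds the composite image")
    window = composite[r0:r1, c0:c1]
    if window.size == 0:
        raise UsageError("empty analysis window")
    bank = _template_bank(gap_size, 2 * half_px + 1, center_rc, display)
    names = list(bank)
    dv = np.array([_ncc_scalar(window, bank[n]) for n in names])
    chosen = _choose(dv, names, rng)
    return TrialResponse(chosen_orientation=chosen, correct=False,
                         decision_variables=dv, strategy=params.strategy)


# ---------------------------------------------------------------------------
# trial dispatch
# ---------------------------------------------------------------------------


def _crop(frame: np.ndarray, r0: int, c0: int, r1: int, c1: int,
          fill: float) -> np.ndarray:
    out = np.full((r1 - r0, c1 - c0), fill, dtype=np.float64)
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if rr1 > rr0 and cc1 > cc0:
        out[rr0 - r0: rr1 - r0, cc0 - c0: cc1 - c0] = frame[rr0:rr1, cc0:cc1]
    return out


def _fixed_pattern(shape: tuple[int, int], sd: float, scale_px: float,
                   rng) -> np.ndarray | None:
    """Retinal fixed-pattern noise field (one draw per trial, identical
    on every frame), low-pass correlated at the pooling scale and
    normalized to the requested pixel SD."""
    if sd <= 0:
        return None
    field = rng.normal(0.0, 1.0, size=shape)
    if scale_px > 0:
        field = ndi.gaussian_filter(field, scale_px, mode="wrap")
        field /= field.std()
    return sd * field


def estimate_trajectory(
    crops,
    params: ObserverParams,
    gap_size: float,
    center_rc: tuple[float, float],
    display: DisplayModel,
    frame_rate: float,
    speeds=None,
) -> np.ndarray:
    """Estimate registration shifts by a predictable-trajectory search.

    The observer assumes the target follows a constant-velocity path
    along the (locally vertical) isoeccentric arc and scans candidate
    speeds, scoring each by the best gap-orientation template match of
    the corresponding registered average.  The winning speed's shift
    profile is returned.  Smooth trajectories are matched well by some
    candidate; frame-shuffled trajectories are not matched by any, so
    registration fails gracefully -- the mechanism by which trajectory
    predictability matters.
    """
    if speeds is None:
        speeds = np.arange(-3.0, 3.01, 0.25)  # deg/s along the arc
    n = len(crops)
    mid = n // 2
    app = display.arcmin_per_pixel
    stack = np.stack(crops)
    bank = None
    best = (-np.inf, 0.0)
    for v in speeds:
        dy_px = v * 60.0 / frame_rate / app * (np.arange(n) - mid)
        rolled = np.zeros_like(crops[0])
        for i in range(n):
            k = int(np.round(dy_px[i]))  # integer-row registration for scoring
            rolled += np.roll(stack[i], k, axis=0)
        comp = rolled / n
        half_px = max(2, int(round(params.window_factor * (gap_size / 0.2)
                                   / 2.0 / app)))
        r0 = int(np.round(center_rc[0])) - half_px
        c0 = int(np.round(center_rc[1])) - half_px
        win = comp[r0: r0 + 2 * half_px + 1, c0: c0 + 2 * half_px + 1]
        if bank is None:
            bank = _template_bank(gap_size, 2 * half_px + 1, center_rc, display)
        score = max(_ncc_scalar(win, t) for t in bank.values())
        if score > best[0]:
            best = (score, float(v))
    v = best[1]
    dy = v * 60.0 / frame_rate * (np.arange(n) - mid)
    return np.column_stack([np.zeros(n), dy])


def simulate_trial(seq: StimulusSequence, params: ObserverParams,
                   seed) -> TrialResponse:
    """Run one 4AFC trial of the configured observer on a stimulus.

    The observer attends a processing window centered on the known
    mid-trajectory target position (wide enough to contain the whole
    trajectory plus the analysis window).  Internal images are the
    stimulus blurred by the front end, plus retinal fixed-pattern noise
    (one field per trial, tied to display coordinates) and temporal
    noise (fresh per frame).  Strategy dispatch:

    - ``single_frame``: decision on the middle frame only.
    - ``prob_summation``: per-frame decision variables at the true
      per-frame target position, pooled with a max rule.
    - ``super_resolution``: registration (oracle / estimated / none),
      shift-and-add, decision on the composite.
    """
    rng = np.random.default_rng(seed)
    display = seq.display
    app = display.arcmin_per_pixel
    mid = seq.n_frames // 2
    if seq.target_positions is None:
        if params.strategy == "super_resolution" and params.motion_knowledge == "oracle":
            raise ConfigurationError(
                "oracle motion knowledge requires true path metadata")
        raise ConfigurationError("sequence lacks target-position metadata")
    pos = np.asarray(seq.target_positions, dtype=float)
    ref_xy = pos[mid]
    diameter = seq.gap_size / 0.2
    win_half = params.window_factor * diameter / 2.0
    bg = display.background_luminance

    # retinal region the trial can touch: trajectory bbox + window + margins
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    fpn_pad = (win_half + 4.0 * params.blur_sigma + 8.0 * app
               + 2.0 * params.fixed_pattern_scale)
    row_t, col_l = display.to_pixel(lo[0] - fpn_pad, hi[1] + fpn_pad)
    row_b, col_r = display.to_pixel(hi[0] + fpn_pad, lo[1] - fpn_pad)
    R0, C0 = int(np.floor(row_t)), int(np.floor(col_l))
    R1, C1 = int(np.ceil(row_b)) + 1, int(np.ceil(col_r)) + 1
    fpn = _fixed_pattern((R1 - R0, C1 - C0), params.fixed_pattern_sd,
                         params.fixed_pattern_scale / app, rng)

    def internal(i: int, r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
        """Front-end image of frame i over a canvas region: blur, then
        fixed-pattern noise (display coordinates), then temporal noise."""
        out = _crop(np.asarray(seq.frames[i], dtype=np.float64),
                    r0, c0, r1, c1, bg)
        if params.blur_sigma > 0:
            out = ndi.gaussian_filter(out, params.blur_sigma / app,
                                      mode="nearest")
        if fpn is not None:
            out = out + _crop(fpn, r0 - R0, c0 - C0, r1 - R0, c1 - C0, 0.0)
        if params.noise_sd > 0:
            out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
        return out

    def window_at(xy) -> tuple[int, int, int, int, tuple[float, float]]:
        margin = win_half + 4.0 * params.blur_sigma + 4.0 * app
        rr, cc = display.to_pixel(*xy)
        h = int(np.ceil(margin / app))
        r0, c0 = int(np.round(rr)) - h, int(np.round(cc)) - h
        return r0, c0, r0 + 2 * h + 1, c0 + 2 * h + 1, (rr - r0, cc - c0)

    if params.strategy == "single_frame":
        r0, c0, r1, c1, center = window_at(pos[mid])
        frame = internal(mid, r0, c0, r1, c1)
        resp = decide_4afc(frame, seq.gap_size, center, params, rng, display)
        return _scored(resp, seq)

    if params.strategy == "prob_summation":
        dv = None
        for i in range(seq.n_frames):
            r0, c0, r1, c1, center = window_at(pos[i])
            frame = internal(i, r0, c0, r1, c1)
            r = decide_4afc(frame, seq.gap_size, center, params, rng, display)
            dv = r.decision_variables if dv is None else np.maximum(
                dv, r.decision_variables)
        chosen = _choose(dv, list(ORIENTATIONS), rng)
        resp = TrialResponse(chosen, False, dv, params.strategy)
        return _scored(resp, seq)

    # super_resolution
    # processing window: trajectory bounding box + analysis window + margin
    pad = win_half + 8.0 * app
    row_t, col_l = display.to_pixel(lo[0] - pad, hi[1] + pad)
    row_b, col_r = display.to_pixel(hi[0] + pad, lo[1] - pad)
    r0, r1 = int(np.floor(row_t)), int(np.ceil(row_b)) + 1
    c0, c1 = int(np.floor(col_l)), int(np.ceil(col_r)) + 1
    crops = [internal(i, r0, c0, r1, c1) for i in range(seq.n_frames)]
    center_rc_full = display.to_pixel(*ref_xy)
    center_rc = (center_rc_full[0] - r0, center_rc_full[1] - c0)

    if params.motion_knowledge == "oracle":
        shifts = pos - ref_xy  # (dx, dy) arcmin of each frame vs reference
    elif params.motion_knowledge == "none":
        shifts = np.zeros_like(pos)
    else:  # estimated
        shifts = estimate_trajectory(crops, params, seq.gap_size, center_rc,
                                     display, display.frame_rate)

    composite, _ = accumulate_sr(crops, shifts, app, fill_value=bg)
    resp = decide_4afc(composite, seq.gap_size, center_rc, params, rng, display)
    return _scored(resp, seq)


def _scored(resp: TrialResponse, seq: StimulusSequence) -> TrialResponse:
    return TrialResponse(
        chosen_orientation=resp.chosen_orientation,
        correct=resp.chosen_orientation == seq.gap_orientation,
        decision_variables=resp.decision_variables,
        strategy=resp.strategy,
    )


# ---------------------------------------------------------------------------
# responders (synthetic subjects for the adaptive track)
# ---------------------------------------------------------------------------


class ImageObserver:
    """Synthetic subject that renders and analyzes the actual stimulus."""

    def __init__(self, params: ObserverParams, display: DisplayModel | None = None):
        self.params = params
        self.display = display or DisplayModel()

    def respond(self, cond, gap_size: float, orientation: str, seed) -> bool:
        from .stimulus import compose_sequence

        seq = compose_sequence(cond, gap_size, orientation, seed,
                               display=self.display)
        return simulate_trial(seq, self.params, seed + 1).correct


class LogisticResponder:
    """Synthetic subject that responds per the 4AFC logistic psychometric
    function p(x) = 0.25 + 0.75 / (1 + exp((mu - x) / sigma)), without
    rendering images.  Used for staircase/fit validation and fast runs."""

    def __init__(self, mu: float, sigma: float):
        if sigma <= 0:
            raise ParameterError("sigma must be positive")
        self.mu = float(mu)
        self.sigma = float(sigma)

    def p_correct(self, gap_size: float) -> float:
        return 0.25 + 0.75 / (1.0 + np.exp((self.mu - gap_size) / self.sigma))

    def respond(self, cond, gap_size: float, orientation: str, seed) -> bool:
        rng = np.random.default_rng(seed)
        return bool(rng.random() < self.p_correct(gap_size))
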