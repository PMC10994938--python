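"""In-silico beam-targeting latency and tracking-error experiment.

Replicates, in simulation, the motion-phantom experiment used to
characterise an MLC-tracking chain: a spherical target (radius ~30 mm)
moves on a 1-D trace (sinusoidal for latency, breathing-like for error);
cine frames are rendered, degraded by k-space truncation, optionally
up-sampled, template-matched to localise the target; the displacement is
delivered — after the imaging-chain delays — to a velocity-limited MLC
aperture.  Target and aperture traces are then sampled at the portal
imager (EPID) rate and analysed:

* end-to-end latency = phase shift between sinusoid fits to the two
  traces,
* geometric error = RMSE between the traces,
* latency-corrected error = RMSE after advancing the aperture trace by
  the measured latency.

Timing uses a mid-exposure convention: a frame exposed around time t_k
represents the target position at t_k and becomes actionable at
t_k + frame_period/2 + (recon + SR + tracking + MLC delays), so the
injected latency is frame_period/2 plus the stage delays.  Setting
``frame_period = 0`` selects an idealized continuous-imaging limit in
which the trace itself is the frame stream (zero imaging latency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import match_template

from .image import GrayImage
from .kspace_ops import kspace_downsample
from .sr_core import upsample_bicubic, upsample_nearest

__all__ = [
    "MotionTrace",
    "PhantomSpec",
    "ChainTiming",
    "MLCSpec",
    "TrackingReport",
    "LostTargetError",
    "gen_sinusoid_trace",
    "gen_breathing_trace",
    "render_frame",
    "template_match",
    "mlc_respond",
    "run_chain",
    "estimate_latency",
    "geometric_error",
    "latency_corrected_error",
    "experiment_suite",
]


class LostTargetError(RuntimeError):
    """Raised when template matching cannot find the target."""


@dataclass(frozen=True)
class MotionTrace:
    """Time-stamped 1-D displacement series (seconds, millimetres)."""

    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        x = np.asarray(self.x, float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("t and x must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("non-finite trace values")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def interp(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.x)


@dataclass(frozen=True)
class PhantomSpec:
    """Moving-sphere phantom geometry and rendering parameters."""

    target_radius: float = 30.0     # mm
    fov: float = 400.0              # mm
    lr_matrix: int = 64
    hr_matrix: int = 256
    target_intensity: float = 3000.0
    background: float = 100.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.target_radius >= self.fov / 2:
            raise ValueError("target radius must be smaller than half the FOV")
        if self.target_intensity < 0 or self.background < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class ChainTiming:
    """Imaging-chain timing: 4 Hz frames, per-stage delays, EPID rate."""

    frame_period: float = 0.25      # s (4 Hz real-time imaging)
    recon_delay: float = 0.0
    sr_delay: float = 0.0
    tracking_delay: float = 0.0
    mlc_delay: float = 0.0
    epid_rate: float = 3.6          # Hz

    def __post_init__(self) -> None:
        for d in (self.frame_period, self.recon_delay, self.sr_delay,
                  self.tracking_delay, self.mlc_delay):
            if d < 0:
                raise ValueError("delays must be nonnegative")

    @property
    def stage_delay_sum(self) -> float:
        return (self.recon_delay + self.sr_delay + self.tracking_delay
                + self.mlc_delay)


@dataclass(frozen=True)
class MLCSpec:
    """Aperture-centroid abstraction of the multi-leaf collimator."""

    max_leaf_velocity: float = 25.0  # mm/s at isocentre
    control_rate: float = 100.0      # Hz

    def __post_init__(self) -> None:
        if self.max_leaf_velocity <= 0:
            raise ValueError("leaf velocity must be positive")


@dataclass
class TrackingReport:
    """Latency / RMSE / corrected RMSE summary for one method."""

    method: str
    latency_mean: float
    latency_sd: float
    rmse_mean: float
    rmse_sd: float
    rmse_corrected_mean: float
    rmse_corrected_sd: float
    n_repeats: int
    latencies: list = field(default_factory=list)
    rmses: list = field(default_factory=list)
    rmses_corrected: list = field(default_factory=list)


# -- trace generators -----------------------------------------------------

def gen_sinusoid_trace(amplitude: float, frequency: float, duration: float,
                       rate: float, phase: float = 0.0) -> MotionTrace:
    """x(t) = A sin(2 pi f t + phi), sampled at ``rate`` Hz."""
    if rate <= 2 * frequency:
        raise ValueError(
            f"sampling rate {rate} Hz undersamples a {frequency} Hz sinusoid")
    t = np.arange(0.0, duration, 1.0 / rate)
    return MotionTrace(t, amplitude * np.sin(2 * np.pi * frequency * t + phase))


def gen_breathing_trace(seed: int, duration: float, rate: float,
                        period: float = 4.0, amplitude: float = 10.0,
                        period_jitter: float = 0.1,
                        amplitude_jitter: float = 0.1,
                        drift: float = 2.0, phase: float = 0.0) -> MotionTrace:
    """Quasi-periodic breathing surrogate.

    Per-cycle period and amplitude are jittered (fractional standard
    deviations ``period_jitter`` / ``amplitude_jitter``) and a slow
    baseline drift (two random-phase sinusoids with 30-60 s periods,
    amplitude ``drift`` mm) is superimposed.  With zero jitter and zero
    drift the output equals :func:`gen_sinusoid_trace` at f = 1/period.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / rate)
    n = len(t)
    x = np.empty(n)

    def draw_period() -> float:
        return period * float(np.clip(1 + period_jitter * rng.standard_normal(),
                                      0.5, 1.5))

    def draw_amp() -> float:
        return amplitude * float(np.clip(1 + amplitude_jitter * rng.standard_normal(),
                                         0.3, 1.7))

    cyc_t, cyc_a = draw_period(), draw_amp()
    ph = 0.0
    dt = 1.0 / rate
    for i in range(n):
        x[i] = cyc_a * np.sin(2 * np.pi * ph + phase)
        ph_next = ph + dt / cyc_t
        if np.floor(ph_next) > np.floor(ph):
            cyc_t, cyc_a = draw_period(), draw_amp()
        ph = ph_next
    if drift > 0:
        for _ in range(2):
            per = rng.uniform(30.0, 60.0)
            x += 0.5 * drift * np.sin(2 * np.pi * t / per + rng.uniform(0, 2 * np.pi))
    return MotionTrace(t, x)


# -- rendering and localisation ------------------------------------------

def render_frame(spec: PhantomSpec, displacement: float, matrix: int,
                 rng: np.random.Generator | None = None) -> GrayImage:
    """Render the sphere cross-section displaced along the column axis.

    The disc edge uses a one-pixel linear partial-volume ramp, which is
    translation-equivariant and puts the half-intensity contour exactly
    at the nominal radius.
    """
    if abs(displacement) + spec.target_radius >= spec.fov / 2:
        raise ValueError("target would leave the field of view")
    spacing = spec.fov / matrix
    rows = (np.arange(matrix) - (matrix - 1) / 2) * spacing
    cols = (np.arange(matrix) - (matrix - 1) / 2) * spacing - displacement
    dist = np.sqrt(rows[:, None] ** 2 + cols[None, :] ** 2)
    cover = np.clip(0.5 + (spec.target_radius - dist) / spacing, 0.0, 1.0)
    px = spec.background + (spec.target_intensity - spec.background) * cover
    if spec.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        px = px + spec.noise_sigma * rng.standard_normal(px.shape)
    return GrayImage(np.maximum(px, 0.0), (spacing, spacing))


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2 * c0 + cp1
    if denom >= 0 or abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def template_match(frame: GrayImage, template: GrayImage,
                   ref_pos: tuple[float, float] | None = None,
                   subpixel: bool = True,
                   min_corr: float = 0.5) -> np.ndarray:
    """Localise the template in the frame by normalised cross-correlation.

    Returns the (row, col) displacement in mm relative to ``ref_pos``
    (template-corner placement, pixels; defaults to the centred
    placement).  Sub-pixel refinement fits a parabola to the 3x3
    correlation neighbourhood of the peak.  Raises
    :class:`LostTargetError` if the peak correlation falls below
    ``min_corr``.
    """
    f, tp = frame.pixels, template.pixels
    if tp.shape[0] >= f.shape[0] or tp.shape[1] >= f.shape[1]:
        raise ValueError("template must be smaller than the frame")
    corr = match_template(f, tp)
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    if corr[peak] < min_corr:
        raise LostTargetError(
            f"peak correlation {corr[peak]:.3f} below {min_corr}")
    pos = np.array(peak, float)
    if subpixel:
        for ax in range(2):
            lo = peak[ax] - 1
            hi = peak[ax] + 1
            if lo >= 0 and hi < corr.shape[ax]:
                idx = list(peak)
                vals = []
                for k in (lo, peak[ax], hi):
                    idx[ax] = k
                    vals.append(corr[tuple(idx)])
                pos[ax] += _parabolic_offset(*vals)
    if ref_pos is None:
        ref_pos = ((f.shape[0] - tp.shape[0]) / 2.0,
                   (f.shape[1] - tp.shape[1]) / 2.0)
    return (pos - np.asarray(ref_pos, float)) * np.array(frame.spacing)


def mlc_respond(commanded: float, state: float, spec: MLCSpec,
                dt: float) -> float:
    """Rate-limited first-order step toward the commanded position."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    max_step = spec.max_leaf_velocity * dt
    return state + float(np.clip(commanded - state, -max_step, max_step))


# -- chain simulation -----------------------------------------------------

def _make_sr(sr_method, factor: int):
    if sr_method in (None, "none"):
        return None
    if sr_method == "nearest":
        return lambda im: upsample_nearest(im, factor)
    if sr_method == "bicubic":
        return lambda im: upsample_bicubic(im, factor)
    if callable(sr_method):
        return sr_method
    raise ValueError(f"unknown sr_method {sr_method!r}")


def _prepare_tracking(spec: PhantomSpec, sr):
    """Reference frame + template on the tracking grid; returns
    (track_frame_fn, template, ref_pos)."""
    factor = spec.hr_matrix // spec.lr_matrix

    def process(displacement: float, rng) -> GrayImage:
        hr = render_frame(spec, displacement, spec.hr_matrix, rng)
        lr = kspace_downsample(hr, factor) if factor > 1 else hr
        return sr(lr) if sr is not None else lr

    ref = process(0.0, None) if spec.noise_sigma == 0 else _noiseless(spec, sr, factor)
    spacing = ref.spacing[0]
    half = int(np.ceil(spec.target_radius / spacing)) + 4
    cr, cc = ref.shape[0] // 2, ref.shape[1] // 2
    r0, c0 = cr - half, cc - half
    template = GrayImage(ref.pixels[r0:r0 + 2 * half, c0:c0 + 2 * half],
                         ref.spacing)
    # even grids: the crop window [c-half, c+half) is centred on the
    # (matrix-1)/2 rendering centre, so the corner index is the exact
    # zero-displacement reference placement
    ref_pos = (float(r0), float(c0))
    return process, template, ref_pos


def _noiseless(spec: PhantomSpec, sr, factor: int) -> GrayImage:
    clean = PhantomSpec(spec.target_radius, spec.fov, spec.lr_matrix,
                        spec.hr_matrix, spec.target_intensity,
                        spec.background, 0.0)
    hr = render_frame(clean, 0.0, spec.hr_matrix)
    lr = kspace_downsample(hr, factor) if factor > 1 else hr
    return sr(lr) if sr is not None else lr


def run_chain(trace: MotionTrace, spec: PhantomSpec, timing: ChainTiming,
              mlc: MLCSpec, sr_method="none", seed: int = 0,
              subpixel: bool = True, localiser=None
              ) -> tuple[MotionTrace, MotionTrace]:
    """Simulate the full frame -> SR -> localise -> MLC chain.

    Returns the ground-truth target trace and the aperture trace, both
    sampled at the EPID rate.  ``localiser`` may replace imaging-based
    localisation with a callable mapping true displacement to measured
    displacement (used to isolate timing effects).
    """
    duration = float(trace.t[-1])
    rng = np.random.default_rng(seed)
    commands: list[tuple[float, float]] = []

    if timing.frame_period == 0:
        # idealized continuous imaging: the trace is the frame stream and
        # the control loop ticks on the trace's own timestamps
        for tk, xk in zip(trace.t, trace.x):
            meas = localiser(xk) if localiser is not None else xk
            commands.append((tk + timing.stage_delay_sum, meas))
        tc = trace.t.copy()
    else:
        sr = _make_sr(sr_method, spec.hr_matrix // spec.lr_matrix)
        if localiser is None:
            process, template, ref_pos = _prepare_tracking(spec, sr)
        last = 0.0
        k = 0
        while k * timing.frame_period <= duration:
            tk = k * timing.frame_period  # mid-exposure instant of frame k
            x_true = trace.interp(np.array([tk]))[0]
            if localiser is not None:
                meas = localiser(x_true)
            else:
                frame = process(x_true, rng)
                try:
                    d = template_match(frame, template, ref_pos, subpixel)
                    meas = float(d[1])
                    last = meas
                except LostTargetError:
                    meas = last  # hold last displacement
            # the command is held until the next frame's command arrives;
            # that zero-order hold contributes the frame_period/2 share of
            # the end-to-end latency (exact for sinusoid phase fits)
            commands.append((tk + timing.stage_delay_sum, meas))
            k += 1
        tc = np.arange(0.0, duration + 1.0 / mlc.control_rate,
                       1.0 / mlc.control_rate)

    # MLC control loop
    aperture = np.empty_like(tc)
    dts = np.diff(tc)
    state, ci, commanded = 0.0, 0, 0.0
    for i, tnow in enumerate(tc):
        while ci < len(commands) and commands[ci][0] <= tnow + 1e-9:
            commanded = commands[ci][1]
            ci += 1
        dt = dts[min(i, len(dts) - 1)] if len(dts) else 1.0 / mlc.control_rate
        state = mlc_respond(commanded, state, mlc, dt)
        aperture[i] = state

    # discard the start-up transient (aperture parked at zero until the
    # first delayed command lands) before sampling at the EPID rate
    settle = timing.stage_delay_sum + 2 * timing.frame_period
    settle += 2.0 / mlc.control_rate if timing.frame_period > 0 else \
        2.0 * float(np.median(np.diff(trace.t)))
    te = np.arange(settle, duration, 1.0 / timing.epid_rate)
    if len(te) < 8:
        raise ValueError("trace too short for the settle window")
    target = MotionTrace(te, trace.interp(te))
    ap = MotionTrace(te, np.interp(te, tc, aperture))
    return target, ap


# -- analysis -------------------------------------------------------------

def _fit_sinusoid(t: np.ndarray, x: np.ndarray,
                  freq: float | None = None) -> tuple[float, float, float, float, float]:
    """LSQ fit x ~ a sin(2 pi f t) + b cos(2 pi f t) + c.

    Returns (amplitude, frequency, phase, offset, residual fraction).
    If ``freq`` is given it is held fixed; otherwise it is refined from
    a periodogram initialisation.
    """
    def design(f: float) -> np.ndarray:
        w = 2 * np.pi * f * t
        return np.column_stack([np.sin(w), np.cos(w), np.ones_like(t)])

    def resid(f: float) -> float:
        coef, res, *_ = np.linalg.lstsq(design(f), x, rcond=None)
        pred = design(f) @ coef
        return float(np.sum((x - pred) ** 2))

    if freq is None:
        xd = x - x.mean()
        n = len(t)
        dt = float(np.median(np.diff(t)))
        spec = np.abs(np.fft.rfft(xd)) ** 2
        freqs = np.fft.rfftfreq(n, dt)
        f0 = float(freqs[1 + int(np.argmax(spec[1:]))])
        # the LSQ residual valley in f is narrow: locate it on a fine grid
        # around the periodogram peak, then polish with a bounded search
        grid = np.linspace(max(f0 * 0.7, 1e-4), f0 * 1.3, 241)
        fg = grid[int(np.argmin([resid(f) for f in grid]))]
        df = grid[1] - grid[0]
        res = optimize.minimize_scalar(resid, bounds=(fg - df, fg + df),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        freq = float(res.x)
    coef, *_ = np.linalg.lstsq(design(freq), x, rcond=None)
    a, b, c = (float(v) for v in coef)
    amp = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a))
    var = float(np.sum((x - x.mean()) ** 2))
    frac = resid(freq) / var if var > 0 else 1.0
    return amp, freq, phase, c, frac


def estimate_latency(target: MotionTrace, aperture: MotionTrace) -> float:
    """Latency as the phase shift between sinusoid fits to the traces.

    The target trace fixes the frequency; the aperture is fitted with
    that frequency held.  The phase difference is wrapped into
    [0, 1/f) seconds.
    """
    if target.t[-1] < aperture.t[0] or aperture.t[-1] < target.t[0]:
        raise ValueError("traces do not overlap in time")
    _, f, phi_t, _, frac = _fit_sinusoid(target.t, target.x)
    if frac > 0.5:
        raise ValueError(
            f"target trace is not sinusoidal (residual fraction {frac:.2f})")
    _, _, phi_a, _, _ = _fit_sinusoid(aperture.t, aperture.x, freq=f)
    lag = (phi_t - phi_a) / (2 * np.pi * f)
    return float(lag % (1.0 / f))


def geometric_error(target: MotionTrace, aperture: MotionTrace) -> float:
    """RMSE between the traces, aperture linearly resampled onto target times."""
    sel = (target.t >= aperture.t[0]) & (target.t <= aperture.t[-1])
    if not np.any(sel):
        raise ValueError("no temporal overlap between traces")
    ap = np.interp(target.t[sel], aperture.t, aperture.x)
    return float(np.sqrt(np.mean((target.x[sel] - ap) ** 2)))


def latency_corrected_error(target: MotionTrace, aperture: MotionTrace,
                            latency: float) -> float:
    """RMSE after advancing the aperture trace by the measured latency."""
    if latency < 0:
        raise ValueError("latency must be nonnegative")
    shifted = MotionTrace(aperture.t - latency, aperture.x)
    sel = (target.t >= shifted.t[0]) & (target.t <= shifted.t[-1])
    if not np.any(sel):
        raise ValueError("latency shift leaves no temporal overlap")
    return geometric_error(target, shifted)


def experiment_suite(sr_methods: dict, n_repeats: int = 3, seed: int = 0,
                     spec: PhantomSpec | None = None,
                     timing: ChainTiming | None = None,
                     mlc: MLCSpec | None = None,
                     sin_amplitude: float = 10.0, sin_frequency: float = 0.25,
                     sin_duration: float = 30.0,
                     breathing_duration: float = 40.0,
                     subpixel: bool = True) -> tuple[pd.DataFrame, list[TrackingReport]]:
    """Run the latency (sinusoid) and error (breathing) experiments.

    ``sr_methods`` maps a display name to an ``sr_method`` accepted by
    :func:`run_chain` (``"none"``, ``"nearest"``, ``"bicubic"`` or a
    callable).  Each experiment is repeated ``n_repeats`` times with
    distinct seeds; the report carries mean +- sd and per-repeat values.
    """
    spec = spec or PhantomSpec()
    timing = timing or ChainTiming()
    mlc = mlc or MLCSpec()
    trace_rate = max(4.0, 4 * sin_frequency)
    reports = []
    for name, method in sr_methods.items():
        lat, rms, rmc = [], [], []
        for rep in range(n_repeats):
            rep_seed = seed + 1000 * rep
            sin_trace = gen_sinusoid_trace(sin_amplitude, sin_frequency,
                                           sin_duration, trace_rate)
            tgt, ap = run_chain(sin_trace, spec, timing, mlc, method,
                                seed=rep_seed, subpixel=subpixel)
            lat.append(estimate_latency(tgt, ap))
            br_trace = gen_breathing_trace(seed=rep_seed + 7, rate=trace_rate,
                                           duration=breathing_duration)
            tgt, ap = run_chain(br_trace, spec, timing, mlc, method,
                                seed=rep_seed + 13, subpixel=subpixel)
            rms.append(geometric_error(tgt, ap))
            rmc.append(latency_corrected_error(tgt, ap, lat[-1]))
        reports.append(TrackingReport(
            method=name,
            latency_mean=float(np.mean(lat)), latency_sd=float(np.std(lat, ddof=1)) if n_repeats > 1 else 0.0,
            rmse_mean=float(np.mean(rms)), rmse_sd=float(np.std(rms, ddof=1)) if n_repeats > 1 else 0.0,
            rmse_corrected_mean=float(np.mean(rmc)),
            rmse_corrected_sd=float(np.std(rmc, ddof=1)) if n_repeats > 1 else 0.0,
            n_repeats=n_repeats, latencies=lat, rmses=rms, rmses_corrected=rmc))
    table = pd.DataFrame([{
        "method": r.method, "latency_s": r.latency_mean,
        "latency_sd": r.latency_sd, "rmse_mm": r.rmse_mean,
        "rmse_sd": r.rmse_sd, "rmse_corrected_mm": r.rmse_corrected_mean,
        "rmse_corrected_sd": r.rmse_corrected_sd, "n_repeats": r.n_repeats,
    } for r in reports])
    return table, reports
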