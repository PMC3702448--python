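"""Pixel-wise T2 and T1 map estimation.

T2: least-squares fit of the two-parameter mono-exponential
``S(TE) = S0 exp(-TE/T2)`` to the three T2-prepared magnitudes.

T1: the MOLLI magnitude series is sign-restored (polarity restoration) and
fitted with the three-parameter inversion-recovery model
``S(TI) = A - B exp(-TI/T1*)``; the apparent time constant is converted to
T1 by the Look-Locker correction ``T1 = T1* (B/A - 1)``.  Because magnitude
data discard polarity, all 12 monotone sign-flip candidates (negating the
k lowest-TI samples, k = 0..11) are fitted and the candidate with the
smallest residual wins.

Both fits are solved by profiling: for a fixed time constant the amplitude
parameters are linear and solved in closed form, leaving a one-dimensional
search over the (log) time constant.  The map-level fitters vectorise this
search over all masked pixels (coarse grid, two zoom stages, parabolic
refinement of the residual minimum), which makes whole-slice fitting a few
matrix products.  Physiologic clamp ranges flag rather than truncate:
an optimum outside the range marks the pixel non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .config import FitOptions, MAP_FOR_SERIES
from .phantom import ImageSeries

__all__ = [
    "ParameterMap",
    "T2PixelFit",
    "T1PixelFit",
    "fit_t2_pixel",
    "fit_t2_map",
    "restore_polarity",
    "fit_t1_pixel",
    "fit_t1_map",
    "look_locker_correct",
    "estimate_noise_floor",
]


@dataclass
class ParameterMap:
    """Pixel-wise fitted map with companion layers.

    ``values`` is NaN exactly where a pixel was skipped or did not
    converge; ``converged`` is the boolean complement of that set within
    the fitted mask.
    """

    values: np.ndarray            # (H, W), ms; NaN where not converged/skipped
    amplitude: np.ndarray         # S0 (T2) or A (T1)
    rmse: np.ndarray
    converged: np.ndarray         # bool
    mask: np.ndarray              # bool, pixels that were attempted
    kind: str                     # "t2" | "t1_pre" | "t1_post"
    slice: str = ""
    subject_id: str = ""
    amplitude_b: np.ndarray | None = None   # B (T1 only)
    t1_star: np.ndarray | None = None       # ms (T1 only)
    polarity_index: np.ndarray | None = None  # count of sign-restored samples
    fit_options: FitOptions = field(default_factory=FitOptions)

    @property
    def nan_fraction(self) -> float:
        m = self.mask
        if not m.any():
            return 0.0
        return float(np.isnan(self.values[m]).mean())


class T2PixelFit(NamedTuple):
    s0: float
    t2: float
    rmse: float
    converged: bool


class T1PixelFit(NamedTuple):
    a: float
    b: float
    t1_star: float
    t1: float
    polarity_index: int
    rmse: float
    converged: bool


def look_locker_correct(a: float, b: float, t1_star: float) -> float:
    """Look-Locker correction T1 = T1* (B/A - 1); requires B > A > 0."""
    if not a > 0 or not b > a:
        raise ValueError("Look-Locker correction requires B > A > 0")
    return t1_star * (b / a - 1.0)


def estimate_noise_floor(frames: np.ndarray, patch: int = 8) -> float:
    """Noise sigma from the four image corners of every frame.

    The corner background is assumed signal-free; the Rician zero-signal
    mean is sigma * sqrt(pi/2).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    h, w = frames.shape[-2:]
    p = min(patch, h // 4, w // 4)
    corners = np.concatenate(
        [
            frames[..., :p, :p].ravel(),
            frames[..., :p, -p:].ravel(),
            frames[..., -p:, :p].ravel(),
            frames[..., -p:, -p:].ravel(),
        ]
    )
    return float(np.mean(corners) / np.sqrt(np.pi / 2.0))


# ---------------------------------------------------------------------------
# profiled residuals (closed-form amplitudes for a fixed time constant)


def _t2_profile(S: np.ndarray, te: np.ndarray, log_tau: np.ndarray):
    """Profiled RSS of S0 exp(-TE/tau) over per-pixel tau grids.

    S: (3, N) signals; log_tau: (N, m) per-pixel grid of log time constants.
    Returns (rss, s0) of shape (N, m).
    """
    tau = np.exp(log_tau)                      # (N, m)
    w = np.exp(-te[None, None, :] / tau[..., None])   # (N, m, 3)
    num = np.einsum("nmf,fn->nm", w, S)
    den = (w * w).sum(-1)
    s0 = num / den
    syy = (S * S).sum(0)                       # (N,)
    rss = syy[:, None] - num * num / den
    return rss, s0


def _t1_profile_sums(x: np.ndarray, Y: np.ndarray, syy: np.ndarray):
    """Closed-form LS fit of y = A - B x for a shared regressor x.

    x: (..., F); Y: (F, N); syy: (N,) = sum of squared y (sign-invariant).
    Returns A, B, rss broadcast over (leading dims of x, N).
    """
    n = x.shape[-1]
    sx = x.sum(-1)                             # (...,)
    sxx = (x * x).sum(-1)
    sy = Y.sum(0)                              # (N,)
    sxy = np.tensordot(x, Y, axes=([-1], [0]))  # (..., N)
    det = n * sxx - sx * sx                    # (...,)
    det = np.where(det == 0, np.nan, det)
    sy_b = sy[..., :]                          # broadcast helper
    a = (sy_b * sxx[..., None] - sx[..., None] * sxy) / det[..., None]
    b = (sx[..., None] * sy_b - n * sxy) / det[..., None]
    rss = syy[None, ...] * np.ones_like(a) - a * sy_b + b * sxy
    return a, b, rss


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vertex abscissa of the parabola through three points per row.

    x, y: (N, 3) with x1 the grid minimum.  Falls back to x[:, 1] where
    the quadratic is degenerate or the vertex leaves the bracket.
    """
    x0, x1, x2 = x[:, 0], x[:, 1], x[:, 2]
    y0, y1, y2 = y[:, 0], y[:, 1], y[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = x1 - 0.5 * (
            (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
        ) / ((x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0))
    bad = ~np.isfinite(v) | (v < np.minimum(x0, x2)) | (v > np.maximum(x0, x2))
    return np.where(bad, x1, v)


# ---------------------------------------------------------------------------
# T2


def fit_t2_pixel(
    signals, te_times=(0.0, 24.0, 55.0), options: FitOptions | None = None
) -> T2PixelFit:
    """Least-squares mono-exponential fit of one pixel's three magnitudes.

    Initialisation comes from the two-point log-linear solution using the
    first and last frame; the bounded search runs over the profiled
    residual in log T2.  All-zero signals are skipped (non-converged
    result), not an error.
    """
    options = options or FitOptions()
    s = np.asarray(signals, dtype=float)
    te = np.asarray(te_times, dtype=float)
    if s.shape != (3,) or te.shape != (3,):
        raise ValueError("exactly three samples and echo times expected")
    if te[0] != 0 or not np.all(np.diff(te) > 0):
        raise ValueError("echo times must start at 0 and increase")
    if np.all(s == 0):
        return T2PixelFit(np.nan, np.nan, np.nan, False)
    fit = _fit_t2_block(s[:, None], te, options)
    return T2PixelFit(
        float(fit["s0"][0]), float(fit["t2"][0]), float(fit["rmse"][0]),
        bool(fit["converged"][0]),
    )


def _fit_t2_block(S: np.ndarray, te: np.ndarray, options: FitOptions) -> dict:
    """Vectorised T2 fit of a (3, N) signal block."""
    n_pix = S.shape[1]
    lo, hi = np.log(options.t2_search_ms[0]), np.log(options.t2_search_ms[1])
    grid = np.linspace(lo, hi, 60)
    log_tau = np.broadcast_to(grid, (n_pix, grid.size))
    rss, _ = _t2_profile(S, te, log_tau)
    best = np.argmin(rss, axis=1)
    centre = grid[best]
    step = grid[1] - grid[0]
    for _ in range(2):
        offsets = np.linspace(-step, step, 15)
        log_tau = centre[:, None] + offsets[None, :]
        np.clip(log_tau, lo, hi, out=log_tau)
        rss, _ = _t2_profile(S, te, log_tau)
        idx = np.argmin(rss, axis=1)
        centre = np.take_along_axis(log_tau, idx[:, None], 1)[:, 0]
        step = offsets[1] - offsets[0]
    # parabolic refinement around the final bracket
    tri = centre[:, None] + np.array([-step, 0.0, step])[None, :]
    np.clip(tri, lo, hi, out=tri)
    rss3, _ = _t2_profile(S, te, tri)
    centre = _parabolic_vertex(tri, rss3)
    rss_f, s0 = _t2_profile(S, te, centre[:, None])
    t2 = np.exp(centre)
    rmse = np.sqrt(np.maximum(rss_f[:, 0], 0.0) / 3.0)
    at_bound = (centre <= lo + 1e-9) | (centre >= hi - 1e-9)
    clamp = options.t2_clamp_ms
    converged = (
        (s0[:, 0] > 0) & ~at_bound & (t2 >= clamp[0]) & (t2 <= clamp[1])
    )
    return {"s0": s0[:, 0], "t2": t2, "rmse": rmse, "converged": converged}


def fit_t2_map(
    series: ImageSeries, mask: np.ndarray, options: FitOptions | None = None
) -> ParameterMap:
    """Fit every masked pixel of a T2-prepared series.

    Pixels whose peak signal is below ``min_signal_factor`` times the
    corner-estimated noise floor are skipped; unmasked pixels are NaN.
    """
    if series.kind != "t2prep":
        raise ValueError(f"expected a t2prep series, got {series.kind!r}")
    options = options or FitOptions()
    return _fit_map(series, mask, options, kind="t2")


# ---------------------------------------------------------------------------
# T1


def restore_polarity(signals, ti_times=None) -> np.ndarray:
    """All monotone sign-flip candidates of a magnitude IR series.

    Candidate k (k = 0..n) negates the k lowest-TI samples; for n samples
    there are n + 1 candidates.  Returned as an (n + 1, n) array.
    """
    s = np.asarray(signals, dtype=float)
    if ti_times is not None:
        ti = np.asarray(ti_times, dtype=float)
        if not np.all(np.diff(ti) > 0):
            raise ValueError("inversion times must be sorted ascending")
    n = s.size
    cands = np.tile(s, (n + 1, 1))
    for k in range(1, n + 1):
        cands[k, :k] *= -1.0
    return cands


def fit_t1_pixel(
    signals, ti_times, options: FitOptions | None = None
) -> T1PixelFit:
    """Three-parameter IR fit of one pixel's 11 MOLLI magnitudes.

    Every polarity candidate is fitted by least squares (amplitudes in
    closed form, bounded search over log T1*); the candidate with the
    minimum residual wins.  ``B <= A`` at the optimum is an unphysical
    recovery and flags the pixel non-converged.
    """
    options = options or FitOptions()
    s = np.asarray(signals, dtype=float)
    ti = np.asarray(ti_times, dtype=float)
    if s.size != ti.size:
        raise ValueError("signals and inversion times must align")
    if not np.all(np.diff(ti) > 0):
        raise ValueError("inversion times must be sorted ascending")
    if np.all(s == 0):
        return T1PixelFit(np.nan, np.nan, np.nan, np.nan, -1, np.nan, False)
    fit = _fit_t1_block(s[:, None], ti, options)
    return T1PixelFit(
        float(fit["a"][0]), float(fit["b"][0]), float(fit["t1_star"][0]),
        float(fit["t1"][0]), int(fit["polarity"][0]), float(fit["rmse"][0]),
        bool(fit["converged"][0]),
    )


def _fit_t1_block(S: np.ndarray, ti: np.ndarray, options: FitOptions) -> dict:
    """Vectorised polarity-restored T1 fit of an (F, N) signal block."""
    n_frames, n_pix = S.shape
    lo = np.log(options.t1_star_search_ms[0])
    hi = np.log(options.t1_star_search_ms[1])
    grid = np.linspace(lo, hi, 60)
    x_grid = np.exp(-ti[None, :] / np.exp(grid)[:, None])   # (J, F)
    syy = (S * S).sum(0)

    # stage 1: all candidates on the shared coarse grid
    best_rss = np.full(n_pix, np.inf)
    best_k = np.zeros(n_pix, dtype=int)
    best_j = np.zeros(n_pix, dtype=int)
    signs = np.ones((n_frames, 1))
    for k in range(n_frames + 1):
        Yk = S * signs if k else S
        _, _, rss = _t1_profile_sums(x_grid, Yk, syy)       # (J, N)
        jmin = np.argmin(rss, axis=0)
        rmin = np.take_along_axis(rss, jmin[None, :], 0)[0]
        better = rmin < best_rss
        best_rss[better] = rmin[better]
        best_k[better] = k
        best_j[better] = jmin[better]
        if k < n_frames:
            signs = np.ones((n_frames, 1))
            signs[: k + 1] = -1.0

    # stages 2+: zoom per candidate group
    centre = grid[best_j]
    step = grid[1] - grid[0]
    a_out = np.empty(n_pix)
    b_out = np.empty(n_pix)
    rss_out = np.empty(n_pix)
    centre_out = np.empty(n_pix)
    for k in np.unique(best_k):
        sel = best_k == k
        Yk = S[:, sel].copy()
        Yk[:k] *= -1.0
        syy_k = syy[sel]
        c = centre[sel]
        st = step
        for _ in range(2):
            offs = np.linspace(-st, st, 15)
            lt = np.clip(c[:, None] + offs[None, :], lo, hi)   # (n, m)
            x = np.exp(-ti[None, None, :] / np.exp(lt)[..., None])  # (n, m, F)
            a, b, rss = _t1_profile_pp(x, Yk, syy_k)
            idx = np.argmin(rss, axis=1)
            c = np.take_along_axis(lt, idx[:, None], 1)[:, 0]
            st = offs[1] - offs[0]
        tri = np.clip(c[:, None] + np.array([-st, 0.0, st])[None, :], lo, hi)
        x = np.exp(-ti[None, None, :] / np.exp(tri)[..., None])
        _, _, rss3 = _t1_profile_pp(x, Yk, syy_k)
        c = _parabolic_vertex(tri, rss3)
        x = np.exp(-ti[None, None, :] / np.exp(c[:, None])[..., None])
        a, b, rss = _t1_profile_pp(x, Yk, syy_k)
        a_out[sel] = a[:, 0]
        b_out[sel] = b[:, 0]
        rss_out[sel] = rss[:, 0]
        centre_out[sel] = c

    t1_star = np.exp(centre_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = t1_star * (b_out / a_out - 1.0)
    at_bound = (centre_out <= lo + 1e-9) | (centre_out >= hi - 1e-9)
    clamp = options.t1_clamp_ms
    converged = (
        (a_out > 0)
        & (b_out > a_out)
        & ~at_bound
        & (t1 >= clamp[0])
        & (t1 <= clamp[1])
    )
    rmse = np.sqrt(np.maximum(rss_out, 0.0) / n_frames)
    return {
        "a": a_out, "b": b_out, "t1_star": t1_star, "t1": t1,
        "polarity": best_k, "rmse": rmse, "converged": converged,
    }


def _t1_profile_pp(x: np.ndarray, Y: np.ndarray, syy: np.ndarray):
    """Per-pixel variant of the closed-form y = A - Bx fit.

    x: (n, m, F) per-pixel regressors; Y: (F, n); syy: (n,).
    Returns A, B, rss of shape (n, m).
    """
    n = x.shape[-1]
    sx = x.sum(-1)
    sxx = (x * x).sum(-1)
    sy = Y.sum(0)[:, None]
    sxy = np.einsum("nmf,fn->nm", x, Y)
    det = n * sxx - sx * sx
    det = np.where(det == 0, np.nan, det)
    a = (sy * sxx - sx * sxy) / det
    b = (sx * sy - n * sxy) / det
    rss = syy[:, None] - a * sy + b * sxy
    return a, b, rss


def fit_t1_map(
    series: ImageSeries, mask: np.ndarray, options: FitOptions | None = None
) -> ParameterMap:
    """Fit every masked pixel of a MOLLI series (pre- or post-contrast)."""
    if series.kind not in ("molli_pre", "molli_post"):
        raise ValueError(f"expected a MOLLI series, got {series.kind!r}")
    options = options or FitOptions()
    return _fit_map(series, mask, options, kind=MAP_FOR_SERIES[series.kind])


# ---------------------------------------------------------------------------
# shared map assembly


def _fit_map(
    series: ImageSeries, mask: np.ndarray, options: FitOptions, kind: str
) -> ParameterMap:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.frames.shape[1:]:
        raise ValueError("mask shape must match the frame shape")
    shape = mask.shape
    nan = np.full(shape, np.nan)
    out = ParameterMap(
        values=nan.copy(),
        amplitude=nan.copy(),
        rmse=nan.copy(),
        converged=np.zeros(shape, dtype=bool),
        mask=mask,
        kind=kind,
        slice=series.slice,
        subject_id=series.subject_id,
        fit_options=options,
    )
    if kind != "t2":
        out.amplitude_b = nan.copy()
        out.t1_star = nan.copy()
        out.polarity_index = np.full(shape, -1, dtype=int)
    if not mask.any():
        return out

    S = series.frames[:, mask]                  # (F, N)
    noise = estimate_noise_floor(series.frames)
    peak = np.abs(S).max(0)
    keep = peak > options.min_signal_factor * noise
    if keep.any():
        Sk = S[:, keep]
        if kind == "t2":
            fit = _fit_t2_block(Sk, series.timings_ms, options)
            values, conv = fit["t2"], fit["converged"]
            amp = fit["s0"]
        else:
            fit = _fit_t1_block(Sk, series.timings_ms, options)
            values, conv = fit["t1"], fit["converged"]
            amp = fit["a"]
        idx = np.flatnonzero(mask.ravel())[keep]

        def scatter(layer, vals):
            flat = layer.ravel()
            flat[idx] = vals

        scatter(out.converged, conv)
        scatter(out.values, np.where(conv, values, np.nan))
        scatter(out.amplitude, amp)
        scatter(out.rmse, fit["rmse"])
        if kind != "t2":
            scatter(out.amplitude_b, fit["b"])
            scatter(out.t1_star, fit["t1_star"])
            scatter(out.polarity_index, fit["polarity"])
    return out
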