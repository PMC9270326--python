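"""Grid-search model fitting with split-half cross-validation.

Voxel time courses are per-condition averages concatenated across the
four condition blocks (odd-run and even-run averages, 4 x 56 = 224 TRs).
Because every event in a block shares one of ~100 unique (duration,
period) timings, a block's predicted BOLD is linear in the vector of
per-timing amplitudes: ``pred = B @ a`` where ``B`` maps unit amplitude
at each unique timing to the convolved, TR-sampled response.  ``B`` is
precomputed once per schedule and HRF (:class:`SessionDesign`), after
which candidate predictions for any parameter set cost a single small
matrix product.  The same forward path generates simulated data, so the
simulator and fitter cannot drift apart.

Fitting: exhaustive grid search (monotonic: compressive exponents with
component amplitudes solved per candidate under a non-negativity
fallback; tuned: six parameters), followed for the tuned model by a
coordinate-wise pattern search seeded at the best grid point and
confined between that point's grid neighbors, with halving steps.

Goodness of fit is variance explained (VE): the squared Pearson
correlation between prediction and data, equivalently 1 - RSS/TSS after
a free gain/offset refit, so VE is invariant to affine transforms of
either series.  Cross-validation regenerates the prediction from the
fitted parameters and refits only gain and offset on the held-out
split.  Tuned fits whose preferred duration or period falls outside
60-990 ms (the presented stimulus range) are flagged out-of-range and
given zero cross-validated VE, since such fits mimic monotonic
responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import response_models as rm
from .hemodynamics import DEFAULT_DT_MS, HRFParams, two_gamma_hrf
from .stimulus_design import CONDITIONS, TR_MS, ConditionSchedule, build_condition_schedule

OOR_LOW_MS = 60
OOR_HIGH_MS = 990


# ---------------------------------------------------------------------------
# design precomputation


class SessionDesign:
    """Precomputed linear map from unique-timing amplitudes to BOLD.

    Blocks are convolved independently (measured time courses are
    per-condition averages over runs with counterbalanced block orders,
    so carry-over between blocks averages out) and concatenated in the
    canonical condition order.
    """

    def __init__(
        self,
        blocks: tuple[ConditionSchedule, ...] | None = None,
        hrf: HRFParams | None = None,
        dt_ms: int = DEFAULT_DT_MS,
    ):
        if blocks is None:
            blocks = tuple(build_condition_schedule(c) for c in CONDITIONS)
        self.blocks = blocks
        self.hrf = hrf or HRFParams()
        self.dt_ms = dt_ms
        self.n_tr = sum(b.n_tr for b in blocks)

        timings = sorted(
            {e.timing for b in blocks for e in b.events},
            key=lambda t: (t.duration_ms, t.period_ms),
        )
        self.timings = timings
        self.dur_s = np.array([t.duration_s for t in timings])
        self.per_s = np.array([t.period_s for t in timings])
        self.freq_hz = np.array([t.frequency_hz for t in timings])
        self._index = {t: i for i, t in enumerate(timings)}
        self.B = self._build_design(self.hrf)

    def _build_design(self, hrf: HRFParams) -> np.ndarray:
        from scipy.signal import fftconvolve

        kernel = two_gamma_hrf(hrf, self.dt_ms)
        m = len(self.timings)
        B = np.zeros((self.n_tr, m))
        step = TR_MS // self.dt_ms
        row = 0
        for block in self.blocks:
            n_samples = block.n_tr * TR_MS // self.dt_ms
            fine = np.zeros((m, n_samples))
            for e in block.events:
                fine[self._index[e.timing], e.offset_ms // self.dt_ms] += 1.0
            conv = fftconvolve(fine, kernel[None, :], axes=1)[:, :n_samples]
            conv[np.abs(conv) < 1e-13] = 0.0
            B[row : row + block.n_tr, :] = conv[:, ::step].T
            row += block.n_tr
        return B

    def with_hrf(self, hrf: HRFParams) -> "SessionDesign":
        new = object.__new__(SessionDesign)
        new.__dict__.update(self.__dict__)
        new.hrf = hrf
        new.B = self._build_design(hrf)
        return new

    # forward predictions ---------------------------------------------------

    def predict_from_amplitudes(self, amplitudes: np.ndarray) -> np.ndarray:
        """(..., m) per-timing amplitudes -> (..., n_tr) predicted BOLD."""
        return np.asarray(amplitudes) @ self.B.T

    def monotonic_regressors(self, exp_dur: float, exp_freq: float):
        """Duration and frequency component time courses for unit betas."""
        d, f = rm.monotonic_amplitudes(self.dur_s, self.freq_hz, exp_dur, exp_freq)
        return self.B @ d, self.B @ f

    def predict_monotonic(self, params: rm.MonotonicParams) -> np.ndarray:
        d, f = self.monotonic_regressors(params.exp_dur, params.exp_freq)
        return params.beta_dur * d + params.beta_freq * f

    def predict_tuned(
        self, params: rm.TunedParams, rotation_mode: str = "corrected"
    ) -> np.ndarray:
        a = rm.tuned_amplitudes(
            self.dur_s,
            self.per_s,
            params.pref_duration_s,
            params.pref_period_s,
            params.sigma_major,
            params.sigma_minor,
            params.theta_rad,
            params.exp_freq,
            rotation_mode,
        )
        return self.B @ a

    def amplitude_vector(self, params) -> np.ndarray:
        """Per-unique-timing amplitudes of a fitted model (for HRF refits)."""
        if isinstance(params, rm.MonotonicParams):
            d, f = rm.monotonic_amplitudes(
                self.dur_s, self.freq_hz, params.exp_dur, params.exp_freq
            )
            return params.beta_dur * d + params.beta_freq * f
        return rm.tuned_amplitudes(
            self.dur_s,
            self.per_s,
            params.pref_duration_s,
            params.pref_period_s,
            params.sigma_major,
            params.sigma_minor,
            params.theta_rad,
            params.exp_freq,
        )


# ---------------------------------------------------------------------------
# grids


def _sigma_pairs(values_ms):
    vals = np.asarray(values_ms, dtype=float)
    maj, mnr = [], []
    for a in vals:
        for b in vals[vals <= a]:
            maj.append(a)
            mnr.append(b)
    return np.array(maj), np.array(mnr)


@dataclass(frozen=True)
class GridSpec:
    """Candidate values per free parameter, plus descent settings.

    Preferred-timing candidates deliberately extend beyond the presented
    60-990 ms range so out-of-range optima are expressible.
    """

    exp_dur_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 1.001, 0.05), 2)
    )
    exp_freq_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 1.001, 0.05), 2)
    )
    pref_ms_values: np.ndarray = field(
        default_factory=lambda: np.arange(25.0, 1501.0, 75.0)
    )
    sigma_ms_values: np.ndarray = field(
        default_factory=lambda: np.round(np.geomspace(50.0, 2000.0, 6), 1)
    )
    theta_values: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, math.pi - 1e-9, math.pi / 8)
    )
    tuned_exp_freq_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 1.001, 0.1), 2)
    )
    shrink: float = 0.5
    tol: float = 1e-4
    max_sweeps: int = 60
    n_starts: int = 3  # descent restarts from the best grid points

    @classmethod
    def coarse(cls) -> "GridSpec":
        """Reduced-density grid for quick exploratory fits and tests."""
        return cls(
            pref_ms_values=np.arange(25.0, 1501.0, 150.0),
            sigma_ms_values=np.round(np.geomspace(50.0, 2000.0, 4), 1),
            theta_values=np.arange(0.0, math.pi - 1e-9, math.pi / 4),
            tuned_exp_freq_values=np.array([0.2, 0.4, 0.6, 0.8, 1.0]),
        )


# ---------------------------------------------------------------------------
# elementary operations


def variance_explained(prediction: np.ndarray, data: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either series is constant."""
    p = np.asarray(prediction, dtype=float)
    y = np.asarray(data, dtype=float)
    if p.shape != y.shape or p.size < 3:
        raise ValueError("series must have equal length >= 3")
    pc = p - p.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(pc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    r = float(pc @ yc / denom)
    return min(r * r, 1.0)


def solve_component_amplitudes(dur_regressor, freq_regressor, data):
    """Two-component GLM (with intercept) under the non-negativity fallback.

    Solve both components freely; a negative amplitude is set to zero and
    the other refit alone; if that refit is also negative both are zero
    (and the model explains no variance).  Returns (beta_dur, beta_freq).
    """
    d = np.asarray(dur_regressor, float)
    f = np.asarray(freq_regressor, float)
    y = np.asarray(data, float)
    dc, fc, yc = d - d.mean(), f - f.mean(), y - y.mean()
    sdd, sff, sdf = dc @ dc, fc @ fc, dc @ fc
    sdy, sfy = dc @ yc, fc @ yc

    def single(sxx, sxy):
        if sxx <= 0:
            return 0.0
        b = sxy / sxx
        return b if b > 0 else 0.0

    det = sdd * sff - sdf * sdf
    if det > 1e-12 * max(sdd * sff, 1e-300):
        bd = (sff * sdy - sdf * sfy) / det
        bf = (sdd * sfy - sdf * sdy) / det
        if bd >= 0 and bf >= 0:
            return bd, bf
        if bd < 0 <= bf:
            return 0.0, single(sff, sfy)
        if bf < 0 <= bd:
            return single(sdd, sdy), 0.0
    # both negative or collinear: best feasible single-component fit
    bd1, bf1 = single(sdd, sdy), single(sff, sfy)
    ve_d = (sdy * sdy / sdd) if bd1 > 0 else -1.0
    ve_f = (sfy * sfy / sff) if bf1 > 0 else -1.0
    if ve_d <= 0 and ve_f <= 0:
        return 0.0, 0.0
    return (bd1, 0.0) if ve_d >= ve_f else (0.0, bf1)


# ---------------------------------------------------------------------------
# batch monotonic fit


def fit_monotonic_batch(Y: np.ndarray, design: SessionDesign, grid: GridSpec | None = None):
    """Exhaustive exponent-grid fit for all voxels at once.

    Returns a dict of per-voxel arrays: exp_dur, exp_freq, beta_dur,
    beta_freq, ve.  Linear comparison variants are obtained by passing a
    grid whose exponent candidates are pinned to 1.
    """
    grid = grid or GridSpec()
    Y = np.atleast_2d(np.asarray(Y, float))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    syy_safe = np.where(syy > 0, syy, 1.0)

    ed_vals = np.asarray(grid.exp_dur_values, float)
    ef_vals = np.asarray(grid.exp_freq_values, float)
    D = design.predict_from_amplitudes(
        design.dur_s[None, :] ** ed_vals[:, None]
    )  # (kd, n_tr)
    F = design.predict_from_amplitudes(
        design.freq_hz[None, :] ** (ef_vals[:, None] - 1.0)
    )
    Dc = D - D.mean(axis=1, keepdims=True)
    Fc = F - F.mean(axis=1, keepdims=True)
    sdd = np.einsum("ij,ij->i", Dc, Dc)
    sff = np.einsum("ij,ij->i", Fc, Fc)
    sdf = Dc @ Fc.T  # (kd, kf)
    Sdy = Dc @ Yc.T  # (kd, nvox)
    Sfy = Fc @ Yc.T  # (kf, nvox)

    nvox = Y.shape[0]
    best = dict(
        ve=np.zeros(nvox),
        exp_dur=np.full(nvox, ed_vals[0]),
        exp_freq=np.full(nvox, ef_vals[0]),
        beta_dur=np.zeros(nvox),
        beta_freq=np.zeros(nvox),
    )
    for i in range(len(ed_vals)):
        for j in range(len(ef_vals)):
            det = sdd[i] * sff[j] - sdf[i, j] ** 2
            sdy, sfy = Sdy[i], Sfy[j]
            if det > 1e-12 * max(sdd[i] * sff[j], 1e-300):
                bd = (sff[j] * sdy - sdf[i, j] * sfy) / det
                bf = (sdd[i] * sfy - sdf[i, j] * sdy) / det
            else:
                bd = np.full(nvox, -1.0)
                bf = np.full(nvox, -1.0)
            bd1 = np.where(sdd[i] > 0, np.maximum(sdy / max(sdd[i], 1e-300), 0.0), 0.0)
            bf1 = np.where(sff[j] > 0, np.maximum(sfy / max(sff[j], 1e-300), 0.0), 0.0)
            ve_d1 = np.where(bd1 > 0, sdy**2 / max(sdd[i], 1e-300), 0.0)
            ve_f1 = np.where(bf1 > 0, sfy**2 / max(sff[j], 1e-300), 0.0)

            both_ok = (bd >= 0) & (bf >= 0)
            neg_d = (bd < 0) & (bf >= 0)
            neg_f = (bf < 0) & (bd >= 0)
            both_bad = ~(both_ok | neg_d | neg_f)

            ve = np.where(both_ok, (bd * sdy + bf * sfy) / syy_safe, 0.0)
            ve = np.where(neg_d, ve_f1 / syy_safe, ve)
            ve = np.where(neg_f, ve_d1 / syy_safe, ve)
            ve = np.where(both_bad, np.maximum(ve_d1, ve_f1) / syy_safe, ve)
            ve = np.clip(ve, 0.0, 1.0)

            out_bd = np.where(both_ok, bd, 0.0)
            out_bd = np.where(neg_f | (both_bad & (ve_d1 >= ve_f1)), bd1, out_bd)
            out_bf = np.where(both_ok, bf, 0.0)
            out_bf = np.where(neg_d | (both_bad & (ve_f1 > ve_d1)), bf1, out_bf)

            upd = ve > best["ve"]
            best["ve"] = np.where(upd, ve, best["ve"])
            best["exp_dur"] = np.where(upd, ed_vals[i], best["exp_dur"])
            best["exp_freq"] = np.where(upd, ef_vals[j], best["exp_freq"])
            best["beta_dur"] = np.where(upd, out_bd, best["beta_dur"])
            best["beta_freq"] = np.where(upd, out_bf, best["beta_freq"])
    best["ve"] = np.where(syy > 0, best["ve"], 0.0)
    return best


# ---------------------------------------------------------------------------
# batch tuned fit


def _tuned_grid_arrays(grid: GridSpec):
    pref = np.asarray(grid.pref_ms_values, float) / 1000.0
    smaj, smin = _sigma_pairs(np.asarray(grid.sigma_ms_values, float) / 1000.0)
    th = np.asarray(grid.theta_values, float)
    pd_, pp_ = np.meshgrid(pref, pref, indexing="ij")
    pd_, pp_ = pd_.ravel(), pp_.ravel()
    # full outer product over (pref pair) x (sigma pair) x theta
    npair, nsig, nth = pd_.size, smaj.size, th.size
    out = dict(
        pref_dur=np.repeat(pd_, nsig * nth),
        pref_per=np.repeat(pp_, nsig * nth),
        sigma_major=np.tile(np.repeat(smaj, nth), npair),
        sigma_minor=np.tile(np.repeat(smin, nth), npair),
        theta=np.tile(th, npair * nsig),
    )
    return out


def fit_tuned_batch(
    Y: np.ndarray,
    design: SessionDesign,
    grid: GridSpec | None = None,
    rotation_mode: str = "corrected",
    descent: bool = True,
):
    """Grid search plus per-voxel local pattern search for the tuned model.

    Returns a dict of per-voxel arrays: pref_dur_s, pref_per_s,
    sigma_major_s, sigma_minor_s, theta, exp_freq, ve, out_of_range.
    """
    grid = grid or GridSpec()
    Y = np.atleast_2d(np.asarray(Y, float))
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(Yc, axis=1)
    ok = ynorm > 0
    Yn = np.where(ok[:, None], Yc / np.where(ynorm[:, None] > 0, ynorm[:, None], 1.0), 0.0)

    g = _tuned_grid_arrays(grid)
    ef_vals = np.asarray(grid.tuned_exp_freq_values, float)
    gauss = rm.tuned_amplitudes(
        design.dur_s[None, :],
        design.per_s[None, :],
        g["pref_dur"][:, None],
        g["pref_per"][:, None],
        g["sigma_major"][:, None],
        g["sigma_minor"][:, None],
        g["theta"][:, None],
        1.0,  # frequency term applied per exp_freq chunk below
        rotation_mode,
    ).astype(np.float32)

    nvox = Y.shape[0]
    n_ef = len(ef_vals)
    ve_per_ef = np.zeros((n_ef, nvox))
    g_per_ef = np.zeros((n_ef, nvox), dtype=np.int64)
    Bt32 = design.B.T.astype(np.float32)
    Yn32 = Yn.astype(np.float32)
    for e, ef in enumerate(ef_vals):
        fterm = (design.freq_hz ** (ef - 1.0)).astype(np.float32)
        P = (gauss * fterm[None, :]) @ Bt32  # (G, n_tr)
        P -= P.mean(axis=1, keepdims=True)
        pn = np.linalg.norm(P, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            P /= np.where(pn[:, None] > 0, pn[:, None], 1.0)
        corr = P @ Yn32.T  # (G, nvox)
        ve = corr.astype(np.float64) ** 2
        ve[pn == 0, :] = 0.0
        g_per_ef[e] = ve.argmax(axis=0)
        ve_per_ef[e] = ve[g_per_ef[e], np.arange(nvox)]

    best_e = ve_per_ef.argmax(axis=0)
    best_g = g_per_ef[best_e, np.arange(nvox)]
    best_ve = ve_per_ef[best_e, np.arange(nvox)]
    params = dict(
        pref_dur_s=g["pref_dur"][best_g],
        pref_per_s=g["pref_per"][best_g],
        sigma_major_s=g["sigma_major"][best_g],
        sigma_minor_s=g["sigma_minor"][best_g],
        theta=g["theta"][best_g],
        exp_freq=ef_vals[best_e],
        ve=best_ve,
    )
    if descent:
        # restart the local search from the best grid point of each of the
        # top frequency-exponent levels: cheap insurance against landing in
        # the wrong basin of this multimodal objective
        n_starts = max(1, min(grid.n_starts, n_ef))
        for v in range(nvox):
            if not ok[v] or best_ve[v] <= 0:
                continue
            starts = np.argsort(-ve_per_ef[:, v])[:n_starts]
            best = None
            for e in starts:
                gi = g_per_ef[e, v]
                res = _tuned_descent(
                    Yn[v],
                    design,
                    grid,
                    rotation_mode,
                    start=dict(
                        pref_dur_s=g["pref_dur"][gi],
                        pref_per_s=g["pref_per"][gi],
                        sigma_major_s=g["sigma_major"][gi],
                        sigma_minor_s=g["sigma_minor"][gi],
                        theta=g["theta"][gi],
                        exp_freq=ef_vals[e],
                    ),
                    start_ve=ve_per_ef[e, v],
                )
                if best is None or res["ve"] > best["ve"]:
                    best = res
            if best["ve"] >= params["ve"][v]:
                for k, val in best.items():
                    params[k][v] = val
    params["ve"] = np.where(ok, np.clip(params["ve"], 0.0, 1.0), 0.0)
    pd_ms = params["pref_dur_s"] * 1000
    pp_ms = params["pref_per_s"] * 1000
    params["out_of_range"] = (
        (pd_ms < OOR_LOW_MS) | (pd_ms > OOR_HIGH_MS) | (pp_ms < OOR_LOW_MS) | (pp_ms > OOR_HIGH_MS)
    )
    return params


def _neighbor_span(values: np.ndarray, x: float) -> tuple[float, float]:
    """Bounds at the grid neighbors of the grid value nearest to x."""
    v = np.asarray(values, float)
    i = int(np.argmin(np.abs(v - x)))
    lo = v[i - 1] if i > 0 else v[0] - (v[1] - v[0]) if v.size > 1 else v[0]
    hi = v[i + 1] if i < v.size - 1 else v[-1] + (v[-1] - v[-2]) if v.size > 1 else v[-1]
    return float(lo), float(hi)


def _tuned_descent(yn, design, grid, rotation_mode, start, start_ve):
    """Coordinate pattern search between grid neighbors, halving steps."""
    names = ["pref_dur_s", "pref_per_s", "sigma_major_s", "sigma_minor_s", "theta", "exp_freq"]
    cur = np.array([start[n] for n in names])
    pref_s = np.asarray(grid.pref_ms_values, float) / 1000.0
    sig_s = np.asarray(grid.sigma_ms_values, float) / 1000.0
    th_step = grid.theta_values[1] - grid.theta_values[0] if len(grid.theta_values) > 1 else math.pi / 8
    ef_v = np.asarray(grid.tuned_exp_freq_values, float)
    bounds = [
        _neighbor_span(pref_s, cur[0]),
        _neighbor_span(pref_s, cur[1]),
        _neighbor_span(sig_s, cur[2]),
        _neighbor_span(sig_s, cur[3]),
        (cur[4] - th_step, cur[4] + th_step),
        _neighbor_span(ef_v, cur[5]),
    ]
    bounds[2] = (max(bounds[2][0], 1e-3), bounds[2][1])
    bounds[3] = (max(bounds[3][0], 1e-3), bounds[3][1])
    bounds[5] = (max(bounds[5][0], 1e-3), min(bounds[5][1], 1.0))
    steps = np.array([(hi - lo) / 4.0 for lo, hi in bounds])

    def ve_of(p):
        if p[3] > p[2]:  # sigma_minor may not exceed sigma_major
            return -1.0
        a = rm.tuned_amplitudes(
            design.dur_s, design.per_s, p[0], p[1], p[2], p[3], p[4], p[5], rotation_mode
        )
        pred = design.B @ a
        pc = pred - pred.mean()
        n = np.linalg.norm(pc)
        if n == 0:
            return 0.0
        r = (pc / n) @ yn
        return r * r

    cur_ve = ve_of(cur)
    if cur_ve < 0:
        cur_ve = start_ve
    for _ in range(grid.max_sweeps):
        improved = False
        for i in range(6):
            for sign in (1.0, -1.0):
                x = cur[i] + sign * steps[i]
                if not bounds[i][0] <= x <= bounds[i][1]:
                    continue
                trial = cur.copy()
                trial[i] = x
                v = ve_of(trial)
                if v > cur_ve:
                    cur, cur_ve = trial, v
                    improved = True
                    break
        if not improved:
            steps *= grid.shrink
            if np.all(steps < grid.tol):
                break
    return dict(
        pref_dur_s=cur[0],
        pref_per_s=cur[1],
        sigma_major_s=cur[2],
        sigma_minor_s=cur[3],
        theta=cur[4] % math.pi,
        exp_freq=cur[5],
        ve=cur_ve,
    )


# ---------------------------------------------------------------------------
# FitResult, per-voxel API, cross-validation, classification


@dataclass
class FitResult:
    """Fit of one model to one voxel, per training split."""

    model_kind: str  # "monotonic" | "tuned"
    params: tuple  # fitted parameter object per split
    ve_train: tuple  # training VE per split
    ve_cv: tuple | None = None  # cross-validated VE per split
    out_of_range: tuple = (False, False)
    classification: str | None = None


def _mono_params_from_batch(res, v) -> rm.MonotonicParams:
    return rm.MonotonicParams(
        exp_dur=float(res["exp_dur"][v]),
        exp_freq=float(res["exp_freq"][v]),
        beta_dur=float(max(res["beta_dur"][v], 0.0)),
        beta_freq=float(max(res["beta_freq"][v], 0.0)),
    )


def _tuned_params_from_batch(res, v) -> rm.TunedParams:
    return rm.TunedParams(
        pref_duration_s=float(res["pref_dur_s"][v]),
        pref_period_s=float(res["pref_per_s"][v]),
        sigma_major=float(res["sigma_major_s"][v]),
        sigma_minor=float(res["sigma_minor_s"][v]),
        theta_rad=float(res["theta"][v]),
        exp_freq=float(min(max(res["exp_freq"][v], 1e-6), 1.0)),
    )


def fit_monotonic(y, design: SessionDesign, grid: GridSpec | None = None) -> FitResult:
    res = fit_monotonic_batch(np.atleast_2d(y), design, grid)
    return FitResult(
        model_kind="monotonic",
        params=(_mono_params_from_batch(res, 0),),
        ve_train=(float(res["ve"][0]),),
    )

def fit_tuned(
    y,
    design: SessionDesign,
    grid: GridSpec | None = None,
    rotation_mode: str = "corrected",
    descent: bool = True,
) -> FitResult:
    res = fit_tuned_batch(np.atleast_2d(y), design, grid, rotation_mode, descent)
    return FitResult(
        model_kind="tuned",
        params=(_tuned_params_from_batch(res, 0),),
        ve_train=(float(res["ve"][0]),),
        out_of_range=(bool(res["out_of_range"][0]),),
    )


def crossvalidate(fit: FitResult, heldout, design: SessionDesign, split: int = 0) -> float:
    """VE of the split's fitted model on the complementary data half.

    Gain and offset are refit implicitly (VE is affine-invariant); tuned
    out-of-range fits score 0.
    """
    if fit.model_kind == "tuned" and fit.out_of_range[split]:
        return 0.0
    p = fit.params[split]
    if fit.model_kind == "monotonic":
        if p.beta_dur == 0 and p.beta_freq == 0:
            return 0.0
        pred = design.predict_monotonic(p)
    else:
        pred = design.predict_tuned(p)
    return variance_explained(pred, heldout)


def classify_voxel(fit_mono: FitResult, fit_tuned: FitResult, threshold: float = 0.2) -> str:
    """'excluded' | 'monotonic' | 'tuned' from both models' split fits.

    Excluded when no model exceeds the training-VE threshold on any
    split; otherwise the label goes to the model with the higher mean
    cross-validated VE (ties and out-of-range tuned fits -> monotonic).
    """
    train_max = max(max(fit_mono.ve_train), max(fit_tuned.ve_train))
    if train_max <= threshold:
        return "excluded"
    cv_mono = float(np.mean(fit_mono.ve_cv))
    cv_tuned = float(np.mean(fit_tuned.ve_cv))
    if all(fit_tuned.out_of_range):
        return "monotonic"
    return "tuned" if cv_tuned > cv_mono else "monotonic"


# ---------------------------------------------------------------------------
# cohort-level driver


def fit_voxels(
    Y_a: np.ndarray,
    Y_b: np.ndarray,
    design: SessionDesign,
    grid: GridSpec | None = None,
    rotation_mode: str = "corrected",
    descent: bool = True,
    voxel_ids=None,
) -> pd.DataFrame:
    """Fit both models on each split of every voxel and cross-validate.

    Returns a tidy frame with one row per voxel x model x training split
    (split 'A' rows were fit on ``Y_a`` and validated on ``Y_b``, and
    vice versa), carrying fitted parameters, training VE and
    cross-validated VE.
    """
    grid = grid or GridSpec()
    Y_a = np.atleast_2d(np.asarray(Y_a, float))
    Y_b = np.atleast_2d(np.asarray(Y_b, float))
    if Y_a.shape != Y_b.shape:
        raise ValueError("split halves must have identical shape")
    nvox = Y_a.shape[0]
    if voxel_ids is None:
        voxel_ids = np.arange(nvox)

    rows = []
    for split, (Yt, Yh) in (("A", (Y_a, Y_b)), ("B", (Y_b, Y_a))):
        mono = fit_monotonic_batch(Yt, design, grid)
        tuned = fit_tuned_batch(Yt, design, grid, rotation_mode, descent)
        # cross-validated VE, vectorized per model
        Yhc = Yh - Yh.mean(axis=1, keepdims=True)
        yhn = np.linalg.norm(Yhc, axis=1)
        for kind, res in (("monotonic", mono), ("tuned", tuned)):
            if kind == "monotonic":
                amp = (
                    res["beta_dur"][:, None] * design.dur_s[None, :] ** res["exp_dur"][:, None]
                    + res["beta_freq"][:, None]
                    * design.freq_hz[None, :] ** (res["exp_freq"][:, None] - 1.0)
                )
            else:
                amp = rm.tuned_amplitudes(
                    design.dur_s[None, :],
                    design.per_s[None, :],
                    res["pref_dur_s"][:, None],
                    res["pref_per_s"][:, None],
                    res["sigma_major_s"][:, None],
                    res["sigma_minor_s"][:, None],
                    res["theta"][:, None],
                    res["exp_freq"][:, None],
                    rotation_mode,
                )
            pred = design.predict_from_amplitudes(amp)
            pc = pred - pred.mean(axis=1, keepdims=True)
            pn = np.linalg.norm(pc, axis=1)
            denom = pn * yhn
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.einsum("ij,ij->i", pc, Yhc) / np.where(denom > 0, denom, 1.0)
            ve_cv = np.where(denom > 0, r**2, 0.0)
            if kind == "tuned":
                ve_cv = np.where(res["out_of_range"], 0.0, ve_cv)
            base = dict(
                voxel_id=voxel_ids,
                model=kind,
                split=split,
                ve_train=res["ve"],
                ve_cv=np.clip(ve_cv, 0.0, 1.0),
            )
            if kind == "monotonic":
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = res["beta_dur"] / res["beta_freq"]
                extra = dict(
                    exp_dur=res["exp_dur"],
                    exp_freq=res["exp_freq"],
                    beta_dur=res["beta_dur"],
                    beta_freq=res["beta_freq"],
                    amplitude_ratio=ratio,
                    out_of_range=False,
                )
            else:
                extra = dict(
                    pref_duration_ms=res["pref_dur_s"] * 1000,
                    pref_period_ms=res["pref_per_s"] * 1000,
                    sigma_major_ms=res["sigma_major_s"] * 1000,
                    sigma_minor_ms=res["sigma_minor_s"] * 1000,
                    theta_rad=res["theta"],
                    tuned_exp_freq=res["exp_freq"],
                    out_of_range=res["out_of_range"],
                )
            rows.append(pd.DataFrame({**base, **extra}))
    return pd.concat(rows, ignore_index=True)


def fit_participant(
    Y_a: np.ndarray,
    Y_b: np.ndarray,
    design: SessionDesign,
    grid: GridSpec | None = None,
    rotation_mode: str = "corrected",
    descent: bool = True,
    hrf_gate: float = 0.10,
):
    """One participant's full fit including the HRF re-estimation cycle.

    Both neural models are first fit with the starting HRF; the
    participant HRF is then refit over voxels whose better model
    explains more than ``hrf_gate`` of the training variance (amplitude
    vectors held fixed), and the neural models are refit once with the
    new HRF.  Returns ``(fits, hrf, design)`` where ``fits`` is the
    :func:`fit_voxels` frame under the refit HRF.
    """
    from .hemodynamics import refit_hrf

    grid = grid or GridSpec()
    Y_a = np.atleast_2d(np.asarray(Y_a, float))
    mono = fit_monotonic_batch(Y_a, design, grid)
    tuned = fit_tuned_batch(Y_a, design, grid, rotation_mode, descent)
    amps = np.empty((Y_a.shape[0], len(design.timings)))
    for v in range(Y_a.shape[0]):
        params = (
            _tuned_params_from_batch(tuned, v)
            if tuned["ve"][v] > mono["ve"][v]
            else _mono_params_from_batch(mono, v)
        )
        amps[v] = design.amplitude_vector(params)
    train_ve = np.maximum(mono["ve"], tuned["ve"])
    hrf, ok = refit_hrf(
        amps,
        Y_a,
        train_ve,
        lambda p: design.with_hrf(p).B,
        start=design.hrf,
        ve_gate=hrf_gate,
    )
    refit_design = design.with_hrf(hrf) if ok else design
    fits = fit_voxels(Y_a, Y_b, refit_design, grid, rotation_mode, descent)
    return fits, hrf, refit_design


def classify_table(fits: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Per-voxel classification from a :func:`fit_voxels` frame."""
    out = []
    for vid, gdf in fits.groupby("voxel_id", sort=False):
        mono = gdf[gdf.model == "monotonic"]
        tun = gdf[gdf.model == "tuned"]
        train_max = max(mono.ve_train.max(), tun.ve_train.max())
        if train_max <= threshold:
            label = "excluded"
        elif tun.out_of_range.all():
            label = "monotonic"
        else:
            label = "tuned" if tun.ve_cv.mean() > mono.ve_cv.mean() else "monotonic"
        out.append(
            dict(
                voxel_id=vid,
                classification=label,
                cv_monotonic=mono.ve_cv.mean(),
                cv_tuned=tun.ve_cv.mean(),
                train_max=train_max,
            )
        )
    return pd.DataFrame(out)
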