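"""Hemodynamic convolution: neural impulse trains -> predicted BOLD.

The haemodynamic response function (HRF) is the canonical difference of
two gamma densities (positive peak minus a scaled undershoot),
normalized to unit peak amplitude, sampled on a fine ``dt`` grid over a
0-30 s support.  Impulses are binned on the same grid, convolved with
the kernel and read out at TR onsets.

One HRF is used per participant.  :func:`refit_hrf` re-estimates the HRF
parameters given already-fit neural models, maximizing summed variance
explained over voxels whose neural model explains more than 10% of the
variance, after which the neural parameters are refit once with the new
HRF (the fit-neural / fit-HRF / refit-neural alternation runs one cycle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

HRF_SUPPORT_S = 30.0
DEFAULT_DT_MS = 10


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF parameters (seconds; ratio is peak/undershoot amplitude)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 6.0

    def __post_init__(self) -> None:
        if min(
            self.peak_delay_s,
            self.undershoot_delay_s,
            self.peak_dispersion_s,
            self.undershoot_dispersion_s,
            self.undershoot_ratio,
        ) <= 0:
            raise ValueError("all HRF parameters must be positive")
        if self.undershoot_delay_s <= self.peak_delay_s:
            raise ValueError("undershoot delay must exceed peak delay")


def two_gamma_hrf(params: HRFParams, dt_ms: int = DEFAULT_DT_MS) -> np.ndarray:
    """Sampled kernel on [0, 30 s] with unit peak amplitude.

    Gamma shapes are delay/dispersion with scale = dispersion (so the
    density mode sits at delay - dispersion).
    """
    if dt_ms <= 0 or 2100 % dt_ms != 0:
        raise ValueError("dt_ms must be positive and divide the 2100 ms TR evenly")
    t = np.arange(0, HRF_SUPPORT_S + 1e-9, dt_ms / 1000.0)
    peak = gamma_dist.pdf(
        t, params.peak_delay_s / params.peak_dispersion_s, scale=params.peak_dispersion_s
    )
    under = gamma_dist.pdf(
        t,
        params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    h = peak - under / params.undershoot_ratio
    return h / h.max()


def predict_bold(
    impulses,
    hrf: HRFParams | np.ndarray,
    tr_ms: int = 2100,
    n_tr: int = 224,
    dt_ms: int = DEFAULT_DT_MS,
) -> np.ndarray:
    """Convolve an impulse train with the HRF and sample at TR onsets.

    ``impulses`` is an iterable of (time_ms, amplitude); times must lie in
    [0, n_tr * tr_ms).  The operator is linear in the impulse amplitudes.
    """
    kernel = two_gamma_hrf(hrf, dt_ms) if isinstance(hrf, HRFParams) else hrf
    n_samples = n_tr * tr_ms // dt_ms
    fine = np.zeros(n_samples)
    for t_ms, a in impulses:
        if not 0 <= t_ms < n_tr * tr_ms:
            raise ValueError(f"impulse at {t_ms} ms lies outside the run")
        fine[int(t_ms // dt_ms)] += a
    conv = np.convolve(fine, kernel)[:n_samples]
    return conv[:: tr_ms // dt_ms].copy()


def refit_hrf(
    amplitude_vectors: np.ndarray,
    data: np.ndarray,
    train_ve: np.ndarray,
    design_builder,
    start: HRFParams | None = None,
    ve_gate: float = 0.10,
    max_iter: int = 40,
    tol: float = 1e-4,
) -> tuple[HRFParams, bool]:
    """Coordinate pattern search for the participant HRF.

    Parameters
    ----------
    amplitude_vectors : (n_vox, m) per-event amplitudes of each voxel's
        fitted neural model on the schedule's unique timings (held fixed).
    data : (n_vox, n_tr) measured time courses.
    train_ve : (n_vox,) training variance explained used for the 10% gate.
    design_builder : callable(HRFParams) -> (n_tr, m) matrix mapping
        unique-timing amplitudes to a predicted time course.
    Returns (params, ok); ``ok`` is False when no voxel passes the gate,
    in which case defaults are returned with a warning.
    """
    start = start or HRFParams()
    keep = np.asarray(train_ve) > ve_gate
    if not keep.any():
        warnings.warn("no voxel passed the HRF refit gate; returning default HRF")
        return start, False
    A = np.asarray(amplitude_vectors)[keep]
    Y = np.asarray(data)[keep]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ynorm = np.linalg.norm(Yc, axis=1)

    def objective(p: HRFParams) -> float:
        B = design_builder(p)
        pred = A @ B.T
        pc = pred - pred.mean(axis=1, keepdims=True)
        pn = np.linalg.norm(pc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", pc, Yc) / (pn * ynorm)
        r = np.nan_to_num(r)
        return float(np.sum(r**2))

    fields = [
        ("peak_delay_s", 1.0, 3.0, 10.0),
        ("undershoot_delay_s", 2.0, 8.0, 24.0),
        ("peak_dispersion_s", 0.3, 0.3, 3.0),
        ("undershoot_dispersion_s", 0.3, 0.3, 3.0),
        ("undershoot_ratio", 2.0, 1.5, 20.0),
    ]
    cur, cur_val = start, objective(start)
    steps = {name: step for name, step, *_ in fields}
    for _ in range(max_iter):
        improved = False
        for name, _, lo, hi in fields:
            for sign in (+1, -1):
                val = getattr(cur, name) + sign * steps[name]
                if not lo <= val <= hi:
                    continue
                cand = replace(cur, **{name: val})
                if cand.undershoot_delay_s <= cand.peak_delay_s:
                    continue
                v = objective(cand)
                if v > cur_val + tol:
                    cur, cur_val = cand, v
                    improved = True
                    break
        if not improved:
            if all(s <= 0.05 for s in steps.values()):
                break
            steps = {k: v / 2 for k, v in steps.items()}
    return cur, True
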