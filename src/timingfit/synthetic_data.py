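"""Synthetic cohort generator.

Builds a full cohort (participants x hemispheres x cortical maps) of
voxels with the statistical structure the map-level analyses assume:

* each map carries a *hierarchy index*; the fraction of ground-truth
  tuned voxels follows a logistic curve in that index, emulating the
  posterior-to-anterior transition from monotonic to timing-tuned
  responses;
* the monotonic component's effective signal strength decays with
  preferred visual-field eccentricity (responses fade away from the
  stimulus location), while tuned components are eccentricity-
  independent;
* every voxel gets two split-half realizations with the same signal and
  independent Gaussian noise, via :func:`timingfit.model_recovery.degrade`.

Eccentricities are sampled from a truncated exponential (denser near the
fovea, mimicking cortical magnification) on [0, 5.6 degrees].  All
randomness derives from one master seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_fitting as mf
from . import model_recovery as mr
from . import response_models as rm

DEFAULT_MAPS = ("V1", "V2", "V3", "LO1", "TO1", "TO2", "IPS0", "IPS1", "sPCS1", "iPCS")


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 8
    n_hemispheres: int = 2
    maps: tuple[str, ...] = DEFAULT_MAPS  # ordered by hierarchy index 1..len
    voxels_per_map: int = 100  # per participant x hemisphere
    tuned_fraction_min: float = 0.1
    tuned_fraction_max: float = 0.9
    tuned_fraction_steepness: float = 0.8
    ecc_scale_deg: float = 2.0
    ecc_max_deg: float = 5.6
    mono_ecc_decay_deg: float = 2.0  # e-folding of monotonic signal gain
    noise_sd_low: float = 0.5
    noise_sd_high: float = 2.5
    amplitude_mean: float = 100.0
    amplitude_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_hemispheres, self.voxels_per_map) <= 0:
            raise ValueError("cohort counts must be positive")
        if not 0 <= self.tuned_fraction_min <= self.tuned_fraction_max <= 1:
            raise ValueError("tuned fractions must satisfy 0 <= min <= max <= 1")
        if self.noise_sd_low < 0 or self.noise_sd_high < self.noise_sd_low:
            raise ValueError("noise band must satisfy 0 <= low <= high")

    def tuned_fraction(self, hierarchy_index: int) -> float:
        """Logistic tuned fraction, non-decreasing in the hierarchy index."""
        mid = (1 + len(self.maps)) / 2.0
        z = 1.0 / (1.0 + np.exp(-self.tuned_fraction_steepness * (hierarchy_index - mid)))
        lo = 1.0 / (1.0 + np.exp(-self.tuned_fraction_steepness * (1 - mid)))
        hi = 1.0 / (1.0 + np.exp(-self.tuned_fraction_steepness * (len(self.maps) - mid)))
        frac = (z - lo) / (hi - lo)
        return self.tuned_fraction_min + frac * (
            self.tuned_fraction_max - self.tuned_fraction_min
        )


def _draw_ecc(rng: np.random.Generator, config: CohortConfig, n: int) -> np.ndarray:
    # inverse-CDF sampling of an exponential truncated at ecc_max
    u = rng.uniform(size=n)
    cap = 1.0 - np.exp(-config.ecc_max_deg / config.ecc_scale_deg)
    return -config.ecc_scale_deg * np.log(1.0 - u * cap)


def _draw_cohort_tuned(rng: np.random.Generator) -> rm.TunedParams:
    # realistic tuned voxel: preference inside the presented range,
    # moderate extents, low-to-mid frequency exponent
    d = rng.uniform(100.0, 850.0)
    p = rng.uniform(d + 50.0, 950.0)
    smaj = rng.uniform(150.0, 800.0)
    smin = rng.uniform(80.0, smaj)
    return rm.TunedParams(
        pref_duration_s=d / 1000.0,
        pref_period_s=p / 1000.0,
        sigma_major=smaj / 1000.0,
        sigma_minor=smin / 1000.0,
        theta_rad=rng.uniform(0.0, np.pi),
        exp_freq=rng.uniform(0.1, 0.6),
    )


def _draw_cohort_monotonic(rng: np.random.Generator) -> rm.MonotonicParams:
    return rm.MonotonicParams(
        exp_dur=rng.uniform(0.2, 0.9),
        exp_freq=rng.uniform(0.2, 0.9),
        beta_dur=rng.uniform(0.2, 1.0),
        beta_freq=rng.uniform(0.2, 1.0),
    )


def generate_cohort(config: CohortConfig, design: mf.SessionDesign | None = None):
    """Draw the full cohort.

    Returns ``(annotations, Y_a, Y_b, ground_truth)``: a per-voxel
    annotation frame (participant, hemisphere, map, hierarchy index,
    eccentricity, polar angle, true kind, noise sd), the two split-half
    time-course matrices (n_vox x n_tr), and a ground-truth parameter
    frame sufficient to regenerate every noiseless signal exactly.
    """
    design = design or mf.SessionDesign()
    rng = np.random.default_rng(config.seed)
    ann_rows, gt_rows, signals, noise_sds = [], [], [], []
    vid = 0
    for part in range(config.n_participants):
        for hemi in ("L", "R"):
            if ("L", "R").index(hemi) >= config.n_hemispheres:
                continue
            for rank, map_label in enumerate(config.maps, start=1):
                frac = config.tuned_fraction(rank)
                ecc = _draw_ecc(rng, config, config.voxels_per_map)
                for v in range(config.voxels_per_map):
                    tuned = rng.uniform() < frac
                    base_noise = rng.uniform(config.noise_sd_low, config.noise_sd_high)
                    if tuned:
                        params = _draw_cohort_tuned(rng)
                        noise = base_noise
                    else:
                        params = _draw_cohort_monotonic(rng)
                        # eccentricity-dependent gain: weaker signal = more
                        # noise per unit signal after z-normalization
                        gain = np.exp(-ecc[v] / config.mono_ecc_decay_deg)
                        noise = base_noise / gain
                    noise = min(noise, 6.0)
                    ann_rows.append(
                        dict(
                            voxel_id=vid,
                            participant_id=f"P{part + 1}",
                            hemisphere_id=hemi,
                            visual_field_map=map_label,
                            hierarchy_index=rank,
                            eccentricity_deg=float(ecc[v]),
                            polar_angle_deg=float(rng.uniform(0, 360)),
                            true_kind="tuned" if tuned else "monotonic",
                            noise_sd=noise,
                        )
                    )
                    gt = dict(voxel_id=vid, true_kind="tuned" if tuned else "monotonic")
                    if tuned:
                        gt.update(
                            pref_duration_ms=params.pref_duration_s * 1000,
                            pref_period_ms=params.pref_period_s * 1000,
                            sigma_major_ms=params.sigma_major * 1000,
                            sigma_minor_ms=params.sigma_minor * 1000,
                            theta_rad=params.theta_rad,
                            exp_freq=params.exp_freq,
                        )
                    else:
                        gt.update(
                            exp_dur=params.exp_dur,
                            exp_freq=params.exp_freq,
                            beta_dur=params.beta_dur,
                            beta_freq=params.beta_freq,
                        )
                    gt_rows.append(gt)
                    signals.append(mr.simulate_noiseless(params, design))
                    noise_sds.append(noise)
                    vid += 1
    annotations = pd.DataFrame(ann_rows)
    ground_truth = pd.DataFrame(gt_rows)
    Y_a = np.empty((vid, design.n_tr))
    Y_b = np.empty_like(Y_a)
    noise_seeds = rng.integers(2**31, size=vid)
    for i, (tc, nsd) in enumerate(zip(signals, noise_sds)):
        Y_a[i], Y_b[i] = mr.degrade(
            tc, nsd, config.amplitude_mean, config.amplitude_sd, int(noise_seeds[i])
        )
    return annotations, Y_a, Y_b, ground_truth


# ---------------------------------------------------------------------------
# fixture I/O (plain TSV + JSON, round-trip identical)

_REQUIRED_ANN_COLS = (
    "voxel_id",
    "participant_id",
    "hemisphere_id",
    "visual_field_map",
    "hierarchy_index",
    "eccentricity_deg",
)


def write_fixtures(tables, out_dir) -> None:
    """Write (annotations, Y_a, Y_b, ground_truth[, config]) to a directory."""
    annotations, Y_a, Y_b, ground_truth, *rest = tables
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    np.savetxt(out / "timecourses_a.tsv", Y_a, delimiter="\t")
    np.savetxt(out / "timecourses_b.tsv", Y_b, delimiter="\t")
    if rest:
        (out / "config.json").write_text(json.dumps(asdict(rest[0]), indent=1))


def read_fixtures(in_dir):
    """Read fixtures back; raises on malformed or incomplete files."""
    src = Path(in_dir)
    annotations = pd.read_csv(src / "annotations.tsv", sep="\t")
    missing = [c for c in _REQUIRED_ANN_COLS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotations table is missing column(s): {', '.join(missing)}")
    ground_truth = pd.read_csv(src / "ground_truth.tsv", sep="\t")
    Y_a = np.loadtxt(src / "timecourses_a.tsv", delimiter="\t", ndmin=2)
    Y_b = np.loadtxt(src / "timecourses_b.tsv", delimiter="\t", ndmin=2)
    cfg_path = src / "config.json"
    config = None
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw["maps"] = tuple(raw["maps"])
        config = CohortConfig(**raw)
    return annotations, Y_a, Y_b, ground_truth, config
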