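"""Spike-train directional-tuning analysis for rotating-sky stimulation.

A restrained moth views a projected starry sky rotated through a full 360°
at 30-45°/s, clockwise (CW) and anticlockwise (CCW), while a neuron's spike
train is recorded.  Spike times are mapped onto the sky-rotation angle
(equivalently the moth's virtual compass heading, after correcting for the
moth's initial mounting orientation), binned at 1° and low-pass filtered
into tuning curves.  Cells are classified by maximum-likelihood model
selection over a uniform / von Mises / axial-mixture family (model ids
M1, M2A, M2B, M2C, M4A, M4B, selected by AIC) into four physiological
categories: (1) unimodally excited, (2) unimodally inhibited,
(3) direction-selective unimodal, (4) direction-selective bimodal.
Per-cell summaries include the preferred angle phi_max, its across-sweep
variability (circular s.d.), the tuning half-width, and the response SNR
(peak in-rotation rate over the s.e.m. of the pre-rotation rate).

Model likelihoods are evaluated on 1°-binned spike counts (excited cells) or
on the per-bin firing *deficit* below baseline (inhibited cells, whose spike
distributions cannot be represented by positive von Mises mixtures); see
``fit_model``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.special import logsumexp

from .angles import circ_diff, wrap360
from .circstats import (circ_mean_vector, circ_sd, vonmises_kappa_mle,
                        vonmises_logpdf)

__all__ = [
    "RotationSweep",
    "TuningCurve",
    "CellClassification",
    "map_time_to_angle",
    "spike_angles",
    "bin_tuning_curve",
    "mean_tuning_curve",
    "smooth_curve",
    "baseline_stats",
    "phi_max_per_sweep",
    "tuning_variability",
    "fit_model",
    "classify_response",
    "half_width",
    "vonmises_halfmax_width",
    "snr",
    "analyze_cell",
]

MODEL_IDS = ("M1", "M2A", "M2B", "M2C", "M4A", "M4B")
BIN_CENTERS = np.arange(360, dtype=float) + 0.5


@dataclass
class RotationSweep:
    """One 360° sky rotation: spike times plus rotation geometry.

    ``spike_times`` may include the pre-stimulus window before
    ``rotation_start`` (used for the baseline rate and the SNR denominator).
    ``initial_heading_correction`` compensates the moth's mounting
    orientation (0° mounted northward, 90° eastward, 180° southward) so that
    rotation angles are comparable across experiments.
    """

    spike_times: np.ndarray
    rotation_start: float
    rotation_end: float
    angular_velocity: float            # deg/s, study range [30, 45]
    direction: str                     # "CW" | "CCW"
    start_angle: float = 0.0
    initial_heading_correction: float = 0.0
    pre_stimulus_window: float = 5.0

    def __post_init__(self):
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))
        if self.direction not in ("CW", "CCW"):
            raise ValueError("direction must be 'CW' or 'CCW'")
        if self.initial_heading_correction % 360 not in (0.0, 90.0, 180.0):
            warnings.warn("initial_heading_correction outside {0, 90, 180}",
                          stacklevel=2)
        dur = self.rotation_end - self.rotation_start
        if abs(dur * self.angular_velocity - 360.0) > 1e-6 * 360.0:
            raise ValueError(
                f"rotation must span exactly 360°: duration {dur} s at "
                f"{self.angular_velocity} deg/s covers {dur * self.angular_velocity}°")
        if not (30.0 <= self.angular_velocity <= 45.0):
            warnings.warn("angular velocity outside the study's 30-45 deg/s range",
                          stacklevel=2)


@dataclass
class TuningCurve:
    """1°-binned firing-rate profile over corrected rotation angle."""

    bin_centers: np.ndarray
    rate: np.ndarray                   # spikes/s per bin, >= 0
    direction: str
    smoothed: bool = False
    n_sweeps: int = 1
    dwell_s: float = field(default=0.0)   # total time spent per 1° bin

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.bin_centers.size != 360 or self.rate.size != 360:
            raise ValueError("tuning curves have exactly 360 one-degree bins")
        if np.any(self.rate < -1e-12):
            raise ValueError("rates must be nonnegative")


@dataclass
class CellClassification:
    model_id: str | None
    aic_table: dict
    phi_max: float | tuple | None      # two angles ~180° apart for M4 models
    category: int | None               # 1..4, None if unclassifiable
    response_sign: str | None          # "excited" | "inhibited"
    direction_selective: bool | None
    params: dict
    per_direction_models: dict = field(default_factory=dict)
    half_width_deg: float | None = None
    snr_per_sweep: list = field(default_factory=list)
    variability_deg: float | None = None
    phi_max_per_direction: dict = field(default_factory=dict)
    n_spikes: int = 0


# ---------------------------------------------------------------------------
# Geometry: time -> rotation angle
# ---------------------------------------------------------------------------


def map_time_to_angle(sweep: RotationSweep, t) -> np.ndarray:
    """Corrected sky-rotation angle at time(s) ``t`` within the sweep.

    CW sweeps increase the compass angle; CCW sweeps decrease it.  The
    initial-heading correction is added modulo 360 (corrections compose
    additively).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < sweep.rotation_start - 1e-9) or np.any(t > sweep.rotation_end + 1e-9):
        raise ValueError("time outside the rotation window")
    sign = 1.0 if sweep.direction == "CW" else -1.0
    ang = (sweep.start_angle + sign * sweep.angular_velocity * (t - sweep.rotation_start)
           + sweep.initial_heading_correction)
    return wrap360(ang)


def spike_angles(sweep: RotationSweep) -> np.ndarray:
    """Corrected rotation angles of all spikes inside the rotation window."""
    m = (sweep.spike_times >= sweep.rotation_start) & (sweep.spike_times <= sweep.rotation_end)
    return map_time_to_angle(sweep, sweep.spike_times[m])


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------


def bin_tuning_curve(sweep: RotationSweep) -> TuningCurve:
    """Bin in-rotation spikes at 1° intervals.

    Each 1° bin is visited for 1/velocity seconds per sweep, so the per-bin
    rate is count * velocity.  Total spike mass is conserved:
    sum(rate) * dwell = spike count.
    """
    ang = spike_angles(sweep)
    counts, _ = np.histogram(ang, bins=360, range=(0.0, 360.0))
    dwell = 1.0 / sweep.angular_velocity
    return TuningCurve(bin_centers=BIN_CENTERS, rate=counts / dwell,
                       direction=sweep.direction, smoothed=False,
                       n_sweeps=1, dwell_s=dwell)


def mean_tuning_curve(curves) -> TuningCurve:
    """Average several same-direction tuning curves bin-by-bin."""
    curves = list(curves)
    rate = np.mean([c.rate for c in curves], axis=0)
    return TuningCurve(bin_centers=BIN_CENTERS, rate=rate,
                       direction=curves[0].direction,
                       smoothed=all(c.smoothed for c in curves),
                       n_sweeps=sum(c.n_sweeps for c in curves),
                       dwell_s=float(np.mean([c.dwell_s for c in curves])))


def smooth_curve(curve: TuningCurve, sigma_deg: float = 5.0) -> TuningCurve:
    """Circular (wrap-around) Gaussian low-pass filter; conserves spike mass."""
    if sigma_deg <= 0:
        raise ValueError("sigma_deg must be positive")
    rate = ndimage.gaussian_filter1d(curve.rate, sigma=sigma_deg, mode="wrap")
    return TuningCurve(bin_centers=curve.bin_centers, rate=rate,
                       direction=curve.direction, smoothed=True,
                       n_sweeps=curve.n_sweeps, dwell_s=curve.dwell_s)


def baseline_stats(sweep: RotationSweep, bin_s: float = 1.0):
    """Mean and s.e.m. of the pre-stimulus firing rate in 1-s bins."""
    t0 = sweep.rotation_start - sweep.pre_stimulus_window
    n_bins = int(round(sweep.pre_stimulus_window / bin_s))
    if n_bins < 2:
        raise ValueError("pre-stimulus window must contain at least two rate bins")
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(sweep.spike_times, bins=edges)
    rates = counts / bin_s
    sem = float(np.std(rates, ddof=1) / np.sqrt(n_bins))
    return float(np.mean(rates)), sem


# ---------------------------------------------------------------------------
# phi_max and variability
# ---------------------------------------------------------------------------


def phi_max_per_sweep(curve: TuningCurve, response_sign: str = "excited",
                      baseline: float = 0.0,
                      noise_floor: float = 1e-9) -> float | None:
    """Preferred rotation angle of one sweep: rate-weighted circular mean.

    Excited cells weight angles by the above-baseline rate; inhibited cells
    by the below-baseline deficit (baseline - rate, clipped at zero), so an
    inhibited cell's phi_max marks its trough, not the opposite angle.
    Returns None (no tuning) for a flat curve.
    """
    if response_sign == "excited":
        w = np.clip(curve.rate - baseline, 0.0, None)
    elif response_sign == "inhibited":
        w = np.clip(baseline - curve.rate, 0.0, None)
    else:
        raise ValueError("response_sign must be 'excited' or 'inhibited'")
    if np.ptp(curve.rate) <= noise_floor or w.sum() <= noise_floor:
        return None
    mv = circ_mean_vector(curve.bin_centers, weights=w)
    return None if mv.undefined else float(mv.alpha)


def tuning_variability(phi_list) -> float:
    """Across-sweep variability of phi_max: circular s.d. in degrees."""
    phi = [p for p in phi_list if p is not None]
    if len(phi) < 2:
        raise ValueError("variability needs phi_max from at least two sweeps")
    return circ_sd(phi)


# ---------------------------------------------------------------------------
# Model family and AIC selection
# ---------------------------------------------------------------------------
# M1  : uniform
# M2A : von Mises(mu, kappa)
# M2B : 0.5 vM + 0.5 uniform (contamination weight fixed)
# M2C : lam vM + (1 - lam) uniform, lam free
# M4A : 0.5 vM(mu, kappa) + 0.5 vM(mu + 180, kappa)  (axial pair)
# M4B : lam vM(mu, kappa) + (1 - lam) vM(mu + 180, kappa), lam free

_LOG_UNIFORM = -np.log(2.0 * np.pi)
_N_PARAMS = {"M1": 0, "M2A": 2, "M2B": 2, "M2C": 3, "M4A": 2, "M4B": 3}


def _model_logpdf(model_id, theta_deg, mu, kappa, lam):
    if model_id == "M1":
        return np.full(np.shape(theta_deg), _LOG_UNIFORM)
    lp1 = vonmises_logpdf(theta_deg, mu, kappa)
    if model_id == "M2A":
        return lp1
    if model_id in ("M2B", "M2C"):
        return logsumexp(
            np.stack([np.log(lam) + lp1,
                      np.full_like(lp1, np.log1p(-lam) + _LOG_UNIFORM)]), axis=0)
    lp2 = vonmises_logpdf(theta_deg, mu + 180.0, kappa)
    return logsumexp(np.stack([np.log(lam) + lp1, np.log1p(-lam) + lp2]), axis=0)


def _weighted_moments(theta_deg, w, axial=False):
    t = np.deg2rad(theta_deg) * (2.0 if axial else 1.0)
    C = np.sum(w * np.cos(t))
    S = np.sum(w * np.sin(t))
    W = np.sum(w)
    r = np.hypot(C, S) / W if W > 0 else 0.0
    mu = np.rad2deg(np.arctan2(S, C))
    if axial:
        mu /= 2.0
    return wrap360(mu), min(r, 1.0 - 1e-9)


def fit_model(model_id: str, theta_deg, weights=None):
    """Weighted ML fit of one mixture model to an angular mass distribution.

    ``weights`` are per-angle masses (spike counts per 1° bin, or the
    per-bin deficit for inhibited cells); omitted weights mean raw angles.
    Returns (params dict, log-likelihood, n_free_params).
    """
    theta = np.asarray(theta_deg, dtype=float)
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    keep = w > 0
    theta, w = theta[keep], w[keep]
    W = float(w.sum())
    if W <= 0:
        raise ValueError("no positive weight to fit")
    if model_id == "M1":
        return {}, W * _LOG_UNIFORM, 0

    axial = model_id.startswith("M4")
    mu0, r0 = _weighted_moments(theta, w, axial=axial)
    k0 = max(vonmises_kappa_mle(r0), 0.05)
    lam_fixed = 0.5 if model_id in ("M2B", "M4A") else None

    def unpack(x):
        mu = x[0]
        kappa = np.exp(np.clip(x[1], -10.0, 8.0))
        if model_id in ("M2C", "M4B"):
            lam = 1.0 / (1.0 + np.exp(-np.clip(x[2], -12.0, 12.0)))
        elif lam_fixed is not None:
            lam = lam_fixed
        else:
            lam = 1.0
        return mu, kappa, lam

    def nll(x):
        mu, kappa, lam = unpack(x)
        return -float(np.sum(w * _model_logpdf(model_id, theta, mu, kappa, lam)))

    x0 = [mu0, np.log(k0)]
    if model_id in ("M2C", "M4B"):
        x0.append(0.0)
    res = optimize.minimize(nll, np.asarray(x0), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600})
    mu, kappa, lam = unpack(res.x)
    params = {"mu": float(wrap360(mu)), "kappa": float(kappa)}
    if model_id in ("M2B", "M2C", "M4A", "M4B"):
        params["lambda"] = float(lam)
    return params, -float(res.fun), _N_PARAMS[model_id]


def _aic_select(theta, weights):
    """Fit the whole family; return (best model id, aic table, params table)."""
    aic, params = {}, {}
    for mid in MODEL_IDS:
        p, logL, k = fit_model(mid, theta, weights)
        aic[mid] = 2.0 * k - 2.0 * logL
        params[mid] = p
    best = min(aic, key=aic.get)
    return best, aic, params


def _deficit_weights(counts, baseline_count_per_bin):
    return np.clip(baseline_count_per_bin - counts, 0.0, None)


def classify_response(cw_sweeps, ccw_sweeps, ds_threshold: float = 0.3,
                      sigma_deg: float = 5.0, min_spikes: int = 30,
                      phi_combine: str = "fit",
                      bimodal_min_weight: float = 0.3) -> CellClassification:
    """Classify a cell from its CW and CCW rotation sweeps.

    Maximum-likelihood fits of the M1/M2x/M4x family to the pooled
    spike-angle mass decide unimodal vs bimodal by AIC; the response sign
    (excited/inhibited, judged against the pre-stimulus baseline) separates
    categories 1 and 2; a cell is direction-selective (categories 3/4) when
    the peak-rate contrast DS = |pCW - pCCW| / (pCW + pCCW) reaches
    ``ds_threshold`` or the per-direction AIC-selected models disagree.

    ``phi_combine`` controls how the per-direction preferred angles merge
    into the cell-level phi_max ("fit" = mu of the pooled model fit, the default;
    "mean" = circular mean of the per-direction estimates; or "cw"/"ccw").
    """
    cw_sweeps, ccw_sweeps = list(cw_sweeps), list(ccw_sweeps)
    if not cw_sweeps or not ccw_sweeps:
        raise ValueError("need at least one full sweep per rotation direction")
    per_dir = {}
    counts_by_dir, base_by_dir = {}, {}
    n_spikes = 0
    for name, sweeps in (("CW", cw_sweeps), ("CCW", ccw_sweeps)):
        curves = [bin_tuning_curve(s) for s in sweeps]
        counts = np.sum([c.rate * c.dwell_s for c in curves], axis=0)
        counts_by_dir[name] = counts
        n_spikes += int(round(counts.sum()))
        base = float(np.mean([baseline_stats(s)[0] for s in sweeps]))
        base_by_dir[name] = base
        per_dir[name] = smooth_curve(mean_tuning_curve(curves), sigma_deg)
    if n_spikes < min_spikes:
        return CellClassification(model_id=None, aic_table={}, phi_max=None,
                                  category=None, response_sign=None,
                                  direction_selective=None, params={},
                                  n_spikes=n_spikes)

    # response sign from the pooled smoothed curve vs mean baseline
    pooled_curve = np.mean([per_dir["CW"].rate, per_dir["CCW"].rate], axis=0)
    base = float(np.mean(list(base_by_dir.values())))
    excited = (pooled_curve.max() - base) >= (base - pooled_curve.min())
    sign = "excited" if excited else "inhibited"

    def weights_for(name):
        counts = counts_by_dir[name]
        if excited:
            return counts
        sweeps = cw_sweeps if name == "CW" else ccw_sweeps
        dwell_total = sum(1.0 / s.angular_velocity for s in sweeps)
        return _deficit_weights(counts, base_by_dir[name] * dwell_total)

    dir_models, dir_family, dir_decisive = {}, {}, {}
    for name in ("CW", "CCW"):
        w = weights_for(name)
        if w.sum() <= 0:
            dir_models[name], dir_family[name], dir_decisive[name] = "M1", "M1", True
            continue
        best, aic_d, params_d = _aic_select(BIN_CENTERS, w)
        dir_models[name] = best
        fam_aic = {}
        for mid, val in aic_d.items():
            fam = mid[:2]
            if fam == "M4":
                lam_d = params_d[mid].get("lambda", 0.5)
                if min(lam_d, 1.0 - lam_d) < bimodal_min_weight:
                    fam = "M2"   # unbalanced axial mixture is unimodal in shape
            fam_aic[fam] = min(fam_aic.get(fam, np.inf), val)
        ordered = sorted(fam_aic.items(), key=lambda kv: kv[1])
        dir_family[name] = ordered[0][0]
        dir_decisive[name] = (ordered[1][1] - ordered[0][1]) >= 2.0

    pooled_w = weights_for("CW") + weights_for("CCW")

    # response screen before model selection: a cell with no angular
    # structure in either the first or the doubled (axial) moment of its
    # pooled spike mass is uniform; this protects AIC from anointing
    # spurious low-amplitude tuning on large spike counts
    def _weighted_rayleigh_p(mult):
        W = pooled_w.sum()
        if W <= 0:
            return 1.0
        rad = np.deg2rad(BIN_CENTERS * mult)
        rbar = np.hypot(np.sum(pooled_w * np.cos(rad)),
                        np.sum(pooled_w * np.sin(rad))) / W
        Z = W * rbar**2
        return float(np.exp(-Z) * (1.0 + (2.0 * Z - Z**2) / (4.0 * W)))

    if min(_weighted_rayleigh_p(1), _weighted_rayleigh_p(2)) > 0.05:
        return CellClassification(
            model_id="M1", aic_table={}, phi_max=None, category=None,
            response_sign=sign, direction_selective=False,
            params={"baseline_hz": base}, per_direction_models=dir_models,
            n_spikes=n_spikes)

    best, aic, all_params = _aic_select(BIN_CENTERS, pooled_w)

    # a bimodal call needs decisive support (AIC margin >= 2 over the best
    # unimodal model) and a genuinely balanced mixture: M4B with lambda near
    # 1 is a unimodal shape in disguise
    if best.startswith("M4"):
        best_m2 = min((m for m in MODEL_IDS if m.startswith("M2")),
                      key=lambda m: aic[m])
        lam = all_params[best].get("lambda", 0.5)
        if aic[best_m2] - aic[best] < 2.0 or min(lam, 1.0 - lam) < bimodal_min_weight:
            best = best_m2
    params = dict(all_params[best])

    # direction-selectivity contrast, measured at the fitted preferred
    # angle(s) (+-15° window) rather than at the global curve extremum,
    # which is biased for the weaker direction
    if best == "M1":
        peak_angles = [float(BIN_CENTERS[np.argmax(pooled_curve)])]
    elif best.startswith("M4"):
        peak_angles = [params["mu"], params["mu"] + 180.0]
    else:
        peak_angles = [params["mu"]]
    window = np.zeros(360, dtype=bool)
    for pa in peak_angles:
        off = np.abs(wrap360(BIN_CENTERS - pa + 180.0) - 180.0)
        window |= off <= 15.0

    def _peak(name):
        r = per_dir[name].rate[window]
        return float(r.max() if excited else base - r.min())

    p_cw, p_ccw = _peak("CW"), _peak("CCW")
    denom = p_cw + p_ccw
    ds_index = abs(p_cw - p_ccw) / denom if denom > 0 else 0.0
    # model disagreement counts at the family level (uniform / unimodal /
    # bimodal) and only when both directions select their family decisively
    # (AIC margin >= 2): M2B vs M2C is a refit of the same shape, and M4B at
    # lambda -> 1 shadows M2A, so raw model-id flips are not selectivity.
    models_disagree = (dir_family["CW"] != dir_family["CCW"]
                       and dir_decisive["CW"] and dir_decisive["CCW"])
    direction_selective = bool(ds_index >= ds_threshold or models_disagree)

    phi_dir = {}
    for name in ("CW", "CCW"):
        phi_dir[name] = phi_max_per_sweep(per_dir[name], response_sign=sign,
                                          baseline=base)

    if best == "M1":
        category, phi = None, None
        model_out = "M1"
    elif best.startswith("M4"):
        category = 4
        phi = (params["mu"], wrap360(params["mu"] + 180.0))
        model_out = best
    else:
        model_out = best
        category = 3 if direction_selective else (1 if excited else 2)
        if phi_combine == "cw":
            phi = phi_dir["CW"]
        elif phi_combine == "ccw":
            phi = phi_dir["CCW"]
        elif phi_combine == "mean":
            both = [p for p in phi_dir.values() if p is not None]
            phi = float(circ_mean_vector(both).alpha) if both else params["mu"]
        else:   # "fit": mu of the pooled ML fit, which weights each
                # direction by its response mass (robust for DS cells)
            phi = params["mu"]

    return CellClassification(model_id=model_out, aic_table=aic, phi_max=phi,
                              category=category, response_sign=sign,
                              direction_selective=direction_selective,
                              params={**params, "ds_index": float(ds_index),
                                      "baseline_hz": base},
                              per_direction_models=dir_models,
                              phi_max_per_direction=phi_dir,
                              n_spikes=n_spikes)


# ---------------------------------------------------------------------------
# Half-width
# ---------------------------------------------------------------------------


def _vonmises_iqr_deg(kappa: float) -> float:
    """Interquartile range of a von Mises distribution, in degrees."""
    return float(np.rad2deg(2.0 * stats.vonmises(kappa).ppf(0.75)))


def vonmises_halfmax_width(kappa: float) -> float:
    """Full width of a von Mises curve at half its peak-to-trough modulation.

    The half level is midway between the curve's maximum and minimum, giving
    cos(theta_half) = 1 + ln((1 + exp(-2 kappa)) / 2) / kappa and full width
    2 * theta_half degrees.
    """
    c = 1.0 + np.log((1.0 + np.exp(-2.0 * kappa)) / 2.0) / kappa
    return float(2.0 * np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def half_width(classification: CellClassification, spike_angles_deg=None,
               curve: TuningCurve | None = None, baseline: float | None = None,
               n_boot: int = 1000, seed: int = 0) -> float | None:
    """Tuning-curve half-width estimator (unimodal cells only).

    Excited cells: bootstrap over spikes — resample spike angles, refit the
    selected unimodal model, and average the interquartile range of the
    fitted von Mises component.  Inhibited cells: the width of the smoothed
    inverted curve at half its modulation depth (midway between the curve's
    extremes).  Bimodal (M4) cells return None (not applicable).
    """
    if classification.model_id is None or classification.model_id.startswith("M4"):
        return None
    if classification.response_sign == "excited":
        if spike_angles_deg is None:
            raise ValueError("excited-cell half-width needs the spike-angle sample")
        ang = np.asarray(spike_angles_deg, dtype=float)
        mid = classification.model_id if classification.model_id != "M1" else "M2A"
        rng = np.random.default_rng(seed)
        # resampling n spikes with replacement == multinomial resampling of
        # their 1°-binned counts, which keeps each refit cheap
        counts, _ = np.histogram(ang, bins=360, range=(0.0, 360.0))
        n = int(counts.sum())
        iqrs = np.empty(n_boot)
        for b in range(n_boot):
            w = rng.multinomial(n, counts / n)
            p, _, _ = fit_model(mid, BIN_CENTERS, w)
            iqrs[b] = _vonmises_iqr_deg(max(p["kappa"], 1e-6))
        return float(np.mean(iqrs))
    # inhibited: width at half modulation depth around the trough
    if curve is None:
        raise ValueError("inhibited-cell half-width needs the smoothed curve")
    rate = curve.rate
    level = 0.5 * (rate.max() + rate.min())
    below = rate <= level
    if below.all():
        return 360.0
    trough = int(np.argmin(rate))
    width = 1
    i = (trough - 1) % 360
    while below[i] and width < 360:
        width += 1
        i = (i - 1) % 360
    i = (trough + 1) % 360
    while below[i] and width < 360:
        width += 1
        i = (i + 1) % 360
    return float(width)


def bimodal_peak_separation(curve: TuningCurve, window_deg: float = 70.0) -> float:
    """Angular separation of the two peaks of a (smoothed) bimodal curve.

    Locates the global peak, then takes baseline-subtracted rate centroids
    within ``window_deg`` of that peak and of its antipode — centroids are
    far more stable than raw argmax positions on noisy curves.  Returns the
    absolute separation in (0, 180] degrees.
    """
    rate = curve.rate
    base = rate.min()
    ang = curve.bin_centers
    p1 = float(ang[int(np.argmax(rate))])

    def centroid(center):
        off = np.abs(wrap360(ang - center + 180.0) - 180.0)
        w = np.where(off <= window_deg, np.clip(rate - base, 0.0, None), 0.0)
        return float(circ_mean_vector(ang, weights=w).alpha)

    c1 = centroid(p1)
    c2 = centroid(p1 + 180.0)
    return abs(float(circ_diff(c2, c1)))


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


def snr(sweep: RotationSweep, curve: TuningCurve | None = None,
        sigma_deg: float = 5.0) -> float:
    """Peak smoothed in-rotation rate over the pre-stimulus rate s.e.m.

    Computed per rotation sweep.  A zero pre-stimulus variance yields inf
    (flagged; summaries exclude such sweeps).
    """
    if curve is None:
        curve = smooth_curve(bin_tuning_curve(sweep), sigma_deg)
    elif not curve.smoothed:
        curve = smooth_curve(curve, sigma_deg)
    _, sem = baseline_stats(sweep)
    if sem <= 0:
        warnings.warn("zero pre-stimulus variance: SNR flagged infinite",
                      stacklevel=2)
        return float("inf")
    return float(curve.rate.max() / sem)


# ---------------------------------------------------------------------------
# Per-cell pipeline
# ---------------------------------------------------------------------------


def analyze_cell(cw_sweeps, ccw_sweeps, ds_threshold: float = 0.3,
                 sigma_deg: float = 5.0, n_boot: int = 1000,
                 seed: int = 0, phi_combine: str = "fit") -> CellClassification:
    """Full per-cell analysis: classification, phi_max, variability, SNR, width."""
    cls = classify_response(cw_sweeps, ccw_sweeps, ds_threshold=ds_threshold,
                            sigma_deg=sigma_deg, phi_combine=phi_combine)
    if cls.category is None:
        return cls
    base = cls.params.get("baseline_hz", 0.0)
    phis = []
    snrs = []
    for s in list(cw_sweeps) + list(ccw_sweeps):
        c = smooth_curve(bin_tuning_curve(s), sigma_deg)
        p = phi_max_per_sweep(c, response_sign=cls.response_sign, baseline=base)
        if p is not None:
            phis.append(p)
        val = snr(s, c)
        if np.isfinite(val):
            snrs.append(val)
    cls.snr_per_sweep = snrs
    if len(phis) >= 2:
        cls.variability_deg = tuning_variability(phis)
    if cls.category == 4:
        return cls
    if cls.response_sign == "excited":
        ang = np.concatenate([spike_angles(s) for s in list(cw_sweeps) + list(ccw_sweeps)])
        cls.half_width_deg = half_width(cls, spike_angles_deg=ang,
                                        n_boot=n_boot, seed=seed)
    else:
        curves = [smooth_curve(bin_tuning_curve(s), sigma_deg)
                  for s in list(cw_sweeps) + list(ccw_sweeps)]
        cls.half_width_deg = half_width(cls, curve=mean_tuning_curve(curves))
    return cls
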