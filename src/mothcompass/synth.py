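"""Synthetic-data generators emulating the study's data-generating processes.

Three generators, each a pure function of its spec + seed (bit-reproducible),
each returning a *truth record* sufficient for downstream recovery tests:

* :func:`gen_heading_population` — quantized von Mises heading streams from a
  population of tethered moths (5 Hz sampling, 3° encoder resolution,
  5-min trials), with between-moth and within-trajectory concentration,
  optional slow within-trial drift, and annotated stop events;
* :func:`gen_cell_sweeps` — inhomogeneous-Poisson spike trains (by thinning)
  for rotating-sky sweeps of a model neuron in one of the four response
  categories (unimodally excited / inhibited, direction-selective unimodal /
  bimodal), with per-sweep jitter of the preferred angle;
* :func:`gen_starfield` — greyscale star-field rasters with Gaussian-profile
  stars plus a bright extended stripe (mimicking the Milky Way band) on a
  background solved to hit a target mean grey level (default 62, the
  reference stimulus mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap360
from .ephys import RotationSweep
from .flight import HeadingSeries
from .sky import StarCatalog

__all__ = [
    "MothPopulationSpec",
    "CellSpec",
    "StarfieldSpec",
    "gen_heading_population",
    "gen_cell_sweeps",
    "gen_starfield",
]


# ---------------------------------------------------------------------------
# Behavioural headings
# ---------------------------------------------------------------------------


@dataclass
class MothPopulationSpec:
    """Population of tethered-flight trials.

    ``kappa_between`` sets how tightly the moths' individual mean headings
    cluster around the population mean (default 6, between-moth angular
    s.d. ~23°, emulating a well-oriented migratory cohort);
    ``kappa_within`` sets the within-trajectory concentration (default 2.9,
    giving a per-moth directedness of r ~ 0.8, the study's threshold for a
    highly oriented trajectory).  ``drift_deg_per_min`` models slow
    within-trial heading wander (default 0).  ``stop_prob`` is the per-minute
    probability of a flight interruption.
    """

    n_moths: int = 40
    mu_deg: float = 0.0
    kappa_between: float = 6.0
    kappa_within: float = 2.9
    drift_deg_per_min: float = 0.0
    sample_rate_hz: float = 5.0
    quantization_deg: float = 3.0
    duration_s: float = 300.0
    stop_prob: float = 0.1
    season: str = "spring"
    condition: str = "natural"
    seed: int = 0

    def __post_init__(self):
        for name in ("kappa_between", "kappa_within", "sample_rate_hz",
                     "quantization_deg", "duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.stop_prob <= 1:
            raise ValueError("stop_prob must lie in [0, 1]")


def gen_heading_population(spec: MothPopulationSpec):
    """Generate heading series for a moth population; returns (series, truth).

    Each moth's mean heading is drawn vM(mu, kappa_between); its 5 Hz samples
    are drawn vM(mean + drift * t, kappa_within), quantized to the encoder
    resolution.  The truth record stores the population mean, every moth's
    drawn mean and stop count.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n_samples) / spec.sample_rate_hz
    minutes = max(int(round(spec.duration_s / 60.0)), 1)
    series, moth_means, stop_counts = [], [], []
    for i in range(spec.n_moths):
        mean = wrap360(spec.mu_deg + np.rad2deg(
            rng.vonmises(0.0, spec.kappa_between)))
        drift = spec.drift_deg_per_min * t / 60.0
        noise = np.rad2deg(rng.vonmises(0.0, spec.kappa_within, size=n_samples))
        h = wrap360(mean + drift + noise)
        q = spec.quantization_deg
        h = wrap360(np.round(h / q) * q)
        stops = int(rng.binomial(minutes, spec.stop_prob))
        series.append(HeadingSeries(
            moth_id=f"moth{i:03d}", timestamps=t, headings=h,
            stop_events=stops, season=spec.season, condition=spec.condition,
            resolution_deg=q))
        moth_means.append(float(mean))
        stop_counts.append(stops)
    truth = {"mu_deg": spec.mu_deg, "moth_means_deg": moth_means,
             "stop_events": stop_counts, "n_samples": n_samples}
    return series, truth


# ---------------------------------------------------------------------------
# Neural sweeps
# ---------------------------------------------------------------------------


@dataclass
class CellSpec:
    """Model neuron for rotating-sky stimulation.

    ``category``: 1 unimodally excited, 2 unimodally inhibited,
    3 direction-selective unimodal, 4 direction-selective bimodal.
    ``modulation_hz`` is the peak rate increase above baseline (categories
    1/3/4) or the trough depth below it (category 2; must not exceed the
    baseline).  ``ds_index`` is the target peak-rate contrast between CW and
    CCW rotations, |pCW - pCCW| / (pCW + pCCW).  ``phi_jitter_deg`` jitters
    the preferred angle independently per sweep.
    """

    category: int = 1
    phi_max_deg: float = 180.0
    baseline_hz: float = 2.0
    modulation_hz: float = 18.0
    kappa: float = 3.0
    ds_index: float = 0.0
    phi_jitter_deg: float = 5.0
    sweeps_per_direction: int = 3
    angular_velocity: float = 36.0
    pre_stimulus_s: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.category not in (1, 2, 3, 4):
            raise ValueError("category must be 1..4")
        if self.baseline_hz < 0 or self.modulation_hz < 0:
            raise ValueError("rates must be nonnegative")
        if self.category == 2 and self.modulation_hz > self.baseline_hz:
            raise ValueError("inhibited trough depth must not exceed baseline")

    @classmethod
    def for_category(cls, category: int, seed: int = 0, **kw):
        """Defaults per response category (inhibited cells need a high
        baseline to reveal a deficit; categories 3/4 are direction-selective)."""
        base = dict(category=category, seed=seed)
        if category == 2:
            base.update(baseline_hz=25.0, modulation_hz=22.0)
        elif category == 3:
            base.update(ds_index=0.5)
        elif category == 4:
            base.update(ds_index=0.5, modulation_hz=18.0)
        base.update(kw)
        return cls(**base)


def _tuning_shape(phi_deg, center_deg, kappa, category):
    """Unit-peak tuning profile g(phi) for one direction of rotation."""
    d = np.deg2rad(np.asarray(phi_deg, dtype=float) - center_deg)
    if category == 4:
        g = 0.5 * (np.exp(kappa * (np.cos(d) - 1.0))
                   + np.exp(kappa * (-np.cos(d) - 1.0)))
        return g / g.max()
    return np.exp(kappa * (np.cos(d) - 1.0))


def _rate_function(spec: CellSpec, center_deg: float, modulation: float):
    def rate(phi_deg):
        g = _tuning_shape(phi_deg, center_deg, spec.kappa, spec.category)
        if spec.category == 2:
            return spec.baseline_hz - modulation * g
        return spec.baseline_hz + modulation * g
    return rate


def _ccw_modulation(spec: CellSpec) -> float:
    """Scale the CCW modulation so the peak-rate contrast hits ds_index."""
    if spec.ds_index <= 0:
        return spec.modulation_hz
    m, b, d = spec.modulation_hz, spec.baseline_hz, spec.ds_index
    s = (m - d * (2.0 * b + m)) / (m * (1.0 + d))
    return float(np.clip(s, 0.0, 1.0)) * m


def _thinned_spikes(rate_fn, t_end, rate_cap, rng):
    """Exact inhomogeneous-Poisson sample on [0, t_end) by thinning."""
    n = rng.poisson(rate_cap * t_end)
    t = np.sort(rng.uniform(0.0, t_end, size=n))
    keep = rng.uniform(0.0, rate_cap, size=n) < rate_fn(t)
    return t[keep]


def gen_cell_sweeps(spec: CellSpec):
    """Generate CW and CCW rotation sweeps for one model neuron.

    Returns (cw_sweeps, ccw_sweeps, truth); truth records the per-sweep
    jittered preferred angles and the CW/CCW peak modulations.
    """
    rng = np.random.default_rng(spec.seed)
    v = spec.angular_velocity
    pre = spec.pre_stimulus_s
    dur = 360.0 / v
    mod_by_dir = {"CW": spec.modulation_hz, "CCW": _ccw_modulation(spec)}
    sweeps = {"CW": [], "CCW": []}
    truth_phi = {"CW": [], "CCW": []}
    cap = 2.0 * (spec.baseline_hz + spec.modulation_hz)
    for direction in ("CW", "CCW"):
        sign = 1.0 if direction == "CW" else -1.0
        for _ in range(spec.sweeps_per_direction):
            phi_c = wrap360(spec.phi_max_deg
                            + rng.normal(0.0, spec.phi_jitter_deg))
            rate_phi = _rate_function(spec, phi_c, mod_by_dir[direction])

            def rate_t(t):
                out = np.full(np.shape(t), float(spec.baseline_hz))
                t = np.asarray(t, dtype=float)
                m = t >= pre
                out[m] = rate_phi(sign * v * (t[m] - pre))
                return out

            spikes = _thinned_spikes(rate_t, pre + dur, cap, rng)
            sweeps[direction].append(RotationSweep(
                spike_times=spikes, rotation_start=pre, rotation_end=pre + dur,
                angular_velocity=v, direction=direction, start_angle=0.0,
                initial_heading_correction=0.0, pre_stimulus_window=pre))
            truth_phi[direction].append(float(phi_c))
    truth = {"category": spec.category, "phi_max_deg": spec.phi_max_deg,
             "phi_per_sweep": truth_phi, "modulation_hz": mod_by_dir,
             "baseline_hz": spec.baseline_hz, "kappa": spec.kappa}
    return sweeps["CW"], sweeps["CCW"], truth


# ---------------------------------------------------------------------------
# Star fields
# ---------------------------------------------------------------------------


@dataclass
class StarfieldSpec:
    """Synthetic night-sky raster: point stars + a bright extended stripe."""

    shape: tuple = (256, 256)
    n_stars: int = 50
    sigma_range: tuple = (1.0, 3.0)
    peak_range: tuple = (60.0, 180.0)    # added intensity above background
    min_separation_px: float = 10.0
    stripe_angle_deg: float = 30.0
    stripe_width_px: float = 25.0
    stripe_peak: float = 35.0
    target_mean: float = 62.0
    min_level: int = 4
    max_level: int = 255
    seed: int = 0

    def __post_init__(self):
        if self.n_stars < 0:
            raise ValueError("n_stars must be nonnegative")
        if not (0 <= self.min_level < self.max_level <= 255):
            raise ValueError("levels must satisfy 0 <= min < max <= 255")


def gen_starfield(spec: StarfieldSpec):
    """Render a star field; returns (image uint8, truth StarCatalog).

    Stars have Gaussian profiles at rejection-sampled positions (minimum
    separation enforced so the truth catalog is unambiguous); the stripe is
    a smooth Gaussian band through the image centre.  The uniform background
    is solved so the global mean hits ``target_mean`` (within +/- 1 grey
    level); an unreachable target raises.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    yy, xx = np.mgrid[:h, :w]

    theta = np.deg2rad(spec.stripe_angle_deg)
    # signed distance from the central line at the given orientation
    d = (yy - h / 2.0) * np.cos(theta) - (xx - w / 2.0) * np.sin(theta)
    stripe = spec.stripe_peak * np.exp(-0.5 * (d / spec.stripe_width_px) ** 2)

    margin = 4.0 * spec.sigma_range[1]
    centers = []
    attempts = 0
    while len(centers) < spec.n_stars:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place stars with the requested separation")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= spec.min_separation_px**2
               for r2, c2 in centers):
            centers.append((r, c))

    stars = np.zeros((h, w))
    rows = []
    for i, (r, c) in enumerate(centers):
        sig = rng.uniform(*spec.sigma_range)
        peak = rng.uniform(*spec.peak_range)
        g = peak * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2.0 * sig**2))
        stars += g
        rows.append({"star_id": i, "row": float(r), "col": float(c),
                     "sigma_px": float(sig), "peak": float(peak)})

    added = stars + stripe
    bg = spec.target_mean - added.mean()
    if not (spec.min_level <= bg <= spec.max_level):
        raise ValueError(
            f"target mean {spec.target_mean} unreachable: background would be {bg:.1f}")
    # clipping at the top shifts the mean slightly; correct the background
    for _ in range(8):
        img = np.clip(np.round(bg + added), spec.min_level, spec.max_level)
        err = spec.target_mean - img.mean()
        if abs(err) <= 0.25:
            break
        bg += err
        if not (spec.min_level <= bg <= spec.max_level):
            raise ValueError("target mean unreachable after clipping correction")
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("peak", ascending=False,
                                  kind="stable").reset_index(drop=True)
        table["star_id"] = np.arange(len(table))
    return img.astype(np.uint8), StarCatalog(table)
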