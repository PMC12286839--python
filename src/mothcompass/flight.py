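"""Tethered-flight behavioural pipeline: encoder logs -> QC -> population stats.

A flight-simulator optical encoder samples a tethered moth's compass heading
at 5 Hz with 3° angular resolution for a 5-min trial.  This module reads and
writes those heading logs, applies the study's inclusion criteria, reduces
each trial to a mean orientation vector, and runs the population-level
circular statistics (r-weighted population vector, Moore's modified Rayleigh
test, bootstrap confidence interval), plus the paired early/late-session
comparisons and the directedness-based cohort split.

Heading-log dialect (versioned): tab-separated text whose first line is
``# mothcompass-headings v1``, with columns ``time_s`` and ``heading_deg``.
Trial metadata (moth id, season, condition, stop-event count, arena, date
and the two pre-experiment QC flags) live in a YAML sidecar next to the log,
``<log>.meta.yaml``.  Stop events are explicit annotations: flight
interruptions are a procedural observation, not derivable from the heading
stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import circstats
from .angles import circ_diff, wrap360
from .circstats import MeanVector, MooreResult, circ_mean_vector

__all__ = [
    "HeadingSeries",
    "QCResult",
    "PopulationResult",
    "PairedShiftResult",
    "load_heading_log",
    "write_heading_log",
    "apply_inclusion_criteria",
    "rejection_rate",
    "moth_mean_vector",
    "population_analysis",
    "split_by_directedness",
    "paired_session_shift",
]

HEADER = "# mothcompass-headings v1"

SEASONS = ("spring", "autumn")
CONDITIONS = ("natural", "rotated180", "randomized",
              "outdoor_clear_early", "outdoor_clear_late", "outdoor_overcast")


@dataclass
class HeadingSeries:
    """One moth's timestamped compass-heading stream plus trial metadata."""

    moth_id: str
    timestamps: np.ndarray          # seconds, nominal 5 Hz, strictly increasing
    headings: np.ndarray            # compass degrees, quantized
    stop_events: int = 0
    season: str = "spring"
    condition: str = "natural"
    arena: str = ""
    date: str = ""
    stalk_vertical: bool = True
    wings_ok: bool = True
    resolution_deg: float = 3.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.headings = wrap360(self.headings)
        if self.timestamps.shape != self.headings.shape:
            raise ValueError("timestamps and headings must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        if self.timestamps.size < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class QCResult:
    included: bool
    reason: str          # ok | stalk_not_vertical | weak_flight | too_many_stops | partial_log
    stop_count: int


@dataclass
class PopulationResult:
    label: str
    moth_ids: list
    vectors: list                  # per-moth MeanVector, aligned with moth_ids
    population: MeanVector
    moore: MooreResult


@dataclass
class PairedShiftResult:
    moth_ids: list
    differences_deg: np.ndarray    # signed late-minus-early heading change
    mean_shift_deg: float
    ci_half_angle: float
    zero_rejected: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_heading_log(series: HeadingSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        fh.write("time_s\theading_deg\n")
        for t, h in zip(series.timestamps, series.headings):
            fh.write(f"{t:.3f}\t{h:.1f}\n")
    meta = {
        "moth_id": series.moth_id, "season": series.season,
        "condition": series.condition, "stop_events": int(series.stop_events),
        "arena": series.arena, "date": series.date,
        "stalk_vertical": bool(series.stalk_vertical),
        "wings_ok": bool(series.wings_ok),
        "resolution_deg": float(series.resolution_deg),
    }
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def load_heading_log(path, resolution_deg: float | None = None) -> HeadingSeries:
    """Read a heading log and its YAML metadata sidecar.

    Headings are wrapped to [0, 360); the encoder quantization is verified
    (values off the resolution grid warn, they are never silently altered).
    Malformed rows raise with their line number; sampling gaps longer than
    1 s only warn.
    """
    import warnings

    path = Path(path)
    times, heads = [], []
    with open(path) as fh:
        lines = fh.readlines()
    body = [(i + 1, ln.strip()) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("#") and not ln.startswith("time_s")]
    for lineno, ln in body:
        parts = ln.split("\t")
        try:
            t, h = float(parts[0]), float(parts[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {ln!r}") from exc
        times.append(t)
        heads.append(h)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    res = resolution_deg if resolution_deg is not None else float(meta.get("resolution_deg", 3.0))
    t = np.asarray(times)
    h = wrap360(np.asarray(heads))
    off_grid = np.abs(h / res - np.round(h / res)).max() > 1e-9 if h.size else False
    if off_grid:
        warnings.warn(f"{path}: headings not on the {res}° encoder grid",
                      stacklevel=2)
    if t.size >= 2 and np.any(np.diff(t) > 1.0):
        warnings.warn(f"{path}: sampling gap exceeding 1 s", stacklevel=2)
    return HeadingSeries(
        moth_id=str(meta.get("moth_id", path.stem)),
        timestamps=t, headings=h,
        stop_events=int(meta.get("stop_events", 0)),
        season=meta.get("season", "spring"),
        condition=meta.get("condition", "natural"),
        arena=meta.get("arena", ""), date=meta.get("date", ""),
        stalk_vertical=bool(meta.get("stalk_vertical", True)),
        wings_ok=bool(meta.get("wings_ok", True)),
        resolution_deg=res,
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def apply_inclusion_criteria(series: HeadingSeries,
                             duration_s: float = 300.0,
                             duration_tol_s: float = 5.0,
                             max_stops: int = 3) -> QCResult:
    """Trial inclusion: pre-experiment flags, continuous flight, full duration.

    A moth that stopped flying four times is rejected (stop_count <= 3 is
    included); the trial must also cover the nominal 5 min within tolerance.
    Stalk verticality and wing vigour are metadata pass-through flags checked
    first.
    """
    if not series.stalk_vertical:
        return QCResult(False, "stalk_not_vertical", series.stop_events)
    if not series.wings_ok:
        return QCResult(False, "weak_flight", series.stop_events)
    if series.stop_events > max_stops:
        return QCResult(False, "too_many_stops", series.stop_events)
    if abs(series.duration - duration_s) > duration_tol_s:
        return QCResult(False, "partial_log", series.stop_events)
    return QCResult(True, "ok", series.stop_events)


def rejection_rate(n_rejected: int, n_total: int) -> float:
    """Percentage of rejected trials, rounded (half up) to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_rejected <= n_total:
        raise ValueError("need 0 <= n_rejected <= n_total")
    pct = 100.0 * n_rejected / n_total
    return float(np.floor(pct * 10.0 + 0.5) / 10.0)


# ---------------------------------------------------------------------------
# Population analysis
# ---------------------------------------------------------------------------


def moth_mean_vector(series: HeadingSeries) -> MeanVector:
    """Per-moth mean orientation vector over every 5 Hz heading sample."""
    return circ_mean_vector(series.headings)


def population_analysis(group, seed: int = 0, label: str = "",
                        n_permutations: int = 10_000, n_boot: int = 10_000,
                        enforce_qc: bool = True) -> PopulationResult:
    """Per-moth mean vectors -> weighted population vector + Moore's test.

    The result is a pure function of the heading data: moth order and arena
    labels do not enter the statistics.
    """
    group = list(group)
    if enforce_qc:
        bad = [s.moth_id for s in group if not apply_inclusion_criteria(s).included]
        if bad:
            raise ValueError(f"trials failing inclusion criteria: {bad}")
    if len(group) < 2:
        raise ValueError("population analysis needs at least two included moths")
    order = np.argsort([s.moth_id for s in group])   # order-invariance
    group = [group[i] for i in order]
    vectors = [moth_mean_vector(s) for s in group]
    pop = circstats.population_mean_vector(vectors)
    moore = circstats.moore_rayleigh_test(vectors, n_permutations=n_permutations,
                                          seed=seed, n_boot=n_boot)
    return PopulationResult(label=label, moth_ids=[s.moth_id for s in group],
                            vectors=vectors, population=pop, moore=moore)


def split_by_directedness(pairs: dict, hi: float = 0.8, lo: float = 0.2) -> dict:
    """Cohort assignment from paired early/late per-moth mean vectors.

    ``pairs`` maps moth_id -> (early MeanVector, late MeanVector).  Cohorts
    (disjoint, exhaustive):

    * ``both_high``  — r > hi in both trials (well oriented throughout);
    * ``one_high``   — r > hi in exactly one trial;
    * ``mid_both``   — neither r > hi, not both r <= lo (less well oriented);
    * ``low_both``   — r <= lo in both trials (flagged separately).
    """
    out = {}
    for moth_id, pair in pairs.items():
        if pair is None or len(pair) != 2 or any(v is None for v in pair):
            raise ValueError(f"moth {moth_id!r} is unpaired")
        early, late = pair
        high = (early.r > hi) + (late.r > hi)
        if high == 2:
            out[moth_id] = "both_high"
        elif high == 1:
            out[moth_id] = "one_high"
        elif early.r <= lo and late.r <= lo:
            out[moth_id] = "low_both"
        else:
            out[moth_id] = "mid_both"
    return out


def paired_session_shift(early: dict, late: dict, n_boot: int = 10_000,
                         seed: int = 0, level: float = 0.95) -> PairedShiftResult:
    """Per-moth signed heading change (late - early) and its test against zero.

    The mean shift is the circular mean of the per-moth signed differences;
    a percentile bootstrap over moths gives a CI, and zero is rejected when
    it falls outside.  Swapping early and late negates every difference.
    """
    ids = sorted(early)
    if sorted(late) != ids:
        missing = set(early).symmetric_difference(late)
        raise ValueError(f"unpaired moths: {sorted(missing)}")
    diffs = np.array([circ_diff(late[i].alpha, early[i].alpha) for i in ids])
    mv = circ_mean_vector(diffs)
    mean_shift = float(circ_diff(mv.alpha, 0.0)) if not mv.undefined else 0.0
    rng = np.random.default_rng(seed)
    n = len(ids)
    idx = rng.integers(0, n, size=(n_boot, n))
    rad = np.deg2rad(diffs)
    C = np.cos(rad)[idx].sum(axis=1)
    S = np.sin(rad)[idx].sum(axis=1)
    boot = np.rad2deg(np.arctan2(S, C))
    d = circ_diff(boot, mean_shift)
    tail = (1.0 - level) / 2.0
    lo_q, hi_q = np.quantile(d, [tail, 1.0 - tail])
    half = float((hi_q - lo_q) / 2.0)
    zero_off = abs(circ_diff(0.0, mean_shift))
    return PairedShiftResult(moth_ids=ids, differences_deg=diffs,
                             mean_shift_deg=mean_shift, ci_half_angle=half,
                             zero_rejected=bool(zero_off > half))
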