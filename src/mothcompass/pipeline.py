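"""Configuration-driven pipeline: simulate -> analyse -> report tables.

A run config (YAML) names the stages to execute and their parameters; every
stochastic step carries an explicit seed, so an identical config produces
byte-identical output files.  Output tables are tab-separated text with
documented formatting (angles in compass degrees to one decimal, p-values in
scientific notation); a provenance file records the config hash, seed and
package version (no timestamps, by design, to keep runs reproducible
byte-for-byte).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, circstats, ephys, flight, sky, synth

__all__ = ["load_config", "validate_config", "run_pipeline"]

_STAGE_KINDS = ("simulate_flight", "flight", "simulate_ephys", "ephys",
                "simulate_sky", "stim")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    stages = cfg.get("stages")
    if not stages:
        raise ValueError("config must list at least one stage")
    for st in stages:
        if st.get("kind") not in _STAGE_KINDS:
            raise ValueError(f"unknown stage kind: {st.get('kind')!r}")
    if "seed" not in cfg:
        raise ValueError("config must carry an explicit top-level seed")


def _fmt_angle(a):
    return "" if a is None or not np.isfinite(a) else f"{a:.1f}"


def _fmt_p(p):
    return f"{p:.3e}"


def _write_table(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}; angles: compass degrees (0=N, clockwise), "
                 "1 decimal; p-values: scientific notation\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: dict, out_dir) -> dict:
    """Execute the configured stages; returns {stage label: output paths}."""
    validate_config(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    outputs = {}
    for i, st in enumerate(cfg["stages"]):
        label = st.get("label", f"stage{i}_{st['kind']}")
        stage_seed = int(st.get("seed", seed + i))
        fn = _RUNNERS[st["kind"]]
        outputs[label] = fn(st, out_dir, label, stage_seed)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    with open(out_dir / "provenance.txt", "w") as fh:
        fh.write(f"config_sha256\t{hashlib.sha256(blob).hexdigest()}\n")
        fh.write(f"seed\t{seed}\n")
        fh.write(f"mothcompass_version\t{__version__}\n")
    return outputs


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _run_simulate_flight(st, out_dir, label, seed):
    spec = synth.MothPopulationSpec(**{**st.get("spec", {}), "seed": seed})
    series, truth = synth.gen_heading_population(spec)
    d = out_dir / label
    d.mkdir(exist_ok=True)
    paths = []
    for s in series:
        p = d / f"{s.moth_id}.tsv"
        flight.write_heading_log(s, p)
        paths.append(p)
    with open(d / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths


def _run_flight(st, out_dir, label, seed):
    src = Path(st["input_dir"])
    if not src.exists():
        raise FileNotFoundError(f"flight stage input missing: {src}")
    series = [flight.load_heading_log(p) for p in sorted(src.glob("*.tsv"))]
    if not series:
        raise FileNotFoundError(f"no heading logs found under {src}")
    qc = [(s, flight.apply_inclusion_criteria(s)) for s in series]
    included = [s for s, q in qc if q.included]
    groups = {}
    for s in included:
        groups.setdefault((s.season, s.condition), []).append(s)

    moth_rows, pop_rows = [], []
    pops = []
    for g, (key, members) in enumerate(sorted(groups.items())):
        res = flight.population_analysis(members, seed=seed + g,
                                         label=f"{key[0]}/{key[1]}",
                                         n_permutations=int(st.get("n_permutations", 10_000)),
                                         n_boot=int(st.get("n_boot", 10_000)))
        pops.append(res)
        for mid, v in zip(res.moth_ids, res.vectors):
            moth_rows.append({"group": res.label, "moth_id": mid,
                              "alpha_deg": _fmt_angle(v.alpha), "r": f"{v.r:.4f}",
                              "n_samples": v.n})
    p_adj = circstats.bonferroni([p.moore.p_value for p in pops])
    for res, padj in zip(pops, p_adj):
        pop_rows.append({"group": res.label, "n_moths": res.moore.n,
                         "alpha_pop_deg": _fmt_angle(res.population.alpha),
                         "r_pop": f"{res.population.r:.4f}",
                         "R_star": f"{res.moore.R_star:.4f}",
                         "p_raw": _fmt_p(res.moore.p_value),
                         "p_bonferroni": _fmt_p(padj),
                         "ci95_half_angle_deg": _fmt_angle(res.moore.ci95_half_angle)})
    qc_rows = [{"moth_id": s.moth_id, "included": q.included, "reason": q.reason,
                "stop_count": q.stop_count} for s, q in qc]
    f1 = out_dir / f"{label}_moth_vectors.tsv"
    f2 = out_dir / f"{label}_population.tsv"
    f3 = out_dir / f"{label}_qc.tsv"
    _write_table(pd.DataFrame(moth_rows), f1, "per-moth mean orientation vectors")
    _write_table(pd.DataFrame(pop_rows), f2,
                 "population statistics (Moore's modified Rayleigh, Bonferroni-corrected)")
    _write_table(pd.DataFrame(qc_rows), f3, "trial inclusion criteria")
    return [f1, f2, f3]


def _run_simulate_ephys(st, out_dir, label, seed):
    d = out_dir / label
    d.mkdir(exist_ok=True)
    paths = []
    cells = st.get("cells") or [{"category": c} for c in (1, 2, 3, 4)]
    truth_all = {}
    for j, cell_kw in enumerate(cells):
        cat = int(cell_kw.get("category", 1))
        spec = synth.CellSpec.for_category(
            cat, seed=seed + j,
            **{k: v for k, v in cell_kw.items() if k != "category"})
        cw, ccw, truth = synth.gen_cell_sweeps(spec)
        cell_id = f"cell{j:02d}"
        spike_rows, sweep_rows = [], []
        for k, s in enumerate(cw + ccw):
            sid = f"{cell_id}_s{k:02d}"
            sweep_rows.append({"sweep_id": sid, "t_start": s.rotation_start,
                               "t_end": s.rotation_end, "direction": s.direction,
                               "velocity_deg_s": s.angular_velocity,
                               "start_angle_deg": s.start_angle,
                               "correction_deg": s.initial_heading_correction,
                               "pre_stimulus_s": s.pre_stimulus_window})
            for t in s.spike_times:
                spike_rows.append({"sweep_id": sid, "spike_time_s": f"{t:.6f}"})
        f_spk = d / f"{cell_id}_spikes.tsv"
        f_swp = d / f"{cell_id}_sweeps.tsv"
        pd.DataFrame(spike_rows).to_csv(f_spk, sep="\t", index=False)
        pd.DataFrame(sweep_rows).to_csv(f_swp, sep="\t", index=False)
        truth_all[cell_id] = truth
        paths += [f_spk, f_swp]
    with open(d / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_all, fh, sort_keys=True)
    return paths


def load_cell(spike_path, sweep_path):
    """Read one cell's spike file + sweep table into CW/CCW sweep lists."""
    spikes = pd.read_csv(spike_path, sep="\t")
    table = pd.read_csv(sweep_path, sep="\t")
    cw, ccw = [], []
    for _, row in table.iterrows():
        t = spikes.loc[spikes["sweep_id"] == row["sweep_id"], "spike_time_s"].to_numpy(float)
        sw = ephys.RotationSweep(
            spike_times=t, rotation_start=float(row["t_start"]),
            rotation_end=float(row["t_end"]), angular_velocity=float(row["velocity_deg_s"]),
            direction=str(row["direction"]), start_angle=float(row["start_angle_deg"]),
            initial_heading_correction=float(row["correction_deg"]),
            pre_stimulus_window=float(row["pre_stimulus_s"]))
        (cw if sw.direction == "CW" else ccw).append(sw)
    return cw, ccw


def _run_ephys(st, out_dir, label, seed):
    src = Path(st["input_dir"])
    if not src.exists():
        raise FileNotFoundError(f"ephys stage input missing: {src}")
    cell_rows, sweep_rows = [], []
    spike_files = sorted(src.glob("*_spikes.tsv"))
    if not spike_files:
        raise FileNotFoundError(f"no spike files found under {src}")
    for f_spk in spike_files:
        cell_id = f_spk.name.replace("_spikes.tsv", "")
        cw, ccw = load_cell(f_spk, src / f"{cell_id}_sweeps.tsv")
        cls = ephys.analyze_cell(
            cw, ccw, ds_threshold=float(st.get("ds_threshold", 0.3)),
            sigma_deg=float(st.get("sigma_deg", 5.0)),
            n_boot=int(st.get("n_boot", 1000)), seed=seed)
        phi = cls.phi_max
        phi1 = phi[0] if isinstance(phi, tuple) else phi
        phi2 = phi[1] if isinstance(phi, tuple) else None
        cell_rows.append({
            "cell_id": cell_id, "model_id": cls.model_id or "",
            "category": cls.category or "", "sign": cls.response_sign or "",
            "direction_selective": cls.direction_selective,
            "phi_max_deg": _fmt_angle(phi1), "phi_max2_deg": _fmt_angle(phi2),
            "half_width_deg": _fmt_angle(cls.half_width_deg),
            "variability_deg": _fmt_angle(cls.variability_deg),
            "snr_median": _fmt_angle(float(np.median(cls.snr_per_sweep))
                                     if cls.snr_per_sweep else None),
            "n_spikes": cls.n_spikes})
        for k, val in enumerate(cls.snr_per_sweep):
            sweep_rows.append({"cell_id": cell_id, "sweep_index": k,
                               "snr": f"{val:.3f}"})
    f1 = out_dir / f"{label}_cells.tsv"
    f2 = out_dir / f"{label}_sweep_snr.tsv"
    _write_table(pd.DataFrame(cell_rows), f1,
                 "per-cell classification (AIC over M1/M2A/M2B/M2C/M4A/M4B)")
    _write_table(pd.DataFrame(sweep_rows), f2, "per-sweep response SNR")
    return [f1, f2]


def _run_simulate_sky(st, out_dir, label, seed):
    spec = synth.StarfieldSpec(**{**st.get("spec", {}), "seed": seed})
    img, catalog = synth.gen_starfield(spec)
    d = out_dir / label
    d.mkdir(exist_ok=True)
    f_img = d / "starfield.png"
    f_cat = d / "truth_catalog.tsv"
    sky.save_image(img, f_img)
    catalog.to_csv(f_cat)
    return [f_img, f_cat]


def _run_stim(st, out_dir, label, seed):
    img = sky.load_image(st["input_image"])
    op = st.get("op", "detect")
    outs = []
    if op == "detect":
        cat = sky.detect_stars(img, scales=tuple(st.get("scales", sky.DEFAULT_SCALES)),
                               threshold=float(st.get("threshold", 0.04)))
        f = out_dir / f"{label}_catalog.tsv"
        cat.to_csv(f)
        outs.append(f)
    elif op == "shuffle-pixels":
        out = sky.randomize_pixels(img, seed=seed)
        f = out_dir / f"{label}_pixels.png"
        sky.save_image(out, f)
        outs.append(f)
    elif op == "shuffle-blocks":
        out = sky.randomize_blocks(img, block=int(st.get("block", 13)), seed=seed)
        f = out_dir / f"{label}_blocks.png"
        sky.save_image(out, f)
        outs.append(f)
    elif op == "shuffle-stars":
        cat = sky.detect_stars(img, scales=tuple(st.get("scales", sky.DEFAULT_SCALES)),
                               threshold=float(st.get("threshold", 0.04)))
        out = sky.randomize_stars(img, cat, seed=seed)
        f = out_dir / f"{label}_stars.png"
        sky.save_image(out, f)
        outs.append(f)
    else:
        raise ValueError(f"unknown stim op: {op!r}")
    return outs


_RUNNERS = {
    "simulate_flight": _run_simulate_flight,
    "flight": _run_flight,
    "simulate_ephys": _run_simulate_ephys,
    "ephys": _run_ephys,
    "simulate_sky": _run_simulate_sky,
    "stim": _run_stim,
}
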