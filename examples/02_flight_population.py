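"""Tethered-flight pipeline: synthetic encoder logs -> population statistics.

Simulates a cohort of moths with a true mean migratory heading of 168°
(5 Hz sampling, 3° resolution, 5-min trials), applies the inclusion
criteria, and runs the full population analysis: per-moth mean vectors, the
r-weighted population vector, Moore's modified Rayleigh test and a
bootstrap confidence interval.  Then recovers a +30° heading shift injected
between paired early/late sessions.
"""

import numpy as np

from mothcompass import (MothPopulationSpec, apply_inclusion_criteria,
                         gen_heading_population, paired_session_shift,
                         population_analysis)
from mothcompass.flight import moth_mean_vector

spec = MothPopulationSpec(n_moths=40, mu_deg=168.0, stop_prob=0.1, seed=12)
series, truth = gen_heading_population(spec)

qc = [apply_inclusion_criteria(s) for s in series]
kept = [s for s, q in zip(series, qc) if q.included]
print(f"{len(kept)}/{len(series)} trials pass QC "
      f"(rejected: {[q.reason for q in qc if not q.included]})")

res = population_analysis(kept, seed=7, label="spring/natural")
print(f"alpha_pop = {res.population.alpha:.1f}° (truth {truth['mu_deg']}°), "
      f"r = {res.population.r:.3f}")
print(f"Moore's test: R* = {res.moore.R_star:.3f}, P = {res.moore.p_value:.1e}, "
      f"95% CI = ±{res.moore.ci95_half_angle:.0f}°")
# P far below 0.05: the cohort is significantly oriented toward ~168°.

# paired early/late sessions with a +30° injected shift
rng = np.random.default_rng(3)
early = {s.moth_id: moth_mean_vector(s) for s in kept}
late = {}
for s in kept:
    mv = early[s.moth_id]
    late[s.moth_id] = type(mv)(alpha=(mv.alpha + 30.0 + rng.normal(0, 8)) % 360,
                               r=mv.r, n=mv.n)
shift = paired_session_shift(early, late, seed=11)
print(f"mean heading shift = {shift.mean_shift_deg:+.1f}° "
      f"± {shift.ci_half_angle:.1f}°, zero rejected: {shift.zero_rejected}")
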