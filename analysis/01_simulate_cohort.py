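"""Simulate the demonstration cohort and write its ground-truth tables.

The cohort mirrors the emulated study layout at desk scale: 24 subjects,
64 channels at 250 Hz, 7 microstate classes, 9 thirty-second Trial
sessions split 3/3/3 over Training/PracticeA/PracticeB, with three planted
brain-behavior associations (two positive coverage effects, one negative
occurrence effect).  Writes truth tables under results/analysis/ — the
recordings themselves are regenerated deterministically by later steps.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

from pathlib import Path

import numpy as np

from eegms.parameters import summarize
from eegms.pipeline import PipelineConfig, effective_sim_config
from eegms.synthetic import implied_coverage, simulate_cohort

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig.from_yaml("configs/demo.yaml")
# same cohort realization the pipeline run (03) will analyze
cohort = simulate_cohort(effective_sim_config(cfg), render=False)

np.savetxt(OUT / "true_maps.csv", cohort.true_maps, delimiter=",")
cohort.true_parameters.to_csv(OUT / "true_parameters.csv", index=False)
summarize(cohort.true_parameters).to_csv(OUT / "true_summary.csv", index=False)
cohort.evaluations.to_csv(OUT / "evaluations.csv", index=False)

cov = implied_coverage(cfg.simulate.dwell_mean_ms)
print(f"{cfg.simulate.n_subjects} subjects x {len(cfg.simulate.session_plan)} "
      f"sessions, {cfg.simulate.n_classes} classes")
print("per-class dwell means (ms):",
      np.round(cfg.simulate.dwell_mean_ms, 1).tolist())
print("implied coverages:", np.round(cov, 3).tolist())
print("planted effects:")
for e in cfg.simulate.planted_effects:
    print(f"  class {e.class_index} {e.parameter} -> {e.dimension} "
          f"(target rho {e.rho:+.1f})")
print(f"wrote ground-truth tables to {OUT}/")
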