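"""Summarize the statistical layer of the pipeline run.

Reads the ANOVA, post hoc and correlation tables written by 03 and states
the findings: the CLASS main effect on each temporal parameter (planted
via per-class dwell means), the absence of a STAGE effect (none planted),
and which planted brain-behavior correlations were recovered at the
Bonferroni-corrected threshold.

Run from the repository root:  python analysis/05_statistics_report.py
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/run")

for param in ("coverage", "duration", "occurrence"):
    a = pd.read_csv(RUN / f"anova_{param}.csv").set_index("source")
    cls, stg = a.loc["class"], a.loc["stage"]
    print(f"{param}: CLASS F({cls.ddof1:.0f},{cls.ddof2:.0f})="
          f"{cls.F:.2f}, p_GG={cls.p_gg:.2g}, eta2_g={cls.eta2_generalized:.3f}"
          f" | STAGE F={stg.F:.2f}, p_GG={stg.p_gg:.2f}")

ev = pd.read_csv(RUN / "anova_evaluations.csv").set_index("source")
print(f"evaluations: DIMENSION F={ev.loc['dimension'].F:.2f} "
      f"p_GG={ev.loc['dimension'].p_gg:.2g}")

corr = pd.read_csv(RUN / "correlations.csv")
tm = pd.read_csv(RUN / "truth_match.csv")
sig = corr[corr.significant]
print(f"\nBonferroni-significant correlation cells "
      f"({len(sig)}/{len(corr)}):")
for _, r in sig.iterrows():
    letter = tm[tm.fitted_class == r["class"]].letter.iloc[0]
    print(f"  {r.parameter:<10s} class {letter} x {r.dimension}: "
          f"rho={r.rho:+.2f} (p_bonf={r.p_bonf:.3g})")
print("\n(planted: coverage of two classes -> D4, D1 positive; "
      "occurrence of one class -> D5 negative)")
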