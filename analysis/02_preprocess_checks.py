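"""Exercise the cleaning chain on one synthetic session and report it.

Renders a single dipolar-map session (where the bad-channel rules'
spatial-correlation assumption holds), plants one flat channel and one
amplitude spike, and runs the full chain: band-pass, bad-channel
detection, epoching, local-channel repair, segment rejection,
interpolation, average reference, resampling.

Run from the repository root:  python analysis/02_preprocess_checks.py
"""

import json
from pathlib import Path

import numpy as np

from eegms.montage import synthetic_montage
from eegms.preprocess import clean
from eegms.synthetic import (default_envelope, make_smooth_topographies,
                             noise_sd_for_snr, render_eeg, simulate_labels)

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

mont = synthetic_montage(64, cap_fraction=1.0)
maps = make_smooth_topographies(mont, 3, dipole_weight=1.0, seed=1)
lab = simulate_labels(30, 250, 80.0, 3, seed=2)
env = default_envelope(len(lab.labels), 250)
rec = render_eeg(lab, maps, 250, env, noise_sd_for_snr(env, 64, 4.0),
                 seed=3, montage=mont)

# plant two faults the chain must find
rec.data[5, :] = 0.17                    # dead (flat) channel
rec.data[11, 2000:2010] += 150.0         # gross amplitude excursion

cleaned, report = clean(rec)
report["planted"] = {"flat": mont.names[5], "spike_channel": mont.names[11]}
(OUT / "preprocess_report.json").write_text(json.dumps(report, indent=1))

print("bad channels found:", report["bad_channels"],
      "(planted flat:", mont.names[5] + ")")
print(f"epochs rejected: {report['n_epochs_rejected']}/{report['n_epochs']}")
print("average reference after chain:",
      bool(np.all(np.abs(cleaned.data.mean(axis=0)) < 1e-9)))
print(f"wrote {OUT}/preprocess_report.json")
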