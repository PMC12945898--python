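"""Run a small end-to-end synthetic study and read off the headline pattern.

Generates a cohort with latent EEA/SEA differences, fits LBA and DDM to
every subject, and checks that the DDM's condition-averaged drift tracks
EEA rather than SEA, and that a criterion loading on EEA is predicted by
EEA but not SEA — the ordering the method is designed to expose.

This is a scaled-down study (16 subjects, 200 trials/condition) so it
finishes in a few minutes; at this size the association table is noisy —
the 40-subject default with full-length fits shows the pattern cleanly.
"""

import tempfile
from pathlib import Path

import pandas as pd

from accumulate import run_study

config = {
    "synth": {"n_subjects": 16, "trials_per_condition": 200, "seed": 5},
    "fit": {"models": ["lba", "ddm"], "burn_in": 300, "block": 150,
            "max_iter": 450, "seed": 5},
    "checks": {"n_draws": 20, "seed": 5},
    "associate": {"n_boot": 100, "seed": 5},
}

out = Path(tempfile.mkdtemp(prefix="accumulate_study_"))
manifest = run_study(config, out)
print(f"artifacts in {out}: {manifest['artifacts']}")
print(f"retained {manifest['n_retained']} subjects; "
      f"converged: {manifest['n_converged']}")

corr = pd.read_csv(out / "correlations.csv")
print("\ncorrelations of fitted measures with DDM drift v_mean:")
print(corr.round(3).to_string(index=False))

assoc = pd.read_csv(out / "association.csv")
print("\nvariance in criteria explained uniquely (part R^2):")
print(assoc.round(3).to_string(index=False))
print("\nExpected pattern: r(EEA, v_mean) >> r(SEA, v_mean). The part-R^2 "
      "ranking is far noisier: at n = 16 it can invert by chance, as the "
      "wide bootstrap CIs show. The 40-subject run in "
      "scripts/acceptance.py gives the stable version "
      "(EEA part R^2 ~ 0.3 vs SEA ~ 0.01).")
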