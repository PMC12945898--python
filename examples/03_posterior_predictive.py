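"""Posterior predictive check of a fitted model.

After fitting, datasets are simulated from posterior draws and summarized
exactly like the data; observed choice proportions and RT quintiles should
fall inside their 95% predictive intervals when the model fits.
"""

from accumulate import FitConfig, LBAParams, coverage, fit_subject, \
    lba_simulate, posterior_predictive
from accumulate.tasks import NBACK

truth = LBAParams(
    v_match={"target": 2.6, "lure": 1.6, "novel": 2.2},
    v_mismatch={"target": 0.9, "lure": 1.1, "novel": 0.5},
    A=0.5, B={r: 0.9 for r in NBACK.responses}, t0=0.3, p_gf=0.03,
)
dataset = lba_simulate(truth, NBACK, 300, seed=8, subject_id="demo")
fit = fit_subject(dataset, "lba",
                  FitConfig(burn_in=300, block=150, max_iter=450, seed=2))

table = posterior_predictive(dataset, fit, n_draws=100, seed=3)
print(table.round(3).head(14).to_string(index=False))
print(f"\ncoverage: {coverage(table):.2f} of observed statistics lie "
      "inside their 95% predictive intervals")
print("(columns: observed statistic vs median and 2.5/97.5 percentiles of "
      "the model's predictive distribution, per condition cell)")
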