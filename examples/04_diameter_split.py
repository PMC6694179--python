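"""Fine/thick parent-root analysis: is branching density diameter-dependent?

Each sample is split at the central parent diameter, 0.5*(min+max), and the
model is calibrated separately on the two sub-populations.  The generator
here gives every sample one shared ISD but a lower emergence probability on
fine roots (P_em 0.6 vs 0.9), the pattern where laterals are sparser on
fine parents.
"""

import numpy as np
from scipy import stats

import rootbranch as rb

rng = np.random.default_rng(11)
table = rb.load_default_table()

samples, _ = rb.generate_panel(rb.compensation_panel_scenarios(20), rng)
splits = [rb.diameter_split_analysis(s, table, rng, n_sim=50_000) for s in samples]

ordering = np.mean([s.fine_fit.params.p_em < s.thick_fit.params.p_em for s in splits])
fine_isd = np.array([s.fine_fit.params.isd for s in splits])
thick_isd = np.array([s.thick_fit.params.isd for s in splits])

print(f"P_em(fine) < P_em(thick) recovered in {ordering*100:.0f}% of samples")
print(f"paired ISD fine-vs-thick t-test p = "
      f"{stats.ttest_rel(fine_isd, thick_isd).pvalue:.3f}")
print(f"mean relative ISD difference (thick-fine): "
      f"{np.mean([s.rel_diff_isd for s in splits])*100:+.1f}%")
print(
    "\nThe split recovers the stratum P_em contrast while the shared ISD is"
    "\nconserved up to a small estimator cross-talk (see docs/methods.md)."
)
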