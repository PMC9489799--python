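"""Compare aggregate length distributions between two simulated samples.

Measures 2000 aggregates per group from the two brain-extract presets
(lognormal medians 55 vs 68 nm) and reports the distribution comparison:
medians, KS and Mann-Whitney tests, and the location of the largest
cumulative-distribution gap.
"""

import numpy as np

from aggremorph import (
    AnalysisConfig,
    compare_groups,
    measure_population,
    scenario_params,
)

rng = np.random.default_rng(2)

# AD-PAINT analysis settings (eps 200 nm, minPts 10, signal >= 60 photons).
config = AnalysisConfig(eps=200.0, min_pts=10, min_signal=60.0,
                        max_precision=40.0)

disease = measure_population(
    scenario_params("pd_brain", n_aggregates=250), config,
    n_target=2000, rng=rng,
)
control = measure_population(
    scenario_params("hc_brain", n_aggregates=250), config,
    n_target=2000, rng=rng,
)

comp = compare_groups(disease["length_nm"].to_numpy(),
                      control["length_nm"].to_numpy(), bin_width=10.0)
print(f"median length: disease {comp.median_a:.0f} nm, "
      f"control {comp.median_b:.0f} nm")
print(f"KS: D = {comp.ks_D:.3f}, p = {comp.ks_p:.2e}")
print(f"Mann-Whitney: U = {comp.mwu_U:.0f}, p = {comp.mwu_p:.2e}")
loc, val = comp.max_cum_difference
print(f"largest cumulative difference: {100 * val:.1f}% at {loc:.0f} nm")
print("(note: raw Feret lengths carry a ~100 nm localization-noise floor;"
      " see docs/methods.md)")
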