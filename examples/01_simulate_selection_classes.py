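"""Simulate one clonal population per evolutionary class and compare them.

Each population is a pool of N = 1,000 stem cells evolving for 500
Wright-Fisher generations over a 20 kb region (desk scale; selection
rescaled so N.s matches a 10,000-cell pool).  The printed numbers show
the class signatures the classifier later exploits: purifying selection
depresses the missense-to-silent ratio (pN/pS < 1), sweeps purge
diversity and push hitchhikers to high frequency (negative Fay & Wu's H,
occupied high-VAF bins).
"""

import numpy as np

from clonesel import (
    CLASS_LABELS,
    FeatureConfig,
    SimConfig,
    assemble_features,
    run_simulation,
    sample_class_params,
)

config = SimConfig.desk_scale()
fcfg = FeatureConfig.from_sim_config(config)
rng = np.random.default_rng(7)

print(f"{'class':<12} {'S':>6} {'pN/pS':>7} {'Tajima D':>9} "
      f"{'FayWu H':>8} {'high-VAF':>9}")
for label in CLASS_LABELS:
    params = sample_class_params(label, rng)
    vt = run_simulation(params, config, seed=rng.integers(2**31 - 1))
    fv = assemble_features(vt, fcfg).to_series()
    high = int(fv["silent_high"] + fv["missense_high"])
    print(f"{label:<12} {int(fv['total_count']):>6} "
          f"{fv['pnps_overall']:>7.2f} {fv['tajimas_d']:>9.2f} "
          f"{fv['fay_wu_h']:>8.1f} {high:>9}")

print(
    "\nS = segregating mutations above the 0.1% detection threshold.\n"
    "Sweeps (positive/combination) purge diversity and occupy the\n"
    "high-VAF (>0.8) bin; strong purifying selection depresses pN/pS,\n"
    "while the nearly-neutral deleterious effects of the negative-only\n"
    "grid leave almost no footprint -- which is exactly why neutral and\n"
    "negative populations are the hard pair to tell apart."
)
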