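"""Repeated random sub-sampling validation of two pipelines.

Runs the 80/20 protocol for a few replicates, refitting everything on each
training split (standardization, weights, REML, BLUP), and reports the mean
and SD of predictive ability.
"""

import snpblup as sb
from snpblup.validate import PipelineConfig

cfg = sb.SimulationConfig(n_individuals=600, n_snps=1200, n_qtl=12, h2_target=0.5, seed=8)
g, data, _ = sb.simulate_dataset(cfg)

for config in (PipelineConfig(scheme="identity"),
               PipelineConfig(scheme="window", S=20, rounds=1)):
    results, summary = sb.subsample_validation(config, data, g, frac_train=0.8,
                                               reps=5, seed=3)
    print(f"{config.scheme:9s} mean r = {summary['mean_r']:.3f} "
          f"(SD {summary['sd_r']:.3f} across {summary['n_replicates']} replicates)")
# Higher mean r means better genomic prediction of unseen individuals.
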