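"""Recover indel frequencies from a simulated editing experiment.

Blends the 26-member indel-mimic panel with wild-type template at known
fractions, simulates noisy qPCR, and recovers each frequency by the DDCt
transform averaged over the screened watching-primer strategies.
"""

import numpy as np

from getpcr import (
    SimConfig,
    apply_panel,
    generate_mixture_experiment,
    mimic_panel,
    select_discriminating_assays,
    standard_strategy_set,
    synthetic_locus,
    wild_fraction,
)

locus, guide = synthetic_locus(1, cut_triplet="ACG")
panel = apply_panel(locus, mimic_panel(locus, guide))
assays = select_discriminating_assays(
    standard_strategy_set(locus, guide), locus.sequence,
    list(panel.values()), SimConfig().penalty_model)
print(f"{len(assays)} watching-primer strategies pass the >= 8-cycle "
      f"worst-case discrimination screen: {', '.join(sorted(assays))}")

config = SimConfig(seed=7, noise_sd=0.1, replicates=3)
fractions = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
ct, truth = generate_mixture_experiment(locus, guide, fractions, config,
                                        assays=assays)

print("\ntrue indel %   estimated % (mean over strategies)")
for sample, true_f in truth["samples"].items():
    ests = [wild_fraction(ct.select(sample, a),
                          ct.select("wild_control", a)).edit_frequency
            for a in assays]
    print(f"   {true_f * 100:5.1f}        {np.mean(ests) * 100:5.1f}")
print("\nEach estimate is 1 - 2^-ddCt of the watch/control channel pair; "
      "recovery is accurate above ~10% true frequency.")
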