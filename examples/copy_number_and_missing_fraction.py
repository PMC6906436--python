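"""Gene copy number from qPCR, and missing-fraction screening.

Copy number: a gene amplicon is compared with a single-copy calibrator (one
allele of a heterozygous SNP); 2^-dCt times the calibrator copies gives the
raw copy number, rounded to the nearest integer.  Missing fraction: per-base
allele percentages that do not sum to 1 reveal an unassayed variant (e.g.
C-to-G editing at a position screened only with C- and T-specific primers).
"""

from getpcr import (
    SimConfig,
    estimate_copy_number,
    generate_copy_number_experiment,
    missing_fraction,
)

for copies in (3, 4):
    config = SimConfig(seed=17 + copies, noise_sd=0.1, replicates=3)
    ct, truth = generate_copy_number_experiment(copies, 1, config)
    est = estimate_copy_number(ct.select(assay_id="gene_cn"),
                               ct.select(assay_id="ref_cn"),
                               gene_id=f"gene_{copies}x")
    print(f"{est.gene_id}: raw {est.raw_copies:.2f} -> called {est.called_copies} "
          f"copies (true {truth['gene_copies']})")

print()
for label, comp in [("clone A", {"C": 0.67, "T": 0.33}),
                    ("clone B", {"C": 0.33, "T": 0.33}),
                    ("clone C", {"C": 0.62, "T": 0.31})]:
    missing, flagged = missing_fraction(comp)
    note = "extra variant suspected" if flagged else "composition complete"
    print(f"{label}: C {comp['C']:.2f} + T {comp['T']:.2f} -> "
          f"missing {missing:.2f} ({note})")
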