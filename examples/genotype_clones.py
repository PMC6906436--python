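"""Genotype single-cell clones at a triploid locus.

Simulates a triploid clone panel with 0-3 base-edited alleles per clone,
quantifies the edited-allele fraction with a variant-specific watching
primer, and snaps each fraction to the nearest k/3 hypothesis — the reason
heterozygous clones read ~33% or ~66%, never 50%, at a three-copy locus.
"""

from getpcr import (
    EditSpec,
    SimConfig,
    apply_edit,
    build_assay,
    call_genotype,
    design_control_amplicon,
    design_variant_primers,
    generate_clone_panel,
    genotype_tally,
    synthetic_locus,
    variant_fraction,
)

locus, guide = synthetic_locus(1, protospacer_preset={7: "C"})
pos = guide.protospacer_start + 7
variant = EditSpec("substitution", pos, "T", label="C-to-T at guide position 8")
edited = apply_edit(locus, variant)

primer = design_variant_primers(locus, variant, "auto")[0]
assay = build_assay("be", "variant",
                    watch_forward=primer if primer.orientation == "forward" else None,
                    watch_reverse=primer if primer.orientation == "reverse" else None,
                    control=design_control_amplicon(locus, guide))
print(f"variant primer: {primer.orientation}, 3'-base {primer.terminal_base} "
      f"(A-terminated primers discriminate best)")

specs = [("wild",) * 3, ("wild", "wild", "edited"), ("wild", "edited", "edited"),
         ("edited",) * 3, ("wild", "wild", "edited")]
config = SimConfig(seed=5, noise_sd=0.1, replicates=3)
ct, truth = generate_clone_panel(locus, 3, specs, {"be": assay},
                                 {"wild": locus.sequence, "edited": edited},
                                 config)

print("\nclone      true k   measured %   called k  ambiguous")
calls = []
for clone, k in truth["edited_allele_counts"].items():
    est = variant_fraction(ct.select(clone, "be"), ct.select("std_edited", "be"))
    call = call_genotype(min(1.0, est.fraction), est.sem, 3, clone_id=clone)
    calls.append(call)
    print(f"{clone}      {k}       {est.fraction * 100:5.1f}        "
          f"{call.edited_allele_count}       {call.ambiguous}")
print(f"\nclones by edited-allele count: {genotype_tally(calls)}")
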