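"""Design watching primers for a CRISPR target.

Builds a synthetic 2-kb locus with a central guide, designs single-direction
and combined watching primers plus the distal control amplicon, and prints
the assay parameters a bench scientist would order.
"""

from getpcr import (
    design_combined_pair,
    design_control_amplicon,
    design_watching_primers,
    synthetic_locus,
)

locus, guide = synthetic_locus(1, cut_triplet="ACG")
print(f"locus {locus.id}: {len(locus)} nt, cut between positions "
      f"{guide.cut_index - 1} and {guide.cut_index} ({guide.strand} strand guide)")

print("\nTop single-direction watching primers (w = cut-spanning 3' bases):")
for mode in ("single_forward", "single_reverse"):
    p = design_watching_primers(locus, guide, mode)[0]
    print(f"  {mode:15s} w={p.watching_bases}  Tm={p.tm_c:5.2f} C  "
          f"3'-base={p.terminal_base}  {p.sequence}")

pair = design_combined_pair(locus, guide)
print(f"\nCombined pair: w = {pair.forward.watching_bases} + "
      f"{pair.reverse.watching_bases} (4 additive watching bases; "
      f"background risk {pair.background.risk} is inherent to the cut overlap)")

ctrl = design_control_amplicon(locus, guide)
lo, hi = ctrl.amplicon_span
print(f"Control amplicon: positions {lo}-{hi} "
      f"({min(abs(lo - guide.cut_index), abs(hi - guide.cut_index))} nt from the cut)")
print("\nA primer ending in A is preferred (A > C > G > T); anneal 4 C above Tm.")
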