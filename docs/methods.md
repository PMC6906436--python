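# Methods

## The measurement principle

Taq polymerase cannot efficiently extend a primer whose 3′-terminal
nucleotide(s) fail to pair with the template.  A *watching primer* is placed
so that its last few bases — the *watching bases*, `w` — span the Cas9 blunt
cut (or a variant position).  An indel at the cut shifts the register of
those bases against the template and creates 3′-terminal mismatches; the
edited alleles therefore drop out of the amplification, and the watch signal
reports the unedited (wild-type) template only.  A control amplicon placed
hundreds of bases away measures total template.  With an unedited reference
sample measured by the same assay,

    dCt  = mean(Ct_watch) − mean(Ct_ref)            per sample
    ddCt = dCt_sample − dCt_reference
    wild fraction f = 2^(−ddCt), clipped to [0, 1]
    indel frequency = 1 − f

For precise edits (HDR knock-ins, C→T base editing) the primer's 3′ end
matches the *variant* bases instead and the same transform against a
100%-variant standard yields the variant-allele fraction directly.

Assumptions: 100% per-cycle amplification efficiency (one doubling per
cycle — the standard transform; the simulator exposes the efficiency as a
parameter), and a non-proofreading polymerase.  Proofreading (3′→5′
exonuclease) enzymes excise terminal mismatches and erase the signal; the
penalty model has a `high_fidelity` flag that reproduces this, and every
simulation pipeline refuses such a model.

## Coordinate conventions

All coordinates are 0-based, half-open, on the + strand.  The blunt cut
falls 3 bp 5′ of the PAM: `cut_index = protospacer_start + 17` for + strand
guides, `protospacer_start + 3` for − strand guides, with the cut between
`cut_index − 1` and `cut_index`.  Watching bases are counted as the primer
bases pairing template positions across the cut from the primer's 5′ anchor
(positions `>= cut_index` for forward primers, `< cut_index` for reverse).
Staggered cuts and paired nickases are out of scope.

## Primer design rules

* Single-direction watching primers carry `w ∈ {3, 4, 5}`; the 3′ terminus
  is fixed by `w` and the 5′ end is extended (14–36 nt) until the melting
  temperature enters `tm_target ± 2 °C` (default target 65 °C).
* Combined forward+reverse designs carry 4 watching bases in sum (splits
  1+3, 2+2, 3+1).  Totals of 5–6 discriminate too but self-amplify; they are
  emitted only on request, with a warning.
* Terminal-base preference A > C > G > T; a T-terminated candidate is never
  ranked above a same-`w` alternative inside the Tm window.  A penultimate A
  earns a small tie-break bonus.  Full tie-break order: terminal base →
  |Tm − target| → smaller `w` → penultimate base → leftmost coordinate,
  which makes the ranking a deterministic total order.
* Recommended annealing temperature: hottest watching-primer Tm + 4 °C,
  rounded to the nearest degree (69 °C at the 65 °C design point).
* The control amplicon (80–250 nt, primer Tm within ±1 °C) is placed
  entirely outside a 300 nt exclusion radius around the cut — a concrete
  reading of "hundreds of base pairs away" — relaxing in 50 nt steps with a
  warning on short loci.  The watch amplicon is 60–300 nt, so control and
  watch amplicons can never overlap at the default radius.

Melting temperatures use the salt-adjusted formula
`Tm = 100.5 + 41·GC/N − 820/N + 16.6·log10([Na+])` at `[Na+] = 0.05 M`
(Wallace rule `2(A+T) + 4(G+C)` below 14 nt), rounded to 0.01 °C so numbers
are bit-reproducible.

Variant (allele-specific) primers place the changed base(s) within the last
1–3 positions and are ranked **variant-distance-first**: a primer whose 3′
terminus sits on the variant discriminates best, so terminal placement
outranks the terminal-base preference here.  Direction `auto` searches both
strands; for a C→T edit this typically selects the reverse-strand primer,
whose terminal base is A — the best discriminator — rather than the
T-terminated forward primer.

A combined pair with 4 total watching bases necessarily shares exactly 4
complementary 3′ bases (both primers cover the same 4 positions around the
cut), so `check_background` reports it as high-risk by the raw rule
(3′-dimer ≥ 4 nt or ≥ 5 total watching bases).  The designer therefore warns
only when complementarity exceeds that inherent overlap, or when the total
is ≥ 5 — the regime where self-amplification is actually observed.

## The mismatch penalty model

`mismatch_profile` aligns a primer to a template by the exact, unique
occurrence of its 5′-most 10 bases and compares base-by-base with no gaps.
Indel "slipping" emerges from the register shift: a +1 insertion at the cut
mismatches all three watching bases of a `w = 3` primer, and a −1 deletion
slips 3 or 4 depending on its position.

The penalty converts a profile into an initiation delay in cycles:

    penalty = min(cap, Σ_mismatches w_pos(d) · w_base(primer base))

with `w_pos = {0: 10, 1: 6, 2: 4, 3: 2, 4–7: 0.5, ≥8: 0}` cycles,
`w_base = {A: 1.3, C: 1.1, G: 0.9, T: 0.6}`, cap 15 cycles, and an
adjacency override: two or more mismatches within the last three bases give
the cap outright.  **These numbers are calibration constants invented for
this package**; no published table exists.  They encode only three
qualitative facts — penalties fall with distance from the 3′ end, A-ended
primers discriminate best (then C, G, T), and clustered terminal mismatches
abolish amplification — and live in a serializable, versioned config
(`PenaltyModel`, YAML round-trip) rather than in code.  Position
monotonicity is enforced at model load.

A template in which the 10 nt anchor is absent (a deletion reaching into the
primer's 5′ half) cannot prime at all; the simulator gives it zero watch
signal and the discrimination ranker scores it at the cap.

Panel-minimum discrimination is *not* monotone in `w`: after slipping, the
shifted bases can coincidentally re-pair, and which templates benefit
differs between `w` values.  The screening helper
`select_discriminating_assays` handles this empirically, keeping assays
whose predicted worst-case shift across the 26-spec panel is ≥ 8 cycles
(≤ 0.4% residual signal) — the design-time analogue of choosing selective
primers before quantifying.

## The 26-spec indel mimic panel

The indel panel that stands in for NHEJ outcomes is a declared, versioned
fixture: deletions of length 1–15 ending at the cut (15), deletions of
length 2/4/6 starting one base further left (3), and insertions of length
1–8 at the cut (8).  Insertion payloads are chosen deterministically to
differ from both cut-flanking bases, so a +1 insertion never silently
recreates the wild sequence.  Real NHEJ spectra are locus-specific; this
panel covers the 1–15 bp size range that dominates them without claiming to
reproduce any particular locus's spectrum.

## The simulator

A mismatch is modelled as a one-time initiation delay: a template with
penalty `p` behaves like `2^(−p)` of its copy number, after which products
amplify at the configured efficiency.  For a template mix,

    Q_watch = Σ_t copies_t · 2^(−penalty_t)        (anchorless templates: 0)
    Ct      = ct_calibration − log_{1+E}(Q) + ε,   ε ~ N(0, noise_sd²)

independently per technical replicate; the reference channel amplifies every
template with penalty 0.  Ct beyond the 40-cycle program is censored to the
no-amplification sentinel, which quantification treats as Ct 40 (a watch
channel censored in all replicates reports below-detection instead of a
number).  For combined assays the per-primer penalties add, capped at the
model maximum.  An optional constant-Ct background floor emulates
primer-pair self-amplification (off by default).

Defaults mirror the study conditions: 3 technical replicates, Gaussian
technical noise of 0.1 cycles (a typical qPCR plate; no published value
exists), calibration Ct 20 for one relative template unit, efficiency 1.0,
40-cycle censoring.  Identical seed + config gives bit-identical tables.
A helper converts DNA mass to template copies at 3.3 pg per haploid genome.

What the simulator does **not** emulate: amplification-efficiency
differences between amplicons, plate/position effects, template degradation,
cross-contamination, polymerase batch effects, or locus-specific NHEJ
spectra.  Passing tests therefore demonstrate that the estimators are
correct under the stated noise model, not that any particular wet-lab run
will achieve the same accuracy.

## Quantification and calling

* Standard errors propagate by the first-order delta method:
  `sem(f) = ln 2 · 2^(−ddCt) · sem(ddCt)`, with `sem(ddCt)` from the four
  replicate means.  Raw fractions outside [0, 1] are clipped and flagged.
* Genotypes: a clone of ploidy `P` with `k` edited alleles shows fraction
  `k/P`; `call_genotype` snaps to the nearest hypothesis (ties toward
  smaller `k`, the conservative choice), flags calls whose margin is within
  `2·sem`, and reports a one-sample t-test p-value against the nearest
  rejected hypothesis when replicate fractions are supplied.  Ploidy is an
  input (established once per locus via copy number), not inferred per
  clone.
* Missing fraction: `max(0, 1 − Σ per-base fractions)`, flagged above 0.15.
  The threshold is a configurable default chosen so that a genuinely
  unassayed allele at a triploid locus (≈ 1/3 missing) is flagged with
  margin while technical shortfalls (a few percent) are not.
* Copy number: `reference_copies · 2^(−(Ct_gene − Ct_ref))` against a
  single-copy calibrator (one allele of a heterozygous SNP), rounded to the
  nearest integer; the residual is reported.
* Group comparisons run Levene's variance test and gate a pooled versus
  Welch two-tailed t-test at α = 0.05; strategy agreement uses Pearson
  correlation.  No multiple-testing correction (single comparisons only).

## Problem sizes in the reproduction script

`scripts/acceptance.py` measures everything by running the pipeline on
synthetic designs: mixture recovery averages the discrimination-screened
subset of the 12-strategy set over 5 independently prepared mixture/control
pairs; triploid clone genotyping averages 6 single-allele-edited clones per
plate over 3 plates and both assay directions; HDR and base-editing pools
average 5 biological samples over both primer directions.  Averaging over
strategies, samples and clones is how the underlying experiment reports its
numbers too; a single assay on a single sample carries ~8% relative noise at
0.1-cycle technical noise with triplicates, which no estimator can remove.

## Known limitations

* The penalty magnitudes are invented calibration constants; only their
  orderings are empirically grounded.  Conclusions that depend on absolute
  cycle shifts (e.g. the 8-cycle screening threshold) are model choices.
* Below ~10% true indel frequency the indirect estimate `1 − f` inherits
  the full relative error of `f`, and accuracy degrades — by design of the
  method, not of the implementation.
* At ploidy 4 with 0.1-cycle noise and triplicates, adjacent genotype
  hypotheses sit ~2σ apart for mid-range `k`; across hundreds of clones an
  occasional miscall is statistically expected.  Such calls fall within the
  ambiguity margin and are flagged rather than reported confidently, and
  combining two independently designed assays (`combine_strategies`)
  restores the margin.
* Per-position calls only: allele-phase reconstruction across positions
  (haplotypes) is out of scope, as are off-target discovery, melting-curve
  analysis and raw fluorescence processing.
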