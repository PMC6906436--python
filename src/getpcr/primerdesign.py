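"""Watching-primer, partner and control-amplicon design.

A *watching primer* spans the Cas9 cut (or a variant position) with its
3'-terminal bases so that indels or unedited bases create 3' mismatches that
block Taq-initiated amplification.  Design rules implemented here:

* single-direction watching primers carry 3-5 watching bases;
* combined forward+reverse pairs carry 4 watching bases in sum (5-6 raise a
  background self-amplification warning);
* 3'-terminal base preference A > C > G > T (thymine avoided when any
  alternative exists in the Tm window);
* primers are extended at the 5' end until the melting temperature falls in a
  +/-2 degC window around the target (default 65 degC), length 14-36 nt;
* the recommended annealing temperature is the hottest watching primer's Tm
  plus 4 degC, rounded to the nearest integer;
* the control amplicon sits entirely outside a 300 nt exclusion radius around
  the cut whenever the locus allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import (
    UndesignableControlError,
    UndesignableLocusError,
    UnsupportedEditError,
    ValidationError,
)
from .seqmodel import EditSpec, GuideTarget, TargetLocus, revcomp

TERMINAL_RANK = {"A": 0, "C": 1, "G": 2, "T": 3}

MIN_PRIMER_LENGTH = 14
MAX_PRIMER_LENGTH = 36
DEFAULT_TM_TARGET_C = 65.0
DEFAULT_NA_MOLAR = 0.05
WATCHING_CHOICES = (3, 4, 5)
COMBINED_TOTAL_WATCHING = 4
CONTROL_EXCLUSION_RADIUS = 300
WATCH_AMPLICON_RANGE = (60, 300)
CONTROL_AMPLICON_RANGE = (80, 250)


def compute_tm(sequence: str, monovalent_salt_molar: float = DEFAULT_NA_MOLAR) -> float:
    """Primer melting temperature in degC, deterministic to 0.01 degC.

    Below 14 nt the Wallace rule ``2*(A+T) + 4*(G+C)`` is used; from 14 nt the
    salt-adjusted formula ``100.5 + 41*GC/N - 820/N + 16.6*log10([Na+])``.
    """
    seq = sequence.upper()
    if len(seq) < 8 or any(b not in "ACGT" for b in seq):
        raise ValidationError(
            f"Tm needs a pure-ACGT sequence of >= 8 nt, got {sequence!r}"
        )
    if monovalent_salt_molar <= 0:
        raise ValidationError("monovalent salt concentration must be positive")
    n = len(seq)
    gc = seq.count("G") + seq.count("C")
    if n < 14:
        tm = 2.0 * (n - gc) + 4.0 * gc
    else:
        tm = 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * math.log10(monovalent_salt_molar)
    return round(tm, 2)


@dataclass(frozen=True)
class Primer:
    """A designed oligo, written 5'->3'.

    ``three_prime_pos`` is the 0-based + strand index of the template base
    paired by the primer's 3' terminus.  A forward primer therefore covers
    + strand positions ``[three_prime_pos - len + 1, three_prime_pos]``; a
    reverse primer covers ``[three_prime_pos, three_prime_pos + len - 1]``
    and its sequence is the reverse complement of that + strand slice.
    """

    sequence: str
    orientation: str           # "forward" | "reverse"
    three_prime_pos: int
    tm_c: float
    watching_bases: int = 0
    role: str = "watch"        # watch | partner | control | variant

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if not self.sequence:
            raise ValidationError("empty primer sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def terminal_base(self) -> str:
        return self.sequence[-1]

    @property
    def plus_span(self) -> tuple[int, int]:
        """Half-open + strand interval covered by the primer."""
        if self.orientation == "forward":
            return (self.three_prime_pos - len(self.sequence) + 1, self.three_prime_pos + 1)
        return (self.three_prime_pos, self.three_prime_pos + len(self.sequence))


def primer_from_span(locus: TargetLocus, start: int, end: int, orientation: str,
                     *, watching_bases: int = 0, role: str = "watch",
                     na_molar: float = DEFAULT_NA_MOLAR) -> Primer:
    """Build a primer from a + strand half-open interval of a locus."""
    if start < 0 or end > len(locus.sequence) or end <= start:
        raise ValidationError(f"primer span [{start}, {end}) outside locus")
    sub = locus.sequence[start:end]
    seq = sub if orientation == "forward" else revcomp(sub)
    tpp = end - 1 if orientation == "forward" else start
    return Primer(seq, orientation, tpp, compute_tm(seq, na_molar),
                  watching_bases=watching_bases, role=role)


def count_watching_bases(primer: Primer, cut_index: int) -> int:
    """Number of primer bases pairing template positions across the cut.

    A forward primer watches + strand positions ``>= cut_index``; a reverse
    primer watches positions ``< cut_index``.  0 means the primer does not
    cross the cut.
    """
    if primer.orientation == "forward":
        w = primer.three_prime_pos - cut_index + 1
    else:
        w = cut_index - primer.three_prime_pos
    return max(0, min(len(primer.sequence), w))


def _rank_key(p: Primer, tm_target: float) -> tuple:
    # Terminal base A>C>G>T, then closest Tm, then fewer watching bases,
    # then (soft bonus) penultimate-A, then leftmost coordinate.
    penultimate_bonus = 0 if len(p.sequence) >= 2 and p.sequence[-2] == "A" else 1
    return (
        TERMINAL_RANK[p.terminal_base],
        round(abs(p.tm_c - tm_target), 6),
        p.watching_bases,
        penultimate_bonus,
        p.plus_span[0],
    )


def _watch_candidates(locus: TargetLocus, cut_index: int, orientation: str, w: int,
                      tm_target: float, tm_window: float, na_molar: float) -> list[Primer]:
    seq = locus.sequence
    out: list[Primer] = []
    if orientation == "forward":
        end = cut_index + w
        if end > len(seq):
            return out
        for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
            start = end - length
            if start < 0:
                break
            p = primer_from_span(locus, start, end, "forward",
                                 watching_bases=w, na_molar=na_molar)
            if abs(p.tm_c - tm_target) <= tm_window:
                out.append(p)
    else:
        start = cut_index - w
        if start < 0:
            return out
        for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
            end = start + length
            if end > len(seq):
                break
            p = primer_from_span(locus, start, end, "reverse",
                                 watching_bases=w, na_molar=na_molar)
            if abs(p.tm_c - tm_target) <= tm_window:
                out.append(p)
    return out


def design_watching_primers(locus: TargetLocus, guide: GuideTarget,
                            mode: str = "single_forward",
                            tm_target_c: float = DEFAULT_TM_TARGET_C, *,
                            tm_window_c: float = 2.0,
                            watching_choices: Sequence[int] = WATCHING_CHOICES,
                            na_molar: float = DEFAULT_NA_MOLAR) -> list[Primer]:
    """Ranked cut-spanning primer candidates for one direction.

    Candidates carry w in ``watching_choices`` (default 3-5) watching bases;
    the 3' terminus is fixed by w and the 5' end is extended until the Tm
    falls within ``tm_target_c +/- tm_window_c``.  Ranking: terminal base
    A>C>G>T, then |Tm - target|, then smaller w (deterministic total order).
    """
    if mode not in ("single_forward", "single_reverse"):
        raise ValidationError(f"mode must be single_forward or single_reverse, got {mode!r}")
    orientation = "forward" if mode == "single_forward" else "reverse"
    candidates: list[Primer] = []
    for w in watching_choices:
        candidates.extend(_watch_candidates(locus, guide.cut_index, orientation, w,
                                            tm_target_c, tm_window_c, na_molar))
    if not candidates:
        raise UndesignableLocusError(
            f"undesignable locus {locus.id!r}: no {orientation} watching primer with "
            f"w in {tuple(watching_choices)} reaches Tm {tm_target_c}+/-{tm_window_c} degC "
            f"within {MAX_PRIMER_LENGTH} nt (locus length {len(locus.sequence)})"
        )
    return sorted(candidates, key=lambda p: _rank_key(p, tm_target_c))


@dataclass(frozen=True)
class BackgroundRisk:
    """Primer-pair self-amplification risk report."""

    dimer_length: int          # perfect 3'-terminal complementarity, nt
    total_watching: int
    risk: str                  # "high" | "low"


def check_background(forward: Primer, reverse: Primer) -> BackgroundRisk:
    """Assess self-amplification risk of a (possibly overlapping) primer pair.

    Risk is high when the two 3' ends are perfectly complementary over >= 4 nt
    or when the pair carries >= 5 watching bases in sum.
    """
    f, r = forward.sequence, reverse.sequence
    dimer = 0
    for length in range(1, min(len(f), len(r)) + 1):
        if f[-length:] == revcomp(r[-length:]):
            dimer = length
    total_w = forward.watching_bases + reverse.watching_bases
    risk = "high" if dimer >= 4 or total_w >= 5 else "low"
    return BackgroundRisk(dimer, total_w, risk)


@dataclass(frozen=True)
class CombinedDesign:
    """Result of combined-mode design; unpacks as ``forward, reverse``."""

    forward: Primer
    reverse: Primer
    background: BackgroundRisk
    warnings: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.forward, self.reverse))


def _combined_candidates(locus: TargetLocus, guide: GuideTarget, tm_target_c: float,
                         total_watching: int, tm_window_c: float,
                         na_molar: float) -> list[CombinedDesign]:
    pairs: list[tuple[tuple, CombinedDesign]] = []
    for wf in range(1, total_watching):
        wr = total_watching - wf
        fwd = _watch_candidates(locus, guide.cut_index, "forward", wf,
                                tm_target_c, tm_window_c, na_molar)
        rev = _watch_candidates(locus, guide.cut_index, "reverse", wr,
                                tm_target_c, tm_window_c, na_molar)
        if not fwd or not rev:
            continue
        f = min(fwd, key=lambda p: _rank_key(p, tm_target_c))
        r = min(rev, key=lambda p: _rank_key(p, tm_target_c))
        bg = check_background(f, r)
        key = (
            TERMINAL_RANK[f.terminal_base] + TERMINAL_RANK[r.terminal_base],
            max(TERMINAL_RANK[f.terminal_base], TERMINAL_RANK[r.terminal_base]),
            1 if bg.risk == "high" else 0,
            round(abs(f.tm_c - tm_target_c) + abs(r.tm_c - tm_target_c), 6),
            wf,
        )
        pairs.append((key, CombinedDesign(f, r, bg)))
    pairs.sort(key=lambda kv: kv[0])
    return [design for _, design in pairs]


def design_combined_pair(locus: TargetLocus, guide: GuideTarget,
                         tm_target_c: float = DEFAULT_TM_TARGET_C, *,
                         total_watching: int = COMBINED_TOTAL_WATCHING,
                         tm_window_c: float = 2.0,
                         na_molar: float = DEFAULT_NA_MOLAR) -> CombinedDesign:
    """Best forward+reverse watching pair with ``total_watching`` bases in sum.

    Splits 1+3, 2+2 and 3+1 (for the default total of 4) are enumerated and
    ranked by the terminal-base rule applied to both ends, then background
    risk, then Tm closeness.  Totals of 5 or more are emitted with a
    background-risk warning (primer self-amplification).
    """
    if total_watching < 2:
        raise ValidationError("a combined pair needs at least 1+1 watching bases")
    ranked = _combined_candidates(locus, guide, tm_target_c, total_watching,
                                  tm_window_c, na_molar)
    if not ranked:
        raise UndesignableLocusError(
            f"undesignable locus {locus.id!r}: no combined pair with "
            f"{total_watching} total watching bases reaches the Tm window"
        )
    best = ranked[0]
    warnings: list[str] = []
    if total_watching >= 5:
        warnings.append(
            f"{total_watching} additive watching bases risk background "
            "self-amplification; 4 is the recommended total"
        )
    # both primers cover the same total_watching bases around the cut, so a
    # 3'-dimer of exactly that length is inherent to the design; only excess
    # complementarity is worth a warning on a recommended 4-base pair
    if best.background.dimer_length > total_watching:
        warnings.append(
            f"3'-dimer of {best.background.dimer_length} nt exceeds the "
            f"{total_watching} nt cut overlap; elevated self-amplification risk"
        )
    return replace(best, warnings=tuple(warnings))


def design_variant_primers(locus: TargetLocus, variants, direction: str = "auto",
                           tm_target_c: float = DEFAULT_TM_TARGET_C, *,
                           allele: str = "variant",
                           tm_window_c: float = 2.0,
                           na_molar: float = DEFAULT_NA_MOLAR) -> list[Primer]:
    """Allele-specific primers whose 3'-terminal 1-3 bases cover the variant.

    ``variants`` is one substitution :class:`EditSpec` or a list of them (for
    adjacent edited positions).  ``allele`` selects whether the primer matches
    the variant sequence (variant-fraction assays) or the wild sequence
    (wild-fraction assays).  ``direction`` may be ``forward``, ``reverse`` or
    ``auto`` (both strands considered).

    Ranking puts the variant as close to the 3' terminus as possible first —
    allele discrimination collapses when the discriminating base drifts from
    the terminus — then applies the usual terminal-base / Tm ordering.  With
    ``auto`` this lets e.g. a C>T edit be assayed from the opposite strand
    with an A-terminated primer.
    """
    if isinstance(variants, EditSpec):
        variants = [variants]
    if not variants:
        raise ValidationError("at least one variant is required")
    for v in variants:
        if v.kind != "substitution":
            raise UnsupportedEditError(
                f"variant primers require substitution edits, got {v.kind!r} "
                f"({v.label or 'unlabelled'})"
            )
    positions = sorted({p for v in variants for p in range(v.position, v.end)})
    first_pos, last_pos = positions[0], positions[-1]
    if last_pos - first_pos > 2:
        raise UnsupportedEditError(
            "variant positions must fit within the primer's last 3 bases "
            f"(span {last_pos - first_pos + 1} nt)"
        )

    template_seq = locus.sequence
    if allele == "variant":
        for v in variants:
            template_seq = (template_seq[: v.position] + v.payload
                            + template_seq[v.end:])
    elif allele != "wild":
        raise ValidationError("allele must be 'variant' or 'wild'")
    template = TargetLocus(locus.id + f"_{allele}", template_seq)

    if direction == "auto":
        directions = ("forward", "reverse")
    elif direction in ("forward", "reverse"):
        directions = (direction,)
    else:
        raise ValidationError(f"direction must be forward/reverse/auto, got {direction!r}")

    scored: list[tuple[tuple, Primer]] = []
    for orient in directions:
        for offset in range(0, 3):
            if orient == "forward":
                end = last_pos + offset + 1
                if first_pos < end - 3 or end > len(template_seq):
                    continue
                spans = [(end - L, end) for L in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1)]
            else:
                start = first_pos - offset
                if last_pos > start + 2 or start < 0:
                    continue
                spans = [(start, start + L) for L in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1)]
            for s, e in spans:
                if s < 0 or e > len(template_seq):
                    continue
                p = primer_from_span(template, s, e, orient,
                                     watching_bases=last_pos - first_pos + 1 + offset,
                                     role="variant", na_molar=na_molar)
                if abs(p.tm_c - tm_target_c) <= tm_window_c:
                    scored.append(((offset,) + _rank_key(p, tm_target_c), p))
    if not scored:
        raise UndesignableLocusError(
            f"undesignable locus {locus.id!r}: no {allele}-specific primer covering "
            f"positions {first_pos}-{last_pos} reaches the Tm window"
        )
    scored.sort(key=lambda kv: kv[0])
    return [p for _, p in scored]


@dataclass(frozen=True)
class ControlDesign:
    """Control-amplicon primer pair; unpacks as ``forward, reverse``."""

    forward: Primer
    reverse: Primer
    warnings: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.forward, self.reverse))

    @property
    def amplicon_span(self) -> tuple[int, int]:
        return (self.forward.plus_span[0], self.reverse.plus_span[1])


def _place_control(locus: TargetLocus, lo: int, hi: int, tm_target: float,
                   tm_window: float, amp_range: tuple[int, int],
                   na_molar: float) -> ControlDesign | None:
    amp_min, amp_max = amp_range
    for s in range(lo, hi - amp_min + 1, 5):
        fwd = None
        for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
            if s + length > hi:
                break
            p = primer_from_span(locus, s, s + length, "forward", role="control",
                                 na_molar=na_molar)
            if abs(p.tm_c - tm_target) <= tm_window:
                fwd = p
                break
        if fwd is None:
            continue
        for amp in range(amp_min, min(amp_max, hi - s) + 1, 5):
            e = s + amp
            for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
                if e - length <= fwd.plus_span[1]:
                    break
                p = primer_from_span(locus, e - length, e, "reverse", role="control",
                                     na_molar=na_molar)
                if abs(p.tm_c - tm_target) <= tm_window:
                    return ControlDesign(fwd, p)
    return None


def design_control_amplicon(locus: TargetLocus, guide: GuideTarget,
                            tm_target_c: float = DEFAULT_TM_TARGET_C, *,
                            exclusion_radius: int = CONTROL_EXCLUSION_RADIUS,
                            amplicon_range: tuple[int, int] = CONTROL_AMPLICON_RANGE,
                            tm_window_c: float = 1.0,
                            na_molar: float = DEFAULT_NA_MOLAR) -> ControlDesign:
    """A control primer pair placed hundreds of bases away from the cut.

    The amplicon (80-250 nt, primer Tm within +/-1 degC of target) lies
    entirely outside ``[cut - exclusion_radius, cut + exclusion_radius]`` when
    the locus allows; otherwise the radius is relaxed in 50 nt steps and a
    warning is attached.
    """
    cut = guide.cut_index
    n = len(locus.sequence)
    for radius in range(exclusion_radius, -1, -50):
        regions = sorted(
            [(0, max(0, cut - radius)), (min(n, cut + radius + 1), n)],
            key=lambda r: r[1] - r[0], reverse=True,
        )
        for lo, hi in regions:
            if hi - lo < amplicon_range[0]:
                continue
            found = _place_control(locus, lo, hi, tm_target_c, tm_window_c,
                                   amplicon_range, na_molar)
            if found is not None:
                if radius < exclusion_radius:
                    found = replace(found, warnings=(
                        f"control amplicon only {radius} nt from the cut; the locus "
                        f"is too short for the requested {exclusion_radius} nt radius",
                    ))
                return found
    raise UndesignableControlError(
        f"undesignable control: locus {locus.id!r} ({n} nt) cannot host a "
        f"{amplicon_range[0]}-{amplicon_range[1]} nt control amplicon"
    )


def design_partner(locus: TargetLocus, watch: Primer, cut_index: int,
                   tm_target_c: float = DEFAULT_TM_TARGET_C, *,
                   amplicon_range: tuple[int, int] = WATCH_AMPLICON_RANGE,
                   tm_window_c: float = 2.0,
                   na_molar: float = DEFAULT_NA_MOLAR) -> Primer:
    """Non-watching partner completing the watch amplicon of a single-direction
    assay.  The partner lies entirely on the far side of the cut (0 watching
    bases) and yields an amplicon of 60-300 nt."""
    n = len(locus.sequence)
    amp_min, amp_max = amplicon_range
    if watch.orientation == "forward":
        astart = watch.plus_span[0]
        for e in range(astart + amp_min, min(n, astart + amp_max) + 1):
            for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
                s = e - length
                if s < cut_index:
                    break
                p = primer_from_span(locus, s, e, "reverse", role="partner",
                                     na_molar=na_molar)
                if abs(p.tm_c - tm_target_c) <= tm_window_c:
                    return p
    else:
        aend = watch.plus_span[1]
        for s in range(max(0, aend - amp_max), aend - amp_min + 1):
            for length in range(MIN_PRIMER_LENGTH, MAX_PRIMER_LENGTH + 1):
                e = s + length
                if e > cut_index:
                    break
                p = primer_from_span(locus, s, e, "forward", role="partner",
                                     na_molar=na_molar)
                if abs(p.tm_c - tm_target_c) <= tm_window_c:
                    return p
    raise UndesignableLocusError(
        f"undesignable locus {locus.id!r}: no partner primer completes the "
        f"watch amplicon for the {watch.orientation} watching primer"
    )


@dataclass(frozen=True)
class PrimerAssay:
    """A complete assay: watching/variant primer(s), partner, control pair."""

    assay_id: str
    mode: str                  # single_forward | single_reverse | combined | variant
    watch_forward: Primer | None = None
    watch_reverse: Primer | None = None
    partner: Primer | None = None
    control_forward: Primer | None = None
    control_reverse: Primer | None = None
    recommended_anneal_c: float = 0.0
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.watch_forward is None and self.watch_reverse is None:
            raise ValidationError("an assay needs at least one watching primer")
        if self.mode == "combined":
            if self.watch_forward is None or self.watch_reverse is None:
                raise ValidationError("combined mode needs both watching primers")
            if self.partner is not None:
                raise ValidationError("combined mode takes no partner primer")

    @property
    def watching_primers(self) -> tuple[Primer, ...]:
        return tuple(p for p in (self.watch_forward, self.watch_reverse) if p is not None)

    @property
    def watch_amplicon_span(self) -> tuple[int, int] | None:
        primers = list(self.watching_primers)
        if self.partner is not None:
            primers.append(self.partner)
        if len(primers) < 2:
            return None
        lo = min(p.plus_span[0] for p in primers)
        hi = max(p.plus_span[1] for p in primers)
        return (lo, hi)


def recommend_annealing(assay: PrimerAssay) -> int:
    """Annealing recommendation: hottest watching-primer Tm + 4 degC, rounded
    to the nearest whole degree (65.0 degC -> 69 degC)."""
    tm = max(p.tm_c for p in assay.watching_primers)
    return int(math.floor(tm + 4.0 + 0.5))


def build_assay(assay_id: str, mode: str, *, watch_forward: Primer | None = None,
                watch_reverse: Primer | None = None, partner: Primer | None = None,
                control: ControlDesign | tuple[Primer, Primer] | None = None,
                flags: Iterable[str] = ()) -> PrimerAssay:
    """Assemble an assay and fill in the annealing recommendation."""
    cf = cr = None
    if control is not None:
        cf, cr = control
    assay = PrimerAssay(assay_id, mode, watch_forward=watch_forward,
                        watch_reverse=watch_reverse, partner=partner,
                        control_forward=cf, control_reverse=cr, flags=tuple(flags))
    return replace(assay, recommended_anneal_c=float(recommend_annealing(assay)))
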