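"""Target loci, guide placements, cut coordinates and edit events.

Coordinate conventions used throughout the package:

* all coordinates are 0-based, half-open, and reported on the + strand;
* a blunt Cas9 cut falls 3 bp 5' of the PAM, between ``cut_index - 1`` and
  ``cut_index`` (``cut_index`` is the first + strand base 3' of the cut);
* for a + strand guide ``cut_index = protospacer_start + 17``; for a - strand
  guide ``cut_index = protospacer_start + 3``, where ``protospacer_start`` is
  the leftmost + strand base covered by the protospacer.

Staggered cuts and paired nickases are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import (
    AmbiguousGuideError,
    GuideNotFoundError,
    UnsupportedEditError,
    ValidationError,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC ambiguity codes, used for PAM patterns only (loci must be pure ACGT).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

MIN_LOCUS_LENGTH = 60
PROTOSPACER_LENGTH = 20
#: blunt cut 3 bp 5' of the PAM, i.e. 17 bases into the 20-nt protospacer
CUT_OFFSET = 17


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValidationError(
                f"{what} contains non-ACGT character {base!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class TargetLocus:
    """A genomic target region.

    ``sequence`` must be plain A/C/G/T (ambiguity codes are rejected so that
    primer arithmetic stays exact) and at least ``MIN_LOCUS_LENGTH`` nt long.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, f"locus {self.id!r}"))
        if len(self.sequence) < MIN_LOCUS_LENGTH:
            raise ValidationError(
                f"locus {self.id!r} is {len(self.sequence)} nt; "
                f"at least {MIN_LOCUS_LENGTH} nt are required"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideTarget:
    """A placed guide: protospacer, PAM and derived blunt-cut coordinate."""

    locus_id: str
    protospacer: str
    pam_pattern: str
    strand: str               # "+" or "-"
    protospacer_start: int    # 0-based, + strand, leftmost covered base
    cut_index: int            # first + strand base 3' of the blunt cut


@dataclass(frozen=True)
class EditSpec:
    """An edit event on the + strand of a locus.

    * ``insertion``: ``payload`` (non-empty DNA) is inserted before ``position``;
    * ``deletion``: ``payload`` is the deletion length (int >= 1), removing
      ``[position, position + length)``;
    * ``substitution``: ``payload`` (DNA) replaces the same-length slice
      starting at ``position``.
    """

    kind: str
    position: int
    payload: object
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValidationError(f"unknown edit kind {self.kind!r}")
        if self.position < 0:
            raise ValidationError("edit position must be non-negative")
        if self.kind == "deletion":
            if not isinstance(self.payload, int) or self.payload < 1:
                raise ValidationError("deletion payload must be a length >= 1")
        else:
            if not isinstance(self.payload, str) or not self.payload:
                raise ValidationError(f"{self.kind} payload must be a non-empty DNA string")
            object.__setattr__(self, "payload", _check_dna(self.payload, f"{self.kind} payload"))

    @property
    def end(self) -> int:
        """One past the last + strand position touched by the edit."""
        if self.kind == "insertion":
            return self.position
        if self.kind == "deletion":
            return self.position + self.payload
        return self.position + len(self.payload)


def _pam_matches(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq, pattern))


def locate_cut_site(locus: TargetLocus, protospacer: str, pam_pattern: str = "NGG") -> GuideTarget:
    """Place a 20-nt protospacer on either strand of a locus and derive the cut.

    The protospacer must match exactly (no mismatches) and the PAM must sit
    immediately 3' of it on the same strand.  The placement must be unique.

    Raises
    ------
    GuideNotFoundError
        if the guide occurs nowhere on either strand.
    AmbiguousGuideError
        if it occurs more than once (all hits are listed in the message).
    """
    protospacer = _check_dna(protospacer, "protospacer")
    if len(protospacer) != PROTOSPACER_LENGTH:
        raise ValidationError(
            f"protospacer must be {PROTOSPACER_LENGTH} nt, got {len(protospacer)}"
        )
    pam_pattern = pam_pattern.upper()
    for ch in pam_pattern:
        if ch not in IUPAC:
            raise ValidationError(f"invalid IUPAC character {ch!r} in PAM pattern")

    seq = locus.sequence
    plen = len(pam_pattern)
    hits: list[GuideTarget] = []

    # + strand: protospacer then PAM, left to right
    start = seq.find(protospacer)
    while start != -1:
        pam = seq[start + PROTOSPACER_LENGTH: start + PROTOSPACER_LENGTH + plen]
        if _pam_matches(pam, pam_pattern):
            hits.append(GuideTarget(locus.id, protospacer, pam_pattern, "+",
                                    start, start + CUT_OFFSET))
        start = seq.find(protospacer, start + 1)

    # - strand: the + strand carries revcomp(protospacer) preceded by
    # revcomp(PAM); equivalently the PAM read 5'->3' on the - strand sits
    # immediately left of the protospacer's + strand footprint.
    rc = revcomp(protospacer)
    start = seq.find(rc)
    while start != -1:
        pam_plus = seq[start - plen: start]
        if len(pam_plus) == plen and _pam_matches(revcomp(pam_plus), pam_pattern):
            hits.append(GuideTarget(locus.id, protospacer, pam_pattern, "-",
                                    start, start + PROTOSPACER_LENGTH - CUT_OFFSET))
        start = seq.find(rc, start + 1)

    if not hits:
        raise GuideNotFoundError(
            f"guide not found: protospacer {protospacer} with PAM {pam_pattern} "
            f"does not occur on either strand of locus {locus.id!r}"
        )
    if len(hits) > 1:
        places = ", ".join(f"{h.strand}@{h.protospacer_start}" for h in hits)
        raise AmbiguousGuideError(
            f"ambiguous guide placement on locus {locus.id!r}: hits at {places}"
        )
    return hits[0]


def apply_edit(locus: TargetLocus, edit: EditSpec) -> str:
    """Return the edited + strand sequence of ``locus`` (plain string)."""
    seq = locus.sequence
    n = len(seq)
    if edit.kind == "insertion":
        if edit.position > n:
            raise ValidationError(f"insertion position {edit.position} beyond locus end {n}")
        return seq[: edit.position] + edit.payload + seq[edit.position:]
    if edit.end > n:
        raise ValidationError(
            f"{edit.kind} range [{edit.position}, {edit.end}) exceeds locus length {n}"
        )
    if edit.kind == "deletion":
        return seq[: edit.position] + seq[edit.end:]
    return seq[: edit.position] + edit.payload + seq[edit.end:]


def _insertion_payload(seq: str, cut_index: int, length: int) -> str:
    """Deterministic inserted sequence of the requested length.

    The first inserted base is chosen to differ from both template neighbours
    of the cut, so a 1-nt insertion always disturbs primer pairing rather than
    silently recreating the wild sequence; longer payloads alternate with a
    second base to avoid homopolymer runs.
    """
    left, right = seq[cut_index - 1], seq[cut_index]
    first = next(b for b in "ACGT" if b != left and b != right)
    second = next(b for b in "ACGT" if b != first and b != right)
    return "".join(first if i % 2 == 0 else second for i in range(length))


def mimic_panel(locus: TargetLocus, guide: GuideTarget) -> list[EditSpec]:
    """The declared 26-member indel panel centred on the cut.

    Composition (fixed, versioned — regenerating with the same inputs is
    byte-identical):

    * deletions of length 1..15 whose rightmost removed base is ``cut_index-1``
      (they end at the cut) — 15 specs;
    * deletions of length 2, 4 and 6 starting at ``cut_index - 1 - L`` (one
      base further left, spanning leftwards) — 3 specs;
    * insertions of length 1..8 at ``cut_index`` — 8 specs.
    """
    cut = guide.cut_index
    seq = locus.sequence
    if cut < 20 or cut > len(seq) - 20:
        raise ValidationError(
            f"cut index {cut} is closer than 20 nt to a locus end; "
            "the mimic panel cannot be placed"
        )
    specs: list[EditSpec] = []
    for length in range(1, 16):
        specs.append(EditSpec("deletion", cut - length, length,
                              label=f"del{length}_ending_at_cut"))
    for length in (2, 4, 6):
        specs.append(EditSpec("deletion", cut - 1 - length, length,
                              label=f"del{length}_left_of_cut"))
    for length in range(1, 9):
        specs.append(EditSpec("insertion", cut, _insertion_payload(seq, cut, length),
                              label=f"ins{length}_at_cut"))
    return specs


def apply_panel(locus: TargetLocus, specs: Iterable[EditSpec]) -> dict[str, str]:
    """Edited sequences for a panel, keyed by spec label."""
    out: dict[str, str] = {}
    for spec in specs:
        if not spec.label:
            raise UnsupportedEditError("panel specs must be labelled")
        out[spec.label] = apply_edit(locus, spec)
    return out
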