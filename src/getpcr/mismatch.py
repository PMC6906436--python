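"""3'-anchored primer-template mismatch profiling and the discrimination
penalty model.

A primer is aligned to a template by the exact, unique occurrence of its
5'-most 10 bases (the anchor; the 5' portion of a designed primer is
mismatch-free by construction) and compared base by base with no gaps.  Indels
between the anchor and the 3' end therefore shift the register of the
3'-terminal bases — the "slipping" that makes a +1 insertion mismatch all
three watching bases of a 3-watching-base primer rather than one.

The penalty converts a profile into a Ct delay (cycles).  Its numeric
defaults are calibration constants, chosen to honor three experimentally
established orderings rather than any published table:

* position monotonicity — a mismatch closer to the 3' terminus delays more;
* terminal-base specificity A > C > G > T;
* adjacency destruction — two or more mismatches within the last three bases
  abolish amplification (the cap, 15 cycles).

Proofreading (3'->5' exonuclease) polymerases excise 3' mismatches; the
``high_fidelity`` model flag emulates them by zeroing the penalty, and any
discrimination pipeline must refuse such a model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    AmbiguousAnchorError,
    UndefinedPenaltyError,
    ValidationError,
)
from .primerdesign import Primer
from .seqmodel import revcomp

ANCHOR_LENGTH = 10

DEFAULT_W_POS = {0: 10.0, 1: 6.0, 2: 4.0, 3: 2.0, 4: 0.5, 5: 0.5, 6: 0.5, 7: 0.5}
DEFAULT_W_BASE = {"A": 1.3, "C": 1.1, "G": 0.9, "T": 0.6}
DEFAULT_MAX_PENALTY = 15.0
DEFAULT_ADJACENCY_DISTANCE = 2


@dataclass(frozen=True)
class Mismatch:
    """One mismatching position, indexed from the primer 3' terminus
    (``d = 0`` is the terminal base)."""

    d: int
    primer_base: str
    template_base: str


@dataclass(frozen=True)
class MismatchProfile:
    anchored: bool
    mismatches: tuple[Mismatch, ...] = ()

    def __post_init__(self) -> None:
        ds = [m.d for m in self.mismatches]
        if len(set(ds)) != len(ds):
            raise ValidationError("duplicate mismatch distances in profile")

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def mismatch_profile(primer: Primer, template: str) -> MismatchProfile:
    """Gapless comparison of a primer against a template, anchored 5'.

    The template is given as its + strand sequence; reverse primers are
    compared against the reverse complement.  Positions where the primer
    overhangs the template end count as mismatches (nothing to pair).

    Returns an unanchored profile when the anchor is absent; raises
    :class:`AmbiguousAnchorError` when it occurs more than once.
    """
    view = template.upper()
    if primer.orientation == "reverse":
        view = revcomp(view)
    anchor = primer.sequence[:ANCHOR_LENGTH]
    if len(primer.sequence) < ANCHOR_LENGTH:
        raise ValidationError("primer shorter than the 10 nt anchor")

    first = view.find(anchor)
    if first == -1:
        return MismatchProfile(anchored=False)
    if view.find(anchor, first + 1) != -1:
        raise AmbiguousAnchorError(
            f"primer anchor {anchor} occurs more than once in the template"
        )

    n = len(primer.sequence)
    mismatches = []
    for i, base in enumerate(primer.sequence):
        tpos = first + i
        tbase = view[tpos] if tpos < len(view) else "-"
        if tbase != base:
            mismatches.append(Mismatch(n - 1 - i, base, tbase))
    return MismatchProfile(anchored=True, mismatches=tuple(sorted(
        mismatches, key=lambda m: m.d)))


@dataclass(frozen=True)
class PenaltyModel:
    """Mismatch -> amplification-initiation delay (cycles).

    ``penalty = min(max_penalty, sum_over_mismatches w_pos[d] * w_base[primer_base])``
    with the adjacency override: >= 2 mismatches within ``d <= adjacency_distance``
    give ``max_penalty`` outright.  ``w_pos`` must be non-increasing in d
    (contiguous keys from 0; larger d falls to 0).
    """

    w_pos: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_W_POS))
    w_base: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_W_BASE))
    max_penalty: float = DEFAULT_MAX_PENALTY
    adjacency_distance: int = DEFAULT_ADJACENCY_DISTANCE
    high_fidelity: bool = False

    def __post_init__(self) -> None:
        keys = sorted(self.w_pos)
        if keys != list(range(len(keys))) or not keys:
            raise ValidationError("w_pos keys must be contiguous integers from 0")
        values = [self.w_pos[k] for k in keys] + [0.0]
        if any(v < 0 for v in values):
            raise ValidationError("position penalties must be non-negative")
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValidationError("w_pos must be non-increasing in distance d")
        if set(self.w_base) != set("ACGT") or any(v < 0 for v in self.w_base.values()):
            raise ValidationError("w_base needs a non-negative multiplier for each of ACGT")
        if self.max_penalty < 0:
            raise ValidationError("max_penalty must be non-negative")

    def position_penalty(self, d: int) -> float:
        return float(self.w_pos.get(d, 0.0))

    def to_dict(self) -> dict:
        return {
            "w_pos": {int(k): float(v) for k, v in self.w_pos.items()},
            "w_base": {str(k): float(v) for k, v in self.w_base.items()},
            "max_penalty": float(self.max_penalty),
            "adjacency_distance": int(self.adjacency_distance),
            "high_fidelity": bool(self.high_fidelity),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PenaltyModel":
        known = {"w_pos", "w_base", "max_penalty", "adjacency_distance", "high_fidelity"}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown penalty-model keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "w_pos" in kwargs:
            kwargs["w_pos"] = {int(k): float(v) for k, v in kwargs["w_pos"].items()}
        return cls(**kwargs)


def penalty(profile: MismatchProfile, model: PenaltyModel) -> float:
    """Ct delay (cycles) incurred by a mismatch profile. 0 for a perfect match.

    Raises :class:`UndefinedPenaltyError` for unanchored profiles — an absent
    anchor means the primer cannot initiate at all, which the simulator treats
    as a non-amplifiable template rather than a finite delay.
    """
    if not profile.anchored:
        raise UndefinedPenaltyError("penalty undefined for an unanchored profile")
    if model.high_fidelity:
        # proofreading removes 3' mismatches before extension
        return 0.0
    if not profile.mismatches:
        return 0.0
    near = [m for m in profile.mismatches if m.d <= model.adjacency_distance]
    if len(near) >= 2:
        return float(model.max_penalty)
    total = sum(model.position_penalty(m.d) * model.w_base[m.primer_base]
                for m in profile.mismatches)
    return float(min(model.max_penalty, total))


def discrimination_delta_ct(primer: Primer, wild_template: str,
                            edited_templates: Sequence[str],
                            model: PenaltyModel | None = None) -> list[float]:
    """Predicted per-template Ct shift of each edited template relative to
    wild type, used to rank candidate primers by worst-case (minimum)
    discrimination across a mimic panel.

    An edited template that no longer contains the primer anchor (e.g. a
    deletion eating into the primer's 5' half) cannot amplify at all and is
    scored at the model cap.
    """
    model = model or PenaltyModel()
    base = penalty(mismatch_profile(primer, wild_template), model)

    def _pen(template: str) -> float:
        prof = mismatch_profile(primer, template)
        return penalty(prof, model) if prof.anchored else model.max_penalty

    return [_pen(t) - base for t in edited_templates]


def assay_discrimination(primers: Sequence[Primer], wild_template: str,
                         edited_templates: Sequence[str],
                         model: PenaltyModel | None = None) -> list[float]:
    """Combined-assay version of :func:`discrimination_delta_ct`: per template,
    the capped sum of every watching primer's penalty (an unanchorable primer
    counts as the cap — that template cannot amplify at all)."""
    model = model or PenaltyModel()
    out = []
    for t in edited_templates:
        total = 0.0
        for p in primers:
            prof = mismatch_profile(p, t)
            if not prof.anchored:
                total = model.max_penalty
                break
            total += penalty(prof, model)
        base = sum(penalty(mismatch_profile(p, wild_template), model) for p in primers)
        out.append(min(total, model.max_penalty) - min(base, model.max_penalty))
    return out
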