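"""Ploidy-aware genotype calls, missing-fraction detection, copy number.

A clone of ploidy P with k edited alleles shows an edited-allele fraction of
k/P, so measured fractions cluster at 0, 1/P, ..., 1 — 33%/66% rather than
50% in the near-triploid Lenti-X 293T background that motivates this module.
``call_genotype`` snaps a measured fraction to the nearest hypothesis k/P,
flags calls whose margin is within 2 standard errors, and (given replicate
fractions) attaches a t-test p-value against the nearest rejected hypothesis.

Copy number is estimated against a single-copy calibrator (one allele of a
heterozygous SNP, the paper-style rs6728203-G control):
``raw_copies = reference_copies * 2 ** -(mean Ct_gene - mean Ct_reference)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InconsistentAssayError,
    ValidationError,
)
from .quant import CtTable, correlate_strategies

MAX_PLOIDY = 8
DEFAULT_MISSING_THRESHOLD = 0.15
DEFAULT_AMBIGUITY_MARGIN = 2.0  # in units of sem


@dataclass(frozen=True)
class GenotypeCall:
    clone_id: str
    ploidy: int
    edited_allele_count: int
    fraction: float
    sem: float
    ambiguous: bool = False
    p_value_vs_neighbors: float | None = None
    missing_fraction: float = 0.0
    fractions: Mapping[str, float] | None = None
    flags: tuple[str, ...] = ()


def call_genotype(fraction: float, sem: float, ploidy: int, *,
                  replicate_fractions: Sequence[float] | None = None,
                  clone_id: str = "",
                  ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN) -> GenotypeCall:
    """Snap a measured edited-allele fraction to the nearest k/P hypothesis.

    Ties break toward fewer edited alleles (conservative).  The call is
    flagged ambiguous when the best and second-best hypotheses' distances
    differ by less than ``ambiguity_margin * sem``.
    """
    if not isinstance(ploidy, int) or not 1 <= ploidy <= MAX_PLOIDY:
        raise ValidationError(f"ploidy must be an integer in 1..{MAX_PLOIDY}, got {ploidy!r}")
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1] (clip upstream)")
    if sem < 0:
        raise ValidationError("sem must be non-negative")

    dists = [abs(fraction - k / ploidy) for k in range(ploidy + 1)]
    k_best = int(np.argmin(dists))           # first minimum = smaller k on ties
    rest = [(d, k) for k, d in enumerate(dists) if k != k_best]
    d_second, k_second = min(rest)
    ambiguous = (d_second - dists[k_best]) < ambiguity_margin * sem

    p_value = None
    if replicate_fractions is not None and len(replicate_fractions) >= 2:
        reps = np.asarray(replicate_fractions, dtype=float)
        if np.ptp(reps) == 0:
            p_value = 0.0 if reps[0] != k_second / ploidy else 1.0
        else:
            _, p_value = stats.ttest_1samp(reps, k_second / ploidy)
            p_value = float(p_value)

    flags = ("ambiguous",) if ambiguous else ()
    return GenotypeCall(clone_id, ploidy, k_best, float(fraction), float(sem),
                        ambiguous=ambiguous, p_value_vs_neighbors=p_value,
                        flags=flags)


def missing_fraction(per_base_fractions: Mapping[str, float], *,
                     threshold: float = DEFAULT_MISSING_THRESHOLD,
                     tolerance: float = 0.02) -> tuple[float, bool]:
    """Unaccounted allele fraction across per-base assays at one position.

    ``missing = max(0, 1 - sum(fractions))``; the flag marks a likely
    unassayed variant (e.g. C-to-G editing seen only as a hole in the C/T
    percentages).  Fraction sums above ``1 + tolerance`` indicate an
    inconsistent assay and raise.
    """
    for base, f in per_base_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"fraction for {base!r} outside [0, 1]: {f}")
    total = float(sum(per_base_fractions.values()))
    if total > 1.0 + tolerance:
        raise InconsistentAssayError(
            f"per-base fractions sum to {total:.3f} > 1 + {tolerance}"
        )
    missing = max(0.0, 1.0 - total)
    return missing, missing > threshold


@dataclass(frozen=True)
class CopyNumberEstimate:
    gene_id: str
    raw_copies: float
    called_copies: int
    reference: str
    residual: float  # |raw - called|


def estimate_copy_number(ct_gene: CtTable, ct_reference: CtTable, *,
                         reference_copies: int = 1,
                         gene_id: str = "gene",
                         reference_label: str = "single_copy_reference") -> CopyNumberEstimate:
    """Gene copy number from qPCR against a single-copy calibrator."""
    if reference_copies < 1:
        raise ValidationError("reference_copies must be >= 1")
    gene = ct_gene.cts()
    ref = ct_reference.cts()
    if gene.size == 0 or ref.size == 0:
        raise ValidationError("both Ct slices must contain measurements")
    if np.isnan(gene).any() or np.isnan(ref).any():
        raise ValidationError("copy-number estimation needs numeric Ct in every well")
    dct = float(np.mean(gene) - np.mean(ref))
    raw = reference_copies * 2.0 ** (-dct)
    called = int(math.floor(raw + 0.5))
    return CopyNumberEstimate(gene_id, raw, called, reference_label,
                              abs(raw - called))


@dataclass(frozen=True)
class AgreementReport:
    pearson_r: float
    pearson_p: float
    n_clones: int
    n_concordant: int
    discordant_clones: tuple[str, ...]


def combine_strategies(fractions_a: Sequence[float], fractions_b: Sequence[float],
                       ploidy: int, *,
                       clone_ids: Sequence[str] | None = None,
                       sems_a: Sequence[float] | None = None,
                       sems_b: Sequence[float] | None = None,
                       ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN
                       ) -> tuple[list[GenotypeCall], AgreementReport]:
    """Merge two independently designed assays measured on the same clones.

    Per clone the combined fraction is the mean of the two strategies; clones
    whose individual integer calls disagree are flagged ambiguous regardless
    of the combined margin.  The report carries the Pearson correlation
    between strategies and per-clone concordance.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if a.size != b.size or a.size == 0:
        raise ValidationError("strategies must cover the same non-empty clone set")
    if clone_ids is None:
        clone_ids = [f"clone_{i + 1:02d}" for i in range(a.size)]
    elif len(clone_ids) != a.size:
        raise ValidationError("clone_ids length must match the fraction vectors")
    zeros = np.zeros(a.size)
    sa = np.asarray(sems_a, dtype=float) if sems_a is not None else zeros
    sb = np.asarray(sems_b, dtype=float) if sems_b is not None else zeros

    calls: list[GenotypeCall] = []
    discordant: list[str] = []
    for cid, fa, fb, ea, eb in zip(clone_ids, a, b, sa, sb):
        ka = call_genotype(fa, ea, ploidy, ambiguity_margin=ambiguity_margin)
        kb = call_genotype(fb, eb, ploidy, ambiguity_margin=ambiguity_margin)
        combined = float(np.clip((fa + fb) / 2.0, 0.0, 1.0))
        sem = math.sqrt(ea ** 2 + eb ** 2) / 2.0
        call = call_genotype(combined, sem, ploidy, clone_id=cid,
                             ambiguity_margin=ambiguity_margin)
        if ka.edited_allele_count != kb.edited_allele_count:
            discordant.append(cid)
            call = GenotypeCall(cid, ploidy, call.edited_allele_count, combined,
                                sem, ambiguous=True,
                                p_value_vs_neighbors=call.p_value_vs_neighbors,
                                flags=call.flags + ("discordant_strategies",))
        calls.append(call)

    try:
        r, p = correlate_strategies(a, b)
    except Exception:
        r, p = float("nan"), float("nan")
    n_conc = a.size - len(discordant)
    return calls, AgreementReport(r, p, int(a.size), int(n_conc), tuple(discordant))


def genotype_tally(calls: Sequence[GenotypeCall]) -> dict[int, int]:
    """Counts of clones by edited-allele number (the paper-style
    'single allele-modified' / 'double allele-modified' summary)."""
    tally: dict[int, int] = {}
    for c in calls:
        tally[c.edited_allele_count] = tally.get(c.edited_allele_count, 0) + 1
    return dict(sorted(tally.items()))
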