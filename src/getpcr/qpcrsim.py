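"""Mismatch-aware qPCR simulator and synthetic experiment generators.

The amplification model treats a 3'-mismatch as a one-time initiation delay:
a template with penalty p behaves like ``2**-p`` of its copy number, after
which products amplify at the configured per-cycle efficiency.  For a
template mix, the watch channel sees the effective quantity

    Q = sum_t copies_t * 2 ** -penalty(assay, t)

(an unanchorable template contributes nothing) and

    Ct = ct_calibration - log_{1+E}(Q) + eps,   eps ~ N(0, noise_sd^2)

independently per technical replicate.  The reference channel amplifies every
template with penalty 0.  Ct values beyond the 40-cycle program are censored
to the no-amplification sentinel.  Everything is deterministic under a fixed
seed.

Generators emulate the printed study designs: 26-indel-mimic/wild blends at
0-100% indel fraction measured with twelve watching-primer strategies,
ploidy-P single-cell clone panels, variant (HDR / base-edit) allele pools,
and copy-number qPCR against a single-copy calibrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import HighFidelityModeError, ValidationError
from .mismatch import PenaltyModel, mismatch_profile, penalty
from .primerdesign import (
    PrimerAssay,
    build_assay,
    check_background,
    design_control_amplicon,
    design_partner,
    design_watching_primers,
    _rank_key,
    _watch_candidates,
)
from .quant import REF, WATCH, CtTable
from .seqmodel import (
    EditSpec,
    GuideTarget,
    TargetLocus,
    apply_panel,
    locate_cut_site,
    mimic_panel,
)

#: mass of one haploid human genome, picograms (standard constant)
HAPLOID_GENOME_PG = 3.3


def genome_copies_from_ng(nanograms: float, ploidy: int = 1) -> float:
    """Template copies of a single-copy locus in ``nanograms`` of genomic DNA
    (3.3 pg per haploid genome)."""
    if nanograms <= 0:
        raise ValidationError("DNA mass must be positive")
    return nanograms * 1000.0 / HAPLOID_GENOME_PG * ploidy


@dataclass(frozen=True)
class TemplateEntry:
    label: str
    sequence: str
    copies: float

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValidationError(f"template {self.label!r} needs copies > 0")


@dataclass(frozen=True)
class TemplateMix:
    """A mixture of template species with relative copy numbers."""

    entries: tuple[TemplateEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("a template mix cannot be empty")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValidationError("template labels must be unique")

    @classmethod
    def of(cls, items: Mapping[str, tuple[str, float]]) -> "TemplateMix":
        """Build from ``{label: (sequence, copies)}``."""
        return cls(tuple(TemplateEntry(k, s, c) for k, (s, c) in items.items()))

    @property
    def total_copies(self) -> float:
        return sum(e.copies for e in self.entries)


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions.

    Defaults mirror the study conditions: 3 technical replicates, Gaussian
    technical noise of 0.1 cycles, a 40-cycle program, 100% per-cycle
    efficiency, and a calibration Ct of 20 for one relative template unit.
    """

    seed: int = 0
    noise_sd: float = 0.1
    ct_calibration: float = 20.0
    penalty_model: PenaltyModel = field(default_factory=PenaltyModel)
    replicates: int = 3
    efficiency: float = 1.0
    max_cycles: float = 40.0
    background_ct: float | None = None  # optional self-amplification floor

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValidationError("per-cycle efficiency must lie in (0, 1]")
        if self.replicates < 1:
            raise ValidationError("at least one replicate is required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def assay_penalty(assay: PrimerAssay, template: str, model: PenaltyModel) -> float | None:
    """Total initiation delay of an assay on one template, capped at the
    model's maximum; None if any watching primer cannot anchor (the template
    is non-amplifiable in the watch channel)."""
    total = 0.0
    for p in assay.watching_primers:
        prof = mismatch_profile(p, template)
        if not prof.anchored:
            return None
        total += penalty(prof, model)
    return min(total, model.max_penalty)


def simulate_ct(mix: TemplateMix, assay: PrimerAssay, config: SimConfig, *,
                sample_id: str = "sample",
                rng: np.random.Generator | None = None) -> CtTable:
    """Simulate watch and ref channel Ct values for one sample.

    Refuses proofreading-polymerase penalty models: the whole method rests on
    Taq's inability to extend a 3' mismatch.
    """
    if config.penalty_model.high_fidelity:
        raise HighFidelityModeError(
            "high-fidelity (proofreading) polymerase models erase 3'-mismatch "
            "discrimination; getPCR simulation refuses them"
        )
    if rng is None:
        rng = config.rng()
    base = 1.0 + config.efficiency

    q_watch = 0.0
    for entry in mix.entries:
        pen = assay_penalty(assay, entry.sequence, config.penalty_model)
        if pen is not None:
            q_watch += entry.copies * 2.0 ** (-pen)
    if config.background_ct is not None:
        q_watch += base ** (config.ct_calibration - config.background_ct)
    q_ref = mix.total_copies

    records = []
    for channel, q in ((WATCH, q_watch), (REF, q_ref)):
        ct0 = math.inf if q <= 0 else config.ct_calibration - math.log(q, base)
        for rep in range(1, config.replicates + 1):
            ct = ct0 + rng.normal(0.0, config.noise_sd) if math.isfinite(ct0) else math.inf
            records.append({
                "sample_id": sample_id,
                "assay_id": assay.assay_id,
                "channel": channel,
                "replicate": rep,
                "ct": float("nan") if ct > config.max_cycles else float(ct),
            })
    return CtTable.from_records(records)


# ---------------------------------------------------------------------------
# synthetic loci

def synthetic_locus(seed: int = 0, *, length: int = 2000,
                    locus_id: str = "synthetic_locus",
                    cut_triplet: str | None = None,
                    protospacer_preset: Mapping[int, str] | None = None
                    ) -> tuple[TargetLocus, GuideTarget]:
    """A random locus with a unique, centrally placed + strand guide.

    The protospacer is read from the generated sequence at the centre and an
    AGG PAM is written immediately 3' of it.  ``cut_triplet`` optionally fixes
    the three bases at ``cut_index .. cut_index+2`` (the protospacer's last
    three nucleotides), which test fixtures use to control mismatch registers;
    ``protospacer_preset`` fixes arbitrary protospacer offsets (0-based within
    the 20-mer), e.g. ``{4: "C", 5: "C"}`` to place target cytosines at guide
    positions 5 and 6 for base-editing scenarios.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(100):
        seq = list(rng.choice(bases, size=length))
        start = length // 2 - 10
        seq[start + 20: start + 23] = list("AGG")
        if cut_triplet is not None:
            if len(cut_triplet) != 3:
                raise ValidationError("cut_triplet must be 3 nt")
            seq[start + 17: start + 20] = list(cut_triplet)
        if protospacer_preset is not None:
            for off, base in protospacer_preset.items():
                if not 0 <= off < 20:
                    raise ValidationError("preset offsets must lie inside the protospacer")
                seq[start + off] = base
        sequence = "".join(seq)
        protospacer = sequence[start: start + 20]
        locus = TargetLocus(locus_id, sequence)
        try:
            guide = locate_cut_site(locus, protospacer, "NGG")
        except ValidationError:
            continue
        if guide.strand == "+" and guide.protospacer_start == start:
            return locus, guide
    raise RuntimeError("failed to synthesize a locus with a unique guide")


# ---------------------------------------------------------------------------
# strategy sets and experiment generators

def standard_strategy_set(locus: TargetLocus, guide: GuideTarget, *,
                          tm_target_c: float = 65.0) -> dict[str, PrimerAssay]:
    """The twelve watching-primer strategies used for mixture quantification:
    single forward and single reverse primers with w = 3, 4, 5 and the two
    best-ranked combined pairs for each split of 4 total watching bases."""
    control = design_control_amplicon(locus, guide, tm_target_c)
    assays: dict[str, PrimerAssay] = {}

    for mode, tag in (("single_forward", "F"), ("single_reverse", "R")):
        ranked = design_watching_primers(locus, guide, mode, tm_target_c)
        for w in (3, 4, 5):
            cands = [p for p in ranked if p.watching_bases == w]
            if not cands:
                continue
            watch = cands[0]
            partner = design_partner(locus, watch, guide.cut_index, tm_target_c)
            name = f"{tag}+{w}"
            assays[name] = build_assay(
                name, mode,
                watch_forward=watch if mode == "single_forward" else None,
                watch_reverse=watch if mode == "single_reverse" else None,
                partner=partner, control=control)

    for wf in (1, 2, 3):
        wr = 4 - wf
        fwd = sorted(_watch_candidates(locus, guide.cut_index, "forward", wf,
                                       tm_target_c, 2.0, 0.05),
                     key=lambda p: _rank_key(p, tm_target_c))
        rev = sorted(_watch_candidates(locus, guide.cut_index, "reverse", wr,
                                       tm_target_c, 2.0, 0.05),
                     key=lambda p: _rank_key(p, tm_target_c))
        for rank in (0, 1):
            if len(fwd) <= rank or len(rev) <= rank:
                continue
            f, r = fwd[rank], rev[rank]
            name = f"F+{wf}/R+{wr}" + ("" if rank == 0 else "b")
            flags = ()
            if check_background(f, r).risk == "high":
                flags = ("background_risk",)
            assays[name] = build_assay(name, "combined", watch_forward=f,
                                       watch_reverse=r, control=control,
                                       flags=flags)
    return assays


def select_discriminating_assays(assays: Mapping[str, PrimerAssay],
                                 wild_template: str,
                                 edited_templates: Sequence[str],
                                 model: PenaltyModel, *,
                                 min_delta_ct: float = 8.0
                                 ) -> dict[str, PrimerAssay]:
    """Screen candidate assays by predicted worst-case discrimination.

    Keeps assays whose minimum predicted Ct shift across the edited templates
    is at least ``min_delta_ct`` cycles (8 cycles ~ 0.4% residual signal) —
    the design-time counterpart of choosing primers with adequate selectivity
    before quantifying.  Falls back to the full set if nothing passes.
    """
    from .mismatch import assay_discrimination

    kept = {}
    for name, assay in assays.items():
        deltas = assay_discrimination(list(assay.watching_primers), wild_template,
                                      list(edited_templates), model)
        if min(deltas) >= min_delta_ct:
            kept[name] = assay
    return kept or dict(assays)


def generate_mixture_experiment(locus: TargetLocus, guide: GuideTarget,
                                fractions: Sequence[float], config: SimConfig, *,
                                assays: Mapping[str, PrimerAssay] | None = None
                                ) -> tuple[CtTable, dict]:
    """Blends of the 26-spec mimic panel with wild template at the requested
    indel fractions, plus a 100%-wild control sample, measured by every assay
    in the strategy set.  Returns the Ct table and a truth record
    ``{"samples": {sample_id: true_indel_fraction}, ...}``."""
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"indel fraction {f} outside [0, 1]")
    if assays is None:
        assays = standard_strategy_set(locus, guide)
    panel = apply_panel(locus, mimic_panel(locus, guide))
    rng = config.rng()

    def mix_for(fraction: float) -> TemplateMix:
        items: dict[str, tuple[str, float]] = {}
        if fraction < 1.0:
            items["wild"] = (locus.sequence, 1.0 - fraction)
        if fraction > 0.0:
            per = fraction / len(panel)
            for label, seq in panel.items():
                items[label] = (seq, per)
        return TemplateMix.of(items)

    samples = {"wild_control": 0.0}
    for f in fractions:
        samples[f"mix_{round(f * 100):03d}pct"] = float(f)

    tables = []
    for sample_id, f in samples.items():
        mix = mix_for(f)
        for assay in assays.values():
            tables.append(simulate_ct(mix, assay, config,
                                      sample_id=sample_id, rng=rng))
    truth = {
        "kind": "mixture",
        "control_sample": "wild_control",
        "samples": {s: f for s, f in samples.items() if s != "wild_control"},
        "assays": sorted(assays),
    }
    return CtTable.concat(tables), truth


def generate_clone_panel(locus: TargetLocus, ploidy: int,
                         clone_specs: Sequence[Sequence[str]],
                         assays: Mapping[str, PrimerAssay],
                         templates: Mapping[str, str],
                         config: SimConfig, *,
                         edited_labels: frozenset[str] | set[str] | None = None,
                         include_standards: bool = True) -> tuple[CtTable, dict]:
    """Single-cell clone panel: each clone assigns one allele state label to
    each of its P alleles; template copies are proportional to allele counts.

    ``templates`` maps labels to full template sequences; ``edited_labels``
    marks which labels count toward the edited-allele number k (default: all
    labels except ``"wild"``).  With ``include_standards`` the output also
    carries a 100%-wild control and a pure standard sample per non-wild label
    (``std_<label>``), ready for DDCt quantification.
    """
    if edited_labels is None:
        edited_labels = set(templates) - {"wild"}
    if "wild" not in templates:
        raise ValidationError("templates must include a 'wild' entry")
    rng = config.rng()

    sample_mixes: dict[str, TemplateMix] = {}
    truth_k: dict[str, int] = {}
    for i, spec in enumerate(clone_specs):
        if len(spec) != ploidy:
            raise ValidationError(
                f"clone {i + 1} assigns {len(spec)} alleles but ploidy is {ploidy}"
            )
        unknown = set(spec) - set(templates)
        if unknown:
            raise ValidationError(f"clone {i + 1} uses unknown label(s) {sorted(unknown)}")
        cid = f"clone_{i + 1:02d}"
        counts: dict[str, int] = {}
        for label in spec:
            counts[label] = counts.get(label, 0) + 1
        sample_mixes[cid] = TemplateMix.of(
            {lab: (templates[lab], n / ploidy) for lab, n in counts.items()})
        truth_k[cid] = sum(n for lab, n in counts.items() if lab in edited_labels)

    if include_standards:
        sample_mixes["wild_control"] = TemplateMix.of({"wild": (templates["wild"], 1.0)})
        for label in sorted(set(templates) - {"wild"}):
            sample_mixes[f"std_{label}"] = TemplateMix.of(
                {label: (templates[label], 1.0)})

    tables = []
    for sample_id, mix in sample_mixes.items():
        for assay in assays.values():
            tables.append(simulate_ct(mix, assay, config,
                                      sample_id=sample_id, rng=rng))
    truth = {
        "kind": "clone_panel",
        "ploidy": ploidy,
        "edited_allele_counts": truth_k,
        "assays": sorted(assays),
    }
    return CtTable.concat(tables), truth


def generate_variant_pool(locus: TargetLocus, variant: EditSpec | Sequence[EditSpec],
                          variant_fraction: float,
                          assays: Mapping[str, PrimerAssay],
                          config: SimConfig, *,
                          sample_id: str = "pool") -> tuple[CtTable, dict]:
    """An allele pool in which ``variant_fraction`` of templates carry the
    substitution(s) (an HDR or base-editing outcome), plus a 100%-variant
    standard sample for DDCt normalization."""
    if not 0.0 <= variant_fraction <= 1.0:
        raise ValidationError("variant fraction must lie in [0, 1]")
    specs = [variant] if isinstance(variant, EditSpec) else list(variant)
    edited = locus.sequence
    for v in specs:
        edited = edited[: v.position] + v.payload + edited[v.end:]
    rng = config.rng()

    items: dict[str, tuple[str, float]] = {}
    if variant_fraction < 1.0:
        items["wild"] = (locus.sequence, 1.0 - variant_fraction)
    if variant_fraction > 0.0:
        items["variant"] = (edited, variant_fraction)
    mixes = {
        sample_id: TemplateMix.of(items),
        "variant_standard": TemplateMix.of({"variant": (edited, 1.0)}),
    }
    tables = []
    for sid, mix in mixes.items():
        for assay in assays.values():
            tables.append(simulate_ct(mix, assay, config, sample_id=sid, rng=rng))
    truth = {"kind": "variant_pool", "standard_sample": "variant_standard",
             "samples": {sample_id: variant_fraction}, "assays": sorted(assays)}
    return CtTable.concat(tables), truth


def generate_copy_number_experiment(gene_copies: int, reference_copies: int,
                                    config: SimConfig) -> tuple[CtTable, dict]:
    """qPCR of a gene amplicon versus a single-copy-reference amplicon from
    one genome at the stated copy ratio (gene assay id ``gene_cn``, reference
    assay id ``ref_cn``)."""
    if gene_copies < 1 or reference_copies < 1:
        raise ValidationError("copy numbers must be >= 1")
    rng = config.rng()
    base = 1.0 + config.efficiency
    records = []
    for assay_id, copies in (("gene_cn", gene_copies), ("ref_cn", reference_copies)):
        ct0 = config.ct_calibration - math.log(copies, base)
        for rep in range(1, config.replicates + 1):
            ct = ct0 + rng.normal(0.0, config.noise_sd)
            records.append({
                "sample_id": "genome", "assay_id": assay_id, "channel": WATCH,
                "replicate": rep,
                "ct": float("nan") if ct > config.max_cycles else float(ct),
            })
    truth = {"kind": "copy_number", "gene_copies": gene_copies,
             "reference_copies": reference_copies}
    return CtTable.from_records(records), truth
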