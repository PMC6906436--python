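"""Simulator determinism, Ct arithmetic, linearity and end-to-end recovery."""

import math

import numpy as np
import pytest
from scipy import stats

from getpcr import (
    EditSpec,
    PenaltyModel,
    SimConfig,
    TemplateMix,
    build_assay,
    call_genotype,
    design_combined_pair,
    design_variant_primers,
    generate_clone_panel,
    generate_copy_number_experiment,
    generate_mixture_experiment,
    generate_variant_pool,
    genome_copies_from_ng,
    simulate_ct,
    standard_strategy_set,
    synthetic_locus,
    variant_fraction,
    wild_fraction,
)
from getpcr.errors import ValidationError
from getpcr.qpcrsim import assay_penalty


@pytest.fixture(scope="module")
def combined_assay(locus_guide):
    locus, guide = locus_guide
    from getpcr import design_control_amplicon
    pair = design_combined_pair(locus, guide)
    ctrl = design_control_amplicon(locus, guide)
    return build_assay("combined", "combined", watch_forward=pair.forward,
                       watch_reverse=pair.reverse, control=ctrl)


@pytest.fixture(scope="module")
def locus_guide():
    return synthetic_locus(1, cut_triplet="ACG")


def wild_mix(locus, copies=1.0):
    return TemplateMix.of({"wild": (locus.sequence, copies)})


class TestSimulateCt:
    def test_matched_primer_unit_copies_hits_calibration(self, locus_guide, combined_assay):
        locus, _ = locus_guide
        cfg = SimConfig(seed=1, noise_sd=0.0)
        ct = simulate_ct(wild_mix(locus), combined_assay, cfg)
        watch = ct.cts("watch")
        assert np.allclose(watch, cfg.ct_calibration)

    def test_halving_copies_raises_ct_by_one(self, locus_guide, combined_assay):
        locus, _ = locus_guide
        cfg = SimConfig(seed=1, noise_sd=0.0)
        full = simulate_ct(wild_mix(locus, 1.0), combined_assay, cfg).cts("watch")[0]
        half = simulate_ct(wild_mix(locus, 0.5), combined_assay, cfg).cts("watch")[0]
        assert half - full == pytest.approx(1.0, abs=1e-9)

    def test_fifty_fifty_mix_with_penalty_ten(self, locus_guide, combined_assay):
        """Q = 0.5 + 0.5 * 2^-10 = 0.500488 relative units."""
        locus, guide = locus_guide
        # an edited template whose combined penalty is exactly the cap is not
        # what we want; use a synthetic template score by patching the model
        cfg = SimConfig(seed=1, noise_sd=0.0,
                        penalty_model=PenaltyModel(w_pos={0: 10.0}, w_base={
                            "A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
                            adjacency_distance=0, max_penalty=10.0))
        from getpcr import apply_edit
        edited = apply_edit(locus, EditSpec("insertion", guide.cut_index, "T"))
        mix = TemplateMix.of({"wild": (locus.sequence, 0.5), "ins": (edited, 0.5)})
        ct = simulate_ct(mix, combined_assay, cfg).cts("watch")[0]
        assert ct - cfg.ct_calibration == pytest.approx(
            -math.log2(0.5 + 0.5 * 2 ** -10), abs=1e-6)

    def test_determinism_bit_identical(self, locus_guide, combined_assay):
        locus, _ = locus_guide
        cfg = SimConfig(seed=42, noise_sd=0.3)
        a = simulate_ct(wild_mix(locus), combined_assay, cfg).df
        b = simulate_ct(wild_mix(locus), combined_assay, cfg).df
        assert a.equals(b)

    def test_censoring_beyond_cycle_40(self, locus_guide, combined_assay):
        locus, _ = locus_guide
        cfg = SimConfig(seed=1, noise_sd=0.0)
        ct = simulate_ct(wild_mix(locus, 2.0 ** -25), combined_assay, cfg)
        assert np.isnan(ct.cts("watch")).all()  # Ct would be 45
        assert np.isnan(ct.cts("ref")).all()

    def test_empty_mix_rejected(self):
        with pytest.raises(ValidationError):
            TemplateMix(())

    def test_log2_linearity_of_dilution_series(self, locus_guide, combined_assay):
        """Ct vs log2(copies) over a 2^10 series: R^2 > 0.999 at noise 0.1."""
        locus, _ = locus_guide
        cfg = SimConfig(seed=9, noise_sd=0.1, replicates=3)
        rng = cfg.rng()
        xs, ys = [], []
        for dilution in range(11):
            copies = 2.0 ** -dilution
            ct = simulate_ct(wild_mix(locus, copies), combined_assay, cfg, rng=rng)
            for v in ct.cts("watch"):
                xs.append(-dilution)
                ys.append(v)
        r = stats.pearsonr(xs, ys)[0]
        assert r ** 2 > 0.999


class TestMixtureExperiment:
    def test_fig4_design_shape(self, locus_guide):
        locus, guide = locus_guide
        cfg = SimConfig(seed=4, noise_sd=0.1)
        assays = standard_strategy_set(locus, guide)
        assert len(assays) == 12
        fractions = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ct, truth = generate_mixture_experiment(locus, guide, fractions, cfg,
                                                assays=assays)
        assert len(truth["samples"]) == 6
        for sample in list(truth["samples"]) + ["wild_control"]:
            for assay in assays:
                sl = ct.select(sample, assay)
                assert sorted(set(sl.df["channel"])) == ["ref", "watch"]
                assert len(sl) == 6  # 3 replicates x 2 channels

    def test_zero_fraction_gives_zero_ddct(self, locus_guide):
        locus, guide = locus_guide
        cfg = SimConfig(seed=4, noise_sd=0.0)
        ct, truth = generate_mixture_experiment(locus, guide, [0.0], cfg)
        for assay in truth["assays"]:
            est = wild_fraction(ct.select("mix_000pct", assay),
                                ct.select("wild_control", assay))
            assert abs(est.delta_delta_ct) < 1e-9

    def test_full_indel_fraction_matches_penalty_arithmetic(self, locus_guide):
        """At 100% indel the watch Ct equals the closed form
        cal - log2(sum_t copies_t 2^-penalty_t) and sits far above the
        calibration (strong suppression of every panel template)."""
        from getpcr import apply_panel, mimic_panel
        locus, guide = locus_guide
        cfg = SimConfig(seed=4, noise_sd=0.0)
        assays = standard_strategy_set(locus, guide)
        name = "F+2/R+2"
        assay = assays[name]
        ct, _ = generate_mixture_experiment(locus, guide, [1.0], cfg,
                                            assays={name: assay})
        watch = ct.select("mix_100pct", name).cts("watch")
        panel = apply_panel(locus, mimic_panel(locus, guide))
        q = 0.0
        for seq in panel.values():
            pen = assay_penalty(assay, seq, cfg.penalty_model)
            if pen is not None:
                q += 2.0 ** (-pen) / len(panel)
        expected = cfg.ct_calibration - math.log2(q)
        assert np.allclose(watch, expected)
        assert np.all(watch >= cfg.ct_calibration + 8.0)

    def test_recovery_within_two_points_midrange(self, locus_guide):
        """Strategy-averaged recovery of 20-80% blends within +/-0.02."""
        locus, guide = locus_guide
        cfg = SimConfig(seed=6, noise_sd=0.1)
        assays = standard_strategy_set(locus, guide)
        fractions = (0.2, 0.4, 0.6, 0.8)
        ct, truth = generate_mixture_experiment(locus, guide, fractions, cfg,
                                                assays=assays)
        for sample, true_f in truth["samples"].items():
            ests = [wild_fraction(ct.select(sample, a),
                                  ct.select("wild_control", a)).edit_frequency
                    for a in assays]
            assert np.mean(ests) == pytest.approx(true_f, abs=0.02)

    def test_low_frequency_accuracy_degrades(self, locus_guide):
        """Relative error grows as the true indel fraction drops below 10%."""
        locus, guide = locus_guide
        cfg = SimConfig(seed=6, noise_sd=0.1)
        assays = standard_strategy_set(locus, guide)
        ct, truth = generate_mixture_experiment(locus, guide, (0.05, 0.4), cfg,
                                                assays=assays)
        rel = {}
        for sample, true_f in truth["samples"].items():
            ests = [wild_fraction(ct.select(sample, a),
                                  ct.select("wild_control", a)).edit_frequency
                    for a in assays]
            rel[true_f] = np.mean(np.abs(np.array(ests) - true_f)) / true_f
        assert rel[0.05] > rel[0.4]


class TestClonePanelAndCopyNumber:
    def test_triploid_clone_fractions_cluster_at_thirds(self, locus_guide):
        locus, guide = locus_guide
        pos = next(guide.protospacer_start + i for i in range(3, 12)
                   if locus.sequence[guide.protospacer_start + i] != "T")
        var = EditSpec("substitution", pos, "T", label="c2t")
        from getpcr import apply_edit, design_control_amplicon
        edited = apply_edit(locus, var)
        ctrl = design_control_amplicon(locus, guide)
        prim = design_variant_primers(locus, var, "auto")[0]
        assay = build_assay("var", "variant",
                            watch_forward=prim if prim.orientation == "forward" else None,
                            watch_reverse=prim if prim.orientation == "reverse" else None,
                            control=ctrl)
        cfg = SimConfig(seed=13, noise_sd=0.1)
        specs = [("wild", "wild", "edited"), ("wild", "edited", "edited"),
                 ("edited", "edited", "edited"), ("wild", "wild", "wild")]
        ct, truth = generate_clone_panel(locus, 3, specs, {"var": assay},
                                         {"wild": locus.sequence, "edited": edited},
                                         cfg)
        for clone, k in truth["edited_allele_counts"].items():
            est = variant_fraction(ct.select(clone, "var"),
                                   ct.select("std_edited", "var"))
            call = call_genotype(min(1.0, est.fraction), est.sem, 3)
            assert call.edited_allele_count == k
            # single-clone DDCt estimates carry ~8% relative noise at
            # noise_sd 0.1 with 3 replicates; 0.1 is a ~1.2 sigma band
            assert est.fraction == pytest.approx(k / 3, abs=0.1)

    def test_genotype_recovery_200_random_clones(self, locus_guide):
        """200 random clones at P in {2,3,4}, noise 0.1, 3 replicates:
        correct k throughout, and any near-boundary call is at least flagged
        ambiguous rather than confidently wrong."""
        locus, guide = locus_guide
        from getpcr import apply_edit, design_control_amplicon
        ins = EditSpec("insertion", guide.cut_index, "T")
        edited = apply_edit(locus, ins)
        ctrl = design_control_amplicon(locus, guide)
        pair = design_combined_pair(locus, guide)
        assay = build_assay("watch", "combined", watch_forward=pair.forward,
                            watch_reverse=pair.reverse, control=ctrl)
        rng = np.random.default_rng(77)
        wrong_confident = 0
        correct = 0
        total = 0
        for ploidy in (2, 3, 4):
            n_clones = 67 if ploidy > 2 else 66
            ks = rng.integers(0, ploidy + 1, size=n_clones)
            specs = [tuple(["edited"] * k + ["wild"] * (ploidy - k)) for k in ks]
            cfg = SimConfig(seed=1000 + ploidy, noise_sd=0.1)
            ct, truth = generate_clone_panel(locus, ploidy, specs, {"watch": assay},
                                             {"wild": locus.sequence, "edited": edited},
                                             cfg)
            for clone, k in truth["edited_allele_counts"].items():
                est = wild_fraction(ct.select(clone, "watch"),
                                    ct.select("wild_control", "watch"))
                call = call_genotype(est.edit_frequency, est.sem, ploidy)
                total += 1
                if call.edited_allele_count == k:
                    correct += 1
                elif not call.ambiguous:
                    wrong_confident += 1
        assert total == 200
        assert wrong_confident == 0
        assert correct / total >= 0.99

    @pytest.mark.parametrize("copies", [3, 4])
    def test_copy_number_recovered(self, copies):
        cfg = SimConfig(seed=21, noise_sd=0.1)
        ct, truth = generate_copy_number_experiment(copies, 1, cfg)
        from getpcr import estimate_copy_number
        est = estimate_copy_number(ct.select(assay_id="gene_cn"),
                                   ct.select(assay_id="ref_cn"))
        assert est.called_copies == copies

    def test_noise_free_copy_number_exact_one_to_six(self):
        from getpcr import estimate_copy_number
        for copies in range(1, 7):
            cfg = SimConfig(seed=1, noise_sd=0.0)
            ct, _ = generate_copy_number_experiment(copies, 1, cfg)
            est = estimate_copy_number(ct.select(assay_id="gene_cn"),
                                       ct.select(assay_id="ref_cn"))
            assert est.raw_copies == pytest.approx(copies, abs=1e-9)

    def test_copy_number_delta_ct_values(self):
        cfg = SimConfig(seed=1, noise_sd=0.0)
        for copies, dct in ((3, -math.log2(3)), (4, -2.0), (1, 0.0)):
            ct, _ = generate_copy_number_experiment(copies, 1, cfg)
            gene = ct.select(assay_id="gene_cn").cts().mean()
            ref = ct.select(assay_id="ref_cn").cts().mean()
            assert gene - ref == pytest.approx(dct, abs=1e-9)


class TestVariantPool:
    def test_quarter_variant_pool_recovered(self, locus_guide):
        locus, guide = locus_guide
        from getpcr import design_control_amplicon
        pos = next(guide.protospacer_start + i for i in range(3, 12)
                   if locus.sequence[guide.protospacer_start + i] != "T")
        var = EditSpec("substitution", pos, "T", label="hdr")
        ctrl = design_control_amplicon(locus, guide)
        assays = {}
        for d in ("forward", "reverse"):
            p = design_variant_primers(locus, var, d)[0]
            assays[d] = build_assay(d, "variant",
                                    watch_forward=p if d == "forward" else None,
                                    watch_reverse=p if d == "reverse" else None,
                                    control=ctrl)
        cfg = SimConfig(seed=8, noise_sd=0.1)
        ct, truth = generate_variant_pool(locus, var, 0.25, assays, cfg)
        vals = [variant_fraction(ct.select("pool", a),
                                 ct.select("variant_standard", a)).variant_fraction
                for a in assays]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.03)


def test_genome_copies_from_ng_standard_constant():
    assert genome_copies_from_ng(10.0) == pytest.approx(10000 / 3.3)
    with pytest.raises(ValidationError):
        genome_copies_from_ng(0.0)
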