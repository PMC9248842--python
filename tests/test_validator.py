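import numpy as np
import pytest

import registercheck as rc
from registercheck.assignment import AssignmentResult
from registercheck.model_io import ProteinChain, Residue
from registercheck.synthetic import (SyntheticSpec, build_helix_model,
                                     generate_profiles, profile_from_sequence,
                                     random_sequence)
from registercheck.validator import (ChainResult, OutcomeClass,
                                     ValidationConfig, adaptive_scan,
                                     calibrate_threshold,
                                     chain_alignment_offset, classify_outcome,
                                     detect_numbering_issues,
                                     detect_sequence_mismatches, merge_regions,
                                     validate_chain)

CFG = ValidationConfig(n_null=100)


def make_chain(model_sequence, backbone_sequence=None):
    """Helical chain recording ``model_sequence``; geometry is helical."""
    model = build_helix_model(backbone_sequence or model_sequence)
    return model.to_chain(model_sequence=model_sequence)


def scan_synthetic(seed, shift=0, span=None, length=120, accuracy=0.6,
                   config=CFG):
    spec = SyntheticSpec(seed=seed, chain_length=length, top1_accuracy=accuracy,
                         shift_offset=shift, shift_span=span)
    reference, density_seq, profile = generate_profiles(spec)
    chain = make_chain(reference, backbone_sequence=density_seq)
    rng = np.random.default_rng(seed + 10_000)
    results = adaptive_scan(chain, reference, profile, config, rng=rng)
    return chain, reference, results


class TestClassifyOutcome:
    def _result(self, p, agrees):
        return AssignmentResult(
            chain_id="A", reference_id="r", fragment_start=0, fragment_length=20,
            model_sequence="A" * 20, offset=0, score=-1.0, p_value=p,
            assigned_sequence="A" * 20 if agrees else "C" * 20)

    def test_confident_agreement_confirmed(self):
        assert classify_outcome(self._result(1e-8, True), 1e-3) == OutcomeClass.CONFIRMED

    def test_confident_disagreement_is_register_error(self):
        assert classify_outcome(self._result(1e-8, False), 1e-3) == OutcomeClass.REGISTER_ERROR

    def test_high_p_is_inconclusive_regardless_of_agreement(self):
        assert classify_outcome(self._result(0.5, True), 1e-3) == OutcomeClass.INCONCLUSIVE
        assert classify_outcome(self._result(0.5, False), 1e-3) == OutcomeClass.INCONCLUSIVE

    def test_no_reference(self):
        assert classify_outcome(None, 1e-3, has_reference=False) == OutcomeClass.NO_REFERENCE


class TestChainAlignment:
    def test_exact_match_offset_zero(self):
        ref = random_sequence(np.random.default_rng(0), 80)
        assert chain_alignment_offset(ref, ref) == 0

    def test_embedded_chain(self):
        rng = np.random.default_rng(1)
        ref = random_sequence(rng, 120)
        assert chain_alignment_offset(ref[30:90], ref) == 30

    def test_shifted_span_does_not_move_global_alignment(self):
        rng = np.random.default_rng(2)
        ref = random_sequence(rng, 150)
        model = rc.inject_register_shift(ref, ref, 7, (60, 85))
        assert chain_alignment_offset(model, ref) == 0


class TestAdaptiveScan:
    def test_high_accuracy_resolves_all_at_base_length(self):
        _, _, results = scan_synthetic(seed=1, accuracy=0.9)
        assert all(r.fragment_length == 20 for r in results)
        assert all(r.p_value <= CFG.p_threshold for r in results)

    def test_low_accuracy_extends_windows(self):
        _, _, results = scan_synthetic(seed=2, accuracy=0.08)
        assert sum(r.fragment_length > 20 for r in results) > len(results) / 2

    def test_extension_clipped_at_short_segment(self):
        spec = SyntheticSpec(seed=3, chain_length=25, top1_accuracy=0.08)
        reference, density_seq, profile = generate_profiles(spec)
        chain = make_chain(reference, backbone_sequence=density_seq)
        results = adaptive_scan(chain, reference, profile,
                                ValidationConfig(n_null=100, seed=3))
        assert all(r.fragment_length <= 25 for r in results)
        assert any(r.fragment_length == 25 for r in results)

    def test_every_window_gets_exactly_one_outcome(self):
        _, _, results = scan_synthetic(seed=4, accuracy=0.5)
        counts = {c: 0 for c in OutcomeClass}
        for r in results:
            counts[classify_outcome(r, CFG.p_threshold)] += 1
        assert sum(counts.values()) == len(results)


class TestMergeRegions:
    def test_consecutive_same_shift_merge(self):
        chain, ref, results = scan_synthetic(seed=5, shift=8, span=(40, 80),
                                             length=160)
        regions = merge_regions(results, chain, CFG)
        shifted = [g for g in regions if g.suggested_shift == 8]
        assert len(shifted) == 1
        g = shifted[0]
        # region boundaries in author numbering (helix numbered from 1)
        assert g.first_residue_number <= 41 + 20
        assert g.last_residue_number >= 80 - 20
        assert g.issue_type == "register_shift"
        assert g.suggested_sequence is not None

    def test_differing_shifts_stay_separate(self):
        rng = np.random.default_rng(6)
        ref = random_sequence(rng, 200)
        density = rc.inject_register_shift(ref, ref, 8, (30, 60))
        density = rc.inject_register_shift(density, ref, -3, (130, 160))
        profile = profile_from_sequence(density, 0.6, rng)
        chain = make_chain(ref, backbone_sequence=density)
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(60))
        regions = merge_regions(results, chain, CFG)
        shifts = sorted(g.suggested_shift for g in regions)
        assert shifts == [-3, 8]

    def test_clean_chain_yields_no_regions(self):
        chain, ref, results = scan_synthetic(seed=7)
        assert merge_regions(results, chain, CFG) == []


class TestSequenceMismatches:
    def test_single_substitution_reported(self):
        rng = np.random.default_rng(8)
        ref = random_sequence(rng, 60)
        # model records T where the reference (and the density) has Y
        pos = 30
        ref = ref[:pos] + "Y" + ref[pos + 1:]
        model_seq = ref[:pos] + "T" + ref[pos + 1:]
        profile = profile_from_sequence(ref, 0.8, rng)
        chain = make_chain(model_seq, backbone_sequence=ref)
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(80))
        mismatches = detect_sequence_mismatches(results, chain, CFG)
        assert len(mismatches) == 1
        m = mismatches[0]
        assert m.first_residue_number == pos + 1
        assert m.suggested_sequence == "Y"
        assert merge_regions(results, chain, CFG) == []

    def test_identical_sequences_give_none(self):
        chain, ref, results = scan_synthetic(seed=9, accuracy=0.8)
        assert detect_sequence_mismatches(results, chain, CFG) == []

    def test_contiguous_run_is_not_a_mismatch(self):
        rng = np.random.default_rng(10)
        ref = random_sequence(rng, 60)
        # three contiguous differing letters at the model's own register
        replacement = "".join("A" if c != "A" else "C" for c in ref[28:31])
        model_seq = ref[:28] + replacement + ref[31:]
        profile = profile_from_sequence(ref, 0.8, rng)
        chain = make_chain(model_seq, backbone_sequence=ref)
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(100))
        assert detect_sequence_mismatches(results, chain, CFG) == []


class TestNumberingIssues:
    def _gapped_chain(self, ref, skip=5, break_at=30):
        """Chain reading ref[:break_at] + ref[break_at+skip:] with continuous
        numbering and a physical break between the halves."""
        seq = ref[:break_at] + ref[break_at + skip:]
        model = build_helix_model(seq)
        chain = model.to_chain()
        # push the second half far away to break CA continuity
        for i in range(break_at, len(chain.residues)):
            r = chain.residues[i]
            moved = {k: v + np.array([200.0, 0, 0]) for k, v in r.backbone.items()}
            chain.residues[i] = Residue(number=r.number, insertion_code="",
                                        name=r.name, ca=moved["CA"],
                                        backbone=moved)
        return chain, seq

    def test_continuous_numbering_across_gap_flagged(self):
        rng = np.random.default_rng(11)
        ref = random_sequence(rng, 100)
        chain, seq = self._gapped_chain(ref, skip=5)
        profile = profile_from_sequence(seq, 0.8, rng)
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(110))
        issues = detect_numbering_issues(chain, results, CFG)
        assert len(issues) == 1
        assert issues[0].issue_type == "numbering_problem"
        assert issues[0].suggested_shift == 5

    def test_consistent_numbering_not_flagged(self):
        rng = np.random.default_rng(12)
        ref = random_sequence(rng, 100)
        chain, seq = self._gapped_chain(ref, skip=5)
        # renumber the second half to account for the 5 skipped residues
        for i in range(30, len(chain.residues)):
            r = chain.residues[i]
            chain.residues[i] = Residue(number=r.number + 5, insertion_code="",
                                        name=r.name, ca=r.ca, backbone=r.backbone)
        profile = profile_from_sequence(seq, 0.8, rng)
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(120))
        assert detect_numbering_issues(chain, results, CFG) == []

    def test_inconclusive_flanks_not_reported(self):
        rng = np.random.default_rng(13)
        ref = random_sequence(rng, 100)
        chain, seq = self._gapped_chain(ref, skip=5)
        profile = profile_from_sequence(seq, 0.07, rng)  # too noisy to confirm
        results = adaptive_scan(chain, ref, profile, CFG,
                                rng=np.random.default_rng(130))
        confirmed = [r for r in results
                     if classify_outcome(r, CFG.p_threshold) == OutcomeClass.CONFIRMED]
        if not confirmed:  # the intended regime: nothing confident
            assert detect_numbering_issues(chain, results, CFG) == []


class TestValidateChain:
    def test_shift_recovery_end_to_end(self):
        spec = SyntheticSpec(seed=21, chain_length=200, top1_accuracy=0.6,
                             shift_offset=9, shift_span=(100, 130))
        reference, density_seq, profile = generate_profiles(spec)
        chain = make_chain(reference, backbone_sequence=density_seq)
        result = validate_chain(chain, [("ref_1", reference)], profile, CFG,
                                rng=np.random.default_rng(21))
        assert result.reference_match is not None
        shifts = [g for g in result.issues if g.issue_type == "register_shift"]
        assert any(g.suggested_shift == 9
                   and g.last_residue_number >= 101
                   and g.first_residue_number <= 130 for g in shifts)

    def test_low_standard_fraction_skipped(self):
        chain = make_chain(random_sequence(np.random.default_rng(14), 40))
        for i in range(0, len(chain.residues), 3):
            r = chain.residues[i]
            chain.residues[i] = Residue(number=r.number, insertion_code="",
                                        name="UNK", ca=r.ca, backbone=r.backbone)
        result = validate_chain(chain, [("r", "A" * 50)],
                                rc.uniform_profile(len(chain)), CFG)
        assert result.skipped_reason is not None

    def test_unidentifiable_reference_reported(self):
        rng = np.random.default_rng(15)
        chain = make_chain(random_sequence(rng, 60))
        result = validate_chain(chain, [("r", random_sequence(rng, 80))],
                                rc.uniform_profile(len(chain)), CFG,
                                rng=np.random.default_rng(150))
        assert result.reference_match is None
        assert any(i.issue_type == "no_reference" for i in result.issues)


class TestCalibrateThreshold:
    def test_quantile_of_mismatch_pvalues(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=2000)
        thr = calibrate_threshold(p, confidence=0.995)
        assert thr == pytest.approx(0.005, abs=0.005)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([]))

    def test_config_round_trip(self, tmp_path):
        cfg = ValidationConfig(window=25, p_threshold=5e-4, seed=7)
        path = tmp_path / "config.json"
        cfg.to_json(path)
        assert ValidationConfig.from_json(path) == cfg
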