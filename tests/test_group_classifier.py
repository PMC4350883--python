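"""Group rule cascade, reference refinement, consensus, global alignment."""

import numpy as np
import pytest

import wrkykit as w
from wrkykit import group_classifier as gc
from wrkykit.domain_scanner import ScanConfig
from wrkykit.errors import PreconditionError
from wrkykit.synthetic_data import load_templates


def _domains(residues, max_mm=0):
    rec = w.SequenceRecord("p", residues)
    domains, _ = w.call_wrky_domains(rec, ScanConfig(max_mismatches=max_mm))
    return rec, domains


X4_FINGER = "C" + "A" * 4 + "C" + "A" * 23 + "H" + "A" + "H"
CHC_FINGER = "C" + "A" * 5 + "C" + "A" * 23 + "H" + "AA" + "C"


class TestRuleCascade:
    def test_two_domain_protein_is_group_one(self):
        cassette = "WRKYGQK" + "GGG" + X4_FINGER
        rec, domains = _domains("LL" + cassette + "LLLL" + cassette)
        calls = w.classify_domain_rules(domains, rec.residues)
        assert [c.group for c in calls] == ["I_NT", "I_CT"]

    def test_cchc_finger_is_group_three(self):
        rec, domains = _domains("LL" + "WRKYGQK" + "GGG" + CHC_FINGER + "LL")
        (call,) = w.classify_domain_rules(domains, rec.residues)
        assert call.group == "III"
        assert call.domain.finger.pattern_class == "C2HC"

    def test_iib_diagnostics_fire_both_rules(self):
        finger = ("C" + "AAAAA" + "C" + "A" * 9 + "QVQR" + "A" * 10 + "H" + "A" + "H")
        rec, domains = _domains("LLDGC" + "WRKYGQK" + "GGG" + finger + "LL")
        (call,) = w.classify_domain_rules(domains, rec.residues)
        assert call.group == "IIb"
        assert set(call.evidence) == {"R4a", "R4b"}

    def test_single_x4_domain_reports_coarse_iic(self):
        rec, domains = _domains("LL" + "WRKYGQK" + "GGG" + X4_FINGER + "LL")
        (call,) = w.classify_domain_rules(domains, rec.residues)
        assert call.group == "IIc"

    def test_moss_signature_with_cchc_is_variant_three(self):
        rec, domains = _domains("LL" + "WKKYGNK" + "GGG" + CHC_FINGER + "LL")
        (call,) = w.classify_domain_rules(domains, rec.residues)
        assert call.group == "III_MOSS_VARIANT"

    def test_input_order_does_not_matter(self):
        cassette = "WRKYGQK" + "GGG" + X4_FINGER
        rec, domains = _domains("LL" + cassette + "LLLL" + cassette)
        fwd = w.classify_domain_rules(domains, rec.residues)
        rev = w.classify_domain_rules(list(reversed(domains)), rec.residues)
        assert [c.group for c in fwd] == [c.group for c in rev]

    def test_empty_input_rejected(self):
        with pytest.raises(PreconditionError):
            w.classify_domain_rules([])


class TestRefinement:
    def test_exact_reference_copy_has_zero_distance(self, reference_set):
        ref = next(e for e in reference_set.entries if e.group == "IId")
        rec = w.SequenceRecord("p", "LLLLLLLLLL" + ref.residues + "LLLLLLLLLL")
        domains, _ = w.call_wrky_domains(rec, ScanConfig(max_mismatches=0))
        (call,) = w.classify_domain_rules(domains, rec.residues)
        refined = w.refine_by_reference(call, reference_set)
        assert refined.group == "IId"
        assert refined.nearest_reference[1] == pytest.approx(0.0)

    def test_mutated_iie_domain_refines_to_iie(self, reference_set):
        spec = w.SynthSpec(seed=7, mutation_rate=0.05,
                           group_counts={"IIe": 10}, decoy_proteins=0)
        records, truth = w.generate_proteome(spec)
        for rec in records:
            domains, _ = w.call_wrky_domains(rec, ScanConfig(max_mismatches=1))
            (call,) = w.classify_domain_rules(domains, rec.residues)
            refined = w.refine_by_reference(call, reference_set)
            assert refined.group == "IIe"

    def test_equidistant_tie_keeps_coarse_label(self):
        seq = "WRKYGQK" + "GGG" + X4_FINGER
        rec = w.SequenceRecord("p", "LL" + seq + "LL")
        domains, _ = w.call_wrky_domains(rec, ScanConfig(max_mismatches=0))
        (call,) = w.classify_domain_rules(domains, rec.residues)
        refs = gc.ReferenceSet(
            [
                gc.ReferenceEntry("ra", "IIc", domains[0].residues),
                gc.ReferenceEntry("rb", "IId", domains[0].residues),
            ]
        )
        refined = w.refine_by_reference(call, refs)
        assert refined.group == "IIc"  # coarse label retained
        assert refined.tie_candidates is not None

    def test_unrefinable_group_rejected(self, reference_set):
        rec, domains = _domains("LL" + "WRKYGQK" + "GGG" + CHC_FINGER + "LL")
        (call,) = w.classify_domain_rules(domains, rec.residues)
        with pytest.raises(PreconditionError):
            w.refine_by_reference(call, reference_set)

    def test_refinement_accuracy_on_rule_ambiguous_groups(self, reference_set):
        """IIc/IId/IIe and IIa/IIb are rule-ambiguous; nearest-reference
        refinement must separate them at 5% mutation."""
        spec = w.SynthSpec(
            seed=8, mutation_rate=0.05, decoy_proteins=0,
            group_counts={"IIa": 20, "IIb": 20, "IIc": 20, "IId": 20, "IIe": 20},
        )
        records, truth = w.generate_proteome(spec)
        correct = total = 0
        for rec in records:
            domains, _ = w.call_wrky_domains(rec, ScanConfig(max_mismatches=1))
            (call,) = w.classify_domain_rules(domains, rec.residues)
            refined = w.refine_by_reference(call, reference_set)
            total += 1
            correct += refined.group == truth.proteins[rec.id].group
        assert correct / total >= 0.95


class TestConsensus:
    def test_identical_rows_return_the_row(self):
        rows = [w.SequenceRecord(f"r{i}", "WRKYGQK") for i in range(3)]
        assert w.consensus_sequence(rows, 0.5) == "WRKYGQK"

    def test_even_split_emits_x(self):
        rows = [w.SequenceRecord(f"r{i}", c) for i, c in enumerate("AAGG")]
        assert w.consensus_sequence(rows, 0.5) == "x"

    def test_majority_above_threshold(self):
        rows = [w.SequenceRecord(f"r{i}", c) for i, c in enumerate("AAAG")]
        assert w.consensus_sequence(rows, 0.5) == "A"

    def test_all_gap_column_is_dash(self):
        rows = [w.SequenceRecord(f"r{i}", "-A") for i in range(4)]
        assert w.consensus_sequence(rows, 0.5) == "-A"

    def test_duplication_invariance(self):
        rows = [w.SequenceRecord("a", "WRAY"), w.SequenceRecord("b", "WRKY"),
                w.SequenceRecord("c", "WRKY")]
        once = w.consensus_sequence(rows, 0.6)
        twice = w.consensus_sequence(
            rows + [w.SequenceRecord(r.id + "_2", r.residues) for r in rows], 0.6
        )
        assert once == twice


def brute_force_affine_align(a, b, table, gap_open, gap_extend):
    """Oracle: exhaustive enumeration of all global alignments with affine gaps."""
    best = [float("-inf")]

    def walk(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "m", score + table[(a[i], b[j])])
        if i < len(a):
            cost = gap_extend if prev == "d" else gap_open
            walk(i + 1, j, "d", score + cost)
        if j < len(b):
            cost = gap_extend if prev == "i" else gap_open
            walk(i, j + 1, "i", score + cost)

    walk(0, 0, None, 0.0)
    return best[0]


class TestAlignGlobal:
    def test_identity_score_is_diagonal_sum(self):
        table = gc.load_substitution_table()
        a1, a2, score = w.align_global("WRKYGQK", "WRKYGQK")
        assert a1 == a2 == "WRKYGQK"
        assert score == sum(table[(c, c)] for c in "WRKYGQK")

    def test_empty_input_rejected(self):
        with pytest.raises(PreconditionError):
            w.align_global("WRKY", "")

    def test_unknown_residue_rejected(self):
        with pytest.raises(PreconditionError):
            w.align_global("WRKB", "WRKY")  # B not in the shipped table

    def test_score_matches_exhaustive_enumeration(self):
        table = gc.load_substitution_table()
        rng = np.random.default_rng(21)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(8):
            a = "".join(rng.choice(aa, size=int(rng.integers(2, 7))))
            b = "".join(rng.choice(aa, size=int(rng.integers(2, 7))))
            _, _, score = w.align_global(a, b)
            oracle = brute_force_affine_align(a, b, table, -10.0, -1.0)
            assert score == pytest.approx(oracle)
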