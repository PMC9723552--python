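"""Alignment summaries, the 4-of-5 set-hit rule, and database screening."""

import numpy as np
import pytest

from genefishkit.errors import ParseError, ValidationError
from genefishkit.sequence_io import SequenceRecord, reverse_complement
from genefishkit.simulate import FamilySpec, make_family, random_gene
from genefishkit.specificity import (
    AlignmentSummary,
    align_probe,
    global_identity,
    longest_mismatch_stretch,
    screen,
    set_hit,
)
from genefishkit.thermo import HybridizationConditions

from _reference import semiglobal_score


class TestAlignProbe:
    def test_identical_sequences(self):
        seq = random_gene(450, 50, 0)
        s = align_probe(seq, seq)
        assert s.percent_identity == 100.0
        assert s.longest_mismatch_stretch_bp == 0
        assert s.probe_coverage == 1.0
        assert s.strand == "+"

    def test_single_central_substitution(self):
        seq = random_gene(450, 50, 1)
        target = list(seq)
        target[225] = {"A": "C", "C": "A", "G": "T", "T": "G"}[target[225]]
        s = align_probe(seq, "".join(target))
        assert s.percent_identity == pytest.approx(449 / 450 * 100, abs=1e-9)
        assert s.longest_mismatch_stretch_bp == 1

    def test_probe_found_inside_longer_target(self):
        probe = random_gene(100, 50, 2)
        target = random_gene(150, 50, 3) + probe + random_gene(150, 50, 4)
        s = align_probe(probe, target)
        assert s.percent_identity == 100.0
        assert s.score == pytest.approx(100.0)

    def test_minus_strand_target_reported(self):
        probe = random_gene(120, 50, 5)
        target = reverse_complement(random_gene(40, 50, 6) + probe + random_gene(40, 50, 7))
        s = align_probe(probe, target)
        assert s.strand == "-"
        assert s.percent_identity == 100.0

    def test_matches_independent_dp_on_random_pairs(self, rng):
        """Score equals a quadratic Gotoh reference; summary fields are
        reproducible from the reported alignment by independent bookkeeping."""
        for _ in range(60):
            lp = int(rng.integers(20, 61))
            lt = int(rng.integers(20, 81))
            probe = random_gene(lp, 50, np.random.default_rng(rng.integers(2**31)))
            target = random_gene(lt, 50, np.random.default_rng(rng.integers(2**31)))
            s = align_probe(probe, target, both_strands=False)
            oracle = semiglobal_score(probe, target)
            assert s.score == pytest.approx(oracle, abs=1e-9)

    def test_n_never_matches(self):
        s = align_probe("ANNNA", "ANNNA", both_strands=False)
        assert s.percent_identity == pytest.approx(2 / 5 * 100, abs=1e-9)
        assert s.longest_mismatch_stretch_bp == 3

    def test_non_dna_rejected(self):
        with pytest.raises(ParseError):
            align_probe("ACGU", "ACGT")

    def test_identity_symmetric_for_substitution_only_pairs(self, rng):
        for _ in range(10):
            a = random_gene(80, 50, np.random.default_rng(rng.integers(2**31)))
            b = list(a)
            for i in rng.choice(80, size=4, replace=False):
                b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
            b = "".join(b)
            assert align_probe(a, b).percent_identity == pytest.approx(
                align_probe(b, a).percent_identity, abs=1e-9
            )


class TestLongestMismatchStretch:
    @pytest.mark.parametrize(
        "cols, expected",
        [
            ([("A", "A")] * 10, 0),
            # M*10, X*3, M*5, D*4, M -> longest pooled run is 4
            ([("A", "A")] * 10 + [("A", "C")] * 3 + [("A", "A")] * 5
             + [("A", "-")] * 4 + [("A", "A")], 4),
            # M*2, X*2, D*2, X*1, M -> substitutions and gaps pool into 5
            ([("A", "A")] * 2 + [("A", "C")] * 2 + [("A", "-")] * 2
             + [("A", "G")] + [("A", "A")], 5),
        ],
    )
    def test_hand_built_traces(self, cols, expected):
        assert longest_mismatch_stretch(cols) == expected


class TestSetHit:
    @pytest.mark.parametrize(
        "identities, expected_hit, expected_n",
        [
            ([85, 83, 92, 79, 80], True, 4),
            ([79, 79, 79, 79, 79], False, 0),
            ([100, 100, 100, 50], False, 3),
        ],
    )
    def test_printed_rule(self, identities, expected_hit, expected_n):
        summaries = [
            AlignmentSummary(
                probe_id=f"p{i}", target_id="t", strand="+", score=0.0,
                percent_identity=float(x), longest_mismatch_stretch_bp=0,
                alignment_length=450, probe_coverage=1.0,
            )
            for i, x in enumerate(identities)
        ]
        hit, n = set_hit(summaries, identity_threshold=80, min_hits=4)
        assert (hit, n) == (expected_hit, expected_n)


def _probes_from(seq, k=5, length=100):
    class P:
        def __init__(self, i, s):
            self.probe_id = f"probe_{i}"
            self.sequence = s

    return [P(i + 1, seq[i * length : (i + 1) * length]) for i in range(k)]


class TestScreen:
    COND = HybridizationConditions(na_molar=0.39, fa_percent=35.0, hyb_temp_c=46.0)

    def test_self_screen_hits_and_is_detectable(self):
        gene = random_gene(500, 50, 10)
        probes = _probes_from(gene)
        db = [SequenceRecord(id="self", sequence=gene)]
        (res,) = screen(probes, db, self.COND)
        assert res.set_hit and res.n_probe_hits == 5
        assert res.implied_mismatch_percent == pytest.approx(0.0, abs=1e-9)
        assert res.predicted_detectable_at_fa

    def test_distant_homolog_misses(self):
        fam = make_family(FamilySpec(ancestor_length=500, identity_targets=(70.0,), seed=4))
        probes = _probes_from(fam.ancestor.sequence)
        db = [SequenceRecord(id="h70", sequence=fam.homologs[0].sequence)]
        (res,) = screen(probes, db, self.COND)
        assert not res.set_hit

    def test_strand_invariance(self):
        gene = random_gene(500, 50, 12)
        fam = make_family(FamilySpec(ancestor_length=500, identity_targets=(90.0,), seed=12))
        probes = _probes_from(fam.ancestor.sequence)
        fwd = [SequenceRecord(id="t", sequence=fam.homologs[0].sequence)]
        rev = [SequenceRecord(id="t", sequence=reverse_complement(fam.homologs[0].sequence))]
        (rf,) = screen(probes, fwd, self.COND)
        (rr,) = screen(probes, rev, self.COND)
        assert rf.set_hit == rr.set_hit and rf.n_probe_hits == rr.n_probe_hits
        for a, b in zip(rf.summaries, rr.summaries):
            assert a.percent_identity == pytest.approx(b.percent_identity, abs=1e-9)
            assert a.strand != b.strand

    def test_raising_threshold_never_adds_hits(self):
        fam = make_family(
            FamilySpec(ancestor_length=500, identity_targets=(95.0, 85.0, 75.0), seed=3)
        )
        probes = _probes_from(fam.ancestor.sequence)
        db = [SequenceRecord(id=h.id, sequence=h.sequence) for h in fam.homologs]
        hits = []
        for thr in (70.0, 80.0, 90.0, 99.0):
            res = screen(probes, db, self.COND, identity_threshold=thr)
            hits.append(sum(r.set_hit for r in res))
        assert all(a >= b for a, b in zip(hits, hits[1:]))

    def test_detectability_monotone_in_fa(self):
        fam = make_family(FamilySpec(ancestor_length=500, identity_targets=(90.0,), seed=8))
        probes = _probes_from(fam.ancestor.sequence)
        db = [SequenceRecord(id="h", sequence=fam.homologs[0].sequence)]
        detect = []
        for fa in (0.0, 10.0, 20.0, 30.0, 40.0, 50.0):
            cond = HybridizationConditions(na_molar=0.39, fa_percent=fa, hyb_temp_c=46.0)
            (res,) = screen(probes, db, cond)
            detect.append(res.predicted_detectable_at_fa)
        # once lost at some FA, never regained at higher FA
        assert detect == sorted(detect, reverse=True)

    def test_duplicate_target_ids_rejected(self):
        gene = random_gene(500, 50, 1)
        probes = _probes_from(gene)
        db = [SequenceRecord(id="x", sequence=gene), SequenceRecord(id="x", sequence=gene)]
        with pytest.raises(ValidationError):
            screen(probes, db, self.COND)


class TestGlobalIdentity:
    def test_exact_copy_and_known_divergence(self):
        a = random_gene(300, 50, 21)
        assert global_identity(a, a) == 100.0
        b = list(a)
        for i in range(0, 300, 10):  # 10% substitutions
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        ident = global_identity(a, "".join(b))
        assert ident == pytest.approx(90.0, abs=1e-9)
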