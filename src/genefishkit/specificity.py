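"""Probe-versus-target comparison and set-level cross-hybridization calling.

Each probe is compared to each database gene by deterministic semi-global
alignment: the probe must align end to end, target overhangs are free.  From
the alignment trace we report percent identity (matches over alignment
columns spanning the aligned probe), the longest run of consecutive
non-match columns (substitutions and gaps pooled — long perfect stretches
are what stabilize a mismatched duplex), and probe coverage.

Set-level calling follows the 4-of-5 rule used for polynucleotide probe
sets: a probe hits a target if its identity is at or above the threshold
(default 80%), and the set hits if at least ``min_hits`` (default 4) probes
hit.  The implied mismatch of a hit set (100 minus the mean identity of the
hitting probes) feeds the Wetmur stringency model to predict whether the
target would be detected at given hybridization conditions.

Alignment scoring is deterministic and documented (match +1, mismatch -2,
gap open -4 covering the first gap position, extension -1); BLAST-compatible
scores are not promised.  N never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidParameterError, ParseError, ValidationError
from .sequence_io import SequenceRecord, reverse_complement
from .thermo import DuplexParams, HybridizationConditions, max_mismatch

__all__ = [
    "AlignmentSummary",
    "ScreenResult",
    "Scoring",
    "align_probe",
    "longest_mismatch_stretch",
    "set_hit",
    "screen",
    "global_identity",
]

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring scheme; gap_open is the score of a gap's first position."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def _substitution_matrix(scoring: Scoring):
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            # N is never a match, not even against itself
            m[a, b] = scoring.match if (a == b and a != "N") else scoring.mismatch
    return m


@lru_cache(maxsize=8)
def _make_aligner(scoring: Scoring, free_target_ends: bool):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _substitution_matrix(scoring)
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if free_target_ends:
        # target overhangs appear as end gaps in the query row; make them free
        aligner.end_deletion_score = 0.0
    return aligner


@dataclass(frozen=True)
class AlignmentSummary:
    """Summary statistics of one probe-target alignment."""

    probe_id: str
    target_id: str
    strand: str
    score: float
    percent_identity: float
    longest_mismatch_stretch_bp: int
    alignment_length: int
    probe_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(f"percent_identity out of range: {self.percent_identity}")
        if self.longest_mismatch_stretch_bp > self.alignment_length:
            raise ValidationError("longest mismatch stretch exceeds alignment length")


def _check_dna(seq: str, name: str) -> None:
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise ParseError(f"{name}: non-DNA characters {sorted(bad)} (only A/C/G/T/N allowed)")
    if not seq:
        raise ParseError(f"{name}: empty sequence")


def longest_mismatch_stretch(columns) -> int:
    """Longest run of consecutive non-match columns in an alignment trace.

    ``columns`` is an iterable of (probe_char, target_char) pairs with ``-``
    for gaps; substitutions and gap positions pool into a single run.
    """
    longest = run = 0
    for a, b in columns:
        if a == b and a != "-" and a != "N":
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    return longest


def _summarize(probe_row: str, target_row: str):
    """Identity, stretch, length and coverage over the aligned probe span."""
    # trim columns outside the probe (query end gaps = target overhang)
    first = next(i for i, c in enumerate(probe_row) if c != "-")
    last = len(probe_row) - next(i for i, c in enumerate(reversed(probe_row)) if c != "-")
    cols = list(zip(probe_row[first:last], target_row[first:last]))
    matches = sum(1 for a, b in cols if a == b and a != "-" and a != "N")
    n_cols = len(cols)
    aligned_probe_residues = sum(1 for a, b in cols if a != "-" and b != "-")
    probe_len = sum(1 for a in probe_row if a != "-")
    return (
        100.0 * matches / n_cols,
        longest_mismatch_stretch(cols),
        n_cols,
        aligned_probe_residues / probe_len,
    )


def align_probe(
    probe_seq: str,
    target_seq: str,
    scoring: Scoring = Scoring(),
    probe_id: str = "probe",
    target_id: str = "target",
    both_strands: bool = True,
) -> AlignmentSummary:
    """Optimal semi-global alignment of a probe against a target.

    The probe aligns globally; target end gaps are free.  Both target strands
    are evaluated and the better-scoring strand reported (forward wins ties).
    """
    _check_dna(probe_seq, probe_id)
    _check_dna(target_seq, target_id)
    aligner = _make_aligner(scoring, free_target_ends=True)

    def _one(target: str):
        alns = aligner.align(target, probe_seq)
        aln = alns[0]
        return alns.score, aln

    score_f, aln_f = _one(target_seq)
    strand, score, aln = "+", score_f, aln_f
    if both_strands:
        score_r, aln_r = _one(reverse_complement(target_seq))
        if score_r > score_f:
            strand, score, aln = "-", score_r, aln_r
    target_row, probe_row = str(aln[0]), str(aln[1])
    identity, stretch, ncols, coverage = _summarize(probe_row, target_row)
    return AlignmentSummary(
        probe_id=probe_id,
        target_id=target_id,
        strand=strand,
        score=float(score),
        percent_identity=identity,
        longest_mismatch_stretch_bp=stretch,
        alignment_length=ncols,
        probe_coverage=coverage,
    )


def global_identity(seq_a: str, seq_b: str, scoring: Scoring = Scoring()) -> float:
    """Percent identity of a global (end-gaps-penalized) pairwise alignment.

    Used for homolog-link identities between loci; the better of the two
    strands of ``seq_b`` is reported.
    """
    _check_dna(seq_a, "seq_a")
    _check_dna(seq_b, "seq_b")
    aligner = _make_aligner(scoring, free_target_ends=False)
    best = None
    for cand in (seq_b, reverse_complement(seq_b)):
        alns = aligner.align(seq_a, cand)
        if best is None or alns.score > best[0]:
            best = (alns.score, alns[0])
    a_row, b_row = str(best[1][0]), str(best[1][1])
    matches = sum(1 for a, b in zip(a_row, b_row) if a == b and a != "-" and a != "N")
    return 100.0 * matches / len(a_row)


def set_hit(
    summaries: list[AlignmentSummary],
    identity_threshold: float = 80.0,
    min_hits: int = 4,
    min_coverage: float = 0.5,
) -> tuple[bool, int]:
    """4-of-5-style set-level hit call.

    A probe hits if its identity is >= ``identity_threshold`` and its coverage
    >= ``min_coverage``; the set hits if at least ``min_hits`` probes hit.
    Returns ``(set_hit, n_probe_hits)``.
    """
    if not summaries:
        raise InvalidParameterError("set_hit requires at least one alignment summary")
    n = sum(
        1
        for s in summaries
        if s.percent_identity >= identity_threshold and s.probe_coverage >= min_coverage
    )
    return n >= min_hits, n


@dataclass(frozen=True)
class ScreenResult:
    """Set-level screening outcome for one probe set against one target."""

    target_id: str
    summaries: tuple[AlignmentSummary, ...]
    n_probe_hits: int
    set_hit: bool
    implied_mismatch_percent: float | None
    predicted_detectable_at_fa: bool


def screen(
    probe_set,
    gene_db: list[SequenceRecord],
    cond: HybridizationConditions | None = None,
    identity_threshold: float = 80.0,
    min_hits: int = 4,
    min_coverage: float = 0.5,
    mismatch_mode: str = "mean",
    scoring: Scoring = Scoring(),
) -> list[ScreenResult]:
    """Screen every database gene against a probe set.

    ``probe_set`` is any iterable of probes with ``probe_id`` and ``sequence``
    attributes (a :class:`~genefishkit.probe_design.ProbeSet` or a list of
    FASTA records).  For each target the per-probe alignments, the set-hit
    call, the implied mismatch (100 minus the mean identity of hitting
    probes, or the worst with ``mismatch_mode='worst'``) and the
    thermodynamic detectability at ``cond`` are computed.
    """
    if cond is None:
        cond = HybridizationConditions()
    if mismatch_mode not in {"mean", "worst"}:
        raise InvalidParameterError(f"mismatch_mode must be 'mean' or 'worst', got {mismatch_mode!r}")
    if not gene_db:
        raise InvalidParameterError("gene database is empty")
    ids = [r.id for r in gene_db]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate target ids in database: {dupes}")

    probes = [(p.probe_id, p.sequence) for p in probe_set]
    results = []
    for target in gene_db:
        summaries = tuple(
            align_probe(seq, target.sequence, scoring, probe_id=pid, target_id=target.id)
            for pid, seq in probes
        )
        hit, n = set_hit(summaries, identity_threshold, min_hits, min_coverage)
        hitting = [
            s
            for s in summaries
            if s.percent_identity >= identity_threshold and s.probe_coverage >= min_coverage
        ]
        if hitting:
            if mismatch_mode == "mean":
                implied = 100.0 - sum(s.percent_identity for s in hitting) / len(hitting)
            else:
                implied = 100.0 - min(s.percent_identity for s in hitting)
            # duplex stand-in for the set: mean probe GC / length of hitting probes
            mean_len = max(1, round(sum(s.alignment_length for s in hitting) / len(hitting)))
            gc = _probe_set_gc(probe_set)
            budget = max_mismatch(DuplexParams(gc_percent=gc, length_bp=mean_len), cond)
            detectable = hit and implied <= budget
        else:
            implied = None
            detectable = False
        results.append(
            ScreenResult(
                target_id=target.id,
                summaries=summaries,
                n_probe_hits=n,
                set_hit=hit,
                implied_mismatch_percent=implied,
                predicted_detectable_at_fa=detectable,
            )
        )
    return results


def _probe_set_gc(probe_set) -> float:
    seqs = [p.sequence for p in probe_set]
    total = sum(len(s) for s in seqs)
    gc = sum(s.count("G") + s.count("C") for s in seqs)
    return 100.0 * gc / total


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Flatten screen results into a probe-level + set-level TSV-ready table."""
    rows = []
    for r in results:
        for s in r.summaries:
            rows.append(
                dict(
                    row_type="probe",
                    probe_id=s.probe_id,
                    target_id=s.target_id,
                    strand=s.strand,
                    percent_identity=s.percent_identity,
                    longest_mismatch_stretch_bp=s.longest_mismatch_stretch_bp,
                    probe_coverage=s.probe_coverage,
                    n_probe_hits=None,
                    set_hit=None,
                    implied_mismatch_percent=None,
                    predicted_detectable_at_fa=None,
                )
            )
        rows.append(
            dict(
                row_type="set",
                probe_id=None,
                target_id=r.target_id,
                strand=None,
                percent_identity=None,
                longest_mismatch_stretch_bp=None,
                probe_coverage=None,
                n_probe_hits=r.n_probe_hits,
                set_hit=r.set_hit,
                implied_mismatch_percent=r.implied_mismatch_percent,
                predicted_detectable_at_fa=r.predicted_detectable_at_fa,
            )
        )
    return pd.DataFrame(rows)
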