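"""Tile a target gene into consecutive Tm/GC-matched polynucleotide probes.

A polynucleotide probe set for gene-targeted FISH consists of k adjacent,
non-overlapping probes that together cover a contiguous window of the gene.
Because the probes are hybridized simultaneously in one buffer, they should
share as similar a melting temperature and GC content as possible.  The
tiling problem solved here is: choose k consecutive interval lengths, each
within [min_len, max_len], minimizing

    objective = tm_spread + weight_gc * gc_spread

where the spreads are (max - min) of the per-probe Wetmur Tm (perfect match,
at the design conditions) and GC percent.  Instances whose breakpoint space
is enumerable (up to 200,000 feasible tilings, which covers typical 5-probe
designs with a published-style narrow length window) are solved exactly with
a full deterministic tie-break; larger spaces fall back to a deterministic
beam search seeded with the balanced split, which is never worse than the
naive equal-length tiling.

Amplification primers for probe synthesis are derived as exact probe termini
(the amplicon is the probe): the forward primer is a prefix, the reverse
primer the reverse complement of a suffix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import ConstraintsRelaxedWarning, InfeasibleDesignError, InvalidParameterError
from .sequence_io import GeneTarget, SequenceRecord, reverse_complement
from .thermo import DuplexParams, HybridizationConditions, wetmur_tm

__all__ = [
    "ProbeCandidate",
    "ProbeSet",
    "PrimerPair",
    "tile_gene",
    "design_primers",
    "gc_percent",
    "PAPER2021_WINDOW",
    "DEFAULT_WINDOW",
]

#: default probe length window (bp) — the typical polynucleotide probe range
DEFAULT_WINDOW = (300, 500)
#: the published five-probe design used 442-456 bp probes
PAPER2021_WINDOW = (442, 456)

#: probes with more than this fraction of N are rejected
MAX_N_FRACTION = 0.01


def gc_percent(seq: str) -> float:
    """GC content in percent; N counts as non-GC."""
    if not seq:
        raise InvalidParameterError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class ProbeCandidate:
    """One probe of a set: a gene slice with its GC and reference Tm."""

    probe_id: str
    start: int
    end: int
    sequence: str
    gc_percent: float
    tm_ref_c: float

    def __len__(self) -> int:
        return self.end - self.start

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.probe_id,
            sequence=self.sequence,
            description=f"interval={self.start}-{self.end} gc={self.gc_percent:.2f} tm={self.tm_ref_c:.2f}",
        )


@dataclass(frozen=True)
class ProbeSet:
    """An ordered, gap-free, non-overlapping tiling of a gene window."""

    gene_id: str
    probes: tuple[ProbeCandidate, ...]
    tm_spread_c: float
    gc_spread: float
    objective_value: float
    window: tuple[int, int]

    def __post_init__(self) -> None:
        for a, b in zip(self.probes, self.probes[1:]):
            if b.start != a.end:
                raise InvalidParameterError("probes must be consecutive and non-overlapping")

    def __iter__(self):
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


class _Scorer:
    """Per-interval GC/Tm from prefix sums; Tm uses the Wetmur model at M=0."""

    def __init__(self, seq: str, cond: HybridizationConditions):
        n = len(seq)
        self.gc_prefix = [0] * (n + 1)
        self.n_prefix = [0] * (n + 1)
        for i, c in enumerate(seq):
            self.gc_prefix[i + 1] = self.gc_prefix[i] + (1 if c in "GC" else 0)
            self.n_prefix[i + 1] = self.n_prefix[i] + (1 if c == "N" else 0)
        na = cond.na_molar
        self.tm_const = (
            81.5 + 16.6 * math.log10(na / (1.0 + 0.7 * na)) - 0.63 * cond.fa_percent
        )

    def valid(self, s: int, e: int) -> bool:
        return (self.n_prefix[e] - self.n_prefix[s]) <= MAX_N_FRACTION * (e - s)

    def gc(self, s: int, e: int) -> float:
        return 100.0 * (self.gc_prefix[e] - self.gc_prefix[s]) / (e - s)

    def tm(self, s: int, e: int) -> float:
        return self.tm_const + 0.41 * self.gc(s, e) - 500.0 / (e - s)


def _count_tilings(total_min: int, total_max: int, k: int, a: int, b: int, cap: int) -> int:
    """Number of length tuples (l1..lk), li in [a,b], with total in [total_min, total_max].

    Counting stops at ``cap + 1`` so callers can test against a limit cheaply.
    """
    # counts[t] = number of ways to reach total t with i parts
    counts = {0: 1}
    for _ in range(k):
        nxt: dict[int, int] = {}
        for t, c in counts.items():
            for l in range(a, b + 1):
                if t + l > total_max:
                    break
                nxt[t + l] = nxt.get(t + l, 0) + c
        counts = nxt
        if sum(counts.values()) > 50 * cap:  # early bail on explosive growth
            return cap + 1
    return sum(c for t, c in counts.items() if total_min <= t <= total_max)


def _enumerate_exact(scorer, start, total_min, total_max, k, a, b, weight_gc):
    """Exhaustive search; returns (key, lengths) with the full tie-break key
    (objective, length_spread, breakpoint tuple) or None if infeasible."""
    best = None

    def rec(i, pos, lengths, tms, gcs):
        nonlocal best
        used = pos - start
        if i == k:
            if used < total_min:
                return
            obj = (max(tms) - min(tms)) + weight_gc * (max(gcs) - min(gcs))
            key = (obj, max(lengths) - min(lengths), tuple(lengths))
            if best is None or key < best[0]:
                best = (key, list(lengths))
            return
        remaining = k - i
        for l in range(a, b + 1):
            e = pos + l
            if used + l + (remaining - 1) * a > total_max:
                break
            if used + l + (remaining - 1) * b < total_min:
                continue
            if not scorer.valid(pos, e):
                continue
            lengths.append(l)
            tms.append(scorer.tm(pos, e))
            gcs.append(scorer.gc(pos, e))
            rec(i + 1, e, lengths, tms, gcs)
            lengths.pop()
            tms.pop()
            gcs.pop()

    rec(0, start, [], [], [])
    return best


def _balanced_lengths(total: int, k: int, a: int, b: int) -> list[int] | None:
    """The most-equal length tuple summing to ``total`` (shorter probes first)."""
    if not k * a <= total <= k * b:
        return None
    base, extra = divmod(total, k)
    lengths = [base] * (k - extra) + [base + 1] * extra
    return lengths if a <= lengths[0] and lengths[-1] <= b else None


def _beam_search(scorer, start, total_min, total_max, k, a, b, weight_gc,
                 beam_width: int = 256):
    """Deterministic beam search over breakpoints for beyond-enumeration instances.

    States are partial tilings summarized by their (Tm, GC) min/max envelope;
    at each level all single-probe extensions of the beam are generated,
    deduplicated, and the ``beam_width`` lowest-width states kept (width =
    current spread objective, then most-equal lengths, then the length tuple
    itself — a deterministic balanced-lengths-preferring ranking).  The
    balanced split is always seeded into the initial beam, so the result is
    never worse than the naive equal-length tiling.
    """
    # state: (width_key, lengths, pos, tmin, tmax, gmin, gmax)
    beam = [((0.0, 0, ()), (), start, None, None, None, None)]
    for i in range(k):
        remaining = k - i
        children = {}
        for _, lengths, pos, tmin, tmax, gmin, gmax in beam:
            used = pos - start
            l_lo = max(a, total_min - used - (remaining - 1) * b)
            l_hi = min(b, total_max - used - (remaining - 1) * a)
            for l in range(l_lo, l_hi + 1):
                e = pos + l
                if not scorer.valid(pos, e):
                    continue
                tm = scorer.tm(pos, e)
                gc = scorer.gc(pos, e)
                ntmin = tm if tmin is None else min(tmin, tm)
                ntmax = tm if tmax is None else max(tmax, tm)
                ngmin = gc if gmin is None else min(gmin, gc)
                ngmax = gc if gmax is None else max(gmax, gc)
                nlengths = lengths + (l,)
                width = (ntmax - ntmin) + weight_gc * (ngmax - ngmin)
                key = (width, max(nlengths) - min(nlengths), nlengths)
                state_id = (e, round(ntmin, 9), round(ntmax, 9), round(ngmin, 9), round(ngmax, 9))
                prev = children.get(state_id)
                if prev is None or key < prev[0]:
                    children[state_id] = (key, nlengths, e, ntmin, ntmax, ngmin, ngmax)
        if not children:
            return None
        beam = sorted(children.values(), key=lambda s: s[0])[:beam_width]

    # make sure the plain balanced tilings are always considered
    finals = list(beam)
    for total in range(total_min, total_max + 1):
        lengths = _balanced_lengths(total, k, a, b)
        if lengths is None:
            continue
        tms, gcs, pos, ok = [], [], start, True
        for l in lengths:
            if not scorer.valid(pos, pos + l):
                ok = False
                break
            tms.append(scorer.tm(pos, pos + l))
            gcs.append(scorer.gc(pos, pos + l))
            pos += l
        if ok:
            width = (max(tms) - min(tms)) + weight_gc * (max(gcs) - min(gcs))
            lt = tuple(lengths)
            finals.append(((width, max(lt) - min(lt), lt), lt, pos, None, None, None, None))

    best = min(finals, key=lambda s: s[0])
    return best[0], list(best[1])


def tile_gene(
    gene: GeneTarget,
    k: int = 5,
    min_len: int = DEFAULT_WINDOW[0],
    max_len: int = DEFAULT_WINDOW[1],
    weight_gc: float = 1.0,
    design_conditions: HybridizationConditions | None = None,
    *,
    offset_grid: int = 10,
    enumeration_limit: int = 200_000,
) -> ProbeSet:
    """Exact Tm/GC-matched tiling of a gene into k consecutive probes.

    If the gene is longer than ``k * max_len`` the covered window is chosen by
    searching start offsets on a ``offset_grid``-bp grid, each window solved to
    optimality and the best kept.  Ties break toward the most equal probe
    lengths, then leftmost breakpoints (exact on enumeration-sized instances).

    Raises
    ------
    InfeasibleDesignError
        If ``k * min_len`` exceeds the gene length, naming the violated bound.
    """
    if design_conditions is None:
        design_conditions = HybridizationConditions()
    if k < 1:
        raise InvalidParameterError(f"k must be >= 1, got {k}")
    if not 1 <= min_len <= max_len:
        raise InvalidParameterError(f"need 1 <= min_len <= max_len, got [{min_len}, {max_len}]")
    L = len(gene.sequence)
    if k * min_len > L:
        raise InfeasibleDesignError(
            f"gene {gene.id!r} of length {L} bp is shorter than k*min_len = "
            f"{k}*{min_len} = {k * min_len} bp"
        )
    scorer = _Scorer(gene.sequence, design_conditions)

    if L <= k * max_len:
        starts = [0]
        bounds = (L, L)  # must cover the whole gene
    else:
        last = L - k * max_len
        starts = list(range(0, last + 1, offset_grid))
        if starts[-1] != last:
            starts.append(last)
        bounds = (k * min_len, k * max_len)

    overall = None  # (key, start, lengths)
    for s in starts:
        total_min, total_max = bounds
        total_max = min(total_max, L - s)
        n_tilings = _count_tilings(total_min, total_max, k, min_len, max_len, enumeration_limit)
        if n_tilings <= enumeration_limit:
            res = _enumerate_exact(scorer, s, total_min, total_max, k, min_len, max_len, weight_gc)
        else:
            res = _beam_search(scorer, s, total_min, total_max, k, min_len, max_len, weight_gc)
        if res is not None and (overall is None or res[0] < overall[0]):
            overall = (res[0], s, res[1])

    if overall is None:
        raise InfeasibleDesignError(
            f"no feasible tiling of gene {gene.id!r} with k={k}, window [{min_len}, {max_len}] "
            f"(every candidate probe exceeded the {MAX_N_FRACTION:.0%} N limit)"
        )

    key, start, lengths = overall
    probes = []
    pos = start
    tms, gcs = [], []
    for i, l in enumerate(lengths, 1):
        seq = gene.sequence[pos : pos + l]
        g = scorer.gc(pos, pos + l)
        tm = wetmur_tm(DuplexParams(gc_percent=g, length_bp=l), design_conditions)
        probes.append(
            ProbeCandidate(
                probe_id=f"{gene.id}_{i}",
                start=pos,
                end=pos + l,
                sequence=seq,
                gc_percent=g,
                tm_ref_c=tm,
            )
        )
        tms.append(tm)
        gcs.append(g)
        pos += l
    return ProbeSet(
        gene_id=gene.id,
        probes=tuple(probes),
        tm_spread_c=max(tms) - min(tms),
        gc_spread=max(gcs) - min(gcs),
        objective_value=(max(tms) - min(tms)) + weight_gc * (max(gcs) - min(gcs)),
        window=(start, pos),
    )


# ---------------------------------------------------------------------------
# primers
# ---------------------------------------------------------------------------


def primer_tm(seq: str) -> float:
    """Simple GC-count primer Tm: 64.9 + 41*(nGC - 16.4)/len (°C).

    A deliberately simple, documented-as-replaceable stand-in for the
    interactive primer tools typically used at the bench.
    """
    ngc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (ngc - 16.4) / len(seq)


@dataclass(frozen=True)
class PrimerPair:
    """Amplification primers for one probe; the amplicon is the probe itself."""

    probe_id: str
    forward: str
    reverse: str
    forward_gc: float
    reverse_gc: float
    forward_tm_c: float
    reverse_tm_c: float
    tm_difference_c: float
    forward_gc_ok: bool
    reverse_gc_ok: bool
    constraints_met: bool

    @property
    def forward_len(self) -> int:
        return len(self.forward)

    @property
    def reverse_len(self) -> int:
        return len(self.reverse)


def design_primers(
    probe: ProbeCandidate,
    primer_min: int = 18,
    primer_max: int = 27,
    gc_low: float = 40.0,
    gc_high: float = 60.0,
    max_tm_diff_c: float = 2.0,
) -> PrimerPair:
    """Pick forward (prefix) and reverse (revcomp of suffix) primers for a probe.

    Among all length pairs in [primer_min, primer_max] whose GC lies in
    [gc_low, gc_high] and whose Tm difference is <= ``max_tm_diff_c``, the
    shortest pair is chosen (total length, then Tm difference, then forward
    length).  If no pair satisfies every constraint, the pair minimizing the
    Tm difference is returned with ``constraints_met = False`` and a
    :class:`ConstraintsRelaxedWarning`.
    """
    seq = probe.sequence
    if len(seq) <= 2 * primer_max:
        raise InvalidParameterError(
            f"probe {probe.probe_id!r} of length {len(seq)} bp is too short for primers "
            f"up to {primer_max} bp (need > {2 * primer_max} bp)"
        )

    def fwd(l: int) -> str:
        return seq[:l]

    def rev(l: int) -> str:
        return reverse_complement(seq[-l:])

    candidates = []
    for lf in range(primer_min, primer_max + 1):
        f = fwd(lf)
        fg, ft = gc_percent(f), primer_tm(f)
        for lr in range(primer_min, primer_max + 1):
            r = rev(lr)
            rg, rt = gc_percent(r), primer_tm(r)
            dt = abs(ft - rt)
            ok = gc_low <= fg <= gc_high and gc_low <= rg <= gc_high and dt <= max_tm_diff_c
            candidates.append((ok, lf, lr, f, r, fg, rg, ft, rt, dt))

    compliant = [c for c in candidates if c[0]]
    if compliant:
        ok, lf, lr, f, r, fg, rg, ft, rt, dt = min(
            compliant, key=lambda c: (c[1] + c[2], c[9], c[1])
        )
        met = True
    else:
        ok, lf, lr, f, r, fg, rg, ft, rt, dt = min(
            candidates, key=lambda c: (c[9], c[1] + c[2], c[1])
        )
        met = False
        warnings.warn(
            f"no primer pair for probe {probe.probe_id!r} satisfies GC in "
            f"[{gc_low}, {gc_high}] and Tm difference <= {max_tm_diff_c} °C; "
            f"returning the minimum-Tm-difference pair",
            ConstraintsRelaxedWarning,
            stacklevel=2,
        )
    return PrimerPair(
        probe_id=probe.probe_id,
        forward=f,
        reverse=r,
        forward_gc=fg,
        reverse_gc=rg,
        forward_tm_c=ft,
        reverse_tm_c=rt,
        tm_difference_c=dt,
        forward_gc_ok=gc_low <= fg <= gc_high,
        reverse_gc_ok=gc_low <= rg <= gc_high,
        constraints_met=met,
    )
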