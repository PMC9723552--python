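"""Independent reference implementations used as oracles by the test suite.

These deliberately share no code with the package: a quadratic-time affine
semi-global aligner (plain Gotoh recurrences), a recursive brute-force probe
tiler, a window-scan PUL rule evaluator, and spreadsheet-style statistics
formulas.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def semiglobal_score(probe: str, target: str, match=1.0, mismatch=-2.0,
                     gap_open=-4.0, gap_extend=-1.0) -> float:
    """Optimal score: probe global, target-overhang (query-row) end gaps free.

    ``gap_open`` is the score of a gap's first position, ``gap_extend`` of
    each further position.
    """
    m, n = len(probe), len(target)

    def sub(a, b):
        return match if (a == b and a != "N") else mismatch

    # D: column ends in residue pair; P: gap in target row (probe residue over
    # '-'); Q: gap in probe row ('-' over target residue)
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    P = [[NEG] * (n + 1) for _ in range(m + 1)]
    Q = [[NEG] * (n + 1) for _ in range(m + 1)]
    D[0][0] = 0.0
    for j in range(1, n + 1):
        Q[0][j] = 0.0  # leading target overhang is free
    for i in range(1, m + 1):
        P[i][0] = gap_open + (i - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = sub(probe[i - 1], target[j - 1])
            D[i][j] = s + max(D[i - 1][j - 1], P[i - 1][j - 1], Q[i - 1][j - 1])
            P[i][j] = max(D[i - 1][j] + gap_open, P[i - 1][j] + gap_extend,
                          Q[i - 1][j] + gap_open)
            Q[i][j] = max(D[i][j - 1] + gap_open, P[i][j - 1] + gap_open,
                          Q[i][j - 1] + gap_extend)
    # trailing target overhang is free: best over all consumed-target amounts
    return max(max(D[m][j], P[m][j], Q[m][j]) for j in range(n + 1))


def rescore_alignment(probe_row: str, target_row: str, match=1.0, mismatch=-2.0,
                      gap_open=-4.0, gap_extend=-1.0) -> float:
    """Score an explicit alignment (gap = '-'); probe-row end gaps are free."""
    first = next(i for i, c in enumerate(probe_row) if c != "-")
    last = len(probe_row) - next(i for i, c in enumerate(reversed(probe_row)) if c != "-")
    score = 0.0
    in_gap = False
    for a, b in zip(probe_row[first:last], target_row[first:last]):
        if a == "-" or b == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += match if (a == b and a != "N") else mismatch
            in_gap = False
    return score


def summarize_alignment(probe_row: str, target_row: str):
    """(identity %, longest non-match run, columns, coverage) over the probe span."""
    first = next(i for i, c in enumerate(probe_row) if c != "-")
    last = len(probe_row) - next(i for i, c in enumerate(reversed(probe_row)) if c != "-")
    cols = list(zip(probe_row[first:last], target_row[first:last]))
    matches = sum(1 for a, b in cols if a == b and a != "-" and a != "N")
    longest = run = 0
    for a, b in cols:
        if a == b and a != "-" and a != "N":
            run = 0
        else:
            run += 1
            longest = max(longest, run)
    probe_len = sum(1 for a in probe_row if a != "-")
    aligned = sum(1 for a, b in cols if a != "-" and b != "-")
    return 100.0 * matches / len(cols), longest, len(cols), aligned / probe_len


# ---------------------------------------------------------------------------
# brute-force probe tiling
# ---------------------------------------------------------------------------


def wetmur_tm_ref(gc_percent, length_bp, na_molar, fa_percent, mismatch=0.0):
    return (81.5 + 16.6 * math.log10(na_molar / (1 + 0.7 * na_molar))
            + 0.41 * gc_percent - 500.0 / length_bp - mismatch - 0.63 * fa_percent)


def brute_force_tilings(seq: str, k: int, a: int, b: int, na: float, fa: float,
                        weight_gc: float = 1.0):
    """Yield (objective, lengths) for every tiling covering the whole sequence."""
    L = len(seq)

    def gc(s, e):
        sl = seq[s:e]
        return 100.0 * (sl.count("G") + sl.count("C")) / (e - s)

    out = []

    def rec(pos, lengths):
        if len(lengths) == k:
            if pos == L:
                stats = []
                p = 0
                for l in lengths:
                    g = gc(p, p + l)
                    stats.append((wetmur_tm_ref(g, l, na, fa), g))
                    p += l
                tms = [t for t, _ in stats]
                gcs = [g for _, g in stats]
                obj = (max(tms) - min(tms)) + weight_gc * (max(gcs) - min(gcs))
                out.append((obj, tuple(lengths)))
            return
        for l in range(a, b + 1):
            if pos + l <= L:
                rec(pos + l, lengths + [l])

    rec(0, [])
    return out


# ---------------------------------------------------------------------------
# brute-force PUL rule
# ---------------------------------------------------------------------------


def brute_force_pul_runs(labels: list[str], max_intergenic: int):
    """Locus candidates as (first, last, is_pul, gm_like) via explicit scanning.

    Reimplements the run definition from scratch: indices of relevant genes,
    split where more than ``max_intergenic`` non-relevant genes intervene.
    """
    import re

    def relevant(lab):
        low = lab.lower()
        return (low.startswith("susc") or low.startswith("susd")
                or low == "sulfatase" or re.fullmatch(r"(GH|PL)\d+", lab) is not None)

    idx = [i for i, lab in enumerate(labels) if relevant(lab)]
    groups: list[list[int]] = []
    for i in idx:
        if groups and i - groups[-1][-1] - 1 <= max_intergenic:
            groups[-1].append(i)
        else:
            groups.append([i])
    calls = []
    for g in groups:
        labs = [labels[i] for i in g]
        n_sus = sum(1 for lab in labs if lab.lower().startswith(("susc", "susd")))
        n_caz = sum(1 for lab in labs if re.fullmatch(r"(GH|PL)\d+", lab))
        n_gh92 = sum(1 for lab in labs if lab.upper() == "GH92")
        n_sulf = sum(1 for lab in labs if lab.lower() == "sulfatase")
        is_pul = n_sus >= 1 and n_caz >= 2
        calls.append((g[0], g[-1], is_pul, is_pul and n_gh92 >= 1 and n_sulf >= 1))
    return calls


# ---------------------------------------------------------------------------
# spreadsheet-style statistics
# ---------------------------------------------------------------------------


def pooled_t_test(a: list[float], b: list[float]):
    """Pooled-variance two-tailed t-test from the textbook formulas."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def f_test_two_tailed(a: list[float], b: list[float]):
    from scipy.stats import f as f_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    F = va / vb
    cdf = f_dist.cdf(F, na - 1, nb - 1)
    return F, min(1.0, 2 * min(cdf, 1 - cdf))
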