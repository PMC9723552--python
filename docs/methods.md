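# Methods

This note documents the models, rules and numerical choices implemented in
`genefishkit`, in the order a probe-design workflow uses them.

## Duplex melting model and stringency calculus (`thermo`)

The melting temperature of a DNA:DNA duplex is modelled with the empirical
Wetmur relation

```
Tm = 81.5 + 16.6·log10([Na+] / (1 + 0.7·[Na+])) + 0.41·GC − 500/N − M − 0.63·FA
```

with `[Na+]` the monovalent sodium concentration (mol/L), `GC` the GC content
(%), `N` the duplex length (bp), `M` the percent mismatch between probe and
target, and `FA` the formamide concentration of the hybridization buffer
(% v/v). The model's two linear penalties are the whole stringency calculus:

* **mismatch budget** — at hybridization temperature `T_h` with safety margin
  `ΔT`, a target is predicted detectable iff its mismatch percent is at most
  `M_max = Tm(M=0) − (T_h + ΔT)`, floored at 0;
* **formamide relaxation** — lowering FA by `M/0.63` percentage points
  exactly compensates the Tm penalty of `M` percent mismatch, so
  `FA_relaxed = FA_stringent − M/0.63`. For a homolog at 86% identity
  (M = 14) designed at 35% FA this gives 12.78%, which rounds to **15% FA**
  in the 5%-steps hybridization buffers are prepared in.

Choices and caveats:

* `Tm` is reported unclamped (it may exceed 100 °C); only the comparison
  against `T_h + ΔT` carries meaning for detectability.
* Mismatch percent is defined as 100 − percent identity of the probe–target
  alignment, tying the thermodynamics to the `specificity` module.
* Default conditions `na_molar = 0.39`, `hyb_temp_c = 46`, `tm_margin_c = 0`
  are protocol-dependent placeholders for a standard geneFISH buffer and
  should be set explicitly when modelling a specific protocol. With these
  defaults the perfect-match budget of a 450-bp, ~45% GC probe at 35% FA is
  ≈ 22% mismatch, i.e. the binary detectability call is permissive; a
  positive `tm_margin_c` tightens it.
* FA recommendations round to the nearest multiple of 5 by default
  (`nearest-5`), with `nearest-5-down` and `none` selectable.
* Scope is deliberately the printed formula only: no nearest-neighbor
  thermodynamics, no RNA:DNA hybrids, no oligonucleotide corrections.

## Probe tiling (`probe_design`)

A polynucleotide probe set is k (default 5) adjacent, non-overlapping,
gap-free probes covering a contiguous window of the gene, each with a length
in `[min_len, max_len]`. Because the probes hybridize simultaneously in one
buffer, the breakpoints are chosen to minimize

```
objective = tm_spread + weight_gc · gc_spread
```

where the spreads are max−min of the per-probe perfect-match Wetmur Tm and
GC percent, and `weight_gc = 1` by default (the two spreads are of the same
order on real sequence, so neither dominates).

* **Solver.** When the breakpoint space has at most 200,000 feasible
  tilings — which covers k = 5 designs with a narrow window such as the
  442–456 bp preset on a ~2.2 kb gene — the optimum is found by exhaustive
  enumeration with a full deterministic tie-break: lowest objective, then
  most-equal probe lengths, then leftmost breakpoints. Larger spaces
  (e.g. the default 300–500 bp window) fall back to a deterministic beam
  search (width 256) over partial tilings ranked by their current spread
  envelope; the balanced equal split is always seeded, so the result is
  never worse than the naive equal-length tiling. Exactness is only claimed
  in the enumeration regime.
* **Window placement.** If the gene is longer than `k·max_len`, start
  offsets are scanned on a 10-bp grid and each window solved independently;
  the best window wins. Which region of a gene to probe is otherwise
  unconstrained — nothing in the hybridization chemistry prefers one end.
* **Length window.** The library default is 300–500 bp, the typical
  polynucleotide probe range; the preset `paper2021` uses 442–456 bp with
  k = 5, matching the published five-probe GH92 designs.
* **Ambiguity.** N counts as non-GC for GC%; candidate probes with more
  than 1% N are infeasible, and a design where every tiling violates this
  raises an error rather than silently shifting the window.
* **Primers.** Amplification primers are exact probe termini (the amplicon
  is the probe): the forward primer is a probe prefix, the reverse the
  reverse complement of a probe suffix. Lengths 18–27 bp are scanned for
  GC within 40–60% and a pairwise Tm difference ≤ 2 °C, preferring the
  shortest total length. Primer Tm uses the simple GC-count formula
  `64.9 + 41·(nGC − 16.4)/len`, documented as replaceable — it stands in
  for the interactive tools normally used at the bench, and only the Tm
  *difference* between the two primers matters for the selection. If no
  pair satisfies every constraint the minimum-Tm-difference pair is
  returned with `constraints_met = False` and a warning.

## Specificity screening (`specificity`)

Each probe is compared to each database gene by **semi-global alignment**:
the probe aligns end to end, target overhangs are free. Scoring is match +1,
mismatch −2, gap open −4 (the first gap position), gap extension −1; both
target strands are evaluated and the better reported. This replaces the
interactive BLAST searches typically used for this step with a deterministic,
parameter-free-to-the-user procedure; BLAST-compatible scores are not
promised. N never counts as a match, not even against N.

From the alignment trace, over the columns spanning the aligned probe:

* `percent_identity` = matches / alignment columns (including internal
  gaps; a probe-length denominator is selectable),
* `longest_mismatch_stretch_bp` = longest run of consecutive non-match
  columns, substitutions and gaps pooled — long perfect stretches between
  mismatches are what stabilize an imperfect duplex,
* `probe_coverage` = fraction of probe residues aligned to target residues.

Set-level calling uses the 4-of-5 rule: a probe hits a target if identity
≥ 80% (and coverage ≥ 0.5 — the published rule states no coverage floor,
so this interpretation is explicit and configurable); the set hits if at
least 4 probes hit. For a hit set the implied mismatch is 100 − mean
identity of the hitting probes (worst-case selectable), which feeds the
thermo module's mismatch budget to predict detectability at the given
hybridization conditions.

## PUL screening (`pul_screen`)

A locus candidate is a maximal run of *relevant* genes (susC-like,
susD-like, GH*nn*, PL*nn*, sulfatase) tolerating at most
`max_intergenic_genes` (default 3) other genes inside the run — the calling
rule defines membership, not boundaries, so the extent is an explicit
heuristic. A candidate **is a PUL** if it has at least one susC-like or
susD-like gene and at least two degradative CAZymes (any GH or PL family
label, GH92 included). It is additionally **glucuronomannan-like** if it
contains at least one GH92 and at least one sulfatase (minimal reading:
≥ 1 of each, no proximity requirement). susC/susD tandem pairs are
immediately adjacent, same-strand pairs in either order. Annotation is
upstream input (labels only; no HMM scanning here); GFF3 and GenBank
coordinates are converted to 0-based half-open on read.

Homolog links between two loci match genes greedily by (label, order along
the locus) — synteny-map style — and score each pair by global pairwise
nucleotide identity under the same alignment definition as the specificity
module.

## Quantification (`quantification`)

The counting unit is the field of view (FOV). Per FOV, the percentage is
`100 · positive_cells / total_cells`, where the denominator is the DAPI
count (detection efficiency) or the count of 16S-rRNA-probe-positive cells
(relative gene abundance). The experiment-level estimate is the
**unweighted mean of the per-FOV percentages** with its **sample SD**
(n−1 denominator, the spreadsheet STDEV convention); a pooled, cell-weighted
estimate is reported alongside for reference. A single FOV yields a mean
with SD "not available". Negative-control rows are reported unmodified; an
NC-adjusted mean (difference of means) exists only behind an explicit call.

Comparisons run a two-tailed variance-ratio F-test first, then always report
the pooled-variance two-tailed t-test; when the F-test rejects at α = 0.05
the result is flagged and a Welch test is reported alongside. Significance
tiers follow the usual figure-legend convention (* ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001).

## Synthetic data (`simulate`)

The generators emulate just enough structure to exercise every module
without downloads:

* **Homolog families** substitute ancestor sites at per-site rate
  `(100 − target_identity)/100`, uniformly or in geometric blocks (mean
  12 bp) that create the long mismatch stretches seen between diverged
  homologs. Substitutions never produce N; indels are off by default so the
  identity target is exact in expectation. Ancestors default to 1350 bp
  (a typical GH92 coding length) and identity targets span 70–100%, the
  range observed between homologous probe targets across genera.
* **Contigs** carry 30 genes each; a `susC,susD,GH92,sulfatase,GH16`
  cassette (satisfying both the PUL rule and the glucuronomannan flag) is
  planted with the chosen density, alongside decoys built to fail the rule;
  plants are spaced so they can never merge at the default intergenic
  tolerance, making ground truth exact.
* **FOV tables** draw binomial counts at a known positive fraction.

What passing tests on these fixtures does **not** show: real homologs
diverge under selection (conserved domains, codon structure, indels), real
annotations mislabel genes, and real micrograph counts carry segmentation
error — none of which the generators model. The fixtures validate the
algorithms, not the biology.

## Verification sizes and numerical conventions

The test suite verifies, at sizes chosen to keep the default run fast:
tiling optimality against exhaustive enumeration on 200 random ≤ 100 bp
instances; alignment scores against an independent quadratic-time Gotoh
implementation on 500 random ≤ 80 bp pairs; set-hit recovery on ~1000
synthetic families (167 per identity level, 5 × 200 bp probes on 1 kb
genes — the transition sharpness at the 80% boundary scales with probe
length, and 200 bp keeps the above/below-boundary separation far outside
binomial noise); PUL calls against a brute-force rule evaluation on 100
synthetic contigs; and the statistics against hand formulas to 1e−8.

Floating-point conventions: Tm comparisons in tests use 1e−9 absolute
tolerance; tie-breaks compare exact float objective values (identical
(GC count, length) pairs produce bit-identical Tm); all randomness flows
through seeded `numpy` generators, so every result in this package is
reproducible bit for bit.

## Known limitations

* Detectability is a binary Tm-threshold call; it does not model signal
  intensity, probe concentration or kinetics, so it cannot predict the
  *reduced but nonzero* detection seen just past the budget.
* Beam-search tilings beyond the enumeration regime are high-quality but
  not certified optimal.
* The semi-global aligner is quadratic per pair; screening millions of
  database genes would need a seed-and-extend prefilter, which is out of
  scope.
* Wet-lab steps (labeling chemistry, hybridization protocol, imaging and
  counting) are entirely outside the package: it starts from sequences and
  count tables.
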