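"""Candidate polysaccharide-utilization-locus (PUL) detection on annotated contigs.

A PUL couples TonB-dependent transport (susC-like) and substrate binding
(susD-like) with degradative CAZymes.  The calling rule applied here: a
locus candidate is a PUL if it contains at least one susC-like or susD-like
gene and at least two degradative CAZymes (any glycoside hydrolase GHnn or
polysaccharide lyase PLnn label).  A PUL additionally containing at least
one GH92 (exo-alpha-mannosidase) and at least one sulfatase is flagged as
glucuronomannan-like — the combination expected for degradation of the
sulfated diatom cell-wall mannan.

Locus extent is heuristic (the rule defines membership, not boundaries):
maximal runs of relevant genes (susC/susD/GH/PL/sulfatase) in which at most
``max_intergenic_genes`` consecutive non-relevant genes are tolerated.
Annotation itself (Prokka, CAZy HMMs) is upstream input; recognition here is
by label only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidParameterError, ValidationError
from .specificity import Scoring, global_identity

__all__ = [
    "GeneAnnotation",
    "PULCall",
    "HomologLink",
    "find_susCD_tandems",
    "find_puls",
    "homolog_links",
    "annotations_from_frame",
]

_CAZYME_RE = re.compile(r"^(GH|PL)(\d+)$")


@dataclass(frozen=True)
class GeneAnnotation:
    """A labeled gene on a contig (0-based half-open interval)."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    label: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def is_susC(self) -> bool:
        return self.label.lower().startswith("susc")

    @property
    def is_susD(self) -> bool:
        return self.label.lower().startswith("susd")

    @property
    def is_cazyme(self) -> bool:
        return _CAZYME_RE.match(self.label) is not None

    @property
    def is_gh92(self) -> bool:
        return self.label.upper() == "GH92"

    @property
    def is_sulfatase(self) -> bool:
        return self.label.lower() == "sulfatase"

    @property
    def is_relevant(self) -> bool:
        return self.is_susC or self.is_susD or self.is_cazyme or self.is_sulfatase


@dataclass(frozen=True)
class PULCall:
    """A locus candidate and its evaluation against the PUL rule."""

    contig_id: str
    first_gene_index: int
    last_gene_index: int
    gene_ids: tuple[str, ...]
    n_susC: int
    n_susD: int
    n_cazymes: int
    n_gh92: int
    n_sulfatases: int
    has_susCD_tandem: bool
    is_pul: bool
    glucuronomannan_like: bool

    def __post_init__(self) -> None:
        if self.is_pul and not ((self.n_susC + self.n_susD >= 1) and self.n_cazymes >= 2):
            raise ValidationError("is_pul set but the susCD/CAZyme rule is not satisfied")
        if self.glucuronomannan_like and not (
            self.is_pul and self.n_gh92 >= 1 and self.n_sulfatases >= 1
        ):
            raise ValidationError("glucuronomannan_like set but GH92+sulfatase rule not satisfied")


def annotations_from_frame(df: pd.DataFrame) -> list[GeneAnnotation]:
    """Build annotations from the table schema of :mod:`genefishkit.sequence_io`."""
    return [
        GeneAnnotation(
            contig_id=str(r.contig),
            gene_id=str(r.gene_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            label=str(r.label),
            sequence=getattr(r, "sequence", None),
        )
        for r in df.itertuples(index=False)
    ]


def _check_sorted(genes: list[GeneAnnotation]) -> None:
    for a, b in zip(genes, genes[1:]):
        if a.contig_id == b.contig_id and b.start < a.start:
            raise ValidationError(
                f"annotations on contig {a.contig_id!r} are not sorted by start "
                f"({b.gene_id!r} at {b.start} after {a.gene_id!r} at {a.start})"
            )


def find_susCD_tandems(genes: list[GeneAnnotation]) -> list[tuple[GeneAnnotation, GeneAnnotation]]:
    """Immediately adjacent susC-like/susD-like pairs on the same strand.

    Input must be one contig's genes sorted by start; either gene order
    (susC first or susD first) counts as a tandem.
    """
    _check_sorted(genes)
    pairs = []
    for a, b in zip(genes, genes[1:]):
        if a.strand != b.strand:
            continue
        if (a.is_susC and b.is_susD) or (a.is_susD and b.is_susC):
            pairs.append((a, b))
    return pairs


def find_puls(genes: list[GeneAnnotation], max_intergenic_genes: int = 3) -> list[PULCall]:
    """Evaluate every locus candidate on (possibly multi-contig) annotations.

    Candidates are maximal runs of relevant genes separated by at most
    ``max_intergenic_genes`` non-relevant genes; every candidate is returned
    with its ``is_pul`` / ``glucuronomannan_like`` evaluation so callers can
    inspect near-misses.  Input must be sorted by start within each contig.
    """
    if max_intergenic_genes < 0:
        raise InvalidParameterError("max_intergenic_genes must be >= 0")
    _check_sorted(genes)
    calls: list[PULCall] = []
    by_contig: dict[str, list[tuple[int, GeneAnnotation]]] = {}
    for idx, g in enumerate(genes):
        by_contig.setdefault(g.contig_id, []).append((idx, g))

    for contig_id, contig_genes in by_contig.items():
        runs: list[list[tuple[int, GeneAnnotation]]] = []
        current: list[tuple[int, GeneAnnotation]] = []
        gap = 0
        for idx, g in contig_genes:
            if g.is_relevant:
                current.append((idx, g))
                gap = 0
            elif current:
                gap += 1
                if gap > max_intergenic_genes:
                    runs.append(current)
                    current = []
                    gap = 0
        if current:
            runs.append(current)

        for run in runs:
            members = [g for _, g in run]
            # the locus spans from the first to the last relevant gene,
            # including tolerated intergenic genes in between
            lo, hi = run[0][0], run[-1][0]
            span = [g for idx, g in contig_genes if lo <= idx <= hi]
            n_susC = sum(g.is_susC for g in members)
            n_susD = sum(g.is_susD for g in members)
            n_caz = sum(g.is_cazyme for g in members)
            n_gh92 = sum(g.is_gh92 for g in members)
            n_sulf = sum(g.is_sulfatase for g in members)
            is_pul = (n_susC + n_susD >= 1) and n_caz >= 2
            calls.append(
                PULCall(
                    contig_id=contig_id,
                    first_gene_index=lo,
                    last_gene_index=hi,
                    gene_ids=tuple(g.gene_id for g in span),
                    n_susC=n_susC,
                    n_susD=n_susD,
                    n_cazymes=n_caz,
                    n_gh92=n_gh92,
                    n_sulfatases=n_sulf,
                    has_susCD_tandem=bool(find_susCD_tandems(span)),
                    is_pul=is_pul,
                    glucuronomannan_like=is_pul and n_gh92 >= 1 and n_sulf >= 1,
                )
            )
    return calls


def puls_table(calls: list[PULCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                contig_id=c.contig_id,
                first_gene_index=c.first_gene_index,
                last_gene_index=c.last_gene_index,
                n_genes=len(c.gene_ids),
                n_susC=c.n_susC,
                n_susD=c.n_susD,
                n_cazymes=c.n_cazymes,
                n_gh92=c.n_gh92,
                n_sulfatases=c.n_sulfatases,
                has_susCD_tandem=c.has_susCD_tandem,
                is_pul=c.is_pul,
                glucuronomannan_like=c.glucuronomannan_like,
            )
            for c in calls
        ]
    )


@dataclass(frozen=True)
class HomologLink:
    """A nucleotide-identity link between homologous genes of two loci."""

    gene_id_a: str
    gene_id_b: str
    label: str
    percent_identity: float


def homolog_links(
    locus_a: list[GeneAnnotation],
    locus_b: list[GeneAnnotation],
    scoring: Scoring = Scoring(),
) -> list[HomologLink]:
    """Match genes across two loci by (label, order) and score nucleotide identity.

    Greedy positional matching: the i-th gene of a label in locus A links to
    the i-th gene of the same label in locus B (synteny-map style).  Genes
    whose label is absent from the other locus stay unlinked; genes without a
    sequence are skipped with a warning.  Identities use the same global
    alignment definition as the specificity module.
    """
    links: list[HomologLink] = []
    by_label_b: dict[str, list[GeneAnnotation]] = {}
    for g in locus_b:
        by_label_b.setdefault(g.label, []).append(g)
    counters: dict[str, int] = {}
    for ga in locus_a:
        pos = counters.get(ga.label, 0)
        partners = by_label_b.get(ga.label, [])
        if pos >= len(partners):
            continue
        counters[ga.label] = pos + 1
        gb = partners[pos]
        if ga.sequence is None or gb.sequence is None:
            warnings.warn(
                f"missing sequence for {ga.gene_id!r} or {gb.gene_id!r}; link skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        links.append(
            HomologLink(
                gene_id_a=ga.gene_id,
                gene_id_b=gb.gene_id,
                label=ga.label,
                percent_identity=global_identity(ga.sequence, gb.sequence, scoring),
            )
        )
    return links


def links_table(links: list[HomologLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                gene_id_a=l.gene_id_a,
                gene_id_b=l.gene_id_b,
                label=l.label,
                percent_identity=l.percent_identity,
            )
            for l in links
        ]
    )
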