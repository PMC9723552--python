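"""Synthetic-data generators: homolog families, annotated contigs, FOV counts.

Every other module is testable without downloads through these generators:

* :func:`make_family` evolves homologs from a random ancestor at controlled
  per-site substitution rates, emulating the structure of a conserved gene
  family whose pairwise identities to a probe span roughly 70-100%.  The
  ``clustered`` stretch model places substitutions in geometric blocks,
  producing the long mismatch/gap stretches seen between diverged homologs.
* :func:`make_contigs` lays out labeled genes on synthetic contigs and plants
  susC/susD/GH92/sulfatase/GH16 cassettes (ground-truth PULs) at a chosen
  density, alongside decoys that deliberately fail the PUL rule.
* :func:`make_fov_counts` draws binomial per-FOV counts at a true positive
  fraction.

All generators are deterministic given their seed.  Substitutions never
create N; indels are off by default so identity targets are exact in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .pul_screen import GeneAnnotation
from .quantification import FOVCount
from .sequence_io import SequenceRecord

__all__ = [
    "FamilySpec",
    "Family",
    "make_family",
    "make_contigs",
    "make_fov_counts",
    "random_gene",
]

_BASES = np.array(list("ACGT"))


def random_gene(length: int, gc: float = 50.0, seed: int | np.random.Generator = 0) -> str:
    """A random DNA sequence of the given length and expected GC content (%)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return "".join(rng.choice(_BASES, size=length, p=probs))


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic homolog family."""

    ancestor_length: int = 1350
    gc_percent: float = 50.0
    identity_targets: tuple[float, ...] = (95.0, 90.0, 85.0, 80.0, 75.0, 70.0)
    stretch_model: str = "uniform"  # or "clustered"
    mean_block_length: int = 12
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise InvalidParameterError("ancestor_length must be >= 1")
        if self.stretch_model not in {"uniform", "clustered"}:
            raise InvalidParameterError(f"unknown stretch_model {self.stretch_model!r}")
        for t in self.identity_targets:
            if not 0.0 < t <= 100.0:
                raise InvalidParameterError(f"identity target must be in (0, 100], got {t}")


@dataclass(frozen=True)
class Family:
    """A generated family: the ancestor and one homolog per identity target."""

    ancestor: SequenceRecord
    homologs: tuple[SequenceRecord, ...]
    realized_identities: tuple[float, ...]


def _substitute(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace each selected site with a uniformly chosen different base."""
    out = seq.copy()
    for i in sites:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _uniform_sites(length: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(length) < rate)


def _clustered_sites(length: int, rate: float, mean_block: int, rng: np.random.Generator) -> np.ndarray:
    """Substituted sites grouped into geometric blocks of mean ``mean_block``."""
    target = rate * length
    marked = np.zeros(length, dtype=bool)
    while marked.sum() < target:
        block = rng.geometric(1.0 / mean_block)
        start = rng.integers(0, length)
        marked[start : start + block] = True
    return np.flatnonzero(marked)


def make_family(spec: FamilySpec) -> Family:
    """Generate an ancestor and one homolog per identity target.

    Each homolog is derived by substituting sites at per-site rate
    ``(100 - target)/100``; in ``clustered`` mode substitutions are grouped
    into geometric blocks, which lengthens the mismatch stretches without
    changing the expected identity much.  Realized identities (to the
    ancestor, ungapped) are recorded in the sequence descriptions.
    """
    rng = np.random.default_rng(spec.seed)
    anc = np.array(list(random_gene(spec.ancestor_length, spec.gc_percent, rng)))
    homologs = []
    realized = []
    for j, target in enumerate(spec.identity_targets):
        rate = (100.0 - target) / 100.0
        if rate == 0.0:
            sites = np.empty(0, dtype=int)
        elif spec.stretch_model == "uniform":
            sites = _uniform_sites(spec.ancestor_length, rate, rng)
        else:
            sites = _clustered_sites(spec.ancestor_length, rate, spec.mean_block_length, rng)
        hom = _substitute(anc, sites, rng)
        if spec.indel_rate > 0.0:
            keep = rng.random(len(hom)) >= spec.indel_rate
            hom = hom[keep]
        ident = 100.0 * np.mean(hom[: len(anc)] == anc[: len(hom)]) if len(hom) else 0.0
        if spec.indel_rate == 0.0:
            ident = 100.0 * np.mean(hom == anc)
        realized.append(float(ident))
        homologs.append(
            SequenceRecord(
                id=f"homolog_{j + 1}_target{target:g}",
                sequence="".join(hom),
                description=f"target_identity={target:g} realized_identity={ident:.2f}",
            )
        )
    ancestor = SequenceRecord(id="ancestor", sequence="".join(anc), description="synthetic ancestor")
    return Family(ancestor=ancestor, homologs=tuple(homologs), realized_identities=tuple(realized))


# ---------------------------------------------------------------------------
# synthetic contigs with planted PUL cassettes
# ---------------------------------------------------------------------------

#: the planted ground-truth cassette: satisfies the PUL rule and the
#: glucuronomannan flag (susCD pair, two CAZymes, GH92 + sulfatase)
PUL_CASSETTE = ("susC-like", "susD-like", "GH92", "sulfatase", "GH16")

#: decoy cassettes that must NOT be called as PULs
DECOYS = (
    ("susC-like", "susD-like", "GH92"),  # only one degradative CAZyme
    ("GH92", "GH16", "sulfatase"),  # no susC/susD
    ("susC-like",),  # transporter alone
)


def make_contigs(
    n: int,
    pul_density: float = 0.5,
    seed: int = 0,
    genes_per_contig: int = 30,
    decoy_density: float = 0.3,
) -> tuple[list[GeneAnnotation], list[tuple[str, int]]]:
    """Synthetic annotated contigs with known ground-truth PUL positions.

    Each contig carries ``genes_per_contig`` genes labeled ``other``; with
    probability ``pul_density`` a :data:`PUL_CASSETTE` is planted at a random
    position (same strand, adjacent genes), and independently with
    probability ``decoy_density`` a rule-violating decoy.  Returns the
    annotation list (sorted by contig and start) and the ground truth as
    ``(contig_id, cassette_start_gene_index)`` pairs.
    """
    if not 0.0 <= pul_density <= 1.0:
        raise InvalidParameterError("pul_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    annotations: list[GeneAnnotation] = []
    truth: list[tuple[str, int]] = []
    for ci in range(n):
        contig_id = f"contig_{ci + 1}"
        labels = ["other"] * genes_per_contig
        planted: list[tuple[int, tuple[str, ...]]] = []

        def plant(cassette: tuple[str, ...]) -> int | None:
            # find a slot not overlapping previous plants
            for _ in range(50):
                pos = int(rng.integers(0, genes_per_contig - len(cassette) + 1))
                span = range(pos, pos + len(cassette))
                # keep >= 4 'other' genes between plants so separate cassettes can
                # never merge into one locus at the default intergenic tolerance (3)
                if all(
                    not (p - 4 <= q < p + len(cas) + 4) for q in span for p, cas in planted
                ):
                    planted.append((pos, cassette))
                    for off, lab in enumerate(cassette):
                        labels[pos + off] = lab
                    return pos
            return None

        if rng.random() < pul_density:
            pos = plant(PUL_CASSETTE)
            if pos is not None:
                truth.append((contig_id, pos))
        if rng.random() < decoy_density:
            plant(tuple(DECOYS[int(rng.integers(0, len(DECOYS)))]))

        cassette_strands = {p: ("+" if rng.random() < 0.5 else "-") for p, _ in planted}
        pos_bp = 0
        for gi, label in enumerate(labels):
            length = int(rng.integers(600, 2400))
            strand = "+" if rng.random() < 0.5 else "-"
            for p, cas in planted:
                if p <= gi < p + len(cas):
                    strand = cassette_strands[p]
            annotations.append(
                GeneAnnotation(
                    contig_id=contig_id,
                    gene_id=f"{contig_id}_g{gi + 1}",
                    start=pos_bp,
                    end=pos_bp + length,
                    strand=strand,
                    label=label,
                )
            )
            pos_bp += length + int(rng.integers(20, 200))
    return annotations, truth


def make_fov_counts(
    n_fovs: int,
    cells_per_fov_range: tuple[int, int] = (100, 400),
    true_fraction: float = 0.7,
    seed: int = 0,
) -> list[FOVCount]:
    """Binomial per-FOV counts at a known true positive fraction."""
    if not 0.0 <= true_fraction <= 1.0:
        raise InvalidParameterError("true_fraction must be in [0, 1]")
    lo, hi = cells_per_fov_range
    if not 1 <= lo <= hi:
        raise InvalidParameterError("cells_per_fov_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    fovs = []
    for i in range(n_fovs):
        total = int(rng.integers(lo, hi + 1))
        pos = int(rng.binomial(total, true_fraction))
        fovs.append(FOVCount(fov_id=f"fov_{i + 1}", total_cells=total, positive_cells=pos))
    return fovs
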