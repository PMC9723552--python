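"""Readers and writers with strict coordinate and strand conventions.

All coordinates are 0-based half-open internally; GenBank and GFF3 (1-based
closed) are converted at the format boundary.  Sequences are uppercased on
read, U is normalized to T, and IUPAC ambiguity codes other than N are mapped
to N with a warning (downstream alignment treats N as never matching).
"""

from __future__ import annotations

import difflib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AmbiguityWarning, ParseError

__all__ = [
    "SequenceRecord",
    "GeneTarget",
    "read_fasta",
    "write_fasta",
    "extract_gene",
    "read_annotation_tsv",
    "read_gff3",
    "read_genbank_annotations",
    "write_tsv",
    "write_json",
    "reverse_complement",
    "normalize_sequence",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_AMBIGUITY = set("RYSWKMBDHV")
_VALID = set("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase, U->T, non-N IUPAC ambiguity codes -> N (with warning)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    amb = bad & _AMBIGUITY
    if amb:
        warnings.warn(
            f"IUPAC ambiguity codes {sorted(amb)} mapped to N{' in ' + context if context else ''}",
            AmbiguityWarning,
            stacklevel=2,
        )
        s = "".join("N" if c in _AMBIGUITY else c for c in s)
        bad = set(s) - _VALID
    if bad:
        raise ParseError(f"non-DNA characters {sorted(bad)}{' in ' + context if context else ''}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, U normalized to T)."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneTarget:
    """A gene sequence in coding orientation, with optional source coordinates.

    ``source`` is ``(record_id, start, end, strand)`` with a 0-based half-open
    interval on the source record; minus-strand genes have already been
    reverse-complemented into coding orientation.
    """

    id: str
    sequence: str
    source: tuple[str, int, int, str] | None = None


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file; duplicate or empty records are parse errors."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), context=f"{path}:{rec.id}")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        # Distinguish "no > lines" from an empty file for a useful message.
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_gene(
    path,
    locus_tag: str | None = None,
    interval: tuple[int, int] | None = None,
    strand: str = "+",
    record_id: str | None = None,
) -> GeneTarget:
    """Extract a gene in coding orientation from GenBank (by locus tag) or FASTA (by interval).

    GenBank: the CDS/gene feature whose ``locus_tag`` qualifier matches is
    extracted with its own strand; an absent tag raises an error listing
    near-matches.  FASTA: ``interval`` is a 0-based half-open slice of the
    (first or named) record; ``strand == '-'`` reverse-complements the slice.
    """
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"} else "fasta"
    if fmt == "genbank":
        if locus_tag is None:
            raise ParseError("a locus_tag is required to extract a gene from GenBank")
        tags = []
        for rec in SeqIO.parse(str(path), "genbank"):
            for feat in rec.features:
                if feat.type not in {"CDS", "gene"}:
                    continue
                tag = feat.qualifiers.get("locus_tag", [None])[0]
                if tag is None:
                    continue
                tags.append(tag)
                if tag == locus_tag:
                    seq = normalize_sequence(str(feat.extract(rec.seq)), context=locus_tag)
                    start, end = int(feat.location.start), int(feat.location.end)
                    sstrand = "-" if feat.location.strand == -1 else "+"
                    return GeneTarget(id=locus_tag, sequence=seq, source=(rec.id, start, end, sstrand))
        near = difflib.get_close_matches(locus_tag, tags, n=5)
        raise ParseError(
            f"{path}: locus tag {locus_tag!r} not found"
            + (f"; near-matches: {', '.join(near)}" if near else "")
        )
    records = read_fasta(path)
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ParseError(f"{path}: record {record_id!r} not found")
        rec = matches[0]
    else:
        rec = records[0]
    if interval is None:
        interval = (0, len(rec.sequence))
    start, end = interval
    if not (0 <= start < end <= len(rec.sequence)):
        raise ParseError(f"interval {interval} out of bounds for record {rec.id!r} (len {len(rec.sequence)})")
    seq = rec.sequence[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ParseError(f"strand must be '+' or '-', got {strand!r}")
    gene_id = f"{rec.id}_{start}_{end}{'_rc' if strand == '-' else ''}"
    return GeneTarget(id=gene_id, sequence=seq, source=(rec.id, start, end, strand))


# ---------------------------------------------------------------------------
# annotation tables (for PUL screening)
# ---------------------------------------------------------------------------

#: substrings searched (case-insensitively) in product/Name text to assign a
#: functional label; first match wins, order matters.
DEFAULT_LABEL_PATTERNS: list[tuple[str, str]] = [
    ("susc", "susC-like"),
    ("tonb-dependent", "susC-like"),
    ("susd", "susD-like"),
    ("sulfatase", "sulfatase"),
    ("arylsulfatase", "sulfatase"),
]


def label_from_text(text: str, patterns: Sequence[tuple[str, str]] | None = None) -> str:
    """Map free annotation text to the controlled label vocabulary.

    Recognizes susC/susD-like genes, sulfatases and CAZyme family codes
    (``GH92``, ``PL17``, ...); anything else becomes ``other``.
    """
    import re

    t = text.strip()
    low = t.lower()
    for needle, label in (patterns or DEFAULT_LABEL_PATTERNS):
        if needle in low:
            return label
    m = re.search(r"\b(GH|PL)(\d+)\b", t, flags=re.IGNORECASE)
    if m:
        return f"{m.group(1).upper()}{int(m.group(2))}"
    return "other"


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a plain annotation table: contig, gene_id, start, end, strand, label.

    ``start``/``end`` are 0-based half-open as written.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "gene_id": str, "label": str})
    required = {"contig", "gene_id", "start", "end", "strand", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_gff3(path, label_patterns=None) -> pd.DataFrame:
    """Read gene/CDS features from GFF3 into the annotation-table schema.

    Labels are derived from the ``product`` (fallback ``Name``) attribute via
    :func:`label_from_text`; GFF3 1-based closed coordinates are converted to
    0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in {"gene", "CDS"}:
                continue
            attr = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attr[k.strip()] = v.strip()
            gene_id = attr.get("locus_tag") or attr.get("ID") or f"{seqid}_{lineno}"
            text = attr.get("product") or attr.get("Name") or ""
            rows.append(
                (seqid, gene_id, int(start) - 1, int(end), strand,
                 label_from_text(text, label_patterns))
            )
    if not rows:
        raise ParseError(f"{path}: no gene/CDS features found")
    return pd.DataFrame(rows, columns=["contig", "gene_id", "start", "end", "strand", "label"])


def read_genbank_annotations(path, label_patterns=None) -> pd.DataFrame:
    """Read CDS features (with sequences) from a GenBank file into the annotation schema."""
    rows = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            gene_id = feat.qualifiers.get("locus_tag", [f"{rec.id}_cds{i}"])[0]
            text = feat.qualifiers.get("product", [""])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            rows.append(
                (rec.id, gene_id, int(feat.location.start), int(feat.location.end), strand,
                 label_from_text(text, label_patterns), str(feat.extract(rec.seq)).upper())
            )
    if not rows:
        raise ParseError(f"{path}: no CDS features found")
    return pd.DataFrame(
        rows, columns=["contig", "gene_id", "start", "end", "strand", "label", "sequence"]
    )


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, float_format: str = "%.4f") -> None:
    """Deterministic TSV with a header line and fixed column order."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
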