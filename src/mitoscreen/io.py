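"""Domain types and readers/writers shared by the whole pipeline.

Internally every coordinate is 0-based half-open; everything written to or
read from disk is 1-based inclusive (GenBank convention).  Circular genomes
are stored linearized at an arbitrary origin; operations that must see
origin-spanning matches (the repeat module) handle the wrap explicitly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

FEATURE_TYPES = {
    "CDS", "rRNA", "tRNA", "exon", "intron", "pseudogene",
    "fragment", "repeat", "other",
}


class ParseError(ValueError):
    """A syntactically invalid record in an input file."""


class CoordinateError(ValueError):
    """A feature interval outside the bounds of its genome."""


@dataclass
class Genome:
    """A named nucleotide sequence, possibly circular, possibly multi-contig.

    ``contig_breaks`` are 0-based positions at which the linearized sequence
    is interrupted by assembly gaps (empty for a single contig).
    """

    id: str
    sequence: str
    circular: bool = False
    contig_breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"genome {self.id!r} contains non-DNA characters {sorted(bad)!r}"
            )
        if self.contig_breaks:
            if sorted(set(self.contig_breaks)) != list(self.contig_breaks):
                raise ValueError("contig_breaks must be strictly increasing")
            if self.contig_breaks[-1] >= len(self.sequence):
                raise ValueError("contig break beyond sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_contigs(self) -> int:
        return len(self.contig_breaks) + 1

    def slice(self, start: int, end: int) -> str:
        """Subsequence [start, end); wraps across the origin when circular."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise CoordinateError(f"[{start}, {end}) outside linear genome {self.id!r}")
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]


@dataclass
class Feature:
    """An annotated interval set: gene/exon/pseudogene/fragment/repeat/...

    ``intervals`` are 0-based half-open and sorted by start for cis features;
    trans features (pieces joined only at the RNA level) carry
    ``qualifiers["trans"] = "yes"`` and keep their biological piece order.
    """

    gene: str
    type: str
    intervals: list[tuple[int, int]]
    strand: str = "+"
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            self.qualifiers.setdefault("original_type", self.type)
            self.type = "other"
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.intervals:
            if not s < e:
                raise ValueError(f"empty interval ({s}, {e}) in {self.gene}")
        if self.qualifiers.get("trans") != "yes":
            self.intervals.sort(key=lambda iv: iv[0])

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    def span_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extract(self, g: Genome) -> str:
        """Spliced sequence of the feature on its coding strand.

        Cis features: concatenate genomic pieces left-to-right, then reverse
        complement the whole product if on the minus strand.  Trans features:
        pieces are already in transcript order, so each piece is oriented
        individually before joining.
        """
        parts = [g.slice(s, e) for s, e in self.intervals]
        if self.qualifiers.get("trans") == "yes":
            if self.strand == "-":
                parts = [revcomp(p) for p in parts]
            return "".join(parts)
        joined = "".join(parts)
        return revcomp(joined) if self.strand == "-" else joined


@dataclass
class ReadRecord:
    """A sequencing read; ``paired_with`` links mates of a pair."""

    id: str
    sequence: str
    qualities: list[int] | None = None
    paired_with: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ParseError(f"read {self.id!r}: quality/sequence length mismatch")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# sequence I/O


def read_sequences(path: str | Path, format: str = "fasta",
                   as_reads: bool = False) -> list[Genome] | list[ReadRecord]:
    """Read FASTA/FASTQ into Genome (default) or ReadRecord objects.

    Order is preserved, sequences are uppercased and U is mapped to T.
    An empty file yields an empty list.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    out: list = []
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = str(rec.seq)
            if format == "fastq" or as_reads:
                quals = rec.letter_annotations.get("phred_quality")
                out.append(ReadRecord(id=rec.id, sequence=seq,
                                      qualities=list(quals) if quals else None))
            else:
                out.append(Genome(id=rec.id, sequence=seq))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_sequences(records, path: str | Path, format: str = "fasta") -> None:
    recs = []
    for r in records:
        sr = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if format == "fastq":
            quals = getattr(r, "qualities", None)
            sr.letter_annotations["phred_quality"] = (
                quals if quals is not None else [40] * len(r.sequence))
        recs.append(sr)
    SeqIO.write(recs, str(path), format)


# ---------------------------------------------------------------------------
# feature I/O

_LOC_PART = re.compile(r"(\d+)\.\.(\d+)")


def parse_location(loc: str) -> tuple[list[tuple[int, int]], str]:
    """Decompose a GenBank-style location string into 0-based intervals + strand.

    Handles ``10..18``, ``join(...)`` and ``complement(...)`` nestings.
    """
    strand = "+"
    loc = loc.replace(" ", "")
    if loc.startswith("complement(") and loc.endswith(")"):
        strand = "-"
        loc = loc[len("complement("):-1]
    if loc.startswith("join(") and loc.endswith(")"):
        loc = loc[len("join("):-1]
    intervals = []
    for m in _LOC_PART.finditer(loc):
        a, b = int(m.group(1)), int(m.group(2))
        if a > b:
            raise ParseError(f"inverted interval in location {loc!r}")
        intervals.append((a - 1, b))  # 1-based inclusive -> 0-based half-open
    if not intervals:
        raise ParseError(f"cannot parse location {loc!r}")
    return intervals, strand


def format_location(intervals: list[tuple[int, int]], strand: str) -> str:
    parts = ",".join(f"{s + 1}..{e}" for s, e in intervals)
    if len(intervals) > 1:
        parts = f"join({parts})"
    return f"complement({parts})" if strand == "-" else parts


TSV_HEADER = ["seqid", "gene", "type", "start", "end", "strand", "qualifiers"]


def _qualifiers_to_str(q: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in q.items()) if q else "."


def _qualifiers_from_str(s: str) -> dict[str, str]:
    if not s or s == ".":
        return {}
    out = {}
    for item in s.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_features(path: str | Path, dialect: str = "feature_tsv",
                  genome_length: int | None = None) -> list[Feature]:
    """Read features from the TSV dialect or a GenBank flat file subset.

    File coordinates are 1-based inclusive in both dialects and are converted
    to internal 0-based half-open intervals.
    """
    path = Path(path)
    if dialect == "feature_tsv":
        feats = _read_feature_tsv(path)
    elif dialect == "genbank_flat":
        feats = _read_genbank_features(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if genome_length is not None:
        for f in feats:
            if f.end > genome_length or f.start < 0:
                raise CoordinateError(
                    f"feature {f.gene!r} interval beyond genome length {genome_length}")
    return feats


def _read_feature_tsv(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(TSV_HEADER)] != TSV_HEADER:
            raise ParseError(f"{path}: bad feature TSV header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns")
            _, gene, ftype, start, end, strand, quals = cols[:7]
            starts = [int(x) for x in start.split(",")]
            ends = [int(x) for x in end.split(",")]
            if len(starts) != len(ends):
                raise ParseError(f"{path}:{lineno}: start/end count mismatch")
            intervals = [(s - 1, e) for s, e in zip(starts, ends)]
            feats.append(Feature(gene=gene, type=ftype, intervals=intervals,
                                 strand=strand,
                                 qualifiers=_qualifiers_from_str(quals)))
    return feats


_GB_TYPE_MAP = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "exon": "exon",
                "intron": "intron", "repeat_region": "repeat"}


def _read_genbank_features(path: Path) -> list[Feature]:
    feats = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for gf in rec.features:
            if gf.type in ("source", "gene"):
                continue
            ftype = _GB_TYPE_MAP.get(gf.type, "other")
            gene = gf.qualifiers.get("gene", gf.qualifiers.get("label", ["?"]))[0]
            strand = "-" if (gf.location.strand or 1) < 0 else "+"
            intervals = [(int(p.start), int(p.end)) for p in gf.location.parts]
            quals = {k: v[0] for k, v in gf.qualifiers.items()
                     if k not in ("translation",)}
            if gf.qualifiers.get("pseudo") is not None or "pseudo" in gf.qualifiers:
                ftype = "pseudogene"
            if gene.endswith("_frag"):
                ftype = "fragment" if ftype in ("other", "CDS") else ftype
            feats.append(Feature(gene=gene, type=ftype, intervals=intervals,
                                 strand=strand, qualifiers=quals))
    return feats


def write_features(feats: list[Feature], path: str | Path,
                   seqid: str = ".") -> None:
    """Write the feature TSV dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for f in feats:
            starts = ",".join(str(s + 1) for s, _ in f.intervals)
            ends = ",".join(str(e) for _, e in f.intervals)
            fh.write("\t".join([seqid, f.gene, f.type, starts, ends, f.strand,
                                _qualifiers_to_str(f.qualifiers)]) + "\n")


# ---------------------------------------------------------------------------
# summary statistics


def genome_stats(g: Genome) -> dict:
    """Length, GC percent (N excluded from the denominator) and contig count."""
    seq = g.sequence
    counts = {b: seq.count(b) for b in "ACGTN"}
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        gc = None  # all-N sequence: GC undefined, flagged as None
    else:
        gc = round(100.0 * (counts["G"] + counts["C"]) / denom, 1)
    return {"length_bp": len(seq), "gc_percent": gc, "n_contigs": g.n_contigs}
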