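"""Genome records, GenBank/FASTA I/O, proteome extraction.

Coordinate conventions used throughout the package:

* intervals are 0-based half-open ``[start, end)``; strand is ``+1``/``-1``
* GenBank 1-based inclusive coordinates are converted on read and restored
  on write
* features wrapping the origin of a circular record carry
  ``end > len(sequence)`` and are resolved modulo the length
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "repeat", "misc")

_GENBANK_KIND_MAP = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "repeat_region": "repeat",
}
_KIND_GENBANK_MAP = {"repeat": "repeat_region"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenBankParseError(ValueError):
    """Raised for structurally invalid GenBank input (names the offending line)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """An annotated element on a genome.

    ``end > genome length`` flags a feature wrapping the origin of a
    circular record; such intervals are resolved modulo the length.
    """

    kind: str
    start: int
    end: int
    strand: int = 1
    qualifiers: dict = field(default_factory=dict)
    codon_table_id: int = 11

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def extract(self, sequence: str) -> str:
        """Feature sequence in reading orientation (strand applied)."""
        n = len(sequence)
        if self.end <= n:
            sub = sequence[self.start : self.end]
        else:
            sub = sequence[self.start :] + sequence[: self.end - n]
        return revcomp(sub) if self.strand == -1 else sub


@dataclass
class GenomeRecord:
    """One replicon: sequence, topology, and sorted annotated features."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)
    description: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-DNA symbols: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if f.wraps(n) and self.topology != "circular":
                raise ValueError(
                    f"feature [{f.start}, {f.end}) wraps a linear record of length {n}"
                )
            if f.start >= n:
                raise ValueError(f"feature start {f.start} outside [0, {n})")
        self.features.sort(key=lambda f: f.start)  # stable for ties

    def __len__(self) -> int:
        return len(self.sequence)

    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass
class ProteinRecord:
    """A translated CDS; the unit of the divergence tabulation."""

    id: str
    gene_index: int
    aa_sequence: str
    genome_id: str
    start: int
    end: int
    strand: int
    locus_tag: str = ""
    product: str = ""
    possible_frameshift: bool = False

    def __len__(self) -> int:
        return len(self.aa_sequence)


def rotate(g: GenomeRecord, offset: int) -> GenomeRecord:
    """Rotate a record so that position ``offset`` becomes the new origin.

    Explicit alternative to implicit circular-permutation matching; features
    that come to span the new origin are represented as wrapping intervals
    (circular records only).
    """
    n = len(g)
    offset %= n
    if offset == 0:
        return g
    seq = g.sequence[offset:] + g.sequence[:offset]
    feats = []
    for f in g.features:
        start = (f.start - offset) % n
        end = start + len(f)
        if end > n and g.topology != "circular":
            raise ValueError("rotation would wrap a feature on a linear record")
        feats.append(
            Feature(f.kind, start, end, f.strand, dict(f.qualifiers), f.codon_table_id)
        )
    return GenomeRecord(g.id, seq, g.topology, feats, g.description)


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_ORIGIN_LINE = re.compile(r"^\s*\d+(?:\s+[A-Za-z]+)+\s*$")


def _validate_origin(path: Path) -> None:
    in_origin = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if stripped.startswith("ORIGIN"):
                in_origin = True
                continue
            if stripped.startswith("//"):
                in_origin = False
                continue
            if in_origin and stripped.strip():
                if not _ORIGIN_LINE.match(stripped):
                    raise GenBankParseError(
                        f"malformed ORIGIN data at line {lineno}: {stripped.strip()!r}"
                    )


def _location_to_interval(loc, seq_len: int, circular: bool) -> tuple[int, int, int]:
    """Convert a Biopython location to (start, end, strand), wrapping joins."""
    strand = -1 if loc.strand == -1 else 1
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        first, last = parts[0], parts[-1]
        if circular and len(parts) == 2 and int(last.end) == seq_len and int(first.start) == 0:
            # join(X..len, 1..Y): wraps the origin
            return int(last.start), seq_len + int(first.end), strand
        return int(min(int(p.start) for p in parts)), int(max(int(p.end) for p in parts)), strand
    return int(loc.start), int(loc.end), strand


def read_genbank(path) -> list[GenomeRecord]:
    """Parse a GenBank flat file into :class:`GenomeRecord` objects.

    1-based inclusive locations become 0-based half-open; ``complement()``
    sets strand -1; origin-spanning ``join()`` on circular records becomes a
    wrapping interval.  A CDS whose ``/translation`` length disagrees with
    its location by more than the terminal stop is recorded as a warning on
    the record; the location is trusted.
    """
    path = Path(path)
    _validate_origin(path)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        seq = str(rec.seq).upper()
        feats: list[Feature] = []
        warnings: list[str] = []
        for sf in rec.features:
            kind = _GENBANK_KIND_MAP.get(sf.type)
            if kind is None:
                if sf.type in ("source", "gene"):
                    continue
                kind = "misc"
            start, end, strand = _location_to_interval(
                sf.location, len(seq), topology == "circular"
            )
            quals = {k: "; ".join(v) for k, v in sf.qualifiers.items()}
            table = int(quals.get("transl_table", 11)) if kind == "CDS" else 11
            feat = Feature(kind, start, end, strand, quals, table)
            if kind == "CDS" and "translation" in quals:
                nt_len = end - start
                expect = nt_len // 3 - 1  # minus terminal stop
                got = len(quals["translation"].replace("; ", ""))
                if abs(got - expect) > 1:
                    warnings.append(
                        f"CDS {quals.get('locus_tag', f'@{start}')}: translation length "
                        f"{got} disagrees with location ({nt_len} nt); location trusted"
                    )
            feats.append(feat)
        records.append(
            GenomeRecord(rec.id or rec.name, seq, topology, feats, rec.description, warnings)
        )
    if not records:
        raise GenBankParseError(f"no GenBank records found in {path}")
    return records


def _interval_to_location(f: Feature, seq_len: int) -> SimpleLocation | CompoundLocation:
    strand = f.strand
    if f.end <= seq_len:
        return SimpleLocation(f.start, f.end, strand=strand)
    # wrapping: emit join(start..len, 1..end-len)
    part1 = SimpleLocation(f.start, seq_len, strand=strand)
    part2 = SimpleLocation(0, f.end - seq_len, strand=strand)
    if strand == -1:
        return CompoundLocation([part2, part1])
    return CompoundLocation([part1, part2])


def write_genbank(records: Iterable[GenomeRecord], path) -> None:
    """Emit records as a GenBank flat file (coordinates back to 1-based)."""
    seqrecs = []
    for g in records:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id.split(".")[0][:16],
                        description=g.description)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = g.topology
        for f in g.features:
            quals = {k: [v] for k, v in f.qualifiers.items()}
            if f.kind == "CDS":
                quals.setdefault("transl_table", [str(f.codon_table_id)])
            sf = SeqFeature(
                _interval_to_location(f, len(g)),
                type=_KIND_GENBANK_MAP.get(f.kind, f.kind if f.kind != "misc" else "misc_feature"),
                qualifiers=quals,
            )
            rec.features.append(sf)
        seqrecs.append(rec)
    SeqIO.write(seqrecs, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    """Write (header, sequence) pairs, wrapping at ``width`` columns."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_proteome_fasta(proteins: Iterable[ProteinRecord], path) -> None:
    """Per-proteome FASTA with ``<genome_id>|<locus_tag>|<gene_index>`` headers."""
    write_fasta(
        ((f"{p.genome_id}|{p.locus_tag}|{p.gene_index}", p.aa_sequence) for p in proteins),
        path,
    )


# ---------------------------------------------------------------------------
# Proteome extraction & composition
# ---------------------------------------------------------------------------


def extract_proteome(g: GenomeRecord) -> list[ProteinRecord]:
    """Translate every CDS of ``g`` in gene order.

    Minus-strand CDS are reverse-complemented before translation.  A CDS
    whose length is not divisible by 3 is translated over its longest
    in-frame prefix and flagged ``possible_frameshift`` (likewise a CDS with
    an internal stop, which is truncated at that stop).
    """
    cds = g.cds()
    if not cds:
        raise ValueError(f"genome {g.id} has no CDS features")
    proteins: list[ProteinRecord] = []
    for idx, f in enumerate(cds):
        nt = f.extract(g.sequence)
        flagged = False
        if len(nt) % 3 != 0:
            nt = nt[: len(nt) - len(nt) % 3]
            flagged = True
        aa = str(Seq(nt).translate(table=f.codon_table_id))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:  # internal stop: pseudogene-like, truncate
            aa = aa.split("*", 1)[0]
            flagged = True
        locus = f.qualifiers.get("locus_tag", f"cds{idx:03d}")
        proteins.append(
            ProteinRecord(
                id=f"{g.id}|{locus}",
                gene_index=idx,
                aa_sequence=aa,
                genome_id=g.id,
                start=f.start,
                end=f.end,
                strand=f.strand,
                locus_tag=locus,
                product=f.qualifiers.get("product", ""),
                possible_frameshift=flagged,
            )
        )
    return proteins


def gc_content(g: GenomeRecord | str) -> float:
    """G+C percentage over A/C/G/T (N excluded), rounded to one decimal."""
    seq = g.sequence if isinstance(g, GenomeRecord) else g.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("G+C content undefined: no A/C/G/T bases")
    return round(100.0 * (counts["G"] + counts["C"]) / denom, 1)
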