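"""Near-identical genome differencing, pileup allele fractions, and a
sigma-70 consensus promoter scan.

``diff_genomes`` is for genome pairs that are expected to be nearly
identical (>= 95%); variants are reported against the first genome's
coordinates and annotations, optionally flagged by named region masks (the
canonical mask being the antireceptor gene plus its variable region, which
soaks up hypermutation-driven differences).  The promoter scan is a
transparent consensus search (TTGACA ... spacer ... TATAAT) standing in for
opaque promoter predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from phagemosaic.genome_io import Feature, GenomeRecord, revcomp

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


@dataclass
class Variant:
    position: int  # 0-based on genome a
    ref: str
    alt: str
    type: str  # substitution | insertion | deletion
    in_mask: bool = False
    mask_name: str = ""
    effect: str = "NONE"  # intergenic | synonymous | missense | nonsense | frameshift | NONE


@dataclass
class DiffReport:
    genome_a_id: str
    genome_b_id: str
    variants: list[Variant]
    masks: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_outside_mask(self) -> int:
        return sum(1 for v in self.variants if not v.in_mask)


@dataclass
class SiteAlleleFractions:
    sites: list[dict]  # position, counts, minor_fraction, excluded
    min_minor_fraction: Optional[float] = None
    max_minor_fraction: Optional[float] = None


@dataclass
class PromoterHit:
    start: int  # region coordinates; interval covers -35 through -10
    end: int
    strand: int
    minus35_sequence: str
    minus10_sequence: str
    spacer_len: int
    mismatch_count: int
    opposing: bool = False


# ---------------------------------------------------------------------------
# Genome differencing
# ---------------------------------------------------------------------------

_gap_fill_aligner = None


def _get_gap_aligner() -> Align.PairwiseAligner:
    global _gap_fill_aligner
    if _gap_fill_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -3
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _gap_fill_aligner = a
    return _gap_fill_aligner


def _chain_anchors(a: str, b: str, k: int = 21) -> list[tuple[int, int, int]]:
    """Co-linear chain of unique shared k-mer anchors (a_pos, b_pos, length),
    merged when contiguous."""
    index: dict[str, int] = {}
    dropped: set[str] = set()
    for i in range(len(a) - k + 1):
        kmer = a[i : i + k]
        if kmer in dropped:
            continue
        if kmer in index:
            del index[kmer]
            dropped.add(kmer)
        else:
            index[kmer] = i
    seen_b: dict[str, int] = {}
    dup_b: set[str] = set()
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        if kmer in dup_b:
            continue
        if kmer in seen_b:
            del seen_b[kmer]
            dup_b.add(kmer)
        else:
            seen_b[kmer] = j
    pairs = sorted(
        (i, seen_b[kmer])
        for kmer, i in index.items()
        if kmer in seen_b
    )
    # longest increasing (in b) chain with consistent diagonals, greedy since
    # genomes are near-identical
    chain: list[tuple[int, int, int]] = []
    last_a = last_b = -1
    for i, j in pairs:
        if i <= last_a or j <= last_b:
            continue
        if chain and i - chain[-1][0] == j - chain[-1][1] and i <= chain[-1][0] + chain[-1][2]:
            ai, bj, ln = chain[-1]
            chain[-1] = (ai, bj, i + k - ai)
        else:
            chain.append((i, j, k))
        last_a, last_b = i, j
    return chain


def _align_genomes(a: str, b: str) -> tuple[str, str]:
    """Anchored global alignment of two near-identical sequences."""
    chain = _chain_anchors(a, b)
    if not chain:
        raise ValueError("no shared anchors: sequences too diverged to diff")
    out_a: list[str] = []
    out_b: list[str] = []
    pa = pb = 0
    aligner = _get_gap_aligner()

    def fill(sa: str, sb: str) -> None:
        if not sa and not sb:
            return
        if not sa:
            out_a.append("-" * len(sb))
            out_b.append(sb)
        elif not sb:
            out_a.append(sa)
            out_b.append("-" * len(sa))
        elif sa == sb:
            out_a.append(sa)
            out_b.append(sb)
        else:
            aln = aligner.align(sa, sb)[0]
            out_a.append(str(aln[0]))
            out_b.append(str(aln[1]))

    for ai, bj, ln in chain:
        # adjacent anchors may overlap on one sequence when an indel placement
        # is ambiguous; trim the later anchor
        delta = max(pa - ai, pb - bj, 0)
        ai, bj, ln = ai + delta, bj + delta, ln - delta
        if ln <= 0:
            continue
        fill(a[pa:ai], b[pb:bj])
        out_a.append(a[ai : ai + ln])
        out_b.append(b[bj : bj + ln])
        pa, pb = ai + ln, bj + ln
    fill(a[pa:], b[pb:])
    return "".join(out_a), "".join(out_b)


def _percent_identity_of_alignment(aa: str, ab: str) -> float:
    ident = sum(1 for x, y in zip(aa, ab) if x == y and x != "-")
    return 100.0 * ident / len(aa)


def _classify_substitution(g: GenomeRecord, pos: int, alt: str) -> str:
    for f in g.cds():
        if f.start <= pos < f.end:
            nt = list(f.extract(g.sequence))
            if f.strand == 1:
                off = pos - f.start
                nt[off] = alt
            else:
                off = f.end - 1 - pos
                nt[off] = revcomp(alt)
            off -= off % 3
            codon_old = f.extract(g.sequence)[off : off + 3]
            codon_new = "".join(nt[off : off + 3])
            if len(codon_new) < 3:
                return "NONE"
            aa_old = str(Seq(codon_old).translate(table=f.codon_table_id))
            aa_new = str(Seq(codon_new).translate(table=f.codon_table_id))
            if aa_new == aa_old:
                return "synonymous"
            if aa_new == "*":
                return "nonsense"
            return "missense"
    return "intergenic"


def _classify_indel(g: GenomeRecord, pos: int, length: int) -> str:
    for f in g.cds():
        if f.start <= pos < f.end:
            return "frameshift" if length % 3 != 0 else "NONE"
    return "intergenic"


def diff_genomes(
    a: GenomeRecord,
    b: GenomeRecord,
    masks: Sequence[tuple[str, int, int]] = (),
    min_identity: float = 95.0,
) -> DiffReport:
    """Variant list between two near-identical genomes, on a's coordinates.

    Substitutions get a codon-level effect call against a's CDS annotations;
    indels inside a CDS whose length is not a multiple of 3 are frameshifts.
    Raises when overall identity falls below ``min_identity`` (use the
    identity profiler for genuinely diverged genomes).
    """
    aa, ab = _align_genomes(a.sequence, b.sequence)
    ident = _percent_identity_of_alignment(aa, ab)
    if ident < min_identity:
        raise ValueError(
            f"genomes are only {ident:.1f}% identical; diff_genomes expects "
            f">= {min_identity}% (use identity_profile for diverged genomes)"
        )
    variants: list[Variant] = []
    pos_a = 0  # position of the next a base
    i = 0
    ncol = len(aa)
    while i < ncol:
        x, y = aa[i], ab[i]
        if x != "-" and y != "-":
            if x != y:
                variants.append(Variant(pos_a, x, y, "substitution"))
            pos_a += 1
            i += 1
            continue
        # group a run of gap columns into one indel event
        j = i
        ins_b = []
        del_a = []
        while j < ncol and (aa[j] == "-" or ab[j] == "-"):
            if aa[j] == "-":
                ins_b.append(ab[j])
            else:
                del_a.append(aa[j])
            j += 1
        anchor = max(pos_a - 1, 0)
        if del_a and not ins_b:
            variants.append(Variant(anchor, "".join(del_a), "", "deletion"))
        elif ins_b and not del_a:
            variants.append(Variant(anchor, "", "".join(ins_b), "insertion"))
        else:  # mixed run: substitution block with length change
            kind = "deletion" if len(del_a) > len(ins_b) else "insertion"
            variants.append(Variant(anchor, "".join(del_a), "".join(ins_b), kind))
        pos_a += len(del_a)
        i = j
    for v in variants:
        for name, s, e in masks:
            if s <= v.position < e:
                v.in_mask = True
                v.mask_name = name
                break
        if v.type == "substitution":
            v.effect = _classify_substitution(a, v.position, v.alt)
        else:
            length = abs(len(v.ref) - len(v.alt))
            v.effect = _classify_indel(a, v.position, length)
    variants.sort(key=lambda v: v.position)
    return DiffReport(a.id, b.id, variants, list(masks))


def antireceptor_mask(
    g: GenomeRecord, vr_interval: Optional[tuple[int, int]] = None
) -> tuple[str, int, int]:
    """Default "antireceptor" mask: the annotated antireceptor CDS extended
    over the variable region when one is supplied."""
    for f in g.cds():
        product = f.qualifiers.get("product", "").lower()
        if "antireceptor" in product or "tail fiber" in product or "tail fibre" in product:
            s, e = f.start, f.end
            if vr_interval is not None:
                s, e = min(s, vr_interval[0]), max(e, vr_interval[1])
            return ("antireceptor", s, e)
    raise ValueError(f"no antireceptor/tail fiber CDS annotated on {g.id}")


def write_vcf(report: DiffReport, path) -> None:
    """Minimal 8-column VCF (positions 1-based; INFO carries mask/effect)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=phagemosaic diff {report.genome_a_id} vs {report.genome_b_id}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in report.variants:
            pos = v.position + 1
            ref, alt = v.ref or ".", v.alt or "."
            info = f"TYPE={v.type};EFFECT={v.effect}"
            if v.in_mask:
                info += f";MASK={v.mask_name}"
            fh.write(f"{report.genome_a_id}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# Pileup allele fractions
# ---------------------------------------------------------------------------


def read_pileup_tsv(path) -> pd.DataFrame:
    """Pileup dialect: columns pos, A, C, G, T, N (tab-separated, 0-based pos)."""
    df = pd.read_csv(path, sep="\t")
    required = {"pos", "A", "C", "G", "T", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    return df


def allele_fractions(
    pileup: pd.DataFrame, sites: Sequence[tuple[int, str]]
) -> SiteAlleleFractions:
    """Fraction of reads carrying the designated alternate allele per site.

    ``sites`` is (position, alt_base) pairs.  Zero-coverage sites are
    flagged and excluded from the min/max summary.
    """
    by_pos = pileup.set_index("pos")
    rows = []
    fractions = []
    for pos, alt in sites:
        if pos not in by_pos.index:
            rows.append({"position": pos, "counts": {}, "minor_fraction": None,
                         "excluded": True})
            continue
        counts = {b: int(by_pos.loc[pos, b]) for b in "ACGTN"}
        total = sum(counts.values())
        if total == 0:
            rows.append({"position": pos, "counts": counts, "minor_fraction": None,
                         "excluded": True})
            continue
        frac = counts.get(alt.upper(), 0) / total
        fractions.append(frac)
        rows.append({"position": pos, "counts": counts, "minor_fraction": frac,
                     "excluded": False})
    return SiteAlleleFractions(
        sites=rows,
        min_minor_fraction=min(fractions) if fractions else None,
        max_minor_fraction=max(fractions) if fractions else None,
    )


# ---------------------------------------------------------------------------
# sigma-70 consensus promoter scan
# ---------------------------------------------------------------------------


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def promoter_scan(
    region: str,
    offset: int = 0,
    max_mismatches: int = 3,
    spacer_range: tuple[int, int] = (15, 19),
) -> list[PromoterHit]:
    """Scan both strands for TTGACA ... spacer ... TATAAT.

    Total mismatches (Hamming to the -35 plus Hamming to the -10 consensus)
    must be <= ``max_mismatches`` with the spacer length in
    ``spacer_range``.  Hits are sorted by mismatch count then position;
    overlapping hits on opposite strands (a promoter firing into an opposing
    promoter) are flagged ``opposing``.  Coordinates are region-relative
    plus ``offset``, always on the forward strand.
    """
    region = region.upper()
    n = len(region)
    if n < 35:
        return []
    hits: list[PromoterHit] = []
    for strand, seq in ((1, region), (-1, revcomp(region))):
        for start in range(0, n - 12 + 1):
            m35 = seq[start : start + 6]
            if len(m35) < 6:
                break
            mm35 = _hamming(m35, MINUS35)
            if mm35 > max_mismatches:
                continue
            for spacer in range(spacer_range[0], spacer_range[1] + 1):
                p10 = start + 6 + spacer
                m10 = seq[p10 : p10 + 6]
                if len(m10) < 6:
                    continue
                mm = mm35 + _hamming(m10, MINUS10)
                if mm > max_mismatches:
                    continue
                s, e = start, p10 + 6
                if strand == -1:
                    s, e = n - e, n - s
                hits.append(
                    PromoterHit(
                        start=s + offset,
                        end=e + offset,
                        strand=strand,
                        minus35_sequence=m35,
                        minus10_sequence=m10,
                        spacer_len=spacer,
                        mismatch_count=mm,
                    )
                )
    hits.sort(key=lambda h: (h.mismatch_count, h.start, -h.strand))
    for i, h in enumerate(hits):
        for g in hits:
            if g is not h and g.strand != h.strand and g.start < h.end and h.start < g.end:
                h.opposing = True
                break
    return hits
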