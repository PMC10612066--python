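"""Prophage location, attL/attR core detection, and disrupted-gene
reconstruction checks.

Integration by site-specific recombination duplicates the att core: one
copy (attL) spans the left prophage boundary and the other (attR) the
right.  When the prophage lands inside a host gene, the phage arm adjacent
to one junction may carry sequence that reconstructs the gene's 5' end, so
the gene remains expressible in the lysogen under a phage promoter.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from phagemosaic.genome_io import Feature, GenomeRecord, revcomp

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class ProphageLocus:
    """An integrated copy of a phage genome on a host replicon."""

    host_genome_id: str
    start: int
    end: int
    matched_phage_id: str
    strand: int = 1
    phage_origin_offset: int = 0  # rotation relating phage record start to prophage left end
    mean_identity: float = 0.0

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReconstructionReport:
    """Frame/terminator analysis of a disrupted gene across an att junction."""

    frame_open: bool
    start_position: Optional[int] = None  # host coordinate of the reconstructing start
    start_codon: Optional[str] = None
    frame_break_offset: Optional[int] = None
    terminator_offset: Optional[int] = None  # nt past the junction in the circular phage
    promoter_region: Optional[tuple[int, int]] = None  # candidate region, coordinates only
    notes: str = ""


@dataclass
class AttSite:
    """attL/attR direct-repeat cores flanking a prophage."""

    core_sequence: str
    attL_interval: tuple[int, int]
    attR_interval: tuple[int, int]
    n_core_mismatches: int
    disrupted_gene: Optional[Feature] = None
    reconstruction_report: Optional[ReconstructionReport] = None


# ---------------------------------------------------------------------------
# Prophage location
# ---------------------------------------------------------------------------


def _anchor_positions(host: str, phage: str, k: int) -> list[tuple[int, int]]:
    """(host_pos, phage_pos) for every exact shared k-mer (phage k-mers kept
    only when unique within the phage)."""
    index: dict[str, int] = {}
    dropped: set[str] = set()
    for i in range(len(phage) - k + 1):
        kmer = phage[i : i + k]
        if kmer in dropped:
            continue
        if kmer in index:
            del index[kmer]
            dropped.add(kmer)
        else:
            index[kmer] = i
    anchors = []
    for h in range(len(host) - k + 1):
        p = index.get(host[h : h + k])
        if p is not None:
            anchors.append((h, p))
    return anchors


def _cluster_loci(
    anchors: list[tuple[int, int]], phage_len: int, k: int
) -> list[dict]:
    """Group anchors into candidate loci, merging the two diagonals produced
    by one circular rotation of the phage."""
    if not anchors:
        return []
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for h, p in anchors:
        by_diag.setdefault(h - p, []).append((h, p))
    diags = sorted(by_diag)
    # merge diagonals within a small slop (indels) and those offset by ~phage_len
    groups: list[list[int]] = []
    for d in diags:
        placed = False
        for grp in groups:
            if any(abs(d - e) <= 20 or abs(abs(d - e) - phage_len) <= 20 for e in grp):
                grp.append(d)
                placed = True
                break
        if not placed:
            groups.append([d])
    loci = []
    for grp in groups:
        pts = [pt for d in grp for pt in by_diag[d]]
        hmin = min(h for h, _ in pts)
        hmax = max(h for h, _ in pts) + k
        # phage position aligned with the leftmost host anchor = rotation offset
        offset = min(pts)[1]
        loci.append({"start": hmin, "end": hmax, "offset": offset,
                     "coverage": len(pts)})
    return loci


def locate_prophage(
    host: GenomeRecord,
    phage: GenomeRecord,
    min_identity: float = 95.0,
    k: int = 31,
) -> list[ProphageLocus]:
    """Find near-identical integrated copies of ``phage`` in ``host``.

    Exact k-mer anchors (k=31 by default) are clustered into co-linear loci
    in both orientations, allowing one circular rotation of the phage; the
    reported rotation offset maps the phage record start onto the prophage
    left end.  Loci covering < 50% of the phage length or below
    ``min_identity`` are dropped.
    """
    if len(host) < len(phage):
        raise ValueError("host shorter than phage")
    results = []
    for strand, phage_seq in ((1, phage.sequence), (-1, revcomp(phage.sequence))):
        anchors = _anchor_positions(host.sequence, phage_seq, k)
        for locus in _cluster_loci(anchors, len(phage), k):
            span = locus["end"] - locus["start"]
            if span > len(phage):
                # anchor bleed past the right junction (att-core duplication
                # re-matches k-mers spanning the phage origin): clip
                locus["end"] = locus["start"] + len(phage)
                span = len(phage)
            if span < 0.5 * len(phage) or span > 1.1 * len(phage):
                continue
            host_seg = host.sequence[locus["start"] : locus["end"]]
            rot = phage_seq[locus["offset"] :] + phage_seq[: locus["offset"]]
            n = min(len(host_seg), len(rot))
            ident = 100.0 * sum(
                1 for a, b in zip(host_seg[:n], rot[:n]) if a == b
            ) / n
            if ident < min_identity:
                continue
            offset = locus["offset"] if strand == 1 else (len(phage) - locus["offset"]) % len(phage)
            results.append(
                ProphageLocus(
                    host_genome_id=host.id,
                    start=locus["start"],
                    end=locus["end"],
                    matched_phage_id=phage.id,
                    strand=strand,
                    phage_origin_offset=offset,
                    mean_identity=ident,
                )
            )
    results.sort(key=lambda l: (l.start, -l.mean_identity))
    return results


# ---------------------------------------------------------------------------
# att core detection
# ---------------------------------------------------------------------------


def find_att(
    host: GenomeRecord,
    locus: ProphageLocus,
    flank: int = 500,
    min_core: int = 12,
    max_mismatch: int = 2,
    slop: int = 15,
) -> Optional[AttSite]:
    """Direct repeat with one copy spanning each prophage boundary.

    Compares the two junction neighborhoods at every relative offset;
    candidate cores are mismatch-delimited runs with <= ``max_mismatch``
    internal mismatches whose copies come within ``slop`` bp of their
    boundary, ranked by length minus a mismatch penalty (so a clean core is
    never beaten by a junk-extended one); prophage ends are thereby refined
    around the duplicated core.  Returns None when no repeat reaches
    ``min_core`` (core-less integration is possible in principle).
    """
    seq = host.sequence
    b1, b2 = locus.start, locus.end
    lo1, hi1 = max(0, b1 - flank), min(len(seq), b1 + flank)
    lo2, hi2 = max(0, b2 - flank), min(len(seq), b2 + flank)
    left = seq[lo1:hi1]
    right = seq[lo2:hi2]
    la = np.frombuffer(left.encode(), dtype=np.uint8)
    ra = np.frombuffer(right.encode(), dtype=np.uint8)
    c1 = b1 - lo1  # boundary index within each window
    c2 = b2 - lo2
    # (score, length, -mismatches, startL, rel)
    best: Optional[tuple[float, int, int, int, int]] = None
    max_shift = flank // 2
    for shift in range(-max_shift, max_shift + 1):
        # left[i] pairs with right[i + rel]
        rel = (c2 - c1) + shift
        i0 = max(0, -rel)
        i1 = min(len(left), len(right) - rel)
        if i1 - i0 < min_core:
            continue
        mism = (np.nonzero(la[i0:i1] != ra[i0 + rel : i1 + rel])[0] + i0).tolist()
        delim = [i0 - 1, *mism, i1]  # sentinels delimit mismatch-free ends
        cover_a, cover_b = c1, c1 - shift
        # only runs whose left copy comes within slop of its boundary matter
        u_lo = max(0, bisect.bisect_left(delim, cover_a - slop) - (max_mismatch + 2))
        u_hi = min(len(delim) - 1, bisect.bisect_right(delim, cover_a + slop) + 1)
        for u in range(u_lo, u_hi):
            for v in range(u + 1, min(u + max_mismatch + 2, len(delim))):
                s, e = delim[u] + 1, delim[v]
                length = e - s
                if length < min_core:
                    continue
                # each copy must come within slop of its boundary
                if not (s - slop <= cover_a <= e + slop):
                    continue
                if not (s - slop <= cover_b <= e + slop):
                    continue
                nm = v - u - 1
                score = length - 4 * nm
                key = (score, length, -nm, -s)
                if best is None or key > (best[0], best[1], best[2], -best[3]):
                    best = (score, length, -nm, s, rel)
    if best is None:
        return None
    _, length, neg_nm, sl, rel = best
    nm = -neg_nm
    sr = sl + rel
    attL = (lo1 + sl, lo1 + sl + length)
    attR = (lo2 + sr, lo2 + sr + length)
    core = seq[attL[0] : attL[1]]
    disrupted = _overlapping_gene(host, attL, attR, (locus.start, locus.end))
    site = AttSite(core, attL, attR, nm, disrupted_gene=disrupted)
    if disrupted is not None:
        try:
            site.reconstruction_report = check_reconstruction(host, site, locus)
        except ValueError:
            site.reconstruction_report = None
    return site


def _overlapping_gene(
    host: GenomeRecord,
    attL: tuple[int, int],
    attR: tuple[int, int],
    prophage: tuple[int, int],
) -> Optional[Feature]:
    """A host gene annotation overlapping attL or attR (prophage-internal
    genes excluded)."""
    for f in host.features:
        if f.kind not in ("CDS", "tRNA", "rRNA"):
            continue
        if prophage[0] <= f.start and f.end <= prophage[1]:
            continue
        for iv in (attL, attR):
            if f.start < iv[1] and iv[0] < f.end:
                return f
    return None


# ---------------------------------------------------------------------------
# Disrupted-gene reconstruction
# ---------------------------------------------------------------------------


def check_reconstruction(
    host: GenomeRecord,
    att: AttSite,
    locus: ProphageLocus,
    alt_starts: bool = True,
    max_scan: int = 300,
) -> ReconstructionReport:
    """Check whether the phage arm reconstructs the disrupted gene's 5' end.

    Implemented for a plus-strand gene remnant downstream of attR (its body
    reads away from the prophage): walking upstream in frame from the
    remnant start, across the attR junction into the phage right arm, the
    frame is open when a start codon appears before any stop.  The first
    in-frame terminator met after circularizing the excised phage (right
    end joined to left end) is reported as an offset past the junction, and
    the phage region immediately upstream of the start is reported as the
    candidate promoter region (coordinates only).
    """
    gene = att.disrupted_gene
    if gene is None:
        raise ValueError("att site has no disrupted gene")
    if gene.strand != 1:
        raise ValueError("reconstruction check implemented for plus-strand remnants")
    seq = host.sequence
    anchor = gene.start  # codon boundary of the remnant
    # --- upstream walk into the phage right arm ---
    frame_open = False
    start_pos = None
    start_codon = None
    pos = anchor - 3
    while pos >= 0 and anchor - pos <= max_scan:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        allowed = START_CODONS if alt_starts else ("ATG",)
        if codon in allowed:
            frame_open = True
            start_pos = pos
            start_codon = codon
            break
        pos -= 3
    if not frame_open:
        return ReconstructionReport(
            frame_open=False,
            frame_break_offset=anchor - pos if pos >= 0 else None,
            notes="no start codon reached before a terminator or scan limit",
        )
    # --- terminator in the circularized phage ---
    phage_seq = seq[locus.start : locus.end]
    junction = len(phage_seq)  # right end of the phage = the attR junction
    start_in_phage = start_pos - locus.start
    terminator_offset = None
    if 0 <= start_in_phage < len(phage_seq):
        circ = phage_seq + phage_seq  # read across the origin
        p = start_in_phage
        while p + 3 <= len(circ) and p < start_in_phage + len(phage_seq):
            if circ[p : p + 3] in STOP_CODONS:
                if p + 3 > junction:
                    terminator_offset = p + 3 - junction  # nt past the junction
                break
            p += 3
    promoter_region = (max(locus.start, start_pos - 100), start_pos)
    return ReconstructionReport(
        frame_open=True,
        start_position=start_pos,
        start_codon=start_codon,
        terminator_offset=terminator_offset,
        promoter_region=promoter_region,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_integration_gff3(
    host: GenomeRecord, locus: ProphageLocus, att: Optional[AttSite], path
) -> None:
    """GFF3 emission of the prophage interval, att cores, and disrupted gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        strand = "+" if locus.strand == 1 else "-"
        fh.write(
            f"{host.id}\tphagemosaic\tprophage\t{locus.start + 1}\t{locus.end}\t.\t"
            f"{strand}\t.\tID=prophage;phage={locus.matched_phage_id};"
            f"origin_offset={locus.phage_origin_offset};"
            f"mean_identity={locus.mean_identity:.2f}\n"
        )
        if att is not None:
            for name, iv in (("attL", att.attL_interval), ("attR", att.attR_interval)):
                fh.write(
                    f"{host.id}\tphagemosaic\tatt_core\t{iv[0] + 1}\t{iv[1]}\t.\t+\t.\t"
                    f"ID={name};core={att.core_sequence};"
                    f"mismatches={att.n_core_mismatches}\n"
                )
            if att.disrupted_gene is not None:
                g = att.disrupted_gene
                gstrand = "+" if g.strand == 1 else "-"
                fh.write(
                    f"{host.id}\tphagemosaic\tdisrupted_gene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{gstrand}\t.\tID={g.qualifiers.get('locus_tag', 'gene')}\n"
                )


def format_junction_alignment(host: GenomeRecord, att: AttSite, context: int = 30) -> str:
    """Human-readable text block showing the attL/attR junctions with the
    shared core marked."""
    seq = host.sequence
    lines = []
    for name, (s, e) in (("attL", att.attL_interval), ("attR", att.attR_interval)):
        lo = max(0, s - context)
        hi = min(len(seq), e + context)
        prefix = seq[lo:s].lower()
        core = seq[s:e]
        suffix = seq[e:hi].lower()
        lines.append(f"{name} {lo + 1:>9} {prefix}{core}{suffix}")
    pad = len(f"{'attL'} {0:>9} ")
    marker = " " * (pad + min(context, att.attL_interval[0])) + "^" * len(att.core_sequence)
    lines.append(marker)
    lines.append(
        f"core ({len(att.core_sequence)} bp, {att.n_core_mismatches} mismatch"
        f"{'es' if att.n_core_mismatches != 1 else ''}): {att.core_sequence}"
    )
    return "\n".join(lines)
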