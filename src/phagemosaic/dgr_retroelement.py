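"""Diversity-generating retroelement (DGR) analysis.

A DGR cassette couples a target gene (the tail-fiber antireceptor), an
accessory variability determinant (avd), a template repeat (TR), and a
reverse transcriptase (RT).  Hypermutation copies the TR into the variable
region (VR) inside the target gene while replacing template adenines with
random bases ("A->N").  This module finds TR/VR repeat pairs near an RT
gene, classifies each TR/VR mismatch as conforming (TR A -> non-A) or not,
and tests the adenine bias of the mismatches with an exact binomial tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from Bio import Align

from phagemosaic.genome_io import Feature, GenomeRecord, ProteinRecord
from phagemosaic import identity_profile


@dataclass
class DGRCassette:
    """A detected TR/VR repeat pair with its associated genes."""

    genome_id: str
    tr_interval: tuple[int, int]
    vr_interval: tuple[int, int]
    rt_gene: Optional[Feature] = None
    rt_pseudogene: bool = False
    antireceptor_gene: Optional[Feature] = None
    avd_gene: Optional[Feature] = None
    orientation: str = "first_is_tr"  # which copy of the candidate pair is template
    tr_is_rt_extension: bool = False
    comparison: Optional["VRComparison"] = None


@dataclass
class VRComparison:
    """Per-column TR/VR mismatch classification.

    A mismatch conforms to the A->N paradigm iff the TR base is A and the
    VR base is one of C/G/T.  Gap columns are tallied separately and
    excluded from the binomial test.
    """

    aligned_tr: str
    aligned_vr: str
    mismatches: list[tuple[int, str, str, str]]  # (pos_in_TR 0-based, tr, vr, class)
    n_conforming: int
    n_nonconforming: int
    n_gap_columns: int
    n_tr_adenines: int
    tr_length: int
    p_value_adenine_bias: float = 1.0


_dna_aligner = None


def _get_dna_aligner() -> Align.PairwiseAligner:
    # match +1, mismatch -1, gap -2 per gap column; equal-length inputs then
    # align gaplessly whenever that is optimal
    global _dna_aligner
    if _dna_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -2
        a.extend_gap_score = -2
        _dna_aligner = a
    return _dna_aligner


def classify_variants(tr: str, vr: str) -> VRComparison:
    """Align TR against VR and classify every mismatch under A->N."""
    if not tr or not vr:
        raise ValueError("empty TR or VR sequence")
    tr, vr = tr.upper(), vr.upper()
    if len(tr) == len(vr):
        # gapless alignment is optimal for equal-length near-identical copies
        atr, avr = tr, vr
    else:
        aln = _get_dna_aligner().align(tr, vr)[0]
        atr, avr = str(aln[0]), str(aln[1])
    mismatches = []
    n_conf = n_nonconf = n_gap = 0
    tr_pos = -1
    for a, b in zip(atr, avr):
        if a != "-":
            tr_pos += 1
        if a == "-" or b == "-":
            n_gap += 1
            continue
        if a == b:
            continue
        cls = "conforming" if (a == "A" and b in "CGT") else "nonconforming"
        if cls == "conforming":
            n_conf += 1
        else:
            n_nonconf += 1
        mismatches.append((tr_pos, a, b, cls))
    comparison = VRComparison(
        aligned_tr=atr,
        aligned_vr=avr,
        mismatches=mismatches,
        n_conforming=n_conf,
        n_nonconforming=n_nonconf,
        n_gap_columns=n_gap,
        n_tr_adenines=tr.count("A"),
        tr_length=len(tr),
    )
    comparison.p_value_adenine_bias = adenine_bias_test(comparison)
    return comparison


def adenine_bias_test(c: VRComparison) -> float:
    """Exact one-sided binomial tail for adenine-biased mismatches.

    With m mismatches and TR adenine fraction f, the p-value is
    P(X >= n_conforming) for X ~ Binomial(m, f): the chance that mismatches
    placed without base preference would hit template adenines at least
    this often.  Zero mismatches -> p = 1 by convention.
    """
    m = c.n_conforming + c.n_nonconforming
    if m == 0:
        return 1.0
    f = c.n_tr_adenines / c.tr_length
    return float(binom.sf(c.n_conforming - 1, m, f))


def adenine_bias_permutation(
    c: VRComparison, n_draws: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo check of :func:`adenine_bias_test`: mismatch positions
    re-drawn uniformly over the TR, counting how often at least
    ``n_conforming`` land on adenines."""
    m = c.n_conforming + c.n_nonconforming
    if m == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    is_a = np.frombuffer(c.aligned_tr.replace("-", "").encode(), dtype=np.uint8) == ord("A")
    hits = 0
    for _ in range(n_draws):
        pos = rng.choice(c.tr_length, size=m, replace=False)
        if int(is_a[pos].sum()) >= c.n_conforming:
            hits += 1
    return hits / n_draws


# ---------------------------------------------------------------------------
# Repeat-pair discovery
# ---------------------------------------------------------------------------


def _extend_pair(
    seq: str, i: int, j: int, k: int, xdrop: float = 16.0
) -> tuple[int, int, int]:
    """Extend an exact seed match at (i, j) in both directions with X-drop
    scoring (match +1, mismatch -3), then trim each end back to its
    maximal-scoring extent.  Returns (start1, start2, length)."""
    # right extension
    right = k
    score = float(k)
    best_score, best_right = score, right
    while score > best_score - xdrop:
        a, b = i + right, j + right
        if b >= len(seq) or (j > i and a >= j):
            break
        score += 1.0 if seq[a] == seq[b] else -3.0
        right += 1
        if score > best_score:
            best_score, best_right = score, right
    # left extension
    left = 0
    score = best_score
    best_left = 0
    while score > best_score - xdrop:
        a, b = i - left - 1, j - left - 1
        if a < 0 or b <= i + best_right - 1:
            break
        score += 1.0 if seq[a] == seq[b] else -3.0
        left += 1
        if score > best_score:
            best_score, best_left = score, left
    return i - best_left, j - best_left, best_left + best_right


def _find_repeat_pairs(
    seq: str, k: int, len_range: tuple[int, int], max_mismatch_frac: float
) -> list[tuple[int, int, int]]:
    """Direct-repeat candidate pairs (start1, start2, length) via
    seed-and-extend over exact k-mers, deduplicated."""
    kmers: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmers.setdefault(seq[i : i + k], []).append(i)
    seen: set[tuple[int, int, int]] = set()
    out = []
    for positions in kmers.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                if j - i < len_range[0]:  # overlapping/adjacent copies
                    continue
                s1, s2, length = _extend_pair(seq, i, j, k)
                key = (s1, s2, length)
                if key in seen:
                    continue
                seen.add(key)
                if not (len_range[0] <= length <= len_range[1]):
                    continue
                mism = sum(
                    1 for t in range(length) if seq[s1 + t] != seq[s2 + t]
                )
                if mism / length > max_mismatch_frac:
                    continue
                out.append(key)
    # collapse near-duplicate extensions of the same underlying repeat
    out.sort(key=lambda p: (-p[2], p[0], p[1]))
    kept: list[tuple[int, int, int]] = []
    for s1, s2, length in out:
        dup = any(
            abs(s1 - t1) <= length // 2 and abs(s2 - t2) <= length // 2
            for t1, t2, _ in kept
        )
        if not dup:
            kept.append((s1, s2, length))
    return kept


def _find_rt_gene(g: GenomeRecord) -> Optional[Feature]:
    for f in g.cds():
        if "reverse transcriptase" in f.qualifiers.get("product", "").lower():
            return f
    return None


def find_tr_vr(
    g: GenomeRecord,
    search_window: int = 5000,
    repeat_len_range: tuple[int, int] = (50, 200),
    max_mismatch_frac: float = 0.35,
    seed_k: int = 12,
    rt_gene: Optional[Feature] = None,
    alpha: float = 0.05,
) -> list[DGRCassette]:
    """Find DGR cassettes: direct-repeat pairs near the RT gene whose
    mismatches are significantly adenine-biased in one copy.

    The adenine-enriched copy is designated the TR; the other copy, when
    inside a CDS, makes that CDS the antireceptor.  Identical repeat pairs
    are rejected (the bias test cannot reject with no mismatches).
    """
    rt = rt_gene or _find_rt_gene(g)
    if rt is None:
        raise ValueError(
            f"genome {g.id}: no gene annotated 'reverse transcriptase'; "
            "supply rt_gene explicitly"
        )
    rt_pseudo = "pseudo" in rt.qualifiers or "frameshift" in rt.qualifiers.get("note", "")
    lo = max(0, rt.start - search_window)
    hi = min(len(g), rt.end + search_window)
    window = g.sequence[lo:hi]
    cassettes = []
    for s1, s2, length in _find_repeat_pairs(window, seed_k, repeat_len_range,
                                             max_mismatch_frac):
        copy1 = window[s1 : s1 + length]
        copy2 = window[s2 : s2 + length]
        fwd = classify_variants(copy1, copy2)  # copy1 as template
        rev = classify_variants(copy2, copy1)  # copy2 as template
        if fwd.n_conforming + fwd.n_nonconforming == 0:
            continue  # identical copies: no evidence of hypermutation
        if fwd.p_value_adenine_bias <= rev.p_value_adenine_bias:
            comparison, orientation, p = fwd, "first_is_tr", fwd.p_value_adenine_bias
            tr_iv = (lo + s1, lo + s1 + length)
            vr_iv = (lo + s2, lo + s2 + length)
        else:
            comparison, orientation, p = rev, "second_is_tr", rev.p_value_adenine_bias
            tr_iv = (lo + s2, lo + s2 + length)
            vr_iv = (lo + s1, lo + s1 + length)
        if p >= alpha:
            continue
        antireceptor = None
        for f in g.cds():
            if f is rt:
                continue
            if f.start <= vr_iv[0] and vr_iv[1] <= f.end:
                antireceptor = f
                break
        avd = None
        if antireceptor is not None:
            between = sorted(
                (
                    f for f in g.cds()
                    if f.start >= min(antireceptor.end, rt.end)
                    and f.end <= max(antireceptor.start, rt.start)
                ),
                key=lambda f: f.start,
            )
            if between:
                avd = between[0]
        # TR translated as an N-terminal extension of the RT: contiguous and
        # in frame with the RT start
        tr_ext = (
            rt.strand == 1
            and tr_iv[1] <= rt.start
            and (rt.start - tr_iv[0]) % 3 == 0
            and rt.start - tr_iv[1] < 3
        )
        cassettes.append(
            DGRCassette(
                genome_id=g.id,
                tr_interval=tr_iv,
                vr_interval=vr_iv,
                rt_gene=rt,
                rt_pseudogene=rt_pseudo,
                antireceptor_gene=antireceptor,
                avd_gene=avd,
                orientation=orientation,
                tr_is_rt_extension=tr_ext,
                comparison=comparison,
            )
        )
    cassettes.sort(key=lambda c: c.comparison.p_value_adenine_bias)
    return cassettes


# ---------------------------------------------------------------------------
# VR protein-level comparison
# ---------------------------------------------------------------------------


def compare_vr_proteins(
    vrs: Sequence[tuple[str, ProteinRecord]],
    region: Optional[tuple[int, int]] = None,
) -> list[dict]:
    """Per-residue variant table over the VR region of the antireceptor.

    The first entry is the reference; the others are pairwise globally
    aligned against it.  ``region`` is a 1-based inclusive residue range on
    the reference (default: whole protein).  Rows are emitted only for
    residues where some genome differs; terminator codons are flagged with
    ``*``.
    """
    if len(vrs) < 2:
        raise ValueError("need >= 2 proteins to compare")
    ref_id, ref = vrs[0]
    nref = len(ref.aa_sequence)
    if region is None:
        region = (1, nref)
    if not (1 <= region[0] <= region[1] <= nref):
        raise ValueError(f"region {region} outside reference protein (1..{nref})")
    # residue-by-residue matrix keyed on reference residue number; terminator
    # symbols are aligned as X (wildcard) but reported verbatim
    columns: dict[str, dict[int, str]] = {}
    ref_clean = ref.aa_sequence.replace("*", "X")
    for gid, prot in vrs[1:]:
        clean = prot.aa_sequence.replace("*", "X")
        aln = identity_profile.align_pair(ref_clean, clean)
        per_residue = {}
        rpos = 0
        ppos = 0
        for a, b in zip(aln.aligned_query, aln.aligned_ref):
            if b != "-":
                ppos += 1
            if a != "-":
                rpos += 1
                per_residue[rpos] = prot.aa_sequence[ppos - 1] if b != "-" else "-"
        columns[gid] = per_residue
    rows = []
    for rpos in range(region[0], region[1] + 1):
        ref_aa = ref.aa_sequence[rpos - 1]
        variants = {gid: columns[gid].get(rpos, "-") for gid, _ in vrs[1:]}
        if all(v == ref_aa for v in variants.values()):
            continue
        rows.append(
            {
                "residue": rpos,
                ref_id: ref_aa,
                **variants,
                "terminator": "*" in variants.values() or ref_aa == "*",
            }
        )
    return rows


def write_variant_table(rows: Sequence[dict], genome_ids: Sequence[str], path) -> None:
    """CSV variant table: residue number, one column per genome, terminator flag."""
    with open(path, "w") as fh:
        fh.write("residue," + ",".join(genome_ids) + ",terminator\n")
        for row in rows:
            vals = [str(row.get(g, "")) for g in genome_ids]
            fh.write(f"{row['residue']}," + ",".join(vals)
                     + f",{'*' if row['terminator'] else ''}\n")


def write_cassette_report(cassettes: Sequence[DGRCassette], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\ttr_start\ttr_end\tvr_start\tvr_end\tn_conforming\t"
                 "n_nonconforming\tp_adenine_bias\trt_pseudogene\t"
                 "tr_is_rt_extension\n")
        for c in cassettes:
            fh.write(
                f"{c.genome_id}\t{c.tr_interval[0]}\t{c.tr_interval[1]}\t"
                f"{c.vr_interval[0]}\t{c.vr_interval[1]}\t"
                f"{c.comparison.n_conforming}\t{c.comparison.n_nonconforming}\t"
                f"{c.comparison.p_value_adenine_bias:.3e}\t"
                f"{int(c.rt_pseudogene)}\t{int(c.tr_is_rt_extension)}\n"
            )


def write_cassette_gff3(cassettes: Sequence[DGRCassette], path) -> None:
    """GFF3 intervals for TR, VR, and the cassette genes (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in cassettes:
            rows = [
                ("template_repeat", c.tr_interval, "."),
                ("variable_region", c.vr_interval, "."),
            ]
            if c.antireceptor_gene is not None:
                f = c.antireceptor_gene
                rows.append(("antireceptor_CDS", (f.start, f.end),
                             "+" if f.strand == 1 else "-"))
            if c.avd_gene is not None:
                f = c.avd_gene
                rows.append(("avd_CDS", (f.start, f.end), "+" if f.strand == 1 else "-"))
            if c.rt_gene is not None:
                f = c.rt_gene
                rows.append(("reverse_transcriptase_CDS", (f.start, f.end),
                             "+" if f.strand == 1 else "-"))
            for name, (s, e), strand in rows:
                fh.write(
                    f"{c.genome_id}\tphagemosaic\t{name}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f"ID={name};p_adenine_bias={c.comparison.p_value_adenine_bias:.3e}\n"
                )
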