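"""Synthetic-data generators: every pipeline stage testable with no
downloads.

All generators are pure functions of (config, seed) and return a truth
structure recording exactly what was planted, so downstream tests read
expected values from truth rather than re-deriving them.  Protein evolution
is a uniform substitution model (targets are realized identity
percentages, not phylogenetic realism) and back-translation picks
synonymous codons uniformly, so synthetic G+C sits near 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from phagemosaic.genome_io import Feature, GenomeRecord, rotate

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOPS = ("TAA", "TAG", "TGA")
STARTS = ("ATG", "GTG", "TTG")

_table11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_table11.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)

# codons that can never read as a start or stop in any frame overlap we use;
# handy for building inert linkers
_INERT_CODONS = ("CCA", "CCT", "CAC", "ACC")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_protein(rng: np.random.Generator, n: int) -> str:
    body = "".join(rng.choice(list(AA20), size=n - 1))
    return "M" + body


def _mutate_protein(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each site with probability ``divergence`` to a uniformly
    chosen different residue (realized identity ~ 1 - divergence)."""
    out = list(seq)
    for i, aa in enumerate(out):
        if rng.random() < divergence:
            choices = [c for c in AA20 if c != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _positional_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return 100.0 * sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """DNA for a protein with uniformly chosen synonymous codons, plus stop."""
    codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein
    ]
    codons.append(STOPS[rng.integers(len(STOPS))])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Mosaic phage families
# ---------------------------------------------------------------------------


@dataclass
class MosaicConfig:
    """Family of genomes with module-structured divergence.

    ``identities[ref][module]`` is the target percent identity of that
    reference's proteins to the query in that module, or None for
    "unrelated" (independent random proteins).  ``recombination_events``
    are (module, ref) pairs: the reference's module is overwritten with a
    near-identical copy of the query module (a block recombination).
    """

    seed: int
    module_sizes: tuple[int, ...] = (10, 10, 10, 10)
    module_names: tuple[str, ...] = (
        "nonstructural", "head_connector", "tail", "antireceptor_dgr",
    )
    mean_protein_len: int = 150
    identities: dict[str, dict[str, Optional[float]]] = field(default_factory=dict)
    recombination_events: list[tuple[str, str]] = field(default_factory=list)
    spacer_len: int = 20

    def __post_init__(self) -> None:
        if len(self.module_sizes) != len(self.module_names):
            raise ValueError("module_sizes and module_names lengths differ")
        for ref, per_mod in self.identities.items():
            for mod, t in per_mod.items():
                if mod not in self.module_names:
                    raise ValueError(f"unknown module {mod!r} for reference {ref!r}")
                if t is not None and not (0 < t <= 100):
                    raise ValueError(f"identity target {t} outside (0, 100]")


def _proteome_to_genome(
    rng: np.random.Generator, genome_id: str, proteins: Sequence[str],
    spacer_len: int, product_prefix: str = "protein",
) -> GenomeRecord:
    parts = [_random_dna(rng, spacer_len)]
    features = []
    pos = spacer_len
    for i, prot in enumerate(proteins):
        dna = back_translate(rng, prot)
        features.append(
            Feature(
                "CDS", pos, pos + len(dna), 1,
                {"locus_tag": f"{genome_id}_{i + 1:03d}",
                 "product": f"{product_prefix} {i + 1}"},
            )
        )
        parts.append(dna)
        pos += len(dna)
        spacer = _random_dna(rng, spacer_len)
        parts.append(spacer)
        pos += spacer_len
    return GenomeRecord(genome_id, "".join(parts), "linear", features)


def gen_mosaic(cfg: MosaicConfig) -> tuple[dict[str, GenomeRecord], dict]:
    """Simulate a query genome plus reference genomes with per-module
    divergence targets.  Truth records module boundaries and realized
    per-gene identities."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = sum(cfg.module_sizes)
    module_of: list[str] = []
    boundaries = {}
    gi = 0
    for name, size in zip(cfg.module_names, cfg.module_sizes):
        boundaries[name] = (gi, gi + size - 1)
        module_of.extend([name] * size)
        gi += size
    lengths = np.maximum(30, rng.poisson(cfg.mean_protein_len, size=n_genes))
    query = [_random_protein(rng, int(n)) for n in lengths]
    ref_proteomes: dict[str, list[Optional[str]]] = {}
    recombined = {(m, r) for m, r in cfg.recombination_events}
    for ref, per_mod in cfg.identities.items():
        prots: list[Optional[str]] = []
        for g, qprot in enumerate(query):
            mod = module_of[g]
            target = per_mod.get(mod)
            if (mod, ref) in recombined:
                target = 99.0
            if target is None:
                prots.append(_random_protein(rng, int(lengths[g])))
            else:
                prots.append(_mutate_protein(rng, qprot, 1.0 - target / 100.0))
        ref_proteomes[ref] = prots
    records = {"query": _proteome_to_genome(rng, "query", query, cfg.spacer_len)}
    for ref, prots in ref_proteomes.items():
        records[ref] = _proteome_to_genome(rng, ref, prots, cfg.spacer_len)
    truth_genes = []
    for g in range(n_genes):
        row = {"gene_index": g, "module": module_of[g]}
        for ref in cfg.identities:
            target = cfg.identities[ref].get(module_of[g])
            if (module_of[g], ref) in recombined:
                target = 99.0
            row[ref] = (
                None if target is None
                else _positional_identity(query[g], ref_proteomes[ref][g])
            )
        truth_genes.append(row)
    truth = {
        "module_boundaries": boundaries,
        "genes": truth_genes,
        "recombination_events": list(cfg.recombination_events),
        "seed": cfg.seed,
    }
    return records, truth


def write_mosaic_truth(truth: dict, path) -> None:
    refs = [k for k in truth["genes"][0] if k not in ("gene_index", "module")]
    with open(path, "w") as fh:
        fh.write("gene_index\tmodule\t" + "\t".join(refs) + "\n")
        for row in truth["genes"]:
            vals = ["NA" if row[r] is None else f"{row[r]:.1f}" for r in refs]
            fh.write(f"{row['gene_index']}\t{row['module']}\t" + "\t".join(vals) + "\n")


def gen_two_lineage_panel(
    seed: int,
    n_genes: int = 5,
    n_phages_per_group: int = 6,
    intra_identity: float = 35.0,
    protein_len: int = 200,
) -> tuple[dict[str, dict[str, tuple[float, float]]], dict[str, str]]:
    """Panel of phages descending from two unrelated tail lineages.

    Returns (per-gene panels of (identity to exemplar A, identity to
    exemplar B), truth group per phage).  Inter-group identity is chance
    level (unrelated random proteins); intra-group identity is
    ``intra_identity``.
    """
    rng = np.random.default_rng(seed)
    phages = {f"pA{i}": "A" for i in range(n_phages_per_group)}
    phages.update({f"pB{i}": "B" for i in range(n_phages_per_group)})
    panels: dict[str, dict[str, tuple[float, float]]] = {}
    d = 1.0 - intra_identity / 100.0
    for g in range(n_genes):
        ex_a = _random_protein(rng, protein_len)
        ex_b = _random_protein(rng, protein_len)
        panel = {}
        for phage, group in phages.items():
            source = ex_a if group == "A" else ex_b
            prot = _mutate_protein(rng, source, d)
            panel[phage] = (
                _positional_identity(prot, ex_a),
                _positional_identity(prot, ex_b),
            )
        panels[f"tail_gene_{g + 1}"] = panel
    return panels, phages


# ---------------------------------------------------------------------------
# DGR cassettes
# ---------------------------------------------------------------------------


@dataclass
class DGRSimConfig:
    """A->N hypermutation simulator configuration.

    ``theta`` is the per-adenine probability of substituting a template A
    to a uniform choice of C/G/T in the VR; ``epsilon`` is a per-site
    background substitution probability applying to all sites.
    """

    seed: int
    repeat_len: int = 150  # multiple of 3
    adenine_fraction: float = 0.45
    theta: float = 0.1
    epsilon: float = 0.0
    flank_len: int = 300
    antireceptor_len_aa: int = 220
    avd_len_aa: int = 100
    rt_len_aa: int = 240
    rt_frameshift: bool = False
    tr_as_rt_extension: bool = True
    edge_guard: int = 8  # repeat bases at each end exempt from mutation
    # (real VR/TR boundaries are conserved anchors; also makes the planted
    # intervals the unique maximal-extension answer)

    def __post_init__(self) -> None:
        if self.repeat_len % 3 != 0:
            raise ValueError("repeat_len must be a multiple of 3")
        for name in ("theta", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _random_tr(
    rng: np.random.Generator, length: int, adenine_fraction: float,
    edge_guard: int = 0,
) -> str:
    """Codon-wise TR with ~the requested adenine fraction and no stop codons
    in frame 0 (so it can sit inside or alongside a CDS).  The guard codons
    at each end are adenine-free: guard positions are exempt from mutation,
    so keeping them A-free stops them from diluting the adenine-bias test."""
    p = [adenine_fraction] + [(1.0 - adenine_fraction) / 3.0] * 3
    n_codons = length // 3
    guard_codons = (edge_guard + 2) // 3
    codons: list[str] = []
    while len(codons) < n_codons:
        edge = len(codons) < guard_codons or len(codons) >= n_codons - guard_codons
        if edge:
            codon = "".join(rng.choice(list("CGT"), size=3))  # CGT-only: never a stop
        else:
            codon = "".join(rng.choice(list("ACGT"), size=3, p=p))
            if codon in STOPS:
                continue
        codons.append(codon)
    return "".join(codons)


def _hypermutate(
    rng: np.random.Generator, tr: str, theta: float, epsilon: float,
    edge_guard: int = 0,
) -> tuple[str, list[tuple[int, str, str, bool]]]:
    """VR from TR under the A->N paradigm plus background noise.  Returns
    (vr, [(pos, tr_base, vr_base, conforming)]).  Positions within
    ``edge_guard`` of either end are left untouched."""
    vr = list(tr)
    events = []
    lo, hi = edge_guard, len(tr) - edge_guard
    for i, base in enumerate(tr):
        if not (lo <= i < hi):
            continue
        if base == "A" and rng.random() < theta:
            new = "CGT"[rng.integers(3)]
            vr[i] = new
            events.append((i, base, new, True))
    for i, base in enumerate(tr):
        if not (lo <= i < hi) or vr[i] != base:
            continue
        if rng.random() < epsilon:
            new = rng.choice([b for b in "ACGT" if b != base])
            vr[i] = new
            events.append((i, base, new, base == "A" and new != "A"))
    events.sort()
    return "".join(vr), events


def _force_mismatch(
    seq: list[str], pos: int, other_base: str, rng: np.random.Generator,
    frames: Sequence[int] = (),
    avoid: Sequence[str] = STOPS,
) -> None:
    """Set seq[pos] to a base differing from both its current value and
    ``other_base``, refusing choices that turn the codon containing ``pos``
    into one of ``avoid`` in any of the given frame anchors (positions
    where codons start)."""
    for cand in rng.permutation(list("ACGT")):
        if cand == other_base or cand == seq[pos]:
            continue
        old = seq[pos]
        seq[pos] = cand
        ok = True
        for anchor in frames:
            codon_start = pos - ((pos - anchor) % 3)
            if codon_start >= 0 and "".join(seq[codon_start : codon_start + 3]) in avoid:
                ok = False
                break
        if ok:
            return
        seq[pos] = old
    raise RuntimeError("could not force a junction mismatch within codon constraints")


def gen_dgr(cfg: DGRSimConfig) -> tuple[GenomeRecord, dict]:
    """A genome carrying one DGR cassette: antireceptor (with VR), avd, TR,
    RT — with the VR hypermutated from the TR under A->N.

    The two bases flanking each repeat copy are forced to differ between
    the copies so the planted repeat boundaries are the maximal-extension
    boundaries (detection can be exact).
    """
    rng = np.random.default_rng(cfg.seed)
    tr = _random_tr(rng, cfg.repeat_len, cfg.adenine_fraction, cfg.edge_guard)
    vr, events = _hypermutate(rng, tr, cfg.theta, cfg.epsilon, cfg.edge_guard)

    # antireceptor: protein with the VR spliced in-frame near the 3' end
    ar_prot = _random_protein(rng, cfg.antireceptor_len_aa)
    ar_dna = back_translate(rng, ar_prot)
    vr_at = len(ar_dna) - 3 - 30 - cfg.repeat_len  # 30 nt before the stop
    ar_dna = ar_dna[:vr_at] + vr + ar_dna[vr_at + cfg.repeat_len :]
    avd_dna = back_translate(rng, _random_protein(rng, cfg.avd_len_aa))
    rt_dna = back_translate(rng, _random_protein(rng, cfg.rt_len_aa))
    if cfg.rt_frameshift:
        mid = (len(rt_dna) // 2) // 3 * 3 + 1
        rt_dna = rt_dna[:mid] + rt_dna[mid + 1 :]  # 1-bp deletion

    left = _random_dna(rng, cfg.flank_len)
    s1 = _random_dna(rng, 42)
    s2 = _random_dna(rng, 30)
    s3 = "" if cfg.tr_as_rt_extension else _random_dna(rng, 10)
    right = _random_dna(rng, cfg.flank_len)
    parts = [left, ar_dna, s1, avd_dna, s2, tr, s3, rt_dna, right]
    seq = list("".join(parts))

    pos = cfg.flank_len
    ar_start, ar_end = pos, pos + len(ar_dna)
    vr_start = ar_start + vr_at
    pos = ar_end + len(s1)
    avd_start, avd_end = pos, pos + len(avd_dna)
    pos = avd_end + len(s2)
    tr_start, tr_end = pos, pos + cfg.repeat_len
    rt_start = tr_end + len(s3)
    rt_end = rt_start + len(rt_dna)

    # junction guards: four mismatching bases beyond each end of each copy,
    # so the planted repeat boundaries are the maximal-extension boundaries
    # (a seed-and-extend detector cannot plausibly re-match past them)
    vr_end = vr_start + cfg.repeat_len
    for d in (1, 2, 3, 4):
        # upstream of VR vs upstream of TR: edit the TR side (spacer s2)
        _force_mismatch(seq, tr_start - d, seq[vr_start - d], rng, frames=())
    # downstream: rewrite the two antireceptor codons after the VR as
    # proline codons (CCx) — C never collides with the RT start (ATG...)
    seq[vr_end : vr_end + 2] = "CC"
    seq[vr_end + 2] = "ACT"[rng.integers(3)]  # never G (the RT start's 3rd base)
    seq[vr_end + 3 : vr_end + 5] = "CC"
    seq[vr_end + 5] = "ACT"[rng.integers(3)]
    for d in range(6):
        if seq[tr_end + d] == seq[vr_end + d]:
            # downstream of the TR: free spacer when the TR is not an RT
            # extension, otherwise RT coding sequence (keep it stop-free)
            frames = (rt_start,) if cfg.tr_as_rt_extension else ()
            _force_mismatch(seq, tr_end + d, seq[vr_end + d], rng, frames=frames)

    sequence = "".join(seq)
    features = [
        Feature("CDS", ar_start, ar_end, 1,
                {"locus_tag": "anti01", "product": "antireceptor (tail fiber)"}),
        Feature("CDS", avd_start, avd_end, 1,
                {"locus_tag": "avd01", "product": "accessory variability determinant"}),
        Feature("CDS", rt_start, rt_end, 1,
                {"locus_tag": "rt01", "product": "reverse transcriptase",
                 **({"note": "frameshift"} if cfg.rt_frameshift else {})}),
    ]
    record = GenomeRecord("dgr_synth", sequence, "linear", features)
    truth = {
        "tr_interval": (tr_start, tr_end),
        "vr_interval": (vr_start, vr_start + cfg.repeat_len),
        "antireceptor": (ar_start, ar_end),
        "avd": (avd_start, avd_end),
        "rt": (rt_start, rt_end),
        "events": events,
        "n_conforming": sum(1 for e in events if e[3]),
        "n_nonconforming": sum(1 for e in events if not e[3]),
        "tr": tr,
        "vr": "".join(seq[vr_start : vr_start + cfg.repeat_len]),
        "seed": cfg.seed,
    }
    return record, truth


# ---------------------------------------------------------------------------
# Lysogens
# ---------------------------------------------------------------------------


@dataclass
class LysogenConfig:
    """Integration-geometry simulator configuration.

    The att core (``core_len`` bases of the host target gene at the
    insertion point) is duplicated on both sides of the prophage;
    ``core_len`` 0 is a blunt, core-less insertion.  ``rotation`` rotates
    the returned phage record relative to the prophage orientation, so
    detection must report it back as ``phage_origin_offset``.
    """

    seed: int
    host_length: int = 20000
    gene_start: int = 9000
    gene_len_aa: int = 300
    insertion_offset: int = 30  # nt into the gene; multiple of 3
    core_len: int = 21
    core_mismatches: int = 0
    rotation: int = 0
    reconstruct_5prime: bool = False
    terminator_offset: int = 90  # in-frame stop planted past the junction (circular phage)

    def __post_init__(self) -> None:
        if self.insertion_offset % 3 != 0:
            raise ValueError("insertion_offset must be a multiple of 3")
        if self.core_len < 0:
            raise ValueError("core_len must be >= 0")
        gene_nt = self.gene_len_aa * 3 + 3
        if self.core_len >= gene_nt - self.insertion_offset:
            raise ValueError("core longer than the remaining gene body")


def gen_phage(seed: int, length: int = 6000, n_genes: int = 4,
              buffer: int = 200, genome_id: str = "phage_synth") -> GenomeRecord:
    """A random annotated phage genome with non-coding buffers at both ends
    (so integration bookkeeping can edit near the termini without touching
    a CDS)."""
    rng = np.random.default_rng(seed)
    coding_span = length - 2 * buffer
    gene_nt = coding_span // n_genes - 20
    aa_len = max(30, gene_nt // 3 - 1)
    seq = list(_random_dna(rng, length))
    features = []
    pos = buffer
    for i in range(n_genes):
        dna = back_translate(rng, _random_protein(rng, aa_len))
        if pos + len(dna) > length - buffer:
            break
        seq[pos : pos + len(dna)] = dna
        features.append(
            Feature("CDS", pos, pos + len(dna), 1,
                    {"locus_tag": f"php{i + 1:02d}", "product": f"phage protein {i + 1}"})
        )
        pos += len(dna) + 20
    return GenomeRecord(genome_id, "".join(seq), "circular", features)


def gen_lysogen(
    cfg: LysogenConfig, phage: GenomeRecord
) -> tuple[GenomeRecord, GenomeRecord, dict]:
    """Integrate ``phage`` into a synthetic host inside a target gene.

    Returns (lysogen record, query phage record rotated by ``cfg.rotation``,
    truth).  The bases just outside each att core copy are forced to
    mismatch between the two junctions, making the planted core the unique
    maximal repeat (exact recovery is well defined).
    """
    rng = np.random.default_rng(cfg.seed)
    if len(phage) >= cfg.host_length:
        raise ValueError("phage must be shorter than host")
    gene_nt = cfg.gene_len_aa * 3 + 3
    g0 = cfg.gene_start
    host = list(_random_dna(rng, cfg.host_length))
    gene_dna = back_translate(rng, _random_protein(rng, cfg.gene_len_aa))
    host[g0 : g0 + gene_nt] = gene_dna
    p = g0 + cfg.insertion_offset
    c = cfg.core_len
    core = "".join(host[p : p + c])

    phage_seq = list(phage.sequence)
    Lp = len(phage_seq)
    # attP: the phage record begins with the core
    phage_seq[0:c] = core
    if cfg.reconstruct_5prime:
        if c % 3 != 0:
            raise ValueError("reconstruct_5prime requires core_len to be a multiple of 3")
        # plant a GTG start 30 nt upstream of the right junction and keep the
        # intervening codons inert; plant an in-frame TAA past the junction
        # in the circularized phage, with the frame clear before it
        for off in range(Lp - 30, Lp, 3):
            phage_seq[off : off + 3] = _INERT_CODONS[rng.integers(len(_INERT_CODONS))]
        phage_seq[Lp - 30 : Lp - 27] = "GTG"
        t = cfg.terminator_offset - 3
        for off in range(c, t, 3):
            if "".join(phage_seq[off : off + 3]) in STOPS:
                phage_seq[off : off + 3] = _INERT_CODONS[rng.integers(len(_INERT_CODONS))]
        phage_seq[t : t + 3] = "TAA"
    else:
        # close the frame one codon shy of the junction, leaving the last
        # codon free for the junction guards below (kept non-start/non-stop;
        # an inert codon guarantees the guard edits always have a legal base)
        phage_seq[Lp - 6 : Lp - 3] = "TAA"
        phage_seq[Lp - 3 : Lp] = _INERT_CODONS[rng.integers(len(_INERT_CODONS))]

    # junction guards (see docstring): four mismatching bases beyond each
    # junction on each side.  The guarded codon next to the right junction
    # must stay non-start/non-stop so the planted frame-open status is what
    # a reading-frame walk recovers; in the frame-closed case the planted
    # stop codon's wobble base doubles as the fourth guard.
    # last phage codon: drawn jointly so every base mismatches its host
    # counterpart and the codon is neither start nor stop
    while True:
        codon = "".join(
            rng.choice([b for b in "ACGT" if b != host[p - 3 + i]]) for i in range(3)
        )
        if codon not in STOPS + STARTS:
            phage_seq[Lp - 3 : Lp] = codon
            break
    if cfg.reconstruct_5prime:
        _force_mismatch(phage_seq, Lp - 4, host[p - 4], rng,
                        frames=[Lp - 3], avoid=STOPS + STARTS)
    elif phage_seq[Lp - 4] == host[p - 4]:
        # phage_seq[Lp-6:Lp-3] is the planted stop; swap it for another stop
        # whose wobble base differs from the host
        phage_seq[Lp - 6 : Lp - 3] = "TAG" if host[p - 4] == "A" else "TAA"
    if c > 0:
        for d in range(4):
            _force_mismatch(phage_seq, c + d, host[p + c + d], rng,
                            frames=[0] if cfg.reconstruct_5prime else [])

    core2 = list(core)
    mismatch_positions = []
    if cfg.core_mismatches > 0:
        if c < 5:
            raise ValueError("core too short to plant interior mismatches")
        span = np.arange(2, c - 2)
        picks = rng.choice(span, size=min(cfg.core_mismatches, len(span)), replace=False)
        for mp in sorted(int(x) for x in picks):
            core2[mp] = [b for b in "ACGT" if b != core2[mp]][rng.integers(3)]
            mismatch_positions.append(mp)

    lysogen_seq = (
        "".join(host[:p]) + "".join(phage_seq) + "".join(core2) + "".join(host[p + c :])
    )
    att_l = (p, p + c)
    att_r = (p + Lp, p + Lp + c)
    remnant_start = p + Lp
    remnant_end = g0 + gene_nt + Lp
    features = [
        Feature("CDS", remnant_start, remnant_end, 1,
                {"locus_tag": "dus01", "product": "tRNA modification enzyme",
                 "note": "disrupted by prophage; 5prime truncated"}),
    ]
    for f in phage.features:
        features.append(
            Feature(f.kind, f.start + p, f.end + p, f.strand, dict(f.qualifiers))
        )
    lysogen = GenomeRecord("lysogen_synth", lysogen_seq, "linear", features)

    prophage_record = GenomeRecord(phage.id, "".join(phage_seq), "circular",
                                   list(phage.features))
    query_phage = rotate(prophage_record, (Lp - cfg.rotation) % Lp)
    truth = {
        "prophage_interval": (p, p + Lp),
        "attL": att_l if c > 0 else None,
        "attR": att_r if c > 0 else None,
        "core": core,
        "core_mismatch_positions": mismatch_positions,
        "rotation": cfg.rotation,
        "insertion_point": p,
        "frame_open": cfg.reconstruct_5prime,
        "start_position": (p + Lp - 30) if cfg.reconstruct_5prime else None,
        "terminator_offset": cfg.terminator_offset if cfg.reconstruct_5prime else None,
        "seed": cfg.seed,
    }
    return lysogen, query_phage, truth


# ---------------------------------------------------------------------------
# Mixed-variant pileups
# ---------------------------------------------------------------------------


def gen_pileup(
    sites: Sequence[int], depth: int, mixture: float, seed: int,
    ref_base: str = "A", alt_base: str = "G",
) -> pd.DataFrame:
    """Per-site pileup counts for a two-variant read mixture.

    Alternate counts are Binomial(depth, mixture); the rest of the reads
    carry the reference base.  Deterministic given the seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= mixture <= 1.0):
        raise ValueError("mixture must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for pos in sites:
        alt = int(rng.binomial(depth, mixture))
        counts = {b: 0 for b in "ACGTN"}
        counts[ref_base] = depth - alt
        counts[alt_base] = alt
        rows.append({"pos": pos, **counts})
    return pd.DataFrame(rows, columns=["pos", "A", "C", "G", "T", "N"])


def write_pileup_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
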