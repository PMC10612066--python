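"""Module-level divergence summaries, change-point segmentation of identity
profiles, and the per-gene two-exemplar bipartition of a phage panel.

Medians (not means) summarize a module so that single genes interjected by
recombinational reassortment move the summary as little as possible; cells
with no measure are excluded from medians but enter the segmentation cost
as an informative "absent" level imputed at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from phagemosaic.identity_profile import IdentityTable

MODULE_NAMES = ("nonstructural", "head_connector", "tail", "antireceptor_dgr")


@dataclass
class ModuleDefinition:
    """A named contiguous gene block (inclusive gene-index range)."""

    name: str
    first_gene: int
    last_gene: int
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.first_gene > self.last_gene:
            raise ValueError("empty gene range")

    def gene_indices(self) -> range:
        return range(self.first_gene, self.last_gene + 1)


@dataclass
class ModuleSummary:
    module: ModuleDefinition
    reference_genome_id: str
    median_identity: Optional[float]
    n_measured: int
    n_unmeasured: int


@dataclass
class Bipartition:
    """Per-gene split of a phage panel between two exemplars.

    Margins are ``identity_to_A - identity_to_B``; assignment is the sign of
    the margin.  ``is_separable`` asks whether a single threshold on the
    margin separates the two groups with no interleaving (checked against
    ``expected_groups`` when supplied, otherwise against the sign-based
    assignment itself, where only a zero margin breaks separability).
    """

    gene_name: str
    exemplar_a_id: str
    exemplar_b_id: str
    per_phage_assignment: dict[str, str]  # phage -> "A" | "B" | "unresolved"
    margins: dict[str, float] = field(default_factory=dict)
    separating_threshold: Optional[float] = None
    is_separable: bool = False


def summarize_module(
    t: IdentityTable, m: ModuleDefinition, ref: str
) -> ModuleSummary:
    """Median identity of a module against one reference.

    Even-count medians are the midpoint of the central pair; cells with no
    measure are excluded from the median but counted as ``n_unmeasured``.
    """
    present = {p.gene_index for p in t.query_proteins}
    idx = [i for i in m.gene_indices() if i in present]
    if not idx:
        raise ValueError(f"module {m.name}: no genes in range for this table")
    values = [t.cells[(i, ref)].percent_identity for i in idx]
    measured = [v for v in values if v is not None]
    median = float(np.median(measured)) if measured else None
    return ModuleSummary(m, ref, median, len(measured), len(values) - len(measured))


# ---------------------------------------------------------------------------
# Change-point segmentation
# ---------------------------------------------------------------------------


def _profile_matrix(t: IdentityTable) -> np.ndarray:
    """Gene x reference identity matrix with None imputed to 0 (absence is
    informative inside the segmentation cost only)."""
    rows = []
    for p in t.query_proteins:
        rows.append([
            0.0 if (v := t.cells[(p.gene_index, r)].percent_identity) is None else v
            for r in t.reference_genome_ids
        ])
    return np.asarray(rows, dtype=float)


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = sum of absolute deviations from the per-reference segment
    median over genes i..j-1 (half-open j)."""
    n = x.shape[0]
    cost = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = x[i:j]
            med = np.median(seg, axis=0)
            cost[i, j] = float(np.abs(seg - med).sum())
    return cost


def _segment_vector(x: np.ndarray, n_modules: int, min_len: int) -> list[int]:
    """Optimal boundaries (gene indices where a new segment starts), with
    cost ties resolved toward lexicographically-earliest boundaries."""
    n = x.shape[0]
    if min_len * n_modules > n:
        raise ValueError(
            f"min_len*{n_modules} = {min_len * n_modules} exceeds gene count {n}"
        )
    cost = _segment_costs(x)
    INF = float("inf")
    # suffix[i][k] = best cost of splitting genes i..n into k segments
    suffix = np.full((n + 1, n_modules + 1), INF)
    suffix[n, 0] = 0.0
    for k in range(1, n_modules + 1):
        for i in range(n - min_len * k, -1, -1):
            best = INF
            for b in range(i + min_len, n - min_len * (k - 1) + 1):
                c = cost[i, b] + suffix[b, k - 1]
                if c < best:
                    best = c
            suffix[i, k] = best
    # reconstruct greedily from the left, taking the earliest boundary that
    # achieves the optimum (lexicographically smallest boundary vector)
    bounds = []
    i, k = 0, n_modules
    eps = 1e-9
    while k > 1:
        for b in range(i + min_len, n - min_len * (k - 1) + 1):
            if cost[i, b] + suffix[b, k - 1] <= suffix[i, k] + eps:
                bounds.append(b)
                i, k = b, k - 1
                break
    return bounds


def segment_modules(
    t: IdentityTable,
    min_len: int = 2,
    n_modules: int | str = 4,
    names: Optional[Sequence[str]] = None,
) -> list[ModuleDefinition]:
    """Exact dynamic-programming change-point segmentation of the identity
    profile into contiguous modules.

    Minimizes total within-segment absolute deviation from the per-reference
    segment median, subject to a minimum segment length; deterministic, with
    cost ties resolved toward the earliest boundaries.  ``n_modules="auto"``
    picks the segment count (2..6) by the largest relative cost drop.
    """
    if len(t.reference_genome_ids) < 2:
        raise ValueError("segmentation needs >= 2 reference columns (patterns are contrasts)")
    x = _profile_matrix(t)
    n = x.shape[0]
    if n_modules == "auto":
        candidates = range(1, min(6, n // min_len) + 1)
        costs = {}
        for k in candidates:
            b = _segment_vector(x, k, min_len)
            edges = [0, *b, n]
            cseg = _segment_costs(x)
            costs[k] = sum(cseg[edges[i], edges[i + 1]] for i in range(k))
        # elbow: smallest k whose next refinement gains < 10% of current cost
        ks = sorted(costs)
        n_modules = ks[-1]
        for a, bk in zip(ks, ks[1:]):
            if costs[a] <= 0 or (costs[a] - costs[bk]) / max(costs[a], 1e-9) < 0.10:
                n_modules = a
                break
        provenance = "auto"
    else:
        provenance = "auto"
    bounds = _segment_vector(x, int(n_modules), min_len)
    edges = [0, *bounds, n]
    gene_indices = [p.gene_index for p in t.query_proteins]
    mods = []
    for s, (lo, hi) in enumerate(zip(edges, edges[1:])):
        name = names[s] if names else f"module_{s + 1}"
        mods.append(
            ModuleDefinition(name, gene_indices[lo], gene_indices[hi - 1], provenance)
        )
    return mods


# ---------------------------------------------------------------------------
# Two-exemplar bipartition
# ---------------------------------------------------------------------------


def bipartition_by_gene(
    panel: dict[str, tuple[Optional[float], Optional[float]]],
    gene: str,
    exemplar_a: str = "A",
    exemplar_b: str = "B",
    expected_groups: Optional[dict[str, str]] = None,
) -> Bipartition:
    """Assign each panel phage to the exemplar it matches better.

    ``panel`` maps phage -> (identity to A, identity to B); None means no
    measure.  Phages with no measure at all are unresolved, as are exact
    ties.  The separating threshold, when separable, is the midpoint of the
    gap between the two groups' margin ranges.
    """
    if len(panel) < 2:
        raise ValueError("panel needs >= 2 phages")
    assignment: dict[str, str] = {}
    margins: dict[str, float] = {}
    for phage, (ia, ib) in panel.items():
        if ia is None and ib is None:
            assignment[phage] = "unresolved"
            continue
        margin = (ia or 0.0) - (ib or 0.0)
        margins[phage] = margin
        if margin > 0:
            assignment[phage] = "A"
        elif margin < 0:
            assignment[phage] = "B"
        else:
            assignment[phage] = "unresolved"
    groups = expected_groups or {p: g for p, g in assignment.items() if g != "unresolved"}
    a_margins = [margins[p] for p, g in groups.items() if g == "A" and p in margins]
    b_margins = [margins[p] for p, g in groups.items() if g == "B" and p in margins]
    separable = False
    threshold = None
    if a_margins and b_margins:
        if min(a_margins) > max(b_margins):
            separable = True
            threshold = (min(a_margins) + max(b_margins)) / 2.0
    elif a_margins or b_margins:
        # one-sided panel: trivially separable, no informative threshold
        separable = all(g != "unresolved" for g in assignment.values())
    return Bipartition(
        gene_name=gene,
        exemplar_a_id=exemplar_a,
        exemplar_b_id=exemplar_b,
        per_phage_assignment=assignment,
        margins=margins,
        separating_threshold=threshold,
        is_separable=separable,
    )


def consensus_groups(
    bipartitions: Sequence[Bipartition],
) -> dict[str, tuple[str, float]]:
    """Majority vote across gene bipartitions.

    Returns phage -> (group, agreement) where agreement is the fraction of
    voting genes concurring with the majority; ties vote "unresolved".
    """
    if not bipartitions:
        raise ValueError("need >= 1 bipartition")
    phages = sorted({p for b in bipartitions for p in b.per_phage_assignment})
    out = {}
    for phage in phages:
        votes = [
            b.per_phage_assignment[phage]
            for b in bipartitions
            if b.per_phage_assignment.get(phage, "unresolved") != "unresolved"
        ]
        if not votes:
            out[phage] = ("unresolved", 0.0)
            continue
        n_a = votes.count("A")
        n_b = votes.count("B")
        if n_a == n_b:
            out[phage] = ("unresolved", 0.5)
        else:
            group = "A" if n_a > n_b else "B"
            out[phage] = (group, max(n_a, n_b) / len(votes))
    return out


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def read_module_definitions(path) -> list[ModuleDefinition]:
    """BED-like 3-column file: module_name, first_gene_index, last_gene_index."""
    mods = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, first, last = line.split("\t")[:3]
            mods.append(ModuleDefinition(name, int(first), int(last), "manual"))
    ranges = sorted((m.first_gene, m.last_gene) for m in mods)
    for (a0, a1), (b0, _) in zip(ranges, ranges[1:]):
        if b0 <= a1:
            raise ValueError("module gene ranges overlap")
    return mods


def write_module_summaries(summaries: Sequence[ModuleSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("module\tfirst_gene\tlast_gene\treference\tmedian_identity\t"
                 "n_measured\tn_unmeasured\n")
        for s in summaries:
            med = "NA" if s.median_identity is None else f"{s.median_identity:.1f}"
            fh.write(
                f"{s.module.name}\t{s.module.first_gene}\t{s.module.last_gene}\t"
                f"{s.reference_genome_id}\t{med}\t{s.n_measured}\t{s.n_unmeasured}\n"
            )


def write_gene_track(t: IdentityTable, modules: Sequence[ModuleDefinition], path) -> None:
    """Per-gene CSV track: gene, product, module, one identity column per
    reference (the text analog of a per-gene map figure)."""
    def module_of(i: int) -> str:
        for m in modules:
            if m.first_gene <= i <= m.last_gene:
                return m.name
        return ""

    with open(path, "w") as fh:
        refs = t.reference_genome_ids
        fh.write("gene_index,locus_tag,product,module," + ",".join(refs) + "\n")
        for p in t.query_proteins:
            vals = []
            for r in refs:
                pid = t.cells[(p.gene_index, r)].percent_identity
                vals.append("" if pid is None else f"{pid:.1f}")
            product = p.product.replace(",", ";")
            fh.write(f"{p.gene_index},{p.locus_tag},{product},{module_of(p.gene_index)},"
                     + ",".join(vals) + "\n")
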