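import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from phagemosaic import identity_profile as ip
from phagemosaic.genome_io import ProteinRecord

# hand-written GenBank fixture: 60 bp, two CDS, one on the minus strand
TWO_GENE_GENBANK = """\
LOCUS       TESTREC                   60 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  synthetic two-gene test record.
ACCESSION   TESTREC
VERSION     TESTREC.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     source          1..60
     CDS             1..9
                     /locus_tag="g1"
                     /product="protein one"
     CDS             complement(10..30)
                     /locus_tag="g2"
                     /product="protein two"
ORIGIN
        1 atggcttaat taagcagcag cagcagccat acgtacgtac gtacgtacgt acgtacgtac
//
"""
# seq[0:9]  = ATGGCTTAA            -> "MA"
# seq[9:30] = TTAAGCAGCAGCAGCAGCCAT; revcomp = ATGGCTGCTGCTGCTGCTTAA -> "MAAAAA"


@pytest.fixture
def two_gene_gb(tmp_path):
    path = tmp_path / "two_gene.gb"
    path.write_text(TWO_GENE_GENBANK)
    return path


def make_protein(idx: int, aa: str, genome_id: str = "q") -> ProteinRecord:
    return ProteinRecord(
        id=f"{genome_id}|p{idx}",
        gene_index=idx,
        aa_sequence=aa,
        genome_id=genome_id,
        start=idx * 100,
        end=idx * 100 + 3 * len(aa),
        strand=1,
        locus_tag=f"p{idx}",
    )


def table_from_matrix(values, refs, query_id="q"):
    """IdentityTable straight from a gene x reference matrix of
    identity-or-None values (synthetic table for segmentation tests)."""
    prots = [make_protein(i, "M", query_id) for i in range(len(values))]
    cells = {}
    for i, row in enumerate(values):
        for r, v in zip(refs, row):
            cells[(i, r)] = ip.IdentityCell(
                query_id=f"{query_id}|p{i}",
                reference_genome_id=r,
                matched_ref_protein_id=None if v is None else f"{r}|x",
                percent_identity=v,
            )
    return ip.IdentityTable(query_id, list(refs), prots, cells)
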