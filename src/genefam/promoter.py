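"""Promoter extraction and IUPAC cis-element scanning.

Promoters are the 2000 bp immediately 5' of the start codon (strand-aware);
offsets of hits are reported as 1-based distance upstream of the A of ATG
(offset 1 = the base adjacent to the start codon). Both strands are scanned;
overlapping and repeated matches are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from genefam._seq import revcomp

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


class PromoterError(ValueError):
    pass


@dataclass
class CisElement:
    element_id: str
    consensus: str           # IUPAC nucleotide string
    function_note: str = ""

    def __post_init__(self):
        if not self.consensus:
            raise PromoterError(f"{self.element_id}: empty consensus")
        bad = [c for c in self.consensus.upper() if c not in IUPAC_CLASSES]
        if bad:
            raise PromoterError(f"{self.element_id}: non-IUPAC symbol {bad[0]!r}")


@dataclass
class CisHit:
    gene_id: str
    element_id: str
    offset: int              # 1-based bp upstream of the start codon (5' end of match)
    strand: str              # '+' or '-'
    matched_sequence: str


@dataclass
class Promoter:
    gene_id: str
    sequence: str
    truncated: bool = False

    def __len__(self):
        return len(self.sequence)


def load_element_catalog(path: str | Path | None = None) -> list[CisElement]:
    """Read an element catalog TSV (element_id, consensus, note); bundled default."""
    if path is None:
        with resources.files("genefam.data").joinpath("cis_elements.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [CisElement(str(r.element_id), str(r.consensus).upper(),
                       str(getattr(r, "note", "")))
            for r in df.itertuples(index=False)]


def write_element_catalog(catalog: list[CisElement], path: str | Path) -> None:
    pd.DataFrame({
        "element_id": [e.element_id for e in catalog],
        "consensus": [e.consensus for e in catalog],
        "note": [e.function_note for e in catalog],
    }).to_csv(path, sep="\t", index=False)


def extract_promoter(gene, genome: dict[str, str], length: int = 2000) -> Promoter:
    """The ``length`` bases 5' of the start codon, strand-aware.

    For '-' strand genes this is the reverse complement of the bases 3' of the
    gene's end coordinate. Truncated (flagged, never padded) at chromosome
    ends. The start codon position is taken from the CDS span (first CDS exon
    boundary) when exon structure is present, else the gene span.
    """
    chrom = genome.get(gene.chromosome)
    if chrom is None:
        raise PromoterError(f"{gene.gene_id}: chromosome {gene.chromosome!r} missing")
    if gene.exons:
        cds_start = min(s for s, _ in gene.exons)
        cds_end = max(e for _, e in gene.exons)
    else:
        cds_start, cds_end = gene.start, gene.end
    if gene.strand == "+":
        lo = max(0, cds_start - length)
        seq = chrom[lo:cds_start]
        truncated = cds_start - lo < length
    else:
        hi = min(len(chrom), cds_end + length)
        seq = revcomp(chrom[cds_end:hi])
        truncated = hi - cds_end < length
    return Promoter(gene_id=getattr(gene, "gene_id", ""), sequence=seq.upper(),
                    truncated=truncated)


def iupac_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(IUPAC_CLASSES[c] for c in consensus.upper()))


def _find_all(seq: str, pattern: re.Pattern, width: int):
    # overlapping matches via zero-width lookahead
    rx = re.compile(f"(?=({pattern.pattern}))")
    for m in rx.finditer(seq):
        yield m.start(), seq[m.start():m.start() + width]


def scan_elements(promoter: Promoter | str, catalog: list[CisElement],
                  gene_id: str | None = None) -> list[CisHit]:
    """Scan both strands of a promoter for every catalogued element."""
    if isinstance(promoter, str):
        promoter = Promoter(gene_id=gene_id or "", sequence=promoter)
    seq = promoter.sequence.upper()
    gid = gene_id or promoter.gene_id
    hits = []
    for element in catalog:
        width = len(element.consensus)
        fwd = iupac_regex(element.consensus)
        rev = iupac_regex(revcomp(element.consensus))
        for start, matched in _find_all(seq, fwd, width):
            hits.append(CisHit(gid, element.element_id, len(seq) - start, "+", matched))
        for start, matched in _find_all(seq, rev, width):
            hits.append(CisHit(gid, element.element_id, len(seq) - start, "-", matched))
    hits.sort(key=lambda h: (-h.offset, h.element_id, h.strand))
    return hits


def element_presence_matrix(hits: list[CisHit], gene_ids: list[str],
                            catalog: list[CisElement]) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x element hit-count matrix plus genes-containing-each-element summary."""
    elements = [e.element_id for e in catalog]
    counts = pd.DataFrame(0, index=list(gene_ids), columns=elements, dtype=int)
    for h in hits:
        if h.gene_id in counts.index and h.element_id in counts.columns:
            counts.loc[h.gene_id, h.element_id] += 1
    presence = (counts > 0).sum(axis=0)
    presence.name = "genes_with_element"
    return counts, presence
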