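"""Family catalogue: genome/annotation IO, gene records, protein parameters, domain screen.

Coordinates are 1-based inclusive in GFF3 and in exported location strings;
the internal representation is 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from genefam._seq import revcomp

# Average (not monoisotopic) residue masses, ProtParam convention, daltons.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# EMBOSS-style pKa values for the ionizable groups.
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
_POSITIVE = ("H", "K", "R")
_NEGATIVE = ("D", "E", "C", "Y")

# Zinc-finger-style consensus used as the default family membership screen.
# A consensus pattern approximates the profile-HMM domain confirmation a full
# study would run; see the methods note.
DEFAULT_DOMAIN_PATTERN = "C-x(2)-C-x(10)-H-x(3)-H"

CATALOG_COLUMNS = [
    "gene", "locus", "orf_bp", "location", "aa",
    "domain_start", "domain_end", "mw", "pi", "exons",
]

_LOCATION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)\.\.(?P<end>\d+)\((?P<strand>[+-])\)$")


class CatalogError(ValueError):
    pass


@dataclass
class DomainHit:
    """One match of the family domain pattern on a protein (0-based, half-open)."""
    gene_id: str
    pattern_id: str
    start: int
    end: int
    matched_subsequence: str


@dataclass
class GeneRecord:
    """One family member with its derived gene/protein parameters."""
    gene_id: str
    locus_tag: str
    chromosome: str
    start: int                       # 0-based
    end: int                         # exclusive
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # CDS intervals, 0-based half-open, genome order
    cds_sequence: str | None = None
    protein_sequence: str | None = None
    orf_length: int = 0
    protein_length: int = 0
    molecular_weight: float | None = None
    isoelectric_point: float | None = None
    exon_count: int = 0
    subfamily: str | None = None
    domain_hits: list[DomainHit] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def intron_count(self) -> int:
        return self.exon_count - 1

    def validate(self) -> None:
        if self.start > self.end:
            raise CatalogError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise CatalogError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise CatalogError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = e
        if self.exons and self.orf_length != sum(e - s for s, e in self.exons):
            raise CatalogError(f"{self.gene_id}: orf_length does not match exon lengths")
        if self.orf_length % 3 != 0:
            raise CatalogError(f"{self.gene_id}: ORF length {self.orf_length} not divisible by 3")
        if self.orf_length and self.protein_length != orf_to_protein_length(self.orf_length):
            raise CatalogError(
                f"{self.gene_id}: protein length {self.protein_length} != "
                f"ORF {self.orf_length}/3 - 1"
            )

    @property
    def location(self) -> str:
        return f"{self.chromosome}:{self.start + 1}..{self.end}({self.strand})"


def orf_to_protein_length(orf_bp: int) -> int:
    """Protein length (aa) encoded by an ORF of ``orf_bp`` nucleotides.

    The ORF includes the stop codon; the protein does not, so the answer is
    orf_bp/3 - 1 (e.g. a 2418 bp ORF encodes 805 aa, a 252 bp one 83 aa).
    """
    if orf_bp % 3 != 0:
        raise CatalogError(f"ORF length {orf_bp} is not divisible by 3 (frame problem)")
    if orf_bp < 6:
        raise CatalogError(f"ORF length {orf_bp} is too short for one codon plus stop")
    return orf_bp // 3 - 1


def _net_charge(protein: str, ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA["Cterm"] - ph))
    for aa in _POSITIVE:
        charge += protein.count(aa) / (1.0 + 10 ** (ph - PKA[aa]))
    for aa in _NEGATIVE:
        charge -= protein.count(aa) / (1.0 + 10 ** (PKA[aa] - ph))
    return charge


def protein_params(protein: str) -> tuple[int, float, float]:
    """Length (aa), molecular weight (Da, average masses) and pI of a protein.

    The pI is the pH at which the Henderson-Hasselbalch net charge over the
    termini and the D/E/C/Y/H/K/R side chains crosses zero, located by
    bisection to |charge| < 1e-4.
    """
    if not protein:
        raise CatalogError("empty protein sequence")
    for i, aa in enumerate(protein):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise CatalogError(f"non-standard residue {aa!r} at position {i}")
    mw = sum(AVERAGE_RESIDUE_MASS[aa] for aa in protein) + WATER_MASS
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-8:        # converges well past |charge| < 1e-4
        mid = (lo + hi) / 2.0
        if _net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return len(protein), mw, (lo + hi) / 2.0


class PatternSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (element {position})")
        self.position = position


def _pattern_to_regex(pattern: str) -> str:
    """Compile a PROSITE-style pattern (A, x, [..], {..}, (n) / (n,m)) to a regex."""
    parts = pattern.strip().rstrip(".").split("-")
    out = []
    for i, part in enumerate(parts):
        m = re.fullmatch(
            r"(?P<core>[A-Za-z]|x|\[[A-Z]+\]|\{[A-Z]+\})(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?",
            part,
        )
        if m is None:
            raise PatternSyntaxError(f"malformed pattern element {part!r}", i)
        core = m.group("core")
        if core == "x":
            rx = "[A-Z]"
        elif core.startswith("["):
            rx = core
        elif core.startswith("{"):
            rx = "[^" + core[1:-1] + "]"
        else:
            rx = core.upper()
        if m.group("lo"):
            rx += "{" + m.group("lo") + ("," + m.group("hi") if m.group("hi") else "") + "}"
        out.append(rx)
    if not out:
        raise PatternSyntaxError("empty pattern", 0)
    return "".join(out)


def scan_domain(protein: str, pattern: str = DEFAULT_DOMAIN_PATTERN,
                gene_id: str = "", pattern_id: str | None = None) -> list[DomainHit]:
    """All non-overlapping leftmost matches of ``pattern`` on ``protein``."""
    rx = re.compile(_pattern_to_regex(pattern))
    hits = []
    for m in rx.finditer(protein):
        hits.append(DomainHit(gene_id=gene_id, pattern_id=pattern_id or pattern,
                              start=m.start(), end=m.end(),
                              matched_subsequence=m.group(0)))
    return hits


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _spliced_cds(genome: dict[str, str], chrom: str, exons: list[tuple[int, int]],
                 strand: str, gene_id: str) -> str:
    if chrom not in genome:
        raise CatalogError(f"{gene_id}: chromosome {chrom!r} missing from genome FASTA")
    seq = "".join(genome[chrom][s:e] for s, e in exons)
    return revcomp(seq) if strand == "-" else seq


def load_catalog(genome: str | Path, annotation: str | Path, cds: str | Path,
                 proteins: str | Path,
                 domain_pattern: str = DEFAULT_DOMAIN_PATTERN) -> list[GeneRecord]:
    """Assemble GeneRecords for every annotated gene present in the family CDS FASTA.

    The CDS is reconstructed from genome + annotation (strand-aware, spliced)
    and must equal the supplied CDS; disagreement flags the record (it is never
    silently dropped). A chromosome missing from the genome is a hard error.
    """
    import gffutils

    genome_seqs = _read_fasta(genome)
    cds_seqs = _read_fasta(cds)
    protein_seqs = _read_fasta(proteins)

    db = gffutils.create_db(str(annotation), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.id
        if gene_id not in cds_seqs:
            continue  # non-family (spacer) gene
        cds_feats = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
        exons = [(f.start - 1, f.end) for f in cds_feats]
        rec = GeneRecord(
            gene_id=gene_id,
            locus_tag=gene.attributes.get("locus_tag", [gene_id])[0],
            chromosome=gene.seqid,
            start=gene.start - 1,
            end=gene.end,
            strand=gene.strand,
            exons=exons,
        )
        supplied = cds_seqs[gene_id]
        rebuilt = _spliced_cds(genome_seqs, gene.seqid, exons, gene.strand, gene_id)
        if rebuilt != supplied:
            rec.flags.append("cds_mismatch")
        rec.cds_sequence = supplied
        rec.orf_length = len(supplied)
        rec.exon_count = len(exons)
        prot = protein_seqs.get(gene_id)
        if prot is None:
            rec.flags.append("protein_missing")
        else:
            rec.protein_sequence = prot
            rec.protein_length, rec.molecular_weight, rec.isoelectric_point = protein_params(prot)
            translated = str(Seq(supplied).translate()).rstrip("*")
            if translated != prot:
                rec.flags.append("translation_mismatch")
            rec.domain_hits = scan_domain(prot, domain_pattern, gene_id=gene_id)
        rec.validate()
        records.append(rec)
    return records


def gene_structure_summary(records) -> dict:
    """Per-gene intron counts plus family-level tallies.

    Accepts GeneRecords or any DataFrame with ``chromosome`` and ``exon_count``
    columns. Returns intronless count, an intron-count histogram and
    per-chromosome gene tallies.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame({
            "gene": [r.gene_id for r in records],
            "chromosome": [r.chromosome for r in records],
            "exon_count": [r.exon_count for r in records],
        })
    introns = df["exon_count"].astype(int) - 1
    if (introns < 0).any():
        raise CatalogError("exon_count must be >= 1")
    per_chrom = df.groupby("chromosome").size().sort_index()
    return {
        "n_genes": int(len(df)),
        "intron_counts": introns.tolist(),
        "intronless_genes": int((introns == 0).sum()),
        "intron_histogram": {int(k): int(v) for k, v in introns.value_counts().sort_index().items()},
        "genes_per_chromosome": {str(k): int(v) for k, v in per_chrom.items()},
        "occupied_chromosomes": int(per_chrom.shape[0]),
    }


def records_to_frame(records: list[GeneRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        hit = r.domain_hits[0] if r.domain_hits else None
        rows.append({
            "gene": r.gene_id,
            "locus": r.locus_tag,
            "orf_bp": r.orf_length,
            "location": r.location,
            "aa": r.protein_length,
            "domain_start": hit.start if hit else pd.NA,
            "domain_end": hit.end if hit else pd.NA,
            "mw": None if r.molecular_weight is None else round(r.molecular_weight, 2),
            "pi": None if r.isoelectric_point is None else round(r.isoelectric_point, 2),
            "exons": r.exon_count,
        })
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def write_catalog_tsv(records: list[GeneRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def _parse_location(location: str) -> tuple[str, int, int, str]:
    m = _LOCATION_RE.match(location)
    if m is None:
        raise CatalogError(f"unparseable location string {location!r}")
    return m.group("chrom"), int(m.group("start")) - 1, int(m.group("end")), m.group("strand")


def read_catalog_tsv(path: str | Path) -> list[GeneRecord]:
    """Re-import an exported catalogue TSV (sequence fields stay unset)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "locus": str})
    records = []
    for row in df.itertuples(index=False):
        chrom, start, end, strand = _parse_location(row.location)
        rec = GeneRecord(
            gene_id=row.gene, locus_tag=row.locus, chromosome=chrom,
            start=start, end=end, strand=strand, exons=[],
            orf_length=int(row.orf_bp),
            protein_length=int(row.aa),
            molecular_weight=None if pd.isna(row.mw) else float(row.mw),
            isoelectric_point=None if pd.isna(row.pi) else float(row.pi),
            exon_count=int(row.exons),
        )
        if not pd.isna(row.domain_start):
            rec.domain_hits = [DomainHit(row.gene, "imported", int(row.domain_start),
                                         int(row.domain_end), "")]
        records.append(rec)
    return records


def load_reference_catalog() -> pd.DataFrame:
    """The bundled tomato family table (printed gene/protein parameters).

    Columns follow the catalogue export; ``chromosome`` and ``exon_count`` are
    added for the structure summary. Note the source prints molecular weights
    labelled kDa although the values are daltons; they are daltons here.
    """
    with resources.files("genefam.data").joinpath("tomato_zhd_table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    parsed = df["location"].map(_parse_location)
    df["chromosome"] = [p[0] for p in parsed]
    df["start"] = [p[1] for p in parsed]
    df["end"] = [p[2] for p in parsed]
    df["strand"] = [p[3] for p in parsed]
    df["exon_count"] = df["exons"]
    return df
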