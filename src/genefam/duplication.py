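"""Pairwise identity/coverage and segmental vs tandem duplication classification.

Segmental: both genes pass the identity and query-coverage threshold (default
>= 80%, inclusive) with either gene as query, on a local alignment. Tandem:
same chromosome, at most 5 intervening annotated genes, and the two genes
within a 100-kb window. When both criteria hold the pair is reported tandem
(physical adjacency is the stronger claim).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


class DuplicationError(ValueError):
    pass


@dataclass
class PairwiseAlignmentStats:
    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    aligned_length: int
    score: float


@dataclass
class DuplicationCall:
    gene_a: str
    gene_b: str
    kind: str                       # segmental | tandem | none
    same_chromosome: bool
    intervening_genes: int | None
    span_bp: int | None
    percent_identity: float | None = None
    coverage_a: float | None = None
    coverage_b: float | None = None


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if mode == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    elif mode == "cds":
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
    else:
        raise DuplicationError(f"unknown alignment mode {mode!r}")
    return aligner


def pairwise_stats(query: str, subject: str, mode: str = "cds",
                   query_id: str = "query", subject_id: str = "subject") -> PairwiseAlignmentStats:
    """Local-alignment identity and query coverage for one ordered pair."""
    if not query or not subject:
        raise DuplicationError("empty sequence")
    aln = _aligner(mode).align(query.upper(), subject.upper())[0]
    c = aln.counts()
    # columns of the local alignment: matches, mismatches and internal gaps
    aligned_length = c.identities + c.mismatches + c.internal_gaps
    identities = c.identities
    identity = 100.0 * identities / aligned_length if aligned_length else 0.0
    qblocks = aln.aligned[0]
    qspan = (qblocks[-1][1] - qblocks[0][0]) if len(qblocks) else 0
    coverage = 100.0 * qspan / len(query)
    return PairwiseAlignmentStats(
        query_id=query_id, subject_id=subject_id,
        percent_identity=identity, query_coverage=coverage,
        aligned_length=int(aligned_length), score=float(aln.score),
    )


def classify_segmental(stats: PairwiseAlignmentStats, threshold: float = 80.0) -> bool:
    """True iff identity >= threshold AND query coverage >= threshold (inclusive)."""
    return stats.percent_identity >= threshold and stats.query_coverage >= threshold


class GeneAnnotation:
    """Coordinate-ordered gene list per chromosome (family and spacer genes)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"gene", "chromosome", "start", "end"}
        if not required.issubset(frame.columns):
            raise DuplicationError(f"annotation needs columns {sorted(required)}")
        self.frame = frame.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
        self._rank = {}
        for chrom, grp in self.frame.groupby("chromosome", sort=False):
            for rank, row in enumerate(grp.itertuples(index=False)):
                self._rank[row.gene] = (chrom, rank, int(row.start), int(row.end))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
        rows = [{"gene": g.id, "chromosome": g.seqid, "start": g.start - 1, "end": g.end}
                for g in db.features_of_type("gene", order_by="start")]
        return cls(pd.DataFrame(rows))

    def locate(self, gene_id: str):
        if gene_id not in self._rank:
            raise DuplicationError(f"gene {gene_id!r} absent from annotation")
        return self._rank[gene_id]


def classify_tandem(a, b, annotation: GeneAnnotation,
                    max_intervening: int = 5, window_bp: int = 100_000) -> DuplicationCall:
    """Tandem call from coordinates: same chromosome, <= max_intervening genes
    strictly between, nearest-end distance <= window_bp."""
    ida = a if isinstance(a, str) else a.gene_id
    idb = b if isinstance(b, str) else b.gene_id
    chrom_a, rank_a, start_a, end_a = annotation.locate(ida)
    chrom_b, rank_b, start_b, end_b = annotation.locate(idb)
    if chrom_a != chrom_b:
        return DuplicationCall(ida, idb, "none", False, None, None)
    intervening = abs(rank_a - rank_b) - 1
    if rank_a <= rank_b:
        span = max(0, start_b - end_a)
    else:
        span = max(0, start_a - end_b)
    kind = "tandem" if (intervening <= max_intervening and span <= window_bp) else "none"
    return DuplicationCall(ida, idb, kind, True, intervening, span)


def call_all_duplications(records, annotation: GeneAnnotation, mode: str = "cds",
                          threshold: float = 80.0, max_intervening: int = 5,
                          window_bp: int = 100_000) -> list[DuplicationCall]:
    """Evaluate every unordered pair for segmental and tandem duplication.

    Segmental requires both orientations (each gene as query) to pass; a pair
    meeting both criteria is reported tandem.
    """
    seq_attr = "cds_sequence" if mode == "cds" else "protein_sequence"
    calls = []
    for a, b in combinations(records, 2):
        tandem = classify_tandem(a, b, annotation, max_intervening, window_bp)
        sa = pairwise_stats(getattr(a, seq_attr), getattr(b, seq_attr), mode,
                            a.gene_id, b.gene_id)
        sb = pairwise_stats(getattr(b, seq_attr), getattr(a, seq_attr), mode,
                            b.gene_id, a.gene_id)
        segmental = classify_segmental(sa, threshold) and classify_segmental(sb, threshold)
        kind = "none"
        if tandem.kind == "tandem":
            kind = "tandem"
        elif segmental:
            kind = "segmental"
        calls.append(DuplicationCall(
            gene_a=a.gene_id, gene_b=b.gene_id, kind=kind,
            same_chromosome=tandem.same_chromosome,
            intervening_genes=tandem.intervening_genes, span_bp=tandem.span_bp,
            percent_identity=round((sa.percent_identity + sb.percent_identity) / 2, 3),
            coverage_a=round(sa.query_coverage, 3), coverage_b=round(sb.query_coverage, 3),
        ))
    return calls


DUPLICATION_COLUMNS = ["gene_a", "gene_b", "identity", "coverage_a", "coverage_b",
                       "kind", "intervening_genes", "span_bp"]


def duplication_report(calls: list[DuplicationCall]) -> pd.DataFrame:
    rows = [{
        "gene_a": c.gene_a, "gene_b": c.gene_b, "identity": c.percent_identity,
        "coverage_a": c.coverage_a, "coverage_b": c.coverage_b, "kind": c.kind,
        "intervening_genes": c.intervening_genes, "span_bp": c.span_bp,
    } for c in calls]
    return pd.DataFrame(rows, columns=DUPLICATION_COLUMNS)
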