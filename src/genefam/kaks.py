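"""Nei-Gojobori (1986) Ka/Ks estimation, selection-mode calls, divergence dating.

The counting method: per-codon synonymous site fractions (changes to stop
codons never count as synonymous), pathway-averaged difference counts for
codons differing at 2 or 3 positions (pathways through stop codons are
discarded; a codon pair whose pathways all hit stops is dropped), sites
averaged over the two sequences, Jukes-Cantor correction of the proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data import CodonTable

from genefam._seq import codons_of

_BASES = "ACGT"


class KaKsError(ValueError):
    pass


class SaturationError(KaKsError):
    """Raised when a proportion of differences is beyond the Jukes-Cantor domain."""


@dataclass
class EvolutionConfig:
    """Molecular-clock settings: per-site yearly substitution rate and code table."""
    r: float = 1.5e-8          # substitutions/site/year, dicot default
    genetic_code: int = 1      # NCBI table id (1 = universal)

    def __post_init__(self):
        if self.r <= 0:
            raise KaKsError("substitution rate r must be positive")


@dataclass
class CodonPairStats:
    """NG86 intermediates and results for one paralog pair."""
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float | None
    Ka: float | None
    codons_used: int
    ks_saturated: bool = False
    ka_saturated: bool = False

    @property
    def ratio(self) -> float | None:
        """Ka/Ks; None when Ks is zero or either correction is saturated."""
        if self.Ks is None or self.Ka is None or self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _code_tables(code: int = 1):
    table = CodonTable.unambiguous_dna_by_id[code]
    fwd = dict(table.forward_table)
    stops = set(table.stop_codons)
    return fwd, stops


def _syn_site_fraction(codon: str, fwd: dict, stops: set) -> float:
    """Fraction of synonymous sites in one codon (sum over positions of s_i/3)."""
    if codon in stops:
        raise KaKsError(f"stop codon {codon} inside coding sequence")
    aa = fwd[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in stops and fwd[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


def _pathway_counts(c1: str, c2: str, fwd: dict, stops: set) -> tuple[float, float] | None:
    """Pathway-averaged (Sd, Nd) for one codon pair; None if every pathway hits a stop."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                blocked = True
                break
            if fwd[cur] == fwd[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return None
    return sd_total / n_paths, nd_total / n_paths


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3), substitutions/site.

    Raises :class:`SaturationError` for p >= 3/4 — never a silent number.
    """
    if p < 0:
        raise KaKsError(f"proportion p={p} must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p={p} is saturated (>= 3/4); distance undefined")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def codon_align(cds_a: str, cds_b: str,
                protein_alignment: tuple[str, str]) -> list[tuple[str, str]]:
    """Back-translate a pairwise protein alignment to aligned codon columns.

    Terminal stop codons are stripped from each CDS first. Translations must
    match the ungapped aligned proteins (mismatch errors name the codon
    index). Alignment gaps propagate as ``---`` codons.
    """
    fwd, stops = _code_tables(1)
    out_cols = []
    seq_codons = []
    for cds in (cds_a, cds_b):
        cod = codons_of(cds.upper())
        if cod and cod[-1] in stops:
            cod = cod[:-1]
        seq_codons.append(cod)
    aln_a, aln_b = (a.upper() for a in protein_alignment)
    if len(aln_a) != len(aln_b):
        raise KaKsError("aligned proteins have unequal lengths")
    idx = [0, 0]
    for col in range(len(aln_a)):
        pair = []
        for k, aa in enumerate((aln_a[col], aln_b[col])):
            if aa == "-":
                pair.append("---")
                continue
            if idx[k] >= len(seq_codons[k]):
                raise KaKsError(f"alignment longer than CDS {k + 1} at codon {idx[k]}")
            codon = seq_codons[k][idx[k]]
            translated = fwd.get(codon, "X")
            if translated != aa:
                raise KaKsError(
                    f"translation mismatch in sequence {k + 1} at codon {idx[k]}: "
                    f"{codon} -> {translated}, alignment has {aa}"
                )
            pair.append(codon)
            idx[k] += 1
        out_cols.append((pair[0], pair[1]))
    for k in (0, 1):
        if idx[k] != len(seq_codons[k]):
            raise KaKsError(f"alignment shorter than CDS {k + 1}")
    return out_cols


def ng86(codon_alignment: list[tuple[str, str]], code: int = 1) -> CodonPairStats:
    """NG86 statistics for a codon-aligned pair.

    Codons containing gaps or ambiguity are dropped pairwise, as are codon
    pairs whose every mutational pathway passes through a stop codon.
    """
    fwd, stops = _code_tables(code)
    s1 = s2 = 0.0
    sd = nd = 0.0
    used = 0
    for c1, c2 in codon_alignment:
        c1, c2 = c1.upper(), c2.upper()
        if any(b not in _BASES for b in c1 + c2):
            continue
        counts = _pathway_counts(c1, c2, fwd, stops)
        if counts is None:
            continue
        s1 += _syn_site_fraction(c1, fwd, stops)
        s2 += _syn_site_fraction(c2, fwd, stops)
        sd += counts[0]
        nd += counts[1]
        used += 1
    if used == 0:
        raise KaKsError("no retained codon pairs")
    S = (s1 + s2) / 2.0
    N = 3.0 * used - S
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = ka = None
    ks_sat = ka_sat = False
    try:
        ks = jukes_cantor(ps)
    except SaturationError:
        ks_sat = True
    try:
        ka = jukes_cantor(pn)
    except SaturationError:
        ka_sat = True
    return CodonPairStats(S=S, N=N, Sd=sd, Nd=nd, ps=ps, pn=pn, Ks=ks, Ka=ka,
                          codons_used=used, ks_saturated=ks_sat, ka_saturated=ka_sat)


def selection_mode(ratio: float | None) -> str:
    """Classify a Ka/Ks ratio: >1 positive, <1 purifying, =1 neutral, else undefined."""
    if ratio is None:
        return "undefined"
    if abs(ratio - 1.0) < 1e-9:
        return "neutral"
    return "positive" if ratio > 1.0 else "purifying"


def divergence_time(ks: float | None, config: EvolutionConfig | None = None) -> float | None:
    """Divergence time T = Ks / (2 r), in millions of years (Mya)."""
    if config is None:
        config = EvolutionConfig()
    if ks is None:
        return None
    if ks < 0:
        raise KaKsError("Ks must be non-negative")
    return ks / (2.0 * config.r) / 1e6
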