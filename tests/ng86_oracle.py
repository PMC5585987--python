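"""Brute-force codon-evolution oracle, independent of the package implementation.

Classifies every single-nucleotide change of every codon by translating with
Biopython, and enumerates all mutational pathways between codon pairs
explicitly. Used to validate the production counting code.
"""

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    """Synonymous-site fraction: synonymous single changes / 3, stops never count."""
    total = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _aa(alt) != "*" and _aa(alt) == _aa(codon):
                total += 1
    return total / 3.0


def oracle_pair(c1: str, c2: str):
    """Pathway-averaged (sd, nd); None when every pathway passes through a stop."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    results = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*":
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def oracle_ng86(codon_pairs):
    """Full NG86 aggregation done the slow explicit way."""
    s1 = s2 = sd = nd = 0.0
    used = 0
    for c1, c2 in codon_pairs:
        if any(b not in BASES for b in c1 + c2):
            continue
        counts = oracle_pair(c1, c2)
        if counts is None:
            continue
        s1 += oracle_syn_sites(c1)
        s2 += oracle_syn_sites(c2)
        sd += counts[0]
        nd += counts[1]
        used += 1
    S = (s1 + s2) / 2.0
    N = 3.0 * used - S
    return {"S": S, "N": N, "Sd": sd, "Nd": nd, "codons_used": used}


SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                if _aa(a + b + c) != "*"]
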