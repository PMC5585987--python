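"""Synthetic gene-family generator with full ground truth.

Emits a mutually consistent bundle (genome FASTA, GFF3, CDS/protein FASTA,
protein alignment, cis-element catalog, Ct table, ground-truth JSON) for a
multigene family arising from duplications with controlled Ks/Ka, a mixed
tandem/dispersed layout, 0-3-intron gene structures, 2000-bp promoters with
planted elements, and triplicate qPCR Ct tables with planted fold changes.
Identical seeds give byte-identical bundles.

The default configuration mirrors a tomato-sized zinc-finger-homeodomain
family: 22 genes in 6 subfamilies on 6 of 12 chromosomes, 13 intronless
genes, four dispersed (segmental) duplicate pairs spanning target Ks
0.13-0.30 (divergence dates ~4.3-10 Mya at r = 1.5e-8) plus one tandem pair,
stress-element tallies MBS 11 / ABRE 11 / HSE 12 / LTR 3 / DRE 1 genes, and
fold inductions in the 1.5-8x range with Gaussian Ct noise (sd 0.2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from genefam._seq import codons_of, revcomp
from genefam.catalog import DEFAULT_DOMAIN_PATTERN
from genefam.kaks import _code_tables, _syn_site_fraction
from genefam.phylogeny import Clade, Tree
from genefam.promoter import CisElement, Promoter, load_element_catalog, scan_elements

_BASES = "ACGT"

# Instantiates the default domain pattern C-x(2)-C-x(10)-H-x(3)-H.
DOMAIN_PEPTIDE = "CAECGKRSFTDWLQHNMVH"
DOMAIN_CODON_OFFSET = 30


class SimulationError(ValueError):
    pass


@dataclass
class DuplicationPlanItem:
    pair: tuple[int, int]            # gene indices (0-based); second derives from first
    layout: str                      # "tandem" | "dispersed"
    target_ks: float
    target_ka: float


def _default_duplication_plan() -> list[DuplicationPlanItem]:
    return [
        DuplicationPlanItem((0, 1), "dispersed", 0.13, 0.039),
        DuplicationPlanItem((6, 7), "dispersed", 0.18, 0.054),
        DuplicationPlanItem((11, 12), "dispersed", 0.24, 0.072),
        DuplicationPlanItem((15, 16), "dispersed", 0.30, 0.090),
        DuplicationPlanItem((18, 19), "tandem", 0.10, 0.030),
    ]


# exon counts 2,2,1,1,2,1,2,1,1,1,1,1,1,1,2,3,2,1,1,1,2,4 -> introns:
_DEFAULT_INTRONS = [1, 1, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 2, 1, 0, 0, 0, 1, 3]

_DEFAULT_SUBFAMILY_SIZES = (6, 5, 4, 3, 3, 1)

# chromosome -> family gene indices, in coordinate order
_DEFAULT_LAYOUT = {
    "ch01": [0, 2, 3, 4, 5, 11],
    "ch02": [1, 6, 12, 20, 21],
    "ch03": [7, 8, 9],
    "ch04": [10, 13, 14],
    "ch05": [15, 17, 18, 19],
    "ch09": [16],
}


def _default_element_plan(n_genes: int) -> dict[str, list[int]]:
    # genes containing each element (tallies mirror the study: 11/11/12/3/1)
    return {
        "MBS": list(range(0, 11)),
        "ABRE": list(range(11, 22)),
        "HSE": list(range(5, 17)),
        "LTR": [3, 9, 15],
        "DRE": [21],
    }


@dataclass
class FamilySimConfig:
    n_genes: int = 22
    n_chromosomes: int = 12
    n_subfamilies: int = 6
    subfamily_sizes: tuple[int, ...] = _DEFAULT_SUBFAMILY_SIZES
    duplication_plan: list[DuplicationPlanItem] = field(default_factory=_default_duplication_plan)
    intron_plan: list[int] = field(default_factory=lambda: list(_DEFAULT_INTRONS))
    element_plan: dict[str, list[int]] | None = None
    samples: tuple[str, ...] = ("0h", "1h", "3h", "9h", "24h")
    calibrator_sample: str = "0h"
    reference_gene: str = "EF1a"
    n_replicates: int = 3
    ct_noise_sd: float = 0.2
    peak_fold_gene: int = 0          # this gene gets an exact 8-fold induction
    peak_fold: float = 8.0
    peak_fold_sample: str = "1h"
    n_codons: int = 180              # excluding the stop codon
    intron_length: int = 200
    root_branch: tuple[float, float] = (0.8, 0.28)      # (Ks, Ka) root -> subfamily
    within_branch: tuple[float, float] = (0.4, 0.12)    # subfamily -> member
    seed: int = 0

    def __post_init__(self):
        if sum(self.subfamily_sizes) != self.n_genes:
            raise SimulationError("subfamily sizes must sum to n_genes")
        if len(self.intron_plan) != self.n_genes:
            raise SimulationError("intron plan length must equal n_genes")
        if any(k < 0 or k > 3 for k in self.intron_plan):
            raise SimulationError("intron counts must be 0-3")
        for item in self.duplication_plan:
            if item.target_ks < 0 or item.target_ka < 0:
                raise SimulationError("duplication targets must be >= 0")
            if max(item.pair) >= self.n_genes:
                raise SimulationError("duplication plan references missing gene")
        if self.element_plan is None:
            self.element_plan = _default_element_plan(self.n_genes)


def _inv_jukes_cantor(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _sense_codons(code: int = 1) -> list[str]:
    fwd, _ = _code_tables(code)
    return sorted(fwd)


def _random_cds(rng: np.random.Generator, n_codons: int, code: int = 1) -> str:
    sense = _sense_codons(code)
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))
    return body + "TAA"


def _encode_peptide(peptide: str, code: int = 1) -> str:
    fwd, _ = _code_tables(code)
    by_aa: dict[str, str] = {}
    for codon in sorted(fwd):
        by_aa.setdefault(fwd[codon], codon)
    return "".join(by_aa[aa] for aa in peptide)


def _plant_domain(cds: str, code: int = 1) -> str:
    dom = _encode_peptide(DOMAIN_PEPTIDE, code)
    start = DOMAIN_CODON_OFFSET * 3
    return cds[:start] + dom + cds[start + len(dom):]


def _domain_codon_indices() -> set[int]:
    return set(range(DOMAIN_CODON_OFFSET, DOMAIN_CODON_OFFSET + len(DOMAIN_PEPTIDE)))


def simulate_codon_divergence(ancestor_cds: str, target_ks: float, target_ka: float,
                              code: int = 1, seed: int | np.random.Generator = 0,
                              frozen_codons: set[int] | None = None):
    """Derive a CDS from an ancestor at target (Ks, Ka), one substitution per codon.

    Substitutions are proposed uniformly, classified synonymous/nonsynonymous
    by translation, and rejected if they create a stop codon; each codon is
    hit at most once so the realized difference counts are exact. Targets are
    inverted through the Jukes-Cantor map into difference counts against the
    ancestor's NG86 site totals. Returns (derived_cds, realized) where
    realized carries Sd, Nd, S, N and the realized JC-corrected Ks/Ka.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fwd, stops = _code_tables(code)
    codons = codons_of(ancestor_cds.upper())
    work = list(codons)
    last = len(codons) - 1
    has_stop = codons[last] in stops
    coding_idx = [i for i, c in enumerate(codons) if not (has_stop and i == last)]
    for i in coding_idx:
        if codons[i] in stops:
            raise SimulationError(f"internal stop codon at {i}")
    frozen = set(frozen_codons or set())
    if has_stop:
        frozen.add(last)
    if target_ks >= 2.0 or target_ka >= 2.0:
        raise SimulationError("target distance saturated/unreachable")
    S = sum(_syn_site_fraction(codons[i], fwd, stops) for i in coding_idx)
    N = 3.0 * len(coding_idx) - S
    ps = _inv_jukes_cantor(target_ks)
    pn = _inv_jukes_cantor(target_ka)
    need_s = int(round(ps * S))
    need_n = int(round(pn * N))
    mutable = [i for i in coding_idx if i not in frozen]
    if need_s + need_n > len(mutable):
        raise SimulationError(
            f"targets need {need_s + need_n} substitutions but only "
            f"{len(mutable)} mutable codons are available")
    plan = ["s"] * need_s + ["n"] * need_n
    rng.shuffle(plan)
    unused = list(mutable)
    done_s = done_n = 0
    for want in plan:
        order = rng.permutation(len(unused))
        placed = False
        for k in order:
            i = unused[k]
            codon = work[i]
            aa = fwd[codon]
            options = []
            for pos in range(3):
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1:]
                    if alt in stops:
                        continue
                    syn = fwd[alt] == aa
                    if (want == "s") == syn:
                        options.append(alt)
            if options:
                work[i] = options[int(rng.integers(0, len(options)))]
                unused.pop(k)
                if want == "s":
                    done_s += 1
                else:
                    done_n += 1
                placed = True
                break
        if not placed:
            raise SimulationError(f"no codon left with a {want!r} change; target unreachable")
    realized = {
        "Sd": done_s, "Nd": done_n, "S": S, "N": N,
        "ks": -0.75 * math.log(1 - 4 * (done_s / S) / 3) if S else 0.0,
        "ka": -0.75 * math.log(1 - 4 * (done_n / N) / 3) if N else 0.0,
    }
    return "".join(work), realized


def _gene_body(rng: np.random.Generator, cds: str, n_introns: int,
               intron_length: int) -> tuple[str, list[tuple[int, int]]]:
    """Sense-strand gene body with introns; exon intervals in body coordinates."""
    if n_introns == 0:
        return cds, [(0, len(cds))]
    cuts = sorted(int(round(len(cds) * (k + 1) / (n_introns + 1))) for k in range(n_introns))
    parts = []
    exons = []
    pos = 0
    body_pos = 0
    for cut in cuts + [len(cds)]:
        chunk = cds[pos:cut]
        parts.append(chunk)
        exons.append((body_pos, body_pos + len(chunk)))
        body_pos += len(chunk)
        pos = cut
        if cut != len(cds):
            inner = "".join(_BASES[i] for i in rng.integers(0, 4, size=intron_length - 4))
            intron = "GT" + inner + "AG"
            parts.append(intron)
            body_pos += len(intron)
    return "".join(parts), exons


def _clean_background(rng: np.random.Generator, length: int,
                      catalog: list[CisElement]) -> str:
    """Random sequence rejection-sampled so no catalogued element matches it."""
    seq = list("".join(_BASES[i] for i in rng.integers(0, 4, size=length)))
    for _ in range(200):
        hits = scan_elements(Promoter("", "".join(seq)), catalog)
        if not hits:
            return "".join(seq)
        for h in hits:
            start = length - h.offset
            for j in range(start, min(length, start + len(h.matched_sequence))):
                seq[j] = _BASES[int(rng.integers(0, 4))]
    raise SimulationError("could not generate element-free background")


def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    from genefam.promoter import IUPAC_CLASSES

    out = []
    for c in consensus.upper():
        cls = IUPAC_CLASSES[c].strip("[]")
        out.append(cls[int(rng.integers(0, len(cls)))])
    return "".join(out)


def _build_promoter(rng: np.random.Generator, length: int, catalog: list[CisElement],
                    plant: list[str]) -> tuple[str, list[dict]]:
    """Element-free background with the requested elements planted on random strands."""
    by_id = {e.element_id: e for e in catalog}
    for _ in range(50):
        seq = list(_clean_background(rng, length, catalog))
        slots = list(range(50, length - 60, 30))
        if len(plant) > len(slots):
            raise SimulationError("too many elements to plant")
        chosen = rng.choice(len(slots), size=len(plant), replace=False)
        truth = []
        for element_id, slot_i in zip(plant, sorted(chosen)):
            start = slots[int(slot_i)]
            inst = _instantiate(rng, by_id[element_id].consensus)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            planted = inst if strand == "+" else revcomp(inst)
            seq[start:start + len(planted)] = list(planted)
            truth.append({"element_id": element_id, "offset": length - start,
                          "strand": strand, "sequence": inst})
        final = "".join(seq)
        hits = scan_elements(Promoter("", final), catalog)
        # a hit is expected iff it sits exactly on a planted window of the same
        # element (a palindromic consensus legitimately matches both strands)
        planted_pos = {(t["element_id"], length - t["offset"]) for t in truth}
        observed_pos = {(h.element_id, length - h.offset) for h in hits}
        if planted_pos == observed_pos:
            hit_counts: dict[str, int] = {}
            for h in hits:
                hit_counts[h.element_id] = hit_counts.get(h.element_id, 0) + 1
            return final, sorted(truth, key=lambda t: -t["offset"]), hit_counts
    raise SimulationError("could not plant elements without accidental matches")


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def _write_fasta(path: Path, entries: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{_wrap_fasta(seq)}\n")


@dataclass
class SimulatedFamily:
    outdir: Path
    paths: dict[str, Path]
    ground_truth: dict


def simulate_family(config: FamilySimConfig, outdir: str | Path) -> SimulatedFamily:
    """Generate the full family bundle under ``outdir``; see module docstring."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    code = 1
    catalog = load_element_catalog()

    # --- sequences ---------------------------------------------------------
    root = _plant_domain(_random_cds(rng, config.n_codons, code), code)
    frozen = _domain_codon_indices()
    subfam_of: dict[int, int] = {}
    i = 0
    for k, size in enumerate(config.subfamily_sizes):
        for _ in range(size):
            subfam_of[i] = k
            i += 1
    pair_child = {item.pair[1]: item for item in config.duplication_plan}
    for item in config.duplication_plan:
        a, b = item.pair
        if subfam_of[a] != subfam_of[b]:
            raise SimulationError("duplication pairs must stay within one subfamily")
    ancestors = [simulate_codon_divergence(root, *config.root_branch, code, rng, frozen)[0]
                 for _ in range(config.n_subfamilies)]
    gene_ids = [f"g{i + 1:02d}" for i in range(config.n_genes)]
    cds: dict[int, str] = {}
    realized_pairs = []
    for i in range(config.n_genes):
        if i in pair_child:
            item = pair_child[i]
            parent = cds[item.pair[0]]
            derived, realized = simulate_codon_divergence(
                parent, item.target_ks, item.target_ka, code, rng, frozen)
            cds[i] = derived
            realized_pairs.append({
                "gene_a": gene_ids[item.pair[0]], "gene_b": gene_ids[i],
                "kind": "tandem" if item.layout == "tandem" else "segmental",
                "layout": item.layout,
                "target_ks": item.target_ks, "target_ka": item.target_ka,
                **realized,
            })
        else:
            cds[i] = simulate_codon_divergence(
                ancestors[subfam_of[i]], *config.within_branch, code, rng, frozen)[0]
    proteins = {i: str(Seq(cds[i]).translate()).rstrip("*") for i in range(config.n_genes)}

    # --- genome layout -----------------------------------------------------
    if config.n_genes == 22 and config.subfamily_sizes == _DEFAULT_SUBFAMILY_SIZES:
        layout = _DEFAULT_LAYOUT
    else:  # fall back: pack genes onto the first chromosomes, 4 per chromosome
        layout = {}
        per = max(1, math.ceil(config.n_genes / max(1, config.n_chromosomes // 2)))
        for i in range(config.n_genes):
            layout.setdefault(f"ch{i // per + 1:02d}", []).append(i)
    tandem_pairs = {tuple(item.pair) for item in config.duplication_plan
                    if item.layout == "tandem"}
    promoter_len = 2000
    chrom_names = [f"ch{k + 1:02d}" for k in range(config.n_chromosomes)]
    genome: dict[str, str] = {}
    gff_rows: list[str] = []
    coords: dict[int, dict] = {}
    element_truth: dict[str, list[dict]] = {}
    element_hit_counts: dict[str, dict[str, int]] = {}
    plant_of_gene: dict[int, list[str]] = {i: [] for i in range(config.n_genes)}
    for element_id, members in config.element_plan.items():
        for gi in members:
            copies = int(rng.integers(1, 4))
            plant_of_gene[gi].extend([element_id] * copies)

    for chrom in chrom_names:
        members = layout.get(chrom, [])
        parts: list[str] = []
        pos = 0

        def emit(seq: str):
            nonlocal pos
            parts.append(seq)
            pos += len(seq)

        emit("".join(_BASES[b] for b in rng.integers(0, 4, size=3000)))
        spacer_counter = 0
        for order_idx, gi in enumerate(members):
            if order_idx > 0:
                prev = members[order_idx - 1]
                n_spacers = 2 if (prev, gi) in tandem_pairs else 8
                for _ in range(n_spacers):
                    emit("".join(_BASES[b] for b in rng.integers(0, 4, size=400)))
                    sp_id = f"sp_{chrom}_{spacer_counter}"
                    spacer_counter += 1
                    s_start = pos
                    emit("".join(_BASES[b] for b in rng.integers(0, 4, size=300)))
                    gff_rows.append(
                        f"{chrom}\tsim\tgene\t{s_start + 1}\t{pos}\t.\t+\t.\tID={sp_id}")
                emit("".join(_BASES[b] for b in rng.integers(0, 4, size=400)))
            strand = "-" if rng.integers(0, 10) < 7 else "+"
            promoter, truth, hit_counts = _build_promoter(rng, promoter_len, catalog,
                                                          plant_of_gene[gi])
            body, exons_rel = _gene_body(rng, cds[gi], config.intron_plan[gi],
                                         config.intron_length)
            unit = promoter + body
            if strand == "-":
                unit = revcomp(unit)
                body_start = pos
                body_end = pos + len(body)
                exon_coords = sorted(
                    (body_start + len(body) - e, body_start + len(body) - s)
                    for s, e in exons_rel)
            else:
                body_start = pos + promoter_len
                body_end = body_start + len(body)
                exon_coords = [(body_start + s, body_start + e) for s, e in exons_rel]
            emit(unit)
            gid = gene_ids[gi]
            coords[gi] = {"chromosome": chrom, "start": body_start, "end": body_end,
                          "strand": strand, "exons": exon_coords}
            element_truth[gid] = truth
            element_hit_counts[gid] = hit_counts
            gff_rows.append(
                f"{chrom}\tsim\tgene\t{body_start + 1}\t{body_end}\t.\t{strand}\t.\tID={gid};locus_tag=LOC{gi + 1:04d}")
            gff_rows.append(
                f"{chrom}\tsim\tmRNA\t{body_start + 1}\t{body_end}\t.\t{strand}\t.\tID={gid}.1;Parent={gid}")
            phases = _cds_phases(exons_rel, strand)
            for (s, e), ph in zip(exon_coords, phases):
                gff_rows.append(
                    f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={gid}.1")
                gff_rows.append(
                    f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{ph}\tID=cds_{gid};Parent={gid}.1")
        emit("".join(_BASES[b] for b in rng.integers(0, 4, size=3000)))
        genome[chrom] = "".join(parts)

    # --- expression plan ---------------------------------------------------
    folds: dict[str, dict[str, float]] = {}
    for gi in range(config.n_genes):
        gid = gene_ids[gi]
        per = {config.calibrator_sample: 1.0}
        others = [s for s in config.samples if s != config.calibrator_sample]
        if gi == config.peak_fold_gene:
            peak_sample, peak = config.peak_fold_sample, config.peak_fold
        else:
            peak_sample = others[int(rng.integers(0, len(others)))]
            peak = float(np.round(rng.uniform(1.5, 8.0), 2))
        for s in others:
            per[s] = peak if s == peak_sample else float(np.round(rng.uniform(0.7, peak / 2.0), 2))
        folds[gid] = per
    ct_rows = []
    base_dct = {gene_ids[gi]: float(np.round(rng.uniform(4.0, 8.0), 2))
                for gi in range(config.n_genes)}
    for s in config.samples:
        for rep in range(1, config.n_replicates + 1):
            ref_ct = 19.0 + rng.normal(0.0, config.ct_noise_sd)
            ct_rows.append({"gene": config.reference_gene, "sample": s,
                            "replicate": rep, "ct": round(ref_ct, 4)})
            for gid in gene_ids:
                true_dct = base_dct[gid] - math.log2(folds[gid][s])
                ct = ref_ct + true_dct + rng.normal(0.0, config.ct_noise_sd)
                ct_rows.append({"gene": gid, "sample": s, "replicate": rep,
                                "ct": round(ct, 4)})
    ct_frame = pd.DataFrame(ct_rows, columns=CT_ORDER)

    # --- generating tree ----------------------------------------------------
    tree = _generating_tree(config, gene_ids, subfam_of, pair_child)

    # --- write bundle -------------------------------------------------------
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "cds": outdir / "cds.fa",
        "proteins": outdir / "proteins.fa",
        "alignment": outdir / "proteins.aln.fa",
        "elements": outdir / "cis_elements.tsv",
        "ct_table": outdir / "ct_table.tsv",
        "tree": outdir / "generating_tree.nwk",
        "ground_truth": outdir / "ground_truth.json",
    }
    _write_fasta(paths["genome"], [(c, genome[c]) for c in chrom_names])
    with open(paths["annotation"], "w") as fh:
        fh.write("##gff-version 3\n")
        for c in chrom_names:
            fh.write(f"##sequence-region {c} 1 {len(genome[c])}\n")
        fh.write("\n".join(gff_rows) + "\n")
    _write_fasta(paths["cds"], [(gene_ids[i], cds[i]) for i in range(config.n_genes)])
    _write_fasta(paths["proteins"], [(gene_ids[i], proteins[i]) for i in range(config.n_genes)])
    # gap-free family: the alignment is the ungapped protein set
    _write_fasta(paths["alignment"], [(gene_ids[i], proteins[i]) for i in range(config.n_genes)])
    from genefam.promoter import write_element_catalog
    write_element_catalog(catalog, paths["elements"])
    ct_frame.to_csv(paths["ct_table"], sep="\t", index=False)
    with open(paths["tree"], "w") as fh:
        fh.write(tree.to_newick() + "\n")

    anchors = {}
    start = 0
    for k, size in enumerate(config.subfamily_sizes):
        anchors[gene_ids[start]] = f"subfamily_{k + 1}"
        start += size
    ground_truth = {
        "seed": config.seed,
        "gene_ids": gene_ids,
        "subfamily": {gene_ids[i]: f"subfamily_{subfam_of[i] + 1}" for i in range(config.n_genes)},
        "anchors": anchors,
        "chromosome": {gene_ids[i]: coords[i]["chromosome"] for i in range(config.n_genes)},
        "strand": {gene_ids[i]: coords[i]["strand"] for i in range(config.n_genes)},
        "intron_plan": {gene_ids[i]: config.intron_plan[i] for i in range(config.n_genes)},
        "duplication_pairs": realized_pairs,
        "planted_elements": element_truth,
        "expected_hit_counts": element_hit_counts,
        "element_gene_counts": {e: len(set(m)) for e, m in config.element_plan.items()},
        "fold_changes": folds,
        "base_delta_ct": base_dct,
        "calibrator_sample": config.calibrator_sample,
        "reference_gene": config.reference_gene,
        "ct_noise_sd": config.ct_noise_sd,
        "generating_tree": tree.to_newick(),
        "domain_pattern": DEFAULT_DOMAIN_PATTERN,
        "domain_peptide": DOMAIN_PEPTIDE,
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return SimulatedFamily(outdir=outdir, paths=paths, ground_truth=ground_truth)


CT_ORDER = ["gene", "sample", "replicate", "ct"]


def _cds_phases(exons_rel: list[tuple[int, int]], strand: str) -> list[str]:
    # phase per CDS feature in genome order; exons_rel are sense-order body coords
    lengths = [e - s for s, e in exons_rel]
    phases = []
    consumed = 0
    for ln in lengths:
        phases.append(str((3 - consumed % 3) % 3))
        consumed += ln
    if strand == "-":
        phases = phases[::-1]
    return phases


def _generating_tree(config: FamilySimConfig, gene_ids, subfam_of, pair_child) -> Tree:
    ks_root, _ = config.root_branch
    ks_within, _ = config.within_branch
    root = Clade()
    start = 0
    for k, size in enumerate(config.subfamily_sizes):
        sub = Clade(branch_length=ks_root)
        members = list(range(start, start + size))
        start += size
        handled = set()
        for i in members:
            if i in handled:
                continue
            item = pair_child.get(i)
            partner = None
            for j in members:
                if j in pair_child and pair_child[j].pair[0] == i:
                    partner = j
            if partner is not None:
                inner = Clade(branch_length=ks_within)
                inner.children.append(Clade(name=gene_ids[i], branch_length=0.0))
                inner.children.append(Clade(name=gene_ids[partner],
                                            branch_length=pair_child[partner].target_ks))
                sub.children.append(inner)
                handled.update({i, partner})
            elif item is None:
                sub.children.append(Clade(name=gene_ids[i], branch_length=ks_within))
                handled.add(i)
        if size == 1:
            only = sub.children[0]
            only.branch_length = (only.branch_length or 0) + ks_root
            root.children.append(only)
        else:
            root.children.append(sub)
    return Tree(root=root, rooted=True)
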