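"""End-to-end orchestration: catalog -> structure -> trees -> duplication ->
Ka/Ks -> promoters -> expression, with per-stage TSV outputs and a JSON summary.

Every stage is a pure function of the inputs and the configuration; rerunning
with the same config and seed reproduces the summary byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from genefam import catalog as cat
from genefam import duplication as dup
from genefam import expression as expr
from genefam import kaks
from genefam import phylogeny as phylo
from genefam import promoter as prom

ALL_STAGES = ("catalog", "structure", "tree", "dup", "kaks", "promoter", "expr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run.

    Defaults follow the conventional desk-study settings: segmental identity
    and coverage >= 80%, tandem window 100 kb with <= 5 intervening genes,
    1000 bootstrap replicates, alpha 0.05, 2000-bp promoters and a dicot
    substitution rate r = 1.5e-8 per site per year.
    """
    genome: str | Path | None = None
    annotation: str | Path | None = None
    cds: str | Path | None = None
    proteins: str | Path | None = None
    alignment: str | Path | None = None
    ct_table: str | Path | None = None
    element_catalog: str | Path | None = None
    anchors: dict[str, str] | None = None
    outdir: str | Path = "genefam_out"
    seed: int = 0
    segmental_threshold: float = 80.0
    tandem_max_intervening: int = 5
    tandem_window_bp: int = 100_000
    bootstrap_replicates: int = 1000
    alpha: float = 0.05
    promoter_length: int = 2000
    substitution_rate: float = 1.5e-8
    domain_pattern: str = cat.DEFAULT_DOMAIN_PATTERN
    reference_gene: str = "EF1a"
    calibrator_sample: str | None = None
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self):
        for name, value in (("segmental_threshold", self.segmental_threshold),
                            ("tandem_max_intervening", self.tandem_max_intervening),
                            ("tandem_window_bp", self.tandem_window_bp),
                            ("bootstrap_replicates", self.bootstrap_replicates),
                            ("alpha", self.alpha),
                            ("promoter_length", self.promoter_length),
                            ("substitution_rate", self.substitution_rate)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    def config_hash(self) -> str:
        # outdir is excluded: where results land is not part of the analysis identity
        payload = {k: str(v) for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _read_alignment(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def _pair_alignment(aln: dict[str, str], a: str, b: str) -> tuple[str, str]:
    sa, sb = aln[a], aln[b]
    keep = [(x, y) for x, y in zip(sa, sb) if not (x == "-" and y == "-")]
    return "".join(x for x, _ in keep), "".join(y for _, y in keep)


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages; write per-stage files plus summary.json.

    Returns the summary dict. Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "stages": list(config.stages)}
    records = None
    annotation = None

    def require(stage, **inputs):
        missing = [k for k, v in inputs.items() if v is None]
        if missing:
            raise PipelineError(stage, f"missing required input(s): {', '.join(missing)}")

    if "catalog" in config.stages or {"structure", "dup", "kaks", "promoter"} & set(config.stages):
        require("catalog", genome=config.genome, annotation=config.annotation,
                cds=config.cds, proteins=config.proteins)
        try:
            records = cat.load_catalog(config.genome, config.annotation, config.cds,
                                       config.proteins, config.domain_pattern)
            annotation = dup.GeneAnnotation.from_gff3(config.annotation)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("catalog", str(e)) from e
        cat.write_catalog_tsv(records, outdir / "catalog.tsv")
        summary["catalog"] = {
            "n_genes": len(records),
            "flagged": sorted(r.gene_id for r in records if r.flags),
            "domain_screen_retained": sum(1 for r in records if r.domain_hits),
        }

    if "structure" in config.stages:
        try:
            struct = cat.gene_structure_summary(records)
        except Exception as e:
            raise PipelineError("structure", str(e)) from e
        summary["structure"] = struct

    if "tree" in config.stages:
        require("tree", alignment=config.alignment)
        try:
            aln = _read_alignment(config.alignment)
            nj = phylo.bootstrap_supports(aln, "nj", config.bootstrap_replicates,
                                          seed=config.seed)
            up = phylo.bootstrap_supports(aln, "upgma", config.bootstrap_replicates,
                                          seed=config.seed)
        except Exception as e:
            raise PipelineError("tree", str(e)) from e
        (outdir / "nj_tree.nwk").write_text(nj.to_newick() + "\n")
        (outdir / "upgma_tree.nwk").write_text(up.to_newick() + "\n")
        summary["tree"] = {"nj": nj.to_newick(), "upgma": up.to_newick()}
        if config.anchors:
            labels = phylo.assign_subfamilies(up, config.anchors)
            pd.Series(labels).rename("subfamily").sort_index().to_csv(
                outdir / "subfamilies.tsv", sep="\t")
            summary["tree"]["subfamilies"] = dict(sorted(labels.items()))

    calls = None
    if "dup" in config.stages:
        try:
            calls = dup.call_all_duplications(
                records, annotation, mode="cds",
                threshold=config.segmental_threshold,
                max_intervening=config.tandem_max_intervening,
                window_bp=config.tandem_window_bp)
        except Exception as e:
            raise PipelineError("dup", str(e)) from e
        report = dup.duplication_report(calls)
        report.to_csv(outdir / "duplications.tsv", sep="\t", index=False)
        positives = report[report["kind"] != "none"]
        summary["dup"] = {
            "n_pairs_evaluated": len(report),
            "segmental": int((report["kind"] == "segmental").sum()),
            "tandem": int((report["kind"] == "tandem").sum()),
            "calls": positives.to_dict(orient="records"),
        }

    if "kaks" in config.stages:
        require("kaks", alignment=config.alignment)
        try:
            if calls is None:
                calls = dup.call_all_duplications(
                    records, annotation, mode="cds",
                    threshold=config.segmental_threshold,
                    max_intervening=config.tandem_max_intervening,
                    window_bp=config.tandem_window_bp)
            aln = dict(_read_alignment(config.alignment))
            cds_of = {r.gene_id: r.cds_sequence for r in records}
            evo = kaks.EvolutionConfig(r=config.substitution_rate)
            rows = []
            for c in calls:
                if c.kind == "none":
                    continue
                pair_aln = _pair_alignment(aln, c.gene_a, c.gene_b)
                stats = kaks.ng86(kaks.codon_align(cds_of[c.gene_a], cds_of[c.gene_b],
                                                   pair_aln))
                t = kaks.divergence_time(stats.Ks, evo)
                rows.append({
                    "pair": f"{c.gene_a}-{c.gene_b}", "kind": c.kind,
                    "S": _round(stats.S, 2), "N": _round(stats.N, 2),
                    "Sd": _round(stats.Sd, 2), "Nd": _round(stats.Nd, 2),
                    "Ks": _round(stats.Ks), "Ka": _round(stats.Ka),
                    "Ka/Ks": _round(stats.ratio),
                    "selection_mode": kaks.selection_mode(stats.ratio),
                    "T_Mya": _round(t, 3),
                })
        except Exception as e:
            raise PipelineError("kaks", str(e)) from e
        frame = pd.DataFrame(rows, columns=["pair", "kind", "S", "N", "Sd", "Nd", "Ks",
                                            "Ka", "Ka/Ks", "selection_mode", "T_Mya"])
        frame.to_csv(outdir / "kaks.tsv", sep="\t", index=False, na_rep="NA")
        summary["kaks"] = rows

    if "promoter" in config.stages:
        try:
            genome_seqs = cat._read_fasta(config.genome)
            catalog = prom.load_element_catalog(config.element_catalog)
            hits = []
            truncated = []
            for r in records:
                p = prom.extract_promoter(r, genome_seqs, config.promoter_length)
                if p.truncated:
                    truncated.append(r.gene_id)
                hits.extend(prom.scan_elements(p, catalog))
            counts, presence = prom.element_presence_matrix(
                hits, [r.gene_id for r in records], catalog)
        except Exception as e:
            raise PipelineError("promoter", str(e)) from e
        hit_frame = pd.DataFrame(
            [{"gene": h.gene_id, "element": h.element_id, "offset_bp_upstream": h.offset,
              "strand": h.strand, "sequence": h.matched_sequence} for h in hits])
        hit_frame.to_csv(outdir / "cis_hits.tsv", sep="\t", index=False)
        counts.rename_axis("gene").to_csv(outdir / "element_matrix.tsv", sep="\t")
        summary["promoter"] = {
            "genes_with_element": {k: int(v) for k, v in presence.items()},
            "total_hits": len(hits),
            "truncated_promoters": truncated,
            "matrix": {g: {e: int(counts.loc[g, e]) for e in counts.columns}
                       for g in counts.index},
        }

    if "expr" in config.stages:
        require("expr", ct_table=config.ct_table)
        try:
            table = expr.CtTable.from_tsv(config.ct_table, config.reference_gene,
                                          config.calibrator_sample)
            report = expr.expression_profile_report(table, alpha=config.alpha)
        except Exception as e:
            raise PipelineError("expr", str(e)) from e
        rows = []
        for gene, summ in report.items():
            for r in summ.table.itertuples(index=False):
                rows.append({"gene": gene, "sample": r.sample,
                             "mean_fold": _round(r.mean_fold, 4),
                             "sd_fold": _round(r.sd_fold, 4),
                             "letters": r.letters})
        pd.DataFrame(rows).to_csv(outdir / "expression.tsv", sep="\t", index=False)
        wide = expr.wide_fold_matrix(report).round(4)
        wide.rename_axis("gene").to_csv(outdir / "expression_matrix.tsv", sep="\t")
        summary["expr"] = {
            gene: {
                "preferential_sample": summ.preferential_sample,
                "max_mean_fold": _round(summ.table["mean_fold"].max(), 4),
                "anova_F": _round(summ.anova.F, 4) if summ.anova else None,
                "anova_p": _round(summ.anova.p, 6) if summ.anova else None,
                "folds": {r.sample: _round(r.mean_fold, 4)
                          for r in summ.table.itertuples(index=False)},
                "letters": {r.sample: r.letters
                            for r in summ.table.itertuples(index=False)},
            }
            for gene, summ in report.items()
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_log(outdir, config)
    return summary


def _write_log(outdir: Path, config: RunConfig) -> None:
    import genefam

    lines = [
        f"genefam {genefam.__version__}",
        f"seed {config.seed}",
        f"config_hash {config.config_hash()}",
    ]
    lines += [f"{k} {v}" for k, v in sorted(asdict(config).items())]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
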