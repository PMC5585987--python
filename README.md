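# genefam

Genome-wide characterization of plant gene families, end to end and at desk
scale. `genefam` is aimed at molecular-evolution and plant-genomics work of
the kind done for transcription-factor families (its defaults mirror a
22-member zinc-finger-homeodomain family in tomato): given a genome, its
annotation and the family's CDS/protein sequences, it

* assembles the member **catalogue** and the standard gene/protein parameter
  table (ORF length, aa length, molecular weight, isoelectric point, exon
  count, domain coordinates from a consensus screen);
* builds **NJ and UPGMA trees** from a protein alignment (p-distance with
  complete deletion) with bootstrap supports, and assigns subfamily labels
  from anchor taxa;
* classifies paralog pairs as **segmental** (identity and query coverage
  ≥ 80% in both orientations, local alignment) or **tandem** (same
  chromosome, ≤ 5 intervening genes, within 100 kb);
* estimates **Ka/Ks by Nei–Gojobori (1986)** counting — pathway-averaged
  differences, stop-codon-aware site counts, Jukes–Cantor correction — calls
  the selection mode (Ka/Ks > 1 positive, < 1 purifying, = 1 neutral) and
  dates duplications by T = Ks/2r with r = 1.5 × 10⁻⁸ site⁻¹ yr⁻¹;
* extracts **2000-bp promoters** and scans both strands for IUPAC
  cis-element consensi (MBS, ABRE, HSE, LTR, DRE by default);
* analyses **qRT-PCR expression** by 2^−ΔΔCt with one-way ANOVA and Tukey
  compact-letter displays.

A fully deterministic **synthetic-family simulator** generates a genome +
annotation + sequences + promoters + Ct tables with known ground truth
(planted duplications at chosen Ks/Ka, planted cis-elements, planted fold
changes), so every stage is testable without downloads.

## Worked example

```python
from genefam import FamilySimConfig, simulate_family, RunConfig, run_pipeline

fam = simulate_family(FamilySimConfig(seed=1), "scratch/family")
cfg = RunConfig(
    genome=fam.paths["genome"], annotation=fam.paths["annotation"],
    cds=fam.paths["cds"], proteins=fam.paths["proteins"],
    alignment=fam.paths["alignment"], ct_table=fam.paths["ct_table"],
    outdir="scratch/results", seed=1, bootstrap_replicates=200)
summary = run_pipeline(cfg)

print("genes:", summary["catalog"]["n_genes"],
      "| intronless:", summary["structure"]["intronless_genes"],
      "| chromosomes occupied:", summary["structure"]["occupied_chromosomes"])
print("duplications: segmental =", summary["dup"]["segmental"],
      ", tandem =", summary["dup"]["tandem"])
for row in sorted(summary["kaks"], key=lambda r: r["Ks"]):
    print(f"  {row['pair']:9s} Ks={row['Ks']:.4f} Ka={row['Ka']:.4f} "
          f"Ka/Ks={row['Ka/Ks']:.3f} ({row['selection_mode']}) T={row['T_Mya']:.2f} Mya")
print("promoter elements (genes containing):", summary["promoter"]["genes_with_element"])
g = summary["expr"]["g01"]
print("g01 peak induction:", g["preferential_sample"], f"{g['max_mean_fold']:.2f}-fold")
```

which prints:

```text
genes: 22 | intronless: 13 | chromosomes occupied: 6
duplications: segmental = 4 , tandem = 1
  g19-g20   Ks=0.1045 Ka=0.0293 Ka/Ks=0.281 (purifying) T=3.48 Mya
  g01-g02   Ks=0.1253 Ka=0.0392 Ka/Ks=0.313 (purifying) T=4.18 Mya
  g08-g07   Ks=0.1856 Ka=0.0545 Ka/Ks=0.294 (purifying) T=6.18 Mya
  g13-g12   Ks=0.2398 Ka=0.0710 Ka/Ks=0.296 (purifying) T=7.99 Mya
  g16-g17   Ks=0.2902 Ka=0.0894 Ka/Ks=0.308 (purifying) T=9.67 Mya
promoter elements (genes containing): {'MBS': 11, 'ABRE': 11, 'HSE': 12, 'LTR': 3, 'DRE': 1}
g01 peak induction: 1h 8.54-fold
```

Reading this: the simulator planted a 22-gene family (13 intronless, on six
chromosomes) with four dispersed duplicate pairs and one tandem pair; the
pipeline re-found exactly those pairs, re-estimated each pair's synonymous
divergence within a few percent of the planted value (all pairs under
purifying selection, duplications dated ≈ 3.5–9.7 million years ago),
recovered the planted per-element promoter tallies, and identified the
planted 8-fold induction of gene `g01` at 1 h (8.54 estimated under Ct noise).
Per-stage TSVs, Newick trees, `summary.json` and a run log land in `outdir`.

The same stages are available from the shell:

```sh
genefam simulate --outdir family --seed 1
genefam all --genome family/genome.fa --annotation family/annotation.gff3 \
    --cds family/cds.fa --proteins family/proteins.fa \
    --alignment family/proteins.aln.fa --ct-table family/ct_table.tsv \
    --outdir results
```

Subcommands `catalog`, `structure`, `tree`, `dup`, `kaks`, `promoter` and
`expr` run single stages; a flat `key=value` file passed as `--config`
overrides flags.

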