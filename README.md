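# mycomine

Genome-annotation analytics for polypore mushrooms and other filamentous
fungi: CAZyme gene-cluster prediction, chromosome-feature heuristics, and
the expression/annotation filter cascades used in comparative studies of
mushroom genomes — with seeded synthetic-data generators so every stage is
testable end-to-end against planted ground truth.

## What it does

Chromosome-level fungal genome projects answer a recurring set of
questions once assembly and annotation are in hand. `mycomine` implements
the downstream computations as a tested, reusable library:

* **CAZyme gene clusters (CAZ-GCs).** Carbohydrate-active enzymes that
  cooperate on a substrate tend to cluster on the chromosome with helper
  "signature" genes (sugar transporters, transcription factors) — the
  fungal analogue of a polysaccharide utilization locus. A candidate
  cluster must contain ≥3 CAZyme genes, or ≥2 CAZyme genes plus ≥1
  signature gene, with every member within two intergenic distances of a
  CAZyme gene. Linkage is applied along the gene order (rank distance ≤ 2,
  i.e. at most one intervening gene) and closed transitively; clusters are
  connected components of the linkage graph. A brute-force oracle
  (`cazgc_oracle`) verifies the production caller on every random instance.
* **Telomeres.** Maximal tandem copies of TTAGGG at 3′ termini and its
  reverse complement CCCTAA at 5′ termini, within a terminal window.
* **Centromere candidates.** The longest interval on each chromosome free
  of protein-coding genes, reported with the fraction covered by filtered
  repeat hits (fungal centromeres are retrotransposon-rich) and the ratio
  of transcriptional read depth inside the interval to its flanks
  (centromeres are transcriptionally depressed).
* **Repeat-hit confidence filtering.** RepeatMasker hits kept when
  length ≥ 140 bp AND Smith–Waterman score ≥ 450, plus class I/II
  (retrotransposon / DNA-transposon) density tracks and family censuses.
* **Mitogenome comparison.** Banded global edit-distance alignment of two
  near-identical circular genomes (co-rotated first), reporting
  substitutions/insertions/deletions and a per-base difference rate —
  the standard internal check of assembly error rates (one difference
  across a 115,207-bp mitogenome pair ⇒ ≤ 8.68 × 10⁻⁶ per base).
* **rDNA copy ratio.** Relative mapping coverage of the 45S rDNA array
  versus single-copy regions, the read-depth estimator of tandem-array
  copy number.
* **Expression statistics.** RPK = count / (length in kb); TPM rescales
  per-sample RPK to sum to 10⁶; differential calls use a two-sided Fisher
  exact test on pooled group counts (gene vs rest-of-library),
  Benjamini–Hochberg FDR < 0.05, fold change ≥ 3 on group-mean TPM, and a
  mean-TPM floor of 0.5. Fruiting-related genes (FRGs) are genes
  up-regulated in fruiting bodies versus **both** monokaryotic and
  dikaryotic vegetative mycelia; FRGs are partitioned by BLASTp orthology
  (E ≤ 10⁻⁵) into fruiting-body-initiation-gene orthologs,
  fruiting-body-development-gene orthologs, other-ortholog, and
  species-specific classes.
* **Annotation filter cascades.** lncRNA candidates (non-gene locus,
  ≥ 200 nt, FPKM > 1, non-coding by all coding-potential evaluators, no
  Pfam domain, ≥ 3 supporting predictors) and effector candidates
  (< 300 aa, signal peptide, no transmembrane domain, no GPI anchor), with
  per-stage exclusion tallies.

## Worked example

```python
from mycomine import synthetic_data as sd, predict_cazgc, detect_telomeres, mito_compare
from mycomine.chromosome_features import format_rate

sim = sd.generate_genome(sd.GenomeSimSpec(seed=11))
for c in predict_cazgc(sim.annotation, sim.signatures):
    print(c.cluster_id, c.members, f"span={c.span[0]}-{c.span[1]}",
          f"cazymes={c.n_cazyme}", f"signatures={c.n_signature}")

t5, t3 = detect_telomeres(sim.annotation.chromosomes[0])
print("chr1 telomeres:", t5.tandem_copies, "x", t5.motif, "/",
      t3.tandem_copies, "x", t3.motif)

a, b, _ = sd.generate_mitogenome_pair(115_207, 1, seed=1)
res = mito_compare(a, b)
print("mitogenome:", res["substitutions"], "substitution(s), per-base rate",
      format_rate(res["per_base_rate"]))
```

prints

```
chr1:CGC1 ('chr1_g009', 'chr1_g010', 'chr1_g011') span=11725-15766 cazymes=3 signatures=0
chr2:CGC1 ('chr2_g010', 'chr2_g011', 'chr2_g012') span=13210-16720 cazymes=2 signatures=1
chr3:CGC1 ('chr3_g010', 'chr3_g011', 'chr3_g013') span=12987-17939 cazymes=3 signatures=0
chr1 telomeres: 3 x CCCTAA / 3 x TTAGGG
mitogenome: 1 substitution(s), per-base rate 8.68e-06
```

The three reported clusters are exactly the three planted in the simulated
genome (one pure triple of CAZymes, one CAZyme–transporter–CAZyme cluster,
one triple with a spacer gene); the decoy patterns — two CAZymes with no
signature gene, and CAZymes three intergenic distances apart — are
rejected. The telomere calls recover the planted tandem copy numbers, and
the mitogenome pair differing by a single substitution yields the per-base
rate 8.68 × 10⁻⁶ at display precision.

The same operations are exposed on the command line:

```bash
mycomine simulate genome --seed 11 --out-dir demo/
mycomine cazgc --gff demo/genes.gff3 --signatures demo/signatures.tsv --out clusters.tsv
mycomine telomeres --fasta demo/genome.fasta --out telomeres.tsv
mycomine centromeres --gff demo/genes.gff3 --repeats demo/repeats.out \
    --depth demo/depth.tsv --out centromeres.tsv
```

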