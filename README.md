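# germcore

Germplasm genetic-diversity analysis and two-track core-collection
construction from SNP genotypes and phenotype data.

Given a multi-sample VCF of biallelic SNPs, a phenotype table (four
agronomic traits) and an accession → population map, the pipeline:

1. **filters** sites (GATK-style hard filters on QUAL/QD/MQ/FS/SOR/
   MQRankSum/ReadPosRankSum, minor-allele-frequency ≥ 0.1, optional
   PLINK-style `--indep-pairwise 50 10 0.2` LD pruning) and reports
   Ts/Tv and per-chromosome SNP densities;
2. computes **diversity statistics** per population (Ho, He, π, MAF, FIS,
   PIC) and phenotype descriptives with a binned Shannon index;
3. estimates pairwise **Weir–Cockerham Fst** in 500 kb windows and converts
   it to gene flow Nm = (1 − Fst)/(4 Fst);
4. builds **structure views**: IBS distances, a deterministic
   neighbor-joining tree (Newick), GRM PCA, PCoA, Ward clustering of
   traits, kinship (genotype correlation) with relatedness bins;
5. selects a **genotype core** (A-NE objective on Modified Rogers
   distances at gradient fractions 5–30 %) and a **phenotype core**
   (A-NE on Gower distances, scored by MD/VD/CR/VR), merges them, and
   **validates** the merged core with ANOVA + Tukey HSD.

A synthetic-data module (Balding–Nichols structure, Dirichlet admixture,
correlated trait clusters) generates panels with known ground truth; the
test suite and fixtures are built entirely from it.

## CLI

```sh
# make a small deterministic demo panel
germcore simulate --fixture --seed 313 --out fixtures/

# individual stages
germcore filter --vcf fixtures/panel.vcf --out kept.vcf --maf 0.1 --ld 50,10,0.2
germcore diversity --vcf kept.vcf --popmap fixtures/popmap.csv \
    --layout fixtures/layout.json --out table1.csv
germcore traits --pheno fixtures/pheno.csv --out table3.csv
germcore fst --vcf kept.vcf --popmap fixtures/popmap.csv --out table2.csv
germcore structure --vcf kept.vcf --pheno fixtures/pheno.csv \
    --popmap fixtures/popmap.csv --out structure/
germcore core --vcf kept.vcf --pheno fixtures/pheno.csv \
    --layout fixtures/layout.json --seed 313 --out core/

# or everything at once
germcore run-all --vcf fixtures/panel.vcf --pheno fixtures/pheno.csv \
    --popmap fixtures/popmap.csv --layout fixtures/layout.json \
    --seed 313 --out run/
```

`run-all` writes the report bundle (diversity/Fst/trait/gradient tables as
CSV, core ID lists, Newick tree, PCA/PCoA coordinates, kinship bins,
ANOVA/Tukey validation, JSON run log) and is a pure function of
(inputs, config, seed).

## Layout

```
src/germcore/
  datatypes.py          shared data model (dosage matrix, variant table, layout)
  genotype_io.py        VCF / CSV / Newick readers and writers
  variant_filter.py     hard filters, MAF filter, LD pruning, Ts/Tv, densities
  diversity_stats.py    Ho/He/π/MAF/FIS/PIC, trait descriptives, Shannon index
  differentiation.py    Weir–Cockerham Fst (windowed) and Nm
  structure_analysis.py distances, PCA/PCoA, NJ tree, clustering, kinship
  core_selection.py     A-NE optimizer, gradient search, MD/VD/CR/VR, merge, ANOVA
  synthetic_data.py     Balding–Nichols panel simulator + fixture suite
  cli_pipeline.py       stage orchestration and report bundle
  cli.py                click entry points
```
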