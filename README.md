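# mtpopgen

Population-genetic analysis of non-recombining organellar genomes, built
around the question that motivates comparative domestication studies in
rice: did the two Asian cultivated lineages (*indica* and *japonica*)
experience **independent selection histories**, as seen through the
maternally inherited, non-recombining mitochondrial genome?

The package is aimed at researchers analyzing multi-sample organellar
variant data (a VCF against a single reference contig plus a
sample-to-subgroup table). It provides, as composable library functions
and a `mtpopgen` command-line tool:

- **Variant summarization and filtering** — per-subgroup SNP/InDel counts,
  transition/transversion ratios, substitution spectra, the
  MAF ≥ 0.01 / missingness ≤ 0.20 quality filter, and shared-variant
  (Venn) analysis across subgroups.
- **Diversity** — per-site nucleotide diversity π in sliding windows
  (default 1000 bp / 500 bp step), with Welch t-tests between groups.
- **Differentiation** — Weir–Cockerham weighted F_ST adapted to haploid
  calls, windowed Tajima's D, PCA and classical MDS.
- **Selective-sweep scans** — reduction of diversity (π_wild/π_cultivated,
  top-5% windows merged into candidate regions) and a composite μ
  statistic multiplying window-span, folded-SFS and LD-contrast factors.
- **Introgression painting** — group-diagnostic alleles (frequency > 0.95
  in one group, < 0.05 in the other) painted along each accession, with
  fragment sizes and genome proportions.
- **Haplotype networks** — haplotype collapsing, group-sharing counts, and
  a minimum-spanning mutational-step network with statistical-parsimony
  connection limits and PopART-compatible NEXUS export.
- **Bottleneck test** — Cornuet–Luikart heterozygosity-excess test under
  the infinite-allele model.
- **dN/dS** — Nei–Gojobori (1986) counting method with Jukes–Cantor
  correction for codon alignments.
- **A coalescent data generator** — one non-recombining genealogy under a
  wild + two-bottlenecked-lineages demography, with planted sweeps and
  ground truth, so every stage is verifiable end to end without any
  external download.

## Statistics at the core

For a haploid sample of size *n* with allele counts *c₁…c_k* at a site,

- π (per site) = `1 − Σᵢ cᵢ(cᵢ−1) / (n(n−1))`, summed over a window and
  divided by the window's bp length;
- Tajima's D = `(π̂ − S/a₁) / √(e₁S + e₂S(S−1))` with the standard
  constants from *n*;
- F_ST (weighted) = `Σ a / Σ (a+b)` over sites and alleles, where *a* and
  *b* are the Weir–Cockerham (1984) between- and within-population
  variance components with the heterozygosity terms identically zero for
  haploid calls;
- reduction of diversity = `π_wild / π_cultivated` per window, top-5%
  windows merged;
- μ = μ_var · μ_sfs · μ_ld over windows of W=20 SNPs;
- He (gene diversity) = `n/(n−1) (1 − Σ pᵢ²)` against its simulated
  equilibrium distribution given the surviving allele count;
- dN/dS by NG86 pathway averaging with `d = −¾ ln(1 − 4p/3)`.

## Worked example

Simulate a rice-like collection (54 wild, 66 indica-like, 278
japonica-like accessions; 490,520 bp genome; a sweep planted at
100–110 kb in the japonica-like lineage) and analyze it:

```bash
$ mtpopgen simulate --out-prefix rice_mt --seed 7 --length 490520
[mtpopgen] simulated 19856 variants x 398 samples -> rice_mt.vcf

$ mtpopgen summarize --vcf rice_mt.vcf --metadata rice_mt.samples.tsv --out summary.tsv
$ cat summary.tsv
group	n_accessions	SNPs	InDels	Total	TsTv
wild_rufipogon	36	8063	3436	11499	2.0074599030212608
wild_nivara	18	7177	3010	10187	2.023167649536647
indica	66	7245	3061	10306	2.0250521920668056
temperate_japonica	250	3071	1267	4338	2.165979381443299
tropical_japonica	28	2711	1115	3826	2.1341040462427747
cultivated	344	8884	3755	12639	2.049776862341229
wild	54	8469	3592	12061	1.9978761061946904
all	398	13910	5905	19815	2.004968675739901

$ mtpopgen fst --vcf rice_mt.vcf --metadata rice_mt.samples.tsv \
      --out fst.tsv --group-a indica --group-b japonica
[mtpopgen] genome-wide weighted F_ST(indica, japonica) = 0.7775

$ mtpopgen sweep --vcf rice_mt.vcf --metadata rice_mt.samples.tsv \
      --out sweep_jap.tsv --cult-group japonica
```

Reading the numbers: wild accessions carry the most variation (11–12k
variants vs ~4k in the bottlenecked japonica-like subgroups), Ts/Tv sits
near 2 as expected for a transition-biased mutation process, and F_ST
between the two cultivated lineages (0.78) exceeds F_ST between indica
and wild (0.64 on the same dataset) — the maternal-lineage signature of
separate domesticated gene pools. The japonica sweep scan's merged
top-5% regions include `101000–103000` and `104000–110000`, recovering
the sweep planted at 100–110 kb; the indica scan shows no region there.

## Layout

```
src/mtpopgen/
  core.py            variants, genotype matrix, sample table, windows
  vcf_io.py          VCF/metadata/GFF3 readers, VCF/FASTA/BED writers
  variant_summary.py filters, per-group summaries, shared-variant sets
  diversity.py       window and genome-wide pi, group comparisons
  differentiation.py F_ST, Tajima's D, PCA/MDS
  selection_scan.py  ROD scan, region overlap, composite mu
  geneflow.py        diagnostic alleles, accession painting
  haplonet.py        haplotype collapsing, MST network, NEXUS export
  bottleneck.py      heterozygosity-excess test (IAM)
  dnds.py            NG86 dN/dS and the per-gene screen
  simulate.py        structured-coalescent generator + recovery scoring
  cli.py             `mtpopgen` subcommands
```

See `docs/methods.md` for the models, parameter choices, numerical
conventions, and known limitations.
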