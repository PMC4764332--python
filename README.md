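# apamir

Positional analysis of microRNA seed-match sites around alternative
polyadenylation (APA) sites, from 3'-end sequencing reads to permutation
statistics.

## The problem

Most mammalian genes carry several cleavage/polyadenylation sites in their
3'UTR, so proliferating cells can switch to proximal sites and express
shortened 3'UTRs. Shortening is usually discussed as a way to *escape*
miRNA repression — distal binding sites are simply cut away. But because
miRNA sites are most effective near the ends of a 3'UTR, shortening can
also *potentiate* repression: a site sitting just upstream of a proximal
APA site ends up next to the new 3' end of the short isoform. `apamir`
implements the analysis chain needed to detect this signature: are
conserved miRNA seed matches enriched immediately 5' of APA sites, is the
enrichment concentrated in particular gene classes (pro-differentiation
vs pro-proliferation, defined by codon usage), and is it carried by
particular miRNA families (e.g. a proliferation-associated cluster like
miR-17-92)?

It is written for computational biologists who have 3'-end sequencing
data (mapped cleavage positions), a 3'UTR annotation, a seed table, and
optionally conservation tracks and per-site scores — and for anyone who
wants to study the statistics themselves on fully synthetic data with
known ground truth.

## The method

1. **Cleavage-site (CS) calling** (`cs_calling`). Pooled 3'-end read
   positions are clustered into *read runs* — maximal intervals where
   consecutive occupied positions are < 10 nt apart. Local maxima of the
   per-position counts are CS candidates; candidates closer than 50 nt are
   resolved in favour of higher read support, and a site needs ≥ 10 reads
   at the run maximum. Sites whose surrounding 50 nt contain a 10-mer with
   ≥ 8 A and the rest G are flagged as oligo-dT internal-priming artifacts
   and excluded downstream.
2. **APA assignment** (`apa_assignment`). A CS belongs to a gene if it
   falls in its 3'UTR or ≤ 20 nt past its 3' end. A gene is APA-positive
   with ≥ 2 assigned sites; the analysis anchor is the 5'-most site.
3. **Seed-match scanning** (`site_mapping`). Sites are perfect 7-mers, the
   reverse complement of miRNA bases 2–8; conservation flags and P_CT /
   context++ scores attach from external tables.
4. **Positional statistics** (`positional_stats`). Site counts are binned
   by signed distance d = site − APA (100-nt bins over ±1 kb, genes with
   ≥ 1 kb of UTR on both sides). Significance per bin comes from:
   a randomized-anchor null (each gene's pseudo-APA drawn uniformly from
   the UTR interior, 10,000 iterations); a two-set partition test
   (density difference between two gene sets vs random re-partitions);
   and a cluster-vs-all test (density in cluster-targeted genes vs all
   genes, against a family-label permutation null). One-sided p-values
   use the +1-corrected estimator (1 + #{null ≥ obs}) / (1 + N).
   Student t-tests compare site scores 300 nt 5' vs 3' of the anchor, and
   relative site positions (site/UTR length) between gene classes.
5. **Conservation profiles** (`conservation`), **codon-usage gene-set
   expansion** (`genesets`), and a **synthetic-data generator**
   (`synthetic_data`) that emits every input format with ground-truth
   bookkeeping.

## Worked example

Generate a 5,000-gene synthetic cohort, run the pipeline, and test the
planted enrichment (3× conserved-site density in the 300 nt 5' of the
proximal APA site, pro-differentiation class only):

```python
import numpy as np
from apamir.synthetic_data import SimConfig, simulate, truth_report
from apamir.cs_calling import call_cleavage_sites
from apamir.apa_assignment import assign_cs_to_utrs, filter_flank
from apamir import site_mapping, positional_stats as ps

bundle = simulate(SimConfig(n_genes=5000, seed=42))
cs = call_cleavage_sites(bundle.read_ends, bundle.genome)
calls = assign_cs_to_utrs(cs, bundle.utrs)
sites = site_mapping.scan_all(bundle.utrs, bundle.seeds)
site_mapping.label_conserved(sites, bundle.conserved_table,
                             bundle.utrs, bundle.seeds)
kept = filter_flank(calls, 1000)
prodiff = bundle.truth.class_members("prodiff")
ens = ps.randomized_apa_null([c for c in kept if c.gene_id in prodiff],
                             sites, n_iter=10000, seed=42)
```

Output of this analysis (print statements omitted above for brevity;
every number below was produced by this session at seed 42):

```
called 7779 cleavage sites (417 flagged as internal priming)
2408 of 5000 genes are APA-positive
50155 seed-match sites, 9882 conserved
361 genes with >=1 kb flanks profiled, 59 in the pro-differentiation class
  bin [ -400, -300):   5 conserved sites, p=0.8425
  bin [ -300, -200):  15 conserved sites, p=0.0160 *
  bin [ -200, -100):  20 conserved sites, p=0.0007 *
  bin [ -100,   +0):  16 conserved sites, p=0.0173 *
  bin [   +0, +100):   4 conserved sites, p=0.9722
  bin [ +100, +200):   5 conserved sites, p=0.9341
two-set test, [-300,0) bins: p = [0.0027 0.0009 0.0069]
recovery vs ground truth: CS recall 0.981, APA-gene recall 0.962
```

Reading it: the three bins covering the 300 nt immediately upstream of
the APA anchor are starred (observed conserved-site counts of 15/20/16
against a randomized-anchor null centred near 6), the bins outside that
window are not, and the two-set partition test confirms the excess is a
property of the pro-differentiation class rather than of APA genes in
general. The caller recovered 98% of planted cleavage sites and 96% of
planted APA genes; the internal-priming filter caught the planted A-rich
decoy clusters (417 flagged sites).

The same steps run from the shell:

```bash
apamir simulate --out sim/ --seed 42
apamir cscall  --reads sim/reads.bed --genome sim/genome.fa --out sites.tsv
apamir apacall --sites sites.tsv --utrs sim/utrs.bed --genome sim/genome.fa --out apa.tsv
apamir sitescan --utrs sim/utrs.bed --genome sim/genome.fa \
    --seeds sim/seeds.tsv --conserved sim/conserved_sites.tsv --out seed_sites.tsv
apamir nulltest --apa apa.tsv --sites seed_sites.tsv \
    --utrs sim/utrs.bed --genome sim/genome.fa --seed 1 --out profile.tsv
```

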