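# repeatloop

Tandem-repeat-aware epigenomic analyses for repeat-associated
paramutation loci.

Some plant alleles switch heritably between an active and a repressed
expression state, and the switch tracks molecular changes at a perfect
tandem repeat array tens of kilobases from the gene: the repressed state
produces 24 nt small RNAs and cytosine methylation at a unique subregion
(USR) embedded in each repeat unit, while the active state shows
chromatin contact between the repeats and the promoter, higher USR RNA
levels and different nuclease accessibility.  `repeatloop` implements the
computational toolkit such a study needs, end to end:

- **haplotype** — perfect tandem-array detection (maximal arrays at their
  primitive period), collapsed references with coordinate lift-over, and
  per-window repetitive-index tracks;
- **mapper** — exact-match read placement with unique / multi / unmapped
  classification and two-pass genome filtering, so repeat-derived reads
  map uniquely to a collapsed reference;
- **fourc** — 4C amplicon parsing by its designed anatomy
  (P5–primer–DpnII–fragment–NlaIII–primer–P7), ligation-tag
  quantification, bait-window exclusion, rpm ranking and 2 kb binning;
- **srna** — small-RNA preprocessing (adapter/UMI protocols), structural
  RNA filtering, cluster calling (merge under 50 bp, 0.5 rpm coverage
  floor), per-cluster differential t-tests, 5'-collapsed size/strand
  profiles, and 21-mer size-class normalisation for polymerase mutants;
- **methylation** — per-cytosine CG/CHG/CHH calls from conversion-treated
  amplicon clones with a lambda-style conversion control;
- **qpcr** — 2^-ΔΔCt quantification for qRT-PCR expression and
  MNase-qPCR accessibility with replicate handling and two-sample tests;
- **simulate** — a generator for every input above with recorded ground
  truth, whose defaults encode the study conditions (2092 bp × 5 array,
  390 bp USR, 9.9×/4.4× repressed-state sRNA folds, 15× RNA fold,
  88/60/7% CG/CHG/CHH methylation).

The statistics are deliberately simple — exact matching, counting, rpm
normalisation, t-tests — because the analyses' value lies in the
filtering and coordinate contracts, which are specified precisely and
tested against independent oracles (see `docs/methods.md`).

## Worked example

Simulate a haplotype and run the cob genotype contrast from the shell:

```sh
$ repeatloop sim haplotype --seed 1 --out-dir hap
haplotype: 50000 bp; array 2092 bp x 5

$ repeatloop haplotype arrays --fasta hap/haplotype.fa \
      --min-unit 1000 --min-copies 3 --out arrays.bed
synthetic_haplotype	24000	34460	unit=2092	copies=5

$ repeatloop srna --seed 1 --depth 20000 --out-dir srna_out
clusters: 30
differential cluster 16 [24850, 25240) fold=9.20 p=8.3e-05
```

Thirty sRNA clusters are called across the collapsed haplotype; exactly
one is differential between the active (Pl-Rh-like) and repressed
(Pl'-like) genotypes, it coincides with the USR (collapsed coordinates
24850–25240), and its abundance is ~9-fold higher in the repressed
state — the planted truth is 9.9.  The same objects are available as a
library:

```python
import numpy as np
from repeatloop import simulate, workflows

rng = np.random.default_rng(1)
hap = simulate.generate_haplotype(rng=rng)
specs = simulate.contrast_specs(hap, rng,
                                simulate.SrnaScenarioConfig(), "cob")
result = workflows.run_srna_contrast(specs, hap, rng, ("Pl-Rh", "Pl'"))
print(workflows.usr_cluster_row(result, hap)[["fold", "p"]])
```

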