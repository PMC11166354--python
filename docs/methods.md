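# Methods

`repeatloop` models the analysis of a repeat-associated regulatory locus:
a plant gene whose heritable expression states (an active, paramutable
state and a repressed, paramutagenic state) track molecular changes at a
perfect tandem repeat array lying tens of kilobases downstream.  Each
repeat unit is mostly transposon-fragment sequence with an embedded unique
subregion (USR).  The package implements the computational side of five
assays against such a haplotype — tandem-array structure, 4C
bait-interaction profiling, small-RNA cluster analysis, amplicon cytosine
methylation, and qPCR quantification — plus a generator that produces all
of their inputs with recorded ground truth.

## Haplotype model and collapsed reference

Tandem arrays are *perfect*: a unit sequence repeated two or more times
with no mismatches.  Detection scans every candidate period `p` from
`min_unit` up to `L / min_copies`, finds maximal runs of `s[i] == s[i+p]`
(a run of length `r` implies `r // p + 1` aligned copies), and reports each
array at its primitive (shortest) period with the leftmost phase.  A
strided pretest (a qualifying run must light a block of consecutive
samples taken every 64 bp) rejects almost all periods in O(L/64) before
the exact run extraction, keeping a ~200 kb scan under a few seconds.
Near-identical arrays (e.g. single-SNP divergence between units) are out
of detection scope but representable in annotations.

Collapsing replaces each array with a single unit and keeps a segment
table mapping the two coordinate spaces.  A collapsed position inside an
array lifts to exactly `copy_number` full positions, one otherwise;
interval lift-over refuses intervals straddling a segment boundary rather
than guessing.  All coordinates are 0-based half-open internally; GFF3 I/O
converts to 1-based closed.

The repetitive index of a window (default 24 bp, the diagnostic sRNA
length) is its exact occurrence count in a background sequence set,
counting both orientations because short-read mapping is strand-blind; a
reverse-complement-palindromic window is counted once per locus.  Windows
containing N get value 0 and a flag.

## Exact-match mapping

The mapper reproduces the contract of a zero-mismatch aligner that
suppresses multi-mappers: occurrences of a read are counted over both
strands of all references; 0 → unmapped, 1 → unique (with placement),
≥2 → multi with no placement reported.  A perfectly palindromic read
matching one locus on both strands counts as two occurrences and is
multi — a declared rule, since aligner behaviour for this corner is
undocumented.  N never matches.  The index is an 8-mer seed table with
full verification; a per-index memo caches classifications because sRNA
libraries are highly redundant.  Two-pass filtering discards reads that
multi-map to a genome background, then keeps only unique placements on
the collapsed haplotype — this is what lets repeat-derived reads be
counted once.

## 4C pipeline

Reads are fixed-length (49 bp) amplicon sequences with the designed
anatomy P5 – forward primer – DpnII site – captured fragment – NlaIII
site – reverse primer – P7.  Parsing has four stages, each with one
rejection reason, so every read is accounted for exactly once:

1. anchor — the read must contain the last 3 primer nt + `GATC`
   (`CTCGATC`, ≤1 mismatch in any 7-mer window);
2. left trim — remove through the 16 nt primer tail (k=16, mink=12,
   hdist=2); a read still longer than 28 nt afterwards had an
   unrecognisable primer and is rejected;
3. right trim — remove `CATGAGCTATGA` (k=12, mink=7, hdist=1) if present
   (long fragments fill the read and legitimately lack it); fragments
   <8 nt are rejected as primer dimers;
4. quality — trim 3' bases below Q20, reject if mean quality <20 or
   length <8.

The adapter-matching contract shared with the sRNA pipeline is defined
operationally: an adapter matches where a k-length window aligns with ≤
hdist mismatches, or a ≥mink partial alignment at the relevant read end.
Retained fragments keep the first-cutter site at their 5' end, so a
fragment's mapped strand-aware 5' coordinate is the restriction-site
position of the interacting locus.  Tags within 2 kb of the bait (distance
measured to the bait centre, inclusive at exactly 2000 bp — the anchor
point of the published rule is unstated) are excluded; remaining counts
are rpm-normalised over retained tags and ranked by competition ranking
(ties share the better rank).  Binning sums rpm into half-open 2 kb bins
tiled from 0.

## Small-RNA pipeline

Preprocessing trims the 3' adapter under the shared k/mink/hdist contract
(k=18, mink=11, hdist=1).  For UMI-bearing kits (4 random nt flanking the
insert on both sides), trimmed reads are filtered to 26–38 nt
(insert + 8), deduplicated on the full trimmed sequence — distinct UMIs
keep genuinely distinct molecules — then stripped of 4 nt per side; the
18–30 nt filter is applied last.  Reads with any exact placement on an
rRNA/tRNA reference are removed; the survivors are the *clean* set whose
count is the rpm denominator for everything downstream.

Cluster calling pools uniquely-mapped read intervals across the defining
libraries, merges intervals separated by fewer than `pad` (50) bp, and
keeps merged intervals whose summed read count reaches
`ceil(mincov_rpm × Σ clean_totals / 1e6)` with `mincov_rpm = 0.5` — the
coverage floor is recomputed from the libraries at hand rather than
hard-coded.  This merge-then-threshold semantics is declared and
oracle-tested; it may differ in corners from island definitions based on
per-position depth.  Per-cluster differential abundance compares rpm
values between genotype groups with a two-sided two-sample t-test (Welch
by default, pooled available).  `quantify_and_test` reports raw p-values
(a Bonferroni column is available off by default); the end-to-end
workflow calls a cluster *differential* when its p-value clears a
Bonferroni-shared α = 0.05 across the called cluster set, since a whole
cluster census is screened at once and a raw per-cluster threshold would
flag a false positive in a sizeable fraction of runs.

5'-collapsed profiles place each read at its strand-aware 5' coordinate
(interval start on plus, interval end − 1 on minus) and accumulate rpm per
10 nt bin, strand and length.  Size-class profiles are per-length read
percentages over 18–30 nt; "overlapping a region" means ≥1 bp
intersection.  Mutant size-class normalisation rescales a mutant profile
by `pct21_control / pct21_mutant` — 21-mers are taken as unaffected by
loss of the 24-mer-producing polymerase, an assumption encoded, not
verified — and reports per-length residual fractions relative to control.
Genome-wide residuals are computed on all clean reads by default (the
uniquely-mapped variant is available through the same functions).

## Methylation amplicon calling

Cytosine contexts follow the two bases 3' of the cytosine on its strand:
CG, CHG (H then G), CHH; terminal cytosines lacking flank are ambiguous
and excluded from denominators.  Clones are compared to the reference
ungapped (equal length after primer removal); reference C read as C is
methylated, as T unmethylated, anything else ambiguous.  Clones with more
than a declared number of non-cytosine mismatches (default 3) are
rejected rather than realigned — appropriate for Sanger clones of a
~123 bp amplicon.  The default strand is the amplified top strand;
bottom-strand analysis is supported (reference C appears as G→A in
forward coordinates).  Conversion efficiency is the converted fraction of
cytosines in a fully unmethylated control (lambda-style spike-in);
libraries under 0.98 are flagged.

## qPCR quantification

Technical replicates are averaged on the Ct scale; ΔCt = Ct_target −
Ct_reference per sample; ΔΔCt subtracts the calibrator-group mean ΔCt;
fold = 2^−ΔΔCt with amplification efficiency fixed at 2.0.  Group
summaries are means and s.e.m. of per-sample folds on the linear scale;
the two-group test is run on folds (reported) and on ΔCt values (also
reported), Welch by default.  The same arithmetic serves expression
(qRT-PCR against a reference gene) and MNase accessibility (tiled
amplicons against a reference locus), the latter applied per amplicon.

## Synthetic data generator

Defaults are desk-sized but keep the study's geometry and effect sizes:
a 50 kb haplotype with a 2092 bp × 5 perfect array at 24 kb; a 390 bp USR
at offset 850 of each unit, with a DpnII site planted inside it (the 4C
scenario presumes a cuttable interacting fragment); a highly repetitive
DNA-TE fragment (offset 200, 300 bp) whose copies also sit in a 20 kb
decoy genome background, making its reads genome-wide multi-mappers; a
relatively unique PIF-Harbinger-type TE (offset 1290, 350 bp) adjacent to
the USR; a bait at 6 kb; and a 2 kb synthetic structural-RNA reference.

sRNA libraries (default 1e5 reads each) draw read origins from weighted
loci: 28 fixed background loci sharing weight 0.75, the repetitive TE at
0.08, the PIF TE at 0.004, structural contamination at 0.05, and the USR
at 0.015 in the repressed state — divided by 9.9 (cob) or 4.4 (seedling)
in the active state, the published contrasts.  Per-locus length
distributions put 80% of reads at 24 nt (79% for the USR); cob libraries
carry an antisense bias for 23-mers (minus-strand probability 0.8).
Mutant scenarios: chromatin-remodeller loss keeps 52% of USR emission and
multiplies the PIF TE by 15.8 with 73%/77.7% 24-mer fractions;
polymerase-pathway mutants scale 24-mer emission to 8% (rpd1-like) or 48%
(rmr1-like) of the heterozygote across all loci with 21-mers untouched,
then resample to depth so that percentages renormalise — exactly the
distortion the 21-mer normalisation must undo.  Reads are wrapped as
4N + insert + 4N + adapter.  Background cluster reads are emitted only
from the defined loci (no uniform scatter), so the default cluster census
is 30: with six deep defining libraries the recomputed coverage floor is
one read, and any scatter would surface as spurious singleton clusters
the real analysis would not contain at matching rpm.

4C libraries (default 1e5 reads, 80% proper) draw captured fragments from
a weighted set of DpnII sites on the collapsed haplotype — modal weight
0.30 at a USR site, elevated weights inside the unit, some mass within
the bait exclusion window — with capture lengths {12, 16, 28} chosen so
trimming is unambiguous at the read length; decoys are anchor-free random
reads.  Methylation clones apply per-context Bernoulli methylation
(repressed: CG 0.88, CHG 0.60, CHH 0.07; active: ~0.02) and convert
unmethylated C→T except with the configured failure rate; the lambda
control is fully unmethylated.  Ct tables use Ct = base − log2(expression)
+ noise with a shared per-sample loading shift (cancelled by ΔCt),
biological s.d. 0.2 on log2 expression, technical s.d. 0.1, and the
reference amplicon unaffected by group; the default qRT design encodes a
true 15-fold difference at the USR amplicon.

Sequencing error is off by default; with exact-match mapping, an optional
uniform substitution rate simply converts affected reads to unmapped.
All randomness flows from a single integer-seeded PCG64 generator, so a
fixed seed reproduces every output byte-for-byte.

### What the generator does not emulate

Real libraries bring PCR duplication structure, quality-score decay,
adapter chimeras, near-identical repeat units, partial digestion and
re-ligation artefacts in 4C, and biological dispersion between replicates
beyond multinomial sampling.  Passing tests therefore show that the
implementations honour their contracts and recover planted effects under
clean sampling noise — not that the defaults match the error structure of
any particular instrument.

## Numerical and design choices

- Fold of B over A is undefined (NaN) when both means are zero, infinite
  when only A is zero; a t-test with zero variance in both groups and
  equal means returns p = 1 by convention.
- Dense ids are assigned to clusters in coordinate order; tag ranks use
  competition ranking.
- The reproduction script (`scripts/acceptance.py`) and the heavier tests
  use 5e4–1e5 reads per sRNA library, 5e4 4C reads, 20–200 clones and
  3×3 qPCR designs — sizes at which every planted effect is comfortably
  detectable on a single CPU.
- Statistical test assertions leave binomial slack on nominal coverage
  (e.g. a nominal-95% interval is asserted to cover ≥85% of 40 seeds) and
  share multiple-comparison budgets family-wise; point assertions on
  stochastic recoveries use tolerances of roughly twice the sampling
  error at the simulated depth.

## Known limitations

Detection handles perfect arrays only; the mapper is exact-match and
ungapped by design (quality-aware or mismatch-tolerant alignment is out
of scope); methylation calling assumes indel-free clones; ΔΔCt assumes
efficiency 2.0 for all amplicons; cluster calling semantics are declared
rather than matched bit-for-bit to any external caller.
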