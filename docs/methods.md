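# Methods

`bearmhc` re-implements, as one tested pipeline, the computational core of a
deep-amplicon MHC genotyping study in a diploid vertebrate: validating allele
sequences out of noisy multigene amplicon reads, inferring expression from
gDNA/cDNA comparison, quantifying historical positive selection on the
validated alleles, and measuring population differentiation when alleles
cannot be assigned to loci. This note records the models, the defaults and
the design choices where the design was genuinely open.

## Amplicon simulator (`simdata`)

The simulator is first-class code: it produces ground-truthed datasets with
exactly the error structure the validation procedure assumes, so sensitivity
and specificity can be measured against known truth.

**Genome model.** A marker (one primer pair) co-amplifies `n_loci` diploid
loci. An ancestral exon fragment of `seq_length_codons` sense codons is
mutated into per-locus base sequences separated by `locus_divergence` of
sites (default 0.08, keeping pairwise distances in the range typical of MHC
exon-2 sets rather than at saturation), and each locus base into
`alleles_per_locus` alleles. Every pair of alleles — within and across loci —
differs by at least `min_pairwise_diff` nucleotides (default 3), so sequence
identity determines the allele; no internal stop codons are generated.
Individuals draw between `alleles_per_individual_range` (default 5–11)
distinct alleles, at most two per locus, with within-locus allele weights
drawn per population from a Dirichlet with concentration `skew` (default
0.5); small concentrations give skewed, population-specific frequencies, so
the two simulated populations are genuinely differentiated.

**Read model.** Each amplicon (individual × template × replicate) carries a
6-bp tag; tags pairwise differ in ≥ 3 positions so a single sequencing error
cannot convert one tag into another. Depth is negative-binomial
(mean `depth_mean` = 500, shape `depth_dispersion` = 20), reflecting unequal
pooling. Template molecules are sampled proportionally to a per-individual,
per-allele log-normal amplification bias (σ = 0.4, drawn once per individual
and shared by its replicates), which spreads true-allele within-amplicon
frequencies — necessary for the grey zone of the classifier to be exercised
at all. Per read: with probability `chimera_fraction` (default 0.05) the
read is a single-crossover recombinant of two distinct co-amplified
templates, crossover uniform over internal positions and parents drawn by
template abundance; substitutions arrive per base at
`substitution_error_rate` (default 10⁻³); each homopolymer run of length ≥ 3
gains or loses one base with probability `indel_rate` (default 10⁻³), the
dominant pyrosequencing error mode. cDNA amplicons exclude alleles of
`nonexpressed_loci`. The default error rates are package choices — the kind
of values reported for PCR + pyrosequencing pipelines — not measurements.

Everything is driven by `numpy.random.default_rng([stage, seed])`, so a
dataset is byte-identical for a fixed seed. What the simulator does *not*
model: flowgram-level signal, quality scores, paired ends, contamination,
allelic dropout. Passing tests therefore demonstrate correctness of the
procedure under its own assumptions, not performance on any particular real
instrument's quirks.

## MPAF allele validation (`genotyping`)

For each unique insert sequence the **maximum per-amplicon frequency**
(MPAF) is the largest fraction of reads the variant reaches in any single
amplicon. By default MPAF is computed over gDNA amplicons only; cDNA
fractions are distorted by expression level and are used solely for
expression calls (the alternative is a config switch). Variants sorted by
descending MPAF are classified by marker-specific bands:

* class I operating point: screen from 1.5%, grey zone 1.53–2.86%, accept
  above — artifacts below the grey zone, true alleles above it;
* DRB operating point: screen from 3%, accept above 10%, with a degenerate
  (empty) grey zone — every variant between 3% and 10% is an artifact.

Ties in the sort are broken by total read count then sequence, making
downstream allele numbering reproducible. Classification is monotone in
MPAF by construction.

**Chimera rule.** A variant is flagged as a PCR chimera iff (i) two distinct
variants of strictly higher MPAF reconstruct it exactly as prefix + suffix
at a single internal crossover, and (ii) both parents occur at higher
within-amplicon frequency in *every* amplicon containing the variant. The
reported crossover is the full interval of breakpoints consistent with the
parents (crossovers between identical stretches are unidentifiable). Only
equal-length variants can be parents; indel-bearing variants are distinct
length variants expected to fall below the screen floor. Note the detection
target is *exact* recombinants: a chimeric read that subsequently acquired a
substitution is a compound artifact, invisible to exact reconstruction and
handled by the frequency floor instead. At a per-base error of 10⁻³ over
~200 bp roughly 17% of chimeric reads are compound in this sense, which is
why detection is scored on exact-crossover variants.

**Grey zone.** The published procedure resolves mid-band variants case by
case; here that step is codified as ordered rules — chimera-flagged →
artifact; one substitution away from a higher-MPAF true allele and never
seen without it → artifact; present in both replicates of a replicated
individual → true allele; otherwise left grey and written to a mandatory
review file. A user decision file overrides the rules, and naming an
unknown variant in it is an error.

**Naming and genotypes.** Validated alleles are named `Prefix-Marker*NN`
in descending order of the number of individuals carrying them (ties by
reads, then sequence). Genotypes are presence/absence of validated allele
sequences in an individual's gDNA amplicons. Replicate concordance reports
discordant calls / total calls over twice-amplified individuals; with zero
discordance it also reports 1/total_calls, the largest per-call error rate
consistent with observing none — both numbers are shown because either
convention appears in the literature, and the printed bound depends only on
how many calls the replicated panel happened to contain.

## Expression and locus counts (`expression`)

An allele is *expressed* when seen in cDNA of any assayed individual,
*not expressed* when seen only in gDNA of the assayed panel, *unassayed*
when absent from the panel. A cDNA observation without the matching gDNA
call warns (possible gDNA dropout) rather than fails. Minimum locus counts
assume diploidy only: an individual with k alleles needs ⌈k/2⌉ loci, so the
population maximum of gDNA counts bounds total loci and the panel maximum
of cDNA counts bounds expressed loci. Both are deliberate underestimates.

## Molecular evolution (`molevol`)

* **Translation / PSC.** Standard-code translation of complete codons
  (`frame_offset` per marker; a 224-bp fragment at offset 0 is 74 codons
  with 2 nt dropped). These are exon-internal fragments, so *any* in-frame
  stop is flagged as a premature stop codon. PSC-containing sequences stay
  in the analysis (their stop codons are excluded pairwise); excluding them
  wholesale is a caller-level subset, supported by `CodonAlignment.subset`.
* **Distances.** p-distance; K2P, `−½ln(1−2P−Q) − ¼ln(1−2Q)` from
  transition/transversion proportions; Poisson amino-acid correction
  `−ln(1−p)`. Saturated inputs raise explicit errors rather than returning
  NaN.
* **Nei–Gojobori.** Potential synonymous sites per codon are per-position
  fractions of synonymous one-step changes with changes to stops counted as
  nonsynonymous (so S̄+N̄ = 3 × codons, conserving sites). Multi-difference
  codons are averaged unweighted over all substitution pathways, pathways
  through stop codons excluded (with a fallback to all pathways in the
  degenerate case where every pathway is blocked). Jukes–Cantor correction
  `−¾ln(1−4p/3)` maps pS, pN to dS, dN. The implementation is verified
  against a brute-force enumeration oracle written independently in the
  test suite. This is the original unweighted-pathway convention; weighted
  variants exist in other software and would differ in the third decimal on
  typical data.
* **Means, SEs, Z test.** Reported statistics are arithmetic means over all
  unordered sequence pairs, ×100 ("per 100 sites"). Standard errors come
  from 1000 bootstrap resamples of alignment columns — codons for
  codon-based statistics, nucleotide sites for nucleotide distances —
  keeping the pair structure intact, which matches SEs computed over sites
  rather than over sequences. The one-tailed selection test is
  Z = (d̄N − d̄S)/SE with SE the bootstrap SE of the *difference* (codons
  resampled jointly for dN and dS); combining the two marginal variances
  instead is available as `variance="sum"`, since published tables rarely
  state which of the two was used. p = 1 − Φ(Z). Saturated bootstrap
  replicates are dropped with a warning; a zero-variance bootstrap with a
  positive difference reports p < 1/n_boot.
* **Partitions.** Antigen-binding-site masks are editable data files of
  1-based codon indices. The bundled masks are *reconstructions* from the
  HLA structural consensus literature mapped onto fragment coordinates and
  are labelled as such; every analysis takes the mask as an input, and the
  tests use explicit synthetic masks.
* **PSS × ABS enrichment.** One-tailed hypergeometric tail probability of
  the observed overlap between externally identified positively selected
  sites and the ABS mask. PSS identification itself (codon models, Bayes
  empirical Bayes) is out of scope; the set is consumed as input.

## Population structure (`popstruct`)

Alleles unassignable to loci are binary-encoded as dominant markers.
Pairwise FST is the AMOVA fixation index σ²a/(σ²a+σ²w) with the distance
between two presence/absence profiles the number of differing loci.
All-zero rows are retained — absence is an observed state under dominant
encoding. Negative estimates are reported unclamped. Two routes compute the
same decomposition: the distance-matrix route on individual-level data, and
a marginal route using only per-locus presence counts, exact because
multilocus Hamming distances are sums of per-locus indicators (pair sums
reduce to k(n−k) terms). Their equality on random matrices is tested. The
marginal route accepts published presence percentages; counts are recovered
by round-half-up, so integer percentages carry a reconstruction error of at
most half an individual per cell, and no permutation p-value is possible in
that mode. The permutation test reshuffles individuals between the two
populations preserving sizes, p = (1 + #{FST* ≥ FST})/(n_perm + 1).

## Problem sizes and numerical defaults

The analysis scripts and the acceptance script use 2 × 20 individuals,
6 loci × 4 alleles, 64 codons, depth 500 — enough for every allele to be
sampled deeply in several amplicons while the full pipeline (simulation →
validation → selection → FST) completes in well under a minute; bootstrap
and permutation replicates default to 1000 and 9999. Tolerances in the
tests are stated per check: closed forms at 10⁻⁴, oracle equivalences at
float precision, FST from integer percentages at ±0.005.

## Known limitations

* Alleles are never assigned to loci; all locus-level statements are the
  conservative diploid minima above.
* The chimera detector requires exact reconstruction, so compound
  chimera+substitution products are controlled by the MPAF floor, not
  flagged individually.
* Marginal-mode FST inherits the information loss of published percentage
  tables: no individual profiles, hence no permutation test.
* The bundled ABS masks are literature-based reconstructions, not
  species-specific annotations.
* Codon-model selection inference (M0/M7/M8, ω estimation, BEB) and
  Bayesian tree building are intentionally outside the package.
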