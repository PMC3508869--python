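# bearmhc

Genotyping and evolutionary analysis of multigene MHC families from deep
amplicon sequencing, built around the brown-bear (*Ursus arctos*) MHC
class I / class II study design: co-amplified loci, tagged amplicons,
allele validation by read-frequency thresholds, expression inference from
gDNA/cDNA, dN/dS selection tests on antigen-binding sites, and population
differentiation with alleles treated as dominant markers.

**Who it is for.** Molecular ecologists genotyping highly polymorphic,
multi-locus gene families (MHC being the canonical case) where a PCR
co-amplifies an unknown number of loci, reads are contaminated by PCR
substitutions, PCR chimeras and homopolymer indels, and variants cannot be
assigned to loci.

## The statistics at the core

* **MPAF validation.** For each sequence variant, the maximum per-amplicon
  frequency MPAF = max over amplicons of (variant reads / amplicon reads).
  True alleles attain high within-amplicon frequencies somewhere; artifacts
  derive from templates in the same reaction and stay rare everywhere.
  Variants are sorted by MPAF and cut by marker-specific bands (class I:
  artifacts < 1.53%, grey 1.53–2.86%, true above; DRB: artifacts < 10%,
  true above), with chimera screening — a chimera must co-occur with both
  parents, at lower frequency, in every amplicon containing it, and be
  their exact single-crossover recombinant — and rule-based grey-zone
  resolution.
* **Selection.** Nei–Gojobori counting with unweighted pathway averaging
  and Jukes–Cantor correction; d̄N vs d̄S compared by a one-tailed Z test,
  Z = (d̄N − d̄S)/SE with SE from a 1000-replicate codon-column bootstrap;
  K2P and Poisson-corrected distances; hypergeometric PSS × ABS enrichment.
* **Differentiation.** AMOVA FST on binary dominant-encoded alleles,
  σ²a/(σ²a+σ²w) from inter-individual Hamming distances, with a
  permutation test — or reconstructed exactly from published per-population
  presence percentages (marginal mode).

A seeded simulator generates ground-truthed datasets with the full error
structure (chimeras, substitutions, homopolymer indels, depth variation,
amplification bias, non-expressed loci, replicates), so the pipeline's
sensitivity and specificity are measured, not assumed. See
`docs/methods.md` for models, defaults and design decisions.

## Worked example

```sh
bearmhc simulate --seed 7 --out demo            # ground-truthed dataset
bearmhc genotype --reads demo/reads.fasta --tagmap demo/tagmap.tsv \
    --primer-f GCTCCCACTCCCTGAGGTAT --primer-r CCACGCTCTGGTTGTAGTA \
    --out demo_geno
```

The `analysis/` scripts run the same pipeline end to end with the study
conditions (6 loci, 5–11 alleles per bear, depth ~500, 0.1% substitution
error, 5% chimeric reads). `python analysis/02_genotype.py` prints:

```
assigned 26303/26303 reads (0 bad tag, 0 bad primer)
4850 variants tallied; 24 validated alleles (truth: 24 sampled alleles;
recovered 24, false positives 0)
chimeric variants flagged: 821/843 (97.4%)
replicate discordance 0.0000 over 77 calls (max error bound 0.0130)
```

i.e. every read lands in its amplicon (tags differ in ≥3 positions, so
single errors cannot migrate reads between amplicons), the MPAF classifier
recovers all 24 true alleles with no false positives out of 4850 raw
variants, 97% of exact-crossover chimeras are flagged with their parents,
and the ten twice-amplified bears give identical genotypes — with 77
concordant calls, the genotyping error consistent with the data is at most
1/77 ≈ 1.3%. `python analysis/05_popstruct.py` prints:

```
         simulated north-south (n=20+20): FST=0.2211  p=0.00010
 published class I north-south (n=100+124): FST=0.2170  p=n/a (marginal mode)
     published DRB north-south (n=100+134): FST=0.3040  p=n/a (marginal mode)
```

the last two rows being the dominant-marker AMOVA FST reconstructed from
the published per-population allele presence percentages bundled in
`src/bearmhc/data/table2_presence.tsv` (published point estimates: 0.216
and 0.304).

## Layout

```
src/bearmhc/        library: simdata, genotyping, expression, molevol,
                    popstruct, pipeline, cli (+ bundled data files)
analysis/           numbered narrative drivers over the library
tests/              pytest suite incl. acceptance checks
scripts/acceptance.py
docs/methods.md     models, parameters, design decisions, limitations
```
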