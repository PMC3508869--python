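"""Shared study conditions for the analysis scripts.

One place defines the simulated study: 6 co-amplified loci with 4 alleles
each, 5-11 alleles per individual, two populations of 20 with skewed
allele frequencies, amplicon depth ~500, per-base substitution error
1e-3, 5% chimeric reads, homopolymer indel rate 1e-3, one non-expressed
locus, 10 twice-amplified individuals and 6 individuals assayed on cDNA.
"""

from bearmhc.simdata import PopulationSpec, SimulationConfig

SEED = 20120197


def study_config(seed: int = SEED) -> SimulationConfig:
    return SimulationConfig(
        n_loci=6,
        alleles_per_locus=4,
        seq_length_codons=64,
        alleles_per_individual_range=(5, 11),
        populations=(PopulationSpec("north", 20, 0.5),
                     PopulationSpec("south", 20, 0.5)),
        depth_mean=500,
        substitution_error_rate=1e-3,
        chimera_fraction=0.05,
        indel_rate=1e-3,
        nonexpressed_loci=frozenset({5}),
        replicate_individuals=10,
        n_cdna_individuals=6,
        seed=seed,
    )
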