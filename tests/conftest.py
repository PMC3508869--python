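import pytest

from bearmhc import genotyping as gt
from bearmhc.pipeline import validate_amplicons
from bearmhc.simdata import PopulationSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def zero_error_config():
    return SimulationConfig(
        n_loci=4,
        alleles_per_locus=3,
        seq_length_codons=64,
        alleles_per_individual_range=(3, 7),
        populations=(PopulationSpec("north", 8, 0.6),
                     PopulationSpec("south", 8, 0.6)),
        depth_mean=200,
        substitution_error_rate=0.0,
        chimera_fraction=0.0,
        indel_rate=0.0,
        nonexpressed_loci=frozenset({3}),
        replicate_individuals=4,
        n_cdna_individuals=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_error_ds(zero_error_config):
    return simulate_dataset(zero_error_config)


@pytest.fixture(scope="session")
def paperlike_config():
    # study conditions: 6 co-amplified loci, 5-11 alleles per individual,
    # amplicon depth ~500, substitution error 1e-3, 5% chimeric reads,
    # 10 twice-amplified individuals, 6 individuals assayed on cDNA
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
        seed=7,
    )


@pytest.fixture(scope="session")
def paperlike_ds(paperlike_config):
    return simulate_dataset(paperlike_config)


def _demux(ds):
    reads = [(r.read_id, r.sequence) for r in ds.reads]
    amplicons, stats = gt.demultiplex(reads, ds.tag_map,
                                      ds.config.primer_f, ds.config.primer_r)
    return amplicons, stats


@pytest.fixture(scope="session")
def paperlike_amplicons(paperlike_ds):
    return _demux(paperlike_ds)


@pytest.fixture(scope="session")
def paperlike_validation(paperlike_ds, paperlike_amplicons):
    amplicons, _ = paperlike_amplicons
    return validate_amplicons(amplicons, gt.CLASS_I_THRESHOLDS,
                              paperlike_ds.config.marker,
                              paperlike_ds.config.species_prefix,
                              paperlike_ds.truth.population_of)


@pytest.fixture(scope="session")
def zero_error_amplicons(zero_error_ds):
    return _demux(zero_error_ds)


@pytest.fixture(scope="session")
def zero_error_validation(zero_error_ds, zero_error_amplicons):
    amplicons, _ = zero_error_amplicons
    return validate_amplicons(amplicons, gt.CLASS_I_THRESHOLDS,
                              zero_error_ds.config.marker,
                              zero_error_ds.config.species_prefix,
                              zero_error_ds.truth.population_of)
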