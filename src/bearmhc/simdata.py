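"""Seeded generator of ground-truthed multilocus MHC amplicon datasets.

Emulates the data structure produced by deep amplicon sequencing of a
multigene MHC family: several co-amplified loci per individual, per-base
PCR substitution error, single-crossover PCR chimeras between co-amplified
alleles, pyrosequencing-style homopolymer indels, unequal per-amplicon
read depth, replicate amplicons for error estimation, and gDNA vs cDNA
templates distinguishing expressed from non-expressed loci.

Every dataset is byte-reproducible from ``SimulationConfig.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AlleleSequence",
    "PopulationSpec",
    "SimulationConfig",
    "TruthSet",
    "SimulatedRead",
    "SimulatedDataset",
    "generate_allele_pool",
    "assign_genotypes",
    "simulate_reads",
    "simulate_dataset",
    "generate_tags",
]

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class AlleleSequence:
    """A named exon-fragment nucleotide sequence for one marker.

    ``locus`` is simulation truth only; with co-amplifying primers the
    locus of origin of a variant is unobservable downstream.
    """

    name: str
    marker: str
    sequence: str
    locus: int | None = None


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int
    skew: float = 1.0  # Dirichlet concentration for within-locus allele weights


@dataclass
class SimulationConfig:
    n_loci: int = 6
    alleles_per_locus: int = 4
    seq_length_codons: int = 64
    min_pairwise_diff: int = 3
    alleles_per_individual_range: tuple[int, int] = (5, 11)
    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("north", 20, 0.5),
        PopulationSpec("south", 20, 0.5),
    )
    depth_mean: float = 500.0
    depth_dispersion: float = 20.0  # negative-binomial shape; larger = tighter
    substitution_error_rate: float = 1e-3
    chimera_fraction: float = 0.05
    indel_rate: float = 1e-3  # per homopolymer run of length >= 3
    nonexpressed_loci: frozenset[int] = frozenset()
    replicate_individuals: int = 10
    n_cdna_individuals: int = 6
    locus_divergence: float = 0.08  # fraction of sites separating locus bases
    amplification_bias_sigma: float = 0.4
    marker: str = "U"
    species_prefix: str = "Urar"
    primer_f: str = "GCTCCCACTCCCTGAGGTAT"
    primer_r: str = "CCACGCTCTGGTTGTAGTA"
    tag_length: int = 6
    seed: int = 0

    @property
    def n_individuals(self) -> int:
        return sum(p.size for p in self.populations)

    @property
    def seq_length_nt(self) -> int:
        return 3 * self.seq_length_codons

    def validate(self) -> None:
        rates = {
            "substitution_error_rate": self.substitution_error_rate,
            "chimera_fraction": self.chimera_fraction,
            "indel_rate": self.indel_rate,
            "locus_divergence": self.locus_divergence,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if self.seq_length_codons < 2:
            raise ValueError("seq_length_codons must be >= 2")
        if self.n_loci < 1 or self.alleles_per_locus < 1:
            raise ValueError("need at least one locus and one allele per locus")
        lo, hi = self.alleles_per_individual_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid alleles_per_individual_range")
        if hi > 2 * self.n_loci:
            raise ValueError(
                f"alleles_per_individual_range upper bound {hi} exceeds "
                f"2 x n_loci = {2 * self.n_loci} (diploid loci)"
            )
        if self.min_pairwise_diff > self.seq_length_nt:
            raise ValueError("min_pairwise_diff exceeds sequence length")
        if not self.populations:
            raise ValueError("at least one population required")
        if any(p.size < 1 for p in self.populations):
            raise ValueError("population sizes must be >= 1")
        if not frozenset(self.nonexpressed_loci) <= set(range(self.n_loci)):
            raise ValueError("nonexpressed_loci indices out of range")

    def to_yaml(self) -> str:
        d = {
            k: (list(v) if isinstance(v, (tuple, frozenset)) else v)
            for k, v in self.__dict__.items()
        }
        d["populations"] = [
            {"name": p.name, "size": p.size, "skew": p.skew}
            for p in self.populations
        ]
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class TruthSet:
    """Ground truth for a simulated dataset."""

    alleles: list[AlleleSequence]
    genotypes: dict[str, frozenset[str]]  # individual -> allele names
    expression_flags: dict[str, bool]  # allele name -> expressed
    population_of: dict[str, str]

    def allele_by_name(self, name: str) -> AlleleSequence:
        return next(a for a in self.alleles if a.name == name)

    def validate(self) -> None:
        names = {a.name for a in self.alleles}
        for ind, geno in self.genotypes.items():
            unknown = geno - names
            if unknown:
                raise ValueError(f"{ind} carries unknown alleles {unknown}")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    amplicon_id: str
    sequence: str  # tag + primer_f + insert + revcomp(primer_r)
    source: str  # allele name, or "chimera(p1|p2|k)"
    is_chimera: bool
    n_substitutions: int
    n_indels: int

    @property
    def is_exact_chimera(self) -> bool:
        """Chimeric and still an exact single-crossover product."""
        return self.is_chimera and self.n_substitutions == 0 and self.n_indels == 0


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def generate_tags(n: int, length: int, rng: np.random.Generator,
                  min_dist: int = 3, max_tries: int = 200_000) -> list[str]:
    """Greedy set of ``n`` tags pairwise differing in >= ``min_dist`` positions."""
    tags: list[str] = []
    tries = 0
    while len(tags) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not find {n} tags of length {length} with pairwise "
                f"distance >= {min_dist}"
            )
        cand = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, t) >= min_dist for t in tags):
            tags.append(cand)
    return tags


def _random_sense_sequence(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Apply n_mut random substitutions, never creating a stop codon."""
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    done = 0
    guard = 0
    while done < n_mut:
        guard += 1
        if guard > 100 * n_mut + 100:
            break
        ci = int(rng.integers(0, len(codons)))
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        base = NUCLEOTIDES[int(rng.integers(0, 4))]
        if base == old[pos]:
            continue
        new = old[:pos] + base + old[pos + 1:]
        if new in STOP_CODONS:
            continue
        codons[ci] = new
        done += 1
    return "".join(codons)


def generate_allele_pool(config: SimulationConfig) -> list[AlleleSequence]:
    """Generate ``n_loci x alleles_per_locus`` codon-aligned allele sequences.

    All alleles are equal length, contain no stop codons, and every pair
    (within and across loci) differs by at least ``min_pairwise_diff``
    nucleotides, so sequence identity uniquely determines the allele.
    Loci descend from a common ancestral sequence separated by
    ``locus_divergence`` of sites, mimicking a multigene family whose
    members are related but distinguishable.
    """
    config.validate()
    rng = _rng(config, stage=1)
    pool: list[AlleleSequence] = []
    seqs: list[str] = []
    ancestor = _random_sense_sequence(config.seq_length_codons, rng)
    n_div = max(config.min_pairwise_diff,
                int(round(config.locus_divergence * config.seq_length_nt)))
    for locus in range(config.n_loci):
        base = _mutate(ancestor, n_div, rng) if config.n_loci > 1 \
            else ancestor
        for j in range(config.alleles_per_locus):
            placed = False
            for attempt in range(300):
                # escalate divergence if the constraint keeps failing
                n_mut = config.min_pairwise_diff + int(
                    rng.integers(0, config.min_pairwise_diff + 2 + attempt // 30)
                )
                cand = _mutate(base, n_mut, rng) if j or attempt else base
                if all(hamming(cand, s) >= config.min_pairwise_diff for s in seqs):
                    seqs.append(cand)
                    pool.append(AlleleSequence(
                        name=f"sim{locus:02d}.{j:02d}",
                        marker=config.marker,
                        sequence=cand,
                        locus=locus,
                    ))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "cannot satisfy min_pairwise_diff "
                    f"{config.min_pairwise_diff} for locus {locus}; "
                    "sequence too short or pool too dense"
                )
    return pool


def assign_genotypes(pool: list[AlleleSequence],
                     config: SimulationConfig) -> TruthSet:
    """Assign each individual 'range' alleles, at most two per (diploid) locus.

    Within-locus allele frequencies are drawn per population from a
    Dirichlet whose concentration is the population's ``skew``; small
    concentrations give strongly skewed, population-specific frequencies
    and hence non-zero differentiation between populations.
    """
    if not pool:
        raise ValueError("allele pool is empty")
    config.validate()
    rng = _rng(config, stage=2)
    by_locus: dict[int, list[AlleleSequence]] = {}
    for a in pool:
        by_locus.setdefault(a.locus, []).append(a)
    loci = sorted(by_locus)
    lo, hi = config.alleles_per_individual_range

    # population-specific within-locus allele weights
    weights: dict[tuple[str, int], np.ndarray] = {}
    for popspec in config.populations:
        for locus in loci:
            k = len(by_locus[locus])
            alpha = np.full(k, max(popspec.skew, 1e-3))
            weights[(popspec.name, locus)] = rng.dirichlet(alpha)

    genotypes: dict[str, frozenset[str]] = {}
    population_of: dict[str, str] = {}
    for popspec in config.populations:
        for i in range(popspec.size):
            ind = f"{popspec.name}_{i + 1:03d}"
            population_of[ind] = popspec.name
            k = int(rng.integers(lo, hi + 1))
            # allocate k chromosome slots over diploid loci
            slots = np.repeat(loci, 2)
            rng.shuffle(slots)
            chosen: list[str] = []
            counts: dict[int, int] = {}
            for locus in slots[:k]:
                counts[locus] = counts.get(locus, 0) + 1
            for locus, c in counts.items():
                alleles = by_locus[locus]
                w = weights[(popspec.name, locus)]
                if c == 1 or len(alleles) == 1:
                    idx = rng.choice(len(alleles), p=w)
                    chosen.append(alleles[int(idx)].name)
                else:
                    idx = rng.choice(len(alleles), size=2, replace=False, p=w)
                    chosen.extend(alleles[int(j)].name for j in idx)
            genotypes[ind] = frozenset(chosen)

    expression_flags = {
        a.name: a.locus not in config.nonexpressed_loci for a in pool
    }
    truth = TruthSet(
        alleles=list(pool),
        genotypes=genotypes,
        expression_flags=expression_flags,
        population_of=population_of,
    )
    truth.validate()
    return truth


def _homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of length >= min_len."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: TruthSet
    reads: list[SimulatedRead]
    tag_map: pd.DataFrame  # amplicon_id, tag, individual, marker, template, replicate

    def read_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [r.read_id for r in self.reads],
                "amplicon_id": [r.amplicon_id for r in self.reads],
                "source": [r.source for r in self.reads],
                "is_chimera": [int(r.is_chimera) for r in self.reads],
                "n_substitutions": [r.n_substitutions for r in self.reads],
                "n_indels": [r.n_indels for r in self.reads],
            }
        )

    def write(self, outdir) -> None:
        """Write reads.fasta, alleles.fasta, tagmap.tsv, genotypes.tsv,
        expression.tsv, read_truth.tsv and config.yaml to ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "reads.fasta", "w") as fh:
            for r in self.reads:
                fh.write(f">{r.read_id}\n")
                for i in range(0, len(r.sequence), 70):
                    fh.write(r.sequence[i:i + 70] + "\n")
        with open(out / "alleles.fasta", "w") as fh:
            for a in self.truth.alleles:
                fh.write(f">{a.name} locus={a.locus}\n")
                for i in range(0, len(a.sequence), 70):
                    fh.write(a.sequence[i:i + 70] + "\n")
        self.tag_map.to_csv(out / "tagmap.tsv", sep="\t", index=False)
        allele_names = sorted(a.name for a in self.truth.alleles)
        rows = []
        for ind in sorted(self.truth.genotypes):
            row = {"individual": ind,
                   "population": self.truth.population_of[ind]}
            row.update({a: int(a in self.truth.genotypes[ind])
                        for a in allele_names})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "genotypes.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "allele": allele_names,
                "expressed": [int(self.truth.expression_flags[a])
                              for a in allele_names],
            }
        ).to_csv(out / "expression.tsv", sep="\t", index=False)
        self.read_truth_frame().to_csv(out / "read_truth.tsv", sep="\t",
                                       index=False)
        with open(out / "config.yaml", "w") as fh:
            fh.write(self.config.to_yaml())


def simulate_reads(truth: TruthSet, config: SimulationConfig) -> SimulatedDataset:
    """Generate tagged amplicon reads for every individual.

    Amplicon plan: one gDNA amplicon per individual; a second gDNA
    replicate for the first ``replicate_individuals`` individuals; a cDNA
    amplicon for the first ``n_cdna_individuals`` individuals, from which
    alleles of non-expressed loci are absent.
    """
    config.validate()
    truth.validate()
    rng = _rng(config, stage=3)
    individuals = sorted(truth.genotypes)
    allele_seq = {a.name: a.sequence for a in truth.alleles}
    locus_of = {a.name: a.locus for a in truth.alleles}

    plan: list[tuple[str, str, int]] = []  # (individual, template, replicate)
    for ind in individuals:
        plan.append((ind, "gDNA", 1))
    for ind in individuals[:config.replicate_individuals]:
        plan.append((ind, "gDNA", 2))
    for ind in individuals[:config.n_cdna_individuals]:
        plan.append((ind, "cDNA", 1))

    tags = generate_tags(len(plan), config.tag_length, rng)
    tag_rows = []
    reads: list[SimulatedRead] = []
    L = config.seq_length_nt
    runs_cache = {name: _homopolymer_runs(seq)
                  for name, seq in allele_seq.items()}

    # per-individual per-allele amplification bias, shared across replicates
    bias: dict[str, dict[str, float]] = {}
    for ind in individuals:
        alleles = sorted(truth.genotypes[ind])
        mult = np.exp(rng.normal(0.0, config.amplification_bias_sigma,
                                 size=len(alleles)))
        bias[ind] = dict(zip(alleles, mult))

    p_nb = config.depth_dispersion / (config.depth_dispersion + config.depth_mean)
    read_no = 0
    for amp_idx, (ind, template, replicate) in enumerate(plan):
        amplicon_id = f"amp{amp_idx:04d}"
        tag_rows.append(
            {
                "amplicon_id": amplicon_id,
                "tag": tags[amp_idx],
                "individual": ind,
                "marker": config.marker,
                "template": template,
                "replicate": replicate,
            }
        )
        alleles = sorted(truth.genotypes[ind])
        if template == "cDNA":
            alleles = [a for a in alleles
                       if locus_of[a] not in config.nonexpressed_loci]
        if not alleles:
            continue
        w = np.array([bias[ind][a] for a in alleles])
        w = w / w.sum()
        depth = max(1, int(rng.negative_binomial(config.depth_dispersion, p_nb)))

        for _ in range(depth):
            is_chimera = (len(alleles) >= 2
                          and rng.random() < config.chimera_fraction)
            if is_chimera:
                i1, i2 = rng.choice(len(alleles), size=2, replace=False,
                                    p=w)
                a1, a2 = alleles[int(i1)], alleles[int(i2)]
                k = int(rng.integers(1, L))  # crossover after position k
                insert = allele_seq[a1][:k] + allele_seq[a2][k:]
                source = f"chimera({a1}|{a2}|{k})"
                runs = _homopolymer_runs(insert)
            else:
                ai = int(rng.choice(len(alleles), p=w))
                a1 = alleles[ai]
                insert = allele_seq[a1]
                source = a1
                runs = runs_cache[a1]

            n_subs = int(rng.binomial(L, config.substitution_error_rate))
            if n_subs:
                chars = list(insert)
                pos = rng.choice(L, size=n_subs, replace=False)
                for p in pos:
                    old = chars[int(p)]
                    alt = [b for b in NUCLEOTIDES if b != old]
                    chars[int(p)] = alt[int(rng.integers(0, 3))]
                insert = "".join(chars)

            n_indels = 0
            if config.indel_rate > 0 and runs:
                events = rng.random(len(runs)) < config.indel_rate
                if events.any():
                    chars = list(insert)
                    # apply right-to-left so positions stay valid
                    for (start, length), ev in sorted(
                            zip(runs, events), reverse=True):
                        if not ev:
                            continue
                        n_indels += 1
                        if rng.random() < 0.5:
                            chars.insert(start, chars[start])
                        else:
                            del chars[start]
                    insert = "".join(chars)

            seq = (tags[amp_idx] + config.primer_f + insert
                   + revcomp(config.primer_r))
            reads.append(SimulatedRead(
                read_id=f"read{read_no:07d}",
                amplicon_id=amplicon_id,
                sequence=seq,
                source=source,
                is_chimera=is_chimera,
                n_substitutions=n_subs,
                n_indels=n_indels,
            ))
            read_no += 1

    return SimulatedDataset(
        config=config,
        truth=truth,
        reads=reads,
        tag_map=pd.DataFrame(tag_rows),
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Pool -> genotypes -> reads, all from ``config.seed``."""
    pool = generate_allele_pool(config)
    truth = assign_genotypes(pool, config)
    return simulate_reads(truth, config)
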