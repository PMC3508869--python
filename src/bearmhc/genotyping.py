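"""Amplicon demultiplexing and MPAF-based allele validation.

The validation statistic is the maximum per-amplicon frequency (MPAF): for
each unique sequence variant, the highest fraction of reads it attains in
any single amplicon across the whole dataset. True alleles are expected to
reach high within-amplicon frequencies somewhere; PCR/sequencing artifacts
derive from a template present in the same reaction and stay rare
everywhere. Variants are sorted by MPAF and classified by marker-specific
thresholds, with an explicit grey zone resolved by ordered rules
(chimera flag, one-off shadow of a validated allele, replicate
confirmation) that codify the case-by-case review step.

Chimera screening uses the co-occurrence rationale: a PCR chimera must
occur together with both parental alleles in every amplicon containing it,
at lower within-amplicon frequency than either parent, and must be an
exact prefix+suffix recombinant of the parents at a single crossover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simdata import AlleleSequence, hamming, revcomp

__all__ = [
    "TaggedRead",
    "Amplicon",
    "ChimeraFlag",
    "VariantRecord",
    "ClassificationThresholds",
    "CLASS_I_THRESHOLDS",
    "DRB_THRESHOLDS",
    "GenotypeTable",
    "DemultiplexStats",
    "demultiplex",
    "tally_variants",
    "classify_variants",
    "detect_chimeras",
    "resolve_grey_zone",
    "name_alleles",
    "call_genotypes",
    "call_genotypes_by_replicate",
    "replicate_concordance",
]

log = logging.getLogger(__name__)

TRUE_ALLELE = "true_allele"
ARTIFACT = "artifact"
GREY_ZONE = "grey_zone"


@dataclass(frozen=True)
class TaggedRead:
    read_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty read sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: alphabet must be ACGTN")


@dataclass
class Amplicon:
    """Read tally for one individual x marker x replicate x template."""

    amplicon_id: str
    individual: str
    marker: str
    replicate: int
    template: str  # "gDNA" | "cDNA"
    variant_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.variant_counts.values())

    def frequency(self, sequence: str) -> float:
        total = self.total_reads
        return self.variant_counts.get(sequence, 0) / total if total else 0.0


@dataclass(frozen=True)
class ChimeraFlag:
    parent1: str  # sequence contributing the prefix
    parent2: str  # sequence contributing the suffix
    crossover: tuple[int, int]  # 1-based inclusive range of breakpoints


@dataclass
class VariantRecord:
    sequence: str
    per_amplicon_frequency: dict[str, float]
    mpaf: float
    n_amplicons: int
    total_reads: int
    classification: str | None = None
    chimera_flag: ChimeraFlag | None = None
    note: str = ""


@dataclass(frozen=True)
class ClassificationThresholds:
    """MPAF bands: below grey -> artifact, above grey -> true allele.

    ``screen_floor`` is where evaluation starts (variants below are
    automatic artifacts); ``accept_threshold`` is the level above which
    no variant was ever an artifact. A degenerate grey zone
    (low == high == accept) means no case-by-case band.
    """

    screen_floor: float
    accept_threshold: float
    grey_zone: tuple[float, float]

    def __post_init__(self):
        low, high = self.grey_zone
        if not (0 < self.screen_floor <= low <= high
                <= self.accept_threshold <= 1):
            raise ValueError(
                "need 0 < screen_floor <= grey.low <= grey.high "
                "<= accept_threshold <= 1"
            )

    def classify(self, mpaf: float) -> str:
        low, high = self.grey_zone
        if mpaf < low:
            return ARTIFACT
        if mpaf > high:
            return TRUE_ALLELE
        return GREY_ZONE


# Published operating points: class I screened from 1.5% with a
# 1.53-2.86% grey zone; class II DRB screened from 3% with every variant
# below 10% resolved as artifact (degenerate grey zone).
CLASS_I_THRESHOLDS = ClassificationThresholds(0.015, 0.03, (0.0153, 0.0286))
DRB_THRESHOLDS = ClassificationThresholds(0.03, 0.10, (0.10, 0.10))


@dataclass
class DemultiplexStats:
    n_reads: int = 0
    n_assigned: int = 0
    n_bad_tag: int = 0
    n_bad_primer: int = 0

    @property
    def n_unassigned(self) -> int:
        return self.n_bad_tag + self.n_bad_primer


def _match(a: str, b: str, max_mm: int) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def demultiplex(reads, tag_map: pd.DataFrame, primer_f: str, primer_r: str,
                max_primer_mismatch: int = 0,
                try_revcomp: bool = True) -> tuple[list[Amplicon], DemultiplexStats]:
    """Assign reads to amplicons by exact leading tag, then strip primers.

    Tag matching is exact by design: tags differing pairwise in >= 3
    positions guarantee that a single sequencing error cannot convert one
    tag into another, so a mismatched tag marks an unassignable read.
    Reads lacking either primer (within ``max_primer_mismatch``) are
    dropped. Returns amplicons (one per tag-map row, possibly empty) and
    assignment statistics.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("empty read collection")
    tags = list(tag_map["tag"])
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate tags in tag map")
    for i in range(len(tags)):
        for j in range(i + 1, len(tags)):
            if hamming(tags[i], tags[j]) < 3:
                raise ValueError(
                    f"tags {tags[i]} and {tags[j]} differ in < 3 positions"
                )
    tag_len = len(tags[0])
    by_tag: dict[str, Amplicon] = {}
    for row in tag_map.itertuples(index=False):
        by_tag[row.tag] = Amplicon(
            amplicon_id=row.amplicon_id,
            individual=row.individual,
            marker=row.marker,
            replicate=int(row.replicate),
            template=row.template,
        )
    rc_r = revcomp(primer_r)
    stats = DemultiplexStats()
    for read in reads:
        if isinstance(read, tuple):
            read = TaggedRead(*read)
        stats.n_reads += 1
        assigned = False
        for seq in ((read.sequence, revcomp(read.sequence))
                    if try_revcomp else (read.sequence,)):
            amp = by_tag.get(seq[:tag_len])
            if amp is None:
                continue
            body = seq[tag_len:]
            if not _match(body[:len(primer_f)], primer_f, max_primer_mismatch):
                stats.n_bad_primer += 1
                assigned = True  # tag recognised; primer failure is final
                break
            tail = body[len(body) - len(rc_r):]
            if not _match(tail, rc_r, max_primer_mismatch):
                stats.n_bad_primer += 1
                assigned = True
                break
            insert = body[len(primer_f):len(body) - len(rc_r)]
            amp.variant_counts[insert] = amp.variant_counts.get(insert, 0) + 1
            stats.n_assigned += 1
            assigned = True
            break
        if not assigned:
            stats.n_bad_tag += 1
    if stats.n_unassigned:
        log.info("demultiplex: %d/%d reads unassigned (%d bad tag, %d bad primer)",
                 stats.n_unassigned, stats.n_reads, stats.n_bad_tag,
                 stats.n_bad_primer)
    return list(by_tag.values()), stats


def tally_variants(amplicons, mpaf_templates: tuple[str, ...] = ("gDNA",),
                   ) -> list[VariantRecord]:
    """One record per unique insert sequence with per-amplicon frequencies.

    MPAF is taken over amplicons whose template is in ``mpaf_templates``
    (gDNA only by default: cDNA read fractions are distorted by
    expression differences and are used solely for expression calls).
    Frequencies in all amplicons are retained for chimera screening.
    """
    amplicons = list(amplicons)
    if not amplicons:
        raise ValueError("no amplicons to tally")
    freqs: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    mpaf: dict[str, float] = {}
    n_amp: dict[str, int] = {}
    for amp in amplicons:
        total = amp.total_reads
        if total == 0:
            log.warning("amplicon %s has no reads; skipped", amp.amplicon_id)
            continue
        in_mpaf = amp.template in mpaf_templates
        for seq, count in amp.variant_counts.items():
            f = count / total
            freqs.setdefault(seq, {})[amp.amplicon_id] = f
            totals[seq] = totals.get(seq, 0) + count
            if in_mpaf:
                if f > mpaf.get(seq, -1.0):
                    mpaf[seq] = f
                n_amp[seq] = n_amp.get(seq, 0) + 1
    return [
        VariantRecord(
            sequence=seq,
            per_amplicon_frequency=freqs[seq],
            mpaf=mpaf.get(seq, 0.0),
            n_amplicons=n_amp.get(seq, 0),
            total_reads=totals[seq],
        )
        for seq in freqs
    ]


def _sort_key(v: VariantRecord):
    return (-v.mpaf, -v.total_reads, v.sequence)


def classify_variants(variants, thresholds: ClassificationThresholds,
                      ) -> list[VariantRecord]:
    """Sort by descending MPAF and apply the threshold bands.

    Ties are broken by total read count (descending) then sequence, so
    ordering — and therefore downstream allele numbering — is
    reproducible.
    """
    out = sorted(variants, key=_sort_key)
    for v in out:
        v.classification = thresholds.classify(v.mpaf)
    return out


def _lcp_lcs(focal: np.ndarray, others: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Longest common prefix/suffix lengths of each row of ``others`` vs focal."""
    eq = others == focal[None, :]
    L = focal.size
    neq = ~eq
    any_neq = neq.any(axis=1)
    first = np.where(any_neq, neq.argmax(axis=1), L)
    last = np.where(any_neq, L - 1 - neq[:, ::-1].argmax(axis=1), -1)
    lcp = first
    lcs = L - 1 - last
    return lcp, lcs


def detect_chimeras(variants, amplicons) -> list[VariantRecord]:
    """Flag variants explainable as single-crossover PCR recombinants.

    A variant is flagged iff (i) two distinct variants of strictly higher
    MPAF reproduce it exactly as prefix+suffix at some single internal
    crossover, and (ii) both parents are present — at higher
    within-amplicon frequency — in every amplicon containing the variant.
    Returns the flagged records; flags are set on the records in place.
    """
    variants = list(variants)
    amp_freq: dict[str, dict[str, float]] = {}
    for amp in amplicons:
        total = amp.total_reads
        if total:
            amp_freq[amp.amplicon_id] = {
                s: c / total for s, c in amp.variant_counts.items()
            }
    mpaf_of = {v.sequence: v.mpaf for v in variants}
    arr_cache: dict[str, np.ndarray] = {}

    def as_arr(seq: str) -> np.ndarray:
        a = arr_cache.get(seq)
        if a is None:
            a = np.frombuffer(seq.encode(), dtype=np.uint8)
            arr_cache[seq] = a
        return a

    flagged = []
    for v in variants:
        v.chimera_flag = None
        amps = list(v.per_amplicon_frequency)
        if not amps:
            continue
        # candidates: higher within-amplicon frequency in EVERY amplicon of v,
        # strictly higher MPAF, same length
        cands: set[str] | None = None
        ok = True
        for aid in amps:
            table = amp_freq.get(aid, {})
            fv = table.get(v.sequence, 0.0)
            here = {s for s, f in table.items() if f > fv}
            cands = here if cands is None else (cands & here)
            if not cands:
                ok = False
                break
        if not ok:
            continue
        L = len(v.sequence)
        cands = [s for s in cands
                 if len(s) == L and mpaf_of.get(s, 0.0) > v.mpaf]
        if len(cands) < 2:
            continue
        focal = as_arr(v.sequence)
        others = np.stack([as_arr(s) for s in cands])
        lcp, lcs = _lcp_lcs(focal, others)
        # need i != j with a breakpoint k in [max(1, L-lcs_j), min(lcp_i, L-1)]
        order = np.argsort(-lcp)
        best = None
        for i in order:
            if lcp[i] < 1:
                break
            for j in np.argsort(-lcs):
                if i == j or lcs[j] < 1:
                    continue
                lo = max(1, L - int(lcs[j]))
                hi = min(int(lcp[i]), L - 1)
                if lo <= hi:
                    best = (int(i), int(j), lo, hi)
                    break
            if best:
                break
        if best:
            i, j, lo, hi = best
            v.chimera_flag = ChimeraFlag(
                parent1=cands[i], parent2=cands[j], crossover=(lo, hi)
            )
            flagged.append(v)
    return flagged


def _replicated_individuals(amplicons) -> dict[str, list[Amplicon]]:
    by_ind: dict[str, list[Amplicon]] = {}
    for amp in amplicons:
        if amp.template == "gDNA":
            by_ind.setdefault(amp.individual, []).append(amp)
    return {ind: amps for ind, amps in by_ind.items()
            if len({a.replicate for a in amps}) >= 2}


def resolve_grey_zone(variants, amplicons,
                      decisions: dict[str, str] | None = None,
                      ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Resolve grey-zone variants by ordered default rules.

    In order: (1) chimera-flagged -> artifact; (2) one substitution away
    from a higher-MPAF true allele and never observed without it ->
    artifact; (3) present in both replicates of a replicated individual
    -> true allele; (4) otherwise left grey and emitted in the review
    table for a human decision. ``decisions`` (sequence -> class) takes
    precedence over every rule; naming an unknown sequence is an error.
    """
    variants = list(variants)
    by_seq = {v.sequence: v for v in variants}
    if decisions:
        unknown = set(decisions) - set(by_seq)
        if unknown:
            raise ValueError(f"decision file names unknown variants: {sorted(unknown)[:3]}")
        for seq, cls in decisions.items():
            if cls not in (TRUE_ALLELE, ARTIFACT):
                raise ValueError(f"invalid decision {cls!r} for {seq[:20]}...")

    true_seqs = [v for v in variants if v.classification == TRUE_ALLELE]
    replicated = _replicated_individuals(amplicons)
    amp_by_id = {a.amplicon_id: a for a in amplicons}
    rows = []
    for v in variants:
        if v.classification != GREY_ZONE:
            continue
        rule, outcome = None, GREY_ZONE
        if decisions and v.sequence in decisions:
            rule, outcome = "user_decision", decisions[v.sequence]
        elif v.chimera_flag is not None:
            rule, outcome = "chimera", ARTIFACT
        else:
            shadow = None
            for t in true_seqs:
                if (t.mpaf > v.mpaf and len(t.sequence) == len(v.sequence)
                        and hamming(t.sequence, v.sequence) == 1):
                    if all(aid in t.per_amplicon_frequency
                           for aid in v.per_amplicon_frequency):
                        shadow = t
                        break
            if shadow is not None:
                rule, outcome = "one_off_shadow", ARTIFACT
            else:
                for ind, amps in replicated.items():
                    reps = {a.replicate for a in amps
                            if a.amplicon_id in v.per_amplicon_frequency}
                    if len(reps) >= 2:
                        rule, outcome = "replicate_confirmed", TRUE_ALLELE
                        break
        if rule is None:
            rule = "unresolved"
        v.classification = outcome
        v.note = rule
        rows.append({"sequence": v.sequence, "mpaf": v.mpaf,
                     "rule": rule, "classification": outcome})
    review = pd.DataFrame(rows, columns=["sequence", "mpaf", "rule",
                                         "classification"])
    return variants, review


def name_alleles(variants, amplicons, marker: str, species_prefix: str,
                 ) -> list[AlleleSequence]:
    """Name validated alleles Prefix-Marker*NN by descending abundance.

    Abundance is the number of individuals whose gDNA contains the
    variant; ties are broken by total read count then sequence, numbering
    from *01 for the most widespread allele.
    """
    true_vars = [v for v in variants if v.classification == TRUE_ALLELE]
    ind_of_amp = {a.amplicon_id: a.individual for a in amplicons
                  if a.template == "gDNA"}
    n_ind = {
        v.sequence: len({ind_of_amp[aid] for aid in v.per_amplicon_frequency
                         if aid in ind_of_amp})
        for v in true_vars
    }
    ordered = sorted(true_vars,
                     key=lambda v: (-n_ind[v.sequence], -v.total_reads,
                                    v.sequence))
    width = max(2, len(str(len(ordered))))
    return [
        AlleleSequence(
            name=f"{species_prefix}-{marker}*{i + 1:0{width}d}",
            marker=marker,
            sequence=v.sequence,
        )
        for i, v in enumerate(ordered)
    ]


class GenotypeTable:
    """Individuals x named alleles presence matrix with population labels."""

    def __init__(self, presence: pd.DataFrame, population: pd.Series,
                 reads: pd.DataFrame | None = None):
        if presence.index.duplicated().any():
            raise ValueError("duplicate individual ids")
        self.presence = presence.astype(int)
        self.population = population.reindex(presence.index)
        self.reads = reads

    @property
    def individuals(self) -> list[str]:
        return list(self.presence.index)

    @property
    def alleles(self) -> list[str]:
        return list(self.presence.columns)

    def allele_counts(self) -> pd.Series:
        """Alleles carried per individual."""
        return self.presence.sum(axis=1)

    def allele_set(self, individual: str) -> frozenset[str]:
        row = self.presence.loc[individual]
        return frozenset(row.index[row > 0])

    def presence_percent(self) -> pd.DataFrame:
        """Percentage of individuals possessing each allele, per population."""
        out = {}
        for pop, sub in self.presence.groupby(self.population):
            out[pop] = 100.0 * sub.mean(axis=0)
        return pd.DataFrame(out)

    def to_tsv(self, path) -> None:
        df = self.presence.copy()
        df.insert(0, "population", self.population)
        df.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", index_col="individual")
        pop = df.pop("population")
        return cls(df, pop)


def call_genotypes(amplicons, alleles: list[AlleleSequence],
                   population_of: dict[str, str] | None = None,
                   template: str = "gDNA") -> GenotypeTable:
    """Presence/absence of each validated allele per individual.

    An allele is present iff its exact sequence was observed in any
    amplicon of the requested template for that individual. Artifact and
    grey variants never enter the table because only named alleles are
    scored.
    """
    if not alleles:
        raise ValueError("no validated alleles to call")
    amps = [a for a in amplicons if a.template == template]
    individuals = sorted({a.individual for a in amps})
    presence = pd.DataFrame(0, index=individuals,
                            columns=[a.name for a in alleles])
    reads = presence.copy()
    for amp in amps:
        for al in alleles:
            c = amp.variant_counts.get(al.sequence, 0)
            if c:
                presence.loc[amp.individual, al.name] = 1
                reads.loc[amp.individual, al.name] += c
    zero = presence.sum(axis=1) == 0
    for ind in presence.index[zero]:
        log.warning("individual %s has no surviving allele calls", ind)
    pop = pd.Series({i: (population_of or {}).get(i, "all")
                     for i in individuals})
    return GenotypeTable(presence, pop, reads)


def call_genotypes_by_replicate(amplicons, alleles: list[AlleleSequence],
                                template: str = "gDNA",
                                ) -> dict[tuple[str, int], frozenset[str]]:
    """Allele set called separately for each (individual, replicate)."""
    seq_to_name = {a.sequence: a.name for a in alleles}
    calls: dict[tuple[str, int], set[str]] = {}
    for amp in amplicons:
        if amp.template != template:
            continue
        key = (amp.individual, amp.replicate)
        s = calls.setdefault(key, set())
        for seq in amp.variant_counts:
            name = seq_to_name.get(seq)
            if name:
                s.add(name)
    return {k: frozenset(v) for k, v in calls.items()}


def replicate_concordance(calls_by_replicate: dict[tuple[str, int], frozenset[str]],
                          ) -> dict:
    """Per-allele-call discordance across replicated individuals.

    Rate = discordant calls / total calls, where per individual the calls
    are the union of alleles seen in either replicate and a call is
    discordant when present in one replicate only. With zero discordance
    the maximum error consistent with the data is reported as
    1/total_calls.
    """
    by_ind: dict[str, dict[int, frozenset[str]]] = {}
    for (ind, rep), s in calls_by_replicate.items():
        by_ind.setdefault(ind, {})[rep] = s
    replicated = {ind: reps for ind, reps in by_ind.items() if len(reps) >= 2}
    if not replicated:
        raise ValueError("no individuals with >= 2 replicates")
    total = 0
    discordant = 0
    for ind, reps in replicated.items():
        sets = list(reps.values())
        union = frozenset().union(*sets)
        inter = sets[0]
        for s in sets[1:]:
            inter &= s
        total += len(union)
        discordant += len(union - inter)
    rate = discordant / total if total else 0.0
    return {
        "n_individuals": len(replicated),
        "total_calls": total,
        "discordant_calls": discordant,
        "discordance_rate": rate,
        "max_error_bound": (1.0 / total) if (discordant == 0 and total)
        else rate,
    }
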