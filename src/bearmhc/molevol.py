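"""Molecular-evolution statistics on codon-aligned allele sets.

Implements the classical toolkit for detecting historical positive
selection on MHC exon fragments: translation with premature-stop-codon
(PSC) screening, variable-site counts, p-distances, Kimura 2-parameter
(K2P) and Poisson-corrected amino-acid distances, Nei-Gojobori counting
of synonymous/nonsynonymous sites and differences with the Jukes-Cantor
correction, codon-column bootstrap standard errors, the one-tailed Z test
of dN > dS on antigen-binding-site (ABS) partitions, and a hypergeometric
test of PSS x ABS overlap.

Conventions follow the original Nei-Gojobori (1986) method: potential
synonymous sites per codon are the per-position fractions of synonymous
changes (changes to stop codons count as nonsynonymous), multi-difference
codons are resolved by unweighted averaging over all substitution
pathways with pathways through stop codons excluded, and
d = -3/4 ln(1 - 4p/3) corrects for multiple hits.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CodonAlignment",
    "SiteMask",
    "NGCounts",
    "PairwiseMean",
    "SelectionTest",
    "translate_codons",
    "translate_and_screen",
    "count_variable_sites",
    "pairwise_p_distance",
    "k2p_distance",
    "poisson_correction",
    "poisson_aa_distance",
    "jc_correction",
    "nei_gojobori_pair",
    "mean_pairwise",
    "z_test_selection",
    "pss_abs_enrichment",
    "selection_table",
    "distance_table",
]

log = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")

PARTITIONS = ("all", "abs", "non_abs")


@dataclass(frozen=True)
class SiteMask:
    """1-based ABS codon indices within a codon alignment."""

    marker: str
    abs_codons: frozenset[int]

    def validate(self, n_codons: int) -> None:
        if not self.abs_codons:
            raise ValueError("empty ABS mask")
        bad = [i for i in self.abs_codons if not 1 <= i <= n_codons]
        if bad:
            raise ValueError(f"ABS codons out of [1, {n_codons}]: {bad}")

    def partition_codons(self, n_codons: int, partition: str) -> np.ndarray:
        """0-based codon indices for a named partition."""
        if partition == "all":
            return np.arange(n_codons)
        self.validate(n_codons)
        abs0 = np.array(sorted(i - 1 for i in self.abs_codons))
        if partition == "abs":
            return abs0
        if partition == "non_abs":
            return np.setdiff1d(np.arange(n_codons), abs0)
        raise ValueError(f"unknown partition {partition!r}")

    @classmethod
    def from_file(cls, path, marker: str) -> "SiteMask":
        """Mask file: lines of ``marker<TAB>space-separated 1-based codons``."""
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, rest = line.partition("\t")
                if name == marker:
                    return cls(marker,
                               frozenset(int(x) for x in rest.split()))
        raise KeyError(f"marker {marker!r} not in mask file {path}")


class CodonAlignment:
    """Equal-length ACGT sequences read in a fixed frame."""

    def __init__(self, sequences: dict[str, str], marker: str = "",
                 frame_offset: int = 0):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        if frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        for name, seq in sequences.items():
            bad = set(seq) - set(NUCLEOTIDES)
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"{name}: non-ACGT character {seq[pos]!r} at position "
                    f"{pos + 1}")
        self.sequences = dict(sequences)
        self.marker = marker
        self.frame_offset = frame_offset

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def codons(self, name: str) -> list[str]:
        s = self.sequences[name]
        o = self.frame_offset
        return [s[o + 3 * i: o + 3 * i + 3] for i in range(self.n_codons)]

    def subset(self, names) -> "CodonAlignment":
        return CodonAlignment({n: self.sequences[n] for n in names},
                              self.marker, self.frame_offset)

    @classmethod
    def from_fasta(cls, path, marker: str = "",
                   frame_offset: int = 0) -> "CodonAlignment":
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, marker=marker, frame_offset=frame_offset)


def translate_codons(codons: list[str]) -> str:
    return "".join(GENETIC_CODE[c] for c in codons)


def translate_and_screen(aln: CodonAlignment) -> tuple[dict[str, str],
                                                       pd.DataFrame, int]:
    """Translate all sequences and flag premature stop codons.

    These alignments are internal exon fragments, so any in-frame stop is
    premature and marks a putative pseudogene. Returns (translations,
    PSC table, number of unique amino-acid sequences).
    """
    translations = {n: translate_codons(aln.codons(n)) for n in aln.names}
    rows = []
    for name, aa in translations.items():
        stops = [i + 1 for i, c in enumerate(aa) if c == "*"]
        if stops:
            rows.append({"name": name,
                         "stop_codons": ",".join(map(str, stops))})
    psc = pd.DataFrame(rows, columns=["name", "stop_codons"])
    return translations, psc, len(set(translations.values()))


def count_variable_sites(aln: CodonAlignment, level: str = "nt",
                         ) -> tuple[int, int, float]:
    """(variable, total, percent) positions with > 1 distinct state."""
    if len(aln.names) < 2:
        raise ValueError("need >= 2 sequences")
    if level == "nt":
        seqs = list(aln.sequences.values())
    elif level == "aa":
        seqs = [translate_codons(aln.codons(n)) for n in aln.names]
    else:
        raise ValueError("level must be 'nt' or 'aa'")
    total = len(seqs[0])
    variable = sum(1 for col in zip(*seqs) if len(set(col)) > 1)
    return variable, total, 100.0 * variable / total


def pairwise_p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing positions (works for nt or aa strings)."""
    if len(seq_a) != len(seq_b):
        raise ValueError("length mismatch")
    if not seq_a:
        raise ValueError("empty sequences")
    return sum(a != b for a, b in zip(seq_a, seq_b)) / len(seq_a)


def _k2p_from_pq(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"K2P saturation: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions."""
    if len(seq_a) != len(seq_b):
        raise ValueError("length mismatch")
    n = len(seq_a)
    ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    return _k2p_from_pq(ts / n, tv / n)


def poisson_correction(p_aa: float) -> float:
    if p_aa >= 1.0:
        raise ValueError("Poisson correction undefined at p = 1")
    return -math.log(1.0 - p_aa)


def poisson_aa_distance(seq_a: str, seq_b: str) -> float:
    return poisson_correction(pairwise_p_distance(seq_a, seq_b))


def jc_correction(p: float) -> float:
    """Jukes-Cantor multiple-hit correction, d = -3/4 ln(1 - 4p/3)."""
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor saturation at p = {p:.4f}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Potential synonymous sites of a sense codon (0..3).

    Per position, the fraction of the three possible changes that are
    synonymous; changes to stop codons count as nonsynonymous, so the
    per-codon site total is always 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two sense codons.

    Unweighted average over all orderings of the differing positions;
    pathways passing through a stop codon are excluded (if every pathway
    is blocked, the average falls back to all pathways).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            if GENETIC_CODE.get(cur, "*") == GENETIC_CODE.get(nxt, "*") \
                    and nxt not in STOP_CODONS and cur not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    use = results or blocked_results
    sd = sum(r[0] for r in use) / len(use)
    nd = sum(r[1] for r in use) / len(use)
    return sd, nd


@dataclass(frozen=True)
class NGCounts:
    syn_sites: float  # S-bar, averaged over the two sequences
    nonsyn_sites: float  # N-bar
    syn_diffs: float  # Sd
    nonsyn_diffs: float  # Nd
    n_codons_compared: int

    @property
    def pS(self) -> float:
        return self.syn_diffs / self.syn_sites if self.syn_sites else 0.0

    @property
    def pN(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites if self.nonsyn_sites \
            else 0.0

    @property
    def dS(self) -> float:
        return jc_correction(self.pS)

    @property
    def dN(self) -> float:
        return jc_correction(self.pN)


def _codon_contributions(codons_a, codons_b):
    """Per-codon (s_mean, sd, nd, compared) arrays for one sequence pair.

    Codon positions where either sequence carries a stop are excluded
    pairwise (compared = 0).
    """
    n = len(codons_a)
    s_mean = np.zeros(n)
    sd = np.zeros(n)
    nd = np.zeros(n)
    compared = np.zeros(n, dtype=bool)
    for i, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        compared[i] = True
        s_mean[i] = 0.5 * (_syn_fraction(ca) + _syn_fraction(cb))
        sd[i], nd[i] = _pathway_diffs(ca, cb)
    return s_mean, sd, nd, compared


def nei_gojobori_pair(codons_a: list[str], codons_b: list[str]) -> NGCounts:
    """Nei-Gojobori synonymous/nonsynonymous sites and differences."""
    if len(codons_a) != len(codons_b):
        raise ValueError("codon count mismatch")
    if not codons_a:
        raise ValueError("empty codon lists")
    s_mean, sd, nd, compared = _codon_contributions(codons_a, codons_b)
    ncomp = int(compared.sum())
    if ncomp == 0:
        raise ValueError("no comparable (stop-free) codons")
    S = float(s_mean[compared].sum())
    return NGCounts(
        syn_sites=S,
        nonsyn_sites=3.0 * ncomp - S,
        syn_diffs=float(sd[compared].sum()),
        nonsyn_diffs=float(nd[compared].sum()),
        n_codons_compared=ncomp,
    )


@dataclass(frozen=True)
class PairwiseMean:
    statistic: str
    partition: str
    mean: float  # x100 ("per 100 sites") to match conventional tables
    se: float  # bootstrap SE, same scale
    n_pairs: int
    n_units: int  # codons or sites resampled
    n_boot: int


class _PairStat:
    """Per-pair per-unit contributions plus a reducer to the statistic."""

    def __init__(self, contrib: list[dict[str, np.ndarray]], reducer,
                 n_units: int):
        self.contrib = contrib
        self.reducer = reducer
        self.n_units = n_units

    def value(self, idx: np.ndarray) -> float:
        """Mean statistic over pairs for the given unit index sample."""
        vals = [self.reducer(c, idx) for c in self.contrib]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            return math.nan
        return float(np.mean(vals))


def _nt_sites_for_codons(codon_idx: np.ndarray, offset: int) -> np.ndarray:
    return (offset + (3 * codon_idx[:, None]
                      + np.arange(3)[None, :])).ravel()


def _build_pair_stat(aln: CodonAlignment, statistic: str,
                     mask: SiteMask | None, partition: str) -> _PairStat:
    names = aln.names
    if len(names) < 2:
        raise ValueError("need >= 2 sequences")
    if partition != "all" and mask is None:
        raise ValueError("ABS mask required for partitioned statistics")
    codon_idx = (mask.partition_codons(aln.n_codons, partition)
                 if mask is not None
                 else np.arange(aln.n_codons))
    if codon_idx.size == 0:
        raise ValueError(f"partition {partition!r} is empty")
    pairs = list(itertools.combinations(names, 2))

    if statistic in ("dn", "ds"):
        contrib = []
        for a, b in pairs:
            s_mean, sd, nd, compared = _codon_contributions(
                aln.codons(a), aln.codons(b))
            contrib.append({"s": s_mean[codon_idx], "sd": sd[codon_idx],
                            "nd": nd[codon_idx],
                            "ok": compared[codon_idx].astype(float)})

        def reducer(c, idx, which=statistic):
            ncomp = c["ok"][idx].sum()
            if ncomp == 0:
                return math.nan
            S = c["s"][idx].sum()
            N = 3.0 * ncomp - S
            if which == "ds":
                p = c["sd"][idx].sum() / S if S > 0 else 0.0
            else:
                p = c["nd"][idx].sum() / N if N > 0 else 0.0
            if p >= 0.75:
                return math.nan
            return jc_correction(p)

        return _PairStat(contrib, reducer, codon_idx.size)

    if statistic in ("k2p", "p_nt"):
        site_idx = _nt_sites_for_codons(codon_idx, aln.frame_offset)
        arrs = {n: np.frombuffer(aln.sequences[n].encode(), dtype=np.uint8)
                for n in names}
        purine = {n: np.isin(arrs[n], np.frombuffer(b"AG", dtype=np.uint8))
                  for n in names}
        contrib = []
        for a, b in pairs:
            diff = (arrs[a] != arrs[b])[site_idx]
            ts = (diff & (purine[a] == purine[b])[site_idx]).astype(float)
            tv = (diff & (purine[a] != purine[b])[site_idx]).astype(float)
            contrib.append({"ts": ts, "tv": tv, "diff": diff.astype(float)})

        def reducer(c, idx, which=statistic):
            n = idx.size
            if which == "p_nt":
                return float(c["diff"][idx].sum() / n)
            P = c["ts"][idx].sum() / n
            Q = c["tv"][idx].sum() / n
            try:
                return _k2p_from_pq(P, Q)
            except ValueError:
                return math.nan

        return _PairStat(contrib, reducer, site_idx.size)

    if statistic in ("poisson_aa", "p_aa"):
        aas = {n: translate_codons(aln.codons(n)) for n in names}
        contrib = []
        for a, b in pairs:
            xa = np.frombuffer(aas[a].encode(), dtype=np.uint8)[codon_idx]
            xb = np.frombuffer(aas[b].encode(), dtype=np.uint8)[codon_idx]
            stop = ord("*")
            ok = (xa != stop) & (xb != stop)
            contrib.append({"diff": ((xa != xb) & ok).astype(float),
                            "ok": ok.astype(float)})

        def reducer(c, idx, which=statistic):
            n = c["ok"][idx].sum()
            if n == 0:
                return math.nan
            p = c["diff"][idx].sum() / n
            if which == "p_aa":
                return float(p)
            if p >= 1.0:
                return math.nan
            return -math.log(1.0 - p)

        return _PairStat(contrib, reducer, codon_idx.size)

    raise ValueError(f"unknown statistic {statistic!r}")


def _bootstrap_means(stat: _PairStat, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    n = stat.n_units
    out = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out[r] = stat.value(idx)
    return out


def mean_pairwise(aln: CodonAlignment, statistic: str,
                  mask: SiteMask | None = None, partition: str = "all",
                  n_boot: int = 1000, seed: int = 0) -> PairwiseMean:
    """Mean of a pairwise statistic over all unordered pairs, x100.

    The bootstrap SE resamples alignment columns — codons for codon-based
    statistics (dN, dS, amino-acid distances), nucleotide sites for
    nucleotide distances — keeping the pair structure intact.
    """
    stat = _build_pair_stat(aln, statistic, mask, partition)
    full = stat.value(np.arange(stat.n_units))
    if math.isnan(full):
        raise ValueError(f"statistic {statistic!r} saturated on these data")
    rng = np.random.default_rng(seed)
    boots = _bootstrap_means(stat, n_boot, rng)
    valid = boots[~np.isnan(boots)]
    if valid.size < n_boot:
        warnings.warn(
            f"{n_boot - valid.size} of {n_boot} bootstrap replicates "
            f"saturated and were dropped")
    se = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return PairwiseMean(statistic=statistic, partition=partition,
                        mean=100.0 * full, se=100.0 * se,
                        n_pairs=len(stat.contrib), n_units=stat.n_units,
                        n_boot=n_boot)


@dataclass(frozen=True)
class SelectionTest:
    partition: str
    mean_dn: float  # x100
    se_dn: float
    mean_ds: float  # x100
    se_ds: float
    z: float
    p_one_tailed: float
    n_boot: int


def z_test_selection(aln: CodonAlignment, mask: SiteMask | None = None,
                     partition: str = "all", n_boot: int = 1000,
                     seed: int = 0,
                     variance: str = "difference") -> SelectionTest:
    """One-tailed Z test of dN > dS with a codon-column bootstrap.

    Z = (mean_dN - mean_dS) / SE, where SE is the bootstrap standard
    error of the difference (codon columns resampled jointly for dN and
    dS; ``variance="sum"`` instead combines the two marginal variances).
    p = 1 - Phi(Z) for the alternative dN > dS.
    """
    if variance not in ("difference", "sum"):
        raise ValueError("variance must be 'difference' or 'sum'")
    stat_dn = _build_pair_stat(aln, "dn", mask, partition)
    stat_ds = _build_pair_stat(aln, "ds", mask, partition)
    n = stat_dn.n_units
    full_idx = np.arange(n)
    dn0 = stat_dn.value(full_idx)
    ds0 = stat_ds.value(full_idx)
    rng = np.random.default_rng(seed)
    dn_b = np.empty(n_boot)
    ds_b = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        dn_b[r] = stat_dn.value(idx)
        ds_b[r] = stat_ds.value(idx)
    ok = ~(np.isnan(dn_b) | np.isnan(ds_b))
    dn_v, ds_v = dn_b[ok], ds_b[ok]
    if ok.sum() < n_boot:
        warnings.warn(f"{n_boot - int(ok.sum())} bootstrap replicates "
                      "saturated and were dropped")
    se_dn = float(dn_v.std(ddof=1)) if dn_v.size > 1 else 0.0
    se_ds = float(ds_v.std(ddof=1)) if ds_v.size > 1 else 0.0
    if variance == "difference":
        se_diff = float((dn_v - ds_v).std(ddof=1)) if dn_v.size > 1 else 0.0
    else:
        se_diff = math.sqrt(se_dn ** 2 + se_ds ** 2)
    diff = dn0 - ds0
    if se_diff == 0.0:
        if diff == 0.0:
            z, p = 0.0, 0.5
        else:
            warnings.warn("zero bootstrap variance with nonzero dN - dS; "
                          f"p reported as < 1/{n_boot}")
            z = math.inf if diff > 0 else -math.inf
            p = 1.0 / n_boot if diff > 0 else 1.0
    else:
        z = diff / se_diff
        p = float(stats.norm.sf(z))
    return SelectionTest(partition=partition,
                         mean_dn=100.0 * dn0, se_dn=100.0 * se_dn,
                         mean_ds=100.0 * ds0, se_ds=100.0 * se_ds,
                         z=z, p_one_tailed=p, n_boot=n_boot)


def pss_abs_enrichment(pss_codons, mask: SiteMask, n_codons: int) -> float:
    """One-tailed p for over-representation of PSS within ABS.

    Hypergeometric tail of the 2x2 table (PSS / non-PSS x ABS / non-ABS):
    the probability of drawing at least the observed number of ABS codons
    when |PSS| codons are drawn without replacement from the alignment.
    """
    mask.validate(n_codons)
    pss = frozenset(pss_codons)
    if not pss <= set(range(1, n_codons + 1)):
        raise ValueError("PSS codons out of alignment range")
    k = len(pss & mask.abs_codons)
    return float(stats.hypergeom.sf(k - 1, n_codons, len(mask.abs_codons),
                                    len(pss)))


def selection_table(aln: CodonAlignment, mask: SiteMask | None,
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """dN/dS means, SEs, Z and p for all sites and ABS partitions."""
    partitions = ["all"] + (["abs", "non_abs"] if mask is not None else [])
    rows = []
    for part in partitions:
        t = z_test_selection(aln, mask, part, n_boot=n_boot, seed=seed)
        rows.append({"partition": part, "mean_dN": t.mean_dn,
                     "se_dN": t.se_dn, "mean_dS": t.mean_ds,
                     "se_dS": t.se_ds, "Z": t.z, "p": t.p_one_tailed})
    return pd.DataFrame(rows)


def distance_table(aln: CodonAlignment, mask: SiteMask | None,
                   n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Mean K2P nucleotide and Poisson amino-acid distances by partition."""
    partitions = ["all"] + (["abs", "non_abs"] if mask is not None else [])
    rows = []
    for part in partitions:
        k = mean_pairwise(aln, "k2p", mask, part, n_boot=n_boot, seed=seed)
        p = mean_pairwise(aln, "poisson_aa", mask, part, n_boot=n_boot,
                          seed=seed)
        rows.append({"partition": part, "mean_K2P": k.mean, "se_K2P": k.se,
                     "mean_poisson_aa": p.mean, "se_poisson_aa": p.se})
    return pd.DataFrame(rows)
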