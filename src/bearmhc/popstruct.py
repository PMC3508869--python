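"""Population differentiation from presence/absence MHC genotypes.

When sequence variants cannot be assigned to loci, each allele is treated
as a dominant marker: one binary locus per allele, scored 1 when the
individual carries the sequence. Pairwise FST between two populations is
then the AMOVA fixation index computed from variance components of
inter-individual distances, with the distance between two binary profiles
the number of differing loci (squared Euclidean on 0/1 data).

Two independent computation routes are provided: ``amova_fst`` works from
the explicit individual-level matrix via pairwise distances, while
``fst_from_marginals`` reconstructs the same decomposition from per-locus
presence counts alone — valid because multilocus Hamming distances are
sums of per-locus indicators, so all pair-distance sums reduce to
k(n - k)-type terms. The two agree exactly on any matrix, which serves as
a built-in cross-check, and the marginal route lets published
per-population presence percentages be used directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeTable

__all__ = [
    "BinaryGenotypeMatrix",
    "FstResult",
    "binary_encode",
    "amova_fst",
    "fst_from_marginals",
    "permutation_test",
]

log = logging.getLogger(__name__)


@dataclass
class BinaryGenotypeMatrix:
    """Individuals x alleles 0/1 matrix with a population label per row."""

    matrix: pd.DataFrame
    population: pd.Series

    def __post_init__(self):
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate individual ids")
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self.population = self.population.reindex(self.matrix.index)

    def rows_for(self, pop: str) -> np.ndarray:
        sel = self.population == pop
        if sel.sum() == 0:
            raise ValueError(f"no individuals in population {pop!r}")
        return self.matrix.loc[sel].to_numpy(dtype=np.int8)


@dataclass(frozen=True)
class FstResult:
    fst: float | None  # None when total variance is zero
    sigma2_among: float
    sigma2_within: float
    p_value: float | None = None
    n_permutations: int = 0


def binary_encode(table: GenotypeTable) -> BinaryGenotypeMatrix:
    """One dominant binary locus per named allele, columns in allele order."""
    if not table.individuals:
        raise ValueError("empty genotype table")
    return BinaryGenotypeMatrix(table.presence.copy(), table.population.copy())


def _variance_components(within_a: float, within_b: float, between: float,
                         n_a: int, n_b: int) -> FstResult:
    """AMOVA decomposition from pair-distance sums.

    ``within_p`` = sum of distances over pairs inside population p,
    ``between`` = sum over cross-population pairs.
    """
    N = n_a + n_b
    ssd_total = (within_a + within_b + between) / N
    ssd_within = within_a / n_a + within_b / n_b
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / (N - 2)
    n_bar = (N - (n_a ** 2 + n_b ** 2) / N)  # / (P - 1) with P = 2
    sigma2_a = (ssd_among - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    if denom == 0:
        log.warning("zero total variance; FST undefined")
        return FstResult(fst=None, sigma2_among=sigma2_a,
                         sigma2_within=sigma2_w)
    return FstResult(fst=sigma2_a / denom, sigma2_among=sigma2_a,
                     sigma2_within=sigma2_w)


def _pair_sums(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float, float]:
    """Within/within/between pair-distance sums from 0/1 matrices."""
    # distance = Hamming over loci; sum over pairs via per-locus counts
    ka = xa.sum(axis=0).astype(float)
    kb = xb.sum(axis=0).astype(float)
    na, nb = xa.shape[0], xb.shape[0]
    within_a = float((ka * (na - ka)).sum())
    within_b = float((kb * (nb - kb)).sum())
    between = float((ka * (nb - kb) + kb * (na - ka)).sum())
    return within_a, within_b, between


def amova_fst(matrix: BinaryGenotypeMatrix, pop_a: str, pop_b: str,
              ) -> FstResult:
    """Pairwise AMOVA FST from the explicit distance matrix.

    Distances are computed between all individual profiles; negative
    estimates are reported as computed, as is standard AMOVA practice.
    """
    xa = matrix.rows_for(pop_a)
    xb = matrix.rows_for(pop_b)
    if xa.shape[0] < 2 or xb.shape[0] < 2:
        raise ValueError("both populations need >= 2 individuals")
    x = np.vstack([xa, xb]).astype(np.int16)
    # pairwise Hamming: for 0/1 data, d = |x_i - x_j| summed over loci
    d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2).astype(float)
    na = xa.shape[0]
    iu = np.triu_indices(na, k=1)
    within_a = float(d[:na, :na][iu].sum())
    nb = xb.shape[0]
    iub = np.triu_indices(nb, k=1)
    within_b = float(d[na:, na:][iub].sum())
    between = float(d[:na, na:].sum())
    return _variance_components(within_a, within_b, between, na, nb)


def fst_from_marginals(percentages: pd.DataFrame, pop_sizes: tuple[int, int],
                       ) -> FstResult:
    """AMOVA FST reconstructed from per-population presence percentages.

    ``percentages`` has one row per allele and two columns (population A
    and B percentages in [0, 100]); ``pop_sizes`` gives the sample sizes.
    Counts are recovered by round-half-up of pct * n / 100, so integer
    published percentages carry a reconstruction error of at most half an
    individual per cell. No permutation p-value is available in this mode
    because individual profiles are unknown.
    """
    if percentages.shape[1] != 2:
        raise ValueError("need exactly two percentage columns")
    n_a, n_b = pop_sizes
    if n_a < 2 or n_b < 2:
        raise ValueError("population sizes must be >= 2")
    pcts = percentages.to_numpy(dtype=float)
    if (pcts < 0).any() or (pcts > 100).any():
        raise ValueError("percentages must lie in [0, 100]")
    ka = np.floor(pcts[:, 0] * n_a / 100.0 + 0.5)
    kb = np.floor(pcts[:, 1] * n_b / 100.0 + 0.5)
    within_a = float((ka * (n_a - ka)).sum())
    within_b = float((kb * (n_b - kb)).sum())
    between = float((ka * (n_b - kb) + kb * (n_a - ka)).sum())
    return _variance_components(within_a, within_b, between, n_a, n_b)


def permutation_test(matrix: BinaryGenotypeMatrix, pop_a: str, pop_b: str,
                     n_perm: int = 9999, seed: int = 0) -> FstResult:
    """Permutation p-value for FST under random label reassignment.

    Individuals are reshuffled between the two populations preserving
    sizes; p = (1 + #{FST_perm >= FST_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = amova_fst(matrix, pop_a, pop_b)
    if obs.fst is None:
        return obs
    xa = matrix.rows_for(pop_a)
    xb = matrix.rows_for(pop_b)
    x = np.vstack([xa, xb])
    na = xa.shape[0]
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[0])
        pa = x[perm[:na]]
        pb = x[perm[na:]]
        w_a, w_b, btw = _pair_sums(pa, pb)
        res = _variance_components(w_a, w_b, btw, pa.shape[0], pb.shape[0])
        if res.fst is not None and res.fst >= obs.fst - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (n_perm + 1)
    return FstResult(fst=obs.fst, sigma2_among=obs.sigma2_among,
                     sigma2_within=obs.sigma2_within, p_value=p,
                     n_permutations=n_perm)
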