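"""Expression calls and minimum locus counts from gDNA/cDNA genotype tables.

Comparing genotypes of the same individuals typed from genomic DNA and
from cDNA classifies each allele as expressed (seen in cDNA), not
expressed (seen in gDNA of assayed individuals, never in cDNA) or
unassayed (absent from the assayed panel). Under diploidy, the number of
loci needed to accommodate k co-occurring alleles in one individual is at
least ceil(k/2), giving conservative minimum locus counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .genotyping import GenotypeTable

__all__ = ["ExpressionCall", "classify_expression", "min_locus_counts"]

log = logging.getLogger(__name__)

EXPRESSED = "expressed"
NOT_EXPRESSED = "not_expressed"
UNASSAYED = "unassayed"


@dataclass(frozen=True)
class ExpressionCall:
    allele: str
    seen_gdna: bool
    seen_cdna: bool
    status: str


def classify_expression(gdna_table: GenotypeTable,
                        cdna_table: GenotypeTable) -> list[ExpressionCall]:
    """Per-allele expression status over the cDNA-assayed panel.

    The assayed panel is the set of individuals present in both tables;
    a disjoint panel is an error. An allele observed in cDNA of an
    individual whose gDNA lacks it indicates possible gDNA dropout and is
    logged as a warning, not an error.
    """
    assayed = [i for i in cdna_table.individuals
               if i in set(gdna_table.individuals)]
    if not assayed:
        raise ValueError("gDNA and cDNA tables share no individuals")
    alleles = list(gdna_table.alleles)
    for a in cdna_table.alleles:
        if a not in alleles:
            alleles.append(a)
    g = gdna_table.presence.reindex(index=assayed, columns=alleles,
                                    fill_value=0)
    c = cdna_table.presence.reindex(index=assayed, columns=alleles,
                                    fill_value=0)
    dropout = (c > g)
    for ind in assayed:
        bad = dropout.loc[ind]
        for allele in bad.index[bad]:
            log.warning("allele %s seen in cDNA but not gDNA of %s "
                        "(possible gDNA dropout)", allele, ind)
    calls = []
    for allele in alleles:
        seen_g = bool(g[allele].any())
        seen_c = bool(c[allele].any())
        if seen_c:
            status = EXPRESSED
        elif seen_g:
            status = NOT_EXPRESSED
        else:
            status = UNASSAYED
        calls.append(ExpressionCall(allele, seen_g, seen_c, status))
    return calls


def expression_frame(calls: list[ExpressionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "allele": [c.allele for c in calls],
            "seen_gdna": [int(c.seen_gdna) for c in calls],
            "seen_cdna": [int(c.seen_cdna) for c in calls],
            "status": [c.status for c in calls],
        }
    )


def min_locus_counts(gdna_table: GenotypeTable,
                     cdna_table: GenotypeTable | None = None,
                     ) -> tuple[int, int | None]:
    """(min_total_loci, min_expressed_loci) under diploidy.

    min_total_loci = ceil(max gDNA allele count over all individuals / 2);
    min_expressed_loci uses the cDNA table over its assayed individuals
    (None when no cDNA table is given).
    """
    if not gdna_table.individuals:
        raise ValueError("empty gDNA table")
    max_g = int(gdna_table.allele_counts().max())
    min_total = math.ceil(max_g / 2)
    min_expressed = None
    if cdna_table is not None and cdna_table.individuals:
        max_c = int(cdna_table.allele_counts().max())
        min_expressed = math.ceil(max_c / 2)
    return min_total, min_expressed
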