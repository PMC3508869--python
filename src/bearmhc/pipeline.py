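"""End-to-end orchestration: reads -> variants -> alleles -> tables.

Thin glue over the stage modules so that the CLI, the analysis scripts
and the tests all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import genotyping as gt
from .genotyping import (Amplicon, ClassificationThresholds, GenotypeTable,
                         VariantRecord)
from .simdata import AlleleSequence

__all__ = [
    "read_fasta_reads",
    "read_tag_map",
    "ValidationResult",
    "validate_amplicons",
    "variants_frame",
    "write_alleles_fasta",
]


def read_fasta_reads(path) -> list[gt.TaggedRead]:
    reads = [gt.TaggedRead(rec.id, str(rec.seq).upper())
             for rec in SeqIO.parse(str(path), "fasta")]
    if not reads:
        raise ValueError(f"no reads in {path}")
    return reads


def read_tag_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = {"amplicon_id", "tag", "individual", "marker", "template",
                "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tag map {path} lacks columns {sorted(missing)}")
    return df


@dataclass
class ValidationResult:
    variants: list[VariantRecord]
    review: pd.DataFrame
    alleles: list[AlleleSequence]
    genotypes: GenotypeTable


def validate_amplicons(amplicons: list[Amplicon],
                       thresholds: ClassificationThresholds,
                       marker: str, species_prefix: str,
                       population_of: dict[str, str] | None = None,
                       decisions: dict[str, str] | None = None,
                       ) -> ValidationResult:
    """Tally -> classify -> chimera screen -> grey zone -> name -> call."""
    variants = gt.tally_variants(amplicons)
    variants = gt.classify_variants(variants, thresholds)
    gt.detect_chimeras(variants, amplicons)
    variants, review = gt.resolve_grey_zone(variants, amplicons,
                                            decisions=decisions)
    alleles = gt.name_alleles(variants, amplicons, marker, species_prefix)
    genotypes = gt.call_genotypes(amplicons, alleles, population_of)
    return ValidationResult(variants, review, alleles, genotypes)


def variants_frame(variants) -> pd.DataFrame:
    rows = []
    for v in variants:
        flag = v.chimera_flag
        rows.append({
            "sequence": v.sequence,
            "mpaf": v.mpaf,
            "n_amplicons": v.n_amplicons,
            "total_reads": v.total_reads,
            "classification": v.classification,
            "chimera": int(flag is not None),
            "chimera_parents": (f"{flag.parent1[:12]}..|{flag.parent2[:12]}.."
                                if flag else "."),
            "crossover": (f"{flag.crossover[0]}-{flag.crossover[1]}"
                          if flag else "."),
            "note": v.note or ".",
        })
    return pd.DataFrame(rows)


def write_alleles_fasta(alleles, path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f">{a.name}\n")
            for i in range(0, len(a.sequence), 70):
                fh.write(a.sequence[i:i + 70] + "\n")
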