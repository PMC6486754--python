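"""Variant-retention rules applied before multiplicity calling.

Two filters are composed (they commute):

* **low-VAF rescue** — single-caller variants with a variant allele
  fraction below a threshold (default 0.05) are likely false positives
  and are dropped unless a second, independent caller (default
  ``mutect2``) also reported them;
* **functional selection** — keep protein-altering variants in the
  configured gene panel (PIK3CA plus the proximal PI3K-pathway genes
  PTEN, PIK3R1, AKT1/2/3 by default) with adequate read depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .errors import DataError
from .formats_io import VariantRecord

logger = logging.getLogger(__name__)

#: Protein-altering consequence classes retained by default. The MAF's
#: Variant_Classification vocabulary already encodes functional impact,
#: so no external annotator is needed.
DEFAULT_CLASS_WHITELIST = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Known (non-retained) consequence classes; anything else triggers an
#: unknown-class warning.
KNOWN_CLASSES = DEFAULT_CLASS_WHITELIST | {
    "Silent",
    "Intron",
    "IGR",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "RNA",
}

DEFAULT_GENE_PANEL = frozenset({"PIK3CA", "PTEN", "PIK3R1", "AKT1", "AKT2", "AKT3"})

SEX_CHROMOSOMES = frozenset({"X", "Y"})


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the retention rules.

    ``vaf_rescue_threshold`` — VAF below which a variant needs
    corroboration by ``rescue_caller`` to survive. ``min_depth`` guards
    against multiplicity estimates from uninformative read counts.
    Variants on X/Y are excluded by default because the dosage model
    fixes the normal copy number at 2 (autosomes).
    """

    vaf_rescue_threshold: float = 0.05
    rescue_caller: str = "mutect2"
    class_whitelist: frozenset[str] = DEFAULT_CLASS_WHITELIST
    gene_panel: frozenset[str] = DEFAULT_GENE_PANEL
    min_depth: int = 10
    exclude_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.vaf_rescue_threshold < 1.0):
            raise DataError(
                f"vaf_rescue_threshold must lie in (0,1), got {self.vaf_rescue_threshold}"
            )
        if not self.gene_panel:
            raise DataError("gene_panel must be non-empty")


class Rejection(NamedTuple):
    """One rejected variant and the clause that dropped it."""

    sample_id: str
    gene: str
    pos: int
    reason: str


def compute_vaf(v: VariantRecord) -> float:
    """Variant allele fraction ``t_alt_count / t_depth``."""
    if v.t_depth <= 0:
        raise DataError(
            f"VAF undefined at zero depth ({v.sample_id} {v.gene}:{v.pos})"
        )
    return v.t_alt_count / v.t_depth


def rescue_filter(
    variants: Sequence[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Drop low-VAF variants lacking corroboration by the rescue caller.

    A variant is retained iff ``VAF >= vaf_rescue_threshold`` or
    ``rescue_caller in callers``.
    """
    kept: list[VariantRecord] = []
    rejected: list[Rejection] = []
    for v in variants:
        if compute_vaf(v) >= cfg.vaf_rescue_threshold or cfg.rescue_caller in v.callers:
            kept.append(v)
        else:
            rejected.append(
                Rejection(
                    v.sample_id,
                    v.gene,
                    v.pos,
                    f"low_vaf_single_caller(vaf<{cfg.vaf_rescue_threshold:g},"
                    f"no {cfg.rescue_caller})",
                )
            )
    return kept, rejected


def functional_filter(
    variants: Sequence[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Keep panel-gene, protein-altering variants with adequate depth."""
    kept: list[VariantRecord] = []
    rejected: list[Rejection] = []
    for v in variants:
        if v.variant_class not in KNOWN_CLASSES:
            logger.warning(
                "unknown variant class %r (%s %s:%d); treated as non-protein-altering",
                v.variant_class,
                v.sample_id,
                v.gene,
                v.pos,
            )
        if v.gene not in cfg.gene_panel:
            rejected.append(Rejection(v.sample_id, v.gene, v.pos, "gene_not_in_panel"))
        elif v.variant_class not in cfg.class_whitelist:
            rejected.append(
                Rejection(v.sample_id, v.gene, v.pos, "non_protein_altering_class")
            )
        elif v.t_depth < cfg.min_depth:
            rejected.append(
                Rejection(v.sample_id, v.gene, v.pos, f"depth<{cfg.min_depth}")
            )
        elif cfg.exclude_sex_chromosomes and v.chrom in SEX_CHROMOSOMES:
            rejected.append(Rejection(v.sample_id, v.gene, v.pos, "sex_chromosome"))
        else:
            kept.append(v)
    return kept, rejected


def apply_filters(
    variants: Sequence[VariantRecord], cfg: FilterConfig
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Rescue then functional filtering; rejections from both stages."""
    after_rescue, rej1 = rescue_filter(variants, cfg)
    kept, rej2 = functional_filter(after_rescue, cfg)
    return kept, rej1 + rej2
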