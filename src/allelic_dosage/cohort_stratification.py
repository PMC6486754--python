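"""Cohort-level stratification of mutant samples by allelic dosage.

Aggregates per-variant multiplicity calls into per-cancer-type and
pooled quantities: prevalence of oncogene mutation, the fraction of
mutant samples with multiple mutant alleles (allelic imbalance, WT loss
included), and the fraction with a "second hit" — either a second
distinct oncogene variant or a protein-altering co-mutation in a
proximal pathway gene.

The sample universe is the purity table, so mutation-negative samples
count in prevalence denominators. Pooled ("AGGREGATE") fractions are
computed from pooled counts, never by averaging per-type fractions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dosage_model import CallFlag, is_dosage_imbalanced
from .errors import DataError
from .formats_io import SamplePurity

logger = logging.getLogger(__name__)

AGGREGATE = "AGGREGATE"

DEFAULT_ONCOGENE = "PIK3CA"
DEFAULT_PATHWAY_GENES = frozenset({"PTEN", "PIK3R1", "AKT1", "AKT2", "AKT3"})

#: Study labels used for real-data runs (shipped as default config).
DEFAULT_CANCER_TYPES = (
    "BLCA", "BRCA", "CESC", "CRC", "ESCA", "GBM",
    "HNSC", "LUSC", "STAD", "UCEC", "UCS",
)

SUMMARY_COLUMNS = (
    "cancer_type",
    "n_samples",
    "n_mut_samples",
    "prevalence",
    "n_dosage_assessable",
    "n_multi_allele",
    "frac_multi_allele",
    "n_second_hit",
    "frac_second_hit",
)

_DROP_FLAGS = {CallFlag.NO_SEGMENT.value, CallFlag.INCONSISTENT.value}


def _call_flags(value: object) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {f for f in str(value).split(";") if f}


def flag_second_hits(
    calls: pd.DataFrame,
    oncogene: str = DEFAULT_ONCOGENE,
    pathway_genes: Iterable[str] = DEFAULT_PATHWAY_GENES,
) -> pd.DataFrame:
    """Per-sample second-hit status over retained calls.

    A sample is flagged when it carries at least two distinct
    (position, alt allele) variants of the oncogene, or at least one
    retained variant in the pathway gene set. Returns a frame with
    columns ``sample, second_hit, reason``.
    """
    pathway = set(pathway_genes)
    rows = []
    for sample, grp in calls.groupby("sample", sort=True):
        onc = grp[grp["gene"] == oncogene]
        distinct = set(zip(onc["pos"], onc["alt_allele"]))
        has_multiple = len(distinct) >= 2
        has_pathway = bool(grp["gene"].isin(pathway).any())
        if has_multiple and has_pathway:
            reason = "distinct_oncogene_variants+pathway_comutation"
        elif has_multiple:
            reason = "distinct_oncogene_variants"
        elif has_pathway:
            reason = "pathway_comutation"
        else:
            reason = ""
        rows.append(
            {"sample": sample, "second_hit": has_multiple or has_pathway, "reason": reason}
        )
    return pd.DataFrame(rows, columns=["sample", "second_hit", "reason"])


def summarize_cohort(
    calls: pd.DataFrame,
    purities: Mapping[str, SamplePurity],
    oncogene: str = DEFAULT_ONCOGENE,
    pathway_genes: Iterable[str] = DEFAULT_PATHWAY_GENES,
    exclude_low_confidence: bool = False,
) -> pd.DataFrame:
    """Build the per-type + pooled dosage/co-hit summary table.

    ``calls`` must contain one row per retained variant with at least
    ``sample, gene, pos, alt_allele, m_star, wt_copies, flags`` — rows
    whose dosage could not be assessed (no covering segment, or zero
    tumor copy number at a mutated locus) carry a missing ``m_star``
    plus the corresponding flag. Such samples still count as mutant for
    prevalence but are excluded from the multi-allele denominator
    (``n_dosage_assessable``), where dosage is genuinely unassessable.

    Every call's sample must appear in the purity table, which defines
    the sample universe (and hence prevalence denominators).
    """
    missing = set(calls["sample"]) - set(purities)
    if missing:
        raise DataError(
            f"calls reference samples absent from the purity table: "
            f"{sorted(missing)[:5]}"
        )

    onc_calls = calls[calls["gene"] == oncogene]
    second = flag_second_hits(calls, oncogene, pathway_genes)
    second_by_sample = dict(zip(second["sample"], second["second_hit"]))

    mut_samples: dict[str, bool] = {}       # sample -> has >=1 oncogene variant
    assessable: dict[str, bool] = {}        # sample -> >=1 dosage-assessable call
    imbalanced: dict[str, bool] = {}        # sample -> >=1 imbalanced call
    for sample, grp in onc_calls.groupby("sample"):
        mut_samples[sample] = True
        ok = grp[grp["m_star"].notna()].copy()
        if exclude_low_confidence and len(ok):
            ok = ok[~ok["flags"].map(lambda f: CallFlag.LOW_CONFIDENCE.value in _call_flags(f))]
        assessable[sample] = len(ok) > 0
        imbalanced[sample] = bool(
            any(
                is_dosage_imbalanced(int(m), int(w))
                for m, w in zip(ok["m_star"], ok["wt_copies"])
            )
        )

    types = sorted({p.cancer_type for p in purities.values()})
    rows = []
    for ctype in types:
        samples = [s for s, p in purities.items() if p.cancer_type == ctype]
        n = len(samples)
        mut = [s for s in samples if mut_samples.get(s, False)]
        n_mut = len(mut)
        n_assessable = sum(assessable.get(s, False) for s in mut)
        n_multi = sum(imbalanced.get(s, False) for s in mut)
        n_second = sum(bool(second_by_sample.get(s, False)) for s in mut)
        rows.append(
            {
                "cancer_type": ctype,
                "n_samples": n,
                "n_mut_samples": n_mut,
                "prevalence": n_mut / n if n else np.nan,
                "n_dosage_assessable": n_assessable,
                "n_multi_allele": n_multi,
                "frac_multi_allele": n_multi / n_assessable if n_assessable else np.nan,
                "n_second_hit": n_second,
                "frac_second_hit": n_second / n_mut if n_mut else np.nan,
            }
        )

    pooled = {
        "cancer_type": AGGREGATE,
        "n_samples": sum(r["n_samples"] for r in rows),
        "n_mut_samples": sum(r["n_mut_samples"] for r in rows),
        "n_dosage_assessable": sum(r["n_dosage_assessable"] for r in rows),
        "n_multi_allele": sum(r["n_multi_allele"] for r in rows),
        "n_second_hit": sum(r["n_second_hit"] for r in rows),
    }
    pooled["prevalence"] = (
        pooled["n_mut_samples"] / pooled["n_samples"] if pooled["n_samples"] else np.nan
    )
    pooled["frac_multi_allele"] = (
        pooled["n_multi_allele"] / pooled["n_dosage_assessable"]
        if pooled["n_dosage_assessable"]
        else np.nan
    )
    pooled["frac_second_hit"] = (
        pooled["n_second_hit"] / pooled["n_mut_samples"]
        if pooled["n_mut_samples"]
        else np.nan
    )
    rows.append(pooled)
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def select_cancer_types(summary: pd.DataFrame, min_prevalence: float = 0.10) -> pd.DataFrame:
    """Retain strata whose mutation prevalence strictly exceeds a floor.

    The AGGREGATE row is recomputed from the retained strata's counts
    (if none remain it has zero counts and NA fractions).
    """
    if summary.empty:
        return summary
    strata = summary[summary["cancer_type"] != AGGREGATE]
    kept = strata[strata["prevalence"] > min_prevalence].reset_index(drop=True)
    pooled = {
        "cancer_type": AGGREGATE,
        "n_samples": int(kept["n_samples"].sum()),
        "n_mut_samples": int(kept["n_mut_samples"].sum()),
        "n_dosage_assessable": int(kept["n_dosage_assessable"].sum()),
        "n_multi_allele": int(kept["n_multi_allele"].sum()),
        "n_second_hit": int(kept["n_second_hit"].sum()),
    }
    pooled["prevalence"] = (
        pooled["n_mut_samples"] / pooled["n_samples"] if pooled["n_samples"] else np.nan
    )
    pooled["frac_multi_allele"] = (
        pooled["n_multi_allele"] / pooled["n_dosage_assessable"]
        if pooled["n_dosage_assessable"]
        else np.nan
    )
    pooled["frac_second_hit"] = (
        pooled["n_second_hit"] / pooled["n_mut_samples"]
        if pooled["n_mut_samples"]
        else np.nan
    )
    out = pd.concat([kept, pd.DataFrame([pooled])], ignore_index=True)
    return out.reindex(columns=list(SUMMARY_COLUMNS))
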