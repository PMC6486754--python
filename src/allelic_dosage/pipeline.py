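"""End-to-end orchestration: read → filter → locate → estimate → classify.

The chain consumes parsed variants, segments and purities and emits the
per-variant calls table consumed by :mod:`.cohort_stratification`. The
CLI wraps these functions; they are equally usable from Python.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

from .dosage_model import (
    CallFlag,
    DEFAULT_LLR_LOW_CONFIDENCE,
    LocusContext,
    SegmentIndex,
    call_variant,
    locate_segment,
)
from .errors import ConfigError, DataError
from .formats_io import (
    CALLS_COLUMNS,
    SamplePurity,
    SegmentRecord,
    VariantRecord,
)
from .variant_filtering import FilterConfig, Rejection, functional_filter, rescue_filter

logger = logging.getLogger(__name__)

NO_SEGMENT_POLICIES = ("drop", "assume_diploid")


def call_multiplicities(
    variants: Sequence[VariantRecord],
    segments: Sequence[SegmentRecord],
    purities: Mapping[str, SamplePurity],
    filter_cfg: FilterConfig | None = None,
    llr_low_confidence: float = DEFAULT_LLR_LOW_CONFIDENCE,
    no_segment_policy: str = "drop",
) -> tuple[pd.DataFrame, list[Rejection], dict[str, int]]:
    """Run filtering and multiplicity calling over a cohort.

    Returns ``(calls, rejections, stage_counts)``. Calls include rows
    for retained variants whose dosage could not be assessed (no
    covering copy-number segment under the ``drop`` policy, or zero
    tumor copies at a mutated locus — flagged ``INCONSISTENT``); those
    rows carry missing estimates but keep the sample countable as
    mutant. With ``no_segment_policy="assume_diploid"`` uncovered loci
    are treated as CN 2 (1+1), flagged ``NO_SEGMENT``.

    Every retained variant's sample must appear in the purity table.
    """
    if no_segment_policy not in NO_SEGMENT_POLICIES:
        raise ConfigError(
            f"no_segment_policy must be one of {NO_SEGMENT_POLICIES}, "
            f"got {no_segment_policy!r}"
        )
    cfg = filter_cfg or FilterConfig()
    after_rescue, rej1 = rescue_filter(variants, cfg)
    retained, rej2 = functional_filter(after_rescue, cfg)
    rejections = rej1 + rej2

    missing = sorted({v.sample_id for v in retained} - set(purities))
    if missing:
        raise DataError(
            f"purity table lacks {len(missing)} mutated sample(s), e.g. {missing[:5]}"
        )

    index = SegmentIndex(segments)
    rows: list[dict] = []
    counts = {
        "n_input": len(variants),
        "n_after_rescue": len(after_rescue),
        "n_retained": len(retained),
        "n_called": 0,
        "n_no_segment": 0,
        "n_inconsistent": 0,
    }
    for v in retained:
        purity = purities[v.sample_id].purity
        ctx, loc_flags = locate_segment(v, index, purity)
        row = {
            "sample": v.sample_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref_allele": v.ref_allele,
            "alt_allele": v.alt_allele,
            "variant_class": v.variant_class,
            "t_alt_count": v.t_alt_count,
            "t_depth": v.t_depth,
            "vaf": v.t_alt_count / v.t_depth,
            "purity": purity,
            "cn_total": None,
            "cn_minor": None,
            "m_hat": None,
            "m_star": None,
            "llr": None,
            "wt_copies": None,
            "config_class": "",
            "flags": "",
        }
        if ctx is None:
            if no_segment_policy == "assume_diploid":
                ctx = LocusContext(purity=purity, tumor_total_cn=2, tumor_minor_cn=1)
                loc_flags = frozenset({CallFlag.NO_SEGMENT})
            else:
                counts["n_no_segment"] += 1
                row["flags"] = CallFlag.NO_SEGMENT.value
                rows.append(row)
                continue
        if ctx.tumor_total_cn == 0:
            # a mutation cannot sit on zero tumor copies
            counts["n_inconsistent"] += 1
            row["flags"] = CallFlag.INCONSISTENT.value
            rows.append(row)
            continue
        call = call_variant(v, ctx, llr_low_confidence, extra_flags=loc_flags)
        counts["n_called"] += 1
        row.update(
            cn_total=ctx.tumor_total_cn,
            cn_minor=ctx.tumor_minor_cn,
            m_hat=call.m_hat,
            m_star=call.m_star,
            llr=call.llr,
            wt_copies=call.wt_copies,
            config_class=call.config_class.value,
            flags=";".join(sorted(f.value for f in call.flags)),
        )
        rows.append(row)

    calls = pd.DataFrame(rows, columns=list(CALLS_COLUMNS))
    for stage, n in counts.items():
        logger.info("STAGE %s count=%d", stage, n)
    return calls, rejections, counts
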