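"""Mutant-allele multiplicity model.

A clonal somatic mutation present at integer multiplicity *m* (copies
per tumor cell) in a tumor of purity *p*, at a locus with tumor total
copy number ``CN_t`` (normal cells contribute ``CN_n = 2`` autosomal
copies), is expected to show a variant allele fraction of

    q(m) = m * p / (p * CN_t + 2 * (1 - p))

— the mutant reads originate from *m* of the ``p * CN_t`` tumor-derived
allele copies, diluted by ``2 * (1 - p)`` normal copies. Two inverse
estimators are provided:

* a continuous point estimate ``m_hat = vaf * (p*CN_t + 2(1-p)) / p``
  (clamped to ``[0, CN_t]``), reported for diagnostics;
* the primary caller: the integer ``m*`` maximizing the binomial
  read-count likelihood ``Binom(t_alt | t_depth, q(m))`` over
  ``m in {1..CN_t}``, with ties broken toward smaller *m* (conservative
  against over-calling amplification) and a log-likelihood-ratio margin
  to the runner-up as confidence.

The resulting call is classified into an allelic configuration:
``SINGLE_COPY`` (one mutant copy, wild type retained), ``MULTI_COPY``
(amplified mutant, wild type retained), ``WT_LOST`` (one mutant copy and
no wild-type copy left — LOH), or ``MULTI_COPY_WT_LOST``. "Multiple
mutant alleles" in the stratification sense means any allelic imbalance:
``m* >= 2`` or zero wild-type copies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import binom

from .errors import DataError, DegenerateLocusError
from .formats_io import SegmentRecord, VariantRecord

logger = logging.getLogger(__name__)

NORMAL_CN = 2  # autosomal normal copy number; X/Y are excluded upstream

#: Default log-likelihood-ratio (natural log) below which a call is
#: flagged LOW_CONFIDENCE.
DEFAULT_LLR_LOW_CONFIDENCE = 2.0


class ConfigClass(str, Enum):
    """Allelic configuration of a called mutation."""

    SINGLE_COPY = "SINGLE_COPY"
    MULTI_COPY = "MULTI_COPY"
    WT_LOST = "WT_LOST"
    MULTI_COPY_WT_LOST = "MULTI_COPY_WT_LOST"


class CallFlag(str, Enum):
    OUT_OF_RANGE = "OUT_OF_RANGE"
    NO_SEGMENT = "NO_SEGMENT"
    AMBIGUOUS = "AMBIGUOUS"
    LOW_CONFIDENCE = "LOW_CONFIDENCE"
    INCONSISTENT = "INCONSISTENT"


@dataclass(frozen=True)
class LocusContext:
    """Purity and local copy number at a variant locus."""

    purity: float
    tumor_total_cn: int
    tumor_minor_cn: int
    normal_cn: int = NORMAL_CN

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise DataError(f"purity must lie in (0,1], got {self.purity}")
        if not (self.tumor_total_cn >= self.tumor_minor_cn >= 0):
            raise DataError(
                f"require CN_t >= minor_cn >= 0, got "
                f"({self.tumor_total_cn},{self.tumor_minor_cn})"
            )


@dataclass(frozen=True)
class MultiplicityCall:
    """Inferred mutant copy number and configuration for one variant."""

    m_hat: float
    m_star: int
    llr: float
    wt_copies: int
    config_class: ConfigClass
    flags: frozenset[CallFlag] = frozenset()


class SegmentIndex:
    """Point-containment index over copy-number segments.

    Intervals are 1-based and fully closed, matching the MAF/ASCAT
    convention.
    """

    def __init__(self, segments: Iterable[SegmentRecord]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for seg in segments:
            key = (seg.sample_id, seg.chrom)
            tree = self._trees.setdefault(key, IntervalTree())
            # closed interval [start, end] -> half-open [start, end+1)
            tree.addi(seg.start, seg.end + 1, seg)

    def lookup(self, sample_id: str, chrom: str, pos: int) -> list[SegmentRecord]:
        tree = self._trees.get((sample_id, chrom))
        if tree is None:
            return []
        hits = sorted(tree.at(pos), key=lambda iv: (iv.begin, iv.end))
        return [iv.data for iv in hits]


def locate_segment(
    v: VariantRecord, index: SegmentIndex, purity: float
) -> tuple[LocusContext | None, frozenset[CallFlag]]:
    """Find the copy-number context of a variant position.

    Returns ``(None, {NO_SEGMENT})`` when no segment contains the
    position. If overlapping segments both contain it, the first by sort
    order is used and the call is flagged ``AMBIGUOUS``.
    """
    hits = index.lookup(v.sample_id, v.chrom, v.pos)
    if not hits:
        return None, frozenset({CallFlag.NO_SEGMENT})
    flags = frozenset() if len(hits) == 1 else frozenset({CallFlag.AMBIGUOUS})
    seg = hits[0]
    return (
        LocusContext(
            purity=purity,
            tumor_total_cn=seg.total_cn,
            tumor_minor_cn=seg.minor_cn,
        ),
        flags,
    )


def expected_vaf(m: int, ctx: LocusContext) -> float:
    """Expected variant allele fraction ``q(m)`` at multiplicity ``m``."""
    if not (0 <= m <= ctx.tumor_total_cn):
        raise DataError(
            f"multiplicity {m} outside [0, CN_t={ctx.tumor_total_cn}]"
        )
    p = ctx.purity
    denom = p * ctx.tumor_total_cn + ctx.normal_cn * (1.0 - p)
    if denom == 0.0:
        raise DegenerateLocusError(
            "expected VAF undefined: no allele copies at locus (p=1, CN_t=0)"
        )
    return m * p / denom


def estimate_multiplicity_point(
    vaf: float, ctx: LocusContext
) -> tuple[float, frozenset[CallFlag]]:
    """Continuous multiplicity estimate by inverting the forward model.

    Returns the raw estimate clamped to ``[0, CN_t]`` plus an
    ``OUT_OF_RANGE`` flag when the unclamped value is more than half a
    copy outside that range (model-inconsistent VAF).
    """
    if ctx.tumor_total_cn < 1:
        raise DataError("point estimate requires CN_t >= 1")
    p = ctx.purity
    raw = vaf * (p * ctx.tumor_total_cn + ctx.normal_cn * (1.0 - p)) / p
    flags: frozenset[CallFlag] = frozenset()
    if raw > ctx.tumor_total_cn + 0.5 or raw < -0.5:
        flags = frozenset({CallFlag.OUT_OF_RANGE})
    m_hat = min(max(raw, 0.0), float(ctx.tumor_total_cn))
    return m_hat, flags


def estimate_multiplicity_ml(
    t_alt: int, t_depth: int, ctx: LocusContext
) -> tuple[int, float]:
    """Integer maximum-likelihood multiplicity under the binomial model.

    Maximizes ``log Binom(t_alt | t_depth, q(m))`` over ``m in
    {1..CN_t}``; ties break toward smaller ``m``. Returns ``(m*, llr)``
    where ``llr`` is the natural-log likelihood margin over the
    runner-up (``+inf`` when ``CN_t == 1``, the single-candidate case).
    """
    if ctx.tumor_total_cn < 1:
        raise DataError("ML multiplicity requires CN_t >= 1")
    if t_depth < 1:
        raise DataError("ML multiplicity requires t_depth >= 1")
    ms = np.arange(1, ctx.tumor_total_cn + 1)
    qs = np.array([expected_vaf(int(m), ctx) for m in ms])
    with np.errstate(divide="ignore"):
        ll = binom.logpmf(t_alt, t_depth, qs)
    best = int(np.argmax(ll))  # first maximum -> smaller m on ties
    if len(ms) == 1:
        return int(ms[best]), math.inf
    runner_up = np.max(np.delete(ll, best))
    llr = float(ll[best] - runner_up)
    return int(ms[best]), llr


def classify_configuration(m_star: int, ctx: LocusContext) -> ConfigClass:
    """Allelic configuration from mutant and residual wild-type copies."""
    if not (1 <= m_star <= ctx.tumor_total_cn):
        raise DataError(
            f"m_star {m_star} outside [1, CN_t={ctx.tumor_total_cn}]"
        )
    wt = ctx.tumor_total_cn - m_star
    if m_star == 1:
        return ConfigClass.SINGLE_COPY if wt >= 1 else ConfigClass.WT_LOST
    return ConfigClass.MULTI_COPY if wt >= 1 else ConfigClass.MULTI_COPY_WT_LOST


def is_dosage_imbalanced(m_star: int, wt_copies: int) -> bool:
    """True when mutant copies are amplified or the wild type is lost.

    This is the "multiple mutant alleles, including WT−" stratification
    predicate: ``m* >= 2`` or ``wt_copies == 0``.
    """
    return m_star >= 2 or wt_copies == 0


def call_variant(
    v: VariantRecord,
    ctx: LocusContext,
    llr_low_confidence: float = DEFAULT_LLR_LOW_CONFIDENCE,
    extra_flags: frozenset[CallFlag] = frozenset(),
) -> MultiplicityCall:
    """Full multiplicity call for one variant at a resolved locus."""
    vaf = v.t_alt_count / v.t_depth
    m_hat, point_flags = estimate_multiplicity_point(vaf, ctx)
    m_star, llr = estimate_multiplicity_ml(v.t_alt_count, v.t_depth, ctx)
    flags = set(extra_flags) | set(point_flags)
    if llr < llr_low_confidence:
        flags.add(CallFlag.LOW_CONFIDENCE)
    return MultiplicityCall(
        m_hat=m_hat,
        m_star=m_star,
        llr=llr,
        wt_copies=ctx.tumor_total_cn - m_star,
        config_class=classify_configuration(m_star, ctx),
        flags=frozenset(flags),
    )
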