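"""Forward VAF model, inverse estimators, classification, segment join."""

import math

import numpy as np
import pytest

from allelic_dosage import (
    ConfigClass,
    LocusContext,
    SegmentIndex,
    SegmentRecord,
    classify_configuration,
    estimate_multiplicity_ml,
    estimate_multiplicity_point,
    expected_vaf,
    is_dosage_imbalanced,
    locate_segment,
)
from allelic_dosage.dosage_model import CallFlag, call_variant
from allelic_dosage.errors import DataError, DegenerateLocusError

from conftest import make_variant

GRID = [
    (p, cn, m)
    for p in np.arange(0.1, 1.01, 0.1)
    for cn in range(1, 7)
    for m in range(1, cn + 1)
]


def _ctx(p, cn, minor=None):
    if minor is None:
        minor = 0 if cn == 1 else 1
    return LocusContext(purity=float(p), tumor_total_cn=cn, tumor_minor_cn=minor)


@pytest.mark.parametrize(
    "m,p,cn,expected",
    [
        (1, 1.0, 2, 0.5),       # pure diploid heterozygote
        (0, 0.6, 3, 0.0),       # absent mutation shows no reads
        (2, 0.6, 3, 1.2 / 2.6), # hand evaluation of the closed form
        (2, 1.0, 2, 1.0),       # homozygous in a pure tumor
    ],
)
def test_expected_vaf_closed_form(m, p, cn, expected):
    assert expected_vaf(m, _ctx(p, cn)) == pytest.approx(expected, abs=1e-12)


def test_expected_vaf_degenerate_locus():
    ctx = LocusContext(purity=1.0, tumor_total_cn=0, tumor_minor_cn=0)
    with pytest.raises(DegenerateLocusError):
        expected_vaf(0, ctx)


def test_expected_vaf_monotone_in_m_and_p():
    """q(m) strictly increases with multiplicity and with purity."""
    for p in np.arange(0.1, 1.01, 0.1):
        for cn in range(1, 7):
            qs = [expected_vaf(m, _ctx(p, cn)) for m in range(0, cn + 1)]
            assert all(b > a for a, b in zip(qs, qs[1:]))
    for cn in range(1, 7):
        for m in range(1, cn + 1):
            qs = [expected_vaf(m, _ctx(p, cn)) for p in np.arange(0.1, 1.01, 0.1)]
            assert all(b > a for a, b in zip(qs, qs[1:]))


def test_forward_inverse_grid_consistency():
    """Point inversion of the forward model recovers m to 1e-9."""
    for p, cn, m in GRID:
        ctx = _ctx(p, cn)
        m_hat, flags = estimate_multiplicity_point(expected_vaf(m, ctx), ctx)
        assert m_hat == pytest.approx(m, abs=1e-9)
        assert not flags


def test_point_estimate_clamps_and_flags():
    # vaf 0.9 at p=0.5, CN_t=2: raw = 0.9*2/0.5 = 3.6 -> clamp to 2, flagged
    ctx = _ctx(0.5, 2)
    m_hat, flags = estimate_multiplicity_point(0.9, ctx)
    assert m_hat == 2.0
    assert CallFlag.OUT_OF_RANGE in flags
    # mildly out of range (within half a copy) clamps silently
    m_hat, flags = estimate_multiplicity_point(expected_vaf(2, ctx) * 1.05, ctx)
    assert m_hat == 2.0
    assert not flags


def _brute_force_ml(t_alt, t_depth, ctx):
    """Independent argmax over an explicitly tabulated binomial pmf."""
    best_m, best_ll = None, -math.inf
    lls = []
    for m in range(1, ctx.tumor_total_cn + 1):
        q = m * ctx.purity / (
            ctx.purity * ctx.tumor_total_cn + 2 * (1 - ctx.purity)
        )
        if q <= 0.0:
            ll = -math.inf if t_alt > 0 else 0.0
        elif q >= 1.0:
            ll = -math.inf if t_alt < t_depth else 0.0
        else:
            ll = (
                math.lgamma(t_depth + 1)
                - math.lgamma(t_alt + 1)
                - math.lgamma(t_depth - t_alt + 1)
                + t_alt * math.log(q)
                + (t_depth - t_alt) * math.log(1 - q)
            )
        lls.append(ll)
        if ll > best_ll:  # strict: ties stay with the smaller m
            best_m, best_ll = m, ll
    others = [ll for i, ll in enumerate(lls) if i != best_m - 1]
    llr = math.inf if not others else best_ll - max(others)
    return best_m, llr


@pytest.mark.parametrize(
    "alt,depth,p,cn,expected_m",
    [
        (60, 100, 0.8, 3, 2),  # q = 0.2857/0.5714/0.8571; 0.6 nearest m=2
        (50, 100, 1.0, 2, 1),  # heterozygote in a pure tumor
        (0, 100, 0.5, 3, 1),   # no alt reads -> smallest multiplicity
    ],
)
def test_ml_examples(alt, depth, p, cn, expected_m):
    m_star, llr = estimate_multiplicity_ml(alt, depth, _ctx(p, cn))
    assert m_star == expected_m
    assert llr >= 0


def test_ml_single_candidate_contract():
    m_star, llr = estimate_multiplicity_ml(17, 60, _ctx(0.7, 1))
    assert (m_star, llr) == (1, math.inf)


def test_ml_matches_brute_force_oracle():
    """ML caller agrees with an independent pmf-table argmax, ties included."""
    rng = np.random.default_rng(20240917)
    for _ in range(1000):
        cn = int(rng.integers(1, 7))
        minor = int(rng.integers(0, cn // 2 + 1))
        p = float(rng.uniform(0.05, 1.0))
        depth = int(rng.integers(1, 400))
        alt = int(rng.integers(0, depth + 1))
        ctx = LocusContext(purity=p, tumor_total_cn=cn, tumor_minor_cn=minor)
        got = estimate_multiplicity_ml(alt, depth, ctx)
        want = _brute_force_ml(alt, depth, ctx)
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1], rel=1e-9, abs=1e-9)


def test_estimators_consistent_at_high_depth():
    """m* equals round(m_hat) when counts match the expectation exactly."""
    depth = 10_000
    for p, cn, m in GRID:
        ctx = _ctx(p, cn)
        alt = round(expected_vaf(m, ctx) * depth)
        m_star, _ = estimate_multiplicity_ml(alt, depth, ctx)
        m_hat, _ = estimate_multiplicity_point(alt / depth, ctx)
        assert m_star == round(m_hat) == m


@pytest.mark.parametrize(
    "m_star,cn,expected_class,imbalanced",
    [
        (1, 2, ConfigClass.SINGLE_COPY, False),
        (2, 2, ConfigClass.MULTI_COPY_WT_LOST, True),
        (2, 4, ConfigClass.MULTI_COPY, True),
        (1, 1, ConfigClass.WT_LOST, True),
    ],
)
def test_classification(m_star, cn, expected_class, imbalanced):
    ctx = _ctx(0.7, cn)
    assert classify_configuration(m_star, ctx) is expected_class
    assert is_dosage_imbalanced(m_star, cn - m_star) is imbalanced


def test_call_conservation_and_confidence():
    """m* + wt = CN_t; low-margin calls are flagged."""
    ctx = _ctx(0.7, 4)
    v = make_variant(t_alt_count=35, t_depth=100)
    call = call_variant(v, ctx)
    assert call.m_star + call.wt_copies == 4
    v_shallow = make_variant(t_alt_count=4, t_depth=12)
    call = call_variant(v_shallow, ctx)
    assert call.m_star + call.wt_copies == 4
    if call.llr < 2.0:
        assert CallFlag.LOW_CONFIDENCE in call.flags


def test_locate_segment_closed_interval():
    segs = [SegmentRecord("S1", "3", 1, 1000, 2, 1)]
    index = SegmentIndex(segs)

    ctx, flags = locate_segment(make_variant(pos=500), index, purity=0.6)
    assert ctx.tumor_total_cn == 3 and ctx.tumor_minor_cn == 1
    assert not flags

    ctx, flags = locate_segment(make_variant(pos=1000), index, purity=0.6)
    assert ctx is not None  # end position is inclusive

    ctx, flags = locate_segment(make_variant(pos=1001), index, purity=0.6)
    assert ctx is None
    assert CallFlag.NO_SEGMENT in flags


def test_locate_segment_overlap_flags_ambiguous():
    segs = [
        SegmentRecord("S1", "3", 1, 1000, 2, 1),
        SegmentRecord("S1", "3", 500, 2000, 3, 0),
    ]
    ctx, flags = locate_segment(make_variant(pos=700), SegmentIndex(segs), purity=0.6)
    assert ctx.tumor_total_cn == 3  # first by sort order
    assert CallFlag.AMBIGUOUS in flags


def test_ml_requires_positive_depth_and_cn():
    with pytest.raises(DataError):
        estimate_multiplicity_ml(0, 0, _ctx(0.5, 2))
    with pytest.raises(DataError):
        estimate_multiplicity_ml(1, 10, LocusContext(0.5, 0, 0))
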