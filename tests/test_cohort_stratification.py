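"""Second-hit flags and cohort summary arithmetic."""

import numpy as np
import pandas as pd
import pytest

from allelic_dosage import (
    SamplePurity,
    call_multiplicities,
    flag_second_hits,
    select_cancer_types,
    summarize_cohort,
)
from allelic_dosage.cohort_stratification import AGGREGATE
from allelic_dosage.errors import DataError
from allelic_dosage.formats_io import CALLS_COLUMNS


def _calls_df(rows):
    return pd.DataFrame(rows, columns=list(CALLS_COLUMNS))


def _call_row(sample, gene="PIK3CA", pos=100, alt="G", m_star=1, cn=2, flags=""):
    return {
        "sample": sample, "gene": gene, "chrom": "3", "pos": pos,
        "ref_allele": "A", "alt_allele": alt, "variant_class": "Missense_Mutation",
        "t_alt_count": 30, "t_depth": 100, "vaf": 0.3, "purity": 0.7,
        "cn_total": cn if m_star is not None else None,
        "cn_minor": 1 if m_star is not None else None,
        "m_hat": float(m_star) if m_star is not None else None,
        "m_star": m_star, "llr": 5.0 if m_star is not None else None,
        "wt_copies": cn - m_star if m_star is not None else None,
        "config_class": "", "flags": flags,
    }


def test_second_hit_clauses():
    calls = _calls_df(
        [
            # pathway co-mutation
            _call_row("A"),
            _call_row("A", gene="PTEN", pos=900),
            # two distinct oncogene variants
            _call_row("B", pos=100, alt="G"),
            _call_row("B", pos=200, alt="T"),
            # same (pos, alt) seen twice is ONE mutation
            _call_row("C", pos=100, alt="G"),
            _call_row("C", pos=100, alt="G"),
            # single variant only
            _call_row("D"),
        ]
    )
    flags = flag_second_hits(calls).set_index("sample")
    assert flags.loc["A", "second_hit"] and flags.loc["A", "reason"] == "pathway_comutation"
    assert flags.loc["B", "second_hit"] and "distinct" in flags.loc["B", "reason"]
    assert not flags.loc["C", "second_hit"]
    assert not flags.loc["D", "second_hit"]


def test_hand_cohort_summary(hand_cohort):
    """Four-sample fixture: prevalence 3/4, multi 1/3, second-hit 2/3."""
    variants, segments, purities = hand_cohort
    calls, _, _ = call_multiplicities(variants, segments, purities)
    summary = summarize_cohort(calls, purities)
    agg = summary[summary["cancer_type"] == AGGREGATE].iloc[0]
    assert agg["n_samples"] == 4
    assert agg["n_mut_samples"] == 3
    assert agg["prevalence"] == pytest.approx(0.75)
    assert agg["frac_multi_allele"] == pytest.approx(1 / 3)
    assert agg["frac_second_hit"] == pytest.approx(2 / 3)


def test_zero_mutant_fractions_are_na():
    purities = {"S1": SamplePurity("S1", 0.7, 2.0, "BRCA")}
    summary = summarize_cohort(_calls_df([]), purities)
    agg = summary[summary["cancer_type"] == AGGREGATE].iloc[0]
    assert agg["prevalence"] == 0.0
    assert np.isnan(agg["frac_multi_allele"])
    assert np.isnan(agg["frac_second_hit"])


def test_pooling_identity_two_identical_types():
    """AGGREGATE counts double; fractions match the per-type values."""
    purities = {}
    rows = []
    for t in ("BRCA", "UCEC"):
        for i in range(4):
            sid = f"{t}-{i}"
            purities[sid] = SamplePurity(sid, 0.7, 2.0, t)
        rows.append(_call_row(f"{t}-0", m_star=2, cn=2))
        rows.append(_call_row(f"{t}-1", m_star=1, cn=2))
    summary = summarize_cohort(_calls_df(rows), purities)
    per_type = summary[summary["cancer_type"] != AGGREGATE]
    agg = summary[summary["cancer_type"] == AGGREGATE].iloc[0]
    for col in ("n_samples", "n_mut_samples", "n_multi_allele", "n_second_hit"):
        assert agg[col] == per_type[col].sum()
    assert agg["prevalence"] == pytest.approx(per_type["prevalence"].iloc[0])
    assert agg["frac_multi_allele"] == pytest.approx(
        per_type["frac_multi_allele"].iloc[0]
    )


def test_unassessable_sample_counts_as_mutant_not_in_dosage_denominator():
    purities = {s: SamplePurity(s, 0.7, 2.0, "BRCA") for s in ("A", "B")}
    rows = [
        _call_row("A", m_star=2, cn=2),
        _call_row("B", m_star=None, flags="NO_SEGMENT"),
    ]
    summary = summarize_cohort(_calls_df(rows), purities)
    agg = summary[summary["cancer_type"] == AGGREGATE].iloc[0]
    assert agg["n_mut_samples"] == 2
    assert agg["n_dosage_assessable"] == 1
    assert agg["frac_multi_allele"] == pytest.approx(1.0)


def test_mutation_free_sample_only_dilutes_prevalence():
    purities = {s: SamplePurity(s, 0.7, 2.0, "BRCA") for s in ("A", "B")}
    rows = [_call_row("A", m_star=2, cn=2)]
    before = summarize_cohort(_calls_df(rows), purities)
    purities["Z"] = SamplePurity("Z", 0.6, 2.0, "BRCA")
    after = summarize_cohort(_calls_df(rows), purities)
    b = before[before["cancer_type"] == AGGREGATE].iloc[0]
    a = after[after["cancer_type"] == AGGREGATE].iloc[0]
    assert a["n_samples"] == b["n_samples"] + 1
    assert a["prevalence"] < b["prevalence"]
    assert a["frac_multi_allele"] == b["frac_multi_allele"]
    assert a["frac_second_hit"] == b["frac_second_hit"]


def test_call_without_purity_row_is_fatal():
    purities = {"A": SamplePurity("A", 0.7, 2.0, "BRCA")}
    with pytest.raises(DataError, match="purity"):
        summarize_cohort(_calls_df([_call_row("GHOST")]), purities)


def test_select_cancer_types_strict_threshold():
    purities = {}
    rows = []
    # HNSC: 1/10 mutant (prevalence exactly 0.10 -> excluded);
    # BRCA: 3/10 (retained)
    for t, n_mut in (("HNSC", 1), ("BRCA", 3)):
        for i in range(10):
            sid = f"{t}-{i}"
            purities[sid] = SamplePurity(sid, 0.7, 2.0, t)
        for i in range(n_mut):
            rows.append(_call_row(f"{t}-{i}"))
    summary = summarize_cohort(_calls_df(rows), purities)
    selected = select_cancer_types(summary, min_prevalence=0.10)
    strata = set(selected["cancer_type"]) - {AGGREGATE}
    assert strata == {"BRCA"}
    agg = selected[selected["cancer_type"] == AGGREGATE].iloc[0]
    assert agg["n_samples"] == 10  # pooled over retained strata only


def test_select_all_excluded_leaves_empty_aggregate():
    purities = {"S1": SamplePurity("S1", 0.7, 2.0, "BRCA")}
    summary = summarize_cohort(_calls_df([_call_row("S1")]), purities)
    selected = select_cancer_types(summary, min_prevalence=1.1)
    assert list(selected["cancer_type"]) == [AGGREGATE]
    agg = selected.iloc[0]
    assert agg["n_samples"] == 0
    assert np.isnan(agg["prevalence"])
    assert np.isnan(agg["frac_multi_allele"])
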