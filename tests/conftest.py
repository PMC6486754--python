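"""Shared fixtures: small printed input files and hand-built cohorts."""

from __future__ import annotations

import pytest

from allelic_dosage import (
    LocusContext,
    SamplePurity,
    SegmentRecord,
    VariantRecord,
    expected_vaf,
)


def make_variant(**kwargs) -> VariantRecord:
    """VariantRecord with sensible defaults, overridable per test."""
    defaults = dict(
        sample_id="S1",
        gene="PIK3CA",
        chrom="3",
        pos=179_218_303,
        ref_allele="A",
        alt_allele="G",
        variant_class="Missense_Mutation",
        t_alt_count=30,
        t_depth=100,
        callers=frozenset({"varscan2", "mutect2"}),
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


#: MAF fixture: header + 5 data rows. Two rows sit below VAF 0.05 (one
#: single-caller -> dropped by rescue; one dual-caller -> rescued), one
#: row is Silent (dropped by functional selection). Retention flow is
#: therefore 5 -> 4 (rescue) -> 3 (functional).
FILTER_MAF = "\t".join(
    [
        "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
        "Tumor_Seq_Allele2", "Variant_Classification", "Tumor_Sample_Barcode",
        "t_alt_count", "t_depth", "callers",
    ]
) + "\n" + "\n".join(
    [
        "PIK3CA\t3\t179218303\tA\tG\tMissense_Mutation\tS1\t30\t100\tvarscan2;mutect2",
        "PIK3CA\t3\t179234297\tG\tA\tMissense_Mutation\tS2\t3\t100\tvarscan2",
        "PIK3CA\t3\t179203765\tC\tT\tMissense_Mutation\tS3\t4\t100\tvarscan2;mutect2",
        "PIK3CA\t3\t179210291\tT\tC\tSilent\tS4\t40\t100\tvarscan2;mutect2",
        "PTEN\t10\t87933147\tC\tT\tNonsense_Mutation\tS5\t25\t100\tvarscan2;mutect2",
    ]
) + "\n"


@pytest.fixture
def filter_maf_path(tmp_path):
    path = tmp_path / "filter_fixture.maf.tsv"
    path.write_text(FILTER_MAF)
    return path


def _counts(m: int, purity: float, major: int, minor: int, depth: int = 100):
    """Noise-free read counts for a mutation of multiplicity m."""
    ctx = LocusContext(purity=purity, tumor_total_cn=major + minor, tumor_minor_cn=minor)
    q = expected_vaf(m, ctx)
    return int(round(q * depth)), depth


@pytest.fixture
def hand_cohort():
    """Four-sample cohort with known dosage configuration.

    A: one PIK3CA mutation at multiplicity 2 on CN 2+0 (imbalanced);
    B: single-copy PIK3CA on CN 1+1 plus a PTEN co-mutation;
    C: two distinct single-copy PIK3CA variants on CN 2+1;
    D: mutation-free.
    Expected: prevalence 3/4, multi-allele 1/3, second-hit 2/3.
    """
    p = 0.8
    variants, segments = [], []

    def seg(sid, chrom, major, minor, start=1, end=300_000_000):
        segments.append(SegmentRecord(sid, chrom, start, end, major, minor))

    seg("A", "3", 2, 0)
    alt, dep = _counts(2, p, 2, 0)
    variants.append(make_variant(sample_id="A", pos=179_210_000, t_alt_count=alt, t_depth=dep))

    seg("B", "3", 1, 1)
    seg("B", "10", 1, 1)
    alt, dep = _counts(1, p, 1, 1)
    variants.append(make_variant(sample_id="B", pos=179_215_000, t_alt_count=alt, t_depth=dep))
    variants.append(
        make_variant(
            sample_id="B", gene="PTEN", chrom="10", pos=87_933_147,
            variant_class="Nonsense_Mutation", t_alt_count=alt, t_depth=dep,
        )
    )

    seg("C", "3", 2, 1)
    alt, dep = _counts(1, p, 2, 1)
    variants.append(make_variant(sample_id="C", pos=179_210_111, alt_allele="T", t_alt_count=alt, t_depth=dep))
    variants.append(make_variant(sample_id="C", pos=179_230_222, alt_allele="C", t_alt_count=alt, t_depth=dep))

    purities = {
        sid: SamplePurity(sid, p, 2.0, "BRCA") for sid in ("A", "B", "C", "D")
    }
    return variants, segments, purities
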