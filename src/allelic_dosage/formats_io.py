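"""Readers and writers for the pipeline's tabular file dialects.

Three inputs are consumed:

* MAF-style somatic mutation tables (tab-delimited, a subset of the TCGA
  MAF columns) carrying tumor alt/total read counts per variant;
* ASCAT-style allele-specific copy-number segment tables
  (``sample, chr, startpos, endpos, nMajor, nMinor``);
* a per-sample purity/ploidy table (``sample, purity, ploidy,
  cancer_type``).

All genomic coordinates are 1-based and intervals are fully closed, the
MAF/ASCAT convention. Chromosome labels are normalized by stripping a
leading ``chr`` prefix. Malformed data rows are rejected individually
with a logged reason; missing required columns abort the whole file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)

SEGMENT_COLUMNS = ("sample", "chr", "startpos", "endpos", "nMajor", "nMinor")
PURITY_COLUMNS = ("sample", "purity", "ploidy", "cancer_type")

#: Calls-table columns, in output order.
CALLS_COLUMNS = (
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "variant_class",
    "t_alt_count",
    "t_depth",
    "vaf",
    "purity",
    "cn_total",
    "cn_minor",
    "m_hat",
    "m_star",
    "llr",
    "wt_copies",
    "config_class",
    "flags",
)


def normalize_chrom(label: object) -> str:
    """Strip a leading ``chr`` prefix from a chromosome label."""
    s = str(label).strip()
    return s[3:] if s.lower().startswith("chr") else s


@dataclass(frozen=True)
class VariantRecord:
    """One somatic mutation with read counts and caller provenance."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    t_alt_count: int
    t_depth: int
    callers: frozenset[str] = frozenset({"unknown"})

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.t_depth < 1:
            raise DataError(f"t_depth must be positive, got {self.t_depth}")
        if not (0 <= self.t_alt_count <= self.t_depth):
            raise DataError(
                f"require 0 <= t_alt_count <= t_depth, got "
                f"{self.t_alt_count}/{self.t_depth}"
            )
        if not self.callers:
            raise DataError("callers must be non-empty")


@dataclass(frozen=True)
class SegmentRecord:
    """Allele-specific integer copy number over a closed genomic interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataError(f"segment start {self.start} > end {self.end}")
        if not (self.major_cn >= self.minor_cn >= 0):
            raise DataError(
                f"require major_cn >= minor_cn >= 0, got "
                f"({self.major_cn},{self.minor_cn})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


@dataclass(frozen=True)
class SamplePurity:
    """Tumor cell fraction, mean ploidy, and study label of one sample."""

    sample_id: str
    purity: float
    ploidy: float
    cancer_type: str

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise DataError(
                f"purity must lie in (0, 1], got {self.purity} "
                f"for sample {self.sample_id}"
            )
        if self.ploidy <= 0:
            raise DataError(
                f"ploidy must be > 0, got {self.ploidy} for sample {self.sample_id}"
            )


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except FileNotFoundError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc


def read_maf(
    path: str | Path, caller_column: str | None = "callers"
) -> list[VariantRecord]:
    """Read a MAF-style mutation table into :class:`VariantRecord` objects.

    ``t_depth`` is taken from the ``t_depth`` column when present, else
    computed as ``t_alt_count + t_ref_count``. Caller provenance is parsed
    from ``caller_column`` (semicolon-separated names); when the column is
    absent every record gets ``{"unknown"}``, which means the low-VAF
    rescue filter cannot distinguish single- from dual-caller variants
    (logged).

    Rows with non-integer or inconsistent counts are rejected
    individually with a logged reason; a missing required column is a
    fatal :class:`FormatError`.
    """
    df = _read_tsv(path)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    if "t_alt_count" not in df.columns:
        raise FormatError(f"{path}: missing required MAF column 't_alt_count'")
    if "t_depth" not in df.columns and "t_ref_count" not in df.columns:
        raise FormatError(
            f"{path}: need either 't_depth' or 't_ref_count' alongside 't_alt_count'"
        )
    has_callers = caller_column is not None and caller_column in df.columns
    if not has_callers:
        logger.warning(
            "%s: no caller column %r; treating every variant as single-caller "
            "'unknown' (low-VAF rescue cannot drop anything it should not)",
            path,
            caller_column,
        )

    records: list[VariantRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            alt = int(row_d["t_alt_count"])
            if "t_depth" in df.columns and not pd.isna(row_d["t_depth"]):
                depth = int(row_d["t_depth"])
            else:
                depth = alt + int(row_d["t_ref_count"])
            if has_callers:
                callers = frozenset(
                    c.strip() for c in str(row_d[caller_column]).split(";") if c.strip()
                )
            else:
                callers = frozenset({"unknown"})
            records.append(
                VariantRecord(
                    sample_id=str(row_d["Tumor_Sample_Barcode"]),
                    gene=str(row_d["Hugo_Symbol"]),
                    chrom=normalize_chrom(row_d["Chromosome"]),
                    pos=int(row_d["Start_Position"]),
                    ref_allele=str(row_d["Reference_Allele"]),
                    alt_allele=str(row_d["Tumor_Seq_Allele2"]),
                    variant_class=str(row_d["Variant_Classification"]),
                    t_alt_count=alt,
                    t_depth=depth,
                    callers=callers,
                )
            )
        except (ValueError, TypeError, DataError) as exc:
            logger.warning("%s line %d: rejected row (%s)", path, idx, exc)
    return records


def read_segments(path: str | Path) -> list[SegmentRecord]:
    """Read an ASCAT-style allele-specific copy-number segment table.

    Rows with ``nMajor < nMinor`` are rejected with a logged reason.
    Overlapping segments on one sample/chromosome trigger a warning and
    only the first (by position sort order) is kept.
    """
    df = _read_tsv(path)
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required segment column {col!r}")

    records: list[SegmentRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            records.append(
                SegmentRecord(
                    sample_id=str(row_d["sample"]),
                    chrom=normalize_chrom(row_d["chr"]),
                    start=int(row_d["startpos"]),
                    end=int(row_d["endpos"]),
                    major_cn=int(row_d["nMajor"]),
                    minor_cn=int(row_d["nMinor"]),
                )
            )
        except (ValueError, TypeError, DataError) as exc:
            logger.warning("%s line %d: rejected segment row (%s)", path, idx, exc)

    # drop later segments that overlap an earlier one on the same
    # sample/chromosome (closed intervals)
    records.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    kept: list[SegmentRecord] = []
    last_end: dict[tuple[str, str], int] = {}
    for seg in records:
        key = (seg.sample_id, seg.chrom)
        if key in last_end and seg.start <= last_end[key]:
            logger.warning(
                "%s: overlapping segment %s:%d-%d for sample %s; keeping first",
                path,
                seg.chrom,
                seg.start,
                seg.end,
                seg.sample_id,
            )
            continue
        last_end[key] = seg.end
        kept.append(seg)
    return kept


def read_purity(path: str | Path) -> dict[str, SamplePurity]:
    """Read the per-sample purity/ploidy table into a mapping.

    Duplicate sample ids and purity values outside (0, 1] are fatal.
    """
    df = _read_tsv(path)
    for col in PURITY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required purity column {col!r}")
    out: dict[str, SamplePurity] = {}
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        sid = str(row_d["sample"])
        if sid in out:
            raise DataError(f"{path}: duplicate sample id {sid!r} in purity table")
        out[sid] = SamplePurity(
            sample_id=sid,
            purity=float(row_d["purity"]),
            ploidy=float(row_d["ploidy"]),
            cancer_type=str(row_d["cancer_type"]),
        )
    return out


def write_purity(purities: Mapping[str, SamplePurity], path: str | Path) -> None:
    rows = [
        {
            "sample": p.sample_id,
            "purity": f"{p.purity:.4f}",
            "ploidy": f"{p.ploidy:.3f}",
            "cancer_type": p.cancer_type,
        }
        for p in purities.values()
    ]
    pd.DataFrame(rows, columns=list(PURITY_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_segments(segments: Iterable[SegmentRecord], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id,
            "chr": s.chrom,
            "startpos": s.start,
            "endpos": s.end,
            "nMajor": s.major_cn,
            "nMinor": s.minor_cn,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_maf(variants: Sequence[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref_allele,
            "Tumor_Seq_Allele2": v.alt_allele,
            "Variant_Classification": v.variant_class,
            "Tumor_Sample_Barcode": v.sample_id,
            "t_alt_count": v.t_alt_count,
            "t_depth": v.t_depth,
            "callers": ";".join(sorted(v.callers)),
        }
        for v in variants
    ]
    cols = list(MAF_REQUIRED_COLUMNS) + ["t_alt_count", "t_depth", "callers"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write the per-variant multiplicity calls table (tab-delimited).

    Expects the columns of :data:`CALLS_COLUMNS`; float columns are
    formatted with fixed precision so repeated runs are byte-identical.
    """
    df = calls.reindex(columns=list(CALLS_COLUMNS)).copy()
    for col, fmt in (("vaf", "{:.6f}"), ("purity", "{:.4f}"), ("m_hat", "{:.4f}"), ("llr", "{:.4f}")):
        df[col] = df[col].map(
            lambda x, fmt=fmt: "" if pd.isna(x) else fmt.format(float(x))
        )
    for col in ("m_star", "wt_copies", "cn_total", "cn_minor"):
        df[col] = df[col].map(lambda x: "" if pd.isna(x) else str(int(x)))
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    return df


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort summary (one row per stratum + AGGREGATE)."""
    df = summary.copy()
    for col in df.columns:
        if col.startswith("frac") or col == "prevalence":
            df[col] = df[col].map(
                lambda x: "NA" if pd.isna(x) else f"{float(x):.6f}"
            )
    df.to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
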