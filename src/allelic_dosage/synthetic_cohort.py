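"""Seeded generator of synthetic tumor cohorts.

Emulates the statistical structure the multiplicity analysis assumes:
per-sample tumor purity, allele-specific integer copy number over
segments, a latent clonal mutation multiplicity, optional second hits
(a pathway co-mutation or a second distinct oncogene variant), and
sequencing read counts drawn binomially at overdispersed depths. The
generator writes the exact file dialects :mod:`.formats_io` reads, plus
a ground-truth table for recovery evaluation.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dosage_model import LocusContext, expected_vaf, classify_configuration
from .errors import ConfigError, DataError
from .formats_io import (
    SamplePurity,
    SegmentRecord,
    VariantRecord,
    write_maf,
    write_purity,
    write_segments,
)

logger = logging.getLogger(__name__)

#: Approximate GRCh38 loci of the simulated genes (chrom, start, end).
#: Positions only need to be internally consistent with the emitted
#: segments; the pipeline never consults a reference genome.
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "PIK3CA": ("3", 179_148_000, 179_240_000),
    "PTEN": ("10", 87_863_000, 87_971_000),
    "PIK3R1": ("5", 68_215_000, 68_301_000),
    "AKT1": ("14", 104_769_000, 104_795_000),
    "AKT2": ("19", 40_230_000, 40_285_000),
    "AKT3": ("1", 243_488_000, 243_851_000),
}

_BASES = ("A", "C", "G", "T")

#: Default allele-specific CN state mixture (major, minor) -> probability.
DEFAULT_CN_STATE_PROBS: dict[tuple[int, int], float] = {
    (1, 0): 0.05,
    (1, 1): 0.45,
    (2, 0): 0.10,
    (2, 1): 0.15,
    (2, 2): 0.10,
    (3, 1): 0.10,
    (4, 2): 0.05,
}

DEFAULT_N_SAMPLES_PER_TYPE: dict[str, int] = {
    # roughly TCGA-scale cohort sizes per study
    "BLCA": 408, "BRCA": 1084, "CESC": 289, "CRC": 594, "ESCA": 182,
    "GBM": 390, "HNSC": 507, "LUSC": 485, "STAD": 439, "UCEC": 530,
    "UCS": 57,
}

TRUTH_COLUMNS = (
    "sample",
    "gene",
    "chrom",
    "pos",
    "alt_allele",
    "true_multiplicity",
    "true_cn_major",
    "true_cn_minor",
    "true_purity",
    "true_config_class",
    "is_artifact",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    ``p_multi_given_mut`` is the probability that a mutant sample's
    oncogene mutation sits in an allelically imbalanced configuration
    (multiplicity >= 2 on a copy-number state that permits it); the
    complementary single-copy draws are placed on states retaining at
    least one wild-type copy, so the truth-level imbalance fraction
    equals this parameter exactly. ``depth_dispersion`` is the negative
    binomial size parameter; ``None`` (infinite dispersion parameter)
    degenerates to Poisson depths.
    """

    seed: int
    n_samples_per_type: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_SAMPLES_PER_TYPE)
    )
    purity_range: tuple[float, float] = (0.4, 0.9)
    cn_state_probs: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_CN_STATE_PROBS)
    )
    p_pik3ca_mut: float = 0.21
    p_multi_given_mut: float = 0.40
    p_second_hit: float = 0.25
    mean_depth: float = 80.0
    depth_dispersion: float | None = 10.0
    p_low_vaf_artifact: float = 0.05
    purity_noise_sd: float = 0.0
    oncogene: str = "PIK3CA"
    pathway_genes: tuple[str, ...] = ("PTEN", "PIK3R1", "AKT1", "AKT2", "AKT3")

    def __post_init__(self) -> None:
        for name in (
            "p_pik3ca_mut",
            "p_multi_given_mut",
            "p_second_hit",
            "p_low_vaf_artifact",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError(f"purity_range must lie within (0,1], got {self.purity_range}")
        total = sum(self.cn_state_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cn_state_probs must sum to 1, got {total}")
        for (major, minor) in self.cn_state_probs:
            if not (major >= minor >= 0):
                raise ConfigError(f"invalid CN state ({major},{minor})")
        if self.mean_depth <= 0:
            raise ConfigError(f"mean_depth must be > 0, got {self.mean_depth}")


@dataclass(frozen=True)
class SimulatedCohort:
    """Paths of the four emitted files."""

    maf: Path
    segments: Path
    purity: Path
    truth: Path


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    mu = cfg.mean_depth
    k = cfg.depth_dispersion
    if k is None or math.isinf(k):
        d = rng.poisson(mu)
    else:
        d = rng.negative_binomial(k, k / (k + mu))
    return int(max(d, 1))


def _draw_cn_state(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    require_major_ge2: bool,
    require_total_ge2: bool,
) -> tuple[int, int]:
    states = list(cfg.cn_state_probs.keys())
    probs = np.array([cfg.cn_state_probs[s] for s in states], dtype=float)
    probs /= probs.sum()
    for attempt in range(1000):
        i = int(rng.choice(len(states), p=probs))
        major, minor = states[i]
        if require_major_ge2 and major < 2:
            logger.debug("CN state (%d,%d) incompatible with multiplicity >= 2; resampling", major, minor)
            continue
        if require_total_ge2 and major + minor < 2:
            logger.debug("CN state (%d,%d) leaves no wild-type copy; resampling", major, minor)
            continue
        return major, minor
    raise ConfigError(
        "cn_state_probs has no state compatible with the requested multiplicity"
    )


def _random_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in _BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


def simulate_cohort(cfg: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate a cohort and write MAF, segments, purity and truth files.

    Each mutated sample gets one copy-number segment spanning the gene
    carrying its variant (the pipeline only ever queries point
    containment). Mutations are placed on the major allele. Genuine
    variant rows carry both callers (``varscan2;mutect2``); injected
    low-VAF artifact rows (VAF < 0.05) carry ``varscan2`` only and a
    truth multiplicity of 0.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    purities: dict[str, SamplePurity] = {}
    segments: list[SegmentRecord] = []
    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []

    def add_variant(
        sid: str,
        gene: str,
        purity: float,
        major: int,
        minor: int,
        m: int,
        used_pos: set[int],
        variant_class: str = "Missense_Mutation",
    ) -> None:
        chrom, gstart, gend = GENE_LOCI[gene]
        pos = int(rng.integers(gstart, gend + 1))
        while pos in used_pos:
            pos = int(rng.integers(gstart, gend + 1))
        used_pos.add(pos)
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _random_alt(rng, ref)
        depth = _draw_depth(rng, cfg)
        ctx = LocusContext(purity=purity, tumor_total_cn=major + minor, tumor_minor_cn=minor)
        q = expected_vaf(m, ctx)
        t_alt = int(rng.binomial(depth, q))
        variants.append(
            VariantRecord(
                sample_id=sid,
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_class=variant_class,
                t_alt_count=t_alt,
                t_depth=depth,
                callers=frozenset({"varscan2", "mutect2"}),
            )
        )
        truth_rows.append(
            {
                "sample": sid,
                "gene": gene,
                "chrom": chrom,
                "pos": pos,
                "alt_allele": alt,
                "true_multiplicity": m,
                "true_cn_major": major,
                "true_cn_minor": minor,
                "true_purity": purity,
                "true_config_class": classify_configuration(m, ctx).value,
                "is_artifact": False,
            }
        )

    for ctype in sorted(cfg.n_samples_per_type):
        n = int(cfg.n_samples_per_type[ctype])
        for i in range(n):
            sid = f"{ctype}-{i:05d}"
            purity = float(np.round(rng.uniform(*cfg.purity_range), 4))
            reported_purity = purity
            if cfg.purity_noise_sd > 0:
                reported_purity = float(
                    np.round(
                        np.clip(purity + rng.normal(0.0, cfg.purity_noise_sd), 0.01, 1.0), 4
                    )
                )
            ploidy = float(np.round(rng.uniform(1.7, 4.2), 3))
            purities[sid] = SamplePurity(sid, reported_purity, ploidy, ctype)

            used_pos: dict[str, set[int]] = {g: set() for g in GENE_LOCI}
            sample_states: dict[str, tuple[int, int]] = {}

            def gene_segment(gene: str, major: int, minor: int) -> None:
                if gene in sample_states:
                    return
                chrom, gstart, gend = GENE_LOCI[gene]
                sample_states[gene] = (major, minor)
                segments.append(
                    SegmentRecord(
                        sample_id=sid,
                        chrom=chrom,
                        start=gstart - 1_000_000,
                        end=gend + 1_000_000,
                        major_cn=major,
                        minor_cn=minor,
                    )
                )

            is_mutant = rng.random() < cfg.p_pik3ca_mut
            if is_mutant:
                want_imbalanced = rng.random() < cfg.p_multi_given_mut
                major, minor = _draw_cn_state(
                    rng,
                    cfg,
                    require_major_ge2=want_imbalanced,
                    require_total_ge2=not want_imbalanced,
                )
                m = int(rng.integers(2, major + 1)) if want_imbalanced else 1
                gene_segment(cfg.oncogene, major, minor)
                add_variant(sid, cfg.oncogene, purity, major, minor, m, used_pos[cfg.oncogene])

                if rng.random() < cfg.p_second_hit:
                    if rng.random() < 0.5:
                        # second distinct oncogene variant, single copy,
                        # same segment
                        add_variant(
                            sid, cfg.oncogene, purity, major, minor, 1,
                            used_pos[cfg.oncogene],
                        )
                    else:
                        gene = cfg.pathway_genes[int(rng.integers(0, len(cfg.pathway_genes)))]
                        g_major, g_minor = _draw_cn_state(
                            rng, cfg, require_major_ge2=False, require_total_ge2=False
                        )
                        gene_segment(gene, g_major, g_minor)
                        add_variant(
                            sid, gene, purity, g_major, g_minor, 1, used_pos[gene],
                            variant_class="Nonsense_Mutation",
                        )

            if rng.random() < cfg.p_low_vaf_artifact:
                gene = cfg.oncogene
                chrom, gstart, gend = GENE_LOCI[gene]
                pos = int(rng.integers(gstart, gend + 1))
                while pos in used_pos[gene]:
                    pos = int(rng.integers(gstart, gend + 1))
                used_pos[gene].add(pos)
                ref = _BASES[int(rng.integers(0, 4))]
                alt = _random_alt(rng, ref)
                depth = max(_draw_depth(rng, cfg), 25)
                target_vaf = float(rng.uniform(0.005, 0.045))
                t_alt = int(round(target_vaf * depth))
                t_alt = min(max(t_alt, 1), math.ceil(0.05 * depth) - 1)
                variants.append(
                    VariantRecord(
                        sample_id=sid,
                        gene=gene,
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref,
                        alt_allele=alt,
                        variant_class="Missense_Mutation",
                        t_alt_count=t_alt,
                        t_depth=depth,
                        callers=frozenset({"varscan2"}),
                    )
                )
                truth_rows.append(
                    {
                        "sample": sid,
                        "gene": gene,
                        "chrom": chrom,
                        "pos": pos,
                        "alt_allele": alt,
                        "true_multiplicity": 0,
                        "true_cn_major": 0,
                        "true_cn_minor": 0,
                        "true_purity": purity,
                        "true_config_class": "",
                        "is_artifact": True,
                    }
                )

    paths = SimulatedCohort(
        maf=out / "mutations.maf.tsv",
        segments=out / "segments.tsv",
        purity=out / "purity.tsv",
        truth=out / "truth.tsv",
    )
    write_maf(variants, paths.maf)
    write_segments(segments, paths.segments)
    write_purity(purities, paths.purity)
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    truth["true_purity"] = truth["true_purity"].map(lambda x: f"{x:.4f}")
    truth.to_csv(paths.truth, sep="\t", index=False)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "sample": str},
        keep_default_na=False,
        na_values=[""],
    )


def evaluate_recovery(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    summary: pd.DataFrame | None = None,
    cfg: SimulationConfig | None = None,
) -> dict:
    """Compare pipeline calls against simulation ground truth.

    Returns a dict with multiplicity accuracy (over called, non-artifact
    truth variants), recall of genuine variants, the artifact rejection
    rate, a multiplicity confusion table, a configuration-class
    confusion table, and — when a cohort summary and the generating
    config are supplied — the errors of the recovered cohort fractions
    relative to the generating parameters.
    """
    key = ["sample", "gene", "pos"]
    truth_k = truth.set_index(key)
    calls_k = calls.set_index(key)
    unmatched = calls_k.index.difference(truth_k.index)
    if len(unmatched):
        raise DataError(
            f"{len(unmatched)} call(s) have no matching truth record, e.g. "
            f"{list(unmatched[:3])}"
        )

    genuine = truth[~truth["is_artifact"]]
    artifacts = truth[truth["is_artifact"]]
    joined = genuine.merge(calls, on=key, how="left", suffixes=("_true", ""))
    called = joined[joined["m_star"].notna()]

    metrics: dict = {
        "n_truth_variants": int(len(genuine)),
        "n_called": int(len(called)),
        "recall": float(len(called) / len(genuine)) if len(genuine) else float("nan"),
    }
    if len(called):
        correct = (called["m_star"].astype(int) == called["true_multiplicity"].astype(int))
        metrics["multiplicity_accuracy"] = float(correct.mean())
        metrics["multiplicity_confusion"] = (
            pd.crosstab(
                called["true_multiplicity"].astype(int),
                called["m_star"].astype(int),
                rownames=["true_m"],
                colnames=["called_m"],
            )
        )
        metrics["class_confusion"] = pd.crosstab(
            called["true_config_class"],
            called["config_class"],
            rownames=["true_class"],
            colnames=["called_class"],
        )
    else:
        metrics["multiplicity_accuracy"] = float("nan")

    n_artifacts_called = (
        int(calls_k.index.isin(artifacts.set_index(key).index).sum())
        if len(artifacts)
        else 0
    )
    metrics["n_artifacts"] = int(len(artifacts))
    metrics["artifact_rejection_rate"] = (
        float(1.0 - n_artifacts_called / len(artifacts)) if len(artifacts) else float("nan")
    )

    if summary is not None and cfg is not None:
        agg = summary[summary["cancer_type"] == "AGGREGATE"].iloc[0]
        metrics["prevalence_error"] = float(agg["prevalence"] - cfg.p_pik3ca_mut)
        metrics["frac_multi_allele_error"] = float(
            agg["frac_multi_allele"] - cfg.p_multi_given_mut
        )
        metrics["frac_second_hit_error"] = float(
            agg["frac_second_hit"] - cfg.p_second_hit
        )
    return metrics
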