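"""Site-level quality filters, MAF filter, LD pruning and SNP accounting.

The hard filter is an OR-of-failures rule set (GATK hard-filter convention):
a site is dropped as soon as any annotated statistic crosses its threshold,
while an *absent* annotation never triggers removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenomeLayout, GenotypeMatrix

_BASES = frozenset("ACGT")
_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})

#: Canonical unordered substitution pair labels.
SUBSTITUTION_TYPES = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


@dataclass
class FilterThresholds:
    """Hard-filter and MAF thresholds (defaults follow the study pipeline)."""

    qual_min: float = 20.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    sor_max: float = 4.0
    mqranksum_min: float = -12.5
    readpos_min: float = -8.0
    maf_min: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        for name, val in asdict(self).items():
            if not np.isfinite(val):
                raise ValueError(f"threshold {name} must be finite")


@dataclass
class TsTvSummary:
    transition_count: int
    transversion_count: int
    ratio: float
    type_percentages: Dict[str, float] = field(default_factory=dict)


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as 'transition' or 'transversion'."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"


def ts_tv_summary(variants: pd.DataFrame) -> TsTvSummary:
    """Count transitions/transversions and per-substitution-type percentages."""
    if not len(variants):
        raise ValueError("no variants to classify")
    pair_counts: Dict[str, int] = {t: 0 for t in SUBSTITUTION_TYPES}
    ts = tv = 0
    for ref, alt in zip(variants["ref"], variants["alt"]):
        kind = classify_substitution(ref, alt)
        if kind == "transition":
            ts += 1
        else:
            tv += 1
        a, b = sorted((ref, alt))
        pair_counts[f"{a}/{b}"] += 1
    total = ts + tv
    if tv == 0:
        warnings.warn("no transversions: Ts/Tv ratio is infinite")
        ratio = float("inf")
    else:
        ratio = ts / tv
    pct = {k: 100.0 * v / total for k, v in pair_counts.items()}
    return TsTvSummary(ts, tv, ratio, pct)


def hard_filter(
    variants: pd.DataFrame, thresholds: Optional[FilterThresholds] = None
) -> Tuple[np.ndarray, Dict[str, int]]:
    """Apply the per-site quality filters.

    Returns a keep mask plus removal counts attributed to each rule (a site
    failing several rules counts once per rule; 'total_removed' counts it
    once).  NaN annotations pass their sub-filter.
    """
    th = thresholds or FilterThresholds()

    def fails(col: np.ndarray, bad: np.ndarray) -> np.ndarray:
        return np.where(np.isnan(col), False, bad)

    qual = variants["qual"].to_numpy(float)
    rules = {
        "QUAL": fails(qual, qual < th.qual_min),
        "QD": fails(variants["QD"].to_numpy(float), variants["QD"].to_numpy(float) < th.qd_min),
        "MQ": fails(variants["MQ"].to_numpy(float), variants["MQ"].to_numpy(float) < th.mq_min),
        "FS": fails(variants["FS"].to_numpy(float), variants["FS"].to_numpy(float) > th.fs_max),
        "SOR": fails(variants["SOR"].to_numpy(float), variants["SOR"].to_numpy(float) > th.sor_max),
        "MQRankSum": fails(
            variants["MQRankSum"].to_numpy(float),
            variants["MQRankSum"].to_numpy(float) < th.mqranksum_min,
        ),
        "ReadPosRankSum": fails(
            variants["ReadPosRankSum"].to_numpy(float),
            variants["ReadPosRankSum"].to_numpy(float) < th.readpos_min,
        ),
    }
    removed = np.zeros(len(variants), dtype=bool)
    counts: Dict[str, int] = {}
    for name, bad in rules.items():
        counts[name] = int(bad.sum())
        removed |= bad
    counts["total_removed"] = int(removed.sum())
    return ~removed, counts


def site_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-site minor allele frequency over non-missing calls (NaN if none)."""
    n_called = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n_called)
    p = np.where(n_called == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def maf_filter(dosages: np.ndarray, maf_min: float = 0.1) -> np.ndarray:
    """Keep sites with minor allele frequency >= maf_min; drop monomorphic.

    All-missing sites are removed with a warning.
    """
    maf = site_maf(dosages)
    if np.isnan(maf).any():
        warnings.warn(f"{int(np.isnan(maf).sum())} all-missing sites removed")
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(maf), False, (maf >= maf_min) & (maf > 0.0))


def _pairwise_r2(cols: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    w = cols.shape[1]
    if not np.isnan(cols).any():
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(cols, rowvar=False)
        return np.square(r)
    masked = np.ma.masked_invalid(cols)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.ma.corrcoef(masked, rowvar=False)
    return np.square(np.ma.filled(r, np.nan))


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Window-based LD pruning on dosage r^2 (PLINK --indep-pairwise style).

    Sites are scanned per chromosome in (chrom, pos) order; inside every
    ``window``-SNP window each pair with r^2 > ``r2_max`` loses its
    later-indexed member; the window advances by ``step`` SNPs.  Returns the
    kept site indices (into the input site order), deterministic.
    """
    if window < 2:
        raise ValueError("window must be >= 2 SNPs")
    sites = geno.sites
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    removed = np.zeros(geno.n_sites, dtype=bool)
    for chrom in pd.unique(sites["chrom"].to_numpy()[order]):
        cidx = order[sites["chrom"].to_numpy()[order] == chrom]
        n_c = len(cidx)
        for start in range(0, n_c, step):
            widx = cidx[start : start + window]
            if len(widx) < 2:
                break
            r2 = _pairwise_r2(geno.dosages[:, widx])
            for a in range(len(widx)):
                if removed[widx[a]]:
                    continue
                for b in range(a + 1, len(widx)):
                    if removed[widx[b]]:
                        continue
                    if r2[a, b] > r2_max:
                        removed[widx[b]] = True
            if start + window >= n_c:
                break
    return np.flatnonzero(~removed)


def snp_density(variants: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Per-chromosome SNP counts and per-kb densities, plus an ALL row."""
    chroms = list(pd.unique(variants["chrom"]))
    missing = [c for c in chroms if c not in layout]
    if missing:
        raise KeyError(f"chromosomes missing from layout: {missing}")
    rows = []
    for chrom in layout.to_dict():
        count = int((variants["chrom"] == chrom).sum())
        rows.append(
            {"chrom": chrom, "n_snps": count, "per_kb": count / (layout[chrom] / 1000.0)}
        )
    total = int(len(variants))
    rows.append(
        {"chrom": "ALL", "n_snps": total, "per_kb": total / (layout.total_length / 1000.0)}
    )
    return pd.DataFrame(rows)
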