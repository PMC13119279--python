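"""Per-population genetic-diversity parameters and phenotype descriptives.

Conventions: expected heterozygosity is 2p(1-p) without finite-sample
correction; nucleotide diversity applies the per-site 2n/(2n-1) correction
and divides by total genome length; FIS is the ratio-of-means
1 - mean(Ho)/mean(He); PIC is the biallelic Botstein form.  "MAF" is the
minor allele frequency throughout.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenomeLayout, GenotypeMatrix

DIVERSITY_COLUMNS = ("population", "n_accessions", "num_snps", "He", "Ho", "pi", "maf", "fis", "pic")


def allele_stats(site_dosages: np.ndarray) -> Tuple[float, int, float]:
    """ALT frequency, number of called diploids, and observed het at a site."""
    d = np.asarray(site_dosages, dtype=float)
    called = ~np.isnan(d)
    n = int(called.sum())
    if n == 0:
        raise ValueError("all calls missing at site")
    p = float(np.nansum(d) / (2 * n))
    ho = float(np.sum(d[called] == 1.0) / n)
    return p, n, ho


def expected_het(p):
    """Expected heterozygosity 2p(1-p)."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def pic_biallelic(p):
    """Polymorphism information content, 1 - (p^2 + q^2) - 2 p^2 q^2."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def fis(ho_mean: float, he_mean: float) -> float:
    """Inbreeding coefficient 1 - Ho/He (ratio of means); NaN if He == 0."""
    if he_mean == 0:
        warnings.warn("He mean is zero: FIS undefined")
        return float("nan")
    return 1.0 - ho_mean / he_mean


def _site_arrays(dosages: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (p, n_called, ho) across sites; NaN where nothing called."""
    called = ~np.isnan(dosages)
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n)
        ho = np.sum(np.where(called, dosages == 1.0, False), axis=0) / n
    p = np.where(n == 0, np.nan, p)
    ho = np.where(n == 0, np.nan, ho)
    return p, n, ho


def nucleotide_diversity(dosages: np.ndarray, total_length: float) -> float:
    """Per-bp nucleotide diversity over the full genome length.

    pi = sum_sites [ (2n/(2n-1)) * 2 p (1-p) ] / L; invariant genome
    positions contribute zero.
    """
    if total_length <= 0:
        raise ValueError("total genome length must be positive")
    p, n, _ = _site_arrays(dosages)
    ok = n > 0
    if not ok.any():
        return 0.0
    n_ok = n[ok].astype(float)
    corr = np.where(2 * n_ok > 1, 2 * n_ok / (2 * n_ok - 1), 0.0)
    return float(np.sum(corr * expected_het(p[ok])) / total_length)


def _diversity_row(
    dosages: np.ndarray, total_length: float, polymorphic_only: bool = False
) -> Dict[str, float]:
    p, n, ho = _site_arrays(dosages)
    ok = n > 0
    poly = ok & (p > 0) & (p < 1)
    sel = poly if polymorphic_only else ok
    he = expected_het(p[sel])
    ho_s = ho[sel]
    maf = np.minimum(p[sel], 1 - p[sel])
    pic = pic_biallelic(p[sel])
    ho_mean = float(np.mean(ho_s)) if sel.any() else float("nan")
    he_mean = float(np.mean(he)) if sel.any() else float("nan")
    return {
        "num_snps": int(poly.sum()),
        "He": he_mean,
        "Ho": ho_mean,
        "pi": nucleotide_diversity(dosages, total_length),
        "maf": float(np.mean(maf)) if sel.any() else float("nan"),
        "fis": fis(ho_mean, he_mean),
        "pic": float(np.mean(pic)) if sel.any() else float("nan"),
    }


def population_diversity(
    geno: GenotypeMatrix,
    popmap: pd.Series,
    layout: GenomeLayout,
    polymorphic_only: bool = False,
) -> pd.DataFrame:
    """Diversity table: one row per population plus an unweighted 'ALL' mean row.

    ``num_snps`` counts sites polymorphic within the population; the summary
    statistics average over all called sites unless ``polymorphic_only``.
    Populations with fewer than two accessions are excluded with a warning.
    """
    L = layout.total_length
    rows = []
    for pop in sorted(popmap.unique()):
        ids = [a for a in geno.accession_ids if popmap.get(a) == pop]
        if len(ids) < 2:
            warnings.warn(f"population {pop!r} has <2 accessions; excluded")
            continue
        sub = geno.dosages[geno.accession_index(ids)]
        row = {"population": pop, "n_accessions": len(ids)}
        row.update(_diversity_row(sub, L, polymorphic_only))
        rows.append(row)
    if not rows:
        raise ValueError("no population with >= 2 accessions")
    table = pd.DataFrame(rows)
    mean_row = {"population": "ALL", "n_accessions": int(table["n_accessions"].sum())}
    for col in ("num_snps", "He", "Ho", "pi", "maf", "fis", "pic"):
        mean_row[col] = float(table[col].mean())
    table = pd.concat([table, pd.DataFrame([mean_row])], ignore_index=True)
    return table[list(DIVERSITY_COLUMNS)]


def panel_diversity(geno: GenotypeMatrix, layout: GenomeLayout) -> Dict[str, float]:
    """Whole-panel diversity row (used for core-vs-panel comparisons)."""
    return _diversity_row(geno.dosages, layout.total_length)


def trait_descriptives(values: Sequence[float]) -> Dict[str, float]:
    """Mean/max/min/range/sd (n-1)/CV% for one trait."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if mean == 0:
        warnings.warn("trait mean is zero: CV undefined")
        cv = float("nan")
    else:
        cv = 100.0 * sd / mean
    return {
        "mean": mean,
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "range": float(np.max(x) - np.min(x)),
        "sd": sd,
        "cv_percent": cv,
    }


def shannon_index(values: Sequence[float], n_classes: int = 10) -> float:
    """Shannon diversity H' of a trait binned into sd-width classes.

    Class 1 is x < mean - 2*sd, the last class is x >= mean + 2*sd, and the
    interior classes step by 0.5*sd (for the default 10 classes).  H' is the
    natural-log entropy over occupied classes; zero spread gives 0.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    m = float(np.mean(x))
    s = float(np.std(x, ddof=1))
    if s == 0:
        return 0.0
    step = 4.0 / (n_classes - 2)
    inner = m + s * np.arange(-2.0, 2.0 + step / 2, step)
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    counts, _ = np.histogram(x, bins=edges)
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log(p)))


def trait_summary_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Descriptive + Shannon table, one row per trait."""
    rows = []
    for trait in pheno.columns:
        row = {"trait": trait}
        row.update(trait_descriptives(pheno[trait].to_numpy()))
        row["shannon_h"] = shannon_index(pheno[trait].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)
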