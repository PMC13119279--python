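"""Pairwise population differentiation (Weir-Cockerham Fst) and gene flow.

The two-population variance-components estimator is implemented from the
published 1984 equations: per site, ``a`` (among populations), ``b`` (among
individuals within populations) and ``c`` (within individuals).  The
genome-wide headline value is the weighted ratio of sums, sum(a)/sum(a+b+c);
a mean over 500 kb windows is also reported.  Small negative estimates are
preserved.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix


def _pop_site_stats(dosages: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_called, alt freq, het freq) per site for one population block."""
    called = ~np.isnan(dosages)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n)
        h = np.sum(np.where(called, dosages == 1.0, False), axis=0) / n
    return n, p, h


def wc_components(
    pop_dosages: Sequence[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham variance components per site for r populations.

    Returns (a, b, c, valid) arrays over sites; ``valid`` marks sites with
    at least two called diploids in every population and polymorphism
    across the pooled sample (other sites carry zeros and are excluded
    from ratio sums by the callers).
    """
    r = len(pop_dosages)
    if r < 2:
        raise ValueError("need at least two populations")
    stats = [_pop_site_stats(d) for d in pop_dosages]
    n = np.stack([s[0] for s in stats])  # (r, m)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])

    valid = (n >= 2).all(axis=0)
    n = np.where(n == 0, np.nan, n)

    nbar = np.nanmean(n, axis=0)
    nsum = np.nansum(n, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - np.nansum(n**2, axis=0) / nsum) / (r - 1)
        pbar = np.nansum(n * p, axis=0) / nsum
        s2 = np.nansum(n * (p - pbar) ** 2, axis=0) / ((r - 1) * nbar)
        hbar = np.nansum(n * h, axis=0) / nsum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    poly = (pbar > 0) & (pbar < 1)
    valid = valid & poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    zero = ~valid
    a = np.where(zero, 0.0, a)
    b = np.where(zero, 0.0, b)
    c = np.where(zero, 0.0, c)
    return a, b, c, valid


def wc_site_components(
    dosages_pop1: np.ndarray, dosages_pop2: np.ndarray
) -> Tuple[float, float, float]:
    """Two-population WC84 components (a, b, c) at a single biallelic site."""
    d1 = np.asarray(dosages_pop1, dtype=float).reshape(-1, 1)
    d2 = np.asarray(dosages_pop2, dtype=float).reshape(-1, 1)
    a, b, c, _ = wc_components([d1, d2])
    return float(a[0]), float(b[0]), float(c[0])


@dataclass
class FstResult:
    pop_pair: Tuple[str, str]
    windows: pd.DataFrame  # chrom, start, end, n_sites, fst
    genome_wide_weighted: float
    genome_wide_mean: float
    nm: float


def nm_from_fst(fst: float) -> float:
    """Gene flow Nm = (1 - Fst) / (4 Fst); NaN (with warning) at Fst == 0."""
    if fst == 0:
        warnings.warn("Fst is exactly zero: Nm undefined")
        return float("nan")
    return (1.0 - fst) / (4.0 * fst)


def windowed_fst(
    geno: GenotypeMatrix,
    popmap: pd.Series,
    pair: Tuple[str, str],
    window_bp: int = 500_000,
) -> FstResult:
    """Weir-Cockerham Fst for one population pair in non-overlapping windows."""
    blocks = []
    for pop in pair:
        ids = [a for a in geno.accession_ids if popmap.get(a) == pop]
        if len(ids) < 2:
            raise ValueError(f"population {pop!r} has <2 accessions")
        blocks.append(geno.dosages[geno.accession_index(ids)])
    a, b, c, valid = wc_components(blocks)
    denom = a + b + c

    chroms = geno.sites["chrom"].to_numpy()
    pos = geno.sites["pos"].to_numpy()
    win_rows: List[Dict] = []
    for chrom in pd.unique(chroms):
        on = (chroms == chrom) & valid
        if not on.any():
            continue
        wbin = (pos[on] - 1) // window_bp
        for wb in np.unique(wbin):
            sel = np.flatnonzero(on)[wbin == wb]
            da = float(a[sel].sum())
            dd = float(denom[sel].sum())
            if dd == 0:
                continue
            win_rows.append(
                {
                    "chrom": chrom,
                    "start": int(wb * window_bp + 1),
                    "end": int((wb + 1) * window_bp),
                    "n_sites": len(sel),
                    "fst": da / dd,
                }
            )
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "n_sites", "fst"])
    total_denom = float(denom[valid].sum())
    weighted = float(a[valid].sum() / total_denom) if total_denom else float("nan")
    mean_win = float(windows["fst"].mean()) if len(windows) else float("nan")
    return FstResult(tuple(pair), windows, weighted, mean_win, nm_from_fst(weighted))


def pairwise_matrix(
    geno: GenotypeMatrix, popmap: pd.Series, window_bp: int = 500_000
) -> pd.DataFrame:
    """Table-2-style matrix: Fst in the lower triangle, Nm in the upper.

    Diagonal entries are NaN.  Symmetric by construction (each pair is
    estimated once).
    """
    pops = sorted(popmap.unique())
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    table = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for p1, p2 in itertools.combinations(pops, 2):
        res = windowed_fst(geno, popmap, (p1, p2), window_bp)
        lo, hi = sorted((p1, p2))
        table.loc[hi, lo] = res.genome_wide_weighted  # lower triangle: Fst
        table.loc[lo, hi] = res.nm  # upper triangle: Nm
    return table
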