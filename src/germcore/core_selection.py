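"""Two-track core-collection construction and evaluation.

Track 1 (genotype): subsets at gradient sampling fractions are optimized for
the average entry-to-nearest-entry (A-NE) distance on Modified Rogers
distances, then scored by how closely their diversity statistics match the
full panel.  Track 2 (phenotype): candidates optimized on Gower distances
are scored by MD/VD/CR/VR.  The two tracks merge by set union.

The optimizer is a seeded random-restart steepest-ascent swap search: a
stand-in for mixed-replica search with the same objective, deterministic
under a fixed seed, and exhaustively verifiable at toy sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenomeLayout, GenotypeMatrix
from .diversity_stats import panel_diversity
from .structure_analysis import gower_distance, modified_rogers_distance

#: Default gradient sampling fractions.
DEFAULT_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

SIGNIFICANCE_COUNT = "significance-count"
RELATIVE_MAGNITUDE = "relative-magnitude"


def core_fraction_size(n: int, fraction: float) -> int:
    """Subset size at a sampling fraction: floor(n * fraction), minimum 1."""
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if fraction > 1:
        raise ValueError("fraction cannot exceed 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, math.floor(n * fraction + 1e-9))


def ane_objective(distance: np.ndarray, subset: Sequence[int]) -> float:
    """Average entry-to-nearest-entry distance of a subset (maximized)."""
    idx = list(subset)
    if len(idx) < 2:
        raise ValueError("subset must contain at least 2 entries")
    if len(set(idx)) != len(idx):
        raise ValueError("subset contains duplicate indices")
    sub = np.asarray(distance, dtype=float)[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _steepest_ascent(D: np.ndarray, initial: np.ndarray) -> Tuple[List[int], float]:
    """Hill-climb by best single swap until locally optimal."""
    n = D.shape[0]
    sel = sorted(int(i) for i in initial)
    k = len(sel)
    current = ane_objective(D, sel)
    while True:
        unsel = sorted(set(range(n)) - set(sel))
        if not unsel:
            break
        best_obj, best_swap = current, None
        for pos in range(k):
            rest = sel[:pos] + sel[pos + 1 :]
            sub = D[np.ix_(rest, rest)].copy()
            np.fill_diagonal(sub, np.inf)
            min_excl = sub.min(axis=1) if len(rest) > 1 else np.full(1, np.inf)
            dRj = D[np.ix_(rest, unsel)]  # (k-1, u)
            others = np.minimum(min_excl[:, None], dRj).sum(axis=0)
            jnn = dRj.min(axis=0)
            obj = (others + jnn) / k
            jbest = int(np.argmax(obj))
            if obj[jbest] > best_obj + 1e-12:
                best_obj = float(obj[jbest])
                best_swap = (pos, unsel[jbest])
        if best_swap is None:
            break
        pos, j = best_swap
        sel = sorted(sel[:pos] + sel[pos + 1 :] + [j])
        current = best_obj
    return sel, current


def optimize_subset(
    distance: np.ndarray,
    size: int,
    seed: int = 313,
    restarts: int = 10,
    patience: Optional[int] = None,
) -> Tuple[List[int], float]:
    """Seeded random-restart steepest-ascent search for the A-NE objective.

    Returns (sorted subset indices, objective).  The result is locally
    optimal: no single selected/unselected swap can improve it.  ``patience``
    stops early after that many restarts without global improvement.
    """
    D = np.asarray(distance, dtype=float)
    n = D.shape[0]
    if size > n:
        raise ValueError("subset size exceeds panel size")
    if size < 2:
        raise ValueError("subset size must be >= 2")
    if size == n:
        return list(range(n)), ane_objective(D, range(n))
    rng = np.random.default_rng(seed)
    patience = restarts if patience is None else patience
    best_sel: List[int] = []
    best_obj = -np.inf
    stale = 0
    for _ in range(restarts):
        init = rng.choice(n, size=size, replace=False)
        sel, obj = _steepest_ascent(D, init)
        if obj > best_obj + 1e-12:
            best_sel, best_obj = sel, obj
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    return best_sel, float(best_obj)


@dataclass
class CoreResult:
    """A candidate core: member IDs plus whatever was measured on it."""

    accession_ids: List[str]
    fraction: float
    objective: float
    diversity: Dict[str, float] = field(default_factory=dict)
    evaluation: Dict[str, float] = field(default_factory=dict)


def gradient_core_search(
    geno: GenotypeMatrix,
    layout: GenomeLayout,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 313,
    restarts: int = 5,
    distance: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, CoreResult, float]:
    """Optimize a genotype core at each fraction and pick the best one.

    Returns the per-fraction diversity table (with a 100% reference row),
    the chosen core, and its fraction.  The choice minimizes the mean
    relative absolute difference of (Ho, He, PIC) against the full panel;
    larger nucleotide diversity breaks ties.
    """
    if not len(fractions):
        raise ValueError("no fractions supplied")
    D = (
        distance
        if distance is not None
        else modified_rogers_distance(geno)
    ).to_numpy()
    full = panel_diversity(geno, layout)
    n = geno.n_accessions
    rows = []
    candidates: List[CoreResult] = []
    for frac in fractions:
        # the A-NE objective needs >= 2 entries, so tiny panels get a floor of 2
        size = max(2, core_fraction_size(n, frac))
        if frac >= 1.0 or size >= n:
            idx, obj = list(range(n)), ane_objective(D, range(n))
        else:
            idx, obj = optimize_subset(D, size, seed=seed, restarts=restarts)
        ids = [geno.accession_ids[i] for i in idx]
        div = panel_diversity(geno.subset_accessions(ids), layout)
        rel = np.mean(
            [
                abs(div[k] - full[k]) / full[k] if full[k] else 0.0
                for k in ("Ho", "He", "pic")
            ]
        )
        cand = CoreResult(ids, frac, obj, diversity=div)
        candidates.append(cand)
        rows.append({"fraction": frac, "size": size, "objective": obj, "rel_diff": rel, **div})
    ref = {"fraction": 1.0, "size": n, "objective": float("nan"), "rel_diff": 0.0}
    ref.update(full)
    table = pd.DataFrame(rows + [ref])
    scored = sorted(
        zip(candidates, table["rel_diff"][: len(candidates)]),
        key=lambda t: (round(float(t[1]), 12), -t[0].diversity["pi"]),
    )
    chosen = scored[0][0]
    return table, chosen, chosen.fraction


def evaluate_core_pheno(
    core_table: pd.DataFrame,
    full_table: pd.DataFrame,
    convention: str = SIGNIFICANCE_COUNT,
    alpha: float = 0.05,
) -> Dict[str, float]:
    """MD/VD/CR/VR evaluation of a phenotype core against the full panel.

    Under ``significance-count``, MD% and VD% are the percentage of traits
    with a significant two-sample t test / variance-ratio F test; under
    ``relative-magnitude`` they are mean relative absolute differences of
    trait means / variances.  CR% and VR% are mean range and CV ratios
    under both conventions.
    """
    if convention not in (SIGNIFICANCE_COUNT, RELATIVE_MAGNITUDE):
        raise ValueError(f"unknown convention {convention!r}")
    traits = [t for t in full_table.columns if t in core_table.columns]
    if not traits:
        raise ValueError("no shared traits between tables")
    md_parts, vd_parts, cr_parts, vr_parts = [], [], [], []
    for trait in traits:
        c = core_table[trait].to_numpy(float)
        f = full_table[trait].to_numpy(float)
        range_f = f.max() - f.min()
        cv_f = np.std(f, ddof=1) / f.mean() if f.mean() else 0.0
        if range_f == 0 or cv_f == 0:
            warnings.warn(f"trait {trait!r} has zero range or CV in full panel; excluded")
            continue
        range_c = c.max() - c.min()
        cv_c = np.std(c, ddof=1) / c.mean()
        cr_parts.append(100.0 * range_c / range_f)
        vr_parts.append(100.0 * cv_c / cv_f)
        if convention == SIGNIFICANCE_COUNT:
            _, p_t = stats.ttest_ind(c, f)
            md_parts.append(100.0 if p_t < alpha else 0.0)
            var_c, var_f = np.var(c, ddof=1), np.var(f, ddof=1)
            F = var_c / var_f if var_f else np.inf
            dfc, dff = len(c) - 1, len(f) - 1
            p_f = 2 * min(stats.f.sf(F, dfc, dff), stats.f.cdf(F, dfc, dff))
            vd_parts.append(100.0 if p_f < alpha else 0.0)
        else:
            md_parts.append(100.0 * abs(c.mean() - f.mean()) / abs(f.mean()))
            vd_parts.append(
                100.0 * abs(np.var(c, ddof=1) - np.var(f, ddof=1)) / np.var(f, ddof=1)
            )
    return {
        "md_percent": float(np.mean(md_parts)),
        "vd_percent": float(np.mean(vd_parts)),
        "cr_percent": float(np.mean(cr_parts)),
        "vr_percent": float(np.mean(vr_parts)),
        "convention": convention,
    }


def select_pheno_core(
    full_table: pd.DataFrame,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 313,
    convention: str = SIGNIFICANCE_COUNT,
    md_max: float = 0.0,
    restarts: int = 5,
) -> Tuple[CoreResult, List[CoreResult]]:
    """Phenotype-track core selection.

    Candidates are A-NE-optimized on Gower distances at each fraction; the
    chosen one maximizes CR% + VR% among candidates with MD% <= ``md_max``
    (falling back, with a warning, to the best-MD candidate when none
    qualifies).
    """
    if not len(fractions):
        raise ValueError("no fractions supplied")
    D = gower_distance(full_table).to_numpy()
    n = len(full_table)
    candidates: List[CoreResult] = []
    for frac in fractions:
        size = max(2, core_fraction_size(n, frac))  # A-NE needs >= 2 entries
        if size >= n:
            idx, obj = list(range(n)), ane_objective(D, range(n))
        else:
            idx, obj = optimize_subset(D, size, seed=seed, restarts=restarts)
        ids = [str(full_table.index[i]) for i in idx]
        ev = evaluate_core_pheno(full_table.iloc[idx], full_table, convention)
        candidates.append(CoreResult(ids, frac, obj, evaluation=ev))
    ok = [c for c in candidates if c.evaluation["md_percent"] <= md_max]
    if ok:
        chosen = max(ok, key=lambda c: c.evaluation["cr_percent"] + c.evaluation["vr_percent"])
    else:
        warnings.warn("no candidate satisfies the MD constraint; returning best-MD candidate")
        chosen = min(candidates, key=lambda c: c.evaluation["md_percent"])
    return chosen, candidates


def merge_cores(
    core1_ids: Sequence[str], core2_ids: Sequence[str]
) -> Tuple[List[str], Dict[str, int]]:
    """Order-stable set union of two cores, with size/overlap bookkeeping."""
    seen = set()
    union: List[str] = []
    for x in list(core1_ids) + list(core2_ids):
        if x not in seen:
            seen.add(x)
            union.append(x)
    overlap = len(set(core1_ids) & set(core2_ids))
    stats_d = {
        "n_core1": len(set(core1_ids)),
        "n_core2": len(set(core2_ids)),
        "n_overlap": overlap,
        "n_union": len(union),
    }
    return union, stats_d


_NOTATION = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_notation(p: float) -> str:
    """Map a p value to N.S./*/**/*** notation."""
    for cut, mark in _NOTATION:
        if p <= cut:
            return mark
    return "N.S."


def validate_core(
    trait_tables: Dict[str, pd.DataFrame]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA + Tukey HSD per trait across the named groups.

    ``trait_tables`` maps group name (e.g. original/core1/core_merge) to a
    phenotype table.  Returns (per-trait ANOVA table, pairwise Tukey table).
    """
    names = list(trait_tables)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name, tbl in trait_tables.items():
        if len(tbl) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    traits = list(trait_tables[names[0]].columns)
    anova_rows, tukey_rows = [], []
    for trait in traits:
        groups = [trait_tables[nm][trait].to_numpy(float) for nm in names]
        if all(np.var(g) == 0 for g in groups):
            warnings.warn(f"trait {trait!r}: zero within-group variance everywhere")
            anova_rows.append(
                {"trait": trait, "F": float("nan"), "p": float("nan"), "notation": "undefined"}
            )
            continue
        F, p = stats.f_oneway(*groups)
        anova_rows.append(
            {"trait": trait, "F": float(F), "p": float(p), "notation": significance_notation(p)}
        )
        res = stats.tukey_hsd(*groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pv = float(res.pvalue[i, j])
                tukey_rows.append(
                    {
                        "trait": trait,
                        "group_a": names[i],
                        "group_b": names[j],
                        "p": pv,
                        "notation": significance_notation(pv),
                    }
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)
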