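"""Population-level crossover summaries and association tests.

Works from the per-isolate count table produced by
:func:`meioscan.calling.count_matrix` (chromosome columns + TCO), an optional
HCO column, and an optional per-isolate mating-type allele label.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import ChromosomeDef


def population_summary(counts: pd.DataFrame, genome: Sequence[ChromosomeDef]) -> dict:
    """Min/mean/max TCO, total events and per-chromosome means per individual."""
    if len(counts) == 0:
        raise ValueError("need at least one isolate")
    chroms = [c.name for c in genome if c.name in counts.columns]
    tco = counts["TCO"]
    return {
        "n_isolates": int(len(counts)),
        "total_crossovers": int(tco.sum()),
        "mean_tco": float(tco.mean()),
        "min_tco": int(tco.min()),
        "max_tco": int(tco.max()),
        "mean_co_per_chromosome": {c: float(counts[c].mean()) for c in chroms},
    }


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mating_type_compare(
    counts: pd.DataFrame,
    mat_alleles: pd.Series,
    traits: Sequence[str] = ("TCO", "HCO"),
) -> dict:
    """Group means and Welch's t-test for each trait between the two
    mating-type allele classes."""
    mat = mat_alleles.reindex(counts.index).dropna()
    labels = sorted(mat.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two mating-type labels, got {labels}")
    out: dict = {"groups": labels}
    for trait in traits:
        if trait not in counts.columns:
            continue
        a = counts.loc[mat[mat == labels[0]].index, trait].to_numpy(dtype=float)
        b = counts.loc[mat[mat == labels[1]].index, trait].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"trait {trait}: each mating-type group needs >= 2 isolates")
        res = stats.ttest_ind(a, b, equal_var=False)
        out[trait] = {
            f"mean_{labels[0]}": float(a.mean()),
            f"mean_{labels[1]}": float(b.mean()),
            "t": float(res.statistic),
            "df": float(res.df),
            "p": float(res.pvalue),
        }
    return out


def segregation_test(mat_alleles: pd.Series) -> dict:
    """Chi-square test of the two mating-type allele counts against 1:1."""
    mat = mat_alleles.dropna()
    if len(mat) == 0:
        raise ValueError("no mating-type calls")
    counts = mat.value_counts().sort_index()
    if len(counts) != 2:
        raise ValueError(f"expected two allele classes, got {list(counts.index)}")
    chi2, p = stats.chisquare(counts.to_numpy())
    return {
        "counts": {str(k): int(v) for k, v in counts.items()},
        "chi2": float(chi2),
        "df": 1,
        "p": float(p),
    }


def length_co_correlation(
    genome: Sequence[ChromosomeDef], counts: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between chromosome length and its mean crossover
    count per individual."""
    chroms = [c for c in genome if c.name in counts.columns]
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes")
    lengths = [c.length for c in chroms]
    means = [counts[c.name].mean() for c in chroms]
    return pearson(lengths, means)
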