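"""Genotype QC, LD pruning, KING-robust kinship and sensitivity exclusions.

The genotype matrix is a samples x variants alt-allele dosage table
(0/1/2, NaN for missing). QC retains variants with minor allele frequency
>= 0.05 (computed from observed calls) and missingness <= 2%, then drops
samples with > 10% missingness on the surviving variants. LD pruning is a
greedy sliding-window scheme (window 200 variants, step 50, r^2 cap 0.2).

Pairwise kinship uses the KING-robust between-family estimator

    phi_hat = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))

over shared non-missing loci, where N_Aa,Aa counts loci at which both
individuals are heterozygous, N_AA,aa counts opposite homozygotes, and
N_Aa(.) counts each individual's heterozygous loci. Classification bands:
phi > 0.354 duplicate/monozygotic, 0.0884 < phi <= 0.354 second-degree or
closer, otherwise unrelated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KinshipEstimate",
    "qc_filter",
    "ld_prune",
    "king_robust",
    "kinship_all_pairs",
    "classify_kinship",
    "sensitivity_exclusions",
    "DUPLICATE_THRESHOLD",
    "RELATED_THRESHOLD",
]

DUPLICATE_THRESHOLD = 0.354
RELATED_THRESHOLD = 0.0884


@dataclass(frozen=True)
class KinshipEstimate:
    id_a: str
    id_b: str
    phi: float
    n_shared: int
    relclass: str  # duplicate_mz | second_degree_or_closer | unrelated
    flagged: bool = False  # undefined/unstable estimate


def classify_kinship(phi: float) -> str:
    if phi > DUPLICATE_THRESHOLD:
        return "duplicate_mz"
    if phi > RELATED_THRESHOLD:
        return "second_degree_or_closer"
    return "unrelated"


def qc_filter(
    matrix: pd.DataFrame,
    maf_min: float = 0.05,
    var_miss_max: float = 0.02,
    sample_miss_max: float = 0.10,
) -> pd.DataFrame:
    """Variant filters first (MAF from observed calls, missingness), then
    sample missingness on the surviving variants."""
    if matrix.empty:
        raise ValueError("empty genotype matrix")
    values = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    var_miss = 1 - obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(values, axis=0) / (2 * obs.sum(axis=0))
    maf = np.minimum(p, 1 - p)
    keep_var = (maf >= maf_min) & (var_miss <= var_miss_max)
    if not keep_var.any():
        raise ValueError("all variants removed by QC")
    reduced = matrix.loc[:, matrix.columns[keep_var]]
    sample_miss = reduced.isna().mean(axis=1)
    return reduced.loc[sample_miss <= sample_miss_max]


def _window_r2(values: np.ndarray) -> np.ndarray:
    """Squared pairwise Pearson correlation of dosage columns, with
    pairwise deletion of missing calls; zero-variance columns and pairs
    with < 3 shared observations contribute r^2 = 0."""
    if np.isnan(values).any():
        masked = np.ma.masked_invalid(values)
        corr = np.ma.corrcoef(masked, rowvar=False)
        r2 = np.asarray(corr.filled(0.0)) ** 2
    else:
        sd = values.std(axis=0)
        ok = sd > 0
        r2 = np.zeros((values.shape[1], values.shape[1]))
        if ok.any():
            sub = np.corrcoef(values[:, ok], rowvar=False)
            r2[np.ix_(ok, ok)] = np.nan_to_num(sub) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    matrix: pd.DataFrame,
    window: int = 200,
    step: int = 50,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy sliding-window pruning of correlated variants.

    Within each window (in column order, assumed genomic), while any
    retained pair exceeds the r^2 cap, the pair member with the lower MAF
    is removed (later position on an exact tie); the window then advances
    by ``step``. Returns retained variant ids in column order.
    """
    values = matrix.to_numpy(dtype=float)
    n_var = values.shape[1]
    cols = list(matrix.columns)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(values, axis=0) / 2
    maf = np.minimum(p, 1 - p)
    retained = np.ones(n_var, dtype=bool)

    start = 0
    while start < n_var:
        stop = min(start + window, n_var)
        idx = np.array([i for i in range(start, stop) if retained[i]])
        if idx.size >= 2:
            r2 = _window_r2(values[:, idx])
            alive = np.ones(idx.size, dtype=bool)
            while True:
                masked = np.where(np.outer(alive, alive), r2, 0.0)
                a, b = np.unravel_index(np.argmax(masked), masked.shape)
                if masked[a, b] <= r2_max:
                    break
                ia, ib = idx[a], idx[b]
                if maf[ia] < maf[ib]:
                    drop = a
                elif maf[ib] < maf[ia]:
                    drop = b
                else:
                    drop = max(a, b)
                alive[drop] = False
            retained[idx[~alive]] = False
        if stop >= n_var:
            break
        start += step
    return [cols[i] for i in range(n_var) if retained[i]]


def king_robust(matrix: pd.DataFrame, pair: tuple[str, str]) -> KinshipEstimate:
    """KING-robust between-family kinship for one sample pair."""
    id_a, id_b = pair
    a = matrix.loc[id_a].to_numpy(dtype=float)
    b = matrix.loc[id_b].to_numpy(dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    n_shared = int(mask.sum())
    if n_shared < 100:
        warnings.warn(f"only {n_shared} shared loci for {id_a}-{id_b}: estimate unstable",
                      stacklevel=2)
    het_a = a == 1
    het_b = b == 1
    n_het_het = int(np.sum(het_a & het_b))
    n_opp_hom = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    denom = int(het_a.sum() + het_b.sum())
    if denom == 0:
        return KinshipEstimate(id_a, id_b, float("nan"), n_shared, "unrelated", flagged=True)
    phi = (n_het_het - 2 * n_opp_hom) / denom
    return KinshipEstimate(id_a, id_b, float(phi), n_shared, classify_kinship(phi))


def kinship_all_pairs(matrix: pd.DataFrame) -> list[KinshipEstimate]:
    return [king_robust(matrix, pair) for pair in itertools.combinations(matrix.index, 2)]


def sensitivity_exclusions(related_pairs: Sequence[tuple[str, str]]) -> list[frozenset[str]]:
    """One member from each related pair, in every combination: k pairs
    yield 2^k exclusion sets (an empty product for k=0)."""
    seen: set[str] = set()
    for pair in related_pairs:
        if len(pair) != 2:
            raise ValueError("each related pair must have exactly two members")
        if seen & set(pair):
            raise ValueError(f"overlapping related pairs at {pair}")
        seen |= set(pair)
    return [frozenset(combo) for combo in itertools.product(*related_pairs)]
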