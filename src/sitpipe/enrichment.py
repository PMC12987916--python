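"""Gene-set over-representation analysis.

Hypergeometric (one-sided upper-tail) over-representation of a query gene
list against a gene-set collection, with set-size bounds (15-500 members),
a minimum intersection of 2, and multiple-testing correction per query
list. The ontology-hierarchy-aware correction used by some web services is
replaced by Bonferroni (default) or Benjamini-Hochberg, a deliberately
conservative choice.

Group gene lists are built from the recessive-model qualifying genes per
individual, with a reciprocal exclusion: case lists exclude
control-qualifying genes (via the upstream subtraction step) and the
control list excludes genes with qualifying variants in any case, giving a
control list of comparable size to the case lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "build_group_gene_lists",
    "hypergeometric_enrichment",
    "adjust_enrichment",
]


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.sets.values()) - self.background if self.sets else set()
        if stray:
            raise ValueError(f"set members outside the background: {sorted(stray)[:5]} ...")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    term_size: int
    query_size: int
    overlap_size: int
    intersection: tuple[str, ...]
    p_raw: float
    p_adjusted: float | None = None
    significant: bool | None = None


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name, description, members...). The background
    defaults to the union of all member genes."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    bg = frozenset(background) if background is not None else frozenset().union(*sets.values())
    return GeneSetCollection(sets=sets, background=bg)


def build_group_gene_lists(
    case_calls,
    recessive_evidence: Mapping[str, Mapping[str, object]],
    group_labels: Mapping[str, str],
    case_qualifying: Mapping[str, Iterable[str]],
    control_qualifying: Mapping[str, Iterable[str]],
    reciprocal: bool = True,
) -> dict[str, set[str]]:
    """Union the per-individual qualifying genes into solved/unsolved/
    control lists; with ``reciprocal`` the control list drops any gene
    qualifying in a case (the case lists already exclude
    control-qualifying genes via subtraction)."""
    lists: dict[str, set[str]] = {"solved": set(), "unsolved": set(), "control": set()}
    for iid, genes in case_qualifying.items():
        label = group_labels[iid]
        lists[label].update(genes)
    for iid, genes in control_qualifying.items():
        lists["control"].update(genes)
    if reciprocal:
        case_union = lists["solved"] | lists["unsolved"]
        lists["control"] -= case_union
    return lists


def hypergeometric_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    min_set: int = 15,
    max_set: int = 500,
    min_intersect: int = 2,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation for each set within
    the size bounds; sets outside the bounds or below the minimum overlap
    are skipped entirely (they do not enter the correction)."""
    if not collection.background:
        raise ValueError("empty background")
    query = set(query)
    outside = query - collection.background
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the background were dropped",
            stacklevel=2,
        )
    query &= collection.background
    n_bg = len(collection.background)
    n_query = len(query)
    results = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        term = len(members)
        if not min_set <= term <= max_set:
            continue
        inter = sorted(query & members)
        k = len(inter)
        if k < min_intersect:
            continue
        # P(X >= k), X ~ Hypergeom(N=n_bg, K=term, n=n_query)
        p = float(hypergeom.sf(k - 1, n_bg, term, n_query))
        results.append(
            EnrichmentResult(
                set_name=name,
                term_size=term,
                query_size=n_query,
                overlap_size=k,
                intersection=tuple(inter),
                p_raw=min(1.0, p),
            )
        )
    return results


def adjust_enrichment(
    results: Sequence[EnrichmentResult],
    method: str = "bonferroni",
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Correct the raw p-values of one query list's results and flag
    significance at ``alpha``."""
    if method not in {"bonferroni", "bh"}:
        raise ValueError(f"unknown method {method!r}")
    if not results:
        return []
    raw = [r.p_raw for r in results]
    adjusted = multipletests(raw, method="bonferroni" if method == "bonferroni" else "fdr_bh")[1]
    return [
        EnrichmentResult(
            r.set_name, r.term_size, r.query_size, r.overlap_size, r.intersection,
            r.p_raw, p_adjusted=float(p), significant=bool(p < alpha),
        )
        for r, p in zip(results, adjusted)
    ]
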