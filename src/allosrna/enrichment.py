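"""GO-term enrichment of gene sets by the upper-tail hypergeometric test,
Benjamini-Hochberg adjusted, significant at FDR <= 0.05.

The annotation is taken as already propagated through the GO graph (no
true-path completion here); the population is the set of annotated genes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

ALPHA = 0.05


@dataclass
class GOAnnotation:
    """term id -> gene set over a fixed gene population."""

    terms: dict[str, set[str]]
    names: dict[str, str]
    population: set[str]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike,
                 names: Mapping[str, str] | None = None) -> "GOAnnotation":
        """Two-column (gene, term) TSV, no header."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
        return cls.from_pairs(df.itertuples(index=False), names)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   names: Mapping[str, str] | None = None) -> "GOAnnotation":
        terms: dict[str, set[str]] = {}
        population: set[str] = set()
        for gene, term in pairs:
            terms.setdefault(term, set()).add(gene)
            population.add(gene)
        return cls(terms, dict(names or {}), population)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N population, K in term, n drawn)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(study_genes: Iterable[str], annotation: GOAnnotation,
           alpha: float = ALPHA) -> pd.DataFrame:
    """One hypergeometric test per annotated term, BH-FDR over all tested terms.

    Study genes absent from the annotated population are dropped (their count
    is reported in the `n_dropped` DataFrame attribute). Result rows are
    sorted by FDR then raw p.
    """
    study = set(study_genes)
    dropped = study - annotation.population
    study &= annotation.population
    if dropped:
        warnings.warn(f"{len(dropped)} study genes absent from the annotation "
                      "population were dropped", stacklevel=2)
    if not study:
        warnings.warn("empty study set after filtering; no enrichment computed",
                      stacklevel=2)
    N = len(annotation.population)
    n = len(study)
    rows = []
    for term, genes in annotation.terms.items():
        K = len(genes)
        if K < 1:
            continue
        k = len(study & genes)
        p = hypergeom_test(k, n, K, N) if n else 1.0
        rows.append((term, annotation.names.get(term, ""), k, n, K, N, p))
    out = pd.DataFrame(rows, columns=["term", "name", "k", "n", "K", "N", "pvalue"])
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy()) if len(out) else []
    out["enriched"] = out["fdr"] <= alpha if len(out) else []
    out = out.sort_values(["fdr", "pvalue", "term"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped"] = len(dropped)
    return out
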