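"""Orthologous-group overrepresentation via the hypergeometric upper tail.

A target gene set (e.g. the co-repressed core) is tested against a
background universe for overrepresentation of single-letter functional
categories (eggNOG/COG style: O, V, T, W, P, Q, ...).  With k category
members among n mapped target genes, K among N mapped background genes,
the p-value is P(X >= k) for X ~ Hypergeometric(N, K, n).  Matching the
published presentation, significance is raw p < alpha (default 0.01); a
Benjamini-Hochberg column is emitted alongside for transparency.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N: background size, K: category hits in background, n: target size,
    k: category hits in target.  Computed through scipy's log-space
    survival function for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts: k={k} outside [0, min(K={K}, n={n})]")
    if k < max(0, n - (N - K)):
        raise ValueError(f"k={k} below the forced minimum overlap {n - (N - K)}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_categories(
    target: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, str] | pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-category overrepresentation of a target set within a background.

    Only annotation-mapped genes count toward n and N.  One row per category
    present in the mapped background, sorted by ascending p (category label
    breaks ties); ``significant`` is strict p < alpha.
    """
    target, background = set(target), set(background)
    if not target <= background:
        raise ValueError("target set must be a subset of the background")
    annot = pd.Series(dict(annotation)) if not isinstance(annotation, pd.Series) else annotation
    annot = annot.dropna()
    mapped_bg = [g for g in background if g in annot.index]
    mapped_tg = [g for g in target if g in annot.index]
    N, n = len(mapped_bg), len(mapped_tg)
    columns = ["category", "k", "K", "n", "N", "p_value", "p_bh", "significant"]
    if n == 0:
        warnings.warn("no target gene is covered by the annotation", stacklevel=2)
        return pd.DataFrame(columns=columns)
    bg_counts = annot.loc[mapped_bg].value_counts()
    tg_counts = annot.loc[mapped_tg].value_counts()
    rows = []
    for category, K in bg_counts.items():
        k = int(tg_counts.get(category, 0))
        rows.append(
            {
                "category": category,
                "k": k,
                "K": int(K),
                "n": n,
                "N": N,
                "p_value": hypergeom_upper(k, int(K), n, N),
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_value"] < alpha
    return (
        table.sort_values(["p_value", "category"], kind="mergesort")
        .reset_index(drop=True)[columns]
    )
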