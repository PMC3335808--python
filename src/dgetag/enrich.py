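"""GO-term and pathway enrichment of DEG sets.

Significance of a term follows the hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

where N is the number of annotated genes in the background, n the number of
DEGs among them, M the background genes carrying the term and m the DEGs
carrying it.  Pathways use a one-sided Fisher exact test on the equivalent
2x2 table, which coincides with the hypergeometric tail on identical
inputs.  GO terms are flagged significant at raw p < 0.05; pathways at
BH-adjusted q < 0.05 (the asymmetry is deliberate and mirrors common DGE
practice).  Ranking for reporting uses the enrichment factor (m/n)/(M/N).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import fisher_exact, hypergeom

from .de import bh_fdr


def _validate_counts(N: int, n: int, M: int, m: int) -> None:
    checks = (
        (0 <= m, "m >= 0"),
        (m <= n, "m <= n"),
        (m <= M, "m <= M"),
        (n <= N, "n <= N"),
        (M <= N, "M <= N"),
        (n >= 0, "n >= 0"),
        (M >= 0, "M >= 0"),
        (N >= 1, "N >= 1"),
        (m >= n + M - N, "m >= n + M - N"),
    )
    for ok, rule in checks:
        if not ok:
            raise ValueError(
                f"invalid enrichment table (N={N}, n={n}, M={M}, m={m}): "
                f"violates {rule}"
            )


def hypergeom_enrichment_p(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n)."""
    _validate_counts(N, n, M, m)
    return float(hypergeom.sf(m - 1, N, M, n))


def fisher_pathway_p(N: int, n: int, M: int, m: int) -> float:
    """One-sided (enrichment direction) Fisher exact p on the 2x2 table.

    Table rows split the background into DEG / non-DEG, columns into
    in-term / out-of-term; numerically identical to the hypergeometric
    upper tail.
    """
    _validate_counts(N, n, M, m)
    table = [[m, n - m], [M - m, N - M - n + m]]
    return float(fisher_exact(table, alternative="greater")[1])


def enrich(
    deg_genes: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    domain: str = "GO",
    descriptions: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term enrichment table for one DEG set.

    The background universe is restricted to genes carrying at least one
    annotation in the vocabulary (the N of the formula); DEGs outside the
    universe are ignored.  Returns a DataFrame sorted by p with columns
    term_id, description, N, n, M, m, p, q, enrichment_factor, significant.
    """
    if domain not in ("GO", "pathway"):
        raise ValueError("domain must be 'GO' or 'pathway'")
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    deg = set(deg_genes)
    if not deg <= background:
        raise ValueError("deg_genes must be a subset of background")
    annotated = background & set().union(*gene_sets.values()) if gene_sets else set()
    if not annotated:
        raise ValueError("no background gene carries any annotation")
    N = len(annotated)
    deg_ann = deg & annotated
    n = len(deg_ann)
    test = hypergeom_enrichment_p if domain == "GO" else fisher_pathway_p

    rows = []
    for term_id in sorted(gene_sets):
        members = gene_sets[term_id] & annotated
        M = len(members)
        m = len(members & deg_ann)
        p = test(N, n, M, m)
        ef = (m / n) / (M / N) if n > 0 and M > 0 else float("nan")
        rows.append({
            "term_id": term_id,
            "description": (descriptions or {}).get(term_id, ""),
            "N": N, "n": n, "M": M, "m": m,
            "p": p, "enrichment_factor": ef,
        })
    table = pd.DataFrame(rows).set_index("term_id")
    table["q"] = bh_fdr(table["p"].to_numpy())
    crit = table["p"] if domain == "GO" else table["q"]
    table["significant"] = crit < alpha
    cols = ["description", "N", "n", "M", "m", "p", "q",
            "enrichment_factor", "significant"]
    return table[cols].sort_values(["p", "term_id"]).copy()


def top_terms(table: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Top-k significant terms ranked by enrichment factor.

    Ties broken by smaller p, then lexical term id; fewer than k significant
    terms simply yield a shorter table.
    """
    sig = table[table["significant"]].copy()
    sig = sig.reset_index()
    sig = sig.sort_values(
        ["enrichment_factor", "p", "term_id"],
        ascending=[False, True, True],
    ).set_index("term_id")
    return sig.head(k)


def pathway_heatmap_matrix(
    tables: list[pd.DataFrame],
    labels: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """-log10 p matrix over pathways significant in >= 1 comparison.

    Rows (pathways) are ordered by average-linkage hierarchical clustering
    on Euclidean distance; columns keep the given comparison order, so the
    time structure of the course stays visible.  A pathway missing from a
    comparison contributes p = 1 (zero signal).  Returns the reordered
    matrix and the scipy linkage matrix.
    """
    if len(tables) < 2:
        raise ValueError("need at least two comparisons")
    if labels is None:
        labels = [f"cmp{i + 1}" for i in range(len(tables))]
    keep: list[str] = []
    for t in tables:
        for term in t.index[t["significant"]]:
            if term not in keep:
                keep.append(term)
    if not keep:
        raise ValueError("no pathway significant in any comparison")
    data = np.zeros((len(keep), len(tables)))
    for j, t in enumerate(tables):
        p = t["p"]
        for i, term in enumerate(keep):
            if term in p.index:
                data[i, j] = -np.log10(max(p[term], 1e-300))
    mat = pd.DataFrame(data, index=pd.Index(keep, name="pathway"), columns=labels)
    if len(keep) > 1:
        lk = linkage(mat.to_numpy(), method="average", metric="euclidean")
        order = leaves_list(lk)
        mat = mat.iloc[order]
    else:
        lk = np.empty((0, 4))
    return mat, lk
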