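"""Between-library normalisation and exact-test differential expression.

One tag library per condition leaves no replicates, so significance comes
from the Audic-Claverie exact conditional test: given ``x`` tags of a gene
in a library of effective size ``N1``, the count ``y`` in a second library
of effective size ``N2`` follows, under the null of equal relative
abundance,

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative-binomial tail that is summed to a two-sided p-value.  Library
sizes are first rescaled by trimmed-mean-of-M-values (TMM) factors so that
composition differences between time points do not masquerade as
differential expression.  A gene is called up (down) when log2FC >= 2
(<= -2), p <= 0.01 and Benjamini-Hochberg FDR < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import nbinom, rankdata
from statsmodels.stats.multitest import multipletests

from .mapping import GeneCountMatrix

DEFAULT_THRESHOLDS = {"p_max": 0.01, "fdr_max": 0.01, "lfc_min": 2.0}


@dataclass
class NormalizationResult:
    """TMM scale factors (unit geometric mean) and effective library sizes."""

    factors: pd.Series
    effective_sizes: pd.Series


def tmm_factors(
    matrix: GeneCountMatrix,
    ref_label: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Trimmed mean of M-values normalisation against a reference library.

    For each library vs the reference, gene-wise log-ratios
    ``M = log2((x/N)/(xr/Nr))`` and average intensities
    ``A = 0.5*log2((x/N)*(xr/Nr))`` are computed over genes positive in
    both; the ``trim_m`` tails of M and ``trim_a`` tails of A are removed
    and the factor is ``2**weighted_mean(M)`` with inverse asymptotic
    binomial variances ``(N-x)/(N*x) + (Nr-xr)/(Nr*xr)`` as precisions.
    Factors are rescaled to unit geometric mean; effective size =
    library size * factor.
    """
    counts = matrix.counts
    sizes = matrix.library_sizes.astype(float)
    if ref_label is None:
        ref_label = counts.columns[0]
    if ref_label not in counts.columns:
        raise ValueError(f"reference library {ref_label!r} not in matrix")
    xr = counts[ref_label].to_numpy(dtype=float)
    nr = float(sizes[ref_label])

    log_factors = {}
    for lib in counts.columns:
        if lib == ref_label:
            log_factors[lib] = 0.0
            continue
        x = counts[lib].to_numpy(dtype=float)
        n = float(sizes[lib])
        both = (x > 0) & (xr > 0)
        if not both.any():
            raise ValueError(f"no genes co-expressed in {lib!r} and {ref_label!r}")
        p, pr = x[both] / n, xr[both] / nr
        m = np.log2(p / pr)
        a = 0.5 * np.log2(p * pr)
        if np.max(np.abs(m)) < 1e-10:
            log_factors[lib] = 0.0
            continue
        w = (n - x[both]) / (n * x[both]) + (nr - xr[both]) / (nr * xr[both])
        k = m.size
        keep = np.ones(k, dtype=bool)
        for values, trim in ((m, trim_m), (a, trim_a)):
            lo = math.floor(k * trim) + 1
            hi = k - math.floor(k * trim)
            r = rankdata(values)
            keep &= (r >= lo) & (r <= hi)
        if not keep.any():
            raise ValueError(f"trimming removed every gene for {lib!r}")
        log_factors[lib] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))

    factors = pd.Series({lib: 2.0 ** lf for lib, lf in log_factors.items()})
    factors = factors.loc[counts.columns]
    factors /= np.exp(np.log(factors).mean())  # unit geometric mean
    return NormalizationResult(factors=factors, effective_sizes=sizes * factors)


def exact_test_pvalues(x, y, n1: float, n2: float) -> np.ndarray:
    """Vectorised two-sided Audic-Claverie p-values.

    The conditional law of ``y`` given ``x`` is negative binomial with
    ``x+1`` successes and success probability ``N1/(N1+N2)``; the two-sided
    p doubles the smaller tail (both tails include the observation) and is
    capped at 1.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    for arr, name in ((x, "x"), (y, "y")):
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError(f"{name} must hold integer counts")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    pr = n1 / (n1 + n2)  # success probability; failures are tags in library 2
    lower = nbinom.cdf(y, x + 1, pr)
    upper = nbinom.sf(y - 1, x + 1, pr)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def exact_test_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p for a single gene (see exact_test_pvalues)."""
    return float(exact_test_pvalues(np.array([x]), np.array([y]), n1, n2)[0])


def log_fold_change(x, y, n1: float, n2: float, pseudo: float = 1.0):
    """log2 of the normalised count ratio, ``log2(((y+c)/N2)/((x+c)/N1))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(((y + pseudo) / n2) / ((x + pseudo) / n1))
    return float(out) if out.ndim == 0 else out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEComparison:
    """Per-gene differential expression results for one library pair.

    ``table`` columns: x, y (counts in the two libraries), log2fc (pseudo
    count applied only when a zero count forces it), avg_log2_cpm (smear
    plot abscissa), p, fdr, call (up/down/NS).
    """

    pair: tuple[str, str]
    n1: float
    n2: float
    table: pd.DataFrame

    @property
    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["call"] != "NS"])

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    def smear_table(self) -> pd.DataFrame:
        return self.table[["avg_log2_cpm", "log2fc", "call"]].copy()


def consecutive_pairs(labels: list[str]) -> list[tuple[str, str]]:
    return list(zip(labels, labels[1:]))


def call_degs(
    matrix: GeneCountMatrix,
    pairs: list[tuple[str, str]] | None = None,
    p_max: float = 0.01,
    fdr_max: float = 0.01,
    lfc_min: float = 2.0,
    norm: NormalizationResult | None = None,
) -> list[DEComparison]:
    """Exact-test DE calls for each library pair at the joint threshold.

    The test uses raw counts with TMM effective library sizes; the reported
    log2 fold change uses raw counts when both are positive and a pseudo
    count of 1 otherwise, so that genes absent from one library still get a
    finite ratio.  FDR is adjusted within each pair.
    """
    if pairs is None:
        pairs = consecutive_pairs(matrix.libraries)
    if norm is None:
        norm = tmm_factors(matrix)
    out = []
    for a, b in pairs:
        if a not in matrix.libraries or b not in matrix.libraries:
            raise ValueError(f"unknown library in pair ({a!r}, {b!r})")
        x = matrix.counts[a].to_numpy()
        y = matrix.counts[b].to_numpy()
        n1 = float(norm.effective_sizes[a])
        n2 = float(norm.effective_sizes[b])
        p = exact_test_pvalues(x, y, n1, n2)
        fdr = bh_fdr(p)
        co_positive = (x > 0) & (y > 0)
        lfc = np.where(
            co_positive,
            log_fold_change(x, y, n1, n2, pseudo=0.0),
            log_fold_change(x, y, n1, n2, pseudo=1.0),
        )
        cpm = 0.5 * (np.log2((x + 0.5) / n1 * 1e6) + np.log2((y + 0.5) / n2 * 1e6))
        call = np.full(x.shape, "NS", dtype=object)
        signif = (p <= p_max) & (fdr < fdr_max)
        call[signif & (lfc >= lfc_min)] = "up"
        call[signif & (lfc <= -lfc_min)] = "down"
        table = pd.DataFrame(
            {"x": x, "y": y, "log2fc": lfc, "avg_log2_cpm": cpm,
             "p": p, "fdr": fdr, "call": call},
            index=matrix.counts.index,
        )
        out.append(DEComparison(pair=(a, b), n1=n1, n2=n2, table=table))
    return out


def venn_summary(comparisons: list[DEComparison]) -> dict[str, int]:
    """DEG overlap classes across exactly three comparisons."""
    if len(comparisons) != 3:
        raise ValueError("venn summary requires exactly three comparisons")
    sets = [c.deg_genes for c in comparisons]
    union = set().union(*sets)
    mult = {g: sum(g in s for s in sets) for g in union}
    out = {
        "exactly_one": sum(1 for m in mult.values() if m == 1),
        "exactly_two": sum(1 for m in mult.values() if m == 2),
        "all_three": sum(1 for m in mult.values() if m == 3),
        "distinct_total": len(union),
    }
    for c, s in zip(comparisons, sets):
        out[f"degs_{c.pair[0]}_{c.pair[1]}"] = len(s)
    return out


def distinct_deg_total(
    per_comparison: tuple[int, int, int],
    n_exactly_two: int,
    n_all_three: int,
) -> int:
    """Distinct DEGs implied by per-comparison counts and overlap classes.

    Genes in exactly two comparisons are counted twice in the per-comparison
    sum and genes in all three are counted three times, so the distinct
    total is ``sum - n_exactly_two - 2 * n_all_three``.
    """
    return int(sum(per_comparison) - n_exactly_two - 2 * n_all_three)


def to_common_reference(
    matrix: GeneCountMatrix,
    norm: NormalizationResult | None = None,
    ref_label: str = "0h",
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 ratio of every library against the t-0 reference.

    Turns the chain of consecutive-pair comparisons into trajectories with a
    common baseline; the reference column is identically zero.
    """
    if ref_label not in matrix.libraries:
        raise ValueError(f"reference library {ref_label!r} not in matrix")
    if norm is None:
        norm = tmm_factors(matrix, ref_label=ref_label)
    xr = matrix.counts[ref_label].to_numpy()
    nr = float(norm.effective_sizes[ref_label])
    data = {}
    for lib in matrix.libraries:
        x = matrix.counts[lib].to_numpy()
        n = float(norm.effective_sizes[lib])
        data[lib] = log_fold_change(xr, x, nr, n, pseudo=pseudo)
    return pd.DataFrame(data, index=matrix.counts.index)
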