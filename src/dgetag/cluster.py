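"""K-means partitioning of DEG time-course profiles into expression patterns.

The union of DEGs across the three consecutive comparisons is clustered on
log2-scale four-point profiles (Lloyd's algorithm, Euclidean distance, best
of n seeded k-means++ restarts).  Clusters are then labelled A-F: a cluster
whose centroid rises to a clear single peak at time point t in {0h, 24h,
48h, 72h} becomes pattern A/B/C/D respectively; the remaining (monotone or
flat) clusters take the leftover letters with the largest cluster receiving
the last letter, mirroring the convention that pattern F is the bulk class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .de import NormalizationResult
from .mapping import GeneCountMatrix


@dataclass
class ClusterModel:
    """Fitted K-means partition of gene expression profiles."""

    k: int
    centroids: np.ndarray  # k x T
    assignments: pd.Series  # gene_id -> cluster index
    inertia: float
    pattern_labels: dict[int, str] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(range(self.k), fill_value=0)


def log_cpm_profiles(
    matrix: GeneCountMatrix,
    norm: NormalizationResult,
    genes: list[str] | None = None,
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """log2(TMM-normalised counts per million + pseudo) profile matrix."""
    counts = matrix.counts if genes is None else matrix.counts.loc[list(genes)]
    eff = norm.effective_sizes.loc[matrix.libraries].to_numpy(dtype=float)
    cpm = counts.to_numpy(dtype=float) / eff * 1e6
    return pd.DataFrame(
        np.log2(cpm + pseudo), index=counts.index, columns=matrix.libraries
    )


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 6,
    n_init: int = 50,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> ClusterModel:
    """Lloyd K-means, best of ``n_init`` k-means++ restarts by inertia.

    Restarts run sequentially from a seed sequence derived from ``seed``, so
    the best-of-n inertia is non-increasing as ``n_init`` grows with the
    same seed, and the whole fit is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profiles) < k:
        raise ValueError(f"k={k} exceeds number of genes ({len(profiles)})")
    x = profiles.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("profiles must be finite")
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2**31)
    best = None
    for s in restart_seeds:
        km = KMeans(
            n_clusters=k, n_init=1, init="k-means++", algorithm="lloyd",
            max_iter=max_iter, tol=tol, random_state=int(s),
        ).fit(x)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    model = ClusterModel(
        k=k,
        centroids=best.cluster_centers_.copy(),
        assignments=pd.Series(best.labels_, index=profiles.index, name="cluster"),
        inertia=float(best.inertia_),
    )
    model.pattern_labels = label_patterns(model)
    return model


def _peakedness(centroid: np.ndarray) -> tuple[int, float] | None:
    """(peak index, sharpness) if the centroid is unimodal-peaked, else None.

    A centroid is peaked when its maximum stands out: the drop from the peak
    to the runner-up exceeds the spread among the non-peak values.  Monotone
    ramps and flat profiles fail this and fall to the E/F classes.
    """
    t = int(np.argmax(centroid))
    rest = np.delete(centroid, t)
    peak = centroid[t]
    runner_up = rest.max()
    sharpness = peak - runner_up
    if sharpness > rest.max() - rest.min():
        return t, float(sharpness)
    return None


def label_patterns(model: ClusterModel) -> dict[int, str]:
    """Assign pattern letters A-F to the clusters of a fitted model."""
    if model.centroids.shape[1] != 4:
        raise ValueError("pattern labelling expects four time points")
    peaked: dict[int, tuple[int, float]] = {}
    for c in range(model.k):
        res = _peakedness(model.centroids[c])
        if res is not None:
            peaked[c] = res
    labels: dict[int, str] = {}
    used: set[str] = set()
    for t, letter in enumerate("ABCD"):
        candidates = [c for c, (pt, _) in peaked.items() if pt == t and c not in labels]
        if not candidates:
            continue
        winner = max(candidates, key=lambda c: (peaked[c][1], -c))
        labels[winner] = letter
        used.add(letter)
    leftover_letters = [ch for ch in "ABCDEF" if ch not in used]
    sizes = model.sizes
    remaining = sorted(
        (c for c in range(model.k) if c not in labels),
        key=lambda c: (int(sizes[c]), -(peaked[c][0] if c in peaked else 4)),
    )
    # larger clusters take later letters (the biggest ends up as F)
    for c, letter in zip(remaining, leftover_letters[-len(remaining):] if remaining else []):
        labels[c] = letter
    return labels


def export_cluster_lists(
    model: ClusterModel,
    profiles: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one TSV per pattern (gene_id, profile columns, cluster).

    Patterns with no genes (a degenerate but possible K-means outcome) still
    produce an empty, headed file so downstream tooling sees all six.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    letters = sorted(set(model.pattern_labels.values()) | set("ABCDEF"[: model.k]))
    cluster_of_letter = {v: c for c, v in model.pattern_labels.items()}
    for letter in letters:
        c = cluster_of_letter.get(letter)
        genes = model.assignments.index[model.assignments == c] if c is not None else []
        sub = profiles.loc[list(genes)].copy()
        sub.insert(0, "pattern", letter)
        sub["cluster"] = c if c is not None else -1
        path = outdir / f"pattern_{letter}.tsv"
        sub.to_csv(path, sep="\t")
        paths[letter] = path
    return paths


def read_cluster_lists(paths: dict[str, Path]) -> pd.Series:
    """Reassemble gene -> pattern assignments from exported lists."""
    frames = []
    for letter, path in paths.items():
        df = pd.read_csv(path, sep="\t", index_col=0)
        if len(df):
            frames.append(pd.Series(letter, index=df.index))
    if not frames:
        return pd.Series(dtype=object)
    return pd.concat(frames).sort_index()
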