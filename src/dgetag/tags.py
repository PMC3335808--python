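"""Raw reads -> clean tag libraries, plus library-level summaries.

A *clean tag* is a 21-nt sequence starting with CATG that survived, in
order: adaptor-only removal, 3'-adaptor trimming, ambiguous-base filtering,
length/structure filtering and singleton removal (tags seen once per library
are treated as sequencing artifacts).  The stage counters mirror the columns
of a library-characteristics table: raw, after adaptor trim, after
low-quality drop, clean (copy >= 2) total, distinct clean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .simulate import ANCHOR, TAG_LEN

#: Default abundance categories (tag copy number ranges); the last is open.
DEFAULT_ABUNDANCE_BINS = ((2, 5), (6, 10), (11, 20), (21, 50), (51, 100), (101, None))


@dataclass
class LibraryStats:
    """Per-stage read/tag counts of one library."""

    raw: int = 0
    after_adaptor_trim: int = 0
    after_quality_drop: int = 0
    clean_total: int = 0
    distinct_clean: int = 0
    adaptor_only: int = 0
    ambiguous_base: int = 0
    bad_structure: int = 0  # length != 21 or missing leading CATG
    singleton_distinct: int = 0
    mapped_distinct: int | None = None
    mapping_rate: float | None = None

    def validate(self) -> None:
        if not (self.raw >= self.after_adaptor_trim >= self.after_quality_drop
                >= self.clean_total >= 0):
            raise ValueError("stage counts must be non-increasing")
        if self.distinct_clean > self.clean_total:
            raise ValueError("distinct_clean exceeds clean_total")


@dataclass
class TagLibrary:
    """One sample's clean tag counts (every count >= 2) plus stage stats."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)
    stats: LibraryStats = field(default_factory=LibraryStats)

    @classmethod
    def from_counts(cls, label: str, counts: Mapping[str, int]) -> "TagLibrary":
        """Wrap an existing clean tag->count mapping (e.g. read from disk)."""
        for tag, c in counts.items():
            if len(tag) != TAG_LEN or not tag.startswith(ANCHOR):
                raise ValueError(f"not a CATG+17 tag: {tag!r}")
            if c < 2:
                raise ValueError(f"clean library may not hold singleton tag {tag!r}")
        total = int(sum(counts.values()))
        stats = LibraryStats(
            raw=total, after_adaptor_trim=total, after_quality_drop=total,
            clean_total=total, distinct_clean=len(counts),
        )
        return cls(label=label, counts=dict(counts), stats=stats)

    @property
    def clean_total(self) -> int:
        return self.stats.clean_total

    @property
    def distinct_clean(self) -> int:
        return self.stats.distinct_clean


def clean_reads(reads: Iterable[str], adaptor: str, label: str = "") -> TagLibrary:
    """Apply the cleaning cascade to raw reads and count clean tags.

    Stages, in order: (1) discard reads that begin with the adaptor
    (adaptor-only); (2) trim the read at the first full adaptor occurrence;
    (3) discard candidates containing an ambiguous base; (4) discard
    candidates whose length differs from 21 nt or that do not start with
    CATG (structural artifacts); (5) count identical tags and (6) drop tags
    with total copy number 1.  Empty input yields an empty library with
    all-zero counters.

    Trimming requires a full adaptor match: tags have a fixed 21-nt length,
    so in an intact read the adaptor always occupies positions 22-35.  A
    read whose adaptor was corrupted by sequencing error is left untrimmed
    and falls through to the length filter.
    """
    if not adaptor:
        raise ValueError("adaptor sequence must be non-empty")
    stats = LibraryStats()
    counter: Counter[str] = Counter()
    for read in reads:
        stats.raw += 1
        cut = read.find(adaptor)
        if cut == 0:
            stats.adaptor_only += 1
            continue
        stats.after_adaptor_trim += 1
        candidate = read if cut == -1 else read[:cut]
        if "N" in candidate:
            stats.ambiguous_base += 1
            continue
        stats.after_quality_drop += 1
        if len(candidate) != TAG_LEN or not candidate.startswith(ANCHOR):
            stats.bad_structure += 1
            continue
        counter[candidate] += 1

    clean = {tag: c for tag, c in counter.items() if c >= 2}
    stats.singleton_distinct = len(counter) - len(clean)
    stats.clean_total = sum(clean.values())
    stats.distinct_clean = len(clean)
    stats.validate()
    return TagLibrary(label=label, counts=clean, stats=stats)


def expand_library(lib: TagLibrary) -> list[str]:
    """Clean tags expanded back to one string per tag instance."""
    out: list[str] = []
    for tag, c in lib.counts.items():
        out.extend([tag] * c)
    return out


def abundance_distribution(
    lib: TagLibrary,
    bins: Iterable[tuple[int, int | None]] = DEFAULT_ABUNDANCE_BINS,
) -> pd.Series:
    """Distinct clean tags per copy-number category.

    ``bins`` must partition [2, inf): contiguous inclusive ranges starting
    at 2, the last open-ended (upper bound ``None``).
    """
    bins = list(bins)
    if not bins or bins[0][0] != 2 or bins[-1][1] is not None:
        raise ValueError("bins must start at 2 and end with an open range")
    for (lo, hi), (nlo, _) in zip(bins, bins[1:]):
        if hi is None or nlo != hi + 1:
            raise ValueError(f"bins must be contiguous and non-overlapping at {lo}-{hi}")
    labels = [f"{lo}-{hi if hi is not None else 'inf'}" for lo, hi in bins]
    out = pd.Series(0, index=labels, name=lib.label or "distinct_tags")
    for c in lib.counts.values():
        for (lo, hi), lab in zip(bins, labels):
            if c >= lo and (hi is None or c <= hi):
                out[lab] += 1
                break
    return out


def library_overlap(libs: list[TagLibrary]) -> dict[frozenset[str], int]:
    """Distinct-tag counts for every non-empty subset of libraries.

    The returned key ``frozenset({a, b})`` counts tags present in exactly
    libraries ``a`` and ``b`` and no others; counts over all subsets sum to
    the size of the union of the distinct tag sets.
    """
    if len(libs) < 2:
        raise ValueError("need at least two libraries")
    labels = [lib.label for lib in libs]
    if len(set(labels)) != len(labels):
        raise ValueError("library labels must be unique")
    membership: dict[str, set[str]] = {}
    for lib in libs:
        for tag in lib.counts:
            membership.setdefault(tag, set()).add(lib.label)
    out: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(labels) + 1)
        for c in combinations(labels, r)
    }
    for tags in membership.values():
        out[frozenset(tags)] += 1
    return out


def saturation_curve(
    lib: TagLibrary,
    gene_of_tag: Mapping[str, str],
    depth_grid: Iterable[int],
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Genes detected vs sequencing depth by subsampling tag instances.

    At each depth, that many tag instances are drawn without replacement
    from the library and the number of distinct genes with at least one
    uniquely mapped tag (per ``gene_of_tag``) is counted.  A plateau in the
    curve indicates the library was sequenced to saturation.
    """
    grid = [int(d) for d in depth_grid]
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("depth_grid must be strictly increasing")
    for d in grid:
        if d < 0 or d > lib.clean_total:
            raise ValueError(
                f"subsampling depth {d} exceeds library clean total {lib.clean_total}"
            )
    tags = list(lib.counts)
    colors = np.array([lib.counts[t] for t in tags], dtype=np.int64)
    rng = np.random.default_rng(seed)
    out = []
    for d in grid:
        sample = rng.multivariate_hypergeometric(colors, d)
        genes = {
            gene_of_tag[tag]
            for tag, c in zip(tags, sample)
            if c > 0 and tag in gene_of_tag
        }
        out.append((d, len(genes)))
    return out


def stats_table(libs: list[TagLibrary]) -> pd.DataFrame:
    """Library characteristics in standard column order (one row per sample)."""
    rows = []
    for lib in libs:
        s = lib.stats
        rows.append({
            "sample": lib.label,
            "raw": s.raw,
            "trim_adaptor": s.after_adaptor_trim,
            "drop_low_quality": s.after_quality_drop,
            "clean_tags": s.clean_total,
            "distinct_clean_tags": s.distinct_clean,
            "mapped_tags": s.mapped_distinct,
            "mapping_rate": s.mapping_rate,
        })
    return pd.DataFrame(rows).set_index("sample")
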