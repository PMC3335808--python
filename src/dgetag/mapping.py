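"""Virtual CATG+17 tag database and tag-to-gene mapping.

The mapping target is not the genome but the set of *all possible* tags a
reference transcript can produce: every CATG occurrence with at least 17 nt
downstream yields one 21-nt window (sense strand).  Clean tags are assigned
to genes by exact hash lookup first and, failing that, by enumerating all 63
single-substitution neighbours (one mismatch tolerated).  Tags whose
admissible matches span more than one gene are discarded as multigene tags;
a gene's expression value is the summed count of its uniquely assigned tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .simulate import ANCHOR, TAG_LEN, ReferenceGene
from .tags import LibraryStats, TagLibrary


@dataclass
class VirtualTagDB:
    """All CATG+17-nt windows of a reference gene set.

    ``entries`` maps each tag to ``{gene_id: rank}`` where rank 1 is the
    gene's 3'-most window; ``gene_index`` lists each gene's tags 3'->5'.
    Genes with no admissible window are listed in ``genes_without_tags``.
    """

    entries: dict[str, dict[str, int]] = field(default_factory=dict)
    gene_index: dict[str, list[str]] = field(default_factory=dict)
    genes_without_tags: tuple[str, ...] = ()

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.entries.get(tag, {})) > 1

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MappingResult:
    """Outcome of mapping one clean library against a virtual tag DB."""

    label: str
    gene_counts: dict[str, int]
    assigned: dict[str, str]  # distinct tag -> gene
    multigene: tuple[str, ...]  # distinct tags discarded as ambiguous
    unmapped: tuple[str, ...]  # distinct tags with no admissible match
    assigned_instances: int
    multigene_instances: int
    unmapped_instances: int

    @property
    def mapped_distinct(self) -> int:
        return len(self.assigned)


def build_virtual_tag_db(genes: list[ReferenceGene]) -> VirtualTagDB:
    """Enumerate every sense-strand CATG+17 window of every gene."""
    seen = set()
    entries: dict[str, dict[str, int]] = {}
    gene_index: dict[str, list[str]] = {}
    tagless: list[str] = []
    for gene in genes:
        if gene.gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        seq = gene.sequence
        positions = []
        i = seq.find(ANCHOR)
        while i != -1:
            if i + TAG_LEN <= len(seq):
                positions.append(i)
            i = seq.find(ANCHOR, i + 1)
        if not positions:
            tagless.append(gene.gene_id)
            continue
        ordered = []  # 3' -> 5'
        for rank, pos in enumerate(reversed(positions), start=1):
            tag = seq[pos:pos + TAG_LEN]
            slot = entries.setdefault(tag, {})
            # a repeated window within one gene keeps its most-3' rank
            slot.setdefault(gene.gene_id, rank)
            if tag not in ordered:
                ordered.append(tag)
        gene_index[gene.gene_id] = ordered
    return VirtualTagDB(entries=entries, gene_index=gene_index,
                        genes_without_tags=tuple(tagless))


def _neighbors(tag: str):
    for i, ch in enumerate(tag):
        head, tail = tag[:i], tag[i + 1:]
        for b in "ACGT":
            if b != ch:
                yield head + b + tail


def map_tags(lib: TagLibrary, db: VirtualTagDB, max_mismatch: int = 1) -> MappingResult:
    """Assign each distinct clean tag to a gene, at best mismatch stratum.

    Exact matches take precedence over 1-mismatch matches; at the tag's best
    stratum, matches spanning more than one gene discard the tag as
    multigene.  Updates ``lib.stats.mapped_distinct`` / ``mapping_rate``.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    gene_counts: dict[str, int] = {}
    assigned: dict[str, str] = {}
    multigene: list[str] = []
    unmapped: list[str] = []
    n_assigned = n_multi = n_unmapped = 0
    for tag, count in lib.counts.items():
        hit = db.entries.get(tag)
        if hit is not None:
            genes = set(hit)
        elif max_mismatch >= 1:
            genes = set()
            for nb in _neighbors(tag):
                e = db.entries.get(nb)
                if e:
                    genes.update(e)
        else:
            genes = set()
        if len(genes) == 1:
            gid = next(iter(genes))
            assigned[tag] = gid
            gene_counts[gid] = gene_counts.get(gid, 0) + count
            n_assigned += count
        elif len(genes) > 1:
            multigene.append(tag)
            n_multi += count
        else:
            unmapped.append(tag)
            n_unmapped += count

    result = MappingResult(
        label=lib.label,
        gene_counts=gene_counts,
        assigned=assigned,
        multigene=tuple(multigene),
        unmapped=tuple(unmapped),
        assigned_instances=n_assigned,
        multigene_instances=n_multi,
        unmapped_instances=n_unmapped,
    )
    lib.stats.mapped_distinct = result.mapped_distinct
    if lib.stats.distinct_clean > 0:
        lib.stats.mapping_rate = mapping_rate(lib.stats)
    return result


def tag_mapping_rate(mapped_distinct: int, distinct_clean: int) -> float:
    """Percent of distinct clean tags uniquely mapped, two decimals.

    Rounding is half away from zero (so 0.125 % reports as 0.13 %).
    """
    if distinct_clean <= 0:
        raise ValueError("mapping rate undefined: no distinct clean tags")
    if mapped_distinct > distinct_clean:
        raise ValueError("mapped_distinct exceeds distinct_clean")
    pct = Decimal(100 * mapped_distinct) / Decimal(distinct_clean)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mapping_rate(stats: LibraryStats) -> float:
    """Mapping rate of a library whose ``mapped_distinct`` has been filled."""
    if stats.mapped_distinct is None:
        raise ValueError("library has not been mapped yet")
    return tag_mapping_rate(stats.mapped_distinct, stats.distinct_clean)


@dataclass
class GeneCountMatrix:
    """Genes x libraries integer counts with per-library mapped totals."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        sums = self.counts.sum(axis=0)
        if not (sums == self.library_sizes.loc[self.counts.columns]).all():
            raise ValueError("column sums must equal library_sizes")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "GeneCountMatrix":
        counts = counts.astype(int)
        return cls(counts=counts, library_sizes=counts.sum(axis=0))

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


def gene_count_matrix(
    results: dict[str, MappingResult],
    gene_ids: list[str] | None = None,
) -> GeneCountMatrix:
    """Assemble per-library mapping results into one count matrix."""
    if gene_ids is None:
        ids: list[str] = []
        seen = set()
        for r in results.values():
            for g in r.gene_counts:
                if g not in seen:
                    seen.add(g)
                    ids.append(g)
        gene_ids = sorted(ids)
    data = {
        label: [r.gene_counts.get(g, 0) for g in gene_ids]
        for label, r in results.items()
    }
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return GeneCountMatrix.from_counts(df)
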