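"""Synthetic reference transcriptomes, expression truth and raw tag reads.

The simulator emulates a 3'-anchored tag-profiling (SAGE/DGE) experiment:
each sampled transcript molecule contributes one 21-nt tag consisting of the
3'-most CATG (NlaIII site) of the transcript plus the 17 nt immediately
downstream, followed by 14 nt of a fixed 3' adaptor to fill a 35-nt read.
Contamination classes (adaptor-only reads, reads with ambiguous bases) and
per-base substitution errors are injected at configurable rates, and the
ground truth of every read's origin is recorded so the downstream cleaning,
mapping, testing and clustering stages can be verified exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCHOR = "CATG"
TAG_LEN = 21  # CATG + 17 nt
READ_LEN = 35
#: Fixed synthetic 3' adaptor filling the read downstream of the tag.
#: The simulator and the cleaner must share this sequence.
ADAPTOR_3P = "TCGTATGCCGTCTT"
#: Sampling time points of the reprogramming course (hours after isolation).
LIBRARIES = ("0h", "24h", "48h", "72h")
PATTERNS = ("A", "B", "C", "D", "E", "F")

# Relative mean per time point expressed as an exponent of the fold change.
# A-D peak at one of the four time points; E falls and F rises monotonically,
# each consecutive step being exactly one fold.
_PATTERN_EXPONENTS = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "B": (0.0, 1.0, 0.0, 0.0),
    "C": (0.0, 0.0, 1.0, 0.0),
    "D": (0.0, 0.0, 0.0, 1.0),
    "E": (1.5, 0.5, -0.5, -1.5),
    "F": (-1.5, -0.5, 0.5, 1.5),
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class ReferenceGene:
    """A reference transcript with flat GO / pathway annotation."""

    gene_id: str
    sequence: str
    go_terms: set[str] = field(default_factory=set)
    pathway_ids: set[str] = field(default_factory=set)


@dataclass
class AnnotationSpec:
    """Term-size distribution for synthetic GO / pathway annotation.

    Each term draws its size uniformly from the given inclusive range and its
    members uniformly without replacement from the gene set; genes left out
    of every term carry no annotation, as in real genomes.
    """

    n_go_terms: int = 30
    n_pathways: int = 15
    go_size_range: tuple[int, int] = (5, 40)
    pathway_size_range: tuple[int, int] = (5, 40)


@dataclass
class ExpressionTruth:
    """Simulated per-library mean expression and DE ground truth for a gene."""

    gene_id: str
    means: tuple[float, float, float, float]
    de_labels: tuple[str, str, str]  # one per consecutive library pair
    pattern: str | None = None

    @property
    def is_de(self) -> bool:
        return any(lab != "none" for lab in self.de_labels)


@dataclass
class ReadSimConfig:
    """Knobs of the read simulator.

    depth
        reads emitted per library (tag instances before cleaning).
    per_base_error_rate
        probability of a substitution at each position of the 35-nt read.
    adaptor_only_fraction
        fraction of reads that are pure adaptor (empty insert).
    n_read_fraction
        fraction of reads carrying at least one ambiguous base in the tag.
    """

    depth: int
    per_base_error_rate: float = 0.0
    adaptor_only_fraction: float = 0.0
    n_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for name in ("per_base_error_rate", "adaptor_only_fraction", "n_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.adaptor_only_fraction + self.n_read_fraction > 1.0:
            raise ValueError("contamination fractions sum to more than 1")


@dataclass
class SimulatedLibrary:
    """Raw reads of one library plus the per-gene tag-origin truth table."""

    label: str
    reads: list[str]
    origin_counts: dict[str, int]  # gene_id -> error-free payload reads
    tags: dict[str, str]  # gene_id -> its 3'-most CATG+17 tag
    undetectable: tuple[str, ...]  # genes with no CATG site
    n_adaptor_only: int
    n_ambiguous_base: int

    def origin_table(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "tag": self.tags.get(g, ""), "count": c,
             "undetectable": g in self.undetectable}
            for g, c in self.origin_counts.items()
        ]
        return pd.DataFrame(rows).set_index("gene_id")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def three_prime_tag(sequence: str) -> str | None:
    """The 3'-most CATG+17-nt tag of a transcript, or None if untaggable."""
    end = len(sequence)
    pos = sequence.rfind(ANCHOR, 0, end)
    while pos != -1:
        if pos + TAG_LEN <= len(sequence):
            return sequence[pos:pos + TAG_LEN]
        # step to the next occurrence to the left (occurrences may be close)
        pos = sequence.rfind(ANCHOR, 0, pos + len(ANCHOR) - 1)
    return None


def tag_sites(sequence: str) -> list[int]:
    """Start positions of every CATG with >= 17 nt downstream, 5'->3'."""
    sites = []
    i = sequence.find(ANCHOR)
    while i != -1:
        if i + TAG_LEN <= len(sequence):
            sites.append(i)
        i = sequence.find(ANCHOR, i + 1)
    return sites


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1500),
    annotation_spec: AnnotationSpec | None = None,
    seed: int = 0,
) -> list[ReferenceGene]:
    """Draw random transcript sequences, each guaranteed at least one tag site.

    Sequences are i.i.d. uniform over ACGT; if a draw happens to contain no
    CATG with 17 nt downstream, one anchor is planted at a random admissible
    position so that every gene is taggable.  Annotation terms are assigned
    per ``annotation_spec``.  Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < TAG_LEN + 4:
        raise ValueError(
            f"minimum gene length must be >= {TAG_LEN + 4} to leave room for a "
            f"CATG + 17-nt tag, got {lo}"
        )
    if hi < lo:
        raise ValueError("length_range max below min")
    spec = annotation_spec or AnnotationSpec()
    rng = np.random.default_rng(seed)

    genes: list[ReferenceGene] = []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        if three_prime_tag(seq) is None:
            pos = int(rng.integers(0, length - TAG_LEN + 1))
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR):]
        genes.append(ReferenceGene(gene_id=f"G{i + 1:0{width}d}", sequence=seq))

    _annotate(genes, spec, rng)
    return genes


def _annotate(genes: list[ReferenceGene], spec: AnnotationSpec, rng: np.random.Generator) -> None:
    n = len(genes)
    for count, size_range, prefix, attr in (
        (spec.n_go_terms, spec.go_size_range, "GO:", "go_terms"),
        (spec.n_pathways, spec.pathway_size_range, "path", "pathway_ids"),
    ):
        lo = min(size_range[0], n)
        hi = min(size_range[1], n)
        for t in range(count):
            term = f"{prefix}{t + 1:05d}"
            size = int(rng.integers(lo, hi + 1))
            for idx in rng.choice(n, size=size, replace=False):
                getattr(genes[int(idx)], attr).add(term)


def annotation_gene_sets(genes: list[ReferenceGene]) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Invert per-gene annotation into term -> gene-id sets (GO, pathway)."""
    go: dict[str, set[str]] = {}
    pw: dict[str, set[str]] = {}
    for g in genes:
        for t in g.go_terms:
            go.setdefault(t, set()).add(g.gene_id)
        for t in g.pathway_ids:
            pw.setdefault(t, set()).add(g.gene_id)
    return go, pw


def simulate_expression_profiles(
    genes: list[ReferenceGene],
    de_fraction: float = 0.2,
    fold: float = 4.0,
    base_mean: float = 100.0,
    seed: int = 0,
) -> list[ExpressionTruth]:
    """Assign each gene a four-point expression trajectory.

    A ``de_fraction`` Bernoulli draw marks genes differentially expressed;
    each DE gene receives one of the six trajectory shapes (peak at one of
    the four time points, monotone down, monotone up), every labelled
    consecutive step changing by exactly ``fold``.  Non-DE genes are flat at
    ``base_mean``.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if fold < 4.0:
        raise ValueError("fold must be >= 4 (the DE calling cutoff)")
    rng = np.random.default_rng(seed)
    is_de = rng.random(len(genes)) < de_fraction
    de_idx = np.flatnonzero(is_de)
    rng.shuffle(de_idx)

    truths: list[ExpressionTruth] = []
    pattern_of: dict[int, str] = {
        int(gi): PATTERNS[k % len(PATTERNS)] for k, gi in enumerate(de_idx)
    }
    for i, gene in enumerate(genes):
        pattern = pattern_of.get(i)
        if pattern is None:
            means = (base_mean,) * 4
            labels = ("none",) * 3
        else:
            exps = _PATTERN_EXPONENTS[pattern]
            means = tuple(base_mean * fold ** e for e in exps)
            labels = tuple(
                "up" if b > a * (fold - 1e-9)
                else "down" if b < a / (fold - 1e-9)
                else "none"
                for a, b in zip(means, means[1:])
            )
        truths.append(ExpressionTruth(gene.gene_id, means, labels, pattern))
    return truths


def _apply_errors(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate == 0.0 or not reads:
        return reads
    n_err = rng.binomial(READ_LEN, rate, size=len(reads))
    out = reads
    for i in np.flatnonzero(n_err):
        r = list(out[i])
        for pos in rng.choice(READ_LEN, size=int(n_err[i]), replace=False):
            alt = [b for b in "ACGT" if b != r[pos]]
            r[pos] = alt[int(rng.integers(0, 3))]
        out[i] = "".join(r)
    return out


def simulate_tag_library(
    genes: list[ReferenceGene],
    truth: list[ExpressionTruth],
    cfg: ReadSimConfig,
    library: int | str = 0,
) -> SimulatedLibrary:
    """Emit raw 35-nt reads for one library of the time course.

    Per-gene read counts are multinomial on the normalised mean expression of
    the requested time point (the library size is fixed, matching the
    conditioning of the downstream exact test).  Every payload read is the
    gene's 3'-most CATG+17 tag plus adaptor; genes lacking a CATG site emit
    nothing and are recorded as undetectable.  Contamination reads (pure
    adaptor; ambiguous-base) and substitution errors are layered on top.
    Deterministic given ``cfg.seed``.
    """
    lib_idx = LIBRARIES.index(library) if isinstance(library, str) else int(library)
    label = LIBRARIES[lib_idx]
    truth_by_id = {t.gene_id: t for t in truth}
    missing = [g.gene_id for g in genes if g.gene_id not in truth_by_id]
    if missing:
        raise ValueError(f"genes without expression truth: {missing[:3]}...")

    rng = np.random.default_rng(cfg.seed)
    tags: dict[str, str] = {}
    undetectable: list[str] = []
    weights: list[float] = []
    taggable: list[str] = []
    for g in genes:
        tag = three_prime_tag(g.sequence)
        if tag is None:
            undetectable.append(g.gene_id)
            continue
        tags[g.gene_id] = tag
        taggable.append(g.gene_id)
        weights.append(truth_by_id[g.gene_id].means[lib_idx])
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("all taggable genes have zero mean expression")
    p = w / w.sum()

    n_adaptor, n_ncls, n_payload = rng.multinomial(
        cfg.depth,
        [cfg.adaptor_only_fraction, cfg.n_read_fraction,
         1.0 - cfg.adaptor_only_fraction - cfg.n_read_fraction],
    )

    payload_counts = rng.multinomial(n_payload, p)
    reads: list[str] = []
    for gid, cnt in zip(taggable, payload_counts):
        if cnt:
            reads.extend([(tags[gid] + ADAPTOR_3P)[:READ_LEN]] * int(cnt))
    reads = _apply_errors(reads, cfg.per_base_error_rate, rng)

    # ambiguous-base reads: drawn from the same gene pool, >=1 N in the tag
    n_counts = rng.multinomial(n_ncls, p) if n_ncls else np.zeros(len(p), int)
    for gid, cnt in zip(taggable, n_counts):
        base = (tags[gid] + ADAPTOR_3P)[:READ_LEN]
        for _ in range(int(cnt)):
            pos = int(rng.integers(0, TAG_LEN))
            reads.append(base[:pos] + "N" + base[pos + 1:])

    adaptor_read = (ADAPTOR_3P * 3)[:READ_LEN]
    reads.extend([adaptor_read] * int(n_adaptor))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    origin = {gid: int(c) for gid, c in zip(taggable, payload_counts)}
    for gid in undetectable:
        origin[gid] = 0
    return SimulatedLibrary(
        label=label,
        reads=reads,
        origin_counts=origin,
        tags=tags,
        undetectable=tuple(undetectable),
        n_adaptor_only=int(n_adaptor),
        n_ambiguous_base=int(n_ncls),
    )


def simulate_experiment(
    genes: list[ReferenceGene],
    truth: list[ExpressionTruth],
    cfg: ReadSimConfig,
) -> dict[str, SimulatedLibrary]:
    """Simulate all four libraries, one independent substream per time point."""
    out = {}
    for i, label in enumerate(LIBRARIES):
        sub = ReadSimConfig(
            depth=cfg.depth,
            per_base_error_rate=cfg.per_base_error_rate,
            adaptor_only_fraction=cfg.adaptor_only_fraction,
            n_read_fraction=cfg.n_read_fraction,
            seed=cfg.seed,
        )
        # independent stream per library derived from the one user seed
        sub_rngseed = np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0]
        sub.seed = int(sub_rngseed % (2**31))
        out[label] = simulate_tag_library(genes, truth, sub, library=i)
    return out


def simulate_count_matrix(
    truth: list[ExpressionTruth],
    depth: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial gene-count matrix straight from the expression truth.

    Bypasses read-level simulation: counts for each library are one
    multinomial draw of ``depth`` tag instances on the normalised means.
    Convenient for testing the count-based stages (normalisation, exact
    test, clustering) at depths where read simulation is unnecessary.
    """
    rng = np.random.default_rng(seed)
    ids = [t.gene_id for t in truth]
    cols = {}
    for i, label in enumerate(LIBRARIES):
        w = np.array([t.means[i] for t in truth], dtype=float)
        cols[label] = rng.multinomial(depth, w / w.sum())
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))


def truth_table(truth: list[ExpressionTruth]) -> pd.DataFrame:
    """Tidy truth table: per-library means, step labels and pattern."""
    rows = []
    for t in truth:
        row = {"gene_id": t.gene_id, "pattern": t.pattern or ""}
        row.update({f"mean_{lab}": m for lab, m in zip(LIBRARIES, t.means)})
        row.update({
            f"label_{a}_{b}": lab
            for (a, b), lab in zip(zip(LIBRARIES, LIBRARIES[1:]), t.de_labels)
        })
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
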