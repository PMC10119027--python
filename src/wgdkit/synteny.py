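"""Synteny-block post-processing and ohnolog/singleton synteny enrichment.

Blocks of conserved sequence order between a query and a target genome are
consumed as BED-like tables (0-based half-open). The pipeline order is:
filter short blocks, merge consecutive same-strand blocks separated by
small gaps, assign genes by start position, then test whether a focal gene
set (e.g. ohnologs) occurs in syntenic regions more often than a
size-matched random draw of other genes, via Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .io import GeneRecord
from . import stats

MIN_BLOCK_BP = 100_000
MAX_MERGE_GAP_BP = 1_000_000


@dataclass(frozen=True)
class SyntenyBlock:
    """A stranded query interval paired with a target-genome interval;
    coordinates are 0-based half-open."""

    query_chrom: str
    q_start: int
    q_end: int
    strand: str
    target_chrom: str
    t_start: int
    t_end: int

    def __post_init__(self):
        if not self.q_start < self.q_end:
            raise ValueError(f"block on {self.query_chrom}: q_start must be < q_end")
        if not self.t_start < self.t_end:
            raise ValueError(f"block on {self.query_chrom}: t_start must be < t_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"block on {self.query_chrom}: bad strand {self.strand!r}")

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start


def read_blocks(path) -> list[SyntenyBlock]:
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    need = ["query_chrom", "q_start", "q_end", "strand",
            "target_chrom", "t_start", "t_end"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        SyntenyBlock(str(r.query_chrom), int(r.q_start), int(r.q_end),
                     str(r.strand), str(r.target_chrom), int(r.t_start), int(r.t_end))
        for r in df.itertuples(index=False)
    ]


def write_blocks(blocks: list[SyntenyBlock], path) -> None:
    pd.DataFrame(
        [(b.query_chrom, b.q_start, b.q_end, b.strand,
          b.target_chrom, b.t_start, b.t_end) for b in blocks],
        columns=["query_chrom", "q_start", "q_end", "strand",
                 "target_chrom", "t_start", "t_end"],
    ).to_csv(path, sep="\t", index=False)


def filter_min_block(blocks: list[SyntenyBlock],
                     min_len: int = MIN_BLOCK_BP) -> list[SyntenyBlock]:
    """Drop blocks shorter than ``min_len`` on the query side (inclusive
    threshold: a block of exactly ``min_len`` is retained)."""
    return [b for b in blocks if b.q_length >= min_len]


def merge_blocks(blocks: list[SyntenyBlock],
                 max_gap: int = MAX_MERGE_GAP_BP) -> list[SyntenyBlock]:
    """Merge consecutive blocks on the same query chromosome and strand when
    the gap between them is strictly below ``max_gap``.

    Blocks are sorted by (query_chrom, q_start); merging repeats to a
    fixpoint. The merged query span covers both inputs (gaps are absorbed,
    so coverage can only grow); target spans are unioned when the target
    chromosome matches, else the first block's target fields are kept.
    """
    current = sorted(blocks, key=lambda b: (b.query_chrom, b.q_start, b.q_end))
    while True:
        merged: list[SyntenyBlock] = []
        changed = False
        for b in current:
            prev = merged[-1] if merged else None
            if (
                prev is not None
                and prev.query_chrom == b.query_chrom
                and prev.strand == b.strand
                and b.q_start - prev.q_end < max_gap
            ):
                if prev.target_chrom == b.target_chrom:
                    t_start = min(prev.t_start, b.t_start)
                    t_end = max(prev.t_end, b.t_end)
                else:
                    t_start, t_end = prev.t_start, prev.t_end
                merged[-1] = replace(
                    prev,
                    q_start=min(prev.q_start, b.q_start),
                    q_end=max(prev.q_end, b.q_end),
                    t_start=t_start,
                    t_end=t_end,
                    target_chrom=prev.target_chrom,
                )
                changed = True
            else:
                merged.append(b)
        current = merged
        if not changed:
            return current


def union_length(blocks: list[SyntenyBlock]) -> int:
    """Total query-side coverage, counting overlapping spans once."""
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.query_chrom, []).append((b.q_start, b.q_end))
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def synteny_fraction(blocks: list[SyntenyBlock], lengths: dict[str, int]) -> float:
    """Fraction of the query genome covered by the union of block spans."""
    for b in blocks:
        if b.query_chrom not in lengths:
            raise ConfigurationError(f"no length for chromosome {b.query_chrom!r}")
    genome = sum(lengths.values())
    if genome <= 0:
        raise ConfigurationError("genome length must be positive")
    return union_length(blocks) / genome


def assign_genes_to_synteny(genes: list[GeneRecord],
                            blocks: list[SyntenyBlock]) -> dict[str, bool]:
    """gene_id -> True iff the gene start falls within a block (half-open)
    on the gene's chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        by_chrom.setdefault(b.query_chrom, []).append((b.q_start, b.q_end))
    for spans in by_chrom.values():
        spans.sort()
    out = {}
    for g in genes:
        spans = by_chrom.get(g.chrom, [])
        hit = False
        if spans:
            starts = np.array([s for s, _ in spans])
            i = int(np.searchsorted(starts, g.start, side="right")) - 1
            hit = i >= 0 and g.start < spans[i][1]
        out[g.gene_id] = hit
    return out


@dataclass
class SyntenyEnrichmentResult:
    table: np.ndarray          # rows: (focal, downsample); cols: (in, out)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    seed: int
    n_sampled: int
    n_reps: int = 1

    def as_series(self) -> pd.Series:
        a, b = self.table[0]
        c, d = self.table[1]
        return pd.Series(
            {"focal_in": a, "focal_out": b, "sample_in": c, "sample_out": d,
             "odds_ratio": self.odds_ratio, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "p_value": self.p_value,
             "seed": self.seed, "n_sampled": self.n_sampled,
             "n_reps": self.n_reps}
        )


def synteny_enrichment(focal_genes: set[str], all_genes: set[str],
                       in_synteny: dict[str, bool], seed: int,
                       include_focal_in_pool: bool = False,
                       n_reps: int = 1) -> SyntenyEnrichmentResult:
    """Test whether ``focal_genes`` occur in syntenic regions more often than
    a size-matched random downsampling of the other genes.

    Draws ``len(focal_genes)`` genes without replacement from
    ``all_genes \\ focal_genes`` (or from all genes when
    ``include_focal_in_pool``), builds the 2x2 table
    (focal, downsample) x (in synteny, not), and returns the two-sided
    Fisher p with the sample odds ratio and its Woolf 95% CI. With
    ``n_reps > 1`` the downsample cells are averaged over replicates and
    rounded, the recorded seed still making the result deterministic.
    """
    if not focal_genes:
        raise ValueError("focal gene set is empty")
    if not focal_genes <= all_genes:
        raise ValueError("focal genes must be a subset of all genes")
    pool = sorted(all_genes if include_focal_in_pool else all_genes - focal_genes)
    k = len(focal_genes)
    if len(pool) < k:
        raise ValueError("background pool smaller than the focal set")
    rng = np.random.default_rng(seed)
    a = sum(in_synteny[g] for g in focal_genes)
    b = k - a
    cs, ds = [], []
    for _ in range(n_reps):
        draw = rng.choice(len(pool), size=k, replace=False)
        c = sum(in_synteny[pool[i]] for i in draw)
        cs.append(c)
        ds.append(k - c)
    c = int(round(float(np.mean(cs))))
    d = k - c
    table = np.array([[a, b], [c, d]], dtype=int)
    p = stats.fisher_exact_2x2(table)
    or_, lo, hi = stats.odds_ratio_ci(table)
    return SyntenyEnrichmentResult(table, or_, lo, hi, p, seed, k, n_reps)
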