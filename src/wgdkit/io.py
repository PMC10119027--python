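"""Readers and writers for the external formats the pipeline consumes.

All tabular formats are UTF-8, tab-delimited, with a header row. Genomic
coordinates are held 0-based half-open internally; GFF3 input/output
converts from/to the 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from .errors import ConsistencyError, FormatError

STRANDS = ("+", "-", "?")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript isoform of a gene; ``tss`` is 1-based."""

    transcript_id: str
    gene_id: str
    chrom: str
    tss: int
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"transcript {self.transcript_id}: length must be > 0")


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus; ``start`` is 0-based. ``placed`` is False when the gene
    sits on an unplaced scaffold rather than an assembled chromosome."""

    gene_id: str
    species: str
    chrom: str
    start: int
    strand: str = "?"
    placed: bool = True

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: start must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class HomoeologPairs:
    """Per-species sets of unordered homoeologous chromosome pairs.

    Homoeologous chromosomes descend from the two duplicated subgenomes of a
    whole-genome duplication; a duplicate pair residing on such chromosomes
    is the positional signature of an ohnolog.
    """

    def __init__(self, pairs: dict[str, set[frozenset]] | None = None):
        self._pairs: dict[str, set[frozenset]] = {}
        for species, ps in (pairs or {}).items():
            for p in ps:
                self.add(species, *tuple(p))

    def add(self, species: str, chrom_a: str, chrom_b: str) -> None:
        if chrom_a == chrom_b:
            raise ValueError(f"homoeolog pair must join two distinct chromosomes: {chrom_a}")
        self._pairs.setdefault(species, set()).add(frozenset((chrom_a, chrom_b)))

    def is_pair(self, species: str, chrom_a: str, chrom_b: str) -> bool:
        return frozenset((chrom_a, chrom_b)) in self._pairs.get(species, set())

    def species(self) -> list[str]:
        return sorted(self._pairs)

    def pairs_for(self, species: str) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs.get(species, set()))


# ---------------------------------------------------------------------------
# gene-family tables (Orthofinder-style dialects)
# ---------------------------------------------------------------------------

def read_gene_count_table(path) -> pd.DataFrame:
    """Read a family-by-species gene count table (GeneCount.tsv dialect).

    First column: family id; one integer column per species; an optional
    trailing ``Total`` column is dropped (it is derivable and never trusted).
    Returns a DataFrame indexed by family id, columns in file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if df.columns.size == 0:
        raise FormatError(f"{path}: no species columns found")
    if df.columns[-1] == "Total":
        df = df.iloc[:, :-1]
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(f"{path}: non-numeric count at family {bad!r}, column {col!r}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ValueError(f"{path}: negative count at family {bad!r}, column {col!r}")
        if (vals != vals.astype(int)).any():
            bad = df.index[vals != vals.astype(int)][0]
            raise ValueError(f"{path}: non-integer count at family {bad!r}, column {col!r}")
        out[col] = vals.astype(int)
    out.index.name = df.index.name or "family_id"
    return out


def write_gene_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "family_id")


def read_family_membership(path) -> dict[str, dict[str, list[str]]]:
    """Read an Orthogroups.tsv-dialect membership table.

    Columns after the family id hold per-species gene lists joined by
    ``", "``. Returns family -> species -> list of gene ids (empty cells
    become empty lists).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    out: dict[str, dict[str, list[str]]] = {}
    for fam, row in df.iterrows():
        out[fam] = {
            sp: [g for g in (cell.split(", ") if cell else []) if g]
            for sp, cell in row.items()
        }
    return out


def write_family_membership(membership: dict[str, dict[str, list[str]]], path,
                            species_order: list[str] | None = None) -> None:
    if species_order is None:
        species_order = sorted({sp for fams in membership.values() for sp in fams})
    rows = {
        fam: {sp: ", ".join(fams.get(sp, [])) for sp in species_order}
        for fam, fams in membership.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=species_order)
    df.to_csv(path, sep="\t", index_label="family_id")


def check_membership_counts(counts: pd.DataFrame,
                            membership: dict[str, dict[str, list[str]]]) -> None:
    """Assert that membership list lengths match the count table."""
    for fam in counts.index:
        if fam not in membership:
            raise ConsistencyError(f"family {fam!r} missing from membership table")
        for sp in counts.columns:
            n = len(membership[fam].get(sp, []))
            if n != counts.at[fam, sp]:
                raise ConsistencyError(
                    f"family {fam!r}, species {sp!r}: count {counts.at[fam, sp]} "
                    f"!= {n} member genes"
                )


def read_homoeolog_pairs(path) -> HomoeologPairs:
    """Read a homoeolog-pair table with columns species, chrom_a, chrom_b."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if df.columns.size < 3:
        raise FormatError(f"{path}: expected columns species, chrom_a, chrom_b")
    hp = HomoeologPairs()
    for _, row in df.iterrows():
        hp.add(row.iloc[0], row.iloc[1], row.iloc[2])
    return hp


def write_homoeolog_pairs(pairs: HomoeologPairs, path) -> None:
    rows = [
        (sp, a, b)
        for sp in pairs.species()
        for a, b in pairs.pairs_for(sp)
    ]
    pd.DataFrame(rows, columns=["species", "chrom_a", "chrom_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff_genes(path, chromosome_list: set[str], species: str = "") -> list[GeneRecord]:
    """Read gene features from a GFF3 file.

    1-based inclusive GFF starts become 0-based internal starts. A gene is
    ``placed`` iff its seqid is in ``chromosome_list`` (supplied explicitly
    because assembly naming schemes vary).
    """
    path = Path(path)
    _prescan_gff(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    chromosome_list = set(chromosome_list)
    out = []
    for feat in db.features_of_type("gene"):
        strand = feat.strand if feat.strand in ("+", "-") else "?"
        out.append(
            GeneRecord(
                gene_id=feat.id,
                species=species,
                chrom=feat.seqid,
                start=feat.start - 1,
                strand=strand,
                placed=feat.seqid in chromosome_list,
            )
        )
    return out


def _prescan_gff(path: Path) -> None:
    """Cheap structural validation providing line numbers for errors."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates")
            if start < 1 or end < start:
                raise FormatError(f"{path}: line {lineno}: bad coordinate range")


def write_gff_genes(genes: list[GeneRecord], path, source: str = "wgdkit") -> None:
    """Write gene records as minimal single-feature GFF3 (length 1 loci are
    written as 1 bp features; wgdkit only consumes start positions)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.start + 1}\t.\t"
                f"{strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# isoform filtering
# ---------------------------------------------------------------------------

def longest_isoform_filter(transcripts: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep one transcript per gene: the longest, ties broken by the
    lexicographically smallest transcript id. Output follows first-seen
    gene order, making the filter idempotent."""
    best: dict[str, TranscriptRecord] = {}
    order: list[str] = []
    for t in transcripts:
        cur = best.get(t.gene_id)
        if cur is None:
            best[t.gene_id] = t
            order.append(t.gene_id)
        elif t.length > cur.length or (
            t.length == cur.length and t.transcript_id < cur.transcript_id
        ):
            best[t.gene_id] = t
    return [best[g] for g in order]


# ---------------------------------------------------------------------------
# homology guide
# ---------------------------------------------------------------------------

def write_homology_guide(classification: pd.DataFrame,
                         membership: dict[str, dict[str, list[str]]],
                         annotations: dict[str, str],
                         path) -> None:
    """Write the per-family homology guide.

    ``classification`` is the long table from ``classify.classify_table``
    (columns family_id, species, category, ...). Output columns per species:
    gene-id list (comma-joined), copy number, category; plus a consensus
    annotation column.
    """
    fams_cls = set(classification["family_id"])
    fams_mem = set(membership)
    if not fams_cls <= fams_mem:
        missing = sorted(fams_cls - fams_mem)[:3]
        raise ConsistencyError(f"families missing from membership: {missing} ...")
    species = sorted(classification["species"].unique())
    wide = classification.set_index(["family_id", "species"])
    rows = []
    for fam in sorted(fams_cls):
        row: dict[str, object] = {"family_id": fam}
        for sp in species:
            genes = membership[fam].get(sp, [])
            row[f"{sp}__genes"] = ",".join(genes)
            row[f"{sp}__count"] = len(genes)
            row[f"{sp}__category"] = wide.at[(fam, sp), "category"]
        row["annotation"] = annotations.get(fam, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_homology_guide(path) -> pd.DataFrame:
    """Read a homology guide back into a DataFrame (lossless round-trip of
    :func:`write_homology_guide` output)."""
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    if "family_id" not in df.columns:
        raise FormatError(f"{path}: missing family_id column")
    for col in df.columns:
        if col.endswith("__count"):
            df[col] = df[col].astype(int)
    return df


# ---------------------------------------------------------------------------
# misc small tables
# ---------------------------------------------------------------------------

def read_chromosome_lengths(path) -> dict[str, int]:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file or missing header") from None
    return {str(row.iloc[0]): int(row.iloc[1]) for _, row in df.iterrows()}


def write_chromosome_lengths(lengths: dict[str, int], path) -> None:
    pd.DataFrame(sorted(lengths.items()), columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False
    )
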