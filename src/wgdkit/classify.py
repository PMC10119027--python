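"""Copy-number classification of gene families after a whole-genome duplication.

Each family in each focal species is labelled by comparing its copy number f
to the count o in an unduplicated outgroup:

* ``contracting``  f < o
* ``singleton``    f = o   (family back at the pre-duplication copy number)
* ``resolving``    o < f < 2o  (duplicate loss under way, not yet complete)
* ``ohnolog``      f = 2o, and for 2:1 families the two copies must lie on a
  declared homoeologous chromosome pair; larger exact doublings are accepted
  without the placement check
* ``paralog``      f = 2, o = 1 but the placement check fails (same
  chromosome, non-homoeologous chromosomes, or an unplaced copy) — i.e. a
  small-scale duplicate rather than a duplication-retained ohnolog
* ``expanding``    f > 2o

Families absent from the focal species (f = 0) or the outgroup (o = 0) get
the edge labels ``absent`` / ``no_outgroup`` and are excluded from all
percentage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import ConfigurationError
from .io import GeneRecord, HomoeologPairs


class Category(str, Enum):
    OHNOLOG = "ohnolog"
    PARALOG = "paralog"
    SINGLETON = "singleton"
    RESOLVING = "resolving"
    EXPANDING = "expanding"
    CONTRACTING = "contracting"
    ABSENT = "absent"
    NO_OUTGROUP = "no_outgroup"


#: the six substantive categories (edge labels excluded)
CORE_CATEGORIES = (
    Category.CONTRACTING,
    Category.EXPANDING,
    Category.SINGLETON,
    Category.RESOLVING,
    Category.OHNOLOG,
    Category.PARALOG,
)

HOMOEOLOG_PASSED = "passed"
HOMOEOLOG_FAILED = "failed"
HOMOEOLOG_NA = "not_applicable"


def classify_family(focal_count: int, outgroup_count: int,
                    focal_gene_records: list[GeneRecord] = (),
                    homoeologs: HomoeologPairs | None = None,
                    species: str | None = None) -> tuple[Category, str]:
    """Classify one family in one focal species.

    Returns ``(label, homoeolog_check)`` where the check outcome is
    ``passed``/``failed`` only for 2:1 families and ``not_applicable``
    otherwise. In count-only mode (no gene records supplied) a 2:1 family
    cannot pass the check and defaults to ``paralog``.
    """
    f, o = int(focal_count), int(outgroup_count)
    if f < 0 or o < 0:
        raise ValueError("counts must be non-negative")
    if f == 0:
        return Category.ABSENT, HOMOEOLOG_NA
    if o == 0:
        return Category.NO_OUTGROUP, HOMOEOLOG_NA
    if f < o:
        return Category.CONTRACTING, HOMOEOLOG_NA
    if f == o:
        return Category.SINGLETON, HOMOEOLOG_NA
    if f < 2 * o:
        return Category.RESOLVING, HOMOEOLOG_NA
    if f > 2 * o:
        return Category.EXPANDING, HOMOEOLOG_NA
    # f == 2o
    if o >= 2:
        # correspondence of copies to homoeologous chromosomes is not
        # resolvable from counts alone for larger families; accepted as
        # ohnologs without a placement check
        return Category.OHNOLOG, HOMOEOLOG_NA
    if _homoeolog_check(list(focal_gene_records), homoeologs, species):
        return Category.OHNOLOG, HOMOEOLOG_PASSED
    return Category.PARALOG, HOMOEOLOG_FAILED


def _homoeolog_check(records: list[GeneRecord],
                     homoeologs: HomoeologPairs | None,
                     species: str | None) -> bool:
    if len(records) != 2 or homoeologs is None:
        return False
    a, b = records
    if not (a.placed and b.placed):
        return False
    if a.chrom == b.chrom:
        return False  # tandem duplicate, not a homoeolog pair
    sp = species if species is not None else a.species
    return homoeologs.is_pair(sp, a.chrom, b.chrom)


def classify_table(counts: pd.DataFrame,
                   membership: dict[str, dict[str, list[str]]] | None,
                   genes: dict[str, dict[str, GeneRecord]] | None,
                   homoeologs: HomoeologPairs | None,
                   outgroup_species: str) -> pd.DataFrame:
    """Classify every family for every non-outgroup species in ``counts``.

    ``genes`` maps species -> gene_id -> GeneRecord; together with
    ``membership`` it supplies the placement evidence for the 2:1
    homoeolog check. Either may be None for count-only classification.

    Returns a long DataFrame with columns family_id, species, category,
    focal_count, outgroup_count, homoeolog_check.
    """
    if outgroup_species not in counts.columns:
        raise ConfigurationError(
            f"outgroup species {outgroup_species!r} not in count table columns"
        )
    focal_species = [c for c in counts.columns if c != outgroup_species]
    rows = []
    for fam, row in counts.iterrows():
        o = int(row[outgroup_species])
        for sp in focal_species:
            f = int(row[sp])
            records: list[GeneRecord] = []
            if f == 2 and o == 1 and membership is not None and genes is not None:
                ids = membership.get(fam, {}).get(sp, [])
                sp_index = genes.get(sp, {})
                records = [sp_index[g] for g in ids if g in sp_index]
            label, check = classify_family(f, o, records, homoeologs, species=sp)
            rows.append((fam, sp, label.value, f, o, check))
    return pd.DataFrame(
        rows,
        columns=["family_id", "species", "category",
                 "focal_count", "outgroup_count", "homoeolog_check"],
    )


def category_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-species gene counts and percentages by category.

    The gene count of a category is the sum of focal copy numbers over its
    families; percentages are taken over the six substantive categories
    (``absent``/``no_outgroup`` never enter the denominator).
    """
    core = [c.value for c in CORE_CATEGORIES]
    sub = classification[classification["category"].isin(core)]
    gene_counts = (
        sub.pivot_table(index="species", columns="category",
                        values="focal_count", aggfunc="sum", fill_value=0)
        .reindex(columns=core, fill_value=0)
    )
    return summary_from_category_gene_counts(gene_counts)


def summary_from_category_gene_counts(gene_counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages from an already-aggregated species x category gene-count
    table (columns = the six substantive categories)."""
    totals = gene_counts.sum(axis=1)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ZeroDivisionError(f"species with zero categorized genes: {zero}")
    out = []
    for sp, row in gene_counts.iterrows():
        for cat, n in row.items():
            out.append((sp, cat, int(n), 100.0 * n / totals[sp]))
    return pd.DataFrame(out, columns=["species", "category", "genes", "percent"])


@dataclass
class RetentionSets:
    """Universal / species-specific / any-species family sets for the
    ohnolog and singleton categories."""

    universal_ohnologs: set = field(default_factory=set)
    universal_singletons: set = field(default_factory=set)
    specific_ohnologs: dict = field(default_factory=dict)    # species -> set
    specific_singletons: dict = field(default_factory=dict)  # species -> set
    any_ohnologs: set = field(default_factory=set)
    any_singletons: set = field(default_factory=set)


def retention_sets(classification: pd.DataFrame,
                   species_list: list[str] | None = None) -> RetentionSets:
    """Universal (all listed species), species-specific (exactly one) and
    present-in-any family sets for ohnologs and singletons."""
    if species_list is None:
        species_list = sorted(classification["species"].unique())
    if len(species_list) == 0:
        raise ConfigurationError("species list is empty")
    sub = classification[classification["species"].isin(species_list)]
    out = RetentionSets()
    for cat, universal, specific, anyset in (
        ("ohnolog", "universal_ohnologs", "specific_ohnologs", "any_ohnologs"),
        ("singleton", "universal_singletons", "specific_singletons", "any_singletons"),
    ):
        hits = sub[sub["category"] == cat]
        per_family = hits.groupby("family_id")["species"].apply(set)
        setattr(out, universal,
                set(per_family.index[per_family.apply(len) == len(species_list)]))
        setattr(out, anyset, set(per_family.index))
        spec: dict[str, set] = {sp: set() for sp in species_list}
        solo = per_family[per_family.apply(len) == 1]
        for fam, sps in solo.items():
            spec[next(iter(sps))].add(fam)
        setattr(out, specific, spec)
    return out
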