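"""Fisher-mode GO enrichment of binary gene labels against a custom
background.

The background is typically built from an outgroup's functional annotation:
each focal gene (or family) inherits the GO terms of its outgroup homolog,
so the test asks which terms are overrepresented among label-1 genes
(e.g. universally retained ohnologs) relative to the rest of that same
background. Terms are size-filtered, tested with a two-sided Fisher exact
test, corrected by Benjamini-Hochberg within each ontology, and clustered
by gene-set overlap so near-redundant terms share a representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import stats
from .errors import FormatError

logger = logging.getLogger(__name__)

ONTOLOGIES = ("CC", "MF", "BP")

DEFAULT_SMALLEST = 50
DEFAULT_LARGEST_FRAC = 0.25
DEFAULT_CUT_HEIGHT = 0.25
DEFAULT_FDR = 0.05


@dataclass
class GoAnnotation:
    """gene -> term-id set plus term metadata (name, ontology)."""

    gene_terms: dict[str, set[str]]
    term_meta: pd.DataFrame  # index term_id; columns name, ontology

    def __post_init__(self):
        terms_used = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        missing = terms_used - set(self.term_meta.index)
        if missing:
            raise ValueError(f"terms without metadata: {sorted(missing)[:3]} ...")
        bad = set(self.term_meta["ontology"]) - set(ONTOLOGIES)
        if bad:
            raise ValueError(f"unknown ontologies: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_terms)

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.term_meta.index}
        for g, ts in self.gene_terms.items():
            for t in ts:
                out[t].add(g)
        return out


def read_annotation(gene_path, term_path) -> GoAnnotation:
    """Read gene->terms (columns gene_id, terms comma-separated) and term
    metadata (columns term_id, name, ontology) TSVs."""
    try:
        genes = pd.read_csv(gene_path, sep="\t", dtype=str, keep_default_na=False)
        meta = pd.read_csv(term_path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError("empty annotation file") from None
    for need, df, path in ((["gene_id", "terms"], genes, gene_path),
                           (["term_id", "name", "ontology"], meta, term_path)):
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    gene_terms = {
        r.gene_id: {t for t in r.terms.split(",") if t}
        for r in genes.itertuples(index=False)
    }
    return GoAnnotation(gene_terms, meta.set_index("term_id")[["name", "ontology"]])


def write_annotation(ann: GoAnnotation, gene_path, term_path) -> None:
    pd.DataFrame(
        [(g, ",".join(sorted(ts))) for g, ts in sorted(ann.gene_terms.items())],
        columns=["gene_id", "terms"],
    ).to_csv(gene_path, sep="\t", index=False)
    ann.term_meta.to_csv(term_path, sep="\t", index_label="term_id")


def filter_terms(ann: GoAnnotation, smallest: int = DEFAULT_SMALLEST,
                 largest_frac: float = DEFAULT_LARGEST_FRAC) -> GoAnnotation:
    """Drop terms annotating fewer than ``smallest`` genes (inclusive
    threshold: exactly ``smallest`` is kept) or more than
    ``largest_frac`` of the background."""
    n_bg = len(ann.gene_terms)
    keep = {
        t for t, gs in ann.term_genes().items()
        if smallest <= len(gs) <= largest_frac * n_bg
    }
    gene_terms = {g: ts & keep for g, ts in ann.gene_terms.items()}
    return GoAnnotation(gene_terms, ann.term_meta.loc[sorted(keep)])


def term_dissimilarity(ann: GoAnnotation) -> tuple[list[str], np.ndarray]:
    """Pairwise term dissimilarity d(A,B) = 1 - |A∩B| / min(|A|,|B|)."""
    terms = sorted(t for t, gs in ann.term_genes().items() if gs)
    genes = ann.genes
    gi = {g: i for i, g in enumerate(genes)}
    m = np.zeros((len(genes), len(terms)), dtype=bool)
    tg = ann.term_genes()
    for j, t in enumerate(terms):
        for g in tg[t]:
            m[gi[g], j] = True
    inter = m.T.astype(np.int64) @ m.astype(np.int64)
    sizes = m.sum(axis=0)
    mins = np.minimum.outer(sizes, sizes)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / mins
    np.fill_diagonal(d, 0.0)
    return terms, d


def cluster_terms(ann: GoAnnotation,
                  cut_height: float = DEFAULT_CUT_HEIGHT) -> dict[str, int]:
    """Complete-linkage clustering of terms on overlap dissimilarity, tree
    cut at ``cut_height``. Returns term -> cluster id. Terms annotating no
    genes form singleton clusters."""
    terms, d = term_dissimilarity(ann)
    out: dict[str, int] = {}
    if len(terms) == 1:
        out[terms[0]] = 1
    elif terms:
        z = linkage(squareform(d, checks=False), method="complete")
        labels = fcluster(z, t=cut_height, criterion="distance")
        out = {t: int(c) for t, c in zip(terms, labels)}
    nxt = max(out.values(), default=0)
    for t in ann.term_meta.index:
        if t not in out:
            nxt += 1
            out[t] = nxt
    return out


def fisher_enrichment(ann: GoAnnotation, labels: dict[str, int],
                      fdr: float = DEFAULT_FDR,
                      ontologies: tuple[str, ...] = ("CC", "MF"),
                      cut_height: float = DEFAULT_CUT_HEIGHT) -> pd.DataFrame:
    """Per-term Fisher enrichment of label-1 genes over the background.

    For each term the 2x2 table (in term, not) x (label 1, label 0) is
    tested two-sided; q-values are Benjamini-Hochberg within each ontology;
    each overlap cluster is represented by its member with the smallest p.

    ``labels`` must cover every background gene. Returns a DataFrame with
    one row per tested term.
    """
    missing = set(ann.gene_terms) - set(labels)
    if missing:
        raise ValueError(f"labels missing for genes: {sorted(missing)[:3]} ...")
    n_bg = len(ann.gene_terms)
    n1 = sum(labels[g] for g in ann.gene_terms)
    if n1 == 0:
        raise ValueError("no label-1 genes in the background")
    tg = ann.term_genes()
    clusters = cluster_terms(ann, cut_height)
    rows = []
    for ont in ontologies:
        terms = [t for t in ann.term_meta.index
                 if ann.term_meta.at[t, "ontology"] == ont]
        if not terms:
            continue
        recs = []
        for t in terms:
            gs = tg[t]
            k = len(gs)
            k1 = sum(labels[g] for g in gs)
            table = [[k1, k - k1], [n1 - k1, (n_bg - k) - (n1 - k1)]]
            p = stats.fisher_exact_2x2(table)
            recs.append((t, k1, k, p))
        q = stats.bh_fdr([r[3] for r in recs])
        for (t, k1, k, p), qv in zip(recs, q):
            rows.append({
                "term_id": t,
                "name": ann.term_meta.at[t, "name"],
                "ontology": ont,
                "n_label1_in_term": k1,
                "n_term": k,
                "n_label1_total": n1,
                "n_background": n_bg,
                "p_value": p,
                "q_value": qv,
                "significant": qv < fdr,
                "cluster": clusters[t],
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    rep = df.loc[df.groupby("cluster")["p_value"].idxmin(), ["cluster", "term_id"]]
    df = df.merge(rep.rename(columns={"term_id": "cluster_representative"}),
                  on="cluster")
    return df.sort_values(["ontology", "p_value", "term_id"]).reset_index(drop=True)


def map_background(focal_to_outgroup: dict[str, str],
                   outgroup_annotation: GoAnnotation) -> GoAnnotation:
    """Build a background in which each focal gene inherits its outgroup
    homolog's GO terms; focal genes whose homolog is absent from the
    outgroup annotation are dropped (count logged)."""
    gene_terms = {}
    dropped = 0
    for focal, homolog in focal_to_outgroup.items():
        if homolog in outgroup_annotation.gene_terms:
            gene_terms[focal] = set(outgroup_annotation.gene_terms[homolog])
        else:
            dropped += 1
    if dropped:
        logger.info("map_background: dropped %d genes with no outgroup homolog annotation",
                    dropped)
    return GoAnnotation(gene_terms, outgroup_annotation.term_meta)
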