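"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* gene-family copy-number vectors under a 2:1 whole-genome duplication with
  a configurable category mixture and homoeolog-aware gene placement;
* synteny blocks covering a target genome fraction, with ohnolog genes
  relocated within their chromosome so that the odds ratio of
  ohnolog-vs-other synteny membership matches a planted value;
* expression counts drawn from the exact OU sample covariance on a
  three-population tree with per-gene beta (latent trait matrix Poisson-
  thinned into integer counts);
* GO annotations with one planted enriched term.

Every generator is a deterministic function of its config (including the
seed); all emitted tables parse through :mod:`wgdkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .classify import Category
from .eve import OUGeneParams, PopulationTree, ou_covariance
from .go import GoAnnotation
from .io import GeneRecord, HomoeologPairs
from .synteny import SyntenyBlock

#: family-level category mixture. Ohnolog families are kept just under the
#: point where their genes (two per family) would exceed half the gene
#: repertoire, so size-matched downsampling from the complement stays
#: feasible for the synteny enrichment test.
DEFAULT_CATEGORY_MIX = {
    "ohnolog": 0.32,
    "singleton": 0.40,
    "paralog": 0.07,
    "resolving": 0.05,
    "expanding": 0.07,
    "contracting": 0.09,
}

#: three-population tree mirroring a locally adapted population triplet
#: (cold montane / cool montane / warm desert). Branch lengths are set so
#: that at the default pull strength alpha=1 the between-population
#: expression correlations exp(-alpha*d) are small (0.14 / 0.02): strongly
#: locally adapted populations have effectively independent expression
#: optima, which is the regime in which the beta-shared test is informative.
DEFAULT_NEWICK = "((cold_montane:1.0,cool_montane:1.0):1.0,warm_desert:2.0);"


@dataclass
class SyntenySimConfig:
    n_blocks: int = 200
    genome_length: int = 100_000_000
    coverage: float = 0.45
    ohnolog_or: float = 1.5


@dataclass
class ExpressionSimConfig:
    n_genes: int = 500
    newick: str = DEFAULT_NEWICK
    samples_per_pop: int = 10
    beta_null: float = 2.0
    beta_divergent: float = 0.2
    divergent_fraction: float = 0.1
    alpha: float = 1.0
    v: float = 1.0
    depth: float = 1.0
    mu_low: float = 4.0
    mu_high: float = 8.0


@dataclass
class GoSimConfig:
    n_genes: int = 5000
    n_terms: int = 200
    label_fraction: float = 0.1
    enrichment_factor: float = 3.0
    min_term_size: int = 20
    max_term_frac: float = 0.3
    planted_size: int = 200


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 2000
    n_species: int = 3
    category_mix: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    universal_fraction: float = 0.4
    outgroup_multicopy_prob: float = 0.1
    n_homoeolog_pairs: int = 5
    synteny: SyntenySimConfig = field(default_factory=SyntenySimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    go: GoSimConfig = field(default_factory=GoSimConfig)

    def validate(self) -> None:
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category_mix sums to {total}, expected 1")
        valid = {c.value for c in Category} - {"absent", "no_outgroup"}
        bad = set(self.category_mix) - valid
        if bad:
            raise ConfigurationError(f"unknown categories in mix: {sorted(bad)}")
        needs_multi = {"resolving", "contracting"}
        if self.outgroup_multicopy_prob == 0 and any(
            self.category_mix.get(c, 0) > 0 for c in needs_multi
        ):
            raise ConfigurationError(
                "resolving/contracting require outgroup_multicopy_prob > 0"
            )
        if self.outgroup_multicopy_prob == 1 and self.category_mix.get("paralog", 0) > 0:
            raise ConfigurationError(
                "paralog (a 2:1 category) requires outgroup_multicopy_prob < 1"
            )
        if not 0 < self.synteny.coverage < 1:
            raise ConfigurationError("synteny coverage must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


OUTGROUP = "outgroup"


@dataclass
class HomologySim:
    counts: pd.DataFrame
    membership: dict[str, dict[str, list[str]]]
    genes: dict[str, dict[str, GeneRecord]]          # species -> gene_id -> record
    homoeologs: HomoeologPairs
    chrom_lengths: dict[str, dict[str, int]]         # species -> chrom -> bp
    truth: pd.DataFrame                               # family_id, species, category

    @property
    def focal_species(self) -> list[str]:
        return [c for c in self.counts.columns if c != OUTGROUP]


def _focal_count(category: str, o: int) -> int:
    return {
        "contracting": o - 1,
        "singleton": o,
        "resolving": o + 1,
        "ohnolog": 2 * o,
        "paralog": 2,
        "expanding": 2 * o + 1,
    }[category]


def _feasible(category: str, o: int) -> bool:
    if category in ("resolving", "contracting"):
        return o >= 2
    if category == "paralog":
        return o == 1
    return True


def simulate_homology_dataset(cfg: SimConfig) -> HomologySim:
    """Draw per-family categories and emit counts, membership, gene records,
    homoeolog pairs and the truth labels the classifier must recover.

    A ``universal_fraction`` of families receives one category in every
    focal species; the remainder draw independently per species from the
    mixture (restricted to categories feasible for the family's outgroup
    count). Ohnolog families place their two copies on a declared homoeolog
    pair; paralog families violate the placement requirement in one of the
    three ways the classifier must detect (same chromosome, non-homoeologous
    chromosomes, or an unplaced copy).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = [f"species_{i + 1}" for i in range(cfg.n_species)]
    n_chrom = 2 * cfg.n_homoeolog_pairs
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    pairs = [(chroms[2 * i], chroms[2 * i + 1]) for i in range(cfg.n_homoeolog_pairs)]
    chrom_len = max(cfg.synteny.genome_length // n_chrom, 1000)
    homoeologs = HomoeologPairs()
    for sp in species:
        for a, b in pairs:
            homoeologs.add(sp, a, b)
    homoeolog_set = {frozenset(p) for p in pairs}

    cats = sorted(cfg.category_mix)
    probs = np.array([cfg.category_mix[c] for c in cats])
    out_chroms = [f"ochr{i + 1}" for i in range(10)]

    counts_rows = []
    membership: dict[str, dict[str, list[str]]] = {}
    genes: dict[str, dict[str, GeneRecord]] = {sp: {} for sp in species}
    chrom_lengths = {sp: {c: chrom_len for c in chroms} for sp in species}
    chrom_lengths[OUTGROUP] = {c: chrom_len for c in out_chroms}
    genes[OUTGROUP] = {}
    truth_rows = []
    scaffold_counter = 0

    def _restricted_draw(o: int) -> str:
        ok = np.array([_feasible(c, o) for c in cats], dtype=float)
        p = probs * ok
        return cats[rng.choice(len(cats), p=p / p.sum())]

    for i in range(cfg.n_families):
        fam = f"F{i:06d}"
        universal = rng.random() < cfg.universal_fraction
        if universal:
            cat = cats[rng.choice(len(cats), p=probs)]
            if cat in ("resolving", "contracting"):
                o = 2
            elif cat == "paralog":
                o = 1
            else:
                o = 2 if rng.random() < cfg.outgroup_multicopy_prob else 1
            fam_cats = {sp: cat for sp in species}
        else:
            o = 2 if rng.random() < cfg.outgroup_multicopy_prob else 1
            fam_cats = {sp: _restricted_draw(o) for sp in species}

        membership[fam] = {}
        row = {OUTGROUP: o}
        out_ids = []
        for j in range(o):
            gid = f"{OUTGROUP}_{fam}_g{j}"
            genes[OUTGROUP][gid] = GeneRecord(
                gid, OUTGROUP, out_chroms[rng.integers(len(out_chroms))],
                int(rng.integers(chrom_len)), "+", True,
            )
            out_ids.append(gid)
        membership[fam][OUTGROUP] = out_ids

        for sp in species:
            cat = fam_cats[sp]
            f = _focal_count(cat, o)
            placements: list[tuple[str, bool]] = []
            if cat == "ohnolog" and o == 1:
                a, b = pairs[rng.integers(len(pairs))]
                placements = [(a, True), (b, True)]
            elif cat == "paralog":
                mode = rng.integers(3)
                if mode == 0:  # tandem: both copies on one chromosome
                    c = chroms[rng.integers(n_chrom)]
                    placements = [(c, True), (c, True)]
                elif mode == 1 and cfg.n_homoeolog_pairs >= 2:
                    while True:
                        a, b = rng.choice(n_chrom, size=2, replace=False)
                        ca, cb = chroms[a], chroms[b]
                        if frozenset((ca, cb)) not in homoeolog_set:
                            placements = [(ca, True), (cb, True)]
                            break
                else:  # one copy on an unplaced scaffold
                    scaffold_counter += 1
                    placements = [
                        (chroms[rng.integers(n_chrom)], True),
                        (f"scaffold_{scaffold_counter}", False),
                    ]
            else:
                placements = [
                    (chroms[rng.integers(n_chrom)], True) for _ in range(f)
                ]
            ids = []
            for j, (chrom, placed) in enumerate(placements):
                gid = f"{sp}_{fam}_g{j}"
                genes[sp][gid] = GeneRecord(
                    gid, sp, chrom, int(rng.integers(chrom_len)), "+", placed,
                )
                ids.append(gid)
            membership[fam][sp] = ids
            row[sp] = f
            truth_rows.append((fam, sp, cat))
        counts_rows.append({"family_id": fam, **row})

    counts = pd.DataFrame(counts_rows).set_index("family_id")[species + [OUTGROUP]]
    truth = pd.DataFrame(truth_rows, columns=["family_id", "species", "category"])
    return HomologySim(counts, membership, genes, homoeologs, chrom_lengths, truth)


# ---------------------------------------------------------------------------
# synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenySim:
    blocks: list[SyntenyBlock]
    chrom_lengths: dict[str, int]
    genes: list[GeneRecord]          # positions after relocation
    in_synteny: dict[str, bool]      # realized truth flags


def simulate_synteny_dataset(cfg: SimConfig, genes: list[GeneRecord],
                             is_ohnolog: dict[str, bool],
                             chrom_lengths: dict[str, int],
                             seed: int | None = None) -> SyntenySim:
    """Place blocks covering ``cfg.synteny.coverage`` of the genome and
    relocate ohnolog genes within their own chromosomes so the realized
    ohnolog-vs-other synteny odds ratio matches ``cfg.synteny.ohnolog_or``.

    Relocation keeps each gene on its original chromosome, so homology
    classification truth is unaffected.
    """
    syn = cfg.synteny
    if not 0 < syn.coverage < 1:
        raise ConfigurationError("coverage must be in (0, 1)")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chroms = sorted(chrom_lengths)
    per_chrom = max(1, syn.n_blocks // len(chroms))
    blocks: list[SyntenyBlock] = []
    block_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for ci, chrom in enumerate(chroms):
        length = chrom_lengths[chrom]
        slot = length // per_chrom
        blk_len = max(int(round(slot * syn.coverage)), 1)
        for k in range(per_chrom):
            lo = k * slot
            off = int(rng.integers(0, max(slot - blk_len, 1)))
            s, e = lo + off, lo + off + blk_len
            # alternate strands so downstream same-strand merging is an
            # identity and planted truth flags survive the pipeline
            strand = "+" if k % 2 == 0 else "-"
            blocks.append(SyntenyBlock(chrom, s, e, strand, f"t{ci + 1}", s, e))
            block_spans[chrom].append((s, e))

    def in_blocks(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in block_spans.get(chrom, []))

    flags = {g.gene_id: g.placed and in_blocks(g.chrom, g.start) for g in genes}
    others = [g for g in genes if not is_ohnolog.get(g.gene_id, False)]
    p0 = float(np.mean([flags[g.gene_id] for g in others])) if others else syn.coverage
    if not 0 < p0 < 1:
        raise ConfigurationError("degenerate background synteny rate; adjust coverage")
    ratio = syn.ohnolog_or
    p1 = ratio * p0 / (1 - p0 + ratio * p0)

    new_genes: list[GeneRecord] = []
    for g in genes:
        if not is_ohnolog.get(g.gene_id, False) or not g.placed:
            new_genes.append(g)
            continue
        want_in = bool(rng.random() < p1)
        if flags[g.gene_id] == want_in:
            new_genes.append(g)
            continue
        spans = block_spans.get(g.chrom, [])
        if want_in:
            lens = np.array([e - s for s, e in spans], dtype=float)
            k = int(rng.choice(len(spans), p=lens / lens.sum()))
            pos = int(rng.integers(spans[k][0], spans[k][1]))
        else:
            pos = None
            for _ in range(10_000):
                cand = int(rng.integers(0, chrom_lengths[g.chrom]))
                if not in_blocks(g.chrom, cand):
                    pos = cand
                    break
            if pos is None:
                raise ConfigurationError("could not place gene outside blocks")
        moved = GeneRecord(g.gene_id, g.species, g.chrom, pos, g.strand, g.placed)
        new_genes.append(moved)
        flags[g.gene_id] = want_in
    return SyntenySim(blocks, dict(chrom_lengths), new_genes, flags)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    latent: pd.DataFrame        # genes x samples, the exact OU trait values
    counts: pd.DataFrame        # Poisson-thinned integer counts
    sample_pops: dict[str, str]
    newick: str
    tree: PopulationTree
    truth: pd.DataFrame         # gene_id, beta_true, divergent, mu


def simulate_expression_dataset(cfg: SimConfig, seed: int | None = None) -> ExpressionSim:
    """Draw per-gene trait vectors from the exact OU sample covariance on
    the configured population tree, with a ``divergent_fraction`` of genes
    at ``beta_divergent`` and the rest at ``beta_null``, then emit integer
    counts via Poisson(depth * 2^latent)."""
    e = cfg.expression
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tree = PopulationTree.from_newick(e.newick)
    samples = []
    sample_pops = {}
    for pop in tree.tips:
        for j in range(e.samples_per_pop):
            name = f"{pop}_s{j + 1}"
            samples.append(name)
            sample_pops[name] = pop
    pops = [sample_pops[s] for s in samples]

    chols = {}
    for beta in {e.beta_null, e.beta_divergent}:
        cov = ou_covariance(tree, pops, OUGeneParams(0.0, e.alpha, e.v, beta))
        chols[beta] = np.linalg.cholesky(cov)

    n_div = int(round(e.n_genes * e.divergent_fraction))
    divergent = np.zeros(e.n_genes, dtype=bool)
    if n_div:
        divergent[rng.choice(e.n_genes, size=n_div, replace=False)] = True

    mus = rng.uniform(e.mu_low, e.mu_high, size=e.n_genes)
    latent = np.empty((e.n_genes, len(samples)))
    for i in range(e.n_genes):
        beta = e.beta_divergent if divergent[i] else e.beta_null
        z = rng.standard_normal(len(samples))
        latent[i] = mus[i] + chols[beta] @ z

    gene_ids = [f"g{i:05d}" for i in range(e.n_genes)]
    latent_df = pd.DataFrame(latent, index=gene_ids, columns=samples)
    counts = rng.poisson(e.depth * np.exp2(latent))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "beta_true": np.where(divergent, e.beta_divergent, e.beta_null),
        "divergent": divergent,
        "mu": mus,
    }).set_index("gene_id")
    return ExpressionSim(latent_df, counts_df, sample_pops, e.newick, tree, truth)


# ---------------------------------------------------------------------------
# GO
# ---------------------------------------------------------------------------

@dataclass
class GoSim:
    annotation: GoAnnotation
    labels: dict[str, int]
    planted_term: str
    truth: pd.DataFrame  # term_id, size, planted


def simulate_go_dataset(cfg: SimConfig, seed: int | None = None) -> GoSim:
    """Random GO annotation with log-uniform term sizes and one planted term
    whose label-1 density is multiplied by ``enrichment_factor``."""
    g = cfg.go
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = [f"g{i:05d}" for i in range(g.n_genes)]
    max_size = int(g.max_term_frac * g.n_genes)
    sizes = np.exp(
        rng.uniform(np.log(g.min_term_size), np.log(max_size), size=g.n_terms)
    ).astype(int)
    sizes[0] = g.planted_size
    gene_terms: dict[str, set[str]] = {gid: set() for gid in genes}
    meta_rows = []
    term_ids = []
    for t in range(g.n_terms):
        tid = f"T{t:04d}"
        term_ids.append(tid)
        members = rng.choice(g.n_genes, size=sizes[t], replace=False)
        for m in members:
            gene_terms[genes[m]].add(tid)
        meta_rows.append((tid, f"simulated term {t}", "CC" if t % 2 == 0 else "MF"))
    meta = pd.DataFrame(meta_rows, columns=["term_id", "name", "ontology"]).set_index("term_id")
    annotation = GoAnnotation(gene_terms, meta)

    planted = term_ids[0]
    p_in = min(1.0, g.enrichment_factor * g.label_fraction)
    labels = {}
    for gid in genes:
        p = p_in if planted in gene_terms[gid] else g.label_fraction
        labels[gid] = int(rng.random() < p)
    truth = pd.DataFrame({
        "term_id": term_ids,
        "size": sizes,
        "planted": [t == planted for t in term_ids],
    }).set_index("term_id")
    return GoSim(annotation, labels, planted, truth)
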