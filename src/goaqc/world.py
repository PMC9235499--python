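"""Fully synthetic study world: ontology, genes, abstracts, consistent GOA.

The generator emulates the shape of the real inputs (a gene2go-style sample
of experimentally evidenced annotations, PubMed titles+abstracts, and the GO
hierarchy) without any biomedical realism beyond mention placement:

* the ontology is a level-wise random DAG over both ``is_a`` and ``part_of``
  edges; a child's name extends its primary parent's name by one leading
  modifier token (mirroring GO naming such as "response to calcium ion" →
  "cellular response to calcium ion"), so term names are unique, dictionary
  matching is unambiguous, and depth is reflected in the name;
* the relation kind of an edge is a deterministic function of the child's
  depth (edges in the deeper half of the hierarchy are ``part_of``), an
  analogue of the namespace-correlated ``part_of`` density in real GO that
  makes edge types predictable from structural node features;
* each document cites at least two genes and embeds, with probability
  ``signal``, the canonical name of every annotated term in a sentence that
  also carries the annotated gene's symbol; distractor term mentions are
  inserted in gene-free sentences so irrelevant-mention synthesis has
  material;
* annotated terms are drawn from all non-root levels with the deepest level
  down-weighted (annotation bias toward mid-depth terms), keeping the
  over-specific synthesis skip rate low;
* everything is driven by a single seeded generator and is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Document, GeneProduct, GOAInstance
from .errors import CapacityError
from .ontology import GODag, GOTerm
from .recognize import build_dictionary, recognize

# Closed pseudo-vocabularies.  Name words (modifiers + heads) never overlap
# filler/verb words, so an abstract can only contain a term name where one
# was deliberately embedded.
_MODIFIERS = [
    "apical", "basal", "cellular", "nuclear", "mitotic", "cortical", "axonal",
    "dendritic", "ciliary", "vesicular", "lysosomal", "peroxisomal", "somatic",
    "germline", "larval", "embryonic", "adult", "ventral", "dorsal", "lateral",
    "medial", "anterior", "posterior", "proximal", "distal", "radial", "polar",
    "septal", "spindle", "chromatin", "telomeric", "centromeric", "ribosomal",
    "proteasomal", "glycolytic", "oxidative", "reductive", "hydrolytic",
    "synaptic", "junctional", "membranous", "fibrillar", "granular", "tubular",
    "lamellar", "vacuolar", "stromal", "luminal", "endosomal", "exosomal",
    "perinuclear", "cytosolic", "flagellar", "microtubular", "filamentous",
    "karyomeric", "plastidial", "thylakoid", "chemotactic", "osmotic",
]
_HEADS = [
    "assembly", "disassembly", "transport", "localization", "biogenesis",
    "maturation", "fusion", "fission", "elongation", "condensation",
    "segregation", "replication", "transcription", "translation", "splicing",
    "folding", "degradation", "ubiquitination", "phosphorylation",
    "methylation", "acetylation", "glycosylation", "secretion", "uptake",
    "efflux", "signaling", "adhesion", "migration", "differentiation",
    "proliferation", "apoptosis", "autophagy", "polarization", "budding",
    "docking", "tethering", "remodeling", "licensing", "silencing",
    "activation", "repression", "oscillation", "gating", "pairing",
    "recombination", "repair", "import", "export", "sorting", "anchoring",
]
_FILLERS = [
    "we", "show", "that", "the", "of", "in", "a", "an", "this", "these",
    "results", "analysis", "data", "observed", "during", "under", "with",
    "after", "before", "robust", "marked", "notable", "was", "were", "is",
    "are", "findings", "suggest", "role", "process", "pathway", "levels",
    "conditions", "cells", "extracts", "samples", "assays", "experiments",
    "strongly", "weakly",
]
_VERBS = [
    "mediates", "regulates", "promotes", "inhibits", "drives", "controls",
    "modulates", "sustains", "triggers", "restrains", "governs", "enables",
    "limits", "supports", "accelerates",
]
_SYMBOL_LETTERS = "BCDFGHKLMNPRSTVWYZ"

DEFAULT_TAXA = (9606, 7227, 10116, 3702, 6239)

_EVIDENCE_CODES = ("EXP", "IDA", "IPI", "IMP", "IGI", "IEP")


@dataclass(frozen=True)
class WorldConfig:
    """Generation knobs; defaults size the world for the full default study."""

    n_terms: int = 400
    n_levels: int = 6
    max_children: int = 6
    n_genes: int = 300
    n_taxa: int = 5
    n_documents: int = 6000
    annotations_per_doc: int = 4
    signal: float = 1.0
    distractor_mentions_per_doc: int = 2
    extra_parent_prob: float = 0.2
    partition_by_taxon: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.signal <= 1.0):
            raise ValueError("signal must lie in [0, 1]")
        for name in ("n_terms", "n_levels", "n_genes", "n_taxa", "n_documents",
                     "annotations_per_doc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def taxa(self) -> tuple[int, ...]:
        base = list(DEFAULT_TAXA)
        while len(base) < self.n_taxa:
            base.append(10000 + len(base))
        return tuple(base[: self.n_taxa])


@dataclass
class World:
    """A generated study world; ``annotations`` are all consistent (CO)."""

    config: WorldConfig
    dag: GODag
    genes: dict[int, GeneProduct]
    docs: dict[str, Document]
    annotations: list[GOAInstance]
    term_taxon: dict[str, int] = field(default_factory=dict)


def _level_sizes(n_terms: int, n_levels: int) -> list[int]:
    weights = np.array([1.7 ** k for k in range(n_levels)])
    sizes = np.maximum(1, np.floor(n_terms * weights / weights.sum()).astype(int))
    sizes[0] = min(max(1, sizes[0]), 3)
    while sizes.sum() > n_terms:
        sizes[int(np.argmax(sizes))] -= 1
    while sizes.sum() < n_terms:
        sizes[-1] += 1
    return [int(s) for s in sizes]


def _build_dag(cfg: WorldConfig, rng: np.random.Generator) -> tuple[GODag, list[list[str]]]:
    sizes = _level_sizes(cfg.n_terms, cfg.n_levels)
    split_level = cfg.n_levels // 2  # children deeper than this attach via part_of
    terms: list[GOTerm] = []
    edges: list[tuple[str, str, str]] = []
    levels: list[list[str]] = []
    names_used: set[str] = set()
    names: dict[str, str] = {}
    child_count: dict[str, int] = {}
    idx = 0
    for level, size in enumerate(sizes):
        level_ids: list[str] = []
        for _ in range(size):
            tid = f"GO:{7000000 + idx:07d}"
            idx += 1
            if level == 0:
                while True:
                    name = " ".join(
                        [rng.choice(_MODIFIERS), rng.choice(_HEADS), rng.choice(_HEADS)]
                    )
                    if name not in names_used:
                        break
            else:
                prev = levels[level - 1]
                capacity = [p for p in prev if child_count.get(p, 0) < cfg.max_children]
                parent = rng.choice(capacity if capacity else prev)
                child_count[parent] = child_count.get(parent, 0) + 1
                while True:
                    name = f"{rng.choice(_MODIFIERS)} {names[parent]}"
                    if name not in names_used:
                        break
                etype = "is_a" if level <= split_level else "part_of"
                edges.append((tid, parent, etype))
                if len(prev) > 1 and rng.random() < cfg.extra_parent_prob:
                    others = [p for p in prev if p != parent]
                    extra = rng.choice(others)
                    edges.append((tid, extra, etype))
            names_used.add(name)
            names[tid] = name
            terms.append(GOTerm(term_id=tid, name=name, namespace="synthetic"))
            level_ids.append(tid)
        levels.append(level_ids)
    return GODag(terms, edges), levels


def _make_genes(cfg: WorldConfig, rng: np.random.Generator) -> dict[int, GeneProduct]:
    genes: dict[int, GeneProduct] = {}
    symbols: set[str] = set()
    taxa = cfg.taxa
    for i in range(cfg.n_genes):
        while True:
            letters = "".join(rng.choice(list(_SYMBOL_LETTERS), size=3))
            symbol = f"{letters}{int(rng.integers(1, 99))}"
            if symbol not in symbols:
                break
        symbols.add(symbol)
        gene_id = 100000 + i
        genes[gene_id] = GeneProduct(gene_id, symbol, taxa[i % len(taxa)])
    return genes


def _fill(rng: np.random.Generator, words: list[str], k: int) -> str:
    return " ".join(rng.choice(words, size=k))


def generate_world(cfg: WorldConfig) -> World:
    """Generate ontology, genes, documents and a consistent annotation table."""
    rng = np.random.default_rng(cfg.seed)
    dag, levels = _build_dag(cfg, rng)
    genes = _make_genes(cfg, rng)
    taxa = cfg.taxa
    names = {tid: t.name for tid, t in dag.terms.items()}

    # candidate annotation terms: non-root levels, deepest level down-weighted
    non_root_levels = levels[1:]
    level_weights = np.ones(len(non_root_levels))
    level_weights[-1] = 0.5
    level_weights /= level_weights.sum()
    if cfg.annotations_per_doc > sum(len(lv) for lv in non_root_levels):
        raise CapacityError("annotations_per_doc exceeds the number of annotatable terms")

    # optional taxon partition of annotatable terms (disjoint-vocabulary OOD worlds)
    term_taxon: dict[str, int] = {}
    if cfg.partition_by_taxon:
        for lv in non_root_levels:
            for j, tid in enumerate(lv):
                term_taxon[tid] = taxa[j % len(taxa)]
        per_taxon: dict[int, int] = {t: 0 for t in taxa}
        for t in term_taxon.values():
            per_taxon[t] += 1
        need = cfg.annotations_per_doc + 1
        short = {t: c for t, c in per_taxon.items() if c < need}
        if short:
            raise CapacityError(
                f"taxon partition leaves too few annotatable terms for taxa {short}"
            )

    genes_by_taxon: dict[int, list[int]] = {t: [] for t in taxa}
    for gid, g in genes.items():
        genes_by_taxon[g.taxon_id].append(gid)
    for t, gl in genes_by_taxon.items():
        if len(gl) < 2:
            raise CapacityError(f"taxon {t} has fewer than two genes; IG synthesis infeasible")

    # per-taxon filler/verb dialects when partitioned; shared otherwise
    def _dialect(words: list[str], taxon_idx: int) -> list[str]:
        if not cfg.partition_by_taxon:
            return words
        chunk = max(3, len(words) // len(taxa))
        start = (taxon_idx * chunk) % len(words)
        picked = [words[(start + j) % len(words)] for j in range(chunk)]
        return picked

    docs: dict[str, Document] = {}
    annotations: list[GOAInstance] = []
    n_terms_available = sum(len(lv) for lv in non_root_levels)
    for d in range(cfg.n_documents):
        taxon_idx = d % len(taxa)
        taxon = taxa[taxon_idx]
        fillers = _dialect(_FILLERS, taxon_idx)
        verbs = _dialect(_VERBS, taxon_idx)
        pmid = str(10000000 + d)

        pool_genes = genes_by_taxon[taxon]
        k_genes = min(len(pool_genes), max(2, (cfg.annotations_per_doc + 1) // 2))
        doc_genes = [int(g) for g in rng.choice(pool_genes, size=k_genes, replace=False)]

        # distinct annotated terms for this document
        doc_terms: list[str] = []
        chosen: set[str] = set()
        while len(doc_terms) < cfg.annotations_per_doc:
            lv = int(rng.choice(len(non_root_levels), p=level_weights))
            candidates = non_root_levels[lv]
            if cfg.partition_by_taxon:
                candidates = [t for t in candidates if term_taxon[t] == taxon]
            if not candidates:
                continue
            tid = str(rng.choice(candidates))
            if tid not in chosen:
                chosen.add(tid)
                doc_terms.append(tid)

        sentences: list[str] = []
        for j, tid in enumerate(doc_terms):
            gene = genes[doc_genes[j % len(doc_genes)]]
            mention = names[tid] if rng.random() < cfg.signal else _fill(rng, fillers, 2)
            sentences.append(
                f"the {gene.symbol} {rng.choice(verbs)} {mention} "
                f"{_fill(rng, fillers, 3)}."
            )
            annotations.append(
                GOAInstance(gene, tid, pmid, str(rng.choice(_EVIDENCE_CODES)), "CO")
            )
        for _ in range(cfg.distractor_mentions_per_doc):
            while True:
                lv = int(rng.choice(len(non_root_levels), p=level_weights))
                candidates = non_root_levels[lv]
                if cfg.partition_by_taxon:
                    candidates = [t for t in candidates if term_taxon[t] == taxon]
                if not candidates:
                    continue
                tid = str(rng.choice(candidates))
                if tid not in chosen or len(chosen) >= n_terms_available:
                    chosen.add(tid)
                    break
            sentences.append(f"{_fill(rng, fillers, 2)} {names[tid]} {_fill(rng, fillers, 2)}.")
        order = rng.permutation(len(sentences))
        abstract = " ".join(sentences[i] for i in order)
        title = f"{_fill(rng, fillers, 4)}."
        docs[pmid] = Document(pmid=pmid, title=title, abstract=abstract)

    return World(cfg, dag, genes, docs, annotations, term_taxon)


def world_stats(world: World, n_docs: int | None = 200) -> pd.DataFrame:
    """Summary counts: terms, edges by type, genes per taxon, mentions per doc."""
    rows: list[tuple[str, float]] = [("terms", len(world.dag))]
    by_type: dict[str, int] = {}
    for e in world.dag.edges:
        by_type[e.edge_type] = by_type.get(e.edge_type, 0) + 1
    rows += [(f"edges_{t}", c) for t, c in sorted(by_type.items())]
    rows.append(("edges_total", len(world.dag.edges)))
    taxa_counts: dict[int, int] = {}
    for g in world.genes.values():
        taxa_counts[g.taxon_id] = taxa_counts.get(g.taxon_id, 0) + 1
    rows += [(f"genes_taxon_{t}", c) for t, c in sorted(taxa_counts.items())]
    dictionary = build_dictionary(world.dag)
    pmids = sorted(world.docs)[: n_docs or len(world.docs)]
    counts = [len(recognize(world.docs[p], dictionary)) for p in pmids]
    rows.append(("mentions_per_doc_mean", float(np.mean(counts)) if counts else 0.0))
    rows.append(("annotations", len(world.annotations)))
    return pd.DataFrame(rows, columns=["quantity", "value"])
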