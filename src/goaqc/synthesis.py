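"""Synthesis of the four inconsistency types from consistent annotations.

Each rule perturbs exactly one field of a consistent (CO) instance:

* OS (over-specific): replace the term by a uniformly chosen *direct child*
  (``is_a``/``part_of``); skip if the term is a leaf.
* OB (over-broad): replace the term by a uniformly chosen *ancestor* at any
  depth; skip if the term is a root.
* IM (irrelevant mention): replace the term by a concept recognized in the
  evidence text but not annotated to this gene for this PMID; skip if none.
* IG (incorrect gene): replace the gene by another gene product co-cited
  under the same PMID that is not associated with this term there; skip if
  none.

``assemble_datasets`` builds train/dev/test splits with disjoint PMIDs,
balanced per the study design (train/dev 50% CO + 12.5% per type; test
``test_consistent`` CO + ``test_per_type`` of each type), back-filling
skipped syntheses from fresh source instances.  ``inject_label_noise`` and
``split_by_taxon`` implement the robustness-experiment manipulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .corpus import Document, GeneProduct, GOAInstance, INCONSISTENCY_LABELS
from .errors import CapacityError, MissingDocumentError
from .ontology import GODag
from .recognize import Dictionary, mentioned_term_ids

__all__ = [
    "SynthesisConfig", "AnnotationIndex",
    "synthesize_over_specific", "synthesize_over_broad",
    "synthesize_irrelevant_mention", "synthesize_incorrect_gene",
    "assemble_datasets", "inject_label_noise", "split_by_taxon",
]


@dataclass(frozen=True)
class SynthesisConfig:
    """Split sizes; defaults reproduce the study's 20 000 / 250 / 430 design."""

    train_size: int = 20000
    dev_size: int = 250
    test_consistent: int = 238
    test_per_type: int = 48
    seed: int = 0

    def __post_init__(self):
        for name in ("train_size", "dev_size", "test_consistent", "test_per_type"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class AnnotationIndex:
    """Lookup structures over the consistent pool, keyed by PMID."""

    def __init__(self, pool: list[GOAInstance]):
        self.by_pmid: dict[str, set[tuple[int, str]]] = {}
        self.by_gene_pmid: dict[tuple[int, str], set[str]] = {}
        self.genes_by_pmid: dict[str, dict[int, GeneProduct]] = {}
        for inst in pool:
            self.by_pmid.setdefault(inst.pmid, set()).add((inst.gene_id, inst.term_id))
            self.by_gene_pmid.setdefault((inst.gene_id, inst.pmid), set()).add(inst.term_id)
            self.genes_by_pmid.setdefault(inst.pmid, {})[inst.gene_id] = inst.gene


def _choice(rng: np.random.Generator, items: set[str] | list) -> object:
    ordered = items if isinstance(items, list) else sorted(items)
    return ordered[int(rng.integers(len(ordered)))]


def synthesize_over_specific(
    inst: GOAInstance, dag: GODag, rng: np.random.Generator
) -> GOAInstance | None:
    """OS: substitute a direct child of the annotated term; None = skip."""
    children = dag.direct_children(inst.term_id)
    if not children:
        return None
    return inst.with_term(str(_choice(rng, children)), "OS")


def synthesize_over_broad(
    inst: GOAInstance, dag: GODag, rng: np.random.Generator
) -> GOAInstance | None:
    """OB: substitute an ancestor (any depth, uniform); None = skip for roots."""
    ancestors = dag.ancestors(inst.term_id)
    if not ancestors:
        return None
    return inst.with_term(str(_choice(rng, ancestors)), "OB")


def synthesize_irrelevant_mention(
    inst: GOAInstance,
    docs: dict[str, Document],
    dictionary: Dictionary,
    index: AnnotationIndex,
    rng: np.random.Generator,
    mention_cache: dict[str, frozenset[str]] | None = None,
) -> GOAInstance | None:
    """IM: substitute a recognized-but-unannotated concept; None = skip."""
    if inst.pmid not in docs:
        raise MissingDocumentError(inst.pmid)
    if mention_cache is not None and inst.pmid in mention_cache:
        recognized = mention_cache[inst.pmid]
    else:
        recognized = mentioned_term_ids(docs[inst.pmid], dictionary)
        if mention_cache is not None:
            mention_cache[inst.pmid] = recognized
    annotated = index.by_gene_pmid.get((inst.gene_id, inst.pmid), set())
    candidates = recognized - annotated
    if not candidates:
        return None
    return inst.with_term(str(_choice(rng, candidates)), "IM")


def synthesize_incorrect_gene(
    inst: GOAInstance, index: AnnotationIndex, rng: np.random.Generator
) -> GOAInstance | None:
    """IG: substitute a co-cited gene not associated with this term; None = skip."""
    pairs = index.by_pmid.get(inst.pmid, set())
    with_term = {g for g, t in pairs if t == inst.term_id}
    candidates = {g for g, _ in pairs} - with_term
    if not candidates:
        return None
    ordered = sorted(candidates)
    gene_id = int(ordered[int(rng.integers(len(ordered)))])
    return inst.with_gene(index.genes_by_pmid[inst.pmid][gene_id], "IG")


def _quotas(total: int) -> dict[str, int]:
    """50% CO + 12.5% per type via largest-remainder so quotas sum to total."""
    shares = {"CO": 0.5, "OS": 0.125, "OB": 0.125, "IM": 0.125, "IG": 0.125}
    floors = {k: math.floor(total * s) for k, s in shares.items()}
    remainder = total - sum(floors.values())
    order = sorted(shares, key=lambda k: (-(total * shares[k] - floors[k]), k))
    for k in order[:remainder]:
        floors[k] += 1
    return floors


def _synthesize_one(
    label: str,
    source: GOAInstance,
    dag: GODag,
    docs: dict[str, Document],
    dictionary: Dictionary,
    index: AnnotationIndex,
    rng: np.random.Generator,
    cache: dict[str, frozenset[str]],
) -> GOAInstance | None:
    if label == "OS":
        return synthesize_over_specific(source, dag, rng)
    if label == "OB":
        return synthesize_over_broad(source, dag, rng)
    if label == "IM":
        return synthesize_irrelevant_mention(source, docs, dictionary, index, rng, cache)
    if label == "IG":
        return synthesize_incorrect_gene(source, index, rng)
    raise ValueError(label)


def _fill_split(
    sources: list[GOAInstance],
    quotas: dict[str, int],
    dag: GODag,
    docs: dict[str, Document],
    dictionary: Dictionary,
    index: AnnotationIndex,
    rng: np.random.Generator,
    cache: dict[str, frozenset[str]],
    split_name: str,
) -> list[GOAInstance]:
    out: list[GOAInstance] = []
    cursor = 0
    n_co = quotas.get("CO", 0)
    if len(sources) < n_co:
        raise CapacityError(
            f"{split_name}: need {n_co} consistent sources, only {len(sources)} available"
        )
    out.extend(sources[:n_co])
    cursor = n_co
    for label in INCONSISTENCY_LABELS:
        achieved = 0
        target = quotas.get(label, 0)
        while achieved < target:
            if cursor >= len(sources):
                raise CapacityError(
                    f"{split_name}: pool exhausted while synthesizing {label} "
                    f"({achieved}/{target} achieved; quotas={quotas})"
                )
            candidate = _synthesize_one(
                label, sources[cursor], dag, docs, dictionary, index, rng, cache
            )
            cursor += 1
            if candidate is not None:
                out.append(candidate)
                achieved += 1
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def assemble_datasets(
    pool: list[GOAInstance],
    dag: GODag,
    docs: dict[str, Document],
    dictionary: Dictionary,
    cfg: SynthesisConfig,
) -> tuple[list[GOAInstance], list[GOAInstance], list[GOAInstance]]:
    """Build (train, dev, test) with PMID-disjoint splits; seed-deterministic.

    Source instances are never reused: each output instance (consistent or
    synthesized) descends from a distinct consistent record, and dev shares
    no source with train.
    """
    rng = np.random.default_rng(cfg.seed)
    index = AnnotationIndex(pool)
    cache: dict[str, frozenset[str]] = {}

    by_pmid: dict[str, list[GOAInstance]] = {}
    for inst in pool:
        by_pmid.setdefault(inst.pmid, []).append(inst)
    pmids = sorted(by_pmid)
    pmid_order = [pmids[i] for i in rng.permutation(len(pmids))]

    test_quotas = {"CO": cfg.test_consistent, **{t: cfg.test_per_type for t in INCONSISTENCY_LABELS}}
    needs = [
        ("test", sum(test_quotas.values()), test_quotas),
        ("dev", cfg.dev_size, _quotas(cfg.dev_size)),
        ("train", cfg.train_size, _quotas(cfg.train_size)),
    ]
    # PMID allocation with headroom for synthesis skips
    split_sources: dict[str, list[GOAInstance]] = {}
    i = 0
    for name, total, _ in needs:
        wanted = int(total * 1.3) + 10
        acc: list[GOAInstance] = []
        while len(acc) < wanted and i < len(pmid_order):
            acc.extend(by_pmid[pmid_order[i]])
            i += 1
        if len(acc) < total:
            raise CapacityError(
                f"pool has too few instances for the {name} split "
                f"(need >= {total}, got {len(acc)})"
            )
        split_sources[name] = acc
    # leftover PMIDs reinforce the train split
    while i < len(pmid_order):
        split_sources["train"].extend(by_pmid[pmid_order[i]])
        i += 1

    splits: dict[str, list[GOAInstance]] = {}
    for name, _, quotas in needs:
        sub = np.random.default_rng([cfg.seed, {"test": 1, "dev": 2, "train": 3}[name]])
        sources = split_sources[name]
        sources = [sources[j] for j in sub.permutation(len(sources))]
        splits[name] = _fill_split(
            sources, quotas, dag, docs, dictionary, index, sub, cache, name
        )
    return splits["train"], splits["dev"], splits["test"]


def inject_label_noise(
    dataset: list[GOAInstance], fraction: float, rng: np.random.Generator
) -> list[GOAInstance]:
    """Relabel exactly round(fraction·N) instances, each at most once.

    An inconsistency label becomes CO; a CO label becomes one of the four
    inconsistency types chosen uniformly.  Contents are untouched.  The
    count uses round-half-away-from-zero.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    n = len(dataset)
    k = int(math.floor(fraction * n + 0.5))
    flip = set(int(j) for j in rng.choice(n, size=k, replace=False)) if k else set()
    out: list[GOAInstance] = []
    for j, inst in enumerate(dataset):
        if j not in flip:
            out.append(inst)
        elif inst.label == "CO":
            new_label = INCONSISTENCY_LABELS[int(rng.integers(4))]
            out.append(GOAInstance(inst.gene, inst.term_id, inst.pmid,
                                   inst.evidence_code, new_label))
        else:
            out.append(GOAInstance(inst.gene, inst.term_id, inst.pmid,
                                   inst.evidence_code, "CO"))
    return out


def split_by_taxon(
    dataset: list[GOAInstance],
    train_taxa: set[int],
    test_taxa: set[int],
) -> tuple[list[GOAInstance], list[GOAInstance]]:
    """Partition instances into (train-taxa, test-taxa) disjoint lists."""
    import warnings

    train_part = [i for i in dataset if i.taxon_id in train_taxa]
    test_part = [i for i in dataset if i.taxon_id in test_taxa and i.taxon_id not in train_taxa]
    if not train_part or not test_part:
        warnings.warn("split_by_taxon produced an empty partition", stacklevel=2)
    return train_part, test_part
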