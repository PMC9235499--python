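"""The four perturbation rules, split assembly, noise injection, taxon splits."""

import numpy as np
import pytest

import goaqc
from goaqc import (
    AnnotationIndex,
    Document,
    GeneProduct,
    GOAInstance,
    SynthesisConfig,
    assemble_datasets,
    inject_label_noise,
    split_by_taxon,
    synthesize_incorrect_gene,
    synthesize_irrelevant_mention,
    synthesize_over_broad,
    synthesize_over_specific,
)
from goaqc.errors import CapacityError, MissingDocumentError
from goaqc.recognize import build_dictionary, mentioned_term_ids


def _rng():
    return np.random.default_rng(0)


def _inst(term, gene=None, pmid="1"):
    gene = gene or GeneProduct(1, "ABC1", 9606)
    return GOAInstance(gene, term, pmid, "IDA", "CO")


class TestOverSpecific:
    def test_fragment_only_child_selected(self, fragment_dag):
        out = synthesize_over_specific(_inst("GO:0051592"), fragment_dag, _rng())
        assert out.term_id == "GO:0071277"
        assert out.label == "OS"

    def test_leaf_skips(self, fragment_dag):
        assert synthesize_over_specific(_inst("GO:0071277"), fragment_dag, _rng()) is None

    def test_membership_oracle(self, std_world):
        dag = std_world.dag
        rng = _rng()
        for inst in std_world.annotations[:500]:
            out = synthesize_over_specific(inst, dag, rng)
            if out is not None:
                assert (out.term_id, inst.term_id) in {
                    (e.child_id, e.parent_id) for e in dag.forward_edges
                }


class TestOverBroad:
    def test_fragment_ancestor(self, fragment_dag):
        seen = set()
        rng = _rng()
        for _ in range(50):
            seen.add(synthesize_over_broad(_inst("GO:0051592"), fragment_dag, rng).term_id)
        assert seen == {"GO:0010038", "GO:0050896"}  # includes non-direct ancestor

    def test_root_skips(self, fragment_dag):
        assert synthesize_over_broad(_inst("GO:0050896"), fragment_dag, _rng()) is None

    def test_closure_oracle(self, std_world):
        import networkx as nx

        dag = std_world.dag
        g = nx.DiGraph((e.child_id, e.parent_id) for e in dag.forward_edges)
        rng = _rng()
        for inst in std_world.annotations[:500]:
            out = synthesize_over_broad(inst, dag, rng)
            if out is not None:
                assert out.term_id in nx.descendants(g, inst.term_id)
                assert out.term_id != inst.term_id


class TestIrrelevantMention:
    def test_spindle_fixture(self, fragment_dag):
        """A mentioned-but-unannotated concept is substituted (the 'spindle' case)."""
        d = build_dictionary(fragment_dag)
        gene = GeneProduct(36264, "Mtor", 7227)
        doc = Document("19273613", "Mtor at anaphase.",
                       "Mtor plays a role in spindle elongation and in "
                       "response to calcium ion dynamics.")
        pool = [GOAInstance(gene, "GO:0051592", "19273613", "IDA", "CO")]
        out = synthesize_irrelevant_mention(
            pool[0], {"19273613": doc}, d, AnnotationIndex(pool), _rng()
        )
        assert out.term_id == "GO:0005819"
        assert out.label == "IM"

    def test_no_mentions_skips(self, fragment_dag):
        d = build_dictionary(fragment_dag)
        doc = Document("5", "nothing here.", "no concepts at all.")
        pool = [_inst("GO:0051592", pmid="5")]
        assert synthesize_irrelevant_mention(
            pool[0], {"5": doc}, d, AnnotationIndex(pool), _rng()
        ) is None

    def test_missing_document_raises(self, fragment_dag):
        d = build_dictionary(fragment_dag)
        pool = [_inst("GO:0051592", pmid="404")]
        with pytest.raises(MissingDocumentError):
            synthesize_irrelevant_mention(pool[0], {}, d, AnnotationIndex(pool), _rng())

    def test_unannotated_oracle(self, std_world, std_dictionary):
        index = AnnotationIndex(std_world.annotations)
        rng = _rng()
        for inst in std_world.annotations[:200]:
            out = synthesize_irrelevant_mention(
                inst, std_world.docs, std_dictionary, index, rng
            )
            if out is not None:
                recognized = mentioned_term_ids(std_world.docs[inst.pmid], std_dictionary)
                assert out.term_id in recognized
                assert out.term_id not in index.by_gene_pmid[(inst.gene_id, inst.pmid)]


class TestIncorrectGene:
    def test_co_cited_gene_selected(self):
        """Pairing the term with the other co-cited gene (the rho-1 case)."""
        rhgf2 = GeneProduct(173748, "RHGF-2", 6239)
        rho1 = GeneProduct(178458, "rho-1", 6239)
        pool = [
            GOAInstance(rhgf2, "GO:0005085", "22363657", "IDA", "CO"),
            GOAInstance(rho1, "GO:0043087", "22363657", "IDA", "CO"),
        ]
        out = synthesize_incorrect_gene(pool[0], AnnotationIndex(pool), _rng())
        assert out.gene_id == 178458
        assert out.term_id == "GO:0005085"
        assert out.label == "IG"

    def test_single_gene_pmid_skips(self):
        pool = [_inst("GO:0000001")]
        assert synthesize_incorrect_gene(pool[0], AnnotationIndex(pool), _rng()) is None

    def test_unassociated_oracle(self, std_world):
        index = AnnotationIndex(std_world.annotations)
        rng = _rng()
        for inst in std_world.annotations[:200]:
            out = synthesize_incorrect_gene(inst, index, rng)
            if out is not None:
                pairs = index.by_pmid[inst.pmid]
                assert any(g == out.gene_id for g, _ in pairs)       # co-cited
                assert (out.gene_id, out.term_id) not in pairs       # unassociated


def test_single_perturbation_property(std_world, std_dictionary):
    """Every synthesized instance differs from its source in exactly one
    field (term for OS/OB/IM, gene for IG) plus the label."""
    dag, docs = std_world.dag, std_world.docs
    index = AnnotationIndex(std_world.annotations)
    rng = _rng()
    checked = 0
    for inst in std_world.annotations[:350]:
        for op, field in (
            (lambda i: synthesize_over_specific(i, dag, rng), "term"),
            (lambda i: synthesize_over_broad(i, dag, rng), "term"),
            (lambda i: synthesize_irrelevant_mention(i, docs, std_dictionary, index, rng),
             "term"),
            (lambda i: synthesize_incorrect_gene(i, index, rng), "gene"),
        ):
            out = op(inst)
            if out is None:
                continue
            checked += 1
            assert (out.pmid, out.evidence_code) == (inst.pmid, inst.evidence_code)
            if field == "term":
                assert out.term_id != inst.term_id and out.gene == inst.gene
            else:
                assert out.gene_id != inst.gene_id and out.term_id == inst.term_id
    assert checked >= 1000


class TestAssemble:
    def test_split_sizes_and_composition(self, std_splits):
        train, dev, test = std_splits
        assert (len(train), len(dev), len(test)) == (2000, 100, 119 + 4 * 24)
        from collections import Counter

        c = Counter(i.label for i in train)
        assert c["CO"] == 1000 and all(c[t] == 250 for t in ("OS", "OB", "IM", "IG"))
        ct = Counter(i.label for i in test)
        assert ct["CO"] == 119 and all(ct[t] == 24 for t in ("OS", "OB", "IM", "IG"))

    def test_pmid_disjointness(self, std_splits):
        train, dev, test = std_splits
        p = [set(i.pmid for i in s) for s in (train, dev, test)]
        assert not (p[0] & p[1]) and not (p[0] & p[2]) and not (p[1] & p[2])

    def test_deterministic(self, std_world, std_dictionary):
        cfg = SynthesisConfig(train_size=200, dev_size=40, test_consistent=20,
                              test_per_type=5, seed=9)
        args = (std_world.annotations, std_world.dag, std_world.docs, std_dictionary, cfg)
        a = assemble_datasets(*args)
        b = assemble_datasets(*args)
        assert a == b

    def test_zero_counts_give_empty_splits(self, std_world, std_dictionary):
        cfg = SynthesisConfig(0, 0, 0, 0, seed=0)
        out = assemble_datasets(std_world.annotations, std_world.dag, std_world.docs,
                                std_dictionary, cfg)
        assert out == ([], [], [])

    def test_capacity_error_on_small_pool(self, std_world, std_dictionary):
        cfg = SynthesisConfig(train_size=10 ** 6, dev_size=0, test_consistent=0,
                              test_per_type=0, seed=0)
        with pytest.raises(CapacityError):
            assemble_datasets(std_world.annotations, std_world.dag, std_world.docs,
                              std_dictionary, cfg)


class TestNoise:
    def test_zero_fraction_is_identity(self, std_splits):
        train = std_splits[0][:100]
        assert inject_label_noise(train, 0.0, _rng()) == train

    def test_exact_flip_count(self, std_splits):
        train = std_splits[0][:200]
        noisy = inject_label_noise(train, 0.25, _rng())
        flips = sum(a.label != b.label for a, b in zip(train, noisy))
        assert flips == 50
        # contents untouched
        assert all((a.gene, a.term_id, a.pmid) == (b.gene, b.term_id, b.pmid)
                   for a, b in zip(train, noisy))

    def test_full_fraction_inverts_every_label(self, std_splits):
        train = std_splits[0][:40]
        noisy = inject_label_noise(train, 1.0, _rng())
        for a, b in zip(train, noisy):
            if a.label == "CO":
                assert b.label in ("OS", "OB", "IM", "IG")
            else:
                assert b.label == "CO"

    def test_rounding_half_away_from_zero(self):
        pool = [_inst("GO:0000001", pmid=str(i)) for i in range(10)]
        noisy = inject_label_noise(pool, 0.25, _rng())  # 2.5 -> 3
        assert sum(a.label != b.label for a, b in zip(pool, noisy)) == 3

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            inject_label_noise([], 1.5, _rng())


class TestTaxonSplit:
    def test_partition_counts(self, std_world):
        data = std_world.annotations[:500]
        train_part, test_part = split_by_taxon(data, {9606}, {7227, 10116})
        assert all(i.taxon_id == 9606 for i in train_part)
        assert all(i.taxon_id in (7227, 10116) for i in test_part)
        per_taxon = {}
        for i in data:
            per_taxon[i.taxon_id] = per_taxon.get(i.taxon_id, 0) + 1
        assert len(train_part) == per_taxon[9606]
        assert len(test_part) == per_taxon[7227] + per_taxon[10116]

    def test_empty_partition_warns(self, std_world):
        with pytest.warns(UserWarning):
            split_by_taxon(std_world.annotations[:10], {1}, {9606})
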