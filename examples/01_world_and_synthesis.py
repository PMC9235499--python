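"""Generate a synthetic annotation world and synthesize the four
inconsistency types from its consistent records.

Prints the world's shape and one example of each perturbation: an
over-specific child substitution (OS), an over-broad ancestor substitution
(OB), an irrelevant recognized mention (IM) and an incorrect co-cited gene
(IG).  Each synthesized instance differs from its consistent source in
exactly one field plus the label.
"""

import numpy as np

import goaqc

world = goaqc.generate_world(goaqc.WorldConfig(
    n_terms=120, n_levels=5, n_genes=40, n_documents=300, seed=3))
print(goaqc.world_stats(world, n_docs=100).to_string(index=False))

dag = world.dag
dictionary = goaqc.build_dictionary(dag)
index = goaqc.AnnotationIndex(world.annotations)
rng = np.random.default_rng(0)

source = next(i for i in world.annotations if dag.direct_children(i.term_id))
print(f"\nconsistent source: gene {source.gene.symbol}, "
      f"term '{dag[source.term_id].name}', PMID {source.pmid}")

for name, out in [
    ("OS", goaqc.synthesize_over_specific(source, dag, rng)),
    ("OB", goaqc.synthesize_over_broad(source, dag, rng)),
    ("IM", goaqc.synthesize_irrelevant_mention(source, world.docs, dictionary,
                                               index, rng)),
    ("IG", goaqc.synthesize_incorrect_gene(source, index, rng)),
]:
    if out is None:
        print(f"{name}: skipped (no eligible substitute)")
    else:
        print(f"{name}: gene {out.gene.symbol}, term '{dag[out.term_id].name}'")

cfg = goaqc.SynthesisConfig(train_size=600, dev_size=50, test_consistent=40,
                            test_per_type=10, seed=1)
train, dev, test = goaqc.assemble_datasets(world.annotations, dag, world.docs,
                                           dictionary, cfg)
print(f"\nsplits: train={len(train)} dev={len(dev)} test={len(test)} "
      f"(test is imbalanced: {cfg.test_consistent} consistent + "
      f"{cfg.test_per_type} per type)")
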