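"""Two-step rule baseline over recognized concepts and the DAG.

Step (a): an instance is consistent iff its term is among the concepts
recognized in title+abstract.  Step (b) classifies the remainder: over-
specific when the term is a strict descendant of *every* recognized term,
over-broad when it is a strict ancestor of *at least one*.  Instances with
no recognized concepts, or matching neither rule, are flagged
``inconsistent_unspecified``.  By construction the baseline can never flag
an irrelevant-mention instance (its term *is* recognized) and emits no
gene-product label at all; evaluation treats those cells as NA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Document, GOAInstance
from .errors import MissingDocumentError
from .ontology import GODag
from .recognize import Dictionary, mentioned_term_ids

CONSISTENT = "consistent"
OVER_SPECIFIC = "over_specific"
OVER_BROAD = "over_broad"
UNSPECIFIED = "inconsistent_unspecified"

BASELINE_LABELS = (CONSISTENT, OVER_SPECIFIC, OVER_BROAD, UNSPECIFIED)

# mapping onto the 5-class evaluation scheme; IM and IG are unreachable (NA)
TO_EVAL_LABEL = {
    CONSISTENT: "CO",
    OVER_SPECIFIC: "OS",
    OVER_BROAD: "OB",
    UNSPECIFIED: "CO",
}


@dataclass(frozen=True)
class BaselineResult:
    label: str
    recognized: frozenset[str]


def classify_baseline(
    inst: GOAInstance,
    doc: Document | None,
    dictionary: Dictionary,
    dag: GODag,
) -> BaselineResult:
    if doc is None:
        raise MissingDocumentError(inst.pmid)
    recognized = mentioned_term_ids(doc, dictionary)
    known = frozenset(t for t in recognized if t in dag)
    term = inst.term_id
    if term in known:
        return BaselineResult(CONSISTENT, known)
    if known and all(dag.is_descendant(term, r) for r in known):
        return BaselineResult(OVER_SPECIFIC, known)
    if any(dag.is_descendant(r, term) for r in known):
        # cannot also satisfy the OS rule: that would require a cycle
        return BaselineResult(OVER_BROAD, known)
    return BaselineResult(UNSPECIFIED, known)
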