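"""Five-class GOA (in)consistency classification.

Every instance is rendered as the structured sequence

    [CLS] title || abstract || gene symbol [SEP] GO term [SEP]

padded or truncated to a fixed length (350 tokens by default; truncation
removes abstract tokens from the right, never the gene symbol or term).
An encoder turns the sequence into a fixed vector; in fusion mode the
instance term's specificity embedding is concatenated to the encoder
output before the single-hidden-layer classification head (five logits
over CO/OS/OB/IM/IG, argmax with lowest-class-index tie-break).

The default encoder is a deterministic *light* featurizer emulating what a
contextual encoder learns for this task from the token stream alone:
term-phrase / text overlap, sentence-level co-occurrence of the gene symbol
with the term phrase, the identity of tokens adjacent to the term match,
the presence of other gene-shaped tokens, and hashed bags of words for the
two segments.  Any object with ``dim`` and ``encode(sequence)`` can be
plugged in instead (e.g. a transformer wrapper); none is bundled.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import zlib

from . import _nn
from .corpus import Document, GOAInstance
from .errors import MissingDocumentError, TrainingError
from .evaluation import entropy
from .ontology import GODag
from .specificity import TrainingConfig

CLASSES = ("CO", "OS", "OB", "IM", "IG")

CLS, SEP, PAD, JOIN = "[CLS]", "[SEP]", "[PAD]", "||"
UNK = "[UNK]"

_WORD_RE = re.compile(r"[A-Za-z0-9]+|\.")
_GENE_SHAPE_RE = re.compile(r"^[A-Z][A-Z0-9]{2,}$")


def word_tokens(text: str) -> list[str]:
    """Case-preserving word tokens; sentence-final periods kept as tokens."""
    return _WORD_RE.findall(text)


def tokenize(text: str, vocab: set[str] | None = None) -> list[str]:
    """Tokenize; with a subword vocabulary, OOV words split greedily into
    pieces with ``##`` continuation markers (e.g. 'polyc', '##omb')."""
    words = word_tokens(text)
    if vocab is None:
        return words
    out: list[str] = []
    for word in words:
        if word in vocab:
            out.append(word)
            continue
        pieces: list[str] = []
        pos = 0
        while pos < len(word):
            prefix = "" if pos == 0 else "##"
            match = None
            for end in range(len(word), pos, -1):
                cand = prefix + word[pos:end]
                if cand in vocab:
                    match = cand
                    pos = end
                    break
            if match is None:
                pieces = [UNK]
                break
            pieces.append(match)
        out.extend(pieces)
    return out


def detokenize(tokens: list[str]) -> str:
    """Inverse of tokenize up to whitespace normalization."""
    words: list[str] = []
    for tok in tokens:
        if tok.startswith("##") and words:
            words[-1] += tok[2:]
        elif tok not in (PAD,):
            words.append(tok)
    return " ".join(words)


def make_wordpiece_vocab(texts: list[str]) -> set[str]:
    """Whole words from the corpus plus a character-level fallback."""
    vocab: set[str] = set()
    for text in texts:
        for word in word_tokens(text):
            vocab.add(word)
            for ch in word:
                vocab.add(ch)
                vocab.add("##" + ch)
    return vocab


@dataclass(frozen=True)
class InputSequence:
    """The classifier's token stream; starts with [CLS], two [SEP] markers."""

    tokens: tuple[str, ...]

    @property
    def length(self) -> int:
        return len(self.tokens)

    def segments(self) -> tuple[list[str], list[str], list[str], list[str]]:
        """(title, abstract, symbol, term) token lists, padding stripped."""
        toks = [t for t in self.tokens if t != PAD]
        seps = [i for i, t in enumerate(toks) if t == SEP]
        first = toks[1 : seps[0]]
        term = toks[seps[0] + 1 : seps[1]]
        joins = [i for i, t in enumerate(first) if t == JOIN]
        title = first[: joins[0]]
        abstract = first[joins[0] + 1 : joins[1]]
        symbol = first[joins[1] + 1 :]
        return title, abstract, symbol, term


def build_input_sequence(
    inst: GOAInstance,
    doc: Document | None,
    dag: GODag,
    max_len: int = 350,
    vocab: set[str] | None = None,
) -> InputSequence:
    """Render the structured sequence; truncate abstract tokens from the right."""
    if doc is None:
        raise MissingDocumentError(inst.pmid)
    title = tokenize(doc.title, vocab)
    abstract = tokenize(doc.abstract, vocab)
    symbol = tokenize(inst.gene.symbol, vocab)
    term = tokenize(dag[inst.term_id].name, vocab)
    fixed = 1 + len(title) + 2 + len(symbol) + 1 + len(term) + 1  # all but abstract
    room = max(0, max_len - fixed)
    abstract = abstract[:room]
    tokens = [CLS, *title, JOIN, *abstract, JOIN, *symbol, SEP, *term, SEP]
    if len(tokens) < max_len:
        tokens += [PAD] * (max_len - len(tokens))
    return InputSequence(tuple(tokens[:max_len]))


# ---------------------------------------------------------------------------
# the light encoder
# ---------------------------------------------------------------------------

def _find_phrase(hay: list[str], needle: list[str]) -> list[int]:
    if not needle or len(needle) > len(hay):
        return []
    return [i for i in range(len(hay) - len(needle) + 1)
            if hay[i : i + len(needle)] == needle]


def _longest_common_run(hay: list[str], needle: list[str]) -> int:
    best = 0
    for length in range(len(needle), 0, -1):
        for s in range(len(needle) - length + 1):
            if _find_phrase(hay, needle[s : s + length]):
                return length
    return best


def _bucket(token: str, dim: int) -> int:
    return zlib.crc32(token.encode()) % dim


class LightEncoder:
    """Deterministic feature extractor over the structured token stream."""

    PREV_DIM = 32
    NEXT_DIM = 32
    TEXT_BOW_DIM = 192
    TERM_BOW_DIM = 64
    N_SCALAR = 9

    def __init__(self):
        self.dim = (self.N_SCALAR + self.PREV_DIM + self.NEXT_DIM
                    + self.TEXT_BOW_DIM + self.TERM_BOW_DIM)
        self.name = "light"

    def encode(self, seq: InputSequence) -> np.ndarray:
        title, abstract, symbol_toks, term = seq.segments()
        text = title + abstract
        text_lower = [t.lower() for t in text]
        term_lower = [t.lower() for t in term]
        symbol = symbol_toks[0] if symbol_toks else ""
        symbol_lower = symbol.lower()

        # sentence spans over the text tokens (periods delimit sentences)
        sentences: list[tuple[int, int]] = []
        start = 0
        for i, tok in enumerate(text):
            if tok == ".":
                sentences.append((start, i))
                start = i + 1
        if start < len(text):
            sentences.append((start, len(text)))

        hits = _find_phrase(text_lower, term_lower)
        tail = term_lower[1:]
        tail_hits = _find_phrase(text_lower, tail) if tail else []
        gene_shaped = [i for i, t in enumerate(text) if _GENE_SHAPE_RE.match(t)
                       and any(c.isdigit() for c in t)]

        def sentence_of(pos: int) -> tuple[int, int] | None:
            for s, e in sentences:
                if s <= pos < e:
                    return (s, e)
            return None

        def co_sentence(match_positions: list[int], phrase_len: int) -> tuple[bool, bool]:
            """(symbol in the match sentence, another gene-shaped token there)."""
            with_symbol = other_gene = False
            for pos in match_positions:
                span = sentence_of(pos)
                if span is None:
                    continue
                s, e = span
                window = text_lower[s:e]
                if symbol_lower in window:
                    with_symbol = True
                for g in gene_shaped:
                    if s <= g < e and text[g].lower() != symbol_lower:
                        if not (pos <= g < pos + phrase_len):
                            other_gene = True
            return with_symbol, other_gene

        exact_co, exact_other = co_sentence(hits, len(term_lower))
        tail_co, _ = co_sentence(tail_hits, len(tail))

        scalars = np.zeros(self.N_SCALAR)
        scalars[0] = 1.0 if hits else 0.0
        scalars[1] = 1.0 if (not hits and tail_hits) else 0.0
        scalars[2] = (_longest_common_run(text_lower, term_lower) / len(term_lower)
                      if term_lower else 0.0)
        scalars[3] = 1.0 if exact_co else 0.0
        scalars[4] = 1.0 if tail_co else 0.0
        scalars[5] = 1.0 if exact_other else 0.0
        scalars[6] = 1.0 if symbol_lower in text_lower else 0.0
        scalars[7] = min(len(term_lower), 10) / 10.0
        scalars[8] = min(len(gene_shaped), 10) / 10.0

        prev = np.zeros(self.PREV_DIM)
        nxt = np.zeros(self.NEXT_DIM)
        if hits:
            pos = hits[0]
            prev_tok = text_lower[pos - 1] if pos > 0 else "<bos>"
            end = pos + len(term_lower)
            next_tok = text_lower[end] if end < len(text_lower) else "<eos>"
            prev[_bucket(prev_tok, self.PREV_DIM)] = 1.0
            nxt[_bucket(next_tok, self.NEXT_DIM)] = 1.0

        text_bow = np.zeros(self.TEXT_BOW_DIM)
        for tok in text_lower:
            if tok != ".":
                text_bow[_bucket(tok, self.TEXT_BOW_DIM)] += 1.0
        if text_bow.sum():
            text_bow /= np.sqrt((text_bow ** 2).sum())
        term_bow = np.zeros(self.TERM_BOW_DIM)
        for tok in term_lower:
            term_bow[_bucket(tok, self.TERM_BOW_DIM)] += 1.0
        if term_bow.sum():
            term_bow /= np.sqrt((term_bow ** 2).sum())

        return np.concatenate([scalars, prev, nxt, text_bow, term_bow])


def _resolve_encoder(encoder_spec):
    if encoder_spec == "light" or encoder_spec is None:
        return LightEncoder()
    if hasattr(encoder_spec, "encode") and hasattr(encoder_spec, "dim"):
        return encoder_spec
    raise TrainingError(f"unusable encoder spec: {encoder_spec!r}")


# ---------------------------------------------------------------------------
# model, training, prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionResult:
    """Probabilities over CO/OS/OB/IM/IG, argmax label, entropy tau (bits)."""

    probs: np.ndarray
    label: str
    tau: float


@dataclass
class ClassifierModel:
    encoder: object
    head: _nn.Sequential
    mu: np.ndarray
    sigma: np.ndarray
    cfg: TrainingConfig
    max_len: int = 350
    embeddings: dict[str, np.ndarray] | None = None
    emb_dim: int = 0
    classes: tuple[str, ...] = CLASSES
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)
    dev_loss_history: list[float] = field(default_factory=list)

    @property
    def fusion(self) -> bool:
        return self.embeddings is not None

    def sidecar(self) -> dict:
        return {
            "encoder": getattr(self.encoder, "name", type(self.encoder).__name__),
            "encoder_dim": self.encoder.dim,
            "emb_dim": self.emb_dim,
            "classes": list(self.classes),
            "seed": self.cfg.seed,
            "config": self.cfg.__dict__,
            "max_len": self.max_len,
        }


def _featurize(
    model: ClassifierModel,
    instances: list[GOAInstance],
    docs: dict[str, Document],
    dag: GODag,
) -> np.ndarray:
    rows = []
    for inst in instances:
        doc = docs.get(inst.pmid)
        if doc is None:
            raise MissingDocumentError(inst.pmid)
        seq = build_input_sequence(inst, doc, dag, max_len=model.max_len)
        vec = model.encoder.encode(seq)
        if model.fusion:
            emb = model.embeddings.get(inst.term_id)
            if emb is None:
                raise TrainingError(f"no specificity embedding for term {inst.term_id}")
            vec = np.concatenate([vec, emb])
        rows.append(vec)
    return np.stack(rows)


def train_classifier(
    train: list[GOAInstance],
    dev: list[GOAInstance],
    dag: GODag,
    docs: dict[str, Document],
    encoder_spec="light",
    embeddings: dict[str, np.ndarray] | None = None,
    cfg: TrainingConfig | None = None,
    hidden: int = 64,
) -> ClassifierModel:
    """Fit the 5-class head; fusion mode concatenates specificity embeddings.

    With no explicit config, plain mode trains for 5 epochs and fusion mode
    for 3, both with batch 16, 300 warmup steps and weight decay 0.01.
    """
    if cfg is None:
        cfg = TrainingConfig(epochs=3 if embeddings is not None else 5,
                             learning_rate=5e-3)
    encoder = _resolve_encoder(encoder_spec)
    emb_dim = len(next(iter(embeddings.values()))) if embeddings else 0
    rng = np.random.default_rng(cfg.seed)
    d_in = encoder.dim + emb_dim
    model = ClassifierModel(
        encoder=encoder,
        head=_nn.mlp(d_in, hidden, len(CLASSES), rng),
        mu=np.zeros(d_in),
        sigma=np.ones(d_in),
        cfg=cfg,
        embeddings=dict(embeddings) if embeddings else None,
        emb_dim=emb_dim,
    )
    # fusion-input integrity: head input width must equal encoder + embedding
    assert model.head.layers[0].W.value.shape[0] == encoder.dim + emb_dim

    x = _featurize(model, train, docs, dag)
    y = np.array([CLASSES.index(i.label) for i in train])
    if len(set(y.tolist())) == 1:
        warnings.warn("training labels are single-class; the model will degenerate",
                      stacklevel=2)
    model.mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    model.sigma = np.where(sigma > 1e-9, sigma, 1.0)
    x = (x - model.mu) / model.sigma
    x_dev = y_dev = None
    if dev:
        x_dev = (_featurize(model, dev, docs, dag) - model.mu) / model.sigma
        y_dev = np.array([CLASSES.index(i.label) for i in dev])

    if cfg.epochs == 0:
        warnings.warn("epochs=0: returning an untrained model", stacklevel=2)
        return model
    opt = _nn.AdamW(model.head.params(), lr=cfg.learning_rate,
                    warmup_steps=cfg.warmup_steps, weight_decay=cfg.weight_decay)
    n = len(train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        batches = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss, dlogits = _nn.softmax_xent(model.head.forward(x[sel]), y[sel])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.head.backward(dlogits)
            opt.step()
            total += loss
            batches += 1
        model.loss_history.append(total / max(batches, 1))
        if x_dev is not None and len(x_dev):
            dev_loss, _ = _nn.softmax_xent(model.head.forward(x_dev), y_dev)
            model.dev_loss_history.append(dev_loss)
    model.trained = True
    return model


def predict(
    model: ClassifierModel, inst: GOAInstance, doc: Document, dag: GODag
) -> PredictionResult:
    """Softmax probabilities, argmax label (lowest class index on ties), tau."""
    return predict_batch(model, [inst], {inst.pmid: doc}, dag)[0]


def predict_batch(
    model: ClassifierModel,
    instances: list[GOAInstance],
    docs: dict[str, Document],
    dag: GODag,
) -> list[PredictionResult]:
    x = (_featurize(model, instances, docs, dag) - model.mu) / model.sigma
    probs = _nn.softmax(model.head.forward(x))
    out = []
    for row in probs:
        label = CLASSES[int(np.argmax(row))]  # argmax returns the lowest index on ties
        out.append(PredictionResult(row, label, entropy(row)))
    return out


def save_model(model: ClassifierModel, path: str) -> None:
    if not isinstance(model.encoder, LightEncoder):
        raise TrainingError("only light-encoder models can be checkpointed")
    payload = {
        "sidecar": model.sidecar(),
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "params": [p.value.tolist() for p in model.head.params()],
        "hidden": model.head.layers[0].W.value.shape[1],
        "embeddings": (
            {tid: v.tolist() for tid, v in model.embeddings.items()}
            if model.fusion else None
        ),
        "trained": model.trained,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> ClassifierModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = TrainingConfig(**payload["sidecar"]["config"])
    encoder = LightEncoder()
    emb = payload["embeddings"]
    embeddings = {t: np.asarray(v) for t, v in emb.items()} if emb else None
    emb_dim = payload["sidecar"]["emb_dim"]
    rng = np.random.default_rng(cfg.seed)
    model = ClassifierModel(
        encoder=encoder,
        head=_nn.mlp(encoder.dim + emb_dim, payload["hidden"], len(CLASSES), rng),
        mu=np.asarray(payload["mu"]),
        sigma=np.asarray(payload["sigma"]),
        cfg=cfg,
        max_len=payload["sidecar"]["max_len"],
        embeddings=embeddings,
        emb_dim=emb_dim,
        trained=payload["trained"],
    )
    for p, stored in zip(model.head.params(), payload["params"]):
        p.value[...] = np.asarray(stored)
    return model
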