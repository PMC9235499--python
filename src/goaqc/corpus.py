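"""Reading and writing annotation records and evidence documents.

Supported formats: NCBI gene2go-style TSV, GAF 2.x, a JSONL document store
(pmid/title/abstract), and the toolkit's internal labeled TSV dialect with
columns ``gene_id, symbol, taxon, term_id, pmid, evidence_code, label``.

Only records carrying a PMID and an experimental evidence code
(EXP, IDA, IPI, IMP, IGI, IEP) are admitted; everything read from a
consistent source is labeled CO until the synthesis stage relabels it.
"""

from __future__ import annotations

import io
import json
import logging
import zlib
from dataclasses import dataclass, replace
from typing import IO, Iterable

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
LABELS = ("CO", "OS", "OB", "IM", "IG")
INCONSISTENCY_LABELS = ("OS", "OB", "IM", "IG")

DATASET_COLUMNS = ["gene_id", "symbol", "taxon", "term_id", "pmid", "evidence_code", "label"]


@dataclass(frozen=True)
class GeneProduct:
    gene_id: int
    symbol: str
    taxon_id: int
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")


@dataclass(frozen=True)
class Document:
    """Title + abstract for one PMID; the only evidence text used."""

    pmid: str
    title: str
    abstract: str = ""

    def __post_init__(self):
        if not self.title:
            raise ValidationError(f"document {self.pmid!r} has an empty title")

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title


@dataclass(frozen=True)
class GOAInstance:
    """One (gene product, GO term, PMID evidence) triplet — the unit of classification."""

    gene: GeneProduct
    term_id: str
    pmid: str
    evidence_code: str
    label: str = "CO"

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValidationError(f"label {self.label!r} not in {LABELS}")

    @property
    def gene_id(self) -> int:
        return self.gene.gene_id

    @property
    def taxon_id(self) -> int:
        return self.gene.taxon_id

    def with_term(self, term_id: str, label: str) -> "GOAInstance":
        return replace(self, term_id=term_id, label=label)

    def with_gene(self, gene: GeneProduct, label: str) -> "GOAInstance":
        return replace(self, gene=gene, label=label)


def _as_handle(stream: str | IO[str]) -> IO[str]:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def _split_pmids(cell: str) -> list[str]:
    if not cell or cell in {"-", "nan"}:
        return []
    return [p.strip() for p in str(cell).split("|") if p.strip() and p.strip() != "-"]


def read_gene2go(stream: str | IO[str]) -> list[GOAInstance]:
    """Read NCBI gene2go-style TSV into CO instances.

    Mandatory columns (case-insensitive, leading ``#`` ignored): tax_id /
    taxon, GeneID, GO_ID, Evidence, PubMed.  Rows without a PMID or with a
    non-experimental evidence code are filtered out; a row listing several
    ``|``-separated PMIDs yields one instance per PMID.
    """
    df = pd.read_csv(_as_handle(stream), sep="\t", dtype=str).fillna("")
    cols = {c.lstrip("#").strip().lower(): c for c in df.columns}

    def col(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise FormatError(f"gene2go input lacks a mandatory column among {names}")

    c_tax = col("tax_id", "taxon", "taxid")
    c_gene = col("geneid", "gene_id")
    c_go = col("go_id", "goid")
    c_ev = col("evidence", "evidence_code")
    c_pm = col("pubmed", "pmid")
    c_sym = cols.get("symbol")

    out: list[GOAInstance] = []
    for _, row in df.iterrows():
        if row[c_ev] not in EXPERIMENTAL_CODES:
            continue
        pmids = _split_pmids(row[c_pm])
        if not pmids:
            continue
        gene_id = int(row[c_gene])
        gene = GeneProduct(
            gene_id=gene_id,
            symbol=(row[c_sym] if c_sym and row[c_sym] else str(gene_id)),
            taxon_id=int(row[c_tax]),
        )
        for pmid in pmids:
            out.append(GOAInstance(gene, row[c_go], pmid, row[c_ev]))
    return out


def _gaf_gene_id(db_object_id: str) -> int:
    """Numeric gene id for a GAF object id; non-numeric ids get a stable CRC32."""
    try:
        return int(db_object_id)
    except ValueError:
        return zlib.crc32(db_object_id.encode())


def read_gaf(stream: str | IO[str]) -> list[GOAInstance]:
    """Read a GAF 2.x file into CO instances (same filter contract as gene2go)."""
    out: list[GOAInstance] = []
    for lineno, line in enumerate(_as_handle(stream), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            raise FormatError(f"GAF line {lineno}: expected >=15 columns, got {len(fields)}")
        symbol = fields[2]
        go_id = fields[4]
        refs = fields[5]
        evidence = fields[6]
        taxon_field = fields[12]
        if evidence not in EXPERIMENTAL_CODES:
            continue
        pmids = [r.split(":", 1)[1] for r in refs.split("|") if r.startswith("PMID:")]
        if not pmids:
            continue
        taxon = int(taxon_field.split("|")[0].replace("taxon:", "") or 0)
        gene = GeneProduct(_gaf_gene_id(fields[1]), symbol or fields[1], taxon)
        for pmid in pmids:
            out.append(GOAInstance(gene, go_id, pmid, evidence))
    return out


def read_documents(stream: str | IO[str]) -> dict[str, Document]:
    """Read a JSONL document store keyed by PMID; duplicate pmid = last wins."""
    docs: dict[str, Document] = {}
    for lineno, line in enumerate(_as_handle(stream), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"documents line {lineno}: invalid JSON ({exc})") from exc
        try:
            pmid = str(obj["pmid"])
            doc = Document(pmid=pmid, title=obj["title"], abstract=obj.get("abstract", ""))
        except KeyError as exc:
            raise FormatError(f"documents line {lineno}: missing key {exc}") from exc
        if pmid in docs:
            logger.warning("duplicate pmid %s at line %d; keeping the last record", pmid, lineno)
        docs[pmid] = doc
    return docs


def write_documents(docs: Iterable[Document], handle: IO[str]) -> None:
    for d in docs:
        handle.write(json.dumps({"pmid": d.pmid, "title": d.title, "abstract": d.abstract}) + "\n")


def write_dataset(instances: Iterable[GOAInstance], handle_or_path: str | IO[str]) -> None:
    """Write instances as the internal labeled TSV dialect (round-trips with read_dataset)."""
    rows = []
    for inst in instances:
        if inst.label not in LABELS:
            raise ValidationError(f"label {inst.label!r} not in {LABELS}")
        rows.append(
            (inst.gene_id, inst.gene.symbol, inst.taxon_id, inst.term_id, inst.pmid,
             inst.evidence_code, inst.label)
        )
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    df.to_csv(handle_or_path, sep="\t", index=False)


def read_dataset(stream: str | IO[str]) -> list[GOAInstance]:
    df = pd.read_csv(_as_handle(stream), sep="\t", dtype=str).fillna("")
    if list(df.columns) != DATASET_COLUMNS:
        raise FormatError(f"dataset columns {list(df.columns)} != {DATASET_COLUMNS}")
    out = []
    for _, row in df.iterrows():
        gene = GeneProduct(int(row["gene_id"]), row["symbol"], int(row["taxon"]))
        out.append(
            GOAInstance(gene, row["term_id"], row["pmid"], row["evidence_code"], row["label"])
        )
    return out
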