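"""Core containers and on-disk formats.

The package works with three tables:

* a **drug table** — TSV with header ``drug_id``, ``smiles``,
  ``indications`` (pipe-separated indication tags), one row per drug;
* an **interaction table** in the STITCH ``chemical_chemical.links.detailed``
  dialect — TSV with two chemical-identifier columns followed by evidence
  score columns including ``combined_score``;
* an optional **cached similarity table** (see
  :mod:`indirank.chem_similarity`).

Interaction confidence is modelled as a total function on unordered drug
pairs: stored pairs carry a strictly positive weight and every absent pair
weighs exactly zero.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger("indirank")

__all__ = [
    "DrugRecord",
    "IndicationCatalog",
    "InteractionTable",
    "Dataset",
    "read_drug_table",
    "write_drug_table",
    "read_stitch_links",
    "write_predictions",
    "read_predictions",
    "normalize_cid",
]


class DataFormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugRecord:
    """A drug: stable identifier, SMILES structure, and its indication tags.

    ``indications`` is a non-empty frozenset of catalog tags — the unit of
    multi-label prediction.  ``smiles`` may be an empty string for records
    without a usable structure (synthetic fixtures, withdrawn structures);
    such records are unusable for similarity but still carry labels.
    """

    drug_id: str
    smiles: str
    indications: frozenset[str]

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        if not self.indications:
            raise ValueError(f"drug {self.drug_id!r} has no indication tags")


class IndicationCatalog:
    """Ordered list of (tag, human-readable name) pairs.

    The catalog order is part of the method definition: it breaks ties
    between equally scored indications deterministically.
    """

    def __init__(self, entries: Iterable[tuple[str, str] | str]):
        pairs: list[tuple[str, str]] = []
        seen: set[str] = set()
        for e in entries:
            tag, name = (e, e) if isinstance(e, str) else (e[0], e[1])
            if tag in seen:
                raise ValueError(f"duplicate catalog tag {tag!r}")
            seen.add(tag)
            pairs.append((tag, name))
        self._pairs: tuple[tuple[str, str], ...] = tuple(pairs)
        self._index: dict[str, int] = {t: i for i, (t, _) in enumerate(pairs)}

    @property
    def tags(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self._pairs)

    def name_of(self, tag: str) -> str:
        return self._pairs[self._index[tag]][1]

    def index(self, tag: str) -> int:
        """Position of *tag* in catalog order; KeyError when unknown."""
        return self._index[tag]

    def __contains__(self, tag: object) -> bool:
        return tag in self._index

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IndicationCatalog) and self._pairs == other._pairs

    def __repr__(self) -> str:
        return f"IndicationCatalog({len(self)} tags)"

    def restrict(self, keep: Iterable[str]) -> "IndicationCatalog":
        keep_set = set(keep)
        return IndicationCatalog(p for p in self._pairs if p[0] in keep_set)


class InteractionTable:
    """Sparse symmetric map from unordered drug-id pairs to confidence scores.

    Scores live in (0, 1]; looking up an absent pair returns exactly 0.0,
    which encodes "no reported interaction".  Self-pairs are never stored.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), s in entries.items():
                self.set(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValueError(f"self-interaction for {a!r} is not storable")
        if not 0.0 < score <= 1.0:
            raise ValueError(f"score for ({a!r}, {b!r}) must be in (0, 1], got {score}")
        self._scores[self._key(a, b)] = float(score)

    def get(self, a: str, b: str) -> float:
        """Confidence score w^i(a, b); 0.0 for any unreported pair."""
        if a == b:
            return 0.0
        return self._scores.get(self._key(a, b), 0.0)

    __call__ = get

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), s in sorted(self._scores.items()):
            yield a, b, s

    def partners(self, drug_id: str) -> set[str]:
        out = set()
        for a, b in self._scores:
            if a == drug_id:
                out.add(b)
            elif b == drug_id:
                out.add(a)
        return out

    def __len__(self) -> int:
        return len(self._scores)

    def __repr__(self) -> str:
        return f"InteractionTable({len(self)} pairs)"


@dataclass
class Dataset:
    """A drug collection with its indication catalog.

    The catalog decomposes the collection into (overlapping) categories
    S_i = {drugs tagged with tag i}; a multi-label drug belongs to each of
    its categories independently.
    """

    catalog: IndicationCatalog
    drugs: list[DrugRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.drugs:
            if d.drug_id in seen:
                raise ValueError(f"duplicate drug_id {d.drug_id!r}")
            seen.add(d.drug_id)
            unknown = d.indications - set(self.catalog.tags)
            if unknown:
                raise ValueError(
                    f"drug {d.drug_id!r} carries tags not in catalog: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.drugs)

    def __iter__(self) -> Iterator[DrugRecord]:
        return iter(self.drugs)

    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.drugs]

    def record(self, drug_id: str) -> DrugRecord:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)

    def members(self, tag: str) -> list[str]:
        """Category S_tag in dataset order."""
        if tag not in self.catalog:
            raise KeyError(f"unknown tag {tag!r}")
        return [d.drug_id for d in self.drugs if tag in d.indications]

    def category_sizes(self) -> dict[str, int]:
        sizes = {t: 0 for t in self.catalog.tags}
        for d in self.drugs:
            for t in d.indications:
                sizes[t] += 1
        return sizes

    def truth(self) -> dict[str, frozenset[str]]:
        return {d.drug_id: d.indications for d in self.drugs}

    def without(self, drug_id: str) -> "Dataset":
        """Copy with one drug removed (leave-one-out training set)."""
        return Dataset(self.catalog, [d for d in self.drugs if d.drug_id != drug_id])

    def subset(self, drug_ids: Iterable[str]) -> "Dataset":
        keep = set(drug_ids)
        return Dataset(self.catalog, [d for d in self.drugs if d.drug_id in keep])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open a TSV for reading, transparently decompressing .gz."""
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _read_header(fh: io.TextIOBase) -> tuple[str, int]:
    """(first non-comment line, its 1-based line number); '#'-prefixed
    provenance lines are skipped."""
    lineno = 0
    for line in fh:
        lineno += 1
        if not line.startswith("#"):
            return line.rstrip("\n"), lineno
    return "", lineno


def read_drug_table(
    path: str | Path, catalog: IndicationCatalog | None = None
) -> Dataset:
    """Read a drug table TSV into a :class:`Dataset`.

    Columns ``drug_id``, ``smiles``, ``indications`` (pipe-separated tags)
    are required, located by header name.  When *catalog* is None it is
    induced from observed tags in first-seen order; when supplied, an
    unobserved tag is an error.  Malformed rows are rejected, not repaired.
    """
    records: list[DrugRecord] = []
    induced: list[str] = []
    seen_ids: set[str] = set()
    with _open_text(path) as fh:
        header_line, header_no = _read_header(fh)
        header = header_line.split("\t")
        try:
            col = {name: header.index(name) for name in ("drug_id", "smiles", "indications")}
        except ValueError as exc:
            raise DataFormatError(f"{path}: missing required column: {exc}") from None
        for lineno, raw in enumerate(fh, start=header_no + 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise DataFormatError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
            drug_id = fields[col["drug_id"]].strip()
            smiles = fields[col["smiles"]].strip()
            tags = [t.strip() for t in fields[col["indications"]].split("|") if t.strip()]
            if not drug_id:
                raise DataFormatError(f"{path}:{lineno}: empty drug_id")
            if drug_id in seen_ids:
                raise DataFormatError(f"{path}:{lineno}: duplicate drug_id {drug_id!r}")
            if not tags:
                raise DataFormatError(f"{path}:{lineno}: drug {drug_id!r} has no indication tags")
            seen_ids.add(drug_id)
            for t in tags:
                if catalog is not None:
                    if t not in catalog:
                        raise DataFormatError(f"{path}:{lineno}: unknown tag {t!r}")
                elif t not in induced:
                    induced.append(t)
            records.append(DrugRecord(drug_id, smiles, frozenset(tags)))
    cat = catalog if catalog is not None else IndicationCatalog(induced)
    return Dataset(cat, records)


def write_drug_table(dataset: Dataset, path: str | Path, comment: str | None = None) -> None:
    """Write a dataset back to the canonical drug-table TSV.

    Tags are written in catalog order, so read→write→read is the identity
    on the canonical form.  *comment* adds a ``#``-prefixed provenance line
    readers skip.
    """
    order = {t: i for i, t in enumerate(dataset.catalog.tags)}
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("drug_id\tsmiles\tindications\n")
        for d in dataset.drugs:
            tags = sorted(d.indications, key=order.__getitem__)
            fh.write(f"{d.drug_id}\t{d.smiles}\t{'|'.join(tags)}\n")


#: column layout of the public STITCH chemical_chemical.links.detailed dump
STITCH_COLUMNS = (
    "chemical1",
    "chemical2",
    "similarity",
    "experimental",
    "database",
    "textmining",
    "combined_score",
)


def read_stitch_links(
    path: str | Path,
    id_filter: set[str] | None = None,
    score_column: str = "combined_score",
    scale: float = 1000.0,
) -> InteractionTable:
    """Read a STITCH-dialect interaction TSV into an :class:`InteractionTable`.

    STITCH publishes integer evidence scores on a 0–1000 scale; stored
    confidence weights are ``raw / scale``.  Only rows with raw score > 0
    are stored — a zero combined score means "no reported interaction" and
    lookups of such pairs return 0.  Rows whose identifiers are not both in
    *id_filter* (when given) are skipped.  A later duplicate of a pair, in
    either identifier order, overrides the earlier row with a warning.
    Self-pairs are dropped.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    table = InteractionTable()
    with _open_text(path) as fh:
        header_line, header_no = _read_header(fh)
        header = header_line.split("\t")
        if len(header) < 3:
            raise DataFormatError(f"{path}: expected at least 3 tab-separated columns")
        if score_column not in header:
            raise DataFormatError(f"{path}: missing score column {score_column!r}")
        a_col, b_col = 0, 1
        s_col = header.index(score_column)
        for lineno, raw in enumerate(fh, start=header_no + 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) <= s_col:
                raise DataFormatError(f"{path}:{lineno}: too few columns")
            a, b = fields[a_col].strip(), fields[b_col].strip()
            try:
                raw_score = float(fields[s_col])
            except ValueError:
                raise DataFormatError(
                    f"{path}:{lineno}: non-numeric {score_column} {fields[s_col]!r}"
                ) from None
            if a == b:
                continue
            if id_filter is not None and (a not in id_filter or b not in id_filter):
                continue
            if raw_score <= 0:
                continue
            if table.get(a, b) > 0.0:
                logger.warning("%s:%d: duplicate pair (%s, %s); last row wins", path, lineno, a, b)
            table.set(a, b, raw_score / scale)
    return table


def write_predictions(
    predictions: Sequence[tuple[str, "RankedPrediction"]],
    path: str | Path,
    comment: str | None = None,
) -> None:
    """Write ranked predictions as TSV: drug_id, rank (1-based), tag, score.

    A drug with an empty ranking contributes zero rows.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("drug_id\trank\tindication\tscore\n")
        for drug_id, pred in predictions:
            for rank, (tag, score) in enumerate(pred.items, start=1):
                fh.write(f"{drug_id}\t{rank}\t{tag}\t{score:.6g}\n")


def read_predictions(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Read a predictions TSV back into {drug_id: [(tag, score), ...]}."""
    out: dict[str, list[tuple[str, float]]] = {}
    with _open_text(path) as fh:
        header = _read_header(fh)[0].split("\t")
        col = {name: header.index(name) for name in ("drug_id", "rank", "indication", "score")}
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            lst = out.setdefault(f[col["drug_id"]], [])
            rank = int(f[col["rank"]])
            if rank != len(lst) + 1:
                raise DataFormatError(f"{path}: non-contiguous ranks for {f[col['drug_id']]!r}")
            lst.append((f[col["indication"]], float(f[col["score"]])))
    return out


_CID_RE = re.compile(r"^CIDm?s?0*(\d+)$")


def normalize_cid(identifier: str) -> str:
    """Collapse PubChem CID zero-padding variants to a canonical form.

    ``CID000005426`` → ``CID5426``; strings that are not padded CIDs pass
    through unchanged.  Identifier matching everywhere else in the package
    is exact string equality — apply this explicitly, before joining tables,
    only when you know both sides use CID identifiers.  It is deliberately
    not applied automatically: silent coercion hides join bugs.
    """
    m = _CID_RE.match(identifier)
    return f"CID{int(m.group(1))}" if m else identifier
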