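"""Load, validate, filter and reshape drug-pair / side-effect association tables.

The raw input is a long table in the Decagon/TWOSIDES layout: one row per
(drug CID, drug CID, side-effect CUI) assertion. This module turns it into
the two shapes the classifiers consume:

* a :class:`PairLabelTable` — one row per unordered drug pair with a
  multi-hot side-effect vector (multi-label classification input), and
* the filtered association list from which the bipartite graph is built.

Pairs are unordered: (a, b, s) and (b, a, s) are the same assertion, and
every pair is canonicalized to lexicographic order on its drug ids.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the Decagon combo distribution file.
DEFAULT_SCHEMA = {
    "drug_a": "STITCH 1",
    "drug_b": "STITCH 2",
    "side_effect_id": "Polypharmacy Side Effect",
    "side_effect_name": "Side Effect Name",
}


class ConfigurationError(ValueError):
    """A table does not expose a column the schema requires."""


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by an opaque id (e.g. PubChem CID) with its SMILES."""

    drug_id: str
    smiles: str
    structure_key: str | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"drug {self.drug_id!r}: empty SMILES")


@dataclass(frozen=True)
class AssociationRecord:
    """One drug-pair -> side-effect assertion (one raw table row).

    The pair is semantically unordered; ``canonical_pair`` fixes a
    reproducible ordering (lexicographic on the id strings).
    """

    drug_a: str
    drug_b: str
    side_effect_id: str
    side_effect_name: str = ""

    @property
    def canonical_pair(self) -> tuple[str, str]:
        a, b = self.drug_a, self.drug_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SideEffectVocabulary:
    """Stable ordered side-effect vocabulary defining multi-hot indices."""

    entries: tuple[tuple[str, str], ...]  # (side_effect_id, name), sorted by id
    index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate side-effect ids in vocabulary")
        object.__setattr__(self, "index", {sid: i for i, sid in enumerate(ids)})

    @classmethod
    def from_records(cls, records: Iterable[AssociationRecord]) -> "SideEffectVocabulary":
        names: dict[str, str] = {}
        for r in records:
            names.setdefault(r.side_effect_id, r.side_effect_name)
        return cls(tuple(sorted(names.items())))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, side_effect_id: str) -> bool:
        return side_effect_id in self.index

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]

    @property
    def names(self) -> list[str]:
        return [name for _, name in self.entries]


@dataclass(frozen=True)
class PairLabelTable:
    """One row per canonical drug pair, carrying its side-effect set.

    ``multihot`` is the (n_pairs, vocab_size) binary matrix; row order is the
    sorted order of canonical pairs so two runs on the same input are
    byte-identical.
    """

    pairs: tuple[tuple[str, str], ...]
    side_effect_sets: tuple[frozenset[str], ...]
    vocab: SideEffectVocabulary

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def multihot(self) -> np.ndarray:
        out = np.zeros((len(self.pairs), len(self.vocab)), dtype=np.int8)
        for i, ses in enumerate(self.side_effect_sets):
            for sid in ses:
                out[i, self.vocab.index[sid]] = 1
        return out

    def to_frame(self) -> pd.DataFrame:
        mh = self.multihot
        df = pd.DataFrame(
            {"drug_a": [p[0] for p in self.pairs], "drug_b": [p[1] for p in self.pairs]}
        )
        return pd.concat([df, pd.DataFrame(mh, columns=self.vocab.ids)], axis=1)


def load_association_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """Parse a delimited association table into :class:`AssociationRecord` rows.

    Self-pairs (drug_a == drug_b) and rows with blank fields are rejected,
    with counts logged. Raises :class:`ConfigurationError` if a schema column
    is missing; an empty file yields an empty list with a warning.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and not len(df.columns):
        logger.warning("association table %s is empty", path)
        return []
    for key in ("drug_a", "drug_b", "side_effect_id"):
        if schema[key] not in df.columns:
            raise ConfigurationError(
                f"column {schema[key]!r} (for {key}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    name_col = schema.get("side_effect_name")
    has_name = name_col in df.columns

    records: list[AssociationRecord] = []
    n_self = n_bad = 0
    col_a = df[schema["drug_a"]].tolist()
    col_b = df[schema["drug_b"]].tolist()
    col_s = df[schema["side_effect_id"]].tolist()
    col_n = df[name_col].tolist() if has_name else [""] * len(df)
    for a, b, sid, name in zip(col_a, col_b, col_s, col_n):
        if pd.isna(a) or pd.isna(b) or pd.isna(sid) or not a or not b or not sid:
            n_bad += 1
            continue
        a, b, sid = str(a).strip(), str(b).strip(), str(sid).strip()
        if a == b:
            n_self += 1
            continue
        records.append(AssociationRecord(a, b, sid, "" if pd.isna(name) else str(name)))
    if n_self or n_bad:
        logger.info(
            "dropped %d self-pair row(s) and %d malformed row(s) from %s",
            n_self, n_bad, path.name,
        )
    if not records:
        logger.warning("association table %s produced no usable records", path)
    return records


def filter_common_side_effects(
    records: Sequence[AssociationRecord],
    min_pairs: int = 500,
) -> tuple[list[AssociationRecord], SideEffectVocabulary]:
    """Keep side effects occurring in at least ``min_pairs`` distinct pairs.

    Pair counting is per distinct canonical pair, not per raw row. Returns
    the filtered records and the vocabulary built from the kept side effects
    (sorted by id, so multi-hot indices are stable across runs).
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    pairs_per_se: dict[str, set[tuple[str, str]]] = defaultdict(set)
    for r in records:
        pairs_per_se[r.side_effect_id].add(r.canonical_pair)
    kept = {sid for sid, ps in pairs_per_se.items() if len(ps) >= min_pairs}
    if not kept:
        logger.warning(
            "min_pairs=%d exceeds every side effect's pair count; empty vocabulary",
            min_pairs,
        )
    filtered = [r for r in records if r.side_effect_id in kept]
    vocab = SideEffectVocabulary.from_records(filtered)
    return filtered, vocab


def group_to_multilabel(
    records: Sequence[AssociationRecord],
    vocab: SideEffectVocabulary,
) -> PairLabelTable:
    """Union each canonical pair's side effects into one multi-label row.

    Input rows (d1, d2, A), (d1, d2, B), (d2, d1, C) collapse to one row for
    the pair with set {A, B, C}. The sum of row-set sizes equals the number
    of distinct (pair, side effect) assertions.
    """
    sets: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        if r.side_effect_id not in vocab:
            raise KeyError(f"side effect {r.side_effect_id!r} not in vocabulary")
        sets[r.canonical_pair].add(r.side_effect_id)
    pairs = tuple(sorted(sets))
    return PairLabelTable(
        pairs=pairs,
        side_effect_sets=tuple(frozenset(sets[p]) for p in pairs),
        vocab=vocab,
    )


def encode_multihot(side_effects: Iterable[str], vocab: SideEffectVocabulary) -> np.ndarray:
    """Binary indicator vector of length ``len(vocab)`` over the given set."""
    out = np.zeros(len(vocab), dtype=np.int8)
    for sid in side_effects:
        if sid not in vocab:
            raise KeyError(f"unknown side effect id {sid!r}")
        out[vocab.index[sid]] = 1
    return out


def decode_multihot(vector: np.ndarray, vocab: SideEffectVocabulary) -> frozenset[str]:
    """Inverse of :func:`encode_multihot`."""
    if len(vector) != len(vocab):
        raise ValueError("vector length does not match vocabulary size")
    return frozenset(sid for sid, v in zip(vocab.ids, vector) if v)


# ---------------------------------------------------------------------------
# Structure keys


def rdkit_inchikey_backend(smiles: str) -> str:
    """Full InChIKey of a SMILES via RDKit; raises ValueError if unparsable."""
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToInchiKey(mol)


def fake_structure_backend(smiles: str) -> str:
    """Deterministic string-normalizing hash standing in for a structure key.

    Sorts the characters of the SMILES and hashes them, so trivially
    reordered writings collide while distinct character multisets do not.
    Not a chemical canonicalization; for tests and synthetic inputs only.
    """
    import hashlib

    norm = "".join(sorted(smiles))
    return hashlib.sha1(norm.encode()).hexdigest()[:27].upper()


@dataclass
class StructureKeyAudit:
    records: list[DrugRecord]
    failed: list[DrugRecord]
    duplicate_keys: dict[str, list[str]]  # key -> drug ids sharing it

    @property
    def n_unique(self) -> int:
        return len({r.structure_key for r in self.records})


def compute_structure_keys(
    drugs: Sequence[DrugRecord],
    backend: Callable[[str], str] = rdkit_inchikey_backend,
) -> StructureKeyAudit:
    """Attach a structure key to each drug and audit key uniqueness.

    Unparsable SMILES are flagged in ``failed``, never silently dropped.
    """
    out: list[DrugRecord] = []
    failed: list[DrugRecord] = []
    by_key: dict[str, list[str]] = defaultdict(list)
    for d in drugs:
        try:
            key = backend(d.smiles)
        except ValueError:
            failed.append(d)
            continue
        out.append(replace(d, structure_key=key))
        by_key[key].append(d.drug_id)
    dupes = {k: ids for k, ids in by_key.items() if len(ids) > 1}
    if failed:
        logger.warning("%d SMILES could not be parsed by the structure backend", len(failed))
    if dupes:
        logger.warning("%d structure keys shared by multiple drugs", len(dupes))
    return StructureKeyAudit(records=out, failed=failed, duplicate_keys=dupes)


def smiles_length_stats(drugs: Sequence[DrugRecord], n_bins: int = 20) -> dict:
    """Character-length summary of a drug library's SMILES strings."""
    if not drugs:
        raise ValueError("empty drug list")
    lengths = np.array([len(d.smiles) for d in drugs])
    hist, edges = np.histogram(lengths, bins=n_bins)
    return {
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "min": int(lengths.min()),
        "max": int(lengths.max()),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
    }


# ---------------------------------------------------------------------------
# Chemistry table


@dataclass
class SmilesFetchResult:
    records: list[DrugRecord]
    missing: list[str]


def fetch_smiles(
    drug_ids: Sequence[str],
    source: str | Path | Callable[[str], str | None],
    cache_path: str | Path | None = None,
) -> SmilesFetchResult:
    """Resolve drug ids to SMILES from a local chemistry table or adapter.

    ``source`` is either a CSV path with columns (cid, smiles) or a callable
    id -> SMILES-or-None (e.g. a remote-fetch adapter; never exercised in
    tests). Unresolvable ids go to the missing report and the pipeline
    continues with the resolved subset. If ``cache_path`` is given, resolved
    records are written there as CSV and reused on later calls.
    """
    cache: dict[str, str] = {}
    if cache_path is not None and Path(cache_path).exists():
        cache = _read_chem_csv(cache_path)

    lookup: Callable[[str], str | None]
    if callable(source):
        lookup = source
    else:
        table = _read_chem_csv(source)
        lookup = table.get

    records: list[DrugRecord] = []
    missing: list[str] = []
    for did in drug_ids:
        smiles = cache.get(did) or lookup(did)
        if smiles:
            records.append(DrugRecord(drug_id=did, smiles=smiles))
            cache[did] = smiles
        else:
            missing.append(did)
    if missing:
        logger.warning("%d drug id(s) unresolved: %s", len(missing), missing[:10])
    if cache_path is not None:
        _write_chem_csv(cache_path, cache)
    return SmilesFetchResult(records=records, missing=missing)


def _read_chem_csv(path: str | Path) -> dict[str, str]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        rows = list(reader)
    if header and header[0].lower() in {"cid", "drug_id"}:
        pass
    elif header:
        rows.insert(0, header)
    return {r[0].strip(): r[1].strip() for r in rows if len(r) >= 2 and r[1].strip()}


def _write_chem_csv(path: str | Path, table: Mapping[str, str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cid", "smiles"])
        for cid in sorted(table):
            writer.writerow([cid, table[cid]])


def association_summary(records: Sequence[AssociationRecord]) -> dict:
    """Headline counts of an association table (before or after filtering)."""
    pairs = {r.canonical_pair for r in records}
    ses = Counter(r.side_effect_id for r in records)
    return {
        "n_associations": len(records),
        "n_distinct_pairs": len(pairs),
        "n_side_effect_types": len(ses),
    }
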