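"""SMILES and side-effect-name embedding providers, and drug-pair fusion.

Every provider satisfies the same contract: ``encode_batch`` maps a list of
strings to an (n, dim) float matrix, deterministically for fixed provider
state, and ``tokenize`` exposes the provider's tokenization when it has one.

Two families are registered:

* ``hash-ngram`` — a fully offline character n-gram feature-hashing encoder
  (n = 1..3, hashed into ``dim`` buckets, L2-normalized, seeded). It
  exercises the whole pipeline with no model download and is the encoder
  used throughout the test suite.
* pretrained language-model adapters (``chemberta-deepchem``,
  ``chemberta-simcse``, ``bert``, ``sbert``, ``gpt-small``, ``mol2vec``,
  ``doc2vec``) — these require model checkpoints or a network API and raise
  :class:`ProviderUnavailableError` on encode in an offline session. Their
  tokenizers, where character-faithful, are implemented locally.

Pair fusion follows e_pair = e1 + e2 by default (summation); concat, mean
and elementwise product are available for the fusion-strategy comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .dataprep import PairLabelTable

FUSION_STRATEGIES = ("sum", "concat", "mean", "product")

#: Character budget for language-model inputs; SMILES in the reference
#: corpus average ~54 characters, so 64 preserves most strings untruncated.
DEFAULT_MAX_LEN = 64


class ProviderUnavailableError(RuntimeError):
    """The provider needs a pretrained checkpoint or network access."""


class UnsupportedOperationError(RuntimeError):
    """The provider does not implement the requested operation."""


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    truncated: bool = False


@dataclass
class EmbeddingProvider:
    """Base contract: name, output dim, truncation length.

    Subclasses implement ``_encode_one`` (or override ``encode_batch``) and
    optionally ``_tokenize``.
    """

    name: str
    dim: int
    max_len: int = DEFAULT_MAX_LEN

    def tokenize(self, text: str) -> TokenSequence:
        tokens = self._tokenize(text)
        truncated = len(tokens) > self.max_len
        if truncated:
            tokens = tokens[: self.max_len]
        return TokenSequence(tuple(tokens), truncated)

    def _tokenize(self, text: str) -> list[str]:
        raise UnsupportedOperationError(f"provider {self.name!r} has no tokenizer")

    def encode_batch(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dim), dtype=np.float64)
        for i, t in enumerate(texts):
            out[i] = self._encode_one(t)
        return out

    def _encode_one(self, text: str) -> np.ndarray:
        raise NotImplementedError


def _char_tokenize(text: str) -> list[str]:
    return list(text)


@dataclass
class HashNgramProvider(EmbeddingProvider):
    """Seeded character n-gram feature hashing into ``dim`` buckets.

    Each 1-, 2- and 3-gram of the (truncated) input is hashed with a seeded
    key to a bucket and a sign; the bucket vector is L2-normalized. Output is
    a pure function of (text, dim, max_len, seed), identical across
    processes and platforms.
    """

    name: str = "hash-ngram"
    dim: int = 128
    max_len: int = DEFAULT_MAX_LEN
    seed: int = 0
    ngram_range: tuple[int, int] = (1, 3)

    def _tokenize(self, text: str) -> list[str]:
        return _char_tokenize(text)

    def _encode_one(self, text: str) -> np.ndarray:
        text = text[: self.max_len]
        vec = np.zeros(self.dim, dtype=np.float64)
        lo, hi = self.ngram_range
        for n in range(lo, hi + 1):
            for i in range(max(len(text) - n + 1, 0)):
                gram = text[i : i + n]
                digest = hashlib.blake2b(
                    gram.encode(), key=str(self.seed).encode()[:64], digest_size=8
                ).digest()
                h = int.from_bytes(digest, "little")
                vec[h % self.dim] += 1.0 if (h >> 63) & 1 else -1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class PretrainedAdapter(EmbeddingProvider):
    """Adapter slot for a pretrained language model or embedding API.

    Tokenization (when character-faithful, as for the ChemBERTa models on
    SMILES) runs locally; encoding requires the checkpoint/API and raises
    :class:`ProviderUnavailableError` when it is not installed.
    """

    name: str = "bert"
    dim: int = 768
    max_len: int = DEFAULT_MAX_LEN
    tokenizer: Callable[[str], list[str]] | None = None

    def _tokenize(self, text: str) -> list[str]:
        if self.tokenizer is None:
            raise UnsupportedOperationError(
                f"provider {self.name!r} tokenizes server-side; no local tokenizer"
            )
        return self.tokenizer(text)

    def encode_batch(self, texts: Sequence[str]) -> np.ndarray:
        raise ProviderUnavailableError(
            f"provider {self.name!r} requires a pretrained checkpoint or network "
            "API that is not available in this session; use 'hash-ngram' for "
            "offline runs"
        )


# SMILES-trained chemical LMs tokenize atom symbols character-wise:
# "C(CS(=O)(=O)O)S" -> C ( C S ( = O ) ( = O ) O ) S
_REGISTRY: dict[str, Callable[..., EmbeddingProvider]] = {
    "hash-ngram": lambda **kw: HashNgramProvider(**kw),
    "chemberta-deepchem": lambda **kw: PretrainedAdapter(
        name="chemberta-deepchem", dim=kw.pop("dim", 384), tokenizer=_char_tokenize, **kw
    ),
    "chemberta-simcse": lambda **kw: PretrainedAdapter(
        name="chemberta-simcse", dim=kw.pop("dim", 384), tokenizer=_char_tokenize, **kw
    ),
    "bert": lambda **kw: PretrainedAdapter(name="bert", dim=kw.pop("dim", 768), **kw),
    "sbert": lambda **kw: PretrainedAdapter(name="sbert", dim=kw.pop("dim", 384), **kw),
    "gpt-small": lambda **kw: PretrainedAdapter(name="gpt-small", dim=kw.pop("dim", 1536), **kw),
    "mol2vec": lambda **kw: PretrainedAdapter(name="mol2vec", dim=kw.pop("dim", 300), **kw),
    "doc2vec": lambda **kw: PretrainedAdapter(name="doc2vec", dim=kw.pop("dim", 300), **kw),
}


def get_provider(name: str, **kwargs) -> EmbeddingProvider:
    """Resolve a provider registry key; unknown names fail at startup."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown embedding provider {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def available_providers() -> list[str]:
    return sorted(_REGISTRY)


def tokenize(provider: EmbeddingProvider, smiles: str) -> TokenSequence:
    return provider.tokenize(smiles)


def encode_batch(provider: EmbeddingProvider, texts: Sequence[str]) -> np.ndarray:
    return provider.encode_batch(list(texts))


def encode_side_effect_names(
    names: Sequence[str], provider: EmbeddingProvider
) -> np.ndarray:
    """Embed side-effect name strings (lowercased) with a text provider."""
    return provider.encode_batch([n.lower() for n in names])


def fuse_pair(e1: np.ndarray, e2: np.ndarray, strategy: str = "sum") -> np.ndarray:
    """Fuse two drug embeddings into one pair embedding.

    ``sum`` (the default, e_pair = e1 + e2), ``mean`` and ``product`` are
    symmetric in the two drugs; ``concat`` is order-sensitive and relies on
    the pair's canonical order.
    """
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    if strategy not in FUSION_STRATEGIES:
        raise ValueError(f"unknown fusion strategy {strategy!r}; use one of {FUSION_STRATEGIES}")
    if strategy == "concat":
        return np.concatenate([e1, e2])
    if e1.shape != e2.shape:
        raise ValueError(f"dim mismatch for {strategy!r} fusion: {e1.shape} vs {e2.shape}")
    if strategy == "sum":
        return e1 + e2
    if strategy == "mean":
        return (e1 + e2) / 2.0
    return e1 * e2


def build_pair_matrix(
    table: PairLabelTable,
    drug_vectors: Mapping[str, np.ndarray],
    strategy: str = "sum",
) -> np.ndarray:
    """Fused pair-embedding matrix aligned row-for-row with the label table."""
    rows = []
    for a, b in table.pairs:
        for d in (a, b):
            if d not in drug_vectors:
                raise KeyError(f"no embedding for drug {d!r}")
        rows.append(fuse_pair(drug_vectors[a], drug_vectors[b], strategy))
    width = rows[0].shape[0] if rows else 0
    return np.array(rows, dtype=np.float64).reshape(len(rows), width)


def embed_drugs(
    drugs: Iterable, provider: EmbeddingProvider
) -> dict[str, np.ndarray]:
    """Map drug_id -> embedding for a DrugRecord iterable."""
    drugs = list(drugs)
    mat = provider.encode_batch([d.smiles for d in drugs])
    return {d.drug_id: mat[i] for i, d in enumerate(drugs)}
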