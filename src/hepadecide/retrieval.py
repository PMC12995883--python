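"""Paragraph chunking, embedding and per-document top-k cosine retrieval.

Reference documents (treatment guidelines, review articles) are split at
paragraph level into self-contained chunks, embedded as unit-length vectors,
and queried with the clinical case text; the top ``k`` chunks *per document*
(five by default) supply the evidence for retrieval-augmented decision
prompts.

The bundled embedder is a deterministic token-hashing bag-of-words model, so
the whole retrieval stage is exactly reproducible and dependency-free; any
object with ``name``, ``dim`` and ``embed(texts) -> array`` (for example a
sentence-transformer wrapper) can be used in its place. Similarity search is
exact (full cosine scan) — corpora here are a handful of documents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .textproc import split_paragraphs, tokenize

DEFAULT_K_PER_DOC = 5


class RetrievalError(ValueError):
    pass


@dataclass
class Chunk:
    """A paragraph-level unit of a reference document."""

    doc_id: str
    chunk_index: int
    text: str
    vector: Optional[np.ndarray] = None


@dataclass(frozen=True)
class RetrievalResult:
    chunk: Chunk
    similarity: float


def chunk_document(doc_id: str, text: str, min_words: int = 5) -> List[Chunk]:
    """Split on blank-line boundaries; paragraphs shorter than ``min_words``
    are merged forward into the next paragraph (the last short paragraph
    merges backward). Order is preserved."""
    paragraphs = split_paragraphs(text)
    if not paragraphs:
        raise RetrievalError(f"document {doc_id!r} is empty")
    merged: List[str] = []
    pending = ""
    for para in paragraphs:
        candidate = (pending + "\n" + para).strip() if pending else para
        if len(candidate.split()) < min_words:
            pending = candidate
        else:
            merged.append(candidate)
            pending = ""
    if pending:
        if merged:
            merged[-1] = merged[-1] + "\n" + pending
        else:
            merged.append(pending)
    return [Chunk(doc_id=doc_id, chunk_index=i, text=t) for i, t in enumerate(merged)]


class HashingEmbedder:
    """Deterministic bag-of-words embedder: each token is hashed to one of
    ``dim`` buckets, counts are accumulated and L2-normalized."""

    def __init__(self, dim: int = 256):
        self.dim = dim
        self.name = f"hashing-{dim}"

    def bucket(self, token: str) -> int:
        digest = hashlib.md5(token.encode("utf-8")).digest()
        return int.from_bytes(digest[:4], "big") % self.dim

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            for tok in tokenize(text):
                out[row, self.bucket(tok.text)] += 1.0
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
        return out


def embed_chunks(chunks: Sequence[Chunk], embedder) -> List[Chunk]:
    """Attach unit-norm vectors to chunks."""
    try:
        vectors = embedder.embed([c.text for c in chunks])
    except Exception as exc:  # noqa: BLE001
        raise RetrievalError(f"embedder {getattr(embedder, 'name', '?')} failed") from exc
    for chunk, vec in zip(chunks, vectors):
        norm = np.linalg.norm(vec)
        chunk.vector = vec / norm if norm > 0 else vec
    return list(chunks)


class VectorIndex:
    """Exact cosine index over embedded chunks from one or more documents."""

    def __init__(self, embedder=None):
        self.embedder = embedder or HashingEmbedder()
        self.chunks: List[Chunk] = []
        self._matrix: Optional[np.ndarray] = None

    def add_document(self, doc_id: str, text: str, min_words: int = 5) -> int:
        chunks = embed_chunks(chunk_document(doc_id, text, min_words), self.embedder)
        self.chunks.extend(chunks)
        self._matrix = None
        return len(chunks)

    def add_chunks(self, chunks: Sequence[Chunk]) -> None:
        for c in chunks:
            if c.vector is None:
                raise RetrievalError("chunks must be embedded before indexing")
        self.chunks.extend(chunks)
        self._matrix = None

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = np.vstack([c.vector for c in self.chunks])
        return self._matrix

    def doc_ids(self) -> List[str]:
        return sorted({c.doc_id for c in self.chunks})

    def retrieve(self, query_text: str, k_per_doc: int = DEFAULT_K_PER_DOC) -> List[RetrievalResult]:
        """Top ``min(k, n_chunks(doc))`` chunks from *each* indexed document,
        sorted by cosine similarity descending; ties broken by
        (doc_id, chunk_index)."""
        if not self.chunks:
            raise RetrievalError("empty index")
        query = self.embedder.embed([query_text])[0]
        norm = np.linalg.norm(query)
        if norm > 0:
            query = query / norm
        sims = self.matrix @ query
        # ties (including float-noise near-ties) break by (doc_id, chunk_index)
        results: List[RetrievalResult] = []
        for doc_id in self.doc_ids():
            scored = [
                (-round(float(sims[i]), 12), c.doc_id, c.chunk_index, i)
                for i, c in enumerate(self.chunks)
                if c.doc_id == doc_id
            ]
            scored.sort()
            for _, _, _, i in scored[:k_per_doc]:
                results.append(RetrievalResult(chunk=self.chunks[i], similarity=float(sims[i])))
        results.sort(
            key=lambda r: (-round(r.similarity, 12), r.chunk.doc_id, r.chunk.chunk_index)
        )
        return results

    # -- persistence --------------------------------------------------------

    def save(self, path: Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), matrix=self.matrix)
        sidecar = {
            "version": 1,
            "embedder": self.embedder.name,
            "dim": int(self.matrix.shape[1]),
            "chunks": [
                {"doc_id": c.doc_id, "chunk_index": c.chunk_index, "text": c.text}
                for c in self.chunks
            ],
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: Path, embedder=None) -> "VectorIndex":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        matrix = np.load(path.with_suffix(".npz"))["matrix"]
        index = cls(embedder=embedder or HashingEmbedder(dim=sidecar["dim"]))
        if index.embedder.name != sidecar["embedder"]:
            raise RetrievalError(
                f"index was built with embedder {sidecar['embedder']!r}, "
                f"got {index.embedder.name!r}"
            )
        chunks = []
        for meta, vec in zip(sidecar["chunks"], matrix):
            chunks.append(Chunk(vector=vec, **meta))
        index.add_chunks(chunks)
        return index


def load_reference_documents(paths: Sequence[Path]) -> Dict[str, str]:
    """Read plain-text/markdown reference documents keyed by file stem."""
    docs = {}
    for p in paths:
        p = Path(p)
        docs[p.stem] = p.read_text(encoding="utf-8")
    return docs


def bundled_reference_documents() -> Dict[str, str]:
    """The two synthetic guideline fixtures shipped with the package."""
    from importlib import resources

    docs = {}
    for name in ("synthetic_guideline", "synthetic_treatment_hierarchy"):
        ref = resources.files("hepadecide").joinpath("data", f"{name}.md")
        docs[name] = ref.read_text(encoding="utf-8")
    return docs
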