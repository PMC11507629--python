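"""Input feature construction: sinusoidal positional encoding, token
embedding, protein-language-model (PLM) embedding providers, and fusion.

The model input for a length-L sequence is the rowwise concatenation of

* a per-residue PLM embedding (L x 1024 from the provider interface), and
* a sequence encoding (L x d_model): a learned token embedding plus the
  fixed sinusoidal positional encoding

    PE(pos, 2i)   = sin(pos / 10000^(2i / d_model))
    PE(pos, 2i+1) = cos(pos / 10000^(2i / d_model))

with 0-based positions, so the pos = 0 row is (0, 1, 0, 1, ...).

Providers are looked up by key: ``"mock"`` (deterministic, dependency-free,
for tests and desk-scale runs), ``"cache"`` (precomputed matrices in an
HDF5 file keyed by sequence id), and ``"prott5"`` (a real half-precision
ProtT5 encoder adapter, available only when the optional ``transformers``
dependency is installed).
"""

from __future__ import annotations

import hashlib
from typing import Dict, Iterable, Mapping, Optional, Union

import h5py
import numpy as np

from .seq_io import RESIDUE_ALPHABET, ResidueSequence

#: Embedding width of the PLM provider contract (per-residue vector size).
PLM_DIM = 1024

#: Default width of the learned sequence encoding.
DEFAULT_D_MODEL = 512

#: Default maximum sequence length; longer inputs are truncated with a warning.
MAX_SEQ_LEN = 2000

RESIDUE_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(RESIDUE_ALPHABET)}


class ConfigurationError(ValueError):
    """Raised for invalid encoding/backbone configuration."""


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding matrix of shape (L, d_model).

    Entry (pos, 2i) is sin(pos / 10000^(2i/d_model)) and entry
    (pos, 2i+1) is cos of the same angle, so each (even, odd) pair lies
    on the unit circle.  Positions are 0-based.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if d_model < 2 or d_model % 2 != 0:
        raise ConfigurationError("d_model must be even and >= 2")
    pos = np.arange(L, dtype=np.float64)[:, None]
    two_i = np.arange(0, d_model, 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, two_i / d_model)
    pe = np.empty((L, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def init_token_table(
    d_model: int, rng: np.random.Generator, scale: float = 0.1
) -> np.ndarray:
    """Initialize the (21, d_model) trainable token-embedding table."""
    return scale * rng.standard_normal((len(RESIDUE_ALPHABET), d_model))


def residue_indices(seq: Union[ResidueSequence, str]) -> np.ndarray:
    residues = seq.residues if isinstance(seq, ResidueSequence) else seq
    return np.array([RESIDUE_INDEX[aa] for aa in residues], dtype=np.intp)


def token_embed(seq: Union[ResidueSequence, str], table: np.ndarray) -> np.ndarray:
    """Look up the token-embedding row of each residue; shape (L, d_model)."""
    idx = residue_indices(seq)
    if table.shape[0] != len(RESIDUE_ALPHABET):
        raise ConfigurationError(
            f"token table must have {len(RESIDUE_ALPHABET)} rows, got {table.shape[0]}"
        )
    return table[idx]


def sequence_encoding(
    seq: Union[ResidueSequence, str], table: np.ndarray
) -> np.ndarray:
    """Token embedding + positional encoding, shape (L, d_model)."""
    tok = token_embed(seq, table)
    L, d_model = tok.shape
    if L == 0:
        return tok
    return tok + positional_encoding(L, d_model)


def fuse_features(
    plm: Optional[np.ndarray] = None, seqenc: Optional[np.ndarray] = None
) -> np.ndarray:
    """Rowwise concatenation of the PLM embedding and the sequence encoding.

    Under ablation either side may be omitted (pass None), in which case
    the remaining side is returned unchanged.
    """
    if plm is None and seqenc is None:
        raise ConfigurationError("at least one of plm/seqenc must be provided")
    if plm is None:
        return seqenc
    if seqenc is None:
        return plm
    if plm.shape[0] != seqenc.shape[0]:
        raise ValueError(
            f"length mismatch: plm has {plm.shape[0]} rows, seqenc {seqenc.shape[0]}"
        )
    return np.concatenate([plm, seqenc], axis=1)


# -- PLM embedding providers ------------------------------------------------


class MockEmbeddingProvider:
    """Deterministic stand-in for a PLM encoder.

    Row t of the embedding is drawn from a generator seeded by a hash of
    (seed, sequence string, position, residue): a pure function of the
    sequence and the seed, independent of batch composition, with
    approximately unit-variance entries.
    """

    name = "mock"

    def __init__(self, seed: int = 0, dim: int = PLM_DIM):
        self.seed = int(seed)
        self.dim = int(dim)

    def embed(self, seq: Union[ResidueSequence, str]) -> np.ndarray:
        residues = seq.residues if isinstance(seq, ResidueSequence) else seq
        out = np.empty((len(residues), self.dim), dtype=np.float64)
        for t, aa in enumerate(residues):
            key = f"{self.seed}|{residues}|{t}|{aa}".encode()
            row_seed = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
            out[t] = np.random.default_rng(row_seed).standard_normal(self.dim)
        return out


class CacheEmbeddingProvider:
    """Reads precomputed per-residue embeddings from an HDF5 cache.

    The cache holds one float dataset per sequence id, each of shape
    (L, dim).  See :func:`write_embedding_cache`.
    """

    name = "cache"

    def __init__(self, path: str):
        self.path = str(path)

    def embed(self, seq: Union[ResidueSequence, str]) -> np.ndarray:
        if not isinstance(seq, ResidueSequence):
            raise ValueError("cache provider requires a ResidueSequence with an id")
        with h5py.File(self.path, "r") as fh:
            if seq.id not in fh:
                raise KeyError(f"no cached embedding for id {seq.id!r} in {self.path}")
            mat = np.asarray(fh[seq.id], dtype=np.float64)
        if mat.shape[0] != len(seq):
            raise ValueError(
                f"cached embedding for {seq.id!r} has {mat.shape[0]} rows, "
                f"sequence has {len(seq)}"
            )
        return mat


def write_embedding_cache(path: str, matrices: Mapping[str, np.ndarray]) -> None:
    """Write an HDF5 embedding cache, one dataset per sequence id."""
    with h5py.File(path, "w") as fh:
        for rec_id, mat in matrices.items():
            fh.create_dataset(rec_id, data=np.asarray(mat, dtype=np.float32))


def get_provider(name: str, *, seed: int = 0, dim: int = PLM_DIM, cache_path: Optional[str] = None):
    """Look up an embedding provider by config key."""
    if name == "mock":
        return MockEmbeddingProvider(seed=seed, dim=dim)
    if name == "cache":
        if cache_path is None:
            raise ConfigurationError("cache provider requires a cache_path")
        return CacheEmbeddingProvider(cache_path)
    if name == "prott5":
        try:
            import transformers  # noqa: F401
        except ImportError as err:
            raise ConfigurationError(
                "the 'prott5' provider needs the optional 'transformers' "
                "dependency (and model weights); use the 'mock' provider for "
                "dependency-free runs or 'cache' for precomputed embeddings"
            ) from err
        raise NotImplementedError(
            "ProtT5 adapter requires downloaded encoder weights; precompute "
            "embeddings and use the 'cache' provider"
        )
    raise ConfigurationError(
        f"unknown embedding provider {name!r}; expected 'mock', 'cache' or 'prott5'"
    )


def plm_embed(seq: Union[ResidueSequence, str], provider) -> np.ndarray:
    """Per-residue PLM embedding via the provider interface; shape (L, dim)."""
    mat = provider.embed(seq)
    if not np.all(np.isfinite(mat)):
        raise ValueError("embedding contains non-finite entries")
    return mat
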