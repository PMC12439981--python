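"""Sequence encodings for the tail repression classifier.

Two parallel representations are used per tail: a ``L x 20`` one-hot matrix
(columns in alphabetical one-letter-code order) and a ``L x D`` per-residue
embedding from a pluggable embedder.  The default embedder is a fixed
physicochemical descriptor table (hydropathy, charge, volume, polarity)
expanded with a seeded orthonormal basis to D = 16, so the package trains
and tests without downloading a protein language model; a large
language-model backend can be registered under the same interface.
"""

from __future__ import annotations

import numpy as np

from .variants import CANONICAL_AA

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
TAIL_LENGTH = 30

# per-residue descriptors: Kyte-Doolittle hydropathy, net charge at pH 7,
# side-chain volume (A^3), Grantham polarity
_DESCRIPTORS = {
    "A": (1.8, 0.0, 88.6, 8.1),
    "C": (2.5, 0.0, 108.5, 5.5),
    "D": (-3.5, -1.0, 111.1, 13.0),
    "E": (-3.5, -1.0, 138.4, 12.3),
    "F": (2.8, 0.0, 189.9, 5.2),
    "G": (-0.4, 0.0, 60.1, 9.0),
    "H": (-3.2, 0.1, 153.2, 10.4),
    "I": (4.5, 0.0, 166.7, 5.2),
    "K": (-3.9, 1.0, 168.6, 11.3),
    "L": (3.8, 0.0, 166.7, 4.9),
    "M": (1.9, 0.0, 162.9, 5.7),
    "N": (-3.5, 0.0, 114.1, 11.6),
    "P": (-1.6, 0.0, 112.7, 8.0),
    "Q": (-3.5, 0.0, 143.8, 10.5),
    "R": (-4.5, 1.0, 173.4, 10.5),
    "S": (-0.8, 0.0, 89.0, 9.2),
    "T": (-0.7, 0.0, 116.1, 8.6),
    "V": (4.2, 0.0, 140.0, 5.9),
    "W": (-0.9, 0.0, 227.8, 5.4),
    "Y": (-1.3, 0.0, 193.6, 6.2),
}


def one_hot_encode(seq: str, length: int = TAIL_LENGTH) -> np.ndarray:
    """``length x 20`` one-hot matrix; exactly one 1 per row."""
    if len(seq) != length:
        raise ValueError(f"sequence length {len(seq)} != {length}")
    out = np.zeros((length, len(CANONICAL_AA)), dtype=np.float64)
    for i, aa in enumerate(seq):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"non-canonical residue {aa!r} at position {i + 1}")
        out[i, j] = 1.0
    return out


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` via per-row argmax."""
    return "".join(CANONICAL_AA[j] for j in np.argmax(mat, axis=1))


class ResidueTableEmbedder:
    """Per-residue table lookup embedder (deterministic, local).

    Columns 0-3 are standardized physicochemical descriptors; the remaining
    columns are a fixed-seed orthonormal random expansion, giving every
    residue a distinct D-dimensional signature independent of user seeds.
    """

    name = "fallback"

    def __init__(self, dim: int = 16, table_seed: int = 20231101) -> None:
        if dim < 4:
            raise ValueError("dim must be >= 4")
        self.dim = dim
        desc = np.array([_DESCRIPTORS[aa] for aa in CANONICAL_AA], dtype=np.float64)
        desc = (desc - desc.mean(axis=0)) / desc.std(axis=0)
        rng = np.random.default_rng(table_seed)
        extra = rng.standard_normal((len(CANONICAL_AA), dim - 4))
        q, _ = np.linalg.qr(extra)
        extra = q * np.sqrt(len(CANONICAL_AA))  # unit column variance
        self.table = np.hstack([desc, extra])

    def embed(self, seq: str) -> np.ndarray:
        idx = [AA_INDEX[aa] for aa in seq]
        return self.table[idx]


class ZerosEmbedder:
    """All-zeros embedder: the embedding branch carries no information."""

    name = "zeros"

    def __init__(self, dim: int = 16) -> None:
        self.dim = dim

    def embed(self, seq: str) -> np.ndarray:
        return np.zeros((len(seq), self.dim), dtype=np.float64)


class ESM2Embedder:
    """Per-residue protein-language-model embeddings (optional backend).

    Requires the ``esm`` and ``torch`` packages; raises at construction when
    they are unavailable.
    """

    name = "esm2"

    def __init__(self, model_name: str = "esm2_t48_15B_UR50D") -> None:
        try:
            import esm  # noqa: F401
            import torch  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "the esm2 embedder requires the 'esm' and 'torch' packages"
            ) from exc
        raise NotImplementedError(  # pragma: no cover
            "language-model embedding requires downloading model weights; "
            "register a wrapper with register_embedder() to enable it"
        )


_REGISTRY: dict[str, object] = {}


def register_embedder(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_embedder(name: str):
    """Instantiate a registered embedder by id (``fallback``, ``zeros``, ...)."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown embedder {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name]()


register_embedder("fallback", ResidueTableEmbedder)
register_embedder("zeros", ZerosEmbedder)
register_embedder("esm2", ESM2Embedder)


def encode_batch(seqs: list[str], embedder, length: int = TAIL_LENGTH):
    """One-hot and embedding tensors for a batch of equal-length sequences."""
    X1 = np.stack([one_hot_encode(s, length) for s in seqs])
    X2 = np.stack([np.asarray(embedder.embed(s), dtype=np.float64) for s in seqs])
    return X1, X2
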