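"""Embedding-provider contract and the deterministic synthetic backend.

A backend turns one (allele, peptide) pair into a :class:`BackendOutput`
bundle: per-position MHC embeddings ``H_mhc`` (M x D_mhc), per-residue
peptide embeddings ``H_p`` (N x D_p), a predicted residue contact map
``A`` (N x N, symmetric, entries in [0, 1], unit diagonal) and an
optional attention profile (rows summing to 1).

In the full-scale pipeline this role is played by fine-tuned protein
language models (an MSA model for the MHC pseudo-sequence, a
general-purpose model for the peptide, the latter also supplying the
contact map).  The synthetic backend below reproduces the *statistical
shape* of those outputs deterministically from a seed, so every
downstream stage is testable on one CPU with no downloads:

* residue embeddings come from seed-determined per-residue-identity
  lookup tables, so embeddings are reproducible, differ whenever the
  sequence differs, and carry residue identity for downstream models;
* the contact map is a banded kernel ``exp(-|i-j| / band_width)``
  (short-range backbone proximity) plus a few planted symmetric
  long-range contacts at value >= 0.9 (tertiary-structure contacts),
  with the planting positions derived from a hash of the sequence;
* the attention profile is the contact map with rows normalized to 1.

The fine-tune objective used at the language-model stage is a mean
squared error between predicted and observed binding reactivity; it is
exposed here as :func:`finetune_loss` so any real backend plugin can
reuse it.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .errors import BackendError, EmptyBatch, ShapeError
from .seq_io import CANONICAL_AA, MHCAllele, validate_sequence


@dataclass
class BackendOutput:
    """Per-pair embedding bundle produced by a backend."""

    H_mhc: np.ndarray  # (M, D_mhc)
    H_p: np.ndarray  # (N, D_p)
    A: np.ndarray  # (N, N) contact scores in [0, 1]
    attention: np.ndarray | None = None  # (N, N), rows sum to 1

    def validate(self, atol: float = 1e-6) -> "BackendOutput":
        for name, arr in (("H_mhc", self.H_mhc), ("H_p", self.H_p), ("A", self.A)):
            if not np.all(np.isfinite(arr)):
                raise BackendError(f"{name} contains non-finite entries")
        n = self.H_p.shape[0]
        if self.A.shape != (n, n):
            raise ShapeError(f"A has shape {self.A.shape}, expected ({n}, {n})")
        if not np.allclose(self.A, self.A.T, atol=atol):
            raise BackendError("contact map is not symmetric")
        if self.A.min() < -atol or self.A.max() > 1 + atol:
            raise BackendError("contact map entries outside [0, 1]")
        return self


def stable_hash(*parts: object, mod: int = 2**31) -> int:
    """Platform-independent deterministic hash of the given parts."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "big") % mod


def finetune_loss(predictions, y) -> float:
    """Mean squared error between predicted and target reactivity.

    The batch-expectation of the squared L2 distance between the model
    output and the binary reactivity target.
    """
    p = np.asarray(predictions, dtype=float).ravel()
    t = np.asarray(y, dtype=float).ravel()
    if p.size == 0:
        raise EmptyBatch("empty fine-tune batch")
    if p.shape != t.shape:
        raise ShapeError(f"predictions {p.shape} vs targets {t.shape}")
    return float(np.mean((p - t) ** 2))


class EmbeddingBackend(ABC):
    """Contract every embedding provider implements."""

    #: stable identifier used for embedding-cache keys
    backend_id: str = "abstract"

    @abstractmethod
    def embed_pair(self, allele: MHCAllele, peptide: str) -> BackendOutput:
        """Embed one (allele, peptide) pair.

        Must be deterministic for a fixed backend state and seed.
        """


@dataclass
class SyntheticBackendConfig:
    D_mhc: int = 32
    D_p: int = 32
    band_width: float = 2.0
    n_longrange: int = 2
    seed: int = 0

    def validate(self) -> "SyntheticBackendConfig":
        if self.D_mhc < 1 or self.D_p < 1:
            raise BackendError("embedding widths must be positive")
        if self.band_width < 0:
            raise BackendError("band_width must be >= 0")
        if self.n_longrange < 0:
            raise BackendError("n_longrange must be >= 0")
        return self


class SyntheticBackend(EmbeddingBackend):
    """Deterministic stand-in backend with structured contact maps.

    Parameters mirror :class:`SyntheticBackendConfig`; all randomness
    is drawn from generators seeded by (seed, role) for the residue
    tables and (seed, sequence) for the per-peptide contact plantings,
    so two calls with identical inputs are bit-identical.
    """

    def __init__(self, config: SyntheticBackendConfig | None = None, **kwargs):
        if config is None:
            config = SyntheticBackendConfig(**kwargs)
        elif kwargs:
            raise BackendError("pass either a config object or keyword fields")
        self.config = config.validate()
        self.backend_id = f"synthetic-{config.seed}-{config.D_mhc}x{config.D_p}"
        # per-residue-identity embedding tables, one per role
        self._table_mhc = self._residue_table("mhc", config.D_mhc)
        self._table_pep = self._residue_table("peptide", config.D_p)

    def _residue_table(self, role: str, width: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(stable_hash(self.config.seed, role, "table"))
        return {aa: rng.standard_normal(width) for aa in CANONICAL_AA}

    # -- contact map -------------------------------------------------------

    def contact_map(self, peptide: str) -> np.ndarray:
        """Banded kernel plus planted symmetric long-range contacts."""
        validate_sequence(peptide, what="peptide")
        n = len(peptide)
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
        bw = self.config.band_width
        if bw > 0:
            with np.errstate(over="ignore"):  # tiny bw: band collapses to 0
                A = np.exp(-dist / bw)
        else:
            A = np.eye(n)
        np.fill_diagonal(A, 1.0)

        # plant long-range contacts well off the band
        margin = max(3, int(np.ceil(3 * bw)))
        cand = [(i, j) for i in range(n) for j in range(i + 1, n) if j - i > margin]
        if cand and self.config.n_longrange > 0:
            rng = np.random.default_rng(
                stable_hash(self.config.seed, peptide, "longrange")
            )
            k = min(self.config.n_longrange, len(cand))
            chosen = rng.choice(len(cand), size=k, replace=False)
            for c in chosen:
                i, j = cand[c]
                val = 0.9 + 0.1 * rng.random()
                A[i, j] = A[j, i] = val
        return A

    def attention_profile(self, A: np.ndarray) -> np.ndarray:
        rows = A.sum(axis=1, keepdims=True)
        return A / rows

    # -- embeddings --------------------------------------------------------

    def _embed_sequence(self, seq: str, table: dict[str, np.ndarray]) -> np.ndarray:
        return np.stack([table[aa] for aa in seq])

    def embed_pair(self, allele: MHCAllele, peptide: str) -> BackendOutput:
        validate_sequence(peptide, what="peptide")
        H_mhc = self._embed_sequence(allele.pseudo_sequence, self._table_mhc)
        H_p = self._embed_sequence(peptide, self._table_pep)
        A = self.contact_map(peptide)
        return BackendOutput(
            H_mhc=H_mhc, H_p=H_p, A=A, attention=self.attention_profile(A)
        ).validate()


class CachingBackend(EmbeddingBackend):
    """In-memory cache keyed by (backend id, allele name, peptide);
    keeps repeated CV/LOMO runs from re-embedding the same pairs."""

    def __init__(self, inner: EmbeddingBackend):
        self.inner = inner
        self.backend_id = inner.backend_id
        self._cache: dict[tuple[str, str, str], BackendOutput] = {}

    def embed_pair(self, allele: MHCAllele, peptide: str) -> BackendOutput:
        key = (self.backend_id, allele.name, peptide)
        out = self._cache.get(key)
        if out is None:
            out = self.inner.embed_pair(allele, peptide)
            self._cache[key] = out
        return out


def make_backend(name: str = "synthetic", **config) -> EmbeddingBackend:
    """Backend factory used by the CLI config (``backend: synthetic``)."""
    if name == "synthetic":
        return SyntheticBackend(SyntheticBackendConfig(**config))
    raise BackendError(
        f"backend {name!r} is not available in this build "
        "(the language-model plugin requires its own weights)"
    )


def synthetic_embed(
    allele: MHCAllele, peptide: str, config: SyntheticBackendConfig | None = None, **kwargs
) -> BackendOutput:
    """Functional wrapper over :class:`SyntheticBackend.embed_pair`."""
    return SyntheticBackend(config, **kwargs).embed_pair(allele, peptide)


__all__ = [
    "BackendOutput",
    "EmbeddingBackend",
    "SyntheticBackend",
    "SyntheticBackendConfig",
    "CachingBackend",
    "make_backend",
    "synthetic_embed",
    "finetune_loss",
    "stable_hash",
]
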