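"""Sequence encoders and interaction-map fusion.

The MHC pseudo-sequence embeddings pass through a bidirectional LSTM
(position order matters: the groove-lining positions are a fixed
alignment) followed by a linear projection to the common width D.  The
peptide residue embeddings pass through a stack of hypergraph
convolution layers over the contact-map hypergraph, each followed by
its own projection to D.  The two encodings are fused into the
interaction map ``H_binding`` (M x N): for each stacked peptide layer
an inner product ``X_mhc X_p^T`` over the feature axis, then an
elementwise max across the stack — the max-pooling step that collapses
the layer stack while preserving the M x N binding-surface shape.

All parameters here are deterministic functions of a seed.  In this
package the trunk acts as a fixed random-feature encoder (see
docs/methods.md); only the prediction heads are trained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import BackendOutput, EmbeddingBackend, stable_hash
from .errors import ShapeError
from .hypergraph import IncidenceStructure, hyperconv_forward, hypergraph_from_contacts
from .seq_io import MHCAllele


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BiLSTM:
    """Numpy forward-only bidirectional LSTM with seeded parameters.

    Weights are drawn once from ``default_rng(seed)`` with a scaled
    Gaussian init and forget-gate bias 1; gate order is (i, f, g, o).
    """

    def __init__(self, input_dim: int, hidden_dim: int, seed: int):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        rng = np.random.default_rng(seed)
        self.params = {}
        for direction in ("fwd", "bwd"):
            scale_w = 1.0 / np.sqrt(input_dim)
            scale_u = 1.0 / np.sqrt(hidden_dim)
            W = rng.standard_normal((input_dim, 4 * hidden_dim)) * scale_w
            U = rng.standard_normal((hidden_dim, 4 * hidden_dim)) * scale_u
            b = np.zeros(4 * hidden_dim)
            b[hidden_dim : 2 * hidden_dim] = 1.0  # forget bias
            self.params[direction] = (W, U, b)

    def _run(self, X: np.ndarray, direction: str) -> np.ndarray:
        W, U, b = self.params[direction]
        h = np.zeros(self.hidden_dim)
        c = np.zeros(self.hidden_dim)
        steps = range(X.shape[0]) if direction == "fwd" else range(X.shape[0] - 1, -1, -1)
        out = np.zeros((X.shape[0], self.hidden_dim))
        hd = self.hidden_dim
        for t in steps:
            z = X[t] @ W + h @ U + b
            i = _sigmoid(z[:hd])
            f = _sigmoid(z[hd : 2 * hd])
            g = np.tanh(z[2 * hd : 3 * hd])
            o = _sigmoid(z[3 * hd :])
            c = f * c + i * g
            h = o * np.tanh(c)
            out[t] = h
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        """(M, input_dim) -> (M, 2 * hidden_dim), fwd/bwd concatenated."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ShapeError(f"expected (M, {self.input_dim}), got {X.shape}")
        return np.concatenate([self._run(X, "fwd"), self._run(X, "bwd")], axis=1)


class MHCEncoder:
    """BiLSTM over MHC position embeddings + projection to width D.

    The recurrent pass is a fixed feature extractor; the projection is
    the (trainable) interface to the common fused width.
    """

    def __init__(self, d_in: int, d_model: int = 64, hidden: int = 32, seed: int = 0):
        self.lstm = BiLSTM(d_in, hidden, seed=stable_hash(seed, "mhc-lstm"))
        rng = np.random.default_rng(stable_hash(seed, "mhc-proj"))
        self.proj = rng.standard_normal((2 * hidden, d_model)) / np.sqrt(2 * hidden)

    def lstm_features(self, H_mhc: np.ndarray) -> np.ndarray:
        return self.lstm.forward(H_mhc)

    def encode(self, H_mhc: np.ndarray) -> np.ndarray:
        return self.lstm_features(H_mhc) @ self.proj


class PeptideEncoder:
    """Stacked hypergraph convolutions with per-layer projections to D.

    ``encode`` returns the final encoding; ``encode_stack`` returns the
    projected encoding of every layer (including layer 0, the raw
    residue embeddings) for stack-pooled fusion.
    """

    def __init__(
        self,
        d_in: int,
        d_model: int = 64,
        layers: int = 2,
        activation: str = "relu",
        seed: int = 0,
    ):
        self.layers = layers
        self.activation = activation
        rng = np.random.default_rng(stable_hash(seed, "pep-params"))
        self.filters = [
            rng.standard_normal((d_in, d_in)) / np.sqrt(d_in) for _ in range(layers)
        ]
        self.projections = [
            rng.standard_normal((d_in, d_model)) / np.sqrt(d_in)
            for _ in range(layers + 1)
        ]

    def encode_stack(self, H_p: np.ndarray, inc: IncidenceStructure) -> list[np.ndarray]:
        X = np.asarray(H_p, dtype=float)
        stack = [X @ self.projections[0]]
        for l in range(self.layers):
            X = hyperconv_forward(X, inc, self.filters[l], activation=self.activation)
            stack.append(X @ self.projections[l + 1])
        return stack

    def encode(self, H_p: np.ndarray, inc: IncidenceStructure) -> np.ndarray:
        return self.encode_stack(H_p, inc)[-1]


def encode_mhc(H_mhc: np.ndarray, d_model: int = 64, hidden: int = 32, seed: int = 0) -> np.ndarray:
    """Functional wrapper: encode MHC position embeddings to (M, D)."""
    return MHCEncoder(H_mhc.shape[1], d_model, hidden, seed).encode(H_mhc)


def encode_peptide(
    H_p: np.ndarray,
    inc: IncidenceStructure,
    d_model: int = 64,
    layers: int = 2,
    activation: str = "relu",
    seed: int = 0,
) -> np.ndarray:
    """Functional wrapper: `layers` hyperconv applications + projection."""
    return PeptideEncoder(H_p.shape[1], d_model, layers, activation, seed).encode(H_p, inc)


def fuse(X_mhc: np.ndarray, X_p) -> np.ndarray:
    """Fuse encodings into the interaction map H_binding (M x N).

    ``H[m, n]`` is the inner product of MHC position m's feature row
    with peptide residue n's feature row.  When ``X_p`` is a list of
    stacked layer outputs, the per-layer maps are max-pooled
    elementwise across the stack first.
    """
    X_mhc = np.asarray(X_mhc, dtype=float)
    if isinstance(X_p, (list, tuple)):
        maps = [fuse(X_mhc, xp) for xp in X_p]
        return np.maximum.reduce(maps)
    X_p = np.asarray(X_p, dtype=float)
    if X_mhc.ndim != 2 or X_p.ndim != 2 or X_mhc.shape[1] != X_p.shape[1]:
        raise ShapeError(
            f"feature widths differ: X_mhc {X_mhc.shape} vs X_p {X_p.shape}"
        )
    return X_mhc @ X_p.T


@dataclass
class FeaturizerConfig:
    d_model: int = 64
    lstm_hidden: int = 32
    hyperconv_layers: int = 2
    activation: str = "relu"
    contact_ratio: float = 0.5
    max_peptide_len: int = 21
    seed: int = 0


class PairFeaturizer:
    """Fixed trunk: backend output -> interaction map -> flat feature row.

    The interaction map of a pair with peptide length N < max_peptide_len
    is zero-padded on the peptide axis so all pairs share the flattened
    width M * max_peptide_len consumed by the prediction heads.
    Raises :class:`RecordRejected` (propagated from hypergraph
    construction) for structureless pairs.
    """

    def __init__(self, backend: EmbeddingBackend, config: FeaturizerConfig | None = None):
        self.backend = backend
        self.config = config or FeaturizerConfig()
        self._mhc_encoder: MHCEncoder | None = None
        self._pep_encoder: PeptideEncoder | None = None
        self._mhc_cache: dict[str, np.ndarray] = {}

    def _encoders_for(self, out: BackendOutput) -> tuple[MHCEncoder, PeptideEncoder]:
        cfg = self.config
        if self._mhc_encoder is None:
            self._mhc_encoder = MHCEncoder(
                out.H_mhc.shape[1], cfg.d_model, cfg.lstm_hidden, seed=cfg.seed
            )
            self._pep_encoder = PeptideEncoder(
                out.H_p.shape[1],
                cfg.d_model,
                cfg.hyperconv_layers,
                cfg.activation,
                seed=cfg.seed,
            )
        return self._mhc_encoder, self._pep_encoder

    def interaction_map(
        self, allele: MHCAllele, peptide: str, output: BackendOutput | None = None
    ) -> np.ndarray:
        """Unpadded H_binding (M x N) for one pair.

        ``output`` overrides the backend call (used by perturbation-
        based interpretation to inject masked embeddings).
        """
        out = output if output is not None else self.backend.embed_pair(allele, peptide)
        mhc_enc, pep_enc = self._encoders_for(out)
        lstm_feat = self._mhc_cache.get(allele.name)
        if lstm_feat is None:
            lstm_feat = mhc_enc.lstm_features(out.H_mhc)
            if output is None:
                self._mhc_cache[allele.name] = lstm_feat
        X_mhc = lstm_feat @ mhc_enc.proj
        inc = hypergraph_from_contacts(out.A, self.config.contact_ratio)
        stack = pep_enc.encode_stack(out.H_p, inc)
        return fuse(X_mhc, stack)

    def features(
        self, allele: MHCAllele, peptide: str, output: BackendOutput | None = None
    ) -> np.ndarray:
        """Flattened feature row of width M * max_peptide_len.

        The peptide axis is zero-padded *centered* in the fixed-width
        frame: MHC-II grooves are open at both ends and peptides
        protrude roughly symmetrically, so center-aligning keeps
        core-proximal residues in comparable feature columns across
        peptide lengths.
        """
        H = self.interaction_map(allele, peptide, output=output)
        return pad_interaction_map(H, self.config.max_peptide_len).ravel()


def pad_interaction_map(H: np.ndarray, max_peptide_len: int) -> np.ndarray:
    """Zero-pad an (M, N) interaction map to (M, max_peptide_len) with
    the peptide centered in the frame."""
    m, n = H.shape
    if n > max_peptide_len:
        raise ShapeError(f"peptide length {n} exceeds max_peptide_len {max_peptide_len}")
    padded = np.zeros((m, max_peptide_len))
    offset = (max_peptide_len - n) // 2
    padded[:, offset : offset + n] = H
    return padded


__all__ = [
    "BiLSTM",
    "MHCEncoder",
    "PeptideEncoder",
    "encode_mhc",
    "encode_peptide",
    "fuse",
    "FeaturizerConfig",
    "PairFeaturizer",
]
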