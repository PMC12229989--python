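"""Residue-level interpretation: importance maps, binding-core
detection and contact profiling.

Two complementary views of residue importance are combined:

* the *contextual contribution* of a residue, obtained by summing its
  attention weights with every other residue (both directions,
  diagonal excluded) and normalizing to a unit-sum profile; and
* the *spatial importance*, obtained by occluding one residue at a
  time (zeroing its embedding row) and measuring the absolute change
  in the predicted binding probability.

Their elementwise product is the residue importance map.  The binding
core — the ~9-residue stretch seated in the MHC-II groove — is located
as the length-9 window with the highest cumulative importance,
scanning with step 1 (leftmost window on ties).  The fused interaction
map, min-max normalized to [0, 1], serves as a residue contact profile
of the binding surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .backend import BackendOutput, EmbeddingBackend
from .errors import InvalidMap, PeptideTooShort, ShapeError
from .seq_io import CoreAnnotation, MHCAllele

CORE_LENGTH = 9


@dataclass(frozen=True)
class CorePrediction:
    """Predicted binding-core window (0-based start, inclusive length)."""

    start: int
    score: float
    length: int = CORE_LENGTH


def attention_contribution(attention: np.ndarray) -> np.ndarray:
    """Per-residue contextual contribution from an attention matrix.

    ``contribution[i] = sum_j (attention[i, j] + attention[j, i])``
    excluding the diagonal, rescaled to sum to 1.  A residue attended
    strongly in either direction scores high.
    """
    A = np.asarray(attention, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError(f"attention must be square, got {A.shape}")
    if np.any(A < 0):
        raise ShapeError("attention weights must be non-negative")
    off = A - np.diag(np.diag(A))
    contrib = off.sum(axis=1) + off.sum(axis=0)
    total = contrib.sum()
    if total <= 0:  # degenerate: no off-diagonal mass
        return np.full(A.shape[0], 1.0 / A.shape[0])
    return contrib / total


def perturbation_importance(
    model, allele: MHCAllele, peptide: str, backend: EmbeddingBackend
) -> np.ndarray:
    """Occlusion-based spatial residue importance.

    ``importance[i] = |p_base - p_masked(i)|`` where ``p_masked(i)`` is
    the binding probability after zeroing residue i's embedding row.
    Deterministic; non-negative by construction.
    """
    base_out = backend.embed_pair(allele, peptide)
    p_base = model.predict_proba_from_output(allele, peptide, base_out)
    imp = np.zeros(len(peptide))
    for i in range(len(peptide)):
        masked = BackendOutput(
            H_mhc=base_out.H_mhc,
            H_p=base_out.H_p.copy(),
            A=base_out.A,
            attention=base_out.attention,
        )
        masked.H_p[i, :] = 0.0
        imp[i] = abs(p_base - model.predict_proba_from_output(allele, peptide, masked))
    return imp


def combine_importance(contextual: np.ndarray, spatial: np.ndarray) -> np.ndarray:
    """Elementwise product of contextual and spatial importance."""
    c = np.asarray(contextual, dtype=float)
    s = np.asarray(spatial, dtype=float)
    if c.shape != s.shape:
        raise ShapeError(f"length mismatch: {c.shape} vs {s.shape}")
    return c * s


def residue_importance(
    model, allele: MHCAllele, peptide: str, backend: EmbeddingBackend
) -> np.ndarray:
    """Full importance map: contextual contribution x spatial importance."""
    out = backend.embed_pair(allele, peptide)
    if out.attention is None:
        raise InvalidMap("backend supplies no attention profile")
    contextual = attention_contribution(out.attention)
    spatial = perturbation_importance(model, allele, peptide, backend)
    return combine_importance(contextual, spatial)


def detect_core(importance: np.ndarray, window: int = CORE_LENGTH) -> CorePrediction:
    """Highest-cumulative-importance window of the given length,
    scanning with step 1; ties resolved toward the smallest start."""
    imp = np.asarray(importance, dtype=float).ravel()
    n = imp.shape[0]
    if n < window:
        raise PeptideTooShort(f"peptide length {n} < window {window}")
    sums = np.array([imp[s : s + window].sum() for s in range(n - window + 1)])
    start = int(np.argmax(sums))  # argmax returns the first maximum
    return CorePrediction(start=start, score=float(sums[start]), length=window)


def contact_profile(H_binding: np.ndarray) -> np.ndarray:
    """Min-max normalize the interaction map to [0, 1].

    A constant map normalizes to all zeros (documented convention so
    the range invariant stays testable).
    """
    H = np.asarray(H_binding, dtype=float)
    if not np.all(np.isfinite(H)):
        raise InvalidMap("interaction map contains non-finite entries")
    lo, hi = H.min(), H.max()
    if hi - lo == 0:
        return np.zeros_like(H)
    return (H - lo) / (hi - lo)


def score_core_overlap(pred: CorePrediction, truth: CoreAnnotation, peptide: str | None = None) -> str:
    """Categorize a core prediction against the annotated truth:
    ``exact`` / ``shifted_1`` / ``shifted_2`` / ``miss``."""
    if peptide is not None and peptide != truth.peptide:
        raise ShapeError("prediction and annotation refer to different peptides")
    delta = abs(pred.start - truth.core_start)
    if delta == 0:
        return "exact"
    if delta <= 2:
        return f"shifted_{delta}"
    return "miss"


def write_core_predictions(
    rows: Sequence[tuple[str, CorePrediction, str]], path: str | Path
) -> None:
    """TSV export: complex_id, start/end (1-based inclusive), score,
    category vs truth."""
    lines = ["complex_id\tstart\tend\tscore\tcategory"]
    for complex_id, pred, category in rows:
        lines.append(
            f"{complex_id}\t{pred.start + 1}\t{pred.start + pred.length}"
            f"\t{pred.score:.6f}\t{category}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_profile_tsv(P: np.ndarray, path: str | Path) -> None:
    """Contact profile as TSV, MHC positions as rows (1-based labels)."""
    P = np.asarray(P)
    header = "pos\t" + "\t".join(f"p{j + 1}" for j in range(P.shape[1]))
    lines = [header]
    for i in range(P.shape[0]):
        lines.append(f"m{i + 1}\t" + "\t".join(f"{v:.6f}" for v in P[i]))
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "CORE_LENGTH",
    "CorePrediction",
    "attention_contribution",
    "perturbation_importance",
    "combine_importance",
    "residue_importance",
    "detect_core",
    "contact_profile",
    "score_core_overlap",
    "write_core_predictions",
    "write_profile_tsv",
]
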