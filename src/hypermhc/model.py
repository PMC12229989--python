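"""Prediction heads and the trainable binding predictor.

:class:`HypergraphBindingPredictor` is a scikit-learn style estimator:
``fit(X, y)`` takes (allele, peptide) pairs and normalized-affinity /
reactivity targets, ``predict_proba`` returns binding probabilities and
``predict_affinity`` the predicted normalized affinity.

The model is trained end-to-end through the fusion stage: the MHC
projection, the peptide pathway (HyperConv filter matrices and the
per-layer projections feeding the interaction map) and the two task
heads — a classification head and a regression head, each a
three-layer MLP with a terminal sigmoid on the flattened interaction
map — are optimized jointly with Adam, minimizing binary cross-entropy
(reactivity) plus squared error (affinity).  The per-residue embedding
tables, the BiLSTM recurrence and the hypergraph structure act as
fixed, seed-determined components; gradients flow through the
interaction-map fusion (with max-pool routing across the layer stack)
and the degree-normalized hypergraph propagation.

Memorization control matters at desk scale: features are standardized
by a frozen affine layer fitted to the initial trunk state, the head
input is dropout-masked during training, and the final predictor is a
small deep ensemble — ``n_ensemble`` independently initialized
replicas whose predictions are averaged.

Pairs whose contact hypergraph has no edge of size >= 2 are rejected
by the trunk and never reach the heads; fit records them in
``rejected_indices_`` and ``n_rejected_``.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .backend import CachingBackend, EmbeddingBackend, SyntheticBackend
from .encoders import (
    FeaturizerConfig,
    PairFeaturizer,
    _sigmoid,
    pad_interaction_map,
)
from .errors import EmptyTrainingSet, RecordRejected, ShapeError
from .hypergraph import hypergraph_from_contacts, propagation_matrix
from .seq_io import BINDER_THRESHOLD, Dataset, MHCAllele, label_from_affinity

CHECKPOINT_FORMAT_VERSION = 3


# ---------------------------------------------------------------------------
# three-layer MLP head


def _init_head(n_in: int, hidden: tuple[int, int], rng: np.random.Generator, tag: str) -> dict:
    h1, h2 = hidden
    return {
        f"{tag}_W1": rng.standard_normal((n_in, h1)) * np.sqrt(2.0 / n_in),
        f"{tag}_b1": np.zeros(h1),
        f"{tag}_W2": rng.standard_normal((h1, h2)) * np.sqrt(2.0 / h1),
        f"{tag}_b2": np.zeros(h2),
        f"{tag}_W3": rng.standard_normal((h2, 1)) * np.sqrt(2.0 / h2),
        f"{tag}_b3": np.zeros(1),
    }


def _head_forward(X: np.ndarray, params: dict, tag: str = "") -> tuple[np.ndarray, dict]:
    pre = tag + "_" if tag else ""
    z1 = X @ params[f"{pre}W1"] + params[f"{pre}b1"]
    a1 = np.maximum(z1, 0.0)
    z2 = a1 @ params[f"{pre}W2"] + params[f"{pre}b2"]
    a2 = np.maximum(z2, 0.0)
    z3 = a2 @ params[f"{pre}W3"] + params[f"{pre}b3"]
    p = _sigmoid(z3[:, 0])
    return p, {"X": X, "z1": z1, "a1": a1, "z2": z2, "a2": a2, "p": p}


def _head_backward(cache: dict, dz3: np.ndarray, params: dict, tag: str = "") -> tuple[dict, np.ndarray]:
    """Gradients given dLoss/dz3 (pre-sigmoid); also returns dLoss/dX."""
    pre = tag + "_" if tag else ""
    dz3 = dz3[:, None]
    grads = {f"{pre}W3": cache["a2"].T @ dz3, f"{pre}b3": dz3.sum(axis=0)}
    da2 = dz3 @ params[f"{pre}W3"].T
    dz2 = da2 * (cache["z2"] > 0)
    grads[f"{pre}W2"] = cache["a1"].T @ dz2
    grads[f"{pre}b2"] = dz2.sum(axis=0)
    da1 = dz2 @ params[f"{pre}W2"].T
    dz1 = da1 * (cache["z1"] > 0)
    grads[f"{pre}W1"] = cache["X"].T @ dz1
    grads[f"{pre}b1"] = dz1.sum(axis=0)
    dX = dz1 @ params[f"{pre}W1"].T
    return grads, dX


def _head_apply(flat_map: np.ndarray, params: dict) -> float:
    x = np.asarray(flat_map, dtype=float).ravel()
    if x.shape[0] != params["W1"].shape[0]:
        raise ShapeError(
            f"flattened map width {x.shape[0]} != head input {params['W1'].shape[0]}"
        )
    p, _ = _head_forward(x[None, :], params)
    return float(p[0])


def classify(H_binding: np.ndarray, params: dict) -> float:
    """Binding probability from a (flattened) interaction map."""
    return _head_apply(H_binding, params)


def regress(H_binding: np.ndarray, params: dict) -> float:
    """Predicted normalized affinity from a (flattened) interaction map."""
    return _head_apply(H_binding, params)


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            g = g + self.wd * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# estimator


class HypergraphBindingPredictor(BaseEstimator):
    """MHC-II binding reactivity + affinity predictor.

    Parameters
    ----------
    backend : EmbeddingBackend or None
        Embedding provider; defaults to a seeded synthetic backend.
    head_hidden : (int, int)
        Widths of the two hidden layers of each three-layer head.
    dropout : float
        Dropout rate applied to the flattened interaction map during
        head training (memorization control).
    n_ensemble : int
        Number of independently initialized trunk+head replicas whose
        predictions are averaged.
    loss_weights : (float, float)
        (classification, regression) loss weights for joint training.
    threshold : float
        Binder cutoff on the normalized-affinity scale used to derive
        labels from 1-D targets.

    Attributes (after fit)
    ----------------------
    members_ : list of dict
        Per-replica featurizer and parameter arrays.
    params_, clf_params_, reg_params_ :
        Parameter views of the first replica.
    history_ : list of dict
        Per-epoch train/validation losses of the first replica.
    n_used_, n_rejected_, rejected_indices_ :
        Reconciliation of records excluded by the hypergraph validity
        rule (used + rejected = input).
    """

    def __init__(
        self,
        backend: EmbeddingBackend | None = None,
        d_model: int = 64,
        lstm_hidden: int = 32,
        hyperconv_layers: int = 2,
        activation: str = "relu",
        contact_ratio: float = 0.5,
        max_peptide_len: int = 21,
        head_hidden: tuple[int, int] = (32, 16),
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 200,
        early_stop_patience: int = 30,
        validation_fraction: float = 0.1,
        weight_decay: float = 1e-3,
        dropout: float = 0.7,
        n_ensemble: int = 3,
        loss_weights: tuple[float, float] = (1.0, 1.0),
        threshold: float = BINDER_THRESHOLD,
        random_state: int = 0,
    ):
        self.backend = backend
        self.d_model = d_model
        self.lstm_hidden = lstm_hidden
        self.hyperconv_layers = hyperconv_layers
        self.activation = activation
        self.contact_ratio = contact_ratio
        self.max_peptide_len = max_peptide_len
        self.head_hidden = head_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.n_ensemble = n_ensemble
        self.loss_weights = loss_weights
        self.threshold = threshold
        self.random_state = random_state

    # -- plumbing ----------------------------------------------------------

    def _shared_backend(self) -> CachingBackend:
        backend = self.backend
        if backend is None:
            backend = SyntheticBackend(seed=self.random_state)
        if not isinstance(backend, CachingBackend):
            backend = CachingBackend(backend)
        return backend

    def _member_featurizer(self, seed: int) -> PairFeaturizer:
        cfg = FeaturizerConfig(
            d_model=self.d_model,
            lstm_hidden=self.lstm_hidden,
            hyperconv_layers=self.hyperconv_layers,
            activation=self.activation,
            contact_ratio=self.contact_ratio,
            max_peptide_len=self.max_peptide_len,
            seed=seed,
        )
        return PairFeaturizer(self.backend_, cfg)

    def _bind_member(self, member: dict) -> None:
        self.featurizer_ = member["featurizer"]
        self.params_ = member["params"]
        self.scaler_mean_ = member["scaler_mean"]
        self.scaler_std_ = member["scaler_std"]

    @staticmethod
    def _as_pair(item) -> tuple[MHCAllele, str]:
        mhc, peptide = item
        if not isinstance(mhc, MHCAllele):
            mhc = MHCAllele(name=str(mhc), pseudo_sequence=str(mhc))
        return mhc, str(peptide)

    def _pair_cache(self, item) -> dict:
        """Fixed per-pair quantities: peptide embeddings, propagation
        matrix of the contact hypergraph, BiLSTM features of the MHC."""
        fz = self.featurizer_
        mhc, peptide = self._as_pair(item)
        out = fz.backend.embed_pair(mhc, peptide)
        mhc_enc, _ = fz._encoders_for(out)
        mhc_feat = fz._mhc_cache.get(mhc.name)
        if mhc_feat is None:
            mhc_feat = mhc_enc.lstm_features(out.H_mhc)
            fz._mhc_cache[mhc.name] = mhc_feat
        inc = hypergraph_from_contacts(out.A, self.contact_ratio)
        return {"H_p": out.H_p, "theta": propagation_matrix(inc), "mhc_feat": mhc_feat}

    def _build_caches(self, X: list) -> tuple[list[dict], list[int], list[int]]:
        caches, used, rejected = [], [], []
        for i, item in enumerate(X):
            try:
                caches.append(self._pair_cache(item))
            except RecordRejected:
                rejected.append(i)
            else:
                used.append(i)
        return caches, used, rejected

    def _targets(self, y, n: int) -> tuple[np.ndarray, np.ndarray]:
        """-> (labels in {0,1}, affinities with NaN where absent)."""
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            if y.shape[0] != n:
                raise ShapeError(f"y has length {y.shape[0]}, expected {n}")
            affinity = y.copy()
            labels = np.array(
                [label_from_affinity(v, self.threshold) for v in affinity], dtype=float
            )
        elif y.ndim == 2 and y.shape[1] == 2:
            labels = y[:, 0].astype(float)
            affinity = y[:, 1].astype(float)
            if not np.isin(labels[~np.isnan(labels)], (0.0, 1.0)).all():
                raise ShapeError("first target column must be binary labels")
            nan_lab = np.isnan(labels)
            if nan_lab.any():
                labels = labels.copy()
                labels[nan_lab] = [
                    label_from_affinity(v, self.threshold) for v in affinity[nan_lab]
                ]
        else:
            raise ShapeError(f"y must be (n,) affinities or (n, 2), got {y.shape}")
        return labels, affinity

    # -- trunk forward/backward -------------------------------------------

    def _trunk_params(self) -> dict:
        """Trainable trunk arrays, aliased into the featurizer's
        encoders so inference sees the trained values."""
        enc = self.featurizer_._pep_encoder
        params = {"proj_mhc": self.featurizer_._mhc_encoder.proj}
        for l, phi in enumerate(enc.filters):
            params[f"phi{l}"] = phi
        for l, proj in enumerate(enc.projections):
            params[f"proj{l}"] = proj
        return params

    def _trunk_forward(self, cache: dict, need_grad: bool = False):
        """Interaction map under the bound member's current parameters."""
        enc = self.featurizer_._pep_encoder
        theta = cache["theta"]
        # proj_mhc is aliased into params_, so this sees trained values
        X_mhc = cache["mhc_feat"] @ self.featurizer_._mhc_encoder.proj
        X = cache["H_p"]
        xs, pres = [X], []
        gs = [X @ enc.projections[0]]
        maps = [X_mhc @ gs[0].T]
        for l in range(self.hyperconv_layers):
            pre = theta @ X @ enc.filters[l]
            if self.activation == "relu":
                X = np.maximum(pre, 0.0)
            elif self.activation == "elu":
                X = np.where(pre > 0, pre, np.expm1(pre))
            else:
                X = pre
            pres.append(pre)
            xs.append(X)
            gs.append(X @ enc.projections[l + 1])
            maps.append(X_mhc @ gs[l + 1].T)
        stacked = np.stack(maps)
        route = np.argmax(stacked, axis=0)
        H = np.max(stacked, axis=0)
        if not need_grad:
            return H, None
        return H, {"xs": xs, "pres": pres, "route": route, "gs": gs, "X_mhc": X_mhc}

    def _trunk_backward(self, cache: dict, fwd: dict, dH: np.ndarray, grads: dict) -> None:
        """Accumulate trunk gradients for one pair given dLoss/dH."""
        enc = self.featurizer_._pep_encoder
        theta = cache["theta"]
        xs, pres, route = fwd["xs"], fwd["pres"], fwd["route"]
        gs, X_mhc = fwd["gs"], fwd["X_mhc"]
        L = self.hyperconv_layers
        dX = [None] * (L + 1)
        dX_mhc = np.zeros_like(X_mhc)
        for l in range(L + 1):
            dH_l = np.where(route == l, dH, 0.0)  # max-pool routing
            dX_mhc += dH_l @ gs[l]
            dG = dH_l.T @ X_mhc  # (N, D)
            grads[f"proj{l}"] += xs[l].T @ dG
            contrib = dG @ enc.projections[l].T
            dX[l] = contrib if dX[l] is None else dX[l] + contrib
        grads["proj_mhc"] += cache["mhc_feat"].T @ dX_mhc
        for l in range(L, 0, -1):
            dpre = dX[l]
            if self.activation == "relu":
                dpre = dpre * (pres[l - 1] > 0)
            elif self.activation == "elu":
                dpre = dpre * np.where(pres[l - 1] > 0, 1.0, np.exp(pres[l - 1]))
            tx = theta @ xs[l - 1]
            grads[f"phi{l - 1}"] += tx.T @ dpre
            dX[l - 1] = dX[l - 1] + theta @ dpre @ enc.filters[l - 1].T

    def _features_from_caches(self, caches: Sequence[dict]) -> np.ndarray:
        rows = []
        for c in caches:
            H, _ = self._trunk_forward(c)
            rows.append(pad_interaction_map(H, self.max_peptide_len).ravel())
        feats = np.vstack(rows)
        return (feats - self.scaler_mean_) / self.scaler_std_

    # -- training ----------------------------------------------------------

    def _joint_loss(self, Z, labels, affinity):
        p_clf, _ = _head_forward(Z, self.params_, "clf")
        p_reg, _ = _head_forward(Z, self.params_, "reg")
        eps = 1e-12
        bce = -np.mean(
            labels * np.log(p_clf + eps) + (1 - labels) * np.log(1 - p_clf + eps)
        )
        mask = ~np.isnan(affinity)
        mse = float(np.mean((p_reg[mask] - affinity[mask]) ** 2)) if mask.any() else 0.0
        w_c, w_r = self.loss_weights
        return w_c * bce + w_r * mse, bce, mse

    def fit(self, X, y):
        X = list(X)
        if not X:
            raise EmptyTrainingSet("empty training set")
        self.backend_ = self._shared_backend()
        labels_all, affinity_all = self._targets(y, len(X))
        self.members_ = []
        for j in range(self.n_ensemble):
            member_seed = int(self.random_state + 7919 * j) % (2**31)
            member = self._fit_member(X, labels_all, affinity_all, member_seed)
            self.members_.append(member)
        first = self.members_[0]
        self._bind_member(first)
        self.rejected_indices_ = first["rejected"]
        self.n_rejected_ = len(first["rejected"])
        self.n_used_ = len(first["used"])
        self.history_ = first["history"]
        self.n_features_in_ = int(first["params"]["clf_W1"].shape[0])
        return self

    def _fit_member(self, X, labels_all, affinity_all, seed: int) -> dict:
        self.featurizer_ = self._member_featurizer(seed)
        caches, used, rejected = self._build_caches(X)
        if not used:
            raise EmptyTrainingSet("no records survive hypergraph validation")
        labels, affinity = labels_all[used], affinity_all[used]

        m = caches[0]["mhc_feat"].shape[0]
        n_features = m * self.max_peptide_len

        # frozen standardization layer fitted to the initial trunk
        # state (identity when a single record leaves no variance)
        self.scaler_mean_ = np.zeros(n_features)
        self.scaler_std_ = np.ones(n_features)
        if len(caches) >= 2:
            feats0 = self._features_from_caches(caches)
            mean, std = feats0.mean(axis=0), feats0.std(axis=0)
            std[std < 1e-8] = 1.0
            self.scaler_mean_, self.scaler_std_ = mean, std

        rng = np.random.default_rng(seed)
        self.params_ = self._trunk_params()
        self.params_.update(_init_head(n_features, tuple(self.head_hidden), rng, "clf"))
        self.params_.update(_init_head(n_features, tuple(self.head_hidden), rng, "reg"))
        opt = _Adam(self.params_, self.learning_rate, self.weight_decay)

        n = len(caches)
        n_val = int(round(self.validation_fraction * n)) if n >= 20 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        w_c, w_r = self.loss_weights
        best_loss, best_state, patience = np.inf, None, 0
        history = []
        for epoch in range(self.max_epochs):
            order = tr_idx[rng.permutation(len(tr_idx))]
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                b = order[start : start + self.batch_size]
                nb = len(b)
                fwds, rows = [], []
                max_n = self.max_peptide_len
                for i in b:
                    H, fwd = self._trunk_forward(caches[i], need_grad=True)
                    fwds.append((H.shape[1], fwd))
                    rows.append(pad_interaction_map(H, max_n).ravel())
                Z = (np.vstack(rows) - self.scaler_mean_) / self.scaler_std_
                drop_mask = None
                if self.dropout > 0:
                    drop_mask = (rng.random(Z.shape) >= self.dropout) / (1 - self.dropout)
                    Z = Z * drop_mask

                grads = {k: np.zeros_like(v) for k, v in self.params_.items()}
                p, cache_c = _head_forward(Z, self.params_, "clf")
                eps = 1e-12
                bce = -np.mean(
                    labels[b] * np.log(p + eps) + (1 - labels[b]) * np.log(1 - p + eps)
                )
                dz3 = w_c * (p - labels[b]) / nb  # BCE-with-logits gradient
                g, dZ = _head_backward(cache_c, dz3, self.params_, "clf")
                for k, v in g.items():
                    grads[k] += v

                ab = affinity[b]
                mask = ~np.isnan(ab)
                mse = 0.0
                if mask.any():
                    p, cache_r = _head_forward(Z, self.params_, "reg")
                    resid = np.where(mask, p - np.nan_to_num(ab), 0.0)
                    mse = float(np.sum(resid**2) / mask.sum())
                    dz3 = w_r * 2.0 * resid * p * (1 - p) / max(mask.sum(), 1)
                    g, dZr = _head_backward(cache_r, dz3, self.params_, "reg")
                    for k, v in g.items():
                        grads[k] += v
                    dZ = dZ + dZr

                if drop_mask is not None:
                    dZ = dZ * drop_mask
                dfeat = dZ / self.scaler_std_
                for row, (i, (n_pep, fwd)) in enumerate(zip(b, fwds)):
                    offset = (max_n - n_pep) // 2
                    dH = dfeat[row].reshape(m, max_n)[:, offset : offset + n_pep]
                    self._trunk_backward(caches[i], fwd, dH, grads)
                opt.step(self.params_, grads)
                epoch_loss += w_c * bce + w_r * mse
                n_batches += 1

            entry = {"epoch": epoch, "train_loss": float(epoch_loss / max(n_batches, 1))}
            monitor = entry["train_loss"]
            if n_val:
                Zv = self._features_from_caches([caches[i] for i in val_idx])
                val_loss, _, _ = self._joint_loss(Zv, labels[val_idx], affinity[val_idx])
                entry["val_loss"] = float(val_loss)
                monitor = val_loss
            history.append(entry)

            if monitor < best_loss - 1e-6:
                best_loss = monitor
                best_state = copy.deepcopy(self.params_)
                patience = 0
            else:
                patience += 1
                if patience >= self.early_stop_patience:
                    break
        if best_state is not None:
            for k, v in best_state.items():
                self.params_[k][...] = v
        return {
            "featurizer": self.featurizer_,
            "params": self.params_,
            "scaler_mean": self.scaler_mean_,
            "scaler_std": self.scaler_std_,
            "history": history,
            "used": used,
            "rejected": rejected,
        }

    @property
    def clf_params_(self) -> dict:
        return {k[4:]: v for k, v in self.params_.items() if k.startswith("clf_")}

    @property
    def reg_params_(self) -> dict:
        return {k[4:]: v for k, v in self.params_.items() if k.startswith("reg_")}

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "members_"):
            raise EmptyTrainingSet("model is not fitted")

    def _ensemble_predict(self, X, tag: str, on_reject: str) -> np.ndarray:
        self._check_fitted()
        X = list(X)
        preds = []
        for member in self.members_:
            self._bind_member(member)
            caches, used, rejected = self._build_caches(X)
            if rejected and on_reject == "raise":
                raise RecordRejected(
                    f"pairs at indices {rejected} have no usable hypergraph"
                )
            p = np.full(len(X), np.nan)
            if used:
                Z = self._features_from_caches(caches)
                p[used], _ = _head_forward(Z, self.params_, tag)
            preds.append(p)
        self._bind_member(self.members_[0])
        return np.mean(preds, axis=0)

    def predict_proba(self, X, on_reject: str = "raise") -> np.ndarray:
        """(n, 2) array of [P(nonbinder), P(binder)]; rejected pairs are
        NaN rows when ``on_reject='nan'``."""
        p = self._ensemble_predict(X, "clf", on_reject)
        return np.column_stack([1 - p, p])

    def predict(self, X, on_reject: str = "raise") -> np.ndarray:
        """Binary reactivity labels (1 = binder)."""
        proba = self.predict_proba(X, on_reject)
        return (proba[:, 1] > 0.5).astype(float)

    def predict_affinity(self, X, on_reject: str = "raise") -> np.ndarray:
        """Predicted normalized affinities in [0, 1]."""
        return self._ensemble_predict(X, "reg", on_reject)

    def predict_proba_from_output(self, allele: MHCAllele, peptide: str, output):
        """Binding probability with an injected backend output (used by
        occlusion-based interpretation)."""
        self._check_fitted()
        ps = []
        for member in self.members_:
            self._bind_member(member)
            x = self.featurizer_.features(allele, peptide, output=output)
            z = (x - self.scaler_mean_) / self.scaler_std_
            ps.append(classify(z, self.clf_params_))
        self._bind_member(self.members_[0])
        return float(np.mean(ps))

    def interaction_map(self, allele: MHCAllele, peptide: str) -> np.ndarray:
        """Fused interaction map of the first ensemble member."""
        self._check_fitted()
        return self.featurizer_.interaction_map(allele, peptide)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config JSON + per-member arrays."""
        self._check_fitted()
        arrays = {}
        for j, member in enumerate(self.members_):
            for k, v in member["params"].items():
                arrays[f"m{j}:{k}"] = v
            arrays[f"m{j}:scaler_mean"] = member["scaler_mean"]
            arrays[f"m{j}:scaler_std"] = member["scaler_std"]
        config = {k: v for k, v in self.get_params().items() if k != "backend"}
        config["head_hidden"] = list(config["head_hidden"])
        config["loss_weights"] = list(config["loss_weights"])
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": config,
            "n_members": len(self.members_),
            "n_features_in": int(self.n_features_in_),
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path, backend: EmbeddingBackend | None = None):
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ShapeError(f"unsupported checkpoint version {meta['format_version']}")
        cfg = meta["config"]
        cfg["head_hidden"] = tuple(cfg["head_hidden"])
        cfg["loss_weights"] = tuple(cfg["loss_weights"])
        model = cls(backend=backend, **cfg)
        model.backend_ = model._shared_backend()
        probe = MHCAllele("PROBE", "A" * 34)
        model.members_ = []
        for j in range(meta["n_members"]):
            member_seed = int(model.random_state + 7919 * j) % (2**31)
            fz = model._member_featurizer(member_seed)
            # prime the lazily built encoders so trunk arrays exist
            out = fz.backend.embed_pair(probe, "ACDEFGHIKLM")
            fz._encoders_for(out)
            model.featurizer_ = fz
            params = model._trunk_params()
            for key in data.files:
                prefix = f"m{j}:"
                if not key.startswith(prefix) or key.endswith("scaler_mean") or key.endswith("scaler_std"):
                    continue
                name = key[len(prefix):]
                if name in params:
                    params[name][...] = data[key]
                else:
                    params[name] = data[key]
            model.members_.append(
                {
                    "featurizer": fz,
                    "params": params,
                    "scaler_mean": data[f"m{j}:scaler_mean"],
                    "scaler_std": data[f"m{j}:scaler_std"],
                    "history": [],
                    "used": [],
                    "rejected": [],
                }
            )
        model._bind_member(model.members_[0])
        model.n_features_in_ = meta["n_features_in"]
        model.history_ = []
        model.n_used_ = model.n_rejected_ = 0
        model.rejected_indices_ = []
        return model


# ---------------------------------------------------------------------------
# dataset-level helpers


def dataset_to_xy(dataset: Dataset) -> tuple[list, np.ndarray]:
    """(allele, peptide) pairs plus an (n, 2) [label, affinity] target
    array (NaN where a target is absent)."""
    X, y = [], []
    for rec in dataset.records:
        X.append((dataset.allele_of(rec), rec.peptide))
        lab = float(rec.label) if rec.label is not None else np.nan
        aff = rec.affinity_norm if rec.affinity_norm is not None else np.nan
        y.append((lab, aff))
    return X, np.asarray(y, dtype=float)


def train(dataset: Dataset, backend: EmbeddingBackend | None = None, **config):
    """Fit a predictor on a dataset; returns (model, training history)."""
    if len(dataset) == 0:
        raise EmptyTrainingSet("empty dataset")
    X, y = dataset_to_xy(dataset)
    model = HypergraphBindingPredictor(backend=backend, **config)
    model.fit(X, y)
    return model, model.history_


def write_training_log(history: Sequence[dict], path: str | Path) -> None:
    cols = ["epoch", "train_loss", "val_loss"]
    lines = ["\t".join(cols)]
    for entry in history:
        lines.append("\t".join(str(entry.get(c, "NA")) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "HypergraphBindingPredictor",
    "classify",
    "regress",
    "train",
    "dataset_to_xy",
    "write_training_log",
]
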