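"""Leakage-confined scaler -> PCA -> transformer-encoder classifier with
attention-derived feature importance and the dual-filter intersection.

Within every cross-validation fold, standardization and PCA are fitted on the
training portion only ("confined" CV). Each principal-component score becomes
one token: a learned scalar->embed_dim linear embedding plus a learned
positional embedding. A 3-layer post-norm transformer encoder (multi-head
self-attention, GELU feed-forward, dropout) feeds a mean-pooled sigmoid head
trained with Adam on binary cross-entropy with an L2 weight-decay penalty and
early stopping on a held-out validation split.

Per-component importance is the attention mass each component token receives,
averaged over heads, layers, and samples; per-feature importance propagates
component importance through squared PCA loadings (the feature's variance
share of each component), which is invariant to component sign flips.

The network is implemented directly on numpy arrays with hand-derived
gradients; the backward pass is validated against numerical differentiation
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, binary_labels
from . import evaluate as ev


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttentionConfig:
    n_components: int = 10
    n_layers: int = 3
    n_heads: int = 2
    embed_dim: int = 24
    dropout: float = 0.5
    weight_decay: float = 0.1
    learning_rate: float = 5e-4
    patience: int = 8
    max_epochs: int = 200
    batch_size: int = 16
    top_fraction: float = 0.20
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")


def default_config(modality: str, seed: int = 0) -> AttentionConfig:
    """Modality-specific defaults: 10 components / 2 heads / lr 5e-4 /
    patience 8 for the metabolome; 30 / 6 / 1e-4 / 10 for the transcriptome.
    Both use 3 layers, dropout 0.5, weight decay 0.1, 5 folds."""
    if modality == "metabolome":
        return AttentionConfig(n_components=10, n_heads=2, learning_rate=5e-4,
                               patience=8, seed=seed)
    if modality == "transcriptome":
        return AttentionConfig(n_components=30, n_heads=6, learning_rate=1e-4,
                               patience=10, seed=seed)
    raise ValueError(f"unknown modality {modality!r}")


@dataclass
class AttentionReport:
    feature_importance: pd.Series
    component_importance: list  # per fold, each sums to 1
    fold_metrics: pd.DataFrame  # columns auc/accuracy/precision/recall/f1
    selected: list  # top-fraction feature ids
    histories: list  # per-fold training histories
    config: AttentionConfig = None


# ---------------------------------------------------------------------------
# Fold-confined scaling + PCA
# ---------------------------------------------------------------------------

def fold_fit_transform(train, test, n_components: int):
    """Standardize and project onto PCA components fitted on train only.

    Returns (train_scores, test_scores, loadings, scaler_params) where
    ``loadings`` is the (features x components) orthonormal matrix.
    """
    from sklearn.decomposition import PCA

    Xtr = train.values.to_numpy(dtype=float) if isinstance(train, OmicsMatrix) else np.asarray(train, dtype=float)
    Xte = test.values.to_numpy(dtype=float) if isinstance(test, OmicsMatrix) else np.asarray(test, dtype=float)
    if n_components > min(Xtr.shape[0] - 1, Xtr.shape[1]):
        raise ValueError("n_components exceeds min(n_train - 1, n_features)")
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Ztr = (Xtr - mean) / sd
    Zte = (Xte - mean) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    Str = pca.fit_transform(Ztr)
    Ste = pca.transform(Zte)
    loadings = pca.components_.T
    return Str, Ste, loadings, {"mean": mean, "sd": sd}


# ---------------------------------------------------------------------------
# Numpy transformer encoder
# ---------------------------------------------------------------------------

def _gelu(x):
    c = math.sqrt(2.0 / math.pi)
    inner = c * (x + 0.044715 * x ** 3)
    return 0.5 * x * (1.0 + np.tanh(inner))


def _gelu_grad(x):
    c = math.sqrt(2.0 / math.pi)
    inner = c * (x + 0.044715 * x ** 3)
    t = np.tanh(inner)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * c * (1.0 + 3 * 0.044715 * x ** 2)


class TransformerEncoderNet:
    """Minimal deterministic transformer encoder for PC-token sequences.

    Post-norm blocks: h = LN(h + Dropout(MHA(h))); h = LN(h + Dropout(FFN(h))).
    A learnable [CLS] token is prepended and the sigmoid head reads its final
    state, so every bit of predictive information must be routed through
    self-attention — which is what makes the attention weights interpretable
    as component usage.
    """

    #: parameter names treated as weights for L2 decay (biases, LayerNorm
    #: gains/offsets, and positional embeddings are exempt)
    _DECAYED_PREFIXES = ("We", "Wq", "Wk", "Wv", "Wo", "W1", "W2", "w_out")

    def __init__(self, n_tokens: int, config: AttentionConfig):
        self.n_tokens = n_tokens
        self.config = config
        self.d = config.embed_dim
        self.h = config.n_heads
        self.dk = self.d // self.h
        self.L = config.n_layers
        self.ff = 2 * self.d
        rng = np.random.default_rng(config.seed)
        self.params = self._init_params(rng)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.trained = False

    def _init_params(self, rng) -> dict:
        d, ff, T = self.d, self.ff, self.n_tokens

        def glorot(shape):
            fan_in, fan_out = shape[0], shape[-1]
            lim = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        p = {
            # per-component embedding: each PC token has its own scalar->d map,
            # so mean pooling is a full-rank linear view of the score vector
            # from the first step (a shared map would average the scores away)
            "We": glorot((T, d)),
            "be": np.zeros(d),
            "cls": 0.02 * rng.standard_normal(d),
            "pos": 0.02 * rng.standard_normal((T + 1, d)),  # position 0 = CLS
            "w_out": glorot((d, 1)),
            "b_out": np.zeros(1),
        }
        for l in range(self.L):
            p[f"Wq{l}"] = glorot((d, d))
            p[f"Wk{l}"] = glorot((d, d))
            p[f"Wv{l}"] = glorot((d, d))
            p[f"Wo{l}"] = glorot((d, d))
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{name}{l}"] = np.zeros(d)
            p[f"ln1g{l}"] = np.ones(d)
            p[f"ln1b{l}"] = np.zeros(d)
            p[f"W1{l}"] = glorot((d, ff))
            p[f"b1{l}"] = np.zeros(ff)
            p[f"W2{l}"] = glorot((ff, d))
            p[f"b2{l}"] = np.zeros(d)
            p[f"ln2g{l}"] = np.ones(d)
            p[f"ln2b{l}"] = np.zeros(d)
        return p

    # -- forward -----------------------------------------------------------

    @staticmethod
    def _layernorm(x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        xhat = (x - mu) / np.sqrt(var + eps)
        return g * xhat + b, (xhat, var, eps)

    def _split_heads(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, H, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * dk)

    def forward(self, X, train: bool = False, rng=None, collect_attention: bool = False):
        """X: (B, T) component scores -> (probs, cache)."""
        p = self.params
        drop = self.config.dropout if train else 0.0
        B, T = X.shape
        cache = {"X": X, "layers": [], "dropout": drop, "attn": []}

        tok = X[:, :, None] * p["We"][None, :, :] + p["be"]
        h = np.concatenate([np.broadcast_to(p["cls"], (B, 1, self.d)), tok], axis=1)
        h = h + p["pos"][None, :, :]
        cache["h0"] = h
        for l in range(self.L):
            lc = {"h_in": h}
            Q = h @ p[f"Wq{l}"] + p[f"bq{l}"]
            K = h @ p[f"Wk{l}"] + p[f"bk{l}"]
            V = h @ p[f"Wv{l}"] + p[f"bv{l}"]
            Qh, Kh, Vh = map(self._split_heads, (Q, K, V))
            S = Qh @ Kh.transpose(0, 1, 3, 2) / math.sqrt(self.dk)
            S = S - S.max(axis=-1, keepdims=True)
            expS = np.exp(S)
            P = expS / expS.sum(axis=-1, keepdims=True)
            O = P @ Vh
            Om = self._merge_heads(O)
            attn_out = Om @ p[f"Wo{l}"] + p[f"bo{l}"]
            if drop > 0:
                mask1 = (rng.random(attn_out.shape) >= drop) / (1 - drop)
                attn_out = attn_out * mask1
            else:
                mask1 = None
            res1 = h + attn_out
            h, ln1c = self._layernorm(res1, p[f"ln1g{l}"], p[f"ln1b{l}"])

            z1 = h @ p[f"W1{l}"] + p[f"b1{l}"]
            a1 = _gelu(z1)
            ffn = a1 @ p[f"W2{l}"] + p[f"b2{l}"]
            if drop > 0:
                mask2 = (rng.random(ffn.shape) >= drop) / (1 - drop)
                ffn = ffn * mask2
            else:
                mask2 = None
            res2 = h + ffn
            h_out, ln2c = self._layernorm(res2, p[f"ln2g{l}"], p[f"ln2b{l}"])

            lc.update(Qh=Qh, Kh=Kh, Vh=Vh, P=P, O=O, Om=Om, mask1=mask1,
                      ln1c=ln1c, h_mid=h, z1=z1, a1=a1, mask2=mask2, ln2c=ln2c)
            cache["layers"].append(lc)
            if collect_attention:
                cache["attn"].append(P)
            h = h_out

        pooled = h[:, 0, :]  # CLS state
        logit = (pooled @ p["w_out"] + p["b_out"])[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache.update(h_final=h, pooled=pooled, logit=logit, prob=prob)
        return prob, cache

    # -- backward ----------------------------------------------------------

    @staticmethod
    def _layernorm_backward(dy, g, ctx):
        xhat, var, eps = ctx
        d = xhat.shape[-1]
        dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        db = dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * g
        inv = 1.0 / np.sqrt(var + eps)
        dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
        return dx, dg, db

    def backward(self, y, cache) -> dict:
        """Mean BCE gradient over the batch for every parameter."""
        p = self.params
        B, T = cache["X"].shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogit = (cache["prob"] - y) / B  # (B,)
        grads["w_out"] = cache["pooled"].T @ dlogit[:, None]
        grads["b_out"] = np.array([dlogit.sum()])
        dpooled = dlogit[:, None] * p["w_out"][:, 0][None, :]
        dh = np.zeros((B, T + 1, self.d))
        dh[:, 0, :] = dpooled

        for l in reversed(range(self.L)):
            lc = cache["layers"][l]
            # second sublayer: LN2(res2)
            dres2, dg2, db2 = self._layernorm_backward(dh, p[f"ln2g{l}"], lc["ln2c"])
            grads[f"ln2g{l}"] = dg2
            grads[f"ln2b{l}"] = db2
            dffn = dres2.copy()
            dh_mid = dres2.copy()
            if lc["mask2"] is not None:
                dffn = dffn * lc["mask2"]
            grads[f"W2{l}"] = np.einsum("btf,btd->fd", lc["a1"], dffn)
            grads[f"b2{l}"] = dffn.sum(axis=(0, 1))
            da1 = dffn @ p[f"W2{l}"].T
            dz1 = da1 * _gelu_grad(lc["z1"])
            grads[f"W1{l}"] = np.einsum("btd,btf->df", lc["h_mid"], dz1)
            grads[f"b1{l}"] = dz1.sum(axis=(0, 1))
            dh_mid = dh_mid + dz1 @ p[f"W1{l}"].T

            # first sublayer: LN1(res1)
            dres1, dg1, db1 = self._layernorm_backward(dh_mid, p[f"ln1g{l}"], lc["ln1c"])
            grads[f"ln1g{l}"] = dg1
            grads[f"ln1b{l}"] = db1
            dattn_out = dres1.copy()
            dh_in = dres1.copy()
            if lc["mask1"] is not None:
                dattn_out = dattn_out * lc["mask1"]
            grads[f"Wo{l}"] = np.einsum("btd,bte->de", lc["Om"], dattn_out)
            grads[f"bo{l}"] = dattn_out.sum(axis=(0, 1))
            dOm = dattn_out @ p[f"Wo{l}"].T
            dO = self._split_heads(dOm)
            P, Qh, Kh, Vh = lc["P"], lc["Qh"], lc["Kh"], lc["Vh"]
            dP = dO @ Vh.transpose(0, 1, 3, 2)
            dVh = P.transpose(0, 1, 3, 2) @ dO
            dS = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
            dS = dS / math.sqrt(self.dk)
            dQh = dS @ Kh
            dKh = dS.transpose(0, 1, 3, 2) @ Qh
            dQ = self._merge_heads(dQh)
            dK = self._merge_heads(dKh)
            dV = self._merge_heads(dVh)
            h_in = lc["h_in"]
            grads[f"Wq{l}"] = np.einsum("btd,bte->de", h_in, dQ)
            grads[f"Wk{l}"] = np.einsum("btd,bte->de", h_in, dK)
            grads[f"Wv{l}"] = np.einsum("btd,bte->de", h_in, dV)
            grads[f"bq{l}"] = dQ.sum(axis=(0, 1))
            grads[f"bk{l}"] = dK.sum(axis=(0, 1))
            grads[f"bv{l}"] = dV.sum(axis=(0, 1))
            dh_in = dh_in + dQ @ p[f"Wq{l}"].T + dK @ p[f"Wk{l}"].T + dV @ p[f"Wv{l}"].T
            dh = dh_in

        grads["pos"] = dh.sum(axis=0)
        grads["cls"] = dh[:, 0, :].sum(axis=0)
        grads["be"] = dh[:, 1:, :].sum(axis=(0, 1))
        grads["We"] = np.einsum("bt,btd->td", cache["X"], dh[:, 1:, :])
        return grads

    # -- optimization ------------------------------------------------------

    def _adam_step(self, grads):
        # Adam with decoupled (AdamW-style) L2 weight decay on weight
        # matrices; coupling the penalty through the adaptive gradient would
        # let the decay term dominate v-hat and stall learning entirely.
        cfg = self.config
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self._adam_t)
            vhat = v / (1 - b2 ** self._adam_t)
            step = mhat / (np.sqrt(vhat) + eps)
            if cfg.weight_decay > 0 and any(k.startswith(pref) for pref in self._DECAYED_PREFIXES):
                step = step + cfg.weight_decay * self.params[k]
            self.params[k] = self.params[k] - cfg.learning_rate * step

    @staticmethod
    def bce_loss(prob, y) -> float:
        eps = 1e-12
        prob = np.clip(prob, eps, 1 - eps)
        return float(-(y * np.log(prob) + (1 - y) * np.log(1 - prob)).mean())

    def fit(self, X, y, X_val=None, y_val=None):
        """Minibatch Adam with early stopping on validation BCE.

        If no explicit validation set is passed, a stratified 20% split of
        the training data is held out. Returns the training history.
        """
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        rng = np.random.default_rng(cfg.seed + 1)

        if X_val is None:
            idx_val, idx_tr = _stratified_holdout(y, 0.2, rng)
            X_val, y_val = X[idx_val], y[idx_val]
            X, y = X[idx_tr], y[idx_tr]

        best_loss = np.inf
        best_params = None
        bad_epochs = 0
        history = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
        n = X.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                bidx = order[start:start + cfg.batch_size]
                prob, cache = self.forward(X[bidx], train=True, rng=rng)
                if not np.isfinite(prob).all():
                    raise FloatingPointError("NaN encountered during training")
                loss = self.bce_loss(prob, y[bidx])
                epoch_loss += loss * len(bidx)
                grads = self.backward(y[bidx], cache)
                self._adam_step(grads)
            history["train_loss"].append(epoch_loss / n)
            val_prob, _ = self.forward(X_val, train=False)
            val_loss = self.bce_loss(val_prob, y_val)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    history["stopped_epoch"] = epoch + 1
                    break
        if history["stopped_epoch"] is None:
            history["stopped_epoch"] = len(history["train_loss"])
        if best_params is not None:
            self.params = best_params
        self.trained = True
        self.history = history
        return history

    def predict_proba(self, X) -> np.ndarray:
        prob, _ = self.forward(np.asarray(X, dtype=float), train=False)
        return prob

    def attention_matrices(self, X) -> list:
        """Eval-mode attention tensors, one (B, H, T, T) array per layer."""
        _, cache = self.forward(np.asarray(X, dtype=float), train=False,
                                collect_attention=True)
        return cache["attn"]


def _stratified_holdout(y, frac, rng):
    """Indices (holdout, rest) of a stratified random split."""
    holdout = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        k = max(1, int(round(frac * len(idx))))
        holdout.extend(rng.choice(idx, size=k, replace=False))
    holdout = np.sort(np.asarray(holdout))
    rest = np.setdiff1d(np.arange(len(y)), holdout)
    return holdout, rest


# ---------------------------------------------------------------------------
# Training / importance / selection
# ---------------------------------------------------------------------------

def train_encoder(train_scores, train_labels, config: AttentionConfig,
                  val_scores=None, val_labels=None):
    """Train a fresh encoder on PC scores; returns (model, history)."""
    y = np.asarray(train_labels, dtype=float)
    model = TransformerEncoderNet(n_tokens=np.asarray(train_scores).shape[1], config=config)
    history = model.fit(np.asarray(train_scores, dtype=float), y,
                        X_val=val_scores, y_val=val_labels)
    return model, history


def attention_importance(model: TransformerEncoderNet, scores, loadings=None) -> dict:
    """Attention mass received per component token, and its propagation to
    original features through squared loadings.

    Component importance: column means of every softmax attention matrix
    (the CLS column excluded), averaged over heads, layers, and samples,
    renormalized to sum to 1. Feature importance:
    sum_c loading_{j,c}^2 * component_importance_c — the feature's variance
    share of each component, weighted by how much attention the component
    receives; sign flips of components leave it unchanged.
    """
    if not getattr(model, "trained", False):
        raise ValueError("model must be trained before importance extraction")
    mats = model.attention_matrices(scores)
    received = np.zeros(model.n_tokens)
    for P in mats:
        received += P.mean(axis=(0, 1, 2))[1:]  # drop the CLS column
    comp = received / received.sum()
    out = {"component_importance": comp}
    if loadings is not None:
        loadings = np.asarray(loadings, dtype=float)
        out["feature_importance"] = (loadings ** 2) @ comp
    return out


def select_top_fraction(importance: pd.Series, top_fraction: float = 0.20) -> list:
    """The ceil(top_fraction * p) highest-importance features; boundary ties
    broken lexicographically by feature id."""
    if importance.isna().any() or not np.isfinite(importance).all():
        raise ValueError("importances must be finite")
    k = math.ceil(top_fraction * len(importance))
    order = sorted(importance.index, key=lambda f: (-importance[f], str(f)))
    return order[:k]


def dual_filter(differential_set, attention_set, universe=None) -> set:
    """Intersection of the classical differential set with the attention
    top-fraction set. Both must live in the same feature universe."""
    a, b = set(differential_set), set(attention_set)
    if universe is not None:
        uni = set(universe)
        if not a.issubset(uni) or not b.issubset(uni):
            raise ValueError("sets must be subsets of the shared feature universe")
    return a & b


# ---------------------------------------------------------------------------
# Confined cross-validation
# ---------------------------------------------------------------------------

def cross_validate(m: OmicsMatrix, labels=None, config: Optional[AttentionConfig] = None,
                   leak_mode: bool = False) -> AttentionReport:
    """Stratified k-fold CV of the scaler->PCA->encoder classifier.

    Confined mode (default): scaler, PCA, and the early-stopping validation
    split are all derived from the fold's training portion only. Leak mode
    (diagnostics only) fits the scaler/PCA on all samples and monitors early
    stopping on the evaluation fold itself — a deliberate leak used to verify
    that the confinement matters.
    """
    from sklearn.model_selection import StratifiedKFold

    if config is None:
        config = default_config(m.modality)
    y = m.binary_labels() if labels is None else binary_labels(labels)
    if min(np.bincount(y)) < config.n_folds:
        raise ValueError("need at least n_folds samples per class")
    X = m.values.to_numpy(dtype=float)
    feature_ids = list(m.values.columns)

    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    fold_rows, comp_imps, histories = [], [], []
    feat_imp = np.zeros(len(feature_ids))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = replace(config, seed=config.seed + 1000 * (fold + 1))
        if leak_mode:
            Str_all, _, loadings, _ = fold_fit_transform(X, X, config.n_components)
            Str, Ste = Str_all[tr], Str_all[te]
            model, history = train_encoder(Str, y[tr], fold_cfg,
                                           val_scores=Ste, val_labels=y[te])
        else:
            Str, Ste, loadings, _ = fold_fit_transform(X[tr], X[te], config.n_components)
            model, history = train_encoder(Str, y[tr], fold_cfg)
        prob = model.predict_proba(Ste)
        cm = ev.classification_metrics((prob >= 0.5).astype(int), y[te])
        fold_rows.append({
            "fold": fold,
            "auc": ev.roc_auc(prob, y[te]) if len(np.unique(y[te])) == 2 else np.nan,
            "accuracy": cm["accuracy"], "precision": cm["precision"],
            "recall": cm["recall"], "f1": cm["f1"],
        })
        imp = attention_importance(model, Str, loadings)
        comp_imps.append(imp["component_importance"])
        feat_imp += imp["feature_importance"]
        histories.append(history)

    feat_imp /= config.n_folds
    importance = pd.Series(feat_imp, index=feature_ids, name="importance")
    selected = select_top_fraction(importance, config.top_fraction)
    return AttentionReport(
        feature_importance=importance,
        component_importance=comp_imps,
        fold_metrics=pd.DataFrame(fold_rows).set_index("fold"),
        selected=selected,
        histories=histories,
        config=config,
    )
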