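"""Quantum-inspired feature-map fusion model.

Two backbone feature vectors ``z_A`` and ``z_B`` are fused as follows:

1. **Hadamard interaction** — both vectors are truncated to
   ``d_H = min(d_A, d_B)`` and multiplied elementwise, giving an explicitly
   multiplicative interaction vector ``z_H``.
2. **Quantum feature map (QFM)** — each of the three vectors passes through
   its own map: a learned phase projection ``theta = W z + b`` followed by
   the trigonometric embedding ``c = cos(theta)``, ``s = sin(theta)``; a
   low-rank multiplicative interaction ``h = (c U) * sin(z V)`` (rank ``r``);
   concatenation ``f~ = [c; s; h]``; a linear projection ``f = W0 f~ + b0``;
   and norm scaling ``psi = f / (||f||_2 + eps)``.  The output always lies
   strictly inside the unit ball, approaching the sphere as ``||f||`` grows —
   the classical analogue of a unit-norm state vector.
3. **Token sequence and attention** — the three P-dimensional tokens
   ``(t_A, t_B, t_H)`` form a 3 x P sequence processed by one multi-head
   self-attention layer, ``softmax(Q K^T / sqrt(d_k)) V`` per head, heads
   concatenated and projected by ``W_O``.  No residual or layer norm.
4. **MLP head** — tokens are mean-pooled, passed through one hidden layer
   with ReLU and dropout, and softmaxed over the classes.

Everything is plain NumPy with hand-derived gradients (exposed through
:meth:`FusionModel.loss_and_grads`); the backbones stay frozen so gradients
are only needed for the fusion parameters, never for the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class HadamardConfig:
    """Dimensions of the Hadamard interaction: ``dH = min(dA, dB)``."""

    dA: int
    dB: int

    @property
    def dH(self) -> int:
        return min(self.dA, self.dB)


@dataclass
class QFMParams:
    """Learnable parameters of one quantum feature map.

    Shapes: ``W`` (P, d), ``b`` (P,), ``U`` (P, r), ``V`` (d, r),
    ``W0`` (P, 2P + r), ``b0`` (P,).  ``eps`` is the norm-scaling constant.
    ``alt_phase_interaction`` selects the variant reading of the low-rank
    term in which the cosine is applied after projecting the phase
    (``h1 = cos(theta U)``) instead of before (``h1 = cos(theta) U``).
    """

    W: np.ndarray
    b: np.ndarray
    U: np.ndarray
    V: np.ndarray
    W0: np.ndarray
    b0: np.ndarray
    eps: float = 1e-6
    alt_phase_interaction: bool = False

    def __post_init__(self) -> None:
        P, d = self.W.shape
        r = self.U.shape[1]
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        if self.b.shape != (P,) or self.U.shape != (P, r):
            raise ValidationError("inconsistent QFM parameter shapes")
        if self.V.shape != (d, r) or self.W0.shape != (P, 2 * P + r) or self.b0.shape != (P,):
            raise ValidationError("inconsistent QFM parameter shapes")

    @property
    def P(self) -> int:
        return self.W.shape[0]

    @property
    def r(self) -> int:
        return self.U.shape[1]

    @property
    def d(self) -> int:
        return self.W.shape[1]


@dataclass
class MHAParams:
    """One multi-head self-attention layer over the 3-token sequence.

    ``WQ``, ``WK``, ``WV`` and ``WO`` are (P, P); the first three are column-
    partitioned into ``n_heads`` blocks of width ``d_k = P / n_heads``.
    """

    WQ: np.ndarray
    WK: np.ndarray
    WV: np.ndarray
    WO: np.ndarray
    n_heads: int = 4

    def __post_init__(self) -> None:
        P = self.WQ.shape[0]
        for M in (self.WQ, self.WK, self.WV, self.WO):
            if M.shape != (P, P):
                raise ValidationError("attention projection matrices must all be P x P")
        if self.n_heads < 1 or P % self.n_heads != 0:
            raise ValidationError("P must be divisible by n_heads")

    @property
    def P(self) -> int:
        return self.WQ.shape[0]

    @property
    def dk(self) -> int:
        return self.P // self.n_heads


@dataclass
class ClassifierHead:
    """Pool -> hidden (ReLU, dropout) -> softmax over the classes."""

    W1: np.ndarray  # (in_dim, hidden)
    b1: np.ndarray
    W2: np.ndarray  # (hidden, K)
    b2: np.ndarray
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.W2.shape[1] < 2:
            raise ValidationError("need at least 2 classes")
        if self.W1.shape[1] != self.b1.shape[0] or self.W2.shape[0] != self.W1.shape[1]:
            raise ValidationError("inconsistent classifier head shapes")

    @property
    def hidden_dim(self) -> int:
        return self.W1.shape[1]

    @property
    def n_classes(self) -> int:
        return self.W2.shape[1]


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_qfm_params(d: int, P: int = 256, r: int = 32, eps: float = 1e-6,
                    rng: np.random.Generator | None = None,
                    alt_phase_interaction: bool = False) -> QFMParams:
    """Variance-scaled uniform init for projections, zeros for biases."""
    rng = rng or np.random.default_rng(0)
    return QFMParams(
        W=_glorot(rng, (P, d)), b=np.zeros(P),
        U=_glorot(rng, (P, r)), V=_glorot(rng, (d, r)),
        W0=_glorot(rng, (P, 2 * P + r)), b0=np.zeros(P),
        eps=eps, alt_phase_interaction=alt_phase_interaction,
    )


def init_mha_params(P: int, n_heads: int = 4,
                    rng: np.random.Generator | None = None) -> MHAParams:
    rng = rng or np.random.default_rng(0)
    return MHAParams(*(_glorot(rng, (P, P)) for _ in range(4)), n_heads=n_heads)


def init_classifier_head(in_dim: int, hidden_dim: int = 256, n_classes: int = 5,
                         dropout_rate: float = 0.3,
                         rng: np.random.Generator | None = None) -> ClassifierHead:
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    rng = rng or np.random.default_rng(0)
    return ClassifierHead(
        W1=_glorot(rng, (in_dim, hidden_dim)), b1=np.zeros(hidden_dim),
        W2=_glorot(rng, (hidden_dim, n_classes)), b2=np.zeros(n_classes),
        dropout_rate=dropout_rate,
    )


# ---------------------------------------------------------------------------
# forward operations

def _as_batch(z: np.ndarray) -> tuple[np.ndarray, bool]:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 1:
        return z[None, :], True
    return z, False


def hadamard_interaction(zA: np.ndarray, zB: np.ndarray) -> np.ndarray:
    """Elementwise product after truncating both vectors to ``min(dA, dB)``.

    Truncation keeps the first ``dH`` components of each input; no learned
    projection is involved.  Accepts single vectors or (n, d) batches.
    """
    zA, singleA = _as_batch(zA)
    zB, singleB = _as_batch(zB)
    if zA.shape[1] == 0 or zB.shape[1] == 0:
        raise ValidationError("feature vectors must be non-empty")
    if zA.shape[0] != zB.shape[0]:
        raise ValidationError("batch sizes differ")
    dH = min(zA.shape[1], zB.shape[1])
    out = zA[:, :dH] * zB[:, :dH]
    return out[0] if (singleA and singleB) else out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


def _qfm_fwd(z: np.ndarray, p: QFMParams) -> tuple[np.ndarray, dict]:
    """Batched QFM forward; returns (psi, cache-for-backward)."""
    theta = z @ p.W.T + p.b
    c, s = np.cos(theta), np.sin(theta)
    if p.alt_phase_interaction:
        m = theta @ p.U
        h1 = np.cos(m)
    else:
        m = None
        h1 = c @ p.U
    zp = z @ p.V
    h2 = np.sin(zp)
    h = h1 * h2
    ft = np.concatenate([c, s, h], axis=1)
    f = ft @ p.W0.T + p.b0
    norm = np.linalg.norm(f, axis=1, keepdims=True)
    psi = f / (norm + p.eps)
    return psi, {"z": z, "theta": theta, "c": c, "s": s, "m": m, "zp": zp,
                 "h1": h1, "h2": h2, "ft": ft, "f": f, "norm": norm}


def qfm_forward(z: np.ndarray, params: QFMParams) -> np.ndarray:
    """Map a feature vector (or batch) through the quantum feature map.

    The output ``psi = f / (||f||_2 + eps)`` has Euclidean norm strictly
    below 1; it approaches 1 as ``||f|| / eps`` grows.
    """
    zb, single = _as_batch(z)
    if zb.shape[1] != params.d:
        raise ValidationError(
            f"input dim {zb.shape[1]} does not match the QFM's d={params.d}")
    psi, _ = _qfm_fwd(zb, params)
    return psi[0] if single else psi


def _qfm_bwd(g_psi: np.ndarray, p: QFMParams, cache: dict) -> dict[str, np.ndarray]:
    f, norm = cache["f"], cache["norm"]
    denom = norm + p.eps
    norm_safe = np.maximum(norm, 1e-300)
    dot = (f * g_psi).sum(axis=1, keepdims=True)
    g_f = g_psi / denom - f * dot / (norm_safe * denom ** 2)
    g_W0 = g_f.T @ cache["ft"]
    g_b0 = g_f.sum(axis=0)
    g_ft = g_f @ p.W0
    P, r = p.P, p.r
    g_c, g_s, g_h = g_ft[:, :P], g_ft[:, P:2 * P], g_ft[:, 2 * P:]
    g_h1 = g_h * cache["h2"]
    g_h2 = g_h * cache["h1"]
    g_theta = np.zeros_like(cache["theta"])
    if p.alt_phase_interaction:
        g_m = -g_h1 * np.sin(cache["m"])
        g_U = cache["theta"].T @ g_m
        g_theta += g_m @ p.U.T
    else:
        g_U = cache["c"].T @ g_h1
        g_c = g_c + g_h1 @ p.U.T
    g_zp = g_h2 * np.cos(cache["zp"])
    g_V = cache["z"].T @ g_zp
    g_theta += -g_c * cache["s"] + g_s * cache["c"]
    return {"W": g_theta.T @ cache["z"], "b": g_theta.sum(axis=0),
            "U": g_U, "V": g_V, "W0": g_W0, "b0": g_b0}


def build_token_sequence(psiA: np.ndarray, psiB: np.ndarray,
                         psiH: np.ndarray) -> np.ndarray:
    """Stack three QFM tokens into the (3, P) sequence (rows A, B, Hadamard).

    Batched inputs (n, P) give an (n, 3, P) stack.
    """
    a, sa = _as_batch(psiA)
    b, sb = _as_batch(psiB)
    h, sh = _as_batch(psiH)
    if not (a.shape == b.shape == h.shape):
        raise ValidationError("all three tokens must share the same dimension")
    T = np.stack([a, b, h], axis=1)
    return T[0] if (sa and sb and sh) else T


def _mha_fwd(T: np.ndarray, p: MHAParams) -> tuple[np.ndarray, dict]:
    n, L, P = T.shape
    h, dk = p.n_heads, p.dk

    def heads(M: np.ndarray) -> np.ndarray:
        return (T @ M).reshape(n, L, h, dk).transpose(0, 2, 1, 3)  # (n,h,L,dk)

    Q, K, V = heads(p.WQ), heads(p.WK), heads(p.WV)
    scores = Q @ K.transpose(0, 1, 3, 2) / np.sqrt(dk)  # (n,h,L,L)
    A = softmax(scores, axis=-1)
    HV = A @ V  # (n,h,L,dk)
    H = HV.transpose(0, 2, 1, 3).reshape(n, L, P)
    out = H @ p.WO
    return out, {"T": T, "Q": Q, "K": K, "V": V, "A": A, "H": H}


def mha_forward(T: np.ndarray, params: MHAParams,
                return_attention: bool = False):
    """Multi-head scaled dot-product self-attention over a token sequence.

    ``T`` is (3, P) or a batch (n, 3, P).  With ``return_attention`` the
    per-head row-stochastic attention weights are returned as well.
    """
    T = np.asarray(T, dtype=np.float64)
    single = T.ndim == 2
    if single:
        T = T[None]
    if T.shape[-1] != params.P:
        raise ValidationError("token dim does not match attention parameters")
    out, cache = _mha_fwd(T, params)
    if single:
        out = out[0]
    if return_attention:
        A = cache["A"][0] if single else cache["A"]
        return out, A
    return out


def _mha_bwd(g_out: np.ndarray, p: MHAParams, cache: dict):
    n, L, P = cache["T"].shape
    h, dk = p.n_heads, p.dk
    T, Q, K, V, A, H = (cache[k] for k in ("T", "Q", "K", "V", "A", "H"))
    g_WO = np.einsum("nip,niq->pq", H, g_out)
    g_H = g_out @ p.WO.T
    g_HV = g_H.reshape(n, L, h, dk).transpose(0, 2, 1, 3)
    g_A = g_HV @ V.transpose(0, 1, 3, 2)
    g_V = A.transpose(0, 1, 3, 2) @ g_HV
    g_S = A * (g_A - (g_A * A).sum(axis=-1, keepdims=True))
    g_Q = g_S @ K / np.sqrt(dk)
    g_K = g_S.transpose(0, 1, 3, 2) @ Q / np.sqrt(dk)

    def unheads(G: np.ndarray) -> np.ndarray:
        return G.transpose(0, 2, 1, 3).reshape(n, L, P)

    gQf, gKf, gVf = unheads(g_Q), unheads(g_K), unheads(g_V)
    grads = {"WQ": np.einsum("nip,niq->pq", T, gQf),
             "WK": np.einsum("nip,niq->pq", T, gKf),
             "WV": np.einsum("nip,niq->pq", T, gVf),
             "WO": g_WO}
    g_T = gQf @ p.WQ.T + gKf @ p.WK.T + gVf @ p.WV.T
    return grads, g_T


def _head_fwd(attended: np.ndarray, head: ClassifierHead, pooling: str,
              train: bool, rng: np.random.Generator | None) -> tuple[np.ndarray, dict]:
    n, L, P = attended.shape
    if pooling == "mean":
        pooled = attended.mean(axis=1)
    elif pooling == "flatten":
        pooled = attended.reshape(n, L * P)
    else:
        raise ValidationError(f"unknown pooling {pooling!r}")
    hid = pooled @ head.W1 + head.b1
    act = np.maximum(hid, 0.0)
    if train and head.dropout_rate > 0.0:
        if rng is None:
            raise ValidationError("dropout in training mode needs an rng")
        keep = 1.0 - head.dropout_rate
        mask = (rng.random(act.shape) < keep) / keep
    else:
        mask = np.ones_like(act)
    dropped = act * mask
    logits = dropped @ head.W2 + head.b2
    probs = softmax(logits, axis=-1)
    return probs, {"pooled": pooled, "hid": hid, "mask": mask,
                   "dropped": dropped, "probs": probs, "shape": (n, L, P)}


def classify(attended: np.ndarray, head: ClassifierHead, pooling: str = "mean",
             train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
    """Class probabilities from the attended token sequence.

    Tokens are mean-pooled by default (``pooling='flatten'`` concatenates
    them instead), then hidden layer -> ReLU -> dropout (inactive unless
    ``train``) -> softmax.
    """
    attended = np.asarray(attended, dtype=np.float64)
    single = attended.ndim == 2
    if single:
        attended = attended[None]
    probs, _ = _head_fwd(attended, head, pooling, train, rng)
    return probs[0] if single else probs


def _head_bwd(g_logits: np.ndarray, head: ClassifierHead, pooling: str,
              cache: dict):
    g_W2 = cache["dropped"].T @ g_logits
    g_b2 = g_logits.sum(axis=0)
    g_dropped = g_logits @ head.W2.T
    g_act = g_dropped * cache["mask"]
    g_hid = g_act * (cache["hid"] > 0)
    g_W1 = cache["pooled"].T @ g_hid
    g_b1 = g_hid.sum(axis=0)
    g_pooled = g_hid @ head.W1.T
    n, L, P = cache["shape"]
    if pooling == "mean":
        g_att = np.repeat(g_pooled[:, None, :] / L, L, axis=1)
    else:
        g_att = g_pooled.reshape(n, L, P)
    return {"W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2}, g_att


# ---------------------------------------------------------------------------
# full model

@dataclass(frozen=True)
class FusionConfig:
    """Hyperparameters of the fusion model (defaults follow the study recipe:
    768-d backbone features, P=256 phase embedding, r=32 low-rank dim,
    4 attention heads, 5 classes)."""

    dA: int = 768
    dB: int = 768
    P: int = 256
    r: int = 32
    n_heads: int = 4
    hidden_dim: int = 256
    dropout_rate: float = 0.3
    n_classes: int = 5
    eps: float = 1e-6
    pooling: str = "mean"
    alt_phase_interaction: bool = False
    seed: int = 0

    @property
    def dH(self) -> int:
        return min(self.dA, self.dB)


class FusionModel:
    """The composed classifier: Hadamard -> 3 QFMs -> attention -> MLP head.

    Three *separate* QFM parameter sets are kept (branches A, B and the
    Hadamard interaction), since the branch input dimensions may differ.
    """

    def __init__(self, config: FusionConfig):
        if config.P % config.n_heads != 0:
            raise ValidationError("P must be divisible by n_heads")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        alt = config.alt_phase_interaction
        self.qfm_a = init_qfm_params(config.dA, config.P, config.r, config.eps, rng, alt)
        self.qfm_b = init_qfm_params(config.dB, config.P, config.r, config.eps, rng, alt)
        self.qfm_h = init_qfm_params(config.dH, config.P, config.r, config.eps, rng, alt)
        self.mha = init_mha_params(config.P, config.n_heads, rng)
        in_dim = config.P if config.pooling == "mean" else 3 * config.P
        self.head = init_classifier_head(in_dim, config.hidden_dim,
                                         config.n_classes, config.dropout_rate, rng)

    # parameters as a flat name -> array dict (arrays are shared, not copied)
    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for tag, p in (("qfm_a", self.qfm_a), ("qfm_b", self.qfm_b), ("qfm_h", self.qfm_h)):
            for k in ("W", "b", "U", "V", "W0", "b0"):
                out[f"{tag}.{k}"] = getattr(p, k)
        for k in ("WQ", "WK", "WV", "WO"):
            out[f"mha.{k}"] = getattr(self.mha, k)
        for k in ("W1", "b1", "W2", "b2"):
            out[f"head.{k}"] = getattr(self.head, k)
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for name, arr in self.parameters().items():
            arr[...] = values[name]

    def _forward(self, zA: np.ndarray, zB: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, dict]:
        zA = np.atleast_2d(np.asarray(zA, dtype=np.float64))
        zB = np.atleast_2d(np.asarray(zB, dtype=np.float64))
        if zA.shape[1] != self.config.dA or zB.shape[1] != self.config.dB:
            raise ValidationError("feature dims do not match the model config")
        zH = hadamard_interaction(zA, zB)
        psiA, ca = _qfm_fwd(zA, self.qfm_a)
        psiB, cb = _qfm_fwd(zB, self.qfm_b)
        psiH, ch = _qfm_fwd(np.atleast_2d(zH), self.qfm_h)
        T = build_token_sequence(psiA, psiB, psiH)
        att, cm = _mha_fwd(T, self.mha)
        probs, chead = _head_fwd(att, self.head, self.config.pooling, train, rng)
        return probs, {"qfm_a": ca, "qfm_b": cb, "qfm_h": ch, "mha": cm, "head": chead}

    def forward(self, zA: np.ndarray, zB: np.ndarray) -> np.ndarray:
        """Inference-mode class probabilities, one row per sample."""
        single = np.asarray(zA).ndim == 1
        probs, _ = self._forward(zA, zB, train=False, rng=None)
        return probs[0] if single else probs

    def predict(self, zA: np.ndarray, zB: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(zA, zB), axis=-1)

    def loss_and_grads(self, zA: np.ndarray, zB: np.ndarray, labels: np.ndarray,
                       rng: np.random.Generator | None = None,
                       train: bool = True):
        """Mean cross-entropy on a batch plus gradients for every parameter."""
        labels = np.asarray(labels)
        probs, cache = self._forward(zA, zB, train, rng)
        n = probs.shape[0]
        p_true = np.clip(probs[np.arange(n), labels], 1e-12, None)
        loss = -np.log(p_true).mean()
        # softmax + CE backward
        g_logits = probs.copy()
        g_logits[np.arange(n), labels] -= 1.0
        g_logits /= n
        g_head, g_att = _head_bwd(g_logits, self.head, self.config.pooling, cache["head"])
        g_mha, g_T = _mha_bwd(g_att, self.mha, cache["mha"])
        grads = {f"head.{k}": v for k, v in g_head.items()}
        grads.update({f"mha.{k}": v for k, v in g_mha.items()})
        for tag, p, g_psi in (("qfm_a", self.qfm_a, g_T[:, 0, :]),
                              ("qfm_b", self.qfm_b, g_T[:, 1, :]),
                              ("qfm_h", self.qfm_h, g_T[:, 2, :])):
            for k, v in _qfm_bwd(g_psi, p, cache[tag]).items():
                grads[f"{tag}.{k}"] = v
        return loss, grads

    # -- checkpointing ------------------------------------------------------
    def save(self, archive_path, manifest_path) -> None:
        """Flat parameter archive (.npz) + JSON hyperparameter manifest."""
        import json
        from dataclasses import asdict
        np.savez(archive_path, **self.parameters())
        with open(manifest_path, "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, archive_path, manifest_path) -> "FusionModel":
        import json
        with open(manifest_path) as fh:
            config = FusionConfig(**json.load(fh))
        model = cls(config)
        with np.load(archive_path) as data:
            model.set_parameters({k: data[k] for k in data.files})
        return model


def fusion_forward(zA: np.ndarray, zB: np.ndarray, model: FusionModel) -> np.ndarray:
    """Functional alias for :meth:`FusionModel.forward` (inference mode)."""
    return model.forward(zA, zB)
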