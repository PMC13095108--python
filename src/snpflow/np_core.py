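"""The SNP-NF model: a sequential neural process with planar-flow latents.

A window of k consecutive visits — (features, label) pairs — conditions
two encoder paths. The deterministic path embeds each pair, runs a
transformer encoder over the k visit slots and mean-pools the outputs
into a representation r_d. The latent path does the same with its own
(unshared) transformer, maps the pooled embedding to a diagonal Gaussian
(mu, sigma), draws a reparameterized sample z0 and pushes it through a
chain of planar normalizing flows to obtain zK with its accumulated
log-det Jacobian. The decoder concatenates [r_d, zK] and predicts the
next visit's diagnosis through a two-layer fully connected head.

Training follows the neural-process objective: cross-entropy of the
predicted next-visit label plus a KL regularizer between the latent
posterior conditioned on context + target (q_full) and the one
conditioned on context alone (q_context). Because both posteriors share
the single global flow chain, the KL between the flowed densities equals
the KL between their Gaussian bases (KL is invariant under a shared
invertible map); the flows shape what the decoder sees rather than the
divergence itself. In eval mode the target pair is never consumed.

Ablation variants (transformer replaced by a per-point feed-forward
encoder, single-path models, a flow-only classifier, a flow-free model)
are built by :func:`build_variant`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .flows import FlowChain, FlowStep, chain_forward, constrain_step, gaussian_log_density
from .windows_io import WindowSample

VARIANTS = (
    "np_plain",
    "tnp_latent_only",
    "tnp_deterministic_only",
    "snp",
    "nf_only",
    "np_nf_no_transformer",
    "snp_nf",
)

SIGMA_MIN, SIGMA_MAX = 1e-4, 10.0


@dataclass
class ModelConfig:
    """Hyperparameters; the defaults are the reference configuration
    (embedding 128, 2 encoder layers, window 4, learning rate 1e-5,
    10 epochs, flow depth 5)."""

    embedding_dim: int = 128
    n_encoder_layers: int = 2
    n_flow_steps: int = 5
    n_heads: int = 4
    latent_dim: Optional[int] = None
    n_classes: int = 3
    n_features: int = 11
    window_k: int = 4
    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 16
    kl_samples: int = 1
    beta: float = 1.0
    seed: int = 0
    variant: str = "snp_nf"

    def __post_init__(self):
        if self.latent_dim is None:
            self.latent_dim = self.embedding_dim
        if self.embedding_dim % self.n_heads != 0:
            raise ValueError("embedding_dim must be divisible by n_heads")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for name in ("embedding_dim", "n_encoder_layers", "n_heads", "n_classes",
                     "window_k", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_flow_steps < 0:
            raise ValueError("n_flow_steps must be >= 0")

    @classmethod
    def scaled_down(cls, **overrides) -> "ModelConfig":
        """A small desk-scale preset: embedding 32, 1 encoder layer, 2 flow
        steps, 10 epochs, batch 16, Adam lr 1e-3 (the reference 1e-5 is far
        too slow for a fresh model trained 10 epochs at this scale)."""
        base = dict(embedding_dim=32, n_encoder_layers=1, n_flow_steps=2,
                    n_heads=4, learning_rate=1e-3, epochs=10, batch_size=16)
        base.update(overrides)
        return cls(**base)


@dataclass
class ContextEncoding:
    per_point: Tensor  # (B, k, d)
    aggregate: Tensor  # (B, d)


@dataclass
class LatentPosterior:
    mu: Tensor
    sigma: Tensor
    z0: Tensor
    zK: Tensor
    total_logdet: Tensor


@dataclass
class Prediction:
    logits: Tensor  # (B, C)

    @property
    def probs(self) -> np.ndarray:
        return ad.softmax(self.logits, axis=-1).data


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encodings over visit slots."""
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((n_pos, dim))
    enc[:, 0::2] = np.sin(angles[:, 0::2])
    enc[:, 1::2] = np.cos(angles[:, 1::2])
    return enc


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros(labels.shape + (n_classes,))
    np.put_along_axis(out, labels[..., None], 1.0, axis=-1)
    return out


class SNPNF:
    """The model. Construct directly for the full architecture or through
    :func:`build_variant` for ablations."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        v = cfg.variant
        self.use_transformer = v not in ("np_plain", "np_nf_no_transformer", "nf_only")
        self.use_deterministic = v in ("snp_nf", "snp", "np_plain",
                                       "np_nf_no_transformer", "tnp_deterministic_only")
        self.use_latent = v in ("snp_nf", "snp", "np_plain",
                                "np_nf_no_transformer", "tnp_latent_only")
        self.is_nf_only = v == "nf_only"
        if v in ("snp", "np_plain"):
            self.n_flow_steps = 0
        else:
            self.n_flow_steps = cfg.n_flow_steps

        self.params: Dict[str, Tensor] = {}
        self._rng_init = np.random.default_rng(cfg.seed)
        self._build()
        self.posenc = sinusoidal_positions(cfg.window_k + 1, cfg.embedding_dim)

    # -- construction ---------------------------------------------------
    def _p(self, name: str, shape, scale: Optional[float] = None) -> Tensor:
        if scale is None:  # Glorot-style default
            fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
            scale = 1.0 / np.sqrt(fan_in)
        t = Tensor(self._rng_init.normal(scale=scale, size=shape), requires_grad=True)
        self.params[name] = t
        return t

    def _zeros(self, name: str, shape) -> Tensor:
        t = Tensor(np.zeros(shape), requires_grad=True)
        self.params[name] = t
        return t

    def _ones(self, name: str, shape) -> Tensor:
        t = Tensor(np.ones(shape), requires_grad=True)
        self.params[name] = t
        return t

    def _build(self) -> None:
        cfg = self.cfg
        d, dz, C, F = cfg.embedding_dim, cfg.latent_dim, cfg.n_classes, cfg.n_features
        d_in = F + C

        if self.is_nf_only:
            # pooled raw (features, one-hot label) -> latent -> flows -> head
            self._p("pool_W", (d_in, dz))
            self._zeros("pool_b", (dz,))
            self._p("dec_W1", (dz, d))
            self._zeros("dec_b1", (d,))
            self._p("dec_W2", (d, C))
            self._zeros("dec_b2", (C,))
            self._build_flows(dz)
            return

        self._p("embed_W", (d_in, d))
        self._zeros("embed_b", (d,))
        if self.use_deterministic:
            self._build_encoder("det", d)
        if self.use_latent:
            self._build_encoder("lat", d)
            self._p("mu_W", (d, dz))
            self._zeros("mu_b", (dz,))
            self._p("logsig_W", (d, dz), scale=1e-2)
            self._zeros("logsig_b", (dz,))

        dec_in = (d if self.use_deterministic else 0) + (dz if self.use_latent else 0)
        self._p("dec_W1", (dec_in, d))
        self._zeros("dec_b1", (d,))
        self._p("dec_W2", (d, C))
        self._zeros("dec_b2", (C,))
        if self.use_latent:
            self._build_flows(dz)

    def _build_encoder(self, tag: str, d: int) -> None:
        for layer in range(self.cfg.n_encoder_layers):
            pre = f"{tag}{layer}"
            if self.use_transformer:
                for nm in ("Wq", "Wk", "Wv", "Wo"):
                    self._p(f"{pre}_{nm}", (d, d))
                self._ones(f"{pre}_ln1_g", (d,)); self._zeros(f"{pre}_ln1_b", (d,))
                self._p(f"{pre}_ff_W1", (d, 2 * d)); self._zeros(f"{pre}_ff_b1", (2 * d,))
                self._p(f"{pre}_ff_W2", (2 * d, d)); self._zeros(f"{pre}_ff_b2", (d,))
                self._ones(f"{pre}_ln2_g", (d,)); self._zeros(f"{pre}_ln2_b", (d,))
            else:
                # per-point feed-forward block (the "without transformer" ablations)
                self._p(f"{pre}_ff_W1", (d, 2 * d)); self._zeros(f"{pre}_ff_b1", (2 * d,))
                self._p(f"{pre}_ff_W2", (2 * d, d)); self._zeros(f"{pre}_ff_b2", (d,))

    def _build_flows(self, dz: int) -> None:
        self.flow_steps: List[FlowStep] = []
        for s in range(self.n_flow_steps):
            u = self._p(f"flow{s}_u", (dz,), scale=0.1)
            w = self._p(f"flow{s}_w", (dz,), scale=0.1)
            b = self._zeros(f"flow{s}_b", ())
            self.flow_steps.append(FlowStep(u=u, w=w, b=b))
        self.chain = FlowChain(steps=self.flow_steps, dim=dz)

    def parameters(self) -> List[Tensor]:
        return list(self.params.values())

    def constrained_chain(self) -> FlowChain:
        """The flow chain with the invertibility reparameterization applied
        to the raw learned directions (differentiable)."""
        return FlowChain(steps=[constrain_step(s) for s in self.flow_steps],
                         dim=self.chain.dim)

    # -- layers ----------------------------------------------------------
    def _layernorm(self, x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        c = x - m
        var = (c * c).mean(axis=-1, keepdims=True)
        return c / ((var + 1e-6) ** 0.5) * g + b

    def _attention(self, x: Tensor, pre: str) -> Tensor:
        B, k, d = x.shape
        h = self.cfg.n_heads
        dh = d // h

        def heads(t):
            return t.reshape(B, k, h, dh).transpose((0, 2, 1, 3))  # (B,h,k,dh)

        q = heads(x @ self.params[f"{pre}_Wq"])
        kk = heads(x @ self.params[f"{pre}_Wk"])
        v = heads(x @ self.params[f"{pre}_Wv"])
        scores = (q @ kk.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        att = ad.softmax(scores, axis=-1)
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(B, k, d)
        return out @ self.params[f"{pre}_Wo"]

    def _encoder(self, x: Tensor, tag: str) -> Tensor:
        for layer in range(self.cfg.n_encoder_layers):
            pre = f"{tag}{layer}"
            if self.use_transformer:
                x = self._layernorm(x + self._attention(x, pre),
                                    self.params[f"{pre}_ln1_g"], self.params[f"{pre}_ln1_b"])
                ff = ad.relu(x @ self.params[f"{pre}_ff_W1"] + self.params[f"{pre}_ff_b1"])
                ff = ff @ self.params[f"{pre}_ff_W2"] + self.params[f"{pre}_ff_b2"]
                x = self._layernorm(x + ff,
                                    self.params[f"{pre}_ln2_g"], self.params[f"{pre}_ln2_b"])
            else:
                ff = ad.relu(x @ self.params[f"{pre}_ff_W1"] + self.params[f"{pre}_ff_b1"])
                x = x + (ff @ self.params[f"{pre}_ff_W2"] + self.params[f"{pre}_ff_b2"])
        return x

    # -- model operations --------------------------------------------------
    def embed_window(self, X: np.ndarray, Y: np.ndarray,
                     positions: Optional[np.ndarray] = None,
                     add_positions: bool = True) -> Tensor:
        """Affine embedding of concatenated (features, one-hot label) pairs
        plus sinusoidal positional encoding over the visit slots.

        X: (B, k, F) standardized features; Y: (B, k) int labels.
        ``add_positions=False`` drops the positional term (the encoders then
        see the window as an unordered set).
        """
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features passed to embed_window")
        B, k, F = X.shape
        pairs = np.concatenate([X, one_hot(Y, self.cfg.n_classes)], axis=-1)
        emb = ad.tensor(pairs) @ self.params["embed_W"] + self.params["embed_b"]
        if not add_positions:
            return emb
        pos = self.posenc[:k] if positions is None else self.posenc[positions]
        return emb + pos

    def encode_deterministic(self, embedded: Tensor) -> ContextEncoding:
        """Transformer (or feed-forward) encoding, mean-aggregated over slots."""
        r = self._encoder(embedded, "det")
        return ContextEncoding(per_point=r, aggregate=r.mean(axis=1))

    def encode_latent(self, embedded: Tensor, rng: np.random.Generator) -> LatentPosterior:
        """Latent path: encode, pool, map to (mu, sigma), sample, flow."""
        s = self._encoder(embedded, "lat").mean(axis=1)
        mu = s @ self.params["mu_W"] + self.params["mu_b"]
        logsig = s @ self.params["logsig_W"] + self.params["logsig_b"]
        sigma = logsig.clip(np.log(SIGMA_MIN), np.log(SIGMA_MAX)).exp()
        eps = rng.standard_normal(mu.shape)
        z0 = mu + sigma * eps
        zK, logdet = chain_forward(z0, self.constrained_chain())
        if not isinstance(logdet, Tensor):
            logdet = ad.tensor(logdet)
        return LatentPosterior(mu=mu, sigma=sigma, z0=z0, zK=zK, total_logdet=logdet)

    def decode(self, r_d: Optional[Tensor], zK: Optional[Tensor]) -> Prediction:
        """[r_d, zK] -> 2-layer ReLU head -> class logits."""
        parts = [t for t in (r_d, zK) if t is not None]
        x = parts[0] if len(parts) == 1 else ad.concatenate(parts, axis=-1)
        h = ad.relu(x @ self.params["dec_W1"] + self.params["dec_b1"])
        return Prediction(logits=h @ self.params["dec_W2"] + self.params["dec_b2"])

    def forward(self, X: np.ndarray, Y: np.ndarray, mode: str = "eval",
                Xt: Optional[np.ndarray] = None, yt: Optional[np.ndarray] = None,
                rng: Optional[np.random.Generator] = None,
                ) -> Tuple[Prediction, Optional[LatentPosterior], Optional[LatentPosterior]]:
        """Full forward pass over a batch of windows.

        In eval mode only the k context pairs are consumed: the decoder uses
        r_d and the context posterior's zK (the target label is never read).
        In train mode a second latent pass over context + target pair yields
        q_full, whose zK feeds the decoder.
        Returns (prediction, q_context, q_full-or-None).
        """
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        rng = rng or np.random.default_rng(self.cfg.seed)

        if self.is_nf_only:
            pairs = np.concatenate([X, one_hot(Y, self.cfg.n_classes)], axis=-1).mean(axis=1)
            z0 = ad.tanh(ad.tensor(pairs) @ self.params["pool_W"] + self.params["pool_b"])
            zK, _ = chain_forward(z0, self.constrained_chain())
            return self.decode(None, zK), None, None

        emb = self.embed_window(X, Y)
        r_d = self.encode_deterministic(emb).aggregate if self.use_deterministic else None

        q_ctx = q_full = None
        z_dec = None
        if self.use_latent:
            q_ctx = self.encode_latent(emb, rng)
            z_dec = q_ctx.zK
            if mode == "train":
                if Xt is None or yt is None:
                    raise ValueError("train mode needs the target pair (Xt, yt)")
                emb_t = self.embed_window(Xt[:, None, :], np.asarray(yt)[:, None],
                                          positions=np.array([self.cfg.window_k]))
                q_full = self.encode_latent(ad.concatenate([emb, emb_t], axis=1), rng)
                z_dec = q_full.zK
        return self.decode(r_d, z_dec), q_ctx, q_full

    def loss(self, pred: Prediction, target: np.ndarray,
             q_full: Optional[LatentPosterior], q_ctx: Optional[LatentPosterior],
             rng: Optional[np.random.Generator] = None,
             ) -> Tuple[Tensor, float, float]:
        """Cross-entropy + beta * KL(q_full || q_context), batch means.

        Both posteriors ride the same global flow chain, so the flowed KL
        collapses to the KL of the Gaussian bases (shared-map invariance);
        it is computed in closed form for empty chains and by a
        reparameterized Monte-Carlo base-log-ratio otherwise.
        """
        target = np.asarray(target, dtype=np.int64)
        if target.min() < 0 or target.max() >= self.cfg.n_classes:
            raise ValueError("target label out of range")
        logp = pred.logits - ad.logsumexp(pred.logits, axis=-1, keepdims=True)
        ce = -(logp[np.arange(target.size), target].mean())

        if q_full is None or q_ctx is None:
            total = ce
            return total, float(ce.data), 0.0
        kl = self._kl(q_full, q_ctx, rng or np.random.default_rng(self.cfg.seed))
        total = ce + self.cfg.beta * kl
        return total, float(ce.data), float(kl.data)

    def _kl(self, qf: LatentPosterior, qc: LatentPosterior,
            rng: np.random.Generator) -> Tensor:
        """Row-wise KL between the flowed posteriors, averaged over the batch.

        Both posteriors ride the single global chain, so the flowed KL
        equals the KL of the Gaussian bases exactly (the change-of-variables
        log-det corrections cancel pointwise at the shared base sample);
        the closed form is the zero-variance estimator of that quantity.
        """
        r = qf.sigma / qc.sigma
        dm = (qf.mu - qc.mu) / qc.sigma
        per_row = 0.5 * ((r * r + dm * dm - 1.0).sum(axis=-1)) - (r.log()).sum(axis=-1)
        return per_row.mean()


def build_variant(name: str, cfg: ModelConfig) -> SNPNF:
    """Construct one of the seven ablation variants on a shared config."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    return SNPNF(replace(cfg, variant=name))


# -- training ---------------------------------------------------------------

def _batch_arrays(windows: Sequence[WindowSample]):
    X = np.stack([w.context_features for w in windows])
    Y = np.stack([w.context_labels for w in windows])
    y = np.array([w.target_label for w in windows], dtype=np.int64)
    Xt = np.stack([w.target_features for w in windows])
    return X, Y, y, Xt


@dataclass
class TrainHistory:
    epochs: List[Dict[str, float]] = field(default_factory=list)

    @property
    def total(self) -> List[float]:
        return [e["total"] for e in self.epochs]


def fit(model: SNPNF, windows: Sequence[WindowSample], verbose: bool = False,
        log_fn=None) -> TrainHistory:
    """Train with Adam on shuffled minibatches; deterministic given cfg.seed."""
    cfg = model.cfg
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7919]))
    windows = list(windows)
    if not windows:
        raise ValueError("no training windows: every patient has fewer than "
                         f"{cfg.window_k + 1} visits (window {cfg.window_k} + target)")
    hist = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(windows))
        ce_sum = kl_sum = tot_sum = 0.0
        n_batches = 0
        for start in range(0, len(windows), cfg.batch_size):
            batch = [windows[i] for i in order[start:start + cfg.batch_size]]
            X, Y, y, Xt = _batch_arrays(batch)
            pred, q_ctx, q_full = model.forward(X, Y, mode="train", Xt=Xt, yt=y, rng=rng)
            total, ce, kl = model.loss(pred, y, q_full, q_ctx, rng=rng)
            opt.zero_grad()
            total.backward()
            opt.step()
            ce_sum += ce; kl_sum += kl; tot_sum += float(total.data)
            n_batches += 1
        rec = {"epoch": epoch + 1, "ce": ce_sum / n_batches,
               "kl": kl_sum / n_batches, "total": tot_sum / n_batches}
        hist.epochs.append(rec)
        if log_fn is not None:
            log_fn(rec)
        elif verbose:
            print(f"epoch {rec['epoch']:3d}  ce {rec['ce']:.4f}  "
                  f"kl {rec['kl']:.4f}  total {rec['total']:.4f}")
    return hist


def predict_proba(model: SNPNF, windows: Sequence[WindowSample],
                  seed: int = 0, batch_size: int = 256,
                  n_latent_samples: int = 8) -> np.ndarray:
    """Eval-mode class probabilities for each window (labels never read).

    The predictive distribution integrates over the latent posterior;
    probabilities are averaged over ``n_latent_samples`` flowed latent
    draws (a single pass for purely deterministic variants).
    """
    if not (model.use_latent or model.is_nf_only):
        n_latent_samples = 1
    out = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    for start in range(0, len(windows), batch_size):
        batch = windows[start:start + batch_size]
        X = np.stack([w.context_features for w in batch])
        Y = np.stack([w.context_labels for w in batch])
        acc = None
        for _ in range(n_latent_samples):
            pred, _, _ = model.forward(X, Y, mode="eval", rng=rng)
            acc = pred.probs if acc is None else acc + pred.probs
        out.append(acc / n_latent_samples)
    return np.concatenate(out, axis=0)


# -- checkpoint serialization ----------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model: SNPNF, path, extra: Optional[dict] = None) -> None:
    """Single-file checkpoint: versioned JSON header (with the resolved
    config echoed, plus any JSON-serializable ``extra`` metadata such as
    split membership and standardizer statistics) + parameter arrays."""
    header = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(model.cfg),
                         "extra": extra or {}})
    arrays = {f"param/{k}": v.data for k, v in model.params.items()}
    np.savez(path, __header__=np.array(header), **arrays)


def load_checkpoint(path) -> Tuple[SNPNF, dict]:
    """Load a checkpoint; returns (model, extra-metadata dict)."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        if header["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header['version']}")
        cfg = ModelConfig(**header["config"])
        model = SNPNF(cfg)
        for k, t in model.params.items():
            t.data = z[f"param/{k}"].copy()
    return model, header.get("extra", {})
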