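"""Sector-split vision transformer for multimodal 1-D inputs.

A flat input vector is split into named *sectors* (demographics, surgical
variables, a flattened CT crop, ...).  Each sector is patchified, prefixed
with a learned class token, run through its own pre-norm transformer encoder
and MLP classification head, and emits a class-probability vector.  The
model's output is the elementwise mean of the sector probabilities
("voting").  A sector of length 0 carries only its class token and lets the
model encode a label prior.

Everything is NumPy; gradients are computed analytically (see
:func:`VvitModel.loss_and_grads`) so the model trains without a deep-learning
framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn

PROB_EPS = 1e-7  # clamp for log-loss, shared with evaluation


@dataclass(frozen=True)
class SectorSpec:
    """One input modality: a name and the number of scalars it contributes."""

    name: str
    length: int

    def __post_init__(self):
        if self.length < 0:
            raise ValueError(f"sector {self.name!r}: negative length")


@dataclass
class VvitConfig:
    """Architecture hyperparameters.

    Defaults: patch dimension 32, head dimension 64, 2 heads, MLP dimension
    64, depth 8; the classification head has 4 hidden layers.  The model
    width (embed_dim) is decoupled from the attention head width.
    """

    patch_dim: int = 32
    head_dim: int = 64
    n_heads: int = 2
    mlp_dim: int = 64
    depth: int = 8
    embed_dim: int = 64
    head_hidden_layers: int = 4
    n_classes: int = 2
    use_pos_embed: bool = True

    def __post_init__(self):
        for name in ("patch_dim", "head_dim", "n_heads", "mlp_dim", "depth",
                     "embed_dim", "head_hidden_layers", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"VvitConfig.{name} must be positive")


@dataclass
class ProbabilityTensor:
    """Per-sector class probabilities plus their voted (mean) aggregate."""

    per_sector: Dict[str, np.ndarray]
    voted: np.ndarray


def split_sequence(flat, sector_specs: Sequence[SectorSpec]):
    """Split a flat input (1-D, or 2-D batched along axis 0) by sector lengths.

    Contiguous and order preserving: concatenating the outputs along the last
    axis reproduces the input exactly.
    """
    flat = np.asarray(flat)
    total = sum(s.length for s in sector_specs)
    if flat.shape[-1] != total:
        raise ValueError(
            f"input length {flat.shape[-1]} != sum of sector lengths {total} "
            f"(sectors: {[(s.name, s.length) for s in sector_specs]})"
        )
    out = {}
    offset = 0
    for s in sector_specs:
        out[s.name] = flat[..., offset:offset + s.length]
        offset += s.length
    return out


def n_patches(length: int, patch_dim: int) -> int:
    """Number of patches a sector of given length produces (0 for length 0)."""
    return -(-length // patch_dim) if length > 0 else 0


def patchify(x, patch_dim: int):
    """Zero-pad a batch (B, a) to a multiple of patch_dim and reshape to
    (B, n_patches, patch_dim).  Length-0 input yields (B, 0, patch_dim)."""
    x = np.atleast_2d(np.asarray(x))
    B, a = x.shape
    npatch = n_patches(a, patch_dim)
    if npatch == 0:
        return np.zeros((B, 0, patch_dim), dtype=x.dtype)
    pad = npatch * patch_dim - a
    if pad:
        x = np.concatenate([x, np.zeros((B, pad), dtype=x.dtype)], axis=1)
    return x.reshape(B, npatch, patch_dim)


def vote(per_sector_probs) -> np.ndarray:
    """Elementwise arithmetic mean of the sector probability vectors."""
    if isinstance(per_sector_probs, dict):
        per_sector_probs = list(per_sector_probs.values())
    if len(per_sector_probs) == 0:
        raise ValueError("vote() needs at least one sector")
    return np.mean(np.stack(per_sector_probs, axis=0), axis=0)


def predict_binary(probs: np.ndarray) -> np.ndarray:
    """Argmax with ties broken toward the positive (decline) class."""
    probs = np.atleast_2d(probs)
    return (probs[..., 1] >= probs[..., 0]).astype(np.int64)


# ---------------------------------------------------------------------------
# functional encoder (used by the model and directly testable)
# ---------------------------------------------------------------------------

def encoder_forward(tokens, params, prefix, config, with_cache=False):
    """Pre-norm transformer encoder.

    depth x [x <- x + MSA(LN(x)); x <- x + MLP(LN(x))], then a final layer
    norm.  The MLP is two layers with GELU.  ``params`` is a flat dict and
    ``prefix`` selects this encoder's parameters.
    """
    x = tokens
    if x.shape[1] == 0:
        raise ValueError("encoder_forward: empty token sequence")
    caches = []
    for i in range(config.depth):
        p = f"{prefix}blocks.{i}."
        h, c_ln1 = nn.layernorm_fwd(x, params[p + "ln1.g"], params[p + "ln1.b"])
        a, c_att = nn.attention_fwd(
            h,
            params[p + "Wq"], params[p + "bq"],
            params[p + "Wk"], params[p + "bk"],
            params[p + "Wv"], params[p + "bv"],
            params[p + "Wo"], params[p + "bo"],
            config.n_heads, config.head_dim,
        )
        x1 = x + a
        h2, c_ln2 = nn.layernorm_fwd(x1, params[p + "ln2.g"], params[p + "ln2.b"])
        u, c_fc1 = nn.linear_fwd(h2, params[p + "W1"], params[p + "b1"])
        g, c_gelu = nn.gelu_fwd(u)
        m, c_fc2 = nn.linear_fwd(g, params[p + "W2"], params[p + "b2"])
        x = x1 + m
        caches.append((c_ln1, c_att, c_ln2, c_fc1, c_gelu, c_fc2))
    y, c_fln = nn.layernorm_fwd(x, params[prefix + "final_ln.g"], params[prefix + "final_ln.b"])
    if np.isnan(y).any():
        raise FloatingPointError("NaN in encoder activations (training divergence)")
    if with_cache:
        return y, (caches, c_fln)
    return y


def encoder_backward(dy, cache, params, prefix, config, grads):
    caches, c_fln = cache
    dx, dg, db = nn.layernorm_bwd(dy, c_fln)
    grads[prefix + "final_ln.g"] = grads.get(prefix + "final_ln.g", 0) + dg
    grads[prefix + "final_ln.b"] = grads.get(prefix + "final_ln.b", 0) + db
    for i in reversed(range(config.depth)):
        p = f"{prefix}blocks.{i}."
        c_ln1, c_att, c_ln2, c_fc1, c_gelu, c_fc2 = caches[i]
        # MLP branch
        dm = dx
        dgelu_out, dW2, db2 = nn.linear_bwd(dm, c_fc2)
        du = nn.gelu_bwd(dgelu_out, c_gelu)
        dh2, dW1, db1 = nn.linear_bwd(du, c_fc1)
        dx1_mlp, dg2, db2n = nn.layernorm_bwd(dh2, c_ln2)
        dx1 = dx + dx1_mlp
        # attention branch
        da = dx1
        dh, att_grads = nn.attention_bwd(da, c_att)
        dx0_att, dg1, db1n = nn.layernorm_bwd(dh, c_ln1)
        dx = dx1 + dx0_att
        grads[p + "W2"] = dW2
        grads[p + "b2"] = db2
        grads[p + "W1"] = dW1
        grads[p + "b1"] = db1
        grads[p + "ln2.g"] = dg2
        grads[p + "ln2.b"] = db2n
        grads[p + "ln1.g"] = dg1
        grads[p + "ln1.b"] = db1n
        for k, v in att_grads.items():
            grads[p + k] = v
    return dx


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class VvitModel:
    """Sector-split transformer with per-sector encoders and voting."""

    def __init__(self, sectors: Sequence[SectorSpec], config: Optional[VvitConfig] = None,
                 seed: Optional[int] = 0, params: Optional[Dict[str, np.ndarray]] = None,
                 dtype=np.float32):
        names = [s.name for s in sectors]
        if len(set(names)) != len(names):
            raise ValueError("sector names must be unique")
        self.sectors = list(sectors)
        self.config = config or VvitConfig()
        self.dtype = np.dtype(dtype)
        if params is not None:
            self.params = params
        else:
            self.params = self._init_params(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng) -> Dict[str, np.ndarray]:
        cfg = self.config
        D, K, M = cfg.embed_dim, cfg.n_heads * cfg.head_dim, cfg.mlp_dim
        std = 0.02

        def norm(*shape):
            return (rng.normal(0.0, std, size=shape)).astype(self.dtype)

        params: Dict[str, np.ndarray] = {}
        for s in self.sectors:
            pre = s.name + "."
            npatch = n_patches(s.length, cfg.patch_dim)
            params[pre + "cls"] = norm(D)
            if cfg.use_pos_embed:
                params[pre + "pos"] = norm(npatch + 1, D)
            if npatch > 0:
                params[pre + "patch.W"] = norm(cfg.patch_dim, D)
                params[pre + "patch.b"] = np.zeros(D, dtype=self.dtype)
            for i in range(cfg.depth):
                p = f"{pre}blocks.{i}."
                params[p + "Wq"] = norm(D, K)
                params[p + "bq"] = np.zeros(K, dtype=self.dtype)
                params[p + "Wk"] = norm(D, K)
                params[p + "bk"] = np.zeros(K, dtype=self.dtype)
                params[p + "Wv"] = norm(D, K)
                params[p + "bv"] = np.zeros(K, dtype=self.dtype)
                params[p + "Wo"] = norm(K, D)
                params[p + "bo"] = np.zeros(D, dtype=self.dtype)
                params[p + "ln1.g"] = np.ones(D, dtype=self.dtype)
                params[p + "ln1.b"] = np.zeros(D, dtype=self.dtype)
                params[p + "ln2.g"] = np.ones(D, dtype=self.dtype)
                params[p + "ln2.b"] = np.zeros(D, dtype=self.dtype)
                params[p + "W1"] = norm(D, M)
                params[p + "b1"] = np.zeros(M, dtype=self.dtype)
                params[p + "W2"] = norm(M, D)
                params[p + "b2"] = np.zeros(D, dtype=self.dtype)
            params[pre + "final_ln.g"] = np.ones(D, dtype=self.dtype)
            params[pre + "final_ln.b"] = np.zeros(D, dtype=self.dtype)
            dims = [D] + [M] * cfg.head_hidden_layers
            for j in range(cfg.head_hidden_layers):
                params[f"{pre}head.{j}.W"] = norm(dims[j], dims[j + 1])
                params[f"{pre}head.{j}.b"] = np.zeros(dims[j + 1], dtype=self.dtype)
            params[pre + "head.out.W"] = norm(dims[-1], cfg.n_classes)
            params[pre + "head.out.b"] = np.zeros(cfg.n_classes, dtype=self.dtype)
        return params

    # -- forward ------------------------------------------------------------

    def _sector_tokens(self, name: str, x):
        cfg = self.config
        x = np.atleast_2d(np.asarray(x, dtype=self.dtype))
        B = x.shape[0]
        patches = patchify(x, cfg.patch_dim)
        pre = name + "."
        if patches.shape[1] > 0:
            tok = patches @ self.params[pre + "patch.W"] + self.params[pre + "patch.b"]
        else:
            tok = np.zeros((B, 0, cfg.embed_dim), dtype=self.dtype)
        cls = np.broadcast_to(self.params[pre + "cls"], (B, 1, cfg.embed_dim))
        tokens = np.concatenate([cls, tok], axis=1)
        if cfg.use_pos_embed:
            tokens = tokens + self.params[pre + "pos"]
        return tokens, patches

    def _sector_forward(self, name: str, x, with_cache=False, dropout=0.0,
                        dropout_rng=None):
        """One sector's forward pass.

        Inverted dropout (training only, when ``dropout`` > 0) is applied to
        the token embeddings and after each GELU in the classification head;
        inference never drops units.
        """
        cfg = self.config
        tokens, patches = self._sector_tokens(name, x)
        pre = name + "."
        keep = 1.0 - dropout
        tok_mask = None
        if dropout > 0.0:
            tok_mask = (dropout_rng.random(tokens.shape) < keep).astype(self.dtype) / keep
            tokens = tokens * tok_mask
        if with_cache:
            enc, enc_cache = encoder_forward(tokens, self.params, pre, cfg, with_cache=True)
        else:
            enc = encoder_forward(tokens, self.params, pre, cfg)
            enc_cache = None
        h = enc[:, 0, :]  # class-token output feeds the head
        head_caches = []
        for j in range(cfg.head_hidden_layers):
            h, c_lin = nn.linear_fwd(h, self.params[f"{pre}head.{j}.W"],
                                     self.params[f"{pre}head.{j}.b"])
            h, c_g = nn.gelu_fwd(h)
            if dropout > 0.0:
                m = (dropout_rng.random(h.shape) < keep).astype(self.dtype) / keep
                h = h * m
            else:
                m = None
            head_caches.append((c_lin, c_g, m))
        logits, c_out = nn.linear_fwd(h, self.params[pre + "head.out.W"],
                                      self.params[pre + "head.out.b"])
        probs = nn.softmax(logits, axis=-1)
        cache = (patches, enc_cache, head_caches, c_out, enc.shape, tok_mask) \
            if with_cache else None
        return probs, logits, cache

    def forward(self, batch: Dict[str, np.ndarray]) -> ProbabilityTensor:
        """Run every sector and vote.  ``batch`` maps sector name -> (B, a_n)."""
        per_sector, per_logits, _ = self._forward_all(batch, with_cache=False)
        return ProbabilityTensor(per_sector=per_sector, voted=vote(per_sector))

    def _forward_all(self, batch, with_cache, dropout=0.0, dropout_rng=None):
        per_sector, per_logits, caches = {}, {}, {}
        for s in self.sectors:
            if s.name not in batch:
                raise KeyError(f"batch missing sector {s.name!r}")
            x = np.atleast_2d(np.asarray(batch[s.name]))
            if x.shape[1] != s.length:
                raise ValueError(
                    f"sector {s.name!r}: expected length {s.length}, got {x.shape[1]}")
            probs, logits, cache = self._sector_forward(
                s.name, x, with_cache=with_cache, dropout=dropout,
                dropout_rng=dropout_rng)
            per_sector[s.name] = probs
            per_logits[s.name] = logits
            caches[s.name] = cache
        return per_sector, per_logits, caches

    # -- loss and gradients --------------------------------------------------

    def loss_and_grads(self, batch, y, loss_mode: str = "voted", dropout: float = 0.0,
                       dropout_rng=None):
        """Binary cross-entropy and analytic parameter gradients.

        loss_mode "voted": BCE attaches to the voted positive probability;
        "per_sector_sum": sum of per-sector BCE terms.  ``dropout`` enables
        inverted dropout during this training pass (requires ``dropout_rng``).
        Returns (loss, grads, ProbabilityTensor).
        """
        if dropout > 0.0 and dropout_rng is None:
            raise ValueError("dropout requires a dropout_rng")
        y = np.asarray(y, dtype=self.dtype).reshape(-1)
        per_sector, per_logits, caches = self._forward_all(
            batch, with_cache=True, dropout=dropout, dropout_rng=dropout_rng)
        names = [s.name for s in self.sectors]
        S = len(names)
        B = y.shape[0]
        voted = vote(per_sector)
        dlogits = {}
        if loss_mode == "voted":
            vp = np.clip(voted[:, 1], PROB_EPS, 1.0 - PROB_EPS)
            loss = float(np.mean(-(y * np.log(vp) + (1 - y) * np.log(1 - vp))))
            inside = (voted[:, 1] > PROB_EPS) & (voted[:, 1] < 1.0 - PROB_EPS)
            dvp = np.where(inside, (vp - y) / (vp * (1.0 - vp)), 0.0) / B
            for name in names:
                p1 = per_sector[name][:, 1]
                p0 = per_sector[name][:, 0]
                dz1 = dvp * (1.0 / S) * p0 * p1
                dlogits[name] = np.stack([-dz1, dz1], axis=1).astype(self.dtype)
        elif loss_mode == "per_sector_sum":
            loss = 0.0
            for name in names:
                p1 = np.clip(per_sector[name][:, 1], PROB_EPS, 1.0 - PROB_EPS)
                loss += float(np.mean(-(y * np.log(p1) + (1 - y) * np.log(1 - p1))))
                # d BCE / d logits for softmax over 2 classes
                dz1 = (p1 - y) / B
                dlogits[name] = np.stack([-dz1, dz1], axis=1).astype(self.dtype)
        else:
            raise ValueError(f"unknown loss_mode {loss_mode!r}")
        grads: Dict[str, np.ndarray] = {}
        for name in names:
            self._sector_backward(name, dlogits[name], caches[name], grads)
        return loss, grads, ProbabilityTensor(per_sector=per_sector, voted=voted)

    def _sector_backward(self, name, dlogits, cache, grads):
        cfg = self.config
        pre = name + "."
        patches, enc_cache, head_caches, c_out, enc_shape, tok_mask = cache
        dh, dW, db = nn.linear_bwd(dlogits, c_out)
        grads[pre + "head.out.W"] = dW
        grads[pre + "head.out.b"] = db
        for j in reversed(range(cfg.head_hidden_layers)):
            c_lin, c_g, m = head_caches[j]
            if m is not None:
                dh = dh * m
            dh = nn.gelu_bwd(dh, c_g)
            dh, dW, db = nn.linear_bwd(dh, c_lin)
            grads[f"{pre}head.{j}.W"] = dW
            grads[f"{pre}head.{j}.b"] = db
        denc = np.zeros(enc_shape, dtype=self.dtype)
        denc[:, 0, :] = dh
        dtokens = encoder_backward(denc, enc_cache, self.params, pre, cfg, grads)
        if tok_mask is not None:
            dtokens = dtokens * tok_mask
        if cfg.use_pos_embed:
            grads[pre + "pos"] = dtokens.sum(axis=0)
        grads[pre + "cls"] = dtokens[:, 0, :].sum(axis=0)
        if patches.shape[1] > 0:
            dtok = dtokens[:, 1:, :]
            B, npatch, _ = patches.shape
            p2 = patches.reshape(B * npatch, -1)
            d2 = dtok.reshape(B * npatch, -1)
            grads[pre + "patch.W"] = p2.T @ d2
            grads[pre + "patch.b"] = d2.sum(axis=0)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        """Single-file checkpoint: config + sector layout JSON and parameters."""
        meta = {
            "config": asdict(self.config),
            "sectors": [(s.name, s.length) for s in self.sectors],
            "dtype": self.dtype.name,
        }
        arrays = {k.replace(".", "__"): v for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "VvitModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k.replace("__", "."): z[k] for k in z.files if k != "__meta__"}
        sectors = [SectorSpec(n, a) for n, a in meta["sectors"]]
        cfg = VvitConfig(**meta["config"])
        return cls(sectors, cfg, params=params, dtype=np.dtype(meta["dtype"]))

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}
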