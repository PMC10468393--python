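"""Gated-recurrent phoneme decoder trained with CTC, in pure NumPy.

Architecture: a day-specific affine input layer (one per recording day,
absorbing across-day changes such as channel relabelings and offsets)
feeding a shared stack of GRU layers and a softmax over 41 tokens
(39 phonemes + SIL + blank).  One decoder step spans 80 ms (four stacked
20 ms bins).  Training minimizes the CTC negative log-likelihood with Adam,
cosine learning-rate decay and gradient clipping; all randomness is seeded.

Backpropagation through time and the input-gradient needed for saliency
extraction are implemented directly; there is no autodiff framework behind
this module.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ctc import ctc_loss_and_grad, greedy_decode, log_softmax
from .metrics import batch_per

logger = logging.getLogger(__name__)


@dataclass
class DecoderConfig:
    n_layers: int = 2
    hidden: int = 96
    input_dim: int = 512          # 2 * electrodes * stack (k=4)
    n_days: int = 1
    n_tokens: int = 41
    dropout: float = 0.0          # input dropout during training
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden <= 0 or self.input_dim <= 0:
            raise ValueError("invalid decoder dimensions")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "DecoderConfig":
        return cls(**json.loads(s))


def paper_scale_config(input_dim: int, n_days: int) -> DecoderConfig:
    """The full-scale preset (five GRU layers); not used by the test suite."""
    return DecoderConfig(n_layers=5, hidden=512, input_dim=input_dim,
                         n_days=n_days)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 4e-3
    final_lr_frac: float = 0.1    # cosine decay floor
    clip: float = 5.0
    weight_decay: float = 0.0
    seed: int = 0
    eval_every: int = 1
    log: bool = False


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class GRUDecoder:
    """Day-input-layer + GRU stack + softmax readout."""

    def __init__(self, config: DecoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, L, C = config.input_dim, config.hidden, config.n_layers, config.n_tokens
        p: Dict[str, np.ndarray] = {}
        # day-specific affine input transforms, initialized at identity
        for d in range(config.n_days):
            p[f"day_A{d}"] = np.eye(D)
            p[f"day_b{d}"] = np.zeros(D)
        for l in range(L):
            din = D if l == 0 else H
            sc_x = 1.0 / np.sqrt(din)
            sc_h = 1.0 / np.sqrt(H)
            for g in ("z", "r", "h"):
                p[f"W{g}{l}"] = rng.normal(0, sc_x, (din, H))
                p[f"U{g}{l}"] = rng.normal(0, sc_h, (H, H))
                p[f"b{g}{l}"] = np.zeros(H)
            p[f"bz{l}"][:] = -1.0   # update-gate bias: favor carrying state
        p["Wo"] = rng.normal(0, 1.0 / np.sqrt(H), (H, C))
        p["bo"] = np.zeros(C)
        self.params = p

    # ------------------------------------------------------------------ forward
    def forward(self, x: np.ndarray, day: int, cache: bool = False):
        """x: (B, T, input_dim) -> logits (B, T, n_tokens).

        With ``cache=True`` also returns the activation cache for backprop.
        """
        cfg = self.config
        if not (0 <= day < cfg.n_days):
            raise ValueError(
                f"unknown day index {day}; decoder has layers for days "
                f"0..{cfg.n_days - 1}")
        p = self.params
        B, T, D = x.shape
        xin = x @ p[f"day_A{day}"] + p[f"day_b{day}"]
        caches = {"x": x, "xin": xin, "day": day, "layers": []}
        inp = xin
        for l in range(cfg.n_layers):
            Wz, Wr, Wh = p[f"Wz{l}"], p[f"Wr{l}"], p[f"Wh{l}"]
            Uz, Ur, Uh = p[f"Uz{l}"], p[f"Ur{l}"], p[f"Uh{l}"]
            bz, br, bh = p[f"bz{l}"], p[f"br{l}"], p[f"bh{l}"]
            H = cfg.hidden
            h = np.zeros((B, H))
            hs = np.empty((T, B, H))
            zs = np.empty((T, B, H))
            rs = np.empty((T, B, H))
            cs = np.empty((T, B, H))
            hprev = np.empty((T, B, H))
            # precompute input projections for all steps at once
            xz = inp @ Wz + bz
            xr = inp @ Wr + br
            xh = inp @ Wh + bh
            for t in range(T):
                hprev[t] = h
                z = _sigmoid(xz[:, t] + h @ Uz)
                r = _sigmoid(xr[:, t] + h @ Ur)
                c = np.tanh(xh[:, t] + (r * h) @ Uh)
                h = (1 - z) * h + z * c
                zs[t], rs[t], cs[t], hs[t] = z, r, c, h
            caches["layers"].append(
                {"inp": inp, "z": zs, "r": rs, "c": cs, "h": hs, "hprev": hprev})
            inp = hs.transpose(1, 0, 2)
        logits = inp @ p["Wo"] + p["bo"]
        caches["top"] = inp
        return (logits, caches) if cache else logits

    def posteriorgram(self, x: np.ndarray, day: int) -> np.ndarray:
        """(T, input_dim) single trial -> (T, n_tokens) probabilities."""
        logits = self.forward(x[None], day)
        return np.exp(log_softmax(logits[0]))

    # ----------------------------------------------------------------- backward
    def backward(self, caches, dlogits: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(logits).

        Returns (grads dict matching params, dx w.r.t. the raw input).
        """
        cfg = self.config
        p = self.params
        B, T, _ = dlogits.shape
        g = {k: np.zeros_like(v) for k, v in p.items()}
        top = caches["top"]
        g["Wo"] = top.reshape(-1, cfg.hidden).T @ dlogits.reshape(-1, cfg.n_tokens)
        g["bo"] = dlogits.sum(axis=(0, 1))
        dinp = dlogits @ p["Wo"].T  # (B, T, H) grad into top layer outputs

        for l in range(cfg.n_layers - 1, -1, -1):
            cache = caches["layers"][l]
            inp = cache["inp"]
            zs, rs, cs, hprev = cache["z"], cache["r"], cache["c"], cache["hprev"]
            Uz, Ur, Uh = p[f"Uz{l}"], p[f"Ur{l}"], p[f"Uh{l}"]
            Wz, Wr, Wh = p[f"Wz{l}"], p[f"Wr{l}"], p[f"Wh{l}"]
            H = cfg.hidden
            dh_next = np.zeros((B, H))
            daz = np.empty((T, B, H))
            dar = np.empty((T, B, H))
            dah = np.empty((T, B, H))
            for t in range(T - 1, -1, -1):
                dh = dinp[:, t] + dh_next
                z, r, c, hp = zs[t], rs[t], cs[t], hprev[t]
                dz = dh * (c - hp)
                dc = dh * z
                dhp = dh * (1 - z)
                da_h = dc * (1 - c * c)
                drh = da_h @ Uh.T
                dr = drh * hp
                dhp = dhp + drh * r
                da_z = dz * z * (1 - z)
                da_r = dr * r * (1 - r)
                dhp = dhp + da_z @ Uz.T + da_r @ Ur.T
                daz[t], dar[t], dah[t] = da_z, da_r, da_h
                dh_next = dhp
            # accumulate parameter grads over time in bulk
            inp_f = inp.reshape(B * T, -1)
            hp_f = hprev.transpose(1, 0, 2).reshape(B * T, H)
            rhp_f = (rs * hprev).transpose(1, 0, 2).reshape(B * T, H)
            daz_f = daz.transpose(1, 0, 2).reshape(B * T, H)
            dar_f = dar.transpose(1, 0, 2).reshape(B * T, H)
            dah_f = dah.transpose(1, 0, 2).reshape(B * T, H)
            g[f"Wz{l}"] = inp_f.T @ daz_f
            g[f"Wr{l}"] = inp_f.T @ dar_f
            g[f"Wh{l}"] = inp_f.T @ dah_f
            g[f"Uz{l}"] = hp_f.T @ daz_f
            g[f"Ur{l}"] = hp_f.T @ dar_f
            g[f"Uh{l}"] = rhp_f.T @ dah_f
            g[f"bz{l}"] = daz_f.sum(axis=0)
            g[f"br{l}"] = dar_f.sum(axis=0)
            g[f"bh{l}"] = dah_f.sum(axis=0)
            dinp = (daz_f @ Wz.T + dar_f @ Wr.T + dah_f @ Wh.T).reshape(B, T, -1)

        day = caches["day"]
        x = caches["x"]
        D = x.shape[2]
        g[f"day_A{day}"] = x.reshape(-1, D).T @ dinp.reshape(-1, D)
        g[f"day_b{day}"] = dinp.sum(axis=(0, 1))
        dx = dinp @ p[f"day_A{day}"].T
        return g, dx

    def input_gradient(self, x: np.ndarray, day: int,
                       dlogits: np.ndarray) -> np.ndarray:
        """d(scalar)/dx for a single trial, given d(scalar)/d(logits)."""
        _, caches = self.forward(x[None], day, cache=True)
        _, dx = self.backward(caches, dlogits[None])
        return dx[0]

    # ------------------------------------------------------------ serialization
    def save(self, path) -> None:
        np.savez(path, __config__=np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "GRUDecoder":
        with np.load(path) as z:
            cfg = DecoderConfig.from_json(bytes(z["__config__"]).decode())
            dec = cls(cfg)
            for k in dec.params:
                dec.params[k] = z[k]
        return dec

    def clone_day_layer(self, src_day: int, dst_day: int) -> None:
        """Initialize a new day's input layer from an existing day's."""
        self.params[f"day_A{dst_day}"] = self.params[f"day_A{src_day}"].copy()
        self.params[f"day_b{dst_day}"] = self.params[f"day_b{src_day}"].copy()


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    valid_per: List[float] = field(default_factory=list)
    epochs: int = 0


def _pad_batch(xs: List[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    T = max(x.shape[0] for x in xs)
    out = np.zeros((len(xs), T, xs[0].shape[1]))
    lens = np.empty(len(xs), dtype=int)
    for i, x in enumerate(xs):
        out[i, : x.shape[0]] = x
        lens[i] = x.shape[0]
    return out, lens


def train_decoder(
    decoder: GRUDecoder,
    train_inputs: Sequence[np.ndarray],
    train_targets: Sequence[Sequence[int]],
    train_days: Sequence[int],
    config: TrainConfig,
    blank: int,
    valid: Optional[Tuple[Sequence[np.ndarray], Sequence[Sequence[int]],
                          Sequence[int]]] = None,
) -> TrainHistory:
    """CTC training with Adam; batches are grouped by day (balanced sampling).

    ``valid`` is (inputs, targets, days); held-out greedy PER is recorded
    every ``eval_every`` epochs.  Trials whose target cannot fit the frame
    count are skipped with a logged warning.
    """
    rng = np.random.default_rng(config.seed)
    p = decoder.params
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(v_) for k, v_ in p.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    hist = TrainHistory()
    days = np.asarray(train_days)
    by_day = {d: np.flatnonzero(days == d) for d in np.unique(days)}
    warned: set = set()
    n_batches = max(1, len(train_inputs) // config.batch_size)
    total_steps = config.epochs * n_batches

    for epoch in range(config.epochs):
        # balanced day-pure batches, order shuffled
        batches: List[Tuple[int, np.ndarray]] = []
        for d, idx in by_day.items():
            idx = rng.permutation(idx)
            for s in range(0, len(idx), config.batch_size):
                batches.append((int(d), idx[s: s + config.batch_size]))
        rng.shuffle(batches)

        epoch_loss, epoch_n = 0.0, 0
        for day, idx in batches:
            xs = [train_inputs[i] for i in idx]
            x, lens = _pad_batch(xs)
            drop = decoder.config.dropout
            if drop > 0:
                mask = rng.random(x.shape) >= drop
                x = x * mask / (1 - drop)
            logits, caches = decoder.forward(x, day, cache=True)
            dlogits = np.zeros_like(logits)
            batch_loss, n_ok = 0.0, 0
            for i, j in enumerate(idx):
                Ti = lens[i]
                nll, grad = ctc_loss_and_grad(logits[i, :Ti], train_targets[j],
                                              blank)
                if not np.isfinite(nll):
                    if j not in warned:
                        logger.warning("skipping trial %d: target longer "
                                       "than %d decoder steps", j, Ti)
                        warned.add(j)
                    continue
                dlogits[i, :Ti] = grad
                batch_loss += nll
                n_ok += 1
            if n_ok == 0:
                continue
            dlogits /= n_ok
            grads, _ = decoder.backward(caches, dlogits)
            # cosine learning-rate decay with gradient clipping
            frac = step / max(1, total_steps)
            lr = config.lr * (config.final_lr_frac + (1 - config.final_lr_frac)
                              * 0.5 * (1 + np.cos(np.pi * frac)))
            gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            scale = min(1.0, config.clip / (gnorm + 1e-12))
            step += 1
            for k in p:
                g = grads[k] * scale
                if config.weight_decay > 0 and not k.startswith(("b", "day_b")):
                    g = g + config.weight_decay * p[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += batch_loss
            epoch_n += n_ok

        hist.train_loss.append(epoch_loss / max(1, epoch_n))
        if valid is not None and (epoch + 1) % config.eval_every == 0:
            hist.valid_per.append(
                evaluate_per(decoder, valid[0], valid[1], valid[2], blank))
        else:
            hist.valid_per.append(np.nan)
        hist.epochs = epoch + 1
        if config.log:
            print(f"epoch {epoch + 1}/{config.epochs} "
                  f"loss {hist.train_loss[-1]:.3f} "
                  f"valid PER {hist.valid_per[-1]:.3f}", file=sys.stderr)
    return hist


def evaluate_per(decoder: GRUDecoder, inputs, targets, days, blank: int) -> float:
    """Aggregate greedy-decoding PER over a set of trials."""
    hyps = [greedy_decode(decoder.posteriorgram(x, d), blank)
            for x, d in zip(inputs, days)]
    return batch_per(hyps, [list(t) for t in targets])
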