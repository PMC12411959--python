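"""Per-segment-type autoencoders producing bounded waveform embeddings.

Each segment type (P, QRS, T) gets its own small fully connected
autoencoder. Segments are linearly resampled to a fixed length and
amplitude-normalized to [0, 1]; the encoder's final layer is a logistic
squashing, so every latent coordinate lies strictly in (0, 1). With the
default latent size of 16, the node feature vector
[one-hot(3) | width(1) | embedding(16) | distances(2)] has dimension 22.

Training minimizes mean squared reconstruction error with Adam on full
batches; everything is deterministic under a fixed seed. Leakage hygiene —
fitting only on training-fold segments — is the responsibility of the
cross-validation pipeline, which retrains the autoencoders per fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

DEFAULT_INPUT_LEN = 64
DEFAULT_LATENT_DIM = 16
MIN_SEGMENTS = 50


@dataclass(frozen=True)
class AEConfig:
    input_len: int = DEFAULT_INPUT_LEN
    hidden: int = 32
    latent_dim: int = DEFAULT_LATENT_DIM
    epochs: int = 120
    lr: float = 3e-3


def resample_to_fixed(samples: np.ndarray, L_in: int = DEFAULT_INPUT_LEN) -> np.ndarray:
    """Linear-interpolation resample to ``L_in`` points, min-max scaled to [0,1].

    A constant segment has no amplitude range; by convention it maps to the
    all-0.5 vector.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    grid = np.linspace(0.0, x.size - 1, L_in)
    y = np.interp(grid, np.arange(x.size), x)
    span = y.max() - y.min()
    if span < 1e-12:
        return np.full(L_in, 0.5)
    return (y - y.min()) / span


@dataclass
class AEModel:
    """Trained autoencoder for one segment type.

    ``layers`` is [enc1, enc2, dec1, dec2]; the encoder output passes
    through a sigmoid, as does the reconstruction (inputs live in [0,1]).
    """

    segment_type: str
    cfg: AEConfig
    layers: list = field(repr=False)
    seed: int = 0
    final_loss: float = float("nan")

    def encode(self, batch: np.ndarray) -> np.ndarray:
        h = nn.relu(self.layers[0].forward(batch))
        return nn.sigmoid(self.layers[1].forward(h))

    def decode(self, z: np.ndarray) -> np.ndarray:
        h = nn.relu(self.layers[2].forward(z))
        return nn.sigmoid(self.layers[3].forward(h))

    def reconstruction_mse(self, batch: np.ndarray) -> float:
        rec = self.decode(self.encode(batch))
        return float(np.mean((rec - batch) ** 2))


def _init_layers(cfg: AEConfig, rng: np.random.Generator) -> list:
    return [
        nn.Dense(cfg.input_len, cfg.hidden, rng),
        nn.Dense(cfg.hidden, cfg.latent_dim, rng),
        nn.Dense(cfg.latent_dim, cfg.hidden, rng),
        nn.Dense(cfg.hidden, cfg.input_len, rng),
    ]


def fit_autoencoder(segments: list[np.ndarray], segment_type: str,
                    cfg: AEConfig = AEConfig(), seed: int = 0) -> AEModel:
    """Fit one autoencoder on raw segments of a single type.

    Segments are resampled/normalized internally. Requires at least
    ``MIN_SEGMENTS`` examples; with fewer, generate more synthetic records
    to enlarge the fitting set.
    """
    if len(segments) < MIN_SEGMENTS:
        raise ValueError(
            f"need >= {MIN_SEGMENTS} {segment_type} segments to fit an autoencoder "
            f"(got {len(segments)}); enlarge the fitting set, e.g. with more "
            "synthetic records"
        )
    batch = np.stack([resample_to_fixed(s, cfg.input_len) for s in segments])
    rng = np.random.default_rng(seed)
    layers = _init_layers(cfg, rng)
    opt = nn.Adam(layers, lr=cfg.lr)
    loss = float("nan")
    for _ in range(cfg.epochs):
        h1 = nn.relu(layers[0].forward(batch))
        zlin = layers[1].forward(h1)
        z = nn.sigmoid(zlin)
        h2 = nn.relu(layers[2].forward(z))
        rlin = layers[3].forward(h2)
        rec = nn.sigmoid(rlin)
        diff = rec - batch
        loss = float(np.mean(diff ** 2))
        opt.zero_grad()
        g = (2.0 / diff.size) * diff * rec * (1 - rec)
        g = layers[3].backward(g)
        g = g * (h2 > 0)
        g = layers[2].backward(g)
        g = g * z * (1 - z)
        g = layers[1].backward(g)
        g = g * (h1 > 0)
        layers[0].backward(g)
        opt.step()
    return AEModel(segment_type, cfg, layers, seed=seed, final_loss=loss)


def embed(ae: AEModel, segment: np.ndarray, segment_type: str | None = None) -> np.ndarray:
    """Latent vector in (0,1)^L for one raw segment."""
    if segment_type is not None and segment_type != ae.segment_type:
        raise ValueError(
            f"segment type {segment_type!r} does not match model {ae.segment_type!r}"
        )
    x = resample_to_fixed(segment, ae.cfg.input_len)
    return ae.encode(x[None, :])[0]


def fit_segment_autoencoders(records, cfg: AEConfig = AEConfig(),
                             seed: int = 0) -> dict[str, AEModel]:
    """Fit AE_P, AE_QRS, AE_T on all segments of the given records."""
    pools: dict[str, list[np.ndarray]] = {"P": [], "QRS": [], "T": []}
    for rec in records:
        for beat in rec.beats:
            for stype, (on, off) in beat.segments.items():
                pools[stype].append(rec.samples[on:off])
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        stype: fit_autoencoder(pools[stype], stype, cfg,
                               seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        for stype, ss in zip(("P", "QRS", "T"), children)
    }


def save_ae(ae: AEModel, path: str | Path) -> Path:
    """Serialize one autoencoder to a portable JSON file."""
    payload = {
        "segment_type": ae.segment_type,
        "cfg": ae.cfg.__dict__,
        "seed": ae.seed,
        "final_loss": ae.final_loss,
        "layers": [{k: v.tolist() for k, v in ly.params.items()} for ly in ae.layers],
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_ae(path: str | Path) -> AEModel:
    payload = json.loads(Path(path).read_text())
    cfg = AEConfig(**payload["cfg"])
    rng = np.random.default_rng(0)
    layers = _init_layers(cfg, rng)
    for ly, saved in zip(layers, payload["layers"]):
        for k, v in saved.items():
            ly.params[k] = np.asarray(v, dtype=float)
    return AEModel(payload["segment_type"], cfg, layers,
                   seed=payload["seed"], final_loss=payload["final_loss"])
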