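"""The two-output shallow network and binding-core alignment.

One hidden layer is shared between two sigmoid output neurons, one per data
type (binding affinity, eluted ligand); only the input->hidden weights are
touched by both data types, so the two assays can exchange information while
keeping separate output scales. A peptide's binding core is the 9-residue
window whose encoding maximizes the output of the head matching the
instance's data type; during the single burn-in iteration the search is
restricted to cores whose P1 residue is hydrophobic.

This module is the float64 reference implementation; the training loop in
:mod:`mhc2lig.training` runs an equivalent float32 kernel for speed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .alphabet import RESIDUES
from .encoding import (
    CORE_LENGTH,
    EncodedInstance,
    EncoderConfig,
    PeptideInstance,
    encode_instance,
)

HEADS = ("BA", "EL")


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of one network."""

    hidden_units: int = 10
    seed: int = 0
    iterations: int = 400
    burn_in_iterations: int = 1
    learning_rate: float = 0.05
    #: final learning rate as a fraction of the initial one; values below 1
    #: decay the rate linearly across iterations so the online weights
    #: settle instead of hovering in SGD noise (default: constant rate)
    lr_final_fraction: float = 1.0
    initial_weight_range: float = 0.1

    def learning_rate_at(self, iteration: int) -> float:
        if self.iterations <= 1:
            return self.learning_rate
        frac = iteration / (self.iterations - 1)
        return self.learning_rate * (1.0 - (1.0 - self.lr_final_fraction) * frac)

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not self.iterations > self.burn_in_iterations >= 0:
            raise ValueError("need iterations > burn_in_iterations >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.lr_final_fraction <= 1.0:
            raise ValueError("lr_final_fraction must be in (0, 1]")


@dataclass
class CoreAlignment:
    """The selected binding core of one peptide under one network."""

    offset: int
    core: str
    per_offset_scores: np.ndarray
    burn_in_active: bool = False


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class NetworkModel:
    """One shallow network with shared hidden layer and per-data-type heads.

    Weight blocks: ``w_in`` (hidden x features), ``b_in`` (hidden),
    ``w_out_ba``/``w_out_el`` (hidden) with scalar biases.
    """

    def __init__(self, config: NetworkConfig, encoder: EncoderConfig,
                 w_in=None, b_in=None, w_out_ba=None, b_out_ba=0.0,
                 w_out_el=None, b_out_el=0.0):
        self.config = config
        self.encoder = encoder
        d = encoder.feature_dim
        h = config.hidden_units
        if w_in is None:
            rng = np.random.default_rng(config.seed)
            r = config.initial_weight_range
            w_in = rng.uniform(-r, r, size=(h, d))
            b_in = rng.uniform(-r, r, size=h)
            w_out_ba = rng.uniform(-r, r, size=h)
            b_out_ba = float(rng.uniform(-r, r))
            w_out_el = rng.uniform(-r, r, size=h)
            b_out_el = float(rng.uniform(-r, r))
        self.w_in = np.asarray(w_in, dtype=np.float64)
        self.b_in = np.asarray(b_in, dtype=np.float64)
        self.w_out_ba = np.asarray(w_out_ba, dtype=np.float64)
        self.b_out_ba = float(b_out_ba)
        self.w_out_el = np.asarray(w_out_el, dtype=np.float64)
        self.b_out_el = float(b_out_el)

    # -- forward ----------------------------------------------------------

    def _head(self, head: str):
        if head == "BA":
            return self.w_out_ba, self.b_out_ba
        if head == "EL":
            return self.w_out_el, self.b_out_el
        raise ValueError(f"head must be one of {HEADS}, got {head!r}")

    def _check_features(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.shape[-1] != self.encoder.feature_dim:
            raise ValueError(
                f"feature length {x.shape[-1]} does not match the model's "
                f"encoder ({self.encoder.feature_dim})"
            )
        return x

    def forward(self, x, head: str) -> float:
        """Sigmoid(hidden) then sigmoid(selected head) for one feature vector."""
        if isinstance(x, EncodedInstance):
            x = x.vector()
        x = self._check_features(x)
        w, b = self._head(head)
        h = _sigmoid(self.w_in @ x + self.b_in)
        return float(_sigmoid(w @ h + b))

    def forward_batch(self, X: np.ndarray, head: str) -> np.ndarray:
        """Vectorized forward over rows of ``X``."""
        X = self._check_features(np.atleast_2d(X))
        w, b = self._head(head)
        H = _sigmoid(X @ self.w_in.T + self.b_in)
        return _sigmoid(H @ w + b)

    # -- core selection ---------------------------------------------------

    def select_core(self, p: PeptideInstance, iteration: int | None = None,
                    *, strict_length: bool = False) -> CoreAlignment:
        """Arg-max binding core for the head matching ``p.data_type``.

        While ``iteration < burn_in_iterations`` only offsets whose P1 residue
        is hydrophobic are admitted; a peptide with no admissible offset falls
        back to the full offset range. Ties break to the smallest offset.
        ``iteration=None`` means prediction time (no burn-in).
        """
        L = len(p.sequence)
        if L < CORE_LENGTH:
            raise ValueError(f"peptide {p.sequence!r} shorter than the 9-residue core")
        burn = iteration is not None and iteration < self.config.burn_in_iterations
        n_off = L - CORE_LENGTH + 1
        scores = np.empty(n_off)
        for o in range(n_off):
            enc = encode_instance(p, o, self.encoder, strict_length=strict_length)
            scores[o] = self.forward(enc, p.data_type)
        admissible = np.ones(n_off, dtype=bool)
        if burn:
            hydro = set(self.encoder.hydrophobic_set)
            mask = np.array([p.sequence[o] in hydro for o in range(n_off)])
            if mask.any():
                admissible = mask
        masked = np.where(admissible, scores, -np.inf)
        offset = int(np.argmax(masked))  # argmax takes the first maximum
        return CoreAlignment(
            offset=offset,
            core=p.sequence[offset : offset + CORE_LENGTH],
            per_offset_scores=scores,
            burn_in_active=burn,
        )

    # -- learning ---------------------------------------------------------

    def loss(self, x, target: float, head: str) -> float:
        """Squared-error loss 0.5*(y - t)^2 used by the gradient step."""
        y = self.forward(x, head)
        return 0.5 * (y - target) ** 2

    def gradients(self, x, target: float, head: str):
        """Analytic gradients of :meth:`loss` w.r.t. every weight block.

        Returns ``(g_w_in, g_b_in, g_w_out, g_b_out)`` for the given head;
        the other head's gradients are identically zero.
        """
        if isinstance(x, EncodedInstance):
            x = x.vector()
        x = self._check_features(x)
        w, b = self._head(head)
        h = _sigmoid(self.w_in @ x + self.b_in)
        y = float(_sigmoid(w @ h + b))
        d_out = (y - target) * y * (1.0 - y)
        d_h = d_out * w * h * (1.0 - h)
        return np.outer(d_h, x), d_h, d_out * h, d_out

    def backward_update(self, p: PeptideInstance, alignment: CoreAlignment,
                        *, strict_length: bool = False) -> "NetworkModel":
        """One online gradient step on ``p`` through its selected core.

        Updates the shared block and the head matching ``p.data_type`` in
        place; the other head's output weights are untouched.
        """
        enc = encode_instance(p, alignment.offset, self.encoder,
                              strict_length=strict_length)
        g_w_in, g_b_in, g_w_out, g_b_out = self.gradients(enc, p.target, p.data_type)
        lr = self.config.learning_rate
        self.w_in -= lr * g_w_in
        self.b_in -= lr * g_b_in
        if p.data_type == "BA":
            self.w_out_ba -= lr * g_w_out
            self.b_out_ba -= lr * g_b_out
        else:
            self.w_out_el -= lr * g_w_out
            self.b_out_el -= lr * g_b_out
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "mhc2lig-network/1",
            "version": __version__,
            "alphabet": RESIDUES,
            "encoder": asdict(self.encoder),
            "config": asdict(self.config),
            "w_in": self.w_in.tolist(),
            "b_in": self.b_in.tolist(),
            "w_out_ba": self.w_out_ba.tolist(),
            "b_out_ba": self.b_out_ba,
            "w_out_el": self.w_out_el.tolist(),
            "b_out_el": self.b_out_el,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        if d.get("format") != "mhc2lig-network/1":
            raise ValueError(f"unrecognized model container format {d.get('format')!r}")
        if d["alphabet"] != RESIDUES:
            raise ValueError("model was saved under a different residue ordering")
        return cls(
            NetworkConfig(**d["config"]), EncoderConfig(**d["encoder"]),
            w_in=d["w_in"], b_in=d["b_in"],
            w_out_ba=d["w_out_ba"], b_out_ba=d["b_out_ba"],
            w_out_el=d["w_out_el"], b_out_el=d["b_out_el"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NetworkModel":
        return cls.from_dict(json.loads(s))


def predict_ensemble(p: PeptideInstance, ensemble: list[NetworkModel], head: str):
    """Mean prediction over an ensemble, each member at its own selected core.

    Returns ``(score, core)`` where the reported core comes from the member
    with the maximal prediction (first such member on ties).
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    best_score = -np.inf
    best_core = None
    total = 0.0
    for m in ensemble:
        aln = m.select_core(p)
        s = aln.per_offset_scores[aln.offset]
        total += s
        if s > best_score:
            best_score = s
            best_core = aln.core
    return total / len(ensemble), best_core
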