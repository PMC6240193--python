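"""Peptide feature encoding for the binding-core alignment network.

A peptide of length L is presented to the network once per candidate binding
core, i.e. once per offset ``0..L-9``. Each presentation is a fixed-length
feature vector composed of:

* the 9 core residues, each as a scaled substitution-matrix row (9 x 20);
* peptide-flanking-region (PFR) summaries for both flanks: the mean residue
  encoding over the up-to-3 flank residues adjacent to the core, plus the
  flank length encoded as ``min(len, 3)/3`` (2 x 21);
* a one-hot "length bin" vector over lengths 11..19 (9);
* optionally, antigen-processing context: the 3 upstream source-protein
  residues, the 3 N-terminal peptide residues, the 3 downstream source-protein
  residues and the 3 C-terminal peptide residues (4 x 3 x 20). Binding-affinity
  instances always present this block as wildcards, i.e. zeros.

The wildcard 'X' encodes to a zero 20-vector everywhere.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import (
    HYDROPHOBIC,
    RESIDUES,
    WILDCARD_CODE,
    seq_to_codes,
    substitution_rows,
)

logger = logging.getLogger(__name__)

CORE_LENGTH = 9
MIN_TRAIN_LENGTH = 11
MAX_TRAIN_LENGTH = 19
N_LENGTH_BINS = MAX_TRAIN_LENGTH - MIN_TRAIN_LENGTH + 1

#: Data types carried by training instances.
DATA_TYPES = ("BA", "EL")


@dataclass(frozen=True)
class EncoderConfig:
    """Residue-encoding and feature-layout configuration.

    Parameters
    ----------
    substitution_matrix, scale
        Residues are encoded as rows of this 20x20 similarity table divided
        by ``scale``.
    hydrophobic_set
        Residues admitted at the P1 core anchor during the burn-in iteration.
    context_mode
        Whether the 12-residue processing-context block is part of the
        feature vector.
    """

    substitution_matrix: str = "BLOSUM50"
    scale: float = 5.0
    hydrophobic_set: str = HYDROPHOBIC
    core_length: int = CORE_LENGTH
    pfr_window: int = 3
    context_block: int = 3
    context_mode: bool = False

    def __post_init__(self) -> None:
        if self.core_length != CORE_LENGTH:
            raise ValueError("the binding core is a fixed stretch of 9 residues")
        if not self.hydrophobic_set:
            raise ValueError("hydrophobic_set must be non-empty")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def residue_table(self) -> np.ndarray:
        """(21, 20) encoding table; last row is the wildcard (zeros)."""
        return substitution_rows(self.substitution_matrix, self.scale)

    @property
    def feature_dim(self) -> int:
        d = 9 * 20 + 2 * 21 + N_LENGTH_BINS
        if self.context_mode:
            d += 4 * self.context_block * 20
        return d

    @property
    def hydrophobic_codes(self) -> frozenset[int]:
        return frozenset(RESIDUES.index(a) for a in self.hydrophobic_set)


@dataclass
class PeptideInstance:
    """One training or prediction record.

    ``context_up``/``context_down`` are the three source-protein residues
    immediately outside the peptide's N/C terminus ('XXX' when unknown;
    binding-affinity data never carries context).
    """

    sequence: str
    target: float = 0.0
    data_type: str = "EL"
    context_up: str = "XXX"
    context_down: str = "XXX"
    source_protein_id: str | None = None
    partition: int | None = None

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}")
        if not 0.0 <= self.target <= 1.0:
            raise ValueError(f"target {self.target} outside [0, 1]")
        if len(self.context_up) != 3 or len(self.context_down) != 3:
            raise ValueError("context strings must have length 3")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class EncodedInstance:
    """Feature blocks for one peptide at one candidate core offset."""

    core_features: np.ndarray  # (9, 20)
    pfr_features: np.ndarray  # (42,) = n-comp(20) + n-len(1) + c-comp(20) + c-len(1)
    length_bins: np.ndarray  # (9,)
    context_features: np.ndarray | None  # (12, 20) or None when context off
    offset: int

    def vector(self) -> np.ndarray:
        parts = [self.core_features.ravel(), self.pfr_features, self.length_bins]
        if self.context_features is not None:
            parts.append(self.context_features.ravel())
        return np.concatenate(parts)


def encode_residue(residue: str, config: EncoderConfig, position: int | None = None) -> np.ndarray:
    """Encode one letter as a 20-vector (wildcard -> zeros)."""
    try:
        code = seq_to_codes(residue)[0]
    except ValueError:
        where = "" if position is None else f" at position {position}"
        raise ValueError(f"unknown residue {residue!r}{where}") from None
    return config.residue_table[code].copy()


def encode_length_bins(length: int, strict: bool = True) -> np.ndarray:
    """One-hot length encoding over 11..19.

    With ``strict=False`` (prediction-time inputs such as 13-21mer benchmark
    windows) out-of-range lengths map to the nearest bin with a warning.
    """
    bins = np.zeros(N_LENGTH_BINS)
    if MIN_TRAIN_LENGTH <= length <= MAX_TRAIN_LENGTH:
        bins[length - MIN_TRAIN_LENGTH] = 1.0
        return bins
    if strict:
        raise ValueError(
            f"peptide length {length} outside the training range "
            f"{MIN_TRAIN_LENGTH}-{MAX_TRAIN_LENGTH}"
        )
    nearest = min(max(length, MIN_TRAIN_LENGTH), MAX_TRAIN_LENGTH)
    if length not in _WARNED_LENGTHS:
        _WARNED_LENGTHS.add(length)
        logger.warning("length %d outside 11-19; using nearest length bin %d",
                       length, nearest)
    bins[nearest - MIN_TRAIN_LENGTH] = 1.0
    return bins


_WARNED_LENGTHS: set[int] = set()


def encode_instance(p: PeptideInstance, offset: int, config: EncoderConfig, *, strict_length: bool = True) -> EncodedInstance:
    """Encode ``p`` with its binding core at ``offset``."""
    L = len(p.sequence)
    if not 0 <= offset <= L - CORE_LENGTH:
        raise ValueError(f"offset {offset} out of range for length-{L} peptide")
    codes = seq_to_codes(p.sequence)
    table = config.residue_table
    enc_seq = table[codes]

    core = enc_seq[offset : offset + CORE_LENGTH]

    w = config.pfr_window
    n_len = offset
    c_len = L - CORE_LENGTH - offset
    pfr = np.zeros(42)
    if n_len > 0:
        lo = max(0, offset - w)
        pfr[:20] = enc_seq[lo:offset].mean(axis=0)
    pfr[20] = min(n_len, w) / w
    if c_len > 0:
        start = offset + CORE_LENGTH
        pfr[21:41] = enc_seq[start : start + min(c_len, w)].mean(axis=0)
    pfr[41] = min(c_len, w) / w

    bins = encode_length_bins(L, strict=strict_length)

    context = None
    if config.context_mode:
        context = np.zeros((12, 20))
        if p.data_type == "EL":
            up = seq_to_codes(p.context_up)
            down = seq_to_codes(p.context_down)
            pep_n = codes[:3]
            pep_c = codes[-3:]
            block = np.concatenate([up, pep_n, down, pep_c])
            context[:] = table[block]
        # BA instances carry wildcard ('XXX') context: all-zero block.

    return EncodedInstance(
        core_features=core, pfr_features=pfr, length_bins=bins,
        context_features=context, offset=offset,
    )


@dataclass
class EncodedDataset:
    """All candidate-core feature rows for a batch of instances, flattened.

    Row ``row_start[i] + o`` is instance ``i`` encoded at offset ``o``.
    Stored float32: this is the array the training kernel and the batch
    predictor consume.
    """

    X: np.ndarray  # (n_rows, D) float32
    row_start: np.ndarray  # (n,) int64
    row_count: np.ndarray  # (n,) int64
    p1_hydro: np.ndarray  # (n_rows,) bool: P1 residue hydrophobic for this row
    has_hydro: np.ndarray  # (n,) bool: any admissible burn-in offset
    targets: np.ndarray  # (n,) float64
    is_el: np.ndarray  # (n,) bool
    lengths: np.ndarray  # (n,) int64
    config: EncoderConfig

    def __len__(self) -> int:
        return len(self.row_start)

    def rows_for(self, i: int) -> slice:
        return slice(self.row_start[i], self.row_start[i] + self.row_count[i])

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        """View-free subset keeping rows of the selected instances."""
        idx = np.asarray(idx)
        counts = self.row_count[idx]
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        rows = np.concatenate([
            np.arange(self.row_start[i], self.row_start[i] + self.row_count[i])
            for i in idx
        ])
        return EncodedDataset(
            X=self.X[rows], row_start=starts, row_count=counts,
            p1_hydro=self.p1_hydro[rows], has_hydro=self.has_hydro[idx],
            targets=self.targets[idx], is_el=self.is_el[idx],
            lengths=self.lengths[idx], config=self.config,
        )


def encode_dataset(instances: list[PeptideInstance], config: EncoderConfig, *, strict_length: bool = True) -> EncodedDataset:
    """Encode every instance at every candidate offset into one flat array."""
    n = len(instances)
    if n == 0:
        raise ValueError("empty instance list")
    table = config.residue_table.astype(np.float32)
    hydro = np.zeros(21, dtype=bool)
    for c in config.hydrophobic_codes:
        hydro[c] = True
    D = config.feature_dim
    w = config.pfr_window

    lengths = np.array([len(p.sequence) for p in instances], dtype=np.int64)
    if (lengths < CORE_LENGTH).any():
        bad = int(np.argmax(lengths < CORE_LENGTH))
        raise ValueError(
            f"peptide {instances[bad].sequence!r} shorter than the 9-residue core"
        )
    counts = lengths - CORE_LENGTH + 1
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    n_rows = int(counts.sum())

    X = np.zeros((n_rows, D), dtype=np.float32)
    p1h = np.zeros(n_rows, dtype=bool)
    has_h = np.zeros(n, dtype=bool)
    targets = np.empty(n)
    is_el = np.empty(n, dtype=bool)

    for i, p in enumerate(instances):
        codes = seq_to_codes(p.sequence)
        L = lengths[i]
        enc = table[codes]  # (L, 20)
        flat = enc.ravel()
        n_off = counts[i]
        # sliding 9-residue core blocks
        core = np.lib.stride_tricks.sliding_window_view(flat, 9 * 20)[:: 20]
        base = starts[i]
        X[base : base + n_off, : 180] = core

        bins = encode_length_bins(int(L), strict=strict_length)
        X[base : base + n_off, 222:231] = bins

        cs = np.vstack([np.zeros(20, dtype=np.float32), np.cumsum(enc, axis=0)])
        for o in range(n_off):
            r = base + o
            if o > 0:
                lo = max(0, o - w)
                X[r, 180:200] = (cs[o] - cs[lo]) / (o - lo)
            X[r, 200] = min(o, w) / w
            c_len = int(L) - CORE_LENGTH - o
            if c_len > 0:
                s0 = o + CORE_LENGTH
                s1 = s0 + min(c_len, w)
                X[r, 201:221] = (cs[s1] - cs[s0]) / (s1 - s0)
            X[r, 221] = min(c_len, w) / w

        if config.context_mode and p.data_type == "EL":
            block = np.concatenate([
                seq_to_codes(p.context_up), codes[:3],
                seq_to_codes(p.context_down), codes[-3:],
            ])
            X[base : base + n_off, 231:] = table[block].ravel()

        p1h[base : base + n_off] = hydro[codes[: n_off]]
        has_h[i] = p1h[base : base + n_off].any()
        targets[i] = p.target
        is_el[i] = p.data_type == "EL"

    return EncodedDataset(
        X=X, row_start=starts, row_count=counts, p1_hydro=p1h, has_hydro=has_h,
        targets=targets, is_el=is_el, lengths=lengths, config=config,
    )
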