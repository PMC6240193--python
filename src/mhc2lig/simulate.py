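"""Ground-truth synthetic world: motif, length law, cleavage signal, proteins.

The generator emulates the statistical structure that the prediction
framework assumes: a 9-residue position-specific binding motif with
concentrated anchors at P1/P4/P6/P9 (P1 hydrophobic), eluted-ligand lengths
11-19 with a unimodal preference around 14-16, a terminal cleavage signal
(proline enrichment at the second residue from each terminus whenever the
flanking region is at least three residues long), and source proteins that
physically embed every ligand so flanking context is well defined. Every
stage of the package can therefore be tested against known truth without
external data.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .alphabet import RESIDUES, RESIDUE_INDEX
from .data import flank_context
from .encoding import (
    CORE_LENGTH,
    MAX_TRAIN_LENGTH,
    MIN_TRAIN_LENGTH,
    PeptideInstance,
)

#: Unimodal length preference over 11..19 with its mode at 15.
DEFAULT_LENGTH_LAW = (0.02, 0.05, 0.10, 0.16, 0.20, 0.18, 0.13, 0.09, 0.07)

ANCHOR_POSITIONS = (0, 3, 5, 8)  # P1, P4, P6, P9 (0-based core positions)

#: Residues eligible as P1 anchors (hydrophobic, matching the burn-in set).
P1_CANDIDATES = "FILMVWY"


@dataclass(frozen=True)
class WorldConfig:
    """Tunable parameters of the synthetic world."""

    n_ligands: int = 2000
    n_ba: int = 1000
    n_proteins: int = 20000
    protein_length: int = 300
    cleavage_prob: float = 0.4
    length_law: tuple = DEFAULT_LENGTH_LAW
    anchor_concentration: float = 0.9  # probability mass on the anchor residues
    binder_frac: float = 0.3  # BA peptides carrying an implanted core
    ba_noise_sd: float = 0.05
    background: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise ValueError("cleavage_prob must be a probability")
        law = np.asarray(self.length_law, dtype=np.float64)
        if law.shape != (9,) or (law < 0).any() or not np.isclose(law.sum(), 1.0):
            raise ValueError("length_law must be a probability vector over lengths 11-19")
        if not 0.0 < self.anchor_concentration < 1.0:
            raise ValueError("anchor_concentration must be in (0, 1)")
        if not 0.0 <= self.binder_frac <= 1.0:
            raise ValueError("binder_frac must be a probability")


@dataclass
class SyntheticWorld:
    """Frozen ground truth emitted by :func:`make_world`."""

    pssm: np.ndarray  # (9, 20) row-stochastic
    length_law: np.ndarray  # (9,) over lengths 11..19
    background: np.ndarray  # (20,)
    config: WorldConfig

    @property
    def seed(self) -> int:
        return self.config.seed

    @property
    def cleavage_prob(self) -> float:
        return self.config.cleavage_prob

    def length_mode(self) -> int:
        return MIN_TRAIN_LENGTH + int(np.argmax(self.length_law))

    def log_odds(self) -> np.ndarray:
        return np.log2(self.pssm / self.background)

    def to_json(self) -> str:
        d = asdict(self.config)
        d["pssm"] = self.pssm.tolist()
        d["length_law_resolved"] = self.length_law.tolist()
        d["background_resolved"] = self.background.tolist()
        return json.dumps(d)


#: Residue frequencies resembling a vertebrate proteome (rounded; used when
#: ``background='proteome'``). Order follows :data:`RESIDUES`.
PROTEOME_LIKE = (
    0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.043, 0.058, 0.100,
    0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.054, 0.060, 0.012, 0.027,
)


def _background_vector(name: str) -> np.ndarray:
    if name == "uniform":
        return np.full(20, 1.0 / 20.0)
    if name == "proteome":
        v = np.asarray(PROTEOME_LIKE, dtype=np.float64)
        return v / v.sum()
    raise ValueError("background must be 'uniform' or 'proteome'")


def make_world(config: WorldConfig | None = None, **kwargs) -> SyntheticWorld:
    """Build the ground-truth world deterministically from ``config.seed``.

    Anchor columns put ``anchor_concentration`` of their mass on 2-3
    seed-chosen residues (hydrophobic ones at P1); non-anchor columns are the
    background with a light Dirichlet jitter, keeping their information
    content near zero.
    """
    if config is None:
        config = WorldConfig(**kwargs)
    elif kwargs:
        raise ValueError("pass either a WorldConfig or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    background = _background_vector(config.background)

    pssm = np.empty((CORE_LENGTH, 20))
    for pos in range(CORE_LENGTH):
        if pos in ANCHOR_POSITIONS:
            candidates = P1_CANDIDATES if pos == 0 else RESIDUES
            k = int(rng.integers(2, 4))  # 2-3 permitted residues
            chosen = rng.choice([RESIDUE_INDEX[a] for a in candidates],
                                size=k, replace=False)
            weights = rng.dirichlet(np.full(k, 4.0))
            col = np.full(20, (1.0 - config.anchor_concentration) / (20 - k))
            col[chosen] = config.anchor_concentration * weights
        else:
            col = rng.dirichlet(background * 400.0)
        pssm[pos] = col / col.sum()

    return SyntheticWorld(
        pssm=pssm,
        length_law=np.asarray(config.length_law, dtype=np.float64),
        background=background,
        config=config,
    )


def _sample_sequence(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(20, size=n, p=probs)


def _codes_to_str(codes) -> str:
    return "".join(RESIDUES[c] for c in codes)


def _apply_cleavage(rng, codes, n_pfr: int, c_pfr: int, prob: float,
                    background: np.ndarray) -> None:
    """Plant the proline cleavage mark at the second residue from each
    terminus, only when that side's PFR is at least three residues long."""
    p_idx = RESIDUE_INDEX["P"]
    if n_pfr >= 3 and rng.random() < prob:
        codes[1] = p_idx
    if c_pfr >= 3 and rng.random() < prob:
        codes[-2] = p_idx


def emit_ligands(world: SyntheticWorld):
    """Generate the eluted-ligand table and the hosting proteome.

    Returns ``(ligands, proteome, truth)`` where ``ligands`` is a list of
    positive :class:`PeptideInstance` (context filled from the protein),
    ``proteome`` maps protein id to sequence, and ``truth`` records the
    ground-truth core offset and protein position per ligand.
    """
    cfg = world.config
    rng = np.random.default_rng([cfg.seed, 2])

    # non-overlapping slots so no ligand or its context collides with another
    slot_stride = MAX_TRAIN_LENGTH + 7
    slots_per_protein = cfg.protein_length // slot_stride
    capacity = cfg.n_proteins * slots_per_protein
    if capacity < cfg.n_ligands:
        raise ValueError(
            f"proteome too small: {capacity} ligand slots available for "
            f"{cfg.n_ligands} ligands (raise n_proteins or protein_length)"
        )

    proteins = rng.choice(
        20, size=(cfg.n_proteins, cfg.protein_length), p=world.background
    ).astype(np.int64)

    all_slots = [(pi, si * slot_stride) for pi in range(cfg.n_proteins)
                 for si in range(slots_per_protein)]
    chosen = rng.choice(len(all_slots), size=cfg.n_ligands, replace=False)

    lengths = MIN_TRAIN_LENGTH + rng.choice(9, size=cfg.n_ligands, p=world.length_law)

    ligands: list[PeptideInstance] = []
    truth = []
    for li in range(cfg.n_ligands):
        L = int(lengths[li])
        n_pfr = int(rng.integers(0, L - CORE_LENGTH + 1))
        c_pfr = L - CORE_LENGTH - n_pfr
        codes = np.empty(L, dtype=np.int64)
        codes[:n_pfr] = _sample_sequence(rng, world.background, n_pfr)
        for pos in range(CORE_LENGTH):
            codes[n_pfr + pos] = rng.choice(20, p=world.pssm[pos])
        if c_pfr:
            codes[n_pfr + CORE_LENGTH:] = _sample_sequence(rng, world.background, c_pfr)
        _apply_cleavage(rng, codes, n_pfr, c_pfr, world.cleavage_prob,
                        world.background)

        pi, slot = all_slots[chosen[li]]
        # keep 3 residues of genuine context on both sides of the slot
        pos = slot + 3
        proteins[pi][pos : pos + L] = codes
        truth.append({"ligand_index": li, "protein": f"prot{pi:05d}",
                      "protein_pos": pos, "core_offset": n_pfr})

    proteome = {f"prot{pi:05d}": _codes_to_str(proteins[pi])
                for pi in range(cfg.n_proteins)}
    for rec in truth:
        seq = proteome[rec["protein"]]
        pos = rec["protein_pos"]
        L = int(lengths[rec["ligand_index"]])
        up, down = flank_context(seq, pos, pos + L)
        ligands.append(PeptideInstance(
            sequence=seq[pos : pos + L], target=1.0, data_type="EL",
            context_up=up, context_down=down, source_protein_id=rec["protein"],
        ))
    return ligands, proteome, truth


def _best_window_score(codes: np.ndarray, log_odds: np.ndarray) -> float:
    best = -np.inf
    for o in range(len(codes) - CORE_LENGTH + 1):
        s = float(log_odds[np.arange(CORE_LENGTH), codes[o : o + CORE_LENGTH]].sum())
        if s > best:
            best = s
    return best


def emit_ba(world: SyntheticWorld) -> list[PeptideInstance]:
    """Generate the binding-affinity table.

    Peptides are background-random, with a ``binder_frac`` fraction carrying
    a motif-sampled core at a random offset (affinity panels are enriched for
    binders). Targets are the best-9mer-window log-odds score mapped through
    a logistic, with additive Gaussian noise (sd ``ba_noise_sd``) clamped to
    [0, 1]. Affinity data never carries context ('XXX').
    """
    cfg = world.config
    rng = np.random.default_rng([cfg.seed, 3])
    log_odds = world.log_odds()
    # logistic placed relative to the strongest possible core score
    s_max = float(log_odds.max(axis=1).sum())
    midpoint, slope = 0.5 * s_max, s_max / 8.0

    out = []
    lengths = MIN_TRAIN_LENGTH + rng.choice(9, size=cfg.n_ba, p=world.length_law)
    for i in range(cfg.n_ba):
        L = int(lengths[i])
        codes = _sample_sequence(rng, world.background, L)
        if rng.random() < cfg.binder_frac:
            off = int(rng.integers(0, L - CORE_LENGTH + 1))
            for pos in range(CORE_LENGTH):
                codes[off + pos] = rng.choice(20, p=world.pssm[pos])
        score = _best_window_score(codes, log_odds)
        target = 1.0 / (1.0 + np.exp(-(score - midpoint) / slope))
        if cfg.ba_noise_sd > 0:
            target += rng.normal(0.0, cfg.ba_noise_sd)
        out.append(PeptideInstance(
            sequence=_codes_to_str(codes),
            target=float(np.clip(target, 0.0, 1.0)),
            data_type="BA",
        ))
    return out


def random_peptides(n: int, rng, background: np.ndarray | None = None,
                    min_length: int = MIN_TRAIN_LENGTH,
                    max_length: int = MAX_TRAIN_LENGTH) -> list[PeptideInstance]:
    """Background-random peptides with uniform lengths — the probe set used
    to read a trained model's motif and length preference."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    lengths = rng.integers(min_length, max_length + 1, size=n)
    return [
        PeptideInstance(sequence=_codes_to_str(
            _sample_sequence(rng, background, int(L))), data_type="EL")
        for L in lengths
    ]
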