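"""Antigen-processing footprints at the ligand termini.

For each ligand terminus the cleavage signal is summarized over six
positions: the three source-protein "context" residues just outside the
ligand and the three terminal ligand residues. Only ligands whose peptide
flanking region (PFR) on that side is at least three residues long
contribute — with shorter PFRs the MHC molecule shields the terminus from
the trimming exopeptidases, so short-PFR termini carry no cleavage signal.
Position order is outermost-context to innermost-peptide upstream
(c-3 c-2 c-1 | p1 p2 p3) and innermost-peptide to outermost-context
downstream (p-3 p-2 p-1 | c+1 c+2 c+3).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import RESIDUES, WILDCARD_CODE, seq_to_codes
from .data import flank_context
from .encoding import CORE_LENGTH, PeptideInstance

logger = logging.getLogger(__name__)

SIDES = ("upstream", "downstream")
N_POSITIONS = 6
MIN_PFR = 3


@dataclass
class PFRAnnotation:
    """A ligand with its binding core located and its flanks measured."""

    ligand: PeptideInstance
    core_offset: int
    context_up: str
    context_down: str

    @property
    def n_pfr_len(self) -> int:
        return self.core_offset

    @property
    def c_pfr_len(self) -> int:
        return len(self.ligand.sequence) - CORE_LENGTH - self.core_offset


@dataclass
class ProcessingMatrix:
    """6-position x 20-residue terminal cleavage-signal summary."""

    side: str
    counts: np.ndarray  # (6, 20) int
    frequencies: np.ndarray  # (6, 20), rows sum to 1 (pseudocounted)
    log_odds: np.ndarray  # (6, 20), log2(freq / background)
    background: np.ndarray  # (20,)
    n_ligands: int

    def flat(self, space: str = "log_odds") -> np.ndarray:
        if space == "log_odds":
            return self.log_odds.ravel()
        if space == "frequencies":
            return self.frequencies.ravel()
        raise ValueError("space must be 'log_odds' or 'frequencies'")


def annotate_pfr(ligands: list[PeptideInstance], core_offsets,
                 proteome: dict[str, str] | None = None) -> list[PFRAnnotation]:
    """Attach core offsets (typically the cross-validated predictions) and
    context to ligands.

    Context missing from a record ('XXX') is looked up in the source protein
    at the ligand's first occurrence; ligands not found in their declared
    protein are excluded with a logged count. Protein-boundary ligands get
    'X'-padded context.
    """
    out = []
    missing = 0
    for p, off in zip(ligands, core_offsets):
        off = int(off)
        if not 0 <= off <= len(p.sequence) - CORE_LENGTH:
            raise ValueError(f"core offset {off} out of range for {p.sequence!r}")
        up, down = p.context_up, p.context_down
        if (up == "XXX" and down == "XXX") and proteome is not None \
                and p.source_protein_id in proteome:
            seq = proteome[p.source_protein_id]
            pos = seq.find(p.sequence)
            if pos < 0:
                missing += 1
                continue
            if seq.count(p.sequence) > 1:
                logger.info("ligand %s occurs %d times in %s; using first occurrence",
                            p.sequence, seq.count(p.sequence), p.source_protein_id)
            up, down = flank_context(seq, pos, pos + len(p.sequence))
        out.append(PFRAnnotation(ligand=p, core_offset=off,
                                 context_up=up, context_down=down))
    if missing:
        logger.warning("excluded %d ligands not found in their declared source protein",
                       missing)
    return out


def _terminal_window(a: PFRAnnotation, side: str) -> str:
    seq = a.ligand.sequence
    if side == "upstream":
        return a.context_up + seq[:3]
    return seq[-3:] + a.context_down


def background_frequencies(proteome: dict[str, str], pseudocount: float = 1.0) -> np.ndarray:
    """Residue frequencies over a set of source proteins (pseudocounted so no
    entry is zero)."""
    counts = np.zeros(20)
    for seq in proteome.values():
        codes = seq_to_codes(seq)
        counts += np.bincount(codes[codes < WILDCARD_CODE], minlength=20)
    freqs = (counts + pseudocount) / (counts.sum() + 20 * pseudocount)
    return freqs


def terminal_matrix(annotations: list[PFRAnnotation], side: str,
                    background: np.ndarray | None = None,
                    proteome: dict[str, str] | None = None,
                    min_pfr: int = MIN_PFR,
                    pseudocount: float = 1.0) -> ProcessingMatrix:
    """Build the 6x20 processing matrix for one ligand terminus.

    The background comes from the source proteins of the ligands (pass
    ``proteome``) or is supplied directly. 'X' padding never enters the
    counts. Frequencies use an add-``pseudocount`` on the counts and
    ``log_odds = log2(freq / background)``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if background is None:
        if proteome is None:
            raise ValueError("need either a background vector or a proteome")
        used = {a.ligand.source_protein_id for a in annotations}
        background = background_frequencies(
            {k: v for k, v in proteome.items() if k in used} or proteome
        )
    background = np.asarray(background, dtype=np.float64)
    if (background <= 0).any():
        raise ValueError("background frequencies must be strictly positive")

    pfr_of = (lambda a: a.n_pfr_len) if side == "upstream" else (lambda a: a.c_pfr_len)
    surviving = [a for a in annotations if pfr_of(a) >= min_pfr]
    if not surviving:
        raise ValueError(
            f"no ligands with {side} PFR >= {min_pfr}; matrix would be empty"
        )

    counts = np.zeros((N_POSITIONS, 20), dtype=np.int64)
    for a in surviving:
        codes = seq_to_codes(_terminal_window(a, side))
        for pos, c in enumerate(codes):
            if c != WILDCARD_CODE:
                counts[pos, c] += 1
    totals = counts.sum(axis=1, keepdims=True)
    frequencies = (counts + pseudocount) / (totals + 20 * pseudocount)
    log_odds = np.log2(frequencies / background)
    return ProcessingMatrix(side=side, counts=counts, frequencies=frequencies,
                            log_odds=log_odds, background=background,
                            n_ligands=len(surviving))


# -- Kullback-Leibler logos ----------------------------------------------


@dataclass
class LogoMatrix:
    """Per-position letter heights of a weighted Kullback-Leibler logo."""

    heights: np.ndarray  # (n_positions, 20): f * log2(f/q), sign kept
    information: np.ndarray  # (n_positions,): sum over residues

    @property
    def n_positions(self) -> int:
        return self.heights.shape[0]


def kl_logo_matrix(frequencies: np.ndarray, background: np.ndarray) -> LogoMatrix:
    """Heights ``f(a) * log2(f(a)/q(a))`` per position; negative terms are
    kept (depleted residues point down). Zero frequencies contribute zero."""
    f = np.asarray(frequencies, dtype=np.float64)
    q = np.asarray(background, dtype=np.float64)
    if not np.allclose(f.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("frequency rows must sum to 1")
    if (q <= 0).any():
        raise ValueError("background must be strictly positive (pseudocount upstream)")
    with np.errstate(divide="ignore", invalid="ignore"):
        heights = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) / q), 0.0)
    return LogoMatrix(heights=heights, information=heights.sum(axis=-1))


def pfr_grouped_logos(annotations: list[PFRAnnotation], side: str,
                      background: np.ndarray,
                      max_pfr: int = 6,
                      pseudocount: float = 1.0) -> dict[int, LogoMatrix]:
    """One logo matrix per PFR length 1..max_pfr: 3 context positions plus
    ``min(PFR, 6)`` peptide positions counted from the terminus. Empty groups
    are skipped with a log line."""
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    pfr_of = (lambda a: a.n_pfr_len) if side == "upstream" else (lambda a: a.c_pfr_len)
    out: dict[int, LogoMatrix] = {}
    for g in range(1, max_pfr + 1):
        group = [a for a in annotations if pfr_of(a) == g]
        if not group:
            logger.info("no ligands with %s PFR length %d; group skipped", side, g)
            continue
        width = 3 + min(g, max_pfr)
        counts = np.zeros((width, 20))
        for a in group:
            seq = a.ligand.sequence
            if side == "upstream":
                window = a.context_up + seq[: min(g, max_pfr)]
            else:
                window = seq[-min(g, max_pfr):] + a.context_down
            codes = seq_to_codes(window)
            for pos, c in enumerate(codes):
                if c != WILDCARD_CODE:
                    counts[pos, c] += 1
        freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 20 * pseudocount)
        out[g] = kl_logo_matrix(freqs, background)
    return out


# -- matrix comparison ----------------------------------------------------


def matrix_pcc(a: ProcessingMatrix, b: ProcessingMatrix, space: str = "log_odds") -> float:
    """Pearson correlation of the flattened 120-element matrices."""
    if a.side != b.side:
        raise ValueError("matrices summarize different termini")
    va, vb = a.flat(space), b.flat(space)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    return float(np.corrcoef(va, vb)[0, 1])


def pcc_permutation_test(set_a: list[PFRAnnotation], set_b: list[PFRAnnotation],
                         side: str, n_perm: int = 999,
                         background: np.ndarray | None = None,
                         proteome: dict[str, str] | None = None,
                         null: str = "entries", space: str = "log_odds",
                         rng=0) -> tuple[float, float]:
    """Test whether the processing-matrix correlation between two ligand sets
    exceeds chance. Returns ``(observed_pcc, p_value)`` with the add-one
    estimator ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.

    ``null='entries'`` (default) permutes the 120 entries of one matrix per
    permutation — the null of no shared positional signal ("different from
    random"). ``null='membership'`` reshuffles which ligand belongs to which
    set and rebuilds both matrices — the null that the two sets are draws
    from one pool.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kw = dict(background=background, proteome=proteome)
    ma = terminal_matrix(set_a, side, **kw)
    mb = terminal_matrix(set_b, side, **kw)
    observed = matrix_pcc(ma, mb, space=space)

    count = 0
    if null == "entries":
        va, vb = ma.flat(space), mb.flat(space)
        for _ in range(n_perm):
            perm = rng.permutation(len(vb))
            if float(np.corrcoef(va, vb[perm])[0, 1]) >= observed:
                count += 1
    elif null == "membership":
        pool = list(set_a) + list(set_b)
        na = len(set_a)
        for _ in range(n_perm):
            order = rng.permutation(len(pool))
            pa = [pool[i] for i in order[:na]]
            pb = [pool[i] for i in order[na:]]
            pcc = matrix_pcc(terminal_matrix(pa, side, **kw),
                             terminal_matrix(pb, side, **kw), space=space)
            if pcc >= observed:
                count += 1
    else:
        raise ValueError("null must be 'entries' or 'membership'")
    return observed, (1 + count) / (1 + n_perm)
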