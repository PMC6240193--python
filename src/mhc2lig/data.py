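"""Training-set assembly: random negatives and leakage-free partitioning.

Eluted-ligand positives (target 1) are complemented with random proteome
subsequences labeled 0: for each length 11-19 the same number of negatives
is added, five times the count of the most represented positive length.
Cross-validation partitions are built with the common-motif approach: any two
peptides sharing an identical 9mer substring are forced into the same
partition (single-linkage), so no 9mer crosses a partition boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import WILDCARD
from .encoding import (
    CORE_LENGTH,
    MAX_TRAIN_LENGTH,
    MIN_TRAIN_LENGTH,
    PeptideInstance,
)

logger = logging.getLogger(__name__)

TRAIN_LENGTHS = range(MIN_TRAIN_LENGTH, MAX_TRAIN_LENGTH + 1)

#: Half-maximal inhibitory concentration mapped to a [0, 1] regression target.
IC50_MAX_NM = 50000.0


def ic50_to_target(ic50_nm) -> np.ndarray:
    """Transform measured IC50 (nM) to ``1 - log(IC50)/log(50000)``, clamped
    to [0, 1] (the standard affinity target of the NetMHCII model lineage)."""
    ic50_nm = np.maximum(np.asarray(ic50_nm, dtype=np.float64), 1e-12)
    return np.clip(1.0 - np.log(ic50_nm) / np.log(IC50_MAX_NM), 0.0, 1.0)


def flank_context(seq: str, start: int, end: int, width: int = 3) -> tuple[str, str]:
    """Source-protein residues flanking ``seq[start:end]``, 'X'-padded at the
    protein boundaries."""
    up = seq[max(0, start - width) : start].rjust(width, WILDCARD)
    down = seq[end : end + width].ljust(width, WILDCARD)
    return up, down


def sample_negatives(positives: list[PeptideInstance], proteome: dict[str, str],
                     rng: np.random.Generator | int | None = 0,
                     n_fold: int = 5) -> list[PeptideInstance]:
    """Draw random proteome subsequences as eluted-ligand negatives.

    For every length 11-19 the same number is drawn: ``n_fold`` times the
    count of the most represented length among the positives. Negatives carry
    their true source-protein context so that context-aware models see
    genuine flanking residues.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = {L: 0 for L in TRAIN_LENGTHS}
    for p in positives:
        L = len(p.sequence)
        if L not in counts:
            raise ValueError(
                f"positive ligand of length {L} outside the 11-19 training range"
            )
        counts[L] += 1
    per_length = n_fold * max(counts.values())

    ids = list(proteome)
    seqs = [proteome[i] for i in ids]
    negatives = []
    for L in TRAIN_LENGTHS:
        starts_per = np.array([max(0, len(s) - L + 1) for s in seqs], dtype=np.int64)
        total = int(starts_per.sum())
        if total == 0:
            raise ValueError(f"no proteome sequence long enough for length {L}")
        cum = np.cumsum(starts_per)
        draws = rng.integers(0, total, size=per_length)
        for d in draws:
            pi = int(np.searchsorted(cum, d, side="right"))
            pos = int(d - (cum[pi - 1] if pi else 0))
            seq = seqs[pi]
            sub = seq[pos : pos + L]
            up, down = flank_context(seq, pos, pos + L)
            negatives.append(PeptideInstance(
                sequence=sub, target=0.0, data_type="EL",
                context_up=up, context_down=down, source_protein_id=ids[pi],
            ))
    logger.info("sampled %d random negatives (%d per length 11-19)",
                len(negatives), per_length)
    return negatives


def _nine_mers(seq: str):
    return {seq[i : i + CORE_LENGTH] for i in range(len(seq) - CORE_LENGTH + 1)}


def common_motif_partition(instances: list[PeptideInstance], k: int = 5) -> np.ndarray:
    """Single-linkage clustering on shared 9mers, then greedy balancing.

    Two peptides link iff they share an identical 9mer substring; linked
    clusters are assigned, largest first, to the currently smallest
    partition. Returns one partition label (0..k-1) per instance.
    """
    n = len(instances)
    if n < k:
        raise ValueError(f"need at least {k} instances, got {n}")
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    seen: dict[str, int] = {}
    for i, p in enumerate(instances):
        for mer in _nine_mers(p.sequence):
            j = seen.setdefault(mer, i)
            if j != i:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), c[0]))

    labels = np.empty(n, dtype=np.int64)
    sizes = np.zeros(k, dtype=np.int64)
    for members in ordered:
        tgt = int(np.argmin(sizes))
        labels[members] = tgt
        sizes[tgt] += len(members)
    return labels


@dataclass
class TrainingSet:
    """Instances plus the bookkeeping of how they were assembled."""

    instances: list[PeptideInstance]
    negatives_added: dict[int, int] = field(default_factory=dict)
    partition_labels: np.ndarray | None = None

    def partitions(self, k: int = 5) -> list[np.ndarray]:
        if self.partition_labels is None:
            raise ValueError("training set has not been partitioned")
        return [np.flatnonzero(self.partition_labels == f) for f in range(k)]


def build_training_set(ligands: list[PeptideInstance],
                       proteome: dict[str, str],
                       ba: list[PeptideInstance] | None = None,
                       rng: np.random.Generator | int | None = 0,
                       k: int = 5) -> TrainingSet:
    """Assemble ligands + random negatives (+ optional binding-affinity data),
    then partition everything jointly with the common-motif approach.

    Negatives are drawn once, before partitioning, so every fold sees the
    same negative pool.
    """
    for p in ligands:
        if not MIN_TRAIN_LENGTH <= len(p.sequence) <= MAX_TRAIN_LENGTH:
            raise ValueError(
                f"training ligand {p.sequence!r} outside the 11-19 length range"
            )
    negatives = sample_negatives(ligands, proteome, rng=rng)
    instances = list(ligands) + negatives + list(ba or [])
    labels = common_motif_partition(instances, k)
    for p, lab in zip(instances, labels):
        p.partition = int(lab)
    per_len: dict[int, int] = {}
    for p in negatives:
        per_len[len(p.sequence)] = per_len.get(len(p.sequence), 0) + 1
    return TrainingSet(instances=instances, negatives_added=per_len,
                       partition_labels=labels)
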