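"""Benchmark metrics and epitope evaluation protocols.

AUC is the Mann-Whitney probability that a random positive outscores a
random negative (ties count one half). AUC 0.1 integrates the ROC curve up
to a false-positive rate of 10% and is normalized by 0.1 so a perfect
classifier scores 1. PPV sorts all predictions and takes the fraction of
true positives among the top N, N being the number of positives — the metric
of choice for the ~10:1 negative:positive imbalance of elution data.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .alphabet import is_standard
from .data import flank_context
from .encoding import CORE_LENGTH, PeptideInstance

logger = logging.getLogger(__name__)


def _validate(y_true, y_score, need_both=True):
    y_true = np.asarray(y_true, dtype=np.float64)
    y_score = np.asarray(y_score, dtype=np.float64)
    if y_true.shape != y_score.shape:
        raise ValueError("labels and scores must have the same length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos + n_neg != len(y_true):
        raise ValueError("labels must be 0/1")
    if need_both and (n_pos == 0 or n_neg == 0):
        raise ValueError(
            f"AUC-type metrics need both classes (got {n_pos} positives, "
            f"{n_neg} negatives)"
        )
    return y_true, y_score, n_pos, n_neg


def auc(y_true, y_score) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity."""
    y_true, y_score, n_pos, n_neg = _validate(y_true, y_score)
    ranks = rankdata(y_score)  # average ranks: ties count 1/2
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(y_true, y_score):
    """ROC points (fpr, tpr) at every distinct threshold, descending, with
    (0, 0) prepended. Tied scores move together."""
    y_true, y_score, n_pos, n_neg = _validate(y_true, y_score)
    order = np.argsort(-y_score, kind="stable")
    ys = y_score[order]
    yt = y_true[order]
    # indices where a threshold group ends
    distinct = np.flatnonzero(np.diff(ys)) if len(ys) > 1 else np.array([], dtype=int)
    ends = np.concatenate([distinct, [len(ys) - 1]])
    tps = np.cumsum(yt)[ends]
    fps = np.cumsum(1 - yt)[ends]
    fpr = np.concatenate([[0.0], fps / n_neg])
    tpr = np.concatenate([[0.0], tps / n_pos])
    return fpr, tpr


def auc01(y_true, y_score, max_fpr: float = 0.1, normalize: bool = True) -> float:
    """Partial ROC area over FPR in [0, max_fpr], trapezoidal, divided by
    ``max_fpr`` so a perfect classifier scores 1."""
    fpr, tpr = roc_curve(y_true, y_score)
    area = 0.0
    for i in range(1, len(fpr)):
        x0, x1 = fpr[i - 1], fpr[i]
        y0, y1 = tpr[i - 1], tpr[i]
        if x0 >= max_fpr:
            break
        if x1 > max_fpr:
            # linear interpolation at the cut
            y1 = y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0)
            x1 = max_fpr
        area += 0.5 * (y0 + y1) * (x1 - x0)
    return float(area / max_fpr) if normalize else float(area)


def ppv(y_true, y_score) -> float:
    """Fraction of true positives among the top-N predictions (N = number of
    positives); tied scores keep their input order."""
    y_true, y_score, n_pos, _ = _validate(y_true, y_score, need_both=False)
    if n_pos == 0:
        raise ValueError("PPV needs at least one positive")
    order = np.argsort(-y_score, kind="stable")
    return float(y_true[order[:n_pos]].mean())


# -- 9mer overlap handling ------------------------------------------------


def nine_mers(seq: str) -> set[str]:
    return {seq[i : i + CORE_LENGTH] for i in range(len(seq) - CORE_LENGTH + 1)}


def _sequence_of(p) -> str:
    return p.sequence if isinstance(p, PeptideInstance) else p


def filter_9mer_overlap(eval_set: list, train_set: list) -> list:
    """Drop every evaluation peptide sharing an identical 9mer substring with
    any training peptide. Idempotent."""
    train_mers: set[str] = set()
    for p in train_set:
        train_mers |= nine_mers(_sequence_of(p))
    kept = [p for p in eval_set if not (nine_mers(_sequence_of(p)) & train_mers)]
    if len(kept) < len(eval_set):
        logger.info("9mer-overlap filter removed %d of %d evaluation peptides",
                    len(eval_set) - len(kept), len(eval_set))
    return kept


# -- epitope benchmarks ---------------------------------------------------

EPITOPE_MIN_LENGTH = 14
EPITOPE_MAX_LENGTH = 19
SCAN_MIN_LENGTH = 13
SCAN_MAX_LENGTH = 21


def _window_instances(protein: str, length: int) -> list[PeptideInstance]:
    out = []
    for i in range(len(protein) - length + 1):
        up, down = flank_context(protein, i, i + length)
        out.append(PeptideInstance(sequence=protein[i : i + length],
                                   data_type="EL", context_up=up,
                                   context_down=down))
    return out


def _score_windows(model, windows: list[PeptideInstance]) -> np.ndarray:
    if callable(model) and not hasattr(model, "predict"):
        return np.asarray([model(w.sequence) for w in windows], dtype=np.float64)
    return np.asarray(model.predict(windows), dtype=np.float64)


def _epitope_labels_and_mask(windows, epitope):
    """Positive = window identical to the epitope; negatives sharing a 9mer
    substring with the epitope are excluded from evaluation."""
    epi_mers = nine_mers(epitope)
    labels, keep = [], []
    for w in windows:
        if w.sequence == epitope:
            labels.append(1)
            keep.append(True)
        else:
            labels.append(0)
            keep.append(not (nine_mers(w.sequence) & epi_mers))
    return np.asarray(labels), np.asarray(keep)


def epitope_auc_direct(epitope: str, protein: str, model) -> float:
    """Per source-protein AUC: digest the protein into epitope-length windows,
    score each with the model's eluted-ligand output, and rank the epitope
    against the non-overlapping windows."""
    if epitope not in protein:
        raise ValueError("epitope does not occur in the source protein")
    if len(protein) <= len(epitope):
        raise ValueError("source protein must be longer than the epitope")
    windows = _window_instances(protein, len(epitope))
    labels, keep = _epitope_labels_and_mask(windows, epitope)
    scores = _score_windows(model, windows)
    return auc(labels[keep], scores[keep])


def epitope_auc_ligand_preference(epitope: str, protein: str, model) -> float:
    """Ligand-preference AUC: every 13-21mer window of the protein is scored,
    and each epitope-length window receives the mean score of all 13-21mers
    overlapping it by at least nine positions; AUC is then computed as in the
    direct benchmark."""
    if epitope not in protein:
        raise ValueError("epitope does not occur in the source protein")
    if len(protein) < SCAN_MIN_LENGTH:
        raise ValueError("source protein shorter than any 13-21mer window")
    scan, scan_pos, scan_len = [], [], []
    for m in range(SCAN_MIN_LENGTH, SCAN_MAX_LENGTH + 1):
        ws = _window_instances(protein, m)
        scan.extend(ws)
        scan_pos.extend(range(len(ws)))
        scan_len.extend([m] * len(ws))
    scan_scores = _score_windows(model, scan)
    scan_pos = np.asarray(scan_pos)
    scan_end = scan_pos + np.asarray(scan_len)

    L = len(epitope)
    windows = _window_instances(protein, L)
    scores = np.empty(len(windows))
    for i in range(len(windows)):
        overlap = np.minimum(scan_end, i + L) - np.maximum(scan_pos, i)
        vals = scan_scores[overlap >= CORE_LENGTH]
        if len(vals) == 0:
            scores[i] = 0.0
        elif (vals == vals[0]).all():
            scores[i] = vals[0]  # keep exact ties exact (constant models)
        else:
            scores[i] = vals.mean()
    labels, keep = _epitope_labels_and_mask(windows, epitope)
    return auc(labels[keep], scores[keep])


def load_epitope_table(rows) -> list[tuple[str, str]]:
    """Validate (epitope, protein_id) pairs for the benchmark: epitopes must
    be 14-19 residues of standard amino acids (entries with nonstandard
    letters, e.g. post-translational annotations, are dropped with a log
    line)."""
    kept, dropped = [], 0
    for epitope, protein_id in rows:
        if not is_standard(epitope):
            dropped += 1
            continue
        if not EPITOPE_MIN_LENGTH <= len(epitope) <= EPITOPE_MAX_LENGTH:
            raise ValueError(
                f"epitope length {len(epitope)} outside the benchmark range "
                f"{EPITOPE_MIN_LENGTH}-{EPITOPE_MAX_LENGTH}"
            )
        kept.append((epitope, protein_id))
    if dropped:
        logger.info("dropped %d epitopes with nonstandard residues", dropped)
    return kept
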