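"""Scikit-learn style estimator over the cross-validated network ensemble.

``MHCIILigandPredictor`` is the package's main entry point: ``fit`` takes a
mixed list of binding-affinity and eluted-ligand instances (or a DataFrame),
partitions them with the common-motif approach, trains the
seeds x hidden-sizes x folds ensemble, and keeps out-of-fold predictions;
``predict`` scores new peptides with the full ensemble. It composes with
scikit-learn tooling through ``get_params``/``set_params``.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .alphabet import HYDROPHOBIC, is_standard
from .encoding import (
    CORE_LENGTH,
    EncoderConfig,
    PeptideInstance,
    encode_dataset,
)
from .training import TrainRunConfig, cross_validate, ensemble_batch_predict

logger = logging.getLogger(__name__)


def instances_from_frame(df: pd.DataFrame) -> list[PeptideInstance]:
    """Build instances from a table with columns ``peptide``, ``target``,
    ``data_type`` and optional ``context_up``/``context_down``/
    ``source_protein_id``/``partition`` ('-' means missing context)."""
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        get = lambda k, default=None: d.get(k, default)
        ctx_u = get("context_up") or "XXX"
        ctx_d = get("context_down") or "XXX"
        part = get("partition")
        out.append(PeptideInstance(
            sequence=d["peptide"],
            target=float(get("target", 0.0)),
            data_type=get("data_type", "EL"),
            context_up="XXX" if ctx_u == "-" else ctx_u,
            context_down="XXX" if ctx_d == "-" else ctx_d,
            source_protein_id=None if get("source_protein_id") in (None, "-")
            else get("source_protein_id"),
            partition=None if part is None or (isinstance(part, float) and np.isnan(part))
            else int(part),
        ))
    return out


def _as_instances(X) -> list[PeptideInstance]:
    if isinstance(X, pd.DataFrame):
        return instances_from_frame(X)
    X = list(X)
    if X and isinstance(X[0], str):
        return [PeptideInstance(sequence=s, data_type="EL") for s in X]
    return X


class MHCIILigandPredictor(BaseEstimator):
    """Cross-validated two-output network ensemble for MHC-II ligands.

    Parameters
    ----------
    seeds : int or sequence of int
        Random seeds per (fold, hidden size); an int means ``range(seeds)``.
    hidden_sizes : sequence of int
        Hidden-layer widths of the ensemble members.
    n_partitions : int
        Cross-validation folds (common-motif partitions).
    iterations, burn_in_iterations, learning_rate, init_weight_range
        Online-training schedule of every member network.
    context_mode : bool
        Present the 12-residue antigen-processing context block to the
        network.
    substitution_matrix, scale, hydrophobic_set
        Residue-encoding configuration.

    Attributes
    ----------
    models_ : list of (fold, seed, hidden, NetworkModel)
    partition_labels_ : ndarray of fold assignments per training instance
    oof_el_, oof_ba_ : out-of-fold scores per training instance
    oof_offset_ : out-of-fold binding-core offsets (eluted-ligand head)
    oof_core_ : out-of-fold binding cores as 9-letter strings
    """

    def __init__(self, seeds=10, hidden_sizes=(2, 10, 20, 40, 60),
                 n_partitions=5, iterations=400, burn_in_iterations=1,
                 learning_rate=0.05, init_weight_range=0.1,
                 context_mode=False, substitution_matrix="BLOSUM50",
                 scale=5.0, hydrophobic_set=HYDROPHOBIC):
        self.seeds = seeds
        self.hidden_sizes = hidden_sizes
        self.n_partitions = n_partitions
        self.iterations = iterations
        self.burn_in_iterations = burn_in_iterations
        self.learning_rate = learning_rate
        self.init_weight_range = init_weight_range
        self.context_mode = context_mode
        self.substitution_matrix = substitution_matrix
        self.scale = scale
        self.hydrophobic_set = hydrophobic_set

    # ------------------------------------------------------------------

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            substitution_matrix=self.substitution_matrix, scale=self.scale,
            hydrophobic_set=self.hydrophobic_set, context_mode=self.context_mode,
        )

    def _run_config(self) -> TrainRunConfig:
        seeds = tuple(range(self.seeds)) if isinstance(self.seeds, (int, np.integer)) \
            else tuple(int(s) for s in self.seeds)
        return TrainRunConfig(
            seeds=seeds, hidden_sizes=tuple(self.hidden_sizes),
            n_partitions=self.n_partitions, context_mode=self.context_mode,
            iterations=self.iterations,
            burn_in_iterations=self.burn_in_iterations,
            learning_rate=self.learning_rate,
            initial_weight_range=self.init_weight_range,
        )

    def fit(self, X, y=None):
        """Train the full cross-validated ensemble.

        ``X`` is a list of :class:`PeptideInstance` (or a DataFrame; see
        :func:`instances_from_frame`) mixing eluted-ligand records (targets
        1/0, lengths 11-19) and binding-affinity records (targets in [0, 1]).
        ``y`` optionally overrides the instance targets. Entries with
        nonstandard residues are dropped with a logged count.
        """
        instances = _as_instances(X)
        if y is not None:
            if len(y) != len(instances):
                raise ValueError("y must align with X")
            for p, t in zip(instances, y):
                p.target = float(t)

        kept = [p for p in instances if is_standard(p.sequence)]
        if len(kept) < len(instances):
            logger.info("dropped %d instances with nonstandard residues",
                        len(instances) - len(kept))
        if not kept:
            raise ValueError("no valid training instances")

        result = cross_validate(kept, self._run_config(), self._encoder_config())
        self.instances_ = kept
        self.models_ = result.models
        self.partition_labels_ = result.partition_labels
        self.oof_el_ = result.oof_el
        self.oof_ba_ = result.oof_ba
        self.oof_offset_ = result.oof_offset
        self.oof_core_ = [
            p.sequence[o : o + CORE_LENGTH]
            for p, o in zip(kept, result.oof_offset)
        ]
        self.encoder_ = self._encoder_config()
        self.n_features_in_ = self.encoder_.feature_dim
        return self

    def _ensemble(self):
        if not hasattr(self, "models_"):
            raise ValueError("this MHCIILigandPredictor instance is not fitted yet")
        return [m for _, _, _, m in self.models_]

    def _encode(self, X):
        instances = _as_instances(X)
        ds = encode_dataset(instances, self.encoder_, strict_length=False)
        return instances, ds

    def predict(self, X, head: str = "EL") -> np.ndarray:
        """Mean ensemble score for each peptide on the requested head."""
        ensemble = self._ensemble()
        _, ds = self._encode(X)
        scores, _ = ensemble_batch_predict(ds, ensemble, head)
        return scores

    def predict_detail(self, X) -> pd.DataFrame:
        """Peptide, binding core (from the best-scoring ensemble member on
        the eluted-ligand head), and both head scores."""
        ensemble = self._ensemble()
        instances, ds = self._encode(X)
        el, off = ensemble_batch_predict(ds, ensemble, "EL")
        ba, _ = ensemble_batch_predict(ds, ensemble, "BA")
        return pd.DataFrame({
            "peptide": [p.sequence for p in instances],
            "core": [p.sequence[o : o + CORE_LENGTH]
                     for p, o in zip(instances, off)],
            "offset": off,
            "score_el": el,
            "score_ba": ba,
        })

    def score(self, X, y) -> float:
        """ROC AUC of the eluted-ligand head against 0/1 labels ``y``."""
        from .metrics import auc

        return auc(np.asarray(y), self.predict(X))
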