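"""Scoring subclonal reconstructions against a known truth.

The clustering accuracy measure is the area under the precision–recall
curve (AUPRC) over unordered SSM pairs: the truth co-clustering matrix M
(M_ij = 1 iff SSMs i and j share a cluster) provides binary labels, and the
posterior-averaged co-clustering matrix provides scores.  The diagonal and
lower triangle are excluded — the diagonal is trivially positive and each
unordered pair is counted once.

The population-count error compares the number of populations surviving
leaf-upward pruning of the best (maximum complete-data likelihood) tree
with the true total population count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .mcmc import ChainSample, best_tree, pruned_population_count

__all__ = [
    "CoclusterMatrix",
    "coclustering",
    "average_coclustering",
    "auprc",
    "population_count_error",
]


@dataclass
class CoclusterMatrix:
    """Square SSM-by-SSM same-cluster matrix.

    Binary for a single clustering; entries in [0, 1] for a posterior
    average.  Symmetric with a unit diagonal.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("co-clustering matrix must be symmetric")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("entries must lie in [0, 1]")

    def reindex(self, ids: Sequence[str]) -> "CoclusterMatrix":
        """Reorder rows/columns to a given id order."""
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return CoclusterMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries, row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CoclusterMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


def coclustering(assignment: Mapping[str, object],
                 ids: Optional[Sequence[str]] = None) -> CoclusterMatrix:
    """Binary co-clustering matrix of one clustering (id -> cluster label)."""
    ids = list(ids) if ids is not None else list(assignment)
    label_index: dict = {}
    labels = np.array([label_index.setdefault(assignment[i], len(label_index))
                       for i in ids])
    values = (labels[:, None] == labels[None, :]).astype(float)
    return CoclusterMatrix(ids, values)


def _sample_assignment(sample: ChainSample) -> dict[str, int]:
    return {mid: spec["id"] for spec in sample.tree["nodes"]
            for mid in spec["mutations"]}


def average_coclustering(chain: Sequence[ChainSample],
                         ids: Optional[Sequence[str]] = None,
                         include_pseudo: bool = False) -> CoclusterMatrix:
    """Entrywise mean of the per-sample binary co-clustering matrices.

    By default pseudo-SSMs (ids starting ``cnv_``) are excluded, since the
    truth clustering is defined over SSMs.
    """
    if not chain:
        raise ValueError("empty chain")
    if ids is None:
        ids = [mid for mid in _sample_assignment(chain[0])
               if include_pseudo or not mid.startswith("cnv_")]
    ids = list(ids)
    total = np.zeros((len(ids), len(ids)))
    for sample in chain:
        assignment = _sample_assignment(sample)
        total += coclustering(assignment, ids).values
    return CoclusterMatrix(ids, total / len(chain))


def auprc(predicted: CoclusterMatrix, truth: CoclusterMatrix) -> float:
    """Area under the precision–recall curve of the predicted co-clustering
    scores against the binary truth, over unordered off-diagonal pairs
    (step-wise integration)."""
    if set(predicted.ids) != set(truth.ids):
        raise ValueError("predicted and truth matrices cover different ids")
    predicted = predicted.reindex(truth.ids)
    y_true = truth.upper_triangle()
    if not np.all(np.isin(y_true, (0.0, 1.0))):
        raise ValueError("truth matrix must be binary")
    if not np.any(y_true):
        raise ValueError("truth has no positive pair; AUPRC undefined")
    return float(average_precision_score(y_true.astype(int), predicted.upper_triangle()))


def population_count_error(chain: Sequence[ChainSample], true_count: int) -> int:
    """Signed error in the number of populations: pruned count of the
    maximum-likelihood tree minus the true total count (normal included)."""
    return pruned_population_count(best_tree(chain)) - int(true_count)
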