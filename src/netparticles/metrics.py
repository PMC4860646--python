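"""Partition comparison: confusion matrix and normalized mutual information.

The NMI used here is the confusion-matrix form of Danon et al.:

    NMI = -2 sum_ij N_ij ln(N_ij N / (N_i N_j))
          / [ sum_i N_i ln(N_i/N) + sum_j N_j ln(N_j/N) ]

with natural logarithms, 0 ln 0 = 0, rows indexing the expected communities
and columns the found ones.  It is 1 iff the two partitions are identical up
to relabeling and 0 when the found partition carries no information about
the expected one.  When both partitions are the single trivial community the
ratio is 0/0 and NMI is defined as 1 (the partitions are identical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netparticles.graphs import Partition


@dataclass(frozen=True)
class ConfusionMatrix:
    """N_ij = #nodes in expected community i and found community j."""

    counts: np.ndarray  # M_R x M_F
    expected_ids: tuple[int, ...]
    found_ids: tuple[int, ...]

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _check_nodes(expected: Partition, found: Partition) -> None:
    if expected.nodes != found.nodes:
        raise ValueError("partitions cover different node sets")


def confusion_matrix(expected: Partition, found: Partition) -> ConfusionMatrix:
    """Tally the expected-vs-found community co-occurrence counts."""
    _check_nodes(expected, found)
    exp_ids = sorted(set(expected.labels.values()))
    fnd_ids = sorted(set(found.labels.values()))
    exp_index = {c: i for i, c in enumerate(exp_ids)}
    fnd_index = {c: j for j, c in enumerate(fnd_ids)}
    counts = np.zeros((len(exp_ids), len(fnd_ids)), dtype=np.int64)
    for node in expected.labels:
        counts[exp_index[expected.labels[node]], fnd_index[found.labels[node]]] += 1
    return ConfusionMatrix(counts, tuple(exp_ids), tuple(fnd_ids))


def nmi(expected: Partition, found: Partition) -> float:
    """Normalized mutual information between two partitions, in [0, 1]."""
    _check_nodes(expected, found)
    if not expected.labels:
        raise ValueError("partitions are empty")
    cm = confusion_matrix(expected, found)
    counts = cm.counts.astype(float)
    n = cm.total
    ni = cm.row_sums.astype(float)
    nj = cm.col_sums.astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log(counts * n / np.outer(ni, nj))
    numer = -2.0 * float(np.sum(counts[counts > 0] * log_term[counts > 0]))
    denom = float(np.sum(ni * np.log(ni / n)) + np.sum(nj * np.log(nj / n)))
    if denom == 0.0:
        # both partitions trivial (one community each): identical
        return 1.0
    value = numer / denom
    # clamp tiny negative / >1 float noise
    return float(min(max(value, 0.0), 1.0))
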