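"""Gap-only pairwise distances over a multiple sequence alignment.

The distance between two aligned rows counts only alignment columns
where exactly one of the two rows is gapped, normalized by the
pairwise effective length (columns where at least one of the two rows
has a residue).  Amino-acid substitutions contribute nothing: two
sequences that are 90% identical but align end-to-end without gaps are
at distance zero, while 100%-identical residues separated by a
5-column gap in a 100-column pairwise span are at distance 0.05.

Columns gapped in *both* rows of a pair are excluded from numerator
and denominator alike — they are insertions belonging to a third
sequence and would otherwise create phantom distance between two rows
with identical gap structure.  Terminal gaps count exactly like
internal gaps, so members of low-cost clades necessarily have very
similar lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import MultipleAlignment


@dataclass
class GapDistanceMatrix:
    """Symmetric gap-only distance matrix with pairwise effective lengths."""

    labels: list[str]
    d: np.ndarray        # (n, n) float, fractions in [0, 1]
    pair_len: np.ndarray  # (n, n) int, columns with >=1 residue in the pair

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix_max(self, labels) -> float:
        """Maximum pairwise distance within a label subset."""
        idx = [self._index[lab] for lab in labels]
        if len(idx) < 2:
            return 0.0
        return float(self.d[np.ix_(idx, idx)].max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        """Debug dump: labels header plus lower triangle."""
        with open(path, "w") as fh:
            fh.write("\t".join(self.labels) + "\n")
            for i in range(len(self.labels)):
                fh.write(
                    "\t".join(f"{self.d[i, j]:.6g}" for j in range(i + 1)) + "\n"
                )


def gap_distance_pair(row_a: str, row_b: str) -> tuple[float, int, int]:
    """Gap distance between two aligned rows.

    Returns ``(distance, pair_len, gap_cols)`` where ``gap_cols`` is the
    number of columns with a gap in exactly one row and ``pair_len`` the
    number of columns with a residue in at least one row.

    Raises
    ------
    ValueError
        If the rows differ in length or every column is gapped in both
        rows (degenerate pair).
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    ga = np.frombuffer(row_a.encode(), dtype="S1") == b"-"
    gb = np.frombuffer(row_b.encode(), dtype="S1") == b"-"
    both = int(np.count_nonzero(ga & gb))
    gap_cols = int(np.count_nonzero(ga ^ gb))
    pair_len = len(row_a) - both
    if pair_len == 0:
        raise ValueError("degenerate pair: no column with a residue")
    return gap_cols / pair_len, pair_len, gap_cols


def gap_distance_matrix(msa: MultipleAlignment) -> GapDistanceMatrix:
    """Compute the full gap-distance matrix for an MSA (>=2 rows).

    Vectorized over the gap indicator matrix: for rows *i*, *j* with gap
    counts :math:`g_i, g_j` and shared-gap count :math:`B_{ij}`, the
    one-sided gap count is :math:`g_i + g_j - 2B_{ij}` and the pairwise
    effective length is :math:`L - B_{ij}`.
    """
    if len(msa.rows) < 2:
        raise ValueError(f"{msa.orthogroup_id}: need >=2 rows for a distance matrix")
    labels = [acc for acc, _ in msa.rows]
    n_cols = msa.n_cols
    gap = np.zeros((len(labels), n_cols), dtype=bool)
    for i, (_, row) in enumerate(msa.rows):
        if len(row) != n_cols:
            raise ValueError(f"{msa.orthogroup_id}: ragged row {labels[i]}")
        gap[i] = np.frombuffer(row.encode(), dtype="S1") == b"-"

    g = gap.sum(axis=1).astype(np.int64)
    both = (gap.astype(np.int64) @ gap.T.astype(np.int64))
    one_sided = g[:, None] + g[None, :] - 2 * both
    pair_len = n_cols - both
    if np.any((pair_len == 0) & ~np.eye(len(labels), dtype=bool)):
        i, j = np.argwhere((pair_len == 0) & ~np.eye(len(labels), dtype=bool))[0]
        raise ValueError(
            f"{msa.orthogroup_id}: degenerate pair ({labels[i]}, {labels[j]})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pair_len > 0, one_sided / np.maximum(pair_len, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return GapDistanceMatrix(labels=labels, d=d, pair_len=pair_len)
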