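"""Search a gap-distance tree for low-cost multi-proteome clades.

A candidate clade holds at most one sequence per proteome and certifies
that *every* pair of its members aligns near-gaplessly: its cost is the
maximum pairwise gap distance within the clade, so cost 0 means all
members align without gaps.  Clades must span at least
``min_proteomes`` distinct proteomes (default 3, the same floor applied
to orthogroups) and cost at most ``cost_threshold`` (default 0.02,
inclusive).

When a tree clade contains several sequences from one proteome —
isoforms of one gene often co-cluster — the member minimizing the
summed gap distance to the clade's other-proteome members is kept
(ties: canonical first, then reviewed, then smallest accession).
Candidates from nested tree nodes are deduplicated keeping the largest
proteome coverage, then the lowest cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .gapdist import GapDistanceMatrix
from .io import SequenceRecord
from .njtree import clades_of

logger = logging.getLogger(__name__)

DEFAULT_COST_THRESHOLD = 0.02
DEFAULT_MIN_PROTEOMES = 3

#: proteomes whose reviewed entries count toward ranking criterion (iv)
REVIEWED_RANK_PROTEOMES = ("HUMAN", "MOUSE")


@dataclass
class CladeCandidate:
    """A low-cost clade: <=1 member per proteome, with ranking features."""

    orthogroup_id: str
    members: dict[str, SequenceRecord]  # proteome_id -> record
    cost: float
    source_leaves: frozenset[str] = field(default_factory=frozenset)
    length_penalty: float = 0.0

    @property
    def n_proteomes(self) -> int:
        return len(self.members)

    @property
    def n_canonical(self) -> int:
        return sum(1 for m in self.members.values() if m.is_canonical)

    @property
    def n_reviewed_hm(self) -> int:
        return sum(
            1
            for m in self.members.values()
            if m.is_reviewed and m.proteome_id in REVIEWED_RANK_PROTEOMES
        )

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(m.accession for m in self.members.values())

    @property
    def gene_groups(self) -> frozenset[str]:
        return frozenset(
            m.gene_group_id for m in self.members.values() if m.gene_group_id
        )

    @property
    def member_lengths(self) -> list[int]:
        return [m.length for m in self.members.values()]


def clade_cost(leaf_set: Iterable[str], matrix: GapDistanceMatrix) -> float:
    """Cost of a leaf set: maximum pairwise gap distance.

    Zero iff no pair has a one-sided gap column.  A singleton has cost 0
    by convention (warned — a one-member clade certifies nothing).
    """
    leaves = list(leaf_set)
    if len(leaves) < 2:
        logger.warning("clade_cost on singleton %s", leaves)
        return 0.0
    return matrix.submatrix_max(leaves)


def resolve_duplicates(
    leaves: Iterable[str],
    matrix: GapDistanceMatrix,
    records: Mapping[str, SequenceRecord],
) -> dict[str, SequenceRecord]:
    """Reduce a leaf set to at most one member per proteome.

    The survivor of a duplicated proteome minimizes its summed gap
    distance to the clade's members from *other* proteomes; ties prefer
    canonical, then reviewed, then lexicographically smallest accession.
    """
    by_proteome: dict[str, list[SequenceRecord]] = {}
    for acc in leaves:
        rec = records[acc]
        by_proteome.setdefault(rec.proteome_id, []).append(rec)

    chosen: dict[str, SequenceRecord] = {}
    for proteome, recs in by_proteome.items():
        if len(recs) == 1:
            chosen[proteome] = recs[0]
            continue
        others = [
            acc
            for acc in leaves
            if records[acc].proteome_id != proteome
        ]

        def key(rec: SequenceRecord):
            summed = sum(matrix.distance(rec.accession, o) for o in others)
            return (summed, not rec.is_canonical, not rec.is_reviewed, rec.accession)

        chosen[proteome] = min(recs, key=key)
    return chosen


def find_low_cost_clades(
    tree,
    matrix: GapDistanceMatrix,
    records: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    orthogroup_id: str = "",
    cost_threshold: float = DEFAULT_COST_THRESHOLD,
    min_proteomes: int = DEFAULT_MIN_PROTEOMES,
) -> list[CladeCandidate]:
    """Exhaustively scan tree nodes for low-cost multi-proteome clades.

    Every internal node whose leaf set — after per-proteome duplicate
    resolution — spans >= ``min_proteomes`` proteomes at cost <=
    ``cost_threshold`` yields one candidate.  Nested or identical
    candidates are deduplicated: a candidate whose member set is
    contained in another's is dropped (largest proteome coverage wins,
    then lowest cost).  An empty result is a valid outcome.
    """
    if not isinstance(records, Mapping):
        records = {r.accession: r for r in records}

    raw: list[CladeCandidate] = []
    seen: set[frozenset[str]] = set()
    for _node, leaves in clades_of(tree):
        members = resolve_duplicates(leaves, matrix, records)
        if len(members) < min_proteomes:
            continue
        accs = frozenset(m.accession for m in members.values())
        if accs in seen:
            continue
        cost = clade_cost(accs, matrix)
        if cost > cost_threshold:
            continue
        seen.add(accs)
        raw.append(
            CladeCandidate(
                orthogroup_id=orthogroup_id,
                members=members,
                cost=cost,
                source_leaves=leaves,
            )
        )

    # keep only maximal member sets; sort big-first so subsets drop out
    raw.sort(key=lambda c: (-c.n_proteomes, c.cost, sorted(c.accessions)))
    kept: list[CladeCandidate] = []
    for cand in raw:
        if any(cand.accessions < other.accessions for other in kept):
            continue
        kept.append(cand)
    return kept


def dump_candidates_tsv(candidates: Iterable[CladeCandidate], path) -> None:
    """Audit dump: one row per candidate clade."""
    with open(path, "w") as fh:
        fh.write("orthogroup_id\tn_proteomes\tcost\tmembers\n")
        for c in candidates:
            members = ",".join(
                f"{p}:{r.accession}" for p, r in sorted(c.members.items())
            )
            fh.write(f"{c.orthogroup_id}\t{c.n_proteomes}\t{c.cost:.6g}\t{members}\n")
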