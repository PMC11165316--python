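"""Rank low-cost clades, pick non-overlapping winners, emit suggestions.

Candidates within an orthogroup are ranked lexicographically on:

(i)   clade cost (lower first),
(ii)  number of proteomes covered (more first),
(iii) number of current-canonical members (more first),
(iv)  number of reviewed human/mouse members (more first),
(v)   length penalty — relative deviation of the clade's median member
      length from the median of the gene groups' current canonical
      lengths (smaller first),

with the smallest member accession as a final deterministic tie-break.
The best candidate is selected first; further candidates are selected
only if their Gene-Centric gene groups are disjoint from everything
already selected.

Each member of a selected clade yields one suggestion: ``confirm`` if
the member is its gene group's current canonical, otherwise
``propose_change`` — except that a reviewed (Swiss-Prot) current
canonical is never changed automatically and is emitted as
``flag_reviewed`` for curator review.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .cladefind import CladeCandidate
from .io import SequenceRecord

logger = logging.getLogger(__name__)

ACTION_CONFIRM = "confirm"
ACTION_PROPOSE = "propose_change"
ACTION_FLAG_REVIEWED = "flag_reviewed"


@dataclass
class Suggestion:
    orthogroup_id: str
    proteome_id: str
    gene_group_id: str
    old_canonical: str
    new_canonical: str
    action: str
    clade_cost: float = 0.0
    clade_size: int = 0
    rank: int = 0


def length_penalty(
    clade: CladeCandidate, canonical_lengths: Sequence[int]
) -> float:
    """Relative deviation of clade median length from canonical median.

    ``|median(member lengths) - median(canonical lengths)| /
    median(canonical lengths)``; 0 (with a warning) when no canonical
    lengths are available.
    """
    if not canonical_lengths:
        logger.warning("length_penalty: empty canonical length set")
        return 0.0
    med_canon = statistics.median(canonical_lengths)
    med_members = statistics.median(clade.member_lengths)
    return abs(med_members - med_canon) / med_canon


def rank_key(clade: CladeCandidate):
    return (
        clade.cost,
        -clade.n_proteomes,
        -clade.n_canonical,
        -clade.n_reviewed_hm,
        clade.length_penalty,
        min(clade.accessions),
    )


def rank_clades(
    candidates: Iterable[CladeCandidate],
    canonical_lengths: Sequence[int] | None = None,
) -> list[CladeCandidate]:
    """Order candidates of one orthogroup by criteria (i)-(v).

    When ``canonical_lengths`` is given, each candidate's
    ``length_penalty`` is (re)computed against it first.
    """
    candidates = list(candidates)
    if canonical_lengths is not None:
        for c in candidates:
            c.length_penalty = length_penalty(c, canonical_lengths)
    return sorted(candidates, key=rank_key)


def select_clades(ranked: Sequence[CladeCandidate]) -> list[CladeCandidate]:
    """Greedy non-overlapping selection over Gene-Centric gene groups.

    Take the best-ranked candidate, then every further candidate whose
    gene groups are disjoint from all groups already covered.
    """
    selected: list[CladeCandidate] = []
    covered: set[str] = set()
    for cand in ranked:
        if cand.gene_groups & covered:
            continue
        selected.append(cand)
        covered |= cand.gene_groups
    return selected


def emit_suggestions(
    selected: Sequence[CladeCandidate],
    canonical_of_group: Mapping[str, SequenceRecord],
) -> list[Suggestion]:
    """Turn selected clades into per-member suggestions.

    ``canonical_of_group`` maps a gene_group_id to its current canonical
    record.  Members without a gene group are skipped with a warning.
    A clade member that *is* the current canonical is confirmed; any
    other member proposes replacing the canonical with the member's base
    accession, unless the current canonical is reviewed, in which case
    the row is flagged for curators instead of changed.
    """
    suggestions: list[Suggestion] = []
    for rank, clade in enumerate(selected, start=1):
        for proteome in sorted(clade.members):
            member = clade.members[proteome]
            if not member.gene_group_id:
                logger.warning(
                    "%s: member %s has no gene group; skipped",
                    clade.orthogroup_id,
                    member.accession,
                )
                continue
            old = canonical_of_group.get(member.gene_group_id)
            if old is None:
                logger.warning(
                    "%s: gene group %s has no canonical on record; skipped",
                    clade.orthogroup_id,
                    member.gene_group_id,
                )
                continue
            if member.accession == old.accession:
                action, new = ACTION_CONFIRM, old.accession
            elif old.is_reviewed:
                action, new = ACTION_FLAG_REVIEWED, member.base_accession
            else:
                action, new = ACTION_PROPOSE, member.base_accession
            suggestions.append(
                Suggestion(
                    orthogroup_id=clade.orthogroup_id,
                    proteome_id=proteome,
                    gene_group_id=member.gene_group_id,
                    old_canonical=old.accession,
                    new_canonical=new,
                    action=action,
                    clade_cost=clade.cost,
                    clade_size=clade.n_proteomes,
                    rank=rank,
                )
            )
    return suggestions


def canonical_lengths_of(records: Iterable[SequenceRecord]) -> list[int]:
    """Current-canonical lengths across an orthogroup's records."""
    return [r.length for r in records if r.is_canonical]


def canonical_by_group(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Map gene_group_id -> its current canonical record."""
    out: dict[str, SequenceRecord] = {}
    for r in records:
        if r.is_canonical and r.gene_group_id:
            if r.gene_group_id in out:
                logger.warning(
                    "gene group %s has two canonicals (%s, %s); keeping first",
                    r.gene_group_id,
                    out[r.gene_group_id].accession,
                    r.accession,
                )
                continue
            out[r.gene_group_id] = r
    return out
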