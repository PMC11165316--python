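"""Extend human-anchored orthogroup assignments to other proteomes.

Panther assigns orthogroups to human accessions; a target-proteome
sequence inherits the orthogroup of its best qualifying hit against
the human proteome.  A hit qualifies when it is at least 50% identical
and covers strictly more than 75% of the human sequence length; both
boundaries are configurable (the identity floor is inclusive, the
coverage floor exclusive, by default).

Coverage is measured over the human sequence: the numerator is the
alignment length minus the gap columns on the human side of the
alignment (a dash in the human row consumes no human residues),
divided by the human sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .gapstats import Gap, decode_btop
from .io import SearchHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingRule:
    """Identity/coverage thresholds for orthogroup inheritance."""

    min_identity: float = 0.50   # fraction of aligned positions identical
    min_coverage: float = 0.75   # fraction of the human sequence aligned
    identity_inclusive: bool = True    # ">=" on identity
    coverage_inclusive: bool = False   # ">" on coverage

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("thresholds must be fractions in (0, 1]")

    def identity_ok(self, identity: float) -> bool:
        return (
            identity >= self.min_identity
            if self.identity_inclusive
            else identity > self.min_identity
        )

    def coverage_ok(self, coverage: float) -> bool:
        return (
            coverage >= self.min_coverage
            if self.coverage_inclusive
            else coverage > self.min_coverage
        )


def human_coverage(hit: SearchHit, human_side: str = "subject") -> float:
    """Fraction of the human sequence covered by the alignment.

    ``human_side`` declares whether the human sequence is the hit's
    query or subject.  Gap columns on the human side (dash in the human
    row) are subtracted from the alignment length before dividing by
    the human sequence length.
    """
    human_len = hit.subject_len if human_side == "subject" else hit.query_len
    if human_len <= 0:
        raise ValueError(
            f"{hit.query_acc} vs {hit.subject_acc}: human length unknown"
        )
    gaps_in_human = 0
    if hit.btop:
        gaps_in_human = sum(
            ev.length
            for ev in decode_btop(hit.btop)
            if isinstance(ev, Gap) and ev.side == human_side
        )
    return (hit.align_len - gaps_in_human) / human_len


def extend_orthogroups(
    hits: Iterable[SearchHit],
    human_orthogroup_map: Mapping[str, str],
    rule: MappingRule = MappingRule(),
    human_side: str = "subject",
) -> dict[str, str]:
    """Assign target accessions to orthogroups via best qualifying hits.

    ``human_orthogroup_map`` maps human accession -> orthogroup id.
    Among a target sequence's qualifying hits the highest identity wins,
    ties by coverage, then by human accession; the result is independent
    of hit file order.  Hits whose human partner is absent from the map
    are ignored with a warning.
    """
    if human_side not in ("query", "subject"):
        raise ValueError("human_side must be 'query' or 'subject'")

    best: dict[str, tuple[float, float, str, str]] = {}
    for hit in hits:
        if human_side == "subject":
            target_acc, human_acc = hit.query_acc, hit.subject_acc
        else:
            target_acc, human_acc = hit.subject_acc, hit.query_acc
        orthogroup = human_orthogroup_map.get(human_acc)
        if orthogroup is None:
            logger.warning(
                "hit %s vs %s: human accession not in orthogroup map; ignored",
                hit.query_acc,
                hit.subject_acc,
            )
            continue
        identity = hit.percent_identity / 100.0
        coverage = human_coverage(hit, human_side)
        if not (rule.identity_ok(identity) and rule.coverage_ok(coverage)):
            continue
        # higher identity, then higher coverage, then smallest human acc
        key = (-identity, -coverage, human_acc)
        cur = best.get(target_acc)
        if cur is None or key < cur[:3]:
            best[target_acc] = (*key, orthogroup)
    return {acc: entry[3] for acc, entry in sorted(best.items())}


def write_assignment_tsv(assignments: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\torthogroup_id\n")
        for acc in sorted(assignments):
            fh.write(f"{acc}\t{assignments[acc]}\n")
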