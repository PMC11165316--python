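"""Alignment gap diagnostics from BTOP-encoded pairwise searches.

BTOP (BLAST trace-back operations) compactly encodes a pairwise
alignment: an integer is a run of identities, a pair of residue
letters is a mismatch (query letter first), a residue letter followed
by ``-`` is a column gapped in the *subject*, and ``-`` followed by a
residue letter is a column gapped in the *query*.

From decoded alignments this module computes per-alignment identity
and gap statistics (maximum gap length, counts of gaps above length
thresholds) and aggregates per-proteome-pair distributions: the
fraction of alignments in each identity bin carrying a gap of at least
a given length — the diagnostic that separates artifactual
isoform-selection gaps from ordinary evolutionary divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SearchHit

GAP_QUERY = "query"      # '-' in the query row
GAP_SUBJECT = "subject"  # '-' in the subject row

DEFAULT_GAP_THRESHOLDS = (5, 10, 50)


class BtopError(ValueError):
    """Malformed BTOP string; carries the character offset."""


@dataclass(frozen=True)
class Identity:
    length: int


@dataclass(frozen=True)
class Mismatch:
    query: str
    subject: str


@dataclass(frozen=True)
class Gap:
    side: str       # GAP_QUERY or GAP_SUBJECT: which row holds the dash
    residues: str   # letters on the non-dash side, one per gap column

    @property
    def length(self) -> int:
        return len(self.residues)


Event = Identity | Mismatch | Gap


def decode_btop(btop: str) -> list[Event]:
    """Decode a BTOP string into an ordered event list.

    Adjacent gap columns on the same side merge into one gap event.
    Raises :class:`BtopError` with the offending offset for characters
    outside the grammar.
    """
    events: list[Event] = []
    i, n = 0, len(btop)

    def push(ev: Event) -> None:
        if events and isinstance(ev, Gap) and isinstance(events[-1], Gap):
            last = events[-1]
            if last.side == ev.side:
                events[-1] = Gap(ev.side, last.residues + ev.residues)
                return
        events.append(ev)

    while i < n:
        c = btop[i]
        if c.isdigit():
            j = i
            while j < n and btop[j].isdigit():
                j += 1
            run = int(btop[i:j])
            if run > 0:
                push(Identity(run))
            i = j
            continue
        if i + 1 >= n:
            raise BtopError(f"dangling character {c!r} at offset {i}")
        d = btop[i + 1]
        if c == "-" and d.isalpha():
            push(Gap(GAP_QUERY, d))
        elif c.isalpha() and d == "-":
            push(Gap(GAP_SUBJECT, c))
        elif c.isalpha() and d.isalpha():
            push(Mismatch(c, d))
        else:
            raise BtopError(f"illegal pair {c + d!r} at offset {i}")
        i += 2

    # merge adjacent identity runs (e.g. from "3" after a merged gap)
    merged: list[Event] = []
    for ev in events:
        if merged and isinstance(ev, Identity) and isinstance(merged[-1], Identity):
            merged[-1] = Identity(merged[-1].length + ev.length)
        else:
            merged.append(ev)
    return merged


def encode_btop(events: Iterable[Event]) -> str:
    """Re-encode an event list into the canonical BTOP string.

    Inverse of :func:`decode_btop` for canonical inputs (gap-merged,
    no zero-length identity runs): ``encode(decode(s)) == s``.
    """
    parts: list[str] = []
    for ev in events:
        if isinstance(ev, Identity):
            parts.append(str(ev.length))
        elif isinstance(ev, Mismatch):
            parts.append(ev.query + ev.subject)
        elif ev.side == GAP_QUERY:
            parts.append("".join("-" + r for r in ev.residues))
        else:
            parts.append("".join(r + "-" for r in ev.residues))
    return "".join(parts)


@dataclass
class AlignmentSummary:
    """Identity and gap statistics of one pairwise alignment."""

    query_acc: str
    subject_acc: str
    align_len: int
    n_identical: int
    gap_events: list[tuple[str, int]] = field(default_factory=list)

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.n_identical / self.align_len if self.align_len else 0.0

    @property
    def max_gap(self) -> int:
        return max((length for _, length in self.gap_events), default=0)

    def n_gaps_ge(self, threshold: int) -> int:
        return sum(1 for _, length in self.gap_events if length >= threshold)


def expanded_length(events: Iterable[Event]) -> int:
    """Number of alignment columns an event list spans."""
    total = 0
    for ev in events:
        if isinstance(ev, Identity):
            total += ev.length
        elif isinstance(ev, Mismatch):
            total += 1
        else:
            total += ev.length
    return total


def summarize_alignment(hit: SearchHit) -> AlignmentSummary:
    """Decode a hit's BTOP into an :class:`AlignmentSummary`.

    The expansion must match the hit's stated alignment length, and the
    derived percent identity must agree with the printed one within 0.1
    (when printed).
    """
    events = decode_btop(hit.btop)
    span = expanded_length(events)
    if hit.align_len and span != hit.align_len:
        raise ValueError(
            f"{hit.query_acc} vs {hit.subject_acc}: BTOP spans {span} columns, "
            f"align_len says {hit.align_len}"
        )
    n_identical = sum(ev.length for ev in events if isinstance(ev, Identity))
    summary = AlignmentSummary(
        query_acc=hit.query_acc,
        subject_acc=hit.subject_acc,
        align_len=span,
        n_identical=n_identical,
        gap_events=[(ev.side, ev.length) for ev in events if isinstance(ev, Gap)],
    )
    if hit.percent_identity and abs(
        summary.percent_identity - hit.percent_identity
    ) > 0.1:
        raise ValueError(
            f"{hit.query_acc} vs {hit.subject_acc}: BTOP identity "
            f"{summary.percent_identity:.2f} != printed {hit.percent_identity:.2f}"
        )
    return summary


def best_hit_filter(
    hits: Iterable[SearchHit],
    min_query_len: int = 100,
    max_evalue: float = 1e-6,
) -> list[AlignmentSummary]:
    """Best significant hit per query, summarized.

    Keeps hits with query length strictly greater than ``min_query_len``
    and E-value strictly below ``max_evalue``; per query the lowest
    E-value wins, ties by higher bit score, then subject accession.
    """
    best: dict[str, SearchHit] = {}
    for h in hits:
        if h.query_len <= min_query_len or not (h.e_value < max_evalue):
            continue
        cur = best.get(h.query_acc)
        if cur is None or (h.e_value, -h.bit_score, h.subject_acc) < (
            cur.e_value,
            -cur.bit_score,
            cur.subject_acc,
        ):
            best[h.query_acc] = h
    return [summarize_alignment(best[q]) for q in sorted(best)]


@dataclass
class PairStats:
    """Aggregated gap statistics for one proteome pair."""

    table: pd.DataFrame       # per identity bin: n, frac with gap >= t
    n_alignments: int
    n_gt90: int               # alignments with identity strictly > 90
    frac_gt90: float          # fraction of all alignments that are > 90% id
    gap_ge_frac_gt90: dict[int, float]  # among >90%-id alignments


def proteome_pair_stats(
    summaries: Sequence[AlignmentSummary],
    id_bins: Sequence[float] | None = None,
    gap_thresholds: Sequence[int] = DEFAULT_GAP_THRESHOLDS,
) -> PairStats:
    """Distribution of gap lengths versus percent identity.

    ``id_bins`` are half-open bin edges ``[lo, hi)``; the default is
    width-1 bins over [0, 101) so that 100% identity lands in the top
    bin.  For each bin the table reports the alignment count and the
    fraction carrying a gap of at least each threshold; the overall
    fraction of alignments that are strictly >90% identical (and, among
    those, the fraction with gaps >= each threshold) is reported
    alongside.
    """
    if id_bins is None:
        id_bins = np.arange(0.0, 102.0, 1.0)
    edges = np.asarray(id_bins, dtype=float)
    pid = np.array([s.percent_identity for s in summaries], dtype=float)
    max_gap = np.array([s.max_gap for s in summaries], dtype=int)

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (pid >= lo) & (pid < hi)
        n = int(mask.sum())
        row = {"id_lo": lo, "id_hi": hi, "n": n}
        for t in gap_thresholds:
            row[f"frac_gap_ge_{t}"] = (
                float((max_gap[mask] >= t).mean()) if n else 0.0
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    gt90 = pid > 90.0
    n_gt90 = int(gt90.sum())
    gap_ge = {
        t: (float((max_gap[gt90] >= t).mean()) if n_gt90 else 0.0)
        for t in gap_thresholds
    }
    return PairStats(
        table=table,
        n_alignments=len(summaries),
        n_gt90=n_gt90,
        frac_gt90=(n_gt90 / len(summaries)) if summaries else 0.0,
        gap_ge_frac_gt90=gap_ge,
    )
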