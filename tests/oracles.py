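"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain python loops and no
calls into the package's own computational code paths, so tests can
compare the implementation against an independent recomputation.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------------------
# gap distances, recomputed column by column
# ---------------------------------------------------------------------------


def pair_gap_distance(row_a: str, row_b: str) -> tuple[float, int, int]:
    """Column-count gap distance between two aligned rows."""
    gap_cols = 0
    pair_len = 0
    for ca, cb in zip(row_a, row_b):
        a_gap, b_gap = ca == "-", cb == "-"
        if a_gap and b_gap:
            continue
        pair_len += 1
        if a_gap != b_gap:
            gap_cols += 1
    return (gap_cols / pair_len if pair_len else 0.0), pair_len, gap_cols


def full_gap_matrix(rows: list[tuple[str, str]]) -> dict[tuple[str, str], float]:
    """All pairwise gap distances keyed by (label_a, label_b)."""
    out = {}
    for (la, ra), (lb, rb) in itertools.combinations(rows, 2):
        d, _, _ = pair_gap_distance(ra, rb)
        out[(la, lb)] = d
        out[(lb, la)] = d
    for la, _ in rows:
        out[(la, la)] = 0.0
    return out


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------


def leaf_sets_of(tree) -> list[frozenset[str]]:
    """Leaf sets of every internal node, by direct recursion."""
    sets = []

    def walk(clade) -> frozenset[str]:
        if not clade.clades:
            return frozenset([clade.name])
        s = frozenset()
        for child in clade.clades:
            s |= walk(child)
        sets.append(s)
        return s

    walk(tree.root)
    return sets


def nontrivial_splits(tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted bipartitions with both sides of size >= 2."""
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    splits = set()
    for side in leaf_sets_of(tree):
        other = all_leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset([side, other]))
    return splits


# ---------------------------------------------------------------------------
# low-cost clade search, brute force
# ---------------------------------------------------------------------------


def brute_force_low_cost_clades(
    tree,
    rows: list[tuple[str, str]],
    records: dict,
    cost_threshold: float,
    min_proteomes: int,
) -> dict[frozenset[str], float]:
    """Recompute candidate clades from the MSA and tree alone.

    Returns ``{member accession set: cost}`` after per-proteome
    duplicate resolution, threshold filtering and maximality dedup —
    the same rules as the implementation, recomputed independently.
    """
    dist = full_gap_matrix(rows)

    found: dict[frozenset[str], float] = {}
    for leaves in leaf_sets_of(tree):
        # duplicate resolution: keep, per proteome, the member with the
        # least summed distance to other-proteome leaves
        proteomes: dict[str, list[str]] = {}
        for acc in leaves:
            proteomes.setdefault(records[acc].proteome_id, []).append(acc)
        chosen = []
        for plist in proteomes.values():
            if len(plist) == 1:
                chosen.append(plist[0])
                continue
            others = [
                a
                for a in leaves
                if records[a].proteome_id != records[plist[0]].proteome_id
            ]
            scored = sorted(
                plist,
                key=lambda a: (
                    sum(dist[(a, o)] for o in others),
                    not records[a].is_canonical,
                    records[a].review_status != "reviewed",
                    a,
                ),
            )
            chosen.append(scored[0])
        if len(chosen) < min_proteomes:
            continue
        cost = max(
            (dist[(a, b)] for a, b in itertools.combinations(sorted(chosen), 2)),
            default=0.0,
        )
        if cost > cost_threshold:
            continue
        key = frozenset(chosen)
        found.setdefault(key, cost)

    # maximality: drop sets strictly contained in another surviving set
    keys = sorted(found, key=len, reverse=True)
    kept: dict[frozenset[str], float] = {}
    for k in keys:
        if any(k < other for other in kept):
            continue
        kept[k] = found[k]
    return kept
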