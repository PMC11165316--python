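"""End-to-end orchestration: gather, align, tree, clades, rank, report.

``run_pipeline`` reads proteome FASTAs and mapping tables, builds one
orthogroup bundle per orthogroup, skips bundles spanning fewer than
``min_proteomes`` proteomes, aligns the rest (or loads pre-aligned
FASTA), and for each alignment computes the gap-distance matrix, the
NJ tree, the low-cost clades, and the ranked / selected suggestions.
Orthogroup failures are isolated: a pathological family is logged and
tallied, the run continues.

Per-orthogroup categories mirror the standard yield accounting:

* ``skipped`` — fewer than ``min_proteomes`` proteomes;
* ``no_low_cost`` — no clade passed the cost threshold;
* ``confirmed`` — every selected clade contains only current
  canonicals;
* ``proposed`` — every selected clade proposes at least one change;
* ``both`` — several selected clades, some confirming and some
  proposing (distinct Gene-Centric gene sets).

The run is deterministic: repeated runs over the same inputs produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cladefind import (
    DEFAULT_COST_THRESHOLD,
    DEFAULT_MIN_PROTEOMES,
    CladeCandidate,
    dump_candidates_tsv,
    find_low_cost_clades,
)
from .gapdist import gap_distance_matrix
from .io import (
    OrthogroupBundle,
    build_bundles,
    read_gene_centric_table,
    read_orthogroup_table,
    read_proteome_fasta,
    write_newick,
    write_suggestion_report,
)
from .msa import MultipleAlignment, align_orthogroup, filter_orthogroups, load_prealigned
from .njtree import nj_tree
from .ranksel import (
    ACTION_CONFIRM,
    Suggestion,
    canonical_by_group,
    canonical_lengths_of,
    emit_suggestions,
    rank_clades,
    select_clades,
)

logger = logging.getLogger(__name__)

CATEGORY_SKIPPED = "skipped"
CATEGORY_NO_LOW_COST = "no_low_cost"
CATEGORY_CONFIRMED = "confirmed"
CATEGORY_PROPOSED = "proposed"
CATEGORY_BOTH = "both"
CATEGORY_FAILED = "failed"


@dataclass
class PipelineConfig:
    fasta_paths: list[str] = field(default_factory=list)
    gene_centric_path: str = ""
    orthogroup_path: str = ""
    prealigned_dir: str | None = None
    aligner_cmd: str | None = None
    out_dir: str = "orthocanon_out"
    cost_threshold: float = DEFAULT_COST_THRESHOLD
    min_proteomes: int = DEFAULT_MIN_PROTEOMES
    write_trees: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key/value YAML config; kwargs override file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunSummary:
    """Yield accounting for one pipeline run."""

    total_groups: int = 0
    skipped: int = 0
    no_low_cost: int = 0
    confirmed_groups: int = 0
    proposed_groups: int = 0
    both_groups: int = 0
    failed_groups: int = 0
    total_canonicals: int = 0
    clade_canonicals: int = 0
    confirmed_canonicals: int = 0
    proposed_changes: int = 0

    def partition_holds(self) -> bool:
        """Every orthogroup lands in exactly one category."""
        return (
            self.skipped
            + self.no_low_cost
            + self.confirmed_groups
            + self.proposed_groups
            + self.both_groups
            + self.failed_groups
            == self.total_groups
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class OrthogroupResult:
    orthogroup_id: str
    category: str
    candidates: list[CladeCandidate] = field(default_factory=list)
    selected: list[CladeCandidate] = field(default_factory=list)
    suggestions: list[Suggestion] = field(default_factory=list)
    tree: object = None


def classify(selected, suggestions) -> str:
    """Categorize an orthogroup from its selected clades' suggestions."""
    if not selected:
        return CATEGORY_NO_LOW_COST
    by_rank: dict[int, list[Suggestion]] = {}
    for s in suggestions:
        by_rank.setdefault(s.rank, []).append(s)
    confirming = sum(
        1
        for rows in by_rank.values()
        if all(s.action == ACTION_CONFIRM for s in rows)
    )
    proposing = len(by_rank) - confirming
    if confirming and proposing:
        return CATEGORY_BOTH
    return CATEGORY_CONFIRMED if confirming else CATEGORY_PROPOSED


def analyze_orthogroup(
    bundle: OrthogroupBundle,
    msa: MultipleAlignment,
    cost_threshold: float = DEFAULT_COST_THRESHOLD,
    min_proteomes: int = DEFAULT_MIN_PROTEOMES,
) -> OrthogroupResult:
    """Run the per-orthogroup core: distances, tree, clades, suggestions."""
    matrix = gap_distance_matrix(msa)
    tree = nj_tree(matrix)
    candidates = find_low_cost_clades(
        tree,
        matrix,
        bundle.members,
        orthogroup_id=bundle.orthogroup_id,
        cost_threshold=cost_threshold,
        min_proteomes=min_proteomes,
    )
    ranked = rank_clades(candidates, canonical_lengths_of(bundle.members))
    selected = select_clades(ranked)
    suggestions = emit_suggestions(selected, canonical_by_group(bundle.members))
    return OrthogroupResult(
        orthogroup_id=bundle.orthogroup_id,
        category=classify(selected, suggestions),
        candidates=ranked,
        selected=selected,
        suggestions=suggestions,
        tree=tree,
    )


def summarize(results, skipped_bundles, all_bundles) -> RunSummary:
    """Fold per-orthogroup results into a :class:`RunSummary`."""
    summary = RunSummary(
        total_groups=len(results) + len(skipped_bundles),
        skipped=len(skipped_bundles),
        total_canonicals=sum(
            1 for b in all_bundles for m in b.members if m.is_canonical
        ),
    )
    for res in results:
        if res.category == CATEGORY_NO_LOW_COST:
            summary.no_low_cost += 1
        elif res.category == CATEGORY_CONFIRMED:
            summary.confirmed_groups += 1
        elif res.category == CATEGORY_PROPOSED:
            summary.proposed_groups += 1
        elif res.category == CATEGORY_BOTH:
            summary.both_groups += 1
        elif res.category == CATEGORY_FAILED:
            summary.failed_groups += 1
        summary.clade_canonicals += sum(
            1
            for clade in res.selected
            for m in clade.members.values()
            if m.is_canonical
        )
        by_rank: dict[int, list[Suggestion]] = {}
        for s in res.suggestions:
            by_rank.setdefault(s.rank, []).append(s)
        for rows in by_rank.values():
            if all(s.action == ACTION_CONFIRM for s in rows):
                summary.confirmed_canonicals += len(rows)
            else:
                summary.proposed_changes += sum(
                    1 for s in rows if s.action != ACTION_CONFIRM
                )
    return summary


def run_pipeline(
    config: PipelineConfig,
    bundles: list[OrthogroupBundle] | None = None,
    msas: dict[str, MultipleAlignment] | None = None,
) -> tuple[list[Suggestion], RunSummary]:
    """Execute the full pipeline and write the reports.

    Inputs normally come from the paths in ``config``; for in-memory
    use (simulated data, tests) pre-built ``bundles`` and ``msas`` can
    be passed directly and the file-reading stage is bypassed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if bundles is None:
        gene_centric = read_gene_centric_table(config.gene_centric_path)
        records = []
        for path in config.fasta_paths:
            records.extend(read_proteome_fasta(path, gene_centric))
        orthogroup_map = read_orthogroup_table(config.orthogroup_path)
        bundles = build_bundles(records, orthogroup_map)

    kept, skipped = filter_orthogroups(bundles, config.min_proteomes)

    results: list[OrthogroupResult] = []
    all_suggestions: list[Suggestion] = []
    for bundle in kept:
        try:
            if msas is not None and bundle.orthogroup_id in msas:
                msa = msas[bundle.orthogroup_id]
            elif config.prealigned_dir:
                safe = bundle.orthogroup_id.replace(":", "_")
                msa = load_prealigned(
                    Path(config.prealigned_dir) / f"{safe}.afa", bundle
                )
            else:
                msa = align_orthogroup(bundle, config.aligner_cmd)
            res = analyze_orthogroup(
                bundle, msa, config.cost_threshold, config.min_proteomes
            )
        except Exception:
            logger.exception("orthogroup %s failed; skipping", bundle.orthogroup_id)
            res = OrthogroupResult(
                orthogroup_id=bundle.orthogroup_id, category=CATEGORY_FAILED
            )
        results.append(res)
        all_suggestions.extend(res.suggestions)
        if config.write_trees and res.tree is not None:
            trees_dir = out_dir / "trees"
            trees_dir.mkdir(exist_ok=True)
            safe = bundle.orthogroup_id.replace(":", "_")
            write_newick(res.tree, trees_dir / f"{safe}.nwk")

    summary = summarize(results, skipped, bundles)

    write_suggestion_report(all_suggestions, out_dir / "suggestions.csv")
    dump_candidates_tsv(
        (c for r in results for c in r.candidates), out_dir / "candidates.tsv"
    )
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return all_suggestions, summary
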