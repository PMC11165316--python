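"""Synthetic multi-proteome orthogroups and proteome-pair searches.

The generator emulates the data the pipeline consumes, with planted
ground truth:

* **Orthogroups with exon-block isoform structure.**  A gene model is a
  set of shared "exon" blocks; the biologically consistent (truth)
  isoform concatenates the core blocks in every proteome, and evolves
  by amino-acid substitutions only, so the truth clade has gap cost
  exactly 0 by construction.  In a configurable subset of proteomes the
  database canonical is instead a decoy isoform carrying a
  proteome-specific N-terminal extension block — the classic
  longest-isoform artifact — while the truth isoform is still present
  in the gene group under a ``-2`` accession.  Extensions differ in
  residues *and* length between proteomes, so decoys never form a
  low-cost clade with each other.  Non-decoy proteomes may additionally
  carry an exon-skip isoform (one core block removed) as a realistic
  distractor.

* **Pairwise m8+BTOP search files** with planted identity and gap-size
  fractions, recoverable exactly by the gap-statistics module.

Because blocks define alignment columns directly, the generator emits
the true MSA itself; tests and desk-scale runs never depend on an
external aligner.  All randomness flows from one integer seed; the
same seed gives byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gapstats import GAP_QUERY, Gap, decode_btop
from .io import (
    OrthogroupBundle,
    SearchHit,
    SequenceRecord,
    write_m8_btop,
    write_proteome_fasta,
)
from .msa import MultipleAlignment, write_aligned_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: default organism mnemonics, UniProt style
PROTEOME_POOL = (
    "HUMAN", "MOUSE", "RAT", "BOVIN", "GORGO", "MONDO",
    "PANTR", "CANLF", "PIG", "HORSE", "RABIT", "MACMU",
)

#: proteomes whose truth canonicals are marked reviewed (Swiss-Prot)
REVIEWED_PROTEOMES = ("HUMAN", "MOUSE")


@dataclass
class ExonBlock:
    block_id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """Exon blocks plus the isoform patterns built from them.

    ``isoform_patterns[truth_pattern_index]`` is the biologically
    consistent isoform shared across proteomes;
    ``canonical_pattern_index`` is the model-level default for what the
    database calls canonical (decoy proteomes override it with their
    proteome-specific extension pattern).
    """

    exon_blocks: list[ExonBlock]
    isoform_patterns: list[tuple[str, ...]]
    truth_pattern_index: int = 0
    canonical_pattern_index: int = 0
    decoy_pattern_of: dict[str, int] = field(default_factory=dict)
    skip_pattern_of: dict[str, int] = field(default_factory=dict)

    def block(self, block_id: str) -> ExonBlock:
        for b in self.exon_blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)

    @property
    def truth_pattern(self) -> tuple[str, ...]:
        return self.isoform_patterns[self.truth_pattern_index]


@dataclass
class SimulationConfig:
    rng_seed: int
    n_proteomes: int = 6
    n_orthogroups: int = 50
    substitution_rate: float = 0.05
    decoy_fraction: float = 0.3          # proteomes with a decoy canonical
    decoy_group_fraction: float = 1.0    # orthogroups containing decoys
    indel_free_truth: bool = True
    include_skip_isoforms: bool = True
    reviewed_decoys: bool = False        # decoy canonicals marked reviewed
    proteome_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        for f in (self.decoy_fraction, self.decoy_group_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if not self.proteome_names:
            self.proteome_names = PROTEOME_POOL[: self.n_proteomes]
        if len(self.proteome_names) != self.n_proteomes:
            raise ValueError("proteome_names length != n_proteomes")


@dataclass
class OrthogroupTruth:
    """Planted ground truth for one synthetic orthogroup."""

    orthogroup_id: str
    decoy_proteomes: list[str]
    expected_canonical: dict[str, str]  # proteome -> accession of truth isoform
    current_canonical: dict[str, str]   # proteome -> accession now canonical
    planted_cost: float = 0.0


@dataclass
class OrthogroupSim:
    bundle: OrthogroupBundle
    msa: MultipleAlignment
    truth: OrthogroupTruth
    model: GeneModel


def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(rng: np.random.Generator, residues: str, rate: float) -> str:
    if rate <= 0:
        return residues
    chars = list(residues)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = AA20.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def random_gene_model(rng: np.random.Generator, config: SimulationConfig) -> GeneModel:
    """Draw a gene model: shared core blocks plus per-proteome extras.

    The core has at least ``max(4, ceil(n_proteomes / 2))`` blocks of
    15-60 aa so that exon-skip distractors are (nearly) proteome-unique
    and every one-sided block gap exceeds the clade cost threshold.
    Extension blocks are 30-80 aa, proteome-specific in residues and
    length.
    """
    k_min = max(4, math.ceil(config.n_proteomes / 2))
    k = int(rng.integers(k_min, k_min + 4))
    core = [
        ExonBlock(f"B{j:02d}", _random_residues(rng, int(rng.integers(15, 61))))
        for j in range(k)
    ]
    extensions = [
        ExonBlock(f"EXT_{p}", _random_residues(rng, int(rng.integers(30, 81))))
        for p in config.proteome_names
    ]
    truth = tuple(b.block_id for b in core)
    patterns: list[tuple[str, ...]] = [truth]
    decoy_of: dict[str, int] = {}
    skip_of: dict[str, int] = {}
    for i, p in enumerate(config.proteome_names):
        patterns.append((f"EXT_{p}",) + truth)
        decoy_of[p] = len(patterns) - 1
    for i, p in enumerate(config.proteome_names):
        skip = tuple(b for j, b in enumerate(truth) if j != i % k)
        patterns.append(skip)
        skip_of[p] = len(patterns) - 1
    return GeneModel(
        exon_blocks=extensions + core,
        isoform_patterns=patterns,
        truth_pattern_index=0,
        canonical_pattern_index=0,
        decoy_pattern_of=decoy_of,
        skip_pattern_of=skip_of,
    )


def generate_orthogroup(
    config: SimulationConfig,
    rng: np.random.Generator,
    index: int = 0,
    gene_model: GeneModel | None = None,
    decoy_proteomes: list[str] | None = None,
) -> OrthogroupSim:
    """Generate one orthogroup bundle, its true MSA, and its truth record.

    ``decoy_proteomes`` overrides the random choice of which proteomes
    carry a decoy canonical; by default exactly
    ``round(decoy_fraction * n_proteomes)`` proteomes do.
    """
    model = gene_model or random_gene_model(rng, config)
    names = config.proteome_names
    if decoy_proteomes is None:
        n_decoys = round(config.decoy_fraction * len(names))
        decoy_proteomes = sorted(
            str(p) for p in rng.choice(list(names), size=n_decoys, replace=False)
        ) if n_decoys else []
    og_id = f"OG{index:04d}:SF1"

    # per-proteome mutated copies of every block (shared by all isoforms
    # of that proteome's gene, as isoforms of one gene share exons)
    mutated: dict[str, dict[str, str]] = {}
    for p in names:
        mutated[p] = {
            b.block_id: _mutate(rng, b.residues, config.substitution_rate)
            for b in model.exon_blocks
        }

    records: list[SequenceRecord] = []
    row_patterns: dict[str, tuple[str, ...]] = {}
    truth_acc: dict[str, str] = {}
    current_acc: dict[str, str] = {}

    def make_record(
        proteome: str, acc: str, pattern: tuple[str, ...], *,
        canonical: bool, reviewed: bool,
    ) -> SequenceRecord:
        residues = "".join(mutated[proteome][b] for b in pattern)
        rec = SequenceRecord(
            accession=acc,
            proteome_id=proteome,
            entry_name=f"OG{index:04d}_{proteome}",
            review_status="reviewed" if reviewed else "unreviewed",
            is_canonical=canonical,
            gene_group_id=f"GC{index:04d}_{proteome}",
            residues=residues,
        )
        records.append(rec)
        row_patterns[acc] = pattern
        return rec

    # isoforms get their own base accession (as TrEMBL isoforms of a
    # gene usually do) plus a -1 suffix, so proposed changes name a
    # genuinely different accession than the one they replace
    for i, p in enumerate(names):
        base = f"Q{index:04d}{i:02d}"
        iso = f"X{index:04d}{i:02d}-1"
        if p in decoy_proteomes:
            decoy_pattern = model.isoform_patterns[model.decoy_pattern_of[p]]
            make_record(
                p, base, decoy_pattern,
                canonical=True, reviewed=config.reviewed_decoys,
            )
            make_record(
                p, iso, model.truth_pattern,
                canonical=False, reviewed=False,
            )
            truth_acc[p] = iso
            current_acc[p] = base
        else:
            make_record(
                p, base, model.truth_pattern,
                canonical=True, reviewed=p in REVIEWED_PROTEOMES,
            )
            truth_acc[p] = base
            current_acc[p] = base
            if config.include_skip_isoforms:
                skip_pattern = model.isoform_patterns[model.skip_pattern_of[p]]
                make_record(
                    p, iso, skip_pattern,
                    canonical=False, reviewed=False,
                )

    # true MSA: blocks used by >=1 record define the columns, in model order
    used = {b for pat in row_patterns.values() for b in pat}
    layout = [b for b in model.exon_blocks if b.block_id in used]
    rows = []
    for rec in records:
        pattern = set(row_patterns[rec.accession])
        row = "".join(
            mutated[rec.proteome_id][b.block_id]
            if b.block_id in pattern
            else "-" * b.length
            for b in layout
        )
        rows.append((rec.accession, row))
    msa = MultipleAlignment(og_id, rows)

    bundle = OrthogroupBundle(orthogroup_id=og_id, members=records)
    truth = OrthogroupTruth(
        orthogroup_id=og_id,
        decoy_proteomes=list(decoy_proteomes),
        expected_canonical=truth_acc,
        current_canonical=current_acc,
        planted_cost=0.0,
    )
    return OrthogroupSim(bundle=bundle, msa=msa, truth=truth, model=model)


def generate_dataset(config: SimulationConfig) -> list[OrthogroupSim]:
    """Generate ``n_orthogroups`` orthogroups from one seed.

    Exactly ``round(decoy_group_fraction * n_orthogroups)`` orthogroups
    contain decoy canonicals; the rest are all-truth (the pipeline must
    confirm them).
    """
    rng = np.random.default_rng(config.rng_seed)
    n_decoy_groups = round(config.decoy_group_fraction * config.n_orthogroups)
    decoy_groups = set(
        rng.choice(config.n_orthogroups, size=n_decoy_groups, replace=False).tolist()
    )
    sims = []
    for g in range(config.n_orthogroups):
        decoys = None if g in decoy_groups else []
        sims.append(generate_orthogroup(config, rng, index=g, decoy_proteomes=decoys))
    return sims


def write_dataset(sims: list[OrthogroupSim], outdir: str | Path) -> dict[str, Path]:
    """Materialize a simulated dataset as pipeline input files.

    Writes per-proteome FASTA (UniProt dialect), the Gene-Centric and
    orthogroup TSVs, pre-aligned FASTA per orthogroup, and a truth JSON.
    """
    outdir = Path(outdir)
    (outdir / "fasta").mkdir(parents=True, exist_ok=True)
    (outdir / "prealigned").mkdir(parents=True, exist_ok=True)

    by_proteome: dict[str, list[SequenceRecord]] = {}
    for sim in sims:
        for rec in sim.bundle.members:
            by_proteome.setdefault(rec.proteome_id, []).append(rec)
    fasta_paths = []
    for p in sorted(by_proteome):
        path = outdir / "fasta" / f"{p}.fasta"
        write_proteome_fasta(by_proteome[p], path)
        fasta_paths.append(path)

    gc_path = outdir / "gene_centric.tsv"
    with open(gc_path, "w") as fh:
        fh.write("gene_group_id\taccession\tis_canonical\treview_status\n")
        for sim in sims:
            for rec in sim.bundle.members:
                fh.write(
                    f"{rec.gene_group_id}\t{rec.accession}\t"
                    f"{int(rec.is_canonical)}\t{rec.review_status}\n"
                )

    og_path = outdir / "orthogroups.tsv"
    with open(og_path, "w") as fh:
        fh.write("orthogroup_id\taccession\n")
        for sim in sims:
            for rec in sim.bundle.members:
                if rec.is_canonical:
                    fh.write(f"{sim.bundle.orthogroup_id}\t{rec.accession}\n")

    for sim in sims:
        safe = sim.bundle.orthogroup_id.replace(":", "_")
        write_aligned_fasta(sim.msa, outdir / "prealigned" / f"{safe}.afa")

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                sim.truth.orthogroup_id: {
                    "decoy_proteomes": sim.truth.decoy_proteomes,
                    "expected_canonical": sim.truth.expected_canonical,
                    "current_canonical": sim.truth.current_canonical,
                    "planted_cost": sim.truth.planted_cost,
                }
                for sim in sims
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return {
        "fasta_dir": outdir / "fasta",
        "gene_centric": gc_path,
        "orthogroups": og_path,
        "prealigned_dir": outdir / "prealigned",
        "truth": truth_path,
    }


# ---------------------------------------------------------------------------
# synthetic proteome-pair searches
# ---------------------------------------------------------------------------


@dataclass
class PairSimConfig:
    """Planted distributions for a synthetic proteome-pair search file."""

    rng_seed: int
    n_alignments: int = 500
    frac_gt90: float = 0.5          # alignments with identity > 90%
    frac_gap_ge5: float = 0.2       # of the >90% set, with a gap >= 5
    gap_len_range: tuple[int, int] = (5, 30)
    small_gap_prob: float = 0.3     # chance of a 1-4 aa gap elsewhere
    plant_max_gap: int | None = None  # force one alignment's gap length


def _build_btop(
    rng: np.random.Generator, n_identical: int, n_mismatch: int, gap_len: int
) -> str:
    """Assemble a BTOP string with the given composition.

    Mismatches are spread through the identity run; a single gap event
    (alternating sides by draw) is placed mid-alignment when
    ``gap_len`` > 0.
    """
    chunks = n_mismatch + 1
    base, extra = divmod(n_identical, chunks)
    parts: list[str] = []
    for i in range(chunks):
        run = base + (1 if i < extra else 0)
        if run:
            parts.append(str(run))
        if i < n_mismatch:
            q, s = rng.choice(list(AA20), size=2, replace=False)
            parts.append(q + s)
    if gap_len > 0:
        side_query = bool(rng.integers(2))
        residues = _random_residues(rng, gap_len)
        gap_str = "".join(
            ("-" + r) if side_query else (r + "-") for r in residues
        )
        mid = len(parts) // 2
        parts.insert(mid, gap_str)
    return "".join(parts)


def generate_pair_hits(config: PairSimConfig) -> list[SearchHit]:
    """Generate best-hit style alignments with planted gap fractions.

    Every query appears exactly once with a strongly significant
    E-value and a query length > 100, so the best-hit filter keeps all
    of them and the planted fractions are recovered exactly:
    ``round(n * frac_gt90)`` alignments are strictly >90% identical and,
    of those, ``round(. * frac_gap_ge5)`` carry one gap >= 5 residues.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_alignments
    n_gt90 = round(n * config.frac_gt90)
    n_gap5 = round(n_gt90 * config.frac_gap_ge5)

    hits: list[SearchHit] = []
    for i in range(n):
        in_gt90 = i < n_gt90
        planted_gap = in_gt90 and i < n_gap5
        if planted_gap:
            lo, hi = config.gap_len_range
            gap_len = int(rng.integers(lo, hi + 1))
            if config.plant_max_gap is not None and i == 0:
                gap_len = config.plant_max_gap
        elif rng.random() < config.small_gap_prob:
            gap_len = int(rng.integers(1, 5))
        else:
            gap_len = 0
        # residue-aligned columns; >= 10x the gap so a >90% identity is
        # attainable even around the gap
        m = int(rng.integers(max(150, 10 * gap_len), max(600, 10 * gap_len + 450)))
        align_len = m + gap_len

        if in_gt90:
            target = rng.uniform(0.905, 0.995)
        else:
            target = rng.uniform(0.55, 0.895)
        n_identical = min(round(target * align_len), m)
        # enforce the identity-class boundary exactly (strict >90 vs <=90)
        if in_gt90 and 100.0 * n_identical / align_len <= 90.0:
            n_identical = math.floor(0.90 * align_len) + 1
        if not in_gt90 and 100.0 * n_identical / align_len > 90.0:
            n_identical = math.floor(0.90 * align_len)
        n_mismatch = m - n_identical

        btop = _build_btop(rng, n_identical, n_mismatch, gap_len)
        events = decode_btop(btop)
        gaps_q = sum(
            ev.length for ev in events if isinstance(ev, Gap) and ev.side == GAP_QUERY
        )
        gaps_s = gap_len - gaps_q
        query_len = m + gaps_s + int(rng.integers(0, 30))
        subject_len = m + gaps_q + int(rng.integers(0, 30))
        hits.append(
            SearchHit(
                query_acc=f"Q{i:05d}",
                subject_acc=f"S{i:05d}",
                percent_identity=round(100.0 * n_identical / align_len, 2),
                align_len=align_len,
                mismatches=n_mismatch,
                gap_opens=1 if gap_len else 0,
                query_start=1,
                query_end=m + gaps_s,
                subject_start=1,
                subject_end=m + gaps_q,
                e_value=1e-30,
                bit_score=round(2.0 * n_identical, 1),
                query_len=query_len,
                subject_len=subject_len,
                btop=btop,
            )
        )
    return hits


def write_pair_hits(config: PairSimConfig, path: str | Path) -> list[SearchHit]:
    hits = generate_pair_hits(config)
    write_m8_btop(hits, path)
    return hits
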