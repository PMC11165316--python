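"""Multiple sequence alignment stage.

One alignment is produced per orthogroup bundle, either by invoking an
external aligner (muscle by default, with ``-maxiters 2 -diags``) or by
validating a pre-computed aligned FASTA against the bundle.  The
aligner is pluggable so that the rest of the pipeline — and the test
suite — never depends on a specific aligner build.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO

from .io import FormatError, OrthogroupBundle, SequenceRecord, write_proteome_fasta

logger = logging.getLogger(__name__)


@dataclass
class MultipleAlignment:
    """An MSA over one orthogroup: ordered (accession, aligned row) pairs."""

    orthogroup_id: str
    rows: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.rows]

    def row(self, accession: str) -> str:
        for acc, aligned in self.rows:
            if acc == accession:
                return aligned
        raise KeyError(accession)

    def validate(self, bundle: OrthogroupBundle | None = None) -> None:
        """Check the MSA invariants (equal widths, ungap round-trip, no
        all-gap column)."""
        widths = {len(r) for _, r in self.rows}
        if len(widths) > 1:
            raise FormatError(f"{self.orthogroup_id}: ragged alignment rows {widths}")
        for c in range(self.n_cols):
            if all(r[c] == "-" for _, r in self.rows):
                raise FormatError(
                    f"{self.orthogroup_id}: column {c} is all-gap"
                )
        if bundle is not None:
            by_acc = {m.accession: m for m in bundle.members}
            for acc, aligned in self.rows:
                rec = by_acc.get(acc)
                if rec is None:
                    raise FormatError(
                        f"{self.orthogroup_id}: aligned row {acc} not in bundle"
                    )
                if aligned.replace("-", "") != rec.residues:
                    raise FormatError(
                        f"{self.orthogroup_id}: ungapped row {acc} differs from input"
                    )

    def subset(self, accessions: Sequence[str]) -> "MultipleAlignment":
        """Restrict to some rows, stripping columns that become all-gap."""
        keep = [(a, r) for a, r in self.rows if a in set(accessions)]
        sub = MultipleAlignment(self.orthogroup_id, keep)
        return strip_all_gap_columns(sub)


def strip_all_gap_columns(msa: MultipleAlignment) -> MultipleAlignment:
    """Drop columns gapped in every row (possible after subsetting)."""
    if not msa.rows:
        return msa
    cols = [
        c
        for c in range(msa.n_cols)
        if any(r[c] != "-" for _, r in msa.rows)
    ]
    if len(cols) == msa.n_cols:
        return msa
    logger.debug(
        "%s: stripped %d all-gap columns", msa.orthogroup_id, msa.n_cols - len(cols)
    )
    return MultipleAlignment(
        msa.orthogroup_id,
        [(a, "".join(r[c] for c in cols)) for a, r in msa.rows],
    )


# ---------------------------------------------------------------------------
# aligner invocation
# ---------------------------------------------------------------------------

#: default external command; ``{infile}`` / ``{outfile}`` are substituted.
DEFAULT_ALIGNER_CMD = "muscle -maxiters 2 -diags -in {infile} -out {outfile}"

Aligner = Callable[[list[SequenceRecord]], list[tuple[str, str]]]


class ExternalAligner:
    """Run an external MSA program through a command template.

    The template must contain ``{infile}`` and ``{outfile}``
    placeholders; input is written as FASTA and the output is expected
    to be aligned FASTA containing every input accession.
    """

    def __init__(self, cmd_template: str = DEFAULT_ALIGNER_CMD):
        self.cmd_template = cmd_template

    def command(self, infile: str, outfile: str) -> list[str]:
        return shlex.split(self.cmd_template.format(infile=infile, outfile=outfile))

    def __call__(self, records: list[SequenceRecord]) -> list[tuple[str, str]]:
        with tempfile.TemporaryDirectory() as tmp:
            infile = str(Path(tmp) / "in.fasta")
            outfile = str(Path(tmp) / "out.afa")
            write_proteome_fasta(records, infile)
            proc = subprocess.run(
                self.command(infile, outfile), capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"aligner failed (exit {proc.returncode}): {proc.stderr.strip()}"
                )
            rows = {}
            for seq in SeqIO.parse(outfile, "fasta"):
                acc = seq.id.split("|")[1] if "|" in seq.id else seq.id
                rows[acc] = str(seq.seq).upper()
        ordered = []
        for rec in records:
            if rec.accession not in rows:
                raise RuntimeError(f"aligner output missing {rec.accession}")
            ordered.append((rec.accession, rows[rec.accession]))
        return ordered


def align_orthogroup(
    bundle: OrthogroupBundle, aligner: Aligner | str | None = None
) -> MultipleAlignment:
    """Align a bundle's members; row order follows the bundle.

    ``aligner`` may be a callable ``records -> [(accession, row), ...]``
    (used by tests with a deterministic stub), a command-template string
    for :class:`ExternalAligner`, or None for the muscle default.
    """
    if len(bundle.members) < 2:
        raise ValueError(f"{bundle.orthogroup_id}: need >=2 sequences to align")
    if aligner is None:
        aligner = ExternalAligner()
    elif isinstance(aligner, str):
        aligner = ExternalAligner(aligner)
    rows = aligner(bundle.members)
    msa = strip_all_gap_columns(MultipleAlignment(bundle.orthogroup_id, list(rows)))
    msa.validate(bundle)
    return msa


def load_prealigned(path: str | Path, bundle: OrthogroupBundle) -> MultipleAlignment:
    """Load and validate a pre-computed aligned FASTA for a bundle.

    All-gap columns are stripped (with a log line); an ungapped row that
    does not match the bundle's residues is an error naming the
    accession.
    """
    rows = []
    for seq in SeqIO.parse(str(path), "fasta"):
        acc = seq.id.split("|")[1] if "|" in seq.id else seq.id
        rows.append((acc, str(seq.seq).upper()))
    msa = strip_all_gap_columns(MultipleAlignment(bundle.orthogroup_id, rows))
    msa.validate(bundle)
    return msa


def write_aligned_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, row in msa.rows:
            fh.write(f">{acc}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def filter_orthogroups(
    bundles: Iterable[OrthogroupBundle], min_proteomes: int = 3
) -> tuple[list[OrthogroupBundle], list[OrthogroupBundle]]:
    """Partition bundles by the minimum-proteome floor (default 3).

    Orthogroups with sequences from fewer than ``min_proteomes``
    distinct proteomes are skipped (they cannot support a multi-proteome
    clade); the boundary is inclusive: exactly ``min_proteomes`` is kept.
    """
    kept, skipped = [], []
    for b in bundles:
        (kept if b.proteome_count >= min_proteomes else skipped).append(b)
    return kept, skipped
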