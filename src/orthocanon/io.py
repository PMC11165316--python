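"""Readers and writers for every external format the pipeline touches.

Formats handled here:

* proteome FASTA in the UniProt reference-proteome dialect
  (``sp|ACC|ENTRY``, ``tr|ACC|ENTRY``, ``sp_iso``/``tr_iso`` for isoform
  files, or bare ``>ACC`` headers),
* TSV mapping tables (orthogroup -> canonical accessions; Gene-Centric
  group -> member accessions with canonical / review flags),
* aligned FASTA,
* newick trees (through :mod:`Bio.Phylo`),
* BLAST-style tabular search output (m8 columns plus a trailing BTOP
  alignment-encoding column),
* the suggestion / report CSV.

The canonical flag's source of truth is the Gene-Centric mapping table,
not the FASTA db tag; where the two disagree the table wins and the
conflict is logged.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import Phylo, SeqIO

logger = logging.getLogger(__name__)

#: residue letters accepted in input sequences: the 20 standard amino
#: acids plus ambiguity/rare codes B, Z, X, U, J, O.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | set("BZXUJO")

_HEADER_RE = re.compile(r"^(sp|tr|sp_iso|tr_iso)\|([^|\s]+)\|(\S+)")
_ISOFORM_RE = re.compile(r"-\d+$")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """One protein sequence with its database context.

    Parameters
    ----------
    accession : str
        UniProt-style accession; isoforms carry a ``-n`` suffix.
    proteome_id : str
        Organism / proteome tag (OS code such as ``"HUMAN"``).
    entry_name : str
        Entry name from the FASTA header (e.g. ``CRBA4_HUMAN``).
    review_status : str
        ``"reviewed"`` (Swiss-Prot) or ``"unreviewed"`` (TrEMBL).
    is_canonical : bool
        Whether this sequence is the current canonical of its gene.
    gene_group_id : str
        Gene-Centric group key; empty string if the accession has no
        gene-group mapping (such records are kept but flagged).
    residues : str
        Uppercase amino-acid string, no gap characters.
    """

    accession: str
    proteome_id: str
    entry_name: str = ""
    review_status: str = "unreviewed"
    is_canonical: bool = False
    gene_group_id: str = ""
    residues: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.accession}: non amino-acid letters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_reviewed(self) -> bool:
        return self.review_status == "reviewed"

    @property
    def base_accession(self) -> str:
        """Accession with any isoform ``-n`` suffix stripped."""
        return _ISOFORM_RE.sub("", self.accession)

    @property
    def is_mapped(self) -> bool:
        """Whether the record has a Gene-Centric group assignment."""
        return bool(self.gene_group_id)


@dataclass
class OrthogroupBundle:
    """All sequences gathered for one orthogroup across proteomes."""

    orthogroup_id: str
    members: list[SequenceRecord] = field(default_factory=list)

    @property
    def proteome_count(self) -> int:
        return len({m.proteome_id for m in self.members})

    @property
    def proteomes(self) -> set[str]:
        return {m.proteome_id for m in self.members}

    def record(self, accession: str) -> SequenceRecord:
        for m in self.members:
            if m.accession == accession:
                return m
        raise KeyError(accession)


@dataclass
class SearchHit:
    """One row of m8+BTOP tabular search output."""

    query_acc: str
    subject_acc: str
    percent_identity: float
    align_len: int
    mismatches: int = 0
    gap_opens: int = 0
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0
    e_value: float = 0.0
    bit_score: float = 0.0
    query_len: int = 0
    subject_len: int = 0
    btop: str = ""


# ---------------------------------------------------------------------------
# mapping tables
# ---------------------------------------------------------------------------


@dataclass
class GeneCentricTable:
    """Gene-Centric mapping: accession -> (group, canonical, review)."""

    gene_group: dict[str, str] = field(default_factory=dict)
    is_canonical: dict[str, bool] = field(default_factory=dict)
    review_status: dict[str, str] = field(default_factory=dict)

    def members_of(self, gene_group_id: str) -> list[str]:
        return sorted(
            acc for acc, g in self.gene_group.items() if g == gene_group_id
        )


def read_gene_centric_table(path: str | Path) -> GeneCentricTable:
    """Read the Gene-Centric TSV.

    Expected columns: ``gene_group_id``, ``accession``, ``is_canonical``
    (0/1 or true/false), ``review_status`` (reviewed/unreviewed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_group_id", "accession", "is_canonical", "review_status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    table = GeneCentricTable()
    for row in df.itertuples(index=False):
        acc = row.accession
        table.gene_group[acc] = row.gene_group_id
        table.is_canonical[acc] = str(row.is_canonical).strip().lower() in (
            "1",
            "true",
            "yes",
        )
        table.review_status[acc] = row.review_status
    return table


def read_orthogroup_table(path: str | Path) -> dict[str, set[str]]:
    """Read the orthogroup -> canonical-accession TSV.

    The first two columns are ``orthogroup_id`` and ``accession``;
    subfamily identifiers (``PTHR…:SF…``) are preserved verbatim.
    Duplicate rows are deduplicated silently; an accession listed under
    two orthogroups is kept in both with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"orthogroup_id", "accession"} <= set(df.columns):
        raise FormatError(
            f"{path}: need columns orthogroup_id, accession; got {list(df.columns)}"
        )
    mapping: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    for row in df.itertuples(index=False):
        og, acc = row.orthogroup_id, row.accession
        mapping.setdefault(og, set()).add(acc)
        if acc in seen and seen[acc] != og:
            logger.warning(
                "accession %s appears in orthogroups %s and %s; kept in both",
                acc,
                seen[acc],
                og,
            )
        seen[acc] = og
    return mapping


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _parse_header(header: str, path: str, lineno: int) -> tuple[str, str, str]:
    """Split a FASTA id into (db, accession, entry_name).

    Accepts ``db|ACC|ENTRY`` with db in {sp, tr, sp_iso, tr_iso} and the
    bare ``>ACC`` form (db and entry empty).
    """
    if "|" in header:
        m = _HEADER_RE.match(header)
        if not m:
            raise FormatError(f"{path}:{lineno}: malformed FASTA header {header!r}")
        return m.group(1), m.group(2), m.group(3)
    if not header or any(c.isspace() for c in header):
        raise FormatError(f"{path}:{lineno}: malformed FASTA header {header!r}")
    return "", header, ""


def _entry_proteome(entry_name: str, default: str) -> str:
    # UniProt entry names end in the OS mnemonic: CRBA4_HUMAN -> HUMAN
    if "_" in entry_name:
        return entry_name.rsplit("_", 1)[1]
    return default


def read_proteome_fasta(
    path: str | Path,
    gene_centric: GeneCentricTable | None = None,
    proteome_id: str = "",
) -> list[SequenceRecord]:
    """Read one proteome FASTA into :class:`SequenceRecord` objects.

    ``review_status`` is taken from the db tag (``sp*`` -> reviewed)
    unless the Gene-Centric table overrides it.  The canonical flag
    comes from the table when the accession is mapped there; otherwise
    it is inferred from the absence of a ``-n`` isoform suffix.
    Records absent from the table are returned with an empty
    ``gene_group_id`` (flagged, not dropped).
    """
    path = Path(path)
    # line numbers for error messages: map header string -> first line no
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                header_lines.setdefault(line[1:].split()[0] if line[1:].strip() else "", i)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for seq in SeqIO.parse(str(path), "fasta"):
        lineno = header_lines.get(seq.id, 0)
        db, acc, entry = _parse_header(seq.id, str(path), lineno)
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc}")
        seen.add(acc)
        review = "reviewed" if db.startswith("sp") else "unreviewed"
        is_iso = bool(_ISOFORM_RE.search(acc))
        canonical = not is_iso
        group = ""
        if gene_centric is not None and acc in gene_centric.gene_group:
            group = gene_centric.gene_group[acc]
            table_canonical = gene_centric.is_canonical[acc]
            if table_canonical != canonical:
                logger.info(
                    "%s: canonical flag from table (%s) overrides header inference",
                    acc,
                    table_canonical,
                )
            canonical = table_canonical
            review = gene_centric.review_status.get(acc, review)
        records.append(
            SequenceRecord(
                accession=acc,
                proteome_id=_entry_proteome(entry, proteome_id),
                entry_name=entry,
                review_status=review,
                is_canonical=canonical,
                gene_group_id=group,
                residues=str(seq.seq).upper(),
            )
        )
    return records


def write_proteome_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records in the UniProt header dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        for rec in records:
            db = "sp" if rec.is_reviewed else "tr"
            if _ISOFORM_RE.search(rec.accession):
                db += "_iso"
            if rec.entry_name:
                fh.write(f">{db}|{rec.accession}|{rec.entry_name}\n")
            else:
                fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def build_bundles(
    records: Iterable[SequenceRecord],
    orthogroup_map: Mapping[str, set[str]],
) -> list[OrthogroupBundle]:
    """Gather per-orthogroup bundles, expanding through Gene-Centric groups.

    The orthogroup table lists canonical accessions; each canonical pulls
    in every record sharing its gene-group (canonical + isoforms).
    Records with a gene group that no orthogroup reaches are retained in
    memory by the caller but never aligned.
    """
    by_acc = {r.accession: r for r in records}
    by_group: dict[str, list[SequenceRecord]] = {}
    for rec in by_acc.values():
        if rec.gene_group_id:
            by_group.setdefault(rec.gene_group_id, []).append(rec)

    bundles = []
    for og_id in sorted(orthogroup_map):
        members: dict[str, SequenceRecord] = {}
        for canon_acc in sorted(orthogroup_map[og_id]):
            rec = by_acc.get(canon_acc)
            if rec is None:
                logger.warning("%s: canonical %s not in FASTA input", og_id, canon_acc)
                continue
            group = rec.gene_group_id
            pool = by_group.get(group, [rec]) if group else [rec]
            for m in pool:
                members[m.accession] = m
        if members:
            bundles.append(
                OrthogroupBundle(
                    orthogroup_id=og_id,
                    members=sorted(members.values(), key=lambda r: r.accession),
                )
            )
    return bundles


# ---------------------------------------------------------------------------
# m8 + BTOP tables
# ---------------------------------------------------------------------------


def read_m8_btop(path: str | Path) -> list[SearchHit]:
    """Read tabular search output: 12 m8 columns plus a final BTOP column.

    A 15-column dialect with query/subject lengths inserted before the
    BTOP column is also accepted (query_len / subject_len stay 0 in the
    13-column form).  Lines starting with ``#`` are skipped.
    """
    hits: list[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (13, 15):
                raise FormatError(
                    f"{path}:{lineno}: expected 13 or 15 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qlen, slen = (
                    (int(fields[12]), int(fields[13])) if len(fields) == 15 else (0, 0)
                )
                hits.append(
                    SearchHit(
                        query_acc=fields[0],
                        subject_acc=fields[1],
                        percent_identity=float(fields[2]),
                        align_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                        query_len=qlen,
                        subject_len=slen,
                        btop=fields[-1],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_m8_btop(hits: Iterable[SearchHit], path: str | Path) -> None:
    """Write hits in the 15-column m8+lengths+BTOP dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_acc,
                        h.subject_acc,
                        f"{h.percent_identity:.2f}",
                        h.align_len,
                        h.mismatches,
                        h.gap_opens,
                        h.query_start,
                        h.query_end,
                        h.subject_start,
                        h.subject_end,
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                        h.query_len,
                        h.subject_len,
                        h.btop,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | Path) -> None:
    """Serialize a Bio.Phylo tree as newick with >=6 significant digits."""
    Phylo.write(tree, str(path), "newick", format_branch_length="%.8g")


def read_newick(path: str | Path):
    return Phylo.read(str(path), "newick")


# ---------------------------------------------------------------------------
# suggestion report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "orthogroup_id",
    "proteome_id",
    "gene_group_id",
    "old_canonical",
    "new_canonical",
    "action",
    "clade_cost",
    "clade_size",
    "rank",
]


def write_suggestion_report(suggestions, path: str | Path) -> None:
    """Write the suggestion CSV, sorted by (orthogroup_id, proteome_id)."""
    rows = sorted(
        suggestions, key=lambda s: (s.orthogroup_id, s.proteome_id, s.gene_group_id)
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for s in rows:
            writer.writerow(
                [
                    s.orthogroup_id,
                    s.proteome_id,
                    s.gene_group_id,
                    s.old_canonical,
                    s.new_canonical,
                    s.action,
                    f"{s.clade_cost:.6g}",
                    s.clade_size,
                    s.rank,
                ]
            )
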