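"""File formats: FASTA (protein and nucleotide), annotation TSV, Newick trees.

All loaders are strict: duplicate identifiers, illegal residues and missing
mandatory columns are hard errors rather than warnings, because every
downstream stage keys on accessions and boolean annotation flags.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")

#: canonical amino acids, alphabetical one-letter order used for composition vectors
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

ANNOTATION_COLUMNS = (
    "accession",
    "intracellular",
    "signal_peptide",
    "er_motif",
    "domain_tags",
    "outgroup_homolog",
)


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: accession, free-text description, residues.

    ``alphabet`` is ``"protein"`` (20 canonical letters plus X) or ``"dna"``
    (ACGTN).  Sequences are stored uppercase.
    """

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position {pos} in {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRow:
    """Per-protein annotation flags consumed by the classification stage.

    The flags stand in for external evidence: ``intracellular`` for a
    database annotation with a defined intracellular function,
    ``signal_peptide`` for a secretion signal prediction, ``er_motif`` for a
    C-terminal HDEL/KDEL endoplasmic-reticulum retention motif,
    ``outgroup_homolog`` for a homologue outside thoracican barnacles.
    ``domain_tags`` hold conserved-domain identifiers (e.g. ``cl08267``,
    ``pfam03098``), lowercased on load.
    """

    accession: str
    intracellular: bool = False
    signal_peptide: bool = False
    er_motif: bool = False
    domain_tags: set[str] = field(default_factory=set)
    outgroup_homolog: bool = False


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased; input order is preserved.  Duplicate ids,
    illegal residues and empty files raise ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc, alphabet=alphabet)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as plain multi-record FASTA, wrapped at ``width`` columns."""
    records = list(records)
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate ids in FASTA output")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_flag(value: object, column: str, row_number: int) -> bool:
    text = "" if value is None or (isinstance(value, float) and pd.isna(value)) else str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"non-boolean value {value!r} for column {column!r} at row {row_number}")


def read_annotations(path: str | Path) -> dict[str, AnnotationRow]:
    """Read the annotation TSV into a mapping accession -> :class:`AnnotationRow`.

    Expected header columns: ``accession intracellular signal_peptide
    er_motif domain_tags outgroup_homolog`` (``domain_tags``
    semicolon-separated).  A missing flag column defaults to all-false /
    empty and is logged loudly, since classification depends on it; unknown
    columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise ValueError(f"annotation file {path} lacks mandatory 'accession' column")
    for col in df.columns:
        if col not in ANNOTATION_COLUMNS:
            logger.warning("ignoring unknown annotation column %r in %s", col, path)
    for col in ANNOTATION_COLUMNS[1:]:
        if col not in df.columns:
            logger.warning(
                "annotation column %r absent in %s: defaulting to %s for every protein "
                "(classification depends on this flag)",
                col, path, "empty set" if col == "domain_tags" else "False",
            )
    rows: dict[str, AnnotationRow] = {}
    for i, rec in enumerate(df.to_dict("records"), start=2):  # row 1 = header
        acc = str(rec["accession"]).strip()
        if not acc:
            raise ValueError(f"empty accession at row {i} in {path}")
        if acc in rows:
            raise ValueError(f"duplicate accession {acc!r} at row {i} in {path}")
        tags_cell = str(rec.get("domain_tags", "")).strip()
        tags = {t.strip().lower() for t in tags_cell.split(";") if t.strip()}
        rows[acc] = AnnotationRow(
            accession=acc,
            intracellular=_parse_flag(rec.get("intracellular", ""), "intracellular", i),
            signal_peptide=_parse_flag(rec.get("signal_peptide", ""), "signal_peptide", i),
            er_motif=_parse_flag(rec.get("er_motif", ""), "er_motif", i),
            domain_tags=tags,
            outgroup_homolog=_parse_flag(rec.get("outgroup_homolog", ""), "outgroup_homolog", i),
        )
    return rows


def write_annotations(rows: Iterable[AnnotationRow], path: str | Path) -> None:
    """Write annotation rows back to the canonical TSV layout."""
    df = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "intracellular": int(r.intracellular),
                "signal_peptide": int(r.signal_peptide),
                "er_motif": int(r.er_motif),
                "domain_tags": ";".join(sorted(r.domain_tags)),
                "outgroup_homolog": int(r.outgroup_homolog),
            }
            for r in rows
        ],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    """Rooted (binary when produced by UPGMA) tree with branch lengths."""

    name: str | None = None
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,']")


def _escape_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string terminated by ';'."""
    names = tree.leaf_names()
    if len(names) < 2:
        raise ValueError("refusing to serialize a tree with fewer than 2 leaves")
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")

    def render(node: TreeNode, root: bool) -> str:
        if node.is_leaf:
            body = _escape_label(node.name or "")
        else:
            body = "(" + ",".join(render(c, False) for c in node.children) + ")"
        return body if root else f"{body}:{node.branch_length:g}"

    return render(tree, True) + ";"


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick (see :func:`to_newick` for constraints)."""
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
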