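"""Pairwise local alignment with affine gaps and Karlin–Altschul statistics.

The aligner is an exact Smith–Waterman/Gotoh search (no heuristic seeding),
computed by Biopython's C ``PairwiseAligner``; this module owns the scoring
conventions, the E-value statistics and the all-vs-all similarity tables
that replace a BLASTp step for desk-scale proteomes.

Conventions
-----------
* Opening a gap of length L costs ``gap_open + L * gap_extend``.
* The unknown residue X scores 0 against everything (including X).
* ``E = K * m * n * exp(-lambda * S)`` with m, n the two sequence lengths;
  no effective-length (edge) correction and no composition-based statistics.
* "Similar" means ``E <= evalue_threshold`` (default 1e-4) — the smaller
  the E-value, the stronger the similarity.
* A pair whose optimal local score is 0 has no alignment and is reported as
  a no-hit (omitted from similarity tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from cementome.seqio import SequenceRecord

#: default gapped BLOSUM62/11/1 Karlin-Altschul parameters
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_EVALUE_THRESHOLD = 1e-4


def load_matrix(name_or_path: str = "BLOSUM62", x_scores_zero: bool = True):
    """Load a substitution matrix by name or from an NCBI-format text file.

    With ``x_scores_zero`` (the default) the X row/column is set to 0 so the
    unknown residue neither rewards nor penalises any pairing.
    """
    if Path(str(name_or_path)).is_file():
        matrix = substitution_matrices.read(str(name_or_path))
    else:
        matrix = substitution_matrices.load(str(name_or_path))
    arr = np.array(matrix)
    if x_scores_zero and "X" in matrix.alphabet:
        xi = matrix.alphabet.index("X")
        arr[xi, :] = 0.0
        arr[:, xi] = 0.0
    out = substitution_matrices.Array(alphabet=matrix.alphabet, dims=2, data=arr)
    return out


@dataclass
class ScoringParams:
    """Scoring model: substitution matrix, affine gap costs, KA statistics.

    Defaults are BLOSUM62 with gap open 11 / extend 1 and the published
    gapped Karlin–Altschul parameters lambda = 0.267, K = 0.041 for that
    scheme.  ``evalue_threshold`` (default 1e-4) is the similarity cut-off
    used throughout the pipeline.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = DEFAULT_LAMBDA
    ka_k: float = DEFAULT_K
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    matrix: object = None  # substitution_matrices.Array; loaded lazily

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.ka_lambda <= 0 or self.ka_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.matrix is None:
            self.matrix = load_matrix(self.matrix_name)
        arr = np.array(self.matrix)
        if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be square and symmetric")

    def aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # convention: gap of length L costs gap_open + L * gap_extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment between one ordered (query, subject) pair."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    percent_identity: float
    query_coverage: float
    query_span: tuple[int, int]  # 1-based inclusive
    subject_span: tuple[int, int]
    aligned_columns: int


def evalue(raw_score: float, m: int, n: int, params: ScoringParams) -> float:
    """Karlin–Altschul expect value ``E = K * m * n * exp(-lambda * S)``.

    m and n are the lengths of the two compared sequences (the search space
    is their product; no edge-effect correction is applied).
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return params.ka_k * m * n * math.exp(-params.ka_lambda * raw_score)


def bit_score(raw_score: float, params: ScoringParams) -> float:
    """Normalised score ``S' = (lambda * S - ln K) / ln 2``."""
    return (params.ka_lambda * raw_score - math.log(params.ka_k)) / math.log(2)


def score_local(
    a: SequenceRecord,
    b: SequenceRecord,
    params: ScoringParams | None = None,
) -> AlignmentResult | None:
    """Optimal affine-gap local alignment of protein ``a`` (query) vs ``b``.

    Returns ``None`` when the optimal local score is 0 (no positive-scoring
    column pair exists): such pairs have no alignment.  Percent identity
    counts identical columns over all aligned columns, gap columns included
    in the denominator; query coverage is the aligned query span as a
    percentage of the query length.  Deterministic for fixed inputs.
    """
    if params is None:
        params = ScoringParams()
    for rec in (a, b):
        if rec.alphabet != "protein":
            raise ValueError(f"score_local requires protein sequences, got {rec.alphabet!r} for {rec.id!r}")
        if len(rec) < 1:
            raise ValueError(f"zero-length sequence {rec.id!r}")
    aligner = params.aligner()
    alignments = aligner.align(a.sequence, b.sequence)
    if alignments.score <= 0:
        return None
    aln = alignments[0]  # deterministic traceback order
    qc, sc = aln.coordinates  # target (=query) first
    identical = 0
    columns = 0
    for i in range(len(qc) - 1):
        dq = qc[i + 1] - qc[i]
        ds = sc[i + 1] - sc[i]
        columns += max(dq, ds)
        if dq and ds:  # ungapped block
            qs = a.sequence[qc[i] : qc[i + 1]]
            ss = b.sequence[sc[i] : sc[i + 1]]
            identical += sum(1 for x, y in zip(qs, ss) if x == y)
    raw = int(round(alignments.score))
    q_span = (int(qc[0]) + 1, int(qc[-1]))
    s_span = (int(sc[0]) + 1, int(sc[-1]))
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        raw_score=raw,
        bit_score=bit_score(raw, params),
        evalue=evalue(raw, len(a), len(b), params),
        percent_identity=float(100.0 * identical / columns),
        query_coverage=100.0 * (q_span[1] - q_span[0] + 1) / len(a),
        query_span=q_span,
        subject_span=s_span,
        aligned_columns=int(columns),
    )


@dataclass
class SimilarityTable:
    """Best-hit rows passing the E-value threshold for ordered pairs.

    ``m_total`` / ``n_total`` record the sizes (numbers of sequences) of the
    query and subject sets.  At most one row per ordered (query, subject)
    pair is stored.
    """

    rows: list[AlignmentResult] = field(default_factory=list)
    m_total: int = 0
    n_total: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def hits_for(self, query_id: str) -> list[AlignmentResult]:
        return [r for r in self.rows if r.query_id == query_id]

    def best_hit(self, query_id: str) -> AlignmentResult | None:
        hits = self.hits_for(query_id)
        if not hits:
            return None
        return min(hits, key=lambda r: (r.evalue, -r.raw_score, r.subject_id))

    def matched_queries(self) -> set[str]:
        return {r.query_id for r in self.rows}

    def matched_subjects(self) -> set[str]:
        return {r.subject_id for r in self.rows}

    def to_dataframe(self):
        """BLAST outfmt-6-style table (plus qcovs), one row per passing pair."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "qseqid": r.query_id,
                    "sseqid": r.subject_id,
                    "pident": round(r.percent_identity, 2),
                    "length": r.aligned_columns,
                    "qstart": r.query_span[0],
                    "qend": r.query_span[1],
                    "sstart": r.subject_span[0],
                    "send": r.subject_span[1],
                    "evalue": r.evalue,
                    "bitscore": round(r.bit_score, 1),
                    "qcovs": round(r.query_coverage, 1),
                }
                for r in self.rows
            ],
            columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend",
                     "sstart", "send", "evalue", "bitscore", "qcovs"],
        )


def all_vs_all(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord] | None = None,
    params: ScoringParams | None = None,
) -> SimilarityTable:
    """All-vs-all similarity search; keeps pairs with ``E <= threshold``.

    With ``set_b=None`` the search runs within ``set_a`` (self-pairs
    excluded) — the "self-BLAST" mode used to verify family cohesion.  An
    empty result table is valid.
    """
    if params is None:
        params = ScoringParams()
    within = set_b is None
    queries = list(set_a)
    subjects = queries if within else list(set_b)
    if not queries or not subjects:
        raise ValueError("both sequence sets must be non-empty")
    table = SimilarityTable(m_total=len(queries), n_total=len(subjects))
    for q in queries:
        for s in subjects:
            if within and q.id == s.id:
                continue
            result = score_local(q, s, params)
            if result is not None and result.evalue <= params.evalue_threshold:
                table.rows.append(result)
    return table
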