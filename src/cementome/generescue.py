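"""Six-frame translation scan of genomic contigs against a query protein.

Genome annotation pipelines can miss genes; when a protein confidently
identified by mass spectrometry has no annotated coding sequence, its gene
may still sit on a contig, possibly split into segments (e.g. by an intron
or an assembly gap).  This module translates a contig in all six frames,
extracts stop-free peptide segments, aligns each against the query protein
and reports the ordered hits with the nucleotide gaps between them — enough
to recognise a split coding sequence such as two exons separated by
~100 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from cementome.align import AlignmentResult, ScoringParams, score_local
from cementome.seqio import SequenceRecord

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class SixFrameHit:
    """A translated contig segment with a passing alignment to the query.

    ``contig_span`` is the 1-based inclusive nucleotide interval of the
    aligned part of the segment on the forward strand; its length is
    divisible by 3 and its translation in ``frame`` equals
    ``translated_segment``.
    """

    frame: int
    contig_span: tuple[int, int]
    translated_segment: str
    alignment: AlignmentResult


def six_frame_translate(
    contig: SequenceRecord, min_len: int = 30
) -> list[tuple[int, tuple[int, int], str]]:
    """Stop-free peptides of length >= ``min_len`` in all six frames.

    Returns ``(frame, forward_span, peptide)`` triples; reverse-strand
    spans are reported in forward 1-based coordinates.  Runs of N translate
    to X (any codon containing N is X).  Contigs shorter than 3 nt are a
    hard error.
    """
    if contig.alphabet != "dna":
        raise ValueError("six_frame_translate requires a dna record")
    seq = contig.sequence.upper()
    length = len(seq)
    if length < 3:
        raise ValueError("contig shorter than one codon")
    out: list[tuple[int, tuple[int, int], str]] = []
    for frame in FRAMES:
        if frame > 0:
            strand_seq = seq
            offset = frame - 1
        else:
            strand_seq = str(Seq(seq).reverse_complement())
            offset = -frame - 1
        n_codons = (len(strand_seq) - offset) // 3
        if n_codons <= 0:
            continue
        peptide = _translate(strand_seq[offset : offset + 3 * n_codons])
        start_codon = 0
        for segment in peptide.split("*"):
            if len(segment) >= min_len:
                # codon interval [start_codon, start_codon + len(segment)) on this strand
                s_nt = offset + 3 * start_codon + 1  # 1-based on strand
                e_nt = offset + 3 * (start_codon + len(segment))
                if frame > 0:
                    span = (s_nt, e_nt)
                else:
                    span = (length - e_nt + 1, length - s_nt + 1)
                out.append((frame, span, segment))
            start_codon += len(segment) + 1  # skip the stop codon
    return out


def _translate(cds: str) -> str:
    """Standard-code translation; any codon containing N becomes X."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        out.append("X" if "N" in codon else str(Seq(codon).translate()))
    return "".join(out)


def scan_contig(
    query: SequenceRecord,
    contig: SequenceRecord,
    params: ScoringParams | None = None,
    min_len: int = 30,
) -> list[SixFrameHit]:
    """Align every six-frame segment to ``query``; keep passing, non-overlapping hits.

    Hits with ``E <= threshold`` are retained; when two hits overlap on the
    contig the one with the higher bit score wins (no chaining).  Hits are
    returned sorted by forward contig position.  The stored contig span is
    trimmed to the aligned part of the segment.
    """
    if params is None:
        params = ScoringParams()
    if query.alphabet != "protein":
        raise ValueError("query must be a protein record")
    candidates: list[SixFrameHit] = []
    for frame, (seg_start, seg_end), peptide in six_frame_translate(contig, min_len=min_len):
        segment = SequenceRecord(
            id=f"{contig.id}|frame{frame:+d}|{seg_start}-{seg_end}",
            sequence=peptide,
            alphabet="protein",
        )
        result = score_local(query, segment, params)
        if result is None or result.evalue > params.evalue_threshold:
            continue
        aa_s, aa_e = result.subject_span  # within the segment peptide
        if frame > 0:
            span = (seg_start + 3 * (aa_s - 1), seg_start + 3 * aa_e - 1)
            aligned_pep = peptide[aa_s - 1 : aa_e]
        else:
            span = (seg_end - 3 * aa_e + 1, seg_end - 3 * (aa_s - 1))
            aligned_pep = peptide[aa_s - 1 : aa_e]
        candidates.append(SixFrameHit(frame=frame, contig_span=span,
                                      translated_segment=aligned_pep, alignment=result))
    candidates.sort(key=lambda h: (-h.alignment.bit_score, h.contig_span))
    kept: list[SixFrameHit] = []
    for hit in candidates:
        if all(hit.contig_span[1] < k.contig_span[0] or hit.contig_span[0] > k.contig_span[1]
               for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.contig_span)
    return kept


@dataclass
class GapReport:
    """Ordered hits with inter-hit nucleotide gaps and query coverage union."""

    hits: list[SixFrameHit]
    nt_gaps: list[int]
    aa_gaps: list[int]
    query_coverage_union: float  # percent of query covered by any hit


def report_gap_structure(hits: list[SixFrameHit], query_length: int) -> GapReport:
    """Nucleotide/amino-acid gaps between consecutive hits and union coverage.

    ``nt_gaps[i]`` is the number of nucleotides strictly between hit i and
    hit i+1 on the contig; ``aa_gaps`` the analogous distance between the
    query spans (0 when the spans touch or overlap).
    """
    hits = sorted(hits, key=lambda h: h.contig_span)
    nt_gaps = [
        max(0, hits[i + 1].contig_span[0] - hits[i].contig_span[1] - 1)
        for i in range(len(hits) - 1)
    ]
    by_query = sorted(hits, key=lambda h: h.alignment.query_span)
    aa_gaps = [
        max(0, by_query[i + 1].alignment.query_span[0] - by_query[i].alignment.query_span[1] - 1)
        for i in range(len(by_query) - 1)
    ]
    covered: set[int] = set()
    for hit in hits:
        s, e = hit.alignment.query_span
        covered.update(range(s, e + 1))
    coverage = 100.0 * len(covered) / query_length if query_length else 0.0
    return GapReport(hits=hits, nt_gaps=nt_gaps, aa_gaps=aa_gaps, query_coverage_union=coverage)


def hits_to_dataframe(hits: list[SixFrameHit]) -> pd.DataFrame:
    """Hit table (frame, contig/query spans, identity, coverage, E-value)."""
    return pd.DataFrame(
        [
            {
                "frame": h.frame,
                "contig_start": h.contig_span[0],
                "contig_end": h.contig_span[1],
                "query_start": h.alignment.query_span[0],
                "query_end": h.alignment.query_span[1],
                "pident": round(h.alignment.percent_identity, 1),
                "qcov": round(h.alignment.query_coverage, 1),
                "evalue": h.alignment.evalue,
            }
            for h in hits
        ],
        columns=["frame", "contig_start", "contig_end", "query_start", "query_end",
                 "pident", "qcov", "evalue"],
    )


def hits_to_bed(hits: list[SixFrameHit], contig_id: str) -> pd.DataFrame:
    """BED-style spans (0-based half-open start/end, strand from frame sign)."""
    return pd.DataFrame(
        [
            {
                "chrom": contig_id,
                "start": h.contig_span[0] - 1,
                "end": h.contig_span[1],
                "name": f"hit_frame{h.frame:+d}",
                "score": int(h.alignment.bit_score),
                "strand": "+" if h.frame > 0 else "-",
            }
            for h in hits
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
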