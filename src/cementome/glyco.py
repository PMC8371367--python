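"""Glycosylation-site heuristics and group summaries.

These are documented motif/context heuristics, not a trained predictor:

* N-linked sites: the canonical sequon N-X-S/T with X != P.
* O-linked sites: S/T residues in a mucin-like context — a local window
  enriched in Ser/Thr/Pro.

Heuristic site counts are comparable between groups of proteins analysed
with the same rules (e.g. Gly/Ser/Thr-rich vs Leu-rich cement proteins) but
are not calibrated against any machine-learned predictor's absolute counts;
every serialized output states this in its header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from cementome.seqio import SequenceRecord

logger = logging.getLogger(__name__)

HEURISTIC_NOTE = (
    "# sites from sequon/mucin-context heuristics (not a trained predictor); "
    "counts are comparable across groups, not to external predictors"
)


@dataclass(frozen=True)
class GlycoPrediction:
    """Predicted N- and O-glycosylation positions (1-based, increasing)."""

    accession: str
    n_sites: tuple[int, ...]
    o_sites: tuple[int, ...]


def predict_n_sites(record: SequenceRecord) -> tuple[int, ...]:
    """1-based positions of N in an N-X-S/T sequon (X != P)."""
    seq = record.sequence.upper()
    return tuple(
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    )


def predict_o_sites(record: SequenceRecord, window: int = 5, min_frac: float = 0.4) -> tuple[int, ...]:
    """1-based positions of S/T whose context is mucin-like.

    The context of position i is the sequence window of half-width
    ``window`` around i (truncated at the ends); the site is called when at
    least ``min_frac`` of the window's residues are S, T or P.
    """
    seq = record.sequence.upper()
    out = []
    for i, ch in enumerate(seq):
        if ch not in "ST":
            continue
        chunk = seq[max(0, i - window) : i + window + 1]
        frac = sum(1 for c in chunk if c in "STP") / len(chunk)
        if frac >= min_frac:
            out.append(i + 1)
    return tuple(out)


def predict_glyco(record: SequenceRecord, window: int = 5, min_frac: float = 0.4) -> GlycoPrediction:
    return GlycoPrediction(
        accession=record.id,
        n_sites=predict_n_sites(record),
        o_sites=predict_o_sites(record, window=window, min_frac=min_frac),
    )


def group_glyco_summary(
    predictions: list[GlycoPrediction],
    groups: dict[str, str],
) -> pd.DataFrame:
    """Totals and per-protein means of N/O sites per group.

    ``groups`` maps accession -> group name (composition group, pheromone
    family, ...).  Groups with no predicted proteins are omitted with a
    warning.
    """
    by_acc = {p.accession: p for p in predictions}
    rows = []
    for group in sorted(set(groups.values())):
        members = [acc for acc, g in groups.items() if g == group and acc in by_acc]
        if not members:
            logger.warning("group %r has no proteins with predictions; omitted", group)
            continue
        n_counts = [len(by_acc[m].n_sites) for m in members]
        o_counts = [len(by_acc[m].o_sites) for m in members]
        rows.append(
            {
                "group": group,
                "n_proteins": len(members),
                "total_n_sites": sum(n_counts),
                "total_o_sites": sum(o_counts),
                "mean_n_sites": sum(n_counts) / len(members),
                "mean_o_sites": sum(o_counts) / len(members),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_proteins", "total_n_sites",
                                       "total_o_sites", "mean_n_sites", "mean_o_sites"])


def sites_in_domains(
    prediction: GlycoPrediction,
    domain_spans: dict[str, tuple[int, int]],
    sequence_length: int,
) -> pd.DataFrame:
    """Count N/O sites inside each domain span (1-based inclusive, boundaries in)."""
    rows = []
    for domain, (start, end) in sorted(domain_spans.items()):
        if not (1 <= start <= end <= sequence_length):
            raise ValueError(
                f"domain {domain!r} span [{start},{end}] outside sequence of length {sequence_length}"
            )
        rows.append(
            {
                "accession": prediction.accession,
                "domain": domain,
                "start": start,
                "end": end,
                "n_sites": sum(1 for p in prediction.n_sites if start <= p <= end),
                "o_sites": sum(1 for p in prediction.o_sites if start <= p <= end),
            }
        )
    return pd.DataFrame(rows, columns=["accession", "domain", "start", "end", "n_sites", "o_sites"])
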