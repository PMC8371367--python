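"""Find a split coding sequence on a genomic contig by six-frame scanning.

Back-translates a query protein into a contig whose coding sequence is
split into two exons by a 120-nt stop-rich spacer, then recovers both
segments by aligning every six-frame translation against the query.
"""

import numpy as np

from cementome import generescue
from cementome.align import ScoringParams
from cementome.seqio import AMINO_ACIDS, SequenceRecord
from cementome.synthetic import _class_freqs, build_split_cds_contig

rng = np.random.default_rng(3)
freqs = _class_freqs("uniform")
query = SequenceRecord(id="query", sequence="".join(
    rng.choice(list(AMINO_ACIDS), size=200, p=freqs)))

contig, truth_spans = build_split_cds_contig(query, gap_nt=120, seed=3)
print(f"contig length {len(contig)} nt; planted exon spans {truth_spans}")

hits = generescue.scan_contig(query, contig, ScoringParams())
print(generescue.hits_to_dataframe(hits).to_string(index=False))

report = generescue.report_gap_structure(hits, len(query))
print(f"\nnucleotide gap(s) between hits : {report.nt_gaps}")
print(f"query coverage of all hits     : {report.query_coverage_union:.0f}%")
# Two hits separated by a ~100-nt gap on the contig, together covering the
# whole query, are the signature of an unannotated gene split by an intron
# or an assembly artefact.
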