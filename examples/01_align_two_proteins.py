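"""Locally align two related proteins and read the similarity statistics.

Builds a pair of proteins where the second is a point-mutated copy of the
first at 60% identity, runs the exact affine-gap local aligner and prints
the raw/bit score, E-value, percent identity and query coverage.
"""

import numpy as np

from cementome import ScoringParams, score_local
from cementome.seqio import SequenceRecord
from cementome.synthetic import BACKGROUND_FREQS, mutate_sequence

rng = np.random.default_rng(0)
letters = list(BACKGROUND_FREQS)
freqs = np.array(list(BACKGROUND_FREQS.values()))
base = "".join(rng.choice(letters, size=240, p=freqs / freqs.sum()))

query = SequenceRecord(id="queryA", sequence=base)
subject = SequenceRecord(id="subjectB", sequence=mutate_sequence(base, 0.6, rng))

result = score_local(query, subject, ScoringParams())
print(f"raw score      : {result.raw_score}")
print(f"bit score      : {result.bit_score:.1f}")
print(f"E-value        : {result.evalue:.3g}")
print(f"identity       : {result.percent_identity:.1f}%")
print(f"query coverage : {result.query_coverage:.1f}%")
# The E-value is the number of equally good alignments expected between two
# random sequences of these lengths; anything at or below 1e-4 counts as a
# cross-species match in the proteome comparison.
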