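import numpy as np
import pytest

from cementome import align, classify
from cementome.synthetic import SyntheticConfig, generate_proteome_pair, BACKGROUND_FREQS
from cementome.seqio import AMINO_ACIDS, SequenceRecord


@pytest.fixture(scope="session")
def params():
    return align.ScoringParams()


def random_protein(rng, length, acc="p"):
    """Background-composition random protein (calibrated for BLOSUM62 stats)."""
    letters = list(AMINO_ACIDS)
    freqs = np.array([BACKGROUND_FREQS[aa] for aa in letters])
    freqs = freqs / freqs.sum()
    return SequenceRecord(
        id=acc, sequence="".join(rng.choice(letters, size=length, p=freqs)), alphabet="protein"
    )


@pytest.fixture(scope="session")
def uniform_bundle():
    """Fixture pair with planted homology but no composition bias.

    The alignment-truth fixtures deliberately use background-composition
    sequences so that sequence identity is the only similarity signal."""
    return generate_proteome_pair(SyntheticConfig(seed=0, class_mix={"uniform": 1.0}))


@pytest.fixture(scope="session")
def biased_bundle():
    """Fixture pair with the default composition-class mix."""
    return generate_proteome_pair(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def uniform_analysis(uniform_bundle, params):
    """Classification + retained records + similarity tables for the uniform pair."""
    d = uniform_bundle
    ca = classify.classify_proteome(d.records_a, d.annotations_a)
    cb = classify.classify_proteome(d.records_b, d.annotations_b)
    retained_a = [r for r in d.records_a if not ca.loc[r.id, "excluded"]]
    retained_b = [r for r in d.records_b if not cb.loc[r.id, "excluded"]]
    cross = align.all_vs_all(retained_a, retained_b, params)
    return {
        "bundle": d,
        "assign_a": ca,
        "assign_b": cb,
        "retained_a": retained_a,
        "retained_b": retained_b,
        "cross": cross,
    }


def make_hit(query_id, subject_id, evalue=1e-6, pident=50.0, raw=100):
    """Stub similarity row for graph/table tests."""
    return align.AlignmentResult(
        query_id=query_id, subject_id=subject_id, raw_score=raw, bit_score=40.0,
        evalue=evalue, percent_identity=pident, query_coverage=80.0,
        query_span=(1, 10), subject_span=(1, 10), aligned_columns=10,
    )
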