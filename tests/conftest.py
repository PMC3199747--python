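import numpy as np
import pytest

from dichot.model import (
    DisorderSource,
    DisorderState,
    DisorderTrack,
    EvidenceBundle,
    HomologyHit,
    Interval,
    Protein,
)


def track_a(states):
    """Build a predictor_a track from an iterable of 'ID'/'unassigned'."""
    return DisorderTrack(DisorderSource.PREDICTOR_A, np.asarray(list(states), dtype="<U10"))


def track_b(states):
    """Build a predictor_b track from an iterable of 'ID'/'SD'."""
    return DisorderTrack(DisorderSource.PREDICTOR_B, np.asarray(list(states), dtype="<U10"))


def uniform_tracks(n, a_state="unassigned", b_state="SD"):
    return track_a([a_state] * n), track_b([b_state] * n)


def make_protein(length, pid="P1"):
    return Protein(id=pid, sequence="A" * length)


def make_bundle(length, hits=(), regions=(), pfam=(), a=None, b=None):
    ta, tb = uniform_tracks(length)
    return EvidenceBundle(
        hits=list(hits),
        regions=list(regions),
        pfam=list(pfam),
        track_a=a if a is not None else ta,
        track_b=b if b is not None else tb,
    )


def hit(start, end, subject_length, subject_id="1abcA"):
    return HomologyHit(Interval(start, end), subject_id, subject_length)


@pytest.fixture
def mixed_protein():
    """The worked 200-residue fixture: KD 1-80, deferred short hit 81-120
    (predictor_b=SD / predictor_a=unassigned there), predictor_a=ID
    elsewhere. External 1-based coordinates in the comments; internal
    half-open in the code."""
    n = 200
    protein = make_protein(n, "MIXED")
    a = ["ID"] * n
    b = ["ID"] * n
    for i in range(80, 120):  # external 81..120
        a[i] = "unassigned"
        b[i] = "SD"
    for i in range(0, 80):  # under the KD hit; stage one masks it anyway
        a[i] = "ID"
    bundle = EvidenceBundle(
        hits=[hit(0, 80, 300), hit(80, 120, 45)],
        track_a=track_a(a),
        track_b=track_b(b),
    )
    return protein, bundle
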