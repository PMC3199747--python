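"""The two-stage decision procedure partitioning proteins into KD/CD/ID.

Stage one masks known structural domains (KDs): residues covered by a
homology hit to a known structure of adequate subject length, by a curated
region annotation (transmembrane, signal/transit peptide, coiled coil), or
by a fibrous Pfam domain (collagen PF01391, alpha-keratin PF00038).
Regions aligned only to short known-structure sequences (subject shorter
than 50 residues) are deferred to stage two rather than masked, because
short PDB entries are often functional disordered regions crystallized in
complex with a partner.

Stage two classifies every unmasked residue from the two disorder tracks:

* predictor_a calls ID            -> ID (regardless of predictor_b)
* predictor_b calls ID, a does not -> ID
* predictor_b calls SD, a does not call ID -> candidate cryptic domain (CD)

Maximal runs of candidate-CD residues strictly longer than the CD minimum
(default 30) become CD segments; shorter runs are relabeled ID so the
output remains a gap-free binary (ordered/disordered) partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DisorderState,
    EvidenceBundle,
    Protein,
    Segment,
    Segmentation,
    SegmentLabel,
    Interval,
)

__all__ = [
    "SegmenterConfig",
    "assign_known_domains",
    "classify_residual",
    "extract_segments",
    "segment_protein",
    "segment_proteome",
]

DEFAULT_FIBROUS_PFAM_IDS = frozenset({"PF01391", "PF00038"})


@dataclass(frozen=True)
class SegmenterConfig:
    """Tunable thresholds of the decision procedure.

    short_subject_threshold
        Homology hits whose *subject* (the known-structure sequence) is
        shorter than this many residues do not assign KD; their residues
        are deferred to disorder-based classification. Default 50.
    cd_min_length
        A candidate cryptic-domain run must be strictly longer than this
        to become a CD segment. Default 30.
    cd_strictly_longer
        If False, runs of exactly ``cd_min_length`` also qualify.
    fibrous_pfam_ids
        Pfam families treated as known fibrous structure.
    """

    short_subject_threshold: int = 50
    cd_min_length: int = 30
    cd_strictly_longer: bool = True
    fibrous_pfam_ids: frozenset[str] = field(default=DEFAULT_FIBROUS_PFAM_IDS)

    def __post_init__(self) -> None:
        if self.short_subject_threshold < 1 or self.cd_min_length < 1:
            raise ValueError("thresholds must be positive")


def assign_known_domains(
    protein: Protein, bundle: EvidenceBundle, config: SegmenterConfig = SegmenterConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Stage one: mask known structural domains.

    Returns ``(kd_mask, deferred_mask)``, both boolean per-residue arrays.
    A residue is KD if covered by any qualifying homology hit
    (``subject_length >= short_subject_threshold``), any region annotation,
    or any fibrous Pfam hit; the three are equal-rank evidence. A residue
    covered *only* by sub-threshold hits is deferred (classified in stage
    two). Resolution is per residue: a residue keeps the best evidence
    covering it even when a short hit partially overlaps a qualifying one.
    """
    n = protein.length
    bundle.validate(n, protein.id)
    kd = np.zeros(n, dtype=bool)
    short = np.zeros(n, dtype=bool)

    for hit in bundle.hits:
        target = kd if hit.subject_length >= config.short_subject_threshold else short
        target[hit.interval.start : hit.interval.end] = True
    for region in bundle.regions:
        kd[region.interval.start : region.interval.end] = True
    for pfam in bundle.pfam:
        if pfam.pfam_id in config.fibrous_pfam_ids:
            kd[pfam.interval.start : pfam.interval.end] = True

    deferred = short & ~kd
    return kd, deferred


def classify_residual(
    protein: Protein,
    kd_mask: np.ndarray,
    track_a,
    track_b,
    config: SegmenterConfig = SegmenterConfig(),
) -> np.ndarray:
    """Stage two: label non-KD residues ID or CD from the disorder tracks.

    Returns a per-residue label vector over {'KD', 'CD', 'ID'}.
    """
    n = protein.length
    for track in (track_a, track_b):
        if len(track.calls) != n:
            raise ValueError(
                f"{protein.id}: {track.source} track length {len(track.calls)} != {n}"
            )
    a_id = track_a.calls == DisorderState.ID.value
    b_id = track_b.calls == DisorderState.ID.value
    b_sd = track_b.calls == DisorderState.SD.value

    labels = np.empty(n, dtype="<U2")
    labels[kd_mask] = SegmentLabel.KD.value
    free = ~kd_mask
    labels[free & (a_id | b_id)] = SegmentLabel.ID.value
    candidate = free & ~a_id & b_sd
    labels[candidate] = SegmentLabel.CD.value

    # demote candidate-CD runs that are too short to be credible domains
    limit = config.cd_min_length
    idx = np.flatnonzero(candidate)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for rs, re in zip(run_starts, run_ends):
            run_len = int(idx[re] - idx[rs] + 1)
            too_short = run_len <= limit if config.cd_strictly_longer else run_len < limit
            if too_short:
                labels[idx[rs] : idx[re] + 1] = SegmentLabel.ID.value
    return labels


def extract_segments(label_vector: np.ndarray, protein_id: str = "?") -> Segmentation:
    """Collapse a per-residue label vector into maximal same-label segments."""
    labels = np.asarray(label_vector, dtype="<U2")
    if labels.size == 0:
        raise ValueError(f"{protein_id}: empty label vector")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    segments = [
        Segment(Interval(int(a), int(b)), SegmentLabel(str(labels[a])))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return Segmentation(protein_id=protein_id, segments=segments)


def segment_protein(
    protein: Protein, bundle: EvidenceBundle, config: SegmenterConfig = SegmenterConfig()
) -> Segmentation:
    """Run both stages and return the protein's KD/CD/ID tiling.

    Deterministic: identical inputs always give identical output.
    """
    kd_mask, _deferred = assign_known_domains(protein, bundle, config)
    labels = classify_residual(protein, kd_mask, bundle.track_a, bundle.track_b, config)
    return extract_segments(labels, protein.id)


def segment_proteome(
    proteins,
    bundles,
    config: SegmenterConfig = SegmenterConfig(),
) -> list[Segmentation]:
    """Segment every protein; ``bundles`` maps protein id to EvidenceBundle."""
    out = []
    for protein in proteins:
        try:
            bundle = bundles[protein.id]
        except KeyError:
            raise KeyError(f"no evidence bundle for protein {protein.id}") from None
        out.append(segment_protein(protein, bundle, config))
    return out
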