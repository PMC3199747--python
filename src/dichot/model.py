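"""Domain types for residue-wise protein segmentation.

Internal coordinates are 0-based half-open throughout; every on-disk format
(FASTA headers aside) uses 1-based inclusive coordinates, the Swiss-Prot/GFF
convention. Conversion happens only at the I/O boundary (:mod:`dichot.io`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SegmentLabel",
    "DisorderState",
    "DisorderSource",
    "HitSource",
    "RegionKind",
    "SiteKind",
    "Localization",
    "INTRACELLULAR",
    "EXTRACELLULAR",
    "Interval",
    "HomologyHit",
    "DisorderTrack",
    "RegionAnnotation",
    "PfamHit",
    "FeatureSite",
    "Protein",
    "Segment",
    "Segmentation",
    "EvidenceBundle",
]


class SegmentLabel(enum.StrEnum):
    """Residue classes: known domain, cryptic domain, intrinsic disorder."""

    KD = "KD"
    CD = "CD"
    ID = "ID"


class DisorderState(enum.StrEnum):
    ID = "ID"
    SD = "SD"
    UNASSIGNED = "unassigned"


class DisorderSource(enum.StrEnum):
    """The two per-residue disorder callers the decision layer consumes.

    ``predictor_a`` is a DISOPRED2-style caller emitting {ID, unassigned};
    ``predictor_b`` is a CLADIST-style binary classifier emitting {ID, SD}
    for every residue.
    """

    PREDICTOR_A = "predictor_a"
    PREDICTOR_B = "predictor_b"


class HitSource(enum.StrEnum):
    BLAST = "blast"
    RPSBLAST = "rpsblast"
    HMM = "hmm"


class RegionKind(enum.StrEnum):
    TRANSMEMBRANE = "transmembrane"
    SIGNAL_PEPTIDE = "signal_peptide"
    TRANSIT_PEPTIDE = "transit_peptide"
    COILED_COIL = "coiled_coil"
    COLLAGEN = "collagen"
    KERATIN = "keratin"


class SiteKind(enum.StrEnum):
    PHOSPHORYLATION = "phosphorylation"
    N_GLYCOSYLATION = "n_glycosylation"
    O_GLYCOSYLATION = "o_glycosylation"
    CLEAVAGE = "cleavage"
    DISULFIDE = "disulfide"
    BREAKPOINT = "breakpoint"
    AS_BOUNDARY = "as_boundary"
    EXON_BOUNDARY = "exon_boundary"


#: kinds whose sites carry two residue positions
PAIRED_SITE_KINDS = frozenset({SiteKind.DISULFIDE, SiteKind.AS_BOUNDARY})


class Localization(enum.StrEnum):
    """Controlled vocabulary of subcellular localization bins."""

    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    NUCLEUS_AND_CYTOPLASM = "nucleus_and_cytoplasm"
    PLASMA_MEMBRANE = "plasma_membrane"
    SECRETED = "secreted"
    ER_GOLGI = "er_golgi"
    MITOCHONDRION = "mitochondrion"
    MITOCHONDRIAL_MEMBRANE = "mitochondrial_membrane"
    MULTIPLE = "multiple"
    OTHER = "other"


INTRACELLULAR = frozenset(
    {Localization.NUCLEUS, Localization.CYTOPLASM, Localization.NUCLEUS_AND_CYTOPLASM}
)
EXTRACELLULAR = frozenset(
    {Localization.SECRETED, Localization.ER_GOLGI, Localization.PLASMA_MEMBRANE}
)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open residue interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class HomologyHit:
    """An alignment of a query region to a sequence of known structure."""

    interval: Interval
    subject_id: str
    subject_length: int
    source: HitSource = HitSource.BLAST

    def __post_init__(self) -> None:
        if self.subject_length < 1:
            raise ValueError("subject_length must be >= 1")


@dataclass
class DisorderTrack:
    """Per-residue disorder calls from one predictor.

    ``calls`` holds one :class:`DisorderState` value per residue.  A
    predictor_a track may not contain SD; a predictor_b track must call
    every residue ID or SD (no ``unassigned``).
    """

    source: DisorderSource
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U10")
        states = set(np.unique(self.calls))
        allowed = (
            {DisorderState.ID.value, DisorderState.UNASSIGNED.value}
            if self.source == DisorderSource.PREDICTOR_A
            else {DisorderState.ID.value, DisorderState.SD.value}
        )
        if not states <= allowed:
            raise ValueError(
                f"{self.source} track contains states {sorted(states - allowed)}; "
                f"allowed: {sorted(allowed)}"
            )

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class RegionAnnotation:
    """A curated region treated as structured by rule (TM, signal, ...)."""

    interval: Interval
    kind: RegionKind


@dataclass(frozen=True)
class PfamHit:
    interval: Interval
    pfam_id: str

    def __post_init__(self) -> None:
        if not (
            self.pfam_id.startswith("PF")
            and len(self.pfam_id) > 2
            and self.pfam_id[2:].isdigit()
        ):
            raise ValueError(f"malformed Pfam identifier: {self.pfam_id!r}")


@dataclass(frozen=True)
class FeatureSite:
    """A typed residue position (or pair) for a modification/splice event.

    Positions are 0-based. Disulfide bonds carry both bonded cysteines;
    alternative-splicing events carry both ends of the variable sequence.
    """

    kind: SiteKind
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.positions):
            raise ValueError("site positions must be non-negative")
        if self.kind == SiteKind.DISULFIDE and len(self.positions) != 2:
            raise ValueError("disulfide sites carry exactly two positions")
        if self.kind not in PAIRED_SITE_KINDS and len(self.positions) not in (1, 2):
            raise ValueError("sites carry one or two positions")


@dataclass
class Protein:
    """A protein sequence with optional localization and feature sites."""

    id: str
    sequence: str
    localization: Localization | None = None
    sites: list[FeatureSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    interval: Interval
    label: SegmentLabel


@dataclass
class Segmentation:
    """An ordered, gap-free, non-overlapping KD/CD/ID tiling of a protein."""

    protein_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"{self.protein_id}: empty segmentation")
        if self.segments[0].interval.start != 0:
            raise ValueError(f"{self.protein_id}: first segment does not start at 0")
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.interval.start != prev.interval.end:
                raise ValueError(f"{self.protein_id}: segments do not tile")
            if cur.label == prev.label:
                raise ValueError(f"{self.protein_id}: adjacent segments share a label")

    @property
    def length(self) -> int:
        return self.segments[-1].interval.end

    def labels(self) -> np.ndarray:
        """Expand to a per-residue label vector (array of 'KD'/'CD'/'ID')."""
        out = np.empty(self.length, dtype="<U2")
        for seg in self.segments:
            out[seg.interval.start : seg.interval.end] = seg.label.value
        return out

    def label_at(self, pos: int) -> SegmentLabel:
        if not 0 <= pos < self.length:
            raise IndexError(f"{self.protein_id}: position {pos} outside [0, {self.length})")
        for seg in self.segments:
            if seg.interval.contains(pos):
                return seg.label
        raise AssertionError("unreachable: segments tile the protein")

    def residue_counts(self) -> dict[SegmentLabel, int]:
        counts = {label: 0 for label in SegmentLabel}
        for seg in self.segments:
            counts[seg.label] += len(seg.interval)
        return counts


@dataclass
class EvidenceBundle:
    """Everything the segmenter consumes for one protein."""

    hits: list[HomologyHit] = field(default_factory=list)
    track_a: DisorderTrack | None = None
    track_b: DisorderTrack | None = None
    regions: list[RegionAnnotation] = field(default_factory=list)
    pfam: list[PfamHit] = field(default_factory=list)

    def validate(self, protein_length: int, protein_id: str = "?") -> None:
        """Check length consistency and in-bounds intervals; raise ValueError."""
        if self.track_a is None or self.track_b is None:
            raise ValueError(f"{protein_id}: both disorder tracks are required")
        for track in (self.track_a, self.track_b):
            if len(track) != protein_length:
                raise ValueError(
                    f"{protein_id}: {track.source} track length {len(track)} "
                    f"!= protein length {protein_length}"
                )
        if self.track_b is not None:
            if DisorderState.UNASSIGNED.value in self.track_b.calls:
                raise ValueError(f"{protein_id}: predictor_b track does not cover every residue")
        for name, ivs in (
            ("hit", [h.interval for h in self.hits]),
            ("region", [r.interval for r in self.regions]),
            ("pfam", [p.interval for p in self.pfam]),
        ):
            for iv in ivs:
                if iv.end > protein_length:
                    raise ValueError(
                        f"{protein_id}: {name} interval [{iv.start},{iv.end}) exceeds "
                        f"protein length {protein_length}"
                    )


def labels_from_states(states: Sequence[str]) -> np.ndarray:
    """Convenience: build a '<U2' label vector from an iterable of strings."""
    return np.asarray([SegmentLabel(s).value for s in states], dtype="<U2")
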