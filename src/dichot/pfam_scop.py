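"""Pfam coverage per residue class and SCOP-superfamily extrapolations.

Pfam defines domains from sequence conservation alone, so Pfam hits land in
known domains, cryptic domains and disordered regions alike; because the
segmenter never consults general Pfam hits, per-class Pfam coverage is an
independent check on the segmentation. Two extrapolations estimate how many
distinct folds (SCOP superfamilies) the cryptic domains may harbor: one
assumes a constant superfamilies-per-unique-Pfam-domain ratio between KDs
and CDs, the other a constant superfamilies-per-residue ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import PfamHit, Segmentation, SegmentLabel

__all__ = [
    "PfamCoverageTable",
    "SuperfamilyEstimate",
    "pfam_coverage_by_class",
    "estimate_superfamilies_by_domain_ratio",
    "estimate_superfamilies_by_residue_ratio",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero-half (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PfamCoverageTable:
    """Per-class residue totals, Pfam-covered residues and unique domains."""

    total: dict[SegmentLabel, int]
    covered: dict[SegmentLabel, int]
    unique_domains: dict[SegmentLabel, int]

    def __post_init__(self) -> None:
        for label in SegmentLabel:
            if self.covered[label] > self.total[label]:
                raise ValueError(f"{label.value}: covered exceeds total")

    def coverage(self, label: SegmentLabel) -> float:
        """Covered / total for one class (0.0 when the class is empty)."""
        return self.covered[label] / self.total[label] if self.total[label] else 0.0

    def coverage_percent(self, label: SegmentLabel, ndigits: int = 1) -> float:
        """Coverage as a percentage rounded to ``ndigits`` decimals."""
        return round(100.0 * self.coverage(label), ndigits)

    @classmethod
    def from_counts(
        cls,
        total: Mapping[SegmentLabel, int],
        covered: Mapping[SegmentLabel, int],
        unique_domains: Mapping[SegmentLabel, int] | None = None,
    ) -> "PfamCoverageTable":
        """Build the table directly from per-class residue counts."""
        return cls(
            total={lab: int(total[lab]) for lab in SegmentLabel},
            covered={lab: int(covered[lab]) for lab in SegmentLabel},
            unique_domains={
                lab: int(unique_domains[lab]) if unique_domains else 0
                for lab in SegmentLabel
            },
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {
            lab.value: {
                "total_residues": self.total[lab],
                "pfam_residues": self.covered[lab],
                "pfam_coverage_percent": self.coverage_percent(lab),
                "unique_pfam_domains": self.unique_domains[lab],
            }
            for lab in SegmentLabel
        }
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class SuperfamilyEstimate:
    known_superfamilies: int
    ratio: float
    estimate: int

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("scaling ratio must be positive")


def pfam_coverage_by_class(
    segmentations: Sequence[Segmentation],
    pfam_hits: Mapping[str, Iterable[PfamHit]],
) -> PfamCoverageTable:
    """Tabulate residue-wise Pfam coverage for each class.

    A residue is Pfam-covered if any hit interval contains it (coverage is
    a set union: overlapping domains count a residue once). Covered
    residues are attributed to the class of the segment containing them.
    A domain overlapping several classes counts toward each class's
    unique-domain tally.
    """
    index = {s.protein_id: s for s in segmentations}
    for pid in pfam_hits:
        if pid not in index:
            raise KeyError(f"pfam hits reference unknown protein {pid!r}")

    total = {lab: 0 for lab in SegmentLabel}
    covered = {lab: 0 for lab in SegmentLabel}
    unique: dict[SegmentLabel, set[str]] = {lab: set() for lab in SegmentLabel}

    for pid, seg in index.items():
        labels = seg.labels()
        for lab in SegmentLabel:
            total[lab] += int(np.sum(labels == lab.value))
        hits = list(pfam_hits.get(pid, []))
        if not hits:
            continue
        mask = np.zeros(seg.length, dtype=bool)
        for hit in hits:
            if hit.interval.end > seg.length:
                raise ValueError(
                    f"protein {pid}: pfam hit [{hit.interval.start},{hit.interval.end}) "
                    f"exceeds length {seg.length}"
                )
            mask[hit.interval.start : hit.interval.end] = True
            hit_labels = set(labels[hit.interval.start : hit.interval.end])
            for lab_str in hit_labels:
                unique[SegmentLabel(lab_str)].add(hit.pfam_id)
        for lab in SegmentLabel:
            covered[lab] += int(np.sum(mask & (labels == lab.value)))

    return PfamCoverageTable(
        total=total,
        covered=covered,
        unique_domains={lab: len(unique[lab]) for lab in SegmentLabel},
    )


def estimate_superfamilies_by_domain_ratio(
    n_superfamilies_kd: int, unique_pfam_kd: int, unique_pfam_cd: int
) -> SuperfamilyEstimate:
    """Extrapolate CD superfamilies assuming a constant superfamilies-per-
    unique-Pfam-domain ratio between KDs and CDs."""
    if min(n_superfamilies_kd, unique_pfam_kd, unique_pfam_cd) < 1:
        raise ValueError("inputs must be positive integers")
    ratio = unique_pfam_cd / unique_pfam_kd
    return SuperfamilyEstimate(
        known_superfamilies=n_superfamilies_kd,
        ratio=ratio,
        estimate=round_half_up(n_superfamilies_kd * ratio),
    )


def estimate_superfamilies_by_residue_ratio(
    n_superfamilies_kd: int, fraction_kd: float, fraction_cd: float
) -> SuperfamilyEstimate:
    """Extrapolate CD superfamilies assuming a constant superfamilies-per-
    residue ratio; fractions may be on any common scale (e.g. percent)."""
    if n_superfamilies_kd < 1 or fraction_kd <= 0 or fraction_cd <= 0:
        raise ValueError("inputs must be positive")
    ratio = fraction_cd / fraction_kd
    return SuperfamilyEstimate(
        known_superfamilies=n_superfamilies_kd,
        ratio=ratio,
        estimate=round_half_up(n_superfamilies_kd * ratio),
    )
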