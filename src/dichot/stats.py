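"""Proteome-wide statistics over KD/CD/ID segmentations.

Class fractions here are residue-weighted by default: a stratum's ID
fraction is (total ID residues in the stratum) / (total residues in the
stratum), the same convention used for the whole-proteome fractions. An
unweighted per-protein mean is available where a protein-wise average is
wanted instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    FeatureSite,
    Localization,
    Protein,
    Segmentation,
    SegmentLabel,
    SiteKind,
)

__all__ = [
    "ClassFractionTable",
    "IdRunSurvival",
    "SiteEnrichmentTable",
    "residue_class_fractions",
    "idp_run_survival",
    "filter_by_length",
    "localization_fractions",
    "site_id_fractions",
    "exon_boundary_fractions",
]

#: strata excluded from localization-stratified analyses
EXCLUDED_STRATA = frozenset({Localization.MULTIPLE, Localization.OTHER})


@dataclass(frozen=True)
class ClassFractionTable:
    """Residue counts and fractions per class for one stratum."""

    stratum: str
    counts: dict[SegmentLabel, int]
    n_proteins: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[SegmentLabel, float]:
        total = self.total
        return {label: self.counts[label] / total for label in SegmentLabel}

    def fraction(self, label: SegmentLabel) -> float:
        return self.counts[label] / self.total

    def to_series(self) -> pd.Series:
        data = {f"{lab.value}_residues": self.counts[lab] for lab in SegmentLabel}
        data |= {f"{lab.value}_fraction": self.fractions[lab] for lab in SegmentLabel}
        data["total_residues"] = self.total
        data["n_proteins"] = self.n_proteins
        return pd.Series(data, name=self.stratum)


@dataclass(frozen=True)
class IdRunSurvival:
    """Per-cutoff percentage of proteins with a long contiguous ID run."""

    cutoffs: tuple[int, ...]
    percentages: tuple[float, ...]
    n_proteins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "percent_proteins": self.percentages}
        )


@dataclass
class SiteEnrichmentTable:
    """Fraction of feature sites falling in ID regions, per stratum and kind.

    ``internal_standard`` is the stratum's residue-wise ID fraction: the
    expected site-in-ID fraction if sites were placed uniformly over the
    stratum's residues.
    """

    rows: list[dict] = field(default_factory=list)

    def add(self, stratum: str, kind: SiteKind, n_sites: int, n_in_id: int,
            internal_standard: float) -> None:
        self.rows.append(
            {
                "stratum": stratum,
                "kind": kind.value,
                "n_positions": n_sites,
                "n_in_id": n_in_id,
                "id_fraction": n_in_id / n_sites if n_sites else float("nan"),
                "internal_standard": internal_standard,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def fraction(self, stratum: str, kind: SiteKind) -> float:
        for row in self.rows:
            if row["stratum"] == stratum and row["kind"] == kind.value:
                return row["id_fraction"]
        raise KeyError((stratum, kind))


def residue_class_fractions(
    segmentations: Iterable[Segmentation], stratum: str = "all"
) -> ClassFractionTable:
    """Pool residue counts per class over a set of segmentations."""
    counts = {label: 0 for label in SegmentLabel}
    n = 0
    for seg in segmentations:
        for label, c in seg.residue_counts().items():
            counts[label] += c
        n += 1
    if n == 0:
        raise ValueError("residue_class_fractions: empty input")
    return ClassFractionTable(stratum=stratum, counts=counts, n_proteins=n)


def per_protein_id_fractions(segmentations: Iterable[Segmentation]) -> np.ndarray:
    """Per-protein residue-wise ID fraction (for unweighted averages)."""
    return np.array(
        [s.residue_counts()[SegmentLabel.ID] / s.length for s in segmentations]
    )


def idp_run_survival(
    segmentations: Sequence[Segmentation],
    cutoffs: Sequence[int],
    strict: bool = True,
) -> IdRunSurvival:
    """Percentage of proteins with a contiguous ID segment longer than each cutoff.

    A protein counts toward cutoff L if it has at least one maximal ID
    segment with length > L (>= L when ``strict`` is False); ID runs are
    never concatenated across interrupting KD/CD segments.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("idp_run_survival: empty cutoffs")
    if any(c <= 0 for c in cutoffs) or any(
        b <= a for a, b in zip(cutoffs, cutoffs[1:])
    ):
        raise ValueError("cutoffs must be positive and strictly increasing")
    if not segmentations:
        raise ValueError("idp_run_survival: empty input")

    longest = np.array(
        [
            max(
                (len(s.interval) for s in seg.segments if s.label == SegmentLabel.ID),
                default=0,
            )
            for seg in segmentations
        ]
    )
    n = len(segmentations)
    percentages = tuple(
        100.0 * float(np.mean(longest > c if strict else longest >= c)) for c in cutoffs
    )
    return IdRunSurvival(cutoffs=tuple(cutoffs), percentages=percentages, n_proteins=n)


def filter_by_length(
    proteins: Iterable[Protein], min_len: int, max_len: int
) -> list[Protein]:
    """Proteins with min_len <= length <= max_len (both bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    return [p for p in proteins if min_len <= p.length <= max_len]


def localization_fractions(
    segmentations: Sequence[Segmentation],
    localizations: Mapping[str, Localization],
    weighting: str = "residue",
) -> list[ClassFractionTable]:
    """Per-localization class fractions, ordered by descending ID fraction.

    Proteins labeled ``multiple`` or ``other`` are excluded; proteins
    annotated to both the nucleus and the cytoplasm form their own
    ``nucleus_and_cytoplasm`` stratum. ``weighting`` is ``"residue"``
    (pooled counts, default) or ``"protein"`` (unweighted mean of
    per-protein fractions; counts still reported pooled).
    """
    if weighting not in ("residue", "protein"):
        raise ValueError(f"unknown weighting {weighting!r}")
    by_stratum: dict[Localization, list[Segmentation]] = {}
    for seg in segmentations:
        try:
            loc = localizations[seg.protein_id]
        except KeyError:
            raise KeyError(f"no localization for protein {seg.protein_id}") from None
        if loc in EXCLUDED_STRATA:
            continue
        by_stratum.setdefault(loc, []).append(seg)

    tables = []
    for loc in Localization:
        if loc in EXCLUDED_STRATA:
            continue
        members = by_stratum.get(loc, [])
        if not members:
            warnings.warn(f"localization stratum {loc.value!r} has no proteins; omitted",
                          stacklevel=2)
            continue
        tables.append(residue_class_fractions(members, stratum=loc.value))

    if weighting == "residue":
        key = lambda t: t.fraction(SegmentLabel.ID)  # noqa: E731
    else:
        means = {
            t.stratum: float(np.mean(per_protein_id_fractions(by_stratum[Localization(t.stratum)])))
            for t in tables
        }
        key = lambda t: means[t.stratum]  # noqa: E731
    return sorted(tables, key=key, reverse=True)


def _segmentation_index(
    segmentations: Sequence[Segmentation],
) -> dict[str, Segmentation]:
    return {s.protein_id: s for s in segmentations}


def site_id_fractions(
    segmentations: Sequence[Segmentation],
    sites: Mapping[str, Sequence[FeatureSite]],
    localizations: Mapping[str, Localization],
    kinds: Sequence[SiteKind] | None = None,
    count_both_disulfide_positions: bool = True,
) -> SiteEnrichmentTable:
    """Fraction of feature-site positions in ID regions per stratum and kind.

    Each site position is judged either in an SD (KD and CD merged) or in
    an ID segment. Disulfide bonds contribute both bonded cysteines (one
    arbitrary position when ``count_both_disulfide_positions`` is False);
    alternative-splicing events contribute both ends of the variable
    sequence. The internal standard attached to every row is the stratum's
    residue-wise ID fraction.
    """
    index = _segmentation_index(segmentations)
    strata = localization_fractions(segmentations, localizations)
    standards = {t.stratum: t.fraction(SegmentLabel.ID) for t in strata}
    wanted = set(kinds) if kinds is not None else set(SiteKind)

    tallies: dict[tuple[str, SiteKind], list[int]] = {}
    for pid, site_list in sites.items():
        if pid not in index:
            continue
        loc = localizations.get(pid)
        if loc is None or loc in EXCLUDED_STRATA:
            continue
        seg = index[pid]
        labels = seg.labels()
        for site in site_list:
            if site.kind not in wanted:
                continue
            positions = site.positions
            if site.kind == SiteKind.DISULFIDE and not count_both_disulfide_positions:
                positions = positions[:1]
            for pos in positions:
                if not 0 <= pos < seg.length:
                    raise ValueError(
                        f"protein {pid}: {site.kind.value} site position {pos + 1} "
                        f"outside length {seg.length}"
                    )
                tally = tallies.setdefault((loc.value, site.kind), [0, 0])
                tally[0] += 1
                tally[1] += int(labels[pos] == SegmentLabel.ID.value)

    table = SiteEnrichmentTable()
    for stratum in standards:
        for kind in SiteKind:
            if kind not in wanted:
                continue
            tally = tallies.get((stratum, kind))
            if tally is None:
                continue
            table.add(stratum, kind, tally[0], tally[1], standards[stratum])
    observed_strata = {s for s, _ in tallies}
    for stratum in standards:
        if stratum not in observed_strata:
            warnings.warn(f"no feature sites in stratum {stratum!r}; omitted", stacklevel=2)
    return table


def exon_boundary_fractions(
    segmentations: Sequence[Segmentation],
    exon_sites: Mapping[str, Sequence[FeatureSite]],
    localizations: Mapping[str, Localization],
) -> SiteEnrichmentTable:
    """Site-in-ID fractions restricted to exon boundaries."""
    return site_id_fractions(
        segmentations, exon_sites, localizations, kinds=[SiteKind.EXON_BOUNDARY]
    )
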