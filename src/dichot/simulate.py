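"""Synthetic proteomes with known ground truth.

The generator emulates the statistical structure the analysis modules
measure on real proteomes: mixed domain/linker architectures with
configurable KD/CD/ID residue fractions, per-localization differences in
disorder content, noisy homology/disorder evidence, modification sites
placed with configurable ID-enrichment odds, and class-dependent Pfam
coverage. Sequence letters are uniform random amino acids — no downstream
stage reads composition.

Architectures are sampled as alternating runs of independent segments:
each segment is a disordered linker with probability p (solved so the
expected residue-wise ID fraction matches the localization's target) or a
domain, which is cryptic with probability ``cd_share``. Segment lengths
are shifted-exponential, so pooled fractions converge to their targets by
the law of large numbers. With all noise rates at zero the emitted
evidence reconstructs the true labels exactly under the segmenter's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .model import (
    DisorderSource,
    DisorderState,
    DisorderTrack,
    EvidenceBundle,
    FeatureSite,
    HitSource,
    HomologyHit,
    Interval,
    Localization,
    PfamHit,
    Protein,
    RegionAnnotation,
    RegionKind,
    Segment,
    Segmentation,
    SegmentLabel,
    SiteKind,
    EXTRACELLULAR,
    INTRACELLULAR,
)
from .segment import extract_segments

__all__ = [
    "SiteModel",
    "GeneratorConfig",
    "GroundTruth",
    "sample_proteome",
    "emit_evidence",
    "place_feature_sites",
    "emit_pfam_hits",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: default per-localization sampling weights (share of proteins)
DEFAULT_LOCALIZATION_WEIGHTS: dict[Localization, float] = {
    Localization.NUCLEUS: 0.16,
    Localization.CYTOPLASM: 0.18,
    Localization.NUCLEUS_AND_CYTOPLASM: 0.06,
    Localization.PLASMA_MEMBRANE: 0.14,
    Localization.SECRETED: 0.12,
    Localization.ER_GOLGI: 0.06,
    Localization.MITOCHONDRIAL_MEMBRANE: 0.03,
    Localization.MITOCHONDRION: 0.06,
    Localization.MULTIPLE: 0.10,
    Localization.OTHER: 0.09,
}

#: default residue-wise ID-fraction targets per localization; the nuclear
#: (0.47) and mitochondrial (0.13) anchors are the extremes of the human
#: proteome, the rest interpolate in the standard descending order
DEFAULT_ID_TARGETS: dict[Localization, float] = {
    Localization.NUCLEUS: 0.47,
    Localization.NUCLEUS_AND_CYTOPLASM: 0.42,
    Localization.CYTOPLASM: 0.38,
    Localization.PLASMA_MEMBRANE: 0.33,
    Localization.SECRETED: 0.27,
    Localization.ER_GOLGI: 0.22,
    Localization.MITOCHONDRIAL_MEMBRANE: 0.18,
    Localization.MITOCHONDRION: 0.13,
    Localization.MULTIPLE: 0.35,
    Localization.OTHER: 0.35,
}


@dataclass(frozen=True)
class SiteModel:
    """Per-feature-kind site placement model.

    ``mean_per_protein`` is the Poisson mean number of sites per eligible
    protein; ``id_odds`` the enrichment odds: a site lands in ID with
    probability q = odds * f / (odds * f + (1 - f)), f being the eligible
    stratum's residue-wise ID fraction. Odds 1 is the uniform null.
    """

    mean_per_protein: float
    id_odds: float

    def __post_init__(self) -> None:
        if self.mean_per_protein < 0 or self.id_odds < 0:
            raise ValueError("site model parameters must be non-negative")


DEFAULT_SITE_MODELS: dict[SiteKind, SiteModel] = {
    SiteKind.PHOSPHORYLATION: SiteModel(2.0, 3.0),
    SiteKind.O_GLYCOSYLATION: SiteModel(1.0, 3.0),
    SiteKind.N_GLYCOSYLATION: SiteModel(1.0, 1.0),
    SiteKind.CLEAVAGE: SiteModel(0.4, 2.0),
    SiteKind.DISULFIDE: SiteModel(1.0, 0.25),
    SiteKind.BREAKPOINT: SiteModel(0.15, 2.0),
    SiteKind.AS_BOUNDARY: SiteModel(0.8, 2.0),
    SiteKind.EXON_BOUNDARY: SiteModel(4.0, 1.0),
}

#: localizations eligible for each feature kind
_SITE_ELIGIBILITY: dict[SiteKind, frozenset[Localization]] = {
    SiteKind.PHOSPHORYLATION: INTRACELLULAR,
    SiteKind.N_GLYCOSYLATION: EXTRACELLULAR,
    SiteKind.O_GLYCOSYLATION: EXTRACELLULAR,
    SiteKind.DISULFIDE: EXTRACELLULAR,
    SiteKind.CLEAVAGE: EXTRACELLULAR,
    SiteKind.BREAKPOINT: frozenset(set(Localization)),
    SiteKind.AS_BOUNDARY: frozenset(set(Localization)),
    SiteKind.EXON_BOUNDARY: frozenset(set(Localization)),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic proteome.

    Defaults are anchored to the human-proteome values the analysis
    modules are meant to reproduce: overall class shares near 52/13/35
    (KD/CD/ID), nuclear ID fraction 0.47, mitochondrial 0.13, CD share
    among ordered residues 13/65, and per-class Pfam coverages
    0.606/0.266/0.085. Noise rates default to zero; noise is opt-in.
    """

    n_proteins: int = 2000
    length_log_mean: float = 5.9
    length_log_sigma: float = 0.45
    min_length: int = 60
    localization_weights: Mapping[Localization, float] = field(
        default_factory=lambda: dict(DEFAULT_LOCALIZATION_WEIGHTS)
    )
    id_targets: Mapping[Localization, float] = field(
        default_factory=lambda: dict(DEFAULT_ID_TARGETS)
    )
    cd_share: float = 13 / 65
    domain_mean_length: float = 110.0
    domain_min_length: int = 32
    linker_mean_length: float = 90.0
    linker_min_length: int = 4
    min_domain_segments: int = 0
    #: gain of the stratum-level controller steering realized ID fractions
    #: to their targets (0 disables feedback; sampling is then i.i.d.)
    target_feedback_gain: float = 5.0
    # evidence noise
    false_call_rate: float = 0.0
    missed_hit_rate: float = 0.0
    short_subject_rate: float = 0.0
    region_kd_rate: float = 0.05
    # feature sites
    site_models: Mapping[SiteKind, SiteModel] = field(
        default_factory=lambda: dict(DEFAULT_SITE_MODELS)
    )
    # Pfam emission
    pfam_coverage: Mapping[SegmentLabel, float] = field(
        default_factory=lambda: {
            SegmentLabel.KD: 0.606,
            SegmentLabel.CD: 0.266,
            SegmentLabel.ID: 0.085,
        }
    )
    pfam_pool_sizes: Mapping[SegmentLabel, int] = field(
        default_factory=lambda: {
            SegmentLabel.KD: 240,
            SegmentLabel.CD: 130,
            SegmentLabel.ID: 180,
        }
    )

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        w = sum(self.localization_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"localization weights sum to {w}, expected 1")
        for loc, f in self.id_targets.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"ID target for {loc} outside [0, 1]")
            if f == 1.0 and self.min_domain_segments > 0:
                raise ValueError(
                    f"ID target 1.0 for {loc} is infeasible with mandatory domains"
                )
        for rate in (
            self.false_call_rate,
            self.missed_hit_rate,
            self.short_subject_rate,
            self.region_kd_rate,
            self.cd_share,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for p in self.pfam_coverage.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("pfam coverage probabilities must lie in [0, 1]")
        if self.domain_min_length < 1 or self.linker_min_length < 1:
            raise ValueError("segment minimum lengths must be positive")

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def linker_probability(self, localization: Localization) -> float:
        """Per-segment linker probability realizing the localization's target.

        Solves f = p*Ll / (p*Ll + (1-p)*Ld) for p, where Ll and Ld are the
        mean linker and domain segment lengths.
        """
        f = self.id_targets[localization]
        ld, ll = self.domain_mean_length, self.linker_mean_length
        return f * ld / (f * ld + (1.0 - f) * ll)


@dataclass
class GroundTruth:
    """True residue labels and annotations of a synthetic proteome."""

    proteins: list[Protein]
    labels: dict[str, np.ndarray]
    localizations: dict[str, Localization]
    architectures: dict[str, list[Segment]]
    sites: dict[str, list[FeatureSite]] = field(default_factory=dict)

    def segmentations(self) -> list[Segmentation]:
        """True labels collapsed to Segmentation objects."""
        return [extract_segments(self.labels[p.id], p.id) for p in self.proteins]

    def id_fraction(self, localization: Localization | None = None) -> float:
        """Residue-wise true ID fraction, optionally for one stratum."""
        num = den = 0
        for p in self.proteins:
            if localization is not None and self.localizations[p.id] != localization:
                continue
            lab = self.labels[p.id]
            num += int(np.sum(lab == SegmentLabel.ID.value))
            den += lab.size
        if den == 0:
            raise ValueError(f"no proteins in stratum {localization}")
        return num / den


def _seg_length(rng: np.random.Generator, mean: float, minimum: int) -> int:
    return minimum + int(round(rng.exponential(max(mean - minimum, 1e-9))))


def _sample_architecture(
    rng: np.random.Generator,
    config: GeneratorConfig,
    localization: Localization,
    tally: list[int] | None = None,
) -> list[Segment]:
    """Sample segments until the target protein length is reached.

    ``tally`` is the stratum's running [ID residues, total residues]; when
    present, the linker probability is nudged toward closing the gap
    between the realized and the target ID fraction, so pooled stratum
    fractions concentrate tightly around their targets.
    """
    p_base = config.linker_probability(localization)
    f_target = config.id_targets[localization]
    gain = config.target_feedback_gain
    target = max(
        config.min_length, int(round(rng.lognormal(config.length_log_mean, config.length_log_sigma)))
    )
    while True:
        segments: list[Segment] = []
        pos = 0
        n_domains = 0
        id_res = 0
        while pos < target:
            p_linker = p_base
            if tally is not None and gain > 0 and tally[1] + pos > 0:
                realized = (tally[0] + id_res) / (tally[1] + pos)
                p_linker = min(1.0, max(0.0, p_base + gain * (f_target - realized)))
                if f_target == 0.0:
                    p_linker = 0.0
                elif f_target == 1.0:
                    p_linker = 1.0
            if rng.random() < p_linker:
                label = SegmentLabel.ID
                length = _seg_length(rng, config.linker_mean_length, config.linker_min_length)
            else:
                label = (
                    SegmentLabel.CD if rng.random() < config.cd_share else SegmentLabel.KD
                )
                n_domains += 1
                length = _seg_length(rng, config.domain_mean_length, config.domain_min_length)
            segments.append(Segment(Interval(pos, pos + length), label))
            pos += length
            if label == SegmentLabel.ID:
                id_res += length
        if n_domains >= config.min_domain_segments:
            if tally is not None:
                tally[0] += id_res
                tally[1] += pos
            return segments


def sample_proteome(
    config: GeneratorConfig, seed: int
) -> tuple[list[Protein], GroundTruth]:
    """Sample a proteome with per-protein true label vectors.

    Deterministic given (config, seed). Realized residue-wise ID fractions
    per localization converge to the configured targets as the proteome
    grows.
    """
    rng = np.random.default_rng(seed)
    locs = list(config.localization_weights)
    weights = np.array([config.localization_weights[l] for l in locs], dtype=float)
    weights /= weights.sum()

    proteins: list[Protein] = []
    labels: dict[str, np.ndarray] = {}
    localizations: dict[str, Localization] = {}
    architectures: dict[str, list[Segment]] = {}
    tallies: dict[Localization, list[int]] = {l: [0, 0] for l in locs}
    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        loc = locs[int(rng.choice(len(locs), p=weights))]
        segments = _sample_architecture(rng, config, loc, tallies[loc])
        length = segments[-1].interval.end
        vec = np.empty(length, dtype="<U2")
        for seg in segments:
            vec[seg.interval.start : seg.interval.end] = seg.label.value
        sequence = "".join(_AA[rng.integers(0, len(_AA), size=length)])
        proteins.append(Protein(id=pid, sequence=sequence, localization=loc))
        labels[pid] = vec
        localizations[pid] = loc
        architectures[pid] = segments

    truth = GroundTruth(
        proteins=proteins,
        labels=labels,
        localizations=localizations,
        architectures=architectures,
    )
    return proteins, truth


def emit_evidence(
    truth: GroundTruth, config: GeneratorConfig, seed: int
) -> dict[str, EvidenceBundle]:
    """Emit per-protein evidence bundles consistent with the ground truth.

    True KD segments emit a homology hit with an adequate subject length
    (or, at ``region_kd_rate``, a curated region annotation instead); at
    ``short_subject_rate`` a hit is emitted with a sub-threshold subject, a
    crystallized-fragment artifact. True CD segments emit predictor_b=SD /
    predictor_a=unassigned; true ID segments emit ID on both tracks. Each
    track call is flipped independently at ``false_call_rate``. With all
    noise rates zero the segmenter reconstructs the truth exactly.
    """
    rng = np.random.default_rng(seed)
    bundles: dict[str, EvidenceBundle] = {}
    region_kinds = [RegionKind.TRANSMEMBRANE, RegionKind.COILED_COIL]
    for protein in truth.proteins:
        pid = protein.id
        n = protein.length
        vec = truth.labels[pid]
        calls_a = np.full(n, DisorderState.UNASSIGNED.value, dtype="<U10")
        calls_b = np.full(n, DisorderState.SD.value, dtype="<U10")
        is_id = vec == SegmentLabel.ID.value
        calls_a[is_id] = DisorderState.ID.value
        calls_b[is_id] = DisorderState.ID.value

        hits: list[HomologyHit] = []
        regions: list[RegionAnnotation] = []
        for k, seg in enumerate(truth.architectures[pid]):
            if seg.label != SegmentLabel.KD:
                continue
            if rng.random() < config.region_kd_rate:
                regions.append(
                    RegionAnnotation(
                        interval=seg.interval,
                        kind=region_kinds[int(rng.integers(0, len(region_kinds)))],
                    )
                )
                continue
            if rng.random() < config.missed_hit_rate:
                continue
            if rng.random() < config.short_subject_rate:
                subject_length = int(rng.integers(20, 50))
            else:
                subject_length = max(50, len(seg.interval) + int(rng.integers(0, 40)))
            hits.append(
                HomologyHit(
                    interval=seg.interval,
                    subject_id=f"pdb_{pid}_{k}",
                    subject_length=subject_length,
                    source=HitSource.BLAST,
                )
            )

        r = config.false_call_rate
        if r > 0:
            flip_a = rng.random(n) < r
            flip_b = rng.random(n) < r
            a_id = calls_a == DisorderState.ID.value
            calls_a[flip_a & a_id] = DisorderState.UNASSIGNED.value
            calls_a[flip_a & ~a_id] = DisorderState.ID.value
            b_id = calls_b == DisorderState.ID.value
            calls_b[flip_b & b_id] = DisorderState.SD.value
            calls_b[flip_b & ~b_id] = DisorderState.ID.value

        bundles[pid] = EvidenceBundle(
            hits=hits,
            track_a=DisorderTrack(DisorderSource.PREDICTOR_A, calls_a),
            track_b=DisorderTrack(DisorderSource.PREDICTOR_B, calls_b),
            regions=regions,
        )
    return bundles


def _compartment_positions(vec: np.ndarray, in_id: bool) -> np.ndarray:
    mask = vec == SegmentLabel.ID.value
    return np.flatnonzero(mask if in_id else ~mask)


def place_feature_sites(
    truth: GroundTruth, config: GeneratorConfig, seed: int
) -> dict[str, list[FeatureSite]]:
    """Place feature sites with configurable ID-enrichment odds.

    For each kind, eligible proteins are those in the kind's localization
    strata (phosphorylation intracellular; glycosylation, disulfide and
    cleavage extracellular; splice/translocation/exon features everywhere).
    Each site lands in ID with probability q = odds*f / (odds*f + 1 - f),
    f being the eligible set's residue-wise ID fraction, then uniformly
    within the chosen compartment (proteins weighted by compartment size).
    The placed sites are also appended to ``truth.sites`` and to each
    protein's ``sites`` list.
    """
    rng = np.random.default_rng(seed)
    sites: dict[str, list[FeatureSite]] = {p.id: [] for p in truth.proteins}
    by_id = {p.id: p for p in truth.proteins}

    for kind, model in config.site_models.items():
        eligible = [
            p for p in truth.proteins
            if truth.localizations[p.id] in _SITE_ELIGIBILITY[kind]
        ]
        if not eligible:
            warnings.warn(f"no eligible proteins for {kind.value} sites", stacklevel=2)
            continue
        id_counts = np.array(
            [int(np.sum(truth.labels[p.id] == SegmentLabel.ID.value)) for p in eligible]
        )
        tot_counts = np.array([p.length for p in eligible])
        sd_counts = tot_counts - id_counts
        f = id_counts.sum() / tot_counts.sum()
        odds = model.id_odds
        q = odds * f / (odds * f + (1.0 - f)) if 0.0 < f < 1.0 else f

        n_sites = int(rng.poisson(model.mean_per_protein * len(eligible)))
        paired = kind in (SiteKind.DISULFIDE, SiteKind.AS_BOUNDARY)
        for _ in range(n_sites):
            if kind == SiteKind.AS_BOUNDARY:
                # one protein, two ends, compartments drawn independently
                j = int(rng.choice(len(eligible), p=tot_counts / tot_counts.sum()))
                vec = truth.labels[eligible[j].id]
                positions = []
                for _end in range(2):
                    want_id = rng.random() < q
                    pool = _compartment_positions(vec, want_id)
                    if pool.size == 0:
                        pool = _compartment_positions(vec, not want_id)
                    positions.append(int(pool[rng.integers(0, pool.size)]))
                site = FeatureSite(kind=kind, positions=tuple(sorted(positions)))
                sites[eligible[j].id].append(site)
                continue

            want_id = rng.random() < q
            counts = id_counts if want_id else sd_counts
            need = 2 if paired else 1
            usable = counts >= need
            if not usable.any():
                counts = sd_counts if want_id else id_counts
                usable = counts >= need
                if not usable.any():
                    continue
            w = np.where(usable, counts, 0).astype(float)
            j = int(rng.choice(len(eligible), p=w / w.sum()))
            pool = _compartment_positions(truth.labels[eligible[j].id], bool(counts is id_counts))
            chosen = rng.choice(pool.size, size=need, replace=False)
            positions = tuple(sorted(int(pool[c]) for c in chosen))
            sites[eligible[j].id].append(FeatureSite(kind=kind, positions=positions))

    for pid, site_list in sites.items():
        truth.sites.setdefault(pid, []).extend(site_list)
        by_id[pid].sites.extend(site_list)
    return sites


def emit_pfam_hits(
    truth: GroundTruth, config: GeneratorConfig, seed: int
) -> dict[str, list[PfamHit]]:
    """Emit domain-shaped Pfam hits with class-dependent residue coverage.

    Each true segment is covered by one hit with its class's coverage
    probability (steered by the same feedback controller the architecture
    sampler uses, so realized per-class coverage concentrates on the
    configured value); identifiers are drawn from disjoint per-class pools
    (never the fibrous families, which would force KD).
    """
    rng = np.random.default_rng(seed)
    base = {SegmentLabel.KD: 50000, SegmentLabel.CD: 60000, SegmentLabel.ID: 70000}
    hits: dict[str, list[PfamHit]] = {}
    gain = config.target_feedback_gain
    tallies = {lab: [0, 0] for lab in SegmentLabel}  # [covered, total] residues
    for protein in truth.proteins:
        out = []
        for seg in truth.architectures[protein.id]:
            p_base = config.pfam_coverage.get(seg.label, 0.0)
            p = p_base
            covered, total = tallies[seg.label]
            if gain > 0 and total > 0 and 0.0 < p_base < 1.0:
                p = min(1.0, max(0.0, p_base + gain * (p_base - covered / total)))
            tallies[seg.label][1] += len(seg.interval)
            if rng.random() < p:
                tallies[seg.label][0] += len(seg.interval)
                pool = config.pfam_pool_sizes[seg.label]
                pfam_id = f"PF{base[seg.label] + int(rng.integers(0, pool)):05d}"
                out.append(PfamHit(interval=seg.interval, pfam_id=pfam_id))
        hits[protein.id] = out
    return hits
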