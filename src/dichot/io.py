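"""Readers and writers for sequences, evidence tables, annotations, segmentations.

File formats use 1-based inclusive coordinates (Swiss-Prot/GFF convention);
everything in memory is 0-based half-open. The two conversions are

    external (s, e)  ->  internal Interval(s - 1, e)
    internal [a, b)  ->  external (a + 1, b)

which compose to the identity in both directions.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
from Bio import SeqIO

from .model import (
    DisorderSource,
    DisorderState,
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
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_evidence_table",
    "write_evidence_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_segmentation",
    "write_segmentation",
    "external_to_interval",
    "interval_to_external",
]


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending record."""


def external_to_interval(start: int, end: int) -> Interval:
    """Convert 1-based inclusive (start, end) to an internal Interval."""
    if start < 1 or end < start:
        raise ParseError(f"invalid 1-based inclusive coordinates ({start}, {end})")
    return Interval(start - 1, end)


def interval_to_external(iv: Interval) -> tuple[int, int]:
    """Convert an internal Interval to 1-based inclusive (start, end)."""
    return iv.start + 1, iv.end


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Protein]:
    """Read proteins from a FASTA file.

    The header token before the first whitespace becomes the protein id;
    sequences are uppercased. An empty file yields an empty list with a
    warning; a record with an empty sequence is a parse error.
    """
    path = Path(path)
    proteins: list[Protein] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"{path}: record {record.id!r} has an empty sequence")
            proteins.append(Protein(id=record.id, sequence=seq))
    except ParseError:
        raise
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ParseError(f"{path}: malformed FASTA ({exc})") from exc
    if not proteins:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, p.length, width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Evidence table (TSV)
#
# Columns: protein_id, record_type, then type-specific fields:
#   hit        -> start, end, subject_id, subject_length, source
#   disorder_a -> state, start, end      (runs; unlisted residues unassigned)
#   disorder_b -> state, start, end      (runs; must cover every residue)
#   region     -> kind, start, end
#   pfam       -> pfam_id, start, end


def _split_row(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").split("\t")]


def read_evidence_table(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, EvidenceBundle]:
    """Read per-protein evidence bundles from the TSV dialect.

    ``lengths`` maps protein id to residue count; it is needed to
    materialize the run-encoded disorder tracks as full-length vectors and
    to validate coordinates. Every protein in ``lengths`` gets a bundle
    (possibly with empty hit lists); predictor_b runs must cover every
    residue of each protein they mention.
    """
    path = Path(path)
    bundles = {pid: EvidenceBundle() for pid in lengths}
    track_runs: dict[str, dict[DisorderSource, list[tuple[str, Interval]]]] = {
        pid: {DisorderSource.PREDICTOR_A: [], DisorderSource.PREDICTOR_B: []}
        for pid in lengths
    }

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            pid, rtype = fields[0], fields[1]
            if pid not in lengths:
                raise ParseError(f"{path}:{lineno}: unknown protein {pid!r}")
            plen = lengths[pid]

            def iv(start_s: str, end_s: str) -> Interval:
                interval = external_to_interval(int(start_s), int(end_s))
                if interval.end > plen:
                    raise ParseError(
                        f"{path}:{lineno}: protein {pid}: coordinate {end_s} exceeds "
                        f"length {plen}"
                    )
                return interval

            try:
                if rtype == "hit":
                    start, end, subject_id, subject_length, source = fields[2:7]
                    bundles[pid].hits.append(
                        HomologyHit(
                            interval=iv(start, end),
                            subject_id=subject_id,
                            subject_length=int(subject_length),
                            source=HitSource(source),
                        )
                    )
                elif rtype in ("disorder_a", "disorder_b"):
                    state, start, end = fields[2:5]
                    source_enum = (
                        DisorderSource.PREDICTOR_A
                        if rtype == "disorder_a"
                        else DisorderSource.PREDICTOR_B
                    )
                    track_runs[pid][source_enum].append(
                        (DisorderState(state).value, iv(start, end))
                    )
                elif rtype == "region":
                    kind, start, end = fields[2:5]
                    bundles[pid].regions.append(
                        RegionAnnotation(interval=iv(start, end), kind=RegionKind(kind))
                    )
                elif rtype == "pfam":
                    pfam_id, start, end = fields[2:5]
                    bundles[pid].pfam.append(PfamHit(interval=iv(start, end), pfam_id=pfam_id))
                else:
                    raise ParseError(f"{path}:{lineno}: unknown record_type {rtype!r}")
            except (ValueError, IndexError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{lineno}: protein {pid}: {exc}") from exc

    from .model import DisorderTrack  # local import to keep module tops light

    for pid, plen in lengths.items():
        # predictor_a: unlisted residues are unassigned
        calls_a = np.full(plen, DisorderState.UNASSIGNED.value, dtype="<U10")
        for state, interval in track_runs[pid][DisorderSource.PREDICTOR_A]:
            calls_a[interval.start : interval.end] = state
        bundles[pid].track_a = DisorderTrack(DisorderSource.PREDICTOR_A, calls_a)

        # predictor_b: runs must cover every residue
        calls_b = np.full(plen, "", dtype="<U10")
        for state, interval in track_runs[pid][DisorderSource.PREDICTOR_B]:
            calls_b[interval.start : interval.end] = state
        uncovered = np.flatnonzero(calls_b == "")
        if uncovered.size:
            raise ParseError(
                f"{path}: protein {pid}: predictor_b track does not cover residue "
                f"{uncovered[0] + 1} (1-based) of {plen}"
            )
        bundles[pid].track_b = DisorderTrack(DisorderSource.PREDICTOR_B, calls_b)
        bundles[pid].validate(plen, pid)
    return bundles


def _runs(values: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal constant runs of a 1-D array as (start, end, value)."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i, str(values[start])))
            start = i
    return out


def write_evidence_table(
    bundles: Mapping[str, EvidenceBundle], path: str | Path
) -> None:
    """Write evidence bundles in the TSV dialect (run-length encodes tracks)."""
    with open(path, "w") as fh:
        fh.write("# protein_id\trecord_type\tfields...\n")
        for pid in bundles:
            b = bundles[pid]
            for h in b.hits:
                s, e = interval_to_external(h.interval)
                fh.write(
                    f"{pid}\thit\t{s}\t{e}\t{h.subject_id}\t{h.subject_length}\t{h.source.value}\n"
                )
            for r in b.regions:
                s, e = interval_to_external(r.interval)
                fh.write(f"{pid}\tregion\t{r.kind.value}\t{s}\t{e}\n")
            for p in b.pfam:
                s, e = interval_to_external(p.interval)
                fh.write(f"{pid}\tpfam\t{p.pfam_id}\t{s}\t{e}\n")
            if b.track_a is not None:
                for a, z, state in _runs(b.track_a.calls):
                    if state != DisorderState.UNASSIGNED.value:
                        fh.write(f"{pid}\tdisorder_a\t{state}\t{a + 1}\t{z}\n")
            if b.track_b is not None:
                for a, z, state in _runs(b.track_b.calls):
                    fh.write(f"{pid}\tdisorder_b\t{state}\t{a + 1}\t{z}\n")


# ---------------------------------------------------------------------------
# Annotation table (TSV)
#
#   protein_id  localization  token[;token...]
#   protein_id  site          kind  pos[  pos2]


def read_annotation_table(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> tuple[dict[str, Localization], dict[str, list[FeatureSite]]]:
    """Read localization labels and feature sites.

    Multiple localization tokens collapse to ``multiple`` unless the pair is
    nucleus + cytoplasm, which maps to ``nucleus_and_cytoplasm``. Unknown
    tokens are an error. When ``lengths`` is given, site positions are
    validated against protein length.
    """
    path = Path(path)
    localizations: dict[str, Localization] = {}
    sites: dict[str, list[FeatureSite]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            pid, rtype = fields[0], fields[1]
            if rtype == "localization":
                tokens = [t.strip() for t in fields[2].split(";") if t.strip()]
                for tok in tokens:
                    if tok not in Localization._value2member_map_:
                        raise ParseError(
                            f"{path}:{lineno}: unknown localization token {tok!r}"
                        )
                if len(tokens) == 1:
                    loc = Localization(tokens[0])
                elif set(tokens) == {Localization.NUCLEUS.value, Localization.CYTOPLASM.value}:
                    loc = Localization.NUCLEUS_AND_CYTOPLASM
                else:
                    loc = Localization.MULTIPLE
                localizations[pid] = loc
            elif rtype == "site":
                kind = SiteKind(fields[2])
                positions = tuple(int(x) - 1 for x in fields[3:] if x)
                if lengths is not None and pid in lengths:
                    for pos in positions:
                        if not 0 <= pos < lengths[pid]:
                            raise ParseError(
                                f"{path}:{lineno}: protein {pid}: site position "
                                f"{pos + 1} outside length {lengths[pid]}"
                            )
                sites.setdefault(pid, []).append(FeatureSite(kind=kind, positions=positions))
            else:
                raise ParseError(f"{path}:{lineno}: unknown record_type {rtype!r}")
    return localizations, sites


def write_annotation_table(
    localizations: Mapping[str, Localization],
    sites: Mapping[str, Iterable[FeatureSite]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\trecord_type\tfields...\n")
        for pid, loc in localizations.items():
            fh.write(f"{pid}\tlocalization\t{loc.value}\n")
        for pid, site_list in sites.items():
            for s in site_list:
                pos = "\t".join(str(p + 1) for p in s.positions)
                fh.write(f"{pid}\tsite\t{s.kind.value}\t{pos}\n")


# ---------------------------------------------------------------------------
# Segmentation GFF3


def write_segmentation(
    segmentations: Iterable[Segmentation], path_or_fh: str | Path | TextIO
) -> None:
    """Write segmentations as GFF3 (type column = KD/CD/ID, 1-based inclusive)."""
    own = not hasattr(path_or_fh, "write")
    fh: TextIO = open(path_or_fh, "w") if own else path_or_fh  # type: ignore[arg-type]
    try:
        fh.write("##gff-version 3\n")
        for seg in segmentations:
            for i, s in enumerate(seg.segments):
                start, end = interval_to_external(s.interval)
                fh.write(
                    f"{seg.protein_id}\tdichot\t{s.label.value}\t{start}\t{end}"
                    f"\t.\t.\t.\tID={seg.protein_id}.seg{i}\n"
                )
    finally:
        if own:
            fh.close()


def read_segmentation(path: str | Path) -> list[Segmentation]:
    """Read segmentations written by :func:`write_segmentation`."""
    path = Path(path)
    per_protein: dict[str, list[Segment]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 GFF columns")
            pid, _source, label, start, end = fields[:5]
            if pid not in per_protein:
                per_protein[pid] = []
                order.append(pid)
            per_protein[pid].append(
                Segment(
                    interval=external_to_interval(int(start), int(end)),
                    label=SegmentLabel(label),
                )
            )
    return [
        Segmentation(protein_id=pid, segments=sorted(per_protein[pid], key=lambda s: s.interval))
        for pid in order
    ]
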