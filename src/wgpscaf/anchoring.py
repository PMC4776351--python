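"""Anchoring scaffolds on the WGP map from tag-to-scaffold alignments.

Tags are short (~50 bp) sequences aligned against the draft assembly with a
standard read mapper.  Only uniquely-placed tags are informative: a tag with
any secondary/supplementary record, alternative-hit (XA) entries, more than
one primary record, or sub-threshold mapping quality is discarded entirely.
The surviving alignments attach map tags to scaffold coordinates, producing
one position-sorted :class:`AnchoredScaffold` per scaffold with at least one
mapped tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pysam

from .errors import ParseError, ValidationError
from .wgp_map_io import WgpMap, WgpTag

__all__ = [
    "TagAlignment",
    "Anchor",
    "AnchoredScaffold",
    "load_tag_alignments",
    "reference_lengths",
    "anchor_scaffolds",
    "detect_nested_scaffolds",
    "write_anchors",
    "read_anchors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagAlignment:
    """A unique placement of one tag on one scaffold (0-based leftmost coordinate)."""

    tag_id: str
    scaffold_id: str
    position: int
    strand: str = "+"
    unique: bool = True


@dataclass(frozen=True)
class Anchor:
    """One (tag, position) couple on an anchored scaffold."""

    tag: WgpTag
    position: int


@dataclass(frozen=True)
class AnchoredScaffold:
    """A scaffold with its position-sorted, uniquely-mapped tags."""

    scaffold_id: str
    length: int
    anchors: tuple[Anchor, ...]

    def __post_init__(self):
        if not self.anchors:
            raise ValidationError(f"scaffold {self.scaffold_id!r}: no anchors")
        positions = [a.position for a in self.anchors]
        if positions != sorted(positions):
            raise ValidationError(f"scaffold {self.scaffold_id!r}: anchors not position-sorted")

    @property
    def first_anchor(self) -> Anchor:
        return self.anchors[0]

    @property
    def last_anchor(self) -> Anchor:
        return self.anchors[-1]


def reference_lengths(path) -> dict[str, int]:
    """Scaffold lengths from the @SQ lines of a SAM/BAM header."""
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        return dict(zip(af.references, af.lengths))


def load_tag_alignments(path, min_mapq: int = 1) -> list[TagAlignment]:
    """Load tag alignments, keeping only tags with exactly one location.

    A tag contributes nothing if it has any secondary or supplementary
    record, an XA alternative-hit tag, several primary records, or a primary
    record with MAPQ below ``min_mapq``.  Unmapped records are ignored.
    SAM's 1-based coordinates are converted to 0-based on ingest.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read alignments: {exc}", path=path)
    hits: dict[str, list[TagAlignment]] = {}
    multi: set[str] = set()
    with af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            name = rec.query_name
            if rec.is_secondary or rec.is_supplementary or rec.has_tag("XA"):
                multi.add(name)
                continue
            if rec.mapping_quality < min_mapq:
                multi.add(name)
                continue
            hits.setdefault(name, []).append(
                TagAlignment(
                    tag_id=name,
                    scaffold_id=rec.reference_name,
                    position=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                )
            )
    out = []
    n_multi = len(multi)
    for name in sorted(hits):
        if name in multi:
            continue
        if len(hits[name]) > 1:
            n_multi += 1
            continue
        out.append(hits[name][0])
    if n_multi:
        logger.info("dropped %d multi-located tags", n_multi)
    return out


def anchor_scaffolds(
    alignments: Iterable[TagAlignment],
    wgp_map: WgpMap,
    lengths: Mapping[str, int],
) -> list[AnchoredScaffold]:
    """Combine unique tag alignments with the map into anchored scaffolds.

    Tags absent from the map are dropped (with a logged count).  Anchors are
    sorted by position, ties broken by tag id.  Output is sorted by scaffold
    id, so the result is invariant to alignment input order.
    """
    per_scaffold: dict[str, list[Anchor]] = {}
    seen_tags: set[str] = set()
    n_unmapped = 0
    for aln in alignments:
        tag = wgp_map.get(aln.tag_id)
        if tag is None:
            n_unmapped += 1
            continue
        if aln.tag_id in seen_tags:
            raise ValidationError(f"tag {aln.tag_id!r} aligned to more than one scaffold")
        seen_tags.add(aln.tag_id)
        if aln.scaffold_id not in lengths:
            raise ValidationError(f"no length known for scaffold {aln.scaffold_id!r}")
        per_scaffold.setdefault(aln.scaffold_id, []).append(Anchor(tag, aln.position))
    if n_unmapped:
        logger.info("dropped %d aligned tags absent from the map", n_unmapped)
    return [
        AnchoredScaffold(
            scaffold_id=scaffold_id,
            length=lengths[scaffold_id],
            anchors=tuple(sorted(per_scaffold[scaffold_id], key=lambda a: (a.position, a.tag.tag_id))),
        )
        for scaffold_id in sorted(per_scaffold)
    ]


def detect_nested_scaffolds(anchored: Iterable[AnchoredScaffold]) -> set[str]:
    """Scaffolds whose anchored map interval lies strictly inside another's.

    Map ranks are the only coordinate system shared between scaffolds, so
    containment is tested on per-BAC-contig rank intervals: a scaffold whose
    anchors all sit on one BAC contig is nested when its [min rank, max rank]
    interval is strictly inside another scaffold's rank interval on the same
    contig.  Nested scaffolds are excluded from linking only, not from
    quality metrics.
    """
    anchored = list(anchored)
    # rank interval of every scaffold on every contig it touches
    intervals: dict[str, dict[str, tuple[float, float]]] = {}
    for scaf in anchored:
        per_contig: dict[str, tuple[float, float]] = {}
        for anchor in scaf.anchors:
            c, r = anchor.tag.bac_contig, anchor.tag.rank
            lo, hi = per_contig.get(c, (r, r))
            per_contig[c] = (min(lo, r), max(hi, r))
        intervals[scaf.scaffold_id] = per_contig
    nested: set[str] = set()
    for scaf in anchored:
        per_contig = intervals[scaf.scaffold_id]
        if len(per_contig) != 1:
            continue
        (contig, (lo, hi)), = per_contig.items()
        for other in anchored:
            if other.scaffold_id == scaf.scaffold_id:
                continue
            iv = intervals[other.scaffold_id].get(contig)
            if iv is not None and iv[0] < lo and hi < iv[1]:
                nested.add(scaf.scaffold_id)
                break
    return nested


def write_anchors(anchored: Iterable[AnchoredScaffold], path) -> None:
    """Write anchored scaffolds as TSV, one row per anchor."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("scaffold_id\tscaffold_length\tposition\ttag_id\tbac_contig\trank\n")
        for scaf in anchored:
            for a in scaf.anchors:
                fh.write(
                    f"{scaf.scaffold_id}\t{scaf.length}\t{a.position}\t"
                    f"{a.tag.tag_id}\t{a.tag.bac_contig}\t{a.tag.rank!r}\n"
                )


def read_anchors(path) -> list[AnchoredScaffold]:
    """Read anchored scaffolds back from the TSV written by :func:`write_anchors`."""
    rows: dict[str, tuple[int, list[Anchor]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or lineno == 1 and line.startswith("scaffold_id"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"expected 6 columns, got {len(fields)}", path=path, line=lineno)
            scaffold_id, length_s, pos_s, tag_id, contig, rank_s = fields
            try:
                length, position, rank = int(length_s), int(pos_s), float(rank_s)
            except ValueError:
                raise ParseError("non-numeric field", path=path, line=lineno)
            entry = rows.setdefault(scaffold_id, (length, []))
            entry[1].append(Anchor(WgpTag(tag_id, contig, rank), position))
    return [
        AnchoredScaffold(sid, length, tuple(sorted(anchors, key=lambda a: (a.position, a.tag.tag_id))))
        for sid, (length, anchors) in sorted(rows.items())
    ]
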