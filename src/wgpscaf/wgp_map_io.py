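"""Reading, writing and construction of Whole Genome Profiling (WGP) tag maps.

A WGP map orders short sequence tags along a genome.  Tags are grouped in
BAC contigs (groups of overlapping, fingerprinted BAC clones) and each tag
carries a *rank* inside its BAC contig.  The rank is derived from the BACs
the tag occurs in: BACs are ordered by their fingerprint coordinates and a
tag's rank is the mean rank of its BACs, so ranks may be fractional and
tied.  The map file dialect used here is a plain 3-column TSV
(``tag_id<TAB>bac_contig<TAB>rank``) with an optional header line and
``#``-prefixed comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

__all__ = [
    "WgpTag",
    "WgpMap",
    "BacRecord",
    "read_wgp_map",
    "write_wgp_map",
    "order_tags_from_fingerprints",
    "read_bac_records",
    "read_tag_occurrences",
]


@dataclass(frozen=True)
class WgpTag:
    """A mapped WGP tag: identifier, BAC contig and (possibly fractional) rank."""

    tag_id: str
    bac_contig: str
    rank: float

    def __post_init__(self):
        if self.rank < 0:
            raise ValidationError(f"tag {self.tag_id!r}: rank must be >= 0, got {self.rank}")


class WgpMap:
    """An ordered tag map: tags grouped in BAC contigs, rank-sorted per contig.

    Tag ids are unique across the whole map.  Within a contig, tags are held
    sorted by rank; the sort is stable so tied ranks preserve insertion order.
    """

    def __init__(self, tags: Iterable[WgpTag] = ()):
        self._tags: dict[str, WgpTag] = {}
        by_contig: dict[str, list[WgpTag]] = {}
        for tag in tags:
            if tag.tag_id in self._tags:
                raise ValidationError(f"duplicate tag id {tag.tag_id!r}")
            self._tags[tag.tag_id] = tag
            by_contig.setdefault(tag.bac_contig, []).append(tag)
        self._by_contig = {c: sorted(ts, key=lambda t: t.rank) for c, ts in by_contig.items()}

    @property
    def bac_contigs(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_contig))

    def contig_tags(self, bac_contig: str) -> tuple[WgpTag, ...]:
        """Tags of one BAC contig, sorted by rank (stable on ties)."""
        return tuple(self._by_contig[bac_contig])

    def contig_ranks(self, bac_contig: str) -> tuple[float, ...]:
        """Sorted distinct ranks present in one BAC contig."""
        return tuple(sorted({t.rank for t in self._by_contig[bac_contig]}))

    def __contains__(self, tag_id: str) -> bool:
        return tag_id in self._tags

    def __getitem__(self, tag_id: str) -> WgpTag:
        return self._tags[tag_id]

    def get(self, tag_id: str, default=None):
        return self._tags.get(tag_id, default)

    def __len__(self) -> int:
        return len(self._tags)

    def __iter__(self):
        """Iterate tags in deterministic map order (contig, then rank)."""
        for contig in self.bac_contigs:
            yield from self._by_contig[contig]

    def __eq__(self, other) -> bool:
        if not isinstance(other, WgpMap):
            return NotImplemented
        return self._tags == other._tags

    def __repr__(self) -> str:
        return f"WgpMap({len(self)} tags, {len(self._by_contig)} BAC contigs)"


@dataclass(frozen=True)
class BacRecord:
    """A fingerprinted BAC clone with its coordinates inside its BAC contig."""

    bac_id: str
    bac_contig: str
    left_pos: int
    right_pos: int

    def __post_init__(self):
        if self.left_pos < 0 or self.right_pos < 0:
            raise ValidationError(f"BAC {self.bac_id!r}: positions must be non-negative")
        if self.left_pos > self.right_pos:
            raise ValidationError(f"BAC {self.bac_id!r}: left_pos > right_pos")


def read_wgp_map(path) -> WgpMap:
    """Read a WGP map from a 3-column TSV file.

    Row order is irrelevant; blank lines and ``#`` comments are skipped; a
    header row (non-numeric rank column) is tolerated in first position.
    """
    tags: list[WgpTag] = []
    seen_data = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 tab-separated columns, got {len(fields)}",
                    path=path, line=lineno,
                )
            tag_id, bac_contig, rank_s = fields
            try:
                rank = float(rank_s)
            except ValueError:
                if not seen_data:
                    # header row
                    continue
                raise ParseError(f"non-numeric rank {rank_s!r}", path=path, line=lineno)
            seen_data = True
            tags.append(WgpTag(tag_id, bac_contig, rank))
    return WgpMap(tags)


def write_wgp_map(wgp_map: WgpMap, path) -> None:
    """Write a WGP map as TSV; ``read_wgp_map`` round-trips it exactly."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("tag_id\tbac_contig\trank\n")
        for tag in wgp_map:
            fh.write(f"{tag.tag_id}\t{tag.bac_contig}\t{tag.rank!r}\n")


def _dense_bac_ranks(bacs: Iterable[BacRecord]) -> dict[str, tuple[str, int]]:
    """Assign per-contig dense ranks to BACs by (left_pos, right_pos).

    BACs with identical coordinates share a rank; the next distinct
    coordinate pair gets the previous rank + 1.  Returns
    ``bac_id -> (bac_contig, rank)``.
    """
    by_contig: dict[str, list[BacRecord]] = {}
    for bac in bacs:
        by_contig.setdefault(bac.bac_contig, []).append(bac)
    out: dict[str, tuple[str, int]] = {}
    for contig in sorted(by_contig):
        rank = 0
        prev = None
        for bac in sorted(by_contig[contig], key=lambda b: (b.left_pos, b.right_pos, b.bac_id)):
            pos = (bac.left_pos, bac.right_pos)
            if pos != prev:
                rank += 1
                prev = pos
            if bac.bac_id in out:
                raise ValidationError(f"duplicate BAC id {bac.bac_id!r}")
            out[bac.bac_id] = (contig, rank)
    return out


def order_tags_from_fingerprints(
    bacs: Iterable[BacRecord],
    occurrences: Mapping[str, Iterable[str]],
    max_rank_spread: float = 5.0,
) -> tuple[WgpMap, set[str]]:
    """Build a WGP map from BAC fingerprint coordinates and tag occurrences.

    BACs are sorted on (left, right) fingerprint coordinates per BAC contig
    and given dense ranks (identical coordinates share a rank).  Each tag's
    position is the mean rank of the BACs it occurs in.  A tag whose BAC
    ranks are too far apart — spread (max − min) exceeding
    ``max_rank_spread`` — or whose BACs span more than one BAC contig is an
    outlier and is excluded from the map.

    Returns the map and the set of outlier tag ids.
    """
    bac_rank = _dense_bac_ranks(bacs)
    tags: list[WgpTag] = []
    outliers: set[str] = set()
    for tag_id in sorted(occurrences):
        bac_ids = sorted(set(occurrences[tag_id]))
        if not bac_ids:
            raise ValidationError(f"tag {tag_id!r}: empty BAC occurrence set")
        placements = []
        for bac_id in bac_ids:
            if bac_id not in bac_rank:
                raise ValidationError(f"tag {tag_id!r}: unknown BAC id {bac_id!r}")
            placements.append(bac_rank[bac_id])
        contigs = {contig for contig, _ in placements}
        if len(contigs) > 1:
            outliers.add(tag_id)
            continue
        ranks = [rank for _, rank in placements]
        if max(ranks) - min(ranks) > max_rank_spread:
            outliers.add(tag_id)
            continue
        tags.append(WgpTag(tag_id, contigs.pop(), sum(ranks) / len(ranks)))
    return WgpMap(tags), outliers


def read_bac_records(path) -> list[BacRecord]:
    """Read BAC fingerprint records from TSV: bac_id, bac_contig, left, right."""
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"expected 4 columns, got {len(fields)}", path=path, line=lineno
                )
            try:
                left, right = int(fields[2]), int(fields[3])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError("non-integer BAC coordinates", path=path, line=lineno)
            records.append(BacRecord(fields[0], fields[1], left, right))
    return records


def read_tag_occurrences(path) -> dict[str, set[str]]:
    """Read tag occurrences from TSV: tag_id, comma-separated bac_ids."""
    occurrences: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"expected 2 columns, got {len(fields)}", path=path, line=lineno
                )
            tag_id, bac_list = fields
            if tag_id in occurrences:
                raise ValidationError(f"duplicate tag id {tag_id!r} at line {lineno}")
            occurrences[tag_id] = {b for b in bac_list.split(",") if b}
    return occurrences
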