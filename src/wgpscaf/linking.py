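"""Candidate map-links between scaffolds adjacent on the WGP map.

Two anchored scaffolds s_i, s_j form a map-link when the BAC contig of
s_i's last anchor equals the BAC contig of s_j's first anchor and the
corresponding ranks satisfy r(last of s_i) <= r(first of s_j).  "Adjacent"
means consecutive in the per-BAC-contig ordering of scaffolds by
(first-anchor rank, last-anchor rank, scaffold id), so each scaffold end
takes part in at most one link per side and no transitive redundant links
are emitted.  Nested scaffolds are excluded beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable

from .anchoring import AnchoredScaffold
from .errors import ParseError, ValidationError

__all__ = ["MapLink", "build_map_links", "write_map_links", "read_map_links"]


@dataclass(frozen=True)
class MapLink:
    """A candidate junction between two map-adjacent scaffolds."""

    left_scaffold: str
    right_scaffold: str
    bac_contig: str
    left_rank: float
    right_rank: float

    def __post_init__(self):
        if self.left_scaffold == self.right_scaffold:
            raise ValidationError("a map-link must join two distinct scaffolds")
        if self.left_rank > self.right_rank:
            raise ValidationError("map-link ranks out of order")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.left_scaffold, self.right_scaffold))


def _terminal(scaf: AnchoredScaffold):
    first, last = scaf.first_anchor, scaf.last_anchor
    return (first.tag.bac_contig, first.tag.rank, last.tag.bac_contig, last.tag.rank)


def build_map_links(
    anchored: Iterable[AnchoredScaffold],
    nested: AbstractSet[str] = frozenset(),
) -> list[MapLink]:
    """Emit one map-link per consecutive, rank-compatible scaffold pair.

    Scaffolds listed in ``nested`` are skipped.  A scaffold whose terminal
    anchors sit on two BAC contigs is placed by both terminals: its first
    anchor serves the right side of a link on one contig, its last anchor
    the left side on the other.
    """
    scaffolds = [s for s in anchored if s.scaffold_id not in nested]
    by_contig: dict[str, list[AnchoredScaffold]] = {}
    for scaf in scaffolds:
        fc, _, lc, _ = _terminal(scaf)
        for contig in {fc, lc}:
            by_contig.setdefault(contig, []).append(scaf)

    def order_key(scaf: AnchoredScaffold, contig: str):
        fc, fr, lc, lr = _terminal(scaf)
        primary = fr if fc == contig else lr
        secondary = lr if lc == contig else fr
        return (primary, secondary, scaf.scaffold_id)

    links: list[MapLink] = []
    for contig in sorted(by_contig):
        group = sorted(by_contig[contig], key=lambda s: order_key(s, contig))
        for left, right in zip(group, group[1:]):
            _, _, lc, lr = _terminal(left)
            fc, fr, _, _ = _terminal(right)
            if lc == contig == fc and lr <= fr:
                links.append(MapLink(left.scaffold_id, right.scaffold_id, contig, lr, fr))
    return links


def write_map_links(links: Iterable[MapLink], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("left_scaffold\tright_scaffold\tbac_contig\tleft_rank\tright_rank\n")
        for link in links:
            fh.write(
                f"{link.left_scaffold}\t{link.right_scaffold}\t{link.bac_contig}\t"
                f"{link.left_rank!r}\t{link.right_rank!r}\n"
            )


def read_map_links(path) -> list[MapLink]:
    links = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("left_scaffold"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"expected 5 columns, got {len(fields)}", path=path, line=lineno)
            try:
                links.append(
                    MapLink(fields[0], fields[1], fields[2], float(fields[3]), float(fields[4]))
                )
            except ValueError:
                raise ParseError("non-numeric rank", path=path, line=lineno)
    return links
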