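"""Mate-pair validation of map-links, orientation voting and gap estimation.

Mate-pair (MP) reads aligned to the assembly provide evidence that two
map-adjacent scaffolds really are neighbors.  For each read pair whose
mates map to *different* scaffolds, a naïve gap estimate is computed from
the library's mean fragment size μ, the read length R and the two read
placements; the four orientation cases are

    gap(+,+) = μ − pos1 − pos2 − 2R
    gap(+,−) = μ − (pos1 + R) − (len2 − pos2)
    gap(−,−) = μ − (len1 − pos1) − (len2 − pos2)
    gap(−,+) = μ − (len1 − pos1) − (pos2 + R)

where pos is the 0-based leftmost coordinate of each read and len the
scaffold length.  The estimate is bounded above by μ and may underestimate
the true gap, but it works with a single supporting pair, which is what
allows map-links in low-coverage regions to be validated at all.

When several orientation classes are reported for one link, the class
supported by the most pairs wins (ties are rejected as ambiguous).  The
link is validated when the mean gap of the winning class is at least
``min_gap`` (−200 bp by default).

Read orientation maps onto scaffold orientation for a left→right join as:
orient1 '−' ⇔ left scaffold forward, orient2 '+' ⇔ right scaffold forward
(the fragment must run off the junction-facing ends of both scaffolds).
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pysam

from .errors import ParseError, ValidationError
from .linking import MapLink

__all__ = [
    "LibraryModel",
    "ReadPairMapping",
    "ValidatedLink",
    "ValidationResult",
    "load_pair_mappings",
    "estimate_gap",
    "validate_links",
    "write_de_file",
    "read_de_file",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_GAP = -200  # bp; minimum allowed mean gap estimate


@dataclass(frozen=True)
class LibraryModel:
    """Mate-pair library: mean fragment size μ, its sd, and read length R (bp)."""

    mu: float
    sigma: float
    read_length: int

    def __post_init__(self):
        if self.mu <= 0:
            raise ValidationError("mu must be > 0")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.read_length <= 0:
            raise ValidationError("read_length must be > 0")


@dataclass(frozen=True)
class ReadPairMapping:
    """One mapping possibility of a read pair with mates on two scaffolds."""

    scaf1: str
    scaf2: str
    orient1: str
    orient2: str
    pos1: int
    pos2: int
    read_length: int
    pair_id: str = ""

    def __post_init__(self):
        if self.scaf1 == self.scaf2:
            raise ValidationError("mates must map to different scaffolds")
        for orient in (self.orient1, self.orient2):
            if orient not in ("+", "-"):
                raise ValidationError(f"unknown orientation {orient!r}")


def _flip(strand: str) -> str:
    return "+" if strand == "-" else "-"


@dataclass(frozen=True)
class ValidatedLink:
    """A map-link confirmed by mate-pairs, with orientation and gap estimate.

    ``orient1``/``orient2`` are the winning read-orientation class;
    ``left_strand``/``right_strand`` translate it into scaffold orientations
    for a left→right join.
    """

    left_scaffold: str
    right_scaffold: str
    orient1: str
    orient2: str
    gap: int
    support: int
    gap_sd: float
    map_link: MapLink | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.support < 1:
            raise ValidationError("support must be >= 1")

    @property
    def left_strand(self) -> str:
        return "+" if self.orient1 == "-" else "-"

    @property
    def right_strand(self) -> str:
        return "+" if self.orient2 == "+" else "-"


_XA_RE = re.compile(r"([^,;]+),([+-])(\d+),([^,;]+),(\d+)")


def _record_hits(rec) -> list[tuple[str, int, str]]:
    """(scaffold, 0-based pos, strand) placements reported by one record,
    including XA alternative hits."""
    hits = [(rec.reference_name, rec.reference_start, "-" if rec.is_reverse else "+")]
    if rec.has_tag("XA"):
        for m in _XA_RE.finditer(rec.get_tag("XA")):
            hits.append((m.group(1), int(m.group(3)) - 1, m.group(2)))
    return hits


def load_pair_mappings(path) -> list[ReadPairMapping]:
    """Every cross-scaffold mapping possibility of each MP read pair.

    Primary and secondary records plus XA alternative hits are all recorded;
    possibilities where the two mates land on the same scaffold, and pairs
    with an unmapped or absent mate, contribute nothing.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot read alignments: {exc}", path=path)
    mates: dict[str, dict[int, list[tuple[str, int, str]]]] = {}
    read_lengths: dict[str, int] = {}
    n_unpaired = 0
    with af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if not rec.is_paired:
                n_unpaired += 1
                continue
            which = 2 if rec.is_read2 else 1
            name = rec.query_name
            mates.setdefault(name, {}).setdefault(which, []).extend(_record_hits(rec))
            if not rec.is_secondary:
                length = rec.infer_query_length() or rec.query_length
                if length:
                    read_lengths[name] = max(read_lengths.get(name, 0), length)
    out: list[ReadPairMapping] = []
    n_half = 0
    for name in sorted(mates):
        sides = mates[name]
        if 1 not in sides or 2 not in sides:
            n_half += 1
            continue
        rlen = read_lengths.get(name, 0)
        for scaf1, pos1, orient1 in sides[1]:
            for scaf2, pos2, orient2 in sides[2]:
                if scaf1 == scaf2:
                    continue
                out.append(
                    ReadPairMapping(scaf1, scaf2, orient1, orient2, pos1, pos2, rlen, pair_id=name)
                )
    if n_unpaired or n_half:
        logger.info("skipped %d unpaired records, %d half-mapped pairs", n_unpaired, n_half)
    return out


def estimate_gap(mapping: ReadPairMapping, lib: LibraryModel, len1: int, len2: int) -> float:
    """Naïve gap estimate between scaf1 and scaf2 for one mapping possibility.

    Applies the orientation-specific formula (see module docstring); the
    result never exceeds μ.
    """
    mu, R = lib.mu, lib.read_length
    key = mapping.orient1 + mapping.orient2
    if key == "++":
        return mu - mapping.pos1 - mapping.pos2 - 2 * R
    if key == "+-":
        return mu - (mapping.pos1 + R) - (len2 - mapping.pos2)
    if key == "--":
        return mu - (len1 - mapping.pos1) - (len2 - mapping.pos2)
    if key == "-+":
        return mu - (len1 - mapping.pos1) - (mapping.pos2 + R)
    raise ValidationError(f"unknown orientation pair {key!r}")


@dataclass
class ValidationResult:
    """Validated links plus bookkeeping counts; iterates over the links."""

    links: list[ValidatedLink]
    n_map_links: int = 0
    n_validated: int = 0
    n_no_support: int = 0
    n_below_min_gap: int = 0
    n_ambiguous: int = 0
    support_histogram: dict[int, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.links)

    def __len__(self):
        return len(self.links)

    def write_report(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"map_links\t{self.n_map_links}\n")
            fh.write(f"validated\t{self.n_validated}\n")
            fh.write(f"no_support\t{self.n_no_support}\n")
            fh.write(f"below_min_gap\t{self.n_below_min_gap}\n")
            fh.write(f"ambiguous_orientation\t{self.n_ambiguous}\n")
            for support in sorted(self.support_histogram):
                fh.write(f"support_{support}\t{self.support_histogram[support]}\n")


def validate_links(
    map_links: Iterable[MapLink],
    mappings: Iterable[ReadPairMapping],
    lib: LibraryModel,
    lengths: Mapping[str, int],
    min_gap: float = DEFAULT_MIN_GAP,
) -> ValidationResult:
    """Validate map-links with MP evidence and estimate their gaps.

    Only mapping possibilities whose scaffold pair matches a map-link are
    considered.  Per link, each read pair contributes at most one
    possibility (the first in deterministic order), possibilities are
    bucketed by orientation class, the best-supported class wins (a tie
    rejects the link as ambiguous), and the link is emitted when the mean
    class gap is at least ``min_gap``.  A single supporting pair suffices;
    its gap sd falls back to the library sigma.
    """
    by_pair: dict[frozenset, list[ReadPairMapping]] = {}
    for m in mappings:
        by_pair.setdefault(frozenset((m.scaf1, m.scaf2)), []).append(m)

    result = ValidationResult(links=[])
    map_links = list(map_links)
    result.n_map_links = len(map_links)
    for link in map_links:
        candidates = by_pair.get(link.pair, [])
        if not candidates:
            result.n_no_support += 1
            continue
        len_left = lengths[link.left_scaffold]
        len_right = lengths[link.right_scaffold]
        # normalize every possibility to the link's left→right frame
        per_pair: dict[str, list[tuple[str, str, float]]] = {}
        for m in candidates:
            if m.scaf1 == link.left_scaffold:
                cls = (m.orient1, m.orient2)
                gap = estimate_gap(m, lib, len_left, len_right)
            else:
                cls = (m.orient2, m.orient1)
                gap = estimate_gap(
                    ReadPairMapping(
                        m.scaf2, m.scaf1, m.orient2, m.orient1, m.pos2, m.pos1,
                        m.read_length, m.pair_id,
                    ),
                    lib, len_left, len_right,
                )
            per_pair.setdefault(m.pair_id, []).append((cls[0], cls[1], gap))
        buckets: dict[tuple[str, str], list[float]] = {}
        for pair_id in sorted(per_pair):
            o1, o2, gap = sorted(per_pair[pair_id])[0]  # one vote per read pair
            buckets.setdefault((o1, o2), []).append(gap)
        best = max(len(v) for v in buckets.values())
        winners = sorted(cls for cls, v in buckets.items() if len(v) == best)
        if len(winners) > 1:
            result.n_ambiguous += 1
            logger.info(
                "link %s-%s rejected: ambiguous orientation",
                link.left_scaffold, link.right_scaffold,
            )
            continue
        (o1, o2), gaps = winners[0], buckets[winners[0]]
        mean_gap = sum(gaps) / len(gaps)
        if mean_gap < min_gap:
            result.n_below_min_gap += 1
            continue
        n = len(gaps)
        gap_sd = statistics.stdev(gaps) if n > 1 else lib.sigma
        result.links.append(
            ValidatedLink(
                left_scaffold=link.left_scaffold,
                right_scaffold=link.right_scaffold,
                orient1=o1,
                orient2=o2,
                gap=round(mean_gap),
                support=n,
                gap_sd=gap_sd,
                map_link=link,
            )
        )
        result.support_histogram[n] = result.support_histogram.get(n, 0) + 1
    result.n_validated = len(result.links)
    return result


def write_de_file(links: Iterable[ValidatedLink], path) -> None:
    """Write validated links in a DistanceEst-style .de dialect.

    One record per left scaffold (sorted), listing each linked right
    scaffold as ``id±,gap,support,sd`` after the oriented left scaffold id.
    This is the link information the SGA scaffolder consumes: names and
    orientations, gap size, supporting pair count and gap sd.
    """
    by_left: dict[str, list[ValidatedLink]] = {}
    strands: dict[str, str] = {}
    for link in links:
        by_left.setdefault(link.left_scaffold, []).append(link)
        strands[link.left_scaffold] = link.left_strand
    with open(path, "wt", encoding="utf-8") as fh:
        for left in sorted(by_left):
            groups = " ".join(
                f"{l.right_scaffold}{l.right_strand},{l.gap},{l.support},{l.gap_sd:.2f}"
                for l in sorted(by_left[left], key=lambda l: l.right_scaffold)
            )
            fh.write(f"{left}{strands[left]}\t{groups}\n")


def read_de_file(path) -> list[ValidatedLink]:
    """Parse a .de file written by :func:`write_de_file`."""
    links: list[ValidatedLink] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                left_field, groups = line.split("\t", 1)
                left, left_strand = left_field[:-1], left_field[-1]
                for group in groups.split(" "):
                    target, gap_s, support_s, sd_s = group.split(",")
                    right, right_strand = target[:-1], target[-1]
                    links.append(
                        ValidatedLink(
                            left_scaffold=left,
                            right_scaffold=right,
                            orient1=_flip(left_strand),
                            orient2=right_strand,
                            gap=int(gap_s),
                            support=int(support_s),
                            gap_sd=float(sd_s),
                        )
                    )
            except (ValueError, IndexError):
                raise ParseError("malformed .de record", path=path, line=lineno)
    return links
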