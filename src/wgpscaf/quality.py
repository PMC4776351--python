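"""Reference-free quality metrics: collinear segments and the Anx family.

A *collinear segment* is a maximal run of a scaffold's anchors whose tags
appear in the same order on the genome map and on the scaffold: consecutive
anchors share a BAC contig and their ranks follow one monotone direction
(either non-decreasing or non-increasing — a scaffold may be anchored in
reverse).  Rank ties never break a run.

Segment lengths feed N50-style statistics with three denominators:

* Anx  — x% of the *anchored* assembly is in collinear segments ≥ Anx bp;
* AnAx — x% of the *total* assembly;
* AnGx — x% of the *estimated genome size*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .anchoring import AnchoredScaffold
from .errors import ValidationError

__all__ = [
    "CollinearSegment",
    "AnxResult",
    "QualityReport",
    "find_collinear_segments",
    "nx_statistic",
    "n50",
    "compute_anx",
    "anx_curve",
    "build_quality_report",
]

#: Default WGP tag length in bp; tags are typically 50-nucleotide sequences
#: flanking the restriction sites used in map construction.
DEFAULT_TAG_SPAN = 50


@dataclass(frozen=True)
class CollinearSegment:
    """A maximal map-collinear run of anchors on one scaffold."""

    scaffold_id: str
    first_anchor_index: int
    last_anchor_index: int
    length: int

    def __post_init__(self):
        if self.first_anchor_index > self.last_anchor_index:
            raise ValidationError("segment indices out of order")
        if self.length < 1:
            raise ValidationError("segment length must be >= 1")


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def find_collinear_segments(
    scaffold: AnchoredScaffold, tag_span: int = DEFAULT_TAG_SPAN
) -> list[CollinearSegment]:
    """Partition a scaffold's anchors into maximal map-collinear runs.

    A run breaks when the BAC contig changes or a strict rank change
    contradicts the run's direction; the direction is fixed by the first
    strict change and ties are compatible with both directions.  Segment
    length spans from the first anchor's position to the last anchor's
    position plus ``tag_span`` (so a single-anchor scaffold contributes one
    segment of ``tag_span`` bp).
    """
    anchors = scaffold.anchors
    segments: list[CollinearSegment] = []

    def emit(start: int, stop: int) -> None:
        length = anchors[stop].position - anchors[start].position + tag_span
        segments.append(CollinearSegment(scaffold.scaffold_id, start, stop, length))

    start = 0
    direction = 0
    for i in range(1, len(anchors)):
        prev, cur = anchors[i - 1], anchors[i]
        broke = False
        if cur.tag.bac_contig != prev.tag.bac_contig:
            broke = True
        else:
            dr = _sign(cur.tag.rank - prev.tag.rank)
            if dr != 0:
                if direction == 0:
                    direction = dr
                elif dr != direction:
                    broke = True
        if broke:
            emit(start, i - 1)
            start = i
            direction = 0
    emit(start, len(anchors) - 1)
    return segments


def nx_statistic(lengths: Iterable[int], denominator: float, x: int) -> tuple[int, bool]:
    """N50-style statistic: smallest length L such that segments ≥ L sum to
    at least x% of ``denominator``.

    Lengths are sorted descending and accumulated until the running sum
    reaches ``x/100 * denominator``; the length crossing the threshold is
    returned with ``reached=True``.  If the total never reaches the
    threshold, returns ``(0, False)``.
    """
    if not 1 <= x <= 100:
        raise ValidationError(f"x must be in 1..100, got {x}")
    if denominator <= 0:
        raise ValidationError(f"denominator must be > 0, got {denominator}")
    threshold = denominator * x / 100.0
    total = 0
    for length in sorted(lengths, reverse=True):
        total += length
        if total >= threshold:
            return length, True
    return 0, False


def n50(lengths: Iterable[int]) -> int:
    """Plain N50 of a length multiset (denominator = total length)."""
    lengths = list(lengths)
    if not lengths:
        return 0
    value, _ = nx_statistic(lengths, sum(lengths), 50)
    return value


@dataclass(frozen=True)
class AnxResult:
    """Anx/AnAx/AnGx values (bp) at one x; 0 with ``reached=False`` when the
    segment total falls short of the denominator threshold."""

    anx: int
    anax: int
    angx: int | None
    anx_reached: bool
    anax_reached: bool
    angx_reached: bool


def compute_anx(
    segment_lengths: Sequence[int],
    anchored_size: int,
    assembly_size: int,
    genome_size: int | None,
    x: int,
) -> AnxResult:
    """Anx, AnAx and AnGx at a single percentage x (1..100).

    ``genome_size`` is a user-supplied estimate; pass ``None`` to skip AnGx.
    """
    if not segment_lengths:
        raise ValidationError("no collinear segments")
    anx, anx_ok = nx_statistic(segment_lengths, anchored_size, x)
    anax, anax_ok = nx_statistic(segment_lengths, assembly_size, x)
    if genome_size is None:
        angx, angx_ok = None, False
    else:
        angx, angx_ok = nx_statistic(segment_lengths, genome_size, x)
    return AnxResult(anx, anax, angx, anx_ok, anax_ok, angx_ok)


def anx_curve(
    segment_lengths: Sequence[int],
    anchored_size: int,
    assembly_size: int,
    genome_size: int | None = None,
) -> pd.DataFrame:
    """Anx/AnAx(/AnGx) table for integer x from 1 to 100.

    Each column is non-increasing in x.  The AnGx column is present only
    when a genome size estimate is supplied.
    """
    rows = []
    for x in range(1, 101):
        res = compute_anx(segment_lengths, anchored_size, assembly_size, genome_size, x)
        row = {"x": x, "anx": res.anx, "anax": res.anax}
        if genome_size is not None:
            row["angx"] = res.angx
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class QualityReport:
    """Collinear-segment lengths plus the Anx-family summary for one assembly."""

    segment_lengths: list[int]
    anchored_size: int
    assembly_size: int
    genome_size: int | None = None
    segments: list[CollinearSegment] = field(default_factory=list)

    def anx(self, x: int) -> AnxResult:
        return compute_anx(
            self.segment_lengths, self.anchored_size, self.assembly_size, self.genome_size, x
        )

    def curve(self) -> pd.DataFrame:
        return anx_curve(
            self.segment_lengths, self.anchored_size, self.assembly_size, self.genome_size
        )

    def summary(self) -> dict:
        a50, a75 = self.anx(50), self.anx(75)
        out = {
            "an50": a50.anx,
            "an75": a75.anx,
            "ana50": a50.anax,
            "ana75": a75.anax,
            "ang50": a50.angx,
            "ang75": a75.angx,
            "n_segments": len(self.segment_lengths),
            "anchored_size": self.anchored_size,
            "assembly_size": self.assembly_size,
            "anchored_fraction": self.anchored_size / self.assembly_size if self.assembly_size else 0.0,
        }
        return out

    def write_summary(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("metric\tvalue\n")
            for key, value in self.summary().items():
                if isinstance(value, float):
                    value = f"{value:.4f}"
                fh.write(f"{key}\t{'' if value is None else value}\n")

    def write_curve(self, path) -> None:
        self.curve().to_csv(path, sep="\t", index=False)

    def plot_curve(self, path) -> None:
        """Plot the Anx/AnAx(/AnGx) curves to an image file (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        curve = self.curve()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["x"], curve["anx"], label="Anx")
        ax.plot(curve["x"], curve["anax"], label="AnAx")
        if "angx" in curve:
            ax.plot(curve["x"], curve["angx"], label="AnGx")
        ax.set_xlabel("x (%)")
        ax.set_ylabel("collinear segment length (bp)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def build_quality_report(
    anchored: Iterable[AnchoredScaffold],
    lengths: Mapping[str, int],
    genome_size: int | None = None,
    tag_span: int = DEFAULT_TAG_SPAN,
) -> QualityReport:
    """Quality report over all anchored scaffolds of an assembly.

    ``lengths`` covers the *whole* assembly (anchored or not); the anchored
    size is the summed length of scaffolds carrying at least one anchor.
    """
    anchored = list(anchored)
    segments: list[CollinearSegment] = []
    for scaf in anchored:
        segments.extend(find_collinear_segments(scaf, tag_span=tag_span))
    return QualityReport(
        segment_lengths=[s.length for s in segments],
        anchored_size=sum(s.length for s in anchored),
        assembly_size=sum(lengths.values()),
        genome_size=genome_size,
        segments=segments,
    )
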