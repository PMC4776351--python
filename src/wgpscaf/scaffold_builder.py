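"""Merging scaffolds along validated links into super-scaffolds.

Validated links form a graph on scaffold ends.  Conflicts (a scaffold end
with several incident links) are resolved by keeping the best-supported
link (ties drop all links at that end), cycles are broken at their
lowest-support link, and the remaining simple paths become
:class:`ScaffoldChain` objects.  Chains are realized as FASTA records —
members reverse-complemented as needed, joined by N-runs of
``max(gap, min_n_run)`` — and described by AGP v2.1 component/gap lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .pair_validation import ValidatedLink

__all__ = [
    "ScaffoldChain",
    "chain_links",
    "complete_chains",
    "build_fasta",
    "write_agp",
    "read_fasta_sequences",
]

logger = logging.getLogger(__name__)

#: N-run length substituted for non-positive gap estimates: the common
#: convention marking a captured gap of unknown size.
DEFAULT_MIN_N_RUN = 20


@dataclass(frozen=True)
class ScaffoldChain:
    """An ordered, oriented run of scaffolds with estimated gaps between them."""

    members: tuple[tuple[str, str], ...]  # (scaffold_id, orientation)
    gaps: tuple[int, ...]
    name: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValidationError("a chain needs at least one member")
        if len(self.gaps) != len(self.members) - 1:
            raise ValidationError("gap count must be member count - 1")

    @property
    def scaffold_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.members)


def _flip(strand: str) -> str:
    return "+" if strand == "-" else "-"


def _link_ends(link: ValidatedLink) -> tuple[tuple[str, str], tuple[str, str]]:
    """The (scaffold, end) slots a link occupies: the junction-facing end of
    each member given its orientation in the join."""
    left_end = (link.left_scaffold, "R" if link.left_strand == "+" else "L")
    right_end = (link.right_scaffold, "L" if link.right_strand == "+" else "R")
    return left_end, right_end


def _resolve_conflicts(links: Sequence[ValidatedLink]) -> list[int]:
    """Indices of links kept after per-end best-support selection."""
    ends: dict[tuple[str, str], list[int]] = {}
    for i, link in enumerate(links):
        for end in _link_ends(link):
            ends.setdefault(end, []).append(i)
    kept = set(range(len(links)))
    for end in sorted(ends):
        live = [i for i in ends[end] if i in kept]
        if len(live) <= 1:
            continue
        best = max(links[i].support for i in live)
        winners = [i for i in live if links[i].support == best]
        if len(winners) == 1:
            kept -= set(live) - {winners[0]}
            logger.info("end %s: kept best-supported link of %d", end, len(live))
        else:
            kept -= set(live)
            logger.info("end %s: support tie, all %d links dropped", end, len(live))
    return sorted(kept)


def _break_cycles(links: Sequence[ValidatedLink], kept: list[int]) -> list[int]:
    """Drop the lowest-support link of every cycle (deterministic tie-break)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    keep = []
    cycle_candidates: dict[str, list[int]] = {}
    # union in a deterministic order that prefers dropping low support:
    # process links best-first so the cycle-closing (dropped) link is the worst
    order = sorted(
        kept,
        key=lambda i: (-links[i].support, links[i].left_scaffold, links[i].right_scaffold),
    )
    dropped = []
    for i in order:
        a, b = find(links[i].left_scaffold), find(links[i].right_scaffold)
        if a == b:
            dropped.append(i)
            logger.info(
                "cycle broken at link %s-%s (support %d)",
                links[i].left_scaffold, links[i].right_scaffold, links[i].support,
            )
            continue
        parent[a] = b
        keep.append(i)
    return sorted(keep)


def chain_links(links: Iterable[ValidatedLink]) -> list[ScaffoldChain]:
    """Extract simple oriented paths from validated links.

    Every scaffold named in the input appears in exactly one output chain
    (as a singleton if all its links were dropped).  Chains are
    canonicalized so the first member id is the smaller terminal, and
    sorted by first member.
    """
    links = list(links)
    kept = _break_cycles(links, _resolve_conflicts(links))

    node_links: dict[str, list[int]] = {}
    all_nodes = set()
    for i, link in enumerate(links):
        all_nodes.update((link.left_scaffold, link.right_scaffold))
    for i in kept:
        node_links.setdefault(links[i].left_scaffold, []).append(i)
        node_links.setdefault(links[i].right_scaffold, []).append(i)

    chains: list[ScaffoldChain] = []
    visited: set[str] = set()
    terminals = sorted(n for n in all_nodes if len(node_links.get(n, [])) <= 1)
    for start in terminals:
        if start in visited:
            continue
        incident = node_links.get(start, [])
        if not incident:
            visited.add(start)
            chains.append(ScaffoldChain(((start, "+"),), ()))
            continue
        members: list[tuple[str, str]] = []
        gaps: list[int] = []
        node, used = start, None
        orient = None
        while True:
            nxt = None
            for i in node_links.get(node, []):
                if i != used:
                    nxt = i
                    break
            if orient is None:
                # orientation of the path's first member from its only link
                link = links[nxt]
                orient = link.left_strand if node == link.left_scaffold else _flip(link.right_strand)
            members.append((node, orient))
            visited.add(node)
            if nxt is None:
                break
            link = links[nxt]
            gaps.append(link.gap)
            if node == link.left_scaffold:
                flipped = orient != link.left_strand
                node, orient = link.right_scaffold, (
                    _flip(link.right_strand) if flipped else link.right_strand
                )
            else:
                flipped = orient != _flip(link.right_strand)
                node, orient = link.left_scaffold, (
                    link.left_strand if flipped else _flip(link.left_strand)
                )
            used = nxt
        if members[-1][0] < members[0][0]:
            members = [(m, _flip(o)) for m, o in reversed(members)]
            gaps = list(reversed(gaps))
        chains.append(ScaffoldChain(tuple(members), tuple(gaps)))
    return sorted(chains, key=lambda c: c.members[0][0])


def complete_chains(
    chains: Iterable[ScaffoldChain], all_scaffolds: Iterable[str]
) -> list[ScaffoldChain]:
    """Add singleton chains for scaffolds not covered by any chain, and
    assign deterministic names (multi-member chains become super-scaffolds,
    singletons keep their scaffold id)."""
    chains = list(chains)
    covered = {m for c in chains for m in c.scaffold_ids}
    for scaffold_id in sorted(set(all_scaffolds) - covered):
        chains.append(ScaffoldChain(((scaffold_id, "+"),), ()))
    chains.sort(key=lambda c: c.members[0][0])
    named = []
    counter = 0
    for chain in chains:
        if len(chain.members) > 1:
            counter += 1
            name = f"superscaffold_{counter:04d}"
        else:
            name = chain.members[0][0]
        named.append(ScaffoldChain(chain.members, chain.gaps, name))
    return named


def gap_run_length(gap: int, min_n_run: int = DEFAULT_MIN_N_RUN) -> int:
    """Realized N-run length for one estimated gap."""
    return max(gap, min_n_run)


def read_fasta_sequences(path) -> dict[str, str]:
    """Load an assembly FASTA as ``id -> uppercase sequence``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def build_fasta(
    chains: Iterable[ScaffoldChain],
    sequences: Mapping[str, str],
    min_n_run: int = DEFAULT_MIN_N_RUN,
) -> list[SeqRecord]:
    """Realize chains as sequence records.

    Members with orientation '−' are reverse-complemented; consecutive
    members are joined by ``max(gap, min_n_run)`` Ns.  Non-N bases are
    conserved exactly.  Chains should carry names (see
    :func:`complete_chains`).
    """
    records = []
    for chain in chains:
        parts: list[str] = []
        for idx, (member, orient) in enumerate(chain.members):
            if member not in sequences:
                raise ValidationError(f"sequence missing for scaffold {member!r}")
            seq = sequences[member]
            if orient == "-":
                seq = str(Seq(seq).reverse_complement())
            if idx > 0:
                parts.append("N" * gap_run_length(chain.gaps[idx - 1], min_n_run))
            parts.append(seq)
        description = "members=" + ",".join(f"{m}{o}" for m, o in chain.members)
        records.append(
            SeqRecord(Seq("".join(parts)), id=chain.name or chain.members[0][0],
                      description=description)
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records wrapped at 60 columns."""
    SeqIO.write(records, str(path), "fasta")


def write_agp(
    chains: Iterable[ScaffoldChain],
    lengths: Mapping[str, int],
    path,
    min_n_run: int = DEFAULT_MIN_N_RUN,
) -> None:
    """Describe chains as AGP v2.1: W lines for members, N lines for joins.

    Gap lines use gap type ``scaffold``, linkage ``yes`` and evidence
    ``paired-ends;map``; coordinates are 1-based inclusive.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##agp-version\t2.1\n")
        for chain in chains:
            obj = chain.name or chain.members[0][0]
            pos = 0
            part = 0
            for idx, (member, orient) in enumerate(chain.members):
                if member not in lengths:
                    raise ValidationError(f"length missing for scaffold {member!r}")
                if idx > 0:
                    run = gap_run_length(chain.gaps[idx - 1], min_n_run)
                    part += 1
                    fh.write(
                        f"{obj}\t{pos + 1}\t{pos + run}\t{part}\tN\t{run}\t"
                        f"scaffold\tyes\tpaired-ends;map\n"
                    )
                    pos += run
                length = lengths[member]
                part += 1
                fh.write(
                    f"{obj}\t{pos + 1}\t{pos + length}\t{part}\tW\t{member}\t1\t{length}\t{orient}\n"
                )
                pos += length
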