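"""End-to-end composition of the five pipeline stages on in-memory objects."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .anchoring import (
    AnchoredScaffold,
    TagAlignment,
    anchor_scaffolds,
    detect_nested_scaffolds,
)
from .linking import MapLink, build_map_links
from .pair_validation import (
    LibraryModel,
    ReadPairMapping,
    ValidationResult,
    validate_links,
    DEFAULT_MIN_GAP,
)
from .quality import DEFAULT_TAG_SPAN, QualityReport, build_quality_report, n50
from .scaffold_builder import (
    DEFAULT_MIN_N_RUN,
    ScaffoldChain,
    chain_links,
    complete_chains,
    gap_run_length,
)
from .wgp_map_io import WgpMap

__all__ = ["PipelineResult", "run_pipeline", "chain_length"]


def chain_length(chain: ScaffoldChain, lengths: Mapping[str, int],
                 min_n_run: int = DEFAULT_MIN_N_RUN) -> int:
    """Total super-scaffold length: member lengths plus realized N-runs."""
    total = sum(lengths[m] for m in chain.scaffold_ids)
    total += sum(gap_run_length(g, min_n_run) for g in chain.gaps)
    return total


@dataclass
class PipelineResult:
    anchored: list[AnchoredScaffold]
    nested: set[str]
    quality: QualityReport
    map_links: list[MapLink]
    validation: ValidationResult
    chains: list[ScaffoldChain]
    output_n50: int
    input_n50: int

    @property
    def joined_pairs(self) -> set[frozenset]:
        """Unordered scaffold pairs placed adjacent in some chain."""
        pairs = set()
        for chain in self.chains:
            ids = chain.scaffold_ids
            for a, b in zip(ids, ids[1:]):
                pairs.add(frozenset((a, b)))
        return pairs


def run_pipeline(
    wgp_map: WgpMap,
    tag_alignments: Iterable[TagAlignment],
    pair_mappings: Iterable[ReadPairMapping],
    lengths: Mapping[str, int],
    lib: LibraryModel,
    min_gap: float = DEFAULT_MIN_GAP,
    tag_span: int = DEFAULT_TAG_SPAN,
    genome_size: int | None = None,
    min_n_run: int = DEFAULT_MIN_N_RUN,
) -> PipelineResult:
    """Anchor, evaluate, link, validate and chain in one call."""
    anchored = anchor_scaffolds(tag_alignments, wgp_map, lengths)
    nested = detect_nested_scaffolds(anchored)
    quality = build_quality_report(anchored, lengths, genome_size, tag_span)
    map_links = build_map_links(anchored, nested)
    validation = validate_links(map_links, pair_mappings, lib, lengths, min_gap)
    chains = complete_chains(chain_links(validation.links), lengths.keys())
    out_lengths = [chain_length(c, lengths, min_n_run) for c in chains]
    return PipelineResult(
        anchored=anchored,
        nested=nested,
        quality=quality,
        map_links=map_links,
        validation=validation,
        chains=chains,
        output_n50=n50(out_lengths),
        input_n50=n50(lengths.values()),
    )
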