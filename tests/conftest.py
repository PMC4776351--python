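"""Shared fixtures: anchored-scaffold builders and a small simulated dataset."""

from __future__ import annotations

import pytest

from wgpscaf.anchoring import Anchor, AnchoredScaffold
from wgpscaf.wgp_map_io import WgpTag


def make_anchored(scaffold_id, anchors, length=None):
    """Build an AnchoredScaffold from (contig, rank, position) triples.

    Tag ids are synthesized from the scaffold id and anchor index.
    """
    anchor_objs = tuple(
        Anchor(WgpTag(f"{scaffold_id}.t{i}", contig, float(rank)), int(pos))
        for i, (contig, rank, pos) in enumerate(sorted(anchors, key=lambda a: a[2]))
    )
    if length is None:
        length = anchor_objs[-1].position + 100
    return AnchoredScaffold(scaffold_id, length, anchor_objs)


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n"


def write_sam(path, references, records):
    """Write a text SAM file: references = {name: length}, records = raw lines."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(SAM_HEADER)
        for name, length in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for rec in records:
            fh.write(rec + "\n")
    return path


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A noise-free 200 kb scenario: 1 BAC contig, 400 tags, 40 scaffolds,
    10 mate pairs per junction, everything parsed and ready to pipeline."""
    from wgpscaf.anchoring import load_tag_alignments
    from wgpscaf.pair_validation import LibraryModel, load_pair_mappings
    from wgpscaf.simulation import simulate_assembly_fixtures, simulate_wgp_map

    out = tmp_path_factory.mktemp("scenario")
    wgp_map, truth = simulate_wgp_map(1, 400, seed=11)
    fixtures = simulate_assembly_fixtures(
        truth, 40, out, mp_mu=3000, mp_sigma=0, read_length=100,
        pairs_per_junction=10, seed=11,
    )
    return {
        "map": wgp_map,
        "truth": truth,
        "fixtures": fixtures,
        "alignments": load_tag_alignments(fixtures.tag_sam),
        "mappings": load_pair_mappings(fixtures.mp_sam),
        "lib": LibraryModel(mu=3000, sigma=0, read_length=100),
    }
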