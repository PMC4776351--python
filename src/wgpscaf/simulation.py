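"""Synthetic genomes, WGP maps and alignment fixtures.

Emulates the study setting end to end with no external data: a linear
genome carrying regularly spaced tag loci grouped in BAC contigs, an
error-free tag map with gamma-distributed rank occupancy, map perturbation
at controlled rates (tags misplaced within their BAC contig, or moved to
another contig), a fragmentation of the genome into scaffolds, and
mate-pair read pairs sampled across the true scaffold junctions.  All
fixtures leave through the standard front door (FASTA, SAM with @SQ
headers, map TSV) so the pipeline consumes them exactly like real data.

What is *not* emulated: sequencing errors, chimeric pairs, repeat-induced
multi-mapping, and the physical BAC library itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .wgp_map_io import WgpMap, WgpTag

__all__ = [
    "TagLocus",
    "SyntheticTruth",
    "Fixtures",
    "simulate_wgp_map",
    "paper_scale_map",
    "inject_errors",
    "simulate_assembly_fixtures",
    "run_error_experiment",
]

#: Gamma parameters of per-rank tag occupancy, inferred in the source study
#: from the Arabidopsis WGP data.
DEFAULT_GAMMA_SHAPE = 1.07
DEFAULT_GAMMA_SCALE = 0.16

DEFAULT_TAG_SPACING = 500  # bp between consecutive tag loci
DEFAULT_TAG_SPAN = 50      # bp, tag length

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TagLocus:
    """The ground-truth placement of one tag on the synthetic genome."""

    tag_id: str
    position: int
    bac_contig: str
    rank: int


@dataclass
class SyntheticTruth:
    """Everything needed to score pipeline output against the simulation."""

    genome_length: int
    tag_loci: list[TagLocus]
    tag_spacing: int = DEFAULT_TAG_SPACING
    tag_span: int = DEFAULT_TAG_SPAN
    scaffold_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    adjacencies: list[tuple[str, str]] = field(default_factory=list)

    @property
    def adjacency_set(self) -> set[frozenset]:
        return {frozenset(pair) for pair in self.adjacencies}


@dataclass
class Fixtures:
    """Paths and metadata of one simulated dataset."""

    assembly_fasta: Path
    tag_sam: Path
    mp_sam: Path
    lengths: dict[str, int]
    truth: SyntheticTruth
    n_tag_records: int
    n_pairs: int


def simulate_wgp_map(
    n_bac_contigs: int,
    n_tags: int,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
    seed: int = 0,
    tag_spacing: int = DEFAULT_TAG_SPACING,
    tag_span: int = DEFAULT_TAG_SPAN,
) -> tuple[WgpMap, SyntheticTruth]:
    """Generate an error-free WGP map over a synthetic linear genome.

    Tags are split near-uniformly over ``n_bac_contigs`` contiguous BAC
    contigs.  Within a contig, consecutive integer ranks are created and
    rank r receives ``max(1, round(draw * c))`` tags, with draws from
    gamma(shape, scale) and a calibration constant ``c = 1/(shape*scale)``
    scaling the draws to unit mean (raw draws at the default parameters
    average ≈0.17 and cannot literally be tag counts).  Tag loci are laid
    out every ``tag_spacing`` bp in map order, so the error-free map is
    perfectly collinear with the genome.
    """
    if n_bac_contigs < 1:
        raise ValidationError("n_bac_contigs must be >= 1")
    if n_tags < n_bac_contigs:
        raise ValidationError("n_tags must be >= n_bac_contigs")
    if gamma_shape <= 0 or gamma_scale <= 0:
        raise ValidationError("gamma parameters must be > 0")
    rng = np.random.default_rng(seed)
    calibration = 1.0 / (gamma_shape * gamma_scale)
    base, extra = divmod(n_tags, n_bac_contigs)
    budgets = [base + (1 if i < extra else 0) for i in range(n_bac_contigs)]
    width = max(5, len(str(n_tags)))
    tags: list[WgpTag] = []
    loci: list[TagLocus] = []
    index = 0
    for ci, budget in enumerate(budgets):
        contig = f"bctg{ci + 1:04d}"
        remaining = budget
        rank = 0
        while remaining > 0:
            rank += 1
            k = max(1, int(round(rng.gamma(gamma_shape, gamma_scale) * calibration)))
            k = min(k, remaining)
            for _ in range(k):
                index += 1
                tag_id = f"tag{index:0{width}d}"
                position = tag_spacing // 2 + (index - 1) * tag_spacing
                tags.append(WgpTag(tag_id, contig, float(rank)))
                loci.append(TagLocus(tag_id, position, contig, rank))
            remaining -= k
    genome_length = n_tags * tag_spacing
    truth = SyntheticTruth(
        genome_length=genome_length,
        tag_loci=loci,
        tag_spacing=tag_spacing,
        tag_span=tag_span,
    )
    return WgpMap(tags), truth


def paper_scale_map(seed: int = 0) -> tuple[WgpMap, SyntheticTruth]:
    """The full-scale preset: 191 BAC contigs, 64 441 tags."""
    return simulate_wgp_map(191, 64441, seed=seed)


def inject_errors(
    wgp_map: WgpMap, error_type: str, rate: float, seed: int = 0
) -> WgpMap:
    """Perturb a fraction ``rate`` of tags, sampled without replacement.

    ``intra``: a tag's rank is replaced by a uniformly chosen existing rank
    of the same BAC contig (different from its own when possible).
    ``inter``: a tag is reassigned to a uniformly chosen other BAC contig,
    at a uniformly chosen existing rank of that contig.  Tag count is
    conserved; ``rate=0`` is the identity.
    """
    if error_type not in ("intra", "inter"):
        raise ValidationError(f"unknown error type {error_type!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"rate must be in [0, 1], got {rate}")
    contigs = list(wgp_map.bac_contigs)
    if error_type == "inter" and len(contigs) < 2:
        raise ValidationError("inter-contig errors need at least two BAC contigs")
    rng = np.random.default_rng(seed)
    tags = list(wgp_map)
    n_err = int(round(rate * len(tags)))
    chosen = set(rng.choice(len(tags), size=n_err, replace=False).tolist()) if n_err else set()
    contig_ranks = {c: list(wgp_map.contig_ranks(c)) for c in contigs}
    out: list[WgpTag] = []
    for i, tag in enumerate(tags):
        if i not in chosen:
            out.append(tag)
            continue
        if error_type == "intra":
            ranks = contig_ranks[tag.bac_contig]
            candidates = [r for r in ranks if r != tag.rank] or ranks
            new_rank = candidates[int(rng.integers(len(candidates)))]
            out.append(WgpTag(tag.tag_id, tag.bac_contig, new_rank))
        else:
            others = [c for c in contigs if c != tag.bac_contig]
            new_contig = others[int(rng.integers(len(others)))]
            ranks = contig_ranks[new_contig]
            new_rank = ranks[int(rng.integers(len(ranks)))]
            out.append(WgpTag(tag.tag_id, new_contig, new_rank))
    return WgpMap(out)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_assembly_fixtures(
    truth: SyntheticTruth,
    n_scaffolds: int,
    out_dir,
    mp_mu: int = 3000,
    mp_sigma: int = 300,
    read_length: int = 100,
    pairs_per_junction: int = 10,
    inter_scaffold_gap: int = 0,
    seed: int = 0,
) -> Fixtures:
    """Cut a random genome into scaffolds and emit alignment fixtures.

    The genome sequence (4-letter alphabet, seeded) is split into
    ``n_scaffolds`` near-equal pieces; ``inter_scaffold_gap`` bases are
    trimmed from the upstream side of each junction, so every junction has
    that true gap.  Tag loci inside a scaffold become unique single-hit SAM
    records; ``pairs_per_junction`` mate pairs are sampled per true
    junction with fragment size Normal(mp_mu, mp_sigma) and emitted as
    cross-scaffold pairs in reverse-forward orientation (read 1 reverse on
    the upstream scaffold, read 2 forward on the downstream one).
    Updates ``truth`` in place with scaffold intervals and adjacencies.
    """
    if mp_mu <= 2 * read_length:
        raise ValidationError("mp_mu must exceed twice the read length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    G = truth.genome_length
    genome = "".join(_BASES[rng.integers(0, 4, size=G)])

    base, extra = divmod(G, n_scaffolds)
    bounds = [0]
    for i in range(n_scaffolds):
        bounds.append(bounds[-1] + base + (1 if i < extra else 0))
    width = len(str(n_scaffolds))
    scaffolds: list[tuple[str, int, int]] = []  # (id, genome start, genome end)
    for i in range(n_scaffolds):
        start = bounds[i]
        end = bounds[i + 1] - (inter_scaffold_gap if i < n_scaffolds - 1 else 0)
        if end - start <= max(read_length, truth.tag_span):
            raise ValidationError("scaffolds too short for the requested geometry")
        scaffolds.append((f"scaf{i + 1:0{width}d}", start, end))
    truth.scaffold_intervals = list(scaffolds)
    truth.adjacencies = [
        (scaffolds[i][0], scaffolds[i + 1][0]) for i in range(n_scaffolds - 1)
    ]
    lengths = {sid: end - start for sid, start, end in scaffolds}

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{sid}\tLN:{lengths[sid]}" for sid, _, _ in scaffolds]

    # assembly FASTA
    assembly_fasta = out_dir / "assembly.fasta"
    with open(assembly_fasta, "wt", encoding="utf-8") as fh:
        for sid, start, end in scaffolds:
            fh.write(f">{sid}\n")
            seq = genome[start:end]
            for off in range(0, len(seq), 60):
                fh.write(seq[off:off + 60] + "\n")

    # tag alignments
    tag_sam = out_dir / "tags.sam"
    n_tag_records = 0
    with open(tag_sam, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        for locus in truth.tag_loci:
            placed = None
            for sid, start, end in scaffolds:
                if start <= locus.position and locus.position + truth.tag_span <= end:
                    placed = (sid, locus.position - start)
                    break
            if placed is None:
                continue  # locus falls in a trimmed inter-scaffold gap
            sid, pos = placed
            seq = genome[locus.position:locus.position + truth.tag_span]
            fh.write(
                f"{locus.tag_id}\t0\t{sid}\t{pos + 1}\t60\t{truth.tag_span}M\t*\t0\t0\t{seq}\t*\n"
            )
            n_tag_records += 1

    # mate pairs across true junctions
    mp_sam = out_dir / "pairs.sam"
    n_pairs = 0
    with open(mp_sam, "wt", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        for j in range(n_scaffolds - 1):
            sid1, start1, end1 = scaffolds[j]
            sid2, start2, end2 = scaffolds[j + 1]
            for k in range(pairs_per_junction):
                frag = mp_mu if mp_sigma == 0 else int(round(rng.normal(mp_mu, mp_sigma)))
                lo = max(start1, start2 - frag + read_length)
                hi = min(end1 - read_length, end2 - frag)
                if lo > hi:
                    continue  # fragment cannot span this junction
                f0 = int(rng.integers(lo, hi + 1))
                pos1 = f0 - start1
                pos2 = (f0 + frag - read_length) - start2
                seq1 = _revcomp(genome[f0:f0 + read_length])
                seq2 = genome[f0 + frag - read_length:f0 + frag]
                name = f"pair_{j + 1}_{k + 1}"
                fh.write(
                    f"{name}\t81\t{sid1}\t{pos1 + 1}\t60\t{read_length}M\t"
                    f"{sid2}\t{pos2 + 1}\t0\t{seq1}\t*\n"
                )
                fh.write(
                    f"{name}\t161\t{sid2}\t{pos2 + 1}\t60\t{read_length}M\t"
                    f"{sid1}\t{pos1 + 1}\t0\t{seq2}\t*\n"
                )
                n_pairs += 1

    return Fixtures(
        assembly_fasta=assembly_fasta,
        tag_sam=tag_sam,
        mp_sam=mp_sam,
        lengths=lengths,
        truth=truth,
        n_tag_records=n_tag_records,
        n_pairs=n_pairs,
    )


def run_error_experiment(
    rates: Sequence[float],
    error_types: Sequence[str] = ("intra", "inter"),
    replicates: int = 5,
    seed: int = 0,
    work_dir=None,
    n_bac_contigs: int = 4,
    n_tags: int = 240,
    n_scaffolds: int = 24,
    mp_mu: int = 3000,
    mp_sigma: int = 300,
    read_length: int = 100,
    pairs_per_junction: int = 5,
    min_gap: float = -200,
):
    """Map-error robustness study: perturb the map, rerun the pipeline.

    One base scenario (genome, error-free map, tag and MP alignments) is
    generated, then for every (error type, rate, replicate) the map is
    perturbed and the full pipeline re-run against the same fixtures.
    Returns a tidy DataFrame with An50, output N50, link counts and
    correct-join/misjoin counts versus the known adjacency truth.
    """
    import pandas as pd
    import tempfile

    from .anchoring import load_tag_alignments
    from .pair_validation import LibraryModel, load_pair_mappings
    from .pipeline import run_pipeline

    rng = np.random.default_rng(seed)
    base_map, truth = simulate_wgp_map(n_bac_contigs, n_tags, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        fixtures = simulate_assembly_fixtures(
            truth,
            n_scaffolds,
            work_dir or tmp,
            mp_mu=mp_mu,
            mp_sigma=mp_sigma,
            read_length=read_length,
            pairs_per_junction=pairs_per_junction,
            seed=seed,
        )
        alignments = load_tag_alignments(fixtures.tag_sam)
        mappings = load_pair_mappings(fixtures.mp_sam)
    lib = LibraryModel(mu=mp_mu, sigma=mp_sigma, read_length=read_length)
    adjacency = truth.adjacency_set

    rows = []
    for error_type in error_types:
        for rate in rates:
            for rep in range(replicates):
                sub_seed = int(rng.integers(0, 2**31))
                emap = inject_errors(base_map, error_type, rate, seed=sub_seed)
                res = run_pipeline(
                    emap, alignments, mappings, fixtures.lengths, lib, min_gap=min_gap
                )
                joined = res.joined_pairs
                correct = sum(1 for p in joined if p in adjacency)
                rows.append(
                    {
                        "error_type": error_type,
                        "rate": rate,
                        "replicate": rep,
                        "an50": res.quality.anx(50).anx,
                        "n50": res.output_n50,
                        "n_map_links": res.validation.n_map_links,
                        "n_validated": res.validation.n_validated,
                        "correct_joins": correct,
                        "misjoins": len(joined) - correct,
                    }
                )
    return pd.DataFrame(rows)
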