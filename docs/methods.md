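# Methods

This note documents the models, conventions and numerical choices behind
`wgpscaf`, in the order the pipeline applies them, plus what the synthetic
data generator does and does not emulate.

## Map construction from fingerprints

`order_tags_from_fingerprints` reproduces the automated tag-ordering
procedure for raw WGP data. BACs are sorted per BAC contig on their
(left, right) fingerprint coordinates and given **dense ranks starting
at 1**: identical coordinate pairs share a rank and the next distinct pair
gets the previous rank + 1. Dense ranking keeps the mean-rank arithmetic
stable under duplicated BACs. A tag's rank is the mean of its BAC ranks
and is kept **fractional** rather than re-compressed to integers — equal
mean BAC ranks must give equal tag ranks, and fractional ranks compare
exactly. A tag is an outlier (excluded from the map) when its BACs span
more than one BAC contig or when its BAC-rank spread (max − min) exceeds
`max_rank_spread` (default 5 ranks; the threshold is inherently
data-dependent and exposed as a parameter). Outlier detection considers
all of a tag's BACs at once; no partial-BAC rescue is attempted, because
there is no principled way to decide which BAC is the aberrant one from
fingerprint data alone.

## Anchoring

Coordinates are 0-based half-open internally; SAM's 1-based positions are
converted on ingest. A tag is *multi-located* — and contributes nothing —
if it has any secondary or supplementary record, an XA alternative-hit
tag, more than one primary record, or MAPQ below `min_mapq` (default 1;
MAPQ 0 is how BWA marks repeat placements). The anchor position is the
leftmost mapped base regardless of strand: the link and quality formalism
uses positions only, so tag strand is retained but unused.

A *nested* scaffold — one whose anchored interval lies inside another
scaffold's — is excluded from linking (not from quality metrics). Since
map ranks are the only coordinate system shared between scaffolds,
containment is tested on per-BAC-contig rank intervals, strict at both
ends. Only scaffolds anchored to a single BAC contig can be classified as
nested; a scaffold spanning contigs is by construction not "inside"
another.

## Collinear segments and the Anx family

A segment breaks when the BAC contig changes or a strict rank change
contradicts the run's direction; the direction is fixed by the first
strict change, ties are compatible with both directions, and an all-tied
run is monotone. Segment length runs from the first anchor's position to
the last anchor's position **plus `tag_span`** (default 50 bp, the
typical WGP tag length): the precise physical extent of a collinear
region is unobservable, and counting the final tag's own span is the
least arbitrary closure. A single-anchor scaffold contributes one segment
of `tag_span` bp — it is vacuously "correctly organized", but crediting
it with the full scaffold length would inflate the metrics exactly where
anchoring is weakest. Whether such scaffolds were counted by earlier
tools is unknown; the convention here is deliberate and documented.

Anx-style statistics sort segment lengths descending and accumulate until
reaching x % of the denominator (anchored size, assembly size or a
user-supplied genome size — no genome-size estimation is attempted). When
the total segment length cannot reach the threshold the value is 0 and
flagged "not reached"; this keeps every column non-increasing in x.

## Map-links

"Adjacent" is interpreted as *consecutive* in the per-contig ordering of
scaffolds by (first-anchor rank, last-anchor rank, scaffold id): linking
every rank-compatible pair would create transitive, redundant links,
while consecutive pairs give each scaffold end at most one candidate per
side. A scaffold whose terminal anchors sit on two BAC contigs is placed
by both terminals (first anchor serves the right side of a link, last
anchor the left side); its internal anchors do not participate, matching
the terminal-anchor link conditions.

## Mate-pair validation and gap estimation

The four orientation formulas (module docstring of `pair_validation`)
implement the naïve estimator: fragment mean μ minus the part of the
fragment each scaffold carries. The estimate is bounded by μ and can
underestimate the true gap; the trade-off is accepted because it remains
defined for a **single** supporting pair, which is what enables
validation in low-coverage regions. Read orientation translates to
scaffold orientation for a left→right join as: read 1 reverse ⇔ left
scaffold forward; read 2 forward ⇔ right scaffold forward.

Conventions chosen where the procedure was genuinely open:

* **One vote per read pair per link.** Alternative hits expand to extra
  mapping possibilities, but a physical pair may support only one
  orientation class of one link (its first possibility in deterministic
  order); anything else double-counts PCR duplicates of evidence.
  Duplicate *pairs* are counted as given — no PCR deduplication.
* **Orientation ties reject the link** as ambiguous (logged). Emitting an
  arbitrary orientation risks misjoins; the cost is one unvalidated link.
* **gap_sd** is the sample sd of per-pair gap estimates within the
  winning class; with a single pair it falls back to the library sigma,
  the correct prior for one draw.
* `min_gap` defaults to −200 bp and is CLI-overridable; μ, σ and R are
  taken from the command line rather than re-estimated.

The `.de` output is a DistanceEst-style dialect (left scaffold with
orientation sign, then `right±,gap,n,sd` groups); it is verified by
parse-back, not byte comparison with any particular historical tool.

## Super-scaffold construction

Chains are built internally instead of shelling out to an external
scaffolder, keeping the artifact dependency-free and the joins testable;
the `.de` file remains available for users who prefer SGA. At a scaffold
end with several incident links, the best-supported link survives (a
support tie drops all links at that end); cycles are broken at their
lowest-support link. Negative or zero gap estimates are realized as a
fixed run of `min_n_run` = 20 Ns — the common convention for a captured
gap of unknown size; overlap-merging negative gaps would require sequence
alignment and is out of scope. Non-N bases are conserved exactly, and the
AGP v2.1 output reconstructs the FASTA byte-for-byte (gap lines carry
`scaffold/yes/paired-ends;map`).

## Synthetic data

`simulate_wgp_map` lays `n_tags` tag loci every `tag_spacing` (500) bp on
a linear genome and groups them into near-equal contiguous BAC contigs.
Within a contig, consecutive integer ranks receive
`max(1, round(draw × c))` tags, with draws from gamma(1.07, 0.16) — the
occupancy distribution observed in real WGP data — and `c = 1/(shape ×
scale)` rescaling the draws to unit mean, since the raw gamma mean
(≈0.17) cannot literally be a tag count. The exact discretization used to
fit those parameters is not recoverable; this calibration reproduces the
distribution's shape while hitting the requested tag total. How the
original 64 441 tags were split over 191 BAC contigs is likewise
unstated; the generator splits uniformly (the preset
`paper_scale_map()` builds that full-scale map).

Error injection perturbs an exact `round(rate × n_tags)` sample of tags,
without replacement: *intra* replaces a tag's rank by a uniformly chosen
existing rank of its own contig (different when possible); *inter* moves
the tag to a uniform other contig at a uniform existing rank. Ranks are
replaced rather than swapped between tags, matching the notion of a tag
being "misplaced" and keeping perturbations independent.

`simulate_assembly_fixtures` cuts a seeded random genome into near-equal
scaffolds, optionally trimming `inter_scaffold_gap` bases upstream of
each junction so every junction has a known true gap. Tag loci become
unique single-hit SAM records; mate pairs are sampled per junction with
fragment size ~ Normal(μ, σ), read 1 reverse on the upstream scaffold and
read 2 forward downstream (reverse-forward chemistry, which maps onto the
estimator's (−,+) case when both scaffolds are genome-oriented). A
fragment too large to fit both scaffolds is skipped — a small, realistic
truncation that can bias gap estimates slightly downward, which is why
the estimator's calibration is asserted one-sided.

Not emulated: sequencing errors, chimeric pairs, repeats (hence
multi-mapping), uneven scaffold sizes, and the BAC library itself.
Passing tests therefore demonstrate the correctness of the algorithms
and their error-robustness under map noise, not performance on
repeat-rich real assemblies, where unique anchoring is the binding
constraint.

## Problem sizes and scenarios

The standard test scenario uses a 200 kb genome, 400 tags, 40 scaffolds
and 10 noise-free pairs per junction. For the end-to-end recovery check
it uses a **single BAC contig**: a junction coinciding with a BAC-contig
boundary can never be map-linked (the link condition requires a shared
contig), so the single-contig scenario is the one in which "every true
adjacency is recoverable" is well-posed. Multi-contig maps are exercised
by the map-error study (4 contigs, 240 tags, 24 scaffolds, μ = 3000 bp,
σ = 300 bp, 5 pairs per junction, rates 0–0.8, both error types), a
desk-scale replica of the robustness experiment: An50 decays once the
error rate passes ~0.1 while misjoins stay at zero, because erroneous
map-links lack mate-pair support and are never validated — accuracy is
map-error-robust, contiguity is not. Gap-estimator calibration uses two
10 kb scaffolds, a known 0/200/500 bp gap and 200 pairs; the mean
estimate is required to stay below μ and within 2σ/√n above the true gap.

## Known limitations

* Tag strand is ignored; orientation evidence comes only from mate pairs,
  so a scaffold anchored by one tag and unsupported by pairs cannot be
  oriented.
* The naïve gap estimator underestimates large gaps approaching μ, and
  junctions farther apart than μ cannot be validated at all — validation
  rates are bounded by the mate-pair library size.
* The `.de` dialect is self-consistent (writer/reader pair) but not
  guaranteed byte-compatible with every DistanceEst consumer.
* `run_error_experiment` reuses one fixed genome/alignment fixture across
  replicates; only the map perturbation is re-randomized, which isolates
  the map-error effect but understates fixture-to-fixture variance.
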