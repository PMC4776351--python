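"""Gap estimation, orientation voting and .de emission."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import write_sam
from wgpscaf.errors import ValidationError
from wgpscaf.linking import MapLink
from wgpscaf.pair_validation import (
    LibraryModel,
    ReadPairMapping,
    ValidatedLink,
    estimate_gap,
    load_pair_mappings,
    read_de_file,
    validate_links,
    write_de_file,
)

LIB = LibraryModel(mu=1000, sigma=75, read_length=100)


def geometric_gap(orient1, orient2, mu, R, pos1, pos2, len1, len2):
    """Independent oracle: place both scaffolds on a line so the fragment runs
    off the junction-facing end of each, and measure the implied gap.

    The junction-facing portion of a scaffold is the part of the fragment it
    carries: from the read through the end the fragment exits by.
    """
    # scaffold 1: fragment exits via the right end of the *placed* scaffold.
    # A '+' read means the scaffold is placed flipped, so the exit distance is
    # measured from coordinate 0 through the read's far edge.
    part1 = (pos1 + R) if orient1 == "+" else (len1 - pos1)
    part2 = (pos2 + R) if orient2 == "+" else (len2 - pos2)
    return mu - part1 - part2


class TestEstimateGap:
    def test_forward_forward_example(self):
        m = ReadPairMapping("A", "B", "+", "+", 100, 200, 100)
        assert estimate_gap(m, LibraryModel(1000, 0, 100), 5000, 5000) == 500

    def test_reverse_reverse_example(self):
        m = ReadPairMapping("A", "B", "-", "-", 100, 150, 100)
        assert estimate_gap(m, LibraryModel(1000, 0, 100), 300, 400) == 550

    def test_mu_is_the_upper_bound(self):
        m = ReadPairMapping("A", "B", "+", "+", 0, 0, 1)
        lib = LibraryModel(1000, 0, 1)
        assert estimate_gap(m, lib, 100, 100) == 1000 - 2

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        o1=st.sampled_from("+-"), o2=st.sampled_from("+-"),
        mu=st.integers(200, 20000), R=st.integers(1, 150),
        len1=st.integers(200, 50000), len2=st.integers(200, 50000),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    def test_matches_geometric_oracle_and_bounded_by_mu(self, o1, o2, mu, R, len1, len2, f1, f2):
        pos1 = int(f1 * (len1 - R))
        pos2 = int(f2 * (len2 - R))
        m = ReadPairMapping("A", "B", o1, o2, pos1, pos2, R)
        lib = LibraryModel(mu, 0, R)
        gap = estimate_gap(m, lib, len1, len2)
        assert gap == geometric_gap(o1, o2, mu, R, pos1, pos2, len1, len2)
        assert gap <= mu

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        o1=st.sampled_from("+-"), o2=st.sampled_from("+-"),
        pos1=st.integers(0, 900), pos2=st.integers(0, 900),
    )
    def test_swapping_reads_mirrors_orientation_and_preserves_gap(self, o1, o2, pos1, pos2):
        lib = LibraryModel(3000, 0, 100)
        m = ReadPairMapping("A", "B", o1, o2, pos1, pos2, 100)
        swapped = ReadPairMapping("B", "A", o2, o1, pos2, pos1, 100)
        assert estimate_gap(m, lib, 1000, 1200) == estimate_gap(swapped, lib, 1200, 1000)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValidationError):
            ReadPairMapping("A", "B", "?", "+", 0, 0, 100)


class TestLoadPairMappings:
    REFS = {"scafA": 5000, "scafB": 5000, "scafC": 5000}

    @staticmethod
    def pair_lines(name, ref1, pos1, ref2, pos2, flag1=97, flag2=145):
        return [
            f"{name}\t{flag1}\t{ref1}\t{pos1}\t60\t100M\t{ref2}\t{pos2}\t0\t*\t*",
            f"{name}\t{flag2}\t{ref2}\t{pos2}\t60\t100M\t{ref1}\t{pos1}\t0\t*\t*",
        ]

    def test_cross_scaffold_pair_kept(self, tmp_path):
        sam = write_sam(tmp_path / "p.sam", self.REFS,
                        self.pair_lines("p1", "scafA", 101, "scafB", 201))
        (m,) = load_pair_mappings(sam)
        assert (m.scaf1, m.scaf2, m.pos1, m.pos2) == ("scafA", "scafB", 100, 200)
        assert (m.orient1, m.orient2) == ("+", "-")

    def test_same_scaffold_pair_excluded(self, tmp_path):
        sam = write_sam(tmp_path / "p.sam", self.REFS,
                        self.pair_lines("p1", "scafA", 101, "scafA", 901))
        assert load_pair_mappings(sam) == []

    def test_half_mapped_pair_excluded(self, tmp_path):
        sam = write_sam(tmp_path / "p.sam", self.REFS, [
            "p1\t73\tscafA\t101\t60\t100M\t*\t0\t0\t*\t*",
            "p1\t133\t*\t0\t0\t*\tscafA\t101\t0\t*\t*",
        ])
        assert load_pair_mappings(sam) == []

    def test_secondary_hits_expand_possibilities(self, tmp_path):
        lines = self.pair_lines("p1", "scafA", 101, "scafB", 201)
        lines.append("p1\t353\tscafC\t301\t0\t100M\tscafB\t201\t0\t*\t*")  # secondary read1
        sam = write_sam(tmp_path / "p.sam", self.REFS, lines)
        mappings = load_pair_mappings(sam)
        assert {(m.scaf1, m.scaf2) for m in mappings} == {("scafA", "scafB"), ("scafC", "scafB")}


class TestValidateLinks:
    LENGTHS = {"A": 2000, "B": 2000, "C": 2000}
    LINK = MapLink("A", "B", "c1", 5, 6)

    @staticmethod
    def mapping(pair_id, o1, o2, pos1, pos2, scaf1="A", scaf2="B"):
        return ReadPairMapping(scaf1, scaf2, o1, o2, pos1, pos2, 100, pair_id=pair_id)

    def test_majority_orientation_wins(self):
        mappings = [
            self.mapping("p1", "+", "-", 100, 1800),
            self.mapping("p2", "+", "-", 200, 1700),
            self.mapping("p3", "+", "-", 150, 1850),
            self.mapping("p4", "+", "+", 100, 100),
        ]
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS)
        (link,) = result.links
        assert (link.orient1, link.orient2) == ("+", "-")
        assert link.support == 3

    def test_mean_gap_below_min_gap_rejected(self):
        # (+,-): gap = mu - (pos1+R) - (len2-pos2) = 3000 - 1900 - 1400 = -300
        mappings = [self.mapping("p1", "+", "-", 1800, 600)]
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS, min_gap=-200)
        assert result.links == [] and result.n_below_min_gap == 1

    def test_single_pair_validates_with_sigma_fallback_sd(self):
        mappings = [self.mapping("p1", "+", "-", 1000, 250)]  # gap = 3000-1100-1750 = 150
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS)
        (link,) = result.links
        assert (link.gap, link.support, link.gap_sd) == (150, 1, 100)

    def test_orientation_tie_is_ambiguous(self):
        mappings = [
            self.mapping("p1", "+", "-", 1500, 200),
            self.mapping("p2", "+", "+", 1500, 200),
        ]
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS)
        assert result.links == [] and result.n_ambiguous == 1

    def test_swapped_mate_roles_give_same_validation(self):
        fwd = [self.mapping("p1", "-", "+", 300, 150)]
        rev = [self.mapping("p1", "+", "-", 150, 300, scaf1="B", scaf2="A")]
        lib = LibraryModel(3000, 100, 100)
        r1 = validate_links([self.LINK], fwd, lib, self.LENGTHS)
        r2 = validate_links([self.LINK], rev, lib, self.LENGTHS)
        assert r1.links[0].gap == r2.links[0].gap
        assert (r1.links[0].orient1, r1.links[0].orient2) == (
            r2.links[0].orient1, r2.links[0].orient2)

    def test_one_vote_per_read_pair(self):
        # the same physical pair reported twice must not count double
        mappings = [
            self.mapping("p1", "+", "-", 1500, 200),
            self.mapping("p1", "+", "-", 1500, 200),
            self.mapping("p2", "+", "+", 1000, 100),
        ]
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS)
        assert result.n_ambiguous == 1

    def test_unsupported_link_counted(self):
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], [], lib, self.LENGTHS)
        assert result.links == [] and result.n_no_support == 1

    def test_support_sum_bounded_by_mapping_count(self):
        rng = random.Random(0)
        mappings = [
            self.mapping(f"p{i}", rng.choice("+-"), rng.choice("+-"),
                         rng.randrange(1900), rng.randrange(1900))
            for i in range(50)
        ]
        lib = LibraryModel(3000, 100, 100)
        result = validate_links([self.LINK], mappings, lib, self.LENGTHS, min_gap=-10**9)
        assert sum(l.support for l in result.links) <= len(mappings)


class TestDeFile:
    def make_link(self, left, right, o1="-", o2="+", gap=150, support=3, sd=75.0):
        return ValidatedLink(left, right, o1, o2, gap, support, sd)

    def test_record_contains_all_fields(self, tmp_path):
        path = tmp_path / "links.de"
        write_de_file([self.make_link("A", "B", o1="+", o2="-")], path)
        text = path.read_text()
        assert text == "A-\tB-,150,3,75.00\n"

    def test_empty_links_empty_file(self, tmp_path):
        path = tmp_path / "links.de"
        write_de_file([], path)
        assert path.read_text() == ""

    def test_parse_back_round_trip(self, tmp_path):
        links = [
            self.make_link("A", "B"),
            self.make_link("A", "C", gap=-50, support=1, sd=300.0),
            self.make_link("B", "C", o1="+", o2="-", gap=900, support=12, sd=10.5),
        ]
        path = tmp_path / "links.de"
        write_de_file(links, path)
        parsed = read_de_file(path)
        assert len(parsed) == 3
        by_pair = {(l.left_scaffold, l.right_scaffold): l for l in parsed}
        for link in links:
            got = by_pair[(link.left_scaffold, link.right_scaffold)]
            assert (got.orient1, got.orient2) == (link.orient1, link.orient2)
            assert (got.gap, got.support) == (link.gap, link.support)
            assert got.gap_sd == pytest.approx(link.gap_sd, abs=0.01)
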