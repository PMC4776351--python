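"""Chain extraction, FASTA realization and AGP emission."""

from collections import Counter

import pytest

from wgpscaf.errors import ValidationError
from wgpscaf.pair_validation import ValidatedLink
from wgpscaf.scaffold_builder import (
    build_fasta,
    chain_links,
    complete_chains,
    gap_run_length,
    write_agp,
    write_fasta,
)


def link(left, right, gap=50, support=5, o1="-", o2="+"):
    """A link joining left(+) to right(+) by default."""
    return ValidatedLink(left, right, o1, o2, gap, support, 10.0)


def assemble_from_agp(agp_path, sequences):
    """Independent oracle: rebuild objects by following AGP lines literally."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    objects: dict[str, list] = {}
    with open(agp_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            obj, start, end, _part, kind = f[0], int(f[1]), int(f[2]), f[3], f[4]
            parts = objects.setdefault(obj, [])
            if kind == "N":
                parts.append((start, "N" * int(f[5])))
            else:
                seq = sequences[f[5]][int(f[6]) - 1:int(f[7])]
                if f[8] == "-":
                    seq = "".join(comp[b] for b in reversed(seq))
                parts.append((start, seq))
            assert end - start + 1 == len(parts[-1][1])
    return {
        obj: "".join(s for _, s in sorted(parts))
        for obj, parts in objects.items()
    }


class TestChainLinks:
    def test_simple_path(self):
        chains = chain_links([link("A", "B"), link("B", "C")])
        (chain,) = chains
        assert chain.members == (("A", "+"), ("B", "+"), ("C", "+"))
        assert chain.gaps == (50, 50)

    def test_branch_resolved_by_support(self):
        chains = chain_links([link("A", "B", support=5), link("A", "C", support=2)])
        by_first = {c.members[0][0]: c for c in chains}
        assert by_first["A"].members == (("A", "+"), ("B", "+"))
        assert by_first["C"].members == (("C", "+"),)

    def test_branch_support_tie_drops_both(self):
        chains = chain_links([link("A", "B", support=3), link("A", "C", support=3)])
        assert all(len(c.members) == 1 for c in chains)
        assert sorted(c.members[0][0] for c in chains) == ["A", "B", "C"]

    def test_three_cycle_broken_at_weakest_link(self):
        links = [
            link("A", "B", support=5),
            link("B", "C", support=4),
            link("C", "A", support=1),
        ]
        (chain,) = chain_links(links)
        assert len(chain.members) == 3
        ids = [m for m, _ in chain.members]
        # the A-B and B-C joins survive, so B is in the middle
        assert ids[1] == "B"

    def test_every_input_scaffold_appears_exactly_once(self):
        links = [
            link("A", "B", support=5),
            link("A", "C", support=5),  # tie at A's end: both dropped
            link("D", "E", support=2),
        ]
        chains = chain_links(links)
        members = [m for c in chains for m, _ in c.members]
        assert sorted(members) == ["A", "B", "C", "D", "E"]

    def test_reversed_member_orientation_propagates(self):
        # A(+) joined to B(-): B's sequence enters reverse-complemented
        chains = chain_links([link("A", "B", o1="-", o2="-")])
        (chain,) = chains
        assert chain.members == (("A", "+"), ("B", "-"))


class TestBuildFasta:
    SEQS = {"A": "ACGTACGTAC", "B": "GGGTTTCCCA", "C": "ATATATATAT"}

    def test_small_gap_padded_to_min_n_run(self):
        chains = complete_chains(chain_links([link("A", "B", gap=7)]), self.SEQS)
        (rec,) = [r for r in build_fasta(chains, self.SEQS) if "superscaffold" in r.id]
        assert str(rec.seq) == self.SEQS["A"] + "N" * 20 + self.SEQS["B"]

    def test_positive_gap_exact_n_run(self):
        chains = complete_chains(chain_links([link("A", "B", gap=25)]), {"A": self.SEQS["A"], "B": self.SEQS["B"]})
        recs = build_fasta(chains, self.SEQS)
        merged = next(r for r in recs if len(r.seq) > 10)
        assert str(merged.seq) == self.SEQS["A"] + "N" * 25 + self.SEQS["B"]

    def test_negative_gap_clipped_to_min_n_run(self):
        chains = complete_chains(chain_links([link("A", "B", gap=-150)]), {"A": "", "B": ""})
        merged = next(c for c in chains if len(c.members) == 2)
        recs = build_fasta([merged], self.SEQS, min_n_run=20)
        assert "N" * 20 in str(recs[0].seq)
        assert "N" * 21 not in str(recs[0].seq)

    def test_reverse_complement_applied(self):
        chains = [c for c in complete_chains(chain_links([link("A", "B", o1="-", o2="-")]),
                                             ["A", "B"]) if len(c.members) == 2]
        (rec,) = build_fasta(chains, self.SEQS)
        assert str(rec.seq).endswith("TGGGAAACCC")  # revcomp of B

    def test_non_n_bases_conserved(self):
        chains = complete_chains(
            chain_links([link("A", "B", gap=30), link("B", "C", gap=-5)]), self.SEQS
        )
        records = build_fasta(chains, self.SEQS)
        got = Counter("".join(str(r.seq) for r in records).replace("N", ""))
        want = Counter("".join(self.SEQS.values()))
        assert got == want

    def test_missing_sequence_rejected(self):
        chains = complete_chains(chain_links([link("A", "Z")]), ["A", "Z"])
        with pytest.raises(ValidationError):
            build_fasta(chains, self.SEQS)

    def test_gap_run_length_rule(self):
        assert gap_run_length(50) == 50
        assert gap_run_length(-150) == 20
        assert gap_run_length(0) == 20


class TestAgp:
    SEQS = {"A": "ACGTACGTAC" * 3, "B": "GGGTTTCCCA" * 2, "C": "ATATATATAT"}

    def test_two_member_chain_structure(self, tmp_path):
        chains = complete_chains(chain_links([link("A", "B", gap=12)]), self.SEQS)
        lengths = {k: len(v) for k, v in self.SEQS.items()}
        path = tmp_path / "out.agp"
        write_agp(chains, lengths, path)
        lines = [l.split("\t") for l in path.read_text().splitlines() if not l.startswith("#")]
        merged = [l for l in lines if l[0].startswith("superscaffold")]
        assert [l[4] for l in merged] == ["W", "N", "W"]
        assert int(merged[-1][2]) == lengths["A"] + 20 + lengths["B"]

    def test_singleton_chain_single_w_line(self, tmp_path):
        chains = complete_chains([], ["C"])
        path = tmp_path / "out.agp"
        write_agp(chains, {"C": 10}, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1 and "\tW\tC\t" in lines[0]

    def test_agp_fasta_round_trip(self, tmp_path):
        chains = complete_chains(
            chain_links([link("A", "B", gap=33, o1="-", o2="-"), link("B", "C", gap=-40)]),
            self.SEQS,
        )
        records = build_fasta(chains, self.SEQS)
        lengths = {k: len(v) for k, v in self.SEQS.items()}
        agp = tmp_path / "out.agp"
        write_agp(chains, lengths, agp)
        rebuilt = assemble_from_agp(agp, self.SEQS)
        assert rebuilt == {r.id: str(r.seq) for r in records}

    def test_fasta_wrapped_at_60_columns(self, tmp_path):
        seqs = {"A": "ACGT" * 50}
        chains = complete_chains([], seqs)
        path = tmp_path / "out.fasta"
        write_fasta(build_fasta(chains, seqs), path)
        body = [l for l in path.read_text().splitlines() if not l.startswith(">")]
        assert max(len(l) for l in body) == 60
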