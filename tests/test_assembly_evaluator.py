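import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metafid.assembly_evaluator import (
    ContigPlacement,
    Taxonomy,
    chimera_sharing_matrix,
    classify_contig,
    compatible_organisms,
    divergence_per_base,
    evaluate_assembly,
    lca_rank,
    n50,
    parse_ace,
    parse_psl,
    percent_reads_in_chimeras,
)
from metafid.community_sampler import Placement
from metafid.fixtures import make_toy_taxonomy

from .oracles import brute_force_chimeric, brute_force_lca


def _prov(mapping):
    """genome-set shorthand -> provenance dict of placements."""
    return {
        rid: [Placement(g, f"{g}_chr", 0, 50, "+") for g in genomes]
        for rid, genomes in mapping.items()
    }


MINIMAL_ACE = """AS 1 2

CO c1 8 2 1 U
AC*GTTGA

BQ
40 40 40 40 40 40 40

AF r1 U 1
AF r2 C 5
BS 1 8 r1

RD r1 4 0 0
AC*G

QA 1 4 1 4
DS CHROMAT_FILE: none PHD_FILE: none TIME: none

RD r2 4 0 0
TTGA

QA 1 4 1 4
DS CHROMAT_FILE: none PHD_FILE: none TIME: none

"""


class TestParseAce:
    def test_padding_stripped_and_offsets_shifted(self, tmp_path):
        path = tmp_path / "m.ace"
        path.write_text(MINIMAL_ACE)
        contigs = parse_ace(path)
        assert len(contigs) == 1
        c = contigs[0]
        assert c.consensus == "ACGTTGA"  # '*' removed
        reads = dict((rid, (off, strand)) for rid, off, strand in c.reads)
        assert reads["r1"] == (0, "+")
        # r2 starts at padded position 5; one pad precedes it
        assert reads["r2"] == (3, "-")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "e.ace"
        path.write_text("")
        with pytest.raises(ValueError, match="empty ACE"):
            parse_ace(path)

    def test_contig_count_mismatch_errors(self, tmp_path):
        path = tmp_path / "bad.ace"
        path.write_text(MINIMAL_ACE.replace("AS 1 2", "AS 2 2"))
        with pytest.raises(ValueError):
            parse_ace(path)


class TestCompatibleOrganisms:
    def test_set_semantics(self):
        prov = _prov({"u": ["A"], "s": ["A", "B"]})
        prov["m"] = [Placement("A", "A_chr", i * 100, i * 100 + 50, "+") for i in range(3)]
        assert compatible_organisms("u", prov) == {"A"}
        assert compatible_organisms("s", prov) == {"A", "B"}
        assert compatible_organisms("m", prov) == {"A"}

    def test_unknown_read_raises(self):
        with pytest.raises(KeyError):
            compatible_organisms("ghost", {})


class TestClassifyContig:
    @pytest.mark.parametrize(
        "sets,expect_chimeric,expect_assigned",
        [
            ([["A"], ["A"], ["A"]], False, {"A"}),
            ([["A"], ["B"]], True, {"A", "B"}),  # tie -> seeded draw
            ([["A", "B"], ["B"]], False, {"B"}),  # B explains every read
        ],
    )
    def test_examples(self, sets, expect_chimeric, expect_assigned, rng):
        prov = _prov({f"r{i}": gs for i, gs in enumerate(sets)})
        contig = ContigPlacement(
            "c", "A" * 200, [(f"r{i}", 0, "+") for i in range(len(sets))]
        )
        assigned, chim = classify_contig(contig, prov, rng)
        assert chim is expect_chimeric
        assert assigned in expect_assigned

    def test_naive_mode_uses_origin_labels_only(self, rng):
        # one read shared between A and B, one A-only: alternative-placement
        # rule says non-chimeric, naive origin-label rule with a B origin
        # says chimeric
        full = _prov({"r0": ["A", "B"], "r1": ["A"]})
        origins = _prov({"r0": ["B"], "r1": ["A"]})
        contig = ContigPlacement("c", "A" * 200, [("r0", 0, "+"), ("r1", 0, "+")])
        assert classify_contig(contig, full, rng)[1] is False
        assert classify_contig(
            contig, origins, rng, use_alternative_placements=False
        )[1] is True

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genomes = [f"G{i}" for i in range(4)]
        n_reads = int(rng.integers(1, 8))
        sets = []
        for _ in range(n_reads):
            k = int(rng.integers(1, 4))
            sets.append(list(rng.choice(genomes, size=k, replace=False)))
        prov = _prov({f"r{i}": s for i, s in enumerate(sets)})
        contig = ContigPlacement(
            "c", "A" * 100, [(f"r{i}", 0, "+") for i in range(n_reads)]
        )
        _, chim = classify_contig(contig, prov, np.random.default_rng(0))
        assert chim == brute_force_chimeric([set(s) for s in sets])

    def test_tie_break_deterministic_given_seed(self):
        prov = _prov({"r0": ["A"], "r1": ["B"]})
        contig = ContigPlacement("c", "A" * 100, [("r0", 0, "+"), ("r1", 0, "+")])
        picks = {
            classify_contig(contig, prov, np.random.default_rng(s))[0]
            for s in range(20)
        }
        assert picks == {"A", "B"}  # both reachable across seeds
        one = [
            classify_contig(contig, prov, np.random.default_rng(3))[0]
            for _ in range(5)
        ]
        assert len(set(one)) == 1  # stable for one seed


class TestPercentReadsInChimeras:
    def test_no_chimeras_zero(self):
        contigs = [ContigPlacement("c1", "A" * 200, [("r", 0, "+")] * 5)]
        pct, _ = percent_reads_in_chimeras(contigs, {"c1": False}, 100)
        assert pct == 0.0

    def test_half_of_reads(self):
        contigs = [
            ContigPlacement("c1", "A" * 200, [(f"a{i}", 0, "+") for i in range(5)]),
            ContigPlacement("c2", "A" * 200, [(f"b{i}", 0, "+") for i in range(5)]),
        ]
        pct, _ = percent_reads_in_chimeras(
            contigs, {"c1": True, "c2": False}, 100
        )
        assert pct == 50.0

    def test_short_chimeric_contig_excluded_entirely(self):
        contigs = [
            ContigPlacement("long", "A" * 200, [(f"a{i}", 0, "+") for i in range(5)]),
            ContigPlacement("short", "A" * 80, [(f"b{i}", 0, "+") for i in range(5)]),
        ]
        pct, _ = percent_reads_in_chimeras(
            contigs, {"long": False, "short": True}, 100
        )
        assert pct == 0.0  # the short chimera is not counted anywhere

    def test_no_retained_contigs_is_na(self):
        contigs = [ContigPlacement("c", "A" * 50, [("r", 0, "+")])]
        pct, pct_sampled = percent_reads_in_chimeras(contigs, {"c": True}, 100)
        assert pct is None

    def test_sampled_denominator(self):
        contigs = [
            ContigPlacement("c1", "A" * 200, [(f"a{i}", 0, "+") for i in range(4)]),
        ]
        _, pct = percent_reads_in_chimeras(
            contigs, {"c1": True}, 100, total_sampled_reads=40
        )
        assert pct == 10.0


class TestLcaRank:
    def test_sibling_strains_meet_at_species(self, toy_taxonomy):
        tax, leaves = toy_taxonomy
        assert lca_rank({leaves[0], leaves[1]}, tax) == "species"

    def test_singleton_returns_own_rank(self, toy_taxonomy):
        tax, leaves = toy_taxonomy
        assert lca_rank({leaves[0]}, tax) == "strain"

    def test_cross_genus_meets_at_family(self, toy_taxonomy):
        tax, leaves = toy_taxonomy
        assert lca_rank({leaves[0], leaves[-1]}, tax) == "family"

    def test_unknown_taxid_raises(self, toy_taxonomy):
        tax, _ = toy_taxonomy
        with pytest.raises(KeyError):
            lca_rank({99999}, tax)

    def test_no_rank_nodes_resolve_to_named_ancestor(self):
        nodes = {
            1: (1, "family"),
            2: (1, "genus"),
            3: (2, "no rank"),
            4: (3, "strain"),
            5: (3, "strain"),
        }
        tax = Taxonomy(nodes=nodes)
        assert lca_rank({4, 5}, tax) == "genus"

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_intersection(self, seed):
        rng = np.random.default_rng(seed)
        shape = {
            "genus": int(rng.integers(2, 4)),
            "species": int(rng.integers(2, 4)),
            "strain": int(rng.integers(2, 4)),
        }
        tax, leaves = make_toy_taxonomy(shape)
        k = int(rng.integers(1, 5))
        taxa = set(rng.choice(leaves, size=k, replace=False).tolist())
        expected_node = brute_force_lca(taxa, tax.nodes)
        assert lca_rank(taxa, tax) == tax.rank(expected_node)


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([10], 10), ([5, 4, 3, 2, 1], 4), ([3, 3, 2, 2], 3)],
    )
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_is_na(self):
        assert n50([]) is None

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=30),
           st.integers(1, 7))
    @settings(max_examples=100, derandomize=True)
    def test_order_invariant_and_scales_linearly(self, lengths, c):
        rng = np.random.default_rng(1)
        shuffled = list(lengths)
        rng.shuffle(shuffled)
        assert n50(shuffled) == n50(lengths)
        assert n50([c * x for x in lengths]) == c * n50(lengths)


class TestDivergence:
    def test_identical_contig_zero(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 500))
        assert divergence_per_base(ref[100:300], reference=ref) == 0.0

    def test_two_substitutions_in_100bp(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 500))
        contig = list(ref[200:300])
        for pos in (20, 70):
            contig[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[contig[pos]]
        d = divergence_per_base("".join(contig), reference=ref)
        assert d == pytest.approx(0.02)

    def test_reverse_complement_contig_aligns(self, rng):
        from metafid.community_sampler import reverse_complement

        ref = "".join(rng.choice(list("ACGT"), 400))
        assert divergence_per_base(
            reverse_complement(ref[50:250]), reference=ref
        ) == 0.0

    def test_no_alignment_is_na(self):
        assert divergence_per_base("A" * 100, reference="C" * 300) is None

    def test_psl_row_fields_honored(self, tmp_path):
        # 98 matches, 2 mismatches, no indels over a 100 bp alignment
        row = "\t".join(
            map(str, [98, 2, 0, 0, 0, 0, 0, 0, "+", "ctg", 100, 0, 100,
                      "ref", 500, 100, 200, 1, "100,", "0,", "100,"])
        )
        path = tmp_path / "a.psl"
        path.write_text(row + "\n")
        rows = parse_psl(path)
        assert len(rows) == 1
        assert divergence_per_base("", psl_row=rows[0]) == pytest.approx(0.02)


class TestChimeraSharingMatrix:
    def test_no_chimeras_zero_matrix(self):
        contigs = [ContigPlacement("c", "A" * 100, [("r0", 0, "+")])]
        prov = _prov({"r0": ["A"]})
        m, ids = chimera_sharing_matrix(
            contigs, {"c": False}, prov, {"A": 10, "B": 10}
        )
        assert (m == 0).all()

    def test_single_chimera_hand_computed(self):
        # 3 reads from A, 1 from B in one chimeric contig; 10 reads per genome
        prov = _prov({"a0": ["A"], "a1": ["A"], "a2": ["A"], "b0": ["B"]})
        contig = ContigPlacement(
            "c", "A" * 100,
            [("a0", 0, "+"), ("a1", 0, "+"), ("a2", 0, "+"), ("b0", 0, "+")],
        )
        m, ids = chimera_sharing_matrix(
            [contig], {"c": True}, prov, {"A": 10, "B": 10}
        )
        i, j = ids.index("A"), ids.index("B")
        assert m[i, j] == pytest.approx(20.0)  # 100 * 4 / 20
        assert np.allclose(m, m.T)
        assert np.diagonal(m).sum() == 0


class TestEvaluateAssembly:
    def test_report_consistency(self, toy_reads, toy_taxonomy):
        gs, profile, reads = toy_reads
        tax, leaves = toy_taxonomy
        taxids = {g: leaves[i] for i, g in enumerate(sorted(gs.genomes))}
        prov = {r.read_id: (r.alt_sites or [r.origin]) for r in reads}
        by_genome = {}
        for r in reads:
            by_genome.setdefault(r.origin.genome_id, []).append(r.read_id)
        from metafid.fixtures import mock_assemble

        plan = [
            by_genome["G0"][:3],
            by_genome["G1"][:2] + by_genome["G2"][:2],
            by_genome["G2"][2:5],
        ]
        contigs, truth = mock_assemble(reads, plan, gs, seed=0)
        report = evaluate_assembly(
            contigs, prov, tax, taxids, profile.read_length, seed=1,
            total_sampled_reads=len(reads),
        )
        chimeric_rows = [row for row in report.per_contig if row["chimeric"]]
        assert len(chimeric_rows) == sum(truth)
        assert sum(report.lca_rank_histogram.values()) == len(chimeric_rows)
        assert report.longest_contig == max(len(c.consensus) for c in contigs)
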