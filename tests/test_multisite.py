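"""Multisite clustering, spectrum classification, spectrum comparison."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from radmut.calling import DnmCall
from radmut.multisite import (
    SPECTRUM_CATEGORIES,
    MultisiteCluster,
    SpectrumTable,
    classify_substitution,
    cluster_multisite,
    compare_spectra,
    flag_known_dinucleotide_signatures,
    spectrum_from_calls,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _snv(pos, tag="", origin="undetermined", child="kid", chrom="chr1",
         ref="A", alt="G"):
    return DnmCall(chrom, pos, ref, alt, child, "SNV", 30, 15,
                   haplotype_tag=tag, parental_origin=origin)


class TestClustering:
    def test_two_close_snvs_one_cluster(self):
        out = cluster_multisite([_snv(100, "h1"), _snv(110, "h1")])
        assert len(out) == 1 and len(out[0].members) == 2

    def test_beyond_window_no_cluster(self):
        assert cluster_multisite([_snv(100, "h1"), _snv(250, "h1")]) == []

    def test_incompatible_haplotypes_stay_separate(self):
        assert cluster_multisite([_snv(100, "h1"), _snv(110, "h2")]) == []
        # origin fallback when tags are absent
        out = cluster_multisite(
            [_snv(100, origin="paternal"), _snv(110, origin="paternal")]
        )
        assert len(out) == 1
        assert cluster_multisite(
            [_snv(100, origin="paternal"), _snv(110, origin="undetermined")]
        ) == []

    def test_chain_exceeding_window_end_to_end(self):
        # pairwise gaps of 80 <= 100 chain into one cluster spanning 160
        out = cluster_multisite([_snv(0, "h1"), _snv(80, "h1"), _snv(160, "h1")])
        assert len(out) == 1 and len(out[0].members) == 3
        assert out[0].span == 160

    def test_different_children_never_cluster(self):
        assert cluster_multisite(
            [_snv(100, "h1", child="a"), _snv(110, "h1", child="b")]
        ) == []

    @pytest.mark.parametrize("seed", range(15))
    def test_equals_graph_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        calls = [
            _snv(
                int(rng.integers(0, 600)),
                tag=rng.choice(["", "h1", "h2"]),
                origin=rng.choice(["undetermined", "paternal", "maternal"]),
            )
            for _ in range(n)
        ]
        # brute-force oracle: connected components of the compatibility graph
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = calls[i], calls[j]
            if abs(a.pos - b.pos) > 100:
                continue
            if a.haplotype_tag and b.haplotype_tag:
                ok = a.haplotype_tag == b.haplotype_tag
            elif a.parental_origin != "undetermined" and b.parental_origin != "undetermined":
                ok = a.parental_origin == b.parental_origin
            else:
                ok = False
            if ok:
                g.add_edge(i, j)
        expected = sorted(
            sorted((calls[i].pos, id(calls[i])) for i in comp)
            for comp in nx.connected_components(g)
            if len(comp) >= 2
        )
        got = sorted(
            sorted((m.pos, id(m)) for m in cl.members) for cl in cluster_multisite(calls)
        )
        assert got == expected
        # permutation invariance
        perm = list(calls)
        rng.shuffle(perm)
        got2 = sorted(
            sorted((m.pos, id(m)) for m in cl.members) for cl in cluster_multisite(perm)
        )
        assert got2 == expected


class TestSubstitutionSpectrum:
    def test_cpg_definitional(self):
        assert classify_substitution("C", "T", "ACG") == "C>T at CpG"
        assert classify_substitution("C", "T", "ACA") == "C>T at non-CpG"
        assert classify_substitution("C", "A", "TCT") == "C>A"

    def test_purine_strand_collapse(self):
        # G>A in context CGT is C>T at CpG on the pyrimidine strand
        assert classify_substitution("G", "A", "CGT") == "C>T at CpG"
        assert classify_substitution("A", "C", "TAT") == "T>G"

    def test_non_snv_is_error(self):
        with pytest.raises(ValueError):
            classify_substitution("CA", "C", "ACA")
        with pytest.raises(ValueError):
            classify_substitution("C", "T", "AAG")  # context centre mismatch

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        rc = seq.translate(_COMP)[::-1]
        fwd, rev = SpectrumTable(), SpectrumTable()
        for _ in range(400):
            p = int(rng.integers(1, len(seq) - 1))
            ref = seq[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd.add(classify_substitution(ref, alt, seq[p - 1 : p + 2]))
            # same event seen on the reverse-complemented genome
            q = len(seq) - 1 - p
            rev.add(
                classify_substitution(rc[q], alt.translate(_COMP), rc[q - 1 : q + 2])
            )
        assert fwd.counts == rev.counts

    def test_spectrum_from_calls_uses_reference_context(self):
        ref = {"chr1": "TTTTTACGTTTTT"}
        calls = [_snv(7, ref="C", alt="T")]  # ...A[C]G... -> CpG
        t = spectrum_from_calls(calls, ref)
        assert t.counts["C>T at CpG"] == 1 and t.total == 1


def _fisher_2x2_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    return sum(p for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
               if (p := prob(x)) <= p_obs * (1 + 1e-9))


class TestCompareSpectra:
    def _table(self, values):
        return SpectrumTable(dict(zip(SPECTRUM_CATEGORIES, values)))

    def test_identical_spectra_all_corrected_p_one(self):
        t = self._table([5, 3, 8, 10, 2, 6, 1])
        res = compare_spectra(t, t, reps=2000, seed=0)
        assert (res.per_category["p_bonferroni"] == 1.0).all()
        assert res.global_p > 0.5

    def test_per_category_fisher_matches_enumeration_oracle(self):
        a = self._table([0, 0, 0, 28, 0, 0, 0])
        b = self._table([0, 0, 40, 210, 0, 0, 0])
        res = compare_spectra(a, b, reps=2000, seed=0)
        row = res.per_category.loc["C>T at CpG"]
        expected = _fisher_2x2_oracle([[0, 28], [40, 210]])
        assert row["p"] == pytest.approx(expected, rel=1e-9)
        assert row["p_bonferroni"] == pytest.approx(min(1, 7 * expected), rel=1e-9)

    def test_equal_proportions_odds_ratio_one(self):
        a = self._table([10, 10, 10, 10, 10, 10, 10])
        b = self._table([30, 30, 30, 30, 30, 30, 30])
        res = compare_spectra(a, b, reps=2000, seed=0)
        assert np.allclose(res.per_category["odds_ratio"], 1.0)

    def test_corrected_p_bounds(self):
        rng = np.random.default_rng(0)
        a = self._table(rng.integers(0, 20, 7))
        b = self._table(rng.integers(0, 20, 7))
        res = compare_spectra(a, b, reps=2000, seed=0)
        assert (res.per_category["p_bonferroni"] >= res.per_category["p"]).all()
        assert (res.per_category["p_bonferroni"] <= 1.0).all()
        assert 0 < res.global_p <= 1

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            compare_spectra(self._table([0] * 7), self._table([1] * 7))


class TestDinucleotideSignatures:
    def _cluster(self, ref2, alt2):
        members = [
            _snv(100, "h1", ref=ref2[0], alt=alt2[0]),
            _snv(101, "h1", ref=ref2[1], alt=alt2[1]),
        ]
        return MultisiteCluster(members=members)

    def test_known_signature_flagged(self):
        assert flag_known_dinucleotide_signatures(self._cluster("GC", "AA")) == {"GC>AA"}
        assert flag_known_dinucleotide_signatures(self._cluster("GA", "TT")) == {"GA>TT"}

    def test_reverse_strand_appearances(self):
        # GC>TT on the plus strand is GC>AA on the minus strand
        assert flag_known_dinucleotide_signatures(self._cluster("GC", "TT")) == {"GC>AA"}
        # TC>AA is the minus-strand appearance of GA>TT
        assert flag_known_dinucleotide_signatures(self._cluster("TC", "AA")) == {"GA>TT"}

    def test_non_signature_not_flagged(self):
        assert flag_known_dinucleotide_signatures(self._cluster("AT", "GC")) == set()
        # TC>TT is GA>AA on the minus strand: not a known signature
        assert flag_known_dinucleotide_signatures(self._cluster("TC", "TT")) == set()

    def test_non_adjacent_positions_ignored(self):
        members = [_snv(100, "h1", ref="G", alt="A"), _snv(103, "h1", ref="C", alt="A")]
        assert flag_known_dinucleotide_signatures(MultisiteCluster(members)) == set()
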