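"""Trio VAF filtering, parent-of-origin assignment, count summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radmut.calling import (
    DnmCall,
    FilterParams,
    assign_parental_origin,
    call_dnm_candidates,
    informative_sites,
    summarize_counts,
)
from radmut.ewc import EwcMask
from radmut.multisite import MultisiteCluster


def _table(rows):
    """rows: (pos, (f_dp, f_ad), (m_dp, m_ad), (c_dp, c_ad))."""
    recs = []
    for pos, f, m, c in rows:
        recs.append(
            {
                "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
                "father_dp": f[0], "father_ad": f[1], "father_ht": "",
                "mother_dp": m[0], "mother_ad": m[1], "mother_ht": "",
                "kid_dp": c[0], "kid_ad": c[1], "kid_ht": "",
            }
        )
    return pd.DataFrame(recs)


def _call(df, params=FilterParams(), mask=None, **kw):
    return call_dnm_candidates(df, "father", "mother", "kid", params, mask, **kw)


class TestVafFilter:
    def test_clean_de_novo_accepted(self):
        calls = _call(_table([(100, (30, 0), (30, 0), (30, 15))]))
        assert len(calls) == 1 and calls[0].mclass == "SNV"

    def test_parent_vaf_at_threshold_rejected(self):
        # father VAF 0.15 >= 0.1 -> not de novo
        calls, rej = _call(
            _table([(100, (40, 6), (40, 0), (40, 20))]), return_rejections=True
        )
        assert not calls and rej.iloc[0]["reason"] == "parent_vaf"

    def test_child_vaf_below_quarter_rejected(self):
        calls, rej = _call(
            _table([(100, (40, 2), (40, 2), (40, 8))]), return_rejections=True
        )
        assert not calls and rej.iloc[0]["reason"] == "child_vaf"

    def test_depth_floor(self):
        calls, rej = _call(
            _table([(100, (5, 0), (30, 0), (30, 15))]), return_rejections=True
        )
        assert not calls and rej.iloc[0]["reason"] == "parent_depth"

    def test_mask_restriction_recorded_not_raised(self):
        mask = EwcMask(intervals={"chr1": np.array([[0, 50]])})
        calls, rej = _call(
            _table([(100, (30, 0), (30, 0), (30, 15))]), mask=mask,
            return_rejections=True,
        )
        assert not calls and rej.iloc[0]["reason"] == "outside_ewc"

    def test_missing_sample_column_is_error(self):
        with pytest.raises(KeyError):
            call_dnm_candidates(_table([]), "father", "mother", "nobody")

    @settings(max_examples=60, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(10, 60),  # depths
                st.integers(10, 60),
                st.integers(10, 60),
                st.floats(0, 1),      # vaf fractions
                st.floats(0, 1),
                st.floats(0, 1),
            ),
            min_size=1,
            max_size=25,
        )
    )
    def test_filter_monotone_in_thresholds(self, data):
        rows = [
            (i + 1, (fd, int(fd * fv)), (md, int(md * mv)), (cd, int(cd * cv)))
            for i, (fd, md, cd, fv, mv, cv) in enumerate(data)
        ]
        df = _table(rows)
        base = {c.pos for c in _call(df, FilterParams(0.1, 0.25))}
        looser_parent = {c.pos for c in _call(df, FilterParams(0.2, 0.25))}
        stricter_child = {c.pos for c in _call(df, FilterParams(0.1, 0.4))}
        assert base <= looser_parent
        assert stricter_child <= base


def _info(sites):
    """sites: (pos, alt_parent, child_ht, child_ad)."""
    return pd.DataFrame(
        [
            {
                "chrom": "chr1", "pos": pos, "ref": "A", "alt": "G",
                "alt_parent": parent, "kid_ht": ht, "kid_ad": ad,
            }
            for pos, parent, ht, ad in sites
        ]
    )


class TestParentalOrigin:
    def _dnm(self, pos=1000, tag="h1"):
        return DnmCall("chr1", pos, "A", "T", "kid", "SNV", 30, 15, haplotype_tag=tag)

    def test_direct_linkage(self):
        info = _info([(1080, "paternal", "h1", 12)])
        assert assign_parental_origin(self._dnm(), info) == ("paternal", False)

    def test_no_site_within_distance(self):
        info = _info([(2000, "paternal", "h1", 12)])
        assert assign_parental_origin(self._dnm(), info, max_distance=500) == (
            "undetermined", False,
        )

    def test_unphased_dnm_is_undetermined(self):
        info = _info([(1080, "paternal", "h1", 12)])
        assert assign_parental_origin(self._dnm(tag=""), info) == ("undetermined", False)

    @pytest.mark.parametrize(
        "site1,site2,expected",
        [
            # exhaustive two-site configurations sharing the DNM's tag
            (("paternal", "h1"), ("paternal", "h1"), ("paternal", False)),
            (("maternal", "h1"), ("maternal", "h1"), ("maternal", False)),
            (("paternal", "h1"), ("maternal", "h1"), ("undetermined", True)),
            (("paternal", "h1"), ("maternal", "h2"), ("paternal", False)),
            (("paternal", "h2"), ("maternal", "h2"), ("undetermined", False)),
        ],
    )
    def test_two_site_configurations(self, site1, site2, expected):
        info = _info([(950, site1[0], site1[1], 10), (1050, site2[0], site2[1], 10)])
        assert assign_parental_origin(self._dnm(), info) == expected

    def test_child_must_carry_the_allele(self):
        info = _info([(1080, "paternal", "h1", 0)])
        assert assign_parental_origin(self._dnm(), info) == ("undetermined", False)


class TestInformativeSites:
    def test_homozygous_patterns(self):
        df = pd.DataFrame(
            [
                # father hom alt, mother hom ref -> paternal marker
                {"chrom": "chr1", "pos": 1, "ref": "A", "alt": "G",
                 "father_dp": 30, "father_ad": 30, "mother_dp": 30, "mother_ad": 0},
                # mother hom alt -> maternal marker
                {"chrom": "chr1", "pos": 2, "ref": "A", "alt": "G",
                 "father_dp": 30, "father_ad": 1, "mother_dp": 30, "mother_ad": 29},
                # both het -> not informative
                {"chrom": "chr1", "pos": 3, "ref": "A", "alt": "G",
                 "father_dp": 30, "father_ad": 15, "mother_dp": 30, "mother_ad": 15},
            ]
        )
        out = informative_sites(df, "father", "mother")
        assert out["alt_parent"].tolist() == ["paternal", "maternal"]


def _snv(pos, tag="h1", child="kid"):
    return DnmCall("chr1", pos, "A", "G", child, "SNV", 30, 15, haplotype_tag=tag)


class TestSummarizeCounts:
    def test_cluster_members_leave_the_snv_tally(self):
        calls = [_snv(100), _snv(110), _snv(5000)]
        clusters = [MultisiteCluster(members=calls[:2])]
        counts = summarize_counts(calls, clusters)
        assert counts == {"SNV": 1, "indel": 0, "multisite": 1, "excluded": 0}

    def test_empty_input(self):
        assert summarize_counts([], []) == {
            "SNV": 0, "indel": 0, "multisite": 0, "excluded": 0,
        }

    def test_conservation(self):
        calls = [_snv(p) for p in (100, 110, 300, 5000, 9000)]
        calls[3].exclusion_flags.add("repeat")
        clusters = [MultisiteCluster(members=calls[:2])]
        c = summarize_counts(calls, clusters)
        assert c["SNV"] + c["indel"] + sum(
            len(cl.members) for cl in clusters
        ) + c["excluded"] == len(calls)

    def test_double_assignment_is_error(self):
        calls = [_snv(100), _snv(110), _snv(120)]
        clusters = [
            MultisiteCluster(members=calls[:2]),
            MultisiteCluster(members=calls[1:]),
        ]
        with pytest.raises(ValueError, match="two clusters"):
            summarize_counts(calls, clusters)


class TestRecoveryOnSyntheticTruth:
    def test_sensitivity_and_fdr(self, demo_cohort, demo_result):
        """Planted DNMs at ~0.5 VAF and depth >= 20 inside the mask are found."""
        mask = demo_result.mask
        called = {c.key for c in demo_result.all_calls()}
        eligible = tp = 0
        for t in demo_cohort.truth.itertuples(index=False):
            key = (t.child, t.chrom, t.pos, t.ref, t.alt)
            dp = demo_cohort.variants.loc[
                (demo_cohort.variants.pos == t.pos)
                & (demo_cohort.variants.chrom == t.chrom),
                f"{t.child}_dp",
            ].iloc[0]
            if mask.contains_vcf_pos(t.chrom, t.pos) and dp >= 20:
                eligible += 1
                tp += key in called
        assert eligible >= 30  # the check must actually exercise something
        assert tp / eligible >= 0.95
        truth_keys = {
            (t.child, t.chrom, t.pos, t.ref, t.alt)
            for t in demo_cohort.truth.itertuples(index=False)
        }
        false_calls = called - truth_keys
        assert len(false_calls) / max(len(called), 1) <= 0.05

    def test_assigned_origins_match_truth(self, demo_cohort, demo_result):
        tmap = {
            (t.child, t.chrom, t.pos): t.parental_origin
            for t in demo_cohort.truth.itertuples(index=False)
        }
        determined = [
            c for c in demo_result.all_calls() if c.parental_origin != "undetermined"
        ]
        assert determined  # phasing markers are dense enough to phase some calls
        for c in determined:
            truth_origin = tmap.get((c.child, c.chrom, c.pos))
            if truth_origin is not None:
                assert c.parental_origin == truth_origin
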