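"""PUL detection against an independently coded brute-force rule checker."""

import itertools

import pytest

from glycomet.io_formats import GeneRecord
from glycomet.pul import (
    assign_roles,
    cazyme_class,
    detect_puls,
    pul_transcription,
    render_locus,
)

ROLES = ("susC", "susD", "cazyme", "other")

_LABEL = {"susC": "susC", "susD": "susD", "cazyme": "GH16", "other": "other"}


def locus_from_roles(roles, contig="c0"):
    genes = [
        GeneRecord(f"{contig}_g{i}", contig, i, 900, frozenset({_LABEL[r]}))
        for i, r in enumerate(roles)
    ]
    return assign_roles(genes)


def pul_oracle(roles, max_gap=6):
    """Brute-force rule checker over a role string.

    Returns merged (start, end) index spans: clause 1 fires on an adjacent
    susC/susD pair (either order) with >= 2 cazymes within max_gap
    intervening genes of the pair boundary; clause 2 on >= 3 cazymes
    chained at <= max_gap intervening genes; overlapping spans merge.
    """
    caz = [i for i, r in enumerate(roles) if r == "cazyme"]
    spans = []
    for i in range(len(roles) - 1):
        if {roles[i], roles[i + 1]} == {"susC", "susD"}:
            lo, hi = i, i + 1
            near = [
                c
                for c in caz
                if (c < lo and lo - c - 1 <= max_gap)
                or (c > hi and c - hi - 1 <= max_gap)
            ]
            if len(near) >= 2:
                spans.append((min([lo] + near), max([hi] + near)))
    run = []
    for c in caz:
        if run and c - run[-1] - 1 > max_gap:
            if len(run) >= 3:
                spans.append((run[0], run[-1]))
            run = []
        run.append(c)
    if len(run) >= 3:
        spans.append((run[0], run[-1]))
    spans.sort()
    merged = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def call_spans(calls):
    out = []
    for c in calls:
        ords = [int(g.rsplit("_g", 1)[1]) for g in c.member_gene_ids]
        out.append((min(ords), max(ords)))
    return sorted(out)


class TestRoles:
    def test_cazyme_subfamily_is_degradative(self, gene_factory):
        locus = assign_roles([gene_factory(labels={"GH16_3"})])
        assert locus.genes[0].role == "degradative_cazyme"

    def test_susd_label(self, gene_factory):
        locus = assign_roles([gene_factory(labels={"susD"})])
        assert locus.genes[0].role == "susD"

    def test_glycosyltransferase_is_other(self, gene_factory):
        locus = assign_roles([gene_factory(labels={"GT2"})])
        assert locus.genes[0].role == "other"
        assert not locus.genes[0].is_degradative

    def test_cbm_not_degradative_by_default(self, gene_factory):
        locus = assign_roles([gene_factory(labels={"CBM32"})])
        assert not locus.genes[0].is_degradative

    def test_dual_susc_cazyme_gene(self, gene_factory):
        locus = assign_roles([gene_factory(labels={"susC", "GH5"})])
        g = locus.genes[0]
        assert g.role == "susC" and g.is_degradative

    def test_cazyme_class_parsing(self):
        assert cazyme_class("GH16_3") == "GH"
        assert cazyme_class("PL7") == "PL"
        assert cazyme_class("susC") is None
        assert cazyme_class("GHx") is None


class TestDetectPuls:
    def test_suscd_pair_with_two_cazymes(self):
        calls = detect_puls(locus_from_roles(["susC", "susD", "cazyme", "cazyme"]))
        assert len(calls) == 1
        assert calls[0].trigger_clause == "susCD_pair"

    def test_cazyme_chain_gap_boundary(self):
        # 6 intervening genes: chain holds; 7: broken
        six = ["cazyme"] + ["other"] * 6 + ["cazyme", "cazyme"]
        seven = ["cazyme"] + ["other"] * 7 + ["cazyme", "cazyme"]
        assert len(detect_puls(locus_from_roles(six))) == 1
        assert detect_puls(locus_from_roles(six))[0].trigger_clause == "cazyme_cluster"
        assert detect_puls(locus_from_roles(seven)) == []

    def test_pair_without_enough_cazymes(self):
        assert detect_puls(locus_from_roles(["susC", "susD", "cazyme"])) == []

    def test_nonadjacent_pair_does_not_fire(self):
        roles = ["susC", "other", "susD", "cazyme", "cazyme"]
        assert all(
            c.trigger_clause != "susCD_pair"
            for c in detect_puls(locus_from_roles(roles))
        )

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exhaustive_against_oracle_short(self, n):
        for roles in itertools.product(ROLES, repeat=n):
            locus = locus_from_roles(roles)
            assert call_spans(detect_puls(locus)) == pul_oracle(roles), roles

    def test_reversal_invariance(self):
        import numpy as np

        rng = np.random.default_rng(21)
        for _ in range(300):
            roles = [ROLES[i] for i in rng.integers(0, 4, size=rng.integers(2, 12))]
            fwd = pul_oracle(roles)
            spans = call_spans(detect_puls(locus_from_roles(roles)))
            rev_spans = call_spans(detect_puls(locus_from_roles(roles[::-1])))
            n = len(roles)
            assert sorted((n - 1 - hi, n - 1 - lo) for lo, hi in rev_spans) == spans
            assert spans == fwd

    def test_distant_other_gene_never_creates_pul(self):
        roles = ["cazyme", "cazyme"] + ["other"] * 10 + ["cazyme"]
        assert detect_puls(locus_from_roles(roles)) == []

    def test_planted_architectures_recovered(self):
        from glycomet.synthetic import make_loci

        archs = [
            ["susC", "susD", "cazyme", "cazyme"],
            ["cazyme", "other", "cazyme", "other", "cazyme"],
        ]
        genes, truth = make_loci(archs, n_filler_contigs=3, seed=1)
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.parent_id, []).append(g)
        for contig, members in by_contig.items():
            calls = detect_puls(assign_roles(members))
            if contig in truth:
                lo, hi = truth[contig]
                assert len(calls) == 1
                spans = call_spans(calls)
                assert spans[0][0] >= lo and spans[0][1] <= hi
            else:
                assert calls == []

    def test_gap_seven_chain_not_called(self):
        from glycomet.synthetic import make_loci

        arch = ["cazyme"] + ["other"] * 7 + ["cazyme"] + ["other"] * 7 + ["cazyme"]
        genes, _ = make_loci([arch], n_filler_contigs=0, seed=2, flank=0)
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.parent_id, []).append(g)
        (members,) = by_contig.values()
        assert detect_puls(assign_roles(members)) == []


class TestPulTranscription:
    def _call(self):
        locus = locus_from_roles(["susC", "susD", "cazyme", "cazyme"])
        (call,) = detect_puls(locus)
        return call

    def test_sum_and_mean(self):
        call = self._call()
        tpms = dict(zip(call.member_gene_ids, [10.0, 20.0, 30.0, 0.0]))
        total, mean = pul_transcription(call, tpms)
        assert total == pytest.approx(60.0)
        assert mean == pytest.approx(15.0)

    def test_all_zero(self):
        call = self._call()
        tpms = {g: 0.0 for g in call.member_gene_ids}
        assert pul_transcription(call, tpms) == (0.0, 0.0)

    def test_missing_tpm_named(self):
        call = self._call()
        with pytest.raises(KeyError, match=call.member_gene_ids[0]):
            pul_transcription(call, {})


class TestRendering:
    def test_diagram_marks_members(self):
        locus = locus_from_roles(["other", "susC", "susD", "cazyme", "cazyme"])
        calls = detect_puls(locus)
        text = render_locus(locus, calls)
        assert "susC-susD" in text and "^" in text
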