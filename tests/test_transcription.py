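"""TPM normalization and relative-transcription metrics."""

import numpy as np
import pytest

from glycomet.transcription import (
    OTHER_COMMUNITY,
    family_transcription_share,
    mag_relative_transcription,
    mag_tpm,
    tpm,
    up_transcribed_families,
)


class TestTpm:
    def test_single_gene_gets_the_million(self):
        assert tpm({"a": 17}, {"a": 500}) == {"a": pytest.approx(1e6)}

    def test_length_normalization_closed_form(self):
        # equal counts, lengths L and 2L -> 2:1 rate split
        out = tpm({"a": 10, "b": 10}, {"a": 300, "b": 600})
        assert out["a"] == pytest.approx(666_666.67, abs=0.01)
        assert out["b"] == pytest.approx(333_333.33, abs=0.01)

    def test_universe_sum_is_one_million(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 50))
            counts = {f"g{i}": int(rng.integers(0, 1000)) for i in range(n)}
            lengths = {f"g{i}": int(rng.integers(100, 5000)) for i in range(n)}
            if sum(counts.values()) == 0:
                continue
            assert sum(tpm(counts, lengths).values()) == pytest.approx(
                1e6, rel=1e-9
            )

    def test_count_scaling_invariance(self):
        counts = {"a": 5, "b": 50, "c": 500}
        lengths = {"a": 100, "b": 1000, "c": 200}
        base = tpm(counts, lengths)
        scaled = tpm({g: 7 * c for g, c in counts.items()}, lengths)
        for g in counts:
            assert scaled[g] == pytest.approx(base[g], rel=1e-12)

    def test_all_zero_universe_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            out = tpm({"a": 0, "b": 0}, {"a": 100, "b": 100})
        assert out == {"a": 0.0, "b": 0.0}

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            tpm({"a": 1}, {"a": 0})


class TestMagTpm:
    def test_community_denominator_makes_values_commensurable(self):
        community = {"c1": 100, "c2": 300}
        lengths = {"c1": 1000, "c2": 1000, "m1": 1000}
        # MAG gene with the same count/length as a community gene
        out = mag_tpm({"m1": 100}, lengths, community)
        full = tpm(community, {k: lengths[k] for k in community})
        assert out["m1"] == pytest.approx(full["c1"])

    def test_mag_total_bounded_by_universe(self):
        rng = np.random.default_rng(1)
        community = {f"c{i}": int(rng.integers(0, 500)) for i in range(100)}
        lengths = {f"c{i}": int(rng.integers(100, 3000)) for i in range(100)}
        mag = {f"c{i}": community[f"c{i}"] for i in range(20)}
        out = mag_tpm(mag, lengths, community)
        assert sum(out.values()) <= 1e6 + 1e-6

    def test_equals_restricted_bruteforce(self):
        community = {"a": 10, "b": 20, "c": 30}
        lengths = {"a": 100, "b": 200, "c": 300}
        out = mag_tpm({"b": 20}, lengths, community)
        assert out == {"b": pytest.approx(tpm(community, lengths)["b"])}


class TestMagRelativeTranscription:
    MARKERS = [f"M{i}" for i in range(16)]

    def test_identical_means_give_one(self):
        vals = {m: float(i + 1) for i, m in enumerate(self.MARKERS)}
        assert mag_relative_transcription(vals, vals) == pytest.approx(1.0)

    def test_half_mean_gives_half(self):
        sample = {m: 10.0 for m in self.MARKERS}
        mag = {m: 5.0 for m in self.MARKERS}
        assert mag_relative_transcription(mag, sample) == pytest.approx(0.5)

    def test_scale_free(self):
        rng = np.random.default_rng(2)
        sample = {m: float(rng.uniform(1, 100)) for m in self.MARKERS}
        mag = {m: float(rng.uniform(1, 100)) for m in self.MARKERS}
        r1 = mag_relative_transcription(mag, sample)
        # scaling every TPM in the sample by c leaves the ratio unchanged
        r2 = mag_relative_transcription(
            {m: 3 * v for m, v in mag.items()},
            {m: 3 * v for m, v in sample.items()},
        )
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_partition_conserves_unity(self):
        """MAGs that partition the sample's SC-RBP expression have ratios
        summing to ~1 when each holds an equal marker complement."""
        rng = np.random.default_rng(3)
        n_mags = 5
        mags = [
            {m: float(rng.uniform(1, 50)) for m in self.MARKERS}
            for _ in range(n_mags)
        ]
        sample = {m: sum(mag[m] for mag in mags) for m in self.MARKERS}
        total = sum(mag_relative_transcription(mag, sample) for mag in mags)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_too_few_markers_rejected(self):
        sample = {m: 1.0 for m in self.MARKERS}
        with pytest.raises(ValueError):
            mag_relative_transcription({"M0": 1.0}, sample, min_markers=8)

    def test_zero_sample_mean_rejected(self):
        zeros = {m: 0.0 for m in self.MARKERS}
        with pytest.raises(ValueError):
            mag_relative_transcription(zeros, zeros)


class TestFamilyShare:
    def test_single_mag_holds_all(self):
        shares = family_transcription_share(50.0, {"mag1": 50.0})
        assert shares["mag1"] == pytest.approx(1.0)
        assert shares[OTHER_COMMUNITY] == pytest.approx(0.0)

    def test_arithmetic_with_remainder(self):
        shares = family_transcription_share(50.0, {"a": 30.0, "b": 10.0})
        assert shares["a"] == pytest.approx(0.6)
        assert shares["b"] == pytest.approx(0.2)
        assert shares[OTHER_COMMUNITY] == pytest.approx(0.2)
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_absent_family_reported_as_none(self):
        assert family_transcription_share(0.0, {}) is None

    def test_overshoot_rejected(self):
        with pytest.raises(ValueError):
            family_transcription_share(10.0, {"a": 20.0})


class TestUpTranscribed:
    def test_strict_threshold(self):
        fams = {"GH16": 10.0, "GH17": 20.0, "PL7": 9.0}
        assert up_transcribed_families(fams, 10.0) == {"GH17"}

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        fams = {f"GH{i}": float(rng.uniform(0, 100)) for i in range(50)}
        baseline = 50.0
        expected = {f for f, v in fams.items() if v > baseline}
        assert up_transcribed_families(fams, baseline) == expected


class TestRatioRecovery:
    def test_negative_binomial_recovery_bias(self):
        """Generating MAG marker expression at fraction p of the sample's
        recovers p with |bias| <= 0.02 at mean count >= 50 (100 reps)."""
        from glycomet.io_formats import GeneRecord
        from glycomet.synthetic import ExpressionSpec, make_transcripts

        p = 0.3
        markers = [f"M{i}" for i in range(16)]
        genes = [
            GeneRecord(f"s_{m}", "sample", i, 900, frozenset({m}))
            for i, m in enumerate(markers)
        ] + [
            GeneRecord(f"m_{m}", "mag", i, 900, frozenset({m}))
            for i, m in enumerate(markers)
        ]
        lengths = {g.gene_id: g.length_bp for g in genes}
        estimates = []
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            sample_rates = {m: float(rng.uniform(0.5, 1.5)) for m in markers}
            rates = {f"s_{m}": sample_rates[m] for m in markers}
            rates.update({f"m_{m}": p * sample_rates[m] for m in markers})
            counts, _ = make_transcripts(
                genes, ExpressionSpec(rates=rates), 6000, seed=rep
            )
            assert np.mean([counts[f"s_{m}"] for m in markers]) >= 50
            tpms = tpm(counts, lengths)
            est = mag_relative_transcription(
                {m: tpms[f"m_{m}"] for m in markers},
                {m: tpms[f"s_{m}"] for m in markers},
            )
            estimates.append(est)
        assert abs(np.mean(estimates) - p) <= 0.02
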