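"""Propensity profiles, EIIP spectra and consensus epitope calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antisense._scales import EIIP
from antisense.epitope import (BUILTIN_SCALES, PropensityScale, ResidueProfile,
                               ScalePolarity, consensus_regions, cross_spectrum,
                               eiip_spectrum, windowed_profile)

KD = BUILTIN_SCALES["kd"]
AAS = sorted("ACDEFGHIKLMNPQRSTVWY")


class TestWindowedProfile:
    def test_homopolymer_constant(self):
        prof = windowed_profile("AAAAA", KD, window=3)
        assert np.allclose(prof.scores, KD.values["A"])

    def test_window_one_is_identity(self):
        seq = "RHSLFHP"
        prof = windowed_profile(seq, KD, window=1)
        assert np.allclose(prof.scores, [KD.values[r] for r in seq])

    def test_hydropathy_window9_centre_value(self):
        """Mean Kyte-Doolittle hydropathy of RHSLFHPED is -13.7/9."""
        prof = windowed_profile("RHSLFHPED", KD, window=9)
        assert prof.scores[4] == pytest.approx(-13.7 / 9, abs=1e-10)

    def test_edge_clamp(self):
        prof = windowed_profile("RHSLFHPED", KD, window=9)
        assert np.allclose(prof.scores, prof.scores[4])  # single full window

    @pytest.mark.parametrize("window", [0, 2, 8, 11])
    def test_bad_windows_rejected(self, window):
        with pytest.raises(ValueError):
            windowed_profile("RHSLFHPED", KD, window=window)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet=AAS, min_size=9, max_size=30),
           st.text(alphabet=AAS, min_size=1, max_size=5))
    def test_shift_equivariance(self, seq, prefix):
        """Prepending k residues shifts interior scores by k."""
        base = windowed_profile(seq, KD, window=9).scores
        shifted = windowed_profile(prefix + seq, KD, window=9).scores
        k = len(prefix)
        # interior positions: full windows lying entirely inside the original seq
        inner = slice(4, len(seq) - 4)
        assert np.allclose(shifted[k:][inner], base[inner])

    def test_product_combine_used_for_emini(self):
        emini = BUILTIN_SCALES["emini"]
        prof = windowed_profile("KKKKK", emini, window=5)
        assert prof.scores[2] == pytest.approx(0.37 ** 5 * 0.97 ** 5)

    def test_scale_requires_all_residues(self):
        with pytest.raises(ValueError, match="missing"):
            PropensityScale("partial", {"A": 1.0})


class TestEiipSpectrum:
    def test_homopolymer_spectrum_is_zero(self):
        spec = eiip_spectrum("GGGGGG")
        assert np.allclose(spec.amplitudes, 0.0)

    def test_alternating_sequence_peaks_at_half(self):
        """A two-residue alternation is a square wave: all energy at f=0.5."""
        spec = eiip_spectrum("LD" * 5)
        assert spec.peak_frequency == pytest.approx(0.5)
        others = spec.amplitudes[spec.frequencies < 0.5]
        assert np.all(others < 1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.text(alphabet=AAS, min_size=4, max_size=40))
    def test_parseval(self, seq):
        spec = eiip_spectrum(seq)
        energy = float(np.sum(spec.signal ** 2))
        assert np.sum(spec.amplitudes ** 2) == pytest.approx(energy, abs=1e-12, rel=1e-9)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            eiip_spectrum("LDF")

    def test_frequencies_in_half_open_interval(self):
        spec = eiip_spectrum("RHSLFHPEDTGQV")
        assert np.all(spec.frequencies > 0) and np.all(spec.frequencies <= 0.5)


class TestCrossSpectrum:
    def test_self_cross_is_squared_amplitudes(self):
        spec = eiip_spectrum("RHSLFHP")
        cross = cross_spectrum(spec, spec)
        assert np.allclose(cross.amplitudes, spec.amplitudes ** 2)

    def test_flat_spectrum_kills_cross(self):
        flat = eiip_spectrum("GGGGGGG")
        other = eiip_spectrum("RHSLFHP")
        assert np.allclose(cross_spectrum(flat, other).amplitudes, 0.0)

    def test_shared_dominant_frequency_survives(self):
        """Two alternating sequences share their square-wave frequency."""
        a = eiip_spectrum("LD" * 6)
        b = eiip_spectrum("ND" * 6)
        assert cross_spectrum(a, b).peak_frequency == pytest.approx(0.5)

    def test_unequal_lengths_zero_padded(self):
        a = eiip_spectrum("LD" * 6)
        b = eiip_spectrum("LDLD")
        cross = cross_spectrum(a, b)
        assert cross.frequencies.size == a.frequencies.size


def _step_profile(seq, hi_start, hi_end, method="m", lo=0.0, hi=1.0):
    scores = np.full(len(seq), lo)
    scores[hi_start:hi_end + 1] = hi
    return ResidueProfile(sequence=seq, method=method, scores=scores, window=1)


class TestConsensusRegions:
    SEQ = "A" * 30

    def test_identical_step_profiles_one_call(self):
        profs = [_step_profile(self.SEQ, 9, 19, m) for m in ("a", "b")]
        calls = consensus_regions(profs, vote_threshold=1.0, min_length=5)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (10, 20)
        assert calls[0].mean_vote == pytest.approx(1.0)

    def test_perfect_disagreement_no_calls(self):
        a = _step_profile(self.SEQ, 0, 14)
        b = _step_profile(self.SEQ, 15, 29)
        assert consensus_regions([a, b], vote_threshold=0.75, min_length=5) == []

    def test_majority_vote_region_recovered(self):
        """3 of 5 profiles agree on residues 53..59 (0-based 52..58)."""
        seq = "A" * 70
        agree = [_step_profile(seq, 52, 58, f"yes{i}") for i in range(3)]
        noise = [_step_profile(seq, 0, 6, "no1"), _step_profile(seq, 63, 69, "no2")]
        calls = consensus_regions(agree + noise, vote_threshold=0.5, min_length=5)
        top = calls[0]
        assert top.start <= 59 and top.end >= 53  # overlaps the agreed region

    def test_mismatched_sequences_rejected(self):
        a = _step_profile("A" * 30, 0, 10)
        b = _step_profile("A" * 31, 0, 10)
        with pytest.raises(ValueError, match="different sequences"):
            consensus_regions([a, b])

    def test_constant_profiles_skipped_with_warning(self):
        profs = [_step_profile(self.SEQ, 9, 19, m) for m in ("a", "b")]
        flat = ResidueProfile(self.SEQ, "flat", np.zeros(30), window=1)
        with pytest.warns(UserWarning, match="constant"):
            calls = consensus_regions(profs + [flat], vote_threshold=1.0, min_length=5)
        assert len(calls) == 1

    def test_calls_disjoint_and_ranked(self):
        seq = "A" * 40
        strong = [_step_profile(seq, 2, 8, f"s{i}") for i in range(2)]
        weak = [_step_profile(seq, 30, 38, f"w{i}") for i in range(2)]
        calls = consensus_regions(strong + weak, vote_threshold=0.5, min_length=5)
        spans = [(c.start, c.end) for c in calls]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2 or e2 < s1
        votes = [c.mean_vote for c in calls]
        assert votes == sorted(votes, reverse=True)

    def test_low_is_epitope_orientation(self):
        """A hydropathy-style scale votes where its raw values are lowest."""
        seq = "A" * 30
        scores = np.zeros(30)
        scores[10:20] = -5.0  # low values = epitope-like under LOW_IS_EPITOPE
        prof = ResidueProfile(seq, "hydro", scores, window=1,
                              polarity=ScalePolarity.LOW_IS_EPITOPE)
        partner = _step_profile(seq, 10, 19, "p")
        calls = consensus_regions([prof, partner], vote_threshold=1.0, min_length=5)
        assert (calls[0].start, calls[0].end) == (11, 20)
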