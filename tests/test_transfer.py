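"""Run correlation, region location, decoys, isotope scoring and transfer."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mbrquant as mq
from mbrquant.model import ISOTOPE_SPACING, PROTON_MASS
from mbrquant.tracing import TraceParams
from mbrquant.transfer import (
    IonObservation,
    RtPairing,
    TransferCandidate,
    TransferScores,
    compute_pair_correlation,
    decoy_mz_candidates,
    deduplicate_transfers,
    isotope_kl,
    locate_rt_region,
    score_candidate,
    select_donor_runs,
    transfer_ion,
)
from tests.conftest import build_peak_map


def _obs(rt, inten=1e6, mz=500.0, im=None):
    return IonObservation(rt=rt, intensity=inten, calibrated_mz=mz,
                          protein_ids=("P1",), im=im)


def _ion(i, charge=2):
    return mq.IonKey(f"PEPTIDE{i}", "", charge)


class TestPairCorrelation:
    def test_identical_runs(self):
        ions = {_ion(i): _obs(rt=5.0 + i, inten=1e5 * (i + 1)) for i in range(5)}
        c = compute_pair_correlation(ions, ions)
        assert c.o == 1.0
        assert c.r1 == pytest.approx(1.0)
        assert c.r2 == pytest.approx(1.0)
        assert c.combined == pytest.approx(1.0)

    def test_disjoint_runs(self):
        a = {_ion(i): _obs(5.0 + i) for i in range(4)}
        b = {_ion(i + 100): _obs(5.0 + i) for i in range(4)}
        assert compute_pair_correlation(a, b).combined == 0.0

    def test_partial_overlap_hand_value(self):
        # donor 8 ions, acceptor 4, all 4 shared; acceptor RT ranks permuted
        donor = {_ion(i): _obs(rt=float(i), inten=100.0 + i) for i in range(8)}
        acc_rts = {0: 0.0, 1: 1.0, 2: 3.0, 3: 2.0}  # ranks (1,2,4,3)
        acceptor = {_ion(i): _obs(rt=acc_rts[i], inten=100.0 + i) for i in range(4)}
        c = compute_pair_correlation(donor, acceptor)
        assert c.o == 1.0
        assert c.r1 == pytest.approx(0.8)
        assert c.r2 == pytest.approx(1.0)
        assert c.combined == pytest.approx(0.9)


class TestSelectDonors:
    def test_min_corr_filters(self):
        corrs = [
            _corr("d1", "acc", 0.9), _corr("d2", "acc", 0.5),
            _corr("d3", "acc", -0.1),
        ]
        assert select_donor_runs("acc", corrs) == ["d1", "d2"]

    def test_top_n_caps(self):
        corrs = [_corr(f"d{i:02d}", "acc", 0.5 + i * 0.01) for i in range(15)]
        sel = select_donor_runs("acc", corrs, top_n=10)
        assert len(sel) == 10
        assert sel[0] == "d14"

    def test_all_below_threshold(self):
        corrs = [_corr("d1", "acc", -0.5), _corr("d2", "acc", 0.0)]
        assert select_donor_runs("acc", corrs) == []


def _corr(donor, acceptor, combined):
    from mbrquant.transfer import RunPairCorrelation

    return RunPairCorrelation(donor, acceptor, 1.0, combined, combined, None,
                              combined)


def _region_oracle(d, a, t, tau):
    """Brute-force median/MAD region recomputation (independent oracle)."""
    pairs = sorted(zip(d, a))
    ds = [p[0] for p in pairs]
    i = 0
    for j in range(len(ds)):
        if ds[j] <= t:
            i = j
    offs = sorted(p[1] - p[0] for p in pairs if abs(p[0] - ds[i]) <= tau)
    n = len(offs)
    med = (offs[n // 2] if n % 2 else 0.5 * (offs[n // 2 - 1] + offs[n // 2]))
    dev = sorted(abs(o - med) for o in offs)
    mad = (dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2]))
    return ds[i] + med - 2 * mad, ds[i] + med + 2 * mad


class TestRegionLocation:
    def test_perfect_alignment_degenerate(self):
        p = RtPairing(d=[1.0, 2.0, 3.0], a=[1.0, 2.0, 3.0])
        r = locate_rt_region(p, 2.5, tau=1.0)
        assert (r.rt_lo, r.rt_hi) == (2.0, 2.0)
        assert r.m == 0.0 and r.sigma == 0.0

    def test_constant_offset(self):
        p = RtPairing(d=[1.0, 2.0, 3.0], a=[1.3, 2.3, 3.3])
        r = locate_rt_region(p, 2.5, tau=1.0)
        assert r.rt_lo == pytest.approx(2.3)
        assert r.rt_hi == pytest.approx(2.3)

    def test_hand_computed_example(self):
        p = RtPairing(d=[10.0, 10.5, 11.0, 11.5], a=[10.2, 10.6, 11.4, 11.5])
        r = locate_rt_region(p, 10.7, tau=1.0)
        assert r.m == pytest.approx(0.15)
        assert r.sigma == pytest.approx(0.10)
        assert r.rt_lo == pytest.approx(10.45)
        assert r.rt_hi == pytest.approx(10.85)

    def test_empty_pairing_errors(self):
        with pytest.raises(ValueError):
            locate_rt_region(RtPairing(d=[], a=[]), 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_oracle(self, data):
        n = data.draw(st.integers(1, 30))
        d = data.draw(st.lists(
            st.floats(0, 60, allow_nan=False), min_size=n, max_size=n))
        a = data.draw(st.lists(
            st.floats(0, 60, allow_nan=False), min_size=n, max_size=n))
        t = data.draw(st.floats(-5, 65, allow_nan=False))
        r = locate_rt_region(RtPairing(d=d, a=a), t, tau=1.0)
        lo, hi = _region_oracle(d, a, t, 1.0)
        assert r.rt_lo == pytest.approx(lo, abs=1e-9)
        assert r.rt_hi == pytest.approx(hi, abs=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        d = np.sort(rng.uniform(0, 30, 20))
        a = d + rng.normal(0.1, 0.05, 20)
        r0 = locate_rt_region(RtPairing(d=d, a=a), 12.0, tau=1.0)
        delta = 4.2
        r1 = locate_rt_region(RtPairing(d=d + delta, a=a + delta), 12.0 + delta,
                              tau=1.0)
        assert r1.rt_lo - r0.rt_lo == pytest.approx(delta, abs=1e-9)
        assert r1.rt_hi - r0.rt_hi == pytest.approx(delta, abs=1e-9)

    def test_im_region_mirrors_rt(self):
        p = RtPairing(d=[1.00, 1.05, 1.10, 1.15],
                      a=[1.02, 1.06, 1.14, 1.15])
        r = mq.locate_im_region(p, 1.07, window=0.1)
        lo, hi = _region_oracle(p.d, p.a, 1.07, 0.1)
        assert r.rt_lo == pytest.approx(lo, abs=1e-12)
        assert r.rt_hi == pytest.approx(hi, abs=1e-12)


class TestDecoyCandidates:
    def test_first_candidate(self):
        assert decoy_mz_candidates(500.0)[0] == pytest.approx(511.0055)

    def test_full_sequence(self):
        expected = [500 + k * 1.0005 for k in range(11, 3, -1)]
        np.testing.assert_allclose(decoy_mz_candidates(500.0), expected)

    def test_always_eight_descending(self):
        rng = np.random.default_rng(0)
        for mz in rng.uniform(300, 1500, 20):
            c = decoy_mz_candidates(mz)
            assert len(c) == 8
            assert np.all(np.diff(c) < 0)


def _truncated_poisson(lam):
    raw = [math.exp(-lam) * lam ** k / math.factorial(k) for k in range(3)]
    s = sum(raw)
    return [r / s for r in raw]


class TestIsotopeKl:
    def test_zero_at_theoretical_envelope(self):
        mz, z = 700.0, 2
        lam = 4.9384e-4 * (mz - PROTON_MASS) * z
        assert isotope_kl(tuple(_truncated_poisson(lam)), mz, z) \
            == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_direct_summation(self):
        # lambda = 0.5 -> theoretical ~ (0.6154, 0.3077, 0.0769)
        obs = (0.5, 0.3, 0.2)
        mz, z = 0.5 / 4.9384e-4 + PROTON_MASS, 1
        theo = _truncated_poisson(0.5)
        expected = sum(p * math.log(p / q) for p, q in zip(obs, theo))
        assert isotope_kl(obs, mz, z) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_envelope_scores_worse(self):
        mz, z = 1400.0, 2  # large lambda
        lam = 4.9384e-4 * (mz - PROTON_MASS) * z
        good = isotope_kl(tuple(_truncated_poisson(lam)), mz, z)
        bad = isotope_kl((1.0, 0.0, 0.0), mz, z)
        assert bad > good

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            isotope_kl((0.0, 0.0, 0.0), 500.0, 2)


class TestScoreCandidate:
    def _feat(self, inten=1e6, ppm=4.0, kl_perfect=True, mz=700.0, z=2):
        lam = 4.9384e-4 * (mz - PROTON_MASS) * z
        iso = tuple(i * inten for i in _truncated_poisson(lam)) if kl_perfect \
            else (inten, 0.0, 0.0)
        return mq.TracedFeature(mono_mz=mz * (1 + ppm * 1e-6), charge=z,
                                rt_apex=10.0, rt_start=9.8, rt_end=10.2,
                                intensity=inten, isotope_intensities=iso,
                                mass_error_ppm=ppm)

    def test_log_intensity(self):
        s = score_candidate(self._feat(inten=1e6), 700.0, predicted_rt=10.0)
        assert s.log_intensity == pytest.approx(6.0)

    def test_ppm_sqrt(self):
        s = score_candidate(self._feat(ppm=4.0), 700.0, predicted_rt=10.0)
        assert s.abs_ppm_sqrt == pytest.approx(2.0)

    def test_kl_floor_keeps_score_finite(self):
        s = score_candidate(self._feat(kl_perfect=True), 700.0, predicted_rt=10.0)
        # perfect envelope: KL ~ 0 clamps at the 1e-6 floor -> -sqrt(6)
        assert s.log_kl == pytest.approx(-math.sqrt(6.0), abs=0.01)

    def test_zero_intensity_dropped(self):
        f = self._feat()
        f.intensity = 0.0
        assert score_candidate(f, 700.0, predicted_rt=10.0) is None


class TestTransferIon:
    MZ = 600.0

    def _setup(self, plant_target=True, plant_decoy=False):
        ion = mq.IonKey("TRANSFERPEP", "", 2)
        # dense shared-ion pairing so the anchor d_i sits at the donor RT
        grid = np.linspace(4.0, 6.0, 21)
        pairing = RtPairing(d=grid, a=grid)
        peaks = []
        if plant_target:
            for k, w in enumerate((1.0, 0.5, 0.15)):
                peaks.append((self.MZ + k * ISOTOPE_SPACING / 2, 5.0, 0.05,
                              500.0 * w))
        if plant_decoy:
            peaks.append((self.MZ + 11 * 1.0005, 5.0, 0.05, 300.0))
        pm = build_peak_map(run_id="acc", peaks=peaks)
        obs = _obs(rt=5.0, mz=self.MZ)
        return ion, obs, pm, pairing

    def test_planted_signal_transferred(self):
        ion, obs, pm, pairing = self._setup(plant_target=True)
        target, decoy = transfer_ion(ion, obs, "don", pm, pairing, None,
                                     set(), TraceParams())
        assert target is not None and target.ion_type == 1
        assert target.feature.intensity > 0
        assert decoy is None  # nothing planted at shifted m/z

    def test_removed_signal_not_transferred(self):
        ion, obs, pm, pairing = self._setup(plant_target=False)
        target, decoy = transfer_ion(ion, obs, "don", pm, pairing, None,
                                     set(), TraceParams())
        assert target is None and decoy is None

    def test_decoy_traced_alongside_target(self):
        ion, obs, pm, pairing = self._setup(plant_target=True, plant_decoy=True)
        target, decoy = transfer_ion(ion, obs, "don", pm, pairing, None,
                                     set(), TraceParams())
        assert target is not None
        assert decoy is not None and decoy.ion_type == -1
        assert decoy.feature.mono_mz == pytest.approx(self.MZ + 11 * 1.0005,
                                                      rel=1e-5)

    def test_type2_when_acceptor_already_identified(self):
        ion, obs, pm, pairing = self._setup(plant_target=True)
        target, _ = transfer_ion(ion, obs, "don", pm, pairing, None,
                                 {ion}, TraceParams())
        assert target.ion_type == 2


def _cand(ion_seq, mz, rt0, rt1, composite, run="acc"):
    feat = mq.TracedFeature(mono_mz=mz, charge=2, rt_apex=(rt0 + rt1) / 2,
                            rt_start=rt0, rt_end=rt1, intensity=10.0,
                            isotope_intensities=(10.0, 5.0, 1.0),
                            mass_error_ppm=0.0)
    scores = TransferScores(1.0, 0.0, 0.0, 0.0)
    return TransferCandidate(ion=mq.IonKey(ion_seq, "", 2), donor_run="d",
                             acceptor_run=run, ion_type=1, feature=feat,
                             scores=scores, protein_ids=("P",),
                             composite=composite)


class TestDeduplicate:
    def test_same_location_keeps_top_score(self):
        out = deduplicate_transfers([
            _cand("AAA", 500.0, 9.9, 10.1, 3.1),
            _cand("BBB", 500.000001, 9.95, 10.15, 2.0),
        ])
        assert len(out) == 1 and out[0].ion.sequence == "AAA"

    def test_disjoint_locations_both_kept(self):
        out = deduplicate_transfers([
            _cand("AAA", 500.0, 9.9, 10.1, 3.1),
            _cand("BBB", 505.0, 9.9, 10.1, 2.0),          # different m/z
            _cand("CCC", 500.0, 20.0, 20.2, 1.0),          # different RT
        ])
        assert len(out) == 3

    def test_exact_tie_deterministic_by_ion(self):
        out = deduplicate_transfers([
            _cand("ZZZ", 500.0, 9.9, 10.1, 2.0),
            _cand("AAA", 500.0, 9.9, 10.1, 2.0),
        ])
        assert out[0].ion.sequence == "AAA"

    def test_requires_composite(self):
        c = _cand("AAA", 500.0, 9.9, 10.1, 1.0)
        c.composite = None
        with pytest.raises(ValueError):
            deduplicate_transfers([c])
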