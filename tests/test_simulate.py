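"""Synthetic ground truth: peptidome generation, dilution mixing, MS1
rendering, MS2 ion statistics and isobaric interferent construction."""

import numpy as np
import pytest

from acquisim import chem, scoring, simulate, targets as targets_mod
from acquisim.acquire import default_scan_params
from acquisim.simulate import (
    GroundTruthPeptide,
    SampleMixture,
    SignalModel,
    generate_peptidome,
    make_dilution_series,
    ms1_observe,
    read_ground_truth,
    simulate_ms2,
    spike_interferents,
    write_ground_truth,
)


class TestGeneratePeptidome:
    def test_deterministic_given_seed(self):
        a = generate_peptidome(100, seed=3)
        b = generate_peptidome(100, seed=3)
        assert [(p.sequence, p.abundance, p.rt_apex) for p in a] == [
            (p.sequence, p.abundance, p.rt_apex) for p in b
        ]

    def test_sequences_unique_and_lengths_modal_at_nine(self):
        peps = generate_peptidome(10_000, seed=1)
        seqs = [p.sequence for p in peps]
        assert len(set(seqs)) == len(seqs)
        lengths = np.array([len(s) for s in seqs])
        counts = {L: int((lengths == L).sum()) for L in range(8, 15)}
        assert max(counts, key=counts.get) == 9
        assert lengths.min() >= 8 and lengths.max() <= 14

    def test_apexes_inside_gradient(self):
        peps = generate_peptidome(200, seed=2, gradient_min=10.0)
        assert all(0.0 <= p.rt_apex <= 10.0 for p in peps)


class TestDilutionSeries:
    def test_negative_control_has_no_spike(self):
        bg = generate_peptidome(20, seed=1)
        spike = generate_peptidome(5, seed=2, source="spike")
        mixtures = make_dilution_series(bg, spike, [1 / 16, 0.0])
        assert all(p.source == "background" for p in mixtures[1].peptides)
        assert len(mixtures[1].peptides) == 20

    def test_background_identical_across_mixtures(self):
        bg = generate_peptidome(20, seed=1)
        spike = generate_peptidome(5, seed=2, source="spike")
        mixtures = make_dilution_series(bg, spike, simulate.DEFAULT_DILUTION_RATIOS)
        ref = [(p.sequence, p.abundance) for p in mixtures[0].peptides[:20]]
        for mx in mixtures[1:]:
            assert [(p.sequence, p.abundance) for p in mx.peptides[:20]] == ref

    def test_spike_abundance_scales_with_ratio(self):
        bg = generate_peptidome(20, seed=1)
        spike = generate_peptidome(5, seed=2, source="spike")
        m16, m1024 = make_dilution_series(bg, spike, [1 / 16, 1 / 1024])
        a16 = {p.sequence: p.abundance for p in m16.peptides if p.source == "spike"}
        a1024 = {p.sequence: p.abundance for p in m1024.peptides if p.source == "spike"}
        for seq in a16:
            assert a16[seq] / a1024[seq] == pytest.approx(64.0)

    def test_colliding_spike_sequences_dropped_with_warning(self):
        bg = generate_peptidome(20, seed=1)
        clash = GroundTruthPeptide(bg[0].sequence, 1.0, 10.0)
        with pytest.warns(UserWarning):
            mixtures = make_dilution_series(bg, [clash], [1 / 16])
        assert len(mixtures[0].peptides) == 20

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            make_dilution_series(generate_peptidome(2, seed=1), [], [-0.5])


class TestMS1Observe:
    def test_intensity_maximal_at_apex_and_gone_far_away(self):
        p = GroundTruthPeptide("SIINFEKLY", 1.0, 60.0)
        m = SampleMixture([p], 1.0, seed=4)
        model = SignalModel()
        at_apex = ms1_observe(m, 60.0, model, seed=9)
        assert len(at_apex) == 1
        far = ms1_observe(m, 60.0 + 10 * p.rt_sigma, model, seed=9)
        assert far == []
        near = ms1_observe(m, 60.2, model, seed=9)
        assert near[0].intensity < at_apex[0].intensity

    def test_coeluting_peptides_give_two_features(self):
        m = SampleMixture(
            [
                GroundTruthPeptide("SIINFEKLY", 1.0, 60.0),
                GroundTruthPeptide("KLDEVTNFAR", 2.0, 60.0),
            ],
            1.0,
            seed=4,
        )
        assert len(ms1_observe(m, 60.0, SignalModel(), seed=9)) == 2

    def test_elution_integral_proportional_to_abundance(self):
        # time-integrated MS1 flux ~ abundance * flux * sigma * sqrt(2 pi)
        model = SignalModel(ms1_noise_floor=1e-9)
        for abundance in (0.5, 2.0):
            p = GroundTruthPeptide("SIINFEKLY", abundance, 60.0)
            m = SampleMixture([p], 1.0, seed=4)
            dt = 0.005
            grid = np.arange(55.0, 65.0, dt)
            integral = sum(
                f.intensity
                for t in grid
                for f in ms1_observe(m, float(t), model, seed=9)
            ) * dt
            expected = (
                abundance * model.ionization_flux * p.rt_sigma * np.sqrt(2 * np.pi)
            )
            assert integral == pytest.approx(expected, rel=0.01)


class TestSimulateMS2:
    def setup_method(self):
        self.model = SignalModel()
        self.params = default_scan_params()

    def test_same_seed_same_arguments_identical(self):
        m = SampleMixture([GroundTruthPeptide("SIINFEKLY", 1.0, 60.0)], 1.0, seed=4)
        mz = chem.precursor_mz(chem.monoisotopic_mass("SIINFEKLY"), 2)
        a = simulate_ms2(mz, 1.2, m, 60.0, self.params["sMS2"], self.model, seed=5)
        b = simulate_ms2(mz, 1.2, m, 60.0, self.params["sMS2"], self.model, seed=5)
        assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)

    def test_wide_window_spectrum_is_chimeric(self):
        # two precursors 1 Th apart: both fragment inside a 3.2 Th window
        seq_a, seq_b = "SIINFEKLY", "LYNFEKIIS"
        m = SampleMixture(
            [
                GroundTruthPeptide(seq_a, 1.0, 60.0, charge_probs=(0, 1, 0)),
                GroundTruthPeptide(seq_b, 1.0, 60.0, charge_probs=(0, 1, 0)),
            ],
            1.0,
            seed=4,
        )
        center = chem.precursor_mz(chem.monoisotopic_mass(seq_a), 2)
        model = SignalModel(ms2_chemical_noise_peaks=0)
        pl = simulate_ms2(center, 3.2, m, 60.0, self.params["dMS2"], model, seed=5)
        observed = set(np.round(pl.mz, 4))
        for seq in (seq_a, seq_b):
            frag_mzs = {
                round(f.mz, 4)
                for f in chem.fragment_mzs(chem.Peptidoform(seq, charge=2), 1)
            }
            assert observed & frag_mzs, f"no fragments of {seq} in the spectrum"

    def test_hms2_collects_more_ions_than_sms2(self):
        m = SampleMixture([GroundTruthPeptide("SIINFEKLY", 0.001, 60.0)], 1.0, seed=4)
        mz = chem.precursor_mz(chem.monoisotopic_mass("SIINFEKLY"), 2)
        model = SignalModel(ms2_chemical_noise_peaks=0)
        totals = {}
        for name in ("sMS2", "hMS2"):
            totals[name] = np.mean(
                [
                    simulate_ms2(
                        mz, 1.2, m, 60.0, self.params[name], model, seed=s
                    ).intensity.sum()
                    for s in range(50)
                ]
            )
        assert totals["hMS2"] > 2 * totals["sMS2"]

    def test_hms2_self_match_xcorr_beats_sms2(self):
        # the mechanism behind the sensitivity gain of triggered scans
        seq = "KLDEVTNFAR"
        m = SampleMixture([GroundTruthPeptide(seq, 0.001, 60.0)], 1.0, seed=7)
        mz = chem.precursor_mz(chem.monoisotopic_mass(seq), 2)
        p = chem.Peptidoform(seq, charge=2)
        medians = {}
        for name in ("sMS2", "hMS2"):
            xs = [
                scoring.xcorr(
                    p,
                    scoring.xcorr_preprocess(
                        scoring.bin_spectrum(
                            simulate_ms2(
                                mz, 1.2, m, 60.0, self.params[name], self.model, seed=s
                            )
                        )
                    ),
                )
                for s in range(200)
            ]
            medians[name] = float(np.median(xs))
        assert medians["hMS2"] > medians["sMS2"]

    def test_empty_window_yields_noise_only_spectrum(self):
        m = SampleMixture([], 1.0, seed=4)
        pl = simulate_ms2(500.0, 1.2, m, 60.0, self.params["sMS2"], self.model, seed=5)
        assert len(pl) == self.model.ms2_chemical_noise_peaks


class TestSpikeInterferents:
    def make_sil(self, seqs, z=2):
        ts = [targets_mod.TargetPeptide(s, rt_pred=50.0) for s in seqs]
        return targets_mod.schedule(ts, charges=(z,), halfwidth_min=15.0)

    def test_zero_per_target_is_identity(self):
        m = SampleMixture(generate_peptidome(10, seed=1), 1.0, seed=2)
        sil = self.make_sil(["SIINFEKLY"])
        assert spike_interferents(m, sil, 0) is m

    def test_interferents_are_isobaric_nontargets_in_window(self):
        m = SampleMixture(generate_peptidome(10, seed=1), 1.0, seed=2)
        seqs = ["SIINFEKLY", "KLDEVTNFAR"]
        sil = self.make_sil(seqs)
        out = spike_interferents(m, sil, 2, tol_ppm=10.0, seed=3)
        added = [p for p in out.peptides if p.source == "interferent"]
        assert len(added) == 2 * len([e for e in sil.entries if not e.mods])
        entry_mzs = [e.mz for e in sil.entries]
        for p in added:
            assert p.sequence not in seqs
            mz = chem.precursor_mz(chem.monoisotopic_mass(p.sequence), 2)
            assert min(abs(mz - emz) / emz * 1e6 for emz in entry_mzs) <= 10.0
            assert 35.0 <= p.rt_apex <= 65.0
            assert p.charge_probs == (0.0, 1.0, 0.0)

    def test_determinism(self):
        m = SampleMixture(generate_peptidome(10, seed=1), 1.0, seed=2)
        sil = self.make_sil(["SIINFEKLY"])
        a = spike_interferents(m, sil, 1, seed=3)
        b = spike_interferents(m, sil, 1, seed=3)
        assert [p.sequence for p in a.peptides] == [p.sequence for p in b.peptides]


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path):
        m = SampleMixture(generate_peptidome(15, seed=1), 1 / 16, seed=2)
        path = tmp_path / "gt.tsv"
        write_ground_truth(m, path)
        back = read_ground_truth(path, ratio=1 / 16, seed=2)
        assert [
            (p.sequence, p.abundance, p.rt_apex, p.charge_probs, p.is_target)
            for p in back.peptides
        ] == [
            (p.sequence, p.abundance, p.rt_apex, p.charge_probs, p.is_target)
            for p in m.peptides
        ]
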