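"""Offline search: decoy generation, chimeric candidate lookup, target-decoy
FDR against a brute-force oracle, TID classification and the co-isolated
mass-difference analysis."""

import itertools
import math

import numpy as np
import pytest

from acquisim import acquire, chem, identify, simulate
from acquisim.acquire import MethodConfig, run_acquisition
from acquisim.identify import (
    PSM,
    SearchConfig,
    build_search_db,
    classify_tids,
    fdr_filter,
    generate_decoys,
    mass_diff_analysis,
    peptide_fdr,
    search_scanlog,
)
from acquisim.scoring import PSMScore
from acquisim.simulate import GroundTruthPeptide, SampleMixture, SignalModel


def make_psm(hyperscore, is_decoy, tag):
    return PSM(
        scan_id=0,
        scan_type="dMS2",
        peptidoform=chem.Peptidoform("ACDEFGHK"[: 8], charge=2),
        score=PSMScore(hyperscore=hyperscore),
        is_decoy=is_decoy,
        isolation_status="isolated",
        group_mz=500.0 + tag,  # unused; keeps objects distinct
    )


def brute_force_accepted(scores, level):
    """Oracle: walk every score cutoff, accept the largest prefix with
    (D+1)/T <= level, with q-values as the monotone minimum from the bottom."""
    order = sorted(scores, key=lambda s: -s[0])
    fdrs = []
    d = t = 0
    for _, is_decoy in order:
        d += is_decoy
        t += not is_decoy
        fdrs.append((d + 1) / max(t, 1))
    qs = [min(fdrs[i:]) for i in range(len(fdrs))]
    return {
        i for i, ((_, dec), q) in enumerate(zip(order, qs)) if not dec and q <= level
    }


class TestGenerateDecoys:
    def test_full_reversal(self):
        assert generate_decoys(["ACDEFG"]) == ["GFEDCA"]

    def test_palindromes_dropped_and_not_more_decoys_than_targets(self):
        targets = ["AA", "ACDEFG", "GFEDCA"]  # AA palindromic; pair collides
        decoys = generate_decoys(targets)
        assert "AA" not in decoys
        assert len(decoys) <= len(targets)
        assert not set(decoys) & set(targets)


class TestFdrFilter:
    def test_matches_bruteforce_oracle_on_random_lists(self):
        rng = np.random.default_rng(0)
        for level in (0.01, 0.05, 0.2):
            for _ in range(20):
                n = int(rng.integers(1, 200))
                scores = [
                    (float(rng.uniform(0, 20)), bool(rng.random() < 0.3))
                    for _ in range(n)
                ]
                psms = [make_psm(h, d, i) for i, (h, d) in enumerate(scores)]
                accepted = fdr_filter(psms, level)
                got = {p.score.hyperscore for p in accepted}
                order = sorted(scores, key=lambda s: -s[0])
                want_idx = brute_force_accepted(scores, level)
                want = {order[i][0] for i in want_idx}
                assert got == want

    def test_99_targets_above_one_decoy_is_not_enough_at_1_percent(self):
        # (D+1)/T needs >= 100 targets above the first decoy
        psms = [make_psm(10.0 + i, False, i) for i in range(99)]
        psms.append(make_psm(1.0, True, 99))
        assert fdr_filter(psms, 0.01) == []

    def test_100_targets_no_decoys_all_accepted(self):
        psms = [make_psm(10.0 + i, False, i) for i in range(100)]
        assert len(fdr_filter(psms, 0.01)) == 100

    def test_empty_input(self):
        assert fdr_filter([], 0.01) == []

    def test_q_values_written_and_monotone(self):
        psms = [make_psm(float(i), i % 3 == 0, i) for i in range(30)]
        fdr_filter(psms, 0.05)
        ordered = sorted(psms, key=lambda p: -p.score.hyperscore)
        qs = [p.q_value for p in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(0 <= q <= 1 for q in qs)


class TestSearchScanlog:
    def test_noise_only_scanlog_yields_no_accepted_psms(self):
        # decoy-free FDR control: 50 noise scans give nothing at 1%
        model = SignalModel(gradient_min=2.5)
        mixture = SampleMixture([], 1.0, seed=1)
        log = run_acquisition(mixture, None, MethodConfig("dda"), model, 7)
        # fabricate noise MS2 scans over the empty sample
        rng = np.random.default_rng(5)
        for i in range(50):
            pl = simulate.simulate_ms2(
                400.0 + i, 3.2, mixture, 1.0, acquire.default_scan_params()["dMS2"],
                model, seed=i,
            )
            log.scans.append(
                acquire.ScanRecord(
                    1000 + i, i % len(log.scans), "dMS2", 0.0, 40.0,
                    precursor_mz=400.0 + i, precursor_z=2,
                    isolation_lo=400.0 + i - 1.6, isolation_hi=400.0 + i + 1.6,
                    peaks=pl, provenance="topN",
                )
            )
        cfg = SearchConfig()
        db_seqs = [
            "".join(rng.choice(list(chem.STANDARD_RESIDUES), 9)) for _ in range(150)
        ]
        db = build_search_db(db_seqs, cfg)
        psms = search_scanlog(log, db, cfg)
        assert fdr_filter(psms, 0.01) == []

    def test_chimeric_mode_identifies_coisolated_pair_from_one_scan(self):
        seq_a, seq_b = "SIINFEKLN", "SIINFEKLD"  # N->D: 0.984 Da apart
        m = SampleMixture(
            [
                GroundTruthPeptide(seq_a, 1.0, 1.0, charge_probs=(0, 1, 0)),
                GroundTruthPeptide(seq_b, 1.0, 1.0, charge_probs=(0, 1, 0)),
            ],
            1.0,
            seed=4,
        )
        model = SignalModel(gradient_min=2.0, ms2_chemical_noise_peaks=0)
        log = run_acquisition(m, None, MethodConfig("dda", top_n=2), model, 3)
        cfg_on = SearchConfig(chimeric=True)
        cfg_off = SearchConfig(chimeric=False)
        db = build_search_db([seq_a, seq_b], cfg_on)
        acc_on = fdr_filter(search_scanlog(log, db, cfg_on), 0.5)
        acc_off = fdr_filter(search_scanlog(log, db, cfg_off), 0.5)
        assert {p.sequence for p in acc_on} >= {p.sequence for p in acc_off}
        per_scan: dict = {}
        for p in acc_on:
            per_scan.setdefault(p.scan_id, set()).add(p.sequence)
        assert any(len(v) == 2 for v in per_scan.values())

    def test_narrow_isolated_search_only_uses_isolated_mass(self, spiked_setup):
        mixture, sil, model, _ = spiked_setup
        log = run_acquisition(mixture, sil, MethodConfig("dda"), model, 3)
        cfg = SearchConfig(chimeric=False)
        db = build_search_db(sorted(mixture.sequences), cfg)
        psms = search_scanlog(log, db, cfg)
        assert psms and all(p.isolation_status == "isolated" for p in psms)


class TestPeptideFdr:
    def test_collapses_to_best_psm_per_sequence(self):
        p1 = make_psm(10.0, False, 0)
        p2 = make_psm(12.0, False, 1)  # same sequence, higher score
        out = peptide_fdr([p1, p2], level=1.0)
        assert len(out) == 1 and out[0].score.hyperscore == 12.0


class TestClassifyTids:
    def run_rtsdda(self, spiked_setup):
        mixture, sil, model, targets = spiked_setup
        log = run_acquisition(mixture, sil, MethodConfig("rtsdda"), model, 3)
        cfg = SearchConfig()
        db = build_search_db(sorted(mixture.sequences | targets), cfg)
        accepted = fdr_filter(search_scanlog(log, db, cfg), 0.01)
        return log, accepted, targets

    def test_tids_reference_hit_events_and_target_sequences(self, spiked_setup):
        log, accepted, targets = self.run_rtsdda(spiked_setup)
        tids = classify_tids(log, accepted, targets)
        assert tids, "expected at least one TID in the spiked run"
        events = {e.event_id: e for e in log.events}
        for tid in tids:
            assert tid.sequence in targets
            assert tid.supporting_scan_types <= {"sMS2", "hMS2"}
            assert events[tid.rts_event_id].entry_sequence == tid.sequence

    def test_no_tid_without_accepted_psm(self, spiked_setup):
        log, _, targets = self.run_rtsdda(spiked_setup)
        assert classify_tids(log, [], targets) == []

    def test_discovery_psm_of_target_gives_no_tid(self, spiked_setup):
        mixture, sil, model, targets = spiked_setup
        # DDA log has no RTS events, so even accepted target PSMs yield no TID
        log = run_acquisition(mixture, sil, MethodConfig("dda"), model, 3)
        cfg = SearchConfig()
        db = build_search_db(sorted(mixture.sequences | targets), cfg)
        accepted = fdr_filter(search_scanlog(log, db, cfg), 0.01)
        assert classify_tids(log, accepted, targets) == []


class TestMassDiffAnalysis:
    def coisolated_pair(self, seq_a, seq_b, tag):
        psms = []
        for i, seq in enumerate((seq_a, seq_b)):
            psms.append(
                PSM(
                    scan_id=tag,
                    scan_type="dMS2",
                    peptidoform=chem.Peptidoform(seq, charge=2),
                    score=PSMScore(hyperscore=10.0),
                    is_decoy=False,
                    isolation_status="isolated" if i == 0 else "co_isolated",
                    group_mz=500.0,
                )
            )
        return psms

    def test_gly_to_ala_substitution_residual(self):
        # G -> A adds CH2 = 14.01565 Da: nearest integer 14, residual 0.01565
        psms = self.coisolated_pair("GSIINFEKL", "ASIINFEKL", 1)
        df, frac = mass_diff_analysis(psms)
        assert len(df) == 1
        assert df.nearest_int_da.iloc[0] == 14
        assert df.residual_da.iloc[0] == pytest.approx(0.015650, abs=1e-5)
        assert frac == 1.0

    def test_identical_mass_pair_residual_zero(self):
        psms = self.coisolated_pair("SIINFEKLY", "LYNFEKIIS", 2)
        df, _ = mass_diff_analysis(psms)
        assert df.residual_da.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_no_multi_psm_scans_gives_empty_table(self):
        df, frac = mass_diff_analysis([make_psm(10.0, False, 0)])
        assert df.empty and frac == 0.0

    def test_different_charge_pairs_excluded_from_residuals(self):
        a, b = self.coisolated_pair("GSIINFEKL", "ASIINFEKL", 3)
        b.peptidoform = chem.Peptidoform(b.peptidoform.sequence, charge=3)
        df, frac = mass_diff_analysis([a, b])
        assert df.empty and frac == 0.0
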