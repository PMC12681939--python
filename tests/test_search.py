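"""Morpheus scoring, glycan mass-gap assignment, the score bundle and
target-decoy FDR, with brute-force oracles for the q-value path."""

import numpy as np
import pytest

from igpkit.constants import OXONIUM_NEUAC, PROTON
from igpkit.glycans import GlycanDatabaseEntry, parse_composition
from igpkit.peptides import PeptideEntry, peptide_mass_unmodified
from igpkit.search import (
    CORE_Y_OFFSETS,
    GlycoPSM,
    ScoreBundle,
    score_core_y,
    score_isotope,
    score_morpheus,
    score_oxonium,
    search_glycan_gap,
    search_spectrum,
    target_decoy_fdr,
)
from igpkit.simulate import simulate_spectra
from igpkit.spectra import oxonium_screen, preprocess


def _entry(comp):
    return GlycanDatabaseEntry.from_composition(parse_composition(comp))


class TestMorpheus:
    def test_full_match(self):
        theo = np.arange(10, dtype=float) * 100 + 200
        assert score_morpheus(theo, np.ones(10), theo) == pytest.approx(11.0)

    def test_no_match_is_zero(self):
        theo = np.array([500.0])
        assert score_morpheus(np.array([800.0]), np.array([1.0]), theo) == 0.0
        assert score_morpheus(np.array([]), np.array([]), theo) == 0.0

    def test_half_intensity_four_fragments(self):
        # 4 theoretical fragments all matched; matched peaks carry half
        # of the total intensity -> 4 + 0.5
        theo = np.array([200.0, 300.0, 400.0, 500.0])
        peaks = np.array([200.0, 300.0, 400.0, 500.0, 900.0])
        inten = np.array([1.0, 1.0, 1.0, 1.0, 4.0])
        assert score_morpheus(peaks, inten, theo) == pytest.approx(4.5)

    def test_invariant_under_intensity_scaling(self):
        rng = np.random.default_rng(3)
        theo = np.sort(rng.uniform(200, 1500, 20))
        peaks = np.concatenate([theo[:12], rng.uniform(200, 1500, 30)])
        inten = rng.uniform(1, 100, len(peaks))
        s1 = score_morpheus(peaks, inten, theo)
        s2 = score_morpheus(peaks, inten * 1000.0, theo)
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestGlycanGap:
    DB = [_entry("N2H3F0S0G0"), _entry("N2H8F0S0G0"), _entry("N3H6F1S1G0")]

    def test_exact_construction_hits(self):
        precursor = 2000.0 + 892.317218
        hits = search_glycan_gap(precursor, 2000.0, self.DB, tol_ppm=10.0)
        assert [str(h.composition) for h in hits] == ["N2H3F0S0G0"]

    def test_out_of_tolerance_misses(self):
        # 2892.35 is ~11.3 ppm away from the true glycan-completed mass
        assert search_glycan_gap(2892.35, 2000.0, self.DB, tol_ppm=10.0) == []

    def test_negative_gap_empty(self):
        assert search_glycan_gap(1500.0, 2000.0, self.DB) == []


class TestCoreY:
    PEP_MASS = 1500.0

    def _mzs(self, offsets, z=1):
        return np.array([(self.PEP_MASS + o + z * PROTON) / z for o in offsets])

    def test_all_five_ladder_ions(self):
        mz = self._mzs(CORE_Y_OFFSETS)
        count, inten = score_core_y(mz, np.ones(5), self.PEP_MASS, charge=2)
        assert count == 5
        assert inten == pytest.approx(5.0)

    def test_no_ladder(self):
        count, _ = score_core_y(np.array([300.0]), np.array([1.0]), self.PEP_MASS, 2)
        assert count == 0

    def test_partial_ladder_at_charge_two(self):
        mz = self._mzs(CORE_Y_OFFSETS[:3], z=2)
        count, _ = score_core_y(mz, np.ones(3), self.PEP_MASS, charge=2)
        assert count == 3


class TestOxoniumScore:
    def test_sialylated_glycan_strong_neuac(self):
        mz = np.array([OXONIUM_NEUAC, 800.0])
        inten = np.array([90.0, 10.0])
        score, penalty = score_oxonium(mz, inten, parse_composition("N4H5F0S2G0"))
        assert score == pytest.approx(0.9)
        assert not penalty

    def test_neuac_without_sialylation_penalized(self):
        mz = np.array([OXONIUM_NEUAC])
        _, penalty = score_oxonium(mz, np.ones(1), parse_composition("N2H5F0S0G0"))
        assert penalty

    def test_no_oxonium_zero(self):
        score, _ = score_oxonium(np.array([900.0]), np.ones(1), parse_composition("N2H5F0S0G0"))
        assert score == 0.0


class TestIsotopeScore:
    def test_matching_envelope_is_one(self):
        from igpkit.search import theoretical_isotope_distribution

        mass, charge = 3000.0, 2
        theo = theoretical_isotope_distribution(mass)
        mono = (mass + charge * PROTON) / charge
        env = np.array([[mono + k * 1.00335 / charge, t] for k, t in enumerate(theo)])
        assert score_isotope(env, mass, charge) == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_envelope_is_zero(self):
        mass, charge = 3000.0, 2
        env = np.array([[500.0, 100.0]])  # nowhere near the envelope
        assert score_isotope(env, mass, charge) == 0.0

    def test_missing_envelope_neutral(self):
        assert score_isotope(None, 3000.0, 2) == 0.5


def _psm(score, is_decoy, seq="PEPTIDEK"):
    p = PeptideEntry(
        sequence=seq, protein_ids=("P",), genes=("G",), sequon_offsets=(0,),
        protein_sites=(1,), n_missed=0, neutral_mass=peptide_mass_unmodified(seq),
        is_decoy=is_decoy,
    )
    return GlycoPSM(
        scan_id=f"s{score}", peptide=p, glycan=_entry("N2H5F0S0G0"), site=1,
        scores=ScoreBundle(morpheus=score), is_decoy=is_decoy,
    )


def _brute_force_q(scores_decoy):
    """Oracle: rank-wise decoy/target ratio, then cumulative min from the
    bottom of the ranked list."""
    ranked = sorted(scores_decoy, key=lambda t: -t[0])
    fdrs = []
    nd = nt = 0
    for _, d in ranked:
        nd += d
        nt += not d
        fdrs.append(nd / max(1, nt))
    qs = []
    running = 1.0
    for f in reversed(fdrs):
        running = min(running, f)
        qs.append(running)
    return list(reversed(qs))


class TestTargetDecoyFDR:
    def test_targets_above_single_decoy_all_retained(self):
        psms = [_psm(s, False) for s in (10, 9, 8, 7)] + [_psm(1, True)]
        out = target_decoy_fdr(psms)
        retained = [p for p in out if p.retained]
        assert len(retained) == 4
        assert all(p.q_value == 0.0 for p in retained)

    def test_alternating_matches_oracle(self):
        seq = [(10, False), (9, True), (8, False), (7, True), (6, False), (5, True)]
        psms = [_psm(s, d) for s, d in seq]
        out = target_decoy_fdr(psms)
        expected = _brute_force_q(seq)
        got = [p.q_value for p in sorted(out, key=lambda p: -p.scores.morpheus)]
        assert got == pytest.approx(expected)

    def test_all_decoys_nothing_retained(self):
        psms = [_psm(s, True) for s in (10, 9, 8)]
        out = target_decoy_fdr(psms)
        assert not any(p.retained for p in out)

    def test_q_values_monotone_and_match_threshold_selection(self, rng):
        seq = [(float(s), bool(d)) for s, d in zip(rng.uniform(0, 100, 60), rng.random(60) < 0.4)]
        psms = [_psm(s, d) for s, d in seq]
        out = sorted(target_decoy_fdr(psms), key=lambda p: -p.scores.morpheus)
        qs = [p.q_value for p in out]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))
        for tau in (0.05, 0.2, 0.5):
            selected = {p.scan_id for p in out if not p.is_decoy and p.q_value < tau}
            oracle_q = _brute_force_q(seq)
            oracle = {
                p.scan_id
                for p, q in zip(out, oracle_q)
                if not p.is_decoy and q < tau
            }
            assert selected == oracle

    def test_decoys_never_retained(self, rng):
        psms = [_psm(float(s), bool(d)) for s, d in zip(rng.uniform(0, 10, 40), rng.random(40) < 0.5)]
        out = target_decoy_fdr(psms, threshold=0.5)
        assert not any(p.retained and p.is_decoy for p in out)


class TestSearchSpectrum:
    def test_planted_pair_recovered(self, small_proteome, glycan_db, search_index):
        spectra, truth = simulate_spectra(
            small_proteome, glycan_db, n_true=20, n_noise=0, noise_level=0.0, seed=31
        )
        recovered = 0
        for s in spectra:
            s2 = preprocess(s)
            assert oxonium_screen(s2)
            psm = search_spectrum(s2, search_index, glycan_db)
            if psm is None:
                continue
            row = truth.table.loc[s.scan_id]
            if psm.peptide.sequence == row["peptide"] and str(psm.glycan.composition) == row["glycan"]:
                recovered += 1
        assert recovered >= 19

    def test_pure_noise_returns_none(self, search_index, glycan_db, rng):
        from igpkit.spectra import FragmentSpectrum

        s = FragmentSpectrum(
            "noise", 900.0, 2, np.sort(rng.uniform(200, 1700, 80)), rng.uniform(1, 10, 80)
        )
        assert search_spectrum(s, search_index, glycan_db) is None

    def test_gap_not_in_db_returns_none(self, small_proteome, glycan_db, search_index):
        spectra, _ = simulate_spectra(
            small_proteome, glycan_db, n_true=3, n_noise=0, noise_level=0.0, seed=32
        )
        s = preprocess(spectra[0])
        # empty glycan database: the peptide matches but no glycan can
        assert search_spectrum(s, search_index, []) is None
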