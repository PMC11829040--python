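"""Synthetic-data generator: determinism, distributions, end-to-end recovery."""

import numpy as np
import pytest
from scipy import stats

from hydramass.chem import parse_formula
from hydramass.ladder import conversion_ladder, infer_nonreactive_sites, match_peaks, theoretical_peaks
from hydramass.registry import (
    DoseResponseParams,
    NucleosideSpec,
    ReactionRule,
    TreatmentCondition,
    load_registry,
)
from hydramass.simulate import (
    DegradingConditionError,
    InstrumentProfile,
    degradation_flag,
    simulate_calibration,
    simulate_concentration_series,
    simulate_peaklist,
    simulate_treatment,
    stage_rng,
)

from conftest import as_fragment


def hot_registry(ec50=5.0, hill=3.0):
    """Registry whose uridine rule converts almost fully at 30% hydrazine."""
    reg = load_registry()
    reg.register(
        NucleosideSpec("U", "uridine", parse_formula("C9H12N2O6")),
        [
            ReactionRule(
                reactant="U",
                product="urea-ribose",
                delta=parse_formula("C-3O-1"),
                mechanism="C6-pyrazolone-loss",
                dose_response=DoseResponseParams(ec50=ec50, hill=hill),
            )
        ],
        overwrite=True,
    )
    return reg


class TestTreatment:
    def test_no_hydrazine_leaves_everything_unreacted(self, registry):
        frag = as_fragment("AUCUG", registry)
        counts = simulate_treatment(
            frag, registry, TreatmentCondition(0.0), 500, stage_rng(0, "t")
        )
        assert sum(counts.values()) == 500
        assert counts[next(sp for sp in counts if sp.k == 0)] == 500

    def test_full_conversion_gives_single_species(self):
        reg = hot_registry(ec50=0.01, hill=6.0)  # p ~ 1 at 30%
        frag = as_fragment("AUCUG", reg)
        counts = simulate_treatment(
            frag, reg, TreatmentCondition(30.0), 500, stage_rng(0, "t")
        )
        kmax = max(sp.k for sp in counts)
        assert counts[next(sp for sp in counts if sp.k == kmax)] == 500

    def test_determinism_identical_seeds_identical_counts(self, registry):
        frag = as_fragment("AUCUGUU", registry)
        kwargs = dict(condition=TreatmentCondition(50.0), n_molecules=2000)
        a = simulate_treatment(frag, registry, rng=stage_rng(9, "t"), **kwargs)
        b = simulate_treatment(frag, registry, rng=stage_rng(9, "t"), **kwargs)
        assert {sp.k: n for sp, n in a.items()} == {sp.k: n for sp, n in b.items()}

    def test_conversion_counts_follow_binomial(self):
        """Chi-square goodness of fit of per-molecule conversion counts."""
        reg = hot_registry(ec50=30.0, hill=1.0)  # p = 0.5 at 30%
        seq = "U" * 16
        frag = as_fragment(seq, reg)
        n = 10_000
        counts = simulate_treatment(
            frag, reg, TreatmentCondition(30.0), n, stage_rng(123, "binomial")
        )
        p = reg.reactivity("U", TreatmentCondition(30.0))
        observed = np.zeros(17)
        for sp, cnt in counts.items():
            observed[sp.k] = cnt
        expected = stats.binom.pmf(np.arange(17), 16, p) * n
        # pool sparse tails so every expected bin is >= 5
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        chi2 = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi2.pvalue > 0.01

    def test_mean_conversions_match_25_percent_rate(self):
        """A 16-U molecule at p=0.25 loses 4 residues on average."""
        reg = hot_registry(ec50=30.0 * 3.0 ** (1 / 1.0), hill=1.0)  # p(30)=0.25
        frag = as_fragment("U" * 16, reg)
        counts = simulate_treatment(
            frag, reg, TreatmentCondition(30.0), 10_000, stage_rng(77, "mean")
        )
        p = reg.reactivity("U", TreatmentCondition(30.0))
        assert p == pytest.approx(0.25, abs=1e-12)
        mean_k = sum(sp.k * n for sp, n in counts.items()) / 10_000
        assert mean_k == pytest.approx(4.0, abs=0.15)

    def test_degrading_condition_refused(self, registry):
        frag = as_fragment("AUG", registry)
        with pytest.raises(DegradingConditionError):
            simulate_treatment(
                frag, registry, TreatmentCondition(30.0, 50.0, 1.0), 10, stage_rng(0, "t")
            )


class TestPeaklist:
    def counts(self, registry, text="AUCUG", conc=30.0, n=1000, seed=0):
        frag = as_fragment(text, registry)
        return simulate_treatment(
            frag, registry, TreatmentCondition(conc), n, stage_rng(seed, "treat")
        )

    def test_zero_jitter_reproduces_theoretical_mz(self, registry):
        counts = self.counts(registry)
        quiet = InstrumentProfile(ppm_sigma=0.0, noise_peak_rate=0.0)
        peaks = simulate_peaklist(counts, quiet, stage_rng(1, "pk"), charges=(1,))
        theo = sorted(
            p.mz
            for p in theoretical_peaks([sp for sp, n in counts.items() if n > 0], charges=(1,))
        )
        assert [p.mz for p in peaks] == pytest.approx(theo, abs=1e-9)

    def test_five_ppm_jitter_keeps_95_percent_within_10_ppm(self):
        reg = hot_registry()
        frag = as_fragment("AUUUUUUG", reg)
        hits = within = 0
        for seed in range(30):
            counts = simulate_treatment(
                frag, reg, TreatmentCondition(30.0), 300, stage_rng(seed, "treat")
            )
            peaks = simulate_peaklist(
                counts,
                InstrumentProfile(ppm_sigma=5.0, noise_peak_rate=0.0),
                stage_rng(seed, "pk"),
                charges=(1,),
            )
            ladder = conversion_ladder(frag, reg)
            theo = theoretical_peaks(ladder, charges=(1,))
            result = match_peaks(peaks, theo, tolerance=10.0, unit="ppm")
            hits += len(peaks)
            within += len(result.assignments)
        assert within / hits >= 0.90  # 2-sigma window holds ~95% on average

    def test_maldi_ladder_shows_four_minus_52_peaks(self, registry):
        """A 3-U fragment treated hard gives the k=0..3 MALDI ladder."""
        reg = hot_registry(ec50=30.0, hill=1.0)  # p = 0.5: all states populated
        frag = as_fragment("AUCUCUG", reg)
        counts = simulate_treatment(
            frag, reg, TreatmentCondition(30.0), 4000, stage_rng(4, "treat")
        )
        profile = InstrumentProfile(maldi=True, maldi_da_sigma=0.1, noise_peak_rate=0.0)
        peaks = simulate_peaklist(counts, profile, stage_rng(4, "pk"), charges=(1,))
        assert len(peaks) == 4
        spacings = np.diff(sorted(p.mz for p in peaks))
        assert np.allclose(spacings, 51.99, atol=0.5)

    def test_noise_peaks_are_poisson_added(self, registry):
        counts = self.counts(registry)
        noisy = InstrumentProfile(ppm_sigma=0.0, noise_peak_rate=20.0)
        peaks = simulate_peaklist(counts, noisy, stage_rng(2, "pk"), charges=(1,))
        clean = simulate_peaklist(
            counts,
            InstrumentProfile(ppm_sigma=0.0, noise_peak_rate=0.0),
            stage_rng(2, "pk"),
            charges=(1,),
        )
        assert len(peaks) > len(clean)


class TestCalibrationSim:
    def test_noise_free_series_is_an_exact_line(self):
        series = simulate_calibration("U", stage_rng(0, "cal"), noise=0.0, slope=0.02)
        assert np.allclose(series.responses, 0.02 * series.amounts)

    def test_default_maxima_follow_the_design(self):
        assert simulate_calibration("U", stage_rng(0, "c")).amounts[0] == 100.0
        assert simulate_calibration("Psi", stage_rng(0, "c")).amounts[0] == 20.0
        assert simulate_calibration("D", stage_rng(0, "c")).amounts[0] == 20.0
        assert simulate_calibration("m3C", stage_rng(0, "c")).amounts[0] == 5.0

    def test_fitted_slope_within_three_sigma(self):
        from hydramass.quant import fit_calibration

        slopes = []
        for seed in range(20):
            series = simulate_calibration(
                "U", stage_rng(seed, "cal"), noise=0.05, slope=0.02
            )
            slopes.append(fit_calibration(series).slope)
        assert np.mean(slopes) == pytest.approx(0.02, rel=0.05)


class TestConcentrationSeries:
    def test_control_column_is_exactly_one(self, registry):
        table = simulate_concentration_series(
            ["U", "s4U"], [0.0, 10.0, 50.0], registry, stage_rng(0, "cs")
        )
        assert (table[0.0] == 1.0).all()

    def test_uridine_half_remaining_at_50_percent(self, registry):
        table = simulate_concentration_series(
            ["U"], [0.0, 50.0], registry, stage_rng(1, "cs"), noise=0.0
        )
        assert table.loc["U", 50.0] == pytest.approx(0.5, abs=0.01)

    def test_s4u_nearly_gone_at_10_percent(self, registry):
        table = simulate_concentration_series(
            ["s4U"], [0.0, 10.0], registry, stage_rng(1, "cs"), noise=0.0
        )
        assert table.loc["s4U", 10.0] <= 0.05

    def test_missing_control_rejected(self, registry):
        with pytest.raises(ValueError):
            simulate_concentration_series(["U"], [10.0, 50.0], registry, stage_rng(0, "cs"))


class TestDegradation:
    @pytest.mark.parametrize(
        "condition, expected",
        [
            ((30.0, 0.0, 24.0), (False, "none")),
            ((30.0, 50.0, 1.0), (True, "severe")),
            ((30.0, 20.0, 1.0), (False, "warning")),
            ((30.0, 20.0, 6.0), (True, "degraded")),
            ((30.0, 30.0, 0.5), (True, "degraded")),
            ((30.0, 10.0, 6.0), (False, "none")),
        ],
    )
    def test_flag_table(self, condition, expected):
        assert degradation_flag(TreatmentCondition(*condition)) == expected


class TestEndToEnd:
    def test_simulate_match_infer_recovers_nonreactive_sites(self):
        """simulate -> match -> infer finds the one Psi among three U-like sites."""
        reg = hot_registry()  # p(U, 30%) ~ 0.995
        condition = TreatmentCondition(30.0)
        assert reg.reactivity("U", condition) >= 0.9
        frag = as_fragment("AUC[Psi]CUG", reg)  # u = 3, one never reacts
        successes = 0
        n_runs = 40
        for seed in range(n_runs):
            counts = simulate_treatment(
                frag, reg, condition, 500, stage_rng(seed, "e2e-treat")
            )
            peaks = simulate_peaklist(
                counts,
                InstrumentProfile(ppm_sigma=5.0, noise_peak_rate=2.0),
                stage_rng(seed, "e2e-peaks"),
                charges=(1, 2),
            )
            ladder = conversion_ladder(frag, reg, condition)
            theo = theoretical_peaks(ladder, charges=(1, 2))
            result = match_peaks(peaks, theo, tolerance=20.0, unit="ppm")
            inference = infer_nonreactive_sites(result.assignments, frag, reg, condition)
            if inference.n_nonreactive == 1:
                successes += 1
        assert successes / n_runs >= 0.95
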