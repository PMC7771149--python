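import dataclasses
from collections import Counter

import numpy as np
import pytest
from scipy import stats

import neckteeth as nt
from neckteeth.likelihoods import ordinal_category_probs
from neckteeth.simulate import (
    GeneratorConfig,
    default_defense_truths,
    default_true_params,
    defense_cell_etas,
)


def _zero_re_config(seed=0, mothers=100):
    """Default truths with random-effect scales set to zero, so empirical
    frequencies can be compared to the analytic category probabilities."""
    truths = {
        i: dataclasses.replace(t, sigma_n=0.0, sigma_p=0.0)
        for i, t in default_defense_truths().items()
    }
    return GeneratorConfig(
        mothers_per_treatment=mothers, defense_truths=truths, seed=seed
    )


@pytest.fixture(scope="module")
def big_zero_re_records():
    return nt.simulate_main_experiment(_zero_re_config(mothers=115))


class TestDesignStructure:
    def test_mother_count_without_missing_cell(self):
        config = GeneratorConfig(include_missing_cell=False, seed=1)
        recs = nt.simulate_main_experiment(config)
        assert len({r.mother_uid for r in recs}) == 2 * 4 * 6

    def test_missing_cell_invariant(self, default_records):
        assert not any(
            r.clone == "P5" and r.instar == 1 and r.kairomone and r.uvr
            for r in default_records
        )

    def test_offspring_counts_within_range(self, default_records):
        per_mother = Counter(r.mother_uid for r in default_records if r.instar == 1)
        # instar-1 rows exist for every juvenile of non-dropped cells
        assert all(5 <= n <= 10 for n in per_mother.values())

    def test_determinism(self):
        a = nt.simulate_main_experiment(GeneratorConfig(seed=5))
        b = nt.simulate_main_experiment(GeneratorConfig(seed=5))
        assert a == b
        c = nt.simulate_main_experiment(GeneratorConfig(seed=6))
        assert a != c

    def test_cell_substreams_stable_under_added_mothers(self):
        few = nt.simulate_main_experiment(GeneratorConfig(seed=3, mothers_per_treatment=2))
        more = nt.simulate_main_experiment(GeneratorConfig(seed=3, mothers_per_treatment=3))
        few_keys = {(r.mother_uid, r.instar, r.neckteeth, r.pedestal, r.body_length)
                    for r in few}
        more_keys = {(r.mother_uid, r.instar, r.neckteeth, r.pedestal, r.body_length)
                     for r in more}
        assert few_keys <= more_keys

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(clones=())
        with pytest.raises(ValueError):
            GeneratorConfig(mothers_per_treatment=0)
        with pytest.raises(ValueError):
            GeneratorConfig(uvr_instar2_mortality=1.5)


class TestCalibration:
    def test_uvr_attrition_at_least_half(self, big_zero_re_records):
        i1_uvr = [r for r in big_zero_re_records if r.instar == 1 and r.uvr]
        frac = np.mean([not r.survived_to_instar2 for r in i1_uvr])
        assert len(i1_uvr) > 2000
        assert frac >= 0.50

    def test_no_mortality_without_uvr(self, default_records):
        assert all(
            r.survived_to_instar2 for r in default_records if r.instar == 1 and not r.uvr
        )

    def test_body_length_ranges(self, default_records, big_zero_re_records):
        for recs in (default_records, big_zero_re_records):
            bl1 = [r.body_length for r in recs if r.instar == 1 if r.body_length]
            bl2 = [r.body_length for r in recs if r.instar == 2 if r.body_length]
            assert min(bl1) >= 0.55 and max(bl1) <= 0.80
            assert min(bl2) >= 0.75 and max(bl2) <= 1.00

    def test_all_present_lengths_positive(self, default_records):
        for r in default_records:
            for v in (r.body_length, r.body_width, r.spina_length):
                assert v is None or v > 0

    def test_trait_frequencies_match_analytic_probabilities(self, big_zero_re_records):
        """With zero maternal scales, empirical category/count frequencies
        must match the closed-form model probabilities within 3 MC SE."""
        config = _zero_re_config(mothers=115)
        assert len(big_zero_re_records) >= 10_000
        for instar in (1, 2):
            etas = defense_cell_etas(config, instar)
            tau = config.defense_truths[instar].tau
            for cell in [("UNI", True, False), ("P5", False, False)]:
                eta_n, eta_p = etas[cell]
                sub = [
                    r
                    for r in big_zero_re_records
                    if r.instar == instar
                    and (r.clone, r.kairomone, r.uvr) == cell
                ]
                n = len(sub)
                assert n > 500
                p_teeth = stats.binom.pmf(np.arange(6), 5, stats.logistic.cdf(eta_n))
                counts = Counter(r.neckteeth for r in sub)
                for k in range(6):
                    se = max(np.sqrt(p_teeth[k] * (1 - p_teeth[k]) / n), 1e-4)
                    assert abs(counts[k] / n - p_teeth[k]) < 3.5 * se
                p_ped = ordinal_category_probs(eta_p, tau)
                ped_counts = Counter(r.pedestal for r in sub)
                for ci, cat in enumerate("ABC"):
                    se = max(np.sqrt(p_ped[ci] * (1 - p_ped[ci]) / n), 1e-4)
                    assert abs(ped_counts[cat] / n - p_ped[ci]) < 3.5 * se

    def test_maternal_clustering_icc(self):
        """Positive intraclass correlation with default scales; none with
        scales at zero."""

        def icc(records):
            groups = {}
            for r in records:
                # one clone and one cell, so group differences are maternal only
                if r.clone == "UNI" and r.instar == 2 and r.kairomone and not r.uvr:
                    groups.setdefault(r.mother_uid, []).append(r.neckteeth)
            groups = {k: v for k, v in groups.items() if len(v) >= 3}
            grand = np.concatenate([np.asarray(v, float) for v in groups.values()])
            between = np.var([np.mean(v) for v in groups.values()], ddof=1)
            within = np.mean([np.var(v, ddof=1) for v in groups.values()])
            nbar = np.mean([len(v) for v in groups.values()])
            sb2 = max(between - within / nbar, 0.0)
            return sb2 / (sb2 + within)

        clustered = nt.simulate_main_experiment(GeneratorConfig(seed=2, mothers_per_treatment=60))
        unclustered = nt.simulate_main_experiment(_zero_re_config(seed=2, mothers=60))
        assert icc(clustered) > 0.10
        assert icc(unclustered) < 0.05
        assert icc(clustered) > 3 * icc(unclustered) if icc(unclustered) > 0 else True


class TestQualitativeEffectStructure:
    """The documented true parameters reproduce the reported modal trait
    patterns (checked analytically on the cell probabilities)."""

    def _modal_teeth(self, config, instar, cell):
        eta_n, _ = defense_cell_etas(config, instar)[cell]
        pmf = stats.binom.pmf(np.arange(6), 5, stats.logistic.cdf(eta_n))
        return int(np.argmax(pmf))

    def test_instar1_canalized(self):
        config = GeneratorConfig()
        for clone in ("UNI", "P5"):
            assert self._modal_teeth(config, 1, (clone, False, False)) in (1, 2, 3)
            assert self._modal_teeth(config, 1, (clone, False, True)) in (1, 2, 3)

    def test_instar2_no_kairomone_no_teeth(self):
        config = GeneratorConfig()
        for clone in ("UNI", "P5"):
            assert self._modal_teeth(config, 2, (clone, False, False)) == 0

    def test_instar2_uni_kairomone_induced(self):
        config = GeneratorConfig()
        assert self._modal_teeth(config, 2, ("UNI", True, False)) in (2, 3)

    def test_uvr_suppresses_instar1_pedestal(self):
        config = GeneratorConfig()
        etas = defense_cell_etas(config, 1)
        tau = config.defense_truths[1].tau
        for clone in ("UNI", "P5"):
            p_no_uvr = ordinal_category_probs(etas[(clone, True, False)][1], tau)
            p_uvr = ordinal_category_probs(etas[(clone, True, True)][1], tau)
            assert p_uvr[2] < p_no_uvr[2]  # large pedestals suppressed
            assert p_uvr[0] > p_no_uvr[0]

    def test_default_true_params_validates_instar(self):
        with pytest.raises(ValueError):
            default_true_params(3)


class TestEffectivity:
    def test_design_counts(self, default_effectivity):
        assert len(default_effectivity) == 120
        cells = Counter((r.treatment, r.exposure_hours) for r in default_effectivity)
        assert len(cells) == 12
        assert set(cells.values()) == {10}

    def test_two_mothers_per_cell(self, default_effectivity):
        mothers = Counter(
            (r.treatment, r.exposure_hours, r.mother_uid) for r in default_effectivity
        )
        per_cell = Counter((t, h) for t, h, _ in mothers)
        assert set(per_cell.values()) == {2}

    def test_determinism(self):
        a = nt.simulate_effectivity_experiment(GeneratorConfig(seed=4))
        b = nt.simulate_effectivity_experiment(GeneratorConfig(seed=4))
        assert a == b

    def test_kairomone_treatments_induce_control_does_not(self, default_effectivity):
        teeth = {t: [] for t in ("control", "PAR", "UVR")}
        for r in default_effectivity:
            teeth[r.treatment].append(r.neckteeth)
        assert np.mean(teeth["control"]) < 0.8
        assert np.mean(teeth["PAR"]) > 1.5
        assert np.mean(teeth["UVR"]) > 1.5
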