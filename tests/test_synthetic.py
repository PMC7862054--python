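import numpy as np
import pandas as pd
import pytest

from cytoprof import synthetic as syn
from cytoprof.preprocessing import qc_retain_samples
from cytoprof.repertoire import clonality


def _tiny_config(seed=0, effects=None, **kw):
    cfg = syn.default_config(seed=seed)
    cfg.n_patients_per_arm = {"treated": 4, "control": 4}
    cfg.paired_fraction = {"treated": 1.0, "control": 1.0}
    cfg.n_controls = 2
    cfg.cells_per_sample_mean = 250
    if effects is not None:
        cfg.effects = effects
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = syn.generate_cohort(_tiny_config(seed=7, effects=[]))
        b = syn.generate_cohort(_tiny_config(seed=7, effects=[]))
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        for sid in a.events:
            assert np.array_equal(a.events[sid].values, b.events[sid].values)
        for sid in a.repertoires:
            assert a.repertoires[sid].equals(b.repertoires[sid])

    def test_different_seed_differs(self):
        a = syn.generate_cohort(_tiny_config(seed=1))
        b = syn.generate_cohort(_tiny_config(seed=2))
        sid = next(iter(a.events))
        assert not np.array_equal(a.events[sid].values, b.events[sid].values)


class TestConfigValidation:
    def test_unknown_parent_rejected(self):
        pops = [syn.PopulationSpec("kid", "ghost", 0.5)]
        with pytest.raises(ValueError, match="unknown parent"):
            syn.generate_cohort(_tiny_config(populations=pops))

    def test_cycle_rejected(self):
        pops = [syn.PopulationSpec("a", "b", 0.5),
                syn.PopulationSpec("b", "a", 0.5)]
        with pytest.raises(ValueError, match="cycle"):
            syn.generate_cohort(_tiny_config(populations=pops))

    def test_sibling_fractions_capped(self):
        pops = [syn.PopulationSpec("a", None, 0.7),
                syn.PopulationSpec("b", None, 0.7)]
        with pytest.raises(ValueError, match="sum"):
            syn.generate_cohort(_tiny_config(populations=pops))

    def test_effect_unknown_population_rejected(self):
        eff = [syn.EffectSpec("treated", "ghost", 0.5)]
        with pytest.raises(ValueError, match="unknown population"):
            syn.generate_cohort(_tiny_config(effects=eff))


class TestStudyLayout:
    def test_metadata_counts_match_reference_design(self):
        ds = syn.generate_cohort(
            syn.default_config(seed=0, cells_per_sample_mean=60)
        )
        md = ds.metadata
        pt = md[~md["control"].astype(bool)]
        assert len(pt[(pt.arm == "treated") & (pt.timepoint == "baseline")]) == 40
        assert len(pt[(pt.arm == "control") & (pt.timepoint == "baseline")]) == 45
        assert len(pt[(pt.arm == "treated") & (pt.timepoint == "on_treatment")]) == 31
        assert len(pt[(pt.arm == "control") & (pt.timepoint == "on_treatment")]) == 33
        assert md["control"].astype(bool).sum() == 38
        assert len(md) == 40 + 45 + 31 + 33 + 38

    def test_paired_samples_share_patient(self, small_cohort):
        md = small_cohort.metadata
        pt = md[~md["control"].astype(bool)]
        per_patient = pt.groupby("patient_id")["sample_id"].count()
        assert (per_patient == 2).all()  # fully paired tiny design

    def test_qc_bookkeeping_fixture(self):
        meta = syn.study_qc_metadata()
        assert len(meta) == 201
        report = qc_retain_samples(meta)
        assert len(report.excluded_qc) == 43
        assert len(report.excluded_paired) == 9
        assert len(report.retained) == 149


class TestEventGeneration:
    def test_zero_cells_empty_matrix(self):
        spec = syn.PopulationSpec("p", None, 1.0, {"CD3": 3.0})
        out = syn.sample_population_events(spec, 0, None, 0,
                                           channels=["CD3", "CD8"])
        assert out.shape == (0, 2)

    def test_shift_moves_mean_within_clt_bound(self, rng):
        spec = syn.PopulationSpec("p", None, 1.0, {"CD69": 1.0},
                                  {"CD69": 0.4})
        n = 4000
        out = syn.sample_population_events(spec, n, {"CD69": 1.0}, rng,
                                           channels=["CD69"])
        assert abs(out[:, 0].mean() - 2.0) < 3 * 0.4 / np.sqrt(n)

    def test_no_shift_recovers_locations(self, rng):
        spec = syn.PopulationSpec("p", None, 1.0, {"CD3": 3.0, "CD8": 0.5})
        out = syn.sample_population_events(spec, 5000, None, rng,
                                           channels=["CD3", "CD8"])
        assert np.allclose(out.mean(axis=0), [3.0, 0.5], atol=0.05)

    def test_unknown_shift_channel_rejected(self, rng):
        spec = syn.PopulationSpec("p", None, 1.0)
        with pytest.raises(ValueError, match="unknown channel"):
            syn.sample_population_events(spec, 5, {"nope": 1.0}, rng,
                                         channels=["CD3"])

    def test_sibling_fraction_sums_bounded(self, small_cohort):
        roots = ["T cells", "NK cells", "B cells", "Monocytes"]
        sums = small_cohort.abundances[roots].sum(axis=1)
        assert (sums <= 1 + 1e-9).all()


class TestAbundanceEffectRecovery:
    def test_multiplier_recovered_within_20pct(self):
        """mean(%total on-treatment)/mean(%total baseline) ~ multiplier."""
        cfg = _tiny_config(
            seed=3,
            effects=[syn.EffectSpec("treated", "NK cells", 0.5)],
        )
        cfg.n_patients_per_arm = {"treated": 25, "control": 5}
        cfg.cells_per_sample_mean = 400
        ds = syn.generate_cohort(cfg)
        md = ds.metadata.set_index("sample_id")
        treated = md[(md.arm == "treated") & ~md.control.astype(bool)]
        base = treated[treated.timepoint == "baseline"].index
        post = treated[treated.timepoint == "on_treatment"].index
        ratio = (ds.abundances.loc[post, "NK cells"].mean()
                 / ds.abundances.loc[base, "NK cells"].mean())
        assert 0.4 <= ratio <= 0.6  # 0.5 within +-20% relative

    def test_effects_only_hit_treated_on_treatment(self):
        cfg = _tiny_config(seed=9)
        ds = syn.generate_cohort(cfg)
        md = ds.metadata.set_index("sample_id")
        ctrl = md[(md.arm == "control") & ~md.control.astype(bool)]
        base = ctrl[ctrl.timepoint == "baseline"].index
        post = ctrl[ctrl.timepoint == "on_treatment"].index
        ratio = (ds.abundances.loc[post, "NK cells"].mean()
                 / ds.abundances.loc[base, "NK cells"].mean())
        assert 0.7 < ratio < 1.4  # no spiked depletion in the control arm

    def test_truth_records_every_effect(self, small_cohort):
        assert len(small_cohort.truth["effects"]) == len(syn.default_effects())


class TestRepertoireGeneration:
    def test_uniform_limit(self, rng):
        r = syn.generate_repertoire(200, 0.0, 50_000, rng)
        assert clonality(r) < 0.02

    def test_single_clone(self, rng):
        r = syn.generate_repertoire(1, 1.0, 100, rng)
        assert len(r) == 1 and r.sum() == 100

    def test_counts_sum_to_total(self, rng):
        r = syn.generate_repertoire(50, 0.8, 5000, rng)
        assert r.sum() == 5000

    def test_clonality_monotone_in_strength(self):
        r = np.random.default_rng(0)
        med = []
        for s in (0.0, 0.5, 1.0):
            med.append(np.median([
                clonality(syn.generate_repertoire(300, s, 10_000, r))
                for _ in range(50)
            ]))
        assert med[0] < med[1] < med[2]


class TestExpressionGeneration:
    def _config(self, **kw):
        return syn.ExpressionConfig(
            n_genes=8,
            abundance_linked_genes={"NKG1": "NK"},
            treatment_shift_genes={},
            housekeeping_genes=("HK1",),
            **kw,
        )

    def test_proportionality_without_noise(self):
        cfg = self._config(noise_sd=0.0)
        ab = pd.DataFrame({"NK": [0.1, 0.2]}, index=["s1", "s2"])
        counts = syn.generate_expression_counts(ab, cfg, 0)
        assert counts.loc["NKG1", "s2"] == pytest.approx(
            2 * counts.loc["NKG1", "s1"]
        )

    def test_zero_abundance_floors(self):
        cfg = self._config(noise_sd=0.0)
        ab = pd.DataFrame({"NK": [0.0]}, index=["s1"])
        counts = syn.generate_expression_counts(ab, cfg, 0)
        assert counts.loc["NKG1", "s1"] == cfg.floor_count

    def test_unlinked_gene_uncorrelated(self):
        r = np.random.default_rng(4)
        cfg = self._config(noise_sd=0.1)
        ab = pd.DataFrame({"NK": r.uniform(0.05, 0.3, 100)},
                          index=[f"s{i}" for i in range(100)])
        counts = syn.generate_expression_counts(ab, cfg, r)
        rho = np.corrcoef(counts.loc["G0001"], ab["NK"])[0, 1]
        assert abs(rho) < 0.25  # ~2.5 sigma under independence at n=100

    def test_unknown_population_rejected(self):
        cfg = self._config()
        ab = pd.DataFrame({"B": [0.1]}, index=["s1"])
        with pytest.raises(ValueError, match="unknown population"):
            syn.generate_expression_counts(ab, cfg, 0)
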