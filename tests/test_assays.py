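"""Assay arithmetic, temperature normalisation, composition budget."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planergy.assays import (BeadAssay, cells_from_h3,
                             cells_from_image_counts, ingested_energy,
                             q10_adjust, build_mass_budget,
                             allometry_contributions, predict_cell_number,
                             AssayError)
from planergy.powerlaw import PowerLawResults
from planergy.synth import GeneratorConfig, gen_composition
from dataclasses import replace

pos = st.floats(1e-3, 1e6, allow_nan=False, allow_infinity=False)


class TestCellCounting:
    def test_h3_formula(self):
        assert cells_from_h3(30000, 10, 300) == pytest.approx(9e5)

    def test_h3_whole_lysate_is_identity(self):
        assert cells_from_h3(12345, 250, 250) == pytest.approx(12345)

    def test_image_count_formula(self):
        assert cells_from_image_counts(500, 50, 1.3e6) == pytest.approx(1.3e7)

    def test_equal_counts_return_total_beads(self):
        assert cells_from_image_counts(77, 77, 1.3e6) == pytest.approx(1.3e6)

    def test_zero_beads_rejected(self):
        with pytest.raises(AssayError):
            cells_from_image_counts(10, 0, 1e6)

    @settings(max_examples=50, derandomize=True)
    @given(c=pos, v=pos, t=pos, s=st.floats(0.1, 10))
    def test_h3_homogeneous_in_numerators(self, c, v, t, s):
        base = cells_from_h3(c, v, t)
        assert cells_from_h3(s * c, v, t) == pytest.approx(s * base, rel=1e-9)
        assert cells_from_h3(c, v, s * t) == pytest.approx(s * base, rel=1e-9)
        assert cells_from_h3(c, s * v, t) == pytest.approx(base / s, rel=1e-9)

    def test_poisson_wells_recover_generating_cell_number(self, rng):
        """Per-animal mean over 10 wells within 3 SEM of the truth."""
        n_true, total_beads = 2e6, 1.3e6
        bead_rate, well_frac = 60.0, None
        well_frac = bead_rate / total_beads
        ests = []
        for _ in range(10):
            beads = rng.poisson(bead_rate)
            cells = rng.poisson(n_true * well_frac)
            if beads > 0:
                ests.append(cells_from_image_counts(cells, beads, total_beads))
        mean, sem = np.mean(ests), np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(mean - n_true) < 3 * sem


class TestFoodIntake:
    def _assay(self, **kw):
        base = dict(red_beads_worm_drop=650.0, red_beads_liver_drop=2600.0,
                    green_beads_drop=300.0, green_beads_reference=300.0,
                    macerate_volume_ul=1000.0,
                    liver_macerate_volume_ul=500.0, liver_volume_basis_ul=2.0)
        base.update(kw)
        return BeadAssay(**base)

    def test_constructed_to_cancel(self):
        """650 red/ul worm-drop against 6.5e5 red/ul liver with a 1000 ul
        macerate is exactly 1 ul eaten, i.e. 6.15 J."""
        vol, energy = ingested_energy(self._assay())
        assert vol == pytest.approx(1.0)
        assert energy == pytest.approx(6.15)

    def test_green_normalisation_unity_is_noop(self):
        a = self._assay(green_beads_drop=123.0, green_beads_reference=123.0)
        b = self._assay()
        assert ingested_energy(a)[0] == pytest.approx(ingested_energy(b)[0])

    def test_green_normalisation_corrects_drop_volume(self):
        # 10% oversized drop inflates red and green counts together
        a = self._assay(red_beads_worm_drop=715.0, green_beads_drop=330.0)
        assert ingested_energy(a)[0] == pytest.approx(1.0)

    def test_energy_density_override(self):
        _, e = ingested_energy(self._assay(), liver_energy_density=1.0)
        assert e == pytest.approx(1.0)

    def test_poisson_counts_keep_relative_error_small(self, rng):
        """Summing counts over the protocol's 10 wells (every expected
        count >= 3000) keeps the volume error below 5% for ~90% of draws."""
        errs = []
        for _ in range(200):
            a = self._assay(
                red_beads_worm_drop=float(rng.poisson(6500)) / 10.0,
                red_beads_liver_drop=float(rng.poisson(26000)) / 10.0,
                green_beads_drop=float(rng.poisson(3000)) / 10.0,
                green_beads_reference=float(rng.poisson(3000)) / 10.0)
            errs.append(abs(ingested_energy(a)[0] - 1.0))
        assert np.quantile(errs, 0.9) < 0.05

    @settings(max_examples=50, derandomize=True)
    @given(s=st.floats(0.1, 10))
    def test_volume_homogeneous_in_worm_counts(self, s):
        v0 = ingested_energy(self._assay())[0]
        v1 = ingested_energy(self._assay(red_beads_worm_drop=650.0 * s))[0]
        assert v1 == pytest.approx(s * v0, rel=1e-9)


class TestQ10:
    def test_conversion_factor_20_to_25(self):
        assert q10_adjust(1.0, 20.0, 25.0) == pytest.approx(2 ** 0.5)

    def test_identity_and_involution(self):
        assert q10_adjust(3.7, 25.0, 25.0) == pytest.approx(3.7)
        assert q10_adjust(q10_adjust(3.7, 20, 37), 37, 20) == pytest.approx(3.7)

    def test_composes_multiplicatively(self):
        direct = q10_adjust(1.0, 20.0, 37.0)
        stepped = q10_adjust(q10_adjust(1.0, 20.0, 25.0), 25.0, 37.0)
        assert stepped == pytest.approx(direct)


def _budget_frame():
    import pandas as pd

    rows = []
    vals = {"TG": {4: 1.0, 16: 4.0}, "protein": {4: 3.0, 16: 4.0},
            "total_dry_mass": {4: 4.0, 16: 8.0}}
    for comp, per in vals.items():
        for sc, v in per.items():
            rows.append({"size_class_mm": float(sc), "component": comp,
                         "replicate_id": "r0", "mass_per_cell_pg": v})
    return pd.DataFrame(rows)


class TestMassBudget:
    def test_mass_conservation_and_residual(self):
        b = build_mass_budget(_budget_frame())
        for sc in b.size_classes:
            total = sum(b.per_cell[c][sc] for c in b.components)
            assert total + b.residual_other[sc] == pytest.approx(
                b.total_per_cell[sc])
        assert b.residual_other[4.0] == pytest.approx(0.0)

    def test_single_component_equal_to_total_zero_residual(self):
        import pandas as pd

        df = pd.DataFrame([
            {"size_class_mm": 4.0, "component": "TG", "replicate_id": "r0",
             "mass_per_cell_pg": 5.0},
            {"size_class_mm": 4.0, "component": "total_dry_mass",
             "replicate_id": "r0", "mass_per_cell_pg": 5.0}])
        b = build_mass_budget(df)
        assert b.residual_other[4.0] == pytest.approx(0.0)

    def test_missing_total_rejected(self):
        df = _budget_frame()
        df = df[df["component"] != "total_dry_mass"]
        with pytest.raises(AssayError, match="total_dry_mass"):
            build_mass_budget(df)

    def test_contribution_shares(self):
        out = allometry_contributions(build_mass_budget(_budget_frame()))
        assert out["share"]["TG"] == pytest.approx(0.75)
        assert out["share"]["protein"] == pytest.approx(0.25)
        assert sum(out["share"].values()) == pytest.approx(1.0)

    def test_constant_component_has_zero_share(self):
        df = _budget_frame()
        df.loc[df["component"] == "protein", "mass_per_cell_pg"] = 3.0
        out = allometry_contributions(build_mass_budget(df))
        assert out["share"]["protein"] == pytest.approx(0.0)

    def test_generator_folds_recovered_noiselessly(self, noiseless_cfg):
        """Configured TG (88x) and glycogen (8.8x) folds survive the
        per-animal -> per-cell normalisation exactly when noise is off."""
        cfg = noiseless_cfg
        comp = gen_composition(cfg, n_replicates=2)
        b = build_mass_budget(comp, cfg.n_vs_area(), cfg.length_area())
        assert b.fold_change("TG") == pytest.approx(88.0, rel=1e-9)
        assert b.fold_change("glycogen") == pytest.approx(8.8, rel=1e-9)
        assert not b.flags

    def test_noisy_shares_recover_generator_truth(self, cfg):
        """Seeded replicate noise: per-component shares within 5 points."""
        comp = gen_composition(cfg, n_replicates=5)
        b = build_mass_budget(comp, cfg.n_vs_area(), cfg.length_area())
        got = allometry_contributions(b)["share"]
        truth_b = build_mass_budget(
            gen_composition(replace(cfg, cv_composition=0.0)),
            cfg.n_vs_area(), cfg.length_area())
        truth = allometry_contributions(truth_b)["share"]
        for comp_name, share in truth.items():
            assert got[comp_name] == pytest.approx(share, abs=0.05)


class TestHumanExtrapolation:
    def test_division_example(self):
        # prefactor chosen so P(70 kg) = 80 W; p = 1 pW
        pre = 80.0 / 70.0 ** 0.75
        out = predict_cell_number(70.0, pre, 1.0)
        assert out["cells"] == pytest.approx(8e13)
        assert out["metabolic_rate_W"] == pytest.approx(80.0)

    def test_doubling_rate_halves_cells(self):
        pre = 80.0 / 70.0 ** 0.75
        assert predict_cell_number(70, pre, 2.0)["cells"] == pytest.approx(
            predict_cell_number(70, pre, 1.0)["cells"] / 2)

    def test_per_cell_rate_sweep_spans_reported_interval(self):
        """p in [0.4, 1.3] pW at P(70 kg) = 80 W spans ~6-20 x 10^13."""
        pre = 80.0 / 70.0 ** 0.75
        hi = predict_cell_number(70.0, pre, 0.4)["cells"]
        lo = predict_cell_number(70.0, pre, 1.3)["cells"]
        assert lo == pytest.approx(6.2e13, rel=0.02)
        assert hi == pytest.approx(20e13, rel=0.02)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(AssayError):
            predict_cell_number(-1.0, 1.0, 1.0)
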