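import numpy as np
import pandas as pd
import pytest

from kmdlign.formula_assign import (
    ElementalLimits,
    Formula,
    assign,
    monoisotopic_mass,
    parse_formula,
)
from kmdlign.kendrick import CH2, find_series, gate, transform
from kmdlign.preprocess import preprocess, subtract_blank
from kmdlign.spectra_io import IonMode, STUDY_SOLVENTS
from kmdlign.synthlign import (
    ComponentSpec,
    G_UNIT,
    SyntheticConfig,
    benchmark_library,
    benchmark_spectrum,
    build_library,
    default_components,
    design_polygons,
    expected_counts,
    oligomer,
    recovery_report,
    simulate_blank,
    simulate_dataset,
    simulate_spectrum,
)

SOLVENT = STUDY_SOLVENTS["1:1 MeOH:H2O"]


class TestLibrary:
    def test_condensation_arithmetic(self):
        assert oligomer([G_UNIT, G_UNIT]) == parse_formula("C20H22O5")

    def test_default_formulas_within_limits_and_valence(self):
        limits = ElementalLimits()
        for spec in default_components():
            for f in spec.formulas:
                assert limits.admits(f)
                assert f.h <= 2 * f.c + f.n + 2
                assert (f.h - f.n) % 2 == 0  # even-electron neutral species

    def test_group_mean_dbe_ordering_matches_design(self):
        """Oxygenated S-dimers > G-dimers > N/S classes > reduced series."""
        from kmdlign.formula_assign import dbe

        means = {
            spec.group_label: np.mean([dbe(f) for f in spec.formulas])
            for spec in default_components()
        }
        assert means[2] > means[1] > means[4] > means[3]

    def test_invalid_component_rejected(self):
        bad = ComponentSpec(group_label=9, formulas=(Formula(95, 8, 0, 1, 0),))
        cfg = SyntheticConfig(seed=1, components=(bad,),
                              mz_range=(100.0, 5000.0))
        with pytest.raises(ValueError, match="limits"):
            build_library(cfg)

    def test_out_of_scan_range_rejected(self):
        heavy = ComponentSpec(group_label=9, formulas=(Formula(150, 200, 0, 20, 0),))
        with pytest.raises(ValueError, match="scan range"):
            SyntheticConfig(seed=1, components=(heavy,))

    def test_sulfur_ban_respected(self):
        comps = tuple(c for c in default_components() if c.group_label != 4)
        assert all(f.s == 0 for spec in comps for f in spec.formulas)


class TestSimulateSpectrum:
    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticConfig(seed=5)
        lib = build_library(cfg)
        s1, t1 = simulate_spectrum(lib, SOLVENT, cfg, 77)
        s2, t2 = simulate_spectrum(lib, SOLVENT, cfg, 77)
        np.testing.assert_array_equal(s1.mz, s2.mz)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_slope_inclusion_near_half(self):
        formulas = tuple(benchmark_library(n=500, seed=2))
        comps = (ComponentSpec(group_label=1, formulas=formulas, solvent_slope=0.0),)
        cfg = SyntheticConfig(seed=5, components=comps)
        included = total = 0
        for seed in range(2):
            _, t = simulate_spectrum(comps, SOLVENT, cfg, seed)
            included += int((t["kind"] == "component").sum())
            total += len(formulas)
        assert 0.46 <= included / total <= 0.54

    def test_jitter_tail_calibrated(self):
        """|m/z error| ~ N(0, 0.15 ppm): <=5 of 1e4 draws beyond 4 sigma,
        none beyond 6 sigma."""
        lib = benchmark_library(n=500, seed=11)
        exceed4 = exceed6 = 0
        for seed in range(20):
            s, t = benchmark_spectrum(lib, seed=seed)
            ppm = np.abs(s.mz - t["true_mz"]) / t["true_mz"] * 1e6
            exceed4 += int((ppm > 4 * 0.15).sum())
            exceed6 += int((ppm > 6 * 0.15).sum())
        assert exceed4 <= 5
        assert exceed6 == 0

    def test_truth_joins_by_peak_index(self):
        cfg = SyntheticConfig(seed=8)
        s, t = simulate_spectrum(build_library(cfg), SOLVENT, cfg, 3)
        assert list(t["peak_index"]) == list(range(len(s)))
        np.testing.assert_allclose(
            s.mz, t.sort_values("peak_index")["mz" if "mz" in t else "true_mz"],
            rtol=1e-5,
        )

    def test_series_members_share_exact_kmd_before_jitter(self):
        cfg = SyntheticConfig(seed=4, ppm_sigma=0.0)
        lib = build_library(cfg)
        s, t = simulate_spectrum(lib, STUDY_SOLVENTS["3:1 MeOH:H2O"], cfg, 12)
        comp = t[t["kind"] == "component"]
        pts = transform(s.take(comp["peak_index"].to_numpy()))
        series = find_series(pts, CH2, kmd_tol=1e-6, min_members=3)
        assert series, "no homologous series recovered from a jitter-free run"
        for s_idx in series:
            kmds = [pts[i].kmd for i in s_idx]
            assert max(kmds) - min(kmds) <= 1e-9


class TestBlankSubtractionInteraction:
    def test_blank_is_contaminants_plus_noise(self):
        cfg = SyntheticConfig(seed=3)
        blank = simulate_blank(cfg, 9, SOLVENT)
        assert len(blank) == len(cfg.blank_contaminants) + cfg.noise_peak_count

    def test_subtraction_removes_all_contaminants(self):
        cfg = SyntheticConfig(seed=21)
        ds = simulate_dataset(cfg)
        for label, sample in ds.samples.items():
            out = subtract_blank(sample, ds.blanks[label])
            contaminated = ds.truth[label].query("kind == 'contaminant'")
            removed_mz = set(sample.mz) - set(out.mz)
            for mz in sample.mz[contaminated["peak_index"].to_numpy()]:
                assert mz in removed_mz

    def test_no_contaminants_means_identity_modulo_noise_overlap(self):
        cfg = SyntheticConfig(seed=6, blank_contaminants=())
        lib = build_library(cfg)
        sample, _ = simulate_spectrum(lib, SOLVENT, cfg, 1)
        blank = simulate_blank(cfg, 2, SOLVENT)
        out = subtract_blank(sample, blank)
        assert len(out) == len(sample)


class TestDesignPolygons:
    def test_polygons_capture_own_group_only(self, default_dataset):
        ds = default_dataset
        comps = ds.config.components
        polys = design_polygons(comps)
        label = "3:1 MeOH:H2O"
        sample = ds.samples[label]
        truth = ds.truth[label]
        pts = transform(sample)
        for spec in comps:
            got = gate(pts, polys[spec.group_label], spec.group_label,
                       min_members=0)
            gated = set(got.member_indices)
            mine = set(truth.query("group_label == @spec.group_label")["peak_index"])
            others = set(
                truth.query("kind == 'component' and group_label != @spec.group_label")[
                    "peak_index"
                ]
            )
            assert mine <= gated
            assert not (gated & others)


class TestRecoveryReport:
    def test_perfect_and_zero_recovery_bounds(self):
        truth = pd.DataFrame(
            {
                "peak_index": [0, 1],
                "kind": ["component", "component"],
                "formula": ["C9H10O2", "C20H22O5"],
                "group_label": [1, 1],
                "solvent_label": ["x", "x"],
                "true_mz": [149.06, 341.14],
            }
        )
        perfect = [
            _fa(0, parse_formula("C9H10O2")), _fa(1, parse_formula("C20H22O5"))
        ]
        assert recovery_report(truth, perfect).recovery_rate == 1.0
        assert recovery_report(truth, []).recovery_rate == 0.0

    def test_truth_without_components_rejected(self):
        truth = pd.DataFrame(
            {"peak_index": [0], "kind": ["noise"], "formula": [""],
             "group_label": [-1], "solvent_label": ["x"], "true_mz": [1.0]}
        )
        with pytest.raises(ValueError):
            recovery_report(truth, [])


def _fa(i, formula):
    from kmdlign.formula_assign import FormulaAssignment

    return FormulaAssignment(
        peak_index=i, formula=formula, neutral_mass=0.0, theoretical_mz=0.0,
        error_ppm=0.0, dbe=0.0, h_c=1.0, o_c=0.1, het_class="O2",
    )


class TestEndToEndRangeContainment:
    def test_summaries_contain_designed_component_ranges(self, default_dataset):
        """Pipeline group summaries must bracket the generator's true
        per-group H/C, O/C and DBE spans."""
        from kmdlign.characterize import summarize_group
        from kmdlign.formula_assign import dbe as dbe_of

        ds = default_dataset
        label = "3:1 MeOH:H2O"
        processed = preprocess(ds.samples[label], ds.blanks[label])
        pts = transform(processed)
        report = assign(processed)
        polys = design_polygons(ds.config.components)
        for spec in ds.config.components:
            if spec.solvent_slope < 0:
                continue  # aqueous-favoring group may be sparse here
            got = gate(pts, polys[spec.group_label], spec.group_label)
            summary = summarize_group(got, pts, report.assignments)
            truth_present = ds.truth[label].query(
                "group_label == @spec.group_label"
            )["formula"]
            present = [parse_formula(f) for f in truth_present]
            kept = [
                f for f in present
                if processed.mz.size and np.any(
                    np.isclose(
                        processed.mz,
                        _ion_mz(f), rtol=3e-6,
                    )
                )
            ]
            hcs = [f.h / f.c for f in kept]
            dbes = [dbe_of(f) for f in kept]
            assert summary.h_c_range[0] <= min(hcs) + 1e-9
            assert summary.h_c_range[1] >= max(hcs) - 1e-9
            assert summary.dbe_range[0] <= min(dbes)
            assert summary.dbe_range[1] >= max(dbes)


def _ion_mz(f):
    from kmdlign.formula_assign import ion_mz

    return ion_mz(monoisotopic_mass(f), IonMode.NEGATIVE)
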