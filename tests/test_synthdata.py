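import numpy as np
import pytest

from orrquant import densmodel as dm
from orrquant import geometry as G
from orrquant import synthdata as S


class TestSectionSpecValidation:
    def test_short_section_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            S.generate_section(S.SectionSpec(length_um=200.0))

    def test_bad_calibration_rejected(self):
        with pytest.raises(ValueError, match="px_per_um"):
            S.generate_section(S.SectionSpec(px_per_um=0.0))

    def test_orr_field_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            S.generate_section(S.SectionSpec(orr_field=1.5))

    def test_layer_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            spec = S.SectionSpec(outer_fractions={"OS": 0.5, "IS": 0.5,
                                                  "ONL": 0.5, "OPL": 0.5})
            spec.validate()


class TestGenerateSection:
    def test_constant_field_ground_truth(self):
        spec = S.SectionSpec(length_um=500.0, orr_field=0.5, seed=1)
        _, truth = S.generate_section(spec, render=False)
        assert truth.regions["orr_true"].tolist() == pytest.approx([0.5, 0.5])

    def test_noiseless_density_matches_printed_equation(self):
        # sd 0 at ORr 0.44: 10^(3.21064) ~ 1624 cells/mm, rounded to the
        # nearest whole nucleus over a 250 um region
        spec = S.SectionSpec(length_um=250.0, orr_field=0.44,
                             nuclei_model=S.NucleiModel(residual_sd_db=0.0),
                             seed=1)
        _, truth = S.generate_section(spec, render=False)
        assert truth.regions["onl_per_mm"][0] == pytest.approx(1624.0, abs=2.0)

    def test_seeded_determinism(self):
        spec = S.SectionSpec(length_um=500.0, seed=9)
        img1, t1 = S.generate_section(spec)
        img2, t2 = S.generate_section(spec)
        assert np.array_equal(img1.labels, img2.labels)
        assert np.array_equal(img1.dapi, img2.dapi)
        assert np.array_equal(img1.marker, img2.marker)
        assert np.array_equal(img1.dab, img2.dab)
        assert t1.regions.equals(t2.regions)
        assert t1.nuclei.equals(t2.nuclei)

    def test_rendered_thickness_matches_field(self, treated_section):
        # per-column rendered ORr reproduces the target field within half a
        # pixel of thickness
        images, truth = treated_section
        ppu = images.px_per_um
        outer_ids = [G.LAYER_LABELS[n] for n in G.OUTER_LAYERS]
        cols = np.arange(50, images.labels.shape[1], 97)
        for c in cols:
            col = images.labels[:, c]
            total = (col > 0).sum()
            outer = np.isin(col, outer_ids).sum()
            x = (c + 0.5) / ppu
            t = G.layer_thicknesses(truth.profile, x)
            assert outer / ppu == pytest.approx(t["OR"], abs=1.0 / ppu)
            assert total / ppu == pytest.approx(t["total"], abs=1.0 / ppu)

    def test_nuclei_lie_inside_their_layer_band(self, treated_section):
        _, truth = treated_section
        prof = truth.profile
        band = {"ONL": ("OPL/ONL", "ONL/IS"), "INL": ("IPL/INL", "INL/OPL"),
                "GCL": ("ILM", "GCL/IPL")}
        for _, n in truth.nuclei.iterrows():
            top_name, bot_name = band[n["layer"]]
            d = prof.boundary_depths(n["x_um"]).ravel()
            top = d[G.BOUNDARY_NAMES.index(top_name)]
            bot = d[G.BOUNDARY_NAMES.index(bot_name)]
            assert top <= n["y_um"] <= bot

    def test_control_orr_distribution(self):
        # control regions follow Normal(0.55, 0.05) truncated to [0.39, 0.69]
        vals = []
        for seed in range(12):
            spec = S.SectionSpec(length_um=4000.0, condition="control",
                                 seed=seed)
            _, truth = S.generate_section(spec, render=False)
            vals.extend(truth.regions["orr_true"])
        vals = np.asarray(vals)
        assert vals.min() >= 0.39 and vals.max() <= 0.69
        assert np.mean(vals) == pytest.approx(0.55, abs=0.02)
        assert np.std(vals) == pytest.approx(0.05, abs=0.015)
        _, truth = S.generate_section(
            S.SectionSpec(length_um=1000.0, condition="control", seed=0),
            render=False)
        assert (truth.regions["group_true"] == 0).all()

    def test_treated_group_mixture_counts(self):
        spec = S.SectionSpec(length_um=6000.0, seed=5)  # 24 regions
        _, truth = S.generate_section(spec, render=False)
        counts = truth.regions["group_true"].value_counts()
        mix = np.asarray(S.DEFAULT_GROUP_MIXTURE) * 24
        for g in (1, 2, 3, 4):
            assert abs(counts.get(g, 0) - mix[g - 1]) <= 1  # rounding only

    def test_density_round_trip(self):
        """Regressing generated per-region ONL counts on true ORr recovers
        the dB density model parameters within 2 standard errors."""
        orr, counts = [], []
        for seed in range(6):
            spec = S.SectionSpec(length_um=22_000.0, seed=100 + seed)
            _, truth = S.generate_section(spec, render=False)
            keep = truth.regions["onl_per_mm"] > 0
            orr.extend(truth.regions.loc[keep, "orr_true"])
            counts.extend(truth.regions.loc[keep, "onl_per_mm"])
        assert len(orr) >= 500
        fit = dm.fit_log_linear(orr, counts)
        # standard errors of the OLS coefficients in dB space
        x = np.asarray(orr)
        resid_var = fit.rmse_db**2 * len(x) / (len(x) - 2)
        sxx = np.sum((x - x.mean()) ** 2)
        se_b = np.sqrt(resid_var / sxx)
        se_a = np.sqrt(resid_var * (1 / len(x) + x.mean() ** 2 / sxx))
        assert abs(fit.A - S.DENSITY_A_DB) <= 2 * se_a
        assert abs(fit.B - S.DENSITY_B_DB) <= 2 * se_b


class TestGenerateCortical:
    def test_determinism(self):
        r1, t1 = S.generate_cortical(90.0, seed=4)
        r2, t2 = S.generate_cortical(90.0, seed=4)
        assert r1.table.equals(r2.table)
        assert t1 == t2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            S.generate_cortical(-5.0)
        with pytest.raises(ValueError):
            S.generate_cortical(90.0, n_channels=1)
        with pytest.raises(ValueError):
            S.generate_cortical(90.0, falloff_per_mm=-0.2)
        with pytest.raises(ValueError):
            S.generate_cortical(90.0, slope_ua=-1.0)

    def test_zero_falloff_uniform_map(self):
        resp, truth = S.generate_cortical(90.0, seed=2, falloff_per_mm=0.0,
                                          noise=None)
        assert truth["d_prime"] == 0.0
        hemi = resp.table[resp.table["hemisphere"] == "contra"]
        plateaus = hemi.groupby("channel")["spikes"].max()
        assert plateaus.max() - plateaus.min() < 1e-9

    def test_spike_counts_monotone_in_current(self):
        resp, _ = S.generate_cortical(90.0, seed=2, noise=None)
        for _, sub in resp.table.groupby("channel"):
            assert np.all(np.diff(sub["spikes"]) >= -1e-12)

    def test_battery_truth_table(self):
        responses, truth = S.generate_cortical_battery(
            n_electrodes_per_group=3, seed=0)
        assert len(responses) == 15
        assert set(truth["group"]) == {0, 1, 2, 3, 4}
        means = truth.groupby("group")["threshold_ua"].mean()
        assert means[0] < means[4]
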