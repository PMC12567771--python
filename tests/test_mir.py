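"""MIR forward model: Beer-Lambert arithmetic, scattering baseline, the
flying-spot point response and MTF, raster-refinement consistency and the
FTIR-like box-average modality."""

import numpy as np
import pytest

from mirfluor.gridops import raster_sample, resample_labels_nearest, spot_average
from mirfluor.mir import (
    BandSet,
    LaserLine,
    RasterGrid,
    SpotProfile,
    absorbance_field,
    default_ftir_bands,
    default_mir_bands,
    flying_spot_scan,
    signal_with_scatter,
    simulate_ftir,
    simulate_mir,
)
from mirfluor.phantom import (
    GRAY_MATTER,
    WHITE_MATTER,
    PhantomConfig,
    Phantom,
    default_class_table,
    generate_brain_phantom,
)


def uniform_phantom(chem, size=64, pitch=2.0, scatter=0.0):
    """Hand-built phantom with spatially constant composition (test scaffold)."""
    shape = (size, size)
    cfg = PhantomConfig(width=size, height=size, seed=0)
    return Phantom(
        labels=np.full(shape, 2, dtype=np.int16),
        chem={s: np.full(shape, chem.get(s, 0.0)) for s in ("lipid", "protein", "water")},
        fluor={f: np.zeros(shape) for f in ("collagen_elastin", "flavin", "lipopigment")},
        scatter=np.full(shape, scatter),
        pitch=pitch,
        classes=tuple(default_class_table()),
        config=cfg,
    )


class TestAbsorbance:
    def test_empty_substrate_and_direct_arithmetic(self):
        line = LaserLine("T", 3000.0, "target", {"lipid": 2.0})
        empty = uniform_phantom({})
        assert np.all(absorbance_field(empty, line) == 0.0)
        ph = uniform_phantom({"lipid": 0.25})
        a = absorbance_field(ph, line, thickness=2.0)
        assert np.allclose(a, 1.0)  # ε·c·l = 2·0.25·2

    def test_multispecies_additivity(self, phantom256):
        line = LaserLine("T", 3000.0, "target", {"lipid": 0.03, "protein": 0.02})
        combined = absorbance_field(phantom256, line)
        parts = sum(
            absorbance_field(
                phantom256, LaserLine("T", 3000.0, "target", {sp: eps})
            )
            for sp, eps in line.epsilon.items()
        )
        assert np.allclose(combined, parts, atol=1e-12)

    def test_scatter_baseline_contract(self, phantom256):
        ref = default_mir_bands().get("L1")
        a = np.zeros_like(phantom256.scatter)
        # reference laser over tissue carries only the baseline
        a_eff = signal_with_scatter(a, phantom256.scatter, ref)
        assert np.allclose(a_eff, phantom256.scatter * (0.2 + 1e-4 * ref.wavenumber))
        # no-scatter limit and wavenumber-flat baseline
        chem = absorbance_field(phantom256, default_mir_bands().get("L3"))
        assert np.allclose(
            signal_with_scatter(chem, np.zeros_like(chem), ref), chem
        )
        flat = [
            signal_with_scatter(a, phantom256.scatter, b, b0=0.3, b1=0.0)
            for b in default_mir_bands()
        ]
        assert all(np.array_equal(flat[0], f) for f in flat[1:])


class TestFlyingSpot:
    def test_uniform_field_transduction(self):
        field = np.full((100, 100), 0.7)
        img = flying_spot_scan(field, 2.0, SpotProfile(), RasterGrid(step=20.0),
                               noise_sd=0.0, i_ref=58000.0)
        assert np.allclose(img, 58000.0 * 10 ** (-0.7))

    def test_point_response_1e2_diameter(self):
        # impulse through the spot: 1/e² diameter should match the beam spec
        spot = SpotProfile(diameter_1e2=22.0)
        field = np.zeros((257, 257))
        field[128, 128] = 1.0
        blurred = spot_average(field, 1.0, spot.sigma)
        profile = blurred[128] / blurred[128, 128]
        x = np.arange(257) - 128.0
        above = np.flatnonzero(profile >= np.exp(-2))
        # linear interpolation of the crossing on each side
        lo, hi = above[0], above[-1]
        def crossing(i0, i1):
            y0, y1 = profile[i0], profile[i1]
            return x[i0] + (np.exp(-2) - y0) / (y1 - y0) * (x[i1] - x[i0])
        diameter = crossing(hi, hi + 1) - crossing(lo, lo - 1)
        assert abs(diameter - 22.0) / 22.0 < 0.05

    @pytest.mark.parametrize("f_lpmm", [10.0, 25.0, 50.0])
    def test_gaussian_mtf_closed_form(self, f_lpmm):
        """Low-amplitude sinusoid: modulation attenuates by exp(−2π²σ²f²) ± 2%."""
        spot = SpotProfile(diameter_1e2=22.0)
        pitch, step = 1.0, 5.0
        period = 1000.0 / f_lpmm
        n = int(24 * period)
        x = np.arange(n) * pitch
        field = np.tile(0.3 + 0.01 * np.sin(2 * np.pi * x / period), (16, 1))
        img = flying_spot_scan(field, pitch, spot, RasterGrid(step=step),
                               noise_sd=0.0, i_ref=58000.0)
        recovered = -np.log10(img / 58000.0).mean(axis=0)
        # trim samples near the non-periodic boundary of the smoothing
        margin = int(np.ceil(6 * spot.sigma / step))
        recovered = recovered[margin:-margin]
        xs = (np.arange(recovered.size) + margin) * step
        design = np.column_stack(
            [np.ones_like(xs), np.cos(2 * np.pi * xs / period), np.sin(2 * np.pi * xs / period)]
        )
        coef, *_ = np.linalg.lstsq(design, recovered, rcond=None)
        measured = np.hypot(coef[1], coef[2]) / 0.01
        expected = np.exp(-2 * np.pi**2 * spot.sigma**2 * (f_lpmm / 1000.0) ** 2)
        assert abs(measured - expected) / expected < 0.02

    def test_noiseless_roundtrip_oracle(self, phantom256):
        """Counts → absorbance inverts the scan to the spot-averaged A_eff."""
        from mirfluor.preprocess import normalize_counts, to_absorbance

        line = default_mir_bands().get("L3")
        a_eff = signal_with_scatter(
            absorbance_field(phantom256, line), phantom256.scatter, line
        )
        spot, grid = SpotProfile(), RasterGrid(step=5.0)
        img = flying_spot_scan(a_eff, phantom256.pitch, spot, grid,
                               noise_sd=0.0, i_ref=58000.0)
        rec = to_absorbance(normalize_counts(img, pitch=5.0), 58000.0 / 65535.0)
        expect = raster_sample(
            spot_average(a_eff, phantom256.pitch, spot.sigma), phantom256.pitch, 5.0
        )
        assert np.abs(rec.values - expect).max() < 1e-9

    def test_counts_decrease_with_absorbance(self):
        a = np.linspace(0, 2, 50)[None, :].repeat(8, axis=0)
        img = flying_spot_scan(a, 2.0, SpotProfile(diameter_1e2=1e-6),
                               RasterGrid(step=2.0), noise_sd=0.0, i_ref=58000.0)
        assert np.all(np.diff(img[0]) < 0)

    def test_raster_refinement_consistency(self, phantom256):
        """A 5 µm-step scan decimated 4× equals the 20 µm-step scan."""
        line = default_mir_bands().get("L2")
        a_eff = signal_with_scatter(
            absorbance_field(phantom256, line), phantom256.scatter, line
        )
        fine = flying_spot_scan(a_eff, phantom256.pitch, SpotProfile(),
                                RasterGrid(step=5.0), noise_sd=0.0, i_ref=58000.0)
        coarse = flying_spot_scan(a_eff, phantom256.pitch, SpotProfile(),
                                  RasterGrid(step=20.0), noise_sd=0.0, i_ref=58000.0)
        dec = fine[::4, ::4][: coarse.shape[0], : coarse.shape[1]]
        assert np.allclose(dec, coarse, atol=1e-9)

    def test_invalid_i_ref(self):
        with pytest.raises(ValueError):
            flying_spot_scan(np.zeros((8, 8)), 2.0, SpotProfile(),
                             RasterGrid(step=4.0), i_ref=0.0)


class TestSimulateMIR:
    def test_grid_step_scales_dimensions(self):
        ph = uniform_phantom({"lipid": 0.5}, size=200)  # 400 µm extent
        s5 = simulate_mir(ph, grid=RasterGrid(step=5.0), noise_sd=0.0)
        s20 = simulate_mir(ph, grid=RasterGrid(step=20.0), noise_sd=0.0)
        assert s5.images["L3"].shape[0] == 4 * s20.images["L3"].shape[0]

    def test_reference_laser_on_bare_gold(self):
        ph = uniform_phantom({}, scatter=0.0)
        scan = simulate_mir(ph, grid=RasterGrid(step=20.0), noise_sd=0.0, i_ref=58000.0)
        assert np.allclose(scan.images["L1"], 58000.0)

    def test_white_matter_darker_at_2928(self, phantom256):
        scan = simulate_mir(phantom256, grid=RasterGrid(step=5.0), noise_sd=0.0)
        img = scan.images["L3"]
        lab = resample_labels_nearest(phantom256.labels, phantom256.pitch, 5.0)
        lab = lab[: img.shape[0], : img.shape[1]]
        assert img[lab == WHITE_MATTER].mean() < img[lab == GRAY_MATTER].mean()

    def test_seeded_determinism(self, phantom256):
        s1 = simulate_mir(phantom256, seed=9)
        s2 = simulate_mir(phantom256, seed=9)
        assert all(np.array_equal(s1.images[k], s2.images[k]) for k in s1.images)


class TestSimulateFTIR:
    def test_pitch_scales_pixels(self, phantom256):
        s6 = simulate_ftir(phantom256, pixel_pitch=6.25, noise_sd=0.0)
        s25 = simulate_ftir(phantom256, pixel_pitch=25.0, noise_sd=0.0)
        n6 = s6.images["L3"].shape[0]
        n25 = s25.images["L3"].shape[0]
        assert abs(n6 / n25 - 4.0) <= 0.1
        assert len(s6.images) == 10

    def test_noiseless_constant_region_is_beer_lambert(self):
        ph = uniform_phantom({"lipid": 0.5, "protein": 0.2}, scatter=0.0)
        scan = simulate_ftir(ph, pixel_pitch=6.25, noise_sd=0.0)
        line = default_ftir_bands().get("L3")
        expected = sum(
            eps * ph.chem[s][0, 0] * ph.thickness for s, eps in line.epsilon.items()
        )
        assert np.allclose(scan.images["L3"], expected, atol=1e-12)

    def test_fine_structure_requires_fine_pitch(self):
        # 10 µm bright stripe on empty substrate: fully resolved at 6.25 µm,
        # diluted below 40% coverage at 25 µm → peak contrast ratio > 2
        ph = uniform_phantom({}, size=128, scatter=0.0)
        ph.chem["lipid"][:, 60:65] = 2.0  # 10 µm wide at 2 µm pitch
        s6 = simulate_ftir(ph, pixel_pitch=6.25, noise_sd=0.0)
        s25 = simulate_ftir(ph, pixel_pitch=25.0, noise_sd=0.0)
        assert s6.images["L3"].max() > 2.0 * s25.images["L3"].max()
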