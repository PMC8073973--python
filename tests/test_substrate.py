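"""Slit-pore accessibility, binding-site density and derived porosities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lignosim as ls
from lignosim.substrate import PoreSizeDistribution, SubstrateSpec


def make_psd(*bins):
    w, v = zip(*bins)
    return PoreSizeDistribution(w, v)


def make_spec(psd, radius=12.5e-4, rho_p=0.8, f_cell=0.45, d=0.8, rho_c=1.5):
    return SubstrateSpec(
        radius_cm=radius, rho_p=rho_p, f_cell=f_cell, digestibility=d,
        rho_c_iv=rho_c, psd=psd,
    )


class TestWallCounting:
    @pytest.mark.parametrize(
        "width,volume,expected_surface,expected_volume",
        [
            # pore narrower than the enzyme: inaccessible
            (40.0, 0.5, 0.0, 0.0),
            # wider than two enzyme diameters: both walls, 2 v / w
            (200.0, 0.5, 2 * 0.5 / 2.0e-6, 0.5),
            # between one and two diameters: one wall, v / w
            (80.0, 0.5, 0.5 / 8.0e-7, 0.5),
            # exact boundaries go to the higher-accessibility class
            (51.0, 0.5, 0.5 / 51e-8, 0.5),
            (102.0, 0.5, 2 * 0.5 / 102e-8, 0.5),
        ],
    )
    def test_single_bin(self, width, volume, expected_surface, expected_volume):
        s, v = ls.accessible_surface_from_psd(make_psd((width, volume)))
        assert s == pytest.approx(expected_surface, rel=1e-12)
        assert v == pytest.approx(expected_volume, rel=1e-12)

    def test_additive_over_bins(self):
        """Splitting a bin's volume in half across two PSDs leaves the
        summed surface unchanged."""
        whole, _ = ls.accessible_surface_from_psd(make_psd((150.0, 0.4)))
        half, _ = ls.accessible_surface_from_psd(make_psd((150.0, 0.2)))
        assert whole == pytest.approx(2 * half, rel=1e-12)

    @given(
        extra_width=st.floats(min_value=51.0, max_value=5000.0),
        extra_volume=st.floats(min_value=0.0, max_value=0.5),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_added_volume(self, extra_width, extra_volume):
        """Adding pore volume at any accessible width never decreases the
        surface, site density or initial porosity."""
        base = make_psd((30.0, 0.05), (200.0, 0.3))
        widths = np.sort(np.unique(np.r_[base.widths_angstrom, extra_width]))
        volumes = []
        for w in widths:
            v = base.volumes_cm3_per_g[base.widths_angstrom == w].sum()
            if np.isclose(w, extra_width):
                v += extra_volume
            volumes.append(v)
        grown = PoreSizeDistribution(widths, volumes)
        s0, v0 = ls.accessible_surface_from_psd(base)
        s1, v1 = ls.accessible_surface_from_psd(grown)
        assert s1 >= s0 - 1e-15 and v1 >= v0 - 1e-15
        d0 = ls.derive_substrate(make_spec(base))
        d1 = ls.derive_substrate(make_spec(grown))
        assert d1.site_density >= d0.site_density
        assert d1.eps_0 >= d0.eps_0

    def test_invalid_psd_rejected(self):
        with pytest.raises(ValueError):
            PoreSizeDistribution([-10.0, 50.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            PoreSizeDistribution([50.0, 50.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            PoreSizeDistribution([], [])
        with pytest.raises(ValueError):
            PoreSizeDistribution([50.0], [-0.1])

    def test_cumulative_flag_converts_to_increments(self):
        inc = PoreSizeDistribution([60.0, 200.0], [0.1, 0.2])
        cum = PoreSizeDistribution([60.0, 200.0], [0.1, 0.3], cumulative=True)
        np.testing.assert_allclose(cum.volumes_cm3_per_g, inc.volumes_cm3_per_g)


class TestSiteDensity:
    def test_zero_surface(self):
        assert ls.binding_site_density(0.0) == 0.0

    def test_product(self):
        assert ls.binding_site_density(5.0e5, 2.1e-12) == pytest.approx(1.05e-6)

    def test_severe_fixture_in_reported_span(self, severe_spec, severe_derived):
        """Realistic pretreated fixtures should land between 0.12 and 1.5
        umol binding sites per g of cellulose."""
        umol_per_g_cellulose = severe_derived.site_density / severe_spec.f_cell * 1e6
        assert 0.12 <= umol_per_g_cellulose <= 1.5


class TestDeriveSubstrate:
    def test_hand_arithmetic(self):
        # accessible volume 0.5 cm^3/g at one 200 A bin, rho_p = 0.8
        psd = make_psd((200.0, 0.5))
        der = ls.derive_substrate(make_spec(psd, d=0.8, f_cell=0.5))
        assert der.eps_0 == pytest.approx(0.4, rel=1e-12)
        assert der.eps_f == pytest.approx(0.4 + 0.8 * 0.5 * 0.8 / 1.5, rel=1e-12)
        assert der.c_s_max0 == pytest.approx(der.site_density * 0.8, rel=1e-12)

    def test_zero_digestibility_keeps_porosity(self):
        der = ls.derive_substrate(make_spec(make_psd((200.0, 0.5)), d=0.0))
        assert der.eps_f == der.eps_0

    def test_infeasible_porosity_raises(self):
        with pytest.raises(ls.InfeasibleSubstrateError):
            ls.derive_substrate(make_spec(make_psd((200.0, 1.5))))  # eps_0 > 1
        with pytest.raises(ls.InfeasibleSubstrateError):
            # eps_f > 1: large accessible volume plus full digestion
            ls.derive_substrate(
                make_spec(make_psd((200.0, 1.1)), d=1.0, f_cell=0.6, rho_c=1.0)
            )

    def test_zero_volume_psd_gives_inert_particle(self):
        der = ls.derive_substrate(make_spec(make_psd((200.0, 0.0))))
        assert der.eps_0 == 0.0 and der.c_s_max0 == 0.0

    def test_cellulose_fraction_scaling_switch(self):
        psd = make_psd((200.0, 0.5))
        full = ls.derive_substrate(make_spec(psd, f_cell=0.5))
        scaled = ls.derive_substrate(make_spec(psd, f_cell=0.5),
                                     cellulose_fraction_scaling=True)
        assert scaled.s_spec == pytest.approx(0.5 * full.s_spec)


class TestSpecIO:
    def test_yaml_json_roundtrip(self, tmp_path, severe_spec):
        for name in ("spec.yaml", "spec.json"):
            path = tmp_path / name
            ls.save_substrate_spec(severe_spec, path)
            back = ls.load_substrate_spec(path)
            assert back.radius_cm == pytest.approx(severe_spec.radius_cm)
            assert back.digestibility == pytest.approx(severe_spec.digestibility)
            np.testing.assert_allclose(
                back.psd.volumes_cm3_per_g, severe_spec.psd.volumes_cm3_per_g
            )

    def test_psd_csv(self, tmp_path):
        path = tmp_path / "psd.csv"
        path.write_text("width_angstrom,volume_cm3_per_g\n80,0.1\n200,0.3\n")
        psd = PoreSizeDistribution.from_csv(path)
        np.testing.assert_allclose(psd.widths_angstrom, [80.0, 200.0])
        np.testing.assert_allclose(psd.volumes_cm3_per_g, [0.1, 0.3])
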