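"""Single-Gaussian scatterer and the two closed-form Z <-> B models."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from zbcorr.core import (
    MODEL2_DOMAIN_LIMIT,
    BComposition,
    GaussianAtom,
    Model2DomainError,
    ModelKind,
    NegativeBIsoWarning,
    NotInvertibleError,
    b2_iso,
    gaussian_density,
    model1_b2,
    model1_b2_iso,
    model2_b2,
    model2_b2_iso,
    occupancy_from_b,
    peak_density,
    sensitivity,
)
from zbcorr.scattering import density_at_origin, effective_b0, get_factor

positive_z = st.floats(min_value=1.0, max_value=100.0)
positive_b = st.floats(min_value=1.0, max_value=100.0)


class TestGaussianAtom:
    def test_peak_density_value(self):
        """Z = 16 e-, B = 18 A^2 gives rho(0) = 9.333 e/A^3."""
        atom = GaussianAtom(z=16.0, b=18.0)
        assert peak_density(atom) == pytest.approx(9.333, abs=1e-3)
        assert gaussian_density(atom, 0.0) == peak_density(atom)

    def test_density_normalizes_to_z(self):
        """int rho(r) 4 pi r^2 dr recovers the electron count."""
        atom = GaussianAtom(z=16.0, b=18.0)
        total, _ = integrate.quad(
            lambda r: gaussian_density(atom, r) * 4 * np.pi * r * r, 0, np.inf
        )
        assert total == pytest.approx(atom.z, rel=1e-8)

    @given(z=positive_z, b=positive_b)
    def test_peak_density_linear_in_z(self, z, b):
        assert peak_density(GaussianAtom(2 * z, b)) == pytest.approx(
            2 * peak_density(GaussianAtom(z, b)), rel=1e-12
        )

    def test_single_gaussian_matches_full_table_peak(self):
        """(Z=7, B=B0+16) reproduces the nitrogen multi-Gaussian peak."""
        b0 = effective_b0(get_factor("N"), 16.0)
        atom = GaussianAtom(z=7.0, b=b0 + 16.0)
        assert peak_density(atom) == pytest.approx(
            density_at_origin(get_factor("N"), 16.0), rel=1e-6
        )

    def test_invariants(self):
        with pytest.raises(ValueError):
            GaussianAtom(0.0, 18.0)
        with pytest.raises(ValueError):
            GaussianAtom(16.0, -1.0)
        with pytest.raises(ValueError):
            gaussian_density(GaussianAtom(16.0, 18.0), -0.5)
        with pytest.raises(ValueError):
            BComposition(b0=0.0, b_iso=0.0)


class TestModel1:
    def test_identity_and_reference_values(self):
        assert model1_b2(16, 18, 16) == pytest.approx(18.0, rel=1e-12)
        assert model1_b2(16, 18, 8) == pytest.approx(11.339, abs=1e-3)
        assert model1_b2_iso(12, 6, 16, 16) == pytest.approx(12.0, rel=1e-12)
        assert model1_b2_iso(12, 6, 16, 8) == pytest.approx(5.339, abs=1e-3)
        assert model1_b2_iso(12, 6, 16, 34) == pytest.approx(23.75, abs=5e-3)

    @given(z1=positive_z, b1=positive_b, z2=positive_z)
    def test_preserves_peak_density(self, z1, b1, z2):
        b2 = model1_b2(z1, b1, z2)
        rho1 = peak_density(GaussianAtom(z1, b1))
        rho2 = peak_density(GaussianAtom(z2, b2))
        assert abs(rho2 - rho1) < 1e-10 * rho1

    def test_negative_b2_iso_warns_but_returns(self):
        with pytest.warns(NegativeBIsoWarning):
            value = model1_b2_iso(1.0, 6.0, 16.0, 2.0)
        assert value == pytest.approx(7.0 * 0.125 ** (2 / 3) - 6.0, rel=1e-12)

    def test_rejects_nonpositive_inputs(self):
        for args in [(0, 18, 8), (16, 0, 8), (16, 18, -1)]:
            with pytest.raises(ValueError):
                model1_b2(*args)


class TestModel2:
    def test_identity_and_reference_values(self):
        assert model2_b2(16, 18, 16) == pytest.approx(18.0, rel=1e-12)
        assert model2_b2(16, 18, 8) == pytest.approx(10.982, abs=1e-3)
        assert model2_b2_iso(12, 6, 16, 8) == pytest.approx(4.982, abs=1e-3)

    def test_singularity_raises(self):
        with pytest.raises(Model2DomainError):
            model2_b2(16, 18, 91)  # u = 5.6875 > 2**(5/2)
        with pytest.raises(Model2DomainError):
            model2_b2(16, 18, 16 * MODEL2_DOMAIN_LIMIT)  # exactly at the pole

    @pytest.mark.parametrize("u", np.arange(0.3, 3.01, 0.1).round(2).tolist())
    def test_ordering_against_model1(self, u):
        """Model 2 predicts larger B2 than model 1 above u=1 and smaller below."""
        b1 = 18.0
        m1 = model1_b2(16.0, b1, 16.0 * u)
        m2 = model2_b2(16.0, b1, 16.0 * u)
        if u > 1:
            assert m2 >= m1
        elif u < 1:
            assert m2 <= m1
        else:
            assert m2 == pytest.approx(m1, rel=1e-12)

    @given(z1=positive_z, b1=positive_b, u=st.floats(min_value=0.05, max_value=5.0))
    def test_strictly_increasing_in_z2(self, z1, b1, u):
        z2 = z1 * u
        eps = 1e-6 * z2
        assert model2_b2(z1, b1, z2 + eps) > model2_b2(z1, b1, z2)
        assert model1_b2(z1, b1, z2 + eps) > model1_b2(z1, b1, z2)


class TestOccupancyInversion:
    def test_reference_values(self):
        assert occupancy_from_b(12, 6, 12, 1) == pytest.approx(1.0, rel=1e-12)
        assert occupancy_from_b(12, 6, 5.339, 1) == pytest.approx(0.500, abs=1e-4)
        assert occupancy_from_b(12, 6, 4.982, 2) == pytest.approx(0.500, abs=1e-4)

    @given(
        b1_iso=st.floats(min_value=2.0, max_value=60.0),
        b0=st.floats(min_value=0.0, max_value=10.0),
        u=st.floats(min_value=0.1, max_value=5.0),
        model=st.sampled_from([ModelKind.MODEL1_EQUAL_PEAK, ModelKind.MODEL2_MIN_DELTA_RHO_SQ]),
    )
    def test_round_trips_forward_model(self, b1_iso, b0, u, model):
        import warnings

        z1 = 16.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativeBIsoWarning)
            b2i = b2_iso(model, b1_iso, b0, z1, z1 * u)
        if b2i + b0 <= 0:
            return
        assert occupancy_from_b(b1_iso, b0, b2i, model) == pytest.approx(u, rel=1e-10)

    def test_not_invertible(self):
        with pytest.raises(NotInvertibleError):
            occupancy_from_b(12, 6, -7.0, 1)


class TestSensitivity:
    def test_bare_exponents_at_unit_ratio(self):
        """With B0 = 0 the log-log slopes are the model exponents 2/3 and 4/5."""
        assert sensitivity(1, 1.0, 12.0, 0.0) == pytest.approx(2 / 3, rel=1e-12)
        assert sensitivity(2, 1.0, 12.0, 0.0) == pytest.approx(4 / 5, rel=1e-12)

    def test_dataset_parameter_slopes(self):
        """At the two structures' parameters the slope is ~1.00 and ~0.87."""
        assert sensitivity(1, 1.0, 12.0, 6.0) == pytest.approx(1.00, abs=1e-10)
        assert sensitivity(1, 1.0, 19.8, 6.0) == pytest.approx(0.869, abs=1e-3)

    def test_matches_finite_differences(self):
        for model in (1, 2):
            for u in (0.7, 1.0, 1.6):
                h = 1e-6
                f = lambda uu: np.log(b2_iso(model, 12.0, 6.0, 16.0, 16.0 * uu))
                numeric = (f(u * np.exp(h)) - f(u * np.exp(-h))) / (2 * h)
                assert sensitivity(model, u, 12.0, 6.0) == pytest.approx(numeric, rel=1e-5)

    def test_domain_error(self):
        with pytest.raises(Model2DomainError):
            sensitivity(2, 6.0, 12.0, 0.0)


class TestModelKind:
    @pytest.mark.parametrize(
        "alias,expected",
        [
            (1, ModelKind.MODEL1_EQUAL_PEAK),
            ("2", ModelKind.MODEL2_MIN_DELTA_RHO_SQ),
            ("model1", ModelKind.MODEL1_EQUAL_PEAK),
            ("MODEL2_MIN_DELTA_RHO_SQ", ModelKind.MODEL2_MIN_DELTA_RHO_SQ),
            (ModelKind.MODEL1_EQUAL_PEAK, ModelKind.MODEL1_EQUAL_PEAK),
        ],
    )
    def test_coerce(self, alias, expected):
        assert ModelKind.coerce(alias) is expected

    def test_coerce_rejects_unknown(self):
        with pytest.raises(ValueError):
            ModelKind.coerce("model3")
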