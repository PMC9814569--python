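"""Mean residue ellipticity and secondary chemical shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catchsim.biophys_utils import (
    CDSpectrum,
    classify_mre_ratio,
    mre_convert,
    mre_ratio,
    secondary_shifts,
)


def spectrum(ellipticity, wavelengths=None, conc=400.0, bonds=10):
    wl = np.asarray(
        wavelengths if wavelengths is not None else
        np.linspace(190, 260, len(np.atleast_1d(ellipticity)))
    )
    return CDSpectrum(wl, np.atleast_1d(ellipticity), conc, bonds)


class TestMreConvert:
    def test_worked_example(self):
        # 10 mdeg, 10 amide bonds, 400 uM -> 10/(10*400e-7)*1e-3 = 25
        s = spectrum([10.0], wavelengths=[212.0])
        assert mre_convert(s)[0] == pytest.approx(25.0)

    def test_zero_maps_to_zero(self):
        s = spectrum(np.zeros(5))
        assert np.all(mre_convert(s) == 0)

    @given(st.floats(-50, 50), st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_linear_in_ellipticity(self, e, scale):
        base = mre_convert(spectrum([e], wavelengths=[210.0]))[0]
        scaled = mre_convert(spectrum([e * scale], wavelengths=[210.0]))[0]
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)

    @given(st.floats(1.0, 1000.0), st.floats(1.5, 8.0))
    @settings(max_examples=100, deadline=None)
    def test_inverse_linear_in_concentration(self, conc, factor):
        a = mre_convert(spectrum([7.0], wavelengths=[210.0], conc=conc))[0]
        b = mre_convert(
            spectrum([7.0], wavelengths=[210.0], conc=conc * factor)
        )[0]
        assert b == pytest.approx(a / factor, rel=1e-9)

    def test_doubling_amide_bonds_halves(self):
        a = mre_convert(spectrum([6.0], wavelengths=[210.0], bonds=5))[0]
        b = mre_convert(spectrum([6.0], wavelengths=[210.0], bonds=10))[0]
        assert b == pytest.approx(a / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mre_convert(spectrum([1.0], wavelengths=[210.0], conc=0.0))
        with pytest.raises(ValueError):
            mre_convert(spectrum([1.0], wavelengths=[210.0], bonds=0))


class TestMreRatio:
    def test_equal_values_give_one(self):
        s = spectrum([3.0, 3.0], wavelengths=[202.0, 212.0])
        assert mre_ratio(s) == pytest.approx(1.0)

    def test_beta_like_exceeds_coil_like(self):
        wl = np.arange(195.0, 231.0)
        beta = -np.exp(-((wl - 216.0) ** 2) / 40.0)  # minimum near 216 nm
        coil = -np.exp(-((wl - 200.0) ** 2) / 40.0)  # minimum near 200 nm
        r_beta = mre_ratio(spectrum(beta, wavelengths=wl))
        r_coil = mre_ratio(spectrum(coil, wavelengths=wl))
        assert r_beta > r_coil

    def test_missing_wavelength_without_nearest(self):
        s = spectrum([1.0, 2.0], wavelengths=[202.0, 213.0])
        with pytest.raises(ValueError, match="212"):
            mre_ratio(s, nearest=False)

    def test_zero_denominator(self):
        s = spectrum([0.0, 2.0], wavelengths=[202.0, 212.0])
        with pytest.raises(ValueError, match="undefined"):
            mre_ratio(s)

    def test_region_classification_ordering(self):
        assert classify_mre_ratio(0.2) == "RC"
        assert classify_mre_ratio(0.8) == "T"
        assert classify_mre_ratio(1.3) == "beta"


class TestSecondaryShifts:
    def _frames(self, observed_co, observed_ca):
        obs = pd.DataFrame(
            {
                "residue": ["Q3", "Q3"],
                "carbon": ["CO", "CA"],
                "shift_ppm": [observed_co, observed_ca],
            }
        )
        ref = pd.DataFrame(
            {
                "residue": ["Q3", "Q3"],
                "carbon": ["CO", "CA"],
                "shift_ppm": [174.7, 54.2],
            }
        )
        return obs, ref

    def test_beta_sheet_magnitudes(self):
        obs, ref = self._frames(172.0, 53.5)
        res = secondary_shifts(obs, ref)
        assert res.mean_co == pytest.approx(-2.7)
        assert res.mean_ca == pytest.approx(-0.7)
        assert res.beta_sheet_consistent

    def test_identical_tables_give_zero(self):
        obs, ref = self._frames(174.7, 54.2)
        res = secondary_shifts(obs, ref)
        assert res.table["delta_ppm"].abs().max() == 0
        assert not res.beta_sheet_consistent

    def test_antisymmetry(self):
        obs, ref = self._frames(176.0, 55.0)
        fwd = secondary_shifts(obs, ref).table["delta_ppm"].to_numpy()
        rev = secondary_shifts(
            ref.assign(shift_ppm=ref["shift_ppm"]),
            obs.rename(columns={}).assign(shift_ppm=obs["shift_ppm"]),
        ).table["delta_ppm"].to_numpy()
        assert np.allclose(fwd, -rev)

    def test_missing_reference_named(self):
        obs = pd.DataFrame(
            {"residue": ["K9"], "carbon": ["CG"], "shift_ppm": [23.0]}
        )
        ref = pd.DataFrame(
            {"residue": ["Q3"], "carbon": ["CO"], "shift_ppm": [174.7]}
        )
        with pytest.raises(KeyError, match="K9"):
            secondary_shifts(obs, ref)
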