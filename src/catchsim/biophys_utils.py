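"""Experimental-side calculations: mean residue ellipticity and NMR
secondary chemical shifts.

The CD conversion follows the conventional normalization of measured
ellipticity (millidegrees) per amide bond and per unit concentration:

    MRE = ellipticity / (n_amide_bonds * concentration * 1e-7) * 1e-3

with the concentration in micromolar.  The formula is applied exactly
as written (path length folded into the constants); an optional
explicit path-length variant is provided and off by default.

The beta-sheet content marker is the ratio MRE(212 nm)/MRE(202 nm):
random coils have a deep minimum near 200 nm, beta-sheets near 216 nm,
so the ratio grows as sheets form.  The region thresholds used for
classification are package defaults chosen to reproduce the qualitative
random-coil -> transition -> beta-sheet ordering; they are not measured
constants.

Secondary chemical shifts are observed minus random-coil reference
shifts; negative values for carbonyl and alpha carbons indicate
beta-strand conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CDSpectrum",
    "mre_convert",
    "mre_ratio",
    "classify_mre_ratio",
    "secondary_shifts",
    "SecondaryShiftResult",
]

#: Default MRE_212/MRE_202 region bounds (dimensionless, package choice):
#: below the first value = random coil, above the second = beta-sheet.
DEFAULT_RC_THRESHOLD = 0.6
DEFAULT_BETA_THRESHOLD = 1.0


@dataclass
class CDSpectrum:
    """A circular-dichroism spectrum in measurement units.

    wavelengths in nm (strictly increasing), ellipticity in
    millidegrees, total peptide concentration in micromolar, and the
    number of amide bonds per peptide.
    """

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    concentration_uM: float
    n_amide_bonds: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise ValueError("wavelength and ellipticity grids differ")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, concentration_uM: float, n_amide_bonds: int):
        df = pd.read_csv(path)
        return cls(
            wavelengths=df.iloc[:, 0].to_numpy(),
            ellipticity=df.iloc[:, 1].to_numpy(),
            concentration_uM=concentration_uM,
            n_amide_bonds=n_amide_bonds,
        )


def mre_convert(
    spec: CDSpectrum, path_length_cm: float | None = None
) -> np.ndarray:
    """Mean residue ellipticity per wavelength point.

    Applies ``ellipticity / (amide_bonds * concentration * 1e-7) * 1e-3``
    pointwise, with concentration in uM.  When ``path_length_cm`` is
    given, the result is additionally divided by the path length in cm
    (the default of the plain formula corresponds to the instrument
    configuration folded into the printed constants).
    """
    if spec.concentration_uM <= 0:
        raise ValueError("concentration must be positive")
    if spec.n_amide_bonds <= 0:
        raise ValueError("amide-bond count must be positive")
    mre = (
        spec.ellipticity
        / (spec.n_amide_bonds * spec.concentration_uM * 1.0e-7)
        * 1.0e-3
    )
    if path_length_cm is not None:
        if path_length_cm <= 0:
            raise ValueError("path length must be positive")
        mre = mre / path_length_cm
    return mre


def _value_at(
    wavelengths: np.ndarray,
    values: np.ndarray,
    wl: float,
    nearest: bool,
    tol: float = 1.0e-9,
) -> float:
    exact = np.where(np.abs(wavelengths - wl) < tol)[0]
    if exact.size:
        return float(values[exact[0]])
    if not nearest:
        raise ValueError(f"wavelength {wl} nm not on the grid")
    return float(values[np.argmin(np.abs(wavelengths - wl))])


def mre_ratio(
    spec: CDSpectrum,
    wl_num: float = 212.0,
    wl_den: float = 202.0,
    nearest: bool = True,
) -> float:
    """MRE(212 nm) / MRE(202 nm), the beta-sheet content marker.

    Wavelengths are matched exactly when on the grid, by
    nearest-neighbour lookup otherwise (disable with ``nearest=False``).
    """
    mre = mre_convert(spec)
    num = _value_at(spec.wavelengths, mre, wl_num, nearest)
    den = _value_at(spec.wavelengths, mre, wl_den, nearest)
    if den == 0:
        raise ValueError(f"MRE at {wl_den} nm is zero; ratio undefined")
    return num / den


def classify_mre_ratio(
    ratio: float,
    rc_threshold: float = DEFAULT_RC_THRESHOLD,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
) -> str:
    """Label an MRE ratio as ``RC`` / ``T`` / ``beta``.

    The default bounds are package conventions for the qualitative
    random-coil, transition and beta-sheet regions.
    """
    if ratio < rc_threshold:
        return "RC"
    if ratio < beta_threshold:
        return "T"
    return "beta"


@dataclass
class SecondaryShiftResult:
    """Per-site secondary shifts plus the CO / CA means."""

    table: pd.DataFrame           # residue, carbon, observed, reference, delta
    mean_co: float
    mean_ca: float

    @property
    def beta_sheet_consistent(self) -> bool:
        """Negative mean CO and CA secondary shifts indicate beta-strand."""
        return self.mean_co < 0 and self.mean_ca < 0


def secondary_shifts(observed: pd.DataFrame, reference: pd.DataFrame) -> SecondaryShiftResult:
    """Secondary chemical shifts: observed minus random-coil reference.

    Both frames need columns ``residue``, ``carbon`` and ``shift_ppm``
    (p.p.m.); carbons are labelled ``CO`` for carbonyl and ``CA`` for
    the alpha carbon (other labels pass through).  Raises if any
    observed site lacks a reference entry.
    """
    ref = reference.set_index(["residue", "carbon"])["shift_ppm"]
    rows = []
    for _, r in observed.iterrows():
        key = (r["residue"], r["carbon"])
        if key not in ref.index:
            raise KeyError(
                f"no random-coil reference for residue {key[0]!r} carbon {key[1]!r}"
            )
        rows.append(
            {
                "residue": r["residue"],
                "carbon": r["carbon"],
                "observed_ppm": float(r["shift_ppm"]),
                "reference_ppm": float(ref[key]),
                "delta_ppm": float(r["shift_ppm"]) - float(ref[key]),
            }
        )
    table = pd.DataFrame(rows)
    co = table[table["carbon"] == "CO"]["delta_ppm"]
    ca = table[table["carbon"] == "CA"]["delta_ppm"]
    return SecondaryShiftResult(
        table=table,
        mean_co=float(co.mean()) if len(co) else float("nan"),
        mean_ca=float(ca.mean()) if len(ca) else float("nan"),
    )
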