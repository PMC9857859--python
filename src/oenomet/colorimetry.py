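"""CIELAB colorimetry for wine.

Wine color is summarised in the CIE 1976 L*a*b* space: L* is lightness
(0 black – 100 white), a* the red–green axis and b* the yellow–blue axis.
From these the chroma C*ab = sqrt(a*² + b*²), the hue angle
h_ab = atan2(b*, a*) in degrees, and the total color difference against a
reference wine ΔE*ab = sqrt(ΔL*² + Δa*² + Δb*²) are derived.  Young red
wines have chroma close to a* (hue angles near 0°, i.e. purple-red).

The primary pipeline path takes measured L*, a*, b* directly.  An
optional, clearly approximate route estimates L*, a*, b* from the four
absorbances (450, 520, 570, 630 nm) commonly read on diluted wine.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class CIELABColor:
    """A CIELAB color with derived chroma and hue angle.

    Attributes
    ----------
    L_star, a_star, b_star : CIELAB coordinates.
    Cab_star : chroma, sqrt(a*² + b*²) >= 0.
    hab_deg : hue angle in degrees, in [0, 360).
    """

    L_star: float
    a_star: float
    b_star: float
    Cab_star: float
    hab_deg: float

    def delta_e(self, reference: "CIELABColor") -> float:
        return delta_e(self, reference)


def derive_color_metrics(L: float, a: float, b: float) -> CIELABColor:
    """Build a :class:`CIELABColor` with chroma and hue angle from L*, a*, b*.

    Raises
    ------
    ValueError
        If any input is non-finite.
    """
    vals = (float(L), float(a), float(b))
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"non-finite CIELAB input {vals}")
    L, a, b = vals
    chroma = math.hypot(a, b)
    hue = math.degrees(math.atan2(b, a)) % 360.0
    return CIELABColor(L, a, b, chroma, hue)


def delta_e(color: CIELABColor, reference: CIELABColor) -> float:
    """Total color difference ΔE*ab between two colors (CIE76, Euclidean)."""
    return math.sqrt(
        (color.L_star - reference.L_star) ** 2
        + (color.a_star - reference.a_star) ** 2
        + (color.b_star - reference.b_star) ** 2
    )


def color_table(
    lab: pd.DataFrame, reference: str | None = "auto"
) -> pd.DataFrame:
    """Derive chroma, hue angle and ΔE*ab for a table of wines.

    Parameters
    ----------
    lab : DataFrame indexed by wine/variety with columns
        ``L_star``, ``a_star``, ``b_star``.
    reference : index label of the reference wine for ΔE*ab, ``"auto"``
        to take the wine with maximal L* (the brightest wine, typically a
        lightly colored *Vitis vinifera* style), or None to skip ΔE.

    Returns
    -------
    DataFrame with columns L_star, a_star, b_star, Cab_star, hab_deg and
    (unless ``reference`` is None) delta_E; the reference's own ΔE is NaN.
    """
    out = lab[["L_star", "a_star", "b_star"]].astype(float).copy()
    colors = {
        idx: derive_color_metrics(r.L_star, r.a_star, r.b_star)
        for idx, r in out.iterrows()
    }
    out["Cab_star"] = [colors[i].Cab_star for i in out.index]
    out["hab_deg"] = [colors[i].hab_deg for i in out.index]
    if reference is not None:
        if reference == "auto":
            reference = out["L_star"].idxmax()
        if reference not in colors:
            raise ValueError(f"reference {reference!r} not in table")
        ref = colors[reference]
        out["delta_E"] = [
            np.nan if i == reference else delta_e(colors[i], ref) for i in out.index
        ]
        out.attrs["reference"] = reference
    return out


# -- optional absorbance route ---------------------------------------------------

#: CIE 1931 2° observer x̄, ȳ, z̄ and D65 relative power at 450/520/570/630 nm.
_CMF = {
    450: (0.3362, 0.0380, 1.7721, 117.008),
    520: (0.0633, 0.7100, 0.0782, 104.790),
    570: (0.7621, 0.9520, 0.0021, 96.061),
    630: (0.6424, 0.2650, 0.0000, 83.288),
}


def absorbance_to_lab(
    A450: float, A520: float, A570: float, A630: float, dilution: float = 10.0
) -> tuple[float, float, float]:
    """Approximate L*, a*, b* from four absorbance readings on diluted wine.

    A simplified four-wavelength colorimetric estimate: transmittance
    T(λ) = 10^(−A(λ)·dilution) at 450/520/570/630 nm is treated as a
    four-point sample of the visible transmission spectrum, weighted by
    the CIE 1931 2° color-matching functions under illuminant D65, and
    the resulting XYZ tristimulus values are converted to CIELAB.  This
    is an *approximation* of the full 400–700 nm integration and is
    flagged as such; use measured L*, a*, b* whenever available.

    A blank (all absorbances 0) maps to the white point: (100, 0, 0).
    Increasing the ``dilution`` factor reconstructs the undiluted, darker
    wine, so L* is monotonically non-increasing in ``dilution``.
    """
    readings = {450: A450, 520: A520, 570: A570, 630: A630}
    for wl, a in readings.items():
        if not math.isfinite(a) or a < 0:
            raise ValueError(f"absorbance at {wl} nm must be finite and >= 0, got {a}")
    if dilution <= 0:
        raise ValueError("dilution factor must be > 0")

    X = Y = Z = 0.0
    Xn = Yn = Zn = 0.0
    for wl, (xb, yb, zb, s) in _CMF.items():
        T = 10.0 ** (-readings[wl] * dilution)
        X += s * xb * T
        Y += s * yb * T
        Z += s * zb * T
        Xn += s * xb
        Yn += s * yb
        Zn += s * zb

    def f(t: float) -> float:
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = f(X / Xn), f(Y / Yn), f(Z / Zn)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return (L, a, b)


def delta_e_matrix(colors: Iterable[CIELABColor]) -> np.ndarray:
    """Pairwise ΔE*ab matrix (symmetric, zero diagonal)."""
    cs = list(colors)
    n = len(cs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = delta_e(cs[i], cs[j])
    return out
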