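"""Hyperspectral vegetation indices and index-versus-trait reporting.

The suite covers 19 published narrowband indices (chlorophyll, stress,
water, xanthophyll and greenness formulations) plus a broadband "MODIS-like"
NDVI built from band-averaged reflectance over the MODIS red (620-670 nm)
and NIR (841-876 nm) ranges.  Indices are always evaluated on raw
reflectance at exact 1-nm grid wavelengths — never on preprocessed spectra
and without band averaging for single-wavelength terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .spectra import Spectrum

__all__ = [
    "IndexDefinition",
    "index_registry",
    "compute_index",
    "compute_all_indices",
    "modis_like_ndvi",
    "index_trait_report",
    "MODIS_RED_RANGE",
    "MODIS_NIR_RANGE",
]

MODIS_RED_RANGE = (620.0, 670.0)
MODIS_NIR_RANGE = (841.0, 876.0)


@dataclass(frozen=True)
class IndexDefinition:
    """One published index: a formula over rho(lambda) terms."""

    name: str
    formula: str
    wavelengths: tuple
    group: str = ""
    reference: str = ""
    extra: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        for wl in self.wavelengths:
            if not 350 <= wl <= 2500:
                raise ValueError(f"{self.name}: wavelength {wl} nm outside 350-2500")


def _load_registry() -> list[IndexDefinition]:
    raw = json.loads(resources.files("leafspec.data")
                     .joinpath("index_registry.json").read_text())
    defs = []
    for d in raw["indices"]:
        defs.append(IndexDefinition(
            name=d["name"], formula=d["formula"],
            wavelengths=tuple(d.get("wavelengths", [])),
            group=d.get("group", ""), reference=d.get("reference", ""),
            extra=bool(d.get("extra", False)), note=d.get("note", "")))
    return defs


_REGISTRY: list[IndexDefinition] = _load_registry()


def index_registry(include_extra: bool = False) -> list[IndexDefinition]:
    """The index suite (19 entries; supplementary variants on request)."""
    return [d for d in _REGISTRY if include_extra or not d.extra]


def _rho(s: Spectrum, wl: float) -> float:
    try:
        return s.value_at(wl)
    except KeyError:
        raise ValueError(f"spectrum does not cover required wavelength {wl:g} nm")


def _safe_div(num: float, den: float) -> float:
    return np.nan if den == 0 else num / den


def compute_index(s: Spectrum, d: IndexDefinition) -> float:
    """Evaluate one index on a raw spectrum.

    Zero denominators yield NaN (an undefined value, not an exception);
    a wavelength missing from the grid raises, naming the wavelength.
    """
    r = {wl: _rho(s, wl) for wl in d.wavelengths}
    name = d.name
    if name == "SR1":
        return _safe_div(r[750], r[700])
    if name == "DoubleDifference":
        return (r[749] - r[720]) - (r[701] - r[672])
    if name == "Vogelmann1":
        return _safe_div(r[740], r[720])
    if name == "mSR705":
        return _safe_div(r[750] - r[445], r[705] - r[445])
    if name == "SRCarter":
        return _safe_div(r[760], r[695])
    if name == "Maccioni":
        return _safe_div(r[780] - r[710], r[780] - r[680])
    if name == "SR3":
        return _safe_div(r[750], r[550])
    if name == "Gitelson":
        return _safe_div(1.0, r[700])
    if name == "NDVI_MODIS":
        return modis_like_ndvi(s)
    if name == "Datt4":
        return _safe_div(r[672], r[550] * r[708])
    if name == "SR4":
        return _safe_div(r[700], r[670])
    if name == "SR2":
        return _safe_div(r[752], r[690])
    if name == "NDVI":
        return _safe_div(r[860] - r[690], r[860] + r[690])
    if name == "Vogelmann2":
        # deliberate variant: a double difference, where the 1993 original
        # divides the two terms
        return (r[734] - r[747]) - (r[715] + r[726])
    if name == "mNDVI":
        return _safe_div(r[800] - r[680], r[800] + r[680] - 2.0 * r[445])
    if name == "NDWI":
        return _safe_div(r[860] - r[1240], r[860] + r[1240])
    if name == "SIPI":
        # deliberate variant: truncated two-band form; the conventional
        # ratio is SIPI_full
        return r[800] - r[445]
    if name == "PRI":
        return _safe_div(r[531] - r[570], r[531] + r[570])
    if name == "mSRCHL":
        return _safe_div(r[800] - r[445], r[680] - r[445])
    if name == "SIPI_full":
        return _safe_div(r[800] - r[445], r[800] - r[680])
    raise KeyError(f"unknown index {name!r}")


def compute_all_indices(s: Spectrum, include_extra: bool = False) -> dict:
    return {d.name: compute_index(s, d)
            for d in index_registry(include_extra=include_extra)}


def _band_values(s: Spectrum, lo: float, hi: float) -> tuple:
    sel = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not sel.any():
        raise ValueError(f"spectrum does not cover the {lo:g}-{hi:g} nm band")
    return s.wavelengths[sel], s.reflectance[sel]


def _fwhm_band_mean(wl: np.ndarray, refl: np.ndarray) -> float:
    """Mean reflectance between the half-height crossings of the
    band-restricted curve (height measured above the band minimum)."""
    half = refl.min() + 0.5 * (refl.max() - refl.min())
    above = np.flatnonzero(refl >= half)
    lo, hi = above[0], above[-1]
    return float(refl[lo:hi + 1].mean())


def modis_like_ndvi(s: Spectrum, mode: str = "band_mean") -> float:
    """Broadband NDVI from MODIS-like red and NIR bands.

    ``band_mean`` (default) averages raw reflectance over the nominal
    band ranges.  ``fwhm`` instead averages between the full-width-half-
    maximum endpoints of each band-restricted curve — an alternate
    reading of a procedure that is under-specified for non-peaked band
    segments.
    """
    wl_r, r_r = _band_values(s, *MODIS_RED_RANGE)
    wl_n, r_n = _band_values(s, *MODIS_NIR_RANGE)
    if mode == "band_mean":
        red, nir = float(r_r.mean()), float(r_n.mean())
    elif mode == "fwhm":
        red, nir = _fwhm_band_mean(wl_r, r_r), _fwhm_band_mean(wl_n, r_n)
    else:
        raise ValueError("mode must be 'band_mean' or 'fwhm'")
    return _safe_div(nir - red, nir + red)


def index_trait_report(index_values: pd.DataFrame,
                       traits: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least-squares of each trait on each index value.

    Parameters
    ----------
    index_values : DataFrame
        One row per leaf, one column per index.
    traits : DataFrame
        One row per leaf (aligned with `index_values`), one column per
        trait (e.g. ``vcmax``, ``jmax``).

    Returns
    -------
    DataFrame with columns (index, trait, r_squared, slope, intercept,
    p_value, n, degenerate), ranked by r_squared within each trait.
    Indices with constant values are flagged degenerate and excluded from
    the ranking (rank = NaN).
    """
    if len(index_values) != len(traits):
        raise ValueError("index_values and traits must have equal length")
    rows = []
    for trait in traits.columns:
        y = np.asarray(traits[trait], dtype=float)
        for name in index_values.columns:
            x = np.asarray(index_values[name], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"fewer than 3 paired observations for {name}")
            degenerate = np.ptp(x[ok]) == 0
            if degenerate:
                rows.append({"index": name, "trait": trait, "r_squared": np.nan,
                             "slope": np.nan, "intercept": np.nan,
                             "p_value": np.nan, "n": n, "degenerate": True})
                continue
            res = sstats.linregress(x[ok], y[ok])
            rows.append({"index": name, "trait": trait,
                         "r_squared": float(res.rvalue ** 2),
                         "slope": float(res.slope),
                         "intercept": float(res.intercept),
                         "p_value": float(res.pvalue), "n": n,
                         "degenerate": False})
    report = pd.DataFrame(rows)
    report["rank"] = (report.groupby("trait")["r_squared"]
                      .rank(ascending=False, method="min"))
    report.loc[report["degenerate"], "rank"] = np.nan
    return report.sort_values(["trait", "rank"]).reset_index(drop=True)
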