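"""Leaf reflectance spectra: containers, replicate handling, QC and the
chemometric preprocessing chain applied before PLSR.

The chain, in fixed order, is: standard normal variate (per spectrum),
Savitzky-Golay second derivative (per spectrum), autoscale (per wavelength,
divide by the calibration-set standard deviation), mean-centre (per
wavelength, subtract the calibration-set mean).  Scaling-then-centring in
that literal order composes to standard column autoscaling; both statistics
come from the training set only and are replayed unchanged on test spectra.
Spectra are subset to the modelling range (450-2500 nm by default) before
any transform.  Vegetation indices are always computed on raw reflectance,
never on preprocessed values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Spectrum",
    "qc_spectrum",
    "average_replicates",
    "interpolate_masked",
    "snv",
    "savgol_second_derivative",
    "SpectralPreprocessor",
    "preprocess_chain",
]

_WL_LO, _WL_HI = 350.0, 2500.0


@dataclass
class Spectrum:
    """A single reflectance spectrum on a strictly increasing 1-nm grid.

    ``mask`` marks wavelengths excluded by QC (True = removed); such cells
    are skipped when replicates are averaged.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-d, equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths[0] < _WL_LO or self.wavelengths[-1] > _WL_HI:
            raise ValueError(f"wavelengths must lie within [{_WL_LO:g}, {_WL_HI:g}] nm")
        if self.mask is None:
            self.mask = np.zeros(self.wavelengths.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.wavelengths.shape:
                raise ValueError("mask must match wavelength grid")
        if np.any(~np.isfinite(self.reflectance[~self.mask])):
            raise ValueError("reflectance must be finite at unmasked wavelengths")

    @property
    def qc_flags(self) -> np.ndarray:
        """Per-wavelength flag: 'ok' or 'negative_removed'."""
        return np.where(self.mask, "negative_removed", "ok")

    def value_at(self, wavelength: float) -> float:
        """Raw reflectance at an exact grid wavelength (no interpolation)."""
        idx = np.searchsorted(self.wavelengths, wavelength)
        if idx >= len(self.wavelengths) or self.wavelengths[idx] != wavelength:
            raise KeyError(f"wavelength {wavelength:g} nm not on the grid")
        return float(self.reflectance[idx])


def qc_spectrum(s: Spectrum) -> Spectrum:
    """Mask negative reflectance values (instrument artefacts).

    Masked cells are excluded from replicate averaging at that wavelength.
    Rejects spectra that are negative everywhere.
    """
    neg = s.reflectance < 0
    if np.all(neg | s.mask):
        raise ValueError("spectrum entirely negative/masked; cannot QC")
    return Spectrum(s.wavelengths, s.reflectance, mask=s.mask | neg, label=s.label)


def average_replicates(spectra: list[Spectrum]) -> Spectrum:
    """Per-wavelength arithmetic mean over the unmasked replicate cells.

    All replicates must share an identical wavelength grid.  A wavelength
    masked in every replicate remains masked in the mean spectrum.
    """
    if not spectra:
        raise ValueError("no replicates supplied")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if s.wavelengths.shape != wl.shape or np.any(s.wavelengths != wl):
            raise ValueError("replicates are on mismatched wavelength grids")
    vals = np.stack([s.reflectance for s in spectra])
    masks = np.stack([s.mask for s in spectra])
    counts = (~masks).sum(axis=0)
    summed = np.where(masks, 0.0, vals).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, summed / np.maximum(counts, 1), np.nan)
    out_mask = counts == 0
    mean = np.where(out_mask, 0.0, mean)  # placeholder under mask
    return Spectrum(wl, mean, mask=out_mask, label=spectra[0].label)


def interpolate_masked(s: Spectrum) -> Spectrum:
    """Fill wavelengths masked in the (averaged) spectrum by linear
    interpolation from neighbouring unmasked wavelengths, with a warning."""
    if not s.mask.any():
        return s
    if s.mask.all():
        raise ValueError("cannot interpolate a fully masked spectrum")
    warnings.warn(
        f"interpolating {int(s.mask.sum())} fully-masked wavelength(s)",
        stacklevel=2)
    good = ~s.mask
    filled = s.reflectance.copy()
    filled[s.mask] = np.interp(s.wavelengths[s.mask], s.wavelengths[good],
                               s.reflectance[good])
    return Spectrum(s.wavelengths, filled, label=s.label)


def snv(x, ddof: int = 1):
    """Standard normal variate: standardise each spectrum across wavelengths.

    Output rows have mean 0 and standard deviation 1 (denominator n-1).
    Constant rows are rejected (zero variance).
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.ptp(x, axis=-1) == 0):
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=ddof, keepdims=True)
    return (x - mean) / sd


def savgol_second_derivative(x, window: int = 15, polyorder: int = 2):
    """Savitzky-Golay second derivative along the last axis (1-nm spacing).

    Exact on polynomials up to `polyorder` (a quadratic a*x^2+b*x+c maps to
    the constant 2a).  Edges are handled by evaluating the polynomial fitted
    to the terminal window, so output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window <= polyorder or polyorder < 2:
        raise ValueError("window must be odd and > polyorder >= 2")
    if x.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(x, window_length=window, polyorder=polyorder,
                         deriv=2, delta=1.0, mode="interp", axis=-1)


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """The full preprocessing chain as a scikit-learn transformer.

    ``fit`` estimates the per-wavelength scale (sd, denominator n-1) and
    centre on the calibration samples after the row-wise stages; ``transform``
    replays the chain with those frozen statistics, so a test row identical
    to a training row maps to the identical preprocessed row.  Wavelength
    columns with zero variance after the row stages are dropped with a
    warning.

    Parameters
    ----------
    wavelengths : array, optional
        Grid of the raw input columns; required to subset to
        ``[wl_min, wl_max]``. If omitted, columns are used as-is.
    wl_min, wl_max : float
        Modelling range in nm (default 450-2500).
    sg_window, sg_polyorder : int
        Savitzky-Golay second-derivative settings (defaults 15 / 2).
    """

    def __init__(self, wavelengths=None, wl_min: float = 450.0,
                 wl_max: float = 2500.0, sg_window: int = 15,
                 sg_polyorder: int = 2):
        self.wavelengths = wavelengths
        self.wl_min = wl_min
        self.wl_max = wl_max
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder

    # -- row-wise (sample-local) stages: subsetting, SNV, SG derivative ----
    def row_stage(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.wavelengths is not None:
            wl = np.asarray(self.wavelengths, dtype=float)
            if wl.size != X.shape[1]:
                raise ValueError("wavelength grid does not match column count")
            keep = (wl >= self.wl_min) & (wl <= self.wl_max)
            X = X[:, keep]
        return savgol_second_derivative(snv(X), window=self.sg_window,
                                        polyorder=self.sg_polyorder)

    def _subset_wavelengths(self):
        if self.wavelengths is None:
            return None
        wl = np.asarray(self.wavelengths, dtype=float)
        return wl[(wl >= self.wl_min) & (wl <= self.wl_max)]

    def fit(self, X, y=None):
        T = self.row_stage(X)
        sd = T.std(axis=0, ddof=1) if T.shape[0] > 1 else np.ones(T.shape[1])
        keep = sd > 1e-15
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance "
                          "wavelength(s) at autoscaling", stacklevel=2)
        self.kept_ = keep
        self.scale_ = sd[keep]
        self.center_ = (T[:, keep] / self.scale_).mean(axis=0)
        wl = self._subset_wavelengths()
        self.wavelengths_ = wl[keep] if wl is not None else None
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        self.preprocessing_state_ = [
            {"step": "subset", "wl_min": self.wl_min, "wl_max": self.wl_max},
            {"step": "snv", "ddof": 1},
            {"step": "savgol_d2", "window": self.sg_window,
             "polyorder": self.sg_polyorder},
            {"step": "autoscale", "ddof": 1},
            {"step": "mean_center"},
        ]
        return self

    def transform(self, X):
        if not hasattr(self, "scale_"):
            raise RuntimeError("SpectralPreprocessor is not fitted")
        one_d = np.asarray(X).ndim == 1
        T = self.row_stage(X)
        out = T[:, self.kept_] / self.scale_ - self.center_
        return out[0] if one_d else out

    # -- serialisation: replay must be bit-identical -----------------------
    def to_dict(self) -> dict:
        return {
            "params": {"wl_min": self.wl_min, "wl_max": self.wl_max,
                       "sg_window": self.sg_window,
                       "sg_polyorder": self.sg_polyorder},
            "wavelengths": (None if self.wavelengths is None
                            else np.asarray(self.wavelengths, float).tolist()),
            "kept": self.kept_.astype(int).tolist(),
            "scale": self.scale_.tolist(),
            "center": self.center_.tolist(),
            "preprocessing_state": self.preprocessing_state_,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralPreprocessor":
        obj = cls(wavelengths=(None if d["wavelengths"] is None
                               else np.asarray(d["wavelengths"], float)),
                  **d["params"])
        obj.kept_ = np.asarray(d["kept"], dtype=bool)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        obj.center_ = np.asarray(d["center"], dtype=float)
        obj.preprocessing_state_ = d["preprocessing_state"]
        wl = obj._subset_wavelengths()
        obj.wavelengths_ = wl[obj.kept_] if wl is not None else None
        return obj

    @classmethod
    def from_json(cls, s: str) -> "SpectralPreprocessor":
        return cls.from_dict(json.loads(s))


def preprocess_chain(X, wavelengths=None, train_index=None, **params):
    """Fit the chain on the (optionally indexed) training rows and apply it
    to all rows.  Returns ``(X_preprocessed, fitted_preprocessor)``."""
    prep = SpectralPreprocessor(wavelengths=wavelengths, **params)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    prep.fit(X if train_index is None else X[train_index])
    return prep.transform(X), prep
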