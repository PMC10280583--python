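"""Scatter-correction and smoothing transforms for absorbance spectra.

Four operators, each a scikit-learn transformer operating on an
(n_samples, n_channels) matrix:

* :class:`SNV` — standard normal variate: per-spectrum centering and
  scaling to unit sample standard deviation. Stateless.
* :class:`MSC` — multiplicative scatter correction: each spectrum is
  regressed (least squares) on a reference spectrum, ``x ~ a + b * ref``,
  and corrected to ``(x - a) / b``. The reference is the column mean of
  the calibration matrix, learned in :meth:`MSC.fit`.
* :class:`SavitzkyGolay` — local least-squares polynomial smoothing or
  differentiation (scipy implementation).
* :class:`MeanCenter` — subtract calibration column means.

MSC and MeanCenter learn state from the calibration set only; SNV and
SavitzkyGolay are per-spectrum and stateless. Fitted transformers
serialize to plain dicts via :func:`spec_to_dict` / :func:`spec_from_dict`
so a calibration-time preprocessing state can be reloaded at prediction
time without leakage.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class SNV(BaseEstimator, TransformerMixin):
    """Standard normal variate: row-wise (x - mean) / sample std (ddof=1)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = check_array(X)
        if X.shape[1] < 2:
            raise ValueError("SNV needs at least 2 channels")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd < 1e-15):
            raise ValueError("constant spectrum: SNV undefined (zero std)")
        return (X - mu) / sd


class MSC(BaseEstimator, TransformerMixin):
    """Multiplicative scatter correction against the calibration mean.

    Attributes
    ----------
    reference_ : (n_channels,) mean calibration spectrum.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[0] < 1:
            raise ValueError("MSC needs a non-empty calibration matrix")
        self.reference_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X)
        if X.shape[1] != self.reference_.size:
            raise ValueError("channel count does not match fitted reference")
        ref = self.reference_
        # per-spectrum least squares x ~= a + b*ref
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        if np.any(np.abs(b) < 1e-12):
            raise ValueError(
                "spectrum uncorrelated with reference (|slope| < 1e-12)"
            )
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


class SavitzkyGolay(BaseEstimator, TransformerMixin):
    """Savitzky-Golay smoothing / differentiation along the wavelength axis.

    Parameters
    ----------
    window_length : odd window size, > polyorder (default 11).
    polyorder : local polynomial degree (default 2).
    deriv : derivative order (default 0 = smoothing).
    delta : channel spacing used to scale derivatives (e.g. 2.0 for a
        2 nm grid); ignored when deriv == 0.

    Edges are handled by scipy's ``mode='interp'``: the polynomial fitted
    to the last full window is evaluated at the edge points, so no data is
    fabricated beyond the spectrum ends and output length equals input
    length.
    """

    def __init__(self, window_length: int = 11, polyorder: int = 2,
                 deriv: int = 0, delta: float = 1.0):
        self.window_length = window_length
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta

    def _validate(self):
        if self.window_length % 2 == 0 or self.window_length < 3:
            raise ValueError("window_length must be odd and >= 3")
        if self.polyorder >= self.window_length:
            raise ValueError("polyorder must be < window_length")
        if self.deriv < 0:
            raise ValueError("deriv must be >= 0")

    def fit(self, X, y=None):
        self._validate()
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        self._validate()
        X = check_array(X)
        if X.shape[1] < self.window_length:
            raise ValueError("spectrum shorter than the filter window")
        return savgol_filter(
            X, self.window_length, self.polyorder,
            deriv=self.deriv, delta=self.delta, axis=1, mode="interp",
        )


class MeanCenter(BaseEstimator, TransformerMixin):
    """Subtract the calibration column means (fit on calibration only)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X)
        if X.shape[1] != self.mean_.size:
            raise ValueError("channel count does not match fitted means")
        return X - self.mean_


class Identity(BaseEstimator, TransformerMixin):
    """No-op operator for the 'original spectrum' benchmark rows."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return check_array(X)


OPERATORS = {
    "none": Identity,
    "snv": SNV,
    "msc": MSC,
    "savgol": SavitzkyGolay,
    "mean_center": MeanCenter,
}

# short labels used in benchmark reports, mirroring the usual table rows
LABELS = {
    "none": "Original",
    "snv": "SNV",
    "msc": "MSC",
    "savgol": "SG",
    "mean_center": "MC",
}


def make_preprocessor(name: str, **params):
    """Instantiate an operator by its short name (none/snv/msc/savgol/mean_center)."""
    try:
        cls = OPERATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown operator {name!r}; choose from {sorted(OPERATORS)}"
        ) from None
    return cls(**params)


def spec_to_dict(op) -> dict:
    """Serialize an operator (params + fitted state) to a JSON-safe dict."""
    name = {v: k for k, v in OPERATORS.items()}[type(op)]
    d = {"operator": name, "params": op.get_params()}
    state = {}
    for attr in ("reference_", "mean_"):
        if hasattr(op, attr):
            state[attr] = getattr(op, attr).tolist()
    d["fitted_state"] = state
    return d


def spec_from_dict(d: dict):
    """Rebuild a (possibly fitted) operator from :func:`spec_to_dict` output."""
    op = make_preprocessor(d["operator"], **d.get("params", {}))
    for attr, val in d.get("fitted_state", {}).items():
        arr = np.asarray(val, dtype=float)
        setattr(op, attr, arr)
        op.n_features_in_ = arr.size
    return op
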