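"""Spectral dataset container, wide-CSV I/O, splitting, and summary statistics.

The universal currency of the package is :class:`SpectraSet`: a wavelength
axis, an absorbance matrix (samples x channels), unique sample identifiers,
and an optional table of per-sample reference values (targets) in percent.

The wide CSV dialect is: one row per sample, first column the sample id,
one column per wavelength (header = the wavelength in nm), and optional
trailing target columns whose headers carry the prefix ``target:``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TARGET_PREFIX = "target:"


@dataclass
class SpectraSet:
    """Immutable-by-convention container for a spectral dataset.

    Parameters
    ----------
    wavelengths : strictly increasing vector of nm values, one per channel.
    absorbance : (n_samples, n_channels) matrix of unitless absorbance.
    sample_ids : unique string identifiers, one per sample.
    targets : optional (n_samples, n_targets) DataFrame of reference values
        in percent, indexed like ``sample_ids``.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    targets: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        validate_spectra(self)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def target_names(self) -> list[str]:
        return [] if self.targets is None else list(self.targets.columns)

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Return the sub-dataset for the given sample ids (in that order)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in ids]
        targets = None if self.targets is None else self.targets.iloc[idx]
        return SpectraSet(
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            targets=targets,
        )


def validate_spectra(data: SpectraSet) -> None:
    """Enforce the SpectraSet invariants; raise ValueError on violation."""
    wl, ab = data.wavelengths, data.absorbance
    if ab.ndim != 2:
        raise ValueError(f"absorbance must be 2-D, got shape {ab.shape}")
    if wl.ndim != 1 or wl.size != ab.shape[1]:
        raise ValueError(
            f"wavelength axis length {wl.size} != channel count {ab.shape[1]}"
        )
    if wl.size >= 2 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.all(np.isfinite(ab)):
        bad = np.argwhere(~np.isfinite(ab))[0]
        raise ValueError(
            f"non-finite absorbance at sample {bad[0]}, channel {bad[1]}"
        )
    if len(data.sample_ids) != ab.shape[0]:
        raise ValueError("one sample id required per spectrum")
    if len(set(data.sample_ids)) != len(data.sample_ids):
        raise ValueError("sample ids must be unique")
    if data.targets is not None:
        if len(data.targets) != ab.shape[0]:
            raise ValueError("targets must have one row per sample")
        if not np.all(np.isfinite(data.targets.to_numpy(dtype=float))):
            raise ValueError("non-finite target value")


@dataclass
class SplitIndex:
    """A calibration/prediction partition of the sample ids."""

    calibration_ids: list[str]
    prediction_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration_ids), set(self.prediction_ids)
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "calibration_ids": self.calibration_ids,
                    "prediction_ids": self.prediction_ids,
                    "seed": self.seed,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "SplitIndex":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["calibration_ids"], d["prediction_ids"], d["seed"])


def read_spectra(path) -> SpectraSet:
    """Read a wide-CSV spectral file.

    Raises a ValueError naming the offending cell for malformed numbers and
    for non-increasing wavelength headers.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    target_cols = [c for c in df.columns if c.startswith(TARGET_PREFIX)]
    wl_cols = [c for c in df.columns if not c.startswith(TARGET_PREFIX)]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc

    def _numeric(block: pd.DataFrame, what: str) -> np.ndarray:
        out = np.empty(block.shape, dtype=float)
        for j, col in enumerate(block.columns):
            try:
                out[:, j] = pd.to_numeric(block[col], errors="raise")
            except (ValueError, TypeError) as exc:
                bad = pd.to_numeric(block[col], errors="coerce")
                row = block.index[int(np.argmax(bad.isna().to_numpy()))]
                raise ValueError(
                    f"malformed {what} cell at row {row!r}, column {col!r}"
                ) from exc
        return out

    absorbance = _numeric(df[wl_cols], "absorbance")
    targets = None
    if target_cols:
        tvals = _numeric(df[target_cols], "target")
        names = [c[len(TARGET_PREFIX):] for c in target_cols]
        targets = pd.DataFrame(tvals, columns=names, index=df.index.astype(str))
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=absorbance,
        sample_ids=list(df.index.astype(str)),
        targets=targets,
    )


def write_spectra(data: SpectraSet, path) -> None:
    """Write the wide-CSV dialect; 12 significant digits round-trip safely."""
    cols = {f"{w:g}": data.absorbance[:, j] for j, w in enumerate(data.wavelengths)}
    df = pd.DataFrame(cols, index=pd.Index(data.sample_ids, name="sample_id"))
    if data.targets is not None:
        for name in data.targets.columns:
            df[f"{TARGET_PREFIX}{name}"] = data.targets[name].to_numpy()
    df.to_csv(path, float_format="%.12g")


def random_split(data: SpectraSet, n_calibration: int, seed: int) -> SplitIndex:
    """Seeded random partition into calibration and prediction sets.

    Sampling is without replacement; the same (n, n_calibration, seed)
    triple always yields the same membership, so one split can be reused
    across instruments measuring the same physical samples.
    """
    n = data.n_samples
    if not 0 < n_calibration < n:
        raise ValueError(
            f"n_calibration must be in (0, {n}), got {n_calibration}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = sorted(perm[:n_calibration].tolist())
    pred = sorted(perm[n_calibration:].tolist())
    ids = data.sample_ids
    return SplitIndex(
        calibration_ids=[ids[i] for i in cal],
        prediction_ids=[ids[i] for i in pred],
        seed=seed,
    )


def target_statistics(data: SpectraSet, split: SplitIndex) -> pd.DataFrame:
    """Min/max/mean/sample-std per target for calibration, prediction, total.

    The standard deviation uses the n-1 denominator (sample statistic),
    the convention for dataset summary tables.
    """
    if data.targets is None:
        raise ValueError("dataset has no targets")
    rows = []
    parts = {
        "calibration": data.subset(split.calibration_ids).targets,
        "prediction": data.subset(split.prediction_ids).targets,
        "total": data.subset(split.calibration_ids + split.prediction_ids).targets,
    }
    for name in data.target_names:
        for part, table in parts.items():
            v = table[name].to_numpy(dtype=float)
            rows.append(
                {
                    "target": name,
                    "partition": part,
                    "min": v.min(),
                    "max": v.max(),
                    "mean": v.mean(),
                    "std": v.std(ddof=1) if v.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
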