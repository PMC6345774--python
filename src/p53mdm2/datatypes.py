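"""Shared lightweight containers used across analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd


@dataclass
class TitrationCurve:
    """Ordered (titrant, signal) pairs with fixed-component metadata.

    ``x`` is the titrated quantity — peptide concentration in M for binding
    titrations, %TFE (v/v) for helix-coil titrations. ``y`` is the observed
    signal (fluorescence intensity or mean residue ellipticity).
    """

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "signal"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have matching shapes")
        if self.x.ndim != 1:
            raise ValueError("titration data must be one-dimensional")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("titrant values must be non-decreasing")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.x_label: self.x, self.y_label: self.y})


@dataclass
class KineticTrace:
    """Time-resolved stopped-flow signal with concentration metadata.

    Pseudo-first-order validity requires the fixed partner (MDM2) to be in
    at least eight-fold excess over the fluorescent peptide.
    """

    time_s: np.ndarray
    signal: np.ndarray
    mdm2_conc_M: float = float("nan")
    peptide_conc_M: float = float("nan")
    n_averaged: int = 1
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.shape != self.signal.shape:
            raise ValueError("time and signal must have matching shapes")
        if self.time_s.size and np.any(self.time_s < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def pseudo_first_order(self) -> bool:
        """True when [MDM2] >= 8 x [peptide]."""
        return bool(self.mdm2_conc_M >= 8.0 * self.peptide_conc_M)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "signal": self.signal})


@dataclass
class RateSeries:
    """(MDM2 concentration, k_obs) pairs for the pseudo-first-order line."""

    mdm2_conc_M: np.ndarray
    kobs_s: np.ndarray
    kobs_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mdm2_conc_M = np.asarray(self.mdm2_conc_M, dtype=float)
        self.kobs_s = np.asarray(self.kobs_s, dtype=float)
        if self.kobs_err is not None:
            self.kobs_err = np.asarray(self.kobs_err, dtype=float)
            if self.kobs_err.shape != self.kobs_s.shape:
                raise ValueError("kobs_err shape mismatch")
        if self.mdm2_conc_M.shape != self.kobs_s.shape:
            raise ValueError("concentration and kobs shapes differ")
        if np.unique(self.mdm2_conc_M).size < 2:
            raise ValueError("need at least 2 distinct concentrations")

    def to_frame(self) -> pd.DataFrame:
        d = {"mdm2_conc_M": self.mdm2_conc_M, "kobs_s": self.kobs_s}
        if self.kobs_err is not None:
            d["kobs_err"] = self.kobs_err
        return pd.DataFrame(d)
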