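"""Myocardial washout-rate statistics with physical decay correction.

Between the early (~15 min) and late (3-4 h) planar acquisitions the
123-I signal drops both because the tracer clears from the myocardium
(the physiology of interest) and because the isotope decays.  The decay
correction factor

    DCF = 0.5 ** (delta_t_hours / 13)

removes the physical component; the convention uses a 13 h half-life for
123-I (the physical value is 13.22 h — ``half_life_hours`` is overridable
but defaults to the conventional 13).

Three washout statistics are in common use, all in percent of the early
signal:

* ``wr_bdc`` — mediastinal-background subtracted and decay corrected:
  ``((H_E - M_E) - (H_L - M_L)/DCF) / (H_E - M_E) * 100``
* ``wr_dc``  — heart counts only, decay corrected:
  ``(H_E - H_L/DCF) / H_E * 100``
* ``wr_hmr`` — from collimator-standardized HMR values, no decay term:
  ``(HMR_E - HMR_L) / HMR_E * 100`` (negative when uptake relative to
  mediastinum rises between the two acquisitions, as it does in most
  normal subjects).

Heart and mediastinal counts are mean counts per ROI pixel, the same
convention the HMR uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .standardize import STD_COLUMNS, HmrPair

__all__ = [
    "DEFAULT_HALF_LIFE_HOURS",
    "WashoutResult",
    "decay_correction_factor",
    "wr_bdc",
    "wr_dc",
    "wr_hmr",
    "washout_from_pair",
    "add_washout_columns",
]

#: Conventional 123-I half-life used by the decay correction, in hours.
DEFAULT_HALF_LIFE_HOURS: float = 13.0


@dataclass(frozen=True)
class WashoutResult:
    """The three washout statistics (percent) for one patient."""

    wr_bdc: float
    wr_dc: float
    wr_hmr: float
    dcf: float
    delta_t_hours: float


def decay_correction_factor(
    delta_t_hours, half_life_hours: float = DEFAULT_HALF_LIFE_HOURS
):
    """DCF = 0.5**(delta_t/half_life); multiplicative in the interval."""
    delta = np.asarray(delta_t_hours, dtype=float)
    if np.any(delta < 0):
        raise ValidationError(f"time between images must be >= 0 h, got {delta_t_hours!r}")
    if half_life_hours <= 0:
        raise ValidationError(f"half-life must be > 0 h, got {half_life_hours!r}")
    out = 0.5 ** (delta / half_life_hours)
    return out if out.ndim else float(out)


def wr_bdc(H_E, M_E, H_L, M_L, dcf):
    """Washout with mediastinal-background and decay corrections, percent."""
    H_E, M_E, H_L, M_L, dcf = map(np.asarray, (H_E, M_E, H_L, M_L, dcf))
    if np.any(H_E <= M_E):
        bad = np.argwhere(np.atleast_1d(H_E <= M_E)).ravel().tolist()
        raise DegenerateInputError(
            f"early heart counts must exceed mediastinal counts; violated at record(s) {bad}"
        )
    if np.any((dcf <= 0) | (dcf > 1)):
        raise ValidationError("dcf must lie in (0, 1]")
    out = ((H_E - M_E) - (H_L - M_L) / dcf) / (H_E - M_E) * 100.0
    return out if out.ndim else float(out)


def wr_dc(H_E, H_L, dcf):
    """Decay-corrected washout from heart counts alone, percent."""
    H_E, H_L, dcf = map(np.asarray, (H_E, H_L, dcf))
    if np.any(H_E <= 0):
        raise DegenerateInputError("early heart counts must be > 0")
    out = (H_E - H_L / dcf) / H_E * 100.0
    return out if out.ndim else float(out)


def wr_hmr(hmr_early, hmr_late):
    """Washout computed from standardized early/late HMR, percent.

    Inputs must be collimator-standardized HMR values; pass an
    :class:`~mibgquant.standardize.HmrPair` through
    :func:`washout_from_pair` to have the standardization flag enforced.
    Invariant under common positive rescaling of both ratios.
    """
    hmr_early, hmr_late = np.asarray(hmr_early, float), np.asarray(hmr_late, float)
    if np.any(hmr_early <= 0):
        raise ValidationError("early HMR must be > 0")
    out = (hmr_early - hmr_late) / hmr_early * 100.0
    return out if out.ndim else float(out)


def washout_from_pair(
    pair: HmrPair,
    H_E: float,
    M_E: float,
    H_L: float,
    M_L: float,
    delta_t_hours: float,
    half_life_hours: float = DEFAULT_HALF_LIFE_HOURS,
) -> WashoutResult:
    """All three washout statistics for one patient.

    ``pair`` must be standardized — the HMR-based washout is defined on
    MEGP-equivalent ratios only.
    """
    if not pair.standardized:
        raise ValidationError("wr_hmr requires collimator-standardized HMR values")
    dcf = decay_correction_factor(delta_t_hours, half_life_hours)
    return WashoutResult(
        wr_bdc=wr_bdc(H_E, M_E, H_L, M_L, dcf),
        wr_dc=wr_dc(H_E, H_L, dcf),
        wr_hmr=wr_hmr(pair.hmr_early, pair.hmr_late),
        dcf=dcf,
        delta_t_hours=delta_t_hours,
    )


def add_washout_columns(
    cohort: pd.DataFrame, half_life_hours: float = DEFAULT_HALF_LIFE_HOURS
) -> pd.DataFrame:
    """Append ``dcf``, ``wr_bdc``, ``wr_dc`` and ``wr_hmr`` columns.

    Requires the count columns (``H_E``, ``M_E``, ``H_L``, ``M_L``),
    acquisition minutes (``t_early_min``, ``t_late_min``) and a
    standardized cohort (``hmr_early_std``/``hmr_late_std`` present).
    """
    missing = [c for c in STD_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(
            f"cohort is not standardized (missing {missing}); run standardize_cohort first"
        )
    out = cohort.copy()
    delta_h = (out["t_late_min"] - out["t_early_min"]) / 60.0
    out["dcf"] = decay_correction_factor(delta_h.to_numpy(), half_life_hours)
    out["wr_bdc"] = wr_bdc(
        out["H_E"].to_numpy(), out["M_E"].to_numpy(),
        out["H_L"].to_numpy(), out["M_L"].to_numpy(), out["dcf"].to_numpy(),
    )
    out["wr_dc"] = wr_dc(out["H_E"].to_numpy(), out["H_L"].to_numpy(), out["dcf"].to_numpy())
    out["wr_hmr"] = wr_hmr(out["hmr_early_std"].to_numpy(), out["hmr_late_std"].to_numpy())
    return out
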