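"""Collimator standardization of the heart-to-mediastinum ratio.

Institutional HMR values measured with different camera-collimator
combinations are mapped to the MEGP-equivalent condition through the
affine transform

    HMR_std = (0.88 / K_i) * (HMR_i - 1) + 1

where ``K_i`` is the conversion coefficient of the institutional
collimator and 0.88 is the MEGP reference coefficient.  The transform
fixes HMR = 1 (no myocardial uptake above mediastinal background is
unchanged by the collimator correction) and is strictly increasing,
hence order-preserving, in the institutional ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .collimators import MEGP_CONVERSION_COEFFICIENT, CollimatorSpec, as_registry
from .errors import ConfigurationError, ValidationError

__all__ = [
    "HmrPair",
    "standardize_hmr",
    "invert_standardize",
    "standardize_cohort",
]

#: Cohort columns added by :func:`standardize_cohort`; their presence marks a
#: cohort as standardized (the "no double application" flag at cohort level).
STD_COLUMNS = ("hmr_early_std", "hmr_late_std")


@dataclass
class HmrPair:
    """An early/late HMR pair with a flag recording standardization state."""

    hmr_early: float
    hmr_late: float
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.hmr_early <= 0 or self.hmr_late <= 0:
            raise ValidationError(
                f"HMR values must be > 0, got ({self.hmr_early!r}, {self.hmr_late!r})"
            )

    def standardize(self, k_i: float) -> "HmrPair":
        if self.standardized:
            raise ValidationError("HmrPair is already standardized")
        return HmrPair(
            standardize_hmr(self.hmr_early, k_i),
            standardize_hmr(self.hmr_late, k_i),
            standardized=True,
        )


def _check_k(k_i) -> None:
    if not np.all(np.asarray(k_i) > 0):
        raise ValidationError(f"conversion coefficient must be > 0, got {k_i!r}")


def standardize_hmr(hmr_i, k_i: float):
    """Map an institutional HMR to MEGP-equivalent conditions.

    Accepts scalars or numpy/pandas arrays for ``hmr_i``.  Values below 1
    (physically unusual: heart colder than mediastinum) are accepted with a
    warning and map below 1.
    """
    _check_k(k_i)
    if np.any(np.asarray(hmr_i) < 1.0):
        warnings.warn(
            "institutional HMR < 1 encountered; standardization maps it below 1",
            stacklevel=2,
        )
    return (MEGP_CONVERSION_COEFFICIENT / k_i) * (hmr_i - 1.0) + 1.0


def invert_standardize(hmr_std, k_i: float):
    """Algebraic inverse: recover the institutional HMR a collimator with
    coefficient ``k_i`` would measure for a given standardized HMR."""
    _check_k(k_i)
    return (hmr_std - 1.0) * k_i / MEGP_CONVERSION_COEFFICIENT + 1.0


def standardize_cohort(
    cohort: pd.DataFrame,
    collimators: Iterable[CollimatorSpec] | Mapping[str, CollimatorSpec] | None = None,
) -> pd.DataFrame:
    """Standardize both early and late institutional HMR of a cohort table.

    Parameters
    ----------
    cohort:
        One row per patient with at least ``collimator_id``,
        ``hmr_early_inst`` and ``hmr_late_inst`` columns.
    collimators:
        Collimator registry (list, mapping, or None for the shipped defaults).

    Returns
    -------
    A copy of the cohort with ``hmr_early_std``/``hmr_late_std`` columns
    appended; institutional values are retained untouched.  A cohort that
    already carries the standardized columns is rejected (no double
    application).
    """
    present = [c for c in STD_COLUMNS if c in cohort.columns]
    if present:
        raise ValidationError(
            f"cohort already standardized (columns {present} present); refusing to re-apply"
        )
    registry = as_registry(collimators)
    out = cohort.copy()
    if len(out) == 0:
        for col in STD_COLUMNS:
            out[col] = pd.Series(dtype=float)
        return out
    # fail fast with the offending patient ids, not midway through a map
    bad = out.loc[~out["collimator_id"].isin(registry)]
    if len(bad):
        ids = ", ".join(map(str, bad.get("patient_id", bad.index).tolist()))
        unknown = ", ".join(sorted(set(map(str, bad["collimator_id"]))))
        raise ConfigurationError(
            f"unknown collimator_id(s) {unknown} for patient(s): {ids}"
        )
    k = out["collimator_id"].map({cid: s.conversion_coefficient for cid, s in registry.items()})
    out["hmr_early_std"] = (MEGP_CONVERSION_COEFFICIENT / k) * (out["hmr_early_inst"] - 1.0) + 1.0
    out["hmr_late_std"] = (MEGP_CONVERSION_COEFFICIENT / k) * (out["hmr_late_inst"] - 1.0) + 1.0
    return out
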