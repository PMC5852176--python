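"""Collimator specifications and conversion-coefficient configuration.

A gamma camera's collimator determines how strongly 159 keV (and higher)
photons of 123-I penetrate the lead septa.  Low-energy collimators suffer
septal penetration that depresses the measured heart-to-mediastinum ratio;
a phantom-derived conversion coefficient ``K_i`` quantifies the effect per
camera-collimator combination.  The medium-energy general purpose (MEGP)
collimator is the reference condition.

Conversion coefficients for specific cameras come from multicenter phantom
experiments and are consumed here as configuration, never derived.  The
non-MEGP defaults shipped below are documented placeholders and should be
replaced with institution-specific values via :func:`read_collimator_config`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, ValidationError

#: Conversion coefficient of the medium-energy general purpose collimator,
#: the reference condition all institutional HMRs are standardized to.
MEGP_CONVERSION_COEFFICIENT: float = 0.88


@dataclass(frozen=True)
class CollimatorSpec:
    """One camera-collimator condition.

    Parameters
    ----------
    collimator_id:
        Short label used in cohort tables and image metadata.
    conversion_coefficient:
        Phantom-derived ``K_i`` (dimensionless, > 0); 0.88 for MEGP.
    psf_sigma:
        Gaussian point-spread width in pixels used by the phantom simulator.
    septal_penetration_fraction:
        Fraction of counts redistributed into a broad septal-penetration
        tail by the simulator; in [0, 1). Simulator-only.
    """

    collimator_id: str
    conversion_coefficient: float
    psf_sigma: float = 3.5
    septal_penetration_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.conversion_coefficient <= 0:
            raise ValidationError(
                f"conversion_coefficient must be > 0, got {self.conversion_coefficient!r}"
            )
        if not 0.0 <= self.septal_penetration_fraction < 1.0:
            raise ValidationError(
                "septal_penetration_fraction must lie in [0, 1), got "
                f"{self.septal_penetration_fraction!r}"
            )
        if self.psf_sigma < 0:
            raise ValidationError(f"psf_sigma must be >= 0, got {self.psf_sigma!r}")


def default_collimators() -> dict[str, CollimatorSpec]:
    """Registry of the collimator conditions the simulator ships with.

    ``MEGP`` carries the reference coefficient 0.88.  The low-energy
    high-resolution (``LEHR``) and low-medium-energy (``LMEGP``)
    coefficients are placeholders on the scale reported for such
    collimators, not values from any specific camera.
    """
    specs = [
        CollimatorSpec("LEHR", 0.55, psf_sigma=3.5, septal_penetration_fraction=0.01),
        CollimatorSpec("LMEGP", 0.69, psf_sigma=4.0, septal_penetration_fraction=0.005),
        CollimatorSpec(
            "MEGP", MEGP_CONVERSION_COEFFICIENT, psf_sigma=4.5, septal_penetration_fraction=0.0
        ),
    ]
    return {s.collimator_id: s for s in specs}


def as_registry(
    collimators: Iterable[CollimatorSpec] | Mapping[str, CollimatorSpec] | None,
) -> dict[str, CollimatorSpec]:
    """Normalize a list/mapping of specs into an id-keyed registry."""
    if collimators is None:
        return default_collimators()
    if isinstance(collimators, Mapping):
        return dict(collimators)
    return {s.collimator_id: s for s in collimators}


def lookup(registry: Mapping[str, CollimatorSpec], collimator_id: str) -> CollimatorSpec:
    try:
        return registry[collimator_id]
    except KeyError:
        known = ", ".join(sorted(registry)) or "<empty>"
        raise ConfigurationError(
            f"unknown collimator_id {collimator_id!r}; configured: {known}"
        ) from None


def read_collimator_config(path: str | Path) -> dict[str, CollimatorSpec]:
    """Read a key-value collimator configuration file.

    Format: blocks of ``key: value`` lines, one block per collimator,
    blocks separated by blank lines.  Recognized keys: ``collimator_id``,
    ``conversion_coefficient``, ``psf_sigma``,
    ``septal_penetration_fraction``.  Lines starting with ``#`` are ignored.
    """
    registry: dict[str, CollimatorSpec] = {}
    block: dict[str, str] = {}

    def flush(block: dict[str, str]) -> None:
        if not block:
            return
        if "collimator_id" not in block:
            raise ConfigurationError(f"collimator block without collimator_id: {block}")
        try:
            spec = CollimatorSpec(
                collimator_id=block["collimator_id"],
                conversion_coefficient=float(block["conversion_coefficient"]),
                psf_sigma=float(block.get("psf_sigma", 3.5)),
                septal_penetration_fraction=float(
                    block.get("septal_penetration_fraction", 0.0)
                ),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"malformed collimator block {block}: {exc}") from exc
        registry[spec.collimator_id] = spec

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            flush(block)
            block = {}
            continue
        if ":" not in line:
            raise ConfigurationError(f"expected 'key: value', got {line!r}")
        key, value = line.split(":", 1)
        block[key.strip()] = value.strip()
    flush(block)
    return registry


def write_collimator_config(registry: Mapping[str, CollimatorSpec], path: str | Path) -> None:
    lines: list[str] = []
    for spec in registry.values():
        lines += [
            f"collimator_id: {spec.collimator_id}",
            f"conversion_coefficient: {spec.conversion_coefficient}",
            f"psf_sigma: {spec.psf_sigma}",
            f"septal_penetration_fraction: {spec.septal_penetration_fraction}",
            "",
        ]
    Path(path).write_text("\n".join(lines))
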