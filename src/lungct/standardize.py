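"""CT-number standardization: internal calibration, scanner-parameter
estimation, and monochromatic energy mapping.

The pipeline standardizes per-foam mean CT numbers measured on the COPD
gene2 phantom so that scans from different scanners and protocols become
comparable.  It runs in two steps:

1. **Internal calibration.**  Measured CT numbers are shifted so the two
   basis materials (air and, in the proposed mode, reference foam 1)
   land exactly on their nominal values; offsets for the other foams are
   interpolated linearly in electron density:

       delta_r1 = measured(basis) - nominal(basis)
       delta_a  = measured(air)   - (-1000)
       Delta_r  = (delta_r1 - delta_a) * rho_f / rho_r1 + delta_a

   and, in rescaled units ``h = CT/1000 + 1``,

       h_cal(r) = h_raw(r) - Delta_r / 1000.

2. **Monochromatic energy mapping.**  A single attenuation parameter
   alpha links rescaled CT number and electron density ratio,

       h / rho_e* = alpha * (1 - Z) + Z,      Z = Zeff*^n,

   so each reference foam yields a per-foam alpha(r); the scanner
   parameter alpha_bar is fitted over the reference foams plus the air
   point, and the target is mapped to the 80 keV reference via

       rho_e,t* = h(t) / [alpha_bar (1 - Z) + Z]
       h80(t)   = rho_e,t* [alpha_80 (1 - Z) + Z]
       ct80(t)  = (h80(t) - 1) * 1000.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RawMeasurement
from .phantom import (
    MATERIAL_ALIASES,
    PhantomDefinition,
    PhysicsConstants,
    default_phantom,
)

__all__ = [
    "rescale",
    "unrescale",
    "compute_offsets",
    "internal_calibrate",
    "alpha_of_foam",
    "estimate_alpha_bar",
    "energy_map",
    "standardize_scan",
    "CalibrationModel",
    "StandardizedResult",
    "CTNumberStandardizer",
]

logger = logging.getLogger("lungct")

#: Calibrated rescaled numbers outside this band flag the scan as
#: physically implausible (excluded from group statistics by default).
DEFAULT_RANGE_LIMITS = (-0.05, 1.05)

#: alpha-fit RMS residual (in rescaled units) above which a warning is
#: logged; roughly a 10 HU systematic misfit.
DEFAULT_RESIDUAL_WARN = 0.01


def rescale(ct: float) -> float:
    """Rescaled/shifted CT number ``h = CT/1000 + 1`` (air 0, water 1)."""
    if not math.isfinite(ct):
        raise ValueError(f"non-finite CT number {ct!r}")
    return ct / 1000.0 + 1.0


def unrescale(h: float) -> float:
    """Inverse of :func:`rescale`: ``CT = (h - 1) * 1000``."""
    if not math.isfinite(h):
        raise ValueError(f"non-finite rescaled number {h!r}")
    return (h - 1.0) * 1000.0


@dataclass
class CalibrationModel:
    """Fitted per-scan calibration: offsets and scanner parameter."""

    delta_r1: float
    delta_a: float
    delta_map: dict[str, float]
    alpha_per_foam: dict[str, float]
    alpha_bar: float
    fit_residual: float
    constants: PhysicsConstants
    alpha_mode: str = "wls"
    basis: str = "Reference 1"
    flagged: bool = False
    flag_reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "delta_r1": self.delta_r1,
            "delta_a": self.delta_a,
            "delta_map": dict(self.delta_map),
            "alpha_per_foam": dict(self.alpha_per_foam),
            "alpha_bar": self.alpha_bar,
            "fit_residual": self.fit_residual,
            "mode": self.alpha_mode,
            "basis": self.basis,
            "flagged": self.flagged,
            "flag_reasons": list(self.flag_reasons),
        }


@dataclass
class StandardizedResult:
    """Standardized CT number of one material plus stage bookkeeping."""

    target_name: str
    rho_e_t: float
    h80: float
    ct80: float
    stage_values: dict[str, float]

    def __post_init__(self) -> None:
        if self.rho_e_t < 0:
            raise ValueError(f"negative electron density for {self.target_name!r}")


def compute_offsets(
    measured: RawMeasurement, phantom: PhantomDefinition
) -> tuple[float, float, dict[str, float]]:
    """Internal-calibration offsets (delta_r1, delta_a, Delta per material).

    ``delta_r1`` is the basis-foam offset (measured minus nominal),
    ``delta_a`` the air offset against -1000 HU; per-material offsets
    interpolate linearly in electron density ratio between the air and
    basis anchors.  Offsets are computed for every calibrated material
    (air, basis, reference foams, targets).
    """
    measured.validate(phantom)
    basis = phantom.basis
    air = phantom.air
    rho_basis = basis.electron_density_ratio
    if rho_basis <= 0:
        raise ValueError("basis material must have positive electron density")
    delta_r1 = measured.values[basis.name] - basis.nominal_ct
    delta_a = measured.values[air.name] - (-1000.0)
    delta_map = {
        m.name: (delta_r1 - delta_a) * (m.electron_density_ratio / rho_basis) + delta_a
        for m in phantom.calibrated_materials
    }
    return delta_r1, delta_a, delta_map


def internal_calibrate(
    measured: RawMeasurement, phantom: PhantomDefinition
) -> dict[str, float]:
    """Internally calibrated rescaled numbers ``h_cal`` per material.

    The basis materials land exactly on their nominal rescaled values;
    other foams are shifted by their interpolated offsets.
    """
    _, _, delta_map = compute_offsets(measured, phantom)
    return {
        name: rescale(measured.values[name] - delta)
        for name, delta in delta_map.items()
    }


def alpha_of_foam(
    h_cal: float, rho_e: float, constants: PhysicsConstants
) -> float:
    """Per-foam attenuation parameter ``alpha = (h/rho_e - Z) / (1 - Z)``.

    Air (rho_e = 0) has no defined per-foam alpha; it instead anchors
    the alpha_bar fit at the origin.
    """
    if rho_e <= 0:
        raise ValueError("rho_e must be positive (air has no per-foam alpha)")
    z = constants.z_pow
    if z >= 1.0:
        raise ValueError("Zeff*^n must be < 1")
    return (h_cal / rho_e - z) / (1.0 - z)


def estimate_alpha_bar(
    h_cal: dict[str, float],
    phantom: PhantomDefinition,
    mode: str = "wls",
) -> tuple[float, float]:
    """Scanner parameter alpha_bar fitted over the reference foams + air.

    ``wls`` (default): least squares on the line ``h = rho_e* * s``
    through the air point (h = rho_e* = 0), with ``s = alpha(1-Z)+Z``;
    equivalently a rho_e*^2-weighted average of the per-foam alphas.
    ``mean``: unweighted mean of the per-foam alphas.

    Returns ``(alpha_bar, rms_residual)`` where the residual is the RMS
    of ``h_cal - rho_e* * s_hat`` over the foams plus the (exactly zero)
    air residual.
    """
    if mode not in ("wls", "mean"):
        raise ValueError(f"unknown alpha fit mode {mode!r}")
    consts = phantom.constants
    z = consts.z_pow
    foams = [
        m
        for m in phantom.regression_foams
        if m.name in h_cal and m.electron_density_ratio > 0
    ]
    if len(foams) < 2:
        raise ValueError("need at least two foams with rho_e* > 0 for the alpha fit")
    rho = np.array([m.electron_density_ratio for m in foams])
    h = np.array([h_cal[m.name] for m in foams])
    if mode == "wls":
        s_hat = float(np.dot(rho, h) / np.dot(rho, rho))
        alpha_bar = (s_hat - z) / (1.0 - z)
    else:
        alphas = (h / rho - z) / (1.0 - z)
        alpha_bar = float(alphas.mean())
        s_hat = consts.scale(alpha_bar)
    resid = h - rho * s_hat
    # air contributes a zero residual at (rho, h) = (0, 0)
    rms = float(np.sqrt((np.sum(resid**2) + 0.0) / (len(foams) + 1)))
    return float(alpha_bar), rms


def energy_map(
    h_target: float, alpha_bar: float, constants: PhysicsConstants
) -> tuple[float, float, float]:
    """Map a calibrated rescaled number to the 80 keV reference.

    Returns ``(rho_e_t, h80, ct80)``: the target's electron density
    ratio, its rescaled number at 80 keV, and the standardized CT
    number in HU.
    """
    if not math.isfinite(alpha_bar):
        raise ValueError("alpha_bar must be finite")
    denom = constants.scale(alpha_bar)
    if denom <= 0:
        raise ValueError(f"non-positive attenuation scale {denom} at alpha={alpha_bar}")
    rho_e_t = h_target / denom
    h80 = rho_e_t * constants.scale(constants.alpha_80)
    return rho_e_t, h80, (h80 - 1.0) * 1000.0


def standardize_scan(
    measured: RawMeasurement,
    phantom: PhantomDefinition,
    alpha_mode: str = "wls",
    range_limits: tuple[float, float] = DEFAULT_RANGE_LIMITS,
    residual_warn: float = DEFAULT_RESIDUAL_WARN,
) -> tuple[CalibrationModel, list[StandardizedResult]]:
    """Full per-scan pipeline: calibrate, fit alpha_bar, map to 80 keV.

    Standardized results are produced for every target material and,
    for reporting, for the basis and reference foams as well.  Scans
    whose calibrated foams leave ``range_limits`` (in rescaled units)
    are flagged but still processed.
    """
    delta_r1, delta_a, delta_map = compute_offsets(measured, phantom)
    h_cal = {
        name: rescale(measured.values[name] - delta)
        for name, delta in delta_map.items()
    }
    consts = phantom.constants
    alpha_per_foam = {
        m.name: alpha_of_foam(h_cal[m.name], m.electron_density_ratio, consts)
        for m in phantom.regression_foams
        if m.name in h_cal
    }
    alpha_bar, fit_residual = estimate_alpha_bar(h_cal, phantom, mode=alpha_mode)

    flag_reasons = []
    lo, hi = range_limits
    for m in (*phantom.regression_foams, *phantom.targets):
        if not lo <= h_cal[m.name] <= hi:
            flag_reasons.append(
                f"{m.name}: calibrated h={h_cal[m.name]:.4f} outside [{lo}, {hi}]"
            )
    if measured.truncation_flag:
        flag_reasons.append("air truncation correction applied upstream")
    if fit_residual > residual_warn:
        logger.warning(
            "alpha fit residual %.4g exceeds %.4g for scanner %s",
            fit_residual,
            residual_warn,
            measured.protocol.scanner_id,
        )

    model = CalibrationModel(
        delta_r1=delta_r1,
        delta_a=delta_a,
        delta_map=delta_map,
        alpha_per_foam=alpha_per_foam,
        alpha_bar=alpha_bar,
        fit_residual=fit_residual,
        constants=consts,
        alpha_mode=alpha_mode,
        basis=phantom.basis_high,
        flagged=bool(flag_reasons),
        flag_reasons=flag_reasons,
    )

    results = []
    for m in (*phantom.regression_foams, *phantom.targets):
        rho_e_t, h80, ct80 = energy_map(h_cal[m.name], alpha_bar, consts)
        results.append(
            StandardizedResult(
                target_name=m.name,
                rho_e_t=rho_e_t,
                h80=h80,
                ct80=ct80,
                stage_values={
                    "raw": measured.values[m.name],
                    "internal_cal": measured.values[m.name] - delta_map[m.name],
                    "standardized": ct80,
                },
            )
        )
    return model, results


# ---------------------------------------------------------------------------
# scikit-learn estimator surface

class CTNumberStandardizer(BaseEstimator, TransformerMixin):
    """Row-wise CT-number standardizer with a scikit-learn interface.

    Each input row holds one scan's measured per-foam mean CT numbers;
    ``transform`` returns the standardized (80 keV) CT numbers of the
    reported materials, each row calibrated against its own reference
    columns.  Composes with sklearn pipelines and ``clone``.

    Parameters
    ----------
    basis : {"foam1", "water"}
        Calibration basis: reference foam 1 (proposed) or water (legacy).
    alpha_mode : {"wls", "mean"}
        Estimator for the scanner parameter alpha_bar.
    phantom : PhantomDefinition, optional
        Explicit phantom definition; overrides ``basis`` when given.
    materials : sequence of str, optional
        Column order for plain-array input; defaults to
        ``("air", "ref1", "ref2", "ref3", "lung")``.  Ignored for
        DataFrame input, where column names are used.

    Attributes
    ----------
    phantom_ : PhantomDefinition
        Resolved phantom definition.
    feature_names_in_ : ndarray of str
        Input material columns seen during ``fit``.
    output_names_ : list of str
        Materials reported by ``transform`` (reference foams + target).
    n_features_in_ : int
    """

    _DEFAULT_COLUMNS = ("air", "ref1", "ref2", "ref3", "lung")

    def __init__(
        self,
        basis: str = "foam1",
        alpha_mode: str = "wls",
        phantom: PhantomDefinition | None = None,
        materials: tuple[str, ...] | None = None,
    ):
        self.basis = basis
        self.alpha_mode = alpha_mode
        self.phantom = phantom
        self.materials = materials

    def _resolve_phantom(self) -> PhantomDefinition:
        if self.phantom is not None:
            return self.phantom
        if self.basis not in ("foam1", "water"):
            raise ValueError(f"unknown basis {self.basis!r}")
        return default_phantom(
            "foam1_basis" if self.basis == "foam1" else "water_basis"
        )

    def _columns(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        cols = self.materials or self._DEFAULT_COLUMNS
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != len(cols):
            raise ValueError(
                f"expected 2-D input with {len(cols)} material columns, got {X.shape}"
            )
        return list(cols)

    def fit(self, X, y=None):
        phantom = self._resolve_phantom()
        cols = self._columns(X)
        canonical = [MATERIAL_ALIASES.get(c, c) for c in cols]
        known = {m.name for m in phantom.materials}
        unknown = [c for c in canonical if c not in known]
        if unknown:
            raise ValueError(f"unknown material columns: {unknown}")
        missing = [n for n in phantom.required_names() if n not in canonical]
        if missing:
            raise ValueError(f"missing required material columns: {missing}")
        self.phantom_ = phantom
        self.columns_ = canonical
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.n_features_in_ = len(cols)
        self.output_names_ = [
            m.name for m in (*phantom.regression_foams, *phantom.targets)
        ]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "phantom_"):
            raise RuntimeError("CTNumberStandardizer is not fitted")
        values = np.asarray(X, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(self.columns_):
            raise ValueError(
                f"expected shape (n_scans, {len(self.columns_)}), got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite CT numbers in input")
        from .io import RawMeasurement, ScanProtocol  # local: avoid cycle at import

        out = np.empty((values.shape[0], len(self.output_names_)))
        for i, row in enumerate(values):
            meas = RawMeasurement(
                protocol=ScanProtocol(scanner_id=f"row{i}"),
                values=dict(zip(self.columns_, row)),
            )
            _, results = standardize_scan(
                meas, self.phantom_, alpha_mode=self.alpha_mode
            )
            by_name = {r.target_name: r.ct80 for r in results}
            out[i] = [by_name[name] for name in self.output_names_]
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "phantom_"):
            raise RuntimeError("CTNumberStandardizer is not fitted")
        return np.asarray(
            [f"{name}_hu80" for name in self.output_names_], dtype=object
        )
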