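"""COPD gene2 phantom description and physics constants.

The COPD gene2 phantom (CTP698, The Phantom Laboratory) carries air and
water sealed in silicone cylinders, an acrylic rod, three reference foams
of known density, and a surrounding lung-equivalent foam.  Everything
downstream — internal calibration, the scanner-parameter fit and the
80 keV monochromatic energy mapping — reads its material table and
constants from this module.

Two calibration bases are supported:

``foam1_basis``
    The proposed scheme: air and the densest reference foam (foam 1,
    321.0 kg/m^3, nominal −700 HU) anchor the calibration; water is
    carried for reporting only.
``water_basis``
    The legacy Chen-Mayer scheme: air and water anchor the calibration.

Electron densities relative to water default to the mass-density ratio
times a configurable composition factor ``za_factor`` (the Z/A ratio of
the foam relative to water).  The calibration offsets of the internal
calibration only consume ratios of electron densities, which are
invariant to ``za_factor``; users with measured SRM electron densities
can override any material via the config interface.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MaterialSpec",
    "PhysicsConstants",
    "PhantomDefinition",
    "default_phantom",
    "electron_density_ratio_from_mass",
    "load_phantom",
    "save_phantom",
]

ROLES = ("air", "basis_foam", "reference_foam", "target", "water", "other")

#: Canonical material table: name -> (density kg/m^3, nominal HU).
#: The lung foam's nominal CT number is quoted as −835 HU in the
#: manufacturer material table and as −856 HU in some SRM-derived text;
#: the table value is the default here and can be overridden via config.
DEFAULT_MATERIALS = (
    ("Air", 0.0, -1000.0),
    ("Reference 3", 64.2, -935.0),
    ("Lung", 160.2, -835.0),
    ("Reference 2", 192.6, -820.0),
    ("Reference 1", 321.0, -700.0),
    ("Water", 1000.0, 0.0),
    ("Acrylic", 1180.0, 130.0),
)

#: Short column aliases used by the tabular CSV interface.
MATERIAL_ALIASES = {
    "air": "Air",
    "ref1": "Reference 1",
    "ref2": "Reference 2",
    "ref3": "Reference 3",
    "lung": "Lung",
    "water": "Water",
    "acrylic": "Acrylic",
}
ALIAS_BY_MATERIAL = {v: k for k, v in MATERIAL_ALIASES.items()}


def electron_density_ratio_from_mass(density: float, za_factor: float = 1.0) -> float:
    """Electron density relative to water from mass density.

    Parameters
    ----------
    density : float
        Mass density in kg/m^3.
    za_factor : float
        Ratio of the material's electrons-per-mass to that of water
        (dimensionless, > 0).  With the default 1.0 the electron density
        ratio is simply ``density / 1000``.

    Returns
    -------
    float
        rho_e* = (density / 1000) * za_factor, dimensionless.
    """
    if not math.isfinite(density) or density < 0:
        raise ValueError(f"density must be finite and >= 0, got {density!r}")
    if not za_factor > 0:
        raise ValueError(f"za_factor must be > 0, got {za_factor!r}")
    return density / 1000.0 * za_factor


@dataclass(frozen=True)
class MaterialSpec:
    """One phantom insert.

    Attributes
    ----------
    name : str
        Label, e.g. ``"Reference 1"``.
    nominal_density : float
        Mass density, kg/m^3.
    nominal_ct : float
        Expected CT number, HU.
    electron_density_ratio : float
        rho_e* relative to water, dimensionless.
    role : str
        One of ``air``, ``basis_foam``, ``reference_foam``, ``target``,
        ``water``, ``other``.
    """

    name: str
    nominal_density: float
    nominal_ct: float
    electron_density_ratio: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.nominal_ct < -1000:
            raise ValueError(f"{self.name}: nominal CT {self.nominal_ct} below -1000 HU")
        if self.electron_density_ratio < 0:
            raise ValueError(f"{self.name}: negative electron density ratio")
        if self.role == "air" and (
            self.electron_density_ratio != 0 or self.nominal_ct != -1000
        ):
            raise ValueError("air must have rho_e* = 0 and nominal CT = -1000 HU")


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the single-parameter CT-number/electron-density mapping.

    The mapping relates the rescaled CT number ``h = CT/1000 + 1`` of a
    material to its electron density ratio rho_e* through a single
    scanner- and protocol-dependent attenuation parameter alpha:

        h / rho_e* = alpha * (1 - Z) + Z,   Z = z_eff ** n

    ``alpha_80`` is the value of alpha at the 80 keV monochromatic
    reference energy, to which all scans are mapped.

    Attributes
    ----------
    n : float
        Atomic exponent for low-density (< 1000 kg/m^3) materials
        (default 3.21).
    z_eff : float
        Effective atomic number ratio Zeff* (default 0.871).
    alpha_80 : float
        Scanner parameter at 80 keV (default 0.946).
    soft_tissue_rho_e : float
        Electron density ratio of thoracic soft tissue, 0.956.  Recorded
        for reference; no equation in this package consumes it (the
        target's electron density is always estimated from its own
        measurement).
    z_pow : float
        Cached ``z_eff ** n``; recomputed on construction, never set.
    """

    n: float = 3.21
    z_eff: float = 0.871
    alpha_80: float = 0.946
    soft_tissue_rho_e: float = 0.956
    z_pow: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.z_eff < 1:
            raise ValueError(f"z_eff must lie in (0, 1), got {self.z_eff}")
        if not 0 < self.alpha_80 <= 1.5:
            raise ValueError(f"alpha_80 must lie in (0, 1.5], got {self.alpha_80}")
        object.__setattr__(self, "z_pow", self.z_eff**self.n)

    def scale(self, alpha: float) -> float:
        """Return ``alpha * (1 - Z) + Z``, the h/rho_e* slope at ``alpha``."""
        return alpha * (1.0 - self.z_pow) + self.z_pow


@dataclass(frozen=True)
class PhantomDefinition:
    """Material table plus calibration-basis designation.

    ``basis_high`` names the dense calibration anchor (foam 1 in the
    proposed mode, water in the legacy mode); air is always the zero
    anchor.
    """

    materials: tuple[MaterialSpec, ...]
    basis_high: str
    constants: PhysicsConstants = field(default_factory=PhysicsConstants)

    def __post_init__(self) -> None:
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise ValueError("duplicate material names")
        airs = [m for m in self.materials if m.role == "air"]
        if len(airs) != 1:
            raise ValueError("exactly one material must have role 'air'")
        basis = self.material(self.basis_high)
        if basis.nominal_density <= 0:
            raise ValueError("basis_high must have positive density")
        if len(self.regression_foams) < 2:
            raise ValueError(
                "need at least two foams with rho_e* > 0 for the alpha fit"
            )
        dens = [
            (m.nominal_density, m.electron_density_ratio)
            for m in sorted(self.materials, key=lambda m: m.nominal_density)
        ]
        for (d0, r0), (d1, r1) in zip(dens, dens[1:]):
            if d1 > d0 and not r1 > r0:
                raise ValueError("electron density must increase with mass density")

    def material(self, name: str) -> MaterialSpec:
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(f"material {name!r} not in phantom")

    @property
    def air(self) -> MaterialSpec:
        return next(m for m in self.materials if m.role == "air")

    @property
    def basis(self) -> MaterialSpec:
        return self.material(self.basis_high)

    @property
    def regression_foams(self) -> tuple[MaterialSpec, ...]:
        """Foams entering the scanner-parameter fit (basis + references)."""
        return tuple(
            m for m in self.materials if m.role in ("basis_foam", "reference_foam")
        )

    @property
    def targets(self) -> tuple[MaterialSpec, ...]:
        return tuple(m for m in self.materials if m.role == "target")

    @property
    def calibrated_materials(self) -> tuple[MaterialSpec, ...]:
        """Materials that receive an internal-calibration offset."""
        return tuple(
            m
            for m in self.materials
            if m.role in ("air", "basis_foam", "reference_foam", "target")
        )

    def required_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.calibrated_materials)


def _role_for(name: str, mode: str) -> str:
    if name == "Air":
        return "air"
    if name == "Lung":
        return "target"
    if name == "Acrylic":
        return "other"
    if name == "Water":
        return "basis_foam" if mode == "water_basis" else "water"
    if name == "Reference 1":
        return "basis_foam" if mode == "foam1_basis" else "reference_foam"
    return "reference_foam"


def default_phantom(
    mode: str = "foam1_basis",
    za_factor: float = 1.0,
    constants: PhysicsConstants | None = None,
) -> PhantomDefinition:
    """Build the seven-material COPD gene2 phantom.

    Parameters
    ----------
    mode : {"foam1_basis", "water_basis"}
        Calibration basis: reference foam 1 (proposed) or water (legacy).
    za_factor : float
        Composition factor applied when deriving electron densities from
        mass densities; see :func:`electron_density_ratio_from_mass`.
    constants : PhysicsConstants, optional
        Override the default physics constants.
    """
    if mode not in ("foam1_basis", "water_basis"):
        raise ValueError(f"unknown mode {mode!r}")
    materials = tuple(
        MaterialSpec(
            name=name,
            nominal_density=dens,
            nominal_ct=hu,
            electron_density_ratio=electron_density_ratio_from_mass(dens, za_factor),
            role=_role_for(name, mode),
        )
        for name, dens, hu in DEFAULT_MATERIALS
    )
    basis = "Reference 1" if mode == "foam1_basis" else "Water"
    return PhantomDefinition(
        materials=materials,
        basis_high=basis,
        constants=constants or PhysicsConstants(),
    )


# ---------------------------------------------------------------------------
# Config (de)serialization

def phantom_to_dict(phantom: PhantomDefinition) -> dict:
    return {
        "basis": phantom.basis_high,
        "constants": {
            "n": phantom.constants.n,
            "z_eff": phantom.constants.z_eff,
            "alpha_80": phantom.constants.alpha_80,
        },
        "materials": [
            {
                "name": m.name,
                "density_kgm3": m.nominal_density,
                "nominal_hu": m.nominal_ct,
                "rho_e_star": m.electron_density_ratio,
                "role": m.role,
            }
            for m in phantom.materials
        ],
    }


def phantom_from_dict(cfg: Mapping) -> PhantomDefinition:
    const_cfg = dict(cfg.get("constants", {}))
    constants = PhysicsConstants(
        n=float(const_cfg.get("n", 3.21)),
        z_eff=float(const_cfg.get("z_eff", 0.871)),
        alpha_80=float(const_cfg.get("alpha_80", 0.946)),
    )
    za = float(cfg.get("za_factor", 1.0))
    materials = []
    for entry in cfg["materials"]:
        dens = float(entry["density_kgm3"])
        rho = entry.get("rho_e_star")
        materials.append(
            MaterialSpec(
                name=str(entry["name"]),
                nominal_density=dens,
                nominal_ct=float(entry["nominal_hu"]),
                electron_density_ratio=(
                    float(rho)
                    if rho is not None
                    else electron_density_ratio_from_mass(dens, za)
                ),
                role=str(entry["role"]),
            )
        )
    return PhantomDefinition(
        materials=tuple(materials), basis_high=str(cfg["basis"]), constants=constants
    )


def save_phantom(phantom: PhantomDefinition, path) -> None:
    """Write a phantom definition to a YAML config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(phantom_to_dict(phantom), fh, sort_keys=False)


def load_phantom(path) -> PhantomDefinition:
    """Read a phantom definition from a YAML config file."""
    with open(path) as fh:
        return phantom_from_dict(yaml.safe_load(fh))
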