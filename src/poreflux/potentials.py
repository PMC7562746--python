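"""Energy models shared by the Brownian-dynamics generator and the estimators.

Everything downstream works in kcal·mol⁻¹ and Å. The potential of mean force
(PMF) models here are analytic stand-ins with known ground truth: sums of
Gaussian wells/barriers along the pore axis ``z``, optionally with a harmonic
radial term in the distance-from-axis coordinate ``b``. They are constructed
so that U → 0 in the bulk region (|z| ≥ 24 Å), which makes "free energy
relative to bulk solvent" hold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

# Boltzmann constant in kcal·mol⁻¹·K⁻¹ and the simulation temperature.
KB = 1.987204e-3
T_DEFAULT = 303.15

# Domain of the reaction coordinate: the molecule is confined to a cylinder
# −28 ≤ z ≤ 28 Å, b ≤ 15 Å around the pore axis.
Z_DOMAIN = (-28.0, 28.0)


def thermal_energy(T: float = T_DEFAULT) -> float:
    """kB·T in kcal·mol⁻¹. Raises ValueError for non-positive temperature."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return KB * T


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian feature of a PMF: positive height = barrier, negative = well."""

    center: float  # Å
    height: float  # kcal·mol⁻¹
    width: float  # Å (standard-deviation parameter)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("Gaussian width must be positive")


@dataclass(frozen=True)
class PmfModel:
    """Analytic ground-truth potential of mean force.

    ``U(z) = Σ hᵢ·exp(−(z−cᵢ)²/(2wᵢ²))`` plus, in 2D mode, a harmonic radial
    term ``½·radial_stiffness·b²``. Widths are kept small enough that every
    shipped fixture is ≈ 0 (within 10⁻³) for |z| ≥ 24 Å.
    """

    name: str
    terms: tuple[GaussianTerm, ...] = ()
    dimensionality: int = 1
    radial_stiffness: float = 0.0  # kcal·mol⁻¹·Å⁻², used when dimensionality == 2

    def __post_init__(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.radial_stiffness < 0:
            raise ValueError("radial stiffness must be non-negative")

    def energy(self, z, b=None):
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for t in self.terms:
            u = u + t.height * np.exp(-((z - t.center) ** 2) / (2.0 * t.width**2))
        if self.dimensionality == 2 and b is not None:
            b = np.asarray(b, dtype=float)
            u = u + 0.5 * self.radial_stiffness * b**2
        return u

    def dU_dz(self, z):
        z = np.asarray(z, dtype=float)
        g = np.zeros_like(z)
        for t in self.terms:
            g = g - t.height * (z - t.center) / t.width**2 * np.exp(
                -((z - t.center) ** 2) / (2.0 * t.width**2)
            )
        return g

    def dU_db(self, b):
        b = np.asarray(b, dtype=float)
        if self.dimensionality == 2:
            return self.radial_stiffness * b
        return np.zeros_like(b)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "dimensionality": self.dimensionality,
            "radial_stiffness": self.radial_stiffness,
            "terms": [
                {"center": t.center, "height": t.height, "width": t.width}
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PmfModel":
        return cls(
            name=d["name"],
            dimensionality=int(d.get("dimensionality", 1)),
            radial_stiffness=float(d.get("radial_stiffness", 0.0)),
            terms=tuple(
                GaussianTerm(float(t["center"]), float(t["height"]), float(t["width"]))
                for t in d.get("terms", ())
            ),
        )


def evaluate_pmf(model: PmfModel, z, b=None):
    """Evaluate the ground-truth PMF at z (and b for 2D models), kcal·mol⁻¹.

    z must lie inside the cylinder domain [−28, 28] Å; for 1D models b is
    ignored.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < Z_DOMAIN[0]) or np.any(z_arr > Z_DOMAIN[1]):
        raise ValueError(f"z outside the cylinder domain {Z_DOMAIN}")
    if model.dimensionality == 1:
        b = None
    return model.energy(z_arr, b) if np.ndim(z) else float(model.energy(z_arr, b))


@dataclass(frozen=True)
class HarmonicBias:
    """Umbrella window bias U_bias = ½·k·(z − z0)²."""

    z0: float  # window center, Å
    k: float  # force constant, kcal·mol⁻¹·Å⁻²

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("bias force constant must be non-negative")

    def energy(self, z):
        return 0.5 * self.k * (np.asarray(z, dtype=float) - self.z0) ** 2

    def force(self, z):
        return -self.k * (np.asarray(z, dtype=float) - self.z0)


@dataclass(frozen=True)
class CylinderRestraint:
    """Flat-bottom confinement: zero inside the cylinder, harmonic walls beyond.

    Matches the sampling geometry: the molecule is free inside
    z ∈ [z_min, z_max], b ∈ [0, b_max] and pushed back with stiffness
    ``wall_k`` when it leaves.
    """

    z_min: float = -28.0
    z_max: float = 28.0
    b_max: float = 15.0
    wall_k: float = 10.0

    def __post_init__(self) -> None:
        if self.z_min >= self.z_max:
            raise ValueError("z_min must be below z_max")
        if self.b_max <= 0:
            raise ValueError("b_max must be positive")
        if self.wall_k < 0:
            raise ValueError("wall stiffness must be non-negative")

    def energy(self, z, b=0.0):
        z = np.asarray(z, dtype=float)
        b = np.asarray(b, dtype=float)
        lo = np.clip(self.z_min - z, 0.0, None)
        hi = np.clip(z - self.z_max, 0.0, None)
        rad = np.clip(b - self.b_max, 0.0, None)
        return 0.5 * self.wall_k * (lo**2 + hi**2 + rad**2)

    def force_z(self, z):
        z = np.asarray(z, dtype=float)
        return self.wall_k * np.clip(self.z_min - z, 0.0, None) - self.wall_k * np.clip(
            z - self.z_max, 0.0, None
        )

    def force_b(self, b):
        b = np.asarray(b, dtype=float)
        return -self.wall_k * np.clip(b - self.b_max, 0.0, None)


def bias_energy(
    bias: HarmonicBias | None, restraint: CylinderRestraint | None, z, b=0.0
):
    """Total biasing energy at (z, b): umbrella term plus flat-bottom walls.

    Either term may be None (free ions carry no umbrella bias but keep the
    cylinder restraint).
    """
    e = np.zeros_like(np.asarray(z, dtype=float))
    if bias is not None:
        e = e + bias.energy(z)
    if restraint is not None:
        e = e + restraint.energy(z, b)
    return float(e) if np.ndim(z) == 0 else e


def place_windows(
    z_min: float, z_max: float, step: float, k: float
) -> list[HarmonicBias]:
    """Inclusive-endpoint grid of umbrella windows at the given spacing.

    The grid (−26, +26, 0.5) gives the 105-window layout used for each
    metabolite. Raises if the range is not commensurate with the step.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if z_max < z_min:
        raise ValueError("z_max must be ≥ z_min")
    n_float = (z_max - z_min) / step
    n = round(n_float)
    if abs(n_float - n) > 1e-9:
        raise ValueError(
            f"window range ({z_min}, {z_max}) is not commensurate with step {step}"
        )
    centers = z_min + step * np.arange(n + 1)
    if n > 0:
        centers[-1] = z_max  # exact endpoint regardless of float accumulation
    return [HarmonicBias(z0=float(c), k=k) for c in centers]


# ---------------------------------------------------------------------------
# Shipped PMF fixtures.
#
# The three-well fixture places minima near z ≈ −12, −5 and +6 Å — the
# qualitative layout of the metabolite profiles through the hexamer pore
# (convex-side well, constriction well, concave-side well) — without claiming
# quantitative equality with any published profile. The single-barrier
# fixtures carry barrier heights {1, 3.5, 3.8, 7.6} kcal·mol⁻¹ used for
# parameter-recovery checks.
# ---------------------------------------------------------------------------

FIXTURES: dict[str, PmfModel] = {}


def _register(model: PmfModel) -> PmfModel:
    FIXTURES[model.name] = model
    return model


_register(PmfModel(name="flat"))
for _h in (1.0, 3.5, 3.8, 7.6):
    _register(
        PmfModel(
            name=f"barrier_{_h:g}",
            terms=(GaussianTerm(center=-6.0, height=_h, width=2.5),),
        )
    )
_register(
    PmfModel(
        name="three_well",
        # term centers tuned so the analytic minima of the summed potential
        # fall at z ≈ −12, −5 and +6 Å
        terms=(
            GaussianTerm(center=-11.5, height=-1.2, width=2.0),
            GaussianTerm(center=-5.5, height=-0.6, width=1.6),
            GaussianTerm(center=6.0, height=-1.5, width=2.0),
            GaussianTerm(center=-8.5, height=1.8, width=1.4),
            GaussianTerm(center=0.5, height=1.2, width=1.6),
        ),
    )
)
_register(
    PmfModel(
        name="three_well_2d",
        terms=FIXTURES["three_well"].terms,
        dimensionality=2,
        radial_stiffness=0.05,
    )
)
_register(
    PmfModel(
        name="barrier_3.8_2d",
        terms=FIXTURES["barrier_3.8"].terms,
        dimensionality=2,
        radial_stiffness=0.05,
    )
)


def get_fixture(name: str) -> PmfModel:
    try:
        return FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown PMF fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None


def save_model(model: PmfModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh)


def load_model(path) -> PmfModel:
    with open(path) as fh:
        return PmfModel.from_dict(yaml.safe_load(fh))
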