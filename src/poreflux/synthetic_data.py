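"""Synthetic test-data generators with known ground truth.

Three generators cover the inputs of the downstream analyses:

* biased umbrella windows — overdamped Langevin (Brownian) dynamics on a
  known analytic PMF plus harmonic umbrella bias plus flat-bottom cylinder
  walls. The update rule per step is

      x ← x + (D/kBT)·F(x)·dt + √(2·D·dt)·ξ,   ξ ~ N(0, 1)

  applied to z (1D) or (z, b) (2D). The radial coordinate b is a
  distance-from-axis coordinate; it is integrated as two Cartesian
  components (bₓ, b_y) with the radial force projected along the radial
  unit vector, so b = √(bₓ² + b_y²) carries the correct entropic measure
  (unbiased radial density ∝ b) without the singular D/b Euler drift.

* unbiased "ion" trajectories confined to the cylinder (no umbrella term),
  each walker an independent simulation.

* hexameric pore coordinate ensembles whose constriction ring breathes
  around a mean radius, optionally dilating when a metabolite particle is in
  contact with a designated residue — a planted, recoverable effect for the
  contact-conditioned diameter statistics.

All randomness flows through numpy's PCG64 generator seeded explicitly;
identical spec + seed gives bit-identical output. Window seeds derive from
the master seed as ``seed + window_index``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .free_energy import UmbrellaWindowData
from .potentials import (
    CylinderRestraint,
    HarmonicBias,
    PmfModel,
    T_DEFAULT,
    thermal_energy,
)
from .pore_geometry import StructureFrame

MAX_STEP_JUMP = 5.0  # Å; larger single-step moves abort with a step-size error


class StepSizeError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one Brownian-dynamics window run.

    D (Å²·ps⁻¹) and dt (ps) are generator-side knobs with no counterpart in
    the emulated experiment; defaults keep the z relaxation time inside a
    5 kcal·mol⁻¹·Å⁻² window (kBT/(D·k) ≈ 0.6 ps) far below the run length.
    """

    model: PmfModel
    bias: HarmonicBias | None
    restraint: CylinderRestraint = field(default_factory=CylinderRestraint)
    n_steps: int = 20_000
    dt: float = 0.02  # ps
    D: float = 0.2  # Å²/ps
    T: float = T_DEFAULT
    seed: int = 0
    sample_stride: int = 2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.D <= 0:
            raise ValueError("dt and D must be positive")
        if self.sample_stride < 1 or self.n_steps < self.sample_stride:
            raise ValueError("need n_steps ≥ sample_stride ≥ 1")


def _integrate(
    model: PmfModel,
    biases: list[HarmonicBias | None],
    restraint: CylinderRestraint,
    z0: np.ndarray,
    b0: np.ndarray,
    n_steps: int,
    dt: float,
    D: float,
    T: float,
    noise_z: np.ndarray,
    noise_b: np.ndarray | None,
    sample_stride: int,
):
    """Batched Euler–Maruyama integration of independent walkers.

    ``noise_z`` has shape (n_steps, n_walkers); ``noise_b`` has shape
    (n_steps, 2, n_walkers) — two components because b is propagated in the
    Cartesian plane. A single walker integrated alone and as part of a batch
    sees identical arithmetic, so batching never changes results.
    """
    two_d = model.dimensionality == 2 and noise_b is not None
    kT = thermal_energy(T)
    mob = D / kT * dt
    sig = np.sqrt(2.0 * D * dt)
    z = z0.astype(float).copy()
    bx = b0.astype(float).copy()
    by = np.zeros_like(bx)
    nw = z.size
    bias_k = np.array([0.0 if bi is None else bi.k for bi in biases])
    bias_z0 = np.array([0.0 if bi is None else bi.z0 for bi in biases])

    n_keep = n_steps // sample_stride
    out_z = np.empty((n_keep, nw))
    out_b = np.empty((n_keep, nw))
    out_t = np.empty(n_keep)
    j = 0
    for step in range(n_steps):
        fz = -model.dU_dz(z) - bias_k * (z - bias_z0) + restraint.force_z(z)
        dz = mob * fz + sig * noise_z[step]
        if np.any(np.abs(dz) > MAX_STEP_JUMP):
            raise StepSizeError(
                f"single-step |Δz| exceeded {MAX_STEP_JUMP} Å at step {step}; "
                "reduce dt"
            )
        z = z + dz
        if two_d:
            b = np.sqrt(bx**2 + by**2)
            safe_b = np.maximum(b, 1e-12)
            fr = -model.dU_db(b) + restraint.force_b(b)  # radial force
            bx = bx + mob * fr * bx / safe_b + sig * noise_b[step, 0]
            by = by + mob * fr * by / safe_b + sig * noise_b[step, 1]
        if (step + 1) % sample_stride == 0:
            out_z[j] = z
            out_b[j] = np.sqrt(bx**2 + by**2)
            out_t[j] = (step + 1) * dt
            j += 1
    return out_t, out_z, out_b


def simulate_window(spec: SimulationSpec) -> UmbrellaWindowData:
    """Run one umbrella window; deterministic given ``spec.seed``.

    The walker starts at the bias center (or z = 0 without bias) with b drawn
    uniformly in [0, b_max/2].
    """
    rng = np.random.default_rng(spec.seed)
    b0 = rng.uniform(0.0, spec.restraint.b_max / 2.0)
    z_init = spec.bias.z0 if spec.bias is not None else 0.0
    two_d = spec.model.dimensionality == 2
    noise_z = rng.standard_normal((spec.n_steps, 1))
    noise_b = rng.standard_normal((spec.n_steps, 2, 1)) if two_d else None
    t, z, b = _integrate(
        spec.model,
        [spec.bias],
        spec.restraint,
        np.array([z_init]),
        np.array([b0]),
        spec.n_steps,
        spec.dt,
        spec.D,
        spec.T,
        noise_z,
        noise_b,
        spec.sample_stride,
    )
    return UmbrellaWindowData(
        bias=spec.bias,
        restraint=spec.restraint,
        T=spec.T,
        time=t,
        z=z[:, 0],
        b=b[:, 0],
        sample_interval=spec.dt * spec.sample_stride,
        meta={"model": spec.model.name, "seed": spec.seed},
    )


def generate_us_dataset(
    model: PmfModel,
    windows: list[HarmonicBias],
    restraint: CylinderRestraint | None = None,
    spec_defaults: SimulationSpec | None = None,
    seed: int = 0,
) -> list[UmbrellaWindowData]:
    """One Brownian-dynamics dataset per umbrella window.

    Window i runs with seed ``seed + i`` and draws exactly the random stream
    simulate_window would, but all walkers are integrated in one batch for
    speed — results are bit-identical to per-window calls.
    """
    if not windows:
        raise ValueError("empty window list")
    restraint = restraint or CylinderRestraint()
    base = spec_defaults or SimulationSpec(model=model, bias=None, restraint=restraint)
    two_d = model.dimensionality == 2
    n_steps, stride = base.n_steps, base.sample_stride

    b0s = np.empty(len(windows))
    nz = np.empty((n_steps, len(windows)))
    nb = np.empty((n_steps, 2, len(windows))) if two_d else None
    for i in range(len(windows)):
        rng = np.random.default_rng(seed + i)
        b0s[i] = rng.uniform(0.0, restraint.b_max / 2.0)
        nz[:, i] = rng.standard_normal((n_steps, 1))[:, 0]
        if two_d:
            nb[:, :, i] = rng.standard_normal((n_steps, 2, 1))[:, :, 0]
    z0s = np.array([w.z0 for w in windows])
    t, z, b = _integrate(
        model, list(windows), restraint, z0s, b0s,
        n_steps, base.dt, base.D, base.T, nz, nb, stride,
    )
    out = []
    for i, w in enumerate(windows):
        out.append(
            UmbrellaWindowData(
                bias=w,
                restraint=restraint,
                T=base.T,
                time=t,
                z=z[:, i],
                b=b[:, i],
                sample_interval=base.dt * stride,
                meta={"model": model.name, "seed": seed + i, "window_index": i},
            )
        )
    return out


def simulate_free_ions(
    model: PmfModel,
    restraint: CylinderRestraint | None = None,
    n_ions: int = 7,
    spec_defaults: SimulationSpec | None = None,
    seed: int = 0,
) -> list[UmbrellaWindowData]:
    """Independent unbiased walkers in the cylinder (no umbrella term).

    Mirrors the free-ion treatment: each ion's trajectory is an independent
    simulation under U_pmf + cylinder walls alone. Ions start uniformly in z.
    """
    if n_ions < 1:
        raise ValueError("need at least one ion")
    restraint = restraint or CylinderRestraint()
    base = spec_defaults or SimulationSpec(model=model, bias=None, restraint=restraint)
    two_d = model.dimensionality == 2
    n_steps, stride = base.n_steps, base.sample_stride

    z0s = np.empty(n_ions)
    b0s = np.empty(n_ions)
    nz = np.empty((n_steps, n_ions))
    nb = np.empty((n_steps, 2, n_ions)) if two_d else None
    for i in range(n_ions):
        rng = np.random.default_rng(seed + i)
        z0s[i] = rng.uniform(restraint.z_min, restraint.z_max)
        b0s[i] = rng.uniform(0.0, restraint.b_max / 2.0)
        nz[:, i] = rng.standard_normal((n_steps, 1))[:, 0]
        if two_d:
            nb[:, :, i] = rng.standard_normal((n_steps, 2, 1))[:, :, 0]
    t, z, b = _integrate(
        model, [None] * n_ions, restraint, z0s, b0s,
        n_steps, base.dt, base.D, base.T, nz, nb, stride,
    )
    return [
        UmbrellaWindowData(
            bias=None,
            restraint=restraint,
            T=base.T,
            time=t,
            z=z[:, i],
            b=b[:, i],
            sample_interval=base.dt * stride,
            meta={"model": model.name, "seed": seed + i, "ion_index": i},
        )
        for i in range(n_ions)
    ]


# ---------------------------------------------------------------------------
# hexameric pore ensembles
# ---------------------------------------------------------------------------

# ring layout: (residue name, residue number, axial position Å, radial offset
# above the constriction ring radius Å). The Ser ring is the constriction.
_RINGS = (
    ("ARG", 11, -10.0, 3.0),
    ("SER", 39, 0.0, 0.0),
    ("LYS", 36, 5.0, 2.0),
)
_CHAINS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class PoreEnsembleSpec:
    """Parameters of the synthetic hexamer-pore ensemble.

    ``contact_dilation`` is the full diameter shift (Å) planted in frames
    where the metabolite touches ``contact_residue``; 0 plants no effect.
    """

    n_frames: int = 2500
    ring_radius_mean: float = 3.0  # Å, constriction-ring atom-center radius
    breathing_sd: float = 0.6  # Å
    atom_vdw: float = 1.7  # Å
    contact_dilation: float = 0.0  # Å diameter shift in contact frames
    contact_fraction: float = 0.3
    contact_residue: str = "LYS36"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_radius_mean <= self.atom_vdw:
            raise ValueError("ring radius must exceed the atom vdW radius")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


def _ring_coords(radius: float, z: float, phase: float) -> np.ndarray:
    ang = phase + np.arange(6) * (np.pi / 3.0)
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)]
    )


def generate_pore_ensemble(
    spec: PoreEnsembleSpec,
) -> tuple[list[StructureFrame], pd.DataFrame]:
    """Breathing hexamer pore with a planted contact-coupled dilation.

    Each frame holds three six-fold-symmetric rings of single-heavy-atom
    pseudo-residues (Arg11 convex side, Ser39 constriction, Lys36 concave
    side) plus one metabolite particle. In a ``contact_fraction`` of frames
    the metabolite sits 2.6–3.4 Å from a designated residue atom (radially
    outside the ring, so it never narrows the pore) and the constriction
    diameter is shifted by ``contact_dilation``.

    Returns the frames and a ground-truth table with columns
    (frame, residue, n_contacts, contact, true_diameter).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    radii = rng.normal(spec.ring_radius_mean, spec.breathing_sd, size=n)
    # keep the ring physically open
    radii = np.maximum(radii, spec.atom_vdw + 0.5)
    n_contact = int(round(spec.contact_fraction * n))
    contact_frames = np.zeros(n, dtype=bool)
    contact_frames[rng.choice(n, size=n_contact, replace=False)] = True
    radii = radii + np.where(contact_frames, spec.contact_dilation / 2.0, 0.0)
    contact_dist = rng.uniform(2.6, 3.4, size=n)

    target_resname, target_resnum = spec.contact_residue[:3], int(
        spec.contact_residue[3:]
    )
    frames: list[StructureFrame] = []
    rows = []
    labels = [f"{rn}{ri}" for rn, ri, _, _ in _RINGS]
    for fi in range(n):
        names, resnames, resnums, chains, coords = [], [], [], [], []
        target_atom_xyz = None
        target_ring_r = None
        for rn, ri, zring, dr in _RINGS:
            ring_r = radii[fi] + dr
            xyz = _ring_coords(ring_r, zring, phase=0.0)
            for c in range(6):
                names.append("CA")
                resnames.append(rn)
                resnums.append(ri)
                chains.append(_CHAINS[c])
                coords.append(xyz[c])
            if rn == target_resname and ri == target_resnum:
                target_atom_xyz = xyz[0]
                target_ring_r = ring_r
        # metabolite: radially outward of the chain-A target atom in contact
        # frames (never inside the pore), parked in bulk otherwise
        if contact_frames[fi]:
            direction = target_atom_xyz.copy()
            direction[2] = 0.0
            direction /= np.linalg.norm(direction)
            met = target_atom_xyz + direction * contact_dist[fi]
        else:
            met = np.array([0.0, 0.0, -20.0])
        names.append("C1")
        resnames.append("LIG")
        resnums.append(1)
        chains.append("X")
        coords.append(met)

        natoms = len(names)
        frames.append(
            StructureFrame(
                serial=np.arange(1, natoms + 1),
                name=np.array(names),
                resname=np.array(resnames),
                resnum=np.array(resnums),
                chain=np.array(chains),
                coords=np.array(coords),
                vdw=np.full(natoms, spec.atom_vdw),
                element=np.array(["C"] * natoms),
                frame_index=fi,
            )
        )
        true_d = 2.0 * (radii[fi] - spec.atom_vdw)
        for lab in labels:
            is_target = lab == spec.contact_residue
            nc = int(contact_frames[fi]) if is_target else 0
            rows.append(
                {
                    "frame": fi,
                    "residue": lab,
                    "n_contacts": nc,
                    "contact": bool(nc),
                    "true_diameter": true_d,
                }
            )
    return frames, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window file I/O: columnar text, one file per window
# ---------------------------------------------------------------------------


def write_window(window: UmbrellaWindowData, path) -> None:
    """Write a window as columnar text: # key=value header, then time z b."""
    r = window.restraint
    header = {
        "z0": window.bias.z0 if window.bias else "none",
        "k": window.bias.k if window.bias else 0.0,
        "T": window.T,
        "sample_interval": window.sample_interval,
        "z_min": r.z_min,
        "z_max": r.z_max,
        "b_max": r.b_max,
        "wall_k": r.wall_k,
    }
    header.update({k: v for k, v in window.meta.items() if np.isscalar(v)})
    buf = io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k}={v}\n")
    buf.write("# time z b\n")
    np.savetxt(
        buf,
        np.column_stack([window.time, window.z, window.b]),
        fmt="%.10g",
    )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_window(path) -> UmbrellaWindowData:
    meta: dict = {}
    with open(path) as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line[1:].split("=", 1)
            meta[k.strip()] = v.strip()
    data = np.loadtxt(io.StringIO(text))
    data = np.atleast_2d(data)
    bias = None
    if meta.get("z0", "none") != "none":
        bias = HarmonicBias(z0=float(meta["z0"]), k=float(meta["k"]))
    restraint = CylinderRestraint(
        z_min=float(meta.get("z_min", -28.0)),
        z_max=float(meta.get("z_max", 28.0)),
        b_max=float(meta.get("b_max", 15.0)),
        wall_k=float(meta.get("wall_k", 10.0)),
    )
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"z0", "k", "T", "sample_interval", "z_min", "z_max", "b_max", "wall_k"}
    }
    return UmbrellaWindowData(
        bias=bias,
        restraint=restraint,
        T=float(meta.get("T", T_DEFAULT)),
        time=data[:, 0],
        z=data[:, 1],
        b=data[:, 2],
        sample_interval=float(meta.get("sample_interval", 1.0)),
        meta=extra,
    )
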