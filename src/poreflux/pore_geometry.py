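"""Structure-based pore analyses.

PDB reading/writing (via biotite), least-squares rigid superposition
(Kabsch), per-residue RMSF, maximal-inscribed-sphere pore-radius profiling
along the pore axis, hexagon pore-entrance area, and distance+angle hydrogen
bond contact detection.

Conventions: the structure is assumed superposed so the pore axis is the z
axis with the center of mass near the origin; lengths in Å.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

# heavy-element van der Waals radii (Å) used for inscribed-sphere profiling
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
DEFAULT_VDW = 1.70

H_BOND_MAX = 1.25  # Å, hydrogen considered covalently bound to a heavy atom


class PdbParseError(ValueError):
    pass


@dataclass
class StructureFrame:
    """Atoms of one trajectory frame or crystal structure."""

    serial: np.ndarray
    name: np.ndarray
    resname: np.ndarray
    resnum: np.ndarray
    chain: np.ndarray
    coords: np.ndarray  # (N, 3) Å
    vdw: np.ndarray  # Å
    element: np.ndarray
    frame_index: int = 0
    time: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(np.asarray(self.vdw, dtype=float) <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def mask(self, selection: str | np.ndarray | None) -> np.ndarray:
        if selection is None:
            return np.ones(self.n_atoms, dtype=bool)
        if isinstance(selection, str):
            return select(self, selection)
        return np.asarray(selection, dtype=bool)

    def subset(self, selection) -> "StructureFrame":
        m = self.mask(selection)
        return StructureFrame(
            serial=self.serial[m],
            name=self.name[m],
            resname=self.resname[m],
            resnum=self.resnum[m],
            chain=self.chain[m],
            coords=self.coords[m],
            vdw=self.vdw[m],
            element=self.element[m],
            frame_index=self.frame_index,
            time=self.time,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        out = StructureFrame(
            serial=self.serial,
            name=self.name,
            resname=self.resname,
            resnum=self.resnum,
            chain=self.chain,
            coords=self.coords @ np.asarray(rotation).T + translation,
            vdw=self.vdw,
            element=self.element,
            frame_index=self.frame_index,
            time=self.time,
        )
        return out


# ---------------------------------------------------------------------------
# selections: "resname SER and name CA", "not resname LIG", "chain A B", ...
# ---------------------------------------------------------------------------


def select(frame: StructureFrame, expression: str) -> np.ndarray:
    """Evaluate a simple and-joined selection expression to a boolean mask.

    Clauses: ``name``, ``resname``, ``resnum``, ``chain``, ``element``, each
    followed by one or more values; a clause may be negated with ``not``.
    ``all`` matches everything.
    """
    mask = np.ones(frame.n_atoms, dtype=bool)
    for clause in expression.split(" and "):
        tokens = clause.split()
        if not tokens:
            continue
        negate = tokens[0] == "not"
        if negate:
            tokens = tokens[1:]
        if tokens == ["all"]:
            sub = np.ones(frame.n_atoms, dtype=bool)
        else:
            key, *values = tokens
            if not values:
                raise ValueError(f"selection clause {clause!r} has no values")
            fields = {
                "name": frame.name,
                "resname": frame.resname,
                "chain": frame.chain,
                "element": frame.element,
            }
            if key == "resnum":
                sub = np.isin(frame.resnum, [int(v) for v in values])
            elif key in fields:
                sub = np.isin(fields[key], values)
            else:
                raise ValueError(f"unknown selection keyword {key!r}")
        mask &= ~sub if negate else sub
    return mask


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PdbParseError(f"line {lineno}: ATOM record shorter than 54 columns")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PdbParseError(
                f"line {lineno}: malformed coordinate field ({exc})"
            ) from None


def read_pdb(source) -> list[StructureFrame]:
    """Parse a (possibly multi-model) PDB file into StructureFrames.

    Only blank or 'A' alternate locations are kept. Van der Waals radii are
    assigned from the bundled element table (unknown elements get the carbon
    radius).
    """
    import biotite.structure.io.pdb as pdb

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    _validate_pdb_text(text)
    pdb_file = pdb.PDBFile.read(io.StringIO(text))
    stack = pdb_file.get_structure(altloc="first")
    if stack.stack_depth() == 0:
        raise PdbParseError("no models found")
    frames = []
    for mi in range(stack.stack_depth()):
        arr = stack[mi]
        element = np.array([e.capitalize() for e in arr.element])
        vdw = np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in element])
        frames.append(
            StructureFrame(
                serial=np.arange(1, arr.array_length() + 1),
                name=np.array(arr.atom_name),
                resname=np.array(arr.res_name),
                resnum=np.array(arr.res_id),
                chain=np.array(arr.chain_id),
                coords=np.array(arr.coord, dtype=float),
                vdw=vdw,
                element=element,
                frame_index=mi,
            )
        )
    return frames


def write_pdb(frames: list[StructureFrame] | StructureFrame, path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if isinstance(frames, StructureFrame):
        frames = [frames]
    arrays = []
    for f in frames:
        arr = struc.AtomArray(f.n_atoms)
        arr.coord = np.asarray(f.coords, dtype=np.float32)
        arr.chain_id = np.asarray(f.chain, dtype="U4")
        arr.res_id = np.asarray(f.resnum, dtype=int)
        arr.res_name = np.asarray(f.resname, dtype="U5")
        arr.atom_name = np.asarray(f.name, dtype="U6")
        arr.element = np.asarray([e.upper() for e in f.element], dtype="U2")
        arr.hetero = np.asarray(f.resname == "LIG", dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# superposition / RMSF
# ---------------------------------------------------------------------------


@dataclass
class Superposition:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å over the fitted selection
    transformed: StructureFrame = field(repr=False)


def superpose(
    mobile: StructureFrame,
    reference: StructureFrame,
    selection: str | np.ndarray | None = None,
) -> Superposition:
    """Least-squares optimal rigid fit of ``mobile`` onto ``reference``.

    Kabsch with determinant correction (proper rotation only), computed on
    the selected atoms; the returned transform is applied to all atoms.
    """
    mm = mobile.mask(selection)
    rm = reference.mask(selection)
    P = mobile.coords[mm]
    Q = reference.coords[rm]
    if P.shape[0] != Q.shape[0]:
        raise ValueError(
            f"selection sizes differ: {P.shape[0]} mobile vs {Q.shape[0]} reference"
        )
    if P.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry; superposition undefined")
    rot, _ = Rotation.align_vectors(Qc, Pc)
    R = rot.as_matrix()
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return Superposition(
        rotation=R, translation=t, rmsd=rmsd, transformed=mobile.transformed(R, t)
    )


def rmsf(
    frames: list[StructureFrame],
    selection: str | np.ndarray | None = None,
    discard_fraction: float = 0.0,
    per_chain: bool = True,
) -> pd.DataFrame:
    """Per-residue RMSF about the time-averaged positions.

    Frames must already be superposed onto a common reference. The first
    ``discard_fraction`` of frames is dropped (equilibration). Atom-level
    fluctuations √⟨|r − ⟨r⟩|²⟩ are averaged per residue, separately per chain
    unless ``per_chain`` is False.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    start = int(np.floor(discard_fraction * len(frames)))
    kept = frames[start:]
    if len(kept) < 2:
        raise ValueError("need at least 2 retained frames")
    ref = kept[0]
    m = ref.mask(selection)
    if not np.any(m):
        raise ValueError("empty selection")
    X = np.stack([f.coords[m] for f in kept])  # (F, N, 3)
    mean = X.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    df = pd.DataFrame(
        {
            "chain": ref.chain[m],
            "res_id": ref.resnum[m],
            "res_name": ref.resname[m],
            "rmsf": fluct,
        }
    )
    keys = ["chain", "res_id", "res_name"] if per_chain else ["res_id", "res_name"]
    return df.groupby(keys, as_index=False)["rmsf"].mean()


# ---------------------------------------------------------------------------
# pore-radius profile (maximal inscribed sphere per z-slice)
# ---------------------------------------------------------------------------


@dataclass
class PoreProfile:
    z_grid: np.ndarray
    radius: np.ndarray  # Å; NaN where no atoms in slab
    center_xy: np.ndarray  # (n_z, 2)

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.radius


def _slice_radius(
    pts: np.ndarray, vdw: np.ndarray, z: float, n_starts: int,
    start_extent: float, escape_cap: float, n_refine: int = 3,
) -> tuple[float, np.ndarray]:
    def neg_r(xy):
        d = np.sqrt(
            (pts[:, 0] - xy[0]) ** 2
            + (pts[:, 1] - xy[1]) ** 2
            + (pts[:, 2] - z) ** 2
        )
        return -np.min(d - vdw)

    g = np.linspace(-start_extent, start_extent, n_starts)
    gx, gy = np.meshgrid(g, g)
    starts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = np.array([neg_r(s) for s in starts])
    best = starts[np.argsort(vals)[:n_refine]]
    r_best, xy_best = -np.inf, starts[np.argmin(vals)]
    for x0 in best:
        res = minimize(
            neg_r, x0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
        )
        if -res.fun > r_best:
            r_best, xy_best = -res.fun, res.x
    return min(max(r_best, 0.0), escape_cap), xy_best


def pore_profile(
    frame: StructureFrame,
    z_range: tuple[float, float] = (-15.0, 15.0),
    z_step: float = 0.5,
    n_starts: int = 5,
    slab_half_width: float = 6.0,
    escape_cap: float = 10.0,
    selection: str | np.ndarray | None = None,
) -> PoreProfile:
    """Maximal-inscribed-sphere radius along the pore (z) axis.

    At each z-slice the center (x, y) maximizing
    ``r(x, y) = min_i(|p_i − (x, y, z)| − vdw_i)`` over atoms within a
    ±``slab_half_width`` slab is found by multi-start local optimization from
    an ``n_starts`` × ``n_starts`` grid over ±2 Å (the best starts refined
    with Nelder–Mead). Radii are clamped at ``escape_cap`` (pore considered
    open) and are NaN where the slab holds no atoms.
    """
    sub = frame.subset(selection) if selection is not None else frame
    zs = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    radius = np.full(zs.size, np.nan)
    centers = np.full((zs.size, 2), np.nan)
    for i, z in enumerate(zs):
        in_slab = np.abs(sub.coords[:, 2] - z) <= slab_half_width
        if not np.any(in_slab):
            continue
        radius[i], centers[i] = _slice_radius(
            sub.coords[in_slab], sub.vdw[in_slab], float(z),
            n_starts, 2.0, escape_cap,
        )
    return PoreProfile(z_grid=zs, radius=radius, center_xy=centers)


def min_constriction(profile: PoreProfile) -> tuple[float, float]:
    """(z, diameter) at the narrowest defined slice; ties go to z nearest 0."""
    ok = np.isfinite(profile.radius)
    if not np.any(ok):
        raise ValueError("profile has no defined slices")
    r = profile.radius[ok]
    z = profile.z_grid[ok]
    rmin = r.min()
    ties = np.abs(r - rmin) < 1e-9
    zi = np.argmin(np.abs(z[ties]))
    return float(z[ties][zi]), float(2.0 * rmin)


# ---------------------------------------------------------------------------
# hexagon pore-entrance area
# ---------------------------------------------------------------------------


def hexagon_area(points, selection: str | None = None) -> float:
    """Area (Å²) of the hexagon through six labelled atoms.

    Fits the least-squares plane, orders vertices by polar angle about their
    centroid in that plane, and sums the 3D areas of the six centroid-fan
    triangles. For a planar convex hexagon every triangulation gives the same
    area; the centroid fan is additionally independent of where the cyclic
    vertex order starts, so near-planar input gives an order-invariant value.
    """
    if isinstance(points, StructureFrame):
        pts = points.coords[points.mask(selection)]
    else:
        pts = np.asarray(points, dtype=float)
    if pts.shape != (6, 3):
        raise ValueError(f"need exactly 6 points, got {pts.shape}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("points are collinear; hexagon undefined")
    u, v = vt[0], vt[1]
    ang = np.arctan2(centered @ v, centered @ u)
    order = np.argsort(ang)
    poly = pts[order]
    area = 0.0
    for i in range(6):
        a = poly[i] - centroid
        b = poly[(i + 1) % 6] - centroid
        area += 0.5 * np.linalg.norm(np.cross(a, b))
    return float(area)


# ---------------------------------------------------------------------------
# contact detection (distance + hydrogen-bond angle criterion)
# ---------------------------------------------------------------------------


@dataclass
class ContactRecord:
    frame_index: int
    residue: str
    n_contacts: int
    contact: bool
    distance_only: bool

    def __post_init__(self) -> None:
        assert self.contact == (self.n_contacts >= 1)


def detect_contacts(
    frame: StructureFrame,
    metabolite_selection: str,
    residue_selection: str,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> list[ContactRecord]:
    """Per-residue contacts between a metabolite and selected residues.

    A candidate pair is a (heavy atom, heavy atom) pair across the two
    selections within ``dist_cutoff``. If the frame contains hydrogens, a
    hydrogen covalently bound to either heavy atom must make a
    donor–hydrogen–acceptor angle within ``angle_cutoff`` of linearity
    (180°). Frames without hydrogens (e.g. coarse probes) fall back to the
    distance criterion alone, flagged ``distance_only``.
    """
    met_mask = frame.mask(metabolite_selection) & (frame.element != "H")
    res_mask = frame.mask(residue_selection) & (frame.element != "H")
    if not np.any(met_mask) or not np.any(res_mask):
        raise ValueError("empty metabolite or residue selection")
    h_mask = frame.element == "H"
    has_h = bool(np.any(h_mask))
    h_xyz = frame.coords[h_mask]

    met_xyz = frame.coords[met_mask]
    res_xyz = frame.coords[res_mask]
    res_labels = np.array(
        [f"{rn}{ri}" for rn, ri in zip(frame.resname[res_mask], frame.resnum[res_mask])]
    )

    d = np.linalg.norm(met_xyz[:, None, :] - res_xyz[None, :, :], axis=2)
    pairs = np.argwhere(d <= dist_cutoff)

    def h_bond_ok(a_xyz: np.ndarray, b_xyz: np.ndarray) -> bool:
        # any hydrogen bound to either heavy atom with D–H…A deviation
        # from linearity ≤ angle_cutoff
        for donor, acceptor in ((a_xyz, b_xyz), (b_xyz, a_xyz)):
            if h_xyz.size == 0:
                continue
            dh = np.linalg.norm(h_xyz - donor, axis=1)
            for hi in np.nonzero(dh <= H_BOND_MAX)[0]:
                h = h_xyz[hi]
                v1 = donor - h
                v2 = acceptor - h
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if abs(180.0 - ang) <= angle_cutoff:
                    return True
        return False

    counts: dict[str, int] = {lab: 0 for lab in np.unique(res_labels)}
    for mi, ri in pairs:
        if has_h and not h_bond_ok(met_xyz[mi], res_xyz[ri]):
            continue
        counts[res_labels[ri]] += 1
    return [
        ContactRecord(
            frame_index=frame.frame_index,
            residue=lab,
            n_contacts=n,
            contact=n >= 1,
            distance_only=not has_h,
        )
        for lab, n in sorted(counts.items())
    ]


def contact_table(
    frames: list[StructureFrame],
    metabolite_selection: str,
    residue_selection: str,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
) -> pd.DataFrame:
    """detect_contacts over a trajectory → tidy (frame, residue, …) table."""
    rows = []
    for f in frames:
        for rec in detect_contacts(
            f, metabolite_selection, residue_selection, dist_cutoff, angle_cutoff
        ):
            rows.append(
                {
                    "frame": rec.frame_index,
                    "residue": rec.residue,
                    "n_contacts": rec.n_contacts,
                    "contact": rec.contact,
                }
            )
    return pd.DataFrame(rows)
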