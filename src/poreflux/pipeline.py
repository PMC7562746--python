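"""End-to-end orchestration: simulate → estimate → geometry → statistics → report.

A run directory is populated stage by stage; every stage reads its inputs
from the directory, so stages can be re-run individually (the CLI exposes
them as subcommands). A manifest records the full configuration, seeds and
SHA-256 checksums of all outputs; identical config + seed reproduces
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import free_energy as fe
from . import pore_geometry as pg
from . import potentials as pot
from . import stats_kinetics as sk
from . import synthetic_data as sd

logger = logging.getLogger("poreflux")

STAGES = (
    "simulate-us",
    "wham",
    "dham",
    "errors",
    "simulate-ions",
    "density",
    "simulate-pore",
    "pore",
    "contacts",
    "stats",
    "kinetics",
    "report",
)


class MissingArtifactError(FileNotFoundError):
    pass


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the emulated study conditions.

    Window grid −26…26 Å at 0.5 Å (105 windows), spring constant
    5 kcal·mol⁻¹·Å⁻², cylinder b_max 15 Å, T 303.15 K, 5 error blocks,
    2500-frame pore ensembles, 3.5 Å / 30° contact criterion.
    """

    fixture: str = "three_well"
    seed: int = 0
    # window grid
    z_min: float = -26.0
    z_max: float = 26.0
    window_step: float = 0.5
    spring_k: float = 5.0
    # restraint
    b_max: float = 15.0
    wall_k: float = 10.0
    T: float = pot.T_DEFAULT
    # Brownian dynamics
    n_steps: int = 20_000
    dt: float = 0.02
    D: float = 0.2
    sample_stride: int = 2
    n_ions: int = 7
    # estimation
    bin_width: float = 0.5
    n_blocks: int = 5
    dham_lag: int = 1
    # pore ensemble
    n_frames: int = 2500
    ring_radius_mean: float = 3.0
    breathing_sd: float = 0.6
    atom_vdw: float = 1.7
    contact_dilation: float = 1.0
    contact_fraction: float = 0.3
    contact_residue: str = "LYS36"
    pore_measure_frames: int = 250  # equidistant subset measured geometrically
    # contact criterion
    dist_cutoff: float = 3.5
    angle_cutoff: float = 30.0
    # kinetics
    barrierless_reference: str = "HCO3-"

    def __post_init__(self) -> None:
        if self.fixture not in pot.FIXTURES:
            raise ValueError(
                f"unknown fixture {self.fixture!r}; available: {sorted(pot.FIXTURES)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def bin_edges(self) -> np.ndarray:
        half = self.bin_width / 2.0
        return np.arange(
            self.z_min - half, self.z_max + half + 1e-9, self.bin_width
        )

    def windows(self) -> list[pot.HarmonicBias]:
        return pot.place_windows(self.z_min, self.z_max, self.window_step, self.spring_k)

    def restraint(self) -> pot.CylinderRestraint:
        return pot.CylinderRestraint(b_max=self.b_max, wall_k=self.wall_k)

    def sim_spec(self) -> sd.SimulationSpec:
        return sd.SimulationSpec(
            model=pot.get_fixture(self.fixture),
            bias=None,
            restraint=self.restraint(),
            n_steps=self.n_steps,
            dt=self.dt,
            D=self.D,
            T=self.T,
            seed=self.seed,
            sample_stride=self.sample_stride,
        )


def _profile_csv(profile: fe.FreeEnergyProfile, path: Path) -> None:
    df = pd.DataFrame(
        {
            "z": np.asarray(profile.bin_centers),
            "G": profile.G,
            "stderr": profile.stderr
            if profile.stderr is not None
            else np.full(len(profile.G), np.nan),
            "n_eff": profile.n_eff,
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")


def _stage(name):
    def deco(fn):
        def wrapped(config: RunConfig, rundir: Path):
            t0 = _time.perf_counter()
            logger.info("stage %s: start", name)
            out = fn(config, rundir)
            logger.info("stage %s: done in %.1f s", name, _time.perf_counter() - t0)
            return out

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


@_stage("simulate-us")
def stage_simulate_us(config: RunConfig, rundir: Path) -> None:
    model = pot.get_fixture(config.fixture)
    windows = sd.generate_us_dataset(
        model, config.windows(), config.restraint(), config.sim_spec(), seed=config.seed
    )
    wdir = rundir / "windows"
    wdir.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(windows):
        sd.write_window(w, wdir / f"window_{i:03d}.tsv")


def _load_windows(rundir: Path) -> list[fe.UmbrellaWindowData]:
    wdir = rundir / "windows"
    files = sorted(wdir.glob("window_*.tsv")) if wdir.is_dir() else []
    if not files:
        raise MissingArtifactError(f"no window files under {wdir}; run simulate-us")
    return [sd.read_window(f) for f in files]


@_stage("wham")
def stage_wham(config: RunConfig, rundir: Path) -> None:
    windows = _load_windows(rundir)
    prof = fe.wham_1d(windows, config.bin_edges())
    (rundir / "profiles").mkdir(exist_ok=True)
    _profile_csv(prof, rundir / "profiles" / "wham_1d.csv")


@_stage("dham")
def stage_dham(config: RunConfig, rundir: Path) -> None:
    windows = _load_windows(rundir)
    prof = fe.dham_1d(windows, config.bin_edges(), lag=config.dham_lag)
    (rundir / "profiles").mkdir(exist_ok=True)
    _profile_csv(prof, rundir / "profiles" / "dham_1d.csv")


@_stage("errors")
def stage_errors(config: RunConfig, rundir: Path) -> None:
    windows = _load_windows(rundir)
    prof = fe.split_block_errors(
        windows, n_blocks=config.n_blocks, bin_edges=config.bin_edges()
    )
    (rundir / "profiles").mkdir(exist_ok=True)
    _profile_csv(prof, rundir / "profiles" / "wham_blocks.csv")
    feats = fe.profile_features(prof)
    with open(rundir / "profiles" / "extrema.json", "w") as fh:
        json.dump(
            [
                {"z": f.z, "G": f.G, "kind": f.kind, "barrier": f.barrier}
                for f in feats
            ],
            fh,
            indent=2,
        )


@_stage("simulate-ions")
def stage_simulate_ions(config: RunConfig, rundir: Path) -> None:
    model = pot.get_fixture(config.fixture)
    ions = sd.simulate_free_ions(
        model, config.restraint(), config.n_ions, config.sim_spec(),
        seed=config.seed + 10_000,
    )
    idir = rundir / "ions"
    idir.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(ions):
        sd.write_window(t, idir / f"ion_{i:02d}.tsv")


@_stage("density")
def stage_density(config: RunConfig, rundir: Path) -> None:
    idir = rundir / "ions"
    files = sorted(idir.glob("ion_*.tsv")) if idir.is_dir() else []
    if not files:
        raise MissingArtifactError(f"no ion trajectories under {idir}; run simulate-ions")
    trajs = [sd.read_window(f) for f in files]
    prof = fe.density_free_energy(trajs, config.bin_edges(), T=config.T)
    (rundir / "profiles").mkdir(exist_ok=True)
    _profile_csv(prof, rundir / "profiles" / "ion_density.csv")


@_stage("simulate-pore")
def stage_simulate_pore(config: RunConfig, rundir: Path) -> None:
    spec = sd.PoreEnsembleSpec(
        n_frames=config.n_frames,
        ring_radius_mean=config.ring_radius_mean,
        breathing_sd=config.breathing_sd,
        atom_vdw=config.atom_vdw,
        contact_dilation=config.contact_dilation,
        contact_fraction=config.contact_fraction,
        contact_residue=config.contact_residue,
        seed=config.seed + 20_000,
    )
    frames, truth = sd.generate_pore_ensemble(spec)
    pdir = rundir / "pore"
    pdir.mkdir(parents=True, exist_ok=True)
    pg.write_pdb(frames, pdir / "ensemble.pdb")
    truth.to_csv(pdir / "truth.csv", index=False, float_format="%.8g")


def _load_ensemble(rundir: Path) -> list[pg.StructureFrame]:
    path = rundir / "pore" / "ensemble.pdb"
    if not path.exists():
        raise MissingArtifactError(f"missing {path}; run simulate-pore")
    return pg.read_pdb(path)


@_stage("pore")
def stage_pore(config: RunConfig, rundir: Path) -> None:
    frames = _load_ensemble(rundir)
    step = max(1, len(frames) // config.pore_measure_frames)
    rows = []
    for f in frames[::step]:
        prof = pg.pore_profile(
            f, z_range=(-12.0, 7.0), z_step=1.0, selection="not resname LIG"
        )
        z_min, diam = pg.min_constriction(prof)
        rows.append({"frame": f.frame_index, "z_min": z_min, "diameter": diam})
    pd.DataFrame(rows).to_csv(
        rundir / "pore" / "diameters.csv", index=False, float_format="%.8g"
    )


@_stage("contacts")
def stage_contacts(config: RunConfig, rundir: Path) -> None:
    frames = _load_ensemble(rundir)
    table = pg.contact_table(
        frames,
        "resname LIG",
        "resname ARG SER LYS",
        dist_cutoff=config.dist_cutoff,
        angle_cutoff=config.angle_cutoff,
    )
    table.to_csv(rundir / "pore" / "contacts.csv", index=False)


@_stage("stats")
def stage_stats(config: RunConfig, rundir: Path) -> None:
    pdir = rundir / "pore"
    truth_path = pdir / "truth.csv"
    contacts_path = pdir / "contacts.csv"
    for p in (truth_path, contacts_path):
        if not p.exists():
            raise MissingArtifactError(f"missing {p}")
    truth = pd.read_csv(truth_path)
    contacts = pd.read_csv(contacts_path)
    diam = truth.drop_duplicates("frame").set_index("frame")["true_diameter"]
    result = sk.compare_conditioned(diam, contacts)
    result.to_csv(pdir / "conditioned_stats.csv", index=False, float_format="%.6g")


@_stage("kinetics")
def stage_kinetics(config: RunConfig, rundir: Path) -> None:
    extrema_path = rundir / "profiles" / "extrema.json"
    if not extrema_path.exists():
        raise MissingArtifactError(f"missing {extrema_path}; run errors")
    with open(extrema_path) as fh:
        feats = json.load(fh)
    barriers = [f for f in feats if f["kind"] == "maximum" and f["barrier"] is not None]
    out = []
    for f in barriers:
        rr = sk.rate_ratio(
            f["barrier"], 0.0, T=config.T,
            label_a=f"{config.fixture}@z={f['z']:g}",
            label_b=config.barrierless_reference,
        )
        out.append(asdict(rr))
    with open(rundir / "kinetics.json", "w") as fh:
        json.dump(out, fh, indent=2)


@_stage("report")
def stage_report(config: RunConfig, rundir: Path) -> str:
    lines = [f"poreflux run report — fixture {config.fixture}, seed {config.seed}", ""]
    warn = []

    prof_path = rundir / "profiles" / "wham_blocks.csv"
    if prof_path.exists():
        with open(rundir / "profiles" / "extrema.json") as fh:
            feats = json.load(fh)
        model = pot.get_fixture(config.fixture)
        lines.append("free-energy extrema (WHAM, 5-block mean ± SEM):")
        for f in feats:
            true_u = pot.evaluate_pmf(model, f["z"])
            extra = (
                f"  barrier ΔG‡ = {f['barrier']:.3f}" if f["barrier"] is not None else ""
            )
            lines.append(
                f"  {f['kind']:8s} z = {f['z']:7.2f} Å  G = {f['G']:7.3f} "
                f"(ground truth U = {true_u:7.3f}) kcal/mol{extra}"
            )
        lines.append("")
    else:
        warn.append("free-energy stages not run; profile sections omitted")

    kin_path = rundir / "kinetics.json"
    if kin_path.exists():
        with open(kin_path) as fh:
            kin = json.load(fh)
        lines.append("rate ratios vs barrierless reference (constant prefactor):")
        for k in kin:
            lines.append(
                f"  {k['numerator']} / {k['denominator']}: "
                f"ΔΔG‡ = {k['ddG']:.3f} kcal/mol → ratio {k['ratio']:.3e}"
            )
        lines.append("")

    stats_path = rundir / "pore" / "conditioned_stats.csv"
    if stats_path.exists():
        df = pd.read_csv(stats_path)
        lines.append("contact-conditioned pore diameters (Wilcoxon rank-sum):")
        for _, r in df.iterrows():
            if r["insufficient"]:
                lines.append(
                    f"  {r['residue']}: insufficient contacts "
                    f"(n_contact={r['n_contact']}, n_nocontact={r['n_nocontact']})"
                )
            else:
                flag = "significant" if r["significant"] else "n.s."
                lines.append(
                    f"  {r['residue']}: median {r['median_contact']:.2f} vs "
                    f"{r['median_nocontact']:.2f} Å, p = {r['p']:.3g} ({flag})"
                )
        lines.append("")

    diam_path = rundir / "pore" / "diameters.csv"
    truth_path = rundir / "pore" / "truth.csv"
    if diam_path.exists() and truth_path.exists():
        meas = pd.read_csv(diam_path)
        truth = pd.read_csv(truth_path).drop_duplicates("frame").set_index("frame")
        joined = meas.set_index("frame").join(truth["true_diameter"])
        err = np.abs(joined["diameter"] - joined["true_diameter"])
        lines.append(
            f"measured vs planted constriction diameters over {len(meas)} frames: "
            f"max |Δ| = {err.max():.4f} Å, "
            f"r = {np.corrcoef(joined['diameter'], joined['true_diameter'])[0, 1]:.4f}"
        )
        lines.append("")

    if warn:
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in warn)
    text = "\n".join(lines) + "\n"
    (rundir / "report.txt").write_text(text)
    return text


_STAGE_FUNCS = {
    "simulate-us": stage_simulate_us,
    "wham": stage_wham,
    "dham": stage_dham,
    "errors": stage_errors,
    "simulate-ions": stage_simulate_ions,
    "density": stage_density,
    "simulate-pore": stage_simulate_pore,
    "pore": stage_pore,
    "contacts": stage_contacts,
    "stats": stage_stats,
    "kinetics": stage_kinetics,
    "report": stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, rundir, stages: tuple[str, ...] = STAGES
) -> Path:
    """Execute stages in dependency order; write a checksum manifest."""
    from . import __version__

    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    for s in stages:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; known: {STAGES}")
    for s in STAGES:  # canonical order regardless of input order
        if s in stages:
            _STAGE_FUNCS[s](config, rundir)
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "stages": [s for s in STAGES if s in stages],
        "checksums": {
            str(p.relative_to(rundir)): _sha256(p)
            for p in sorted(rundir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return rundir
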