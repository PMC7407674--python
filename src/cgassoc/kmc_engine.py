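"""Rigid-body kinetic Monte Carlo engine for protein-protein association.

Each trajectory starts from a random configuration of the two partners in a
periodic cubic box (uniform centers, uniform random orientations, resampled
until clash-free).  Every step, both proteins undergo a joint rigid-body
diffusion move (Gaussian translation with per-axis standard deviation
``sqrt(2 D_t dt)``; rotation about a uniform random axis by a Gaussian angle
with standard deviation ``sqrt(2 D_r dt)``), accepted or rejected as a single
Metropolis decision on the total intermolecular energy (kT units, so the
Metropolis temperature is 1).  After each step, a combinable set of encounter
criteria is evaluated: number and percentage of restored native contacts
(a native contact counts as restored when its SC-SC distance is within
``contact_tolerance`` of the native distance), complex RMSD, interface
distance, and total energy.  When all active criteria pass, an encounter
complex has formed and the trajectory terminates (unless termination is
disabled for landscape scans).

Translational and rotational diffusion constants default to Stokes-Einstein
values for the protein's hydrodynamic radius (0.9 Rg + 4 A) in water at
298 K; both can be overridden.  The absolute diffusion scale only shifts the
effective time unit; rate estimates are rescaled downstream against the
benchmark's probability range.

All randomness flows through ``numpy`` generators seeded per trajectory
(``base_seed + trajectory_index``), making ensembles bitwise reproducible
and order-independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import CoarseProtein, NativeContactMap
from .constants import KT_JOULES, WATER_VISCOSITY_PA_S
from .forcefield import (
    HybridForceField,
    contact_distances,
    energy_components,
    pair_distances,
)
from .traj_analysis import complex_rmsd_state

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionParams",
    "AssociationCriteria",
    "SimulationConfig",
    "TrajectoryRecord",
    "EnsembleResult",
    "InitializationError",
    "random_initial_configuration",
    "diffusion_move",
    "metropolis_accept",
    "check_association",
    "run_trajectory",
    "run_ensemble",
    "write_ensemble_summary",
    "write_run_metadata",
]


class InitializationError(RuntimeError):
    """Could not place the two proteins without steric clash."""


@dataclass(frozen=True)
class DiffusionParams:
    """Rigid-body diffusion constants of one protein.

    ``d_trans`` in A^2/ns, ``d_rot`` in rad^2/ns.
    """

    d_trans: float
    d_rot: float

    def __post_init__(self) -> None:
        if self.d_trans < 0 or self.d_rot < 0:
            raise ValueError("diffusion constants must be non-negative")

    @classmethod
    def stokes_einstein(
        cls,
        hydrodynamic_radius: float,
        viscosity: float = WATER_VISCOSITY_PA_S,
        kt: float = KT_JOULES,
    ) -> "DiffusionParams":
        """Stokes-Einstein estimates for a sphere of the given radius (A).

        ``D_t = kT / (6 pi eta R)`` and ``D_r = kT / (8 pi eta R^3)``,
        converted to A^2/ns and rad^2/ns.
        """
        r_m = hydrodynamic_radius * 1e-10
        d_t = kt / (6.0 * np.pi * viscosity * r_m) * 1e11  # m^2/s -> A^2/ns
        d_r = kt / (8.0 * np.pi * viscosity * r_m**3) * 1e-9  # rad^2/s -> rad^2/ns
        return cls(d_t, d_r)


@dataclass
class AssociationCriteria:
    """Conjunctive thresholds defining encounter-complex formation.

    Any threshold set to ``None`` is inactive; at least one must be active.
    ``min_contact_fraction`` is a percentage of the native contact count.
    """

    min_native_contacts: int | None = 3
    min_contact_fraction: float | None = None
    max_rmsd: float | None = None
    max_interface_distance: float | None = None
    max_energy: float | None = None
    contact_tolerance: float = 2.0

    def __post_init__(self) -> None:
        if self.contact_tolerance <= 0:
            raise ValueError("contact_tolerance must be positive")
        if not self.active():
            raise ValueError("at least one association criterion must be active")
        for name in ("min_native_contacts", "min_contact_fraction", "max_rmsd",
                     "max_interface_distance", "max_energy"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite")

    def active(self) -> list[str]:
        return [
            name
            for name in ("min_native_contacts", "min_contact_fraction", "max_rmsd",
                         "max_interface_distance", "max_energy")
            if getattr(self, name) is not None
        ]

    @property
    def needs_rmsd(self) -> bool:
        return self.max_rmsd is not None

    @property
    def needs_energy(self) -> bool:
        return self.max_energy is not None


@dataclass
class SimulationConfig:
    """Run-level settings of the KMC simulation.

    Defaults follow the standard protocol: a 100 A (10 nm) periodic cubic
    box, 10^3 steps of 1 ns each, and 10^4 trajectories per complex.
    """

    box_edge: float = 100.0
    n_steps: int = 1000
    dt: float = 1.0
    n_trajectories: int = 10_000
    base_seed: int = 0
    record_every: int = 1
    criteria: AssociationCriteria = field(default_factory=AssociationCriteria)
    terminate_on_association: bool = True
    record_rmsd: bool = True
    record_diagnostics: bool = False
    max_init_attempts: int = 1000

    def __post_init__(self) -> None:
        if min(self.box_edge, self.n_steps, self.dt, self.n_trajectories) <= 0:
            raise ValueError("box_edge, n_steps, dt and n_trajectories must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class TrajectoryRecord:
    """Outcome and traces of a single trajectory."""

    seed: int
    associated: bool
    association_step: int | None
    energy_trace: np.ndarray
    rmsd_trace: np.ndarray | None
    final_receptor_pose: tuple[np.ndarray, np.ndarray]
    final_ligand_pose: tuple[np.ndarray, np.ndarray]
    final_energy: float
    final_rmsd: float | None
    final_native_contacts: int
    diagnostics: dict[str, np.ndarray] | None = None


@dataclass
class EnsembleResult:
    """A trajectory ensemble and its association probability."""

    records: list[TrajectoryRecord]
    probability: float
    n_associated: int
    config: SimulationConfig


# ---------------------------------------------------------------------------
# elementary moves
# ---------------------------------------------------------------------------

def _random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _has_clash(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    ff: HybridForceField,
    box_edge: float,
) -> bool:
    r = pair_distances(receptor.positions, ligand.positions, box_edge)
    sigma = ff.physics.sigma_matrix(receptor.site_kinds, ligand.site_kinds)
    return bool(np.any(r < sigma))


def random_initial_configuration(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    config: SimulationConfig,
    rng: np.random.Generator,
    ff: HybridForceField | None = None,
) -> tuple[CoarseProtein, CoarseProtein]:
    """Place both proteins uniformly in the box with uniform orientations.

    The whole placement is resampled until the configuration is free of
    steric clashes (no inter-protein site pair below its contact radius).
    """
    ff = ff or HybridForceField()
    rec, lig = receptor.copy(), ligand.copy()
    for _ in range(config.max_init_attempts):
        for protein in (rec, lig):
            center = rng.uniform(0.0, config.box_edge, size=3)
            protein.set_pose(_random_rotation_matrix(rng), center)
        if not _has_clash(rec, lig, ff, config.box_edge):
            return rec, lig
    raise InitializationError(
        f"no clash-free placement in {config.max_init_attempts} attempts "
        f"(box edge {config.box_edge} A too small?)"
    )


def diffusion_move(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    diff_receptor: DiffusionParams,
    diff_ligand: DiffusionParams,
    dt: float,
    rng: np.random.Generator,
    box_edge: float,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Propose one joint rigid-body diffusion step for both proteins.

    Returns the two proposed poses ``(rotation, center)`` without mutating
    the inputs; centers are wrapped back into the box.
    """
    poses = []
    for protein, diff in ((receptor, diff_receptor), (ligand, diff_ligand)):
        shift = rng.normal(0.0, np.sqrt(2.0 * diff.d_trans * dt), size=3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, np.sqrt(2.0 * diff.d_rot * dt))
        r_move = Rotation.from_rotvec(axis * angle).as_matrix()
        new_center = np.mod(protein.center + shift, box_edge)
        poses.append((r_move @ protein.rotation, new_center))
    return poses[0], poses[1]


def metropolis_accept(e_old: float, e_new: float, rng: np.random.Generator) -> bool:
    """Accept with probability ``min(1, exp(-(e_new - e_old)))`` (energies in kT)."""
    delta = e_new - e_old
    if delta <= 0.0:
        return True
    return bool(rng.random() < np.exp(-delta))


def check_association(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    contacts: NativeContactMap,
    criteria: AssociationCriteria,
    *,
    box_edge: float | None = None,
    energy: float | None = None,
    native: tuple[CoarseProtein, CoarseProtein] | None = None,
    rmsd: float | None = None,
) -> tuple[bool, dict[str, float]]:
    """Evaluate the encounter criteria on the current configuration.

    ``energy`` (total, kT) must be supplied when an energy criterion is
    active; RMSD is computed from ``native`` reference proteins unless given
    directly.  Returns (associated, diagnostics) where diagnostics carries
    each criterion's current value.
    """
    r = contact_distances(receptor, ligand, contacts, box_edge)
    restored = np.abs(r - contacts.r0) < criteria.contact_tolerance
    n_restored = int(restored.sum())
    fraction = 100.0 * n_restored / contacts.n_contacts
    interface_distance = float(r.min())

    diag: dict[str, float] = {
        "native_contacts": float(n_restored),
        "contact_fraction": fraction,
        "interface_distance": interface_distance,
    }

    ok = True
    if criteria.min_native_contacts is not None:
        ok &= n_restored >= criteria.min_native_contacts
    if criteria.min_contact_fraction is not None:
        ok &= fraction >= criteria.min_contact_fraction
    if criteria.max_interface_distance is not None:
        ok &= interface_distance <= criteria.max_interface_distance
    if criteria.needs_rmsd or rmsd is not None:
        if rmsd is None:
            if native is None:
                raise ValueError("RMSD criterion requires native reference proteins")
            rmsd = complex_rmsd_state(receptor, ligand, *native, box_edge=box_edge)
        diag["rmsd"] = float(rmsd)
        if criteria.max_rmsd is not None:
            ok &= rmsd <= criteria.max_rmsd
    if criteria.needs_energy:
        if energy is None:
            raise ValueError("energy criterion requires the current total energy")
        ok &= energy <= criteria.max_energy
    if energy is not None:
        diag["energy"] = float(energy)
    return bool(ok), diag


# ---------------------------------------------------------------------------
# trajectories and ensembles
# ---------------------------------------------------------------------------

def _default_diffusion(protein: CoarseProtein) -> DiffusionParams:
    return DiffusionParams.stokes_einstein(protein.hydrodynamic_radius)


def run_trajectory(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    ff: HybridForceField,
    contacts: NativeContactMap,
    config: SimulationConfig,
    seed: int,
    diffusion: tuple[DiffusionParams, DiffusionParams] | None = None,
) -> TrajectoryRecord:
    """Run one association trajectory from a fresh random configuration.

    ``receptor`` and ``ligand`` must be in their native poses; they serve as
    the reference for RMSD and are not mutated.  The result is bitwise
    reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    diff_rec, diff_lig = diffusion or (_default_diffusion(receptor), _default_diffusion(ligand))
    native = (receptor, ligand)
    box = config.box_edge
    criteria = config.criteria
    record_rmsd = config.record_rmsd or criteria.needs_rmsd or config.record_diagnostics

    rec, lig = random_initial_configuration(receptor, ligand, config, rng, ff)
    energy = energy_components(rec, lig, ff, contacts, box).total(ff.omega)

    energies: list[float] = []
    rmsds: list[float] = []
    diag_rows: list[dict[str, float]] = []
    associated = False
    association_step: int | None = None
    n_restored = 0

    def _observe(step: int) -> tuple[bool, dict[str, float]]:
        nonlocal n_restored
        rmsd = (
            complex_rmsd_state(rec, lig, *native, box_edge=box) if record_rmsd else None
        )
        assoc, diag = check_association(
            rec, lig, contacts, criteria,
            box_edge=box, energy=energy, native=native, rmsd=rmsd,
        )
        n_restored = int(diag["native_contacts"])
        if step % config.record_every == 0:
            energies.append(energy)
            if record_rmsd:
                rmsds.append(diag.get("rmsd", np.nan))
            if config.record_diagnostics:
                diag_rows.append(diag)
        return assoc, diag

    assoc, _ = _observe(0)
    if assoc:
        associated, association_step = True, 0

    step = 0
    while step < config.n_steps and not (associated and config.terminate_on_association):
        step += 1
        old_poses = (rec.pose, lig.pose)
        pose_rec, pose_lig = diffusion_move(rec, lig, diff_rec, diff_lig, config.dt, rng, box)
        rec.set_pose(*pose_rec)
        lig.set_pose(*pose_lig)
        e_new = energy_components(rec, lig, ff, contacts, box).total(ff.omega)
        if metropolis_accept(energy, e_new, rng):
            energy = e_new
        else:
            rec.set_pose(*old_poses[0])
            lig.set_pose(*old_poses[1])
        assoc, _ = _observe(step)
        if assoc and not associated:
            associated, association_step = True, step

    final_rmsd = rmsds[-1] if rmsds else (
        complex_rmsd_state(rec, lig, *native, box_edge=box) if record_rmsd else None
    )
    diagnostics = None
    if config.record_diagnostics:
        diagnostics = {
            key: np.array([row.get(key, np.nan) for row in diag_rows])
            for key in ("native_contacts", "contact_fraction", "interface_distance",
                        "rmsd", "energy")
        }
    return TrajectoryRecord(
        seed=seed,
        associated=associated,
        association_step=association_step,
        energy_trace=np.array(energies),
        rmsd_trace=np.array(rmsds) if record_rmsd else None,
        final_receptor_pose=rec.pose,
        final_ligand_pose=lig.pose,
        final_energy=energy,
        final_rmsd=final_rmsd,
        final_native_contacts=n_restored,
        diagnostics=diagnostics,
    )


def run_ensemble(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    ff: HybridForceField,
    contacts: NativeContactMap,
    config: SimulationConfig,
    diffusion: tuple[DiffusionParams, DiffusionParams] | None = None,
) -> EnsembleResult:
    """Run ``n_trajectories`` independent trajectories (seed = base_seed + t).

    The association probability is the fraction of trajectories that formed
    an encounter complex.  Trajectories are independent given their seeds, so
    any execution order yields the same set of records.
    """
    if config.n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    if diffusion is None:
        diffusion = (_default_diffusion(receptor), _default_diffusion(ligand))
    records = [
        run_trajectory(receptor, ligand, ff, contacts, config, config.base_seed + t, diffusion)
        for t in range(config.n_trajectories)
    ]
    n_assoc = sum(r.associated for r in records)
    return EnsembleResult(records, n_assoc / config.n_trajectories, n_assoc, config)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_ensemble_summary(result: EnsembleResult, path: str | Path) -> None:
    """Per-trajectory summary TSV (one row per trajectory)."""
    with open(path, "w") as fh:
        fh.write("seed\tassociated\tassociation_step\tfinal_energy\tfinal_rmsd\tfinal_contacts\n")
        for r in result.records:
            step = "" if r.association_step is None else str(r.association_step)
            rmsd = "" if r.final_rmsd is None else f"{r.final_rmsd:.3f}"
            fh.write(
                f"{r.seed}\t{int(r.associated)}\t{step}\t{r.final_energy:.4f}"
                f"\t{rmsd}\t{r.final_native_contacts}\n"
            )


def write_run_metadata(
    path: str | Path,
    config: SimulationConfig,
    ff: HybridForceField,
    probability: float | None = None,
) -> None:
    """Echo the run configuration (and outcome) as JSON."""
    meta = {
        "config": {
            "box_edge": config.box_edge,
            "n_steps": config.n_steps,
            "dt": config.dt,
            "n_trajectories": config.n_trajectories,
            "base_seed": config.base_seed,
            "terminate_on_association": config.terminate_on_association,
            "criteria": {k: getattr(config.criteria, k) for k in (
                "min_native_contacts", "min_contact_fraction", "max_rmsd",
                "max_interface_distance", "max_energy", "contact_tolerance")},
        },
        "forcefield": {
            "omega": ff.omega,
            "stat_mode": ff.stat_mode,
            "dielectric": ff.physics.dielectric,
            "debye_length": ff.physics.debye_length,
            "w_alpha": ff.physics.w_alpha,
            "epsilon_rep": ff.physics.epsilon_rep,
            "table_provenance": ff.table.provenance,
        },
    }
    if probability is not None:
        meta["association_probability"] = probability
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
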