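"""Structural and energetic analysis of trajectory ensembles.

The central quantity is the complex RMSD: the receptor C-alpha trace of a
configuration is superposed onto the native receptor by a least-squares rigid
fit (Kabsch), and the RMSD is then taken over the ligand C-alpha positions.
This isolates the binding-pose error from trivial global motion.  An all-CA
variant is available via ``mode="all"``.

Analysis uses the ligand's nearest periodic image relative to the receptor,
so a partner that crossed the box boundary is not counted as artificially
distant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cg_model import CoarseProtein

if TYPE_CHECKING:  # pragma: no cover
    from .kmc_engine import TrajectoryRecord

__all__ = [
    "superpose",
    "complex_rmsd",
    "complex_rmsd_state",
    "energy_rmsd_correlation",
    "ligand_cloud",
    "LigandCloud",
]


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Returns ``(R, t)`` with ``x -> R @ x + t`` minimizing the RMSD between
    the transformed mobile points and the target points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    r_mat = rot.as_matrix()
    return r_mat, tc - r_mat @ mc


def complex_rmsd(
    rec_ca: np.ndarray,
    lig_ca: np.ndarray,
    native_rec_ca: np.ndarray,
    native_lig_ca: np.ndarray,
    mode: str = "ligand",
) -> float:
    """RMSD of a configuration from the native complex (A).

    Receptor CAs are superposed onto the native receptor; the RMSD is then
    computed over the ligand CAs (``mode="ligand"``) or over all CAs
    (``mode="all"``).
    """
    r_mat, t = superpose(rec_ca, native_rec_ca)
    lig_fit = lig_ca @ r_mat.T + t
    if mode == "ligand":
        diff = lig_fit - native_lig_ca
    elif mode == "all":
        rec_fit = rec_ca @ r_mat.T + t
        diff = np.vstack([rec_fit - native_rec_ca, lig_fit - native_lig_ca])
    else:
        raise ValueError("mode must be 'ligand' or 'all'")
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def _nearest_image_positions(
    receptor: CoarseProtein, ligand: CoarseProtein, box_edge: float | None
) -> np.ndarray:
    """Ligand CA positions shifted to the periodic image nearest the receptor."""
    pos = ligand.ca_positions
    if box_edge is None:
        return pos
    sep = ligand.center - receptor.center
    shift = box_edge * np.round(sep / box_edge)
    return pos - shift


def complex_rmsd_state(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    native_receptor: CoarseProtein,
    native_ligand: CoarseProtein,
    box_edge: float | None = None,
    mode: str = "ligand",
) -> float:
    """Complex RMSD of the current poses of two coarse proteins."""
    return complex_rmsd(
        receptor.ca_positions,
        _nearest_image_positions(receptor, ligand, box_edge),
        native_receptor.ca_positions,
        native_ligand.ca_positions,
        mode=mode,
    )


def energy_rmsd_correlation(records: Sequence["TrajectoryRecord"]) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between final energy and final RMSD.

    Computed over the final configurations of *all* trajectories, associated
    or not; a positive value is the signature of a funnel-like interaction
    landscape (energies decrease with structural similarity to native).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    table = pd.DataFrame(
        {
            "seed": [r.seed for r in records],
            "final_energy": [r.final_energy for r in records],
            "final_rmsd": [r.final_rmsd for r in records],
            "associated": [r.associated for r in records],
        }
    )
    e, d = table["final_energy"].to_numpy(), table["final_rmsd"].to_numpy()
    if np.ptp(e) == 0 or np.ptp(d) == 0:
        raise ValueError("zero variance in energy or RMSD")
    pcc = float(np.corrcoef(e, d)[0, 1])
    return pcc, table


@dataclass
class LigandCloud:
    """Final ligand centers of mass in the receptor-aligned native frame."""

    points: np.ndarray  # (n, 3)
    associated: np.ndarray  # (n,) bool
    native_point: np.ndarray  # (3,)
    seeds: np.ndarray  # (n,) trajectory seeds of the sampled records

    @property
    def distances_to_native(self) -> np.ndarray:
        return np.linalg.norm(self.points - self.native_point, axis=1)


def ligand_cloud(
    records: Sequence["TrajectoryRecord"],
    native_receptor: CoarseProtein,
    native_ligand: CoarseProtein,
    sample_size: int = 1000,
    seed: int = 0,
    box_edge: float | None = None,
) -> LigandCloud:
    """Spatial distribution of final ligand positions around the native pose.

    Each sampled record's final receptor is superposed onto the native
    receptor and the same transform is applied to the final ligand center of
    mass (nearest periodic image relative to the receptor).  Subsampling is
    deterministic given ``seed``.
    """
    if not records:
        raise ValueError("no records")
    rng = np.random.default_rng(seed)
    if sample_size >= len(records):
        if sample_size > len(records):
            warnings.warn(
                f"sample_size {sample_size} exceeds record count {len(records)}; using all",
                stacklevel=2,
            )
        chosen = list(records)
    else:
        idx = rng.choice(len(records), size=sample_size, replace=False)
        chosen = [records[i] for i in sorted(idx)]

    rec = native_receptor.copy()
    lig = native_ligand.copy()
    points, assoc, seeds = [], [], []
    for record in chosen:
        rec.set_pose(*record.final_receptor_pose)
        lig.set_pose(*record.final_ligand_pose)
        lig_com = lig.center
        if box_edge is not None:
            sep = lig_com - rec.center
            lig_com = lig_com - box_edge * np.round(sep / box_edge)
        r_mat, t = superpose(rec.ca_positions, native_receptor.ca_positions)
        points.append(r_mat @ lig_com + t)
        assoc.append(record.associated)
        seeds.append(record.seed)
    return LigandCloud(
        np.array(points),
        np.array(assoc, dtype=bool),
        native_ligand.center_of_mass,
        np.array(seeds),
    )
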