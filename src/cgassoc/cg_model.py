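"""Two-site-per-residue coarse-grained protein model.

Each residue of a protein chain is reduced to two interaction sites: its
C-alpha atom and the functional center of its side chain (the centroid of the
side-chain heavy atoms; glycine's functional center coincides with its
C-alpha).  A protein is treated as a rigid body: the internal geometry is
frozen at the input coordinates and only a global rotation + translation
(the *pose*) changes during a simulation.

The native binding interface is summarized by a :class:`NativeContactMap`:
all inter-chain residue pairs whose side-chain heavy atoms approach within
``atom_cutoff`` (default 5.5 A) in the native complex, together with the
native SC-SC center distance ``r0`` of each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    BACKBONE_ATOMS,
    KYTE_DOOLITTLE,
    NONSTANDARD_ALIASES,
    RESIDUE_CHARGE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "CoarseProtein",
    "NativeContactMap",
    "ChainNotFoundError",
    "NonStandardResidueError",
    "ZeroContactsError",
    "load_coarse_protein",
    "native_contacts",
    "rotate_about",
]


class ChainNotFoundError(ValueError):
    """A requested chain ID is absent from the structure."""


class NonStandardResidueError(ValueError):
    """A polymer residue could not be mapped to one of the 20 standard types."""


class ZeroContactsError(ValueError):
    """No inter-chain residue pair satisfies the contact criterion."""


@dataclass(frozen=True)
class Site:
    """A single coarse-grained interaction site.

    Attributes
    ----------
    residue_index:
        0-based ordinal of the residue within the selected chains.
    residue_type:
        Three-letter amino-acid code.
    kind:
        ``"CA"`` or ``"SC"``.
    position:
        Cartesian coordinates, Angstrom (current pose applied).
    charge:
        Side-chain charge in elementary-charge units (0 on CA sites).
    hydropathy:
        Kyte-Doolittle score of the residue type.
    """

    residue_index: int
    residue_type: str
    kind: str
    position: np.ndarray
    charge: float
    hydropathy: float


class CoarseProtein:
    """Rigid body of 2N coarse-grained sites (N C-alpha + N side-chain centers).

    Reference coordinates are stored centered on the reference center of mass
    (unweighted mean over all 2N sites); the current pose is a rotation matrix
    plus a center position.  Applying a pose can therefore never distort
    intra-protein distances.
    """

    def __init__(
        self,
        residue_types: Sequence[str],
        ca_coords: np.ndarray,
        sc_coords: np.ndarray,
        *,
        name: str = "protein",
        chains: tuple[str, ...] = (),
        hydrodynamic_radius: float | None = None,
        charge_overrides: dict[str, float] | None = None,
    ) -> None:
        residue_types = [str(t).upper() for t in residue_types]
        unknown = sorted(set(residue_types) - set(AMINO_ACIDS))
        if unknown:
            raise NonStandardResidueError(f"unknown residue types: {unknown}")
        ca = np.asarray(ca_coords, dtype=float)
        sc = np.asarray(sc_coords, dtype=float)
        n = len(residue_types)
        if ca.shape != (n, 3) or sc.shape != (n, 3):
            raise ValueError("ca_coords and sc_coords must both have shape (n_residues, 3)")
        if n == 0:
            raise ValueError("protein must contain at least one residue")

        self.name = name
        self.chains = tuple(chains)
        self._types = tuple(residue_types)
        self._type_indices = np.array([AA_INDEX[t] for t in residue_types], dtype=int)

        charges = dict(RESIDUE_CHARGE)
        if charge_overrides:
            charges.update({k.upper(): float(v) for k, v in charge_overrides.items()})
        self._charges = np.array([charges.get(t, 0.0) for t in residue_types])
        self._hydropathies = np.array([KYTE_DOOLITTLE[t] for t in residue_types])

        ref = np.vstack([ca, sc])
        ref_com = ref.mean(axis=0)
        self._ref = ref - ref_com
        self.rotation = np.eye(3)
        self.center = ref_com.copy()

        # Rg over all sites of the reference geometry (pose-invariant).
        self._rg = float(np.sqrt((self._ref**2).sum(axis=1).mean()))
        if hydrodynamic_radius is None:
            hydrodynamic_radius = 0.9 * self._rg + 4.0
        self.hydrodynamic_radius = float(hydrodynamic_radius)

    # ------------------------------------------------------------------ sizes
    @property
    def n_residues(self) -> int:
        return len(self._types)

    @property
    def n_sites(self) -> int:
        return 2 * self.n_residues

    @property
    def residue_types(self) -> tuple[str, ...]:
        return self._types

    @property
    def type_indices(self) -> np.ndarray:
        """Residue types as indices into :data:`cgassoc.constants.AMINO_ACIDS`."""
        return self._type_indices

    @property
    def charges(self) -> np.ndarray:
        """Per-residue side-chain charge (e units)."""
        return self._charges

    @property
    def hydropathies(self) -> np.ndarray:
        return self._hydropathies

    @property
    def site_kinds(self) -> np.ndarray:
        """0 for CA sites, 1 for SC sites, in the order of :meth:`positions`."""
        n = self.n_residues
        return np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])

    # ------------------------------------------------------------------ pose
    @property
    def pose(self) -> tuple[np.ndarray, np.ndarray]:
        return self.rotation.copy(), self.center.copy()

    def set_pose(self, rotation: np.ndarray, center: np.ndarray) -> None:
        rotation = np.asarray(rotation, dtype=float)
        center = np.asarray(center, dtype=float)
        if rotation.shape != (3, 3) or center.shape != (3,):
            raise ValueError("pose is a 3x3 rotation and a 3-vector center")
        self.rotation = rotation
        self.center = center

    def translate(self, shift: np.ndarray) -> None:
        self.center = self.center + np.asarray(shift, dtype=float)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.center.copy()

    @property
    def radius_of_gyration(self) -> float:
        return self._rg

    def copy(self) -> "CoarseProtein":
        new = object.__new__(CoarseProtein)
        new.__dict__.update(self.__dict__)
        new.rotation = self.rotation.copy()
        new.center = self.center.copy()
        return new

    # ------------------------------------------------------------- positions
    @property
    def reference_positions(self) -> np.ndarray:
        """(2N, 3) reference coordinates, COM at the origin, CA block first."""
        return self._ref.copy()

    @property
    def positions(self) -> np.ndarray:
        """(2N, 3) current-pose coordinates: CA block then SC block."""
        return self._ref @ self.rotation.T + self.center

    @property
    def ca_positions(self) -> np.ndarray:
        n = self.n_residues
        return self._ref[:n] @ self.rotation.T + self.center

    @property
    def sc_positions(self) -> np.ndarray:
        n = self.n_residues
        return self._ref[n:] @ self.rotation.T + self.center

    # ------------------------------------------------------------------ misc
    def sites(self) -> list[Site]:
        pos = self.positions
        n = self.n_residues
        out = []
        for i, t in enumerate(self._types):
            out.append(Site(i, t, "CA", pos[i].copy(), 0.0, self._hydropathies[i]))
        for i, t in enumerate(self._types):
            out.append(Site(i, t, "SC", pos[n + i].copy(), self._charges[i], self._hydropathies[i]))
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Dump the coarse model (current pose) as a TSV for inspection."""
        pos = self.positions
        n = self.n_residues
        with open(path, "w") as fh:
            fh.write("residue\ttype\tsite\tx\ty\tz\tq\thp\n")
            for kind, offset in (("CA", 0), ("SC", n)):
                for i, t in enumerate(self._types):
                    x, y, z = pos[offset + i]
                    q = self._charges[i] if kind == "SC" else 0.0
                    fh.write(
                        f"{i}\t{t}\t{kind}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
                        f"\t{q:.2f}\t{self._hydropathies[i]:.1f}\n"
                    )


def rotate_about(protein: CoarseProtein, rotation: np.ndarray, origin: np.ndarray) -> None:
    """Rotate a protein rigidly about an arbitrary fixed point (in place)."""
    rotation = np.asarray(rotation, dtype=float)
    origin = np.asarray(origin, dtype=float)
    new_center = rotation @ (protein.center - origin) + origin
    protein.set_pose(rotation @ protein.rotation, new_center)


@dataclass
class NativeContactMap:
    """Interface residue pairs of the native complex.

    ``receptor_residues[k]`` / ``ligand_residues[k]`` are 0-based residue
    ordinals within each protein; ``r0[k]`` is the native SC-SC center
    distance of the pair (A).
    """

    receptor_residues: np.ndarray
    ligand_residues: np.ndarray
    r0: np.ndarray
    atom_cutoff: float = 5.5

    def __post_init__(self) -> None:
        self.receptor_residues = np.asarray(self.receptor_residues, dtype=int)
        self.ligand_residues = np.asarray(self.ligand_residues, dtype=int)
        self.r0 = np.asarray(self.r0, dtype=float)
        if not (len(self.receptor_residues) == len(self.ligand_residues) == len(self.r0)):
            raise ValueError("contact arrays must have equal length")
        if np.any(self.r0 <= 0):
            raise ValueError("native distances must be positive")

    @property
    def n_contacts(self) -> int:
        return len(self.r0)

    @property
    def interface_receptor(self) -> np.ndarray:
        """Unique receptor residues at the interface."""
        return np.unique(self.receptor_residues)

    @property
    def interface_ligand(self) -> np.ndarray:
        return np.unique(self.ligand_residues)

    def swapped(self) -> "NativeContactMap":
        """The same map with receptor/ligand labels exchanged."""
        return NativeContactMap(
            self.ligand_residues.copy(),
            self.receptor_residues.copy(),
            self.r0.copy(),
            self.atom_cutoff,
        )


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

_parser = PDBParser(QUIET=True)


def _parse_structure(pdb_file):
    name = getattr(pdb_file, "name", None) or "structure"
    return _parser.get_structure(str(name), pdb_file)


def _extract_residues(model, chains: Iterable[str], source: str):
    """Yield (residue_type, ca_coord, sc_centroid, sc_atom_coords) per residue.

    ``sc_atom_coords`` are the side-chain heavy atoms used by the 5.5 A
    interface criterion; for glycine (or residues missing every side-chain
    heavy atom) the C-alpha stands in for both the functional center and the
    contact-criterion atom set, with a logged warning in the fallback case.
    """
    chains = list(chains)
    present = {c.id for c in model}
    missing = [c for c in chains if c not in present]
    if missing:
        raise ChainNotFoundError(f"chain(s) {missing} not found in {source} (has {sorted(present)})")

    records = []
    for cid in chains:
        for res in model[cid]:
            het, _, _ = res.id
            resname = res.get_resname().strip().upper()
            if resname in AA_INDEX:
                rtype = resname
            elif resname in NONSTANDARD_ALIASES:
                rtype = NONSTANDARD_ALIASES[resname]
                logger.info("%s: mapping non-standard residue %s -> %s", source, resname, rtype)
            elif het != " ":
                continue  # solvent / ligand HETATM records
            else:
                raise NonStandardResidueError(
                    f"{source}: residue {resname} {res.id} in chain {cid} cannot be mapped"
                )
            if "CA" not in res:
                logger.warning("%s: residue %s %s lacks a CA atom; skipped", source, resname, res.id)
                continue
            ca = res["CA"].get_coord().astype(float)
            sc_atoms = [
                a.get_coord().astype(float)
                for a in res.get_atoms()
                if a.element != "H" and a.get_name().strip() not in BACKBONE_ATOMS
            ]
            if sc_atoms:
                sc = np.mean(sc_atoms, axis=0)
                sc_coords = np.array(sc_atoms)
            else:
                if rtype != "GLY":
                    logger.warning(
                        "%s: residue %s %s has no side-chain heavy atoms; SC falls back to CA",
                        source, resname, res.id,
                    )
                sc = ca.copy()
                sc_coords = ca[None, :].copy()
            records.append((rtype, ca, sc, sc_coords))
    return records


def load_coarse_protein(
    pdb_file,
    chains: Sequence[str],
    *,
    name: str | None = None,
    hydrodynamic_radius: float | None = None,
    charge_overrides: dict[str, float] | None = None,
) -> CoarseProtein:
    """Parse a PDB file and reduce the named chains to the two-site model.

    Parameters
    ----------
    pdb_file:
        Path or open text handle of a PDB file (model 1 of multi-model files).
    chains:
        Chain IDs making up this protein, in the order residues should be
        numbered.
    hydrodynamic_radius:
        Override for the default ``0.9 Rg + 4 A`` size proxy (Angstrom).
    charge_overrides:
        Optional per-residue-type charge overrides (e.g. ``{"HIS": 0.5}``).
    """
    structure = _parse_structure(pdb_file)
    model = next(structure.get_models())
    source = name or getattr(pdb_file, "name", None) or str(pdb_file)
    records = _extract_residues(model, chains, str(source))
    if not records:
        raise ValueError(f"{source}: no standard residues found in chains {list(chains)}")
    types = [r[0] for r in records]
    ca = np.array([r[1] for r in records])
    sc = np.array([r[2] for r in records])
    return CoarseProtein(
        types, ca, sc,
        name=str(name or source),
        chains=tuple(chains),
        hydrodynamic_radius=hydrodynamic_radius,
        charge_overrides=charge_overrides,
    )


def native_contacts(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    native_pdb,
    *,
    atom_cutoff: float = 5.5,
) -> NativeContactMap:
    """Extract the native interface contact map from the complex structure.

    Two residues are in contact when any pair of their side-chain heavy atoms
    is closer than ``atom_cutoff`` in the native structure.  ``native_pdb`` is
    re-parsed at atom level using the chain selections stored on the two
    coarse proteins; the residue ordering therefore matches the coarse models
    by construction.
    """
    if not receptor.chains or not ligand.chains:
        raise ValueError("receptor and ligand must carry their chain selections")
    structure = _parse_structure(native_pdb)
    model = next(structure.get_models())
    source = getattr(native_pdb, "name", None) or str(native_pdb)
    rec = _extract_residues(model, receptor.chains, str(source))
    lig = _extract_residues(model, ligand.chains, str(source))
    if len(rec) != receptor.n_residues or len(lig) != ligand.n_residues:
        raise ValueError(
            "native structure residue counts do not match the coarse proteins "
            f"({len(rec)} vs {receptor.n_residues} receptor, {len(lig)} vs {ligand.n_residues} ligand)"
        )

    ri, li, r0 = [], [], []
    for i, (_, _, sc_i, atoms_i) in enumerate(rec):
        for j, (_, _, sc_j, atoms_j) in enumerate(lig):
            d = np.linalg.norm(atoms_i[:, None, :] - atoms_j[None, :, :], axis=-1)
            if d.min() < atom_cutoff:
                ri.append(i)
                li.append(j)
                r0.append(float(np.linalg.norm(sc_i - sc_j)))
    if not ri:
        raise ZeroContactsError(
            f"{source}: no residue pair within {atom_cutoff} A between chains "
            f"{receptor.chains} and {ligand.chains} -- check the chain assignment"
        )
    return NativeContactMap(np.array(ri), np.array(li), np.array(r0), atom_cutoff)
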