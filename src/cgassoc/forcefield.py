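"""Hybrid intermolecular force field.

The total interaction energy between the two rigid binding partners is a
weighted mix of a physics-based and a statistics-based potential::

    E_tot = (1 - omega) * E_physics + omega * E_statistics

``E_physics`` contains three terms:

* screened electrostatics between charged side-chain centers (Kim-Hummer
  style distance-dependent dielectric ``D_eff = D_s * exp(r / xi)`` with
  Debye length ``xi``),
* a hydrophobic term proportional to the summed Kyte-Doolittle scores of
  side-chain pairs in contact, and
* a 12-6 excluded-volume wall whose depth ``eps`` is a step function of the
  site-kind-dependent contact radius ``sigma0`` (3.8 A CA-CA, 2.8 A CA-SC,
  2.2 A SC-SC): 5 kT inside ``sigma0``, zero outside.

``E_statistics`` is a Go-like native-topology term over the native interface
contact pairs, modulated per pair by a quasi-chemical contact potential
``u_sc(i, j)`` derived from interface contact statistics::

    u_sc(i, j) = -kT ln[ N_obs(i, j) / (chi_i * chi_j * N_obs) ]

Negative ``u_sc`` (pairs observed more often than the random-mixing
expectation) is attractive; positive ``u_sc`` is repulsive.  Three
functional forms are available via ``stat_mode`` (``x = (r0/r)^6``):

``"anchored"`` (default)
    ``|u| (x^2 - 2x)`` for attractive pairs -- a 12-6 well of depth ``|u|``
    with its minimum exactly at the native distance ``r0`` -- and
    ``u x^2`` (pure wall) for repulsive pairs.  This is the only form whose
    attractive branch is bounded below, which rigid-body sampling requires:
    the unanchored forms let a single contact pair collapse far below
    ``r0`` into an effectively infinite well and freeze the complex in a
    non-native geometry.
``"scaled"``
    ``|u| (g x^2 - f x)`` with the sign prefactors ``f = sign(-u)`` and
    ``g = -1`` for attractive pairs, ``0`` otherwise.
``"literal"``
    the unscaled ``g x^2 - f x`` form (prefactors +/-1 only, ``u`` acting
    purely as a sign).

All energies are in kT; the Metropolis temperature is therefore 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .cg_model import CoarseProtein, NativeContactMap
from .constants import AA_INDEX, AMINO_ACIDS, COULOMB_KT_A

__all__ = [
    "PhysicsParams",
    "StatPotentialTable",
    "HybridForceField",
    "EnergyComponents",
    "OverlapError",
    "electrostatic_energy",
    "hydrophobic_energy",
    "excluded_volume_energy",
    "physics_energy",
    "statistical_energy",
    "total_energy",
    "energy_components",
    "derive_usc",
    "default_table",
]


class OverlapError(ValueError):
    """Two interacting sites coincide (zero distance)."""


def minimum_image(displacements: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Fold displacement vectors to their nearest periodic image."""
    if box_edge is None:
        return displacements
    return displacements - box_edge * np.round(displacements / box_edge)


def pair_distances(pos_a: np.ndarray, pos_b: np.ndarray, box_edge: float | None) -> np.ndarray:
    """(n_a, n_b) matrix of minimum-image distances."""
    disp = minimum_image(pos_a[:, None, :] - pos_b[None, :, :], box_edge)
    return np.linalg.norm(disp, axis=-1)


@dataclass
class PhysicsParams:
    """Parameters of the physics-based potential.

    Attributes
    ----------
    dielectric:
        Solvent dielectric constant ``D_s`` (dimensionless).
    debye_length:
        Debye screening length ``xi``, Angstrom.  Use
        :meth:`debye_length_from_ionic_strength` to set it from an ionic
        strength in mol/L.
    w_alpha:
        Hydrophobic weight (kT per unit of summed Kyte-Doolittle score).
    epsilon_rep:
        Excluded-volume step depth, kT.
    sigma_ca_ca, sigma_ca_sc, sigma_sc_sc:
        Contact radii per site-kind pair, Angstrom.
    hp_cutoff:
        SC-SC distance below which a pair counts as a hydrophobic contact, A.
    elec_cutoff:
        Electrostatic interaction cutoff, A.
    hydrophobic_attractive:
        If True (default) hydrophobic burial of high-score pairs lowers the
        energy (the summed-score term enters with a minus sign).
    """

    dielectric: float = 80.0
    debye_length: float = 10.0
    w_alpha: float = 0.1
    epsilon_rep: float = 5.0
    sigma_ca_ca: float = 3.8
    sigma_ca_sc: float = 2.8
    sigma_sc_sc: float = 2.2
    hp_cutoff: float = 7.5
    elec_cutoff: float = 30.0
    hydrophobic_attractive: bool = True

    def __post_init__(self) -> None:
        for name in ("debye_length", "sigma_ca_ca", "sigma_ca_sc", "sigma_sc_sc",
                     "hp_cutoff", "elec_cutoff", "dielectric"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsilon_rep < 0:
            raise ValueError("epsilon_rep must be >= 0")

    @staticmethod
    def debye_length_from_ionic_strength(ionic_strength_molar: float) -> float:
        """Debye length (A) of an aqueous 1:1 electrolyte at 298 K."""
        if ionic_strength_molar <= 0:
            raise ValueError("ionic strength must be positive")
        return 3.04 / np.sqrt(ionic_strength_molar)

    def sigma_matrix(self, kinds_a: np.ndarray, kinds_b: np.ndarray) -> np.ndarray:
        """(n_a, n_b) contact radii from site kinds (0 = CA, 1 = SC)."""
        table = np.array([
            [self.sigma_ca_ca, self.sigma_ca_sc],
            [self.sigma_ca_sc, self.sigma_sc_sc],
        ])
        return table[np.asarray(kinds_a)[:, None], np.asarray(kinds_b)[None, :]]


@dataclass
class StatPotentialTable:
    """Symmetric 20x20 residue-pair contact potential, kT units."""

    u: np.ndarray
    provenance: str = ""
    residue_types: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        n = len(self.residue_types)
        if self.u.shape != (n, n):
            raise ValueError(f"table must be {n}x{n}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("table entries must be finite")
        if not np.allclose(self.u, self.u.T, atol=1e-9):
            raise ValueError("table must be symmetric")

    @classmethod
    def zeros(cls, provenance: str = "null potential") -> "StatPotentialTable":
        return cls(np.zeros((20, 20)), provenance)

    def lookup(self, type_i: str, type_j: str) -> float:
        return float(self.u[AA_INDEX[type_i.upper()], AA_INDEX[type_j.upper()]])

    def lookup_many(self, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
        return self.u[np.asarray(idx_i), np.asarray(idx_j)]

    def rmse(self, other: "StatPotentialTable") -> float:
        return float(np.sqrt(((self.u - other.u) ** 2).mean()))

    def to_tsv(self, path: str | Path) -> None:
        """Write the 210 unordered residue-type pairs as TSV."""
        with open(path, "w") as fh:
            for line in self.provenance.splitlines():
                fh.write(f"# {line}\n")
            fh.write("res_i\tres_j\tu_sc\n")
            for i, ti in enumerate(self.residue_types):
                for j in range(i, len(self.residue_types)):
                    fh.write(f"{ti}\t{self.residue_types[j]}\t{self.u[i, j]:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "StatPotentialTable":
        provenance: list[str] = []
        u = np.full((20, 20), np.nan)
        if hasattr(path, "read"):
            lines = path.read().splitlines()
        else:
            lines = Path(path).read_text().splitlines()
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                provenance.append(line.lstrip("# "))
                continue
            parts = line.split("\t")
            if parts[0] == "res_i":
                continue
            ti, tj, val = parts[0].upper(), parts[1].upper(), float(parts[2])
            i, j = AA_INDEX[ti], AA_INDEX[tj]
            u[i, j] = u[j, i] = val
        if np.isnan(u).any():
            missing = int(np.isnan(u[np.triu_indices(20)]).sum())
            raise ValueError(f"incomplete table: {missing} unordered pairs missing")
        return cls(u, "\n".join(provenance))


def default_table() -> StatPotentialTable:
    """The package's bundled contact-potential table.

    Derived from the synthetic contact-library pipeline (see
    ``scripts/make_default_table.py``); it encodes hydrophobic attraction and
    charge complementarity with realistic magnitudes but is *not* a
    reproduction of any published table.
    """
    ref = importlib.resources.files("cgassoc").joinpath("data/default_usc.tsv")
    with ref.open("r") as fh:
        return StatPotentialTable.from_tsv(fh)


@dataclass
class HybridForceField:
    """Weighted mix of the physics and statistical potentials (Eq. above)."""

    omega: float = 0.6
    physics: PhysicsParams = field(default_factory=PhysicsParams)
    table: StatPotentialTable = field(default_factory=StatPotentialTable.zeros)
    stat_mode: str = "anchored"

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if self.stat_mode not in STAT_MODES:
            raise ValueError(f"stat_mode must be one of {STAT_MODES}")


@dataclass(frozen=True)
class EnergyComponents:
    electrostatic: float
    hydrophobic: float
    excluded_volume: float
    statistical: float

    @property
    def physics(self) -> float:
        return self.electrostatic + self.hydrophobic + self.excluded_volume

    def total(self, omega: float) -> float:
        return (1.0 - omega) * self.physics + omega * self.statistical


# ---------------------------------------------------------------------------
# individual terms (each computes distances from scratch; the hot path in
# energy_components shares one distance matrix instead)
# ---------------------------------------------------------------------------

def _electrostatic(q_a, q_b, r, params: PhysicsParams) -> float:
    if r.size == 0:
        return 0.0
    if np.any(r == 0.0):
        raise OverlapError("charged sites overlap (r = 0)")
    qq = np.outer(q_a, q_b)
    mask = r <= params.elec_cutoff
    d_eff = params.dielectric * np.exp(r[mask] / params.debye_length)
    return float(COULOMB_KT_A * np.sum(qq[mask] / (d_eff * r[mask])))


def _hydrophobic(hp_a, hp_b, r, params: PhysicsParams) -> float:
    mask = r <= params.hp_cutoff
    if not mask.any():
        return 0.0
    hp_sum = (hp_a[:, None] + hp_b[None, :])[mask].sum()
    sign = -1.0 if params.hydrophobic_attractive else 1.0
    return float(sign * params.w_alpha * hp_sum)


def _excluded_volume(r, sigma, params: PhysicsParams) -> float:
    mask = r < sigma
    if not mask.any():
        return 0.0
    rm = r[mask]
    if np.any(rm == 0.0):
        return float("inf")
    x6 = (sigma[mask] / rm) ** 6
    return float(params.epsilon_rep * np.sum(x6 * x6 - x6))


STAT_MODES = ("anchored", "scaled", "literal")


def _statistical(u, r, r0, mode: str) -> float:
    if np.any(r == 0.0):
        raise OverlapError("native-contact sites overlap (r = 0)")
    x = (r0 / r) ** 6
    if mode == "anchored":
        attract = np.abs(u) * (x * x - 2.0 * x)
        repel = u * x * x
        terms = np.where(u < 0, attract, np.where(u > 0, repel, 0.0))
        return float(terms.sum())
    if mode in ("scaled", "literal"):
        f = np.where(u < 0, 1.0, np.where(u > 0, -1.0, 0.0))
        g = np.where(u < 0, -1.0, 0.0)
        bracket = g * x * x - f * x
        scale = 1.0 if mode == "literal" else np.abs(u)
        return float(np.sum(scale * bracket))
    raise ValueError(f"stat_mode must be one of {STAT_MODES}")


def electrostatic_energy(
    protein_a: CoarseProtein,
    protein_b: CoarseProtein,
    params: PhysicsParams,
    box_edge: float | None = None,
) -> float:
    """Screened Coulomb energy between charged SC sites, kT."""
    ia = np.nonzero(protein_a.charges)[0]
    ib = np.nonzero(protein_b.charges)[0]
    if ia.size == 0 or ib.size == 0:
        return 0.0
    r = pair_distances(protein_a.sc_positions[ia], protein_b.sc_positions[ib], box_edge)
    return _electrostatic(protein_a.charges[ia], protein_b.charges[ib], r, params)


def hydrophobic_energy(
    protein_a: CoarseProtein,
    protein_b: CoarseProtein,
    params: PhysicsParams,
    box_edge: float | None = None,
) -> float:
    """Kyte-Doolittle contact term over SC-SC pairs within ``hp_cutoff``, kT."""
    r = pair_distances(protein_a.sc_positions, protein_b.sc_positions, box_edge)
    return _hydrophobic(protein_a.hydropathies, protein_b.hydropathies, r, params)


def excluded_volume_energy(
    protein_a: CoarseProtein,
    protein_b: CoarseProtein,
    params: PhysicsParams,
    box_edge: float | None = None,
) -> float:
    """Steric 12-6 wall over all inter-protein site pairs, kT."""
    r = pair_distances(protein_a.positions, protein_b.positions, box_edge)
    sigma = params.sigma_matrix(protein_a.site_kinds, protein_b.site_kinds)
    return _excluded_volume(r, sigma, params)


def physics_energy(
    protein_a: CoarseProtein,
    protein_b: CoarseProtein,
    params: PhysicsParams,
    box_edge: float | None = None,
) -> float:
    return (
        electrostatic_energy(protein_a, protein_b, params, box_edge)
        + hydrophobic_energy(protein_a, protein_b, params, box_edge)
        + excluded_volume_energy(protein_a, protein_b, params, box_edge)
    )


def statistical_energy(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    contacts: NativeContactMap,
    table: StatPotentialTable,
    box_edge: float | None = None,
    mode: str = "anchored",
) -> float:
    """Go-like native-contact term modulated by the contact potential, kT."""
    u = table.lookup_many(
        receptor.type_indices[contacts.receptor_residues],
        ligand.type_indices[contacts.ligand_residues],
    )
    disp = minimum_image(
        receptor.sc_positions[contacts.receptor_residues]
        - ligand.sc_positions[contacts.ligand_residues],
        box_edge,
    )
    r = np.linalg.norm(disp, axis=-1)
    return _statistical(u, r, contacts.r0, mode)


def contact_distances(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    contacts: NativeContactMap,
    box_edge: float | None = None,
) -> np.ndarray:
    """Current minimum-image SC-SC distances of the native contact pairs."""
    disp = minimum_image(
        receptor.sc_positions[contacts.receptor_residues]
        - ligand.sc_positions[contacts.ligand_residues],
        box_edge,
    )
    return np.linalg.norm(disp, axis=-1)


def energy_components(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    ff: HybridForceField,
    contacts: NativeContactMap | None = None,
    box_edge: float | None = None,
) -> EnergyComponents:
    """All energy terms from a single shared distance matrix."""
    n_a, n_b = receptor.n_residues, ligand.n_residues
    r_all = pair_distances(receptor.positions, ligand.positions, box_edge)
    params = ff.physics

    sigma = params.sigma_matrix(receptor.site_kinds, ligand.site_kinds)
    e_ev = _excluded_volume(r_all, sigma, params)

    r_sc = r_all[n_a:, n_b:]
    e_hp = _hydrophobic(receptor.hydropathies, ligand.hydropathies, r_sc, params)

    ia = np.nonzero(receptor.charges)[0]
    ib = np.nonzero(ligand.charges)[0]
    if ia.size and ib.size:
        e_el = _electrostatic(
            receptor.charges[ia], ligand.charges[ib], r_sc[np.ix_(ia, ib)], params
        )
    else:
        e_el = 0.0

    if contacts is not None and contacts.n_contacts:
        u = ff.table.lookup_many(
            receptor.type_indices[contacts.receptor_residues],
            ligand.type_indices[contacts.ligand_residues],
        )
        r_pairs = r_sc[contacts.receptor_residues, contacts.ligand_residues]
        e_stat = _statistical(u, r_pairs, contacts.r0, ff.stat_mode)
    else:
        e_stat = 0.0

    return EnergyComponents(e_el, e_hp, e_ev, e_stat)


def total_energy(
    receptor: CoarseProtein,
    ligand: CoarseProtein,
    ff: HybridForceField,
    contacts: NativeContactMap | None = None,
    box_edge: float | None = None,
) -> float:
    """Hybrid total ``(1 - omega) E_physics + omega E_statistics``, kT."""
    return energy_components(receptor, ligand, ff, contacts, box_edge).total(ff.omega)


# ---------------------------------------------------------------------------
# statistical-potential derivation
# ---------------------------------------------------------------------------

def derive_usc(
    contact_library: Iterable[Sequence[tuple[str, str]]],
    pseudo_count: float = 1.0,
    provenance: str = "derived from contact library",
) -> StatPotentialTable:
    """Derive the quasi-chemical contact potential from interface statistics.

    ``contact_library`` iterates over interfaces, each a sequence of
    ``(type_i, type_j)`` residue-pair contacts.  Counting is over ordered
    pairs (each contact contributes to both (i, j) and (j, i)) so the mole
    fractions ``chi`` are exactly the marginals of the count matrix and the
    resulting table is symmetric by construction.  Zero-count cells between
    observed types receive ``pseudo_count`` to keep entries finite; types
    never observed at any interface get ``u = 0``.
    """
    counts = np.zeros((20, 20))
    n_contacts = 0
    for interface in contact_library:
        for ti, tj in interface:
            i, j = AA_INDEX[ti.upper()], AA_INDEX[tj.upper()]
            counts[i, j] += 1
            counts[j, i] += 1
            n_contacts += 1
    if n_contacts == 0:
        raise ValueError("contact library is empty")

    n_obs = counts.sum()
    chi = counts.sum(axis=1) / n_obs
    expected = np.outer(chi, chi) * n_obs
    observed = np.where(counts > 0, counts, pseudo_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -np.log(observed / expected)
    u[expected == 0] = 0.0  # residue type absent from the library
    u = 0.5 * (u + u.T)
    return StatPotentialTable(u, f"{provenance}; contacts={n_contacts}")
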