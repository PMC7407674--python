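"""Programmatic generation of test inputs.

Two families of fixtures, both pure functions of a spec plus a seed:

* **Toy dimers** -- a pair of rigid "mini-proteins" written as a valid PDB
  file with a prescribed number of native interface contacts at a prescribed
  SC-SC distance.  The emitted file round-trips through the coarse-graining
  pipeline, so every fixture exercises the real PDB path.
* **Synthetic contact libraries** -- interface residue-pair samples drawn
  from the Boltzmann-like distribution induced by a known contact-potential
  table over a background amino-acid composition, for parameter-recovery
  tests of the quasi-chemical inversion.

Toy-dimer geometry: each chain is a straight virtual-CA backbone with 3.8 A
spacing along x; side-chain pseudo-atoms (written as CB) sit 2 A off the
backbone.  Contact residues occupy every second position and point their
side chains at the partner chain, which runs parallel at the distance that
puts the paired SC sites exactly ``contact_distance`` apart; all other
side chains point away, keeping every non-designed pair well outside the
5.5 A atom criterion.  The construction is clash-free by design and is
validated by re-extracting the contact map from the written file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .cg_model import (
    CoarseProtein,
    NativeContactMap,
    load_coarse_protein,
    native_contacts,
)
from .constants import AA_INDEX, AMINO_ACIDS
from .forcefield import StatPotentialTable

__all__ = [
    "ToyDimerSpec",
    "ToyDimer",
    "FixtureError",
    "make_toy_dimer",
    "write_pdb",
    "make_contact_library",
    "implied_contact_table",
]


class FixtureError(ValueError):
    """The requested fixture specification is not realizable."""


#: Default residue palette cycled along toy chains: a mix of hydrophobic,
#: charged and polar types so every energy term is exercised.
DEFAULT_PALETTE = (
    "LEU", "GLU", "LYS", "ILE", "SER", "ASP",
    "ARG", "VAL", "THR", "PHE", "ASN", "MET",
)

_CA_SPACING = 3.8  # A, virtual-CA backbone step
_SC_OFFSET = 2.0  # A, side-chain pseudo-atom offset from the backbone


@dataclass(frozen=True)
class ToyDimerSpec:
    """Specification of a two-chain toy complex.

    ``n_contacts`` native contacts are built at SC-SC distance
    ``contact_distance`` (A); contact residues sit at every second backbone
    position, so ``n_residues >= 2 * n_contacts - 1`` is required.  ``jitter``
    adds a small seeded coordinate perturbation (A) so distinct seeds give
    distinct, still-valid geometries.
    """

    n_residues: int = 12
    n_contacts: int = 4
    contact_distance: float = 4.0
    receptor_types: tuple[str, ...] | None = None
    ligand_types: tuple[str, ...] | None = None
    seed: int = 0
    jitter: float = 0.03

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise FixtureError("n_residues must be >= 1")
        if self.n_contacts < 0:
            raise FixtureError("n_contacts must be >= 0")
        if self.n_contacts and self.n_residues < 2 * self.n_contacts - 1:
            raise FixtureError(
                f"{self.n_contacts} contacts need at least {2 * self.n_contacts - 1} residues"
            )
        if not 2.4 <= self.contact_distance <= 5.4:
            raise FixtureError("contact_distance must lie in [2.4, 5.4] A")
        if not 0.0 <= self.jitter <= 0.1:
            raise FixtureError("jitter must lie in [0, 0.1] A")

    def types_for(self, chain: str) -> tuple[str, ...]:
        given = self.receptor_types if chain == "A" else self.ligand_types
        if given is not None:
            if len(given) != self.n_residues:
                raise FixtureError(f"need {self.n_residues} residue types for chain {chain}")
            return tuple(t.upper() for t in given)
        start = 0 if chain == "A" else 3
        return tuple(
            DEFAULT_PALETTE[(start + i) % len(DEFAULT_PALETTE)] for i in range(self.n_residues)
        )


@dataclass
class ToyDimer:
    """A generated toy complex in its native pose."""

    receptor: CoarseProtein
    ligand: CoarseProtein
    contacts: NativeContactMap
    spec: ToyDimerSpec
    pdb_text: str
    pdb_path: Path | None = None


def _build_coordinates(spec: ToyDimerSpec):
    """Native-pose CA/CB coordinates for both chains."""
    rng = np.random.default_rng(spec.seed)
    n, m, d = spec.n_residues, spec.n_contacts, spec.contact_distance
    contact_idx = {2 * k for k in range(m)}

    x = _CA_SPACING * np.arange(n)
    rec_ca = np.column_stack([x, np.zeros(n), np.zeros(n)])
    rec_sc_y = np.where([i in contact_idx for i in range(n)], _SC_OFFSET, -_SC_OFFSET)
    rec_sc = np.column_stack([x, rec_sc_y, np.zeros(n)])

    lig_ca_y = _SC_OFFSET + d + _SC_OFFSET  # backbone of the partner chain
    lig_sc_y = np.where(
        [i in contact_idx for i in range(n)], _SC_OFFSET + d, lig_ca_y + _SC_OFFSET
    )
    lig_ca = np.column_stack([x, np.full(n, lig_ca_y), np.zeros(n)])
    lig_sc = np.column_stack([x, lig_sc_y, np.zeros(n)])

    if spec.jitter:
        for arr in (rec_ca, rec_sc, lig_ca, lig_sc):
            arr += rng.uniform(-spec.jitter, spec.jitter, size=arr.shape)
    return rec_ca, rec_sc, lig_ca, lig_sc


def write_pdb(
    chains: dict[str, list[tuple[str, np.ndarray, np.ndarray | None]]],
    path: str | Path | None = None,
) -> str:
    """Write chains of (residue_type, CA coord, side-chain coord or None) as PDB.

    The side-chain pseudo-atom is written as CB; glycine (or an explicit
    ``None``) gets no side-chain atom.  Returns the PDB text; also writes it
    to ``path`` when given.
    """
    builder = StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)
    serial = 1
    builder.init_seg("    ")
    for chain_id, residues in chains.items():
        builder.init_chain(chain_id)
        for i, (rtype, ca, sc) in enumerate(residues, start=1):
            rtype = rtype.upper()
            if rtype not in AA_INDEX:
                raise FixtureError(f"unknown residue type {rtype}")
            builder.init_residue(rtype, " ", i, " ")
            builder.init_atom("CA", np.asarray(ca, dtype=float), 0.0, 1.0, " ", " CA ", serial, "C")
            serial += 1
            if rtype != "GLY" and sc is not None:
                builder.init_atom("CB", np.asarray(sc, dtype=float), 0.0, 1.0, " ", " CB ", serial, "C")
                serial += 1
    pdbio = PDBIO()
    pdbio.set_structure(builder.get_structure())
    buf = io.StringIO()
    pdbio.save(buf)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def make_toy_dimer(spec: ToyDimerSpec, pdb_path: str | Path | None = None) -> ToyDimer:
    """Build a toy complex and round-trip it through the coarse-graining pipeline.

    The returned proteins and contact map are extracted from the emitted PDB
    text (not from the raw coordinates), so agreement with the construction
    is guaranteed only through the real parsing path.  Raises
    :class:`cgassoc.cg_model.ZeroContactsError` for a zero-contact spec and
    :class:`FixtureError` if the realized contact count deviates from the
    request.
    """
    rec_ca, rec_sc, lig_ca, lig_sc = _build_coordinates(spec)
    rec_types = spec.types_for("A")
    lig_types = spec.types_for("B")
    chains = {
        "A": [(t, rec_ca[i], rec_sc[i]) for i, t in enumerate(rec_types)],
        "B": [(t, lig_ca[i], lig_sc[i]) for i, t in enumerate(lig_types)],
    }
    text = write_pdb(chains, pdb_path)

    receptor = load_coarse_protein(io.StringIO(text), ["A"], name="toy_receptor")
    ligand = load_coarse_protein(io.StringIO(text), ["B"], name="toy_ligand")
    contacts = native_contacts(receptor, ligand, io.StringIO(text))
    if contacts.n_contacts != spec.n_contacts:
        raise FixtureError(
            f"constructed {contacts.n_contacts} contacts, expected {spec.n_contacts}"
        )
    return ToyDimer(
        receptor, ligand, contacts, spec, text,
        Path(pdb_path) if pdb_path is not None else None,
    )


# ---------------------------------------------------------------------------
# synthetic contact libraries
# ---------------------------------------------------------------------------

def _contact_distribution(
    table: StatPotentialTable, background: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or np.any(background < 0):
        raise ValueError("background must be 20 non-negative mole fractions")
    background = background / background.sum()
    joint = np.outer(background, background) * np.exp(-table.u)
    joint /= joint.sum()
    return joint, background


def implied_contact_table(
    table: StatPotentialTable, background: np.ndarray | None = None
) -> StatPotentialTable:
    """The self-consistent table of the sampling distribution.

    Contacts are drawn with probability proportional to
    ``chi_i chi_j exp(-u_ij)``; the quasi-chemical inversion applied to that
    distribution recovers ``-ln(P_ij / (m_i m_j))`` with ``m`` the contact
    marginals, which equals the input table exactly when the table preserves
    the background marginals (e.g. the null table) and otherwise differs by
    per-type additive shifts.  This is the exact target that
    :func:`cgassoc.forcefield.derive_usc` estimates from a finite sample.
    """
    joint, _ = _contact_distribution(table, background)
    marginal = joint.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = -np.log(joint / np.outer(marginal, marginal))
    u[~np.isfinite(u)] = 0.0
    u = 0.5 * (u + u.T)
    return StatPotentialTable(u, "implied self-consistent table")


def make_contact_library(
    true_usc: StatPotentialTable,
    n_interfaces: int,
    rng: np.random.Generator | int,
    background: np.ndarray | None = None,
    contacts_per_interface: int = 50,
) -> list[list[tuple[str, str]]]:
    """Sample a synthetic interface contact library from a known potential.

    Returns ``n_interfaces`` interfaces of ``contacts_per_interface``
    residue-pair contacts each, drawn i.i.d. from the distribution induced
    by ``true_usc`` over the ``background`` composition (uniform by default).
    """
    if n_interfaces < 1 or contacts_per_interface < 1:
        raise ValueError("n_interfaces and contacts_per_interface must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    joint, _ = _contact_distribution(true_usc, background)
    flat = joint.ravel()
    n_total = n_interfaces * contacts_per_interface
    draws = rng.choice(flat.size, size=n_total, p=flat)
    ii, jj = np.unravel_index(draws, joint.shape)
    pairs = [(AMINO_ACIDS[i], AMINO_ACIDS[j]) for i, j in zip(ii, jj)]
    return [
        pairs[k * contacts_per_interface:(k + 1) * contacts_per_interface]
        for k in range(n_interfaces)
    ]
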