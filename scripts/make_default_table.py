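"""Regenerate the bundled contact-potential table.

The bundled table is produced by the package's own synthetic pipeline: a
seed potential encoding hydrophobic attraction and charge complementarity is
used to sample a large synthetic interface contact library, and the
quasi-chemical inversion (`derive_usc`) is applied to that library.  The
result has realistic magnitudes (tenths of kT) and the statistical structure
of a library-derived table, but is synthetic: it is not extracted from any
structural database.

Run from the repository root:  python scripts/make_default_table.py
"""

from pathlib import Path

import numpy as np

from cgassoc.constants import AMINO_ACIDS, KYTE_DOOLITTLE, RESIDUE_CHARGE
from cgassoc.forcefield import StatPotentialTable, derive_usc
from cgassoc.synthetic_fixtures import make_contact_library

SEED = 20260924
N_INTERFACES = 20_000
CONTACTS_PER_INTERFACE = 50


def seed_table() -> StatPotentialTable:
    hp = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS])
    q = np.array([RESIDUE_CHARGE.get(a, 0.0) for a in AMINO_ACIDS])
    # Hydrophobic pairs attract (burial), like charges repel, opposite attract.
    u = -0.05 * (hp[:, None] + hp[None, :]) + 0.4 * np.outer(q, q)
    return StatPotentialTable(u, "seed potential (hydropathy + charge)")


def main() -> None:
    seed = seed_table()
    library = make_contact_library(
        seed, N_INTERFACES, np.random.default_rng(SEED),
        contacts_per_interface=CONTACTS_PER_INTERFACE,
    )
    table = derive_usc(
        library,
        provenance=(
            "synthetic default table: quasi-chemical inversion of a "
            f"{N_INTERFACES * CONTACTS_PER_INTERFACE}-contact library sampled from a "
            "hydropathy+charge seed potential (scripts/make_default_table.py, "
            f"seed {SEED}); not derived from any structural database"
        ),
    )
    out = Path(__file__).resolve().parents[1] / "src" / "cgassoc" / "data" / "default_usc.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
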