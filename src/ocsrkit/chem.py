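"""SMILES handling: canonicalization, ring forms, and substituent attachment.

All molecule manipulation goes through RDKit.  Molecules travel through the
package as SMILES strings; the two ring forms used by the corpus categories are

* ``aromatic`` — aromatic rings written with lowercase aromatic atoms,
* ``kekule``  — aromatic rings written with alternating explicit bonds.

Substituent attachment emulates the decoration of scaffolds with patent-style
R-group fragments and bracket atoms: a pool fragment is bonded to a randomly
chosen atom that still carries an implicit hydrogen.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


class ChemError(ValueError):
    """Raised for unparseable SMILES or impossible chemistry operations."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise ChemError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical (aromatic-form) SMILES of *smiles*.

    Idempotent: ``canonicalize(canonicalize(s)) == canonicalize(s)``.

    Raises
    ------
    ChemError
        If the string does not parse to a valid molecule.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def to_ring_form(smiles: str, form: str) -> str:
    """Rewrite *smiles* in the requested ring form.

    ``form`` is ``"aromatic"`` or ``"kekule"``.  Molecule identity is
    preserved: both outputs canonicalize (with aromatic perception) to the
    same string.  Kekulization of a non-kekulizable aromatic system raises
    :class:`ChemError`.
    """
    mol = _mol_from_smiles(smiles)
    if form == "aromatic":
        return Chem.MolToSmiles(mol)
    if form == "kekule":
        try:
            Chem.Kekulize(mol, clearAromaticFlags=True)
        except Chem.KekulizeException as exc:
            raise ChemError(f"cannot kekulize {smiles!r}: {exc}") from exc
        return Chem.MolToSmiles(mol, kekuleSmiles=True)
    raise ValueError(f"unknown ring form {form!r}")


# Bracket atoms injected alongside substituents.  Single atoms written with
# explicit brackets (isotopes, charges, fixed H counts) as they appear in
# patent depictions.
BRACKET_ATOMS = (
    "[Pb]", "[NH]", "[Ru]", "[Li]", "[K]", "[Si]", "[S+]", "[O]", "[O-]",
    "[N+]", "[N]", "[P]", "[C]", "[H]", "[2H]", "[3H]", "[B]",
)

# Patent-literature style R-group fragments.  Each entry is a fragment SMILES
# whose attachment atom (first atom with a free valence) is bonded to the
# scaffold.  The pool is swappable: any text file with one fragment per line
# can be loaded via SubstituentPools.from_files.
DEFAULT_SUBSTITUENTS = (
    "C",            # methyl
    "CC",           # ethyl
    "C(C)C",        # isopropyl
    "C(C)(C)C",     # tert-butyl
    "O",            # hydroxyl
    "OC",           # methoxy
    "OCC",          # ethoxy
    "N",            # amino
    "NC",           # methylamino
    "N(C)C",        # dimethylamino
    "F",
    "Cl",
    "Br",
    "I",
    "C#N",          # nitrile
    "C(F)(F)F",     # trifluoromethyl
    "OC(F)(F)F",    # trifluoromethoxy
    "[N+](=O)[O-]", # nitro
    "C=O",          # formyl
    "C(=O)O",       # carboxyl
    "C(=O)OC",      # methyl ester
    "C(=O)N",       # amide
    "S",            # thiol
    "SC",           # thiomethyl
    "S(=O)(=O)C",   # methylsulfonyl
    "S(=O)(=O)N",   # sulfonamide
    "c1ccccc1",     # phenyl
    "Cc1ccccc1",    # benzyl
    "c1ccncc1",     # pyridyl
    "C1CCNCC1",     # piperidinyl
    "N1CCOCC1",     # morpholino
    "C1CC1",        # cyclopropyl
)


@dataclass(frozen=True)
class SubstituentPools:
    """Attachable fragment inventories used for category 3/4 decoration."""

    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    bracket_atoms: tuple[str, ...] = BRACKET_ATOMS

    @classmethod
    def from_files(cls, substituent_path=None, bracket_path=None) -> "SubstituentPools":
        """Load pools from plain-text files, one fragment per line."""

        def _load(path, default):
            if path is None:
                return default
            with open(path) as fh:
                entries = tuple(line.strip() for line in fh if line.strip())
            return entries or default

        return cls(
            substituents=_load(substituent_path, DEFAULT_SUBSTITUENTS),
            bracket_atoms=_load(bracket_path, BRACKET_ATOMS),
        )

    def all_entries(self) -> tuple[str, ...]:
        return self.substituents + self.bracket_atoms


def _substitutable_sites(mol: Chem.Mol) -> list[int]:
    """Indices of atoms carrying at least one implicit or explicit hydrogen."""
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _fragment_attachment_atom(frag: Chem.Mol) -> int:
    """Pick the fragment atom that receives the new bond.

    Single-atom fragments (bracket atoms) attach at that atom; otherwise the
    first atom with a spare hydrogen is used.
    """
    if frag.GetNumAtoms() == 1:
        return 0
    for atom in frag.GetAtoms():
        if atom.GetTotalNumHs() >= 1:
            return atom.GetIdx()
    return 0


def _try_attach(mol: Chem.Mol, fragment: str, site: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(fragment, sanitize=True)
    if frag is None:
        # bracket atoms like [NH] only parse without full sanitization
        frag = Chem.MolFromSmiles(fragment, sanitize=False)
        if frag is None:
            return None
        try:
            frag.UpdatePropertyCache(strict=False)
        except Exception:
            return None
    combined = Chem.RWMol(Chem.CombineMols(mol, frag))
    frag_at = mol.GetNumAtoms() + _fragment_attachment_atom(frag)
    site_atom = combined.GetAtomWithIdx(site)
    # keep explicitly written H counts (e.g. [NH]) intact on the scaffold side
    if site_atom.GetNumExplicitHs() > 0:
        site_atom.SetNumExplicitHs(site_atom.GetNumExplicitHs() - 1)
    combined.AddBond(site, frag_at, Chem.BondType.SINGLE)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return product


def attach_substituents(
    smiles: str,
    pools: SubstituentPools,
    n_attach: int,
    rng: random.Random,
    max_attempts: int = 20,
) -> str:
    """Bond ``n_attach`` pool fragments to randomly chosen substitutable sites.

    A substitutable site is an atom with >= 1 hydrogen.  Attachment that
    fails sanitization is retried at another (site, fragment) draw up to
    ``max_attempts`` times per fragment.  Deterministic for a fixed ``rng``
    state.

    Raises
    ------
    ChemError
        If the molecule has no substitutable site, or attempts are exhausted.
    """
    if n_attach < 1:
        raise ValueError("n_attach must be >= 1")
    mol = _mol_from_smiles(smiles)
    entries = pools.all_entries()
    for _ in range(n_attach):
        sites = _substitutable_sites(mol)
        if not sites:
            raise ChemError(f"no substitutable site on {Chem.MolToSmiles(mol)!r}")
        attached = None
        for _attempt in range(max_attempts):
            site = rng.choice(sites)
            fragment = rng.choice(entries)
            attached = _try_attach(mol, fragment, site)
            if attached is not None:
                break
        if attached is None:
            raise ChemError(
                f"could not attach a substituent to {Chem.MolToSmiles(mol)!r} "
                f"after {max_attempts} attempts"
            )
        mol = attached
    return Chem.MolToSmiles(mol)
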