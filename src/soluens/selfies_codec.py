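"""A self-contained SELFIES codec for small organic molecules.

SELFIES (self-referencing embedded strings) is a molecular string grammar in
which every symbol is a bracketed group such as ``[C]``, ``[=O]``,
``[Branch1]`` or ``[Ring1]``.  Branch and ring symbols are followed by index
symbols drawn from a fixed 16-symbol alphabet that encode, in base 16, the
branch length (in symbols) or the ring-closure distance (in derivation steps).

This module implements the subset of the grammar needed for neutral and
singly-charged organic molecules:

* atoms: B, C, N, O, F, P, S, Cl, Br, I, optionally carrying a +1/-1 charge
  (written ``[N+1]``, ``[O-1]``, ...);
* bonds: single, double (``=`` prefix) and triple (``#`` prefix);
* nested branches (``[Branch1]``/``[Branch2]``/``[Branch3]`` with ``=``/``#``
  variants mirroring the bond order of the first bond in the branch);
* ring closures (``[Ring1]``..``[Ring3]`` with bond-order variants).

Stereochemistry, isotopes, radicals and multiply-charged atoms are outside the
subset and raise :class:`SelfiesEncodeError`.  Aromatic systems are handled by
kekulization, so decoding yields a Kekulé structure that canonicalizes to the
same molecule.

The decoder only guarantees correct inversion of strings produced by the
encoder (plus any string differing only in token order conventions); it raises
:class:`SelfiesDecodeError` on strings it cannot derive rather than silently
repairing them.
"""

from __future__ import annotations

import re

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SelfiesError(ValueError):
    """Base class for codec failures."""


class SelfiesEncodeError(SelfiesError):
    """Molecule falls outside the supported SELFIES subset."""


class SelfiesDecodeError(SelfiesError):
    """String is not a derivable SELFIES in the supported subset."""


# Index alphabet: symbol at position i encodes digit i (base 16).
INDEX_ALPHABET = (
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
)
_INDEX_OF = {s: i for i, s in enumerate(INDEX_ALPHABET)}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

_ELEMENTS = {"B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}

# Maximum bonding capacity used when deriving implicit structure.  Neutral
# values follow the common organic valence model; charged entries cover the
# ubiquitous onium/oxide cases.
_MAX_VALENCE = {
    ("B", 0): 3, ("C", 0): 4, ("N", 0): 3, ("O", 0): 2, ("F", 0): 1,
    ("P", 0): 5, ("S", 0): 6, ("Cl", 0): 1, ("Br", 0): 1, ("I", 0): 1,
    ("N", 1): 4, ("O", 1): 3, ("S", 1): 3, ("P", 1): 4, ("C", 1): 3,
    ("N", -1): 2, ("O", -1): 1, ("S", -1): 1, ("C", -1): 3,
}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")
_ATOM_RE = re.compile(r"^\[([=#]?)([A-Z][a-z]?)([+-]\d)?\]$")
_BRANCH_RE = re.compile(r"^\[([=#]?)Branch([123])\]$")
_RING_RE = re.compile(r"^\[([=#]?)Ring([123])\]$")


def split_tokens(selfies: str) -> list[str]:
    """Split a SELFIES string into its bracketed tokens.

    The concatenation of the returned tokens equals the input; malformed
    strings (stray characters, unbalanced brackets) raise
    :class:`SelfiesDecodeError`.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise SelfiesDecodeError(
            f"malformed SELFIES (unbalanced brackets or stray text): {selfies!r}"
        )
    return tokens


def _index_symbols(value: int, n_symbols: int) -> list[str]:
    digits = []
    for _ in range(n_symbols):
        digits.append(INDEX_ALPHABET[value % 16])
        value //= 16
    return digits[::-1]


def _read_index(tokens: list[str], pos: int, n_symbols: int, context: str) -> tuple[int, int]:
    if pos + n_symbols > len(tokens):
        raise SelfiesDecodeError(f"truncated index after {context}")
    value = 0
    for k in range(n_symbols):
        sym = tokens[pos + k]
        if sym not in _INDEX_OF:
            raise SelfiesDecodeError(f"{sym} is not an index symbol (after {context})")
        value = value * 16 + _INDEX_OF[sym]
    return value, pos + n_symbols


def _n_symbols_for(value: int) -> int:
    n = 1
    while value >= 16**n:
        n += 1
    if n > 3:  # would need [Branch4]/[Ring4]; never reached for sane molecules
        raise SelfiesEncodeError(f"index {value} too large for the grammar")
    return n


def _atom_token(atom: Chem.Atom, bond_order: int) -> str:
    sym = atom.GetSymbol()
    charge = atom.GetFormalCharge()
    if sym not in _ELEMENTS:
        raise SelfiesEncodeError(f"element {sym} outside the supported alphabet")
    if (sym, charge) not in _MAX_VALENCE:
        raise SelfiesEncodeError(f"charge {charge:+d} on {sym} is not supported")
    if atom.GetNumRadicalElectrons():
        raise SelfiesEncodeError(f"radical centre on {sym} is not supported")
    if atom.GetIsotope():
        raise SelfiesEncodeError("isotope labels are not supported")
    chg = "" if charge == 0 else f"{'+' if charge > 0 else '-'}{abs(charge)}"
    return f"[{_BOND_PREFIX[bond_order]}{sym}{chg}]"


def encode(smiles: str) -> str:
    """Encode a SMILES string as SELFIES.

    The molecule is kekulized and stereochemistry is dropped; the result
    decodes back to the same canonical molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesEncodeError(f"cannot parse SMILES: {smiles!r}")
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    if mol.GetNumAtoms() == 0:
        raise SelfiesEncodeError("empty molecule")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise SelfiesEncodeError("multi-fragment inputs are not supported")

    order = {}  # atom idx -> derivation position
    used_bonds: set[int] = set()
    counter = [0]

    def bond_int(a: int, b: int) -> tuple[int, Chem.Bond]:
        bond = mol.GetBondBetweenAtoms(a, b)
        bt = bond.GetBondType()
        if bt == Chem.BondType.SINGLE:
            return 1, bond
        if bt == Chem.BondType.DOUBLE:
            return 2, bond
        if bt == Chem.BondType.TRIPLE:
            return 3, bond
        raise SelfiesEncodeError(f"unsupported bond type {bt}")

    def visit(idx: int, parent: int, bond_order: int) -> list[str]:
        atom = mol.GetAtomWithIdx(idx)
        tokens = [_atom_token(atom, bond_order)]
        order[idx] = counter[0]
        counter[0] += 1
        # Ring closures terminate at the later-derived endpoint.
        for nbr in atom.GetNeighbors():
            j = nbr.GetIdx()
            if j == parent or j not in order:
                continue
            bo, bond = bond_int(idx, j)
            if bond.GetIdx() in used_bonds:
                continue
            used_bonds.add(bond.GetIdx())
            q = order[idx] - order[j] - 1
            n = _n_symbols_for(q)
            tokens.append(f"[{_BOND_PREFIX[bo]}Ring{n}]")
            tokens.extend(_index_symbols(q, n))
        # Tree children; all but the last are wrapped in branches.
        child_chunks: list[list[str]] = []
        for nbr in atom.GetNeighbors():
            j = nbr.GetIdx()
            if j in order:
                continue
            bo, bond = bond_int(idx, j)
            used_bonds.add(bond.GetIdx())
            child_chunks.append(visit(j, idx, bo))
        for chunk in child_chunks[:-1]:
            q = len(chunk) - 1
            n = _n_symbols_for(q)
            first = _ATOM_RE.match(chunk[0])
            prefix = first.group(1) if first else ""
            tokens.append(f"[{prefix}Branch{n}]")
            tokens.extend(_index_symbols(q, n))
            tokens.extend(chunk)
        if child_chunks:
            tokens.extend(child_chunks[-1])
        return tokens

    return "".join(visit(0, -1, 1))


def decode(selfies: str) -> str:
    """Decode a SELFIES string to a canonical SMILES."""
    tokens = split_tokens(selfies)
    if not tokens:
        raise SelfiesDecodeError("empty SELFIES string")

    rw = Chem.RWMol()
    derived: list[int] = []  # rdkit atom idx per derivation position
    pos_of: dict[int, int] = {}
    bond_degree: dict[int, int] = {}

    def free_valence(aidx: int) -> int:
        atom = rw.GetAtomWithIdx(aidx)
        key = (atom.GetSymbol(), atom.GetFormalCharge())
        return _MAX_VALENCE[key] - bond_degree.get(aidx, 0)

    def add_atom(token_match: re.Match, attach: int | None) -> int:
        prefix, sym, chg = token_match.group(1), token_match.group(2), token_match.group(3)
        charge = int(chg) if chg else 0
        if sym not in _ELEMENTS or (sym, charge) not in _MAX_VALENCE:
            raise SelfiesDecodeError(f"unsupported atom token [{prefix}{sym}{chg or ''}]")
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(charge)
        aidx = rw.AddAtom(atom)
        if attach is not None:
            bo = _BOND_ORDER[prefix]
            if free_valence(attach) < bo or _MAX_VALENCE[(sym, charge)] < bo:
                raise SelfiesDecodeError(
                    f"bond order {bo} exceeds free valence at derivation step {len(derived)}"
                )
            rw.AddBond(attach, aidx, _RDKIT_BOND[bo])
            bond_degree[attach] = bond_degree.get(attach, 0) + bo
            bond_degree[aidx] = bo
        pos_of[aidx] = len(derived)
        derived.append(aidx)
        return aidx

    def derive(pos: int, limit: int, attach: int | None) -> int:
        """Derive up to ``limit`` tokens starting at ``pos``; returns new pos."""
        current = attach
        end = pos + limit
        while pos < end and pos < len(tokens):
            tok = tokens[pos]
            m = _ATOM_RE.match(tok)
            if m:
                current = add_atom(m, current)
                pos += 1
                continue
            m = _BRANCH_RE.match(tok)
            if m:
                if current is None:
                    raise SelfiesDecodeError("branch before any atom")
                q, pos2 = _read_index(tokens, pos + 1, int(m.group(2)), tok)
                pos = derive(pos2, q + 1, current)
                continue
            m = _RING_RE.match(tok)
            if m:
                if current is None:
                    raise SelfiesDecodeError("ring closure before any atom")
                q, pos = _read_index(tokens, pos + 1, int(m.group(2)), tok)
                target_pos = pos_of[current] - (q + 1)
                if target_pos < 0:
                    raise SelfiesDecodeError(f"ring closure reaches before the first atom ({tok})")
                target = derived[target_pos]
                bo = _BOND_ORDER[m.group(1)]
                if target == current or rw.GetBondBetweenAtoms(target, current) is not None:
                    raise SelfiesDecodeError("degenerate ring closure")
                if free_valence(current) < bo or free_valence(target) < bo:
                    raise SelfiesDecodeError("ring closure exceeds free valence")
                rw.AddBond(target, current, _RDKIT_BOND[bo])
                bond_degree[target] = bond_degree.get(target, 0) + bo
                bond_degree[current] = bond_degree.get(current, 0) + bo
                continue
            raise SelfiesDecodeError(f"unrecognized token {tok}")
        return pos

    derive(0, len(tokens), None)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - guarded by valence checks above
        raise SelfiesDecodeError(f"derived molecule failed sanitization: {exc}") from exc
    return Chem.MolToSmiles(mol)
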