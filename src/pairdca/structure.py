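"""Inter-residue distances on a docked complex structure.

Top-ranked co-varying pairs are validated by measuring how far apart the
two residues sit in a docking model of the complex.  The default distance
is the minimum over all heavy-atom pairs (side-chain contacts of 2-3 Å are
invisible to a Cα-Cα measure); Cα mode is kept for comparison.  When one
protein is a homodimer, its segment maps to several chains and the
reported distance is the minimum over mapped chains — the model does not
say which protomer an interaction uses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .exceptions import ConfigurationError, FormatError, ParameterError, ResidueLookupError
from .pair_analysis import AnnotatedPair, with_distance

logger = logging.getLogger(__name__)

MODE_HEAVY = "heavy_atom_min"
MODE_CALPHA = "calpha"


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: int
    name: str
    #: atom name -> (x, y, z) in Å; heavy atoms only
    atoms: dict


@dataclass
class StructureModel:
    """Heavy-atom coordinates of a complex, indexed by (chain, residue)."""

    #: chain id -> {residue number -> Residue}
    chains: dict

    def residue(self, chain_id: str, number: int) -> Residue:
        try:
            return self.chains[chain_id][number]
        except KeyError:
            raise ResidueLookupError(
                f"residue {number} of chain {chain_id!r} not in structure"
            ) from None

    def has_residue(self, chain_id: str, number: int) -> bool:
        return chain_id in self.chains and number in self.chains[chain_id]


def read_structure(path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Keeps ATOM-record heavy atoms; hydrogens and HETATM records are
    ignored.  Parsing is strict: a malformed record raises a
    :class:`~pairdca.exceptions.FormatError` naming the offending line.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise FormatError(f"malformed PDB {path}: {exc}") from exc
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    chains: dict = {}
    model = next(structure.get_models(), None)
    if model is None:
        raise FormatError(f"{path}: no models in structure")
    for chain in model:
        residues = {}
        for res in chain:
            hetflag, resnum, _ = res.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            atoms = {
                atom.get_name(): np.array(atom.get_coord(), dtype=float)
                for atom in res
                if (atom.element or "").upper() != "H"
            }
            if atoms:
                residues[resnum] = Residue(chain.id, resnum, res.get_resname(), atoms)
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise FormatError(f"{path}: no ATOM records")
    return StructureModel(chains)


def residue_min_distance(
    s: StructureModel,
    res1: tuple[str, int],
    res2: tuple[str, int],
    mode: str = MODE_HEAVY,
) -> float:
    """Distance (Å) between two residues.

    ``heavy_atom_min`` minimises over all heavy-atom pairs;
    ``calpha`` measures Cα-Cα and fails if a residue lacks a Cα.
    """
    r1 = s.residue(*res1)
    r2 = s.residue(*res2)
    if mode == MODE_CALPHA:
        for r in (r1, r2):
            if "CA" not in r.atoms:
                raise ParameterError(
                    f"residue {r.number} of chain {r.chain_id!r} has no CA atom"
                )
        return float(np.linalg.norm(r1.atoms["CA"] - r2.atoms["CA"]))
    if mode != MODE_HEAVY:
        raise ParameterError(f"unknown distance mode {mode!r}")
    a1 = np.stack(list(r1.atoms.values()))
    a2 = np.stack(list(r2.atoms.values()))
    d2 = ((a1[:, None, :] - a2[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def annotate_pairs_with_distances(
    pairs: list[AnnotatedPair],
    s: StructureModel,
    chain_map: dict,
    mode: str = MODE_HEAVY,
) -> list[AnnotatedPair]:
    """Fill the distance field of ranked pairs from the structure.

    ``chain_map`` maps segment tags ("A", "B") to one or more chain ids;
    a segment mapped to several chains (a dimer) gets the minimum distance
    over all chain combinations.  A pair whose residue is unresolved in
    the structure keeps ``distance=None`` rather than failing.
    """
    if not chain_map:
        raise ConfigurationError("empty chain map")
    norm = {}
    for seg, chains in chain_map.items():
        ids = [chains] if isinstance(chains, str) else list(chains)
        missing = [c for c in ids if c not in s.chains]
        if missing:
            raise ConfigurationError(
                f"chain(s) {missing} mapped to segment {seg} absent from structure"
            )
        norm[seg] = ids
    out = []
    for p in pairs:
        try:
            chains_i = norm[p.protein_i]
            chains_j = norm[p.protein_j]
        except KeyError as exc:
            raise ConfigurationError(f"segment {exc.args[0]!r} missing from chain map") from None
        best = None
        for ci in chains_i:
            for cj in chains_j:
                if not (s.has_residue(ci, p.res_i) and s.has_residue(cj, p.res_j)):
                    continue
                d = residue_min_distance(s, (ci, p.res_i), (cj, p.res_j), mode=mode)
                if best is None or d < best:
                    best = d
        if best is None:
            logger.warning(
                "pair %s:%d / %s:%d unresolved in structure; distance left missing",
                p.protein_i, p.res_i, p.protein_j, p.res_j,
            )
        out.append(with_distance(p, best))
    return out
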