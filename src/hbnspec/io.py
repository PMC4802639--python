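"""PDB and table input/output.

Structures arrive as standard PDB files (models built elsewhere; the
coordinates are consumed as-is, no optimisation or hydrogen placement).
A :class:`SiteMap` translates file residue numbering to bovine-rhodopsin
site numbering — the identity map by default, which is correct for
models numbered on the rhodopsin template — and selects the water
molecules and the Schiff-base nitrogen atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from .geometry import HBN_SITES, HBNStructure

log = logging.getLogger(__name__)

#: Default Schiff-base nitrogen selector: the NZ of the retinal-binding
#: lysine at site 296 (any HETATM/ATOM residue numbered 296 with an NZ,
#: or a retinal-lysine adduct residue).
DEFAULT_SB_RESIDUE = 296
DEFAULT_SB_ATOM = "NZ"


class StructureReadError(ValueError):
    pass


@dataclass
class SiteMap:
    """Mapping from PDB addressing to bovine-rhodopsin site numbers.

    ``residue_map`` sends ``(chain_id, residue_number)`` to a site
    number; empty means identity on residue numbers over all chains.
    ``water_ids`` lists the residue numbers of the (up to two) HBN
    waters; empty means: take the first two HOH residues encountered.
    """

    residue_map: Dict[Tuple[str, int], int] = field(default_factory=dict)
    water_ids: List[int] = field(default_factory=list)
    sb_residue: int = DEFAULT_SB_RESIDUE
    sb_atom: str = DEFAULT_SB_ATOM

    def __post_init__(self) -> None:
        sites = list(self.residue_map.values())
        if len(sites) != len(set(sites)):
            raise ValueError("site map is not injective")

    def site_of(self, chain_id: str, resnum: int) -> Optional[int]:
        if self.residue_map:
            return self.residue_map.get((chain_id, resnum))
        return resnum if resnum in HBN_SITES else None

    @classmethod
    def from_yaml(cls, path) -> "SiteMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        residue_map = {
            (str(e["chain"]), int(e["residue"])): int(e["site"])
            for e in doc.get("residues", [])
        }
        return cls(
            residue_map=residue_map,
            water_ids=[int(w) for w in doc.get("waters", [])],
            sb_residue=int(doc.get("sb_residue", DEFAULT_SB_RESIDUE)),
            sb_atom=str(doc.get("sb_atom", DEFAULT_SB_ATOM)),
        )


def read_structure(
    pdb_path, site_map: Optional[SiteMap] = None, pigment_id: Optional[str] = None
) -> HBNStructure:
    """Read an :class:`HBNStructure` from a PDB file.

    Only residues mapped to HBN sites, the configured waters and the
    Schiff-base nitrogen are extracted; hydrogens and alternate
    locations other than the primary are ignored.  Unmapped HBN sites
    are logged (site 86 may legitimately be absent).
    """
    site_map = site_map or SiteMap()
    parser = PDBParser(QUIET=True)
    try:
        model = parser.get_structure("s", str(pdb_path))[0]
    except Exception as exc:  # Bio.PDB raises assorted types on bad input
        raise StructureReadError(f"cannot parse {pdb_path}: {exc}") from exc

    residues: Dict[int, Dict[str, np.ndarray]] = {}
    waters: Dict[str, np.ndarray] = {}
    sb_nitrogen = None
    n_waters_taken = 0
    for chain in model:
        for res in chain:
            resnum = res.id[1]
            resname = res.get_resname().strip()
            if resname == "HOH":
                wanted = not site_map.water_ids or resnum in site_map.water_ids
                if wanted and n_waters_taken < 2:
                    atom = next(iter(res))
                    waters[f"W{n_waters_taken + 1}"] = atom.coord.astype(float)
                    n_waters_taken += 1
                continue
            if resnum == site_map.sb_residue:
                for atom in res:
                    if atom.get_name() == site_map.sb_atom:
                        sb_nitrogen = atom.coord.astype(float)
            site = site_map.site_of(chain.id, resnum)
            if site is None:
                continue
            atoms = {}
            for atom in res:
                if atom.element == "H":
                    continue
                if atom.get_altloc() not in (" ", "A"):
                    continue
                atoms[atom.get_name()] = atom.coord.astype(float)
            if atoms:
                residues[site] = atoms
    if not residues:
        raise StructureReadError(f"{pdb_path}: no mapped HBN sites found")
    for site in HBN_SITES:
        if site not in residues:
            log.info("%s: HBN site %d not present in %s", pigment_id or "structure", site, pdb_path)
    return HBNStructure(
        pigment_id=pigment_id or str(pdb_path),
        residues=residues,
        sb_nitrogen=sb_nitrogen,
        waters=waters,
    )


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with header, checking mandatory columns; an empty file
    yields an empty frame with a warning."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        log.warning("%s: empty table", path)
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return df


def write_table(df: pd.DataFrame, path, columns: Optional[Sequence[str]] = None) -> None:
    """Write a TSV with a deterministic column order (declared columns
    first, any extra columns after, in sorted order)."""
    if columns:
        extra = sorted(c for c in df.columns if c not in columns)
        df = df[[*columns, *extra]]
    df.to_csv(path, sep="\t", index=False)
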