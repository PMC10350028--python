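"""Reading refined B-factors at named sites from PDB-format coordinate files.

Supports the workflow of pulling the refined isotropic B of specific atoms
(e.g. the four sulfides of a [4Fe:4S] cluster) into a :class:`~zbcorr.fit.ZBTable`
for model fitting or occupancy inversion.  PDB-format text only; parsing is
delegated to gemmi, which also supplies the element -> atomic number lookup.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi

from .fit import ZBTable

__all__ = ["SiteSelection", "read_bfactor_sites"]


@dataclass(frozen=True)
class SiteSelection:
    """One atom site: chain / residue name / residue number / atom name [/ altloc]."""

    chain: str
    res_name: str
    res_seq: int
    atom: str
    altloc: str | None = None

    def __post_init__(self) -> None:
        if not self.atom:
            raise ValueError("atom name must be non-empty")

    def __str__(self) -> str:
        alt = f":{self.altloc}" if self.altloc else ""
        return f"{self.chain}/{self.res_name}{self.res_seq}/{self.atom}{alt}"

    @classmethod
    def parse(cls, text: str) -> "SiteSelection":
        """Parse ``CHAIN:RESNAME:RESSEQ:ATOM[:ALTLOC]``."""
        parts = text.split(":")
        if len(parts) not in (4, 5):
            raise ValueError(
                f"selection {text!r} must be CHAIN:RESNAME:RESSEQ:ATOM[:ALTLOC]"
            )
        chain, res_name, res_seq, atom = parts[:4]
        altloc = parts[4] if len(parts) == 5 else None
        return cls(chain=chain, res_name=res_name, res_seq=int(res_seq), atom=atom, altloc=altloc)


def _element_z(symbol: str, element_map: Mapping[str, int] | None) -> int:
    if element_map and symbol in element_map:
        return int(element_map[symbol])
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return el.atomic_number


def read_bfactor_sites(
    path,
    selections: Sequence[SiteSelection],
    element_map: Mapping[str, int] | None = None,
) -> ZBTable:
    """Extract (element, Z, B_iso) rows for the selected atoms of a PDB file.

    Each selection must resolve to at least one atom; unresolved selections
    raise a ``ValueError`` listing every miss.  Occupancy is carried through
    in the row label as ``chain/res/atom occ=x.xx``.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in file")
    model = structure[0]
    records: list[dict] = []
    misses: list[str] = []
    for sel in selections:
        found = False
        for chain in model:
            if chain.name != sel.chain:
                continue
            for residue in chain:
                if residue.name != sel.res_name or residue.seqid.num != sel.res_seq:
                    continue
                for atom in residue:
                    if atom.name != sel.atom:
                        continue
                    if sel.altloc and atom.altloc != sel.altloc:
                        continue
                    if atom.b_iso <= 0:
                        raise ValueError(
                            f"{sel}: non-positive isotropic B ({atom.b_iso}); if the file "
                            "carries only anisotropic ADPs, convert them to B_iso first"
                        )
                    symbol = atom.element.name
                    records.append(
                        {
                            "element": symbol,
                            "Z": float(_element_z(symbol, element_map)),
                            "B_iso": float(atom.b_iso),
                            "label": f"{sel} occ={atom.occ:.2f}",
                        }
                    )
                    found = True
        if not found:
            misses.append(str(sel))
    if misses:
        raise ValueError(f"unresolved selections: {', '.join(misses)}")
    import pandas as pd

    if not records:
        return ZBTable(pd.DataFrame(columns=list(ZBTable.COLUMNS)))
    return ZBTable.from_records(records)
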