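"""Minimal PDB v3.3 text formatting shared by the conformer writer and the
synthetic-fixture generator. Reading is done with Biopython; only writing is
hand-formatted here because both producers need byte-deterministic output.
"""

from __future__ import annotations

__all__ = ["format_atom_line", "format_ter_line"]


def format_atom_line(serial: int, name: str, res_name: str, chain_id: str,
                     res_seq: int, x: float, y: float, z: float,
                     element: str, record: str = "ATOM") -> str:
    """One fixed-width ATOM/HETATM record (PDB v3.3 columns)."""
    # names of up to three characters start in column 14
    atom_field = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:5d} {atom_field:4s} {res_name:<3s} "
            f"{chain_id}{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def format_ter_line(serial: int, res_name: str, chain_id: str,
                    res_seq: int) -> str:
    return f"TER   {serial:5d}      {res_name:<3s} {chain_id}{res_seq:4d}"
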