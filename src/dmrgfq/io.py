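"""Plain-text geometry I/O: XYZ files (single and multi-frame).

XYZ coordinates are in Ångström on disk and converted to Bohr by callers
that need atomic units.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_xyz", "read_multi_xyz", "write_xyz", "write_multi_xyz"]


def _parse_block(lines, start):
    natoms = int(lines[start].split()[0])
    comment = lines[start + 1].rstrip("\n")
    elements, coords = [], []
    for ln in lines[start + 2 : start + 2 + natoms]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords), comment, start + 2 + natoms


def read_xyz(path):
    """Read a single-frame XYZ file -> (elements, coords_angstrom, comment)."""
    with open(path) as fh:
        lines = fh.readlines()
    elements, coords, comment, _ = _parse_block(lines, 0)
    return elements, coords, comment


def read_multi_xyz(path):
    """Read concatenated XYZ blocks -> list of (elements, coords_angstrom, comment)."""
    with open(path) as fh:
        lines = [ln for ln in fh.readlines() if ln.strip() or True]
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        elements, coords, comment, pos = _parse_block(lines, pos)
        frames.append((elements, coords, comment))
    return frames


def _format_block(elements, coords, comment=""):
    out = [f"{len(elements)}", comment]
    for el, (x, y, z) in zip(elements, coords):
        out.append(f"{el:<4s} {x: .10f} {y: .10f} {z: .10f}")
    return "\n".join(out) + "\n"


def write_xyz(path, elements, coords, comment=""):
    with open(path, "w") as fh:
        fh.write(_format_block(elements, coords, comment))


def write_multi_xyz(path, frames):
    """Write a list of (elements, coords, comment) blocks to one file."""
    with open(path, "w") as fh:
        for elements, coords, comment in frames:
            fh.write(_format_block(elements, coords, comment))
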