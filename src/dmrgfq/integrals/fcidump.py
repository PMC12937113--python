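"""FCIDUMP (Molpro convention) text I/O for active-space integrals.

Layout: a namelist header (&FCI NORB=..., NELEC=..., MS2=..., ORBSYM=...,
ISYM=... &END) followed by lines ``value i j k l`` with 1-based indices:
two-electron (ij|kl) for i,j,k,l > 0, one-electron h_ij for k = l = 0, and
the core energy for i = j = k = l = 0.  Only symmetry-unique two-electron
elements are written.
"""

from __future__ import annotations

import re

import numpy as np

from .active_space import ActiveSpaceIntegrals

__all__ = ["read_fcidump", "write_fcidump"]


def write_fcidump(path, integrals: ActiveSpaceIntegrals, orbsym=None, tol=0.0):
    L = integrals.n_orbitals_active
    if orbsym is None:
        orbsym = [1] * L
    lines = [
        f"&FCI NORB={L},NELEC={integrals.n_electrons_active},"
        f"MS2={integrals.spin_projection},",
        " ORBSYM=" + ",".join(str(s) for s in orbsym) + ",",
        " ISYM=1,",
        "&END",
    ]

    def emit(v, i, j, k, l):
        lines.append(f"{v: .16e} {i:4d} {j:4d} {k:4d} {l:4d}")

    g = integrals.g
    for i in range(L):
        for j in range(i + 1):
            for k in range(i + 1):
                lmax = j if k == i else k
                for l in range(lmax + 1):
                    v = g[i, j, k, l]
                    if abs(v) > tol:
                        emit(v, i + 1, j + 1, k + 1, l + 1)
    for i in range(L):
        for j in range(i + 1):
            v = integrals.h[i, j]
            if abs(v) > tol:
                emit(v, i + 1, j + 1, 0, 0)
    emit(integrals.core_energy, 0, 0, 0, 0)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_header(text):
    m = re.search(r"&FCI(.*?)(?:&END|/)", text, flags=re.S | re.I)
    if not m:
        raise ValueError("no &FCI namelist header found")
    body = m.group(1)
    fields = {}
    for key in ("NORB", "NELEC", "MS2", "ISYM"):
        km = re.search(rf"{key}\s*=\s*(-?\d+)", body, flags=re.I)
        if km:
            fields[key] = int(km.group(1))
    om = re.search(r"ORBSYM\s*=\s*([\d,\s]+)", body, flags=re.I)
    if om:
        fields["ORBSYM"] = [int(x) for x in re.findall(r"\d+", om.group(1))]
    if "NORB" not in fields or "NELEC" not in fields:
        raise ValueError("FCIDUMP header missing NORB or NELEC")
    return fields, m.end()


def read_fcidump(path) -> ActiveSpaceIntegrals:
    with open(path) as fh:
        text = fh.read()
    fields, offset = _parse_header(text)
    L = fields["NORB"]
    h = np.zeros((L, L))
    g = np.zeros((L, L, L, L))
    core = 0.0
    for line in text[offset:].splitlines():
        parts = line.split()
        if len(parts) != 5:
            continue
        v = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        if i == j == k == l == 0:
            core = v
        elif k == 0 and l == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = v
        else:
            i, j, k, l = i - 1, j - 1, k - 1, l - 1
            for p, q in ((i, j), (j, i)):
                for r, s in ((k, l), (l, k)):
                    g[p, q, r, s] = g[r, s, p, q] = v
    return ActiveSpaceIntegrals(
        h=h,
        g=g,
        core_energy=core,
        n_electrons_active=fields["NELEC"],
        spin_projection=fields.get("MS2", 0),
        metadata={"orbsym": fields.get("ORBSYM", [1] * L)},
    )
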