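"""Wavefunction file readers: Molden, AIM .wfn/.wfx, and the package's
compact JSON fixture format.

Only closed-shell determinants are accepted; anything spin-polarized is
rejected loudly rather than silently collapsed.  d shells are cartesian
(6d, Molden order); spherical-harmonic d input raises an explicit error
because a silent mis-assignment would corrupt every downstream observable.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .wavefunction import (ANGSTROM, ELEMENTS, NCART, SYMBOLS, Nucleus, Shell,
                           Wavefunction, WavefunctionError, _double_fact,
                           _symmetric_orthonormalize)

__all__ = ["read_wavefunction", "ParseError"]


class ParseError(Exception):
    """A wavefunction file could not be parsed; the message names the record."""


_L_OF = {"s": 0, "p": 1, "d": 2}
# AIM primitive type codes -> (l, cartesian component index in Molden order)
_WFN_TYPE = {1: (0, 0),
             2: (1, 0), 3: (1, 1), 4: (1, 2),
             5: (2, 0), 6: (2, 1), 7: (2, 2), 8: (2, 3), 9: (2, 4), 10: (2, 5)}


def read_wavefunction(path, format: str = "auto") -> Wavefunction:
    """Parse a wavefunction file into the internal GTO representation.

    Supported formats: ``molden``, ``wfn``, ``wfx``, ``json`` (the package's
    fixture format); ``auto`` sniffs the extension and content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if format == "auto":
        ext = path.suffix.lower().lstrip(".")
        if ext in ("molden", "wfn", "wfx", "json"):
            format = ext
        elif "[Molden Format]" in text:
            format = "molden"
        elif "<Number of Nuclei>" in text:
            format = "wfx"
        elif text.lstrip().startswith("{"):
            format = "json"
        elif re.search(r"MOL\s*ORBITALS", text):
            format = "wfn"
        else:
            raise ParseError(f"cannot determine wavefunction format of {path}")
    reader = {"molden": _read_molden, "wfn": _read_wfn, "wfx": _read_wfx,
              "json": _read_json}.get(format)
    if reader is None:
        raise ParseError(f"unknown format {format!r}")
    try:
        wf = reader(text)
    except (IndexError, ValueError, KeyError) as e:
        raise ParseError(f"truncated or malformed {format} file: {e}") from e
    wf.validate()
    return wf


# ------------------------------------------------------------------- molden
def _read_molden(text: str) -> Wavefunction:
    if "[Molden Format]" not in text:
        raise ParseError("missing [Molden Format] header")
    if re.search(r"\[(5D|5D7F|5D10F|7F|9G)\]", text):
        raise ParseError("spherical-harmonic shells ([5D]-style) are not supported; "
                         "re-export with cartesian (6d) functions")
    sections = {}
    current = None
    for line in text.splitlines():
        m = re.match(r"\s*\[([A-Za-z0-9 ]+)\]\s*(.*)", line)
        if m:
            current = m.group(1).strip().lower()
            sections[current] = [m.group(2)] if m.group(2).strip() else []
        elif current is not None:
            sections[current].append(line)

    if "atoms" not in sections:
        raise ParseError("missing [Atoms] section")
    unit = 1.0
    head = sections["atoms"][0].strip().lower() if sections["atoms"] else ""
    body = sections["atoms"][1:] if head in ("au", "angs", "(au)", "(angs)") else sections["atoms"]
    if head.startswith("angs"):
        unit = ANGSTROM
    nuclei = []
    for line in body:
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"malformed [Atoms] record: {line!r}")
        sym, _, z = parts[0], parts[1], int(parts[2])
        xyz = np.array([float(v) for v in parts[3:6]]) * unit
        nuclei.append(Nucleus(sym.capitalize(), float(z), xyz))

    if "gto" not in sections:
        raise ParseError("missing [GTO] section")
    shells = []
    lines = [ln for ln in sections["gto"]]
    i = 0
    natom_seen = 0
    while i < len(lines):
        ln = lines[i].strip()
        i += 1
        if not ln:
            continue
        parts = ln.split()
        if not parts[0].isdigit():
            raise ParseError(f"expected atom index in [GTO], got {ln!r}")
        iatom = int(parts[0]) - 1
        natom_seen += 1
        # shell blocks until blank line
        while i < len(lines):
            ln = lines[i].strip()
            i += 1
            if not ln:
                break
            p = ln.split()
            ltag = p[0].lower()
            if ltag not in _L_OF:
                raise ParseError(f"unsupported shell type {ltag!r} in [GTO]")
            nprim = int(p[1])
            exps, coefs = [], []
            for _ in range(nprim):
                if i >= len(lines):
                    raise ParseError("truncated [GTO] primitive table")
                row = lines[i].replace("D", "E").replace("d", "e").split()
                i += 1
                exps.append(float(row[0]))
                coefs.append(float(row[1]))
            shells.append(Shell(iatom, _L_OF[ltag], np.array(exps), np.array(coefs)))
    if natom_seen < len(nuclei):
        raise ParseError("truncated [GTO] section: fewer atoms than in [Atoms]")

    if "mo" not in sections:
        raise ParseError("missing [MO] section")
    nbf = sum(NCART[s.l] for s in shells)
    cols, occs = [], []
    cur = None
    occ = None
    spin = "alpha"
    for ln in sections["mo"] + ["Sym= _end"]:
        s = ln.strip()
        m = re.match(r"(Sym|Ene|Spin|Occup)\s*=\s*(.*)", s, re.I)
        if m:
            key = m.group(1).lower()
            if key == "sym" and cur is not None:
                _close_mo(cols, occs, cur, occ, spin, nbf)
                cur, occ, spin = None, None, "alpha"
            if key == "sym":
                cur = np.zeros(nbf)
            elif key == "occup":
                occ = float(m.group(2))
            elif key == "spin":
                spin = m.group(2).strip().lower()
        elif s:
            if cur is None:
                cur = np.zeros(nbf)
            parts = s.split()
            if len(parts) != 2:
                raise ParseError(f"malformed [MO] coefficient line: {s!r}")
            idx = int(parts[0]) - 1
            if idx >= nbf:
                raise ParseError(f"MO coefficient index {idx + 1} exceeds basis size {nbf}")
            cur[idx] = float(parts[1].replace("D", "E").replace("d", "e"))
    if not cols:
        raise ParseError("no occupied MOs found in [MO] section")
    charge = int(round(sum(n.charge for n in nuclei) - sum(occs)))
    return Wavefunction(nuclei, shells, np.column_stack(cols), np.array(occs), charge)


def _close_mo(cols, occs, cur, occ, spin, nbf):
    if occ is None:
        raise ParseError("[MO] block missing Occup= record")
    if spin not in ("alpha",):
        if occ > 0:
            raise WavefunctionError("open-shell (beta-spin) input is not supported")
        return
    if occ <= 0:
        return
    if abs(occ - 2.0) > 1e-8:
        raise WavefunctionError(
            f"fractional/single occupation {occ} - only closed-shell determinants supported")
    cols.append(cur)
    occs.append(occ)


# ----------------------------------------------------------------- wfn/wfx
def _primitive_wavefunction(nuclei, centers, types, exps, occs, coef_rows):
    """Assemble shells from expanded AIM primitives.

    coef_rows: (nmo, nprim) coefficients multiplying *unnormalized* cartesian
    primitives, the AIMPAC convention.
    """
    groups = {}   # (center, l, exponent) -> shell slot
    order = []
    for p, (ic, it, al) in enumerate(zip(centers, types, exps)):
        if it not in _WFN_TYPE:
            raise ParseError(f"unsupported primitive type code {it} (beyond d)")
        l, comp = _WFN_TYPE[it]
        key = (ic, l, round(float(al), 10))
        if key not in groups:
            groups[key] = len(order)
            order.append(key)
    shells = [Shell(k[0], k[1], np.array([k[2]]), np.array([1.0])) for k in order]
    offs = np.cumsum([0] + [s.ncart for s in shells])
    nbf = offs[-1]
    nmo = len(occs)
    C = np.zeros((nbf, nmo))
    for p, (ic, it, al) in enumerate(zip(centers, types, exps)):
        l, comp = _WFN_TYPE[it]
        ish = groups[(ic, l, round(float(al), 10))]
        sh = shells[ish]
        # our basis function = comp_scale * N_(l00) * monomial * exp
        n_l00 = (2 * al / np.pi) ** 0.75 * (4 * al) ** (l / 2.0) / np.sqrt(_double_fact(2 * l - 1))
        scale = sh.component_scales()[comp] * n_l00
        C[offs[ish] + comp, :] += coef_rows[:, p] / scale
    return Wavefunction(nuclei, shells, C, np.asarray(occs, float),
                        int(round(sum(n.charge for n in nuclei) - sum(occs))))


def _read_wfn(text: str) -> Wavefunction:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("truncated .wfn file")
    m = re.search(r"(\d+)\s+MOL\s*ORBITALS\s+(\d+)\s+PRIMITIVES\s+(\d+)\s+NUCLEI",
                  lines[1], re.I)
    if not m:
        raise ParseError("missing .wfn header counts line")
    nmo, nprim, nnuc = (int(g) for g in m.groups())
    nuclei = []
    i = 2
    for _ in range(nnuc):
        ln = lines[i]
        i += 1
        mm = re.match(r"\s*([A-Za-z]+)\s*\d*\s+\d+\s+\(CENTRE\s*\d+\)\s+"
                      r"([-\d.]+)\s+([-\d.]+)\s+([-\d.]+)\s+CHARGE\s*=\s*([\d.]+)", ln)
        if not mm:
            raise ParseError(f"malformed nucleus record: {ln!r}")
        sym = mm.group(1).capitalize()
        xyz = np.array([float(mm.group(k)) for k in (2, 3, 4)])
        nuclei.append(Nucleus(sym, float(mm.group(5)), xyz))

    def read_ints(tag, count):
        nonlocal i
        vals = []
        while len(vals) < count:
            if i >= len(lines):
                raise ParseError(f"truncated {tag} table")
            if tag not in lines[i].upper().replace(" ", ""):
                raise ParseError(f"expected {tag} record, got {lines[i]!r}")
            vals.extend(int(v) for v in lines[i].split("ASSIGNMENTS")[-1].split())
            i += 1
        return vals

    centers = read_ints("CENTREASSIGNMENTS", nprim)
    types = read_ints("TYPEASSIGNMENTS", nprim)
    exps = []
    while len(exps) < nprim:
        if i >= len(lines) or "EXPONENTS" not in lines[i].upper():
            raise ParseError("truncated EXPONENTS table")
        exps.extend(float(v.replace("D", "E")) for v in lines[i].split()[1:])
        i += 1
    occs, rows = [], []
    while i < len(lines):
        ln = lines[i]
        if ln.strip().upper().startswith("END DATA"):
            break
        mm = re.search(r"OCC\s*NO\s*=\s*([-\d.DEde+]+)", ln)
        if mm:
            occ = float(mm.group(1).replace("D", "E"))
            i += 1
            coefs = []
            while len(coefs) < nprim:
                if i >= len(lines):
                    raise ParseError("truncated MO coefficient block")
                coefs.extend(float(v.replace("D", "E")) for v in lines[i].split())
                i += 1
            if occ > 0:
                if abs(occ - 2.0) > 1e-8:
                    raise WavefunctionError("only closed-shell .wfn files supported")
                occs.append(occ)
                rows.append(coefs)
        else:
            i += 1
    if len(occs) == 0:
        raise ParseError("no occupied MOs in .wfn file")
    centers0 = [c - 1 for c in centers]
    return _primitive_wavefunction(nuclei, centers0, types, np.array(exps),
                                   occs, np.array(rows))


def _wfx_tag(text, name, required=True):
    m = re.search(rf"<{re.escape(name)}>\s*(.*?)\s*</{re.escape(name)}>", text, re.S)
    if not m:
        if required:
            raise ParseError(f"missing <{name}> section in .wfx file")
        return None
    return m.group(1)


def _read_wfx(text: str) -> Wavefunction:
    natom = int(_wfx_tag(text, "Number of Nuclei"))
    nprim = int(_wfx_tag(text, "Number of Primitives"))
    syms_raw = _wfx_tag(text, "Nuclear Names", required=False)
    zs = [float(v) for v in _wfx_tag(text, "Nuclear Charges").split()]
    coords = np.array([float(v) for v in
                       _wfx_tag(text, "Nuclear Cartesian Coordinates").split()]).reshape(-1, 3)
    if len(zs) != natom or len(coords) != natom:
        raise ParseError("nucleus table lengths disagree in .wfx file")
    if syms_raw:
        syms = [re.sub(r"\d", "", s) for s in syms_raw.split()]
    else:
        syms = [SYMBOLS.get(int(z), "X") for z in zs]
    nuclei = [Nucleus(s.capitalize(), z, c) for s, z, c in zip(syms, zs, coords)]
    centers = [int(v) - 1 for v in _wfx_tag(text, "Primitive Centers").split()]
    types = [int(v) for v in _wfx_tag(text, "Primitive Types").split()]
    exps = np.array([float(v.replace("D", "E")) for v in
                     _wfx_tag(text, "Primitive Exponents").split()])
    if not (len(centers) == len(types) == len(exps) == nprim):
        raise ParseError("primitive table lengths disagree in .wfx file")
    occs = [float(v) for v in
            _wfx_tag(text, "Molecular Orbital Occupation Numbers").split()]
    coef_sec = _wfx_tag(text, "Molecular Orbital Primitive Coefficients")
    blocks = re.split(r"<MO Number>\s*\d+\s*</MO Number>", coef_sec)[1:]
    if len(blocks) != len(occs):
        raise ParseError("MO coefficient blocks do not match occupation count")
    rows, kept = [], []
    for occ, blk in zip(occs, blocks):
        if occ <= 0:
            continue
        if abs(occ - 2.0) > 1e-8:
            raise WavefunctionError("only closed-shell .wfx files supported")
        vals = [float(v.replace("D", "E")) for v in blk.split()]
        if len(vals) != nprim:
            raise ParseError("truncated MO coefficient block in .wfx file")
        rows.append(vals)
        kept.append(occ)
    return _primitive_wavefunction(nuclei, centers, types, exps, kept, np.array(rows))


# -------------------------------------------------------------------- json
def _read_json(text: str) -> Wavefunction:
    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON wavefunction: {e}") from e
    if d.get("format") != "elfiqa-wavefunction-1":
        raise ParseError("not an elfiqa wavefunction JSON (missing format tag)")
    charges = d.get("nuclear_charges") or [float(ELEMENTS[s]) for s in d["symbols"]]
    nuclei = [Nucleus(s, float(z), np.array(x))
              for s, z, x in zip(d["symbols"], charges, d["coords_bohr"])]
    shells = [Shell(c, l, np.array(e), np.array(co)) for c, l, e, co in d["shells"]]
    C = np.array(d["mo_coefficients"])
    occ = np.array(d["mo_occupations"], float)
    wf = Wavefunction(nuclei, shells, C, occ, int(d.get("charge", 0)),
                      meta=d.get("meta", {}))
    # stored coefficients are rounded; restore orthonormality in their span
    S = wf.overlap_matrix()
    wf.mo_coefficients = _symmetric_orthonormalize(C, S)
    return wf


def write_fixture_json(wf: Wavefunction, name: str, path, ndigits: int = 5,
                       meta: dict | None = None):
    """Serialize a wavefunction to the compact fixture format."""
    d = {
        "format": "elfiqa-wavefunction-1",
        "name": name,
        "symbols": [n.symbol for n in wf.nuclei],
        "nuclear_charges": [float(n.charge) for n in wf.nuclei],
        "charge": wf.net_charge,
        "coords_bohr": [[round(float(v), 8) for v in n.xyz] for n in wf.nuclei],
        "shells": [[s.center, s.l, [float(e) for e in s.exponents],
                    [float(c) for c in s.coefficients]] for s in wf.shells],
        "mo_occupations": [float(o) for o in wf.mo_occupations],
        "mo_coefficients": [[float(f"{v:.{ndigits}e}") for v in row]
                            for row in wf.mo_coefficients],
        "meta": meta or wf.meta,
    }
    Path(path).write_text(json.dumps(d, separators=(",", ":")))
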