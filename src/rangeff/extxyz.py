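"""Extended-XYZ reader/writer.

Per-frame metadata lives in the comment line as ``key=value`` pairs
(``Lattice``, ``pbc``, ``energy``, plus free-form string tags); per-atom data
is described by the ``Properties`` key, e.g.
``Properties=species:S:1:pos:R:3:forces:R:3``. Round-trips preserve all
fields the package uses.
"""

from __future__ import annotations

import re
from typing import Optional

import numpy as np

from .elements import number_of, symbol_of
from .graph_core import AtomicConfiguration

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KV_RE.finditer(line.strip()):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _parse_properties(spec: str):
    fields = spec.split(":")
    if len(fields) % 3:
        raise ValueError(f"malformed Properties spec {spec!r}")
    cols = []
    for i in range(0, len(fields), 3):
        cols.append((fields[i], fields[i + 1], int(fields[i + 2])))
    return cols


def read_extxyz(path) -> list:
    """Read all frames of an extended-XYZ file."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        natoms = int(lines[i].strip())
        meta = _parse_comment(lines[i + 1])
        cols = _parse_properties(meta.pop("Properties", "species:S:1:pos:R:3"))
        rows = [lines[i + 2 + k].split() for k in range(natoms)]
        i += 2 + natoms

        species = np.zeros(natoms, dtype=np.int64)
        arrays: dict[str, np.ndarray] = {}
        col = 0
        for name, kind, width in cols:
            if name == "species":
                for k, row in enumerate(rows):
                    tok = row[col]
                    species[k] = int(tok) if tok.isdigit() else number_of(tok)
            else:
                arrays[name] = np.array(
                    [[float(row[col + w]) for w in range(width)] for row in rows]
                )
                if width == 1:
                    arrays[name] = arrays[name].reshape(-1)
            col += width

        cell = pbc = None
        if "Lattice" in meta:
            cell = np.fromstring(meta.pop("Lattice"), sep=" ").reshape(3, 3)
        if "pbc" in meta:
            pbc = np.array([t in ("T", "True", "1") for t in meta.pop("pbc").split()])
        energy = float(meta.pop("energy")) if "energy" in meta else None

        pos = arrays.pop("pos")
        forces = arrays.pop("forces", None)
        tags = dict(meta)
        for name, arr in arrays.items():  # extra per-atom columns survive as tags
            tags[f"column:{name}"] = " ".join(f"{float(v):.12g}" for v in np.ravel(arr))
        frames.append(
            AtomicConfiguration(
                positions=pos,
                species=species,
                cell=cell,
                pbc=pbc,
                energy=energy,
                forces=forces,
                tags=tags,
            )
        )
    return frames


def _fmt(v: float) -> str:
    return f"{v:.12g}"


def write_extxyz(
    path,
    configs,
    extra_columns: Optional[dict] = None,
    mode: str = "w",
) -> None:
    """Write frames to extended XYZ.

    ``extra_columns`` maps column name → list of per-frame (n_atoms,) arrays
    appended as additional real per-atom columns.
    """
    if isinstance(configs, AtomicConfiguration):
        configs = [configs]
    extra_columns = extra_columns or {}
    with open(path, mode) as fh:
        for fi, c in enumerate(configs):
            props = "species:S:1:pos:R:3"
            blocks = [None, c.positions]
            if c.forces is not None:
                props += ":forces:R:3"
                blocks.append(c.forces)
            extras = []
            for name, per_frame in extra_columns.items():
                arr = np.asarray(per_frame[fi], dtype=np.float64).reshape(-1)
                if len(arr) != c.n_atoms:
                    raise ValueError(f"extra column {name!r} length mismatch")
                props += f":{name}:R:1"
                extras.append(arr)

            parts = [f"Properties={props}"]
            if c.cell is not None:
                parts.append('Lattice="' + " ".join(_fmt(v) for v in c.cell.ravel()) + '"')
            if c.pbc is not None:
                parts.append('pbc="' + " ".join("T" if b else "F" for b in c.pbc) + '"')
            if c.energy is not None:
                parts.append(f"energy={_fmt(c.energy)}")
            for k, v in c.tags.items():
                if k.startswith("column:"):
                    continue
                sv = str(v)
                parts.append(f'{k}="{sv}"' if " " in sv else f"{k}={sv}")

            fh.write(f"{c.n_atoms}\n{' '.join(parts)}\n")
            for a in range(c.n_atoms):
                row = [symbol_of(int(c.species[a]))]
                row += [_fmt(v) for v in c.positions[a]]
                if c.forces is not None:
                    row += [_fmt(v) for v in c.forces[a]]
                for arr in extras:
                    row.append(_fmt(arr[a]))
                fh.write(" ".join(row) + "\n")
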