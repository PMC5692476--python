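"""Readers and writers for the toolkit's on-disk formats.

Coordinates travel as GRO files (fixed-column, nm; converted to Angstrom
on read), single-frame or multi-frame by concatenation.  Bead roles are
resolved through a topology map from residue name to the ordered bead
names of that lipid; a built-in MARTINI-style PC mapping covers the 2-,
3- and 4-bead-chain lipids the synthetic generator emits.  Residues whose
name is not in the map are treated as protein beads (unrecognized names
are logged).

Tabular inputs are plain CSV: transients as
``time_s, signal, condition, replicate, batch``; titrations as
``ligand_M, signal``; CD spectra as ``wavelength_nm, theta_mdeg``.
Fit results are emitted as schema-versioned JSON records with rates in
s^-1 and half-times in seconds.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import MDAnalysis as mda
from MDAnalysis.lib.util import NamedStream

from .binding import Titration
from .errors import DegenerateDataError, ParseError
from .kinetics import FoldingTransient
from .membrane import CGFrame, Trajectory

__all__ = [
    "MARTINI_PC_TOPOLOGY",
    "read_gro",
    "write_gro",
    "read_transients_csv",
    "write_transients_csv",
    "read_titration_csv",
    "read_cd_csv",
    "write_results_json",
    "read_results_json",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: residue name -> ordered bead names; chains of 2, 3 and 4 acyl beads
MARTINI_PC_TOPOLOGY: dict[str, list[str]] = {
    "DCPC": ["NC3", "PO4", "GL1", "GL2", "C1A", "C2A", "C1B", "C2B"],
    "DLPC": ["NC3", "PO4", "GL1", "GL2", "C1A", "C2A", "C3A",
             "C1B", "C2B", "C3B"],
    "DPPC": ["NC3", "PO4", "GL1", "GL2", "C1A", "C2A", "C3A", "C4A",
             "C1B", "C2B", "C3B", "C4B"],
}

_LIPID_RESNAME_BY_CHAIN = {2: "DCPC", 3: "DLPC", 4: "DPPC"}


# ---------------------------------------------------------------------------
# GRO coordinates
# ---------------------------------------------------------------------------

def _split_gro_blocks(text: str, path: str) -> list[tuple[int, str]]:
    """Split a (possibly multi-frame) GRO file into frame blocks.

    Returns (starting line number, block text) pairs; raises
    :class:`ParseError` with the offending line for truncated frames.
    """
    lines = text.splitlines()
    blocks = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if i + 1 >= len(lines):
            raise ParseError("truncated GRO frame: missing atom count", line=i + 2)
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ParseError("malformed atom-count line", line=i + 2) from None
        end = i + 2 + n_atoms + 1  # title + count + atoms + box
        if end > len(lines):
            raise ParseError("truncated GRO frame: missing atoms or box line",
                             line=len(lines))
        box_fields = lines[end - 1].split()
        if len(box_fields) < 3:
            raise ParseError("missing or malformed box line", line=end)
        try:
            [float(x) for x in box_fields]
        except ValueError:
            raise ParseError("missing or malformed box line", line=end) from None
        blocks.append((i + 1, "\n".join(lines[i:end]) + "\n"))
        i = end
    if not blocks:
        raise ParseError("no frames found in GRO file " + path, line=1)
    return blocks


def read_gro(path: str | Path,
             topology_map: dict[str, list[str]] | None = None) -> list[CGFrame]:
    """Read one or more frames from a (concatenated) GRO file.

    Positions are converted nm -> Angstrom.  Residues with a name in
    ``topology_map`` (default: the built-in MARTINI PC mapping) become
    lipid records; everything else becomes protein beads.
    """
    topology_map = topology_map if topology_map is not None else MARTINI_PC_TOPOLOGY
    text = Path(path).read_text()
    frames = []
    for start_line, block in _split_gro_blocks(text, str(path)):
        try:
            with warnings.catch_warnings():
                # stream wrapping and CG-bead mass guessing are both benign
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", PendingDeprecationWarning)
                warnings.simplefilter("ignore", UserWarning)
                u = mda.Universe(NamedStream(_io.StringIO(block), "frame.gro"))
        except Exception as exc:
            raise ParseError(f"could not parse GRO frame: {exc}",
                             line=start_line) from exc
        frames.append(_frame_from_universe(u, topology_map))
    return frames


def _frame_from_universe(u, topology_map) -> CGFrame:
    box = np.asarray(u.dimensions[:3], dtype=float)
    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    pos = u.atoms.positions.astype(float)

    lipid_mask = np.isin(resnames, list(topology_map))
    unknown = set()

    lip_resids, po4, gl1, gl2, nc3 = [], [], [], [], []
    chains_a, chains_b = [], []
    chain_len = None
    protein_idx = []

    # iterate residues in file order
    boundaries = np.nonzero(np.diff(resids, prepend=resids[0] - 1))[0]
    for start, stop in zip(boundaries, list(boundaries[1:]) + [len(resids)]):
        resname = resnames[start]
        if not lipid_mask[start]:
            protein_idx.extend(range(start, stop))
            if resname not in _PROTEIN_RESNAMES:
                unknown.add(str(resname))
            continue
        bead = {n: pos[j] for n, j in zip(names[start:stop], range(start, stop))}
        try:
            po4.append(bead["PO4"])
            gl1.append(bead["GL1"])
            gl2.append(bead["GL2"])
        except KeyError as exc:
            raise ParseError(
                f"lipid {resname} {resids[start]} missing bead {exc}") from exc
        nc3.append(bead.get("NC3", bead["PO4"]))
        a = [bead[n] for n in sorted(bead) if n.startswith("C") and n.endswith("A")]
        b = [bead[n] for n in sorted(bead) if n.startswith("C") and n.endswith("B")]
        if len(a) != len(b) or not 2 <= len(a) <= 4:
            raise ParseError(
                f"lipid {resname} {resids[start]} has unbalanced chains")
        if chain_len is None:
            chain_len = len(a)
        elif chain_len != len(a):
            raise ParseError("mixed chain lengths are not supported")
        chains_a.append(a)
        chains_b.append(b)
        lip_resids.append(int(resids[start]))

    if unknown:
        log.info("treating unrecognized residues as protein: %s",
                 ", ".join(sorted(unknown)))
    if not lip_resids:
        raise ParseError("no lipids recognized via the topology map")
    protein_idx = np.asarray(protein_idx, dtype=int)
    return CGFrame(
        box=box,
        lipid_resids=np.asarray(lip_resids, dtype=int),
        po4=np.asarray(po4), gl1=np.asarray(gl1), gl2=np.asarray(gl2),
        chain_a=np.asarray(chains_a), chain_b=np.asarray(chains_b),
        nc3=np.asarray(nc3),
        protein_xyz=pos[protein_idx].reshape(-1, 3),
        protein_resids=resids[protein_idx].astype(int),
        protein_resnames=resnames[protein_idx] if protein_idx.size else None,
    )


_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _gro_atom_line(resid: int, resname: str, name: str, serial: int,
                   xyz_nm: np.ndarray) -> str:
    return (f"{resid % 100000:5d}{resname:<5s}{name:>5s}{serial % 100000:5d}"
            f"{xyz_nm[0]:8.3f}{xyz_nm[1]:8.3f}{xyz_nm[2]:8.3f}")


def write_gro(frames: Sequence[CGFrame] | Trajectory, path: str | Path,
              title: str = "foldkit synthetic bilayer") -> None:
    """Write frames as a (multi-frame, concatenated) GRO file in nm.

    Lipid residue names are chosen from the chain length (DCPC/DLPC/DPPC
    for 2/3/4 acyl beads) so the file round-trips through the built-in
    topology map.  MDAnalysis writes single-frame GRO only, so frames are
    formatted here and concatenated.
    """
    if isinstance(frames, Trajectory):
        frames = frames.frames
    lines: list[str] = []
    for i_frame, frame in enumerate(frames):
        resname = _LIPID_RESNAME_BY_CHAIN[frame.chain_beads]
        beads = MARTINI_PC_TOPOLOGY[resname]
        lines.append(f"{title} frame {i_frame}")
        n_atoms = frame.n_lipids * len(beads) + frame.protein_xyz.shape[0]
        lines.append(f"{n_atoms:5d}")
        serial = 1
        for j in range(frame.n_lipids):
            per_role = {
                "NC3": frame.nc3[j] if frame.nc3 is not None else frame.po4[j],
                "PO4": frame.po4[j], "GL1": frame.gl1[j], "GL2": frame.gl2[j],
            }
            for b in range(frame.chain_beads):
                per_role[f"C{b + 1}A"] = frame.chain_a[j, b]
                per_role[f"C{b + 1}B"] = frame.chain_b[j, b]
            for name in beads:
                lines.append(_gro_atom_line(int(frame.lipid_resids[j]), resname,
                                            name, serial, per_role[name] / 10.0))
                serial += 1
        prot_names = (frame.protein_resnames
                      if frame.protein_resnames is not None
                      else ["ALA"] * frame.protein_xyz.shape[0])
        for xyz, resid, rname in zip(frame.protein_xyz, frame.protein_resids,
                                     prot_names):
            lines.append(_gro_atom_line(int(resid), str(rname), "BB", serial,
                                        xyz / 10.0))
            serial += 1
        lines.append("".join(f"{x / 10.0:10.5f}" for x in frame.box))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

_TRANSIENT_COLUMNS = ["time_s", "signal", "condition", "replicate", "batch"]


def read_transients_csv(path: str | Path) -> list[FoldingTransient]:
    """Read folding transients grouped by (condition, replicate, batch).

    The header ``time_s, signal, condition, replicate, batch`` is
    required; time must be strictly increasing within each group (the
    offending row is reported otherwise).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRANSIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing} in {path}")
    try:
        df["time_s"] = df["time_s"].astype(float)
        df["signal"] = df["signal"].astype(float)
    except ValueError as exc:
        raise ParseError(
            f"non-numeric time/signal (duplicated header line?): {exc}") from exc

    out = []
    for (cond, rep, batch), group in df.groupby(
            ["condition", "replicate", "batch"], sort=True, dropna=False):
        t = group["time_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            row = int(group.index[bad[0] + 1]) + 2  # +header +1-based
            raise ParseError(
                f"time not strictly increasing for ({cond}, {rep}, {batch})",
                line=row)
        out.append(FoldingTransient(
            time=t, signal=group["signal"].to_numpy(),
            condition_label=str(cond), replicate_id=str(rep),
            batch_id=None if pd.isna(batch) else str(batch)))
    return out


def write_transients_csv(transients: Sequence[FoldingTransient],
                         path: str | Path) -> None:
    rows = []
    for tr in transients:
        rows.append(pd.DataFrame({
            "time_s": tr.time, "signal": tr.signal,
            "condition": tr.condition_label, "replicate": tr.replicate_id,
            "batch": tr.batch_id if tr.batch_id is not None else "",
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_titration_csv(path: str | Path,
                       fixed_partner_concentration: float = 100e-9) -> Titration:
    """Read a titration table with columns ``ligand_M, signal``."""
    df = pd.read_csv(path)
    for col in ("ligand_M", "signal"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    try:
        conc = df["ligand_M"].astype(float).to_numpy()
        sig = df["signal"].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric titration data: {exc}") from exc
    return Titration(ligand_concentration=conc, signal=sig,
                     fixed_partner_concentration=fixed_partner_concentration)


def write_titration_csv(titration: Titration, path: str | Path) -> None:
    pd.DataFrame({"ligand_M": titration.ligand_concentration,
                  "signal": titration.signal}).to_csv(path, index=False)


def read_cd_csv(path: str | Path) -> pd.DataFrame:
    """Read a CD spectrum with columns ``wavelength_nm, theta_mdeg``."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "theta_mdeg"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r} in {path}")
    return df.astype(float)


# ---------------------------------------------------------------------------
# results JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results_json(results, path: str | Path) -> None:
    """Write any result record (dataclass/dict/list) as versioned JSON."""
    from . import __version__
    payload = {"schema_version": SCHEMA_VERSION, "package": "foldkit",
               "package_version": __version__, "results": _jsonable(results)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_results_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "results" not in payload:
        raise ParseError(f"not a foldkit results file: {path}")
    return payload
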