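"""Readers and writers for the formats the toolkit touches.

PDB structures (via gemmi), two-record aligned FASTA, the package's
plain-text distogram format, whitespace n x n distance matrices,
assessment-metric CSV, single-line 8-state secondary-structure strings,
and TSV/JSON report writing.  Every parser returns or records a
``ParseReport`` so nothing is dropped silently.

Distogram file format::

    #DGRAM n=<N> edges=<e1,e2,...>
    i j p1 p2 ... p_nbins

with 1-based indices; the upper triangle (plus optional diagonal) is
sufficient, and omitted pairs (including the diagonal) default to all
mass in the first bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .distogram import Distogram, ModeDistanceMatrix
from .errors import FormatError, ValidationError
from .evaluation import MetricTable, PairAlignment
from .geometry import (NONSTANDARD_PARENT, STANDARD_AA3, ResidueModel,
                       StructureModel)
from .losses import DSSP8_ALPHABET

__all__ = [
    "ParseReport",
    "read_structure",
    "read_alignment",
    "pair_alignment_from_strings",
    "read_distogram",
    "write_distogram",
    "read_mode_matrix",
    "write_mode_matrix",
    "read_metric_csv",
    "read_ss",
    "write_report",
]


@dataclass
class ParseReport:
    """Record of everything a parser skipped or resolved: list of
    (severity, record reference, message) plus the kept record count."""

    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    n_records: int = 0

    def warn(self, ref: str, message: str, severity: str = "warning") -> None:
        self.warnings.append((severity, ref, message))


# ---------------------------------------------------------------------------
# PDB structures

def read_structure(path, chain: str | None = None):
    """Read the first model of a PDB file into a StructureModel.

    Altloc conflicts resolve to the highest-occupancy atom, ties to the
    lowest altloc letter.  HETATM records are skipped unless the residue
    is a mapped nonstandard (e.g. MSE); waters and unmapped ligands are
    skipped with a report entry.  Author numbering and insertion codes
    are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    model = st[0]
    report = ParseReport()
    if len(st) > 1:
        report.warn(str(path), f"{len(st)} models present; using the first")

    chain_names = [ch.name for ch in model]
    if chain is None:
        if not chain_names:
            raise FormatError(f"{path}: no chains")
        chain = chain_names[0]
    if chain not in chain_names:
        raise FormatError(
            f"{path}: chain {chain!r} not found (have {chain_names})")

    residues: list[ResidueModel] = []
    for res in model[chain]:
        ref = f"{res.name} {chain}{res.seqid.num}{res.seqid.icode.strip()}"
        name = res.name.upper()
        if name not in STANDARD_AA3 and name not in NONSTANDARD_PARENT:
            report.warn(ref, "skipped: not a standard amino acid or a mapped "
                             "nonstandard residue")
            continue
        if name in NONSTANDARD_PARENT:
            report.warn(ref, f"nonstandard residue mapped to "
                             f"{NONSTANDARD_PARENT[name]}")
        atoms: dict[str, np.ndarray] = {}
        chosen: dict[str, gemmi.Atom] = {}
        for atom in res:
            prev = chosen.get(atom.name)
            if prev is None:
                chosen[atom.name] = atom
            else:
                report.warn(ref, f"altloc conflict on {atom.name}: kept the "
                                 "highest-occupancy, lowest-letter conformer")
                if (atom.occ, -ord(atom.altloc or "Z")) > (prev.occ,
                                                           -ord(prev.altloc or "Z")):
                    chosen[atom.name] = atom
        for atom_name, atom in chosen.items():
            atoms[atom_name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        rm = ResidueModel(name=name, index=res.seqid.num, atoms=atoms,
                          insertion_code=res.seqid.icode.strip())
        if not rm.is_complete_backbone:
            report.warn(ref, "incomplete backbone (missing N, CA or C)")
        residues.append(rm)
    if not residues:
        raise FormatError(f"{path}: chain {chain!r} has no usable residues")
    report.n_records = len(residues)
    return StructureModel(residues=residues, chain_id=chain), report


# ---------------------------------------------------------------------------
# Alignments

def read_alignment(path) -> PairAlignment:
    """Read a two-record aligned FASTA into a PairAlignment.

    Both records must have equal aligned length; columns with a residue
    in both rows become matched pairs, gap ('-' or '.') columns are
    skipped.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    name, seq = None, []
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(seq)))
            name, seq = line[1:], []
        elif name is None:
            raise FormatError(f"{path}: sequence data before any header")
        else:
            seq.append(line)
    if name is not None:
        records.append((name, "".join(seq)))
    if len(records) != 2:
        raise FormatError(
            f"{path}: expected exactly 2 aligned records, found {len(records)}")
    (_, row_q), (_, row_t) = records
    return pair_alignment_from_strings(row_q, row_t)


def pair_alignment_from_strings(row_query: str, row_template: str) -> PairAlignment:
    """Build a PairAlignment from two equal-length gapped rows."""
    if len(row_query) != len(row_template):
        raise FormatError(
            f"aligned rows differ in length: {len(row_query)} vs "
            f"{len(row_template)}")
    gaps = {"-", "."}
    pairs = []
    q = t = 0
    for cq, ct in zip(row_query, row_template):
        if cq not in gaps:
            q += 1
        if ct not in gaps:
            t += 1
        if cq not in gaps and ct not in gaps:
            pairs.append((q, t))
    return PairAlignment(pairs=pairs, query_length=q, template_length=t)


# ---------------------------------------------------------------------------
# Distograms and distance matrices

def write_distogram(dg: Distogram, path) -> None:
    """Write the package distogram format (upper triangle incl. diagonal)."""
    path = Path(path)
    edges = ",".join(repr(float(e)) for e in dg.bin_edges)
    with path.open("w") as fh:
        fh.write(f"#DGRAM n={dg.n_residues} edges={edges}\n")
        for i in range(dg.n_residues):
            for j in range(i, dg.n_residues):
                row = " ".join(repr(float(p)) for p in dg.probs[i, j])
                fh.write(f"{i + 1} {j + 1} {row}\n")


def read_distogram(path) -> Distogram:
    """Read the package distogram format (see module docstring)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#DGRAM"):
        raise FormatError(f"{path}: missing #DGRAM header")
    header = lines[0]
    try:
        fields = dict(tok.split("=", 1) for tok in header.split()[1:])
        n = int(fields["n"])
        edges = np.array([float(x) for x in fields["edges"].split(",")])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}:1: malformed header: {exc}") from exc
    n_bins = edges.size
    probs = np.zeros((n, n, n_bins))
    probs[..., 0] = 1.0  # omitted pairs default to mass in the first bin
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 + n_bins:
            raise FormatError(
                f"{path}:{lineno}: expected 2 indices + {n_bins} probabilities, "
                f"got {len(parts)} fields")
        try:
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            row = np.array([float(x) for x in parts[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if not (0 <= i < n and 0 <= j < n):
            raise FormatError(f"{path}:{lineno}: index out of range")
        probs[i, j] = row
        probs[j, i] = row
    try:
        return Distogram(edges, probs)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_mode_matrix(m: ModeDistanceMatrix, path) -> None:
    np.savetxt(path, m.d, fmt="%.9g")


def read_mode_matrix(path) -> ModeDistanceMatrix:
    """Read a plain whitespace-separated n x n distance matrix."""
    try:
        d = np.loadtxt(path, ndmin=2)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read matrix {path}: {exc}") from exc
    try:
        return ModeDistanceMatrix(d)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Metric tables and secondary structure

def read_metric_csv(path) -> MetricTable:
    """Read an assessment table: CSV with header group,domain,metric,value."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read metric CSV {path}: {exc}") from exc
    expected = ["group", "domain", "metric", "value"]
    if list(df.columns[:4]) != expected:
        raise FormatError(
            f"{path}: header must be {','.join(expected)}; got "
            f"{','.join(map(str, df.columns))}")
    try:
        df["value"] = df["value"].astype(float)
        return MetricTable(rows=df[expected])
    except (ValueError, ValidationError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_ss(path) -> str:
    """Read a single-line 8-state secondary-structure string
    (alphabet H, G, I, E, B, T, S, '-')."""
    text = Path(path).read_text().strip()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith(">")]
    ss = "".join(lines)
    for col, ch in enumerate(ss, start=1):
        if ch not in DSSP8_ALPHABET:
            raise FormatError(
                f"{path}: illegal secondary-structure character {ch!r} at "
                f"column {col}")
    if not ss:
        raise FormatError(f"{path}: empty secondary-structure string")
    return ss


# ---------------------------------------------------------------------------
# Reports

def write_report(data: dict, path, fmt: str = "json") -> None:
    """Write a flat report dict as JSON or two-column TSV."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif fmt == "tsv":
        with path.open("w") as fh:
            for key, value in data.items():
                fh.write(f"{key}\t{value}\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
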