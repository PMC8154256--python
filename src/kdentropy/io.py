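"""File readers and writers.

Supported formats: whitespace-delimited dihedral tables as written by
trajectory-analysis tools (header line starting with '#', first column the
frame index, e.g. cpptraj's ``multidihedral`` output), plain CSV variants of
the same, one/two-column boost-potential files, CSV/JSON entropy tables, and
a PDB writer that projects per-residue entropies into the B-factor column for
structure-colouring workflows.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .dihedral import DihedralSeries, ResiduewiseEntropy
from .errors import DataError

Dialect = Literal["cpptraj", "csv"]

_RESIDUE_SUFFIX = re.compile(r"^(.*?)[:_](\d+)$")


@dataclass(frozen=True)
class DihedralTable:
    """A parsed dihedral file: frame indices plus one series per column."""

    frame_index: np.ndarray
    series: List[DihedralSeries]
    source_path: str

    @property
    def n_frames(self) -> int:
        return self.frame_index.size


def parse_series_name(name: str) -> tuple[str, Optional[int]]:
    """Split 'phi_12' / 'psi:3' into a dihedral label and a residue index."""
    m = _RESIDUE_SUFFIX.match(name.strip())
    if m:
        return m.group(1), int(m.group(2))
    return name.strip(), None


def _read_table(path: str, dialect: Dialect) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise DataError(f"no such file: {path}")
    text = p.read_text()
    if not text.strip():
        raise DataError(f"{path} is empty")
    if dialect == "cpptraj":
        lines = text.splitlines()
        header = lines[0]
        if not header.lstrip().startswith("#"):
            raise DataError(f"{path}:1: cpptraj table must start with a '#' header")
        names = header.lstrip("#").split()
        body = [ln for ln in lines[1:] if ln.strip() and not ln.lstrip().startswith("#")]
        if not body:
            raise DataError(f"{path}: header only, no data rows")
        rows = []
        for lineno, ln in enumerate(body, start=2):
            parts = ln.split()
            if len(parts) != len(names):
                raise DataError(
                    f"{path}:{lineno}: expected {len(names)} columns, got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        return pd.DataFrame(rows, columns=names)
    if dialect == "csv":
        try:
            frame = pd.read_csv(p)
        except Exception as exc:  # pandas raises several parser error types
            raise DataError(f"{path}: {exc}") from exc
        if frame.empty:
            raise DataError(f"{path}: header only, no data rows")
        non_numeric = [c for c in frame.columns
                       if not np.issubdtype(frame[c].dtype, np.number)]
        if non_numeric:
            raise DataError(f"{path}: non-numeric column(s) {non_numeric}")
        return frame
    raise DataError(f"unknown dialect {dialect!r}")


def read_dihedral_table(path: str, dialect: Dialect = "cpptraj") -> DihedralTable:
    """Read a dihedral time-series table.

    The first column is the frame index; every other column becomes a
    :class:`DihedralSeries` (angles wrapped to [-180, 180) on ingestion).
    Residue indices are parsed from trailing digits of column names like
    ``phi_12`` or ``psi:3``.
    """
    frame = _read_table(path, dialect)
    if frame.shape[1] < 2:
        raise DataError(f"{path}: need a frame column plus at least one angle column")
    frame_index = frame.iloc[:, 0].to_numpy()
    series = []
    for col in frame.columns[1:]:
        label, residue = parse_series_name(str(col))
        series.append(
            DihedralSeries(
                angles=frame[col].to_numpy(dtype=float),
                name=str(col).strip(),
                residue_index=residue,
                residue_name=label if residue is not None else None,
            )
        )
    return DihedralTable(frame_index=np.asarray(frame_index), series=series,
                         source_path=str(path))


def write_dihedral_table(
    path: str,
    names: Sequence[str],
    columns: Sequence[np.ndarray],
    dialect: Dialect = "cpptraj",
) -> None:
    """Write angle series in either dialect (used by the fixtures command)."""
    if len(names) != len(columns):
        raise DataError("names and columns must align")
    n = len(columns[0])
    frame = pd.DataFrame({"Frame": np.arange(1, n + 1)})
    for name, col in zip(names, columns):
        if len(col) != n:
            raise DataError("all columns must share the frame count")
        frame[name] = col
    if dialect == "cpptraj":
        with open(path, "w") as fh:
            fh.write("#" + " ".join(frame.columns) + "\n")
            for _, row in frame.iterrows():
                fh.write(f"{int(row.iloc[0]):8d} " +
                         " ".join(f"{v:12.4f}" for v in row.iloc[1:]) + "\n")
    elif dialect == "csv":
        frame.to_csv(path, index=False)
    else:
        raise DataError(f"unknown dialect {dialect!r}")


def read_boost_file(path: str, column: int = -1) -> np.ndarray:
    """Read per-frame boost potentials from a 1- or 2-column text/CSV file.

    By default the last column is taken as dV (a leading column, if any, is
    assumed to be the frame index).
    """
    p = Path(path)
    if not p.exists():
        raise DataError(f"no such file: {path}")
    values = []
    for lineno, line in enumerate(p.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        try:
            values.append(float(parts[column]))
        except IndexError:
            raise DataError(f"{path}:{lineno}: no column {column}") from None
        except ValueError:
            if lineno == 1:  # header line
                continue
            raise DataError(
                f"{path}:{lineno}: non-numeric boost value {parts[column]!r}"
            ) from None
    if not values:
        raise DataError(f"{path} contains no boost values")
    return np.asarray(values, dtype=float)


def _entropy_frame(results: Sequence[ResiduewiseEntropy]) -> pd.DataFrame:
    dihedral_names: List[str] = []
    for r in results:
        for name in r.entropy_values:
            if name not in dihedral_names:
                dihedral_names.append(name)
    rows = []
    for r in sorted(results, key=lambda r: r.residue_index):
        row = {"residue_index": r.residue_index, "residue_name": r.residue_name}
        for name in dihedral_names:
            row[name] = r.entropy_values.get(name, np.nan)
        row["combined"] = r.combined
        rows.append(row)
    return pd.DataFrame(rows, columns=["residue_index", "residue_name",
                                       *dihedral_names, "combined"])


def write_entropy_table(
    results: Sequence[ResiduewiseEntropy],
    path: str,
    format: Literal["csv", "json"] = "csv",
) -> None:
    """Write per-residue entropies (J/(mol K)) as CSV or JSON.

    Column order is deterministic: residue_index, residue_name, one column
    per dihedral name in first-appearance order, combined.
    """
    frame = _entropy_frame(results)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
    else:
        raise DataError(f"unknown format {format!r}")


def project_to_bfactor(
    results: Sequence[ResiduewiseEntropy],
    pdb_in: str,
    pdb_out: str,
) -> int:
    """Write a copy of a PDB with B-factors replaced by combined entropies.

    Each ATOM/HETATM record's temperature-factor field (columns 61-66) is set
    to its residue's combined dihedral entropy, clamped to [0, 999.99] for
    the fixed-width field; residues without a result get 0.00.  Returns the
    number of residues that matched.
    """
    by_residue = {r.residue_index: max(0.0, min(999.99, r.combined)) for r in results}
    clamped = [r.residue_index for r in results if not 0.0 <= r.combined <= 999.99]
    if clamped:
        import logging
        logging.getLogger(__name__).warning(
            "entropy outside the B-factor field range clamped for residues %s", clamped
        )
    src = Path(pdb_in)
    if not src.exists():
        raise DataError(f"no such file: {pdb_in}")
    matched = set()
    out_lines = []
    for lineno, line in enumerate(src.read_text().splitlines(keepends=True), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line.rstrip("\n")) < 66:
                raise DataError(f"{pdb_in}:{lineno}: truncated ATOM record")
            try:
                resseq = int(line[22:26])
            except ValueError:
                raise DataError(f"{pdb_in}:{lineno}: unreadable residue number "
                                f"{line[22:26]!r}") from None
            value = by_residue.get(resseq, 0.0)
            if resseq in by_residue:
                matched.add(resseq)
            line = line[:60] + f"{value:6.2f}" + line[66:]
        out_lines.append(line)
    if not matched:
        raise DataError(
            f"no residue in {pdb_in} overlaps the {len(by_residue)} computed residues"
        )
    Path(pdb_out).write_text("".join(out_lines))
    return len(matched)
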