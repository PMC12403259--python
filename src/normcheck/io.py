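"""CSV data input and fixture generation.

Input files are single-column (or column-selected) numeric CSV in the
RFC-4180 comma dialect with '.' as the decimal mark and an optional header
row. Non-numeric cells are skipped with a per-line report rather than
aborting the read.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fleishman import generate_nonnormal, solve_fleishman
from .sample import Sample

__all__ = ["DataColumn", "read_data_column", "write_sample", "make_fixtures", "EmptyDataError"]


class EmptyDataError(ValueError):
    """The file contains no numeric data in the selected column."""


@dataclass(frozen=True)
class DataColumn:
    """A parsed numeric column: the sample plus parse diagnostics."""

    sample: Sample
    source: str
    column: str | int
    n_rows: int
    skipped: tuple  # (line_number, cell_text) pairs


def read_data_column(path, column: str | int | None = None) -> DataColumn:
    """Read one numeric column from a CSV file.

    ``column`` may be a header name, a 0-based index, or None (first
    column). A non-numeric first row is treated as a header. Blank and
    non-numeric cells are skipped and reported in ``skipped``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise EmptyDataError(f"{path}: file is empty")

    header = [c.strip() for c in rows[0]]
    idx: int
    has_header: bool
    if isinstance(column, str):
        if column not in header:
            raise KeyError(f"{path}: no column named {column!r} (header: {header})")
        idx = header.index(column)
        has_header = True
    else:
        idx = int(column) if column is not None else 0
        if idx >= len(header):
            raise KeyError(f"{path}: column index {idx} out of range")
        first = header[idx]
        has_header = not _is_number(first)

    values: list[float] = []
    skipped: list[tuple[int, str]] = []
    start = 1 if has_header else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or idx >= len(row):
            continue
        cell = row[idx].strip()
        if cell == "":
            continue
        if _is_number(cell):
            values.append(float(cell))
        else:
            skipped.append((lineno, cell))
    if not values:
        raise EmptyDataError(f"{path}: no numeric rows in column {column!r}")
    if len(values) < 3:
        raise EmptyDataError(f"{path}: need at least 3 numeric rows, got {len(values)}")
    return DataColumn(
        sample=Sample(values),
        source=str(path),
        column=column if column is not None else 0,
        n_rows=len(values),
        skipped=tuple(skipped),
    )


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return np.isfinite(float(text))


def write_sample(sample: Sample, path, header_comment: str | None = None) -> None:
    """Write a sample as single-column CSV, optionally with a '#' metadata line."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("value\n")
        for v in sample.values:
            fh.write(f"{float(v)!r}\n")


def make_fixtures(outdir, seed: int = 20240) -> dict:
    """Write the pinned test samples used by the test suite.

    Produces deterministic CSV fixtures (hand-derived small samples, integer
    ramps, seeded normal and Fleishman draws) plus a manifest with a sha256
    checksum per file. Same seed, same bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    fixtures: dict[str, np.ndarray] = {
        "hand_sym3.csv": np.array([-1.0, 0.0, 1.0]),
        "hand_asym4.csv": np.array([-1.0, 0.0, 1.0, 2.0]),
        "ramp10.csv": np.arange(1.0, 11.0),
        "ramp20.csv": np.arange(1.0, 21.0),
        "normal30.csv": rng.standard_normal(30),
        "lognormal25.csv": np.exp(rng.standard_normal(25)),
        "uniform40.csv": rng.uniform(0.0, 1.0, 40),
    }
    coeffs = solve_fleishman(0.75, 3.0)
    fixtures["fleishman50.csv"] = generate_nonnormal(coeffs, 50, seed + 1).values

    manifest = {}
    for name, values in fixtures.items():
        path = outdir / name
        write_sample(Sample(values), path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest[name] = {"sha256": digest, "n": int(values.size)}
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": seed, "files": manifest}, fh, indent=2, sort_keys=True)
    return manifest
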