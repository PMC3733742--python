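"""Delimited-text readers/writers and the run manifest.

Default dialect is TSV, '.' decimal separator, UTF-8.  Expression files
carry gene identifiers in the first column and sample identifiers in the
header; design files are two columns ``sample_id`` and ``variety``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroupDesign
from .exceptions import DimensionMismatchError, MissingValueError, ParseError

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "write_table",
    "RunManifest",
]

_FLOAT_FORMAT = "%.10g"


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    design_path: str | Path | None = None,
    log2_transform: bool = False,
) -> tuple[ExpressionMatrix, GroupDesign | None]:
    """Read a genes x samples expression matrix (and optional design sidecar).

    Rejects duplicate identifiers, missing cells and non-numeric cells with
    errors naming the offending coordinates.  ``log2_transform`` applies
    log2(x + 1) for users holding raw intensities; the pipeline itself
    assumes log-scale input.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame.iloc[:, j]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise MissingValueError(
                    f"{path}: empty cell at gene {frame.index[i]!r}, sample {col!r}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{frame.index[i]!r}, sample {col!r}"
                ) from exc
    if log2_transform:
        if np.any(values < -1):
            raise ParseError(f"{path}: values below -1 cannot be log2(x+1) transformed")
        values = np.log2(values + 1.0)
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=tuple(str(i) for i in frame.index),
        sample_ids=tuple(str(c) for c in frame.columns),
    )
    design = None
    if design_path is not None:
        design = read_design(design_path, delimiter=delimiter, sample_ids=matrix.sample_ids)
    return matrix, design


def read_design(
    path: str | Path, delimiter: str = "\t", sample_ids: tuple[str, ...] | None = None
) -> GroupDesign:
    """Read a ``sample_id <tab> variety`` table, reordered to match ``sample_ids``."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype={0: str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not {"sample_id", "variety"}.issubset(frame.columns):
        raise ParseError(f"{path}: expected columns 'sample_id' and 'variety'")
    mapping = dict(zip(frame["sample_id"].astype(str), frame["variety"]))
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise DimensionMismatchError(
                f"{path}: no variety for sample {missing[0]!r}"
            )
        variety = np.array([int(mapping[s]) for s in sample_ids])
    else:
        variety = frame["variety"].to_numpy(dtype=int)
    return GroupDesign(variety)


def write_expression(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=delimiter, float_format=_FLOAT_FORMAT, index_label="gene_id")
    return path


def write_design(design: GroupDesign, sample_ids: tuple[str, ...], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": list(sample_ids), "variety": design.variety}).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index=index)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    command: str
    config: dict[str, Any]
    seed: int | None = None
    software_version: str = ""
    started: str = ""
    finished: str = ""
    selected_k: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def start(cls, command: str, config: dict[str, Any], seed: int | None = None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config,
            seed=seed,
            software_version=__version__,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(Path(path)))

    def write(self, path: str | Path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        for out in self.outputs:
            if not Path(out).exists():
                raise FileNotFoundError(f"declared output missing: {out}")
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
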