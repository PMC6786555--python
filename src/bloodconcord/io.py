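"""Readers and writers for the pipeline's tabular formats.

Canonical dialect is plain TSV.  Intensity tables additionally accept an
Agilent-Feature-Extraction-like dialect in which the signal columns are
named ``rMedianSignal``/``gMedianSignal``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import (
    ANNOTATION_COLUMNS,
    FormatError,
    IntensityArray,
    validate_annotation,
    validate_sample_sheet,
)

_INTENSITY_DIALECTS = {
    "plain": {"red_signal": "red_signal", "green_signal": "green_signal"},
    "agilent": {"red_signal": "rMedianSignal", "green_signal": "gMedianSignal"},
}


def read_intensity_table(
    path: str | Path, dialect: str = "plain", sample_id: str | None = None
) -> IntensityArray:
    """Read one array's two-channel intensities from TSV.

    ``dialect='agilent'`` accepts Feature-Extraction style column names.
    The sample id defaults to the file stem.
    """
    path = Path(path)
    if dialect not in _INTENSITY_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _INTENSITY_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t")
    required = ["probe_id", "gene_id", colmap["red_signal"], colmap["green_signal"]]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    df = df[required].rename(columns={
        colmap["red_signal"]: "red_signal",
        colmap["green_signal"]: "green_signal",
    })
    return IntensityArray(sample_id=sample_id or path.stem, data=df)


def write_intensity_table(
    array: IntensityArray, path: str | Path, dialect: str = "plain"
) -> None:
    colmap = _INTENSITY_DIALECTS[dialect]
    df = array.data.rename(columns={
        "red_signal": colmap["red_signal"],
        "green_signal": colmap["green_signal"],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str,
                                               "platform": str})
    return validate_sample_sheet(sheet)


def read_annotation(path: str | Path) -> pd.DataFrame:
    annotation = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    return validate_annotation(annotation)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read gene sets from GMT (name <TAB> description <TAB> gene...).

    Returns ``{name: {"description": str, "genes": set[str]}}``.
    """
    sets: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{Path(path).name}:{lineno}: GMT line needs name, description "
                f"and at least one gene"
            )
        name, description, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{Path(path).name}:{lineno}: empty gene set {name!r}")
        if name in sets:
            raise FormatError(f"{Path(path).name}:{lineno}: duplicate set {name!r}")
        sets[name] = {"description": description, "genes": set(genes)}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    lines = [
        "\t".join([name, s["description"], *sorted(s["genes"])])
        for name, s in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.10g")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(annotation)[list(ANNOTATION_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
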