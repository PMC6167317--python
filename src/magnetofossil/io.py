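"""CSV readers and writers for every table the package consumes or emits.

Dialects (all UTF-8, header required):

* crystals — ``sample_id, length_nm, width_nm[, morphology]``
* IRM curves — ``field_mT, remanence[, sample_id]``
* FORC grids — long form ``Ba_mT, Bb_mT, M_norm`` plus a JSON metadata
  sidecar (``<name>.meta.json``); an instrument-style text dialect with
  comment-marker header lines followed by bare triples is also read.
* FORC distributions — ``Bc_mT, Bu_mT, rho``
* assemblage export — one row per particle with positions, axes, sizes
* down-core tables — ``depth_mcd`` plus named proxy columns
* low-temperature curves — ``temperature_K, moment, treatment``

Writers round-trip at full precision; readers preserve unknown columns and
raise naming any missing required ones.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assemblage import ChainAssemblage
from .forcproc import ForcDistribution
from .micromag import ForcDataset
from .morphometry import CrystalMeasurement
from .proxies import LowTempCurve
from .synthetic import IrmCurve

__all__ = [
    "read_crystals_csv",
    "write_crystals_csv",
    "read_irm_csv",
    "write_irm_csv",
    "read_forc_csv",
    "write_forc_csv",
    "read_forc_instrument",
    "write_distribution_csv",
    "write_assemblage_csv",
    "read_assemblage_csv",
    "read_downcore_csv",
    "write_downcore_csv",
    "read_lowtemp_csv",
    "write_lowtemp_csv",
]


class SchemaError(ValueError):
    """A table is missing required columns or is empty."""


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")


def read_crystals_csv(path) -> list[CrystalMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["sample_id", "length_nm", "width_nm"], path)
    has_morph = "morphology" in df.columns
    return [
        CrystalMeasurement(
            sample_id=str(r.sample_id),
            length=float(r.length_nm),
            width=float(r.width_nm),
            morphology=str(r.morphology) if has_morph and pd.notna(r.morphology) else "unlabelled",
        )
        for r in df.itertuples()
    ]


def write_crystals_csv(crystals: list[CrystalMeasurement], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in crystals],
            "length_nm": [repr(c.length) for c in crystals],
            "width_nm": [repr(c.width) for c in crystals],
            "morphology": [c.morphology for c in crystals],
        }
    ).to_csv(path, index=False)


def read_irm_csv(path, sample_id: str | None = None) -> IrmCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["field_mT", "remanence"], path)
    if sample_id is not None and "sample_id" in df.columns:
        df = df[df["sample_id"].astype(str) == sample_id]
        if df.empty:
            raise SchemaError(f"{path}: no rows for sample_id={sample_id!r}")
    sid = sample_id or (str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else "")
    return IrmCurve(df["field_mT"].to_numpy(float), df["remanence"].to_numpy(float), sample_id=sid)


def write_irm_csv(curve: IrmCurve, path) -> None:
    df = pd.DataFrame({"field_mT": curve.fields_mT, "remanence": curve.remanence})
    if curve.sample_id:
        df["sample_id"] = curve.sample_id
    df.to_csv(path, index=False, float_format="%.17g")


def write_forc_csv(dataset: ForcDataset, path) -> None:
    path = Path(path)
    ii, jj = np.where(~np.isnan(dataset.magnetization))
    pd.DataFrame(
        {
            "Ba_mT": dataset.ba[ii],
            "Bb_mT": dataset.bb[jj],
            "M_norm": dataset.magnetization[ii, jj],
        }
    ).to_csv(path, index=False, float_format="%.17g")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(dataset.metadata, indent=1, default=str)
    )


def _triples_to_dataset(df: pd.DataFrame, metadata: dict) -> ForcDataset:
    ba = np.sort(df["Ba_mT"].unique())[::-1]
    bb = np.sort(df["Bb_mT"].unique())
    grid = np.full((ba.size, bb.size), np.nan)
    ia = np.searchsorted(-ba, -df["Ba_mT"].to_numpy())
    ib = np.searchsorted(bb, df["Bb_mT"].to_numpy())
    grid[ia, ib] = df["M_norm"].to_numpy()
    return ForcDataset(ba=ba, bb=bb, magnetization=grid, metadata=metadata)


def read_forc_csv(path) -> ForcDataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["Ba_mT", "Bb_mT", "M_norm"], path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return _triples_to_dataset(df, meta)


def read_forc_instrument(path, comment_markers: tuple[str, ...] = ("#", ";", "%")) -> ForcDataset:
    """Read an instrument-style FORC text file: commented header, then
    whitespace- or comma-separated (Ba, Bb, M) triples."""
    rows = []
    header_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(comment_markers):
                header_lines.append(line)
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise SchemaError(f"{path}: expected Ba/Bb/M triple, got {line!r}")
            rows.append([float(p) for p in parts])
    if not rows:
        raise SchemaError(f"{path}: no data rows")
    df = pd.DataFrame(rows, columns=["Ba_mT", "Bb_mT", "M_norm"])
    return _triples_to_dataset(df, {"header": header_lines})


def write_distribution_csv(dist: ForcDistribution, path) -> None:
    gu, gc = np.meshgrid(dist.bu, dist.bc, indexing="ij")
    ok = ~np.isnan(dist.rho)
    pd.DataFrame(
        {"Bc_mT": gc[ok], "Bu_mT": gu[ok], "rho": dist.rho[ok]}
    ).to_csv(path, index=False, float_format="%.17g")


def write_assemblage_csv(asm: ChainAssemblage, path) -> None:
    pd.DataFrame(
        {
            "chain_id": asm.chain_ids,
            "x_nm": asm.positions[:, 0],
            "y_nm": asm.positions[:, 1],
            "z_nm": asm.positions[:, 2],
            "axis_x": asm.easy_axes[:, 0],
            "axis_y": asm.easy_axes[:, 1],
            "axis_z": asm.easy_axes[:, 2],
            "length_nm": asm.lengths,
            "width_nm": asm.widths,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_assemblage_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(
        df,
        ["chain_id", "x_nm", "y_nm", "z_nm", "axis_x", "axis_y", "axis_z", "length_nm", "width_nm"],
        path,
    )
    return df


def read_downcore_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["depth_mcd"], path)
    return df


def write_downcore_csv(df: pd.DataFrame, path) -> None:
    if "depth_mcd" not in df.columns:
        raise SchemaError(f"{path}: table lacks depth_mcd column")
    df.to_csv(path, index=False, float_format="%.17g")


def read_lowtemp_csv(path, treatment: str | None = None) -> LowTempCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["temperature_K", "moment", "treatment"], path)
    if treatment is not None:
        df = df[df["treatment"] == treatment]
        if df.empty:
            raise SchemaError(f"{path}: no rows with treatment={treatment!r}")
    tr = treatment or str(df["treatment"].iloc[0])
    return LowTempCurve(df["temperature_K"].to_numpy(float), df["moment"].to_numpy(float), tr)


def write_lowtemp_csv(curves: list[LowTempCurve], path) -> None:
    frames = [
        pd.DataFrame(
            {"temperature_K": c.temperature_K, "moment": c.moment, "treatment": c.treatment}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
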