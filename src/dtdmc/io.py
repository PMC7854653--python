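"""CSV/JSON serialization with unit and convention markers.

Designs, signals and ensembles travel as headered CSV; CNTVD parameters
and fit results as versioned JSON.  Design CSVs store the *plain* 3x3
b-matrix entries (bxy, not 2*bxy); the factor of two of the contraction
convention is applied on load, and the header comment records this so a
file with unknown provenance is rejected rather than silently misread.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import BMatrix, BMatrixDesign
from .cntvd import CNTVDParams, TensorEnsemble
from .signal import SignalDataset

__all__ = [
    "write_design_csv",
    "read_design_csv",
    "write_signal_csv",
    "read_signal_csv",
    "read_signal_dataset",
    "write_ensemble_csv",
    "read_ensemble_csv",
    "write_params_json",
    "read_params_json",
    "write_result_json",
    "read_result_json",
]

_DESIGN_MARKER = "# dtdmc design v1; units ms/um^2; offdiag plain (doubled on load)"
_SIGNAL_MARKER = "# dtdmc signal v1; arbitrary units"
_ENSEMBLE_MARKER = "# dtdmc ensemble v1; units um^2/ms"
_SCHEMA_VERSION = 1


def _read_marked_csv(path, marker: str, what: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or marker.split(";")[1].strip() not in first:
            raise ValueError(
                f"{what} file {path} lacks the convention marker "
                f"({marker!r}); refusing to guess units/scaling"
            )
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError(f"{what} file {path} contains NaN values")
    return df


def write_design_csv(design: BMatrixDesign, path) -> None:
    rows = []
    for k, b in enumerate(design.bmatrices):
        m = b.matrix
        rows.append(
            dict(
                id=k, rank=b.rank,
                bxx=m[0, 0], byy=m[1, 1], bzz=m[2, 2],
                bxy=m[0, 1], bxz=m[0, 2], byz=m[1, 2],
                trace=b.trace,
            )
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_DESIGN_MARKER + "\n")
        df.to_csv(fh, index=False)


def read_design_csv(path, b_range: tuple[float, float] | None = None) -> BMatrixDesign:
    df = _read_marked_csv(path, _DESIGN_MARKER, "design")
    if df["id"].duplicated().any():
        raise ValueError("duplicate b-matrix ids")
    mats = []
    for _, r in df.sort_values("id").iterrows():
        m = np.array(
            [
                [r.bxx, r.bxy, r.bxz],
                [r.bxy, r.byy, r.byz],
                [r.bxz, r.byz, r.bzz],
            ]
        )
        mats.append(BMatrix(m, rank=int(r["rank"])))
    traces = [b.trace for b in mats]
    return BMatrixDesign(
        mats, b_range=b_range or (0.0, float(max(traces))), rank_mix=float("nan")
    )


def write_signal_csv(signal: np.ndarray, path, ids=None) -> None:
    signal = np.asarray(signal, dtype=float).reshape(-1)
    ids = np.arange(len(signal)) if ids is None else np.asarray(ids)
    with open(path, "w") as fh:
        fh.write(_SIGNAL_MARKER + "\n")
        pd.DataFrame({"id": ids, "signal": signal}).to_csv(fh, index=False)


def read_signal_csv(path) -> pd.DataFrame:
    df = _read_marked_csv(path, _SIGNAL_MARKER, "signal")
    if df["id"].duplicated().any():
        raise ValueError("duplicate signal ids")
    return df.sort_values("id")


def read_signal_dataset(design_path, signal_path, snr: float = np.inf) -> SignalDataset:
    design = read_design_csv(design_path)
    sig = read_signal_csv(signal_path)
    if len(sig) != len(design):
        raise ValueError("signal and design lengths differ")
    return SignalDataset(design=design, signal=sig["signal"].to_numpy(), snr=snr)


def write_ensemble_csv(ensemble: TensorEnsemble, path) -> None:
    with open(path, "w") as fh:
        fh.write(_ENSEMBLE_MARKER + f"; n_proposed {ensemble.n_proposed}\n")
        ensemble.to_dataframe().to_csv(fh, index=False)


def read_ensemble_csv(path) -> TensorEnsemble:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if "um^2/ms" not in first:
            raise ValueError(f"ensemble file {path} lacks the units marker")
        n_proposed = int(first.rsplit("n_proposed", 1)[1]) if "n_proposed" in first else -1
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError("ensemble file contains NaN values")
    d6 = df[["dxx", "dyy", "dzz", "dxy", "dxz", "dyz"]].to_numpy()
    return TensorEnsemble(d6, n_proposed=n_proposed if n_proposed > 0 else len(d6))


def _params_dict(params: CNTVDParams) -> dict:
    return {
        "mean_d6": params.mean_d6.tolist(),
        "omega": params.omega.tolist(),
        "s0": params.s0,
        "symmetry_class": params.symmetry_class,
        "units": {"mean_d6": "um^2/ms", "omega": "(um^2/ms)^2"},
    }


def write_params_json(params: CNTVDParams, path) -> None:
    doc = {"schema": "dtdmc.params", "version": _SCHEMA_VERSION, **_params_dict(params)}
    Path(path).write_text(json.dumps(doc, indent=1))


def _check_schema(doc: dict, name: str) -> None:
    if doc.get("schema") != name or doc.get("version") != _SCHEMA_VERSION:
        raise ValueError(f"expected {name} v{_SCHEMA_VERSION} JSON, got {doc.get('schema')!r}")


def read_params_json(path) -> CNTVDParams:
    doc = json.loads(Path(path).read_text())
    _check_schema(doc, "dtdmc.params")
    if doc["units"]["mean_d6"] != "um^2/ms":
        raise ValueError("unexpected diffusivity units")
    return CNTVDParams(
        mean_d6=np.array(doc["mean_d6"]),
        omega=np.array(doc["omega"]),
        s0=doc["s0"],
        symmetry_class=doc.get("symmetry_class"),
    )


def write_result_json(result, path, seeds: dict | None = None) -> None:
    from . import __version__

    doc = {
        "schema": "dtdmc.fit_result",
        "version": _SCHEMA_VERSION,
        "software_version": __version__,
        "selected": {"mean_class": result.selected.mean_class, "cov_class": result.selected.cov_class},
        "rss": result.rss,
        "converged": bool(result.converged),
        "seeds": seeds or result.seeds,
        "bic_table": result.bic_table.to_dict(orient="records"),
        **_params_dict(result.params),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_result_json(path):
    from .estimation import FitResult
    from .models import ModelSpec

    doc = json.loads(Path(path).read_text())
    _check_schema(doc, "dtdmc.fit_result")
    params = CNTVDParams(
        mean_d6=np.array(doc["mean_d6"]),
        omega=np.array(doc["omega"]),
        s0=doc["s0"],
        symmetry_class=doc.get("symmetry_class"),
    )
    return FitResult(
        selected=ModelSpec(doc["selected"]["mean_class"], doc["selected"]["cov_class"]),
        params=params,
        bic_table=pd.DataFrame(doc["bic_table"]),
        rss=doc["rss"],
        converged=doc["converged"],
        seeds=doc.get("seeds", {}),
    )
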