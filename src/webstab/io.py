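"""Plain-text readers/writers: edge lists, adjacency CSV, matrix CSV, reports.

Edge lists are TSV, one "resource<TAB>consumer" link per line with 1-based
species IDs and '#' comments.  Adjacency matrices are dense 0/1 CSV
(headerless by default); community matrices are dense real CSV with a JSON
sidecar carrying seed, Z moments, d and the species ordering.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .ordering import OrderingResult
from .spectra import StabilityPrediction
from .strengths import CommunityMatrix, StrengthDistribution
from .webgen import FoodWeb

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "prediction_report",
    "ordering_report",
    "write_json_report",
]

PathLike = Union[str, Path]


def write_edge_list(web: FoodWeb, path: PathLike) -> None:
    """Write a web as TSV links "resource<TAB>consumer", 1-based IDs."""
    path = Path(path)
    lines = [f"# S={web.S} model={web.model}"]
    ri, cj = np.nonzero(web.K)
    lines += [f"{i + 1}\t{j + 1}" for i, j in zip(ri, cj)]
    path.write_text("\n".join(lines) + "\n")


def read_edge_list(path: PathLike, S: Optional[int] = None) -> FoodWeb:
    """Read a TSV edge list; S is inferred from a "# S=" header comment or
    the largest species ID unless given explicitly."""
    links = []
    header_S = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("S="):
                    header_S = int(tok[2:])
            continue
        a, b = line.split("\t")
        links.append((int(a) - 1, int(b) - 1))
    if S is None:
        S = header_S if header_S is not None else max(max(l) for l in links) + 1
    K = np.zeros((S, S), dtype=np.int8)
    for i, j in links:
        K[i, j] = 1
    return FoodWeb(S, K, model="user")


def write_adjacency_csv(web: FoodWeb, path: PathLike, header: bool = False) -> None:
    """Dense S x S 0/1 CSV (optional 1-based species-ID header row/column)."""
    df = pd.DataFrame(web.K)
    if header:
        df.index = df.columns = range(1, web.S + 1)
    df.to_csv(path, header=header, index=header)


def read_adjacency_csv(path: PathLike, header: bool = False) -> FoodWeb:
    df = pd.read_csv(path, header=0 if header else None, index_col=0 if header else None)
    K = df.to_numpy()
    return FoodWeb(K.shape[0], K, model="user")


def write_matrix_csv(
    mat: CommunityMatrix,
    path: PathLike,
    Z: Optional[StrengthDistribution] = None,
    seed: Optional[int] = None,
) -> None:
    """Dense real CSV plus a self-describing JSON sidecar (<path>.json)."""
    path = Path(path)
    np.savetxt(path, mat.M, delimiter=",")
    sidecar = {
        "S": mat.S,
        "d": mat.d,
        "seed": seed,
        "ordering": [int(i) + 1 for i in mat.ordering],
        "Z": dataclasses.asdict(Z) if Z is not None else None,
        "note": "Z moments are synthetic stand-ins unless supplied by the user",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix_csv(path: PathLike) -> CommunityMatrix:
    path = Path(path)
    M = np.loadtxt(path, delimiter=",")
    d = 0.0
    ordering = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        d = float(meta.get("d", 0.0))
        if meta.get("ordering"):
            ordering = np.array(meta["ordering"], dtype=int) - 1
    return CommunityMatrix(M.shape[0], M, d=d, ordering=ordering)


def prediction_report(pred: StabilityPrediction, extra: Optional[dict] = None) -> dict:
    """JSON-ready dict with all moments, components, regime and baselines.

    The May / Tang comparison values use the exchangeable-moment mapping
    E = (mu_U + mu_L)/2, V = (sigma_U^2 + sigma_L^2)/2 + (mu_U - mu_L)^2/4,
    rho = (cov_UL - (mu_U - mu_L)^2/4)/V; may = sqrt(SV) - d and
    tang = sqrt(SV)(1 + rho) - E - d.
    """
    rep = {
        "predicted": pred.predicted,
        "re_lambda_A": pred.re_lambda_A,
        "r_h_B": pred.r_h_B,
        "regime": pred.regime,
        "d": pred.d,
        "moments": dataclasses.asdict(pred.moments),
        "circle": {
            "c_A": pred.circle.c_A,
            "r_A": pred.circle.r_A,
            "degenerate": pred.circle.degenerate,
            "method": pred.circle.method,
        },
        "ellipse": {
            "alpha": pred.ellipse.alpha,
            "r_h": pred.ellipse.r_h,
            "r_v": pred.ellipse.r_v,
            "low_confidence": pred.ellipse.low_confidence,
        },
        "comparisons": {"may": pred.may_value, "tang": pred.tang_value},
        "numeric_value": pred.numeric_value,
        "flags": pred.flags,
        "connectance_convention": "C is defined per pair, against S(S-1)/2 potential links",
    }
    if extra:
        rep.update(extra)
    return _jsonable(rep)


def ordering_report(result: OrderingResult) -> dict:
    return {
        "permutation": [int(i) + 1 for i in result.permutation],  # 1-based
        "lower_fill": result.lower_fill,
        "method": result.method,
        "iterations": result.iterations,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_json_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=2) + "\n")
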