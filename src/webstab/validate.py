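"""End-to-end validation workflow and tiny worked-example fixtures.

Replicates the numerical protocol used to assess the approximation: draw
web size S from a small set and connectance C uniformly from a range,
generate a web, parameterize it, sort cyclic webs toward the
most-upper-triangular order, and compare the analytic prediction (and the
May / Tang baselines) against the numerically computed Re(lambda_M,1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import webgen
from .ordering import sort_most_upper_triangular
from .spectra import numeric_leading_eigenvalue, predict_stability
from .strengths import StrengthDistribution, bodysize_standin, build_community_matrix
from .webgen import FoodWeb, has_cycles

__all__ = ["run_validation", "summarize_validation", "make_fixtures", "GENERATORS"]

logger = logging.getLogger("webstab")

GENERATORS = {
    "cascade": webgen.generate_cascade,
    "niche": webgen.generate_niche,
    "cascade_degree_matched": webgen.generate_cascade_degree_matched,
    "cascade_interval": webgen.generate_cascade_interval,
    "niche_cycleless": webgen.generate_niche_cycleless,
}

DEFAULT_S_CHOICES = (500, 750, 1000)
DEFAULT_C_RANGE = (0.1, 0.3)


def run_validation(
    models: Sequence[str] = ("cascade",),
    replicates: int = 50,
    S_choices: Sequence[int] = DEFAULT_S_CHOICES,
    C_range: Sequence[float] = DEFAULT_C_RANGE,
    Z: Optional[StrengthDistribution] = None,
    d: float = 0.0,
    seed: Optional[int] = None,
    dense_limit: int = 2000,
    compute_numeric: bool = True,
    sort_budget: int = 100,
) -> pd.DataFrame:
    """Per-replicate validation table for one or more web models.

    For each replicate: S is drawn uniformly from ``S_choices`` and C
    uniformly from ``C_range``; a web is generated and parameterized with
    Z; cyclic webs are re-ordered by the feedback-arc heuristic; the
    prediction is parameterized from the measured triangle moments of the
    ordered matrix, alongside the May and Tang baselines and (optionally)
    the numeric leading eigenvalue.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    unknown = set(models) - set(GENERATORS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")
    if Z is None:
        Z = bodysize_standin("default")
    ss = np.random.SeedSequence(seed)
    rows = []
    for model in models:
        for rep, child in enumerate(ss.spawn(replicates)):
            rng = np.random.default_rng(child)
            S = int(rng.choice(S_choices))
            C = float(rng.uniform(*C_range))
            web = GENERATORS[model](S, C, rng)
            mat = build_community_matrix(web, Z, d=d, seed=rng)
            if has_cycles(web):
                order = sort_most_upper_triangular(web, budget=sort_budget)
                perm, lower_fill = order.permutation, order.lower_fill
            else:
                perm, lower_fill = np.arange(S), 0
            pred = predict_stability(mat, ordering=perm)
            observed = np.nan
            if compute_numeric and S <= dense_limit:
                observed = numeric_leading_eigenvalue(mat, dense_limit).real
            rows.append(
                dict(
                    model=model,
                    rep=rep,
                    S=S,
                    C=C,
                    n_links=web.n_links,
                    lower_fill=lower_fill,
                    re_lambda_A=pred.re_lambda_A,
                    r_h_B=pred.r_h_B,
                    predicted=pred.predicted,
                    may=pred.may_value,
                    tang=pred.tang_value,
                    observed=observed,
                    regime=pred.regime,
                )
            )
            logger.info(
                "%s rep=%d S=%d C=%.3f predicted=%.4f observed=%.4f",
                model, rep, S, C, pred.predicted, observed,
            )
    return pd.DataFrame(rows)


def summarize_validation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-model error summary: mean absolute / signed / relative errors of
    the prediction and of the May and Tang baselines."""
    out = []
    for model, grp in table.groupby("model"):
        obs = grp["observed"]
        out.append(
            dict(
                model=model,
                replicates=len(grp),
                mae_predicted=(grp["predicted"] - obs).abs().mean(),
                mae_may=(grp["may"] - obs).abs().mean(),
                mae_tang=(grp["tang"] - obs).abs().mean(),
                bias_predicted=(grp["predicted"] - obs).mean(),
                median_rel_error=((grp["predicted"] - obs).abs() / obs.abs()).median(),
            )
        )
    return pd.DataFrame(out)


def make_fixtures(outdir) -> dict:
    """Write tiny deterministic worked examples; returns {name: path}.

    Contents: the complete S=5 cascade web, a 3-cycle, a fixed S=8 digraph
    small enough for exact ordering, and a point-mass community matrix on
    the complete cascade web.
    """
    from .io import write_edge_list, write_matrix_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    complete = webgen.generate_cascade(5, 1.0, seed=0)
    paths["cascade_complete_S5"] = outdir / "cascade_complete_S5.tsv"
    write_edge_list(complete, paths["cascade_complete_S5"])

    K3 = np.zeros((3, 3), dtype=np.int8)
    K3[0, 1] = K3[1, 2] = K3[2, 0] = 1
    paths["three_cycle"] = outdir / "three_cycle.tsv"
    write_edge_list(FoodWeb(3, K3, model="user"), paths["three_cycle"])

    rng = np.random.default_rng(2025)
    K8 = (rng.random((8, 8)) < 0.35).astype(np.int8)
    np.fill_diagonal(K8, 0)
    paths["digraph_S8"] = outdir / "digraph_S8.tsv"
    write_edge_list(FoodWeb(8, K8, model="user"), paths["digraph_S8"])

    Z = StrengthDistribution(-1.0, 0.5, family="point_mass")
    mat = build_community_matrix(complete, Z, d=0.0, seed=0)
    paths["pointmass_matrix_S5"] = outdir / "pointmass_matrix_S5.csv"
    write_matrix_csv(mat, paths["pointmass_matrix_S5"], Z=Z, seed=0)

    return paths
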