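"""Assigning functional units to EM neurons and scoring the assignments.

Once EM nucleus centroids have been carried into the 2P functional
space (by the fiducial transform stack or by the vessel displacement
field), units and neurons are paired per scan by minimum-weight
bipartite matching on Euclidean distance. Two confidence scores
accompany every match:

* residual - distance (um) between the unit centroid and the matched,
  transformed EM soma centroid;
* separation - distance to the nearest *other* EM neuron minus the
  residual; negative iff the nearest neuron was not the one chosen.

Scores can be converted to within-table percentiles, thresholded, and
two automatch tables can be merged into an agreement ("hybrid") table.
Automatch tables are evaluated against manual matches with the
common-attempt restriction protocol (precision/recall).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import rankdata

__all__ = [
    "UNIT_KEY",
    "MATCH_KEY",
    "EvalReport",
    "assign_matches",
    "separation_scores",
    "to_percentiles",
    "filter_matches",
    "hybrid_agreement",
    "evaluate_against_manual",
]

UNIT_KEY = ["session", "scan_idx", "field", "unit_id"]
MATCH_KEY = UNIT_KEY + ["em_id"]

#: default cap (um) on matched distance; pairs farther apart are left unmatched
DEFAULT_MAX_DISTANCE_UM = 25.0

_XYZ = ["x_um", "y_um", "z_um"]


def _coords(df: pd.DataFrame) -> np.ndarray:
    missing = [c for c in _XYZ if c not in df.columns]
    if missing:
        raise ValueError(f"table missing coordinate columns: {missing}")
    xyz = df[_XYZ].to_numpy(float)
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite coordinates")
    return xyz


def _empty_match_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "session": pd.Series(dtype=int),
            "scan_idx": pd.Series(dtype=int),
            "field": pd.Series(dtype=int),
            "unit_id": pd.Series(dtype=int),
            "em_id": pd.Series(dtype=int),
            "residual_um": pd.Series(dtype=float),
            "method": pd.Series(dtype=object),
        }
    )


def assign_matches(
    units: pd.DataFrame,
    em: pd.DataFrame,
    max_distance: Optional[float] = DEFAULT_MAX_DISTANCE_UM,
    method: str = "fiducial_auto",
) -> pd.DataFrame:
    """Minimum-total-distance one-to-one assignment of one scan's units to EM neurons.

    ``units`` carries the unit key columns and 2P-space coordinates;
    ``em`` carries em_id and coordinates already transformed into the
    same space. Surplus rows on either side stay unmatched; pairs
    farther than ``max_distance`` (um) are excluded. Set
    ``max_distance=None`` to disable the cap.
    """
    if len(units) == 0:
        return _empty_match_table()
    if len(em) == 0:
        return _empty_match_table()
    if units.groupby(UNIT_KEY).size().max() > 1:
        raise ValueError("duplicate unit keys within the scan")
    if em["em_id"].duplicated().any():
        raise ValueError("duplicate em_id in centroid table")
    u_xyz = _coords(units)
    e_xyz = _coords(em)
    cost = np.linalg.norm(u_xyz[:, None, :] - e_xyz[None, :, :], axis=-1)
    if max_distance is not None:
        big = max(1e6, 1e3 * cost.max())
        capped = np.where(cost > max_distance, big, cost)
    else:
        capped = cost
    rows_i, cols_i = linear_sum_assignment(capped)
    keep = cost[rows_i, cols_i] <= (max_distance if max_distance is not None else np.inf)
    rows_i, cols_i = rows_i[keep], cols_i[keep]
    out = units.iloc[rows_i][UNIT_KEY].reset_index(drop=True)
    out["em_id"] = em.iloc[cols_i]["em_id"].to_numpy()
    out["residual_um"] = cost[rows_i, cols_i]
    out["method"] = method
    return out


def separation_scores(matches: pd.DataFrame, em: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Add the separation column: distance to the nearest EM neuron other than
    the matched one, minus the residual.

    Positive iff the matched neuron is the unit's nearest neighbour in
    the candidate table. With a single candidate neuron the score is
    undefined and recorded as NaN.
    """
    if "residual_um" not in matches.columns:
        raise ValueError("matches must carry residual_um")
    out = matches.copy()
    if len(out) == 0:
        out["separation_um"] = pd.Series(dtype=float)
        return out
    if len(em) < 2:
        out["separation_um"] = np.nan
        return out
    e_xyz = _coords(em)
    em_ids = em["em_id"].to_numpy()
    id_to_col = {i: k for k, i in enumerate(em_ids)}
    tree = cKDTree(e_xyz)
    u = matches.merge(units, on=UNIT_KEY, how="left", validate="one_to_one")
    u_xyz = _coords(u)
    d, j = tree.query(u_xyz, k=2)
    matched_col = np.array([id_to_col[i] for i in out["em_id"]])
    nearest_other = np.where(j[:, 0] == matched_col, d[:, 1], d[:, 0])
    out["separation_um"] = nearest_other - out["residual_um"].to_numpy()
    return out


def to_percentiles(matches: pd.DataFrame, per_scan: bool = False) -> pd.DataFrame:
    """Rank-based percentiles of residual and separation, average-rank convention:
    pct = (rank - 0.5) / n * 100, ties sharing their mean rank."""
    if len(matches) < 2:
        raise ValueError("need >= 2 rows to compute percentiles")
    out = matches.copy()

    def pct(x: pd.Series) -> np.ndarray:
        v = x.to_numpy(float)
        p = np.full(len(v), np.nan)
        ok = np.isfinite(v)
        if ok.sum():
            p[ok] = (rankdata(v[ok], method="average") - 0.5) / ok.sum() * 100.0
        return p

    groups = out.groupby(["session", "scan_idx"]) if per_scan else [(None, out)]
    for _, g in groups:
        out.loc[g.index, "residual_pct"] = pct(g["residual_um"])
        if "separation_um" in out.columns:
            out.loc[g.index, "separation_pct"] = pct(g["separation_um"])
    return out


def filter_matches(
    matches: pd.DataFrame,
    residual_pct_max: Optional[float] = None,
    separation_pct_min: Optional[float] = None,
) -> pd.DataFrame:
    """Drop rows above the residual-percentile cap or below the separation-percentile floor."""
    for t in (residual_pct_max, separation_pct_min):
        if t is not None and not 0 <= t <= 100:
            raise ValueError("percentile thresholds must be in [0, 100]")
    out = matches
    if residual_pct_max is not None:
        out = out[out["residual_pct"] <= residual_pct_max]
    if separation_pct_min is not None:
        out = out[out["separation_pct"] >= separation_pct_min]
    return out.reset_index(drop=True)


def hybrid_agreement(a: pd.DataFrame, b: pd.DataFrame, suffixes=("_a", "_b")) -> pd.DataFrame:
    """Inner join of two automatch tables on the five match keys; rows where
    both methods assigned the same EM neuron to the same unit."""
    score_cols = [c for c in a.columns if c not in MATCH_KEY and c != "method"]
    merged = a.merge(b, on=MATCH_KEY, how="inner", suffixes=suffixes)
    merged["method"] = "hybrid"
    keep = MATCH_KEY + [c + s for c in score_cols for s in suffixes if c + s in merged.columns]
    return merged[keep + ["method"]]


@dataclass
class EvalReport:
    """Precision/recall of an automatch table against manual matches."""

    tp: int
    fp: int
    fn: int
    n_common_units: int
    n_common_neurons: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def evaluate_against_manual(auto: pd.DataFrame, manual: pd.DataFrame) -> EvalReport:
    """Precision/recall after restricting both tables to commonly attempted rows.

    A row is kept when its functional unit or its EM neuron appears in
    both tables (was "commonly attempted"). True positives are rows in
    both restricted tables; false positives only in auto; false
    negatives only in manual. Undefined ratios are NaN, never 0.
    """
    if len(auto) == 0 or len(manual) == 0:
        # the common-attempt restriction is vacuous with an empty side:
        # everything remaining in the other table counts against it
        return EvalReport(tp=0, fp=len(auto), fn=len(manual),
                          n_common_units=0, n_common_neurons=0)
    a_units = set(map(tuple, auto[UNIT_KEY].itertuples(index=False)))
    m_units = set(map(tuple, manual[UNIT_KEY].itertuples(index=False)))
    a_ems = set(auto["em_id"])
    m_ems = set(manual["em_id"])
    common_units = a_units & m_units
    common_ems = a_ems & m_ems

    def restrict(df):
        unit_t = list(map(tuple, df[UNIT_KEY].itertuples(index=False)))
        keep = [
            (u in common_units) or (e in common_ems)
            for u, e in zip(unit_t, df["em_id"])
        ]
        return df[np.asarray(keep, bool)]

    ra, rm = restrict(auto), restrict(manual)
    sa = set(map(tuple, ra[MATCH_KEY].itertuples(index=False)))
    sm = set(map(tuple, rm[MATCH_KEY].itertuples(index=False)))
    tp = len(sa & sm)
    return EvalReport(
        tp=tp,
        fp=len(sa) - tp,
        fn=len(sm) - tp,
        n_common_units=len(common_units),
        n_common_neurons=len(common_ems),
    )
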