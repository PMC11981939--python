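"""Reliability statistics on repeated-trial responses and cross-scan unit consolidation.

The oracle score quantifies how reliably a unit responds to repeated
presentations of the same "oracle" stimuli: per clip, each repeat is
correlated with the mean of the remaining repeats (a jackknife), and the
correlations are averaged over repeats and then clips. Signal
correlation compares two units' trial-averaged responses. Units
recorded in more than one scan are consolidated into unique neurons by
greedy proximity grouping under distance and z-extent constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matching import UNIT_KEY

__all__ = [
    "ResponseBlock",
    "ConsolidationResult",
    "oracle_score",
    "signal_correlation",
    "validate_matches_across_scans",
    "consolidate_units",
]


@dataclass
class ResponseBlock:
    """Repeats x time activity traces for the oracle-stimulus trials of one unit.

    ``traces`` maps clip id -> (n_repeats, n_samples) array of
    deconvolved activity (arbitrary units).
    """

    unit_key: tuple  # (session, scan_idx, field, unit_id)
    traces: dict
    sampling_rate: float = 30.0

    def __post_init__(self):
        for cid, arr in self.traces.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"clip {cid}: traces must be repeats x time")
            self.traces[cid] = arr

    @property
    def n_repeats(self) -> int:
        return min(a.shape[0] for a in self.traces.values())

    def trial_average(self) -> np.ndarray:
        """Trial-averaged responses of all clips, concatenated in clip-id order."""
        return np.concatenate([self.traces[c].mean(axis=0) for c in sorted(self.traces)])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def oracle_score(block: ResponseBlock, normalize_repeats: bool = False) -> float:
    """Jackknife reliability: per clip, correlate each repeat with the mean of
    the other repeats; average over repeats, then over clips.

    Constant (zero-variance) traces yield undefined correlations, which
    are excluded with a warning; if nothing is defined the score is NaN.
    ``normalize_repeats`` z-scores each repeat before the jackknife.
    """
    clip_means = []
    n_undef = 0
    for cid in sorted(block.traces):
        arr = block.traces[cid]
        r = arr.shape[0]
        if r < 2:
            raise ValueError(f"clip {cid}: need >= 2 repeats")
        if normalize_repeats:
            sd = arr.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            arr = (arr - arr.mean(axis=1, keepdims=True)) / sd
        total = arr.sum(axis=0)
        cors = []
        for i in range(r):
            loo_mean = (total - arr[i]) / (r - 1)
            c = _pearson(arr[i], loo_mean)
            if np.isnan(c):
                n_undef += 1
            else:
                cors.append(c)
        if cors:
            clip_means.append(np.mean(cors))
    if n_undef:
        warnings.warn(f"{n_undef} constant repeat(s) excluded from the oracle score")
    return float(np.mean(clip_means)) if clip_means else np.nan


def signal_correlation(block_a: ResponseBlock, block_b: ResponseBlock) -> float:
    """Pearson correlation between two units' concatenated trial-averaged clip responses."""
    if sorted(block_a.traces) != sorted(block_b.traces):
        raise ValueError("blocks must share the same clip set")
    for c in block_a.traces:
        if block_a.traces[c].shape[1] != block_b.traces[c].shape[1]:
            raise ValueError(f"clip {c}: trace lengths differ")
    return _pearson(block_a.trial_average(), block_b.trial_average())


def validate_matches_across_scans(
    matches: pd.DataFrame,
    blocks: Sequence[ResponseBlock],
    units: pd.DataFrame,
) -> pd.DataFrame:
    """Cross-scan match validation by in vivo signal correlation.

    For every EM neuron matched in at least two scans and every scan
    pair (A, B): the signal correlation between the two matched units,
    plus two controls - matched unit in A against the nearest unit in B
    *not* matched to that neuron, and vice versa. Rows with missing
    response data are dropped.
    """
    by_key = {tuple(b.unit_key): b for b in blocks}
    u_xyz = {
        tuple(r[k] for k in UNIT_KEY): np.array([r["x_um"], r["y_um"], r["z_um"]])
        for _, r in units.iterrows()
    }
    rows = []
    for em_id, grp in matches.groupby("em_id"):
        scans = sorted(set(grp["scan_idx"]))
        if len(scans) < 2:
            continue
        key_of = {
            s: tuple(grp[grp["scan_idx"] == s].iloc[0][k] for k in UNIT_KEY) for s in scans
        }
        for sa, sb in combinations(scans, 2):
            ka, kb = key_of[sa], key_of[sb]
            if ka not in by_key or kb not in by_key:
                continue
            corr = signal_correlation(by_key[ka], by_key[kb])

            def control(anchor_key, other_scan, grab=matches):
                """nearest unit in other_scan not matched to this em_id"""
                cand = units[units["scan_idx"] == other_scan]
                matched_here = grab[(grab["scan_idx"] == other_scan) & (grab["em_id"] == em_id)]
                banned = set(map(tuple, matched_here[UNIT_KEY].itertuples(index=False)))
                anchor_xyz = u_xyz.get(key_of[other_scan])
                best_key, best_d = None, np.inf
                for _, r in cand.iterrows():
                    k = tuple(r[c] for c in UNIT_KEY)
                    if k in banned or k not in by_key:
                        continue
                    d = np.linalg.norm(np.array([r["x_um"], r["y_um"], r["z_um"]]) - anchor_xyz)
                    if d < best_d:
                        best_key, best_d = k, d
                if best_key is None:
                    return np.nan
                return signal_correlation(by_key[anchor_key], by_key[best_key])

            rows.append(
                {
                    "em_id": em_id,
                    "scan_a": sa,
                    "scan_b": sb,
                    "signal_corr_matched": corr,
                    "signal_corr_control_ab": control(ka, sb),
                    "signal_corr_control_ba": control(kb, sa),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "em_id",
            "scan_a",
            "scan_b",
            "signal_corr_matched",
            "signal_corr_control_ab",
            "signal_corr_control_ba",
        ],
    )


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


@dataclass
class ConsolidationResult:
    """A partition of units into unique-neuron groups."""

    groups: list  # list of dicts: members (list of unit keys), centroid, z_extent
    mapping: dict  # unit key -> group index

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def consolidate_units(
    units: pd.DataFrame,
    min_separation: float = 10.0,
    max_z_extent: float = 20.0,
) -> ConsolidationResult:
    """Greedy agglomeration of duplicate units recorded in different scans.

    Repeatedly joins the closest pair of groups (single linkage: closest
    cross-group member pair, members from different scans only) while
    that distance is <= ``min_separation``, the groups' scan sets are
    disjoint, and the merged group's z extent stays <= ``max_z_extent``.
    Ties break on the lowest (scan_idx, unit_id) lexicographic member
    keys so runs are deterministic. Group centroid = mean of members.
    """
    keys = [tuple(r) for r in units[UNIT_KEY].itertuples(index=False)]
    xyz = units[["x_um", "y_um", "z_um"]].to_numpy(float)
    n = len(keys)
    members = [[i] for i in range(n)]
    scans = [{keys[i][1]} for i in range(n)]
    alive = [True] * n

    def link(a: int, b: int) -> float:
        pa, pb = xyz[members[a]], xyz[members[b]]
        return float(np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)))

    def sort_key(a, b):
        ka = min((keys[i][1], keys[i][3]) for i in members[a])
        kb = min((keys[i][1], keys[i][3]) for i in members[b])
        return min(ka, kb), max(ka, kb)

    while True:
        best = None
        for a in range(n):
            if not alive[a]:
                continue
            for b in range(a + 1, n):
                if not alive[b] or (scans[a] & scans[b]):
                    continue
                z_all = xyz[members[a] + members[b], 2]
                if z_all.max() - z_all.min() > max_z_extent:
                    continue
                d = link(a, b)
                if d > min_separation:
                    continue
                cand = (d, sort_key(a, b), a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        _, _, a, b = best
        members[a] = members[a] + members[b]
        scans[a] = scans[a] | scans[b]
        alive[b] = False

    groups, mapping = [], {}
    for g in range(n):
        if not alive[g]:
            continue
        idx = members[g]
        z = xyz[idx, 2]
        groups.append(
            {
                "members": [keys[i] for i in idx],
                "centroid": xyz[idx].mean(axis=0),
                "z_extent": float(z.max() - z.min()),
            }
        )
        for i in idx:
            mapping[keys[i]] = len(groups) - 1
    return ConsolidationResult(groups, mapping)
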