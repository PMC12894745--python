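"""Hybrid TF-TF network construction from activity time courses.

Two independently derived networks are intersected:

1. **Directed, weighted** — a semi-parametric ODE model per target TF,

       (x_i(t_{k+1}) − x_i(t_k)) / Δt + α·x_i(t_k) = f_i(x(t_k)),

   with f_i learned by a tree ensemble (random forest or extra-trees)
   over all (patient, replicate) series of one condition; the
   normalised impurity importance of regulator j for target i is the
   edge weight w_ji ∈ [0, 1]. The decay rate α is estimated from the
   observed dynamic range of each TF's pooled series and the median is
   used for all targets. The fit is repeated n times with different
   seeds and only edges with w ≥ w_min in every run survive; the two
   condition networks are then merged (edge union, max weight).

2. **Undirected, signed** — Pearson correlation of the zeroed
   differential-activity score vectors (patients × intervals) of each
   TF pair within one condition; edges require |r| ≥ cor_min and carry
   sign(r).

The consensus keeps a directed edge i→j iff {i, j} is a correlation
edge, copying its sign; direction and weight come from the forest,
sign from the correlation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor, ExtraTreeRegressor

from ._rng import child_seed, rng_for
from .datamodel import DataError, NetworkEdgeTable, SampleDesign


@dataclasses.dataclass
class DecayRates:
    """Per-TF first-order decay estimates and their pooled median."""

    per_tf: pd.Series
    pooled: float


def estimate_decay(activities: pd.DataFrame, design: SampleDesign) -> DecayRates:
    """Decay from the dynamic range: α_i = ln((range_i + 1)/1) / (t_last − t_first).

    Each TF's series is pooled over all samples, shifted so its minimum
    is 0 and offset by ε = 1; a constant series gives α = 0. The pooled
    value (median over TFs) is what the network fit uses.
    """
    days = design.days()
    if len(days) < 2:
        raise DataError("decay estimation needs at least 2 time points")
    span = float(days[-1] - days[0])
    values = activities.to_numpy(dtype=float)
    rng_range = values.max(axis=1) - values.min(axis=1)
    alpha = np.log(rng_range + 1.0) / span
    per_tf = pd.Series(alpha, index=activities.index, name="alpha")
    return DecayRates(per_tf=per_tf, pooled=float(per_tf.median()))


def _training_pairs(
    activities: pd.DataFrame, design: SampleDesign, condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (x(t_k), x(t_{k+1}), Δt) over all series and consecutive days."""
    x_now, x_next, dt = [], [], []
    for patient in design.patients:
        reps = sorted(set(design.table[
            (design.table["patient"] == patient) & (design.table["condition"] == condition)
        ]["replicate"]))
        for rep in reps:
            days = sorted(set(design.table[
                (design.table["patient"] == patient)
                & (design.table["condition"] == condition)
                & (design.table["replicate"] == rep)
            ]["day"]))
            if len(days) < 2:
                raise DataError(
                    f"series ({patient}, {condition}, rep {rep}) has < 2 time points"
                )
            cols = []
            for day in days:
                (sid,) = design.samples_for(patient, condition, day, rep)
                cols.append(sid)
            series = activities.loc[:, cols].to_numpy(dtype=float)
            for k in range(len(days) - 1):
                x_now.append(series[:, k])
                x_next.append(series[:, k + 1])
                dt.append(float(days[k + 1] - days[k]))
    return np.array(x_now), np.array(x_next), np.array(dt)


def _ensemble_importances(
    x32: np.ndarray, y: np.ndarray, n_trees: int, tree_method: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean normalised impurity importance over a bagged tree ensemble.

    Built tree-by-tree from scikit-learn regression trees with √p
    feature subsampling — bootstrap aggregation for 'rf', unbagged
    random-split trees for 'et' — validating the design matrix once
    per target instead of once per tree, which is what makes forests
    over many targets and runs cheap.
    """
    n = x32.shape[0]
    y64 = np.ascontiguousarray(y, dtype=np.float64)
    total = np.zeros(x32.shape[1])
    for _ in range(n_trees):
        tree_seed = int(rng.integers(2**31))
        if tree_method == "rf":
            idx = rng.integers(0, n, n)
            tree = DecisionTreeRegressor(max_features="sqrt", random_state=tree_seed)
            tree.fit(x32[idx], y64[idx], check_input=False)
        else:
            tree = ExtraTreeRegressor(max_features="sqrt", random_state=tree_seed)
            tree.fit(x32, y64, check_input=False)
        total += tree.tree_.compute_feature_importances(normalize=True)
    return total / n_trees


def fit_dyn_network(
    activities: pd.DataFrame,
    design: SampleDesign,
    condition: str,
    alpha: float,
    n_trees: int = 1000,
    seed: int = 0,
    tree_method: str = "rf",
) -> NetworkEdgeTable:
    """One tree-ensemble fit of the semi-parametric ODE model (one run).

    Targets whose response has zero variance contribute no incoming
    edges; otherwise each target's incoming weights are the ensemble's
    impurity importances with the self-importance discarded and the
    rest renormalised to sum 1.
    """
    x_now, x_next, dt = _training_pairs(activities, design, condition)
    tfs = list(activities.index)
    if tree_method not in ("rf", "et"):
        raise DataError(f"unknown tree_method {tree_method!r}; expected 'rf' or 'et'")
    x32 = np.ascontiguousarray(x_now, dtype=np.float32)
    rows = []
    for i, target in enumerate(tfs):
        y = (x_next[:, i] - x_now[:, i]) / dt + alpha * x_now[:, i]
        if np.allclose(y, y[0]):
            continue
        importances = _ensemble_importances(
            x32, y, n_trees, tree_method,
            rng_for(seed, "forest", condition, target),
        )
        importances[i] = 0.0  # self-regulation is carried by the decay term
        total = importances.sum()
        if total <= 0:
            continue
        importances /= total
        for j, regulator in enumerate(tfs):
            if j != i and importances[j] > 0:
                rows.append((regulator, target, float(importances[j])))
    return NetworkEdgeTable(
        pd.DataFrame(rows, columns=["source", "target", "weight"]).assign(
            provenance=f"dyn:{condition}"
        ),
        directed=True,
    )


def stability_intersect(
    runs: Sequence[NetworkEdgeTable], w_min: float = 0.01
) -> NetworkEdgeTable:
    """Keep edges with w ≥ w_min in *every* run; report the mean weight."""
    if len(runs) == 0:
        raise DataError("stability_intersect needs at least one run")
    provenance = runs[0].edges["provenance"].iloc[0] if len(runs[0]) else ""
    kept: pd.DataFrame | None = None
    for r, run in enumerate(runs):
        e = run.edges.loc[run.edges["weight"] >= w_min, ["source", "target", "weight"]]
        e = e.rename(columns={"weight": f"w{r}"})
        kept = e if kept is None else kept.merge(e, on=["source", "target"], how="inner")
    wcols = [c for c in kept.columns if c.startswith("w")]
    out = kept[["source", "target"]].copy()
    out["weight"] = kept[wcols].mean(axis=1)
    out["provenance"] = provenance
    return NetworkEdgeTable(out, directed=True)


def infer_condition_network(
    activities: pd.DataFrame,
    design: SampleDesign,
    condition: str,
    alpha: float,
    n_runs: int = 10,
    n_trees: int = 1000,
    w_min: float = 0.01,
    seed: int = 0,
    tree_method: str = "rf",
    return_runs: bool = False,
):
    """n seeded forest runs intersected at w ≥ w_min (the per-condition network)."""
    runs = [
        fit_dyn_network(
            activities, design, condition, alpha,
            n_trees=n_trees, seed=child_seed(seed, "run", condition, r),
            tree_method=tree_method,
        )
        for r in range(n_runs)
    ]
    net = stability_intersect(runs, w_min=w_min)
    return (net, runs) if return_runs else net


def merge_conditions(
    net_auto: NetworkEdgeTable, net_mono: NetworkEdgeTable
) -> NetworkEdgeTable:
    """Edge union of the two condition networks; weight = max, tags retained."""
    a = net_auto.edges[["source", "target", "weight"]].assign(in_autologous=True)
    m = net_mono.edges[["source", "target", "weight"]].assign(in_monoculture=True)
    merged = a.merge(m, on=["source", "target"], how="outer", suffixes=("_a", "_m"))
    merged["in_autologous"] = merged["in_autologous"].fillna(False).astype(bool)
    merged["in_monoculture"] = merged["in_monoculture"].fillna(False).astype(bool)
    merged["weight"] = merged[["weight_a", "weight_m"]].max(axis=1)

    def _tag(row):
        both = row["in_autologous"] and row["in_monoculture"]
        return "both" if both else ("autologous" if row["in_autologous"] else "monoculture")

    merged["conditions"] = merged.apply(_tag, axis=1) if len(merged) else ""
    out = merged[["source", "target", "weight", "conditions"]].copy()
    out["provenance"] = "dyn:merged"
    return NetworkEdgeTable(out, directed=True)


def diff_corr_network(
    diff_table: pd.DataFrame,
    condition: str,
    tfs: Sequence[str],
    cor_min: float = 0.5,
) -> NetworkEdgeTable:
    """Signed undirected network from correlated differential-activity profiles.

    Each TF's profile is its stored (zeroed) scores over all
    (patient, interval) cells of the condition, concatenated in a fixed
    order; pairs where either profile has zero variance are skipped.
    """
    sub = diff_table[diff_table["condition"] == condition]
    if len(sub) == 0:
        raise DataError(f"no differential-activity rows for condition {condition!r}")
    cells = sorted(set(zip(sub["patient"], sub["day_a"], sub["day_b"])))
    profiles = {}
    for tf in tfs:
        rows = sub[sub["tf"] == tf].set_index(["patient", "day_a", "day_b"])["score"]
        vec = np.array([rows.get(c, np.nan) for c in cells], dtype=float)
        if np.isnan(vec).any():
            continue  # TF unscored in some cell (too few targets there)
        profiles[tf] = vec
    names = sorted(profiles)
    if len(names) and len(next(iter(profiles.values()))) < 2:
        raise DataError("correlation profiles need at least 2 entries")
    rows = []
    for a_i in range(len(names)):
        va = profiles[names[a_i]]
        if va.std() == 0:
            continue
        for b_i in range(a_i + 1, len(names)):
            vb = profiles[names[b_i]]
            if vb.std() == 0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if abs(r) >= cor_min:
                rows.append((names[a_i], names[b_i], r, 1 if r > 0 else -1))
    return NetworkEdgeTable(
        pd.DataFrame(rows, columns=["source", "target", "correlation", "sign"]).assign(
            provenance=f"cor:{condition}"
        ),
        directed=False,
    )


def merge_corr_networks(nets: Sequence[NetworkEdgeTable]) -> NetworkEdgeTable:
    """Union of per-condition correlation networks.

    A pair appearing in several conditions keeps the entry with the
    larger |r|, which also resolves conflicting signs.
    """
    frames = [n.edges for n in nets if len(n)]
    if not frames:
        return NetworkEdgeTable(
            pd.DataFrame(columns=["source", "target", "correlation", "sign", "provenance"]),
            directed=False,
        )
    allrows = pd.concat(frames, ignore_index=True)
    key = allrows.apply(lambda r: tuple(sorted((r["source"], r["target"]))), axis=1)
    allrows = allrows.assign(_key=key, _abs=allrows["correlation"].abs())
    best = allrows.sort_values("_abs", ascending=False).drop_duplicates("_key")
    return NetworkEdgeTable(
        best.drop(columns=["_key", "_abs"]).reset_index(drop=True), directed=False
    )


def consensus(
    directed_net: NetworkEdgeTable, corr_net: NetworkEdgeTable
) -> NetworkEdgeTable:
    """Directed edges whose unordered pair is also a correlation edge.

    Direction and weight come from the forest network; sign and
    correlation from the pair. Both orientations survive if both were
    inferred.
    """
    pair_info = {}
    for row in corr_net.edges.itertuples(index=False):
        pair_info[frozenset((row.source, row.target))] = (row.correlation, row.sign)
    rows = []
    for row in directed_net.edges.itertuples(index=False):
        info = pair_info.get(frozenset((row.source, row.target)))
        if info is None:
            continue
        cor, sign = info
        conditions = getattr(row, "conditions", "")
        rows.append((row.source, row.target, row.weight, int(sign), float(cor), conditions))
    return NetworkEdgeTable(
        pd.DataFrame(
            rows, columns=["source", "target", "weight", "sign", "correlation", "conditions"]
        ).assign(provenance="consensus"),
        directed=True,
    )
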