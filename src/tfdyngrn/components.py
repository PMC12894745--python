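"""Independent-component decomposition, variance projection, and set statistics.

ICA factorises the (gene-centred) expression matrix X (genes × samples)
as X ≈ M A, where the columns of the metagene matrix M are statistically
independent over genes and the metasample matrix A holds each
component's profile across samples. The proportion of variance
explained by a component subset is obtained by projecting X onto the
corresponding columns of M with the Moore–Penrose pseudoinverse,

    X̂ = M (MᵀM)⁻¹ Mᵀ X,      PVE = Σ_genes Var(X̂) / Σ_genes Var(X),

with per-gene population variances (the denominator convention cancels
in the ratio). Restart stability is the mean absolute correlation of
each component with its best match across seeded FastICA restarts.

The module also provides the hypergeometric over-representation test
and Benjamini–Hochberg adjustment shared by every enrichment table in
the pipeline.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import FastICA
from statsmodels.stats.multitest import multipletests

from ._rng import child_seed
from .datamodel import DataError


@dataclasses.dataclass
class ICAResult:
    metagenes: pd.DataFrame       # genes × components, unit-norm columns
    metasamples: pd.DataFrame     # components × samples
    stability: pd.Series          # per component, mean matched |r| across restarts
    k: int
    seed: int

    def __post_init__(self) -> None:
        m = self.metagenes.to_numpy()
        if np.linalg.matrix_rank(m) < m.shape[1]:
            warnings.warn("metagene matrix is rank-deficient", stacklevel=2)


def _fit_single_ica(x: np.ndarray, k: int, seed: int, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    from sklearn.exceptions import ConvergenceWarning

    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter, whiten="unit-variance")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            sources = ica.fit_transform(x)  # genes × k
        except ConvergenceWarning as exc:
            raise DataError(f"FastICA did not converge within {max_iter} iterations") from exc
    return sources, ica.mixing_  # (genes × k, samples × k)


def ica_decompose(
    X: pd.DataFrame, k: int = 10, n_restarts: int = 5, seed: int = 0, max_iter: int = 1000
) -> ICAResult:
    """FastICA of gene-centred X into k metagenes with restart-matching stability.

    The sign convention makes the largest-|loading| entry of each
    metagene positive; metagene columns have unit norm, with the scale
    moved into the metasample matrix so that X ≈ M·A + row-means.
    """
    if k > min(X.shape):
        raise DataError(f"k={k} exceeds min(matrix dims)={min(X.shape)}")
    xc = X.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=1, keepdims=True)
    sources, mixing = _fit_single_ica(xc, k, child_seed(seed, "ica", 0), max_iter)

    norms = np.linalg.norm(sources, axis=0)
    if (norms == 0).any():
        raise DataError("degenerate (all-zero) independent component")
    m = sources / norms
    a = (mixing * norms).T  # k × samples
    flip = np.sign(m[np.abs(m).argmax(axis=0), np.arange(k)])
    m *= flip
    a *= flip[:, None]

    matches = np.zeros((max(n_restarts - 1, 1), k))
    if n_restarts > 1:
        for r in range(1, n_restarts):
            s_r, _ = _fit_single_ica(xc, k, child_seed(seed, "ica", r), max_iter)
            corr = np.abs(np.corrcoef(m, s_r, rowvar=False)[:k, k:])
            row, col = optimize.linear_sum_assignment(-corr)
            matches[r - 1, row] = corr[row, col]
        stability = matches.mean(axis=0)
    else:
        stability = np.ones(k)

    comp_names = [f"IC{i + 1}" for i in range(k)]
    return ICAResult(
        metagenes=pd.DataFrame(m, index=X.index, columns=comp_names),
        metasamples=pd.DataFrame(a, index=comp_names, columns=X.columns),
        stability=pd.Series(stability, index=comp_names, name="stability"),
        k=k,
        seed=seed,
    )


@dataclasses.dataclass
class PveReport:
    components: tuple[str, ...]
    pve: float
    reconstruction_variance: float
    total_variance: float


def pve(
    X: pd.DataFrame, metagenes: pd.DataFrame, components: Sequence[str] | None = None
) -> PveReport:
    """Variance explained by a component subset via pseudoinverse projection."""
    if list(X.index) != list(metagenes.index):
        raise DataError("X and the metagene matrix must be row-aligned")
    cols = list(components) if components is not None else list(metagenes.columns)
    m = metagenes.loc[:, cols].to_numpy(dtype=float)
    x = X.to_numpy(dtype=float)
    gram = m.T @ m
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        warnings.warn("restricted metagene matrix is rank-deficient; using pseudoinverse",
                      stacklevel=2)
        xhat = m @ (np.linalg.pinv(m) @ x)
    else:
        xhat = m @ np.linalg.solve(gram, m.T @ x)
    var_hat = float(np.var(xhat, axis=1).sum())
    var_x = float(np.var(x, axis=1).sum())
    if var_x == 0:
        raise DataError("X has zero total variance")
    return PveReport(
        components=tuple(cols), pve=var_hat / var_x,
        reconstruction_variance=var_hat, total_variance=var_x,
    )


def pve_per_component(X: pd.DataFrame, result: ICAResult) -> pd.Series:
    vals = {c: pve(X, result.metagenes, [c]).pve for c in result.metagenes.columns}
    return pd.Series(vals, name="pve")


def ora(
    query: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[int, int, int, int, float]:
    """Upper-tail hypergeometric over-representation test.

    Returns (k overlap, K set size, n query size, N universe size, p)
    with p = P(X ≥ k) for X ~ Hypergeometric(N, K, n).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    query = set(query)
    if not query <= universe:
        raise DataError("query is not contained in the universe")
    gene_set = set(gene_set) & universe
    k = len(query & gene_set)
    K, n, N = len(gene_set), len(query), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ora_table(
    query: Iterable[str], gene_sets: Mapping[str, Iterable[str]], universe: Iterable[str]
) -> pd.DataFrame:
    """ORA of one query against a gene-set collection, BH-adjusted."""
    universe = set(universe)
    rows = []
    for name, members in gene_sets.items():
        k, K, n, N, p = ora(query, members, universe)
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    out["p_adj"] = bh_adjust(out["p"]) if len(out) else []
    return out.sort_values("p").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise DataError(f"empty GMT file: {path}")
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(set(members))]) for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
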