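"""Regulon enrichment scores and differential TF activity.

A TF's activity in a gene-level signature z is scored with the
weighted, mode-signed z-sum over its measured targets,

    NES = Σ_g w_g · m_g · z_g / sqrt(Σ_g w_g²),

where m_g ∈ {−1, +1} is the regulation mode and w_g the confidence
weight. Under independent standard-normal target z-scores the statistic
is itself standard normal, which is what makes it a normalised
enrichment score. Significance comes from an empirical null built by
permuting gene labels of the signature (the sample axis offers far too
few rearrangements with two replicates per group).

Differential activity between consecutive time points is the NES of
the later-vs-earlier contrast signature within one patient and
condition; scores failing the permutation test are stored as 0, and a
TF is "differentially activated" (DA) if it is significant in at least
one interval of one patient/condition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

from ._rng import rng_for
from .datamodel import DataError, ExpressionMatrix, Regulon, SampleDesign
from .preprocess import SignatureVector, contrast_signature

DEFAULT_MIN_TARGETS = 5


@dataclasses.dataclass
class EnrichmentResult:
    tf: str
    nes: float
    p: float | None
    n_targets_used: int


class TooFewTargets(DataError):
    """The TF has fewer measured targets than min_targets."""


def _target_arrays(
    signature_z: pd.Series, regulon: Regulon, tf: str, min_targets: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positions, signed modes and weights of the TF's measured targets."""
    entries = regulon.targets_of(tf)
    pos = signature_z.index.get_indexer(entries["target"])
    measured = pos >= 0
    if measured.sum() < min_targets:
        raise TooFewTargets(
            f"TF {tf}: {int(measured.sum())} measured targets < min_targets={min_targets}"
        )
    return (
        pos[measured],
        entries["mode"].to_numpy()[measured].astype(float),
        entries["weight"].to_numpy()[measured].astype(float),
    )


def nes(
    signature: SignatureVector | pd.Series,
    regulon: Regulon,
    tf: str,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> EnrichmentResult:
    """Weighted mode-signed z-sum enrichment score for one TF."""
    z = signature.z if isinstance(signature, SignatureVector) else signature
    pos, modes, weights = _target_arrays(z, regulon, tf, min_targets)
    zvals = z.to_numpy()[pos]
    score = float((weights * modes * zvals).sum() / np.sqrt((weights**2).sum()))
    return EnrichmentResult(tf=tf, nes=score, p=None, n_targets_used=len(pos))


def permutation_p(
    signature: SignatureVector | pd.Series,
    regulon: Regulon,
    tf: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> EnrichmentResult:
    """Two-sided permutation p-value for one TF's NES.

    The null reassigns the signature's z-values to genes at random
    (gene-label permutation); p uses the add-one rule
    (1 + #{|null| ≥ |obs|}) / (n_perm + 1) and can never be 0.
    """
    z = signature.z if isinstance(signature, SignatureVector) else signature
    obs = nes(z, regulon, tf, min_targets=min_targets)
    pos, modes, weights = _target_arrays(z, regulon, tf, min_targets)
    rng = rng_for(seed, "perm", tf)
    zarr = z.to_numpy()
    k = len(pos)
    draws = np.argpartition(rng.random((n_perm, zarr.size)), k - 1, axis=1)[:, :k]
    null = (zarr[draws] * (weights * modes)[None, :]).sum(axis=1) / np.sqrt((weights**2).sum())
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(obs.nes))) / (n_perm + 1.0)
    return EnrichmentResult(tf=tf, nes=obs.nes, p=float(p), n_targets_used=k)


def _null_from_shuffles(
    zarr: np.ndarray,
    target_pos: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    n_perm: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Shared gene-label permutations of one signature → null NES per TF."""
    order = np.argsort(rng.random((n_perm, zarr.size)), axis=1)
    permuted = zarr[order]  # (n_perm, n_genes)
    out = {}
    for tf, (pos, modes, weights) in target_pos.items():
        out[tf] = permuted[:, pos] @ (weights * modes) / np.sqrt((weights**2).sum())
    return out


def enrichment_table(
    signature: SignatureVector | pd.Series,
    regulon: Regulon,
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.DataFrame:
    """NES and permutation p for every scorable TF, one shared null per signature."""
    z = signature.z if isinstance(signature, SignatureVector) else signature
    zarr = z.to_numpy(dtype=float)
    target_pos = {}
    skipped = []
    for tf in regulon.tfs:
        try:
            target_pos[tf] = _target_arrays(z, regulon, tf, min_targets)
        except TooFewTargets:
            skipped.append(tf)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} TFs with < {min_targets} measured targets",
                      stacklevel=2)
    rng = rng_for(seed, "enrichment-null")
    nulls = _null_from_shuffles(zarr, target_pos, n_perm, rng)
    rows = []
    for tf, (pos, modes, weights) in target_pos.items():
        obs = float(zarr[pos] @ (weights * modes) / np.sqrt((weights**2).sum()))
        p = (1.0 + np.count_nonzero(np.abs(nulls[tf]) >= abs(obs))) / (n_perm + 1.0)
        rows.append((tf, obs, p, len(pos)))
    return pd.DataFrame(rows, columns=["tf", "nes", "p", "n_targets"]).set_index("tf")


def activity_matrix(
    standardised: ExpressionMatrix,
    regulon: Regulon,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.DataFrame:
    """TF × sample activity matrix: per-sample standardised values as signatures."""
    if standardised.layer != "standardised":
        raise DataError("activity_matrix expects the standardised layer")
    z = standardised.data
    target_pos = {}
    for tf in regulon.tfs:
        try:
            target_pos[tf] = _target_arrays(z.iloc[:, 0], regulon, tf, min_targets)
        except TooFewTargets:
            continue
    if not target_pos:
        raise DataError("no TF has enough measured targets")
    values = z.to_numpy(dtype=float)
    rows = {}
    for tf, (pos, modes, weights) in target_pos.items():
        rows[tf] = (weights * modes) @ values[pos, :] / np.sqrt((weights**2).sum())
    return pd.DataFrame(rows, index=z.columns).T.loc[sorted(target_pos)]


def differential_activity(
    norm_expr: ExpressionMatrix,
    design: SampleDesign,
    regulon: Regulon,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.DataFrame:
    """Interval-wise differential TF activity for every patient and condition.

    For each consecutive design-day pair (a, b) the signature is the
    later-vs-earlier Welch contrast; ``score_raw`` is its NES, ``p``
    the gene-permutation p, and ``score`` is zeroed whenever p > alpha.
    """
    rows = []
    for patient in design.patients:
        for condition in design.conditions:
            days = design.days(patient, condition)
            for day_a, day_b in zip(days[:-1], days[1:]):
                earlier = design.samples_for(patient, condition, day_a)
                later = design.samples_for(patient, condition, day_b)
                if len(earlier) < 2 or len(later) < 2:
                    warnings.warn(
                        f"interval ({day_a},{day_b}) of {patient}/{condition} skipped: "
                        "needs ≥2 replicates on both days",
                        stacklevel=2,
                    )
                    continue
                sig = contrast_signature(norm_expr, later, earlier)
                table = enrichment_table(
                    sig, regulon, n_perm=n_perm,
                    seed=rng_for(seed, "da", patient, condition, day_a, day_b).integers(2**31),
                    min_targets=min_targets,
                )
                for tf, rec in table.iterrows():
                    stored = rec["nes"] if rec["p"] <= alpha else 0.0
                    rows.append(
                        (tf, patient, condition, day_a, day_b, rec["nes"], stored, rec["p"])
                    )
    out = pd.DataFrame(
        rows,
        columns=["tf", "patient", "condition", "day_a", "day_b", "score_raw", "score", "p"],
    )
    return out


@dataclasses.dataclass
class DaTfSet:
    """Differentially activated TFs with the contexts in which they fired."""

    tfs: list[str]
    tags: pd.DataFrame  # significant rows of the differential-activity table

    def conditions_of(self, tf: str) -> set[str]:
        return set(self.tags.loc[self.tags["tf"] == tf, "condition"])

    def patients_of(self, tf: str) -> set[str]:
        return set(self.tags.loc[self.tags["tf"] == tf, "patient"])

    def intervals_of(self, tf: str) -> set[tuple[int, int]]:
        sub = self.tags[self.tags["tf"] == tf]
        return set(zip(sub["day_a"], sub["day_b"]))

    def members_in(self, condition: str) -> list[str]:
        return sorted(set(self.tags.loc[self.tags["condition"] == condition, "tf"]))

    def __len__(self) -> int:
        return len(self.tfs)


def select_da_tfs(diff_table: pd.DataFrame, alpha: float = 0.05) -> DaTfSet:
    """Union of TFs significant (p < alpha) in ≥1 (patient, condition, interval)."""
    hits = diff_table[diff_table["p"] < alpha]
    if len(hits) == 0:
        raise DataError("no TF passes the differential-activity threshold; "
                        "the downstream network is undefined")
    return DaTfSet(tfs=sorted(set(hits["tf"])), tags=hits.reset_index(drop=True))


def ora_tf_targets(
    da_set: DaTfSet,
    regulon: Regulon,
    gene_sets: dict[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of {DA TFs ∪ their targets} in each gene set."""
    from .components import ora_table

    query = set(da_set.tfs)
    for tf in da_set.tfs:
        query |= set(regulon.targets_of(tf)["target"])
    return ora_table(query, gene_sets, set(universe))
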