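"""Synthetic ground truth for the whole pipeline.

The generator emulates the study design the pipeline was built for:
3 patients × 2 culture conditions (autologous, monoculture) × 2
replicates sampled on days 1, 4, 8, 11 and 14. A known signed TF-TF
network drives latent TF activities through a saturating first-order
ODE,

    dx_i/dt = −α_i x_i + Σ_j s_ij w_ij tanh(x_j) + b_i + u_{p,i} + v_{c,i}
              + g(t)·e_{c,i},

integrated per (patient, condition, replicate) with fixed-step Euler
from a random initial state. Patient (u) and condition (v) effects are
additive per-TF constants; edges may be scoped to one condition only,
in which case they contribute nothing in the other. g(t)·e is a
mid-culture environmental shift — a logistic gate g rising around
``event_time`` scaling a per-TF, per-condition input, emulating the
change in culture milieu when nurse-like cells establish themselves —
which gives each TF a second, independent temporal mode beyond the
initial-state relaxation. Observed activities are the trajectory at
the design days plus Gaussian noise.

Each TF also gets a dedicated regulon of target genes; target-gene
counts are negative binomial around softplus means modulated by the
TF's activity, so the downstream activity-estimation and network-
inference stages can be scored against the known network.
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd

from ._rng import rng_for
from .datamodel import AUTOLOGOUS, CONDITIONS, ExpressionMatrix, Regulon, SampleDesign

SCOPE_BOTH = "both"
SCOPE_AUTO = "autologous_only"
SCOPE_MONO = "monoculture_only"

#: trajectories beyond this magnitude abort integration as a blow-up
ACTIVITY_CAP = 1e3


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults are the benchmark conditions used throughout: a
    25-TF network at 8% edge density with 20% repressive and 20%
    condition-specific edges, observed on the study's 5-day grid with
    observation noise sd 0.1.
    """

    n_tfs: int = 25
    edge_density: float = 0.08
    frac_negative_edges: float = 0.2
    frac_condition_specific: float = 0.2
    strength_range: tuple[float, float] = (0.5, 1.5)
    n_patients: int = 3
    n_replicates: int = 2
    days: tuple[int, ...] = (1, 4, 8, 11, 14)
    decay_range: tuple[float, float] = (0.1, 0.35)  # per day
    basal_sd: float = 0.3
    patient_effect_sd: float = 0.3
    condition_effect_sd: float = 0.3
    init_sd: float = 1.0
    share_replicate_initial: bool = False
    frac_input_tfs: float = 0.4    # receptor-proximal TFs receiving exogenous drive
    event_effect_sd: float = 0.4   # mid-culture environment shift, per input TF and condition
    event_time: float = 8.0        # day the shift is centred on
    event_width: float = 1.5       # days; logistic rise time of the shift
    obs_noise_sd: float = 0.1
    targets_per_tf: int = 10
    frac_repressed_targets: float = 0.3
    n_background_genes: int = 200
    activity_scale: float = 1.5  # λ: activity-to-expression coupling
    beta0_mean: float = 2.0
    beta0_sd: float = 1.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[float, float] = (8.0, 16.0)
    euler_step: float = 0.05  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 2:
            raise ValueError("n_tfs must be at least 2")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must lie in [0, 1]")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        for name in ("basal_sd", "patient_effect_sd", "condition_effect_sd",
                     "obs_noise_sd", "init_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        gaps = np.diff(self.days)
        if len(gaps) and self.euler_step >= gaps.min():
            raise ValueError("euler_step must be smaller than the smallest day gap")

    @property
    def tf_names(self) -> list[str]:
        width = len(str(self.n_tfs))
        return [f"TF{i + 1:0{width}d}" for i in range(self.n_tfs)]


@dataclasses.dataclass
class GroundTruthNet:
    """True signed, directed TF-TF network with per-edge condition scope."""

    tfs: list[str]
    edges: pd.DataFrame  # columns: regulator, target, strength, sign, scope

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("ground-truth network may not contain self-edges")

    def __len__(self) -> int:
        return len(self.edges)

    def scoped_pairs(self, condition: str | None = None) -> set[tuple[str, str]]:
        """Directed (regulator, target) pairs active in ``condition`` (None = any)."""
        if condition is None:
            keep = np.ones(len(self.edges), dtype=bool)
        else:
            scope = SCOPE_AUTO if condition == AUTOLOGOUS else SCOPE_MONO
            keep = self.edges["scope"].isin([SCOPE_BOTH, scope]).to_numpy()
        sub = self.edges[keep]
        return set(zip(sub["regulator"], sub["target"]))

    def sign_of(self) -> dict[tuple[str, str], int]:
        return {
            (r, t): int(s)
            for r, t, s in zip(self.edges["regulator"], self.edges["target"], self.edges["sign"])
        }


def sample_ground_truth(cfg: SimulationConfig) -> GroundTruthNet:
    """Erdős–Rényi signed network: each ordered non-self pair kept independently."""
    rng = rng_for(cfg.seed, "ground-truth")
    tfs = cfg.tf_names
    rows = []
    for i, reg in enumerate(tfs):
        for j, tgt in enumerate(tfs):
            if i == j or rng.random() >= cfg.edge_density:
                continue
            sign = -1 if rng.random() < cfg.frac_negative_edges else 1
            if rng.random() < cfg.frac_condition_specific:
                scope = SCOPE_AUTO if rng.random() < 0.5 else SCOPE_MONO
            else:
                scope = SCOPE_BOTH
            strength = rng.uniform(*cfg.strength_range)
            rows.append((reg, tgt, strength, sign, scope))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "strength", "sign", "scope"])
    return GroundTruthNet(tfs=tfs, edges=edges)


def make_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    for p in range(1, cfg.n_patients + 1):
        for cond in CONDITIONS:
            tag = "auto" if cond == AUTOLOGOUS else "mono"
            for day in cfg.days:
                for r in range(1, cfg.n_replicates + 1):
                    rows.append((f"p{p}_{tag}_d{day}_r{r}", f"p{p}", cond, day, r))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "patient", "condition", "day", "replicate"]))


def _coupling_matrices(net: GroundTruthNet, cfg: SimulationConfig) -> dict[str, np.ndarray]:
    """Signed weight matrix W[i, j] = effect of TF j on TF i, per condition."""
    idx = {tf: i for i, tf in enumerate(net.tfs)}
    out = {}
    for cond in CONDITIONS:
        scope = SCOPE_AUTO if cond == AUTOLOGOUS else SCOPE_MONO
        w = np.zeros((cfg.n_tfs, cfg.n_tfs))
        for row in net.edges.itertuples(index=False):
            if row.scope in (SCOPE_BOTH, scope):
                w[idx[row.target], idx[row.regulator]] = row.sign * row.strength
        out[cond] = w
    return out


def simulate_activities(
    net: GroundTruthNet, cfg: SimulationConfig
) -> tuple[pd.DataFrame, SampleDesign, dict]:
    """Integrate the activity ODE for every series and sample it at design days.

    Returns the observed TF × sample activity matrix, the matching
    design, and the dense trajectories keyed by
    (patient, condition, replicate) as (times, states) pairs.
    """
    if set(net.tfs) != set(cfg.tf_names) or len(net.tfs) != cfg.n_tfs:
        raise ValueError("network and config disagree on the TF universe")
    design = make_design(cfg)
    rng = rng_for(cfg.seed, "activities")
    n = cfg.n_tfs
    alpha = rng.uniform(cfg.decay_range[0], cfg.decay_range[1], size=n)
    b = rng.normal(0.0, cfg.basal_sd, size=n)
    u = {p: rng.normal(0.0, cfg.patient_effect_sd, size=n) for p in design.patients}
    v = {c: rng.normal(0.0, cfg.condition_effect_sd, size=n) for c in CONDITIONS}
    # the mid-culture environmental shift (e.g. nurse-like cells forming
    # around day 8) acts on a receptor-proximal subset of TFs, with a
    # response that differs between patients — mirroring the strong
    # inter-patient heterogeneity of the cultures it emulates
    input_mask = (rng.random(n) < cfg.frac_input_tfs).astype(float)
    e = {
        (c, p): rng.normal(0.0, cfg.event_effect_sd, size=n) * input_mask
        for c in CONDITIONS
        for p in design.patients
    }
    coupling = _coupling_matrices(net, cfg)

    days = np.asarray(cfg.days, dtype=float)
    t_grid = np.arange(days[0], days[-1] + cfg.euler_step / 2, cfg.euler_step)
    day_index = np.searchsorted(t_grid, days - 1e-9)

    observed = pd.DataFrame(0.0, index=net.tfs, columns=design.sample_ids)
    trajectories: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
    for patient in design.patients:
        for cond in CONDITIONS:
            shared_x0 = rng.normal(0.0, cfg.init_sd, size=n)
            for rep in range(1, cfg.n_replicates + 1):
                x0 = (
                    shared_x0
                    if cfg.share_replicate_initial
                    else rng.normal(0.0, cfg.init_sd, size=n)
                )
                drive = b + u[patient] + v[cond]
                w = coupling[cond]
                gate = 1.0 / (1.0 + np.exp(-(t_grid - cfg.event_time) / cfg.event_width))
                states = np.empty((len(t_grid), n))
                x = x0.astype(float).copy()
                states[0] = x
                event = e[(cond, patient)]
                for k in range(1, len(t_grid)):
                    dx = -alpha * x + w @ np.tanh(x) + drive + gate[k - 1] * event
                    x = x + cfg.euler_step * dx
                    if np.abs(x).max() > ACTIVITY_CAP:
                        raise FloatingPointError(
                            f"activity blow-up (|x| > {ACTIVITY_CAP}) in series "
                            f"({patient}, {cond}, rep {rep})"
                        )
                    states[k] = x
                trajectories[(patient, cond, rep)] = (t_grid.copy(), states)
                at_days = states[day_index]  # (n_days, n_tfs)
                noise = rng.normal(0.0, cfg.obs_noise_sd, size=at_days.shape)
                for d, day in enumerate(cfg.days):
                    (sid,) = design.samples_for(patient, cond, day, rep)
                    observed[sid] = at_days[d] + noise[d]
    return observed, design, trajectories


def sample_regulons(net: GroundTruthNet, cfg: SimulationConfig) -> tuple[Regulon, pd.DataFrame]:
    """Dedicated target genes per TF plus the target-level ground truth table."""
    if cfg.targets_per_tf < 1:
        raise ValueError("targets_per_tf must be at least 1")
    rng = rng_for(cfg.seed, "regulons")
    rows = []
    for tf in net.tfs:
        for k in range(1, cfg.targets_per_tf + 1):
            mode = -1 if rng.random() < cfg.frac_repressed_targets else 1
            rows.append((tf, f"{tf}_tgt{k:02d}", mode, 1.0))
    truth = pd.DataFrame(rows, columns=["tf", "target", "mode", "weight"])
    return Regulon(truth.copy()), truth


def expression_from_activities(
    activities: pd.DataFrame,
    design: SampleDesign,
    regulon_truth: pd.DataFrame,
    cfg: SimulationConfig,
) -> ExpressionMatrix:
    """Negative-binomial counts whose means follow the TF activities.

    Target gene g of TF j with mode m has mean
    ``softplus(β0_g + m·λ·x_{js}) · libsize_s``; background genes use
    activity-independent softplus means. λ is ``cfg.activity_scale``.
    """
    if not np.isfinite(activities.to_numpy()).all():
        raise ValueError("non-finite activity values")
    rng = rng_for(cfg.seed, "expression")
    samples = design.sample_ids
    genes = list(regulon_truth["target"]) + [
        f"bg{i + 1:03d}" for i in range(cfg.n_background_genes)
    ]
    beta0 = rng.normal(cfg.beta0_mean, cfg.beta0_sd, size=len(genes))
    libsize = rng.uniform(*cfg.library_size_range, size=len(samples))

    eta = np.tile(beta0[:, None], (1, len(samples)))
    act = activities.loc[:, samples].to_numpy()
    tf_index = {tf: i for i, tf in enumerate(activities.index)}
    for g, (tf, mode) in enumerate(zip(regulon_truth["tf"], regulon_truth["mode"])):
        eta[g] = beta0[g] + mode * cfg.activity_scale * act[tf_index[tf]]
    mu = np.logaddexp(0.0, eta) * libsize[None, :]  # softplus, numerically stable

    if cfg.nb_dispersion > 0:
        size = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    return ExpressionMatrix(df, layer="counts")


def simulate_dataset(cfg: SimulationConfig):
    """One call producing every artefact of a synthetic study.

    Returns (ground-truth net, design, true activity matrix, regulon,
    regulon truth table, counts).
    """
    net = sample_ground_truth(cfg)
    activities, design, _ = simulate_activities(net, cfg)
    regulon, truth = sample_regulons(net, cfg)
    counts = expression_from_activities(activities, design, truth, cfg)
    return net, design, activities, regulon, truth, counts
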