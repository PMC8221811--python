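"""Synthetic cohort generator.

Emulates the data structure of an accelerated-longitudinal decision-making
study: a 32-measure battery whose covariance carries one cross-task common
factor ("decision acuity") plus three task-specific factors and high
uniqueness; age / IQ / retention structure over five 2-year age bins spanning
14-24 years; round-by-round investor-trustee exchanges; and modular
resting-state connectivity matrices with a sparse linear edge signal for the
phenotypes plus site / motion / brain-volume confounds.

Everything is generated from a single seeded RNG per call, and the latent
scores and planted parameters are returned in a :class:`GroundTruth` sidecar
so recovery tests can compare estimates against the quantities that actually
generated the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import edge_index, rng_from, unvectorize_edges
from .trust import TrustExchange

# ---------------------------------------------------------------------------
# The 32-measure battery. Names follow the task (prefix) and the parameter
# each measure summarizes. Task letters: gng = Go-NoGo, econ = economic
# preferences, aac = approach-avoidance conflict, twostep = two-step,
# ig = information gathering, trust = investor-trustee, disc = interpersonal
# discounting.
# ---------------------------------------------------------------------------

MEASURES: tuple[str, ...] = (
    "gng_pavlovian_bias",
    "gng_rt_threat",
    "gng_rt_opportunity",
    "gng_outcome_sensitivity",
    "gng_go_bias",
    "gng_decision_noise",
    "gng_lr_appetitive",
    "gng_lr_aversive",
    "econ_gambling_pref",
    "econ_risk_pref",
    "econ_skew_pref",
    "econ_ev_sensitivity",
    "aac_threat_sensitivity",
    "aac_loss_sensitivity",
    "aac_performance",
    "twostep_model_based",
    "twostep_learning_rate",
    "twostep_perseveration",
    "twostep_reward_sensitivity",
    "twostep_eligibility_trace",
    "ig_sampling_noise",
    "ig_subjective_cost",
    "ig_costed_noise",
    "ig_costed_cost",
    "trust_initial",
    "trust_cooperativeness",
    "trust_responsiveness",
    "disc_hyperbolic_k",
    "disc_social_influence",
    "disc_taste_uncertainty",
    "disc_other_variability",
    "disc_decision_noise",
)

MEASURE_TASK: dict[str, str] = {m: m.split("_")[0] for m in MEASURES}

#: Tasks assessed at both waves (the economic-preferences task ran at
#: baseline only, so longitudinal scoring restricts weights to these six).
LONGITUDINAL_TASKS: tuple[str, ...] = ("gng", "aac", "twostep", "ig", "trust", "disc")

#: Measures whose marginals are exponentiated after the linear factor model,
#: so the gaussianization step downstream has real work to do. Reaction
#: times, decision-noise parameters and discounting constants are the
#: classically log-normal ones.
SKEWED_MEASURES: tuple[str, ...] = (
    "gng_rt_threat",
    "gng_decision_noise",
    "econ_risk_pref",
    "twostep_learning_rate",
    "ig_sampling_noise",
    "disc_hyperbolic_k",
    "disc_decision_noise",
)

# Signed, sparse common-factor loading pattern: decision-noise-like
# parameters load negatively, learning rates / outcome sensitivities /
# initial trust load positively, and most measures load weakly so uniqueness
# stays high across the battery. Within each task that also carries a
# specific factor, the common loadings are chosen orthogonal to the specific
# loading vector, so the common factor and the single-task factors are
# geometrically separated (as distinct constructs should be).
DEFAULT_COMMON_LOADINGS: np.ndarray = np.array([
    -0.36, -0.30, -0.34, 0.58, 0.12, -0.60, 0.42, 0.36,      # gng
    0.04, -0.24, -0.11, 0.43,                                  # econ
    -0.22, 0.12, 0.29,                                         # aac
    0.42, 0.38, -0.12, 0.55, 0.10,                             # twostep
    -0.24, 0.18, -0.18, 0.19,                                  # ig
    0.42, 0.36, 0.14,                                          # trust
    -0.12, 0.34, 0.08, -0.08, -0.25,                           # disc
])

#: Three task-specific factors (the single-task factors that accompany the
#: common factor): discounting, information gathering, economic preferences.
DEFAULT_SPECIFIC_STRUCTURE: dict[str, dict[int, float]] = {
    "economic": {8: 0.55, 9: 0.60, 10: 0.50, 11: 0.40},
    "info_gathering": {20: 0.50, 21: 0.60, 22: 0.50, 23: 0.55},
    "discounting": {27: 0.55, 28: 0.50, 29: 0.55, 30: 0.45, 31: 0.40},
}

WINNINGS_TASKS: tuple[str, ...] = ("gng", "ig", "trust", "twostep")


@dataclass
class CohortSpec:
    """Study conditions for the behavioral cohort.

    Defaults mirror the study design: 830 participants in five 2-year age
    bins from 14 to 24, balanced sex, ~70% retention with a follow-up
    about 18 months later, a standardized age slope of 0.24 on the latent
    common factor, and IQ-subscore slopes giving the composite a moderate
    relation to decision acuity.
    """

    n_subjects: int = 830
    age_range: tuple[float, float] = (14.0, 24.0)
    n_age_bins: int = 5
    sex_ratio: float = 0.5
    common_loadings: Optional[np.ndarray] = None
    specific_structure: Optional[dict[str, dict[int, float]]] = None
    uniqueness: Optional[np.ndarray] = None
    beta_age: float = 0.24
    iq_betas: tuple[float, float] = (0.20, 0.35)  # (matrix, vocabulary), z-scale
    iq_subscore_corr: float = 0.45
    retention: float = 0.70
    retest_r: float = 0.75
    followup_interval_months: float = 18.0
    followup_jitter_months: float = 6.0
    missing_rate: float = 0.02
    n_sites: int = 3
    seed: int = 0

    def resolve(self):
        """Validate and return (loadings, specific loading matrix, uniqueness)."""
        lam_c = np.asarray(
            DEFAULT_COMMON_LOADINGS if self.common_loadings is None else self.common_loadings,
            dtype=float,
        )
        if lam_c.shape != (32,) or not np.all(np.isfinite(lam_c)):
            raise ValueError("common_loadings must be a finite vector of length 32")
        structure = (
            DEFAULT_SPECIFIC_STRUCTURE if self.specific_structure is None else self.specific_structure
        )
        lam_s = np.zeros((32, len(structure)))
        for f, (name, members) in enumerate(structure.items()):
            for idx, loading in members.items():
                if not 0 <= idx < 32:
                    raise ValueError(f"specific factor {name}: measure index {idx} out of range")
                lam_s[idx, f] = loading
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.uniqueness is not None:
            uniq = np.asarray(self.uniqueness, float)
            if uniq.shape != (32,) or np.any(uniq < 0):
                raise ValueError("uniqueness must be a nonnegative vector of length 32")
        else:
            resid_var = 1.0 - lam_c**2 - (lam_s**2).sum(axis=1)
            if np.any(resid_var < 0):
                raise ValueError("planted loadings imply negative residual variance")
            uniq = np.sqrt(resid_var)
        return lam_c, lam_s, uniq


@dataclass
class ConnectivitySpec:
    """Study conditions for the synthetic connectivity stage.

    Defaults: 168 nodes in 14 equal modules (within-module edges stronger
    than between), subject-level edge noise, and a sparse linear edge signal
    for each phenotype calibrated so that the planted edges jointly carry a
    total R^2 of about 0.3 on the target. Confounds are additive: three site
    offsets plus linear head-motion and brain-volume effects on all edges.
    """

    n_nodes: int = 168
    n_modules: int = 14
    within_block_mean: float = 0.25
    between_block_mean: float = 0.02
    subject_noise_sd: float = 0.25
    n_signal_edges_d: int = 20
    n_signal_edges_iq: int = 20
    signal_edges_d: Optional[np.ndarray] = None
    signal_edges_iq: Optional[np.ndarray] = None
    effect_d: Optional[float] = None
    effect_iq: Optional[float] = None
    target_r2_d: float = 0.30
    target_r2_iq: float = 0.30
    signal_module_d: int = 3
    signal_module_iq: int = 5
    site_offsets: tuple[float, ...] = (0.0, 0.01, -0.01)
    fd_slope: float = 0.03
    volume_slope: float = 0.015
    fd_mean: float = 0.16
    fd_sd: float = 0.08
    seed: int = 0

    def validate(self):
        if self.n_modules > self.n_nodes:
            raise ValueError("n_modules cannot exceed n_nodes")
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        for name in ("signal_edges_d", "signal_edges_iq"):
            edges = getattr(self, name)
            if edges is not None:
                edges = np.asarray(edges, int)
                if edges.size and (edges.min() < 0 or edges.max() >= n_edges):
                    raise ValueError(f"{name} outside valid edge index range [0, {n_edges})")


@dataclass
class GroundTruth:
    """Oracle-only record of the latent quantities that generated the data."""

    latent: pd.DataFrame  # subject, wave, age, sex, site, d, iq_matrix_z, iq_vocab_z, iq_comp
    planted_loadings: np.ndarray
    planted_specific: np.ndarray
    planted_uniqueness: np.ndarray
    planted_partition: Optional[np.ndarray] = None
    planted_edges_d: Optional[np.ndarray] = None
    planted_edges_iq: Optional[np.ndarray] = None
    effect_d: Optional[float] = None
    effect_iq: Optional[float] = None


# ---------------------------------------------------------------------------
# Measure table
# ---------------------------------------------------------------------------


def _latent_d(spec: CohortSpec, z_age, z_m, z_v, stable, occasion):
    b_m, b_v = spec.iq_betas
    var_iq = b_m**2 + b_v**2 + 2 * b_m * b_v * spec.iq_subscore_corr
    s2 = 1.0 - spec.beta_age**2 - var_iq
    if s2 <= 0:
        raise ValueError("beta_age and iq_betas leave no residual variance for latent d")
    # Split residual variance so the latent baseline/follow-up correlation
    # hits retest_r: stable share rho, occasion share 1 - rho.
    shared = spec.beta_age**2 + var_iq  # age barely changes between waves
    rho = (spec.retest_r - shared) / s2
    if not 0 <= rho <= 1:
        raise ValueError(
            f"retest_r={spec.retest_r} unreachable given beta_age/iq_betas (implied rho={rho:.3f})"
        )
    resid = np.sqrt(rho) * stable + np.sqrt(1 - rho) * occasion
    return spec.beta_age * z_age + b_m * z_m + b_v * z_v + np.sqrt(s2) * resid


def _measures_from_latent(rng, d, lam_c, lam_s, uniq):
    n = d.shape[0]
    k_spec = lam_s.shape[1]
    f_spec = rng.standard_normal((n, k_spec))
    eps = rng.standard_normal((n, 32))
    x = np.outer(d, lam_c) + f_spec @ lam_s.T + eps * uniq
    cols = {}
    for j, name in enumerate(MEASURES):
        col = x[:, j]
        if name in SKEWED_MEASURES:
            col = np.exp(col)
        cols[name] = col
    return cols


def generate_measure_table(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate baseline + follow-up measure tables with known latent structure.

    Returns a single table with a ``wave`` column (1 = baseline, 2 =
    follow-up; follow-up covers ~``retention`` of the baseline subjects) and
    the :class:`GroundTruth` sidecar. Ages are uniform within equal-width
    bins; the follow-up visit happens ``followup_interval_months`` +/-
    jitter later. A fixed subset of measures is exponentiated so marginal
    skew is present, and cells go missing completely at random at
    ``missing_rate``.
    """
    lam_c, lam_s, uniq = spec.resolve()
    rng = rng_from(spec.seed)
    n = int(spec.n_subjects)
    if n < 2:
        raise ValueError("n_subjects must be at least 2")

    lo, hi = spec.age_range
    bin_edges = np.linspace(lo, hi, spec.n_age_bins + 1)
    bins = rng.integers(0, spec.n_age_bins, size=n)
    age = bin_edges[bins] + rng.uniform(0, 1, size=n) * (bin_edges[1] - bin_edges[0])
    age_mean, age_sd = age.mean(), age.std()

    sex = (rng.uniform(size=n) < spec.sex_ratio).astype(int)  # 1 = male
    site = rng.integers(0, spec.n_sites, size=n)

    # Latent IQ subscores (z-scale), correlated but independent of age so
    # the age slope on d has a single unambiguous value.
    g = rng.standard_normal(n)
    r = spec.iq_subscore_corr
    z_m = np.sqrt(r) * g + np.sqrt(1 - r) * rng.standard_normal(n)
    z_v = np.sqrt(r) * g + np.sqrt(1 - r) * rng.standard_normal(n)

    stable = rng.standard_normal(n)
    z_age_b = (age - age_mean) / age_sd
    d_base = _latent_d(spec, z_age_b, z_m, z_v, stable, rng.standard_normal(n))

    # Follow-up: retained subjects, ~18 months later.
    keep = rng.uniform(size=n) < spec.retention
    interval = (
        spec.followup_interval_months
        + rng.uniform(-spec.followup_jitter_months, spec.followup_jitter_months, size=n)
    ) / 12.0
    age_f = age + interval
    z_age_f = (age_f - age_mean) / age_sd  # baseline standardization throughout
    d_fu_all = _latent_d(spec, z_age_f, z_m, z_v, stable, rng.standard_normal(n))

    def build_wave(wave, idx, d, ages):
        cols = _measures_from_latent(rng, d[idx], lam_c, lam_s, uniq[None, :].ravel())
        df = pd.DataFrame({
            "subject": idx,
            "wave": wave,
            "age": ages[idx],
            "sex": sex[idx],
            "site": site[idx],
            "iq_vocab_raw": 40.0 + 10.0 * z_v[idx],
            "iq_matrix_raw": 25.0 + 6.0 * z_m[idx],
            "parental_education": np.round(
                np.clip(2.5 + 0.8 * rng.standard_normal(idx.size), 0, 5)
            ),
            "sociality": 0.30 * d[idx] + np.sqrt(1 - 0.30**2) * rng.standard_normal(idx.size),
            "aberrant_thinking": -0.15 * d[idx]
            + np.sqrt(1 - 0.15**2) * rng.standard_normal(idx.size),
        })
        for task in WINNINGS_TASKS:
            df[f"winnings_{task}"] = 100.0 + 20.0 * (
                0.5 * d[idx] + np.sqrt(0.75) * rng.standard_normal(idx.size)
            )
        for name, vals in cols.items():
            df[name] = vals
        return df

    all_idx = np.arange(n)
    base = build_wave(1, all_idx, d_base, age)
    fu = build_wave(2, all_idx[keep], d_fu_all, age_f)
    table = pd.concat([base, fu], ignore_index=True)

    if spec.missing_rate > 0:
        mask = rng.uniform(size=(len(table), 32)) < spec.missing_rate
        vals = table.loc[:, list(MEASURES)].to_numpy()
        vals[mask] = np.nan
        table.loc[:, list(MEASURES)] = vals

    b_m, b_v = spec.iq_betas
    denom = np.sqrt(b_m**2 + b_v**2 + 2 * b_m * b_v * r)
    iq_comp = (z_m + z_v) / np.sqrt(2 + 2 * r)
    latent = pd.DataFrame({
        "subject": np.concatenate([all_idx, all_idx[keep]]),
        "wave": np.concatenate([np.ones(n, int), np.full(keep.sum(), 2, int)]),
        "age": np.concatenate([age, age_f[keep]]),
        "sex": np.concatenate([sex, sex[keep]]),
        "site": np.concatenate([site, site[keep]]),
        "d": np.concatenate([d_base, d_fu_all[keep]]),
        "iq_matrix_z": np.concatenate([z_m, z_m[keep]]),
        "iq_vocab_z": np.concatenate([z_v, z_v[keep]]),
        "iq_comp": np.concatenate([iq_comp, iq_comp[keep]]),
    })
    truth = GroundTruth(
        latent=latent,
        planted_loadings=lam_c.copy(),
        planted_specific=lam_s.copy(),
        planted_uniqueness=uniq.copy(),
    )
    return table, truth


def measure_columns(table: pd.DataFrame) -> list[str]:
    return [m for m in MEASURES if m in table.columns]


def implied_d_iq_correlation(spec: CohortSpec) -> float:
    """Population corr(latent d, IQ composite) implied by the spec's slopes."""
    b_m, b_v = spec.iq_betas
    r = spec.iq_subscore_corr
    # cov(d, z_m + z_v) = b_m(1 + r) + b_v(1 + r); var(z_m + z_v) = 2 + 2r
    return float((b_m + b_v) * (1 + r) / np.sqrt(2 + 2 * r))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def _block_partition(n_nodes: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module labels 1..n_modules."""
    sizes = np.full(n_modules, n_nodes // n_modules)
    sizes[: n_nodes % n_modules] += 1
    return np.repeat(np.arange(1, n_modules + 1), sizes)


def _module_edge_pool(partition, modules: Sequence[int]) -> np.ndarray:
    """Edge indices internal to the union of the given modules."""
    i, j = edge_index(partition.size)
    in_set = np.isin(partition, modules)
    return np.flatnonzero(in_set[i] & in_set[j])


def generate_connectivity(
    spec: ConnectivitySpec,
    truth: GroundTruth,
    wave: int = 1,
    subjects: Optional[np.ndarray] = None,
):
    """Per-subject symmetric connectivity with planted sparse edge signal.

    Each subject's matrix is the modular block template plus symmetric
    subject noise, plus ``effect * z(score)`` on the planted edge sets for
    decision acuity and IQ, plus additive site / head-motion / brain-volume
    confounds on all edges. Returns a
    :class:`~dacuity.network.ConnectivityDataset`; the planted partition and
    edge sets are recorded on ``truth``.
    """
    from .network import ConnectivityDataset  # deferred: network imports nothing from here

    spec.validate()
    # planted structure (edge sets) is a property of the spec and must be
    # identical across waves; subject-level noise is wave-specific
    rng = rng_from(spec.seed)
    rng_wave = np.random.default_rng([int(spec.seed), int(wave)])
    lat = truth.latent
    rows = lat[lat["wave"] == wave]
    if rows.empty:
        raise ValueError(f"ground truth has no latent scores for wave {wave}")
    if subjects is not None:
        rows = rows[rows["subject"].isin(np.asarray(subjects))]
        if rows.empty:
            raise ValueError(f"none of the requested subjects have wave-{wave} latent scores")

    n_sub = len(rows)
    n_nodes = spec.n_nodes
    partition = _block_partition(n_nodes, spec.n_modules)
    i, j = edge_index(n_nodes)
    n_edges = i.size

    within = partition[i] == partition[j]
    template = np.where(within, spec.within_block_mean, spec.between_block_mean)

    def pick_edges(preset, n_pick, modules, effect):
        if preset is not None:
            return np.asarray(preset, int)
        if effect == 0.0 or n_pick == 0:
            return np.empty(0, int)  # explicit null: no signal set needed
        pool = _module_edge_pool(partition, modules)
        if pool.size < n_pick:
            raise ValueError("not enough intra-module edges for the requested signal set")
        return np.sort(rng.choice(pool, size=n_pick, replace=False))

    # Phenotype signal lives inside a pair of adjacent modules, so modules
    # sharing no planted edges stay clean for lesion-specificity checks.
    m_d = min(spec.signal_module_d, spec.n_modules - 1)
    m_iq = min(spec.signal_module_iq, spec.n_modules - 1)
    edges_d = pick_edges(spec.signal_edges_d, spec.n_signal_edges_d, [m_d, m_d + 1], spec.effect_d)
    edges_iq = pick_edges(
        spec.signal_edges_iq, spec.n_signal_edges_iq, [m_iq, m_iq + 1], spec.effect_iq
    )

    # Confound contributions are common to all edges and cannot be averaged
    # away within the planted set, so they enter the calibration of the
    # per-edge slope: the planted edges jointly predict the phenotype with
    # R^2 = e^2 / (e^2 + var_confound + noise^2 / n_edges) = target_r2.
    offs = np.asarray(spec.site_offsets, float)
    var_conf = float(offs.var() + spec.fd_slope**2 + spec.volume_slope**2)

    def resolve_effect(effect, n_sig, target_r2):
        if effect is not None:
            return float(effect)
        if n_sig == 0:
            return 0.0
        return float(
            np.sqrt(
                target_r2 / (1 - target_r2)
                * (var_conf + spec.subject_noise_sd**2 / n_sig)
            )
        )

    eff_d = resolve_effect(spec.effect_d, edges_d.size, spec.target_r2_d)
    eff_iq = resolve_effect(spec.effect_iq, edges_iq.size, spec.target_r2_iq)

    def z(v):
        v = np.asarray(v, float)
        return (v - v.mean()) / v.std() if v.std() > 0 else np.zeros_like(v)

    zd = z(rows["d"].to_numpy())
    ziq = z(rows["iq_comp"].to_numpy())

    site = rows["site"].to_numpy()
    fd = np.clip(rng_wave.normal(spec.fd_mean, spec.fd_sd, size=n_sub), 0.01, None)
    volume = rng_wave.normal(1200.0, 100.0, size=n_sub)
    dof = np.clip(rng_wave.normal(60.0, 5.0, size=n_sub), 30, None)

    feats = np.tile(template, (n_sub, 1))
    feats += spec.subject_noise_sd * rng_wave.standard_normal((n_sub, n_edges))
    if edges_d.size:
        feats[:, edges_d] += eff_d * zd[:, None]
    if edges_iq.size:
        feats[:, edges_iq] += eff_iq * ziq[:, None]
    offsets = np.asarray(spec.site_offsets, float)[site % len(spec.site_offsets)]
    feats += offsets[:, None]
    feats += spec.fd_slope * ((fd - fd.mean()) / fd.std())[:, None]
    feats += spec.volume_slope * ((volume - volume.mean()) / volume.std())[:, None]

    matrices = unvectorize_edges(feats, n_nodes)
    covariates = pd.DataFrame({
        "subject": rows["subject"].to_numpy(),
        "age": rows["age"].to_numpy(),
        "sex": rows["sex"].to_numpy(),
        "site": site,
        "fd": fd,
        "dof": dof,
        "volume": volume,
    })
    truth.planted_partition = partition
    truth.planted_edges_d = edges_d
    truth.planted_edges_iq = edges_iq
    truth.effect_d = eff_d
    truth.effect_iq = eff_iq
    return ConnectivityDataset(
        subjects=rows["subject"].to_numpy().copy(),
        matrices=matrices,
        covariates=covariates,
        wave=wave,
    )


# ---------------------------------------------------------------------------
# Trust-game exchanges
# ---------------------------------------------------------------------------


def generate_trust_exchanges(
    policy_params: dict,
    n_rounds: int = 10,
    seed=0,
    n_subjects: int = 1,
    endowment: float = 20.0,
    multiplier: float = 3.0,
) -> list[TrustExchange]:
    """Simulate multi-round investor-trustee exchanges under a named policy.

    Policies:
      - ``coaxing``: the investor escalates their contribution while the
        trustee returns a near-constant fraction -> fractional-change
        vectors point along the positive investor axis (orientation ~ 0 deg).
      - ``mutual_reduction``: both parties reduce their fractional
        contribution in lockstep -> orientation ~ -135 deg.
      - ``random``: uninformative play covering all quadrant classes.
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2 (round-to-round changes undefined)")
    if endowment <= 0 or multiplier <= 0:
        raise ValueError("endowment and return multiplier must be positive")
    rng = rng_from(seed)
    policy = policy_params.get("policy", "random")
    noise = float(policy_params.get("noise", 0.02))

    exchanges = []
    for _ in range(n_subjects):
        inv = np.empty(n_rounds)
        frac_ret = np.empty(n_rounds)
        if policy == "coaxing":
            inv[0] = policy_params.get("initial", 0.40) * endowment
            step = policy_params.get("step", 0.06)
            for t in range(1, n_rounds):
                inv[t] = inv[t - 1] + (step + noise * rng.standard_normal()) * endowment
            frac_ret[:] = policy_params.get("return_fraction", 0.35) + noise * rng.standard_normal(
                n_rounds
            )
        elif policy == "mutual_reduction":
            inv[0] = policy_params.get("initial", 0.80) * endowment
            step = policy_params.get("step", 0.07)
            frac0 = policy_params.get("return_fraction", 0.55)
            for t in range(1, n_rounds):
                inv[t] = inv[t - 1] - (step + noise * rng.standard_normal()) * endowment
            frac_ret[:] = frac0 - step * np.arange(n_rounds) + noise * rng.standard_normal(n_rounds)
        elif policy == "random":
            inv[:] = rng.uniform(0.05, 1.0, n_rounds) * endowment
            frac_ret[:] = rng.uniform(0.0, 1.0, n_rounds)
        else:
            raise ValueError(f"unknown trust policy {policy!r}")

        inv = np.clip(inv, 0.0, endowment)
        returns = np.clip(frac_ret, 0.0, 1.0) * multiplier * inv
        exchanges.append(
            TrustExchange(
                endowment=np.full(n_rounds, endowment),
                investor=inv,
                trustee=returns,
                multiplier=multiplier,
            )
        )
    return exchanges


# ---------------------------------------------------------------------------
# Writers (delimited text only)
# ---------------------------------------------------------------------------


def write_measure_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, directory) -> None:
    """Oracle-only sidecar: never an input to the analysis pipeline."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.latent.to_csv(directory / "ground_truth_latent.tsv", sep="\t", index=False)
    meta = {
        "planted_loadings": truth.planted_loadings.tolist(),
        "planted_specific": truth.planted_specific.tolist(),
        "planted_uniqueness": truth.planted_uniqueness.tolist(),
        "planted_partition": None
        if truth.planted_partition is None
        else truth.planted_partition.tolist(),
        "planted_edges_d": None if truth.planted_edges_d is None else truth.planted_edges_d.tolist(),
        "planted_edges_iq": None
        if truth.planted_edges_iq is None
        else truth.planted_edges_iq.tolist(),
        "effect_d": truth.effect_d,
        "effect_iq": truth.effect_iq,
        "note": "oracle-only ground truth; not a pipeline input",
    }
    (directory / "ground_truth_meta.json").write_text(json.dumps(meta, indent=2))
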