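"""Synthetic cohort generator.

Draws cohorts with the statistical structure the downstream analysis
assumes: per-group multivariate-normal regional volumes (group means/SDs
on the mm^3 scale with a shared inter-ROI correlation, optionally scaled
per group), demographic covariates, per-trial navigation distance
errors, raw cognitive test scores with within-domain correlation, and
Bernoulli conversion outcomes for the followed-up subgroup.

Default parameters are calibrated to the observed four-group cohort
(normal controls, SCD with good/bad navigation, MCI; n = 77/40/40/23):
group volume means and SDs per region, standardized navigation error
means, covariate distributions, and conversion to MCI in 0/20 and 4/19
followed-up subjects.  No inter-ROI correlation is reported for the real
data, so the default is an assumed exchangeable structure: 0.4 among the
17 network nodes, 0.2 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nodes import (
    ALL_ROIS,
    BASAL_FOREBRAIN_SUBFIELDS,
    GROUPS,
    RIGHT_HIPPOCAMPAL_SUBFIELDS,
    SUBCORTICAL_NUCLEI,
)
from .clinical import DEFAULT_DOMAIN_MAP, EGO_TRIAL_COLUMNS, ALLO_TRIAL_COLUMNS

# ---------------------------------------------------------------------------
# default parameters: per-group ROI volume mean/SD in mm^3
# (NC, G-SCD, B-SCD, MCI)
# ---------------------------------------------------------------------------

DEFAULT_ROI_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "Basal forebrain": ((535.24, 40.62), (539.47, 51.05), (515.08, 42.47), (499.95, 36.37)),
    "L-Thalamus": ((5946.67, 563.92), (5955.59, 650.65), (5801.25, 580.15), (5567.23, 414.48)),
    "L-Caudate": ((3077.73, 354.22), (3176.93, 371.77), (3065.99, 417.08), (3084.21, 403.91)),
    "L-Putamen": ((4519.79, 448.30), (4493.13, 518.10), (4440.52, 554.15), (4398.10, 347.17)),
    "L-Pallidum": ((1862.60, 240.92), (1847.12, 219.02), (1807.77, 254.06), (1781.75, 262.65)),
    "L-Hippocampus": ((3577.23, 352.48), (3576.78, 424.65), (3484.67, 345.05), (3312.63, 293.79)),
    "L-Amygdala": ((1359.26, 221.99), (1281.10, 230.21), (1301.93, 220.96), (1232.48, 210.16)),
    "L-Accumbens": ((502.48, 87.68), (493.19, 82.03), (487.24, 77.49), (448.04, 91.01)),
    "R-Thalamus": ((5813.13, 576.93), (5757.73, 576.39), (5667.74, 572.91), (5498.96, 420.97)),
    "R-Caudate": ((3176.42, 349.43), (3277.09, 376.46), (3171.37, 415.60), (3226.93, 493.72)),
    "R-Putamen": ((4503.70, 501.74), (4494.81, 492.07), (4466.18, 546.24), (4406.74, 401.24)),
    "R-Pallidum": ((1757.02, 198.94), (1784.53, 213.82), (1754.38, 250.43), (1702.58, 246.80)),
    "R-Hippocampus": ((3678.94, 379.55), (3677.84, 450.97), (3575.85, 407.17), (3319.50, 345.14)),
    "R-Amygdala": ((1534.93, 278.04), (1484.69, 256.68), (1474.44, 231.41), (1358.29, 171.53)),
    "R-Accumbens": ((494.64, 81.59), (489.63, 83.88), (475.37, 66.99), (454.74, 78.25)),
    "Ch4p": ((85.80, 8.03), (86.40, 9.27), (81.96, 6.34), (79.78, 5.74)),
    "Ch4a-i": ((142.37, 10.17), (144.01, 13.01), (137.13, 11.32), (134.19, 10.03)),
    "Ch3": ((135.73, 10.25), (136.77, 13.27), (130.98, 11.29), (126.73, 9.47)),
    "NSP": ((104.60, 8.16), (104.93, 10.01), (101.44, 9.79), (98.22, 7.23)),
    "Ch1/2": ((66.74, 6.73), (67.36, 8.00), (63.56, 6.17), (61.03, 6.91)),
    "Tail": ((533.30, 68.27), (541.56, 73.41), (521.76, 77.54), (494.31, 68.98)),
    "Subiculum": ((405.03, 48.60), (407.07, 50.87), (398.36, 47.67), (368.83, 47.03)),
    "CA1": ((599.83, 77.12), (590.84, 78.50), (571.73, 69.33), (539.58, 59.69)),
    "Fissure": ((174.85, 34.63), (168.29, 29.36), (164.64, 30.02), (154.86, 24.73)),
    "Presubiculum": ((281.58, 29.56), (278.40, 33.66), (278.86, 30.81), (256.79, 38.83)),
    "Parasubiculum": ((52.84, 9.26), (51.21, 8.47), (52.46, 9.98), (49.38, 7.39)),
    "Molecular layer": ((528.53, 58.90), (525.75, 62.01), (512.38, 53.09), (474.96, 54.67)),
    "Dentate gyrus": ((270.86, 34.67), (264.55, 30.37), (260.47, 27.93), (242.87, 28.10)),
    "CA2/3": ((185.85, 30.40), (186.76, 28.44), (179.64, 25.24), (166.14, 25.92)),
    "CA4": ((229.72, 29.34), (224.50, 25.27), (222.68, 24.02), (207.10, 22.62)),
    "Fimbria": ((72.61, 17.86), (64.33, 13.40), (65.69, 15.80), (64.57, 18.49)),
    "HATA": ((55.43, 8.44), (54.19, 9.15), (53.15, 9.60), (48.61, 8.14)),
}

#: standardized navigation distance error (mean, SD) per group
DEFAULT_NAVIGATION_PARAMS: dict[str, tuple[float, float]] = {
    "NC": (-0.28, 0.65),
    "G-SCD": (-0.51, 0.27),
    "B-SCD": (0.80, 0.69),
    "MCI": (0.42, 1.03),
}

#: per-group covariate parameters
DEFAULT_COVARIATE_PARAMS: dict[str, dict] = {
    "age": {"NC": (65.36, 5.80), "G-SCD": (64.40, 5.49), "B-SCD": (65.18, 5.90), "MCI": (65.87, 5.80)},
    "education_years": {"NC": (12.86, 2.97), "G-SCD": (12.68, 2.64), "B-SCD": (11.79, 2.36), "MCI": (12.65, 3.61)},
    "tiv": {"NC": (0.05, 0.99), "G-SCD": (0.11, 0.90), "B-SCD": (-0.09, 1.07), "MCI": (-0.21, 1.10)},
    "iqr": {"NC": (84.50, 1.93), "G-SCD": (84.69, 1.79), "B-SCD": (84.59, 1.73), "MCI": (84.93, 1.46)},
    "male_fraction": {"NC": 14 / 77, "G-SCD": 7 / 40, "B-SCD": 7 / 40, "MCI": 4 / 23},
    "scanner_tx_fraction": {"NC": 30 / 77, "G-SCD": 13 / 40, "B-SCD": 17 / 40, "MCI": 9 / 23},
}

#: per-group (mean, SD) of the latent domain ability on the z scale
DEFAULT_DOMAIN_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "memory": {"NC": (0.29, 0.78), "G-SCD": (0.10, 0.71), "B-SCD": (-0.11, 0.78), "MCI": (-0.97, 0.73)},
    "language": {"NC": (0.21, 0.82), "G-SCD": (0.24, 0.63), "B-SCD": (-0.31, 0.79), "MCI": (-0.59, 0.70)},
    "executive": {"NC": (0.10, 0.60), "G-SCD": (0.28, 0.64), "B-SCD": (-0.15, 0.65), "MCI": (-0.56, 0.63)},
}

#: other questionnaire scores (mean, SD) per group, generated directly
DEFAULT_SCALE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "scd_q": {"NC": (3.90, 1.99), "G-SCD": (5.68, 1.29), "B-SCD": (5.81, 1.25), "MCI": (5.20, 2.07)},
    "mmse": {"NC": (28.73, 1.19), "G-SCD": (28.75, 1.28), "B-SCD": (28.43, 1.53), "MCI": (27.26, 3.55)},
}

#: raw scale (location, scale) of each cognitive test; the group effect
#: enters through the latent domain ability
DEFAULT_TEST_SCALES: dict[str, tuple[float, float]] = {
    "avlt_immediate": (20.0, 5.0),
    "avlt_short_delayed": (7.0, 2.5),
    "avlt_long_delayed": (6.5, 2.5),
    "avlt_cued": (7.0, 2.5),
    "avlt_recognition": (21.0, 2.5),
    "tmt_a": (60.0, 20.0),
    "tmt_b": (150.0, 50.0),
    "sdmt": (35.0, 10.0),
    "cdt": (24.0, 4.0),
    "aft": (16.0, 4.0),
    "bnt": (22.0, 4.0),
}

#: probability of conversion to MCI among followed-up subjects
DEFAULT_CONVERSION_PROBS: dict[str, float] = {
    "NC": 0.0,
    "G-SCD": 0.0,
    "B-SCD": 4 / 19,
    "MCI": 0.0,
}

#: fraction of each group with follow-up data (only SCD was re-assessed)
DEFAULT_FOLLOWUP_FRACTION: dict[str, float] = {
    "NC": 0.0,
    "G-SCD": 20 / 40,
    "B-SCD": 19 / 40,
    "MCI": 0.0,
}

#: follow-up interval in days (mean, SD), about 1.5 years
DEFAULT_FOLLOWUP_INTERVAL: tuple[float, float] = (537.0, 166.0)

NETWORK_NODES = BASAL_FOREBRAIN_SUBFIELDS + RIGHT_HIPPOCAMPAL_SUBFIELDS


def default_base_correlation(
    rois: tuple[str, ...] = ALL_ROIS,
    network_nodes: tuple[str, ...] = NETWORK_NODES,
    rho_nodes: float = 0.4,
    rho_background: float = 0.2,
) -> pd.DataFrame:
    """Exchangeable inter-ROI correlation: ``rho_nodes`` among the network
    nodes, ``rho_background`` for every other pair."""
    p = len(rois)
    C = np.full((p, p), rho_background)
    idx = [i for i, r in enumerate(rois) if r in set(network_nodes)]
    C[np.ix_(idx, idx)] = rho_nodes
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=list(rois), columns=list(rois))


def modular_base_correlation(
    nodes: tuple[str, ...] = NETWORK_NODES,
    block_sizes: tuple[int, ...] = (len(BASAL_FOREBRAIN_SUBFIELDS), len(RIGHT_HIPPOCAMPAL_SUBFIELDS)),
    rho_within: float = 0.65,
    rho_between: float = 0.08,
) -> pd.DataFrame:
    """Block (modular) node correlation: stronger within anatomical
    modules (basal forebrain; hippocampus) than between them.

    Defaults give a mean off-diagonal correlation of ~0.40, so scaling
    the off-diagonals by 1.5 / 0.5 yields group mean correlation levels
    of ~0.6 / ~0.2 while preserving the modular structure that makes
    network topology — including path length — respond to covariance
    strength (a sharp within/between contrast keeps the binarized
    topology stable across subject relabelings, which is what lets
    metric differences stand out of the permutation null).
    """
    if sum(block_sizes) != len(nodes):
        raise ValueError("block sizes must sum to the node count")
    p = len(nodes)
    C = np.full((p, p), rho_between)
    start = 0
    for size in block_sizes:
        C[start : start + size, start : start + size] = rho_within
        start += size
    np.fill_diagonal(C, 1.0)
    if float(np.linalg.eigvalsh(C).min()) < -1e-10:
        raise ValueError("modular base correlation is not positive semidefinite")
    return pd.DataFrame(C, index=list(nodes), columns=list(nodes))


def scale_offdiagonal(correlation: np.ndarray, factor: float) -> np.ndarray:
    """Multiply off-diagonal correlations by ``factor`` (clipped to
    (-1, 1)); raises if the result is not positive semidefinite."""
    C = np.asarray(correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation must be square")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("correlation must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-12):
        raise ValueError("correlation must have a unit diagonal")
    if factor < 0:
        raise ValueError("factor must be positive")
    out = np.clip(C * factor, -1.0 + 1e-12, 1.0 - 1e-12)
    np.fill_diagonal(out, 1.0)
    lam_min = float(np.linalg.eigvalsh(out).min())
    if lam_min < -1e-10:
        raise ValueError(
            f"scaled correlation is not positive semidefinite "
            f"(smallest eigenvalue {lam_min:.3g} with factor {factor})"
        )
    return out


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Everything defaults to the study conditions; ``roi_params`` maps each
    region to per-group (mean mm^3, SD mm^3); ``base_correlation`` is the
    shared inter-ROI correlation, scaled per group by
    ``covariance_strength`` (off-diagonals multiplied, then checked for
    positive semidefiniteness).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 77, "G-SCD": 40, "B-SCD": 40, "MCI": 23}
    )
    roi_params: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_PARAMS)
    )
    base_correlation: pd.DataFrame | None = None
    covariance_strength: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GROUPS}
    )
    navigation_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NAVIGATION_PARAMS)
    )
    #: SD of per-trial noise around the subject's latent navigation error
    trial_noise_sd: float = 0.3
    covariate_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PARAMS.items()}
    )
    domain_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DOMAIN_PARAMS.items()}
    )
    scale_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SCALE_PARAMS.items()}
    )
    test_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TEST_SCALES)
    )
    #: SD of test-specific noise around the latent domain ability (z scale)
    test_noise_sd: float = 0.5
    conversion_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONVERSION_PROBS)
    )
    followup_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLLOWUP_FRACTION)
    )
    followup_interval: tuple[float, float] = DEFAULT_FOLLOWUP_INTERVAL
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects, got {n}")
        for roi, per_group in self.roi_params.items():
            if len(per_group) != len(self.group_sizes):
                raise ValueError(
                    f"roi {roi!r} has {len(per_group)} (mean, sd) pairs for "
                    f"{len(self.group_sizes)} groups"
                )
            for mean, sd in per_group:
                if sd <= 0:
                    raise ValueError(f"roi {roi!r} has non-positive SD {sd}")
        for g, pr in self.conversion_probs.items():
            if not 0 <= pr <= 1:
                raise ValueError(f"conversion probability for {g!r} outside [0, 1]")
        if self.base_correlation is None:
            self.base_correlation = default_base_correlation(tuple(self.roi_params))
        C = self.base_correlation.to_numpy(dtype=float)
        if not np.allclose(C, C.T, atol=1e-12) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("base_correlation must be symmetric with unit diagonal")
        if float(np.linalg.eigvalsh(C).min()) < -1e-10:
            raise ValueError("base_correlation is not positive semidefinite")

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.roi_params)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.group_sizes)


MAX_RESAMPLE_ATTEMPTS = 100


def _draw_volumes(
    rng: np.random.Generator, spec: CohortSpec, group: str, gi: int, n: int
) -> np.ndarray:
    """Multivariate-normal volumes for one group, resampling rows with a
    non-positive volume (capped at MAX_RESAMPLE_ATTEMPTS per subject)."""
    rois = spec.rois
    means = np.array([spec.roi_params[r][gi][0] for r in rois])
    sds = np.array([spec.roi_params[r][gi][1] for r in rois])
    base = spec.base_correlation.loc[list(rois), list(rois)].to_numpy(dtype=float)
    try:
        corr = scale_offdiagonal(base, spec.covariance_strength.get(group, 1.0))
    except ValueError as err:
        raise ValueError(f"group {group!r}: {err}") from err
    cov = corr * np.outer(sds, sds)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(rois)))
    X = means + rng.standard_normal((n, len(rois))) @ L.T
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        bad = np.flatnonzero((X <= 0).any(axis=1))
        if bad.size == 0:
            return X
        X[bad] = means + rng.standard_normal((bad.size, len(rois))) @ L.T
    raise RuntimeError(
        f"group {group!r}: could not draw positive volumes for "
        f"{bad.size} subject(s) after {MAX_RESAMPLE_ATTEMPTS} attempts"
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a subject-per-row table.

    Fully reproducible: identical spec and seed give an identical table.
    ``seed`` overrides ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    sid = 0
    for gi, (group, n) in enumerate(spec.group_sizes.items()):
        rec: dict[str, np.ndarray | list] = {}
        rec["subject_id"] = [f"S{sid + i + 1:04d}" for i in range(n)]
        sid += n
        rec["group"] = [group] * n

        cov = spec.covariate_params
        for name in ("age", "education_years", "tiv", "iqr"):
            m, s = cov[name][group]
            rec[name] = rng.normal(m, s, size=n)
        rec["sex"] = np.where(
            rng.random(n) < cov["male_fraction"][group], "M", "F"
        )
        rec["scanner"] = np.where(
            rng.random(n) < cov["scanner_tx_fraction"][group], "TX", "CX"
        )

        for name, per_group in spec.scale_params.items():
            m, s = per_group[group]
            rec[name] = rng.normal(m, s, size=n)

        # latent domain abilities drive the raw test scores
        ability = {
            d: rng.normal(*spec.domain_params[d][group], size=n)
            for d in spec.domain_params
        }
        for test, (domain, higher_better) in DEFAULT_DOMAIN_MAP.items():
            loc, scale = spec.test_scales[test]
            z = ability[domain] + rng.normal(0.0, spec.test_noise_sd, size=n)
            rec[test] = loc + scale * (z if higher_better else -z)

        # navigation: subject-level latent error plus per-trial noise
        nav_m, nav_s = spec.navigation_params[group]
        latent = rng.normal(nav_m, nav_s, size=n)
        for col in EGO_TRIAL_COLUMNS + ALLO_TRIAL_COLUMNS:
            rec[col] = latent + rng.normal(0.0, spec.trial_noise_sd, size=n)

        X = _draw_volumes(rng, spec, group, gi, n)
        for j, roi in enumerate(spec.rois):
            rec[roi] = X[:, j]

        # follow-up: a fixed-size random subset of the group
        n_fu = int(round(spec.followup_fraction.get(group, 0.0) * n))
        fu_idx = rng.choice(n, size=n_fu, replace=False) if n_fu else np.empty(0, int)
        outcome = np.array(["missing"] * n, dtype=object)
        days = np.full(n, np.nan)
        if n_fu:
            p_conv = spec.conversion_probs.get(group, 0.0)
            conv = rng.random(n_fu) < p_conv
            outcome[fu_idx] = np.where(conv, "converter", "nonconverter")
            mu_d, sd_d = spec.followup_interval
            days[fu_idx] = np.maximum(np.round(rng.normal(mu_d, sd_d, size=n_fu)), 30.0)
        rec["followup_outcome"] = outcome
        rec["followup_days"] = days

        frames.append(pd.DataFrame(rec))
    return pd.concat(frames, ignore_index=True)


def null_spec(**overrides) -> CohortSpec:
    """A cohort spec in which the four group labels are exchangeable:
    every group shares the NC volume/covariate/score parameters."""
    roi_params = {
        roi: (per_group[0],) * len(GROUPS) for roi, per_group in DEFAULT_ROI_PARAMS.items()
    }
    nav = {g: DEFAULT_NAVIGATION_PARAMS["NC"] for g in GROUPS}
    covp = {
        k: ({g: v["NC"] for g in GROUPS} if isinstance(v, dict) else v)
        for k, v in DEFAULT_COVARIATE_PARAMS.items()
    }
    domp = {d: {g: v["NC"] for g in GROUPS} for d, v in DEFAULT_DOMAIN_PARAMS.items()}
    scp = {s: {g: v["NC"] for g in GROUPS} for s, v in DEFAULT_SCALE_PARAMS.items()}
    kwargs: dict = dict(
        roi_params=roi_params,
        navigation_params=nav,
        covariate_params=covp,
        domain_params=domp,
        scale_params=scp,
        covariance_strength={g: 1.0 for g in GROUPS},
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
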