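"""Synthetic roadside-transect concentration data.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without the original field
samples:

* **Marginals** — lognormal per element and barrier side, parameterised by
  the target median m and coefficient of variation CV via
  sigma^2 = ln(1 + CV^2), mu = ln(m).  Lognormal is the natural choice for
  trace-element concentrations: the survey summaries show mean > median
  and strong positive skewness throughout.
* **Dependence** — a Gaussian copula imposes the target Spearman rank
  correlations; targets are converted to latent Pearson correlations with
  rho = 2 sin(pi r_s / 6) and the assembled matrix is repaired to the
  nearest positive semidefinite correlation matrix if needed.
* **Spatial pattern** — a multiplicative Gaussian-shaped bump in
  log-distance: concentrations peak at 2.5 m on the left (windward) side
  of the barrier and at 50 m on the right side, decaying smoothly to 1
  elsewhere.  The per-element lognormal sigma and the profile factors are
  jointly calibrated so that the side-wide sample median *and* CV both
  converge to their configured targets (the bump's own spread is part of
  the marginal CV, not added on top of it).
* **Replicates** — each station value is wrapped in the requested number
  of field subsamples with a small median-1 lognormal dispersion
  (default CV 8%, inside the 10% field QC rule).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import survey
from .reference import ELEMENTS
from .samples import STUDY_DISTANCES_LEFT, STUDY_DISTANCES_RIGHT, aggregate_replicates

__all__ = ["SyntheticConfig", "default_config", "generate", "study_replica"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Targets and layout of the synthetic transect.

    ``medians``/``cvs`` map side -> element -> target (mg/kg and
    dimensionless); ``rank_corr`` maps side -> Spearman target matrix.
    ``peak_distance``/``peak_multiplier`` place the per-side concentration
    bump (element overrides via ``peak_overrides[side][element]`` as
    ``(distance, multiplier)``).  ``peak_log_width`` is the bump's Gaussian
    width in natural-log-distance units.
    """

    medians: Mapping[str, Mapping[str, float]]
    cvs: Mapping[str, Mapping[str, float]]
    rank_corr: Mapping[str, pd.DataFrame]
    distances: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {"left": STUDY_DISTANCES_LEFT, "right": STUDY_DISTANCES_RIGHT}
    )
    peak_distance: Mapping[str, float] = field(default_factory=lambda: {"left": -2.5, "right": 50.0})
    peak_multiplier: Mapping[str, float] = field(default_factory=lambda: {"left": 2.0, "right": 2.0})
    peak_overrides: Mapping[str, Mapping[str, tuple[float, float]]] = field(default_factory=dict)
    peak_log_width: float = 0.4
    n_along: int = 11
    along_spacing_m: float = 150.0
    replicates: int = 6
    replicate_cv: float = 0.08
    seed: int = 0

    def median(self, element: str, side: str) -> float:
        return float(self.medians[side][element])

    def cv(self, element: str, side: str) -> float:
        return float(self.cvs[side][element])

    def rank_corr_target(self, a: str, b: str, side: str) -> float:
        return float(self.rank_corr[side].at[a, b])

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.medians["left"].keys())

    def validate(self) -> None:
        for side in ("left", "right"):
            for el in self.elements:
                if self.median(el, side) <= 0:
                    raise ValueError(f"median must be > 0 for {el}/{side}")
                if self.cv(el, side) < 0:
                    raise ValueError(f"CV must be >= 0 for {el}/{side}")
            mat = self.rank_corr[side].loc[list(self.elements), list(self.elements)].to_numpy()
            if not np.allclose(mat, mat.T):
                raise ValueError(f"rank correlation target for {side!r} is not symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"rank correlation target for {side!r} lacks a unit diagonal")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")


def default_config(seed: int = 0) -> SyntheticConfig:
    """Configuration replicating the published survey's study conditions.

    Medians and CVs are the published per-side summary values, rank
    correlations the published Spearman matrix; the spatial bump doubles
    concentrations at 2.5 m on the left and 50 m on the right side of the
    barrier; 11 along-road stations, 6 replicates at CV 8%.
    """
    medians = {s: survey.side_statistic(s, "Med").to_dict() for s in survey.SIDES}
    cvs = {s: survey.side_statistic(s, "CV").to_dict() for s in survey.SIDES}
    corr = {s: survey.rank_correlation(s) for s in survey.SIDES}
    return SyntheticConfig(medians=medians, cvs=cvs, rank_corr=corr, seed=seed)


def _nearest_psd_correlation(mat: np.ndarray, tol: float = 0.1) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix.

    Raises if the repair has to move any entry by more than ``tol``.
    """
    w, v = np.linalg.eigh(mat)
    if w.min() >= 1e-10:
        return mat
    w = np.clip(w, 1e-10, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    if np.max(np.abs(fixed - mat)) > tol:
        raise ValueError("correlation target is too far from positive semidefinite")
    return fixed


def _bump(distances: np.ndarray, peak_d: float, mult: float, log_width: float) -> np.ndarray:
    z = (np.log(distances) - np.log(abs(peak_d))) / log_width
    return 1.0 + (mult - 1.0) * np.exp(-0.5 * z**2)


def _factor_cv2(factors: np.ndarray) -> float:
    m1, m2 = float(np.mean(factors)), float(np.mean(factors**2))
    return m2 / m1**2 - 1.0


def _profile_factors(config: SyntheticConfig, side: str, element: str) -> np.ndarray:
    """Multiplicative spatial bump per perpendicular distance.

    The peak multiplier is capped per element so the bump contributes at
    most half of the element's squared log-variability,
    1 + cv_f^2 <= sqrt(1 + cv_target^2): an element whose configured CV is
    small cannot, by construction, carry a large deterministic spatial
    swing, and capping keeps both the marginal-CV calibration feasible and
    the copula dependence alive.
    """
    dist = np.abs(np.asarray(config.distances[side], dtype=float))
    peak_d, mult = config.peak_distance[side], config.peak_multiplier[side]
    override = config.peak_overrides.get(side, {}).get(element)
    if override is not None:
        peak_d, mult = override
    cv_t = config.cv(element, side)
    limit = np.sqrt(np.sqrt(1.0 + cv_t**2) - 1.0)  # max allowed cv_f
    factors = _bump(dist, peak_d, mult, config.peak_log_width)
    if mult > 1.0 and _factor_cv2(factors) > limit**2:
        capped = optimize.brentq(
            lambda m: _factor_cv2(_bump(dist, peak_d, m, config.peak_log_width)) - limit**2,
            1.0, mult, xtol=1e-10,
        )
        factors = _bump(dist, peak_d, capped, config.peak_log_width)
    return factors


def _median_calibration(factors: np.ndarray, sigma: float) -> float:
    """Median of an equal-weight mixture of factor-scaled unit-median lognormals.

    Dividing the profile factors by this value makes the side-wide sample
    median converge to the configured target.
    """
    logf = np.log(factors)
    if sigma == 0:
        return float(np.exp(np.median(logf)))
    lo, hi = logf.min() - 6 * sigma, logf.max() + 6 * sigma

    def cdf_minus_half(x: float) -> float:
        return float(np.mean(sps.norm.cdf((x - logf) / sigma)) - 0.5)

    root = optimize.brentq(cdf_minus_half, lo, hi, xtol=1e-12)
    return float(np.exp(root))


def _calibrated_sigma(factors: np.ndarray, target_cv: float) -> float:
    """Lognormal sigma whose mixture with the profile factors has ``target_cv``.

    With D uniform over the distance grid and L lognormal(sigma),
    1 + CV^2 of f_D * L equals (1 + cv_f^2) * exp(sigma^2), so
    sigma^2 = ln((1 + cv_t^2) / (1 + cv_f^2)).  If the factor spread alone
    already exceeds the target CV the sigma floor of 0 applies and the
    marginal CV overshoots; the default narrow bump keeps every built-in
    target feasible.
    """
    m1, m2 = float(np.mean(factors)), float(np.mean(factors**2))
    one_plus_cvf2 = m2 / m1**2
    arg = (1.0 + target_cv**2) / one_plus_cvf2
    return float(np.sqrt(np.log(arg))) if arg > 1.0 else 0.0


def generate(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a full synthetic transect with replicates.

    Returns a wide concentration matrix with metadata columns
    ``site_id, side, distance_m, along_m, replicate`` followed by one
    column per element; identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    elements = list(config.elements)
    k = len(elements)
    sigma_rep = np.sqrt(np.log1p(config.replicate_cv**2))

    frames = []
    for side in ("left", "right"):
        distances = np.asarray(config.distances[side], dtype=float)
        rs = config.rank_corr[side].loc[elements, elements].to_numpy()
        latent = _nearest_psd_correlation(2.0 * np.sin(np.pi * rs / 6.0))
        np.fill_diagonal(latent, 1.0)
        chol = np.linalg.cholesky(latent + 1e-12 * np.eye(k))

        mu = np.array([np.log(config.median(el, side)) for el in elements])
        factors = np.column_stack([_profile_factors(config, side, el) for el in elements])
        sigma = np.array(
            [_calibrated_sigma(factors[:, j], config.cv(el, side)) for j, el in enumerate(elements)]
        )
        calib = np.array(
            [_median_calibration(factors[:, j], sigma[j]) for j in range(k)]
        )

        n_sites = config.n_along * len(distances)
        z = rng.standard_normal((n_sites, k)) @ chol.T
        site_conc = np.exp(mu + sigma * z)  # lognormal with target median/CV

        rows = []
        idx = 0
        for ia in range(config.n_along):
            along = ia * config.along_spacing_m
            for idist, d in enumerate(distances):
                conc = site_conc[idx] * factors[idist] / calib
                idx += 1
                site_id = f"{side[0].upper()}{ia + 1:02d}@{d:+g}m"
                if config.replicate_cv > 0:
                    noise = np.exp(sigma_rep * rng.standard_normal((config.replicates, k)))
                else:
                    noise = np.ones((config.replicates, k))
                for rep in range(config.replicates):
                    rows.append(
                        {
                            "site_id": site_id,
                            "side": side,
                            "distance_m": float(d),
                            "along_m": float(along),
                            "replicate": rep + 1,
                            **{el: conc[j] * noise[rep, j] for j, el in enumerate(elements)},
                        }
                    )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def study_replica(seed: int = 0) -> pd.DataFrame:
    """Site-level replica of the published sampling design.

    Generates the default configuration (11 along-road stations x 6 left +
    5 right distances x 6 replicates) and aggregates replicates, yielding
    121 site rows with per-element replicate CVs attached.
    """
    raw = generate(default_config(), seed=seed)
    return aggregate_replicates(raw)
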