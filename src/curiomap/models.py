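"""Bayesian multilevel analyses of exploration and cognitive-map precision.

Four analyses share one sampling backend (:mod:`curiomap.gibbs`):

* :func:`fit_exploration_model` — bivariate model of path and head-direction
  roaming entropy on within/between-person curiosity and interest plus
  duration, with participant random intercepts (and slopes) and correlated
  residuals across the two outcomes;
* :func:`fit_moderation_model` — path RE with the four trait-curiosity
  subscales and their interactions with within-person curiosity;
* :func:`fit_map_model` — composite sketch-map score on curiosity, interest
  and both RE measures;
* :func:`mediation` — within-person product-of-coefficients indirect effect
  of curiosity on map precision through path RE.

Posterior summaries default to the mean and the 93% highest posterior density
interval; convergence is gated on split-R-hat <= 1.01 and bulk ESS >= 400 for
every structural parameter (fits that fail carry a visible warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .gibbs import sample_mlmm

__all__ = [
    "SamplerSettings",
    "PosteriorSummary",
    "ModelFit",
    "MediationResult",
    "hpdi",
    "fit_exploration_model",
    "fit_moderation_model",
    "fit_map_model",
    "coefficient_contrast",
    "mediation",
    "indirect_effect_draws",
]

HPDI_LEVEL = 0.93


@dataclass(frozen=True)
class SamplerSettings:
    """Chains and per-chain iterations (first half is warm-up)."""

    chains: int = 4
    iterations: int = 4800

    @property
    def warmup(self) -> int:
        return self.iterations // 2

    @classmethod
    def reduced(cls) -> "SamplerSettings":
        """Short preset for quick runs and continuous testing."""
        return cls(chains=2, iterations=1200)


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    hpdi_low: float
    hpdi_high: float
    level: float = HPDI_LEVEL
    flagged_multimodal: bool = False

    def excludes_zero(self) -> bool:
        return self.hpdi_low > 0 or self.hpdi_high < 0


def hpdi(draws: np.ndarray, level: float = HPDI_LEVEL, *, min_draws: int = 100) -> PosteriorSummary:
    """Shortest interval containing ``ceil(level * n)`` sorted draws.

    Ties in window width are broken toward the earliest window.  Requires at
    least ``min_draws`` draws.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < min_draws:
        raise ValueError(f"need at least {min_draws} draws for an HPDI, got {n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m = math.ceil(level * n)
    if m >= n:
        lo, hi = x[0], x[-1]
    else:
        widths = x[m - 1 :] - x[: n - m + 1]
        j = int(np.argmin(widths))
        lo, hi = x[j], x[j + m - 1]
    mean = float(x.mean())
    return PosteriorSummary(
        mean=mean,
        hpdi_low=float(lo),
        hpdi_high=float(hi),
        level=level,
        flagged_multimodal=not (lo <= mean <= hi),
    )


@dataclass
class ModelFit:
    """Posterior draws keyed by parameter name, shaped (chains, draws)."""

    draws: dict[str, np.ndarray]
    outcomes: list[str]
    fixed_effects: list[str]
    settings: SamplerSettings
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise KeyError(f"unknown parameter {name!r}; available: {sorted(self.draws)}")
        return self.draws[name].ravel()

    def summary(self, level: float = HPDI_LEVEL) -> pd.DataFrame:
        rows = []
        diag = self.diagnostics.set_index("parameter") if len(self.diagnostics) else None
        for name, arr in self.draws.items():
            s = hpdi(arr, level)
            row = {
                "parameter": name,
                "mean": s.mean,
                "hpdi_low": s.hpdi_low,
                "hpdi_high": s.hpdi_high,
                "sd": float(arr.std(ddof=1)),
            }
            if diag is not None and name in diag.index:
                row["rhat"] = diag.loc[name, "rhat"]
                row["ess"] = diag.loc[name, "ess"]
            rows.append(row)
        return pd.DataFrame(rows)


def _run_chains(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    fixed_names: list[str],
    z_names: list[str],
    outcome_names: list[str],
    settings: SamplerSettings,
    seed: int | None,
    prior_sd: np.ndarray,
) -> ModelFit:
    d = Y.shape[1]
    q = Z.shape[1]
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(settings.chains)
    per_chain = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        per_chain.append(
            sample_mlmm(
                Y, X, Z, groups,
                prior_sd=prior_sd,
                n_iter=settings.iterations,
                warmup=settings.warmup,
                rng=rng,
            )
        )

    draws: dict[str, np.ndarray] = {}
    for j, pred in enumerate(fixed_names):
        for k, out in enumerate(outcome_names):
            draws[f"{pred}:{out}"] = np.stack([c.B[:, j, k] for c in per_chain])
    for k, out in enumerate(outcome_names):
        draws[f"sigma:{out}"] = np.stack([np.sqrt(c.Sigma[:, k, k]) for c in per_chain])
    if d > 1:
        for k1 in range(d):
            for k2 in range(k1 + 1, d):
                corr = [
                    c.Sigma[:, k1, k2] / np.sqrt(c.Sigma[:, k1, k1] * c.Sigma[:, k2, k2])
                    for c in per_chain
                ]
                draws[f"resid_corr:{outcome_names[k1]},{outcome_names[k2]}"] = np.stack(corr)
    for jz, zn in enumerate(z_names):
        for k, out in enumerate(outcome_names):
            pos = k * q + jz  # column-major vec ordering
            draws[f"sd_u:{zn}:{out}"] = np.stack([np.sqrt(c.T[:, pos, pos]) for c in per_chain])

    # split-R-hat / bulk ESS for the structural parameters
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    diag = pd.DataFrame(
        {
            "parameter": list(draws),
            "rhat": [float(rhat[k].values) for k in draws],
            "ess": [float(ess[k].values) for k in draws],
        }
    )
    fit = ModelFit(
        draws=draws,
        outcomes=outcome_names,
        fixed_effects=fixed_names,
        settings=settings,
        diagnostics=diag,
    )
    structural = [f"{p}:{o}" for p in fixed_names for o in outcome_names]
    bad = diag[diag["parameter"].isin(structural) & ((diag["rhat"] > 1.01) | (diag["ess"] < 400))]
    if len(bad):
        fit.converged = False
        msg = (
            "convergence gate failed (R-hat > 1.01 or ESS < 400) for: "
            + ", ".join(bad["parameter"].tolist())
        )
        fit.warnings_.append(msg)
        warnings.warn(msg, stacklevel=3)
    return fit


def _design_matrices(
    design: pd.DataFrame,
    fixed_cols: list[str],
    z_cols: list[str],
    outcome_cols: list[str],
    room_factor: bool,
):
    df = design
    fixed_names = ["intercept"] + list(fixed_cols)
    X_parts = [np.ones((len(df), 1))] + [df[c].to_numpy(dtype=float)[:, None] for c in fixed_cols]
    if room_factor:
        dummies = pd.get_dummies(df["room_id"], prefix="room", drop_first=True)
        X_parts.append(dummies.to_numpy(dtype=float))
        fixed_names += list(dummies.columns)
    X = np.hstack(X_parts)
    z_names = ["intercept"] + list(z_cols)
    Z = np.hstack([np.ones((len(df), 1))] + [df[c].to_numpy(dtype=float)[:, None] for c in z_cols])
    Y = df[outcome_cols].to_numpy(dtype=float)
    groups = pd.factorize(df["participant_id"])[0]
    for c, name in zip(X.T, fixed_names):
        if name != "intercept" and np.allclose(c, c[0]):
            raise ValueError(f"predictor {name!r} is constant; model unidentifiable")
    for oc in outcome_cols:
        if np.allclose(df[oc], df[oc].iloc[0]):
            raise ValueError(f"outcome {oc!r} is constant; model unidentifiable")
    return Y, X, Z, groups, fixed_names, z_names


def _prior_sd(fixed_names: list[str], prior_scale: float, intercept_prior_scale: float) -> np.ndarray:
    return np.array(
        [intercept_prior_scale if n == "intercept" else prior_scale for n in fixed_names]
    )


def _check_min_structure(design: pd.DataFrame) -> None:
    counts = design.groupby("participant_id").size()
    if len(counts) < 2 or (counts < 2).all():
        raise ValueError("need at least 2 participants with at least 2 trials each")


def fit_exploration_model(
    design: pd.DataFrame,
    *,
    settings: SamplerSettings = SamplerSettings(),
    seed: int | None = None,
    prior_scale: float = 1.0,
    intercept_prior_scale: float = 5.0,
    random_slopes: bool = True,
    room_factor: bool = False,
) -> ModelFit:
    """Bivariate multilevel model of (path_re, head_re).

    Fixed effects: within-person curiosity and interest, their grand-centred
    person means, and grand-centred duration, per outcome; participant random
    intercepts plus (by default) random slopes for the within-person
    predictors; residuals correlated across outcomes.
    """
    _check_min_structure(design)
    fixed = ["curiosity_w", "interest_w", "curiosity_m", "interest_m", "duration_c"]
    zcols = ["curiosity_w", "interest_w"] if random_slopes else []
    Y, X, Z, groups, fnames, znames = _design_matrices(
        design, fixed, zcols, ["path_re", "head_re"], room_factor
    )
    return _run_chains(
        Y, X, Z, groups, fnames, znames, ["path_re", "head_re"], settings, seed,
        _prior_sd(fnames, prior_scale, intercept_prior_scale),
    )


def fit_moderation_model(
    design: pd.DataFrame,
    *,
    settings: SamplerSettings = SamplerSettings(),
    seed: int | None = None,
    prior_scale: float = 1.0,
    intercept_prior_scale: float = 5.0,
    random_slopes: bool = True,
) -> ModelFit:
    """Path RE with trait main effects and trait x within-curiosity interactions.

    Traits (Joyous Exploration, Deprivation Sensitivity, Stress Tolerance,
    Thrill Seeking) enter grand-centred; each also interacts with the
    within-person curiosity deviation.
    """
    _check_min_structure(design)
    traits = ["trait_JE_c", "trait_DS_c", "trait_ST_c", "trait_TS_c"]
    missing = [t for t in traits if t not in design.columns]
    if missing:
        raise ValueError(f"design lacks centred trait columns {missing}; pass traits to build_design")
    df = design.copy()
    inter = []
    for t in traits:
        name = f"{t}x_curiosity_w"
        df[name] = df[t] * df["curiosity_w"]
        inter.append(name)
    fixed = ["curiosity_w", "interest_w", "curiosity_m", "interest_m", "duration_c"] + traits + inter
    zcols = ["curiosity_w", "interest_w"] if random_slopes else []
    Y, X, Z, groups, fnames, znames = _design_matrices(df, fixed, zcols, ["path_re"], False)
    return _run_chains(
        Y, X, Z, groups, fnames, znames, ["path_re"], settings, seed,
        _prior_sd(fnames, prior_scale, intercept_prior_scale),
    )


def fit_map_model(
    design: pd.DataFrame,
    *,
    settings: SamplerSettings = SamplerSettings(),
    seed: int | None = None,
    prior_scale: float = 1.0,
    intercept_prior_scale: float = 5.0,
    random_slopes: bool = True,
) -> ModelFit:
    """Composite sketch-map score on curiosity, interest and both RE measures."""
    if "composite" not in design.columns:
        raise ValueError("design lacks a 'composite' column; pass composites to build_design")
    df = design.dropna(subset=["composite"]).reset_index(drop=True)
    _check_min_structure(df)
    fixed = [
        "curiosity_w", "interest_w", "path_re_w", "head_re_w",
        "curiosity_m", "interest_m", "path_re_m", "head_re_m", "duration_c",
    ]
    zcols = ["curiosity_w", "interest_w", "path_re_w", "head_re_w"] if random_slopes else []
    Y, X, Z, groups, fnames, znames = _design_matrices(df, fixed, zcols, ["composite"], False)
    return _run_chains(
        Y, X, Z, groups, fnames, znames, ["composite"], settings, seed,
        _prior_sd(fnames, prior_scale, intercept_prior_scale),
    )


def coefficient_contrast(
    fit: ModelFit, coefficient: str, outcome_a: str, outcome_b: str, level: float = HPDI_LEVEL
) -> PosteriorSummary:
    """Draw-wise difference of one coefficient between two outcomes."""
    da = fit.draws.get(f"{coefficient}:{outcome_a}")
    db = fit.draws.get(f"{coefficient}:{outcome_b}")
    if da is None or db is None:
        raise KeyError(
            f"coefficient {coefficient!r} not present for outcomes "
            f"({outcome_a!r}, {outcome_b!r})"
        )
    diff = (da - db).ravel()
    if np.allclose(diff, 0):
        return PosteriorSummary(0.0, 0.0, 0.0, level)
    return hpdi(diff, level)


def indirect_effect_draws(a_draws: np.ndarray, b_draws: np.ndarray) -> np.ndarray:
    """Draw-wise product a*b (never the product of posterior means)."""
    a = np.asarray(a_draws).ravel()
    b = np.asarray(b_draws).ravel()
    if a.shape != b.shape:
        raise ValueError("a and b draws must align draw-by-draw")
    return a * b


@dataclass
class MediationResult:
    a: PosteriorSummary
    b: PosteriorSummary
    indirect: PosteriorSummary
    direct: PosteriorSummary
    indirect_draws: np.ndarray
    mediator_fit: ModelFit
    outcome_fit: ModelFit


def mediation(
    design: pd.DataFrame,
    *,
    settings: SamplerSettings = SamplerSettings(),
    seed: int | None = None,
    prior_scale: float = 1.0,
    intercept_prior_scale: float = 5.0,
    level: float = HPDI_LEVEL,
) -> MediationResult:
    """Within-person mediation of curiosity -> path RE -> map precision.

    Two submodels fitted with matched sampler settings and paired by draw
    index: mediator ``path_re ~ curiosity_w (+ curiosity_m + duration)`` and
    outcome ``composite ~ curiosity_w + path_re_w (+ means + duration)``, both
    with participant random intercepts and within-person random slopes.  The
    indirect effect is the draw-wise product ``a * b``.
    """
    if "composite" not in design.columns:
        raise ValueError("mediation needs composite scores in the design")
    df = design.dropna(subset=["composite"]).reset_index(drop=True)
    _check_min_structure(df)

    Y, X, Z, groups, fnames, znames = _design_matrices(
        df, ["curiosity_w", "curiosity_m", "duration_c"], ["curiosity_w"], ["path_re"], False
    )
    med_fit = _run_chains(
        Y, X, Z, groups, fnames, znames, ["path_re"], settings, seed,
        _prior_sd(fnames, prior_scale, intercept_prior_scale),
    )

    fixed = ["curiosity_w", "path_re_w", "curiosity_m", "path_re_m", "duration_c"]
    Y, X, Z, groups, fnames, znames = _design_matrices(
        df, fixed, ["curiosity_w", "path_re_w"], ["composite"], False
    )
    out_seed = None if seed is None else seed + 1
    out_fit = _run_chains(
        Y, X, Z, groups, fnames, znames, ["composite"], settings, out_seed,
        _prior_sd(fnames, prior_scale, intercept_prior_scale),
    )

    a_draws = med_fit.flat("curiosity_w:path_re")
    b_draws = out_fit.flat("path_re_w:composite")
    ind = indirect_effect_draws(a_draws, b_draws)
    return MediationResult(
        a=hpdi(a_draws, level),
        b=hpdi(b_draws, level),
        indirect=hpdi(ind, level),
        direct=hpdi(out_fit.flat("curiosity_w:composite"), level),
        indirect_draws=ind,
        mediator_fit=med_fit,
        outcome_fit=out_fit,
    )
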