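"""Bayesian inference of the 12 model parameters from a feature table.

The likelihood is Gaussian per datum: each normalized feature value at each
heteroplasmy level contributes a term with its propagated measurement SE as
the (fixed) noise scale.  Only the six measured features enter (wild-type
copy number follows the parameter-free line 1 - h and carries no
information about the adjustable parameters), and only levels with
h <= 0.9 — the model does not describe the transition to homoplasmy.

Sampling uses the affine-invariant ensemble sampler (emcee) on a
transformed coordinate system in which the default priors are flat
(logarithms of positive parameters, bounded fractions as-is); the posterior
is non-differentiable in h_star wherever the changepoint crosses a data
abscissa, which a gradient-free ensemble handles without special casing.

Usage follows the statsmodels convention::

    model = HeteroplasmyModel(feature_table)
    result = model.fit(seed=1)
    print(result.summary())
    band = result.credible_band(h_grid, "V", (25, 75))
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .model import OBSERVABLE_FEATURES, normalized_predictions, predict_all
from .parameters import PARAM_NAMES, FixedConstants, ModelParameters
from .priors import PriorSpec, Uniform, LogUniform, default_priors

__all__ = [
    "LikelihoodSpec",
    "HeteroplasmyModel",
    "HeteroplasmyResults",
    "log_likelihood",
    "log_posterior",
    "run_mcmc",
    "sample_posterior",
    "credible_band",
    "derived_posteriors",
    "map_estimate",
]

logger = logging.getLogger(__name__)

#: Features entering the likelihood; N_plus is parameter-free and excluded.
FIT_FEATURES: tuple[str, ...] = ("M_ETC", "P_plus", "M_gly", "V", "G", "R_max")

RHAT_FLAG_THRESHOLD = 1.05


@dataclass(frozen=True)
class LikelihoodSpec:
    """Which data enter the Gaussian likelihood and with what noise floor.

    The feature table is expected on the fold-change scale (h = 0 value 1
    per feature).  Uncertainties of zero (or below the floor) are replaced
    by ``sigma_floor`` times the feature's h = 0 value; exact zeros would
    make the Gaussian degenerate.

    With ``infer_noise_scale`` (the default) every per-datum SE is
    multiplied by a single global scale that is inferred alongside the model
    parameters (log-uniform prior on ``noise_scale_bounds``).  Reported
    technical SEs understate the effective noise — replicate-based SE
    estimates are themselves noisy, and the volume transform induces shared
    errors across features at one heteroplasmy level — so a fixed-SE
    posterior is overconfident; the inferred multiplier restores
    calibration.  Set it to False to treat the reported SEs as exact.
    """

    features: tuple[str, ...] = FIT_FEATURES
    h_max: float = 0.9
    sigma_floor: float = 0.01
    infer_noise_scale: bool = True
    noise_scale_bounds: tuple[float, float] = (0.1, 10.0)


class _FitData:
    """Long-form fit arrays extracted once from a feature table."""

    def __init__(self, table: pd.DataFrame, spec: LikelihoodSpec):
        mask = (
            table["feature"].isin(spec.features)
            & (table["h"] <= spec.h_max)
            & ~table["excluded_from_fit"].astype(bool)
        )
        sub = table.loc[mask].copy()
        if sub.empty:
            raise ValueError("feature table contains no rows eligible for fitting")
        self.features = tuple(spec.features)
        self.h_unique = np.sort(sub["h"].unique())
        h_pos = {h: i for i, h in enumerate(self.h_unique)}
        f_pos = {f: j for j, f in enumerate(self.features)}
        self.h_idx = sub["h"].map(h_pos).to_numpy()
        self.f_idx = sub["feature"].map(f_pos).to_numpy()
        self.y = sub["value"].to_numpy(dtype=float)

        sigma = sub["uncertainty"].to_numpy(dtype=float)
        ref = table[(table["h"] == 0.0) & table["feature"].isin(spec.features)]
        ref_values = {f: 1.0 for f in spec.features}
        ref_values.update(dict(zip(ref["feature"], ref["value"].astype(float))))
        floor = np.array([spec.sigma_floor * abs(ref_values[f]) for f in sub["feature"]])
        n_floored = int(np.sum(sigma < floor))
        if n_floored:
            logger.info(
                "floored %d of %d measurement SEs to %.3g x their h=0 feature value",
                n_floored, len(sigma), spec.sigma_floor,
            )
        self.sigma = np.maximum(sigma, floor)
        self.log_norm = float(np.sum(np.log(self.sigma * np.sqrt(2.0 * np.pi))))

    def __len__(self) -> int:
        return len(self.y)


def _predict_matrix(theta: np.ndarray, h: np.ndarray, features: tuple[str, ...]) -> np.ndarray:
    """Normalized feature predictions, rows = h values, columns = features.

    Inlined fast path of the forward model (fold-change scale), used inside
    the sampler; agreement with :func:`mitohet.model.normalized_predictions`
    is covered by tests.
    """
    beta, k_mRNA, k_m, h0, delta_p, c1, m2, h_star, k_o, k_g, k_gr, k_p = theta
    hh = np.append(h, 0.0)  # final row is the h = 0 reference
    n_plus = 1.0 - hh
    delta_m = k_mRNA * expit(-k_m * (hh - h0))
    m_etc = beta / (delta_m + 1.0) * n_plus
    p_plus = n_plus * m_etc / delta_p
    m_gly = np.where(hh <= h_star, c1, m2 * hh + (c1 - m2 * h_star))
    volume = k_o * p_plus + k_g * m_gly
    cols = {
        "N_plus": n_plus,
        "M_ETC": m_etc,
        "P_plus": p_plus,
        "M_gly": m_gly,
        "V": volume,
        "G": k_gr / volume,
        "R_max": k_p * p_plus,
    }
    mat = np.column_stack([cols[f] for f in features])
    return mat[:-1] / mat[-1]


def _log_likelihood_fast(theta: np.ndarray, data: _FitData, scale: float = 1.0) -> float:
    pred = _predict_matrix(theta, data.h_unique, data.features)
    resid = (data.y - pred[data.h_idx, data.f_idx]) / data.sigma
    return (
        -0.5 * float(resid @ resid) / scale**2
        - data.log_norm
        - len(data) * np.log(scale)
    )


def log_likelihood(
    params: ModelParameters,
    table: pd.DataFrame,
    spec: LikelihoodSpec = LikelihoodSpec(),
) -> float:
    """Gaussian log-likelihood of a feature table under the model.

    Rows for excluded features (N_plus), flagged rows and rows with
    h > ``spec.h_max`` contribute nothing.  Parameters outside their support
    yield ``-inf`` rather than raising.
    """
    try:
        theta = np.asarray(params.to_array())
    except AttributeError:
        theta = np.asarray(params, dtype=float)
        try:
            ModelParameters.from_array(theta)
        except ValueError:
            return -np.inf
    return _log_likelihood_fast(theta, _FitData(table, spec))


def log_posterior(
    params,
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    spec: LikelihoodSpec = LikelihoodSpec(),
) -> float:
    """log prior + log likelihood; -inf outside the prior support."""
    priors = priors or default_priors()
    theta = np.asarray(params.to_array() if hasattr(params, "to_array") else params, dtype=float)
    lp = priors.log_prior(theta)
    if not np.isfinite(lp):
        return -np.inf
    return lp + _log_likelihood_fast(theta, _FitData(table, spec))


# --------------------------------------------------------------------------
# generic ensemble-sampling helper (also used by sampler-validation tests)


def default_moves():
    """Ensemble move mixture used for fitting.

    Differential-evolution moves travel along the ridge directions left by
    weakly identified parameter combinations far better than the plain
    stretch move, which is what makes short chains usable here.
    """
    return [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]


def sample_posterior(
    log_prob_fn,
    p0: np.ndarray,
    nsteps: int,
    seed: int,
    moves=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the ensemble sampler (emcee) on an arbitrary log density.

    Parameters
    ----------
    log_prob_fn : callable
        Maps a coordinate vector to a log density (may return -inf).
    p0 : ndarray, shape (nwalkers, ndim)
        Initial walker positions, all with finite log density.
    nsteps, seed : int
        Chain length per walker and RNG seed (deterministic given both).
    moves : optional
        emcee move set; defaults to the plain stretch move.

    Returns
    -------
    chain : ndarray, shape (nsteps, nwalkers, ndim)
    log_prob : ndarray, shape (nsteps, nwalkers)
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    nwalkers, ndim = p0.shape
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob_fn, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    sampler.run_mcmc(state, nsteps, progress=False)
    return sampler.get_chain(), sampler.get_log_prob()


# --------------------------------------------------------------------------
# model / results objects


class HeteroplasmyModel:
    """Bayesian model of a normalized feature table.

    Parameters
    ----------
    feature_table : DataFrame
        Tidy rows (h, feature, value, uncertainty, excluded_from_fit) on the
        fold-change scale, as produced by
        :func:`mitohet.normalize.assemble_feature_table`.
    priors : PriorSpec, optional
        Defaults to :func:`mitohet.priors.default_priors`.
    likelihood : LikelihoodSpec, optional
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        priors: PriorSpec | None = None,
        likelihood: LikelihoodSpec | None = None,
        constants: FixedConstants = FixedConstants(),
    ):
        self.feature_table = feature_table.reset_index(drop=True)
        self.priors = priors or default_priors()
        self.likelihood_spec = likelihood or LikelihoodSpec()
        self.constants = constants
        self._data = _FitData(self.feature_table, self.likelihood_spec)
        if len(self._data) < len(PARAM_NAMES):
            warnings.warn(
                f"only {len(self._data)} fitting data for {len(PARAM_NAMES)} parameters; "
                "the posterior will be strongly prior-driven",
                stacklevel=2,
            )

    @classmethod
    def from_bundle(cls, bundle, **kwargs) -> "HeteroplasmyModel":
        """Build directly from a raw study bundle (normalizes it first)."""
        from .normalize import assemble_feature_table

        return cls(assemble_feature_table(bundle), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HeteroplasmyModel":
        return cls(df, **kwargs)

    # --- densities ---------------------------------------------------------

    def loglike(self, params) -> float:
        theta = np.asarray(params.to_array() if hasattr(params, "to_array") else params, dtype=float)
        return _log_likelihood_fast(theta, self._data)

    def logposterior(self, params) -> float:
        theta = np.asarray(params.to_array() if hasattr(params, "to_array") else params, dtype=float)
        lp = self.priors.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglike(theta)

    # --- sampling-space plumbing --------------------------------------------
    #
    # The sampling vector is the 12 transformed model parameters, plus one
    # trailing coordinate log(noise scale) when the likelihood infers the
    # global SE multiplier.

    @property
    def _ndim(self) -> int:
        return len(PARAM_NAMES) + (1 if self.likelihood_spec.infer_noise_scale else 0)

    def _split(self, coords: np.ndarray) -> tuple[np.ndarray, float]:
        if self.likelihood_spec.infer_noise_scale:
            return coords[: len(PARAM_NAMES)], float(np.exp(coords[-1]))
        return coords, 1.0

    def _full_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.priors.transformed_bounds()
        if self.likelihood_spec.infer_noise_scale:
            s_lo, s_hi = self.likelihood_spec.noise_scale_bounds
            lo = np.append(lo, np.log(s_lo))
            hi = np.append(hi, np.log(s_hi))
        return lo, hi

    def _log_prob_transformed(self, coords: np.ndarray) -> float:
        param_coords, scale = self._split(np.asarray(coords, dtype=float))
        lp = self.priors.log_prior_transformed(param_coords)
        if not np.isfinite(lp):
            return -np.inf
        if self.likelihood_spec.infer_noise_scale:
            s_lo, s_hi = self.likelihood_spec.noise_scale_bounds
            if not s_lo < scale < s_hi:  # log-uniform prior, flat in log s
                return -np.inf
        return lp + _log_likelihood_fast(
            self.priors.untransform(param_coords), self._data, scale
        )

    # --- point estimation --------------------------------------------------

    def _flat_priors(self) -> bool:
        return all(isinstance(p, (Uniform, LogUniform)) for _, p in self.priors.items())

    def _residuals_transformed(self, param_coords: np.ndarray) -> np.ndarray:
        theta = self.priors.untransform(param_coords)
        pred = _predict_matrix(theta, self._data.h_unique, self._data.features)
        return (self._data.y - pred[self._data.h_idx, self._data.f_idx]) / self._data.sigma

    def optimize_posterior(self, start_coords: np.ndarray) -> np.ndarray:
        """Local posterior maximization in the sampling coordinates.

        With flat-in-sampling-space priors (the defaults) the parameter MAP
        is the bounded weighted least-squares optimum, found with a
        trust-region reflective solver — a uniform SE multiplier does not
        move the WLS optimum, and its own conditional MAP has the closed
        form s^2 = SSE/n.  Otherwise fall back to Nelder-Mead on the
        negative log posterior.
        """
        lo, hi = self._full_bounds()
        npar = len(PARAM_NAMES)
        x0 = np.clip(np.asarray(start_coords, dtype=float), lo + 1e-9, hi - 1e-9)
        if self._flat_priors():
            sol = optimize.least_squares(
                self._residuals_transformed, x0[:npar], bounds=(lo[:npar], hi[:npar]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=20000,
            )
            best = sol.x
            if self.likelihood_spec.infer_noise_scale:
                sse = float(sol.fun @ sol.fun)
                log_s = 0.5 * np.log(max(sse, 1e-300) / len(self._data))
                best = np.append(best, np.clip(log_s, lo[-1] + 1e-9, hi[-1] - 1e-9))
            return best

        def neg(coords):
            lp = self._log_prob_transformed(coords)
            return -lp if np.isfinite(lp) else 1e300

        sol = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            options={"maxfev": 40000, "xatol": 1e-10, "fatol": 1e-10, "adaptive": True},
        )
        return sol.x

    # --- sampling ----------------------------------------------------------

    def fit(
        self,
        seed: int,
        nwalkers: int = 32,
        nsteps: int = 4000,
        burn: int = 2000,
        thin: int = 1,
        optimize_start: bool = True,
        refine_map: bool = True,
        init_scale: float = 0.3,
    ) -> "HeteroplasmyResults":
        """Sample the posterior and return a results object.

        The walkers start in a small Gaussian ball (``init_scale`` in the
        sampling coordinates) around a local posterior optimum found from
        the prior-typical point (or around that point directly if
        ``optimize_start`` is False).  Deterministic given ``seed``.
        """
        rng = np.random.default_rng(seed)
        ndim = self._ndim
        start = self.priors.transform(self.priors.typical_point())
        if self.likelihood_spec.infer_noise_scale:
            start = np.append(start, 0.0)  # noise scale 1 as the typical point
        if optimize_start:
            start = self.optimize_posterior(start)
        lo, hi = self._full_bounds()

        p0 = np.empty((nwalkers, ndim))
        for w in range(nwalkers):
            for _ in range(200):
                cand = np.clip(start + init_scale * rng.standard_normal(ndim),
                               lo + 1e-9, hi - 1e-9)
                if np.isfinite(self._log_prob_transformed(cand)):
                    p0[w] = cand
                    break
            else:
                raise RuntimeError("could not find finite-posterior initial walker positions")

        chain, log_prob = sample_posterior(
            self._log_prob_transformed, p0, nsteps,
            seed=int(rng.integers(2**31)), moves=default_moves(),
        )
        return HeteroplasmyResults(
            model=self,
            chain=chain,
            log_prob=log_prob,
            burn=burn,
            thin=thin,
            seed=seed,
            sampler_settings={
                "nwalkers": nwalkers, "nsteps": nsteps, "burn": burn,
                "thin": thin, "init_scale": init_scale,
                "optimize_start": optimize_start,
            },
            refine_map=refine_map,
        )


class HeteroplasmyResults:
    """Posterior draws, point estimates, intervals and diagnostics.

    Attributes
    ----------
    draws : DataFrame
        Post-burn-in draws in natural parameter space, one column per
        parameter, plus ``log_posterior``.
    map_params, mean_params : ModelParameters
        Highest-posterior point (best draw, optionally refined by local
        optimization) and the posterior mean.
    diagnostics : dict
        Split-Rhat and bulk ESS per parameter, and a convergence flag.
    """

    def __init__(
        self,
        model: HeteroplasmyModel,
        chain: np.ndarray,
        log_prob: np.ndarray,
        burn: int,
        thin: int,
        seed: int,
        sampler_settings: dict,
        refine_map: bool = True,
    ):
        if burn >= chain.shape[0]:
            raise ValueError(f"burn-in {burn} >= chain length {chain.shape[0]}")
        self.model = model
        self.seed = seed
        self.sampler_settings = dict(sampler_settings)
        self._chain = chain           # (nsteps, nwalkers, ndim), sampling space
        self._log_prob = log_prob     # (nsteps, nwalkers)
        self.burn = burn
        self.thin = thin

        kept = chain[burn::thin]
        kept_lp = log_prob[burn::thin]
        flat_coords = kept.reshape(-1, kept.shape[-1])
        npar = len(PARAM_NAMES)
        natural = np.array(
            [model.priors.untransform(c[:npar]) for c in flat_coords]
        )
        self.draws = pd.DataFrame(natural, columns=list(PARAM_NAMES))
        self._has_noise_scale = model.likelihood_spec.infer_noise_scale
        if self._has_noise_scale:
            self.draws["noise_scale"] = np.exp(flat_coords[:, -1])
        self.draws["log_posterior"] = kept_lp.reshape(-1)

        best = int(self.draws["log_posterior"].to_numpy().argmax())
        best_coords = flat_coords[best]
        best_lp = float(self.draws["log_posterior"].iloc[best])
        if refine_map:
            refined = model.optimize_posterior(best_coords)
            refined_lp = model._log_prob_transformed(refined)
            if refined_lp >= best_lp:
                best_coords, best_lp = refined, refined_lp
        self.map_params = ModelParameters.from_array(
            model.priors.untransform(best_coords[:npar])
        )
        self.map_noise_scale = (
            float(np.exp(best_coords[-1])) if self._has_noise_scale else 1.0
        )
        self.map_log_posterior = float(best_lp)
        self.mean_params = ModelParameters.from_array(
            self.draws[list(PARAM_NAMES)].mean().to_numpy()
        )
        self.diagnostics = self._compute_diagnostics(kept)

    @classmethod
    def from_draws(
        cls,
        model: HeteroplasmyModel,
        draws: pd.DataFrame,
        seed: int = 0,
        refine_map: bool = False,
    ) -> "HeteroplasmyResults":
        """Rebuild a results object from saved posterior draws.

        Used to render reports from a persisted ``posterior_draws.csv``
        without re-sampling; the draws are laid out as a single chain.
        """
        coords = np.array(
            [model.priors.transform(row) for row in draws[list(PARAM_NAMES)].to_numpy()]
        )
        if model.likelihood_spec.infer_noise_scale:
            scale = (
                draws["noise_scale"].to_numpy(dtype=float)
                if "noise_scale" in draws
                else np.ones(len(draws))
            )
            coords = np.column_stack([coords, np.log(scale)])
        chain = coords[:, None, :]
        if "log_posterior" in draws:
            log_prob = draws["log_posterior"].to_numpy()[:, None]
        else:
            log_prob = np.array(
                [model._log_prob_transformed(c) for c in coords]
            )[:, None]
        return cls(
            model=model, chain=chain, log_prob=log_prob, burn=0, thin=1,
            seed=seed, sampler_settings={"reconstructed_from_draws": True},
            refine_map=refine_map,
        )

    # --- diagnostics -------------------------------------------------------

    def _compute_diagnostics(self, kept: np.ndarray) -> dict:
        # treat walkers as chains: (chain, draw) layout for arviz
        names = list(PARAM_NAMES) + (["noise_scale"] if self._has_noise_scale else [])
        per_param = {name: kept[:, :, i].T for i, name in enumerate(names)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.convert_to_dataset(per_param)
            rhat = az.rhat(ds)
            ess = az.ess(ds)
        rhat_d = {k: float(rhat[k].values) for k in names}
        ess_d = {k: float(ess[k].values) for k in names}
        worst = max(rhat_d.values())
        converged = worst <= RHAT_FLAG_THRESHOLD
        if not converged:
            logger.warning("split-Rhat exceeds %.2f (max %.3f); chains may be unconverged",
                           RHAT_FLAG_THRESHOLD, worst)
        return {"rhat": rhat_d, "ess_bulk": ess_d, "max_rhat": worst, "converged": converged}

    # --- summaries ---------------------------------------------------------

    def param_intervals(self, quantiles: tuple[float, float] = (25.0, 75.0)) -> pd.DataFrame:
        """Per-parameter posterior quantile interval (percent units)."""
        lo, hi = quantiles
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"invalid quantile pair {quantiles}")
        q = self.draws[list(PARAM_NAMES)].quantile([lo / 100.0, hi / 100.0]).T
        q.columns = [f"q{lo:g}", f"q{hi:g}"]
        return q

    def h_star_interval(self, quantiles: tuple[float, float] = (5.0, 95.0)) -> tuple[float, float]:
        """Credible interval for the critical heteroplasmy."""
        lo, hi = quantiles
        vals = self.draws["h_star"].to_numpy()
        return (
            float(np.percentile(vals, lo)),
            float(np.percentile(vals, hi)),
        )

    def predict(self, h_grid, params: ModelParameters | None = None) -> pd.DataFrame:
        """Normalized feature predictions at the MAP (or given) parameters."""
        return normalized_predictions(h_grid, params or self.map_params, self.model.constants)

    def _draw_matrix(self, max_draws: int | None) -> np.ndarray:
        theta = self.draws[list(PARAM_NAMES)].to_numpy()
        if max_draws is not None and len(theta) > max_draws:
            idx = np.linspace(0, len(theta) - 1, max_draws).astype(int)
            theta = theta[idx]
        return theta

    def credible_band(
        self,
        h_grid,
        feature: str,
        quantiles: tuple[float, float] = (25.0, 75.0),
        max_draws: int | None = 1000,
    ) -> pd.DataFrame:
        """Pointwise posterior quantile band of one predicted feature.

        Observable features are on the fold-change scale used for fitting;
        derived trajectories (``delta_m``, ``density``,
        ``oxphos_fraction``) are on their natural scale.
        """
        lo, hi = quantiles
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"invalid quantile pair {quantiles}")
        h = np.atleast_1d(np.asarray(h_grid, dtype=float))
        samples = self._trajectory_samples(h, feature, max_draws)
        return pd.DataFrame(
            {
                "h": h,
                "lo": np.percentile(samples, lo, axis=0),
                "hi": np.percentile(samples, hi, axis=0),
            }
        )

    def _trajectory_samples(self, h: np.ndarray, feature: str, max_draws: int | None) -> np.ndarray:
        normalized = feature in OBSERVABLE_FEATURES
        rows = []
        for theta in self._draw_matrix(max_draws):
            params = ModelParameters.from_array(theta)
            pred = (
                normalized_predictions(h, params, self.model.constants)
                if normalized
                else predict_all(h, params, self.model.constants)
            )
            rows.append(pred[feature].to_numpy())
        return np.asarray(rows)

    def derived_posteriors(
        self,
        h_grid,
        quantiles: tuple[float, float] = (25.0, 75.0),
        max_draws: int | None = 1000,
    ) -> dict[str, pd.DataFrame]:
        """Posterior trajectories of the derived quantities.

        Returns per feature (wild-type mtDNA density N+/V, ETC mRNA
        degradation rate delta_m(h), OXPHOS supply fraction) a table of the
        pointwise posterior median and the requested quantile band.
        """
        h = np.atleast_1d(np.asarray(h_grid, dtype=float))
        out: dict[str, pd.DataFrame] = {}
        for feature in ("density", "delta_m", "oxphos_fraction"):
            samples = self._trajectory_samples(h, feature, max_draws)
            band = self.credible_band(h, feature, quantiles, max_draws)
            band["median"] = np.percentile(samples, 50, axis=0)
            out[feature] = band[["h", "median", "lo", "hi"]]
        return out

    def summary(self) -> str:
        """Plain-text fit summary table."""
        q = self.draws[list(PARAM_NAMES)].quantile([0.05, 0.25, 0.75, 0.95]).T
        lines = [
            "Heteroplasmy bioenergetics model — posterior summary",
            f"draws: {len(self.draws)}  seed: {self.seed}  "
            f"max split-Rhat: {self.diagnostics['max_rhat']:.3f}"
            + ("" if self.diagnostics["converged"] else "  [NOT CONVERGED]"),
            f"MAP log-posterior: {self.map_log_posterior:.3f}",
        ]
        if self._has_noise_scale:
            lines.append(
                f"inferred SE multiplier: MAP {self.map_noise_scale:.3f}, "
                f"mean {self.draws['noise_scale'].mean():.3f}"
            )
        lines += [
            "",
            f"{'parameter':<10}{'MAP':>12}{'mean':>12}{'q5':>12}{'q25':>12}{'q75':>12}{'q95':>12}",
            "-" * 82,
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"{name:<10}"
                f"{getattr(self.map_params, name):>12.4g}"
                f"{getattr(self.mean_params, name):>12.4g}"
                f"{q.loc[name, 0.05]:>12.4g}{q.loc[name, 0.25]:>12.4g}"
                f"{q.loc[name, 0.75]:>12.4g}{q.loc[name, 0.95]:>12.4g}"
            )
        return "\n".join(lines)

    def to_summary_dict(self) -> dict:
        """JSON-serializable summary (MAP, mean, intervals, diagnostics)."""
        return {
            "map": self.map_params.to_dict(),
            "posterior_mean": self.mean_params.to_dict(),
            "map_log_posterior": self.map_log_posterior,
            "noise_scale": (
                {
                    "map": self.map_noise_scale,
                    "posterior_mean": float(self.draws["noise_scale"].mean()),
                }
                if self._has_noise_scale
                else None
            ),
            "intervals": {
                "25_75": self.param_intervals((25, 75)).to_dict(orient="index"),
                "5_95": self.param_intervals((5, 95)).to_dict(orient="index"),
            },
            "h_star_interval_25_75": self.h_star_interval((25, 75)),
            "h_star_interval_5_95": self.h_star_interval((5, 95)),
            "diagnostics": self.diagnostics,
            "seed": self.seed,
            "sampler": self.sampler_settings,
            "priors": self.model.priors.describe(),
            "n_data": len(self.model._data),
        }

    def save(self, out_dir: str | Path, band_h_grid=None) -> None:
        """Write posterior_draws.csv, fit_summary.json and per-feature bands."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(out / "posterior_draws.csv", index=False)
        (out / "fit_summary.json").write_text(json.dumps(self.to_summary_dict(), indent=2))
        if band_h_grid is not None:
            for feature in FIT_FEATURES:
                inner = self.credible_band(band_h_grid, feature, (25, 75))
                outer = self.credible_band(band_h_grid, feature, (5, 95))
                band = inner.rename(columns={"lo": "q25", "hi": "q75"})
                band[["q5", "q95"]] = outer[["lo", "hi"]]
                band.to_csv(out / f"band_{feature}.csv", index=False)


# --------------------------------------------------------------------------
# functional front-ends


def run_mcmc(
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> HeteroplasmyResults:
    """Fit a feature table: convenience wrapper over HeteroplasmyModel.fit."""
    return HeteroplasmyModel(table, priors=priors).fit(seed=seed, **fit_kwargs)


def credible_band(result: HeteroplasmyResults, h_grid, feature, quantiles=(25.0, 75.0)):
    return result.credible_band(h_grid, feature, quantiles)


def derived_posteriors(result: HeteroplasmyResults, h_grid, quantiles=(25.0, 75.0)):
    return result.derived_posteriors(h_grid, quantiles)


def map_estimate(result: HeteroplasmyResults) -> ModelParameters:
    return result.map_params
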