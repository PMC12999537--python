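"""Relative and absolute model fit: WAIC, LOOIC, PPMC-SRMR, RT posterior
predictive p-values.

Information criteria are computed from the pointwise posterior
log-likelihood of each person-by-item cell (classes marginalized out), on
the deviance scale: ``WAIC = -2 (lppd - p_WAIC)``, LOOIC via
Pareto-smoothed importance sampling.  Both come in a response-only and a
joint (responses + response times) scope, the latter defined only for RT
variants.

Absolute fit uses posterior predictive model checking: SRMR is the root
mean square difference between the observed item intercorrelations
(Pearson correlations of the raw category scores) and their posterior
predictive means; the RT check is a per-item posterior predictive p-value
for the mean log response time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimate import PosteriorResult, _ChainSampler, make_evaluator, state_pointwise_loglik
from .types import AssessmentData

__all__ = [
    "InformationCriteria",
    "information_criteria",
    "ppmc_srmr",
    "RtPosteriorPredictive",
    "ppp_rt_means",
    "posterior_predictive_replicate",
]


@dataclass
class InformationCriteria:
    """Deviance-scale WAIC/LOOIC plus the log-likelihood at the posterior mean."""

    waic: float
    p_waic: float
    looic: float
    p_loo: float
    log_likelihood: float
    scope: str
    n_bad_pareto_k: int = 0


def waic_loo_from_pointwise(arr: np.ndarray) -> dict:
    """Deviance-scale WAIC and PSIS-LOOIC from a (chains, draws, n_points)
    pointwise log-likelihood array."""
    import arviz as az

    arr = np.asarray(arr, dtype=float)
    flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
    # a placeholder posterior group is required for the PSIS relative
    # efficiency computation
    idata = az.from_dict(
        posterior={"placeholder": np.zeros(flat.shape[:2])},
        log_likelihood={"cell": flat},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        waic_res = az.waic(idata, scale="deviance")
        loo_res = az.loo(idata, scale="deviance")
    return {
        "waic": float(waic_res.elpd_waic),
        "p_waic": float(waic_res.p_waic),
        "looic": float(loo_res.elpd_loo),
        "p_loo": float(loo_res.p_loo),
        "n_bad_pareto_k": int(np.sum(np.asarray(loo_res.pareto_k) > 0.7)),
    }


def information_criteria(
    result: PosteriorResult, data: AssessmentData, scope: str = "response_only"
) -> InformationCriteria:
    """WAIC and PSIS-LOOIC from the stored pointwise log-likelihood arrays.

    ``scope`` is ``response_only`` (RT factors excluded) or ``joint``.
    Unstable importance ratios (Pareto k > 0.7) are counted and reported,
    never hidden.
    """
    if scope not in ("response_only", "joint"):
        raise ValueError("scope must be 'response_only' or 'joint'")
    arr = result.loglik_resp if scope == "response_only" else result.loglik_joint
    if arr is None:
        if scope == "joint":
            raise ValueError("joint criteria are defined only for fitted RT models")
        raise ValueError("pointwise log-likelihood was not stored during fitting")
    res = waic_loo_from_pointwise(arr)
    ll = float(
        state_pointwise_loglik(
            data, result.spec, result.mean_state(), include_rt=(scope == "joint")
        ).sum()
    )
    return InformationCriteria(
        waic=res["waic"],
        p_waic=res["p_waic"],
        looic=res["looic"],
        p_loo=res["p_loo"],
        log_likelihood=ll,
        scope=scope,
        n_bad_pareto_k=res["n_bad_pareto_k"],
    )


def srmr_value(obs_corr: np.ndarray, rep_corrs, per_replicate: bool = False) -> float:
    """SRMR over unique item pairs given the observed correlation matrix and
    a sequence of replicated correlation matrices (or their upper triangles)."""
    obs_corr = np.asarray(obs_corr, dtype=float)
    iu = np.triu_indices(obs_corr.shape[0], 1)
    obs = obs_corr[iu]
    reps = [
        np.asarray(r, dtype=float)[iu] if np.asarray(r).ndim == 2 else np.asarray(r, dtype=float)
        for r in rep_corrs
    ]
    if per_replicate:
        return float(np.mean([np.sqrt(np.mean((obs - r) ** 2)) for r in reps]))
    mean_rep = np.mean(reps, axis=0)
    return float(np.sqrt(np.mean((obs - mean_rep) ** 2)))


def posterior_predictive_replicate(
    ev: _ChainSampler, state: dict, rng: np.random.Generator, with_rt: bool = False
):
    """Simulate one replicated dataset from a posterior draw.

    Person latents are taken from the draw; classes are redrawn from the
    latent response model (or the person-level class proportions), then
    responses and, optionally, response times.
    """
    spec = ev.spec
    N, I = ev.N, ev.I
    if spec.mixture == "cell":
        p = np.exp(ev._class_logp(state))  # (N, I, 3)
        u = rng.random((N, I, 1))
        zeta = (u > np.cumsum(p, axis=-1)[:, :, :-1]).sum(axis=-1)
        pos = zeta  # mixture variants carry all three classes in order
    elif spec.mixture == "person":
        u = rng.random((N, 1))
        zper = (u > np.cumsum(state["pi"])[None, :-1]).sum(axis=1)
        zeta = np.broadcast_to(zper[:, None], (N, I))
        pos = zeta
    else:
        zeta = np.zeros((N, I), dtype=int)
        pos = zeta  # single active class stored at position 0
    catp = np.exp(ev.category_log_probs(state))  # (C, N, I, K+1)
    cellp = np.take_along_axis(catp, pos[None, :, :, None], axis=0)[0]
    u = rng.random((N, I, 1))
    y = (u > np.cumsum(cellp, axis=-1)[:, :, :-1]).sum(axis=-1)
    if not with_rt:
        return y, None
    if not spec.include_rt:
        raise ValueError("RT replication requested for a response-only variant")
    mu_by_class = np.stack(
        [
            state["delta_s"][None, :].repeat(N, 0),
            (state["delta_s"] + state["lam"] * state["delta_f"])[None, :].repeat(N, 0),
            state["delta_f"][None, :].repeat(N, 0),
        ]
    ) - state["nu_phi"] * state["X"][:, ev.pcol][None, :, None]
    mu = np.take_along_axis(mu_by_class, pos[None], axis=0)[0]
    sig = state["sigma_rt"][zeta if spec.mixture != "none" else np.full_like(zeta, spec.classes[0])]
    t = np.exp(rng.normal(mu, sig))
    return y, t


def _draw_states(result: PosteriorResult, n_rep: int, rng: np.random.Generator):
    chains, samples = result.n_chains, result.n_samples
    idx = rng.integers(0, chains * samples, size=n_rep)
    for flat in idx:
        yield result.state_at(flat // samples, flat % samples)


def ppmc_srmr(
    result: PosteriorResult,
    data: AssessmentData,
    n_rep: int = 200,
    seed: int = 0,
    per_replicate: bool = False,
) -> float:
    """Posterior predictive SRMR for the item response intercorrelations.

    Default: average the replicated correlation matrices first, then take
    the root mean square of observed-minus-mean over unique item pairs.
    ``per_replicate=True`` instead averages per-replicate SRMR values.
    Items with zero observed variance are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    ev = make_evaluator(data, result.spec, result.priors, result.mcmc)
    y_obs = data.responses.astype(float)
    keep = y_obs.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {np.sum(~keep)} constant item(s) from SRMR")
    obs = np.corrcoef(y_obs[:, keep], rowvar=False)
    iu = np.triu_indices(obs.shape[0], 1)

    rep_corrs = []
    for state in _draw_states(result, n_rep, rng):
        y_rep, _ = posterior_predictive_replicate(ev, state, rng)
        y_rep = y_rep.astype(float)[:, keep]
        sd = y_rep.std(axis=0)
        if np.any(sd == 0):  # degenerate replicate: perturb to keep the pair count
            y_rep = y_rep + rng.normal(0, 1e-9, y_rep.shape)
        rep_corrs.append(np.corrcoef(y_rep, rowvar=False)[iu])
    return srmr_value(obs, rep_corrs, per_replicate=per_replicate)


@dataclass
class RtPosteriorPredictive:
    """Per-item posterior predictive p-values for mean log response times."""

    per_item: np.ndarray
    mean: float
    range: tuple[float, float]


def ppp_rt_means(
    result: PosteriorResult, data: AssessmentData, n_rep: int = 200, seed: int = 0
) -> RtPosteriorPredictive:
    """Posterior predictive p-value per item: the fraction of replicated
    datasets whose mean log-RT exceeds the observed mean log-RT."""
    if not result.spec.include_rt:
        raise ValueError("RT posterior predictive check requires a fitted RT model")
    rng = np.random.default_rng(seed)
    ev = make_evaluator(data, result.spec, result.priors, result.mcmc)
    obs = np.log(data.times).mean(axis=0)
    exceed = np.zeros(data.n_items)
    for state in _draw_states(result, n_rep, rng):
        _, t_rep = posterior_predictive_replicate(ev, state, rng, with_rt=True)
        exceed += np.log(t_rep).mean(axis=0) > obs
    ppp = exceed / n_rep
    return RtPosteriorPredictive(
        per_item=ppp, mean=float(ppp.mean()), range=(float(ppp.min()), float(ppp.max()))
    )
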