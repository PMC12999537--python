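"""Bayesian estimation of the faking mixture model family.

The sampler is an adaptive blocked Metropolis-within-Gibbs scheme written
directly on the vectorized likelihood: person latents are updated with one
multivariate random-walk proposal per person (accepted person-wise in
parallel), item parameters with per-item block proposals (accepted
item-wise), and global structural parameters with joint proposals.  The
discrete latent class of each person-by-item cell is marginalized out of
the likelihood by an exact three-term log-sum-exp (the default), or
sampled explicitly as in a classical data-augmented Gibbs scheme
(``marginalize=False``) — both target the same posterior.

Positivity constraints (slopes, the proportionality constant, residual
SDs) are handled by sampling on the log scale with the change-of-variable
Jacobian, which is equivalent to truncation at zero for the half-normal
and half-Cauchy priors used.  The latent correlation matrix has a uniform
prior over positive-definite correlation matrices (proposals leaving the
PD cone are rejected).

Seven model variants are supported:

========================  ====  =======  =========================
variant                   RTs   mixture  latent person dimensions
========================  ====  =======  =========================
person_by_item_rt         yes   cell     theta(D), eta, phi, psi
person_by_item_no_rt      no    cell     theta(D), eta, psi
person_mix_rt             yes   person   theta(D), eta, phi
person_mix_no_rt          no    person   theta(D), eta
nonmixture_mnrm           no    none     theta(D), eta
nonmixture_mgpcm          no    none     theta(D)
nonmixture_nrm            no    none     eta
========================  ====  =======  =========================

Person-mixture variants replace the cell-level latent response model with
a person-constant class drawn from a categorical distribution with a flat
Dirichlet prior on the class proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from . import _kernels
from .types import AssessmentData, ItemParameters, PopulationParameters, ScoringWeights

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

VARIANTS: dict[str, dict] = {
    "person_by_item_rt": dict(include_rt=True, mixture="cell", latents=("theta", "eta", "phi", "psi"), classes=(0, 1, 2)),
    "person_by_item_no_rt": dict(include_rt=False, mixture="cell", latents=("theta", "eta", "psi"), classes=(0, 1, 2)),
    "person_mix_rt": dict(include_rt=True, mixture="person", latents=("theta", "eta", "phi"), classes=(0, 1, 2)),
    "person_mix_no_rt": dict(include_rt=False, mixture="person", latents=("theta", "eta"), classes=(0, 1, 2)),
    "nonmixture_mnrm": dict(include_rt=False, mixture="none", latents=("theta", "eta"), classes=(1,)),
    "nonmixture_mgpcm": dict(include_rt=False, mixture="none", latents=("theta",), classes=(0,)),
    "nonmixture_nrm": dict(include_rt=False, mixture="none", latents=("eta",), classes=(2,)),
}


def _log_softmax(a: np.ndarray) -> np.ndarray:
    """Row-wise log-softmax over the last axis (lean replacement for the
    scipy generic, saving temporaries on the sampler's hot path)."""
    m = a.max(axis=-1, keepdims=True)
    z = a - m
    e = np.exp(z)
    s = e.sum(axis=-1, keepdims=True)
    np.log(s, out=s)
    z -= s
    return z


def _lse_last(a: np.ndarray) -> np.ndarray:
    """Log-sum-exp over the last axis."""
    m = a.max(axis=-1)
    out = np.exp(a - m[..., None]).sum(axis=-1)
    np.log(out, out=out)
    out += m
    return out


@dataclass
class ModelSpec:
    """Which member of the model family to fit, plus its scoring weights."""

    variant: str
    weights: ScoringWeights

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}; choose from {sorted(VARIANTS)}")

    @property
    def include_rt(self) -> bool:
        return VARIANTS[self.variant]["include_rt"]

    @property
    def mixture(self) -> str:
        return VARIANTS[self.variant]["mixture"]

    @property
    def classes(self) -> tuple[int, ...]:
        return VARIANTS[self.variant]["classes"]

    @property
    def n_traits(self) -> int:
        return self.weights.n_traits

    @property
    def latent_names(self) -> list[str]:
        names = []
        for part in VARIANTS[self.variant]["latents"]:
            if part == "theta":
                names += [f"theta{d + 1}" for d in range(self.n_traits)]
            else:
                names.append(part)
        return names

    @property
    def n_latent(self) -> int:
        return len(self.latent_names)

    @property
    def has_traits(self) -> bool:
        return any(c in (0, 1) for c in self.classes)

    @property
    def has_faking(self) -> bool:
        return any(c in (1, 2) for c in self.classes)


@dataclass
class PriorConfig:
    """Prior settings: half-normal slopes, diffuse normal intercepts,
    empirically centered time intensities, half-normal proportionality
    constant, half-Cauchy residual SDs, uniform-over-PD correlations."""

    slope_sd: float = 2.0
    intercept_sd: float = 4.0
    delta_sd: float = 1.0
    lambda_sd: float = 0.5
    sigma_scale: float = 1.0

    def __post_init__(self):
        for name in ("slope_sd", "intercept_sd", "delta_sd", "lambda_sd", "sigma_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior scale {name} must be positive")


@dataclass
class McmcConfig:
    """Sampler settings.  Defaults are the reduced desk-scale settings; the
    large-scale reference settings (4 chains, 4000 warmup, 10000 draws) can
    be requested explicitly."""

    chains: int = 2
    warmup: int = 500
    samples: int = 500
    seed: int = 0
    marginalize: bool = True
    algorithm: str = "hmc"  # "hmc" (gradient-based) or "rw" (random-walk blocks)
    n_leapfrog: int = 12
    target_accept: float = 0.8
    store_persons: bool = True
    store_loglik: bool = True
    adapt_target_scalar: float = 0.44
    adapt_target_block: float = 0.25

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 1 or self.samples < 1:
            raise ValueError("chains, warmup and samples must be positive")
        if self.algorithm not in ("hmc", "rw"):
            raise ValueError("algorithm must be 'hmc' or 'rw'")
        if not self.marginalize and self.algorithm == "hmc":
            # explicit class sampling requires the blocked random-walk scheme
            self.algorithm = "rw"


@dataclass
class PosteriorResult:
    """Posterior draws and diagnostics for one fitted model.

    ``draws`` maps parameter names to arrays of shape ``(chains, samples,
    ...)`` in the model's structured layout; ``person_draws`` holds the
    latent person scores ``(chains, samples, N, P)``.  Pointwise
    log-likelihood arrays (per person-by-item cell) support WAIC/LOOIC.
    """

    spec: ModelSpec
    draws: dict[str, np.ndarray]
    person_draws: np.ndarray | None
    loglik_resp: np.ndarray | None
    loglik_joint: np.ndarray | None
    mcmc: McmcConfig
    priors: PriorConfig
    converged: bool = False
    rhat_offenders: list[str] = field(default_factory=list)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def posterior_mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=(0, 1))

    def mean_state(self) -> dict:
        """Posterior means of all parameters, in the sampler's state layout."""
        out = {k: self.posterior_mean(k) for k in self.draws}
        if self.person_draws is not None:
            out["X"] = self.person_draws.mean(axis=(0, 1)).astype(float)
        return out

    def state_at(self, chain: int, idx: int) -> dict:
        """One retained draw as a state dictionary (for predictive checks)."""
        out = {k: np.asarray(v[chain, idx], dtype=float) for k, v in self.draws.items()}
        if self.person_draws is not None:
            out["X"] = np.asarray(self.person_draws[chain, idx], dtype=float)
        return out

    def mean_items(self) -> ItemParameters:
        s = self.mean_state()
        return ItemParameters(
            alpha_trait=s["alpha_trait"], alpha_fake=s["alpha_fake"],
            gamma=s["gamma"], beta=s["beta"], delta_s=s["delta_s"], delta_f=s["delta_f"],
        )

    def mean_population(self) -> PopulationParameters:
        s = self.mean_state()
        corr = _nearest_corr(s["corr"])
        return PopulationParameters(
            corr=corr, nu_phi=float(s["nu_phi"]), nu_psi=float(s["nu_psi"]),
            lam=float(s["lam"]), sigma_rt=s["sigma_rt"],
        )

    def mean_persons(self) -> np.ndarray:
        """Posterior-mean latent person scores, ``(N, P)`` in latent_names order."""
        if self.person_draws is None:
            raise ValueError("person draws were not stored")
        return self.person_draws.mean(axis=(0, 1)).astype(float)


def _nearest_corr(mat: np.ndarray) -> np.ndarray:
    """Symmetrize and unit-diagonalize an averaged correlation matrix, nudging
    it back into the PD cone if averaging left it on the boundary."""
    m = 0.5 * (mat + mat.T)
    np.fill_diagonal(m, 1.0)
    w = np.linalg.eigvalsh(m)
    if w.min() <= 1e-10:
        m = m + (1e-8 - w.min()) * np.eye(m.shape[0])
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
    return m


# ---------------------------------------------------------------------------
# sampler internals


def _halfnormal_logpdf(v, sd):
    return -0.5 * v * v / (sd * sd)


def _halfcauchy_logpdf(v, scale):
    return -np.log1p((v / scale) ** 2)


class _ChainSampler:
    """One MCMC chain of the blocked adaptive Metropolis-within-Gibbs sampler.

    Likelihood caches kept in sync across block updates: the trait and
    faking propensity terms ``tt``/``ft`` (N, I, K+1), the class-conditional
    cell log-likelihoods ``resp_ll``/``rt_ll``/``ccll`` (C, N, I), the
    cell-mixture class log-weights ``clp`` (N, I, 3), and the per-cell
    (or per-person) marginal log-likelihood.
    """

    def __init__(self, data: AssessmentData, spec: ModelSpec, priors: PriorConfig,
                 mcmc: McmcConfig, seed_key: tuple):
        self.data, self.spec, self.priors, self.mcmc = data, spec, priors, mcmc
        self.rng = np.random.default_rng(seed_key)
        self.N, self.I = data.n_persons, data.n_items
        self.D = spec.n_traits
        self.K1 = spec.weights.n_categories
        self.C = len(spec.classes)
        self.classes = spec.classes
        if data.responses.max() >= self.K1:
            raise ValueError("responses exceed the category range of the scoring weights")
        if spec.include_rt and not data.has_times:
            raise ValueError("RT variant requested but the data carry no response times")

        names = spec.latent_names
        self.P = len(names)
        self.tcols = np.array([j for j, nm in enumerate(names) if nm.startswith("theta")], dtype=int)
        self.ecol = names.index("eta") if "eta" in names else None
        self.pcol = names.index("phi") if "phi" in names else None
        self.scol = names.index("psi") if "psi" in names else None

        w = spec.weights
        self.trait_mask = w.trait_loadings  # (I, D)
        self.w_trait = w.trait
        self.w_fake = w.faking
        self.y = np.ascontiguousarray(data.responses.astype(np.int64))
        self._ygather = self.y[None, :, :, None]
        self._dummy = np.zeros((1, 1, 1))
        if data.has_times:
            self.log_t = np.log(data.times)
        self.delta_center = float(self.log_t.mean()) if spec.include_rt else 0.0

        self._init_state()
        self._init_scales()
        self.zeta = None  # complete-data class draws in Gibbs mode

    # -- state ---------------------------------------------------------------

    def _init_state(self):
        """Data-informed, chain-jittered starting values.

        Category intercepts start at the empirical category logits, time
        intensities at per-item mean log-RTs, latent scores at standardized
        observed proxies (scale scores, desirability-weighted scores,
        negated mean log-RT).  Each chain adds independent noise, so chains
        remain overdispersed for the split R-hat check while starting
        inside the dominant posterior basin.
        """
        rng, I, D, K1, P = self.rng, self.I, self.D, self.K1, self.P
        s: dict = {}
        a = np.zeros((I, D))
        a[self.trait_mask] = np.exp(rng.normal(np.log(0.3), 0.3, self.trait_mask.sum()))
        s["alpha_trait"] = a
        s["alpha_fake"] = np.exp(rng.normal(np.log(0.3), 0.3, I))
        counts = np.stack([(self.y == k).sum(axis=0) for k in range(K1)], axis=1)  # (I, K1)
        logit0 = np.log(counts + 1.0) - np.log(counts[:, :1] + 1.0)
        g = logit0[None, :, :] + rng.normal(0.0, 0.3, (3, I, K1))
        g[:, :, 0] = 0.0
        s["gamma"] = g
        b = np.zeros((I, 3))
        b[:, 1] = rng.normal(-0.5, 0.3, I)
        b[:, 2] = rng.normal(-1.0, 0.3, I)
        s["beta"] = b
        if self.spec.include_rt:
            item_logt = self.log_t.mean(axis=0)
            s["delta_s"] = item_logt + rng.normal(0.05, 0.1, I)
            s["delta_f"] = item_logt + rng.normal(-0.05, 0.1, I)
            s["sigma_rt"] = float(self.log_t.std()) * np.exp(rng.normal(-0.2, 0.1, 3))
        else:
            s["delta_s"] = self.delta_center + rng.normal(0.0, 0.2, I)
            s["delta_f"] = self.delta_center + rng.normal(0.0, 0.2, I)
            s["sigma_rt"] = np.exp(rng.normal(np.log(0.5), 0.1, 3))
        s["nu_phi"] = float(np.exp(rng.normal(np.log(0.5), 0.2)))
        s["nu_psi"] = float(np.exp(rng.normal(np.log(1.0), 0.2)))
        s["lam"] = float(np.exp(rng.normal(np.log(0.2), 0.3)))
        s["pi"] = rng.dirichlet(np.full(3, 10.0))
        s["corr"] = np.eye(P)

        def standardize(x):
            sd = x.std()
            return (x - x.mean()) / (sd if sd > 0 else 1.0)

        X = rng.standard_normal((self.N, P)) * 0.5
        yc = self.y - self.y.mean(axis=0)  # (N, I) centered responses
        for d_i, j in enumerate(self.tcols):
            mask = self.trait_mask[:, d_i]
            if mask.any():
                X[:, j] += 0.8 * standardize(yc[:, mask].mean(axis=1))
        if self.ecol is not None or self.scol is not None:
            wdes = np.take_along_axis(self.w_fake[None, :, :], self.y[:, :, None], axis=-1)[..., 0]
            des_score = standardize(wdes.mean(axis=1))
            if self.ecol is not None:
                X[:, self.ecol] += 0.8 * des_score
            if self.scol is not None:
                # desirability-aligned responding is the observable footprint of
                # a pronounced self-presentation strategy; use it as the start
                X[:, self.scol] += 0.8 * des_score
        if self.pcol is not None and self.spec.include_rt:
            X[:, self.pcol] += 0.8 * standardize(-self.log_t.mean(axis=1))
        s["X"] = X
        self.state = s
        self._chol = np.linalg.cholesky(s["corr"])

    # -- likelihood pieces ---------------------------------------------------

    def _terms(self, s, X):
        """Trait and faking propensity terms, each (N, I, K+1) or None."""
        tt = ft = None
        if self.spec.has_traits:
            loaded = s["alpha_trait"][:, :, None] * self.w_trait
            tt = np.einsum("nd,idk->nik", X[:, self.tcols], loaded)
        if self.spec.has_faking:
            ft = X[:, self.ecol, None, None] * (s["alpha_fake"][:, None] * self.w_fake)[None]
        return tt, ft

    def _class_logits(self, s, c, tt, ft):
        g = s["gamma"]
        if c == 0:
            return tt + g[0]
        if c == 1:
            return tt + ft + g[1]
        return ft + g[2]

    def category_log_probs(self, s, X=None, tt=None, ft=None, classes=None) -> np.ndarray:
        """Class-conditional log category probabilities, (C', N, I, K+1)."""
        X = s["X"] if X is None else X
        if (tt is None and self.spec.has_traits) or (ft is None and self.spec.has_faking):
            tt, ft = self._terms(s, X)
        classes = self.classes if classes is None else classes
        out = np.empty((len(classes), self.N, self.I, self.K1))
        for j, c in enumerate(classes):
            out[j] = _log_softmax(self._class_logits(s, c, tt, ft))
        return out

    def _resp_ll(self, s, X=None, tt=None, ft=None, classes=None) -> np.ndarray:
        """Class-conditional response log-likelihood, (C', N, I)."""
        X = s["X"] if X is None else X
        if (tt is None and self.spec.has_traits) or (ft is None and self.spec.has_faking):
            tt, ft = self._terms(s, X)
        classes = self.classes if classes is None else classes
        out = np.empty((len(classes), self.N, self.I))
        g = s["gamma"]
        tt_arr = tt if tt is not None else self._dummy
        ft_arr = ft if ft is not None else self._dummy
        for j, c in enumerate(classes):
            use_tt = c in (0, 1) and tt is not None
            use_ft = c in (1, 2) and ft is not None
            _kernels.resp_loglik(tt_arr, ft_arr, np.ascontiguousarray(g[c]), self.y,
                                 use_tt, use_ft, out[j])
        return out

    def _rt_ll(self, s, X=None, classes=None) -> np.ndarray:
        """Class-conditional log-RT log-density, (C', N, I)."""
        X = s["X"] if X is None else X
        classes = self.classes if classes is None else classes
        speed = s["nu_phi"] * X[:, self.pcol][:, None]
        out = np.empty((len(classes), self.N, self.I))
        mu_by_class = {
            0: s["delta_s"][None, :],
            1: (s["delta_s"] + s["lam"] * s["delta_f"])[None, :],
            2: s["delta_f"][None, :],
        }
        for j, c in enumerate(classes):
            sig = s["sigma_rt"][c]
            z = (self.log_t - (mu_by_class[c] - speed)) / sig
            out[j] = -0.5 * (_LOG_2PI + z * z) - np.log(sig) - self.log_t
        return out

    def _class_logp(self, s, X=None) -> np.ndarray:
        """Cell-mixture class log-probabilities, (N, I, 3)."""
        X = s["X"] if X is None else X
        out = np.empty((self.N, self.I, 3))
        _kernels.class_logp(np.ascontiguousarray(X[:, self.scol]), float(s["nu_psi"]),
                            np.ascontiguousarray(s["beta"]), out)
        return out

    def _ccll(self, s, X=None) -> np.ndarray:
        ll = self._resp_ll(s, X)
        if self.spec.include_rt:
            ll = ll + self._rt_ll(s, X)
        return ll

    def _cell_ll_cellmix(self, clp, ccll):
        out = np.empty((self.N, self.I))
        if self.zeta is not None:
            _kernels.mix3_select(clp, ccll[0], ccll[1], ccll[2], self.zeta, out)
        else:
            _kernels.mix3_marginal(clp, ccll[0], ccll[1], ccll[2], out)
        return out

    def _refresh(self):
        """Recompute all cached likelihood pieces from the current state."""
        s = self.state
        self.tt, self.ft = self._terms(s, s["X"])
        self.resp_ll = self._resp_ll(s, tt=self.tt, ft=self.ft)
        self.rt_ll = self._rt_ll(s) if self.spec.include_rt else None
        self.ccll = self.resp_ll + self.rt_ll if self.rt_ll is not None else self.resp_ll
        if self.spec.mixture == "cell":
            self.clp = self._class_logp(s)
            self.cell_ll = self._cell_ll_cellmix(self.clp, self.ccll)
        elif self.spec.mixture == "person":
            self.S = self.ccll.sum(axis=2)  # (C, N)
            self._refresh_person_ll()
        else:
            self.cell_ll = self.ccll[0]

    def _refresh_person_ll(self):
        logpi = np.log(self.state["pi"])
        if self.zeta is not None:
            self.person_ll = logpi[self.zeta] + np.take_along_axis(self.S, self.zeta[None, :], axis=0)[0]
        else:
            self.person_ll = _lse_last((logpi[:, None] + self.S).T)

    def _refresh_from_caches(self):
        self.ccll = self.resp_ll + self.rt_ll if self.rt_ll is not None else self.resp_ll
        if self.spec.mixture == "cell":
            self.cell_ll = self._cell_ll_cellmix(self.clp, self.ccll)
        elif self.spec.mixture == "person":
            self.S = self.ccll.sum(axis=2)
            self._refresh_person_ll()
        else:
            self.cell_ll = self.ccll[0]

    # -- marginal quantities for storage ------------------------------------

    def marginal_pointwise(self, include_rt: bool) -> np.ndarray:
        """Per-cell marginal log-likelihood (N, I), classes integrated out."""
        ccll = self.ccll if (include_rt or self.rt_ll is None) else self.resp_ll
        if self.spec.mixture == "cell":
            out = np.empty((self.N, self.I))
            _kernels.mix3_marginal(self.clp, ccll[0], ccll[1], ccll[2], out)
            return out
        if self.spec.mixture == "person":
            # Rao-Blackwellized cell likelihood: weight the class-conditional
            # cell likelihoods by the person's posterior class probabilities
            logpi = np.log(self.state["pi"])[:, None]
            logw = logpi + ccll.sum(axis=2)
            logw = logw - _lse_last(logw.T)[None, :]
            return _lse_last(np.moveaxis(logw[:, :, None] + ccll, 0, -1))
        return ccll[0]

    # -- adaptation ----------------------------------------------------------

    def _init_scales(self):
        I = self.I
        self.log_scale = {
            "persons": np.full(self.N, np.log(0.4 / np.sqrt(self.P))),
            "alpha_s": np.full(I, np.log(0.15)),
            "alpha_f": np.full(I, np.log(0.15)),
            "gamma0": np.full(I, np.log(0.2)),
            "gamma1": np.full(I, np.log(0.2)),
            "gamma2": np.full(I, np.log(0.2)),
            "beta": np.full(I, np.log(0.2)),
            "delta": np.full(I, np.log(0.08)),
            "rt_glob": np.log(0.04),
            "nu_psi": np.log(0.1),
            "pi": np.log(0.15),
            "corr": np.log(0.5 / max(self.P, 2)),
        }
        self._acc_count: dict[str, float] = {}
        self._acc_total: dict[str, float] = {}

    def _adapt(self, key, accepted, t, scalar=False):
        target = self.mcmc.adapt_target_scalar if scalar else self.mcmc.adapt_target_block
        self._acc_count[key] = self._acc_count.get(key, 0.0) + float(np.sum(accepted))
        self._acc_total[key] = self._acc_total.get(key, 0.0) + float(np.size(accepted))
        if t >= self.mcmc.warmup:
            return
        rate = 1.5 * (t + 10.0) ** -0.6
        if np.ndim(self.log_scale[key]):
            self.log_scale[key] += rate * (np.asarray(accepted, dtype=float) - target)
        else:
            acc = float(np.mean(accepted))
            self.log_scale[key] += rate * (acc - target)

    # -- item-block updates ---------------------------------------------------

    def _update_item_block(self, key, mutate, t):
        """Generic per-item block update.

        ``mutate(prop_state, step)`` perturbs a shallow copy of the state and
        returns (per-item prior log-ratio, response classes to recompute,
        whether the RT factors changed).  Items are conditionally
        independent given persons and globals, so all items are proposed at
        once and accepted item-wise.
        """
        s = self.state
        step = np.exp(self.log_scale[key])
        prop = dict(s)
        d_prior, resp_classes, rt_changed = mutate(prop, step)
        resp_classes = [c for c in resp_classes if c in self.classes]

        # slope proposals change the cached propensity terms; intercepts do not
        tt_prop, ft_prop = self.tt, self.ft
        if key == "alpha_s":
            loaded = prop["alpha_trait"][:, :, None] * self.w_trait
            tt_prop = np.einsum("nd,idk->nik", s["X"][:, self.tcols], loaded)
        elif key == "alpha_f":
            ft_prop = s["X"][:, self.ecol, None, None] * (prop["alpha_fake"][:, None] * self.w_fake)[None]

        resp_prop = self.resp_ll
        if resp_classes:
            resp_prop = self.resp_ll.copy()
            rows = [self.classes.index(c) for c in resp_classes]
            resp_prop[rows] = self._resp_ll(prop, tt=tt_prop, ft=ft_prop, classes=tuple(resp_classes))
        rt_prop = self.rt_ll
        if rt_changed and self.spec.include_rt:
            rt_prop = self._rt_ll(prop)
        ccll_prop = resp_prop + rt_prop if rt_prop is not None else resp_prop

        if self.spec.mixture == "person" and self.zeta is None:
            # coupled across items: sequential accept using running sums
            logpi = np.log(s["pi"])[:, None]
            acc = np.zeros(self.I, dtype=bool)
            for i in range(self.I):
                S_new = self.S - self.ccll[:, :, i] + ccll_prop[:, :, i]
                pll_new = _lse_last((logpi + S_new).T)
                logr = (pll_new - self.person_ll).sum() + d_prior[i]
                if np.log(self.rng.random()) < logr:
                    acc[i] = True
                    self.S = S_new
                    self.person_ll = pll_new
                    self.ccll[:, :, i] = ccll_prop[:, :, i]
                    self.resp_ll[:, :, i] = resp_prop[:, :, i]
                    if rt_prop is not None:
                        self.rt_ll[:, :, i] = rt_prop[:, :, i]
        elif self.spec.mixture == "person":
            # Gibbs mode: complete-data likelihood factors per cell
            idx = self._zeta_cells()
            d_cell = np.take_along_axis(ccll_prop, idx, axis=0)[0] - \
                np.take_along_axis(self.ccll, idx, axis=0)[0]
            acc = np.log(self.rng.random(self.I)) < d_cell.sum(axis=0) + d_prior
            self.resp_ll[:, :, acc] = resp_prop[:, :, acc]
            if rt_prop is not None:
                self.rt_ll[:, :, acc] = rt_prop[:, :, acc]
            self._refresh_from_caches()
        else:
            if self.spec.mixture == "cell":
                cell_prop = self._cell_ll_cellmix(self.clp, ccll_prop)
            else:
                cell_prop = ccll_prop[0]
            d_ll = (cell_prop - self.cell_ll).sum(axis=0)
            acc = np.log(self.rng.random(self.I)) < d_ll + d_prior
            self.resp_ll[:, :, acc] = resp_prop[:, :, acc]
            if rt_prop is not None:
                self.rt_ll[:, :, acc] = rt_prop[:, :, acc]
            self.ccll = self.resp_ll + self.rt_ll if self.rt_ll is not None else self.resp_ll
            self.cell_ll[:, acc] = cell_prop[:, acc]

        # merge accepted item parameters into the state (and the ft cache,
        # which depends on the faking slopes)
        for k in prop:
            if isinstance(prop[k], np.ndarray) and prop[k] is not s[k]:
                if k == "gamma":
                    s[k][:, acc, :] = prop[k][:, acc, :]
                else:  # (I,) or (I, ...) arrays
                    s[k][acc] = prop[k][acc]
        if key == "alpha_s":
            self.tt[:, acc, :] = tt_prop[:, acc, :]
        elif key == "alpha_f":
            self.ft[:, acc, :] = ft_prop[:, acc, :]
        self._adapt(key, acc, t)

    def _zeta_cells(self) -> np.ndarray:
        """Cell-level class indices (1, N, I) in Gibbs mode."""
        if self.zeta.ndim == 2:
            return self.zeta[None, :, :]
        return np.broadcast_to(self.zeta[None, :, None], (1, self.N, self.I))

    # block mutators -----------------------------------------------------------

    def _mut_alpha_s(self, prop, step):
        s, pr = self.state, self.priors
        at = s["alpha_trait"]
        z = self.rng.standard_normal(at.shape) * step[:, None] * self.trait_mask
        new = np.where(self.trait_mask, at * np.exp(z), at)
        d_prior = np.sum(
            (_halfnormal_logpdf(new, pr.slope_sd) - _halfnormal_logpdf(at, pr.slope_sd) + z)
            * self.trait_mask, axis=1,
        )
        prop["alpha_trait"] = new
        return d_prior, (0, 1), False

    def _mut_alpha_f(self, prop, step):
        s, pr = self.state, self.priors
        af = s["alpha_fake"]
        z = self.rng.standard_normal(self.I) * step
        new = af * np.exp(z)
        d_prior = _halfnormal_logpdf(new, pr.slope_sd) - _halfnormal_logpdf(af, pr.slope_sd) + z
        prop["alpha_fake"] = new
        return d_prior, (1, 2), False

    def _make_mut_gamma(self, c):
        def mut(prop, step):
            s, pr = self.state, self.priors
            g = s["gamma"].copy()
            z = self.rng.standard_normal((self.I, self.K1 - 1)) * step[:, None]
            g[c, :, 1:] = g[c, :, 1:] + z
            d_prior = -0.5 * ((g[c, :, 1:] ** 2).sum(axis=1)
                              - (s["gamma"][c, :, 1:] ** 2).sum(axis=1)) / pr.intercept_sd ** 2
            prop["gamma"] = g
            return d_prior, (c,), False
        return mut

    def _mut_delta(self, prop, step):
        s, pr = self.state, self.priors
        zs = self.rng.standard_normal(self.I) * step
        zf = self.rng.standard_normal(self.I) * step
        ds, df = s["delta_s"] + zs, s["delta_f"] + zf
        d_prior = (-0.5 * ((ds - self.delta_center) ** 2 - (s["delta_s"] - self.delta_center) ** 2)
                   - 0.5 * ((df - self.delta_center) ** 2 - (s["delta_f"] - self.delta_center) ** 2)) / pr.delta_sd ** 2
        prop["delta_s"], prop["delta_f"] = ds, df
        return d_prior, (), True

    # class-weight updates ------------------------------------------------------

    def _update_beta(self, t):
        s, pr = self.state, self.priors
        step = np.exp(self.log_scale["beta"])
        b = s["beta"].copy()
        z = self.rng.standard_normal((self.I, 2)) * step[:, None]
        b[:, 1:] = b[:, 1:] + z
        d_prior = -0.5 * ((b[:, 1:] ** 2).sum(axis=1) - (s["beta"][:, 1:] ** 2).sum(axis=1)) / pr.intercept_sd ** 2
        clp_prop = self._class_logp(dict(s, beta=b))
        cell_prop = self._cell_ll_cellmix(clp_prop, self.ccll)
        d_ll = (cell_prop - self.cell_ll).sum(axis=0)
        acc = np.log(self.rng.random(self.I)) < d_ll + d_prior
        s["beta"][acc] = b[acc]
        self.clp[:, acc, :] = clp_prop[:, acc, :]
        self.cell_ll[:, acc] = cell_prop[:, acc]
        self._adapt("beta", acc, t)

    def _update_nu_psi(self, t):
        s = self.state
        step = float(np.exp(self.log_scale["nu_psi"]))
        z = self.rng.standard_normal() * step
        new = s["nu_psi"] * np.exp(z)
        clp_prop = self._class_logp(dict(s, nu_psi=new))
        cell_prop = self._cell_ll_cellmix(clp_prop, self.ccll)
        d_prior = _halfnormal_logpdf(new, self.priors.slope_sd) - \
            _halfnormal_logpdf(s["nu_psi"], self.priors.slope_sd) + z
        acc = np.log(self.rng.random()) < (cell_prop - self.cell_ll).sum() + d_prior
        if acc:
            s["nu_psi"] = new
            self.clp = clp_prop
            self.cell_ll = cell_prop
        self._adapt("nu_psi", acc, t, scalar=True)

    # global updates -------------------------------------------------------------

    def _update_rt_globals(self, t):
        s, pr = self.state, self.priors
        step = float(np.exp(self.log_scale["rt_glob"]))
        z = self.rng.standard_normal(5) * step
        new_nu = s["nu_phi"] * np.exp(z[0])
        new_lam = s["lam"] * np.exp(z[1])
        new_sig = s["sigma_rt"] * np.exp(z[2:])
        prop = dict(s, nu_phi=new_nu, lam=new_lam, sigma_rt=new_sig)
        rt_prop = self._rt_ll(prop)
        ccll_prop = self.resp_ll + rt_prop
        d_prior = (
            _halfnormal_logpdf(new_nu, pr.slope_sd) - _halfnormal_logpdf(s["nu_phi"], pr.slope_sd) + z[0]
            + _halfnormal_logpdf(new_lam, pr.lambda_sd) - _halfnormal_logpdf(s["lam"], pr.lambda_sd) + z[1]
            + np.sum(_halfcauchy_logpdf(new_sig, pr.sigma_scale)
                     - _halfcauchy_logpdf(s["sigma_rt"], pr.sigma_scale) + z[2:])
        )
        if self.spec.mixture == "cell":
            cell_prop = self._cell_ll_cellmix(self.clp, ccll_prop)
            d_ll = (cell_prop - self.cell_ll).sum()
        elif self.spec.mixture == "person":
            if self.zeta is not None:
                idx = self._zeta_cells()
                d_ll = (np.take_along_axis(ccll_prop, idx, axis=0)
                        - np.take_along_axis(self.ccll, idx, axis=0)).sum()
            else:
                S_prop = ccll_prop.sum(axis=2)
                pll_prop = _lse_last((np.log(s["pi"])[:, None] + S_prop).T)
                d_ll = (pll_prop - self.person_ll).sum()
        else:
            d_ll = (ccll_prop[0] - self.cell_ll).sum()
        acc = np.log(self.rng.random()) < d_ll + d_prior
        if acc:
            s["nu_phi"], s["lam"], s["sigma_rt"] = new_nu, new_lam, new_sig
            self.rt_ll = rt_prop
            self._refresh_from_caches()
        self._adapt("rt_glob", acc, t, scalar=True)

    def _update_pi(self, t):
        s = self.state
        if self.zeta is not None:  # conjugate Dirichlet update
            counts = np.bincount(self.zeta, minlength=3)
            s["pi"] = self.rng.dirichlet(1.0 + counts)
            self._refresh_person_ll()
            return
        step = float(np.exp(self.log_scale["pi"]))
        a = np.log(s["pi"] / s["pi"][0])  # (0, a1, a2) logit representation
        a_new = a.copy()
        a_new[1:] += self.rng.standard_normal(2) * step
        pi_new = np.exp(a_new - _lse_last(a_new[None, :])[0])
        pll_prop = _lse_last((np.log(pi_new)[:, None] + self.S).T)
        # flat Dirichlet prior plus softmax Jacobian (product of proportions)
        d_prior = np.sum(np.log(pi_new)) - np.sum(np.log(s["pi"]))
        acc = np.log(self.rng.random()) < (pll_prop - self.person_ll).sum() + d_prior
        if acc:
            s["pi"] = pi_new
            self.person_ll = pll_prop
        self._adapt("pi", acc, t, scalar=True)

    def _update_persons(self, t):
        s = self.state
        step = np.exp(self.log_scale["persons"])[:, None]
        X = s["X"]
        X_prop = X + self.rng.standard_normal(X.shape) * step
        tt_prop, ft_prop = self._terms(s, X_prop)
        resp_prop = self._resp_ll(s, X_prop, tt=tt_prop, ft=ft_prop)
        rt_prop = self._rt_ll(s, X_prop) if self.spec.include_rt else None
        ccll_prop = resp_prop + rt_prop if rt_prop is not None else resp_prop
        if self.spec.mixture == "cell":
            clp_prop = self._class_logp(s, X_prop)
            cell_prop = self._cell_ll_cellmix(clp_prop, ccll_prop)
            d_ll = (cell_prop - self.cell_ll).sum(axis=1)
        elif self.spec.mixture == "person":
            S_prop = ccll_prop.sum(axis=2)
            logpi = np.log(s["pi"])
            if self.zeta is not None:
                pll_prop = logpi[self.zeta] + np.take_along_axis(S_prop, self.zeta[None, :], axis=0)[0]
            else:
                pll_prop = _lse_last((logpi[:, None] + S_prop).T)
            d_ll = pll_prop - self.person_ll
        else:
            cell_prop = ccll_prop[0]
            d_ll = (cell_prop - self.cell_ll).sum(axis=1)
        # multivariate normal prior per person
        q_old = solve_triangular(self._chol, X.T, lower=True)
        q_new = solve_triangular(self._chol, X_prop.T, lower=True)
        d_prior = -0.5 * ((q_new ** 2).sum(axis=0) - (q_old ** 2).sum(axis=0))
        acc = np.log(self.rng.random(self.N)) < d_ll + d_prior
        X[acc] = X_prop[acc]
        if tt_prop is not None:
            self.tt[acc] = tt_prop[acc]
        if ft_prop is not None:
            self.ft[acc] = ft_prop[acc]
        self.resp_ll[:, acc, :] = resp_prop[:, acc, :]
        if rt_prop is not None:
            self.rt_ll[:, acc, :] = rt_prop[:, acc, :]
        self.ccll = self.resp_ll + self.rt_ll if self.rt_ll is not None else self.resp_ll
        if self.spec.mixture == "cell":
            self.clp[acc] = clp_prop[acc]
            self.cell_ll = self._cell_ll_cellmix(self.clp, self.ccll)
        elif self.spec.mixture == "person":
            self.S[:, acc] = S_prop[:, acc]
            self.person_ll[acc] = pll_prop[acc]
        else:
            self.cell_ll = self.ccll[0]
        self._adapt("persons", acc, t)

    def _update_corr(self, t):
        if self.P < 2:
            return
        s = self.state
        step = float(np.exp(self.log_scale["corr"]))
        P = self.P
        iu = np.triu_indices(P, 1)
        new = s["corr"].copy()
        new[iu] = new[iu] + self.rng.standard_normal(len(iu[0])) * step
        new.T[iu] = new[iu]
        if np.any(np.abs(new[iu]) >= 1.0):
            self._adapt("corr", False, t, scalar=True)
            return
        try:
            chol_new = np.linalg.cholesky(new)
        except np.linalg.LinAlgError:
            self._adapt("corr", False, t, scalar=True)
            return
        X = s["X"]
        q_old = solve_triangular(self._chol, X.T, lower=True)
        q_new = solve_triangular(chol_new, X.T, lower=True)
        d_ll = (-np.log(np.diag(chol_new)).sum() + np.log(np.diag(self._chol)).sum()) * self.N \
            - 0.5 * ((q_new ** 2).sum() - (q_old ** 2).sum())
        acc = np.log(self.rng.random()) < d_ll  # uniform prior over PD matrices
        if acc:
            s["corr"] = new
            self._chol = chol_new
        self._adapt("corr", acc, t, scalar=True)

    # Hamiltonian updates -------------------------------------------------------
    #
    # The continuous parameters (person latents, item parameters, global
    # slopes/scales, class proportions) are updated jointly by HMC on the
    # unconstrained scale, with analytic gradients of the class-marginalized
    # log-posterior.  The correlation matrix keeps its Metropolis step (its
    # conditional given the latents is cheap and well-behaved), and the
    # likelihood-invariant parameter-expansion moves run after each
    # trajectory to decorrelate latent scales/locations from their slopes
    # and intercepts.

    def _build_layout(self):
        """Slices of the unconstrained parameter vector, in pack order."""
        spec = self.spec
        sizes = [("X", self.N * self.P)]
        if spec.has_traits:
            sizes.append(("alpha_trait", int(self.trait_mask.sum())))
        if spec.has_faking:
            sizes.append(("alpha_fake", self.I))
        sizes.append(("gamma", self.C * self.I * (self.K1 - 1)))
        if spec.mixture == "cell":
            sizes += [("beta", 2 * self.I), ("nu_psi", 1)]
        if spec.mixture == "person":
            sizes.append(("pi", 2))
        if spec.include_rt:
            sizes += [("delta_s", self.I), ("delta_f", self.I),
                      ("nu_phi", 1), ("lam", 1), ("sigma_rt", 3)]
        self._slices = {}
        off = 0
        for name, n in sizes:
            self._slices[name] = slice(off, off + n)
            off += n
        self._dim = off

    def _pack(self, s) -> np.ndarray:
        v = np.empty(self._dim)
        sl = self._slices
        v[sl["X"]] = s["X"].ravel()
        if "alpha_trait" in sl:
            v[sl["alpha_trait"]] = np.log(s["alpha_trait"][self.trait_mask])
        if "alpha_fake" in sl:
            v[sl["alpha_fake"]] = np.log(s["alpha_fake"])
        v[sl["gamma"]] = s["gamma"][list(self.classes)][:, :, 1:].ravel()
        if "beta" in sl:
            v[sl["beta"]] = s["beta"][:, 1:].ravel()
            v[sl["nu_psi"]] = np.log(s["nu_psi"])
        if "pi" in sl:
            v[sl["pi"]] = np.log(s["pi"][1:] / s["pi"][0])
        if "delta_s" in sl:
            v[sl["delta_s"]] = s["delta_s"]
            v[sl["delta_f"]] = s["delta_f"]
            v[sl["nu_phi"]] = np.log(s["nu_phi"])
            v[sl["lam"]] = np.log(s["lam"])
            v[sl["sigma_rt"]] = np.log(s["sigma_rt"])
        return v

    def _unpack(self, v) -> dict:
        s = dict(self.state)
        sl = self._slices
        s["X"] = v[sl["X"]].reshape(self.N, self.P)
        if "alpha_trait" in sl:
            a = np.zeros((self.I, self.D))
            a[self.trait_mask] = np.exp(v[sl["alpha_trait"]])
            s["alpha_trait"] = a
        if "alpha_fake" in sl:
            s["alpha_fake"] = np.exp(v[sl["alpha_fake"]])
        g = self.state["gamma"].copy()
        g[list(self.classes), :, 1:] = v[sl["gamma"]].reshape(self.C, self.I, self.K1 - 1)
        s["gamma"] = g
        if "beta" in sl:
            b = np.zeros((self.I, 3))
            b[:, 1:] = v[sl["beta"]].reshape(self.I, 2)
            s["beta"] = b
            s["nu_psi"] = float(np.exp(v[sl["nu_psi"]][0]))
        if "pi" in sl:
            a = np.concatenate([[0.0], v[sl["pi"]]])
            e = np.exp(a - a.max())
            s["pi"] = e / e.sum()
        if "delta_s" in sl:
            s["delta_s"] = v[sl["delta_s"]].copy()
            s["delta_f"] = v[sl["delta_f"]].copy()
            s["nu_phi"] = float(np.exp(v[sl["nu_phi"]][0]))
            s["lam"] = float(np.exp(v[sl["lam"]][0]))
            s["sigma_rt"] = np.exp(v[sl["sigma_rt"]])
        return s

    def _logpost_and_grad(self, v):
        """Marginalized log-posterior and its gradient on the unconstrained scale.

        States a diverged trajectory pushes outside the numerically
        representable region return -inf (rejected), never raise.
        """
        if not np.all(np.isfinite(v)) or np.any(np.abs(v) > 1e6):
            return -np.inf, np.zeros(self._dim)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                return self._logpost_and_grad_impl(v)
            except (ZeroDivisionError, FloatingPointError):
                return -np.inf, np.zeros(self._dim)

    def _logpost_and_grad_impl(self, v):
        spec, pr, sl = self.spec, self.priors, self._slices
        s = self._unpack(v)
        N, I, K1, C = self.N, self.I, self.K1, self.C
        X = s["X"]
        grad = np.zeros(self._dim)

        tt, ft = self._terms(s, X)
        tt_arr = tt if tt is not None else self._dummy
        ft_arr = ft if ft is not None else self._dummy
        # class-conditional log-likelihood components and softmax probs
        p_full = np.empty((C, N, I, K1))
        ccll = np.empty((C, N, I))
        g = s["gamma"]
        for j, c in enumerate(self.classes):
            _kernels.resp_prob_loglik(
                tt_arr, ft_arr, np.ascontiguousarray(g[c]), self.y,
                c in (0, 1) and tt is not None, c in (1, 2) and ft is not None,
                p_full[j], ccll[j],
            )
        if spec.include_rt:
            log_t = self.log_t
            speed = s["nu_phi"] * X[:, self.pcol][:, None]
            mu_by_class = {
                0: s["delta_s"][None, :],
                1: (s["delta_s"] + s["lam"] * s["delta_f"])[None, :],
                2: s["delta_f"][None, :],
            }
            z_rt = np.empty((C, N, I))
            for j, c in enumerate(self.classes):
                sig = s["sigma_rt"][c]
                z_rt[j] = (log_t - (mu_by_class[c] - speed)) / sig
                ccll[j] += -0.5 * (_LOG_2PI + z_rt[j] ** 2) - np.log(sig) - log_t

        # mixture weights and responsibilities (cell weights r, (C, N, I))
        if spec.mixture == "cell":
            clp = self._class_logp(s, X)
            cell_ll = np.empty((N, I))
            r3 = np.empty((N, I, 3))
            _kernels.mix3_resp(clp, ccll[0], ccll[1], ccll[2], cell_ll, r3)
            ll = float(cell_ll.sum())
            r = np.ascontiguousarray(np.moveaxis(r3, -1, 0))
        elif spec.mixture == "person":
            S = ccll.sum(axis=2)  # (C, N)
            a = np.log(s["pi"])[:, None] + S
            pll = _lse_last(a.T)
            ll = float(pll.sum())
            r_person = np.exp(a - pll[None, :])  # (C, N)
            r = np.ascontiguousarray(np.broadcast_to(r_person[:, :, None], (C, N, I)))
        else:
            ll = float(ccll[0].sum())
            r = np.ones((1, N, I))

        # ---- response-model gradients (fused per-class kernel)
        ggrad = np.zeros((C, I, K1))
        xg_theta = np.zeros((N, max(self.D, 1)))
        ag = np.zeros((I, max(self.D, 1)))
        xg_eta = np.zeros(N)
        fg = np.zeros(I)
        theta_arr = np.ascontiguousarray(X[:, self.tcols]) if spec.has_traits else np.zeros((N, 1))
        eta_arr = np.ascontiguousarray(X[:, self.ecol]) if spec.has_faking else np.zeros(N)
        wt_arr = self.w_trait if spec.has_traits else np.zeros((I, 1, K1))
        at_arr = s["alpha_trait"] if spec.has_traits else np.zeros((I, 1))
        af_arr = s["alpha_fake"] if spec.has_faking else np.zeros(I)
        for j, c in enumerate(self.classes):
            _kernels.resp_grad(
                p_full[j], r[j], self.y, wt_arr, at_arr, theta_arr,
                self.w_fake, af_arr, eta_arr,
                c in (0, 1) and spec.has_traits, c in (1, 2) and spec.has_faking,
                ggrad[j], xg_theta, ag, xg_eta, fg,
            )
        gg = ggrad[:, :, 1:] - g[list(self.classes), :, 1:] / pr.intercept_sd ** 2
        grad[sl["gamma"]] = gg.ravel()
        Xgrad = np.zeros((N, self.P))
        if spec.has_traits:
            Xgrad[:, self.tcols] = xg_theta[:, : self.D]
            agrad = ag[:, : self.D] * s["alpha_trait"]  # chain rule to the log scale
            agrad += 1.0 - s["alpha_trait"] ** 2 / pr.slope_sd ** 2  # prior + Jacobian
            grad[sl["alpha_trait"]] = agrad[self.trait_mask]
        if spec.has_faking:
            Xgrad[:, self.ecol] += xg_eta
            fgrad = fg * s["alpha_fake"]
            fgrad += 1.0 - s["alpha_fake"] ** 2 / pr.slope_sd ** 2
            grad[sl["alpha_fake"]] = fgrad

        # ---- RT-model gradients
        if spec.include_rt:
            W = r * z_rt / s["sigma_rt"][list(self.classes), None, None]  # (C, N, I)
            Wsum = W.sum(axis=0)
            grad[sl["delta_s"]] = (W[0] + W[1]).sum(axis=0) \
                - (s["delta_s"] - self.delta_center) / pr.delta_sd ** 2
            grad[sl["delta_f"]] = (W[2] + s["lam"] * W[1]).sum(axis=0) \
                - (s["delta_f"] - self.delta_center) / pr.delta_sd ** 2
            lam_grad = float((W[1] * s["delta_f"][None, :]).sum()) * s["lam"]
            grad[sl["lam"]] = lam_grad + 1.0 - s["lam"] ** 2 / pr.lambda_sd ** 2
            Xgrad[:, self.pcol] = -s["nu_phi"] * Wsum.sum(axis=1)
            nu_grad = -float((X[:, self.pcol] * Wsum.sum(axis=1)).sum()) * s["nu_phi"]
            grad[sl["nu_phi"]] = nu_grad + 1.0 - s["nu_phi"] ** 2 / pr.slope_sd ** 2
            sg = np.array([
                float((r[j] * (z_rt[j] ** 2 - 1.0)).sum()) for j in range(C)
            ])  # d/d sigma * sigma (log-scale chain rule folds the 1/sigma)
            ratio2 = (s["sigma_rt"] / pr.sigma_scale) ** 2
            grad[sl["sigma_rt"]] = sg + 1.0 - 2.0 * ratio2 / (1.0 + ratio2)

        # ---- latent-response-model gradients
        if spec.mixture == "cell":
            pi_s = np.exp(clp)  # structural class probabilities (N, I, 3)
            Dm = np.moveaxis(r, 0, -1) - pi_s
            bgrad = Dm.sum(axis=0)[:, 1:] - s["beta"][:, 1:] / pr.intercept_sd ** 2
            grad[sl["beta"]] = bgrad.ravel()
            psi_load = Dm[:, :, 1] + 2.0 * Dm[:, :, 2]  # (N, I)
            Xgrad[:, self.scol] = s["nu_psi"] * psi_load.sum(axis=1)
            npsi_grad = float((X[:, self.scol] * psi_load.sum(axis=1)).sum()) * s["nu_psi"]
            grad[sl["nu_psi"]] = npsi_grad + 1.0 - s["nu_psi"] ** 2 / pr.slope_sd ** 2
        elif spec.mixture == "person":
            r_person = r[:, :, 0]  # (C, N)
            pig = r_person.sum(axis=1) - N * s["pi"]
            pig += 1.0 - 3.0 * s["pi"]  # flat Dirichlet + softmax Jacobian
            grad[sl["pi"]] = pig[1:]

        # ---- person prior (MVN with the current correlation matrix)
        q = solve_triangular(self._chol, X.T, lower=True)
        prior_X = -0.5 * float((q ** 2).sum())
        Xgrad -= solve_triangular(self._chol, q, lower=True, trans=1).T
        grad[sl["X"]] += Xgrad.ravel()

        # ---- remaining prior terms in the log-posterior value
        lp = ll + prior_X
        lp += -0.5 * float((s["gamma"][list(self.classes), :, 1:] ** 2).sum()) / pr.intercept_sd ** 2
        if spec.has_traits:
            a = s["alpha_trait"][self.trait_mask]
            lp += float(np.sum(_halfnormal_logpdf(a, pr.slope_sd) + np.log(a)))
        if spec.has_faking:
            a = s["alpha_fake"]
            lp += float(np.sum(_halfnormal_logpdf(a, pr.slope_sd) + np.log(a)))
        if spec.mixture == "cell":
            lp += -0.5 * float((s["beta"][:, 1:] ** 2).sum()) / pr.intercept_sd ** 2
            lp += float(_halfnormal_logpdf(s["nu_psi"], pr.slope_sd) + np.log(s["nu_psi"]))
        if spec.mixture == "person":
            lp += float(np.sum(np.log(s["pi"])))
        if spec.include_rt:
            lp += -0.5 * float(((s["delta_s"] - self.delta_center) ** 2).sum()) / pr.delta_sd ** 2
            lp += -0.5 * float(((s["delta_f"] - self.delta_center) ** 2).sum()) / pr.delta_sd ** 2
            lp += float(_halfnormal_logpdf(s["nu_phi"], pr.slope_sd) + np.log(s["nu_phi"]))
            lp += float(_halfnormal_logpdf(s["lam"], pr.lambda_sd) + np.log(s["lam"]))
            lp += float(np.sum(_halfcauchy_logpdf(s["sigma_rt"], pr.sigma_scale)
                               + np.log(s["sigma_rt"])))
        return lp, grad

    def _hmc_update(self, t):
        mcmc = self.mcmc
        q0 = self._pack(self.state)
        lp0, g0 = self._logpost_and_grad(q0)
        mass = self._hmc_mass
        p0 = self.rng.standard_normal(self._dim) * np.sqrt(mass)
        eps = float(np.exp(self._hmc_log_eps)) * float(
            np.exp(0.2 * self.rng.standard_normal())
        )
        L = max(2, int(mcmc.n_leapfrog * (0.75 + 0.5 * self.rng.random())))
        q, p, g = q0.copy(), p0.copy(), g0
        lp = lp0
        diverged = False
        for _ in range(L):
            p = p + 0.5 * eps * g
            q = q + eps * p / mass
            lp, g = self._logpost_and_grad(q)
            if not np.isfinite(lp):
                diverged = True
                break
            p = p + 0.5 * eps * g
        if diverged:
            acc_prob = 0.0
        else:
            h0 = -lp0 + 0.5 * float((p0 ** 2 / mass).sum())
            h1 = -lp + 0.5 * float((p ** 2 / mass).sum())
            dh = h0 - h1
            acc_prob = 1.0 if dh >= 0 else (0.0 if dh < -50 else float(np.exp(dh)))
        accept = self.rng.random() < acc_prob
        if accept:
            self.state = self._unpack(q)
        # step-size adaptation and mass estimation during warmup
        self._acc_count["hmc"] = self._acc_count.get("hmc", 0.0) + acc_prob
        self._acc_total["hmc"] = self._acc_total.get("hmc", 0.0) + 1.0
        W = mcmc.warmup
        if t < W:
            rate = 1.2 * (t + 10.0) ** -0.6
            self._hmc_log_eps += rate * (acc_prob - mcmc.target_accept)
            if W // 4 <= t < (3 * W) // 4:
                cur = self._pack(self.state)
                self._hmc_msum += cur
                self._hmc_msqsum += cur ** 2
                self._hmc_mcount += 1
            if t == (3 * W) // 4 and self._hmc_mcount > 10:
                var = self._hmc_msqsum / self._hmc_mcount - (self._hmc_msum / self._hmc_mcount) ** 2
                var = np.clip(var, 1e-4, 25.0)
                self._hmc_mass = 1.0 / var

    def _init_hmc(self):
        self._build_layout()
        self._hmc_mass = np.ones(self._dim)
        self._hmc_log_eps = np.log(0.01)
        self._hmc_msum = np.zeros(self._dim)
        self._hmc_msqsum = np.zeros(self._dim)
        self._hmc_mcount = 0

    # parameter-expansion moves -------------------------------------------------
    #
    # The posterior couples each latent column to the slopes that multiply it
    # (scale) and to the intercepts that can absorb its mean (location);
    # plain random-walk updates crawl along these ridges.  The moves below
    # rescale / shift a whole latent column together with its compensating
    # parameters, leaving the likelihood exactly invariant, so acceptance
    # involves only priors and Jacobians.  Caches of final log-likelihood
    # values stay valid; only the propensity-term caches need adjusting for
    # location moves.

    def _scale_groups(self):
        groups = []
        for d_i, j in enumerate(self.tcols):
            groups.append((f"scale_theta{d_i + 1}", j, "alpha_trait", d_i))
        if self.ecol is not None and self.spec.has_faking:
            groups.append(("scale_eta", self.ecol, "alpha_fake", None))
        if self.pcol is not None:
            groups.append(("scale_phi", self.pcol, "nu_phi", None))
        if self.scol is not None:
            groups.append(("scale_psi", self.scol, "nu_psi", None))
        return groups

    def _mvn_prior_delta(self, X_new, X_old):
        q_new = solve_triangular(self._chol, X_new.T, lower=True)
        q_old = solve_triangular(self._chol, X_old.T, lower=True)
        return -0.5 * ((q_new ** 2).sum() - (q_old ** 2).sum())

    def _update_scale_moves(self, t):
        s, pr = self.state, self.priors
        for key, j, slope_key, d_i in self._scale_groups():
            if key not in self.log_scale:
                self.log_scale[key] = np.log(0.05)
            eps = float(np.exp(self.log_scale[key]))
            c = float(np.exp(eps * self.rng.standard_normal()))
            X_new = s["X"].copy()
            X_new[:, j] *= c
            if slope_key == "alpha_trait":
                mask = self.trait_mask[:, d_i]
                old = s["alpha_trait"][mask, d_i]
                sd = pr.slope_sd
            elif slope_key == "alpha_fake":
                old = s["alpha_fake"]
                sd = pr.slope_sd
            else:
                old = np.atleast_1d(s[slope_key])
                sd = pr.slope_sd
            new = old / c
            logr = (
                self._mvn_prior_delta(X_new, s["X"])
                + np.sum(_halfnormal_logpdf(new, sd) - _halfnormal_logpdf(old, sd))
                + (self.N - old.size) * np.log(c)
            )
            acc = np.log(self.rng.random()) < logr
            if acc:
                s["X"][:, j] = X_new[:, j]
                if slope_key == "alpha_trait":
                    s["alpha_trait"][mask, d_i] = new
                elif slope_key == "alpha_fake":
                    s["alpha_fake"] = new
                else:
                    s[slope_key] = float(new[0])
                # the likelihood and all final-loglik caches are invariant
            self._adapt(key, acc, t, scalar=True)

    def _update_location_moves(self, t):
        s, pr = self.state, self.priors
        moves = []
        for d_i, j in enumerate(self.tcols):
            moves.append((f"loc_theta{d_i + 1}", "theta", j, d_i))
        if self.ecol is not None and self.spec.has_faking:
            moves.append(("loc_eta", "eta", self.ecol, None))
        if self.scol is not None and self.spec.mixture == "cell":
            moves.append(("loc_psi", "psi", self.scol, None))
        isd2 = pr.intercept_sd ** 2
        for key, kind, j, d_i in moves:
            if key not in self.log_scale:
                self.log_scale[key] = np.log(0.05)
            eps = float(np.exp(self.log_scale[key]))
            m = eps * self.rng.standard_normal()
            X_new = s["X"].copy()
            X_new[:, j] += m
            d_prior = self._mvn_prior_delta(X_new, s["X"])
            if kind == "theta":
                shift = s["alpha_trait"][:, d_i, None] * self.w_trait[:, d_i, :] * m  # (I, K1)
                g_new = s["gamma"].copy()
                for c in (0, 1):
                    if c in self.classes:
                        g_new[c] -= shift
                        d_prior += -0.5 * ((g_new[c, :, 1:] ** 2).sum()
                                           - (s["gamma"][c, :, 1:] ** 2).sum()) / isd2
            elif kind == "eta":
                shift = s["alpha_fake"][:, None] * (self.w_fake - self.w_fake[:, :1]) * m
                g_new = s["gamma"].copy()
                for c in (1, 2):
                    if c in self.classes:
                        g_new[c] -= shift
                        d_prior += -0.5 * ((g_new[c, :, 1:] ** 2).sum()
                                           - (s["gamma"][c, :, 1:] ** 2).sum()) / isd2
            else:  # psi
                b_new = s["beta"].copy()
                b_new[:, 1] -= s["nu_psi"] * m
                b_new[:, 2] -= 2.0 * s["nu_psi"] * m
                d_prior += -0.5 * ((b_new[:, 1:] ** 2).sum() - (s["beta"][:, 1:] ** 2).sum()) / isd2
            acc = np.log(self.rng.random()) < d_prior
            if acc:
                s["X"][:, j] = X_new[:, j]
                if kind == "theta":
                    s["gamma"] = g_new
                    if self.tt is not None:
                        self.tt += s["alpha_trait"][None, :, d_i, None] * self.w_trait[None, :, d_i, :] * m
                elif kind == "eta":
                    s["gamma"] = g_new
                    if self.ft is not None:
                        self.ft += (s["alpha_fake"][:, None] * self.w_fake)[None] * m
                else:
                    s["beta"] = b_new
                # final log-likelihood caches are invariant (softmax shift)
            self._adapt(key, acc, t, scalar=True)

    def _draw_zeta(self):
        """Gibbs mode: sample latent classes from their full conditional."""
        s = self.state
        if self.spec.mixture == "cell":
            comp = self._class_logp(s) + np.moveaxis(self.ccll, 0, -1)
            p = np.exp(comp - _lse_last(comp)[..., None])
            u = self.rng.random((self.N, self.I, 1))
            self.zeta = (u > np.cumsum(p, axis=-1)[:, :, :-1]).sum(axis=-1)
        else:
            logw = np.log(s["pi"])[:, None] + self.S
            p = np.exp(logw - _lse_last(logw.T)[None, :]).T  # (N, C)
            u = self.rng.random((self.N, 1))
            self.zeta = (u > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
        self._refresh_from_caches()

    # -- main loop -----------------------------------------------------------

    def run(self):
        spec, mcmc = self.spec, self.mcmc
        hmc = mcmc.algorithm == "hmc"
        if hmc:
            self._init_hmc()
            self.tt = self.ft = None
        else:
            self._refresh()
        n_iter = mcmc.warmup + mcmc.samples
        store: dict[str, list] = {k: [] for k in self._stored_keys()}
        persons_store, ll_resp, ll_joint = [], [], []

        for t in range(n_iter):
            if hmc:
                self._hmc_update(t)
                # interleave cheap per-item Metropolis sweeps for the
                # slowest-mixing families (class-specific intercepts and the
                # class weights) between trajectories
                self._refresh()
                for c in (0, 1, 2):
                    if c in spec.classes:
                        self._update_item_block(f"gamma{c}", self._make_mut_gamma(c), t)
                if spec.mixture == "cell":
                    self._update_beta(t)
                self._update_corr(t)
                self._update_scale_moves(t)
                self._update_location_moves(t)
            else:
                if not mcmc.marginalize and spec.mixture in ("cell", "person"):
                    self._draw_zeta()
                self._update_persons(t)
                if spec.has_traits:
                    self._update_item_block("alpha_s", self._mut_alpha_s, t)
                if spec.has_faking:
                    self._update_item_block("alpha_f", self._mut_alpha_f, t)
                for c in (0, 1, 2):
                    if c in spec.classes:
                        self._update_item_block(f"gamma{c}", self._make_mut_gamma(c), t)
                if spec.mixture == "cell":
                    self._update_beta(t)
                    self._update_nu_psi(t)
                if spec.mixture == "person":
                    self._update_pi(t)
                if spec.include_rt:
                    self._update_item_block("delta", self._mut_delta, t)
                    self._update_rt_globals(t)
                self._update_corr(t)
                self._update_scale_moves(t)
                self._update_location_moves(t)

            if t >= mcmc.warmup:
                s = self.state
                for k in store:
                    v = s[k]
                    store[k].append(v.copy() if isinstance(v, np.ndarray) else v)
                if mcmc.store_persons:
                    persons_store.append(s["X"].astype(np.float32))
                if mcmc.store_loglik:
                    ll_resp.append(self.marginal_pointwise(include_rt=False).astype(np.float32))
                    if spec.include_rt:
                        ll_joint.append(self.marginal_pointwise(include_rt=True).astype(np.float32))

        draws = {k: np.array(v) for k, v in store.items()}
        return dict(
            draws=draws,
            persons=np.array(persons_store) if persons_store else None,
            ll_resp=np.array(ll_resp) if ll_resp else None,
            ll_joint=np.array(ll_joint) if ll_joint else None,
            acceptance={k: self._acc_count[k] / self._acc_total[k] for k in self._acc_count},
        )

    def _stored_keys(self):
        spec = self.spec
        keys = ["gamma"]
        if spec.has_traits:
            keys.append("alpha_trait")
        if spec.has_faking:
            keys.append("alpha_fake")
        if spec.mixture == "cell":
            keys += ["beta", "nu_psi"]
        if spec.mixture == "person":
            keys.append("pi")
        if spec.include_rt:
            keys += ["delta_s", "delta_f", "nu_phi", "lam", "sigma_rt"]
        if self.P >= 2:
            keys.append("corr")
        return keys


# ---------------------------------------------------------------------------
# public API


def make_evaluator(
    data: AssessmentData, spec: ModelSpec,
    priors: PriorConfig | None = None, mcmc: McmcConfig | None = None,
) -> _ChainSampler:
    """A likelihood evaluator for arbitrary state dictionaries (no sampling)."""
    return _ChainSampler(data, spec, priors or PriorConfig(), mcmc or McmcConfig(),
                         seed_key=(0,))


def state_pointwise_loglik(
    data: AssessmentData, spec: ModelSpec, state: dict,
    include_rt: bool | None = None, ev: _ChainSampler | None = None,
) -> np.ndarray:
    """Per-cell marginal log-likelihood (N, I) of one parameter state.

    Classes are integrated out: exactly per cell for cell-mixture and
    non-mixture variants; for person-mixture variants the class-conditional
    cell likelihoods are weighted by the person's posterior class
    probabilities under the state (the Rao-Blackwellized analogue of
    conditioning on a sampled person class).
    """
    ev = ev or make_evaluator(data, spec)
    if include_rt is None:
        include_rt = spec.include_rt
    if include_rt and not spec.include_rt:
        raise ValueError("joint likelihood undefined for a response-only variant")
    ccll = ev._resp_ll(state, X=state["X"])
    if include_rt:
        ccll = ccll + ev._rt_ll(state, X=state["X"])
    if spec.mixture == "cell":
        return _lse_last(ev._class_logp(state, X=state["X"]) + np.moveaxis(ccll, 0, -1))
    if spec.mixture == "person":
        logw = np.log(state["pi"])[:, None] + ccll.sum(axis=2)
        logw = logw - _lse_last(logw.T)[None, :]
        return _lse_last(np.moveaxis(logw[:, :, None] + ccll, 0, -1))
    return ccll[0]


def fit(
    data: AssessmentData,
    spec: ModelSpec,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorResult:
    """Fit one model variant by adaptive blocked MCMC.

    Runs ``mcmc.chains`` independent chains, assembles the retained draws,
    and assesses convergence by split R-hat on all non-person parameters
    (``converged`` is never silently true: a run with any R-hat at or above
    1.1 is flagged).
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    chain_outputs = []
    for chain in range(mcmc.chains):
        sampler = _ChainSampler(data, spec, priors, mcmc, seed_key=(mcmc.seed, chain))
        logger.info("fit %s: chain %d/%d (N=%d, I=%d)", spec.variant, chain + 1,
                    mcmc.chains, data.n_persons, data.n_items)
        chain_outputs.append(sampler.run())

    draws = {
        k: np.stack([co["draws"][k] for co in chain_outputs])
        for k in chain_outputs[0]["draws"]
    }
    acceptance = {
        k: float(np.mean([co["acceptance"][k] for co in chain_outputs]))
        for k in chain_outputs[0]["acceptance"]
    }
    result = PosteriorResult(
        spec=spec,
        draws=draws,
        person_draws=np.stack([co["persons"] for co in chain_outputs]) if chain_outputs[0]["persons"] is not None else None,
        loglik_resp=np.stack([co["ll_resp"] for co in chain_outputs]) if chain_outputs[0]["ll_resp"] is not None else None,
        loglik_joint=np.stack([co["ll_joint"] for co in chain_outputs]) if chain_outputs[0]["ll_joint"] is not None else None,
        mcmc=mcmc,
        priors=priors,
    )
    if mcmc.chains >= 2:
        converged, offenders = check_convergence(result)
        result.converged = converged
        result.rhat_offenders = offenders
    result.acceptance = acceptance
    return result


def monitored_draws(result: PosteriorResult, include_persons: bool = False) -> dict[str, np.ndarray]:
    """Flattened free-parameter draws (chains, samples, n_free) per family,
    excluding structurally fixed entries (zero intercepts, unloaded slopes,
    diagonal correlations)."""
    spec = result.spec
    d = result.draws
    out = {}
    if "alpha_trait" in d:
        mask = spec.weights.trait_loadings
        out["alpha_s"] = d["alpha_trait"][:, :, mask]
    if "alpha_fake" in d:
        out["alpha_f"] = d["alpha_fake"]
    g = d["gamma"]
    out["gamma"] = g[:, :, list(spec.classes), :, 1:].reshape(g.shape[0], g.shape[1], -1)
    if "beta" in d:
        out["beta"] = d["beta"][:, :, :, 1:].reshape(d["beta"].shape[0], d["beta"].shape[1], -1)
    for k in ("nu_psi", "nu_phi", "lam"):
        if k in d:
            out[k] = d[k]
    if "sigma_rt" in d:
        out["sigma_rt"] = d["sigma_rt"]
    if "pi" in d:
        out["pi"] = d["pi"]
    for k in ("delta_s", "delta_f"):
        if k in d:
            out[k] = d[k]
    if "corr" in d:
        P = d["corr"].shape[-1]
        iu = np.triu_indices(P, 1)
        out["corr"] = d["corr"][:, :, iu[0], iu[1]]
    if include_persons and result.person_draws is not None:
        pd_ = result.person_draws
        out["persons"] = pd_.reshape(pd_.shape[0], pd_.shape[1], -1)
    return out


def check_convergence(
    result: PosteriorResult, threshold: float = 1.1, include_persons: bool = False
) -> tuple[bool, list[str]]:
    """Split R-hat convergence check over all monitored parameters.

    Returns the overall flag (true iff every monitored R-hat is below the
    threshold) and the list of offending parameter families with their
    worst R-hat.
    """
    import arviz as az

    if result.n_chains < 2:
        raise ValueError("split R-hat requires at least two chains")
    mon = monitored_draws(result, include_persons=include_persons)
    offenders = []
    for name, arr in mon.items():
        a = np.asarray(arr, dtype=float)
        if a.ndim == 2:
            a = a[:, :, None]
        rh = np.asarray(az.rhat(az.convert_to_dataset(a))["x"])
        worst = float(np.nanmax(rh))
        if not np.isfinite(worst) or worst >= threshold:
            offenders.append(f"{name} (max R-hat {worst:.3f})")
    return (len(offenders) == 0, offenders)
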