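"""Probability kernel of the response-time-based latent response mixture model.

Every density and probability the simulator, the samplers and the fit indices
need is defined here as a pure, vectorized function of parameter containers.

The measurement model mixes three response strategies per person-by-item
cell.  Conditional on the latent class of a cell, the response follows a
constrained multidimensional nominal response model:

* S-only (class 0): category propensities depend on the substantive traits
  only (faking slope zeroed) — a multidimensional generalized partial credit
  model with intercepts ``gamma[0]``.
* S&F (class 1): propensities combine trait and faking terms with
  intercepts ``gamma[1]``.
* F-only (class 2): propensities depend on faking alone (trait slopes
  zeroed) — a unidimensional nominal response model with intercepts
  ``gamma[2]``.

Log response times are conditionally normal with a person speed term
``-nu_phi * phi`` and class-specific time intensities: ``delta_s`` (S-only),
``delta_s + lam * delta_f`` (S&F) and ``delta_f`` (F-only).  Class membership
per cell follows a partial credit model on strategy inclination ``psi`` with
integer class scores 0, 1, 2 and item-class intercepts ``beta``.

All computation is carried out in log space; mixtures use log-sum-exp.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_softmax, logsumexp

from .types import (
    N_CLASSES,
    AssessmentData,
    ItemParameters,
    PersonParameters,
    PopulationParameters,
    ScoringWeights,
)

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "category_logits",
    "category_probabilities",
    "response_log_probs",
    "rt_log_means",
    "rt_log_density",
    "class_probabilities",
    "class_log_probs",
    "cell_log_components",
    "joint_marginal_loglik",
    "responsibilities",
]


# ---------------------------------------------------------------------------
# item response models


def category_logits(
    items: ItemParameters, weights: ScoringWeights, persons: PersonParameters
) -> np.ndarray:
    """Raw category propensities, shape ``(3, N, I, K+1)``.

    ``out[c, n, i, k]`` is the class-c propensity of person n choosing
    category k on item i, before softmax normalization.
    """
    if items.n_categories != weights.n_categories or items.n_items != weights.n_items:
        raise ValueError(
            "item parameters and scoring weights disagree on items/categories: "
            f"{items.n_items}x{items.n_categories} vs {weights.n_items}x{weights.n_categories}"
        )
    if weights.n_traits != persons.n_traits:
        raise ValueError("scoring weights and persons disagree on the number of traits")
    # (I, D, K+1) slopes times weights, contracted with traits -> (N, I, K+1)
    loaded = items.alpha_trait[:, :, None] * weights.trait
    trait_term = np.einsum("nd,idk->nik", persons.theta, loaded)
    fake_term = persons.eta[:, None, None] * (items.alpha_fake[:, None] * weights.faking)[None]
    out = np.empty((N_CLASSES, persons.n_persons) + trait_term.shape[1:])
    out[0] = trait_term + items.gamma[0]
    out[1] = trait_term + fake_term + items.gamma[1]
    out[2] = fake_term + items.gamma[2]
    return out


def category_probabilities(
    cls: int,
    persons: PersonParameters,
    items: ItemParameters,
    weights: ScoringWeights,
) -> np.ndarray:
    """Class-conditional response category probabilities, shape ``(N, I, K+1)``."""
    if cls not in (0, 1, 2):
        raise ValueError("latent class must be 0 (S-only), 1 (S&F) or 2 (F-only)")
    logits = category_logits(items, weights, persons)[cls]
    return np.exp(log_softmax(logits, axis=-1))


def response_log_probs(
    responses: np.ndarray,
    items: ItemParameters,
    weights: ScoringWeights,
    persons: PersonParameters,
) -> np.ndarray:
    """Log probability of each observed response under each class, ``(3, N, I)``."""
    responses = np.asarray(responses)
    if np.any(responses >= items.n_categories):
        raise ValueError("responses outside the 0..K category range")
    logp = log_softmax(category_logits(items, weights, persons), axis=-1)
    return np.take_along_axis(logp, responses[None, :, :, None], axis=-1)[..., 0]


# ---------------------------------------------------------------------------
# response time models


def rt_log_means(
    items: ItemParameters, pop: PopulationParameters, persons: PersonParameters
) -> np.ndarray:
    """Expected log response time per class, shape ``(3, N, I)``."""
    speed = pop.nu_phi * persons.phi[:, None]  # (N, 1) broadcast over items
    out = np.empty((N_CLASSES, persons.n_persons, items.n_items))
    out[0] = items.delta_s[None, :] - speed
    out[1] = (items.delta_s + pop.lam * items.delta_f)[None, :] - speed
    out[2] = items.delta_f[None, :] - speed
    return out


def rt_log_density(
    times: np.ndarray,
    items: ItemParameters,
    pop: PopulationParameters,
    persons: PersonParameters,
) -> np.ndarray:
    """Log of the log-normal RT density under each class, shape ``(3, N, I)``.

    This is the density of the raw response time ``t`` (i.e. the normal
    density of ``ln t`` times the ``1/t`` change-of-variable factor), which
    is the RT factor entering the marginal likelihood.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("response times must be strictly positive")
    if np.any(pop.sigma_rt <= 0):
        raise ValueError("residual SDs must be positive")
    log_t = np.log(times)
    mu = rt_log_means(items, pop, persons)
    sig = pop.sigma_rt[:, None, None]
    z = (log_t[None] - mu) / sig
    return -0.5 * (_LOG_2PI + z * z) - np.log(sig) - log_t[None]


# ---------------------------------------------------------------------------
# latent response model


def class_log_probs(
    items: ItemParameters, pop: PopulationParameters, persons: PersonParameters
) -> np.ndarray:
    """Log class-membership probabilities per cell, shape ``(N, I, 3)``.

    Partial credit model: the class-c propensity is
    ``nu_psi * c * psi_n + beta[i, c]`` with integer class scores 0, 1, 2
    and the S-only intercept fixed at 0.
    """
    if pop.nu_psi <= 0:
        raise ValueError("nu_psi must be positive")
    scores = np.arange(N_CLASSES, dtype=float)
    logits = pop.nu_psi * persons.psi[:, None, None] * scores + items.beta[None, :, :]
    return log_softmax(logits, axis=-1)


def class_probabilities(
    persons: PersonParameters, items: ItemParameters, pop: PopulationParameters
) -> np.ndarray:
    """Class-membership probabilities per cell, shape ``(N, I, 3)``."""
    return np.exp(class_log_probs(items, pop, persons))


# ---------------------------------------------------------------------------
# marginal likelihood over classes


def cell_log_components(
    data: AssessmentData,
    items: ItemParameters,
    weights: ScoringWeights,
    persons: PersonParameters,
    pop: PopulationParameters,
    include_rt: bool = True,
) -> np.ndarray:
    """The three per-cell mixture summands on the log scale, ``(N, I, 3)``.

    ``out[n, i, c] = log p(class c) + log p(y | c) [+ log f(t | c)]``.
    The per-cell marginal likelihood is the log-sum-exp over the last axis.
    """
    resp = response_log_probs(data.responses, items, weights, persons)  # (3, N, I)
    comp = class_log_probs(items, pop, persons) + np.moveaxis(resp, 0, -1)
    if include_rt:
        if not data.has_times:
            raise ValueError("include_rt requested but the data carry no response times")
        comp = comp + np.moveaxis(rt_log_density(data.times, items, pop, persons), 0, -1)
    return comp


def joint_marginal_loglik(
    data: AssessmentData,
    items: ItemParameters,
    weights: ScoringWeights,
    persons: PersonParameters,
    pop: PopulationParameters,
    include_rt: bool = True,
    pointwise: bool = False,
):
    """Joint log-likelihood marginalized over the three classes per cell.

    With ``include_rt`` off, the RT factors drop out and the value is the
    response-only marginal log-likelihood.  ``pointwise=True`` returns the
    ``(N, I)`` per-cell contributions instead of their sum.
    """
    comp = cell_log_components(data, items, weights, persons, pop, include_rt)
    cellwise = logsumexp(comp, axis=-1)
    return cellwise if pointwise else float(cellwise.sum())


def responsibilities(
    data: AssessmentData,
    items: ItemParameters,
    weights: ScoringWeights,
    persons: PersonParameters,
    pop: PopulationParameters,
    include_rt: bool = True,
) -> np.ndarray:
    """Posterior class probabilities per cell given the observed data, ``(N, I, 3)``.

    Normalizes the three mixture summands of each cell; this is the
    categorical distribution a data-augmented Gibbs sampler draws the latent
    class from.
    """
    comp = cell_log_components(data, items, weights, persons, pop, include_rt)
    return np.exp(comp - logsumexp(comp, axis=-1, keepdims=True))
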