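import numpy as np
import pytest

from fakemix.estimate import McmcConfig, ModelSpec, fit
from fakemix.simulate import SimulationDesign, simulate
from fakemix.types import (
    AssessmentData,
    ItemParameters,
    PersonParameters,
    PopulationParameters,
    ScoringWeights,
)


@pytest.fixture(scope="session")
def tiny_design():
    return SimulationDesign(n_persons=40, items_per_trait=2, seed=11)


@pytest.fixture(scope="session")
def tiny_data(tiny_design):
    return simulate(tiny_design)


@pytest.fixture(scope="session")
def tiny_fit(tiny_design, tiny_data):
    """A short but real posterior fit of the full model on a small dataset."""
    spec = ModelSpec(variant="person_by_item_rt", weights=tiny_design.weights)
    mcmc = McmcConfig(chains=2, warmup=150, samples=150, seed=4, n_leapfrog=8)
    return fit(tiny_data, spec, mcmc=mcmc)


def random_instance(rng, n_persons=4, n_items=3, n_traits=2, n_categories=3):
    """A fully random, small model instance for brute-force oracle checks."""
    I, D, K1 = n_items, n_traits, n_categories
    trait_of_item = rng.integers(0, D, I)
    trait_w = np.zeros((I, D, K1))
    trait_w[np.arange(I), trait_of_item, :] = np.arange(K1, dtype=float)
    fake_w = rng.uniform(0, 6, (I, K1))
    weights = ScoringWeights(trait=trait_w, faking=fake_w)

    gamma = rng.normal(0, 1, (3, I, K1))
    gamma[:, :, 0] = 0.0
    beta = np.zeros((I, 3))
    beta[:, 1:] = rng.normal(0, 1, (I, 2))
    alpha_trait = np.zeros((I, D))
    alpha_trait[np.arange(I), trait_of_item] = rng.uniform(0.2, 1.5, I)
    items = ItemParameters(
        alpha_trait=alpha_trait,
        alpha_fake=rng.uniform(0.2, 1.5, I),
        gamma=gamma,
        beta=beta,
        delta_s=rng.normal(1.7, 0.2, I),
        delta_f=rng.normal(1.5, 0.2, I),
    )
    A = rng.normal(0, 0.3, (D + 3, D + 3))
    cov = A @ A.T + np.eye(D + 3)
    dd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(dd, dd)
    pop = PopulationParameters(
        corr=corr,
        nu_phi=rng.uniform(0.3, 1.2),
        nu_psi=rng.uniform(0.3, 1.5),
        lam=rng.uniform(0.05, 0.6),
        sigma_rt=rng.uniform(0.2, 0.8, 3),
    )
    persons = PersonParameters(values=rng.normal(0, 1, (n_persons, D + 3)), n_traits=D)
    data = AssessmentData(
        responses=rng.integers(0, K1, (n_persons, I)),
        times=np.exp(rng.normal(1.6, 0.5, (n_persons, I))),
    )
    return data, items, weights, persons, pop


def brute_force_cell_terms(data, items, weights, persons, pop, n, i, include_rt=True):
    """Scalar-arithmetic mixture summands for one cell: log p(class) +
    log p(y | class) [+ log f(t | class)], computed with plain loops and
    library densities, independently of the vectorized kernel."""
    from scipy.stats import norm

    D = weights.n_traits
    K1 = weights.n_categories
    y = int(data.responses[n, i])
    theta = persons.values[n, :D]
    eta, phi, psi = persons.values[n, D], persons.values[n, D + 1], persons.values[n, D + 2]

    # class-membership probabilities (partial credit model)
    props = [pop.nu_psi * c * psi + items.beta[i, c] for c in range(3)]
    mx = max(props)
    denom = sum(np.exp(p - mx) for p in props)
    log_class = [p - mx - np.log(denom) for p in props]

    out = []
    for c in range(3):
        logits = []
        for k in range(K1):
            v = items.gamma[c, i, k]
            if c in (0, 1):
                for d in range(D):
                    v += items.alpha_trait[i, d] * weights.trait[i, d, k] * theta[d]
            if c in (1, 2):
                v += items.alpha_fake[i] * weights.faking[i, k] * eta
            logits.append(v)
        mx = max(logits)
        denom = sum(np.exp(v - mx) for v in logits)
        log_resp = logits[y] - mx - np.log(denom)
        term = log_class[c] + log_resp
        if include_rt:
            t = data.times[n, i]
            mu = [items.delta_s[i], items.delta_s[i] + pop.lam * items.delta_f[i], items.delta_f[i]][c]
            mu -= pop.nu_phi * phi
            term += norm.logpdf(np.log(t), loc=mu, scale=pop.sigma_rt[c]) - np.log(t)
        out.append(term)
    return out
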