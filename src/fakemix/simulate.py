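"""Synthetic assessment generator mirroring the parameter-recovery design.

The default scenario emulates a high-stakes personality test: three
substantive traits measured by 10 items each on a 7-point scale, N = 500
test-takers, with generating values calibrated to the empirical anchors of
the model (mean S-only time intensity 1.72 and F-only 1.53 log-seconds,
proportionality constant 0.23, strategy-inclination slope 1.05, latent
correlations in the 0 to .36 range, and overall class proportions near
49/26/25%).  Item desirability trajectories mix monotone-increasing,
interior-peak and midpoint-peak shapes, so nonmonotonic faking effects are
present in the default data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .types import (
    AssessmentData,
    ItemParameters,
    PersonParameters,
    PopulationParameters,
    ScoringWeights,
)

__all__ = [
    "SimulationDesign",
    "make_desirability_weights",
    "default_correlations",
    "default_scenario",
    "draw_persons",
    "simulate",
]

# surrogate for minus infinity on the propensity scale: exp(-30) underflows
# any softmax weight to ~1e-13 while keeping arithmetic finite
NEG_PROPENSITY = -30.0


def make_desirability_weights(shape: str, K: int, peak_category: int | None = None) -> np.ndarray:
    """Faking scoring weights (desirability trajectory) for one item.

    ``monotone-increasing`` is the evenly spaced 0..6 grid; ``peak-interior``
    and ``peak-at-midpoint`` are triangular trajectories with maximum 6 at
    ``peak_category`` that decay linearly and reach 0 at the farther extreme.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if shape == "monotone-increasing":
        return np.linspace(0.0, 6.0, K + 1)
    if shape == "peak-at-midpoint":
        peak_category = K // 2
    elif shape == "peak-interior":
        if peak_category is None:
            raise ValueError("peak-interior shape requires peak_category")
    else:
        raise ValueError(f"unknown desirability shape {shape!r}")
    if not 0 <= peak_category <= K:
        raise ValueError("peak category outside the 0..K range")
    k = np.arange(K + 1)
    half_width = max(peak_category, K - peak_category)
    w = 6.0 * (1.0 - np.abs(k - peak_category) / half_width)
    return np.clip(w, 0.0, 6.0)


def default_correlations() -> np.ndarray:
    """Default latent correlation matrix (theta1..3, eta, phi, psi).

    Values follow the empirically estimated correlation pattern: moderate
    positive trait intercorrelations, negative trait-faking correlations,
    small trait-speed correlations, and a .32 faking-strategy-inclination
    correlation.
    """
    corr = np.array(
        [
            #  t1     t2     t3    eta    phi    psi
            [1.00, 0.20, 0.24, -0.23, 0.11, -0.06],
            [0.20, 1.00, 0.36, -0.01, 0.09, 0.14],
            [0.24, 0.36, 1.00, -0.24, 0.08, -0.31],
            [-0.23, -0.01, -0.24, 1.00, 0.01, 0.32],
            [0.11, 0.09, 0.08, 0.01, 1.00, 0.00],
            [-0.06, 0.14, -0.31, 0.32, 0.00, 1.00],
        ]
    )
    return corr


@dataclass
class SimulationDesign:
    """Design of a synthetic assessment study.

    Defaults mirror the recovery design: D = 3 traits, 10 items per trait,
    7 response categories, N = 500 persons, 50 replications.  The generating
    parameters may be supplied explicitly (e.g. taken verbatim from an
    external calibration); otherwise :func:`default_scenario` fills them in.
    """

    n_persons: int = 500
    n_traits: int = 3
    items_per_trait: int = 10
    n_categories: int = 7
    n_replications: int = 50
    seed: int = 0
    items: ItemParameters | None = None
    weights: ScoringWeights | None = None
    population: PopulationParameters | None = None
    fresh_persons_per_replication: bool = True
    _frozen_persons: PersonParameters | None = field(default=None, repr=False)

    @property
    def n_items(self) -> int:
        return self.n_traits * self.items_per_trait

    def __post_init__(self):
        if self.n_persons < 1 or self.n_traits < 1 or self.items_per_trait < 1:
            raise ValueError("design counts must be positive")
        if self.n_categories < 2:
            raise ValueError("at least two response categories are required")
        if self.items is None or self.weights is None or self.population is None:
            items, weights, pop = default_scenario(
                self.n_traits, self.items_per_trait, self.n_categories, self.seed
            )
            self.items = self.items or items
            self.weights = self.weights or weights
            self.population = self.population or pop
        if self.items.n_items != self.n_items or self.weights.n_items != self.n_items:
            raise ValueError("item parameters / weights inconsistent with the design size")


def default_scenario(
    n_traits: int = 3,
    items_per_trait: int = 10,
    n_categories: int = 7,
    seed: int = 0,
) -> tuple[ItemParameters, ScoringWeights, PopulationParameters]:
    """Generating parameters of the default recovery scenario.

    Item-level values scatter around the calibrated anchors: trait and
    faking slopes uniform on [0.2, 0.5]; category intercepts N(0, 1) with
    the first category fixed at 0; item-class intercepts N(-0.45, 0.5^2) for
    the S&F class and N(-1.0, 0.5^2) for the F-only class (calibrated so the
    average class split is about 49/26/25%); time intensities N(1.72, 0.15^2)
    and N(1.53, 0.15^2) log-seconds.  Items of the trait scales are
    interleaved in a random order, as on the empirical test; desirability
    trajectories cycle through monotone, interior-peak and midpoint-peak
    shapes.
    """
    rng = np.random.default_rng(seed)
    I = n_traits * items_per_trait
    K = n_categories - 1

    # interleave scale membership in random order; the order has no model role
    trait_of_item = rng.permutation(np.repeat(np.arange(n_traits), items_per_trait))
    trait_w = np.zeros((I, n_traits, n_categories))
    trait_w[np.arange(I), trait_of_item, :] = np.arange(n_categories, dtype=float)

    shapes = ["monotone-increasing", "monotone-increasing", "peak-interior", "peak-at-midpoint"]
    fake_w = np.empty((I, n_categories))
    for i in range(I):
        shape = shapes[i % len(shapes)]
        peak = K - 1 if shape == "peak-interior" else None
        fake_w[i] = make_desirability_weights(shape, K, peak)
    weights = ScoringWeights(trait=trait_w, faking=fake_w)

    alpha_trait = np.zeros((I, n_traits))
    alpha_trait[np.arange(I), trait_of_item] = rng.uniform(0.8, 1.6, I)
    alpha_fake = rng.uniform(0.8, 1.6, I)
    # class-specific intercepts: item-specific scatter plus a desirability
    # tilt that grows with the pronouncedness of the strategy, so F-only
    # responses concentrate on desirable categories while S-only responses
    # track the substantive traits (the class-specific item response
    # distribution pattern of the empirical demonstration)
    tilt = fake_w - fake_w.mean(axis=1, keepdims=True)
    gamma = np.empty((3, I, n_categories))
    for c, tc in enumerate((0.0, 0.35, 0.8)):
        raw = rng.normal(0.0, 0.7, size=(I, n_categories)) + tc * tilt
        gamma[c] = raw - raw[:, :1]  # anchor the first category at 0
    beta = np.zeros((I, 3))
    beta[:, 1] = rng.normal(-0.45, 0.7, I)
    beta[:, 2] = rng.normal(-1.0, 0.7, I)
    items = ItemParameters(
        alpha_trait=alpha_trait,
        alpha_fake=alpha_fake,
        gamma=gamma,
        beta=beta,
        delta_s=rng.normal(1.72, 0.15, I),
        delta_f=rng.normal(1.53, 0.15, I),
    )
    pop = PopulationParameters(
        corr=default_correlations() if n_traits == 3 else np.eye(n_traits + 3),
        nu_phi=0.5,
        nu_psi=1.05,
        lam=0.23,
        sigma_rt=np.array([0.30, 0.33, 0.30]),
    )
    return items, weights, pop


def draw_persons(
    n_persons: int, corr: np.ndarray, seed: int | np.random.Generator = 0, n_traits: int | None = None
) -> PersonParameters:
    """Draw person parameters from the joint standard multivariate normal."""
    corr = np.asarray(corr, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_traits is None:
        n_traits = corr.shape[0] - 3
    if corr.shape != (n_traits + 3, n_traits + 3):
        raise ValueError("correlation matrix must have order D+3")
    chol = np.linalg.cholesky(corr)  # raises on non-PD input
    values = rng.standard_normal((n_persons, corr.shape[0])) @ chol.T
    return PersonParameters(values=values, n_traits=n_traits)


def simulate(
    design: SimulationDesign,
    replication: int = 0,
    persons: PersonParameters | None = None,
) -> AssessmentData:
    """Generate one synthetic assessment from the design.

    Per cell: draw the latent class from the latent response model, then the
    response from the class-conditional category probabilities, then the RT
    from the class-specific log-normal.  Ground-truth classes and person
    parameters are stored with the data.  ``replication`` offsets the seed so
    replications are independent but individually reproducible.
    """
    rng = np.random.default_rng((design.seed, replication))
    items, weights, pop = design.items, design.weights, design.population
    if persons is None:
        if design.fresh_persons_per_replication or design._frozen_persons is None:
            persons = draw_persons(design.n_persons, pop.corr, rng, design.n_traits)
            if not design.fresh_persons_per_replication:
                design._frozen_persons = persons
        else:
            persons = design._frozen_persons

    N, I = design.n_persons, design.n_items
    class_p = model.class_probabilities(persons, items, pop)  # (N, I, 3)
    u = rng.random((N, I, 1))
    zeta = (u > np.cumsum(class_p, axis=-1)[:, :, :-1]).sum(axis=-1)

    cat_p = np.stack(
        [model.category_probabilities(c, persons, items, weights) for c in range(3)]
    )  # (3, N, I, K+1)
    cell_p = np.take_along_axis(cat_p, zeta[None, :, :, None], axis=0)[0]
    u = rng.random((N, I, 1))
    y = (u > np.cumsum(cell_p, axis=-1)[:, :, :-1]).sum(axis=-1)

    mu = np.take_along_axis(model.rt_log_means(items, pop, persons), zeta[None], axis=0)[0]
    sig = pop.sigma_rt[zeta]
    t = np.exp(rng.normal(mu, sig))

    return AssessmentData(
        responses=y.astype(int),
        times=t,
        true_classes=zeta.astype(int),
        true_persons=persons,
    )
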