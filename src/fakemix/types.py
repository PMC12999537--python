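"""Core data containers for the faking mixture model.

Array conventions used throughout the package:

* ``N`` persons, ``I`` items, ``D`` substantive traits, ``K + 1`` response
  categories (``0 .. K``).
* Latent classes are ordered ``0`` = S-only (substantive traits only),
  ``1`` = S&F (traits and faking), ``2`` = F-only (faking only).  The order
  is ordinal in the pronouncedness of the self-presentation strategy.
* Person parameters are stacked column-wise as
  ``(theta_1, ..., theta_D, eta, phi, psi)``: substantive traits, faking,
  speed, strategy inclination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

S_ONLY, S_AND_F, F_ONLY = 0, 1, 2
CLASS_NAMES = ("S-only", "S&F", "F-only")
N_CLASSES = 3


def _as2d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    return a


@dataclass
class ScoringWeights:
    """Item-by-category scoring weights for the nominal response models.

    ``trait`` has shape ``(I, D, K+1)``; the row for a trait an item measures
    is an evenly spaced nonnegative grid (conventionally ``0..K``), rows for
    unmeasured traits are all zero.  ``faking`` has shape ``(I, K+1)`` and
    holds the desirability values of each category on the common 0-6 metric.
    """

    trait: np.ndarray
    faking: np.ndarray

    def __post_init__(self):
        self.trait = np.asarray(self.trait, dtype=float)
        self.faking = np.asarray(self.faking, dtype=float)
        if self.trait.ndim != 3:
            raise ValueError("trait weights must have shape (I, D, K+1)")
        if self.faking.shape != (self.trait.shape[0], self.trait.shape[2]):
            raise ValueError(
                "faking weights shape %s inconsistent with trait weights %s"
                % (self.faking.shape, self.trait.shape)
            )
        if np.any(self.faking < 0) or np.any(self.faking > 6):
            raise ValueError("faking weights must lie in [0, 6]")

    @property
    def n_items(self) -> int:
        return self.trait.shape[0]

    @property
    def n_traits(self) -> int:
        return self.trait.shape[1]

    @property
    def n_categories(self) -> int:
        """Number of response categories, K + 1."""
        return self.trait.shape[2]

    @property
    def trait_loadings(self) -> np.ndarray:
        """Boolean (I, D) mask of which trait each item measures."""
        return np.any(self.trait != 0.0, axis=2)


@dataclass
class ItemParameters:
    """All item-side parameters of the full person-by-item mixture model.

    ``gamma`` stacks the class-specific category intercepts as
    ``(3, I, K+1)`` in class order (S-only, S&F, F-only); the first category
    of every item is fixed at 0 in every class.  ``beta`` has shape
    ``(I, 3)`` with the S-only column fixed at 0.  ``delta_s`` / ``delta_f``
    are the S-only / F-only time intensities on the log-seconds scale.
    """

    alpha_trait: np.ndarray  # (I, D) slopes, >= 0
    alpha_fake: np.ndarray  # (I,) faking slopes, >= 0
    gamma: np.ndarray  # (3, I, K+1)
    beta: np.ndarray  # (I, 3)
    delta_s: np.ndarray  # (I,)
    delta_f: np.ndarray  # (I,)

    def __post_init__(self):
        self.alpha_trait = _as2d(self.alpha_trait, "alpha_trait")
        self.alpha_fake = np.asarray(self.alpha_fake, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = _as2d(self.beta, "beta")
        self.delta_s = np.asarray(self.delta_s, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        I = self.alpha_trait.shape[0]
        if self.gamma.ndim != 3 or self.gamma.shape[0] != N_CLASSES or self.gamma.shape[1] != I:
            raise ValueError("gamma must have shape (3, I, K+1)")
        if self.beta.shape != (I, N_CLASSES):
            raise ValueError("beta must have shape (I, 3)")
        if self.alpha_fake.shape != (I,) or self.delta_s.shape != (I,) or self.delta_f.shape != (I,):
            raise ValueError("alpha_fake, delta_s, delta_f must have shape (I,)")
        if np.any(self.alpha_trait < 0) or np.any(self.alpha_fake < 0):
            raise ValueError("slopes must be nonnegative")
        if np.any(self.gamma[:, :, 0] != 0):
            raise ValueError("first-category intercepts must be fixed at 0")
        if np.any(self.beta[:, S_ONLY] != 0):
            raise ValueError("S-only class intercepts must be fixed at 0")

    @property
    def n_items(self) -> int:
        return self.alpha_trait.shape[0]

    @property
    def n_categories(self) -> int:
        return self.gamma.shape[2]


@dataclass
class PersonParameters:
    """Latent person scores stacked as an ``(N, D+3)`` matrix.

    Columns: the D substantive traits, then faking ``eta``, speed ``phi``
    and strategy inclination ``psi``, all on the standard-normal scale.
    """

    values: np.ndarray
    n_traits: int

    def __post_init__(self):
        self.values = _as2d(self.values, "person values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("person parameters must be finite")
        if self.values.shape[1] != self.n_traits + 3:
            raise ValueError(
                f"expected {self.n_traits + 3} latent columns, got {self.values.shape[1]}"
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def theta(self) -> np.ndarray:
        return self.values[:, : self.n_traits]

    @property
    def eta(self) -> np.ndarray:
        return self.values[:, self.n_traits]

    @property
    def phi(self) -> np.ndarray:
        return self.values[:, self.n_traits + 1]

    @property
    def psi(self) -> np.ndarray:
        return self.values[:, self.n_traits + 2]


@dataclass
class PopulationParameters:
    """Population-level structural parameters.

    ``corr`` is the (D+3)x(D+3) latent correlation matrix; ``nu_phi`` and
    ``nu_psi`` are the item-invariant speed and strategy-inclination slopes;
    ``lam`` is the positive proportionality constant linking the S&F time
    intensity to the F-only one; ``sigma_rt`` holds the residual SDs of
    log response times per class, ordered (S-only, S&F, F-only).
    """

    corr: np.ndarray
    nu_phi: float = 1.0
    nu_psi: float = 1.0
    lam: float = 0.2
    sigma_rt: np.ndarray = field(default_factory=lambda: np.array([0.4, 0.4, 0.4]))

    def __post_init__(self):
        self.corr = _as2d(self.corr, "corr")
        self.sigma_rt = np.asarray(self.sigma_rt, dtype=float)
        if self.sigma_rt.shape != (N_CLASSES,):
            raise ValueError("sigma_rt must have 3 entries (S-only, S&F, F-only)")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.linalg.eigvalsh(self.corr) <= 0):
            raise ValueError("correlation matrix must be positive definite")
        if self.nu_phi <= 0 or self.nu_psi <= 0 or self.lam <= 0:
            raise ValueError("nu_phi, nu_psi and lam must be positive")
        if np.any(self.sigma_rt <= 0):
            raise ValueError("residual SDs must be positive")


@dataclass
class AssessmentData:
    """Observed (or simulated) responses and response times.

    ``responses`` is an ``(N, I)`` integer matrix with categories ``0..K``;
    ``times`` the matching response times in seconds (strictly positive), or
    None for response-only data.  Simulated data may carry the generating
    classes and person parameters as ground truth.
    """

    responses: np.ndarray
    times: np.ndarray | None = None
    true_classes: np.ndarray | None = None
    true_persons: PersonParameters | None = None
    person_ids: list[str] | None = None
    item_ids: list[str] | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be an (N, I) matrix")
        if not np.issubdtype(self.responses.dtype, np.integer):
            as_int = self.responses.astype(int)
            if not np.array_equal(as_int, self.responses):
                raise ValueError("responses must be integer-coded categories")
            self.responses = as_int
        if np.any(self.responses < 0):
            raise ValueError("responses must be coded 0..K")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.responses.shape:
                raise ValueError("times must match the shape of responses")
            if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
                raise ValueError("response times must be finite and strictly positive")
        if self.true_classes is not None:
            self.true_classes = np.asarray(self.true_classes)
            if self.true_classes.shape != self.responses.shape:
                raise ValueError("true_classes must match the shape of responses")
        if self.person_ids is None:
            self.person_ids = [f"p{n + 1}" for n in range(self.responses.shape[0])]
        if self.item_ids is None:
            self.item_ids = [f"i{i + 1}" for i in range(self.responses.shape[1])]

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def has_times(self) -> bool:
        return self.times is not None
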