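"""Derived posterior quantities: class probabilities, assignments, recovery metrics.

Two flavors of posterior class probability are exposed.  The *structural*
flavor plugs each retained draw of the latent response model parameters
(strategy inclination scores, item-class intercepts, inclination slope)
into the class-membership model and averages across draws; it reflects the
model-implied mixing proportions.  The *conditional* flavor additionally
conditions on the observed response and response time of each cell
(normalizing the three mixture summands), which is what an explicit
data-augmented sampler implicitly does when drawing the latent classes.
The two coincide exactly when the response and RT models do not differ
between classes; with informative data the conditional table is sharper
and is the default basis for modal assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .estimate import McmcConfig, PosteriorResult, PriorConfig, _ChainSampler
from .types import CLASS_NAMES, AssessmentData

__all__ = [
    "ClassProbabilityTable",
    "class_probability_table",
    "modal_assignment",
    "strategy_consistency",
    "hit_rate",
    "RecoveryReport",
    "recovery_metrics",
    "fisher_mean_correlation",
]


@dataclass
class ClassProbabilityTable:
    """Posterior class probabilities per person-by-item cell.

    ``probs`` has shape ``(N, I, 3)`` (rows sum to 1), ``item_proportions``
    ``(I, 3)``, ``overall`` ``(3,)``; ``overall_ci`` holds the central 95%
    interval across draws of the draw-wise mean proportion, shape ``(3, 2)``.
    """

    probs: np.ndarray
    item_proportions: np.ndarray
    overall: np.ndarray
    overall_ci: np.ndarray
    mode: str

    def to_frame(self, data: AssessmentData) -> pd.DataFrame:
        n, i = np.meshgrid(np.arange(self.probs.shape[0]), np.arange(self.probs.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "person_id": np.asarray(data.person_ids)[n.ravel()],
                "item_id": np.asarray(data.item_ids)[i.ravel()],
                **{f"p_{name}": self.probs[:, :, c].ravel() for c, name in enumerate(CLASS_NAMES)},
            }
        )


def _evaluator(result: PosteriorResult, data: AssessmentData) -> _ChainSampler:
    return _ChainSampler(data, result.spec, result.priors or PriorConfig(),
                         result.mcmc or McmcConfig(), seed_key=(0,))


def class_probability_table(
    result: PosteriorResult,
    data: AssessmentData,
    mode: str = "conditional",
    thin: int = 1,
) -> ClassProbabilityTable:
    """Average class probabilities over retained draws.

    ``mode='structural'`` uses the latent response model only;
    ``mode='conditional'`` conditions on each cell's observed data.
    Undefined for non-mixture variants.
    """
    spec = result.spec
    if spec.mixture == "none":
        raise ValueError("class probabilities are undefined for non-mixture models")
    if mode not in ("structural", "conditional"):
        raise ValueError("mode must be 'structural' or 'conditional'")
    if result.person_draws is None:
        raise ValueError("class probabilities require stored person draws")
    ev = _evaluator(result, data)
    chains, samples = result.n_chains, result.n_samples
    total = np.zeros((data.n_persons, data.n_items, 3))
    overall_draws = []
    count = 0
    for ch in range(chains):
        for ix in range(0, samples, thin):
            state = result.state_at(ch, ix)
            probs = _cell_probs_one_draw(ev, spec, state, mode)
            total += probs
            overall_draws.append(probs.mean(axis=(0, 1)))
            count += 1
    probs = total / count
    overall_draws = np.array(overall_draws)
    return ClassProbabilityTable(
        probs=probs,
        item_proportions=probs.mean(axis=0),
        overall=probs.mean(axis=(0, 1)),
        overall_ci=np.quantile(overall_draws, [0.025, 0.975], axis=0).T,
        mode=mode,
    )


def _cell_probs_one_draw(ev: _ChainSampler, spec, state, mode) -> np.ndarray:
    N, I = ev.N, ev.I
    if spec.mixture == "cell":
        clp = ev._class_logp(state)
        if mode == "structural":
            return np.exp(clp)
        comp = clp + np.moveaxis(ev._ccll(state), 0, -1)
        return np.exp(comp - logsumexp(comp, axis=-1, keepdims=True))
    # person mixture: a person's class applies to every item
    logpi = np.log(state["pi"])
    if mode == "structural":
        return np.broadcast_to(np.exp(logpi), (N, I, 3)).copy()
    logw = logpi[:, None] + ev._ccll(state).sum(axis=2)  # (3, N)
    w = np.exp(logw - logsumexp(logw, axis=0, keepdims=True))
    return np.broadcast_to(w.T[:, None, :], (N, I, 3)).copy()


def modal_assignment(table: ClassProbabilityTable) -> np.ndarray:
    """Class with the highest posterior probability per cell, ``(N, I)``.

    Exact ties resolve to the lower class index, i.e. the less pronounced
    self-presentation strategy.
    """
    return np.argmax(table.probs, axis=-1)


def strategy_consistency(assignments: np.ndarray) -> pd.DataFrame:
    """Summarize how consistently each person used the response strategies.

    Returns one row per consistency pattern (single class, each two-class
    pair, all three classes) with the number of persons showing it.
    """
    assignments = np.asarray(assignments)
    rows = {f"one class: {name}": 0 for name in CLASS_NAMES}
    rows.update({f"two classes: {a}/{b}": 0 for a, b in combinations(CLASS_NAMES, 2)})
    rows["three classes"] = 0
    for person_row in assignments:
        used = sorted(set(int(c) for c in person_row))
        if len(used) == 1:
            rows[f"one class: {CLASS_NAMES[used[0]]}"] += 1
        elif len(used) == 2:
            rows[f"two classes: {CLASS_NAMES[used[0]]}/{CLASS_NAMES[used[1]]}"] += 1
        else:
            rows["three classes"] += 1
    return pd.DataFrame({"pattern": list(rows), "n_persons": list(rows.values())})


def hit_rate(assignments: np.ndarray, true_classes: np.ndarray) -> float:
    """Percentage of person-by-item cells whose modal class matches the
    generating class, pooled over all cells."""
    if true_classes is None:
        raise ValueError("hit rate requires ground-truth classes")
    assignments = np.asarray(assignments)
    true_classes = np.asarray(true_classes)
    if assignments.shape != true_classes.shape:
        raise ValueError("assignment and truth shapes differ")
    return 100.0 * float(np.mean(assignments == true_classes))


def fisher_mean_correlation(corrs) -> float:
    """Mean correlation across replications via Fisher's z transform."""
    z = np.arctanh(np.clip(np.asarray(corrs, dtype=float), -0.999999, 0.999999))
    return float(np.tanh(np.mean(z)))


@dataclass
class RecoveryReport:
    """Per-family recovery summary: mean bias and RMSE across replications,
    plus the Fisher-z-aggregated estimate-truth correlation where it is
    meaningful (person parameter families)."""

    table: pd.DataFrame

    def __getitem__(self, family: str) -> pd.Series:
        return self.table.loc[family]


def recovery_metrics(
    estimates: dict[str, list[np.ndarray]],
    truths: dict[str, list[np.ndarray]],
    correlation_families: tuple[str, ...] = (),
) -> RecoveryReport:
    """Bias / RMSE / recovery-correlation table across replications.

    ``estimates[family]`` and ``truths[family]`` are parallel lists with one
    array per replication.  Bias and RMSE are computed within replication
    and averaged; correlations (for the families named in
    ``correlation_families``) are aggregated with Fisher's z.
    """
    rows = []
    for family, est_list in estimates.items():
        true_list = truths[family]
        if len(est_list) != len(true_list):
            raise ValueError(f"family {family}: replication counts differ")
        biases, rmses, corrs = [], [], []
        for est, true in zip(est_list, true_list):
            est = np.asarray(est, dtype=float).ravel()
            true = np.asarray(true, dtype=float).ravel()
            if est.shape != true.shape:
                raise ValueError(f"family {family}: estimate/truth length mismatch")
            err = est - true
            biases.append(err.mean())
            rmses.append(np.sqrt(np.mean(err**2)))
            if family in correlation_families:
                if est.size < 3 or np.std(est) == 0 or np.std(true) == 0:
                    warnings.warn(f"family {family}: correlation undefined in a replication")
                else:
                    corrs.append(np.corrcoef(est, true)[0, 1])
        rows.append(
            {
                "family": family,
                "bias": float(np.mean(biases)),
                "rmse": float(np.mean(rmses)),
                "correlation": fisher_mean_correlation(corrs) if corrs else np.nan,
                "n_replications": len(est_list),
            }
        )
    return RecoveryReport(table=pd.DataFrame(rows).set_index("family"))
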