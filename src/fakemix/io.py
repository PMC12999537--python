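"""Reading and writing assessments, scoring weights, and posterior draws.

The canonical on-disk format is tidy long CSV: one row per person-by-item
cell with columns ``person_id, item_id, response, rt_seconds`` and
optionally ``true_class``.  A wide layout (one row per person, one response
column per item, optional ``rt_<item>`` columns) is supported read-only.
Scoring weights travel as one row per item-by-category-by-dimension triple.
Posteriors are persisted as an ``.npz`` of draw arrays plus a JSON sidecar
describing the model variant and sampler settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import McmcConfig, ModelSpec, PosteriorResult, PriorConfig
from .types import AssessmentData, ScoringWeights

__all__ = [
    "read_assessment",
    "write_assessment",
    "read_weights",
    "write_weights",
    "rescale_desirability",
    "save_posterior",
    "load_posterior",
]

FAKING_DIMENSION = "FAKING"


def read_assessment(path, format: str = "long", rt_unit: str = "seconds") -> AssessmentData:
    """Read an assessment table into rectangular person-by-item arrays.

    ``rt_unit='milliseconds'`` divides the stored times by 1,000 so that the
    in-memory unit is always seconds.
    """
    if rt_unit not in ("seconds", "milliseconds"):
        raise ValueError("rt_unit must be 'seconds' or 'milliseconds'")
    df = pd.read_csv(path, float_precision="round_trip")
    if format == "long":
        data = _from_long(df)
    elif format == "wide":
        data = _from_wide(df)
    else:
        raise ValueError("format must be 'long' or 'wide'")
    if rt_unit == "milliseconds" and data.times is not None:
        data.times = data.times / 1000.0
    return data


def _from_long(df: pd.DataFrame) -> AssessmentData:
    problems = []
    for col in ("person_id", "item_id", "response"):
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise ValueError("malformed assessment table: " + "; ".join(problems))
    rt_col = "rt_seconds" if "rt_seconds" in df.columns else ("rt" if "rt" in df.columns else None)

    dup = df.duplicated(subset=["person_id", "item_id"])
    if dup.any():
        pairs = df.loc[dup, ["person_id", "item_id"]].head(5).to_records(index=False)
        problems.append(f"duplicate (person,item) rows, e.g. {list(pairs)}")
    persons = list(dict.fromkeys(df["person_id"].astype(str)))
    items = list(dict.fromkeys(df["item_id"].astype(str)))
    if not dup.any() and len(df) != len(persons) * len(items):
        problems.append(
            f"non-rectangular data: {len(df)} rows for {len(persons)} persons x {len(items)} items"
        )
    resp_float = pd.to_numeric(df["response"], errors="coerce")
    if resp_float.isna().any() or not np.allclose(resp_float, resp_float.round()):
        problems.append("responses must be integer category codes")
    if (resp_float < 0).any():
        problems.append("negative response categories found")
    if rt_col is not None:
        rt = pd.to_numeric(df[rt_col], errors="coerce")
        bad = rt.isna() | (rt <= 0)
        if bad.any():
            problems.append(f"{int(bad.sum())} nonpositive/missing response times")
    if problems:
        raise ValueError("malformed assessment table: " + "; ".join(problems))

    pidx = {p: i for i, p in enumerate(persons)}
    iidx = {it: i for i, it in enumerate(items)}
    N, I = len(persons), len(items)
    y = np.full((N, I), -1, dtype=int)
    rows = df["person_id"].astype(str).map(pidx).to_numpy()
    cols = df["item_id"].astype(str).map(iidx).to_numpy()
    y[rows, cols] = resp_float.round().astype(int).to_numpy()
    if (y < 0).any():
        raise ValueError("malformed assessment table: missing person-item cells")
    t = None
    if rt_col is not None:
        t = np.zeros((N, I))
        t[rows, cols] = pd.to_numeric(df[rt_col]).to_numpy()
    true_classes = None
    if "true_class" in df.columns:
        true_classes = np.zeros((N, I), dtype=int)
        true_classes[rows, cols] = df["true_class"].astype(int).to_numpy()
    return AssessmentData(responses=y, times=t, true_classes=true_classes,
                          person_ids=persons, item_ids=items)


def _from_wide(df: pd.DataFrame) -> AssessmentData:
    if "person_id" not in df.columns:
        raise ValueError("wide assessment table needs a person_id column")
    rt_cols = [c for c in df.columns if c.startswith("rt_")]
    item_cols = [c for c in df.columns if c != "person_id" and not c.startswith("rt_")]
    if not item_cols:
        raise ValueError("wide assessment table has no item columns")
    y = df[item_cols].to_numpy()
    t = None
    if rt_cols:
        expected = [f"rt_{c}" for c in item_cols]
        if sorted(rt_cols) != sorted(expected):
            raise ValueError("rt_ columns do not match item columns")
        t = df[expected].to_numpy(dtype=float)
    return AssessmentData(responses=y, times=t,
                          person_ids=df["person_id"].astype(str).tolist(),
                          item_ids=item_cols)


def write_assessment(data: AssessmentData, path) -> None:
    """Write tidy long CSV (person_id, item_id, response, rt_seconds[, true_class])."""
    n, i = np.meshgrid(np.arange(data.n_persons), np.arange(data.n_items), indexing="ij")
    out = pd.DataFrame(
        {
            "person_id": np.asarray(data.person_ids)[n.ravel()],
            "item_id": np.asarray(data.item_ids)[i.ravel()],
            "response": data.responses.ravel(),
        }
    )
    if data.times is not None:
        out["rt_seconds"] = data.times.ravel()
    if data.true_classes is not None:
        out["true_class"] = data.true_classes.ravel()
    out.to_csv(path, index=False)


def write_weights(weights: ScoringWeights, path, item_ids=None, trait_names=None) -> None:
    """One row per item x category x dimension: (item_id, category, dimension, weight)."""
    I, D, K1 = weights.trait.shape
    item_ids = item_ids or [f"i{i + 1}" for i in range(I)]
    trait_names = trait_names or [f"trait{d + 1}" for d in range(D)]
    rows = []
    for i in range(I):
        for k in range(K1):
            for d in range(D):
                rows.append((item_ids[i], k, trait_names[d], weights.trait[i, d, k]))
            rows.append((item_ids[i], k, FAKING_DIMENSION, weights.faking[i, k]))
    pd.DataFrame(rows, columns=["item_id", "category", "dimension", "weight"]).to_csv(path, index=False)


def read_weights(path, item_ids=None) -> ScoringWeights:
    """Read a scoring-weight table; categories must be contiguous 0..K and
    every item x category must carry exactly one weight per dimension."""
    df = pd.read_csv(path)
    for col in ("item_id", "category", "dimension", "weight"):
        if col not in df.columns:
            raise ValueError(f"weight table is missing column {col!r}")
    items = item_ids or list(dict.fromkeys(df["item_id"].astype(str)))
    dims = list(dict.fromkeys(df["dimension"].astype(str)))
    if FAKING_DIMENSION not in dims:
        raise ValueError("weight table has no FAKING dimension rows")
    traits = [d for d in dims if d != FAKING_DIMENSION]
    cats = sorted(df["category"].unique())
    if cats != list(range(len(cats))):
        raise ValueError("categories must be contiguous 0..K")
    K1, I, D = len(cats), len(items), len(traits)
    if len(df) != I * K1 * (D + 1) or df.duplicated(["item_id", "category", "dimension"]).any():
        raise ValueError("every item x category needs exactly one weight per dimension")
    trait_w = np.zeros((I, D, K1))
    fake_w = np.zeros((I, K1))
    iidx = {s: i for i, s in enumerate(items)}
    didx = {s: d for d, s in enumerate(traits)}
    for _, row in df.iterrows():
        i, k = iidx[str(row["item_id"])], int(row["category"])
        if row["dimension"] == FAKING_DIMENSION:
            fake_w[i, k] = row["weight"]
        else:
            trait_w[i, didx[str(row["dimension"])], k] = row["weight"]
    return ScoringWeights(trait=trait_w, faking=fake_w)


def rescale_desirability(ratings, scale_min: float, scale_max: float) -> np.ndarray:
    """Affinely map raw desirability ratings onto the common 0-6 weight metric.

    The mapping sends the rating scale's *possible* minimum to 0 and its
    possible maximum to 6, preserving order and relative spacing.
    """
    ratings = np.asarray(ratings, dtype=float)
    if scale_max <= scale_min:
        raise ValueError("degenerate rating scale: scale_max must exceed scale_min")
    if np.any(ratings < scale_min) or np.any(ratings > scale_max):
        raise ValueError("ratings outside the declared scale range")
    return (ratings - scale_min) * 6.0 / (scale_max - scale_min)


def save_posterior(result: PosteriorResult, path) -> None:
    """Persist draws as .npz with a JSON sidecar of model/sampler metadata."""
    path = Path(path)
    arrays = {f"draws__{k}": v for k, v in result.draws.items()}
    if result.person_draws is not None:
        arrays["person_draws"] = result.person_draws
    if result.loglik_resp is not None:
        arrays["loglik_resp"] = result.loglik_resp
    if result.loglik_joint is not None:
        arrays["loglik_joint"] = result.loglik_joint
    arrays["weights_trait"] = result.spec.weights.trait
    arrays["weights_faking"] = result.spec.weights.faking
    np.savez_compressed(path, **arrays)
    meta = {
        "variant": result.spec.variant,
        "converged": bool(result.converged),
        "rhat_offenders": result.rhat_offenders,
        "mcmc": {k: getattr(result.mcmc, k) for k in ("chains", "warmup", "samples", "seed", "marginalize")},
        "priors": vars(result.priors),
        "acceptance": result.acceptance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_posterior(path) -> PosteriorResult:
    path = Path(path)
    npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    weights = ScoringWeights(trait=npz["weights_trait"], faking=npz["weights_faking"])
    spec = ModelSpec(variant=meta["variant"], weights=weights)
    draws = {k[len("draws__"):]: npz[k] for k in npz.files if k.startswith("draws__")}
    result = PosteriorResult(
        spec=spec,
        draws=draws,
        person_draws=npz["person_draws"] if "person_draws" in npz.files else None,
        loglik_resp=npz["loglik_resp"] if "loglik_resp" in npz.files else None,
        loglik_joint=npz["loglik_joint"] if "loglik_joint" in npz.files else None,
        mcmc=McmcConfig(**meta["mcmc"]),
        priors=PriorConfig(**meta["priors"]),
        converged=meta["converged"],
        rhat_offenders=meta["rhat_offenders"],
    )
    result.acceptance = meta.get("acceptance", {})
    return result
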