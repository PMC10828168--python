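"""Elastic-net methylation clocks and their cross-validation.

A clock is a sparse linear model on beta values: the response is a
species-aware transform of chronological age (log-linear anchored at sexual
maturity, relative age = age/L, or untransformed years for single-species
clocks), fitted by elastic net with mixing parameter alpha = 0.5 (midway
between ridge and lasso, not tuned), the penalty strength chosen by an
internal 10-fold cross-validation minimising mean squared error on the
transformed scale.  Accuracy is estimated by an outer cross-validation —
leave-one-out for the frog-only clocks, seeded cohort-stratified 10-fold for
the dual human-frog clocks — and summarised by the Pearson correlation R
between predicted and observed age and the MEDIAN absolute error.

Fitting standardises CpGs internally (as glmnet does) but the reported
coefficients are folded back to the raw beta scale, so a saved clock is a
single linear formula on betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .age import AgeTransformSpec
from .io import MethylationCohort, SpeciesRegistry, ValidationError, handle_missing

__all__ = [
    "ClockSpec",
    "ClockModel",
    "CVResult",
    "CLOCK_SPECS",
    "clock_spec",
    "filter_detectable",
    "fit_clock",
    "predict_age",
    "cross_validate",
    "evaluate",
    "write_clock",
    "read_clock",
]

DETECT_LO = 0.05
DETECT_HI = 0.95


@dataclass(frozen=True)
class ClockSpec:
    """What to train a clock on and how to validate it."""

    name: str
    species: tuple            # species included (metadata filter)
    transform: str            # identity | loglinear | relative
    cv: str = "loo"           # loo | kfold
    max_age: float | None = None
    n_folds: int = 10
    l1_ratio: float = 0.5
    inner_folds: int = 10
    detect_lo: float = DETECT_LO
    detect_hi: float = DETECT_HI
    missing_policy: str = "drop"

    def eligible_mask(self, cohort: MethylationCohort) -> np.ndarray:
        mask = np.isin(cohort.species, list(self.species))
        if self.max_age is not None:
            mask &= cohort.ages < self.max_age
        return mask


FROGS = ("laevis", "tropicalis")

#: The seven clocks of the study design.
CLOCK_SPECS = {
    "pan": ClockSpec("pan", FROGS, "loglinear", "loo"),
    "relative_pan": ClockSpec("relative_pan", FROGS, "relative", "loo"),
    "young": ClockSpec("young", FROGS, "loglinear", "loo", max_age=2.0),
    "laevis": ClockSpec("laevis", ("laevis",), "identity", "loo"),
    "tropicalis": ClockSpec("tropicalis", ("tropicalis",), "identity", "loo"),
    "dual_chrono": ClockSpec("dual_chrono", FROGS + ("human",), "loglinear", "kfold"),
    "dual_relative": ClockSpec("dual_relative", FROGS + ("human",), "relative", "kfold"),
}


def clock_spec(name: str) -> ClockSpec:
    try:
        return CLOCK_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown clock {name!r}; available: {sorted(CLOCK_SPECS)}"
        ) from None


@dataclass
class ClockModel:
    """A fitted clock: sparse linear formula on betas plus its transform."""

    name: str
    cpg_ids: list             # CpGs with nonzero coefficients
    coefficients: np.ndarray  # aligned to cpg_ids, raw beta scale
    intercept: float
    transform: AgeTransformSpec
    n_train: int
    species: tuple
    seed: int
    penalty: float            # lambda chosen by inner CV
    n_input_cpgs: int         # CpGs offered to the regression

    @property
    def n_selected(self) -> int:
        return len(self.cpg_ids)

    def score(self, cohort: MethylationCohort) -> np.ndarray:
        """Linear score intercept + sum(coef * beta) per sample."""
        missing = [c for c in self.cpg_ids if c not in set(cohort.beta.cpg_ids)]
        if missing:
            raise ValidationError(f"cohort lacks model CpGs: {missing[:10]}")
        if self.cpg_ids:
            sub = cohort.beta.subset_cpgs(self.cpg_ids)
            return self.intercept + self.coefficients @ sub.values
        return np.full(cohort.n_samples, self.intercept)


@dataclass
class CVResult:
    """Out-of-fold predictions and the study's two accuracy metrics."""

    clock: str
    predictions: pd.Series  # out-of-fold predicted age, by sample_id
    observed: pd.Series     # observed age on the same scale
    folds: pd.Series        # fold index per sample
    pearson_r: float
    median_abs_error: float

    def metrics_for(self, sample_ids) -> tuple:
        """(R, median abs error) restricted to a subset of samples."""
        ids = [s for s in self.predictions.index if s in set(sample_ids)]
        return evaluate(self.predictions.loc[ids], self.observed.loc[ids])


def filter_detectable(cohort: MethylationCohort, lo: float = DETECT_LO,
                      hi: float = DETECT_HI) -> MethylationCohort:
    """Keep CpGs whose mean beta across the (training) samples lies in
    [lo, hi]; CpGs saturated near 0 or 1 carry no usable signal."""
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        means = np.nanmean(cohort.beta.values, axis=1)
    keep = [
        c for c, m in zip(cohort.beta.cpg_ids, means)
        if not np.isnan(m) and lo <= m <= hi
    ]
    if not keep:
        raise ValidationError(
            f"no CpG has mean beta within [{lo}, {hi}]; widen the bounds"
        )
    return cohort.select_cpgs(keep)


def _training_view(cohort, spec, registry):
    """Eligible samples, detectability filter, missing-data policy, response."""
    mask = spec.eligible_mask(cohort)
    sub = cohort.select_samples(mask)
    n_min = max(spec.inner_folds, 10)
    if sub.n_samples < n_min:
        raise ValidationError(
            f"clock {spec.name!r} needs >= {n_min} samples, has {sub.n_samples}"
        )
    for sp in set(sub.species):
        if sp not in registry:
            raise ValidationError(f"species {sp!r} not in registry")
    # canonical sample order: the fit (incl. inner-CV folds) is invariant
    # to the order samples arrive in
    order = np.argsort([s.sample_id for s in sub.samples])
    sub = MethylationCohort(
        sub.beta.subset_samples([sub.samples[i].sample_id for i in order]),
        [sub.samples[i] for i in order],
    )
    sub = handle_missing(sub, spec.missing_policy)
    sub = filter_detectable(sub, spec.detect_lo, spec.detect_hi)
    transform = AgeTransformSpec.from_registry(
        spec.transform, registry, sorted(set(sub.species))
    )
    y = np.array(
        [transform.forward(s.age_years, s.species) for s in sub.samples],
        dtype=float,
    )
    return sub, transform, y


def _fit_enet(X, y, spec, seed):
    """Inner-CV elastic net on standardised predictors; coefficients folded
    back to the raw scale.  Returns (coef, intercept, penalty)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    usable = sd > 0
    Xs = (X[:, usable] - mu[usable]) / sd[usable]
    inner = KFold(n_splits=spec.inner_folds, shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=spec.l1_ratio,
        alphas=50,
        cv=inner,
        max_iter=5000,
        tol=1e-3,
        selection="cyclic",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    coef = np.zeros(X.shape[1])
    coef[usable] = model.coef_ / sd[usable]
    intercept = float(model.intercept_ - np.sum(model.coef_ * mu[usable] / sd[usable]))
    return coef, intercept, float(model.alpha_)


def fit_clock(cohort: MethylationCohort, spec: ClockSpec,
              registry: SpeciesRegistry, seed: int = 0) -> ClockModel:
    """Fit one clock on all eligible samples of *cohort*.

    Deterministic given the seed (which drives only the inner-CV fold
    assignment).
    """
    sub, transform, y = _training_view(cohort, spec, registry)
    X = sub.beta.values.T  # samples x CpGs
    coef, intercept, penalty = _fit_enet(X, y, spec, seed)
    nz = np.nonzero(coef)[0]
    return ClockModel(
        name=spec.name,
        cpg_ids=[sub.beta.cpg_ids[i] for i in nz],
        coefficients=coef[nz].copy(),
        intercept=intercept,
        transform=transform,
        n_train=sub.n_samples,
        species=tuple(sorted(set(sub.species))),
        seed=seed,
        penalty=penalty,
        n_input_cpgs=sub.n_cpgs,
    )


def predict_age(model: ClockModel, cohort: MethylationCohort,
                registry: SpeciesRegistry | None = None) -> pd.Series:
    """Per-sample age predictions in reporting units (years for
    chronological clocks, fractions for relative clocks)."""
    scores = model.score(cohort)
    preds = np.array(
        [
            model.transform.inverse(sc, s.species)
            if model.transform.kind == "loglinear"
            else float(sc)
            for sc, s in zip(scores, cohort.samples)
        ],
        dtype=float,
    )
    return pd.Series(preds, index=[s.sample_id for s in cohort.samples],
                     name=f"{model.name}_predicted")


def _fold_assignment(sub, spec, seed):
    """Outer folds: LOO, or a seeded shuffle stratified by cohort label so
    every fold mixes human and frog samples."""
    n = sub.n_samples
    if spec.cv == "loo":
        return np.arange(n)
    if spec.cv != "kfold":
        raise ValueError(f"unknown outer CV scheme {spec.cv!r}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    labels = sub.cohorts
    for lab in sorted(set(labels)):
        idx = np.nonzero(labels == lab)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % spec.n_folds
    return folds


def cross_validate(cohort: MethylationCohort, spec: ClockSpec,
                   registry: SpeciesRegistry, seed: int = 0) -> CVResult:
    """Out-of-fold accuracy of a clock.

    Every outer training set is refit from scratch — detectability filter,
    standardisation and inner penalty search included — so each held-out
    prediction is untouched by its own sample.
    """
    mask = spec.eligible_mask(cohort)
    sub = cohort.select_samples(mask)
    if sub.n_samples < 3:
        raise ValidationError("cross-validation needs >= 3 eligible samples")
    folds = _fold_assignment(sub, spec, seed)
    sample_ids = [s.sample_id for s in sub.samples]
    preds = pd.Series(index=sample_ids, dtype=float)

    inner_spec = replace(spec, max_age=None)  # eligibility already applied
    for f in sorted(set(folds)):
        test_mask = folds == f
        train = sub.select_samples(~test_mask)
        test = sub.select_samples(test_mask)
        model = fit_clock(train, inner_spec, registry, seed)
        preds.loc[[s.sample_id for s in test.samples]] = predict_age(
            model, test, registry
        ).to_numpy()

    transform = AgeTransformSpec.from_registry(
        spec.transform, registry, sorted(set(sub.species))
    )
    observed = pd.Series(
        [float(transform.observed(s.age_years, s.species)) for s in sub.samples],
        index=sample_ids,
        dtype=float,
    )
    r, mae = evaluate(preds, observed)
    return CVResult(
        clock=spec.name,
        predictions=preds,
        observed=observed,
        folds=pd.Series(folds, index=sample_ids),
        pearson_r=r,
        median_abs_error=mae,
    )


def evaluate(predicted, observed) -> tuple:
    """(Pearson R, median absolute error) between prediction and truth."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise ValidationError("need equal-length vectors with >= 3 entries")
    if np.std(observed) == 0:
        raise ValidationError("observed ages are constant; R undefined")
    if np.std(predicted) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(predicted, observed)[0, 1])
    mae = float(np.median(np.abs(predicted - observed)))
    return r, mae


# ---------------------------------------------------------------------------
# clock serialisation: header block + coefficient table, tab-delimited
# ---------------------------------------------------------------------------

def write_clock(model: ClockModel, path) -> None:
    lines = [
        f"#name\t{model.name}",
        f"#transform\t{model.transform.kind}",
    ]
    for sp in sorted(model.transform.params):
        p = model.transform.params[sp]
        lines.append(f"#species\t{sp}\t{p['m']!r}\t{p['k']!r}\t{p['L']!r}")
    lines += [
        f"#intercept\t{model.intercept!r}",
        f"#n_train\t{model.n_train}",
        f"#seed\t{model.seed}",
        f"#penalty\t{model.penalty!r}",
        f"#n_input_cpgs\t{model.n_input_cpgs}",
        "cpg_id\tcoefficient",
    ]
    for cpg, c in zip(model.cpg_ids, model.coefficients):
        lines.append(f"{cpg}\t{float(c)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_clock(path) -> ClockModel:
    header = {}
    params = {}
    cpgs, coefs = [], []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if parts[0] == "species":
                sp, m, k, L = parts[1], float(parts[2]), float(parts[3]), float(parts[4])
                params[sp] = {"m": m, "k": k, "L": L}
            else:
                header[parts[0]] = parts[1]
        elif not in_table and line.startswith("cpg_id"):
            in_table = True
        else:
            cpg, c = line.split("\t")
            cpgs.append(cpg)
            coefs.append(float(c))
    return ClockModel(
        name=header["name"],
        cpg_ids=cpgs,
        coefficients=np.array(coefs),
        intercept=float(header["intercept"]),
        transform=AgeTransformSpec(kind=header["transform"], params=params),
        n_train=int(header["n_train"]),
        species=tuple(sorted(params)),
        seed=int(header["seed"]),
        penalty=float(header["penalty"]),
        n_input_cpgs=int(header["n_input_cpgs"]),
    )
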