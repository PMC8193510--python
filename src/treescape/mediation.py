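"""Path models linking age, tree integration and behavior.

Mediation is estimated by the product-of-coefficients method on standardized
variables: ``a`` from regressing the mediator (leaf fraction) on x (age) plus
covariates, ``b`` and the direct effect ``c'`` from regressing the outcome on
mediator + x + covariates. The indirect effect is a*b with a percentile
bootstrap confidence interval (subjects resampled with replacement);
significance is the interval excluding zero. Moderation is the ordinary
least-squares interaction test (x * group).

Behavior batteries are reduced to domain scores either as composites
(standardized mean of the assigned standardized tests) or by maximum-likelihood
exploratory factor analysis with oblique (oblimin) rotation and
regression-method factor scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.multivariate.factor import Factor

from .errors import SchemaError, TreescapeError

WORKING_MEMORY_TESTS = ("wms_digit_span", "wms_symbol_span", "wms_letter_number")
EXECUTIVE_TESTS = ("dkefs_verbal_fluency", "cpt_dprime", "stroop_conflict")


@dataclass
class FactorModel:
    n_factors: int
    loadings: pd.DataFrame  # tests x factors
    scores: pd.DataFrame    # subjects x factors, standardized
    method: str


@dataclass
class MediationEstimate:
    outcome: str
    a: float
    b: float
    c_prime: float
    indirect: float
    c_total: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n: int
    covariates: tuple = ()
    significant: bool = False

    def as_dict(self) -> dict:
        return {"outcome": self.outcome, "a": self.a, "b": self.b,
                "c_prime": self.c_prime, "indirect": self.indirect,
                "c_total": self.c_total, "ci": [self.ci_low, self.ci_high],
                "n_boot": self.n_boot, "seed": self.seed, "n": self.n,
                "covariates": list(self.covariates),
                "significant": self.significant}


@dataclass
class ModerationEstimate:
    interaction_beta: float
    p: float
    n: int


def _z(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        raise TreescapeError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def extract_factors(scores: pd.DataFrame, spec, method: str = "composite") -> FactorModel:
    """Reduce a test battery to domain scores.

    ``method='composite'``: ``spec`` maps factor name -> list of test columns;
    each factor score is the standardized mean of the standardized tests.
    ``method='efa'``: ``spec`` is the number of factors; ML extraction with
    oblimin rotation, regression-method scores. Rows with missing values are
    dropped with a warning (listwise deletion).
    """
    if scores.isna().any().any():
        import warnings
        warnings.warn("missing values: listwise deletion applied", RuntimeWarning,
                      stacklevel=2)
        scores = scores.dropna()
    if method == "composite":
        if not isinstance(spec, dict):
            raise SchemaError("composite mode needs a factor->tests mapping")
        cols, load_rows = {}, {}
        for fac, tests in spec.items():
            missing = [t for t in tests if t not in scores.columns]
            if missing:
                raise SchemaError(f"tests not in table: {missing}")
            zs = np.column_stack([_z(scores[t].to_numpy()) for t in tests])
            cols[fac] = _z(zs.mean(axis=1))
            for t in tests:
                load_rows.setdefault(t, {})[fac] = 1.0
        loadings = pd.DataFrame(load_rows).T.reindex(columns=list(spec)).fillna(0.0)
        sc = pd.DataFrame(cols, index=scores.index)
        return FactorModel(len(spec), loadings, sc, "composite")
    if method == "efa":
        n_factors = int(spec)
        x = np.column_stack([_z(scores[c].to_numpy()) for c in scores.columns])
        try:
            res = Factor(x, n_factor=n_factors, method="ml").fit()
        except Exception as exc:  # singular correlation etc.
            raise TreescapeError(
                f"EFA did not converge: {exc}; condition number of the "
                f"correlation matrix: {np.linalg.cond(np.corrcoef(x.T)):.3g}"
            ) from exc
        if n_factors > 1:
            res.rotate("oblimin")
        loadings = pd.DataFrame(res.loadings, index=list(scores.columns),
                                columns=[f"factor{j+1}" for j in range(n_factors)])
        raw = res.factor_scoring(x, method="regression")
        sc = pd.DataFrame(
            {f"factor{j+1}": _z(raw[:, j]) for j in range(n_factors)},
            index=scores.index)
        return FactorModel(n_factors, loadings, sc, "efa")
    raise ValueError(f"unknown method {method!r}")


def _prep_design(covariates, n):
    if covariates is None:
        return np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    cov = np.column_stack([_z(cov[:, j]) for j in range(cov.shape[1])])
    full = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise TreescapeError("collinear covariates")
    return cov


def _paths(x, m, y, cov):
    """Point estimates of a, b, c', c on already-standardized inputs."""
    n = len(x)
    Xa = np.column_stack([np.ones(n), x, cov])
    a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
    Xb = np.column_stack([np.ones(n), m, x, cov])
    bb = np.linalg.lstsq(Xb, y, rcond=None)[0]
    b, c_prime = bb[1], bb[2]
    c = np.linalg.lstsq(Xa, y, rcond=None)[0][1]
    return float(a), float(b), float(c_prime), float(c)


def fit_mediation(
    x, mediator, y, covariates=None, n_boot: int = 5000, seed: int = 0,
    conf: float = 0.95, outcome_names=None,
) -> list[MediationEstimate]:
    """Product-of-coefficients mediation with percentile bootstrap CIs.

    ``y`` may be one vector or a 2-D array of several outcomes (columns); one
    estimate is returned per outcome. All variables are standardized
    internally, so coefficients are on the standardized (beta) scale.
    """
    x = _z(x)
    m = _z(mediator)
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(x)
    if n < 10:
        raise TreescapeError("mediation needs n >= 10")
    if Y.shape[0] != n or len(m) != n:
        raise SchemaError("x, mediator and outcomes must share length")
    Y = np.column_stack([_z(Y[:, j]) for j in range(Y.shape[1])])
    cov = _prep_design(covariates, n)
    names = list(outcome_names) if outcome_names is not None else [
        f"y{j}" for j in range(Y.shape[1])]

    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - conf) / 2, 1 - (1 - conf) / 2
    out = []
    for j in range(Y.shape[1]):
        yj = Y[:, j]
        a, b, c_prime, c = _paths(x, m, yj, cov)
        boots = _bootstrap_indirect(x, m, yj, cov, n_boot, rng)
        ci_low, ci_high = np.quantile(boots, [lo_q, hi_q])
        est = MediationEstimate(
            outcome=names[j], a=a, b=b, c_prime=c_prime, indirect=a * b,
            c_total=c, ci_low=float(ci_low), ci_high=float(ci_high),
            n_boot=n_boot, seed=seed, n=n,
            covariates=tuple(f"cov{k}" for k in range(cov.shape[1])),
            significant=bool(ci_low > 0 or ci_high < 0),
        )
        out.append(est)
    return out


def _bootstrap_indirect(x, m, y, cov, n_boot, rng, chunk: int = 500) -> np.ndarray:
    """Vectorized bootstrap of a*b: batched normal equations over resampled
    subjects, solved chunk-wise to bound memory."""
    n = len(x)
    Da = np.column_stack([np.ones(n), x, cov])            # mediator model
    Db = np.column_stack([np.ones(n), m, x, cov])         # outcome model
    boots = np.empty(n_boot)
    done = 0
    while done < n_boot:
        b_sz = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b_sz, n))
        Xa = Da[idx]                      # (B, n, pa)
        Xb = Db[idx]                      # (B, n, pb)
        mm = m[idx]                       # (B, n)
        yy = y[idx]
        AtA = np.einsum("bni,bnj->bij", Xa, Xa)
        Atm = np.einsum("bni,bn->bi", Xa, mm)
        BtB = np.einsum("bni,bnj->bij", Xb, Xb)
        Bty = np.einsum("bni,bn->bi", Xb, yy)
        try:
            a_hat = np.linalg.solve(AtA, Atm[..., None])[:, 1, 0]
            b_hat = np.linalg.solve(BtB, Bty[..., None])[:, 1, 0]
        except np.linalg.LinAlgError:
            a_hat = np.array([np.linalg.lstsq(Xa[k], mm[k], rcond=None)[0][1]
                              for k in range(b_sz)])
            b_hat = np.array([np.linalg.lstsq(Xb[k], yy[k], rcond=None)[0][1]
                              for k in range(b_sz)])
        boots[done:done + b_sz] = a_hat * b_hat
        done += b_sz
    return boots


def fit_moderation(x, group, y, covariates=None) -> ModerationEstimate:
    """OLS interaction test: y ~ x + group + x*group (+ covariates); reports
    the interaction coefficient and its t-test p-value."""
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise TreescapeError("degenerate moderator: group is constant")
    if len(labels) > 2:
        raise TreescapeError("moderation supports exactly two groups")
    g = (group == labels[1]).astype(float)
    x = _z(x)
    y = _z(y)
    n = len(x)
    cov = _prep_design(covariates, n)
    X = sm.add_constant(np.column_stack([x, g, x * g, cov]))
    fit = sm.OLS(y, X).fit()
    return ModerationEstimate(
        interaction_beta=float(fit.params[3]), p=float(fit.pvalues[3]), n=n)


# ---------------------------------------------------------------------------
# the four pre-registered model configurations


def run_models(metrics: pd.DataFrame, phenotypes: pd.DataFrame, model_id: int,
               mediator_col: str = "Lf", n_boot: int = 5000, seed: int = 0,
               use_latent_structure: bool = False) -> dict:
    """Model 1: age -> Lf -> cognition, controls only.
    Model 2: same, both groups pooled.
    Model 3: age -> Lf -> three symptom domains, patients only.
    Model 4: moderation — does group modify the age -> Lf slope? All subjects.

    Covariates: head motion and gender everywhere; medication additionally in
    the patient-only model. ``use_latent_structure`` replaces the mediator with
    the first principal component of the six standardized global metrics.
    """
    if model_id not in (1, 2, 3, 4):
        raise ValueError(f"model_id must be 1-4, got {model_id}")
    df = metrics.merge(phenotypes, on="subject_id", how="inner")
    if df.empty:
        raise SchemaError("metrics and phenotypes share no subjects")

    def mediator_of(sub):
        if use_latent_structure:
            from .inference import GLOBAL_METRICS
            z = np.column_stack([_z(sub[c].to_numpy()) for c in GLOBAL_METRICS
                                 if np.isfinite(sub[c]).all() and sub[c].std() > 0])
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            pc1 = u[:, 0] * s[0]
            # orient toward leaf fraction so signs are comparable
            if np.corrcoef(pc1, sub[mediator_col])[0, 1] < 0:
                pc1 = -pc1
            return pc1
        return sub[mediator_col].to_numpy(dtype=float)

    def covs_of(sub, with_med):
        cols = [sub["motion"].to_numpy(dtype=float),
                (sub["gender"].to_numpy() == "M").astype(float)]
        if with_med:
            cols.append(sub["medication"].to_numpy(dtype=float))
        return np.column_stack(cols)

    report = {"model": model_id, "n_boot": n_boot, "seed": seed,
              "mediator": "latent_structure_pc1" if use_latent_structure else mediator_col}

    if model_id == 4:
        sub = df.dropna(subset=[mediator_col, "age"])
        est = fit_moderation(sub["age"], sub["group"], mediator_of(sub),
                             covs_of(sub, with_med=False))
        report.update({"interaction_beta": est.interaction_beta, "p": est.p,
                       "n": est.n})
        return report

    if model_id in (1, 2):
        sub = df[df["group"] == "control"] if model_id == 1 else df
        fm = extract_factors(
            sub[list(WORKING_MEMORY_TESTS) + list(EXECUTIVE_TESTS)],
            {"working_memory": list(WORKING_MEMORY_TESTS),
             "executive_function": list(EXECUTIVE_TESTS)},
            method="composite")
        sub = sub.loc[fm.scores.index]  # respect listwise deletion
        outcomes = fm.scores.to_numpy()
        names = list(fm.scores.columns)
        with_med = False
    else:  # model 3
        sub = df[df["group"] == "patient"]
        names = ["psychotic_symptom", "negative_symptom", "disorganization"]
        sub = sub.dropna(subset=names)
        outcomes = sub[names].to_numpy(dtype=float)
        with_med = True

    ests = fit_mediation(
        sub["age"].to_numpy(dtype=float), mediator_of(sub), outcomes,
        covariates=covs_of(sub, with_med), n_boot=n_boot, seed=seed,
        outcome_names=names)
    report["estimates"] = [e.as_dict() for e in ests]
    return report
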