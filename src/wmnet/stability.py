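"""Decomposition stability and predictive validity.

Bootstrap stability: the sample is repeatedly split into two disjoint
subsamples, each is decomposed, every estimated component is matched to its
best reference component (the full-sample decomposition), and the matched
voxel loadings of the two subsamples are correlated.

Cross-validation: components estimated on a training split are projected
onto held-out subjects (dual-regression-style least squares) and the
projected scores are regressed on task performance; the share of runs with
nominally significant associations is compared against a permutation null in
which the performance measures are shuffled across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linmod
from .containers import ICADecomposition
from .errors import DegenerateInputError
from .ica import fastica_decompose, project_scores, standardize_maps


def _row_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of A and every row of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    if np.any(sa == 0) or np.any(sb == 0):
        raise DegenerateInputError("zero-variance source row in matching")
    Ac = (A - A.mean(axis=1, keepdims=True)) / sa[:, None]
    Bc = (B - B.mean(axis=1, keepdims=True)) / sb[:, None]
    return Ac @ Bc.T / A.shape[1]


@dataclass
class ComponentMatch:
    """Mapping from estimated to reference components with signed r."""

    mapping: np.ndarray  # ref index per estimated component
    r: np.ndarray  # signed correlation with the matched reference
    sign_flip: np.ndarray  # True where r < 0
    corr: np.ndarray  # full estimated x reference correlation matrix


def match_components(
    reference_S: np.ndarray, estimated_S: np.ndarray, one_to_one: bool = False
) -> ComponentMatch:
    """Match each estimated component to the reference component with the
    largest |Pearson r| of voxel loadings.

    The default is greedy per estimated component (two estimated components
    may share a reference); ``one_to_one=True`` solves the assignment problem
    maximizing total |r| instead.
    """
    C = _row_corr(np.asarray(estimated_S), np.asarray(reference_S))
    if one_to_one:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-np.abs(C))
        mapping = np.empty(C.shape[0], dtype=int)
        mapping[rows] = cols
    else:
        mapping = np.abs(C).argmax(axis=1)
    r = C[np.arange(C.shape[0]), mapping]
    return ComponentMatch(mapping=mapping, r=r, sign_flip=r < 0, corr=C)


def _matched_for_reference(reference_S, est: ICADecomposition, ref_ids):
    """For each requested reference component, the best-matching estimated
    source and sign-aligned scores."""
    C = _row_corr(est.sources, np.asarray(reference_S))
    sources, scores, rs = [], [], []
    for ref in ref_ids:
        j = int(np.abs(C[:, ref]).argmax())
        sgn = 1.0 if C[j, ref] >= 0 else -1.0
        sources.append(sgn * est.sources[j])
        scores.append(sgn * est.scores[:, j])
        rs.append(C[j, ref])
    return np.array(sources), np.column_stack(scores), np.array(rs)


@dataclass
class StabilityReport:
    runs: pd.DataFrame
    mean_abs_r: pd.Series
    coefficients: pd.DataFrame | None
    subsample_size: int
    n_runs: int
    seed: int


def bootstrap_stability(
    X,
    k: int,
    subsample_size: int,
    n_runs: int = 100,
    seed: int = 0,
    reference: ICADecomposition | None = None,
    behavior: pd.DataFrame | None = None,
    predictors: list[str] | None = None,
    covariates: list[str] | None = None,
    ica_kwargs: dict | None = None,
) -> StabilityReport:
    """Disjoint-split bootstrap of the decomposition.

    Per run two non-intersecting subject subsamples are decomposed, matched
    (sign-aligned) to the full-sample reference, and the matched voxel
    loadings of the two subsamples are correlated.  When a behavior table is
    given, the association models are refit in each subsample and their
    coefficients aggregated across runs.
    """
    from .assoc import fit_ic_model

    values = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    m = values.shape[0]
    if 2 * subsample_size > m:
        raise ValueError("two disjoint subsamples do not fit in the sample")
    ica_kwargs = dict(ica_kwargs or {})
    ss = np.random.SeedSequence(seed)
    if reference is None:
        reference = fastica_decompose(
            values, k, seed=int(ss.generate_state(1)[0] % 2**31), **ica_kwargs
        )
    rng = np.random.default_rng(ss.spawn(1)[0])
    ref_ids = list(range(reference.k))

    rows, coef_rows = [], []
    for run in range(n_runs):
        perm = rng.permutation(m)
        idx1, idx2 = perm[:subsample_size], perm[subsample_size : 2 * subsample_size]
        assert not set(idx1) & set(idx2)
        run_seed = int(rng.integers(2**31 - 1))
        halves = []
        for half, idx in enumerate((idx1, idx2)):
            est = fastica_decompose(values[idx], k, seed=run_seed + half, **ica_kwargs)
            src, sc, r_ref = _matched_for_reference(reference.sources, est, ref_ids)
            halves.append((idx, src, sc, r_ref))
            if behavior is not None and predictors:
                sub = behavior.iloc[idx].reset_index(drop=True)
                for c in ref_ids:
                    others = np.delete(sc, c, axis=1)
                    cov = pd.DataFrame(
                        {f"ic{j}": others[:, jj] for jj, j in enumerate([x for x in ref_ids if x != c])}
                    )
                    for name in covariates or []:
                        cov[name] = sub[name].to_numpy(dtype=float)
                    fit = fit_ic_model(sc[:, c], sub[predictors], cov, component=c)
                    fit["run"] = run
                    fit["half"] = half
                    coef_rows.append(fit)
        r_between = np.array(
            [np.corrcoef(halves[0][1][c], halves[1][1][c])[0, 1] for c in ref_ids]
        )
        for c in ref_ids:
            rows.append(
                {
                    "run": run,
                    "component": c,
                    "r_between": r_between[c],
                    "abs_r_between": abs(r_between[c]),
                    "r_ref_sub1": halves[0][3][c],
                    "r_ref_sub2": halves[1][3][c],
                }
            )

    runs = pd.DataFrame(rows)
    coefficients = None
    if coef_rows:
        allc = pd.concat(coef_rows, ignore_index=True)
        allc["se"] = np.abs(allc["beta"] / allc["t"].replace(0, np.nan))
        coefficients = (
            allc[allc["is_predictor"]]
            .groupby(["component", "predictor"])
            .agg(mean_beta=("beta", "mean"), mean_se=("se", "mean"))
            .reset_index()
        )
    return StabilityReport(
        runs=runs,
        mean_abs_r=runs.groupby("component")["abs_r_between"].mean(),
        coefficients=coefficients,
        subsample_size=subsample_size,
        n_runs=n_runs,
        seed=seed,
    )


def _safe_columns(df: pd.DataFrame, names, allow_drop: bool) -> dict[str, np.ndarray]:
    out = {}
    for name in names:
        v = df[name].to_numpy(dtype=float)
        if v.std(ddof=1) == 0:
            if allow_drop:
                continue
            raise DegenerateInputError(f"constant column {name!r} in test sample")
        out[name] = linmod.zscore(v)
    return out


def _run_regressions(proj, test_idx, behavior, components, measures, covariates):
    """Per component: z-scored OLS of projected scores on measures + covariates."""
    sub = behavior.iloc[test_idx]
    cols = _safe_columns(sub, measures, allow_drop=False)
    cols.update(_safe_columns(sub, covariates, allow_drop=True))
    D, terms = linmod.design_matrix(cols)
    rows = []
    for ci, comp in enumerate(components):
        y = linmod.zscore(proj[:, ci])
        res = linmod.ols(y, D, terms)
        for meas in measures:
            j = terms.index(meas)
            rows.append(
                {"component": comp, "measure": meas, "beta": res.beta[j], "p": res.p[j]}
            )
    return rows


@dataclass
class CrossValidationReport:
    summary: pd.DataFrame  # per (component, measure): percent_significant, mean_beta
    per_run: pd.DataFrame
    runs: list = field(repr=False, default_factory=list)  # (test_idx, projected scores)
    components: tuple = ()
    measures: tuple = ()
    covariates: tuple = ()
    n_runs: int = 0
    seed: int = 0


def cross_validate(
    X,
    behavior: pd.DataFrame,
    train_size: int | None = None,
    test_size: int = 100,
    n_runs: int = 100,
    seed: int = 0,
    k: int = 6,
    components: tuple = (0, 1),
    measures: tuple = ("d_prime_2back", "d_prime_0back"),
    covariates: tuple = ("sex", "age"),
    reference: ICADecomposition | None = None,
    alpha: float = 0.05,
    ica_kwargs: dict | None = None,
) -> CrossValidationReport:
    """Projection cross-validation.

    Per run the sample is split into disjoint training and test subsets; the
    training subjects are decomposed, the estimated components matched to the
    full-sample reference, and their sources projected onto the standardized
    test maps.  The projected scores of the designated components are then
    regressed on the performance measures (plus covariates), and the
    percentage of runs with nominal p < alpha is reported.
    """
    values = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X)
    m = values.shape[0]
    if train_size is None:
        train_size = m - test_size
    if train_size + test_size > m:
        raise ValueError("train_size + test_size exceeds the sample")
    ica_kwargs = dict(ica_kwargs or {})
    ss = np.random.SeedSequence(seed)
    if reference is None:
        reference = fastica_decompose(
            values, k, seed=int(ss.generate_state(1)[0] % 2**31), **ica_kwargs
        )
    rng = np.random.default_rng(ss.spawn(1)[0])

    run_rows, run_store = [], []
    for run in range(n_runs):
        perm = rng.permutation(m)
        test_idx = perm[:test_size]
        train_idx = perm[test_size : test_size + train_size]
        est = fastica_decompose(
            values[train_idx], k, seed=int(rng.integers(2**31 - 1)), **ica_kwargs
        )
        src, _, _ = _matched_for_reference(reference.sources, est, components)
        proj = project_scores(src, values[test_idx], standardize=True)
        run_store.append((test_idx, proj))
        for row in _run_regressions(proj, test_idx, behavior, components, measures, covariates):
            row["run"] = run
            run_rows.append(row)

    per_run = pd.DataFrame(run_rows)
    summary = (
        per_run.groupby(["component", "measure"])
        .agg(
            percent_significant=("p", lambda p: 100.0 * (p < alpha).mean()),
            mean_beta=("beta", "mean"),
        )
        .reset_index()
    )
    return CrossValidationReport(
        summary=summary,
        per_run=per_run,
        runs=run_store,
        components=tuple(components),
        measures=tuple(measures),
        covariates=tuple(covariates),
        n_runs=n_runs,
        seed=seed,
    )


def permutation_empirical_p(
    report: CrossValidationReport,
    behavior: pd.DataFrame,
    n_outer: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical p for the observed percent-significant against a permutation
    null in which the performance measures are shuffled across subjects.

    The projections do not depend on the performance measures, so each outer
    repeat reuses the stored per-run projected scores and only refits the
    regressions -- an exact reformulation of rerunning the cross-validation
    on permuted behavior.  p = (1 + #{null >= observed}) / (n_outer + 1).
    """
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    rng = np.random.default_rng(seed)
    measures = list(report.measures)
    m = len(behavior)
    combos = [(c, meas) for c in report.components for meas in measures]
    null = {combo: np.zeros(n_outer) for combo in combos}

    for rep in range(n_outer):
        perm = rng.permutation(m)
        permuted = behavior.copy()
        permuted[measures] = behavior[measures].to_numpy()[perm]
        counts = {combo: 0 for combo in combos}
        for test_idx, proj in report.runs:
            for row in _run_regressions(
                proj, test_idx, permuted, report.components, measures, report.covariates
            ):
                if row["p"] < alpha:
                    counts[(row["component"], row["measure"])] += 1
        for combo in combos:
            null[combo][rep] = 100.0 * counts[combo] / len(report.runs)

    rows = []
    for _, obs in report.summary.iterrows():
        combo = (obs["component"], obs["measure"])
        nd = null[combo]
        rows.append(
            {
                "component": obs["component"],
                "measure": obs["measure"],
                "observed_percent": obs["percent_significant"],
                "null_mean_percent": nd.mean(),
                "empirical_p": (1.0 + (nd >= obs["percent_significant"]).sum())
                / (n_outer + 1.0),
            }
        )
    return pd.DataFrame(rows)
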