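"""Approximate Bayesian computation with random forests.

The workflow mirrors the standard ABC-RF recipe: simulate a reference table
of (model, parameters, summary statistics) rows under each candidate
demographic scenario, append the first two linear-discriminant axes of the
summaries as extra features, classify the observed summary vector with a
random forest (model choice; the posterior probability reported is the
plurality vote fraction), then regress each parameter on the summaries with
a quantile-regression forest restricted to the winning model's rows
(weighted median and 95% interval from leaf co-membership weights).

Summary statistics per dataset: the folded SFS normalized by the number of
segregating sites S (shape information, decoupled from the mutation scale),
S itself, theta_pi, theta_w and Tajima's D.

Out-of-bag (OOB) error and the OOB confusion matrix act as the internal
cross-validation of the classifier; an OOB-versus-trees curve is available
to choose the forest size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalsim import DEFAULT_DEME, DEFAULT_GRID, DEFAULT_MU, DemographicModel, SampleSpec, simulate_sfs
from .errors import ConfigError, SampleSizeError
from .sfs import FoldedSFS, tajimas_d, theta_pi, theta_w

__all__ = [
    "PriorSpec",
    "SimConfig",
    "ReferenceTable",
    "ModelPosterior",
    "ParamPosterior",
    "draw_params",
    "summarize_sfs",
    "summary_names",
    "build_reference_table",
    "append_lda_axes",
    "augment_observed",
    "rf_model_select",
    "rf_param_estimate",
    "confusion_matrix_oob",
    "oob_error_curve",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors; Nm is the product of the N and m uniforms
    truncated to its own support by rejection."""

    N_mod: tuple[float, float] = (100.0, 100_000.0)
    N_anc: tuple[float, float] = (100.0, 100_000.0)
    T_c: tuple[float, float] = (100.0, 1_500_000.0)
    N: tuple[float, float] = (100.0, 10_000.0)
    m: tuple[float, float] = (1e-6, 1e-2)
    Nm: tuple[float, float] = (0.0001, 100.0)
    T_col: tuple[float, float] = (100.0, 1_500_000.0)

    def __post_init__(self) -> None:
        for name in ("N_mod", "N_anc", "T_c", "N", "m", "Nm", "T_col"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"prior {name}: lower bound must be < upper")


@dataclass(frozen=True)
class SimConfig:
    """Per-dataset simulation settings shared by the whole reference table."""

    n_dip: int = 10
    n_loci: int = 500
    locus_len: int = 100
    mu: float = DEFAULT_MU
    deme: tuple[int, int] = DEFAULT_DEME
    grid: tuple[int, int] = DEFAULT_GRID


MODEL_PARAMS = {
    "NS": ("N_mod", "N_anc", "T_c"),
    "FIM": ("N", "m", "Nm", "T_col", "N_anc"),
    "SST": ("N", "m", "Nm", "T_col", "N_anc"),
}


def draw_params(
    prior: PriorSpec,
    kind: str,
    rng: int | np.random.Generator | None = None,
    max_tries: int = 10_000,
) -> dict[str, float]:
    """One joint draw from the prior of the given model kind."""
    gen = np.random.default_rng(rng)
    if kind == "NS":
        return {
            "N_mod": gen.uniform(*prior.N_mod),
            "N_anc": gen.uniform(*prior.N_anc),
            "T_c": gen.uniform(*prior.T_c),
        }
    if kind not in ("FIM", "SST"):
        raise ConfigError(f"unknown model kind {kind!r}")
    for _ in range(max_tries):
        N = float(gen.integers(int(prior.N[0]), int(prior.N[1]) + 1))
        m = gen.uniform(*prior.m)
        if prior.Nm[0] <= N * m <= prior.Nm[1]:
            return {
                "N": N,
                "m": m,
                "Nm": N * m,
                "T_col": gen.uniform(*prior.T_col),
                "N_anc": gen.uniform(*prior.N_anc),
            }
    raise ConfigError("Nm rejection sampling failed: empty feasible region?")


def _model_from_params(kind: str, params: dict[str, float], cfg: SimConfig) -> DemographicModel:
    if kind == "NS":
        return DemographicModel(kind="NS", mu=cfg.mu, N_mod=params["N_mod"],
                                N_anc=params["N_anc"], T_c=params["T_c"])
    return DemographicModel(kind=kind, mu=cfg.mu, grid=cfg.grid, N=params["N"],
                            m=params["m"], T_col=params["T_col"], N_anc=params["N_anc"])


def summary_names(n_haploid: int) -> list[str]:
    half = n_haploid // 2
    return [f"ss_eta{j}" for j in range(1, half + 1)] + ["ss_S", "ss_pi", "ss_w", "ss_td"]


def summarize_sfs(sfs: FoldedSFS) -> np.ndarray:
    """Summary vector: eta/S, S, theta_pi, theta_w, Tajima's D."""
    S = sfs.S
    if S == 0:
        raise ValueError("cannot summarize a monomorphic dataset")
    return np.concatenate([
        sfs.eta / S,
        [S, theta_pi(sfs), theta_w(sfs), tajimas_d(sfs)],
    ])


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summaries) rows driving the ABC step."""

    df: pd.DataFrame
    n_haploid: int
    config: SimConfig
    seed: int | None = None
    lda: LinearDiscriminantAnalysis | None = field(default=None, repr=False)
    lda_keep: np.ndarray | None = field(default=None, repr=False)

    @property
    def summary_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(("ss_", "ld"))]

    def model_counts(self) -> pd.Series:
        return self.df["model"].value_counts()

    def X(self) -> np.ndarray:
        return self.df[self.summary_cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        return self.df["model"].to_numpy()


def build_reference_table(
    models: list[str],
    prior: PriorSpec,
    nsim_per_model: int,
    config: SimConfig = SimConfig(),
    rng: int | np.random.Generator | None = None,
    max_retries: int = 20,
) -> ReferenceTable:
    """Simulate the reference table: draw parameters, simulate an SFS dataset,
    summarize. Monomorphic datasets are resampled (bounded retries).
    Rows are shuffled; everything is deterministic under a fixed seed."""
    gen = np.random.default_rng(rng)
    seed = int(gen.integers(2**31 - 1))
    gen = np.random.default_rng(seed)
    spec = SampleSpec(deme="panmictic", n_dip=config.n_dip)
    n = 2 * config.n_dip
    rows = []
    for kind in models:
        kspec = spec if kind == "NS" else SampleSpec(deme=config.deme, n_dip=config.n_dip)
        for _ in range(nsim_per_model):
            for _try in range(max_retries):
                params = draw_params(prior, kind, gen)
                model = _model_from_params(kind, params, config)
                sfs = simulate_sfs(model, kspec, n_loci=config.n_loci,
                                   locus_len=config.locus_len, rng=gen)
                if sfs.S > 0:
                    break
            else:
                raise RuntimeError(f"{kind}: {max_retries} monomorphic draws in a row")
            row = {"model": kind}
            row.update({f"param_{k}": v for k, v in params.items()})
            row.update(dict(zip(summary_names(n), summarize_sfs(sfs))))
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sample(frac=1.0, random_state=seed % (2**32)).reset_index(drop=True)
    return ReferenceTable(df=df, n_haploid=n, config=config, seed=seed)


def append_lda_axes(
    table: ReferenceTable, observed: np.ndarray
) -> tuple[ReferenceTable, np.ndarray]:
    """Fit an LDA on the summary columns (labels = model) and append its first
    two axes to the table and to the observed vector. Original columns are
    untouched; constant columns are dropped from the projection only."""
    labels = table.y()
    if len(np.unique(labels)) < 2:
        raise SampleSizeError("LDA needs >= 2 model labels")
    cols = [c for c in table.df.columns if c.startswith("ss_")]
    X = table.df[cols].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if keep.sum() < 1:
        raise SampleSizeError("all summary columns are constant")
    n_comp = min(2, len(np.unique(labels)) - 1, int(keep.sum()))
    lda = LinearDiscriminantAnalysis(n_components=n_comp)
    Z = lda.fit_transform(X[:, keep], labels)
    obs = np.asarray(observed, dtype=float)
    zo = lda.transform(obs[None, keep])[0]
    df = table.df.copy()
    for i in range(n_comp):
        df[f"ld{i + 1}"] = Z[:, i]
    aug = np.concatenate([obs, zo])
    out = ReferenceTable(df=df, n_haploid=table.n_haploid, config=table.config,
                         seed=table.seed, lda=lda, lda_keep=keep)
    return out, aug


def augment_observed(table: ReferenceTable, observed: np.ndarray) -> np.ndarray:
    """Project a new observed summary vector through the table's fitted LDA."""
    if table.lda is None:
        raise ConfigError("table has no fitted LDA (call append_lda_axes first)")
    obs = np.asarray(observed, dtype=float)
    zo = table.lda.transform(obs[None, table.lda_keep])[0]
    return np.concatenate([obs, zo])


@dataclass(frozen=True)
class ModelPosterior:
    selected: str
    posterior_probability: float
    votes: dict[str, float]
    oob_error: float
    confusion: pd.DataFrame

    def __post_init__(self) -> None:
        tot = sum(self.votes.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("vote fractions must sum to 1")


@dataclass(frozen=True)
class ParamPosterior:
    param: str
    median: float
    q025: float
    q975: float
    oob_mse: float
    oob_rmse: float
    constant_response: bool = False

    def __post_init__(self) -> None:
        if not (self.q025 <= self.median <= self.q975):
            raise ValueError("quantiles out of order")


def _forest_seed(rng) -> int:
    return int(np.random.default_rng(rng).integers(2**31 - 1))


def rf_model_select(
    table: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 500,
    rng: int | np.random.Generator | None = None,
) -> ModelPosterior | list[ModelPosterior]:
    """Random-forest model choice; PP is the winner's vote fraction.

    ``observed`` may be one summary vector or a matrix of vectors (one per
    row); a single forest is trained either way.
    """
    if n_trees < 1:
        raise ConfigError("n_trees must be >= 1")
    X = table.X()
    y = table.y()
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    if obs.shape[1] != X.shape[1]:
        raise ConfigError("observed summary dimension does not match table")
    clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                 random_state=_forest_seed(rng), n_jobs=1)
    clf.fit(X, y)
    votes_arr = np.zeros((obs.shape[0], len(clf.classes_)))
    for tree in clf.estimators_:
        pred = tree.predict(obs).astype(int)
        votes_arr[np.arange(obs.shape[0]), pred] += 1
    votes_arr /= n_trees
    conf = _oob_confusion(clf, y)
    oob_err = float(1.0 - clf.oob_score_)
    results = []
    for row in votes_arr:
        winner = clf.classes_[int(np.argmax(row))]
        results.append(ModelPosterior(
            selected=str(winner),
            posterior_probability=float(row.max()),
            votes={str(k): float(v) for k, v in zip(clf.classes_, row)},
            oob_error=oob_err,
            confusion=conf,
        ))
    if np.asarray(observed).ndim == 1:
        return results[0]
    return results


def _oob_confusion(clf: RandomForestClassifier, y: np.ndarray) -> pd.DataFrame:
    dec = clf.oob_decision_function_
    ok = ~np.isnan(dec).any(axis=1) & (dec.sum(axis=1) > 0)
    pred = clf.classes_[np.argmax(dec[ok], axis=1)]
    truth = y[ok]
    classes = list(clf.classes_)
    conf = pd.DataFrame(0.0, index=classes, columns=classes)
    for t in classes:
        sel = truth == t
        if sel.sum() == 0:
            conf.loc[t, t] = 1.0  # degenerate: no OOB rows for this class
            continue
        for p in classes:
            conf.loc[t, p] = float(np.mean(pred[sel] == p))
    return conf


def confusion_matrix_oob(
    table: ReferenceTable,
    n_trees: int = 500,
    rng: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-normalized OOB confusion matrix and per-model error rates."""
    X = table.X()
    y = table.y()
    clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                 random_state=_forest_seed(rng), n_jobs=1)
    clf.fit(X, y)
    conf = _oob_confusion(clf, y)
    per_model_error = 1.0 - pd.Series(np.diag(conf), index=conf.index)
    return conf, per_model_error


def oob_error_curve(
    table: ReferenceTable,
    tree_grid=(50, 100, 200, 500, 1000),
    rng: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """OOB error as a function of forest size (the forest-size diagnostic)."""
    seed = _forest_seed(rng)
    X = table.X()
    y = table.y()
    out = []
    for nt in tree_grid:
        clf = RandomForestClassifier(n_estimators=int(nt), oob_score=True,
                                     random_state=seed, n_jobs=1)
        clf.fit(X, y)
        out.append({"n_trees": int(nt), "oob_error": float(1.0 - clf.oob_score_)})
    return pd.DataFrame(out)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


def rf_param_estimate(
    table: ReferenceTable,
    observed: np.ndarray,
    param: str,
    n_trees: int = 500,
    rng: int | np.random.Generator | None = None,
    min_samples_leaf: int = 5,
) -> ParamPosterior:
    """Quantile-regression-forest posterior for one parameter.

    The table must be restricted to a single model. Per-tree leaf
    co-membership of the observed vector yields weights over the training
    responses; the weighted median and the 2.5%/97.5% quantiles form the
    point estimate and 95% interval. OOB MSE/RMSE quantify forest fit.
    """
    kinds = table.df["model"].unique()
    if len(kinds) != 1:
        raise ConfigError("parameter estimation expects a single-model table")
    col = f"param_{param}"
    if col not in table.df.columns:
        raise ConfigError(f"unknown parameter {param!r} for model {kinds[0]}")
    y = table.df[col].to_numpy(dtype=float)
    X = table.X()
    obs = np.asarray(observed, dtype=float)
    if np.all(y == y[0]):
        return ParamPosterior(param=param, median=float(y[0]), q025=float(y[0]),
                              q975=float(y[0]), oob_mse=0.0, oob_rmse=0.0,
                              constant_response=True)
    reg = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                min_samples_leaf=min_samples_leaf,
                                random_state=_forest_seed(rng), n_jobs=1)
    reg.fit(X, y)
    leaves = reg.apply(X)
    obs_leaves = reg.apply(obs[None, :])[0]
    w = np.zeros(len(y))
    for t in range(n_trees):
        same = leaves[:, t] == obs_leaves[t]
        w[same] += 1.0 / same.sum()
    w /= n_trees
    med = _weighted_quantile(y, w, 0.5)
    q025 = _weighted_quantile(y, w, 0.025)
    q975 = _weighted_quantile(y, w, 0.975)
    resid = y - reg.oob_prediction_
    mse = float(np.mean(resid**2))
    return ParamPosterior(param=param, median=med, q025=q025, q975=q975,
                          oob_mse=mse, oob_rmse=float(np.sqrt(mse)))
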