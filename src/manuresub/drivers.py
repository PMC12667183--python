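"""Driver analysis: what explains yield and soil quality?

Two permutation-based procedures link the soil variables (physicochemical
indicators, hydrolase activities, stoichiometry vector length and angle)
to the responses of interest:

* **Mantel tests** correlate distance matrices: variables are grouped into
  blocks, each block is z-scored and turned into a Euclidean sample
  distance matrix, and the correlation with the response distance matrix
  is tested by simultaneously permuting rows and columns of one matrix.

* **Permutation importance with significance** follows the rfPermute
  scheme: a bagged ensemble of regression trees is fitted, each feature's
  importance is the mean increase in out-of-bag (OOB) squared error when
  that feature's OOB values are shuffled, and a per-feature null
  distribution is built by refitting the whole ensemble with the response
  vector permuted.  p-values use the add-one rule and are never zero.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "MantelResult",
    "ImportanceResult",
    "mantel_test",
    "feature_distance",
    "permutation_importance",
    "correlation_table",
    "driver_report",
    "significance_stars",
]


# ---------------------------------------------------------------- Mantel


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    method: str


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    d1,
    d2,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson (or Spearman) correlation of the upper-triangle
    entries; the null is built by applying the same random permutation to
    the rows and columns of ``d2``.  One-tailed
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    """
    a = _check_distance_matrix(d1, "d1")
    b = _check_distance_matrix(d2, "d2")
    if a.shape != b.shape:
        raise ValueError("distance matrices must have the same dimension")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)

    if method == "pearson":
        corr = lambda u, v: stats.pearsonr(u, v)[0]
    elif method == "spearman":
        corr = lambda u, v: stats.spearmanr(u, v)[0]
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r_obs = corr(a[iu], b[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b_perm = b[np.ix_(perm, perm)]
        if corr(a[iu], b_perm[iu]) >= r_obs:
            hits += 1
    return MantelResult(
        r=float(r_obs), p=(1 + hits) / (1 + n_perm), n_perm=n_perm,
        seed=seed, method=method,
    )


def feature_distance(block: pd.DataFrame) -> pd.DataFrame:
    """Euclidean sample distance on a z-scored block of variables."""
    x = block.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0  # constant columns contribute nothing
    z = (x - x.mean(axis=0)) / sd
    dm = squareform(pdist(z, metric="euclidean"))
    return pd.DataFrame(dm, index=block.index, columns=block.index)


# --------------------------------------- permutation importance (rfPermute)


@dataclass
class ImportanceResult:
    """Per-feature OOB permutation importance with permutation p-values."""

    table: pd.DataFrame  # index feature; columns importance, p
    n_trees: int
    n_null: int
    seed: int | None

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("importance", ascending=False)


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, rng, max_features):
    """Bagged regression trees with explicit bootstrap/OOB bookkeeping."""
    n = len(y)
    trees, oob_masks = [], []
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oob_masks.append(oob)
    return trees, oob_masks


def _oob_importances(trees, oob_masks, X, y, rng) -> np.ndarray:
    """Mean OOB MSE increase per feature over the ensemble.

    For each tree, every feature's OOB column is shuffled once; all the
    perturbed copies are stacked into a single predict call per tree.
    """
    n, p = X.shape
    deltas = np.zeros(p)
    used = 0
    for tree, oob in zip(trees, oob_masks):
        idx = np.flatnonzero(oob)
        if len(idx) < 2:
            continue
        used += 1
        x_oob, y_oob = X[idx], y[idx]
        m = len(idx)
        stacked = np.tile(x_oob, (p + 1, 1))
        for f in range(p):
            block = stacked[(f + 1) * m : (f + 2) * m]
            block[:, f] = x_oob[rng.permutation(m), f]
        pred = tree.predict(stacked).reshape(p + 1, m)
        errs = np.mean((pred - y_oob) ** 2, axis=1)
        deltas += errs[1:] - errs[0]
    if used == 0:
        raise RuntimeError("no tree had enough out-of-bag samples")
    return deltas / used


def permutation_importance(
    features: pd.DataFrame,
    response,
    n_trees: int = 500,
    n_null: int = 100,
    seed: int | None = None,
    max_features: float = 1.0 / 3.0,
) -> ImportanceResult:
    """OOB permutation importance with response-permutation significance.

    ``features`` is a samples x variables table, ``response`` a per-sample
    vector.  The null distribution for each feature's importance comes
    from ``n_null`` complete refits with the response permuted, so the
    p-value asks: could an importance this large arise with no
    feature-response association at all?
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and response must align on samples")
    if X.shape[0] < 8:
        raise ValueError("need at least 8 samples")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite values are not supported")
    if np.ptp(y) == 0:
        raise ValueError("constant response: no variance to explain")

    rng = np.random.default_rng(seed)
    trees, oob = _fit_forest(X, y, n_trees, rng, max_features)
    obs = _oob_importances(trees, oob, X, y, rng)

    null_hits = np.zeros(X.shape[1])
    for _ in range(n_null):
        y_perm = y[rng.permutation(len(y))]
        t_null, o_null = _fit_forest(X, y_perm, n_trees, rng, max_features)
        imp_null = _oob_importances(t_null, o_null, X, y_perm, rng)
        null_hits += imp_null >= obs
    p = (1.0 + null_hits) / (1.0 + n_null)

    table = pd.DataFrame(
        {"importance": obs, "p": p}, index=features.columns
    )
    return ImportanceResult(table=table, n_trees=n_trees, n_null=n_null, seed=seed)


# ------------------------------------------------------------ full report


def significance_stars(p: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    features: pd.DataFrame, response, method: str = "pearson"
) -> pd.DataFrame:
    """Per-feature correlation with a response, with p-values and stars."""
    y = np.asarray(response, dtype=float)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            r, p = np.nan, np.nan
        elif method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append({"feature": name, "r": r, "p": p,
                     "stars": significance_stars(p) if np.isfinite(p) else ""})
    return pd.DataFrame(rows).set_index("feature")


#: Variable blocks used for block-level Mantel tests.
MANTEL_BLOCKS = {
    "physicochemical": ("SOC", "TN", "MBC", "MBN", "DOC", "DON", "AHN",
                        "AP", "AK", "BD", "SW"),
    "enzymes": ("BG", "CB", "XYL", "NAG", "LAP", "ALP"),
    "stoichiometry": ("length", "angle"),
}


def driver_report(
    dataset,
    vectors: pd.DataFrame,
    sqi: dict,
    *,
    yield_variable: str = "yield",
    depths=None,
    n_perm: int = 999,
    n_null: int = 100,
    n_trees: int = 100,
    seed: int | None = 0,
    correlation: str = "pearson",
) -> dict[str, dict]:
    """Assemble the per-depth driver tables for yield and SQI.

    For each depth the feature matrix combines the physicochemical
    indicators, enzyme activities, and stoichiometry vector length/angle.
    The report holds, per response (yield, SQI): the pairwise correlation
    table with stars, block-level Mantel tests, and ranked permutation
    importance.
    """
    wide = dataset.to_wide()
    available_depths = list(wide.index.get_level_values("depth").unique())
    plot_level = "plot" in available_depths
    if depths is None:
        depths = [d for d in available_depths if d != "plot"]

    vec = vectors.set_index(["treatment", "replicate", "depth"])[["length", "angle"]]

    # plot-level responses (yield) are shared across depths
    if plot_level:
        resp_source = wide.xs("plot", level="depth")
    else:
        resp_source = None

    rng = np.random.default_rng(seed)
    report: dict[str, dict] = {}
    for depth in depths:
        feats = wide.xs(depth, level="depth", drop_level=False)
        feats = feats.join(vec, how="inner")
        feats = feats.droplevel("depth")
        feats = feats.dropna(axis=1, how="any")

        responses: dict[str, pd.Series] = {}
        if yield_variable in feats.columns:
            responses["yield"] = feats.pop(yield_variable)
        elif resp_source is not None and yield_variable in resp_source.columns:
            responses["yield"] = resp_source[yield_variable].reindex(feats.index)
        if depth in sqi:
            responses["SQI"] = sqi[depth].sqi.reindex(feats.index)

        feature_cols = [c for c in feats.columns
                        if any(c in block for block in MANTEL_BLOCKS.values())]
        feats = feats[feature_cols]

        depth_report: dict[str, dict] = {}
        for resp_name, resp in responses.items():
            if resp.isna().any():
                raise ValueError(f"response {resp_name!r} unaligned at depth {depth}")
            resp_dist = feature_distance(resp.to_frame())
            mantel_rows = []
            for block_name, block_vars in MANTEL_BLOCKS.items():
                cols = [c for c in block_vars if c in feats.columns]
                if not cols:
                    continue
                res = mantel_test(
                    resp_dist.to_numpy(),
                    feature_distance(feats[cols]).to_numpy(),
                    n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                mantel_rows.append(
                    {"block": block_name, "r": res.r, "p": res.p,
                     "stars": significance_stars(res.p)}
                )
            importance = permutation_importance(
                feats, resp, n_trees=n_trees, n_null=n_null,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            depth_report[resp_name] = {
                "correlations": correlation_table(feats, resp, method=correlation),
                "mantel": pd.DataFrame(mantel_rows).set_index("block"),
                "importance": importance.ranked(),
            }
        report[depth] = depth_report
    return report
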