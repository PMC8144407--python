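"""Secondary analyses: 3-D embeddings, arm-level association, tissue specificity.

These mirror the exploratory analyses that accompany the classifier: a
PCA+t-SNE embedding of the meta-feature projections, ordinary least squares
of arm-level normalized mutation burden on copy-number and epigenomic
covariates (marginal and cumulative R^2, Spearman rank correlation), and
tumor-wise scaling of regional projections to visualize tissue specificity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def embed_3d(
    projections: np.ndarray,
    n_pcs: int = 30,
    seed: int = 0,
    perplexity: float = 30.0,
) -> np.ndarray:
    """PCA to ``n_pcs`` components followed by 3-D t-SNE.

    Deterministic for a fixed seed.  Perplexity is clipped to a feasible
    value for small cohorts.
    """
    from sklearn.decomposition import PCA
    from sklearn.manifold import TSNE

    X = np.asarray(projections, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need >= 4 samples for a 3-D embedding")
    k = min(n_pcs, p, n - 1)
    pcs = PCA(n_components=k, random_state=seed).fit_transform(X)
    perp = min(perplexity, (n - 1) / 3.0)
    ts = TSNE(n_components=3, random_state=seed, perplexity=perp, init="pca")
    return ts.fit_transform(pcs)


def arm_averages(
    bin_values: pd.DataFrame, cytobands: pd.DataFrame
) -> pd.DataFrame:
    """Average bin-level values within chromosome arms.

    ``bin_values`` is indexed by (chrom, bin) with one column per quantity;
    ``cytobands`` has columns (chrom, start, end, arm) in 0-based half-open
    coordinates.  Each 1-Mb bin is assigned to the arm containing its start
    position; autosomes only.
    """
    from .metafeatures import DEFAULT_BIN_SIZE

    rows = []
    arms = cytobands.copy()
    arms["chrom"] = arms["chrom"].astype(str).str.replace(r"^chr", "", regex=True)
    arms = arms[arms["chrom"].str.fullmatch(r"\d+")]
    for (chrom, b), vals in bin_values.iterrows():
        start = (int(b) - 1) * DEFAULT_BIN_SIZE  # bin's 0-based start
        hit = arms[(arms["chrom"] == str(chrom))
                   & (arms["start"] <= start) & (start < arms["end"])]
        if len(hit) == 0:
            continue
        rows.append({"arm": f"{chrom}{hit.iloc[0]['arm']}", **vals.to_dict()})
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).groupby("arm").mean()


def arm_regression(
    arm_table: pd.DataFrame, response: str, predictors: list[str]
) -> pd.DataFrame:
    """Marginal and cumulative OLS R^2 of arm-level burden on covariates.

    Marginal: response ~ predictor alone.  Cumulative: response ~ the first
    j predictors, j = 1..len(predictors); the cumulative sequence is
    non-decreasing by construction.  Requires >= 3 complete arms; a constant
    response yields NaN.
    """
    df = arm_table[[response] + predictors].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 arms with complete data")
    y = df[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        return pd.DataFrame(
            {"predictor": predictors, "marginal_r2": np.nan, "cumulative_r2": np.nan}
        )

    def _r2(cols: list[str]) -> float:
        X = np.column_stack([np.ones(len(df))]
                            + [df[c].to_numpy(dtype=float) for c in cols])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    marg = [_r2([p]) for p in predictors]
    cum = [_r2(predictors[: j + 1]) for j in range(len(predictors))]
    return pd.DataFrame(
        {"predictor": predictors, "marginal_r2": marg, "cumulative_r2": cum}
    )


def arm_spearman(arm_table: pd.DataFrame, response: str, feature: str) -> float:
    """Spearman rank correlation (average ranks on ties) between two arm-level
    quantities; NaN when either input is constant."""
    df = arm_table[[response, feature]].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 arms")
    x, y = df[response].to_numpy(float), df[feature].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def region_specificity(
    projections: pd.DataFrame, labels
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor-wise scaled regional projections and per-site quartiles.

    Each tumor's selected region projections are divided by that tumor's
    standard deviation across the selected regions (so every retained tumor
    has scaled SD exactly 1); tumors with zero SD are excluded.  Returns the
    scaled per-tumor table and per-(site, region) quartile summaries.
    """
    X = projections.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 region columns for a tumor-wise SD")
    sds = X.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.all():
        import logging
        logging.getLogger(__name__).warning(
            "%d tumor(s) with zero SD across regions excluded", int((~keep).sum())
        )
    scaled = pd.DataFrame(
        X[keep] / sds[keep, None],
        index=projections.index[keep],
        columns=projections.columns,
    )
    labels_kept = np.asarray(labels)[keep]
    long = scaled.assign(site=labels_kept).melt(
        id_vars="site", var_name="region", value_name="scaled"
    )
    quartiles = (
        long.groupby(["site", "region"])["scaled"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .rename(columns={0.25: "q1", 0.5: "median", 0.75: "q3"})
    )
    return scaled, quartiles
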