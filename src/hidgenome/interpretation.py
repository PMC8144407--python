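"""Per-predictor effect quantification via one-vs-rest odds ratios.

For predictor l and class k, the odds ratio is the multiplicative change in
the odds of classification into site k (versus all other sites) when the
l-th predictor moves one standard deviation up from its mean while all other
predictors sit at their means:

    OR(l, k) = exp(s_l g_{l,k}) *
               sum_{k'!=k} exp(a_{k'} + zbar' g_{.,k'}) /
               sum_{k'!=k} exp(a_{k'} + zbar' g_{.,k'} + s_l g_{l,k'})

which by construction equals the ratio of odds(p_k) computed from the model's
predictive probabilities at zbar + s_l e_l and at zbar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HidGenomeModel

_FAMILY_ORDER = ("variant", "intercept-mf", "gene", "sbs96", "region", "epigenome")


@dataclass
class OddsRatioTable:
    """Predictor x class one-vs-rest odds ratios plus the moments used."""

    table: pd.DataFrame          # index: predictor name; columns: classes
    families: pd.Series          # family per predictor
    col_means: np.ndarray
    col_sds: np.ndarray

    def log(self) -> pd.DataFrame:
        return np.log(self.table)


def odds_ratio_ovr(model: HidGenomeModel, l: int, k: int) -> float:
    """One-vs-rest odds ratio for predictor l, class k (closed form)."""
    s_l = model.col_sds[l]
    if s_l <= 0:
        raise ValueError(f"predictor {model.columns[l]!r} has zero SD")
    base = model.alpha + model.col_means @ model.Gamma     # scores at zbar
    bump = base + s_l * model.Gamma[l]                     # scores at zbar + s_l e_l
    others = [kk for kk in range(model.K) if kk != k]
    num = np.exp(base[others] - base.max()).sum()
    den = np.exp(bump[others] - base.max()).sum()
    return float(np.exp(s_l * model.Gamma[l, k]) * num / den)


def odds_ratio_table(model: HidGenomeModel) -> OddsRatioTable:
    """All (predictor, class) one-vs-rest odds ratios.

    Predictors with zero SD are reported as NaN (undefined); inactive groups
    come out exactly 1.
    """
    m, K = model.Gamma.shape
    out = np.full((m, K), np.nan)
    base = model.alpha + model.col_means @ model.Gamma
    c = base.max()
    eb = np.exp(base - c)
    tot = eb.sum()
    for l in range(m):
        s_l = model.col_sds[l]
        if s_l <= 0:
            continue
        ebump = np.exp(base - c + s_l * model.Gamma[l])
        tot_b = ebump.sum()
        for k in range(K):
            num = tot - eb[k]
            den = tot_b - ebump[k]
            out[l, k] = np.exp(s_l * model.Gamma[l, k]) * num / den
    table = pd.DataFrame(out, index=model.columns, columns=model.classes)
    families = pd.Series(model.families, index=model.columns, name="family")
    return OddsRatioTable(table=table, families=families,
                          col_means=model.col_means, col_sds=model.col_sds)


def top_predictors(
    ortable: OddsRatioTable, m: int = 40, active_only: bool = True
) -> pd.DataFrame:
    """Top-m predictors by max-over-classes |log OR|, grouped by family.

    Ties break by family order (variant, intercept-mf, gene, sbs96, region,
    epigenome) then predictor name.  Returns per-class log-ORs with a
    ``max_abs_log_or`` column.
    """
    logs = np.log(ortable.table)
    score = logs.abs().max(axis=1)
    df = logs.copy()
    df["family"] = ortable.families
    df["max_abs_log_or"] = score
    if active_only:
        df = df[score > 0]
    fam_rank = {f: i for i, f in enumerate(_FAMILY_ORDER)}
    df = df.assign(_fr=df["family"].map(lambda f: fam_rank.get(f, len(fam_rank))),
                   _name=df.index)
    df = df.sort_values(["max_abs_log_or", "_fr", "_name"],
                        ascending=[False, True, True], kind="mergesort")
    df = df.drop(columns=["_fr", "_name"]).head(m)
    order = [f for f in _FAMILY_ORDER if f in set(df["family"])]
    df["_fr"] = df["family"].map({f: i for i, f in enumerate(order)})
    df = df.sort_values(["_fr", "max_abs_log_or"], ascending=[True, False],
                        kind="mergesort").drop(columns="_fr")
    return df


def selection_summary(model: HidGenomeModel) -> pd.DataFrame:
    """Active vs total predictor-group counts per feature family."""
    fams = pd.Series(model.families, name="family")
    active = pd.Series(model.active_groups, name="active")
    df = pd.DataFrame({"family": fams.values, "active": active.values})
    out = df.groupby("family", sort=False).agg(
        active=("active", "sum"), total=("active", "size")
    )
    out["active"] = out["active"].astype(int)
    return out
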