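"""Profile normalization, meta-feature scalar projections, model matrix.

Each tumor's binary mutation profile x_i is normalized to the unit vector
x̃_i = x_i / ||x_i|| (the norm is the square root of total mutation burden).
The scalar projection x̃_i' U_col(l) is then the mutation burden of tumor i
attributable to meta-feature l, normalized by sqrt(burden); for a binary
meta-feature it is (count of the tumor's mutations in the category)/sqrt(m),
and for the intercept meta-feature it is sqrt(m) itself.

The model matrix Z concatenates the d0 screened normalized variant
indicators ("residual effect" predictors) with the p projection columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .catalog import MutationCatalog
from .metafeatures import MetaDesign
from .screening import ScreenResult


def normalize_profiles(X: sp.spmatrix) -> sp.csr_matrix:
    """Row-normalize a binary incidence matrix by sqrt(row sum).

    Raises on any zero-mutation row (those samples should have been removed
    upstream).
    """
    X = X.tocsr().astype(float)
    m = np.asarray(X.sum(axis=1)).ravel()
    if (m < 1).any():
        bad = int(np.flatnonzero(m < 1)[0])
        raise ValueError(f"zero-mutation row at index {bad}")
    inv = 1.0 / np.sqrt(m)
    return sp.diags(inv) @ X


def project(catalog: MutationCatalog, meta_design: MetaDesign) -> np.ndarray:
    """Dense n x p block of meta-feature scalar projections x̃_i' U_col(l)."""
    if meta_design.U.shape[0] != catalog.n_variants:
        raise ValueError(
            f"meta-design rows ({meta_design.U.shape[0]}) != catalog variants "
            f"({catalog.n_variants})"
        )
    Xn = normalize_profiles(catalog.incidence)
    P = Xn @ meta_design.U
    return np.asarray(P.todense()) if sp.issparse(P) else np.asarray(P)


@dataclass
class ProjectedDesign:
    """Tumor x (screened variants + projections) model matrix with metadata.

    The variant block is kept sparse; the projection block is dense.  Each
    column forms its own penalty group spanning all K classes.  Column
    moments (mean, sample SD over the training rows) back the internal
    standardization and the per-SD odds ratios.
    """

    Z_variants: sp.csr_matrix          # n x d0 normalized indicators
    Z_meta: np.ndarray                 # n x p projections
    columns: list[str]                 # variant labels then meta columns
    families: list[str]                # "variant" | meta family per column
    col_means: np.ndarray
    col_sds: np.ndarray                # ddof=1 over training rows
    train_mask: np.ndarray             # bool, rows used for moments/fitting
    screened_variant_idx: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        n1, d0 = self.Z_variants.shape
        n2, p = self.Z_meta.shape
        if n1 != n2:
            raise ValueError("variant and projection blocks disagree on n")
        if d0 + p != len(self.columns) or len(self.columns) != len(self.families):
            raise ValueError("column metadata does not match Z")

    @property
    def n(self) -> int:
        return self.Z_variants.shape[0]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def dense(self) -> np.ndarray:
        """Full dense model matrix [variant block | projection block]."""
        return np.hstack([np.asarray(self.Z_variants.todense()), self.Z_meta])

    def subset_rows(self, mask: np.ndarray) -> "ProjectedDesign":
        idx = np.flatnonzero(np.asarray(mask))
        return ProjectedDesign(
            Z_variants=self.Z_variants[idx].tocsr(),
            Z_meta=self.Z_meta[idx],
            columns=list(self.columns),
            families=list(self.families),
            col_means=self.col_means,
            col_sds=self.col_sds,
            train_mask=self.train_mask[idx],
            screened_variant_idx=self.screened_variant_idx,
        )


def assemble_design(
    catalog: MutationCatalog,
    meta_design: MetaDesign,
    screen: ScreenResult,
    train_mask: np.ndarray | None = None,
) -> ProjectedDesign:
    """Build the model matrix Z = [screened x̃ columns | x̃' U columns].

    ``train_mask`` marks the rows over which column moments are computed
    (defaults to the labeled samples).  Test rows are transformed with the
    training moments — they never influence them.
    """
    if meta_design.U.shape[0] != catalog.n_variants:
        raise ValueError("meta-design built on a different variant list")
    sel = np.asarray(screen.selected, dtype=np.int64)
    if sel.size and sel.max() >= catalog.n_variants:
        raise ValueError("screened variant index outside catalog")
    if train_mask is None:
        train_mask = catalog.labeled_mask
    train_mask = np.asarray(train_mask, dtype=bool)

    Xn = normalize_profiles(catalog.incidence)
    Zv = Xn[:, sel].tocsr()
    Zm = np.asarray((Xn @ meta_design.U).todense())

    var_cols = [catalog.variants[j].label for j in sel]
    columns = var_cols + list(meta_design.columns)
    fam_map = {"intercept": "intercept-mf"}
    families = ["variant"] * len(var_cols) + [
        fam_map.get(f, f) for f in meta_design.families
    ]

    Zfull = np.hstack([np.asarray(Zv.todense()), Zm]) if Zv.shape[1] else Zm
    tr = Zfull[train_mask]
    if tr.shape[0] < 2:
        raise ValueError("need >= 2 training rows for column moments")
    col_means = tr.mean(axis=0)
    col_sds = tr.std(axis=0, ddof=1)
    return ProjectedDesign(
        Z_variants=Zv, Z_meta=Zm, columns=columns, families=families,
        col_means=col_means, col_sds=col_sds, train_mask=train_mask,
        screened_variant_idx=sel,
    )
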