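"""Mutual-information screening of individual variants.

Variants are ranked by the mutual information between their binary presence
indicator and the cancer-site label, estimated with plug-in relative
frequencies and the 0 log 0 = 0 convention (natural logarithm).  Only the
top d0 survive as individual "residual effect" predictors; all remaining
variants contribute solely through their meta-feature projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import MutationCatalog


@dataclass
class ScreenResult:
    """Outcome of MI screening on a labeled catalog."""

    mi: np.ndarray          # nats, one per variant
    counts: np.ndarray      # training occurrence count per variant
    order: np.ndarray       # variant indices sorted best-first
    selected: np.ndarray    # indices of the retained variants, in rank order
    d0: int

    @property
    def ranks(self) -> np.ndarray:
        """1-based rank per variant (1 = most informative)."""
        r = np.empty(len(self.order), dtype=np.int64)
        r[self.order] = np.arange(1, len(self.order) + 1)
        return r


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(x[nz])
    return out


def mutual_information(catalog: MutationCatalog) -> np.ndarray:
    """Plug-in MI (nats) between each variant indicator and the site label.

    Touches only the nonzero entries of the incidence matrix plus per-class
    counts, so cost is O(nnz + d*K).  Requires a fully labeled catalog.
    """
    codes, classes = catalog.label_codes()
    if (codes < 0).any():
        raise ValueError("unlabeled sample present; screening is training-set only")
    K = len(classes)
    if K < 2:
        raise ValueError("need >= 2 classes")
    n = catalog.n_samples
    X = catalog.incidence.tocsc()
    d = catalog.n_variants

    n_k = np.bincount(codes, minlength=K).astype(float)       # class sizes
    # per-variant, per-class presence counts via one sparse product
    Y = np.zeros((n, K))
    Y[np.arange(n), codes] = 1.0
    n_jk = np.asarray((X.T @ Y))                               # d x K, x=1 counts
    n_j = n_jk.sum(axis=1)                                     # total presence

    # joint probabilities for x=1 and x=0
    p1 = n_jk / n                                              # P(X=1, C=k)
    p0 = (n_k[None, :] - n_jk) / n                             # P(X=0, C=k)
    q1 = (n_j / n)[:, None]                                    # P(X=1)
    q0 = 1.0 - q1
    pk = (n_k / n)[None, :]

    # MI = sum p * log(p / (q * pk)) with 0 log 0 = 0; expand as
    # sum [ p log p - p log q - p log pk ] guarding zeros
    def _term(p: np.ndarray, q: np.ndarray) -> np.ndarray:
        t = _xlogx(p)
        nz = p > 0
        t[nz] -= p[nz] * (np.log(np.broadcast_to(q, p.shape)[nz])
                          + np.log(np.broadcast_to(pk, p.shape)[nz]))
        return t.sum(axis=1)

    mi = _term(p1, q1) + _term(p0, q0)
    return np.maximum(mi, 0.0)  # clip -0.0 / rounding dust


def select_top(
    mi: np.ndarray,
    counts: np.ndarray,
    catalog: MutationCatalog,
    d0: int = 250,
) -> ScreenResult:
    """Retain the top-d0 variants by MI.

    Ties break by higher total mutation count, then lexicographic variant key,
    so cross-validation folds are bit-reproducible.  Variants never observed
    in the (training) catalog are ineligible regardless of d0.
    """
    if d0 < 0:
        raise ValueError("d0 must be >= 0")
    d = len(mi)
    keys = [(v.chrom, v.pos, v.ref, v.alt) for v in catalog.variants]
    lex = np.array(sorted(range(d), key=lambda j: keys[j]))
    lex_rank = np.empty(d, dtype=np.int64)
    lex_rank[lex] = np.arange(d)
    # np.lexsort: last key is primary; all ascending, so negate mi and counts
    order = np.lexsort((lex_rank, -counts, -mi))
    eligible = counts[order] > 0
    ranked = order[eligible]
    ranked = np.concatenate([ranked, order[~eligible]])
    selected = ranked[: min(d0, int(eligible.sum()))]
    return ScreenResult(mi=mi, counts=counts, order=ranked,
                        selected=selected, d0=d0)


def screen_catalog(catalog: MutationCatalog, d0: int = 250) -> ScreenResult:
    """Convenience: MI + top-d0 selection on a labeled catalog."""
    mi = mutual_information(catalog)
    counts = np.asarray(catalog.incidence.sum(axis=0)).ravel()
    return select_top(mi, counts, catalog, d0=d0)
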