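"""Somatic SNV catalogs: reading, validation, labeling, and coverage restriction.

A catalog is a sparse binary tumor x variant incidence matrix together with
ordered sample identifiers, ordered variant keys, and optional cancer-site
labels.  Presence/absence is the native encoding: the classifier models the
binary indicator of each variant, so duplicate calls collapse to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: default column-name mapping for MAF-like TSV input
DEFAULT_DIALECT = {
    "sample": "sample",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "context5": "context5",
    "context3": "context3",
}


@dataclass(frozen=True, order=True)
class VariantKey:
    """A single-nucleotide somatic variant keyed by (chrom, pos, ref, alt).

    ``context5``/``context3`` are the immediate 5' and 3' reference flanking
    bases when known; they do not participate in identity or ordering.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    context5: str | None = field(default=None, compare=False)
    context3: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt for variant at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class MutationCatalog:
    """Sparse binary incidence of variants across tumors, plus site labels.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (rows).
    variants : list of VariantKey
        Ordered variant keys (columns), sorted (chrom, pos, ref, alt).
    incidence : scipy.sparse.csr_matrix
        Binary n x d matrix; entry (i, j) = 1 iff tumor i carries variant j.
    labels : list of (str | None)
        Cancer-site label per sample; ``None`` marks a prediction-only tumor.
    ingest_report : dict
        Counts recorded while reading (dropped non-SNV rows etc.).
    """

    samples: list[str]
    variants: list[VariantKey]
    incidence: sp.csr_matrix
    labels: list[str | None] = field(default=None)  # type: ignore[assignment]
    ingest_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = [None] * len(self.samples)
        n, d = self.incidence.shape
        if n != len(self.samples) or d != len(self.variants):
            raise ValueError("incidence shape does not match samples/variants")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def classes(self) -> list[str]:
        """Sorted distinct site labels among labeled samples."""
        return sorted({lab for lab in self.labels if lab is not None})

    @property
    def labeled_mask(self) -> np.ndarray:
        return np.array([lab is not None for lab in self.labels], dtype=bool)

    def burdens(self) -> np.ndarray:
        """Per-tumor total mutation burden (row sums)."""
        return np.asarray(self.incidence.sum(axis=1)).ravel()

    def subset_samples(self, mask: np.ndarray) -> "MutationCatalog":
        idx = np.flatnonzero(np.asarray(mask))
        return MutationCatalog(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            incidence=self.incidence[idx].tocsr(),
            labels=[self.labels[i] for i in idx],
            ingest_report=dict(self.ingest_report),
        )

    def label_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer class codes for labeled samples plus the class list.

        Unlabeled samples get code -1.
        """
        classes = self.classes
        lut = {c: k for k, c in enumerate(classes)}
        codes = np.array(
            [lut[lab] if lab is not None else -1 for lab in self.labels], dtype=np.int64
        )
        return codes, classes


def _normalize_chrom(chrom: pd.Series, strip_chr: bool) -> pd.Series:
    s = chrom.astype(str)
    if strip_chr:
        s = s.str.replace(r"^chr", "", regex=True)
    return s


def read_maf(
    path,
    dialect: Mapping[str, str] | None = None,
    strip_chr: bool = True,
) -> MutationCatalog:
    """Read a MAF-like TSV of somatic SNV calls into a MutationCatalog.

    Non-SNV rows (multi-base or non-ACGT ref/alt) and ref==alt rows are
    dropped and counted in ``ingest_report``.  Duplicate (sample, variant)
    rows collapse to a single incidence of 1.  Variant columns are ordered
    (chrom, pos, ref, alt).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    mandatory = ["sample", "chrom", "pos", "ref", "alt"]
    missing = [cols[c] for c in mandatory if cols[c] not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError("no variants: input contains a header only")

    df = df.rename(columns={v: k for k, v in cols.items() if v in df.columns})
    df["chrom"] = _normalize_chrom(df["chrom"], strip_chr)
    df["pos"] = df["pos"].astype(np.int64)

    ref_u = df["ref"].str.upper()
    alt_u = df["alt"].str.upper()
    is_snv = ref_u.isin(_BASES) & alt_u.isin(_BASES)
    n_non_snv = int((~is_snv).sum())
    same = is_snv & (ref_u == alt_u)
    n_ref_eq_alt = int(same.sum())
    keep = is_snv & ~same
    if n_non_snv:
        logger.info("dropped %d non-SNV rows", n_non_snv)
    if n_ref_eq_alt:
        logger.info("rejected %d rows with ref == alt", n_ref_eq_alt)
    df = df.loc[keep].copy()
    df["ref"] = ref_u[keep]
    df["alt"] = alt_u[keep]
    if len(df) == 0:
        raise ValueError("no variants: all rows were rejected")

    have_ctx = "context5" in df.columns and "context3" in df.columns

    vdf = df[["chrom", "pos", "ref", "alt"]].drop_duplicates().sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    )
    ctx5: dict[tuple, str] = {}
    ctx3: dict[tuple, str] = {}
    if have_ctx:
        for row in df.itertuples(index=False):
            key = (row.chrom, row.pos, row.ref, row.alt)
            c5, c3 = getattr(row, "context5"), getattr(row, "context3")
            if isinstance(c5, str) and isinstance(c3, str):
                ctx5.setdefault(key, c5.upper())
                ctx3.setdefault(key, c3.upper())
    variants = [
        VariantKey(
            r.chrom, int(r.pos), r.ref, r.alt,
            ctx5.get((r.chrom, r.pos, r.ref, r.alt)),
            ctx3.get((r.chrom, r.pos, r.ref, r.alt)),
        )
        for r in vdf.itertuples(index=False)
    ]
    vindex = {(v.chrom, v.pos, v.ref, v.alt): j for j, v in enumerate(variants)}

    samples = sorted(df["sample"].unique())
    sindex = {s: i for i, s in enumerate(samples)}
    rows = df["sample"].map(sindex).to_numpy()
    key_cols = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    colidx = np.array([vindex[k] for k in key_cols], dtype=np.int64)
    data = np.ones(len(df), dtype=np.int8)
    X = sp.coo_matrix((data, (rows, colidx)), shape=(len(samples), len(variants)))
    X = X.tocsr()
    X.data[:] = 1  # collapse duplicate (sample, variant) calls
    X.sum_duplicates()
    X.data[:] = 1

    report = {"non_snv_dropped": n_non_snv, "ref_eq_alt_rejected": n_ref_eq_alt}
    return MutationCatalog(samples=samples, variants=variants, incidence=X,
                           ingest_report=report)


def write_maf(catalog: MutationCatalog, path) -> None:
    """Write a catalog back to MAF-like TSV (one row per (sample, variant))."""
    coo = catalog.incidence.tocoo()
    recs = []
    for i, j in zip(coo.row, coo.col):
        v = catalog.variants[j]
        recs.append(
            (catalog.samples[i], v.chrom, v.pos, v.ref, v.alt,
             v.context5 or "", v.context3 or "")
        )
    out = pd.DataFrame(
        recs, columns=["sample", "chrom", "pos", "ref", "alt", "context5", "context3"]
    ).sort_values(["sample", "chrom", "pos", "ref", "alt"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def attach_labels(
    catalog: MutationCatalog, labels: Mapping[str, str] | pd.DataFrame
) -> MutationCatalog:
    """Attach cancer-site labels; samples absent from the table become test-only.

    Raises if a labeled sample id is unknown to the catalog, or if fewer than
    two distinct classes remain among labeled samples.
    """
    if isinstance(labels, pd.DataFrame):
        mapping = dict(zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1].astype(str)))
    else:
        mapping = dict(labels)
    known = set(catalog.samples)
    offenders = sorted(set(mapping) - known)
    if offenders:
        raise ValueError(f"labels refer to unknown sample(s): {', '.join(offenders)}")
    new_labels = [mapping.get(s) for s in catalog.samples]
    k = len({lab for lab in new_labels if lab is not None})
    if k < 2:
        raise ValueError("single class: need >= 2 distinct site labels")
    return replace(catalog, labels=new_labels)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label table needs (sample_id, site) columns")
    return df


def read_bed(path, strip_chr: bool = True) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into a DataFrame.

    Columns: chrom, start, end, and name when a 4th column is present.
    Malformed lines raise with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from None
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {lineno}: bad interval")
            chrom = parts[0]
            if strip_chr and chrom.startswith("chr"):
                chrom = chrom[3:]
            rows.append((chrom, start, end, parts[3] if len(parts) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def restrict_to_regions(
    catalog: MutationCatalog, mask: pd.DataFrame
) -> tuple[MutationCatalog, dict]:
    """Keep only variants inside the BED mask; drop emptied samples.

    ``mask`` is a BED DataFrame (0-based half-open).  A variant at 1-based
    position p is retained iff p-1 falls in some [start, end) interval on its
    chromosome.  Samples whose row sum becomes zero are removed; the report
    counts removed variants and samples.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in mask.groupby("chrom"):
        ivals = grp[["start", "end"]].to_numpy(dtype=np.int64)
        ivals = ivals[np.argsort(ivals[:, 0], kind="mergesort")]
        # merge overlapping intervals so searchsorted membership is valid
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=np.int64)
        by_chrom[str(chrom)] = (arr[:, 0], arr[:, 1])

    keep_var = np.zeros(catalog.n_variants, dtype=bool)
    for j, v in enumerate(catalog.variants):
        iv = by_chrom.get(v.chrom)
        if iv is None:
            continue
        starts, ends = iv
        p0 = v.pos - 1  # to 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        if idx >= 0 and p0 < ends[idx]:
            keep_var[j] = True

    vidx = np.flatnonzero(keep_var)
    X = catalog.incidence[:, vidx].tocsr()
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    keep_smp = row_sums > 0
    n_removed_samples = int((~keep_smp).sum())
    if n_removed_samples:
        logger.info("removed %d sample(s) with no in-mask variants", n_removed_samples)
    sidx = np.flatnonzero(keep_smp)
    restricted = MutationCatalog(
        samples=[catalog.samples[i] for i in sidx],
        variants=[catalog.variants[j] for j in vidx],
        incidence=X[sidx].tocsr(),
        labels=[catalog.labels[i] for i in sidx],
        ingest_report=dict(catalog.ingest_report),
    )
    report = {
        "variants_removed": int(catalog.n_variants - len(vidx)),
        "samples_removed": n_removed_samples,
    }
    return restricted, report


def save_catalog(catalog: MutationCatalog, path) -> None:
    """Serialize a catalog to an .npz archive."""
    X = catalog.incidence.tocsr()
    np.savez_compressed(
        path,
        samples=np.array(catalog.samples, dtype=object),
        labels=np.array(
            [lab if lab is not None else "" for lab in catalog.labels], dtype=object
        ),
        v_chrom=np.array([v.chrom for v in catalog.variants], dtype=object),
        v_pos=np.array([v.pos for v in catalog.variants], dtype=np.int64),
        v_ref=np.array([v.ref for v in catalog.variants], dtype=object),
        v_alt=np.array([v.alt for v in catalog.variants], dtype=object),
        v_c5=np.array([v.context5 or "" for v in catalog.variants], dtype=object),
        v_c3=np.array([v.context3 or "" for v in catalog.variants], dtype=object),
        indptr=X.indptr, indices=X.indices, data=X.data, shape=np.array(X.shape),
    )


def load_catalog(path) -> MutationCatalog:
    z = np.load(path, allow_pickle=True)
    X = sp.csr_matrix((z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"]))
    variants = [
        VariantKey(c, int(p), r, a, c5 or None, c3 or None)
        for c, p, r, a, c5, c3 in zip(
            z["v_chrom"], z["v_pos"], z["v_ref"], z["v_alt"], z["v_c5"], z["v_c3"]
        )
    ]
    labels = [lab if lab else None for lab in z["labels"]]
    return MutationCatalog(
        samples=list(z["samples"]), variants=variants, incidence=X, labels=labels
    )
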