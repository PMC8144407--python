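"""Meta-feature construction: the variant x meta-feature design matrix U.

Each variant row u_j annotates the mutational context of variant j with five
feature families plus an intercept:

* ``intercept`` — a column of ones; its scalar projection is the square root
  of the tumor's total mutation burden.
* ``gene`` — binary cancer-gene membership columns from a BED interval list.
* ``sbs96`` — the 96 single-base-substitution categories in trinucleotide
  context, pyrimidine-strand collapsed.
* ``region`` — contiguous 1-Mb bin indicators along each chromosome
  (regional mutation density after projection).
* ``epigenome`` — site-specific log-log-transformed chromatin accessibility /
  histone-mark read totals looked up in the variant's bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .catalog import VariantKey, read_bed

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
#: the six pyrimidine-reference substitution types
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = ("A", "C", "G", "T")
#: canonical ordering of the 96 SBS category labels, e.g. "C>A A.A"
SBS96_LABELS = tuple(
    f"{sub} {f5}.{f3}" for sub in SUBSTITUTIONS for f5 in _FLANKS for f3 in _FLANKS
)

FAMILIES = ("intercept", "gene", "sbs96", "region", "epigenome")

DEFAULT_BIN_SIZE = 1_000_000


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def assign_sbs96(variant: VariantKey) -> str | None:
    """SBS-96 category of a variant, pyrimidine-strand collapsed.

    Purine-reference variants are reverse-complemented (ref, alt, and swapped
    complemented flanks) before labeling, so a substitution and its reverse
    complement map to the same category.  Returns ``None`` when a flank is
    missing or ambiguous (context-unassignable).
    """
    ref, alt = variant.ref, variant.alt
    f5, f3 = variant.context5, variant.context3
    if f5 is None or f3 is None or f5 not in COMPLEMENT or f3 not in COMPLEMENT:
        return None
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        return None
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        f5, f3 = COMPLEMENT[f3], COMPLEMENT[f5]
    return f"{ref}>{alt} {f5}.{f3}"


def assign_region(
    variant: VariantKey,
    chrom_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> tuple[str, int]:
    """1-based bin id of the variant: bin k covers (k-1)*bin_size+1 .. k*bin_size."""
    length = chrom_lengths.get(variant.chrom)
    if length is None:
        raise ValueError(f"unknown chromosome {variant.chrom!r}")
    if variant.pos > length:
        raise ValueError(
            f"position {variant.pos} beyond {variant.chrom} length {length}"
        )
    k = -(-variant.pos // bin_size)  # ceil division
    return (variant.chrom, int(k))


def region_bins(
    chrom_lengths: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE
) -> list[tuple[str, int]]:
    """The full bin universe implied by a chromosome-lengths table."""
    bins: list[tuple[str, int]] = []
    for chrom in sorted(chrom_lengths):
        n_bins = -(-int(chrom_lengths[chrom]) // bin_size)
        bins.extend((chrom, k) for k in range(1, n_bins + 1))
    return bins


def read_chrom_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype=str)
    out = {}
    for r in df.itertuples(index=False):
        chrom = r.chrom[3:] if r.chrom.startswith("chr") else r.chrom
        out[chrom] = int(r.length)
    return out


def build_gene_indicators(
    variants: Sequence[VariantKey], gene_intervals: pd.DataFrame
) -> tuple[sp.csr_matrix, list[str]]:
    """Binary d x G membership matrix from a named-interval BED DataFrame.

    A variant may fall in several overlapping genes (all columns set; the
    overlap count is logged).  Intergenic variants get an all-zero row.
    """
    genes = sorted(gene_intervals["name"].unique())
    gidx = {g: l for l, g in enumerate(genes)}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for r in gene_intervals.itertuples(index=False):
        by_chrom.setdefault(str(r.chrom), []).append((int(r.start), int(r.end), gidx[r.name]))
    rows, cols = [], []
    n_overlap = 0
    for j, v in enumerate(variants):
        hits = set()
        for s, e, l in by_chrom.get(v.chrom, ()):
            if s <= v.pos - 1 < e:
                hits.add(l)
        if len(hits) > 1:
            n_overlap += 1
        rows.extend([j] * len(hits))
        cols.extend(hits)
    if n_overlap:
        logger.info("%d variant(s) fall in multiple overlapping genes", n_overlap)
    M = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(variants), len(genes))
    ).tocsr()
    return M, genes


def loglog1p(x):
    """The epigenome score transform f(x) = log(1 + log(1 + x)), natural logs."""
    return np.log1p(np.log1p(x))


@dataclass
class EpigenomeTrack:
    """Bin-level read totals for one epigenomic mark across tissue samples.

    ``data`` has one row per recorded (bin, sample) signal value with columns
    [chrom, bin, sample, signal]; ``sample_sites`` maps each sample id to its
    cancer site.
    """

    mark: str
    data: pd.DataFrame
    sample_sites: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.data["signal"].to_numpy(dtype=float) < 0).any():
            raise ValueError(f"track {self.mark}: negative signal value")


def read_epigenome_track(path, mark: str, sample_sites: Mapping[str, str]) -> EpigenomeTrack:
    """Read a track TSV with columns (chrom, bin, sample, signal) or
    (chrom, start, end, sample, signal)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "bin" not in df.columns:
        if "start" in df.columns:
            df["bin"] = df["start"] // DEFAULT_BIN_SIZE + 1
        else:
            raise ValueError("track needs a 'bin' or 'start' column")
    df["chrom"] = df["chrom"].astype(str).str.replace(r"^chr", "", regex=True)
    return EpigenomeTrack(mark=mark, data=df[["chrom", "bin", "sample", "signal"]],
                          sample_sites=sample_sites)


def build_epigenome_metafeatures(
    track: EpigenomeTrack, sites: Sequence[str]
) -> pd.DataFrame:
    """Per-bin, per-site scores for one mark.

    For each (bin, sample) the thresholded total is the sum of signal values
    strictly exceeding the global median of all signal values in the track
    (values <= median contribute 0).  Thresholded totals are averaged across
    the samples of each requested site and transformed with
    f(x) = log(1 + log(1 + x)).  Bins never recorded for a sample contribute 0
    to that sample's totals.

    Returns a DataFrame indexed by (chrom, bin) with one column per site.
    """
    df = track.data
    site_of = dict(track.sample_sites)
    samples_by_site: dict[str, list[str]] = {s: [] for s in sites}
    for smp, site in site_of.items():
        if site in samples_by_site:
            samples_by_site[site].append(smp)
    empty = [s for s in sites if not samples_by_site[s]]
    if empty:
        raise ValueError(
            f"track {track.mark}: no samples for site(s): {', '.join(empty)}"
        )

    sig = df["signal"].to_numpy(dtype=float)
    med = float(np.median(sig))
    exceed = df.loc[sig > med].copy()
    if len(exceed):
        totals = (
            exceed.groupby(["chrom", "bin", "sample"], sort=True)["signal"]
            .sum()
            .unstack("sample", fill_value=0.0)
        )
    else:
        totals = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["chrom", "bin"])
        )
    out = {}
    for site in sites:
        smps = samples_by_site[site]
        present = [s for s in smps if s in totals.columns]
        if totals.shape[0] == 0:
            vals = pd.Series(0.0, index=totals.index)
        else:
            block = totals.reindex(columns=smps, fill_value=0.0)
            vals = block.mean(axis=1)
        out[site] = loglog1p(vals)
    result = pd.DataFrame(out)
    result.index.names = ["chrom", "bin"]
    return result


@dataclass
class MetaDesign:
    """The d x p meta-design matrix U with named, family-tagged columns."""

    U: sp.csr_matrix
    columns: list[str]
    families: list[str]
    #: same variant ordering as the catalog the design was built from
    variant_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.U.shape[1] != len(self.columns) or len(self.columns) != len(self.families):
            raise ValueError("column metadata does not match U")

    @property
    def p(self) -> int:
        return self.U.shape[1]

    @property
    def family_groups(self) -> dict[str, np.ndarray]:
        fams = np.asarray(self.families)
        return {f: np.flatnonzero(fams == f) for f in dict.fromkeys(self.families)}


def assemble_meta_design(
    catalog,
    chrom_lengths: Mapping[str, int] | None = None,
    gene_intervals: pd.DataFrame | None = None,
    epitracks: Iterable[EpigenomeTrack] = (),
    sites: Sequence[str] | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    include_intercept: bool = True,
    include_sbs96: bool = True,
    include_regions: bool = True,
) -> MetaDesign:
    """Assemble U for a catalog's variant list.

    Column order is [intercept | genes | sbs96 | regions | epigenome].  The
    region universe comes from ``chrom_lengths`` (needed when regions or
    epigenome tracks are requested).  ``sites`` fixes the epigenome column
    order; it defaults to the catalog's label classes.
    """
    variants = catalog.variants
    d = len(variants)
    blocks: list[sp.spmatrix] = []
    columns: list[str] = []
    families: list[str] = []

    if include_intercept:
        blocks.append(sp.csr_matrix(np.ones((d, 1))))
        columns.append("intercept")
        families.append("intercept")

    if gene_intervals is not None:
        G, gene_names = build_gene_indicators(variants, gene_intervals)
        blocks.append(G)
        columns.extend(f"gene:{g}" for g in gene_names)
        families.extend(["gene"] * len(gene_names))

    sbs_labels = [assign_sbs96(v) for v in variants]
    if include_sbs96:
        lut = {lab: l for l, lab in enumerate(SBS96_LABELS)}
        rows = [j for j, lab in enumerate(sbs_labels) if lab is not None]
        cols = [lut[sbs_labels[j]] for j in rows]
        n_unassigned = d - len(rows)
        if n_unassigned:
            logger.info("%d variant(s) context-unassignable for SBS-96", n_unassigned)
        S = sp.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(d, 96)
        ).tocsr()
        blocks.append(S)
        columns.extend(f"sbs96:{lab}" for lab in SBS96_LABELS)
        families.extend(["sbs96"] * 96)

    need_bins = include_regions or any(True for _ in epitracks)
    epitracks = list(epitracks)
    if (include_regions or epitracks) and chrom_lengths is None:
        raise ValueError("chrom_lengths required for region/epigenome meta-features")

    bin_of_variant: list[tuple[str, int]] | None = None
    if include_regions or epitracks:
        bin_of_variant = [assign_region(v, chrom_lengths, bin_size) for v in variants]

    if include_regions:
        universe = region_bins(chrom_lengths, bin_size)
        bidx = {b: l for l, b in enumerate(universe)}
        rows = list(range(d))
        cols = [bidx[b] for b in bin_of_variant]
        R = sp.coo_matrix(
            (np.ones(d), (rows, cols)), shape=(d, len(universe))
        ).tocsr()
        blocks.append(R)
        columns.extend(f"region:{c}:{k}" for c, k in universe)
        families.extend(["region"] * len(universe))

    if epitracks:
        if sites is None:
            sites = catalog.classes
        if not sites:
            raise ValueError("sites required for epigenome meta-features")
        for track in epitracks:
            scores = build_epigenome_metafeatures(track, sites)
            lookup = {
                (str(c), int(b)): scores.loc[(c, b)].to_numpy(dtype=float)
                for c, b in scores.index
            }
            E = np.zeros((d, len(sites)))
            for j, b in enumerate(bin_of_variant):
                vals = lookup.get((b[0], b[1]))
                if vals is not None:
                    E[j] = vals
            blocks.append(sp.csr_matrix(E))
            columns.extend(f"epi:{track.mark}:{s}" for s in sites)
            families.extend(["epigenome"] * len(sites))

    if not blocks:
        raise ValueError("no meta-features requested")
    U = sp.hstack(blocks, format="csr")
    return MetaDesign(
        U=U, columns=columns, families=families,
        variant_labels=[v.label for v in variants],
    )
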