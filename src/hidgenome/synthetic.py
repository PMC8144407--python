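"""Synthetic multi-site tumor cohorts with planted discriminative structure.

The generator emulates the statistical regime the classifier is built for:
an enormous variant universe in which almost every observed variant is a
singleton, per-tumor burdens spanning orders of magnitude (log-normal,
site-specific means), site-specific regional propensities over 1-Mb bins,
site-specific SBS-96 spectra, a handful of recurrent hotspot variants, and
cancer-gene enrichment.  Every planted signal is recorded in a
``SimulatedTruth`` so recovery can be checked end to end without external
data.  Generation is a pure function of the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .catalog import MutationCatalog, VariantKey
from .metafeatures import (COMPLEMENT, DEFAULT_BIN_SIZE, EpigenomeTrack,
                           SBS96_LABELS, region_bins)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults give a 4-site cohort, 100 tumors per site, 3 synthetic
    chromosomes of 1000 Mb (3000 one-Mb bins), log-normal burdens with
    site means 50-500, and strong planted effects in every feature family:
    5 regions, 3 SBS-96 categories, 2 hotspot variants, and 2 enriched genes
    among 20.
    """

    sites: tuple[str, ...] = ("breast", "lung", "skin", "colorectal")
    n_per_site: int = 100
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 1_000_000_000, "2": 1_000_000_000,
                                 "3": 1_000_000_000}
    )
    bin_size: int = DEFAULT_BIN_SIZE
    burden_means: tuple[float, ...] = (50.0, 120.0, 250.0, 500.0)
    burden_log_sd: float = 0.5
    n_planted_regions: int = 5
    region_weight: float = 0.12        # per-site propensity mass on a planted bin
    n_planted_sbs: int = 3
    sbs_weight: float = 0.30           # spectrum mass on a site's planted category
    n_hotspots: int = 2
    hotspot_prob_in: float = 0.8       # occurrence prob in the enriched site
    hotspot_prob_out: float = 0.01
    n_genes: int = 20
    gene_length: int = 100_000
    n_planted_genes: int = 2
    gene_prob_in: float = 0.8          # extra in-gene mutation prob, enriched site
    gene_prob_out: float = 0.02
    epi_marks: tuple[str, ...] = ("dnase", "h3k36me3", "h3k4me1")
    epi_samples_per_site: int = 2

    def __post_init__(self) -> None:
        if len(self.burden_means) != len(self.sites):
            raise ValueError("burden_means must match sites")
        if any(m <= 0 for m in self.burden_means):
            raise ValueError("burden means must be > 0")

    @property
    def bins(self) -> list[tuple[str, int]]:
        return region_bins(self.chrom_lengths, self.bin_size)

    # -- planted structure (deterministic functions of the config) ---------

    def planted_bins(self) -> list[tuple[str, int]]:
        chroms = sorted(self.chrom_lengths)
        out = []
        for i in range(self.n_planted_regions):
            chrom = chroms[i % len(chroms)]
            n_bins = -(-int(self.chrom_lengths[chrom]) // self.bin_size)
            out.append((chrom, 1 + (10 + 40 * i) % n_bins))
        if len(set(out)) != len(out):
            raise ValueError("genome too small for the requested planted regions")
        return out

    def planted_sbs(self) -> list[str]:
        # spread over substitution types: C>A A.A, C>T A.A, T>C A.A, ...
        return [SBS96_LABELS[16 * (2 * i)] for i in range(self.n_planted_sbs)]

    def hotspot_keys(self) -> list[VariantKey]:
        chrom = sorted(self.chrom_lengths)[0]
        if self.chrom_lengths[chrom] < (5 + self.n_hotspots) * self.bin_size:
            raise ValueError("genome too small for the requested hotspots")
        return [
            VariantKey(chrom, (5 + h) * self.bin_size - 123, "C", "T", "A", "A")
            for h in range(self.n_hotspots)
        ]

    def gene_table(self) -> pd.DataFrame:
        """Gene intervals as a BED-like DataFrame (0-based half-open)."""
        chroms = sorted(self.chrom_lengths)
        rows = []
        for g in range(self.n_genes):
            chrom = chroms[g % len(chroms)]
            start = 10_000_000 + 2_000_000 * g
            if start + self.gene_length > self.chrom_lengths[chrom]:
                raise ValueError("genome too small for the requested gene list")
            rows.append((chrom, start, start + self.gene_length, f"G{g:03d}"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def site_of_planted(self) -> dict[str, dict[int, int]]:
        """Which site index each planted feature discriminates."""
        K = len(self.sites)
        return {
            "region": {i: i % K for i in range(self.n_planted_regions)},
            "sbs": {i: i % K for i in range(self.n_planted_sbs)},
            "hotspot": {h: (2 * h) % K for h in range(self.n_hotspots)},
            "gene": {g: (2 * g + 1) % K for g in range(self.n_planted_genes)},
        }

    def bin_propensities(self) -> np.ndarray:
        """Per-site probability vectors over the bin universe."""
        bins = self.bins
        idx = {b: i for i, b in enumerate(bins)}
        K = len(self.sites)
        P = np.ones((K, len(bins)))
        assign = self.site_of_planted()["region"]
        for i, b in enumerate(self.planted_bins()):
            s = assign[i]
            # planted bin takes region_weight of its site's total mass
            P[s, idx[b]] = self.region_weight * len(bins) / (1 - self.region_weight)
        return P / P.sum(axis=1, keepdims=True)

    def sbs_spectra(self) -> np.ndarray:
        K = len(self.sites)
        S = np.ones((K, 96))
        assign = self.site_of_planted()["sbs"]
        lut = {lab: i for i, lab in enumerate(SBS96_LABELS)}
        for i, lab in enumerate(self.planted_sbs()):
            s = assign[i]
            S[s, lut[lab]] = self.sbs_weight * 96 / (1 - self.sbs_weight)
        return S / S.sum(axis=1, keepdims=True)


@dataclass
class SimulatedTruth:
    """Planted discriminative features, named as meta-design columns."""

    planted_region_columns: list[str]
    planted_sbs_columns: list[str]
    hotspot_variants: list[str]
    planted_gene_columns: list[str]
    site_assignment: dict[str, dict[int, int]]

    @property
    def planted_columns(self) -> list[str]:
        return (self.planted_region_columns + self.planted_sbs_columns
                + self.hotspot_variants + self.planted_gene_columns)


def _variant_from_sbs(rng, chrom: str, pos: int, sbs_label: str) -> VariantKey:
    """Build a variant consistent with an SBS-96 category, random strand."""
    sub, flanks = sbs_label.split(" ")
    ref, alt = sub.split(">")
    f5, f3 = flanks.split(".")
    if rng.random() < 0.5:  # purine-strand representation
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        f5, f3 = COMPLEMENT[f3], COMPLEMENT[f5]
    return VariantKey(chrom, pos, ref, alt, f5, f3)


def simulate_cohort(
    config: SimulationConfig, seed: int
) -> tuple[MutationCatalog, dict, SimulatedTruth]:
    """Draw a labeled cohort; returns (catalog, context tables, truth).

    Per tumor: burden m ~ log-normal (site mean, min 1); m mutations placed
    by sampling (bin, SBS category) from the site's propensities, a distinct
    position uniformly within the bin, and a strand-randomized context
    consistent with the category; hotspot occurrences and in-gene extras are
    added by per-site Bernoulli draws.
    """
    rng = np.random.default_rng(seed)
    bins = config.bins
    P_bin = config.bin_propensities()
    P_sbs = config.sbs_spectra()
    hotspots = config.hotspot_keys()
    genes = config.gene_table()
    assign = config.site_of_planted()
    K = len(config.sites)

    sample_variants: list[tuple[str, VariantKey]] = []
    samples, labels = [], []
    canonical: dict[tuple, VariantKey] = {}

    def _intern(v: VariantKey) -> VariantKey:
        return canonical.setdefault((v.chrom, v.pos, v.ref, v.alt), v)

    idx = 0
    for s, site in enumerate(config.sites):
        mu = np.log(config.burden_means[s]) - 0.5 * config.burden_log_sd**2
        for _ in range(config.n_per_site):
            name = f"T{idx:04d}"
            idx += 1
            samples.append(name)
            labels.append(site)
            m = 0
            while m < 1:
                m = int(round(rng.lognormal(mu, config.burden_log_sd)))
            taken: set[tuple[str, int]] = set()
            bin_draws = rng.choice(len(bins), size=m, p=P_bin[s])
            sbs_draws = rng.choice(96, size=m, p=P_sbs[s])
            for bi, ci in zip(bin_draws, sbs_draws):
                chrom, k = bins[bi]
                lo = (k - 1) * config.bin_size + 1
                hi = min(k * config.bin_size, config.chrom_lengths[chrom])
                while True:
                    pos = int(rng.integers(lo, hi + 1))
                    if (chrom, pos) not in taken:
                        taken.add((chrom, pos))
                        break
                v = _intern(_variant_from_sbs(rng, chrom, pos, SBS96_LABELS[ci]))
                sample_variants.append((name, v))
            for h, hv in enumerate(hotspots):
                p = (config.hotspot_prob_in if assign["hotspot"][h] == s
                     else config.hotspot_prob_out)
                if rng.random() < p and (hv.chrom, hv.pos) not in taken:
                    taken.add((hv.chrom, hv.pos))
                    sample_variants.append((name, _intern(hv)))
            for g in range(config.n_planted_genes):
                p = (config.gene_prob_in if assign["gene"][g] == s
                     else config.gene_prob_out)
                if rng.random() < p:
                    row = genes.iloc[g]
                    while True:
                        pos = int(rng.integers(row["start"] + 1, row["end"] + 1))
                        if (row["chrom"], pos) not in taken:
                            taken.add((row["chrom"], pos))
                            break
                    ci = int(rng.choice(96, p=P_sbs[s]))
                    v = _variant_from_sbs(rng, row["chrom"], pos, SBS96_LABELS[ci])
                    sample_variants.append((name, _intern(v)))

    variants = sorted(canonical.values())
    vindex = {(v.chrom, v.pos, v.ref, v.alt): j for j, v in enumerate(variants)}
    sindex = {smp: i for i, smp in enumerate(samples)}
    rows = [sindex[smp] for smp, _ in sample_variants]
    cols = [vindex[(v.chrom, v.pos, v.ref, v.alt)] for _, v in sample_variants]
    X = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(samples), len(variants)),
    ).tocsr()
    X.sum_duplicates()
    X.data[:] = 1

    catalog = MutationCatalog(samples=samples, variants=variants, incidence=X,
                              labels=list(labels))
    truth = SimulatedTruth(
        planted_region_columns=[f"region:{c}:{k}" for c, k in config.planted_bins()],
        planted_sbs_columns=[f"sbs96:{lab}" for lab in config.planted_sbs()],
        hotspot_variants=[v.label for v in hotspots],
        planted_gene_columns=[
            f"gene:{genes.iloc[g]['name']}" for g in range(config.n_planted_genes)
        ],
        site_assignment=assign,
    )
    tables = {
        "genes": genes,
        "chrom_lengths": dict(config.chrom_lengths),
        "bin_propensities": P_bin,
        "sbs_spectra": P_sbs,
    }
    return catalog, tables, truth


def simulate_epigenome_tracks(
    config: SimulationConfig, seed: int, r: float = 0.9
) -> list[EpigenomeTrack]:
    """Bin-level epigenome tracks correlated with site mutation propensities.

    For each mark and site, the site-level signal over bins is a linear blend
    of the standardized mutation propensity (weight ``r``) and independent
    noise (weight sqrt(1-r^2)), mapped affinely to non-negative read totals;
    each of the >= 2 pseudo-samples per site adds small independent noise.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation r must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    bins = config.bins
    P_bin = config.bin_propensities()
    tracks = []
    for mark in config.epi_marks:
        recs = []
        sample_sites = {}
        for s, site in enumerate(config.sites):
            prop = P_bin[s]
            z = (prop - prop.mean()) / prop.std()
            noise = rng.standard_normal(len(bins))
            latent = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
            base = np.maximum(0.0, 100.0 + 30.0 * latent)
            for rep in range(config.epi_samples_per_site):
                smp = f"{site}_ep{rep}"
                sample_sites[smp] = site
                vals = np.maximum(0.0, base + rng.normal(0.0, 5.0, len(bins)))
                recs.extend(
                    (c, k, smp, float(v)) for (c, k), v in zip(bins, vals)
                )
        df = pd.DataFrame(recs, columns=["chrom", "bin", "sample", "signal"])
        tracks.append(EpigenomeTrack(mark=mark, data=df, sample_sites=sample_sites))
    return tracks


def coverage_mask(config: SimulationConfig, fraction_per_bin: float) -> pd.DataFrame:
    """A BED-like mask keeping the first fraction of every 1-Mb bin.

    Emulates restricting whole-genome calls to a smaller sequenced footprint
    (exome- or panel-scale), which thins burdens and removes tumors left with
    no in-mask variants.
    """
    if not 0 < fraction_per_bin <= 1:
        raise ValueError("fraction_per_bin must be in (0, 1]")
    width = int(fraction_per_bin * config.bin_size)
    rows = [
        (c, (k - 1) * config.bin_size, (k - 1) * config.bin_size + width)
        for c, k in config.bins
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = ""
    return df


def write_cohort(
    outdir, config: SimulationConfig, seed: int, with_epigenome: bool = True
) -> dict:
    """Materialize a cohort as plain-text files (MAF, labels, BED, TSV, JSON)."""
    import json
    from pathlib import Path

    from .catalog import write_maf

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, tables, truth = simulate_cohort(config, seed)
    write_maf(catalog, out / "mutations.maf.tsv")
    pd.DataFrame({"sample": catalog.samples, "site": catalog.labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    tables["genes"].to_csv(out / "genes.bed", sep="\t", index=False, header=False)
    pd.DataFrame(
        sorted(tables["chrom_lengths"].items()), columns=["chrom", "length"]
    ).to_csv(out / "chrom_lengths.tsv", sep="\t", index=False, header=False)
    paths = {
        "maf": out / "mutations.maf.tsv",
        "labels": out / "labels.tsv",
        "genes": out / "genes.bed",
        "chrom_lengths": out / "chrom_lengths.tsv",
    }
    if with_epigenome:
        for track in simulate_epigenome_tracks(config, seed + 1):
            p = out / f"epi_{track.mark}.tsv"
            df = track.data.copy()
            df["site"] = df["sample"].map(dict(track.sample_sites))
            df.to_csv(p, sep="\t", index=False)
            paths[f"epi_{track.mark}"] = p
    (out / "truth.json").write_text(json.dumps(dataclasses.asdict(truth), indent=2))
    paths["truth"] = out / "truth.json"
    return paths
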