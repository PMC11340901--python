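"""Windowed diversity and differentiation over an all-sites genotype table.

Nucleotide diversity (pi) and absolute divergence (dxy) use missing-data-aware
counting: every site contributes a count of pairwise allele differences and a
count of pairwise comparisons among the alleles actually genotyped, and a
window's value is the ratio of the summed counts — invariant sites add
comparisons without differences, so the estimates are unbiased by missingness
(the counting convention popularised by pixy).  FST uses the two-population
Weir–Cockerham (1984) variance-component estimator as a ratio of sums, and
Tajima's D follows the original 1989 constants with the full sample size.

Windows are fixed 50 kb tiles by default; a window only enters compartment
averages when it contains at least 10,000 genotyped sites, except for the
mitochondrial genome which is treated as a single window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import (
    ABSENT,
    CompartmentMap,
    GenotypeIOError,
    GenotypeTable,
    expected_ploidy,
)

WINDOW_SIZE = 50_000
MIN_GENOTYPED_SITES = 10_000


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(
    contig_lengths: dict[str, int],
    compartment_map: CompartmentMap,
    window_size: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Tile every contig with fixed windows (0-based half-open); contigs
    labelled ``mt`` are a single full-length window."""
    rows = []
    for contig, length in contig_lengths.items():
        label = compartment_map.label_sites(
            pd.DataFrame({"contig": [contig], "pos": [1]})
        )[0]
        if label == "mt":
            rows.append((contig, 0, int(length), label))
            continue
        for start in range(0, int(length), window_size):
            rows.append((contig, start, min(start + window_size, int(length)), label))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "compartment"])


def _window_index(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Window id for each site (−1 if outside all windows)."""
    out = np.full(len(sites), -1, dtype=np.int64)
    pos0 = sites["pos"].to_numpy() - 1
    contigs = sites["contig"].to_numpy()
    for contig, sub in windows.groupby("contig", sort=False):
        m = contigs == contig
        if not m.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        k = np.searchsorted(starts, pos0[m], side="right") - 1
        ok = (k >= 0) & (pos0[m] < ends[np.clip(k, 0, len(ends) - 1)])
        ids = np.where(ok, sub.index.to_numpy()[np.clip(k, 0, len(ends) - 1)], -1)
        out[m] = ids
    return out


# ---------------------------------------------------------------------------
# per-site counting
# ---------------------------------------------------------------------------

def _pop_counts(table: GenotypeTable, idx: np.ndarray):
    """(n_ref, n_alt, n_called, n_het, n_half_individuals) per site for a
    population given by sample indices."""
    g = table.gt[:, idx, :]
    called = g >= 0
    n_called = called.sum(axis=(1, 2))
    n_alt = (g == 1).sum(axis=(1, 2))
    n_ref = n_called - n_alt
    het = (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0) & (g[:, :, 0] != g[:, :, 1])
    return n_ref, n_alt, n_called, het.sum(axis=1)


def site_pair_counts(
    n_ref_x: np.ndarray,
    n_alt_x: np.ndarray,
    n_ref_y: np.ndarray | None = None,
    n_alt_y: np.ndarray | None = None,
):
    """Pairwise difference and comparison counts per site.

    Within one population: ``diffs = n_ref*n_alt``, ``comparisons =
    C(n_ref+n_alt, 2)``.  Between two populations: ``diffs = n_ref_x*n_alt_y +
    n_alt_x*n_ref_y``, ``comparisons = n_x*n_y``.  Invariant sites naturally
    give (0, comparisons).
    """
    if n_ref_y is None:
        n = n_ref_x + n_alt_x
        return n_ref_x * n_alt_x, n * (n - 1) // 2
    diffs = n_ref_x * n_alt_y + n_alt_x * n_ref_y
    comps = (n_ref_x + n_alt_x) * (n_ref_y + n_alt_y)
    return diffs, comps


def _full_hap_count(
    pop: list[str],
    sample_sheet: pd.DataFrame,
    compartment: str,
) -> int:
    sex = dict(zip(sample_sheet["sample_id"], sample_sheet["sex"]))
    return sum(expected_ploidy(compartment, sex[s]) for s in pop)


def _implicit_needs(table: GenotypeTable, sample_sheet):
    if not table.explicit_invariant and sample_sheet is None:
        raise GenotypeIOError(
            "variant-only table: pass sample_sheet so implicit invariant sites "
            "can be counted"
        )


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def windowed_pi(
    table: GenotypeTable,
    population: list[str],
    compartment_map: CompartmentMap,
    window_size: int = WINDOW_SIZE,
    min_sites: int = MIN_GENOTYPED_SITES,
    sample_sheet: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per window for one population."""
    _implicit_needs(table, sample_sheet)
    idx = table.sample_index(population)
    windows = make_windows(table.contig_lengths, compartment_map, window_size)
    wid = _window_index(table.sites, windows)
    valid = ~_multiallelic(table)
    n_ref, n_alt, n_called, _ = _pop_counts(table, idx)
    diffs, comps = site_pair_counts(n_ref, n_alt)
    use = valid & (wid >= 0)
    out = _aggregate(
        windows, wid[use], diffs[use].astype(float), comps[use].astype(float),
        genotyped=(comps[use] > 0),
    )
    if not table.explicit_invariant:
        _add_implicit(
            out, windows, table, wid, population, sample_sheet, compartment_map,
            between=None,
        )
    _finalize(out, min_sites, statistic="pi")
    return out


def windowed_dxy(
    table: GenotypeTable,
    pop_x: list[str],
    pop_y: list[str],
    compartment_map: CompartmentMap,
    window_size: int = WINDOW_SIZE,
    min_sites: int = MIN_GENOTYPED_SITES,
    sample_sheet: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Absolute divergence per window between two populations (symmetric)."""
    _implicit_needs(table, sample_sheet)
    ix, iy = table.sample_index(pop_x), table.sample_index(pop_y)
    windows = make_windows(table.contig_lengths, compartment_map, window_size)
    wid = _window_index(table.sites, windows)
    valid = ~_multiallelic(table)
    rx, ax, cx, _ = _pop_counts(table, ix)
    ry, ay, cy, _ = _pop_counts(table, iy)
    diffs, comps = site_pair_counts(rx, ax, ry, ay)
    use = valid & (wid >= 0)
    out = _aggregate(
        windows, wid[use], diffs[use].astype(float), comps[use].astype(float),
        genotyped=(comps[use] > 0),
    )
    if not table.explicit_invariant:
        _add_implicit(
            out, windows, table, wid, pop_x, sample_sheet, compartment_map,
            between=pop_y,
        )
    _finalize(out, min_sites, statistic="dxy")
    return out


def wc_site_components(
    n_ref_x, n_alt_x, het_x, n_ref_y, n_alt_y, het_y
):
    """Weir–Cockerham (1984) two-population variance components a, b, c per
    site.  Sample sizes are in individuals (allele count / 2, so hemizygous
    calls contribute half an individual and cannot be heterozygous)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = (n_ref_x + n_alt_x) / 2.0
        n2 = (n_ref_y + n_alt_y) / 2.0
        p1 = np.where(n1 > 0, n_alt_x / (2 * n1), np.nan)
        p2 = np.where(n2 > 0, n_alt_y / (2 * n2), np.nan)
        h1 = np.where(n1 > 0, het_x / n1, 0.0)
        h2 = np.where(n2 > 0, het_y / n2, 0.0)
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    ok = (n1 > 0) & (n2 > 0) & (nbar > 1) & np.isfinite(a)
    z = np.zeros_like(a)
    return np.where(ok, a, z), np.where(ok, b, z), np.where(ok, c, z), ok


def hudson_site_components(n_ref_x, n_alt_x, n_ref_y, n_alt_y):
    """Hudson (1992) estimator components (numerator, denominator) per site."""
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = n_ref_x + n_alt_x
        ny = n_ref_y + n_alt_y
        p1 = n_alt_x / nx
        p2 = n_alt_y / ny
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (nx - 1) - p2 * (1 - p2) / (ny - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (nx > 1) & (ny > 1) & np.isfinite(num)
    z = np.zeros_like(num, dtype=float)
    return np.where(ok, num, z), np.where(ok, den, z), ok


def windowed_fst(
    table: GenotypeTable,
    pop_x: list[str],
    pop_y: list[str],
    compartment_map: CompartmentMap,
    window_size: int = WINDOW_SIZE,
    min_sites: int = MIN_GENOTYPED_SITES,
    sample_sheet: pd.DataFrame | None = None,
    estimator: str = "wc",
) -> pd.DataFrame:
    """Windowed FST between two populations (ratio of summed components,
    not a mean of per-site ratios); negative window values are retained."""
    _implicit_needs(table, sample_sheet)
    ix, iy = table.sample_index(pop_x), table.sample_index(pop_y)
    windows = make_windows(table.contig_lengths, compartment_map, window_size)
    wid = _window_index(table.sites, windows)
    valid = ~_multiallelic(table) & table.is_variant()
    rx, ax, cx, hx = _pop_counts(table, ix)
    ry, ay, cy, hy = _pop_counts(table, iy)
    if estimator == "wc":
        a, b, c, ok = wc_site_components(rx, ax, hx, ry, ay, hy)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den, ok = hudson_site_components(rx, ax, ry, ay)
    else:
        raise GenotypeIOError(f"unknown FST estimator {estimator!r}")
    use = valid & ok & (wid >= 0)
    out = _aggregate(windows, wid[use], num[use], den[use], genotyped=np.ones(use.sum(), bool))
    # genotyped-site tally for qualification mirrors the pi/dxy counting
    _, compsx = site_pair_counts(rx, ax)
    _, compsy = site_pair_counts(ry, ay)
    geno = (~_multiallelic(table)) & (compsx > 0) & (compsy > 0) & (wid >= 0)
    tallies = np.bincount(wid[geno], minlength=len(out))
    out["n_sites"] = tallies[: len(out)]
    if not table.explicit_invariant:
        _add_implicit(
            out, windows, table, wid, pop_x, sample_sheet, compartment_map,
            between=pop_y, counts_only=True,
        )
    _finalize(out, min_sites, statistic=f"fst_{estimator}")
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaConstants:
    """Closed-form constants of Tajima (1989) for n sampled chromosomes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 4:
            raise GenotypeIOError("Tajima's D needs at least 4 chromosomes")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d_from_counts(S: int, pi_hat: float, n: int) -> float:
    """Tajima's D from a segregating-site count and the summed mean pairwise
    differences of a window."""
    if S == 0:
        return float("nan")
    k = TajimaConstants.for_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_hat - S / k.a1) / np.sqrt(var)


def windowed_tajimas_d(
    table: GenotypeTable,
    population: list[str],
    compartment_map: CompartmentMap,
    window_size: int = WINDOW_SIZE,
    min_snps: int = 1,
) -> pd.DataFrame:
    """Tajima's D per window.  Constants use the full sample size (total
    chromosome copies of the population in the window's compartment); sites
    with any missing call in the population are excluded from both the
    segregating-site count and the pairwise-difference sum."""
    idx = table.sample_index(population)
    windows = make_windows(table.contig_lengths, compartment_map, window_size)
    wid = _window_index(table.sites, windows)
    g = table.gt[:, idx, :]
    exists = g != ABSENT
    complete = ~((g == -1).any(axis=(1, 2)))  # no MISSING among existing slots
    n_per_site = exists.sum(axis=(1, 2))
    variant = table.is_biallelic_snp()
    n_alt = (g == 1).sum(axis=(1, 2))
    seg = variant & complete & (n_alt > 0) & (n_alt < n_per_site)

    rows = []
    for w, win in windows.iterrows():
        m = (wid == w) & seg
        S = int(m.sum())
        if S == 0:
            rows.append((S, np.nan, 0))
            continue
        n = int(n_per_site[m].max())
        if n < 4:  # too few chromosomes for the variance constants
            rows.append((S, np.nan, n))
            continue
        na = n_alt[m].astype(float)
        pi_hat = float(np.sum(na * (n - na)) / (n * (n - 1) / 2.0))
        rows.append((S, tajimas_d_from_counts(S, pi_hat, n), n))
    out = windows.copy()
    out[["n_snps", "value", "n_chromosomes"]] = pd.DataFrame(rows, index=windows.index)
    out["qualifies"] = out["n_snps"] >= min_snps
    out["statistic"] = "tajimas_d"
    return out


# ---------------------------------------------------------------------------
# aggregation helpers + compartment summary
# ---------------------------------------------------------------------------

def _multiallelic(table: GenotypeTable) -> np.ndarray:
    return table.sites["alt"].astype(str).str.contains(",").to_numpy()


def _aggregate(windows, wid, num, den, genotyped):
    k = len(windows)
    out = windows.copy()
    out["diff_count"] = np.bincount(wid, weights=num, minlength=k)[:k]
    out["comparison_count"] = np.bincount(wid, weights=den, minlength=k)[:k]
    out["n_sites"] = np.bincount(wid[genotyped], minlength=k)[:k]
    return out


def _add_implicit(
    out, windows, table, wid, pop, sample_sheet, compartment_map,
    between=None, counts_only=False,
):
    """Account for implicitly genotyped invariant sites of a variant-only
    table: they contribute comparisons (and the genotyped-site tally) but no
    differences."""
    listed = np.bincount(wid[wid >= 0], minlength=len(windows))[: len(windows)]
    span = (windows["end"] - windows["start"]).to_numpy()
    n_implicit = np.maximum(span - listed, 0)
    for w in range(len(windows)):
        comp = windows.iloc[w]["compartment"]
        nx = _full_hap_count(pop, sample_sheet, comp)
        if between is None:
            comps = nx * (nx - 1) / 2.0
        else:
            ny = _full_hap_count(between, sample_sheet, comp)
            comps = float(nx * ny)
        if comps <= 0:
            continue
        if not counts_only:
            out.loc[out.index[w], "comparison_count"] += n_implicit[w] * comps
        out.loc[out.index[w], "n_sites"] += n_implicit[w]


def _finalize(out, min_sites, statistic):
    with np.errstate(invalid="ignore", divide="ignore"):
        out["value"] = np.where(
            out["comparison_count"] > 0,
            out["diff_count"] / out["comparison_count"],
            np.nan,
        )
    out["qualifies"] = (out["n_sites"] >= min_sites) | (out["compartment"] == "mt")
    out["statistic"] = statistic


def compartment_summary(
    stats: pd.DataFrame,
    autosome_contigs: list[str] | None = None,
) -> pd.DataFrame:
    """Mean ± SE of a windowed statistic per compartment (qualifying windows
    only) plus each compartment's ratio to the autosomal mean.

    ``autosome_contigs`` restricts the autosomal windows entering the ratio
    denominator (the large-chromosome convention); the compartment means
    themselves always use all qualifying windows.
    """
    q = stats[stats["qualifies"] & np.isfinite(stats["value"])]
    rows = []
    auto = q[q["compartment"] == "autosome"]
    if autosome_contigs is not None:
        auto = auto[auto["contig"].isin(autosome_contigs)]
    auto_mean = float(auto["value"].mean()) if len(auto) else np.nan
    for comp in stats["compartment"].unique():
        sub = q[q["compartment"] == comp]
        k = len(sub)
        mean = float(sub["value"].mean()) if k else np.nan
        se = float(sub["value"].std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan
        ratio = mean / auto_mean if np.isfinite(auto_mean) and auto_mean != 0 else np.nan
        rows.append(
            {
                "compartment": comp, "n_windows": k, "mean": mean, "se": se,
                "ratio_to_autosome": ratio,
            }
        )
        if k == 0:
            import warnings

            warnings.warn(f"compartment {comp!r} has no qualifying windows")
    return pd.DataFrame(rows)
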