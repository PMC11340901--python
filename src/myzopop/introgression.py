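"""Frequency-based ABBA-BABA introgression statistics with block jackknife.

For a four-taxon topology (((P1,P2),P3),P4) the D statistic measures excess
sharing of derived alleles between P2 and P3 (ABBA patterns) over P1 and P3
(BABA patterns); under incomplete lineage sorting alone the two pattern
classes are equally frequent and D = 0.  Population allele frequencies are
used rather than single genomes, with derived alleles polarised against the
P4 outgroup (the P4-minor allele; P4-polymorphic sites are retained with
frequency weighting).  Significance comes from a leave-one-block-out
jackknife over contiguous equal-SNP blocks.

The f4 admixture ratio estimates the admixture proportion under unidirectional
P3→P2 gene flow by substituting one half of P3 for P2 in the denominator; the
windowed fdM statistic (dynamic-donor normalisation) is symmetric about zero
and negates under a P1↔P2 swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeIOError, GenotypeTable


@dataclass
class QuartetSpec:
    """Populations of a four-taxon test; P4 is the outgroup."""

    p1: list[str]
    p2: list[str]
    p3: list[str]
    p4: list[str]
    label: str = "quartet"

    def __post_init__(self) -> None:
        pops = [self.p1, self.p2, self.p3, self.p4]
        if not self.p4:
            raise GenotypeIOError("P4 (outgroup) must be non-empty")
        flat = [s for p in pops for s in p]
        if len(set(flat)) != len(flat):
            raise GenotypeIOError("quartet populations must be disjoint")

    def swapped(self) -> "QuartetSpec":
        return QuartetSpec(self.p2, self.p1, self.p3, self.p4, self.label + "_swapped")


@dataclass
class QuartetResult:
    label: str
    abba_sum: float
    baba_sum: float
    d: float
    se: float
    z: float
    p_value: float
    n_blocks: int
    n_snps: int
    f4_ratio: float = float("nan")
    f4_ratio_se: float = float("nan")
    f4_note: str = ""
    fdm_windows: pd.DataFrame | None = None
    fdm_mean_nonneg: float = float("nan")
    fdm_se_nonneg: float = float("nan")
    fdm_mean_all: float = float("nan")
    fdm_se_all: float = float("nan")


# ---------------------------------------------------------------------------
# site-level machinery
# ---------------------------------------------------------------------------

def derived_frequencies(table: GenotypeTable, quartet: QuartetSpec):
    """Derived-allele frequency per usable site in each quartet population.

    Returns ``(freqs, site_index)`` where ``freqs`` is (S_used, 4).  A site is
    usable when it is a biallelic SNP and every population has at least one
    called allele.  The derived allele is the one at minority frequency in P4
    (alt on ties); both P4-fixed and P4-polymorphic sites are retained.
    """
    freqs = []
    counts = []
    for pop in (quartet.p1, quartet.p2, quartet.p3, quartet.p4):
        idx = table.sample_index(pop)
        g = table.gt[:, idx, :]
        called = (g >= 0).sum(axis=(1, 2))
        alt = (g == 1).sum(axis=(1, 2))
        counts.append(called)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs.append(np.where(called > 0, alt / called, np.nan))
    freqs = np.stack(freqs, axis=1)  # alt-allele frequency
    usable = table.is_biallelic_snp()
    for c in counts:
        usable &= c > 0
    site_index = np.flatnonzero(usable)
    f = freqs[site_index]
    # polarise: derived = P4-minor allele
    flip = f[:, 3] > 0.5
    f[flip] = 1.0 - f[flip]
    return f, site_index


def site_patterns(freqs: np.ndarray):
    """ABBA and BABA contributions per site from derived frequencies."""
    p1, p2, p3, p4 = freqs.T
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba, baba


def _jackknife(values_num: np.ndarray, values_den: np.ndarray, n_blocks: int):
    """Leave-one-block-out jackknife of a ratio-of-sums statistic over
    contiguous equal-SNP blocks.  Returns (estimate, SE, n_blocks)."""
    S = len(values_num)
    if S < n_blocks:
        raise GenotypeIOError(
            f"{S} usable SNPs but {n_blocks} jackknife blocks requested; "
            "reduce n_blocks"
        )
    num, den = float(values_num.sum()), float(values_den.sum())
    est = num / den if den != 0 else float("nan")
    bounds = np.linspace(0, S, n_blocks + 1).astype(int)
    pseudo = []
    for b in range(n_blocks):
        s = slice(bounds[b], bounds[b + 1])
        dn = den - float(values_den[s].sum())
        if dn == 0:
            continue
        pseudo.append((num - float(values_num[s].sum())) / dn)
    pseudo = np.asarray(pseudo)
    B = len(pseudo)
    if B < 2:
        return est, float("nan"), B
    se = float(np.sqrt((B - 1) / B * np.sum((pseudo - pseudo.mean()) ** 2)))
    return est, se, B


# ---------------------------------------------------------------------------
# D statistic
# ---------------------------------------------------------------------------

def d_statistic(
    table: GenotypeTable, quartet: QuartetSpec, n_blocks: int = 20
) -> QuartetResult:
    """Genome-wide D with block-jackknife SE, Z and two-sided p."""
    f, _ = derived_frequencies(table, quartet)
    abba, baba = site_patterns(f)
    d, se, B = _jackknife(abba - baba, abba + baba, n_blocks)
    z = d / se if se and np.isfinite(se) and se > 0 else float("nan")
    p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return QuartetResult(
        label=quartet.label,
        abba_sum=float(abba.sum()),
        baba_sum=float(baba.sum()),
        d=d, se=se, z=z, p_value=float(p),
        n_blocks=B, n_snps=len(f),
    )


# ---------------------------------------------------------------------------
# f4 admixture ratio
# ---------------------------------------------------------------------------

def f4_admixture_ratio(
    table: GenotypeTable, quartet: QuartetSpec, n_blocks: int = 20
):
    """Admixture proportion assuming unidirectional P3 → P2 gene flow.

    P3 is split deterministically into even-index (P3a) and odd-index (P3b)
    halves; the ratio compares the observed ABBA−BABA excess with the value
    expected under complete admixture (P3a substituted for P2).
    Returns ``(ratio, jackknife SE, note)``; a non-positive denominator gives
    NaN with a note suggesting an alternative topology.
    """
    if len(quartet.p3) < 2:
        raise GenotypeIOError("f4 ratio needs at least 2 samples in P3")
    p3a = quartet.p3[0::2]
    p3b = quartet.p3[1::2]
    q_num = QuartetSpec(quartet.p1, quartet.p2, p3a, quartet.p4, "num")
    q_den = QuartetSpec(quartet.p1, p3b, p3a, quartet.p4, "den")
    f_num, idx_num = derived_frequencies(table, q_num)
    f_den, idx_den = derived_frequencies(table, q_den)
    # align on the intersection of usable sites so blocks match
    common, i_num, i_den = np.intersect1d(idx_num, idx_den, return_indices=True)
    an, bn = site_patterns(f_num[i_num])
    ad, bd = site_patterns(f_den[i_den])
    num_site = an - bn
    den_site = ad - bd
    if den_site.sum() <= 0:
        return float("nan"), float("nan"), "non-positive denominator: consider the alternative topology"
    ratio, se, _ = _jackknife(num_site, den_site, n_blocks)
    return ratio, se, ""


# ---------------------------------------------------------------------------
# windowed fdM
# ---------------------------------------------------------------------------

def fdm_site_values(freqs: np.ndarray):
    """Per-site fdM numerator (ABBA−BABA) and dynamic-donor denominator.

    When p2 ≥ p1 the donor frequency pD = max(p2, p3) replaces both p2 and
    p3; when p1 > p2 the mirrored form with pD = max(p1, p3) is used and
    negated, so a P1↔P2 swap negates fdM exactly.
    """
    p1, p2, p3, p4 = freqs.T
    abba, baba = site_patterns(freqs)
    num = abba - baba

    d23 = np.maximum(p2, p3)
    den23 = (1 - p1) * d23 * d23 * (1 - p4) - p1 * (1 - d23) * d23 * (1 - p4)
    d13 = np.maximum(p1, p3)
    den13 = -((1 - d13) * p2 * d13 * (1 - p4) - d13 * (1 - p2) * d13 * (1 - p4))
    den = np.where(p2 >= p1, den23, den13)
    return num, den


def fdm_windows(
    table: GenotypeTable, quartet: QuartetSpec, window_snps: int = 100
):
    """fdM in non-overlapping SNP windows plus the ≥0-filtered summary.

    Returns ``(per-window DataFrame, summary dict)``; the summary reports the
    mean over windows with fdM ≥ 0 (the reporting convention for admixture
    panels) and the unfiltered mean with its SE.
    """
    f, site_index = derived_frequencies(table, quartet)
    num, den = fdm_site_values(f)
    S = len(f)
    rows = []
    for w, start in enumerate(range(0, S, window_snps)):
        s = slice(start, min(start + window_snps, S))
        dsum = float(den[s].sum())
        if dsum == 0:
            continue
        rows.append(
            {
                "window": w,
                "n_snps": s.stop - s.start,
                "first_site": int(site_index[s.start]),
                "fdm": float(num[s].sum()) / dsum,
            }
        )
    df = pd.DataFrame(rows, columns=["window", "n_snps", "first_site", "fdm"])
    vals = df["fdm"].to_numpy()
    nn = vals[vals >= 0]
    summary = {
        "mean_nonneg": float(nn.mean()) if len(nn) else float("nan"),
        "se_nonneg": (
            float(nn.std(ddof=1) / np.sqrt(len(nn))) if len(nn) > 1 else float("nan")
        ),
        "mean_all": float(vals.mean()) if len(vals) else float("nan"),
        "se_all": (
            float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        ),
        "n_windows": len(vals),
    }
    return df, summary


# ---------------------------------------------------------------------------
# combined quartet analysis
# ---------------------------------------------------------------------------

def quartet_analysis(
    table: GenotypeTable,
    quartet: QuartetSpec,
    n_blocks: int = 20,
    fdm_window_snps: int = 100,
) -> QuartetResult:
    """D + jackknife, f4 ratio, and windowed fdM for one topology/region."""
    res = d_statistic(table, quartet, n_blocks)
    try:
        ratio, rse, note = f4_admixture_ratio(table, quartet, n_blocks)
        res.f4_ratio, res.f4_ratio_se, res.f4_note = ratio, rse, note
    except GenotypeIOError:
        res.f4_note = "too few SNPs or P3 samples for the f4 ratio"
    df, summary = fdm_windows(table, quartet, fdm_window_snps)
    res.fdm_windows = df
    res.fdm_mean_nonneg = summary["mean_nonneg"]
    res.fdm_se_nonneg = summary["se_nonneg"]
    res.fdm_mean_all = summary["mean_all"]
    res.fdm_se_all = summary["se_all"]
    return res


def results_table(results: list[QuartetResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label, "n_snps": r.n_snps, "ABBA": r.abba_sum,
                "BABA": r.baba_sum, "D": r.d, "SE": r.se, "Z": r.z,
                "p": r.p_value, "f4_ratio": r.f4_ratio, "f4_SE": r.f4_ratio_se,
                "mean_fdM_nonneg": r.fdm_mean_nonneg, "mean_fdM_all": r.fdm_mean_all,
                "n_fdM_windows": 0 if r.fdm_windows is None else len(r.fdm_windows),
                "note": r.f4_note,
            }
        )
    return pd.DataFrame(rows)
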