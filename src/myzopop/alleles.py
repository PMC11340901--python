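"""Private / fixed / shared allele classification and the maternal-marker
asymmetry test.

These reproduce the custom per-site allele bookkeeping used to compare
populations and sampling locations: an allele is *private* to a focal group
when no genotyped individual outside the group carries it and at least five
focal individuals do; a site is a *fixed difference* when the two groups are
fixed for alternate alleles (with at least five genotyped individuals per
group), and a *shared polymorphism* when both groups segregate.  The
asymmetry of heterospecific maternal-marker carriage between species is
tested with a two-sided Fisher's exact test on the 2×2 phenotype ×
marker-origin table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeIOError, GenotypeTable


@dataclass
class AlleleClassCounts:
    region: str
    n_private: int = 0
    n_fixed: int = 0
    n_shared_polymorphic: int = 0
    thresholds: dict = field(default_factory=dict)
    locality_breakdown: pd.DataFrame | None = None


def _counts(table: GenotypeTable, samples: list[str]):
    idx = table.sample_index(samples)
    g = table.gt[:, idx, :]
    called = g >= 0
    n_alt = (g == 1).sum(axis=(1, 2))
    n_called = called.sum(axis=(1, 2))
    carriers_alt = ((g == 1).any(axis=2)).sum(axis=1)
    carriers_ref = ((g == 0).any(axis=2)).sum(axis=1)
    return n_alt, n_called, carriers_ref, carriers_alt, idx


def private_alleles(
    table: GenotypeTable,
    focal_samples: list[str],
    other_samples: list[str],
    min_carriers: int = 5,
    sample_localities: dict | None = None,
    region: str = "all",
) -> AlleleClassCounts:
    """Count alleles carried by ≥ ``min_carriers`` focal individuals and
    absent from every genotyped non-focal sample (monomorphic and biallelic
    sites both count; each qualifying allele counts once)."""
    fa, fc, f_ref_car, f_alt_car, fidx = _counts(table, focal_samples)
    oa, oc, o_ref_car, o_alt_car, _ = _counts(table, other_samples)
    snp_or_mono = ~table.sites["alt"].astype(str).str.contains(",").to_numpy()

    alt_private = snp_or_mono & (f_alt_car >= min_carriers) & (oa == 0)
    # ref allele private to focal: others carry only alt
    ref_private = (
        snp_or_mono & (f_ref_car >= min_carriers) & (o_ref_car == 0) & (oc > 0)
    )
    n_private = int(alt_private.sum() + ref_private.sum())

    breakdown = None
    if sample_localities is not None:
        g = table.gt[:, fidx, :]
        rows = []
        for mask, allele in ((alt_private, 1), (ref_private, 0)):
            carry = (g[mask] == allele).any(axis=2)  # (S_priv, n_focal)
            locs = np.array([sample_localities[s] for s in focal_samples])
            for site_row in carry:
                present = sorted(set(locs[site_row]))
                rows.append("+".join(present))
        breakdown = pd.Series(rows, dtype=str).value_counts().rename_axis(
            "localities"
        ).reset_index(name="n_alleles")
    return AlleleClassCounts(
        region=region,
        n_private=n_private,
        thresholds={"min_carriers": min_carriers},
        locality_breakdown=breakdown,
    )


def fixed_and_shared(
    table: GenotypeTable,
    group_a: list[str],
    group_b: list[str],
    min_per_group: int = 5,
    region: str = "all",
) -> AlleleClassCounts:
    """Fixed differences and shared polymorphisms between two groups among
    sites with ≥ ``min_per_group`` genotyped individuals in each group
    (symmetric in group order)."""
    aa, ac, _, _, ia = _counts(table, group_a)
    ba, bc, _, _, ib = _counts(table, group_b)
    ga = table.gt[:, ia, :]
    gb = table.gt[:, ib, :]
    inds_a = ((ga >= 0).any(axis=2)).sum(axis=1)
    inds_b = ((gb >= 0).any(axis=2)).sum(axis=1)
    ok = (
        table.is_biallelic_snp()
        & (inds_a >= min_per_group)
        & (inds_b >= min_per_group)
    )
    fixed = ok & (((aa == 0) & (ba == bc)) | ((aa == ac) & (ba == 0)))
    shared = ok & (aa > 0) & (aa < ac) & (ba > 0) & (ba < bc)
    return AlleleClassCounts(
        region=region,
        n_fixed=int(fixed.sum()),
        n_shared_polymorphic=int(shared.sum()),
        thresholds={"min_per_group": min_per_group},
    )


# ---------------------------------------------------------------------------
# maternal-marker asymmetry
# ---------------------------------------------------------------------------

def build_maternal_contingency(
    assignments: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    females_only: bool = False,
    sympatric_only: bool = True,
) -> np.ndarray:
    """2×2 table: rows = phenotypic species (card, tris), columns =
    (conspecific, heterospecific) maternal-marker carriage."""
    df = assignments.merge(sample_sheet, on="sample_id")
    df = df[df["species"].isin(["card", "tris"])]
    if sympatric_only:
        df = df[df["locality"] == "sympatric"]
    if females_only:
        df = df[df["sex"] == "F"]
    df = df[df["maternal_assignment"].isin(["card", "tris"])]
    table = np.zeros((2, 2), dtype=int)
    for i, sp in enumerate(("card", "tris")):
        sub = df[df["species"] == sp]
        table[i, 0] = int((sub["maternal_assignment"] == sp).sum())
        table[i, 1] = int((sub["maternal_assignment"] != sp).sum())
    return table


def maternal_marker_asymmetry_test(counts: np.ndarray):
    """Two-sided Fisher's exact test on a 2×2 contingency table.

    Returns ``(odds_ratio, p)``; the p-value is the sum of hypergeometric
    probabilities of all tables (with the observed margins) at most as
    likely as the observed one.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 2):
        raise GenotypeIOError("contingency table must be 2x2")
    if (counts < 0).any():
        raise GenotypeIOError("contingency table cells must be non-negative")
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    return float(odds), float(p)
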