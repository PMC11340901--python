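"""Diagnostic panels, hybrid index / interspecific heterozygosity, triangle
classification, panel-based ancestry proportions, and genotype PCA.

A diagnostic panel is the set of biallelic SNPs fixed for alternate alleles
between the two species sampled in allopatry (per-site FST = 1).  On such
loci the allele-counting hybrid index equals the likelihood-based estimator,
and hybrid classes separate geometrically in the (hybrid index,
interspecific heterozygosity) triangle: F1s sit at maximal heterozygosity
with index ~0.5, first-generation backcrosses at (0.25 or 0.75, ~0.5), and
advanced backcrosses slide down the legs toward the parental corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (
    ABSENT,
    CompartmentMap,
    GenotypeIOError,
    GenotypeTable,
)


@dataclass
class DiagnosticPanel:
    """Fixed-difference loci with the species orientation of each allele."""

    loci: pd.DataFrame  # site_index, contig, pos, card_allele, tris_allele, compartment

    def __len__(self) -> int:
        return len(self.loci)

    def subset(self, compartments) -> "DiagnosticPanel":
        m = self.loci["compartment"].isin(list(compartments))
        return DiagnosticPanel(self.loci[m].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.loci.to_csv(path, sep="\t", index=False)


@dataclass
class HybridRecord:
    sample_id: str
    h: float  # hybrid index: fraction of tris-diagnostic alleles
    h_int: float  # interspecific heterozygosity
    n_loci: int
    reliable: bool = True
    triangle_class: str = ""


@dataclass(frozen=True)
class TriangleThresholds:
    """Decision boxes in (h, H_int) space; always reported with output."""

    f1_het_min: float = 0.85
    f1_h: tuple = (0.4, 0.6)
    parental_het_max: float = 0.05
    parental_h: float = 0.05
    backcross_het: tuple = (0.05, 0.85)


def fixed_difference_panel(
    table: GenotypeTable,
    allopatric_card: list[str],
    allopatric_tris: list[str],
    min_per_side: int = 5,
    compartment_map: CompartmentMap | None = None,
) -> DiagnosticPanel:
    """Biallelic SNPs where all genotyped allopatric card alleles are one
    allele and all genotyped allopatric tris alleles are the other, with at
    least ``min_per_side`` genotyped individuals on each side."""
    ic = table.sample_index(allopatric_card)
    it = table.sample_index(allopatric_tris)
    gc = table.gt[:, ic, :]
    gt_ = table.gt[:, it, :]
    biall = table.is_biallelic_snp()

    def side(g):
        called = g >= 0
        n_ind = (called.any(axis=2)).sum(axis=1)
        n_alt = (g == 1).sum(axis=(1, 2))
        n_called = called.sum(axis=(1, 2))
        return n_ind, n_alt, n_called

    nc_ind, nc_alt, nc_all = side(gc)
    nt_ind, nt_alt, nt_all = side(gt_)
    fixed_opposite = ((nc_alt == 0) & (nt_alt == nt_all)) | (
        (nc_alt == nc_all) & (nt_alt == 0)
    )
    keep = biall & fixed_opposite & (nc_ind >= min_per_side) & (nt_ind >= min_per_side)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        raise GenotypeIOError(
            "empty diagnostic panel: increase divergence, sample size, or "
            "lower min_per_side"
        )
    card_allele = np.where(nc_alt[idx] == 0, 0, 1)
    loci = pd.DataFrame(
        {
            "site_index": idx,
            "contig": table.sites["contig"].to_numpy()[idx],
            "pos": table.sites["pos"].to_numpy()[idx],
            "card_allele": card_allele,
            "tris_allele": 1 - card_allele,
        }
    )
    if compartment_map is not None:
        loci["compartment"] = compartment_map.label_sites(loci[["contig", "pos"]])
    else:
        loci["compartment"] = ""
    return DiagnosticPanel(loci)


def hybrid_index_and_het(
    table: GenotypeTable,
    panel: DiagnosticPanel,
    sample: str,
    min_loci: int = 10,
) -> HybridRecord:
    """Hybrid index (fraction of tris-diagnostic alleles) and interspecific
    heterozygosity over the genotyped panel loci of one diploid sample."""
    j = table.samples.index(sample)
    idx = panel.loci["site_index"].to_numpy()
    g = table.gt[idx, j, :]
    called = (g >= 0).all(axis=1)  # diploid complete calls
    g = g[called]
    tris = panel.loci["tris_allele"].to_numpy()[called]
    n = len(g)
    if n == 0:
        return HybridRecord(sample, float("nan"), float("nan"), 0, reliable=False)
    n_tris = (g == tris[:, None]).sum()
    het = (g[:, 0] != g[:, 1]).sum()
    return HybridRecord(
        sample_id=sample,
        h=float(n_tris) / (2 * n),
        h_int=float(het) / n,
        n_loci=n,
        reliable=n >= min_loci,
    )


def classify_triangle(
    record: HybridRecord, thresholds: TriangleThresholds = TriangleThresholds()
) -> str:
    """Assign a record to a triangle-plot class from its (h, H_int) box."""
    h, het = record.h, record.h_int
    t = thresholds
    if not np.isfinite(h) or not np.isfinite(het):
        return "advanced/ambiguous"
    if het >= t.f1_het_min and t.f1_h[0] <= h <= t.f1_h[1]:
        cls = "F1"
    elif het <= t.parental_het_max and h <= t.parental_h:
        cls = "parental_card"
    elif het <= t.parental_het_max and h >= 1 - t.parental_h:
        cls = "parental_tris"
    elif h < t.f1_h[0] and t.backcross_het[0] < het < t.backcross_het[1]:
        cls = "backcross_card"
    elif h > t.f1_h[1] and t.backcross_het[0] < het < t.backcross_het[1]:
        cls = "backcross_tris"
    else:
        cls = "advanced/ambiguous"
    record.triangle_class = cls
    return cls


def triangle_records(
    table: GenotypeTable,
    panel: DiagnosticPanel,
    samples: list[str],
    thresholds: TriangleThresholds = TriangleThresholds(),
    min_loci: int = 10,
) -> pd.DataFrame:
    rows = []
    for s in samples:
        rec = hybrid_index_and_het(table, panel, s, min_loci)
        classify_triangle(rec, thresholds)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def ancestry_proportion(
    table: GenotypeTable,
    panel: DiagnosticPanel,
    sample: str,
    haploid_agreement: float = 0.9,
):
    """Fraction of card-diagnostic alleles carried by one sample per
    compartment of the panel.

    Diploid compartments give a dosage (1 − hybrid index); haploid
    compartments (female Z, W, mtDNA) give a haplotype assignment: "card" or
    "tris" when at least ``haploid_agreement`` of diagnostic alleles agree,
    otherwise a "recombinant" flag.
    """
    j = table.samples.index(sample)
    out = {}
    for comp, sub in panel.loci.groupby("compartment"):
        idx = sub["site_index"].to_numpy()
        g = table.gt[idx, j, :]
        card = sub["card_allele"].to_numpy()
        called = g >= 0
        n_alleles = called.sum()
        if n_alleles == 0:
            out[comp] = {"card_fraction": float("nan"), "n_loci": 0, "assignment": "no_data"}
            continue
        n_card = int((np.where(called, g, -9) == card[:, None]).sum())
        frac = n_card / n_alleles
        haploid = (g[:, 1] == ABSENT).all()
        entry = {"card_fraction": float(frac), "n_loci": int(called.any(axis=1).sum())}
        if haploid:
            if frac >= haploid_agreement:
                entry["assignment"] = "card"
            elif frac <= 1 - haploid_agreement:
                entry["assignment"] = "tris"
            else:
                entry["assignment"] = "recombinant"
        else:
            entry["assignment"] = "diploid"
        out[comp] = entry
    return out


def maternal_assignments(
    table: GenotypeTable,
    panel: DiagnosticPanel,
    samples: list[str],
    compartments=("W", "neoW", "mt"),
    haploid_agreement: float = 0.9,
) -> pd.DataFrame:
    """Species assignment of each sample's maternally inherited haplotypes
    (W/neo-W for females, mtDNA for everyone) from diagnostic-allele majority."""
    sub = panel.subset(compartments)
    rows = []
    for s in samples:
        props = ancestry_proportion(table, sub, s, haploid_agreement)
        votes = [
            p["assignment"] for p in props.values() if p["assignment"] in ("card", "tris")
        ]
        if not votes:
            call = "no_data"
        elif all(v == votes[0] for v in votes):
            call = votes[0]
        else:
            call = "conflict"
        rows.append({"sample_id": s, "maternal_assignment": call})
    return pd.DataFrame(rows)


def genotype_pca(
    table: GenotypeTable,
    samples: list[str],
    n_components: int = 10,
    orient_negative: list[str] | None = None,
):
    """PCA of allele dosages: mean-imputed, centred, scaled by sqrt(p(1−p)).

    Returns ``(coordinates DataFrame, explained-variance fractions)``.
    ``orient_negative`` fixes the sign convention by forcing that group's
    centroid negative on each component (by default PC1-orienting is left to
    the caller).  Raises on zero-variance input.
    """
    idx = table.sample_index(samples)
    keep = table.is_biallelic_snp()
    g = table.gt[np.flatnonzero(keep)][:, idx, :]
    called = g >= 0
    ncall = called.sum(axis=2).astype(float)  # ploidy actually called
    dose = np.where(called, g, 0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(ncall > 0, dose / ncall, np.nan)  # 0..1 dosage
    p = np.nanmean(x, axis=1)
    var_ok = np.nan_to_num(np.nanvar(x, axis=1)) > 0
    if not var_ok.any():
        raise GenotypeIOError("zero-variance genotype matrix: PCA undefined")
    x = x[var_ok]
    p = p[var_ok]
    x = np.where(np.isnan(x), p[:, None], x)
    scale = np.sqrt(p * (1 - p))
    xs = (x - p[:, None]) / scale[:, None]
    u, s, vt = np.linalg.svd(xs.T, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    explained = (s**2) / float((s**2).sum())
    if orient_negative:
        ref = [samples.index(r) for r in orient_negative if r in samples]
        for c in range(k):
            if coords[ref, c].mean() > 0:
                coords[:, c] = -coords[:, c]
    df = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(k)], index=samples
    ).rename_axis("sample_id").reset_index()
    return df, explained[:k]
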