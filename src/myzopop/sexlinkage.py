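"""Compartment assignment of contigs from sex-stratified read depth.

In a ZW system, males (ZZ) show autosome-like depth on Z-linked sequence
while females (ZW) show half of it, and W-linked sequence is covered almost
exclusively in females at half depth.  Normalising each individual's
per-contig depth by its own autosomal mean makes the rule independent of
library size; contigs are then classified from the (male mean, female mean)
pair of normalised coverages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeIOError


@dataclass
class CoverageProfile:
    """Mean raw depth per (sample, contig) plus sample sexes and the contigs
    used as the autosomal normaliser."""

    depths: pd.DataFrame  # columns: sample, contig, mean_depth
    sex: dict  # sample -> "M" | "F"
    autosome_contigs: list

    @classmethod
    def from_tsv(cls, path, sample_sheet: pd.DataFrame, autosome_contigs) -> "CoverageProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            depths=df,
            sex=dict(zip(sample_sheet["sample_id"], sample_sheet["sex"])),
            autosome_contigs=list(autosome_contigs),
        )

    def validate(self) -> None:
        if (self.depths["mean_depth"] < 0).any():
            raise GenotypeIOError("negative depth")
        missing = set(self.depths["sample"]) - set(self.sex)
        if missing:
            raise GenotypeIOError(f"samples without sex label: {sorted(missing)}")


@dataclass(frozen=True)
class ClassifyThresholds:
    """Boxes in normalised-coverage space for the contig classification."""

    autosomal: tuple = (0.8, 1.2)  # both sexes
    z_female: tuple = (0.35, 0.65)  # with male in the autosomal box
    w_male_max: float = 0.1
    w_female: tuple = (0.35, 0.65)


def compute_normalized_coverage(profile: CoverageProfile) -> pd.DataFrame:
    """Per-contig mean normalised coverage per sex.

    Each sample's depths are divided by that sample's mean over the autosomal
    contigs before averaging within sexes, so the output is invariant to
    per-sample sequencing effort.
    """
    profile.validate()
    df = profile.depths.copy()
    df["sex"] = df["sample"].map(profile.sex)
    if df["sex"].isna().any():
        raise GenotypeIOError("missing sex labels")
    if not {"M", "F"} <= set(df["sex"]):
        raise GenotypeIOError("need at least one sample of each sex")
    auto = df[df["contig"].isin(profile.autosome_contigs)]
    norm = auto.groupby("sample")["mean_depth"].mean()
    if (norm <= 0).any():
        raise GenotypeIOError("sample with non-positive autosomal mean depth")
    df["normalized"] = df["mean_depth"] / df["sample"].map(norm)
    out = (
        df.pivot_table(index="contig", columns="sex", values="normalized", aggfunc="mean")
        .rename(columns={"M": "mean_M", "F": "mean_F"})
        .reset_index()
    )
    for col in ("mean_M", "mean_F"):
        if col not in out:
            out[col] = np.nan
    return out[["contig", "mean_M", "mean_F"]]


def classify_contigs(
    normalized: pd.DataFrame,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> pd.DataFrame:
    """Label each contig autosomal / Z-linked / W-linked / ambiguous from its
    sex-mean normalised coverage, reporting the evidence with every call."""
    t = thresholds
    rows = []
    for _, r in normalized.iterrows():
        m, f = r["mean_M"], r["mean_F"]
        in_auto = lambda v: t.autosomal[0] <= v <= t.autosomal[1]
        if in_auto(m) and in_auto(f):
            label = "autosomal"
        elif in_auto(m) and t.z_female[0] <= f <= t.z_female[1]:
            label = "Z-linked"
        elif m < t.w_male_max and t.w_female[0] <= f <= t.w_female[1]:
            label = "W-linked"
        else:
            label = "ambiguous"
        rows.append(
            {"contig": r["contig"], "mean_M": m, "mean_F": f, "label": label}
        )
    return pd.DataFrame(rows)
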