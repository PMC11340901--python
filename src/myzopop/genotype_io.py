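"""Genotype containers, VCF/BED/TSV input-output, and the site-filtering cascade.

The central container is :class:`GenotypeTable`, a sites-by-samples matrix of
allele indices that keeps invariant sites, per-site quality annotations
(QD, SOR, FS, MQ, MQRankSum, ReadPosRankSum), per-sample read depth, and a
running log of applied filters.  Ploidy is encoded per call slot so that one
table can mix diploid autosomal calls, hemizygous (haploid) female Z/W calls,
and haploid mitochondrial calls.

Call encoding (``gt`` array, shape ``(n_sites, n_samples, 2)``, int8):

* ``0``/``1`` ... — allele index into ``ref`` + ``alt``
* ``MISSING`` (−1) — a call slot that exists but was not genotyped
* ``ABSENT`` (−2) — the slot does not exist (second slot of a haploid call,
  or both slots for a sample that does not carry the compartment, e.g. a
  male at a W-linked site)

The filtering cascade mirrors a GATK-style short-read workflow: hard site
filters on annotations and a repeat mask, depth-band filters per genomic
compartment, masking of spurious female heterozygous calls on sex-linked
sequence, and a MAF + LD-pruning step for individual-level analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
ABSENT = -2

#: canonical compartment labels
COMPARTMENTS = ("autosome", "neoPAR", "Z", "neoZ", "W", "neoW", "mt")

#: inheritance mode of each compartment
INHERITANCE = {
    "autosome": "biparental",
    "neoPAR": "biparental",
    "Z": "Z-like",
    "neoZ": "Z-like",
    "W": "W-like",
    "neoW": "W-like",
    "mt": "mitochondrial",
}

#: compartments treated as autosome-like for depth filtering
_AUTOSOMAL_LIKE = ("autosome", "neoPAR")
_SEX_LINKED = ("Z", "neoZ", "W", "neoW")

ANNOTATION_KEYS = ("QD", "SOR", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

SAMPLE_SHEET_COLUMNS = ("sample_id", "species", "locality", "sex", "phenotype")


class GenotypeIOError(ValueError):
    """Malformed input (VCF record, sample sheet, BED interval...)."""


# ---------------------------------------------------------------------------
# compartment map
# ---------------------------------------------------------------------------

@dataclass
class CompartmentMap:
    """BED-like map from genomic intervals (0-based half-open) to compartments.

    Intervals must not overlap; every site of a loaded table must fall inside
    exactly one interval.
    """

    intervals: pd.DataFrame  # columns: contig, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals
        need = {"contig", "start", "end", "label"}
        if not need.issubset(df.columns):
            raise GenotypeIOError(f"compartment map needs columns {sorted(need)}")
        bad = set(df["label"]) - set(COMPARTMENTS)
        if bad:
            raise GenotypeIOError(f"unknown compartment label(s): {sorted(bad)}")
        for contig, sub in df.groupby("contig"):
            sub = sub.sort_values("start")
            if (sub["end"].values[:-1] > sub["start"].values[1:]).any():
                raise GenotypeIOError(f"overlapping intervals on {contig}")

    @classmethod
    def from_bed(cls, path) -> "CompartmentMap":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["contig", "start", "end", "label"],
            dtype={"contig": str, "start": np.int64, "end": np.int64, "label": str},
        )
        return cls(df)

    def to_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)

    def contig_lengths(self) -> dict[str, int]:
        return dict(self.intervals.groupby("contig")["end"].max())

    def label_sites(self, sites: pd.DataFrame) -> np.ndarray:
        """Compartment label for each site (``pos`` is 1-based)."""
        out = np.full(len(sites), "", dtype=object)
        pos0 = sites["pos"].to_numpy() - 1
        contigs = sites["contig"].to_numpy()
        for _, iv in self.intervals.iterrows():
            m = (contigs == iv["contig"]) & (pos0 >= iv["start"]) & (pos0 < iv["end"])
            out[m] = iv["label"]
        if (out == "").any():
            i = int(np.argmax(out == ""))
            raise GenotypeIOError(
                f"site {contigs[i]}:{pos0[i] + 1} maps to no compartment interval"
            )
        return out.astype(str)

    def inheritance(self, label: str) -> str:
        return INHERITANCE[label]


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Sites × samples genotype matrix with annotations, depth and provenance.

    ``sites`` columns: contig, pos (1-based), ref, alt ("." for invariant).
    When ``explicit_invariant`` is False the table holds variant sites only and
    every position of ``contig_lengths`` that is not listed is an implicitly
    fully genotyped invariant site (the way large clean simulations are kept
    in memory); windowed statistics account for them through the compartment
    map.
    """

    sites: pd.DataFrame
    gt: np.ndarray  # (S, N, 2) int8
    samples: list[str]
    contig_lengths: dict[str, int]
    annotations: pd.DataFrame | None = None
    depth: np.ndarray | None = None  # (S, N) int32
    minor_read_frac: np.ndarray | None = None  # (S, N) float32, mt heteroplasmy
    explicit_invariant: bool = True
    filter_log: list[dict] = field(default_factory=list)

    # -- basic api ----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:
            raise GenotypeIOError(f"unknown sample {e.args[0]!r}") from None

    def validate(self) -> None:
        if self.gt.shape != (self.n_sites, self.n_samples, 2):
            raise GenotypeIOError("gt shape inconsistent with sites/samples")
        for contig, sub in self.sites.groupby("contig", sort=False):
            p = sub["pos"].to_numpy()
            if (np.diff(p) <= 0).any():
                raise GenotypeIOError(f"positions not strictly increasing on {contig}")
        n_alt = self.sites["alt"].map(lambda a: 0 if a in (".", "") else len(a.split(",")))
        max_allele = self.gt.max(axis=(1, 2))
        if (max_allele > n_alt.to_numpy()).any():
            raise GenotypeIOError("call references undeclared allele")

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            sites=self.sites.copy(),
            gt=self.gt.copy(),
            samples=list(self.samples),
            contig_lengths=dict(self.contig_lengths),
            annotations=None if self.annotations is None else self.annotations.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            minor_read_frac=(
                None if self.minor_read_frac is None else self.minor_read_frac.copy()
            ),
            explicit_invariant=self.explicit_invariant,
            filter_log=list(self.filter_log),
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        t = GenotypeTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            gt=self.gt[index],
            samples=list(self.samples),
            contig_lengths=dict(self.contig_lengths),
            annotations=(
                None if self.annotations is None
                else self.annotations.iloc[index].reset_index(drop=True)
            ),
            depth=None if self.depth is None else self.depth[index],
            minor_read_frac=(
                None if self.minor_read_frac is None else self.minor_read_frac[index]
            ),
            explicit_invariant=self.explicit_invariant,
            filter_log=list(self.filter_log),
        )
        return t

    def is_variant(self) -> np.ndarray:
        return (self.sites["alt"].to_numpy() != ".") & (self.sites["alt"].to_numpy() != "")

    def is_biallelic_snp(self) -> np.ndarray:
        alt = self.sites["alt"].astype(str)
        return (alt.str.len() == 1).to_numpy() & (alt != ".").to_numpy()

    def called_sites_count(self) -> int:
        """Number of sites with at least one non-missing call (log metric)."""
        return int(((self.gt >= 0).any(axis=(1, 2))).sum())

    def _log(self, stage: str, sites_in: int) -> None:
        self.filter_log.append(
            {"stage": stage, "sites_in": sites_in, "sites_out": self.called_sites_count()}
        )

    @staticmethod
    def concat(tables: Sequence["GenotypeTable"]) -> "GenotypeTable":
        if not tables:
            raise GenotypeIOError("nothing to concatenate")
        samples = tables[0].samples
        for t in tables[1:]:
            if t.samples != samples:
                raise GenotypeIOError("inconsistent sample sets across fragments")
        ann = None
        if all(t.annotations is not None for t in tables):
            ann = pd.concat([t.annotations for t in tables], ignore_index=True)
        depth = None
        if all(t.depth is not None for t in tables):
            depth = np.concatenate([t.depth for t in tables])
        mrf = None
        if any(t.minor_read_frac is not None for t in tables):
            mrf = np.concatenate(
                [
                    t.minor_read_frac
                    if t.minor_read_frac is not None
                    else np.zeros((t.n_sites, t.n_samples), dtype=np.float32)
                    for t in tables
                ]
            )
        lengths: dict[str, int] = {}
        for t in tables:
            lengths.update(t.contig_lengths)
        return GenotypeTable(
            sites=pd.concat([t.sites for t in tables], ignore_index=True),
            gt=np.concatenate([t.gt for t in tables]),
            samples=list(samples),
            contig_lengths=lengths,
            annotations=ann,
            depth=depth,
            minor_read_frac=mrf,
            explicit_invariant=all(t.explicit_invariant for t in tables),
        )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise GenotypeIOError(f"sample sheet missing columns {sorted(missing)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def samples_for(
    sheet: pd.DataFrame,
    species: str | None = None,
    locality: str | None = None,
    sex: str | None = None,
    phenotype: str | None = None,
) -> list[str]:
    """Select sample ids from a sample sheet by attribute."""
    m = pd.Series(True, index=sheet.index)
    if species is not None:
        m &= sheet["species"] == species
    if locality is not None:
        m &= sheet["locality"] == locality
    if sex is not None:
        m &= sheet["sex"] == sex
    if phenotype is not None:
        m &= sheet["phenotype"] == phenotype
    return sheet.loc[m, "sample_id"].tolist()


def expected_ploidy(compartment: str, sex: str) -> int:
    """Copies of a compartment carried by an individual of the given sex."""
    if compartment in _AUTOSOMAL_LIKE:
        return 2
    if compartment in ("Z", "neoZ"):
        return 2 if sex == "M" else 1
    if compartment in ("W", "neoW"):
        return 0 if sex == "M" else 1
    if compartment == "mt":
        return 1
    raise GenotypeIOError(f"unknown compartment {compartment!r}")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_allsites_vcf(path, sample_sheet: pd.DataFrame, compartment_map: CompartmentMap) -> GenotypeTable:
    """Read an all-sites VCF (variant + invariant records) into a GenotypeTable.

    Invariant records (ALT=".") are retained.  Ploidy is taken from the calls
    as written; the female-hemizygote masking stage handles erroneously
    diploid sex-linked calls downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sheet_ids = set(sample_sheet["sample_id"])
    unknown = [s for s in vcf.samples if s not in sheet_ids]
    if unknown:
        raise GenotypeIOError(f"VCF sample(s) absent from sample sheet: {unknown}")
    samples = list(vcf.samples)
    n = len(samples)

    contigs, poss, refs, alts = [], [], [], []
    gts, depths, ann_rows, mrf_rows = [], [], [], []
    any_ad = False
    for i, v in enumerate(vcf):
        alt = ",".join(v.ALT) if v.ALT else "."
        contigs.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(alt)
        # genotype.array(): allele columns then a phase flag column;
        # -1 missing, -2 ploidy padding
        arr = v.genotype.array()[:, :-1]
        if arr.shape[1] == 1:
            arr = np.hstack([arr, np.full((n, 1), ABSENT, dtype=arr.dtype)])
        gts.append(arr[:, :2].astype(np.int8))
        dp = v.format("DP")
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int32)
            dp[dp < 0] = 0
            depths.append(dp.astype(np.int16))
        else:
            depths.append(np.zeros(n, dtype=np.int16))
        ann_rows.append([_info_float(v, k) for k in ANNOTATION_KEYS])
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            tot = ad.clip(min=0).sum(axis=1).astype(np.float64)
            mx = ad.clip(min=0).max(axis=1).astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(tot > 0, 1.0 - mx / tot, 0.0)
            mrf_rows.append(frac.astype(np.float32))
            any_ad = True
        else:
            mrf_rows.append(np.zeros(n, dtype=np.float32))

    sites = pd.DataFrame({"contig": contigs, "pos": poss, "ref": refs, "alt": alts})
    gt = np.array(gts, dtype=np.int8) if gts else np.zeros((0, n, 2), np.int8)
    # a written "." is ambiguous between a missing call and a compartment the
    # sample does not carry; reconcile with the expected ploidy
    if len(sites):
        labels = compartment_map.label_sites(sites)
        sex = dict(zip(sample_sheet["sample_id"], sample_sheet["sex"]))
        for label in np.unique(labels):
            rows = labels == label
            for j, s in enumerate(samples):
                if expected_ploidy(label, sex[s]) == 0:
                    block = gt[rows, j, :]
                    block[block == MISSING] = ABSENT
                    gt[rows, j, :] = block
    table = GenotypeTable(
        sites=sites,
        gt=gt,
        samples=samples,
        contig_lengths=compartment_map.contig_lengths(),
        annotations=pd.DataFrame(ann_rows, columns=list(ANNOTATION_KEYS)),
        depth=np.array(depths, dtype=np.int16) if depths else np.zeros((0, n), np.int16),
        minor_read_frac=np.array(mrf_rows, dtype=np.float32) if any_ad else None,
        explicit_invariant=True,
    )
    table.validate()
    return table


def _info_float(v, key: str) -> float:
    x = v.INFO.get(key)
    return float("nan") if x is None else float(x)


def write_allsites_vcf(table: GenotypeTable, path) -> None:
    """Write a GenotypeTable as a VCF 4.2 text file (GT:DP, plus AD on records
    carrying allele-fraction information)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=myzopop\n")
        for contig, length in table.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for key in ANNOTATION_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for lo in range(0, table.n_sites, 100_000):
            _write_vcf_chunk(table, fh, lo, min(lo + 100_000, table.n_sites))


def _write_vcf_chunk(table: GenotypeTable, fh, lo: int, hi: int) -> None:
    """Vectorised body writer for a slice of sites."""
    sites = table.sites.iloc[lo:hi]
    g = table.gt[lo:hi]
    S = hi - lo
    # allele characters indexed by code+2: ABSENT -> "", MISSING -> "."
    lut = np.array(["", "."] + [str(i) for i in range(10)], dtype="U1")
    a0 = lut[g[:, :, 0].astype(np.int16) + 2]
    a1 = lut[g[:, :, 1].astype(np.int16) + 2]
    haploid = g[:, :, 1] == ABSENT
    geno = np.where(
        g[:, :, 0] == ABSENT,
        ".",
        np.where(haploid, a0, np.char.add(np.char.add(a0, "/"), a1)),
    )
    if table.depth is not None:
        dp = table.depth[lo:hi].astype(np.int64)
    else:
        dp = np.zeros((S, table.n_samples), dtype=np.int64)
    int_lut = np.array([str(i) for i in range(int(dp.max()) + 2)])
    dps = int_lut[dp]
    field = np.char.add(np.char.add(geno, ":"), dps)
    variant = (sites["alt"] != ".").to_numpy()
    has_ad = np.zeros(S, dtype=bool)
    if table.minor_read_frac is not None:
        mrf = table.minor_read_frac[lo:hi]
        has_ad = variant & (mrf > 0).any(axis=1)
        if has_ad.any():
            minor = np.rint(dp * mrf).astype(np.int64)
            ad = np.char.add(np.char.add(int_lut[dp - minor], ","), int_lut[minor])
            with_ad = np.char.add(np.char.add(field, ":"), ad)
            field = np.where(has_ad[:, None], with_ad, field)
    if table.annotations is not None:
        parts = None
        for key in ANNOTATION_KEYS:
            vals = table.annotations[key].to_numpy()[lo:hi]
            piece = np.where(
                np.isfinite(vals),
                np.char.add(f"{key}=", np.char.mod("%.6g", vals)),
                "",
            )
            piece = np.where(piece == "", piece, np.char.add(piece, ";"))
            parts = piece if parts is None else np.char.add(parts, piece)
        info = np.char.rstrip(parts, ";")
        info = np.where(info == "", ".", info)
    else:
        info = np.full(S, ".", dtype="U1")
    field = field.astype(object)
    cols = {
        "#CHROM": sites["contig"].to_numpy(),
        "POS": sites["pos"].to_numpy(),
        "ID": ".",
        "REF": sites["ref"].to_numpy(),
        "ALT": sites["alt"].to_numpy(),
        "QUAL": ".",
        "FILTER": ".",
        "INFO": info.astype(object),
        "FORMAT": np.where(has_ad, "GT:DP:AD", "GT:DP").astype(object),
    }
    for j, s in enumerate(table.samples):
        cols[s] = field[:, j]
    pd.DataFrame(cols).to_csv(fh, sep="\t", header=False, index=False)


def write_filter_log(table: GenotypeTable, path) -> None:
    pd.DataFrame(table.filter_log).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HardFilterThresholds:
    """GATK-style hard-filter thresholds; a site failing any is masked.

    The defaults for the two rank-sum statistics follow standard GATK
    practice (−12.5 and −8.0).  :meth:`as_printed` exposes the alternative
    +12.5 / −80.0 convention for comparison.
    """

    qd_min: float = 2.0
    sor_max: float = 3.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0

    @classmethod
    def as_printed(cls) -> "HardFilterThresholds":
        return cls(mqranksum_min=12.5, readposranksum_min=-80.0)


def apply_hard_site_filters(
    table: GenotypeTable,
    thresholds: HardFilterThresholds = HardFilterThresholds(),
    repeat_mask: pd.DataFrame | None = None,
) -> GenotypeTable:
    """Mask (recode as missing) sites failing annotation thresholds or inside
    repeat intervals.  Missing (NaN) annotations pass.  Idempotent."""
    t = table.copy()
    sites_in = t.called_sites_count()
    fail = np.zeros(t.n_sites, dtype=bool)
    if t.annotations is not None and t.n_sites:
        a = t.annotations
        with np.errstate(invalid="ignore"):
            fail |= (a["QD"].to_numpy() < thresholds.qd_min)
            fail |= (a["SOR"].to_numpy() > thresholds.sor_max)
            fail |= (a["FS"].to_numpy() > thresholds.fs_max)
            fail |= (a["MQ"].to_numpy() < thresholds.mq_min)
            fail |= (a["MQRankSum"].to_numpy() < thresholds.mqranksum_min)
            fail |= (a["ReadPosRankSum"].to_numpy() < thresholds.readposranksum_min)
    if repeat_mask is not None and t.n_sites:
        pos0 = t.sites["pos"].to_numpy() - 1
        contigs = t.sites["contig"].to_numpy()
        for _, iv in repeat_mask.iterrows():
            fail |= (contigs == iv["contig"]) & (pos0 >= iv["start"]) & (pos0 < iv["end"])
    _mask_sites(t, fail)
    t._log("hard_site_filters", sites_in)
    return t


def apply_depth_filters(
    table: GenotypeTable,
    compartment_map: CompartmentMap,
    autosomal_range: tuple[float, float] = (10.0, 34.0),
    sex_linked_range: tuple[float, float] = (6.0, 24.0),
    mt_min: float = 10.0,
    heteroplasmy_threshold: float = 0.2,
) -> GenotypeTable:
    """Mask sites whose mean depth across carrying samples falls outside the
    compartment's band, and mitochondrial sites flagged heteroplasmic."""
    t = table.copy()
    sites_in = t.called_sites_count()
    if t.depth is None:
        t._log("depth_filters", sites_in)
        return t
    labels = compartment_map.label_sites(t.sites)
    carrier = t.gt[:, :, 0] != ABSENT  # samples that carry the compartment
    depth = t.depth.astype(np.float64)
    n_car = carrier.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dp = np.where(n_car > 0, (depth * carrier).sum(axis=1) / n_car, np.nan)
    fail = np.zeros(t.n_sites, dtype=bool)
    auto = np.isin(labels, _AUTOSOMAL_LIKE)
    sexl = np.isin(labels, _SEX_LINKED)
    mt = labels == "mt"
    with np.errstate(invalid="ignore"):
        fail |= auto & ((mean_dp < autosomal_range[0]) | (mean_dp > autosomal_range[1]))
        fail |= sexl & ((mean_dp < sex_linked_range[0]) | (mean_dp > sex_linked_range[1]))
        fail |= mt & (mean_dp < mt_min)
    fail |= np.isnan(mean_dp)  # no depth data: treated as missing
    if t.minor_read_frac is not None:
        het = (t.minor_read_frac > heteroplasmy_threshold).any(axis=1)
        fail |= mt & het
    _mask_sites(t, fail)
    t._log("depth_filters", sites_in)
    return t


def mask_female_sex_heterozygotes(
    table: GenotypeTable,
    compartment_map: CompartmentMap,
    sample_sheet: pd.DataFrame,
) -> GenotypeTable:
    """Recode heterozygous female calls on Z/neo-Z/W/neo-W as missing.

    The neo-PAR, which recombines in both sexes, is untouched, as are males
    (genuinely diploid on Z-linked sequence)."""
    t = table.copy()
    sites_in = t.called_sites_count()
    labels = compartment_map.label_sites(t.sites)
    sex = dict(zip(sample_sheet["sample_id"], sample_sheet["sex"]))
    female = np.array([sex.get(s) == "F" for s in t.samples])
    target = np.isin(labels, _SEX_LINKED)
    g = t.gt
    het = (g[:, :, 0] >= 0) & (g[:, :, 1] >= 0) & (g[:, :, 0] != g[:, :, 1])
    mask = target[:, None] & female[None, :] & het
    g[mask] = MISSING
    t._log("female_hemizygote_mask", sites_in)
    return t


def prepare_individual_dataset(
    table: GenotypeTable,
    maf_min: float = 0.05,
    ld_window: int = 50,
    ld_step: int = 5,
    r2_max: float = 0.5,
) -> GenotypeTable:
    """Variant-only dataset for individual-level analyses: drop invariant
    sites, apply a minor-allele-frequency floor, and LD-prune in sliding
    SNP windows (remove the later SNP of any pair with r² above the cutoff,
    then advance the window)."""
    if not (0 < r2_max <= 1):
        raise GenotypeIOError("r2_max must be in (0, 1]")
    keep = table.is_biallelic_snp()
    t = table.take_sites(np.flatnonzero(keep))
    sites_in = table.called_sites_count()

    g = t.gt
    called = (g >= 0)
    alt = (g == 1)
    n_called = called.sum(axis=(1, 2))
    n_alt = alt.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, n_alt / n_called, 0.0)
    maf = np.minimum(p, 1 - p)
    t = t.take_sites(np.flatnonzero((maf >= maf_min) & (n_called > 0)))

    keep_idx = _ld_prune(t, ld_window, ld_step, r2_max)
    t = t.take_sites(keep_idx)
    t.explicit_invariant = False
    t._log("maf_ld_prune", sites_in)
    return t


def _ld_prune(table: GenotypeTable, window: int, step: int, r2_max: float) -> np.ndarray:
    """plink-style windowed LD pruning on allele-count genotypes."""
    S = table.n_sites
    if S == 0:
        return np.zeros(0, dtype=np.intp)
    g = table.gt.astype(np.float64)
    called = g >= 0
    dose = np.where(called, g, 0).sum(axis=2)
    ncall = called.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dose = np.where(ncall > 0, dose / ncall * 2, np.nan)  # 0..2 scale
    removed = np.zeros(S, dtype=bool)
    # windows advance within each contig so pairs never straddle contigs
    contigs = table.sites["contig"].to_numpy()
    for contig in pd.unique(contigs):
        idx = np.flatnonzero(contigs == contig)
        start = 0
        while start < len(idx):
            win = idx[start:start + window]
            act = win[~removed[win]]
            if len(act) > 1:
                X = dose[act]  # (w, N)
                mu = np.nanmean(X, axis=1, keepdims=True)
                Xc = np.where(np.isnan(X), 0.0, X - mu)
                cov = Xc @ Xc.T
                var = np.diag(cov).copy()
                var[var == 0] = np.nan
                with np.errstate(invalid="ignore", divide="ignore"):
                    r2 = cov**2 / np.outer(var, var)
                for a in range(len(act)):
                    if removed[act[a]]:
                        continue
                    for b in range(a + 1, len(act)):
                        if removed[act[b]]:
                            continue
                        if np.isfinite(r2[a, b]) and r2[a, b] > r2_max:
                            removed[act[b]] = True  # drop the later SNP
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(~removed)


def _mask_sites(table: GenotypeTable, fail: np.ndarray) -> None:
    g = table.gt
    m = fail[:, None, None] & (g >= 0)
    g[m] = MISSING
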