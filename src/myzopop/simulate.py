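"""Synthetic genotype data for a two-species secondary-contact scenario.

The generator emulates the study design of a recent avian contact zone:
two honeyeater species (an invading *Myzomela cardinalis*-like species,
"card", and a resident *M. tristrami*-like species, "tris") that diverged
on the order of a million years ago and came back into contact roughly a
hundred years (a few tens of generations) before sampling, with an outgroup
("pulc") for polarising derived alleles.  Individuals are sampled in
allopatry and sympatry, in both sexes, across genomic compartments with
distinct inheritance: autosomes and a new pseudo-autosomal region
(biparental, recombining), Z-like sequence (diploid in males, hemizygous in
females), W-like sequence (female-limited, maternal), and mitochondrial DNA
(maternal in both sexes).  Post-contact migration is direction-specific and
female-biased for the maternally co-transmitted compartments, which is what
produces asymmetric W/mtDNA introgression.

The default coalescent engine is msprime under a five-deme demography
(outgroup; allopatric/sympatric deme per species, splitting at the contact
time).  A discrete-generation Wright-Fisher backward sampler is provided as
an alternative engine for the small, non-recombining maternal compartments.

Effective sizes default to values calibrated from the printed autosomal
diversities of the two species via pi = 4*Ne*mu; sequence lengths default
to desk scale while sample counts keep the study design (40 + 40 card,
20 + 30 tris, 12 hybrids, 1 outgroup).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import msprime
import numpy as np
import pandas as pd

from .genotype_io import (
    ABSENT,
    ANNOTATION_KEYS,
    COMPARTMENTS,
    INHERITANCE,
    MISSING,
    CompartmentMap,
    GenotypeTable,
    expected_ploidy,
    write_allsites_vcf,
    write_sample_sheet,
)

_BASES = np.array(list("ACGT"))
_DEMES = ("pulc", "card_allo", "card_sym", "tris_allo", "tris_sym")


class ConfigError(ValueError):
    """A scenario configuration field is unknown or violates an invariant."""


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def _default_sample_design() -> dict:
    return {
        ("card", "allopatric", "M"): 20,
        ("card", "allopatric", "F"): 20,
        ("card", "sympatric", "M"): 20,
        ("card", "sympatric", "F"): 20,
        ("tris", "allopatric", "M"): 10,
        ("tris", "allopatric", "F"): 10,
        ("tris", "sympatric", "M"): 15,
        ("tris", "sympatric", "F"): 15,
        ("pulc", "allopatric", "F"): 1,
    }


_GEN_TIME = {"card": 2.25, "tris": 2.51, "pulc": 2.37}
_MEAN_GEN = (_GEN_TIME["card"] + _GEN_TIME["tris"]) / 2.0


@dataclass
class ScenarioConfig:
    """Parameters of the simulated secondary-contact scenario.

    Times are in generations before present; effective sizes are diploid.
    ``maternal_bias`` is the fraction of effective migrants that are female
    and scales migration for the W-like and mitochondrial compartments.
    ``pulse_c2t``/``pulse_t2c`` add a one-pulse admixture event (fraction of
    the receiving sympatric deme replaced) midway through the contact period,
    in addition to the continuous per-generation rates ``m_c2t``/``m_t2c``.
    """

    T_div: float = 1.1e6 / _MEAN_GEN
    T_contact: float = 100.0 / _MEAN_GEN
    T_out: float = 2.5e6 / _MEAN_GEN
    Ne_card: float = 125_000.0
    Ne_tris: float = 150_000.0
    Ne_pulc: float = 150_000.0
    mu: float = 4.6e-9
    recomb_rate: float = 1e-8
    gen_time_years: dict = field(default_factory=lambda: dict(_GEN_TIME))
    m_c2t: float = 0.004
    m_t2c: float = 0.002
    pulse_c2t: float = 0.0
    pulse_t2c: float = 0.0
    maternal_bias: float = 0.9
    compartment_scalings: dict = field(
        default_factory=lambda: {
            "autosome": 1.0, "neoPAR": 1.0, "Z": 0.75, "neoZ": 0.75,
            "W": 0.25, "neoW": 0.25, "mt": 0.25,
        }
    )
    sample_design: dict = field(default_factory=_default_sample_design)
    hybrid_design: dict = field(
        default_factory=lambda: {"F1": 4, "BC_card": 4, "BC_tris": 4}
    )
    f1_mother: str = "card"
    bc_mother: str = "F1"  # "F1" or "recurrent"
    z_crossovers: int = 1  # crossovers per Z gamete in hybrid synthesis
    seq_lengths: dict = field(
        default_factory=lambda: {
            "autosome": 450_000, "neoPAR": 100_000, "Z": 120_000,
            "neoZ": 120_000, "W": 60_000, "neoW": 60_000, "mt": 16_000,
        }
    )
    n_autosome_contigs: int = 3
    link_maternal: bool = True  # W/neo-W/mt share one non-recombining genealogy
    depth_mean: float = 16.95
    mt_depth_factor: float = 10.0
    fail_fraction: float = 0.0
    heteroplasmy_fraction: float = 0.0
    seed: int = 2024

    def validate(self) -> None:
        if not (0 < self.T_contact < self.T_div < self.T_out):
            raise ConfigError("need 0 < T_contact < T_div < T_out")
        for name in ("m_c2t", "m_t2c", "pulse_c2t", "pulse_t2c", "maternal_bias",
                     "fail_fraction", "heteroplasmy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("Ne_card", "Ne_tris", "Ne_pulc", "mu", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for comp, length in self.seq_lengths.items():
            if comp not in COMPARTMENTS:
                raise ConfigError(f"unknown compartment {comp!r} in seq_lengths")
            if length <= 0:
                raise ConfigError(f"seq_lengths[{comp!r}] must be positive")
        for comp, s in self.compartment_scalings.items():
            if comp not in COMPARTMENTS:
                raise ConfigError(f"unknown compartment {comp!r} in scalings")
            if s <= 0:
                raise ConfigError("compartment scaling must be positive")
        for key, count in self.sample_design.items():
            if count <= 0:
                raise ConfigError(f"sample_design count for {key} must be positive")
        if self.n_autosome_contigs < 1:
            raise ConfigError("n_autosome_contigs must be >= 1")

    def scaled_ne(self, species: str, compartment: str) -> float:
        ne = {"card": self.Ne_card, "tris": self.Ne_tris, "pulc": self.Ne_pulc}[species]
        return ne * self.compartment_scalings[compartment]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sample_design"] = [
            {"species": k[0], "locality": k[1], "sex": k[2], "count": v}
            for k, v in self.sample_design.items()
        ]
        return json.dumps(d, indent=1, sort_keys=True)

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def build_scenario_config(overrides: Mapping | None = None) -> ScenarioConfig:
    """Default configuration with ``overrides`` applied.

    Unknown field names raise :class:`ConfigError`."""
    config = ScenarioConfig()
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    for key, value in (overrides or {}).items():
        if key not in known:
            raise ConfigError(f"unknown configuration field {key!r}")
        if key == "sample_design" and isinstance(value, list):
            # the JSON serialisation: a list of row records
            value = {
                (r["species"], r["locality"], r["sex"]): r["count"] for r in value
            }
        setattr(config, key, value)
    config.validate()
    return config


# ---------------------------------------------------------------------------
# sample sheet / contigs / truth
# ---------------------------------------------------------------------------

def build_sample_sheet(config: ScenarioConfig) -> pd.DataFrame:
    """Parental (non-hybrid) sample sheet implied by the sample design."""
    rows = []
    counter: dict[str, int] = {}
    for (species, locality, sex), count in config.sample_design.items():
        for _ in range(count):
            counter[species] = counter.get(species, 0) + 1
            rows.append(
                {
                    "sample_id": f"{species}_{locality[:4]}_{sex}{counter[species]:03d}",
                    "species": species,
                    "locality": locality,
                    "sex": sex,
                    "phenotype": species if species != "pulc" else "pulc",
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "species", "locality", "sex", "phenotype"])


def contig_table(config: ScenarioConfig) -> pd.DataFrame:
    """Contigs (name, compartment, length) of the simulated genome."""
    rows = []
    for comp, length in config.seq_lengths.items():
        if comp == "autosome":
            per = int(length // config.n_autosome_contigs)
            for i in range(config.n_autosome_contigs):
                rows.append({"contig": f"chr{i + 1}", "compartment": comp, "length": per})
        else:
            rows.append({"contig": comp, "compartment": comp, "length": int(length)})
    return pd.DataFrame(rows)


def default_compartment_map(config: ScenarioConfig) -> CompartmentMap:
    ct = contig_table(config)
    return CompartmentMap(
        pd.DataFrame(
            {
                "contig": ct["contig"],
                "start": 0,
                "end": ct["length"],
                "label": ct["compartment"],
            }
        )
    )


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset for recovery tests."""

    samples: pd.DataFrame  # sample_id, true_card_fraction, maternal_origin, hybrid_class
    compartment_seeds: dict = field(default_factory=dict)
    contig_compartment: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.samples["sample_id"].duplicated().any():
            raise ConfigError("duplicated sample in truth record")
        if self.samples["maternal_origin"].isna().any():
            raise ConfigError("maternal origin undefined for some sample")

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)


def _parental_truth(sheet: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sheet["sample_id"],
            "true_card_fraction": [
                {"card": 1.0, "tris": 0.0}.get(sp, np.nan) for sp in sheet["species"]
            ],
            "maternal_origin": sheet["species"],
            "hybrid_class": "parental",
        }
    )


# ---------------------------------------------------------------------------
# coalescent engine (msprime)
# ---------------------------------------------------------------------------

def _deme_of(species: str, locality: str) -> str:
    if species == "pulc":
        return "pulc"
    return f"{species}_{'allo' if locality == 'allopatric' else 'sym'}"


def _demography(config: ScenarioConfig, compartment: str) -> msprime.Demography:
    maternal = INHERITANCE[compartment] in ("W-like", "mitochondrial")
    bias = config.maternal_bias if maternal else 1.0
    dem = msprime.Demography()
    dem.add_population(name="pulc", initial_size=config.scaled_ne("pulc", compartment))
    for sp in ("card", "tris"):
        for loc in ("allo", "sym"):
            dem.add_population(
                name=f"{sp}_{loc}", initial_size=config.scaled_ne(sp, compartment)
            )
    dem.add_population(name="anc", initial_size=config.scaled_ne("tris", compartment))
    dem.add_population(name="root", initial_size=config.scaled_ne("tris", compartment))
    # backwards in time: lineages now in the recipient deme trace to the donor
    dem.set_migration_rate(source="tris_sym", dest="card_sym", rate=config.m_c2t * bias)
    dem.set_migration_rate(source="card_sym", dest="tris_sym", rate=config.m_t2c * bias)
    if config.pulse_c2t > 0:
        dem.add_mass_migration(
            time=config.T_contact / 2, source="tris_sym", dest="card_sym",
            proportion=min(1.0, config.pulse_c2t * bias),
        )
    if config.pulse_t2c > 0:
        dem.add_mass_migration(
            time=config.T_contact / 2, source="card_sym", dest="tris_sym",
            proportion=min(1.0, config.pulse_t2c * bias),
        )
    dem.add_migration_rate_change(time=config.T_contact, rate=0.0)
    dem.add_population_split(
        time=config.T_contact, derived=["card_sym"], ancestral="card_allo"
    )
    dem.add_population_split(
        time=config.T_contact, derived=["tris_sym"], ancestral="tris_allo"
    )
    dem.add_population_split(
        time=config.T_div, derived=["card_allo", "tris_allo"], ancestral="anc"
    )
    dem.add_population_split(time=config.T_out, derived=["anc", "pulc"], ancestral="root")
    dem.sort_events()
    return dem


def _carriers(sheet: pd.DataFrame, compartment: str) -> list[tuple[int, str, int]]:
    """(sample index, deme, n copies) per carrying sample, grouped by deme."""
    out = []
    for deme in _DEMES:
        for idx, row in sheet.iterrows():
            if _deme_of(row["species"], row["locality"]) != deme:
                continue
            k = expected_ploidy(compartment, row["sex"])
            if k > 0:
                out.append((int(idx), deme, k))
    return out


def simulate_compartment_genotypes(
    config: ScenarioConfig,
    compartment: str,
    sample_sheet: pd.DataFrame | None = None,
    engine: str = "msprime",
    seed: int | None = None,
) -> tuple[GenotypeTable, dict]:
    """Simulate phased genotypes for one compartment of the genome.

    Returns a variant-only :class:`GenotypeTable` over all contigs of the
    compartment (every unlisted position is an implicitly genotyped invariant
    site) and a truth fragment with the seeds used.
    """
    if compartment not in COMPARTMENTS:
        raise ConfigError(f"unknown compartment {compartment!r}")
    if config.compartment_scalings[compartment] <= 0:
        raise ConfigError("non-positive scaled Ne")
    sheet = build_sample_sheet(config) if sample_sheet is None else sample_sheet
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([base_seed, COMPARTMENTS.index(compartment)])
    contigs = contig_table(config)
    contigs = contigs[contigs["compartment"] == compartment]
    carriers = _carriers(sheet, compartment)
    if not carriers:
        raise ConfigError(f"no sample carries compartment {compartment!r}")

    frags = []
    seeds_used = {}
    recombining = INHERITANCE[compartment] in ("biparental", "Z-like")
    for (_, contig), child in zip(contigs.iterrows(), ss.spawn(len(contigs))):
        s1, s2 = (int(x) for x in child.generate_state(2) % (2**31 - 1) + 1)
        if engine == "msprime":
            sites, gt = _msprime_contig(
                config, compartment, carriers, len(sheet),
                int(contig["length"]), recombining, s1, s2,
            )
        elif engine == "wf":
            sites, gt = _wf_contig(
                config, compartment, carriers, len(sheet), int(contig["length"]), s1
            )
        else:
            raise ConfigError(f"unknown engine {engine!r}")
        sites.insert(0, "contig", contig["contig"])
        frags.append((sites, gt))
        seeds_used[contig["contig"]] = (s1, s2)

    table = GenotypeTable(
        sites=pd.concat([f[0] for f in frags], ignore_index=True),
        gt=np.concatenate([f[1] for f in frags]),
        samples=sheet["sample_id"].tolist(),
        contig_lengths={
            row["contig"]: int(row["length"]) for _, row in contigs.iterrows()
        },
        explicit_invariant=False,
    )
    truth_fragment = {
        "compartment": compartment,
        "seeds": seeds_used,
        "contigs": contigs["contig"].tolist(),
    }
    return table, truth_fragment


def _msprime_contig(config, compartment, carriers, n_samples, length, recombining, s1, s2):
    sample_sets = []
    hap_owner = []  # (sample index, slot)
    deme_counts: dict[str, int] = {}
    for si, deme, k in carriers:
        deme_counts.setdefault(deme, 0)
        for slot in range(k):
            hap_owner.append((si, slot))
        deme_counts[deme] += k
    for deme in _DEMES:
        if deme_counts.get(deme, 0) > 0:
            sample_sets.append(
                msprime.SampleSet(deme_counts[deme], population=deme, ploidy=1)
            )
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=_demography(config, compartment),
        sequence_length=length,
        recombination_rate=config.recomb_rate if recombining else 0.0,
        random_seed=s1,
    )
    mts = msprime.sim_mutations(
        ts, rate=config.mu, random_seed=s2, model=msprime.BinaryMutationModel()
    )
    positions, genos = [], []
    for var in mts.variants():
        alleles = np.array([int(a) for a in var.alleles if a is not None])
        g = alleles[var.genotypes]
        if g.min() == g.max():
            continue
        positions.append(int(var.site.position) + 1)  # 1-based
        genos.append(g.astype(np.int8))
    rng = np.random.default_rng(s2)
    S = len(positions)
    gt = np.full((S, n_samples, 2), ABSENT, dtype=np.int8)
    if S:
        G = np.array(genos)  # (S, n_haps)
        for h, (si, slot) in enumerate(hap_owner):
            gt[:, si, slot] = G[:, h]
    ref_i = rng.integers(0, 4, size=S)
    alt_i = (ref_i + rng.integers(1, 4, size=S)) % 4
    sites = pd.DataFrame(
        {"pos": positions, "ref": _BASES[ref_i], "alt": _BASES[alt_i]}
    )
    # positions are unique per msprime site but may repeat 1-based after cast; dedupe
    keep = ~sites["pos"].duplicated()
    return sites[keep].reset_index(drop=True), gt[keep.to_numpy()]


# ---------------------------------------------------------------------------
# Wright-Fisher fallback engine (non-recombining compartments)
# ---------------------------------------------------------------------------

def _wf_contig(config, compartment, carriers, n_samples, length, seed):
    """Discrete-generation backward sampler for a non-recombining compartment.

    Lineages are tracked generation by generation through the contact epoch
    (with per-generation migration between the sympatric demes), then jump
    between coalescences within each epoch.  Mutations are dropped on the
    resulting genealogy under an infinite-sites approximation.
    """
    rng = np.random.default_rng(seed)
    maternal = INHERITANCE[compartment] in ("W-like", "mitochondrial")
    bias = config.maternal_bias if maternal else 1.0

    def copies(species):  # haploid copy number of the compartment
        return max(2.0, 2.0 * config.scaled_ne(species, compartment))

    hap_owner = []
    lineage_deme = []
    for si, deme, k in carriers:
        for slot in range(k):
            hap_owner.append((si, slot))
            lineage_deme.append(deme)
    n_leaves = len(hap_owner)
    parent = {}
    node_time = {i: 0.0 for i in range(n_leaves)}
    children: dict[int, list[int]] = {}
    next_node = n_leaves
    active = list(range(n_leaves))
    deme_of = dict(zip(range(n_leaves), lineage_deme))

    def deme_size(deme):
        sp = "pulc" if deme == "pulc" else deme.split("_")[0]
        if deme == "anc":
            sp = "tris"
        if deme == "root":
            sp = "tris"
        return copies(sp)

    def coalesce_pair(deme, t):
        nonlocal next_node
        members = [l for l in active if deme_of[l] == deme]
        a, b = rng.choice(len(members), size=2, replace=False)
        la, lb = members[a], members[b]
        new = next_node
        next_node += 1
        node_time[new] = t
        parent[la] = new
        parent[lb] = new
        children[new] = [la, lb]
        active.remove(la)
        active.remove(lb)
        active.append(new)
        deme_of[new] = deme

    # epoch 1: [0, T_contact), per-generation with migration + optional pulse
    m_back = {  # backward move probability per lineage per generation
        "tris_sym": config.m_c2t * bias,
        "card_sym": config.m_t2c * bias,
    }
    move_to = {"tris_sym": "card_sym", "card_sym": "tris_sym"}
    t_pulse = config.T_contact / 2
    pulse = {
        "tris_sym": min(1.0, config.pulse_c2t * bias),
        "card_sym": min(1.0, config.pulse_t2c * bias),
    }
    t = 0.0
    while t < config.T_contact:
        t += 1.0
        for l in list(active):
            d = deme_of[l]
            if d in m_back and rng.random() < m_back[d]:
                deme_of[l] = move_to[d]
        if t - 1.0 < t_pulse <= t:
            for l in list(active):
                d = deme_of[l]
                if d in pulse and pulse[d] > 0 and rng.random() < pulse[d]:
                    deme_of[l] = move_to[d]
        for deme in set(deme_of[l] for l in active):
            k = sum(1 for l in active if deme_of[l] == deme)
            if k >= 2 and rng.random() < (k * (k - 1) / 2) / deme_size(deme):
                coalesce_pair(deme, t)

    def merge(demes, into):
        for l in active:
            if deme_of[l] in demes:
                deme_of[l] = into

    def run_epoch(t0, t1):
        t_local = t0
        while True:
            demes = sorted(set(deme_of[l] for l in active))
            waits = []
            for deme in demes:
                k = sum(1 for l in active if deme_of[l] == deme)
                if k >= 2:
                    p = min(1.0, (k * (k - 1) / 2) / deme_size(deme))
                    waits.append((float(rng.geometric(p)), deme))
            if not waits:
                return
            dt, deme = min(waits)
            if t_local + dt >= t1:
                return
            t_local += dt
            coalesce_pair(deme, t_local)

    merge({"card_sym"}, "card_allo")
    merge({"tris_sym"}, "tris_allo")
    run_epoch(config.T_contact, config.T_div)
    merge({"card_allo", "tris_allo"}, "anc")
    run_epoch(config.T_div, config.T_out)
    merge({"anc", "pulc"}, "root")
    run_epoch(config.T_out, np.inf)

    # drop mutations: Poisson per branch, infinite sites over [1, length]
    leaf_sets: dict[int, np.ndarray] = {}

    def leaves_under(node):
        if node in leaf_sets:
            return leaf_sets[node]
        if node < n_leaves:
            out = np.array([node])
        else:
            out = np.concatenate([leaves_under(c) for c in children[node]])
        leaf_sets[node] = out
        return out

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * (len(node_time) + 10)))
    try:
        mut_pos, mut_leafsets = [], []
        for node, par in parent.items():
            blen = node_time[par] - node_time[node]
            n_mut = rng.poisson(config.mu * length * blen)
            for _ in range(n_mut):
                mut_pos.append(int(rng.integers(1, length + 1)))
                mut_leafsets.append(leaves_under(node))
    finally:
        sys.setrecursionlimit(old)

    order = np.argsort(mut_pos, kind="stable")
    gt = np.full((0, n_samples, 2), ABSENT, dtype=np.int8)
    positions, rows = [], []
    seen = set()
    for i in order:
        p = mut_pos[i]
        if p in seen:
            continue  # infinite-sites approximation: drop collisions
        seen.add(p)
        row = np.zeros(n_leaves, dtype=np.int8)
        row[mut_leafsets[i]] = 1
        if row.min() == row.max():
            continue
        positions.append(p)
        rows.append(row)
    S = len(positions)
    gt = np.full((S, n_samples, 2), ABSENT, dtype=np.int8)
    for h, (si, slot) in enumerate(hap_owner):
        for r in range(S):
            gt[r, si, slot] = rows[r][h]
    ref_i = rng.integers(0, 4, size=S)
    alt_i = (ref_i + rng.integers(1, 4, size=S)) % 4
    sites = pd.DataFrame({"pos": positions, "ref": _BASES[ref_i], "alt": _BASES[alt_i]})
    return sites, gt


# ---------------------------------------------------------------------------
# hybrid synthesis
# ---------------------------------------------------------------------------

class _Parent:
    """Phased haplotypes of one (possibly virtual) individual, per compartment,
    with per-site card-ancestry tracks."""

    def __init__(self, sex: str):
        self.sex = sex
        self.haps: dict[str, list[np.ndarray]] = {}
        self.anc: dict[str, list[np.ndarray]] = {}


def _parent_from_table(tables, sheet, sample_id: str) -> _Parent:
    row = sheet[sheet["sample_id"] == sample_id].iloc[0]
    is_card = row["species"] == "card"
    p = _Parent(row["sex"])
    for comp, t in tables.items():
        j = t.samples.index(sample_id)
        k = expected_ploidy(comp, row["sex"])
        p.haps[comp] = [t.gt[:, j, s].copy() for s in range(k)]
        p.anc[comp] = [
            np.full(t.n_sites, 1 if is_card else 0, dtype=np.int8) for _ in range(k)
        ]
    return p


def _gamete(parent: _Parent, comp: str, table: GenotypeTable, config, rng):
    """One gamete (haplotype + ancestry track) for a compartment; None if the
    parent does not transmit it (e.g. W from a male)."""
    haps, anc = parent.haps.get(comp, []), parent.anc.get(comp, [])
    if not haps:
        return None
    if len(haps) == 1:
        return haps[0].copy(), anc[0].copy()
    mode = INHERITANCE[comp]
    S = len(haps[0])
    if mode == "biparental":
        choice = rng.integers(0, 2, size=S)  # free recombination
    else:  # Z-like: limited crossovers along the physical map
        pos = table.sites["pos"].to_numpy()
        total = sum(table.contig_lengths.values())
        breaks = np.sort(rng.integers(1, max(2, total), size=config.z_crossovers))
        choice = np.zeros(S, dtype=np.int64)
        first = rng.integers(0, 2)
        seg = np.searchsorted(breaks, pos)
        choice = (first + seg) % 2
    h = np.where(choice == 0, haps[0], haps[1]).astype(np.int8)
    a = np.where(choice == 0, anc[0], anc[1]).astype(np.int8)
    return h, a


def synthesize_hybrids(
    tables: dict[str, GenotypeTable],
    sample_sheet: pd.DataFrame,
    config: ScenarioConfig,
    seed: int | None = None,
) -> tuple[dict[str, GenotypeTable], pd.DataFrame, pd.DataFrame]:
    """Create hybrid individuals (F1 and first-generation backcrosses) from
    simulated parental genotypes.

    Returns the per-compartment tables with hybrid columns appended, the
    extended sample sheet, and the hybrid truth fragment (realised ancestry
    fractions and maternal origins).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 7])
    )
    sheet = sample_sheet

    def pool(species, sex):
        m = (sheet["species"] == species) & (sheet["sex"] == sex)
        if m.any():
            sub = sheet[m]
            sym = sub[sub["locality"] == "sympatric"]
            return (sym if len(sym) else sub)["sample_id"].tolist()
        return []

    def need_female(species):
        ids = pool(species, "F")
        if not ids:
            raise ConfigError(f"no female {species} parents available")
        return ids

    def make_f1(sex: str, mother_species: str) -> _Parent:
        father_species = "tris" if mother_species == "card" else "card"
        mother = _parent_from_table(
            tables, sheet, str(rng.choice(need_female(mother_species)))
        )
        fathers = pool(father_species, "M")
        if not fathers:
            raise ConfigError(f"no male {father_species} parents available")
        father = _parent_from_table(tables, sheet, str(rng.choice(fathers)))
        return _cross(mother, father, sex, config, rng)

    def _cross(mother: _Parent, father: _Parent, sex: str, config, rng) -> _Parent:
        child = _Parent(sex)
        for comp, t in tables.items():
            mode = INHERITANCE[comp]
            if mode == "biparental":
                gm = _gamete(mother, comp, t, config, rng)
                gf = _gamete(father, comp, t, config, rng)
                child.haps[comp] = [gm[0], gf[0]]
                child.anc[comp] = [gm[1], gf[1]]
            elif mode == "Z-like":
                gf = _gamete(father, comp, t, config, rng)
                if sex == "M":  # sons: Z from both parents
                    gm = _gamete(mother, comp, t, config, rng)
                    child.haps[comp] = [gm[0], gf[0]]
                    child.anc[comp] = [gm[1], gf[1]]
                else:  # daughters: single Z from the father
                    child.haps[comp] = [gf[0]]
                    child.anc[comp] = [gf[1]]
            elif mode == "W-like":
                if sex == "F":
                    gm = _gamete(mother, comp, t, config, rng)
                    child.haps[comp] = [gm[0]]
                    child.anc[comp] = [gm[1]]
                else:
                    child.haps[comp] = []
                    child.anc[comp] = []
            else:  # mitochondrial
                gm = _gamete(mother, comp, t, config, rng)
                child.haps[comp] = [gm[0]]
                child.anc[comp] = [gm[1]]
        return child

    hybrids: list[tuple[str, str, _Parent, str]] = []  # (id, class, parent, mt origin)
    counter = 0
    for cls, count in config.hybrid_design.items():
        for i in range(count):
            counter += 1
            sex = "F" if i % 2 == 0 else "M"
            hid = f"hyb_{cls}_{counter:03d}"
            if cls == "F1":
                mother_sp = config.f1_mother
                child = make_f1(sex, mother_sp)
                mt_origin = mother_sp
            elif cls in ("BC_card", "BC_tris"):
                recurrent = "card" if cls == "BC_card" else "tris"
                if config.bc_mother == "F1":
                    f1 = make_f1("F", config.f1_mother)
                    fathers = pool(recurrent, "M")
                    if not fathers:
                        raise ConfigError(f"no male {recurrent} parents available")
                    father = _parent_from_table(tables, sheet, str(rng.choice(fathers)))
                    child = _cross(f1, father, sex, config, rng)
                    mt_origin = config.f1_mother
                else:  # recurrent-species mother, F1 father
                    mother = _parent_from_table(
                        tables, sheet, str(rng.choice(need_female(recurrent)))
                    )
                    f1 = make_f1("M", config.f1_mother)
                    child = _cross(mother, f1, sex, config, rng)
                    mt_origin = recurrent
            else:
                raise ConfigError(f"unknown hybrid class {cls!r}")
            hybrids.append((hid, cls, child, mt_origin))

    if not hybrids:
        return tables, sheet, pd.DataFrame(
            columns=["sample_id", "true_card_fraction", "maternal_origin", "hybrid_class"]
        )

    out_tables = {}
    for comp, t in tables.items():
        extra = np.full((t.n_sites, len(hybrids), 2), ABSENT, dtype=np.int8)
        for j, (_, _, child, _) in enumerate(hybrids):
            for slot, hap in enumerate(child.haps.get(comp, [])):
                extra[:, j, slot] = hap
        out_tables[comp] = GenotypeTable(
            sites=t.sites.copy(),
            gt=np.concatenate([t.gt, extra], axis=1),
            samples=t.samples + [h[0] for h in hybrids],
            contig_lengths=dict(t.contig_lengths),
            explicit_invariant=t.explicit_invariant,
        )

    sheet_rows = [
        {
            "sample_id": hid,
            "species": "hybrid",
            "locality": "sympatric",
            "sex": child.sex,
            "phenotype": "hybrid",
        }
        for hid, _, child, _ in hybrids
    ]
    new_sheet = pd.concat([sheet, pd.DataFrame(sheet_rows)], ignore_index=True)

    truth_rows = []
    for hid, cls, child, mt_origin in hybrids:
        auto_anc = np.concatenate(
            [np.concatenate(child.anc[c]) for c in ("autosome", "neoPAR") if c in child.anc]
        )
        truth_rows.append(
            {
                "sample_id": hid,
                "true_card_fraction": float(auto_anc.mean()) if len(auto_anc) else np.nan,
                "maternal_origin": mt_origin,
                "hybrid_class": cls,
            }
        )
    return out_tables, new_sheet, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# coverage and annotations
# ---------------------------------------------------------------------------

def _mean_depth(config: ScenarioConfig, compartment: str, sex: str) -> float:
    """Expected read depth given copy number (autosomal diploid = depth_mean)."""
    if compartment == "mt":
        return config.depth_mean * config.mt_depth_factor
    copies = expected_ploidy(compartment, sex)
    return config.depth_mean * copies / 2.0


def simulate_coverage(
    config: ScenarioConfig,
    sample_sheet: pd.DataFrame,
    seed: int | None = None,
):
    """Per-(sample, contig) mean raw depths under Poisson sequencing noise.

    Returns a :class:`myzopop.sexlinkage.CoverageProfile`.
    """
    from .sexlinkage import CoverageProfile

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 11])
    )
    ct = contig_table(config)
    rows = []
    for _, s in sample_sheet.iterrows():
        for _, c in ct.iterrows():
            mean = _mean_depth(config, c["compartment"], s["sex"])
            L = int(c["length"])
            obs = rng.poisson(mean * L) / L  # mean of per-site Poisson counts
            rows.append(
                {"sample": s["sample_id"], "contig": c["contig"], "mean_depth": obs}
            )
    autosomes = ct.loc[ct["compartment"] == "autosome", "contig"].tolist()
    return CoverageProfile(
        depths=pd.DataFrame(rows),
        sex=dict(zip(sample_sheet["sample_id"], sample_sheet["sex"])),
        autosome_contigs=autosomes,
    )


def draw_annotations(n_sites: int, rng, fail_fraction: float = 0.0):
    """Per-site quality annotations: passing sites from mid-range
    distributions, a ``fail_fraction`` of sites pushed past one threshold."""
    ann = pd.DataFrame(
        {
            "QD": rng.uniform(10, 30, n_sites),
            "SOR": rng.uniform(0.5, 2.0, n_sites),
            "FS": rng.uniform(0, 10, n_sites),
            "MQ": rng.uniform(50, 60, n_sites),
            "MQRankSum": rng.normal(0, 1, n_sites),
            "ReadPosRankSum": rng.normal(0, 1, n_sites),
        }
    )
    fail = np.zeros(n_sites, dtype=bool)
    if fail_fraction > 0 and n_sites:
        fail = rng.random(n_sites) < fail_fraction
        idx = np.flatnonzero(fail)
        which = rng.integers(0, 6, size=len(idx))
        bad = {
            0: ("QD", rng.uniform(0.1, 1.9, len(idx))),
            1: ("SOR", rng.uniform(3.1, 6.0, len(idx))),
            2: ("FS", rng.uniform(61, 120, len(idx))),
            3: ("MQ", rng.uniform(20, 39, len(idx))),
            4: ("MQRankSum", rng.uniform(-20, -13, len(idx))),
            5: ("ReadPosRankSum", rng.uniform(-15, -8.5, len(idx))),
        }
        for w, (key, vals) in bad.items():
            sel = which == w
            ann.loc[idx[sel], key] = vals[sel]
    return ann, fail


# ---------------------------------------------------------------------------
# all-sites materialisation + dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: ScenarioConfig
    sample_sheet: pd.DataFrame
    compartment_map: CompartmentMap
    tables: dict  # compartment -> variant-only GenotypeTable
    truth: TruthRecord
    coverage: object  # sexlinkage.CoverageProfile
    allsites: GenotypeTable | None = None

    def variant_table(self) -> GenotypeTable:
        """All compartments concatenated (variant-only, implicit invariants)."""
        return GenotypeTable.concat([self.tables[c] for c in self.tables])


def materialize_allsites(
    dataset_tables: dict[str, GenotypeTable],
    config: ScenarioConfig,
    sample_sheet: pd.DataFrame,
    seed: int | None = None,
) -> GenotypeTable:
    """Expand variant-only simulated tables to an explicit all-sites table
    with annotations, per-sample depths, and (for mtDNA) allele fractions."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 13])
    )
    ct = contig_table(config)
    samples = next(iter(dataset_tables.values())).samples
    sex = dict(zip(sample_sheet["sample_id"], sample_sheet["sex"]))
    n = len(samples)
    frags = []
    for _, c in ct.iterrows():
        comp, contig, L = c["compartment"], c["contig"], int(c["length"])
        src = dataset_tables[comp]
        sub = src.sites["contig"] == contig
        vsites = src.sites[sub].reset_index(drop=True)
        vgt = src.gt[sub.to_numpy()]
        # invariant scaffold
        pos = np.arange(1, L + 1, dtype=np.int64)
        gt = np.zeros((L, n, 2), dtype=np.int8)
        for j, s in enumerate(samples):
            k = expected_ploidy(comp, sex[s])
            if k == 0:
                gt[:, j, :] = ABSENT
            elif k == 1:
                gt[:, j, 1] = ABSENT
        ref = _BASES[rng.integers(0, 4, size=L)]
        alt = np.full(L, ".", dtype=object)
        vidx = vsites["pos"].to_numpy() - 1
        gt[vidx] = vgt
        ref[vidx] = vsites["ref"].to_numpy()
        alt[vidx] = vsites["alt"].to_numpy()
        ann, _ = draw_annotations(L, rng, config.fail_fraction)
        depth = np.empty((L, n), dtype=np.int16)
        for j, s in enumerate(samples):
            depth[:, j] = rng.poisson(_mean_depth(config, comp, sex[s]), size=L)
        mrf = None
        if comp == "mt":
            mrf = rng.uniform(0, 0.05, size=(L, n)).astype(np.float32)
            if config.heteroplasmy_fraction > 0:
                hsites = rng.random(L) < config.heteroplasmy_fraction
                hsamp = rng.integers(0, n, size=int(hsites.sum()))
                mrf[np.flatnonzero(hsites), hsamp] = rng.uniform(
                    0.25, 0.45, size=int(hsites.sum())
                ).astype(np.float32)
        frags.append(
            GenotypeTable(
                sites=pd.DataFrame(
                    {"contig": contig, "pos": pos, "ref": ref, "alt": alt}
                ),
                gt=gt,
                samples=list(samples),
                contig_lengths={contig: L},
                annotations=ann,
                depth=depth,
                minor_read_frac=mrf,
                explicit_invariant=True,
            )
        )
    return GenotypeTable.concat(frags)


def simulate_maternal_unit(
    config: ScenarioConfig,
    sample_sheet: pd.DataFrame,
    seed: int | None = None,
) -> dict[str, GenotypeTable]:
    """Simulate the maternally co-transmitted compartments (W, neo-W, mtDNA)
    on a single non-recombining genealogy, as they are co-inherited in a ZW
    system.  Every sample contributes one maternal lineage; W-like sites are
    then masked in males, whose W haplotype is never transmitted or observed.
    """
    comps = [c for c in ("W", "neoW", "mt") if c in config.seq_lengths]
    if not comps:
        return {}
    lengths = {c: int(config.seq_lengths[c]) for c in comps}
    total = sum(lengths.values())
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([base_seed, 101])
    s1, s2 = (int(x) for x in ss.generate_state(2) % (2**31 - 1) + 1)
    # one maternal lineage per sample, Ne scaled like the W
    carriers = []
    for deme in _DEMES:
        for idx, row in sample_sheet.iterrows():
            if _deme_of(row["species"], row["locality"]) == deme:
                carriers.append((int(idx), deme, 1))
    sites, gt = _msprime_contig(
        config, comps[0], carriers, len(sample_sheet), total,
        recombining=False, s1=s1, s2=s2,
    )
    male = (sample_sheet["sex"] == "M").to_numpy()
    out = {}
    offset = 0
    for comp in comps:
        L = lengths[comp]
        m = (sites["pos"] > offset) & (sites["pos"] <= offset + L)
        sub = sites[m].reset_index(drop=True).copy()
        sub["pos"] = sub["pos"] - offset
        sub["contig"] = comp
        g = gt[m.to_numpy()].copy()
        if INHERITANCE[comp] == "W-like":
            g[:, male, :] = ABSENT
        out[comp] = GenotypeTable(
            sites=sub[["contig", "pos", "ref", "alt"]],
            gt=g,
            samples=sample_sheet["sample_id"].tolist(),
            contig_lengths={comp: L},
            explicit_invariant=False,
        )
        offset += L
    return out


def simulate_dataset(
    config: ScenarioConfig,
    materialize: bool = False,
    engine: str = "msprime",
) -> SimulatedDataset:
    """Run the full generator: parental coalescent simulation per compartment,
    hybrid synthesis, coverage, and (optionally) all-sites materialisation."""
    sheet = build_sample_sheet(config)
    tables: dict[str, GenotypeTable] = {}
    truth = TruthRecord(samples=_parental_truth(sheet))
    maternal = (
        simulate_maternal_unit(config, sheet)
        if config.link_maternal and engine == "msprime"
        else {}
    )
    for comp in config.seq_lengths:
        if comp in maternal:
            tables[comp] = maternal[comp]
            truth.compartment_seeds[comp] = {"linked_maternal_unit": True}
            truth.contig_compartment[comp] = comp
            continue
        t, frag = simulate_compartment_genotypes(config, comp, sheet, engine=engine)
        tables[comp] = t
        truth.compartment_seeds[comp] = frag["seeds"]
        for contig in frag["contigs"]:
            truth.contig_compartment[contig] = comp
    if sum(config.hybrid_design.values()) > 0:
        tables, sheet, hybrid_truth = synthesize_hybrids(tables, sheet, config)
        truth.samples = pd.concat([truth.samples, hybrid_truth], ignore_index=True)
    truth.validate()
    coverage = simulate_coverage(config, sheet)
    ds = SimulatedDataset(
        config=config,
        sample_sheet=sheet,
        compartment_map=default_compartment_map(config),
        tables=tables,
        truth=truth,
        coverage=coverage,
    )
    if materialize:
        ds.allsites = materialize_allsites(tables, config, sheet)
    return ds


def emit_dataset(dataset: SimulatedDataset, outdir) -> dict:
    """Write the dataset as files: all-sites VCF, sample sheet, compartment
    BED, truth record, coverage table, and the scenario provenance."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset.allsites is None:
        dataset.allsites = materialize_allsites(
            dataset.tables, dataset.config, dataset.sample_sheet
        )
    paths = {
        "vcf": out / "allsites.vcf",
        "samples": out / "samples.tsv",
        "bed": out / "compartments.bed",
        "truth": out / "truth.tsv",
        "coverage": out / "coverage.tsv",
        "config": out / "scenario.json",
    }
    write_allsites_vcf(dataset.allsites, paths["vcf"])
    write_sample_sheet(dataset.sample_sheet, paths["samples"])
    dataset.compartment_map.to_bed(paths["bed"])
    dataset.truth.to_tsv(paths["truth"])
    dataset.coverage.depths.to_csv(paths["coverage"], sep="\t", index=False)
    paths["config"].write_text(dataset.config.to_json())
    return {k: str(v) for k, v in paths.items()}
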