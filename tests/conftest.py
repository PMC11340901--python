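"""Shared fixtures: small simulated datasets and toy-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import myzopop as mp
from myzopop.genotype_io import ABSENT, MISSING, CompartmentMap, GenotypeTable


SMALL_DESIGN = {
    ("card", "allopatric", "M"): 5, ("card", "allopatric", "F"): 5,
    ("card", "sympatric", "M"): 5, ("card", "sympatric", "F"): 5,
    ("tris", "allopatric", "M"): 5, ("tris", "allopatric", "F"): 5,
    ("tris", "sympatric", "M"): 5, ("tris", "sympatric", "F"): 5,
    ("pulc", "allopatric", "F"): 1,
}

SMALL_LENGTHS = {
    "autosome": 100_000, "neoPAR": 30_000, "Z": 40_000, "neoZ": 40_000,
    "W": 30_000, "neoW": 30_000, "mt": 16_000,
}


def small_config(**overrides):
    base = {
        "seq_lengths": dict(SMALL_LENGTHS),
        "n_autosome_contigs": 2,
        "sample_design": dict(SMALL_DESIGN),
        "hybrid_design": {"F1": 2, "BC_card": 2, "BC_tris": 2},
        "seed": 11,
    }
    base.update(overrides)
    return mp.build_scenario_config(base)


@pytest.fixture(scope="session")
def contact_ds():
    """Two species in secondary contact with default migration and hybrids."""
    return mp.simulate_dataset(small_config())


@pytest.fixture(scope="session")
def nomig_ds():
    """Complete isolation (no migration, no pulses): clean species structure,
    hybrids synthesised from unadmixed parents."""
    return mp.simulate_dataset(
        small_config(m_c2t=0.0, m_t2c=0.0, seed=13)
    )


@pytest.fixture(scope="session")
def asym_ds():
    """Asymmetric, fully female-biased migration from card into tris."""
    return mp.simulate_dataset(
        small_config(
            m_c2t=0.0075, m_t2c=0.0, maternal_bias=1.0, seed=17,
            sample_design={
                ("card", "allopatric", "M"): 5, ("card", "allopatric", "F"): 10,
                ("card", "sympatric", "M"): 15, ("card", "sympatric", "F"): 20,
                ("tris", "allopatric", "M"): 5, ("tris", "allopatric", "F"): 10,
                ("tris", "sympatric", "M"): 15, ("tris", "sympatric", "F"): 20,
                ("pulc", "allopatric", "F"): 1,
            },
            seq_lengths={**SMALL_LENGTHS, "W": 200_000},
        )
    )


def pops_of(ds):
    sheet = ds.sample_sheet
    g = mp.samples_for
    return {
        "card_allo": g(sheet, species="card", locality="allopatric"),
        "card_sym": g(sheet, species="card", locality="sympatric"),
        "tris_allo": g(sheet, species="tris", locality="allopatric"),
        "tris_sym": g(sheet, species="tris", locality="sympatric"),
        "pulc": g(sheet, species="pulc"),
    }


# ---------------------------------------------------------------------------
# toy table construction
# ---------------------------------------------------------------------------

def toy_table(
    calls,
    samples=None,
    contig="chr1",
    positions=None,
    alts=None,
    contig_length=None,
    annotations=None,
    depth=None,
    compartment="autosome",
):
    """Build a GenotypeTable from a nested call list.

    ``calls[i][j]`` is a pair of allele codes for site i, sample j
    (use ``None`` for a missing allele, ``"-"`` for an absent slot).
    """
    code = {None: MISSING, "-": ABSENT}
    gt = np.array(
        [[[code.get(a, a) for a in pair] for pair in row] for row in calls],
        dtype=np.int8,
    )
    S, N = gt.shape[0], gt.shape[1]
    samples = samples or [f"s{j}" for j in range(N)]
    positions = positions or list(range(1, S + 1))
    alts = alts or ["T"] * S
    length = contig_length or (max(positions) + 10)
    t = GenotypeTable(
        sites=pd.DataFrame(
            {"contig": contig, "pos": positions, "ref": "A", "alt": alts}
        ),
        gt=gt,
        samples=list(samples),
        contig_lengths={contig: length},
        annotations=annotations,
        depth=depth,
        explicit_invariant=True,
    )
    return t


def toy_cmap(table, label="autosome"):
    return CompartmentMap(
        pd.DataFrame(
            {
                "contig": list(table.contig_lengths),
                "start": 0,
                "end": list(table.contig_lengths.values()),
                "label": label,
            }
        )
    )
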