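"""Diversity statistics against independent oracles (brute-force pairwise
enumeration, hand-coded estimator formulas)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myzopop as mp
from myzopop.diversity import (
    TajimaConstants,
    compartment_summary,
    make_windows,
    site_pair_counts,
    tajimas_d_from_counts,
    wc_site_components,
    windowed_dxy,
    windowed_fst,
    windowed_pi,
    windowed_tajimas_d,
)
from myzopop.genotype_io import GenotypeIOError

from conftest import toy_cmap, toy_table


# ---------------------------------------------------------------------------
# per-site counting
# ---------------------------------------------------------------------------

class TestSitePairCounts:
    def test_within_population_enumeration(self):
        # 3 ref + 1 alt alleles: enumerate all C(4,2)=6 pairs, 3 differ
        d, c = site_pair_counts(np.array([3]), np.array([1]))
        assert (d[0], c[0]) == (3, 6)

    def test_between_fixed_difference(self):
        d, c = site_pair_counts(
            np.array([2]), np.array([0]), np.array([0]), np.array([2])
        )
        assert (d[0], c[0]) == (4, 4)  # site dxy = 1

    def test_invariant_site(self):
        d, c = site_pair_counts(np.array([10]), np.array([0]))
        assert (d[0], c[0]) == (0, 45)

    @given(
        n_ref=st.integers(0, 12),
        n_alt=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_explicit_pair_enumeration(self, n_ref, n_alt):
        alleles = [0] * n_ref + [1] * n_alt
        expect_d = sum(a != b for a, b in itertools.combinations(alleles, 2))
        expect_c = len(list(itertools.combinations(alleles, 2)))
        d, c = site_pair_counts(np.array([n_ref]), np.array([n_alt]))
        assert (d[0], c[0]) == (expect_d, expect_c)


# ---------------------------------------------------------------------------
# windowed pi / dxy
# ---------------------------------------------------------------------------

def _brute_pi(table, samples):
    """Mean pairwise difference fraction by direct enumeration over all
    allele pairs, summed over sites."""
    idx = table.sample_index(samples)
    diffs = comps = 0
    for i in range(table.n_sites):
        alleles = [a for a in table.gt[i, idx, :].ravel() if a >= 0]
        for x, y in itertools.combinations(alleles, 2):
            comps += 1
            diffs += x != y
    return diffs / comps if comps else float("nan")


def _brute_dxy(table, sx, sy):
    ix, iy = table.sample_index(sx), table.sample_index(sy)
    diffs = comps = 0
    for i in range(table.n_sites):
        ax = [a for a in table.gt[i, ix, :].ravel() if a >= 0]
        ay = [a for a in table.gt[i, iy, :].ravel() if a >= 0]
        for x in ax:
            for y in ay:
                comps += 1
                diffs += x != y
    return diffs / comps if comps else float("nan")


class TestWindowedPi:
    def test_matches_brute_force_with_missing_data(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(20, 6, 2))
        calls[rng.random(calls.shape) < 0.15] = -1
        t = toy_table(calls.tolist())
        got = windowed_pi(t, t.samples, toy_cmap(t), window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == pytest.approx(
            _brute_pi(t, t.samples), abs=1e-12
        )

    def test_invariant_window_is_zero(self):
        t = toy_table([[[0, 0], [0, 0]]] * 5, alts=["."] * 5)
        got = windowed_pi(t, t.samples, toy_cmap(t), window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == 0.0

    def test_min_sites_qualification(self):
        t = toy_table([[[0, 1], [0, 0]]])
        got = windowed_pi(t, t.samples, toy_cmap(t), min_sites=10_000)
        assert not got["qualifies"].iloc[0]
        got2 = windowed_pi(t, t.samples, toy_cmap(t), min_sites=1)
        assert got2["qualifies"].iloc[0]

    def test_all_missing_sample_does_not_change_pi(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, size=(10, 4, 2)).tolist()
        t = toy_table(calls)
        with_ghost = [row + [[None, None]] for row in calls]
        t2 = toy_table(with_ghost)
        a = windowed_pi(t, t.samples, toy_cmap(t), window_size=10**6, min_sites=0)
        b = windowed_pi(t2, t2.samples, toy_cmap(t2), window_size=10**6, min_sites=0)
        assert a["value"].iloc[0] == b["value"].iloc[0]

    def test_implicit_invariant_sites_counted(self):
        """A variant-only table over a known contig length gives the same pi
        as the explicit all-sites version."""
        calls = [[[0, 1], [1, 1]], [[0, 0], [0, 1]]]
        explicit = toy_table(
            calls + [[[0, 0], [0, 0]]] * 8,
            positions=[1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
            alts=["T", "T"] + ["."] * 8,
            contig_length=10,
        )
        implicit = toy_table(calls, positions=[1, 2], contig_length=10)
        implicit.explicit_invariant = False
        sheet = pd.DataFrame(
            {"sample_id": explicit.samples, "species": "tris",
             "locality": "allopatric", "sex": ["M", "F"], "phenotype": "tris"}
        )
        a = windowed_pi(explicit, explicit.samples, toy_cmap(explicit),
                        window_size=10**6, min_sites=0)
        b = windowed_pi(implicit, implicit.samples, toy_cmap(implicit),
                        window_size=10**6, min_sites=0, sample_sheet=sheet)
        assert a["value"].iloc[0] == pytest.approx(b["value"].iloc[0], abs=1e-15)
        assert a["n_sites"].iloc[0] == b["n_sites"].iloc[0]


class TestWindowedDxy:
    def test_symmetry(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 2, size=(15, 6, 2)).tolist()
        t = toy_table(calls)
        x, y = t.samples[:3], t.samples[3:]
        a = windowed_dxy(t, x, y, toy_cmap(t), window_size=10**6, min_sites=0)
        b = windowed_dxy(t, y, x, toy_cmap(t), window_size=10**6, min_sites=0)
        assert a["value"].iloc[0] == b["value"].iloc[0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 2, size=(12, 5, 2))
        calls[rng.random(calls.shape) < 0.1] = -1
        t = toy_table(calls.tolist())
        x, y = t.samples[:2], t.samples[2:]
        got = windowed_dxy(t, x, y, toy_cmap(t), window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == pytest.approx(_brute_dxy(t, x, y), abs=1e-12)

    def test_fixed_difference_fraction(self):
        calls = [
            [[0, 0], [1, 1]],  # fixed difference
            [[0, 0], [0, 0]],  # invariant
            [[0, 0], [0, 0]],
            [[0, 0], [1, 1]],
        ]
        t = toy_table(calls, alts=["T", ".", ".", "T"])
        got = windowed_dxy(t, [t.samples[0]], [t.samples[1]], toy_cmap(t),
                           window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _wc_reference(n1, p1, h1, n2, p2, h2):
    """Independent coding of the Weir-Cockerham (1984) a, b, c components."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFst:
    def test_fixed_difference_site_is_one(self):
        calls = [[[0, 0]] * 10 + [[1, 1]] * 10]
        t = toy_table(calls)
        x, y = t.samples[:10], t.samples[10:]
        got = windowed_fst(t, x, y, toy_cmap(t), window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_components_match_independent_formulas(self):
        # 4+4 diploids: pop X half hom-ref half hom-alt, pop Y all hom-ref
        calls = [
            [[0, 0], [0, 0], [1, 1], [1, 1], [0, 0], [0, 0], [0, 0], [0, 0]]
        ]
        t = toy_table(calls)
        a, b, c, ok = wc_site_components(
            np.array([4]), np.array([4]), np.array([0]),
            np.array([8]), np.array([0]), np.array([0]),
        )
        ra, rb, rc = _wc_reference(4, 0.5, 0.0, 4, 0.0, 0.0)
        assert a[0] == pytest.approx(ra, abs=1e-12)
        assert b[0] == pytest.approx(rb, abs=1e-12)
        assert c[0] == pytest.approx(rc, abs=1e-12)
        got = windowed_fst(t, t.samples[:4], t.samples[4:], toy_cmap(t),
                           window_size=10**6, min_sites=0)
        assert got["value"].iloc[0] == pytest.approx(ra / (ra + rb + rc), abs=1e-12)

    def test_panmictic_near_zero(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.2, 0.8, size=60)
        calls = (rng.random((60, 16, 2)) < p[:, None, None]).astype(int)
        t = toy_table(calls.tolist())
        got = windowed_fst(t, t.samples[:8], t.samples[8:], toy_cmap(t),
                           window_size=10**6, min_sites=0)
        assert abs(got["value"].iloc[0]) < 0.05  # may be slightly negative

    def test_hudson_estimator_available(self):
        calls = [[[0, 0]] * 5 + [[1, 1]] * 5]
        t = toy_table(calls)
        got = windowed_fst(t, t.samples[:5], t.samples[5:], toy_cmap(t),
                           window_size=10**6, min_sites=0, estimator="hudson")
        assert got["value"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_reference(S, pi_hat, n):
    """Independent coding of the Tajima (1989) constants and statistic."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_matches_independent_constants(self):
        assert tajimas_d_from_counts(16, 3.888, 10) == pytest.approx(
            _tajima_reference(16, 3.888, 10), abs=1e-12
        )

    @pytest.mark.parametrize("n,S,pi", [(4, 3, 1.2), (20, 50, 11.0), (60, 7, 0.9)])
    def test_constant_grid(self, n, S, pi):
        assert tajimas_d_from_counts(S, pi, n) == pytest.approx(
            _tajima_reference(S, pi, n), abs=1e-10
        )

    def test_zero_numerator_gives_zero(self):
        k = TajimaConstants.for_n(10)
        S = 5
        assert tajimas_d_from_counts(S, S / k.a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(GenotypeIOError):
            TajimaConstants.for_n(3)

    def test_windowed_excludes_incomplete_sites(self):
        calls = [
            [[0, 1], [0, 0], [0, 0]],
            [[0, 1], [None, None], [0, 0]],  # missing call: dropped
        ]
        t = toy_table(calls)
        got = windowed_tajimas_d(t, t.samples, toy_cmap(t))
        assert got["n_snps"].iloc[0] == 1

    def test_growth_gives_negative_d(self, nomig_ds):
        """The resident species' recent history is neutral-constant here, so
        D is near zero; an excess of rare variants created by subsampling
        singleton-rich data drives D negative."""
        rng = np.random.default_rng(21)
        n = 20
        # site-frequency spectrum heavily skewed to singletons
        calls = []
        for _ in range(200):
            row = [[0, 0] for _ in range(n)]
            row[rng.integers(0, n)][rng.integers(0, 2)] = 1
            calls.append(row)
        t = toy_table(calls, positions=list(range(1, 201)))
        got = windowed_tajimas_d(t, t.samples, toy_cmap(t))
        assert got["value"].iloc[0] < -1.0


# ---------------------------------------------------------------------------
# windows + summaries
# ---------------------------------------------------------------------------

class TestWindowsAndSummary:
    def test_windows_tile_contig_with_partial_last(self):
        cmap = toy_cmap(toy_table([[[0, 0]]], contig_length=120_000))
        w = make_windows({"chr1": 120_000}, cmap)
        assert w[["start", "end"]].values.tolist() == [
            [0, 50_000], [50_000, 100_000], [100_000, 120_000]
        ]

    def test_mt_single_window(self):
        t = toy_table([[[0, "-"]]], contig="mt", contig_length=16_000,
                      compartment="mt")
        w = make_windows({"mt": 16_000}, toy_cmap(t, "mt"))
        assert len(w) == 1 and w["end"].iloc[0] == 16_000

    def test_summary_mean_se_oracle(self):
        stats = pd.DataFrame(
            {
                "contig": ["chr1"] * 3,
                "start": [0, 50_000, 100_000],
                "end": [50_000, 100_000, 150_000],
                "compartment": ["autosome"] * 3,
                "n_sites": [20_000] * 3,
                "value": [1.0, 2.0, 6.0],
                "qualifies": [True] * 3,
                "statistic": ["pi"] * 3,
            }
        )
        s = compartment_summary(stats)
        row = s[s["compartment"] == "autosome"].iloc[0]
        vals = np.array([1.0, 2.0, 6.0])
        assert row["mean"] == pytest.approx(3.0)
        assert row["se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(3))

    def test_constant_windows_zero_se(self):
        stats = pd.DataFrame(
            {
                "contig": ["chr1"] * 4, "start": range(4), "end": range(1, 5),
                "compartment": ["Z"] * 4, "n_sites": [20_000] * 4,
                "value": [0.5] * 4, "qualifies": [True] * 4, "statistic": ["pi"] * 4,
            }
        )
        s = compartment_summary(stats)
        assert s["se"].iloc[0] == pytest.approx(0.0)

    def test_nonqualifying_window_excluded_from_mean(self):
        stats = pd.DataFrame(
            {
                "contig": ["chr1"] * 2, "start": [0, 1], "end": [1, 2],
                "compartment": ["autosome"] * 2, "n_sites": [20_000, 9_999],
                "value": [1.0, 100.0], "qualifies": [True, False],
                "statistic": ["pi"] * 2,
            }
        )
        s = compartment_summary(stats)
        assert s[s["compartment"] == "autosome"]["mean"].iloc[0] == 1.0
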