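"""Private alleles, fixed differences, diagnostic panels, genotype recoding.

The discovery scans are checked against exhaustive per-site brute-force
reimplementations written independently of the vectorized code paths.
"""

import numpy as np
import pytest

from hylin import (
    MISSING,
    diagnostic_panel,
    fixed_differences,
    private_alleles,
    recode_genotypes,
    thin_by_distance,
)

from conftest import make_matrix


def random_group_matrix(seed, n_sites=200, missing=0.0):
    rng = np.random.default_rng(seed)
    groups = ["hybrid"] * 6 + ["parentalA"] * 5 + ["parentalB"] * 5 + ["outgroup"] * 4
    # skewed frequencies so private/fixed configurations actually occur
    p = rng.beta(0.3, 0.3, size=(len(groups), n_sites))
    G = rng.binomial(2, p).astype(np.int8)
    if missing:
        G[rng.random(G.shape) < missing] = MISSING
    return make_matrix(G, groups=groups)


# ----------------------------------------------------------------------
# independent brute-force oracles


def brute_private(matrix, focal, others, min_freq):
    hits = []
    fidx = [i for i, g in enumerate(matrix.groups) if g == focal]
    oidx = {g: [i for i, gg in enumerate(matrix.groups) if gg == g] for g in others}
    for j in range(matrix.n_sites):
        counts = {}
        skip = False
        for name, idx in [("focal", fidx)] + list(oidx.items()):
            alleles = [matrix.G[i, j] for i in idx if matrix.G[i, j] != MISSING]
            if not alleles:
                skip = True
                break
            counts[name] = (sum(alleles), 2 * len(alleles))
        if skip:
            continue
        for allele in ("alt", "ref"):
            num, den = counts["focal"]
            f = num / den if allele == "alt" else 1 - num / den
            if not (min_freq <= f < 1.0):
                continue
            absent = all(
                (num_o == 0 if allele == "alt" else num_o == den_o)
                for num_o, den_o in (counts[g] for g in others)
            )
            if absent:
                hits.append((matrix.chrom[j], matrix.pos[j], allele))
    return hits


def brute_fixed(matrix, groupA, groupB):
    hits = []
    ia = [i for i, g in enumerate(matrix.groups) if g == groupA]
    ib = [i for i, g in enumerate(matrix.groups) if g == groupB]
    for j in range(matrix.n_sites):
        ga = [matrix.G[i, j] for i in ia if matrix.G[i, j] != MISSING]
        gb = [matrix.G[i, j] for i in ib if matrix.G[i, j] != MISSING]
        if not ga or not gb:
            continue
        fa, fb = sum(ga) / (2 * len(ga)), sum(gb) / (2 * len(gb))
        if (fa, fb) in ((1.0, 0.0), (0.0, 1.0)):
            hits.append((matrix.chrom[j], matrix.pos[j]))
    return hits


# ----------------------------------------------------------------------


class TestPrivateAlleles:
    def test_reported_when_private_and_high_frequency(self):
        G = np.array(
            [[1, 1], [2, 1], [1, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0]],
            dtype=np.int8,
        )
        m = make_matrix(
            G, groups=["hybrid"] * 3 + ["parentalA"] * 3 + ["parentalB"] * 2
        )
        # site 1: hybrid alt freq 4/6 = 0.67, absent elsewhere -> private
        # site 2: freq 2/6 = 0.33 < 0.5 -> not reported
        df = private_alleles(m, "hybrid", ["parentalA", "parentalB"], 0.5)
        assert list(df["pos"]) == [100]
        assert df["focal_freq"].iloc[0] == pytest.approx(4 / 6)

    def test_single_copy_elsewhere_disqualifies(self):
        """'Not detected in any other species' is strict: one copy kills it."""
        G = np.array([[1, 1], [1, 1], [1, 1], [0, 1], [0, 0]], dtype=np.int8)
        m = make_matrix(G, groups=["hybrid"] * 3 + ["parentalA"] * 2)
        df = private_alleles(m, "hybrid", ["parentalA"], 0.5)
        assert list(df["pos"]) == [100]

    def test_focal_must_be_polymorphic(self):
        G = np.array([[2, 1], [2, 1], [0, 0]], dtype=np.int8)
        m = make_matrix(G, groups=["hybrid", "hybrid", "parentalA"])
        df = private_alleles(m, "hybrid", ["parentalA"], 0.5)
        assert list(df["pos"]) == [200]  # fixed site (freq 1.0) excluded

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_scan(self, seed):
        m = random_group_matrix(seed)
        df = private_alleles(m, "hybrid", ["parentalA", "parentalB", "outgroup"], 0.5)
        got = list(zip(df["chrom"], df["pos"], df["private_allele"]))
        assert got == brute_private(
            m, "hybrid", ["parentalA", "parentalB", "outgroup"], 0.5
        )

    def test_sites_without_group_data_skipped_and_counted(self):
        G = np.array([[1, 1], [0, 1], [MISSING, 0]], dtype=np.int8)
        m = make_matrix(G, groups=["hybrid", "hybrid", "parentalA"])
        df = private_alleles(m, "hybrid", ["parentalA"], 0.5)
        assert df.attrs["skipped_nodata"] == 1
        assert list(df["pos"]) == [200]

    def test_invariant_to_sample_order_and_monomorphic_padding(self):
        m = random_group_matrix(3)
        df0 = private_alleles(m, "hybrid", ["parentalA"], 0.5)
        perm = np.random.default_rng(0).permutation(m.n_samples)
        df1 = private_alleles(m.take_samples(perm), "hybrid", ["parentalA"], 0.5)
        assert set(zip(df0["pos"], df0["private_allele"])) == set(
            zip(df1["pos"], df1["private_allele"])
        )
        # appending monomorphic sites changes nothing
        pad = make_matrix(np.zeros((m.n_samples, 5), np.int8),
                          pos=m.pos.max() + 100 * np.arange(1, 6),
                          groups=m.groups)
        import numpy as _np
        from hylin import GenotypeMatrix
        m2 = GenotypeMatrix(
            samples=m.samples, groups=m.groups,
            chrom=_np.concatenate([m.chrom, pad.chrom]),
            pos=_np.concatenate([m.pos, pad.pos]),
            ref=_np.concatenate([m.ref, pad.ref]),
            alt=_np.concatenate([m.alt, pad.alt]),
            G=_np.concatenate([m.G, pad.G], axis=1),
        )
        df2 = private_alleles(m2, "hybrid", ["parentalA"], 0.5)
        assert len(df2) == len(df0)

    def test_carrier_criterion_mode(self):
        # 2 of 4 hybrids carry the allele (freq 0.25 but carrier fraction 0.5)
        G = np.array([[1, 0], [1, 0], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
        m = make_matrix(G, groups=["hybrid"] * 4 + ["parentalA"])
        assert len(private_alleles(m, "hybrid", ["parentalA"], 0.5, "freq")) == 0
        df = private_alleles(m, "hybrid", ["parentalA"], 0.5, "carrier")
        assert list(df["pos"]) == [100]


class TestFixedDifferences:
    def test_definition_and_near_fixed_excluded(self):
        # site 1: A fixed alt, B fixed ref -> included
        # site 2: A freq 0.9, B 0 -> excluded (not fully fixed)
        G = np.array(
            [[2, 2], [2, 2], [2, 2], [2, 2], [2, 1], [0, 0], [0, 0]], dtype=np.int8
        )
        m = make_matrix(G, groups=["parentalA"] * 5 + ["parentalB"] * 2)
        df = fixed_differences(m, "parentalA", "parentalB")
        assert list(df["pos"]) == [100]
        assert bool(df["a_is_alt"].iloc[0]) is True

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_brute_force_scan(self, seed):
        m = random_group_matrix(seed)
        df = fixed_differences(m, "parentalA", "parentalB")
        assert list(zip(df["chrom"], df["pos"])) == brute_fixed(
            m, "parentalA", "parentalB"
        )

    def test_group_swap_same_sites_opposite_orientation(self):
        m = random_group_matrix(6)
        d1 = fixed_differences(m, "parentalA", "parentalB")
        d2 = fixed_differences(m, "parentalB", "parentalA")
        assert list(d1["pos"]) == list(d2["pos"])
        assert (d1["a_is_alt"].to_numpy() == ~d2["a_is_alt"].to_numpy()).all()

    def test_count_grows_with_divergence_time(self):
        """Deeper parental splits accumulate more fixed differences."""
        from hylin import SimConfig, simulate

        counts = []
        for tau in (20, 400):
            cfg = SimConfig(
                n_chromosomes=10, chrom_length=1_000_000, n_loci=2000,
                # large ancestral size keeps the stem polymorphic so the
                # parental branches can fix for alternative alleles
                ne_ancestral=10_000, ne_parentalA=50, ne_parentalB=50,
                ne_hybrid=50, tau_split=tau, tau_hybrid=1,
                sample_sizes={"parentalA": 8, "parentalB": 8},
                seed=tau,
            )
            m = simulate(cfg).matrix
            counts.append(len(fixed_differences(m, "parentalA", "parentalB")))
        assert counts[1] > counts[0]

    def test_empty_group_rejected(self):
        m = make_matrix(np.zeros((2, 2), np.int8), groups=["parentalA"] * 2)
        with pytest.raises(ValueError):
            fixed_differences(m, "parentalA", "parentalB")


class TestDiagnosticPanel:
    def _two_site_matrix(self, fa2=0.10):
        """Site 1 passes 95/5; site 2's parental-B frequency is fa2."""
        rng = np.random.default_rng(9)
        nA = nB = 20
        G = np.zeros((nA + nB, 2), dtype=np.int8)
        G[:nA, 0] = 2; G[0, 0] = 1          # freq in A: 39/40 = 0.975
        G[nA:, 0] = 0; G[nA, 0] = 1         # freq in B: 1/40 = 0.025
        G[:nA, 1] = 2                        # freq in A: 1.0
        G[nA:, 1] = rng.binomial(2, fa2, nB)
        return make_matrix(G, groups=["parentalA"] * nA + ["parentalB"] * nB)

    def test_frequency_contrast_and_orientation(self):
        m = self._two_site_matrix(fa2=0.25)
        panel = diagnostic_panel(m, "parentalA", "parentalB", thin_bp=0)
        assert list(panel.pos) == [100]
        assert panel.a_is_alt[0]
        assert panel.freqA[0] == pytest.approx(0.975)
        assert panel.freqB[0] == pytest.approx(0.025)

    def test_degenerate_thresholds_equal_fixed_differences(self):
        m = random_group_matrix(7)
        panel = diagnostic_panel(m, "parentalA", "parentalB", hi=1.0, lo=0.0, thin_bp=0)
        fd = fixed_differences(m, "parentalA", "parentalB")
        assert list(panel.pos) == list(fd["pos"])

    def test_thinning_applied(self):
        rng = np.random.default_rng(1)
        n = 30
        G = np.concatenate(
            [np.full((5, n), 2, np.int8), np.zeros((5, n), np.int8)]
        )
        m = make_matrix(
            G, pos=np.arange(1, n + 1) * 10_000,
            groups=["parentalA"] * 5 + ["parentalB"] * 5,
        )
        panel = diagnostic_panel(m, "parentalA", "parentalB", thin_bp=50_000)
        reference = thin_by_distance(m, 50_000)
        assert list(panel.pos) == list(reference.pos)

    def test_empty_panel_warns(self, caplog):
        m = make_matrix(
            np.array([[1, 1], [1, 1]], np.int8), groups=["parentalA", "parentalB"]
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="hylin.markers"):
            panel = diagnostic_panel(m, "parentalA", "parentalB")
        assert panel.n_sites == 0
        assert any("no qualifying" in r.message for r in caplog.records)

    def test_hi_le_lo_rejected(self):
        m = random_group_matrix(8)
        with pytest.raises(ValueError):
            diagnostic_panel(m, "parentalA", "parentalB", hi=0.4, lo=0.5)


class TestRecode:
    def test_codes_count_non_parentalA_alleles(self, f1_scenario):
        matrix, individuals, freqs = f1_scenario
        panel = diagnostic_panel(matrix, "parentalA", "parentalB", thin_bp=0)
        coded = recode_genotypes(matrix, panel)
        iA = matrix.sample_indices("parentalA")
        iB = matrix.sample_indices("parentalB")
        assert (coded[iA] == 0).all()  # homozygous parental A -> 0
        assert (coded[iB] == 2).all()
        f1_rows = [i for i, s in enumerate(matrix.samples) if s.startswith("F1_")]
        assert (coded[f1_rows] == 1).all()  # heterozygotes -> 1

    def test_swapping_parents_maps_codes_0_2(self):
        G = np.array([[0, 1, 2, MISSING]], dtype=np.int8).T.reshape(1, 4)
        m = make_matrix(np.vstack([G, np.full((3, 4), 2, np.int8),
                                   np.zeros((3, 4), np.int8)]),
                        groups=["hybrid"] + ["parentalA"] * 3 + ["parentalB"] * 3)
        pAB = diagnostic_panel(m, "parentalA", "parentalB", thin_bp=0)
        pBA = diagnostic_panel(m, "parentalB", "parentalA", thin_bp=0)
        cAB = recode_genotypes(m, pAB)[0]
        cBA = recode_genotypes(m, pBA)[0]
        swap = {0: 2, 1: 1, 2: 0, MISSING: MISSING}
        assert [swap[int(x)] for x in cAB] == [int(x) for x in cBA]

    def test_panel_site_absent_from_matrix_rejected(self):
        m = make_matrix(np.zeros((2, 2), np.int8),
                        groups=["parentalA", "parentalB"])
        from hylin.markers import DiagnosticPanel

        panel = DiagnosticPanel(
            chrom=np.array(["chr9"], object), pos=np.array([123]),
            a_is_alt=np.array([True]), freqA=np.array([1.0]), freqB=np.array([0.0]),
        )
        with pytest.raises(KeyError):
            recode_genotypes(m, panel)
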