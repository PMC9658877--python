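import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_block_fractions, brute_components
from oligoscan.confidence import (AnalysisConfig, PaeMatrix, block_fractions,
                                  classify_reliability, infer_substoichiometry,
                                  read_pae)
from oligoscan.errors import DomainMapError, PaeDialectError, PaeFormatError
from oligoscan.structure_io import DomainMap, DomainSpan

SEG2 = [("A", 30), ("B", 30)]
DM30 = DomainMap([DomainSpan("BTB", 1, 12), DomainSpan("hinge", 13, 15),
                  DomainSpan("CTD", 16, 30)])


def _matrix(seg, fill):
    L = sum(n for _, n in seg)
    return PaeMatrix(np.full((L, L), float(fill)), seg)


class TestReadPae:
    def test_nested_dialect(self, tmp_path):
        data = [[0.5, 2, 7], [2, 0.5, 3], [7, 3, 0.5]]
        path = tmp_path / "pae.json"
        path.write_text(json.dumps({"predicted_aligned_error": data}))
        pae = read_pae(path)
        assert pae.values.shape == (3, 3)
        assert pae.values[0, 2] == 7.0

    def test_dialects_agree(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = np.round(rng.uniform(0, 20, (4, 4)), 3)
        np.fill_diagonal(mat, 0.5)
        p1 = tmp_path / "nested.json"
        p1.write_text(json.dumps({"pae": mat.tolist()}))
        r1, r2 = np.indices((4, 4))
        p2 = tmp_path / "flat.json"
        p2.write_text(json.dumps({"residue1": (r1 + 1).ravel().tolist(),
                                  "residue2": (r2 + 1).ravel().tolist(),
                                  "distance": mat.ravel().tolist()}))
        assert np.array_equal(read_pae(p1).values, read_pae(p2).values)

    def test_nonsquare_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"pae": [[1, 2, 3, 4]] * 3}))
        with pytest.raises(PaeFormatError):
            read_pae(path)

    def test_unknown_keys_listed(self, tmp_path):
        path = tmp_path / "odd.json"
        path.write_text(json.dumps({"plddt": [1, 2, 3]}))
        with pytest.raises(PaeDialectError, match="plddt"):
            read_pae(path)

    def test_dialect_warning_on_large_diagonal(self):
        with pytest.warns(UserWarning, match="diagonal"):
            pae = PaeMatrix(np.full((4, 4), 9.0), [("A", 4)])
        assert pae.dialect_warning


class TestBlockFractions:
    def test_all_zero_gives_100(self, default_config):
        blocks = block_fractions(_matrix(SEG2, 0.0), DM30, default_config)
        assert all(v.fraction_below == 100.0 for v in blocks.classes.values())

    def test_all_twenty_gives_0(self, default_config):
        blocks = block_fractions(_matrix(SEG2, 20.0), DM30, default_config)
        assert all(v.fraction_below == 0.0 for v in blocks.classes.values())

    def test_exact_threshold_not_below(self, default_config):
        # entries exactly at the cutoff are NOT counted (strict inequality)
        blocks = block_fractions(_matrix(SEG2, 10.0), DM30, default_config)
        assert all(v.fraction_below == 0.0 for v in blocks.classes.values())

    @pytest.mark.parametrize("symmetrization", ["mean", "min", "ordered"])
    @pytest.mark.parametrize("adjacency", ["cyclic", "all_pairs"])
    def test_matches_bruteforce(self, symmetrization, adjacency):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 25, (60, 60))
        np.fill_diagonal(values, 0.5)
        pae = PaeMatrix(values, SEG2)
        config = AnalysisConfig(adjacency=adjacency,
                                pair_symmetrization=symmetrization)
        got = block_fractions(pae, DM30, config)
        expected = brute_block_fractions(values, SEG2, DM30, config)
        assert set(got.classes) == set(expected)
        for cls, (count, frac) in expected.items():
            assert got.classes[cls].pair_count == count
            assert got.classes[cls].fraction_below == pytest.approx(frac, abs=1e-12)

    def test_five_chain_cyclic_matches_bruteforce(self):
        seg = [(c, 20) for c in "ABCDE"]
        dm = DomainMap([DomainSpan("BTB", 1, 8), DomainSpan("CTD", 11, 20)])
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 25, (100, 100))
        np.fill_diagonal(values, 0.5)
        pae = PaeMatrix(values, seg)
        config = AnalysisConfig()
        got = block_fractions(pae, dm, config)
        expected = brute_block_fractions(values, seg, dm, config)
        for cls, (count, frac) in expected.items():
            assert got.classes[cls].pair_count == count
            assert got.classes[cls].fraction_below == pytest.approx(frac, abs=1e-12)

    def test_missing_domains_error(self, default_config):
        dm = DomainMap([DomainSpan("hinge", 1, 30)])
        with pytest.raises(DomainMapError):
            block_fractions(_matrix(SEG2, 1.0), dm, default_config)

    def test_chain_permutation_invariance(self, default_config):
        rng = np.random.default_rng(3)
        seg = [(c, 30) for c in "ABC"]
        values = rng.uniform(0, 25, (90, 90))
        pae = PaeMatrix(values, seg)
        got = block_fractions(pae, DM30, default_config)
        # simultaneously permute whole chain blocks (B, C, A) and relabel
        perm = np.r_[np.arange(30, 60), np.arange(60, 90), np.arange(0, 30)]
        pae2 = PaeMatrix(values[np.ix_(perm, perm)], seg)
        got2 = block_fractions(pae2, DM30, default_config)
        for cls in got.classes:
            assert got.classes[cls].fraction_below == pytest.approx(
                got2.classes[cls].fraction_below, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.floats(5.0, 15.0), st.floats(0.1, 10.0))
    def test_threshold_monotonicity(self, seed, thr, delta):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 25, (20, 20))
        pae = PaeMatrix(values, [("A", 10), ("B", 10)])
        dm = DomainMap([DomainSpan("BTB", 1, 5), DomainSpan("CTD", 6, 10)])
        low = block_fractions(pae, dm, AnalysisConfig(pae_threshold=thr))
        high = block_fractions(pae, dm, AnalysisConfig(pae_threshold=thr + delta))
        for cls in low.classes:
            assert high.classes[cls].fraction_below >= low.classes[cls].fraction_below


class TestClassifyReliability:
    def _blocks(self, **fracs):
        from oligoscan.confidence import BlockStat, BlockStatistics
        return BlockStatistics(classes={k.replace("_", "-"): BlockStat(10, v)
                                        for k, v in fracs.items()})

    def test_all_100_is_reliable(self, default_config):
        rep = classify_reliability(
            self._blocks(**{"intra-BTB": 100, "intra-CTD": 100,
                            "inter-BTB": 100, "inter-CTD": 100}), default_config)
        assert (rep.stability, rep.grade) == ("S", "R")

    def test_exact_65_not_reliable(self, default_config):
        # "higher than" is strict: a block at exactly 65.0% cannot be R
        rep = classify_reliability(
            self._blocks(**{"intra-BTB": 90, "intra-CTD": 90,
                            "inter-BTB": 65.0, "inter-CTD": 90}), default_config)
        assert rep.grade == "PR"

    def test_low_inter_is_unstable(self, default_config):
        rep = classify_reliability(
            self._blocks(**{"intra-BTB": 90, "intra-CTD": 90,
                            "inter-BTB": 90, "inter-CTD": 20}), default_config)
        assert (rep.stability, rep.grade) == ("U", "U")

    def test_r_implies_s(self, default_config):
        rep = classify_reliability(
            self._blocks(**{"intra-BTB": 80, "inter-BTB": 70}), default_config)
        assert rep.grade == "R" and rep.stability == "S"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=4, max_size=4),
           st.lists(st.floats(0, 20), min_size=4, max_size=4))
    def test_grade_monotone_under_increase(self, fracs, bumps):
        config = AnalysisConfig()
        names = ["intra-BTB", "intra-CTD", "inter-BTB", "inter-CTD"]
        rank = {"U": 0, "PR": 1, "R": 2}
        base = classify_reliability(
            self._blocks(**dict(zip(names, fracs))), config)
        bumped_fracs = [min(100.0, f + b) for f, b in zip(fracs, bumps)]
        bumped = classify_reliability(
            self._blocks(**dict(zip(names, bumped_fracs))), config)
        assert rank[bumped.grade] >= rank[base.grade]


class TestSubstoichiometry:
    def _pae(self, pattern, n=5, per_chain=10):
        """pattern: set of frozenset chain-id pairs that get low error."""
        seg = [(chr(65 + k), per_chain) for k in range(n)]
        L = n * per_chain
        values = np.full((L, L), 25.0)
        for a in range(n):
            sa = slice(a * per_chain, (a + 1) * per_chain)
            values[sa, sa] = 2.0
            for b in range(n):
                if a != b and frozenset((chr(65 + a), chr(65 + b))) in pattern:
                    sb = slice(b * per_chain, (b + 1) * per_chain)
                    values[sa, sb] = 2.0
        np.fill_diagonal(values, 0.5)
        return PaeMatrix(values, seg)

    def test_all_low_is_single_pentamer(self, default_config):
        import itertools
        pattern = {frozenset(p) for p in itertools.combinations("ABCDE", 2)}
        result = infer_substoichiometry(self._pae(pattern), default_config)
        assert result.components == [list("ABCDE")]
        assert result.label == "pentamer"

    def test_two_dimers_detected(self, default_config):
        pattern = {frozenset("AB"), frozenset("CD")}
        result = infer_substoichiometry(self._pae(pattern), default_config)
        assert result.components == [["A", "B"], ["C", "D"], ["E"]]
        assert result.label == "dimer propensity"

    def test_single_chain_rejected(self, default_config):
        pae = PaeMatrix(np.full((5, 5), 1.0), [("A", 5)])
        with pytest.raises(PaeFormatError):
            infer_substoichiometry(pae, default_config)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed, default_config):
        rng = np.random.default_rng(seed)
        seg = [(c, 10) for c in "ABCDE"]
        # random block pattern: each chain pair low or high error
        values = np.full((50, 50), 25.0)
        for a in range(5):
            for b in range(a + 1, 5):
                if rng.random() < 0.5:
                    values[a * 10:(a + 1) * 10, b * 10:(b + 1) * 10] = 2.0
                    values[b * 10:(b + 1) * 10, a * 10:(a + 1) * 10] = 2.0
        np.fill_diagonal(values, 0.5)
        pae = PaeMatrix(values, seg)
        got = infer_substoichiometry(pae, default_config)
        assert got.components == brute_components(values, seg, default_config)


class TestRecovery:
    @pytest.mark.parametrize("inter,expected", [(25.0, "U"), (6.0, "R")])
    def test_regime_recovery(self, inter, expected, default_config):
        from oligoscan.synthetic_data import make_pae
        dm = DomainMap([DomainSpan("BTB", 1, 12), DomainSpan("CTD", 16, 30)])
        means = {"intra-BTB": 4.0, "intra-CTD": 4.0,
                 "inter-BTB": inter, "inter-CTD": inter,
                 "cross-domain": 4.0, "other": 15.0, "nonadjacent": 20.0}
        pae = make_pae([(c, 30) for c in "ABCDE"], dm, means, pae_noise=1.0, seed=9)
        rep = classify_reliability(block_fractions(pae, dm, default_config),
                                   default_config)
        assert rep.grade == expected
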