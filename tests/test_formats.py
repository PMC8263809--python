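import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import prstools as pt
from prstools.formats import FormatError, read_effects, write_effects
from prstools.model import PrsModel


def _write_manual_plink(tmp_path, bed_payload, n, bim_rows, name="manual"):
    prefix = tmp_path / name
    (prefix.with_suffix(".bed")).write_bytes(
        bytes([0x6C, 0x1B, 0x01]) + bed_payload
    )
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in bim_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            fh.write(f"F{i} I{i} 0 0 0 -9\n")
    return prefix


class TestPlink:
    def test_two_bit_decoding_matches_published_table(self, tmp_path):
        """Byte 0b11_10_01_00 decodes to (hom A1, missing, het, hom A2)."""
        prefix = _write_manual_plink(
            tmp_path, bytes([0b11_10_01_00]), n=4,
            bim_rows=[(1, "rs1", 0.0, 100, "A", "G")],
        )
        _, G, _ = pt.read_plink(prefix)
        got = G.dosages[:, 0]
        assert got[0] == 2.0       # hom A1
        assert np.isnan(got[1])    # missing
        assert got[2] == 1.0       # het
        assert got[3] == 0.0       # hom A2

    def test_round_trip_reproduces_dosages_exactly(self, tmp_path):
        rng = np.random.default_rng(3)
        n, m = 17, 9
        dos = rng.integers(0, 3, size=(n, m)).astype(float)
        dos[rng.random((n, m)) < 0.1] = np.nan
        dos[:, 0] = [0, 1] * (n // 2) + [0]  # keep polymorphic
        panel = pt.SnpPanel(
            snp_id=[f"rs{j}" for j in range(m)],
            chromosome=np.ones(m, int),
            bp_position=np.arange(1, m + 1) * 1000,
            cm_position=np.zeros(m),
            allele1=["A"] * m, allele2=["G"] * m,
            maf=np.full(m, 0.3),
        )
        prefix = tmp_path / "rt"
        pt.write_plink(prefix, panel, pt.GenotypeMatrix(dos))
        panel2, G2, fam = pt.read_plink(prefix)
        np.testing.assert_array_equal(
            np.isnan(dos), np.isnan(G2.dosages)
        )
        np.testing.assert_array_equal(
            dos[~np.isnan(dos)], G2.dosages[~np.isnan(G2.dosages)]
        )
        assert list(panel2.snp_id) == list(panel.snp_id)

    def test_all_zero_cm_column_falls_back_to_bp_over_1mb(self, tmp_path):
        prefix = _write_manual_plink(
            tmp_path, bytes([0b0011_0010]), n=3,
            bim_rows=[(1, "rs1", 0.0, 2_000_000, "A", "G")],
        )
        panel, _, _ = pt.read_plink(prefix)
        assert panel.cm_position[0] == pytest.approx(2.0)

    def test_bad_magic_bytes_rejected(self, tmp_path):
        prefix = _write_manual_plink(
            tmp_path, bytes([0]), n=3,
            bim_rows=[(1, "rs1", 0.0, 100, "A", "G")],
        )
        (prefix.with_suffix(".bed")).write_bytes(b"\x00\x00\x00\x00")
        with pytest.raises(FormatError, match="magic"):
            pt.read_plink(prefix)

    def test_inconsistent_row_counts_rejected(self, tmp_path):
        prefix = _write_manual_plink(
            tmp_path, bytes([0b0010, 0b0010]), n=3,  # 2 SNPs worth of bytes
            bim_rows=[(1, "rs1", 0.0, 100, "A", "G")],
        )
        with pytest.raises(FormatError, match="payload"):
            pt.read_plink(prefix)


class TestStandardize:
    def test_explicit_column_zero_one_two(self):
        G = pt.GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]))
        X = G.standardized()
        expect = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(X[:, 0], expect, atol=1e-12)
        assert abs(X[:, 0].mean()) < 1e-10
        assert abs(X[:, 0].var() - 1.0) < 1e-8

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 4))
        G1 = pt.standardize(pt.GenotypeMatrix(X))
        G2 = pt.standardize(G1)
        np.testing.assert_allclose(G1.dosages, G2.dosages, atol=1e-12)

    def test_missing_imputed_to_observed_column_mean(self):
        G = pt.GenotypeMatrix(np.array([[0.0], [2.0], [np.nan]]))
        X = G.standardized()
        dev = np.array([-1.0, 1.0, 0.0])
        np.testing.assert_allclose(X[:, 0], dev / dev.std(), atol=1e-12)

    def test_monomorphic_column_error_names_the_snp(self):
        G = pt.GenotypeMatrix(
            np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]),
            snp_ids=np.array(["rsBAD", "rsOK"], dtype=object),
        )
        with pytest.raises(ValueError, match="rsBAD"):
            G.standardized()


class TestHarmonize:
    def _panel(self, a1, a2):
        m = len(a1)
        return pt.SnpPanel(
            snp_id=[f"rs{j}" for j in range(m)],
            chromosome=np.ones(m, int),
            bp_position=np.arange(1, m + 1) * 1000,
            cm_position=np.arange(m, dtype=float),
            allele1=a1, allele2=a2, maf=np.full(m, 0.3),
        )

    def _ss(self, a1, a2, r):
        m = len(a1)
        return pt.SummaryStats.from_r(
            [f"rs{j}" for j in range(m)], a1, a2,
            np.full(m, 100), np.asarray(r, float),
        )

    def test_swapped_alleles_flip_the_sign(self):
        panel = self._panel(["G"], ["A"])
        out = pt.harmonize(self._ss(["A"], ["G"], [0.1]), panel)
        assert out.r[0] == pytest.approx(-0.1)
        assert out.allele1[0] == "G"

    def test_strand_flip_resolved_via_complement(self):
        panel = self._panel(["T"], ["C"])
        out = pt.harmonize(self._ss(["A"], ["G"], [0.1]), panel)
        assert out.r[0] == pytest.approx(0.1)

    def test_ambiguous_pairs_dropped_when_requested(self):
        panel = self._panel(["A", "C"], ["T", "A"])
        ss = self._ss(["A", "C"], ["T", "A"], [0.1, 0.2])
        out = pt.harmonize(ss, panel, drop_ambiguous=True)
        assert list(out.snp_id) == ["rs1"]  # the A/T SNP is dropped
        kept = pt.harmonize(ss, panel, drop_ambiguous=False)
        assert kept.m == 2

    def test_identity_and_idempotence(self):
        panel = self._panel(["A", "C"], ["G", "G"])
        ss = self._ss(["A", "C"], ["G", "G"], [0.1, -0.2])
        once = pt.harmonize(ss, panel)
        twice = pt.harmonize(once, panel)
        np.testing.assert_allclose(once.r, ss.r)
        np.testing.assert_allclose(once.r, twice.r)

    def test_irreconcilable_alleles_dropped(self):
        panel = self._panel(["A", "C"], ["G", "G"])
        ss = self._ss(["A", "C"], ["C", "G"], [0.1, 0.2])  # first mismatched
        out = pt.harmonize(ss, panel)
        assert list(out.snp_id) == ["rs1"]


class TestSumstatsIO:
    def test_round_trip_preserves_all_fields(self, tmp_path, toy_sim):
        ss = toy_sim["ss"]
        path = tmp_path / "ss.txt"
        pt.write_sumstats(ss, path)
        back = pt.read_sumstats(path)
        np.testing.assert_allclose(back.r, ss.r, rtol=1e-12)
        np.testing.assert_allclose(back.stat, ss.stat, rtol=1e-12)
        np.testing.assert_array_equal(back.n, ss.n)

    def test_stat_from_correlation_hand_value(self):
        ss = pt.SummaryStats.from_r(["rs1"], ["A"], ["G"], [100], [0.1])
        assert ss.stat[0] == pytest.approx(100 * 0.01 / 0.99, rel=1e-12)
        assert ss.stat[0] == pytest.approx(1.010101, abs=1e-6)

    def test_zero_stat_gives_zero_correlation(self):
        ss = pt.SummaryStats.from_stat(["rs1"], ["A"], ["G"], [100], [0.0])
        assert ss.r[0] == 0.0

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        pd.DataFrame({"Predictor": ["rs1"], "A1": ["A"]}).to_csv(
            path, sep=" ", index=False
        )
        with pytest.raises(FormatError, match="missing columns"):
            pt.read_sumstats(path)

    def test_sample_size_of_one_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            pt.SummaryStats.from_r(["rs1"], ["A"], ["G"], [1], [0.1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=-0.999, max_value=0.999),
           st.integers(min_value=2, max_value=10**6))
    def test_stat_correlation_bijection(self, r, n):
        """S = n r^2/(1-r^2) and r = sign * sqrt(S/(n+S)) invert each other."""
        s = n * r**2 / (1 - r**2)
        back = np.sign(r) * np.sqrt(s / (n + s)) if s > 0 else 0.0
        assert back == pytest.approx(r, abs=1e-12)


class TestEffectsIO:
    def _model(self, beta, sd):
        m = len(beta)
        return PrsModel(
            snp_id=np.array([f"rs{j}" for j in range(m)], dtype=object),
            allele1=np.array(["A"] * m, dtype=object),
            allele2=np.array(["G"] * m, dtype=object),
            beta=np.asarray(beta, float),
            centre=np.full(m, 0.5), sd=np.asarray(sd, float),
        )

    def test_raw_effect_is_standardized_over_sd(self, tmp_path):
        model = self._model([0.5], [0.7])
        path = tmp_path / "eff.txt"
        write_effects(model, path)
        back = read_effects(path)
        assert back.beta[0] / back.sd[0] == pytest.approx(0.714286, abs=1e-6)

    def test_round_trip_is_bitwise_stable(self, tmp_path):
        rng = np.random.default_rng(8)
        model = self._model(rng.standard_normal(1000),
                            rng.uniform(0.3, 1.0, 1000))
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_effects(model, p1)
        write_effects(read_effects(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_zero_model_round_trip(self, tmp_path):
        model = self._model([0.0, 0.0], [0.5, 0.5])
        path = tmp_path / "zero.txt"
        write_effects(model, path)
        back = read_effects(path)
        np.testing.assert_array_equal(back.beta, 0.0)

    def test_duplicate_snp_ids_rejected(self, tmp_path):
        model = self._model([0.1, 0.2], [0.5, 0.5])
        model.snp_id = np.array(["rs1", "rs1"], dtype=object)
        with pytest.raises(ValueError, match="duplicate"):
            write_effects(model, tmp_path / "dup.txt")
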