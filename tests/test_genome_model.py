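import numpy as np
import pytest

from clonephy.genome_model import (
    CNV,
    InputError,
    Locus,
    SSM,
    associate_ssms_to_cnvs,
    cnv_to_pseudo_ssm,
    default_support_depth,
    load_cnv_table,
    load_ssm_table,
    write_cnv_table,
    write_ssm_table,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadSSMTable:
    def test_single_sample_row(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\td\ns0\t23\t47\n")
        (ssm,) = load_ssm_table(path)
        assert ssm.id == "s0"
        assert ssm.a.tolist() == [23] and ssm.d.tolist() == [47]
        assert ssm.mu_v == 0.5 and ssm.mu_r == 1 - ssm.epsilon

    def test_multi_sample_row(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\td\ns0\t35,12\t69,50\n")
        (ssm,) = load_ssm_table(path)
        assert ssm.n_samples == 2
        assert ssm.a.tolist() == [35, 12] and ssm.d.tolist() == [69, 50]

    def test_a_exceeding_d_rejected(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\td\ns0\t50\t40\n")
        with pytest.raises(InputError, match="exceeds d"):
            load_ssm_table(path)

    def test_inconsistent_sample_count_rejected(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\td\ns0\t1\t2\ns1\t1,1\t2,2\n")
        with pytest.raises(InputError, match="inconsistent sample count"):
            load_ssm_table(path)

    def test_malformed_counts_name_the_row(self, tmp_path):
        path = _write(tmp_path, "s.tsv", "id\ta\td\ns0\t1\t2\nsX\tfoo\t2\n")
        with pytest.raises(InputError, match="sX"):
            load_ssm_table(path)


class TestLoadCNVTable:
    HEADER = "id\tchrom\tstart\tend\tC\tCm\tCp\tphi\tsupport_depth\n"

    def test_total_loss_infers_breakdown(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.HEADER + "c0\t1\t0\t100\t0\t\t\t0.5\t60\n")
        (cnv,) = load_cnv_table(path)
        assert (cnv.Cm, cnv.Cp) == (0, 0) and not cnv.phased

    def test_single_copy_loss_unphased_convention(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.HEADER + "c0\t1\t0\t100\t1\t\t\t0.4\t60\n")
        (cnv,) = load_cnv_table(path)
        assert (cnv.Cm, cnv.Cp) == (0, 1) and not cnv.phased

    def test_amplification_requires_breakdown(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.HEADER + "c0\t1\t0\t100\t3\t\t\t0.4\t60\n")
        with pytest.raises(InputError, match="breakdown required"):
            load_cnv_table(path)

    def test_breakdown_must_sum_to_total(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.HEADER + "c0\t1\t0\t100\t3\t1\t1\t0.4\t60\n")
        with pytest.raises(InputError, match="Cm\\+Cp"):
            load_cnv_table(path)

    def test_phi_outside_unit_interval_rejected(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.HEADER + "c0\t1\t0\t100\t1\t\t\t1.4\t60\n")
        with pytest.raises(InputError):
            load_cnv_table(path)


class TestPseudoSSM:
    @pytest.mark.parametrize("phi,depth,b_expected", [
        (0.5, 60, 15),        # 60 * 0.25 exactly
        (0.0, 100, 0),        # zero-frequency CNV
        (0.35, 43, 8),        # round(7.525) with half-away-from-zero
    ])
    def test_variant_reads_rounding(self, phi, depth, b_expected):
        cnv = CNV(id="c", chrom="1", start=0, end=10, C=1, phi=[phi],
                  support_depth=depth)
        pseudo = cnv_to_pseudo_ssm(cnv)
        assert pseudo.d.tolist() == [depth]
        assert pseudo.b.tolist() == [b_expected]
        assert pseudo.source_cnv_id == "c"

    def test_variant_fraction_tracks_half_phi(self, rng):
        # |b/d - phi/2| <= 0.5/d for any random CNV
        for _ in range(200):
            phi = float(rng.uniform(0, 1))
            d = int(rng.integers(1, 500))
            cnv = CNV(id="c", chrom="1", start=0, end=10, C=1, phi=[phi],
                      support_depth=d)
            pseudo = cnv_to_pseudo_ssm(cnv)
            assert abs(pseudo.b[0] / d - phi / 2) <= 0.5 / d + 1e-12

    def test_default_support_depth_doubles_mean(self):
        ssms = [SSM(id="a", a=[10], d=[40]), SSM(id="b", a=[10], d=[60])]
        assert default_support_depth(ssms) == 100


class TestOverlap:
    def test_halfopen_containment(self):
        cnv = CNV(id="c", chrom="1", start=50, end=200, C=1, phi=[0.5])
        inside = SSM(id="in", a=[1], d=[2], locus=Locus("1", 100))
        boundary = SSM(id="edge", a=[1], d=[2], locus=Locus("1", 200))
        start = SSM(id="start", a=[1], d=[2], locus=Locus("1", 50))
        out = associate_ssms_to_cnvs([inside, boundary, start], [cnv])
        assert out == {"in": ["c"], "edge": [], "start": ["c"]}

    def test_multiple_cnvs_listed_in_input_order(self):
        c1 = CNV(id="late", chrom="1", start=0, end=300, C=1, phi=[0.5])
        c2 = CNV(id="early", chrom="1", start=50, end=150, C=0, Cm=0, Cp=0, phi=[0.2])
        ssm = SSM(id="s", a=[1], d=[2], locus=Locus("1", 100))
        assert associate_ssms_to_cnvs([ssm], [c1, c2])["s"] == ["late", "early"]

    def test_missing_locus_maps_to_empty(self):
        cnv = CNV(id="c", chrom="1", start=0, end=10, C=1, phi=[0.5])
        ssm = SSM(id="s", a=[1], d=[2])
        assert associate_ssms_to_cnvs([ssm], [cnv]) == {"s": []}

    def test_matches_bruteforce_scan(self, rng):
        cnvs = []
        for i in range(30):
            start = int(rng.integers(0, 900))
            cnvs.append(CNV(id=f"c{i}", chrom=str(rng.integers(1, 3)),
                            start=start, end=start + int(rng.integers(1, 200)),
                            C=1, phi=[0.5]))
        ssms = [SSM(id=f"s{i}", a=[1], d=[2],
                    locus=Locus(str(rng.integers(1, 3)), int(rng.integers(0, 1100))))
                for i in range(50)]
        got = associate_ssms_to_cnvs(ssms, cnvs)
        for s in ssms:
            brute = [c.id for c in cnvs
                     if c.chrom == s.locus.chrom and c.start <= s.locus.pos < c.end]
            assert got[s.id] == brute


class TestRoundTrip:
    def test_ssm_table(self, tmp_path, rng):
        ssms = [
            SSM(id="s0", a=[3, 5], d=[10, 12], mu_r=0.999, mu_v=0.5,
                locus=Locus("2", 123), phase="maternal", epsilon=0.001),
            SSM(id="s1", a=[0, 0], d=[7, 9]),
        ]
        path = tmp_path / "s.tsv"
        write_ssm_table(ssms, path)
        back = load_ssm_table(path)
        for orig, re in zip(ssms, back):
            assert orig.id == re.id
            assert orig.a.tolist() == re.a.tolist()
            assert orig.d.tolist() == re.d.tolist()
            assert orig.mu_r == re.mu_r and orig.mu_v == re.mu_v
            assert orig.locus == re.locus and orig.phase == re.phase
            assert orig.epsilon == re.epsilon

    def test_cnv_table(self, tmp_path):
        cnvs = [
            CNV(id="c0", chrom="1", start=10, end=500, C=3, Cm=2, Cp=1,
                phi=[0.4, 0.1], support_depth=80),
            CNV(id="c1", chrom="2", start=0, end=99, C=1, phi=[0.25, 0.5]),
        ]
        path = tmp_path / "c.tsv"
        write_cnv_table(cnvs, path)
        back = load_cnv_table(path)
        for orig, re in zip(cnvs, back):
            assert orig.id == re.id and orig.chrom == re.chrom
            assert (orig.start, orig.end, orig.C) == (re.start, re.end, re.C)
            assert (orig.Cm, orig.Cp, orig.phased) == (re.Cm, re.Cp, re.phased)
            assert orig.phi.tolist() == re.phi.tolist()
            assert orig.support_depth == re.support_depth
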