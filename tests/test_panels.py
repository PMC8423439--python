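"""Panel IO, cohort filters, period assignment, and variant intersection."""

import numpy as np
import pandas as pd
import pytest

from paleoprs import panels
from paleoprs.panels import (
    PanelFormatError,
    assign_periods,
    filter_geobox,
    filter_samples_missingness,
    intersect_variants,
    read_eigenstrat,
    read_plink,
    write_eigenstrat,
)
from paleoprs.periods import DEFAULT_BOUNDS_BP, bce_to_bp, resolve_period

from .conftest import make_panel


class TestEigenstrat:
    def _write_trio(self, tmp_path, geno_lines, n_snp=3, n_ind=2):
        (tmp_path / "p.geno").write_text("".join(line + "\n" for line in geno_lines))
        (tmp_path / "p.snp").write_text(
            "".join(f"v{j}\t1\t0.0\t{1000 * (j + 1)}\tA\tG\n" for j in range(n_snp)))
        (tmp_path / "p.ind").write_text(
            "".join(f"s{i}\tU\tPop\n" for i in range(n_ind)))
        return str(tmp_path / "p")

    def test_nine_maps_to_missing_at_the_right_cell(self, tmp_path):
        prefix = self._write_trio(tmp_path, ["02", "92", "00"])
        panel = read_eigenstrat(prefix)
        assert panel.dosage.shape == (2, 3)
        assert np.isnan(panel.dosage[0, 1])  # sample 0, variant 1
        assert panel.dosage[1, 1] == 2.0
        assert np.isnan(panel.dosage).sum() == 1

    def test_ragged_row_raises_with_line_number(self, tmp_path):
        prefix = self._write_trio(tmp_path, ["02", "021", "00"])
        with pytest.raises(PanelFormatError, match="line 2"):
            read_eigenstrat(prefix)

    def test_row_count_mismatch_raises(self, tmp_path):
        prefix = self._write_trio(tmp_path, ["02", "00"])
        with pytest.raises(PanelFormatError, match="2 variant rows"):
            read_eigenstrat(prefix)

    def test_empty_geno_gives_zero_variant_panel(self, tmp_path):
        prefix = self._write_trio(tmp_path, [], n_snp=0)
        panel = read_eigenstrat(prefix)
        assert panel.n_variants == 0 and panel.n_samples == 2

    def test_write_read_roundtrip(self, tmp_path, rng):
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(4, 6))
        panel = make_panel(dosage, ploidy=["diploid"] * 4)
        write_eigenstrat(panel, str(tmp_path / "rt"))
        back = read_eigenstrat(str(tmp_path / "rt"))
        assert np.array_equal(back.dosage, panel.dosage, equal_nan=True)
        assert back.sample_ids == panel.sample_ids


class TestPlink:
    def test_bed_decoding_matches_eigenstrat(self, tmp_path, rng):
        # synthetic .bed written bit-by-bit from the same dosages
        dosage = rng.choice([0.0, 1.0, 2.0, np.nan], size=(5, 4))
        panel = make_panel(dosage)
        code_of = {0.0: 0b11, 1.0: 0b10, 2.0: 0b00}
        with open(tmp_path / "p.bed", "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))
            for j in range(panel.n_variants):
                byte, out = 0, []
                for i in range(panel.n_samples):
                    c = code_of.get(panel.dosage[i, j], 0b01)
                    byte |= c << (2 * (i % 4))
                    if i % 4 == 3:
                        out.append(byte)
                        byte = 0
                if panel.n_samples % 4:
                    out.append(byte)
                fh.write(bytes(out))
        (tmp_path / "p.bim").write_text("".join(
            f"1\tv{j}\t0\t{1000 * (j + 1)}\tA\tG\n" for j in range(panel.n_variants)))
        (tmp_path / "p.fam").write_text("".join(
            f"F{i}\ts{i}\t0\t0\t0\t-9\n" for i in range(panel.n_samples)))
        back = read_plink(str(tmp_path / "p"))
        assert np.array_equal(back.dosage, panel.dosage, equal_nan=True)
        assert back.sample_ids == panel.sample_ids

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "q.bed").write_bytes(b"\x00\x00\x00")
        (tmp_path / "q.bim").write_text("1\tv0\t0\t1000\tA\tG\n")
        (tmp_path / "q.fam").write_text("F0\ts0\t0\t0\t0\t-9\n")
        with pytest.raises(PanelFormatError, match="magic"):
            read_plink(str(tmp_path / "q"))


class TestMissingnessFilter:
    def test_above_threshold_removed_boundary_kept(self):
        # 97% missing at a 0.96 threshold is filtered out; exactly 70% at a
        # 0.70 threshold survives ("above" is strict)
        dosage = np.full((3, 100), 2.0)
        dosage[0, :97] = np.nan
        dosage[1, :70] = np.nan
        panel = make_panel(dosage, ploidy=["pseudo_haploid"] * 3)
        assert filter_samples_missingness(panel, 0.96).sample_ids == ["s1", "s2"]
        assert "s1" in filter_samples_missingness(panel, 0.70).sample_ids

    def test_fully_genotyped_panel_unchanged(self):
        panel = make_panel(np.ones((4, 5)), ploidy=["diploid"] * 4)
        assert filter_samples_missingness(panel, 0.96).sample_ids == panel.sample_ids

    def test_idempotent(self, rng):
        dosage = rng.choice([0.0, 2.0, np.nan], size=(10, 40), p=[0.2, 0.2, 0.6])
        panel = make_panel(dosage, ploidy=["pseudo_haploid"] * 10)
        once = filter_samples_missingness(panel, 0.5)
        twice = filter_samples_missingness(once, 0.5)
        assert twice.sample_ids == once.sample_ids


class TestGeobox:
    @pytest.mark.parametrize(
        "lat,lon,kept",
        [
            (52.0, 5.0, True),    # interior
            (34.9, 5.0, False),   # below 35 N
            (35.0, -10.0, True),  # boundary inclusive
            (70.0, 40.0, True),   # opposite corner
            (52.0, 41.0, False),  # east of 40 E
        ],
    )
    def test_box_membership(self, lat, lon, kept):
        meta = pd.DataFrame({"sample_id": ["a"], "age_bp": [5000],
                             "latitude": [lat], "longitude": [lon], "period": [None]})
        assert (len(filter_geobox(meta)) == 1) is kept

    def test_missing_coordinates_removed(self):
        meta = pd.DataFrame({"sample_id": ["a", "b"], "age_bp": [1, 2],
                             "latitude": [np.nan, 50.0], "longitude": [5.0, 5.0],
                             "period": [None, None]})
        assert filter_geobox(meta)["sample_id"].tolist() == ["b"]


class TestAssignPeriods:
    def _meta(self, ages, labels=None):
        n = len(ages)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)], "age_bp": ages,
            "latitude": [50.0] * n, "longitude": [5.0] * n,
            "period": labels if labels is not None else [None] * n,
        })

    def test_explicit_label_overrides_age_rule(self):
        # 7,300 BP sits in the Neolithic/post-Neolithic overlap region; the
        # archaeological label wins over any age-based rule
        meta = assign_periods(self._meta([7300], ["Neolithic"]))
        assert meta["period"].tolist() == ["Neolithic"]

    def test_pre_eup_age_is_eup(self):
        assert assign_periods(self._meta([bce_to_bp(30_000)]))["period"][0] == "EUP"

    def test_age_zero_is_modern(self):
        assert assign_periods(self._meta([0]))["period"][0] == "Modern"

    @pytest.mark.parametrize(
        "bce,expected",
        [
            (20_000, "LUP"),
            (9_000, "Mesolithic"),
            (7_000, "Neolithic"),   # Meso/Neo overlap, closer to Neolithic midpoint
            (4_500, "Neolithic"),   # Neo/post-Neo overlap, closer to Neolithic midpoint
            (2_000, "PostNeolithic"),
        ],
    )
    def test_unlabeled_assignment_including_overlaps(self, bce, expected):
        assert resolve_period(bce_to_bp(bce)) == expected

    def test_unassignable_age_flagged(self):
        bounds = {"Neolithic": DEFAULT_BOUNDS_BP["Neolithic"], "Modern": (0, 0)}
        meta = assign_periods(self._meta([500]), bounds)
        assert meta["period"].isna().all()

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_periods(self._meta([-5]))


class TestIntersectVariants:
    def test_disjoint_sets_give_zero_variant_panel(self):
        a = make_panel(np.zeros((1, 2)), pos=[1000, 2000])
        b = make_panel(np.zeros((1, 2)), pos=[5000, 6000])
        assert intersect_variants(a, b).n_variants == 0

    def test_identical_sets_preserved(self, rng):
        dosage = rng.choice([0.0, 2.0], size=(3, 5))
        a = make_panel(dosage, ploidy=["pseudo_haploid"] * 3)
        b = make_panel(rng.choice([0.0, 1.0, 2.0], size=(2, 5)),
                       ploidy=["diploid"] * 2, sample_ids=["m0", "m1"])
        merged = intersect_variants(a, b)
        assert merged.n_variants == 5
        assert merged.n_samples == 5
        assert np.array_equal(merged.dosage[:3], a.dosage, equal_nan=True)

    def test_swapped_alleles_recode_modern_dosage(self):
        a = make_panel(np.array([[2.0]]), allele1=["C"], allele2=["T"])
        b = make_panel(np.array([[2.0]]), allele1=["T"], allele2=["C"],
                       sample_ids=["m0"], ploidy=["diploid"])
        merged = intersect_variants(a, b)
        assert merged.variants["allele1"][0] == "C"
        assert merged.dosage[1, 0] == 0.0  # 2 copies of T = 0 copies of C

    def test_incompatible_allele_sets_dropped(self):
        a = make_panel(np.zeros((1, 1)), allele1=["A"], allele2=["G"])
        b = make_panel(np.zeros((1, 1)), allele1=["A"], allele2=["C"], sample_ids=["m"])
        assert intersect_variants(a, b).n_variants == 0

    def test_missingness_and_geobox_filters_commute(self, rng):
        dosage = rng.choice([0.0, 2.0, np.nan], size=(8, 30), p=[0.3, 0.3, 0.4])
        panel = make_panel(dosage, ploidy=["pseudo_haploid"] * 8)
        meta = pd.DataFrame({
            "sample_id": panel.sample_ids, "age_bp": rng.integers(100, 9000, 8),
            "latitude": rng.uniform(20, 80, 8), "longitude": rng.uniform(-30, 60, 8),
            "period": [None] * 8,
        })
        p1 = filter_samples_missingness(panel, 0.5)
        p1, m1 = panels.restrict_to_meta(p1, filter_geobox(meta))
        m2 = filter_geobox(meta)
        p2 = filter_samples_missingness(panel, 0.5)
        p2, m2 = panels.restrict_to_meta(p2, m2)
        assert p1.sample_ids == p2.sample_ids
        assert m1.equals(m2)
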