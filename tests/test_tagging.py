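"""Deletion-tagging LD: carrier selection, windows, r², best tag, summaries."""

import numpy as np
import pytest

from cnvpop.core import CnClass, GenomicInterval
from cnvpop.io import SnpGenotypeMatrix
from cnvpop.tagging import (
    DeletionGenotypeVector,
    best_tag,
    pairwise_r2,
    select_common_deletions,
    snps_in_window,
    tag_all,
    tagging_summary,
)


def snp_matrix(positions, dosages, chrom="1", samples=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    samples = samples or [f"s{i}" for i in range(dosages.shape[1])]
    return SnpGenotypeMatrix(
        sample_ids=samples,
        snp_ids=[f"snp{i}" for i in range(len(positions))],
        chroms=np.array([chrom] * len(positions), dtype=object),
        positions=np.array(positions, dtype=np.int64),
        dosages=dosages,
    )


def deletion(start=1_000_000, end=1_010_000, carriers=(1, 1, 0, 0), chrom="1"):
    return DeletionGenotypeVector(
        deletion_id="d1",
        interval=GenomicInterval(chrom, start, end),
        carrier_status=np.array(carriers, dtype=np.int8),
        sample_ids=[f"s{i}" for i in range(len(carriers))],
    )


class TestCommonDeletionSelection:
    def _cohort(self, carrier_samples):
        from cnvpop.consensus import ConsensusCnv
        from cnvpop.cnvr import merge_to_cnvrs

        all_samples = [f"s{i}" for i in range(10)]
        per_sample = {s: [] for s in all_samples}
        for s in carrier_samples:
            per_sample[s].append(
                ConsensusCnv(
                    s,
                    GenomicInterval("1", 5000, 9000),
                    CnClass.HET_DEL,
                    frozenset({("ngs", "cnmops"), ("ngs", "vendor_ngs")}),
                    "intra",
                    "intersection",
                )
            )
        cnvrs = merge_to_cnvrs([c for v in per_sample.values() for c in v], "Q1", 10)
        return per_sample, cnvrs

    def test_three_carriers_excluded_four_included(self):
        per_sample, cnvrs = self._cohort(["s0", "s1", "s2"])
        assert select_common_deletions(per_sample, cnvrs, min_carriers=4) == []
        per_sample, cnvrs = self._cohort(["s0", "s1", "s2", "s3"])
        sel = select_common_deletions(per_sample, cnvrs, min_carriers=4)
        assert len(sel) == 1 and sel[0].carrier_count == 4

    def test_dosage_coding_distinguishes_hom_and_het(self):
        from cnvpop.consensus import ConsensusCnv
        from cnvpop.cnvr import merge_to_cnvrs

        per_sample = {f"s{i}": [] for i in range(6)}
        for sid, cn in [("s0", CnClass.HOM_DEL), ("s1", CnClass.HET_DEL),
                        ("s2", CnClass.HET_DEL), ("s3", CnClass.HOM_DEL)]:
            per_sample[sid].append(
                ConsensusCnv(sid, GenomicInterval("1", 5000, 9000), cn,
                             frozenset({("ngs", "cnmops"), ("ngs", "vendor_ngs")}),
                             "intra", "intersection")
            )
        cnvrs = merge_to_cnvrs([c for v in per_sample.values() for c in v], "Q1", 6)
        sel = select_common_deletions(per_sample, cnvrs, min_carriers=4, coding="dosage")
        assert len(sel) == 1
        assert sel[0].carrier_status.tolist() == [2, 1, 1, 2, 0, 0]
        assert sel[0].carrier_count == 4
        with pytest.raises(ValueError):
            select_common_deletions(per_sample, cnvrs, coding="fraction")

    def test_noiseless_selection_equals_planted(self, noiseless_cohort):
        from cnvpop.consensus import integrate
        from cnvpop.cnvr import merge_to_cnvrs
        from cnvpop.core import PipelineConfig

        cfg, truth, call_sets = noiseless_cohort
        calls = [c for v in call_sets.values() for c in v]
        final, report = integrate(calls, PipelineConfig())
        subpop_of = {s.sample_id: s.subpopulation for s in truth.samples}
        cnvrs = []
        for sp in ("Q1", "Q2", "Q3"):
            cnvs_sp = [c for sid, v in final.items() if subpop_of[sid] == sp for c in v]
            cnvrs += merge_to_cnvrs(cnvs_sp, sp)
        sel = select_common_deletions(final, cnvrs, min_carriers=4)
        # expected: planted deletion loci with ≥4 carriers among detected CNVs
        detected = {}
        for sid, v in final.items():
            for c in v:
                if c.cn.direction == "deletion":
                    detected.setdefault((c.interval.chrom, c.interval.start, c.interval.end), set()).add(sid)
        expected = {k for k, v in detected.items() if len(v) >= 4}
        got = {(d.interval.chrom, d.interval.start, d.interval.end) for d in sel}
        assert got == expected and len(got) > 0


class TestWindow:
    def test_closed_boundaries(self):
        d = deletion(start=1_000_000, end=1_010_000)
        mat = snp_matrix([500_000, 499_999, 1_509_999, 1_510_000, 1_005_000],
                         np.zeros((5, 4)))
        idx = snps_in_window(d.interval, mat.chroms, mat.positions, window=500_000)
        got = set(mat.positions[idx].tolist())
        assert 500_000 in got          # start − window, inclusive
        assert 499_999 not in got      # one past the window
        assert 1_509_999 in got        # end + window − 1 (inside)
        assert 1_005_000 in got        # inside the deletion
        assert 1_510_000 in got        # end + window, inclusive

    def test_matches_brute_force_scan(self, rng):
        d = deletion()
        pos = rng.integers(0, 3_000_000, 500)
        mat = snp_matrix(sorted(pos.tolist()), np.zeros((500, 4)))
        idx = snps_in_window(d.interval, mat.chroms, mat.positions, window=500_000)
        brute = [
            j
            for j in range(500)
            if d.interval.start - 500_000 <= mat.positions[j] <= d.interval.end + 500_000
        ]
        assert sorted(idx.tolist()) == brute


class TestPairwiseR2:
    def test_identity_gives_one(self):
        c = np.array([1, 1, 0, 0, 1], dtype=np.int8)
        assert pairwise_r2(c, c) == pytest.approx(1.0)

    def test_hand_computed_nine_elevenths(self):
        """carriers {1,1,0,0} vs dosages {2,1,0,0} → r² = 9/11."""
        r2 = pairwise_r2(np.array([1, 1, 0, 0]), np.array([2, 1, 0, 0]))
        assert r2 == pytest.approx(9 / 11, abs=1e-12)

    def test_monomorphic_undefined(self):
        assert pairwise_r2(np.array([1, 1, 0, 0]), np.array([1, 1, 1, 1])) is None
        assert pairwise_r2(np.array([0, 0, 0, 0]), np.array([2, 1, 0, 1])) is None

    def test_missing_handled_pairwise_complete(self):
        c = np.array([1, 1, 0, 0, -1], dtype=np.int8)
        d = np.array([2, 1, 0, -1, 0], dtype=np.int8)
        # complete cases: indices 0,1,2 → carriers {1,1,0} vs {2,1,0}
        expected = np.corrcoef([1, 1, 0], [2, 1, 0])[0, 1] ** 2
        assert pairwise_r2(c, d) == pytest.approx(expected)
        assert pairwise_r2(np.array([1, -1]), np.array([-1, 1])) is None

    def test_affine_invariance_and_symmetry(self, rng):
        c = (rng.random(40) < 0.4).astype(np.int8)
        d = rng.integers(0, 3, 40).astype(np.int8)
        if pairwise_r2(c, d) is None:
            pytest.skip("degenerate draw")
        assert pairwise_r2(c, d) == pytest.approx(pairwise_r2(d, c))
        assert pairwise_r2(c, (2 * d + 1).astype(np.int8)) == pytest.approx(pairwise_r2(c, d))


class TestBestTag:
    def test_closest_of_equal_r2_wins(self):
        d = deletion(start=1_000_000, end=1_010_000, carriers=(1, 1, 0, 0))
        tag_geno = [1, 1, 0, 0]
        mat = snp_matrix(
            [1_010_000 + 10_000 - 1, 1_010_000 + 100_000 - 1],
            [tag_geno, tag_geno],
        )
        t = best_tag(d, mat)
        assert t.snp_id == "snp0" and t.distance_bp == 10_000

    def test_single_snp_selected_regardless_of_r2(self):
        d = deletion(carriers=(1, 1, 0, 0))
        mat = snp_matrix([1_200_000], [[0, 1, 1, 0]])  # weak tag
        t = best_tag(d, mat)
        assert t.snp_id == "snp0" and t.r2 is not None and t.r2 < 0.5

    def test_planted_perfect_tag_beats_noise(self, rng):
        d = deletion(carriers=tuple((rng.random(30) < 0.4).astype(int)))
        noise = rng.integers(0, 3, (20, 30))
        dosages = np.vstack([noise[:10], d.carrier_status[None, :], noise[10:]])
        positions = sorted(rng.integers(600_000, 1_400_000, 21).tolist())
        mat = snp_matrix(positions, dosages, samples=d.sample_ids)
        t = best_tag(d, mat)
        assert t.r2 == pytest.approx(1.0)
        assert t.snp_id == "snp10"

    def test_no_defined_r2_yields_undefined(self):
        d = deletion(carriers=(1, 1, 0, 0))
        mat = snp_matrix([1_005_000], [[1, 1, 1, 1]])  # monomorphic
        t = best_tag(d, mat)
        assert t.r2 is None and t.snp_id is None and t.n_snps_in_window == 1

    def test_distance_never_exceeds_window(self, rng):
        d = deletion(carriers=tuple((rng.random(20) < 0.5).astype(int)))
        pos = rng.integers(400_000, 1_600_000, 50)
        mat = snp_matrix(sorted(pos.tolist()), rng.integers(0, 3, (50, 20)),
                         samples=d.sample_ids)
        t = best_tag(d, mat, window=500_000)
        assert t.distance_bp is None or t.distance_bp <= 500_000


class TestTaggingSummary:
    def _table(self, r2_by_panel):
        import pandas as pd

        rows = []
        for panel, r2s in r2_by_panel.items():
            for i, r2 in enumerate(r2s):
                rows.append({"deletion": f"d{i}", "panel": panel, "snp": f"x{i}",
                             "r2": r2, "distance_bp": 0, "n_snps_in_window": 1})
        return pd.DataFrame(rows)

    def test_perfect_tagging_fraction_one_everywhere(self):
        tbl = self._table({"wgs_full": [1.0, 1.0, 1.0]})
        s = tagging_summary(tbl)
        assert (s["fraction"] == 1.0).all()

    def test_no_snps_fraction_zero(self):
        tbl = self._table({"wgs_full": [None, None]})
        s = tagging_summary(tbl)
        assert (s["fraction"] == 0.0).all()

    def test_monotone_in_threshold(self, rng):
        tbl = self._table({"wgs_full": rng.random(100).tolist()})
        s = tagging_summary(tbl).sort_values("threshold")
        fr = s["fraction"].to_numpy()
        assert (np.diff(fr) <= 1e-12).all()

    def test_superset_panel_dominates(self, small_cohort):
        """With array SNPs ⊂ WGS SNPs, the WGS tagged fraction is ≥ the
        array's at every threshold."""
        from cnvpop import simulate as sim
        from cnvpop.consensus import integrate
        from cnvpop.cnvr import merge_to_cnvrs
        from cnvpop.core import PipelineConfig

        cfg, truth, call_sets = small_cohort
        snps, registry = sim.simulate_linked_snps(truth, cfg)
        calls = [c for v in call_sets.values() for c in v]
        final, _ = integrate(calls, PipelineConfig())
        subpop_of = {s.sample_id: s.subpopulation for s in truth.samples}
        cnvrs = []
        for sp in ("Q1", "Q2", "Q3"):
            cnvs_sp = [c for sid, v in final.items() if subpop_of[sid] == sp for c in v]
            cnvrs += merge_to_cnvrs(cnvs_sp, sp)
        dels = select_common_deletions(final, cnvrs, 4)
        kept = sorted(final)
        order = [snps.sample_ids.index(s) for s in kept]
        dels = [
            DeletionGenotypeVector(d.deletion_id, d.interval,
                                   d.carrier_status[[d.sample_ids.index(s) for s in kept]], kept)
            for d in dels
        ]
        import dataclasses

        snps_kept = dataclasses.replace(snps, sample_ids=kept, dosages=snps.dosages[:, order])
        snp_index = {s: i for i, s in enumerate(snps.snp_ids)}
        array_idx = np.array(sorted(snp_index[s] for s in registry.array_subset_snp_ids))
        tbl = tag_all(dels, snps_kept, {"wgs_full": None, "array_subset": array_idx})
        s = tagging_summary(tbl)
        wide = s.pivot_table(index=["subset", "threshold"], columns="panel", values="fraction")
        assert (wide["wgs_full"] >= wide["array_subset"] - 1e-12).all()
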