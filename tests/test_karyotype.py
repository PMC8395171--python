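import numpy as np
import pytest

import paintmap as pm
from _util import mc_estimands
from paintmap.datasets import (
    karyotype_true_arms,
    single_cell_measurements_from_table,
)


def rec(cell, label, long_um, short_um):
    return pm.MeasurementRecord(cell, label, long_um, short_um)


class TestSummarize:
    def test_single_cell_published_arms(self):
        rows = pm.summarize_karyotype([rec("c1", "Chr.1", 2.02, 1.56)])
        r = rows[0]
        assert r.total_mean == pytest.approx(3.58)
        assert r.ratio_mean == pytest.approx(2.02 / 1.56)
        assert pm.round_half_up(r.ratio_mean) == 1.29
        assert r.n_cells == 1 and r.total_sd == 0.0

    def test_equal_arms_metacentric(self):
        r = pm.summarize_karyotype([rec("c1", "Chr.1", 1.0, 1.0)])[0]
        assert r.ratio_mean == 1.0 and r.centromere_class == "m"

    def test_ratio_is_mean_of_per_cell_ratios(self):
        """Mean of per-cell ratios (2.0, 1.0 -> 1.5) differs from the ratio
        of mean arms (1.75/1.25 = 1.4); the former is reported."""
        rows = pm.summarize_karyotype(
            [rec("c1", "X", 2.0, 1.0), rec("c2", "X", 1.5, 1.5)]
        )
        assert rows[0].ratio_mean == pytest.approx(1.5)
        assert rows[0].long_mean / rows[0].short_mean == pytest.approx(1.4)

    def test_homologs_averaged_within_cell_first(self):
        """Copies (2,1) and (3,3) in one cell: the cell ratio is the ratio of
        homolog means 2.5/2.0 = 1.25, not the mean of copy ratios (1.5)."""
        rows = pm.summarize_karyotype(
            [rec("c1", "X", 2.0, 1.0), rec("c1", "X", 3.0, 3.0)]
        )
        assert rows[0].ratio_mean == pytest.approx(1.25)

    def test_permutation_invariant(self, rng):
        recs = [
            rec(f"c{i}", f"Chr.{j}", 1.5 + 0.01 * i + 0.1 * j, 1.0 + 0.01 * i)
            for i in range(5)
            for j in range(3)
            for _ in range(2)
        ]
        a = pm.summarize_karyotype(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert pm.summarize_karyotype(shuffled) == a

    def test_total_equals_long_plus_short(self):
        rows = pm.summarize_karyotype(single_cell_measurements_from_table())
        for r in rows:
            assert r.total_mean == pytest.approx(r.long_mean + r.short_mean)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pm.summarize_karyotype(
                [rec("c1", "Chr.99", 2.0, 1.0)], expected_labels=["Chr.1"]
            )

    def test_more_labels_than_basic_number_rejected(self):
        recs = [rec("c1", f"Chr.{j}", 2.0, 1.0) for j in range(1, 12)]
        with pytest.raises(ValueError, match="basic number"):
            pm.summarize_karyotype(recs, ploidy=pm.Ploidy(60, 10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pm.summarize_karyotype([])

    def test_noisy_recovery_matches_order_statistic_estimands(self):
        """With per-record long/short ordering enforced, the summary estimates
        order-statistic means; recovered values sit within a family-calibrated
        z-bound of Monte-Carlo estimands at 10 cells, noise 0.15 um."""
        true_arms = karyotype_true_arms()
        recs = pm.simulate_measurements(
            true_arms, noise_sd_um=0.15, n_cells=10, copies_per_cell=6,
            missing_copy_rate=0.0, seed=20260920,
        )
        rows = {r.chrom_label: r for r in pm.summarize_karyotype(recs)}
        zmax = 0.0
        for label, (lt, st) in true_arms.items():
            est = mc_estimands(lt, st, sd=0.15, copies=6, n_cells=10, seed=7)
            r = rows[label]
            for key in ("long", "short", "ratio"):
                z = abs(getattr(r, f"{key}_mean") - est[key][0]) / est[key][1]
                zmax = max(zmax, z)
        assert zmax <= 3.5


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,cls",
        [(1.14, "m"), (1.7, "m"), (1.71, "sm"), (2.03, "sm"),
         (3.0, "sm"), (3.01, "st"), (7.0, "st"), (7.01, "t")],
    )
    def test_boundaries(self, ratio, cls):
        assert pm.classify_centromere(ratio) == cls

    def test_monotone_in_ratio(self):
        order = {"m": 0, "sm": 1, "st": 2, "t": 3}
        ratios = np.linspace(1.0, 10.0, 200)
        classes = [order[pm.classify_centromere(r)] for r in ratios]
        assert classes == sorted(classes)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            pm.classify_centromere(0.9)


class TestPloidy:
    def test_hexaploid(self):
        p = pm.Ploidy(60, 10)
        assert p.ploidy_level == 6

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            pm.Ploidy(61, 10)


class TestReferenceAssignment:
    def test_exact_barcode_match(self, table1_calls):
        res = pm.assign_reference_numbers(table1_calls, table1_calls)
        assert res.mapping == {c: c for c in table1_calls.chromosomes}
        assert res.unassigned == () and not res.ambiguous and not res.shared

    def test_all_zero_barcode_flagged_unassigned(self, table1):
        import pandas as pd

        target = table1.copy()
        target.loc[:, "Sorghum5"] = 0  # silence every probe on one chromosome
        res = pm.assign_reference_numbers(
            pm.call_signals(target), pm.call_signals(table1)
        )
        assert "Sorghum5" in res.unassigned

    def test_hexaploid_groups_recover_source_numbering(self):
        """Every homoeologous copy of the synthetic hexaploid maps back to
        its source reference chromosome, checked against the truth log."""
        bundle = pm.generate_preset("tripidium-like", seed=11, length_scale=0.03)
        lib, ref, tgt = bundle["library"], bundle["reference"], bundle["target"]
        thresholds = pm.SignalThresholds(**bundle["thresholds"])
        params = bundle["screen_params"]  # short seed for the diverged target
        ref_calls = pm.call_signals(
            pm.count_per_chromosome(pm.screen_library(lib, ref, params)), thresholds
        )
        tgt_calls = pm.call_signals(
            pm.count_per_chromosome(pm.screen_library(lib, tgt, params)), thresholds
        )
        res = pm.assign_reference_numbers(tgt_calls, ref_calls)
        truth = bundle["truth"].chromosomes
        assert len(res.mapping) == 60 and not res.unassigned and not res.ambiguous
        for copy_name, ref_name in res.mapping.items():
            basic = truth[copy_name]["source"]       # e.g. tchr3
            assert truth[basic]["source"] == ref_name  # e.g. chr3
        # six copies share each reference number, reported not hidden
        assert all(len(v) == 6 for v in res.shared.values())

    def test_mismatched_probe_rows_rejected(self, table1, table1_calls):
        other = pm.call_signals(table1.iloc[:5])
        with pytest.raises(ValueError):
            pm.assign_reference_numbers(other, table1_calls)


class TestIdiogram:
    def make_rows(self):
        return pm.summarize_karyotype(single_cell_measurements_from_table())

    def test_ten_bars_longest_chr1_shortest_chr8(self):
        idio = pm.build_idiogram(self.make_rows())
        assert len(idio.rows) == 10
        assert [r.chrom_label for r in idio.rows][:2] == ["Chr.1", "Chr.2"]
        totals = {r.chrom_label: r.total_mean for r in idio.rows}
        assert max(totals, key=totals.get) == "Chr.1"
        assert min(totals, key=totals.get) == "Chr.8"

    def test_svg_deterministic_and_scaled(self):
        rows = self.make_rows()
        svg1 = pm.build_idiogram(rows).to_svg()
        svg2 = pm.build_idiogram(rows).to_svg()
        assert svg1 == svg2
        heights = [
            float(part.split('height="')[1].split('"')[0])
            for part in svg1.split("<rect")[2:]  # skip background
            if 'rx="8"' in part
        ]
        assert max(heights) == heights[0]  # Chr.1 drawn longest

    def test_rdna_annotations_render_on_their_chromosomes(self):
        idio = pm.build_idiogram(
            self.make_rows(),
            [
                pm.IdiogramAnnotation("Chr.5", "5S", "red", "pericentromeric"),
                pm.IdiogramAnnotation("Chr.6", "35S", "green", "distal-long"),
            ],
        )
        svg = idio.to_svg()
        assert "<title>5S</title>" in svg and "<title>35S</title>" in svg
        doc = idio.to_dict()
        assert {a["chrom_label"] for a in doc["annotations"]} == {"Chr.5", "Chr.6"}

    def test_single_chromosome(self):
        rows = pm.summarize_karyotype([rec("c1", "Chr.1", 2.0, 1.0)])
        svg = pm.build_idiogram(rows).to_svg()
        assert svg.count('rx="8"') == 1 and "<line" in svg

    def test_annotation_to_missing_chromosome_rejected(self):
        with pytest.raises(ValueError, match="missing chromosome"):
            pm.build_idiogram(
                self.make_rows(), [pm.IdiogramAnnotation("Chr.99", "5S", "red")]
            )

    def test_label_ordering_numeric(self):
        rows = pm.summarize_karyotype(
            [rec("c1", "Chr.10", 1.4, 1.2), rec("c1", "Chr.2", 2.0, 1.5)]
        )
        idio = pm.build_idiogram(rows)
        assert [r.chrom_label for r in idio.rows] == ["Chr.2", "Chr.10"]
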