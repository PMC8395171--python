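import io

import numpy as np
import pytest
from scipy import stats

import paintmap as pm
from paintmap.synthetic import SCENARIOS, retention_fraction_at_truth


def small_config(seed=1, lengths=(30_000, 24_000), density=0.25):
    return pm.SimulationConfig(
        seed=seed, n_chrom=len(lengths), chrom_lengths_bp=lengths,
        oligo_density_per_kb=density,
    )


def fasta_text(genome):
    buf = io.StringIO()
    for c in genome:
        buf.write(f">{c.chrom_name}\n{c.sequence}\n")
    return buf.getvalue()


class TestReferenceGenome:
    def test_same_seed_byte_identical(self):
        g1, _ = pm.simulate_reference_genome(small_config(seed=4))
        g2, _ = pm.simulate_reference_genome(small_config(seed=4))
        assert fasta_text(g1) == fasta_text(g2)
        g3, _ = pm.simulate_reference_genome(small_config(seed=5))
        assert fasta_text(g1) != fasta_text(g3)

    def test_requested_shapes(self):
        cfg = pm.SimulationConfig(seed=1, n_chrom=3, chrom_lengths_bp=(50_000,) * 3)
        g, log = pm.simulate_reference_genome(cfg)
        assert len(g) == 3
        assert all(c.length_bp == 50_000 for c in g)
        assert set(log.chromosomes) == {"chr1", "chr2", "chr3"}

    def test_gc_fraction_near_half_at_1mb(self):
        cfg = pm.SimulationConfig(seed=2, n_chrom=1, chrom_lengths_bp=(1_000_000,))
        g, _ = pm.simulate_reference_genome(cfg)
        seq = g["chr1"].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_rdna_sites_logged(self):
        cfg = pm.SimulationConfig(seed=3)
        g, log = pm.simulate_reference_genome(cfg)
        assert log.rdna["5S"]["chrom"] == "chr9"
        assert log.rdna["35S"]["chrom"] == "chr6"
        assert log.rdna["35S"]["end"] <= g["chr6"].length_bp


class TestOligoLibrary:
    def test_density_yields_expected_count(self):
        cfg = pm.SimulationConfig(seed=1, n_chrom=1, chrom_lengths_bp=(1_000_000,))
        g, _ = pm.simulate_reference_genome(cfg)
        lib, log = pm.design_oligo_library(g, cfg)
        assert lib.set_sizes() == {"CP1": 250}  # 0.25 per kb over 1 Mb
        assert len(log.oligos) == 250

    def test_every_oligo_single_copy_exhaustive(self):
        cfg = small_config(seed=6, lengths=(15_000, 12_000))
        g, _ = pm.simulate_reference_genome(cfg)
        lib, _ = pm.design_oligo_library(g, cfg)
        whole = {c.chrom_name: c.sequence for c in g}
        for oligo in lib:
            n = sum(
                s.count(oligo.sequence) + s.count(pm.reverse_complement(oligo.sequence))
                for s in whole.values()
            )
            assert n == 1

    def test_duplicated_segment_is_avoided(self):
        """A genome with an internal duplication forces the single-copy
        filter to resample the affected start."""
        cfg = small_config(seed=7, lengths=(20_000,))
        g, _ = pm.simulate_reference_genome(cfg)
        seq = g["chr1"].sequence
        dup = seq[:100] + seq[4000:4100] + seq[200:]  # copy of a candidate window
        g2 = pm.Genome([pm.GenomeSequence("chr1", dup)], "dup")
        cfg2 = pm.SimulationConfig(seed=7, n_chrom=1, chrom_lengths_bp=(len(dup),))
        lib, _ = pm.design_oligo_library(g2, cfg2)
        for oligo in lib:
            n = dup.count(oligo.sequence) + dup.count(pm.reverse_complement(oligo.sequence))
            assert n == 1

    def test_self_screen_fully_retained_at_identity(self):
        cfg = small_config(seed=8)
        g, _ = pm.simulate_reference_genome(cfg)
        lib, log = pm.design_oligo_library(g, cfg)
        aset = pm.screen_library(lib, g)
        assert sum(aset.retained_per_set().values()) == len(lib)
        best = {h.oligo_id: h for h in aset.hits if h.identity == 1.0}
        for oligo in lib:
            truth = log.oligos[oligo.oligo_id]
            h = best[oligo.oligo_id]
            assert (h.chrom_name, h.start) == (truth["chrom"], truth["start"])


class TestDivergence:
    def test_rate_zero_identity(self):
        cfg = small_config(seed=9)
        g, _ = pm.simulate_reference_genome(cfg)
        t, log = pm.diverge_genome(g, SCENARIOS["identity"], seed=3)
        assert [c.sequence for c in t] == [c.sequence for c in g]
        assert all(v["n_substitutions"] == 0 for v in log.chromosomes.values())

    def test_expected_matched_bases_at_ten_percent(self):
        """At 10% substitution, mean matched bases across the library at the
        true loci is ~45 x 0.9, within 3 SE."""
        cfg = small_config(seed=10, lengths=(60_000, 50_000))
        g, _ = pm.simulate_reference_genome(cfg)
        lib, log = pm.design_oligo_library(g, cfg)
        t, tlog = pm.diverge_genome(g, pm.DivergenceScenario("r10", 0.10), seed=4)
        src_to_tgt = {v["source"]: k for k, v in tlog.chromosomes.items()}
        matched = []
        for oligo in lib:
            e = log.oligos[oligo.oligo_id]
            seg = t[src_to_tgt[e["chrom"]]].sequence[e["start"] : e["start"] + 45]
            matched.append(sum(a == b for a, b in zip(oligo.sequence, seg)))
        se = np.std(matched, ddof=1) / np.sqrt(len(matched))
        assert abs(np.mean(matched) - 45 * 0.9) <= 3 * se

    def test_retention_brackets_binomial_closed_form(self):
        cfg = small_config(seed=11, lengths=(60_000, 50_000, 40_000))
        g, _ = pm.simulate_reference_genome(cfg)
        lib, log = pm.design_oligo_library(g, cfg)
        params = pm.ScreenParams()
        for rate in (0.2, 0.3):
            t, tlog = pm.diverge_genome(g, pm.DivergenceScenario("x", rate), seed=5)
            frac = retention_fraction_at_truth(lib, t, log, tlog, params)
            n = len(lib)
            p = 1 - stats.binom.cdf(31, 45, 1 - rate)
            lo, hi = stats.binom.interval(0.9973, n, p)
            assert lo <= frac * n <= hi

    def test_screen_retention_monotone_in_divergence(self):
        cfg = small_config(seed=12, lengths=(180_000, 140_000))
        g, _ = pm.simulate_reference_genome(cfg)
        lib, _ = pm.design_oligo_library(g, cfg)
        fracs = []
        for rate in (0.0, 0.05, 0.10, 0.20, 0.30):
            t, _ = pm.diverge_genome(g, pm.DivergenceScenario("x", rate), seed=6)
            aset = pm.screen_library(lib, t, pm.ScreenParams(seed_k=10))
            fracs.append(sum(aset.retained_per_set().values()) / len(lib))
        assert fracs[0] == 1.0
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] > fracs[2] > fracs[4]  # strict across the wide gaps

    def test_translocation_moves_segment_and_rdna_tag(self):
        cfg = small_config(seed=13, lengths=(30_000, 30_000))
        g, _ = pm.simulate_reference_genome(cfg)
        trans = pm.Translocation("chr1", 1000, 3000, "chr2", 500, tag="5S")
        t, log = pm.diverge_genome(g, SCENARIOS["identity"], [trans], seed=7)
        assert t["tchr1"].length_bp == 28_000
        assert t["tchr2"].length_bp == 32_000
        moved = g["chr1"].sequence[1000:3000]
        assert t["tchr2"].sequence[500:2500] == moved
        assert log.rdna["5S"] == {"chrom": "tchr2", "start": 500, "end": 2500}

    def test_overlapping_rearrangements_rejected(self):
        cfg = small_config(seed=13, lengths=(30_000, 30_000))
        g, _ = pm.simulate_reference_genome(cfg)
        with pytest.raises(ValueError, match="overlapping"):
            pm.diverge_genome(
                g, SCENARIOS["identity"],
                [pm.Translocation("chr1", 0, 2000, "chr2", 0),
                 pm.Translocation("chr1", 1000, 3000, "chr2", 5000)],
                seed=1,
            )

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.DivergenceScenario("bad", 0.8)


class TestPolyploid:
    def test_hexaploid_complement_shape(self):
        cfg = small_config(seed=14, lengths=tuple([12_000] * 10))
        g, _ = pm.simulate_reference_genome(cfg)
        poly, log = pm.polyploidize(g, pm.Ploidy(60, 10), 0.02, seed=8)
        assert len(poly) == 60
        groups = {}
        for name, info in log.chromosomes.items():
            groups.setdefault(info["homoeologous_group"], []).append(name)
        assert len(groups) == 10 and all(len(v) == 6 for v in groups.values())

    def test_zero_jitter_identical_copies(self):
        cfg = small_config(seed=15, lengths=(12_000, 12_000))
        g, _ = pm.simulate_reference_genome(cfg)
        poly, _ = pm.polyploidize(g, pm.Ploidy(4, 2), 0.0, seed=9)
        assert poly["chr1_h1"].sequence == poly["chr1_h2"].sequence == g["chr1"].sequence

    def test_wrong_basic_number_rejected(self):
        cfg = small_config(seed=15, lengths=(12_000, 12_000))
        g, _ = pm.simulate_reference_genome(cfg)
        with pytest.raises(ValueError, match="basic number"):
            pm.polyploidize(g, pm.Ploidy(60, 10), 0.0, seed=1)


class TestMeasurements:
    def test_zero_noise_recovers_truth_exactly(self):
        arms = {"Chr.1": (2.02, 1.56), "Chr.2": (2.03, 1.54)}
        recs = pm.simulate_measurements(arms, noise_sd_um=0.0, n_cells=3,
                                        copies_per_cell=4, seed=1)
        rows = {r.chrom_label: r for r in pm.summarize_karyotype(recs)}
        for label, (lt, st) in arms.items():
            assert rows[label].long_mean == pytest.approx(lt)
            assert rows[label].short_mean == pytest.approx(st)
            assert rows[label].ratio_mean == pytest.approx(lt / st)
            assert rows[label].total_sd == pytest.approx(0.0)

    def test_missing_copies_thin_records_but_summaries_hold(self):
        arms = {f"Chr.{i}": (2.0, 1.0) for i in range(1, 11)}
        recs = pm.simulate_measurements(arms, noise_sd_um=0.1, n_cells=10,
                                        copies_per_cell=6, missing_copy_rate=0.1,
                                        seed=2)
        assert len(recs) < 10 * 60
        rows = pm.summarize_karyotype(recs)
        assert len(rows) == 10 and all(r.n_cells == 10 for r in rows)

    def test_records_ordered_long_ge_short(self):
        arms = {"Chr.10": (1.38, 1.21)}  # close arms: swaps must be repaired
        recs = pm.simulate_measurements(arms, noise_sd_um=0.3, n_cells=5,
                                        copies_per_cell=6, seed=3)
        assert all(r.long_arm_um >= r.short_arm_um > 0 for r in recs)


class TestPresets:
    def test_preset_reproducible_and_complete(self, tmp_path):
        b1 = pm.generate_preset("sorghum-like", seed=21, length_scale=0.04)
        b2 = pm.generate_preset("sorghum-like", seed=21, length_scale=0.04)
        assert fasta_text(b1["target"]) == fasta_text(b2["target"])
        assert [r.sequence for r in b1["library"]] == [r.sequence for r in b2["library"]]
        paths = pm.write_preset_inputs(b1, tmp_path)
        assert all(p.exists() for p in paths.values())
        # truth covers every oligo and every chromosome of both genomes
        truth = pm.TruthLog.from_json(paths["truth"])
        assert set(truth.oligos) == {r.oligo_id for r in b1["library"]}
        for genome in (b1["reference"], b1["target"]):
            assert set(genome.chrom_names) <= set(truth.chromosomes)

    def test_tripidium_preset_moves_5s_to_chr5_analog(self):
        b = pm.generate_preset("tripidium-like", seed=22, length_scale=0.03)
        assert b["truth"].rdna["reference"]["5S"]["chrom"] == "chr9"
        assert b["truth"].rdna["target"]["5S"]["chrom"] == "tchr5"
        assert b["truth"].rdna["target"]["35S"]["chrom"] == "tchr6"
        assert len(b["target"]) == 60

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            pm.generate_preset("nope", seed=1)
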