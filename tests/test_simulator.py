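import numpy as np
import pytest

from amperr.library import assemble_construct
from amperr.simulate import (DecliningQuality, FixedLength, FlatQuality, NoisyQuality,
                             PlatformErrorModel, TruncatedLength,
                             homopolymer_indel_enrichment, preset, replay, simulate_run)


def _noise_free(length=250):
    return PlatformErrorModel(subst_rate=0.0, indel_rate=0.0,
                              length_model=FixedLength(length))


class TestPresets:
    @pytest.mark.parametrize("tag,subst,indel", [
        ("flx454", 0.0007, 0.0018),
        ("pgm", 0.0013, 0.0060),
        ("miseq", 0.0153, 0.0004),
    ])
    def test_published_run_rates(self, tag, subst, indel):
        model = preset(tag)
        assert model.subst_rate == subst
        assert model.indel_rate == indel

    def test_flow_platforms_have_homopolymer_scaling(self):
        assert preset("flx454").homopolymer_indel_factor > 1
        assert preset("pgm").homopolymer_indel_factor > 1
        assert preset("miseq").homopolymer_indel_factor == 1.0

    def test_unknown_tag(self):
        with pytest.raises(ValueError):
            preset("solid")


class TestDeterminism:
    def test_same_seed_identical_output(self, panel, miseq_spec, barcodes16):
        model = preset("miseq")
        r1, _ = simulate_run(panel, miseq_spec, barcodes16, model, 200, seed=42)
        r2, _ = simulate_run(panel, miseq_spec, barcodes16, model, 200, seed=42)
        assert all(a.bases == b.bases and (a.quals == b.quals).all()
                   for a, b in zip(r1, r2))

    def test_different_seed_differs(self, panel, miseq_spec, barcodes16):
        model = preset("miseq")
        r1, _ = simulate_run(panel, miseq_spec, barcodes16, model, 50, seed=1)
        r2, _ = simulate_run(panel, miseq_spec, barcodes16, model, 50, seed=2)
        assert any(a.bases != b.bases for a, b in zip(r1, r2))


class TestErrorInjection:
    def test_zero_rates_emit_exact_constructs(self, panel, miseq_spec, barcodes16):
        reads, log = simulate_run(panel, miseq_spec, barcodes16, _noise_free(1000),
                                  50, seed=7)
        refs_by_name = {r.name: r for r in panel}
        from amperr.io import reverse_complement
        for read, rec in zip(reads, log.reads):
            insert = refs_by_name[rec["ref_name"]].seq
            if rec["strand"] == "-":
                insert = reverse_complement(insert)
            construct = assemble_construct(
                miseq_spec, barcodes16.entries[rec["sample_id"]], insert)
            assert read.bases == construct
        assert log.totals["sub_total"] == 0 and log.events == []

    def test_injected_substitution_count_binomial(self, panel, miseq_spec, barcodes16):
        # ~1e6 template bases at rate 0.01: count within 3 binomial SD of n*p
        model = PlatformErrorModel(subst_rate=0.01, indel_rate=0.0,
                                   length_model=FixedLength(250))
        _, log = simulate_run(panel, miseq_spec, barcodes16, model, 4000, seed=13)
        n = log.totals["template_bases"]
        assert n >= 1_000_000
        expected = n * 0.01
        tol = 3 * np.sqrt(n * 0.01 * 0.99)
        assert abs(log.totals["sub_total"] - expected) <= tol

    def test_replay_reproduces_emitted_reads(self, panel, pgm_spec, barcodes10):
        reads, log = simulate_run(panel, pgm_spec, barcodes10, preset("pgm"), 300, seed=3)
        rebuilt = replay(log, panel, pgm_spec, barcodes10)
        assert [r.bases for r in reads] == rebuilt

    def test_homopolymer_indel_enrichment(self, panel, flx454_spec, barcodes10):
        model = PlatformErrorModel(subst_rate=0.0, indel_rate=0.0018,
                                   homopolymer_indel_factor=1.8,
                                   length_model=FixedLength(500))
        _, log = simulate_run(panel, flx454_spec, barcodes10, model, 8000, seed=21)
        out = homopolymer_indel_enrichment(log)
        assert out["bases_in_runs"] >= 100_000
        assert out["rate_in_runs"] > out["rate_out_runs"]
        assert out["pvalue"] < 0.01


class TestLengthAndQualityModels:
    def test_fixed_length_truncates(self, panel, miseq_spec, barcodes16):
        reads, _ = simulate_run(panel, miseq_spec, barcodes16, _noise_free(250), 30, seed=5)
        assert {len(r) for r in reads} == {250}

    def test_truncated_model_produces_short_tail(self, panel, pgm_spec, barcodes10):
        model = PlatformErrorModel(subst_rate=0, indel_rate=0,
                                   length_model=TruncatedLength(380, keep_full=0.55,
                                                                tail_mean=170.0))
        reads, _ = simulate_run(panel, pgm_spec, barcodes10, model, 400, seed=9)
        lengths = np.array([len(r) for r in reads])
        full = min(380, lengths.max())
        assert (lengths == full).mean() > 0.4
        assert (lengths < full - 50).mean() > 0.1

    def test_quality_models(self, panel, miseq_spec, barcodes16):
        flat, _ = simulate_run(panel, miseq_spec, barcodes16,
                               PlatformErrorModel(0, 0, length_model=FixedLength(100),
                                                  quality_model=FlatQuality(38)),
                               5, seed=1)
        assert all((r.quals == 38).all() for r in flat)
        dec, _ = simulate_run(panel, miseq_spec, barcodes16,
                              PlatformErrorModel(0, 0, length_model=FixedLength(300),
                                                 quality_model=DecliningQuality(38, 0.02)),
                              5, seed=1)
        assert all(r.quals[0] > r.quals[-1] for r in dec)
        noisy, _ = simulate_run(panel, miseq_spec, barcodes16,
                                PlatformErrorModel(0, 0, length_model=FixedLength(100),
                                                   quality_model=NoisyQuality(32, 2.5)),
                                5, seed=1)
        assert all((r.quals >= 2).all() and (r.quals <= 40).all() for r in noisy)


class TestValidation:
    def test_bad_bias_rejected(self):
        bias = np.full((4, 4), 0.25)
        with pytest.raises(ValueError):
            PlatformErrorModel(subst_rate=0.01, indel_rate=0.0, subst_bias=bias)

    def test_zero_reads_rejected(self, panel, miseq_spec, barcodes16):
        with pytest.raises(ValueError):
            simulate_run(panel, miseq_spec, barcodes16, _noise_free(), 0, seed=1)

    def test_mismatched_barcode_length_rejected(self, panel, miseq_spec, barcodes10):
        with pytest.raises(ValueError, match="barcode"):
            simulate_run(panel, miseq_spec, barcodes10, _noise_free(), 5, seed=1)
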