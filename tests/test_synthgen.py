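"""Synthetic-benchmark generator: determinism, laws and round-trips."""

import numpy as np
import pytest

from idrbench import caid_io, metrics, significance, stratify, synthgen
from idrbench.af2_transform import plddt_to_disorder, smooth_rsa
from idrbench.metrics import roc_auc


def pooled(entries, profiles):
    scores = np.concatenate([p.scores for p in profiles])
    labels = np.concatenate([e.disorder for e in entries])
    return scores, labels


class TestGenReference:
    def test_seed_determinism(self):
        cfg = synthgen.GenConfig(n_proteins=30, seed=5)
        a = synthgen.gen_reference(cfg)
        b = synthgen.gen_reference(cfg)
        for ea, eb in zip(a, b):
            assert ea.sequence == eb.sequence
            np.testing.assert_array_equal(ea.disorder, eb.disorder)
            np.testing.assert_array_equal(ea.binding, eb.binding)

    def test_zero_terminus_probability_keeps_idrs_internal(self):
        cfg = synthgen.GenConfig(
            n_proteins=500, seed=2, p_terminus=0.0, p_fdp=0.0,
            mean_ordered_len=200.0, mean_idr_len=20.0, length_log_mean=5.0,
        )
        for entry in synthgen.gen_reference(cfg):
            segments = stratify.extract_idrs(entry.disorder)
            assert not any(s.at_terminus for s in segments)

    def test_run_length_law_orders_median_idr_length(self):
        base = dict(n_proteins=150, seed=3, p_fdp=0.0)
        long_cfg = synthgen.GenConfig(mean_idr_len=50.0, **base)
        short_cfg = synthgen.GenConfig(mean_idr_len=10.0, **base)

        def median_idr(cfg):
            lengths = [
                s.length
                for e in synthgen.gen_reference(cfg)
                for s in stratify.extract_idrs(e.disorder)
            ]
            return np.median(lengths)

        assert median_idr(long_cfg) > median_idr(short_cfg)

    def test_binding_is_painted_on_whole_runs(self):
        cfg = synthgen.GenConfig(n_proteins=100, seed=4, p_binding=0.5)
        for entry in synthgen.gen_reference(cfg):
            segments = stratify.extract_idrs(entry.disorder)
            for seg in segments:
                run = entry.binding[seg.start - 1:seg.end]
                assert run.min() == run.max()  # all-or-nothing per region
            # binding labels never outside disordered runs
            assert not np.any(entry.binding & (1 - entry.disorder))

    def test_prevalence_converges_to_run_length_law(self):
        # long chains: terminus boundary effects on the run process vanish
        cfg = synthgen.GenConfig(n_proteins=40, seed=6, p_fdp=0.0,
                                 p_terminus=0.0, length_log_mean=8.0)
        entries = synthgen.gen_reference(cfg)
        labels = np.concatenate([e.disorder for e in entries])
        assert labels.size > 100_000
        expected = cfg.mean_idr_len / (cfg.mean_idr_len + cfg.mean_ordered_len)
        assert labels.mean() == pytest.approx(expected, abs=0.02)


class TestGenPredictor:
    def test_uninformative_scores_give_half_auc(self):
        cfg = synthgen.GenConfig(n_proteins=300, seed=7)
        entries = synthgen.gen_reference(cfg)
        profiles = synthgen.gen_predictor(entries, (0.5, 0.5, 1.0), seed=7)
        scores, labels = pooled(entries, profiles)
        assert labels.size > 100_000
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.01)

    def test_closed_form_binormal_target(self):
        cfg = synthgen.GenConfig(n_proteins=200, seed=8)
        entries = synthgen.gen_reference(cfg)
        profiles = synthgen.gen_predictor(entries, (0.0, 1.0, 1.0), seed=8)
        scores, labels = pooled(entries, profiles)
        expected = synthgen.binormal_auc(0.0, 1.0, 1.0)  # Phi(1/sqrt(2))
        assert expected == pytest.approx(0.7602, abs=1e-3)
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=0.01)

    def test_stronger_method_earns_plus_verdict(self):
        cfg = synthgen.GenConfig(n_proteins=100, seed=9)
        entries = synthgen.gen_reference(cfg)
        references = {e.id: e for e in entries}
        strong = {p.id: p for p in synthgen.gen_predictor(entries, (0.0, 1.5, 1.0),
                                                          seed=9, method="strong")}
        weak = {p.id: p for p in synthgen.gen_predictor(entries, (0.0, 0.5, 1.0),
                                                        seed=9, method="weak")}
        plan = significance.make_subsets(sorted(references), "disjoint_5pct", seed=9)

        def evaluator(profiles):
            def evaluate(ids):
                scores = np.concatenate([profiles[i].scores for i in ids])
                labels = np.concatenate([references[i].disorder for i in ids])
                return metrics.roc_auc(scores, labels)
            return evaluate

        series_a = significance.subset_metric_series(plan, evaluator(strong))
        series_b = significance.subset_metric_series(plan, evaluator(weak))
        verdict = significance.paired_verdict(series_a, series_b)
        assert verdict.symbol == "+"


class TestGenAf2Series:
    def test_zero_quality_is_uninformative(self):
        cfg = synthgen.GenConfig(n_proteins=150, seed=10)
        entries = synthgen.gen_reference(cfg)
        plddt, _ = synthgen.gen_af2_series(entries, quality=0.0, seed=10)
        scores = np.concatenate([plddt_to_disorder(s).scores for s in plddt])
        labels = np.concatenate([e.disorder for e in entries])
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_auc_increases_with_quality(self):
        cfg = synthgen.GenConfig(n_proteins=120, seed=11)
        entries = synthgen.gen_reference(cfg)
        labels = np.concatenate([e.disorder for e in entries])
        aucs = []
        for quality in (0.5, 1.0, 2.0):
            plddt, rsa = synthgen.gen_af2_series(entries, quality=quality, seed=11)
            p_scores = np.concatenate([plddt_to_disorder(s).scores for s in plddt])
            r_scores = np.concatenate([smooth_rsa(s).scores for s in rsa])
            aucs.append((roc_auc(p_scores, labels), roc_auc(r_scores, labels)))
        assert aucs[0][0] < aucs[1][0] < aucs[2][0]
        assert aucs[0][1] < aucs[1][1] < aucs[2][1]

    def test_smoothing_helps_long_idrs_more_than_short(self):
        base = dict(n_proteins=150, p_fdp=0.0, length_log_mean=5.5)
        long_entries = synthgen.gen_reference(
            synthgen.GenConfig(mean_idr_len=60.0, seed=12, **base))
        short_entries = synthgen.gen_reference(
            synthgen.GenConfig(mean_idr_len=8.0, mean_ordered_len=45.0,
                               seed=12, **base))

        def gain(entries):
            _, rsa = synthgen.gen_af2_series(entries, quality=1.0, seed=12)
            labels = np.concatenate([e.disorder for e in entries])
            raw = np.concatenate([s.values for s in rsa])
            smoothed = np.concatenate([smooth_rsa(s).scores for s in rsa])
            return roc_auc(smoothed, labels) - roc_auc(raw, labels)

        assert gain(long_entries) > gain(short_entries)


class TestRoundTrips:
    def test_generated_artifacts_survive_io(self, tmp_path):
        cfg = synthgen.GenConfig(n_proteins=20, seed=13)
        entries = synthgen.gen_reference(cfg)
        ref_path = tmp_path / "ref.txt"
        bind_path = tmp_path / "bind.txt"
        caid_io.write_reference(entries, ref_path)
        caid_io.write_reference(entries, bind_path, labels="binding")
        back = caid_io.read_reference(ref_path, bind_path)
        assert len(back) == len(entries)
        for a, b in zip(entries, back):
            assert a.id == b.id and a.sequence == b.sequence
            np.testing.assert_array_equal(a.disorder, b.disorder)
            np.testing.assert_array_equal(a.binding, b.binding)
        profiles = synthgen.gen_predictor(entries, (0.0, 1.0, 1.0), seed=13)
        pred_path = tmp_path / "pred.txt"
        caid_io.write_prediction(profiles, pred_path)
        back_profiles = caid_io.read_prediction(pred_path)
        for a, b in zip(profiles, back_profiles):
            assert a.id == b.id
            np.testing.assert_allclose(a.scores, b.scores, atol=5e-4)


class TestParameterRecovery:
    def test_content_error_decreases_with_separation(self):
        cfg = synthgen.GenConfig(n_proteins=150, seed=14)
        entries = synthgen.gen_reference(cfg)
        references = {e.id: e for e in entries}
        maes = []
        for separation in (0.5, 1.5, 3.0):
            profiles = synthgen.gen_predictor(entries, (0.0, separation, 1.0),
                                              seed=14)
            t = metrics.calibrate_threshold(profiles, references)
            pred = [metrics.disorder_content(metrics.binarize(p, t).binary)
                    for p in profiles]
            native = [references[p.id].disorder_content for p in profiles]
            maes.append(metrics.content_mae(pred, native))
        assert maes[0] > maes[1] > maes[2]
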